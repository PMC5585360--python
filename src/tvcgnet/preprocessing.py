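"""Signal preprocessing chains evaluated by the classifier pipeline.

Three chains are supported:

``de_chazal``
    Baseline estimation by a cascade of running medians (200 ms then
    600 ms windows) subtracted from the signal, followed by a 12-tap
    linear-phase FIR low-pass with its -3 dB point at 35 Hz.
``common``
    The same 12-tap low-pass followed by a high-pass with -3 dB at 1 Hz.
    A 12-tap FIR cannot place a -3 dB corner at 1 Hz at ECG sampling
    rates, so the high-pass is realized as the spectral complement of a
    long (1.5 s) linear-phase low-pass: ``hp(x) = x - lp_long(x)``.
``none``
    Identity.

All chains preserve signal length; FIR group delay is compensated by a
forward shift.  Filter corners are tuned numerically so the realized
response meets the stated -3 dB frequency for the given tap count.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_data import ECGRecord

FILTER_NAMES = ("de_chazal", "common", "none")
_SQRT_HALF = 2.0 ** -0.5


@dataclass(frozen=True)
class FilterSpec:
    name: str
    fs: float

    def __post_init__(self) -> None:
        if self.name not in FILTER_NAMES:
            raise ValueError(f"unknown filter {self.name!r}; use {FILTER_NAMES}")


def _odd_window(ms: float, fs: float) -> int:
    w = int(round(ms * fs / 1000.0))
    return max(1, w if w % 2 else w + 1)


def median_baseline(x: np.ndarray, fs: float) -> np.ndarray:
    """Baseline estimate: 200 ms running median, then 600 ms running median
    of that result.  Window lengths are rounded to the nearest odd sample
    count; edges are handled by shrinking windows (length is preserved)."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("signal must be non-empty")
    out = pd.Series(x)
    for ms in (200.0, 600.0):
        w = _odd_window(ms, fs)
        out = out.rolling(w, center=True, min_periods=1).median()
    return out.to_numpy()


def _amplitude_response(taps: np.ndarray, f: float, fs: float) -> float:
    """Real amplitude of a linear-phase FIR at frequency f (delay removed)."""
    n = np.arange(len(taps))
    delay = (len(taps) - 1) / 2.0
    return float(np.real(np.sum(taps * np.exp(-2j * np.pi * f / fs * (n - delay)))))


def _tune_cutoff(numtaps: int, fs: float, f3db: float, target: float,
                 lo: float, hi: float) -> np.ndarray:
    """Bisect the firwin cutoff until |H(f3db)| hits ``target`` (1/sqrt(2)
    for a low-pass corner, 1 - 1/sqrt(2) for the complement high-pass)."""
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        h = sps.firwin(numtaps, mid, fs=fs)
        if _amplitude_response(h, f3db, fs) < target:
            lo = mid
        else:
            hi = mid
    return sps.firwin(numtaps, 0.5 * (lo + hi), fs=fs)


@lru_cache(maxsize=8)
def lowpass_taps(fs: float, numtaps: int = 12, f3db: float = 35.0) -> np.ndarray:
    """12-tap Hamming-window FIR low-pass tuned to -3 dB at ``f3db``."""
    if fs <= 2 * f3db:
        raise ValueError(f"fs={fs} too low for a {f3db} Hz corner")
    return _tune_cutoff(numtaps, fs, f3db, _SQRT_HALF, f3db / 4, fs / 2 * 0.999)


@lru_cache(maxsize=8)
def highpass_complement_taps(fs: float, f3db: float = 1.0,
                             length_s: float = 1.5) -> np.ndarray:
    """Long odd-length low-pass whose complement is a -3 dB@``f3db``
    high-pass."""
    numtaps = int(round(length_s * fs))
    if numtaps % 2 == 0:
        numtaps += 1
    # complement amplitude 1 - H(f3db) = 1/sqrt(2)  =>  H(f3db) = 1 - 1/sqrt(2)
    return _tune_cutoff(numtaps, fs, f3db, 1.0 - _SQRT_HALF,
                        f3db / 50, fs / 2 * 0.5)


def _fir_apply(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Convolve and shift forward by the (floor of the) group delay so the
    output stays aligned and length-preserved."""
    delay = (len(taps) - 1) // 2
    full = np.convolve(x, taps, mode="full")
    return full[delay:delay + len(x)]


def apply_filter(record: ECGRecord, spec: FilterSpec) -> ECGRecord:
    """Apply the named preprocessing chain to both leads of a record."""
    if spec.name == "none":
        return record
    if record.fs <= 70:
        raise ValueError(f"fs={record.fs} too low for the 35 Hz low-pass")
    lp = lowpass_taps(record.fs)

    def chain(x: np.ndarray) -> np.ndarray:
        if spec.name == "de_chazal":
            y = x - median_baseline(x, record.fs)
            return _fir_apply(y, lp)
        # common: low-pass then complement high-pass
        y = _fir_apply(x, lp)
        hp = highpass_complement_taps(record.fs)
        return y - _fir_apply(y, hp)

    return replace_signal(record, chain(record.lead_a), chain(record.lead_b))


def replace_signal(record: ECGRecord, lead_a: np.ndarray,
                   lead_b: np.ndarray) -> ECGRecord:
    return ECGRecord(record_id=record.record_id, fs=record.fs,
                     lead_a=lead_a, lead_b=lead_b, beats=list(record.beats))
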