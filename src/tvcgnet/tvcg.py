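"""Beat windows and (temporal) vectorcardiogram point sets.

A heartbeat is analysed in a fixed window around its annotated R point
([-250 ms, +450 ms] by default, wide enough for every morphological sampling
region).  The vectorcardiogram (VCG) plots lead A against lead B, discarding
time; the temporal vectorcardiogram (TVCG) keeps time as a third axis, so a
beat becomes an ordered 3-D point cloud.  Each TVCG axis is min-max
normalized to [0, 1] before any distance computation, so that the time axis
(in samples) does not dominate Euclidean edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io_data import ECGRecord, map_to_superclass

logger = logging.getLogger(__name__)

WINDOW_PRE_MS = 250.0
WINDOW_POST_MS = 450.0
DEFAULT_SUBSAMPLE_STEP = 2


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero toward +inf."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class Fiducials:
    """Landmark sample indices for one beat (record- or window-relative)."""

    r_index: int
    qrs_onset: int
    qrs_offset: int
    t_end: int
    p_wave_present: bool

    def __post_init__(self) -> None:
        if not (self.qrs_onset < self.r_index < self.qrs_offset <= self.t_end):
            raise ValueError(
                "fiducials must satisfy qrs_onset < r < qrs_offset <= t_end, "
                f"got {self}"
            )

    def shifted(self, offset: int) -> "Fiducials":
        return replace(
            self,
            r_index=self.r_index + offset,
            qrs_onset=self.qrs_onset + offset,
            qrs_offset=self.qrs_offset + offset,
            t_end=self.t_end + offset,
        )


@dataclass
class BeatWindow:
    """A fixed-length two-lead excerpt around one annotated R point.

    RR context is attached in seconds: the interval to the previous beat
    (pre), to the next beat (post), and the local average of the pre-RR
    intervals of the surrounding beats.
    """

    lead_a: np.ndarray
    lead_b: np.ndarray
    fs: float
    fiducials: Fiducials  # window-relative
    label: str
    pre_rr_s: float
    post_rr_s: float
    local_rr_s: float

    def __post_init__(self) -> None:
        self.lead_a = np.asarray(self.lead_a, float)
        self.lead_b = np.asarray(self.lead_b, float)
        if self.lead_a.shape != self.lead_b.shape:
            raise ValueError("both leads must have the same window length")
        n = len(self.lead_a)
        f = self.fiducials
        if not (0 <= f.qrs_onset and f.t_end < n):
            raise ValueError("fiducials must lie inside the window")


@dataclass(frozen=True)
class TVCGPoints:
    """Ordered 3-D point set of a beat: (lead A, lead B, time), each axis
    min-max normalized to [0, 1]."""

    points: np.ndarray  # (n_v, 3)

    @property
    def n_v(self) -> int:
        return len(self.points)


def window_bounds(fs: float, pre_ms: float = WINDOW_PRE_MS,
                  post_ms: float = WINDOW_POST_MS) -> tuple[int, int]:
    """Samples before / after the R point included in a beat window."""
    return round_half_up(pre_ms * fs / 1000.0), round_half_up(post_ms * fs / 1000.0)


def _clip_fiducials(f: Fiducials, n: int) -> Fiducials:
    """Clamp window-relative fiducials into [0, n-1] preserving ordering."""
    r = int(np.clip(f.r_index, 1, n - 2))
    onset = int(np.clip(f.qrs_onset, 0, r - 1))
    offset = int(np.clip(f.qrs_offset, r + 1, n - 1))
    t_end = int(np.clip(f.t_end, offset, n - 1))
    return Fiducials(r, onset, offset, t_end, f.p_wave_present)


def extract_beat_window(
    record: ECGRecord,
    beat_index: int,
    fiducials: Fiducials | None = None,
    pre_ms: float = WINDOW_PRE_MS,
    post_ms: float = WINDOW_POST_MS,
    n_local: int = 10,
) -> BeatWindow:
    """Cut the analysis window around the ``beat_index``-th annotated beat.

    Parameters
    ----------
    fiducials : Fiducials, optional
        Record-absolute landmarks for this beat (e.g. from the synthetic
        detector).  When omitted, nominal landmarks are placed at R -/+ 50 ms
        (QRS) and R + 300 ms (T end) with the P wave assumed present.
    n_local : int
        Number of surrounding beats whose pre-RR intervals enter the local
        average (shrinking at record edges).

    Raises
    ------
    ValueError
        If the record has fewer than two beats (RR features undefined).
    """
    beats = record.beat_samples()
    if len(beats) < 2:
        raise ValueError("RR features undefined on a record with < 2 beats")
    if not 0 <= beat_index < len(beats):
        raise IndexError(f"beat_index {beat_index} out of range")
    r = int(beats[beat_index])
    fs = record.fs
    pre, post = window_bounds(fs, pre_ms, post_ms)
    lo, hi = r - pre, r + post + 1

    def cut(x: np.ndarray) -> np.ndarray:
        pad_lo, pad_hi = max(0, -lo), max(0, hi - len(x))
        if pad_lo or pad_hi:
            logger.debug("zero-padding window at record edge (%d, %d)", pad_lo, pad_hi)
        seg = x[max(lo, 0):min(hi, len(x))]
        return np.pad(seg, (pad_lo, pad_hi))

    rr = np.diff(beats) / fs  # rr[i] = interval between beat i and i+1
    if beat_index == 0:
        post_rr = float(rr[0])
        pre_rr = post_rr  # first beat: fall back to post-RR
        logger.debug("first beat: pre_rr falls back to post_rr")
    elif beat_index == len(beats) - 1:
        pre_rr = float(rr[-1])
        post_rr = pre_rr
        logger.debug("last beat: post_rr falls back to pre_rr")
    else:
        pre_rr = float(rr[beat_index - 1])
        post_rr = float(rr[beat_index])
    half = n_local // 2
    lo_b = max(1, beat_index - half)
    hi_b = min(len(beats) - 1, beat_index + half)
    local = float(np.mean(rr[lo_b - 1:hi_b]))

    if fiducials is None:
        d50 = max(1, round_half_up(0.050 * fs))
        fiducials = Fiducials(r, r - d50, r + d50,
                              r + round_half_up(0.300 * fs), True)
    win_fid = _clip_fiducials(fiducials.shifted(-lo), hi - lo)

    symbol = record.beats[beat_index][1]
    return BeatWindow(
        lead_a=cut(record.lead_a),
        lead_b=cut(record.lead_b),
        fs=fs,
        fiducials=win_fid,
        label=map_to_superclass(symbol),
        pre_rr_s=pre_rr,
        post_rr_s=post_rr,
        local_rr_s=local,
    )


def build_vcg(beat: BeatWindow) -> np.ndarray:
    """2-D vectorcardiogram: point k = (lead_a[k], lead_b[k]); time dropped."""
    return np.column_stack([beat.lead_a, beat.lead_b])


def _minmax(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        logger.debug("constant axis in TVCG; mapped to zeros")
        return np.zeros_like(x)
    return (x - x.min()) / span


def build_tvcg(beat: BeatWindow,
               subsample_step: int = DEFAULT_SUBSAMPLE_STEP) -> TVCGPoints:
    """3-D temporal vectorcardiogram of a beat.

    Every ``subsample_step``-th sample is kept; axes are (lead A, lead B,
    time index), each min-max normalized to [0, 1] over the beat.  A
    constant axis maps to all-zeros.
    """
    if subsample_step < 1:
        raise ValueError("subsample_step must be >= 1")
    x = beat.lead_a[::subsample_step]
    y = beat.lead_b[::subsample_step]
    z = np.arange(len(beat.lead_a), dtype=float)[::subsample_step]
    if len(x) < 2:
        raise ValueError("fewer than 2 points after subsampling")
    pts = np.column_stack([_minmax(x), _minmax(y), _minmax(z)])
    return TVCGPoints(points=pts)
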