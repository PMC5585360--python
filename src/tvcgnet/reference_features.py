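"""Reference feature sets the TVCG descriptors compete against.

Three blocks are computed per beat window:

* ``morph`` (148): amplitudes resampled from four named segments of each
  lead -- 10 across the QRS, 9 from QRS end to the T wave, 10 from
  R - 50 ms to R + 100 ms, 8 from R + 150 ms to R + 500 ms (clipped to the
  window) -- in both absolute and per-lead max-normalized form.
* ``interval`` (13): per-lead QRS duration, T-wave duration and P-wave
  presence, the three RR features (pre, post, local average), and four
  normalized RR ratios.
* ``wavelet`` (7): from a two-level orthonormal Haar DWT of lead A, the
  lag-1 autocorrelation and the relative amplitude min/max of each sub-band
  (D1, D2, A2), plus the variance of the QRS samples.

Together with the m x 5 TVCG block the assembled vector has 148 + 13 + 7 +
5 m dimensions (178 for the default m = 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .complex_network import CNParams, tvcg_feature_names
from .tvcg import BeatWindow

logger = logging.getLogger(__name__)

_SEGMENT_SPEC = (
    # (name, n_samples, start, end) -- start/end resolved per beat below
    ("qrs", 10),
    ("qrs_to_t", 9),
    ("around_r", 10),
    ("late", 8),
)


@dataclass
class FeatureVector:
    """A named feature vector; ``names`` parallels ``values``."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")

    def __len__(self) -> int:
        return len(self.values)


def _resample_segment(x: np.ndarray, start: float, end: float, n: int) -> np.ndarray:
    """n amplitudes at equally spaced positions in [start, end] by linear
    interpolation; a degenerate segment repeats the single amplitude."""
    if end < start:
        start, end = end, start
    pos = np.linspace(start, end, n)
    return np.interp(pos, np.arange(len(x)), x)


def morphology_samples(beat: BeatWindow) -> FeatureVector:
    """148 raw-wave amplitudes: 37 per lead, absolute and normalized."""
    f = beat.fiducials
    fs = beat.fs
    n = len(beat.lead_a)
    r = f.r_index

    def clip(v: float) -> float:
        vv = float(np.clip(v, 0, n - 1))
        if vv != v:
            logger.debug("morphology segment endpoint clipped to window")
        return vv

    segments = {
        "qrs": (f.qrs_onset, f.qrs_offset),
        "qrs_to_t": (f.qrs_offset, f.t_end),
        "around_r": (clip(r - 0.050 * fs), clip(r + 0.100 * fs)),
        "late": (clip(r + 0.150 * fs), clip(r + 0.500 * fs)),
    }
    values: list[float] = []
    names: list[str] = []
    for lead_name, x in (("a", beat.lead_a), ("b", beat.lead_b)):
        maxabs = float(np.max(np.abs(x)))
        raw: list[float] = []
        raw_names: list[str] = []
        for seg_name, count in _SEGMENT_SPEC:
            lo, hi = segments[seg_name]
            samp = _resample_segment(x, lo, hi, count)
            raw.extend(samp)
            raw_names.extend(f"morph_{lead_name}_{seg_name}_{k}" for k in range(count))
        values.extend(raw)
        names.extend(f"{nm}_abs" for nm in raw_names)
        if maxabs == 0:
            logger.debug("all-zero lead; normalized morphology set to 0")
            values.extend([0.0] * len(raw))
        else:
            values.extend(v / maxabs for v in raw)
        names.extend(f"{nm}_norm" for nm in raw_names)
    return FeatureVector(np.array(values), names)


def interval_features(beat: BeatWindow) -> FeatureVector:
    """13 fiducial/rhythm features: 3 RR, per-lead QRS duration, T duration
    and P presence, and 4 normalized RR ratios."""
    f = beat.fiducials
    fs = beat.fs
    qrs_dur = (f.qrs_offset - f.qrs_onset) / fs
    t_dur = (f.t_end - f.qrs_offset) / fs
    p_flag = 1.0 if f.p_wave_present else 0.0
    pre, post, local = beat.pre_rr_s, beat.post_rr_s, beat.local_rr_s

    def ratio(a: float, b: float) -> float:
        return a / b if b else 0.0

    values = [
        pre, post, local,
        qrs_dur, t_dur, p_flag,        # lead A
        qrs_dur, t_dur, p_flag,        # lead B (shared fiducials)
        ratio(pre, local), ratio(post, local), ratio(pre, post),
        ratio(0.5 * (pre + post), local),
    ]
    names = [
        "int_pre_rr", "int_post_rr", "int_local_rr",
        "int_a_qrs_dur", "int_a_t_dur", "int_a_p_present",
        "int_b_qrs_dur", "int_b_t_dur", "int_b_p_present",
        "int_pre_over_local", "int_post_over_local", "int_pre_over_post",
        "int_mean_over_local",
    ]
    return FeatureVector(np.array(values), names)


def autocorrelation(x: np.ndarray, lag: int = 1) -> float:
    """Raw (unnormalized) autocorrelation sum(x[n] x[n-lag]) for n >= lag."""
    x = np.asarray(x, float)
    if lag >= len(x):
        return 0.0
    return float(np.dot(x[lag:], x[:len(x) - lag]))


def relative_amplitude(x: np.ndarray) -> float:
    """min(x)/max(x); 0 when max(x) = 0."""
    mx = float(np.max(x))
    if mx == 0:
        logger.debug("relative amplitude with max 0 -> feature set to 0")
        return 0.0
    return float(np.min(x)) / mx


def haar_features(beat: BeatWindow) -> FeatureVector:
    """7 wavelet/autocorrelation features from lead A."""
    x = beat.lead_a
    if len(x) < 4:
        raise ValueError("lead_a must have length >= 4 for a 2-level DWT")
    a2, d2, d1 = pywt.wavedec(x, "haar", level=2)
    f = beat.fiducials
    qrs = x[f.qrs_onset:f.qrs_offset + 1]
    values, names = [], []
    for band_name, band in (("d1", d1), ("d2", d2), ("a2", a2)):
        values.append(autocorrelation(band, 1))
        names.append(f"wav_{band_name}_ac1")
        values.append(relative_amplitude(band))
        names.append(f"wav_{band_name}_relamp")
    values.append(float(np.var(qrs)))
    names.append("wav_qrs_var")
    return FeatureVector(np.array(values), names)


def assemble_features(beat: BeatWindow, cn: np.ndarray,
                      cn_params: CNParams) -> FeatureVector:
    """Concatenate [morph, interval, wavelet, tvcg] for one beat."""
    cn = np.asarray(cn, float)
    if len(cn) != 5 * cn_params.m:
        raise ValueError(
            f"TVCG block has length {len(cn)}, expected {5 * cn_params.m}"
        )
    blocks = [morphology_samples(beat), interval_features(beat),
              haar_features(beat)]
    values = np.concatenate([b.values for b in blocks] + [cn])
    names = sum((b.names for b in blocks), []) + tvcg_feature_names(cn_params)
    return FeatureVector(values, names)


class FeatureStandardizer:
    """Per-feature z-score standardization fitted on training data only.

    Undefined features (zero variance, or NaN from degenerate inputs) map
    to 0 after standardization so the vector length stays fixed for the
    feature-selection mask.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureStandardizer":
        X = np.asarray(X, float)
        self.mean_ = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("standardizer not fitted")
        Z = (np.asarray(X, float) - self.mean_) / self.scale_
        bad = ~np.isfinite(Z)
        if bad.any():
            logger.debug("imputed %d undefined standardized features to 0",
                         int(bad.sum()))
            Z[bad] = 0.0
        return Z

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def checksum(self) -> str:
        """Stable digest of the fitted parameters, for reuse assertions."""
        import hashlib
        if self.mean_ is None:
            raise RuntimeError("standardizer not fitted")
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.mean_).tobytes())
        h.update(np.ascontiguousarray(self.scale_).tobytes())
        return h.hexdigest()
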