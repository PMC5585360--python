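"""Seeded synthetic two-lead heartbeat records with class-dependent structure.

The generator is not a biophysical simulator: each beat is a sum of
truncated Gaussian bumps (P wave, QRS complex, T wave) per lead, placed at
RR intervals scaled by a per-class prematurity factor, on top of sinusoidal
baseline wander and white noise.  The class structure mirrors what matters
for arrhythmia features:

* ventricular ectopic (V) beats have a wider QRS than normal (N) beats and
  no P wave;
* supraventricular ectopic (S) beats are premature (shortened pre-RR) and a
  premature beat is followed by a compensatory pause;
* every "patient" (record) carries its own small random morphology offset,
  so inter-patient splits are meaningful in tests.

Bumps are truncated at four standard deviations, so with noise and wander
disabled the sample at each QRS centre equals the configured QRS amplitude
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_data import ECGRecord
from .tvcg import Fiducials, round_half_up

#: canonical annotation symbol emitted per superclass
CLASS_SYMBOL = {"N": "N", "S": "A", "V": "V", "F": "F", "Q": "Q"}

_P_CENTER_MS = -160.0
_P_SD_MS = 22.0
_T_CENTER_MS = 260.0
_T_SD_MS = 40.0
_TRUNC_SD = 4.0


@dataclass(frozen=True)
class ClassParams:
    """Morphology parameters of one beat superclass."""

    qrs_width_ms: float
    qrs_amp_mV: tuple[float, float]  # (lead A, lead B)
    p_amp_mV: float
    t_amp_mV: float
    prematurity_factor: float


def _default_class_params() -> dict[str, ClassParams]:
    return {
        "N": ClassParams(80.0, (1.00, 0.55), 0.15, 0.30, 1.00),
        "S": ClassParams(82.0, (0.95, 0.50), 0.08, 0.28, 0.65),
        "V": ClassParams(150.0, (1.25, 0.95), 0.00, -0.40, 0.85),
        "F": ClassParams(115.0, (1.10, 0.75), 0.05, 0.10, 0.90),
        "Q": ClassParams(100.0, (0.60, 0.60), 0.00, 0.15, 1.00),
    }


@dataclass
class SyntheticBeatConfig:
    """Generator configuration; defaults give clearly separable N/S/V beats
    at MIT-BIH-like scale (360 Hz, ~75 bpm, ~1 mV QRS)."""

    fs: float = 360.0
    base_rr_s: float = 0.8
    noise_sd_mV: float = 0.02
    baseline_wander_amp_mV: float = 0.05
    baseline_wander_freq_Hz: float = 0.33
    morphology_jitter_sd: float = 0.05
    class_params: dict[str, ClassParams] = field(default_factory=_default_class_params)

    def __post_init__(self) -> None:
        cp = self.class_params
        if not cp["V"].qrs_width_ms > cp["N"].qrs_width_ms:
            raise ValueError("V beats must have wider QRS than N beats")
        if not cp["S"].prematurity_factor < 1.0 == cp["N"].prematurity_factor:
            raise ValueError("S beats must be premature; N beats are not")
        if cp["V"].p_amp_mV != 0.0:
            raise ValueError("V beats carry no P wave")


def _bump(t: np.ndarray, center_s: float, sd_s: float, amp: float) -> np.ndarray:
    """Gaussian bump truncated at +/- 4 sd (exact zero outside support)."""
    out = np.zeros_like(t)
    lo, hi = center_s - _TRUNC_SD * sd_s, center_s + _TRUNC_SD * sd_s
    mask = (t >= lo) & (t <= hi)
    out[mask] = amp * np.exp(-0.5 * ((t[mask] - center_s) / sd_s) ** 2)
    return out


def generate_record(
    config: SyntheticBeatConfig,
    class_sequence: list[str],
    seed: int,
    record_id: str = "synth",
) -> ECGRecord:
    """Generate one synthetic "patient" record for the given beat classes.

    Deterministic for fixed (config, class_sequence, seed).  Each QRS centre
    is annotated with the canonical symbol of its class.
    """
    if not class_sequence:
        raise ValueError("class_sequence must be non-empty")
    unknown = set(class_sequence) - set(config.class_params)
    if unknown:
        raise ValueError(f"unknown classes in sequence: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    # per-record morphology offset = this patient's signature
    amp_scale = 1.0 + config.morphology_jitter_sd * rng.standard_normal()
    width_scale = 1.0 + config.morphology_jitter_sd * rng.standard_normal()
    amp_scale = float(np.clip(amp_scale, 0.7, 1.3))
    width_scale = float(np.clip(width_scale, 0.7, 1.3))

    # beat times: RR to beat k scaled by prematurity of class k, followed by
    # a compensatory pause restoring the underlying rhythm
    r_times = []
    t = config.base_rr_s  # lead-in
    prev_prem = 1.0
    for label in class_sequence:
        prem = config.class_params[label].prematurity_factor
        interval = config.base_rr_s * prem
        if prem >= 1.0:  # on-time beat absorbs the pause after an ectopic one
            interval += config.base_rr_s * (1.0 - prev_prem)
        t += interval
        r_times.append(t)
        prev_prem = prem
    total_s = r_times[-1] + 1.0
    n = int(np.ceil(total_s * config.fs)) + 1
    tt = np.arange(n) / config.fs

    lead_a = np.zeros(n)
    lead_b = np.zeros(n)
    beats: list[tuple[int, str]] = []
    for r_t, label in zip(r_times, class_sequence):
        p = config.class_params[label]
        r_idx = round_half_up(r_t * config.fs)
        r_t = r_idx / config.fs  # snap so the QRS centre is on a sample
        qrs_sd = width_scale * p.qrs_width_ms / 1000.0 / (2 * _TRUNC_SD)
        for lead, qrs_amp in ((lead_a, p.qrs_amp_mV[0]), (lead_b, p.qrs_amp_mV[1])):
            lead += _bump(tt, r_t, qrs_sd, amp_scale * qrs_amp)
            if p.p_amp_mV:
                lead += _bump(tt, r_t + _P_CENTER_MS / 1000.0,
                              _P_SD_MS / 1000.0, amp_scale * p.p_amp_mV)
            lead += _bump(tt, r_t + _T_CENTER_MS / 1000.0,
                          _T_SD_MS / 1000.0, amp_scale * p.t_amp_mV)
        beats.append((r_idx, CLASS_SYMBOL[label]))

    if config.baseline_wander_amp_mV:
        wander = config.baseline_wander_amp_mV * np.sin(
            2 * np.pi * config.baseline_wander_freq_Hz * tt
        )
        lead_a += wander
        lead_b += wander
    if config.noise_sd_mV:
        lead_a += config.noise_sd_mV * rng.standard_normal(n)
        lead_b += config.noise_sd_mV * rng.standard_normal(n)

    return ECGRecord(record_id=record_id, fs=config.fs,
                     lead_a=lead_a, lead_b=lead_b, beats=beats)


def detect_fiducials_synthetic(
    record: ECGRecord, config: SyntheticBeatConfig
) -> list[Fiducials]:
    """Nominal fiducials for a generated record, one per annotated beat.

    QRS onset/offset sit at the configured half-width around each annotation
    (offset - onset = round(qrs_width_ms * fs), half-up rounding); T end at
    the configured T-wave offset; P presence follows the class parameters.
    Stands in for a full delineator, which generated records do not need.
    """
    sym_to_class = {v: k for k, v in CLASS_SYMBOL.items()}
    fs = record.fs
    out = []
    for r_idx, sym in record.beats:
        p = config.class_params[sym_to_class[sym]]
        ws = round_half_up(p.qrs_width_ms * fs / 1000.0)
        onset = r_idx - ws // 2
        offset = onset + ws
        t_end = r_idx + round_half_up(
            (_T_CENTER_MS + 2 * _T_SD_MS) * fs / 1000.0
        )
        out.append(Fiducials(r_idx, onset, offset, t_end, p.p_amp_mV > 0))
    return out
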