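"""Record-to-feature-matrix plumbing shared by the optimization stages,
the final evaluation and the CLI."""

from __future__ import annotations

import numpy as np

from .complex_network import CNParams, WeightMatrix, features_from_weights, \
    tvcg_feature_names, weight_matrix
from .io_data import ECGRecord
from .preprocessing import FilterSpec, apply_filter
from .reference_features import assemble_features
from .synthetic_ecg import SyntheticBeatConfig, detect_fiducials_synthetic
from .tvcg import BeatWindow, DEFAULT_SUBSAMPLE_STEP, Fiducials, \
    build_tvcg, extract_beat_window


def beats_from_record(
    record: ECGRecord,
    fiducials: list[Fiducials] | None = None,
    synthetic_config: SyntheticBeatConfig | None = None,
    filter_spec: FilterSpec | None = None,
) -> list[BeatWindow]:
    """Extract every annotated beat of a record as a BeatWindow.

    Fiducials may be supplied directly, derived from a synthetic generator
    config, or left to the nominal fallback of ``extract_beat_window``.
    Filtering (if any) is applied before windowing.
    """
    if fiducials is None and synthetic_config is not None:
        fiducials = detect_fiducials_synthetic(record, synthetic_config)
    if filter_spec is not None and filter_spec.name != "none":
        record = apply_filter(record, filter_spec)
    out = []
    for i in range(len(record.beats)):
        fid = fiducials[i] if fiducials is not None else None
        out.append(extract_beat_window(record, i, fiducials=fid))
    return out


def beats_from_records(
    records: list[ECGRecord],
    synthetic_config: SyntheticBeatConfig | None = None,
    filter_spec: FilterSpec | None = None,
) -> list[BeatWindow]:
    beats: list[BeatWindow] = []
    for rec in records:
        beats.extend(beats_from_record(rec, synthetic_config=synthetic_config,
                                       filter_spec=filter_spec))
    return beats


def labels_of(beats: list[BeatWindow]) -> np.ndarray:
    return np.array([b.label for b in beats], dtype=object)


def precompute_weight_matrices(
    beats: list[BeatWindow],
    subsample_step: int = DEFAULT_SUBSAMPLE_STEP,
) -> list[WeightMatrix]:
    """TVCG weight matrices per beat; independent of (T_0, T_Q, m), so the
    expensive O(n_v^2) distances are computed once per beat."""
    return [weight_matrix(build_tvcg(b, subsample_step)) for b in beats]


def tvcg_rr_matrix(
    beats: list[BeatWindow],
    wmats: list[WeightMatrix],
    params: CNParams,
) -> np.ndarray:
    """Stage-1 feature matrix: the m x 5 TVCG descriptors plus the three RR
    features per beat."""
    rows = [
        np.concatenate([
            features_from_weights(w, params),
            [b.pre_rr_s, b.post_rr_s, b.local_rr_s],
        ])
        for b, w in zip(beats, wmats)
    ]
    return np.array(rows)


def full_feature_matrix(
    beats: list[BeatWindow],
    params: CNParams,
    subsample_step: int = DEFAULT_SUBSAMPLE_STEP,
    wmats: list[WeightMatrix] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assembled [morph, interval, wavelet, tvcg] matrix with names."""
    if wmats is None:
        wmats = precompute_weight_matrices(beats, subsample_step)
    names: list[str] | None = None
    rows = []
    for b, w in zip(beats, wmats):
        fv = assemble_features(b, features_from_weights(w, params), params)
        if names is None:
            names = fv.names
        rows.append(fv.values)
    assert names is not None
    return np.array(rows), names


def stage1_feature_names(params: CNParams) -> list[str]:
    return tvcg_feature_names(params) + ["int_pre_rr", "int_post_rr",
                                         "int_local_rr"]
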