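"""Record I/O, AAMI superclass mapping, and inter-patient record partitions.

Two-lead ECG records with beat annotations are read either from WFDB
record/annotation files (via the optional ``wfdb`` package) or from a plain
CSV dialect: a signal file with columns ``sample, lead_a_mV, lead_b_mV`` and
a companion annotation file with columns ``sample, symbol``.  Sample indices
are 0-based everywhere.

The MIT-BIH inter-patient partitions (DS1/DS2 of de Chazal, with DS1 further
split into DS11/DS12 for the optimization stages) are shipped as constants;
the four paced records (102, 104, 107, 217) are excluded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five AAMI heartbeat superclasses.
SUPERCLASSES = ("N", "S", "V", "F", "Q")

#: MIT-BIH beat annotation symbol -> AAMI superclass.  The standard table:
#: normal and bundle-branch/escape beats map to N, atrial ectopy to S,
#: ventricular ectopy to V, fusion of V and N to F, paced/unclassifiable to Q.
#: Shipped as data so callers can override.
AAMI_SYMBOL_MAP: dict[str, str] = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}

#: Inter-patient record partitions.  DS1 trains, DS2 tests; DS11/DS12 split
#: DS1 by patient for the optimization stages.  Paced records excluded.
PARTITIONS: dict[str, tuple[str, ...]] = {
    "DS1": ("101", "106", "108", "109", "112", "114", "115", "116", "118",
            "119", "122", "124", "201", "203", "205", "207", "208", "209",
            "215", "220", "223", "230"),
    "DS11": ("101", "106", "108", "109", "114", "115", "116", "119", "122",
             "209", "223"),
    "DS12": ("112", "118", "124", "201", "203", "205", "207", "208", "215",
             "220", "230"),
    # "111" is the canonical member of this test split; some published
    # listings truncate it to "11".
    "DS2": ("100", "103", "105", "111", "113", "117", "121", "123", "200",
            "202", "210", "212", "213", "214", "219", "221", "222", "228",
            "231", "232", "233", "234"),
}


class RecordParseError(ValueError):
    """Raised when a record file is malformed."""


class UnsupportedRecordError(ValueError):
    """Raised when a record does not carry the two required leads."""


@dataclass
class ECGRecord:
    """A two-lead annotated ECG record.

    Attributes
    ----------
    record_id : str
        Identifier (e.g. the MIT-BIH record number).
    fs : float
        Sampling rate in Hz.
    lead_a, lead_b : ndarray
        Amplitude series in mV, equal length.
    beats : list of (int, str)
        Beat annotations as (sample_index, symbol), strictly increasing
        0-based sample indices within signal bounds.
    """

    record_id: str
    fs: float
    lead_a: np.ndarray
    lead_b: np.ndarray
    beats: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lead_a = np.asarray(self.lead_a, dtype=float)
        self.lead_b = np.asarray(self.lead_b, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.lead_a.shape != self.lead_b.shape or self.lead_a.ndim != 1:
            raise UnsupportedRecordError(
                "lead_a and lead_b must be 1-D arrays of equal length "
                f"(got {self.lead_a.shape} and {self.lead_b.shape})"
            )
        n = len(self.lead_a)
        prev = -1
        for idx, sym in self.beats:
            if not 0 <= idx < n:
                raise RecordParseError(
                    f"beat sample index {idx} outside signal of length {n}"
                )
            if idx <= prev:
                raise RecordParseError(
                    f"beat sample indices not strictly increasing at {idx}"
                )
            prev = idx

    @property
    def n_samples(self) -> int:
        return len(self.lead_a)

    def beat_samples(self) -> np.ndarray:
        return np.array([i for i, _ in self.beats], dtype=int)


@dataclass(frozen=True)
class Partition:
    """A named inter-patient record partition."""

    name: str
    record_ids: tuple[str, ...]


def map_to_superclass(symbol: str, table: dict[str, str] | None = None) -> str:
    """Map a beat annotation symbol onto its AAMI superclass.

    Non-beat annotations (rhythm and signal-quality marks) must be filtered
    out before this call; an unknown symbol raises ``KeyError`` naming it.
    """
    table = AAMI_SYMBOL_MAP if table is None else table
    try:
        return table[symbol]
    except KeyError:
        raise KeyError(
            f"unknown beat annotation symbol {symbol!r}; known symbols: "
            f"{sorted(table)}"
        ) from None


def get_partition(name: str) -> Partition:
    """Return the shipped inter-patient partition with the given name."""
    try:
        return Partition(name, PARTITIONS[name])
    except KeyError:
        raise KeyError(
            f"unknown partition {name!r}; valid names: {sorted(PARTITIONS)}"
        ) from None


def partitions_to_json(path: str | Path) -> None:
    """Export the partition constants as JSON."""
    Path(path).write_text(json.dumps({k: list(v) for k, v in PARTITIONS.items()},
                                     indent=2))


def _ann_path(signal_path: Path) -> Path:
    return signal_path.with_suffix(".ann.csv")


def load_record(path: str | Path, dialect: str = "csv") -> ECGRecord:
    """Load a two-lead annotated record.

    Parameters
    ----------
    path : path
        For ``csv``: the signal file ``<stem>.csv`` (annotations are read
        from ``<stem>.ann.csv``).  For ``wfdb``: the record path without
        extension, as accepted by ``wfdb.rdrecord``.
    dialect : {"csv", "wfdb"}

    Non-beat annotation symbols are dropped with a logged count.
    """
    path = Path(path)
    if dialect == "csv":
        return _load_csv(path)
    if dialect == "wfdb":
        return _load_wfdb(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'wfdb'")


def _load_csv(path: Path) -> ECGRecord:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        sig = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RecordParseError(f"cannot parse signal file {path}: {exc}") from exc
    for col in ("sample", "lead_a_mV", "lead_b_mV"):
        if col not in sig.columns:
            if col == "lead_b_mV":
                raise UnsupportedRecordError(
                    f"{path}: single-lead record (missing column {col!r})"
                )
            raise RecordParseError(f"{path}: missing column {col!r}")
    fs = _fs_from_header(path)
    ann_file = _ann_path(path)
    beats: list[tuple[int, str]] = []
    if ann_file.exists():
        ann = pd.read_csv(ann_file, dtype={"symbol": str})
        for col in ("sample", "symbol"):
            if col not in ann.columns:
                raise RecordParseError(f"{ann_file}: missing column {col!r}")
        beats = [(int(r.sample), str(r.symbol)) for r in ann.itertuples()]
    return ECGRecord(
        record_id=path.stem,
        fs=fs,
        lead_a=sig["lead_a_mV"].to_numpy(float),
        lead_b=sig["lead_b_mV"].to_numpy(float),
        beats=beats,
    )


def _fs_from_header(path: Path) -> float:
    """Sampling rate for a CSV record: a sidecar ``<stem>.fs.txt`` if present,
    else the MIT-BIH default of 360 Hz."""
    side = path.with_suffix(".fs.txt")
    if side.exists():
        return float(side.read_text().strip())
    return 360.0


def write_record(record: ECGRecord, path: str | Path) -> None:
    """Write a record in the CSV dialect (inverse of ``load_record``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = record.n_samples
    # %.17g round-trips IEEE doubles bit-exactly
    pd.DataFrame({
        "sample": np.arange(n),
        "lead_a_mV": record.lead_a,
        "lead_b_mV": record.lead_b,
    }).to_csv(path, index=False, float_format="%.17g")
    pd.DataFrame(
        [(i, s) for i, s in record.beats], columns=["sample", "symbol"]
    ).to_csv(_ann_path(path), index=False)
    path.with_suffix(".fs.txt").write_text(repr(float(record.fs)))


def _load_wfdb(path: Path) -> ECGRecord:
    try:
        import wfdb  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the WFDB dialect requires the optional 'wfdb' package "
            "(pip install wfdb); the CSV dialect needs no extra dependency"
        ) from exc
    rec = wfdb.rdrecord(str(path))
    if rec.p_signal is None or rec.p_signal.shape[1] < 2:
        raise UnsupportedRecordError(f"{path}: fewer than two leads")
    ann = wfdb.rdann(str(path), "atr")
    beats = []
    dropped = 0
    for idx, sym in zip(ann.sample, ann.symbol):
        if sym in AAMI_SYMBOL_MAP:
            beats.append((int(idx), sym))
        else:
            dropped += 1
    if dropped:
        logger.info("%s: dropped %d non-beat annotations", path, dropped)
    return ECGRecord(
        record_id=path.name,
        fs=float(rec.fs),
        lead_a=rec.p_signal[:, 0],
        lead_b=rec.p_signal[:, 1],
        beats=beats,
    )
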