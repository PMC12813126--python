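"""Reading and writing VCG recordings and derived feature tables.

Recordings are three synchronized orthogonal (Frank) leads x, y, z in mV.
Two on-disk forms are supported: WFDB header/signal pairs (the format the
PTB diagnostic database ships in, signal format 16) and plain CSV with
columns ``time,x,y,z`` (time optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VCGRecord",
    "FEATURE_NAMES",
    "LeadNotFoundError",
    "read_wfdb_record",
    "read_csv_record",
    "write_csv_record",
    "write_feature_table",
    "read_feature_table",
]

#: Canonical feature-column order for feature tables, most to least
#: discriminative in the reference cohort analysis.
FEATURE_NAMES = (
    "stdVelT",
    "areaQRS",
    "stdVelQRS",
    "maxVecT",
    "arcQRS",
    "maxVelQRS",
    "meanVelT",
    "meanVelQRS",
    "maxVelT",
    "maxGravQRS",
    "maxVecQRS",
    "areaT",
)

DEFAULT_LEAD_NAMES = ("vx", "vy", "vz")


class LeadNotFoundError(KeyError):
    """A requested lead name is absent from a WFDB header."""


@dataclass
class VCGRecord:
    """A three-lead orthogonal VCG recording.

    Parameters
    ----------
    record_id : str
        Identifier of the record (file stem for on-disk records).
    fs : float
        Sampling rate in Hz; must be positive.
    x, y, z : ndarray
        Equal-length lead voltage series in mV.
    label : str
        Class tag: ``"MI"``, ``"HC"`` or ``"unknown"``.
    """

    record_id: str
    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("leads x, y, z must have identical length")
        if len(self.x) < 1:
            raise ValueError("record must contain at least one sample")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in ("MI", "HC", "unknown"):
            raise ValueError(f"label must be MI, HC or unknown, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def xyz(self) -> np.ndarray:
        """Samples as an (n, 3) array."""
        return np.column_stack([self.x, self.y, self.z])

    @property
    def duration_s(self) -> float:
        return len(self.x) / self.fs

    def crop(self, max_seconds: float) -> "VCGRecord":
        """Return a copy truncated to at most ``max_seconds`` of signal."""
        n = min(len(self), int(round(max_seconds * self.fs)))
        return VCGRecord(self.record_id, self.fs, self.x[:n], self.y[:n],
                         self.z[:n], self.label)


# ---------------------------------------------------------------------------
# WFDB (header + format-16 signal file)
# ---------------------------------------------------------------------------

@dataclass
class _WFDBSignalSpec:
    file_name: str
    fmt: str
    gain: float      # ADC units per physical unit (mV)
    baseline: int    # ADC value mapping to 0 physical units
    description: str


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[_WFDBSignalSpec]]:
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    rec_name = rec_fields[0].split("/")[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    specs: list[_WFDBSignalSpec] = []
    for ln in lines[1 : 1 + n_sig]:
        f = ln.split()
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        # gain field: gain(baseline)/units, every part optional
        gain_field = f[2] if len(f) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            baseline = int(b.rstrip(")"))
        else:
            g, baseline = gain_part, 0
        gain = float(g) if g else 200.0
        if gain == 0:
            gain = 200.0
        description = " ".join(f[8:]) if len(f) > 8 else f"sig{len(specs)}"
        specs.append(_WFDBSignalSpec(f[0], fmt, gain, baseline, description))
    return rec_name, n_sig, fs, n_samples, specs


def read_wfdb_record(
    path: str | Path,
    lead_names: Sequence[str] = DEFAULT_LEAD_NAMES,
    label: str = "unknown",
) -> VCGRecord:
    """Read three named leads from a WFDB record into a :class:`VCGRecord`.

    ``path`` is the record path without extension (a ``.hea``/``.dat`` pair
    must exist). Only signal format 16 (little-endian int16, sample-major
    interleaved) is supported — the format of the PTB diagnostic records.
    Voltages are converted to mV using the per-lead gain and baseline from
    the header.

    Raises
    ------
    FileNotFoundError
        If the header or signal file is missing.
    LeadNotFoundError
        If any of the three requested lead names is absent.
    """
    if len(lead_names) != 3:
        raise ValueError("exactly three lead names are required")
    path = Path(path)
    hea_path = path.with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea_path}")
    rec_name, n_sig, fs, n_samples, specs = _parse_header(hea_path)

    available = [s.description for s in specs]
    indices = []
    for name in lead_names:
        matches = [i for i, s in enumerate(specs) if s.description == name]
        if not matches:
            raise LeadNotFoundError(
                f"lead {name!r} not found in {hea_path.name}; "
                f"available leads: {available}")
        indices.append(matches[0])

    for s in specs:
        if s.fmt != "16":
            raise NotImplementedError(
                f"unsupported WFDB signal format {s.fmt!r}; only format 16 "
                "is supported")
    dat_files = {s.file_name for s in specs}
    if len(dat_files) != 1:
        raise NotImplementedError("multi-file WFDB records are not supported")
    dat_path = hea_path.parent / dat_files.pop()
    if not dat_path.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")

    raw = np.fromfile(dat_path, dtype="<i2")
    if n_samples:
        raw = raw[: n_samples * n_sig]
    frames = raw.reshape(-1, n_sig)
    leads = []
    for idx in indices:
        s = specs[idx]
        leads.append((frames[:, idx].astype(float) - s.baseline) / s.gain)
    return VCGRecord(rec_name, fs, leads[0], leads[1], leads[2], label)


# ---------------------------------------------------------------------------
# CSV records
# ---------------------------------------------------------------------------

def read_csv_record(
    path: str | Path,
    fs: float,
    label: str = "unknown",
) -> VCGRecord:
    """Read a ``time,x,y,z`` (time optional) CSV record.

    When a ``time`` column is present, its spacing must be uniform and
    consistent with ``fs`` within 1%.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float)))]
            row = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col!r} "
                             f"near line {row}")
    if "time" in df.columns and len(df) > 1:
        dt = np.diff(df["time"].to_numpy(dtype=float))
        expected = 1.0 / fs
        if np.any(np.abs(dt - expected) > 0.01 * expected):
            raise ValueError(
                f"{path}: time column spacing inconsistent with fs={fs} Hz")
    return VCGRecord(path.stem, fs, df["x"].to_numpy(dtype=float),
                     df["y"].to_numpy(dtype=float),
                     df["z"].to_numpy(dtype=float), label)


def write_csv_record(record: VCGRecord, path: str | Path,
                     include_time: bool = True) -> None:
    """Write a record as ``time,x,y,z`` CSV (inverse of :func:`read_csv_record`)."""
    cols = {}
    if include_time:
        cols["time"] = np.arange(len(record)) / record.fs
    cols.update(x=record.x, y=record.y, z=record.z)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(
    rows: Iterable[tuple[str, str, dict]],
    path: str | Path,
) -> None:
    """Write ``(record_id, label, features)`` rows as a canonical CSV.

    The header is ``record_id,label`` followed by the 12 feature columns in
    :data:`FEATURE_NAMES` order. Every feature dict must carry exactly the
    canonical names; duplicate record ids are rejected.
    """
    rows = list(rows)
    seen: set[str] = set()
    out = []
    for record_id, label, feats in rows:
        if record_id in seen:
            raise ValueError(f"duplicate record_id {record_id!r}")
        seen.add(record_id)
        if set(feats) != set(FEATURE_NAMES):
            missing = set(FEATURE_NAMES) - set(feats)
            extra = set(feats) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature vector for {record_id!r} does not match the "
                f"canonical schema (missing={sorted(missing)}, "
                f"extra={sorted(extra)})")
        out.append({"record_id": record_id, "label": label,
                    **{k: feats[k] for k in FEATURE_NAMES}})
    df = pd.DataFrame(out, columns=["record_id", "label", *FEATURE_NAMES])
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["record_id", "label", *FEATURE_NAMES]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: unexpected feature table columns "
                         f"{list(df.columns)}")
    return df
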