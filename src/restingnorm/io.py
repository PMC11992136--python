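"""File I/O: EDF signals, plain-text montages, cohort and feature tables.

EDF (European Data Format) is the 16-bit interchange format used for the
raw recordings.  The reader/writer here implements the standard fixed
layout (256-byte global header, 256 bytes of per-signal fields, int16
little-endian data records); signals are converted to microvolts using
the physical-dimension/range header fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import Montage, Recording

_DIG_MIN, _DIG_MAX = -32768, 32767

_UNIT_TO_UV = {"uV": 1.0, "\xb5V": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6, "": 1.0}


class EdfFormatError(ValueError):
    """Raised for corrupt or inconsistent EDF files."""


# ---------------------------------------------------------------------------
# EDF


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: Recording, path) -> None:
    """Write a Recording to EDF (16-bit; one-second data records).

    Each channel gets a symmetric physical range covering its data, so
    the quantization step is (2*max|x|)/65535 microvolts.
    """
    rate = recording.rate
    if abs(rate - round(rate)) > 1e-9:
        raise EdfFormatError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1-s record
    data = recording.data
    n_ch, n_samp = data.shape
    n_rec = n_samp // spr
    if n_rec * spr != n_samp:
        data = data[:, : n_rec * spr]
    if n_rec == 0:
        raise EdfFormatError("recording shorter than one data record")

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_min = -phys_max
    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header_bytes = 256 + 256 * n_ch
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad(recording.subject_id or "X", 80))
        f.write(_pad("Startdate 01-JAN-2000", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(n_ch), 4))
        for label in recording.montage.labels:
            f.write(_pad(label, 16))
        f.write(_pad("", 80) * n_ch)
        f.write(_pad("uV", 8) * n_ch)
        for v in phys_min:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        f.write(_pad(str(_DIG_MIN), 8) * n_ch)
        f.write(_pad(str(_DIG_MAX), 8) * n_ch)
        f.write(_pad("", 80) * n_ch)
        f.write(_pad(str(spr), 8) * n_ch)
        f.write(_pad("", 32) * n_ch)
        # records: per record, per signal, contiguous samples
        blocks = digital.reshape(n_ch, n_rec, spr)
        for r in range(n_rec):
            f.write(blocks[:, r, :].tobytes())


def _read_field(f, width: int) -> str:
    return f.read(width).decode("ascii", "replace").strip()


def read_edf(path, montage: Montage) -> Recording:
    """Read an EDF file into a Recording on the given montage.

    Every EDF signal label must be present in ``montage``; the returned
    recording uses the EDF channel order with the montage restricted to
    those labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as f:
        version = _read_field(f, 8)
        if version != "0":
            raise EdfFormatError(f"unsupported EDF version field {version!r}")
        subject_id = _read_field(f, 80)
        f.read(80 + 8 + 8)
        try:
            header_bytes = int(_read_field(f, 8))
        except ValueError as e:
            raise EdfFormatError("corrupt header-bytes field") from e
        f.read(44)
        try:
            n_rec = int(_read_field(f, 8))
            rec_dur = float(_read_field(f, 8))
            n_ch = int(_read_field(f, 4))
        except ValueError as e:
            raise EdfFormatError("corrupt record-count fields") from e
        if header_bytes != 256 + 256 * n_ch:
            raise EdfFormatError("header size inconsistent with signal count")
        labels = [_read_field(f, 16) for _ in range(n_ch)]
        f.read(80 * n_ch)
        units = [_read_field(f, 8) for _ in range(n_ch)]
        phys_min = np.array([float(_read_field(f, 8)) for _ in range(n_ch)])
        phys_max = np.array([float(_read_field(f, 8)) for _ in range(n_ch)])
        dig_min = np.array([float(_read_field(f, 8)) for _ in range(n_ch)])
        dig_max = np.array([float(_read_field(f, 8)) for _ in range(n_ch)])
        f.read(80 * n_ch)
        spr = [int(_read_field(f, 8)) for _ in range(n_ch)]
        f.read(32 * n_ch)
        if len(set(spr)) != 1:
            raise EdfFormatError("mismatched per-signal sample counts")
        spr = spr[0]
        raw = np.frombuffer(f.read(n_rec * n_ch * spr * 2), dtype="<i2")
        if raw.size != n_rec * n_ch * spr:
            raise EdfFormatError("truncated data section")
    for label in labels:
        if label not in montage.labels:
            raise EdfFormatError(f"EDF channel {label!r} absent from montage")
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = raw.reshape(n_rec, n_ch, spr).transpose(1, 0, 2).reshape(n_ch, -1)
    data = (data - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    for i, u in enumerate(units):
        factor = _UNIT_TO_UV.get(u)
        if factor is None:
            raise EdfFormatError(f"unknown physical dimension {u!r}")
        if factor != 1.0:
            data[i] *= factor
    rate = spr / rec_dur
    return Recording(
        data=data, rate=rate, montage=montage.subset(labels), subject_id=subject_id
    )


# ---------------------------------------------------------------------------
# Montage text files ("label x y z" per line)


def write_montage_file(montage: Montage, path) -> None:
    with open(path, "w") as f:
        for label, p in zip(montage.labels, montage.positions):
            f.write(f"{label} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")


def read_montage_file(path, exclusion_set=()) -> Montage:
    labels, positions = [], []
    with open(path) as f:
        for line_no, line in enumerate(f, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{line_no}: expected 'label x y z'")
            labels.append(parts[0])
            positions.append([float(v) for v in parts[1:]])
    return Montage(
        labels=tuple(labels),
        positions=np.array(positions),
        exclusion_set=frozenset(exclusion_set),
    )


# ---------------------------------------------------------------------------
# Channel selection


def select_analysis_channels(recording: Recording) -> Recording:
    """Drop the montage's excluded (face/neck) channels, order preserved.

    Idempotent: the result's montage has an empty exclusion set.
    """
    keep = recording.montage.analysis_labels
    if not keep:
        raise ValueError("exclusion set removes every channel")
    idx = [recording.montage.index_of(l) for l in keep]
    sub = recording.montage.subset(keep)
    sub = Montage(labels=sub.labels, positions=sub.positions, exclusion_set=frozenset())
    return Recording(
        data=recording.data[idx],
        rate=recording.rate,
        montage=sub,
        subject_id=recording.subject_id,
    )


# ---------------------------------------------------------------------------
# Tables

COHORT_COLUMNS = ["subject_id", "group", "age", "sex", "site", "quality_ratio"]
GROUPS = ("CTRL", "DEL", "DUP")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in cohort table")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    if not set(df["sex"]) <= {"M", "F"}:
        raise ValueError("sex must be 'M' or 'F'")
    if not set(df["site"]) <= {0, 1}:
        raise ValueError("site must be encoded 0 or 1")
    return df


def write_feature_table(rows, path) -> None:
    """Write subject x feature rows to CSV (17 significant digits).

    `rows` is a sequence of dicts sharing one schema; an empty sequence
    with a known schema writes a header-only file.
    """
    rows = list(rows)
    if rows:
        schema = tuple(rows[0].keys())
        for r in rows[1:]:
            if tuple(r.keys()) != schema:
                raise ValueError("feature rows have heterogeneous schemas")
        df = pd.DataFrame(rows, columns=list(schema))
    else:
        df = pd.DataFrame(columns=["subject_id", "feature", "value"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
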