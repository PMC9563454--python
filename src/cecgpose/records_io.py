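"""Reading and writing signal records.

Two on-disk formats are supported:

* **csv** — UTF-8, comma-delimited, header ``t_s,ch1_mv,ch2_mv``, one sample
  per row, amplitudes written with 6 decimal places (below the sensor noise
  floor).
* **edf** — European Data Format, 16-bit, physical dimension mV, one-second
  data records (so the record duration must be a whole number of seconds and
  the sampling rate an integer).

Posture labels travel in a sidecar csv ``<stem>.labels.csv`` with columns
``start_s,end_s,label`` (half-open intervals, labels serialized "S"/"L"/"R").
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError, RateError, ShapeError
from .records import PostureLabel, PostureSchedule, SignalRecord

__all__ = ["write_record", "read_record", "label_sidecar_path"]

_TS_TOL = 1e-6  # max deviation of csv timestamps from a uniform grid, seconds


def label_sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".labels.csv")


def _write_labels(schedule: PostureSchedule, path: Path) -> None:
    rows = [(iv.start_s, iv.end_s, iv.label.value) for iv in schedule]
    df = pd.DataFrame(rows, columns=["start_s", "end_s", "label"])
    df.to_csv(path, index=False, float_format="%.6f")


def _read_labels(path: Path, duration_s: float) -> PostureSchedule:
    if not path.exists():
        raise ParseError(f"label sidecar {path} not found")
    df = pd.read_csv(path)
    missing = {"start_s", "end_s", "label"} - set(df.columns)
    if missing:
        raise ParseError(f"label sidecar {path} missing columns {sorted(missing)}")
    try:
        ivs = [
            (float(r.start_s), float(r.end_s), PostureLabel.from_code(str(r.label)))
            for r in df.itertuples()
        ]
    except ValueError as e:
        raise ParseError(f"label sidecar {path}: {e}") from e
    return PostureSchedule(ivs)


# ---------------------------------------------------------------- csv format


def _write_csv(record: SignalRecord, path: Path) -> None:
    t = record.times
    arr = np.column_stack([t, record.channels[0], record.channels[1]])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("t_s,ch1_mv,ch2_mv\n")
        np.savetxt(fh, arr, fmt="%.6f", delimiter=",")


def _read_csv(path: Path) -> tuple[float, np.ndarray]:
    try:
        df = pd.read_csv(path)
    except Exception as e:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: {e}") from e
    expected = ["t_s", "ch1_mv", "ch2_mv"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected header {expected}, got {list(df.columns)}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        bad = df.isna().any(axis=1)
        row = int(bad.idxmax()) + 2  # 1-based + header line
        col = df.columns[df.loc[bad.idxmax()].isna().argmax()]
        raise ParseError(f"{path}: missing/unparseable field in column {col!r} near line {row}")
    t = df["t_s"].to_numpy(dtype=np.float64)
    if len(t) < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise RateError(f"{path}: non-increasing timestamps")
    fs = 1.0 / dt
    # round to the nearest integer rate when plausible (csv stores 6 decimals)
    if abs(fs - round(fs)) < 1e-3:
        fs = float(round(fs))
    grid = np.arange(len(t)) / fs
    dev = np.max(np.abs(t - grid))
    if dev > _TS_TOL + 1e-12:
        i = int(np.argmax(np.abs(t - grid)))
        raise RateError(
            f"{path}: timestamps deviate from a uniform {fs} Hz grid by {dev:.2e} s "
            f"(first offender line {i + 2})"
        )
    ch = df[["ch1_mv", "ch2_mv"]].to_numpy(dtype=np.float64).T
    return fs, ch


# ---------------------------------------------------------------- edf format

_EDF_LABELS = ("cECG ch1", "cECG ch2")


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")
    if len(b) > n:
        raise ParameterError(f"EDF field too long: {s!r}")
    return b.ljust(n)


def _write_edf(record: SignalRecord, path: Path) -> None:
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError(f"EDF export requires an integer sampling rate, got {fs}")
    fs_i = int(round(fs))
    n = record.n_samples
    if n % fs_i != 0:
        raise ParameterError("EDF export requires a whole number of seconds of data")
    n_rec = n // fs_i
    ns = 2
    header_bytes = 256 * (ns + 1)

    phys_max = []
    dig = np.empty((ns, n), dtype="<i2")
    for k in range(ns):
        x = record.channels[k]
        pm = max(float(np.max(np.abs(x))), 1e-6)
        phys_max.append(pm)
        dig[k] = np.round(x / pm * 32767.0).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(f"subject {record.subject_id}", 80))
        fh.write(_pad("cECG simulated recording", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))  # data-record duration, seconds
        fh.write(_pad(str(ns), 4))
        for k in range(ns):
            fh.write(_pad(_EDF_LABELS[k], 16))
        for _ in range(ns):
            fh.write(_pad("capacitive electrode", 80))
        for _ in range(ns):
            fh.write(_pad("mV", 8))
        for k in range(ns):
            fh.write(_pad(f"{-phys_max[k]:.6g}"[:8], 8))
        for k in range(ns):
            fh.write(_pad(f"{phys_max[k]:.6g}"[:8], 8))
        for _ in range(ns):
            fh.write(_pad("-32767", 8))
        for _ in range(ns):
            fh.write(_pad("32767", 8))
        for _ in range(ns):
            fh.write(_pad("BP 0.5-40Hz none", 80))
        for _ in range(ns):
            fh.write(_pad(str(fs_i), 8))
        for _ in range(ns):
            fh.write(_pad("", 32))
        # data records: per record, all samples of ch1 then all of ch2
        for r in range(n_rec):
            sl = slice(r * fs_i, (r + 1) * fs_i)
            fh.write(dig[0, sl].tobytes())
            fh.write(dig[1, sl].tobytes())


def _read_edf(path: Path) -> tuple[float, np.ndarray]:
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise ParseError(f"{path}: truncated EDF header")
        try:
            n_rec = int(hdr[236:244].decode("ascii").strip())
            rec_dur = float(hdr[244:252].decode("ascii").strip())
            ns = int(hdr[252:256].decode("ascii").strip())
        except ValueError as e:
            raise ParseError(f"{path}: malformed EDF header: {e}") from e
        if ns != 2:
            raise ShapeError(f"{path}: expected 2 signals, EDF declares {ns}")
        sig_hdr = fh.read(256 * ns)

        def field(offset: int, width: int, k: int) -> str:
            start = offset * ns + width * k
            return sig_hdr[start : start + width].decode("ascii").strip()

        # per-signal field block offsets within the signal header, in bytes
        # label 16, transducer 80, dim 8, phys_min 8, phys_max 8, dig_min 8,
        # dig_max 8, prefilter 80, n_samp 8, reserved 32
        off = {"dim": 96, "pmin": 104, "pmax": 112, "dmin": 120, "dmax": 128, "nsamp": 216}
        try:
            pmin = [float(field(off["pmin"], 8, k)) for k in range(ns)]
            pmax = [float(field(off["pmax"], 8, k)) for k in range(ns)]
            dmin = [float(field(off["dmin"], 8, k)) for k in range(ns)]
            dmax = [float(field(off["dmax"], 8, k)) for k in range(ns)]
            nsamp = [int(field(off["nsamp"], 8, k)) for k in range(ns)]
        except ValueError as e:
            raise ParseError(f"{path}: malformed EDF signal header: {e}") from e
        if nsamp[0] != nsamp[1]:
            raise ShapeError(f"{path}: channels have different rates {nsamp}")
        fs = nsamp[0] / rec_dur
        data = fh.read(2 * sum(nsamp) * n_rec)
        total = sum(nsamp) * n_rec
        raw = np.frombuffer(data, dtype="<i2", count=total)
    raw = raw.reshape(n_rec, sum(nsamp))
    ch = np.empty((ns, n_rec * nsamp[0]), dtype=np.float64)
    col = 0
    for k in range(ns):
        digv = raw[:, col : col + nsamp[k]].reshape(-1).astype(np.float64)
        scale = (pmax[k] - pmin[k]) / (dmax[k] - dmin[k])
        ch[k] = (digv - dmin[k]) * scale + pmin[k]
        col += nsamp[k]
    return float(fs), ch


# ------------------------------------------------------------------- public


def write_record(record: SignalRecord, path: str | Path, format: str | None = None) -> None:
    """Write a record plus its label sidecar; format from arg or extension."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        _write_csv(record, path)
    elif fmt == "edf":
        _write_edf(record, path)
    else:
        raise ParameterError(f"unsupported format {fmt!r} (expected csv or edf)")
    _write_labels(record.labels, label_sidecar_path(path))


def read_record(path: str | Path, subject_id: str | None = None) -> SignalRecord:
    """Read a record written by :func:`write_record` (format by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        fs, ch = _read_csv(path)
    elif fmt == "edf":
        fs, ch = _read_edf(path)
    else:
        raise ParameterError(f"unsupported format {fmt!r} (expected csv or edf)")
    duration = ch.shape[1] / fs
    labels = _read_labels(label_sidecar_path(path), duration)
    return SignalRecord(
        subject_id=subject_id if subject_id is not None else path.stem,
        fs=fs,
        channels=ch,
        labels=labels,
    )
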