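"""Reading and writing ECG signals and fiducial annotations.

Supported formats
-----------------
* WFDB records: a text ``.hea`` header plus a format-16 (little-endian int16)
  ``.dat`` signal file.  Gain and baseline from the header are applied at load
  so the in-memory unit is always millivolts.  This is a purpose-built reader
  and writer for the format-16 subset of the WFDB specification; other signal
  formats are rejected with a clear error.
* WFDB (MIT-format) annotation files, with the QTDB-style paired
  onset/peak/offset markers ``(``, ``N``, ``t``, ``)``.
* Plain CSV signals with ``time_s,mv`` columns (or a single ``mv`` column and
  an explicit sampling rate).
* Fiducial tables as CSV (columns ``beat,q_on,r_peak,t_peak,t_off,morphology``)
  or an equivalent JSON mirror.  Sample indices are 0-based everywhere; absent
  T fiducials are empty cells / JSON nulls, never sentinel numbers.
"""

from __future__ import annotations

import json
import logging
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ECGRecord, FiducialSet

__all__ = [
    "read_wfdb_record",
    "write_wfdb_record",
    "read_csv_signal",
    "write_csv_signal",
    "read_annotations",
    "write_annotations_wfdb",
    "write_fiducials",
    "DEFAULT_SYMBOL_TABLE",
]

logger = logging.getLogger(__name__)


class ECGLoadError(RuntimeError):
    """Raised when a signal or annotation file cannot be loaded."""


# --------------------------------------------------------------------------
# WFDB signal records (format 16 only)
# --------------------------------------------------------------------------

def write_wfdb_record(
    record: ECGRecord | list[ECGRecord],
    path: str | Path,
    gain: float = 1000.0,
) -> Path:
    """Write one or more leads as a WFDB header/signal pair (format 16).

    ``path`` is the record path without extension; ``<path>.hea`` and
    ``<path>.dat`` are produced.  Samples are quantized to ``round(mv*gain)``
    ADC units (int16), so a gain of 1000 preserves 1 uV resolution.
    """
    path = Path(path)
    records = [record] if isinstance(record, ECGRecord) else list(record)
    if not records:
        raise ValueError("no channels to write")
    fs = records[0].fs
    n = records[0].n_samples
    for r in records:
        if r.fs != fs or r.n_samples != n:
            raise ValueError("all channels must share fs and length")
    adc = np.stack(
        [np.clip(np.round(r.samples * gain), -32768, 32767).astype(np.int16) for r in records],
        axis=1,
    )
    name = path.name
    lines = [f"{name} {len(records)} {fs:g} {n}"]
    for r in records:
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 {r.lead}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    path.with_suffix(".dat").write_bytes(adc.astype("<i2").tobytes())
    return path


def read_wfdb_record(path: str | Path, channel: int | str = 0) -> ECGRecord:
    """Read one channel of a WFDB record into an :class:`ECGRecord`.

    ``channel`` selects by index or by the lead name in the header's
    description field.  Only signal format 16 is supported.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise ECGLoadError(f"header file not found: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise ECGLoadError(f"malformed WFDB header line in {hea}: {lines[0]!r}")
    n_sig = int(head[1])
    fs = float(head[2])
    n_samples = int(head[3])
    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) < n_sig:
        raise ECGLoadError(f"{hea}: expected {n_sig} signal lines")

    specs = []
    for ln in sig_lines:
        tok = ln.split()
        fname, fmt = tok[0], tok[1]
        if fmt.split("x")[0] != "16":
            raise ECGLoadError(f"{hea}: unsupported WFDB signal format {fmt!r} (only 16)")
        gain, baseline, units = 200.0, 0.0, "mV"
        if len(tok) > 2:
            g = tok[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g[:-1].split("(")
                baseline = float(b)
            gain = float(g) if g else 200.0
        desc = tok[8] if len(tok) > 8 else ""
        specs.append({"file": fname, "gain": gain, "baseline": baseline, "units": units, "desc": desc})

    if isinstance(channel, str):
        names = [s["desc"] for s in specs]
        if channel not in names:
            raise ECGLoadError(f"{hea}: no channel named {channel!r} (have {names})")
        ch = names.index(channel)
    else:
        ch = int(channel)
        if not 0 <= ch < n_sig:
            raise ECGLoadError(f"{hea}: channel {ch} out of range (record has {n_sig})")

    dat = hea.parent / specs[ch]["file"]
    if not dat.exists():
        raise ECGLoadError(f"signal file not found: {dat}")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if raw.size < n_sig * n_samples:
        raise ECGLoadError(f"{dat}: expected {n_sig * n_samples} samples, found {raw.size}")
    adc = raw[: n_sig * n_samples].reshape(n_samples, n_sig)[:, ch].astype(float)
    mv = (adc - specs[ch]["baseline"]) / specs[ch]["gain"]
    lead = specs[ch]["desc"] or "II"
    return ECGRecord(mv, fs=fs, lead=lead, source=f"{hea}:{ch}")


# --------------------------------------------------------------------------
# CSV signals
# --------------------------------------------------------------------------

def write_csv_signal(record: ECGRecord, path: str | Path, include_time: bool = True) -> Path:
    path = Path(path)
    if include_time:
        df = pd.DataFrame({"time_s": record.time_s, "mv": record.samples})
    else:
        df = pd.DataFrame({"mv": record.samples})
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_csv_signal(path: str | Path, fs: float | None = None) -> ECGRecord:
    """Read a CSV voltage trace (``time_s,mv`` columns, or ``mv`` plus ``fs``).

    A time column is checked for uniform sampling: any step deviating by more
    than 1% of the median sampling period is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ECGLoadError(f"signal file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ECGLoadError(f"cannot parse {path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "mv" not in cols:
        raise ECGLoadError(f"{path}: no 'mv' column (found {cols})")
    mv = pd.to_numeric(df["mv"], errors="coerce").to_numpy()
    if np.isnan(mv).any():
        raise ECGLoadError(f"{path}: non-numeric or missing voltage values")
    if "time_s" in cols:
        t = pd.to_numeric(df["time_s"], errors="coerce").to_numpy()
        if np.isnan(t).any():
            raise ECGLoadError(f"{path}: non-numeric time values")
        dt = np.diff(t)
        period = float(np.median(dt))
        if period <= 0:
            raise ECGLoadError(f"{path}: time column not increasing")
        if np.max(np.abs(dt - period)) >= 0.01 * period:
            raise ECGLoadError(f"{path}: non-uniform sampling in time column")
        # snap to 6 decimals so text-format rounding cannot perturb fs
        fs_file = round(1.0 / period, 6)
        if fs is not None and abs(fs - fs_file) > 0.01 * fs_file:
            raise ECGLoadError(
                f"{path}: fs argument {fs} disagrees with time column ({fs_file:.6g})"
            )
        fs = fs_file
    elif fs is None:
        raise ECGLoadError(f"{path}: single-column CSV requires an explicit fs")
    return ECGRecord(mv, fs=float(fs), source=str(path))


# --------------------------------------------------------------------------
# Fiducial CSV / JSON
# --------------------------------------------------------------------------

_FID_COLS = ["beat", "q_on", "r_peak", "t_peak", "t_off", "morphology"]


def write_fiducials(
    f: FiducialSet,
    path: str | Path,
    format: str = "csv",
    fs: float | None = None,
) -> Path:
    """Write a fiducial set as CSV or JSON (lossless round-trip).

    When ``fs`` is given, a redundant ``r_peak_time_s`` column is added for
    human inspection; it is ignored on read.
    """
    path = Path(path)
    df = f.beats.copy()
    df.insert(0, "beat", np.arange(len(df)))
    if fs is not None:
        df["r_peak_time_s"] = df["r_peak"].astype(float) / fs
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.9g")
    elif format == "json":
        recs = []
        for _, row in df.iterrows():
            recs.append(
                {
                    c: (None if pd.isna(row[c]) else (int(row[c]) if c != "morphology" and c != "r_peak_time_s" else row[c]))
                    for c in df.columns
                }
            )
        path.write_text(json.dumps({"beats": recs}, indent=1) + "\n")
    else:
        raise ValueError(f"unknown fiducial format {format!r}")
    return path


def _fiducials_from_frame(df: pd.DataFrame) -> FiducialSet:
    for col in ("q_on", "r_peak", "t_peak", "t_off"):
        if col not in df.columns:
            df[col] = pd.NA
        df[col] = pd.to_numeric(df[col], errors="coerce").round().astype("Int64")
    if "morphology" not in df.columns:
        df["morphology"] = pd.NA
    df["morphology"] = df["morphology"].astype("object").where(~pd.isna(df["morphology"]), pd.NA)
    return FiducialSet(df[["q_on", "r_peak", "t_peak", "t_off", "morphology"]])


def read_fiducials_csv(path: str | Path) -> FiducialSet:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "r_peak" not in df.columns:
        raise ECGLoadError(f"{path}: fiducial CSV needs an r_peak column")
    return _fiducials_from_frame(df)


def read_fiducials_json(path: str | Path) -> FiducialSet:
    data = json.loads(Path(path).read_text())
    df = pd.DataFrame(data["beats"]) if data.get("beats") else pd.DataFrame(
        columns=["q_on", "r_peak", "t_peak", "t_off", "morphology"]
    )
    return _fiducials_from_frame(df)


# --------------------------------------------------------------------------
# WFDB (MIT-format) annotation files
# --------------------------------------------------------------------------

# annotation code <-> symbol, per the WFDB annotation code table
_CODE_SYMBOL = {1: "N", 24: "p", 27: "t", 28: "u", 39: "(", 40: ")"}
_SYMBOL_CODE = {v: k for k, v in _CODE_SYMBOL.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

#: How annotation symbols map onto fiducial roles.  Overridable via the
#: ``symbol_table`` argument of :func:`read_annotations`.
DEFAULT_SYMBOL_TABLE = {
    "N": "beat",   # beat label; its sample index is the R peak
    "t": "t_peak",
    "(": "onset",  # onset of the wave announced by the following symbol
    ")": "offset",  # offset of the wave announced by the preceding symbol
}


def _read_mit_annotations(path: Path) -> list[tuple[int, str]]:
    """Decode an MIT-format annotation file into (sample, symbol) pairs."""
    data = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 2 <= len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code = word >> 10
        field = word & 0x3FF
        if code == 0 and field == 0:
            break  # EOF
        if code == _SKIP:
            if i + 4 > len(data):
                raise ECGLoadError(f"{path}: truncated SKIP annotation")
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            pending_skip += (hi << 16) | lo
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += field + (field & 1)
            continue
        t += field + pending_skip
        pending_skip = 0
        sym = _CODE_SYMBOL.get(code, f"?{code}")
        out.append((t, sym))
    return out


def write_annotations_wfdb(f: FiducialSet, path: str | Path) -> Path:
    """Write a fiducial set as an MIT-format annotation file.

    Emits, per beat and in time order: ``(`` at q_on, ``N`` at r_peak, ``t``
    at t_peak and ``)`` at t_off (the latter three/two omitted when absent).
    Morphology labels are not representable in this dialect.
    """
    path = Path(path)
    events: list[tuple[int, str]] = []
    for _, row in f.beats.iterrows():
        if not pd.isna(row["q_on"]):
            events.append((int(row["q_on"]), "("))
        events.append((int(row["r_peak"]), "N"))
        if not pd.isna(row["t_peak"]):
            events.append((int(row["t_peak"]), "t"))
        if not pd.isna(row["t_off"]):
            events.append((int(row["t_off"]), ")"))
    events.sort(key=lambda e: e[0])
    buf = bytearray()
    prev = 0
    for t, sym in events:
        delta = t - prev
        prev = t
        code = _SYMBOL_CODE[sym]
        if delta > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<H", (delta >> 16) & 0xFFFF)
            buf += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
    buf += struct.pack("<H", 0)  # EOF
    path.write_bytes(bytes(buf))
    return path


def _fiducials_from_events(
    events: list[tuple[int, str]],
    symbol_table: dict[str, str],
) -> FiducialSet:
    beats: list[dict] = []
    pending_onset: int | None = None
    unmapped: dict[str, int] = {}
    for t, sym in events:
        role = symbol_table.get(sym)
        if role is None:
            unmapped[sym] = unmapped.get(sym, 0) + 1
            continue
        if role == "onset":
            pending_onset = t
        elif role == "beat":
            beats.append({"q_on": pending_onset, "r_peak": t, "t_peak": None, "t_off": None})
            pending_onset = None
        elif role == "t_peak":
            if beats:
                beats[-1]["t_peak"] = t  # QTDB biphasic T: keep the last 't'
            pending_onset = None
        elif role == "offset":
            if beats and beats[-1]["t_peak"] is not None and beats[-1]["t_off"] is None:
                beats[-1]["t_off"] = t
            # ')' closing a QRS or P wave carries no fiducial here
    if unmapped:
        logger.warning("skipped unmapped annotation symbols: %s", unmapped)
    if not beats:
        return FiducialSet.empty()
    return FiducialSet.from_arrays(
        r_peak=[b["r_peak"] for b in beats],
        q_on=[b["q_on"] for b in beats],
        t_peak=[b["t_peak"] for b in beats],
        t_off=[b["t_off"] for b in beats],
    )


def read_annotations(
    path: str | Path,
    dialect: str = "csv",
    symbol_table: dict[str, str] | None = None,
) -> FiducialSet:
    """Read fiducial annotations from CSV, JSON or a WFDB annotation file.

    The WFDB dialect uses :data:`DEFAULT_SYMBOL_TABLE` (QTDB-style paired
    markers) unless an override table is supplied; unmapped symbols are
    skipped with a logged count, never fatal.  An empty file yields an empty
    :class:`FiducialSet`.
    """
    path = Path(path)
    if not path.exists():
        raise ECGLoadError(f"annotation file not found: {path}")
    if dialect == "csv":
        return read_fiducials_csv(path)
    if dialect == "json":
        return read_fiducials_json(path)
    if dialect == "wfdb":
        events = _read_mit_annotations(path)
        return _fiducials_from_events(events, symbol_table or DEFAULT_SYMBOL_TABLE)
    raise ValueError(f"unknown annotation dialect {dialect!r}")
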