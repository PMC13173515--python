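"""Core data containers: single-lead ECG records and per-beat fiducial sets.

The two containers defined here flow through the whole package: the synthetic
generator and the WFDB/CSV readers produce them, the delineator consumes an
:class:`ECGRecord` and produces a :class:`FiducialSet`, and the interval and
evaluation layers consume fiducial sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "ECGRecord",
    "FiducialSet",
    "Morphology",
    "ClinicalType",
    "clinical_type",
]


class Morphology(str, Enum):
    """Internal T-wave shape classes used by the generator and delineator."""

    MONOPHASIC_POS = "monophasic_pos"
    MONOPHASIC_NEG = "monophasic_neg"
    BIPHASIC_PN = "biphasic_pn"
    BIPHASIC_NP = "biphasic_np"
    NOTCHED = "notched"
    FLAT = "flat"


class ClinicalType(str, Enum):
    """Clinical five-type T-wave taxonomy.

    A: normal, B: flattened, C: peaked, D: inverted, E: other (biphasic or
    notched shapes).
    """

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"


def clinical_type(
    morphology: Morphology | str,
    t_amp: float | None = None,
    r_amp: float | None = None,
    peaked_frac: float = 0.60,
) -> ClinicalType:
    """Map an internal shape class to the clinical A-E type.

    ``peaked`` (type C) has no internal shape counterpart: a monophasic
    positive T wave is called peaked when its amplitude reaches
    ``peaked_frac`` of the R amplitude, otherwise it is normal (type A).
    When amplitudes are not supplied, monophasic-positive maps to A.
    """
    m = Morphology(morphology)
    if m is Morphology.FLAT:
        return ClinicalType.B
    if m is Morphology.MONOPHASIC_NEG:
        return ClinicalType.D
    if m in (Morphology.BIPHASIC_PN, Morphology.BIPHASIC_NP, Morphology.NOTCHED):
        return ClinicalType.E
    # monophasic positive: peaked vs normal by relative amplitude
    if t_amp is not None and r_amp is not None and r_amp > 0:
        if abs(t_amp) >= peaked_frac * r_amp:
            return ClinicalType.C
    return ClinicalType.A


@dataclass
class ECGRecord:
    """A uniformly sampled single-lead voltage trace.

    Parameters
    ----------
    samples:
        Voltage samples in millivolts.
    fs:
        Sampling frequency in Hz.
    lead:
        Lead label, by convention ``"II"``.
    source:
        Free-form provenance string (file path, generator spec hash, ...).
    """

    samples: np.ndarray
    fs: float
    lead: str = "II"
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a record needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("record contains missing or non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


_FIDUCIAL_COLUMNS = ["q_on", "r_peak", "t_peak", "t_off", "morphology"]


@dataclass
class FiducialSet:
    """Per-beat fiducial sample indices plus a T-wave morphology label.

    Stored as a DataFrame with nullable-integer columns ``q_on``, ``r_peak``,
    ``t_peak``, ``t_off`` (0-based sample indices) and a string ``morphology``
    column.  ``r_peak`` is mandatory per beat; the others may be absent
    (``pd.NA``).  Beats are kept sorted by ``r_peak``.
    """

    beats: pd.DataFrame = field(default_factory=lambda: FiducialSet.empty().beats)

    def __post_init__(self) -> None:
        df = self.beats.copy()
        for col in ("q_on", "r_peak", "t_peak", "t_off"):
            if col not in df.columns:
                df[col] = pd.Series([pd.NA] * len(df), dtype="Int64")
            df[col] = df[col].astype("Int64")
        if "morphology" not in df.columns:
            df["morphology"] = pd.Series([pd.NA] * len(df), dtype="object")
        df = df[_FIDUCIAL_COLUMNS]
        if df["r_peak"].isna().any():
            raise ValueError("every beat must have an r_peak index")
        df = df.sort_values("r_peak", kind="stable").reset_index(drop=True)
        if len(df) > 1 and not np.all(np.diff(df["r_peak"].to_numpy(dtype=int)) > 0):
            raise ValueError("r_peak indices must be strictly increasing")
        self.beats = df

    # -- constructors ---------------------------------------------------
    @classmethod
    def empty(cls) -> "FiducialSet":
        df = pd.DataFrame(
            {
                "q_on": pd.Series([], dtype="Int64"),
                "r_peak": pd.Series([], dtype="Int64"),
                "t_peak": pd.Series([], dtype="Int64"),
                "t_off": pd.Series([], dtype="Int64"),
                "morphology": pd.Series([], dtype="object"),
            }
        )
        obj = cls.__new__(cls)
        obj.beats = df
        return obj

    @classmethod
    def from_arrays(
        cls,
        r_peak,
        q_on=None,
        t_peak=None,
        t_off=None,
        morphology=None,
    ) -> "FiducialSet":
        n = len(r_peak)

        def col(x):
            if x is None:
                return pd.Series([pd.NA] * n, dtype="Int64")
            vals = [pd.NA if v is None or (isinstance(v, float) and np.isnan(v)) else int(v) for v in x]
            return pd.Series(vals, dtype="Int64")

        def as_label(m):
            if m is None or (isinstance(m, float) and np.isnan(m)):
                return pd.NA
            try:
                return Morphology(m).value
            except ValueError:
                return str(m)

        morph = (
            pd.Series([pd.NA] * n, dtype="object")
            if morphology is None
            else pd.Series([as_label(m) for m in morphology], dtype="object")
        )
        df = pd.DataFrame(
            {
                "q_on": col(q_on),
                "r_peak": col(r_peak),
                "t_peak": col(t_peak),
                "t_off": col(t_off),
                "morphology": morph,
            }
        )
        return cls(df)

    # -- accessors ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.beats)

    def column(self, name: str) -> np.ndarray:
        """Return a fiducial column as float array with NaN for absent."""
        return self.beats[name].astype("float64").to_numpy()

    @property
    def r_peaks(self) -> np.ndarray:
        return self.beats["r_peak"].to_numpy(dtype=int)

    @property
    def morphologies(self) -> list:
        return list(self.beats["morphology"])

    # -- validation -----------------------------------------------------
    def validate(self, n_samples: int | None = None) -> None:
        """Check within-beat ordering and index-range invariants.

        Raises ``ValueError`` on the first violation.
        """
        df = self.beats
        for col in ("q_on", "r_peak", "t_peak", "t_off"):
            vals = df[col].dropna()
            if len(vals) and (vals < 0).any():
                raise ValueError(f"negative sample index in column {col}")
            if n_samples is not None and len(vals) and (vals >= n_samples).any():
                raise ValueError(f"{col} index beyond record end")
        q, r = self.column("q_on"), self.column("r_peak")
        tp, to = self.column("t_peak"), self.column("t_off")
        bad = (~np.isnan(q)) & ~(q < r)
        if bad.any():
            raise ValueError("q_on must precede r_peak")
        bad = (~np.isnan(tp)) & ~(r < tp)
        if bad.any():
            raise ValueError("t_peak must follow r_peak")
        bad = (~np.isnan(tp)) & (~np.isnan(to)) & ~(tp < to)
        if bad.any():
            raise ValueError("t_peak must precede t_off")

    def equals(self, other: "FiducialSet") -> bool:
        return self.beats.equals(other.beats)
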