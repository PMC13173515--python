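"""Per-beat interval series: RRI, QT, heart-rate-corrected QT, and RQT_diff.

Indexing convention (one slot per beat ``i``; absent values are NaN):

* ``rri[i]``  = time of R_{i+1} minus time of R_i (the interval *following*
  beat i's R peak); the last slot is undefined.
* ``qt[i]``   = beat i's own Q-onset-to-T-offset duration.
* ``qtc[i]``  = qt[i] corrected using rri[i].
* ``rqt_diff[i]`` = rri[i-1] - qtc[i-1] for ``i >= 2`` — the differential is
  anchored two beats into the record, so its first two slots are always
  absent and a three-beat record yields exactly one value.

The cardinal identity, checked on every defined element, is

    rqt_diff[i] = rri[i-1] - qtc[i-1]        (exact, to 1e-9 ms)

Internal unit is milliseconds throughout; seconds appear only inside the
correction formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FiducialSet

__all__ = [
    "IntervalSeries",
    "compute_rri",
    "compute_qt",
    "correct_qt",
    "compute_rqt_diff",
    "build_interval_series",
    "flag_artifacts",
]

CORRECTION_METHODS = ("bazett", "fridericia", "hodges")


def compute_rri(f: FiducialSet, fs: float) -> np.ndarray:
    """RR intervals in ms, one slot per beat; the final slot is NaN."""
    if len(f) < 2:
        raise ValueError("need at least 2 beats for RR intervals")
    r = f.r_peaks.astype(float)
    rri = np.full(len(f), np.nan)
    rri[:-1] = np.diff(r) * 1000.0 / fs
    return rri


def compute_qt(f: FiducialSet, fs: float) -> np.ndarray:
    """QT duration (Q onset to T offset) in ms per beat; NaN where absent."""
    q = f.column("q_on")
    t = f.column("t_off")
    return (t - q) * 1000.0 / fs


def correct_qt(qt: float | np.ndarray, rri: float | np.ndarray, method: str = "bazett"):
    """Heart-rate-corrected QT in ms.

    ``bazett``:     QTc = QT / sqrt(RRI_s)
    ``fridericia``: QTc = QT / RRI_s**(1/3)
    ``hodges``:     QTc = QT + 1.75 * (HR - 60),  HR = 60000 / RRI_ms

    QT stays in ms; the RR interval enters the Bazett/Fridericia root in
    seconds — the standard clinical convention.
    """
    qt = np.asarray(qt, dtype=float)
    rri = np.asarray(rri, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((qt <= 0) & ~np.isnan(qt)) or np.any((rri <= 0) & ~np.isnan(rri)):
            raise ValueError("QT and RRI must be positive")
    rri_s = rri / 1000.0
    if method == "bazett":
        out = qt / np.sqrt(rri_s)
    elif method == "fridericia":
        out = qt / np.cbrt(rri_s)
    elif method == "hodges":
        out = qt + 1.75 * (60000.0 / rri - 60.0)
    else:
        raise ValueError(f"unknown correction method {method!r}; use one of {CORRECTION_METHODS}")
    return float(out) if out.ndim == 0 else out


def compute_rqt_diff(rri: np.ndarray, qtc: np.ndarray) -> np.ndarray:
    """The RQT differential: ``out[i] = rri[i-1] - qtc[i-1]`` for ``i >= 2``.

    The differential belongs to the beat *after* the interval it is computed
    from, and the series is anchored two beats into the record: the first two
    slots are always absent (a three-beat record yields exactly one value).
    Inputs must be aligned slot-wise (same length).
    """
    rri = np.asarray(rri, dtype=float)
    qtc = np.asarray(qtc, dtype=float)
    if rri.shape != qtc.shape:
        raise ValueError("rri and qtc series must have equal length")
    out = np.full(rri.shape, np.nan)
    if len(out) > 2:
        out[2:] = rri[1:-1] - qtc[1:-1]
    return out


def flag_artifacts(rri: np.ndarray, lo: float = 300.0, hi: float = 2000.0, dev_frac: float = 0.2) -> np.ndarray:
    """Flag physiologically implausible or ectopic RR intervals.

    An interval is flagged when outside ``[lo, hi]`` ms or deviating more
    than ``dev_frac`` from the 11-beat running median.  Off by default in
    :func:`build_interval_series` (sinus-rhythm recordings need no guard).
    """
    rri = np.asarray(rri, dtype=float)
    med = pd.Series(rri).rolling(11, center=True, min_periods=1).median().to_numpy()
    with np.errstate(invalid="ignore"):
        flag = (rri < lo) | (rri > hi) | (np.abs(rri - med) > dev_frac * med)
    return np.where(np.isnan(rri), False, flag)


@dataclass
class IntervalSeries:
    """Aligned per-beat interval series (ms) plus bookkeeping metadata."""

    rri: np.ndarray
    qt: np.ndarray
    qtc: np.ndarray
    rqt_diff: np.ndarray
    correction_method: str
    fs: float

    def __len__(self) -> int:
        return len(self.rri)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat": np.arange(len(self.rri)),
                "rri_ms": self.rri,
                "qt_ms": self.qt,
                "qtc_ms": self.qtc,
                "rqt_diff_ms": self.rqt_diff,
            }
        )

    def check_identity(self, tol: float = 1e-9) -> None:
        """Assert the cardinal identity rqt_diff[i] == rri[i-1] - qtc[i-1]."""
        lhs = self.rqt_diff[1:]
        rhs = self.rri[:-1] - self.qtc[:-1]
        both = ~np.isnan(lhs) & ~np.isnan(rhs)
        if np.any(np.abs(lhs[both] - rhs[both]) > tol):
            raise AssertionError("RRI - QTc - RQT_diff identity violated")
        # a defined differential requires defined inputs
        if np.any(~np.isnan(lhs) & ~both):
            raise AssertionError("rqt_diff defined where rri/qtc are not")

    def defined_rqt_count(self) -> int:
        return int(np.sum(~np.isnan(self.rqt_diff)))


def aligned_hrv_inputs(
    series: "IntervalSeries",
    beat_times_s: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lag-consistent (times, rri, rqt_diff) arrays for joint HRV analysis.

    ``rqt_diff[i]`` derives from the interval in slot ``i-1``, so for HRV the
    two series are aligned on that source slot: element ``k`` carries
    ``rri[j]`` and ``rqt_diff[j+1]`` at the time of beat ``j``.  Slots where
    either value is undefined are dropped jointly.  With a constant QTc this
    makes the RQT-diff series exactly the RRI series minus a constant.
    """
    t = np.asarray(beat_times_s, dtype=float)
    if t.shape[0] != len(series):
        raise ValueError("beat_times length must match the interval series")
    rri_src = series.rri[:-1]
    rqt_dst = series.rqt_diff[1:]
    ok = ~np.isnan(rri_src) & ~np.isnan(rqt_dst)
    return t[:-1][ok], rri_src[ok], rqt_dst[ok]


def build_interval_series(
    f: FiducialSet,
    fs: float,
    method: str = "bazett",
    exclude_artifacts: bool = False,
) -> IntervalSeries:
    """Assemble all four per-beat series from a fiducial set.

    Beats with an absent QT propagate NaN into QTc and into the dependent
    RQT_diff slot.  ``qt >= rri`` slots (non-physiological) are kept but a
    warning would be the caller's concern; they are flagged via NaN-free
    bookkeeping only when ``exclude_artifacts`` is set.
    """
    if len(f) < 2:
        raise ValueError("need at least 2 beats")
    rri = compute_rri(f, fs)
    qt = compute_qt(f, fs)
    if exclude_artifacts:
        bad = flag_artifacts(rri)
        rri = np.where(bad, np.nan, rri)
    with np.errstate(invalid="ignore"):
        ok = ~np.isnan(qt) & ~np.isnan(rri)
    qtc = np.full(len(f), np.nan)
    if np.any(ok):
        qtc[ok] = correct_qt(qt[ok], rri[ok], method)
    rqt = compute_rqt_diff(rri, qtc)
    series = IntervalSeries(rri=rri, qt=qt, qtc=qtc, rqt_diff=rqt, correction_method=method, fs=fs)
    series.check_identity()
    return series
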