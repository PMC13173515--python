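"""Delineation benchmarking and group-discrimination statistics.

Two concerns live here: comparing a detected fiducial set against reference
annotations (positive predictive value plus signed interval-error summaries
for the RR and QT intervals), and the statistics used to compare subject
groups — ROC analysis with a Youden-optimal cutoff, BMI-adjusted binary
logistic regression with a Hosmer-Lemeshow goodness-of-fit test, standard
bivariate tests, and T-wave morphology tabulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

from .core import ClinicalType, FiducialSet, Morphology, clinical_type

__all__ = [
    "ValidationMetrics",
    "ClassifierReport",
    "benchmark_delineation",
    "roc_analysis",
    "logistic_model",
    "bivariate_stats",
    "tabulate_morphology",
]


# --------------------------------------------------------------------------
# delineation benchmark
# --------------------------------------------------------------------------

@dataclass
class IntervalErrorSummary:
    ppv: float
    median_err: float
    mean_err: float
    sd_err: float
    n_matched: int
    n_spurious: int
    n_missed: int


@dataclass
class ValidationMetrics:
    """Per-interval-type (RRI, QTI) PPV and error summaries, in ms."""

    rri: IntervalErrorSummary
    qti: IntervalErrorSummary
    n_reference: int
    n_excluded_low_t: int

    def to_dict(self) -> dict:
        return {
            k: vars(v) if isinstance(v, IntervalErrorSummary) else v
            for k, v in vars(self).items()
        }


def _greedy_match(det: np.ndarray, ref: np.ndarray, tol: int) -> list[tuple[int, int]]:
    """One-to-one matching by increasing |distance|; each index used once."""
    pairs = []
    for i, d in enumerate(det):
        j = int(np.argmin(np.abs(ref - d))) if ref.size else -1
        if j >= 0 and abs(int(ref[j]) - int(d)) <= tol:
            pairs.append((abs(int(ref[j]) - int(d)), i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    out = []
    for _, i, j in pairs:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        out.append((i, j))
    return sorted(out)


def _summary(errors: np.ndarray, n_matched: int, n_spurious: int, n_missed: int) -> IntervalErrorSummary:
    denom = n_matched + n_spurious
    ppv = 100.0 * n_matched / denom if denom > 0 else 0.0
    if errors.size:
        med, mean = float(np.median(errors)), float(np.mean(errors))
        sd = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    else:
        med = mean = sd = float("nan")
    return IntervalErrorSummary(ppv, med, mean, sd, n_matched, n_spurious, n_missed)


def benchmark_delineation(
    detected: FiducialSet,
    reference: FiducialSet,
    fs: float,
    match_tol: float = 150.0,
    quality_frac: float = 0.15,
    record: np.ndarray | None = None,
) -> ValidationMetrics:
    """Compare detected fiducials against reference annotations.

    Reference beats whose T amplitude is below ``quality_frac`` of the R
    amplitude are excluded (requires ``record`` samples; without them, beats
    lacking a reference T offset are excluded instead).  R peaks are matched
    one-to-one within ``match_tol`` ms; errors are signed detected-minus-
    reference, RRI errors per matched consecutive pair and QT errors per
    matched beat where both sides delineated the beat.
    """
    if len(reference) == 0:
        raise ValueError("empty reference annotation set")
    tol = int(round(match_tol / 1000.0 * fs))

    ref_df = reference.beats
    keep = np.ones(len(ref_df), dtype=bool)
    n_excluded = 0
    if record is not None:
        for k, row in ref_df.iterrows():
            if pd.isna(row["t_peak"]):
                keep[k] = False
                continue
            r_amp = abs(float(record[int(row["r_peak"])]))
            t_amp = abs(float(record[int(row["t_peak"])]))
            if r_amp == 0 or t_amp < quality_frac * r_amp:
                keep[k] = False
    else:
        keep = ~ref_df["t_off"].isna().to_numpy()
    n_excluded = int(np.sum(~keep))
    ref_kept = ref_df[keep].reset_index(drop=True)
    if len(ref_kept) == 0:
        raise ValueError("no reference beats pass the T-amplitude quality screen")

    det_df = detected.beats
    det_r = det_df["r_peak"].to_numpy(dtype=int) if len(det_df) else np.array([], dtype=int)
    ref_r = ref_kept["r_peak"].to_numpy(dtype=int)
    matches = _greedy_match(det_r, ref_r, tol)
    matched_d = {i for i, _ in matches}
    n_matched = len(matches)
    n_spurious = len(det_r) - n_matched
    n_missed = len(ref_r) - n_matched

    # RRI errors over consecutive matched reference beats
    rri_err = []
    by_ref = {j: i for i, j in matches}
    for j in range(len(ref_r) - 1):
        if j in by_ref and (j + 1) in by_ref:
            d_rri = (det_r[by_ref[j + 1]] - det_r[by_ref[j]]) * 1000.0 / fs
            r_rri = (ref_r[j + 1] - ref_r[j]) * 1000.0 / fs
            rri_err.append(d_rri - r_rri)

    # QT errors per matched beat with both sides fully delineated
    qt_err = []
    n_qt_matched = 0
    n_qt_spurious = 0
    for i in range(len(det_r)):
        if i not in matched_d:
            if not pd.isna(det_df["q_on"].iloc[i]) and not pd.isna(det_df["t_off"].iloc[i]):
                n_qt_spurious += 1
            continue
    for i, j in matches:
        d_q, d_t = det_df["q_on"].iloc[i], det_df["t_off"].iloc[i]
        r_q, r_t = ref_kept["q_on"].iloc[j], ref_kept["t_off"].iloc[j]
        if pd.isna(d_q) or pd.isna(d_t) or pd.isna(r_q) or pd.isna(r_t):
            continue
        n_qt_matched += 1
        qt_err.append(((int(d_t) - int(d_q)) - (int(r_t) - int(r_q))) * 1000.0 / fs)

    return ValidationMetrics(
        rri=_summary(np.asarray(rri_err), n_matched, n_spurious, n_missed),
        qti=_summary(
            np.asarray(qt_err), n_qt_matched, n_qt_spurious, len(ref_r) - n_qt_matched
        ),
        n_reference=len(ref_df),
        n_excluded_low_t=n_excluded,
    )


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

def roc_analysis(scores, labels) -> dict:
    """AUC (rank/trapezoid), Youden-optimal cutoff, and score orientation.

    The AUC is reported for the orientation in which higher scores predict
    the positive class; ``orientation`` is ``+1`` when the raw scores already
    do so and ``-1`` when they were negated.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    orientation = 1
    if auc < 0.5:
        fpr, tpr, thr = roc_curve(y, -s)
        auc = float(np.trapezoid(tpr, fpr))
        orientation = -1
    j = tpr - fpr
    k = int(np.argmax(j))
    cutoff = float(thr[k]) * orientation
    return {
        "auc": auc,
        "optimal_cutoff": cutoff,
        "orientation": orientation,
        "youden_j": float(j[k]),
    }


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------

@dataclass
class ClassifierReport:
    """Fitted two-predictor logistic model (index plus covariate)."""

    auc: float
    coefficients: dict            # name -> B
    exp_b: dict                   # name -> odds ratio
    ci95: dict                    # name -> (lo, hi) for Exp(B)
    p_values: dict
    hl_p: float
    hl_chi2: float
    overall_pct: float
    converged: bool
    separation: bool = False
    notes: str = ""


def hosmer_lemeshow(y: np.ndarray, p: np.ndarray, n_groups: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow chi-square over deciles of fitted risk (stable sort)."""
    order = np.argsort(p, kind="stable")
    splits = np.array_split(order, n_groups)
    chi2 = 0.0
    used = 0
    for idx in splits:
        if idx.size == 0:
            continue
        o1, e1 = float(np.sum(y[idx])), float(np.sum(p[idx]))
        o0, e0 = idx.size - o1, idx.size - e1
        if e1 <= 0 or e0 <= 0:
            continue
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        used += 1
    dof = max(1, used - 2)
    return chi2, float(stats.chi2.sf(chi2, dof))


def logistic_model(outcome, index, covariate, index_name: str = "index", covariate_name: str = "bmi") -> ClassifierReport:
    """ML logistic fit of ``logit P(outcome) = B0 + B1*index + B2*covariate``.

    Reports Wald 95% CIs on the odds-ratio scale, the Hosmer-Lemeshow decile
    test, and the overall percentage correctly classified at probability 0.5.
    Perfect separation is detected and reported rather than silently fitted.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.column_stack([np.asarray(index, float), np.asarray(covariate, float)])
    if y.size < 30:
        raise ValueError("need n >= 30 for a stable logistic fit")
    if np.linalg.matrix_rank(np.column_stack([np.ones(y.size), X])) < 3:
        raise ValueError("collinear predictors")
    exog = sm.add_constant(X)
    names = ["const", index_name, covariate_name]
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is handled below
            fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
    except Exception:  # noqa: BLE001 - statsmodels raises on perfect separation
        return ClassifierReport(
            auc=float("nan"), coefficients={}, exp_b={}, ci95={}, p_values={},
            hl_p=float("nan"), hl_chi2=float("nan"), overall_pct=float("nan"),
            converged=False, separation=True, notes="perfect separation detected",
        )
    p = np.asarray(fit.predict(exog))
    separation = bool(np.all((p > 0.999) == (y == 1)) and np.all((p < 0.001) == (y == 0)) and np.all((p > 0.999) | (p < 0.001)))
    if separation or not converged:
        return ClassifierReport(
            auc=float("nan"), coefficients={}, exp_b={}, ci95={}, p_values={},
            hl_p=float("nan"), hl_chi2=float("nan"), overall_pct=float("nan"),
            converged=converged, separation=True, notes="perfect separation detected",
        )
    ci = fit.conf_int(alpha=0.05)
    coeffs = dict(zip(names, fit.params))
    chi2, hl_p = hosmer_lemeshow(y, p)
    acc = 100.0 * float(np.mean((p >= 0.5) == (y == 1)))
    return ClassifierReport(
        auc=roc_analysis(p, y.astype(int))["auc"],
        coefficients=coeffs,
        exp_b={k: float(np.exp(v)) for k, v in coeffs.items()},
        ci95={names[i]: (float(np.exp(ci[i, 0])), float(np.exp(ci[i, 1]))) for i in range(3)},
        p_values=dict(zip(names, (float(v) for v in fit.pvalues))),
        hl_p=hl_p,
        hl_chi2=chi2,
        overall_pct=acc,
        converged=converged,
    )


# --------------------------------------------------------------------------
# bivariate tests and morphology tabulation
# --------------------------------------------------------------------------

def bivariate_stats(a, b_or_groups, kind: str = "ttest") -> tuple[float, float]:
    """Two-sided t-test / Mann-Whitney U between groups, or Spearman rho.

    For ``ttest``/``mannwhitney``, ``a`` holds values and ``b_or_groups`` the
    binary group labels (or directly the second sample).  ``spearman`` treats
    the inputs as paired series (average ranks on ties).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b_or_groups)
    if kind == "spearman":
        if a.size != b.size:
            raise ValueError("paired series must have equal length")
        rho, p = stats.spearmanr(a, b.astype(float))
        return float(rho), float(p)
    if a.size == b.size and set(np.unique(b.astype(float))) <= {0.0, 1.0}:
        g0, g1 = a[b.astype(float) == 0], a[b.astype(float) == 1]
    else:
        g0, g1 = a, b.astype(float)
    if min(g0.size, g1.size) < 3:
        raise ValueError("each group needs at least 3 observations")
    if kind == "ttest":
        if np.std(g0) == 0 and np.std(g1) == 0 and np.mean(g0) == np.mean(g1):
            return 0.0, 1.0
        t, p = stats.ttest_ind(g0, g1)
        return float(t), float(p)
    if kind == "mannwhitney":
        u, p = stats.mannwhitneyu(g0, g1, alternative="two-sided")
        return float(u), float(p)
    raise ValueError(f"unknown test kind {kind!r}")


def subject_clinical_type(f: FiducialSet, peaked_frac: float = 0.60) -> ClinicalType:
    """Modal per-beat clinical type; ties break toward the abnormal label."""
    labels = []
    for m in f.morphologies:
        if pd.isna(m) or m is None:
            continue
        labels.append(clinical_type(Morphology(m)).value)
    if not labels:
        raise ValueError("subject has no labelled beats")
    counts = pd.Series(labels).value_counts()
    top = counts[counts == counts.max()].index.tolist()
    # "A" is the only normal label; prefer any abnormal one on a tie
    abnormal = [t for t in top if t != "A"]
    return ClinicalType(sorted(abnormal)[0] if abnormal else "A")


def tabulate_morphology(subject_sets: dict, group_labels: dict) -> pd.DataFrame:
    """Count and percentage of clinical T-wave types per group.

    ``subject_sets`` maps subject id to a FiducialSet; ``group_labels`` maps
    subject id to a group name.  Returns a table with one row per type and
    ``<group>_n`` / ``<group>_pct`` columns (percentages to one decimal).
    """
    if not subject_sets:
        raise ValueError("no subjects")
    rows = {t.value: {} for t in ClinicalType}
    groups = sorted(set(group_labels.values()))
    for g in groups:
        subj = [s for s, gl in group_labels.items() if gl == g]
        types = [subject_clinical_type(subject_sets[s]).value for s in subj]
        counts = pd.Series(types).value_counts()
        total = len(subj)
        for t in rows:
            n = int(counts.get(t, 0))
            rows[t][f"{g}_n"] = n
            rows[t][f"{g}_pct"] = round(100.0 * n / total, 1) if total else 0.0
    return pd.DataFrame(rows).T
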