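"""Benchmark metrics and group statistics against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from rqtecg.core import FiducialSet, Morphology
from rqtecg.evaluation import (
    benchmark_delineation,
    bivariate_stats,
    hosmer_lemeshow,
    logistic_model,
    roc_analysis,
    subject_clinical_type,
    tabulate_morphology,
)


def brute_force_auc(scores, labels):
    """Concordant-pair fraction over all positive/negative pairs (ties 0.5)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def irls_logistic(y, X, iters=100, tol=1e-12):
    """Hand-written iteratively reweighted least squares (the oracle)."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X1.shape[1])
    for _ in range(iters):
        eta = X1 @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        z = eta + (y - p) / w
        beta_new = np.linalg.solve(X1.T @ (w[:, None] * X1), X1.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def _fiducials(r, q_off=25, t_off=175):
    r = np.asarray(r)
    return FiducialSet.from_arrays(
        r_peak=r, q_on=r - q_off, t_peak=r + 125, t_off=r + t_off
    )


class TestBenchmark:
    def test_identical_sets_are_perfect(self):
        ref = _fiducials(np.arange(50) * 450 + 300)
        m = benchmark_delineation(ref, ref, fs=500)
        assert m.rri.ppv == 100.0 and m.qti.ppv == 100.0
        for s in (m.rri, m.qti):
            assert s.median_err == 0.0 and s.mean_err == 0.0 and s.sd_err == 0.0

    def test_one_spurious_detection_lowers_ppv(self):
        ref = _fiducials(np.arange(100) * 450 + 300)
        extra = np.sort(np.append(ref.r_peaks, 190))
        det = _fiducials(extra)
        m = benchmark_delineation(det, ref, fs=500)
        assert m.rri.n_matched == 100 and m.rri.n_spurious == 1
        assert m.rri.ppv == pytest.approx(100.0 * 100 / 101)

    def test_low_amplitude_t_beats_excluded(self):
        r = np.arange(20) * 450 + 300
        ref = _fiducials(r)
        record = np.zeros(int(r[-1]) + 400)
        record[r] = 1.0
        record[r + 125] = 0.30
        record[r[7] + 125] = 0.10  # this beat's T is 10% of R
        m = benchmark_delineation(ref, ref, fs=500, quality_frac=0.15, record=record)
        assert m.n_excluded_low_t == 1
        assert m.qti.n_matched == 19

    def test_sign_convention_detected_minus_reference(self):
        ref = _fiducials(np.arange(50) * 450 + 300, t_off=175)
        det = _fiducials(np.arange(50) * 450 + 300, t_off=165)  # T ends 20 ms early
        m = benchmark_delineation(det, ref, fs=500)
        assert m.qti.median_err == pytest.approx(-20.0)
        swapped = benchmark_delineation(ref, det, fs=500)
        assert swapped.qti.median_err == pytest.approx(20.0)
        assert swapped.qti.sd_err == pytest.approx(m.qti.sd_err)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            benchmark_delineation(_fiducials([300]), FiducialSet.empty(), fs=500)

    def test_empty_detection_gives_zero_ppv(self):
        ref = _fiducials(np.arange(10) * 450 + 300)
        m = benchmark_delineation(FiducialSet.empty(), ref, fs=500)
        assert m.rri.ppv == 0.0 and m.rri.n_matched == 0


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res["auc"] == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = np.repeat([0, 1], 1000)
        assert 0.45 <= roc_analysis(scores, labels)["auc"] <= 0.55

    def test_matches_exhaustive_pair_oracle(self, rng):
        for _ in range(5):
            scores = rng.normal(size=60)
            labels = rng.integers(0, 2, size=60)
            if len(set(labels)) < 2:
                continue
            res = roc_analysis(scores, labels)
            oracle = brute_force_auc(scores, labels)
            assert res["auc"] == pytest.approx(max(oracle, 1 - oracle), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        a1 = roc_analysis(scores, labels)["auc"]
        a2 = roc_analysis(np.exp(scores), labels)["auc"]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1.0, 2.0], [1, 1])


class TestLogistic:
    def test_null_index_ci_contains_one(self, rng):
        n = 500
        index = rng.normal(size=n)
        bmi = rng.normal(25, 4, size=n)
        y = rng.integers(0, 2, size=n)
        rep = logistic_model(y, index, bmi)
        lo, hi = rep.ci95["index"]
        assert lo <= 1.0 <= hi
        assert abs(rep.coefficients["index"]) < 0.5

    def test_perfect_separation_reported(self):
        y = np.repeat([0, 1], 25)
        index = y.astype(float)
        bmi = np.random.default_rng(0).normal(25, 4, 50)
        rep = logistic_model(y, index, bmi)
        assert rep.separation

    def test_coefficients_match_irls_oracle(self, rng):
        n = 300
        index = rng.normal(size=n)
        bmi = rng.normal(25, 4, size=n)
        logit = -1.0 + 0.8 * index + 0.05 * bmi
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        rep = logistic_model(y, index, bmi)
        oracle = irls_logistic(y, np.column_stack([index, bmi]))
        fitted = [rep.coefficients["const"], rep.coefficients["index"], rep.coefficients["bmi"]]
        assert np.allclose(fitted, oracle, atol=1e-6)

    def test_rescaling_index_rescales_coefficient(self, rng):
        n = 300
        index = rng.normal(size=n)
        bmi = rng.normal(25, 4, size=n)
        y = (rng.random(n) < 0.5).astype(float)
        rep1 = logistic_model(y, index, bmi)
        rep2 = logistic_model(y, index * 10.0, bmi)
        assert rep2.coefficients["index"] == pytest.approx(
            rep1.coefficients["index"] / 10.0, rel=1e-6
        )

    def test_collinear_inputs_rejected(self, rng):
        n = 100
        index = rng.normal(size=n)
        y = rng.integers(0, 2, size=n).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            logistic_model(y, index, 2.0 * index)

    def test_hosmer_lemeshow_well_calibrated_model(self, rng):
        p = rng.uniform(0.05, 0.95, 1000)
        y = (rng.random(1000) < p).astype(float)
        _, pval = hosmer_lemeshow(y, p)
        assert pval > 0.01


class TestBivariate:
    def test_identical_groups_ttest(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0)])
        g = np.repeat([0, 1], 10)
        t, p = bivariate_stats(x, g, kind="ttest")
        assert t == 0.0 and p == 1.0

    def test_spearman_perfect_monotone(self):
        a = np.arange(20.0)
        rho, _ = bivariate_stats(a, a**3, kind="spearman")
        assert rho == pytest.approx(1.0)

    def test_parametric_p_close_to_permutation_p(self, rng):
        g0 = rng.normal(0.0, 1.0, 15)
        g1 = rng.normal(0.8, 1.0, 15)
        t_obs, p_param = bivariate_stats(g0, g1, kind="ttest")
        res = stats.permutation_test(
            (g0, g1),
            lambda a, b: np.mean(a) - np.mean(b),
            permutation_type="independent",
            n_resamples=10**5,
            random_state=np.random.default_rng(7),
        )
        assert abs(p_param - res.pvalue) <= 0.02

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            bivariate_stats(np.array([1.0, 2.0]), np.array([3.0, 4.0]), kind="ttest")


class TestMorphologyTabulation:
    @staticmethod
    def _subject(morph):
        return FiducialSet.from_arrays(
            r_peak=[100, 600, 1100], morphology=[morph] * 3
        )

    def test_percentages_to_one_decimal(self):
        sets, groups = {}, {}
        for i in range(93):
            sets[f"g1_{i}"] = self._subject(
                "monophasic_pos" if i < 70 else "monophasic_neg"
            )
            groups[f"g1_{i}"] = "group1"
        for i in range(88):
            sets[f"g2_{i}"] = self._subject(
                "monophasic_pos" if i < 59 else "monophasic_neg"
            )
            groups[f"g2_{i}"] = "group2"
        table = tabulate_morphology(sets, groups)
        assert table.loc["A", "group1_n"] == 70
        assert table.loc["A", "group1_pct"] == 75.3
        assert table.loc["A", "group2_n"] == 59
        assert table.loc["A", "group2_pct"] == 67.0

    def test_single_type_is_100_percent(self):
        sets = {f"s{i}": self._subject("flat") for i in range(5)}
        groups = {k: "g" for k in sets}
        table = tabulate_morphology(sets, groups)
        assert table.loc["B", "g_pct"] == 100.0
        assert table.drop("B")["g_n"].sum() == 0

    def test_modal_tie_breaks_toward_abnormal(self):
        f = FiducialSet.from_arrays(
            r_peak=[100, 600], morphology=["monophasic_pos", "flat"]
        )
        assert subject_clinical_type(f).value == "B"

    def test_empty_subject_set_rejected(self):
        with pytest.raises(ValueError):
            tabulate_morphology({}, {})
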