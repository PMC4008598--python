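import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from msrisk.performance import (
    best_threshold,
    delong_auc_ci,
    delong_paired_test,
    mann_whitney,
    predictive_values,
    roc_curve,
)

# ----------------------------------------------------------------- oracles


def pairwise_auc(cases, controls):
    """Brute-force AUC: (#concordant + 0.5 #ties) / (m*n)."""
    c = np.asarray(cases)[:, None]
    k = np.asarray(controls)[None, :]
    return ((c > k).sum() + 0.5 * (c == k).sum()) / (c.size * k.size)


def psi_matrix(cases, controls):
    c = np.asarray(cases, dtype=float)[:, None]
    k = np.asarray(controls, dtype=float)[None, :]
    return (c > k).astype(float) + 0.5 * (c == k)


def delong_var_oracle(cases, controls):
    """Direct placement-value variance from the full psi matrix."""
    m, n = len(cases), len(controls)
    psi = psi_matrix(cases, controls)
    v10 = psi.mean(axis=1)  # per case
    v01 = psi.mean(axis=0)  # per control
    return v10.var(ddof=1) / m + v01.var(ddof=1) / n


def delong_paired_oracle(scores_a, scores_b, is_case):
    m = int(is_case.sum())
    n = int((~is_case).sum())
    stats_out = []
    placements = []
    for s in (scores_a, scores_b):
        psi = psi_matrix(s[is_case], s[~is_case])
        stats_out.append(psi.mean())
        placements.append((psi.mean(axis=1), psi.mean(axis=0)))
    (v10a, v01a), (v10b, v01b) = placements
    var_a = v10a.var(ddof=1) / m + v01a.var(ddof=1) / n
    var_b = v10b.var(ddof=1) / m + v01b.var(ddof=1) / n
    cov = np.cov(v10a, v10b, ddof=1)[0, 1] / m + np.cov(v01a, v01b, ddof=1)[0, 1] / n
    z = (stats_out[0] - stats_out[1]) / np.sqrt(var_a + var_b - 2 * cov)
    return z, 2 * stats.norm.sf(abs(z))


def labelled(cases, controls):
    scores = np.concatenate([cases, controls])
    labels = np.array(["case"] * len(cases) + ["control"] * len(controls), dtype=object)
    return scores, labels


# --------------------------------------------------------------------- ROC


class TestRocCurve:
    def test_perfect_separation(self):
        scores, labels = labelled([2, 3], [0, 1])
        assert roc_curve(scores, labels).auc == 1.0

    def test_identical_distributions(self):
        scores, labels = labelled([1, 2], [1, 2])
        assert roc_curve(scores, labels).auc == 0.5

    def test_small_fixture_pair_counting(self):
        scores, labels = labelled([3, 1, 4], [2, 0])
        assert roc_curve(scores, labels).auc == pytest.approx(5 / 6, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_equals_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        cases = rng.integers(0, 6, size=23).astype(float)
        controls = rng.integers(0, 6, size=31).astype(float)
        scores, labels = labelled(cases, controls)
        assert roc_curve(scores, labels).auc == pytest.approx(
            pairwise_auc(cases, controls), abs=1e-12
        )

    def test_monotone_operating_points_and_trapezoid(self):
        rng = np.random.default_rng(5)
        scores, labels = labelled(rng.normal(1, 1, 40), rng.normal(0, 1, 50))
        roc = roc_curve(scores, labels)
        assert (np.diff(roc.thresholds) > 0).all()
        assert (np.diff(roc.sens) <= 0).all()
        assert (np.diff(roc.spec) >= 0).all()
        # trapezoid over the (1-spec, sens) polyline reproduces the AUC
        x = 1 - roc.spec
        area = -np.trapezoid(roc.sens, x)  # x decreasing along the arrays
        assert roc.auc == pytest.approx(area, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], ["case", "case"])

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([np.nan, 1.0], ["case", "control"])


class TestDelongVariance:
    def test_perfect_separation_zero_variance(self):
        scores, labels = labelled([3.0, 4.0, 5.0], [0.0, 1.0, 2.0])
        roc = roc_curve(scores, labels)
        var, lo, hi = delong_auc_ci(roc, scores, labels)
        assert var == 0.0
        assert (lo, hi) == (1.0, 1.0)

    def test_matches_placement_value_oracle(self):
        rng = np.random.default_rng(42)
        cases = rng.normal(0.8, 1, 10)
        controls = rng.normal(0, 1, 10)
        scores, labels = labelled(cases, controls)
        roc = roc_curve(scores, labels)
        var, lo, hi = delong_auc_ci(roc, scores, labels)
        assert var == pytest.approx(delong_var_oracle(cases, controls), rel=1e-10)
        assert lo <= roc.auc <= hi

    def test_matches_oracle_with_ties(self):
        cases = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        controls = np.array([0.0, 2.0, 2.0, 4.0, 1.0])
        scores, labels = labelled(cases, controls)
        roc = roc_curve(scores, labels)
        var, *_ = delong_auc_ci(roc, scores, labels)
        assert var == pytest.approx(delong_var_oracle(cases, controls), rel=1e-10)

    def test_within_15pct_of_bootstrap(self):
        rng = np.random.default_rng(2024)
        m = n = 40
        cases = rng.normal(1.0, 1.0, m)
        controls = rng.normal(0.0, 1.0, n)
        scores, labels = labelled(cases, controls)
        var, *_ = delong_auc_ci(roc_curve(scores, labels), scores, labels)
        reps = 10_000
        bi = rng.integers(0, m, size=(reps, m))
        bj = rng.integers(0, n, size=(reps, n))
        bc = cases[bi][:, :, None]
        bk = controls[bj][:, None, :]
        aucs = ((bc > bk).mean(axis=(1, 2)) + 0.5 * (bc == bk).mean(axis=(1, 2)))
        boot_var = aucs.var(ddof=1)
        assert abs(var - boot_var) / boot_var < 0.15

    def test_degenerate_class_sizes_rejected(self):
        scores, labels = labelled([1.0], [0.0, 0.5])
        with pytest.raises(ValueError):
            delong_auc_ci(roc_curve(scores, labels), scores, labels)


class TestDelongPairedTest:
    def test_identical_models(self):
        scores, labels = labelled([1.0, 3.0, 2.0], [0.0, 1.5, 0.5])
        z, p = delong_paired_test(scores, scores, labels)
        assert (z, p) == (0.0, 1.0)

    def test_direction_of_z(self):
        labels = np.array(["case"] * 3 + ["control"] * 3, dtype=object)
        a = np.array([3.0, 4.0, 5.0, 0.0, 1.0, 2.0])  # perfectly separating
        b = -a  # anti-separating
        z, p = delong_paired_test(a, b, labels)
        assert z > 0

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(7)
        is_case = np.array([True] * 10 + [False] * 10)
        base = rng.normal(0, 1, 20) + 0.9 * is_case
        a = base + rng.normal(0, 0.3, 20)
        b = 0.7 * base + rng.normal(0, 0.6, 20)
        labels = np.where(is_case, "case", "control").astype(object)
        z, p = delong_paired_test(a, b, labels)
        z_exp, p_exp = delong_paired_oracle(a, b, is_case)
        assert z == pytest.approx(z_exp, rel=1e-10)
        assert p == pytest.approx(p_exp, rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_paired_test([1.0, 2.0], [1.0], ["case", "control"])


class TestAgainstPROC:
    """Cross-check against R pROC — the reference DeLong implementation."""

    CASES = [1.3, 2.1, 0.4, 3.3, 2.8, 1.9, 0.9, 2.4, 3.0, 1.1, 2.2, 1.7]
    CONTROLS = [0.2, 1.0, 1.5, 0.3, 2.0, 0.8, 1.2, 0.1, 1.8, 0.6, 2.6, 0.5]

    def run_proc(self):
        cases, controls = self.CASES, self.CONTROLS
        a = cases + controls
        b = [0.5 * x + ((-1) ** i) * 0.4 for i, x in enumerate(a)]
        code = f"""
        suppressMessages(library(pROC))
        resp <- c(rep(1, {len(cases)}), rep(0, {len(controls)}))
        sA <- c({', '.join(map(str, a))})
        sB <- c({', '.join(map(str, b))})
        r1 <- roc(resp, sA, quiet=TRUE, direction="<")
        r2 <- roc(resp, sB, quiet=TRUE, direction="<")
        tt <- roc.test(r1, r2, method="delong", paired=TRUE)
        cat(sprintf("%.15f %.15f %.15f", as.numeric(auc(r1)), var(r1, method="delong"), tt$p.value))
        """
        out = subprocess.run(
            ["Rscript", "-e", code], capture_output=True, text=True, check=True
        ).stdout.split()
        return [float(x) for x in out], np.array(a), np.array(b)

    def test_auc_variance_and_paired_p(self):
        (auc_r, var_r, p_r), a, b = self.run_proc()
        labels = np.array(["case"] * len(self.CASES) + ["control"] * len(self.CONTROLS), dtype=object)
        roc = roc_curve(a, labels)
        var, *_ = delong_auc_ci(roc, a, labels)
        _, p = delong_paired_test(a, b, labels)
        assert roc.auc == pytest.approx(auc_r, abs=1e-10)
        assert var == pytest.approx(var_r, rel=1e-8)
        assert p == pytest.approx(p_r, rel=1e-6)


class TestBestThreshold:
    def test_perfect_separation(self):
        scores, labels = labelled([6.0, 7.0], [3.0, 4.0])
        thr, sens, spec = best_threshold(roc_curve(scores, labels))
        assert 4.0 < thr <= 6.0
        assert sens == 1.0 and spec == 1.0

    def test_exhaustive_scan_oracle(self):
        cases, controls = [3.0, 1.0, 4.0], [2.0, 0.0]
        scores, labels = labelled(cases, controls)
        thr, sens, spec = best_threshold(roc_curve(scores, labels))
        best = max(
            (
                (np.mean([c >= t for c in cases]) + np.mean([k < t for k in controls]))
                for t in np.unique(scores)
            )
        )
        assert sens + spec == pytest.approx(best, abs=1e-12)

    def test_all_scores_equal_degenerate(self):
        scores, labels = labelled([1.0, 1.0], [1.0, 1.0])
        thr, sens, spec = best_threshold(roc_curve(scores, labels))
        assert sens + spec == pytest.approx(1.0)


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        with pytest.warns(UserWarning):
            u, p = mann_whitney([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_exact_enumeration_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2 * 1/C(6,3)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_u_auc_identity(self, seed):
        rng = np.random.default_rng(seed)
        cases = rng.integers(0, 8, 25).astype(float)
        controls = rng.integers(0, 8, 30).astype(float)
        u, _ = mann_whitney(cases, controls)
        assert u / (len(cases) * len(controls)) == pytest.approx(
            pairwise_auc(cases, controls), abs=1e-12
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPredictiveValues:
    def test_low_prevalence_screening(self):
        # sens/spec of the best full-model threshold at 1/1,000 prevalence
        ppv, npv = predictive_values(0.714, 0.785, 0.001)
        assert ppv < 0.01
        assert ppv == pytest.approx(0.714e-3 / (0.714e-3 + 0.215 * 0.999), rel=1e-12)
        assert npv > 0.999

    def test_even_prevalence(self):
        ppv, _ = predictive_values(0.714, 0.785, 0.5)
        assert ppv == pytest.approx(0.714 / (0.714 + 0.215), rel=1e-9)

    def test_perfect_test(self):
        assert predictive_values(1.0, 1.0, 0.3) == (1.0, 1.0)

    def test_zero_denominator_gives_nan(self):
        ppv, npv = predictive_values(0.0, 1.0, 0.0)
        assert np.isnan(ppv)
        assert npv == 1.0

    @given(
        sens=st.floats(0.05, 0.95),
        spec=st.floats(0.05, 0.95),
        prev=st.floats(0.01, 0.5),
        bump=st.floats(0.01, 0.4),
    )
    def test_ppv_increasing_in_prevalence(self, sens, spec, prev, bump):
        ppv1, _ = predictive_values(sens, spec, prev)
        ppv2, _ = predictive_values(sens, spec, min(prev + bump, 0.99))
        assert ppv2 > ppv1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            predictive_values(1.2, 0.5, 0.1)
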