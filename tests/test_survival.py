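"""Survival machinery: KM, log-rank, Cox PH, ROC cutoff, screen, associations."""

import numpy as np
import pandas as pd
import pytest

from mdsplice.io import ValidationError
from mdsplice.survival import (
    contingency_chi2,
    cox_ph_fit,
    group_comparisons,
    kaplan_meier,
    logrank_test,
    roc_survival_cutoff,
    univariate_event_screen,
)


# --- independent oracles -----------------------------------------------------

def km_oracle(time, event):
    """Product-limit estimate by direct enumeration over event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(time[event == 1])):
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def cox_grid_oracle(time, event, x, lo=-3.0, hi=3.0):
    """Brute-force 1-D partial-likelihood maximizer, refined to ~1e-6."""
    from mdsplice.survival import cox_partial_loglik

    def nll(b):
        return -cox_partial_loglik(np.array([b]), time, event, x[:, None])

    for _ in range(6):
        grid = np.linspace(lo, hi, 201)
        vals = [nll(b) for b in grid]
        k = int(np.argmin(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, 200)]
    return (lo + hi) / 2


class TestKaplanMeier:
    def test_hand_example(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_all_censored(self):
        km = kaplan_meier([5, 8, 12], [0, 0, 0])
        assert km.times.size == 0
        assert np.isinf(km.median)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            kaplan_meier([-1, 2], [1, 1])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        t = rng.exponential(10, 60).round(1)  # rounding forces ties
        e = rng.integers(0, 2, 60)
        if e.sum() == 0:
            e[0] = 1
        km = kaplan_meier(t, e)
        ot, os_ = km_oracle(t, e)
        assert np.allclose(km.times, ot)
        assert np.allclose(km.survival, os_, atol=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 40)
        km = kaplan_meier(t, np.ones(40, int))
        emp = [(t > ti).mean() for ti in km.times]
        assert np.allclose(km.survival, emp, atol=1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 3, 5, 7]
        e = [1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_worked_four_observation_example(self):
        # risk tables by hand: O-E = 7/6, Var = 17/36 -> chi2 = 49/17
        chi2, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(49 / 17, rel=1e-9)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(5, 20), rng.exponential(8, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        ea[0] = eb[0] = 1
        assert logrank_test(ta, ea, tb, eb) == pytest.approx(
            logrank_test(tb, eb, ta, ea))

    def test_type_one_error_under_null(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            t = rng.exponential(10, 40)
            e = (t <= 15).astype(int)
            t = np.minimum(t, 15)
            _, p = logrank_test(t[:20], e[:20], t[20:], e[20:])
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestCoxPH:
    def test_null_covariate_small_coefficient(self):
        rng = np.random.default_rng(4)
        coefs = []
        for _ in range(40):
            x = rng.normal(size=150)
            t = rng.exponential(10, 150)
            e = (t <= 12).astype(int)
            fit = cox_ph_fit(np.minimum(t, 12), e, pd.DataFrame({"x": x}))
            coefs.append(fit.summary["coef"].iloc[0])
        assert abs(np.mean(coefs)) < 0.05

    def test_recovers_true_hazard_ratio_two(self):
        rng = np.random.default_rng(5)
        n = 500
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.05 * np.exp(np.log(2) * x)))
        e = (t <= 40).astype(int)
        fit = cox_ph_fit(np.minimum(t, 40), e, pd.DataFrame({"x": x}))
        assert fit.summary["coef"].iloc[0] == pytest.approx(np.log(2), abs=0.15)
        lo, hi = fit.summary["ci_low"].iloc[0], fit.summary["ci_high"].iloc[0]
        assert lo <= fit.summary["hr"].iloc[0] <= hi

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(6)
        n = 20
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * x))
        e = np.ones(n, int)
        fit = cox_ph_fit(t, e, pd.DataFrame({"x": x}))
        oracle = cox_grid_oracle(t, e, x)
        assert fit.summary["coef"].iloc[0] == pytest.approx(oracle, abs=1e-4)

    def test_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(7)
        n = 120
        X = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-(0.5 * X[:, 0] - 0.3 * X[:, 1])))
        e = (t <= 2).astype(int)
        t = np.minimum(t, 2)
        mine = cox_ph_fit(t, e, pd.DataFrame(X, columns=["a", "b"]))
        df = pd.DataFrame({"t": t, "e": e, "a": X[:, 0], "b": X[:, 1]})
        ll = CoxPHFitter().fit(df, "t", "e")  # Efron == Breslow when tie-free
        assert np.allclose(mine.summary["coef"], ll.params_, atol=1e-4)
        assert np.allclose(mine.summary["se"], ll.standard_errors_, atol=1e-4)

    def test_breslow_and_efron_agree_without_ties(self):
        rng = np.random.default_rng(8)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        fit_b = cox_ph_fit(t, np.ones(n, int), pd.DataFrame({"x": x}), "breslow")
        fit_e = cox_ph_fit(t, np.ones(n, int), pd.DataFrame({"x": x}), "efron")
        assert fit_b.summary["coef"].iloc[0] == pytest.approx(
            fit_e.summary["coef"].iloc[0], abs=1e-6)

    def test_affine_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(9)
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        e = np.ones(n, int)
        base = cox_ph_fit(t, e, pd.DataFrame({"x": x})).summary["coef"].iloc[0]
        shifted = cox_ph_fit(t, e, pd.DataFrame({"x": x + 100})).summary["coef"].iloc[0]
        scaled = cox_ph_fit(t, e, pd.DataFrame({"x": 2 * x})).summary["coef"].iloc[0]
        assert shifted == pytest.approx(base, rel=1e-6)
        assert scaled == pytest.approx(base / 2, rel=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            cox_ph_fit([1, 2, 3], [1, 1, 1], pd.DataFrame({"x": [1.0, 1.0, 1.0]}))

    def test_separation_flagged_and_capped(self):
        # covariate perfectly orders survival: monotone likelihood
        t = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        e = np.ones(8, int)
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="monotone"):
            fit = cox_ph_fit(t, e, pd.DataFrame({"x": x}))
        assert fit.separation
        assert abs(fit.summary["coef"].iloc[0]) <= 40.0


class TestROCCutoff:
    def test_perfect_separation(self):
        res = roc_survival_cutoff([1, 2, 3, 4], [10, 9, 2, 1], [0, 0, 1, 1])
        assert res.cutoff == 2.5
        assert res.youden_j == 1.0
        assert res.youden_j == res.sensitivity + res.specificity - 1

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(10)
        s = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        res = roc_survival_cutoff(s, np.ones(60), y)
        uniq = np.unique(s)
        best = max(
            ((s[y == 1] > c).mean() + (s[y == 0] <= c).mean() - 1)
            for c in (uniq[:-1] + uniq[1:]) / 2)
        assert res.youden_j == pytest.approx(best, abs=1e-12)

    def test_permuted_labels_give_small_j(self):
        rng = np.random.default_rng(11)
        s = rng.normal(size=200)
        js = []
        for _ in range(100):
            y = rng.permutation(np.repeat([0, 1], 100))
            js.append(roc_survival_cutoff(s, np.ones(200), y).youden_j)
        assert np.mean(js) < 0.25

    def test_identical_labels_rejected(self):
        with pytest.raises(ValidationError):
            roc_survival_cutoff([1, 2, 3], [1, 2, 3], [1, 1, 1])

    def test_logrank_scan_variant(self):
        rng = np.random.default_rng(12)
        s = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
        t = np.concatenate([rng.exponential(30, 30), rng.exponential(5, 30)])
        e = np.ones(60, int)
        res = roc_survival_cutoff(s, t, e, method="logrank")
        hi = s > res.cutoff
        assert 0 < hi.sum() < 60


class TestScreen:
    def _make_si(self, preds: pd.DataFrame):
        """Wrap a psr x patient log2-SI frame as a SplicingIndexMatrix."""
        from mdsplice.io import ExpressedGeneSet
        from mdsplice.splicing import SplicingIndexMatrix
        ratio = np.exp2(preds)
        conv = ratio.where(ratio >= 1, -1.0 / ratio)
        genes = pd.Series([f"G{i}" for i in range(len(preds))],
                          index=preds.index)
        return SplicingIndexMatrix(
            linear_ratio=ratio, converted=conv, analyzable=ratio.notna(),
            expressed=ExpressedGeneSet(frozenset(genes), len(genes),
                                       len(genes), 0.0),
            gene_of=genes)

    def test_bonferroni_arithmetic_and_zero_variance_exclusion(self):
        rng = np.random.default_rng(13)
        n = 60
        patients = [f"P{i}" for i in range(n)]
        x = rng.normal(size=n)
        preds = pd.DataFrame(
            [x, rng.normal(size=n), np.zeros(n)],
            index=pd.Index(["psr_a", "psr_b", "psr_const"], name="psr_id"),
            columns=patients)
        t = rng.exponential(np.exp(-1.2 * x))
        outcomes = pd.DataFrame({"time": t, "event": 1}, index=patients)
        res = univariate_event_screen(self._make_si(preds), outcomes)
        assert res.m_tested == 2                    # constant PSR not in M
        assert "psr_const" not in res.table.index
        assert np.allclose(res.table["p_bonferroni"],
                           np.minimum(1.0, res.table["p_raw"] * 2))

    def test_pass_set_shrinks_as_m_grows(self):
        rng = np.random.default_rng(14)
        n = 80
        patients = [f"P{i}" for i in range(n)]
        x = rng.normal(size=n)
        rows = [x] + [rng.normal(size=n) for _ in range(30)]
        preds = pd.DataFrame(rows,
                             index=pd.Index([f"psr{i}" for i in range(31)],
                                            name="psr_id"),
                             columns=patients)
        t = rng.exponential(np.exp(-1.0 * x))
        outcomes = pd.DataFrame({"time": t, "event": 1}, index=patients)
        si = self._make_si(preds)
        small = univariate_event_screen(si, outcomes, psr_ids=["psr0", "psr1"])
        big = univariate_event_screen(si, outcomes)
        assert set(big.passed) <= set(small.passed) | set(
            p for p in big.passed if p not in ("psr0", "psr1"))
        # same raw p, larger correction burden -> adjusted p never smaller
        assert (big.table.loc["psr0", "p_bonferroni"]
                >= small.table.loc["psr0", "p_bonferroni"])

    def test_family_wise_error_controlled_under_null(self):
        rng = np.random.default_rng(15)
        n, m = 80, 60
        false_hits = 0
        n_rep = 40
        patients = [f"P{i}" for i in range(n)]
        for _ in range(n_rep):
            preds = pd.DataFrame(rng.normal(size=(m, n)),
                                 index=pd.Index([f"psr{i}" for i in range(m)],
                                                name="psr_id"),
                                 columns=patients)
            t = rng.exponential(10, n)
            outcomes = pd.DataFrame({"time": t, "event": 1}, index=patients)
            res = univariate_event_screen(self._make_si(preds), outcomes)
            false_hits += len(res.passed) > 0
        # FWER target 0.05; allow binomial slack at 40 replicates
        assert false_hits <= 5


class TestAssociations:
    def test_reported_sex_association(self):
        # high/low score split: male 87/34, female 30/25
        chi2, p = contingency_chi2([[87, 34], [30, 25]])
        closed_form = 176 * (87 * 25 - 34 * 30) ** 2 / (121 * 55 * 117 * 59)
        assert chi2 == pytest.approx(closed_form, rel=1e-12)
        assert round(p, 3) == 0.024

    def test_independence_gives_zero(self):
        chi2, p = contingency_chi2([[50, 50], [50, 50]])
        assert chi2 == 0.0
        assert p == 1.0

    def test_fisher_matches_hypergeometric_enumeration(self):
        from scipy.stats import hypergeom
        table = [[8, 2], [1, 5]]
        _, p = contingency_chi2(table, method="fisher")
        a, b, c, d = 8, 2, 1, 5
        n, K, N = a + b + c + d, a + b, a + c
        probs = [hypergeom.pmf(k, n, K, N)
                 for k in range(max(0, K + N - n), min(K, N) + 1)]
        p0 = hypergeom.pmf(a, n, K, N)
        enumerated = sum(q for q in probs if q <= p0 * (1 + 1e-9))
        assert p == pytest.approx(enumerated, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            contingency_chi2([[0, 0], [5, 5]])

    def test_anova_hand_example(self):
        f, p = group_comparisons([1, 2, 3, 4, 5, 6],
                                 groups=["a", "a", "a", "b", "b", "b"])
        assert f == pytest.approx(13.5, rel=1e-12)

    def test_identical_groups_f_zero(self):
        f, p = group_comparisons([1, 2, 3, 1, 2, 3],
                                 groups=["a", "a", "a", "b", "b", "b"])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = group_comparisons(x, y=2 * x + 1, kind="pearson_corr")
        assert r == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            group_comparisons([1, 1, 1], y=[1, 2, 3], kind="pearson_corr")
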