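"""Benchmark metrics against closed-form and brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ffpearray.concordance import (
    BenchmarkConfig,
    ConcordanceReport,
    compare_pipelines,
    concordance_report,
    differential_expression,
    fold_change_agreement,
    leave_one_out_robustness,
    probeset_correlation,
    sample_correlation,
    sensitivity_ppv,
)
from ffpearray.errors import ConfigurationError, ValidationError


def _expr(rng, n_ps=20, samples=("a", "b", "c", "d")):
    return pd.DataFrame(
        rng.normal(7, 1.5, size=(n_ps, len(samples))),
        index=[f"ps{i}" for i in range(n_ps)],
        columns=samples,
    )


PAIRS4 = [(f"f{i}", f"p{i}") for i in range(4)]


def pearson_oracle(x, y):
    x, y = np.asarray(x), np.asarray(y)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / math.sqrt(np.sum(xm**2) * np.sum(ym**2)))


class TestSampleCorrelation:
    def test_identical_and_reflected(self, rng):
        f = _expr(rng, samples=[p[0] for p in PAIRS4])
        p_same = f.copy()
        p_same.columns = [p[1] for p in PAIRS4]
        r, med = sample_correlation(f, p_same, PAIRS4)
        np.testing.assert_allclose(r.to_numpy(), 1.0)
        assert med == pytest.approx(1.0)
        p_neg = -f.copy() + 14
        p_neg.columns = [p[1] for p in PAIRS4]
        r, med = sample_correlation(f, p_neg, PAIRS4)
        np.testing.assert_allclose(r.to_numpy(), -1.0)

    def test_matches_textbook_formula(self, rng):
        f = _expr(rng, n_ps=100, samples=[p[0] for p in PAIRS4])
        p = _expr(rng, n_ps=100, samples=[p[1] for p in PAIRS4])
        r, _ = sample_correlation(f, p, PAIRS4)
        for fcol, pcol in PAIRS4:
            assert r[fcol] == pytest.approx(pearson_oracle(f[fcol], p[pcol]), abs=1e-12)

    def test_too_few_probesets(self, rng):
        f = _expr(rng, n_ps=1, samples=[p[0] for p in PAIRS4])
        p = _expr(rng, n_ps=1, samples=[p[1] for p in PAIRS4])
        with pytest.raises(ValidationError):
            sample_correlation(f, p, PAIRS4)


class TestProbesetCorrelation:
    def test_identical_matrices_all_one(self, rng):
        f = _expr(rng, samples=[p[0] for p in PAIRS4])
        p = f.copy()
        p.columns = [q[1] for q in PAIRS4]
        r, med = probeset_correlation(f, p, PAIRS4)
        np.testing.assert_allclose(r.to_numpy(), 1.0, atol=1e-12)
        assert med == pytest.approx(1.0)

    def test_iqr_filter_keeps_most_variant_half(self, rng):
        f = _expr(rng, n_ps=10, samples=[p[0] for p in PAIRS4])
        p = _expr(rng, n_ps=10, samples=[p[1] for p in PAIRS4])
        r, _ = probeset_correlation(f, p, PAIRS4)
        iqr = f.quantile(0.75, axis=1) - f.quantile(0.25, axis=1)
        expected = set(iqr.sort_values(ascending=False).index[:5])
        assert set(r.index) == expected and len(r) == 5

    def test_constant_probeset_never_produces_nan(self, rng):
        f = _expr(rng, n_ps=6, samples=[p[0] for p in PAIRS4])
        f.iloc[0] = 5.0  # zero IQR: ranked last, excluded by the filter
        p = _expr(rng, n_ps=6, samples=[p[1] for p in PAIRS4])
        r, med = probeset_correlation(f, p, PAIRS4)
        assert "ps0" not in r.index
        assert np.isfinite(r.to_numpy()).all() and np.isfinite(med)

    def test_requires_three_pairs(self, rng):
        f = _expr(rng, samples=["f0", "f1"])
        p = _expr(rng, samples=["p0", "p1"])
        with pytest.raises(ValidationError):
            probeset_correlation(f, p, [("f0", "p0"), ("f1", "p1")])


class TestDifferentialExpression:
    def test_hand_computed_t_on_toy_table(self):
        # two probesets, groups of 3 vs 3; equal-variance Student's t
        a = np.array([5.0, 6.0, 7.0])
        b = np.array([9.0, 8.0, 10.0])
        expr = pd.DataFrame(
            [np.concatenate([a, b]), np.concatenate([b, a])],
            index=["x", "y"],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        res = differential_expression(expr, labels)
        sp = math.sqrt(((2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4) * (2 / 3))
        t_expected = (a.mean() - b.mean()) / sp
        from scipy import stats as st

        p_expected = 2 * st.t.sf(abs(t_expected), df=4)
        assert res.table.loc["x", "t"] == pytest.approx(t_expected, abs=1e-12)
        assert res.table.loc["x", "p"] == pytest.approx(p_expected, abs=1e-12)
        assert res.table.loc["x", "log2_fc"] == pytest.approx(-3.0)
        assert res.table.loc["y", "log2_fc"] == pytest.approx(3.0)

    def test_bh_adjustment_hand_worked(self, rng):
        # engineer distinct p values, then verify the BH staircase
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.01, 0.02, 0.04])
        adj = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.004, 0.02, 0.0267, 0.04], atol=1e-4)
        # and the same staircase computed by hand: min over j>=i of p_j*n/j
        hand = [min(p[j] * 4 / (j + 1) for j in range(i, 4)) for i in range(4)]
        np.testing.assert_allclose(adj, hand, atol=1e-12)

    def test_equal_groups_give_p_near_one(self, rng):
        base = rng.normal(7, 1, size=10)
        expr = pd.DataFrame(
            np.column_stack([base + rng.normal(0, 1e-6, 10) for _ in range(6)]),
            index=[f"ps{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        res = differential_expression(expr, labels)
        assert (res.table["p"] > 0.01).all()
        assert np.allclose(res.table["log2_fc"], 0.0, atol=1e-5)
        assert not res.table["de"].any()

    def test_fdr_rule(self, rng):
        expr = _expr(rng, n_ps=8, samples=[f"s{i}" for i in range(6)])
        labels = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        res = differential_expression(
            expr, labels, BenchmarkConfig(de_rule="fdr", fdr_threshold=0.5)
        )
        assert res.rule == "fdr"
        assert res.de_ids == set(res.table.index[res.table["p_adj"] < 0.5])

    def test_group_size_validation(self, rng):
        expr = _expr(rng, samples=["s0", "s1", "s2"])
        with pytest.raises(ValidationError):
            differential_expression(expr, {"s0": "A", "s1": "A", "s2": "B"})


class TestFoldChangeAgreement:
    def test_perfect_agreement(self, rng):
        fc = pd.Series(rng.normal(size=50), index=[f"ps{i}" for i in range(50)])
        res = fold_change_agreement(fc, fc)
        assert res.correlation.value == pytest.approx(1.0)
        assert res.slope.value == pytest.approx(1.0, abs=1e-12)
        assert res.slope.ci_low <= 1.0 <= res.slope.ci_high
        assert res.correlation.ci_low <= 1.0 <= res.correlation.ci_high

    def test_attenuated_fold_changes(self, rng):
        fc = pd.Series(rng.normal(size=50), index=[f"ps{i}" for i in range(50)])
        res = fold_change_agreement(fc, 0.5 * fc)
        assert res.correlation.value == pytest.approx(1.0)
        assert res.slope.value == pytest.approx(0.5, abs=1e-12)

    def test_slope_and_ci_match_normal_equations(self, rng):
        x = pd.Series(rng.normal(size=200), index=[f"ps{i}" for i in range(200)])
        y = 0.7 * x + pd.Series(rng.normal(scale=0.3, size=200), index=x.index)
        res = fold_change_agreement(x, y, BenchmarkConfig(ci_level=0.95))
        X = np.column_stack([np.ones(200), x.to_numpy()])
        beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        resid = y.to_numpy() - X @ beta
        s2 = resid @ resid / (200 - 2)
        se = math.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        from scipy import stats as st

        tcrit = st.t.ppf(0.975, 198)
        assert res.slope.value == pytest.approx(beta[1], abs=1e-10)
        assert res.slope.ci_low == pytest.approx(beta[1] - tcrit * se, abs=1e-10)
        assert res.slope.ci_high == pytest.approx(beta[1] + tcrit * se, abs=1e-10)
        # Fisher-z CI for the correlation
        r = pearson_oracle(x, y)
        z = np.arctanh(r)
        half = st.norm.ppf(0.975) / math.sqrt(197)
        assert res.correlation.value == pytest.approx(r, abs=1e-12)
        assert res.correlation.ci_low == pytest.approx(math.tanh(z - half), abs=1e-10)
        assert res.correlation.ci_high == pytest.approx(math.tanh(z + half), abs=1e-10)


class TestSensitivityPpv:
    def test_set_counting(self):
        assert sensitivity_ppv({"a", "b", "c", "d"}, {"c", "d", "e"}) == (0.5, 2 / 3)
        assert sensitivity_ppv({"a"}, {"a"}) == (1.0, 1.0)
        assert sensitivity_ppv({"a"}, {"b"}) == (0.0, 0.0)

    def test_empty_denominators_are_missing(self):
        sens, ppv = sensitivity_ppv(set(), {"a"})
        assert sens is None and ppv == 0.0
        sens, ppv = sensitivity_ppv({"a"}, set())
        assert sens == 0.0 and ppv is None

    def test_role_swap_exchanges_metrics(self, rng):
        universe = [f"ps{i}" for i in range(30)]
        a = set(rng.choice(universe, 10, replace=False))
        b = set(rng.choice(universe, 14, replace=False))
        assert sensitivity_ppv(a, b) == tuple(reversed(sensitivity_ppv(b, a)))


class TestLeaveOneOut:
    def _setup(self, rng, n=5):
        pairs = [(f"f{i}", f"p{i}") for i in range(2 * n)]
        f = _expr(rng, n_ps=40, samples=[q[0] for q in pairs])
        p = f + rng.normal(scale=0.5, size=f.shape)
        p.columns = [q[1] for q in pairs]
        f.iloc[:6, :n] += 2.0  # subgroup effect on the first samples
        p.iloc[:6, :n] += 2.0
        labels = {f"f{i}": ("A" if i < n else "B") for i in range(2 * n)}
        return f, p, labels, pairs

    def test_one_replicate_per_removal(self, rng):
        f, p, labels, pairs = self._setup(rng)
        res = leave_one_out_robustness(f, p, labels, pairs,
                                       BenchmarkConfig(de_p_threshold=0.01))
        assert len(res.sensitivity) == len(pairs)
        assert res.n_skipped == 0
        assert np.isfinite(res.ppv_sd)

    def test_removal_below_two_skipped(self, rng):
        f, p, labels, pairs = self._setup(rng, n=2)
        with pytest.warns(UserWarning, match="skipped"):
            res = leave_one_out_robustness(f, p, labels, pairs,
                                           BenchmarkConfig(de_p_threshold=0.01))
        assert res.n_skipped == len(pairs)


def _report(name, sc, pc):
    return ConcordanceReport(
        pipeline=name,
        sample_correlations=sc,
        median_sample_correlation=float(sc.median()),
        probeset_correlations=pc,
        median_probeset_correlation=float(pc.median()),
        fold_change=None,
        sensitivity=None,
        ppv=None,
        n_probesets=len(pc),
        n_de_frozen=0,
        n_de_ffpe=0,
    )


class TestComparePipelines:
    def test_self_comparison_p_one(self, rng):
        sc = pd.Series(rng.uniform(0.5, 0.9, 10), index=[f"f{i}" for i in range(10)])
        pc = pd.Series(rng.uniform(0, 1, 30))
        table = compare_pipelines([_report("x", sc, pc), _report("x2", sc.copy(), pc.copy())])
        assert table.loc[0, "sample_corr_wilcoxon_p"] == 1.0
        assert table.loc[0, "probeset_corr_mannwhitney_p"] == 1.0

    def test_uniform_shift_detected_by_signed_rank(self, rng):
        """One pipeline uniformly +0.1 over another on 20 pairs: the exact
        signed-rank p for 20 same-sign differences is 2/2^20."""
        sc = pd.Series(rng.uniform(0.4, 0.8, 20), index=[f"f{i}" for i in range(20)])
        pc = pd.Series(rng.uniform(0, 1, 30))
        table = compare_pipelines([_report("hi", sc + 0.1, pc), _report("lo", sc, pc)])
        p = table.loc[0, "sample_corr_wilcoxon_p"]
        assert p == pytest.approx(2 / 2**20, rel=1e-6)
        assert p < 0.01

    def test_mannwhitney_matches_rank_enumeration(self, rng):
        a = pd.Series([0.9, 0.8, 0.7, 0.6])
        b = pd.Series([0.5, 0.4, 0.3])
        sc = pd.Series(rng.uniform(size=5), index=[f"f{i}" for i in range(5)])
        table = compare_pipelines([_report("a", sc, a), _report("b", sc.copy(), b)])
        # exact U-test by enumerating all 7!/(4!3!) arrangements
        from scipy.stats import rankdata

        combined = np.concatenate([a, b])
        ranks = rankdata(combined)
        u_obs = ranks[:4].sum() - 4 * 5 / 2
        stats_all = []
        for comb in itertools.combinations(range(7), 4):
            stats_all.append(ranks[list(comb)].sum() - 4 * 5 / 2)
        stats_all = np.array(stats_all)
        mean_u = 4 * 3 / 2
        p_exact = np.mean(np.abs(stats_all - mean_u) >= abs(u_obs - mean_u))
        assert table.loc[0, "probeset_corr_mannwhitney_p"] == pytest.approx(p_exact, rel=1e-9)

    def test_mismatched_pair_sets_rejected(self, rng):
        sc1 = pd.Series(rng.uniform(size=5), index=[f"f{i}" for i in range(5)])
        sc2 = pd.Series(rng.uniform(size=5), index=[f"g{i}" for i in range(5)])
        pc = pd.Series(rng.uniform(size=10))
        with pytest.raises(ValidationError):
            compare_pipelines([_report("a", sc1, pc), _report("b", sc2, pc)])


class TestBenchmarkConfig:
    def test_threshold_bounds(self):
        with pytest.raises(ConfigurationError):
            BenchmarkConfig(de_p_threshold=0.0)
        with pytest.raises(ConfigurationError):
            BenchmarkConfig(iqr_fraction=1.5)
        with pytest.raises(ConfigurationError):
            BenchmarkConfig(de_rule="bonferroni")


class TestConcordanceReport:
    def test_full_report_on_simulated_expression(self, small_dataset, descriptions):
        from ffpearray.normalization import rma

        cd = descriptions["refseq_dist"]
        expr_f = rma(small_dataset.frozen, cd)
        expr_p = rma(small_dataset.ffpe, cd)
        rep = concordance_report(
            "(rma, refseq_dist)", expr_f, expr_p, small_dataset.annotation,
            BenchmarkConfig(de_p_threshold=0.01), leave_one_out=True,
        )
        assert -1 <= rep.median_sample_correlation <= 1
        assert rep.fold_change.correlation.ci_low <= rep.fold_change.correlation.value
        assert rep.fold_change.slope.ci_low <= rep.fold_change.slope.value <= rep.fold_change.slope.ci_high
        if rep.sensitivity is not None:
            assert 0 <= rep.sensitivity <= 1
        if rep.ppv is not None:
            assert 0 <= rep.ppv <= 1
        assert rep.leave_one_out is not None
        summary = rep.summary()
        assert summary["pipeline"] == "(rma, refseq_dist)"
        assert "loo_ppv_sd" in summary
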