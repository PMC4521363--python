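"""Folded-Skellam mixture fitting, LRT, signal designation and SNP calls."""

import numpy as np
import pytest

from aeimix.folded_mixture import (
    ComponentTestResult,
    FoldedSkellamComponent,
    FoldedSkellamMixtureModel,
    classify_snps,
    designate_signal_components,
    fit_mixture_em,
    fit_mixture_em_best,
    lrt_equal_means,
    posterior_probs,
    select_k_bic_folded,
)
from aeimix.skellam import sample_folded_skellam


def _model(components):
    total_w = sum(w for w, _, _ in components)
    comps = tuple(
        FoldedSkellamComponent(weight=w / total_w, lambda_hi=max(a, b), lambda_lo=min(a, b))
        for w, a, b in components
    )
    return FoldedSkellamMixtureModel(
        K=len(comps), components=comps, loglik=0.0, bic=0.0, n_obs=1
    )


class TestEmFit:
    def test_all_zero_data_shrinks_rates(self):
        m = fit_mixture_em([0] * 50 + [1], K=1)
        assert m.components[0].total < 0.2

    def test_k1_recovery(self):
        y = sample_folded_skellam(10_000, (90, 160), seed=3)
        m = fit_mixture_em(y, K=1, seed=4)
        c = m.components[0]
        assert c.lambda_hi == pytest.approx(160, rel=0.05)
        assert c.lambda_lo == pytest.approx(90, rel=0.05)

    def test_k2_recovery(self):
        y = np.concatenate(
            [
                sample_folded_skellam(7000, (5, 5), seed=5),
                sample_folded_skellam(3000, (90, 160), seed=6),
            ]
        )
        m = fit_mixture_em_best(y, K=2, restarts=4, seed=7)
        wide = m.components[1]
        assert m.components[0].weight == pytest.approx(0.7, abs=0.03)
        assert wide.lambda_hi == pytest.approx(160, rel=0.10)
        assert wide.lambda_lo == pytest.approx(90, rel=0.10)

    def test_monotone_loglik(self):
        y = sample_folded_skellam(2000, (20, 40), seed=8)
        lls = []
        for iters in (1, 2, 4, 8, 16):
            m = fit_mixture_em(y, K=2, max_iter=iters, seed=9)
            lls.append(m.loglik)
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_k_exceeding_distinct_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_mixture_em([2, 2, 2], K=2)


class TestSelectK:
    def test_one_population(self):
        y = sample_folded_skellam(3000, (30, 30), seed=10)
        m = select_k_bic_folded(y, range(1, 4), restarts=2, seed=11)
        assert m.K == 1

    def test_two_populations(self):
        y = np.concatenate(
            [
                sample_folded_skellam(2500, (6, 6), seed=12),
                sample_folded_skellam(1500, (80, 170), seed=13),
            ]
        )
        m = select_k_bic_folded(y, range(1, 4), restarts=2, seed=14)
        assert m.K == 2

    def test_singleton_range(self):
        y = sample_folded_skellam(800, (10, 30), seed=15)
        m = select_k_bic_folded(y, [4], restarts=2, seed=16)
        assert m.K == 4


class TestPosterior:
    def test_k1_all_ones(self):
        m = _model([(1.0, 5, 5)])
        post = posterior_probs(m, [0, 1, 2, 3])
        assert np.allclose(post, 1.0)

    def test_tail_point_goes_to_wide_component(self):
        m = _model([(0.9, 5, 5), (0.1, 90, 160)])
        post = posterior_probs(m, [120])
        assert post[0, 1] > 0.999

    def test_rows_sum_to_one(self):
        m = _model([(0.5, 3, 3), (0.3, 20, 40), (0.2, 90, 160)])
        rng = np.random.default_rng(17)
        post = posterior_probs(m, rng.integers(0, 200, size=50))
        assert np.allclose(post.sum(axis=1), 1.0)


class TestLrt:
    def test_null_data_small_stat(self):
        y = sample_folded_skellam(2000, (66, 66), seed=18)
        m = fit_mixture_em(y, K=1, seed=19)
        res = lrt_equal_means(m, 0, y)
        assert res.tested
        assert res.stat < 15  # no systematic signal on null data

    def test_imbalanced_data_rejects(self):
        y = sample_folded_skellam(400, (93, 166), seed=20)
        m = fit_mixture_em(y, K=1, seed=21)
        res = lrt_equal_means(m, 0, y)
        assert res.pvalue < 1e-6

    def test_stat_clamped_nonnegative(self):
        # component rates far from the data's own MLE force L1 < L0
        m = _model([(1.0, 40, 40)])
        y = sample_folded_skellam(100, (5, 5), seed=22)
        res = lrt_equal_means(m, 0, y)
        assert res.stat == 0.0
        assert res.pvalue == 1.0

    def test_small_component_untested(self):
        m = _model([(1.0, 5, 5)])
        res = lrt_equal_means(m, 0, [1, 2, 3], min_test_n=10)
        assert not res.tested
        assert np.isnan(res.pvalue)


class TestDesignation:
    def test_no_significant_no_signal(self):
        m = _model([(0.6, 5, 5), (0.4, 20, 20)])
        results = [
            ComponentTestResult(0, 100, True, pvalue=0.4, stat=0.5),
            ComponentTestResult(1, 100, True, pvalue=0.2, stat=1.0),
        ]
        assert designate_signal_components(m, results) == set()

    def test_untested_inherit_by_larger_gap(self):
        # mirrors the published configuration: two significant components,
        # two untested ones even further from zero, two null components
        m = _model(
            [
                (0.54, 65.7, 69.2),   # null
                (0.10, 83.8, 106),    # significant, gap 22.2
                (0.0065, 268, 80.3),  # untested, gap 187.7
                (0.037, 92.7, 166),   # significant, gap 73.3
                (0.0003, 214.8, 78.1),  # untested, gap 136.7
                (0.3, 4.81, 5.39),    # null
            ]
        )
        results = [
            ComponentTestResult(0, 5459, True, pvalue=1.0),
            ComponentTestResult(1, 482, True, pvalue=1e-6),
            ComponentTestResult(2, 3, False),
            ComponentTestResult(3, 130, True, pvalue=1e-6),
            ComponentTestResult(4, 2, False),
            ComponentTestResult(5, 4626, True, pvalue=1.0),
        ]
        assert designate_signal_components(m, results) == {1, 2, 3, 4}

    def test_untested_small_gap_excluded(self):
        m = _model([(0.5, 50, 100), (0.45, 10, 10), (0.05, 30, 40)])
        results = [
            ComponentTestResult(0, 500, True, pvalue=1e-8),  # gap 50
            ComponentTestResult(1, 450, True, pvalue=0.9),
            ComponentTestResult(2, 5, False),                # gap 10 < 50
        ]
        assert designate_signal_components(m, results) == {0}


class TestClassify:
    def test_zero_signal_prob_is_no_aei(self):
        m = _model([(0.7, 5, 5), (0.3, 90, 160)])
        calls = classify_snps(m, [0, 1], {1})
        assert list(calls["designation"]) == ["no_AEI", "no_AEI"]
        assert (calls["signal_prob"] < 0.01).all()

    def test_threshold_rule_boundary(self):
        m = _model([(0.5, 8, 8), (0.5, 30, 60)])
        y = [18]
        calls80 = classify_snps(m, y, {1}, rule="threshold", threshold=0.8)
        agg = calls80["signal_prob"].iloc[0]
        expected = "AEI" if agg >= 0.8 else ("uncertain" if agg > 0.05 else "no_AEI")
        assert calls80["designation"].iloc[0] == expected

    def test_k1_empty_signal_set(self):
        m = _model([(1.0, 10, 10)])
        calls = classify_snps(m, [0, 5, 12], set())
        assert (calls["designation"] == "no_AEI").all()

    def test_max_prob_vs_threshold_counts(self):
        m = _model([(0.8, 6, 6), (0.2, 40, 90)])
        rng = np.random.default_rng(23)
        y = np.abs(rng.poisson(6, 300) - rng.poisson(6, 300))
        max_calls = classify_snps(m, y, {1}, rule="max_prob")
        thr_calls = classify_snps(m, y, {1}, rule="threshold", threshold=0.99)
        assert (thr_calls["designation"] == "AEI").sum() <= (
            max_calls["designation"] == "AEI"
        ).sum() + 1
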