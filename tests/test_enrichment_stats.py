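"""Negative Binomial / Beta fitting, p-values, fold change, merging."""

import math

import numpy as np
import pytest
from scipy import stats

from multioverlap import (
    Combination,
    ShuffleSamples,
    cramers_v_fit,
    empirical_pvalue,
    fit_beta_pvalue,
    fit_negbin_moments,
    fold_change,
    merge_runs,
    negbin_pvalue,
    summarize_combination,
)


class TestNegBinFit:
    def test_closed_form_moments(self):
        # mean 10, sample variance 20 -> p = 0.5, r = 10
        a = math.sqrt(10)  # two points 10 -/+ a have ddof=1 variance 2a^2 = 20
        params = fit_negbin_moments([10 - a, 10 + a])
        assert params.p == pytest.approx(0.5, rel=1e-9)
        assert params.r == pytest.approx(10.0, rel=1e-9)

    def test_parameter_recovery_from_simulation(self):
        rng = np.random.default_rng(1234)
        draws = rng.negative_binomial(5, 0.3, size=10_000)
        params = fit_negbin_moments(draws)
        assert not params.degenerate
        assert abs(params.r - 5) / 5 < 0.10

    def test_constant_samples_degenerate(self):
        params = fit_negbin_moments([7, 7, 7, 7])
        assert params.degenerate
        assert params.reason == "underdispersed"

    def test_all_zero_samples_flagged(self):
        params = fit_negbin_moments([0, 0, 0])
        assert params.degenerate
        assert params.reason == "all_zero"

    def test_underdispersed_flagged(self):
        rng = np.random.default_rng(0)
        draws = rng.binomial(20, 0.5, size=1000)  # variance < mean
        params = fit_negbin_moments(draws)
        assert params.degenerate


class TestNegBinPvalue:
    def test_zero_observation_gives_one(self):
        params = fit_negbin_moments(np.random.default_rng(0).negative_binomial(5, 0.3, 500))
        p, fallback = negbin_pvalue(params, 0)
        assert p == 1.0 and not fallback

    def test_geometric_special_case(self):
        # NB(r=1, p=0.5) is geometric: P(X >= 3) = 0.5^3 = 0.125
        from multioverlap.enrichment_stats import NegBinParams
        params = NegBinParams(r=1.0, p=0.5, mean=1.0, variance=2.0)
        p, _ = negbin_pvalue(params, 3)
        assert p == pytest.approx(0.125, rel=1e-9)

    def test_monotone_in_observation(self):
        from multioverlap.enrichment_stats import NegBinParams
        params = NegBinParams(r=3.0, p=0.4, mean=4.5, variance=11.25)
        ps = [negbin_pvalue(params, s)[0] for s in range(0, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_degenerate_falls_back_flagged(self):
        params = fit_negbin_moments([5, 5, 5, 5])
        p, fallback = negbin_pvalue(params, 10)
        assert fallback
        assert p == pytest.approx(float(stats.poisson.sf(9, 5.0)))


class TestEmpiricalPvalue:
    def test_add_one_floor(self):
        samples = np.arange(199)
        assert empirical_pvalue(samples, 10_000) == pytest.approx(1 / 200)

    def test_minimum_gives_one(self):
        samples = np.array([3, 5, 9])
        assert empirical_pvalue(samples, 3) == 1.0

    def test_direct_count(self):
        samples = np.arange(100)  # {0..99}
        assert empirical_pvalue(samples, 50) == pytest.approx(51 / 101)


class TestFoldChange:
    def test_identity(self):
        assert fold_change(20, 20) == 0.0

    def test_large_enrichment(self):
        assert fold_change(2000, 2) == pytest.approx(math.log2(1000), rel=1e-12)

    def test_zero_observed_finite(self):
        fc = fold_change(0, 100)
        assert math.isfinite(fc) and fc < -6  # log2(1/101)

    def test_zero_expected_finite(self):
        fc = fold_change(100, 0)
        assert math.isfinite(fc) and fc > 6


class TestCramersV:
    def test_self_fit_is_good(self):
        rng = np.random.default_rng(5)
        draws = rng.negative_binomial(5, 0.3, size=1000)
        params = fit_negbin_moments(draws)
        diag = cramers_v_fit(draws, params)
        assert diag.verdict == "good"
        assert diag.cramers_v < 0.1

    def test_misfit_scores_higher_than_self_fit(self):
        rng = np.random.default_rng(6)
        draws = rng.negative_binomial(5, 0.3, size=1000)
        params = fit_negbin_moments(draws)
        v_self = cramers_v_fit(draws, params).cramers_v
        uniform = rng.integers(0, int(4 * draws.mean()) + 1, size=1000)
        v_misfit = cramers_v_fit(uniform, params).cramers_v
        assert v_misfit > 2 * v_self

    def test_constant_samples_untestable(self):
        params = fit_negbin_moments([5, 5, 5, 5])
        assert cramers_v_fit([5] * 100, params).verdict == "untestable"


class TestBetaFit:
    def test_shape_recovery(self):
        rng = np.random.default_rng(8)
        scale = 1_000_000
        draws = (rng.beta(2, 50, size=20_000) * scale).astype(int)
        params, _ = fit_beta_pvalue(draws, s_obs=1, scale=scale)
        assert not params.degenerate
        assert abs(params.a - 2) / 2 < 0.15

    def test_zero_observation_gives_one(self):
        rng = np.random.default_rng(9)
        draws = (rng.beta(2, 50, size=2000) * 1000).astype(int)
        _, p = fit_beta_pvalue(draws, 0, 1000)
        assert p == 1.0

    def test_constant_samples_degenerate(self):
        params, p = fit_beta_pvalue([10, 10, 10], 5, 1000)
        assert params.degenerate and p is None

    def test_few_shuffles_flagged_low_confidence(self):
        rng = np.random.default_rng(10)
        draws = (rng.beta(2, 50, size=200) * 1000).astype(int)
        params, _ = fit_beta_pvalue(draws, 5, 1000)
        assert params.low_confidence


class TestSummarize:
    def test_locked_setup_gives_null_result(self):
        comb = Combination((True, True))
        S = np.full(50, 123)
        N = np.full(50, 4)
        st = summarize_combination(comb, S, N, S_obs=123, N_obs=4, scale=10_000)
        assert st.log2_fold_change == 0.0
        assert st.p_empirical_S == 1.0
        assert st.nb_params_S.degenerate  # constant samples

    def test_contract_on_toy_simulation(self):
        rng = np.random.default_rng(11)
        comb = Combination((True, True))
        S = rng.negative_binomial(5, 0.1, size=200)
        N = rng.negative_binomial(3, 0.3, size=200)
        st = summarize_combination(comb, S, N, S_obs=int(S.mean() * 2),
                                   N_obs=5, scale=1_000_000)
        for p in (st.p_nb_S, st.p_nb_N, st.p_empirical_S, st.p_beta_S):
            assert 0.0 <= p <= 1.0
        assert st.S_exp_mean == pytest.approx(S.mean())

    def test_nb_and_empirical_pvalues_agree_under_h0(self):
        # draws from a genuine NB: the fitted-NB p-value at any observation
        # should track the empirical one closely when the fit is good
        rng = np.random.default_rng(12)
        comb = Combination((True, True))
        S = rng.negative_binomial(8, 0.2, size=500)
        N = rng.negative_binomial(4, 0.4, size=500)
        s_obs = int(np.percentile(S, 80))
        st = summarize_combination(comb, S, N, s_obs, 3, scale=1_000_000)
        assert st.fit.verdict == "good"
        assert abs(st.p_nb_S - st.p_empirical_S) < 0.05


class TestMergeRuns:
    def _run(self, seed, combos, n=10):
        rng = np.random.default_rng(seed)
        run = ShuffleSamples(["A", "B", "C"], "transitive", n)
        for c in combos:
            run.S[c] = rng.integers(0, 50, size=n)
            run.N[c] = rng.integers(0, 5, size=n)
        return run

    def test_self_merge_doubles_samples(self):
        AB = Combination((True, True, False))
        run = self._run(0, [AB])
        merged = merge_runs([run, run])
        assert merged.n_shuffles == 20
        assert merged.S[AB].mean() == pytest.approx(run.S[AB].mean())

    def test_disjoint_combinations_zero_padded(self):
        AB = Combination((True, True, False))
        BC = Combination((False, True, True))
        merged = merge_runs([self._run(1, [AB]), self._run(2, [BC])])
        assert set(merged.combinations()) == {AB, BC}
        assert (merged.S[AB][10:] == 0).all()
        assert (merged.S[BC][:10] == 0).all()

    def test_pooled_moments_identity(self):
        AB = Combination((True, True, False))
        r1, r2 = self._run(3, [AB]), self._run(4, [AB])
        merged = merge_runs([r1, r2])
        pooled = np.concatenate([r1.S[AB], r2.S[AB]])
        assert merged.S[AB].mean() == pytest.approx(pooled.mean())
        assert merged.S[AB].var(ddof=1) == pytest.approx(pooled.var(ddof=1))

    def test_mismatched_set_lists_rejected(self):
        AB = Combination((True, True, False))
        r1 = self._run(5, [AB])
        r2 = self._run(6, [AB])
        r2.set_names = ["A", "B", "D"]
        with pytest.raises(ValueError):
            merge_runs([r1, r2])
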