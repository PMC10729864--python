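"""Pair counting, beta-binomial fit, p-values and FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coregnet import (
    BetaBinomParams,
    betabinom_pmf,
    compute_fdr,
    count_coregulation,
    fit_betabinom,
    pair_pvalue,
)

from _oracles import brute_pair_counts
from conftest import random_binary_matrix


def _frames(binary, signed):
    genes = [f"g{i}" for i in range(binary.shape[0])]
    cols = [f"c{k}" for k in range(binary.shape[1])]
    return (
        pd.DataFrame(binary, index=genes, columns=cols),
        pd.DataFrame(signed, index=genes, columns=cols),
    )


class TestCountCoregulation:
    def test_hand_example(self):
        signed = np.array([[1, 1, 0, 1], [-1, 0, 0, 1]], dtype=np.int8)
        binary = (signed != 0).astype(np.int8)
        out = count_coregulation(*_frames(binary, signed), min_obs=0)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["n"] == 2 and row["n_discordant"] == 1 and row["K"] == 4

    def test_all_zero_gene_excluded_at_min_obs_1(self):
        signed = np.array([[1, 1], [0, 0]], dtype=np.int8)
        binary = (signed != 0).astype(np.int8)
        out = count_coregulation(*_frames(binary, signed), min_obs=1)
        assert len(out) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        binary = random_binary_matrix(8, 12, 0.4, seed)
        signed = binary * rng.choice([-1, 1], size=binary.shape)
        out = count_coregulation(*_frames(binary, signed), min_obs=0)
        oracle = brute_pair_counts(binary, signed)
        genes = [f"g{i}" for i in range(8)]
        for row in out.itertuples():
            i, j = genes.index(row.gene_i), genes.index(row.gene_j)
            assert (row.n, row.n_discordant) == oracle[(i, j)]

    def test_alignment_error(self):
        b, s = _frames(np.ones((2, 2), np.int8), np.ones((2, 2), np.int8))
        with pytest.raises(ValueError, match="aligned"):
            count_coregulation(b, s.iloc[:, :1])


class TestBetabinomPmf:
    def test_uniform_prior_makes_uniform_pmf(self):
        params = BetaBinomParams(1.0, 1.0, 5)
        for n in range(6):
            assert betabinom_pmf(n, params) == pytest.approx(1 / 6)

    def test_single_trial_equals_prior_mean(self):
        assert betabinom_pmf(1, BetaBinomParams(2.0, 3.0, 1)) == pytest.approx(2 / 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_and_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(1, 60))
        a, b = rng.uniform(0.1, 20, 2)
        params = BetaBinomParams(a, b, K)
        ns = np.arange(K + 1)
        mine = betabinom_pmf(ns, params)
        ref = sps.betabinom(K, a, b).pmf(ns)
        np.testing.assert_allclose(mine, ref, rtol=1e-10)
        assert abs(mine.sum() - 1.0) < 1e-9

    def test_monte_carlo_two_stage_oracle(self):
        # draws p ~ Beta(2.5, 7.1), then Binomial(10, p); compare mass at 4
        params = BetaBinomParams(2.5, 7.1, 10)
        rng = np.random.default_rng(12)
        draws = rng.binomial(10, rng.beta(2.5, 7.1, 1_000_000))
        est = (draws == 4).mean()
        se = np.sqrt(est * (1 - est) / draws.size)
        assert abs(betabinom_pmf(4, params) - est) <= 3 * se

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            BetaBinomParams(0.0, 1.0, 5)
        with pytest.raises(ValueError):
            betabinom_pmf(6, BetaBinomParams(1.0, 1.0, 5))


class TestFitBetabinom:
    def test_parameter_recovery_from_simulated_draws(self):
        rng = np.random.default_rng(0)
        draws = rng.binomial(20, rng.beta(2.0, 5.0, 100_000))
        fit = fit_betabinom(draws, K=20)
        assert 1.8 <= fit.alpha <= 2.2
        assert 4.5 <= fit.beta <= 5.5

    def test_binomial_vector_falls_back_to_binomial_variance(self):
        rng = np.random.default_rng(1)
        draws = rng.binomial(20, 0.3, 50_000)
        fit = fit_betabinom(draws, K=20)
        fitted_var = sps.betabinom(20, fit.alpha, fit.beta).var()
        binom_var = 20 * 0.3 * 0.7
        assert abs(fitted_var - binom_var) / binom_var < 0.05

    def test_all_zero_vector_is_degenerate(self):
        fit = fit_betabinom(np.zeros(100), K=10)
        assert fit.degenerate and fit.point_mass == 0.0
        assert pair_pvalue(0, fit) == 1.0
        assert 0 < pair_pvalue(3, fit) < 1e-300

    def test_mle_refinement_close_to_moments(self):
        rng = np.random.default_rng(2)
        draws = rng.binomial(15, rng.beta(3.0, 4.0, 5000))
        mom = fit_betabinom(draws, K=15)
        mle = fit_betabinom(draws, K=15, method="mle")
        assert mle.alpha == pytest.approx(mom.alpha, rel=0.3)
        assert mle.beta == pytest.approx(mom.beta, rel=0.3)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_betabinom([1.0], K=5)
        with pytest.raises(ValueError):
            fit_betabinom([1, 7], K=5)
        with pytest.raises(ValueError):
            fit_betabinom([1, 2], K=5, method="nope")


class TestPairPvalue:
    def test_zero_observation_gives_one(self):
        assert pair_pvalue(0, BetaBinomParams(2.0, 3.0, 10)) == pytest.approx(1.0)

    def test_uniform_tail_single_point(self):
        assert pair_pvalue(5, BetaBinomParams(1.0, 1.0, 5)) == pytest.approx(1 / 6)

    def test_matches_direct_summation(self):
        params = BetaBinomParams(2.0, 2.0, 10)
        expected = sum(sps.betabinom(10, 2.0, 2.0).pmf(j) for j in range(7, 11))
        assert pair_pvalue(7, params) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_non_increasing_in_observation(self, seed):
        rng = np.random.default_rng(seed)
        params = BetaBinomParams(*rng.uniform(0.2, 10, 2), int(rng.integers(2, 40)))
        ps = [pair_pvalue(n, params) for n in range(params.K + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
        assert all(0 <= p <= 1 for p in ps)


class TestComputeFdr:
    def test_hand_bh(self):
        df = pd.DataFrame({"p_value": [0.01, 0.02, 0.03]})
        out = compute_fdr(df)
        np.testing.assert_allclose(out["fdr"], [0.03, 0.03, 0.03])

    def test_single_pair(self):
        out = compute_fdr(pd.DataFrame({"p_value": [0.2]}))
        assert out["fdr"].iloc[0] == pytest.approx(0.2)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        out = compute_fdr(pd.DataFrame({"p_value": p}))
        fdr_by_p = out.sort_values("p_value")["fdr"].to_numpy()
        assert (np.diff(fdr_by_p) >= -1e-12).all()
        assert ((out["fdr"] >= out["p_value"] - 1e-12)).all()

    def test_empty(self):
        out = compute_fdr(pd.DataFrame({"p_value": []}))
        assert len(out) == 0 and "fdr" in out.columns
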