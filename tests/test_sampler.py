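"""Tests of the collapsed Gibbs sampler: bookkeeping exactness,
reproducibility, degenerate priors, concentration updates, and agreement
with the brute-force posterior on toy problems."""

import numpy as np
import pytest
from psdf import (
    ChainConfig,
    DiscreteDataset,
    FeaturePrior,
    PSDFSampler,
    feature_probabilities,
    fusion_probabilities,
    posterior_similarity,
    run_chain,
    run_multichain,
    sample_concentration,
)
from psdf.sampler import ClusterStats

from _oracles import ExactPosterior, concentration_log_conditional


def _toy_config(**kw):
    base = dict(
        n_chains=1, n_iterations=200, burn_in=50, thin=2,
        sample_alpha=False, alpha_init=1.0, seed=5,
    )
    base.update(kw)
    return ChainConfig(**base)


class TestChainConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_iterations": 0},
            {"burn_in": 10, "n_iterations": 10},
            {"thin": 0},
            {"rho": 1.5},
            {"alpha_prior_shape": 0.0},
            {"n_iterations": 10, "burn_in": 5, "thin": 100},  # retains nothing
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            ChainConfig(**kw)

    def test_retained_count(self):
        cfg = ChainConfig(n_iterations=100, burn_in=40, thin=10)
        assert cfg.n_retained == 6


class TestClusterStats:
    def test_remove_then_readd_restores_exactly(self, rng):
        st = ClusterStats((3, 2), capacity=8)
        lv = {0: np.array([0, 1, 2]), 1: np.array([2, 2])}
        st.add_draw(0, lv)
        st.add_draw(0, {0: np.array([1, 1, 1]), 1: np.array([0, 1])})
        before = [c.copy() for c in st.counts]
        st.add_draw(1, lv)
        st.remove_draw(1, lv)
        assert all(np.array_equal(a, b) for a, b in zip(before, st.counts))
        assert st.K == 1 and st.total_draws == 2

    def test_compaction_moves_last_cluster(self):
        st = ClusterStats((2, 2), capacity=8)
        a = {0: np.array([0, 1])}
        b = {1: np.array([2, 0])}
        st.add_draw(0, a)
        st.add_draw(1, b)
        st.add_draw(2, a)
        renamed = st.remove_draw(1, b)
        assert renamed == 2  # last cluster moved into the freed slot
        assert st.K == 2
        assert st.n_obs[0][1] == 1 and st.n_obs[1][1] == 0

    def test_rejects_non_contiguous_label(self):
        st = ClusterStats((2, 2), capacity=8)
        with pytest.raises(ValueError):
            st.add_draw(1, {0: np.array([0, 1])})


class TestSamplerInvariants:
    def test_sufficient_stats_match_scratch_recompute(self, toy_pair):
        d1, d2 = toy_pair
        sampler = PSDFSampler(d1, d2, _toy_config(seed=9))
        for _ in range(25):
            sampler.sweep()
        fresh = sampler.recompute_stats()
        assert fresh.K == sampler.stats.K
        assert fresh.total_draws == sampler.stats.total_draws
        np.testing.assert_array_equal(fresh.draws, sampler.stats.draws)
        for d in (0, 1):
            np.testing.assert_array_equal(fresh.n_obs[d], sampler.stats.n_obs[d])
            np.testing.assert_array_equal(fresh.counts[d], sampler.stats.counts[d])

    def test_same_seed_reproduces_samples(self, toy_pair):
        d1, d2 = toy_pair
        cfg = _toy_config(seed=77)
        a = run_chain(d1, d2, cfg)
        b = run_chain(d1, d2, cfg)
        assert len(a) == len(b) == cfg.n_retained
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.fusion, sb.fusion)
            np.testing.assert_array_equal(sa.fused_labels, sb.fused_labels)
            np.testing.assert_array_equal(
                sa.unfused_labels[0], sb.unfused_labels[0]
            )
            assert sa.alpha == sb.alpha

    def test_mismatched_item_sets_rejected(self, toy_pair):
        d1, _ = toy_pair
        other = DiscreteDataset(
            d1.values, ("w", "x", "y", "z"), ("g1", "g2")
        )
        with pytest.raises(ValueError):
            PSDFSampler(d1, other, _toy_config())

    def test_rho_one_keeps_everything_fused(self, toy_pair):
        d1, d2 = toy_pair
        samples = run_chain(d1, d2, _toy_config(rho=1.0))
        assert all(s.fusion.all() for s in samples)

    def test_rho_zero_keeps_everything_unfused(self, toy_pair):
        d1, d2 = toy_pair
        samples = run_chain(d1, d2, _toy_config(rho=0.0))
        assert not any(s.fusion.any() for s in samples)

    def test_q_one_keeps_all_features_on(self, toy_pair):
        d1, d2 = toy_pair
        samples = run_chain(d1, d2, _toy_config(q_feature=1.0))
        assert all(s.feature_on[0].all() and s.feature_on[1].all() for s in samples)

    def test_off_features_do_not_influence_assignments(self, toy_pair):
        """With every feature OFF the chain is driven by the CRP alone,
        so altering the data must not change the sampled trajectories."""
        d1, d2 = toy_pair
        cfg = _toy_config(q_feature=0.0, seed=31)
        a = run_chain(d1, d2, cfg)
        d1_alt = DiscreteDataset(
            np.roll(d1.values, 1, axis=0), d1.item_labels, d1.feature_labels
        )
        b = run_chain(d1_alt, d2, cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.fusion, sb.fusion)
            np.testing.assert_array_equal(sa.fused_labels, sb.fused_labels)

    def test_label_relabelling_leaves_summaries_unchanged(self, toy_pair):
        d1, d2 = toy_pair
        samples = run_chain(d1, d2, _toy_config(seed=13))
        relabelled = []
        for s in samples:
            # apply a permutation to the shared cluster ids
            k_max = max(
                int(s.fused_labels.max()),
                int(s.unfused_labels[0].max()),
                int(s.unfused_labels[1].max()),
                0,
            )
            perm = np.roll(np.arange(k_max + 1), 1)

            def remap(lab):
                out = lab.copy()
                mask = out >= 0
                out[mask] = perm[out[mask]]
                return out

            relabelled.append(
                type(s)(
                    iteration=s.iteration,
                    fusion=s.fusion,
                    fused_labels=remap(s.fused_labels),
                    unfused_labels=(
                        remap(s.unfused_labels[0]),
                        remap(s.unfused_labels[1]),
                    ),
                    feature_on=s.feature_on,
                    alpha=s.alpha,
                )
            )
        np.testing.assert_allclose(
            posterior_similarity(samples), posterior_similarity(relabelled)
        )
        np.testing.assert_allclose(
            fusion_probabilities(samples), fusion_probabilities(relabelled)
        )


class TestConcentration:
    def test_no_items_samples_from_prior(self, rng):
        draws = [
            sample_concentration(1.0, 0, 1, 2.0, 1.0, rng) for _ in range(4000)
        ]
        assert np.mean(draws) == pytest.approx(2.0, rel=0.1)  # Gamma(2,1) mean

    def test_posterior_mean_increases_with_cluster_count(self, rng):
        means = []
        for k in (2, 10, 25):
            draws = [
                sample_concentration(1.0, 50, k, 2.0, 1.0, rng)
                for _ in range(3000)
            ]
            means.append(np.mean(draws))
        assert means[0] < means[1] < means[2]

    def test_matches_grid_integrated_conditional(self, rng):
        """Kolmogorov distance < 0.02 between the auxiliary-variable
        sampler's equilibrium draws and the exact conditional for
        n = 50 draws in k = 5 clusters."""
        n, k = 50, 5
        alpha = 1.0
        draws = []
        for _ in range(20_000):
            alpha = sample_concentration(alpha, n, k, 2.0, 1.0, rng)
            draws.append(alpha)
        draws = np.sort(draws[2000:])
        grid = np.linspace(1e-4, 25, 8000)
        logpdf = concentration_log_conditional(grid, n, k, 2.0, 1.0)
        pdf = np.exp(logpdf - logpdf.max())
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        exact_cdf_at = np.interp(draws, grid, cdf)
        empirical = np.arange(1, draws.size + 1) / draws.size
        assert np.abs(empirical - exact_cdf_at).max() < 0.02

    def test_rejects_impossible_counts(self, rng):
        with pytest.raises(ValueError):
            sample_concentration(1.0, 3, 5, 2.0, 1.0, rng)


class TestExactPosteriorAgreement:
    def test_toy_marginals_match_enumeration(self):
        """Long-run Gibbs co-clustering, fusion, and feature
        probabilities agree with brute-force enumeration over every
        (fusion, partition, feature) configuration of a 3-item toy."""
        x1 = np.array([[1, 1], [1, 1], [3, 3]])
        x2 = np.array([[1, 1], [3, 3], [3, 3]])
        d1 = DiscreteDataset(x1, ("a", "b", "c"), ("f1", "f2"))
        d2 = DiscreteDataset(x2, ("a", "b", "c"), ("g1", "g2"))
        pr1, pr2 = FeaturePrior.from_dataset(d1), FeaturePrior.from_dataset(d2)
        exact = ExactPosterior(
            x1 - 1, x2 - 1, pr1.beta, pr2.beta,
            pr1.indifference_p, pr2.indifference_p,
            rho=0.5, q=0.5, alpha=1.0,
        )
        cfg = ChainConfig(
            n_chains=1, n_iterations=30_000, burn_in=1_000, thin=2,
            sample_alpha=False, alpha_init=1.0, seed=2024,
        )
        samples = run_chain(d1, d2, cfg)
        fus = fusion_probabilities(samples)
        psm = posterior_similarity(samples)
        fp, _ = feature_probabilities(samples)
        assert np.abs(fus - exact.fusion_prob).max() < 0.02
        assert np.abs(psm - exact.psm).max() < 0.02
        assert np.abs(fp[0] - exact.feature_prob[0]).max() < 0.02
        assert np.abs(fp[1] - exact.feature_prob[1]).max() < 0.02


class TestMultiChain:
    def test_dispersion_zero_for_identical_chains(self, toy_pair):
        from psdf.sampler import multichain_result

        d1, d2 = toy_pair
        chain = run_chain(d1, d2, _toy_config(seed=3))
        result = multichain_result([chain, chain])
        assert np.all(result.fusion_prob_sd == 0)
        assert result.cluster_count_sd == 0

    def test_multichain_runs_and_reports(self, toy_pair):
        d1, d2 = toy_pair
        cfg = _toy_config(n_chains=3, seed=8)
        result = run_multichain(d1, d2, cfg)
        assert len(result.chains) == 3
        assert result.fusion_prob_mean.shape == (4,)
        assert np.all(result.fusion_prob_sd >= 0)

    def test_dispersion_shrinks_with_chain_length(self, toy_pair):
        """Cross-chain SD of the fusion probability decreases as chains
        grow (well-mixed toy)."""
        d1, d2 = toy_pair
        sds = []
        for n_it in (200, 1000, 5000):
            cfg = ChainConfig(
                n_chains=4, n_iterations=n_it, burn_in=n_it // 4, thin=2,
                sample_alpha=False, seed=99,
            )
            result = run_multichain(d1, d2, cfg)
            sds.append(result.fusion_prob_sd.mean())
        assert sds[2] < sds[0]

    def test_default_protocol_matches_analysis_settings(self):
        cfg = ChainConfig()
        assert cfg.n_chains == 50
        assert cfg.thin == 10
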