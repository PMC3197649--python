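"""Tests for posterior summaries: similarity matrix, probabilities,
consensus partition, and cluster-count posterior."""

import numpy as np
import pytest

from psdf import (
    cluster_count_posterior,
    consensus_partition,
    feature_probabilities,
    fusion_probabilities,
    posterior_similarity,
)
from psdf.sampler import ModelState
from psdf.summaries import binder_loss


def make_state(fusion, fused, unf1, unf2, on1=None, on2=None, it=1, alpha=1.0):
    fusion = np.asarray(fusion, dtype=bool)
    n = fusion.size
    if on1 is None:
        on1 = np.ones(2, dtype=bool)
    if on2 is None:
        on2 = np.ones(2, dtype=bool)
    return ModelState(
        iteration=it,
        fusion=fusion,
        fused_labels=np.where(fusion, np.asarray(fused), -1),
        unfused_labels=(
            np.where(~fusion, np.asarray(unf1), -1),
            np.where(~fusion, np.asarray(unf2), -1),
        ),
        feature_on=(np.asarray(on1, dtype=bool), np.asarray(on2, dtype=bool)),
        alpha=alpha,
    )


class TestPosteriorSimilarity:
    def test_single_sample_equals_indicator_matrix(self):
        s = make_state([1, 1, 0], fused=[0, 0, -1], unf1=[-1, -1, 1], unf2=[-1, -1, 1])
        psm = posterior_similarity([s])
        # items 0,1 share a fused cluster in both data types
        assert psm[0, 1] == 1.0
        # item 2 sits in cluster 1 alone in both views
        assert psm[0, 2] == 0.0
        np.testing.assert_array_equal(np.diag(psm), 1.0)

    def test_partial_coclustering_averages_over_types_and_samples(self):
        # sample 1: pair co-clusters in both data types
        s1 = make_state([1, 1], fused=[0, 0], unf1=[-1, -1], unf2=[-1, -1])
        # sample 2: both unfused, same cluster in type 1 only
        s2 = make_state([0, 0], fused=[-1, -1], unf1=[0, 0], unf2=[0, 1])
        psm = posterior_similarity([s1, s2])
        assert psm[0, 1] == pytest.approx((1.0 + 0.5) / 2)

    def test_fused_and_unfused_items_cocluster_when_sharing_atom(self):
        # item 0 fused in cluster 0; item 1 unfused with type-1 draw in
        # cluster 0 and type-2 draw in cluster 1
        s = make_state([1, 0], fused=[0, -1], unf1=[-1, 0], unf2=[-1, 1])
        psm = posterior_similarity([s])
        assert psm[0, 1] == pytest.approx(0.5)

    def test_symmetric_unit_diagonal(self, toy_pair):
        from psdf import run_chain, ChainConfig

        d1, d2 = toy_pair
        samples = run_chain(
            d1, d2,
            ChainConfig(n_chains=1, n_iterations=120, burn_in=20, thin=2, seed=1),
        )
        psm = posterior_similarity(samples)
        np.testing.assert_allclose(psm, psm.T)
        np.testing.assert_allclose(np.diag(psm), 1.0)
        assert psm.min() >= 0 and psm.max() <= 1


class TestProbabilities:
    def test_fusion_probability_is_indicator_mean(self):
        samples = [
            make_state([f, 1], fused=[0, 0], unf1=[0, 0], unf2=[0, 0])
            for f in (1, 1, 1, 0)
        ]
        np.testing.assert_allclose(
            fusion_probabilities(samples), [0.75, 1.0]
        )

    def test_merged_chains_weight_by_retained_counts(self):
        chain_a = [make_state([1], [0], [0], [0])] * 3
        chain_b = [make_state([0], [0], [0], [0])]
        np.testing.assert_allclose(
            fusion_probabilities([chain_a, chain_b]), [0.75]
        )

    def test_feature_probability_and_rank(self):
        samples = [
            make_state([1], [0], [0], [0], on1=[1, 0], on2=[1, 1]),
            make_state([1], [0], [0], [0], on1=[1, 1], on2=[0, 1]),
        ]
        probs, ranks = feature_probabilities(samples)
        np.testing.assert_allclose(probs[0], [1.0, 0.5])
        np.testing.assert_allclose(probs[1], [0.5, 1.0])
        assert list(ranks[0]) == [0, 1]
        assert list(ranks[1]) == [1, 0]

    def test_requires_samples(self):
        with pytest.raises(ValueError):
            fusion_probabilities([])


class TestConsensusPartition:
    def test_block_diagonal_psm_recovers_blocks(self):
        psm = np.zeros((6, 6))
        psm[:3, :3] = 1.0
        psm[3:, 3:] = 1.0
        labels, k = consensus_partition(psm)
        assert k == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_permutation_consistency(self):
        rng = np.random.default_rng(3)
        psm = np.eye(7)
        blocks = [0, 0, 0, 1, 1, 2, 2]
        for i in range(7):
            for j in range(7):
                if blocks[i] == blocks[j]:
                    psm[i, j] = 0.9 if i != j else 1.0
                else:
                    psm[i, j] = 0.05
        labels, _ = consensus_partition(psm)
        perm = rng.permutation(7)
        labels_p, _ = consensus_partition(psm[np.ix_(perm, perm)])
        # same partition up to renaming
        for i in range(7):
            for j in range(7):
                assert (labels[perm[i]] == labels[perm[j]]) == (
                    labels_p[i] == labels_p[j]
                )

    def test_cut_minimises_binder_loss_over_dendrogram_scan(self):
        """For <= 8 items the returned cut's Binder loss equals the
        minimum over every dendrogram cut, with the loss recomputed
        independently by explicit pair-counting."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(11)
        raw = rng.random((8, 8))
        psm = (raw + raw.T) / 2
        np.fill_diagonal(psm, 1.0)
        labels, _ = consensus_partition(psm)

        def pair_loss(lab):
            total = 0.0
            for i in range(8):
                for j in range(i + 1, 8):
                    if lab[i] == lab[j]:
                        total += 1.0 - psm[i, j]
                    else:
                        total += psm[i, j]
            return total

        d = 1.0 - psm
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="average")
        best = min(
            pair_loss(fcluster(z, t=k, criterion="maxclust"))
            for k in range(1, 9)
        )
        assert pair_loss(labels) == pytest.approx(best)
        assert binder_loss(labels, psm) == pytest.approx(pair_loss(labels))

    def test_labels_contiguous_from_one(self):
        psm = np.eye(5)
        labels, k = consensus_partition(psm)
        assert sorted(set(labels)) == list(range(1, k + 1))


class TestClusterCountPosterior:
    def test_identical_samples_concentrate_mass(self):
        s = make_state(
            [1, 1, 1, 1], fused=[0, 1, 2, 3], unf1=[0] * 4, unf2=[0] * 4
        )
        kp = cluster_count_posterior([s] * 5)
        assert kp.overall == {4.0: pytest.approx(1.0)}
        assert kp.mode_overall == 4.0
        assert kp.mode_fused == 4

    def test_histogram_sums_to_one(self, toy_pair):
        from psdf import run_chain, ChainConfig

        d1, d2 = toy_pair
        samples = run_chain(
            d1, d2,
            ChainConfig(n_chains=1, n_iterations=150, burn_in=30, thin=3, seed=4),
        )
        kp = cluster_count_posterior(samples)
        assert sum(kp.overall.values()) == pytest.approx(1.0)
        assert sum(kp.fused.values()) == pytest.approx(1.0)

    def test_overall_count_averages_type_views(self):
        # fused item in cluster 0; unfused item in clusters 0 (type 1)
        # and 1 (type 2): type views have 1 and 2 clusters
        s = make_state([1, 0], fused=[0, -1], unf1=[-1, 0], unf2=[-1, 1])
        kp = cluster_count_posterior([s])
        assert kp.mean_overall == pytest.approx(1.5)
        assert kp.mode_fused == 1

    def test_toy_count_posterior_matches_enumeration(self):
        """P(number of clusters) from the chain agrees with brute-force
        enumeration on a 3-item toy."""
        from psdf import ChainConfig, DiscreteDataset, FeaturePrior, run_chain
        from _oracles import ExactPosterior

        x1 = np.array([[1, 1], [1, 1], [3, 3]])
        x2 = np.array([[1, 1], [1, 1], [3, 3]])
        d1 = DiscreteDataset(x1, ("a", "b", "c"), ("f1", "f2"))
        d2 = DiscreteDataset(x2, ("a", "b", "c"), ("g1", "g2"))
        pr1, pr2 = FeaturePrior.from_dataset(d1), FeaturePrior.from_dataset(d2)
        exact = ExactPosterior(
            x1 - 1, x2 - 1, pr1.beta, pr2.beta,
            pr1.indifference_p, pr2.indifference_p,
            rho=0.5, q=0.5, alpha=1.0,
        )
        cfg = ChainConfig(
            n_chains=1, n_iterations=20_000, burn_in=1_000, thin=2,
            sample_alpha=False, alpha_init=1.0, seed=6,
        )
        kp = cluster_count_posterior(run_chain(d1, d2, cfg))
        for k, p in exact.k_overall.items():
            assert kp.overall.get(k, 0.0) == pytest.approx(p, abs=0.02)
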