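"""Posterior summaries of retained MCMC samples.

Produces the model's reported outputs: the posterior similarity matrix
(pairwise co-clustering probabilities averaged over the two data types
and over samples), per-item fusion probabilities, per-feature selection
probabilities, a consensus partition (Binder-loss-minimising cut of an
average-linkage dendrogram on the similarity matrix), and the posterior
over the number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .sampler import ModelState, MultiChainResult

__all__ = [
    "PosteriorSummary",
    "ClusterCountPosterior",
    "posterior_similarity",
    "fusion_probabilities",
    "feature_probabilities",
    "consensus_partition",
    "cluster_count_posterior",
    "binder_loss",
    "summarize_chains",
]


def _as_samples(samples) -> list[ModelState]:
    if isinstance(samples, MultiChainResult):
        return samples.samples
    samples = list(samples)
    if samples and isinstance(samples[0], list):
        samples = [s for chain in samples for s in chain]
    if not samples:
        raise ValueError("need at least one retained sample")
    return samples


def posterior_similarity(samples) -> np.ndarray:
    """Item x item co-clustering probabilities.

    Per sample and per data type, two items co-cluster when they share a
    cluster in that data type's view (a fused item's single cluster
    counts for both views; clusters are drawn from one shared pool, so
    fused and unfused items can co-cluster). The indicator is averaged
    over the two data types, then over samples.
    """
    samples = _as_samples(samples)
    n = samples[0].fusion.size
    psm = np.zeros((n, n))
    for s in samples:
        for d in (0, 1):
            lab = s.labels_for_type(d)
            psm += 0.5 * (lab[:, None] == lab[None, :])
    psm /= len(samples)
    np.fill_diagonal(psm, 1.0)
    return psm


def fusion_probabilities(samples) -> np.ndarray:
    """Per-item posterior probability of being fused."""
    samples = _as_samples(samples)
    return np.mean([s.fusion for s in samples], axis=0)


def feature_probabilities(samples):
    """Per data type, per-feature posterior selection probability.

    Returns ``(probs, ranks)`` where ``ranks[d]`` orders features of data
    type ``d`` from most to least frequently selected (the heatmap
    ordering).
    """
    samples = _as_samples(samples)
    probs = tuple(
        np.mean([s.feature_on[d] for s in samples], axis=0) for d in (0, 1)
    )
    ranks = tuple(np.argsort(-p, kind="stable") for p in probs)
    return probs, ranks


def binder_loss(labels: np.ndarray, psm: np.ndarray) -> float:
    """Binder loss of a partition against a similarity matrix: the sum
    over pairs of ``psm`` for separated pairs and ``1 − psm`` for merged
    pairs (equal misclassification costs)."""
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices_from(psm, k=1)
    return float(np.where(same[iu], 1.0 - psm[iu], psm[iu]).sum())


def consensus_partition(psm: np.ndarray) -> tuple[np.ndarray, int]:
    """Point-estimate partition from the similarity matrix.

    Average-linkage hierarchical clustering on ``1 − psm``; the cut (over
    all dendrogram cuts) minimising the Binder loss is returned, ties
    broken toward fewer clusters. Labels are contiguous from 1 in order
    of first appearance.
    """
    psm = np.asarray(psm, dtype=float)
    n = psm.shape[0]
    if n == 1:
        return np.array([1]), 1
    dist = 1.0 - psm
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    z = linkage(squareform(dist, checks=False), method="average")
    best_labels, best_loss, best_k = None, np.inf, None
    for k in range(1, n + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        k_actual = np.unique(labels).size
        loss = binder_loss(labels, psm)
        better = loss < best_loss - 1e-12 or (
            abs(loss - best_loss) <= 1e-12 and best_k is not None and k_actual < best_k
        )
        if best_labels is None or better:
            best_labels, best_loss, best_k = labels, loss, k_actual
    # relabel contiguously from 1 in order of first appearance
    out = np.zeros(n, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(best_labels):
        mapping.setdefault(int(lab), len(mapping) + 1)
        out[i] = mapping[int(lab)]
    return out, len(mapping)


@dataclass(frozen=True)
class ClusterCountPosterior:
    """Posterior over the number of clusters.

    ``overall`` histograms the per-sample average of the two
    per-data-type view counts; ``fused`` histograms the number of
    clusters holding at least one fused item.
    """

    overall: dict[float, float]
    fused: dict[int, float]

    @property
    def mode_overall(self) -> float:
        return max(self.overall, key=lambda k: (self.overall[k], -k))

    @property
    def mode_fused(self) -> int:
        return max(self.fused, key=lambda k: (self.fused[k], -k))

    @property
    def mean_overall(self) -> float:
        return sum(k * p for k, p in self.overall.items())

    @property
    def mean_fused(self) -> float:
        return sum(k * p for k, p in self.fused.items())


def _count_clusters(sample: ModelState) -> tuple[float, int]:
    n_fused = np.unique(sample.fused_labels[sample.fusion]).size
    per_type = [np.unique(sample.labels_for_type(d)).size for d in (0, 1)]
    return float(np.mean(per_type)), n_fused


def cluster_count_posterior(samples) -> ClusterCountPosterior:
    """Normalised histograms of the cluster count across samples."""
    samples = _as_samples(samples)
    overall: dict[float, float] = {}
    fused: dict[int, float] = {}
    w = 1.0 / len(samples)
    for s in samples:
        ko, kf = _count_clusters(s)
        overall[ko] = overall.get(ko, 0.0) + w
        fused[kf] = fused.get(kf, 0.0) + w
    return ClusterCountPosterior(overall=overall, fused=fused)


@dataclass(frozen=True)
class PosteriorSummary:
    """Bundle of all posterior summaries for one analysis."""

    psm: np.ndarray
    fusion_prob: np.ndarray
    feature_prob: tuple[np.ndarray, np.ndarray]
    feature_rank: tuple[np.ndarray, np.ndarray]
    consensus: np.ndarray
    n_consensus_clusters: int
    k_posterior: ClusterCountPosterior
    item_labels: tuple[str, ...] | None = None
    feature_labels: tuple[tuple[str, ...], tuple[str, ...]] | None = None
    fusion_prob_sd: np.ndarray | None = None
    feature_prob_sd: tuple[np.ndarray, np.ndarray] | None = None


def summarize_chains(
    samples,
    item_labels: tuple[str, ...] | None = None,
    feature_labels: tuple[tuple[str, ...], tuple[str, ...]] | None = None,
) -> PosteriorSummary:
    """Compute every summary from retained samples (one chain, a list of
    chains, or a :class:`MultiChainResult`)."""
    chain_sd_fus = chain_sd_feat = None
    if isinstance(samples, MultiChainResult):
        chain_sd_fus = samples.fusion_prob_sd
        chain_sd_feat = samples.feature_prob_sd
    flat = _as_samples(samples)
    psm = posterior_similarity(flat)
    consensus, k = consensus_partition(psm)
    probs, ranks = feature_probabilities(flat)
    return PosteriorSummary(
        psm=psm,
        fusion_prob=fusion_probabilities(flat),
        feature_prob=probs,
        feature_rank=ranks,
        consensus=consensus,
        n_consensus_clusters=k,
        k_posterior=cluster_count_posterior(flat),
        item_labels=item_labels,
        feature_labels=feature_labels,
        fusion_prob_sd=chain_sd_fus,
        feature_prob_sd=chain_sd_feat,
    )
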