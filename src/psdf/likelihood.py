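"""Per-feature likelihoods for the feature-selection competition.

Each feature in each data set is scored under two models:

* **on** — the multinomial-Dirichlet marginal likelihood evaluated per
  cluster (the class probabilities are marginalised under a weakly
  informative Dirichlet prior whose hyperparameters match the feature's
  empirical level proportions, rescaled to sum to 1.5 — the Jeffreys value
  0.5 summed over three levels);
* **off** — the "indifference" likelihood in which the class probabilities
  are fixed at the feature's whole-data-set proportions, so the cluster
  assignment of any item is irrelevant for that feature.

Feature selection is the posterior competition between the simpler
indifference model and the per-cluster marginal's ability to explain
non-random assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data import DiscreteDataset

__all__ = [
    "FeaturePrior",
    "compute_prior_beta",
    "cluster_feature_loglik",
    "indifference_p",
    "indifference_loglik",
]

DEFAULT_TARGET_SUM = 1.5


@dataclass(frozen=True)
class FeaturePrior:
    """Per-feature Dirichlet hyperparameters and indifference probabilities.

    Attributes
    ----------
    beta
        ``(n_features, V)`` positive Dirichlet hyperparameters; each row
        sums to ``target_sum``.
    indifference_p
        ``(n_features, V)`` fixed class probabilities for the feature-off
        model; each row sums to 1 with strictly positive entries.
    target_sum
        Common row sum of ``beta`` (default 1.5).
    """

    beta: np.ndarray
    indifference_p: np.ndarray
    target_sum: float = DEFAULT_TARGET_SUM

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        p = np.asarray(self.indifference_p, dtype=float)
        if beta.ndim != 2 or p.shape != beta.shape:
            raise ValueError("beta and indifference_p must be matching 2-D arrays")
        if np.any(beta <= 0):
            raise ValueError("beta entries must be strictly positive")
        if not np.allclose(beta.sum(axis=1), self.target_sum, atol=1e-9):
            raise ValueError(f"each beta row must sum to {self.target_sum}")
        if np.any(p <= 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("indifference_p rows must be positive and sum to 1")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "indifference_p", p)

    @classmethod
    def from_dataset(
        cls, dataset: DiscreteDataset, target_sum: float = DEFAULT_TARGET_SUM
    ) -> "FeaturePrior":
        beta = compute_prior_beta(dataset, target_sum)
        counts = _floored_counts(dataset.level_counts())
        p = counts / counts.sum(axis=1, keepdims=True)
        return cls(beta=beta, indifference_p=p, target_sum=target_sum)


def _floored_counts(counts: np.ndarray) -> np.ndarray:
    """Raise zero level tallies to one pseudo-observation.

    Mirrors the minimum-count-of-one rule used for the indifference
    probabilities, guaranteeing strictly positive hyperparameters even for
    levels absent from a feature's column.
    """
    counts = np.asarray(counts, dtype=float)
    return np.where(counts == 0, 1.0, counts)


def compute_prior_beta(
    dataset: DiscreteDataset, target_sum: float = DEFAULT_TARGET_SUM
) -> np.ndarray:
    """Dirichlet hyperparameters matched to each feature's level proportions.

    Per feature, the level tallies (zero tallies floored at one) are
    rescaled so the hyperparameter vector sums to ``target_sum``.

    Returns an array of shape ``(n_features, V)``.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    counts = _floored_counts(dataset.level_counts())
    return target_sum * counts / counts.sum(axis=1, keepdims=True)


def cluster_feature_loglik(counts: np.ndarray, beta: np.ndarray) -> float:
    """Log multinomial-Dirichlet marginal likelihood of one feature's tallies.

    ``log Gamma(sum beta) - log Gamma(n + sum beta)
    + sum_v [log Gamma(x_v + beta_v) - log Gamma(beta_v)]``
    with ``n = sum_v x_v``. Returns 0 for an empty cluster.
    """
    counts = np.asarray(counts, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(beta <= 0):
        raise ValueError("beta must be strictly positive")
    sb = beta.sum()
    n = counts.sum()
    return float(
        gammaln(sb) - gammaln(n + sb) + (gammaln(counts + beta) - gammaln(beta)).sum()
    )


def indifference_p(feature_column: np.ndarray, n_levels: int = 3) -> np.ndarray:
    """Fixed class probabilities for the feature-off model.

    Proportions of each level across the whole data set for this feature,
    with every level's tally floored at one so the probabilities are
    strictly positive.
    """
    col = np.asarray(feature_column)
    if col.size == 0:
        raise ValueError("feature column must be non-empty")
    if col.min() < 1 or col.max() > n_levels:
        raise ValueError(f"levels must lie in 1..{n_levels}")
    counts = np.array([(col == v).sum() for v in range(1, n_levels + 1)], dtype=float)
    counts = _floored_counts(counts)
    return counts / counts.sum()


def indifference_loglik(counts: np.ndarray, p: np.ndarray) -> float:
    """Log likelihood of one feature's tallies under fixed class probabilities.

    ``sum_v x_v log p_v``; summing over clusters depends only on the
    feature's total tallies, never on the partition.
    """
    counts = np.asarray(counts, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(p <= 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("p must be strictly positive and sum to 1")
    return float(np.dot(counts, np.log(p)))
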