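"""Synthetic paired data sets with known fusion and feature ground truth.

The construction emulates a validation design for integrative
clustering: start from one clustered three-level *base* matrix of signal
items x signal features; both data sets copy it, so signal items share
identical structure across data sets and are fused by construction.
Noise items are then appended, each an independent with-replacement draw
from the signal items — drawn separately per data set, so a noise item
generally mixes two different source items and is unfused except by
coincidence (both sources in the same base cluster). Finally noise
features are appended, columns resampled with replacement from the base
matrix's values: they match the global level distribution but carry no
cluster structure and should be rejected by feature selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .data import DiscreteDataset
from .summaries import PosteriorSummary

__all__ = [
    "SimulationTruth",
    "generate_base",
    "build_fusion_simulation",
    "expected_coincidental_fusion",
    "score_against_truth",
    "SimulationScore",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated pair of data sets.

    ``base_labels`` covers all items: the true cluster for signal items
    and, for noise items, −1. ``noise_sources[d]`` records, per noise
    item, the signal-item index its row in data set ``d`` was copied
    from. A noise item is *coincidentally fused* when its two sources
    share a base cluster.
    """

    k: int
    seed: int
    base_labels: np.ndarray
    is_noise_item: np.ndarray
    is_noise_feature: tuple[np.ndarray, np.ndarray]
    noise_sources: tuple[np.ndarray, np.ndarray]

    @property
    def n_signal_items(self) -> int:
        return int((~self.is_noise_item).sum())

    @property
    def n_noise_items(self) -> int:
        return int(self.is_noise_item.sum())

    @property
    def coincidentally_fused(self) -> np.ndarray:
        """Boolean over noise items: both per-data-set sources share a
        base cluster (bookkeeping only, never used for scoring)."""
        s1, s2 = self.noise_sources
        return self.base_labels[s1] == self.base_labels[s2]

    def to_json(self) -> str:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "base_labels": self.base_labels.tolist(),
            "is_noise_item": self.is_noise_item.astype(int).tolist(),
            "is_noise_feature": [a.astype(int).tolist() for a in self.is_noise_feature],
            "noise_sources": [a.tolist() for a in self.noise_sources],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            k=d["k"],
            seed=d["seed"],
            base_labels=np.array(d["base_labels"], dtype=np.int64),
            is_noise_item=np.array(d["is_noise_item"], dtype=bool),
            is_noise_feature=tuple(
                np.array(a, dtype=bool) for a in d["is_noise_feature"]
            ),
            noise_sources=tuple(np.array(a, dtype=np.int64) for a in d["noise_sources"]),
        )


def generate_base(
    n_items: int = 106,
    n_features: int = 200,
    k: int = 5,
    separation: float = 0.9,
    seed: int = 0,
    n_levels: int = 3,
) -> tuple[DiscreteDataset, np.ndarray]:
    """Clustered three-level base matrix standing in for a real
    copy-number signal matrix.

    Items are split into ``k`` near-equal clusters. Each (cluster,
    feature) has a dominant level drawn uniformly; an item's entry is the
    dominant level with probability ``separation + (1 - separation)/V``
    and any other level with probability ``(1 - separation)/V`` each
    (``separation = 1`` gives within-cluster-constant columns, 0 gives
    structure-free noise). Defaults mirror a 106-item, 200-feature,
    5-cluster design.
    """
    if not 0.0 < separation <= 1.0:
        raise ValueError("separation must lie in (0, 1]")
    if k > n_items:
        raise ValueError("k must not exceed n_items")
    rng = np.random.default_rng(seed)
    sizes = np.full(k, n_items // k)
    sizes[: n_items % k] += 1
    labels = np.repeat(np.arange(k), sizes)
    dominant = rng.integers(0, n_levels, size=(k, n_features))
    base_p = (1.0 - separation) / n_levels
    if base_p == 0.0:
        levels = dominant[labels]
    else:
        u = rng.random((n_items, n_features))
        # cumulative trick: dominant level gets base_p + separation mass
        draw = np.floor(u / base_p).astype(np.int64)  # uniform level if < V
        is_dom = draw >= n_levels
        levels = np.where(is_dom, dominant[labels], np.minimum(draw, n_levels - 1))
    item_labels = tuple(f"item{i + 1}" for i in range(n_items))
    feature_labels = tuple(f"sig{j + 1}" for j in range(n_features))
    data = DiscreteDataset(levels + 1, item_labels, feature_labels, n_levels)
    return data, labels


def build_fusion_simulation(
    base: DiscreteDataset,
    base_labels: np.ndarray,
    n_noise_items: int = 50,
    n_noise_features: int = 200,
    seed: int = 0,
    per_feature_noise: bool = False,
) -> tuple[DiscreteDataset, DiscreteDataset, SimulationTruth]:
    """Assemble the paired simulation data sets from a clustered base.

    Both data sets start as copies of the base. Per data set,
    independently: ``n_noise_items`` rows are drawn with replacement from
    the signal items, and ``n_noise_features`` columns are filled by
    resampling values with replacement from the base matrix
    (``per_feature_noise=True`` resamples each noise column from one
    randomly chosen base column instead of the pooled values).
    """
    rng = np.random.default_rng(seed)
    n_sig, n_feat = base.n_items, base.n_features
    n_total = n_sig + n_noise_items
    pool = base.values.ravel()

    datasets = []
    sources = []
    noise_flags = []
    for d in (0, 1):
        src = rng.integers(0, n_sig, size=n_noise_items)
        rows = np.vstack([base.values, base.values[src]])
        if per_feature_noise:
            cols = rng.integers(0, n_feat, size=n_noise_features)
            noise = np.column_stack(
                [
                    rng.choice(base.values[:, c], size=n_total, replace=True)
                    for c in cols
                ]
            ) if n_noise_features else np.empty((n_total, 0), dtype=rows.dtype)
        else:
            noise = rng.choice(pool, size=(n_total, n_noise_features), replace=True)
        values = np.hstack([rows, noise.astype(rows.dtype)])
        item_labels = tuple(base.item_labels) + tuple(
            f"noise{i + 1}" for i in range(n_noise_items)
        )
        feature_labels = tuple(base.feature_labels) + tuple(
            f"noisefeat{j + 1}" for j in range(n_noise_features)
        )
        datasets.append(
            DiscreteDataset(values, item_labels, feature_labels, base.n_levels)
        )
        sources.append(src)
        noise_flags.append(
            np.concatenate(
                [np.zeros(n_feat, dtype=bool), np.ones(n_noise_features, dtype=bool)]
            )
        )

    truth = SimulationTruth(
        k=int(np.unique(base_labels).size),
        seed=seed,
        base_labels=np.concatenate(
            [np.asarray(base_labels, dtype=np.int64), np.full(n_noise_items, -1)]
        ),
        is_noise_item=np.concatenate(
            [np.zeros(n_sig, dtype=bool), np.ones(n_noise_items, dtype=bool)]
        ),
        is_noise_feature=(noise_flags[0], noise_flags[1]),
        noise_sources=(sources[0], sources[1]),
    )
    return datasets[0], datasets[1], truth


def expected_coincidental_fusion(
    cluster_sizes: np.ndarray, n_noise_items: int
) -> float:
    """Expected number of noise items whose two independent source draws
    fall in the same cluster: ``n_noise x sum_k (s_k / n)^2``."""
    sizes = np.asarray(cluster_sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("cluster sizes must be positive")
    p = sizes / sizes.sum()
    return float(n_noise_items * (p**2).sum())


@dataclass(frozen=True)
class SimulationScore:
    """Simulation-study scorecard.

    ``item_table[(group, state)]`` counts items by truth group
    (signal/noise) and thresholded fusion call (fused/unfused);
    ``feature_table[d][(group, state)]`` counts features of data type
    ``d`` by truth group and selection call; ``ari_signal`` is the
    adjusted Rand index of the consensus partition against the base
    labels over signal items only.
    """

    item_table: dict[tuple[str, str], int]
    feature_table: tuple[dict[tuple[str, str], int], dict[tuple[str, str], int]]
    ari_signal: float

    @property
    def fused_signal(self) -> int:
        return self.item_table[("signal", "fused")]

    @property
    def fused_noise(self) -> int:
        return self.item_table[("noise", "fused")]

    def rejected_noise_features(self) -> int:
        return sum(t[("noise", "rejected")] for t in self.feature_table)

    def selected_noise_features(self) -> int:
        return sum(t[("noise", "selected")] for t in self.feature_table)


def score_against_truth(
    summary: PosteriorSummary,
    truth: SimulationTruth,
    fuse_thr: float = 0.5,
    feat_thr: float = 0.5,
) -> SimulationScore:
    """Threshold the posterior probabilities and tabulate against truth."""
    if not (0.0 <= fuse_thr < 1.0 and 0.0 <= feat_thr < 1.0):
        raise ValueError("thresholds must lie in [0, 1)")
    fus = np.asarray(summary.fusion_prob)
    if fus.size != truth.is_noise_item.size:
        raise ValueError("summary and truth disagree on the number of items")
    fused = fus > fuse_thr
    item_table = {}
    for group, mask in (("signal", ~truth.is_noise_item), ("noise", truth.is_noise_item)):
        item_table[(group, "fused")] = int((fused & mask).sum())
        item_table[(group, "unfused")] = int((~fused & mask).sum())

    feature_tables = []
    for d in (0, 1):
        prob = np.asarray(summary.feature_prob[d])
        noise = truth.is_noise_feature[d]
        if prob.size != noise.size:
            raise ValueError("summary and truth disagree on the number of features")
        selected = prob >= feat_thr
        t = {}
        for group, mask in (("signal", ~noise), ("noise", noise)):
            t[(group, "selected")] = int((selected & mask).sum())
            t[(group, "rejected")] = int((~selected & mask).sum())
        feature_tables.append(t)

    signal = ~truth.is_noise_item
    ari = adjusted_rand_score(
        truth.base_labels[signal], np.asarray(summary.consensus)[signal]
    )
    return SimulationScore(
        item_table=item_table,
        feature_table=(feature_tables[0], feature_tables[1]),
        ari_signal=float(ari),
    )
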