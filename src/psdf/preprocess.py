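"""Feature extraction from continuous matrices to discrete clustering input.

Two pipelines are supported, mirroring common array designs:

* **probe-centric** — each expression probe is matched to its nearest
  copy-number probe on the same chromosome (many expression probes may
  share one copy-number probe); matched pairs are tested for
  copy-number/expression correlation and copy-number probes kept when
  any of their pairs passes a Benjamini-Hochberg-adjusted p-value cut;
* **gene-centric** — probes are aggregated per gene: copy number by the
  per-item median over the gene's probes, expression by the single probe
  most correlated with the gene's copy-number profile.

Expression is discretised by global quantiles (top q as over-expressed,
bottom q as under-expressed, default q = 0.10); copy number by symmetric
log-ratio thresholds (a simple threshold caller standing where a
mixture-model caller would run in a full array pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import DiscreteDataset

__all__ = [
    "ContinuousMatrix",
    "discretize_expression",
    "call_copy_number",
    "match_probes",
    "preselect_correlated",
    "gene_centric_aggregate",
    "top_n_by_score",
]


@dataclass(frozen=True)
class ContinuousMatrix:
    """Item x feature matrix of continuous values (log2 ratios) with
    optional per-feature genomic positions ``(chromosome, coordinate)``
    (1-based)."""

    values: np.ndarray
    item_labels: tuple[str, ...]
    feature_labels: tuple[str, ...]
    positions: dict[str, tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("values must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        item_labels = tuple(str(x) for x in self.item_labels)
        feature_labels = tuple(str(x) for x in self.feature_labels)
        if len(item_labels) != values.shape[0] or len(feature_labels) != values.shape[1]:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(item_labels)) != len(item_labels) or len(
            set(feature_labels)
        ) != len(feature_labels):
            raise ValueError("duplicate labels")
        if self.positions is not None:
            missing = set(feature_labels) - set(self.positions)
            if missing:
                raise ValueError(
                    f"positions missing for {len(missing)} features"
                )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "item_labels", item_labels)
        object.__setattr__(self, "feature_labels", feature_labels)

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.item_labels), columns=list(self.feature_labels)
        )

    def subset_features(self, keep: list[str]) -> "ContinuousMatrix":
        idx = [self.feature_labels.index(f) for f in keep]
        pos = (
            {f: self.positions[f] for f in keep} if self.positions is not None else None
        )
        return ContinuousMatrix(
            self.values[:, idx], self.item_labels, tuple(keep), pos
        )


def discretize_expression(
    matrix: ContinuousMatrix, q: float = 0.10, per_feature: bool = False
) -> DiscreteDataset:
    """Quantile discretisation of expression log2 ratios.

    The top ``q`` fraction of values maps to level 3 (over-expressed),
    the bottom ``q`` to level 1 (under-expressed), the rest to level 2.
    Quantiles are computed over the whole matrix by default
    (``per_feature=True`` computes them per column). Values exactly at a
    boundary go to the extreme level.
    """
    if not 0.0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    vals = matrix.values
    if per_feature:
        lo = np.quantile(vals, q, axis=0, keepdims=True)
        hi = np.quantile(vals, 1.0 - q, axis=0, keepdims=True)
    else:
        lo = np.quantile(vals, q)
        hi = np.quantile(vals, 1.0 - q)
    if np.any(lo >= hi):
        raise ValueError("degenerate matrix: discretisation quantiles coincide")
    levels = np.where(vals <= lo, 1, np.where(vals >= hi, 3, 2))
    return DiscreteDataset(levels, matrix.item_labels, matrix.feature_labels)


def call_copy_number(
    matrix: ContinuousMatrix, loss_thr: float = -0.2, gain_thr: float = 0.2
) -> DiscreteDataset:
    """Threshold calling of copy-number log2 ratios into loss/neutral/gain
    (levels 1/2/3)."""
    if not loss_thr < gain_thr:
        raise ValueError("loss_thr must be below gain_thr")
    vals = matrix.values
    levels = np.where(vals < loss_thr, 1, np.where(vals > gain_thr, 3, 2))
    return DiscreteDataset(levels, matrix.item_labels, matrix.feature_labels)


def match_probes(
    expr_positions: dict[str, tuple[str, int]],
    cn_positions: dict[str, tuple[str, int]],
) -> tuple[dict[str, str], list[str]]:
    """Match each expression probe to its nearest copy-number probe.

    Nearest is by absolute genomic distance on the same chromosome;
    several expression probes may map to one copy-number probe.
    Distance ties break toward the lower coordinate. Returns the mapping
    and the list of unmatched expression probes (no copy-number probe on
    their chromosome).
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for label, (chrom, coord) in cn_positions.items():
        by_chrom.setdefault(chrom, []).append((int(coord), label))
    for probes in by_chrom.values():
        probes.sort()
    mapping: dict[str, str] = {}
    unmatched: list[str] = []
    for label, (chrom, coord) in expr_positions.items():
        probes = by_chrom.get(chrom)
        if not probes:
            unmatched.append(label)
            continue
        coords = [c for c, _ in probes]
        i = np.searchsorted(coords, coord)
        candidates = []
        if i > 0:
            candidates.append(probes[i - 1])
        if i < len(probes):
            candidates.append(probes[i])
        # min distance; ties toward the lower coordinate (sort order)
        best = min(candidates, key=lambda cl: (abs(cl[0] - coord), cl[0]))
        mapping[label] = best[1]
    return mapping, unmatched


def _pair_correlations(
    cn: ContinuousMatrix, expr: ContinuousMatrix, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    cn_idx = {f: j for j, f in enumerate(cn.feature_labels)}
    ex_idx = {f: j for j, f in enumerate(expr.feature_labels)}
    rows = []
    for ef, cf in pairs:
        x = cn.values[:, cn_idx[cf]]
        y = expr.values[:, ex_idx[ef]]
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(x, y)
        rows.append((ef, cf, r, p))
    return pd.DataFrame(rows, columns=["expr", "cn", "r", "p"])


def preselect_correlated(
    cn: ContinuousMatrix,
    expr: ContinuousMatrix,
    mapping: dict[str, str],
    fdr_threshold: float = 0.1,
) -> tuple[list[str], pd.DataFrame]:
    """Keep copy-number features whose expression pairing is significant.

    Pearson correlation across items for every (expression probe,
    matched copy-number probe) pair; two-sided p-values are
    Benjamini-Hochberg adjusted across all pairs, and a copy-number
    feature is selected when any of its pairs has adjusted p below the
    threshold. Returns the selected features and the full pair table.
    """
    if cn.n_items != expr.n_items or cn.item_labels != expr.item_labels:
        raise ValueError("matrices must share an identical ordered item set")
    if cn.n_items < 3:
        raise ValueError("need at least 3 items for correlation testing")
    pairs = sorted(mapping.items())
    if not pairs:
        raise ValueError("empty probe mapping")
    table = _pair_correlations(cn, expr, pairs)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    hits = table.loc[table["p_adj"] < fdr_threshold, "cn"]
    selected = [f for f in cn.feature_labels if f in set(hits)]
    return selected, table


def gene_centric_aggregate(
    cn: ContinuousMatrix,
    expr: ContinuousMatrix,
    gene_annotation: dict[str, str],
) -> tuple[ContinuousMatrix, ContinuousMatrix, list[str]]:
    """Aggregate probe-level matrices to genes.

    Per gene: copy number is the per-item median over the gene's
    copy-number probes; expression is the single probe whose Pearson
    correlation with the gene's copy-number profile is maximal. Genes
    with probes in only one data type are excluded (returned in the
    third element). The resulting per-gene matrices can be filtered with
    :func:`preselect_correlated` using an identity mapping.
    """
    if cn.item_labels != expr.item_labels:
        raise ValueError("matrices must share an identical ordered item set")
    cn_by_gene: dict[str, list[int]] = {}
    ex_by_gene: dict[str, list[int]] = {}
    for j, f in enumerate(cn.feature_labels):
        g = gene_annotation.get(f)
        if g is not None:
            cn_by_gene.setdefault(g, []).append(j)
    for j, f in enumerate(expr.feature_labels):
        g = gene_annotation.get(f)
        if g is not None:
            ex_by_gene.setdefault(g, []).append(j)
    genes = sorted(set(cn_by_gene) & set(ex_by_gene))
    excluded = sorted((set(cn_by_gene) | set(ex_by_gene)) - set(genes))
    if not genes:
        raise ValueError("no gene has probes in both data types")
    cn_out = np.empty((cn.n_items, len(genes)))
    ex_out = np.empty((cn.n_items, len(genes)))
    for g_i, g in enumerate(genes):
        profile = np.median(cn.values[:, cn_by_gene[g]], axis=1)
        cn_out[:, g_i] = profile
        best_j, best_r = ex_by_gene[g][0], -np.inf
        for j in ex_by_gene[g]:
            y = expr.values[:, j]
            if np.std(profile) == 0 or np.std(y) == 0:
                r = -np.inf if len(ex_by_gene[g]) > 1 else 0.0
            else:
                r = stats.pearsonr(profile, y)[0]
            if r > best_r:
                best_j, best_r = j, r
        ex_out[:, g_i] = expr.values[:, best_j]
    genes_t = tuple(genes)
    return (
        ContinuousMatrix(cn_out, cn.item_labels, genes_t),
        ContinuousMatrix(ex_out, cn.item_labels, genes_t),
        excluded,
    )


def top_n_by_score(
    matrix: ContinuousMatrix, scores: dict[str, float], n: int
) -> ContinuousMatrix:
    """Keep the ``n`` best-scoring features (higher is better; ties by
    label for determinism). Generic hook for any downstream ranking."""
    ranked = sorted(
        matrix.feature_labels, key=lambda f: (-scores.get(f, -np.inf), f)
    )
    return matrix.subset_features(ranked[: min(n, len(ranked))])
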