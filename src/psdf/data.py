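"""Discrete data container for three-level molecular calls.

Copy-number data arrive as loss/neutral/gain calls and expression data as
under/normal/over calls; both are represented as integer levels ``1..V``
(``V = 3`` by default) in an item x feature matrix with unique row and
column labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DiscreteDataset"]


@dataclass(frozen=True)
class DiscreteDataset:
    """Labelled item x feature matrix of discrete levels in ``{1..V}``.

    Parameters
    ----------
    values
        Integer matrix of shape ``(n_items, n_features)`` with entries in
        ``{1..n_levels}``. No missing entries are allowed.
    item_labels, feature_labels
        Unique row / column labels.
    n_levels
        Number of discrete levels ``V`` (default 3: e.g. loss/neutral/gain).
    """

    values: np.ndarray
    item_labels: tuple[str, ...]
    feature_labels: tuple[str, ...]
    n_levels: int = 3

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("values must be a non-empty 2-D matrix")
        if not np.issubdtype(values.dtype, np.integer):
            if np.issubdtype(values.dtype, np.floating) and np.all(
                values == np.floor(values)
            ):
                values = values.astype(np.int64)
            else:
                raise ValueError("values must be integer levels")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if values.min() < 1 or values.max() > self.n_levels:
            raise ValueError(
                f"all entries must lie in 1..{self.n_levels}; "
                f"found range [{values.min()}, {values.max()}]"
            )
        item_labels = tuple(str(x) for x in self.item_labels)
        feature_labels = tuple(str(x) for x in self.feature_labels)
        if len(item_labels) != values.shape[0]:
            raise ValueError("item_labels length does not match matrix rows")
        if len(feature_labels) != values.shape[1]:
            raise ValueError("feature_labels length does not match matrix columns")
        if len(set(item_labels)) != len(item_labels):
            raise ValueError("duplicate item labels")
        if len(set(feature_labels)) != len(feature_labels):
            raise ValueError("duplicate feature labels")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "item_labels", item_labels)
        object.__setattr__(self, "feature_labels", feature_labels)

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def level_counts(self) -> np.ndarray:
        """Per-feature level tallies, shape ``(n_features, n_levels)``."""
        out = np.zeros((self.n_features, self.n_levels), dtype=np.int64)
        for v in range(1, self.n_levels + 1):
            out[:, v - 1] = (self.values == v).sum(axis=0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.item_labels),
            columns=list(self.feature_labels),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_levels: int = 3) -> "DiscreteDataset":
        return cls(
            values=frame.to_numpy(),
            item_labels=tuple(str(i) for i in frame.index),
            feature_labels=tuple(str(c) for c in frame.columns),
            n_levels=n_levels,
        )

    def reorder_items(self, labels: list[str] | tuple[str, ...]) -> "DiscreteDataset":
        """Return a copy with rows reordered to match ``labels``."""
        index = {lab: i for i, lab in enumerate(self.item_labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing or len(labels) != self.n_items:
            raise ValueError(f"item sets differ (missing: {missing[:5]})")
        order = [index[lab] for lab in labels]
        return DiscreteDataset(
            self.values[order], tuple(labels), self.feature_labels, self.n_levels
        )
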