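"""Readers and writers for every external format the tool touches.

One TSV dialect throughout: tab-separated, UTF-8, ``#`` comment lines.
Matrices carry a header row of feature labels and a first column of item
labels. Discrete cells may be integer levels or the aliases
loss/neutral/gain and under/normal/over. Retained MCMC samples go to a
line-oriented TSV (one row per sample); run metadata to a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DiscreteDataset
from .preprocess import ContinuousMatrix
from .sampler import ChainConfig, ModelState
from .summaries import PosteriorSummary

__all__ = [
    "LEVEL_ALIASES",
    "read_discrete_matrix",
    "write_discrete_matrix",
    "read_continuous_matrix",
    "write_continuous_matrix",
    "read_positions",
    "write_positions",
    "read_gene_annotation",
    "write_samples",
    "read_samples",
    "write_summary",
    "write_manifest",
]

LEVEL_ALIASES = {
    "loss": 1, "neutral": 2, "gain": 3,
    "under": 1, "normal": 2, "over": 3,
}


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)


def read_discrete_matrix(path, n_levels: int = 3) -> DiscreteDataset:
    """Read a discrete item x feature TSV (integer levels or named calls)."""
    frame = _read_tsv(path)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate item label {dup!r}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate feature label {dup!r}")
    values = np.zeros(frame.shape, dtype=np.int64)
    raw = frame.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(raw[i, j]).strip().lower()
            if tok in LEVEL_ALIASES:
                values[i, j] = LEVEL_ALIASES[tok]
            else:
                try:
                    values[i, j] = int(tok)
                except ValueError:
                    raise ParseError(
                        f"{path}: unknown token {raw[i, j]!r} at item "
                        f"{frame.index[i]!r}, feature {frame.columns[j]!r}"
                    ) from None
    try:
        return DiscreteDataset(
            values, tuple(frame.index), tuple(frame.columns), n_levels
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_discrete_matrix(path, dataset: DiscreteDataset) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index_label="item")


def read_continuous_matrix(path, positions=None) -> ContinuousMatrix:
    frame = _read_tsv(path)
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from None
    try:
        return ContinuousMatrix(
            values, tuple(frame.index), tuple(frame.columns), positions
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_continuous_matrix(path, matrix: ContinuousMatrix) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="item")


def read_positions(path) -> dict[str, tuple[str, int]]:
    """BED-like TSV: chrom, start, end, feature label (1-based inclusive).

    The feature's coordinate is the interval midpoint (rounded down).
    """
    out: dict[str, tuple[str, int]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, label = parts[0], parts[1], parts[2], parts[3]
            try:
                coord = (int(start) + int(end)) // 2
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if label in out:
                raise ParseError(f"{path}:{lineno}: duplicate feature {label!r}")
            out[label] = (chrom, coord)
    return out


def write_positions(path, positions: dict[str, tuple[str, int]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# chrom\tstart\tend\tfeature (1-based inclusive)\n")
        for label, (chrom, coord) in positions.items():
            fh.write(f"{chrom}\t{coord}\t{coord}\t{label}\n")


def read_gene_annotation(path) -> dict[str, str]:
    """Two-column TSV: feature label, gene symbol."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


# --------------------------------------------------------------------- #
# retained-sample archive


def _bits(arr: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in arr)


def _ints(arr: np.ndarray) -> str:
    return ",".join(str(int(v)) for v in arr)


def write_samples(path, chains: list[list[ModelState]]) -> None:
    """One row per retained sample: chain, iteration, concentration,
    fusion bits, fused/unfused label vectors (−1 where not applicable),
    and per-data-type feature bits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "# chain\titeration\talpha\tfusion\t"
            "fused_labels\tunfused_labels_1\tunfused_labels_2\t"
            "features_on_1\tfeatures_on_2\n"
        )
        for c, chain in enumerate(chains):
            for s in chain:
                fh.write(
                    f"{c}\t{s.iteration}\t{s.alpha:.10g}\t"
                    f"{_bits(s.fusion)}\t{_ints(s.fused_labels)}\t"
                    f"{_ints(s.unfused_labels[0])}\t{_ints(s.unfused_labels[1])}\t"
                    f"{_bits(s.feature_on[0])}\t{_bits(s.feature_on[1])}\n"
                )


def read_samples(path) -> list[list[ModelState]]:
    chains: dict[int, list[ModelState]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            try:
                c = int(parts[0])
                state = ModelState(
                    iteration=int(parts[1]),
                    fusion=np.array([ch == "1" for ch in parts[3]], dtype=bool),
                    fused_labels=np.array(parts[4].split(","), dtype=np.int64),
                    unfused_labels=(
                        np.array(parts[5].split(","), dtype=np.int64),
                        np.array(parts[6].split(","), dtype=np.int64),
                    ),
                    feature_on=(
                        np.array([ch == "1" for ch in parts[7]], dtype=bool),
                        np.array([ch == "1" for ch in parts[8]], dtype=bool),
                    ),
                    alpha=float(parts[2]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            chains.setdefault(c, []).append(state)
    if not chains:
        raise ParseError(f"{path}: no samples")
    return [chains[c] for c in sorted(chains)]


# --------------------------------------------------------------------- #
# summary outputs


def _labels_or_default(labels, n, prefix) -> list[str]:
    return list(labels) if labels is not None else [f"{prefix}{i + 1}" for i in range(n)]


def write_summary(outdir, summary: PosteriorSummary) -> dict[str, str]:
    """Write all summary files into ``outdir``; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    items = _labels_or_default(summary.item_labels, summary.psm.shape[0], "item")
    written: dict[str, str] = {}

    psm = pd.DataFrame(summary.psm, index=items, columns=items)
    path = outdir / "psm.tsv"
    psm.to_csv(path, sep="\t", index_label="item", float_format="%.6f")
    written["psm"] = str(path)

    fus = pd.DataFrame({"item": items, "fusion_prob": summary.fusion_prob})
    if summary.fusion_prob_sd is not None:
        fus["chain_sd"] = summary.fusion_prob_sd
    path = outdir / "fusion_prob.tsv"
    fus.to_csv(path, sep="\t", index=False, float_format="%.6f")
    written["fusion_prob"] = str(path)

    for d in (0, 1):
        feats = _labels_or_default(
            summary.feature_labels[d] if summary.feature_labels else None,
            summary.feature_prob[d].size,
            "feature",
        )
        tab = pd.DataFrame(
            {"feature": feats, "selection_prob": summary.feature_prob[d]}
        )
        if summary.feature_prob_sd is not None:
            tab["chain_sd"] = summary.feature_prob_sd[d]
        path = outdir / f"feature_prob_{d + 1}.tsv"
        tab.to_csv(path, sep="\t", index=False, float_format="%.6f")
        written[f"feature_prob_{d + 1}"] = str(path)

    cons = pd.DataFrame({"item": items, "cluster": summary.consensus})
    path = outdir / "consensus.tsv"
    cons.to_csv(path, sep="\t", index=False)
    written["consensus"] = str(path)

    kp = summary.k_posterior
    path = outdir / "k_posterior.json"
    path.write_text(
        json.dumps(
            {
                "overall": {str(k): v for k, v in sorted(kp.overall.items())},
                "fused": {str(k): v for k, v in sorted(kp.fused.items())},
                "mode_overall": kp.mode_overall,
                "mode_fused": kp.mode_fused,
                "n_consensus_clusters": summary.n_consensus_clusters,
            },
            indent=1,
        )
    )
    written["k_posterior"] = str(path)

    # heatmap ordering: items by consensus cluster, features by
    # selection probability (high to low)
    order = np.argsort(summary.consensus, kind="stable")
    lines = ["# heatmap ordering"]
    lines.append("items\t" + "\t".join(items[i] for i in order))
    for d in (0, 1):
        feats = _labels_or_default(
            summary.feature_labels[d] if summary.feature_labels else None,
            summary.feature_prob[d].size,
            "feature",
        )
        lines.append(
            f"features_{d + 1}\t"
            + "\t".join(feats[j] for j in summary.feature_rank[d])
        )
    path = outdir / "heatmap_order.tsv"
    path.write_text("\n".join(lines) + "\n")
    written["heatmap_order"] = str(path)
    return written


def write_manifest(path, config: ChainConfig, extra: dict | None = None) -> None:
    from . import __version__

    payload = {
        "tool": "psdf",
        "version": __version__,
        "config": {
            k: getattr(config, k)
            for k in (
                "n_chains", "n_iterations", "burn_in", "thin", "rho",
                "q_feature", "alpha_prior_shape", "alpha_prior_rate",
                "alpha_init", "sample_alpha", "fuse_threshold",
                "feature_threshold", "seed",
            )
        },
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))
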