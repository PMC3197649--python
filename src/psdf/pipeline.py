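"""End-to-end analysis runs: configuration, execution, output bundle."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as psdf_io
from .data import DiscreteDataset
from .preprocess import call_copy_number, discretize_expression
from .sampler import ChainConfig, multichain_result, run_multichain
from .summaries import PosteriorSummary, summarize_chains

__all__ = ["RunConfig", "run_psdf", "summarize"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs.

    ``mode`` is ``"discrete"`` (inputs already called/discretised) or
    ``"continuous"`` (data set 1 treated as copy-number log ratios and
    thresholded, data set 2 as expression log ratios and
    quantile-discretised before clustering).
    """

    data1: str
    data2: str
    outdir: str
    mode: str = "discrete"
    quantile_q: float = 0.10
    cn_loss_thr: float = -0.2
    cn_gain_thr: float = 0.2
    chain: ChainConfig = field(default_factory=ChainConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("discrete", "continuous"):
            raise ValueError("mode must be 'discrete' or 'continuous'")
        for path in (self.data1, self.data2):
            if not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        chain = ChainConfig(**raw.pop("chain", {}))
        return cls(chain=chain, **raw)


def _config_hash(config: ChainConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> tuple[DiscreteDataset, DiscreteDataset]:
    if config.mode == "discrete":
        d1 = psdf_io.read_discrete_matrix(config.data1)
        d2 = psdf_io.read_discrete_matrix(config.data2)
    else:
        cn = psdf_io.read_continuous_matrix(config.data1)
        expr = psdf_io.read_continuous_matrix(config.data2)
        d1 = call_copy_number(cn, config.cn_loss_thr, config.cn_gain_thr)
        d2 = discretize_expression(expr, config.quantile_q)
    if set(d1.item_labels) != set(d2.item_labels):
        raise ValueError("input matrices do not cover the same item set")
    if d1.item_labels != d2.item_labels:
        d2 = d2.reorder_items(list(d1.item_labels))
    return d1, d2


def run_psdf(config: RunConfig) -> dict[str, str]:
    """Run preprocessing (if any), the multi-chain sampler, and all
    posterior summaries; write the full output bundle into
    ``config.outdir`` and return a name -> path map."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    d1, d2 = _load_inputs(config)
    log(f"loaded {d1.n_items} items; {d1.n_features} + {d2.n_features} features")

    def progress(c: int, seconds: float) -> None:
        log(f"chain {c + 1}/{config.chain.n_chains} done in {seconds:.1f}s "
            f"({config.chain.n_retained} retained samples)")

    result = run_multichain(d1, d2, config.chain, progress=progress)
    summary = summarize_chains(
        result,
        item_labels=d1.item_labels,
        feature_labels=(d1.feature_labels, d2.feature_labels),
    )

    written = psdf_io.write_summary(outdir, summary)
    samples_path = outdir / "samples.tsv"
    psdf_io.write_samples(samples_path, result.chains)
    written["samples"] = str(samples_path)

    manifest_path = outdir / "manifest.json"
    psdf_io.write_manifest(
        manifest_path,
        config.chain,
        extra={
            "inputs": {"data1": str(config.data1), "data2": str(config.data2)},
            "mode": config.mode,
            "config_hash": _config_hash(config.chain),
            "outputs": sorted(written),
            "n_consensus_clusters": summary.n_consensus_clusters,
        },
    )
    written["manifest"] = str(manifest_path)
    log("run complete")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    written["log"] = str(outdir / "run.log")
    return written


def summarize(
    samples_path,
    outdir,
    item_labels=None,
    feature_labels=None,
) -> PosteriorSummary:
    """Recompute every posterior summary from a stored sample archive
    (no MCMC re-run) and write the summary bundle to ``outdir``."""
    chains = psdf_io.read_samples(samples_path)
    result = multichain_result(chains)
    summary = summarize_chains(
        result, item_labels=item_labels, feature_labels=feature_labels
    )
    psdf_io.write_summary(outdir, summary)
    return summary
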