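"""Collapsed Gibbs sampler for patient-specific data fusion.

The model clusters patients from two discretised data types at once.
There is a single shared pool of clusters, each carrying a multinomial
profile for *both* data types. Every patient has a binary fusion state:

* a **fused** patient makes one draw from the pool — one cluster
  explains both of their data types (concordant signal);
* an **unfused** patient makes two independent draws — one cluster per
  data type (contradictory signal).

The draws follow one Chinese restaurant process (mixture weights
marginalised analytically), so fused and unfused patients share cluster
atoms: an unfused patient's copy-number draw can land in the same
cluster as a fused patient. This sharing is essential — were the fused
and unfused processes given disjoint cluster pools, the marginal
likelihood's preference for pooling same-profile items into one cluster
would force every patient unfused as soon as any genuinely unfused
items seeded a duplicate cluster structure.

Per-feature ON/OFF indicators compete the per-cluster
multinomial-Dirichlet marginal against the fixed-probability
indifference likelihood; OFF features contribute identically to every
cluster and cancel from assignment and fusion conditionals. The fusion
indicator is updated jointly with the patient's assignment(s): the
assignments are marginalised when the indicator is drawn, then sampled.
The DP concentration gets the standard auxiliary-variable update under
a Gamma prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

from .data import DiscreteDataset
from .likelihood import FeaturePrior

__all__ = [
    "ChainConfig",
    "ModelState",
    "ClusterStats",
    "MultiChainResult",
    "PSDFSampler",
    "sample_concentration",
    "run_chain",
    "run_multichain",
    "multichain_result",
]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC protocol and model hyperparameters.

    Defaults follow the analysis protocol: 50 chains, thinning by 10,
    symmetric fusion prior ``rho = 0.5`` and feature prior
    ``q_feature = 0.5``, Gamma(2, 1) prior on the DP concentration.
    """

    n_chains: int = 50
    n_iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    rho: float = 0.5
    q_feature: float = 0.5
    alpha_prior_shape: float = 2.0
    alpha_prior_rate: float = 1.0
    alpha_init: float = 1.0
    sample_alpha: bool = True
    fuse_threshold: float = 0.5
    feature_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iterations < 1 or self.thin < 1:
            raise ValueError("n_chains, n_iterations and thin must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if (self.n_iterations - self.burn_in) // self.thin < 1:
            raise ValueError("config retains no samples")
        if not (0.0 <= self.rho <= 1.0 and 0.0 <= self.q_feature <= 1.0):
            raise ValueError("rho and q_feature must lie in [0, 1]")
        if self.alpha_prior_shape <= 0 or self.alpha_prior_rate <= 0:
            raise ValueError("alpha prior parameters must be positive")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class ModelState:
    """One retained MCMC sample.

    ``fused_labels[i]`` is the cluster of item ``i`` when ``fusion[i]``
    is True (−1 otherwise); ``unfused_labels[d][i]`` is the data-type-
    ``d`` cluster when ``fusion[i]`` is False (−1 otherwise). Labels
    index one shared cluster pool, so fused and unfused items may carry
    the same cluster id.
    """

    iteration: int
    fusion: np.ndarray
    fused_labels: np.ndarray
    unfused_labels: tuple[np.ndarray, np.ndarray]
    feature_on: tuple[np.ndarray, np.ndarray]
    alpha: float

    def labels_for_type(self, d: int) -> np.ndarray:
        """Cluster label of every item in the data-type-``d`` view."""
        return np.where(
            self.fusion, self.fused_labels, self.unfused_labels[d]
        ).astype(np.int64)


class ClusterStats:
    """Incrementally maintained tallies for the shared cluster pool.

    Per cluster ``k``: ``draws[k]`` counts CRP draws (fused items
    contribute one, unfused items one per data type); ``n_obs[d][k]``
    counts data-type-``d`` rows held by the cluster; ``counts[d][k, f,
    v]`` tallies level ``v`` of feature ``f`` among those rows.
    """

    def __init__(self, n_features: tuple[int, int], capacity: int,
                 n_levels: int = 3) -> None:
        self.counts = [
            np.zeros((capacity, f, n_levels), dtype=np.int32) for f in n_features
        ]
        self.n_obs = [np.zeros(capacity, dtype=np.int64) for _ in n_features]
        self.draws = np.zeros(capacity, dtype=np.int64)
        self.K = 0
        self.total_draws = 0
        self._arange = [np.arange(f) for f in n_features]

    def add_draw(self, k: int, levels: dict[int, np.ndarray]) -> None:
        """Add one CRP draw to cluster ``k`` carrying the data rows in
        ``levels`` (data type -> 0-based level vector); ``k == K``
        opens a new cluster."""
        if k > self.K:
            raise ValueError("cluster labels must stay contiguous")
        if k == self.K:
            self.K += 1
        for d, lv in levels.items():
            self.counts[d][k, self._arange[d], lv] += 1
            self.n_obs[d][k] += 1
        self.draws[k] += 1
        self.total_draws += 1

    def remove_draw(self, k: int, levels: dict[int, np.ndarray]) -> int | None:
        """Remove one draw; returns the old label renamed to ``k`` if the
        cluster emptied and the last cluster was moved into its slot."""
        for d, lv in levels.items():
            self.counts[d][k, self._arange[d], lv] -= 1
            self.n_obs[d][k] -= 1
        self.draws[k] -= 1
        self.total_draws -= 1
        if self.draws[k] == 0:
            self.K -= 1
            last = self.K
            if k != last:
                for d in (0, 1):
                    self.counts[d][k] = self.counts[d][last]
                    self.counts[d][last] = 0
                    self.n_obs[d][k] = self.n_obs[d][last]
                    self.n_obs[d][last] = 0
                self.draws[k] = self.draws[last]
                self.draws[last] = 0
                return last
            for d in (0, 1):
                self.counts[d][last] = 0
                self.n_obs[d][last] = 0
        return None


def sample_concentration(
    alpha: float,
    n_items: int,
    n_clusters: int,
    prior_shape: float,
    prior_rate: float,
    rng: np.random.Generator,
) -> float:
    """One auxiliary-variable update of a DP concentration.

    Standard Gamma-prior scheme: draw ``eta ~ Beta(alpha + 1, n)``, then
    draw ``alpha`` from the two-component Gamma mixture the conditional
    factorises into. With no draws the conditional is the prior itself.
    """
    if n_items == 0:
        return float(rng.gamma(prior_shape, 1.0 / prior_rate))
    if n_clusters < 1 or n_items < n_clusters:
        raise ValueError("need 1 <= n_clusters <= n_items")
    eta = rng.beta(alpha + 1.0, n_items)
    rate = prior_rate - np.log(eta)
    odds = (prior_shape + n_clusters - 1.0) / (n_items * rate)
    shape = prior_shape + n_clusters
    if rng.random() >= odds / (1.0 + odds):
        shape -= 1.0
    return float(rng.gamma(shape, 1.0 / rate))


def _sample_from_log_weights(rng: np.random.Generator, lw: np.ndarray) -> int:
    w = np.exp(lw - lw.max())
    c = np.cumsum(w)
    return int(np.searchsorted(c, rng.random() * c[-1]))


def _logsumexp(lw: np.ndarray) -> float:
    m = lw.max()
    return float(m + np.log(np.exp(lw - m).sum()))


class PSDFSampler:
    """Gibbs sampler over fusion indicators, cluster assignments,
    feature indicators, and the DP concentration.

    Parameters
    ----------
    data1, data2
        Discretised data sets over an identical ordered item set.
    config
        Protocol and hyperparameters.
    priors
        Optional pair of :class:`FeaturePrior`; computed from the data
        when omitted.
    rng
        Source of randomness; a fresh generator seeded from
        ``config.seed`` when omitted.
    """

    def __init__(
        self,
        data1: DiscreteDataset,
        data2: DiscreteDataset,
        config: ChainConfig,
        priors: tuple[FeaturePrior, FeaturePrior] | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        if data1.item_labels != data2.item_labels:
            raise ValueError("data sets must share an identical ordered item set")
        if data1.n_levels != 3 or data2.n_levels != 3:
            raise ValueError("sampler currently supports three-level data")
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.item_labels = data1.item_labels
        self.N = data1.n_items
        self.x = [data1.values - 1, data2.values - 1]  # 0-based levels
        self.F = [data1.n_features, data2.n_features]
        if priors is None:
            priors = (FeaturePrior.from_dataset(data1), FeaturePrior.from_dataset(data2))
        self.priors = priors
        self.target_sum = priors[0].target_sum
        self.beta = [priors[0].beta, priors[1].beta]

        # per-item gathered hyperparameters beta[f, x[i, f]] and the
        # empty-cluster predictive log(beta_x / sum beta)
        self._bx = [
            self.beta[d][np.arange(self.F[d])[None, :], self.x[d]] for d in (0, 1)
        ]
        self._lb0 = [np.log(self._bx[d] / self.target_sum) for d in (0, 1)]

        # log-gamma tables for the feature sweep: glt[d][m, f, v] =
        # lgamma(m + beta[f, v]) for every integer tally m that can occur
        m = np.arange(self.N + 1, dtype=float)
        self._glt = [
            gammaln(m[:, None, None] + self.beta[d][None, :, :]) for d in (0, 1)
        ]
        self._glt0sum = [self._glt[d][0].sum(axis=1) for d in (0, 1)]
        self._gl_n = gammaln(m + self.target_sum)
        self._gl_ts = float(gammaln(self.target_sum))
        self._fI = [np.arange(self.F[d])[None, :, None] for d in (0, 1)]
        self._vI = np.arange(3)[None, None, :]

        # indifference log-likelihood of each feature's total tallies
        # (constant: every item contributes its row exactly once per type)
        self._offll = []
        for d in (0, 1):
            tot = np.zeros((self.F[d], 3))
            for v in range(3):
                tot[:, v] = (self.x[d] == v).sum(axis=0)
            self._offll.append((tot * np.log(priors[d].indifference_p)).sum(axis=1))

        # capacity: every unfused item contributes two draws
        self.stats = ClusterStats((self.F[0], self.F[1]), capacity=2 * self.N)
        self.fused_labels = np.full(self.N, -1, dtype=np.int64)
        self.unfused_labels = [np.full(self.N, -1, dtype=np.int64) for _ in (0, 1)]
        self.fusion = np.zeros(self.N, dtype=bool)
        self.on = [np.ones(self.F[d], dtype=bool) for d in (0, 1)]
        self.alpha = float(config.alpha_init)
        self._refresh_on_cache()
        self._init_state()

    # ------------------------------------------------------------------ #
    # state plumbing

    def _refresh_on_cache(self) -> None:
        self._on_idx = [np.flatnonzero(self.on[d]) for d in (0, 1)]
        self._x_on = [self.x[d][:, self._on_idx[d]] for d in (0, 1)]
        self._bx_on = [self._bx[d][:, self._on_idx[d]] for d in (0, 1)]
        self._pred0 = [self._lb0[d][:, self._on_idx[d]].sum(axis=1) for d in (0, 1)]

    def _relabel(self, old: int, new: int) -> None:
        self.fused_labels[self.fused_labels == old] = new
        for d in (0, 1):
            self.unfused_labels[d][self.unfused_labels[d] == old] = new

    def _add_fused(self, i: int, k: int) -> None:
        self.stats.add_draw(k, {0: self.x[0][i], 1: self.x[1][i]})
        self.fused_labels[i] = k

    def _add_unfused(self, i: int, d: int, k: int) -> None:
        self.stats.add_draw(k, {d: self.x[d][i]})
        self.unfused_labels[d][i] = k

    def _remove_fused(self, i: int) -> None:
        k = self.fused_labels[i]
        self.fused_labels[i] = -1
        renamed = self.stats.remove_draw(k, {0: self.x[0][i], 1: self.x[1][i]})
        if renamed is not None:
            self._relabel(renamed, k)

    def _remove_unfused(self, i: int, d: int) -> None:
        k = self.unfused_labels[d][i]
        self.unfused_labels[d][i] = -1
        renamed = self.stats.remove_draw(k, {d: self.x[d][i]})
        if renamed is not None:
            self._relabel(renamed, k)

    def _drop_item(self, i: int) -> None:
        if self.fusion[i]:
            self._remove_fused(i)
        else:
            self._remove_unfused(i, 0)
            self._remove_unfused(i, 1)

    def _init_state(self) -> None:
        """All features ON; all items start fused (unless ``rho = 0``)
        with assignments from a sequential posterior-predictive CRP draw,
        then a few assignment-consolidation passes.

        Starting fused matters: contradictory items can unfuse one at a
        time, but with many informative features fusion cannot nucleate
        from an unfused start — a freshly fused cluster is too small for
        its predictive to compete. The consolidation passes dissolve the
        splinter clusters a single sequential pass leaves behind, which
        would otherwise trigger spurious unfusing on the first sweep.
        """
        start_fused = self.config.rho > 0.0
        for i in range(self.N):
            self.fusion[i] = start_fused
            if start_fused:
                self._add_fused(i, _sample_from_log_weights(
                    self.rng, self._log_weights_fused(i)))
            else:
                for d in (0, 1):
                    self._add_unfused(i, d, _sample_from_log_weights(
                        self.rng, self._log_weights_unfused(i, d)))
        for _ in range(3):
            for i in self.rng.permutation(self.N):
                self.update_assignment(int(i))

    # ------------------------------------------------------------------ #
    # conditionals

    def _log_pred(self, d: int, i: int) -> np.ndarray:
        """Log posterior-predictive of item ``i``'s data-type-``d`` row
        (ON features only) under each existing cluster plus a new one
        (last entry). OFF features cancel and are omitted."""
        st = self.stats
        K = st.K
        lp = np.empty(K + 1)
        idx = self._on_idx[d]
        lp[K] = self._pred0[d][i]
        if K == 0:
            return lp
        if idx.size == 0:
            lp[:K] = 0.0
            return lp
        cnt = st.counts[d][:K, idx, self._x_on[d][i]]
        lp[:K] = np.log(cnt + self._bx_on[d][i]).sum(axis=1)
        lp[:K] -= idx.size * np.log(st.n_obs[d][:K] + self.target_sum)
        return lp

    def _crp_log_weights(self) -> np.ndarray:
        st = self.stats
        lw = np.empty(st.K + 1)
        lw[: st.K] = np.log(st.draws[: st.K])
        lw[st.K] = np.log(self.alpha)
        return lw

    def _log_weights_fused(self, i: int) -> np.ndarray:
        return self._crp_log_weights() + self._log_pred(0, i) + self._log_pred(1, i)

    def _log_weights_unfused(self, i: int, d: int) -> np.ndarray:
        return self._crp_log_weights() + self._log_pred(d, i)

    def update_fusion(self, i: int) -> None:
        """Joint move on (fusion indicator, assignments) for one item.

        With the item's draws removed, let ``w_k`` be CRP weights and
        ``p_dk`` the data-type-``d`` predictives. Then

        * P(fused) ∝ rho × sum_k w_k p_1k p_2k / (M + alpha),
        * P(unfused) ∝ (1 − rho) × sum_{k1,k2} of the two sequential CRP
          draws' joint weight × p_1,k1 p_2,k2, the second draw seeing the
          first (same-cluster and same-new-cluster options included),

        the assignments being sampled afterwards from the chosen branch.
        """
        rho = self.config.rho
        self._drop_item(i)
        st = self.stats
        K = st.K
        lcrp = self._crp_log_weights()
        lp1 = self._log_pred(0, i)
        lp2 = self._log_pred(1, i)
        lw_fused = lcrp + lp1 + lp2

        if rho >= 1.0:
            fused = True
        elif rho <= 0.0:
            fused = False
        else:
            m_alpha = st.total_draws + self.alpha
            # second-draw mixture: sum_k (m_k + [k = k1]) p_2k + alpha p_2,new,
            # with the k1-dependent part folded in via logaddexp
            ls2 = _logsumexp(lcrp + lp2)
            lw_unf = lcrp + lp1 + np.logaddexp(ls2, lp2)
            lo_fused = np.log(rho) + _logsumexp(lw_fused) - np.log(m_alpha)
            lo_unf = (
                np.log1p(-rho)
                + _logsumexp(lw_unf)
                - np.log(m_alpha)
                - np.log(m_alpha + 1.0)
            )
            fused = self.rng.random() < expit(lo_fused - lo_unf)

        self.fusion[i] = fused
        if fused:
            self._add_fused(i, _sample_from_log_weights(self.rng, lw_fused))
        else:
            if rho <= 0.0:
                lw1 = lcrp + lp1
            else:
                lw1 = lw_unf
            self._add_unfused(i, 0, _sample_from_log_weights(self.rng, lw1))
            # predictives for type 2 are unchanged by the type-1 draw;
            # only the CRP weights moved (possibly a new cluster opened)
            self._add_unfused(i, 1, _sample_from_log_weights(
                self.rng, self._crp_log_weights() + self._log_pred(1, i)))

    def update_assignment(self, i: int) -> None:
        """Resample the item's draw(s) given its fusion state."""
        if self.fusion[i]:
            self._remove_fused(i)
            self._add_fused(i, _sample_from_log_weights(
                self.rng, self._log_weights_fused(i)))
        else:
            for d in (0, 1):
                self._remove_unfused(i, d)
                self._add_unfused(i, d, _sample_from_log_weights(
                    self.rng, self._log_weights_unfused(i, d)))

    def _feature_on_logodds(self, d: int) -> np.ndarray:
        """Log odds of each feature of data type ``d`` being ON given the
        current partition (vectorised over features)."""
        st = self.stats
        K = st.K
        hold = np.flatnonzero(st.n_obs[d][:K] > 0)
        onll = np.zeros(self.F[d])
        if hold.size:
            g = self._glt[d][st.counts[d][hold], self._fI[d], self._vI]
            onll = g.sum(axis=(0, 2)) - hold.size * self._glt0sum[d]
            onll += hold.size * self._gl_ts - self._gl_n[st.n_obs[d][hold]].sum()
        q = self.config.q_feature
        if q >= 1.0:
            return np.full(self.F[d], np.inf)
        if q <= 0.0:
            return np.full(self.F[d], -np.inf)
        return np.log(q / (1.0 - q)) + onll - self._offll[d]

    def update_features(self, d: int) -> None:
        self.on[d] = self.rng.random(self.F[d]) < expit(self._feature_on_logodds(d))
        self._refresh_on_cache()

    def update_concentration(self) -> None:
        cfg = self.config
        self.alpha = sample_concentration(
            self.alpha, self.stats.total_draws, max(self.stats.K, 1),
            cfg.alpha_prior_shape, cfg.alpha_prior_rate, self.rng,
        )

    # ------------------------------------------------------------------ #
    # sweeps

    def sweep(self) -> None:
        """One full Gibbs iteration: fusion (joint with assignments),
        then all assignments, then feature indicators, then the DP
        concentration. Item orders are randomised per pass."""
        for i in self.rng.permutation(self.N):
            self.update_fusion(int(i))
        for i in self.rng.permutation(self.N):
            self.update_assignment(int(i))
        for d in (0, 1):
            self.update_features(d)
        if self.config.sample_alpha:
            self.update_concentration()

    def snapshot(self, iteration: int) -> ModelState:
        return ModelState(
            iteration=iteration,
            fusion=self.fusion.copy(),
            fused_labels=self.fused_labels.copy(),
            unfused_labels=(
                self.unfused_labels[0].copy(), self.unfused_labels[1].copy()
            ),
            feature_on=(self.on[0].copy(), self.on[1].copy()),
            alpha=float(self.alpha),
        )

    def run(self) -> list[ModelState]:
        cfg = self.config
        retained: list[ModelState] = []
        for it in range(1, cfg.n_iterations + 1):
            self.sweep()
            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                retained.append(self.snapshot(it))
        return retained

    # ------------------------------------------------------------------ #
    # verification helpers

    def recompute_stats(self) -> ClusterStats:
        """Rebuild the cluster tallies from scratch from the current
        labels (used to verify the incremental bookkeeping)."""
        fresh = ClusterStats((self.F[0], self.F[1]), capacity=2 * self.N)
        draws = []
        for i in range(self.N):
            if self.fusion[i]:
                draws.append((int(self.fused_labels[i]),
                              {0: self.x[0][i], 1: self.x[1][i]}))
            else:
                for d in (0, 1):
                    draws.append((int(self.unfused_labels[d][i]),
                                  {d: self.x[d][i]}))
        for k, levels in sorted(draws, key=lambda t: t[0]):
            fresh.add_draw(k, levels)
        return fresh


@dataclass(frozen=True)
class MultiChainResult:
    """Chains plus cross-chain dispersion of headline statistics."""

    chains: list[list[ModelState]]
    fusion_prob_mean: np.ndarray
    fusion_prob_sd: np.ndarray
    feature_prob_mean: tuple[np.ndarray, np.ndarray]
    feature_prob_sd: tuple[np.ndarray, np.ndarray]
    cluster_count_mean: float
    cluster_count_sd: float

    @property
    def samples(self) -> list[ModelState]:
        return [s for chain in self.chains for s in chain]


def run_chain(
    data1: DiscreteDataset,
    data2: DiscreteDataset,
    config: ChainConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> list[ModelState]:
    """Run one chain and return its retained samples."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    return PSDFSampler(data1, data2, config, rng=rng).run()


def multichain_result(chains: list[list[ModelState]]) -> MultiChainResult:
    """Assemble cross-chain means and standard deviations of the fusion,
    feature and cluster-count statistics from per-chain samples."""
    from .summaries import (
        cluster_count_posterior,
        feature_probabilities,
        fusion_probabilities,
    )

    fus = np.stack([fusion_probabilities(c) for c in chains])
    fp = [np.stack([feature_probabilities(c)[0][d] for c in chains]) for d in (0, 1)]
    kmeans = np.array([cluster_count_posterior(c).mean_overall for c in chains])
    ddof = 1 if len(chains) > 1 else 0
    return MultiChainResult(
        chains=chains,
        fusion_prob_mean=fus.mean(axis=0),
        fusion_prob_sd=fus.std(axis=0, ddof=ddof),
        feature_prob_mean=(fp[0].mean(axis=0), fp[1].mean(axis=0)),
        feature_prob_sd=(fp[0].std(axis=0, ddof=ddof), fp[1].std(axis=0, ddof=ddof)),
        cluster_count_mean=float(kmeans.mean()),
        cluster_count_sd=float(kmeans.std(ddof=ddof)),
    )


def run_multichain(
    data1: DiscreteDataset,
    data2: DiscreteDataset,
    config: ChainConfig,
    progress=None,
) -> MultiChainResult:
    """Run ``config.n_chains`` chains with independent seeds spawned from
    ``config.seed`` and report cross-chain dispersion of the fusion,
    feature and cluster-count statistics. ``progress`` is an optional
    callback ``(chain_index, seconds)`` invoked as each chain finishes."""
    import time

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    for c, s in enumerate(seeds):
        t0 = time.perf_counter()
        chains.append(run_chain(data1, data2, config, seed=s))
        if progress is not None:
            progress(c, time.perf_counter() - t0)
    return multichain_result(chains)
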