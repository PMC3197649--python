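"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (set
partitions, explicit CRP probabilities, memoised gamma-ratio marginals,
Monte-Carlo integration) so it cannot share a code path with the
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln


def set_partitions(items):
    """All partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for p in set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1:]
        yield p + [[first]]


def crp_logprob(partition, alpha: float, n: int) -> float:
    """Log probability of a partition under a CRP with concentration alpha."""
    if n == 0:
        return 0.0
    return (
        len(partition) * np.log(alpha)
        - (gammaln(alpha + n) - gammaln(alpha))
        + sum(gammaln(len(block)) for block in partition)
    )


def dirichlet_multinomial_mc(counts, beta, n_draws: int = 1_000_000, seed: int = 0):
    """Monte-Carlo estimate of the Dirichlet-multinomial probability of
    count vectors: E_theta[prod_v theta_v^{x_v}] x multinomial
    coefficient, theta ~ Dirichlet(beta).

    ``counts`` may be one vector or a matrix of row vectors (all sharing
    the same draws, chunked to bound memory); returns a scalar or a
    vector accordingly.
    """
    rng = np.random.default_rng(seed)
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    total = np.zeros(counts.shape[0])
    chunk = 100_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        log_theta = np.log(rng.dirichlet(beta, size=m))
        total += np.exp(log_theta @ counts.T).sum(axis=0)
        done += m
    mean = total / n_draws
    coef = np.exp(gammaln(counts.sum(axis=1) + 1) - gammaln(counts + 1).sum(axis=1))
    out = coef * mean
    return out if out.size > 1 else float(out[0])


def concentration_log_conditional(alpha_grid, n: int, k: int,
                                  prior_shape: float, prior_rate: float):
    """Unnormalised log conditional density of a DP concentration given
    ``k`` clusters among ``n`` draws, under a Gamma(shape, rate) prior:
    p(alpha | k, n) ∝ Gamma-pdf(alpha) x alpha^k Gamma(alpha)/Gamma(alpha+n).
    """
    a = np.asarray(alpha_grid, dtype=float)
    return (
        (prior_shape - 1) * np.log(a)
        - prior_rate * a
        + k * np.log(a)
        + gammaln(a)
        - gammaln(a + n)
    )


class ExactPosterior:
    """Brute-force posterior for the shared-pool fusion model.

    Enumerates every fusion vector and every partition of the resulting
    CRP draws (a fused item contributes one draw carrying both data
    types; an unfused item one draw per data type), with feature ON/OFF
    indicators marginalised per feature.
    """

    def __init__(self, x1, x2, beta1, beta2, p1, p2,
                 rho: float, q: float, alpha: float) -> None:
        self.x = [np.asarray(x1), np.asarray(x2)]  # 0-based levels
        self.beta = [np.asarray(beta1), np.asarray(beta2)]
        self.p = [np.asarray(p1), np.asarray(p2)]
        self.rho, self.q, self.alpha = rho, q, alpha
        self.N = self.x[0].shape[0]
        self.F = [self.x[0].shape[1], self.x[1].shape[1]]
        self._dm_cache: dict = {}
        self._off = [
            [
                float(
                    np.bincount(self.x[d][:, f], minlength=3)
                    @ np.log(self.p[d][f])
                )
                for f in range(self.F[d])
            ]
            for d in (0, 1)
        ]
        self._compute()

    def _dm(self, counts, d: int, f: int) -> float:
        key = (tuple(counts), d, f)
        if key not in self._dm_cache:
            c = np.asarray(counts, dtype=float)
            b = self.beta[d][f]
            self._dm_cache[key] = float(
                gammaln(b.sum()) - gammaln(c.sum() + b.sum())
                + (gammaln(c + b) - gammaln(b)).sum()
            )
        return self._dm_cache[key]

    def _compute(self) -> None:
        N, rho, q = self.N, self.rho, self.q
        fusion = np.zeros(N)
        psm = np.zeros((N, N))
        fprob = [np.zeros(self.F[0]), np.zeros(self.F[1])]
        k_overall: dict[float, float] = {}
        weights, configs = [], []
        for mask in itertools.product([0, 1], repeat=N):
            if rho >= 1 and not all(mask):
                continue
            if rho <= 0 and any(mask):
                continue
            lp_ind = 0.0
            if 0 < rho < 1:
                lp_ind = sum(
                    np.log(rho) if m else np.log1p(-rho) for m in mask
                )
            tokens = []
            for i in range(N):
                if mask[i]:
                    tokens.append(("F", i))
                else:
                    tokens += [("1", i), ("2", i)]
            for part in set_partitions(tokens):
                lp = lp_ind + crp_logprob(part, self.alpha, len(tokens))
                fons = [np.zeros(self.F[0]), np.zeros(self.F[1])]
                for d in (0, 1):
                    tags = ("F", str(d + 1))
                    for f in range(self.F[d]):
                        onl = 0.0
                        for block in part:
                            members = [i for tag, i in block if tag in tags]
                            if members:
                                cnt = np.bincount(
                                    self.x[d][members, f], minlength=3
                                )
                                onl += self._dm(cnt, d, f)
                        offl = self._off[d][f]
                        if q >= 1:
                            comb, pon = onl, 1.0
                        elif q <= 0:
                            comb, pon = offl, 0.0
                        else:
                            m_ = max(onl, offl)
                            comb = m_ + np.log(
                                q * np.exp(onl - m_) + (1 - q) * np.exp(offl - m_)
                            )
                            pon = q * np.exp(onl - comb)
                        lp += comb
                        fons[d][f] = pon
                weights.append(lp)
                configs.append((mask, part, fons))
        w = np.array(weights)
        w = np.exp(w - w.max())
        w /= w.sum()
        for wi, (mask, part, fons) in zip(w, configs):
            fusion += wi * np.array(mask)
            counts_per_type = []
            for d in (0, 1):
                tags = ("F", str(d + 1))
                lab = np.zeros(N, dtype=int)
                for ci, block in enumerate(part):
                    for tag, i in block:
                        if tag in tags:
                            lab[i] = ci
                psm += 0.5 * wi * (lab[:, None] == lab[None, :])
                fprob[d] += wi * fons[d]
                counts_per_type.append(np.unique(lab).size)
            ko = float(np.mean(counts_per_type))
            k_overall[ko] = k_overall.get(ko, 0.0) + wi
        self.fusion_prob = fusion
        self.psm = psm
        self.feature_prob = fprob
        self.k_overall = k_overall
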