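# psdf — patient-specific data fusion

Bayesian nonparametric integrative clustering of two discretised
molecular data types — typically copy-number calls (loss/neutral/gain)
and expression calls (under/normal/over) — measured on the same tumour
samples. For each patient the model infers whether the two data types
tell a *concordant* story (the patient is **fused**: one cluster
explains both profiles) or a *contradictory* one (**unfused**: one
cluster per data type), while simultaneously selecting informative
features and inferring the number of clusters. It is aimed at cancer
subtype discovery, where the degree of genomic–transcriptomic
concordance varies from patient to patient and from cancer type to
cancer type.

## Model in brief

A single Dirichlet-process mixture over a shared pool of clusters,
each cluster carrying a naive-Bayes multinomial profile per data type.
Patient *i* has a fusion indicator *g*<sub>*i*</sub> ~ Bernoulli(ρ):
fused patients make one draw from the pool (both data rows generated by
that cluster), unfused patients make two independent draws (one per
data type). Mixture weights are marginalised, so inference is collapsed
Gibbs sampling over fusion indicators, cluster assignments, feature
ON/OFF indicators and the DP concentration α (Gamma prior,
auxiliary-variable update).

Per feature *j* and cluster, the feature-ON likelihood is the
multinomial-Dirichlet marginal

&nbsp;&nbsp;log Γ(Σ<sub>v</sub>β<sub>jv</sub>) − log Γ(n + Σ<sub>v</sub>β<sub>jv</sub>) + Σ<sub>v</sub>[log Γ(x<sub>jv</sub> + β<sub>jv</sub>) − log Γ(β<sub>jv</sub>)],

with β<sub>j</sub> matched to the feature's level proportions and
rescaled to sum to 1.5 (the Jeffreys value 0.5 per level). The
feature-OFF ("indifference") likelihood fixes the level probabilities
at whole-data-set proportions, Σ<sub>v</sub> x<sub>jv</sub> log p<sub>jv</sub>,
making the partition irrelevant for that feature; selection is the
posterior competition between the two. Outputs are posterior
similarity matrices (averaged over the two data types), per-patient
fusion probabilities, per-feature selection probabilities, a
Binder-loss consensus partition, and the posterior over the number of
clusters — with cross-chain uncertainty on each probability.

See `docs/methods.md` for the full model, the sampler, and the design
rationale (in particular why fused and unfused patients share one
cluster pool).

## Worked example

Simulate a paired data set with known ground truth and analyse it:

```bash
psdf simulate --n-items 106 --n-features 200 --k 5 \
    --noise-items 50 --noise-features 200 --seed 3 --outdir sim/
psdf run --data1 sim/data1.tsv --data2 sim/data2.tsv \
    --n-chains 5 --n-iterations 2000 --burn-in 1000 --thin 10 \
    --seed 9 --outdir out/
```

Each simulated data set has 156 items (106 concordant signal items and
50 per-data-set resampled noise items) × 400 features (200 clustered
signal features and 200 structure-free noise features). The same
analysis through the Python API, scored against the generator's truth:

```python
from psdf import (ChainConfig, build_fusion_simulation, generate_base,
                  run_multichain, score_against_truth, summarize_chains)

base, labels = generate_base(106, 200, k=5, separation=0.9, seed=101)
d1, d2, truth = build_fusion_simulation(base, labels, 50, 200, seed=102)
cfg = ChainConfig(n_chains=5, n_iterations=2000, burn_in=1000, thin=10, seed=103)
summary = summarize_chains(run_multichain(d1, d2, cfg), item_labels=d1.item_labels)
score = score_against_truth(summary, truth)
print(score.item_table)
print(score.rejected_noise_features(), score.ari_signal)
```

prints

```
{('signal', 'fused'): 106, ('signal', 'unfused'): 0,
 ('noise', 'fused'): 10, ('noise', 'unfused'): 40}
400 1.0
```

All 106 concordant items are called fused; 10 of the 50 noise items are
fused, matching the closed-form coincidental-fusion expectation
50 × Σ<sub>k</sub>(s<sub>k</sub>/n)² = 10.0 (a noise item whose two
independent source draws happen to share a base cluster is concordant
by accident); all 400 injected noise features are rejected by feature
selection; and the consensus partition recovers the 5 generating
clusters exactly (adjusted Rand index 1.0 on signal items).

`psdf run` writes `psm.tsv`, `fusion_prob.tsv`, `feature_prob_{1,2}.tsv`,
`consensus.tsv`, `k_posterior.json`, a heatmap-ordering file, the
retained-sample archive `samples.tsv` and a JSON manifest;
`psdf summarize --samples out/samples.tsv --outdir re/` recomputes every
summary from the archive without re-running MCMC. `psdf preprocess`
turns continuous log2-ratio matrices into the discrete inputs
(probe-centric nearest-probe matching with a Benjamini–Hochberg
adjusted-correlation filter, or gene-centric median/best-probe
aggregation).

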