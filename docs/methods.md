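# Methods

## The problem

Copy-number alteration and gene-expression profiles of the same tumour
cohort offer complementary views of disease structure, but their
signals do not agree for every patient: some tumours show concordant
genomic and transcriptomic changes, others do not. Forcing all
patients into a single joint clustering blurs subtypes; clustering each
data type separately discards the shared signal. `psdf` models the
choice patient by patient.

## Model

Both inputs are item × feature matrices of three-level calls
(loss/neutral/gain for copy number, under/normal/over for expression),
over an identical ordered item set.

**Clusters.** There is one shared, countably infinite pool of clusters.
Cluster *k* carries a multinomial level-probability vector per feature
*per data type*, i.e. an atom is a pair of naive-Bayes profiles.
Features are conditionally independent given the cluster.

**Fusion.** Each item *i* has a binary fusion state
*g*<sub>*i*</sub> ~ Bernoulli(ρ) (default ρ = 0.5). A fused item makes
**one** draw from the cluster pool and both of its data rows are
generated by that cluster. An unfused item makes **two independent
draws** — one cluster per data type. All draws follow a single
Dirichlet-process mixture whose weights are marginalised, giving a
Chinese restaurant process over draws with concentration α
(Gamma(2, 1) prior, resampled by the standard auxiliary-variable
scheme). The number of realised clusters is thereby inferred from the
data.

Sharing one cluster pool between fused and unfused items is a
deliberate and load-bearing design choice. We first implemented the
alternative — disjoint pools: one fused partition and one unfused
partition per data type, coupled only by the fusion indicators — and
found it *cannot* keep concordant items fused in the presence of any
genuinely unfused items. The reason is quantitative: the
multinomial-Dirichlet marginal rewards pooling two same-profile groups
into one cluster by roughly 1–2 nats per feature per cluster (measured
on three-level data at realistic cluster sizes). With disjoint pools,
the only way a fused item can share a cluster with an unfused item of
identical profile is to unfuse, so once a few genuinely discordant
items seed a duplicate cluster structure in the unfused contexts, that
pooling pressure — thousands of nats at hundreds of features —
unravels fusion entirely. We verified this is a property of that
posterior, not a sampler defect, by checking the sampler against
brute-force enumeration on small problems. With a shared pool the
pooling term cancels between the fused and unfused branches and the
fusion state is decided by what it should be: whether one cluster can
explain both rows, at the CRP's mild economy of one draw versus two.
A corollary matching observed practice on real cohorts: clusters may
contain fused and unfused members simultaneously.

**Per-feature likelihoods and selection.** Each feature of each data
type has a binary ON/OFF indicator with prior q = 0.5.

* ON: the multinomial-Dirichlet marginal per cluster,
  log Γ(Σβ) − log Γ(n + Σβ) + Σ<sub>v</sub>[log Γ(x<sub>v</sub> + β<sub>v</sub>) − log Γ(β<sub>v</sub>)],
  with per-feature Dirichlet hyperparameters β matched to the feature's
  own level proportions and rescaled to sum to 1.5 — the Jeffreys value
  0.5 summed over the three levels, a weakly informative constraint.
* OFF: an *indifference* likelihood Σ<sub>v</sub> x<sub>v</sub> log p<sub>v</sub>
  with p fixed at the feature's whole-data-set level proportions, each
  level's tally floored at one count. Under it, cluster assignment is
  irrelevant for the feature, so it contributes identically to every
  assignment and fusion option and cancels from those conditionals.

Zero tallies are floored at one pseudo-observation in both β and p, so
hyperparameters and probabilities stay strictly positive even for
levels absent from a column; this applies one rule symmetrically to
both quantities. Selection is a model competition: the indifference
model is simpler (known probabilities), so a feature stays ON only when
its within-cluster distributions beat that simplicity.

## Inference

Collapsed Gibbs sampling. One iteration sweeps, in randomised item
order:

1. **fusion, jointly with assignment** — the item's draw(s) are
   removed; the fusion indicator is sampled with assignments
   marginalised (for the unfused branch the second CRP draw correctly
   sees the first, including the same-cluster and same-new-cluster
   options), then the assignment(s) are sampled from the chosen branch;
2. **assignments** for every item given its fusion state;
3. **feature indicators**, each from its exact conditional (vectorised
   over features with precomputed log-gamma tables);
4. **the concentration** α (optional; exact toy comparisons fix it).

Sufficient statistics (per-cluster level tallies, per-type observation
counts, draw counts) are maintained incrementally; empty clusters are
compacted immediately. All likelihood computation is in log space.

**Initialisation.** All features ON; all items fused (when ρ > 0) with
assignments from a sequential posterior-predictive CRP pass, followed
by three assignment-only consolidation passes before the first fusion
move. The direction matters: a discordant item can always unfuse on its
own, but with many informative features fusion cannot nucleate from an
unfused start, because a freshly fused cluster is too small for its
predictive to compete with large established clusters. The
consolidation passes dissolve the splinter clusters a single sequential
pass leaves, which would otherwise trigger spurious unfusing in the
first sweep.

**Protocol.** Default 50 chains of 10,000 iterations (5,000 burn-in),
thinned by 10, with chain seeds spawned from one master seed. Multiple
chains provide cross-chain standard deviations of fusion
probabilities, feature probabilities and cluster counts — a direct
mixing diagnostic. The chain length and burn-in are configuration, not
claims about any particular data set; the scaled-down validation runs
in this repository use 5 chains × 2,000 iterations (burn-in 1,000),
which the simulation results show is sufficient at 156 items × 400
features per data type.

## Posterior summaries

* **Posterior similarity matrix**: per sample and data type, two items
  co-cluster when they share a cluster in that type's view (a fused
  item's single cluster serves both views); the indicator is averaged
  over the two types, then over samples.
* **Fusion / selection probabilities**: posterior means of the
  indicators, with cross-chain SDs.
* **Consensus partition**: average-linkage hierarchical clustering on
  1 − PSM; the dendrogram cut minimising the Binder loss (equal
  misclassification costs) is returned, ties toward fewer clusters.
  This gives a deterministic point partition without a *k* input.
* **Cluster-count posterior**: per sample, the number of clusters in
  each data-type view (averaged over the two views) and the number of
  clusters holding fused items; both reported as normalised histograms.
* Thresholded calls (fused if posterior probability > 0.5; feature
  rejected if < 0.5) are configuration parameters.

## Synthetic data

The generator emulates a two-layer validation design:

* `generate_base(n_items=106, n_features=200, k=5, separation=0.9)` —
  a clustered three-level matrix standing in for a real copy-number
  signal matrix (that matrix belongs to an external cohort, so a
  parametric stand-in preserves the design without a download). Items
  split into near-equal clusters; each (cluster, feature) has a
  uniformly drawn dominant level emitted with probability
  `separation + (1 − separation)/3`, the rest uniform. `separation`
  0.9 gives strongly separated clusters while leaving per-item noise;
  1.0 gives within-cluster-constant columns.
* `build_fusion_simulation(..., n_noise_items=50, n_noise_features=200)`
  — both data sets copy the base (signal items concordant, hence fused
  by construction); each noise item resamples a signal row with
  replacement, independently per data set (unfused except when both
  sources share a base cluster); each noise feature is a column
  resampled with replacement from the pooled base values (correct
  global level distribution, no cluster structure; a per-column
  resampling mode is available as a flag).

The closed-form expectation for coincidentally fused noise items is
n<sub>noise</sub> Σ<sub>k</sub>(s<sub>k</sub>/n)² — 10.0 for 50 noise
items over five equal clusters.

What the generator does *not* emulate: real probe-level correlation
structure along the genome, feature-feature dependence within a
cluster (the naive-Bayes assumption is exactly true here), unequal
cluster separations, and measurement artefacts. Passing the simulation
checks therefore demonstrates correct inference under the model's own
assumptions and the stated construction — not robustness to their
violation on real arrays.

## Preprocessing

Two standard feature-extraction paths from continuous log2-ratio
matrices:

* **probe-centric**: each expression probe matched to the nearest
  copy-number probe on its chromosome (many-to-one allowed; distance
  ties to the lower coordinate); Pearson correlation per matched pair
  across items; Benjamini–Hochberg adjustment across all pairs; a
  copy-number probe is kept when any of its pairs has adjusted
  p < 0.1. A generic keep-top-N-by-score hook stands where a
  survival-based ranking would plug in.
* **gene-centric**: per gene, copy number is the per-item median over
  the gene's probes and expression is the single probe most correlated
  with that median profile; genes with probes in only one data type
  are excluded; the same adjusted-p filter applies gene-wise.

Discretisation: expression by global quantiles (top/bottom q = 0.10 →
over/under; a per-feature mode is a flag; boundary values go to the
extreme level, linear-interpolation quantiles); copy number by
symmetric log-ratio thresholds ±0.2 — a simple threshold caller in
place of a segmentation/mixture-model caller, adequate for already
normalised ratios and exposed in configuration.

## Numerical choices and edge cases

* Log-space throughout; log-gamma tables precomputed for every integer
  tally plus β (feature sweep) and direct `log` on gathered counts
  (assignment sweep).
* Categorical sampling via cumulative sums of shifted exponentials;
  cluster labels compacted by moving the last cluster into the freed
  slot.
* ρ or q at 0/1 short-circuit their conditionals exactly; an empty
  draw set makes the concentration conditional the prior.
* Missing values are rejected at load time; the model has no missing
  mechanism.
* Degenerate inputs raise: constant matrices in quantile
  discretisation, fewer than 3 items in correlation testing, duplicate
  labels anywhere.

## Known limitations

* Exactly two data types; three-level calls only.
* Single-site moves: no split-merge. The fused initialisation is the
  practical answer to the fusion-nucleation barrier; pathological data
  could in principle still trap a chain, which the multi-chain
  dispersion would reveal.
* The consensus partition is restricted to cuts of one average-linkage
  dendrogram (standard, deterministic, but not a global Binder
  optimum).
* The threshold copy-number caller ignores segment structure along the
  genome.
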