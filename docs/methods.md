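# Methods

## Scope and data model

The pipeline consumes a feature × individual FPKM matrix with two
annotations: each feature is a `lncRNA` or an `mRNA`, and each
individual belongs to one of exactly two environments (`env1` is the
reference/native site, `env2` the transplant/stress site). FPKM
computation from reads is out of scope; the matrix is the input. All
tabular I/O is TSV with a header row; sequences are FASTA.

## Population statistics

Per feature and environment we compute the expression level
`E_p = mean(E_i)`, the expression diversity
`E_d = sum(|E_i − E_p|) / ((n−1)·E_p)` and the expression frequency
(fraction of individuals with FPKM strictly above the detection
threshold, default 0). Properties relied on downstream:

- `E_d` is scale invariant and bounded in [0, 2]; it is reported as
  undefined (NaN) when `E_p = 0` rather than coerced to a number.
- "Expressed" means FPKM strictly greater than the threshold; the
  threshold is configurable because FPKM pipelines differ in their
  noise floor.
- The population frequency filter (default: keep features expressed in
  at least 20 individuals) pools both environments; a per-environment
  variant exists but is off by default.

Between-environment ratios are oriented env2/env1. The `E_p` ratio
applies an additive pseudocount (default 0.01 FPKM) to numerator and
denominator **only when either level is zero**, so well-defined ratios
are exact; `E_d` ratios use no pseudocount and propagate NaN when either
`E_d` is undefined or zero. Fold thresholds ("more than 2-fold",
"larger than 1.5") are strict inequalities throughout.

## lncRNA screening

A transcript is a candidate lncRNA iff its length is strictly greater
than 200 bp and its longest open reading frame is strictly shorter than
150 bp. The ORF scan covers all six frames (both strands; a
single-strand mode exists); an ORF is ATG…in-frame stop with no internal
in-frame stop, counted in nucleotides including the stop codon, and a
start with no downstream in-frame stop does not count — assembled
transcripts are treated as complete. Codons containing N never match a
start or stop, and N is excluded from both terms of the GC fraction.
The length rule is applied before the ORF rule, and the rejection reason
records the first failed rule. Coding-potential classifiers and
homology screens against ncRNA databases are deliberately outside this
package's scope; the ORF rule is the implemented coding filter and every
pipeline run report declares this deviation.

## Differential expression

Per feature, environment 1 vs environment 2, two-sided. The test is
chosen adaptively: Student's t (Welch) when both groups pass
Shapiro–Wilk at α = 0.05, otherwise the Wilcoxon rank-sum
(Mann–Whitney) test; constant groups always fall to the rank test, and
two identical constant groups are reported with p = 1 and a NaN
statistic (the conservative contract for untestable features).
Benjamini–Hochberg adjustment runs within each feature class by default
— mirroring separately reported lncRNA and mRNA counts — with pooled
adjustment behind a flag; the adjustment itself is delegated to
statsmodels and cross-checked in the tests against an independent
step-up implementation. A feature is called `up` when FDR < 0.01 and
its `E_p` ratio ≥ 2, `down` when FDR < 0.01 and ratio ≤ 1/2. The fold
filter uses population means rather than paired per-individual ratios
because individuals are not paired across environments. Features whose
`E_d` ratio changes more than 2-fold (both directions by default, the
one-sided variant is a flag) form the "diversity responsive" set;
features with undefined ratios are excluded and tallied.

## Co-expression networks

All (lncRNA, mRNA) pairs among features whose `E_d` exceeds 0.6 in at
least one environment (the gate bounds the all-pairs cost; the paperless
choice of "at least one environment" is this package's reading — a
feature diverse in either site can carry signal there; an override
removes the gate). Spearman coefficients use average ranks on ties and
are computed as standardized-rank inner products, vectorised over all
pairs per environment. p-values use the t approximation, with exact
rank-permutation enumeration when an environment has ≤ 9 individuals
and the vectors are tie-free. Zero-variance features produce NaN
coefficients — reported missing, never fabricated.

Classification schemes (a significance gate, default p < 0.001, applies
before any rule):

| scheme | rule |
|---|---|
| `robust` | R > 0.9 in both environments |
| `robust_strict` | R > 0.95 in both |
| `specific_0.95_0.7` | R > 0.95 in one, < 0.7 in the other |
| `specific_0.95_0.1` | R > 0.95 in one, < 0.1 in the other |
| `responsive` | \|R\| > 0.7 in exactly one, \|R\| < 0.5 in the other |

The first four operate on signed R, the responsive rule on |R| with the
sign recorded; both conventions are switchable, since which convention
produced the published tables is not stated. The `robust_strict` set is
nested in `robust` by construction, and the tests assert it. The
environment-responsive network first restricts features to
`E_d` ratio > 1.5 (diversity grew in the stress environment — a
one-sided gate by design) and uses a p < 0.05 gate matching the
methods-level rule. Hub sub-networks keep edges incident to nodes whose
bipartite degree strictly exceeds the cutoff, returning connected
components largest-first.

## Trait association

Per gene, the all-combinations ratio matrix
`M[i, j] = (FPKM_env2_i + 0.01) / (FPKM_env1_j + 0.01)`; genes with
median FPKM of 0 are ineligible. The same construction on the trait
vector (no pseudocount; traits are continuous and nonzero) yields the
trait matrix. The Mantel statistic is the Spearman correlation of the
two row-major-flattened matrices — flattening order affects nothing
statistically but is fixed for bit-reproducibility. The permutation
null shuffles the environment-2 (row) labels of the gene matrix only:
this breaks the gene–trait linkage while preserving each matrix's
marginal structure, which is standard Mantel practice; which labels the
original analysis permuted is not stated, so this is a declared package
choice, as is the two-sided comparison on |rho|. The p-value is the
add-one estimator `(1 + k)/(B + 1)` (never exactly zero), candidates at
p < 0.01. A useful implementation fact: row permutation only reorders
the flattened entries, so ranks are computed once and re-indexed,
making 1,000–10,000 permutations per gene cheap. The trait network
links lncRNAs to candidate genes at pooled-individual |Spearman| ≥ 0.7
(pooling both environments matches the network's cross-environment
purpose; a per-environment mode exists) and keeps hub lncRNAs with
degree strictly greater than 5.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
on the log scale: for feature *f*, individual *i* in environment *e*,

```
log FPKM = mu_f + s_f·Δ·[e = env2] + z_{m(f), e, i} + eps
```

- `mu_f ~ N(baseline_log_mean, feature_log_mean_sd²)` — between-feature
  spread of baselines (natural-log FPKM units).
- `eps ~ N(0, sd_class²)` with `sd_lncRNA ≥ sd_mRNA` — drives the
  higher `E_d` of lncRNAs.
- Planted fold changes: a fraction `frac_DE` of features receives a
  signed log2 effect `Δ = de_log2fc·ln 2` in env2.
- Diversity inflation: a disjoint fraction gets its env2 noise sd
  multiplied by `diversity_inflation_env2`, emulating diversity growth
  in the stress site.
- Modules: disjoint sets of lncRNAs and mRNAs share a latent
  `z ~ N(0, module_latent_sd²)` per individual — in both environments
  (shared scope) or in exactly one (environment-specific scope).
- Dropout is detection-limit censoring: FPKM is recorded as 0 when
  log-FPKM falls below the class detection threshold, set at the
  `dropout_prob` quantile of the class's reference marginal. Censoring
  ties zeros to low expression the way FPKM zeros arise in practice,
  produces a realistic spread of per-feature expression frequencies,
  and keeps planted shifts detectable by rank tests; expression-
  independent Bernoulli zeroing was rejected because at lncRNA-realistic
  rates it caps the rank-test effect size below what any fold change can
  overcome.
- The trait is a unit-loading sum of `log(FPKM + 0.01)` over
  `n_trait_genes` consistently detected mRNAs carrying no other planted
  signal, plus `N(0, trait_noise_sd²)` noise. Plants are pairwise
  disjoint (DE, diversity, modules, trait genes) so each can be scored
  in isolation; in particular the closed-form expectation
  `E[log2 E_p ratio] = ±de_log2fc` holds exactly for uncensored DE
  features (censoring adds a tractable Φ-factor bias, so the
  closed-form check in the tests runs at dropout 0).

One global seed feeds `numpy.random.SeedSequence(seed).spawn`, with one
child stream per stage (expression, sequences, trait), so any stage can
be regenerated independently and all outputs are bit-reproducible.

Transcript sequences are uniform over A/C/G/T conditioned on a target
GC. Coding sequences embed a forward-strand ORF of ≥ 150 nt (start,
non-stop codons, stop) at a random offset. Noncoding sequences are
screened: any chance six-frame ORF reaching 150 nt is disrupted by
mutating a randomly chosen codon of the offending ORF into a stop,
iterating until clean — unlike rejection sampling this terminates at
any sequence length (a fixed mutation position can oscillate when ORFs
on opposite strands overlap, hence the random position).

### Default conditions

| parameter | default | meaning |
|---|---|---|
| `n_individuals_per_env` | 40 | two sites, 80 individuals total |
| `n_lncRNA` / `n_mRNA` | 600 / 900 | desk-scale feature mix |
| `baseline_log_mean` | 1.0 | median FPKM ≈ e ≈ 2.7 |
| `feature_log_mean_sd` | 1.0 | between-feature baseline spread |
| `baseline_log_sd_mRNA` | 0.6 | within-environment mRNA noise |
| `baseline_log_sd_lncRNA` | 0.9 | larger spread → higher lncRNA `E_d` |
| `dropout_prob_mRNA` | 0.05 | marginal non-detection rate |
| `dropout_prob_lncRNA` | 0.25 | → lower lncRNA expression frequency |
| `frac_DE` | 0.10 | fraction with a planted environment effect |
| `de_log2fc` | 2.0 | planted 4-fold change, sign random |
| `frac_diversity_inflated` | 0.25 | fraction with env2 variance growth |
| `diversity_inflation_env2` | 1.8 | multiplicative sd factor in env2 |
| `n_modules_shared` / `env_specific` | 2 / 2 | planted co-expression modules |
| `module_size_lncRNA` / `mRNA` | 5 / 8 | members per module |
| `module_latent_sd` | 5.0 | latent dominates noise → pair R ≳ 0.9 |
| `n_trait_genes` | 5 | mRNAs driving the trait |
| `trait_noise_sd` | 0.5 | trait measurement noise |

The class parameters were fixed once so that the three class contrasts
(level, diversity, frequency) hold and the planted structures are
recoverable at the analysis' own thresholds across consecutive seeds;
`module_latent_sd` must dominate the member noise because a pair's
correlation is `σ_z²/(σ_z² + σ_ε²)` and the robust rule demands
R > 0.9.

### What the generator does not emulate

No read-level simulation (FPKM is the unit), no alternative splicing or
assembly chimeras, no length/GC covariance with expression, no
population genetic structure among individuals, and dropout is a single
per-class detection limit rather than a per-sample one. Passing tests
therefore demonstrate correctness of the statistics and recoverability
of planted structure under a lognormal model — not that real tissue
data satisfies that model.

## Numerical choices

- Zero-variance groups: tests skipped, p = 1, flagged.
- Spearman: average ranks on ties; exact permutation p only for n ≤ 9
  without ties, else the t approximation.
- BH adjustment guarantees `fdr ≥ p` and monotonicity after sorting.
- Undefined values (NaN) propagate; they are never silently replaced.
- The pipeline derives per-stage seeds from one global seed and writes
  every stage's outputs before the next starts; identical config + seed
  gives byte-identical TSV outputs (asserted end-to-end in the tests,
  excepting the wall-clock fields of the run report).

## Problem sizes in tests and the acceptance script

The test suite runs the calibration experiments at the study's design
scale — 2,000 features × 40 individuals per environment across 20 seeds
for DE calibration, 200 genes × 1,000 permutations for Mantel null
uniformity, 5 seeds for trait-gene recovery — and desk scale (≈ 150
features, 15–20 individuals per environment) for end-to-end and I/O
checks; the whole suite completes in about a minute. The acceptance
script runs the full default conditions with 1,000 Mantel permutations
per gene.

## Known limitations

- The adaptive t/Wilcoxon choice inherits Shapiro–Wilk's behaviour at
  n = 40; heavily tied data (many zeros) always routes to the rank test.
- The `E_d` statistic saturates at 2, so strongly dispersed features
  cannot show large `E_d` ratios — a property of the statistic, visible
  in the recovery experiments.
- Exact Spearman p-values are enumerated only for n ≤ 9; environments
  of 10–30 individuals rely on the t approximation, which is slightly
  anticonservative in the extreme tail.
- The Mantel screen treats genes independently; no multiplicity
  correction is applied across genes (candidates are defined by the
  per-gene permutation p, matching the procedure it implements).
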