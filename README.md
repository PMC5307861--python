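# lncpop

Population-scale comparison of long non-coding RNAs (lncRNAs) with
protein-coding mRNAs across two environments: sequence-rule candidate
screening, population expression statistics, differential expression,
environment-robust vs environment-specific co-expression networks, and
quantitative-trait association — with a synthetic-data generator that
plants known signals so every stage can be scored against ground truth.

## Who this is for

Plant and population transcriptomics groups analysing a feature ×
individual FPKM matrix collected in two environments (for example a
common-garden transplant design with ~40 individuals per site), who want
to ask: are lncRNAs regulated more loosely than mRNAs, which features
respond to the environment, which lncRNA–mRNA relationships are robust
versus environment-specific, and which genes track a measured trait such
as water use efficiency (WUE)?

## The statistics at the core

For a feature with FPKM values $E_1,\dots,E_n$ over the $n$ individuals
of one environment:

- **Population expression level** $E_p = \frac{1}{n}\sum_i E_i$.
- **Expression diversity**
  $E_d = \frac{\sum_i |E_i - E_p|}{(n-1)\,E_p}$ — a dimensionless,
  scale-invariant dispersion (mean absolute deviation normalised by the
  level), bounded by $0 \le E_d \le 2$.
- **Expression frequency** — the fraction of individuals with FPKM
  strictly above a detection threshold (0 by default).

Between-environment change is summarised by the env2/env1 ratios of
$E_p$ and $E_d$ and the difference of frequencies. Differential
expression combines a per-feature two-sample test (t when both groups
pass Shapiro–Wilk normality, Wilcoxon rank-sum otherwise) with
Benjamini–Hochberg FDR < 0.01 and a 2-fold $E_p$-ratio rule.
Co-expression pairs are classified by per-environment Spearman
coefficients (robust: $R > 0.9$ in both environments;
environment-specific: high in one, low in the other). Trait association
builds, per gene, the all-combinations ratio matrix
$M_{ij} = \mathrm{FPKM}_{i}^{(2)} / \mathrm{FPKM}_{j}^{(1)}$
(environment-2 individual $i$ over environment-1 individual $j$), the
same matrix for the trait, and tests their flattened Spearman
correlation against a permutation null that shuffles the gene matrix's
rows (10,000 permutations by default; candidates at $p < 0.01$).

lncRNA candidates are transcripts longer than 200 bp whose longest open
reading frame over all six frames is shorter than 150 bp, retained only
when expressed in at least 20 of the 80 individuals.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
bundled generator (large intermediates go to `scratch/`, summaries to
`results/`):

```bash
cd analysis
python 01_simulate_population.py
python 03_population_stats.py
python 04_differential_expression.py
```

which prints, for the default conditions (600 lncRNAs + 900 mRNAs,
40 individuals per environment, seed 0):

```
simulated 1500 features x 80 individuals -> .../scratch/analysis/data
planted: 150 DE features, 52 module members, 5 trait genes
env1: median E_d lncRNA 0.766 > mRNA 0.483 (p=8.85e-170); median freq lncRNA 0.875 < mRNA 1.000 (p=5.71e-91)
env2: median E_d lncRNA 0.847 > mRNA 0.527 (p=2.41e-89); median freq lncRNA 0.825 < mRNA 1.000 (p=2.37e-73)
DE calls: {'lncRNA': {'up': 34, 'down': 14}, 'mRNA': {'up': 50, 'down': 47}}
recovery of planted signals: recall 0.986, FDP 0.007
```

Read: lncRNAs show higher expression diversity and lower expression
frequency than mRNAs in both environments (the two population contrasts
the analysis is designed around), and the FDR + fold-change caller
recovers 98.6% of the planted 4-fold signals with a 0.7% false-discovery
proportion. `05_coexpression_networks.py` and `06_trait_association.py`
continue with network classification and the Mantel trait screen.

The same stages are available as a CLI (`lncpop simulate`,
`filter-lncrna`, `popstats`, `diffexp`, `network`, `wue`, `run`); see
`lncpop --help`.

## Layout

- `src/lncpop/` — library: `simulate`, `sequence_qc`, `popstats`,
  `diffexp`, `networks`, `trait_assoc`, `io`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — model, parameter and design documentation.
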