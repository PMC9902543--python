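# Methods

This note documents the statistical model behind `diaquant`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Data model and pipeline order

The quantification unit is the **precursor** (a charged peptide species,
quantified per MS run on a linear scale); several precursors map to one
**protein group**, kept as a verbatim string key throughout — no
re-grouping, no accession splitting, and multi-accession groups
(`;`-separated) pass unchanged into annotation matching.

The stage order is fixed and recorded in the manifest:

    log2 → quantile normalization → min-observation filter → imputation
         → precursor t-tests → protein roll-up → BH → flags

Rationale: imputation must produce values on the normalized scale, and
filtering must count *real* observations, so both follow normalization and
precede testing. Row filtering uses pre-imputation observation counts
pooled over all conditions of the compartment; precursors surviving the
filter are tested in every comparison (no per-comparison re-filtering).

## Stage semantics and parameters

**Quantile normalization** (per compartment, observed entries only).
Within each run, observed values are ranked; the reference distribution is
the mean across runs of each run's sorted observed values at matched
quantiles, with type-7 linear interpolation where observed counts differ.
Ties within a run receive the mean of the reference values they span.
Missing entries are untouched. With complete data this reduces to classic
quantile normalization (identical sorted columns afterwards).

**Minimum observations** — `min_runs` (default **5**): a precursor seen in
fewer runs than this across the compartment is dropped, i.e. precursors
observed in ≤ 4 runs are excluded.

**Imputation** — `center_quantile` (default **0.001**) and `sd` (default
**0.2** log2 units): missing entries are independent draws from
N(q, sd²) with q the global `center_quantile` quantile of *all* observed
entries of the compartment matrix. "Global" pooling (rather than per run or
per precursor) is the simplest consistent reading of an experiment-wide
detection floor; a per-run variant would be a straightforward extension but
is not claimed to be equivalent. The Gaussian family is the established
left-censored ("low-abundance downshift") imputation model.

**Testing**: two-sided pooled-variance Student *t* per precursor and
condition pair, each group needing ≥ 2 runs. Zero pooled variance is
resolved explicitly: p = 1 when the group means agree, p = 0 (flagged
degenerate) otherwise. log2FC is test − reference; the study design's
reference is the bleomycin-alone arm (B), and a `flip_sign` switch
reverses the orientation for workflows that report reference − test.

**Roll-up**: protein log2FC and p are arithmetic means of the member
precursors' values. Averaging p-values is *not* a calibrated combination
rule (it is conservative relative to Fisher's or Stouffer's method and has
no uniform-null guarantee after averaging); it is implemented literally as
the pipeline's summary statistic, and the null-calibration test shows the
single-precursor case — where the mean is the identity — is well
calibrated. Treat multi-precursor protein p-values as a ranking heuristic
that BH then thresholds.

**FDR and flags**: BH step-up within each comparison × compartment family
(adjusted values capped at 1, ties sharing their rank value). `regulated`
/`significant` ⇔ |log2FC| ≥ 1 AND adjusted p ≤ 0.05, both inclusive.
Whether correction should instead pool all comparisons jointly is a
defensible alternative; per-comparison families match how per-comparison
protein lists are reported.

**Clustering**: rows of the profile matrix are proteins regulated in ≥ 1
included comparison *and* quantified in all of them (Euclidean distance
needs complete vectors); entries are raw log2FCs, deliberately not
standardized — the profiles live on a common, meaningful scale. Similarity
is defined literally as 1 − Euclidean distance (negative beyond distance
1). The partitioner is Lloyd k-means, best of `restarts` (default 25)
initializations; the gap statistic uses W_k = Σ_clusters (within-cluster
pairwise squared distances)/(2·size) — equal to the centroid sum of
squares — with B (default 100, ≥ 10 enforced) reference datasets drawn
uniformly over each column's observed range (the simpler Tibshirani
reference, no PCA rotation) and the 1-SE rule: the smallest k with
gap(k) ≥ gap(k+1) − s(k+1), falling back to `k_max`. Combined
(cross-compartment, columns = compartment:comparison) and per-compartment
profile matrices are both supported; combined is the default and restricts
rows to proteins quantified in every compartment.

**Over-representation**: one-sided hypergeometric upper tail P(X ≥ k) by
default ("over"); a two-sided Fisher exact option covers combined
over/under-representation. The background defaults to all proteins covered
by the MS analysis of the same compartment; the annotation table (GMT or
TSV) is user input and carries no ontology-release claim. BH across tested
terms, consistent with the rest of the pipeline.

## Synthetic experiments

`SimConfig` defaults emulate the study structure: cohorts B:5, BTH:5,
DEX:4, TH:4, V:4 (22 runs per compartment); precursors per protein
geometric with mean 5 truncated to [1, 30]; baseline log2 intensity
N(14, 2.5²); per-run offsets N(0, 0.3²); residual noise N(0, 0.25²);
10 % regulated proteins at |effect| = 2 (sign drawn independently per
non-reference condition, so regulated proteins carry an effect in every
comparison); logistic left censoring with midpoint 9 and slope 1.5 on the
log2 scale followed by 2 % uniform dropout. Noise and missingness
magnitudes are package choices of plausible DIA behavior, not estimates
from any particular dataset. Effects are identical across a protein's
precursors — exactly the additivity the mean roll-up assumes.

What passing tests show: the pipeline recovers known effects (RMSE ≈ 0.11,
sensitivity 1.0 on complete 5 v 5 data at |log2FC| = 2), is calibrated
under the null, selects planted cluster numbers, and is bytewise
reproducible. What they do not show: robustness to peptide-specific
(interference, miscleavage) effects, correlated noise, retention-time
drift, or search-engine identification errors — none of which the
generator emulates. Under the generator's default censoring the pipeline's
sensitivity drops to ~0.5 at these sample sizes because imputation
attenuates fold changes of poorly detected proteins; that attenuation is a
property of the method itself and is reported honestly by
`truth_evaluation`.

One simulator check deviates from a literal all-defaults reading: the
"null group-mean differences center at zero" law-of-large-numbers test
disables per-run offsets, because offsets shared by all precursors of a
run do not average out across precursors (they contribute ±0.19 to the
grand mean at 5 v 5); removing run-scale offsets is the normalization
stage's job, which the normalization contract tests cover.

## Numerical and reproducibility choices

- Quantiles use the type-7 (linear interpolation) convention everywhere.
- A single pipeline seed spawns per-stage substreams (imputation, gap
  reference, k-means) via `numpy` `SeedSequence`, so stages can be re-run
  in isolation from the manifest; k-means seeds are reduced mod 2³¹.
- Cluster ids are renumbered 1..k by first appearance down the sorted
  profile rows, making labels independent of k-means' internal ordering.
- Result tables are sorted (compartment, comparison, protein_group) with
  floats fixed at 6 decimals; identical config + seed ⇒ byte-identical
  outputs. The JSON manifest records parameters, substream seeds, and
  per-stage row counts.
- Overlap percentages round to the nearest integer of the union total.

## Validation scale

Test and acceptance workloads are sized for a single-CPU desk run: null
calibration and effect recovery use 2,000 proteins; gap-statistic recovery
uses 100 replicates of 150 four-dimensional profiles with k_max 6, B = 20
and 5 restarts; the end-to-end determinism check uses a 22-run, ~10,000
precursor experiment with k_max 8 and B = 20. These sizes are the
package's validation defaults; analysis defaults (k_max 12, B = 100,
25 restarts) remain the larger values above.

## Known limitations

- Mean-of-p roll-up has no formal error-rate guarantee at the protein
  level for multi-precursor proteins (see above).
- Quantile normalization assumes broadly similar intensity distributions
  across runs; strong global regulation violates this and slightly
  attenuates large effects.
- The gap statistic with a uniform reference tends to prefer k = 1 for
  profile clouds without pronounced substructure; this is by design of the
  1-SE rule, not a failure mode.
- No moderated-variance testing, covariate models, or MaxLFQ-style
  share-based quantification; these are out of scope.
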