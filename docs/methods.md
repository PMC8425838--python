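# Methods

This note documents the statistical procedures implemented in `sevmir`, the
defaults and their rationale, what the synthetic generator does and does not
emulate, and the decisions taken where the underlying assay conventions are
genuinely open.

## Sample quality control

Per sample, three metrics are computed from the raw count matrix:

* **total reads** — column sum; fail below `min_total_reads` (default 10⁶).
* **spike fraction** — reads on positive-control probes divided by total;
  fail at or above `max_spike_fraction` (default 0.10). The comparator is the
  conservative `>=`: a sample exactly at 10% is removed.
* **CV** — sd/mean (ddof 1) of the sample's **housekeeping-probe counts**;
  fail at or above `max_cv` (default 0.15). Which counts the CV filter should
  be computed over is an assay convention rather than a published rule; the
  housekeeping probes are the panel's intended invariant signal, so a noisy
  housekeeping profile marks a degraded sample. The probe class is
  configurable (`cv_probe_class="positive_control"`), and the definition is
  echoed into every run report.

Dropping failed samples refuses to leave any group with fewer than two
members, because two-group inference downstream would be impossible.

## Normalization

TPM divides each count by its probe length in kilobases and rescales every
sample to sum to 10⁶. Positive-control spikes are excluded from both the
numerator set and the scaling denominator — their abundance is an assay
design choice, not biology, and would distort the compositional scale.
Probe lengths default to 1.0 kb (nuclease-protection probes are uniform, so
TPM ≡ CPM); a `length_kb` column in the annotation is honored when present.
Column sums equal 10⁶ to relative tolerance 1e-9, TPM is invariant to
rescaling a sample's counts, and with unit lengths TPM equals counts per
million — all three are asserted by property tests.

Log transformation is log2(TPM + pseudocount) with pseudocount 1.0 by
default; 0 is allowed only when no zeros are present. The low-expression
filter removes a probe when **all** samples in both groups are below 1 TPM
(default), or when **any** sample is (the stricter variant, selectable with
`mode="any_sample_below"`); both rules circulate in panel reports, so both
are implemented and the mode used is recorded. Housekeeping probes are never
removed — they anchor the downstream normalization.

## Presence–absence

A miRNA is present in a group when the minimum TPM over the group's
QC-passed replicates is ≥ the threshold (default 1.0, comparator inclusive).
Presence is computed on the full probed universe *before* the low-expression
filter, since detected/not-detected is a statement about the whole panel.
Housekeeping and positive-control probes are kept out of the miRNA Venn
counts and reported separately. Presence is monotone in the threshold, and
`common + unique(g) = |present(g)|` for each group; both are tested.

## Differential expression

**Normalization.** Every probe's TPM is divided by the geometric mean of the
housekeeping probes in that sample (the "aggregate housekeeping" scale).
After this step the housekeeping aggregate is exactly 1 in every sample. The
pipeline applies a pseudocount of 1 TPM before the ratio so that zeros
survive the log.

**Fold change** is the ratio of group geometric means, computed as
`2**(mean log2 case − mean log2 control)` on the normalized values. The
orientation is case/control, and FC(case/control)·FC(control/case) = 1
exactly.

**Test statistic.** Welch *t* on the log2 normalized values. With four
animals per group an equal-variance assumption is not defensible; Welch
costs little under equal variances and is robust otherwise. Two-sided
p-values use |t|.

**Permutation schemes.** Three are implemented:

* `exhaustive` — all C(n₁+n₂, n₁) group-label assignments are enumerated per
  probe; p = #{|T*| ≥ |T_obs|}/C. The identity assignment is in the
  enumeration, so p > 0, and p lives on the grid k/C (at 4 vs 4, C = 70 and
  the smallest achievable p is 1/70; complete separation gives 2/70 because
  the mirror assignment ties the observed |t|).
* `monte_carlo` — B random assignments with the add-one correction
  p = (1 + #{|T*| ≥ |T_obs|})/(B + 1).
* `pooled` (pipeline default) — all C assignments are computed for every
  probe and the |T*| values of **all probes** are pooled into one common
  null; a probe's p is the upper-tail fraction of its observed |t| in the
  pool. This is the standard small-n genomics device (as in
  significance-analysis-of-microarrays): the per-probe exhaustive floor of
  1/70 ≈ 0.014 sits *above* the 0.01 calling threshold, so a per-probe test
  can never call anything at 4 vs 4, whereas pooling across ~2,000 probes
  buys resolution of 1/(70·n_probes) ≈ 7×10⁻⁶. Under a global null with
  exchangeable samples and independent probes, the expected fraction of
  probes with pooled p < α equals α regardless of heterogeneity between
  probes' null distributions (the pool is exactly the mixture of the
  per-probe permutation distributions); the test suite verifies this
  calibration empirically over 20 simulation replicates.

Probes that are constant across all samples get p = 1 with a warning.
Assignments with zero variance in both groups yield t = 0 on ties and ±∞
otherwise. Tail counting uses a relative tolerance of 1e-12 on |T_obs| so
that mirror assignments tie with the observed one despite last-ulp float
noise.

**Calling.** A probe is DE when p < α (default 0.01) and FC ≥ fc_min or
FC ≤ 1/fc_min (default 2.0). Benjamini–Hochberg adjusted p-values are
reported alongside but are not used for calling by default (`call_on="p_adj"`
switches). The BH family is the miRNA-class probes only; housekeeping probes
remain testable and reportable but carry `p_adj = NaN` rather than competing
in the multiplicity family.

**Clustergram.** Samples are clustered by average linkage on
1 − Pearson r between their log2 expression columns. Leaf order is made
deterministic by placing, at every merge, the subtree with the smaller
minimum original index first. Trees are serialized as Newick with
ultrametric branch lengths (node height = half the merge distance, so the
leaf-to-leaf path length equals the cophenetic distance). A constant sample
column is an error (its correlation is undefined), reported by name.

## Cytokine panel

Censored (below-LLOQ) wells are imputed at the analyte's LLOQ — the
convention for multiplex immunoassays when a value is detected but not
quantifiable; it biases differences toward zero rather than inventing
signal. Concentrations are divided by each sample's total protein (mg/mL) to
give pg/mg. Group differences use the two-tailed Welch *t* (from raw values
when available; an algebraically identical summary-statistics path
`welch_from_summary` is exposed for published tables that print only mean,
SD, n, and the two paths agree to 1e-12 by property test). BH adjustment is
applied within each assayed fraction separately (each fraction's panel is
its own 23-test family); a config option pools the families. The BH step-up
is implemented directly because an `m` override (reported subset of a larger
tested family) is needed; it is cross-checked against
`statsmodels.stats.multitest` in the tests. Note BH-adjusted values are not
a fixed point of the procedure — re-adjusting adjusted values changes them —
so no idempotence is claimed.

The hind-paw weight-bearing ratio 2R/(R+L)×100% and the pooled-variance
Student *t* (used for vesicle characterization comparisons) are included as
small utilities.

## Cross-cohort name harmonization

Names are lowercased and a known miRBase species prefix (hsa-, mmu-, rno-,
…) is stripped; the arm suffix (-5p/-3p) is kept. The default `strict`
policy requires arm equality — merging the two arms of one hairpin would
conflate distinct mature sequences, and a false merge is worse than a miss.
The `relaxed` policy lets an arm-less legacy name match either arm. Matching
is name-level only; no sequence or accession resolution is attempted, so
renamed miRNAs in very old cohorts will not match. Overlap counts are
invariant to duplicates and, under `strict`, symmetric in query/reference.

## Target consolidation and enrichment

A gene is a consolidated target when at least one query miRNA predicts it
with score strictly above the threshold (default 0.9) *and* at least one
query miRNA has validated evidence for it. Over-representation per gene set
is the one-sided upper-tail hypergeometric probability P(X ≥ k) with
population N (background), K term genes, n query genes, followed by BH FDR
across tested terms (significant below 0.05). The background defaults to the
collection's explicit universe or, failing that, the union of all term
genes; the end-to-end pipeline uses the union of gene-set and target-table
genes, since the GMT dialect cannot carry an explicit universe. Background
genes in no term influence results only through N. Term relatedness is
reported as a shared-gene graph (edge weight = number of shared member
genes) and an average-linkage dendrogram on 1 − Jaccard distance between
member-gene sets, with the same deterministic leaf ordering as the sample
clustergram.

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes:

* **Design**: 5 control / 4 case samples; one control planted to fail the
  spike filter (so the post-QC design is 4 vs 4); ~2,000 miRNA probes, 13
  housekeeping probes, 5 positive-control spikes.
* **Counts**: negative binomial around probe-specific expected proportions
  times a per-sample library size (lognormal around 3×10⁶ reads, σ = 0.1).
  Baseline miRNA abundances are lognormal (σ = 2.5), spanning the dynamic
  range from undetectable (TPM « 1, feeding the presence/filter logic) to
  abundant. Dispersion is 0.05 for miRNA probes and 0.005 for housekeeping
  probes — inbred, age-matched male mice under one protocol put biological
  CV near 20–25%, and housekeeping genes are chosen for stability.
* **Planted DE**: 57 miRNAs (matching the reference study's signature size)
  with fold changes uniform on [2, 6], planted only on probes with baseline
  TPM ≥ 5 — a study's reportable DE miRNAs are by construction detectable in
  all samples. Case-group proportions are renormalized, so the planted fold
  change is preserved *exactly* on the housekeeping-relative scale
  (composition cancels in the ratio).
* **QC failures** are explicit config (`low_reads` forces a library of
  5×10⁵; `high_spike` forces a 15% spike share; `high_cv` inflates
  housekeeping dispersion to 0.25), making QC tests deterministic. All
  housekeeping probes share one expected abundance so the within-sample
  housekeeping CV is a pure noise metric; real panels would first standardize
  per-gene abundances.
* **Cytokines**: 23 analytes (the mouse 23-plex panel), lognormal with
  within-group σ = 0.5, n = 6 control / 8 case. The sEV fraction's case
  medians are shifted ×0.7 (a sub-significance downward trend), the
  sEV-deplete fraction ×2.5 on six inflammatory analytes. At this n and
  ~50% CV a 2.5-fold shift gives only partial power, so per-run significance
  counts vary — faithful to small-n immunoassay panels. LLOQ sits at 0.3× of
  each analyte's baseline median; wells below it are censored.
* **Annotation resources**: predicted targets with scores in [0.5, 1.0] and
  a validated subset; 30 gene sets of which 10 are enriched for the planted
  DE miRNAs' high-confidence targets; reference signatures that overlap the
  planted DE set by an exactly configured count and carry an "hsa-" prefix
  to exercise harmonization.

What the generator does **not** emulate: probe-specific hybridization
efficiency or GC bias, between-sample batch structure, correlated miRNA
co-regulation (probes are independent given the design), mixed up/down DE
(the planted signature is all up-regulated, as in the reference study), or
raw sequencing reads. Passing recovery tests therefore demonstrate that the
statistics behave correctly under the assumed count model at the study's
n — not that the pipeline is robust to batch effects or annotation errors in
real panels.

All generators are deterministic under a fixed seed (three independent
streams, offset from the config seed, for counts, cytokines and annotation,
so that regenerating one input does not perturb the others).

## Problem sizes and numerical choices

Recovery and calibration statistics are averaged over 20 simulation
replicates at the full panel size (2,000 miRNA probes, 4 vs 4 after QC); at
these sizes the whole suite runs in well under a minute. Measured on the
default conditions: sensitivity ≈ 0.92, empirical FDR ≈ 0.01, and a null
rejection rate at α = 0.01 of ≈ 0.010.

Ties in permutation tail counts are absorbed with a 1e-12 relative
tolerance; hierarchical-clustering ties are broken by the minimum-original-
index rule; top-term selection breaks FDR ties by raw p then term id;
`mergesort` is used wherever a stable order matters. Degenerate inputs
(all-zero samples, constant probes or samples, zero housekeeping values,
empty groups) raise validation errors that name the offending sample/probe,
except where a convention is standard (constant probe → p = 1 with warning;
equal means with zero variance → p = 1).
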