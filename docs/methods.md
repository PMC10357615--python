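# Methods

`amyloprot` re-implements, as a tested library, the statistical core of a
label-free-quantification (LFQ) proteomics analysis of an amyloid (5xFAD-type)
mouse model: from protein-group intensity matrices to a ranked CSF biomarker
candidate. This note documents the models, the defaults and why they were
chosen, what the synthetic world does and does not emulate, and the numerical
choices a maintainer would want to know.

## Study design

The default `StudyDesign` is 2 brain regions (cortex, hippocampus) x 3 ages
(2, 5, 8 months) x 2 genotypes (wild type, transgenic) x 5 animals per cell,
with 2 technical MS replicates per tissue homogenate (3 for the 5-month
hippocampus). Animals are shared between tissues (both regions come from one
mouse); technical replicates belong to one homogenate. Acquisition batches
default to 2 per tissue, assigned round-robin over animals so no batch is
confounded with age or genotype — the original study does not describe its
batch structure, so the batch covariate is a free parameter of the design
rather than an assertion about the real data.

## Reliability filtering (no imputation)

Missing LFQ values are informative (low-abundance proteins drop out of
detection), so nothing is imputed. A protein is *reliable* in a condition when
strictly fewer than half of the condition's samples are missing; the
comparison `2 * n_missing < n_samples` is exact integer arithmetic, so the
odd 15-sample condition behaves deterministically (7 missing reliable, 8 not).
Technical replicates count in the denominator: condition sizes of ~10 match 5
animals x 2 replicates.

The phrase "unreliable in each individual condition" admits two readings. The
default excludes a protein only when it is unreliable in *every* condition of
a tissue; the stricter any-condition reading is available via
`reading="any-condition"`. The default was chosen because the stricter
reading would make the subsequent genotype-pair step (reliable in both
genotypes at one tissue/age) redundant.

The full-model universe keeps proteins reliable in all conditions of both
tissues and intersects the tissues after reconciling protein-group
identifiers. Identifier relations that are many-to-many between the tissue
datasets are dropped (connected components of the bipartite identifier graph);
one-to-many relations are dropped by default and can be kept by policy. This
operates on identifier-set overlap of protein groups, an approximation to
whatever peptide-sharing logic produced the ambiguity in the first place.

## Batch adjustment

Location/scale parametric empirical-Bayes adjustment (the ComBat model) on
log10 intensities, re-implemented to be missing-aware: missing entries stay
missing and are excluded from every estimate. Per protein, values are
standardized by a covariate-protected least-squares fit (condition labels are
protected by default, so biological effects are not absorbed); per-batch
location and scale are shrunk toward moment-matched normal / inverse-gamma
priors with the usual iterative conditional-modes solution (tolerance 1e-8,
max 200 iterations). A batch with fewer than 2 observed values for a protein
falls back to the prior expectation and is counted. A single batch is the
identity; a batch perfectly confounded with a protected covariate level is
refused. On complete data the implementation agrees with scanpy's ComBat to
~1e-4 (a test asserts this), the residual difference being iteration
stopping rules.

## Differential abundance

Per protein, condition means (cell-means coding) are estimated by generalized
least squares with compound-symmetric correlation ρ within blocks, where a
block is one animal-tissue homogenate. ρ is a single consensus value across
proteins — per-protein intraclass correlations (one-way ANOVA within each
condition, pooled sums of squares) are Fisher-z transformed, 10%-trimmed-mean
averaged, and back-transformed. Blocking on (animal, tissue) rather than
animal alone reflects that technical replicates share a homogenate;
correlating an animal's cortex and hippocampus runs would overstate the
replicate structure. ρ = 0 reduces to ordinary least squares exactly.

Residual variances are moderated by closed-form empirical Bayes: prior
degrees of freedom d0 and prior variance s0² come from moment matching on the
log residual variances (digamma/trigamma relations; the trigamma inverse is a
Newton solve to 1e-8). The moderated variance
s̃² = (d0·s0² + d·s²)/(d0 + d) lies between s² and s0²; the moderated t has
d0 + d degrees of freedom. d0 = 0 gives the ordinary t, d0 = ∞ full pooling.
On a complete two-group matrix the whole chain (d0, s0², every t and p)
matches limma's `lmFit`/`eBayes` to ~1e-10 (a test runs the R oracle).

Transgene effects (TG − WT) are estimated per tissue and age; interaction
contrasts compare transgene effects between ages (e.g. `A82TH`) or tissues
(`A5THC`) and their coefficients sum to zero. The pairwise model applies the
same machinery restricted to one (tissue, age) on the pairwise reliability
set, yielding the `DE.<tissue>.Age<k>` families. Benjamini-Hochberg FDR is
computed separately within each contrast; significance is FDR < 0.05.
Proteins that cannot estimate a contrast (a weighted condition entirely
missing) get no row, so downstream counts equal set cardinalities. Effects
are log10 (multiply by 1/log10(2) ≈ 3.32 for log2).

## Aggregate-trajectory classification

Each differential protein's 3-point log-fold-change trajectory over age is
Pearson-correlated with four per-tissue aggregate readout trajectories
(membrane-filter assay, plaque load, 6E10 and ThioS plaque counts; each a
mean over 5 animals per age). Significance is the two-tailed t-test
t = r·√((n−2)/(1−r²)) with n−2 df; with n = 3 the critical |r| at α = 0.05
is ≈ 0.9969. r = ±1 is assigned p = 0 and classified — excluding perfect
correlation would be indefensible. A protein correlated with one readout and
anticorrelated with another is resolved by the smallest p (tie: |r| closest
to 1) and logged as a conflict. Classification uses the 3 per-age mean LFCs,
not per-animal values; a 3-point correlation is intrinsically low-powered,
which matters below.

`plaque_load` implements percent of region volume occupied by plaques,
excluding plaques below 50 µm³ (boundary included).

## Cross-species concordance and signatures

Both translation directions of the ortholog map are combined into a bipartite
symbol graph; one-to-one components are resolved, many-to-many components
dropped, one-to-many dropped by default. A protein is *concordant* when
significant with the same effect sign in ≥ 1 mouse dataset (H5, H8, C8
pairwise families) and ≥ 1 human dataset; the stricter all-datasets-agree
rule is a flag. Sign conflicts are flagged and resolved by the mouse dataset
with the largest absolute effect. Signatures are the top-15 up (Sig+) and
down (Sig−) concordant proteins ranked by largest |mouse log fold-change|
among significant mouse datasets; ties break lexicographically so output is
independent of row order. Human effect sizes keep their native scales — only
signs and ranks cross the species boundary.

## Candidate funnel

Six conjunctive stages over the hippocampus: reliability-filtered universe →
pairwise-significant DEPs → significant in ≥ 1 human dataset (via orthologs)
→ concordant direction → trajectory-correlated AND in the per-age top-25
effect ranking at all three ages → annotation filter (default lysosomal
terms). "Effect size" for the top-25 ranking is read as |moderated t|
(|logfc| is a flag), and "across all three time points" as membership in the
per-age top-25 at every age. Stage outputs and counts are recorded; empty
stages propagate rather than raise.

## CSF biomarker evaluation

AUC is the linear-trapezoid integral of the empirical ROC with midrank tie
handling, hence exactly the Mann-Whitney U statistic over n₁·n₂ (tested as an
identity). No covariates. Group comparison is an unpaired two-tailed t-test
(classic by default, Welch flag). Biomarker association is Spearman with a
t-approximation p and no multiplicity adjustment by default.

## The synthetic world

The generator's defaults are the stated study conditions: the design above,
log10 intensities with baseline N(7.0, 0.8), animal noise SD 0.08 and
technical noise SD 0.05 (ICC ≈ 0.7, typical for LFQ re-injections), batch
mean shift 0.15 with per-protein jitter 0.05, and logistic
missing-not-at-random masking P(missing) = expit(2.0·(5.6 − x)) — the
standard LFQ assumption the reliability filter guards against, giving ~10%
missingness concentrated in low-abundance proteins. 10% of 4000 proteins
carry transgene effects with monotone age ramps peaking at 0.15-0.5 log10
units; 50 correlated and 30 anticorrelated proteins have trajectories exactly
proportional to a per-tissue aggregate readout (true |r| = 1); one candidate
is hippocampus-specific, affine in the hippocampal readout (offset 0.25, peak
0.45 — the offset keeps it top-ranked at every age while correlation, being
offset-invariant, stays 1), lysosome-annotated and forced human-concordant.
Aggregate readout means rise strictly and ~3-5-fold faster in hippocampus
than cortex, with a ~10x membrane-filter jump between 5 and 8 months. Human
tables contain a controllable overlap fraction (default 0.5) of mouse
differential symbols with controllable sign concordance (default 0.8) over
~1500 background genes. The CSF analyte is log-normal with standardized log
difference 0.8666 between 38 cases and 44 controls — the value whose
theoretical AUC Φ(d/√2) ≈ 0.73 — with biomarker columns rank-correlated
through a Gaussian copula (ratio 42/40 at ρ = −0.405, p-tau +0.35,
t-tau +0.20, Aβ42 −0.25, Aβ40 0).

All randomness flows from one seed through named substreams per table, so any
table regenerates in isolation and fixed-seed runs are byte-identical.

What the generator does **not** emulate: peptide-level quantification and
protein-group inference, correlated (co-regulated) proteins, heavy-tailed
intensity noise, batch-by-condition interactions, or real ortholog
nomenclature. A green end-to-end test therefore establishes that the
machinery recovers what was planted under the stated noise model — not that
the biological conclusions of any particular dataset are correct.

A deliberately low-noise "engineered funnel" preset (animal SD 0.02,
technical SD 0.01, concordance 1.0) exists for the funnel recovery test:
with three time points the critical |r| ≈ 0.9969 means realistic estimation
noise can push a truly correlated trajectory below threshold, so candidate
recovery through all six stages is only guaranteed when trajectory noise is
negligible. At the realistic preset the late funnel stages may legitimately
come up empty — that is a property of 3-point correlation power, not a bug.

## Numerical choices and scaling

- Proteins are grouped by missingness pattern; each pattern's GLS factors are
  computed once and applied to all its proteins (complete data is one fully
  vectorized group).
- Trigamma-inverse Newton tolerance 1e-8; ComBat iteration tolerance 1e-8.
- Haldane correction (add 0.5 to all cells) for degenerate odds ratios in the
  wild-type expression split; the omitted central "medium" band defaults to
  one third of proteins because a literal median split cannot produce three
  groups.
- Simulation-based tests are scaled to a single-CPU budget: null calibration
  uses 200 runs x 400 proteins, power/FDR recovery 10 seeds, the BH reference
  comparison 10^4 random vectors plus one 10^5-length vector. Thresholds are
  never adjusted to the scale.

## Known limitations

- ComBat standardization uses a per-protein pooled residual variance across
  batches; proteins observed in only one batch pass through with a prior
  fallback rather than a refusal.
- The consensus correlation is a single value for all proteins (as in the
  duplicateCorrelation approach); proteins with genuinely different replicate
  correlation are mis-weighted.
- Ortholog resolution is purely graph-structural; it cannot prefer a
  biologically better match inside a one-to-many component.
- The 15-point (per-animal) trajectory correlation mode mentioned as an
  alternative to 3-point means is not implemented; 3-point mode is canonical.
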