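# Methods

This note records the statistical procedure, the generator that exercises
it, the numerical conventions and the design choices that were genuinely
open, in the package's own words.

## Study design and testing procedure

The pipeline assumes a one-factor layout: one control group (default
`HDFa`) and a set of disease groups (default the 11 MPS types/subtypes
I, II, IIIA–IIID, IVA, IVB, VI, VII, IX), each with ≥ 2 biological
replicates (default 4). Analysis starts from a feature × sample count
matrix; alignment and transcript assembly are out of scope.

**Quantification.** Classic FPKM with library size `N_s` taken as the
column sum of the supplied count matrix. When counts arrive as a matrix
rather than an aligner's "total mapped reads", the column sum is the
faithful analogue of the classic library-size normalisation; FPKM is
invariant to rescaling a sample's counts, which is what makes desk-scale
simulated libraries representative. Effective length is the annotated
feature length — no fragment-length correction. Working values for all
tests are `log2(1 + FPKM)`.

**Omnibus + post-hoc scheme.** Per feature, a one-way fixed-effects ANOVA
across all groups; BH step-up over the ANOVA p-values of all *tested*
features defines the feature-level FDR (`q_bh`). Per disease group, a
pooled-variance Student's t contrast vs control, Bonferroni-corrected with
family size m = number of disease groups (only vs-control contrasts are
made). A tiered call in group G requires all three gates:
`q_bh < fdr_max`, `p_bonf(G) < p_max`, `|log2FC(G)| > lfc_min` (strict).
The interpretation that the FDR gate is feature-level (omnibus) and the
"p" gate is the adjusted per-group contrast is a deliberate reading that
makes per-group calls well-defined; both the choice of adjusted (rather
than raw) post-hoc p and the omnibus-level BH are isolated in
`call_significance`/`fit` and can be switched by supplying custom tiers or
by testing on raw `p_t` columns.

**Fold changes.** `log2((mean FPKM_grp + c)/(mean FPKM_ctrl + c))` with
pseudocount c = 1 by default, consistent with the `log2(1 + x)` transform.
Computed on the FPKM scale (not on means of logs). The pseudocount shrinks
fold changes of weakly expressed features toward 0; this matters for the
strict 2.5 gate of the extreme tier (see Limitations).

**Untestable features.** Features with all-zero counts or zero variance
across all samples are excluded from testing *and from the BH
denominator*, and reported in a skipped-features table. Zero within-group
variance with unequal means yields the `F = ∞, p = 0` convention and is
flagged. No expression prefilter is applied by default.

**GO profiling.** Annotations are propagated along `is_a` edges only (no
`part_of`/`regulates`): a gene counts toward a direct child C of the root
("cellular process", GO:0009987) when any annotated term equals C or
reaches C through `is_a` ancestors. Multi-membership is kept. Counting
unit defaults to transcript; a feature→gene map enables gene-level
collapse, where a gene carrying both up and down transcripts in one group
takes the direction of the transcript with the largest |log2FC|. Strong
processes are those with ≥ 30 changed transcripts (inclusive) at the
stringent tier, per group. Ordering of reported processes is by total
change then term id — deterministic output.

**Cross-type analyses.** Common-gene (chord) matrices intersect per-group
changed-gene sets within each process at the stringent tier, direction-
agnostic (a gene up in one type and down in another is still shared);
direction is instead retained in the recurrence table, which lists genes
passing the extreme tier (FDR < 10⁻⁶, p < 0.01, |log2FC| > 2.5, strict)
in at least `min_types` groups (default 2).

**qPCR.** ΔCt = Ct_target − arithmetic mean of the two reference-gene Cts
(equivalent to the geometric mean of reference expression — standard
multi-reference practice; the combination rule was an open choice).
ΔΔCt = group mean ΔCt − control mean ΔCt, computed from group means rather
than per-sample pairing (plate pairing is not modelled). Relative
expression `2^−ΔΔCt`; significance from a two-group one-way ANOVA on
replicate ΔCt values (identical to the pooled t-test, F = t²). Reported
spread, where needed, is the SD of per-replicate −ΔCt deviations.

## Synthetic generator

Counts for feature g, sample s in group G are negative binomial with

    mean = L_s · λ_g · 2^{β_{g,G}},   var = μ + φ·μ²

* `λ_g` — baseline relative abundance, log2-uniform in (−16, −8). With the
  default library sizes this puts per-feature mean counts at roughly
  1.5–400, spanning censored-to-comfortable coverage like a shallow real
  library does.
* `L_s` — library size, uniform integer in 1e5–2e5. Real experiments run
  tens of millions of reads; FPKM's scale invariance makes the smaller
  libraries statistically equivalent for everything downstream, at desk-
  scale cost.
* `φ` — dispersion, default 0.05: a moderate biological-replicate level
  for clonal cell culture (CV² ≈ 1/μ + φ).
* `β` — planted log2 effects, zero for the control; one effect record may
  target several groups at once (cluster-shared effects, emulating the
  observation that disease types share changed gene sets).

A single seed feeds independent spawned streams for lengths, baselines,
library sizes and counts, so runs are reproducible and changing one
parameter leaves unrelated draws untouched. Generating means above 2³¹
are rejected.

The GO fixture builds a single-rooted `is_a` DAG with a configurable
number of direct children and chain depth, annotating genes (1–3 processes
each) at the deepest terms so that profiling must actually propagate.
The qPCR generator inverts the ΔΔCt arithmetic (target Ct = baseline −
log2fc + noise; references constant across groups), so the noise-free
plate is recovered exactly — an inverse-construction oracle.

What the generator does **not** emulate: GC/length bias, batch effects,
transcript-level isoform structure (features are independent), correlated
co-expression, and library-preparation artefacts. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
assumed NB model, not robustness to real-data artefacts.

## Validation fixtures: sizes and rationale

* Null error control: 20 replicates of the 12 × 4 design with 5,000 null
  features; the mean false-discovery proportion among tier-1 ANOVA
  discoveries (all discoveries are false under the global null) is
  compared against the nominal 0.1 plus Monte-Carlo slack.
* Recovery: 5,000 features, 200 planted effects of |log2| = 3, each shared
  by 1–3 cyclically assigned groups. Effects are planted on features in
  the upper half of the baseline-abundance range: a multiplicative effect
  on a feature with ~2 mean counts is not identifiable at n = 4 by any
  method (the observation is censored), so uniform planting would measure
  the abundance distribution rather than the procedure. Sensitivity is
  summarised per group; precision is pooled over all (feature, group)
  calls — per-group false-call counts are small-sample noisy and
  correlated across groups because every contrast shares the same four
  control replicates, so the pooled rate is the quantity the procedure
  actually controls (both are reported by the acceptance script).
* Oracles: BH against a direct step-up evaluation; ANOVA against the
  hand-computable three-group toy and the two-group F = t² identity; GO
  assignment against explicit transitive closure on random DAGs ≤ 50
  terms; overlaps against brute-force set intersection; ΔΔCt against
  inverse construction.

## Numerical conventions

* BH implemented by reverse cumulative minimum after a stable mergesort;
  ties preserve input order, q clipped to 1.
* Strict inequalities at every gate (`q < fdr_max`, `p_bonf < p_max`,
  `|lfc| > lfc_min`): a fold change of exactly 2.5 is *not* extreme.
* Output TSVs have fixed column order and 6-significant-digit floats;
  repeated runs are byte-identical.
* Degenerate contrasts: zero pooled variance with equal means → t = 0,
  p = 1; with unequal means → t = ±∞, p = 0 (flagged upstream by the
  zero-within-variance ANOVA flag).

## Known limitations

* Student's pooled t and plain one-way ANOVA, as the procedure specifies —
  no variance moderation (limma/DESeq2-style shrinkage), no Welch
  correction, no batch covariates. With n = 4 per group, per-feature
  variance estimates are noisy; the tiers' joint gates compensate only
  partially.
* The pseudocount-1 fold change under-reports fold changes of features
  whose FPKM is of order 1; extreme-tier counts are therefore conservative
  at low expression.
* FDR is controlled at the feature level (omnibus); per-group calls
  inherit false calls both from BH-admitted null features and from
  post-hoc leakage across the shared control, at the nominal rates.
* GO profiling counts transcripts; it performs no enrichment test, by
  design.
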