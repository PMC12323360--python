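# Methods

## The two indices

**MAPI.** For a sample with abundance map over taxa, each taxon is
classified *aerotolerant*, *strict anaerobe*, or *unclassified* against
a classification table; the score is `ln(A/S)` over the two category
sums. Properties that follow directly and are enforced by tests: scale
invariance (counts and proportions give the same score), strict
monotonicity in each category's mass, antisymmetry under swapping the
categories, and zero influence of unclassified taxa. Because the
classification partitions a sample's mass exactly, the three component
masses are reported alongside the score.

Classification is genus-level with species-level overrides consulted
first. The override mechanism exists for *Bifidobacterium*, whose
strict anaerobes are defined per species, but it is honored for every
genus: one general rule instead of a special case. Name matching is
exact after case-folding and underscore/space unification; there is no
synonym resolution. The curated aerotolerance list is an external
input; the bundled starter table covers common gut genera
(Enterobacteriaceae, lactic acid bacteria and other facultative
anaerobes as aerotolerant; the dominant gut commensal genera as strict
anaerobes) and records per taxon how borderline physiologies
(microaerophiles, aerotolerant anaerobes) were counted, rather than
resolving that question globally. Swap in any curated table via
`--aerotolerance-table`; scores are only comparable under a fixed
table.

**Zero handling.** If both category sums are zero the score is an
error. If exactly one is zero, a pseudocount (default 1e-6 on the
relative-abundance scale) is added to *both* sums, which keeps edge
samples finite without moving the A = S balance point; the flag
`pseudocount_used` is carried into the score table so such samples are
auditable, and a pseudocount of 0 turns these cases into errors
instead. Typical samples (both sums positive) are never perturbed.
Scores are written to 6 decimals — natural-log units do not support
more meaningful precision.

**Keystone score.** Per species, `L = log10(p + 1e-6)` over relative
proportions, Z-scored with the sample SD (n−1) across the *whole*
analyzed cohort — all phenotypes pooled, since contrasting phenotypes
on a common scale requires a pooled reference. A species with zero
variance yields an all-zero Z column rather than a division by zero.
The per-sample score is the row sum; by construction cohort scores sum
to zero, so the score is a within-cohort ranking with no absolute
scale. *M. smithii* is scored like the other five; its anomalous
behavior under disease is a property of data, not of the scoring rule.
The panel is replaceable (one binomial per line); the default is the
six species above.

## Table harmonization

Three TSV dialects funnel into one in-memory cohort. Lineage strings
accept both `;` and `|` separators in all dialects (the upstream
pipelines convert between them), fold `sk__` into `k__`, discard a
leading `Root`, join a bare species epithet to its genus into a
binomial, and treat an empty rank field (`g__`) as unassigned — such
taxa can never match a genus-level classification. Rank order must
strictly descend; violations are malformed, not reordered. Taxonomy
-summary exports get four edits, in order: strip the stray `s` before
`k__` in each taxon identifier (the exact artifact varies between
exports, so the pattern is a configurable regex with this default),
remove `Root;` occurrences, rename the `SampleID` header cell to
`OTU ID`, and replace `;` with `|`. Duplicate lineage rows are summed
— 100% OTU tables legitimately repeat an assignment across OTUs.
Orientation (taxa on rows vs samples on rows) is an explicit parameter;
`auto` applies a heuristic (lineage-like header cells, else the
majority-numeric axis) because silent transposition is a classic
corruption source. Files are UTF-8 with decimal points; the plain
-dialect writer emits full-precision floats so a write/read round trip
is exact.

## Phenotype binning

Condition lists normalize (case-fold, whitespace, apostrophes, a small
synonym map for survey aliases like GERD and IBD) and bin by severity
dominance: any diseased term wins, else any mild term, else an empty
list is healthy. A non-empty list of only unrecognized terms is
`unknown` — a distinct value excluded from comparisons, not coerced to
mild, so unparseable survey text cannot contaminate the healthy/mild
contrast. Adding a recognized condition can never lower the bin.

## Cohort statistics

Two-group comparisons use the unpaired two-sided Mann-Whitney U test
with midranks. The exact mode enumerates all C(n, n1) assignments of
the pooled observations to groups and counts those whose U deviates
from n1·n2/2 by at least the observed deviation — the standard
two-sided permutation p, valid under ties (with ties the U null
distribution need not be symmetric, so this deviation form rather than
a doubled tail is used consistently). `auto` uses the exact mode for
combined n ≤ 12 without ties and otherwise the normal approximation
with tie correction and continuity correction (via scipy). The omnibus
test is Kruskal-Wallis (midranks, tie correction, chi-square reference)
with the all-tied case reported as H = 0, p = 1. Pairwise bin
comparisons are adjusted with Benjamini-Hochberg step-up (BH, not BY;
no dependency qualifier is assumed); note BH adjustment is a one-shot
map — re-adjusting already-adjusted values is meaningless and not a
fixed point. Group summaries report n, mean, sample SD (absent for
n = 1), median, and quartiles, with per-bin counts of excluded missing
scores.

One naming caveat: cross-sectional gender groups are unpaired, so the
two-group comparison here is the rank-sum test even where legacy
descriptions of this analysis say "signed-rank" (which requires
pairing that does not exist in these data).

## Synthetic cohort generator

The generator emulates what the analysis needs and nothing more:
per-sample profiles over a small genus panel with a controllable
aerotolerant mass fraction, log-normal keystone abundances with graded
phenotype shifts, and survey covariates. It inverts the MAPI formula:
for target score m the aerotolerant fraction of classified mass is the
logistic `1/(1+e^−m)`; within-category masses follow a symmetric
Dirichlet (concentration 1.0 — heterogeneous but not degenerate
within-category compositions). Keystone species, all strict anaerobes,
take their log-normal draws out of the strict-anaerobe budget with the
remaining anaerobe genera scaled to fill it, so the recomputed score
equals the target to ~1e-12 (keystone draws are capped at 0.9× the
budget; under the default calibration the cap never binds). An optional
unclassified fraction routes mass to taxa outside both categories
without touching the score.

Calibration defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| healthy MAPI mean / SD | −5.2 / 1.8 | published healthy-adult distribution |
| mild, diseased mean shifts | +0.5, +1.0 | invented effect sizes: group tests at n≈200/group separate while distributions overlap heavily, matching the reported "considerable variation" |
| age effect | +0.5 for bins 61+, as a mean-zero contrast | reported direction (scores increase after 60); centering keeps each phenotype's marginal mean at its calibrated value |
| age/gender frequencies | the commercial cohort's reported composition | realistic covariate mix |
| keystone log10 means | −1.5 … −3.0, SD 0.5 | plausible gut relative-abundance ranges; Z-scores are location-free so only the spread and shifts matter |
| keystone disease shift | −0.5 log10 (mild: half), ×0 for M. smithii | one SD in log space; preserves the species' anomalous direction |

MAPI draws are normal (the healthy distribution is summarized by
mean ± SD only). Condition lists are sampled from the phenotype's term
set (healthy: empty), so they round-trip through phenotype assignment
to the generating label with 100% agreement. A single RNG stream with
a documented draw order makes cohorts byte-identical across runs for a
given seed.

What the generator does **not** emulate: sequencing noise, read-count
depth, compositional artifacts beyond renormalization, taxon
co-occurrence structure, or any real data set's correlation between
covariates and composition. Passing tests therefore demonstrate that
the *pipeline* recovers the structure it assumes, not that real
cohorts have that structure.

## Problem sizes and numerical choices

The test suite exercises the calibration at the published healthy
cohort size (2,415 profiles), direction recovery over 100 replicates
of 200 samples/group, null calibration of the omnibus test over 1,000
simulated score sets (drawn directly from one normal distribution —
the null concerns the test, not the profile machinery), and exhaustive
rank-sum enumeration for all splits of pooled sizes 4–8 with and
without ties. Relative-abundance sums are required to hit 1 within
1e-9; Z columns are standardized within 1e-9; cohort keystone sums
within 1e-6; generated-score round trips within 1e-9.

Known limitations: exact rank-sum enumeration is combinatorial and
capped at combined n = 12; the bundled aerotolerance table is a
starter, not the curated published list, and absolute MAPI values
depend on the table in use; keystone scores are not comparable across
cohorts (they are cohort-referenced by construction); the demographics
module carries the source cohort tables verbatim and flags the rows
whose printed percentages are inconsistent with their printed counts.
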