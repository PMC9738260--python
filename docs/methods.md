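# Methods

## Data model

A locus-group analysis (DRB, DQ or DP — cross-reactions among HLA class II
are essentially intralocus, so loci are never mixed) takes three inputs:

- an **eplet registry**: one row per (allele, eplet) pair with an ElliPro
  antibody-accessibility category (High / Intermediate / Low / VeryLow; a
  blank cell loads as Unknown). The registry is validated for inverse
  consistency, chain-class coherence (an eplet is an α-chain or a β-chain
  feature, never both) and locus membership.
- a **bead panel**: DR beads carry one DRB1/3/4/5 protein; DQ and DP beads
  carry an α+β heterodimer, so one chain allele may pair into several beads
  (and hence, later, several response groups).
- a **raw MFI matrix** (patients × beads, device units). All values enter
  the analysis irrespective of any positivity call; negative raw values
  (background-subtracted exports) are accepted, only non-finite cells are
  rejected. Patients with missing bead values are dropped with a logged
  count (policy `drop`, configurable to `error`). There is no imputation.

## Standardization

Each bead column is centered and scaled to unit sample standard deviation
(ddof = 1, the dominant convention in statistical software). A zero-variance
column cannot be scaled; the default is an error naming the bead, with an
opt-in `drop` policy for small or heavily clipped cohorts. Standardization
is idempotent to 1e-9 and is the only transformation before ordination and
distance computation.

## Ordination

PCA on the correlation matrix, computed through the SVD of the standardized
matrix for numerical stability: eigenvalue λₖ = sₖ²/(n−1), with
min(n−1, p) components. Invariants maintained (and tested): Σλ equals the
number of beads to 1e-6; score column k has sample variance λₖ and score
columns are uncorrelated; variable coordinates are eigenvector columns
scaled by √λₖ, their squares are the variable cos² and sum to 1 per bead;
individual cos² is the squared score over the individual's squared distance
from the origin (defined as 0 for an all-zero row). Eigenvector signs are
fixed deterministically — the largest-magnitude entry of each eigenvector is
made positive, ties resolved by the first such entry — so outputs are
platform-reproducible. Components with λ < 1e-12 are reported as exactly 0
with zero coordinates. No rotation is applied.

## Antigenic clustering

Bead feature vectors are the transposed standardized columns. Distances are
Minkowski of order p ≥ 1 (default p = 2, the canonical member; configurable
`--minkowski-p`). Agglomeration is Ward's minimum-variance method via the
Lance–Williams recursion applied to squared dissimilarities with heights
reported unsquared (the "ward.D2" convention; a "D" variant exists for
sensitivity checks). For p ≠ 2 the update is applied as a heuristic with a
logged notice, since Ward's variance interpretation presumes Euclidean
geometry. The implementation is written here rather than delegated because
reproducibility requires a specified tie-break — among equal-minimum pairs
the lexicographically least (smaller id, larger id) pair merges first —
which library implementations do not guarantee; scipy's Ward serves as an
independent cross-check in the test suite, alongside a brute-force
agglomerator that recomputes the Ward objective increase from scratch at
every step. Merge heights are non-decreasing (Ward admits no inversions).

`cut_tree(k)` removes the k−1 highest merges; groups are numbered by their
lexicographically smallest member label. Defaults use k = 3 per locus (the
number of main dendrogram branches); an explicit bead→group file always
takes precedence over the automated cut, because published group
assignments are typically read off the ordination rather than cut from the
tree. Dendrograms export as rooted binary Newick with ultrametric branch
lengths (child branch = parent height − child height, leaves at height 0);
children are ordered by the smallest leaf label in their subtree and labels
containing metacharacters are quoted, so standard readers round-trip the
topology and leaf depths.

## Driver nomination

Each group's allele set is the union of its beads' alleles (both chains for
heterodimer beads). For eplet e, the panel-restricted expressing set S(e) is
its registry expressing set intersected with the union of group sets;
registry alleles never tested are ignored with a logged count, since
exclusivity can only be judged against tested alleles. e is **exclusive**
to a group iff S(e) is non-empty and is a subset of exactly that one group's
set. With overlapping group sets (DQ/DP α chains) an eplet whose S(e) is
contained in two groups' sets is non-exclusive by this rule.

Filters, in order of precedence: `single_allele` (fewer than
`min_allele_count` = 2 tested expressing alleles — a one-allele eplet cannot
explain a correlated multi-bead cluster), then `low_score` (ElliPro category
outside {High, Intermediate, Unknown}). Unknown passes the filter: a blank
registry cell is an absence of evidence, not evidence of inaccessibility.
An eplet failing both filters counts as single-allele, so the reported
(single, low) decomposition is well defined. Chain attribution partitions
the retained list into α- and β-chain eplets.

A note on a tempting invariant: "merging two groups never decreases the
number of exclusive eplets" is true when group allele sets are disjoint
(any DR panel), and is tested under that condition; with overlapping sets
it fails — an eplet exclusive to a third group can become non-exclusive if
the merged union newly covers its expressing set — so the property is not
asserted in general.

Locus-wide totals for "x of N eplets" reporting (123 DR, 83 DQ, 62 DP) are
configuration constants in `data/registry_totals.json`: the shipped
fixtures transcribe only the group-exclusive subsets, so totals are not
computable from them.

## Packaged fixtures

`data/drb_table1.csv`, `data/dq_table2.csv` and `data/dp_table3.csv` carry
the exclusive-eplet subsets for the three locus groups (32, 28 and 23
eplets respectively) with their expressing alleles and ElliPro categories,
alongside matching bead panels and the published group assignments.
"Whole group" allele shorthands were expanded to explicit allele lists at
fixture-authoring time, and two-field WHO nomenclature is used throughout,
so the loader stays simple and the fixtures auditable. One DP eplet is
spelled `84DEAV` following its table row (a prose variant `84DAEV` exists);
the DR eplet `96HK` has a genuinely blank ElliPro cell and loads as
Unknown, which the score filter retains.

## Synthetic cohorts

The generator operationalizes the cross-reactivity premise — antibodies
target eplets, so beads sharing eplets respond together. Per patient: a
Bernoulli(`sensitization_prob` = 0.6) responder draw; responders draw
`1 + Poisson(exposures_per_responder − 1)` exposure alleles (mean 2)
uniformly without replacement from the panel; each eplet of an exposure
allele is targeted with probability given by its ElliPro category
(High 0.9, Intermediate 0.6, Low 0.2, VeryLow 0.05, Unknown 0.6); each
targeted eplet contributes one log-normal reactivity (median 5000 MFI,
log-SD 0.5) shared across all beads carrying it; bead MFI = Gaussian
background (mean 100, SD 50) + eplet reactivities + Gaussian noise
(SD 100), clipped to [0, 25000]. Composition is additive with a hard cap —
the simplest saturating model. All draws flow from one seed
(`numpy.random.default_rng`), so cohorts are bit-reproducible. A
direct-injection entry point (`sensitize`) fixes each patient's eplet set
exactly, for deterministic propagation tests.

Defaults are conventional for Luminex-scale data rather than estimated —
no distributional facts about the source cohorts are available for
calibration. The generator reproduces the *correlation mechanism* only: it
does not model prozone/complement interference, IgG subclasses, affinity
maturation, bead-lot variation, or dense epitope-sharing between groups.
Passing recovery tests therefore show that the pipeline inverts this
mechanism, not that real cohorts are this clean.

The recovery harness simulates a cohort, runs the full pipeline, and scores
(a) the Adjusted Rand Index of the k-group bead partition against the
design blocks and (b) recall/precision of the retained drivers against the
eplets actually used in sensitization. On the default block design
(3 groups × 4 beads, disjoint eplet blocks, 300 patients) a 25-seed pilot
scored ARI = recall = precision = 1.0 on every seed; the test suite asserts
the frozen thresholds ARI ≥ 0.9 and recall ≥ 0.8 over 20 seeds.

One numerical caveat the tests respect: with the default background/noise
SDs the clip at 0 MFI slightly biases null-cohort column means upward, so
the "no responders ⇒ columns at background" check runs at reduced
dispersion (SD 20) where clipping is negligible.

## Problem sizes

The shipped analyses are desk-scale: panels of 24–36 beads, registries of
23–32 eplets, simulated cohorts of up to 400 patients, and oracle
comparisons on a few hundred random instances of n ≤ 8 — the whole suite
runs in a few seconds.

## Known limitations

- Exclusivity is judged against the tested panel; an eplet exclusive among
  tested alleles may be shared more widely in the full registry.
- The automated k-group cut will not reproduce a published grouping that
  was read off a biplot by eye; explicit group files exist for that reason.
- Ward on p ≠ 2 Minkowski dissimilarities is a heuristic.
- The DQ/DP fixture arithmetic inherits the source tables as printed;
  where their narrative counts disagree internally, this package reports
  what the tabulated data imply and does not adjudicate.
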