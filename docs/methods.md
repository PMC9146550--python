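# Methods

This note documents the models, parameter choices and numerical
decisions behind `coexmix`, and what the synthetic-data validation does
and does not establish.

## Exposure catalog

List-presence records assert that a chemical appears in some product or
use inventory under a curated keyword; keywords are many-to-one mapped
to broader exposure-source categories supplied by the user (keyword
matching is trimmed and case-insensitive, since curated text fields vary
in casing between releases). The presence matrix holds 1 where a
(chemical, category) pair was observed at least once. Chemicals present
in fewer than `min_categories` (default 2) distinct categories are
removed — co-occurrence is undefined for them — and categories left with
no presence are dropped because an all-zero column has no Jaccard
distance to anything. Chemical identifiers are joined on a normalized
key (trimmed, uppercased, internal spaces removed), accommodating both
CAS registry numbers and DTXSID-style accessions; the screening and
exposure sources must share this key for the intersection stage to work.

## Bioactivity screen

Summary-level screening records carry a binary hit call, a
cytotoxicity-burst Z-score and an AC50 per chemical × endpoint. The
active set is `hit_call == 1 AND cytotox_zscore > z_threshold` with
`z_threshold = 2` and a strict inequality (a Z-score of exactly 2
fails). A missing Z-score passes with an audit flag by default: in
summary releases the Z-score is undefined when no cytotoxicity was
observed at any tested concentration, which is itself evidence that
activity lies far from the burst region; `missing_z_policy="fail"`
inverts this. Hit calls are accepted only as exact 0/1 integers unless
`continuous_hitc=True` thresholds continuous calls at 0.9, so
forward-compatibility with later data formats is explicit rather than
silent. Endpoint matching is exact and case-sensitive (controlled
vocabulary).

## Co-occurrence clustering

Both axes of the presence matrix are clustered independently on Jaccard
distances (a metric on non-empty binary vectors). Design choices:

- **Linkage: Ward by default, configurable.** No linkage is canonical
  for this task. In planted-block benchmarks (below) Ward recovered the
  planted partition substantially more reliably than average, complete
  or single linkage at every selection rule tested, so it is the
  default; the linkage used is always recorded in output provenance.
- **Duplicate profiles are never split.** Identical presence rows are
  one co-occurrence pattern. Trees are built over distinct profiles
  only; silhouette and WSS are evaluated on the full distance matrix so
  patterns keep their multiplicity weight; candidate k stops one short
  of the distinct-profile count. Without this, the silhouette argmax
  degenerates: zero-distance twins form "perfect" clusters with
  s(i) = 1, and the optimal k drifts toward n.
- **k selection: first local maximum of the average-silhouette profile**
  (`selection_rule="first_silhouette_peak"`, with plain
  `max_silhouette` argmax available). Even with duplicates collapsed,
  near-identical profiles make the global argmax favor many tiny tight
  clusters on discrete data. Taking the first peak formalizes how an
  analyst reads a silhouette/WSS profile plot, involves no fitted
  constants, and in benchmarks dominates the argmax on both recovery
  rate and adjusted Rand index. Silhouette uses the s(i) = 0 convention
  for singletons; k = 1 appears in the WSS elbow profile only, where
  the silhouette is undefined.
- **WSS in pairwise-distance form**, Σ_C Σ_{i<j∈C} d²(i,j)/|C|, which
  needs no coordinates and reduces to the centroid form for Euclidean
  distances. It is reported as a diagnostic, never used for selection.
- **Determinism.** Agglomeration, cutting and renumbering are
  deterministic; cluster indices are assigned 1..k by first appearance
  along the dendrogram leaf order (top to bottom), matching the heatmap.

**Planted-block benchmark.** The generator plants three equal chemical
blocks over two category blocks in a 60 × 12 matrix with within-block
presence probability 0.9 and background 0.05. With three row blocks and
two column blocks, identifiability of both plantings forces the
association design {block A → categories 1}, {B → categories 2},
{C → both}: the third block is genuinely broader and overlaps the other
two, which mirrors the broad household-exposure cluster the workflow
exists to find but also caps separability. Under these conditions the
default pipeline recovers k = 3 in 19 of the 20 seeded test replicates
(mean adjusted Rand index 0.96); across larger seed sweeps (200
additional replicates) the per-seed recovery rate is ≈ 0.81–0.87 with
mean ARI ≈ 0.93–0.96, the residual failures being near-tie splits of
one block (k = 4) or a merge of the broad block with a neighbor
(k = 2). At lower noise (p_within ≥ 0.95, p_between ≤ 0.01) recovery is
exact.

## Cluster prioritization

Clusters are ranked by the arithmetic mean of their members' distinct
exposure-source counts, descending; ties break by larger membership,
then lower cluster index. A household-relevance criterion is exposed as
an optional `required_categories` set (clusters covering none are
demoted) rather than hard-coded, because that judgement is
application-specific. The final manual subselection of chemicals within
the nominated cluster (vendor availability, solution stability) is not
algorithmic; the full member list is emitted with an annotation slot.

## Dose–response and AC90

Raw plate signals are normalized to percent viability against the mean
vehicle (dose 0) signal. The decreasing four-parameter logistic is fit
on log10 dose by bounded least squares with a deterministic multi-start
grid (midpoint at the geometric mean of doses and at every tested dose;
hill ∈ {0.5, 1, 2}); the lowest-SSE converged start wins, making fits
reproducible without a global optimizer. The top plateau is left free
(not pinned to 100%) because low doses often show mildly elevated
viability; a free top absorbs that while the decreasing limb keeps a
unique 90% crossing (`pin_top` restores the constrained fit). Dose 0 is
excluded from the log-dose fit. The AC90 is the analytic inverse
d = midpoint · ((top − 90)/(90 − bottom))^(1/hill), valid only when
bottom < 90 < top; if the inverse does not exist or falls outside the
tested dose range, the configured fallback concentration (default
1000 µM over a 0–2000 µM range) is carried forward with
`not_reached_fallback` status, which propagates through the mixture
sheet. Under the bench-scale simulated design (8 log-spaced doses
1–2000 µM, triplicate, 5% multiplicative noise) the median relative
AC90 error is ≈ 12–13%; shallow curves crossing 90% far below the
lowest sampled dose carry the largest errors.

## Mixture design

Components are exactly AC90 × i in µM (no unit conversions); linearity
holds to 1 ulp for decimal-exact inputs. Fallback-status AC90s
participate identically, with status carried in the output sheet.
Component order is canonical (alphabetical) for reproducibility.

## Expression (ddCt)

Technical replicates are averaged to one Ct per (sample, gene) before
any statistics, so n is the number of biological replicates. The
housekeeping reference per sample is the arithmetic mean of the
housekeeping genes' Cts — on the linear 2^−Ct scale this is their
geometric mean, and with a single housekeeping gene (default GAPDH) it
is that gene's Ct. ΔΔCt subtracts the mean control-condition ΔCt per
gene; fold change is 2^−ΔΔCt with amplification efficiency fixed at 2
(no efficiency correction). The significance test is a two-sided Welch
two-sample t-test on replicate ΔCt values (equivalent to testing
log₂FC, which differs by a constant); Student's test is available and
the method used is recorded. The pipeline is exactly invariant to any
per-sample additive Ct offset, and on noiseless synthetic plates
recovers planted log₂ fold changes to numerical precision (≤ 1e-12).

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (parameters, seed); a master seed
derives per-generator substreams, so one integer reproduces the whole
fixture suite. Defaults mirror the bench-scale design the workflow
targets: a five-chemical mixture panel, 8-dose viability curves in
triplicate with 5% noise, qPCR in biological and technical triplicate
with 0.1-cycle Ct noise, planted expression effects in the 0.2–1.5
log₂ range for individual exposures with a larger joint mixture effect,
and a screening table of 500 records with ~8% planted actives
(including a decoy at exactly Z = 2.0 to pin the strict inequality).
The end-to-end simulation uses a higher active fraction (0.7) among the
60 exposure-catalogued chemicals so that all planted blocks remain
clusterable after screening.

Not emulated: realistic keyword frequency distributions, correlated
assay noise, plate effects or probe efficiency differences, and any
relationship between a chemical's bioactivity and its exposure profile.
Passing the planted-truth tests therefore shows the *computations* are
correct and the pipeline recovers structure under the stated noise
model; it says nothing about how strong co-occurrence signal is in real
product-inventory data.

## Problem sizes

Tests and the acceptance script run at the scale the method targets on
a desk machine: 60 × 12 presence matrices (20 replicates for recovery
statistics), 500-record screens, five-chemical dose–response panels
(20 noisy replicates), and ~200 small qPCR simulations for the power
check. Distance-matrix operations are O(n²)–O(n³) and remain
interactive up to a few thousand chemicals.

## Known limitations

- The silhouette first-peak rule, like any automatic k selection, can
  split or merge genuinely ambiguous blocks; both the silhouette and
  WSS profiles are emitted so the choice can be audited or overridden.
- The 4PL fit assumes monotone decreasing viability; hormetic
  (biphasic) dose–response shapes are absorbed by the free top plateau
  but not modeled.
- ddCt assumes perfect doubling per cycle; efficiency-corrected methods
  are out of scope.
- The screen consumes summary-level hit calls and Z-scores as given; it
  does not re-derive them from concentration–response data.
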