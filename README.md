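# coexmix

Prioritization and design of environmentally co-occurring chemical
mixtures that act on a shared molecular target.

People are exposed to household chemicals in combinations, yet toxicity
testing is overwhelmingly single-chemical. `coexmix` implements an
in-silico-to-in-vitro workflow for finding mixtures worth testing: it
screens summary-level high-throughput bioactivity data for chemicals
that activate a common target — the nuclear receptor PPARγ in the
motivating application — without cytotoxicity confounding, clusters
those chemicals by co-occurrence across consumer-product exposure
sources, nominates the broadest cluster, designs a potency-proportional
mixture from per-chemical cytotoxicity thresholds, and analyzes the
resulting qPCR readouts. It is a library first (one module per stage),
with narrative scripts under `examples/` and a thin `coexmix` CLI for
end-to-end runs.

## Method

**Screen.** A chemical passes when its assay endpoint hit call equals 1
and its cytotoxicity-burst Z-score exceeds 2 (strict), i.e. activity
occurs well below the concentration region where signal loss reflects
dying cells rather than biology.

**Co-occurrence clustering.** Chemical presence across exposure-source
categories is a binary matrix *M* ∈ {0,1}^(n×m). Both axes are clustered
on the Jaccard distance

    d(A, B) = 1 − |A ∩ B| / |A ∪ B|

with agglomerative (default Ward) trees. The cluster count *k* is chosen
from the average silhouette width s̄(k) (per-point
s(i) = (b(i) − a(i)) / max(a(i), b(i))) profiled over 2 ≤ k ≤ 34,
taking the first local maximum of the profile; the within-cluster sum of
squares in pairwise-distance form, Σ_C Σ_{i<j∈C} d(i,j)² / |C|, is
emitted as an elbow diagnostic. Identical presence profiles are never
split across clusters.

**Prioritize.** Chemical clusters are ranked by the mean number of
distinct exposure-source categories per member; the broadest cluster is
nominated for testing.

**Mixture design.** Given per-chemical AC90 values (concentration
retaining 90% viability, from decreasing 4PL fits
v(d) = bottom + (top − bottom)/(1 + (d/midpoint)^hill) inverted
analytically at v = 90), the mixture at scaling factor *i* is

    C_i = Σ_c AC90_c · i

so component ratios are fixed by relative potency. When a curve never
reaches 90% inside the tested range, a configured fallback concentration
(1000 µM by default) is carried forward.

**Expression.** qPCR Ct tables are analyzed by the comparative-Ct
method: ΔCt against the housekeeping reference within each sample,
ΔΔCt against the vehicle-control condition, fold change 2^−ΔΔCt
(log₂FC = −ΔΔCt), with Welch two-sample tests on replicate ΔCt values.

Every stage has a synthetic-data generator (`coexmix.simulate`) that
plants known truth — block structure, active sets, 4PL parameters,
log₂ fold changes — so the whole pipeline is testable without any
database download or wet-lab data.

## Worked example

Potency-proportional mixture for the five household chemicals bundled
with the package (`python examples/04_mixture_design.py`):

```
individual AC90 concentrations (µM):
  Benzyl cinnamate            1000  [1000 µM fallback: 90% viability never reached <= 2000 µM]
  Butylparaben                 150
  Decanoic acid               1300
  Eugenol                      150
  Sodium dodecyl sulfate       250

mixture series C_i = sum(AC90_c * i):
  C_1: total 2850 µM  (Benzyl 1000, Butylparaben 150, Decanoic 1300, Eugenol 150, Sodium 250)
  C_0.5: total 1425 µM  (Benzyl 500, Butylparaben 75, Decanoic 650, Eugenol 75, Sodium 125)
  C_0.2: total 570 µM  (Benzyl 200, Butylparaben 30, Decanoic 260, Eugenol 30, Sodium 50)
```

Each C_0.2 component is exactly one fifth of that chemical's AC90: the
dilution that retained viability in mixture testing and was carried into
expression analysis.

Planted-structure recovery by the clustering stage
(`python examples/03_cooccurrence_clustering.py`):

```
planted: 3 chemical blocks x 2 category blocks
recovered: 3 chemical clusters, 2 category clusters
adjusted Rand index vs planted chemical blocks: 1.000 (1.0 = perfect)
```

The full simulated pipeline, from list-presence records to expression
statistics, runs with

```sh
coexmix run-all --simulate --seed 1 --outdir out
```

and writes per-stage artifacts (presence matrix, screen provenance,
cluster assignments and k-selection profiles, ranked clusters, AC90
table, mixture sheet, expression results) plus a human-readable
`report.txt`; reruns under the same seed are byte-identical.

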