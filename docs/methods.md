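# Methods

## Occupancy classification

The substrate is a clusters × genomes matrix of member counts.  Occupancy
of a cluster is the number of genomes with at least one member — paralogs
(cells > 1) deliberately count their genome once, because the categories
are defined by *how many genomes encode* a cluster, not by copy number.
With `N` genomes, soft-core fraction `f` (default 0.95) and cloud cutoff
`c` (default 2):

| category | occupancy |
|---|---|
| core | `N` |
| softcore (nested) | `≥ ⌊f·N⌋` |
| shell | `c < occ < ⌊f·N⌋` |
| cloud | `≤ c` |

The floor rule reproduces the published 124-genome boundaries
(⌊0.95·124⌋ = 117).  The 0.95 fraction is the pangenome-clustering-tool
convention rather than a biological constant, so it is a parameter, not a
constant.  Two views are computed throughout: *nested* (softcore includes
core — the convention under which published softcore/shell/cloud counts
sum to the total) and *exclusive* (core split out, so the four categories
partition the clusters).  Reporting defaults to the exclusive view
because distribution histograms and quartile tables treat the categories
as disjoint; the choice cannot be disambiguated from per-genome gene
counts alone and is therefore surfaced as the `view` argument.

Thresholds are validated as `cloud_max < 3 ≤ softcore_min ≤ N`; smaller
pangenomes (N ≤ 4 at f = 0.95) leave no room for a shell class and are
rejected rather than silently reclassified.

## Circular geometry

Internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted exactly at the I/O boundary.  A gene wrapping the
sequence origin is encoded as `end ≤ start` and unwrapped by adding `L`.

A gene's representative position is its integer midpoint (configurable to
`start`); midpoint is the default because it is invariant under strand
and wrap.  From position `p` and origin `o` on a circle of length `L`:

* `dist = min(|p−o|, L−|p−o|)` — shortest arc, in `[0, L/2]`;
* `rel_dist u = 2·dist/L` — 0 at *ori*, 1 at the antipode;
* `recentred = ((p−o) mod L)`, mapped into `(−L/2, L/2]` — a signed
  ori-centred plotting coordinate, clockwise positive;
* `half` — *upper* iff `dist < L/4`, ties at exactly `L/4` go *lower*
  (ties are measure-zero but must be deterministic).

When an explicit terminus is supplied the two replichore arcs may be
unequal; a position is then *upper* iff it lies in the half of its own
arc nearer *ori* (per-arc midpoint rule).  The default terminus is the
antipode, matching the equal-halves design of the distribution analysis.
Strand is carried but never used by positional statistics.

## Positional bias scan

For each (genome, chromosome, category) the upper/lower counts are tested
with a 1-df chi-square goodness of fit.  The default null is a 50:50
split — the halves are equal arcs by construction.  A
`cds_proportional` null (expected split = the chromosome's overall
upper:lower CDS ratio) is available because total gene density can itself
be biased; which null the original R `chisq.test()` analyses used is not
derivable from their outputs, so the ambiguity is a flag rather than a
hidden choice.  Expected counts below 5 log a warning (classical validity
limit) without switching tests; an expected count of zero is an error
advising an exact test.

The Bonferroni family is *all* tests executed in one scan
(genomes × chromosomes × categories with ≥ 1 gene) — the most
conservative defensible family.  Direction is the sign of
(observed − expected) upper count.

## Expression gradients

RPKM uses as denominator the total reads assigned to CDS of the genome
(both chromosomes), since alignment is upstream of this package and
counts are its input; within a sample this is a monotone rescaling of any
library-total variant.  Replicate runs of a condition are summed per gene
before RPKM (per-replicate analysis is available by fitting each counts
table separately).

The global expression map is log₂(RPKM / median RPKM), one median per
dataset by default (`per_chromosome` optional).  Zero-RPKM genes have no
finite ratio; they are imputed at ε = half the smallest nonzero RPKM of
the scope and flagged.  Imputed genes are *excluded* from slope fits but
*kept* in quartile tables, so a category half with many silent genes can
legitimately report Q1 = 0.

The trend line is a centred moving average over gene order (default 200
genes; shrunk to the gene count on small inputs), wrapping across the
origin — the chromosome is circular, and the wrap choice only matters
within half a window of the origin.  Quartiles interpolate linearly
between order statistics at position (n−1)q.

The upper-vs-lower comparison of two different gene sets has no pairing,
so the "Wilcoxon" test is executed as the unpaired two-sample rank-sum
(Mann-Whitney) procedure — exact enumeration when both groups have ≤ 50
values, otherwise the normal approximation with tie correction — with
Bonferroni adjustment over the scan's tests.

`ExpressionGradient.fit()` additionally regresses log₂ ratio on `u`
(imputed genes excluded, large chromosome only): under the dosage model
expression ∝ 2^{k(1−u)}, the slope is −k, so the fit yields an implied
dosage exponent with a standard error.  Note that on data with planted
(or real) positional bias the *global* slope conflates dosage with
category composition — highly expressed conserved genes also sit near
*ori* — which is why the per-category tables exist.

## Synthetic-data generator

The generator emulates the joint structure the analysis assumes; all
randomness flows from one integer seed.

* **Occupancy**: a four-component mixture with weights defaulting to
  (0.012, 0.018, 0.23, 0.74) for core/softcore/shell/cloud — the
  proportions observed in the 124-genome *Vibrionaceae* pangenome — and
  within-category occupancies uniform on the category's range.  Present
  genes get a 2% chance of a second (paralogous) copy, exercising the
  paralogs-count-once rule; paralog copies are placed uniformly.
* **Positions**: on Chr 1, `u ~ Beta(1, 1+b)` for core/softcore (mass at
  *ori*) and `Beta(1+b, 1)` for shell/cloud (mass at *ter*); Chr 2 and
  `b = 0` are uniform.  Beta gives a one-parameter bias with closed-form
  mean `E[u] = 1/(2+b)`, used directly as a generator test oracle.  The
  default `b = 3` plants a strong, unambiguous signature; it is a
  generator convention, not a literature estimate.
* **Chromosomes**: defaults 3.2 Mb and 1.8 Mb (large/small replicon of a
  *Vibrio*-like genome), *ori* at 10% of each length so recentring and
  wrapping are exercised; 12 genomes, 6000 clusters by default
  (≈ 1500 genes/genome — scaled down from real genomes to keep suites
  fast while leaving every per-category cell well populated).
* **Expression**: expected expression = baseline(category) ·
  2^{k_eff(1−u)} · exp(ε), ε ~ N(0, σ²), flat on Chr 2 (the small
  replicon replicates late, so its dosage is position-independent);
  `k_eff = k` (default 1.5) at fast growth, 0 at slow growth.  Baselines
  default to (4, 3, 1, 0.5) for core/softcore/shell/cloud — conserved
  genes are enriched for highly expressed growth machinery.  Counts are
  Poisson with rates proportional to expression × gene length, scaled to
  a ~5 M-read library; overdispersion enters through the lognormal gene
  effect (σ = 0.3), keeping RPKM behaviour analytically checkable (a
  negative-binomial layer was considered and rejected as adding a
  parameter no test needs).
* An optional `slow_residual_k` plants per-category gradients at slow
  growth for the non-core categories; this mimics the observed
  slow-growth pattern whose mechanism is not modelled here, and is off by
  default.

What the generator does **not** emulate: nucleotide sequence, operon
structure and co-oriented gene clusters, overlap constraints (genes may
overlap), replication-timing dynamics beyond the static dosage law, and
inter-genome phylogenetic correlation (genome memberships are exchangeable).
Passing recovery tests therefore demonstrate the *statistical machinery* is
correct and calibrated, not that real genomes satisfy the model.

## Calibration and recovery experiments

Run via `panpos recovery` or the acceptance test suite; problem sizes are
the package's own choices:

* **Type-I calibration**: with `b = 0`, datasets are simulated until
  ≥ 2000 scan tests accumulate; the Bonferroni-adjusted significant
  fraction must be ≤ 0.05 + 3 binomial SEs (it is far below, as Bonferroni
  is conservative).  Raw per-test calibration at α = 0.05 is checked
  separately on 2000 binomial(200, ½) draws.
* **Bias recovery**: 50 replicates at `b = 3` with a 6-genome design whose
  mixture weights are inverse to per-genome presence (0.1264, 0.1516,
  0.2166, 0.5054; 24 000 clusters), giving ≈ 2000 genes per category per
  genome on Chr 1; ≥ 95% of replicates must reproduce the full
  qualitative signature in every genome with Chr 2 silent.
* **Dosage recovery**: one 3000-gene single-category dataset
  (`k = 1.5`, σ = 0.3, positions uniform so composition cannot confound);
  the fitted slope must lie within 2 SEs of −1.5.  The slow-growth null
  (`k = 0`) is checked over 30 replicates of the mixed-category design:
  the core upper-vs-lower rank test must be non-significant in ≥ 90%.

## Numerical and degenerate-input choices

* Writers are deterministic (fixed column order, `%.6g` floats,
  stable mergesort ordering) so reruns are byte-identical.
* Matrix orientation: header row is assumed to hold genome ids; a
  supplied genome list enables label-based auto-detection and
  `--transpose` forces the genomes-as-rows layout.
* Orphan genes (no cluster assignment) are dropped with a warning by
  default; `label` and `strict` policies exist.
* Even sliding windows take the extra point upstream; `window > n` is an
  error suggesting a smaller window.
* Empty distribution cells are reported with zero counts and excluded
  from the chi-square scan (no test is fabricated for empty categories).

## Known limitations

* The chi-square scan tests each category against its own half split
  (goodness of fit, df = 1), not category-vs-rest 2×2 contingency; the
  two framings usually agree in direction but not in statistic.
* Leading/lagging strand, GC skew and replichore asymmetry diagnostics
  are out of scope; strand is carried but unused.
* The dosage law 2^{k(1−u)} is a static, minimal monotone model — no
  replication-timing dynamics, no growth-rate inference.
* Visual output is Circos-dialect text tracks; the package does not
  render plots.
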