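# panpos

Positional analysis of pangene categories on circular bacterial
chromosomes, with an expression-gradient stage for bulk RNA-seq counts.

Bacteria with bipartite genomes (two circular chromosomes, as in the
*Vibrionaceae*) replicate from a single origin per replicon.  In fast
growers, overlapping replication rounds (multifork replication) raise the
per-cell copy number of origin-proximal genes, so *where* a gene sits on
the ori→ter axis affects both its dosage and its expression.  `panpos`
asks whether the pangenome structure of a taxon mirrors that geometry: are
widely conserved genes (core/softcore) packed near the origin of the large
chromosome while accessory genes (shell/cloud) accumulate near the
terminus, and does expression follow?

The package takes the standard artefacts of a comparative-genomics
workflow — per-genome CDS coordinates (GFF3), a clusters × genomes
membership matrix from a pangenome clustering tool, per-chromosome origin
positions, and per-CDS read-count tables — and provides:

1. **Occupancy classification.** A cluster present in *n* of *N* genomes is
   *core* (n = N), *softcore* (n ≥ ⌊0.95 N⌋), *shell* (in between) or
   *cloud* (n ≤ 2); paralogs count their genome once.  At N = 124 the
   boundaries are 124 / ≥117 / 3–116 / ≤2.  Both the nested view (softcore
   ⊇ core, the clustering-tool convention) and the exclusive partition are
   reported.
2. **Circular geometry.** Each gene is reduced to its midpoint on the
   circle; the shortest arc distance *d* to *ori*, the scaled distance
   *u* = 2d/L ∈ [0, 1], an ori-centred signed coordinate, and a chromosome
   half — *upper* (ori-proximal, d < L/4) or *lower* (ter-proximal) — are
   derived.  Origin-wrapping genes and an explicit, non-antipodal terminus
   are handled.
3. **Positional bias** (`PositionalBias(loci).fit()`): per (genome,
   chromosome, category) a 1-df chi-square goodness-of-fit test of the
   upper/lower split against a 50:50 null (or the chromosome's overall CDS
   ratio), Bonferroni-corrected over the whole scan.
4. **Expression gradients** (`ExpressionGradient(counts, loci).fit()`):
   RPKM = count / ((length/10³)·(total/10⁶)); per-gene log₂(RPKM/median)
   "global expression maps"; a circular 200-gene sliding-window trend; an
   OLS fit of log₂ ratio on *u* whose negative slope estimates the dosage
   exponent *k* (expression ∝ 2^{k(1−u)}); per-category upper/lower
   quartile tables; and unpaired Wilcoxon rank-sum tests of upper vs lower
   RPKM.
5. **Synthetic data** (`simulate_pangenome` / `simulate_counts`): fully
   seeded generator with a U-shaped occupancy mixture, Beta-law positional
   bias planted on Chr 1 only, and Poisson counts around a
   2^{k(1−u)} dosage expectation with lognormal noise — used for the
   calibration and parameter-recovery test suites.

## Worked example

Everything below is synthetic and reproducible (`--seed 11`):

```sh
panpos simulate --seed 11 --n-genomes 6 --n-clusters 2000 --out sim
panpos classify --matrix sim/matrix.tsv --out cls
```

```
category  n_nested  n_exclusive  pct_exclusive
    core        25           25           1.25
softcore        62           37           1.85
   shell       475          475          23.75
   cloud      1463         1463          73.15
```

The exclusive partition sums to 100%; nested softcore (62) equals core
(25) plus exclusive softcore (37).  Locate the genes and scan for bias:

```sh
panpos locate --gff g001 sim/g001.gff3 ... --ori sim/ori.csv \
       --categories cls/cluster_categories.tsv --out loc
panpos bias --loci loc/loci.tsv --out bias
```

```
Positional bias scan (chi-square goodness of fit, df=1)
null: uniform; alpha=0.05; Bonferroni family m=48

        g001     chr1      core upper=11     lower=1      chi2=    8.333 p_adj=0.187 upper
*       g001     chr1  softcore upper=22     lower=3      chi2=   14.440 p_adj=0.00695 upper
*       g001     chr1     shell upper=16     lower=166    chi2=  123.626 p_adj=4.88e-27 lower
*       g001     chr1     cloud upper=16     lower=205    chi2=  161.633 p_adj=2.39e-35 lower
        g001     chr2      core upper=7      lower=7      chi2=    0.000 p_adj=1 none
```

The planted signature is visible: conserved categories crowd the upper
half of chr1, accessory categories the lower half, and chr2 is flat (the
tiny core class on chr1 loses significance here only because this demo is
small).  Finally, the expression stage on the bundled fast-growth counts:

```sh
panpos exprmap --loci loc/loci.tsv --genome g001 --samples samples.tsv --out expr
```

```
Expression gradient (fast)
total CDS-mapped reads: 5000523
median RPKM: 892
log2(RPKM/median) ~ rel_dist on chr1: slope -3.3699 +/- 0.1551 (p=1.49e-71)
implied dosage exponent k = 3.370
```

The generator planted k = 1.5; the *observed* global slope is steeper
because with positional bias switched on the highly expressed conserved
categories also sit near *ori*, so the global map conflates gene dosage
with category composition — exactly the superposition the per-category
quartile tables and rank tests are there to dissect.  With composition
controlled (single category, unbiased positions), the fitted slope
recovers the planted −k within its standard error; see the recovery suite
(`panpos recovery --seed 1`).

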