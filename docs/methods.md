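# Methods

## Scope and model

`bsascan` implements a bulked-segregant mapping analysis for a qualitative
trait in an F2 population: two inbred parents (a sterile line and a
fertility-restorer line), an F2 generation segregating for a single dominant
locus, and two sequencing pools built from the phenotype extremes — the
sterile plants (homozygous recessive; the "mut" pool) and fertile plants
(the "wt" pool).  The analysis entry point is post-variant-calling data: for
every SNP locus, four base-count quadruples (reads of A, C, G, T) — one per
parent and one per bulk.  Read alignment and variant calling are upstream of
this package.

## Locus filters

Two filter paths mirror the two scans:

* **SNP-index path**, applied in order, each locus charged to the first rule
  it fails: (1) multi-allelic loci; (2) loci with total read support below
  `min_bulk_depth` (default 4) in either bulk; (3) loci without a usable
  parental polymorphism.  "Usable" means both parents have reads and their
  consensus bases differ — without an orientation between the parental
  alleles the SNP-index is undefined.  The removal counts plus the retained
  count always partition the input (tested property).
* **ED path**: only the depth rule, followed by a *pool-divergence*
  selection — loci whose coarse genotype call (hom/het/hom by
  restorer-allele fraction) differs between the two bulks.

The genotype binning for pool divergence is a design choice with no single
convention.  `select_pool_divergent` defaults to the conventional
(0.25, 0.75) heterozygote band.  The pipeline's `ed_het_band` instead
defaults to (0.40, 0.60): at the study's design point (30-plant bulks,
~50× depth) the conventional band marks only ~10% of well-covered loci as
divergent, whereas the observed fraction for this kind of experiment is
~40% — which (0.40, 0.60) reproduces.  The band matters because the ED
threshold is empirical (below): it needs a genome-wide background of
divergent loci, not just the causal peak.

## Statistics and thresholds

**SNP-index.**  Per bulk, the fraction of reads carrying the
restorer-parent allele among reads matching either parental allele; error
bases are excluded from the denominator.  A bulk with zero informative reads
yields an absent point, never 0/0.  ΔSNP-index = index(mut) − index(wt).
With the orientation used here the causal Δ is negative (the sterile pool
lacks the restorer allele), so region calling uses |Δ|.

**Theoretical F2 threshold.**  Enumerating RR:Rr:rr at 1:2:1 and
conditioning on phenotype: the recessive bulk has restorer-allele fraction
0, the dominant bulk (1·2 + 2·1)/(3·2) = 2/3.  The expected |Δ| is exactly
2/3, reported at two decimals as 0.67.  `ThresholdSpec` keeps the exact
value for comparisons and the rounded value for display.  Note the exact
expectation lies *below* the rounded 0.67, so an observed causal |Δ| —
unbiased around 2/3 — exceeds 0.67 only about half the time at any depth;
with finite bulks and depths the simulated threshold (next) is the workable
rule, and it is what the end-to-end pipeline defaults to in the recovery
tests.

**Simulated threshold.**  Null |Δ| by Monte-Carlo: each bulk draws
2·`bulk_size` chromosomes at allele frequency 1/2 (no linkage), then reads
binomially at observed per-locus depth pairs; the threshold is a percentile
(default 0.95) of |Δ| over `n_rep` (default 10,000) replicates, fully
seed-determined.  Verified against exhaustive enumeration of the compound
binomial at small depth/bulk sizes.

**ED.**  Euclidean distance between the bulks' four-base frequency vectors,
computed over *all* reads (error bases included — the statistic is defined
on the full base composition).  Raw ED ∈ [0, √2].  The background-
suppression transform raises ED to `power` (default 5, the established
convention; configurable including 1); it is strictly monotone, so locus
ranking is power-invariant.  The association cutoff is median + 3·SD
(sample SD, n−1 denominator) of the *fitted* track values pooled over
chromosomes.  Whether such a cutoff should use raw or powered, locus-level
or fitted values is genuinely ambiguous in the field; this package pins it
to the fitted powered track and exposes the pieces (`ed_scan(power=...)`,
`ed_threshold`) so any variant is reconstructable.

## Fitting and region calling

Fitting is a sliding-window mean: evaluation points every `step_bp`
(default 10 kb) along each chromosome, each averaging raw values within
±`window_bp`/2 (default 1 Mb window).  Windows containing no loci are
absent, never zero.  Maximal runs of grid-adjacent evaluation points at or
above the threshold become regions; runs closer than `merge_gap_bp`
(default 0 — separate intervals stay separate) are merged.  Region size is
reported as (end − start)/10⁶ Mb to two decimals, matching the convention
of published association-region tables (e.g. 39,558,551–40,416,294 →
0.86 Mb).  Intersection of the two methods' region sets is plain interval
intersection with method labels unioned and sizes recomputed.

## Variant-context classification

Categories follow the precedence exonic > splicing > intronic >
upstream/downstream > intergenic, with `splice_bp` = 2 and `flank_bp` =
1,000 as the conventional distances (both exposed).  Coding effects for
SNVs come from codon translation with the standard genetic code
(synonymous / nonsynonymous / stop_gain / stop_loss); indel effects from
length difference mod 3 (frameshift / nonframeshift).  The reading frame is
taken from the concatenated CDS segments in transcription order.  A variant
touching several genes is annotated at the highest-precedence single
category so counts partition the variant set.  Exonic variants outside the
CDS, or without a reference sequence, get a category but no effect (with a
warning).

## The simulator

`simulate_f2_experiment` emulates the study design, not reads:

* **Genetics** — uniform marker placement; recombination between adjacent
  markers by Haldane's mapping function (no interference) at
  `recomb_cm_per_mb` (default 2.5 cM/Mb, a typical plant average); each F2
  plant is two independent F1 gametes; phenotype is dominant at the planted
  causal locus.  Bulks take the lowest-indexed `bulk_size` plants of each
  phenotype class, so bulking is reproducible; a phenotype class smaller
  than the bulk is an explicit error naming the deficit.
* **Sequencing** — per-locus depth ~ Poisson around the configured means
  (defaults 47.90× parents, 50.78× bulks, the design's stated averages);
  reads draw alleles binomially from the pool's true allele frequency; each
  read is misread to one of the three other bases uniformly with
  `seq_error_rate` (default 0.001, i.e. Q30-grade calls).  The error model
  is what gives ED its nonzero background.
* **Defaults** — 26 chromosomes (named in the cotton A/D-subgenome style),
  137,741 loci, 30-plant bulks, causal locus on chrD05.  The F2 population
  size from which extremes are drawn is a free design parameter (default
  200; a typical BSA population).

What it deliberately does not model: read-level artifacts (mapping bias,
indel realignment, duplicate reads), linked selection outside the single
causal locus, segregation distortion, and multi-allelic sites (those are
planted only by the filter-ledger fixture).  Passing tests on simulated
data therefore demonstrate the statistical machinery under the stated
model, not robustness to alignment pathology.

`make_filter_fixture` builds deterministic tables with exact numbers of
multi-allelic, low-depth and parent-absent loci (disjoint classes assigned
in filter order) so the filter ledger can be validated against published
counts exactly.

## Problem sizes in the test suite

Property and end-to-end tests run at reduced scale chosen to keep the suite
fast while leaving the conclusions meaningful: recovery tests use 20
replicates of 2,000 loci on five 60-Mb chromosomes with a 2-Mb fitting
window (sparser markers than a full experiment need a wider window than the
1-Mb default), 200 F2 plants and 30+30 bulks at the design depths.  At that
scale the intersected candidate region contains the planted locus in ≥ 90%
of replicates and covers ~3% of the genome on average.

## Known limitations

* The SNP-index orientation fixes "mut pool" = sterile bulk; datasets
  labelled the other way round flip the sign of Δ (magnitudes and regions
  are unaffected).
* The empirical median+3SD ED cutoff assumes the causal signal occupies a
  small fraction of fitted points; on very small genomes the SD term is
  inflated by the peak itself.
* Gene models take the first mRNA of each gene; alternative isoforms are
  not annotated separately.
* The theoretical 0.67 cutoff is an idealisation (see above); finite-depth
  experiments should prefer the simulated threshold.
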