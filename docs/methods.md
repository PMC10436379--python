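# Methods

## The problem

Cancer genomes lose DNA methylation over megabase-scale blocks —
partially methylated domains (PMDs) — while normal somatic cells hold a
near-uniform ~80% CpG methylation level. Nested inside PMDs sit smaller
preserved methylation islands (PMIs) that keep the normal level.
`pmdscape` implements the computations needed to map this structure from
sparse single-cell bisulfite data, to compare it across sample sources
(patients, cell lines), and to exploit it for detecting rare tumor DNA
in long-read sequencing of blood: a single long read spanning a PMD
carries enough CpG calls to classify its cell of origin.

## Domain calling

**Windowing.** Each source's CpG calls (pooled over its cells) are
averaged in 100-kb windows placed at every 200-bp offset that fits
entirely inside a chromosome. Windows intersecting a CpG island or an
assembly gap by ≥1 bp are discarded; windows covering fewer than 10
CpG sites are scored as missing. Window methylation is
(Σ methylated)/(Σ total) over the covered sites, computed with
per-chromosome prefix sums over the sorted site table, O(#sites +
#windows); naive per-window scans would be quadratic in practice at
genome scale.

**Thresholding.** The distribution of window methylation is summarized
by a binned Gaussian kernel density: counts on a 1,001-point grid over
[0, 1], smoothed with a Gaussian of bandwidth 0.03 (truncated at 12
standard deviations so the density stays strictly positive between
modes). Modes are local maxima with prominence ≥5% of the global
maximum. A source is *bimodal* when the two highest modes are separated
by ≥0.20; its hypomethylation threshold is then the density valley
between them. A *unimodal* source (normal cells) falls back to a fixed
60% threshold.

The valley between well-separated modes is typically a near-flat plateau
(populated only by windows straddling domain boundaries), so the exact
grid argmin is decided by sampling noise and is not reproducible across
runs. We therefore resolve near-ties toward lower methylation: among
grid points within 10% (relative, `valley_tolerance`) of the valley
minimum, the lowest methylation value is chosen. On sharply-valleyed
mixtures the near-tie band is ~0.001 wide and the choice coincides with
the argmin; on plateau valleys it pins the threshold to the
reproducible low edge of the plateau, which also minimizes how far PMD
boundary calls bleed into flanking methylated sequence.

**Segmentation.** Windows below the threshold are merged when
overlapping or book-ended (zero gap); merged runs shorter than 250 kb
are removed, yielding per-source PMDs. With a 200-bp step the book-end
rule only matters where discarded (CGI/gap) windows interrupt a run; a
CGI inside a hypomethylated region therefore splits the run, as each
fragment must clear the length filter on its own. The *total* PMD set is
the genomic union across sources. The *hypomethylated fraction* of a
source is the bp footprint of merged sub-threshold windows (before the
length filter) over the footprint of all scored windows; missing windows
count in neither numerator nor denominator.

**Core PMDs.** For every total-PMD interval and every source we pool the
source's calls over the interval, quantile-normalize the per-source
columns against each other (rank → mean of order statistics, ties
averaged — identical columns map to themselves), and flag a PMD as
*core* when its row mean of normalized values is below 25%. Methylation
is measured over the union interval in every source rather than each
source's own boundaries; at toy scale this mixes a few percent of
flanking background into each row, which is why planted core domains
should be large relative to the 100-kb window. Intervals with no
coverage in some source are excluded from eligibility and logged.

**PMIs.** Candidates are the gaps between consecutive per-source PMDs on
one chromosome (chromosome ends are not flanked); a candidate is a PMI
iff its length is strictly between 30 kb and 3 Mb. Total PMIs are the
cross-source union; a union PMI is *core* when it overlaps (≥1 bp) a
per-source PMI in every source. Reciprocal-overlap definitions were
considered and rejected as stricter than the uniformity requirement
implies; the ≥1 bp rule keeps core designation monotone under union.

## Long-read detector

Per read, *eligible* calls lie inside a PMD and outside CGIs. A read
passes with ≥30 eligible calls; a passing read is hypomethylated when
its mean eligible methylation is below 0.50. The published procedure
does not pin the per-read cut; 0.50 sits midway between the PMD state
(20–40%) and the normal background (~80%) and is exposed in the config
and echoed in CLI output. A sample's signal is 100 × hypomethylated /
passing reads, defined only when run QC passes: lambda spike-in
methylation (pooled over control-read calls) below 1% and at least 300
(metastatic) or 400 (localized) PMD-aligned reads, where "PMD-aligned"
means ≥1 eligible call. Healthy donors are QC'd with the floor of the
patient cohort they accompany (default 300; override via `min_reads`).
Cohorts are compared by an equal-variance two-tailed t-test on signal
percents, and each cohort's maximum is reported, since an operating
threshold "above all healthy donors" is the healthy maximum.

The spike-in model scores labelled reads by 1 − mean eligible
methylation and sweeps every observed score into a precision–recall
curve; the area integrates the curve along the threshold sweep by
trapezoid (no interpolation between operating points, so tied-recall
steps contribute zero width). Curves are reported overall and per
stratum of eligible-call count (nearest of ~5/10/30/50), quantifying the
gain in precision from longer reads.

## Array metrics, CNV score, heterogeneity, expression screen

Probe beta values are averaged into fixed 10-kb bins (`[k·10⁴,
(k+1)·10⁴)`, probe-free bins absent); bins with mean normal-sample
methylation <70% are removed; a sample's global (or locus) methylation
is the fraction of retained bins strictly above 50%. The reference locus
`CD1A_IFI16_LOCUS` (chr1:158,130,000–158,340,000, hg19) ships as a named
constant; any interval is accepted.

The CNV score of a binned integer copy-number profile is the bp-weighted
mean of |cᵢ − 2| — zero for diploid, invariant under bin splitting.
Heterogeneity is assessed two ways: mean pairwise bp-Jaccard of per-cell
hypomethylated interval sets within a group (two empty sets score 1,
logged), and mean pairwise Pearson correlation over features non-missing
in both cells, with a leave-one-cell-out jackknife standard error,
SE = √((n−1)/n · Σ(θᵢ − θ̄)²). Spearman is available via `method=`.

The expression screen drops genes whose 95th-percentile expression is
below 1 (FPKM-like floor), applies an equal-variance two-tailed t-test
per remaining gene, Benjamini–Hochberg FDR across tested genes, and
calls significance at FDR < 0.1 with direction = sign(tumor − normal
mean). Genes with zero variance in both groups get p = 1 (logged) — a
degenerate-input convention, not an inference. Gene-set enrichment is
the upper-tail hypergeometric probability P(X ≥ k) of the overlap
between significant genes and each set within the chosen universe
(BH-adjusted values reported alongside raw p); whether the universe is
all tested genes or all annotated genes is the caller's choice.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes:

* CpG sites at mean spacing 100 bp (exponential gaps, ≥2 bp), 5× denser
  inside CGIs; CGIs ~1 per Mb, 0.5–2 kb, placed outside planted PMDs by
  default because PMDs are gene- and CGI-poor (`cgi_in_pmd_factor`
  re-admits them).
* Background per-site methylation drawn once per site from Beta(16, 4)
  (mean 0.80) — site heterogeneity with binary per-cell calls — then
  each cell observes each site with probability 0.3 (sparse single-cell
  coverage) and emits one Bernoulli call. A per-call beta-binomial was
  rejected as adding a parameter the binary single-cell data cannot
  constrain.
* Planted PMDs carry a single per-interval state drawn uniform
  [0.20, 0.40]; nested PMIs revert to background.
* The default toy genome is 2 × 10 Mb with 6 Mb (30%) in the PMD state:
  a solid 3-Mb PMD on chr1 and a 4.5-Mb PMD on chr2 interrupted by a
  1.5-Mb PMI. Sizes are set by window resolution: each domain edge is
  localized to ~half a 100-kb window, so planted domains must be
  multi-Mb for bp-level recovery (Jaccard ≥0.95 PMD, ≥0.90 PMI) to be a
  meaningful yardstick at desk scale. `multisource_spec` adds one shared
  deep PMD (state 0.20, the designation target) plus one private PMD per
  source to create core/non-core contrast.
* Long reads are placed inside supplied PMDs (length-weighted), carry
  5/10/30/50 CpG calls, and draw calls at a PMD-state probability
  (tumor origin) or the background (normal origin); origin labels are
  returned for scoring. Lambda control reads use a 0.005 per-call error
  rate. Copy-number, beta-matrix and expression generators plant
  segments, hypomethylated intervals and two-fold-down genes
  respectively, always returning the planted truth.

All generators are pure functions of (spec, seed). What passing tests on
these data do **not** show: robustness to real-data features the
generators omit — CpG density waves, replication-timing–correlated
methylation gradients at PMD edges (planted edges are step functions),
copy-number–methylation interactions, cell-to-cell coverage imbalance,
bisulfite conversion failure, and mapping artifacts. Recovery scores
here bound algorithmic, not biological, error.

## Problem sizes and runtime

The shipped test and benchmark configurations use the 20-Mb toy genome
(~200k CpG sites, 10 cells, ~88k scored windows per source), 4-source
core designation on an 18-Mb genome, and 20k-read spike-in mixtures —
sizes at which the full suite runs in well under a minute of compute per
stage while leaving every statistical check adequately powered.
Full-genome inputs differ only in scale; the windowing is linear in
sites plus windows.

## Known limitations

* Threshold selection needs ≥500 scored windows and errors below that;
  very small genomes must lower `min_windows` deliberately.
* Valley placement on plateau valleys is resolved by a tolerance rule;
  the resulting threshold is reproducible but sits at the plateau's low
  edge by construction, a conservative (under-calling) choice.
* Core-PMD methylation uses union intervals, slightly diluting deeply
  hypomethylated sources whose own domains are narrower.
* The per-read hypomethylation cut and the eligible-read definition
  ("≥1 eligible call") are pragmatic choices exposed in the config, not
  published constants.
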