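# pmdscape

Partially methylated domain (PMD) calling, core-domain designation, and
rare-cell hypomethylation detection from sparse CpG methylation calls.

Cancer genomes lose DNA methylation over megabase-scale blocks (PMDs)
while normal cells stay near 80% methylation; smaller preserved
methylation islands (PMIs) inside PMDs keep the normal level. This
package is for epigenomics analysts working with single-cell or bulk
bisulfite data and Nanopore-style per-read methylation calls who need
to map that domain structure, compare it across patients and cell
lines, and use it to detect rare tumor reads in blood.

## What it computes

For each sample source *s* with window-methylation values m(w):

* **Windowing** — mean methylation in 100-kb windows at 200-bp offsets,
  excluding windows that touch CpG islands or assembly gaps, masking
  windows with <10 covered CpGs.
* **Threshold** — t(s) = density valley between the two modes of a
  bimodal window-methylation distribution (kernel density, bandwidth
  0.03); t(s) = 0.60 for unimodal sources.
* **PMDs** — merged runs of windows with m(w) < t(s), length ≥ 250 kb;
  the total set is the union over sources. A PMD is **core** when its
  mean quantile-normalized methylation across sources is <25%.
* **PMIs** — gaps between consecutive per-source PMDs with
  30 kb < length < 3 Mb (strict); core PMIs overlap a per-source PMI in
  every source.
* **CNV score** — bp-weighted mean of |cᵢ − 2| over copy-number bins.
* **Array metrics** — fraction of 10-kb beta-value bins >50% methylated
  (after removing bins with normal-tissue mean <70%), genome-wide or at
  a locus.
* **Long-read detector** — per-read mean methylation over calls inside
  PMDs and outside CGIs; reads with ≥30 such calls are classified
  hypomethylated below 0.50; a sample's signal is the percent of
  passing reads classified hypomethylated, gated by run QC (lambda
  spike-in <1%, ≥300/400 PMD-aligned reads for metastatic/localized
  cohorts), with a spike-in precision–recall model for validation.
* **Expression screen** — 95th-percentile floor of 1, equal-variance
  two-tailed t-test, Benjamini–Hochberg FDR <0.1, hypergeometric
  gene-set enrichment.

A synthetic-data module generates every input with planted truth
(domains, read origins, copy-number segments, differential genes) so
the whole pipeline is testable end to end. See `docs/methods.md` for
the model details and design choices.

## Worked example

```sh
pmdscape simulate --seed 3 --kind tumor --out sim/
pmdscape call-pmds sim/tumor_0.c*.cov \
    --chrom-sizes sim/chrom.sizes --cgi-bed sim/cgi.bed \
    --gap-bed sim/gaps.bed \
    --sources tumor_0,tumor_0,tumor_0,tumor_0,tumor_0,tumor_0,tumor_0,tumor_0,tumor_0,tumor_0 \
    --out pmds.bed
```

prints

```
tumor_0: bimodal, threshold 0.494, 3 PMDs
total PMDs: 3 -> pmds.bed
```

The source's window-methylation distribution was bimodal, so the
threshold sits at the density valley (0.494) rather than the 60%
unimodal fallback; three merged sub-threshold runs survived the 250-kb
filter. The toy genome plants 6 Mb of PMD-state sequence as three
segments (one of its two planted PMDs is interrupted by a 1.5-Mb PMI),
and the calls land within about half a window of the planted edges:

```
chr1    958000   4043400  PMD/total      (planted 1.00–4.00 Mb)
chr2    1951000  3546000  PMD/total      (planted 2.00–3.50 Mb)
```

Calling PMIs on those PMDs recovers the planted island:

```sh
pmdscape call-pmis pmds.bed --out pmis.bed
# total PMIs: 1; core PMIs: 1
# chr2  3546000  4955200  PMI/total      (planted 3.50–5.00 Mb)
```

The same workflow is available as library calls
(`generate_methylome`, `build_window_track`, `select_threshold`,
`call_pmds_per_source`, …); each returns plain dataclasses and pandas
frames.

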