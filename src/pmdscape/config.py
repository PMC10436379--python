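"""Pipeline-wide parameters.

Every tunable the pipeline exposes lives in :class:`PipelineConfig` with
its default value; functions accept a config object so a study's choices
are recorded in one place. Defaults follow the published methylation-domain
calling conventions for single-cell bisulfite data:

* 100-kb windows at 200-bp offsets, discarded over CpG islands and
  assembly gaps, scored only with >=10 CpG calls;
* hypomethylation threshold at the density valley of a bimodal
  window-methylation distribution, 60% fallback for unimodal sources;
* PMDs >=250 kb; PMIs strictly between 30 kb and 3 Mb; core PMDs below
  25% mean quantile-normalized methylation across sources;
* per-read filter of >=30 eligible CpG calls, 0.50 hypomethylation cut;
* run QC: lambda spike-in methylation <1%, >=300 (metastatic) / >=400
  (localized) PMD-aligned reads; cell QC: >4M unique CpGs, >98%
  bisulfite conversion;
* 10-kb array bins, 70% normal-tissue floor, >50% hypermethylation cut;
* expression screen: 95th-percentile floor of 1, equal-variance t-test,
  BH FDR < 0.1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    # windowing
    window_size: int = 100_000
    window_step: int = 200
    min_cpgs_per_window: int = 10

    # threshold selection (binned Gaussian KDE valley finder)
    fallback_threshold: float = 0.60
    min_windows: int = 500
    density_grid_points: int = 1001
    density_bandwidth: float = 0.03
    mode_prominence: float = 0.05   # fraction of the global density maximum
    mode_min_separation: float = 0.20
    valley_tolerance: float = 0.10  # near-tie band around the valley minimum

    # domain geometry
    min_pmd_length: int = 250_000
    pmi_min_length: int = 30_000    # exclusive
    pmi_max_length: int = 3_000_000  # exclusive
    core_pmd_cutoff: float = 0.25

    # long-read detector
    min_cpgs_per_read: int = 30
    read_hypo_threshold: float = 0.50
    min_reads_metastatic: int = 300
    min_reads_localized: int = 400
    lambda_max: float = 0.01

    # cell-level QC
    qc_min_unique_cpgs: int = 4_000_000
    qc_min_conversion: float = 0.98

    # array metrics
    array_bin: int = 10_000
    array_normal_floor: float = 0.70
    array_hypo_cut: float = 0.50

    # expression screen
    de_fdr: float = 0.10
    de_expr_floor: float = 1.0
    de_expr_floor_percentile: float = 95.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_size", "window_step", "min_pmd_length",
                     "pmi_min_length", "pmi_max_length", "array_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_step > self.window_size:
            raise ValueError("window_step must not exceed window_size")
        for name in ("fallback_threshold", "core_pmd_cutoff", "read_hypo_threshold",
                     "lambda_max", "qc_min_conversion", "array_normal_floor",
                     "array_hypo_cut", "de_fdr", "mode_prominence",
                     "mode_min_separation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")

    def min_reads_for_cohort(self, cohort: str) -> int:
        """Cohort-specific floor on PMD-aligned read count.

        Healthy donors are QC'd against the floor of the patient cohort they
        are compared with; the default (metastatic context) applies the
        lower floor.
        """
        table = {
            "metastatic": self.min_reads_metastatic,
            "localized": self.min_reads_localized,
            "healthy": self.min_reads_metastatic,
        }
        try:
            return table[cohort]
        except KeyError:
            raise ValueError(f"unknown cohort {cohort!r}") from None

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


DEFAULT_CONFIG = PipelineConfig()

#: the CD1A-IFI16 reference locus for the array locus metric (hg19)
CD1A_IFI16_LOCUS = ("chr1", 158_130_000, 158_340_000)
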