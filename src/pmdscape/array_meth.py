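"""Methylation-array (450K-style) binning metrics.

Probe beta values are averaged into fixed 10-kb non-overlapping genomic
bins; bins without probes are absent, and bins whose mean normal-tissue
methylation falls below 70% are removed before scoring. A sample's
global methylation level is the fraction of retained bins exceeding 50%
methylation, optionally restricted to a locus of interest.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig, CD1A_IFI16_LOCUS
from .model import BetaMatrix

log = logging.getLogger(__name__)

__all__ = ["bin_beta_matrix", "filter_bins_by_normal",
           "global_methylation", "locus_methylation", "CD1A_IFI16_LOCUS"]


class BinnedBeta:
    """Bin-level methylation: MultiIndex (chrom, bin_start) x samples."""

    def __init__(self, values: pd.DataFrame, bin_size: int, groups: dict):
        self.values = values
        self.bin_size = bin_size
        self.groups = dict(groups)

    def samples_in(self, group: str) -> list:
        return [s for s in self.values.columns if self.groups[s] == group]


def bin_beta_matrix(b: BetaMatrix, cfg: PipelineConfig = DEFAULT_CONFIG) -> BinnedBeta:
    """Mean beta per sample within each ``array_bin``-sized genomic bin.

    Bin *k* covers ``[k*bin, (k+1)*bin)``; probes are assigned by
    position; bins holding no probes are absent from the result. NaN
    probe values are ignored per sample.
    """
    bin_size = cfg.array_bin
    key = pd.MultiIndex.from_arrays(
        [b.probes["chrom"].to_numpy(),
         (b.probes["pos"].to_numpy(np.int64) // bin_size) * bin_size],
        names=["chrom", "bin_start"])
    vals = b.values.set_axis(key, axis=0)
    binned = vals.groupby(level=["chrom", "bin_start"]).mean()
    return BinnedBeta(binned.sort_index(), bin_size, b.groups)


def filter_bins_by_normal(binned: BinnedBeta,
                          cfg: PipelineConfig = DEFAULT_CONFIG) -> BinnedBeta:
    """Drop bins whose mean over normal samples is below the normal floor."""
    normals = binned.samples_in("normal")
    if not normals:
        raise ValueError("no normal samples to anchor the bin filter")
    normal_mean = binned.values[normals].mean(axis=1)
    keep = normal_mean >= cfg.array_normal_floor
    return BinnedBeta(binned.values[keep], binned.bin_size, binned.groups)


def _fraction_above(vals: pd.Series, cut: float) -> float:
    v = vals.dropna()
    if not len(v):
        return np.nan
    return float((v > cut).mean())


def global_methylation(binned: BinnedBeta, sample: str,
                       cfg: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Fraction of retained bins with methylation strictly above 50%."""
    if sample not in binned.values.columns:
        raise KeyError(sample)
    return _fraction_above(binned.values[sample], cfg.array_hypo_cut)


def locus_methylation(binned: BinnedBeta, sample: str,
                      interval: tuple = CD1A_IFI16_LOCUS,
                      cfg: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Same metric restricted to bins inside ``interval`` (chrom, start, end).

    NaN (logged) when the interval holds no retained bins.
    """
    if sample not in binned.values.columns:
        raise KeyError(sample)
    chrom, start, end = interval
    idx = binned.values.index
    mask = ((idx.get_level_values("chrom") == chrom)
            & (idx.get_level_values("bin_start") >= start)
            & (idx.get_level_values("bin_start") < end))
    sub = binned.values.loc[mask, sample]
    if not len(sub.dropna()):
        log.warning("locus %s:%d-%d holds no retained bins for sample %s",
                    chrom, start, end, sample)
        return np.nan
    return _fraction_above(sub, cfg.array_hypo_cut)
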