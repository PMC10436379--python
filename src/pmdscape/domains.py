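"""PMD/PMI segmentation: windowing, thresholding, merging, core designation.

The calling pipeline per sample source:

1. pool the source's CpG calls into overlapping 100-kb windows placed at
   200-bp offsets, discarding windows that intersect CpG islands or
   assembly gaps and masking windows with fewer than 10 covered CpGs;
2. set the source's hypomethylation threshold at the density valley
   between the two modes of a bimodal window-methylation distribution
   (60% fallback when unimodal);
3. merge overlapping/book-ended sub-threshold windows into per-source
   PMDs and drop those shorter than 250 kb;
4. union per-source PMDs into the total set; quantile-normalize
   per-source methylation over total PMDs and flag PMDs whose mean
   normalized methylation stays below 25% in every source as "core";
5. call PMIs as inter-PMD gaps strictly between 30 kb and 3 Mb, and
   flag union PMIs overlapped by a per-source PMI in every source as
   core.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.stats import rankdata

from . import intervals as iv
from .config import DEFAULT_CONFIG, PipelineConfig
from .model import (CpGCallTable, DomainSet, GenomeLayout, SourceThreshold,
                    WindowTrack)

log = logging.getLogger(__name__)

__all__ = [
    "build_window_track", "select_threshold", "call_pmds_per_source",
    "union_domains", "designate_core_pmds", "core_pmds_from_matrix",
    "call_pmis_per_source", "designate_core_pmis", "hypomethylated_fraction",
    "quantile_normalize_columns", "hypomethylated_windows", "pmd_methylation_matrix",
]


# ---------------------------------------------------------------------------
# windowing

def _window_track_one_source(calls: CpGCallTable, layout: GenomeLayout,
                             cfg: PipelineConfig, source: str) -> WindowTrack:
    pooled = calls.pooled_by_site()
    frames = []
    W, step = cfg.window_size, cfg.window_step
    for chrom, length in layout.chromosomes:
        if length < W:
            continue
        starts = np.arange(0, length - W + 1, step, dtype=np.int64)
        keep = iv.ranges_clear(starts, W, layout.excluded(chrom))
        starts = starts[keep]
        if len(starts) == 0:
            continue
        sub = pooled[pooled["chrom"] == chrom]
        pos = sub["pos"].to_numpy(np.int64)
        cm = np.concatenate(([0], np.cumsum(sub["meth"].to_numpy(np.int64))))
        ct = np.concatenate(([0], np.cumsum(sub["total"].to_numpy(np.int64))))
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + W, side="left")
        n_sites = hi - lo
        tot = ct[hi] - ct[lo]
        meth = np.where(tot > 0, (cm[hi] - cm[lo]) / np.maximum(tot, 1), np.nan)
        meth = np.where(n_sites >= cfg.min_cpgs_per_window, meth, np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "meth": meth,
            "n_cpg": n_sites.astype(np.int64)}))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["chrom", "start", "meth", "n_cpg"]))
    return WindowTrack(source=source, df=df, window_size=W, window_step=step)


def build_window_track(calls: CpGCallTable, layout: GenomeLayout,
                       cfg: PipelineConfig = DEFAULT_CONFIG) -> dict:
    """Per-source sliding-window mean methylation.

    Windows are placed at every ``window_step`` offset fully inside the
    chromosome; windows intersecting any CGI or gap interval are absent;
    window methylation pools (sum methylated)/(sum total) over all cells
    of the source; windows covering fewer than ``min_cpgs_per_window``
    CpG sites are masked as missing.

    Returns ``{source: WindowTrack}``.
    """
    sources = calls.source_names
    if not sources:
        raise ValueError("call table contains no sources")
    return {s: _window_track_one_source(calls.for_source(s), layout, cfg, s)
            for s in sources}


# ---------------------------------------------------------------------------
# threshold selection

def _density_on_grid(values: np.ndarray, cfg: PipelineConfig) -> tuple:
    """Binned Gaussian kernel density of window methylation on [0, 1]."""
    n_grid = cfg.density_grid_points
    grid = np.linspace(0.0, 1.0, n_grid)
    step = 1.0 / (n_grid - 1)
    idx = np.clip(np.round(values / step).astype(int), 0, n_grid - 1)
    counts = np.bincount(idx, minlength=n_grid).astype(float)
    # wide truncation keeps the density strictly positive between modes,
    # so valley finding never degenerates on an exact-zero plateau
    density = gaussian_filter1d(counts, sigma=cfg.density_bandwidth / step,
                                mode="constant", truncate=12.0)
    return grid, density


def select_threshold(track: WindowTrack,
                     cfg: PipelineConfig = DEFAULT_CONFIG) -> SourceThreshold:
    """Source hypomethylation threshold from the window-methylation density.

    Modes are local density maxima with prominence at least
    ``mode_prominence`` of the global maximum; the source is bimodal when
    the two highest qualifying modes are separated by at least
    ``mode_min_separation``, in which case the threshold sits at the
    density valley strictly between them. Valleys between well-separated
    modes are typically near-flat plateaus whose exact argmin is decided
    by sampling noise, so near-ties are resolved toward the lower
    methylation value: among grid points within ``valley_tolerance``
    (relative) of the valley minimum, the lowest methylation wins.
    Unimodal sources fall back to the 60% threshold.
    """
    values = track.values
    if len(values) < cfg.min_windows:
        raise ValueError(
            f"source {track.source!r}: only {len(values)} scored windows "
            f"(< {cfg.min_windows}); aborting threshold selection")
    grid, density = _density_on_grid(values, cfg)
    peaks, _ = find_peaks(density, prominence=cfg.mode_prominence * density.max())
    modes = tuple(grid[p] for p in sorted(peaks, key=lambda p: -density[p]))
    if len(modes) >= 2:
        m1, m2 = sorted(modes[:2])
        if m2 - m1 >= cfg.mode_min_separation:
            in_between = (grid > m1) & (grid < m2)
            seg = np.where(in_between, density, np.inf)
            dmin = float(seg.min())
            near_tie = in_between & (density <= dmin * (1.0 + cfg.valley_tolerance))
            t = float(grid[int(np.argmax(near_tie))])  # lowest near-tied point
            return SourceThreshold(source=track.source, modality="bimodal",
                                   threshold=t, grid=grid, density=density,
                                   modes=(m1, m2))
    return SourceThreshold(source=track.source, modality="unimodal",
                           threshold=cfg.fallback_threshold,
                           grid=grid, density=density,
                           modes=modes[:1])


# ---------------------------------------------------------------------------
# PMD calling

def hypomethylated_windows(track: WindowTrack, thr: SourceThreshold) -> dict:
    """Merged intervals of sub-threshold windows (before the length filter)."""
    df = track.scored_windows()
    hypo = df[df["meth"] < thr.threshold]
    out = {}
    for chrom, sub in hypo.groupby("chrom", sort=True):
        s = sub["start"].to_numpy(np.int64)
        out[str(chrom)] = iv.merge(np.column_stack((s, s + track.window_size)))
    return out


def call_pmds_per_source(track: WindowTrack, thr: SourceThreshold,
                         cfg: PipelineConfig = DEFAULT_CONFIG) -> DomainSet:
    """Merge sub-threshold windows and apply the minimum-length filter."""
    merged = hypomethylated_windows(track, thr)
    kept = {c: a[(a[:, 1] - a[:, 0]) >= cfg.min_pmd_length]
            for c, a in merged.items()}
    return DomainSet.from_chrom_dict(kept, "PMD", scope="per-source",
                                     source=track.source)


def union_domains(per_source: list) -> DomainSet:
    """Genomic union of per-source domain sets (overlaps/book-ends merged)."""
    if not per_source:
        raise ValueError("need at least one per-source domain set")
    kind = per_source[0].kind
    u = iv.genome_union(*[d.by_chrom() for d in per_source])
    return DomainSet.from_chrom_dict(u, kind, scope="total")


def hypomethylated_fraction(track: WindowTrack, thr: SourceThreshold) -> float:
    """Percent of the scored genome inside merged hypomethylated windows.

    Computed before the PMD minimum-length filter; the denominator is the
    bp footprint of all scored (non-missing) windows.
    """
    df = track.scored_windows()
    if not len(df):
        raise ValueError("no scored windows")
    scored = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        s = sub["start"].to_numpy(np.int64)
        scored[str(chrom)] = iv.merge(np.column_stack((s, s + track.window_size)))
    hypo = hypomethylated_windows(track, thr)
    denom = iv.genome_total_bp(scored)
    num = iv.genome_total_bp(hypo)
    return 100.0 * num / denom


# ---------------------------------------------------------------------------
# quantile normalization and core PMDs

def quantile_normalize_columns(m: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across columns.

    Each column is mapped onto the reference distribution formed by the
    row means of the column-sorted matrix; tied values receive the mean
    of the reference values at their tied ranks. Identical columns map
    to themselves.
    """
    x = m.to_numpy(float)
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    ranks_axis = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, ranks_axis, ref)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def pmd_methylation_matrix(total: DomainSet, calls: CpGCallTable) -> pd.DataFrame:
    """Pooled per-source methylation over each total-PMD interval.

    Rows indexed ``chrom:start-end``; NaN where a source has no covered
    CpG in the interval.
    """
    sources = calls.source_names
    idx = [f"{r.chrom}:{r.start}-{r.end}" for r in total.df.itertuples()]
    mat = pd.DataFrame(np.nan, index=idx, columns=sources)
    for src in sources:
        pooled = calls.for_source(src).pooled_by_site()
        for chrom, sub in pooled.groupby("chrom", sort=False):
            rows = total.df[total.df["chrom"] == chrom]
            if not len(rows):
                continue
            pos = sub["pos"].to_numpy(np.int64)
            cm = np.concatenate(([0], np.cumsum(sub["meth"].to_numpy(np.int64))))
            ct = np.concatenate(([0], np.cumsum(sub["total"].to_numpy(np.int64))))
            lo = np.searchsorted(pos, rows["start"].to_numpy(np.int64))
            hi = np.searchsorted(pos, rows["end"].to_numpy(np.int64))
            tot = ct[hi] - ct[lo]
            meth = np.where(tot > 0, (cm[hi] - cm[lo]) / np.maximum(tot, 1), np.nan)
            for k, r in enumerate(rows.itertuples()):
                mat.loc[f"{r.chrom}:{r.start}-{r.end}", src] = meth[k]
    return mat


def core_pmds_from_matrix(m: pd.DataFrame, cutoff: float = 0.25) -> tuple:
    """Core flags from a per-PMD x per-source methylation matrix.

    Columns are quantile-normalized against each other; a PMD is core
    when its row mean of normalized values is below ``cutoff``. Rows with
    any missing source are excluded from eligibility (flag False, logged).

    Returns ``(core_flags: Series[bool], normalized: DataFrame)``.
    """
    complete = m.dropna()
    dropped = len(m) - len(complete)
    if dropped:
        log.warning("%d PMD(s) lack coverage in some source; excluded from "
                    "core eligibility", dropped)
    norm = quantile_normalize_columns(complete)
    row_mean = norm.mean(axis=1)
    flags = pd.Series(False, index=m.index)
    flags.loc[row_mean.index] = row_mean < cutoff
    norm_full = norm.reindex(m.index)
    return flags, norm_full


def designate_core_pmds(total: DomainSet, calls: CpGCallTable,
                        cfg: PipelineConfig = DEFAULT_CONFIG) -> tuple:
    """Quantile-normalized core-PMD designation across sources.

    Returns ``(core: DomainSet, matrix: DataFrame, normalized: DataFrame)``
    where ``matrix`` is the raw per-PMD x per-source pooled methylation.
    """
    mat = pmd_methylation_matrix(total, calls)
    flags, norm = core_pmds_from_matrix(mat, cutoff=cfg.core_pmd_cutoff)
    out = total.df.copy()
    out["core"] = flags.to_numpy()
    out["mean_qn_meth"] = norm.mean(axis=1).to_numpy()
    core = DomainSet(out[out["core"]].drop(columns="core"),
                     kind="PMD", scope="core")
    return core, mat, norm


# ---------------------------------------------------------------------------
# PMIs

def call_pmis_per_source(pmds: DomainSet,
                         cfg: PipelineConfig = DEFAULT_CONFIG) -> DomainSet:
    """Inter-PMD gaps strictly between the PMI length bounds.

    A candidate is the gap between two consecutive PMDs on one
    chromosome; chromosome ends are not flanked and never yield PMIs.
    """
    out = {}
    for chrom, arr in pmds.by_chrom().items():
        if len(arr) < 2:
            continue
        gaps = np.column_stack((arr[:-1, 1], arr[1:, 0]))
        lengths = gaps[:, 1] - gaps[:, 0]
        keep = (lengths > cfg.pmi_min_length) & (lengths < cfg.pmi_max_length)
        if keep.any():
            out[chrom] = gaps[keep]
    return DomainSet.from_chrom_dict(out, "PMI", scope="per-source",
                                     source=pmds.source)


def designate_core_pmis(per_source_pmis: list) -> tuple:
    """Total (union) PMIs plus the core subset overlapped in every source.

    A union interval is core when it overlaps (>=1 bp) at least one
    per-source PMI in every source. Returns ``(total, core)``.
    """
    if not per_source_pmis:
        raise ValueError("need at least one per-source PMI set")
    total = union_domains(per_source_pmis)
    src_sets = [d.by_chrom() for d in per_source_pmis]
    core_rows = []
    for r in total.df.itertuples():
        q = np.array([[r.start, r.end]], dtype=np.int64)
        if all(iv.overlap_bp(q, s.get(r.chrom, np.empty((0, 2), np.int64))) > 0
               for s in src_sets):
            core_rows.append((r.chrom, r.start, r.end))
    core = DomainSet(pd.DataFrame(core_rows, columns=["chrom", "start", "end"]),
                     kind="PMI", scope="core")
    return total, core
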