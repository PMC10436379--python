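"""Rare-cell hypomethylation detection from long-read methylation calls.

A tumor cell's genome is hypomethylated across PMDs while normal blood
cells stay near 80% methylation there, so a single long read spanning a
PMD carries enough CpG calls to reveal its cell of origin. The detector:

* averages each read's binary CpG calls over *eligible* sites — those
  inside predefined PMDs and outside CpG islands;
* keeps reads with at least 30 eligible calls and flags those whose
  mean methylation falls below the per-read cut (default 0.50);
* reports a sample's signal as the percent of passing reads flagged
  hypomethylated, gated by run QC (lambda spike-in methylation <1%,
  cohort-specific minimum of PMD-aligned reads);
* validates the approach on labelled in-silico spike-in mixtures via
  precision-recall curves stratified by CpG calls per read.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import precision_recall_curve

from . import intervals as iv
from .config import DEFAULT_CONFIG, PipelineConfig
from .model import DomainSet, GenomeLayout, LongReadRecord, SampleSignal

log = logging.getLogger(__name__)

__all__ = ["read_methylation", "filter_and_classify", "sample_signal",
           "cohort_compare", "spikein_pr_model"]


def _eligible_mask(r: LongReadRecord, pmd_by_chrom: dict,
                   layout: GenomeLayout) -> np.ndarray:
    pmds = pmd_by_chrom.get(r.chrom, np.empty((0, 2), np.int64))
    in_pmd = iv.points_in(r.positions, pmds)
    cgi = layout.cgi_intervals.get(r.chrom, np.empty((0, 2), np.int64))
    in_cgi = iv.points_in(r.positions, cgi)
    return in_pmd & ~in_cgi


def read_methylation(r: LongReadRecord, pmds: DomainSet,
                     layout: GenomeLayout) -> tuple:
    """Mean methylation over eligible calls and the eligible-call count.

    Eligible calls lie inside a PMD interval and outside CGI intervals.
    Mean is NaN when no call is eligible.
    """
    if r.is_lambda:
        raise ValueError("lambda control reads have no genomic eligibility")
    mask = _eligible_mask(r, pmds.by_chrom(), layout)
    n = int(mask.sum())
    mean = float(r.calls[mask].mean()) if n else float("nan")
    return mean, n


def filter_and_classify(reads, pmds: DomainSet, layout: GenomeLayout,
                        cfg: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-read eligibility, filter and hypomethylation classification.

    A read passes with at least ``min_cpgs_per_read`` eligible calls and
    is hypomethylated when its eligible-call mean methylation is below
    ``read_hypo_threshold``. Lambda control reads never pass the genomic
    filter.
    """
    pmd_by_chrom = pmds.by_chrom()
    rows = []
    for r in reads:
        if r.is_lambda:
            rows.append((r.read_id, True, 0, np.nan, False, False))
            continue
        mask = _eligible_mask(r, pmd_by_chrom, layout)
        n = int(mask.sum())
        mean = float(r.calls[mask].mean()) if n else np.nan
        passes = n >= cfg.min_cpgs_per_read
        hypo = bool(passes and mean < cfg.read_hypo_threshold)
        rows.append((r.read_id, False, n, mean, passes, hypo))
    return pd.DataFrame(rows, columns=["read_id", "is_lambda", "n_eligible",
                                       "mean_meth", "passes", "hypomethylated"])


def lambda_methylation(reads) -> float:
    """Methylated fraction over all calls of lambda control reads (NaN if none)."""
    n_meth = n_tot = 0
    for r in reads:
        if r.is_lambda:
            n_meth += int(r.calls.sum())
            n_tot += r.n_calls
    return n_meth / n_tot if n_tot else float("nan")


def sample_signal(reads, cohort: str, pmds: DomainSet, layout: GenomeLayout,
                  cfg: PipelineConfig = DEFAULT_CONFIG,
                  sample_id: str = None, min_reads: int = None) -> SampleSignal:
    """Sample-level hypomethylation signal with run QC.

    QC passes when lambda spike-in methylation is below ``lambda_max``
    and the number of PMD-aligned reads (>=1 eligible call) meets the
    cohort floor (``min_reads`` overrides it, e.g. for healthy donors
    matched to a localized cohort). Signal (percent) is defined only for
    QC-passing samples.
    """
    floor = min_reads if min_reads is not None else cfg.min_reads_for_cohort(cohort)
    per_read = filter_and_classify(reads, pmds, layout, cfg)
    genomic = per_read[~per_read["is_lambda"]]
    n_in_pmds = int((genomic["n_eligible"] >= 1).sum())
    n_pass = int(genomic["passes"].sum())
    n_hypo = int(genomic["hypomethylated"].sum())
    lam = lambda_methylation(reads)
    qc = (not np.isnan(lam)) and lam < cfg.lambda_max and n_in_pmds >= floor
    sid = sample_id or (reads[0].sample_id if reads else "sample")
    signal = 100.0 * n_hypo / n_pass if (qc and n_pass) else (0.0 if qc else None)
    return SampleSignal(sample_id=sid, cohort=cohort,
                        n_reads_in_pmds=n_in_pmds, n_reads_passing=n_pass,
                        n_reads_hypomethylated=n_hypo,
                        lambda_methylation=float(lam), qc_pass=bool(qc),
                        signal=signal)


def cohort_compare(signals, group_a: str, group_b: str) -> dict:
    """Equal-variance two-tailed t-test between two cohorts' signal percents.

    Only QC-passing samples enter; each group's maximum is also reported
    (the operating threshold "above all healthy donors" is the healthy
    group's max). Degenerate variance in both groups yields p = 1 with a
    warning.
    """
    xs = [s.signal for s in signals if s.cohort == group_a and s.qc_pass]
    ys = [s.signal for s in signals if s.cohort == group_b and s.qc_pass]
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each cohort needs >=2 QC-passing samples")
    x, y = np.array(xs, float), np.array(ys, float)
    if x.var() == 0 and y.var() == 0:
        warnings.warn("zero variance in both cohorts; p set to 1")
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(x, y, equal_var=True)
    return {"t": float(t), "p": float(p),
            "mean_a": float(x.mean()), "mean_b": float(y.mean()),
            "max_a": float(x.max()), "max_b": float(y.max()),
            "n_a": len(x), "n_b": len(y)}


def spikein_pr_model(reads, origins: dict, pmds: DomainSet,
                     layout: GenomeLayout,
                     strata=(5, 10, 30, 50),
                     cfg: PipelineConfig = DEFAULT_CONFIG) -> dict:
    """Precision-recall of tumor-read recovery on a labelled spike-in mixture.

    Each read is scored by ``1 - mean eligible methylation`` (higher =
    more tumor-like); curves sweep every observed score. Curves and
    trapezoidal areas are reported overall and per stratum of
    eligible-call count (each nominal stratum value collects reads whose
    eligible count is nearest to it), quantifying how precision grows
    with CpG calls per read.

    Returns ``{"overall": {...}, "by_stratum": {k: {...}}}`` with keys
    precision, recall, thresholds, area, n, n_positive per entry.
    """
    pmd_by_chrom = pmds.by_chrom()
    rows = []
    for r in reads:
        if r.is_lambda:
            continue
        mask = _eligible_mask(r, pmd_by_chrom, layout)
        n = int(mask.sum())
        if n == 0:
            continue
        mean = float(r.calls[mask].mean())
        rows.append((r.read_id, n, 1.0 - mean, origins[r.read_id] == "tumor"))
    df = pd.DataFrame(rows, columns=["read_id", "n_eligible", "score", "label"])
    if df["label"].nunique() < 2:
        raise ValueError("need both tumor- and normal-origin reads")

    def _curve(sub: pd.DataFrame) -> dict:
        prec, rec, thr = precision_recall_curve(
            sub["label"].to_numpy(), sub["score"].to_numpy())
        # integrate along the threshold sweep (recall decreasing in the
        # sklearn output); tied-recall points then contribute zero width
        area = float(np.trapezoid(prec[::-1], rec[::-1]))
        return {"precision": prec, "recall": rec, "thresholds": thr,
                "area": area, "n": len(sub), "n_positive": int(sub["label"].sum())}

    out = {"overall": _curve(df), "by_stratum": {}}
    strata = np.asarray(sorted(strata))
    nearest = strata[np.argmin(
        np.abs(df["n_eligible"].to_numpy()[:, None] - strata[None, :]), axis=1)]
    for k in strata:
        sub = df[nearest == k]
        if len(sub) and sub["label"].nunique() == 2:
            out["by_stratum"][int(k)] = _curve(sub)
    return out
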