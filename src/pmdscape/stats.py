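"""Aneuploidy score, heterogeneity indices, and the domain-gene
expression screen with hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_CONFIG, PipelineConfig
from .model import CopyNumberProfile, ExpressionMatrix
from . import intervals as iv

log = logging.getLogger(__name__)

__all__ = ["cnv_score", "jaccard_heterogeneity", "correlation_heterogeneity",
           "screen_domain_genes", "hgsea"]


def cnv_score(p: CopyNumberProfile) -> float:
    """Genome-average absolute deviation from diploidy, |c_i - 2|.

    Bins are weighted by their bp length, so ragged terminal bins carry
    proportionally less weight and splitting a bin leaves the score
    unchanged.
    """
    if not len(p.df):
        raise ValueError("empty copy-number profile")
    lengths = (p.df["end"] - p.df["start"]).to_numpy(float)
    dev = np.abs(p.df["cn"].to_numpy(float) - 2.0)
    return float((lengths * dev).sum() / lengths.sum())


# ---------------------------------------------------------------------------
# heterogeneity

def jaccard_heterogeneity(cells: dict, groups: dict) -> tuple:
    """Mean within-group pairwise bp Jaccard of per-cell interval sets.

    ``cells`` maps cell id to a chrom->(n,2) interval dict (e.g. each
    cell's hypomethylated windows); ``groups`` maps cell id to a group
    label. Higher mean Jaccard means less heterogeneity. A pair with one
    empty set scores 0; two empty sets score 1 (logged).

    Returns ``(group_means: dict, pairs: DataFrame)``.
    """
    rows = []
    for g in sorted(set(groups.values())):
        members = sorted(c for c, gg in groups.items() if gg == g)
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        for a, b in itertools.combinations(members, 2):
            sa, sb = cells[a], cells[b]
            if iv.genome_total_bp(sa) == 0 and iv.genome_total_bp(sb) == 0:
                log.warning("cells %s and %s both have empty interval sets; "
                            "pair Jaccard set to 1", a, b)
            rows.append((g, a, b, iv.genome_jaccard(sa, sb)))
    pairs = pd.DataFrame(rows, columns=["group", "cell_a", "cell_b", "jaccard"])
    means = pairs.groupby("group")["jaccard"].mean().to_dict()
    return means, pairs


def correlation_heterogeneity(m: pd.DataFrame, groups: dict,
                              method: str = "pearson") -> tuple:
    """Mean pairwise correlation per group plus a jackknife standard error.

    ``m`` is cells x features (NaN = missing); each pair correlates over
    features non-missing in both cells (pairs with fewer than 2 shared
    features are skipped, logged). The jackknife leaves one cell out at a
    time and recomputes the mean over the remaining pairs;
    SE = sqrt((n-1)/n * sum((theta_i - theta_bar)^2)).

    Returns ``(summary: DataFrame[group, mean_corr, jackknife_se], pairs)``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    rows = []
    for g in sorted(set(groups.values())):
        members = sorted(c for c, gg in groups.items() if gg == g)
        if len(members) < 3:
            raise ValueError(f"group {g!r} needs >=3 cells for the jackknife")
        for a, b in itertools.combinations(members, 2):
            xa, xb = m.loc[a].to_numpy(float), m.loc[b].to_numpy(float)
            ok = ~(np.isnan(xa) | np.isnan(xb))
            if ok.sum() < 2:
                log.warning("pair (%s, %s): <2 shared features, skipped", a, b)
                continue
            if method == "pearson":
                r = sps.pearsonr(xa[ok], xb[ok]).statistic
            else:
                r = sps.spearmanr(xa[ok], xb[ok]).statistic
            rows.append((g, a, b, float(r)))
    pairs = pd.DataFrame(rows, columns=["group", "cell_a", "cell_b", "corr"])
    out = []
    for g in sorted(set(groups.values())):
        members = sorted(c for c, gg in groups.items() if gg == g)
        sub = pairs[pairs["group"] == g]
        mean_corr = float(sub["corr"].mean())
        theta = []
        for drop in members:
            rest = sub[(sub["cell_a"] != drop) & (sub["cell_b"] != drop)]
            theta.append(float(rest["corr"].mean()))
        theta = np.array(theta)
        n = len(members)
        se = float(np.sqrt((n - 1) / n * ((theta - theta.mean()) ** 2).sum()))
        out.append((g, mean_corr, se))
    summary = pd.DataFrame(out, columns=["group", "mean_corr", "jackknife_se"])
    return summary, pairs


# ---------------------------------------------------------------------------
# expression screen

def screen_domain_genes(e: ExpressionMatrix, domain_genes=None,
                        cfg: PipelineConfig = DEFAULT_CONFIG,
                        test_group: str = "tumor",
                        ref_group: str = "normal") -> pd.DataFrame:
    """Differential-expression screen for domain-resident genes.

    Genes whose 95th-percentile expression (across all samples) is below
    the floor are discarded; the rest get an equal-variance two-tailed
    two-sample t-test, Benjamini-Hochberg FDR across tested genes, and a
    ``significant`` flag at FDR < ``de_fdr``. ``direction`` is the sign
    of the tumor-minus-normal mean. ``domain_genes`` restricts the
    screen to genes residing in PMDs/PMIs (any iterable of gene ids);
    None screens every gene.

    Zero-variance genes (both groups constant) get p = 1, logged.
    """
    tum = e.samples_in(test_group)
    ref = e.samples_in(ref_group)
    if len(tum) < 2 or len(ref) < 2:
        raise ValueError("both groups need >=2 samples")
    vals = e.values
    if domain_genes is not None:
        vals = vals.loc[vals.index.intersection(list(domain_genes))]
    pct = np.percentile(vals.to_numpy(float), cfg.de_expr_floor_percentile, axis=1)
    kept = pct >= cfg.de_expr_floor
    out = pd.DataFrame(index=vals.index)
    out["kept"] = kept
    out["t"] = np.nan
    out["p"] = np.nan
    out["direction"] = 0
    x = vals[tum].to_numpy(float)
    y = vals[ref].to_numpy(float)
    diff = x.mean(axis=1) - y.mean(axis=1)
    out["direction"] = np.sign(diff).astype(int)
    tested = np.flatnonzero(kept)
    if len(tested):
        t, p = sps.ttest_ind(x[tested], y[tested], axis=1, equal_var=True)
        degenerate = (x[tested].var(axis=1) == 0) & (y[tested].var(axis=1) == 0)
        if degenerate.any():
            log.warning("%d gene(s) with zero variance in both groups: p set to 1",
                        int(degenerate.sum()))
            t = np.where(degenerate, 0.0, t)
            p = np.where(degenerate, 1.0, p)
        out.iloc[tested, out.columns.get_loc("t")] = t
        out.iloc[tested, out.columns.get_loc("p")] = p
        _, fdr, _, _ = multipletests(p, method="fdr_bh")
        out["fdr"] = np.nan
        out.iloc[tested, out.columns.get_loc("fdr")] = fdr
    else:
        out["fdr"] = np.nan
    out["significant"] = out["kept"] & (out["fdr"] < cfg.de_fdr)
    return out


def hgsea(selected, universe, sets: dict) -> pd.DataFrame:
    """Hypergeometric gene-set enrichment (upper tail, phyper-style).

    For each set: p = P(X >= k) with k = |selected ∩ set|, drawing
    |selected| genes from the universe containing |set ∩ universe|
    successes. Selected genes must be a subset of the universe; sets are
    intersected with the universe first. BH-adjusted values are reported
    alongside the raw p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for name, genes in sets.items():
        in_univ = set(genes) & universe
        K = len(in_univ)
        k = len(selected & in_univ)
        # upper tail P(X >= k) = sf(k - 1)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, K, k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    if len(out):
        _, fdr, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["fdr"] = fdr
    return out
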