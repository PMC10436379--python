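"""Readers and writers for the external formats the pipeline touches.

Dialects
--------
bismark-cov
    ``chrom  pos  pos  percent  n_meth  n_unmeth`` with 1-based inclusive
    positions (Bismark coverage output).
bedgraph
    The 6-column Bismark-style variant ``chrom  start  end  percent
    n_meth  n_unmeth`` with 0-based half-open coordinates; the CpG
    position is taken as ``start``. The count columns are required so
    that observations round-trip exactly.
BED
    0-based half-open; used for domains, CGI/gap annotation and
    copy-number bins (4th column = integer copy number).
per-read methylation TSV
    ``read_id  contig  pos  call`` (Nanopolish-style, one CpG call per
    row, call in {0,1}); contigs named ``lambda*`` flag control reads.
GMT
    ``set_name  description  gene1  gene2 ...`` per line.

All conversion between external 1-based and internal 0-based half-open
coordinates happens here and nowhere else.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (BetaMatrix, CpGCallTable, DomainSet, ExpressionMatrix,
                    GenomeLayout, LongReadRecord, CopyNumberProfile)

log = logging.getLogger(__name__)

LAMBDA_PREFIX = "lambda"


# ---------------------------------------------------------------------------
# CpG call tables

def read_cpg_calls(path, format: str = "bismark-cov", cell: str = None,
                   source: str = None) -> CpGCallTable:
    """Parse a per-cell methylation call file into a :class:`CpGCallTable`.

    ``cell`` defaults to the file stem; ``source`` defaults to ``cell``.
    """
    path = Path(path)
    cell = cell if cell is not None else path.stem
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            try:
                chrom = parts[0]
                a, b = int(parts[1]), int(parts[2])
                n_meth, n_unmeth = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable numeric field") from exc
            if format == "bismark-cov":
                pos = a - 1                      # 1-based inclusive -> 0-based
            elif format == "bedgraph":
                pos = a                          # already 0-based half-open
            else:
                raise ValueError(f"unknown call-table format {format!r}")
            total = n_meth + n_unmeth
            if total < 1:
                raise ValueError(f"{path}:{lineno}: zero total count")
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}:{lineno}: methylated > total or negative count")
            rows.append((cell, chrom, pos, n_meth, total))
    df = pd.DataFrame(rows, columns=["cell", "chrom", "pos", "meth", "total"])
    return CpGCallTable(df, {cell: source if source is not None else cell})


def write_cpg_calls(table: CpGCallTable, path, format: str = "bismark-cov") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for _, r in table.df.iterrows():
            meth, total = int(r["meth"]), int(r["total"])
            pct = 100.0 * meth / total
            unmeth = total - meth
            if format == "bismark-cov":
                p = int(r["pos"]) + 1
                fh.write(f"{r['chrom']}\t{p}\t{p}\t{pct:g}\t{meth}\t{unmeth}\n")
            elif format == "bedgraph":
                p = int(r["pos"])
                fh.write(f"{r['chrom']}\t{p}\t{p + 1}\t{pct:g}\t{meth}\t{unmeth}\n")
            else:
                raise ValueError(f"unknown call-table format {format!r}")


# ---------------------------------------------------------------------------
# long-read methylation calls

def read_longread_calls(path, sample_id: str = None,
                        known_chroms=None) -> list:
    """Group per-call TSV rows into :class:`LongReadRecord` objects.

    Rows on unknown contigs (when ``known_chroms`` is given) are skipped
    with a logged count. Contigs starting with ``lambda`` become
    spike-in control reads.
    """
    path = Path(path)
    sample_id = sample_id if sample_id is not None else path.stem
    per_read = OrderedDict()
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("read_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            rid, contig, pos, call = parts[0], parts[1], int(parts[2]), int(parts[3])
            is_lambda = contig.startswith(LAMBDA_PREFIX)
            if known_chroms is not None and not is_lambda and contig not in known_chroms:
                skipped += 1
                continue
            per_read.setdefault((rid, contig, is_lambda), []).append((pos, call))
    if skipped:
        log.warning("%s: skipped %d calls on unknown contigs", path, skipped)
    records = []
    for (rid, contig, is_lambda), calls in per_read.items():
        calls.sort()
        pos = np.array([p for p, _ in calls], dtype=np.int64)
        val = np.array([c for _, c in calls], dtype=np.int8)
        records.append(LongReadRecord(
            read_id=rid, sample_id=sample_id, chrom=contig,
            start=int(pos[0]), end=int(pos[-1]) + 1,
            positions=pos, calls=val, is_lambda=is_lambda))
    return records


def write_longread_calls(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tpos\tcall\n")
        for r in records:
            for p, c in zip(r.positions, r.calls):
                fh.write(f"{r.read_id}\t{r.chrom}\t{int(p)}\t{int(c)}\n")


# ---------------------------------------------------------------------------
# BED: domains, plain intervals, copy-number bins

def write_domains(domains: DomainSet, path) -> None:
    """BED4 with the name column encoding kind/scope, deterministic order."""
    with open(path, "w") as fh:
        fh.write(f"# pmdscape domains kind={domains.kind} scope={domains.scope}\n")
        name = f"{domains.kind}/{domains.scope}"
        for _, r in domains.df.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t{name}\n")


def read_domains(path) -> DomainSet:
    rows, kind, scope = [], None, None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    if tok.startswith("kind="):
                        kind = tok[5:]
                    elif tok.startswith("scope="):
                        scope = tok[6:]
                continue
            parts = line.split("\t")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
            if kind is None and len(parts) > 3:
                kind = parts[3].split("/")[0]
                if "/" in parts[3]:
                    scope = parts[3].split("/")[1]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return DomainSet(df, kind=kind or "PMD", scope=scope or "per-source")


def read_bed_intervals(path) -> dict:
    """Plain BED3+ -> chrom -> (n,2) interval array (used for CGIs/gaps)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return {c: np.array(v, dtype=np.int64) for c, v in out.items()}


def write_bed_intervals(d: dict, path) -> None:
    with open(path, "w") as fh:
        for c in sorted(d):
            for s, e in np.asarray(d[c], dtype=np.int64).reshape(-1, 2):
                fh.write(f"{c}\t{int(s)}\t{int(e)}\n")


def read_copy_number(path, bin_size: int = None, cell: str = None) -> CopyNumberProfile:
    """BED-like bins with a 4th integer copy-number column."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            rows.append((parts[0], int(parts[1]), int(parts[2]), int(parts[3])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])
    if bin_size is None and len(df):
        bin_size = int((df["end"] - df["start"]).max())
    return CopyNumberProfile(df, bin_size=bin_size or 0, cell=cell)


# ---------------------------------------------------------------------------
# matrices and gene sets

def read_expression_tsv(path, groups: dict) -> ExpressionMatrix:
    """Genes-by-samples TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, dict(groups))


def read_beta_tsv(probes_path, values_path, groups: dict) -> BetaMatrix:
    """Probe annotation TSV (probe_id, chrom, pos) + beta value TSV."""
    probes = pd.read_csv(probes_path, sep="\t")
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    return BetaMatrix(probes, values, dict(groups))


def read_gmt(path) -> dict:
    """GMT gene-set collection -> {set_name: set(genes)}."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


# ---------------------------------------------------------------------------
# cell-level QC

def qc_cell(table: CpGCallTable, conversion_rate: float,
            cfg=None) -> tuple:
    """Bisulfite cell QC: unique covered CpGs and conversion rate.

    A cell passes with more than ``qc_min_unique_cpgs`` unique covered
    CpG sites and a conversion rate above ``qc_min_conversion`` (both
    strict).

    Returns ``(passed, metrics_dict)``.
    """
    from .config import DEFAULT_CONFIG
    cfg = cfg or DEFAULT_CONFIG
    if not 0.0 <= conversion_rate <= 1.0:
        raise ValueError("conversion rate must be a fraction in [0, 1]")
    n_unique = len(table.df.drop_duplicates(["chrom", "pos"]))
    passed = (n_unique > cfg.qc_min_unique_cpgs
              and conversion_rate > cfg.qc_min_conversion)
    return passed, {"unique_cpgs": n_unique, "conversion_rate": conversion_rate}
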