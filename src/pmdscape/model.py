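"""In-memory containers shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package;
conversion to/from 1-based external dialects happens only in
:mod:`pmdscape.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv

__all__ = [
    "GenomeLayout",
    "CpGCallTable",
    "WindowTrack",
    "SourceThreshold",
    "DomainSet",
    "CopyNumberProfile",
    "LongReadRecord",
    "SampleSignal",
    "BetaMatrix",
    "ExpressionMatrix",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes plus CpG-island and assembly-gap annotation.

    Interval sets are normalized (sorted, merged) at construction and
    checked against chromosome bounds.
    """

    chromosomes: tuple  # ((name, length), ...)
    cgi_intervals: dict = field(default_factory=dict)   # chrom -> (n,2) array
    gap_intervals: dict = field(default_factory=dict)

    def __post_init__(self):
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        if len({n for n, _ in chroms}) != len(chroms):
            raise ValueError("duplicate chromosome names")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n} has non-positive length {l}")
        object.__setattr__(self, "chromosomes", chroms)
        sizes = dict(chroms)
        for attr in ("cgi_intervals", "gap_intervals"):
            raw = getattr(self, attr)
            norm = {}
            for c, a in raw.items():
                if c not in sizes:
                    raise ValueError(f"{attr} on unknown chromosome {c!r}")
                a = iv.merge(a)
                if len(a) and (a[0, 0] < 0 or a[-1, 1] > sizes[c]):
                    raise ValueError(f"{attr} outside chromosome {c}")
                if len(a):
                    norm[c] = a
            object.__setattr__(self, attr, norm)

    @property
    def chrom_names(self) -> list:
        return [n for n, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for n, l in self.chromosomes:
            if n == chrom:
                return l
        raise KeyError(chrom)

    def excluded(self, chrom: str) -> np.ndarray:
        """Merged CGI + gap intervals for a chromosome (window blacklist)."""
        return iv.union(
            self.cgi_intervals.get(chrom, np.empty((0, 2), np.int64)),
            self.gap_intervals.get(chrom, np.empty((0, 2), np.int64)),
        )


_CALL_COLUMNS = ["cell", "chrom", "pos", "meth", "total"]


@dataclass
class CpGCallTable:
    """Sparse per-cell CpG methylation observations.

    ``df`` holds one row per (cell, chrom, pos) with methylated and total
    call counts; ``sources`` maps each cell to its sample source (patient
    or cell line). Positions are 0-based.
    """

    df: pd.DataFrame
    sources: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.df
        missing = [c for c in _CALL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"call table missing columns {missing}")
        if len(df):
            if (df["total"] < 1).any():
                raise ValueError("total_count must be >= 1")
            if ((df["meth"] < 0) | (df["meth"] > df["total"])).any():
                raise ValueError("methylated_count outside [0, total_count]")
        unknown = set(df["cell"].unique()) - set(self.sources)
        if unknown:
            # default: each unlabelled cell is its own source
            self.sources = {**{c: c for c in unknown}, **self.sources}

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cells(self) -> list:
        return sorted(self.df["cell"].unique().tolist())

    @property
    def source_names(self) -> list:
        return sorted(set(self.sources.values()))

    def for_cell(self, cell) -> "CpGCallTable":
        return CpGCallTable(self.df[self.df["cell"] == cell].reset_index(drop=True),
                            {cell: self.sources.get(cell, cell)})

    def for_source(self, source) -> "CpGCallTable":
        cells = [c for c, s in self.sources.items() if s == source]
        sub = self.df[self.df["cell"].isin(cells)].reset_index(drop=True)
        return CpGCallTable(sub, {c: source for c in cells})

    def pooled_by_site(self) -> pd.DataFrame:
        """Sum counts over cells -> per-site (chrom, pos, meth, total), sorted."""
        if not len(self.df):
            return pd.DataFrame(columns=["chrom", "pos", "meth", "total"])
        g = (self.df.groupby(["chrom", "pos"], sort=True)[["meth", "total"]]
             .sum().reset_index())
        return g


@dataclass
class WindowTrack:
    """Per-source mean methylation over sliding windows.

    ``df`` columns: chrom, start, meth (NaN when the window holds fewer
    covered CpG sites than the configured minimum), n_cpg. Windows that
    intersect CGIs or gaps are absent entirely.
    """

    source: str
    df: pd.DataFrame
    window_size: int
    window_step: int

    @property
    def values(self) -> np.ndarray:
        """Non-missing window methylation values."""
        v = self.df["meth"].to_numpy(float)
        return v[~np.isnan(v)]

    def scored_windows(self) -> pd.DataFrame:
        return self.df[self.df["meth"].notna()]


@dataclass(frozen=True)
class SourceThreshold:
    source: str
    modality: str              # "unimodal" | "bimodal"
    threshold: float
    grid: np.ndarray = None
    density: np.ndarray = None
    modes: tuple = ()

    def __post_init__(self):
        if self.modality not in ("unimodal", "bimodal"):
            raise ValueError(f"bad modality {self.modality!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be a fraction")
        if self.modality == "bimodal":
            lo, hi = sorted(self.modes)[:2] if len(self.modes) >= 2 else (0, 1)
            if not lo < self.threshold < hi:
                raise ValueError("bimodal threshold must lie strictly between the modes")


@dataclass
class DomainSet:
    """Sorted, non-overlapping genomic intervals labelled PMD or PMI.

    ``scope`` records whether the set is per-source, the cross-source
    union ("total"), or the uniform "core" subset. Optional per-interval
    annotation columns (e.g. quantile-normalized methylation, core flag)
    ride along in ``df``.
    """

    df: pd.DataFrame            # columns: chrom, start, end [+ extras]
    kind: str                   # "PMD" | "PMI"
    scope: str = "per-source"   # "per-source" | "total" | "core"
    source: str = None

    def __post_init__(self):
        if self.kind not in ("PMD", "PMI"):
            raise ValueError(f"bad domain kind {self.kind!r}")
        df = self.df.reset_index(drop=True)
        if not {"chrom", "start", "end"} <= set(df.columns):
            raise ValueError("DomainSet frame needs chrom/start/end")
        if len(df):
            if (df["end"] <= df["start"]).any():
                raise ValueError("empty or inverted interval")
            df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
            for c, sub in df.groupby("chrom", sort=False):
                if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                    raise ValueError(f"overlapping intervals on {c}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def by_chrom(self) -> dict:
        """chrom -> (n,2) interval array."""
        out = {}
        for c, sub in self.df.groupby("chrom", sort=True):
            out[str(c)] = iv.as_array(sub[["start", "end"]].to_numpy(np.int64))
        return out

    @property
    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy(np.int64)

    @classmethod
    def from_chrom_dict(cls, d: dict, kind: str, scope: str = "per-source",
                        source: str = None) -> "DomainSet":
        rows = []
        for c in sorted(d):
            for s, e in iv.as_array(d[c]):
                rows.append((c, int(s), int(e)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls(df, kind=kind, scope=scope, source=source)


@dataclass
class CopyNumberProfile:
    """Integer copy number per fixed-size bin for one cell."""

    df: pd.DataFrame            # chrom, start, end, cn
    bin_size: int
    cell: str = None

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        need = {"chrom", "start", "end", "cn"}
        if not need <= set(df.columns):
            raise ValueError("copy-number frame needs chrom/start/end/cn")
        if len(df):
            if (df["cn"] < 0).any():
                raise ValueError("copy numbers must be >= 0")
            if not np.array_equal(df["cn"], df["cn"].astype(np.int64)):
                raise ValueError("copy numbers must be integral")
            df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
            for c, sub in df.groupby("chrom", sort=False):
                s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
                if (s[1:] != e[:-1]).any():
                    raise ValueError(f"bins do not tile chromosome {c}")
        self.df = df


@dataclass
class LongReadRecord:
    """One long read with its CpG methylation calls (binary, sorted)."""

    read_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    positions: np.ndarray       # call positions, 0-based, sorted
    calls: np.ndarray           # 0/1 per position
    is_lambda: bool = False

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        calls = np.asarray(self.calls, dtype=np.int8)
        if pos.shape != calls.shape:
            raise ValueError("positions and calls differ in length")
        order = np.argsort(pos, kind="stable")
        pos, calls = pos[order], calls[order]
        if len(pos) and not self.is_lambda:
            if pos[0] < self.start or pos[-1] >= self.end:
                raise ValueError("calls outside read span")
        if not np.isin(calls, [0, 1]).all():
            raise ValueError("calls must be binary")
        self.positions, self.calls = pos, calls

    @property
    def n_calls(self) -> int:
        return len(self.positions)


@dataclass
class SampleSignal:
    """Per-sample long-read hypomethylation signal with its QC context."""

    sample_id: str
    cohort: str
    n_reads_in_pmds: int
    n_reads_passing: int
    n_reads_hypomethylated: int
    lambda_methylation: float
    qc_pass: bool
    signal: float = None        # percent, defined only when qc_pass

    def __post_init__(self):
        if self.qc_pass:
            if self.signal is None or not 0.0 <= self.signal <= 100.0:
                raise ValueError("qc-passing sample must carry a signal in [0, 100]")
        else:
            self.signal = None


@dataclass
class BetaMatrix:
    """450K-style probe beta values: probes x samples plus group labels."""

    probes: pd.DataFrame        # probe_id, chrom, pos
    values: pd.DataFrame        # index probe_id, columns sample ids
    groups: dict                # sample -> "tumor" | "normal"

    def __post_init__(self):
        if not self.probes["probe_id"].is_unique:
            raise ValueError("duplicate probe ids")
        v = self.values.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v, initial=0.0) < 0 or np.nanmax(v, initial=0.0) > 1:
                raise ValueError("beta values outside [0, 1]")
        unknown = set(self.values.columns) - set(self.groups)
        if unknown:
            raise ValueError(f"samples without group label: {sorted(unknown)}")

    def samples_in(self, group: str) -> list:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass
class ExpressionMatrix:
    """Gene-level nonnegative expression (FPKM-like): genes x samples."""

    values: pd.DataFrame        # index gene, columns samples
    groups: dict                # sample -> group label

    def __post_init__(self):
        if (self.values.to_numpy(float) < 0).any():
            raise ValueError("expression values must be >= 0")
        unknown = set(self.values.columns) - set(self.groups)
        if unknown:
            raise ValueError(f"samples without group label: {sorted(unknown)}")

    def samples_in(self, group: str) -> list:
        return [s for s in self.values.columns if self.groups[s] == group]
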