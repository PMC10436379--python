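"""Synthetic methylome, long-read, copy-number, array and expression generators.

The generators emulate the statistical structure the domain-calling
pipeline assumes so that every stage can be exercised end-to-end without
external data:

* a unimodal "normal" methylome whose per-window methylation peaks near
  80% (per-site means drawn once from Beta(16, 4), then binary per-cell
  Bernoulli calls observed at a sparse coverage fraction);
* "tumor" methylomes with planted partially methylated domains (PMDs)
  whose internal state is drawn uniformly from 20-40% methylation, and
  preserved methylation islands (PMIs) nested inside PMDs that revert to
  the background state;
* long reads whose CpG calls sample the methylation state of the region
  of origin, plus near-zero-methylation lambda spike-in control reads;
* segmental integer copy-number profiles, probe beta matrices, and
  group-structured expression with planted fold changes.

Every generator is a pure function of ``(spec, seed)``: the same seed
reproduces byte-identical outputs. Planted truth is always returned so
recovery can be scored without re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .model import (CopyNumberProfile, CpGCallTable, DomainSet,
                    ExpressionMatrix, BetaMatrix, GenomeLayout, LongReadRecord)

__all__ = [
    "PlantedDomain", "SourceSpec", "SynthSpec", "Truth",
    "toy_tumor_spec", "toy_normal_spec", "multisource_spec",
    "generate_methylome", "generate_longreads",
    "generate_copy_number", "generate_beta_matrix", "generate_expression",
]

# distinct child-seed tags so the generators draw independent streams
_TAG_METHYLOME, _TAG_READS, _TAG_BETA, _TAG_EXPR, _TAG_CGI = 11, 13, 17, 19, 23


@dataclass(frozen=True)
class PlantedDomain:
    """A planted PMD with optional nested PMIs.

    ``state`` is the PMD-interior methylation level; ``None`` means draw
    once from the spec's PMD state range. PMIs revert to background.
    """

    chrom: str
    start: int
    end: int
    state: float = None
    pmis: tuple = ()            # ((start, end), ...) strictly inside [start, end)


@dataclass(frozen=True)
class SourceSpec:
    label: str
    kind: str = "tumor"         # "tumor" | "normal"
    n_cells: int = 10
    pmd_indices: tuple = None   # indices into SynthSpec.true_pmds; None = all (tumor)


@dataclass(frozen=True)
class SynthSpec:
    genome: tuple = (("chr1", 10_000_000), ("chr2", 10_000_000))
    # CpG island model: expected islands per bp, sizes, density boost inside
    cgi_density: float = 1.0e-6
    cgi_size_range: tuple = (500, 2000)
    cgi_spacing_factor: float = 5.0
    cgi_in_pmd_factor: float = 0.0   # PMDs are CGI-poor; 0 keeps islands outside
    gaps: tuple = ()                 # ((chrom, start, end), ...)
    # methylation model
    true_pmds: tuple = ()
    pmd_state_range: tuple = (0.20, 0.40)
    background_beta: tuple = (16.0, 4.0)   # per-site mean ~0.80
    mean_cpg_spacing: float = 100.0
    coverage: float = 0.3
    sources: tuple = (SourceSpec("tumor_0"),)
    # long-read model
    calls_per_read_choices: tuple = (5, 10, 30, 50)
    spike_fraction: float = 0.01
    lambda_reads: int = 50
    lambda_calls_per_read: int = 200
    lambda_error: float = 0.005
    # copy-number model
    cn_bin_size: int = 1_000_000
    cn_segments: tuple = ()          # ((chrom, start, end, cn), ...)
    # beta-array model
    probe_spacing: int = 2_000
    n_beta_tumor: int = 8
    n_beta_normal: int = 4
    beta_normal_mean: float = 0.85
    beta_pmd_mean: float = 0.30
    beta_sd: float = 0.05
    # expression model
    n_genes: int = 200
    n_genes_down: int = 20
    n_genes_low: int = 10
    n_expr_per_group: int = 20
    expr_log2_sd: float = 0.5
    expr_log2_effect: float = 1.0    # planted two-fold change
    seed: int = 0

    def __post_init__(self):
        sizes = dict(self.genome)
        for d in self.true_pmds:
            if d.chrom not in sizes:
                raise ValueError(f"planted PMD on unknown chromosome {d.chrom}")
            if not 0 <= d.start < d.end <= sizes[d.chrom]:
                raise ValueError("planted PMD outside chromosome bounds")
            for s, e in d.pmis:
                if not d.start < s < e < d.end:
                    raise ValueError("planted PMI must lie strictly inside its PMD")
        for c, sub in _group_by_chrom(self.true_pmds).items():
            a = np.array([(d.start, d.end) for d in sub])
            a = a[np.argsort(a[:, 0])]
            if (a[1:, 0] < a[:-1, 1]).any():
                raise ValueError(f"planted PMDs overlap on {c}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be a fraction")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike_fraction must be a fraction")

    def pmds_for(self, src: SourceSpec) -> tuple:
        if src.kind == "normal":
            return ()
        if src.pmd_indices is None:
            return tuple(self.true_pmds)
        return tuple(self.true_pmds[i] for i in src.pmd_indices)


@dataclass
class Truth:
    """Planted structure, sufficient to score recovery."""

    pmd_by_source: dict          # source -> DomainSet (PMD-state bp, PMIs removed)
    pmi_by_source: dict          # source -> DomainSet
    pmd_total: DomainSet
    pmi_total: DomainSet
    states: dict                 # (chrom, start, end) -> methylation state


def _group_by_chrom(domains) -> dict:
    out = {}
    for d in domains:
        out.setdefault(d.chrom, []).append(d)
    return out


# ---------------------------------------------------------------------------
# canned specs

def toy_tumor_spec(seed: int = 0, n_cells: int = 10) -> SynthSpec:
    """Two 10-Mb chromosomes; 6 Mb (30%) of the genome in the PMD state.

    chr1 carries a solid 3-Mb PMD; chr2 a 4.5-Mb PMD interrupted by a
    1.5-Mb PMI, leaving two 1.5-Mb PMD-state segments. Sizes are multiples
    of the 100-kb window so boundary localization error (about half a
    window per edge) stays small relative to domain length.
    """
    return SynthSpec(
        true_pmds=(
            PlantedDomain("chr1", 1_000_000, 4_000_000),
            PlantedDomain("chr2", 2_000_000, 6_500_000,
                          pmis=((3_500_000, 5_000_000),)),
        ),
        gaps=(("chr1", 7_000_000, 7_100_000), ("chr2", 8_000_000, 8_100_000)),
        sources=(SourceSpec("tumor_0", kind="tumor", n_cells=n_cells),),
        seed=seed,
    )


def toy_normal_spec(seed: int = 0, n_cells: int = 10) -> SynthSpec:
    """Same genome with no planted PMDs and a single normal source."""
    return replace(toy_tumor_spec(seed=seed), true_pmds=(),
                   sources=(SourceSpec("normal_0", kind="normal", n_cells=n_cells),))


def multisource_spec(n_sources: int = 4, seed: int = 0, n_cells: int = 4,
                     chrom_len: int = 6_000_000) -> SynthSpec:
    """Several tumor sources sharing one PMD (-> core) plus one private
    PMD each (-> total but not core); shared PMI nested in the shared PMD."""
    shared = PlantedDomain("chr1", 500_000, 5_500_000, state=0.20,
                           pmis=((2_500_000, 3_500_000),))
    private = [PlantedDomain("chr2", 500_000 + i * 1_200_000,
                             1_500_000 + i * 1_200_000)
               for i in range(n_sources)]
    if private[-1].end > chrom_len * 2:
        raise ValueError("too many sources for this chromosome length")
    sources = tuple(
        SourceSpec(f"src_{i}", kind="tumor", n_cells=n_cells,
                   pmd_indices=(0, 1 + i))
        for i in range(n_sources))
    return SynthSpec(
        genome=(("chr1", chrom_len), ("chr2", chrom_len * 2)),
        true_pmds=(shared, *private),
        sources=sources,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# methylome generation

def _planted_arrays(spec: SynthSpec, domains) -> tuple:
    """(pmd_minus_pmi, pmi) chrom-dicts for a collection of planted domains."""
    pmd, pmi = {}, {}
    for d in domains:
        pmd.setdefault(d.chrom, []).append((d.start, d.end))
        for s, e in d.pmis:
            pmi.setdefault(d.chrom, []).append((s, e))
    pmd = {c: iv.merge(v) for c, v in pmd.items()}
    pmi = {c: iv.merge(v) for c, v in pmi.items()}
    pmd_minus = {c: iv.subtract(a, pmi.get(c, np.empty((0, 2), np.int64)))
                 for c, a in pmd.items()}
    return pmd_minus, pmi


def _draw_states(spec: SynthSpec, rng: np.random.Generator) -> dict:
    """One methylation state per planted PMD interval, deterministic in seed."""
    lo, hi = spec.pmd_state_range
    states = {}
    for d in spec.true_pmds:
        key = (d.chrom, d.start, d.end)
        states[key] = float(d.state) if d.state is not None else float(rng.uniform(lo, hi))
    return states


def _make_layout(spec: SynthSpec, rng: np.random.Generator) -> GenomeLayout:
    sizes = dict(spec.genome)
    pmd_all = {}
    for d in spec.true_pmds:
        pmd_all.setdefault(d.chrom, []).append((d.start, d.end))
    pmd_all = {c: iv.merge(v) for c, v in pmd_all.items()}
    cgis = {}
    for chrom, length in spec.genome:
        n = int(round(spec.cgi_density * length))
        if n == 0:
            continue
        lo, hi = spec.cgi_size_range
        placed = []
        guard = 0
        while len(placed) < n and guard < 50 * n:
            guard += 1
            size = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(1, length - size)))
            inside_pmd = bool(iv.points_in(
                np.array([start, start + size - 1]),
                pmd_all.get(chrom, np.empty((0, 2), np.int64))).any())
            if inside_pmd and rng.random() >= spec.cgi_in_pmd_factor:
                continue
            placed.append((start, start + size))
        if placed:
            cgis[chrom] = iv.merge(placed)
    gaps = {}
    for chrom, s, e in spec.gaps:
        gaps.setdefault(chrom, []).append((s, e))
    gaps = {c: iv.merge(v) for c, v in gaps.items()}
    return GenomeLayout(tuple(spec.genome), cgis, gaps)


def _cpg_positions(spec: SynthSpec, layout: GenomeLayout,
                   rng: np.random.Generator) -> dict:
    """Per-chromosome sorted CpG site positions; denser inside CGIs."""
    out = {}
    for chrom, length in spec.genome:
        n_bg = int(length / spec.mean_cpg_spacing * 1.3)
        gaps_bp = rng.exponential(spec.mean_cpg_spacing, size=n_bg)
        pos = np.cumsum(np.maximum(2.0, gaps_bp)).astype(np.int64)
        pos = pos[pos < length]
        extra = []
        for s, e in layout.cgi_intervals.get(chrom, np.empty((0, 2), np.int64)):
            dense = spec.mean_cpg_spacing / spec.cgi_spacing_factor
            k = int((e - s) / dense)
            if k > 0:
                extra.append(s + np.sort(rng.integers(0, e - s, size=k)).astype(np.int64))
        if extra:
            pos = np.concatenate([pos] + extra)
        out[chrom] = np.unique(pos)
    return out


def generate_methylome(spec: SynthSpec, seed: int = None
                       ) -> tuple:
    """Simulate sparse single-cell CpG calls with planted domain structure.

    Returns ``(layout, calls, truth)``. Each CpG's methylation
    probability equals the state of its containing planted region
    (background sites: a per-site draw from the background Beta); each
    cell observes each site independently with the coverage fraction and
    emits a single Bernoulli call at that probability.
    """
    root = spec.seed if seed is None else seed
    rng = np.random.default_rng([int(root), _TAG_METHYLOME])
    layout = _make_layout(spec, rng)
    sites = _cpg_positions(spec, layout, rng)
    states = _draw_states(spec, rng)

    a, b = spec.background_beta
    base_p = {c: rng.beta(a, b, size=len(p)) for c, p in sites.items()}

    # per-source site probabilities: overwrite PMD-state sites
    frames = []
    sources_map = {}
    truth_pmd_src, truth_pmi_src = {}, {}
    cell_counter = 0
    for src in spec.sources:
        planted = spec.pmds_for(src)
        pmd_minus, pmi = _planted_arrays(spec, planted)
        truth_pmd_src[src.label] = DomainSet.from_chrom_dict(
            pmd_minus, "PMD", scope="per-source", source=src.label)
        truth_pmi_src[src.label] = DomainSet.from_chrom_dict(
            pmi, "PMI", scope="per-source", source=src.label)
        p_src = {}
        for chrom, pos in sites.items():
            p = base_p[chrom].copy()
            for d in planted:
                if d.chrom != chrom:
                    continue
                st = states[(d.chrom, d.start, d.end)]
                span = iv.subtract(np.array([[d.start, d.end]]),
                                   iv.as_array(list(d.pmis)))
                mask = iv.points_in(pos, span)
                p[mask] = st
            p_src[chrom] = p
        for _ in range(src.n_cells):
            cell = f"{src.label}.c{cell_counter}"
            cell_counter += 1
            sources_map[cell] = src.label
            if spec.coverage <= 0.0:
                continue
            for chrom, pos in sites.items():
                cov = rng.random(len(pos)) < spec.coverage
                if not cov.any():
                    continue
                p = p_src[chrom][cov]
                meth = (rng.random(cov.sum()) < p).astype(np.int8)
                frames.append(pd.DataFrame({
                    "cell": cell, "chrom": chrom, "pos": pos[cov],
                    "meth": meth.astype(np.int64), "total": np.int64(1)}))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["cell", "chrom", "pos", "meth", "total"])
    calls = CpGCallTable(df, sources_map)

    all_pmd = iv.genome_union(*[t.by_chrom() for t in truth_pmd_src.values()]) \
        if truth_pmd_src else {}
    all_pmi = iv.genome_union(*[t.by_chrom() for t in truth_pmi_src.values()]) \
        if truth_pmi_src else {}
    truth = Truth(
        pmd_by_source=truth_pmd_src,
        pmi_by_source=truth_pmi_src,
        pmd_total=DomainSet.from_chrom_dict(all_pmd, "PMD", scope="total"),
        pmi_total=DomainSet.from_chrom_dict(all_pmi, "PMI", scope="total"),
        states=states,
    )
    return layout, calls, truth


# ---------------------------------------------------------------------------
# long reads

def generate_longreads(spec: SynthSpec, pmds: DomainSet, n_reads: int,
                       tumor_fraction: float, seed: int = None,
                       sample_id: str = "sample") -> tuple:
    """Simulate PMD-aligned long reads with known cell of origin.

    Tumor-origin reads draw their CpG calls at a PMD-state methylation
    probability; normal-origin reads at the high background probability.
    Lambda spike-in control reads are appended at the spec's per-call
    error rate. Returns ``(records, origins)`` where ``origins`` maps
    read id to ``"tumor" | "normal" | "lambda"``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    if len(pmds) == 0:
        raise ValueError("need at least one PMD interval to place reads")
    root = spec.seed if seed is None else seed
    rng = np.random.default_rng([int(root), _TAG_READS])

    ivs = pmds.df[["chrom", "start", "end"]].to_numpy(object)
    lens = (pmds.df["end"] - pmds.df["start"]).to_numpy(np.int64)
    weights = lens / lens.sum()
    lo, hi = spec.pmd_state_range
    a, b = spec.background_beta

    records, origins = [], {}
    for i in range(n_reads):
        rid = f"{sample_id}.r{i}"
        tumor = bool(rng.random() < tumor_fraction)
        origins[rid] = "tumor" if tumor else "normal"
        k = int(rng.choice(spec.calls_per_read_choices))
        j = int(rng.choice(len(lens), p=weights))
        chrom, s0, e0 = str(ivs[j, 0]), int(ivs[j, 1]), int(ivs[j, 2])
        gaps_bp = np.maximum(2.0, rng.exponential(spec.mean_cpg_spacing, size=k))
        offsets = np.cumsum(gaps_bp).astype(np.int64)
        span = int(offsets[-1])
        if span >= (e0 - s0):
            # rescale into the interval; keeps exactly k calls inside the PMD
            offsets = (offsets * ((e0 - s0 - 1) / span)).astype(np.int64)
            offsets = np.unique(offsets)
            span = int(offsets[-1]) if len(offsets) else 0
        start = s0 + int(rng.integers(0, max(1, e0 - s0 - span)))
        pos = start + offsets
        p = float(rng.uniform(lo, hi)) if tumor else float(rng.beta(a, b))
        calls = (rng.random(len(pos)) < p).astype(np.int8)
        records.append(LongReadRecord(
            read_id=rid, sample_id=sample_id, chrom=chrom,
            start=int(pos[0]), end=int(pos[-1]) + 1,
            positions=pos, calls=calls))
    for i in range(spec.lambda_reads):
        rid = f"{sample_id}.lambda{i}"
        origins[rid] = "lambda"
        k = spec.lambda_calls_per_read
        pos = np.arange(k, dtype=np.int64) * 50
        calls = (rng.random(k) < spec.lambda_error).astype(np.int8)
        records.append(LongReadRecord(
            read_id=rid, sample_id=sample_id, chrom="lambda",
            start=0, end=int(pos[-1]) + 1, positions=pos, calls=calls,
            is_lambda=True))
    return records, origins


# ---------------------------------------------------------------------------
# copy number, beta matrix, expression

def generate_copy_number(spec: SynthSpec, cell: str = "cell_0") -> CopyNumberProfile:
    """Tile each chromosome into bins; diploid except planted segments.

    A bin takes the copy number of the planted segment containing its
    midpoint (diploid otherwise). Deterministic: no randomness involved.
    """
    rows = []
    for chrom, length in spec.genome:
        starts = np.arange(0, length, spec.cn_bin_size, dtype=np.int64)
        ends = np.minimum(starts + spec.cn_bin_size, length)
        mids = (starts + ends) // 2
        cn = np.full(len(starts), 2, dtype=np.int64)
        for (c, s, e, v) in spec.cn_segments:
            if c == chrom:
                cn[(mids >= s) & (mids < e)] = int(v)
        for s, e, v in zip(starts, ends, cn):
            rows.append((chrom, int(s), int(e), int(v)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])
    return CopyNumberProfile(df, bin_size=spec.cn_bin_size, cell=cell)


def generate_beta_matrix(spec: SynthSpec, seed: int = None) -> tuple:
    """Probe beta values: tumor samples hypomethylated inside planted PMDs.

    Returns ``(BetaMatrix, truth)`` where truth records the planted
    hypomethylated intervals (PMD-state bp).
    """
    root = spec.seed if seed is None else seed
    rng = np.random.default_rng([int(root), _TAG_BETA])
    pmd_minus, _ = _planted_arrays(spec, spec.true_pmds)
    probes = []
    for chrom, length in spec.genome:
        for pos in range(spec.probe_spacing // 2, length, spec.probe_spacing):
            probes.append((f"cg_{chrom}_{pos}", chrom, pos))
    pdf = pd.DataFrame(probes, columns=["probe_id", "chrom", "pos"])
    in_pmd = np.zeros(len(pdf), dtype=bool)
    for chrom, arr in pmd_minus.items():
        m = pdf["chrom"] == chrom
        in_pmd[m.to_numpy()] = iv.points_in(pdf.loc[m, "pos"].to_numpy(), arr)
    samples, groups = [], {}
    cols = {}
    for i in range(spec.n_beta_tumor):
        s = f"tumor_{i}"
        mu = np.where(in_pmd, spec.beta_pmd_mean, spec.beta_normal_mean)
        cols[s] = np.clip(rng.normal(mu, spec.beta_sd), 0.0, 1.0)
        groups[s] = "tumor"
    for i in range(spec.n_beta_normal):
        s = f"normal_{i}"
        cols[s] = np.clip(rng.normal(spec.beta_normal_mean, spec.beta_sd,
                                     size=len(pdf)), 0.0, 1.0)
        groups[s] = "normal"
    values = pd.DataFrame(cols, index=pdf["probe_id"])
    truth = {"hypo_intervals": pmd_minus, "pmd_probe_mask": in_pmd}
    return BetaMatrix(pdf, values, groups), truth


def generate_expression(spec: SynthSpec, seed: int = None) -> tuple:
    """FPKM-like expression with planted two-fold-down genes in tumors.

    Returns ``(ExpressionMatrix, truth)`` with the planted differential
    and below-floor gene lists.
    """
    root = spec.seed if seed is None else seed
    rng = np.random.default_rng([int(root), _TAG_EXPR])
    genes = [f"gene_{i}" for i in range(spec.n_genes)]
    down = genes[: spec.n_genes_down]
    low = genes[spec.n_genes_down: spec.n_genes_down + spec.n_genes_low]
    mu = rng.normal(3.0, 1.0, size=spec.n_genes)   # log2 baseline
    cols, groups = {}, {}
    for g_idx, grp in enumerate(("tumor", "normal")):
        for i in range(spec.n_expr_per_group):
            s = f"{grp}_{i}"
            shift = np.zeros(spec.n_genes)
            if grp == "tumor":
                shift[: spec.n_genes_down] = -spec.expr_log2_effect
            x = 2.0 ** rng.normal(mu + shift, spec.expr_log2_sd)
            x[spec.n_genes_down: spec.n_genes_down + spec.n_genes_low] = \
                rng.uniform(0.0, 0.5, size=spec.n_genes_low)
            cols[s] = x
            groups[s] = grp
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    truth = {"down_genes": down, "below_floor_genes": low}
    return ExpressionMatrix(values, groups), truth
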