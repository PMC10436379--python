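"""Windowing, valley thresholding, PMD/PMI segmentation and core designation."""

import numpy as np
import pandas as pd
import pytest

import pmdscape as pm
from pmdscape import intervals as iv
from pmdscape.domains import (call_pmds_per_source, call_pmis_per_source,
                              core_pmds_from_matrix, designate_core_pmis,
                              hypomethylated_fraction, hypomethylated_windows,
                              quantile_normalize_columns, union_domains)
from pmdscape.model import SourceThreshold

from conftest import make_track


def _single_window_layout(n_pos, meth_per_site=1, total_per_site=1,
                          length=100_000):
    layout = pm.GenomeLayout((("chr1", length),))
    pos = np.linspace(1000, length - 1000, n_pos).astype(np.int64)
    df = pd.DataFrame({"cell": "c0", "chrom": "chr1", "pos": pos,
                       "meth": meth_per_site, "total": total_per_site})
    return layout, pm.CpGCallTable(df, {"c0": "s"})


class TestWindowTrack:
    def test_fully_methylated_window(self):
        layout, calls = _single_window_layout(20)
        track = pm.build_window_track(calls, layout)["s"]
        assert len(track.df) == 1
        assert track.df.iloc[0]["meth"] == 1.0
        assert track.df.iloc[0]["n_cpg"] == 20

    def test_window_pools_counts_over_cells(self):
        layout = pm.GenomeLayout((("chr1", 100_000),))
        pos = np.linspace(1000, 99_000, 20).astype(np.int64)
        df = pd.concat([
            pd.DataFrame({"cell": "a", "chrom": "chr1", "pos": pos,
                          "meth": 1, "total": 1}),
            pd.DataFrame({"cell": "b", "chrom": "chr1", "pos": pos,
                          "meth": 0, "total": 1})])
        calls = pm.CpGCallTable(df, {"a": "s", "b": "s"})
        track = pm.build_window_track(calls, layout)["s"]
        assert track.df.iloc[0]["meth"] == pytest.approx(0.5)

    def test_window_touching_cgi_by_one_bp_is_absent(self):
        layout = pm.GenomeLayout((("chr1", 300_000),),
                                 cgi_intervals={"chr1": [(199_999, 200_500)]})
        pos = np.arange(1000, 299_000, 500, dtype=np.int64)
        df = pd.DataFrame({"cell": "c", "chrom": "chr1", "pos": pos,
                           "meth": 1, "total": 1})
        track = pm.build_window_track(pm.CpGCallTable(df, {"c": "s"}), layout)["s"]
        starts = set(track.df["start"])
        assert 100_000 not in starts     # [100000, 200000) overlaps 199999
        assert 99_800 in starts          # [99800, 199800) clears it

    def test_window_below_min_cpgs_is_missing(self):
        layout, calls = _single_window_layout(9)
        track = pm.build_window_track(calls, layout)["s"]
        assert np.isnan(track.df.iloc[0]["meth"])
        assert track.df.iloc[0]["n_cpg"] == 9

    def test_no_sources_errors(self):
        layout = pm.GenomeLayout((("chr1", 100_000),))
        empty = pm.CpGCallTable(
            pd.DataFrame(columns=["cell", "chrom", "pos", "meth", "total"]))
        with pytest.raises(ValueError, match="no sources"):
            pm.build_window_track(empty, layout)


def brute_force_kde_argmin(values, lo, hi, bandwidth=0.03, step=0.001):
    """Independent valley oracle: exact Gaussian-kernel sum on a fine grid."""
    ts = np.arange(lo, hi, step)
    d2 = (ts[:, None] - values[None, :]) ** 2
    dens = np.exp(-d2 / (2 * bandwidth ** 2)).sum(axis=1)
    return float(ts[int(np.argmin(dens))])


class TestThreshold:
    def test_unimodal_source_falls_back_to_60(self):
        rng = np.random.default_rng(0)
        track = make_track(rng.beta(16, 4, size=5000))
        thr = pm.select_threshold(track)
        assert thr.modality == "unimodal"
        assert thr.threshold == 0.60

    def test_bimodal_valley_matches_grid_search_oracle(self):
        rng = np.random.default_rng(1)
        vals = np.clip(np.concatenate([rng.normal(0.25, 0.03, 5000),
                                       rng.normal(0.80, 0.03, 5000)]), 0, 1)
        thr = pm.select_threshold(make_track(vals))
        assert thr.modality == "bimodal"
        assert 0.35 < thr.threshold < 0.70
        oracle = brute_force_kde_argmin(vals, 0.35, 0.70)
        assert abs(thr.threshold - oracle) <= 0.05

    def test_close_modes_treated_unimodal(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0.70, 0.02, 3000),
                               rng.normal(0.80, 0.02, 3000)])
        thr = pm.select_threshold(make_track(vals))
        assert thr.modality == "unimodal"
        assert thr.threshold == 0.60

    def test_too_few_windows_errors(self):
        track = make_track(np.full(100, 0.8))
        with pytest.raises(ValueError, match="scored windows"):
            pm.select_threshold(track)


def _run_track(run_bp, state=0.2, background=0.8, step=200, W=100_000,
               chrom_bp=1_000_000):
    """Track whose first `run_bp` of merged window span is hypomethylated."""
    starts = np.arange(0, chrom_bp - W + 1, step, dtype=np.int64)
    meth = np.where(starts + W <= run_bp, state, background)
    df = pd.DataFrame({"chrom": "chr1", "start": starts, "meth": meth,
                       "n_cpg": 100})
    return pm.WindowTrack("s", df, W, step)


THR = SourceThreshold(source="s", modality="unimodal", threshold=0.5)


class TestPmdCalling:
    def test_run_of_300kb_is_retained(self):
        pmds = call_pmds_per_source(_run_track(300_000), THR)
        assert pmds.df.values.tolist() == [["chr1", 0, 300_000]]

    def test_run_of_150kb_is_removed(self):
        pmds = call_pmds_per_source(_run_track(150_000), THR)
        assert len(pmds) == 0

    def test_no_window_below_threshold_gives_empty_set(self):
        pmds = call_pmds_per_source(_run_track(0), THR)
        assert len(pmds) == 0

    def test_raising_threshold_never_shrinks_hypo_set(self):
        rng = np.random.default_rng(3)
        track = make_track(rng.uniform(0, 1, 2000))
        lo = hypomethylated_windows(
            track, SourceThreshold("s", "unimodal", 0.4))
        hi = hypomethylated_windows(
            track, SourceThreshold("s", "unimodal", 0.7))
        assert iv.genome_total_bp(iv.genome_union(lo, hi)) == iv.genome_total_bp(hi)

    def test_all_windows_below_threshold_gives_100_percent(self):
        track = _run_track(1_000_000)
        assert hypomethylated_fraction(track, THR) == 100.0


class TestUnion:
    def test_overlapping_sources_merge(self):
        a = pm.DomainSet(pd.DataFrame([("chr1", 0, 1_000_000)],
                                      columns=["chrom", "start", "end"]), "PMD")
        b = pm.DomainSet(pd.DataFrame([("chr1", 500_000, 1_500_000)],
                                      columns=["chrom", "start", "end"]), "PMD")
        u = union_domains([a, b])
        assert u.df.values.tolist() == [["chr1", 0, 1_500_000]]
        assert u.scope == "total"

    def test_identical_sources_idempotent(self):
        a = pm.DomainSet(pd.DataFrame([("chr1", 0, 300_000),
                                       ("chr2", 100_000, 600_000)],
                                      columns=["chrom", "start", "end"]), "PMD")
        u = union_domains([a, a, a])
        pd.testing.assert_frame_equal(u.df, a.df)

    def test_random_sets_match_bp_membership_oracle(self):
        rng = np.random.default_rng(4)
        sets = []
        for _ in range(4):
            starts = np.sort(rng.choice(np.arange(0, 990, 10), 5, replace=False))
            rows = [("chr1", int(s) * 1000, int(s + rng.integers(1, 10)) * 1000)
                    for s in starts]
            sets.append(pm.DomainSet(
                pd.DataFrame(iv.merge([(r[1], r[2]) for r in rows]),
                             columns=["start", "end"]).assign(chrom="chr1"),
                "PMD"))
        u = union_domains(sets)
        member = np.zeros(1_000_000, dtype=bool)   # 1-kb resolution oracle
        for d in sets:
            for r in d.df.itertuples():
                member[r.start // 1000 * 1000: r.end] = True
        got = np.zeros_like(member)
        for r in u.df.itertuples():
            got[r.start: r.end] = True
        assert np.array_equal(got, member)


class TestQuantileNormalization:
    def test_identical_columns_map_to_themselves(self):
        rng = np.random.default_rng(5)
        col = rng.uniform(0, 1, 50)
        m = pd.DataFrame({f"s{i}": col for i in range(8)})
        out = quantile_normalize_columns(m)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy())

    def test_normalization_preserves_within_column_order(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.uniform(0, 1, (40, 5)))
        out = quantile_normalize_columns(m)
        for j in m.columns:
            assert (np.argsort(m[j].to_numpy(), kind="stable")
                    == np.argsort(out[j].to_numpy(), kind="stable")).all()

    def test_core_flags_respect_cutoff(self):
        rows = {"deep": 0.10, "shallow": 0.30}
        data = {f"s{i}": [0.10, 0.30] + [0.80] * 6 for i in range(8)}
        m = pd.DataFrame(data, index=["deep", "shallow"] + [f"f{k}" for k in range(6)])
        flags, norm = core_pmds_from_matrix(m, cutoff=0.25)
        assert flags["deep"] and not flags["shallow"]
        assert norm.loc["deep"].mean() < 0.25 <= norm.loc["shallow"].mean()

    def test_uncovered_row_excluded_from_core(self, caplog):
        m = pd.DataFrame({"a": [0.1, 0.1], "b": [0.1, np.nan]},
                         index=["r1", "r2"])
        with caplog.at_level("WARNING"):
            flags, _ = core_pmds_from_matrix(m)
        assert flags["r1"] and not flags["r2"]
        assert "lack coverage" in caplog.text


def _pmds_with_gaps(*gaps):
    rows, cur = [], 0
    for g in gaps:
        rows.append(("chr1", cur, cur + 100_000))
        cur += 100_000 + g
    rows.append(("chr1", cur, cur + 100_000))
    return pm.DomainSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                        "PMD", source="s")


class TestPmiCalling:
    def test_length_bounds_are_strict(self):
        pmis = call_pmis_per_source(_pmds_with_gaps(20_000, 100_000, 3_500_000))
        assert pmis.lengths().tolist() == [100_000]
        assert call_pmis_per_source(_pmds_with_gaps(30_000)).df.empty
        assert call_pmis_per_source(_pmds_with_gaps(3_000_000)).df.empty
        assert len(call_pmis_per_source(_pmds_with_gaps(30_001))) == 1

    def test_single_pmd_yields_no_pmi(self):
        single = pm.DomainSet(pd.DataFrame([("chr1", 0, 300_000)],
                                           columns=["chrom", "start", "end"]),
                              "PMD")
        assert len(call_pmis_per_source(single)) == 0

    def _pmi(self, *rows):
        return pm.DomainSet(pd.DataFrame(list(rows),
                                         columns=["chrom", "start", "end"]),
                            "PMI")

    def test_core_requires_overlap_in_every_source(self):
        shared = self._pmi(("chr1", 0, 50_000))
        total, core = designate_core_pmis([shared, shared, shared])
        assert len(core) == 1
        other = self._pmi(("chr1", 500_000, 550_000))
        total, core = designate_core_pmis([shared, shared, other])
        assert len(core) == 0 and len(total) == 2

    def test_staggered_overlapping_pmis_are_core(self):
        a = self._pmi(("chr1", 0, 50_000))
        b = self._pmi(("chr1", 40_000, 90_000))
        c = self._pmi(("chr1", 45_000, 55_000))
        total, core = designate_core_pmis([a, b, c])
        assert core.df.values.tolist() == [["chr1", 0, 90_000]]


class TestRecovery:
    """Planted-domain recovery on the default toy tumor methylome."""

    def test_pipeline_recovers_planted_pmds(self, tumor_run):
        thr = tumor_run["thr"]
        assert thr.modality == "bimodal"
        pmds = call_pmds_per_source(tumor_run["track"], thr)
        assert (pmds.lengths() >= 250_000).all()
        j = iv.genome_jaccard(pmds.by_chrom(),
                              tumor_run["truth"].pmd_by_source["tumor_0"].by_chrom())
        assert j >= 0.95

    def test_pipeline_recovers_planted_pmis(self, tumor_run):
        pmds = call_pmds_per_source(tumor_run["track"], tumor_run["thr"])
        pmis = call_pmis_per_source(pmds)
        lens = pmis.lengths()
        assert ((lens > 30_000) & (lens < 3_000_000)).all()
        j = iv.genome_jaccard(pmis.by_chrom(),
                              tumor_run["truth"].pmi_by_source["tumor_0"].by_chrom())
        assert j >= 0.90

    def test_core_sets_are_subsets_of_total(self, multisource_run):
        total, core = multisource_run["total"], multisource_run["core"]
        assert iv.genome_overlap_bp(core.by_chrom(), total.by_chrom()) == core.total_bp
        tot_pmi, core_pmi = designate_core_pmis(multisource_run["per_pmi"])
        assert iv.genome_overlap_bp(core_pmi.by_chrom(), tot_pmi.by_chrom()) \
            == core_pmi.total_bp

    def test_shared_planted_pmd_is_core_private_is_not(self, multisource_run):
        core, norm = multisource_run["core"], multisource_run["norm"]
        # the two chr1 segments of the shared PMD are core, the four
        # private chr2 PMDs are not
        assert sorted(core.df["chrom"].unique()) == ["chr1"]
        assert len(core) == 2
        row_means = norm.mean(axis=1)
        assert (row_means[core.df.apply(
            lambda r: f"{r.chrom}:{r.start}-{r.end}", axis=1)] < 0.25).all()

    def test_shared_planted_pmi_is_core(self, multisource_run):
        tot, core = designate_core_pmis(multisource_run["per_pmi"])
        assert len(core) == 1
        planted = np.array([[2_500_000, 3_500_000]])
        assert iv.overlap_bp(core.by_chrom()["chr1"], planted) > 900_000
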