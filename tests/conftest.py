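import numpy as np
import pandas as pd
import pytest

import pmdscape as pm


@pytest.fixture(scope="session")
def tumor_run():
    """Default toy tumor methylome run through windowing + thresholding."""
    spec = pm.toy_tumor_spec(seed=1)
    layout, calls, truth = pm.generate_methylome(spec)
    track = pm.build_window_track(calls, layout)["tumor_0"]
    thr = pm.select_threshold(track)
    return {"spec": spec, "layout": layout, "calls": calls, "truth": truth,
            "track": track, "thr": thr}


@pytest.fixture(scope="session")
def normal_run():
    spec = pm.toy_normal_spec(seed=1)
    layout, calls, truth = pm.generate_methylome(spec)
    track = pm.build_window_track(calls, layout)["normal_0"]
    thr = pm.select_threshold(track)
    return {"spec": spec, "layout": layout, "calls": calls, "truth": truth,
            "track": track, "thr": thr}


@pytest.fixture(scope="session")
def multisource_run():
    spec = pm.multisource_spec(n_sources=4, seed=3, n_cells=4)
    layout, calls, truth = pm.generate_methylome(spec)
    tracks = pm.build_window_track(calls, layout)
    per_pmd, per_pmi = [], []
    for src in sorted(tracks):
        thr = pm.select_threshold(tracks[src])
        p = pm.call_pmds_per_source(tracks[src], thr)
        per_pmd.append(p)
        per_pmi.append(pm.call_pmis_per_source(p))
    total = pm.union_domains(per_pmd)
    core, mat, norm = pm.designate_core_pmds(total, calls)
    return {"spec": spec, "layout": layout, "calls": calls, "truth": truth,
            "per_pmd": per_pmd, "per_pmi": per_pmi, "total": total,
            "core": core, "matrix": mat, "norm": norm}


@pytest.fixture(scope="session")
def spikein_run():
    """1% in-silico tumor spike-in long-read mixture over the toy PMDs."""
    spec = pm.toy_tumor_spec(seed=1)
    layout, _, truth = pm.generate_methylome(spec)
    pmds = truth.pmd_total
    reads, origins = pm.generate_longreads(spec, pmds, n_reads=20_000,
                                           tumor_fraction=0.01, seed=1)
    return {"spec": spec, "layout": layout, "pmds": pmds,
            "reads": reads, "origins": origins}


def make_track(values, source="s", window_size=100_000, window_step=200,
               chrom="chr1"):
    """WindowTrack with given methylation values at consecutive offsets."""
    values = np.asarray(values, float)
    starts = np.arange(len(values), dtype=np.int64) * window_step
    df = pd.DataFrame({"chrom": chrom, "start": starts, "meth": values,
                       "n_cpg": 100})
    return pm.WindowTrack(source=source, df=df, window_size=window_size,
                          window_step=window_step)
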