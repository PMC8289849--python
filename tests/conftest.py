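import pandas as pd
import pytest

import tcr_clonoscope as tc
from tcr_clonoscope.simulate import SimConfig, simulate


def run_pipeline(bundle, workdir):
    """Round-trip a simulated bundle through the file readers and call
    clonotypes — the same path the CLI takes."""
    d = bundle.write(workdir)
    frames = [
        tc.read_contigs(p, p.stem.removeprefix("contigs_"))
        for p in sorted(d.glob("contigs_*.csv"))
    ]
    contigs = pd.concat(frames, ignore_index=True)
    meta = tc.read_cell_meta(d / "meta.tsv")
    cells = tc.call_clonotypes(tc.pair_chains(contigs, meta))
    cells.attrs["run_id"] = bundle.ground_truth["run_id"]
    return cells


def truth_cells(bundle):
    """Called-cell table assembled from generator bookkeeping (bypasses
    parsing; used where only the downstream statistics are under test).
    Clonotype pairs are globally unique by construction, so the registry
    index IS the pooled clonotype."""
    cells = bundle.cells.copy()
    idx = cells["clonotype_idx"]
    cells["clonotype_id"] = idx.where(idx >= 0).map(
        lambda i: f"ct{int(i)}", na_action="ignore"
    )
    sizes = cells[idx >= 0].groupby("clonotype_idx")["barcode"].size()
    cells["clone_size"] = idx.map(sizes).where(idx >= 0)
    cells["has_ab"] = ~cells["na"]
    truth = bundle.ground_truth["clonotypes"]
    cells["alpha_cdr3"] = [truth[i]["alpha"] if i >= 0 else None for i in idx]
    cells["beta_cdr3"] = [truth[i]["beta"] if i >= 0 else None for i in idx]
    return cells


@pytest.fixture(scope="session")
def default_bundle():
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_cells(default_bundle, tmp_path_factory):
    return run_pipeline(default_bundle, tmp_path_factory.mktemp("bundle"))
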