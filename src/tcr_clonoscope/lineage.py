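"""TCR-sharing lineage evidence.

Clonotypes whose cells occupy several transcriptomic clusters connect those
clusters as putative differentiation states; this module finds clonotypes
spanning a target cluster set, places clonotypes in a 2-D trajectory or
embedding by averaging member-cell coordinates, and summarizes sample
composition over a k x k grid of the embedding.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def shared_clonotypes(
    cells: pd.DataFrame,
    target_clusters,
    restrict=None,
) -> pd.DataFrame:
    """Clonotypes whose (restricted) cells cover every target cluster.

    ``restrict`` is an optional boolean mask or predicate (e.g. PD blood
    only) applied before span evaluation.  Returns one row per spanning
    clonotype with its full cluster occupancy and cell count; an empty
    result (with a warning) if a target cluster is absent from the data.
    """
    targets = set(map(str, target_clusters))
    sub = cells
    if restrict is not None:
        mask = restrict(cells) if callable(restrict) else restrict
        sub = cells[np.asarray(mask, dtype=bool)]
    sub = sub[sub["clonotype_id"].notna() & sub["cluster"].notna()]
    observed = set(sub["cluster"].astype(str).unique())
    absent = targets - observed
    if absent:
        logger.warning("target clusters absent from data: %s", sorted(absent))
        return pd.DataFrame(columns=["clonotype_id", "clusters_present", "n_cells"])
    rows = []
    for cid, grp in sub.groupby("clonotype_id", sort=True):
        present = set(grp["cluster"].astype(str))
        if targets <= present:
            rows.append(
                {
                    "clonotype_id": cid,
                    "clusters_present": ",".join(sorted(present)),
                    "n_cells": len(grp),
                }
            )
    out = pd.DataFrame(rows, columns=["clonotype_id", "clusters_present", "n_cells"])
    return out.sort_values("clonotype_id", kind="mergesort").reset_index(drop=True) if len(out) else out


def clonotype_centroids(cells: pd.DataFrame, stratify_by_cluster: bool = False) -> pd.DataFrame:
    """Clonotype positions in the embedding: the arithmetic mean of member-cell
    coordinates, optionally per (clonotype, cluster) stratum.

    Cells without coordinates are excluded (count logged).  Output columns:
    clonotype_id, [cluster,] x, y, size.
    """
    sub = cells[cells["clonotype_id"].notna()]
    missing = sub["embed_x"].isna() | sub["embed_y"].isna()
    if missing.any():
        logger.info("excluding %d cells without embedding coordinates", int(missing.sum()))
    sub = sub[~missing]
    keys = ["clonotype_id", "cluster"] if stratify_by_cluster else ["clonotype_id"]
    if stratify_by_cluster:
        sub = sub[sub["cluster"].notna()]
    out = (
        sub.groupby(keys, sort=True)
        .agg(x=("embed_x", "mean"), y=("embed_y", "mean"), size=("barcode", "size"))
        .reset_index()
    )
    return out


def grid_composition(
    cells: pd.DataFrame,
    k: int = 10,
    composition_key: str = "sample_id",
) -> pd.DataFrame:
    """Composition of cells over a k x k grid of the embedding.

    Bins are equal-width over [min, max] of each coordinate with the last
    edge inclusive; a degenerate axis (max == min) collapses to a single bin
    with a warning.  Only occupied bins are returned, long-format: bin_x,
    bin_y, level of ``composition_key`` (sample or condition), n_cells,
    fraction; fractions sum to 1 within each bin.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = cells[cells["embed_x"].notna() & cells["embed_y"].notna()].copy()
    if sub.empty:
        raise ValueError("no cells with embedding coordinates")

    def _bin(values: pd.Series) -> np.ndarray:
        lo, hi = float(values.min()), float(values.max())
        if hi == lo:
            logger.warning("degenerate embedding axis (min == max); using a single bin")
            return np.zeros(len(values), dtype=int)
        idx = np.floor((values.to_numpy() - lo) / (hi - lo) * k).astype(int)
        return np.clip(idx, 0, k - 1)  # max edge inclusive

    sub["bin_x"] = _bin(sub["embed_x"])
    sub["bin_y"] = _bin(sub["embed_y"])
    counts = (
        sub.groupby(["bin_x", "bin_y", composition_key]).size().rename("n_cells").reset_index()
    )
    totals = counts.groupby(["bin_x", "bin_y"])["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    return counts.sort_values(["bin_x", "bin_y", composition_key]).reset_index(drop=True)
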