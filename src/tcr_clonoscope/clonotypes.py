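"""Clonotype calling on paired-chain cells.

Cells with identical alpha-chain AND beta-chain CDR3 amino-acid sequences
belong to one clonotype; chains are pooled across samples and tissues before
calling, so one clonotype may span samples.  Identity is at the amino-acid
level only (case-normalized); V genes do not enter the key — the modal V
genes of member cells are recorded for downstream CDR3 grouping.

Cells lacking either chain are never clonotyped but are kept by the caller
for NA-stratum statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


def call_clonotypes(cells: pd.DataFrame) -> pd.DataFrame:
    """Assign clonotype ids to paired cells.

    Eligible cells (``has_ab`` true) are partitioned by their
    ``(alpha_cdr3, beta_cdr3)`` key, pooled across all samples.  Ids are
    ``clonotype1, clonotype2, ...`` in descending total size, ties broken by
    lexicographic (alpha, beta) key, so calling is invariant to row order.

    Returns a copy of ``cells`` with ``clonotype_id`` (NaN for NA-stratum
    cells) and ``clone_size`` (pooled size of the cell's clonotype) columns.
    """
    out = cells.copy()
    out["clonotype_id"] = pd.Series(np.nan, index=out.index, dtype=object)
    out["clone_size"] = np.nan
    eligible = out["has_ab"].fillna(False).astype(bool)
    if not eligible.any():
        return out
    sub = out.loc[eligible]
    keys = list(zip(sub["alpha_cdr3"].str.upper(), sub["beta_cdr3"].str.upper()))
    counts: dict[tuple[str, str], int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    ordered = sorted(counts, key=lambda k: (-counts[k], k[0], k[1]))
    ids = {k: f"clonotype{i + 1}" for i, k in enumerate(ordered)}
    out.loc[eligible, "clonotype_id"] = [ids[k] for k in keys]
    out.loc[eligible, "clone_size"] = [counts[k] for k in keys]
    return out


def _modal(series: pd.Series) -> str:
    """Most frequent value; ties broken lexicographically."""
    vc = series.dropna().value_counts()
    if vc.empty:
        return ""
    top = vc[vc == vc.max()].index
    return sorted(top)[0]


def clonotype_table(cells: pd.DataFrame, wide_by: str = "sample_id") -> pd.DataFrame:
    """Summarize called cells into one row per clonotype.

    Columns: clonotype_id, alpha_cdr3, beta_cdr3, modal alpha/beta V genes,
    size, plus one ``n_<value>`` count column per level of ``wide_by``
    (sample by default).  Row order follows the deterministic id ranking.
    """
    called = cells[cells["clonotype_id"].notna()]
    if called.empty:
        return pd.DataFrame(
            columns=["clonotype_id", "alpha_cdr3", "beta_cdr3", "alpha_v", "beta_v", "size"]
        )
    agg = called.groupby("clonotype_id", sort=False).agg(
        alpha_cdr3=("alpha_cdr3", "first"),
        beta_cdr3=("beta_cdr3", "first"),
        alpha_v=("alpha_v", _modal),
        beta_v=("beta_v", _modal),
        size=("barcode", "size"),
    )
    wide = (
        called.groupby(["clonotype_id", wide_by]).size().unstack(fill_value=0).add_prefix("n_")
    )
    table = agg.join(wide).reset_index()
    table["_rank"] = table["clonotype_id"].str.removeprefix("clonotype").astype(int)
    table = table.sort_values("_rank").drop(columns="_rank").reset_index(drop=True)
    return table


def sizes_by(cells: pd.DataFrame, key: str) -> pd.DataFrame:
    """Per-clonotype cell counts broken down by ``key``
    (one of sample_id, cluster, tissue, condition); counts sum to size."""
    called = cells[cells["clonotype_id"].notna()]
    return called.groupby(["clonotype_id", key]).size().unstack(fill_value=0)


class ClonotypeCaller(BaseEstimator):
    """Clustering-style estimator wrapping :func:`call_clonotypes`.

    ``fit(X)`` takes the paired-cell DataFrame and exposes:

    - ``labels_`` : integer clonotype label per input row (-1 for NA cells),
      0-based in the deterministic id order;
    - ``cells_`` : the input with ``clonotype_id``/``clone_size`` columns;
    - ``clonotypes_`` : the per-clonotype summary table.
    """

    def __init__(self, wide_by: str = "sample_id"):
        self.wide_by = wide_by

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame) or "has_ab" not in X.columns:
            raise ValueError("X must be a paired-cell DataFrame with a 'has_ab' column")
        cells = call_clonotypes(X)
        self.cells_ = cells
        self.clonotypes_ = clonotype_table(cells, wide_by=self.wide_by)
        labels = np.full(len(cells), -1, dtype=int)
        mask = cells["clonotype_id"].notna().to_numpy()
        labels[mask] = (
            cells.loc[mask, "clonotype_id"].str.removeprefix("clonotype").astype(int) - 1
        )
        self.labels_ = labels
        self.n_clonotypes_ = int(len(self.clonotypes_))
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_
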