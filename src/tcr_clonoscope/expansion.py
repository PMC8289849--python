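"""Clonal-expansion statistics.

Covers the clone-size spectrum (clonotypes per clone size), the downsampling
comparison of spectra between two cell groups (paired two-sided Wilcoxon
across matched clone-size bins, repeated over seeded draws), per-sample
clone-size strata percentages, per-cluster Fisher enrichment of clonally
expanded cells with Benjamini-Hochberg correction, mean clone size, and
cell-type composition stratified by clone size.

"Clonally expanded" means clone size >= 2 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXPANDED_MIN_SIZE = 2

#: clone-size strata as displayed: NA plus cumulative thresholds
STRATA_CUMULATIVE = ("NA", "=1", ">=2", ">=20", ">=100")
STRATA_DISJOINT = ("NA", "1", "2-19", "20-99", ">=100")


@dataclass(frozen=True)
class CloneSizeSpectrum:
    """Map clone size -> number of clonotypes of that size within one group."""

    group_id: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(sum(s * c for s, c in self.counts.items()))

    @property
    def n_clonotypes(self) -> int:
        return int(sum(self.counts.values()))


def clone_size_spectrum(cells: pd.DataFrame, restrict=None, group_id: str = "all") -> CloneSizeSpectrum:
    """Clone-size spectrum over a (possibly restricted) cell subset.

    ``restrict`` is a boolean mask or a predicate applied to the cell table;
    clonotype sizes are recomputed within the restricted subset, so a pooled
    clonotype contributes at the size it attains inside the subset.
    NA-stratum cells never contribute.
    """
    sub = cells
    if restrict is not None:
        mask = restrict(cells) if callable(restrict) else restrict
        sub = cells[np.asarray(mask, dtype=bool)]
    sub = sub[sub["clonotype_id"].notna()]
    if sub.empty:
        return CloneSizeSpectrum(group_id, {})
    sizes = sub["clonotype_id"].value_counts()
    spectrum = sizes.value_counts().sort_index()
    return CloneSizeSpectrum(group_id, {int(s): int(c) for s, c in spectrum.items()})


@dataclass(frozen=True)
class DownsampleResult:
    p_values: np.ndarray  # per-iteration, NaN where a test was degenerate
    median_p: float
    n_drawn: int
    n_iter: int


def _binned_counts(ids: np.ndarray) -> dict[int, int]:
    _, per_clone = np.unique(ids, return_counts=True)
    sizes, n_clonotypes = np.unique(per_clone, return_counts=True)
    return dict(zip(sizes.tolist(), n_clonotypes.tolist()))


def downsample_compare(
    group_a: np.ndarray | pd.Series,
    group_b: np.ndarray | pd.Series,
    n_iter: int = 100,
    seed: int = 0,
    log_counts: bool = False,
) -> DownsampleResult:
    """Downsampling comparison of clone-size spectra between two cell groups.

    Each group is an array of clonotype ids, one entry per cell.  Per
    iteration, ``min(|A|, |B|)`` cells are drawn without replacement from
    each group (removing the bias from unequal totals), clone sizes are
    recomputed within each draw, and the clonotypes-per-clone-size counts of
    the two draws — matched on the union of observed sizes, zeros imputed —
    are compared with a paired two-sided Wilcoxon signed-rank test.

    The per-group random substream for iteration ``i`` is seeded by
    ``(seed, i)`` independently of argument order, so swapping the groups
    reproduces the identical p-values.  All paired differences zero gives
    p = 1.0 by convention; an iteration with fewer than two clone-size bins
    is recorded as NaN and excluded from the median.

    ``log_counts`` applies log1p to the binned counts before testing.
    """
    a = np.asarray(pd.Series(group_a).dropna())
    b = np.asarray(pd.Series(group_b).dropna())
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    m = min(a.size, b.size)
    pvals = np.full(n_iter, np.nan)
    # equal-sized groups: every draw is a permutation of the full group, so
    # all iterations yield the same spectra; compute once and broadcast
    full_draw = a.size == b.size == m
    for i in range(1 if full_draw else n_iter):
        draws = []
        for grp in (a, b):
            rng = np.random.default_rng([seed, i])
            idx = rng.choice(grp.size, size=m, replace=False)
            draws.append(_binned_counts(grp[idx]))
        ca, cb = draws
        union = sorted(set(ca) | set(cb))
        if len(union) < 2:
            logger.warning("iteration %d: fewer than 2 clone-size bins; recording NaN", i)
            continue
        va = np.array([ca.get(s, 0) for s in union], dtype=float)
        vb = np.array([cb.get(s, 0) for s in union], dtype=float)
        if log_counts:
            va, vb = np.log1p(va), np.log1p(vb)
        if np.all(va == vb):
            pvals[i] = 1.0
            continue
        res = stats.wilcoxon(va, vb, alternative="two-sided", zero_method="wilcox")
        pvals[i] = float(res.pvalue)
    if full_draw:
        pvals[:] = pvals[0]
    if np.isnan(pvals).all():
        logger.warning("all iterations degenerate; median p undefined")
        median = float("nan")
    else:
        median = float(np.nanmedian(pvals))
    return DownsampleResult(pvals, median, m, n_iter)


def _stratum_disjoint(size: float) -> str:
    if np.isnan(size):
        return "NA"
    if size == 1:
        return "1"
    if size < 20:
        return "2-19"
    if size < 100:
        return "20-99"
    return ">=100"


def strata_percentages(cells: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-sample percentage of cells per clone-size stratum.

    A cell's stratum derives from its pooled clonotype size (``clone_size``);
    cells without a complete alpha-beta pair form the NA stratum.  Returns
    two views: ``'cumulative'`` (NA, =1, >=2, >=20, >=100 — overlapping by
    construction) and ``'disjoint'`` (NA, 1, 2-19, 20-99, >=100 — rows sum
    to 100%).
    """
    df = cells.copy()
    size = pd.to_numeric(df["clone_size"], errors="coerce")
    df["_band"] = [_stratum_disjoint(s) for s in size]
    totals = df.groupby("sample_id").size()

    disjoint = (
        df.groupby(["sample_id", "_band"]).size().unstack(fill_value=0)
        .reindex(columns=list(STRATA_DISJOINT), fill_value=0)
    )
    disjoint = 100.0 * disjoint.div(totals, axis=0)
    disjoint.columns.name = None

    cumulative = pd.DataFrame(index=disjoint.index)
    cumulative["NA"] = disjoint["NA"]
    cumulative["=1"] = disjoint["1"]
    cumulative[">=2"] = disjoint[["2-19", "20-99", ">=100"]].sum(axis=1)
    cumulative[">=20"] = disjoint[["20-99", ">=100"]].sum(axis=1)
    cumulative[">=100"] = disjoint[">=100"]
    return {"cumulative": cumulative, "disjoint": disjoint}


def cluster_expansion_enrichment(
    cells: pd.DataFrame,
    design: str = "condition_by_expanded",
    conditions: tuple[str, str] = ("PD", "HC"),
) -> pd.DataFrame:
    """Per-cluster Fisher exact test for enrichment of clonal expansion.

    ``design='condition_by_expanded'`` (default) builds, within each
    cluster, the 2x2 table (condition PD vs HC) x (expanded vs not), asking
    whether expanded cells in the cluster are disproportionately from PD.
    ``design='within_condition'`` restricts to the first condition's cells
    and tests (in-cluster vs out-of-cluster) x (expanded vs not).

    Expanded means pooled clone size >= 2.  P-values are two-sided;
    Benjamini-Hochberg FDR is computed across the cluster family.  Clusters
    with an empty table margin are flagged degenerate (p = 1, odds ratio
    NaN).  Results are sorted by FDR then cluster label.
    """
    df = cells[cells["cluster"].notna()].copy()
    df["_expanded"] = pd.to_numeric(df["clone_size"], errors="coerce") >= EXPANDED_MIN_SIZE
    records = []
    clusters = sorted(df["cluster"].astype(str).unique())
    for cl in clusters:
        in_cl = df["cluster"].astype(str) == cl
        if design == "condition_by_expanded":
            sub = df[in_cl]
            is_a = sub["condition"] == conditions[0]
            a = int((is_a & sub["_expanded"]).sum())
            b = int((is_a & ~sub["_expanded"]).sum())
            c = int((~is_a & sub["_expanded"]).sum())
            d = int((~is_a & ~sub["_expanded"]).sum())
        elif design == "within_condition":
            sub = df[df["condition"] == conditions[0]]
            in_sub = sub["cluster"].astype(str) == cl
            a = int((in_sub & sub["_expanded"]).sum())
            b = int((in_sub & ~sub["_expanded"]).sum())
            c = int((~in_sub & sub["_expanded"]).sum())
            d = int((~in_sub & ~sub["_expanded"]).sum())
        else:
            raise ValueError(f"unknown design {design!r}")
        table = np.array([[a, b], [c, d]])
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if degenerate:
            odds, p = float("nan"), 1.0
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        records.append(
            {
                "cluster": cl,
                "odds_ratio": float(odds),
                "p_value": float(p),
                "a_expanded": a,
                "a_not": b,
                "b_expanded": c,
                "b_not": d,
                "degenerate": bool(degenerate),
            }
        )
    res = pd.DataFrame(records)
    if not res.empty:
        res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
        res = res.sort_values(["fdr", "cluster"], kind="mergesort").reset_index(drop=True)
    return res


def mean_clone_size(cells: pd.DataFrame) -> float:
    """Cells per distinct clonotype within a subset (e.g. 2301 cells in 371
    clonotypes -> 6.2).  All cells must be clonotyped; empty input is an error."""
    if len(cells) == 0:
        raise ValueError("empty cell subset")
    if cells["clonotype_id"].isna().any():
        raise ValueError("subset contains unclonotyped cells")
    return len(cells) / cells["clonotype_id"].nunique()


def composition_by_clone_size(cells: pd.DataFrame) -> pd.DataFrame:
    """Cell-type (cluster) composition per sample and clone-size stratum.

    Long-format output with columns sample_id, stratum (disjoint bands plus
    NA), cluster, n_cells, fraction; fractions sum to 1 within each
    (sample, stratum) that has at least one cell.
    """
    df = cells[cells["cluster"].notna()].copy()
    size = pd.to_numeric(df["clone_size"], errors="coerce")
    df["stratum"] = [_stratum_disjoint(s) for s in size]
    counts = (
        df.groupby(["sample_id", "stratum", "cluster"]).size().rename("n_cells").reset_index()
    )
    totals = counts.groupby(["sample_id", "stratum"])["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    return counts.sort_values(["sample_id", "stratum", "cluster"]).reset_index(drop=True)
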