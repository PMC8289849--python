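"""D50 repertoire diversity and between-group comparison.

D50 is the percentage of top-ranked clonotypes needed to accumulate half of
all receptor sequences detected in a sample: with per-sample frequencies
N_1 >= N_2 >= ... >= N_n, D50 = 100 * k* / n where k* is the smallest k such
that sum_{i<=k} N_i >= (1/2) sum_i N_i.  A maximally even repertoire
approaches 50; heavy clonal expansion drives it toward 100/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RepertoireCounts:
    """One sample's descending clonotype frequency vector.

    ``freqs`` is validated and stored sorted non-increasing; all entries
    must be positive integers.
    """

    sample_id: str
    freqs: np.ndarray = field(repr=False)

    def __post_init__(self):
        arr = np.asarray(self.freqs)
        if arr.size == 0:
            raise ValueError("empty frequency vector")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("frequencies must be integers")
            arr = np.round(arr).astype(np.int64)
        if (arr < 1).any():
            raise ValueError("frequencies must be >= 1")
        arr = np.sort(arr)[::-1]
        arr.setflags(write=False)
        object.__setattr__(self, "freqs", arr)

    @property
    def n(self) -> int:
        return int(self.freqs.size)

    @property
    def total(self) -> int:
        return int(self.freqs.sum())


def d50(counts: RepertoireCounts | np.ndarray) -> float:
    """D50 of one repertoire, as a percentage in (0, 100].

    A maximally even repertoire gives 50 (up to the +1 discretization for
    odd clonotype counts); heavy expansion drives the value toward 100/n.

    Accepts a :class:`RepertoireCounts` or a raw frequency vector (sorted
    internally).  Ties at exactly half the total count as reached.
    """
    if not isinstance(counts, RepertoireCounts):
        counts = RepertoireCounts("_", np.asarray(counts))
    cs = np.cumsum(counts.freqs)
    half = counts.total / 2.0
    k = int(np.argmax(cs >= half)) + 1
    return 100.0 * k / counts.n


def repertoire_counts(cells: pd.DataFrame, by: str = "clonotype") -> list[RepertoireCounts]:
    """Per-sample frequency vectors from a called cell table.

    ``by='clonotype'`` counts cells per paired-chain clonotype within each
    sample (default); ``by='beta'`` counts cells per beta-chain CDR3, which
    matches a CDR3-level reading of the statistic.
    """
    if by == "clonotype":
        sub = cells[cells["clonotype_id"].notna()]
        key = "clonotype_id"
    elif by == "beta":
        sub = cells[cells["beta_cdr3"].notna()]
        key = "beta_cdr3"
    else:
        raise ValueError("by must be 'clonotype' or 'beta'")
    out = []
    for sid, grp in sub.groupby("sample_id", sort=True):
        out.append(RepertoireCounts(str(sid), grp[key].value_counts().to_numpy()))
    return out


@dataclass(frozen=True)
class DiversityComparison:
    statistic: float
    pvalue: float
    test: str
    d50_by_group: dict[str, np.ndarray]


def compare_diversity(
    samples: list[RepertoireCounts],
    labels: list[str],
    test: str = "wilcoxon_two_sided",
) -> DiversityComparison:
    """Two-sample comparison of per-sample D50 between two condition groups.

    ``test`` is ``'wilcoxon_two_sided'`` (two-sided Wilcoxon rank-sum /
    Mann-Whitney, default) or ``'t_test'`` (Welch).  Requires at least two
    samples per condition.
    """
    if len(samples) != len(labels):
        raise ValueError("samples and labels must align")
    values: dict[str, list[float]] = {}
    for rc, lab in zip(samples, labels):
        values.setdefault(str(lab), []).append(d50(rc))
    if len(values) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {sorted(values)}")
    (ga, xs), (gb, ys) = sorted(values.items())
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("insufficient replication: need >= 2 samples per condition")
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if test == "wilcoxon_two_sided":
        if np.ptp(np.concatenate([xs, ys])) == 0:
            # all values identical: no evidence of a difference by convention
            res_stat, pvalue = float(len(xs) * len(ys) / 2.0), 1.0
        else:
            res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method="auto")
            res_stat, pvalue = float(res.statistic), float(res.pvalue)
    elif test == "t_test":
        res = stats.ttest_ind(xs, ys, equal_var=False)
        res_stat, pvalue = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError("test must be 'wilcoxon_two_sided' or 't_test'")
    return DiversityComparison(res_stat, pvalue, test, {ga: xs, gb: ys})
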