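"""CDR3 specificity grouping.

Beta-chain CDR3s are clustered into putative antigen-specificity groups
under three rules: at most one amino-acid mismatch, or at most one
insertion/deletion (never both in one pair), and identical V gene across the
group.  Pairs satisfying the rules are edges; groups are the single-linkage
connected components with at least two members.

Candidate pairs are enumerated only inside buckets of (V gene, length) and
(V gene, adjacent lengths), which keeps grouping near-linear while provably
returning the same components as exhaustive all-pairs matching: a qualifying
pair always shares a V gene and has lengths differing by at most one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

_ALLELE_SUFFIX = re.compile(r"\*.*$")


def normalize_v_gene(v_gene: str) -> str:
    """Strip the allele suffix (e.g. ``TRBV5-1*01`` -> ``TRBV5-1``)."""
    return _ALLELE_SUFFIX.sub("", str(v_gene).strip())


@dataclass(frozen=True, order=True)
class TcrBeta:
    """One beta-chain receptor observation from one sample compartment."""

    cdr3: str
    v_gene: str
    sample_id: str
    tissue: str
    condition: str


@dataclass(frozen=True)
class SpecificityGroup:
    """A connected component of near-identical beta CDR3s sharing one V gene."""

    group_id: str
    members: tuple[TcrBeta, ...]
    v_gene: str

    @property
    def sample_set(self) -> frozenset[str]:
        return frozenset(m.sample_id for m in self.members)

    @property
    def cdr3s(self) -> frozenset[str]:
        return frozenset(m.cdr3 for m in self.members)

    @property
    def pd_specific(self) -> bool:
        """True when the group holds at least one PD-blood and one PD-CSF member."""
        has_blood = any(m.condition == "PD" and m.tissue == "blood" for m in self.members)
        has_csf = any(m.condition == "PD" and m.tissue == "CSF" for m in self.members)
        return has_blood and has_csf


def _hamming_le1(a: str, b: str) -> bool:
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > 1:
                return False
    return True


def _one_deletion(longer: str, shorter: str) -> bool:
    """True iff ``shorter`` equals ``longer`` with exactly one residue deleted
    and no additional mismatch."""
    i = j = 0
    skipped = False
    while i < len(longer) and j < len(shorter):
        if longer[i] == shorter[j]:
            i += 1
            j += 1
        elif not skipped:
            skipped = True
            i += 1
        else:
            return False
    return True  # any trailing surplus on `longer` is the (single) deletion


def cdr3_sequences_match(a: str, b: str) -> bool:
    """Sequence-level rule: equal length with Hamming distance <= 1, or
    lengths differing by one with a single clean deletion (edit distance <= 1,
    substitution and indel never combined)."""
    la, lb = len(a), len(b)
    if la == lb:
        return _hamming_le1(a, b)
    if abs(la - lb) != 1:
        return False
    longer, shorter = (a, b) if la > lb else (b, a)
    return _one_deletion(longer, shorter)


def cdr3_match(a: TcrBeta, b: TcrBeta) -> bool:
    """Full pairing rule: same V gene (allele-stripped) and CDR3s within one
    substitution or one indel."""
    if normalize_v_gene(a.v_gene) != normalize_v_gene(b.v_gene):
        return False
    return cdr3_sequences_match(a.cdr3.upper(), b.cdr3.upper())


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _dedup_members(tcrs) -> list[TcrBeta]:
    seen = {}
    for t in tcrs:
        member = TcrBeta(
            cdr3=t.cdr3.upper(),
            v_gene=normalize_v_gene(t.v_gene),
            sample_id=t.sample_id,
            tissue=t.tissue,
            condition=t.condition,
        )
        seen.setdefault(member, None)
    return sorted(seen)


def build_groups(tcrs) -> list[SpecificityGroup]:
    """Group beta CDR3s into specificity clusters.

    Input observations are deduplicated on (cdr3, V gene, sample, tissue,
    condition); identical receptors from different samples remain distinct
    members, so a two-sample public clone forms a valid group.  Components
    of size one are discarded.  Group ids are ``G1, G2, ...`` ranked by
    descending member count, ties broken by smallest member CDR3 then V
    gene, so output is independent of input order.
    """
    members = _dedup_members(tcrs)
    n = len(members)
    dsu = _DisjointSet(n)

    # bucket indices by (v_gene, cdr3) identity first: zero-distance merges
    by_key: dict[tuple[str, str], list[int]] = {}
    for i, m in enumerate(members):
        by_key.setdefault((m.v_gene, m.cdr3), []).append(i)
    uniq = sorted(by_key)  # one representative per distinct (v, cdr3)
    for idxs in by_key.values():
        for j in idxs[1:]:
            dsu.union(idxs[0], j)

    buckets: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for v, cdr3 in uniq:
        buckets.setdefault((v, len(cdr3)), []).append((cdr3, by_key[(v, cdr3)][0]))

    for (v, length), items in buckets.items():
        # same-length: Hamming distance <= 1
        for i in range(len(items)):
            ci, ri = items[i]
            for j in range(i + 1, len(items)):
                cj, rj = items[j]
                if _hamming_le1(ci, cj):
                    dsu.union(ri, rj)
        # adjacent-length: single deletion
        for cl, rl in buckets.get((v, length + 1), []):
            for cs, rs in items:
                if _one_deletion(cl, cs):
                    dsu.union(rl, rs)

    components: dict[int, list[TcrBeta]] = {}
    roots = [dsu.find(i) for i in range(n)]
    for i, root in enumerate(roots):
        components.setdefault(root, []).append(members[i])
    comps = [tuple(sorted(c)) for c in components.values() if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), min(m.cdr3 for m in c), c[0].v_gene))
    return [
        SpecificityGroup(group_id=f"G{i + 1}", members=c, v_gene=c[0].v_gene)
        for i, c in enumerate(comps)
    ]


def screen_pd_specific(groups: list[SpecificityGroup]) -> list[SpecificityGroup]:
    """Groups holding at least one TCR from PD blood and one from PD CSF,
    the candidates for disease-relevant specificities."""
    return [g for g in groups if g.pd_specific]


def tcrs_from_cells(cells: pd.DataFrame) -> list[TcrBeta]:
    """Extract beta-chain observations from a paired-cell table."""
    sub = cells[cells["beta_cdr3"].notna() & cells["beta_v"].notna()]
    return [
        TcrBeta(
            cdr3=str(r.beta_cdr3),
            v_gene=str(r.beta_v),
            sample_id=str(r.sample_id),
            tissue=str(r.tissue),
            condition=str(r.condition),
        )
        for r in sub.itertuples()
    ]


def groups_to_frame(groups: list[SpecificityGroup]) -> pd.DataFrame:
    """Long-format member table (group_id, cdr3, v_gene, sample_id, tissue,
    condition, pd_specific)."""
    rows = [
        {
            "group_id": g.group_id,
            "cdr3": m.cdr3,
            "v_gene": m.v_gene,
            "sample_id": m.sample_id,
            "tissue": m.tissue,
            "condition": m.condition,
            "pd_specific": g.pd_specific,
        }
        for g in groups
        for m in g.members
    ]
    return pd.DataFrame(
        rows, columns=["group_id", "cdr3", "v_gene", "sample_id", "tissue", "condition", "pd_specific"]
    )


class SpecificityClusterer(ClusterMixin, BaseEstimator):
    """Clustering estimator over beta-chain observations.

    ``fit(X)`` takes a DataFrame with columns cdr3, v_gene, sample_id,
    tissue, condition (one row per observation).  Fitted attributes:

    - ``labels_`` : integer group label per input row, -1 for singletons;
    - ``groups_`` : the list of :class:`SpecificityGroup`;
    - ``n_groups_`` : number of groups.
    """

    _required = ("cdr3", "v_gene", "sample_id", "tissue", "condition")

    def fit(self, X: pd.DataFrame, y=None):
        missing = [c for c in self._required if c not in X.columns]
        if missing:
            raise ValueError(f"X missing columns: {missing}")
        tcrs = [
            TcrBeta(str(r.cdr3), str(r.v_gene), str(r.sample_id), str(r.tissue), str(r.condition))
            for r in X.itertuples()
        ]
        self.groups_ = build_groups(tcrs)
        member_to_label = {
            m: i for i, g in enumerate(self.groups_) for m in g.members
        }
        labels = []
        for t in tcrs:
            key = TcrBeta(
                t.cdr3.upper(), normalize_v_gene(t.v_gene), t.sample_id, t.tissue, t.condition
            )
            labels.append(member_to_label.get(key, -1))
        import numpy as np

        self.labels_ = np.asarray(labels, dtype=int)
        self.n_groups_ = len(self.groups_)
        return self
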