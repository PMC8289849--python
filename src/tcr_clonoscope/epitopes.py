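"""Candidate-epitope generation and TCR-group / HLA-allele linkage.

Proteins of interest (e.g. alpha-synuclein and mitochondrial proteins) are
cut into 9-mer and 15-mer sliding-window peptides — the lengths presented by
MHC class I and class II respectively.  Binding predictions for these
peptides are consumed from an external predictor's output table, never
computed here.  A TCR specificity group is linked to an HLA allele when
every sample contributing a TCR to the group also carries the allele
(sample-set containment), with a minimum number of shared samples; binder
peptides of the allele then become the group's candidate epitopes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from tcr_clonoscope.io import AA_ALPHABET
from tcr_clonoscope.specificity import SpecificityGroup

logger = logging.getLogger(__name__)

_CLASS_I_GENES = ("A", "B", "C", "E", "F", "G")
_ALLELE_RE = re.compile(r"^(?:HLA-)?([A-Z]+[0-9]*)\*?([0-9]+):([0-9]+)")


def normalize_allele(allele: str) -> str:
    """Normalize an HLA allele string to ``HLA-<gene><2-field code>``.

    Examples: ``HLA-C*06:02:01`` -> ``HLA-C06:02``; ``DRB1*15:01`` ->
    ``HLA-DRB115:01``.  Unparseable strings are returned stripped/uppercased.
    """
    s = str(allele).strip().upper()
    m = _ALLELE_RE.match(s)
    if not m:
        return s
    gene, f1, f2 = m.groups()
    return f"HLA-{gene}{f1}:{f2}"


def allele_mhc_class(allele: str) -> str:
    """``'I'`` for classical class I genes (A/B/C/E/F/G), ``'II'`` otherwise
    (DR/DQ/DP...)."""
    m = re.match(r"^HLA-([A-Z]+)", normalize_allele(allele))
    gene = m.group(1) if m else ""
    return "I" if gene in _CLASS_I_GENES else "II"


def read_proteins(path) -> list[tuple[str, str]]:
    """Read protein FASTA into (accession, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def window_peptides(proteins: list[tuple[str, str]], k: int) -> dict[str, set[str]]:
    """All length-``k`` sliding-window peptides (stride 1) from a protein set.

    Redundant proteins are removed by exact sequence first; peptides are
    deduplicated globally and each retains the accessions of every source
    protein.  Windows containing a residue outside the 20-letter alphabet
    (e.g. X) are dropped; sequences shorter than ``k`` contribute nothing.
    """
    if k not in (9, 15):
        raise ValueError("k must be 9 (class I) or 15 (class II)")
    # redundancy removal: one entry per distinct sequence, accessions merged
    by_seq: dict[str, set[str]] = {}
    for acc, seq in proteins:
        by_seq.setdefault(seq.upper(), set()).add(acc)
    peptides: dict[str, set[str]] = {}
    for seq, accs in sorted(by_seq.items()):
        if len(seq) < k:
            logger.info("sequence(s) %s shorter than %d; skipped", sorted(accs), k)
            continue
        for i in range(len(seq) - k + 1):
            pep = seq[i : i + k]
            if set(pep) <= AA_ALPHABET:
                peptides.setdefault(pep, set()).update(accs)
    return peptides


@dataclass
class TcrAntigenLink:
    """One (specificity group, HLA allele) association via shared samples."""

    group_id: str
    allele: str
    shared_samples: frozenset[str]
    peptides: frozenset[str] = field(default_factory=frozenset)
    no_binding_data: bool = False


def link_groups_to_alleles(
    groups: list[SpecificityGroup],
    typing: pd.DataFrame,
    min_shared: int = 2,
) -> list[TcrAntigenLink]:
    """Link specificity groups to HLA alleles by sample-set containment.

    A group's sample set is first restricted to samples present in the
    typing table (groups with no typed sample are skipped with a warning).
    A link (G, A) is emitted when every typed sample of G carries allele A
    and the shared set has at least ``min_shared`` samples.
    """
    carriers: dict[str, set[str]] = {}
    for r in typing.itertuples():
        carriers.setdefault(str(r.allele), set()).add(str(r.sample_id))
    typed_samples = set(typing["sample_id"].astype(str))
    links: list[TcrAntigenLink] = []
    for g in groups:
        samples = set(g.sample_set) & typed_samples
        if not samples:
            logger.warning("group %s has no typed samples; skipped", g.group_id)
            continue
        if len(samples) < min_shared:
            continue
        for allele in sorted(carriers):
            if samples <= carriers[allele]:
                links.append(TcrAntigenLink(g.group_id, allele, frozenset(samples)))
    return links


def attach_peptides(
    links: list[TcrAntigenLink],
    binding: pd.DataFrame,
    rank_threshold: float = 0.0,
) -> list[TcrAntigenLink]:
    """Attach candidate binder peptides to each link.

    A peptide attaches when its binding row for the link's allele has
    ``binder`` true, or ``rank_percent <= rank_threshold`` when a positive
    threshold is given.  Links to alleles absent from the binding table, or
    with zero qualifying peptides, are retained and flagged.
    """
    keep = binding["binder"].astype(bool)
    if rank_threshold > 0:
        keep = keep | (pd.to_numeric(binding["rank_percent"], errors="coerce") <= rank_threshold)
    hits = binding[keep]
    by_allele = {a: frozenset(grp["peptide"]) for a, grp in hits.groupby("allele")}
    covered = set(binding["allele"].unique())
    out = []
    for link in links:
        if link.allele not in covered:
            logger.warning("allele %s absent from binding table", link.allele)
            out.append(
                TcrAntigenLink(link.group_id, link.allele, link.shared_samples, frozenset(), True)
            )
        else:
            out.append(
                TcrAntigenLink(
                    link.group_id,
                    link.allele,
                    link.shared_samples,
                    by_allele.get(link.allele, frozenset()),
                    False,
                )
            )
    return out


def links_to_frame(links: list[TcrAntigenLink]) -> pd.DataFrame:
    """Flat table of links (one row per link; peptides/samples joined by ';')."""
    rows = [
        {
            "group_id": l.group_id,
            "allele": l.allele,
            "shared_samples": ";".join(sorted(l.shared_samples)),
            "n_shared": len(l.shared_samples),
            "peptides": ";".join(sorted(l.peptides)),
            "n_peptides": len(l.peptides),
            "no_binding_data": l.no_binding_data,
        }
        for l in links
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "allele",
            "shared_samples",
            "n_shared",
            "peptides",
            "n_peptides",
            "no_binding_data",
        ],
    )
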