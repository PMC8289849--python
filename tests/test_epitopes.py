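import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from tcr_clonoscope.epitopes import (
    allele_mhc_class,
    attach_peptides,
    link_groups_to_alleles,
    links_to_frame,
    normalize_allele,
    read_proteins,
    window_peptides,
)
from tcr_clonoscope.specificity import SpecificityGroup, TcrBeta


def group(gid, samples):
    members = tuple(
        TcrBeta(f"CASS{i}F", "TRBV1", s, "blood", "PD") for i, s in enumerate(samples)
    )
    return SpecificityGroup(group_id=gid, members=members, v_gene="TRBV1")


def typing(pairs):
    return pd.DataFrame(pairs, columns=["sample_id", "allele"])


class TestAlleles:
    def test_normalize(self):
        assert normalize_allele("HLA-C*06:02:01") == "HLA-C06:02"
        assert normalize_allele("C06:02") == "HLA-C06:02"
        assert normalize_allele("DRB1*15:01") == "HLA-DRB115:01"
        assert normalize_allele("hla-a*02:01") == "HLA-A02:01"
        assert normalize_allele("weird") == "WEIRD"

    def test_idempotent(self):
        for a in ("HLA-C*06:02", "DQB1*06:02", "A02:01"):
            once = normalize_allele(a)
            assert normalize_allele(once) == once

    def test_mhc_class(self):
        assert allele_mhc_class("HLA-A02:01") == "I"
        assert allele_mhc_class("HLA-C*06:02") == "I"
        assert allele_mhc_class("HLA-DRB115:01") == "II"
        assert allele_mhc_class("DQB1*06:02") == "II"


class TestWindows:
    def test_window_count(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"  # length 20, all distinct windows
        peps = window_peptides([("p1", seq)], 9)
        assert len(peps) == 12  # L - k + 1

    def test_duplicate_protein_same_set(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        one = window_peptides([("p1", seq)], 9)
        two = window_peptides([("p1", seq), ("p2", seq)], 9)
        assert set(one) == set(two)
        assert all("p1" in accs and "p2" in accs for accs in two.values())

    def test_printed_peptide_present(self):
        peps = window_peptides([("syn", "KTKEGVLYVGSKTKEGVVH")], 15)
        assert "KTKEGVLYVGSKTKE" in peps

    def test_short_sequence_contributes_nothing(self):
        assert window_peptides([("tiny", "ACDEF")], 9) == {}

    def test_nonstandard_residue_window_dropped(self):
        peps = window_peptides([("p1", "AAAXAAAAAAAAA")], 9)
        assert all("X" not in p for p in peps)
        assert "AAAAAAAAA" in peps  # the clean tail window survives

    def test_k_validation(self):
        with pytest.raises(ValueError, match="9.*15"):
            window_peptides([("p1", "A" * 20)], 10)

    def test_rerun_idempotence(self):
        seq = "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVATVAEKTK"
        first = window_peptides([("syn", seq)], 9)
        again = window_peptides([("syn", seq)], 9)
        assert first == again


def test_read_proteins_fasta(tmp_path):
    p = tmp_path / "p.fasta"
    p.write_text(">acc1 description\nacdef\n>acc2\nKLMNP\n")
    prots = read_proteins(p)
    assert prots == [("acc1", "ACDEF"), ("acc2", "KLMNP")]


class TestLinkage:
    def test_paper_shaped_example(self):
        g = group("G1", ["P1", "P4"])
        ty = typing([("P1", "HLA-C06:02"), ("P4", "HLA-C06:02"), ("P2", "HLA-A02:01")])
        links = link_groups_to_alleles([g], ty)
        assert len(links) == 1
        assert links[0].allele == "HLA-C06:02"
        assert links[0].shared_samples == {"P1", "P4"}

    def test_partial_carriage_no_link(self):
        g = group("G1", ["P1", "P4"])
        ty = typing([("P1", "HLA-C06:02"), ("P4", "HLA-B07:02")])
        assert link_groups_to_alleles([g], ty) == []

    def test_untyped_samples_restricted_away(self):
        # P9 is untyped; containment is evaluated on typed samples only
        g = group("G1", ["P1", "P4", "P9"])
        ty = typing([("P1", "HLA-C06:02"), ("P4", "HLA-C06:02")])
        links = link_groups_to_alleles([g], ty)
        assert [l.shared_samples for l in links] == [{"P1", "P4"}]

    def test_group_with_no_typed_samples_skipped(self, caplog):
        g = group("G1", ["X1", "X2"])
        with caplog.at_level(logging.WARNING):
            links = link_groups_to_alleles([g], typing([("P1", "HLA-C06:02")]))
        assert links == []
        assert any("no typed samples" in r.message for r in caplog.records)

    def test_min_shared_anti_monotone(self):
        groups = [group("G1", ["P1", "P4"]), group("G2", ["P1", "P2", "P3"])]
        ty = typing(
            [(s, "HLA-C06:02") for s in ("P1", "P2", "P3", "P4")]
            + [("P1", "HLA-A02:01"), ("P4", "HLA-A02:01")]
        )
        by_min = {
            m: {(l.group_id, l.allele) for l in link_groups_to_alleles(groups, ty, min_shared=m)}
            for m in (1, 2, 3, 4)
        }
        assert by_min[4] <= by_min[3] <= by_min[2] <= by_min[1]
        assert ("G1", "HLA-A02:01") in by_min[2]
        assert by_min[3] == {("G2", "HLA-C06:02")}

    def test_matches_exhaustive_oracle_random(self):
        rng = np.random.default_rng(21)
        samples = [f"P{i}" for i in range(1, 9)]
        alleles = [f"HLA-B{i:02d}:01" for i in range(1, 7)]
        ty_rows = [
            (s, a) for s in samples for a in alleles if rng.random() < 0.4
        ]
        groups = [
            group(f"G{j}", list(rng.choice(samples, size=rng.integers(2, 5), replace=False)))
            for j in range(12)
        ]
        ty = typing(ty_rows)
        got = {(l.group_id, l.allele) for l in link_groups_to_alleles(groups, ty, min_shared=2)}
        carriers = {a: {s for s, aa in ty_rows if aa == a} for a in alleles}
        typed = {s for s, _ in ty_rows}
        want = set()
        for g, a in itertools.product(groups, alleles):
            shared = set(g.sample_set) & typed
            if shared and len(shared) >= 2 and shared <= carriers[a]:
                want.add((g.group_id, a))
        assert got == want


class TestAttachPeptides:
    BINDING = pd.DataFrame(
        {
            "peptide": ["KTKEGVLYV", "AAAAAAAAA", "CCCCCCCCC"],
            "allele": ["HLA-C06:02", "HLA-C06:02", "HLA-C06:02"],
            "score": [0.9, 0.2, 0.1],
            "rank_percent": [0.5, 1.5, 40.0],
            "binder": [True, False, False],
        }
    )

    def _link(self, allele="HLA-C06:02"):
        from tcr_clonoscope.epitopes import TcrAntigenLink

        return TcrAntigenLink("G1", allele, frozenset({"P1", "P4"}))

    def test_threshold_zero_binder_only(self):
        out = attach_peptides([self._link()], self.BINDING, rank_threshold=0.0)
        assert out[0].peptides == {"KTKEGVLYV"}
        assert not out[0].no_binding_data

    def test_positive_threshold_adds_rank_hits(self):
        out = attach_peptides([self._link()], self.BINDING, rank_threshold=2.0)
        assert out[0].peptides == {"KTKEGVLYV", "AAAAAAAAA"}

    def test_hand_filter_equivalence(self):
        rng = np.random.default_rng(9)
        binding = pd.DataFrame(
            {
                "peptide": [f"PEP{i:03d}AAAA"[:9] for i in range(50)],
                "allele": rng.choice(["HLA-A02:01", "HLA-B07:02"], size=50),
                "score": rng.random(50),
                "rank_percent": rng.random(50) * 50,
                "binder": rng.random(50) < 0.3,
            }
        )
        thr = 5.0
        out = attach_peptides([self._link("HLA-A02:01")], binding, rank_threshold=thr)
        sub = binding[binding["allele"] == "HLA-A02:01"]
        want = set(sub.loc[sub["binder"] | (sub["rank_percent"] <= thr), "peptide"])
        assert out[0].peptides == want

    def test_absent_allele_flagged(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = attach_peptides([self._link("HLA-E01:01")], self.BINDING)
        assert out[0].no_binding_data and out[0].peptides == frozenset()

    def test_links_to_frame(self):
        out = attach_peptides([self._link()], self.BINDING)
        frame = links_to_frame(out)
        assert frame.loc[0, "n_shared"] == 2
        assert frame.loc[0, "peptides"] == "KTKEGVLYV"


def test_planted_links_recovered(default_bundle, default_cells, tmp_path):
    from tcr_clonoscope.io import read_binding_table, read_hla_typing
    from tcr_clonoscope.simulate import evaluate_recovery
    from tcr_clonoscope.specificity import build_groups, screen_pd_specific, tcrs_from_cells

    d = tmp_path
    default_bundle.hla.to_csv(d / "hla.tsv", sep="\t", index=False)
    default_bundle.binding.to_csv(d / "binding.tsv", sep="\t", index=False)
    groups = screen_pd_specific(build_groups(tcrs_from_cells(default_cells)))
    links = attach_peptides(
        link_groups_to_alleles(groups, read_hla_typing(d / "hla.tsv")),
        read_binding_table(d / "binding.tsv"),
    )
    report = evaluate_recovery(
        default_bundle.ground_truth, cells=default_cells, groups=groups, links=links
    )
    assert report["links"] == {"precision": 1.0, "recall": 1.0}
    # each planted link carries exactly its planted binder peptide
    planted = {(b["allele"], b["peptide"]) for b in default_bundle.ground_truth["planted_binders"]}
    got = {(l.allele, p) for l in links for p in l.peptides}
    assert got == planted
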