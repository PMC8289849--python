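"""Synthetic paired-chain repertoire generator with planted ground truth.

Emulates the statistical structure the downstream analyses assume: a
two-condition (PD vs HC), two-compartment (blood vs CSF) cohort of samples;
per-condition clone-size laws (a geometric bulk with an optional heavy tail
of large clones for the disease condition); a fraction of cells with no
alpha-beta receptor (gamma/delta contigs only — the NA stratum); clonotypes
planted to span chosen cluster sets (lineage tracking); CDR3 motif families
within one V gene (specificity grouping); per-sample HLA allotypes with
planted group-allele co-carriage (linkage); and toy proteins plus a binding
table with planted binder peptides.

Everything is determined by the seed; two runs with the same config produce
byte-identical output files.  The generated files parse through the package
reader stack at default settings.

The bundled alpha-synuclein-like protein sequence is a synthetic stand-in
(the human alpha-synuclein N-terminal repeat region) used only so that toy
peptide windows resemble real epitope candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_CDR3_LENGTHS = np.arange(10, 21)
_CDR3_LENGTH_W = np.array([1, 2, 4, 6, 8, 6, 4, 3, 2, 1, 1], dtype=float)
_CDR3_LENGTH_W /= _CDR3_LENGTH_W.sum()

TRBV_POOL = tuple(f"TRBV{i}" for i in range(1, 31))
TRAV_POOL = tuple(f"TRAV{i}" for i in range(1, 31))

# alpha-synuclein residues 1-60; contains the KTKEGVLYVGSKTKE repeat-region peptides
_SYN_LIKE = "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVATVAEKTK"


@dataclass(frozen=True)
class CloneSizeLaw:
    """Clone-size distribution: geometric(p) bulk plus an optional heavy
    tail placing ``heavy_cell_frac`` of CELLS into clones of size
    [heavy_min, heavy_max]."""

    p: float = 0.7
    heavy_cell_frac: float = 0.0
    heavy_min: int = 20
    heavy_max: int = 150

    def validate(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("geometric parameter p must be in (0, 1]")
        if not (0 <= self.heavy_cell_frac <= 1):
            raise ValueError("heavy_cell_frac must be in [0, 1]")
        if self.heavy_min < 2 or self.heavy_max < self.heavy_min:
            raise ValueError("invalid heavy clone size range")


@dataclass(frozen=True)
class MotifPlant:
    """One planted CDR3 motif family: ``n_members`` variants within one
    substitution of a common base CDR3, all sharing one V gene.  Bridging
    families place members in both PD blood and PD CSF samples (and are
    therefore PD-specific by construction); non-bridging families live in HC
    blood only."""

    n_members: int = 4
    pd_bridging: bool = True


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults mirror the cohort shape: 8 PD and 6 HC blood
    donors, 6 PD and 9 HC CSF donors, with per-sample cell counts scaled to
    desk size.  The PD clone-size law carries the heavy tail."""

    n_pd_blood: int = 8
    n_hc_blood: int = 6
    n_pd_csf: int = 6
    n_hc_csf: int = 9
    cells_per_blood_sample: int = 500
    cells_per_csf_sample: int = 150
    clone_size_laws: dict = field(
        default_factory=lambda: {
            "HC": CloneSizeLaw(p=0.7),
            "PD": CloneSizeLaw(p=0.7, heavy_cell_frac=0.05),
        }
    )
    frac_na_cells: float = 0.05
    cluster_labels: tuple = ("C1", "C3", "C5", "C6", "C9", "C13", "C15")
    na_cluster: str = "C10"
    #: clonotypes planted to span a cluster set: (count, clusters, size per clonotype)
    lineage_plants: tuple = ((5, ("C15", "C3", "C6"), 6),)
    #: when set, clones of size >= 2 in that condition live in the given cluster
    expanded_cluster: dict = field(default_factory=dict)
    motif_plants: tuple = (
        MotifPlant(4, True),
        MotifPlant(4, True),
        MotifPlant(4, True),
        MotifPlant(4, False),
        MotifPlant(3, False),
    )
    #: (motif family index, allele) pairs whose typed samples co-carry the allele
    planted_links: tuple = (
        (0, "HLA-C06:02"),
        (1, "HLA-A02:01"),
        (2, "HLA-DRB115:01"),
    )
    frac_extra_contigs: float = 0.01
    frac_nonproductive: float = 0.01
    seed: int = 0


@dataclass
class SimBundle:
    """Everything one simulation produced, in memory."""

    config: SimConfig
    cells: pd.DataFrame  # generator's own cell bookkeeping (truth, not pipeline output)
    contigs: pd.DataFrame  # Cell Ranger dialect rows, all samples, with sample_id
    meta: pd.DataFrame
    hla: pd.DataFrame
    binding: pd.DataFrame
    proteins: list
    ground_truth: dict

    def write(self, outdir) -> Path:
        """Write the full input bundle (per-sample contig CSVs, metadata and
        HLA/binding TSVs, protein FASTA, ground_truth.json)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        contig_cols = [
            "barcode",
            "is_cell",
            "contig_id",
            "chain",
            "v_gene",
            "d_gene",
            "j_gene",
            "cdr3",
            "cdr3_nt",
            "productive",
            "umis",
        ]
        for sid, grp in self.contigs.groupby("sample_id", sort=True):
            grp[contig_cols].to_csv(out / f"contigs_{sid}.csv", index=False, lineterminator="\n")
        self.meta.to_csv(out / "meta.tsv", sep="\t", index=False, lineterminator="\n")
        self.hla.to_csv(out / "hla.tsv", sep="\t", index=False, lineterminator="\n")
        self.binding.to_csv(out / "binding.tsv", sep="\t", index=False, lineterminator="\n")
        with open(out / "proteins.fasta", "w") as fh:
            for acc, seq in self.proteins:
                fh.write(f">{acc}\n{seq}\n")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return out


def sample_clone_sizes(law: CloneSizeLaw, n_cells: int, rng: np.random.Generator) -> list[int]:
    """Draw clone sizes under ``law`` until exactly ``n_cells`` cells are
    covered (the last clone is truncated to fit; a truncated heavy clone
    smaller than ``heavy_min`` is merged into its predecessor)."""
    law.validate()

    def fill(draw, target):
        sizes, tot = [], 0
        while tot < target:
            s = max(1, int(draw()))
            if tot + s > target:
                s = target - tot
            sizes.append(s)
            tot += s
        return sizes

    n_heavy = int(round(law.heavy_cell_frac * n_cells))
    heavy = fill(lambda: rng.integers(law.heavy_min, law.heavy_max + 1), n_heavy)
    if len(heavy) >= 2 and heavy[-1] < law.heavy_min:
        stub = heavy.pop()
        heavy[-1] += stub
    light = fill(lambda: rng.geometric(law.p), n_cells - n_heavy)
    return heavy + light


def clonotype_ids_from_law(
    law: CloneSizeLaw, n_cells: int, rng: np.random.Generator, prefix: str = "c"
) -> np.ndarray:
    """Flat per-cell clonotype-id array drawn under ``law`` — the raw
    material for resampling-test studies."""
    sizes = sample_clone_sizes(law, n_cells, rng)
    return np.repeat([f"{prefix}{i}" for i in range(len(sizes))], sizes)


def _random_cdr3(rng: np.random.Generator, used: set, length: int | None = None) -> str:
    while True:
        L = int(rng.choice(_CDR3_LENGTHS, p=_CDR3_LENGTH_W)) if length is None else length
        s = "C" + "".join(rng.choice(AA, size=L - 2)) + "F"
        if s not in used:
            used.add(s)
            return s


def _mutate_once(base: str, pos: int, rng: np.random.Generator, used: set) -> str:
    """One substitution at interior position ``pos`` (avoiding the conserved
    first/last residues by caller's choice of pos)."""
    for _ in range(100):
        repl = str(rng.choice(AA))
        if repl != base[pos]:
            cand = base[:pos] + repl + base[pos + 1 :]
            if cand not in used:
                used.add(cand)
                return cand
    raise RuntimeError("could not generate a fresh one-substitution variant")


def _validate(config: SimConfig) -> None:
    if not (0 <= config.frac_na_cells < 1):
        raise ValueError("frac_na_cells must be in [0, 1)")
    for law in config.clone_size_laws.values():
        law.validate()
    for count, clusters, size in config.lineage_plants:
        if size < len(clusters):
            raise ValueError("planted spanning clonotype smaller than its cluster set")
        unknown = set(clusters) - set(config.cluster_labels)
        if unknown:
            raise ValueError(f"lineage plant references unknown clusters {sorted(unknown)}")
        if count < 0:
            raise ValueError("negative lineage plant count")
    for fam in config.motif_plants:
        if fam.n_members < 2:
            raise ValueError("motif family needs >= 2 members")
    n_bridge = sum(1 for f in config.motif_plants if f.pd_bridging)
    for fam_idx, _ in config.planted_links:
        if fam_idx >= len(config.motif_plants) or not config.motif_plants[fam_idx].pd_bridging:
            raise ValueError("planted links must reference pd_bridging motif families")
    if n_bridge and config.n_pd_blood < 4:
        raise ValueError("bridging families need at least 4 PD blood samples")
    if any(f.pd_bridging for f in config.motif_plants) and config.n_pd_csf < 2:
        raise ValueError("bridging families need at least 2 PD CSF samples")
    hc_needed = max((f.n_members for f in config.motif_plants if not f.pd_bridging), default=0)
    if hc_needed > config.n_hc_blood:
        raise ValueError("non-bridging family larger than the HC blood cohort")


def simulate(config: SimConfig | None = None) -> SimBundle:
    """Run one simulation; fully determined by ``config.seed``."""
    config = config or SimConfig()
    _validate(config)
    rng = np.random.default_rng(config.seed)

    samples = (
        [(f"P{i + 1}", "PD", "blood", config.cells_per_blood_sample) for i in range(config.n_pd_blood)]
        + [(f"N{i + 1}", "HC", "blood", config.cells_per_blood_sample) for i in range(config.n_hc_blood)]
        + [(f"PD{i + 1}", "PD", "CSF", config.cells_per_csf_sample) for i in range(config.n_pd_csf)]
        + [(f"HC{i + 1}", "HC", "CSF", config.cells_per_csf_sample) for i in range(config.n_hc_csf)]
    )
    pd_blood = [s[0] for s in samples if s[1] == "PD" and s[2] == "blood"]
    hc_blood = [s[0] for s in samples if s[1] == "HC" and s[2] == "blood"]
    pd_csf = [s[0] for s in samples if s[1] == "PD" and s[2] == "CSF"]

    used_alpha: set = set()
    used_beta: set = set()
    centers = {
        lab: (5.0 * np.cos(2 * np.pi * i / (len(config.cluster_labels) + 1)),
              5.0 * np.sin(2 * np.pi * i / (len(config.cluster_labels) + 1)))
        for i, lab in enumerate((*config.cluster_labels, config.na_cluster))
    }

    # ---- lay out clonotypes per sample -----------------------------------
    lineage_alloc: dict[str, list[tuple[tuple, int]]] = {}
    true_spans = []
    plant_idx = 0
    for count, clusters, size in config.lineage_plants:
        for _ in range(count):
            sid = pd_blood[plant_idx % len(pd_blood)]
            lineage_alloc.setdefault(sid, []).append((tuple(clusters), size))
            plant_idx += 1

    cell_rows = []  # generator truth, one dict per cell
    singleton_pool: dict[str, list[int]] = {}  # sample -> indices into clonotype registry
    clonotypes = []  # registry: dict per clonotype

    for sid, cond, tissue, n_cells in samples:
        n_na = int(round(config.frac_na_cells * n_cells))
        n_ab = n_cells - n_na
        planted_here = lineage_alloc.get(sid, [])
        n_planted_cells = sum(size for _, size in planted_here)
        if n_planted_cells > n_ab:
            raise ValueError(f"lineage plants exceed the cell budget of sample {sid}")
        law = config.clone_size_laws[cond]
        sizes = sample_clone_sizes(law, n_ab - n_planted_cells, rng)

        local = [(tuple(clusters), size, True) for clusters, size in planted_here]
        for s in sizes:
            if s >= 2 and cond in config.expanded_cluster:
                home = config.expanded_cluster[cond]
            else:
                home = str(rng.choice(np.asarray(config.cluster_labels)))
            local.append(((home,), s, False))

        for clusters, s, is_planted in local:
            alpha = _random_cdr3(rng, used_alpha)
            beta = _random_cdr3(rng, used_beta)
            beta_v = str(rng.choice(np.asarray(TRBV_POOL)))
            alpha_v = str(rng.choice(np.asarray(TRAV_POOL)))
            reg_idx = len(clonotypes)
            clonotypes.append(
                {
                    "alpha": alpha,
                    "beta": beta,
                    "alpha_v": alpha_v,
                    "beta_v": beta_v,
                    "size": s,
                    "sample": sid,
                    "planted_span": list(clusters) if is_planted else None,
                }
            )
            if is_planted:
                true_spans.append({"alpha": alpha, "beta": beta, "clusters": sorted(clusters), "sample": sid})
            if s == 1 and not is_planted:
                singleton_pool.setdefault(sid, []).append(reg_idx)
            for j in range(s):
                cl = clusters[j % len(clusters)] if is_planted else clusters[0]
                cell_rows.append(
                    {
                        "sample_id": sid,
                        "condition": cond,
                        "tissue": tissue,
                        "cluster": cl,
                        "clonotype_idx": reg_idx,
                        "na": False,
                    }
                )
        for _ in range(n_na):
            cell_rows.append(
                {
                    "sample_id": sid,
                    "condition": cond,
                    "tissue": tissue,
                    "cluster": config.na_cluster,
                    "clonotype_idx": -1,
                    "na": True,
                }
            )

    # ---- motif families: overwrite beta chains of chosen singletons ------
    family_v_genes = [TRBV_POOL[(7 * i + 3) % len(TRBV_POOL)] for i in range(len(config.motif_plants))]
    true_groups = []
    for f_idx, fam in enumerate(config.motif_plants):
        if fam.pd_bridging:
            pair = (pd_blood[f_idx % len(pd_blood)], pd_blood[(f_idx + 3) % len(pd_blood)])
            targets = [pair[0], pair[1]]
            c = 0
            while len(targets) < fam.n_members:
                targets.append(pd_csf[(f_idx + c) % len(pd_csf)])
                c += 1
        else:
            targets = [hc_blood[(f_idx + j) % len(hc_blood)] for j in range(fam.n_members)]
            if len(set(targets)) < fam.n_members:
                raise ValueError("non-bridging family cannot fit in distinct HC samples")
        base_len = 12 + (f_idx % 4)
        base = _random_cdr3(rng, used_beta, length=base_len)
        variants = [base]
        for m in range(1, fam.n_members):
            pos = 1 + ((m - 1) % (base_len - 2))
            variants.append(_mutate_once(base, pos, rng, used_beta))
        members = []
        v_gene = family_v_genes[f_idx]
        for variant, sid in zip(variants, targets):
            pool = singleton_pool.get(sid, [])
            if not pool:
                raise ValueError(f"sample {sid} has no spare singleton clonotype for motif planting")
            reg_idx = pool.pop(0)
            clonotypes[reg_idx]["beta"] = variant
            clonotypes[reg_idx]["beta_v"] = v_gene
            cond = "PD" if sid in pd_blood + pd_csf else "HC"
            tissue = "CSF" if sid in pd_csf else "blood"
            members.append(
                {"cdr3": variant, "v_gene": v_gene, "sample": sid, "tissue": tissue, "condition": cond}
            )
        true_groups.append(
            {"v_gene": v_gene, "pd_bridging": fam.pd_bridging, "members": members}
        )

    # ---- HLA typing (PD blood donors only, as in a WGS-typed patient set) -
    hla_rows = []
    typed = list(pd_blood)
    for i, sid in enumerate(typed):
        hla_rows.append({"sample_id": sid, "allele": f"HLA-B{35 + i}:01"})
        hla_rows.append({"sample_id": sid, "allele": f"HLA-DQB10{i + 1}:02"})
    true_links = []
    for fam_idx, allele in config.planted_links:
        members = true_groups[fam_idx]["members"]
        shared = sorted({m["sample"] for m in members if m["sample"] in typed})
        for sid in shared:
            hla_rows.append({"sample_id": sid, "allele": allele})
        true_links.append({"group_index": fam_idx, "allele": allele, "samples": shared})
    hla = pd.DataFrame(hla_rows).sort_values(["sample_id", "allele"]).reset_index(drop=True)

    # ---- proteins and binding table --------------------------------------
    mito_seq = "M" + "".join(rng.choice(AA, size=79))
    proteins = [
        ("synA_alpha_synuclein_like", _SYN_LIKE),
        ("synB_alpha_synuclein_like_duplicate", _SYN_LIKE),
        ("mito_1_synthetic", mito_seq),
    ]
    planted_binders = []
    binding_rows = []
    pep9, pep15 = "KTKEGVLYV", "KTKEGVLYVGSKTKE"
    for _, allele in config.planted_links:
        from tcr_clonoscope.epitopes import allele_mhc_class

        pep = pep9 if allele_mhc_class(allele) == "I" else pep15
        binding_rows.append(
            {"peptide": pep, "allele": allele, "score": 0.9, "rank_percent": 0.5, "binder": True}
        )
        planted_binders.append({"peptide": pep, "allele": allele})
    for i in range(5):  # non-binder decoys from the mitochondrial-like protein
        pep = mito_seq[i * 3 : i * 3 + 9]
        binding_rows.append(
            {"peptide": pep, "allele": "HLA-C06:02", "score": 0.05, "rank_percent": 35.0, "binder": False}
        )
    binding = pd.DataFrame(binding_rows).drop_duplicates(["peptide", "allele"]).reset_index(drop=True)

    # ---- materialize cells / meta / contigs ------------------------------
    rows = []
    contig_rows = []
    counters: dict[str, int] = {}
    for cell in cell_rows:
        sid = cell["sample_id"]
        i = counters.get(sid, 0)
        counters[sid] = i + 1
        barcode = f"BC{i + 1:06d}-1"
        cx, cy = centers[cell["cluster"]]
        ex = cx + rng.normal(0, 0.4)
        ey = cy + rng.normal(0, 0.4)
        rows.append(
            {
                "barcode": barcode,
                "sample_id": sid,
                "tissue": cell["tissue"],
                "condition": cell["condition"],
                "cluster": cell["cluster"],
                "embed_x": round(ex, 6),
                "embed_y": round(ey, 6),
                "clonotype_idx": cell["clonotype_idx"],
                "na": cell["na"],
            }
        )
        if cell["na"]:
            for chain, v in (("TRG", "TRGV9"), ("TRD", "TRDV2")):
                contig_rows.append(
                    {
                        "barcode": barcode,
                        "sample_id": sid,
                        "is_cell": "True",
                        "contig_id": f"{barcode}_{chain}",
                        "chain": chain,
                        "v_gene": f"{v}*01",
                        "d_gene": "None",
                        "j_gene": f"{chain}J1*01",
                        "cdr3": "C" + "".join(rng.choice(AA, size=10)) + "F",
                        "cdr3_nt": "",
                        "productive": "True",
                        "umis": int(rng.integers(2, 30)),
                    }
                )
            continue
        ct = clonotypes[cell["clonotype_idx"]]
        for chain, cdr3, v in (("TRA", ct["alpha"], ct["alpha_v"]), ("TRB", ct["beta"], ct["beta_v"])):
            umis = int(rng.integers(5, 60))
            contig_rows.append(
                {
                    "barcode": barcode,
                    "sample_id": sid,
                    "is_cell": "True",
                    "contig_id": f"{barcode}_{chain}",
                    "chain": chain,
                    "v_gene": f"{v}*01",
                    "d_gene": "None",
                    "j_gene": ("TRAJ33*01" if chain == "TRA" else "TRBJ2-7*01"),
                    "cdr3": cdr3,
                    "cdr3_nt": "",
                    "productive": "True",
                    "umis": umis,
                }
            )
            # occasional second contig of the same chain with strictly lower
            # umis: exercises the tie-break without changing the truth
            if rng.random() < config.frac_extra_contigs and umis > 3:
                contig_rows.append(
                    {
                        "barcode": barcode,
                        "sample_id": sid,
                        "is_cell": "True",
                        "contig_id": f"{barcode}_{chain}_2",
                        "chain": chain,
                        "v_gene": f"{v}*01",
                        "d_gene": "None",
                        "j_gene": ("TRAJ33*01" if chain == "TRA" else "TRBJ2-7*01"),
                        "cdr3": "C" + "".join(rng.choice(AA, size=11)) + "F",
                        "cdr3_nt": "",
                        "productive": "True",
                        "umis": int(rng.integers(1, umis)),
                    }
                )
        if rng.random() < config.frac_nonproductive:
            contig_rows.append(
                {
                    "barcode": barcode,
                    "sample_id": sid,
                    "is_cell": "True",
                    "contig_id": f"{barcode}_np",
                    "chain": "TRB",
                    "v_gene": "TRBV1*01",
                    "d_gene": "None",
                    "j_gene": "TRBJ1-1*01",
                    "cdr3": "None",
                    "cdr3_nt": "",
                    "productive": "None",
                    "umis": 1,
                }
            )

    cells = pd.DataFrame(rows)
    contigs = pd.DataFrame(contig_rows)
    meta = cells[["barcode", "sample_id", "tissue", "condition", "cluster", "embed_x", "embed_y"]].copy()

    # pooled clonotype truth (alpha/beta pairs are globally unique by design)
    truth_clonotypes = [
        {"alpha": ct["alpha"], "beta": ct["beta"], "size": ct["size"], "sample": ct["sample"]}
        for ct in clonotypes
    ]
    run_id = f"sim-{config.seed}"
    ground_truth = {
        "run_id": run_id,
        "seed": config.seed,
        "samples": [
            {"sample_id": s, "condition": c, "tissue": t, "n_cells": n} for s, c, t, n in samples
        ],
        "clonotypes": truth_clonotypes,
        "lineage_spans": true_spans,
        "span_targets": [sorted(cl) for _, cl, _ in config.lineage_plants],
        "motif_groups": true_groups,
        "links": true_links,
        "planted_binders": planted_binders,
        "typed_samples": typed,
    }
    for df in (cells, meta, contigs):
        df.attrs["run_id"] = run_id
    return SimBundle(config, cells, contigs, meta, hla, binding, proteins, ground_truth)


def _match_group(group, truth_members: list[dict]) -> bool:
    got = {(m.cdr3, m.v_gene, m.sample_id, m.tissue, m.condition) for m in group.members}
    want = {
        (m["cdr3"], m["v_gene"], m["sample"], m["tissue"], m["condition"]) for m in truth_members
    }
    return got == want


def evaluate_recovery(
    ground_truth: dict,
    cells: pd.DataFrame | None = None,
    groups=None,
    spans: pd.DataFrame | None = None,
    links=None,
) -> dict:
    """Compare pipeline outputs against the generator's ground truth.

    Each output is optional; only the supplied ones are scored.  ``cells``
    must be the called cell table produced from this simulation's files (the
    run id recorded on the simulated tables is checked when present).
    Returns exact-match precision/recall per component.
    """
    report: dict = {"run_id": ground_truth.get("run_id")}
    if cells is not None:
        got_run = cells.attrs.get("run_id")
        if got_run is not None and got_run != ground_truth.get("run_id"):
            raise ValueError(
                f"outputs from run {got_run!r} scored against truth {ground_truth.get('run_id')!r}"
            )
        called = cells[cells["clonotype_id"].notna()]
        got = {
            (a.upper(), b.upper(), len(grp))
            for (a, b), grp in called.groupby(["alpha_cdr3", "beta_cdr3"])
        }
        want = {(c["alpha"], c["beta"], c["size"]) for c in ground_truth["clonotypes"]}
        report["clonotypes"] = {
            "precision": len(got & want) / len(got) if got else 0.0,
            "recall": len(got & want) / len(want) if want else 1.0,
        }
    if groups is not None:
        truth_fams = ground_truth["motif_groups"]
        matched = [any(_match_group(g, fam["members"]) for fam in truth_fams) for g in groups]
        recovered = [
            any(_match_group(g, fam["members"]) for g in groups) for fam in truth_fams
        ]
        report["groups"] = {
            "precision": sum(matched) / len(groups) if groups else 1.0,
            "recall": sum(recovered) / len(truth_fams) if truth_fams else 1.0,
        }
    if spans is not None and cells is not None:
        id_to_key = {
            cid: (grp["alpha_cdr3"].iloc[0].upper(), grp["beta_cdr3"].iloc[0].upper())
            for cid, grp in cells[cells["clonotype_id"].notna()].groupby("clonotype_id")
        }
        got = {id_to_key[c] for c in spans["clonotype_id"] if c in id_to_key}
        want = {(s["alpha"], s["beta"]) for s in ground_truth["lineage_spans"]}
        report["spans"] = {
            "precision": len(got & want) / len(got) if got else 1.0,
            "recall": len(got & want) / len(want) if want else 1.0,
        }
    if links is not None and groups is not None:
        truth_fams = ground_truth["motif_groups"]
        gid_to_fam = {}
        for g in groups:
            for i, fam in enumerate(truth_fams):
                if _match_group(g, fam["members"]):
                    gid_to_fam[g.group_id] = i
        got = {(gid_to_fam.get(l.group_id, -1), l.allele) for l in links}
        want = {(l["group_index"], l["allele"]) for l in ground_truth["links"]}
        report["links"] = {
            "precision": len(got & want) / len(got) if got else 1.0,
            "recall": len(got & want) / len(want) if want else 1.0,
        }
    return report


def config_from_yaml(path) -> SimConfig:
    """Load a SimConfig from a YAML file holding a subset of its fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "clone_size_laws" in raw:
        raw["clone_size_laws"] = {
            cond: CloneSizeLaw(**law) for cond, law in raw["clone_size_laws"].items()
        }
    if "motif_plants" in raw:
        raw["motif_plants"] = tuple(MotifPlant(**m) for m in raw["motif_plants"])
    if "lineage_plants" in raw:
        raw["lineage_plants"] = tuple(
            (int(c), tuple(cl), int(s)) for c, cl, s in raw["lineage_plants"]
        )
    if "planted_links" in raw:
        raw["planted_links"] = tuple((int(i), str(a)) for i, a in raw["planted_links"])
    if "cluster_labels" in raw:
        raw["cluster_labels"] = tuple(raw["cluster_labels"])
    return SimConfig(**raw)
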