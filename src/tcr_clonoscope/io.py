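"""Reading, validation and chain pairing for repertoire input tables.

The contig dialect is the Cell Ranger ``filtered_contig_annotations.csv``
(columns ``barcode, is_cell, contig_id, chain, v_gene, d_gene, j_gene, cdr3,
cdr3_nt, productive, umis``; extra columns are tolerated, only a mandatory
subset is enforced).  Per-cell metadata (sample, tissue, condition, optional
transcriptomic cluster and 2-D embedding coordinates) arrives as a TSV
produced by an upstream single-cell transcriptome pipeline.

Cells are the unit of analysis: one ``(barcode, sample_id)`` pair.  Pairing
keeps at most one productive TRA and one TRB contig per cell; cells whose
contigs are exclusively gamma/delta (TRG/TRD), and annotated cells with no
V(D)J contigs at all, are retained with both alpha/beta chains absent — the
"NA stratum" of cells with no alpha-beta TCR detected.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

CONTIG_REQUIRED = ("barcode", "chain", "v_gene", "j_gene", "cdr3", "productive")
META_REQUIRED = ("barcode", "sample_id", "tissue", "condition")
TISSUES = ("blood", "CSF")
CONDITIONS = ("PD", "HC")

#: canonical column order of the paired-cell table
CELL_COLUMNS = [
    "barcode",
    "sample_id",
    "alpha_cdr3",
    "alpha_v",
    "alpha_j",
    "beta_cdr3",
    "beta_v",
    "beta_j",
    "has_ab",
    "tissue",
    "condition",
    "cluster",
    "embed_x",
    "embed_y",
]


class SchemaError(ValueError):
    """An input table is missing a mandatory column or violates an enum/invariant."""


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing mandatory column(s): {', '.join(missing)}")


def _as_bool(series: pd.Series) -> pd.Series:
    # Cell Ranger writes "True"/"None"/"False"; accept booleans too.
    if series.dtype == bool:
        return series
    return series.astype(str).str.strip().str.lower().eq("true")


def read_contigs(path, sample_id: str, require_productive: bool = True) -> pd.DataFrame:
    """Read one sample's contig annotation table.

    Parameters
    ----------
    path
        CSV in the Cell Ranger filtered-contig dialect.
    sample_id
        Sample identifier attached to every row (the file itself carries none).
    require_productive
        Drop rows whose ``productive`` flag is not true.

    Returns
    -------
    DataFrame with columns ``barcode, sample_id, chain, cdr3_aa, cdr3_nt,
    v_gene, j_gene, productive, umis`` (one row per contig).
    """
    df = pd.read_csv(path)
    _require_columns(df, CONTIG_REQUIRED, f"contig table {path}")
    if df.empty:
        logger.warning("contig table %s is empty", path)
    out = pd.DataFrame(
        {
            "barcode": df["barcode"].astype(str),
            "sample_id": sample_id,
            "chain": df["chain"].astype(str),
            "cdr3_aa": df["cdr3"].astype(str).str.upper(),
            "cdr3_nt": df["cdr3_nt"].astype(str) if "cdr3_nt" in df.columns else "",
            "v_gene": df["v_gene"].astype(str),
            "j_gene": df["j_gene"].astype(str),
            "productive": _as_bool(df["productive"]),
            "umis": pd.to_numeric(df["umis"], errors="coerce").fillna(0).astype(int)
            if "umis" in df.columns
            else 1,
        }
    )
    if (out["umis"] < 0).any():
        raise SchemaError(f"contig table {path} contains negative umis")
    if require_productive:
        out = out[out["productive"]].reset_index(drop=True)
    return out


def read_cell_meta(path) -> pd.DataFrame:
    """Read the per-cell metadata TSV (barcode, sample_id, tissue, condition,
    optional cluster and embedding coordinates)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, META_REQUIRED, f"metadata table {path}")
    df = df.copy()
    df["barcode"] = df["barcode"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    bad_tissue = set(df["tissue"].unique()) - set(TISSUES)
    if bad_tissue:
        raise SchemaError(f"metadata tissue values outside {TISSUES}: {sorted(bad_tissue)}")
    bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(f"metadata condition values outside {CONDITIONS}: {sorted(bad_cond)}")
    if df.duplicated(["barcode", "sample_id"]).any():
        raise SchemaError("metadata contains duplicate (barcode, sample_id) rows")
    has_x = "embed_x" in df.columns
    has_y = "embed_y" in df.columns
    if has_x != has_y:
        raise SchemaError("embed_x and embed_y must be supplied together")
    if has_x and (df["embed_x"].isna() != df["embed_y"].isna()).any():
        raise SchemaError("embed_x present iff embed_y present must hold row-wise")
    for col in ("cluster", "embed_x", "embed_y"):
        if col not in df.columns:
            df[col] = np.nan
    return df


def read_hla_typing(path) -> pd.DataFrame:
    """Read a per-sample HLA typing TSV (columns sample_id, allele).

    Allele strings are normalized to gene + two-field code (see
    :func:`tcr_clonoscope.epitopes.normalize_allele`).
    """
    from tcr_clonoscope.epitopes import normalize_allele

    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("sample_id", "allele"), f"HLA typing table {path}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["allele"] = df["allele"].astype(str).map(normalize_allele)
    return df.drop_duplicates(["sample_id", "allele"]).reset_index(drop=True)


def read_binding_table(path) -> pd.DataFrame:
    """Read a peptide x allele binding-prediction TSV
    (columns peptide, allele, score, rank_percent, binder).

    Rows violating the class pairing (9-mer with a class II allele, 15-mer
    with class I) are dropped with a warning; the predictions themselves are
    always consumed, never computed here.
    """
    from tcr_clonoscope.epitopes import allele_mhc_class, normalize_allele

    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("peptide", "allele", "binder"), f"binding table {path}")
    df = df.copy()
    df["peptide"] = df["peptide"].astype(str).str.upper()
    df["allele"] = df["allele"].astype(str).map(normalize_allele)
    df["binder"] = _as_bool(df["binder"])
    if "rank_percent" not in df.columns:
        df["rank_percent"] = np.nan
    if "score" not in df.columns:
        df["score"] = np.nan
    plen = df["peptide"].str.len()
    cls = df["allele"].map(allele_mhc_class)
    ok = ((plen == 9) & (cls == "I")) | ((plen == 15) & (cls == "II"))
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("dropping %d binding rows violating 9-mer/class I, 15-mer/class II pairing", n_bad)
    return df[ok].reset_index(drop=True)


def _best_per_chain(ab: pd.DataFrame) -> pd.DataFrame:
    """One contig per (cell, chain), by the deterministic tie-break:
    highest umis, then longest CDR3, then lexicographically smallest CDR3."""
    ranked = ab.assign(_len=ab["cdr3_aa"].str.len()).sort_values(
        ["barcode", "sample_id", "chain", "umis", "_len", "cdr3_aa"],
        ascending=[True, True, True, False, False, True],
        kind="mergesort",
    )
    return ranked.drop_duplicates(["barcode", "sample_id", "chain"], keep="first")


def pair_chains(
    contigs: pd.DataFrame,
    meta: pd.DataFrame,
    policy: str = "error",
) -> pd.DataFrame:
    """Pair chains into one row per cell and attach metadata.

    Per cell, at most one TRA and one TRB contig is retained (tie-break:
    max umis, then longest CDR3, then lexicographically smallest).  Cells
    whose contigs are all TRG/TRD keep both chains absent, as do annotated
    cells with no contigs at all; together they form the NA stratum.

    Parameters
    ----------
    contigs
        Concatenated productive contig rows from :func:`read_contigs`.
    meta
        Per-cell metadata from :func:`read_cell_meta`; must cover every
        contig cell unless ``policy='drop_unannotated'``.
    policy
        ``'error'`` (default) or ``'drop_unannotated'``.

    Returns
    -------
    DataFrame with one row per cell (:data:`CELL_COLUMNS`); ``has_ab`` is
    true when both alpha and beta CDR3s are present.
    """
    if policy not in ("error", "drop_unannotated"):
        raise ValueError(f"unknown policy {policy!r}")

    key_cols = ["barcode", "sample_id"]
    frames = [meta[key_cols]]
    if len(contigs):
        frames.append(contigs[key_cols])
    all_cells = (
        pd.concat(frames, ignore_index=True)
        .drop_duplicates(key_cols)
        .sort_values(key_cols, kind="mergesort")
        .reset_index(drop=True)
    )
    if all_cells.empty:
        return pd.DataFrame(columns=CELL_COLUMNS)

    cells = all_cells
    for chain, prefix in (("TRA", "alpha"), ("TRB", "beta")):
        if len(contigs):
            best = _best_per_chain(contigs[contigs["chain"] == chain])
            best = best[key_cols + ["cdr3_aa", "v_gene", "j_gene"]].rename(
                columns={
                    "cdr3_aa": f"{prefix}_cdr3",
                    "v_gene": f"{prefix}_v",
                    "j_gene": f"{prefix}_j",
                }
            )
            cells = cells.merge(best, on=key_cols, how="left")
        else:
            cells[f"{prefix}_cdr3"] = np.nan
            cells[f"{prefix}_v"] = np.nan
            cells[f"{prefix}_j"] = np.nan
    cells["has_ab"] = cells["alpha_cdr3"].notna() & cells["beta_cdr3"].notna()

    merged = cells.merge(
        meta[["barcode", "sample_id", "tissue", "condition", "cluster", "embed_x", "embed_y"]],
        on=["barcode", "sample_id"],
        how="left",
        indicator=True,
    )
    unannotated = merged["_merge"] == "left_only"
    if unannotated.any():
        if policy == "error":
            example = merged.loc[unannotated, ["barcode", "sample_id"]].iloc[0]
            raise SchemaError(
                f"{int(unannotated.sum())} cells lack metadata "
                f"(e.g. barcode={example['barcode']} sample={example['sample_id']}); "
                "set policy='drop_unannotated' to drop them"
            )
        logger.warning("dropping %d cells without metadata", int(unannotated.sum()))
        merged = merged[~unannotated]
    merged = merged.drop(columns="_merge").reset_index(drop=True)
    return merged[CELL_COLUMNS]


def write_cells(cells: pd.DataFrame, path) -> None:
    """Write a paired-cell table (optionally with clonotype columns) as TSV."""
    cells.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_cells(path) -> pd.DataFrame:
    """Read back a paired-cell TSV written by :func:`write_cells`."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("barcode", "sample_id", "has_ab"), f"cell table {path}")
    for col in CELL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["barcode"] = df["barcode"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def _ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
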