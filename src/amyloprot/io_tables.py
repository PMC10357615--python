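"""Tabular I/O with strict schemas.

Reads and writes every table the pipeline consumes or produces: protein-group
LFQ intensity matrices (MaxQuant ``proteinGroups.txt`` dialect), sample
metadata, differential-abundance results, human differential-abundance tables,
ortholog maps, transcript (DEG) tables and CSF measurement tables. Missing LFQ
values are represented explicitly as NaN — never imputed, never zero.

All writers prepend a ``#`` comment header carrying the tool version and an
optional configuration hash so derived tables are auditable; all readers skip
such comments. Round-trip (write then read) is the identity for every table
type.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .design import META_COLUMNS, StudyDesign, validate_sample_meta

#: proteinGroups rows carrying these flags are decoys/contaminants, dropped on read
PG_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")

HUMAN_DATASETS = ("D22", "J20", "J22", "J22_Asym")
CSF_GROUPS = ("AD", "control", "HD", "control_HD")

DIFF_COLUMNS = ("protein_id", "contrast_id", "logfc", "moderated_stat", "p_value", "fdr", "significant")


@dataclass
class IntensityMatrix:
    """Proteins x samples log10 LFQ intensities with explicit missingness.

    Attributes
    ----------
    values :
        DataFrame indexed by unique protein-group ids (semicolon-joined
        accessions allowed), columns are sample ids; entries are log10
        intensities or NaN for missing.
    sample_meta :
        One row per sample with columns ``sample, tissue, age, genotype,
        animal_id, tech_rep, batch``, in the column order of ``values``.
    gene_symbols :
        Gene symbol per protein group (may be empty strings).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_symbols: pd.Series = None

    def __post_init__(self) -> None:
        self.values.index = self.values.index.rename("protein_id")
        self.values.columns = self.values.columns.rename("sample")
        if self.values.index.duplicated().any():
            raise ValueError("protein ids are not unique")
        if self.values.columns.duplicated().any():
            raise ValueError("sample ids are not unique")
        meta = self.sample_meta
        validate_sample_meta(meta)
        if list(meta["sample"]) != list(self.values.columns):
            meta = meta.set_index("sample").loc[list(self.values.columns)].reset_index()
            self.sample_meta = meta
        with np.errstate(invalid="ignore"):
            arr = self.values.to_numpy(float)
        if np.isinf(arr).any():
            raise ValueError("intensities must be finite or missing (NaN)")
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series("", index=self.values.index)
        else:
            self.gene_symbols = self.gene_symbols.reindex(self.values.index).fillna("")

    # -- convenience views ------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def condition_of(self) -> pd.Series:
        """Sample -> "(tissue, age, genotype)" condition key."""
        m = self.sample_meta
        return pd.Series(
            list(zip(m["tissue"], m["age"], m["genotype"])), index=m["sample"].to_numpy()
        )

    def subset_proteins(self, proteins) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.loc[list(proteins)], self.sample_meta.copy(), self.gene_symbols
        )

    def subset_tissue(self, tissue: str) -> "IntensityMatrix":
        keep = self.sample_meta["tissue"] == tissue
        if not keep.any():
            raise ValueError(f"no samples of tissue {tissue!r}")
        meta = self.sample_meta.loc[keep].reset_index(drop=True)
        return IntensityMatrix(self.values[meta["sample"]], meta, self.gene_symbols)


def _header(comment: str | None = None, config_hash: str | None = None) -> str:
    parts = [f"# amyloprot {__version__}"]
    if config_hash:
        parts.append(f"config_hash={config_hash}")
    if comment:
        parts.append(comment)
    return " ".join(parts) + "\n"


def _write(df: pd.DataFrame, path, sep: str, config_hash: str | None = None, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config_hash=config_hash))
        df.to_csv(fh, sep=sep, index=False, **kwargs)


def _read(path, sep: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kwargs)


# ---------------------------------------------------------------------------
# proteinGroups dialect
# ---------------------------------------------------------------------------

def read_protein_groups(
    path,
    sample_meta: pd.DataFrame,
    linear_to_log: bool = True,
    drop_flagged: bool = True,
) -> tuple[IntensityMatrix, dict]:
    """Parse a proteinGroups-dialect TSV into an :class:`IntensityMatrix`.

    Zero LFQ intensities become missing (NaN), not ``-inf``. Rows flagged
    ``Reverse``, ``Potential contaminant`` or ``Only identified by site`` are
    dropped by default and counted in the returned log dict.

    Parameters
    ----------
    sample_meta :
        Metadata table whose ``sample`` column names the ``LFQ intensity
        <sample>`` columns expected in the file.
    linear_to_log :
        If true (default), intensities are log10-transformed after
        zero-to-missing conversion; set false if the file already stores
        log10 values.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"Protein IDs": str})
    if "Protein IDs" not in table.columns:
        raise ValueError("schema error: mandatory column 'Protein IDs' not found")
    lfq_cols = {}
    for s in sample_meta["sample"]:
        col = f"LFQ intensity {s}"
        if col not in table.columns:
            raise ValueError(f"schema error: mandatory column {col!r} not found")
        lfq_cols[col] = s
    if len(set(lfq_cols.values())) != len(lfq_cols):
        raise ValueError("duplicate sample names")

    log = {"proteins_in": int(len(table))}
    if drop_flagged:
        for flag in PG_FLAG_COLUMNS:
            if flag in table.columns:
                hit = table[flag].fillna("").astype(str).str.strip() == "+"
                log[f"dropped_{flag}"] = int(hit.sum())
                table = table.loc[~hit]
    log["proteins_out"] = int(len(table))

    values = table[list(lfq_cols)].rename(columns=lfq_cols).astype(float)
    values[values == 0.0] = np.nan  # zero-as-missing convention
    if (values.to_numpy() < 0).any():
        raise ValueError("negative raw LFQ intensity on the linear scale")
    if linear_to_log:
        values = np.log10(values)
    values.index = pd.Index(table["Protein IDs"], name="protein_id")
    symbols = None
    if "Gene names" in table.columns:
        symbols = pd.Series(table["Gene names"].fillna("").to_numpy(), index=values.index)
    matrix = IntensityMatrix(values, sample_meta.reset_index(drop=True), symbols)
    return matrix, log


def write_protein_groups(matrix: IntensityMatrix, path, config_hash: str | None = None) -> None:
    """Write an :class:`IntensityMatrix` back to the proteinGroups dialect.

    Values are written on the linear scale (``10**x``) with missing as 0,
    matching the input convention of :func:`read_protein_groups`.
    """
    linear = np.power(10.0, matrix.values)
    cols = {"Protein IDs": matrix.protein_ids, "Gene names": matrix.gene_symbols.to_numpy()}
    for s in matrix.values.columns:
        cols[f"LFQ intensity {s}"] = linear[s].fillna(0.0).to_numpy()
    for flag in PG_FLAG_COLUMNS:
        cols[flag] = ""
    _write(pd.DataFrame(cols), path, sep="\t", config_hash=config_hash)


# ---------------------------------------------------------------------------
# simple tables
# ---------------------------------------------------------------------------

def read_sample_meta(path, design: StudyDesign | None = None) -> pd.DataFrame:
    meta = _read(path, sep=",")
    return validate_sample_meta(meta, design)


def write_sample_meta(meta: pd.DataFrame, path, config_hash: str | None = None) -> None:
    _write(meta[list(META_COLUMNS)], path, sep=",", config_hash=config_hash)


def write_diff_table(results: pd.DataFrame, path, config_hash: str | None = None) -> None:
    missing = [c for c in DIFF_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"diff table lacks column(s) {missing}")
    cols = [c for c in results.columns if c in DIFF_COLUMNS or c == "gene_symbol"]
    _write(results[cols], path, sep=",", config_hash=config_hash, float_format="%.17g")


def read_diff_table(path) -> pd.DataFrame:
    table = _read(path, sep=",")
    missing = [c for c in DIFF_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"diff table lacks column(s) {missing}")
    bad = table[(table["p_value"] < 0) | (table["p_value"] > 1) | (table["fdr"] < 0) | (table["fdr"] > 1)]
    if len(bad):
        raise ValueError("p/fdr values outside [0, 1]")
    if not (table["significant"] == (table["fdr"] < 0.05)).all():
        raise ValueError("significance flag inconsistent with fdr < 0.05")
    return table


def read_human_tables(paths: dict) -> dict:
    """Read one CSV per human dataset id; keys must be from the closed set."""
    tables = {}
    for dataset_id, path in paths.items():
        if dataset_id not in HUMAN_DATASETS:
            raise ValueError(f"unknown human dataset {dataset_id!r}; allowed: {HUMAN_DATASETS}")
        t = _read(path, sep=",")
        for col in ("gene_symbol", "effect", "significant"):
            if col not in t.columns:
                raise ValueError(f"{dataset_id}: missing column {col!r}")
        if (t["gene_symbol"].astype(str).str.len() == 0).any() or t["gene_symbol"].isna().any():
            raise ValueError(f"{dataset_id}: empty gene symbol")
        t["dataset_id"] = dataset_id
        tables[dataset_id] = t
    return tables


def write_human_table(table: pd.DataFrame, path, config_hash: str | None = None) -> None:
    _write(table[["gene_symbol", "effect", "significant"]], path, sep=",", config_hash=config_hash)


def read_ortholog_map(path) -> pd.DataFrame:
    """Two-column symbol pairs with a translation-direction tag (TSV)."""
    table = _read(path, sep="\t")
    for col in ("mouse_symbol", "human_symbol", "source_direction"):
        if col not in table.columns:
            raise ValueError(f"ortholog map: missing column {col!r}")
    bad_dir = ~table["source_direction"].isin(["m2h", "h2m"])
    if bad_dir.any():
        raise ValueError("ortholog map: source_direction must be 'm2h' or 'h2m'")
    dup = table.duplicated(subset=["mouse_symbol", "human_symbol", "source_direction"])
    if dup.any():
        rows = (table.index[dup] + 2).tolist()  # 1-based + header
        raise ValueError(f"ortholog map: duplicated triple at file row(s) {rows}")
    return table


def write_ortholog_map(table: pd.DataFrame, path, config_hash: str | None = None) -> None:
    _write(table[["mouse_symbol", "human_symbol", "source_direction"]], path, sep="\t",
           config_hash=config_hash)


def read_deg_table(path) -> pd.DataFrame:
    table = _read(path, sep=",")
    for col in ("gene_symbol", "log2fc", "adjusted_p", "significant"):
        if col not in table.columns:
            raise ValueError(f"DEG table: missing column {col!r}")
    if ((table["adjusted_p"] < 0) | (table["adjusted_p"] > 1)).any():
        raise ValueError("DEG table: adjusted_p outside [0, 1]")
    return table


def write_deg_table(table: pd.DataFrame, path, config_hash: str | None = None) -> None:
    _write(table[["gene_symbol", "log2fc", "adjusted_p", "significant"]], path, sep=",",
           config_hash=config_hash)


def read_csf_table(path) -> pd.DataFrame:
    table = _read(path, sep=",")
    for col in ("subject_id", "group", "analyte"):
        if col not in table.columns:
            raise ValueError(f"CSF table: missing column {col!r}")
    bad = set(table["group"]) - set(CSF_GROUPS)
    if bad:
        raise ValueError(f"CSF table: unknown group(s) {sorted(bad)}; allowed: {CSF_GROUPS}")
    num_cols = [c for c in table.columns if c not in ("subject_id", "group")]
    if (table[num_cols].to_numpy(float) < 0).any():
        raise ValueError("CSF table: concentrations must be >= 0")
    return table


def write_csf_table(table: pd.DataFrame, path, config_hash: str | None = None) -> None:
    _write(table, path, sep=",", config_hash=config_hash)
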