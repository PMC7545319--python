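"""Readers, writers, and validated containers for the pipeline's formats.

Formats handled: tab-delimited expression matrices (gene id column plus one
column per sample), GCT 1.2, GMT gene-set collections, clinical TSV
(survival + chemotherapy response + covariates), and MAF-lite somatic
mutation tables.  All outputs are UTF-8 and tab-delimited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44

#: MAF variant classes counted as coding/nonsynonymous (Silent excluded).
CODING_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)

VALID_VARIANT_TYPES = ("SNV", "INS", "DEL")
VALID_RESPONSES = ("CR", "PR", "SD", "PD", "unknown")

#: Common free-text aliases for RECIST response tokens.
RESPONSE_ALIASES = {
    "CR": "CR",
    "COMPLETE RESPONSE": "CR",
    "COMPLETE REMISSION": "CR",
    "PR": "PR",
    "PARTIAL RESPONSE": "PR",
    "PARTIAL REMISSION": "PR",
    "SD": "SD",
    "STABLE DISEASE": "SD",
    "PD": "PD",
    "PROGRESSIVE DISEASE": "PD",
    "CLINICAL PROGRESSIVE DISEASE": "PD",
}

# MAF column-name aliases -> canonical MAF-lite names
MAF_ALIASES = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_class",
    "Variant_Type": "variant_type",
}
# MAF Variant_Type tokens -> MAF-lite tokens
VARIANT_TYPE_ALIASES = {"SNP": "SNV", "SNV": "SNV", "INS": "INS", "DEL": "DEL"}


class FormatError(ValueError):
    """A file failed structural validation."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale tag (log2 or linear)."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups[:5])}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample ids: {list(dups[:5])}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_linear(self) -> "ExpressionMatrix":
        """Back-transform log2 values to the linear scale (no-op if linear)."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(2.0**self.values, scale="linear")


class GeneSetCollection(dict):
    """Ordered map set name -> list of member gene ids.

    A thin dict subclass so set iteration order is the file order.
    """

    def __init__(self, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None):
        for name, members in sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        super().__init__(sets)
        self.descriptions = descriptions or {}

    @property
    def set_names(self) -> list[str]:
        return list(self.keys())


@dataclass
class SurvivalTable:
    """Per-sample follow-up: observed time (months) and event indicator."""

    data: pd.DataFrame  # columns: sample_id, time, event
    endpoint: str = "OS"
    time_unit: str = "months"

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"survival table missing columns: {sorted(missing)}")
        if self.endpoint not in ("OS", "RFS"):
            raise ValueError(f"endpoint must be OS or RFS, got {self.endpoint!r}")
        if self.data["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in survival table")
        if (self.data["time"] <= 0).any():
            raise FormatError("survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise FormatError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def subset(self, sample_ids) -> "SurvivalTable":
        keep = self.data[self.data["sample_id"].isin(set(sample_ids))].reset_index(drop=True)
        return SurvivalTable(keep, endpoint=self.endpoint, time_unit=self.time_unit)


@dataclass
class MutationTable:
    """Somatic mutation records (MAF-lite)."""

    data: pd.DataFrame  # columns: sample_id, gene, variant_class, variant_type, coding

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "variant_class", "variant_type", "coding"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"mutation table missing columns: {sorted(missing)}")
        bad = set(self.data["variant_type"]) - set(VALID_VARIANT_TYPES)
        if bad:
            raise FormatError(
                f"unknown variant_type token(s) {sorted(bad)}; valid: {VALID_VARIANT_TYPES}"
            )
        if (self.data["gene"].astype(str).str.len() == 0).any():
            raise FormatError("empty gene symbol in mutation table")


@dataclass
class ChemoTable:
    """Chemotherapy exposure and RECIST-style response per sample."""

    data: pd.DataFrame  # columns: sample_id, received_chemo, response

    def __post_init__(self) -> None:
        required = {"sample_id", "received_chemo", "response"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"chemo table missing columns: {sorted(missing)}")
        if self.data["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in chemo table")
        bad = set(self.data["response"]) - set(VALID_RESPONSES)
        if bad:
            raise FormatError(f"invalid response token(s): {sorted(bad)}")


@dataclass
class CohortBundle:
    """Everything known about one cohort."""

    cohort_id: str
    expression: ExpressionMatrix
    survival: SurvivalTable
    mutations: MutationTable | None = None
    chemo: ChemoTable | None = None
    covariates: pd.DataFrame | None = None  # indexed by sample_id

    def __post_init__(self) -> None:
        extra = set(self.survival.sample_ids) - set(self.expression.sample_ids)
        if extra:
            raise FormatError(
                f"cohort {self.cohort_id}: survival samples missing from "
                f"expression: {sorted(extra)[:5]}"
            )


# ---------------------------------------------------------------------------
# expression

def read_expression(path: str | Path, format: str = "tsv", scale: str = "log2") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT 1.2.

    Duplicate gene rows are collapsed by taking the per-sample max (logged).
    """
    path = Path(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(header) != len(set(header)):
            raise FormatError(f"{path}:1: duplicate sample ids in header")
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}:1: expected GCT header '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}:2: expected '<n_genes>\\t<n_samples>'")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape[0] != n_genes:
            raise FormatError(
                f"{path}: GCT declares {n_genes} genes but contains {df.shape[0]} rows"
            )
        if df.shape[1] != n_samples:
            raise FormatError(
                f"{path}: GCT declares {n_samples} samples but contains {df.shape[1]} columns"
            )
    else:
        raise ValueError(f"format must be 'tsv' or 'gct', got {format!r}")

    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("read_expression: collapsing %d duplicate gene row(s) by max", n_dup)
        df = df.groupby(level=0, sort=False).max()
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df.astype(float), scale=scale)


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        expr.values.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
            out = expr.values.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"format must be 'tsv' or 'gct', got {format!r}")


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, fields name, description, members."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (< 3)")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = sets.descriptions.get(name, "na") if hasattr(sets, "descriptions") else "na"
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# clinical

def read_clinical(
    path: str | Path,
    id_col: str = "sample_id",
    time_col: str = "time",
    event_col: str = "event",
    response_col: str | None = "response",
    chemo_col: str | None = "received_chemo",
    endpoint: str = "OS",
    time_unit: str = "months",
) -> tuple[SurvivalTable, ChemoTable | None, pd.DataFrame]:
    """Read a clinical TSV into survival, chemo, and covariate tables.

    Rows with time <= 0 (or missing time/event) are dropped with a logged
    count; unrecognized response tokens map to ``unknown`` with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in (id_col, time_col, event_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mapped column {col!r}")

    df = df.rename(columns={id_col: "sample_id", time_col: "time", event_col: "event"})
    n0 = len(df)
    df = df[df["time"].notna() & df["event"].notna()]
    df = df[df["time"] > 0]
    dropped = n0 - len(df)
    if dropped:
        logger.info("read_clinical: %d row(s) removed (time <= 0 or missing)", dropped)
    df = df.reset_index(drop=True)

    surv = SurvivalTable(
        df[["sample_id", "time", "event"]].assign(event=lambda d: d["event"].astype(int)),
        endpoint=endpoint,
        time_unit=time_unit,
    )

    chemo = None
    if response_col and response_col in df.columns or chemo_col and chemo_col in df.columns:
        resp = df[response_col] if response_col and response_col in df.columns else "unknown"
        mapped = (
            pd.Series(resp, index=df.index)
            .astype(str)
            .str.strip()
            .str.upper()
            .map(RESPONSE_ALIASES)
        )
        n_unknown = int(mapped.isna().sum())
        if n_unknown:
            logger.warning("read_clinical: %d unrecognized response token(s) -> unknown", n_unknown)
        received = (
            df[chemo_col].fillna(0).astype(int)
            if chemo_col and chemo_col in df.columns
            else (mapped.notna()).astype(int)
        )
        chemo = ChemoTable(
            pd.DataFrame(
                {
                    "sample_id": df["sample_id"],
                    "received_chemo": received,
                    "response": mapped.fillna("unknown"),
                }
            )
        )

    drop_cols = {"time", "event"}
    if response_col:
        drop_cols.add(response_col)
    if chemo_col:
        drop_cols.add(chemo_col)
    covariates = df.drop(columns=[c for c in drop_cols if c in df.columns]).set_index("sample_id")
    return surv, chemo, covariates


def write_clinical(
    surv: SurvivalTable,
    path: str | Path,
    chemo: ChemoTable | None = None,
    covariates: pd.DataFrame | None = None,
) -> None:
    out = surv.data.copy()
    if chemo is not None:
        out = out.merge(chemo.data, on="sample_id", how="left")
    if covariates is not None:
        out = out.merge(covariates.reset_index(), on="sample_id", how="left")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MAF-lite

def read_maf_lite(
    path: str | Path, coding_classes: frozenset[str] = CODING_CLASSES
) -> MutationTable:
    """Read a MAF-lite TSV (standard MAF column names accepted as aliases)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={k: v for k, v in MAF_ALIASES.items() if k in df.columns})
    required = {"sample_id", "gene", "variant_class", "variant_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    vt = df["variant_type"].astype(str).str.upper().map(VARIANT_TYPE_ALIASES)
    bad = df.loc[vt.isna(), "variant_type"].unique()
    if len(bad):
        raise FormatError(
            f"{path}: unknown variant_type token(s) {list(bad)}; "
            f"valid: {sorted(set(VARIANT_TYPE_ALIASES))}"
        )
    df = df.assign(
        variant_type=vt,
        coding=df["variant_class"].isin(coding_classes),
    )
    return MutationTable(df[["sample_id", "gene", "variant_class", "variant_type", "coding"]])


def write_maf_lite(muts: MutationTable, path: str | Path) -> None:
    muts.data.drop(columns=["coding"]).to_csv(path, sep="\t", index=False)


def write_chemo(chemo: ChemoTable, path: str | Path) -> None:
    chemo.data.to_csv(path, sep="\t", index=False)


def days_to_months(days):
    """Convert survival times in days to months (30.44 days/month)."""
    return np.asarray(days, dtype=float) / DAYS_PER_MONTH


def months_to_days(months):
    return np.asarray(months, dtype=float) * DAYS_PER_MONTH
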