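"""Readers, writers and validated containers for every table the pipeline touches.

Supported formats: tab-delimited text with a header row (expression matrices,
mutation tables, signatures, sample annotations), GCT v1.2 (expression) and GMT
(gene sets). Gene identifiers are HGNC symbols, compared case-insensitively
after trimming; every reader normalises symbols to upper case on ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A cell could not be parsed; the message names the offending row/column."""


class SchemaError(ValueError):
    """A mandatory column is missing or a file header is malformed."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


# MAF-style variant-classification vocabulary. Terms outside this set are
# retained but mapped to OTHER with a warning.
TRUNCATING_TERMS = frozenset(
    {
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
    }
)
MISSENSE_TERMS = frozenset({"Missense_Mutation"})
OTHER_CODING_TERMS = frozenset(
    {
        "In_Frame_Del",
        "In_Frame_Ins",
        "Silent",
        "Start_Codon_SNP",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
        "OTHER",
    }
)
MUTATION_VOCABULARY = TRUNCATING_TERMS | MISSENSE_TERMS | OTHER_CODING_TERMS

SIGNATURE_CLASSES = ("NE", "NON_NE", "MEMBER")
GENOTYPE_STATUS = ("WT", "T", "M")


def normalize_gene(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale abundance plus per-sample metadata.

    ``values`` is indexed by upper-cased HGNC symbols; columns are sample ids.
    ``sample_meta`` (optional) is indexed by sample id and may carry
    ``source_cohort``, ``histology`` and ``reference_class`` columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = [normalize_gene(g) for g in self.values.index]
        self.values.columns = [str(c) for c in self.values.columns]
        if self.values.index.duplicated().any():
            dups = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValidationError(f"duplicate gene ids after case-normalization: {dups}")
        if self.values.columns.duplicated().any():
            dups = sorted(set(self.values.columns[self.values.columns.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise ValidationError("expression matrix contains non-finite values")
        self.values = self.values.astype(float)
        if self.sample_meta is not None:
            self.sample_meta = self.sample_meta.copy()
            self.sample_meta.index = [str(s) for s in self.sample_meta.index]
            missing = [s for s in self.sample_ids if s not in self.sample_meta.index]
            if missing:
                raise ValidationError(f"sample_meta missing samples: {missing}")
            self.sample_meta = self.sample_meta.loc[list(self.sample_ids)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sources(self) -> pd.Series:
        """Per-sample source-cohort labels; errors if metadata is absent."""
        if self.sample_meta is None or "source_cohort" not in self.sample_meta:
            raise ValidationError("matrix has no source_cohort metadata")
        return self.sample_meta["source_cohort"]


# A merged, source-tagged matrix is structurally an ExpressionMatrix whose
# sample_meta carries the source_cohort column; kept as an alias for clarity.
MergedMatrix = ExpressionMatrix


@dataclass
class MutationTable:
    """Per-sample variant records (sample, gene, variant_classification, protein_change)."""

    records: pd.DataFrame

    COLUMNS = ("sample", "gene", "variant_classification", "protein_change")

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"mutation table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].astype(str)
        df["gene"] = df["gene"].map(normalize_gene)
        dup = df.duplicated(subset=["sample", "gene", "protein_change"])
        if dup.any():
            warnings.warn(
                f"dropping {int(dup.sum())} duplicate (sample, gene, protein_change) records"
            )
            df = df.loc[~dup]
        unknown = ~df["variant_classification"].isin(MUTATION_VOCABULARY)
        if unknown.any():
            warnings.warn(
                f"{int(unknown.sum())} record(s) with classification outside the "
                "declared vocabulary mapped to OTHER"
            )
            df.loc[unknown, "variant_classification"] = "OTHER"
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample"]))


@dataclass
class GeneSignature:
    """Named gene set, optionally split into NE / NON_NE classes.

    When any gene carries an NE or NON_NE class the signature must also carry
    reference mean profiles (``mean_ne``, ``mean_nonne``) covering every such
    gene; these are the anchors of the correlation-based neuroendocrine score.
    """

    name: str
    members: dict[str, str]
    reference_profiles: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"signature {self.name!r} is empty")
        norm: dict[str, str] = {}
        for gene, cls in self.members.items():
            if cls not in SIGNATURE_CLASSES:
                raise ValidationError(f"invalid signature class {cls!r} for gene {gene!r}")
            norm[normalize_gene(gene)] = cls
        self.members = norm
        classed = [g for g, c in self.members.items() if c in ("NE", "NON_NE")]
        if classed:
            if self.reference_profiles is None:
                raise ValidationError(
                    f"signature {self.name!r} has NE/NON_NE classes but no reference profiles"
                )
            prof = self.reference_profiles.copy()
            prof.index = [normalize_gene(g) for g in prof.index]
            for col in ("mean_ne", "mean_nonne"):
                if col not in prof.columns:
                    raise ValidationError(f"reference profiles lack column {col!r}")
            missing = [g for g in classed if g not in prof.index or prof.loc[g].isna().any()]
            if missing:
                raise ValidationError(f"reference profiles do not cover genes: {missing}")
            self.reference_profiles = prof.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.members)

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, c in self.members.items() if c == cls]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class AnnotationTable:
    """Per-sample annotations: source cohort, histology, reference class, genotype."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        df.index = [str(s) for s in df.index]
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise ValidationError(f"duplicate sample ids in annotations: {dups}")
        for col in df.columns:
            if col in ("TP53", "RB1", "SMARCA4"):
                bad = ~df[col].astype(str).isin(GENOTYPE_STATUS)
                if bad.any():
                    raise ValidationError(
                        f"genotype column {col} has values outside {GENOTYPE_STATUS}"
                    )
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def _parse_numeric_block(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Convert a str-typed block to float, naming the first bad cell on failure."""
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return out


def _collapse_duplicate_genes(df: pd.DataFrame, how: str) -> pd.DataFrame:
    if not df.index.duplicated().any():
        return df
    dups = sorted(set(df.index[df.index.duplicated()]))
    warnings.warn(f"collapsing duplicate gene rows by {how}: {dups}")
    grouped = df.groupby(level=0, sort=False)
    return grouped.max() if how == "max" else grouped.mean()


def read_expression_matrix(
    path: str | Path, format: str = "tsv", collapse: str = "max"
) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT v1.2.

    Duplicate gene rows (after case-normalization) are collapsed by per-sample
    ``max`` (default) or ``mean`` with a warning. Duplicate sample ids and
    non-numeric cells raise.
    """
    path = Path(path)
    if collapse not in ("max", "mean"):
        raise ValueError(f"collapse must be 'max' or 'mean', got {collapse!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if format == "gct":
        if len(lines) < 3 or not lines[0].startswith("#1.2"):
            raise SchemaError(f"{path}: not a GCT v1.2 file")
        try:
            n_genes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
        except ValueError as exc:
            raise SchemaError(f"{path}: malformed GCT dimension line") from exc
        header = lines[2].split("\t")
        if header[:2] != ["Name", "Description"]:
            raise SchemaError(f"{path}: GCT header must start with Name\\tDescription")
        samples = header[2:]
        body = [ln.split("\t") for ln in lines[3:] if ln]
        genes = [normalize_gene(r[0]) for r in body]
        data = [r[2:] for r in body]
        if len(genes) != n_genes or len(samples) != n_samples:
            raise SchemaError(f"{path}: GCT dimension line does not match body")
    elif format == "tsv":
        if not lines:
            raise SchemaError(f"{path}: empty file")
        header = lines[0].split("\t")
        samples = header[1:]
        body = [ln.split("\t") for ln in lines[1:] if ln]
        genes = [normalize_gene(r[0]) for r in body]
        data = [r[1:] for r in body]
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if len(samples) != len(set(samples)):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    raw = pd.DataFrame(data, index=genes, columns=samples, dtype=str)
    num = _parse_numeric_block(raw, path)
    num = _collapse_duplicate_genes(num, collapse)
    return ExpressionMatrix(values=num)


def write_expression_matrix(
    em: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        em.values.rename_axis("gene").to_csv(path, sep="\t")
    elif format == "gct":
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{em.n_genes}\t{em.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(em.sample_ids) + "\n")
            for gene, row in em.values.iterrows():
                fh.write(gene + "\t" + gene + "\t" + "\t".join(repr(v) for v in row) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# Mutation tables
# ---------------------------------------------------------------------------

_MAF_ALIASES = {
    "sample": ("sample", "Tumor_Sample_Barcode"),
    "gene": ("gene", "Hugo_Symbol"),
    "variant_classification": ("variant_classification", "Variant_Classification"),
    "protein_change": ("protein_change", "Protein_Change", "HGVSp_Short"),
}


def read_mutation_table(path: str | Path) -> MutationTable:
    """Read a MAF-subset TSV; accepts native or MAF column names.

    Only sample / gene / variant-classification (/ protein-change) columns are
    used; any other MAF columns are ignored. Unknown classification terms are
    mapped to OTHER with a warning. An empty body yields an empty table.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    cols: dict[str, str] = {}
    for canonical, aliases in _MAF_ALIASES.items():
        found = next((a for a in aliases if a in df.columns), None)
        if found is None:
            if canonical == "protein_change":
                df["protein_change"] = ""
                found = "protein_change"
            else:
                raise SchemaError(f"{path}: missing mandatory column {canonical!r}")
        cols[canonical] = found
    out = pd.DataFrame(
        {canonical: df[src] for canonical, src in cols.items()}
    )
    return MutationTable(records=out)


def write_mutation_table(mut: MutationTable, path: str | Path) -> None:
    mut.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene signatures
# ---------------------------------------------------------------------------


def read_signature(path: str | Path, format: str = "tsv") -> GeneSignature:
    """Read a gene signature from GMT (all-MEMBER) or TSV.

    TSV columns: ``gene`` (mandatory), ``class`` in {NE, NON_NE, MEMBER}
    (optional; absent means all MEMBER), ``mean_ne`` / ``mean_nonne``
    (mandatory whenever NE/NON_NE classes appear).
    """
    path = Path(path)
    if format == "gmt":
        with open(path, "rt", encoding="utf-8") as fh:
            line = fh.readline().rstrip("\n")
        fields = line.split("\t")
        if len(fields) < 3:
            raise SchemaError(f"{path}: GMT line needs name, description and >=1 gene")
        name, _desc, *genes = fields
        return GeneSignature(name=name, members={g: "MEMBER" for g in genes if g})
    if format != "tsv":
        raise ValueError(f"unknown signature format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene" not in df.columns:
        raise SchemaError(f"{path}: signature TSV needs a 'gene' column")
    classes = df["class"] if "class" in df.columns else pd.Series("MEMBER", index=df.index)
    members = dict(zip(df["gene"], classes))
    profiles = None
    if {"mean_ne", "mean_nonne"} <= set(df.columns):
        prof = df.set_index("gene")[["mean_ne", "mean_nonne"]].replace("", np.nan)
        prof = prof.apply(pd.to_numeric, errors="raise")
        profiles = prof
    return GeneSignature(name=path.stem, members=members, reference_profiles=profiles)


def write_signature(sig: GeneSignature, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "gmt":
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(sig.name + "\t" + sig.name + "\t" + "\t".join(sig.genes) + "\n")
        return
    rows = []
    for gene, cls in sig.members.items():
        row = {"gene": gene, "class": cls}
        if sig.reference_profiles is not None and gene in sig.reference_profiles.index:
            row["mean_ne"] = sig.reference_profiles.loc[gene, "mean_ne"]
            row["mean_nonne"] = sig.reference_profiles.loc[gene, "mean_nonne"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> AnnotationTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample" not in df.columns:
        raise SchemaError(f"{path}: annotations need a 'sample' column")
    return AnnotationTable(table=df.set_index("sample"))


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    ann.table.rename_axis("sample").to_csv(path, sep="\t")
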