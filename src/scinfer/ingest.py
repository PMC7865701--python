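"""Readers and validators for the four tabular inputs.

The pipeline consumes already-annotated tables: a variant table (one row per
variant call, with VEP-style consequence terms and SIFT scores), a per-gene
total copy-number table, a drug-response table of natural-log IC50 values,
and -- for the patient cohort -- somatic mutations in MAF format plus a
clinical table with overall-survival follow-up.

All readers return plain :class:`pandas.DataFrame` objects with standardised
column names; downstream modules operate on those frames. Column names in the
files are remapped through an optional ``dialect`` mapping
(``{standard_name: file_column_name}``), so arbitrary exports can be ingested
without rewriting headers.

Population-frequency filtering removes variants that are common in ESP or
1000 Genomes (germline / artifact candidates); rare or unobserved variants
are retained.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError, SchemaError, TableParseError

__all__ = [
    "VARIANT_COLUMNS",
    "MAF_CONSEQUENCE_MAP",
    "FilterReport",
    "read_variant_table",
    "read_copy_number_table",
    "read_drug_response_table",
    "read_clinical_table",
    "read_maf",
    "filter_population_variants",
    "write_table",
]

#: standard variant-table columns; the first three are mandatory
VARIANT_COLUMNS = ("sample_id", "gene", "consequence", "sift_score", "esp_af", "kg_af")
_VARIANT_MANDATORY = ("sample_id", "gene", "consequence")
_VARIANT_NUMERIC = ("sift_score", "esp_af", "kg_af")

#: MAF Variant_Classification -> Sequence Ontology consequence term.
#: Versioned with the package; unmapped classifications become "other"
#: (with a warning) and never abort a run.
MAF_CONSEQUENCE_MAP: Mapping[str, str] = {
    "Missense_Mutation": "missense_variant",
    "Nonsense_Mutation": "stop_gained",
    "Nonstop_Mutation": "stop_lost",
    "Frame_Shift_Del": "frameshift_variant",
    "Frame_Shift_Ins": "frameshift_variant",
    "In_Frame_Del": "inframe_deletion",
    "In_Frame_Ins": "inframe_insertion",
    "Splice_Site": "splice_acceptor_variant",
    "Splice_Region": "splice_region_variant",
    "Translation_Start_Site": "start_lost",
    "Silent": "synonymous_variant",
    "Intron": "intron_variant",
    "5'UTR": "5_prime_UTR_variant",
    "3'UTR": "3_prime_UTR_variant",
    "5'Flank": "upstream_gene_variant",
    "3'Flank": "downstream_gene_variant",
    "RNA": "non_coding_transcript_variant",
    "IGR": "intergenic_variant",
}

# VEP-style annotations often look like "deleterious(0.01)"
_SIFT_PAREN = re.compile(r"\(([-+0-9.eE]+)\)")


def _default_sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _apply_dialect(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    if not dialect:
        return df
    rename = {file_col: std for std, file_col in dialect.items() if file_col in df.columns}
    return df.rename(columns=rename)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing mandatory column(s): {', '.join(missing)}")


def _parse_numeric(df: pd.DataFrame, col: str, *, header_lines: int = 1) -> pd.Series:
    """Coerce a column to float; empty cells become NaN, garbage raises.

    Line numbers in the error are 1-based file lines (header included).
    """
    raw = df[col]
    if raw.dtype.kind in "fiu":
        return raw.astype(float)
    stripped = raw.astype("string").str.strip()
    parsed = pd.to_numeric(stripped, errors="coerce")
    bad = stripped.notna() & (stripped != "") & parsed.isna()
    if bad.any():
        lines = [str(i + header_lines + 1) for i in np.flatnonzero(bad.to_numpy())[:10]]
        raise TableParseError(
            f"column '{col}': unparseable numeric value(s) at line(s) {', '.join(lines)}"
        )
    return parsed.astype(float)


def _check_unit_interval(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    for col in cols:
        vals = df[col]
        out = vals.notna() & ((vals < 0) | (vals > 1))
        if out.any():
            raise DataError(f"{what}: column '{col}' has values outside [0, 1]")


def read_variant_table(path, dialect: Mapping[str, str] | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a variant table into the standard frame.

    Parameters
    ----------
    path
        TSV/CSV file with one row per variant call.
    dialect
        Optional ``{standard_name: file_column}`` remapping.
    sep
        Field separator; inferred from the extension when omitted.

    Returns
    -------
    DataFrame with columns ``sample_id, gene, consequence, sift_score,
    esp_af, kg_af``. Extra file columns are dropped; absent optional numeric
    columns become all-missing.
    """
    df = pd.read_csv(path, sep=sep or _default_sep(path), dtype="string")
    df = _apply_dialect(df, dialect)
    _require_columns(df, _VARIANT_MANDATORY, "variant table")
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "gene": df["gene"].astype(str),
            "consequence": df["consequence"].astype(str),
        }
    )
    for col in _VARIANT_NUMERIC:
        out[col] = _parse_numeric(df, col) if col in df.columns else np.nan
    _check_unit_interval(out, _VARIANT_NUMERIC, "variant table")
    return out


def read_copy_number_table(path, dialect: Mapping[str, str] | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a per-gene total copy-number table (``sample_id, gene, total_copy_number``)."""
    df = pd.read_csv(path, sep=sep or _default_sep(path), dtype="string")
    df = _apply_dialect(df, dialect)
    _require_columns(df, ("sample_id", "gene", "total_copy_number"), "copy-number table")
    cn = _parse_numeric(df, "total_copy_number")
    if cn.isna().any():
        raise DataError("copy-number table: missing total_copy_number values")
    if (cn < 0).any():
        raise DataError("copy-number table: negative total_copy_number")
    return pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "gene": df["gene"].astype(str),
            "total_copy_number": cn.astype(int),
        }
    )


def read_drug_response_table(path, dialect: Mapping[str, str] | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a drug-response table (``sample_id, drug, ln_ic50``); ln IC50 must be finite."""
    df = pd.read_csv(path, sep=sep or _default_sep(path), dtype="string")
    df = _apply_dialect(df, dialect)
    _require_columns(df, ("sample_id", "drug", "ln_ic50"), "drug-response table")
    y = _parse_numeric(df, "ln_ic50")
    if not np.isfinite(y.to_numpy(dtype=float)).all():
        raise DataError("drug-response table: non-finite ln_ic50 values")
    return pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "drug": df["drug"].astype(str),
            "ln_ic50": y.astype(float),
        }
    )


def read_clinical_table(path, dialect: Mapping[str, str] | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a clinical table (``patient_id, os_time, os_event`` and optional ``stage``)."""
    df = pd.read_csv(path, sep=sep or _default_sep(path), dtype="string")
    df = _apply_dialect(df, dialect)
    _require_columns(df, ("patient_id", "os_time", "os_event"), "clinical table")
    time = _parse_numeric(df, "os_time")
    event = _parse_numeric(df, "os_event")
    if (time < 0).any():
        raise DataError("clinical table: negative os_time")
    if not event.dropna().isin([0, 1]).all():
        raise DataError("clinical table: os_event must be 0/1")
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype(str),
            "os_time": time.astype(float),
            "os_event": event.astype(int),
        }
    )
    out["stage"] = df["stage"].astype("string") if "stage" in df.columns else pd.NA
    return out


def _parse_sift_annotation(series: pd.Series) -> pd.Series:
    """Accept plain numbers or VEP-style 'deleterious(0.01)' strings."""
    stripped = series.astype("string").str.strip()
    extracted = stripped.str.extract(_SIFT_PAREN, expand=False)
    merged = extracted.fillna(stripped)
    return pd.to_numeric(merged, errors="coerce").astype(float)


def read_maf(path, sift_column: str | None = "SIFT") -> pd.DataFrame:
    """Read a MAF somatic-mutation file into the standard variant frame.

    ``Variant_Classification`` terms are translated to Sequence Ontology
    consequence terms through :data:`MAF_CONSEQUENCE_MAP`; unknown terms map
    to ``"other"`` with a warning. ``Tumor_Sample_Barcode`` becomes
    ``sample_id``. ``#``-comment lines are skipped.

    Set ``sift_column=None`` for MAFs without SIFT annotation (all
    ``sift_score`` missing) -- disruption then rests on loss-of-function
    consequences alone.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype="string", low_memory=False)
    required = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    if sift_column is not None:
        required.append(sift_column)
    _require_columns(df, required, "MAF file")

    classification = df["Variant_Classification"].astype(str)
    unknown = sorted(set(classification) - set(MAF_CONSEQUENCE_MAP))
    if unknown:
        warnings.warn(
            f"MAF contains unmapped Variant_Classification terms kept as 'other': {unknown}",
            stacklevel=2,
        )
    consequence = classification.map(MAF_CONSEQUENCE_MAP).fillna("other")

    out = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"].astype(str),
            "gene": df["Hugo_Symbol"].astype(str),
            "consequence": consequence,
        }
    )
    out["sift_score"] = (
        _parse_sift_annotation(df[sift_column]) if sift_column is not None else np.nan
    )
    out["esp_af"] = np.nan
    out["kg_af"] = np.nan
    _check_unit_interval(out, ("sift_score",), "MAF file")
    return out


@dataclass(frozen=True)
class FilterReport:
    """Counts from one pass of the population-frequency filter."""

    n_input: int
    n_removed_esp: int
    n_removed_kg: int
    n_removed: int
    n_kept: int
    esp_max: float
    kg_max: float

    def to_tsv(self, path) -> None:
        pd.DataFrame([self.__dict__]).to_csv(path, sep="\t", index=False)


def filter_population_variants(
    variants: pd.DataFrame,
    esp_max: float = 0.00025,
    kg_max: float = 0.0014,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove likely-germline variants by population allele frequency.

    A variant is retained iff its ESP frequency is missing or below
    ``esp_max`` AND its 1000 Genomes frequency is missing or below
    ``kg_max``. Missing frequencies count as "not observed in the
    population" and are never grounds for removal.

    Returns the retained subset (row order preserved) and a
    :class:`FilterReport` with removal counts.
    """
    for name, thr in (("esp_max", esp_max), ("kg_max", kg_max)):
        if not (0 < thr <= 1):
            raise ParameterError(f"{name} must be in (0, 1], got {thr}")
    esp = variants["esp_af"]
    kg = variants["kg_af"]
    esp_fail = esp.notna() & (esp >= esp_max)
    kg_fail = kg.notna() & (kg >= kg_max)
    keep = ~(esp_fail | kg_fail)
    report = FilterReport(
        n_input=len(variants),
        n_removed_esp=int(esp_fail.sum()),
        n_removed_kg=int(kg_fail.sum()),
        n_removed=int((~keep).sum()),
        n_kept=int(keep.sum()),
        esp_max=esp_max,
        kg_max=kg_max,
    )
    return variants.loc[keep].copy(), report


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a standard frame back to disk (missing cells as empty fields)."""
    df.to_csv(path, sep=sep, index=False)
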