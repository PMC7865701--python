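"""Binary gene-disruption calls and the sample x gene disruption matrix.

A gene is *disrupted* in a sample when it carries an intolerant missense
variant (SIFT < 0.05), a loss-of-function variant (nonsense, frameshift,
start loss, or splice-site-region change), or a homozygous deletion (total
copy number 0). The per-(sample, gene) OR over all such events yields a
binary disruption matrix, the substrate of the pair screen.

Missense variants lacking a SIFT score are conservatively NOT disruptive.
Heterozygous losses and amplifications are not disruptive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError

__all__ = [
    "DEFAULT_LOF_CONSEQUENCES",
    "DisruptionMatrix",
    "is_disruptive_variant",
    "disruptive_variant_mask",
    "is_disruptive_copy_number",
    "build_disruption_matrix",
    "gene_disruption_frequency",
]

#: Loss-of-function consequence terms. "Splice site region mutation" is read
#: as covering splice_region_variant in addition to the canonical
#: donor/acceptor terms; pass a custom set for the narrower reading.
DEFAULT_LOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "start_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
    }
)


def is_disruptive_variant(
    consequence: str,
    sift_score: float | None = None,
    sift_threshold: float = 0.05,
    lof_consequences: frozenset[str] = DEFAULT_LOF_CONSEQUENCES,
) -> bool:
    """Classify a single variant as disruptive.

    True iff the consequence is loss-of-function, or it is a missense variant
    with a present SIFT score strictly below ``sift_threshold``.
    """
    if not lof_consequences:
        raise ParameterError("lof_consequences must be non-empty")
    if consequence in lof_consequences:
        return True
    if consequence == "missense_variant":
        return sift_score is not None and not (isinstance(sift_score, float) and math.isnan(sift_score)) and sift_score < sift_threshold
    return False


def disruptive_variant_mask(
    variants: pd.DataFrame,
    sift_threshold: float = 0.05,
    lof_consequences: frozenset[str] = DEFAULT_LOF_CONSEQUENCES,
) -> pd.Series:
    """Vectorised :func:`is_disruptive_variant` over a standard variant frame."""
    if not lof_consequences:
        raise ParameterError("lof_consequences must be non-empty")
    lof = variants["consequence"].isin(lof_consequences)
    missense = (variants["consequence"] == "missense_variant") & (
        variants["sift_score"] < sift_threshold
    )
    return lof | missense


def is_disruptive_copy_number(total_copy_number: int) -> bool:
    """True iff the deletion is homozygous (total copy number exactly 0)."""
    return total_copy_number == 0


@dataclass
class DisruptionMatrix:
    """samples x genes binary indicator of functional gene disruption.

    ``data`` holds 0/1 int8 cells indexed by sample and gene identifiers
    (opaque, case-sensitive strings). ``provenance`` optionally tags each
    positive cell with its evidence source (variant / copy_number / both /
    none).
    """

    data: pd.DataFrame
    provenance: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise DataError("disruption matrix cells must be 0/1")
        if self.data.index.has_duplicates:
            raise DataError("duplicate sample identifiers")
        if self.data.columns.has_duplicates:
            raise DataError("duplicate gene identifiers")
        self.data = self.data.astype(np.int8)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def column(self, gene: str) -> np.ndarray:
        """Boolean disruption vector of one gene, in sample order."""
        if gene not in self.data.columns:
            raise KeyError(f"gene '{gene}' not in disruption matrix")
        return self.data[gene].to_numpy(dtype=bool)

    def restrict_samples(self, samples: Sequence[str]) -> "DisruptionMatrix":
        """Sub-matrix over the given samples (matrix order preserved)."""
        keep = [s for s in self.sample_ids if s in set(samples)]
        prov = self.provenance.loc[keep] if self.provenance is not None else None
        return DisruptionMatrix(self.data.loc[keep], prov)

    def frequency(self) -> pd.Series:
        return gene_disruption_frequency(self)

    def to_tsv(self, path, provenance_path=None) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")
        if provenance_path is not None and self.provenance is not None:
            self.provenance.to_csv(provenance_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, provenance_path=None) -> "DisruptionMatrix":
        data = pd.read_csv(path, sep="\t", index_col="sample_id")
        data.index = data.index.astype(str)
        prov = None
        if provenance_path is not None:
            prov = pd.read_csv(provenance_path, sep="\t", index_col="sample_id")
            prov.index = prov.index.astype(str)
        return cls(data, prov)


def build_disruption_matrix(
    variants: pd.DataFrame,
    copy_number: pd.DataFrame | None,
    samples: Sequence[str],
    genes: Sequence[str] | str = "auto",
    sift_threshold: float = 0.05,
    lof_consequences: frozenset[str] = DEFAULT_LOF_CONSEQUENCES,
    with_provenance: bool = True,
) -> DisruptionMatrix:
    """Assemble the binary disruption matrix from variant and copy-number calls.

    Parameters
    ----------
    variants, copy_number
        Standard frames (see :mod:`scinfer.ingest`); ``copy_number`` may be
        None (mutation-only matrix, e.g. for MAF-derived patient cohorts).
    samples
        Ordered sample universe; rows for unknown samples are dropped with a
        warning; samples with no events get all-zero rows.
    genes
        Ordered gene universe, or ``"auto"`` for the sorted union of genes
        observed in either input.
    """
    samples = list(samples)
    if not samples:
        raise ParameterError("sample list must be non-empty")
    if len(set(samples)) != len(samples):
        raise DataError("duplicate sample identifiers")

    dis_var = variants.loc[disruptive_variant_mask(variants, sift_threshold, lof_consequences)]
    if copy_number is not None:
        dis_cnv = copy_number.loc[copy_number["total_copy_number"] == 0]
    else:
        dis_cnv = pd.DataFrame(columns=["sample_id", "gene"])

    if isinstance(genes, str) and genes == "auto":
        observed: set[str] = set(variants["gene"]) | (
            set(copy_number["gene"]) if copy_number is not None else set()
        )
        genes = sorted(observed)
    else:
        genes = list(genes)
    if len(set(genes)) != len(genes):
        raise DataError("duplicate gene identifiers")

    sample_pos = {s: i for i, s in enumerate(samples)}
    gene_pos = {g: i for i, g in enumerate(genes)}

    cells = np.zeros((len(samples), len(genes)), dtype=np.int8)
    var_hit = np.zeros_like(cells, dtype=bool)
    cnv_hit = np.zeros_like(cells, dtype=bool)

    n_unknown = 0
    for frame, hit in ((dis_var, var_hit), (dis_cnv, cnv_hit)):
        if frame.empty:
            continue
        srows = frame["sample_id"].map(sample_pos)
        unknown = srows.isna()
        n_unknown += int(unknown.sum())
        frame = frame.loc[~unknown]
        srows = srows.loc[~unknown].astype(int).to_numpy()
        gcols = frame["gene"].map(gene_pos)
        known_gene = gcols.notna()
        hit[srows[known_gene.to_numpy()], gcols.dropna().astype(int).to_numpy()] = True
    if n_unknown:
        warnings.warn(f"dropped {n_unknown} event record(s) for samples outside the sample list", stacklevel=2)

    cells[var_hit | cnv_hit] = 1
    data = pd.DataFrame(cells, index=pd.Index(samples, name="sample_id"), columns=genes)

    prov = None
    if with_provenance:
        tags = np.full(cells.shape, "none", dtype=object)
        tags[var_hit & ~cnv_hit] = "variant"
        tags[cnv_hit & ~var_hit] = "copy_number"
        tags[var_hit & cnv_hit] = "both"
        prov = pd.DataFrame(tags, index=data.index, columns=genes)
    return DisruptionMatrix(data, prov)


def gene_disruption_frequency(m: DisruptionMatrix) -> pd.Series:
    """Per-gene fraction of samples disrupted (column mean of the matrix)."""
    if m.n_samples < 1:
        raise ParameterError("matrix must have at least one sample")
    return m.data.mean(axis=0)
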