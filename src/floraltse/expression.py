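"""Transcriptome-sequencing expression (TSE): best-hit counting, RPKM,
reference normalization, presence calls and qPCR cross-validation.

Two quantification strategies are distinguished by their reference:

* **TSE1** — reads mapped to orthologous reference CDS models; the gene-model
  length is the reference CDS length.
* **TSE2** — reads mapped to the de novo contigs; the gene-model length is
  the full contig length (which may include UTR padding, and a chimeric
  contig collects reads from every transcript it concatenates).

Each read contributes exactly one count, to its single best hit.  Expression
is normalized to reads per kilobase of gene model per million mappable reads
(RPKM), where the mappable total is the number of reads with at least one
retained hit under the active strategy:

    RPKM_g = count_g * 1e9 / (model_length_g * N_mappable)

Relative profiles divide each gene's RPKM by that of a reference
(housekeeping) gene, mirroring normalization against an ACT7 homolog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import best_hit_per_query
from .io_formats import HitRecord

__all__ = [
    "ExpressionTable",
    "NormalizedProfile",
    "ValidationReport",
    "count_reads",
    "rpkm_table",
    "normalize_to_reference",
    "call_presence",
    "validate_against_qpcr",
]


def count_reads(
    read_hits: Iterable[HitRecord],
    exclude_subjects: frozenset[str] | set[str] = frozenset(),
) -> tuple[dict[str, int], int]:
    """Single-best-hit read counting.

    Each read (query) contributes one count to its best retained hit, with
    the same deterministic tie-break as annotation (bitscore, then e-value,
    then subject id).  Hits to ``exclude_subjects`` are discarded before
    selection; reads left without any retained hit are unmapped.

    Returns ``(counts, n_mappable)`` with ``sum(counts.values()) == n_mappable``.
    """
    if exclude_subjects:
        read_hits = (h for h in read_hits if h.subject_id not in exclude_subjects)
    best = best_hit_per_query(read_hits)
    counts: dict[str, int] = {}
    for hit in best.values():
        counts[hit.subject_id] = counts.get(hit.subject_id, 0) + 1
    return counts, len(best)


@dataclass
class ExpressionTable:
    """Per-gene read counts, gene-model lengths and RPKM for one strategy.

    ``df`` is indexed by gene id with columns ``read_count``, ``model_length``
    and ``rpkm``; the count column sums to :attr:`n_mappable`.
    """

    df: pd.DataFrame
    n_mappable: int
    strategy: str = "TSE1"

    def __post_init__(self) -> None:
        # tables quantifying the full gene universe satisfy equality; a
        # table restricted to a subset may count fewer reads, never more
        total = int(self.df["read_count"].sum())
        if total > self.n_mappable:
            raise ValueError(
                f"count conservation violated: sum of counts {total} > N_mappable {self.n_mappable}"
            )

    @property
    def counts(self) -> Mapping[str, int]:
        return self.df["read_count"].to_dict()

    @property
    def rpkm(self) -> Mapping[str, float]:
        return self.df["rpkm"].to_dict()


def rpkm_table(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    n_mappable: int,
    strategy: str = "TSE1",
) -> ExpressionTable:
    """Build an expression table with RPKM = count * 1e9 / (length * N_mappable).

    ``lengths`` defines the gene universe: genes with a model length but a
    zero count are included with RPKM 0.  A counted gene without a length is
    an error, as is ``n_mappable == 0``.
    """
    if n_mappable <= 0:
        raise ValueError("RPKM undefined: no mappable reads (N_mappable = 0)")
    missing = sorted(set(counts) - set(lengths))
    if missing:
        raise ValueError(f"missing model length for counted gene(s): {missing[:5]}")
    gene_ids = sorted(lengths)
    length_arr = np.array([lengths[g] for g in gene_ids], dtype=float)
    if np.any(length_arr <= 0):
        raise ValueError("gene-model lengths must be positive")
    count_arr = np.array([counts.get(g, 0) for g in gene_ids], dtype=np.int64)
    rpkm = count_arr * 1e9 / (length_arr * n_mappable)
    df = pd.DataFrame(
        {
            "read_count": count_arr,
            "model_length": length_arr.astype(int),
            "rpkm": rpkm,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ExpressionTable(df=df, n_mappable=n_mappable, strategy=strategy)


@dataclass
class NormalizedProfile:
    """Per-gene expression as a ratio to a reference gene's expression."""

    reference_gene_id: str
    ratios: dict[str, float]

    def shared_genes(self, other: "NormalizedProfile") -> list[str]:
        return sorted(set(self.ratios) & set(other.ratios))


def normalize_to_reference(table: ExpressionTable, reference_gene: str) -> NormalizedProfile:
    """Divide every gene's RPKM by the reference gene's RPKM.

    The profile is invariant to any common rescaling of counts and the
    mappable total.  An unexpressed (zero-count) or absent reference is an
    error.
    """
    rpkm = table.df["rpkm"]
    if reference_gene not in rpkm.index:
        raise ValueError(f"reference gene {reference_gene!r} not in expression table")
    ref_val = float(rpkm.loc[reference_gene])
    if ref_val <= 0:
        raise ValueError(f"reference gene {reference_gene!r} is unexpressed")
    ratios = {g: float(v) / ref_val for g, v in rpkm.items()}
    return NormalizedProfile(reference_gene_id=reference_gene, ratios=ratios)


def call_presence(table: ExpressionTable, min_count: int = 1) -> set[str]:
    """Genes considered present: read count >= ``min_count`` (default 1)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = table.df["read_count"]
    return set(counts.index[counts >= min_count])


@dataclass
class ValidationReport:
    """Least-squares comparison of two normalized expression profiles."""

    genes: list[str]
    values_a: list[float]
    values_b: list[float]
    r_squared: float
    slope: float
    intercept: float
    excluded_ids: list[str]
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"R^2 out of range: {self.r_squared}")


def validate_against_qpcr(
    tse_profile: NormalizedProfile,
    qpcr_profile: NormalizedProfile,
    exclude: Iterable[str] = (),
    log_scale: bool = False,
) -> ValidationReport:
    """Regress TSE fold ratios on qPCR fold ratios over the shared gene set.

    Returns the least-squares line and the squared Pearson correlation.
    ``exclude`` removes named genes (e.g. known discordant members of large
    gene families) before fitting; at least 3 shared genes must remain.
    With ``log_scale`` both profiles are log10-transformed (all ratios must
    then be positive).
    """
    excluded = sorted(set(exclude))
    shared = [g for g in tse_profile.shared_genes(qpcr_profile) if g not in set(excluded)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes after exclusion, got {len(shared)}")
    x = np.array([qpcr_profile.ratios[g] for g in shared], dtype=float)
    y = np.array([tse_profile.ratios[g] for g in shared], dtype=float)
    if log_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-scale validation requires strictly positive ratios")
        x, y = np.log10(x), np.log10(y)
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    return ValidationReport(
        genes=shared,
        values_a=y.tolist(),
        values_b=x.tolist(),
        r_squared=min(max(r2, 0.0), 1.0),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        excluded_ids=excluded,
        log_scale=log_scale,
    )
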