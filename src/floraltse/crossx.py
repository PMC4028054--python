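"""Qualitative cross-platform presence/absence comparison.

One floral transcriptome is defined by microarray detection (side A, e.g.
the *A. thaliana* flower across developmental stages), the other by RNA-seq
read counts (side B, the de novo transcriptome).  Because microarray
intensities and RPKM are not on a common scale, the two platforms are
compared only qualitatively: a transcript is present on the microarray side
if it exceeds the detection threshold in at least one stage/sample, and on
the RNA-seq side if it reaches a minimum read count.  Orthologous pairs from
the annotation step link the two gene universes; genes without a partner are
reported separately and never enter the differential lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .annotate import AnnotationPair
from .io_formats import MatrixTable

__all__ = [
    "ProbeMap",
    "PresenceComparison",
    "filter_unique_probes",
    "microarray_presence",
    "compare_presence",
]

#: probe id -> set of target gene ids
ProbeMap = dict[str, set[str]]


def filter_unique_probes(probe_map: Mapping[str, set[str]]) -> ProbeMap:
    """Retain only probes hybridizing to exactly one transcript.

    Multi-target probes cannot give a gene-resolved presence call and are
    dropped.  Probes with empty target sets are invalid.
    """
    out: ProbeMap = {}
    for probe, targets in probe_map.items():
        if not targets:
            raise ValueError(f"probe {probe!r} has an empty target set")
        if len(targets) == 1:
            out[probe] = set(targets)
    return out


def microarray_presence(expr: MatrixTable, detection_threshold: float) -> set[str]:
    """Genes detected in at least one floral stage / sample subset.

    A gene (row) is present iff any cell reaches ``detection_threshold``;
    for boolean matrices any ``True`` cell counts.
    """
    import math

    if not math.isfinite(detection_threshold):
        raise ValueError("detection threshold must be finite")
    df = expr.df
    if all(dt == bool for dt in df.dtypes):
        mask = df.any(axis=1)
    else:
        mask = (df >= detection_threshold).any(axis=1)
    return set(df.index[mask])


@dataclass
class PresenceComparison:
    """Decomposition of two platforms' present sets through a homology map."""

    present_a: set[str]
    present_b: set[str]
    only_a: set[str]  # present in A, mapped partner absent in B
    only_b: set[str]  # present in B, mapped partner absent in A
    shared_a: set[str]  # present in A with partner present in B
    shared_b: set[str]
    unmapped_a: set[str]  # present in A without any partner
    unmapped_b: set[str]
    a_to_b: dict[str, str]

    def __post_init__(self) -> None:
        # each side's present set is partitioned into only / shared / unmapped
        for present, parts in (
            (self.present_a, (self.only_a, self.shared_a, self.unmapped_a)),
            (self.present_b, (self.only_b, self.shared_b, self.unmapped_b)),
        ):
            union: set[str] = set()
            total = 0
            for p in parts:
                union |= p
                total += len(p)
            if union != present or total != len(present):
                raise ValueError("presence classes do not partition the present set")


def compare_presence(
    present_a: Iterable[str],
    present_b: Iterable[str],
    homology: Iterable[AnnotationPair] | Iterable[tuple[str, str]],
) -> PresenceComparison:
    """Differential presence lists through a one-to-one homology map.

    ``homology`` pairs side-A gene ids with side-B ids (``AnnotationPair``
    objects contribute ``(ref_gene_id, contig_id)``).  The map must be a
    partial matching — a duplicated partner on either side is an error.
    ``only_a`` holds genes present in A whose mapped partner is absent from
    B (and symmetrically); genes without a partner are reported as
    unmapped, never as differential.
    """
    a_to_b: dict[str, str] = {}
    b_to_a: dict[str, str] = {}
    for item in homology:
        if isinstance(item, AnnotationPair):
            a_id, b_id = item.ref_gene_id, item.contig_id
        else:
            a_id, b_id = item
        if a_id in a_to_b or b_id in b_to_a:
            raise ValueError(f"homology map is not a matching at ({a_id!r}, {b_id!r})")
        a_to_b[a_id] = b_id
        b_to_a[b_id] = a_id

    pa = set(present_a)
    pb = set(present_b)
    only_a = {a for a in pa if a in a_to_b and a_to_b[a] not in pb}
    shared_a = {a for a in pa if a in a_to_b and a_to_b[a] in pb}
    unmapped_a = {a for a in pa if a not in a_to_b}
    only_b = {b for b in pb if b in b_to_a and b_to_a[b] not in pa}
    shared_b = {b for b in pb if b in b_to_a and b_to_a[b] in pa}
    unmapped_b = {b for b in pb if b not in b_to_a}
    return PresenceComparison(
        present_a=pa,
        present_b=pb,
        only_a=only_a,
        only_b=only_b,
        shared_a=shared_a,
        shared_b=shared_b,
        unmapped_a=unmapped_a,
        unmapped_b=unmapped_b,
        a_to_b=a_to_b,
    )
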