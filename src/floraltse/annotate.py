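"""Contig annotation by reciprocal best bidirectional hits and chimera flagging.

De novo contigs are assigned to reference genes by the reciprocal best hit
(RBH) rule: a contig/gene pair is kept only when each is the other's single
best hit in the two opposite-direction similarity searches.  "Best" is made
deterministic by a total order: highest bitscore, then lowest e-value, then
lexicographically smallest subject id — so the result is invariant to input
row order.

A contig is flagged as a putative chimera (an assembly artifact concatenating
fragments of two or more transcripts) when it carries strong hits to at least
two distinct reference genes on essentially disjoint query intervals.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

from .io_formats import HitRecord

__all__ = [
    "AnnotationPair",
    "ChimeraCall",
    "best_hit_per_query",
    "reciprocal_best_hits",
    "flag_chimeras",
]


def _hit_order(hit: HitRecord):
    # total order: best = highest bitscore, then lowest e-value, then
    # lexicographically smallest subject id
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def best_hit_per_query(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Map each query id to its single best hit.

    Ties on bitscore are broken by lower e-value, then by lexicographically
    smallest subject id, making the selection deterministic and independent
    of input order.
    """
    best: dict[str, HitRecord] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or _hit_order(hit) < _hit_order(cur):
            best[hit.query_id] = hit
    return best


@dataclass(frozen=True)
class AnnotationPair:
    """A reciprocal-best-hit contig/reference-gene assignment."""

    contig_id: str
    ref_gene_id: str
    fwd_hit: HitRecord
    rev_hit: HitRecord

    def __post_init__(self) -> None:
        if self.fwd_hit.query_id != self.contig_id or self.fwd_hit.subject_id != self.ref_gene_id:
            raise ValueError("forward hit does not link contig to reference gene")
        if self.rev_hit.query_id != self.ref_gene_id or self.rev_hit.subject_id != self.contig_id:
            raise ValueError("reverse hit does not link reference gene to contig")


def reciprocal_best_hits(
    fwd: Iterable[HitRecord], rev: Iterable[HitRecord]
) -> list[AnnotationPair]:
    """Keep the best bidirectional hit per contig as its annotation.

    A pair ``(c, g)`` is returned iff ``g`` is the best forward hit of ``c``
    and ``c`` is the best reverse hit of ``g``.  The result is a partial
    matching: each contig and each gene occurs in at most one pair.  Pairs
    are sorted by contig id.
    """
    fbest = best_hit_per_query(fwd)
    rbest = best_hit_per_query(rev)
    pairs: list[AnnotationPair] = []
    for contig_id in sorted(fbest):
        fhit = fbest[contig_id]
        gene_id = fhit.subject_id
        rhit = rbest.get(gene_id)
        if rhit is not None and rhit.subject_id == contig_id:
            pairs.append(
                AnnotationPair(
                    contig_id=contig_id,
                    ref_gene_id=gene_id,
                    fwd_hit=fhit,
                    rev_hit=rhit,
                )
            )
    return pairs


@dataclass(frozen=True)
class ChimeraCall:
    """A contig flagged as chimeric, with its per-gene query segments."""

    contig_id: str
    segments: tuple[tuple[str, int, int], ...]  # (ref_gene_id, q_start, q_end)

    def __post_init__(self) -> None:
        if len(self.segments) < 2:
            raise ValueError("a chimera call needs at least two segments")
        genes = [g for g, _, _ in self.segments]
        if len(set(genes)) != len(genes):
            raise ValueError("chimera segments must involve distinct reference genes")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def flag_chimeras(
    fwd_hits: Iterable[HitRecord],
    min_segment: int = 100,
    max_overlap: int = 30,
    max_evalue: float = 1e-10,
) -> list[ChimeraCall]:
    """Flag contigs whose hits decompose into near-disjoint multi-gene segments.

    A contig is flagged iff it has hits to >= 2 distinct reference genes,
    each covering a query interval of at least ``min_segment`` with e-value
    <= ``max_evalue``, such that the selected intervals overlap pairwise by
    at most ``max_overlap``.  Per gene the best qualifying hit is taken as
    that gene's segment; a maximal pairwise-compatible set of segments is
    then chosen greedily by query end coordinate.
    """
    if min_segment <= 0 or max_overlap < 0 or max_evalue <= 0:
        raise ValueError("chimera thresholds must be positive")
    by_query: dict[str, dict[str, HitRecord]] = defaultdict(dict)
    for hit in fwd_hits:
        if hit.evalue > max_evalue or hit.q_span < min_segment:
            continue
        cur = by_query[hit.query_id].get(hit.subject_id)
        if cur is None or _hit_order(hit) < _hit_order(cur):
            by_query[hit.query_id][hit.subject_id] = hit
    calls: list[ChimeraCall] = []
    for contig_id in sorted(by_query):
        candidates = sorted(
            by_query[contig_id].values(), key=lambda h: (h.q_end, h.q_start, h.subject_id)
        )
        selected: list[HitRecord] = []
        for hit in candidates:
            if all(
                _overlap(hit.q_start, hit.q_end, s.q_start, s.q_end) <= max_overlap
                for s in selected
            ):
                selected.append(hit)
        if len(selected) >= 2:
            segments = tuple(
                (h.subject_id, h.q_start, h.q_end)
                for h in sorted(selected, key=lambda h: (h.q_start, h.q_end))
            )
            calls.append(ChimeraCall(contig_id=contig_id, segments=segments))
    return calls
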