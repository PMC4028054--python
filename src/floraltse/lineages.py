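"""Lineage-specific gene detection on a fixed five-taxon rosid tree.

Each de novo contig from the focal taxon (Th, *Tarenaya hassleriana*) gets a
four-flag presence vector recording whether it has an above-threshold
similarity hit in each comparator transcriptome: At (*Arabidopsis
thaliana*), Br (*Brassica rapa*), Cp (*Carica papaya*) and Pt (*Populus
trichocarpa*).  The focal taxon is implicitly always present.  The 16
possible vectors partition the contig universe into the named overlap
subsets (B, C, E, G, I, K, O and the residual focal-specific set Z, plus
eight unnamed masks).

Each vector is then interpreted on the fixed rooted topology
``(Pt,(Cp,(Th,(At,Br))))`` under Dollo parsimony: a single gene birth on the
edge above the most recent common ancestor of all present leaves, followed
by a minimal set of losses — one per maximal all-absent clade inside the
birth clade.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .io_formats import HitRecord

__all__ = [
    "TAXA",
    "FOCAL_TAXON",
    "DEFAULT_NEWICK",
    "LETTER_MAP",
    "TaxonTree",
    "PresenceVector",
    "SubsetPartition",
    "DolloReconstruction",
    "presence_vectors",
    "decompose_sets",
    "dollo_events",
    "summarize_births_losses",
]

#: Comparator taxa, in presence-mask order.
TAXA: tuple[str, ...] = ("At", "Br", "Cp", "Pt")
FOCAL_TAXON = "Th"

#: Fixed rosid topology with named internal nodes.
DEFAULT_NEWICK = "(Pt,(Cp,(Th,(At,Br)Brassicaceae)coreBrassicales)malvids)root;"

#: Names used for the subsets the comparative analysis distinguishes
#: (mask order At, Br, Cp, Pt; the focal taxon is implicit).
LETTER_MAP: dict[tuple[int, int, int, int], str] = {
    (1, 1, 0, 0): "B",  # shared with the core Brassicales (At, Br)
    (0, 1, 0, 0): "C",  # shared with B. rapa only (lost in At)
    (1, 1, 1, 0): "E",  # shared across the Brassicales (At, Br, Cp)
    (0, 0, 1, 0): "G",  # shared with C. papaya only (lost in Brassicaceae)
    (1, 1, 1, 1): "I",  # shared across all rosids
    (0, 0, 1, 1): "K",  # shared with Cp and Pt (lost in Brassicaceae)
    (0, 0, 0, 1): "O",  # shared with P. trichocarpa only (lost in Brassicales)
    (0, 0, 0, 0): "Z",  # focal-taxon specific
}


def subset_label(mask: tuple[int, int, int, int]) -> str:
    """The named subset letter, or the raw bitmask for the unnamed eight."""
    return LETTER_MAP.get(mask, "".join(str(b) for b in mask))


class TaxonTree:
    """A rooted taxon tree with named internal nodes.

    Edges are identified by the name of the node below them; the edge above
    the root carries the root's name.  The focal taxon must be a leaf.
    """

    def __init__(self, newick: str = DEFAULT_NEWICK, focal: str = FOCAL_TAXON):
        self.tree = dendropy.Tree.get(data=newick, schema="newick")
        self.focal = focal
        self._name_of: dict = {}
        self._below: dict[str, frozenset[str]] = {}
        self._children: dict[str, list[str]] = {}
        unnamed = 0
        for node in self.tree.preorder_node_iter():
            if node.taxon is not None:
                name = node.taxon.label
            elif node.label:
                name = node.label
            else:
                unnamed += 1
                name = f"node{unnamed}"
            self._name_of[node] = name
        names = list(self._name_of.values())
        if len(set(names)) != len(names):
            raise ValueError("tree node names must be unique")
        for node in self.tree.postorder_node_iter():
            name = self._name_of[node]
            kids = [self._name_of[c] for c in node.child_nodes()]
            self._children[name] = kids
            if not kids:
                self._below[name] = frozenset([name])
            else:
                self._below[name] = frozenset().union(*(self._below[k] for k in kids))
        self.root_name = self._name_of[self.tree.seed_node]
        if focal not in self._below[self.root_name]:
            raise ValueError(f"focal taxon {focal!r} is not a leaf of the tree")

    @property
    def leaf_names(self) -> frozenset[str]:
        return self._below[self.root_name]

    @property
    def edge_names(self) -> list[str]:
        """All edges, preorder, named by the node below each."""
        return [self._name_of[n] for n in self.tree.preorder_node_iter()]

    def leaves_below(self, name: str) -> frozenset[str]:
        return self._below[name]

    def children(self, name: str) -> list[str]:
        return self._children[name]

    def mrca(self, leaves: Iterable[str]) -> str:
        """Name of the most recent common ancestor of the given leaves."""
        target = frozenset(leaves)
        if not target:
            raise ValueError("mrca of an empty leaf set is undefined")
        unknown = target - self.leaf_names
        if unknown:
            raise ValueError(f"unknown leaves: {sorted(unknown)}")
        node = self.root_name
        while True:
            descended = False
            for child in self._children[node]:
                if target <= self._below[child]:
                    node = child
                    descended = True
                    break
            if not descended:
                return node


@dataclass(frozen=True)
class PresenceVector:
    """Four-taxon homology flags for one contig (focal taxon implicit)."""

    contig_id: str
    flags: tuple[bool, bool, bool, bool]  # order: TAXA

    @property
    def mask(self) -> tuple[int, int, int, int]:
        return tuple(int(b) for b in self.flags)  # type: ignore[return-value]

    @property
    def present_taxa(self) -> tuple[str, ...]:
        return tuple(t for t, b in zip(TAXA, self.flags) if b)


def presence_vectors(
    contig_ids: Sequence[str],
    hits_by_taxon: Mapping[str, Iterable[HitRecord]],
    evalue_cutoff: float = 1e-10,
) -> list[PresenceVector]:
    """Presence flag per comparator taxon: >= 1 hit with e-value <= cutoff.

    ``contig_ids`` defines the universe — contigs with no hit anywhere get
    the all-absent vector.  Hits from unlisted contigs are ignored.
    """
    if evalue_cutoff <= 0:
        raise ValueError("e-value cutoff must be positive")
    missing = set(TAXA) - set(hits_by_taxon)
    if missing:
        raise ValueError(f"missing hit table(s) for taxa: {sorted(missing)}")
    universe = list(dict.fromkeys(contig_ids))
    present: dict[str, set[str]] = {t: set() for t in TAXA}
    for taxon in TAXA:
        for hit in hits_by_taxon[taxon]:
            if hit.evalue <= evalue_cutoff:
                present[taxon].add(hit.query_id)
    return [
        PresenceVector(
            contig_id=c, flags=tuple(c in present[t] for t in TAXA)  # type: ignore[arg-type]
        )
        for c in universe
    ]


@dataclass
class SubsetPartition:
    """The 16-subset decomposition of the contig universe by presence mask."""

    by_mask: dict[tuple[int, int, int, int], set[str]]

    def __post_init__(self) -> None:
        all_masks = [
            (a, b, c, d) for a in (0, 1) for b in (0, 1) for c in (0, 1) for d in (0, 1)
        ]
        for m in all_masks:
            self.by_mask.setdefault(m, set())
        seen: set[str] = set()
        total = 0
        for ids in self.by_mask.values():
            total += len(ids)
            seen |= ids
        if total != len(seen):
            raise ValueError("subsets are not disjoint")

    @property
    def n_contigs(self) -> int:
        return sum(len(v) for v in self.by_mask.values())

    def sizes(self) -> dict[str, int]:
        """Subset sizes keyed by letter (named subsets) or bitmask."""
        return {
            subset_label(m): len(self.by_mask[m])
            for m in sorted(self.by_mask, reverse=True)
        }

    def members(self, label: str) -> set[str]:
        for m, ids in self.by_mask.items():
            if subset_label(m) == label:
                return set(ids)
        raise KeyError(label)


def decompose_sets(vectors: Iterable[PresenceVector]) -> SubsetPartition:
    """Group contigs by presence mask into the 16 disjoint, exhaustive subsets."""
    by_mask: dict[tuple[int, int, int, int], set[str]] = {}
    seen: set[str] = set()
    for vec in vectors:
        if vec.contig_id in seen:
            raise ValueError(f"duplicate contig id {vec.contig_id!r}")
        seen.add(vec.contig_id)
        by_mask.setdefault(vec.mask, set()).add(vec.contig_id)
    return SubsetPartition(by_mask=by_mask)


@dataclass(frozen=True)
class DolloReconstruction:
    """Single-gain / minimal-loss interpretation of one presence vector."""

    contig_id: str
    birth_branch: str
    loss_branches: frozenset[str]


@lru_cache(maxsize=None)
def _dollo_for_mask(
    mask: tuple[int, int, int, int], tree: TaxonTree
) -> tuple[str, frozenset[str]]:
    present = {FOCAL_TAXON} | {t for t, b in zip(TAXA, mask) if b}
    birth = tree.mrca(present)

    losses: list[str] = []

    def collect(node: str) -> None:
        for child in tree.children(node):
            if tree.leaves_below(child) & present:
                collect(child)
            else:
                losses.append(child)  # maximal all-absent clade

    collect(birth)
    return birth, frozenset(losses)


def dollo_events(vector: PresenceVector, tree: TaxonTree | None = None) -> DolloReconstruction:
    """Dollo-parsimony birth branch and minimal loss branches for one contig.

    The birth is placed on the edge above the MRCA of all present leaves
    (including the focal taxon); losses sit on the edges to the maximal
    clades inside the birth clade containing no present leaf.
    """
    if tree is None:
        tree = _default_tree()
    birth, losses = _dollo_for_mask(vector.mask, tree)
    return DolloReconstruction(
        contig_id=vector.contig_id, birth_branch=birth, loss_branches=losses
    )


_DEFAULT_TREE: TaxonTree | None = None


def _default_tree() -> TaxonTree:
    global _DEFAULT_TREE
    if _DEFAULT_TREE is None:
        _DEFAULT_TREE = TaxonTree()
    return _DEFAULT_TREE


def summarize_births_losses(
    partition: SubsetPartition, tree: TaxonTree | None = None
) -> pd.DataFrame:
    """Per-branch totals of inferred gene births and losses.

    Aggregates the Dollo reconstruction of every contig in the partition;
    rows are tree edges (named by the node below), columns ``gains`` and
    ``losses``.
    """
    if tree is None:
        tree = _default_tree()
    gains = {e: 0 for e in tree.edge_names}
    losses = {e: 0 for e in tree.edge_names}
    for mask, ids in partition.by_mask.items():
        if not ids:
            continue
        birth, loss_set = _dollo_for_mask(mask, tree)
        gains[birth] += len(ids)
        for edge in loss_set:
            losses[edge] += len(ids)
    return pd.DataFrame(
        {"gains": pd.Series(gains), "losses": pd.Series(losses)}
    ).loc[tree.edge_names]
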