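"""Ground-truthed synthetic data emulating a 454-style floral transcriptome study.

The generators reproduce the data-generating process the downstream stages
assume, with every planted fact recorded so parameter recovery can be
verified exactly:

* a universe of gene families born on the branches of the fixed five-taxon
  rosid tree and independently lost below, giving each family a known
  four-taxon presence mask (the focal taxon Th is always present — families
  are defined by its transcripts);
* log-normal transcript abundances with a configurable unexpressed fraction;
* reads drawn length-weighted from transcripts (CDS + 3' UTR), with
  normal-length reads (~316 nt, emulating 454 pyrosequencing) split across
  replicate libraries;
* de novo contigs, one per expressed family, UTR-padded, with a configured
  fraction of planted chimeras (two families concatenated into one contig,
  replacing both families' own contigs);
* noisy similarity hit tables standing in for the alignment engines: true
  hits carry e-values well below the 1e-10 detection threshold
  (log10 e ~ U(-180, -11)), spurious hits straddle it (log10 e ~ U(-12, -2)),
  and hits are dropped at a configurable miss rate;
* dilution-series and replicate Cq tables for the qPCR stage.

Sequencing base-call errors are not simulated: hit-table noise is the error
model, since alignment itself is outside the pipeline's scope.

A deliberate piece of realism: each family carries both the length of its
transcript in the focal taxon (``th_cds_length``) and the length of the
orthologous reference gene model (``ref_cds_length >= th_cds_length``).
Shallow 454 assemblies often recover only part of a gene, while read
counts are normalized to the *full* ortholog model under TSE1 — the
mismatch that makes contig-based quantification (TSE2, normalized to the
shorter contig) read systematically higher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import HitRecord, SeqRecord
from .lineages import TAXA, TaxonTree, _dollo_for_mask, _default_tree
from .qpcr import DilutionSeries

__all__ = [
    "GeneFamily",
    "CqExperiment",
    "BIRTH_BRANCHES",
    "DEFAULT_BIRTH_PROBS",
    "DEFAULT_LOSS_PROB",
    "family_gene_id",
    "generate_universe",
    "generate_abundances",
    "generate_reads",
    "generate_contigs",
    "generate_annotation_hits",
    "generate_read_hit_tables",
    "generate_hit_tables",
    "generate_cq",
    "generate_microarray",
    "expected_dollo_counts",
]

#: Branches on which a family ancestral to the focal taxon can be born.
BIRTH_BRANCHES: tuple[str, ...] = ("root", "malvids", "coreBrassicales", "Th")

#: Comparator taxa inside each birth clade.
_TAXA_BELOW: dict[str, tuple[str, ...]] = {
    "root": ("At", "Br", "Cp", "Pt"),
    "malvids": ("At", "Br", "Cp"),
    "coreBrassicales": ("At", "Br"),
    "Th": (),
}

#: Branches on which a family born above may be lost (never on the focal path).
_LOSS_EDGES_BELOW: dict[str, tuple[str, ...]] = {
    "root": ("Pt", "Cp", "Brassicaceae", "At", "Br"),
    "malvids": ("Cp", "Brassicaceae", "At", "Br"),
    "coreBrassicales": ("Brassicaceae", "At", "Br"),
    "Th": (),
}

#: Loss edges that disconnect each comparator taxon from the root.
_PATH_EDGES: dict[str, tuple[str, ...]] = {
    "At": ("Brassicaceae", "At"),
    "Br": ("Brassicaceae", "Br"),
    "Cp": ("Cp",),
    "Pt": ("Pt",),
}

# Defaults echo the published subset proportions (focal-specific ~11%,
# core-Brassicales-specific ~3%, Brassicales-specific ~1.4%).
DEFAULT_BIRTH_PROBS: dict[str, float] = {
    "root": 0.75,
    "malvids": 0.05,
    "coreBrassicales": 0.08,
    "Th": 0.12,
}
DEFAULT_LOSS_PROB: float = 0.01

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def family_gene_id(family_id: str) -> str:
    """Id of the orthologous reference gene model for a family."""
    return "g" + family_id.removeprefix("fam")


@dataclass
class GeneFamily:
    """One gene family of the synthetic universe (defined by a focal transcript)."""

    family_id: str
    birth_branch: str
    loss_branches: tuple[str, ...]
    presence: dict[str, bool]  # comparator taxa only; the focal taxon is implicit
    th_cds_length: int
    utr_length: int
    ref_cds_length: int
    sequence: str  # focal transcript: CDS then 3' UTR
    true_abundance: float = 0.0

    def __post_init__(self) -> None:
        if self.th_cds_length < 150:
            raise ValueError("CDS length must be >= 150 nt")
        if self.utr_length < 0 or self.true_abundance < 0:
            raise ValueError("UTR length and abundance must be non-negative")
        if self.ref_cds_length < self.th_cds_length:
            raise ValueError("reference model cannot be shorter than the covered CDS")

    @property
    def transcript_length(self) -> int:
        return self.th_cds_length + self.utr_length

    @property
    def mask(self) -> tuple[int, int, int, int]:
        return tuple(int(self.presence[t]) for t in TAXA)  # type: ignore[return-value]

    @property
    def gene_id(self) -> str:
        return family_gene_id(self.family_id)

    @property
    def expressed(self) -> bool:
        return self.true_abundance > 0


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


def _presence_from_events(birth: str, losses: Iterable[str]) -> dict[str, bool]:
    loss_set = set(losses)
    taxa_below = set(_TAXA_BELOW[birth])
    return {
        t: (t in taxa_below) and not (loss_set & set(_PATH_EDGES[t])) for t in TAXA
    }


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def generate_universe(
    n_families: int = 2000,
    birth_probs: Mapping[str, float] | None = None,
    loss_probs: Mapping[str, float] | float | None = None,
    seed: int = 0,
    cds_log_mean: float = math.log(1100.0),
    cds_log_sd: float = 0.35,
    cds_min: int = 300,
    cds_max: int = 8000,
    utr_mean: float = 250.0,
    complete_fraction: float = 0.7,
    min_completeness: float = 0.3,
) -> list[GeneFamily]:
    """Draw a universe of gene families with planted birth/loss histories.

    Each family is assigned a birth branch on the root-to-focal path
    (probabilities ``birth_probs``, normalized) and independent losses on
    the eligible branches below it (``loss_probs``, a scalar or a per-edge
    map; losses never sever the focal taxon).  Presence flags follow from
    the events.  Lengths and a random transcript sequence (CDS + 3' UTR)
    are drawn per family; the ortholog model length is the CDS length
    divided by an assembly-completeness factor.  Deterministic per seed.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    bp = dict(DEFAULT_BIRTH_PROBS if birth_probs is None else birth_probs)
    unknown = set(bp) - set(BIRTH_BRANCHES)
    if unknown:
        raise ValueError(f"unknown birth branches: {sorted(unknown)}")
    for k, v in bp.items():
        _check_prob(f"birth_probs[{k}]", v)
    weights = np.array([bp.get(b, 0.0) for b in BIRTH_BRANCHES], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("birth probabilities must not all be zero")
    weights = weights / weights.sum()
    if loss_probs is None:
        loss_probs = DEFAULT_LOSS_PROB
    if isinstance(loss_probs, (int, float)):
        lp = {e: float(loss_probs) for e in _LOSS_EDGES_BELOW["root"]}
    else:
        lp = {e: float(loss_probs.get(e, 0.0)) for e in _LOSS_EDGES_BELOW["root"]}
    for k, v in lp.items():
        _check_prob(f"loss_probs[{k}]", v)
    if not (0.0 <= complete_fraction <= 1.0) or not (0.0 < min_completeness <= 1.0):
        raise ValueError("completeness parameters out of range")

    rng = np.random.default_rng(seed)
    births = rng.choice(len(BIRTH_BRANCHES), size=n_families, p=weights)
    families: list[GeneFamily] = []
    for i in range(n_families):
        fid = f"fam{i:05d}"
        birth = BIRTH_BRANCHES[births[i]]
        losses = tuple(
            e for e in _LOSS_EDGES_BELOW[birth] if rng.random() < lp[e]
        )
        cds = int(np.clip(round(rng.lognormal(cds_log_mean, cds_log_sd)), cds_min, cds_max))
        utr = int(round(rng.exponential(utr_mean)))
        if rng.random() < complete_fraction:
            completeness = 1.0
        else:
            completeness = rng.uniform(min_completeness, 1.0)
        ref_len = max(cds, int(round(cds / completeness)))
        families.append(
            GeneFamily(
                family_id=fid,
                birth_branch=birth,
                loss_branches=losses,
                presence=_presence_from_events(birth, losses),
                th_cds_length=cds,
                utr_length=utr,
                ref_cds_length=ref_len,
                sequence=_random_sequence(rng, cds + utr),
            )
        )
    return families


def generate_abundances(
    families: Sequence[GeneFamily],
    lognormal_mu: float = 2.0,
    lognormal_sigma: float = 1.5,
    zero_fraction: float = 0.2,
    seed: int = 0,
) -> list[GeneFamily]:
    """Assign i.i.d. log-normal transcript abundances; a ``zero_fraction``
    of families is unexpressed.  Returns a new family list."""
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    if not (0.0 <= zero_fraction < 1.0):
        raise ValueError("zero_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(families)
    abundances = rng.lognormal(lognormal_mu, lognormal_sigma, size=n)
    zeros = rng.random(n) < zero_fraction
    abundances[zeros] = 0.0
    if abundances.sum() <= 0:
        raise ValueError("all families drew zero abundance; lower zero_fraction")
    return [replace(f, true_abundance=float(a)) for f, a in zip(families, abundances)]


def generate_reads(
    families: Sequence[GeneFamily],
    n_reads: int = 100_000,
    mean_len: float = 316.0,
    sd_len: float = 90.0,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[dict[str, list[SeqRecord]], pd.DataFrame]:
    """Sample reads length-weighted across expressed transcripts.

    The origin family of each read is drawn with probability proportional
    to ``true_abundance * transcript_length`` (a fragmentation model: more
    template mass yields more fragments).  Read length is normal
    (``mean_len``, ``sd_len``) truncated to ``[50, transcript_length]``;
    the read is a uniformly placed substring.  Reads are split at random
    into ``n_replicates`` disjoint libraries.

    Returns ``(reads_by_replicate, layout)`` where ``layout`` records each
    read's origin family, 0-based start, length and replicate.
    """
    if mean_len < 50:
        raise ValueError("mean read length must be >= 50 nt")
    if n_replicates < 1 or n_reads < 1:
        raise ValueError("need >= 1 read and >= 1 replicate")
    expressed = [f for f in families if f.expressed]
    if not expressed:
        raise ValueError("no expressed families to sample reads from")
    lengths = np.array([f.transcript_length for f in expressed], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("family with zero transcript length")
    weights = np.array([f.true_abundance for f in expressed]) * lengths
    rng = np.random.default_rng(seed)
    origin = rng.choice(len(expressed), size=n_reads, p=weights / weights.sum())
    raw_len = rng.normal(mean_len, sd_len, size=n_reads)
    read_len = np.minimum(np.maximum(np.round(raw_len), 50), lengths[origin]).astype(int)
    starts = np.floor(rng.random(n_reads) * (lengths[origin] - read_len + 1)).astype(int)
    replicates = rng.integers(0, n_replicates, size=n_reads)

    reads_by_rep: dict[str, list[SeqRecord]] = {
        f"rep{r + 1}": [] for r in range(n_replicates)
    }
    rows = []
    for i in range(n_reads):
        fam = expressed[origin[i]]
        rid = f"r{i:07d}"
        s, ln = int(starts[i]), int(read_len[i])
        rep = f"rep{replicates[i] + 1}"
        reads_by_rep[rep].append(SeqRecord(id=rid, sequence=fam.sequence[s : s + ln]))
        rows.append((rid, fam.family_id, s, ln, rep))
    layout = pd.DataFrame(
        rows, columns=["read_id", "family_id", "start", "length", "replicate"]
    )
    return reads_by_rep, layout


def generate_contigs(
    families: Sequence[GeneFamily],
    chimera_fraction: float = 0.01,
    utr_padding: str = "true_utr",
    seed: int = 0,
) -> tuple[list[SeqRecord], dict[str, tuple[tuple[str, int, int], ...]]]:
    """Assemble one contig per expressed family, with planted chimeras.

    With ``utr_padding="true_utr"`` a contig carries the full transcript
    (CDS + 3' UTR); with ``"none"`` only the CDS.  A ``chimera_fraction``
    of the expressed families (rounded, in pairs) is concatenated two-to-a-
    contig, replacing both families' own contigs, so reads from both
    transcripts later pool on the chimera.

    Returns ``(contigs, constituents)`` where ``constituents`` maps each
    contig id to its ``(family_id, start, end)`` spans (1-based inclusive).
    """
    if utr_padding not in ("none", "true_utr"):
        raise ValueError(f"unknown utr_padding mode {utr_padding!r}")
    if not (0.0 <= chimera_fraction <= 0.5):
        raise ValueError("chimera_fraction must be in [0, 0.5]")
    expressed = sorted((f for f in families if f.expressed), key=lambda f: f.family_id)
    if not expressed:
        raise ValueError("no expressed families to assemble")
    n_chim = int(round(chimera_fraction * len(expressed)))
    if chimera_fraction > 0 and len(expressed) < 2:
        raise ValueError("chimeras need at least two expressed families")
    n_chim = min(n_chim, len(expressed) // 2)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(expressed), size=2 * n_chim, replace=False)
    in_chimera = {expressed[i].family_id for i in chosen}

    def part(f: GeneFamily) -> str:
        return f.sequence if utr_padding == "true_utr" else f.sequence[: f.th_cds_length]

    # units keyed by their first family id so contig numbering is stable
    units: list[tuple[str, list[GeneFamily]]] = [
        (f.family_id, [f]) for f in expressed if f.family_id not in in_chimera
    ]
    for k in range(n_chim):
        fa = expressed[chosen[2 * k]]
        fb = expressed[chosen[2 * k + 1]]
        pair = sorted((fa, fb), key=lambda f: f.family_id)
        units.append((pair[0].family_id, pair))
    units.sort(key=lambda u: u[0])

    contigs: list[SeqRecord] = []
    constituents: dict[str, tuple[tuple[str, int, int], ...]] = {}
    for idx, (_, members) in enumerate(units):
        cid = f"tc{idx:05d}"
        seq_parts = []
        spans = []
        pos = 0
        for f in members:
            p = part(f)
            spans.append((f.family_id, pos + 1, pos + len(p)))
            seq_parts.append(p)
            pos += len(p)
        contigs.append(SeqRecord(id=cid, sequence="".join(seq_parts)))
        constituents[cid] = tuple(spans)
    return contigs, constituents


def _true_evalue(rng: np.random.Generator) -> float:
    return 10.0 ** (-rng.uniform(11.0, 180.0))


def _spurious_evalue(rng: np.random.Generator) -> float:
    return 10.0 ** (-rng.uniform(2.0, 12.0))


def generate_annotation_hits(
    constituents: Mapping[str, tuple[tuple[str, int, int], ...]],
    families: Sequence[GeneFamily],
    seed: int = 0,
) -> tuple[list[HitRecord], list[HitRecord]]:
    """Forward (contig -> reference gene) and reverse hit tables for annotation.

    Each constituent family yields one forward hit covering its span in the
    contig and the mirrored reverse hit; e-values are far below threshold
    and bitscores scale with alignment length, so noise-free reciprocal
    best hits recover the planted assignments.
    """
    by_id = {f.family_id: f for f in families}
    rng = np.random.default_rng(seed)
    fwd: list[HitRecord] = []
    for cid in sorted(constituents):
        for fam_id, start, end in constituents[cid]:
            fam = by_id[fam_id]
            span = end - start + 1
            aln = min(span, fam.th_cds_length)
            fwd.append(
                HitRecord(
                    query_id=cid,
                    subject_id=fam.gene_id,
                    pct_identity=float(rng.uniform(88.0, 100.0)),
                    aln_length=aln,
                    mismatches=0,
                    gap_opens=0,
                    q_start=start,
                    q_end=start + aln - 1,
                    s_start=1,
                    s_end=aln,
                    evalue=_true_evalue(rng),
                    bitscore=2.0 * aln,
                )
            )
    rev = [h.flipped() for h in fwd]
    return fwd, rev


def generate_read_hit_tables(
    layout: pd.DataFrame,
    families: Sequence[GeneFamily],
    constituents: Mapping[str, tuple[tuple[str, int, int], ...]] | None = None,
    target: str = "ref_cds",
    miss_rate: float = 0.0,
    seed: int = 0,
) -> list[HitRecord]:
    """Hit table for the read-mapping step of quantification.

    ``target="ref_cds"`` emulates mapping reads onto orthologous reference
    CDS models (TSE1): a read maps iff its midpoint falls within the CDS
    portion of its origin transcript (UTR reads find no protein-space hit).
    ``target="contig"`` emulates mapping onto the de novo contigs (TSE2):
    a read maps iff its midpoint falls within the portion of its transcript
    the contig carries — everything, under UTR padding.  Each mapped read
    yields exactly one hit (its origin model), dropped with probability
    ``miss_rate``.
    """
    if target not in ("ref_cds", "contig"):
        raise ValueError(f"unknown read-mapping target {target!r}")
    _check_prob("miss_rate", miss_rate)
    by_id = {f.family_id: f for f in families}
    fam_contig: dict[str, tuple[str, int, int]] = {}
    if target == "contig":
        if constituents is None:
            raise ValueError("contig target requires the contig constituents map")
        for cid, spans in constituents.items():
            for fam_id, start, end in spans:
                fam_contig[fam_id] = (cid, start, end)
    rng = np.random.default_rng(seed)
    miss_draws = rng.random(len(layout))
    evalue_exp = rng.uniform(11.0, 180.0, size=len(layout))
    hits: list[HitRecord] = []
    for i, row in enumerate(layout.itertuples(index=False)):
        fam = by_id[row.family_id]
        mid = row.start + row.length / 2.0
        if target == "ref_cds":
            if mid >= fam.th_cds_length:
                continue
            subject = fam.gene_id
            s_off, limit = 0, fam.th_cds_length
        else:
            if row.family_id not in fam_contig:
                continue
            cid, c_start, c_end = fam_contig[row.family_id]
            part_len = c_end - c_start + 1
            if mid >= part_len:
                continue
            subject = cid
            s_off, limit = c_start - 1, part_len
        if miss_draws[i] < miss_rate:
            continue
        aln = min(row.start + row.length, limit) - row.start
        hits.append(
            HitRecord(
                query_id=row.read_id,
                subject_id=subject,
                pct_identity=100.0,
                aln_length=int(aln),
                mismatches=0,
                gap_opens=0,
                q_start=1,
                q_end=int(aln),
                s_start=s_off + row.start + 1,
                s_end=s_off + row.start + int(aln),
                evalue=float(10.0 ** -evalue_exp[i]),
                bitscore=2.0 * float(aln),
            )
        )
    return hits


def generate_hit_tables(
    constituents: Mapping[str, tuple[tuple[str, int, int], ...]],
    families: Sequence[GeneFamily],
    miss_rate: float = 0.0,
    spurious_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, list[HitRecord]], dict[str, list[HitRecord]]]:
    """Per-comparator-taxon contig hit tables (forward and mirrored reverse).

    For each contig and each taxon where any constituent family is present,
    a true hit is emitted with e-value below the 1e-10 detection threshold
    (log10 e ~ U(-180, -11)), dropped with probability ``miss_rate``.
    Spurious hits to random families appear at rate ``spurious_rate`` per
    contig and taxon with e-values straddling the threshold
    (log10 e ~ U(-12, -2)).  Bitscores are anti-monotone in e-value.
    """
    _check_prob("miss_rate", miss_rate)
    _check_prob("spurious_rate", spurious_rate)
    by_id = {f.family_id: f for f in families}
    all_ids = [f.family_id for f in families]
    rng = np.random.default_rng(seed)
    fwd: dict[str, list[HitRecord]] = {t: [] for t in TAXA}
    for taxon in TAXA:
        for cid in sorted(constituents):
            spans = constituents[cid]
            present = [
                (fam_id, start, end)
                for fam_id, start, end in spans
                if by_id[fam_id].presence[taxon]
            ]
            if present and rng.random() >= miss_rate:
                fam_id, start, end = present[0]
                ev = _true_evalue(rng)
                fwd[taxon].append(
                    HitRecord(
                        query_id=cid,
                        subject_id=f"{taxon}_{fam_id}",
                        pct_identity=float(rng.uniform(70.0, 100.0)),
                        aln_length=end - start + 1,
                        mismatches=0,
                        gap_opens=0,
                        q_start=start,
                        q_end=end,
                        s_start=1,
                        s_end=end - start + 1,
                        evalue=ev,
                        bitscore=-2.0 * math.log10(ev),
                    )
                )
            if rng.random() < spurious_rate:
                fake = all_ids[rng.integers(len(all_ids))]
                ev = _spurious_evalue(rng)
                aln = min(120, spans[0][2])
                fwd[taxon].append(
                    HitRecord(
                        query_id=cid,
                        subject_id=f"{taxon}_{fake}",
                        pct_identity=float(rng.uniform(40.0, 70.0)),
                        aln_length=aln,
                        mismatches=0,
                        gap_opens=0,
                        q_start=1,
                        q_end=aln,
                        s_start=1,
                        s_end=aln,
                        evalue=ev,
                        bitscore=-2.0 * math.log10(ev),
                    )
                )
    rev = {t: [h.flipped() for h in hits] for t, hits in fwd.items()}
    return fwd, rev


@dataclass
class CqExperiment:
    """Synthetic qPCR study: SDR dilution series, replicate Cq values, truth."""

    dilution_series: dict[str, DilutionSeries]
    replicates: dict[str, dict[str, list[float]]]  # gene -> group -> Cq values
    efficiencies: dict[str, float]  # planted per-assay efficiencies
    reference_gene: str
    true_folds: dict[str, float]  # gene -> fold (test vs control, vs reference)


def generate_cq(
    gene_ids: Sequence[str],
    efficiencies: Mapping[str, float],
    reference_gene: str,
    group_means: Mapping[str, Mapping[str, float]],
    replicate_sd: float = 0.15,
    n_replicates: int = 6,
    dilution_factors: Sequence[float] = (50.0, 500.0, 5000.0, 50000.0),
    dilution_sd: float = 0.0,
    seed: int = 0,
) -> CqExperiment:
    """Dilution-series and replicate Cq tables from planted efficiencies.

    The SDR model is ``Cq = intercept - log_E(template)``; the serial
    dilutions default to 1:50 through 1:50,000.  Replicate Cq values are
    normal around the given per-group means (``replicate_sd``); the planted
    fold change of each gene versus the reference between the first two
    groups is recorded as truth.
    """
    if reference_gene not in gene_ids:
        raise ValueError("reference gene must be among the measured genes")
    factors = list(dilution_factors)
    if len(factors) < 3 or any(b <= a for a, b in zip(factors, factors[1:])):
        raise ValueError("dilution factors must be >= 3 and strictly increasing")
    for g in gene_ids:
        e = efficiencies[g]
        if e <= 1.0:
            raise ValueError(f"amplification efficiency must exceed 1 (gene {g}: {e})")
    if replicate_sd < 0 or dilution_sd < 0:
        raise ValueError("noise SDs must be non-negative")
    rng = np.random.default_rng(seed)
    dilution_series: dict[str, DilutionSeries] = {}
    replicates: dict[str, dict[str, list[float]]] = {}
    for g in gene_ids:
        e = float(efficiencies[g])
        intercept = float(rng.uniform(16.0, 24.0))
        points = []
        for factor in factors:
            log_amount = -math.log10(factor)
            cq = intercept - log_amount / math.log10(e)
            if dilution_sd > 0:
                cq += rng.normal(0.0, dilution_sd)
            points.append((log_amount, cq))
        dilution_series[g] = DilutionSeries(gene_id=g, points=tuple(points))
        replicates[g] = {}
        for group, mean in group_means[g].items():
            replicates[g][group] = [
                float(v) for v in rng.normal(mean, replicate_sd, size=n_replicates)
            ]
    groups = list(next(iter(group_means.values())))
    true_folds: dict[str, float] = {}
    if len(groups) >= 2:
        test, control = groups[0], groups[1]
        e_ref = float(efficiencies[reference_gene])
        dcq_ref = group_means[reference_gene][test] - group_means[reference_gene][control]
        for g in gene_ids:
            e_g = float(efficiencies[g])
            dcq_g = group_means[g][test] - group_means[g][control]
            true_folds[g] = float(e_g ** (-dcq_g) / e_ref ** (-dcq_ref))
    return CqExperiment(
        dilution_series=dilution_series,
        replicates=replicates,
        efficiencies={g: float(efficiencies[g]) for g in gene_ids},
        reference_gene=reference_gene,
        true_folds=true_folds,
    )


def generate_microarray(
    families: Sequence[GeneFamily],
    detection_threshold: float = 100.0,
    expressed_fraction: float = 0.85,
    multi_probe_fraction: float = 0.05,
    n_stages: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, set[str]], set[str]]:
    """Synthetic comparator-side (microarray) floral expression.

    For every family present in the At comparator, the ortholog gene gets a
    row over ``n_stages`` floral stages.  An ``expressed_fraction`` of genes
    is detected (above threshold in >= 1 stage); the rest stay below
    threshold everywhere.  The probe map is mostly one probe per gene, with
    a fraction of two-target probes (to be removed by the unique-probe
    filter).  Returns ``(matrix_df, probe_map, truly_present_genes)``.
    """
    _check_prob("expressed_fraction", expressed_fraction)
    _check_prob("multi_probe_fraction", multi_probe_fraction)
    genes = sorted(f.gene_id for f in families if f.presence["At"])
    if not genes:
        raise ValueError("no families present in the At comparator")
    rng = np.random.default_rng(seed)
    expressed = rng.random(len(genes)) < expressed_fraction
    values = rng.uniform(0.0, 0.8 * detection_threshold, size=(len(genes), n_stages))
    for i, is_expr in enumerate(expressed):
        if is_expr:
            k = int(rng.integers(1, n_stages + 1))
            stages = rng.choice(n_stages, size=k, replace=False)
            values[i, stages] = rng.uniform(
                1.5 * detection_threshold, 50.0 * detection_threshold, size=k
            )
    stage_ids = [f"stage{s + 1}" for s in range(n_stages)]
    matrix = pd.DataFrame(values, index=genes, columns=stage_ids)
    probe_map: dict[str, set[str]] = {
        f"p{i:05d}": {g} for i, g in enumerate(genes)
    }
    n_multi = int(round(multi_probe_fraction * len(genes)))
    if n_multi > 0 and len(genes) >= 2:
        for j in range(n_multi):
            pair = rng.choice(len(genes), size=2, replace=False)
            probe_map[f"pm{j:05d}"] = {genes[pair[0]], genes[pair[1]]}
    present = {g for g, e in zip(genes, expressed) if e}
    return matrix, probe_map, present


def expected_dollo_counts(
    n_families: int,
    birth_probs: Mapping[str, float] | None = None,
    loss_probs: Mapping[str, float] | float | None = None,
    tree: TaxonTree | None = None,
) -> pd.DataFrame:
    """Expected per-branch Dollo-reconstructed gain/loss counts.

    Enumerates every (birth branch, loss pattern) the generator can plant,
    derives the resulting presence mask, applies the Dollo reconstruction
    to that mask, and accumulates probability-weighted counts.  This is the
    identifiable expectation: stem losses that erase all evidence of the
    original birth are attributed the way Dollo parsimony must attribute
    them (e.g. a root birth whose outgroup copy was lost reconstructs as a
    later birth with no loss).
    """
    from itertools import product

    if tree is None:
        tree = _default_tree()
    bp = dict(DEFAULT_BIRTH_PROBS if birth_probs is None else birth_probs)
    weights = np.array([bp.get(b, 0.0) for b in BIRTH_BRANCHES], dtype=float)
    weights = weights / weights.sum()
    if loss_probs is None:
        loss_probs = DEFAULT_LOSS_PROB
    if isinstance(loss_probs, (int, float)):
        lp = {e: float(loss_probs) for e in _LOSS_EDGES_BELOW["root"]}
    else:
        lp = {e: float(loss_probs.get(e, 0.0)) for e in _LOSS_EDGES_BELOW["root"]}

    gains = {e: 0.0 for e in tree.edge_names}
    losses = {e: 0.0 for e in tree.edge_names}
    for b_idx, birth in enumerate(BIRTH_BRANCHES):
        edges = _LOSS_EDGES_BELOW[birth]
        for pattern in product((False, True), repeat=len(edges)):
            prob = weights[b_idx]
            for e, lost in zip(edges, pattern):
                prob *= lp[e] if lost else 1.0 - lp[e]
            if prob == 0.0:
                continue
            lost_edges = [e for e, flag in zip(edges, pattern) if flag]
            presence = _presence_from_events(birth, lost_edges)
            mask = tuple(int(presence[t]) for t in TAXA)
            rec_birth, rec_losses = _dollo_for_mask(mask, tree)
            gains[rec_birth] += prob * n_families
            for e in rec_losses:
                losses[e] += prob * n_families
    return pd.DataFrame({"gains": pd.Series(gains), "losses": pd.Series(losses)}).loc[
        tree.edge_names
    ]
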