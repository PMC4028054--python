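"""End-to-end orchestration of the synthetic comparative-transcriptome study.

``run_pipeline`` executes the stages in dependency order —

    synth -> annotate -> expression -> rarefaction -> lineages -> crossx -> qpcr

— from a single YAML-style configuration with one global seed, writing every
intermediate as plain TSV/FASTA/JSON under an output directory and returning
a machine-readable run report.  Each stage can also be run individually
(the CLI exposes one subcommand per stage); stages communicate only through
the files they write, so reruns are reproducible and byte-identical for a
fixed (config, seed).

Per-stage randomness is fanned out from the global seed through
``numpy.random.SeedSequence`` with a fixed stage index, so enabling or
disabling one stage never perturbs another's draws.
"""

from __future__ import annotations

import json
import logging
import math
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import annotate as _annotate
from . import crossx as _crossx
from . import expression as _expression
from . import lineages as _lineages
from . import qpcr as _qpcr
from . import rarefaction as _rarefaction
from . import synthdata as _synth
from .io_formats import (
    MatrixTable,
    parse_hit_table,
    read_fasta,
    read_matrix,
    write_fasta,
    write_hit_table,
    write_matrix,
)
from .qpcr import DilutionSeries

logger = logging.getLogger(__name__)

__all__ = [
    "demo_config",
    "load_config",
    "validate_config",
    "run_pipeline",
    "STAGES",
]

STAGES = ("synth", "annotate", "expression", "rarefaction", "lineages", "crossx", "qpcr")

_STAGE_SEED_INDEX = {name: i for i, name in enumerate(STAGES)}


def _stage_rng_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), _STAGE_SEED_INDEX[stage]])


def demo_config() -> dict:
    """The bundled, fully synthetic demonstration configuration."""
    from importlib import resources

    text = resources.files("floraltse").joinpath("data/demo.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as handle:
        cfg = yaml.safe_load(handle)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _get(cfg: Mapping, section: str, key: str, default=None):
    return (cfg.get(section) or {}).get(key, default)


def validate_config(config: Mapping[str, Any]) -> list[str]:
    """Return a list of human-readable violations; empty iff runnable."""
    v: list[str] = []
    stages_cfg = config.get("stages") or {}
    enabled = {s: bool(stages_cfg.get(s, True)) for s in STAGES}
    unknown = set(stages_cfg) - set(STAGES)
    if unknown:
        v.append(f"unknown stage toggle(s): {sorted(unknown)}")
    seed = config.get("seed")
    stochastic = enabled["synth"] or (
        enabled["rarefaction"] and bool(_get(config, "rarefaction", "mc", False))
    )
    if stochastic and not isinstance(seed, int):
        v.append("seed (integer) is mandatory when a stochastic stage is enabled")

    def check(section, key, ok, message):
        val = _get(config, section, key)
        if val is not None and not ok(val):
            v.append(f"{section}.{key}: {message} (got {val!r})")

    check("synth", "n_families", lambda x: isinstance(x, int) and x >= 1, "must be a positive integer")
    check("synth", "zero_fraction", lambda x: 0 <= x < 1, "must be in [0, 1)")
    check("synth", "chimera_fraction", lambda x: 0 <= x <= 0.5, "must be in [0, 0.5]")
    check("synth", "utr_padding", lambda x: x in ("none", "true_utr"), "must be 'none' or 'true_utr'")
    check("synth", "n_reads", lambda x: isinstance(x, int) and x >= 1, "must be a positive integer")
    check("synth", "mean_len", lambda x: x >= 50, "must be >= 50 nt")
    check("synth", "n_replicates", lambda x: isinstance(x, int) and x >= 1, "must be >= 1")
    check("synth", "miss_rate", lambda x: 0 <= x <= 1, "must be in [0, 1]")
    check("synth", "spurious_rate", lambda x: 0 <= x < 1, "must be in [0, 1)")
    check("annotate", "min_segment", lambda x: x > 0, "must be positive")
    check("annotate", "max_overlap", lambda x: x >= 0, "must be non-negative")
    check("annotate", "max_evalue", lambda x: x > 0, "must be positive")
    check("expression", "min_count", lambda x: isinstance(x, int) and x >= 1, "must be >= 1")
    check("rarefaction", "grid_points", lambda x: isinstance(x, int) and x >= 2, "must be >= 2")
    check("rarefaction", "reps", lambda x: isinstance(x, int) and x >= 1, "must be >= 1")
    check("rarefaction", "theta", lambda x: x >= 0, "must be non-negative")
    check("lineages", "evalue_cutoff", lambda x: x > 0, "must be positive")
    check("crossx", "detection_threshold", lambda x: math.isfinite(float(x)), "must be finite")
    check("qpcr", "n_validation_genes", lambda x: isinstance(x, int) and x >= 3, "must be >= 3")
    return v


# ----------------------------------------------------------------------
# small deterministic writers


def _write_tsv(df: pd.DataFrame, path, float_fmt: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_fmt, lineterminator="\n")


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def _read_truth(outdir: Path) -> dict:
    with open(outdir / "truth.json", "r", encoding="utf-8") as handle:
        return json.load(handle)


# ----------------------------------------------------------------------
# stages


def stage_synth(config: Mapping, outdir: Path) -> dict:
    """Generate the ground-truthed synthetic inputs and write them to disk."""
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    cfg = config.get("synth") or {}
    base = _stage_rng_seed(seed, "synth")
    children = base.spawn(10)

    families = _synth.generate_universe(
        n_families=cfg.get("n_families", 2000),
        birth_probs=cfg.get("birth_probs"),
        loss_probs=cfg.get("loss_probs"),
        complete_fraction=cfg.get("complete_fraction", 0.7),
        seed=children[0],
    )
    families = _synth.generate_abundances(
        families,
        lognormal_mu=cfg.get("lognormal_mu", 2.0),
        lognormal_sigma=cfg.get("lognormal_sigma", 1.5),
        zero_fraction=cfg.get("zero_fraction", 0.2),
        seed=children[1],
    )
    reads_by_rep, layout = _synth.generate_reads(
        families,
        n_reads=cfg.get("n_reads", 100_000),
        mean_len=cfg.get("mean_len", 316.0),
        sd_len=cfg.get("sd_len", 90.0),
        n_replicates=cfg.get("n_replicates", 2),
        seed=children[2],
    )
    contigs, constituents = _synth.generate_contigs(
        families,
        chimera_fraction=cfg.get("chimera_fraction", 0.01),
        utr_padding=cfg.get("utr_padding", "true_utr"),
        seed=children[3],
    )
    ann_fwd, ann_rev = _synth.generate_annotation_hits(constituents, families, seed=children[4])
    taxon_fwd, _taxon_rev = _synth.generate_hit_tables(
        constituents,
        families,
        miss_rate=cfg.get("miss_rate", 0.0),
        spurious_rate=cfg.get("spurious_rate", 0.0),
        seed=children[5],
    )
    matrix, probe_map, at_present = _synth.generate_microarray(
        families,
        detection_threshold=_get(config, "crossx", "detection_threshold", 100.0),
        expressed_fraction=cfg.get("microarray_expressed_fraction", 0.85),
        multi_probe_fraction=cfg.get("microarray_multi_probe_fraction", 0.05),
        seed=children[6],
    )

    # ------------------------------------------------------------------
    # qPCR design: a housekeeping reference (well-assembled, highly
    # expressed, non-chimeric) and a validation panel spanning the
    # high/moderate/low normalized-expression range, with a couple of
    # planted discordant genes (qPCR sees less template than the reads
    # suggest, emulating cross-mapping within large gene families).
    chimeric_families = {
        fam for spans in constituents.values() if len(spans) > 1 for fam, _, _ in spans
    }
    by_id = {f.family_id: f for f in families}
    clean = [
        f
        for f in families
        if f.expressed
        and f.family_id not in chimeric_families
        and f.ref_cds_length == f.th_cds_length
    ]
    if not clean:
        raise RuntimeError("synth: no clean candidate for the reference gene")
    # the housekeeping reference sits high in the abundance distribution but
    # not at its extreme, so the panel can straddle it (ratios 0.05-10)
    clean_sorted = sorted(clean, key=lambda f: f.true_abundance)
    reference_family = clean_sorted[int(0.98 * (len(clean_sorted) - 1))]
    ref_ab = reference_family.true_abundance
    candidates = [
        f
        for f in clean_sorted
        if f is not reference_family and 0.05 <= f.true_abundance / ref_ab <= 10.0
    ]
    n_panel = int(_get(config, "qpcr", "n_validation_genes", 14))
    if len(candidates) < n_panel:
        raise RuntimeError("synth: too few candidates for the qPCR validation panel")
    log_ratios = np.log10([f.true_abundance / ref_ab for f in candidates])
    targets = np.linspace(log_ratios.min(), log_ratios.max(), n_panel)
    panel, used = [], set()
    for t in targets:  # nearest unused candidate per log-spaced target ratio
        order = np.argsort(np.abs(log_ratios - t))
        idx = next(int(i) for i in order if int(i) not in used)
        used.add(idx)
        panel.append(candidates[idx])
    panel.sort(key=lambda f: f.true_abundance)
    rng_q = np.random.default_rng(children[7])
    n_outliers = int(cfg.get("qpcr_n_outliers", 2))
    # discordant genes sit in the upper half of the expression range, where
    # cross-mapping within large families distorts the read counts most
    upper = np.arange(len(panel) // 2, len(panel))
    outlier_idx = rng_q.choice(upper, size=min(n_outliers, len(upper)), replace=False)
    outliers = {panel[i].family_id for i in outlier_idx}
    discordance = float(cfg.get("qpcr_discordance_factor", 8.0))

    gene_ids = [reference_family.gene_id] + [f.gene_id for f in panel]
    efficiencies = {
        g: float(rng_q.uniform(*cfg.get("qpcr_efficiency_range", (1.85, 2.0))))
        for g in gene_ids
    }
    # Common fluorescence-threshold intercept across assays; the calibrator
    # group is an equimolar template (genomic DNA), so efficiency-corrected
    # fold changes against it recover abundance ratios exactly.
    intercept = 20.0
    gdna_amount = 0.1
    group_means: dict[str, dict[str, float]] = {}
    for fam in [reference_family] + panel:
        ab = fam.true_abundance
        if fam.family_id in outliers:
            ab = ab / discordance
        e = efficiencies[fam.gene_id]
        group_means[fam.gene_id] = {
            "flower": intercept - math.log(ab) / math.log(e),
            "calibrator": intercept - math.log(gdna_amount) / math.log(e),
        }
    cq = _synth.generate_cq(
        gene_ids,
        efficiencies,
        reference_family.gene_id,
        group_means,
        replicate_sd=cfg.get("qpcr_replicate_sd", 0.15),
        n_replicates=cfg.get("qpcr_n_replicates", 6),
        dilution_sd=cfg.get("qpcr_dilution_sd", 0.0),
        seed=children[8],
    )

    # ------------------------------------------------------------------
    # write everything
    fam_df = pd.DataFrame(
        {
            "family_id": [f.family_id for f in families],
            "gene_id": [f.gene_id for f in families],
            "birth_branch": [f.birth_branch for f in families],
            "loss_branches": [",".join(f.loss_branches) for f in families],
            **{t: [int(f.presence[t]) for f in families] for t in _lineages.TAXA},
            "th_cds_length": [f.th_cds_length for f in families],
            "utr_length": [f.utr_length for f in families],
            "ref_cds_length": [f.ref_cds_length for f in families],
            "true_abundance": [f.true_abundance for f in families],
        }
    ).set_index("family_id")
    _write_tsv(fam_df, outdir / "families.tsv")
    write_fasta(contigs, outdir / "contigs.fasta")
    for rep, recs in reads_by_rep.items():
        write_fasta(recs, outdir / f"reads_{rep}.fasta")
    write_hit_table(ann_fwd, outdir / "ann_fwd.tsv")
    write_hit_table(ann_rev, outdir / "ann_rev.tsv")
    for taxon, hits in taxon_fwd.items():
        write_hit_table(hits, outdir / f"taxon_hits_{taxon}.tsv")
    replicate_ids = sorted(reads_by_rep)
    for rep in replicate_ids:
        sub = layout[layout["replicate"] == rep]
        for target, stem in (("ref_cds", "read_hits_cds"), ("contig", "read_hits_contig")):
            hits = _synth.generate_read_hit_tables(
                sub,
                families,
                constituents,
                target=target,
                miss_rate=cfg.get("read_miss_rate", 0.0),
                seed=np.random.SeedSequence(
                    [seed, 900 + replicate_ids.index(rep), 0 if target == "ref_cds" else 1]
                ),
            )
            write_hit_table(hits, outdir / f"{stem}_{rep}.tsv")
    write_matrix(MatrixTable(matrix), outdir / "microarray.tsv")
    with open(outdir / "probe_map.tsv", "w", encoding="utf-8") as handle:
        for probe in sorted(probe_map):
            handle.write(f"{probe}\t{','.join(sorted(probe_map[probe]))}\n")
    dil_rows = []
    for g in gene_ids:
        for log_amount, cqv in cq.dilution_series[g].points:
            dil_rows.append((g, log_amount, cqv))
    _write_tsv(
        pd.DataFrame(dil_rows, columns=["gene_id", "log10_amount", "cq"]).set_index("gene_id"),
        outdir / "cq_dilutions.tsv",
    )
    rep_rows = []
    for g in gene_ids:
        for group, values in cq.replicates[g].items():
            for k, val in enumerate(values, start=1):
                rep_rows.append((g, group, k, val))
    _write_tsv(
        pd.DataFrame(rep_rows, columns=["gene_id", "group", "replicate", "cq"]).set_index(
            "gene_id"
        ),
        outdir / "cq_replicates.tsv",
    )
    truth = {
        "seed": seed,
        "reference_gene": reference_family.gene_id,
        "validation_genes": [f.gene_id for f in panel],
        "outlier_genes": sorted(_synth.family_gene_id(f) for f in outliers),
        "qpcr_groups": ["flower", "calibrator"],
        "true_efficiencies": cq.efficiencies,
        "true_folds": cq.true_folds,
        "at_present_genes": sorted(at_present),
        "chimeric_contigs": sorted(
            cid for cid, spans in constituents.items() if len(spans) > 1
        ),
        "constituents": {cid: [list(s) for s in spans] for cid, spans in constituents.items()},
        "presence": {f.family_id: list(f.mask) for f in families},
        "true_abundance": {f.family_id: f.true_abundance for f in families},
        "n_reads": int(len(layout)),
        "replicates": replicate_ids,
    }
    _write_json(truth, outdir / "truth.json")
    n_expressed = sum(1 for f in families if f.expressed)
    return {
        "n_families": len(families),
        "n_expressed": n_expressed,
        "n_reads": int(len(layout)),
        "n_contigs": len(contigs),
        "n_chimeric_planted": len(truth["chimeric_contigs"]),
    }


def stage_annotate(config: Mapping, outdir: Path) -> dict:
    """Reciprocal-best-hit annotation and chimera flagging from hit tables."""
    cfg = config.get("annotate") or {}
    fwd = parse_hit_table(outdir / "ann_fwd.tsv")
    rev = parse_hit_table(outdir / "ann_rev.tsv")
    pairs = _annotate.reciprocal_best_hits(fwd, rev)
    ann_df = pd.DataFrame(
        {
            "contig_id": [p.contig_id for p in pairs],
            "gene_id": [p.ref_gene_id for p in pairs],
            "fwd_evalue": [p.fwd_hit.evalue for p in pairs],
            "rev_evalue": [p.rev_hit.evalue for p in pairs],
        }
    ).set_index("contig_id")
    _write_tsv(ann_df, outdir / "annotation.tsv")
    calls = _annotate.flag_chimeras(
        fwd,
        min_segment=cfg.get("min_segment", 100),
        max_overlap=cfg.get("max_overlap", 30),
        max_evalue=cfg.get("max_evalue", 1e-10),
    )
    chim_df = pd.DataFrame(
        {
            "contig_id": [c.contig_id for c in calls],
            "n_segments": [len(c.segments) for c in calls],
            "segments": [
                ";".join(f"{g}:{s}-{e}" for g, s, e in c.segments) for c in calls
            ],
        }
    ).set_index("contig_id")
    _write_tsv(chim_df, outdir / "chimeras.tsv")
    n_contigs = len(read_fasta(outdir / "contigs.fasta"))
    if len(pairs) > n_contigs:
        raise RuntimeError("annotate: more annotations than contigs")
    return {
        "n_contigs": n_contigs,
        "n_annotated": len(pairs),
        "n_chimeric_flagged": len(calls),
    }


def _load_read_hits(outdir: Path, stem: str, replicates: list[str]):
    hits = []
    for rep in replicates:
        hits.extend(parse_hit_table(outdir / f"{stem}_{rep}.tsv"))
    return hits


def _replicate_ids(outdir: Path) -> list[str]:
    return list(_read_truth(outdir)["replicates"])


def _select_reference_gene(tse1, ann_df, contig_lengths) -> str:
    """Auto-pick the ACT7-like reference: highest-count TSE1 gene whose
    annotated contig covers essentially the whole gene model."""
    counts = tse1.df["read_count"]
    lengths = tse1.df["model_length"]
    best, best_count = None, -1
    for contig_id, row in ann_df.iterrows():
        gene = row["gene_id"]
        if gene not in counts.index:
            continue
        if contig_lengths.get(contig_id, 0) < 0.95 * lengths.loc[gene]:
            continue
        if int(counts.loc[gene]) > best_count:
            best, best_count = gene, int(counts.loc[gene])
    if best is None or best_count < 1:
        raise RuntimeError("expression: no suitable reference gene found")
    return best


def stage_expression(config: Mapping, outdir: Path) -> dict:
    """TSE1 and TSE2 quantification, RPKM tables and normalized profiles."""
    cfg = config.get("expression") or {}
    replicates = _replicate_ids(outdir)
    fam_df = pd.read_csv(outdir / "families.tsv", sep="\t", index_col=0)
    ref_lengths = dict(zip(fam_df["gene_id"], fam_df["ref_cds_length"].astype(int)))
    contigs = read_fasta(outdir / "contigs.fasta")
    contig_lengths = {c.id: c.length for c in contigs}
    ann_df = pd.read_csv(outdir / "annotation.tsv", sep="\t", index_col=0)
    flagged = set(pd.read_csv(outdir / "chimeras.tsv", sep="\t", index_col=0).index)

    cds_hits = _load_read_hits(outdir, "read_hits_cds", replicates)
    tse1_counts, tse1_n = _expression.count_reads(cds_hits)
    tse1 = _expression.rpkm_table(tse1_counts, ref_lengths, tse1_n, strategy="TSE1")
    _write_tsv(tse1.df, outdir / "expression_tse1.tsv")

    contig_hits = _load_read_hits(outdir, "read_hits_contig", replicates)
    exclude = flagged if cfg.get("exclude_chimeras", True) else set()
    tse2_counts, tse2_n = _expression.count_reads(contig_hits, exclude_subjects=exclude)
    tse2_lengths = {cid: L for cid, L in contig_lengths.items() if cid not in exclude}
    tse2 = _expression.rpkm_table(tse2_counts, tse2_lengths, tse2_n, strategy="TSE2")
    _write_tsv(tse2.df, outdir / "expression_tse2.tsv")

    # the qPCR design (synth stage) fixes the housekeeping reference a
    # priori, like ACT7; fall back to auto-selection when absent
    designed = _read_truth(outdir).get("reference_gene")
    reference = cfg.get("reference_gene") or designed or _select_reference_gene(
        tse1, ann_df, contig_lengths
    )
    profile1 = _expression.normalize_to_reference(tse1, reference)
    # gene-level TSE2 profile through the annotation map
    gene_of_contig = dict(zip(ann_df.index, ann_df["gene_id"]))
    ref_contigs = [c for c, g in gene_of_contig.items() if g == reference]
    if not ref_contigs or ref_contigs[0] not in tse2.rpkm:
        raise RuntimeError("expression: reference gene has no quantified contig")
    ref_contig = ref_contigs[0]
    tse2_rpkm = tse2.rpkm
    profile2_ratios = {}
    ref_val = tse2_rpkm[ref_contig]
    if ref_val <= 0:
        raise RuntimeError("expression: reference contig is unexpressed under TSE2")
    for contig_id, gene in gene_of_contig.items():
        if contig_id in tse2_rpkm:
            profile2_ratios[gene] = tse2_rpkm[contig_id] / ref_val
    profile2 = _expression.NormalizedProfile(reference_gene_id=reference, ratios=profile2_ratios)

    _write_tsv(
        pd.DataFrame(
            {"ratio": pd.Series(profile1.ratios).sort_index()}
        ).rename_axis("gene_id"),
        outdir / "normalized_tse1.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            {"ratio": pd.Series(profile2.ratios).sort_index()}
        ).rename_axis("gene_id"),
        outdir / "normalized_tse2.tsv",
    )
    min_count = int(cfg.get("min_count", 1))
    present_contigs = _expression.call_presence(tse2, min_count=min_count)
    with open(outdir / "present_contigs.txt", "w", encoding="utf-8") as handle:
        for cid in sorted(present_contigs):
            handle.write(cid + "\n")
    n_reads = _read_truth(outdir)["n_reads"]
    _write_json(
        {"reference_gene": reference, "tse1_n_mappable": tse1_n, "tse2_n_mappable": tse2_n},
        outdir / "expression_meta.json",
    )
    return {
        "reference_gene": reference,
        "tse1_n_mappable": tse1_n,
        "tse2_n_mappable": tse2_n,
        "tse1_mapping_rate": tse1_n / n_reads,
        "tse2_mapping_rate": tse2_n / n_reads,
    }


def stage_rarefaction(config: Mapping, outdir: Path) -> dict:
    """Per-replicate and merged gene-discovery curves with saturation calls."""
    cfg = config.get("rarefaction") or {}
    replicates = _replicate_ids(outdir)
    grid_points = int(cfg.get("grid_points", 50))
    theta = float(cfg.get("theta", 1e-3))
    libs: dict[str, _rarefaction.RarefactionLibrary] = {}
    for rep in replicates:
        hits = parse_hit_table(outdir / f"read_hits_contig_{rep}.tsv")
        counts, _ = _expression.count_reads(hits)
        libs[rep] = _rarefaction.RarefactionLibrary.from_counts(counts)
    merged = libs[replicates[0]]
    for rep in replicates[1:]:
        merged = _rarefaction.merge_libraries(merged, libs[rep])
    libs["merged"] = merged

    saturation: dict[str, dict] = {}
    for name in [*replicates, "merged"]:
        lib = libs[name]
        grid = _rarefaction.default_grid(lib.N, grid_points)
        curve = _rarefaction.rarefaction_curve_analytic(lib, grid, label=name)
        mc_sd = None
        if cfg.get("mc", False) and name == "merged":
            mc_curve = _rarefaction.rarefaction_curve_mc(
                lib,
                grid,
                reps=int(cfg.get("reps", 1000)),
                seed=_stage_rng_seed(int(config["seed"]), "rarefaction"),
                label=name,
            )
            mc_sd = mc_curve.mc_sd
            _write_tsv(
                pd.DataFrame(
                    {
                        "n": mc_curve.grid,
                        "mc_mean": mc_curve.expected_richness,
                        "mc_sd": mc_curve.mc_sd,
                    }
                ).set_index("n"),
                outdir / f"rarefaction_mc_{name}.tsv",
            )
        df = pd.DataFrame({"n": curve.grid, "expected_genes": curve.expected_richness})
        _write_tsv(df.set_index("n"), outdir / f"rarefaction_{name}.tsv")
        call = _rarefaction.assess_saturation(curve, theta=theta)
        saturation[name] = {
            "N": lib.N,
            "S": lib.S,
            "tail_slope": call.tail_slope,
            "threshold": call.threshold,
            "is_saturated": call.is_saturated,
        }
    _write_json(saturation, outdir / "saturation.json")
    if cfg.get("plot", False):
        curves = [
            _rarefaction.rarefaction_curve_analytic(
                libs[name], _rarefaction.default_grid(libs[name].N, grid_points), label=name
            )
            for name in [*replicates, "merged"]
        ]
        _rarefaction.plot_curves(curves, outdir / "rarefaction.png")
    return {name: info["is_saturated"] for name, info in saturation.items()} | {
        "merged_S": saturation["merged"]["S"]
    }


def stage_lineages(config: Mapping, outdir: Path) -> dict:
    """Presence vectors, 16-subset decomposition and Dollo event summary."""
    cfg = config.get("lineages") or {}
    cutoff = float(cfg.get("evalue_cutoff", 1e-10))
    contig_ids = [c.id for c in read_fasta(outdir / "contigs.fasta")]
    hits_by_taxon = {
        t: parse_hit_table(outdir / f"taxon_hits_{t}.tsv") for t in _lineages.TAXA
    }
    tree = _lineages.TaxonTree(cfg["newick"]) if cfg.get("newick") else _lineages._default_tree()
    vectors = _lineages.presence_vectors(contig_ids, hits_by_taxon, evalue_cutoff=cutoff)
    partition = _lineages.decompose_sets(vectors)
    rows = []
    for vec in vectors:
        rec = _lineages.dollo_events(vec, tree)
        rows.append(
            (
                vec.contig_id,
                *vec.mask,
                _lineages.subset_label(vec.mask),
                rec.birth_branch,
                ",".join(sorted(rec.loss_branches)),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["contig_id", *_lineages.TAXA, "subset", "birth_branch", "loss_branches"],
    ).set_index("contig_id")
    _write_tsv(df, outdir / "lineage_vectors.tsv")
    sizes = partition.sizes()
    if sum(sizes.values()) != len(contig_ids):
        raise RuntimeError("lineages: subset sizes do not sum to the contig count")
    _write_json(sizes, outdir / "subset_sizes.json")
    summary = _lineages.summarize_births_losses(partition, tree)
    _write_tsv(summary.rename_axis("branch"), outdir / "branch_events.tsv")
    return {"subset_sizes": sizes}


def stage_crossx(config: Mapping, outdir: Path) -> dict:
    """Microarray-vs-RNA-seq qualitative presence comparison."""
    cfg = config.get("crossx") or {}
    threshold = float(cfg.get("detection_threshold", 100.0))
    matrix = read_matrix(outdir / "microarray.tsv", value_kind="real")
    probe_map: dict[str, set[str]] = {}
    with open(outdir / "probe_map.tsv", "r", encoding="utf-8") as handle:
        for line in handle:
            probe, targets = line.rstrip("\n").split("\t")
            probe_map[probe] = set(targets.split(","))
    unique = _crossx.filter_unique_probes(probe_map)
    probed_genes = {next(iter(t)) for t in unique.values()}
    sub = MatrixTable(matrix.df.loc[sorted(probed_genes & set(matrix.df.index))])
    present_a = _crossx.microarray_presence(sub, threshold)
    with open(outdir / "present_contigs.txt", "r", encoding="utf-8") as handle:
        present_b = {line.strip() for line in handle if line.strip()}
    ann_df = pd.read_csv(outdir / "annotation.tsv", sep="\t", index_col=0)
    homology = [(g, c) for c, g in zip(ann_df.index, ann_df["gene_id"])]
    comparison = _crossx.compare_presence(present_a, present_b, homology)
    for name, ids in (
        ("only_A", comparison.only_a),
        ("only_B", comparison.only_b),
        ("shared_A", comparison.shared_a),
        ("unmapped_A", comparison.unmapped_a),
        ("unmapped_B", comparison.unmapped_b),
    ):
        with open(outdir / f"crossx_{name}.tsv", "w", encoding="utf-8") as handle:
            for gid in sorted(ids):
                handle.write(gid + "\n")
    return {
        "n_probes_unique": len(unique),
        "present_A": len(comparison.present_a),
        "present_B": len(comparison.present_b),
        "only_A": len(comparison.only_a),
        "only_B": len(comparison.only_b),
    }


def stage_qpcr(config: Mapping, outdir: Path) -> dict:
    """SDR efficiencies, ΔΔCq fold changes, ANOVA, and TSE validation."""
    truth = _read_truth(outdir)
    reference = truth["reference_gene"]
    panel = list(truth["validation_genes"])
    test_group, control_group = truth["qpcr_groups"]
    replicates = truth["replicates"]

    dil = pd.read_csv(outdir / "cq_dilutions.tsv", sep="\t")
    series = {
        g: DilutionSeries(
            gene_id=g,
            points=tuple(
                (float(r.log10_amount), float(r.cq))
                for r in sub.itertuples(index=False)
            ),
        )
        for g, sub in dil.groupby("gene_id", sort=True)
        for sub in [sub.sort_values("log10_amount", ascending=False)]
    }
    efficiencies = {g: _qpcr.fit_efficiency(s) for g, s in series.items()}
    eff_df = pd.DataFrame(
        {
            "slope": {g: e.slope for g, e in efficiencies.items()},
            "efficiency": {g: e.efficiency for g, e in efficiencies.items()},
            "r_squared": {g: e.r_squared for g, e in efficiencies.items()},
        }
    ).rename_axis("gene_id")
    _write_tsv(eff_df, outdir / "qpcr_efficiencies.tsv")

    reps = pd.read_csv(outdir / "cq_replicates.tsv", sep="\t")
    cq_by_gene: dict[str, dict[str, list[float]]] = {}
    for (gene, group), sub in reps.groupby(["gene_id", "group"], sort=True):
        cq_by_gene.setdefault(gene, {})[group] = list(sub["cq"])
    folds = {}
    for gene in panel:
        folds[gene] = _qpcr.fold_change(
            cq_by_gene[gene],
            cq_by_gene[reference],
            e_target=efficiencies[gene].efficiency,
            e_reference=efficiencies[reference].efficiency,
            test_group=test_group,
            control_group=control_group,
            target_gene=gene,
            reference_gene=reference,
        )
    qpcr_profile = _expression.NormalizedProfile(
        reference_gene_id=reference,
        ratios={g: fc.fold for g, fc in folds.items()} | {reference: 1.0},
    )

    tse_profiles = {}
    for strategy in ("tse1", "tse2"):
        ratios = pd.read_csv(outdir / f"normalized_{strategy}.tsv", sep="\t", index_col=0)[
            "ratio"
        ]
        tse_profiles[strategy] = _expression.NormalizedProfile(
            reference_gene_id=reference,
            ratios={g: float(ratios[g]) for g in [*panel, reference] if g in ratios.index},
        )

    # validation against TSE1 over the panel (the reference itself would be
    # a forced (1,1) anchor and is left out), then with the most discordant
    # genes (largest absolute residuals) removed
    report_all = _expression.validate_against_qpcr(
        tse_profiles["tse1"], qpcr_profile, exclude={reference}
    )
    resid = {
        g: abs(a - (report_all.intercept + report_all.slope * b))
        for g, a, b in zip(report_all.genes, report_all.values_a, report_all.values_b)
    }
    n_excl = int(_get(config, "qpcr", "n_outlier_exclusions", 2))
    worst = sorted(resid, key=lambda g: (-resid[g], g))[:n_excl]
    report_excl = _expression.validate_against_qpcr(
        tse_profiles["tse1"], qpcr_profile, exclude={reference, *worst}
    )
    report_tse2 = _expression.validate_against_qpcr(tse_profiles["tse2"], qpcr_profile)

    # per-replicate TSE ratios for the per-gene ANOVA across methods
    fam_df = pd.read_csv(outdir / "families.tsv", sep="\t", index_col=0)
    ref_lengths = dict(zip(fam_df["gene_id"], fam_df["ref_cds_length"].astype(int)))
    ann_df = pd.read_csv(outdir / "annotation.tsv", sep="\t", index_col=0)
    contig_of_gene = {g: c for c, g in zip(ann_df.index, ann_df["gene_id"])}
    contig_lengths = {c.id: c.length for c in read_fasta(outdir / "contigs.fasta")}
    anova_rows = []
    tse1_rep: dict[str, list[float]] = {g: [] for g in panel}
    tse2_rep: dict[str, list[float]] = {g: [] for g in panel}
    for rep in replicates:
        cds_counts, _ = _expression.count_reads(
            parse_hit_table(outdir / f"read_hits_cds_{rep}.tsv")
        )
        contig_counts, _ = _expression.count_reads(
            parse_hit_table(outdir / f"read_hits_contig_{rep}.tsv")
        )
        ref_density1 = cds_counts.get(reference, 0) / ref_lengths[reference]
        ref_contig = contig_of_gene[reference]
        ref_density2 = contig_counts.get(ref_contig, 0) / contig_lengths[ref_contig]
        for g in panel:
            if ref_density1 > 0:
                tse1_rep[g].append(
                    (cds_counts.get(g, 0) / ref_lengths[g]) / ref_density1
                )
            contig = contig_of_gene.get(g)
            if contig is not None and ref_density2 > 0:
                tse2_rep[g].append(
                    (contig_counts.get(contig, 0) / contig_lengths[contig]) / ref_density2
                )
    e_ref = efficiencies[reference].efficiency
    dcq_ref = float(
        np.mean(cq_by_gene[reference][test_group])
        - np.mean(cq_by_gene[reference][control_group])
    )
    for g in panel:
        e_g = efficiencies[g].efficiency
        calib_g = float(np.mean(cq_by_gene[g][control_group]))
        qpcr_ratios = [
            float(e_g ** -(cq - calib_g) / e_ref**-dcq_ref)
            for cq in cq_by_gene[g][test_group]
        ]
        groups = [qpcr_ratios, tse1_rep[g], tse2_rep[g]]
        if all(len(gr) >= 2 for gr in groups):
            f_stat, p_val = _qpcr.one_way_anova(groups)
            anova_rows.append((g, f_stat, p_val))
    _write_tsv(
        pd.DataFrame(anova_rows, columns=["gene_id", "F", "p_value"]).set_index("gene_id"),
        outdir / "qpcr_anova.tsv",
    )
    fold_df = pd.DataFrame(
        {
            "dcq_target": {g: fc.dcq_target for g, fc in folds.items()},
            "dcq_reference": {g: fc.dcq_reference for g, fc in folds.items()},
            "ddcq": {g: fc.ddcq for g, fc in folds.items()},
            "fold": {g: fc.fold for g, fc in folds.items()},
        }
    ).rename_axis("gene_id")
    _write_tsv(fold_df, outdir / "qpcr_fold_changes.tsv")
    validation = {
        "r_squared_all": report_all.r_squared,
        "r_squared_excluded": report_excl.r_squared,
        "excluded_genes": worst,
        "r_squared_tse2_all": report_tse2.r_squared,
        "n_genes": len(report_all.genes),
    }
    _write_json(validation, outdir / "validation.json")
    return validation


_STAGE_FUNCS = {
    "synth": stage_synth,
    "annotate": stage_annotate,
    "expression": stage_expression,
    "rarefaction": stage_rarefaction,
    "lineages": stage_lineages,
    "crossx": stage_crossx,
    "qpcr": stage_qpcr,
}


def run_pipeline(config: Mapping[str, Any], outdir) -> dict:
    """Run all enabled stages in dependency order; return the run report.

    Validation failures or a stage error abort the run; the report names
    the failing stage.  For a fixed (config, seed) the TSV/JSON outputs are
    byte-identical across runs.
    """
    from . import __version__

    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages_cfg = config.get("stages") or {}
    report: dict[str, Any] = {
        "version": __version__,
        "config": {k: v for k, v in config.items()},
        "stages": {},
    }
    for stage in STAGES:
        if not stages_cfg.get(stage, True):
            logger.info("stage %s disabled; skipping", stage)
            continue
        t0 = time.perf_counter()
        try:
            result = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.1fs", stage, time.perf_counter() - t0)
        report["stages"][stage] = result
    _write_json(report, outdir / "run_report.json")
    return report
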