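"""End-to-end pipeline: simulate -> CNV -> mutations -> classify -> compare.

:func:`run_all` chains every stage on synthetic data under one
:class:`~tumorcross.io.RunConfig`, writing the intermediate text files
and a machine-readable ``summary.json``.  Deterministic for a fixed
seed; any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._util import derive_seed
from .cnv import MadContext, annotate_genes, call_cnv, cbs_segment, compute_log2_ratio
from .cohort import classify_tumor, cohort_summary
from .compare import (
    ALTERATION_CLASSES,
    OrthologMap,
    common_genes,
    compare_event_rates,
    human_included_genes,
    mouse_alteration_set,
    overrepresentation,
)
from .genome import CnvTruth, GenomeModel, make_genome
from .io import RunConfig, write_bed, write_cohort, write_mutations, write_seg, write_windows
from .mutations import aggregate_by_gene, classify_frame, summarize_per_tumor
from .simulate import CohortSpec, cohort_to_frame, simulate_cohort, simulate_depth, simulate_mutations

__all__ = ["run_all", "random_truth", "call_tumor_cnvs"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def random_truth(
    genome: GenomeModel,
    n_segments: int,
    seed: int,
    purity: float = 1.0,
    min_windows: int = 10,
    max_windows: int = 40,
    ratios: tuple[float, ...] = (0.5, 2.0, 3.0),
) -> CnvTruth:
    """Implant non-overlapping random amp/del segments, window-aligned."""
    rng = np.random.default_rng(seed)
    w = genome.window_size
    segs: list[tuple[str, int, int, float]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    attempts = 0
    while len(segs) < n_segments and attempts < 200 * max(n_segments, 1):
        attempts += 1
        chrom, length = genome.chromosomes[rng.integers(0, len(genome.chromosomes))]
        n_win = int(rng.integers(min_windows, max_windows + 1))
        max_start_win = length // w - n_win
        if max_start_win < 1:
            continue
        start = int(rng.integers(0, max_start_win)) * w
        end = start + n_win * w
        if any(s < end and start < e for s, e in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append((start, end))
        segs.append((chrom, start, end, float(rng.choice(ratios))))
    if len(segs) < n_segments:
        raise ValueError("could not place the requested truth segments without overlap")
    return CnvTruth(segments=tuple(segs), purity=purity)


def call_tumor_cnvs(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    genome: GenomeModel,
    tumor_id: str,
    config: RunConfig,
):
    """Windows -> normalized ratios -> CBS -> MAD calls -> gene records."""
    ratios = compute_log2_ratio(tumor, normal, min_normal_count=config.min_normal_count)
    segments = cbs_segment(
        ratios,
        alpha=config.alpha,
        n_permutations=config.n_permutations,
        min_width=3,
        seed=derive_seed(config.seed, zlib.crc32(tumor_id.encode()) % 10_000),
    )
    context = MadContext.from_ratios(ratios, threshold_multiplier=config.mad_multiplier)
    labelled = call_cnv(segments, context)
    gene_cnvs = annotate_genes(labelled, genome, tumor_id)
    return ratios, labelled, gene_cnvs


def _stage(name: str, fn: Callable):
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run the whole synthetic-data pipeline and write a report directory.

    Products: gene BED, per-tumor window TSVs and labelled SEG files,
    the mouse mutation MAF, the human cohort TSV, per-tumor event
    counts, category fractions, cross-species common-gene reports, an
    over-representation table and ``summary.json`` aggregating it all.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = _stage(
        "simulate.genome",
        lambda: make_genome(
            n_chromosomes=config.n_chromosomes,
            chromosome_length_bp=config.chromosome_length_bp,
            n_genes=config.n_genes,
            min_gene_len=config.min_gene_len,
            max_gene_len=config.max_gene_len,
            seed=derive_seed(config.seed, 1),
            window_size=config.window_size,
        ),
    )
    write_bed(outdir / "genes.bed", genome.genes, config)

    # --- mouse arm: depth + CNV calling per tumor -------------------------
    def mouse_cnvs():
        gene_frames = []
        for t in range(config.n_mouse_tumors):
            tumor_id = f"M{t + 1}"
            truth = random_truth(
                genome,
                n_segments=4,
                seed=derive_seed(config.seed, 100 + t),
                purity=config.purity,
            )
            tumor, normal = simulate_depth(
                genome,
                truth,
                mean_depth_per_window=config.mean_depth_per_window,
                dispersion=config.dispersion,
                seed=derive_seed(config.seed, 200 + t),
            )
            write_windows(outdir / f"windows_{tumor_id}.tsv", tumor, normal, config)
            _, labelled, gene_cnvs = call_tumor_cnvs(tumor, normal, genome, tumor_id, config)
            write_seg(outdir / f"segments_{tumor_id}.seg", labelled, tumor_id, config, labels=True)
            gene_frames.append(gene_cnvs)
        nonempty = [f for f in gene_frames if len(f)]
        return pd.concat(nonempty, ignore_index=True) if nonempty else gene_frames[0]

    gene_cnvs = _stage("cnv", mouse_cnvs)
    gene_cnvs.to_csv(outdir / "gene_cnvs.tsv", sep="\t", index=False)

    # --- mouse arm: mutations --------------------------------------------
    def mouse_mutations():
        table, _truth = simulate_mutations(
            genome,
            n_tumors=config.n_mouse_tumors,
            mutations_per_tumor=config.mutations_per_tumor,
            deleterious_fraction=config.deleterious_fraction,
            seed=derive_seed(config.seed, 300),
            tumor_ids=[f"M{t + 1}" for t in range(config.n_mouse_tumors)],
        )
        classified = classify_frame(table, consensus_mode=config.consensus_mode)
        write_mutations(outdir / "mutations.maf.tsv", classified, config)
        return classified

    classified = _stage("mutations", mouse_mutations)
    mut_table = aggregate_by_gene(classified, n_tumors=config.n_mouse_tumors)
    per_tumor, summary_stats = summarize_per_tumor(classified, gene_cnvs)
    per_tumor.to_csv(outdir / "per_tumor_counts.tsv", sep="\t", index=False)

    # --- human arm: cohort + classification -------------------------------
    def human_cohort():
        spec = CohortSpec(
            n_tumors=config.n_human_tumors,
            category_probs=config.category_probs,
            background_gene_alteration_rate=config.background_gene_alteration_rate,
            seed=derive_seed(config.seed, 400),
        )
        profiles, _cats = simulate_cohort(spec, genome)
        frame = cohort_to_frame(profiles)
        write_cohort(outdir / "cohort.tsv", frame, config)
        labels = [classify_tumor(p, mode=config.classifier_mode) for p in profiles]
        pd.DataFrame({"tumor_id": [p.tumor_id for p in profiles], "category": labels}).to_csv(
            outdir / "cohort_labels.tsv", sep="\t", index=False
        )
        return profiles, frame, labels

    profiles, cohort_frame, labels = _stage("classify", human_cohort)
    categories = cohort_summary(labels)

    # --- cross-species comparison -----------------------------------------
    def cross_species():
        ortho = OrthologMap.identity_for(genome.genes["name"])
        lengths = genome.gene_lengths()
        human_lengths = {name.upper(): int(v) for name, v in lengths.items()}
        reports = {}
        mouse_sets = {
            "NSPM_InDel": mouse_alteration_set(classified, "NSPM_InDel", min_tumors=1),
            "CNA": mouse_alteration_set(gene_cnvs, "CNA", min_tumors=1),
            "CND": mouse_alteration_set(gene_cnvs, "CND", min_tumors=1),
        }
        for cls in ALTERATION_CLASSES:
            human = human_included_genes(
                cohort_frame,
                cls,
                min_tumors=1 if cls == "NSPM_InDel" else config.min_tumors,
                gene_lengths=human_lengths,
            )
            reports[cls] = common_genes(mouse_sets[cls], human, ortho)
        return reports

    reports = _stage("compare", cross_species)

    # --- enrichment over synthetic gene sets -------------------------------
    def enrich():
        universe = sorted(genome.genes["name"])
        rng = np.random.default_rng(derive_seed(config.seed, 500))
        gene_sets = {
            f"SET_{i + 1}": set(rng.choice(universe, size=min(15, len(universe)), replace=False))
            for i in range(5)
        }
        common = sorted({g for rep in reports.values() for g in rep.common_genes})
        if len(common) < 2:
            return pd.DataFrame(columns=["set_name", "set_size", "overlap", "p", "q"])
        return overrepresentation(common, gene_sets, universe)

    enrichment = _stage("enrich", enrich)
    enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # --- event-rate comparison ---------------------------------------------
    human_mut_counts = (
        cohort_frame[cohort_frame["deleterious_flag"].astype(bool)]
        .groupby("tumor_id")
        .size()
        .reindex([p.tumor_id for p in profiles], fill_value=0)
    )
    rates = compare_event_rates(
        per_tumor["deleterious_mutations"].tolist(), human_mut_counts.tolist()
    )

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_mouse_tumors": config.n_mouse_tumors,
        "n_human_tumors": config.n_human_tumors,
        "per_tumor_means": {
            row["metric"]: {"mean": row["mean"], "mean_1dp": row["mean_1dp"], "sem": row["sem"]}
            for row in summary_stats.to_dict("records")
        },
        "mutated_gene_count": mut_table.n_genes,
        "category_fractions": categories,
        "common_gene_reports": {
            cls: {
                "mouse_total": rep.mouse_total,
                "human_total": rep.human_total,
                "n_common": len(rep.common_genes),
                "percentage": rep.percentage,
            }
            for cls, rep in reports.items()
        },
        "deleterious_event_rate_test": rates,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
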