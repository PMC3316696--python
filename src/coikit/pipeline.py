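"""End-to-end barcode assessment pipeline and per-family summary table.

``run_full_pipeline`` chains the stages: QC filtering -> K2p/p distance
matrices and saturation table -> NJ tree with bootstrap supports -> group
monophyly scores -> sister pairs, family thresholds and candidate-species
delimitation -> optional subsampling and mini-barcode experiment series.
All artefacts are plain TSV/newick/JSON files in the output directory, and a
manifest records every tunable plus the seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .delimit import (
    ThresholdTable,
    build_threshold_table,
    candidate_count,
    cluster_unidentified,
    find_sister_pairs,
    mean_interspecific_divergence,
    reference_records,
)
from .distances import distance_matrix, saturation_table
from .experiments import (
    ExperimentConfig,
    run_fragment_series,
    run_subsampling,
    summarize_conditions,
)
from .monophyly import score_all_groups, summarize_scores
from .qc import (
    DEFAULT_MIN_LENGTH,
    DEFAULT_OUTLIER_CUTOFF,
    combine_reports,
    detect_frame,
    divergence_outlier_filter,
    length_filter,
    stop_codon_filter,
)
from .seqio import Alignment, read_fasta_with_metadata
from .trees import bootstrap_support, neighbor_joining, write_newick

logger = logging.getLogger("coikit")

__all__ = ["RunConfig", "run_full_pipeline", "run_qc", "summarize_table2"]


@dataclass
class RunConfig:
    model: str = "k2p"
    min_length: int = DEFAULT_MIN_LENGTH
    outlier_cutoff: float = DEFAULT_OUTLIER_CUTOFF
    min_support_sister: float = 70.0
    support_threshold_high: float = 90.0
    bootstrap_reps: int = 1000
    fractions: tuple[float, ...] = (0.75, 0.50, 0.25, 0.10)
    n_subsets: int = 100
    fragment_lengths: tuple[int, ...] = (450, 300, 200, 100)
    seed: int = 42
    run_subsampling: bool = False
    run_fragments: bool = False


def run_qc(alignment: Alignment, config: RunConfig) -> tuple[Alignment, pd.DataFrame]:
    """Apply the three QC filters; return passing records and the report."""
    length_reports = length_filter(alignment, config.min_length)
    long_enough = [r.id for r, rep in zip(alignment.records, length_reports) if rep.passed]
    reports = [length_reports]
    if len(long_enough) >= 1:
        surviving = alignment.subset(long_enough)
        surviving.frame_offset = detect_frame(surviving)
        stop_reports = stop_codon_filter(surviving)
        reports.append(stop_reports)
        clean_ids = [r.id for r, rep in zip(surviving.records, stop_reports) if rep.passed]
        if len(clean_ids) >= 2:
            clean = surviving.subset(clean_ids)
            dm = distance_matrix(clean, model="k2p")
            reports.append(divergence_outlier_filter(clean, dm, config.outlier_cutoff))
    merged = combine_reports(*reports)
    frame = pd.DataFrame(
        {
            "id": [r.id for r in merged],
            "passed": [r.passed for r in merged],
            "reasons": [";".join(r.reasons) for r in merged],
        }
    )
    passing = [r.id for r in merged if r.passed]
    filtered = alignment.subset(passing)
    filtered.frame_offset = detect_frame(filtered)
    return filtered, frame


def summarize_table2(
    alignment: Alignment,
    matrix_k2p,
    matrix_p,
    thresholds: ThresholdTable,
    per_family_candidates: dict[str, tuple[int, int]],
) -> pd.DataFrame:
    """Per-family divergence/threshold/candidate summary (percentages, 1 dp)."""
    families = sorted({r.family for r in alignment.records})
    rows = []
    for family in families:
        refs = reference_records(alignment, family)
        if len(refs) >= 2:
            mean_k2p = mean_interspecific_divergence(alignment, matrix_k2p, family)
            mean_p = mean_interspecific_divergence(alignment, matrix_p, family)
            mean_str = f"{100 * mean_k2p:.1f}/{100 * mean_p:.1f}"
        else:
            mean_str = "NA"
        t_k2p = thresholds.threshold(family, "k2p")
        t_p = thresholds.threshold(family, "p")
        thr_str = f"{100 * t_k2p:.1f}/{100 * t_p:.1f}" if t_k2p is not None else "NA"
        cmin, cmax = per_family_candidates.get(family, (0, 0))
        rows.append(
            {
                "family": family,
                "n_reference_species": len(refs),
                "mean_divergence_k2p_p_pct": mean_str,
                "n_sister_pairs": thresholds.n_pairs(family),
                "threshold_k2p_p_pct": thr_str,
                "candidates": f"{cmin}" if cmin == cmax else f"{cmin}-{cmax}",
            }
        )
    return pd.DataFrame(rows)


def run_full_pipeline(
    alignment_or_paths,
    config: RunConfig,
    outdir: str | Path,
) -> dict:
    """Run every stage and write artefacts under ``outdir``.

    ``alignment_or_paths`` is either an :class:`Alignment` or a
    ``(fasta_path, tsv_path)`` tuple. Returns a dict of headline results
    (also persisted as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if isinstance(alignment_or_paths, Alignment):
        alignment = alignment_or_paths
    else:
        fasta, meta = alignment_or_paths
        alignment = read_fasta_with_metadata(fasta, meta)

    # -- QC ----------------------------------------------------------------
    filtered, qc_frame = run_qc(alignment, config)
    qc_frame.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    logger.info("QC: %d/%d records pass (%.1fs)", len(filtered), len(alignment), time.time() - t0)

    # -- distances ---------------------------------------------------------
    matrix_k2p = distance_matrix(filtered, model="k2p")
    matrix_p = distance_matrix(filtered, model="p")
    matrix_k2p.write_long_tsv(outdir / "dist_k2p.tsv")
    matrix_p.write_long_tsv(outdir / "dist_p.tsv")
    saturation_table(filtered).to_csv(outdir / "saturation.tsv", sep="\t", index=False)

    # -- tree + bootstrap --------------------------------------------------
    tree = neighbor_joining(matrix_k2p if config.model == "k2p" else matrix_p)
    annotated, _, n_dropped = bootstrap_support(
        filtered, config.model, tree, config.bootstrap_reps, config.seed
    )
    write_newick(annotated, outdir / "tree.nwk")
    logger.info("tree: %d leaves, %d bootstrap replicates dropped", len(filtered), n_dropped)

    # -- monophyly scores --------------------------------------------------
    taxonomy = filtered.taxonomy()
    score_rows = []
    summaries = {}
    for level in ("genus", "family"):
        scores = score_all_groups(annotated, taxonomy, level)
        summaries[level] = summarize_scores(scores, config.support_threshold_high)
        score_rows.extend(
            {
                "group": s.group,
                "level": s.level,
                "n_members": s.n_members,
                "monophyletic": s.monophyletic,
                "support": s.support,
                "excluded": s.excluded,
            }
            for s in scores
        )
    pd.DataFrame(score_rows).to_csv(outdir / "group_scores.tsv", sep="\t", index=False)

    # -- delimitation ------------------------------------------------------
    pairs = find_sister_pairs(
        annotated, filtered, matrix_k2p, matrix_p, config.min_support_sister
    )
    pd.DataFrame([asdict_pair(p) for p in pairs]).to_csv(
        outdir / "sister_pairs.tsv", sep="\t", index=False
    )
    thresholds = build_threshold_table(pairs)
    thr_rows = [
        {
            "family": fam,
            "n_pairs": thresholds.n_pairs(fam),
            "threshold_k2p_pct": round(100 * thresholds.threshold(fam, "k2p"), 1),
            "threshold_p_pct": round(100 * thresholds.threshold(fam, "p"), 1),
        }
        for fam in thresholds.families()
    ]
    pd.DataFrame(thr_rows, columns=["family", "n_pairs", "threshold_k2p_pct", "threshold_p_pct"]).to_csv(
        outdir / "thresholds.tsv", sep="\t", index=False
    )
    lineages_k2p, unresolved_k2p = cluster_unidentified(matrix_k2p, filtered, thresholds)
    lineages_p, unresolved_p = cluster_unidentified(matrix_p, filtered, thresholds)
    cand_rows = [
        {
            "lineage_id": f"{lin.model}_{i}",
            "members": ";".join(lin.members),
            "family": lin.family,
            "model": lin.model,
            "nearest_nominal": lin.nearest_nominal,
            "nn_distance_pct": round(100 * lin.nn_distance, 1),
            "threshold_pct": round(100 * lin.threshold_used, 1),
            "flagged": lin.flagged,
        }
        for i, lin in enumerate(lineages_k2p + lineages_p)
    ]
    pd.DataFrame(cand_rows).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    cmin, cmax, per_family = candidate_count(lineages_k2p, lineages_p)

    table2 = summarize_table2(filtered, matrix_k2p, matrix_p, thresholds, per_family)
    table2.to_csv(outdir / "family_summary.tsv", sep="\t", index=False)

    # -- experiments (optional) -------------------------------------------
    exp_config = ExperimentConfig(
        fractions=config.fractions,
        n_subsets=config.n_subsets,
        fragment_lengths=config.fragment_lengths,
        bootstrap_reps=config.bootstrap_reps,
        seed=config.seed,
        model=config.model,
        support_threshold=config.support_threshold_high,
    )
    if config.run_subsampling:
        results, failures = run_subsampling(filtered, exp_config)
        results.to_csv(outdir / "subsampling_results.tsv", sep="\t", index=False)
        summarize_conditions(results, config.support_threshold_high).to_csv(
            outdir / "subsampling_summary.tsv", sep="\t", index=False
        )
        for f in failures:
            logger.warning("subsampling failure: %s", f)
    if config.run_fragments:
        results, failures = run_fragment_series(filtered, exp_config)
        results.to_csv(outdir / "fragment_results.tsv", sep="\t", index=False)
        summarize_conditions(results, config.support_threshold_high).to_csv(
            outdir / "fragment_summary.tsv", sep="\t", index=False
        )
        for f in failures:
            logger.warning("fragment failure: %s", f)

    summary = {
        "n_records_input": len(alignment),
        "n_records_passing_qc": len(filtered),
        "n_undefined_k2p": matrix_k2p.n_undefined,
        "genus_summary": summaries["genus"],
        "family_summary": summaries["family"],
        "n_sister_pairs": len(pairs),
        "n_families_with_threshold": len(thresholds.families()),
        "unresolved_records": sorted(set(unresolved_k2p) | set(unresolved_p)),
        "candidate_count_min": cmin,
        "candidate_count_max": cmax,
        "elapsed_s": round(time.time() - t0, 2),
    }
    manifest = {"config": asdict(config), "version": __version__, **summary}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def asdict_pair(p) -> dict:
    return {
        "species_a": p.species_a,
        "species_b": p.species_b,
        "family": p.family,
        "support": p.support,
        "distance_k2p_pct": round(100 * p.distance_k2p, 1),
        "distance_p_pct": round(100 * p.distance_p, 1),
    }
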