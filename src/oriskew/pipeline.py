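"""End-to-end orchestration of the origin-analysis stages.

One :func:`run_pipeline` call sequences the full analysis on a synthetic
study: per-line origin definition from replicate peaks, Venn overlap counts
against wild type, initiation-zone clustering, differential classification
and the CommonKO merges, sequence-property comparisons, permutation
colocalization against the annotation track, replication-timing
distribution comparisons, and ergodic rate analysis of the flow sample.
The run is deterministic given the seed; a JSON-serializable summary is
returned and optionally written together with per-stage tables.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ergodic, intervals, permtest, quant, seqprops, timing
from .intervals import IntervalSet
from .synthetic import (
    CELL_LINES,
    KO_LINES,
    SyntheticConfig,
    SyntheticStudy,
    default_gate,
    simulate_study,
    write_study,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Thresholds and scale for one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    fold_threshold: float = 1.5
    n_perm: int = 1000
    normality_alpha: float = 0.05
    max_size_change: float = 0.05
    outdir: Path | None = None
    write_inputs: bool = False

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0 or self.n_perm < 1 or self.normality_alpha <= 0:
            raise ValueError("thresholds must be positive")


def _line_origins(study: SyntheticStudy) -> dict[str, IntervalSet]:
    """Per-line origin sets: base-pair intersection of the two replicates."""
    return {
        line: intervals.intersect_replicates(reps[0], reps[1], mode="region")
        for line, reps in study.peaksets.items()
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic study and summarize the results."""
    seed = config.synthetic.seed
    study = simulate_study(config.synthetic)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        if config.write_inputs:
            write_study(study, outdir / "inputs")

    summary: dict = {"seed": seed, "parameters": {
        "fold_threshold": config.fold_threshold,
        "n_perm": config.n_perm,
        "normality_alpha": config.normality_alpha,
        "max_size_change": config.max_size_change,
    }}

    # --- origins per line -------------------------------------------------
    origins = _line_origins(study)
    summary["origin_counts"] = {line: len(s) for line, s in origins.items()}
    logger.info("origin counts: %s", summary["origin_counts"])

    # --- Venn overlaps vs WT ---------------------------------------------
    venn = {}
    for line in KO_LINES:
        count, wt_only, ko_only = intervals.overlap_count_min(
            origins["WT"], origins[line]
        )
        venn[line] = {"overlap": count, "wt_only": wt_only, f"{line}_only": ko_only}
    summary["venn_min_overlap"] = venn

    # --- initiation zones -------------------------------------------------
    med = intervals.median_interpeak_distance(origins["WT"])
    zones = intervals.cluster_initiation_zones(origins["WT"], med)
    summary["initiation_zones"] = {
        "median_interpeak_bp": med,
        "n_zones": len(zones),
    }

    # --- differential classification and CommonKO sets -------------------
    merged_counts = pd.DataFrame(index=study.counts.index)
    library_sizes = {}
    for line in CELL_LINES:
        cols = [f"{line}_rep1", f"{line}_rep2"]
        total, lib = quant.merge_replicates(
            [study.counts[c].to_numpy() for c in cols],
            [study.library_sizes[c] for c in cols],
        )
        merged_counts[line] = total
        library_sizes[line] = lib
    classified = quant.classify_origins(
        study.truth.origin_set(), merged_counts, library_sizes,
        wt="WT", threshold=config.fold_threshold,
    )
    common_up, common_down = quant.derive_common_sets(classified, KO_LINES)
    summary["common_ko"] = {"up": len(common_up), "down": len(common_down)}
    if outdir:
        classified.to_csv(outdir / "classified_origins.tsv", sep="\t", index=False)
        intervals.write_bed(common_up, outdir / "commonko_up.bed")
        intervals.write_bed(common_down, outdir / "commonko_down.bed")

    # --- sequence properties ---------------------------------------------
    prop_sets = {"WT": origins["WT"], "CommonKO_up": common_up,
                 "CommonKO_down": common_down}
    tables = {
        name: seqprops.property_table(s, study.sequences)
        for name, s in prop_sets.items() if len(s) >= 3
    }
    comparisons = []
    if "WT" in tables:
        for name, tab in tables.items():
            if name == "WT":
                continue
            for col in ("length", "gc_content", "gc_skew", "ta_skew"):
                cmp = seqprops.compare_groups(
                    tables["WT"][col], tab[col], config.normality_alpha
                )
                comparisons.append({
                    "comparison": f"WT_vs_{name}", "property": col,
                    "test": cmp.test, "pvalue": cmp.pvalue,
                    "effect_name": cmp.effect_name, "effect": cmp.effect,
                })
    if comparisons:
        adj = seqprops.bh_adjust([c["pvalue"] for c in comparisons])
        for c, q in zip(comparisons, adj):
            c["adjusted_pvalue"] = float(q)
    summary["property_comparisons"] = comparisons
    if outdir:
        for name, tab in tables.items():
            tab.to_csv(outdir / f"properties_{name}.tsv", sep="\t", index=False)

    # --- permutation colocalization ---------------------------------------
    perm = {}
    track = study.annotations["annotation"]
    for line in ("WT", "ORC2KO"):
        res = permtest.permutation_enrichment(
            origins[line], track, study.layout,
            n_perm=config.n_perm, seed=seed + 1000,
        )
        perm[line] = {
            "observed": res.observed, "fold": res.fold, "zscore": res.zscore,
            "p_greater": res.p_greater, "p_less": res.p_less,
        }
    summary["permutation_enrichment"] = perm

    # --- replication timing ------------------------------------------------
    timing_values = {
        line: timing.assign_origin_timing(origins[line], study.timing)
        for line in CELL_LINES
    }
    background = study.timing.values()
    timing_summary = {}
    for line in CELL_LINES:
        if len(timing_values[line]) == 0:
            continue
        cmp = timing.compare_timing(timing_values[line], background)
        timing_summary[f"{line}_vs_background"] = {
            "ks": cmp.ks_statistic, "ks_p": cmp.ks_pvalue,
            "wasserstein": cmp.wasserstein,
        }
    summary["timing"] = timing_summary

    # --- ergodic rate analysis --------------------------------------------
    gate = default_gate(config.synthetic)
    era = ergodic.estimate_loading_rate(study.flow, gate)
    summary["ergodic"] = {
        "alpha_per_h": era.alpha, "F": era.F,
        "mean_rate_per_h": era.mean_rate,
        "expected_mean_rate_per_h": study.truth.expected_mean_rate,
        "n_empty_bins": era.n_empty_bins,
    }
    if outdir and len(era.W_n):
        era.to_frame().to_csv(outdir / "era_bins.tsv", sep="\t", index=False)

    if outdir:
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
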