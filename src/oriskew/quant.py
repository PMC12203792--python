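"""Read-count quantification over origins and differential classification.

Replicate read counts are merged by summing counts and library sizes before
normalizing to reads per million (RPM).  An origin is called up- or
downregulated in a knockout line when its RPM changes at least ``threshold``
fold (default 1.5) relative to wild type; origins called in the same
direction in all three knockout lines form the CommonKO_up / CommonKO_down
sets.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, common_ko_merge

__all__ = [
    "compute_rpm",
    "merge_replicates",
    "classify_differential",
    "classify_origins",
    "derive_common_sets",
]

UP, DOWN, UNCHANGED = "up", "down", "unchanged"


def compute_rpm(counts: np.ndarray | Sequence[float], library_size: float) -> np.ndarray:
    """RPM_i = counts_i / library_size * 1e6."""
    counts = np.asarray(counts, dtype=float)
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    return counts / library_size * 1e6


def merge_replicates(
    counts: Sequence[np.ndarray | Sequence[float]],
    library_sizes: Sequence[float],
) -> tuple[np.ndarray, float]:
    """Sum replicate counts and replicate library sizes (merge-then-normalize)."""
    if len(counts) != len(library_sizes):
        raise ValueError("counts and library_sizes length mismatch")
    total = np.sum([np.asarray(c, dtype=float) for c in counts], axis=0)
    return total, float(np.sum(library_sizes))


def classify_differential(
    rpm_wt: np.ndarray | Sequence[float],
    rpm_ko: np.ndarray | Sequence[float],
    threshold: float = 1.5,
) -> np.ndarray:
    """Per-origin class in {up, down, unchanged} from aligned RPM vectors.

    Boundary-inclusive: up iff rpm_ko >= threshold * rpm_wt; down iff
    rpm_ko <= rpm_wt / threshold.  A zero WT RPM with positive KO RPM is
    "up"; both zero is "unchanged".
    """
    rpm_wt = np.asarray(rpm_wt, dtype=float)
    rpm_ko = np.asarray(rpm_ko, dtype=float)
    if rpm_wt.shape != rpm_ko.shape:
        raise ValueError("rpm vectors must be aligned on a common origin set")
    if (rpm_wt < 0).any() or (rpm_ko < 0).any():
        raise ValueError("negative RPM")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = np.full(rpm_wt.shape, UNCHANGED, dtype=object)
    both_zero = (rpm_wt == 0) & (rpm_ko == 0)
    up = (rpm_ko >= threshold * rpm_wt) & ~both_zero
    down = (rpm_ko <= rpm_wt / threshold) & ~both_zero
    out[down] = DOWN
    out[up] = UP  # up wins only when both hold is impossible for threshold > 1
    return out


def classify_origins(
    origins: IntervalSet,
    counts: pd.DataFrame,
    library_sizes: Mapping[str, float],
    wt: str = "WT",
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Classify every origin in every KO line against wild type.

    ``counts`` has one row per origin (aligned with ``origins``) and one
    column per cell line holding replicate-merged read counts;
    ``library_sizes`` maps cell line to total mapped reads.  Returns a table
    with chrom/start/end, per-line RPM, and per-KO fold and class columns.
    """
    if len(counts) != len(origins):
        raise ValueError("counts rows must align with origins")
    table = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in origins],
            "start": [iv.start for iv in origins],
            "end": [iv.end for iv in origins],
        }
    )
    for line in counts.columns:
        table[f"rpm_{line}"] = compute_rpm(counts[line].to_numpy(), library_sizes[line])
    wt_rpm = table[f"rpm_{wt}"].to_numpy()
    for line in counts.columns:
        if line == wt:
            continue
        ko_rpm = table[f"rpm_{line}"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(wt_rpm > 0, ko_rpm / wt_rpm, np.inf)
        fold = np.where((wt_rpm == 0) & (ko_rpm == 0), 1.0, fold)
        table[f"fold_{line}"] = fold
        table[f"class_{line}"] = classify_differential(wt_rpm, ko_rpm, threshold)
    return table


def derive_common_sets(
    classified: pd.DataFrame, ko_lines: Sequence[str]
) -> tuple[IntervalSet, IntervalSet]:
    """CommonKO_up / CommonKO_down from a :func:`classify_origins` table.

    Per direction, the per-KO differential origins are intersected across all
    KO lines and mutually overlapping peaks are merged
    (:func:`oriskew.intervals.common_ko_merge`).
    """
    out = []
    for direction in (UP, DOWN):
        per_ko = []
        for line in ko_lines:
            sel = classified[classified[f"class_{line}"] == direction]
            per_ko.append(
                IntervalSet(
                    (
                        GenomicInterval(r.chrom, int(r.start), int(r.end))
                        for r in sel.itertuples()
                    ),
                    label=f"{line}_{direction}",
                )
            )
        merged = common_ko_merge(per_ko)
        merged.label = f"CommonKO_{direction}"
        out.append(merged)
    return out[0], out[1]
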