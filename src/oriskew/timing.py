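"""Replication-timing track processing and distribution comparison.

A timing track is a probe grid with one replication-timing value per probe
(after collapsing repeated measurements to their median).  By convention,
higher values mean earlier replication; the convention is configurable at
the plotting/interpretation layer and does not affect the statistics here.

Origin sets are compared through the distributions of the timing values at
their positions, using the two-sample Kolmogorov-Smirnov statistic and the
1-Wasserstein distance (the area between the two ECDFs; for equal-sized
samples it equals the mean absolute difference of the sorted values).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "TimingTrack",
    "TimingComparison",
    "collapse_probe_medians",
    "filter_size_change",
    "assign_origin_timing",
    "compare_timing",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass
class TimingTrack:
    """Probe positions with replication-timing values.

    ``probes`` columns: chrom, start, end, value, probe_id (optional).
    Sorted by (chrom, start, end); one value per probe.
    """

    probes: pd.DataFrame
    higher_is_earlier: bool = True

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "value"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"timing track missing columns: {sorted(missing)}")
        if len(self.probes) == 0:
            raise ValueError("empty probe grid")
        self.probes = (
            self.probes.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.probes)

    def values(self) -> np.ndarray:
        return self.probes["value"].to_numpy(dtype=float)


@dataclass
class TimingComparison:
    """KS statistic/p and Wasserstein distance between two timing samples."""

    ks_statistic: float
    ks_pvalue: float
    wasserstein: float
    n_x: int
    n_y: int


def collapse_probe_medians(
    measurements: pd.DataFrame | Mapping[str, Sequence[float]],
    positions: pd.DataFrame | None = None,
) -> TimingTrack | pd.Series:
    """Collapse repeated per-probe measurements to one median per probe id.

    ``measurements`` is either a mapping ``probe_id -> values`` or a long
    DataFrame with columns (probe_id, value).  When ``positions`` (columns
    probe_id, chrom, start, end) is given, the medians are joined onto the
    genomic grid and a :class:`TimingTrack` is returned; otherwise a Series
    of medians indexed by probe_id.
    """
    if isinstance(measurements, pd.DataFrame):
        med = measurements.groupby("probe_id")["value"].median()
    else:
        med = pd.Series(
            {pid: float(np.median(vals)) for pid, vals in measurements.items()},
            name="value",
        )
        med.index.name = "probe_id"
    if positions is None:
        return med
    joined = positions.merge(med.rename("value"), on="probe_id", how="inner")
    return TimingTrack(joined[["chrom", "start", "end", "value", "probe_id"]])


def filter_size_change(
    original: GenomicInterval, lifted: GenomicInterval, max_change: float = 0.05
) -> bool:
    """Keep a lifted locus iff its length changed by <= ``max_change``.

    Emulates the post-liftover sanity filter: loci whose size changed beyond
    5% between assemblies are discarded.
    """
    change = abs(len(lifted) - len(original)) / len(original)
    return change <= max_change


def assign_origin_timing(
    origins: IntervalSet, track: TimingTrack, mode: str = "mean"
) -> np.ndarray:
    """Timing value per origin: mean of overlapping probes (default).

    mode="nearest" assigns the value of the probe whose midpoint is closest
    to the origin midpoint on the same chromosome.  Origins overlapping no
    probe (mode="mean") or on probe-free chromosomes (mode="nearest") are
    dropped with a logged count.
    """
    if mode not in ("mean", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    values: list[float] = []
    dropped = 0
    grouped = {c: g for c, g in track.probes.groupby("chrom", sort=False)}
    for iv in origins:
        g = grouped.get(iv.chrom)
        if g is None:
            dropped += 1
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        vals = g["value"].to_numpy(dtype=float)
        if mode == "mean":
            hit = (starts < iv.end) & (ends > iv.start)
            if not hit.any():
                dropped += 1
                continue
            values.append(float(vals[hit].mean()))
        else:
            mids = (starts + ends) / 2
            values.append(float(vals[np.argmin(np.abs(mids - (iv.start + iv.end) / 2))]))
    if dropped:
        logger.info("dropped %d origin(s) without overlapping probes", dropped)
    return np.asarray(values, dtype=float)


def compare_timing(x: Sequence[float], y: Sequence[float]) -> TimingComparison:
    """Two-sample KS test and 1-Wasserstein distance between timing samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty timing sample")
    ks = stats.ks_2samp(x, y, method="asymp" if max(len(x), len(y)) > 500 else "auto")
    wd = stats.wasserstein_distance(x, y)
    return TimingComparison(
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        wasserstein=float(wd),
        n_x=len(x),
        n_y=len(y),
    )


def read_bedgraph(path: str | Path) -> TimingTrack:
    """Read a 4-column bedGraph (chrom, start, end, value) as a TimingTrack."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return TimingTrack(df)


def write_bedgraph(track: TimingTrack, path: str | Path) -> None:
    track.probes[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )
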