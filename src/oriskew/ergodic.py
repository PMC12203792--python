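"""Ergodic rate analysis (ERA) of MCM loading from chromatin flow cytometry.

A single snapshot of an asynchronously cycling, exponentially growing
population contains the full time course of MCM2-7 loading: in steady state
the fraction of cells found at each stage of a one-way progression is
inversely proportional to the speed at which cells traverse that stage.
Gating G1 MCM-positive cells on a (DAPI, MCM) plot and binning their MCM
intensities into 10 equal-width bins gives per-bin loading rates

    W_n = alpha * (2 - F) / f_n,     alpha = ln(2) / doubling_time,

where F is the fraction of all cells that are G1 MCM-positive and f_n the
fraction of gated cells in bin n.  The mean loading rate is the arithmetic
mean of the per-bin rates.  W_n is in 1/hour and is invariant to rescaling
the MCM intensity axis (only the bin occupancies enter), so rates are
comparable across stains and instruments but carry no absolute
intensity-per-hour unit.

The module also provides two back-of-envelope licensing estimators: the
number of licensed origins implied by an inter-origin fiber distance, and a
molecules-per-cell count implied by a western-blot signal fraction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FlowSample",
    "GateConfig",
    "ErgodicResult",
    "gate_g1_mcm",
    "bin_mcm",
    "loading_rates",
    "estimate_loading_rate",
    "ploidy_fractions",
    "estimate_licensed_origins",
    "molecules_from_fraction",
    "read_flow_csv",
]


@dataclass
class FlowSample:
    """Per-event (DAPI, MCM) fluorescence intensities in arbitrary units."""

    dapi: np.ndarray
    mcm: np.ndarray
    doubling_time: float  # hours
    label: str = ""

    def __post_init__(self) -> None:
        self.dapi = np.asarray(self.dapi, dtype=float)
        self.mcm = np.asarray(self.mcm, dtype=float)
        if self.dapi.shape != self.mcm.shape:
            raise ValueError("dapi and mcm must have the same length")
        if self.doubling_time <= 0:
            raise ValueError("doubling_time must be > 0")
        if (self.dapi < 0).any() or (self.mcm < 0).any():
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.dapi)

    @property
    def alpha(self) -> float:
        """Population growth rate ln(2)/doubling_time, 1/hour."""
        return float(np.log(2) / self.doubling_time)


@dataclass
class GateConfig:
    """Rectangular G1 MCM-positive gate.

    ``dapi_window`` brackets the 2N DAPI peak; ``mcm_threshold`` is the MCM
    positivity floor taken from a secondary-antibody-only control;
    ``mcm_high`` optionally closes the gate from above, as a hand-drawn flow
    gate does (None = open).
    """

    dapi_window: tuple[float, float]
    mcm_threshold: float
    mcm_high: float | None = None

    def __post_init__(self) -> None:
        low, high = self.dapi_window
        if not low < high:
            raise ValueError("dapi window must satisfy low < high")
        if self.mcm_threshold < 0:
            raise ValueError("mcm_threshold must be >= 0")
        if self.mcm_high is not None and self.mcm_high <= self.mcm_threshold:
            raise ValueError("mcm_high must exceed mcm_threshold")


@dataclass
class ErgodicResult:
    """Gate fraction, bin occupancies, per-bin rates and mean rate."""

    alpha: float  # 1/h
    F: float  # gated fraction of all events
    f_n: np.ndarray  # occupancy of retained (nonempty) bins, sums to 1
    W_n: np.ndarray  # 1/h, per retained bin
    mean_rate: float  # 1/h
    n_bins: int
    n_empty_bins: int
    bin_edges: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"f_n": self.f_n, "W_n": self.W_n})


def gate_g1_mcm(sample: FlowSample, gate: GateConfig) -> tuple[np.ndarray, float]:
    """Select G1 MCM-positive events; return their MCM values and F.

    F = gated events / total events.  MCM positivity is strict
    (mcm > threshold); the DAPI window is inclusive.
    """
    if len(sample) == 0:
        raise ValueError("zero total events")
    low, high = gate.dapi_window
    sel = (
        (sample.dapi >= low)
        & (sample.dapi <= high)
        & (sample.mcm > gate.mcm_threshold)
    )
    if gate.mcm_high is not None:
        sel &= sample.mcm <= gate.mcm_high
    selected = sample.mcm[sel]
    return selected, float(len(selected) / len(sample))


def bin_mcm(mcm: np.ndarray, n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bin occupancies of gated MCM values.

    Bins span [min, max] of the data (as MATLAB ``histogram`` with
    ``BinLimits``); the rightmost bin is closed, so the maximum value counts
    in bin ``n_bins``.  Returns (f_n for all bins including empty ones,
    bin_edges).
    """
    mcm = np.asarray(mcm, dtype=float)
    if len(mcm) < 2:
        raise ValueError("need >= 2 gated events")
    lo, hi = float(mcm.min()), float(mcm.max())
    if lo == hi:
        raise ValueError("degenerate range: all MCM values equal")
    counts, edges = np.histogram(mcm, bins=n_bins, range=(lo, hi))
    return counts / len(mcm), edges


def loading_rates(
    f_n: Sequence[float],
    alpha: float,
    F: float,
    drop_empty: bool = True,
) -> tuple[np.ndarray, float]:
    """Per-bin rates W_n = alpha*(2 - F)/f_n and their arithmetic mean.

    Empty bins (f_n = 0) are excluded from the mean with a logged count by
    default; ``drop_empty=False`` reproduces the literal division, yielding
    infinite rates and a non-finite mean when any bin is empty.
    """
    f = np.asarray(f_n, dtype=float)
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if not 0 <= F <= 1:
        raise ValueError("F must lie in [0, 1]")
    if drop_empty:
        empty = int((f == 0).sum())
        if empty:
            logger.warning("excluding %d empty bin(s) from the mean rate", empty)
        f = f[f > 0]
        if len(f) == 0:
            raise ValueError("all bins empty")
    with np.errstate(divide="ignore"):
        w = alpha * (2 - F) / f
    return w, float(w.mean())


def estimate_loading_rate(
    sample: FlowSample, gate: GateConfig, n_bins: int = 10
) -> ErgodicResult:
    """Full ERA pipeline: gate, bin, rate.

    When no event passes the gate the loading rate is reported as 0 (nothing
    is being loaded above the control threshold).
    """
    mcm, F = gate_g1_mcm(sample, gate)
    alpha = sample.alpha
    if len(mcm) < 2:
        logger.warning("no MCM-positive G1 population: mean rate reported as 0")
        return ErgodicResult(
            alpha=alpha, F=F, f_n=np.array([]), W_n=np.array([]),
            mean_rate=0.0, n_bins=n_bins, n_empty_bins=n_bins,
        )
    f_all, edges = bin_mcm(mcm, n_bins=n_bins)
    w, mean_rate = loading_rates(f_all, alpha, F)
    retained = f_all[f_all > 0]
    return ErgodicResult(
        alpha=alpha, F=F, f_n=retained, W_n=w, mean_rate=mean_rate,
        n_bins=n_bins, n_empty_bins=int((f_all == 0).sum()), bin_edges=edges,
    )


def ploidy_fractions(
    sample: FlowSample,
    g1_max: float,
    g2_min: float,
    g2_max: float,
) -> dict[str, float]:
    """Fractions of events in G1, S, G2 and >G2 by DAPI thresholds.

    G1: dapi <= g1_max; S: g1_max < dapi < g2_min; G2: g2_min <= dapi <=
    g2_max; >G2 (re-replication): dapi > g2_max.  Fractions sum to 1.
    """
    if not g1_max < g2_min <= g2_max:
        raise ValueError("require g1_max < g2_min <= g2_max")
    if len(sample) == 0:
        raise ValueError("zero total events")
    d = sample.dapi
    n = len(d)
    return {
        "G1": float((d <= g1_max).sum() / n),
        "S": float(((d > g1_max) & (d < g2_min)).sum() / n),
        "G2": float(((d >= g2_min) & (d <= g2_max)).sum() / n),
        ">G2": float((d > g2_max).sum() / n),
    }


def estimate_licensed_origins(genome_size: float, inter_origin_distance: float) -> int:
    """Licensed-origin count implied by a mean inter-origin fiber distance.

    E.g. a ~40 kb spacing on a 6e9 bp diploid genome implies ~150,000
    licensed origins.
    """
    if genome_size <= 0 or inter_origin_distance <= 0:
        raise ValueError("genome_size and inter_origin_distance must be > 0")
    return int(round(genome_size / inter_origin_distance))


def molecules_from_fraction(reference_copies: float, fraction: float) -> int:
    """Molecules per cell implied by a signal fraction of a reference protein.

    E.g. a band at 0.23% of a 150,000-copies/cell reference corresponds to
    345 molecules per cell.
    """
    if reference_copies < 0 or fraction < 0:
        raise ValueError("reference_copies and fraction must be >= 0")
    return int(round(reference_copies * fraction))


def read_flow_csv(
    path: str | Path, doubling_time: float, label: str = ""
) -> FlowSample:
    """Read a per-event CSV with columns ``dapi`` and ``mcm``."""
    df = pd.read_csv(path)
    missing = {"dapi", "mcm"} - set(df.columns)
    if missing:
        raise ValueError(f"flow CSV missing columns: {sorted(missing)}")
    return FlowSample(
        dapi=df["dapi"].to_numpy(float),
        mcm=df["mcm"].to_numpy(float),
        doubling_time=doubling_time,
        label=label or Path(path).stem,
    )
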