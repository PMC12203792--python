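"""Synthetic study generator with known ground truth.

Emulates every input the origin-analysis pipeline consumes, at desk scale:

* a small multi-chromosome genome with controllable background GC content,
  planted GC skew and a planted short tandem repeat at designated origins,
  and randomly masked blocks;
* four cell lines (one wild type, three knockouts) whose replicate peak sets
  share a core of origins, with per-knockout line-specific gains/losses and
  planted fold changes in read counts (Poisson, with per-replicate library
  factors);
* annotation tracks enriched at origins with configurable odds;
* a replication-timing probe grid in which origins are biased toward early
  replication by a configurable shift;
* a flow-cytometry snapshot of an exponentially growing population loading
  MCM during G1 at a known linear rate, with the steady-state age density
  g(a) = (2 ln2 / T) 2^(-a/T) on [0, T].

Every generator is a pure function of its configuration: identical seed and
config give bit-identical outputs.  The ground truth needed to score
downstream recovery (origin labels, planted folds, the model-implied mean
MCM loading rate) is emitted alongside the data.
"""
from __future__ import annotations

import json
import textwrap
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ergodic import ErgodicResult, FlowSample, GateConfig
from .intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    merge_overlapping,
    write_bed,
    write_chrom_sizes,
)
from .timing import TimingTrack, write_bedgraph

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "make_layout",
    "generate_genome",
    "generate_peaksets",
    "generate_annotations",
    "generate_timing_track",
    "generate_liftover_pairs",
    "generate_flow_sample",
    "default_gate",
    "expected_ergodic",
    "SyntheticStudy",
    "simulate_study",
    "write_study",
]

CELL_LINES = ("WT", "ORC1KO", "ORC2KO", "ORC5KO")
KO_LINES = CELL_LINES[1:]

# fixed per-stage streams so each generator is independently reproducible
_STREAMS = {"mask": 0, "origins": 1, "genome": 2, "peaks": 3,
            "annotations": 4, "timing": 5, "flow": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream])))


@dataclass
class SyntheticConfig:
    """All simulation knobs, with defaults set to the study conditions.

    Genome and peak-set scale is deliberately desk-sized (a few megabases,
    hundreds of origins); rates and fractions mirror an HCT116-like cell
    line (doubling time 19.5 h) and SNS-seq-like peak geometry.
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    mask_fraction: float = 0.05
    gc_content_bg: float = 0.41
    # origins
    n_core_origins: int = 200
    origin_length_mean: float = 1_000.0
    origin_length_sd: float = 300.0
    frac_line_specific: float = 0.10
    n_planted_up: int = 20
    n_planted_down: int = 20
    fold_change_up: float = 2.0
    fold_change_down: float = 0.5
    planted_gc_skew: float = 0.3
    planted_repeat: str = "ATCC"
    planted_repeat_copies: int = 8
    # read counts
    reads_per_origin_mean: float = 100.0
    boundary_jitter_sd: float = 50.0
    library_factor_sd: float = 0.1  # lognormal sd of per-replicate depth
    reads_in_peaks_fraction: float = 0.1
    # annotations
    annotation_enrichment: float = 5.0  # odds of landing on an origin vs background
    n_annotations: int = 300
    annotation_length: int = 500
    # timing
    probe_spacing: int = 10_000
    probe_length: int = 500
    timing_shift: float = 1.0  # higher = earlier
    # flow cytometry
    doubling_time: float = 19.5  # hours
    g1_fraction: float = 0.40
    s_fraction: float = 0.40
    licensing_fraction: float = 0.8  # fraction of G1 by which loading completes
    mcm_load_rate: float = 10.0  # AU/hour during the loading ramp
    mcm_background: float = 5.0  # AU, nonspecific staining
    dapi_g1: float = 100.0  # AU at 2N DNA content
    noise_cv: float = 0.05
    dapi_cv: float = 0.03
    n_events: int = 50_000

    def __post_init__(self) -> None:
        fracs = {
            "mask_fraction": self.mask_fraction,
            "gc_content_bg": self.gc_content_bg,
            "frac_line_specific": self.frac_line_specific,
            "g1_fraction": self.g1_fraction,
            "s_fraction": self.s_fraction,
            "licensing_fraction": self.licensing_fraction,
            "reads_in_peaks_fraction": self.reads_in_peaks_fraction,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.g1_fraction:
            raise ValueError("g1_fraction must be in (0, 1)")
        if self.g1_fraction + self.s_fraction >= 1:
            raise ValueError("g1_fraction + s_fraction must be < 1")
        positive = {
            "n_chroms": self.n_chroms,
            "chrom_length": self.chrom_length,
            "origin_length_mean": self.origin_length_mean,
            "doubling_time": self.doubling_time,
            "n_events": self.n_events,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name, v in {
            "n_core_origins": self.n_core_origins,
            "n_planted_up": self.n_planted_up,
            "n_planted_down": self.n_planted_down,
        }.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_planted_up + self.n_planted_down > self.n_core_origins:
            raise ValueError("planted origins exceed the core set")
        if abs(self.planted_gc_skew) > 1:
            raise ValueError("planted_gc_skew must lie in [-1, 1]")
        if self.mcm_load_rate < 0 or self.mcm_background < 0:
            raise ValueError("rates and intensities must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth emitted with a synthetic study.

    ``origins`` has one row per origin: chrom/start/end, origin_id, label
    (one of shared, planted_up, planted_down, specific_<line>), the true
    per-knockout fold change, and a presence flag per cell line.  Scalars
    record the planted annotation odds and the flow-model truth.
    """

    origins: pd.DataFrame
    annotation_enrichment: float
    mcm_load_rate: float
    expected_mean_rate: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "origins": self.origins.to_dict(orient="list"),
            "annotation_enrichment": self.annotation_enrichment,
            "mcm_load_rate": self.mcm_load_rate,
            "expected_mean_rate": self.expected_mean_rate,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        return cls(
            origins=pd.DataFrame(payload["origins"]),
            annotation_enrichment=payload["annotation_enrichment"],
            mcm_load_rate=payload["mcm_load_rate"],
            expected_mean_rate=payload["expected_mean_rate"],
        )

    def origin_set(self, label: str | None = None) -> IntervalSet:
        df = self.origins
        if label is not None:
            df = df[df["label"] == label]
        return IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=str(r.origin_id))
            for r in df.itertuples()
        )


# ---------------------------------------------------------------------------
# Genome and origins


def make_layout(config: SyntheticConfig) -> GenomeLayout:
    """Chromosome table plus random masked blocks covering ~mask_fraction."""
    rng = _rng(config.seed, "mask")
    sizes = {f"chrSim{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    masked: list[GenomicInterval] = []
    block = max(1000, config.chrom_length // 200)
    for chrom, size in sizes.items():
        target = int(config.mask_fraction * size)
        covered = 0
        while covered < target:
            length = min(block, target - covered) or 1
            start = int(rng.integers(0, size - length + 1))
            masked.append(GenomicInterval(chrom, start, start + length))
            covered += length
    return GenomeLayout(sizes, merge_overlapping(IntervalSet(masked)))


def _place_origins(config: SyntheticConfig, layout: GenomeLayout,
                   n: int, rng: np.random.Generator) -> list[GenomicInterval]:
    """Place n non-overlapping origin intervals in unmasked gaps."""
    gaps = layout.unmasked_gaps()
    gap_lens = np.array([g[2] - g[1] for g in gaps], dtype=np.int64)
    lengths = np.maximum(
        rng.normal(config.origin_length_mean, config.origin_length_sd, n), 100
    ).astype(np.int64)
    if lengths.sum() > gap_lens.sum():
        raise ValueError(
            "total origin footprint exceeds the unmasked genome; "
            "increase chrom_length or reduce n_core_origins"
        )
    placed: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for length in lengths:
        for _attempt in range(1000):
            valid = np.maximum(gap_lens - length + 1, 0)
            total = int(valid.sum())
            if total == 0:
                raise ValueError(f"origin of length {length} exceeds every gap")
            draw = int(rng.integers(0, total))
            gi = int(np.searchsorted(np.cumsum(valid), draw, side="right"))
            off = draw - int(np.cumsum(valid)[gi] - valid[gi])
            chrom = gaps[gi][0]
            start = gaps[gi][1] + off
            end = start + int(length)
            if all(not (start < e and s < end) for s, e in occupied.get(chrom, ())):
                occupied.setdefault(chrom, []).append((start, end))
                placed.append(GenomicInterval(chrom, int(start), int(end)))
                break
        else:
            raise ValueError("could not place origins without overlap")
    return sorted(placed, key=GenomicInterval.sort_key)


def simulate_origins(config: SyntheticConfig,
                     layout: GenomeLayout | None = None) -> TruthRecord:
    """Deterministic origin truth table for a configuration.

    Core origins are shared by all four lines; ``n_planted_up`` /
    ``n_planted_down`` of them carry planted fold changes in every knockout;
    each knockout additionally loses and gains ``frac_line_specific *
    n_core_origins`` origins (losses never touch planted origins).
    """
    layout = layout or make_layout(config)
    rng = _rng(config.seed, "origins")
    n_spec = int(round(config.frac_line_specific * config.n_core_origins))
    total = config.n_core_origins + 3 * n_spec
    placed = _place_origins(config, layout, total, rng)
    order = rng.permutation(total)
    core_idx = order[: config.n_core_origins]
    gain_idx = {
        line: order[config.n_core_origins + i * n_spec:
                    config.n_core_origins + (i + 1) * n_spec]
        for i, line in enumerate(KO_LINES)
    }
    labels = np.array(["shared"] * total, dtype=object)
    up_idx = core_idx[: config.n_planted_up]
    down_idx = core_idx[config.n_planted_up:
                        config.n_planted_up + config.n_planted_down]
    labels[up_idx] = "planted_up"
    labels[down_idx] = "planted_down"
    for line, idx in gain_idx.items():
        labels[idx] = f"specific_{line}"

    presence = {line: np.zeros(total, dtype=bool) for line in CELL_LINES}
    presence["WT"][core_idx] = True
    lossable = np.array(
        [i for i in core_idx if labels[i] == "shared"], dtype=np.int64
    )
    for line in KO_LINES:
        pres = np.zeros(total, dtype=bool)
        pres[core_idx] = True
        losses = rng.choice(lossable, size=min(n_spec, len(lossable)),
                            replace=False) if n_spec else np.array([], dtype=np.int64)
        pres[losses] = False
        pres[gain_idx[line]] = True
        presence[line] = pres

    fold = np.ones(total)
    fold[up_idx] = config.fold_change_up
    fold[down_idx] = config.fold_change_down
    df = pd.DataFrame(
        {
            "origin_id": [f"ori{i:05d}" for i in range(total)],
            "chrom": [iv.chrom for iv in placed],
            "start": [iv.start for iv in placed],
            "end": [iv.end for iv in placed],
            "label": labels,
            "true_fold": fold,
            **{f"in_{line}": presence[line] for line in CELL_LINES},
        }
    )
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return TruthRecord(
        origins=df,
        annotation_enrichment=config.annotation_enrichment,
        mcm_load_rate=config.mcm_load_rate,
    )


def generate_genome(
    config: SyntheticConfig, truth: TruthRecord | None = None,
    layout: GenomeLayout | None = None,
) -> tuple[dict[str, str], GenomeLayout]:
    """Random genome with planted composition signals at designated origins.

    Background bases are i.i.d. with P(G) = P(C) = gc/2.  Planted-up origins
    carry a positive GC skew (G over C on the plus strand) and the planted
    tandem repeat at their center; planted-down origins carry the opposite
    skew.
    """
    layout = layout or make_layout(config)
    truth = truth or simulate_origins(config, layout)
    rng = _rng(config.seed, "genome")
    gc = config.gc_content_bg
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    seqs: dict[str, np.ndarray] = {}
    for chrom, size in layout.chrom_sizes.items():
        seqs[chrom] = alphabet[rng.choice(4, size=size, p=probs)].copy()

    def skew_probs(skew: float) -> np.ndarray:
        return np.array(
            [(1 - gc) / 2, gc * (1 - skew) / 2, gc * (1 + skew) / 2, (1 - gc) / 2]
        )

    for row in truth.origins.itertuples():
        if row.label not in ("planted_up", "planted_down"):
            continue
        skew = config.planted_gc_skew if row.label == "planted_up" else -config.planted_gc_skew
        window = alphabet[
            rng.choice(4, size=row.end - row.start, p=skew_probs(skew))
        ]
        seqs[row.chrom][row.start:row.end] = window
        if row.label == "planted_up" and config.planted_repeat_copies > 0:
            motif = config.planted_repeat * config.planted_repeat_copies
            mid = (row.start + row.end) // 2 - len(motif) // 2
            mid = max(row.start, min(mid, row.end - len(motif)))
            if mid + len(motif) <= row.end:
                seqs[row.chrom][mid:mid + len(motif)] = np.frombuffer(
                    motif.encode(), dtype="S1"
                )
    # mask regions as N
    for iv in layout.masked:
        seqs[iv.chrom][iv.start:iv.end] = b"N"
    return {c: s.tobytes().decode() for c, s in seqs.items()}, layout


# ---------------------------------------------------------------------------
# Peak sets and counts


def _jitter_interval(iv_row, rng: np.random.Generator, sd: float,
                     chrom_len: int) -> GenomicInterval:
    start = int(round(iv_row.start + rng.normal(0, sd))) if sd else iv_row.start
    end = int(round(iv_row.end + rng.normal(0, sd))) if sd else iv_row.end
    start = max(0, min(start, chrom_len - 2))
    end = max(start + 1, min(end, chrom_len))
    return GenomicInterval(iv_row.chrom, start, end, name=str(iv_row.origin_id))


def generate_peaksets(
    config: SyntheticConfig, layout: GenomeLayout | None = None,
) -> tuple[dict[str, list[IntervalSet]], pd.DataFrame, dict[str, float], TruthRecord]:
    """Replicate peak sets, per-origin read counts and library sizes.

    Returns ``(peaksets, counts, library_sizes, truth)``: two replicate
    IntervalSets per cell line with jittered boundaries; a counts table with
    one row per origin and one column per (line, replicate) pair, Poisson
    around ``reads_per_origin_mean x true fold x library factor``; library
    sizes per (line, replicate) assuming ``reads_in_peaks_fraction`` of the
    library falls in peaks.
    """
    layout = layout or make_layout(config)
    truth = simulate_origins(config, layout)
    rng = _rng(config.seed, "peaks")
    df = truth.origins
    peaksets: dict[str, list[IntervalSet]] = {}
    counts = pd.DataFrame(index=df["origin_id"])
    library_sizes: dict[str, float] = {}
    for line in CELL_LINES:
        present = df[df[f"in_{line}"]]
        reps = []
        for rep in (1, 2):
            factor = float(rng.lognormal(0, config.library_factor_sd))
            ivs = [
                _jitter_interval(r, rng, config.boundary_jitter_sd,
                                 layout.chrom_sizes[r.chrom])
                for r in present.itertuples()
            ]
            reps.append(IntervalSet(ivs, label=f"{line}_rep{rep}"))
            mean = (
                config.reads_per_origin_mean
                * np.where(df[f"in_{line}"], 1.0, 0.0)
                * np.where(line == "WT", 1.0, df["true_fold"].to_numpy())
                * factor
            )
            col = rng.poisson(mean).astype(np.int64)
            counts[f"{line}_rep{rep}"] = col
            library_sizes[f"{line}_rep{rep}"] = float(
                col.sum() / config.reads_in_peaks_fraction
            )
        peaksets[line] = reps
    return peaksets, counts, library_sizes, truth


# ---------------------------------------------------------------------------
# Annotations


def generate_annotations(
    config: SyntheticConfig,
    layout: GenomeLayout,
    origins: IntervalSet,
    names: Sequence[str] = ("annotation",),
) -> dict[str, IntervalSet]:
    """Annotation tracks placed on origins with configured odds.

    With enrichment odds w, each interval is origin-targeted with
    probability (w - 1) rho / ((w - 1) rho + 1) where rho is the origin
    fraction of the unmasked genome, and uniform over the unmasked genome
    otherwise; odds = 1 therefore reduces exactly to the uniform null and
    odds -> infinity forces every interval onto an origin.  Tracks avoid
    masked regions.
    """
    rng = _rng(config.seed, "annotations")
    gaps = layout.unmasked_gaps()
    gap_starts = np.array([g[1] for g in gaps])
    gap_lens = np.array([g[2] - g[1] for g in gaps])
    unmasked = int(gap_lens.sum())
    rho = origins.total_bases() / unmasked if unmasked else 0.0
    w = config.annotation_enrichment
    if w < 0:
        raise ValueError("annotation_enrichment must be >= 0")
    if np.isinf(w):
        p_target = 1.0 if len(origins) else 0.0
    else:
        p_target = (w - 1) * rho / ((w - 1) * rho + 1) if len(origins) else 0.0
        p_target = min(max(p_target, 0.0), 1.0)
    length = config.annotation_length
    origin_list = list(origins)
    mask_map = layout.masked.by_chrom()

    def hits_mask(chrom: str, start: int, end: int) -> bool:
        if chrom not in mask_map:
            return False
        m_starts, m_ends = mask_map[chrom]
        return bool(((m_starts < end) & (m_ends > start)).any())

    valid = np.maximum(gap_lens - length + 1, 0)
    cum = np.cumsum(valid)
    total = int(valid.sum())
    tracks: dict[str, IntervalSet] = {}
    for name in names:
        ivs: list[GenomicInterval] = []
        while len(ivs) < config.n_annotations:
            if origin_list and rng.random() < p_target:
                o = origin_list[int(rng.integers(0, len(origin_list)))]
                lo = max(0, o.start - length + 1)
                start = int(rng.integers(lo, o.end))
                chrom = o.chrom
            else:
                draw = int(rng.integers(0, total))
                gi = int(np.searchsorted(cum, draw, side="right"))
                start = int(gap_starts[gi] + draw - (cum[gi] - valid[gi]))
                chrom = gaps[gi][0]
            end = start + length
            if end > layout.chrom_sizes[chrom] or hits_mask(chrom, start, end):
                continue
            ivs.append(GenomicInterval(chrom, start, end))
        tracks[name] = IntervalSet(ivs, label=name)
    return tracks


# ---------------------------------------------------------------------------
# Replication timing


def generate_timing_track(
    config: SyntheticConfig, layout: GenomeLayout, origins: IntervalSet
) -> TimingTrack:
    """Probe grid with standard-normal timing plus an early shift at origins.

    Values follow the higher-is-earlier convention: probes overlapping an
    origin get ``timing_shift`` added to their background N(0, 1) value.
    """
    rng = _rng(config.seed, "timing")
    rows = []
    omap = origins.by_chrom()
    for chrom, size in layout.chrom_sizes.items():
        starts = np.arange(0, size - config.probe_length, config.probe_spacing)
        if len(starts) == 0:
            continue
        ends = starts + config.probe_length
        values = rng.normal(0.0, 1.0, size=len(starts))
        if chrom in omap:
            o_starts, o_ends = omap[chrom]
            idx = np.searchsorted(o_starts, ends, side="left")
            prev_end = np.where(idx > 0, o_ends[np.maximum(idx - 1, 0)], -1)
            hit = (idx > 0) & (prev_end > starts)
            # origins may be shorter than probe spacing; also check containment
            for j in range(len(starts)):
                if not hit[j]:
                    hit[j] = bool(
                        ((o_starts < ends[j]) & (o_ends > starts[j])).any()
                    )
            values = values + config.timing_shift * hit
        for s, e, v in zip(starts, ends, values):
            rows.append((chrom, int(s), int(e), float(v)))
    if not rows:
        raise ValueError("empty probe grid: chromosomes shorter than probe spacing")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    df["probe_id"] = [f"probe{i:06d}" for i in range(len(df))]
    return TimingTrack(df)


def generate_liftover_pairs(
    config: SyntheticConfig, origins: IntervalSet, frac_bad: float = 0.1
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """(original, lifted) interval pairs with small length perturbations.

    A fraction ``frac_bad`` of pairs get a length change beyond 5% so the
    post-liftover size filter has something to discard.
    """
    rng = _rng(config.seed, "timing")
    pairs = []
    for iv in origins:
        bad = rng.random() < frac_bad
        rel = rng.uniform(0.06, 0.2) if bad else rng.uniform(0.0, 0.04)
        delta = int(round(len(iv) * rel)) * (1 if rng.random() < 0.5 else -1)
        new_end = max(iv.start + 1, iv.end + delta)
        pairs.append((iv, GenomicInterval(iv.chrom, iv.start, new_end)))
    return pairs


# ---------------------------------------------------------------------------
# Flow cytometry


def _mcm_signal(age: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Noise-free MCM intensity as a function of cell age (hours)."""
    T = config.doubling_time
    g1 = config.g1_fraction * T
    s = config.s_fraction * T
    load_end = config.licensing_fraction * g1
    peak = config.mcm_background + config.mcm_load_rate * load_end
    m = np.empty_like(age)
    in_g1 = age < g1
    m[in_g1] = config.mcm_background + config.mcm_load_rate * np.minimum(
        age[in_g1], load_end
    )
    in_s = (age >= g1) & (age < g1 + s)
    m[in_s] = config.mcm_background + (peak - config.mcm_background) * (
        1 - (age[in_s] - g1) / s
    )
    m[age >= g1 + s] = config.mcm_background
    return m


def _dapi_signal(age: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Noise-free DAPI intensity: 2N in G1, ramping to 4N through S."""
    T = config.doubling_time
    g1 = config.g1_fraction * T
    s = config.s_fraction * T
    d = np.full_like(age, config.dapi_g1)
    in_s = (age >= g1) & (age < g1 + s)
    d[in_s] = config.dapi_g1 * (1 + (age[in_s] - g1) / s)
    d[age >= g1 + s] = 2 * config.dapi_g1
    return d


def generate_flow_sample(config: SyntheticConfig) -> FlowSample:
    """Snapshot of an exponentially growing population loading MCM in G1.

    Ages are drawn from the steady-state age density of exponential growth,
    g(a) = (2 ln2 / T) 2^(-a/T) on [0, T] (young cells outnumber old ones
    two-to-one at the extremes).  G1 cells load MCM linearly at
    ``mcm_load_rate`` until licensing completes at ``licensing_fraction`` of
    G1, then hold a plateau; MCM leaves chromatin linearly through S.
    Multiplicative Gaussian noise with CVs ``noise_cv`` (MCM) and ``dapi_cv``
    (DAPI) is applied and intensities are clipped at 0.
    """
    rng = _rng(config.seed, "flow")
    T = config.doubling_time
    u = rng.uniform(0, 1, size=config.n_events)
    age = -T * np.log2(1 - u / 2)
    mcm = _mcm_signal(age, config) * (1 + config.noise_cv * rng.standard_normal(config.n_events))
    dapi = _dapi_signal(age, config) * (1 + config.dapi_cv * rng.standard_normal(config.n_events))
    return FlowSample(
        dapi=np.clip(dapi, 0, None),
        mcm=np.clip(mcm, 0, None),
        doubling_time=T,
        label="synthetic",
    )


def default_gate(config: SyntheticConfig) -> GateConfig:
    """Rectangular G1 MCM-positive gate matched to the generator.

    DAPI window brackets the 2N peak at +/- 5 CVs; the MCM floor sits 5 CVs
    above the nonspecific background (emulating a secondary-antibody-only
    control) and the ceiling 3 CVs above the licensing plateau, as a
    hand-drawn gate around the G1 MCM-positive cloud would.
    """
    d = config.dapi_g1
    window = (d * (1 - 5 * config.dapi_cv), d * (1 + 5 * config.dapi_cv))
    floor = config.mcm_background * (1 + 5 * config.noise_cv)
    peak = config.mcm_background + config.mcm_load_rate * (
        config.licensing_fraction * config.g1_fraction * config.doubling_time
    )
    ceiling = max(peak * (1 + 3 * config.noise_cv), floor * 1.5 + 1e-9)
    return GateConfig(dapi_window=window, mcm_threshold=floor, mcm_high=ceiling)


def expected_ergodic(
    config: SyntheticConfig, gate: GateConfig | None = None, n_bins: int = 10,
    n_quad: int = 4000,
) -> ErgodicResult:
    """Analytic (infinite-population) value of the ergodic rate estimate.

    Integrates the generative model — steady-state age density, the
    noise-free signal curves and the multiplicative noise — over a fine age
    grid to obtain the exact gate fraction F and bin occupancies f_n on the
    gate's MCM span, then applies W_n = alpha (2 - F) / f_n.  Serves as the
    ground-truth oracle for parameter-recovery checks; sampling, gating and
    data-driven bin limits are the only things it does not model.
    """
    gate = gate or default_gate(config)
    T = config.doubling_time
    alpha = float(np.log(2) / T)
    a = np.linspace(0, T, n_quad)
    dens = (2 * np.log(2) / T) * np.power(2.0, -a / T)
    m = _mcm_signal(a, config)
    d = _dapi_signal(a, config)
    sd_m = np.maximum(m * config.noise_cv, 1e-12)
    sd_d = np.maximum(d * config.dapi_cv, 1e-12)
    lo, hi = gate.dapi_window
    p_dapi = stats.norm.cdf((hi - d) / sd_d) - stats.norm.cdf((lo - d) / sd_d)
    top = gate.mcm_high if gate.mcm_high is not None else float(np.max(m) * 2)
    edges = np.linspace(gate.mcm_threshold, top, n_bins + 1)
    # P(mcm in (edge_k, edge_{k+1}]) per age, times P(dapi in window)
    cdf = stats.norm.cdf((edges[:, None] - m[None, :]) / sd_m[None, :])
    bin_mass = np.trapezoid(dens * p_dapi * (cdf[1:] - cdf[:-1]), a, axis=1)
    F = float(bin_mass.sum())
    if F <= 0:
        return ErgodicResult(alpha=alpha, F=0.0, f_n=np.array([]),
                             W_n=np.array([]), mean_rate=0.0,
                             n_bins=n_bins, n_empty_bins=n_bins, bin_edges=edges)
    f_n = bin_mass / F
    keep = f_n > 0
    W = alpha * (2 - F) / f_n[keep]
    return ErgodicResult(
        alpha=alpha, F=F, f_n=f_n[keep], W_n=W, mean_rate=float(W.mean()),
        n_bins=n_bins, n_empty_bins=int((~keep).sum()), bin_edges=edges,
    )


# ---------------------------------------------------------------------------
# Whole-study bundle


@dataclass
class SyntheticStudy:
    """Everything a pipeline run consumes, with ground truth attached."""

    config: SyntheticConfig
    layout: GenomeLayout
    sequences: dict[str, str]
    truth: TruthRecord
    peaksets: dict[str, list[IntervalSet]]
    counts: pd.DataFrame
    library_sizes: dict[str, float]
    annotations: dict[str, IntervalSet]
    timing: TimingTrack
    flow: FlowSample

    @property
    def wt_origins(self) -> IntervalSet:
        df = self.truth.origins
        return IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=str(r.origin_id))
            for r in df[df["in_WT"]].itertuples()
        )


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate every pipeline input from one configuration, deterministically."""
    layout = make_layout(config)
    truth = simulate_origins(config, layout)
    sequences, _ = generate_genome(config, truth=truth, layout=layout)
    peaksets, counts, library_sizes, truth = generate_peaksets(config, layout)
    origins = truth.origin_set()
    annotations = generate_annotations(config, layout, origins)
    timing = generate_timing_track(config, layout, origins)
    flow = generate_flow_sample(config)
    truth.expected_mean_rate = expected_ergodic(config).mean_rate
    return SyntheticStudy(
        config=config, layout=layout, sequences=sequences, truth=truth,
        peaksets=peaksets, counts=counts, library_sizes=library_sizes,
        annotations=annotations, timing=timing, flow=flow,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write a study to disk in standard text formats.

    FASTA + chrom.sizes for the genome, BED6 per replicate peak set and
    annotation track, TSV counts, bedGraph timing, CSV flow events, JSON
    truth and config.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "genome.fa").open("w") as fh:
        for chrom, seq in study.sequences.items():
            fh.write(f">{chrom}\n")
            fh.write(textwrap.fill(seq, 60) + "\n")
    write_chrom_sizes(study.layout.chrom_sizes, out / "genome.chrom.sizes")
    write_bed(study.layout.masked, out / "mask.bed")
    for line, reps in study.peaksets.items():
        for i, rep in enumerate(reps, start=1):
            write_bed(rep, out / f"peaks_{line}_rep{i}.bed")
    study.counts.to_csv(out / "counts.tsv", sep="\t")
    pd.Series(study.library_sizes).to_csv(
        out / "library_sizes.tsv", sep="\t", header=False
    )
    for name, track in study.annotations.items():
        write_bed(track, out / f"annotation_{name}.bed")
    write_bedgraph(study.timing, out / "timing.bedgraph")
    pd.DataFrame({"dapi": study.flow.dapi, "mcm": study.flow.mcm}).to_csv(
        out / "flow_events.csv", index=False
    )
    study.truth.to_json(out / "truth.json")
    (out / "config.json").write_text(json.dumps(asdict(study.config), indent=1))
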