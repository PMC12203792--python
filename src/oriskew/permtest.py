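"""Permutation colocalization testing of origin sets against genomic targets.

The null model re-places each query interval uniformly at random across the
canonical chromosomes, preserving interval lengths and avoiding masked
regions (randomized intervals may overlap one another).  Enrichment of the
observed overlap count against the randomized distribution is summarized by
fold enrichment (observed / mean randomized), a z-score, and empirical
p-values with the +1 correction.  Two query sets tested against the same
target can be compared through their per-permutation enrichment vectors with
a Welch t-test, BH-corrected across a family of comparisons.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import GenomeLayout, GenomicInterval, IntervalSet, merge_overlapping
from .seqprops import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "randomize_regions",
    "count_overlapping",
    "permutation_enrichment",
    "compare_enrichment_sets",
    "compare_enrichment_batch",
]


@dataclass
class PermutationResult:
    """Observed overlap vs the randomized-overlap distribution."""

    observed: int
    random_overlaps: np.ndarray
    fold: float  # observed / mean(random); nan when mean(random) == 0
    zscore: float  # nan when sd(random) == 0
    p_greater: float
    p_less: float
    n_query: int
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return len(self.random_overlaps)


class _RandomizerUniverse:
    """Pre-computed unmasked gaps for fast repeated randomization."""

    def __init__(self, layout: GenomeLayout) -> None:
        gaps = layout.unmasked_gaps()
        self.chroms = [g[0] for g in gaps]
        self.gap_starts = np.array([g[1] for g in gaps], dtype=np.int64)
        self.gap_ends = np.array([g[2] for g in gaps], dtype=np.int64)
        self.gap_lens = self.gap_ends - self.gap_starts

    def place_arrays(
        self, lengths: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Random placements as (gap_index, start, end) arrays."""
        gap_idx = np.empty(len(lengths), dtype=np.int64)
        starts = np.empty(len(lengths), dtype=np.int64)
        # group identical lengths so the valid-position table is built once
        for length in np.unique(lengths):
            sel = lengths == length
            valid = np.maximum(self.gap_lens - length + 1, 0)
            total = int(valid.sum())
            if total == 0:
                raise ValueError(
                    f"interval of length {length} exceeds every unmasked gap"
                )
            cum = np.cumsum(valid)
            draws = rng.integers(0, total, size=int(sel.sum()))
            gi = np.searchsorted(cum, draws, side="right")
            gap_idx[sel] = gi
            starts[sel] = self.gap_starts[gi] + draws - (cum[gi] - valid[gi])
        return gap_idx, starts, starts + lengths

    def place(self, lengths: np.ndarray, rng: np.random.Generator) -> IntervalSet:
        gap_idx, starts, ends = self.place_arrays(np.asarray(lengths), rng)
        return IntervalSet(
            GenomicInterval(self.chroms[gi], int(s), int(e))
            for gi, s, e in zip(gap_idx, starts, ends)
        )


def randomize_regions(
    regions: IntervalSet,
    layout: GenomeLayout,
    rng: np.random.Generator | int | None = None,
) -> IntervalSet:
    """Uniformly re-place each interval in the unmasked genome.

    Interval lengths are preserved as a multiset; each placement is uniform
    over all valid start positions across all canonical chromosomes (so
    larger chromosomes receive proportionally more placements); no randomized
    interval overlaps a masked region; randomized intervals may overlap each
    other.
    """
    rng = np.random.default_rng(rng)
    if len(regions) == 0:
        return IntervalSet()
    return _RandomizerUniverse(layout).place(regions.lengths(), rng)


def count_overlapping(query: IntervalSet, target: IntervalSet) -> int:
    """Number of query intervals with >= 1 bp overlap with any target.

    Each query interval counts at most once, however many targets it hits.
    """
    merged = merge_overlapping(target)
    total = 0
    tmap = merged.by_chrom()
    for chrom, (q_starts, q_ends) in query.by_chrom().items():
        if chrom not in tmap:
            continue
        t_starts, t_ends = tmap[chrom]
        # merged target => ends increasing with starts; a query hits iff the
        # last target starting before q.end extends past q.start
        idx = np.searchsorted(t_starts, q_ends, side="left")
        hit = (idx > 0) & (t_ends[np.maximum(idx - 1, 0)] > q_starts)
        total += int(hit.sum())
    return total


def permutation_enrichment(
    query: IntervalSet,
    target: IntervalSet,
    layout: GenomeLayout,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation test of query/target colocalization.

    Empirical p-values use the +1 correction:
    ``p_greater = (1 + #{random >= observed}) / (n_perm + 1)`` and the
    analogous ``p_less``; they are never exactly 0.  ``fold`` is NaN when the
    randomized mean is 0 and ``zscore`` is NaN when the randomized overlaps
    are constant.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if len(target) == 0:
        logger.warning("empty target: observed overlap 0, fold undefined")
    observed = count_overlapping(query, target)
    universe = _RandomizerUniverse(layout)
    lengths = query.lengths()
    merged_target = merge_overlapping(target)
    tmap = merged_target.by_chrom()
    # gap index -> integer chromosome id for array-level overlap counting
    chrom_names = sorted({*tmap, *universe.chroms})
    chrom_id = {c: i for i, c in enumerate(chrom_names)}
    gap_chrom = np.array([chrom_id[c] for c in universe.chroms])
    targets_by_id = {
        chrom_id[c]: arrays for c, arrays in tmap.items()
    }
    random_overlaps = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        if len(query) == 0:
            random_overlaps[i] = 0
            continue
        gi, starts, ends = universe.place_arrays(lengths, rng)
        cids = gap_chrom[gi]
        hits = 0
        for cid in np.unique(cids):
            if cid not in targets_by_id:
                continue
            sel = cids == cid
            t_starts, t_ends = targets_by_id[cid]
            idx = np.searchsorted(t_starts, ends[sel], side="left")
            hit = (idx > 0) & (t_ends[np.maximum(idx - 1, 0)] > starts[sel])
            hits += int(hit.sum())
        random_overlaps[i] = hits
    mean = random_overlaps.mean() if n_perm else np.nan
    sd = random_overlaps.std(ddof=1) if n_perm > 1 else 0.0
    fold = observed / mean if mean > 0 else float("nan")
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p_greater = (1 + int((random_overlaps >= observed).sum())) / (n_perm + 1)
    p_less = (1 + int((random_overlaps <= observed).sum())) / (n_perm + 1)
    return PermutationResult(
        observed=observed,
        random_overlaps=random_overlaps,
        fold=float(fold),
        zscore=float(z),
        p_greater=p_greater,
        p_less=p_less,
        n_query=len(query),
        seed=seed if isinstance(seed, int) else None,
    )


def _enrichment_vector(result: PermutationResult) -> np.ndarray:
    """Per-permutation enrichments observed/random_i, dropping random_i = 0."""
    rand = result.random_overlaps.astype(float)
    nonzero = rand > 0
    dropped = int((~nonzero).sum())
    if dropped:
        logger.warning("dropped %d permutation(s) with zero random overlap", dropped)
    return result.observed / rand[nonzero]


def compare_enrichment_sets(
    result_a: PermutationResult, result_b: PermutationResult
) -> tuple[float, float]:
    """Welch t-test between the per-permutation enrichment vectors.

    Returns ``(t, p)``; BH adjustment over a family of such comparisons is
    applied by :func:`compare_enrichment_batch`.
    """
    if result_a.n_perm != result_b.n_perm:
        raise ValueError("results must share n_perm")
    ea, eb = _enrichment_vector(result_a), _enrichment_vector(result_b)
    if len(ea) < 3 or len(eb) < 3:
        raise ValueError("fewer than 3 usable enrichment values in a group")
    if np.array_equal(ea, eb):
        return 0.0, 1.0
    res = stats.ttest_ind(ea, eb, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_enrichment_batch(
    pairs: Sequence[tuple[PermutationResult, PermutationResult]],
) -> list[tuple[float, float, float]]:
    """(t, raw p, BH-adjusted p) for each pair of permutation results."""
    raw = [compare_enrichment_sets(a, b) for a, b in pairs]
    adj = bh_adjust([p for _, p in raw])
    return [(t, p, float(q)) for (t, p), q in zip(raw, adj)]
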