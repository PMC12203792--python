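"""Independent brute-force oracles used by the test suite.

Every oracle here works on per-base boolean genome arrays or explicit
pairwise enumeration, deliberately avoiding the sweep/sorted-array
algorithms used by the package, so agreement is a real cross-check.
"""
from __future__ import annotations

import numpy as np

from oriskew.intervals import GenomicInterval, IntervalSet


def coverage(intervals: IntervalSet, chrom: str, size: int) -> np.ndarray:
    """Boolean per-base coverage array for one chromosome."""
    cov = np.zeros(size, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            cov[iv.start:iv.end] = True
    return cov


def runs(cov: np.ndarray, chrom: str) -> list[GenomicInterval]:
    """Maximal True runs of a coverage array as intervals."""
    out = []
    padded = np.concatenate([[False], cov, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def brute_intersect_region(
    a: IntervalSet, b: IntervalSet, chroms: dict[str, int]
) -> list[GenomicInterval]:
    """Per-base AND of the two coverages."""
    out = []
    for chrom, size in chroms.items():
        out.extend(runs(coverage(a, chrom, size) & coverage(b, chrom, size), chrom))
    return sorted(out, key=GenomicInterval.sort_key)


def brute_intersect_peak(a: IntervalSet, b: IntervalSet,
                         chroms: dict[str, int]) -> list[GenomicInterval]:
    """a-peaks whose footprint intersects the b coverage."""
    covs = {c: coverage(b, c, size) for c, size in chroms.items()}
    return [iv for iv in a if covs[iv.chrom][iv.start:iv.end].any()]


def _pairwise_overlap(x: GenomicInterval, y: GenomicInterval) -> bool:
    return x.chrom == y.chrom and x.start < y.end and y.start < x.end


def brute_overlap_count_min(a: IntervalSet, b: IntervalSet) -> tuple[int, int, int]:
    """Connected components by explicit union-find over all peak pairs."""
    peaks = [(iv, 0) for iv in a] + [(iv, 1) for iv in b]
    parent = list(range(len(peaks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            if _pairwise_overlap(peaks[i][0], peaks[j][0]):
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(len(peaks)):
        comps.setdefault(find(i), []).append(i)
    count = a_only = b_only = 0
    for members in comps.values():
        na = sum(1 for i in members if peaks[i][1] == 0)
        nb = sum(1 for i in members if peaks[i][1] == 1)
        if na and nb:
            count += min(na, nb)
        elif na:
            a_only += na
        else:
            b_only += nb
    return count, a_only, b_only


def brute_cluster(peaks: IntervalSet, threshold: float) -> list[GenomicInterval]:
    """Single-linkage via union-find over all pairs with gap < threshold."""
    ivs = list(peaks)
    parent = list(range(len(ivs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ivs)):
        for j in range(i + 1, len(ivs)):
            if ivs[i].chrom != ivs[j].chrom:
                continue
            gap = max(ivs[i].start, ivs[j].start) - min(ivs[i].end, ivs[j].end)
            if gap < threshold:
                parent[find(i)] = find(j)
    comps: dict[int, list[GenomicInterval]] = {}
    for i, iv in enumerate(ivs):
        comps.setdefault(find(i), []).append(iv)
    out = []
    for members in comps.values():
        out.append(
            GenomicInterval(
                members[0].chrom,
                min(m.start for m in members),
                max(m.end for m in members),
                score=float(len(members)),
            )
        )
    return sorted(out, key=GenomicInterval.sort_key)


def brute_common_merge(sets: list[IntervalSet],
                       chroms: dict[str, int]) -> list[GenomicInterval]:
    """Enumerate all mutually overlapping peak triples, merge their spans."""
    spans: list[GenomicInterval] = []
    for x in sets[0]:
        for y in sets[1]:
            if not _pairwise_overlap(x, y):
                continue
            for z in sets[2]:
                if _pairwise_overlap(x, z) and _pairwise_overlap(y, z):
                    spans.append(
                        GenomicInterval(
                            x.chrom,
                            min(x.start, y.start, z.start),
                            max(x.end, y.end, z.end),
                        )
                    )
    # merge strictly overlapping spans to a fixed point (gap < 0 pairs)
    merged = brute_cluster(IntervalSet(spans), 0)
    dedup = sorted({(m.chrom, m.start, m.end) for m in merged})
    return [GenomicInterval(c, s, e) for c, s, e in dedup]


def brute_count_overlapping(query: IntervalSet, target: IntervalSet,
                            chroms: dict[str, int]) -> int:
    covs = {c: coverage(target, c, size) for c, size in chroms.items()}
    return sum(1 for iv in query if covs[iv.chrom][iv.start:iv.end].any())


def random_intervalset(rng: np.random.Generator, chroms: dict[str, int],
                       n: int, max_len: int = 500) -> IntervalSet:
    ivs = []
    names = list(chroms)
    for _ in range(n):
        chrom = names[int(rng.integers(0, len(names)))]
        size = chroms[chrom]
        length = int(rng.integers(1, min(max_len, size) + 1))
        start = int(rng.integers(0, size - length + 1))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs)
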