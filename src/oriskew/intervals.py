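"""BED-level interval algebra for replication-origin maps.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Two intervals overlap when they share at least one base,
i.e. ``a.start < b.end and b.start < a.end``.  Strand is ignored; short
nascent strand (SNS-seq) peaks are unstranded.

The module covers the peak-set operations used to turn per-replicate SNS-seq
peak calls into origin sets and to compare origin sets between cell lines:

* replicate intersection (origins = peaks supported by both replicates),
* minimum-count Venn overlap between two origin sets,
* initiation-zone clustering at the median inter-peak distance,
* the merge of differential origins shared by all knockout lines.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GenomeLayout",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "intersect_replicates",
    "overlap_count_min",
    "median_interpeak_distance",
    "cluster_initiation_zones",
    "common_ko_merge",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Always sorted by ``(chrom, start, end)``; every operation preserves
    sortedness.  ``label`` records provenance (cell line or track name).
    """

    def __init__(
        self, intervals: Iterable[GenomicInterval] = (), label: str | None = None
    ) -> None:
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )
        self.label = label
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [
            (iv.chrom, iv.start, iv.end) for iv in self
        ] == [(iv.chrom, iv.start, iv.end) for iv in other]

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return f"<IntervalSet{lab} n={len(self)}>"

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, cached."""
        if self._by_chrom is None:
            out: dict[str, list[list[int]]] = {}
            for iv in self.intervals:
                out.setdefault(iv.chrom, [[], []])
                out[iv.chrom][0].append(iv.start)
                out[iv.chrom][1].append(iv.end)
            self._by_chrom = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in out.items()
            }
        return self._by_chrom

    def total_bases(self) -> int:
        """Bases covered by the union of the intervals."""
        return sum(iv.end - iv.start for iv in merge_overlapping(self))

    def lengths(self) -> np.ndarray:
        return np.array([iv.end - iv.start for iv in self.intervals], dtype=np.int64)

    def restrict_to(self, layout: "GenomeLayout") -> "IntervalSet":
        """Drop intervals on non-canonical chromosomes (logged)."""
        keep = [iv for iv in self if iv.chrom in layout.chrom_sizes]
        dropped = len(self) - len(keep)
        if dropped:
            logger.info(
                "dropped %d interval(s) on non-canonical chromosomes", dropped
            )
        return IntervalSet(keep, label=self.label)


@dataclass
class GenomeLayout:
    """Canonical chromosome names/lengths plus masked regions.

    The masked regions (assembly gaps, blacklisted repeats, ...) are excluded
    from the permutation universe used by region randomization.
    """

    chrom_sizes: dict[str, int]
    masked: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self) -> None:
        for iv in self.masked:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"masked interval on unknown chromosome {iv.chrom}")
            if iv.end > size:
                raise ValueError(
                    f"masked interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {size}"
                )
        self.masked = merge_overlapping(self.masked)

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def unmasked_gaps(self) -> list[tuple[str, int, int]]:
        """Maximal unmasked runs ``(chrom, start, end)`` across the genome."""
        masked_by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.masked:
            masked_by_chrom.setdefault(iv.chrom, []).append(iv)
        gaps: list[tuple[str, int, int]] = []
        for chrom, size in self.chrom_sizes.items():
            pos = 0
            for iv in masked_by_chrom.get(chrom, []):
                if iv.start > pos:
                    gaps.append((chrom, pos, iv.start))
                pos = max(pos, iv.end)
            if pos < size:
                gaps.append((chrom, pos, size))
        return gaps


# ---------------------------------------------------------------------------
# I/O


def read_bed(
    path: str | Path, layout: GenomeLayout | None = None, label: str | None = None
) -> IntervalSet:
    """Read a BED3/BED6 file into an :class:`IntervalSet`.

    Lines must have >= 3 tab-separated columns.  Output is sorted regardless
    of input order.  When a layout is bound, intervals on non-canonical
    chromosomes are dropped with a logged count.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid coordinates {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            intervals.append(GenomicInterval(fields[0], start, end, name, score))
    out = IntervalSet(intervals, label=label or path.stem)
    if layout is not None:
        out = out.restrict_to(layout)
    return out


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write BED6 (name/score filled with '.'/'0' when absent)."""
    with Path(path).open("w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# Core algebra


def merge_overlapping(intervals: IntervalSet, min_gap: int = 0) -> IntervalSet:
    """Union-merge intervals whose gap is < ``min_gap`` (0 = overlap only).

    With the default ``min_gap=0`` only intervals sharing >= 1 base are
    merged; touching intervals (gap 0) stay separate, matching the strict
    overlap definition used throughout.
    """
    merged: list[GenomicInterval] = []
    cur: list | None = None
    for iv in intervals:
        if cur is not None and iv.chrom == cur[0] and iv.start - cur[2] < min_gap:
            cur[2] = max(cur[2], iv.end)
        else:
            if cur is not None:
                merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
            cur = [iv.chrom, iv.start, iv.end]
    if cur is not None:
        merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
    return IntervalSet(merged, label=intervals.label)


def intersect_replicates(
    rep1: IntervalSet, rep2: IntervalSet, mode: str = "region"
) -> IntervalSet:
    """Origins supported by both replicates.

    mode="region" (default): emit the base-pair intersection segment of every
    overlapping (rep1, rep2) peak pair, like ``bedtools intersect``.
    mode="peak": emit each rep1 peak having >= 1 bp overlap with any rep2
    peak, keeping its original coordinates.
    """
    if mode not in ("region", "peak"):
        raise ValueError(f"unknown mode {mode!r}")
    out: list[GenomicInterval] = []
    b_chrom = rep2.by_chrom()
    for iv in rep1:
        if iv.chrom not in b_chrom:
            continue
        starts, ends = b_chrom[iv.chrom]
        # candidates: b.start < iv.end and b.end > iv.start
        hit = (starts < iv.end) & (ends > iv.start)
        if mode == "peak":
            if hit.any():
                out.append(iv)
            continue
        for s, e in zip(starts[hit], ends[hit]):
            out.append(
                GenomicInterval(iv.chrom, max(iv.start, int(s)), min(iv.end, int(e)))
            )
    return IntervalSet(out, label=rep1.label)


def _overlap_components(
    a: IntervalSet, b: IntervalSet
) -> list[tuple[int, int]]:
    """Connected components of the overlap graph over peaks of ``a`` u ``b``.

    On a line, single-linkage by strict overlap equals graph connectivity.
    Returns (n_a, n_b) peak counts per component, including singletons.
    """
    tagged = [(iv.chrom, iv.start, iv.end, 0) for iv in a] + [
        (iv.chrom, iv.start, iv.end, 1) for iv in b
    ]
    tagged.sort()
    comps: list[tuple[int, int]] = []
    cur_chrom, cur_end, na, nb = None, -1, 0, 0
    for chrom, start, end, tag in tagged:
        if cur_chrom == chrom and start < cur_end:
            cur_end = max(cur_end, end)
        else:
            if cur_chrom is not None:
                comps.append((na, nb))
            cur_chrom, cur_end, na, nb = chrom, end, 0, 0
        if tag == 0:
            na += 1
        else:
            nb += 1
    if cur_chrom is not None:
        comps.append((na, nb))
    return comps


def overlap_count_min(a: IntervalSet, b: IntervalSet) -> tuple[int, int, int]:
    """Minimum-count Venn overlap between two peak sets.

    Within each connected component of mutually overlapping peaks, the
    overlap contributes ``min(#a peaks, #b peaks)`` — the convention used for
    peak-set Venn diagrams where a component is never counted more often than
    the smaller of its two sides.  Returns ``(count, a_only, b_only)``.
    """
    count = a_only = b_only = 0
    for na, nb in _overlap_components(a, b):
        if na and nb:
            count += min(na, nb)
        elif na:
            a_only += na
        else:
            b_only += nb
    return count, a_only, b_only


def median_interpeak_distance(peaks: IntervalSet, mode: str = "end_to_start") -> float:
    """Median gap between adjacent same-chromosome peaks.

    mode="end_to_start" (default): gap = next.start - prev.end.
    mode="start_to_start": gap = next.start - prev.start.
    Raises ValueError when no chromosome carries >= 2 peaks.
    """
    if mode not in ("end_to_start", "start_to_start"):
        raise ValueError(f"unknown mode {mode!r}")
    gaps: list[int] = []
    for chrom, (starts, ends) in peaks.by_chrom().items():
        if len(starts) < 2:
            continue
        if mode == "end_to_start":
            gaps.extend((starts[1:] - ends[:-1]).tolist())
        else:
            gaps.extend((starts[1:] - starts[:-1]).tolist())
    if not gaps:
        raise ValueError("no interpeak distances: need >=2 peaks on one chromosome")
    return float(np.median(gaps))


def cluster_initiation_zones(peaks: IntervalSet, threshold: float) -> IntervalSet:
    """Single-linkage merge of peaks closer than ``threshold`` (strict <).

    Peaks whose end-to-start gap is < threshold join one cluster (initiation
    zone); each cluster is reported as the spanning interval with the member
    count stored in ``score``.  ``threshold=0`` merges nothing on
    non-overlapping input.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out: list[GenomicInterval] = []
    cur: list | None = None  # [chrom, start, end, count]
    for iv in peaks:
        if cur is not None and iv.chrom == cur[0] and iv.start - cur[2] < threshold:
            cur[2] = max(cur[2], iv.end)
            cur[3] += 1
        else:
            if cur is not None:
                out.append(GenomicInterval(cur[0], cur[1], cur[2], score=float(cur[3])))
            cur = [iv.chrom, iv.start, iv.end, 1]
    if cur is not None:
        out.append(GenomicInterval(cur[0], cur[1], cur[2], score=float(cur[3])))
    return IntervalSet(out, label=peaks.label)


def _intersect_regions(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-pair intersection of two merged coverages."""
    return merge_overlapping(intersect_replicates(merge_overlapping(a), merge_overlapping(b)))


def common_ko_merge(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Regions where peaks from *all* given sets mutually overlap, merged.

    By Helly's theorem in one dimension, pairwise overlap of one peak per set
    implies a common base, so the seeds are the base-pair intersection of all
    coverages.  Each seed is expanded to the union span of the peaks (from
    any set) that contain it, and overlapping spans are merged — the
    behaviour of intersecting the differential peak sets and merging the
    mutually overlapping peaks.
    """
    if not sets:
        return IntervalSet()
    seed = merge_overlapping(sets[0])
    for other in sets[1:]:
        seed = _intersect_regions(seed, other)
        if len(seed) == 0:
            return IntervalSet()
    spans: list[GenomicInterval] = []
    chrom_maps = [s.by_chrom() for s in sets]
    for region in seed:
        lo, hi = region.start, region.end
        for cmap in chrom_maps:
            if region.chrom not in cmap:
                continue
            starts, ends = cmap[region.chrom]
            hit = (starts < region.end) & (ends > region.start)
            if hit.any():
                lo = min(lo, int(starts[hit].min()))
                hi = max(hi, int(ends[hit].max()))
        spans.append(GenomicInterval(region.chrom, lo, hi))
    return merge_overlapping(IntervalSet(spans))
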