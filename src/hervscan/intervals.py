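"""Coordinate mapping between SNVs, elements, region classes and tracks.

All overlap operations are strand-blind and half-open. Chromosome names are
normalized with a tolerant prefix rule so "chr1" and "1" unify.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np

from hervscan.model import GenomicInterval, HervElement, RegionClass, SnvRecord

logger = logging.getLogger(__name__)


def normalize_chrom(name: str, strip_prefix: bool = True) -> str:
    """Unify UCSC-style ("chr1") and ENSEMBL-style ("1") chromosome names."""
    name = str(name)
    if strip_prefix and name.lower().startswith("chr"):
        return name[3:]
    return name


class IntervalIndex:
    """Static point/range query structure over intervals with payload indices.

    Per chromosome the intervals are kept sorted by (start, input order) with
    a running maximum of ends, giving the classic augmented-list stabbing
    query: candidates have start <= pos, and the backward scan stops as soon
    as the prefix max-end falls at or below the query point. Query results
    are identical to a linear scan; construction copies, never mutates.
    """

    def __init__(self, intervals: Sequence[GenomicInterval], strip_prefix: bool = True):
        self._strip_prefix = strip_prefix
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, iv in enumerate(intervals):
            per_chrom.setdefault(normalize_chrom(iv.chrom, strip_prefix), []).append(
                (iv.start, i, iv.end)
            )
        self._chroms: dict[str, tuple[list[int], list[int], list[int], list[int]]] = {}
        for chrom, entries in per_chrom.items():
            entries.sort()
            starts = [s for s, _, _ in entries]
            idxs = [i for _, i, _ in entries]
            ends = [e for _, _, e in entries]
            maxend = list(np.maximum.accumulate(ends))
            self._chroms[chrom] = (starts, ends, maxend, idxs)

    def query_point(self, chrom: str, pos0: int) -> list[int]:
        """Input indices of intervals containing 0-based ``pos0``, ordered by
        (start, input order)."""
        entry = self._chroms.get(normalize_chrom(chrom, self._strip_prefix))
        if entry is None:
            return []
        starts, ends, maxend, idxs = entry
        hi = bisect.bisect_right(starts, pos0)
        hits = []
        for j in range(hi - 1, -1, -1):
            if maxend[j] <= pos0:
                break
            if ends[j] > pos0:
                hits.append(j)
        return [idxs[j] for j in sorted(hits)]

    def query_range(self, chrom: str, start: int, end: int) -> list[int]:
        """Input indices of intervals overlapping [start, end)."""
        entry = self._chroms.get(normalize_chrom(chrom, self._strip_prefix))
        if entry is None or end <= start:
            return []
        starts, ends, maxend, idxs = entry
        hi = bisect.bisect_left(starts, end)  # start < end required to overlap
        hits = []
        for j in range(hi - 1, -1, -1):
            if maxend[j] <= start:
                break
            if ends[j] > start:
                hits.append(j)
        return [idxs[j] for j in sorted(hits)]


def build_index(intervals: Sequence[GenomicInterval], strip_prefix: bool = True) -> IntervalIndex:
    return IntervalIndex(intervals, strip_prefix=strip_prefix)


def assign_snvs_to_elements(
    snvs: Sequence[SnvRecord],
    elements: Sequence[HervElement],
) -> tuple[dict[str, int], list[list[str]]]:
    """Map each SNV to the elements whose span contains it.

    Returns per-element observed counts keyed by element id (every element
    present, zero included) and, parallel to ``snvs``, the list of element ids
    hit by each SNV. An SNV inside several overlapping elements counts toward
    all of them, so counts may sum to more than ``len(snvs)``.
    """
    index = build_index([e.interval for e in elements])
    counts: dict[str, int] = {e.element_id: 0 for e in elements}
    per_snv: list[list[str]] = []
    missing_chroms: set[str] = set()
    chrom_set = {normalize_chrom(e.interval.chrom) for e in elements}
    for snv in snvs:
        hits = index.query_point(snv.chrom, snv.pos0)
        ids = [elements[i].element_id for i in hits]
        for eid in ids:
            counts[eid] += 1
        per_snv.append(ids)
        if not hits and normalize_chrom(snv.chrom) not in chrom_set:
            missing_chroms.add(snv.chrom)
    if missing_chroms:
        logger.info(
            "SNV chromosomes absent from the element annotation (no hits): %s",
            ", ".join(sorted(missing_chroms)),
        )
    return counts, per_snv


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of possibly-overlapping intervals, per normalized chromosome."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per_chrom.setdefault(normalize_chrom(iv.chrom), []).append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        spans = sorted(per_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def classify_region(
    snvs: Sequence[SnvRecord],
    coding_intervals: Sequence[GenomicInterval],
) -> list[SnvRecord]:
    """Set ``region_class`` on each SNV: coding iff inside any coding span.

    Only the positional test is applied; any interval supplied in the coding
    set counts as coding, none are inferred.
    """
    merged = merge_intervals(coding_intervals)
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        per_chrom.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    grouped: dict[str, list[tuple[int, int]]] = {}
    for iv in merged:
        grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
    arrays = {
        chrom: (np.array([s for s, _ in spans]), np.array([e for _, e in spans]))
        for chrom, spans in grouped.items()
    }
    out: list[SnvRecord] = []
    for snv in snvs:
        chrom = normalize_chrom(snv.chrom)
        cls = RegionClass.NONCODING
        entry = arrays.get(chrom)
        if entry is not None:
            starts, ends = entry
            j = int(np.searchsorted(starts, snv.pos0, side="right")) - 1
            if j >= 0 and snv.pos0 < ends[j]:
                cls = RegionClass.CODING
        out.append(replace(snv, region_class=cls))
    return out


def region_total_bases(intervals: Sequence[GenomicInterval], merge_overlaps: bool = True) -> int:
    """Total bases covered; with ``merge_overlaps`` the union is measured."""
    if merge_overlaps:
        return sum(iv.length for iv in merge_intervals(intervals))
    return sum(iv.length for iv in intervals)


def subtract_from_genome(
    genome_length: int,
    intervals: Sequence[GenomicInterval],
    exclusion: Sequence[GenomicInterval] = (),
) -> int:
    """Genome length minus the union of ``intervals`` and ``exclusion``.

    Used to derive the non-coding L from a declared genome size and the
    coding union (optionally also dropping assembly-gap spans).
    """
    union = region_total_bases(list(intervals) + list(exclusion), merge_overlaps=True)
    if union > genome_length:
        raise ValueError(
            f"excluded union ({union}) exceeds the declared genome length ({genome_length})"
        )
    return genome_length - union
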