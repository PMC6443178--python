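"""Synthetic mutation landscapes with the structure the scan assumes.

The generator places non-overlapping elements on a multi-chromosome genome
and mutates every base independently: rate ``base_rate`` outside elements,
``base_rate * multiplier`` inside spiked ones. Variants are site-unique by
default (one per base), draw ref/alt uniformly from distinct nucleotides
and a cancer label from a fixed mixture. Everything is reproducible from
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from hervscan.model import (
    BackgroundModel,
    FunctionalTrack,
    GenomicInterval,
    HervElement,
    RegionClass,
    SimTruth,
    SnvRecord,
    Supergroup,
    make_background,
)

_NUC = np.array(list("ACGT"))

# Small taxonomy to draw from; group -> (supergroup, canonical share irrelevant)
_GROUPS: tuple[tuple[str, Supergroup], ...] = (
    ("HERV-H/LTR7", Supergroup.GE),
    ("HERV-9/LTR12", Supergroup.GE),
    ("HERV-W/LTR17/HERV17", Supergroup.GE),
    ("HERV-IP10F/LTR10F", Supergroup.GE),
    ("HML-2/HERV-K/LTR5", Supergroup.AB),
    ("HML-8/HERV-K11I/MER11A", Supergroup.AB),
    ("HERV-L/MLT2", Supergroup.S),
    ("MST/MaLR", Supergroup.S),
)

DEFAULT_MIXTURE: Mapping[str, float] = {
    "skin cancer": 0.5,
    "lung cancer": 0.3,
    "colon cancer": 0.2,
}

DEFAULT_TRACK_COVERAGE: Mapping[str, float] = {
    "lncRNA": 0.03,
    "intron": 0.05,
    "TFBS": 0.01,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic landscape.

    Default scale (10 Mb, 200 elements, base rate 2e-3) gives per-element
    expectations around the tens, large enough for enrichment tests while
    generating in well under a second.
    """

    genome_length: int = 10_000_000
    n_chromosomes: int = 2
    n_elements: int = 200
    element_length_min: int = 500
    element_length_max: int = 5_000
    coding_fraction: float = 0.05
    base_rate: float = 2e-3
    spikes: Mapping[int, float] = field(default_factory=dict)
    cancer_mixture: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    track_coverage: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRACK_COVERAGE))
    site_unique: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.n_chromosomes < 1 or self.n_elements < 0:
            raise ValueError("genome_length/n_chromosomes must be >= 1, n_elements >= 0")
        if not (0 < self.element_length_min <= self.element_length_max):
            raise ValueError("need 0 < element_length_min <= element_length_max")
        if not (0.0 <= self.coding_fraction <= 1.0):
            raise ValueError("coding_fraction must be in [0, 1]")
        max_mult = max(self.spikes.values(), default=1.0)
        if self.base_rate < 0 or self.base_rate * max(max_mult, 1.0) > 1.0:
            raise ValueError("base_rate (x max spike multiplier) must lie in [0, 1]")
        for idx, mult in self.spikes.items():
            if mult <= 0:
                raise ValueError(f"spike multiplier for element {idx} must be > 0")
            if not (0 <= idx < self.n_elements):
                raise ValueError(f"spike index {idx} outside [0, {self.n_elements})")
        if self.cancer_mixture:
            total = sum(self.cancer_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cancer_mixture must sum to 1, got {total}")
        for name, frac in self.track_coverage.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"track coverage for {name} must be in [0, 1]")


def _chrom_lengths(config: SimConfig) -> dict[str, int]:
    base = config.genome_length // config.n_chromosomes
    lengths = {f"chr{i + 1}": base for i in range(config.n_chromosomes)}
    lengths[f"chr{config.n_chromosomes}"] += config.genome_length - base * config.n_chromosomes
    return lengths


def _sample_distinct(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct integers from [0, n), uniform, O(k) expected for k << n."""
    if k > n:
        raise ValueError(f"cannot draw {k} distinct values from {n}")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if k * 3 >= n:  # dense regime: permutation is fine
        return rng.permutation(n)[:k].astype(np.int64)
    chosen: set[int] = set()
    need = k
    while need > 0:
        draw = rng.integers(0, n, size=int(need * 1.2) + 8)
        for v in draw:
            iv = int(v)
            if iv not in chosen:
                chosen.add(iv)
                if len(chosen) == k:
                    break
        need = k - len(chosen)
    out = np.fromiter(chosen, dtype=np.int64, count=k)
    out.sort()
    return out


def _place_elements(rng: np.random.Generator, config: SimConfig) -> list[HervElement]:
    """Non-overlapping uniform placement via the gap-insertion construction."""
    chrom_lengths = _chrom_lengths(config)
    chroms = list(chrom_lengths)
    lengths = rng.integers(
        config.element_length_min, config.element_length_max + 1, size=config.n_elements
    )
    genome = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_of = rng.choice(len(chroms), size=config.n_elements, p=genome / genome.sum())
    elements: list[HervElement] = []
    order = 0
    for ci, chrom in enumerate(chroms):
        idxs = np.flatnonzero(chrom_of == ci)
        if idxs.size == 0:
            continue
        lens = lengths[idxs]
        slack = chrom_lengths[chrom] - int(lens.sum())
        if slack < 0:
            raise ValueError(
                f"elements do not fit: {int(lens.sum())} bases of elements on "
                f"{chrom} of length {chrom_lengths[chrom]}"
            )
        # sorted anchors in the compacted space, then re-inflate by cumsum
        anchors = np.sort(rng.integers(0, slack + 1, size=idxs.size))
        starts = anchors + np.concatenate(([0], np.cumsum(lens[:-1])))
        for j, (s, ln) in enumerate(zip(starts, lens)):
            gi = rng.integers(0, len(_GROUPS))
            group, supergroup = _GROUPS[gi]
            elements.append(
                HervElement(
                    element_id=f"E{order:04d}",
                    interval=GenomicInterval(chrom, int(s), int(s + ln)),
                    group=group,
                    supergroup=supergroup,
                    canonical=bool(rng.integers(0, 2)),
                )
            )
            order += 1
    return elements


def _periodic_intervals(
    chrom_lengths: Mapping[str, int], fraction: float, span: int, phase: int
) -> list[GenomicInterval]:
    """Deterministic periodic tiling covering ~fraction of each chromosome."""
    if fraction <= 0:
        return []
    period = max(span + 1, int(round(span / fraction)))
    out = []
    for chrom, length in chrom_lengths.items():
        start = phase % period
        while start + span <= length:
            out.append(GenomicInterval(chrom, start, start + span))
            start += period
    return out


def simulate_landscape(
    config: SimConfig,
) -> tuple[list[HervElement], list[GenomicInterval], list[FunctionalTrack], list[SnvRecord], SimTruth]:
    """Generate (elements, coding intervals, tracks, snvs, truth).

    Elements never overlap; coding intervals and tracks are deterministic
    periodic tilings (independent of variant positions by construction).
    """
    rng = np.random.default_rng(config.seed)
    chrom_lengths = _chrom_lengths(config)
    elements = _place_elements(rng, config)

    coding = _periodic_intervals(chrom_lengths, config.coding_fraction, span=200, phase=0)
    tracks = [
        FunctionalTrack(
            name=name,
            intervals=tuple(
                _periodic_intervals(chrom_lengths, frac, span=300, phase=101 + 37 * i)
            ),
        )
        for i, (name, frac) in enumerate(config.track_coverage.items())
        if frac > 0
    ]

    # segment the genome into homogeneous-rate pieces
    segments: list[tuple[str, int, int, float]] = []  # (chrom, start, end, rate)
    by_chrom: dict[str, list[HervElement]] = {c: [] for c in chrom_lengths}
    for e in elements:
        by_chrom[e.interval.chrom].append(e)
    multiplier = {e.element_id: 1.0 for e in elements}
    for idx, mult in config.spikes.items():
        multiplier[elements_sorted_id(elements, idx)] = float(mult)
    for chrom, length in chrom_lengths.items():
        cursor = 0
        for e in sorted(by_chrom[chrom], key=lambda x: x.interval.start):
            if e.interval.start > cursor:
                segments.append((chrom, cursor, e.interval.start, config.base_rate))
            segments.append(
                (chrom, e.interval.start, e.interval.end, config.base_rate * multiplier[e.element_id])
            )
            cursor = e.interval.end
        if cursor < length:
            segments.append((chrom, cursor, length, config.base_rate))

    labels = list(config.cancer_mixture) or [None]
    probs = np.array([config.cancer_mixture[l] for l in labels]) if config.cancer_mixture else None

    snvs: list[SnvRecord] = []
    for chrom, start, end, rate in segments:
        n = end - start
        if rate <= 0 or n <= 0:
            continue
        k = int(rng.binomial(n, rate))
        if k == 0:
            continue
        if config.site_unique:
            offsets = _sample_distinct(rng, n, k)
        else:
            offsets = np.sort(rng.integers(0, n, size=k))
        refs = rng.integers(0, 4, size=k)
        alts = (refs + rng.integers(1, 4, size=k)) % 4
        if probs is not None:
            label_idx = rng.choice(len(labels), size=k, p=probs)
        for j in range(k):
            label = labels[int(label_idx[j])] if probs is not None else None
            snvs.append(
                SnvRecord(
                    chrom=chrom,
                    pos=int(start + offsets[j]) + 1,
                    ref_allele=str(_NUC[refs[j]]),
                    alt_allele=str(_NUC[alts[j]]),
                    cancer_label=label,
                )
            )
    snvs.sort(key=lambda s: (s.chrom, s.pos, s.alt_allele))
    truth = SimTruth(
        seed=config.seed,
        base_rate=config.base_rate,
        spiked_elements={
            elements_sorted_id(elements, idx): float(m) for idx, m in config.spikes.items()
        },
        cancer_mixture=dict(config.cancer_mixture),
    )
    return elements, coding, tracks, snvs, truth


def elements_sorted_id(elements: Sequence[HervElement], index: int) -> str:
    """Element id for a configured spike index (placement order)."""
    return elements[index].element_id


# Worked-example fixture: the four-element hotspot table. The per-base
# density 2047/26400 is exactly 20.47/264, so the first element's
# expectation reproduces to the printed two decimals by construction.
_TABLE_ROWS = (
    ("6114", "chr1", 264, "HERV-9/LTR12", Supergroup.GE, 35),
    ("4780", "chr19", 702, "MST/MaLR", Supergroup.S, 92),
    ("4062", "chr14", 1044, "HERV-IP10F/LTR10F", Supergroup.GE, 116),
    ("4673", "chr19", 1585, "HERV-W/LTR17/HERV17", Supergroup.GE, 249),
)


def table2_fixture() -> tuple[list[HervElement], BackgroundModel, dict[str, int]]:
    """Four-element worked example with a calibrated background.

    Returns the elements (lengths 264/702/1044/1585), a coding background
    whose density is exactly 20.47/264 per base, and the observed counts
    (35/92/116/249).
    """
    elements = []
    offset = 10_000
    for eid, chrom, length, group, supergroup, _ in _TABLE_ROWS:
        elements.append(
            HervElement(
                element_id=eid,
                interval=GenomicInterval(chrom, offset, offset + length),
                group=group,
                supergroup=supergroup,
                canonical=False,
            )
        )
        offset += 100_000
    background = make_background(RegionClass.CODING, total_bases_L=26_400, total_snvs_N=2_047)
    observed = {eid: n for eid, _, _, _, _, n in _TABLE_ROWS}
    return elements, background, observed
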