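"""Per-element over/under-representation testing against the uniform null.

For an element of length n_F in a region of L bases carrying N variant
sites, the hit probability is p_F = n_F / L, the expectation n_E = N * p_F,
and the tail probabilities come from Binomial(N, p_F). Family-wise error is
controlled by Bonferroni division of alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

import numpy as np
from scipy import stats

from hervscan.intervals import assign_snvs_to_elements, normalize_chrom
from hervscan.model import (
    BackgroundModel,
    Direction,
    ElementTestResult,
    GenomicInterval,
    HervElement,
    SnvRecord,
)

TailMode = Literal["exact_binomial", "poisson", "normal_paper_compat"]


@dataclass(frozen=True)
class ScanConfig:
    """Knobs for one enrichment scan.

    ``n_tests="auto"`` divides alpha by the number of elements actually
    tested; an explicit integer overrides it (the historical coding and
    non-coding scans used 58 and 3,130 tests). ``two_sided`` doubles the
    direction-matched tail (capped at 1) instead of using it raw.
    ``count_mode="sites"`` collapses recurrent variants at one base to a
    single site before counting; ``"events"`` counts every record.
    """

    alpha: float = 0.05
    n_tests: Union[int, Literal["auto"]] = "auto"
    tail_mode: TailMode = "exact_binomial"
    min_observed_to_test: int = 1
    two_sided: bool = False
    count_mode: Literal["sites", "events"] = "sites"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_tests != "auto" and int(self.n_tests) < 1:
            raise ValueError(f"n_tests must be >= 1, got {self.n_tests}")
        if self.min_observed_to_test < 0:
            raise ValueError("min_observed_to_test must be >= 0")


@dataclass(frozen=True)
class FragmentScanResult:
    """Outcome of the fixed-width random-window background check."""

    fragment_size: int
    counts: tuple[int, ...]
    observed_ratio: float
    seed: int


def expected_count(element_length: int, background: BackgroundModel) -> float:
    """Expected variant count n_E = density * length, at full precision."""
    if element_length < 0:
        raise ValueError(f"element_length must be >= 0, got {element_length}")
    return background.density * element_length


def binomial_tail(n_O: int, N: int, p_F: float, tail: Literal["upper", "lower"]) -> float:
    """Exact binomial tail: upper = P(X >= n_O), lower = P(X <= n_O).

    Evaluated through the regularized incomplete beta function, which stays
    accurate far into the tails (well below 1e-300 in log terms the survival
    function underflows gracefully to the nearest representable double).
    """
    if not (0 <= n_O <= N):
        raise ValueError(f"n_O must satisfy 0 <= n_O <= N, got n_O={n_O}, N={N}")
    if not (0.0 <= p_F <= 1.0):
        raise ValueError(f"p_F must be in [0, 1], got {p_F}")
    if tail == "upper":
        return float(stats.binom.sf(n_O - 1, N, p_F))
    if tail == "lower":
        return float(stats.binom.cdf(n_O, N, p_F))
    raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")


def poisson_tail(n_O: int, lam: float, tail: Literal["upper", "lower"]) -> float:
    """Poisson tail approximation (large-N, small-p limit of the binomial)."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if n_O < 0:
        raise ValueError(f"n_O must be >= 0, got {n_O}")
    if tail == "upper":
        return float(stats.poisson.sf(n_O - 1, lam))
    if tail == "lower":
        return float(stats.poisson.cdf(n_O, lam))
    raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")


def normal_tail(n_O: int, N: int, p_F: float, tail: Literal["upper", "lower"]) -> float:
    """Continuity-uncorrected normal approximation, z = (n_O - n_E)/sd.

    Provided for comparison with historical outputs only; the exact binomial
    is authoritative.
    """
    n_E = N * p_F
    sd = math.sqrt(n_E * (1.0 - p_F)) if n_E > 0 else 0.0
    if sd == 0.0:
        return 1.0 if (tail == "upper") == (n_O <= n_E) else 0.0
    z = (n_O - n_E) / sd
    return float(stats.norm.sf(z) if tail == "upper" else stats.norm.cdf(z))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise cutoff alpha / n_tests."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / n_tests


def _tails(n_O: int, N: int, p_F: float, mode: TailMode) -> tuple[float, float]:
    if mode == "exact_binomial":
        return binomial_tail(n_O, N, p_F, "upper"), binomial_tail(n_O, N, p_F, "lower")
    if mode == "poisson":
        lam = N * p_F
        return poisson_tail(n_O, lam, "upper"), poisson_tail(n_O, lam, "lower")
    if mode == "normal_paper_compat":
        return normal_tail(n_O, N, p_F, "upper"), normal_tail(n_O, N, p_F, "lower")
    raise ValueError(f"unknown tail mode {mode!r}")


def collapse_sites(snvs: Sequence[SnvRecord]) -> list[SnvRecord]:
    """Keep one record per (chrom, pos) site, first occurrence wins."""
    seen: set[tuple[str, int]] = set()
    out = []
    for snv in snvs:
        key = (normalize_chrom(snv.chrom), snv.pos)
        if key not in seen:
            seen.add(key)
            out.append(snv)
    return out


def scan(
    elements: Sequence[HervElement],
    snvs: Sequence[SnvRecord],
    background: BackgroundModel,
    config: ScanConfig = ScanConfig(),
) -> list[ElementTestResult]:
    """Test every element with at least ``min_observed_to_test`` variants.

    ``snvs`` must already be restricted to ``background.region_class``
    (classification is the caller's step). Results come back sorted by
    ascending direction-matched p-value. Direction is over iff n_O > n_E,
    under iff n_O < n_E; exact ties are "equal" and never significant.
    """
    if not elements:
        return []
    counted = collapse_sites(snvs) if config.count_mode == "sites" else list(snvs)
    counts, _ = assign_snvs_to_elements(counted, elements)
    tested = [e for e in elements if counts[e.element_id] >= config.min_observed_to_test]
    n_tests = len(tested) if config.n_tests == "auto" else int(config.n_tests)
    if not tested:
        return []
    cutoff = bonferroni_threshold(config.alpha, n_tests)

    L = background.total_bases_L
    N = background.total_snvs_N
    results: list[ElementTestResult] = []
    for element in tested:
        n_F = element.length
        n_O = counts[element.element_id]
        p_F = n_F / L
        n_E = N * p_F
        n_O_capped = min(n_O, N)  # overlapping elements can double-count past N
        p_upper, p_lower = _tails(n_O_capped, N, min(p_F, 1.0), config.tail_mode)
        if n_O > n_E:
            direction = Direction.OVER
        elif n_O < n_E:
            direction = Direction.UNDER
        else:
            direction = Direction.EQUAL
        if direction is Direction.OVER:
            p_matched = p_upper
        elif direction is Direction.UNDER:
            p_matched = p_lower
        else:
            p_matched = min(p_upper, p_lower)
        if config.two_sided:
            p_matched = min(1.0, 2.0 * p_matched)
        significant = direction is not Direction.EQUAL and p_matched < cutoff
        results.append(
            ElementTestResult(
                element_id=element.element_id,
                n_F=n_F,
                n_O=n_O,
                p_F=p_F,
                n_E=n_E,
                p_upper=p_upper,
                p_lower=p_lower,
                direction=direction,
                alpha_adjusted=cutoff,
                significant=significant,
                element=element,
            )
        )
    results.sort(key=lambda r: (r.p_matched, r.element_id))
    return results


def manhattan_table(results: Sequence[ElementTestResult]) -> list[dict]:
    """Plot-ready rows: chromosome, element midpoint, -log10 matched p."""
    rows = []
    for r in results:
        if r.element is None:
            continue
        iv = r.element.interval
        p = max(r.p_matched, 5e-324)
        rows.append(
            {
                "chrom": iv.chrom,
                "midpoint": (iv.start + iv.end) // 2,
                "neg_log10_p": -math.log10(p),
                "element_id": r.element_id,
                "direction": r.direction.value,
            }
        )
    return rows


def fragment_ratio_scan(
    region_intervals: Sequence[GenomicInterval],
    snvs: Sequence[SnvRecord],
    fragment_size: int = 1000,
    n_fragments: int = 1000,
    seed: int = 0,
) -> FragmentScanResult:
    """Sample fixed-width windows inside the region and measure SNV density.

    Windows are placed uniformly at random (with replacement) among all
    placements that fit inside a single region interval, which is the
    rejection rule "resample windows crossing a boundary" evaluated
    directly. Deterministic for a fixed seed.
    """
    if fragment_size < 1:
        raise ValueError(f"fragment_size must be >= 1, got {fragment_size}")
    if n_fragments < 1:
        raise ValueError(f"n_fragments must be >= 1, got {n_fragments}")
    eligible = [iv for iv in region_intervals if iv.length >= fragment_size]
    if not eligible:
        raise ValueError(
            f"no region interval is at least fragment_size={fragment_size} bases long"
        )
    rng = np.random.default_rng(seed)
    n_placements = np.array([iv.length - fragment_size + 1 for iv in eligible], dtype=float)
    weights = n_placements / n_placements.sum()
    which = rng.choice(len(eligible), size=n_fragments, p=weights)
    offsets = rng.integers(0, n_placements[which].astype(int))

    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {normalize_chrom(iv.chrom) for iv in eligible}:
        pos = sorted(s.pos0 for s in snvs if normalize_chrom(s.chrom) == chrom)
        pos_by_chrom[chrom] = np.asarray(pos, dtype=np.int64)
    counts = []
    for k, off in zip(which, offsets):
        iv = eligible[int(k)]
        start = iv.start + int(off)
        pos = pos_by_chrom[normalize_chrom(iv.chrom)]
        counts.append(int(np.searchsorted(pos, start + fragment_size) - np.searchsorted(pos, start)))
    total = int(sum(counts))
    return FragmentScanResult(
        fragment_size=fragment_size,
        counts=tuple(counts),
        observed_ratio=total / (n_fragments * fragment_size),
        seed=seed,
    )
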