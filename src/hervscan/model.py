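"""Domain types shared by every pipeline stage.

Coordinates are 0-based half-open internally (BED convention); SNV positions
arrive 1-based (VCF convention) and are converted on access via
:attr:`SnvRecord.pos0`.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

NUCLEOTIDES = frozenset("ACGT")


class FormatError(RuntimeError):
    """A malformed input file. Carries the path and, when known, the line."""

    def __init__(self, message: str, path: Optional[str] = None, line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class Supergroup(str, enum.Enum):
    GE = "GE"
    AB = "AB"
    S = "S"
    UNCERTAIN_ERRANTIVIRUS = "UncertainErrantivirus"
    UNCLASSIFIED = "Unclassified"


# Long-form labels as they appear in supplementary annotation tables, plus the
# short class codes; matching is case-insensitive and whitespace-tolerant.
_SUPERGROUP_ALIASES: Mapping[str, Supergroup] = {
    "ge": Supergroup.GE,
    "gamma-retrovirus/epsilon-retrovirus-related": Supergroup.GE,
    "gamma-retrovirus/epsilon-retrovirus-related (ge)": Supergroup.GE,
    "class i": Supergroup.GE,
    "ab": Supergroup.AB,
    "alpha-retrovirus/beta-retrovirus-related": Supergroup.AB,
    "alpha-retrovirus/beta-retrovirus-related (ab)": Supergroup.AB,
    "class ii": Supergroup.AB,
    "s": Supergroup.S,
    "spumavirus-related": Supergroup.S,
    "spumavirus-related (s)": Supergroup.S,
    "class iii": Supergroup.S,
    "uncertainerrantivirus": Supergroup.UNCERTAIN_ERRANTIVIRUS,
    "uncertain errantivirus-like proviruses": Supergroup.UNCERTAIN_ERRANTIVIRUS,
    "uncertain errantivirus-like": Supergroup.UNCERTAIN_ERRANTIVIRUS,
    "unclassified": Supergroup.UNCLASSIFIED,
}


def parse_supergroup(label: str) -> Supergroup:
    """Map a supergroup label (short code or long form) to the enumeration.

    Unknown labels map to :attr:`Supergroup.UNCLASSIFIED`; callers that need
    to distinguish should compare the raw label first.
    """
    key = re.sub(r"\s+", " ", str(label).strip().lower()).replace("/ ", "/")
    return _SUPERGROUP_ALIASES.get(key, Supergroup.UNCLASSIFIED)


class RegionClass(str, enum.Enum):
    CODING = "coding"
    NONCODING = "noncoding"
    UNASSIGNED = "unassigned"


class Direction(str, enum.Enum):
    OVER = "over"
    UNDER = "under"
    EQUAL = "equal"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in (None, "+", "-", "unknown"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        """Membership of a 0-based position (half-open: end is excluded)."""
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class HervElement:
    """One annotated retroviral element with its taxonomy."""

    element_id: str
    interval: GenomicInterval
    group: str
    supergroup: Supergroup = Supergroup.UNCLASSIFIED
    canonical: bool = False

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group must be non-empty")
        if not isinstance(self.supergroup, Supergroup):
            raise ValueError(f"supergroup must be a Supergroup, got {self.supergroup!r}")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class SnvRecord:
    """A somatic single-nucleotide variant; ``pos`` is 1-based as in VCF."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    cancer_label: Optional[str] = None
    region_class: RegionClass = RegionClass.UNASSIGNED
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos is 1-based, got {self.pos}")
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(
                f"alleles must be single nucleotides in ACGT, got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical: {self.ref_allele}")

    @property
    def pos0(self) -> int:
        """0-based position for interval arithmetic."""
        return self.pos - 1


@dataclass(frozen=True)
class BackgroundModel:
    """Uniform null for one region class: N variant sites over L bases."""

    region_class: RegionClass
    total_bases_L: int
    total_snvs_N: int

    def __post_init__(self) -> None:
        if self.total_bases_L <= 0:
            raise ValueError(f"total_bases_L must be positive, got {self.total_bases_L}")
        if self.total_snvs_N < 0:
            raise ValueError(f"total_snvs_N must be >= 0, got {self.total_snvs_N}")

    @property
    def density(self) -> float:
        """Per-base variant density N/L."""
        return self.total_snvs_N / self.total_bases_L


def make_background(region_class: RegionClass | str, total_bases_L: int, total_snvs_N: int) -> BackgroundModel:
    """Construct the per-region-class null model.

    Raises ``ValueError`` for non-positive L or negative N.
    """
    return BackgroundModel(RegionClass(region_class), int(total_bases_L), int(total_snvs_N))


@dataclass(frozen=True)
class ElementTestResult:
    """Per-element test outcome.

    ``n_F`` is the element length in bases, ``n_O`` the observed variant
    count, ``p_F = n_F / L`` the per-site hit probability and
    ``n_E = N * p_F`` the expected count under the null.
    """

    element_id: str
    n_F: int
    n_O: int
    p_F: float
    n_E: float
    p_upper: float
    p_lower: float
    direction: Direction
    alpha_adjusted: float
    significant: bool
    element: Optional[HervElement] = None

    def __post_init__(self) -> None:
        for name, p in (("p_upper", self.p_upper), ("p_lower", self.p_lower)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} out of [0, 1]: {p}")

    @property
    def p_matched(self) -> float:
        """The tail p-value matching the observed direction."""
        if self.direction is Direction.OVER:
            return self.p_upper
        if self.direction is Direction.UNDER:
            return self.p_lower
        return min(self.p_upper, self.p_lower)


TRACK_NAMES = ("lncRNA", "intron", "TFBS", "AS", "PE", "CpG",
               "tRNA", "miRNA", "snoRNA", "enhancer", "other")


@dataclass(frozen=True)
class FunctionalTrack:
    """A named set of functional intervals (lncRNA, intron, TFBS, ...)."""

    name: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "intervals",
            tuple(sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))),
        )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted alongside a synthetic landscape."""

    seed: int
    base_rate: float
    spiked_elements: Mapping[str, float]
    cancer_mixture: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.cancer_mixture:
            total = sum(self.cancer_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cancer mixture must sum to 1, got {total}")
        for eid, mult in self.spiked_elements.items():
            if mult <= 0:
                raise ValueError(f"spike multiplier for {eid} must be > 0, got {mult}")


def sort_elements(elements: Sequence[HervElement]) -> list[HervElement]:
    """Canonical ordering by (chrom, start, end, id)."""
    return sorted(
        elements,
        key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end, e.element_id),
    )
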