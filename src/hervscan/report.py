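"""Cross-tabulations and summary tables over scan output.

Covers taxonomy/direction summaries, element-by-cancer crosstabs,
functional-track overlap (multi-count and exclusive precedence modes) and
the protein functional-site annotation join.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Any, Hashable, Mapping, Optional, Sequence

import pandas as pd

from hervscan.intervals import build_index
from hervscan.model import FunctionalTrack, SnvRecord

#: Precedence for exclusive-mode functional assignment, highest share first.
DEFAULT_PRECEDENCE = ("lncRNA", "intron", "TFBS", "AS", "PE", "CpG")

UNLABELED = "unlabeled"


@dataclass(frozen=True)
class GroupSummary:
    """Count and share of one key value within a grouping universe."""

    key: Hashable
    count: int
    proportion: float


@dataclass(frozen=True)
class SiteAnnotation:
    """A protein functional site: gene symbol, 1-based residue, effect text."""

    gene: str
    aa_pos: int
    effect: str

    def __post_init__(self) -> None:
        if self.aa_pos < 1:
            raise ValueError(f"aa_pos is 1-based, got {self.aa_pos}")


def _get_key(item: Any, key: str) -> Hashable:
    if isinstance(item, Mapping):
        if key not in item:
            raise ValueError(f"unknown key {key!r}")
        return item[key]
    try:
        value = getattr(item, key)
    except AttributeError:
        # fall through to the element carried by a test result
        element = getattr(item, "element", None)
        if element is not None and hasattr(element, key):
            value = getattr(element, key)
        else:
            raise ValueError(f"unknown key {key!r}") from None
    return value.value if hasattr(value, "value") and not isinstance(value, int) else value


def summarize_by_group(items: Sequence[Any], keys: str | Sequence[str]) -> list[GroupSummary]:
    """Counts and proportions per key value, ordered by descending count.

    ``items`` may be test results, SNV records, dataclasses or mappings;
    ``keys`` is a field name or a list of them (grouped jointly). Enum
    values are flattened to their string form. Raises ValueError for a key
    no item carries.
    """
    if isinstance(keys, str):
        keys = [keys]
    if not items:
        return []
    counter: Counter = Counter()
    for item in items:
        values = tuple(_get_key(item, k) for k in keys)
        counter[values[0] if len(values) == 1 else values] += 1
    total = sum(counter.values())
    summaries = [
        GroupSummary(key=k, count=c, proportion=c / total) for k, c in counter.items()
    ]
    summaries.sort(key=lambda g: (-g.count, str(g.key)))
    return summaries


def percent(part: int | float, whole: int | float, decimals: int = 1) -> float:
    """Percentage of ``part`` in ``whole`` rounded to ``decimals`` places.

    ``decimals=0`` mirrors integer-percent report styles (still a float).
    """
    if whole == 0:
        raise ValueError("whole must be non-zero")
    return round(100.0 * part / whole, decimals)


def cancer_crosstab(
    assignments: Sequence[tuple[Hashable, Optional[str]]],
) -> pd.DataFrame:
    """Count matrix (row key x cancer label) from per-SNV assignments.

    Each assignment pairs a row key (element id, group, ...) with the SNV's
    cancer label; ``None`` aggregates under "unlabeled". Row/column sums
    equal the number of assignments.
    """
    if not assignments:
        return pd.DataFrame()
    rows = [key for key, _ in assignments]
    cols = [label if label is not None else UNLABELED for _, label in assignments]
    table = pd.crosstab(pd.Series(rows, name="key"), pd.Series(cols, name="cancer_label"))
    return table.sort_index(axis=0).sort_index(axis=1)


def crosstab_to_tidy(table: pd.DataFrame) -> pd.DataFrame:
    """Long-form (key, cancer_label, count) rows for external plotting."""
    if table.empty:
        return pd.DataFrame(columns=["key", "cancer_label", "count"])
    tidy = table.stack().rename("count").reset_index()
    return tidy[tidy["count"] > 0].reset_index(drop=True)


def functional_overlap(
    snvs: Sequence[SnvRecord],
    tracks: Sequence[FunctionalTrack],
    mode: str = "exclusive",
    precedence: Optional[Sequence[str]] = None,
) -> tuple[dict[str, int], list[list[str]], int]:
    """Overlap SNVs with functional tracks.

    multi mode counts an SNV once per overlapped track; exclusive mode
    assigns each SNV only to its highest-precedence overlapped track.
    Returns (per-track counts, per-SNV assigned categories, count of SNVs
    overlapping no track).
    """
    if mode not in ("multi", "exclusive"):
        raise ValueError(f"mode must be 'multi' or 'exclusive', got {mode!r}")
    track_names = [t.name for t in tracks]
    if mode == "exclusive":
        order = list(precedence) if precedence is not None else list(DEFAULT_PRECEDENCE)
        missing = [n for n in track_names if n not in order]
        if missing:
            raise ValueError(f"precedence does not cover track(s): {missing}")
        rank = {name: i for i, name in enumerate(order)}
    indexes = {t.name: build_index(t.intervals) for t in tracks}
    counts: dict[str, int] = {n: 0 for n in track_names}
    per_snv: list[list[str]] = []
    n_none = 0
    for snv in snvs:
        hits = [n for n in track_names if indexes[n].query_point(snv.chrom, snv.pos0)]
        if not hits:
            n_none += 1
            per_snv.append([])
            continue
        if mode == "exclusive":
            hits = [min(hits, key=lambda n: rank[n])]
        for n in hits:
            counts[n] += 1
        per_snv.append(hits)
    return counts, per_snv, n_none


def annotate_sites(
    variants: Sequence[Any],
    site_table: Sequence[SiteAnnotation],
) -> list[str]:
    """Attach functional-site effect flags by (gene, residue position).

    ``variants`` need ``gene`` and ``aa_pos`` fields. Unmatched variants get
    an empty flag (rendered "-"); duplicate site rows deduplicate, multiple
    effects join with ";" in sorted order.
    """
    lookup: dict[tuple[str, int], set[str]] = {}
    for site in site_table:
        lookup.setdefault((site.gene, site.aa_pos), set()).add(site.effect)
    flags = []
    for v in variants:
        gene = v["gene"] if isinstance(v, Mapping) else v.gene
        aa_pos = v["aa_pos"] if isinstance(v, Mapping) else v.aa_pos
        effects = lookup.get((str(gene), int(aa_pos)), set())
        flags.append(";".join(sorted(effects)))
    return flags


def read_site_table(path: str) -> list[SiteAnnotation]:
    """TSV with columns gene, aa_pos, effect."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("gene", "aa_pos", "effect"):
        if col not in df.columns:
            raise ValueError(f"site table is missing column {col!r}")
    return [
        SiteAnnotation(gene=str(r.gene), aa_pos=int(r.aa_pos), effect=str(r.effect))
        for r in df.itertuples(index=False)
    ]
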