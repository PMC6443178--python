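"""Readers and writers for every on-disk format the pipeline touches.

Dialects: element annotation and SNV tables are TSV with named headers,
variants also read/write as plain VCF 4.x, functional tracks are BED3/BED4.
TSV SNV positions are 1-based (matching VCF); BED stays 0-based half-open.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import pandas as pd
import pysam

from hervscan.model import (
    Direction,
    ElementTestResult,
    FormatError,
    FunctionalTrack,
    GenomicInterval,
    HervElement,
    RegionClass,
    SnvRecord,
    Supergroup,
    parse_supergroup,
    sort_elements,
)

logger = logging.getLogger(__name__)

_TRUTHY = {"1", "true", "yes", "y", "canonical", "canon"}
_FALSY = {"0", "false", "no", "n", "noncanonical", "non-canon", "non-canonical", "noncanon"}


@dataclass(frozen=True)
class ColumnMap:
    """Logical field -> column header mapping for tabular element inputs.

    ``coords`` declares the coordinate convention of the start/end columns;
    1-based inclusive inputs are converted to 0-based half-open on read.
    """

    element_id: str = "element_id"
    chrom: str = "chrom"
    start: str = "start"
    end: str = "end"
    group: str = "group"
    supergroup: str = "supergroup"
    canonical: str = "canonical"
    coords: Literal["0-halfopen", "1-inclusive"] = "0-halfopen"

    def required(self) -> dict[str, str]:
        return {
            "element_id": self.element_id,
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
        }


def _parse_canonical(value, path: str, line: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise FormatError(f"cannot parse canonical flag {value!r}", path=path, line=line)


def read_herv_table(path: str, column_map: ColumnMap = ColumnMap()) -> list[HervElement]:
    """Read an element annotation TSV; returns elements sorted by (chrom, start).

    Unknown supergroup strings map to Unclassified with a logged warning;
    a missing required column or an empty/inverted span is a FormatError
    that names the offender.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for logical, header in column_map.required().items():
        if header not in df.columns:
            raise FormatError(f"missing required column {header!r} (field {logical})", path=path)
    elements: list[HervElement] = []
    offset = 1 if column_map.coords == "1-inclusive" else 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rec = dict(zip(df.columns, row))
        start = int(rec[column_map.start]) - offset
        end = int(rec[column_map.end])
        if end <= start:
            raise FormatError(
                f"element {rec[column_map.element_id]!r}: end ({end}) <= start ({start})",
                path=path,
                line=line,
            )
        raw_sg = rec.get(column_map.supergroup)
        if raw_sg is None or pd.isna(raw_sg):
            supergroup = Supergroup.UNCLASSIFIED
        else:
            supergroup = parse_supergroup(raw_sg)
            if supergroup is Supergroup.UNCLASSIFIED and str(raw_sg).strip().lower() != "unclassified":
                logger.warning("%s:%d unknown supergroup %r, mapped to Unclassified", path, line, raw_sg)
        raw_canon = rec.get(column_map.canonical)
        canonical = (
            _parse_canonical(raw_canon, path, line)
            if raw_canon is not None and not pd.isna(raw_canon)
            else False
        )
        group = rec.get(column_map.group) or "unknown"
        elements.append(
            HervElement(
                element_id=str(rec[column_map.element_id]),
                interval=GenomicInterval(str(rec[column_map.chrom]), start, end),
                group=str(group),
                supergroup=supergroup,
                canonical=canonical,
            )
        )
    return sort_elements(elements)


def write_herv_table(elements: Sequence[HervElement], path: str) -> None:
    """Write elements as 0-based half-open TSV readable by read_herv_table."""
    df = pd.DataFrame(
        {
            "element_id": [e.element_id for e in elements],
            "chrom": [e.interval.chrom for e in elements],
            "start": [e.interval.start for e in elements],
            "end": [e.interval.end for e in elements],
            "group": [e.group for e in elements],
            "supergroup": [e.supergroup.value for e in elements],
            "canonical": [int(e.canonical) for e in elements],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# VCF INFO values may not contain whitespace; free-text cancer labels are
# percent-encoded on write and decoded on read (VCF 4.3 escaping).
def _vcf_encode(text: str) -> str:
    return urllib.parse.quote(text, safe="")


def _vcf_decode(text: str) -> str:
    return urllib.parse.unquote(text)


def _read_snvs_vcf(path: str, default_region_class: RegionClass) -> list[SnvRecord]:
    records: list[SnvRecord] = []
    skipped = 0
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF: {exc}", path=path) from exc
    with vcf:
        has_cancer = "CANCER" in vcf.header.info
        has_sample = "SAMPLE" in vcf.header.info
        for rec in vcf:
            cancer = rec.info.get("CANCER") if has_cancer else None
            if isinstance(cancer, tuple):
                cancer = cancer[0]
            cancer = _vcf_decode(str(cancer)) if cancer is not None else None
            sample = rec.info.get("SAMPLE") if has_sample else None
            if isinstance(sample, tuple):
                sample = sample[0]
            sample = _vcf_decode(str(sample)) if sample is not None else None
            ref = rec.ref or ""
            for alt in rec.alts or ():
                if len(ref) != 1 or len(alt) != 1 or ref == alt or alt not in "ACGT" or ref not in "ACGT":
                    skipped += 1
                    continue
                records.append(
                    SnvRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        cancer_label=cancer,
                        region_class=default_region_class,
                        sample_id=sample,
                    )
                )
    if skipped:
        logger.info("%s: skipped %d non-SNV allele(s) (indels/MNVs/symbolic)", path, skipped)
    return records


def _read_snvs_tsv(path: str, default_region_class: RegionClass) -> list[SnvRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}", path=path)
    records: list[SnvRecord] = []
    skipped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        ref, alt = str(rec["ref"]), str(rec["alt"])
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            skipped += 1
            continue
        cancer = rec.get("cancer_label")
        cancer = None if cancer is None or pd.isna(cancer) else str(cancer)
        sample = rec.get("sample_id")
        sample = None if sample is None or pd.isna(sample) else str(sample)
        region = rec.get("region_class")
        region_class = (
            RegionClass(str(region))
            if region is not None and not pd.isna(region)
            else default_region_class
        )
        try:
            records.append(
                SnvRecord(
                    chrom=str(rec["chrom"]),
                    pos=int(rec["pos"]),
                    ref_allele=ref,
                    alt_allele=alt,
                    cancer_label=cancer,
                    region_class=region_class,
                    sample_id=sample,
                )
            )
        except ValueError as exc:
            raise FormatError(str(exc), path=path, line=i + 2) from exc
    if skipped:
        logger.info("%s: skipped %d non-SNV record(s)", path, skipped)
    return records


def read_snvs(
    path: str,
    format: Literal["vcf", "tsv"] = "vcf",
    default_region_class: RegionClass = RegionClass.UNASSIGNED,
) -> list[SnvRecord]:
    """Read variants from VCF 4.x or the tabular dialect.

    Multi-allelic VCF lines expand to one record per alt; non-SNV alleles
    are skipped and counted in the log. TSV positions are 1-based.
    """
    if format == "vcf":
        return _read_snvs_vcf(path, default_region_class)
    if format == "tsv":
        return _read_snvs_tsv(path, default_region_class)
    raise ValueError(f"format must be 'vcf' or 'tsv', got {format!r}")


def write_snvs_tsv(snvs: Sequence[SnvRecord], path: str) -> None:
    """1-based tabular variant dump, round-trippable through read_snvs."""
    with open(path, "w") as fh:
        fh.write("# positions are 1-based (VCF convention)\n")
        fh.write("chrom\tpos\tref\talt\tcancer_label\tregion_class\tsample_id\n")
        for s in snvs:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t"
                f"{s.cancer_label if s.cancer_label is not None else ''}\t"
                f"{s.region_class.value}\t{s.sample_id if s.sample_id is not None else ''}\n"
            )


def write_snvs_vcf(
    snvs: Sequence[SnvRecord],
    path: str,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Plain-text VCF with CANCER/SAMPLE INFO fields (percent-encoded).

    ``contig_lengths`` adds lengths to the ##contig header lines so that
    downstream stages can recover the genome size without a sidecar file.
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=CANCER,Number=1,Type=String,Description="Cancer type label">')
    header.add_line('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">')
    contigs = dict.fromkeys(s.chrom for s in snvs)
    if contig_lengths:
        for chrom in contig_lengths:
            contigs.setdefault(chrom, None)
    for chrom in contigs:
        if contig_lengths and chrom in contig_lengths:
            header.add_line(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>")
            continue
        header.add_line(f"##contig=<ID={chrom}>")
    with pysam.VariantFile(path, "w", header=header) as out:
        for s in snvs:
            rec = out.new_record(
                contig=s.chrom, start=s.pos0, stop=s.pos, alleles=(s.ref_allele, s.alt_allele)
            )
            if s.cancer_label is not None:
                rec.info["CANCER"] = _vcf_encode(s.cancer_label)
            if s.sample_id is not None:
                rec.info["SAMPLE"] = _vcf_encode(s.sample_id)
            out.write(rec)


def read_contig_lengths(path: str) -> dict[str, int]:
    """Contig lengths from a VCF header; contigs without lengths are omitted."""
    out: dict[str, int] = {}
    with pysam.VariantFile(path) as vcf:
        for name, contig in vcf.header.contigs.items():
            if contig.length is not None:
                out[name] = int(contig.length)
    return out


def read_bed_track(path: str, name: str) -> FunctionalTrack:
    """Read a BED3+ file (0-based half-open) into one named track."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED line has {len(fields)} column(s), need >= 3", path=path, line=lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"non-integer coordinates {fields[1]!r}/{fields[2]!r}", path=path, line=lineno) from exc
            if start >= end:
                raise FormatError(f"start ({start}) >= end ({end})", path=path, line=lineno)
            intervals.append(GenomicInterval(fields[0], start, end))
    return FunctionalTrack(name=name, intervals=tuple(intervals))


def write_bed(intervals: Sequence[GenomicInterval], path: str, names: Optional[Sequence[str]] = None) -> None:
    """BED3 (or BED4 when per-interval names are given)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = f"{iv.chrom}\t{iv.start}\t{iv.end}"
            if names is not None:
                row += f"\t{names[i]}"
            fh.write(row + "\n")


def read_tracks_bed4(path: str) -> list[FunctionalTrack]:
    """Read a BED4 where column 4 is the track name; one track per name."""
    by_name: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError("BED4 with a track-name column required", path=path, line=lineno)
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"start ({start}) >= end ({end})", path=path, line=lineno)
            by_name.setdefault(fields[3], []).append(GenomicInterval(fields[0], start, end))
    return [FunctionalTrack(name=n, intervals=tuple(ivs)) for n, ivs in sorted(by_name.items())]


def write_tracks_bed4(tracks: Sequence[FunctionalTrack], path: str) -> None:
    with open(path, "w") as fh:
        for track in tracks:
            for iv in track.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{track.name}\n")


RESULTS_COLUMNS = [
    "element_id", "group", "supergroup", "canonical", "chrom", "length",
    "observed", "expected", "p_upper", "p_lower", "direction", "significant",
]


def write_results_tsv(results: Sequence[ElementTestResult], path: str) -> None:
    """One row per element test; p-values in scientific notation, >= 6 s.f."""
    if results is None:
        raise ValueError("results must not be None")
    with open(path, "w") as fh:
        fh.write("\t".join(RESULTS_COLUMNS) + "\n")
        for r in results:
            e = r.element
            fh.write(
                "\t".join(
                    [
                        r.element_id,
                        e.group if e else "",
                        e.supergroup.value if e else "",
                        str(int(e.canonical)) if e else "",
                        e.interval.chrom if e else "",
                        str(r.n_F),
                        str(r.n_O),
                        f"{r.n_E:.10g}",
                        f"{r.p_upper:.9e}",
                        f"{r.p_lower:.9e}",
                        r.direction.value,
                        str(int(r.significant)),
                    ]
                )
                + "\n"
            )


def read_results_tsv(path: str, alpha_adjusted: float = float("nan")) -> list[ElementTestResult]:
    """Re-load a results TSV (for reporting stages and round-trip checks)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing result column(s) {missing}", path=path)
    out: list[ElementTestResult] = []
    for i, row in df.iterrows():
        element = None
        if row["chrom"] and not pd.isna(row["chrom"]):
            element = HervElement(
                element_id=str(row["element_id"]),
                interval=GenomicInterval(str(row["chrom"]), 0, int(row["length"])),
                group=str(row["group"]),
                supergroup=Supergroup(str(row["supergroup"])),
                canonical=bool(int(row["canonical"])),
            )
        out.append(
            ElementTestResult(
                element_id=str(row["element_id"]),
                n_F=int(row["length"]),
                n_O=int(row["observed"]),
                p_F=float("nan"),
                n_E=float(row["expected"]),
                p_upper=float(row["p_upper"]),
                p_lower=float(row["p_lower"]),
                direction=Direction(str(row["direction"])),
                alpha_adjusted=alpha_adjusted,
                significant=bool(int(row["significant"])),
                element=element,
            )
        )
    return out
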