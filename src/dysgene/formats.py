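"""Readers and writers for the alignment, interval, and phenotype files the
pipeline touches.

Every other module operates on one internal alignment representation,
:class:`AlignmentRecord`, with 0-based half-open coordinates throughout.
SAM input (1-based) is converted on ingest; PAF and BED are native 0-based.
``clip_head``/``clip_tail`` are the soft/hard-clipped base counts in
*reference orientation* (the convention SAM's CIGAR uses), so a record whose
clipped head abuts an insertion breakpoint always has the breakpoint at
``target_start`` regardless of strand.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "TEAnnotation",
    "PhenotypeRecord",
    "FormatError",
    "parse_alignments",
    "write_alignments",
    "write_bed",
    "read_phenotypes",
    "write_phenotypes",
    "phenotypes_to_frame",
]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned block of one read against one target sequence.

    ``mate`` is 1 or 2 for paired-end reads, 0 for unpaired/long reads.
    ``read_start``/``read_end`` are coordinates on the reference-oriented
    read (i.e. ``read_start == clip_head``).
    """

    read_id: str
    mate: int
    target_id: str
    target_start: int
    target_end: int
    read_start: int
    read_end: int
    strand: str
    mapq: int
    clip_head: int
    clip_tail: int
    secondary: bool = False
    supplementary: bool = False

    def __post_init__(self) -> None:
        if not (self.target_start < self.target_end):
            raise ValueError(
                f"target_start {self.target_start} !< target_end {self.target_end}"
            )
        if not (self.read_start < self.read_end):
            raise ValueError(f"read_start {self.read_start} !< read_end {self.read_end}")
        if self.clip_head < 0 or self.clip_tail < 0:
            raise ValueError("clips must be >= 0")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def read_length(self) -> int:
        return self.clip_head + (self.read_end - self.read_start) + self.clip_tail


@dataclass(frozen=True)
class TEAnnotation:
    """A transposable-element consensus: length, ordered exon intervals
    (0-based half-open), and terminal-inverted-repeat length."""

    name: str
    length: int
    exons: tuple[tuple[int, int], ...]
    tir_length: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.tir_length < 0:
            raise ValueError("tir_length must be >= 0")
        last = -1
        for start, end in self.exons:
            if not (0 <= start < end <= self.length):
                raise ValueError(f"exon ({start},{end}) outside [0,{self.length})")
            if start < last:
                raise ValueError("exons must be sorted and disjoint")
            last = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class PhenotypeRecord:
    """One F1 female: cross identity, rearing conditions, and ovary phenotype.

    ``ovarioles`` holds one count per *functional* ovary, so its length equals
    ``ovary_count``; ``mean_ovarioles`` is None for fully atrophied females
    (they carry no ovarioles and are missing data for ovariole models).
    """

    female_id: str
    mother_genotype: str  # "M" or "P" cytotype of the mother
    father_line: str
    temperature: float  # degrees C
    age: float  # days post-eclosion
    ovary_count: int  # 0, 1 or 2 functional ovaries
    ovarioles: tuple[int, ...] = ()
    father_pe_cn: float = math.nan
    father_hobo_cn: float = math.nan

    def __post_init__(self) -> None:
        if self.ovary_count not in (0, 1, 2):
            raise ValueError(f"ovary_count must be 0/1/2, got {self.ovary_count}")
        if len(self.ovarioles) != self.ovary_count:
            raise ValueError(
                f"{len(self.ovarioles)} ovariole counts for {self.ovary_count} ovaries"
            )
        if any(v < 0 for v in self.ovarioles):
            raise ValueError("ovariole counts must be >= 0")

    @property
    def mean_ovarioles(self) -> float | None:
        if self.ovary_count == 0:
            return None
        return sum(self.ovarioles) / self.ovary_count

    @property
    def dysgenic(self) -> bool:
        """At least one atrophied ovary."""
        return self.ovary_count < 2


# ---------------------------------------------------------------------------
# alignments


def parse_alignments(path: str | Path, dialect: str) -> Iterator[AlignmentRecord]:
    """Stream :class:`AlignmentRecord` from a SAM or PAF file.

    Records with missing mandatory fields are skipped; the number skipped is
    logged. Unmapped SAM records are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "sam":
        yield from _parse_sam(path)
    elif dialect == "paf":
        yield from _parse_paf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'sam' or 'paf')")


def _parse_sam(path: Path) -> Iterator[AlignmentRecord]:
    n_skipped = 0
    try:
        handle = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise FormatError(f"malformed SAM header in {path}: {exc}") from exc
    with handle:
        for aln in handle:
            if aln.is_unmapped or aln.reference_name is None:
                n_skipped += 1
                continue
            cigar = aln.cigartuples
            if cigar is None:
                n_skipped += 1
                continue
            clip_head = 0
            i = 0
            while i < len(cigar) and cigar[i][0] in (4, 5):
                clip_head += cigar[i][1]
                i += 1
            clip_tail = 0
            j = len(cigar) - 1
            while j >= 0 and cigar[j][0] in (4, 5):
                clip_tail += cigar[j][1]
                j -= 1
            qlen = sum(n for op, n in cigar if op in (0, 1, 4, 5, 7, 8))
            aligned = qlen - clip_head - clip_tail
            if aligned <= 0:
                n_skipped += 1
                continue
            mate = 1 if aln.is_read1 else 2 if aln.is_read2 else 0
            yield AlignmentRecord(
                read_id=aln.query_name,
                mate=mate,
                target_id=aln.reference_name,
                target_start=aln.reference_start,
                target_end=aln.reference_end,
                read_start=clip_head,
                read_end=clip_head + aligned,
                strand="-" if aln.is_reverse else "+",
                mapq=aln.mapping_quality,
                clip_head=clip_head,
                clip_tail=clip_tail,
                secondary=aln.is_secondary,
                supplementary=aln.is_supplementary,
            )
    if n_skipped:
        logger.info("skipped %d unmapped/incomplete SAM records in %s", n_skipped, path)


_PAF_MIN_FIELDS = 12


def _parse_paf(path: Path) -> Iterator[AlignmentRecord]:
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < _PAF_MIN_FIELDS:
                n_skipped += 1
                continue
            try:
                qname = fields[0]
                qlen, qstart, qend = (int(fields[i]) for i in (1, 2, 3))
                strand = fields[4]
                tname = fields[5]
                tstart, tend = int(fields[7]), int(fields[8])
                mapq = int(fields[11])
            except ValueError:
                n_skipped += 1
                continue
            tags = dict(
                (f.split(":", 2)[0], f.split(":", 2)[2])
                for f in fields[12:]
                if f.count(":") >= 2
            )
            secondary = tags.get("tp") == "S"
            mate = 0
            base = qname
            if qname.endswith("/1") or qname.endswith("/2"):
                base, mate = qname[:-2], int(qname[-1])
            # PAF query coords are on the original read; convert clips to
            # reference orientation.
            if strand == "+":
                clip_head, clip_tail = qstart, qlen - qend
            else:
                clip_head, clip_tail = qlen - qend, qstart
            yield AlignmentRecord(
                read_id=base,
                mate=mate,
                target_id=tname,
                target_start=tstart,
                target_end=tend,
                read_start=clip_head,
                read_end=clip_head + (qend - qstart),
                strand=strand,
                mapq=mapq,
                clip_head=clip_head,
                clip_tail=clip_tail,
                secondary=secondary,
            )
    if n_skipped:
        logger.info("skipped %d malformed PAF lines in %s", n_skipped, path)


def write_alignments(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    dialect: str,
    target_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as SAM or PAF.

    For SAM a header is required, so ``target_lengths`` must cover every
    target (for PAF it is used for the column-7 target length, defaulting to
    the largest end seen).
    """
    records = list(records)
    if dialect == "sam":
        if target_lengths is None:
            raise ValueError("target_lengths is required for SAM output")
        _write_sam(records, Path(path), target_lengths)
    elif dialect == "paf":
        _write_paf(records, Path(path), target_lengths or {})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_sam(
    records: Sequence[AlignmentRecord], path: Path, target_lengths: dict[str, int]
) -> None:
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": n, "LN": l} for n, l in target_lengths.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.read_id
            a.reference_name = rec.target_id
            a.reference_start = rec.target_start
            a.mapping_quality = rec.mapq
            flag = 0
            if rec.strand == "-":
                flag |= 0x10
            if rec.mate:
                flag |= 0x1 | (0x40 if rec.mate == 1 else 0x80)
            if rec.secondary:
                flag |= 0x100
            if rec.supplementary:
                flag |= 0x800
            a.flag = flag
            aligned = rec.read_end - rec.read_start
            cig = []
            if rec.clip_head:
                cig.append((4, rec.clip_head))
            cig.append((0, aligned))
            if rec.clip_tail:
                cig.append((4, rec.clip_tail))
            a.cigartuples = cig
            a.query_sequence = "N" * rec.read_length
            a.query_qualities = pysam.qualitystring_to_array("I" * rec.read_length)
            out.write(a)


def _write_paf(
    records: Sequence[AlignmentRecord], path: Path, target_lengths: dict[str, int]
) -> None:
    with open(path, "w") as out:
        for rec in records:
            qlen = rec.read_length
            if rec.strand == "+":
                qstart, qend = rec.clip_head, rec.clip_head + (rec.read_end - rec.read_start)
            else:
                qend = qlen - rec.clip_head
                qstart = rec.clip_tail
            name = rec.read_id + (f"/{rec.mate}" if rec.mate else "")
            tlen = target_lengths.get(rec.target_id, rec.target_end)
            alen = rec.target_end - rec.target_start
            fields = [
                name,
                qlen,
                qstart,
                qend,
                rec.strand,
                rec.target_id,
                tlen,
                rec.target_start,
                rec.target_end,
                alen,
                alen,
                rec.mapq,
            ]
            if rec.secondary:
                fields.append("tp:A:S")
            out.write("\t".join(str(f) for f in fields) + "\n")


# ---------------------------------------------------------------------------
# BED


def write_bed(sites: Sequence, path: str | Path) -> None:
    """Write insertion sites as BED3+ (contig, pos, pos+1, line_id, support,
    precision), sorted by contig then position."""
    rows = sorted(sites, key=lambda s: (s.contig, s.position))
    with open(path, "w") as out:
        for s in rows:
            out.write(
                f"{s.contig}\t{s.position}\t{s.position + 1}\t"
                f"{s.line_id}\t{s.support}\t{s.precision}\n"
            )


# ---------------------------------------------------------------------------
# phenotype CSV

PHENOTYPE_COLUMNS = [
    "female_id",
    "mother_genotype",
    "father_line",
    "father_pe_cn",
    "father_hobo_cn",
    "temperature",
    "age",
    "ovary_count",
    "ovarioles_left",
    "ovarioles_right",
]

_REQUIRED = {
    "female_id",
    "mother_genotype",
    "father_line",
    "temperature",
    "age",
    "ovary_count",
    "ovarioles_left",
    "ovarioles_right",
}


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype CSV into records, validating ovary counts.

    Ovariole cells must be empty exactly for atrophied ovaries: a female with
    ovary_count 0 has both cells blank, with 1 only the left cell filled.
    """
    records: list[PhenotypeRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = _REQUIRED - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"phenotype CSV missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, 2):
            try:
                ovary_count = int(row["ovary_count"])
            except ValueError as exc:
                raise FormatError(f"row {i}: bad ovary_count {row['ovary_count']!r}") from exc
            if ovary_count not in (0, 1, 2):
                raise FormatError(
                    f"row {i} (female {row['female_id']}): ovary_count "
                    f"{ovary_count} outside {{0,1,2}}"
                )
            cells = [row["ovarioles_left"].strip(), row["ovarioles_right"].strip()]
            filled = [c for c in cells if c != ""]
            if len(filled) != ovary_count:
                raise FormatError(
                    f"row {i} (female {row['female_id']}): {len(filled)} ovariole "
                    f"values for ovary_count {ovary_count}"
                )
            records.append(
                PhenotypeRecord(
                    female_id=row["female_id"],
                    mother_genotype=row["mother_genotype"],
                    father_line=row["father_line"],
                    temperature=float(row["temperature"]),
                    age=float(row["age"]),
                    ovary_count=ovary_count,
                    ovarioles=tuple(int(c) for c in filled),
                    father_pe_cn=float(row["father_pe_cn"]) if row.get("father_pe_cn") else math.nan,
                    father_hobo_cn=float(row["father_hobo_cn"]) if row.get("father_hobo_cn") else math.nan,
                )
            )
    return records


def write_phenotypes(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PHENOTYPE_COLUMNS)
        for r in records:
            cells = ["", ""]
            for k, v in enumerate(r.ovarioles):
                cells[k] = str(v)
            writer.writerow(
                [
                    r.female_id,
                    r.mother_genotype,
                    r.father_line,
                    "" if math.isnan(r.father_pe_cn) else f"{r.father_pe_cn:g}",
                    "" if math.isnan(r.father_hobo_cn) else f"{r.father_hobo_cn:g}",
                    f"{r.temperature:g}",
                    f"{r.age:g}",
                    r.ovary_count,
                    cells[0],
                    cells[1],
                ]
            )


def phenotypes_to_frame(records: Sequence[PhenotypeRecord]):
    """Tabulate records for model fitting.

    Adds derived columns used throughout the statistics module: ``mother_M``
    (1 for M-cytotype mothers), ``father_type`` (P if the father carries at
    least half a copy), ``cross`` label, and ``mean_ovarioles``.
    """
    import pandas as pd

    rows = []
    for r in records:
        father_type = (
            "P" if (not math.isnan(r.father_pe_cn) and r.father_pe_cn >= 0.5) else "M"
        )
        rows.append(
            {
                "female_id": r.female_id,
                "mother_genotype": r.mother_genotype,
                "father_line": r.father_line,
                "father_pe_cn": r.father_pe_cn,
                "father_hobo_cn": r.father_hobo_cn,
                "temperature": r.temperature,
                "age": r.age,
                "ovary_count": r.ovary_count,
                "mean_ovarioles": r.mean_ovarioles,
                "mother_M": 1.0 if r.mother_genotype == "M" else 0.0,
                "father_type": father_type,
                "cross": f"{r.mother_genotype}x{father_type}",
                "dysgenic": r.dysgenic,
            }
        )
    return pd.DataFrame(rows)
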