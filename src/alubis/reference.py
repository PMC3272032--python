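"""Converted-reference construction, annotation loading, and flank extraction.

The mapping stage works in two conversion spaces: a C->T ("CT") space for
reads originating on the plus strand and a G->A ("GA") space for the
reverse complement.  Alu-anchored reads carry a 5' genomic flank followed
by the 5' end of an Alu element; :func:`extract_flank` masks the Alu
portion by local alignment against converted consensus heads and retains
flanks of at least ``min_flank`` bases (default 40).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path

from alubis._align import (
    convert_ct,
    convert_ga,
    encode_bisulfite_ref,
    make_aligner,
)

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


class ReferenceError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class ConvertedReference:
    """In-silico bisulfite-converted genome in both conversion spaces."""

    source: dict[str, str]
    ct: dict[str, str]
    ga: dict[str, str]
    source_id: str = "genome"

    def converted_positions(self, chrom: str, space: str = "CT") -> list[int]:
        """Positions that differ from the source in the given space."""
        base = "C" if space == "CT" else "G"
        seq = self.source[chrom]
        return [i for i, b in enumerate(seq) if b == base]


def convert_reference(genome: dict[str, str], source_id: str = "genome") -> ConvertedReference:
    """Build CT-space (C->T) and GA-space (G->A) copies of every chromosome."""
    ct: dict[str, str] = {}
    ga: dict[str, str] = {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        bad = next((i for i, b in enumerate(seq) if b not in _VALID), None)
        if bad is not None:
            raise ReferenceError(
                f"non-IUPAC character {seq[bad]!r} at {chrom}:{bad}"
            )
        ct[chrom] = convert_ct(seq)
        ga[chrom] = convert_ga(seq)
    return ConvertedReference(source=dict(genome), ct=ct, ga=ga, source_id=source_id)


@dataclass(frozen=True)
class AluAnnotation:
    chrom: str
    start: int
    end: int
    family: str
    strand: str = "+"

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the element's 5' terminus."""
        return self.start if self.strand == "+" else self.end


class AluAnnotationTable:
    """Sorted, per-chromosome interval table with nearest-neighbour queries."""

    def __init__(self, records: list[AluAnnotation] | None = None):
        self.records: list[AluAnnotation] = []
        self._by_chrom: dict[str, list[AluAnnotation]] = {}
        self._starts: dict[str, list[int]] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, rec: AluAnnotation) -> None:
        if rec.start >= rec.end:
            raise AnnotationError(f"interval end <= start: {rec}")
        if not rec.family:
            raise AnnotationError(f"empty family label: {rec}")
        self.records.append(rec)
        self._by_chrom.setdefault(rec.chrom, [])
        recs = self._by_chrom[rec.chrom]
        starts = self._starts.setdefault(rec.chrom, [])
        i = bisect.bisect_left(starts, rec.start)
        recs.insert(i, rec)
        starts.insert(i, rec.start)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def nearest(self, chrom: str, pos: int) -> tuple[AluAnnotation | None, int | None]:
        """Record minimizing distance to ``pos`` (0 if pos inside interval).

        Returns ``(None, None)`` on an empty table or unknown chromosome.
        The distance is unsigned.
        """
        recs = self._by_chrom.get(chrom)
        if not recs:
            return None, None
        starts = self._starts[chrom]
        i = bisect.bisect_right(starts, pos)
        best: AluAnnotation | None = None
        best_d: int | None = None
        for rec in recs[max(0, i - 8) : i + 8]:
            if rec.start <= pos < rec.end:
                d = 0
            else:
                d = min(abs(pos - rec.start), abs(pos - (rec.end - 1)))
            if best_d is None or d < best_d:
                best, best_d = rec, d
        return best, best_d

    def nearest_five_prime(self, chrom: str, pos: int) -> tuple[AluAnnotation | None, int | None]:
        """Record whose 5' boundary is closest to ``pos`` (signed: boundary - pos)."""
        recs = self._by_chrom.get(chrom)
        if not recs:
            return None, None
        best: AluAnnotation | None = None
        best_d: int | None = None
        for rec in recs:
            d = rec.five_prime - pos
            if best_d is None or abs(d) < abs(best_d):
                best, best_d = rec, d
        return best, best_d

    def overlapping(self, chrom: str, start: int, end: int) -> list[AluAnnotation]:
        return [
            rec
            for rec in self._by_chrom.get(chrom, [])
            if rec.start < end and rec.end > start
        ]


def _parse_bed_line(line: str, lineno: int) -> AluAnnotation:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        raise AnnotationError(f"line {lineno}: expected >=3 BED columns, got {len(parts)}")
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: non-integer coordinate") from exc
    if end <= start:
        raise AnnotationError(f"line {lineno}: end <= start ({start}, {end})")
    family = parts[3] if len(parts) > 3 and parts[3] else "Alu"
    strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
    return AluAnnotation(parts[0], start, end, family, strand)


def _parse_repeatmasker_line(line: str, lineno: int) -> AluAnnotation | None:
    # RepeatMasker .out dialect: whitespace-separated, 1-based inclusive
    # coordinates in columns 6-7, strand in column 9 ('+' or 'C'), repeat
    # name in column 10.
    parts = line.split()
    if not parts or not parts[0].lstrip("-").isdigit():
        return None  # header / separator line
    if len(parts) < 11:
        raise AnnotationError(f"line {lineno}: truncated RepeatMasker record")
    try:
        start = int(parts[5]) - 1
        end = int(parts[6])
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: non-integer coordinate") from exc
    if end <= start:
        raise AnnotationError(f"line {lineno}: end <= start")
    strand = "-" if parts[8] == "C" else "+"
    return AluAnnotation(parts[4], start, end, parts[9], strand)


def load_annotations(path: str | Path, fmt: str = "bed") -> AluAnnotationTable:
    """Load a repeat annotation table from BED or RepeatMasker-style text."""
    table = AluAnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            if fmt == "bed":
                table.add(_parse_bed_line(line, lineno))
            elif fmt == "repeatmasker":
                rec = _parse_repeatmasker_line(line, lineno)
                if rec is not None:
                    table.add(rec)
            else:
                raise ValueError(f"unknown annotation format: {fmt}")
    logger.info("loaded %d repeat annotations from %s", len(table), path)
    return table


@dataclass(frozen=True)
class FlankExtract:
    read_id: str
    flank_seq: str
    alu_seq: str
    junction_offset: int
    library_id: str = ""
    consensus_hit: str = ""
    hit_score: float = 0.0


@dataclass(frozen=True)
class RejectedRead:
    read_id: str
    reason: str  # "no_alu" | "short_flank"


def prepare_masking_set(
    consensus: dict[str, str], head_length: int = 150
) -> dict[str, str]:
    """Encode consensus 5' heads for conversion-aware local alignment."""
    if not consensus:
        raise ValueError("empty consensus set")
    return {
        name: encode_bisulfite_ref(seq[:head_length].upper())
        for name, seq in consensus.items()
    }


def extract_flank(
    read_id: str,
    read_seq: str,
    masking_set: dict[str, str],
    min_flank: int = 40,
    score_threshold: float = 25.0,
    library_id: str = "",
) -> FlankExtract | RejectedRead:
    """Mask the Alu portion of a read and keep its 5' genomic flank.

    The best local alignment of any encoded consensus head against the
    read defines the junction; everything from the alignment start to the
    read end is treated as Alu sequence.
    """
    if not masking_set:
        raise ValueError("empty consensus masking set")
    read_seq = read_seq.upper()
    aligner = make_aligner(mode="local", bisulfite=True)
    best_score = float("-inf")
    best_start = None
    best_name = ""
    for name, encoded in masking_set.items():
        alns = aligner.align(read_seq, encoded)
        if len(alns) == 0:
            continue
        aln = alns[0]
        if aln.score > best_score:
            t_blocks = aln.aligned[0]
            if len(t_blocks) == 0:
                continue
            best_score = aln.score
            best_start = int(t_blocks[0][0])
            best_name = name
    if best_start is None or best_score < score_threshold:
        return RejectedRead(read_id, "no_alu")
    if best_start < min_flank:
        return RejectedRead(read_id, "short_flank")
    return FlankExtract(
        read_id=read_id,
        flank_seq=read_seq[:best_start],
        alu_seq=read_seq[best_start:],
        junction_offset=best_start,
        library_id=library_id,
        consensus_hit=best_name,
        hit_score=best_score,
    )


# --- small plain-text IO helpers -------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_fasta(path: str | Path, seqs: dict[str, str], width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_annotation_bed(path: str | Path, table: AluAnnotationTable) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in sorted(table.records, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.family}\t0\t{rec.strand}\n")
    return path
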