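"""Junction classification, clustering, novelty and genic context, and
library-level summary statistics.

A uniquely mapped flank predicts the 5' boundary of an Alu element at the
reference coordinate abutting its Alu-mask junction.  Junctions within the
adjacency window (default 10 bp) of an annotated Alu 5' boundary are the
expected, already-documented class; everything else is a putative novel
insertion, clustered by coordinate and cross-referenced against known
polymorphic-insertion tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from alubis.mapper import MappedRead
from alubis.reference import AluAnnotationTable, AnnotationError

logger = logging.getLogger(__name__)


def round_pct(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage on the reporting scale, rounded like the summary tables."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, digits)


@dataclass(frozen=True)
class JunctionCall:
    read_id: str
    library_id: str
    chrom: str
    junction_pos: int
    distance_to_nearest_alu: int | None  # signed, element-downstream positive
    verdict: str  # "known_adjacent" | "putative_novel"


def classify_junction(
    mapped_read: MappedRead,
    alu_table: AluAnnotationTable,
    adjacency_window: int = 10,
    library_id: str = "",
) -> JunctionCall:
    """Classify a uniquely mapped flank's junction against known Alus.

    The junction is the 3' end of the flank alignment in read orientation:
    the alignment end in CT (forward) space, the alignment start in GA
    (reverse-complement) space.
    """
    if mapped_read.status != "unique" or mapped_read.best is None:
        raise ValueError("classify_junction requires a uniquely mapped read")
    aln = mapped_read.best
    junction = aln.end if aln.space == "CT" else aln.start
    if len(alu_table) == 0:
        logger.warning(
            "empty Alu annotation table: every junction will be called putative_novel"
        )
        return JunctionCall(
            mapped_read.read_id, library_id, aln.chrom, junction, None, "putative_novel"
        )
    rec, signed = alu_table.nearest_five_prime(aln.chrom, junction)
    if rec is None:
        distance = None
        verdict = "putative_novel"
    else:
        # express the distance in element orientation: positive when the
        # annotated element lies downstream of the junction
        distance = signed if rec.strand == "+" else -signed
        verdict = "known_adjacent" if abs(signed) <= adjacency_window else "putative_novel"
    return JunctionCall(
        mapped_read.read_id, library_id, aln.chrom, junction, distance, verdict
    )


@dataclass
class InsertionCluster:
    cluster_id: str
    chrom: str
    breakpoint_lo: int
    breakpoint_hi: int
    read_ids: list[str]
    library_counts: dict[str, int]
    novel: bool | None = None
    genic_context: str | None = None
    gene_id: str | None = None

    @property
    def libraries(self) -> set[str]:
        return set(self.library_counts)

    @property
    def n_reads(self) -> int:
        return sum(self.library_counts.values())

    @property
    def midpoint(self) -> int:
        return (self.breakpoint_lo + self.breakpoint_hi) // 2


def cluster_candidates(
    calls: list[JunctionCall], merge_window: int = 10
) -> list[InsertionCluster]:
    """Single-linkage merge of putative-novel junctions within the window."""
    novel = sorted(
        (c for c in calls if c.verdict == "putative_novel"),
        key=lambda c: (c.chrom, c.junction_pos),
    )
    clusters: list[InsertionCluster] = []
    current: list[JunctionCall] = []

    def _flush():
        if not current:
            return
        counts: dict[str, int] = {}
        for c in current:
            counts[c.library_id] = counts.get(c.library_id, 0) + 1
        clusters.append(
            InsertionCluster(
                cluster_id=f"cl{len(clusters) + 1:05d}",
                chrom=current[0].chrom,
                breakpoint_lo=current[0].junction_pos,
                breakpoint_hi=current[-1].junction_pos,
                read_ids=[c.read_id for c in current],
                library_counts=counts,
            )
        )

    for call in novel:
        if (
            current
            and call.chrom == current[-1].chrom
            and call.junction_pos - current[-1].junction_pos <= merge_window
        ):
            current.append(call)
        else:
            _flush()
            current = [call]
    _flush()
    return clusters


def load_simple_bed(path: str | Path) -> list[tuple[str, int, int]]:
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise AnnotationError(f"line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: non-integer coordinate") from exc
            if end <= start:
                raise AnnotationError(f"line {lineno}: end <= start")
            intervals.append((parts[0], start, end))
    return intervals


def annotate_novelty(
    clusters: list[InsertionCluster],
    known: list[tuple[str, int, int]],
    overlap_window: int = 50,
) -> list[InsertionCluster]:
    """Flag clusters with no known polymorphic insertion within the window."""
    for cl in clusters:
        cl.novel = not any(
            chrom == cl.chrom
            and start - overlap_window < cl.breakpoint_hi
            and end + overlap_window > cl.breakpoint_lo
            for chrom, start, end in known
        )
    return clusters


# --- gene models ------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def context_at(self, pos: int) -> str | None:
        if not (self.start <= pos < self.end):
            return None
        for es, ee in self.exons:
            if es <= pos < ee:
                if self.cds_start <= pos < self.cds_end:
                    return "exonic"
                if pos < self.cds_start:
                    return "utr5" if self.strand == "+" else "utr3"
                return "utr3" if self.strand == "+" else "utr5"
        return "intronic"


def load_gene_models(path: str | Path) -> list[Transcript]:
    """Load transcripts from BED12 (blocks = exons, thick span = CDS)."""
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 12:
                raise AnnotationError(f"line {lineno}: expected BED12, got {len(p)} columns")
            try:
                start, end = int(p[1]), int(p[2])
                thick_start, thick_end = int(p[6]), int(p[7])
                sizes = [int(x) for x in p[10].rstrip(",").split(",")]
                offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: malformed BED12 field") from exc
            if end <= start or len(sizes) != len(offsets):
                raise AnnotationError(f"line {lineno}: inconsistent BED12 record")
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            if any(ee <= es for es, ee in exons) or any(
                e2[0] < e1[1] for e1, e2 in zip(exons, exons[1:])
            ):
                raise AnnotationError(f"line {lineno}: unsorted or invalid exon blocks")
            transcripts.append(
                Transcript(
                    chrom=p[0], start=start, end=end,
                    strand=p[5] if p[5] in "+-" else "+",
                    gene_id=p[3], exons=exons,
                    cds_start=thick_start, cds_end=thick_end,
                )
            )
    return transcripts


_CONTEXT_RANK = {"exonic": 0, "utr5": 1, "utr3": 1, "intronic": 2}


def annotate_genic_context(
    clusters: list[InsertionCluster], transcripts: list[Transcript]
) -> list[InsertionCluster]:
    """Assign genic context by cluster midpoint, precedence exon > UTR > intron."""
    for cl in clusters:
        pos = cl.midpoint
        best: tuple[int, str, str] | None = None
        for tx in transcripts:
            if tx.chrom != cl.chrom:
                continue
            ctx = tx.context_at(pos)
            if ctx is None:
                continue
            cand = (_CONTEXT_RANK[ctx], ctx, tx.gene_id)
            if best is None or cand[0] < best[0]:
                best = cand
        if best is None:
            cl.genic_context, cl.gene_id = "intergenic", None
        else:
            cl.genic_context, cl.gene_id = best[1], best[2]
    return clusters


# --- library summary --------------------------------------------------------

@dataclass(frozen=True)
class LibraryStats:
    library_id: str
    reads_mapped: int
    regions_mapped: int
    insertion_reads: int
    insertion_regions: int

    @property
    def ratio(self) -> float:
        """Insertion regions per 100 mapped regions, rounded to 2 decimals."""
        return round(100.0 * self.insertion_regions / self.regions_mapped, 2)


def summarize_libraries(
    clusters: list[InsertionCluster],
    mapping_totals: dict[str, dict[str, int]],
    tissue_classes: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-library statistics plus the aggregate cluster report.

    ``mapping_totals`` supplies ``reads_mapped`` and ``regions_mapped`` per
    library.  A cluster contributes one region incidence to every library
    it appears in, so the incidence total can exceed the distinct cluster
    count.  ``tissue_classes`` (library -> "normal"/"tumor") enables the
    normal-and-tumor sharing percentage among multi-library clusters.
    """
    libraries_seen = sorted({lib for cl in clusters for lib in cl.libraries})
    missing = [lib for lib in libraries_seen if lib not in mapping_totals]
    if missing:
        raise KeyError(f"libraries missing from mapping_totals: {missing}")

    rows = []
    for lib in mapping_totals:
        ins_reads = sum(cl.library_counts.get(lib, 0) for cl in clusters)
        ins_regions = sum(1 for cl in clusters if lib in cl.libraries)
        stats = LibraryStats(
            library_id=lib,
            reads_mapped=mapping_totals[lib]["reads_mapped"],
            regions_mapped=mapping_totals[lib]["regions_mapped"],
            insertion_reads=ins_reads,
            insertion_regions=ins_regions,
        )
        rows.append(
            {
                "library_id": lib,
                "reads_mapped": stats.reads_mapped,
                "regions_mapped": stats.regions_mapped,
                "insertion_reads": stats.insertion_reads,
                "insertion_regions": stats.insertion_regions,
                "ratio": stats.ratio,
            }
        )
    table = pd.DataFrame(rows)

    n_clusters = len(clusters)
    multi_read = sum(1 for cl in clusters if cl.n_reads > 1)
    multi_lib = [cl for cl in clusters if len(cl.libraries) > 1]
    aggregate = {
        "n_clusters": n_clusters,
        "total_insertion_reads": int(table["insertion_reads"].sum()),
        "total_insertion_regions": int(table["insertion_regions"].sum()),
        "n_clusters_multi_read": multi_read,
        "n_clusters_multi_library": len(multi_lib),
        "pct_clusters_multi_read": round_pct(multi_read, n_clusters) if n_clusters else None,
        "pct_clusters_multi_library": round_pct(len(multi_lib), n_clusters) if n_clusters else None,
        "n_clusters_novel": sum(1 for cl in clusters if cl.novel),
        "n_clusters_intronic": sum(1 for cl in clusters if cl.genic_context == "intronic"),
    }
    if n_clusters and any(cl.genic_context is not None for cl in clusters):
        aggregate["pct_clusters_intronic"] = round_pct(
            aggregate["n_clusters_intronic"], n_clusters
        )
    if tissue_classes is not None and multi_lib:
        shared = sum(
            1
            for cl in multi_lib
            if {"normal", "tumor"}
            <= {tissue_classes.get(lib, "unknown") for lib in cl.libraries}
        )
        aggregate["n_multi_library_shared_normal_tumor"] = shared
        aggregate["pct_multi_library_shared_normal_tumor"] = round_pct(
            shared, len(multi_lib)
        )
    return table, aggregate


# --- cluster table IO -------------------------------------------------------

def write_clusters_tsv(path: str | Path, clusters: list[InsertionCluster]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tchrom\tbreakpoint_lo\tbreakpoint_hi\tn_reads\t"
            "libraries\tlibrary_counts\tnovel\tgenic_context\tgene_id\tread_ids\n"
        )
        for cl in clusters:
            counts = ";".join(f"{k}:{v}" for k, v in sorted(cl.library_counts.items()))
            fh.write(
                f"{cl.cluster_id}\t{cl.chrom}\t{cl.breakpoint_lo}\t{cl.breakpoint_hi}\t"
                f"{cl.n_reads}\t{','.join(sorted(cl.libraries))}\t{counts}\t"
                f"{cl.novel}\t{cl.genic_context or '.'}\t{cl.gene_id or '.'}\t"
                f"{','.join(cl.read_ids)}\n"
            )


def write_clusters_bed(path: str | Path, clusters: list[InsertionCluster]) -> None:
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(
                f"{cl.chrom}\t{cl.breakpoint_lo}\t{cl.breakpoint_hi + 1}\t"
                f"{cl.cluster_id}\t{cl.n_reads}\t+\n"
            )
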