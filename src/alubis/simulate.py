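"""Synthetic genomes, TPRT insertion events, methylomes, and bisulfite
amplicon reads with a complete truth table.

The TPRT model nicks the genome at a 6-mer within Hamming distance 1 of
TTAAAA, duplicates a target-site segment (the TSD), and inserts an
optionally 5'-truncated subfamily consensus followed by a poly-A tail
between the two TSD copies.  Hemizygous events keep an unmodified second
haplotype.  Only plus-strand (C->T) bisulfite chemistry is simulated: each
read molecule is converted on its own strand, with methylated CpG
cytosines protected according to the per-CpG methylome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from alubis._align import revcomp
from alubis.calling import Transcript
from alubis.consensus import DEFAULT_CONSENSUS
from alubis.reference import AluAnnotation, AluAnnotationTable

logger = logging.getLogger(__name__)

NICK_MOTIF = "TTAAAA"
BASES = np.array(list("ACGT"))


class PlacementError(RuntimeError):
    pass


class NickSiteError(RuntimeError):
    pass


@dataclass(frozen=True)
class MethylationProfile:
    default_level: float = 0.8
    element_level: float = 0.907
    island_level: float = 0.0
    n_islands: int = 0
    island_length: int = 500
    overrides: tuple[tuple[str, int, int, float], ...] = ()

    def __post_init__(self):
        for frac in (self.default_level, self.element_level, self.island_level):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"methylation level outside [0,1]: {frac}")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 100_000
    gc_fraction: float = 0.41
    n_background_alus: int = 10
    n_novel_insertions: int = 5
    tsd_length_range: tuple[int, int] = (4, 17)
    polya_length_range: tuple[int, int] = (11, 45)
    truncation_prob: float = 0.0
    methylation: MethylationProfile = field(default_factory=MethylationProfile)
    conversion_rate: float = 0.99
    error_rate: float = 0.0
    reads_per_locus: int = 3
    flank_length_range: tuple[int, int] = (40, 250)
    alu_portion_range: tuple[int, int] = (80, 160)
    hemizygous_prob: float = 0.5
    allele_ratio: float = 0.5
    library_ids: tuple[str, ...] = ("L1",)
    chrom_name: str = "sim1"
    background_divergence: float = 0.0
    min_site_spacing: int = 700

    def __post_init__(self):
        for name in ("tsd_length_range", "polya_length_range",
                     "flank_length_range", "alu_portion_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} is empty or negative: ({lo}, {hi})")
        for name in ("gc_fraction", "truncation_prob", "conversion_rate",
                     "error_rate", "hemizygous_prob", "allele_ratio",
                     "background_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0,1]: {v}")
        if not self.library_ids:
            raise ValueError("library_ids must be nonempty")


@dataclass(frozen=True)
class TruthInsertion:
    locus_id: str
    chrom: str
    breakpoint: int  # 0-based nick position in the reference
    insertion_point: int  # breakpoint + TSD length: predicted element 5' boundary
    tsd_seq: str
    polya_length: int
    subfamily: str
    truncated_5p: int
    zygosity: str  # "hemizygous" | "homozygous"
    body_length: int
    methylation_probs: tuple[float, ...] = ()

    @property
    def inserted_length(self) -> int:
        return self.body_length + self.polya_length + len(self.tsd_seq)


@dataclass(frozen=True)
class ElementSite:
    locus_id: str
    chrom: str
    start: int  # element body start in haplotype coordinates
    body_end: int
    tail_end: int  # poly-A end = start of the downstream TSD copy
    strand: str
    family: str
    kind: str  # "novel" | "background"


@dataclass
class HapGenome:
    name: str
    seqs: dict[str, str]
    elements: dict[str, ElementSite]
    empty_sites: dict[str, int] = field(default_factory=dict)


@dataclass
class TprtSimulation:
    reference: dict[str, str]
    truths: list[TruthInsertion]
    haplotypes: dict[str, HapGenome]

    def hap_annotation(self, hap: str = "hapA") -> AluAnnotationTable:
        table = AluAnnotationTable()
        for site in self.haplotypes[hap].elements.values():
            table.add(
                AluAnnotation(site.chrom, site.start, site.tail_end or site.body_end,
                              site.family, site.strand)
            )
        return table


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[int(rng.integers(3))]
    return "".join(chars)


def make_reference(
    config: SimulationConfig,
    consensus: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], AluAnnotationTable]:
    """Random genome seeded with full-length background Alu copies."""
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    consensus = consensus or DEFAULT_CONSENSUS
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom = config.chrom_name
    seq = list(_random_sequence(rng, config.genome_length, config.gc_fraction))

    elem_len = max(len(s) for s in consensus.values())
    buffer = config.flank_length_range[1] + 60
    needed = config.n_background_alus * (elem_len + 2 * buffer) + 2000
    if config.n_background_alus and needed > config.genome_length:
        raise PlacementError(
            f"cannot place {config.n_background_alus} background Alus of "
            f"{elem_len} bp with {buffer} bp buffers in a "
            f"{config.genome_length} bp genome (needs >= {needed} bp)"
        )
    table = AluAnnotationTable()
    placed: list[tuple[int, int]] = []
    families = sorted(consensus)
    attempts = 0
    while len(placed) < config.n_background_alus:
        attempts += 1
        if attempts > 20_000:
            raise PlacementError(
                "background Alu placement failed: genome too crowded for the "
                "requested copy number and flank buffer"
            )
        start = int(rng.integers(buffer, config.genome_length - elem_len - buffer))
        if any(start - buffer < e and start + elem_len + buffer > s for s, e in placed):
            continue
        fam = families[int(rng.integers(len(families)))]
        strand = "+" if rng.random() < 0.5 else "-"
        body = _diverge(rng, consensus[fam], config.background_divergence)
        insert = body if strand == "+" else revcomp(body)
        seq[start : start + len(insert)] = list(insert)
        placed.append((start, start + len(insert)))
        table.add(AluAnnotation(chrom, start, start + len(insert), fam, strand))
    return {chrom: "".join(seq)}, table


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def find_nick_sites(seq: str, max_mismatch: int = 1) -> list[int]:
    """Nick positions (between the TT and AAAA halves) of all 6-mer windows
    within Hamming distance ``max_mismatch`` of TTAAAA."""
    k = len(NICK_MOTIF)
    return [
        i + 2
        for i in range(len(seq) - k + 1)
        if _hamming(seq[i : i + k], NICK_MOTIF) <= max_mismatch
    ]


def _shifted(pos: int, insertions: list[tuple[int, int]]) -> int:
    """Shift a reference coordinate by insertions (point, length) left of it."""
    return pos + sum(length for point, length in insertions if point <= pos)


def simulate_tprt_insertion(
    genome: dict[str, str],
    annotation: AluAnnotationTable,
    config: SimulationConfig,
    n: int | None = None,
    consensus: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> TprtSimulation:
    """Insert ``n`` de-novo TPRT events; returns two haplotypes plus truth."""
    n = config.n_novel_insertions if n is None else n
    consensus = consensus or DEFAULT_CONSENSUS
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    chrom = config.chrom_name
    seq = genome[chrom]
    margin = config.flank_length_range[1] + 120

    eligible = [
        bp
        for bp in find_nick_sites(seq)
        if margin <= bp <= len(seq) - margin
        and all(
            bp + config.min_site_spacing <= rec.start
            or bp - config.min_site_spacing >= rec.end
            for rec in annotation
        )
    ]
    if not eligible:
        raise NickSiteError("no eligible TT/AAAA-like nick site in the genome")
    chosen: list[int] = []
    for bp in rng.permutation(eligible):
        if all(abs(bp - c) >= config.min_site_spacing for c in chosen):
            chosen.append(int(bp))
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise NickSiteError(
            f"requested {n} insertions but only {len(chosen)} mutually "
            f"spaced eligible nick sites exist"
        )
    chosen.sort()

    truths: list[TruthInsertion] = []
    families = sorted(consensus)
    for i, bp in enumerate(chosen):
        tsd_len = int(rng.integers(config.tsd_length_range[0], config.tsd_length_range[1] + 1))
        polya = int(rng.integers(config.polya_length_range[0], config.polya_length_range[1] + 1))
        fam = families[int(rng.integers(len(families)))]
        trunc = 0
        if config.truncation_prob and rng.random() < config.truncation_prob:
            trunc = int(rng.integers(1, len(consensus[fam]) // 2))
        zygosity = "hemizygous" if rng.random() < config.hemizygous_prob else "homozygous"
        truths.append(
            TruthInsertion(
                locus_id=f"ins{i + 1:03d}",
                chrom=chrom,
                breakpoint=bp,
                insertion_point=bp + tsd_len,
                tsd_seq=seq[bp : bp + tsd_len],
                polya_length=polya,
                subfamily=fam,
                truncated_5p=trunc,
                zygosity=zygosity,
                body_length=len(consensus[fam]) - trunc,
            )
        )

    haplotypes: dict[str, HapGenome] = {}
    for hap_name, keep in (
        ("hapA", lambda t: True),
        ("hapB", lambda t: t.zygosity == "homozygous"),
    ):
        events = [t for t in truths if keep(t)]
        hap_seq = seq
        for t in sorted(events, key=lambda t: -t.insertion_point):
            body = consensus[t.subfamily][t.truncated_5p :]
            segment = body + "A" * t.polya_length
            q = t.insertion_point
            hap_seq = hap_seq[:q] + segment + hap_seq[t.breakpoint :]
        ins_points = [(t.insertion_point, t.inserted_length) for t in events]
        elements: dict[str, ElementSite] = {}
        for t in events:
            shift = sum(
                length for point, length in ins_points if point < t.insertion_point
            )
            start = t.insertion_point + shift
            elements[t.locus_id] = ElementSite(
                locus_id=t.locus_id, chrom=chrom, start=start,
                body_end=start + t.body_length,
                tail_end=start + t.body_length + t.polya_length,
                strand="+", family=t.subfamily, kind="novel",
            )
        for j, rec in enumerate(annotation):
            lid = f"bg{j + 1:03d}"
            start = _shifted(rec.start, ins_points)
            elements[lid] = ElementSite(
                locus_id=lid, chrom=rec.chrom, start=start,
                body_end=start + (rec.end - rec.start),
                tail_end=start + (rec.end - rec.start),
                strand=rec.strand, family=rec.family, kind="background",
            )
        empty = {
            t.locus_id: t.insertion_point
            + sum(l for p, l in ins_points if p < t.insertion_point)
            for t in truths
            if not keep(t)
        }
        haplotypes[hap_name] = HapGenome(
            name=hap_name, seqs={chrom: hap_seq}, elements=elements, empty_sites=empty
        )

    expected = len(seq) + sum(t.inserted_length for t in truths)
    assert len(haplotypes["hapA"].seqs[chrom]) == expected, "length conservation violated"
    return TprtSimulation(reference=dict(genome), truths=truths, haplotypes=haplotypes)


class Methylome:
    """Per-CpG methylation probabilities for one genome."""

    def __init__(self, probs: dict[str, dict[int, float]]):
        self.probs = probs

    def prob(self, chrom: str, pos: int) -> float:
        return self.probs[chrom].get(pos, 0.0)

    def positions(self, chrom: str) -> list[int]:
        return sorted(self.probs[chrom])


def assign_methylome(
    seqs: dict[str, str],
    default_level: float,
    overrides: list[tuple[str, int, int, float]] | None = None,
) -> Methylome:
    """Probability for every plus-strand CpG; non-CpG cytosines get 0.

    Later overrides win over earlier ones.
    """
    probs: dict[str, dict[int, float]] = {}
    for chrom, seq in seqs.items():
        probs[chrom] = {
            i: default_level for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"
        }
    for chrom, start, end, level in overrides or []:
        if chrom not in seqs or start < 0 or end > len(seqs[chrom]) or start >= end:
            raise ValueError(
                f"override region {chrom}:{start}-{end} outside genome bounds"
            )
        if not (0.0 <= level <= 1.0):
            raise ValueError(f"override level outside [0,1]: {level}")
        for pos in list(probs[chrom]):
            if start <= pos < end:
                probs[chrom][pos] = level
    return Methylome(probs)


def bisulfite_convert_molecule(
    molecule: str,
    gpos: list[int],
    molecule_strand: str,
    hap_seq: str,
    chrom: str,
    methylome: Methylome,
    conversion_rate: float,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int]]]:
    """Convert one molecule in its own strand space.

    ``gpos[i]`` is the haplotype coordinate underlying molecule position
    ``i``.  Returns the converted sequence and the drawn per-CpG states as
    (plus-strand CpG position, 0/1) pairs.
    """
    out = list(molecule)
    states: list[tuple[int, int]] = []
    for i, base in enumerate(molecule):
        if base != "C":
            continue
        g = gpos[i]
        if molecule_strand == "+":
            is_cpg = hap_seq[g : g + 2] == "CG"
            cpg_pos = g
        else:
            is_cpg = g > 0 and hap_seq[g - 1 : g + 1] == "CG"
            cpg_pos = g - 1
        if is_cpg:
            methylated = rng.random() < methylome.prob(chrom, cpg_pos)
            states.append((cpg_pos, int(methylated)))
            if methylated:
                continue
        if rng.random() < conversion_rate:
            out[i] = "T"
    return "".join(out), states


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < error_rate)
    for i in hits:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[int(rng.integers(3))]
    return "".join(chars)


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    seq: str
    library_id: str
    locus_id: str
    haplotype: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    flank_len: int
    has_element: bool
    cpg_states: tuple[tuple[int, int], ...]


def simulate_reads(
    sim: TprtSimulation,
    methylomes: dict[str, Methylome],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    loci: list[str] | None = None,
) -> list[SimulatedRead]:
    """Alu-anchored amplicon reads: 5' genomic flank + element 5' portion.

    Hemizygous loci additionally yield empty-allele reads spanning the
    naked target site on the unmodified haplotype.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    hapA = sim.haplotypes["hapA"]
    hapB = sim.haplotypes["hapB"]
    if not hapA.elements:
        raise ValueError("no Alu element to target: simulate at least one")
    hemizygous = {t.locus_id for t in sim.truths if t.zygosity == "hemizygous"}
    target_ids = loci if loci is not None else sorted(hapA.elements)
    reads: list[SimulatedRead] = []
    counter = 0
    for locus in target_ids:
        site_a = hapA.elements[locus]
        for _ in range(config.reads_per_locus):
            lib = config.library_ids[int(rng.integers(len(config.library_ids)))]
            flank_len = int(rng.integers(config.flank_length_range[0],
                                         config.flank_length_range[1] + 1))
            portion = int(rng.integers(config.alu_portion_range[0],
                                       config.alu_portion_range[1] + 1))
            if locus in hemizygous:
                hap = hapA if rng.random() < config.allele_ratio else hapB
            else:
                hap = hapA if rng.random() < 0.5 else hapB
            chrom = site_a.chrom
            hap_seq = hap.seqs[chrom]
            if hap.name == "hapB" and locus in hap.empty_sites:
                junction = hap.empty_sites[locus]
                start = junction - flank_len
                end = min(junction + portion, len(hap_seq))
                strand = "+"
                has_element = False
            else:
                site = hap.elements[locus]
                strand = site.strand
                has_element = True
                span_len = site.tail_end - site.start
                portion = min(portion, span_len if span_len else portion)
                if strand == "+":
                    start = site.start - flank_len
                    end = min(site.start + portion, len(hap_seq))
                else:
                    start = max(site.body_end - portion, 0)
                    end = site.body_end + flank_len
            if start < 0 or end > len(hap_seq):
                logger.warning(
                    "read at locus %s skipped: flank of %d bp exceeds available "
                    "sequence", locus, flank_len,
                )
                continue
            segment = hap_seq[start:end]
            if strand == "+":
                molecule = segment
                gpos = list(range(start, end))
            else:
                molecule = revcomp(segment)
                gpos = list(range(end - 1, start - 1, -1))
            converted, states = bisulfite_convert_molecule(
                molecule, gpos, strand, hap_seq, chrom,
                methylomes[hap.name], config.conversion_rate, rng,
            )
            final = _apply_errors(converted, config.error_rate, rng)
            counter += 1
            reads.append(
                SimulatedRead(
                    read_id=f"r{counter:06d}", seq=final, library_id=lib,
                    locus_id=locus, haplotype=hap.name, chrom=chrom,
                    strand=strand, span_start=start, span_end=end,
                    flank_len=flank_len, has_element=has_element,
                    cpg_states=tuple(states),
                )
            )
    return reads


def make_gene_models(
    genome_length: int,
    chrom: str,
    n_genes: int,
    rng: np.random.Generator,
) -> list[Transcript]:
    """Simple non-overlapping multi-exon transcripts with UTR margins."""
    transcripts = []
    if n_genes <= 0:
        return transcripts
    slot = genome_length // n_genes
    for g in range(n_genes):
        lo = g * slot + 200
        span = int(rng.integers(min(3000, slot // 2), min(8000, slot - 400)))
        start = lo + int(rng.integers(0, max(1, slot - span - 400)))
        end = start + span
        n_exons = int(rng.integers(3, 7))
        bounds = sorted(rng.choice(np.arange(1, span - 1), size=2 * n_exons - 2,
                                   replace=False).tolist())
        edges = [0] + bounds + [span]
        exons = tuple(
            (start + edges[2 * i], start + edges[2 * i + 1]) for i in range(n_exons)
        )
        cds_start = exons[0][1] - max(1, (exons[0][1] - exons[0][0]) // 2)
        cds_end = exons[-1][0] + max(1, (exons[-1][1] - exons[-1][0]) // 2)
        transcripts.append(
            Transcript(
                chrom=chrom, start=start, end=end,
                strand="+" if rng.random() < 0.5 else "-",
                gene_id=f"gene{g + 1:03d}", exons=exons,
                cds_start=cds_start, cds_end=cds_end,
            )
        )
    return transcripts


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: dict[str, str]
    annotation: AluAnnotationTable
    tprt: TprtSimulation
    methylomes: dict[str, Methylome]
    reads: list[SimulatedRead]
    transcripts: list[Transcript]
    islands: list[tuple[str, int, int]]

    @property
    def truths(self) -> list[TruthInsertion]:
        return self.tprt.truths


def simulate_dataset(
    config: SimulationConfig,
    consensus: dict[str, str] | None = None,
    n_genes: int = 0,
) -> SimulatedDataset:
    """Run the full generator: reference, insertions, methylome, reads."""
    consensus = consensus or DEFAULT_CONSENSUS
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in seeds]
    genome, annotation = make_reference(config, consensus, rng=rngs[0])
    tprt = simulate_tprt_insertion(
        genome, annotation, config, config.n_novel_insertions, consensus, rng=rngs[1]
    )
    chrom = config.chrom_name
    profile = config.methylation

    islands: list[tuple[str, int, int]] = []
    if profile.n_islands:
        occupied = [(rec.start, rec.end) for rec in annotation] + [
            (t.breakpoint - 300, t.insertion_point + 300) for t in tprt.truths
        ]
        tries = 0
        while len(islands) < profile.n_islands and tries < 10_000:
            tries += 1
            s = int(rngs[2].integers(500, config.genome_length - profile.island_length - 500))
            e = s + profile.island_length
            if any(s < oe + 100 and e > os - 100 for os, oe in occupied):
                continue
            occupied.append((s, e))
            islands.append((chrom, s, e))

    methylomes: dict[str, Methylome] = {}
    for hap in tprt.haplotypes.values():
        ins_points = [
            (t.insertion_point, t.inserted_length)
            for t in tprt.truths
            if t.locus_id in hap.elements
        ]
        overrides = [
            (c, _shifted(s, ins_points), _shifted(e, ins_points), profile.island_level)
            for c, s, e in islands
        ]
        overrides += [
            (site.chrom, site.start, max(site.tail_end, site.body_end),
             profile.element_level)
            for site in hap.elements.values()
        ]
        overrides += list(profile.overrides)
        methylomes[hap.name] = assign_methylome(
            hap.seqs, profile.default_level, overrides
        )

    reads = simulate_reads(tprt, methylomes, config, rng=rngs[3])
    transcripts = make_gene_models(config.genome_length, chrom, n_genes, rngs[4])
    return SimulatedDataset(
        config=config, reference=genome, annotation=annotation, tprt=tprt,
        methylomes=methylomes, reads=reads, transcripts=transcripts, islands=islands,
    )


# --- plain-text writers -----------------------------------------------------

def write_fastq(path: str | Path, reads: list[SimulatedRead]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
    return path


READ_TRUTH_COLUMNS = (
    "read_id", "library_id", "locus_id", "haplotype", "chrom", "strand",
    "span_start", "span_end", "flank_len", "has_element", "cpg_states",
)


def read_truth_frame(reads: list[SimulatedRead]) -> pd.DataFrame:
    rows = []
    for r in reads:
        rows.append(
            {
                "read_id": r.read_id, "library_id": r.library_id,
                "locus_id": r.locus_id, "haplotype": r.haplotype,
                "chrom": r.chrom, "strand": r.strand,
                "span_start": r.span_start, "span_end": r.span_end,
                "flank_len": r.flank_len, "has_element": int(r.has_element),
                "cpg_states": ";".join(f"{p}:{s}" for p, s in r.cpg_states),
            }
        )
    return pd.DataFrame(rows, columns=READ_TRUTH_COLUMNS)


def write_truth_insertions(path: str | Path, truths: list[TruthInsertion]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "locus_id\tchrom\tbreakpoint\tinsertion_point\ttsd_seq\t"
            "polya_length\tsubfamily\ttruncated_5p\tzygosity\tbody_length\n"
        )
        for t in truths:
            fh.write(
                f"{t.locus_id}\t{t.chrom}\t{t.breakpoint}\t{t.insertion_point}\t"
                f"{t.tsd_seq}\t{t.polya_length}\t{t.subfamily}\t{t.truncated_5p}\t"
                f"{t.zygosity}\t{t.body_length}\n"
            )
    return path


def write_gene_models_bed12(path: str | Path, transcripts: list[Transcript]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for tx in transcripts:
            sizes = ",".join(str(e - s) for s, e in tx.exons)
            offsets = ",".join(str(s - tx.start) for s, _ in tx.exons)
            fh.write(
                f"{tx.chrom}\t{tx.start}\t{tx.end}\t{tx.gene_id}\t0\t{tx.strand}\t"
                f"{tx.cds_start}\t{tx.cds_end}\t0\t{len(tx.exons)}\t{sizes}\t{offsets}\n"
            )
    return path
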