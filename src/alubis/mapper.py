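"""Multi-cycle decreasing-word-size mapping against the converted reference.

Reproduces the cycle contract of the original Megablast-based strategy:
word size starts at 100 and drops by 20 each cycle; a candidate alignment
must reach 95% identity in every cycle except the last, where acceptance
requires a best perfect match of at least 40 bp.  Reads resolved (uniquely
or ambiguously) in one cycle are never revisited.

Seeds are exact k-mers of the fully converted read against the converted
reference; identity is then computed conversion-aware against the original
reference (read T over reference C counts as a match in CT space, and the
analogous rule in GA space).  Extension is ungapped: the simulators and
oracles in this package produce substitution errors only, so gapped rescue
would never change a status and is deliberately omitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from alubis._align import convert_ct, convert_ga, revcomp
from alubis.reference import ConvertedReference

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CycleSchedule:
    word_sizes: tuple[int, ...] = (100, 80, 60, 40)
    identity_cutoffs: tuple[float, ...] = (0.95, 0.95, 0.95, 1.0)
    min_perfect_match: int = 40

    def __post_init__(self):
        if len(self.word_sizes) != len(self.identity_cutoffs):
            raise ValueError("word_sizes and identity_cutoffs must have equal length")
        if any(w2 >= w1 for w1, w2 in zip(self.word_sizes, self.word_sizes[1:])):
            raise ValueError("word sizes must be strictly decreasing")
        if any(not (0.0 < c <= 1.0) for c in self.identity_cutoffs):
            raise ValueError("identity cutoffs must lie in (0, 1]")

    @property
    def n_cycles(self) -> int:
        return len(self.word_sizes)


@dataclass(frozen=True)
class Alignment:
    read_id: str
    chrom: str
    start: int
    end: int
    space: str  # "CT" (forward) | "GA" (reverse complement)
    identity: float
    aligned_length: int
    cycle_index: int
    score: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"alignment start >= end: {self}")


@dataclass(frozen=True)
class MappedRead:
    read_id: str
    best: Alignment | None
    status: str  # "unique" | "ambiguous" | "unmapped"


class SeedIndex:
    """Exact k-mer index over the CT and GA spaces of a converted reference."""

    def __init__(self, conv_ref: ConvertedReference, word_size: int):
        if word_size < 8:
            raise ValueError("word_size must be >= 8")
        self.word_size = word_size
        self.ct: dict[str, list[tuple[str, int]]] = {}
        self.ga: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in conv_ref.ct.items():
            if word_size > len(seq):
                logger.warning(
                    "word size %d exceeds length of %s (%d); chromosome not indexed",
                    word_size, chrom, len(seq),
                )
                continue
            self._index_seq(self.ct, chrom, seq)
            self._index_seq(self.ga, chrom, conv_ref.ga[chrom])

    def _index_seq(self, table: dict, chrom: str, seq: str) -> None:
        w = self.word_size
        for i in range(len(seq) - w + 1):
            table.setdefault(seq[i : i + w], []).append((chrom, i))

    def lookup(self, kmer: str, space: str) -> list[tuple[str, int]]:
        table = self.ct if space == "CT" else self.ga
        return table.get(kmer, [])


def build_index(conv_ref: ConvertedReference, word_size: int) -> SeedIndex:
    return SeedIndex(conv_ref, word_size)


def _match_vector(query: str, ref: str, offset: int, space: str) -> list[bool]:
    """Conversion-aware per-position matches of ``query`` laid on ``ref[offset:]``.

    For the GA space the query must already be the reverse complement of
    the read (unconverted): a query A over a reference G is then the
    conversion-consistent match.
    """
    out = []
    for i, q in enumerate(query):
        g = ref[offset + i]
        if space == "CT":
            out.append(q == g or (q == "T" and g == "C"))
        else:
            out.append(q == g or (q == "A" and g == "G"))
    return out


def _longest_run(bits: list[bool]) -> tuple[int, int]:
    """(length, start) of the longest run of True."""
    best = cur = 0
    best_start = cur_start = 0
    for i, b in enumerate(bits):
        if b:
            if cur == 0:
                cur_start = i
            cur += 1
            if cur > best:
                best, best_start = cur, cur_start
        else:
            cur = 0
    return best, best_start


def _extend(
    read_id: str,
    query: str,
    ref: str,
    chrom: str,
    offset: int,
    space: str,
    cycle_index: int,
    cutoff: float,
    last_cycle: bool,
    min_perfect: int,
) -> Alignment | None:
    """Ungapped extension of a candidate placement; None if not accepted."""
    q_lo = max(0, -offset)
    q_hi = min(len(query), len(ref) - offset)
    if q_hi - q_lo < min_perfect:
        return None
    sub = query[q_lo:q_hi]
    bits = _match_vector(sub, ref, offset + q_lo, space)
    if last_cycle:
        run, run_start = _longest_run(bits)
        if run < min_perfect:
            return None
        start = offset + q_lo + run_start
        return Alignment(
            read_id=read_id, chrom=chrom, start=start, end=start + run,
            space=space, identity=1.0, aligned_length=run,
            cycle_index=cycle_index, score=float(run),
        )
    matches = sum(bits)
    length = len(bits)
    identity = matches / length
    if identity < cutoff:
        return None
    return Alignment(
        read_id=read_id, chrom=chrom, start=offset + q_lo, end=offset + q_hi,
        space=space, identity=identity, aligned_length=length,
        cycle_index=cycle_index, score=float(2 * matches - length),
    )


def assess_ambiguity(
    alignments: list[Alignment], margin: float = 5.0
) -> tuple[str, Alignment]:
    """Decide unique vs ambiguous from the accepted alignments of one read.

    Unique iff a single locus was accepted, or the best score beats the
    runner-up by at least ``margin``.  Ties are deterministically ambiguous.
    """
    if not alignments:
        raise ValueError("assess_ambiguity needs at least one alignment")
    ranked = sorted(
        alignments, key=lambda a: (-a.score, a.chrom, a.start, a.space)
    )
    best = ranked[0]
    if len(ranked) == 1 or best.score - ranked[1].score >= margin:
        return "unique", best
    return "ambiguous", best


def _dedupe_candidates(alignments: list[Alignment]) -> list[Alignment]:
    """Collapse overlapping placements at the same locus, keeping the best."""
    kept: list[Alignment] = []
    for aln in sorted(
        alignments, key=lambda a: (-a.score, a.chrom, a.start, a.space, a.end)
    ):
        clash = False
        for other in kept:
            if (
                aln.chrom == other.chrom
                and aln.space == other.space
                and aln.start < other.end
                and aln.end > other.start
            ):
                clash = True
                break
        if not clash:
            kept.append(aln)
    return kept


def map_iterative(
    flanks: list[tuple[str, str]],
    conv_ref: ConvertedReference,
    schedule: CycleSchedule | None = None,
    margin: float = 5.0,
) -> dict[str, MappedRead]:
    """Map ``(read_id, flank_seq)`` pairs through the cycle schedule.

    Every input read appears exactly once in the result, with status
    unique, ambiguous, or unmapped.
    """
    schedule = schedule or CycleSchedule()
    if not flanks:
        return {}
    results: dict[str, MappedRead] = {}
    pending = [(rid, seq.upper()) for rid, seq in flanks]
    for cycle, (word, cutoff) in enumerate(
        zip(schedule.word_sizes, schedule.identity_cutoffs)
    ):
        if not pending:
            break
        last = cycle == schedule.n_cycles - 1
        index = build_index(conv_ref, word)
        still_pending: list[tuple[str, str]] = []
        for rid, seq in pending:
            accepted = _map_one(
                rid, seq, conv_ref, index, word, cutoff, cycle, last,
                schedule.min_perfect_match,
            )
            if accepted:
                status, best = assess_ambiguity(accepted, margin=margin)
                results[rid] = MappedRead(rid, best, status)
            else:
                still_pending.append((rid, seq))
        pending = still_pending
    for rid, _seq in pending:
        results[rid] = MappedRead(rid, None, "unmapped")
    return results


def _map_one(
    read_id: str,
    seq: str,
    conv_ref: ConvertedReference,
    index: SeedIndex,
    word: int,
    cutoff: float,
    cycle: int,
    last: bool,
    min_perfect: int,
) -> list[Alignment]:
    if len(seq) < word or set(seq) <= {"N"}:
        return []
    queries = {
        "CT": (convert_ct(seq), seq),
        "GA": (convert_ga(revcomp(seq)), revcomp(seq)),
    }
    accepted: list[Alignment] = []
    for space, (conv_query, raw_query) in queries.items():
        seen: set[tuple[str, int]] = set()
        for i in range(len(conv_query) - word + 1):
            for chrom, pos in index.lookup(conv_query[i : i + word], space):
                offset = pos - i
                if (chrom, offset) in seen:
                    continue
                seen.add((chrom, offset))
                aln = _extend(
                    read_id, raw_query, conv_ref.source[chrom], chrom, offset,
                    space, cycle, cutoff, last, min_perfect,
                )
                if aln is not None:
                    accepted.append(aln)
    return _dedupe_candidates(accepted)


# --- mapping table IO -------------------------------------------------------

MAPPING_COLUMNS = (
    "read_id", "status", "chrom", "start", "end", "space",
    "identity", "aligned_length", "cycle", "score",
)


def write_mapping_tsv(path, mapped: dict[str, MappedRead]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MAPPING_COLUMNS) + "\n")
        for rid in sorted(mapped):
            m = mapped[rid]
            if m.best is None:
                fh.write(f"{rid}\t{m.status}\t.\t-1\t-1\t.\tnan\t0\t-1\tnan\n")
            else:
                b = m.best
                fh.write(
                    f"{rid}\t{m.status}\t{b.chrom}\t{b.start}\t{b.end}\t{b.space}\t"
                    f"{b.identity:.6f}\t{b.aligned_length}\t{b.cycle_index}\t{b.score}\n"
                )


def read_mapping_tsv(path) -> dict[str, MappedRead]:
    out: dict[str, MappedRead] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == list(MAPPING_COLUMNS), f"unexpected mapping header: {header}"
        for line in fh:
            p = line.rstrip("\n").split("\t")
            rid, status = p[0], p[1]
            if p[2] == ".":
                out[rid] = MappedRead(rid, None, status)
            else:
                out[rid] = MappedRead(
                    rid,
                    Alignment(
                        read_id=rid, chrom=p[2], start=int(p[3]), end=int(p[4]),
                        space=p[5], identity=float(p[6]), aligned_length=int(p[7]),
                        cycle_index=int(p[8]), score=float(p[9]),
                    ),
                    status,
                )
    return out
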