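"""TPRT hallmark annotation for insertion alleles.

Given the sequence context of a verified (or simulated) insertion, this
module recovers the target-site duplication, the endonuclease cleavage
motif, the poly-A tail length, and the source subfamily.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from alubis._align import aligned_pairs, make_aligner
from alubis.consensus import SUBFAMILY_AGE_ORDER

CLEAVAGE_MOTIF = "TTAAAA"


@dataclass(frozen=True)
class CleavageSite:
    site: str
    mismatches: int
    offset_from_junction: int  # distance from motif start to flank 3' end
    credible: bool


@dataclass(frozen=True)
class SubfamilyCall:
    subfamily: str
    identity: float
    score: float
    low_confidence: bool = False


@dataclass(frozen=True)
class InsertionFeatures:
    locus_id: str
    tsd_seq: str
    cleavage_site: CleavageSite
    polya_len: int
    polya_region: str
    subfamily: str
    subfamily_identity: float

    @property
    def tsd_len(self) -> int:
        return len(self.tsd_seq)


def detect_tsd(
    upstream_flank: str,
    downstream_after_tail: str,
    min_len: int = 4,
    max_scan: int = 25,
) -> str:
    """Longest exact suffix of the upstream flank that prefixes the
    downstream sequence (the second TSD copy); empty if shorter than
    ``min_len``.  Only the ``max_scan`` bases nearest the junction are
    considered, which bounds spurious joins."""
    upstream_flank = upstream_flank.upper()
    downstream_after_tail = downstream_after_tail.upper()
    limit = min(max_scan, len(upstream_flank), len(downstream_after_tail))
    for length in range(limit, min_len - 1, -1):
        if upstream_flank[-length:] == downstream_after_tail[:length]:
            return upstream_flank[-length:]
    return ""


def find_cleavage_site(
    upstream_flank: str,
    window: int = 20,
    max_mismatch: int = 1,
    motif: str = CLEAVAGE_MOTIF,
) -> CleavageSite:
    """Best match to the TT/AAAA nick motif near the junction.

    Scans every ``len(motif)``-mer whose start lies within ``window`` bases
    of the flank's 3' end (the junction); ties are broken toward the
    junction.  Sites worse than ``max_mismatch`` are reported but flagged
    not credible.
    """
    upstream_flank = upstream_flank.upper()
    k = len(motif)
    if len(upstream_flank) < k:
        raise ValueError(f"flank shorter than motif ({len(upstream_flank)} < {k})")
    n = len(upstream_flank)
    lo = max(0, n - window)
    best: tuple[int, int] | None = None  # (mismatches, -start)
    for start in range(lo, n - k + 1):
        kmer = upstream_flank[start : start + k]
        mm = sum(1 for a, b in zip(kmer, motif) if a != b)
        if best is None or (mm, -start) < best:
            best = (mm, -start)
    mm, neg_start = best
    start = -neg_start
    return CleavageSite(
        site=upstream_flank[start : start + k],
        mismatches=mm,
        offset_from_junction=n - start,
        credible=mm <= max_mismatch,
    )


def measure_polya(tail_region: str) -> int:
    """Maximal uninterrupted A-run after the leading non-A remnant.

    The tail region is the sequence between the element's 3' terminus and
    the downstream TSD copy; an element-terminal remnant such as ``CTC``
    is skipped before measuring.  Empty input yields 0.
    """
    if not tail_region:
        return 0
    runs = re.findall("A+", tail_region.upper())
    return max((len(r) for r in runs), default=0)


def classify_subfamily(
    alu_seq: str,
    consensus_set: dict[str, str],
    min_length: int = 50,
) -> SubfamilyCall:
    """Best-scoring consensus wins; ties go to the younger subfamily."""
    if not consensus_set:
        raise ValueError("empty consensus set")
    alu_seq = alu_seq.upper()
    aligner = make_aligner(mode="local", bisulfite=False)
    age = {name: i for i, name in enumerate(SUBFAMILY_AGE_ORDER)}
    best: tuple[float, int, str, float] | None = None  # (-score, age, name, identity)
    for name, cons in consensus_set.items():
        alns = aligner.align(cons.upper(), alu_seq)
        if len(alns) == 0:
            continue
        aln = alns[0]
        pairs = aligned_pairs(aln)
        if not pairs:
            continue
        matches = sum(1 for t, q in pairs if cons[t].upper() == alu_seq[q])
        identity = matches / len(pairs)
        key = (-aln.score, age.get(name, len(age)), name, identity)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no alignment produced against any consensus")
    return SubfamilyCall(
        subfamily=best[2],
        identity=best[3],
        score=-best[0],
        low_confidence=len(alu_seq) < min_length,
    )


def features_from_spans(
    seq: str,
    elem_start: int,
    body_end: int,
    tail_end: int,
    consensus_set: dict[str, str],
    locus_id: str = "",
    max_scan: int = 25,
    cleavage_window: int = 20,
) -> InsertionFeatures:
    """Annotate one insertion from its genomic context and element spans.

    ``elem_start``/``body_end`` bound the element body, ``tail_end`` marks
    the start of the downstream TSD copy (i.e. the end of the poly-A
    tail).  The upstream flank ends at ``elem_start``.
    """
    if not (0 <= elem_start < body_end <= tail_end <= len(seq)):
        raise ValueError("invalid element spans")
    upstream = seq[max(0, elem_start - max(max_scan, cleavage_window + 20)) : elem_start]
    downstream = seq[tail_end : tail_end + max_scan + 10]
    tail_region = seq[body_end:tail_end]
    tsd = detect_tsd(upstream, downstream, max_scan=max_scan)
    # the nick motif sits just upstream of the TSD: widen the scan window
    # by the TSD length so it is covered
    cleavage = find_cleavage_site(upstream, window=cleavage_window + len(tsd))
    sub = classify_subfamily(seq[elem_start:body_end], consensus_set)
    return InsertionFeatures(
        locus_id=locus_id,
        tsd_seq=tsd,
        cleavage_site=cleavage,
        polya_len=measure_polya(tail_region),
        polya_region=tail_region,
        subfamily=sub.subfamily,
        subfamily_identity=sub.identity,
    )


def write_features_tsv(path, features: list[InsertionFeatures]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "locus_id\tsubfamily\tsubfamily_identity\ttsd\ttsd_len\t"
            "cleavage_site\tcleavage_mismatches\tpolya_len\tpolya_region\n"
        )
        for f in features:
            fh.write(
                f"{f.locus_id}\t{f.subfamily}\t{f.subfamily_identity:.4f}\t"
                f"{f.tsd_seq or '.'}\t{f.tsd_len}\t{f.cleavage_site.site}\t"
                f"{f.cleavage_site.mismatches}\t{f.polya_len}\t{f.polya_region or '.'}\n"
            )
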