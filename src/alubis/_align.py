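"""Shared alignment helpers for bisulfite-space sequence comparison.

The package-wide matching convention: a read T aligned over a reference C
is a match in C->T space (the read derives from converted DNA), while a
read C over a reference C is also a match (protected methylated cytosine).
Reference sequences are encoded with ``E`` in place of ``C`` so that a
standard substitution matrix can express this asymmetric rule.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ALPHABET = "ACGTEN"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def convert_ct(seq: str) -> str:
    """Full bisulfite conversion on the plus strand: every C becomes T."""
    return seq.replace("C", "T")


def convert_ga(seq: str) -> str:
    """Complementary-space conversion: every G becomes A."""
    return seq.replace("G", "A")


def encode_bisulfite_ref(seq: str) -> str:
    """Mark cytosines of an (unconverted) reference as the wildcard ``E``.

    Under :func:`bisulfite_matrix`, ``E`` scores as a match against both C
    and T, implementing the conversion-aware rule.
    """
    return seq.replace("C", "E")


@lru_cache(maxsize=1)
def bisulfite_matrix():
    m = substitution_matrices.Array(ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            m[a, b] = -1.0
    for a in "ACGT":
        m[a, a] = 1.0
    m["E", "E"] = 1.0
    m["E", "C"] = m["C", "E"] = 1.0
    m["E", "T"] = m["T", "E"] = 1.0
    return m


@lru_cache(maxsize=1)
def plain_matrix():
    m = substitution_matrices.Array(ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            m[a, b] = 1.0 if (a == b and a != "N") else -1.0
    return m


def make_aligner(
    mode: str = "local",
    bisulfite: bool = True,
    open_gap: float = -2.0,
    extend_gap: float = -2.0,
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = bisulfite_matrix() if bisulfite else plain_matrix()
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def aligned_pairs(alignment) -> list[tuple[int, int]]:
    """(target_pos, query_pos) for every aligned column (gaps excluded)."""
    pairs: list[tuple[int, int]] = []
    t_blocks, q_blocks = alignment.aligned
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        pairs.extend(zip(range(ts, te), range(qs, qe)))
    return pairs


def alignment_identity(alignment, target: str, query: str, bisulfite: bool = True) -> float:
    """Fraction of aligned columns that match (conversion-aware if asked).

    ``target`` is passed in its original (un-encoded) form.
    """
    pairs = aligned_pairs(alignment)
    if not pairs:
        return 0.0
    matches = 0
    for t, q in pairs:
        tb, qb = target[t], query[q]
        if tb == qb or (bisulfite and tb == "C" and qb == "T"):
            matches += 1
    return matches / len(pairs)
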