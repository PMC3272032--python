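"""Independent oracles used by the test suite.

The brute-force mapper scores *every* offset of every flank against both
conversion spaces with NumPy sliding windows; it shares no code with the
k-mer-seeded mapper it checks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_A, _C, _G, _T = (ord(b) for b in "ACGT")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _candidates_for_space(query: str, ref: str, chrom: str, space: str,
                          word: int, cutoff: float, last: bool, min_perfect: int):
    """All accepted (ungapped) placements of one query in one space."""
    qa = np.frombuffer(query.encode(), np.uint8)
    ra = np.frombuffer(ref.encode(), np.uint8)
    L, G = len(qa), len(ra)
    if L < min_perfect:
        return []
    pad = np.full(L, ord("X"), np.uint8)
    windows = sliding_window_view(np.concatenate([pad, ra, pad]), L)
    # row j <-> offset o = j - L
    offsets = np.arange(-L, G + 1)
    if space == "CT":
        aware = (windows == qa) | ((qa == _T) & (windows == _C))
        conv_w = np.where(windows == _C, _T, windows)
        conv_q = np.where(qa == _C, _T, qa)
    else:
        aware = (windows == qa) | ((qa == _A) & (windows == _G))
        conv_w = np.where(windows == _G, _A, windows)
        conv_q = np.where(qa == _G, _A, qa)
    eq = conv_w == conv_q

    def longest_runs(bits):
        n = bits.shape[0]
        cur = np.zeros(n, dtype=np.int64)
        best = np.zeros(n, dtype=np.int64)
        best_end = np.zeros(n, dtype=np.int64)
        for i in range(bits.shape[1]):
            cur = np.where(bits[:, i], cur + 1, 0)
            improved = cur > best
            best = np.where(improved, cur, best)
            best_end = np.where(improved, i, best_end)
        return best, best_end

    eq_run, _ = longest_runs(eq)
    q_lo = np.maximum(0, -offsets)
    q_hi = np.minimum(L, G - offsets)
    overlap = np.maximum(0, q_hi - q_lo)
    out = []
    if last:
        aware_run, aware_end = longest_runs(aware)
        ok = (aware_run >= min_perfect) & (eq_run >= word)
        for j in np.flatnonzero(ok):
            run = int(aware_run[j])
            start = int(offsets[j]) + int(aware_end[j]) - run + 1
            out.append((chrom, start, start + run, space, 1.0, float(run)))
    else:
        matches = aware.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            identity = np.where(overlap > 0, matches / np.maximum(overlap, 1), 0.0)
        ok = (eq_run >= word) & (overlap >= min_perfect) & (identity >= cutoff)
        for j in np.flatnonzero(ok):
            o = int(offsets[j])
            start, end = o + int(q_lo[j]), o + int(q_hi[j])
            score = float(2 * int(matches[j]) - int(overlap[j]))
            out.append((chrom, start, end, space, float(identity[j]), score))
    return out


def _dedupe(cands):
    kept = []
    for cand in sorted(cands, key=lambda c: (-c[5], c[0], c[1], c[3], c[2])):
        chrom, start, end, space = cand[0], cand[1], cand[2], cand[3]
        if any(
            chrom == k[0] and space == k[3] and start < k[2] and end > k[1]
            for k in kept
        ):
            continue
        kept.append(cand)
    return kept


def brute_force_map(flanks, genome: dict[str, str], word_sizes, identity_cutoffs,
                    min_perfect: int = 40, margin: float = 5.0):
    """Status and best locus per read, scoring every offset in both spaces."""
    results = {}
    for rid, seq in flanks:
        seq = seq.upper()
        rc = _revcomp(seq)
        status, best = "unmapped", None
        for cycle, (word, cutoff) in enumerate(zip(word_sizes, identity_cutoffs)):
            last = cycle == len(word_sizes) - 1
            cands = []
            for chrom, ref in genome.items():
                cands += _candidates_for_space(seq, ref, chrom, "CT", word,
                                               cutoff, last, min_perfect)
                cands += _candidates_for_space(rc, ref, chrom, "GA", word,
                                               cutoff, last, min_perfect)
            cands = _dedupe(cands)
            if cands:
                ranked = sorted(cands, key=lambda c: (-c[5], c[0], c[1], c[3]))
                best = ranked[0]
                if len(ranked) == 1 or best[5] - ranked[1][5] >= margin:
                    status = "unique"
                else:
                    status = "ambiguous"
                break
        results[rid] = (status, best[:4] if best else None)
    return results


def linear_scan_nearest(intervals, pos):
    """Nearest interval by unsigned distance; 0 when pos is inside."""
    best = None
    best_d = None
    for iv in intervals:
        start, end = iv[1], iv[2]
        if start <= pos < end:
            d = 0
        else:
            d = min(abs(pos - start), abs(pos - (end - 1)))
        if best_d is None or d < best_d:
            best, best_d = iv, d
    return best, best_d
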