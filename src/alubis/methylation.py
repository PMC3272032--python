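"""Per-CpG methylation calling from bisulfite reads.

Calls are made against the unconverted local reference: a read C over a
reference CpG cytosine means the cytosine was protected (methylated), a
read T means it was converted (unmethylated), anything else - including an
indel over the CpG - is uncallable and excluded from every denominator.
The fraction of non-CpG reference cytosines read as T serves as the
per-read incomplete-conversion monitor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from alubis._align import aligned_pairs, encode_bisulfite_ref, make_aligner

Z95 = 1.959963984540054


@dataclass(frozen=True)
class CpGCall:
    read_id: str
    position: int  # local-reference coordinate of the CpG cytosine
    state: str  # "methylated" | "unmethylated" | "uncallable"
    context: str = "CpG"


@dataclass(frozen=True)
class ConversionQC:
    read_id: str
    n_non_cpg_c: int
    n_converted: int
    flagged: bool

    @property
    def fraction(self) -> float | None:
        if self.n_non_cpg_c == 0:
            return None
        return self.n_converted / self.n_non_cpg_c


@dataclass(frozen=True)
class RegionDef:
    name: str
    start: int
    end: int  # half-open, local-reference coordinates

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty region: {self}")


# Canonical internal promoter boxes, 1-based 5-16 and 75-84 from the
# element 5' terminus.
A_BOX = (4, 16)
B_BOX = (74, 84)


def canonical_regions(
    elem_start: int,
    body_end: int,
    left_arm_length: int = 131,
    linker_length: int = 5,
) -> list[RegionDef]:
    regions = [
        RegionDef("whole_element", elem_start, body_end),
        RegionDef("A_box", elem_start + A_BOX[0], elem_start + A_BOX[1]),
        RegionDef("B_box", elem_start + B_BOX[0], elem_start + B_BOX[1]),
        RegionDef("left_arm", elem_start, elem_start + left_arm_length),
    ]
    right_start = elem_start + left_arm_length + linker_length
    if right_start < body_end:
        regions.append(RegionDef("right_arm", right_start, body_end))
    return regions


@dataclass(frozen=True)
class MethylationSummary:
    region: str
    n_calls: int
    n_methylated: int
    n_unmethylated: int
    level: float | None  # percent; None when no callable CpG covered


def cpg_positions(seq: str) -> list[int]:
    """Plus-strand CpG cytosine positions of a sequence."""
    return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


def align_read_to_reference(read_seq: str, local_ref: str):
    """Conversion-aware local alignment of a read to the unconverted
    reference; returns the aligned (ref_pos, read_pos) pairs."""
    aligner = make_aligner(mode="local", bisulfite=True)
    alns = aligner.align(encode_bisulfite_ref(local_ref.upper()), read_seq.upper())
    if len(alns) == 0:
        return []
    return aligned_pairs(alns[0])


def call_cpg_states(
    read_id: str,
    read_seq: str,
    local_ref: str,
    pairs: list[tuple[int, int]] | None = None,
    qc_threshold: float = 0.98,
) -> tuple[list[CpGCall], ConversionQC]:
    """One call per reference CpG cytosine covered by the alignment."""
    read_seq = read_seq.upper()
    local_ref = local_ref.upper()
    if pairs is None:
        pairs = align_read_to_reference(read_seq, local_ref)
    if not pairs:
        raise ValueError(f"read {read_id}: no alignment to the local reference")
    by_ref = dict(pairs)
    ref_lo = min(by_ref)
    ref_hi = max(by_ref) + 1
    cpgs = [p for p in cpg_positions(local_ref) if ref_lo <= p < ref_hi]
    if not cpgs:
        raise ValueError(f"read {read_id}: alignment covers no reference CpG")
    calls: list[CpGCall] = []
    for p in cpgs:
        q = by_ref.get(p)
        if q is None:
            state = "uncallable"  # indel over the CpG: never guessed
        else:
            base = read_seq[q]
            state = {"C": "methylated", "T": "unmethylated"}.get(base, "uncallable")
        calls.append(CpGCall(read_id, p, state))
    cpg_set = set(cpgs)
    n_c = n_t = 0
    for p, q in by_ref.items():
        if local_ref[p] == "C" and p not in cpg_set:
            n_c += 1
            if read_seq[q] == "T":
                n_t += 1
    fraction = (n_t / n_c) if n_c else None
    qc = ConversionQC(
        read_id=read_id,
        n_non_cpg_c=n_c,
        n_converted=n_t,
        flagged=fraction is not None and fraction < qc_threshold,
    )
    return calls, qc


def summarize_methylation(
    calls: list[CpGCall], regions: list[RegionDef]
) -> list[MethylationSummary]:
    """Per-region levels; uncallable states are excluded everywhere."""
    out: list[MethylationSummary] = []
    for region in regions:
        n_m = n_u = 0
        for c in calls:
            if region.start <= c.position < region.end:
                if c.state == "methylated":
                    n_m += 1
                elif c.state == "unmethylated":
                    n_u += 1
        n = n_m + n_u
        level = (100.0 * n_m / n) if n else None
        out.append(MethylationSummary(region.name, n, n_m, n_u, level))
    return out


def lollipop_matrix(calls: list[CpGCall]) -> pd.DataFrame:
    """Read x CpG-position matrix: 1 methylated, 0 unmethylated, NaN else."""
    state_num = {"methylated": 1.0, "unmethylated": 0.0}
    records = {}
    for c in calls:
        records.setdefault(c.read_id, {})[c.position] = state_num.get(c.state, np.nan)
    df = pd.DataFrame.from_dict(records, orient="index")
    return df.sort_index(axis=0).sort_index(axis=1)


def compare_alleles(calls_df: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG methylation comparison between insertion-bearing and empty
    alleles.

    ``calls_df`` needs columns read_id, allele ("with"/"without"),
    position (a coordinate shared between the alleles, e.g. reference
    flank coordinates), and state.  Levels are percentages; a side with no
    callable reads is reported as NaN and yields no interval.
    """
    required = {"read_id", "allele", "position", "state"}
    if not required <= set(calls_df.columns):
        raise ValueError(f"calls_df must have columns {sorted(required)}")
    rows = []
    for pos, grp in calls_df.groupby("position"):
        row: dict = {"position": pos}
        stats = {}
        for allele in ("with", "without"):
            sub = grp[(grp["allele"] == allele) & (grp["state"] != "uncallable")]
            n = len(sub)
            m = int((sub["state"] == "methylated").sum())
            level = 100.0 * m / n if n else np.nan
            row[f"n_{allele}"] = n
            row[f"level_{allele}"] = level
            stats[allele] = (n, m)
        n1, m1 = stats["with"]
        n0, m0 = stats["without"]
        if n1 and n0:
            p1, p0 = m1 / n1, m0 / n0
            se = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
            diff = 100.0 * (p1 - p0)
            row["diff"] = diff
            row["ci_lo"] = diff - 100.0 * Z95 * se
            row["ci_hi"] = diff + 100.0 * Z95 * se
            row["significant"] = not (row["ci_lo"] <= 0.0 <= row["ci_hi"])
        else:
            row["diff"] = np.nan
            row["ci_lo"] = np.nan
            row["ci_hi"] = np.nan
            row["significant"] = False
        rows.append(row)
    return pd.DataFrame(rows).sort_values("position").reset_index(drop=True)


def flanking_cpgs(local_ref: str, elem_start: int, tail_end: int) -> dict[str, int | None]:
    """Nearest CpG 5' of the upstream TSD copy and 3' of the downstream one."""
    positions = cpg_positions(local_ref)
    five = [p for p in positions if p < elem_start]
    three = [p for p in positions if p >= tail_end]
    return {
        "flank_5p_CpG": five[-1] if five else None,
        "flank_3p_CpG": three[0] if three else None,
    }


def write_summary_tsv(path, summaries: list[tuple[str, MethylationSummary]]) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tregion\tn_calls\tn_methylated\tn_unmethylated\tlevel\n")
        for locus, s in summaries:
            level = "NA" if s.level is None else f"{s.level:.2f}"
            fh.write(
                f"{locus}\t{s.region}\t{s.n_calls}\t{s.n_methylated}\t"
                f"{s.n_unmethylated}\t{level}\n"
            )
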