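"""Bundled AluY-family consensus stand-ins.

Synthetic 281 bp consensus sequences (left arm, A5 linker, right arm) with
a realistic CpG density and a handful of diagnostic substitutions that
distinguish the subfamilies.  They are deliberately not the Repbase
sequences: users working with real data can supply their own FASTA to any
function that accepts a consensus set.

Each sequence ends in a non-A trinucleotide so the boundary between the
element body and an appended poly-A tail is unambiguous.
"""

from __future__ import annotations

from pathlib import Path

# Youngest first; used to break ties when two consensuses score equally.
SUBFAMILY_AGE_ORDER = ("AluYb9", "AluYb8", "AluYg6", "AluYa5", "AluY")

DEFAULT_CONSENSUS: dict[str, str] = {
    "AluY": (
        "AGCAGTCGGTGTTCCGGGCGCCAACGCCCCCCCGTAGCCGCGGAGGGGCGAGTGTCGTGG"
        "ACCTAGTCGCTTCCATCCGCAGGGGACGGCCGGCTGTGTGTCCACCGGGTCGTGAAGCGT"
        "CGTACCCCCCAAAAAACTCTGCGCGGACCCTAACGGCGTCCTACCCCGAGGCGCGTCAGG"
        "CGATGACGTTCGTGGAGTGGCGTCTGCGCCGGGGTAGCAGGGTTCCCTAGACGATGGCGT"
        "GGTCCGCCAGTCGTCGCATCGCAGGTCGGCAGCTCTGGGCC"
    ),
    "AluYa5": (
        "AGCAGTCGGTGTTCCGGGCGCCTACGCCCCCCCGTAGCCGCGGAGGGGCGAGTGTCGTGG"
        "AACTAGTCGCTTCCATCCGCAGGGGACGGCCGGCTGTGTGTCCTCCGGGTCGTGAAGCGT"
        "CGTACCCCCCAAAAAACTCTGCGCGGACCCTAACGGCGTCCTACCCCGAGGCGCGTCCGG"
        "CGATGACGTTCGTGGAGTGGCGTCTGCGCCGGGGTAGCAGGGTTCCCTAGACGTTGGCGT"
        "GGTCCGCCAGTCGTCGCATCGCAGGTCGGCAGCTCTGGGCC"
    ),
    "AluYb8": (
        "AGCAGTCGGTATTCCGGGCGCCAACGCCCCCCCTTAGCCGCGGAGGGGCGAGTGTCGTCG"
        "ACCTAGTCGCTTCCATCCGCAGGGGACAGCCGGCTGTGTGTCCACCGGGTCGTGAAGCGT"
        "CGTACCCCCCAAAAAACTCTTCGCGGACCCTAACGGCGTCCTACCCCGAGGCGCGTCAGG"
        "CGATGACGTTAGTGGAGTGGCGTCTGCGCCGGGGTCGCAGGGTTCCCTAGACGATGGCGT"
        "GGTCCGCCAGGCGTCGCATCGCAGGTCGGCAGCTCTGGGCC"
    ),
    "AluYb9": (
        "AGCAGTCGGTATTCCGGGCGCCAACGCCCCCCCTTAGCCGCGGAGGGGCGAGTGTCGTCG"
        "ACCTAGTCGCTTCCATCCGCAGGGGACAGCCGGCTGTGTGTCCACCGGGTCGTGAAGCGT"
        "CGTACCCCCCAAAAAACTCTTCGCGGACCCTAACGGCGTCCTACCCCGAGGCGCGTCAGG"
        "CGATGACGTTAGTGGAGTGGCGTCTGCGCCGGGGTCGCAGGGTTCCCTAGACGATGGCGT"
        "GGTCCGCCAGGCGTCGCATCGCAGGACGGCAGCTCTGGGCC"
    ),
    "AluYg6": (
        "AGCAGTCGGTGTTCCGGACGCCAACGCCCCCCCGTAGCCGCGGAGTGGCGAGTGTCGTGG"
        "ACCTAGTCGCTTCCATCCGCAGGGGACGGCCGGCTGTGTATCCACCGGGTCGTGAAGCGT"
        "CGTACCCCCCAAAAAACTCTGCGCGGACCCCAACGGCGTCCTACCCCGAGGCGCGTCAGG"
        "CGATGACGTTCGTGGAGTGGCGTCTTCGCCGGGGTAGCAGGGTTCCCTAGACGATGGCGT"
        "GATCCGCCAGTCGTCGCATCGCAGGTCGGCAGCTCTGGGCC"
    ),
}

#: Length of the left arm in the bundled consensuses (before the A5 linker).
LEFT_ARM_LENGTH = 131
LINKER_LENGTH = 5


def write_consensus_fasta(path: str | Path, consensus: dict[str, str] | None = None) -> Path:
    """Write a consensus set (default: the bundled one) as FASTA."""
    consensus = consensus if consensus is not None else DEFAULT_CONSENSUS
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in consensus.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


def load_consensus_fasta(path: str | Path) -> dict[str, str]:
    """Read a consensus FASTA into an ordered ``{name: sequence}`` dict."""
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
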