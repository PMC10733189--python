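"""Shared sequence utilities: alphabets, hydropathy scale, codon tables, aligners.

Coordinate conventions: proteins use 1-based residue numbering at the API
surface (bovine-rhodopsin convention); nucleotide intervals are 0-based
half-open internally and converted to 1-based inclusive only in GFF3 output.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

# Kyte-Doolittle hydropathy
KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Residues used for simulated transmembrane segments and loop regions.  The
# TM alphabet is restricted to the strongly hydrophobic residues so that
# sliding-window hydropathy cleanly separates segments from loops even after
# substitution along deep gene trees.
TM_ALPHABET = "ILV"
TM_KEEPABLE = set("ILV")     # anchor residues a TM position may retain
LOOP_ALPHABET = "DEKRSTNQGP"

# One fixed codon per amino acid (common high-usage codons); determinism is the
# only requirement for back-translation in the simulator.
CODON_FOR = {
    "A": "GCC", "R": "CGC", "N": "AAC", "D": "GAC", "C": "TGC", "Q": "CAG",
    "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC", "L": "CTG", "K": "AAG",
    "M": "ATG", "F": "TTC", "P": "CCC", "S": "AGC", "T": "ACC", "W": "TGG",
    "Y": "TAC", "V": "GTG", "*": "TAA",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a nucleotide string (standard code); N-containing codons -> X."""
    return str(Seq(cds[: len(cds) - len(cds) % 3]).translate())


def back_translate(protein: str, stop: bool = True) -> str:
    cds = "".join(CODON_FOR[a] for a in protein)
    return cds + (CODON_FOR["*"] if stop else "")


@lru_cache(maxsize=1)
def anchor_record() -> tuple[str, str]:
    """Packaged bovine rhodopsin (NP_001014890.1): (id, sequence)."""
    text = (resources.files("photorep.data") / "bovine_rhodopsin.fasta").read_text()
    lines = text.strip().splitlines()
    name = lines[0][1:].split()[0]
    return name, "".join(lines[1:])


@lru_cache(maxsize=1)
def blosum62():
    return substitution_matrices.load("BLOSUM62")


def make_global_aligner() -> Align.PairwiseAligner:
    """Global affine-gap aligner with free end gaps (BLOSUM62, 11/1)."""
    a = Align.PairwiseAligner()
    a.substitution_matrix = blosum62()
    a.mode = "global"
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    try:
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    except AttributeError:  # older PairwiseAligner API
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    return a


def make_local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = blosum62()
    a.mode = "local"
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def aligned_blocks(alignment) -> tuple:
    """(target_blocks, query_blocks) as lists of (start, end) pairs."""
    t, q = alignment.aligned
    return [tuple(b) for b in t], [tuple(b) for b in q]


def pairwise_identity(a: str, b: str) -> float:
    """Identity of a global alignment of two sequences (matches / aligned columns)."""
    aligner = make_global_aligner()
    aln = aligner.align(a, b)[0]
    tb, qb = aligned_blocks(aln)
    matches = 0
    cols = 0
    for (ts, te), (qs, qe) in zip(tb, qb):
        cols += te - ts
        matches += sum(1 for i in range(te - ts) if a[ts + i] == b[qs + i])
    return matches / max(cols, 1)


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
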