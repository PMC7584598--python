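"""Global pairwise sequence identity (dynamin-1 vs dynamin-2 worked example).

Human dynamin-1 and dynamin-2 share roughly 80% sequence identity, which is
why dyn-1 structures serve as templates for dyn-2 assemblies.  This helper
reproduces that number from any two protein sequences the user supplies
(e.g. the canonical UniProt entries); no sequences ship with the package.
"""
from __future__ import annotations


def percent_identity(seq_a: str, seq_b: str, gap_open: float = -10.0, gap_extend: float = -0.5) -> float:
    """Percent identity of a global (Needleman-Wunsch) alignment, BLOSUM62.

    Identity = identical aligned positions / alignment length (gaps included),
    as a percentage.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    seq_a = "".join(seq_a.split()).upper()
    seq_b = "".join(seq_b.split()).upper()
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignment = aligner.align(seq_a, seq_b)[0]
    a, b = str(alignment[0]), str(alignment[1])
    identical = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * identical / len(a)


def read_single_fasta(path) -> str:
    """Sequence of the first record of a FASTA file."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)
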