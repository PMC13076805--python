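"""Intercysteine-loop decomposition and sequence comparison of cyclotides.

A six-cysteine cyclotide partitions into six intercysteine loops (loop k
runs from Cys k to Cys k+1 in cyclic order; loop 6 wraps from Cys VI back
to Cys I).  Loops are the natural unit of comparison across the family:
a loop string shared with many database entries is "common", one shared
with none is "unique".

Because a cyclic sequence has no intrinsic start, every operation first
maps the stored rotation to a canonical one: if the sequence contains the
cyclization junction motif — Asn or Asp followed by Gly — the rotation
starts at that Gly; otherwise the lexicographically smallest rotation is
used.  Both choices are rotation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .masses import PeptideSpecies

__all__ = [
    "LoopDecomposition",
    "PairwiseAlignmentResult",
    "canonical_rotation",
    "decompose_loops",
    "loop_uniqueness",
    "global_align",
    "frequency_counts",
]


@dataclass
class LoopDecomposition:
    """Cys positions (1-based, canonical rotation) and the six loops."""

    cys_positions: tuple[int, ...]
    loops: dict[str, str]  # loop1..loop6

    def reassemble(self) -> str:
        """Concatenate C+loop1+...+C+loop6; a rotation of the input."""
        out = []
        for k in range(1, 7):
            out.append("C")
            out.append(self.loops[f"loop{k}"])
        return "".join(out)


@dataclass
class PairwiseAlignmentResult:
    percent_identity: float
    percent_similarity: float
    aligned_length: int
    gap_count: int
    scoring_scheme: str

    def __post_init__(self):
        assert 0 <= self.percent_identity <= self.percent_similarity <= 100


def _rotations(seq: str) -> list[str]:
    return [seq[k:] + seq[:k] for k in range(len(seq))]


def canonical_rotation(p: PeptideSpecies | str) -> str:
    """Deterministic, rotation-invariant representative of a cyclic sequence.

    Rotations starting at a Gly preceded (cyclically) by Asn or Asp mark
    the head-to-tail cyclization junction; the lexicographically smallest
    such rotation is chosen.  Without a junction motif the
    lexicographically smallest rotation overall is returned.
    """
    seq = p.sequence if isinstance(p, PeptideSpecies) else p
    if isinstance(p, PeptideSpecies) and not p.is_cyclic():
        raise ValueError("canonical rotation is defined for cyclic peptides")
    n = len(seq)
    junction = [
        seq[k:] + seq[:k]
        for k in range(n)
        if seq[k] == "G" and seq[(k - 1) % n] in "ND"
    ]
    if junction:
        return min(junction)
    return min(_rotations(seq))


def decompose_loops(p: PeptideSpecies | str) -> LoopDecomposition:
    """Split a six-cysteine cyclic peptide into intercysteine loops.

    Output is computed on the canonical rotation, hence identical for
    every stored rotation of the same ring.
    """
    seq = canonical_rotation(p)
    n_cys = seq.count("C")
    if n_cys != 6:
        raise ValueError(f"expected 6 cysteines, found {n_cys}")
    cys = [k for k, aa in enumerate(seq) if aa == "C"]
    loops = {}
    for k in range(6):
        a = cys[k]
        b = cys[(k + 1) % 6]
        if k < 5:
            loops[f"loop{k + 1}"] = seq[a + 1 : b]
        else:
            loops["loop6"] = seq[a + 1 :] + seq[:b]
    return LoopDecomposition(
        cys_positions=tuple(c + 1 for c in cys),
        loops=loops,
    )


def loop_uniqueness(
    d: LoopDecomposition, reference: list[LoopDecomposition]
) -> dict[str, int]:
    """Count, per loop, how many reference entries share the exact string.

    A zero count marks the loop as unique relative to the reference set.
    Exact string matching (not per-loop alignment) is used.
    """
    counts = {}
    for k in range(1, 7):
        key = f"loop{k}"
        counts[key] = sum(1 for r in reference if r.loops[key] == d.loops[key])
    return counts


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignmentResult:
    """Needleman–Wunsch-style global alignment with affine gaps.

    Identity is the fraction of identical aligned pairs over the alignment
    length; similarity additionally counts pairs with a positive
    substitution-matrix score.  Defaults mimic the common EMBOSS global
    aligner settings (BLOSUM62, open 10, extend 0.5).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    subs = substitution_matrices.load(matrix)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = subs
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    length = len(sa)
    identical = similar = gaps = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == y:
            identical += 1
            similar += 1
        elif subs[x, y] > 0:
            similar += 1
    return PairwiseAlignmentResult(
        percent_identity=100.0 * identical / length,
        percent_similarity=100.0 * similar / length,
        aligned_length=length,
        gap_count=gaps,
        scoring_scheme=f"{matrix}/open{gap_open}/ext{gap_extend}",
    )


def frequency_counts(aligned: list[str]) -> pd.DataFrame:
    """Column-wise residue counts of an aligned (equal-length) sequence set.

    The logo-ready matrix has one row per symbol seen and one column per
    alignment position; each column sums to the number of sequences.
    """
    if not aligned:
        raise ValueError("empty input")
    length = len(aligned[0])
    if any(len(s) != length for s in aligned):
        raise ValueError("aligned sequences must have equal length")
    symbols = sorted({aa for s in aligned for aa in s})
    data = {
        pos: {sym: sum(1 for s in aligned if s[pos] == sym) for sym in symbols}
        for pos in range(length)
    }
    return pd.DataFrame(data).reindex(symbols)
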