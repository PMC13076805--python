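"""Mining transcript contigs for cyclotide precursor genes.

Cyclotides are ribosomally synthesized: a precursor protein carries an ER
signal peptide, an N-terminal propeptide, the mature cyclotide domain and a
short C-terminal tail.  Discovery therefore reduces to six-frame
translation of assembled contigs, local alignment of known mature
sequences against the translated ORFs, and rule-based extraction of the
mature domain from each hit.  The extracted candidates, assumed cyclic and
fully oxidized, yield a theoretical mass table for MS1 dereplication.

The processing-site rules default to the classic asparaginyl-endopeptidase
convention for cyclotides — the mature domain begins with a Gly directly
after the propeptide boundary and ends with Asn (or Asp) followed by a
small residue — and are configurable, since published precursors vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .cck import dereplicate
from .masses import PeptideSpecies

__all__ = [
    "Contig",
    "ProcessingRules",
    "PrecursorAnnotation",
    "MaturePeptideCandidate",
    "six_frame_translate",
    "scan_precursors",
    "extract_mature",
    "detection_table",
    "has_signal_peptide",
]

_FRAMES = (1, 2, 3, -1, -2, -3)
_HYDROPHOBIC = set("AVLIMFWC")


@dataclass
class Contig:
    """An assembled transcript contig (nucleotide, ACGT/N alphabet)."""

    id: str
    sequence: str

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        for pos, nt in enumerate(self.sequence, start=1):
            if nt not in "ACGTN":
                raise ValueError(f"invalid nucleotide {nt!r} at position {pos}")


@dataclass(frozen=True)
class ProcessingRules:
    """Rules locating the mature cyclotide domain inside a precursor ORF."""

    mature_start: str = "G"  # residue beginning the mature domain
    mature_end: str = "ND"  # residue ending the mature domain
    follower: str = "GASL"  # small residue after the processing site
    min_length: int = 25
    max_length: int = 40
    n_cys: int = 6


@dataclass
class PrecursorAnnotation:
    """A query hit inside one translated frame of a contig."""

    contig_id: str
    frame: int  # +1..+3 forward, -1..-3 reverse complement
    orf_nt_start: int  # 1-based on the read strand
    orf_nt_end: int
    protein: str  # the ORF protein sequence (no stops)
    hit_start: int  # 0-based aa span of the query hit within `protein`
    hit_end: int
    score: float
    query_id: str = ""
    signal_detected: bool = False
    mature_span: tuple[int, int] | None = None  # filled by extract_mature


@dataclass
class MaturePeptideCandidate:
    sequence: str
    predicted_mz: float  # cyclic, fully oxidized [M+H]+
    source: PrecursorAnnotation = field(repr=False, default=None)

    @property
    def species(self) -> PeptideSpecies:
        return PeptideSpecies(self.sequence, "cyclic")


def six_frame_translate(contig: Contig) -> dict[int, str]:
    """Translate a contig in all six frames (standard genetic code).

    Frames −1..−3 translate the reverse complement; stop codons appear as
    ``*``.  Trailing partial codons are dropped.
    """
    seq = Seq(contig.sequence)
    rc = seq.reverse_complement()
    frames = {}
    for f in _FRAMES:
        s = seq if f > 0 else rc
        offset = abs(f) - 1
        sub = s[offset : offset + 3 * ((len(s) - offset) // 3)]
        frames[f] = str(sub.translate())
    return frames


def has_signal_peptide(protein: str, n_terminal: int = 25, min_hydrophobic: int = 8) -> bool:
    """Crude ER-signal check: a hydrophobic stretch near the N-terminus.

    Heuristic only (at least ``min_hydrophobic`` hydrophobic residues among
    the first ``n_terminal``); flagged as such in outputs.
    """
    head = protein[:n_terminal]
    return sum(aa in _HYDROPHOBIC for aa in head) >= min_hydrophobic


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _orfs(protein: str, min_aa: int = 20):
    """Yield (aa_start, segment) for stop-free segments of a frame."""
    start = 0
    for k, aa in enumerate(protein + "*"):
        if aa == "*":
            if k - start >= min_aa:
                yield start, protein[start:k]
            start = k + 1


def scan_precursors(
    contigs: list[Contig],
    queries: dict[str, str] | list[str],
    min_score: float = 30.0,
    min_orf_aa: int = 20,
) -> list[PrecursorAnnotation]:
    """Locally align mature cyclotide queries against six-frame ORFs.

    Scoring follows a simple protein local alignment (match +2, mismatch
    −1, gap open −5, gap extend −1).  Contigs shorter than 60 nt are not
    scanned.  For each (contig, frame, ORF, query) the best local hit above
    ``min_score`` is reported; per ORF only the best-scoring query is kept.
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    if isinstance(queries, list):
        queries = {f"query{k + 1}": q for k, q in enumerate(queries)}
    aligner = _aligner()
    annotations = []
    for contig in contigs:
        if len(contig.sequence) < 60:
            continue
        frames = six_frame_translate(contig)
        for frame, protein in frames.items():
            for aa_start, orf in _orfs(protein, min_orf_aa):
                best = None
                for qid, query in queries.items():
                    alns = aligner.align(orf, query)
                    if len(alns) == 0:
                        continue
                    aln = alns[0]
                    if aln.score < min_score:
                        continue
                    if best is None or aln.score > best[0]:
                        span = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
                        best = (aln.score, qid, span)
                if best is None:
                    continue
                score, qid, (h0, h1) = best
                offset = abs(frame) - 1
                nt_start = offset + 3 * aa_start + 1
                nt_end = offset + 3 * (aa_start + len(orf))
                annotations.append(
                    PrecursorAnnotation(
                        contig_id=contig.id,
                        frame=frame,
                        orf_nt_start=nt_start,
                        orf_nt_end=nt_end,
                        protein=orf,
                        hit_start=h0,
                        hit_end=h1,
                        score=score,
                        query_id=qid,
                        signal_detected=has_signal_peptide(orf),
                    )
                )
    annotations.sort(key=lambda a: (-a.score, a.contig_id, a.frame))
    return annotations


def extract_mature(
    annotation: PrecursorAnnotation,
    rules: ProcessingRules = ProcessingRules(),
) -> MaturePeptideCandidate:
    """Extract the mature cyclotide domain around an alignment hit.

    Candidate windows start at a ``mature_start`` residue, end at a
    ``mature_end`` residue followed by a small residue, span
    ``min_length``–``max_length`` residues and contain exactly ``n_cys``
    cysteines.  Among valid windows the one overlapping the alignment hit
    most is chosen (ties: shorter, then leftmost).  If no window
    satisfies the rules the candidate is rejected with a reason.
    """
    from .cck import predicted_oxidized_mz

    protein = annotation.protein
    hit = range(annotation.hit_start, annotation.hit_end)
    windows = []
    for g in range(len(protein)):
        if protein[g] not in rules.mature_start:
            continue
        for e in range(g + rules.min_length - 1, min(g + rules.max_length, len(protein) - 1)):
            if protein[e] not in rules.mature_end:
                continue
            if protein[e + 1] not in rules.follower:
                continue
            window = protein[g : e + 1]
            if window.count("C") != rules.n_cys:
                continue
            overlap = len(set(range(g, e + 1)) & set(hit))
            windows.append((-overlap, len(window), g, e, window))
    if not windows:
        raise ValueError(
            f"no mature domain satisfying the processing rules in ORF of "
            f"{annotation.contig_id} (frame {annotation.frame})"
        )
    windows.sort()
    _, _, g, e, window = windows[0]
    annotation.mature_span = (g, e)
    candidate = MaturePeptideCandidate(sequence=window, predicted_mz=0.0,
                                       source=annotation)
    candidate.predicted_mz = predicted_oxidized_mz(candidate.species)
    return candidate


def detection_table(
    candidates: list[MaturePeptideCandidate],
    peaks,
    tol: float = 0.25,
):
    """MS1 detection table for mined candidates (dereplication + provenance).

    Duplicate candidate sequences collapse to one row; provenance columns
    give the source contig and frame of the first occurrence.
    """
    unique: dict[str, MaturePeptideCandidate] = {}
    for cand in candidates:
        unique.setdefault(cand.sequence, cand)
    cands = list(unique.values())
    table = dereplicate([c.species for c in cands], peaks, tol)
    table.insert(0, "contig", [
        c.source.contig_id if c.source else "" for c in cands
    ])
    table.insert(1, "frame", [c.source.frame if c.source else 0 for c in cands])
    return table
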