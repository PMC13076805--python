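"""Inference of cysteine count and backbone cyclicity from mass shifts.

The decision workflow for an unknown peptide seen only by MALDI-MS:

1. Reduce all disulfides and alkylate the freed thiols with iodoacetamide.
   Each cysteine gains 58.029114 Da (+1.007825 reduction + 57.021464
   carbamidomethyl), so the observed shift divided by that step size
   estimates the cysteine count.
2. Digest the alkylated species with an enzyme that has a single site.
   A cyclic backbone yields ONE product exactly one water (+18.011 Da)
   heavier — the ring opened without losing a residue — whereas a linear
   backbone fragments into two lighter products.
3. Count MS1 signals in the m/z 2000–4000 cyclotide window, and match
   candidate masses against the peak list (dereplication).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .constants import REDUCTION_ALKYLATION_PER_CYS, WATER
from .masses import PROTON_ADDUCT, PeptideSpecies, ion_mz, peptide_mass

__all__ = [
    "ModificationLadder",
    "CCKEvidence",
    "infer_cys_count",
    "infer_cyclic",
    "ms1_fingerprint",
    "dereplicate",
    "predicted_oxidized_mz",
]

#: Mass gained per cysteine on reduction + carbamidomethylation.
CYS_STEP = REDUCTION_ALKYLATION_PER_CYS


@dataclass
class ModificationLadder:
    """Observed [M+H]+ values along the reduction/alkylation/ring-opening
    ladder of one peptide."""

    native_mz: float
    alkylated_mz: float
    reduced_mz: float | None = None
    enzyme_opened_mz: float | None = None

    def __post_init__(self):
        for v in (self.native_mz, self.alkylated_mz, self.reduced_mz,
                  self.enzyme_opened_mz):
            if v is not None and v <= 0:
                raise ValueError("observed m/z values must be positive")
        if self.alkylated_mz < self.native_mz:
            raise ValueError("alkylated m/z below native m/z")


@dataclass
class CCKEvidence:
    n_cys_estimate: int
    cys_residual: float
    is_cyclic: bool
    rationale: str


def infer_cys_count(ladder: ModificationLadder) -> tuple[int, float]:
    """Estimate the cysteine count from the reduction/alkylation shift.

    Returns ``(n, residual)`` with ``n = round(shift / 58.029114)`` and the
    residual distance of the shift from ``n`` whole steps.
    """
    delta = ladder.alkylated_mz - ladder.native_mz
    if delta < 0:
        raise ValueError(f"negative alkylation shift {delta}")
    n = round(delta / CYS_STEP)
    residual = abs(delta - n * CYS_STEP)
    return n, residual


def infer_cyclic(
    ladder: ModificationLadder,
    n_products_after_single_site_enzyme: int,
    tol: float = 0.25,
) -> bool:
    """Decide backbone cyclicity from a single-site endoproteolysis.

    True iff the digest produced exactly one product whose mass exceeds the
    alkylated species by one water (within ``tol``): the ring opened with
    no residue loss.  Two products, or any mass loss, indicate a linear
    backbone.
    """
    if ladder.enzyme_opened_mz is None:
        raise ValueError("ladder has no enzyme-opened observation")
    if n_products_after_single_site_enzyme != 1:
        return False
    shift = ladder.enzyme_opened_mz - ladder.alkylated_mz
    return abs(shift - WATER) <= tol


def ms1_fingerprint(
    peaks: list[tuple[float, float]] | pd.DataFrame,
    window: tuple[float, float] = (2000.0, 4000.0),
) -> tuple[int, list[tuple[float, float]]]:
    """Count peaks inside the cyclotide mass window (default m/z 2000–4000).

    Peak lists are assumed monoisotopic-picked; no deisotoping is applied.
    Returns the count and the in-window peak subset.
    """
    if isinstance(peaks, pd.DataFrame):
        peaks = list(zip(peaks.iloc[:, 0], peaks.iloc[:, 1]))
    lo, hi = window
    subset = [(mz, i) for mz, i in peaks if lo <= mz <= hi]
    return len(subset), subset


def predicted_oxidized_mz(candidate: PeptideSpecies) -> float:
    """Theoretical [M+H]+ of a candidate assuming full cysteine oxidation.

    A 2k-cysteine candidate is assigned k disulfides (3 for the canonical
    six-cysteine cyclotide), matching how native extracts are measured.
    """
    n_bonds = candidate.sequence.count("C") // 2
    bare = PeptideSpecies(candidate.sequence, candidate.topology)
    mass = peptide_mass(bare) - 2.015650 * n_bonds
    return ion_mz(mass, PROTON_ADDUCT)


def dereplicate(
    candidates: list[PeptideSpecies],
    peaks: list[tuple[float, float]] | pd.DataFrame,
    tol: float = 0.25,
) -> pd.DataFrame:
    """Match candidate masses against an MS1 peak list.

    Each candidate is marked ``y`` iff any peak lies within ``tol`` Da of
    its theoretical fully-oxidized [M+H]+.  Returns a detection table with
    columns sequence / predicted m/z / matched peak (or None) / detected.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if isinstance(peaks, pd.DataFrame):
        peaks = list(zip(peaks.iloc[:, 0], peaks.iloc[:, 1]))
    mzs = sorted(mz for mz, _ in peaks)
    rows = []
    for cand in candidates:
        theo = predicted_oxidized_mz(cand)
        best = None
        for mz in mzs:
            if abs(mz - theo) <= tol and (
                best is None or abs(mz - theo) < abs(best - theo)
            ):
                best = mz
        rows.append(
            {
                "sequence": cand.sequence,
                "predicted_mz": round(theo, 4),
                "matched_peak": round(best, 4) if best is not None else None,
                "detected": "y" if best is not None else "n",
            }
        )
    return pd.DataFrame(
        rows, columns=["sequence", "predicted_mz", "matched_peak", "detected"]
    )
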