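"""Theoretical b/y ion series, spectrum matching and isobaric-residue flags.

Models the MALDI post-source-decay regime: singly protonated b and y ions
only.  For a linear n-mer, b_i is the first i residues plus a proton and
y_j the last j residues plus water and a proton, so the complementarity
identity b_i + y_{n-i} = [M+H]+ + 1.007276 holds exactly for every i.

De novo search is out of scope: the module *scores* candidate sequences
against observed spectra, which is how a manual annotation is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .constants import PROTON, WATER
from .masses import DEFAULT_TABLE, PeptideSpecies

__all__ = [
    "FragmentIon",
    "Spectrum",
    "SpectrumAnnotation",
    "ion_series",
    "annotate",
    "isobaric_flags",
]


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' | 'y'
    index: int  # 1..n-1
    mz: float  # singly protonated
    composed_sequence: str


@dataclass
class Spectrum:
    """An observed MS/MS spectrum: precursor and (m/z, intensity) peaks."""

    precursor_mz: float
    precursor_charge: int
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")
        self.peaks = sorted(self.peaks)


@dataclass
class SpectrumAnnotation:
    """Result of matching a candidate's ion series against a spectrum."""

    matches: list[tuple[FragmentIon, int, float]]  # (ion, peak index, error Da)
    y_coverage: float
    b_coverage: float
    ambiguous_positions: list[tuple[int, tuple[str, ...]]]

    def to_table(self, spectrum: Spectrum) -> pd.DataFrame:
        rows = [
            {
                "ion": f"{ion.series}{ion.index}",
                "theoretical_mz": round(ion.mz, 4),
                "observed_mz": round(spectrum.peaks[k][0], 4),
                "error_da": round(err, 4),
            }
            for ion, k, err in self.matches
        ]
        return pd.DataFrame(
            rows, columns=["ion", "theoretical_mz", "observed_mz", "error_da"]
        )


def _site_mod_mass(p: PeptideSpecies, position: int) -> float:
    """Extra mass carried by the residue at ``position`` (1-based)."""
    return sum(
        spec.delta_mass
        for spec, site in p.modifications
        if site == position
    )


def ion_series(p: PeptideSpecies) -> list[FragmentIon]:
    """All n−1 b ions and n−1 y ions of a linear peptide.

    Ring-opened digestion products are acceptable; an intact cyclic species
    is rejected (it has no termini to anchor the series — ring-open first).
    Per-site modifications are included in the running sums; peptide-wide
    (global) modification deltas are not position-resolved and are ignored.
    """
    if p.is_cyclic():
        raise ValueError("ion series require a linear peptide; ring-open first")
    n = len(p.sequence)
    residue = [
        DEFAULT_TABLE.mass(aa) + _site_mod_mass(p, k)
        for k, aa in enumerate(p.sequence, start=1)
    ]
    ions = []
    acc = 0.0
    for i in range(1, n):
        acc += residue[i - 1]
        ions.append(FragmentIon("b", i, acc + PROTON, p.sequence[:i]))
    acc = 0.0
    for j in range(1, n):
        acc += residue[n - j]
        ions.append(FragmentIon("y", j, acc + WATER + PROTON, p.sequence[n - j:]))
    return ions


def annotate(
    spectrum: Spectrum, candidate: PeptideSpecies, tol: float = 0.3
) -> SpectrumAnnotation:
    """Match the candidate's theoretical b/y ions to observed peaks.

    Greedy nearest-match within ``tol`` Da: candidate (ion, peak) pairs are
    ranked by absolute error, ties broken toward the lower ion index; each
    peak is used by at most one ion per series.  Coverage is the matched
    fraction of each series.  An empty spectrum yields a zero-coverage
    annotation, not an error.
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    ions = ion_series(candidate)
    n = len(candidate.sequence)
    mzs = [mz for mz, _ in spectrum.peaks]
    candidates = []
    for ion in ions:
        for k, mz in enumerate(mzs):
            err = mz - ion.mz
            if abs(err) <= tol:
                candidates.append((abs(err), ion.index, ion, k, err))
    candidates.sort(key=lambda t: (t[0], t[1], t[2].series))
    used_peaks = {"b": set(), "y": set()}
    used_ions = set()
    matches = []
    for _, _, ion, k, err in candidates:
        key = (ion.series, ion.index)
        if key in used_ions or k in used_peaks[ion.series]:
            continue
        used_ions.add(key)
        used_peaks[ion.series].add(k)
        matches.append((ion, k, err))
    matches.sort(key=lambda m: (m[0].series, m[0].index))
    n_b = sum(1 for ion, _, _ in matches if ion.series == "b")
    n_y = sum(1 for ion, _, _ in matches if ion.series == "y")
    return SpectrumAnnotation(
        matches=matches,
        y_coverage=n_y / (n - 1),
        b_coverage=n_b / (n - 1),
        ambiguous_positions=isobaric_flags(candidate, tol),
    )


def isobaric_flags(
    candidate: PeptideSpecies, tol: float = 0.3
) -> list[tuple[int, tuple[str, ...]]]:
    """Positions whose residue is mass-indistinguishable from another.

    A residue is flagged when substituting it by a different residue would
    change the peptide mass by less than ``tol`` Da.  Ile/Leu (Δ = 0) are
    always flagged; Lys/Gln (Δ = 0.03639 Da) only at tolerances above that
    difference.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    flags = []
    for pos, aa in enumerate(candidate.sequence, start=1):
        m = DEFAULT_TABLE.mass(aa)
        alts = tuple(
            sorted(
                other
                for other in DEFAULT_TABLE.mono
                if other != aa
                and (
                    DEFAULT_TABLE.mass(other) == m  # exact isobars (Ile/Leu)
                    or abs(DEFAULT_TABLE.mass(other) - m) < tol
                )
            )
        )
        if alts:
            flags.append((pos, alts))
    return flags
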