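"""Seeded generators for every input class the pipeline consumes.

Each generator takes a :class:`GeneratorConfig` and returns data together
with its ground truth, so downstream operations can be tested by recovery:
cyclotide sequences with the cystine-knot connectivity, MALDI MS1 peak
lists with sodium satellites and noise peaks, b/y MS/MS spectra with peak
dropout, transcript contigs embedding precursor genes, and plate-reader /
stability-assay data with known IC50 and half-life.

All randomness flows through ``numpy.random.default_rng(cfg.seed)``: the
same seed reproduces the same outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .cck import predicted_oxidized_mz
from .kinetics import KineticTrace
from .masses import PeptideSpecies
from .msms import Spectrum, ion_series

__all__ = [
    "GeneratorConfig",
    "gen_cyclotide",
    "gen_ms_data",
    "gen_msms",
    "gen_transcripts",
    "gen_assay",
    "gen_decay",
]

#: Loop alphabet: the 19 non-Cys standard residues (a loop residue must
#: not add a seventh cysteine).
_LOOP_ALPHABET = "ADEFGHIKLMNPQRSTVWY"

#: [M+Na]+ sits this far above [M+H]+.
_NA_MINUS_H = 22.989218 - 1.007276


@dataclass
class GeneratorConfig:
    """Knobs for all generators; defaults emulate the study conditions.

    Loop-length ranges span the psysol-3 pattern 3/4/4/1/5/7; MALDI mass
    noise, sodium-satellite probability and MS/MS peak dropout default to
    clean data (recovery tests switch individual noise sources on).
    """

    seed: int = 0
    n_items: int = 10
    mass_sigma: float = 0.0  # Da, MS1 peak position noise
    rfu_sigma: float = 0.0  # plate-reader noise (RFU)
    dropout: float = 0.0  # MS/MS peak dropout probability
    na_probability: float = 0.3  # chance of a sodium satellite per peak
    n_noise_peaks: int = 0  # uniform noise peaks in the MS1 window
    ms1_window: tuple = (2000.0, 4000.0)
    loop_length_ranges: tuple = ((2, 4), (3, 5), (3, 5), (1, 2), (4, 6), (6, 8))
    flank_nt: int = 90  # random nucleotides around an embedded precursor
    # assay settings (units follow the caller's convention)
    true_ic50: float = 1.35
    hill: float = 1.0
    concentrations: tuple = None  # defaults to 8 half-log steps around IC50
    replicates: int = 3
    v0: float = 100.0  # uninhibited slope, RFU/min
    read_times_min: tuple = (0.0, 3.0, 6.0, 9.0)
    true_half_life_h: float = 6.7
    decay_times_h: tuple = (0.0, 5 / 60, 10 / 60, 20 / 60, 40 / 60, 1.0, 2.0, 4.0, 24.0)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_loop(rng, lo, hi, exclude_cys=True) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(_LOOP_ALPHABET), size=n))


def gen_cyclotide(cfg: GeneratorConfig) -> list[PeptideSpecies]:
    """Generate cyclic six-cysteine peptides with knot connectivity.

    The stored rotation starts at the cyclization-junction Gly inside loop
    6 and ends with the Asn processing site, as in natural sequences.  The
    three disulfides I–IV, II–V, III–VI are recorded as ground truth on
    each species.
    """
    rng = cfg.rng()
    out = []
    for _ in range(cfg.n_items):
        loops = [
            _random_loop(rng, lo, hi) for lo, hi in cfg.loop_length_ranges[:5]
        ]
        lo6, hi6 = cfg.loop_length_ranges[5]
        n6 = int(rng.integers(max(lo6, 4), hi6 + 1))
        body6 = "".join(rng.choice(list(_LOOP_ALPHABET), size=n6 - 2))
        split = n6 // 2
        # loop6 wraps the junction: ...{prefix}N | G{suffix}...
        prefix6 = body6[: split - 1] + "N"
        suffix6 = "G" + body6[split - 1 :]
        seq = (
            suffix6
            + "C" + loops[0]
            + "C" + loops[1]
            + "C" + loops[2]
            + "C" + loops[3]
            + "C" + loops[4]
            + "C" + prefix6
        )
        cys = [k + 1 for k, aa in enumerate(seq) if aa == "C"]
        bonds = [(cys[0], cys[3]), (cys[1], cys[4]), (cys[2], cys[5])]
        out.append(PeptideSpecies(seq, "cyclic", disulfide_bonds=bonds))
    return out


def gen_ms_data(
    species: list[PeptideSpecies], cfg: GeneratorConfig
) -> tuple[list[tuple[float, float]], dict[str, float]]:
    """Simulate a MALDI MS1 peak list for a set of oxidized species.

    Each species contributes its [M+H]+ (± ``mass_sigma``), with
    probability ``na_probability`` a sodium satellite, and
    ``n_noise_peaks`` uniform noise peaks are added across the window.
    Returns the sorted peak list and a ground-truth map sequence → exact
    theoretical [M+H]+.
    """
    if not species:
        raise ValueError("species set must be non-empty")
    rng = cfg.rng()
    peaks = []
    truth = {}
    for p in species:
        theo = predicted_oxidized_mz(p)
        truth[p.sequence] = theo
        mz = theo + (rng.normal(0.0, cfg.mass_sigma) if cfg.mass_sigma else 0.0)
        peaks.append((mz, float(rng.uniform(500, 5000))))
        if rng.random() < cfg.na_probability:
            peaks.append((mz + _NA_MINUS_H, float(rng.uniform(100, 1000))))
    lo, hi = cfg.ms1_window
    for _ in range(cfg.n_noise_peaks):
        peaks.append((float(rng.uniform(lo, hi)), float(rng.uniform(50, 500))))
    peaks.sort()
    return peaks, truth


def gen_msms(linear: PeptideSpecies, cfg: GeneratorConfig) -> Spectrum:
    """Simulate an MS/MS spectrum from a linear candidate's b/y series.

    Every theoretical ion appears unless dropped (probability
    ``dropout``); peak positions get ``mass_sigma`` Gaussian noise.
    """
    rng = cfg.rng()
    peaks = []
    for ion in ion_series(linear):
        if cfg.dropout and rng.random() < cfg.dropout:
            continue
        mz = ion.mz + (rng.normal(0.0, cfg.mass_sigma) if cfg.mass_sigma else 0.0)
        peaks.append((mz, float(rng.uniform(100, 1000))))
    from .masses import peptide_mass

    return Spectrum(
        precursor_mz=peptide_mass(linear) + 1.007276,
        precursor_charge=1,
        peaks=peaks,
    )


def _codons_for(rng, protein: str) -> str:
    table = standard_dna_table
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    return "".join(rng.choice(sorted(by_aa[aa])) for aa in protein)


#: Oak1-style scaffold around an embedded mature domain: ER signal
#: (hydrophobic core), N-terminal propeptide, then mature, then a small
#: C-terminal tail starting with a small residue (the AEP ligation site).
_SIGNAL = "MAKLTALVLLFAALLLVSA"
_PROPEPTIDE = "AEDALKTEAQVLSE"
_TAIL = "SLAA"


def build_precursor(mature: str) -> str:
    """Assemble an oak1-style precursor protein around a mature domain."""
    return _SIGNAL + _PROPEPTIDE + mature + _TAIL


def gen_transcripts(
    species: list[PeptideSpecies], cfg: GeneratorConfig
) -> tuple[list, list[dict]]:
    """Embed precursor genes for the given mature peptides into contigs.

    Each contig carries one precursor (signal + pro + mature + tail) at a
    random frame and strand, codon-randomized, flanked by random
    nucleotides.  Returns contigs and a ground-truth record per contig
    (mature sequence, frame, nucleotide start of the precursor).
    """
    from .mining import Contig

    rng = cfg.rng()
    contigs, truth = [], []
    for k, p in enumerate(species):
        protein = build_precursor(p.sequence)
        coding = _codons_for(rng, protein)
        offset = int(rng.integers(0, 3))
        flank1 = "".join(rng.choice(list("ACGT"), size=cfg.flank_nt + offset))
        flank2 = "".join(rng.choice(list("ACGT"), size=cfg.flank_nt))
        forward = flank1 + coding + flank2
        start = len(flank1)  # 0-based start of the precursor on `forward`
        frame = start % 3 + 1
        reverse = bool(rng.random() < 0.5)
        if reverse:
            contig_seq = str(Seq(forward).reverse_complement())
            frame = -frame
        else:
            contig_seq = forward
        contigs.append(Contig(f"contig{k + 1}", contig_seq))
        truth.append(
            {
                "contig": f"contig{k + 1}",
                "mature": p.sequence,
                "frame": frame,
                "precursor_nt_start": start + 1,
                "protein": protein,
            }
        )
    return contigs, truth


def _remaining_activity(c: float, ic50: float, hill: float) -> float:
    return 100.0 / (1.0 + 10.0 ** ((np.log10(c) - np.log10(ic50)) * hill))


def gen_assay(cfg: GeneratorConfig) -> tuple[list[KineticTrace], dict]:
    """Simulate plate-reader kinetic traces for a dose–response experiment.

    Sample wells read fluorescence linear in time with slope
    ``v0 × remaining(c)/100`` under the true 4PL; ``max_activity`` wells
    have the uninhibited slope and ``substrate_control`` wells are flat.
    Gaussian RFU noise is ``rfu_sigma``.  Ground truth holds the true
    IC50, hill slope and v0.
    """
    if cfg.true_ic50 <= 0 or cfg.hill == 0:
        raise ValueError("true IC50 must be positive and hill non-zero")
    rng = cfg.rng()
    concs = cfg.concentrations
    if concs is None:
        concs = tuple(cfg.true_ic50 * 10.0 ** e for e in np.arange(-2, 2, 0.5))
    t = np.asarray(cfg.read_times_min)
    traces = []
    well = 0

    def noise(size):
        return rng.normal(0.0, cfg.rfu_sigma, size) if cfg.rfu_sigma else np.zeros(size)

    for c in concs:
        slope = cfg.v0 * _remaining_activity(c, cfg.true_ic50, cfg.hill) / 100.0
        for _ in range(cfg.replicates):
            well += 1
            traces.append(
                KineticTrace(
                    well=f"S{well}",
                    sample="sample",
                    concentration=float(c),
                    times=list(t),
                    rfu=list(slope * t + noise(len(t))),
                )
            )
    for r in range(cfg.replicates):
        traces.append(
            KineticTrace(
                well=f"MAX{r + 1}",
                sample="max_activity",
                concentration=0.0,
                times=list(t),
                rfu=list(cfg.v0 * t + noise(len(t))),
            )
        )
        traces.append(
            KineticTrace(
                well=f"BG{r + 1}",
                sample="substrate_control",
                concentration=0.0,
                times=list(t),
                rfu=list(noise(len(t))),
            )
        )
    return traces, {"ic50": cfg.true_ic50, "hill": cfg.hill, "v0": cfg.v0}


def gen_decay(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate a one-phase stability time course (percent intact vs h).

    Exact exponential with half-life ``true_half_life_h``; multiplicative
    Gaussian noise of relative size ``rfu_sigma``/100 when set.
    """
    rng = cfg.rng()
    t = np.asarray(cfg.decay_times_h, dtype=float)
    k = np.log(2) / cfg.true_half_life_h
    y = 100.0 * np.exp(-k * t)
    if cfg.rfu_sigma:
        y = y * (1.0 + rng.normal(0.0, cfg.rfu_sigma / 100.0, len(t)))
    return t, y, {"half_life": cfg.true_half_life_h, "k": k}
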