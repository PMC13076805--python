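"""Residue mass tables, modification registry and peptide mass arithmetic.

The unit of computation is the :class:`PeptideSpecies`: a residue string with
a topology (linear, or head-to-tail cyclic), a set of disulfide bonds and a
list of chemical modifications.  Masses obey simple additive bookkeeping:

* a linear peptide weighs the sum of its residue masses plus one water;
* a head-to-tail cyclic peptide has no free termini and therefore no water;
* each disulfide bond removes two hydrogens (−2.015650 Da);
* every registered modification contributes its signed delta.

Cyclic sequences are stored as one explicit rotation; all mass operations
are rotation-invariant by construction because they only ever sum over the
multiset of residues.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

from .constants import DISULFIDE, PROTON, SODIUM, WATER

__all__ = [
    "ResidueMassTable",
    "ModificationSpec",
    "PeptideSpecies",
    "AdductSpec",
    "MODIFICATIONS",
    "DEFAULT_TABLE",
    "PROTON_ADDUCT",
    "SODIUM_ADDUCT",
    "peptide_mass",
    "ion_mz",
    "modification_delta",
    "apply_protocol",
]


class ResidueMassTable:
    """Monoisotopic and average masses of the 20 standard residues.

    Shipped as a TSV inside the package; user tables can be loaded from any
    path with the same three-column layout.
    """

    def __init__(self, mono: dict[str, float], average: dict[str, float]):
        self.mono = dict(mono)
        self.average = dict(average)
        for aa, m in self.mono.items():
            if m <= 0 or self.average[aa] <= 0:
                raise ValueError(f"non-positive mass for residue {aa!r}")
            if m >= self.average[aa] and aa != "G":
                # monoisotopic < average for every multi-isotope composition
                raise ValueError(f"monoisotopic >= average for residue {aa!r}")

    @classmethod
    def from_tsv(cls, path=None) -> "ResidueMassTable":
        if path is None:
            path = importlib.resources.files("cycloms.data") / "residues.tsv"
        mono, average = {}, {}
        with open(str(path)) as fh:
            header = fh.readline()
            assert header.startswith("residue_code")
            for line in fh:
                if not line.strip():
                    continue
                code, m, a = line.split("\t")
                mono[code] = float(m)
                average[code] = float(a)
        return cls(mono, average)

    def mass(self, residue: str, scale: str = "monoisotopic") -> float:
        table = self.mono if scale == "monoisotopic" else self.average
        try:
            return table[residue]
        except KeyError:
            raise KeyError(f"unknown residue {residue!r}") from None

    def __contains__(self, residue: str) -> bool:
        return residue in self.mono


@dataclass(frozen=True)
class ModificationSpec:
    """A named mass modification.

    ``site_rule`` is either a string of residue letters the modification may
    attach to, or one of the sentinels ``"cyclic"`` (applies to the backbone
    of a cyclic peptide) and ``"cterm"`` (C-terminus of a linear peptide).
    ``per_site`` modifications are applied once per matching site; others
    once per peptide.
    """

    name: str
    delta_mass: float
    site_rule: str
    per_site: bool


def _load_modifications() -> dict[str, ModificationSpec]:
    path = importlib.resources.files("cycloms.data") / "modifications.tsv"
    registry = {}
    with open(str(path)) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            name, delta, rule, per_site = parts
            registry[name] = ModificationSpec(name, float(delta), rule, per_site == "1")
    return registry


#: Shipped modification registry (disulfide bond, reduction,
#: carbamidomethylation, ring-opening hydration, C-terminal amidation).
MODIFICATIONS: dict[str, ModificationSpec] = _load_modifications()

DEFAULT_TABLE = ResidueMassTable.from_tsv()


@dataclass(frozen=True)
class AdductSpec:
    """Charge carrier of an observed ion (proton or sodium cation)."""

    name: str
    charge_carrier_mass: float
    charge: int = 1

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")


PROTON_ADDUCT = AdductSpec("H", PROTON, 1)
SODIUM_ADDUCT = AdductSpec("Na", SODIUM, 1)


@dataclass
class PeptideSpecies:
    """A peptide sequence with topology, disulfides and modifications.

    ``sequence`` is in N→C order; for a cyclic peptide it is one chosen
    rotation.  ``disulfide_bonds`` are 1-based residue-index pairs on that
    rotation.  ``modifications`` is a list of ``(ModificationSpec, site)``
    where ``site`` is a 1-based index or the string ``"global"``.
    """

    sequence: str
    topology: str = "linear"
    disulfide_bonds: list[tuple[int, int]] = field(default_factory=list)
    modifications: list[tuple[ModificationSpec, object]] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        if self.topology not in ("linear", "cyclic"):
            raise ValueError(f"topology must be linear|cyclic, got {self.topology!r}")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in DEFAULT_TABLE:
                raise ValueError(f"unknown residue {aa!r} at position {pos}")
        bonded = set()
        for i, j in self.disulfide_bonds:
            for idx in (i, j):
                if not 1 <= idx <= len(self.sequence):
                    raise ValueError(f"disulfide index {idx} out of range")
                if self.sequence[idx - 1] != "C":
                    raise ValueError(f"disulfide index {idx} does not point at Cys")
                if idx in bonded:
                    raise ValueError(f"Cys {idx} listed in two disulfide bonds")
                bonded.add(idx)
        for spec, site in self.modifications:
            self._check_site(spec, site, bonded)

    def _check_site(self, spec: ModificationSpec, site, bonded: set[int]):
        if spec.site_rule == "cyclic":
            if self.topology != "cyclic":
                raise ValueError(f"{spec.name} applies to cyclic peptides only")
            return
        if spec.site_rule == "cterm":
            if self.topology != "linear":
                raise ValueError(
                    f"{spec.name} is a terminal modification; cyclic topology has no termini"
                )
            return
        if site == "global":
            sites = [
                k for k, aa in enumerate(self.sequence, start=1) if aa in spec.site_rule
            ]
            if not sites:
                raise ValueError(f"no site matching {spec.site_rule!r} for {spec.name}")
            check = sites
        else:
            if not 1 <= site <= len(self.sequence):
                raise ValueError(f"modification site {site} out of range")
            if self.sequence[site - 1] not in spec.site_rule:
                raise ValueError(
                    f"{spec.name} not allowed on {self.sequence[site - 1]!r} at site {site}"
                )
            check = [site]
        if spec.name == "carbamidomethyl":
            clash = [k for k in check if k in bonded]
            if clash:
                raise ValueError(
                    f"Cys at {clash} cannot be both disulfide-bonded and alkylated"
                )

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")

    def is_cyclic(self) -> bool:
        return self.topology == "cyclic"

    def rotated(self, offset: int) -> "PeptideSpecies":
        """Return the same cyclic species stored from a different start."""
        if self.topology != "cyclic":
            raise ValueError("only cyclic species can be rotated")
        n = len(self.sequence)
        offset %= n

        def shift(idx: int) -> int:
            return (idx - 1 - offset) % n + 1

        return PeptideSpecies(
            sequence=self.sequence[offset:] + self.sequence[:offset],
            topology="cyclic",
            disulfide_bonds=[(shift(i), shift(j)) for i, j in self.disulfide_bonds],
            modifications=[
                (spec, site if site == "global" else shift(site))
                for spec, site in self.modifications
            ],
        )


def _modification_sum(p: PeptideSpecies) -> float:
    total = 0.0
    for spec, site in p.modifications:
        if site == "global" and spec.per_site and spec.site_rule not in ("cyclic", "cterm"):
            n = sum(aa in spec.site_rule for aa in p.sequence)
            total += spec.delta_mass * n
        else:
            total += spec.delta_mass
    return total


def peptide_mass(
    p: PeptideSpecies,
    scale: str = "monoisotopic",
    table: ResidueMassTable | None = None,
) -> float:
    """Neutral mass of a peptide species in Da.

    Sum of residue masses, plus one water for a linear backbone, plus all
    modification deltas, minus 2.015650 Da per disulfide bond.
    """
    if scale not in ("monoisotopic", "average"):
        raise ValueError(f"scale must be monoisotopic|average, got {scale!r}")
    table = table or DEFAULT_TABLE
    mass = sum(table.mass(aa, scale) for aa in p.sequence)
    if p.topology == "linear":
        mass += WATER
    mass += _modification_sum(p)
    mass -= DISULFIDE * len(p.disulfide_bonds)
    return mass


def ion_mz(mass: float, adduct: AdductSpec) -> float:
    """m/z of an ion: ``(M + z * carrier) / z``."""
    if mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {mass}")
    return (mass + adduct.charge * adduct.charge_carrier_mass) / adduct.charge


def _resolve(spec) -> ModificationSpec:
    if isinstance(spec, ModificationSpec):
        return spec
    return MODIFICATIONS[spec]


def modification_delta(
    p: PeptideSpecies, protocol: list[tuple]
) -> float:
    """Total signed mass change of a modification protocol.

    ``protocol`` is a list of ``(modification, count)`` pairs, where the
    modification is a :class:`ModificationSpec` or a registry name.
    Reducing *k* disulfides contributes +2.015650 k; alkylating *c*
    cysteines +57.021464 c; opening the ring +18.010565.  Alkylation of
    more cysteines than are thiol-free after the protocol's reductions is
    rejected.
    """
    delta = 0.0
    n_reduced = 0
    free_cys = p.n_cys - 2 * len(p.disulfide_bonds)
    for entry in protocol:
        spec, count = entry
        spec = _resolve(spec)
        if count < 0:
            raise ValueError(f"negative count for {spec.name}")
        if spec.name == "reduction":
            if n_reduced + count > len(p.disulfide_bonds):
                raise ValueError(
                    f"cannot reduce {n_reduced + count} disulfides; species has "
                    f"{len(p.disulfide_bonds)}"
                )
            n_reduced += count
            free_cys += 2 * count
        elif spec.name == "carbamidomethyl":
            if count > free_cys:
                raise ValueError(
                    f"cannot alkylate {count} Cys; only {free_cys} free thiols "
                    "(reduce disulfides first)"
                )
            free_cys -= count
        elif spec.site_rule == "cyclic" and p.topology != "cyclic":
            raise ValueError(f"{spec.name} applies to cyclic peptides only")
        delta += spec.delta_mass * count
    return delta


def apply_protocol(p: PeptideSpecies, protocol: list[tuple]) -> PeptideSpecies:
    """Return the species that results from running a protocol on ``p``.

    Reductions remove disulfide bonds (lowest-index pairs first),
    carbamidomethylation attaches per-site modifications to free cysteines,
    and ring opening converts the topology to linear.  The returned species
    satisfies ``peptide_mass(result) == peptide_mass(p) + modification_delta``.
    """
    modification_delta(p, protocol)  # validate up front
    bonds = sorted(p.disulfide_bonds)
    mods = list(p.modifications)
    topology = p.topology
    for entry in protocol:
        spec, count = entry
        spec = _resolve(spec)
        if spec.name == "reduction":
            bonds = bonds[count:]
        elif spec.name == "carbamidomethyl":
            bonded = {i for pair in bonds for i in pair}
            free = [
                k
                for k, aa in enumerate(p.sequence, start=1)
                if aa == "C"
                and k not in bonded
                and not any(s == k and m.name == "carbamidomethyl" for m, s in mods)
            ]
            for site in free[:count]:
                mods.append((spec, site))
        elif spec.name == "ring_open_hydration":
            if topology != "cyclic":
                raise ValueError("ring opening applies to cyclic peptides only")
            # the linear topology itself carries the +water; no mod entry needed
            topology = "linear"
        else:
            mods.append((spec, "global"))
    return replace(p, disulfide_bonds=bonds, modifications=mods, topology=topology)
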