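"""In-silico proteolysis of linear and head-to-tail cyclic peptides.

A cyclic backbone behaves differently from a linear one under proteolysis:
a single cleavage site does not fragment the molecule but *opens the ring*,
yielding one full-length linear peptide that is one water heavier than the
ring.  Two or more sites yield arcs between ordered site pairs; partial
digestion leaves internal sites uncut (missed cleavages).  This mass
signature — one product, +18.011 Da, no residue loss — is the standard
evidence for backbone cyclicity.

Coordinates are 1-based inclusive on the stored rotation; wrap-around arcs
are written with ``start > end`` (e.g. 26–7 on a 30-mer).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .constants import PROTON, SODIUM
from .masses import PeptideSpecies, peptide_mass

__all__ = [
    "CleavageRule",
    "DigestProduct",
    "ENZYMES",
    "cleavage_sites",
    "digest",
    "digest_table",
]


@dataclass(frozen=True)
class CleavageRule:
    """An enzyme specificity: cleave after ``cleave_after`` residues unless
    the next residue is in ``blocked_before``."""

    enzyme_name: str
    cleave_after: frozenset = frozenset()
    blocked_before: frozenset = frozenset()

    def __post_init__(self):
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")


def _load_enzymes() -> dict[str, CleavageRule]:
    path = importlib.resources.files("cycloms.data") / "enzymes.tsv"
    rules = {}
    with open(str(path)) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            parts = (line.rstrip("\n").split("\t") + [""])[:3]
            name, after, blocked = parts
            rules[name] = CleavageRule(name, frozenset(after), frozenset(blocked))
    return rules


#: Shipped enzyme rules.  ``chymotrypsin`` cleaves after F/Y/W/L/M with no
#: proline block — the broad specificity needed to account for cleavage at
#: Leu–Pro bonds seen in long MALDI digests; ``chymotrypsin_strict`` is the
#: textbook F/Y/W-with-P-block variant.  ``gluc`` is Glu-only (ammonium
#: bicarbonate conditions); ``gluc_de`` adds Asp.
ENZYMES: dict[str, CleavageRule] = _load_enzymes()


@dataclass
class DigestProduct:
    """One proteolytic product: an arc of the parent sequence.

    ``start``/``end`` are 1-based inclusive on the parent's stored rotation;
    a wrap-around arc on a cyclic parent has ``start > end``.  The mass is
    that of the arc read as a *linear* peptide (it gains one water on
    cleavage) carrying the parent's per-site modifications that fall inside
    the arc.
    """

    parent: PeptideSpecies
    start: int
    end: int
    sequence: str
    n_missed: int
    mass: float
    is_ring_opened_full_length: bool = False
    species: PeptideSpecies = field(default=None, repr=False)

    @property
    def mz_h(self) -> float:
        """[M+H]+ of the product."""
        return self.mass + PROTON

    @property
    def mz_na(self) -> float:
        """[M+Na]+ of the product."""
        return self.mass + SODIUM


def cleavage_sites(p: PeptideSpecies, rule: CleavageRule) -> list[int]:
    """Positions (1-based residue index) after which the enzyme cuts.

    On a cyclic peptide the bond between the last and first stored residue
    is a valid site; on a linear peptide there is no bond after the final
    residue.
    """
    seq = p.sequence
    n = len(seq)
    sites = []
    for i in range(1, n + 1):
        if seq[i - 1] not in rule.cleave_after:
            continue
        if p.is_cyclic():
            nxt = seq[i % n]
        else:
            if i == n:
                continue
            nxt = seq[i]
        if nxt in rule.blocked_before:
            continue
        sites.append(i)
    return sites


def _arc_indices(n: int, start: int, end: int) -> list[int]:
    if start <= end:
        return list(range(start, end + 1))
    return list(range(start, n + 1)) + list(range(1, end + 1))


def _product(p: PeptideSpecies, start: int, end: int, n_missed: int,
             full_length: bool = False) -> DigestProduct:
    idx = _arc_indices(len(p.sequence), start, end)
    seq = "".join(p.sequence[k - 1] for k in idx)
    pos_map = {k: new + 1 for new, k in enumerate(idx)}
    in_arc = set(idx)
    mods = []
    for spec, site in p.modifications:
        if site == "global":
            if full_length:
                mods.append((spec, "global"))
        elif site in in_arc:
            mods.append((spec, pos_map[site]))
    bonds = [
        (pos_map[i], pos_map[j])
        for i, j in p.disulfide_bonds
        if i in in_arc and j in in_arc
    ]
    species = PeptideSpecies(seq, "linear", disulfide_bonds=bonds, modifications=mods)
    return DigestProduct(
        parent=p,
        start=start,
        end=end,
        sequence=seq,
        n_missed=n_missed,
        mass=peptide_mass(species),
        is_ring_opened_full_length=full_length,
        species=species,
    )


def digest(
    p: PeptideSpecies,
    rules: CleavageRule | list[CleavageRule],
    max_missed: int | None = None,
) -> list[DigestProduct]:
    """Enumerate proteolytic products of ``p`` under one or several enzymes.

    Several rules act as a combined digest (union of their cleavage sites).
    ``max_missed`` bounds internal uncut sites per product; ``None`` means
    unlimited (appropriate when matching peaks from partial time-course
    digests).

    A cyclic parent with exactly one site yields the single ring-opened
    full-length linear product; with k ≥ 2 sites it yields all arcs between
    ordered pairs of distinct sites.  A cyclic parent with no site yields
    an empty list (the intact ring is not a digestion product).
    """
    if isinstance(rules, CleavageRule):
        rules = [rules]
    sites = sorted({s for r in rules for s in cleavage_sites(p, r)})
    n = len(p.sequence)
    products: list[DigestProduct] = []
    if p.is_cyclic():
        k = len(sites)
        if k == 0:
            return []
        if k == 1:
            s = sites[0]
            start = s % n + 1
            return [_product(p, start, s, 0, full_length=True)]
        for a in range(k):
            for b in range(k):
                if a == b:
                    continue
                missed = (b - a - 1) % k
                if max_missed is not None and missed > max_missed:
                    continue
                start = sites[a] % n + 1
                products.append(_product(p, start, sites[b], missed))
    else:
        bounds = [0] + sites + [n]
        for i in range(len(bounds) - 1):
            for j in range(i + 1, len(bounds)):
                missed = j - i - 1
                if max_missed is not None and missed > max_missed:
                    continue
                products.append(_product(p, bounds[i] + 1, bounds[j], missed))
    products.sort(key=lambda d: (d.n_missed, d.start, d.end))
    return products


def digest_table(products: list[DigestProduct]) -> pd.DataFrame:
    """Tabulate a digest: arc, sequence, missed cleavages, neutral mass,
    [M+H]+ and [M+Na]+ (m/z to 4 decimals on output)."""
    rows = [
        {
            "arc": f"{d.start}-{d.end}",
            "sequence": d.sequence,
            "n_missed": d.n_missed,
            "neutral_mass": round(d.mass, 4),
            "mz_h": round(d.mz_h, 4),
            "mz_na": round(d.mz_na, 4),
        }
        for d in products
    ]
    return pd.DataFrame(
        rows, columns=["arc", "sequence", "n_missed", "neutral_mass", "mz_h", "mz_na"]
    )
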