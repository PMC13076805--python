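"""Shipped worked example: the cyclotide psysol 3 and human oxytocin.

Psysol 3 is a 30-residue head-to-tail cyclic cystine-knot peptide from
*Psychotria solitudinum* with three disulfides in the canonical cyclotide
connectivity (CysI–CysIV, CysII–CysV, CysIII–CysVI).  Its full
modification ladder (native → reduced/alkylated → ring-opened) and digest
tables are the package's reference workflow.

Oxytocin is the nonapeptide substrate of prolyl oligopeptidase used in the
stability assays: linear CYIQNCPLG with a Cys1–Cys6 disulfide and a
C-terminal amide.
"""

from __future__ import annotations

from .masses import MODIFICATIONS, PeptideSpecies, apply_protocol

PSYSOL3_SEQUENCE = "GLPTCFETCILGTCYTPGCSCSTYRLCLNN"

#: CysI-IV, CysII-V, CysIII-VI on the stored rotation (positions 5, 9, 14,
#: 19, 21, 27) — the cystine-knot connectivity, annotated as assumed.
PSYSOL3_DISULFIDES = [(5, 19), (9, 21), (14, 27)]

OXYTOCIN_SEQUENCE = "CYIQNCPLG"


def psysol3() -> PeptideSpecies:
    """Native psysol 3: cyclic, three disulfides."""
    return PeptideSpecies(
        PSYSOL3_SEQUENCE, "cyclic", disulfide_bonds=list(PSYSOL3_DISULFIDES)
    )


def psysol3_reduced_alkylated() -> PeptideSpecies:
    """Psysol 3 after DTT reduction and iodoacetamide alkylation of all six
    cysteines (still cyclic)."""
    return apply_protocol(
        psysol3(), [("reduction", 3), ("carbamidomethyl", 6)]
    )


def oxytocin() -> PeptideSpecies:
    """Human oxytocin: linear CYIQNCPLG, Cys1–Cys6 disulfide, C-terminal
    amide."""
    return PeptideSpecies(
        OXYTOCIN_SEQUENCE,
        "linear",
        disulfide_bonds=[(1, 6)],
        modifications=[(MODIFICATIONS["amidation"], "global")],
    )
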