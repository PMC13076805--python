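"""Physical constants used throughout the mass arithmetic (Da)."""

#: Mass of one water molecule; the difference between a linear peptide and
#: the sum of its residue masses, and between a cyclic backbone and its
#: ring-opened linear form.
WATER = 18.010565

#: Mass of a proton (charge carrier of [M+nH]n+ ions).
PROTON = 1.007276

#: Mass of a hydrogen atom; a disulfide bond removes two of these.
HYDROGEN = 1.007825

#: Mass of a sodium cation (charge carrier of [M+Na]+ adducts).
SODIUM = 22.989218

#: Mass lost on forming one disulfide bond (2 H).
DISULFIDE = 2 * HYDROGEN

#: Carbamidomethylation of a cysteine thiol by iodoacetamide.
CARBAMIDOMETHYL = 57.021464

#: Net mass step per cysteine in a reduction + alkylation protocol:
#: +1 H from opening half a disulfide, +57.021464 from the acetamide group.
REDUCTION_ALKYLATION_PER_CYS = HYDROGEN + CARBAMIDOMETHYL
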