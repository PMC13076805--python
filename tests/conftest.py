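import pytest

from cycloms.examples import oxytocin, psysol3, psysol3_reduced_alkylated

# Monoisotopic residue masses, restated independently of the package's
# shipped table so oracle computations in the tests do not share its code
# path (standard amino-acid residue values).
RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565
PROTON = 1.007276


def naive_linear_mass(seq: str, n_cam: int = 0) -> float:
    """Independent brute-force mass oracle: plain table summation."""
    return sum(RESIDUE_MONO[aa] for aa in seq) + WATER + n_cam * 57.021464


@pytest.fixture
def native():
    return psysol3()


@pytest.fixture
def alkylated():
    return psysol3_reduced_alkylated()


@pytest.fixture
def ot():
    return oxytocin()
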