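"""In-silico proteolysis: site finding, ring opening, fragment enumeration."""

import itertools
import random

import pytest

from cycloms.constants import WATER
from cycloms.digestion import ENZYMES, cleavage_sites, digest, digest_table
from cycloms.masses import PeptideSpecies, peptide_mass


def scan_sites_oracle(seq: str, cyclic: bool, after: str, blocked: str) -> list[int]:
    """Independent position-by-position cleavage-site scan."""
    n = len(seq)
    out = []
    for i in range(1, n + 1):
        if seq[i - 1] not in after:
            continue
        if not cyclic and i == n:
            continue
        nxt = seq[i % n]
        if nxt in blocked:
            continue
        out.append(i)
    return out


class TestCleavageSites:
    def test_trypsin_finds_single_arg_site_on_psysol3(self, alkylated):
        assert cleavage_sites(alkylated, ENZYMES["trypsin"]) == [25]

    def test_gluc_finds_single_glu_site_on_psysol3(self, alkylated):
        assert cleavage_sites(alkylated, ENZYMES["gluc"]) == [7]

    def test_lysine_proline_bond_is_blocked(self):
        assert cleavage_sites(PeptideSpecies("KPAA"), ENZYMES["trypsin"]) == []

    def test_chymotrypsin_sites_match_scan_oracle(self, alkylated):
        rule = ENZYMES["chymotrypsin"]
        assert cleavage_sites(alkylated, rule) == scan_sites_oracle(
            alkylated.sequence, True, "FYWLM", ""
        )

    def test_wraparound_site_between_last_and_first_residue(self):
        # K is the final stored residue of this ring; the bond to residue 1 cuts
        p = PeptideSpecies("AAGK", "cyclic")
        assert cleavage_sites(p, ENZYMES["trypsin"]) == [4]


class TestDigestPsysol3:
    def test_trypsin_yields_single_ring_opened_full_length(self, alkylated):
        products = digest(alkylated, ENZYMES["trypsin"])
        assert len(products) == 1
        (product,) = products
        assert product.is_ring_opened_full_length
        assert product.sequence == "LCLNNGLPTCFETCILGTCYTPGCSCSTYR"
        assert product.mz_h == pytest.approx(3575.5, abs=0.25)

    def test_ring_opened_product_gains_one_water(self, alkylated):
        (product,) = digest(alkylated, ENZYMES["trypsin"])
        assert product.mass - peptide_mass(alkylated) == pytest.approx(
            WATER, abs=1e-9
        )

    def test_gluc_plus_trypsin_two_arcs_match_printed_masses(self, alkylated):
        products = digest(alkylated, [ENZYMES["gluc"], ENZYMES["trypsin"]], 0)
        assert len(products) == 2
        by_arc = {(d.start, d.end): d for d in products}
        assert by_arc[(8, 25)].sequence == "TCILGTCYTPGCSCSTYR"
        assert by_arc[(8, 25)].mz_h == pytest.approx(2156.8, abs=0.25)
        assert by_arc[(26, 7)].sequence == "LCLNNGLPTCFE"
        assert by_arc[(26, 7)].mz_na == pytest.approx(1459.5, abs=0.25)

    @pytest.mark.parametrize(
        "fragment, printed_mz",
        [
            ("PTCF", 524.2),
            ("ETCIL", 635.3),
            ("GTCY", 500.2),
            ("TPGCSCSTY", 1032.4),
            ("RLCLNNGLPTCF", 1464.7),
            ("RLCLNNGLPTCFETCIL", 2080.9),
            ("RLCLNNGLPTCFETCILGTCY", 2562.2),
        ],
    )
    def test_chymotryptic_fragments_match_printed_masses(
        self, alkylated, fragment, printed_mz
    ):
        """Partial chymotryptic digests reproduce the observed MALDI signals
        (unlimited missed cleavages; the PTCF fragment requires cleavage at
        a Leu-Pro bond, hence the broad chymotrypsin specificity)."""
        products = digest(alkylated, ENZYMES["chymotrypsin"])
        by_seq = {d.sequence: d for d in products}
        assert fragment in by_seq
        assert by_seq[fragment].mz_h == pytest.approx(printed_mz, abs=0.25)

    def test_cyclic_peptide_with_no_sites_yields_nothing(self):
        p = PeptideSpecies("GAGAGAGA", "cyclic")
        assert digest(p, ENZYMES["trypsin"]) == []


def brute_force_cyclic_digest(seq: str, after: str, max_missed) -> set:
    """All-rotations substring oracle: every arc bounded by cleavage sites,
    enumerated per rotation without wrap, deduplicated by arc coordinates."""
    n = len(seq)
    sites = scan_sites_oracle(seq, True, after, "")
    if len(sites) < 2:
        return set()
    arcs = set()
    for rot in range(n):
        rotated = seq[rot:] + seq[:rot]
        cuts = sorted(
            ((s - rot - 1) % n) + 1 for s in sites
        )  # site positions on this rotation
        for a, b in itertools.combinations(range(len(cuts)), 2):
            start_rot, end_rot = cuts[a] + 1, cuts[b]
            missed = b - a - 1
            if max_missed is not None and missed > max_missed:
                continue
            # map back to original coordinates
            start = (start_rot + rot - 1) % n + 1
            end = (end_rot + rot - 1) % n + 1
            arcs.add((start, end, rotated[start_rot - 1 : end_rot], missed))
    return arcs


class TestDigestProperties:
    def test_random_cyclic_digests_equal_substring_oracle(self):
        rng = random.Random(42)
        for _ in range(25):
            n = rng.randint(6, 15)
            seq = "".join(rng.choice("ACDEFGKLRSTY") for _ in range(n))
            p = PeptideSpecies(seq, "cyclic")
            for max_missed in (0, 1, None):
                got = {
                    (d.start, d.end, d.sequence, d.n_missed)
                    for d in digest(p, ENZYMES["trypsin"], max_missed)
                    if not d.is_ring_opened_full_length
                }
                want = brute_force_cyclic_digest(seq, "KR", max_missed)
                # oracle only covers the k>=2 case; single-site rings are
                # ring-opened full-length products, checked elsewhere
                if len(cleavage_sites(p, ENZYMES["trypsin"])) >= 2:
                    assert got == want

    def test_complete_digest_masses_conserve_parent_mass(self, alkylated):
        """Sum of 0-missed arc masses minus one water per cut equals the
        parent ring mass."""
        for enzymes in ([ENZYMES["chymotrypsin"]], [ENZYMES["gluc"], ENZYMES["trypsin"]]):
            products = [d for d in digest(alkylated, enzymes, 0)]
            k = len(products)
            assert k >= 2
            total = sum(d.mass for d in products)
            assert total - k * WATER == pytest.approx(
                peptide_mass(alkylated), abs=1e-4
            )

    def test_zero_missed_products_tile_the_ring_once(self, alkylated):
        products = digest(alkylated, ENZYMES["chymotrypsin"], 0)
        covered = []
        n = len(alkylated.sequence)
        for d in products:
            if d.start <= d.end:
                covered.extend(range(d.start, d.end + 1))
            else:
                covered.extend(list(range(d.start, n + 1)) + list(range(1, d.end + 1)))
        assert sorted(covered) == list(range(1, n + 1))

    def test_product_count_nondecreasing_in_max_missed(self, alkylated):
        counts = [
            len(digest(alkylated, ENZYMES["chymotrypsin"], m))
            for m in (0, 1, 2, 3, None)
        ]
        assert counts == sorted(counts)

    def test_linear_digest_standard_subpeptides(self):
        p = PeptideSpecies("AAKGGRCC")
        products = digest(p, ENZYMES["trypsin"], 0)
        assert [d.sequence for d in products] == ["AAK", "GGR", "CC"]
        assert [(d.start, d.end) for d in products] == [(1, 3), (4, 6), (7, 8)]

    def test_digest_table_columns(self, alkylated):
        table = digest_table(digest(alkylated, ENZYMES["trypsin"]))
        assert list(table.columns) == [
            "arc", "sequence", "n_missed", "neutral_mass", "mz_h", "mz_na",
        ]
        assert table.loc[0, "arc"] == "26-25"
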