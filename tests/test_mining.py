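"""Six-frame translation, precursor scanning and mature-domain extraction."""

import random

import pytest

from cycloms.cck import predicted_oxidized_mz
from cycloms.masses import PeptideSpecies
from cycloms.mining import (
    Contig,
    ProcessingRules,
    detection_table,
    extract_mature,
    scan_precursors,
    six_frame_translate,
)
from cycloms.simulate import (
    GeneratorConfig,
    build_precursor,
    gen_cyclotide,
    gen_ms_data,
    gen_transcripts,
)

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def codon_walk_oracle(nt: str, frame: int) -> str:
    """Naive frame-by-frame codon lookup, independent of Biopython."""
    if frame < 0:
        nt = "".join(COMPLEMENT[c] for c in reversed(nt))
    offset = abs(frame) - 1
    out = []
    for k in range(offset, len(nt) - 2, 3):
        codon = nt[k : k + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


class TestSixFrameTranslate:
    def test_simple_forward_frame(self):
        frames = six_frame_translate(Contig("c", "ATGGGA"))
        assert frames[1] == "MG"

    def test_reverse_frame_equals_forward_of_revcomp(self):
        rng = random.Random(5)
        for _ in range(10):
            nt = "".join(rng.choice("ACGT") for _ in range(rng.randint(60, 120)))
            rc = "".join(COMPLEMENT[c] for c in reversed(nt))
            f = six_frame_translate(Contig("a", nt))
            g = six_frame_translate(Contig("b", rc))
            assert f[-1] == g[1]
            assert f[-2] == g[2]

    def test_random_contigs_match_codon_walk_oracle(self):
        rng = random.Random(99)
        for _ in range(100):
            nt = "".join(rng.choice("ACGT") for _ in range(rng.randint(60, 150)))
            frames = six_frame_translate(Contig("c", nt))
            for frame in (1, 2, 3, -1, -2, -3):
                assert frames[frame] == codon_walk_oracle(nt, frame)

    def test_invalid_nucleotide_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            Contig("bad", "ACXGT")


class TestScanAndExtract:
    def test_embedded_precursor_found_at_correct_frame(self):
        cfg = GeneratorConfig(seed=31, n_items=6)
        species = gen_cyclotide(cfg)
        contigs, truth = gen_transcripts(species, cfg)
        queries = {f"q{k}": p.sequence for k, p in enumerate(species)}
        annotations = scan_precursors(contigs, queries, min_score=40)
        by_contig = {a.contig_id: a for a in annotations}
        for rec in truth:
            assert rec["contig"] in by_contig
            assert by_contig[rec["contig"]].frame == rec["frame"]

    def test_random_contig_yields_no_hits_at_stringent_score(self):
        rng = random.Random(8)
        contigs = [
            Contig("noise", "".join(rng.choice("ACGT") for _ in range(600)))
        ]
        hits = scan_precursors(contigs, ["GLPTCFETCILGTCYTPGCSCSTYRLCLNN"], 50)
        assert hits == []

    def test_planted_mature_domain_extracted_exactly(self):
        cfg = GeneratorConfig(seed=32, n_items=10)
        species = gen_cyclotide(cfg)
        contigs, truth = gen_transcripts(species, cfg)
        annotations = scan_precursors(
            contigs, [p.sequence for p in species], min_score=40
        )
        by_contig = {a.contig_id: a for a in annotations}
        for rec in truth:
            candidate = extract_mature(by_contig[rec["contig"]])
            assert candidate.sequence == rec["mature"]

    def test_planted_recovery_rate_at_least_98_percent(self):
        """Desk-scale recovery: 50 seeded contigs, one precursor each."""
        cfg = GeneratorConfig(seed=33, n_items=50)
        species = gen_cyclotide(cfg)
        contigs, truth = gen_transcripts(species, cfg)
        annotations = scan_precursors(
            contigs, [p.sequence for p in species], min_score=40
        )
        by_contig = {a.contig_id: a for a in annotations}
        recovered = 0
        for rec in truth:
            ann = by_contig.get(rec["contig"])
            if ann is None:
                continue
            try:
                if extract_mature(ann).sequence == rec["mature"]:
                    recovered += 1
            except ValueError:
                pass
        assert recovered >= 49

    def test_mature_with_wrong_cysteine_count_rejected(self):
        mature = "GLPTCFETCILGTCYTPGGSGSTYRLALNN"  # 4 Cys only
        protein = build_precursor(mature)
        ann_protein = protein
        from cycloms.mining import PrecursorAnnotation

        ann = PrecursorAnnotation(
            contig_id="c", frame=1, orf_nt_start=1,
            orf_nt_end=3 * len(ann_protein), protein=ann_protein,
            hit_start=len(ann_protein) - len(mature) - 4,
            hit_end=len(ann_protein) - 4, score=60.0,
        )
        with pytest.raises(ValueError, match="no mature domain"):
            extract_mature(ann)

    def test_psysol3_planted_in_scaffold_recovers_printed_mass(self):
        """The mature sequence planted in an oak1-style precursor predicts
        the printed native [M+H]+."""
        mature = "GLPTCFETCILGTCYTPGCSCSTYRLCLNN"
        cfg = GeneratorConfig(seed=34, n_items=1)
        contigs, _ = gen_transcripts([PeptideSpecies(mature, "cyclic")], cfg)
        (ann,) = scan_precursors(contigs, [mature], min_score=40)
        candidate = extract_mature(ann)
        assert candidate.sequence == mature
        assert candidate.predicted_mz == pytest.approx(3209.4, abs=0.25)

    def test_signal_peptide_heuristic_flags_scaffold(self):
        cfg = GeneratorConfig(seed=35, n_items=1)
        species = gen_cyclotide(cfg)
        contigs, _ = gen_transcripts(species, cfg)
        (ann,) = scan_precursors(contigs, [species[0].sequence], min_score=40)
        assert ann.signal_detected


class TestDetectionTable:
    def test_spiked_subset_detected(self):
        cfg = GeneratorConfig(seed=36, n_items=10, na_probability=0.0)
        species = gen_cyclotide(cfg)
        contigs, _ = gen_transcripts(species, cfg)
        annotations = scan_precursors(
            contigs, [p.sequence for p in species], min_score=40
        )
        candidates = [extract_mature(a) for a in annotations]
        peaks, _ = gen_ms_data(species[:7], cfg)
        table = detection_table(candidates, peaks, 0.25)
        assert (table["detected"] == "y").sum() == 7
        assert (table["detected"] == "n").sum() == 3

    def test_empty_peaks_all_undetected(self):
        cfg = GeneratorConfig(seed=37, n_items=3)
        species = gen_cyclotide(cfg)
        contigs, _ = gen_transcripts(species, cfg)
        annotations = scan_precursors(
            contigs, [p.sequence for p in species], min_score=40
        )
        candidates = [extract_mature(a) for a in annotations]
        table = detection_table(candidates, [], 0.25)
        assert set(table["detected"]) == {"n"}

    def test_duplicate_candidates_collapse(self):
        cfg = GeneratorConfig(seed=38, n_items=2)
        species = gen_cyclotide(cfg)
        contigs, _ = gen_transcripts(species + species, cfg)
        annotations = scan_precursors(
            contigs, [p.sequence for p in species], min_score=40
        )
        candidates = [extract_mature(a) for a in annotations]
        table = detection_table(candidates, [], 0.25)
        assert len(table) == len({c.sequence for c in candidates})
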