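# Methods

## Mass model

All arithmetic is monoisotopic by default, over the 20 standard residues
(shipped as a TSV, values to 6 decimals, cross-checked in the test suite
against an independent proteomics mass library).  Constants: water
18.010565 Da, proton 1.007276 Da, hydrogen atom 1.007825 Da, sodium
cation 22.989218 Da.  A linear peptide is the residue sum plus one water;
a head-to-tail cyclic peptide has no terminal water.  Each disulfide bond
removes two hydrogens (−2.015650 Da).  The modification registry ships
disulfide formation/reduction (∓2.015650), carbamidomethylation
(+57.021464, Cys only), ring-opening hydration (+18.010565, cyclic only)
and C-terminal amidation (−0.984016, linear only); users can extend the
TSV.  "S-acetamidation" by iodoacetamide is modeled as
carbamidomethylation — the iodoacetamide reaction product.

Cyclic sequences are stored as one explicit rotation; every mass operation
sums over the residue multiset and is therefore rotation-invariant by
construction (verified by rotation-sweep tests).  Printed MALDI-TOF values
in the reference workflow deviate from theory by up to ~0.2 Da, so the
default MS1 match tolerance is ±0.25 Da (configurable; ppm mode
available).  MS/MS matching defaults to ±0.3 Da, typical for MALDI-TOF
LIFT spectra.  Average masses are available for every operation but no
average-mass calibration model is attempted.

The doubly charged oxytocin transition is computed as 504.23; published
usage varies between 504.2 and 504.741, and theory supports the former,
which the tests assert.

## Digestion

Cleavage rules are (cleave-after set, blocked-before set) pairs in a
shipped TSV: trypsin after K/R not before P; GluC after E (E/D variant
selectable); chymotrypsin after F/Y/W/L/M with **no** proline block.  The
broad chymotrypsin default is deliberate: long partial-digest MALDI
fragments of cyclotides include cleavage at Leu–Pro bonds, which the
textbook F/Y/W + P-block rule would forbid; that stricter variant ships as
`chymotrypsin_strict`.  On a ring, the bond between the last and first
stored residue is a valid site.  A single site yields the ring-opened
full-length linear product (+1 water); k ≥ 2 sites yield all arcs between
ordered pairs of distinct sites, with missed cleavages counted as interior
sites.  Products carry the parent's per-site modifications that fall
inside the arc and are massed as linear peptides.  Coordinates are 1-based
inclusive on the stored rotation with wrap-around arcs written start > end
(e.g. 26–7 on a 30-mer).  Missed cleavages default to unlimited when
matching observed peaks from partial time-course digests, and should be
capped (typically 2) for prospective digests.  Where published fragment
position labels conflict with the printed rotation, fragment *sequences*
are authoritative and positions are recomputed.

## MS/MS annotation

Only singly protonated b and y ions are modeled (MALDI post-source decay
regime); a/x series and neutral losses are excluded.  The complementarity
identity b_i + y_{n−i} = [M+H]+ + proton is exact and serves as an
internal consistency check.  Annotation is greedy nearest-match: candidate
(ion, peak) pairs within tolerance are ranked by absolute error (ties to
the lower ion index), each peak used at most once per series.  Full de
novo sequencing is out of scope — the module scores candidate sequences
against spectra, which is how a manual annotation is validated.  Isobaric
flags report residues whose substitution changes the peptide mass by less
than the tolerance (Ile/Leu always; Lys/Gln above 0.0364 Da).

## Cysteine count and cyclicity inference

The per-cysteine reduction+alkylation step is fixed at 58.029114 Da; the
estimate is the rounded quotient of the observed shift, with the residual
reported.  Cyclicity requires a single-site digest with exactly one
product one water heavier than its parent; two products or a mass loss
classify the backbone as linear.  Dereplication predicts candidate masses
under full oxidation (all Cys paired — 3 disulfides for a 6-Cys
candidate), matching native-extract measurements; the ±0.25 Da matching
tolerance is this package's default, not a published figure.  Disulfide
*connectivity* (I–IV, II–V, III–VI) is annotated as assumed, never
inferred from data.  Peak lists are assumed monoisotopic-picked; no
deisotoping is performed.

## Precursor mining

An internal Smith–Waterman-style search (Biopython PairwiseAligner, local
mode, match +2 / mismatch −1 / gap open −5 / extend −1) over six-frame
translations replaces an external tblastn dependency; at desk scale the
discovery semantics are the same.  ORFs are stop-free segments of ≥ 20 aa
in contigs of ≥ 60 nt.  Mature-domain extraction is rule-based and
configurable: the domain starts at Gly after the propeptide boundary,
ends at Asn/Asp followed by a small residue (G/A/S/L), spans 25–40
residues and contains exactly six cysteines; among valid windows the one
best overlapping the alignment hit wins (ties: shorter, then leftmost).
These defaults follow the classic cyclotide asparaginyl-endopeptidase
processing convention; published precursors vary, and the rules are
explicitly configuration, not established fact.  ER-signal detection is a
deliberately crude hydrophobicity heuristic (≥ 8 hydrophobic residues in
the first 25) and is flagged as such.

## Loop analysis

The canonical rotation starts at a Gly cyclically preceded by Asn/Asp
(the ligation junction); with several such motifs the lexicographically
smallest rotation wins, and without any the overall lexicographic minimum
is used — both deterministic and rotation-invariant.  Loop k spans Cys k
to Cys k+1; loop 6 wraps.  Loop comparison against reference sets uses
exact string matching per loop (whether published loop-wise comparisons
used exact matching or per-loop alignment is unstated; exact matching is
the simpler, reproducible choice).  Pairwise global alignment uses
BLOSUM62 with gap open 10 / extend 0.5 (common EMBOSS-style defaults);
identity is identical pairs over alignment length, similarity adds
positive-scoring pairs.  Published similarity percentages from web tools
with unstated parameters are treated qualitatively (identity ≤ similarity
ordering), never as numeric targets.

## Assay kinetics

Initial velocity is the slope over the first read interval (3-minute
grid by default) after point-wise background subtraction; discarding the
t0 read for lag handling is a flag, off by default.  Percent remaining
activity is v_i/v_0 × 100 against the uninhibited control.  The IC50 fit
is a least-squares constrained 4PL (bottom 0, top 100 fixed), fitted in
log10-IC50 space with scipy's Levenberg–Marquardt; the IC50 SD is
delta-method propagated, and non-convergence is reported in the result
object rather than silently replaced.  One-phase decay fixes the plateau
at zero, seeds the rate from a log-linear regression and reports
τ = ln 2 / k.  Extract ranking reports Spearman's ρ between peptide count
and IC50; more peptides associated with lower IC50 gives ρ < 0.

## Synthetic data

Generators emulate the study's input classes with known ground truth:
six-cysteine cyclic sequences with loop lengths drawn per-loop from
ranges spanning the 3/4/4/1/5/7 pattern of the reference cyclotide,
junction-anchored rotations, and knot connectivity recorded; MS1 peaks at
theoretical [M+H]+ with Gaussian jitter, probabilistic sodium satellites
and uniform noise peaks; b/y spectra with Bernoulli peak dropout; contigs
embedding codon-randomized oak1-style precursors (signal + propeptide +
mature + tail) at random frames and strands with random flanks; plate
traces linear in time with slopes scaled by the true 4PL and exponential
stability time courses on the 0–24 h grid.  Published assay outcomes
(IC50 1.35 µM, extract IC50s, half-lives 6.7/23.4 h) are **generator
settings for recovery tests**, not reproduction targets — the raw plate
data and spectra are not published.  Where text and figure legends
disagree on half-lives (6.7/23.4 vs ~7.5/>21 h), the text values are the
generator defaults, with both noted here.

What the generators deliberately do not model: isotope envelopes,
ionization efficiency, chromatographic retention, enzyme kinetics of the
digests, or fluorophore inner-filter effects.  Passing recovery tests
therefore demonstrates correctness of the arithmetic and estimators under
idealized noise, not instrument-level realism.

## Problem sizes and determinism

The test and acceptance workloads are desk-scale by design: ≤ 50
synthetic contigs per recovery experiment, ≤ 100 seeded replicates per
bias check, 500-entry reference sets for loop statistics.  Every
stochastic test and generator is seeded; identical seeds reproduce
identical outputs, and the pipeline report carries a content hash so runs
can be compared.

## Known limitations

Multiply charged ESI deconvolution, average-mass MALDI calibration,
isotope envelopes and de novo sequencing are out of scope.  The
processing-site and signal-peptide rules are heuristics that will miss
unconventional precursors.  Disulfide connectivity is assumed, not
determined.  mzML is not read (MGF/TSV only).
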