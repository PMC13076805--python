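# cycloms

A toolkit for the mass-spectrometric discovery and characterization of
**cyclotides** — plant peptides of ~28–37 residues with a head-to-tail
cyclic backbone and three disulfides in a cyclic cystine knot (CCK) — and
for the protease-inhibition assays used to screen them.  It is aimed at
peptidomics groups who identify cyclic cysteine-rich peptides from plant
extracts by MALDI-TOF MS, mine transcriptome assemblies for their
precursor genes, and quantify inhibition of targets such as human prolyl
oligopeptidase (POP).

## What it computes

The core is exact mass arithmetic on cyclic peptides.  For a species *P*
with residue set *R*, topology *t* and *d* disulfide bonds:

```
M(P) = Σ_r m(r)  +  18.010565·[t = linear]  +  Σ mods  −  2.015650·d
m/z  = (M + z·m_carrier) / z        (proton 1.007276, Na+ 22.989218)
```

A head-to-tail cycle carries no terminal water; ring opening by a
single-site endoprotease adds exactly one water (+18.011 Da) with no
residue loss — the diagnostic signature of backbone cyclicity.  Reduction
plus iodoacetamide alkylation adds 58.029114 Da per cysteine
(2·1.007825/2 + 57.021464), so the observed shift divided by that step
estimates the cysteine count.

Around this core the package provides:

* **digestion** — in-silico proteolysis of linear and cyclic peptides
  (trypsin, GluC, chymotrypsin, user rules), wrap-around arcs, missed
  cleavages, fragment mass tables;
* **msms** — theoretical b/y ion series (b_i + y_{n−i} = [M+H]+ + 1.007276),
  greedy spectrum annotation with coverage statistics, isobaric-residue
  flags (Ile/Leu, Lys/Gln);
* **cck** — cysteine-count and cyclicity inference from modification
  ladders, MS1 fingerprints in the m/z 2000–4000 cyclotide window,
  dereplication of candidate masses against peak lists;
* **mining** — six-frame translation of transcript contigs, local
  alignment of known mature cyclotides against ORFs, rule-based mature
  domain extraction (Gly start, Asn/Asp + small-residue processing site,
  25–40 residues, 6 Cys);
* **loops** — canonical rotation of cyclic sequences, intercysteine loop
  decomposition (loops 1–6), loop-wise comparison against reference sets,
  global alignment identity/similarity, logo-ready frequency matrices;
* **kinetics** — initial velocities from plate-reader traces, percent
  inhibition, constrained four-parameter logistic IC50 fits
  (`remaining = 100 / (1 + 10^((log c − log IC50)·h))`, bottom 0 / top
  100), one-phase decay half-lives (`y = 100·e^(−kt)`, τ = ln 2 / k);
* **simulate** — seeded generators for every input class, with ground
  truth, so each stage is testable by parameter recovery;
* **io / pipeline / cli** — FASTA, MGF, TSV peak lists, plate CSVs, YAML
  config, an orchestrated pipeline and a `cycloms` command line.

## Worked example

The reference workflow characterizes the cyclotide **psysol 3**,
cyclo-GLPTCFETCILGTCYTPGCSCSTYRLCLNN with three disulfides:

```python
>>> import cycloms
>>> p = cycloms.psysol3()
>>> round(cycloms.peptide_mass(p) + 1.007276, 4)     # native [M+H]+
3209.3328
>>> cycloms.modification_delta(p, [("reduction", 3), ("carbamidomethyl", 6)])
348.175734
>>> ra = cycloms.psysol3_reduced_alkylated()
>>> from cycloms.digestion import ENZYMES, digest
>>> [d.sequence for d in digest(ra, ENZYMES["trypsin"])]
['LCLNNGLPTCFETCILGTCYTPGCSCSTYR']
>>> round(digest(ra, ENZYMES["trypsin"])[0].mz_h, 4)  # ring-opened, +1 water
3575.5191
```

The single tryptic product, exactly one water heavier than the alkylated
ring, is the evidence for a cyclic backbone; the +348.18 Da
reduction/alkylation shift indicates six cysteines.  The same digest
tables drive MS/MS annotation and the intercysteine loops fall out of

```
$ cycloms loops GLPTCFETCILGTCYTPGCSCSTYRLCLNN
loop1   FET
loop2   ILGT
loop3   YTPG
loop4   S
loop5   STYRL
loop6   LNNGLPT
```

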