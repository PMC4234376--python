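# oligoms

Mapping post-transcriptional modifications onto large RNAs — such as the
N4-acetylcytidines (ac4C) of the eukaryotic small-subunit rRNA — from
negative-mode LC-MS/MS data of ribonuclease digests.

## The problem

Short ribonuclease T1 digestion products (cleavage 3′ of G, leaving 5′-OH /
3′-phosphate termini) are the unit of observation when an rRNA is analysed
by mass spectrometry. A modification shows up as a mass shift on one digest
product, and collision-induced dissociation (CID) of that product localizes
the shift to a single residue via the a/c/w/y backbone ion series. Two
obstacles make this non-trivial on a ~1.8 kb rRNA:

1. **Sequence redundancy.** A trinucleotide product like CCGp can occur at
   many parent positions (nine, in the fission-yeast 18S rRNA), so even a
   perfectly localized acetyl on its middle residue does not identify the
   site in the parent frame. The remedy is directed RNase H cleavage: a
   synthetic 20–28-mer DNA guide targets cuts that excise a coordinate
   window; observing the modified product in one window's digest pins it to
   the single copy inside that window.
2. **Within-oligo ambiguity.** Isomeric placements of a modification on the
   same residue string are precursor-indistinguishable and must be separated
   by discriminating fragment ions.

`oligoms` implements this workflow end to end: modification-aware
monoisotopic mass and m/z arithmetic, in-silico T1 digestion with missed
cleavages, ppm-tolerance database search of MS/MS spectra, RNase-H window
design and disambiguation, extracted-ion-chromatogram (XIC) presence calls
for differential strain comparisons, and a synthetic-data generator that
makes every stage testable without instrument data.

## The core arithmetic

For an oligonucleotide of residues $r_1 \dots r_n$ with modification deltas
$\Delta_j$, the neutral monoisotopic mass with 5′-OH / 3′-linear-phosphate
termini is

$$M = \sum_i m_{\mathrm{NMP}}(r_i) - (n-1)\,m_{\mathrm{H_2O}} + \sum_j \Delta_j$$

and a z-fold deprotonated negative ion appears at
$m/z = (M - z\,m_p)/z$ with $m_p = 1.0072765$ Da. CID fragments follow the
standard nucleic-acid nomenclature — 5′ fragments a (3′-OH) and c
(3′-phosphate), 3′ fragments w (5′-phosphate) and y (5′-OH) — obeying the
complementary-pair law $c_i + y_{n-i} = a_i + w_{n-i} = M + m_{\mathrm{H_2O}}$.
Matching uses relative tolerances: ±20 ppm on precursors, ±750 ppm on
ion-trap MS/MS fragments, 3 ppm XIC windows.

## Worked example

```
$ oligoms mass 'UUUC[ac4C]G>p' --charges 1,2
oligo	UUUC[ac4C]G>p
neutral_mass	1933.2270
mz_1-	1932.2198
mz_2-	965.6062
```

`UUUC[ac4C]G>p` is the bracket notation for the T1 product UUUC(AcC)Gp — an
acetylcytidine as residue 5, linear 3′-phosphate. Its doubly deprotonated
ion at m/z 965.61 is the species selected for CID in a survey scan; the
singly charged C(AcC)Gp marker sits at m/z 1014.14.

A full synthetic study (three strains: wild type, acetyltransferase-dead
mutant, rescue) and its analysis:

```
$ oligoms simulate --preset paper-mimic --seed 4 --out sim
wrote 1464 spectra across 3 conditions to sim/

$ printf 'WT/win1177-1428\t1177\t1428\n' > runwin.tsv
$ oligoms search run sim/parent.fasta sim/WT.mgf --windows-tsv runwin.tsv --out res
assigned 368 spectra; coverage 93.9%
   parent  position modification      fragment    status       window occurrences                spectra
mimic-18S      1297         ac4C    C[ac4C]G>p localized win1177-1428   1296-1298 WT/win1177-1428#s00433
mimic-18S      1815         ac4C UUUC[ac4C]G>p localized         None   1811-1816              WT#s00002

$ oligoms compare sim/parent.fasta WT=sim/WT.mgf mutant=sim/mutant.mgf 'C[ac4C]G>p'
...
verdict	C[ac4C]G>p 1-	present/absent
```

Position 1297 is reported *localized* only because the CCGp copy at
1296–1298 is the sole one inside the 1177–1428 RNase-H window; without the
window link the site is demoted to *sequence_redundant*. Position 1815 needs
no window because UUUCCGp is unique in the parent. Coverage excludes the
free guanosine monophosphates, which carry no sequence information.

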