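# Methods

This note documents the models, parameter choices and numerical conventions
behind `oligoms`, and states what the synthetic benchmark does and does not
demonstrate.

## Mass model

Masses are monoisotopic and assembled from a single embedded element table
(NIST values: H 1.00782503207, C 12, N 14.0030740048, O 15.9949146196,
P 30.97376163 Da), so results are bit-stable across platforms. An
oligonucleotide is a chain of ribonucleoside-3′-monophosphate residues
losing one water per phosphodiester bond; the baseline terminal chemistry
is the RNase T1 product form (5′-OH, 3′-linear-phosphate), with corrections
of +HPO₃ for a 5′-phosphate, −HPO₃ for a 3′-OH and −H₂O for a 2′,3′-cyclic
phosphate. Negative ions subtract z protons at the fixed constant
1.0072765 Da.

Two conventions matter for interpreting published figures:

* **Linear vs. cyclic 3′-phosphate.** Real T1 digests contain both forms;
  the printed marker m/z values (972.133, 1014.143, 965.60) match the
  linear form, which is therefore the default. The cyclic form (−18.0106
  Da) is selectable per oligo. How the two forms partition in any given
  chromatogram is not modelled.
* **Printed precision.** The published m/z figures are truncated, not
  rounded (e.g. computed 1014.1439 prints as 1014.143, 965.6062 as 965.60).
  Regression tests therefore assert agreement within one unit of the last
  printed digit.

The modification alphabet ships with the small-subunit rRNA repertoire:
ac4C (+42.010565), the 2′-O-methylnucleosides and m7G (+14.015650), m66A
(+28.031300), and m1acp3Y handled as a single composite delta
(+115.063328) on U — pseudouridine itself is mass-silent, so the
methyl + aminocarboxypropyl increment is what MS observes. A generic
`methyl` entry (any base) supports searches. 2′-O-methylguanosine is
flagged as blocking T1 cleavage; this is standard enzymology rather than
something the digest data alone could establish, and it changes the digest,
so it is an explicit, defaulted-on flag.

## Fragment ions

CID backbone fragments use the nucleic-acid a/c/w/y nomenclature: a and c
retain the 5′ terminus (ending 3′-OH and 3′-phosphate respectively), w and
y retain the 3′ terminus (starting 5′-phosphate and 5′-OH). w/y indices
count residues from the 3′ end, so c_i and y_{n−i} arise from the same
cleavage and satisfy c_i + y_{n−i} = a_i + w_{n−i} = M + H₂O — a law the
test suite checks exhaustively at small lengths and densely to 12-mers.
Base-loss ions (a−B) are implemented but off by default; when the lost
residue carries a base modification, the modification delta leaves with the
base. Internal ions, neutral losses beyond base loss, and isotope envelopes
are out of scope. Fragments are predicted singly charged by default
(`fragment_max_charge`), which matches ion-trap CID of small digest
products.

## Digestion and windows

RNase T1 cuts 3′ of G; products with 0..`max_missed` internal Gs are
emitted, and the parent's own termini are inherited by the first and last
product. Coordinates are 1-based inclusive everywhere except the BED
export (0-based half-open).

Occurrence bookkeeping makes a deliberate distinction. `locate_product` is
a plain overlapping substring scan. A digest product's `occurrences` list,
by contrast, is *cleavage-consistent*: an occurrence must start at the 5′
end or immediately after a G, and end in G or at the 3′ end. The
distinction is what makes a CCGp product count come out right when the
parent also contains UUUCCGp — the CCG inside it is a substring but not a
T1 product.

RNase H cleavage is idealized as exact excision of a coordinate window
(the real protocol gel- or LC-purifies the fragments before digestion, and
trimming heterogeneity is not modelled). `disambiguate` keeps the
occurrence intervals fully contained in a window; a single survivor
upgrades a redundant site to *localized*. `propose_windows` designs a
non-overlapping window tiling greedily (leftmost feasible cut first, hence
deterministic) such that each window holds at most one occurrence of every
given redundant product, and emits reverse-complement DNA guides
(default 24-mers) spanning each cut; melting-temperature optimization is
out of scope. Note that a window set taken from the literature need not
satisfy the ≤1-copy property globally — the seven-window design this
package's mimic reuses holds two and three CCGp copies in two of its
windows — so `verify_window_design` reports honest per-window counts and
site localization only relies on the one isolating window.

## Spectrum matching and localization

All tolerances are relative: defaults 20 ppm (precursor), 750 ppm (ion-trap
MS/MS), 3 ppm (XIC), all config-exposed. Ion-to-peak assignment is a
global greedy over all (predicted ion, peak) pairs within tolerance in
order of |ppm error| (ties: series a &lt; a−B &lt; c &lt; w &lt; y, then index, then
charge), each peak consumed at most once; the assignment is deterministic
and unaffected by peaks that match nothing.

The match score is `n_matched + 0.25 × Σ_series (longest consecutive index
run − 1)`: deterministic, monotone (adding a matched ion never lowers it),
and a documented stand-in — the scoring function of the original database
search engine is defined in prior literature, not re-derived here.

Within-oligo localization enumerates every arrangement of the oligo's
modification multiset over compatible residues. The reported placement is
*localized* only if, for each alternative, at least one matched ion's
observed peak is inside tolerance of the reported placement's theoretical
m/z but outside the alternative's. With no matched ions a modified
candidate is always *ambiguous_within_oligo*.

One spec-level property — "removing noise peaks never reduces the matched
set" — cannot hold verbatim under one-peak-per-ion matching when a noise
peak was itself matched (its removal can force two ions to compete for one
true peak). The guaranteed, tested property is the sound version: removing
*unmatched* peaks leaves the assignment bit-identical.

## Search

Candidates are unique (sequence, missed-cleavage) digest products expanded
over variable-modification placements; the default searched set is one
methylation (any base) plus one acetylation (C) per fragment. The
historical search that motivated this package printed a methylation-only
variable-mod set, which by itself cannot yield acetyl hits; the searched
set here is fully user-specified, with a default that makes the acetyl
discovery path reproducible. Expansion beyond a per-product cap (default
5000) is an explicit error, never a silent truncation.

Per spectrum, the best-scoring candidate within precursor tolerance wins;
ties break on fewer modifications, then lexicographic sequence — fully
deterministic, one candidate per spectrum (no chimeras). Site assignments
lift modified positions to the parent frame: a unique-occurrence product
localizes directly; a redundant product localizes only when the spectrum's
run is linked (via `CleavageWindow.run_id`) to a window containing exactly
one occurrence. Windows are the only disambiguation mechanism. Redundant
or ambiguous entries subsumed by a localized call on the same fragment and
placement are dropped from the final table. Coverage marks every
occurrence interval of every assigned multi-nucleotide product;
mononucleotide products (free Gp) are excluded, which is why coverage
plateaus a few percent below 100 on random parents. No decoy/FDR
machinery: the validation surface is synthetic ground truth.

XIC presence calls sum MS1 intensity per scan within the ppm window; a
trace is *present* when its apex exceeds 3× the median MS1 peak intensity
of the run (config-exposed). Intensities are arbitrary units; no absolute
quantification is claimed.

## Synthetic data generator

The generator emulates, per condition (strain): one Gaussian elution train
per digest-product form in the MS1 dimension (σ = 1.2 retention units,
apex ∝ abundance, tails kept above 0.5% of apex), one MS/MS spectrum per
form containing the singly charged a/c/w/y ions with Gaussian ppm jitter,
per-ion dropout, and uniform-m/z noise peaks with log-uniform intensities;
precursor charge follows z = clamp(round(n/3), 1, 4). Abundance is in copy
units: a product sequence with k parent copies contributes k minus the
occupied fraction to its unmodified form and the occupancy to each
modified form. Every MS1 scan additionally carries a 200-peak
chemical-noise floor with intensities spanning one decade (10²–10³) — real
centroided survey scans never have an empty baseline, and without a floor
a median-based presence threshold is ill-defined. Windowed runs contain
MS/MS of the sequence-redundant interior products of each excised fragment
(the only spectra that window evidence can act on); boundary products with
RNase-H termini are excluded as chemically distinct.

Motif planting guarantees exact digestion-consistent copy counts: planted
motifs are written at fixed or random positions, G is forced before
G-terminal motifs so each copy is a true T1 product, and accidental
background occurrences are repaired by point mutations outside protected
regions until the occurrence set is exact. All randomness flows from one
seed; a fixed seed is byte-reproducible, and distinct seeds change
background and noise but not the planted structure.

The `paper-mimic` preset reproduces the occurrence structure of the
fission-yeast 18S study on a synthetic 1842-nt parent: CCGp at the nine
canonical coordinates (285, 575, 664, 866, 1048, 1296, 1476, 1541, 1758;
acetyl at 1297 on the 1296 copy), unique UUUCCGp at 1811 (acetyl at 1815),
the seven RNase-H windows, and three strains at acetyl occupancy
1 / 0 / 1 (wild type / mutant / rescue). Because the real 18S sequence is
not bundled, the background around the planted structure is random — the
digest arithmetic, redundancy counts and window logic are exactly those of
the real sequence, but absolute product inventories differ.

What passing the benchmark shows: the pipeline recovers planted sites
exactly at zero noise, retains ≥90% of site-instances under 10 ppm MS1 /
200 ppm MS2 jitter with 50 noise peaks per spectrum (20 replicates; the
dominant loss is precursors jittered beyond the ±20 ppm tolerance, an
irreducible property of those settings, with zero false localizations
observed), and reproduces the all-or-none differential XIC pattern. What
it does not show: robustness to co-elution, isotope interference,
retention drift, charge-state ambiguity, or real chromatographic intensity
structure, none of which the generator models.

## Problem sizes

The test suite and the acceptance script run the mimic at full parent
length (1842 nt, ~370 assigned spectra per strain run); recovery uses 3
clean and 20 stressed replicates, chosen to keep the whole acceptance
surface around a minute of CPU while leaving the binomial sampling error
on the recovery rate a few percent.
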