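"""Ground-truth-annotated synthetic parents, digests and simulated MS runs.

The generator emulates the data a nanoflow LC-MS/MS experiment on a
ribonuclease T1 digest of an rRNA produces: negative-mode multiply
deprotonated precursors, a/c/w/y backbone fragment series with ppm-scale
mass jitter, Gaussian elution peak trains in the MS1 dimension, uniform
noise peaks, and per-strain modification occupancy (e.g. wild-type
modified, catalytic mutant unmodified, rescue re-modified).  Every emitted
spectrum's provenance is recorded in a machine-readable sidecar so any
pipeline output can be scored without reading the generator.

The ``paper_mimic`` scenario reproduces the occurrence structure that makes
acetylcytidine mapping on the fission-yeast small-subunit rRNA interesting:
an 1842-nt parent in which the digest product CCGp occurs at exactly nine
fixed positions (the copy at 1296-1298 carrying N4-acetylcytidine at 1297,
isolable by the 1177-1428 RNase-H window) and a unique UUUCCGp at
1811-1816 carrying acetylcytidine at 1815.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chemistry import (
    ModificationAlphabet,
    Oligonucleotide,
    fragment_ions,
    mz,
    neutral_mass,
)
from .digestion import (
    CleavageWindow,
    DigestProduct,
    ParentRNA,
    apply_windows,
    digest_t1,
    product_occurrences,
)

__all__ = [
    "PlantedMod",
    "MotifPlant",
    "SimScenario",
    "SimulatedDataset",
    "generate_parent",
    "simulate_runs",
    "simulate",
    "paper_mimic",
    "precursor_charge",
    "PRESETS",
]

_BASES = np.array(list("ACGU"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedMod:
    """A ground-truth modification with per-condition occupancy in [0, 1]."""

    position: int
    name: str
    occupancy: Tuple[Tuple[str, float], ...]  # condition -> occupancy

    def __post_init__(self):
        for cond, occ in self.occupancy:
            if not 0.0 <= occ <= 1.0:
                raise SimulationError(f"occupancy {occ} for {cond!r} outside [0,1]")

    @property
    def occupancy_map(self) -> Dict[str, float]:
        return dict(self.occupancy)


@dataclass(frozen=True)
class MotifPlant:
    """Plant ``motif`` as a digestion-consistent product exactly ``copies`` times.

    ``positions`` (1-based starts) may be given explicitly; otherwise they
    are drawn uniformly without overlap.  Motifs ending in G are planted
    with a preceding G so that each copy is a genuine RNase T1 product.
    """

    motif: str
    copies: int
    positions: Optional[Tuple[int, ...]] = None

    def __post_init__(self):
        if self.copies < 1:
            raise SimulationError("copies must be >= 1")
        if self.positions is not None and len(self.positions) != self.copies:
            raise SimulationError("positions length must equal copies")


@dataclass
class SimScenario:
    """Everything that defines one synthetic study.

    A fixed seed yields byte-identical output.  Jitter sigmas are in ppm;
    ``dropout`` is the per-ion probability that a fragment ion is missing
    from its MS/MS spectrum.
    """

    parent_length: int = 1842
    gc_content: float = 0.5
    motif_plants: Tuple[MotifPlant, ...] = ()
    planted_mods: Tuple[PlantedMod, ...] = ()
    windows: Tuple[Tuple[int, int], ...] = ()
    noise_peaks: int = 0
    ms1_jitter_ppm: float = 0.0
    ms2_jitter_ppm: float = 0.0
    dropout: float = 0.0
    seed: int = 0
    # chemical-noise floor present in every real MS1 scan, independent of
    # the stress-testing noise_peaks; intensities span one decade so the
    # floor is well separated from analyte elution apexes
    ms1_background_peaks: int = 200
    n_ms1_scans: int = 120
    retention_span: float = 60.0
    base_intensity: float = 1.0e6
    elution_sigma: float = 1.2
    scan_mz_range: Tuple[float, float] = (500.0, 1950.0)
    parent_id: str = "synthetic-rRNA"

    def conditions(self) -> List[str]:
        seen: List[str] = []
        for mod in self.planted_mods:
            for cond, _ in mod.occupancy:
                if cond not in seen:
                    seen.append(cond)
        return seen or ["sample"]


@dataclass
class SimulatedDataset:
    parent: ParentRNA
    truth: Dict
    runs: Dict[str, List]  # condition -> SpectrumRecord list (MS1 + MS2)
    windows: Dict[str, List[CleavageWindow]]  # condition -> run-linked windows


def precursor_charge(length: int) -> int:
    """Charge-state rule for negative-mode oligonucleotide precursors."""
    return min(4, max(1, round(length / 3)))


def _draw_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=length, p=p)


def _random_positions(
    rng: np.random.Generator, length: int, motif_len: int, copies: int, taken: List[Tuple[int, int]]
) -> List[int]:
    out: List[int] = []
    for _ in range(copies):
        for _attempt in range(4000):
            # leave room for a forced preceding G and a following cut
            s = int(rng.integers(2, length - motif_len))
            span = (s - 1, s + motif_len)
            if all(span[1] < t0 or span[0] > t1 for t0, t1 in taken):
                taken.append(span)
                out.append(s)
                break
        else:
            raise SimulationError(
                f"cannot place {copies} copies of a {motif_len}-mer in length {length}"
            )
    return sorted(out)


def generate_parent(scenario: SimScenario) -> Tuple[ParentRNA, Dict]:
    """Random parent honouring GC content with exact motif plant counts.

    Guarantees that each planted motif occurs as a digestion-consistent
    product exactly ``copies`` times, at the recorded positions; accidental
    extra occurrences arising from the random background are repaired by
    point mutation outside the protected plant regions.
    """
    if scenario.parent_length < 50:
        raise SimulationError("parent length must be >= 50")
    rng = np.random.default_rng(scenario.seed)
    seq = _draw_sequence(rng, scenario.parent_length, scenario.gc_content)
    letters = list("".join(_BASES[seq]))
    n = scenario.parent_length

    protected = np.zeros(n, dtype=bool)
    plants: List[Tuple[MotifPlant, List[int]]] = []
    taken: List[Tuple[int, int]] = []
    for plant in scenario.motif_plants:
        if plant.positions is not None:
            positions = sorted(plant.positions)
            for s in positions:
                if s < 1 or s + len(plant.motif) - 1 > n:
                    raise SimulationError(f"motif position {s} outside parent")
        else:
            positions = _random_positions(rng, n, len(plant.motif), plant.copies, taken)
        for s in positions:
            for k, base in enumerate(plant.motif):
                letters[s - 1 + k] = base
                protected[s - 1 + k] = True
            if plant.motif.endswith("G") and s > 1:
                letters[s - 2] = "G"  # make the copy a genuine T1 product
                protected[s - 2] = True
        plants.append((plant, positions))

    # Repair pass: mutate background bases until each motif's
    # digestion-consistent occurrence set equals exactly the planted one.
    for _round in range(500):
        parent = ParentRNA(scenario.parent_id, "".join(letters))
        dirty = False
        for plant, positions in plants:
            wanted = {(s, s + len(plant.motif) - 1) for s in positions}
            occs = set(product_occurrences(parent, plant.motif))
            if not wanted <= occs:
                raise SimulationError(
                    f"planted occurrences of {plant.motif} destroyed: {wanted - occs}"
                )
            for s, e in sorted(occs - wanted):
                # break the spurious occurrence at its first mutable base
                for pos in range(s, e + 1):
                    if not protected[pos - 1]:
                        old = letters[pos - 1]
                        choices = [b for b in "AU" if b != old] or ["C"]
                        letters[pos - 1] = choices[int(rng.integers(len(choices)))]
                        dirty = True
                        break
                else:
                    # all bases protected (overlap of plants): break the
                    # preceding-G context instead
                    if s > 1 and not protected[s - 2]:
                        letters[s - 2] = "A"
                        dirty = True
                    else:
                        raise SimulationError(
                            f"cannot repair spurious occurrence ({s},{e}) of {plant.motif}"
                        )
        if not dirty:
            break
    else:
        raise SimulationError("motif repair did not converge")

    parent = ParentRNA(scenario.parent_id, "".join(letters))
    alphabet = ModificationAlphabet.default()
    for mod in scenario.planted_mods:
        base = parent.sequence[mod.position - 1]
        if base not in alphabet[mod.name].allowed_bases:
            raise SimulationError(
                f"planted {mod.name} at {mod.position} sits on {base}, not allowed"
            )
    truth = {
        "parent_id": parent.id,
        "length": len(parent),
        "conditions": scenario.conditions(),
        "motif_plants": [
            {"motif": plant.motif, "positions": positions} for plant, positions in plants
        ],
        "planted_mods": [
            {
                "position": mod.position,
                "name": mod.name,
                "occupancy": mod.occupancy_map,
            }
            for mod in scenario.planted_mods
        ],
        "windows": [list(w) for w in scenario.windows],
        "seed": scenario.seed,
        "spectra": {},
    }
    return parent, truth


def _elution_profile(
    rng: np.random.Generator, scenario: SimScenario
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Retention apex plus (scan times, relative intensity >= 0.5% apex)."""
    center = float(rng.uniform(0.08, 0.92) * scenario.retention_span)
    times = np.linspace(0.0, scenario.retention_span, scenario.n_ms1_scans)
    rel = np.exp(-0.5 * ((times - center) / scenario.elution_sigma) ** 2)
    keep = rel >= 0.005
    return center, times, np.where(keep, rel, 0.0)


def _jitter(rng: np.random.Generator, value: float, sigma_ppm: float) -> float:
    if sigma_ppm <= 0:
        return value
    return value * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6)


def _forms_for_product(
    product, planted: Sequence[PlantedMod], condition: str
) -> List[Tuple[Dict[int, str], float]]:
    """(mods, abundance) forms of one positional digest product.

    Abundance is in copy units: an unmodified unique product has abundance
    1; a product sequence with k parent copies contributes k minus the
    occupied fraction to the unmodified form, and each planted mod
    contributes its occupancy to the corresponding modified form.
    """
    s, e = product.start, product.end
    local = {
        m.position - s + 1: m for m in planted if s <= m.position <= e
    }
    if not local:
        return [({}, 1.0)]
    occ = 1.0
    mods: Dict[int, str] = {}
    for pos, m in local.items():
        occ *= m.occupancy_map.get(condition, 0.0)
        mods[pos] = m.name
    forms: List[Tuple[Dict[int, str], float]] = []
    if occ > 1e-12:
        forms.append((mods, occ))
    if 1.0 - occ > 1e-12:
        forms.append(({}, 1.0 - occ))
    return forms


def simulate_runs(
    parent: ParentRNA,
    truth: Dict,
    scenario: SimScenario,
    alphabet: Optional[ModificationAlphabet] = None,
) -> SimulatedDataset:
    """Simulate per-condition MS1 elution trains and MS/MS spectra.

    For each zero-missed digest product present under a condition's
    occupancy the generator emits an MS1 Gaussian peak train at the correct
    m/z (charge by the length rule) and one MS/MS spectrum holding the
    a/c/w/y series with ppm jitter, dropout and uniform noise peaks.
    Windowed runs (one per declared RNase-H window, run id
    ``{condition}/win{start}-{end}``) carry MS/MS spectra of the
    sequence-redundant interior products of the excised fragment — the
    evidence used for positional disambiguation.  Mononucleotide products
    are skipped entirely.
    """
    from .spectra import SpectrumRecord

    if alphabet is None:
        alphabet = ModificationAlphabet.default()
    rng = np.random.default_rng(
        np.random.SeedSequence([scenario.seed, 0xA11CE]).generate_state(1)
    )
    planted = scenario.planted_mods
    products = [p for p in digest_t1(parent, max_missed=0) if len(p.sequence) >= 2]
    # one representative positional product per unique sequence; a product
    # containing a planted modification stands in for all copies of its
    # sequence (the copy-count bonus below accounts for the others)
    special: List[DigestProduct] = []
    special_seqs = set()
    for p in products:
        if any(p.start <= m.position <= p.end for m in planted):
            special.append(p)
            special_seqs.add(p.sequence)
    reps: Dict[str, DigestProduct] = {}
    for p in products:
        if p.sequence not in special_seqs and p.sequence not in reps:
            reps[p.sequence] = p
    main_products = special + [reps[k] for k in sorted(reps)]

    redundant_seqs = {p.sequence for p in products if len(p.occurrences) > 1}
    window_objs = [
        CleavageWindow(parent.id, s, e) for s, e in scenario.windows
    ]
    sub_parents = apply_windows(parent, window_objs) if window_objs else []

    runs: Dict[str, List[SpectrumRecord]] = {}
    windows_by_cond: Dict[str, List[CleavageWindow]] = {}
    mz_lo, mz_hi = scenario.scan_mz_range
    for condition in scenario.conditions():
        spectra: List[SpectrumRecord] = []
        scan_counter = 0
        ms1_peaks: List[List[Tuple[float, float]]] = [
            [] for _ in range(scenario.n_ms1_scans)
        ]
        ms1_times = np.linspace(0.0, scenario.retention_span, scenario.n_ms1_scans)

        def emit_ms2(run_id: str, oligo: Oligonucleotide, retention: float) -> None:
            nonlocal scan_counter
            scan_counter += 1
            z = precursor_charge(len(oligo))
            theo_mz = mz(neutral_mass(oligo, alphabet), z)
            obs_mz = _jitter(rng, theo_mz, scenario.ms1_jitter_ppm)
            peaks = []
            for spec, ion_mz in fragment_ions(
                oligo, alphabet, series=("a", "c", "w", "y"), max_charge=1
            ):
                if scenario.dropout > 0 and rng.random() < scenario.dropout:
                    continue
                peaks.append(
                    (_jitter(rng, ion_mz, scenario.ms2_jitter_ppm), float(rng.uniform(2e4, 1e5)))
                )
            for _ in range(scenario.noise_peaks):
                peaks.append(
                    (
                        float(rng.uniform(mz_lo, mz_hi)),
                        float(10 ** rng.uniform(2.0, 4.0)),
                    )
                )
            scan_id = f"s{scan_counter:05d}"
            spectra.append(
                SpectrumRecord(
                    run_id=run_id,
                    scan_id=scan_id,
                    retention=retention,
                    peaks=np.array(peaks).reshape(-1, 2),
                    ms_level=2,
                    precursor_mz=obs_mz,
                    precursor_charge=z,
                )
            )
            truth["spectra"][f"{run_id}#{scan_id}"] = {
                "sequence": oligo.residues,
                "mods": dict(oligo.mods),
                "charge": z,
                "theoretical_mz": theo_mz,
                "retention": retention,
            }

        # --- main run: MS1 trains + one MS2 per product form
        for product in main_products:
            n_copies = len(product.occurrences)
            for mods, base_abundance in _forms_for_product(product, planted, condition):
                abundance = base_abundance + (
                    n_copies - 1 if not mods and n_copies > 1 else 0
                )
                oligo = product.oligo.with_mods(mods)
                z = precursor_charge(len(oligo))
                theo_mz = mz(neutral_mass(oligo, alphabet), z)
                center, times, rel = _elution_profile(rng, scenario)
                apex = scenario.base_intensity * abundance
                for i, r in enumerate(rel):
                    if r > 0:
                        ms1_peaks[i].append(
                            (_jitter(rng, theo_mz, scenario.ms1_jitter_ppm), apex * r)
                        )
                emit_ms2(condition, oligo, center)

        # chemical-noise floor plus any stress noise peaks
        for i in range(scenario.n_ms1_scans):
            nbg = scenario.ms1_background_peaks
            if nbg:
                bg_mz = rng.uniform(mz_lo, mz_hi, size=nbg)
                bg_int = 10 ** rng.uniform(2.0, 3.0, size=nbg)
                ms1_peaks[i].extend(zip(bg_mz.tolist(), bg_int.tolist()))
            for _ in range(scenario.noise_peaks):
                ms1_peaks[i].append(
                    (float(rng.uniform(mz_lo, mz_hi)), float(10 ** rng.uniform(2.0, 4.0)))
                )
            scan_counter += 1
            spectra.append(
                SpectrumRecord(
                    run_id=condition,
                    scan_id=f"ms1-{i:05d}",
                    retention=float(ms1_times[i]),
                    peaks=np.array(ms1_peaks[i]).reshape(-1, 2),
                    ms_level=1,
                )
            )

        # --- windowed runs: redundant interior products only
        cond_windows: List[CleavageWindow] = []
        for w, sub in zip(window_objs, sub_parents):
            run_id = f"{condition}/{w.name}"
            emitted = False
            for product in digest_t1(sub, max_missed=0):
                if len(product.sequence) < 2 or product.sequence not in redundant_seqs:
                    continue
                if (
                    product.oligo.five_prime != "OH"
                    or product.oligo.three_prime != "linear_phosphate"
                ):
                    continue  # boundary products have RNase-H termini
                parent_start = w.start + product.start - 1
                parent_end = w.start + product.end - 1
                shifted = DigestProduct(
                    oligo=dataclasses.replace(
                        product.oligo, origin=(parent.id, parent_start, parent_end)
                    ),
                    missed_cleavages=product.missed_cleavages,
                    occurrences=[(parent_start, parent_end)],
                )
                for mods, abundance in _forms_for_product(shifted, planted, condition):
                    oligo = shifted.oligo.with_mods(mods)
                    center = float(rng.uniform(5.0, scenario.retention_span - 5.0))
                    emit_ms2(run_id, oligo, center)
                    emitted = True
            if emitted:
                cond_windows.append(
                    CleavageWindow(parent.id, w.start, w.end, run_id=run_id)
                )
        runs[condition] = spectra
        windows_by_cond[condition] = cond_windows

    return SimulatedDataset(parent=parent, truth=truth, runs=runs, windows=windows_by_cond)


def simulate(scenario: SimScenario) -> SimulatedDataset:
    """Generate parent + runs in one call."""
    parent, truth = generate_parent(scenario)
    return simulate_runs(parent, truth, scenario)


# The printed nine CCGp positions and seven RNase-H windows of the
# small-subunit rRNA study this package models; used as the canonical
# occurrence structure for the mimic scenario.
MIMIC_CCG_STARTS = (285, 575, 664, 866, 1048, 1296, 1476, 1541, 1758)
MIMIC_UUUCCG_START = 1811
MIMIC_WINDOWS = (
    (1, 170),
    (183, 538),
    (554, 693),
    (703, 986),
    (1003, 1162),
    (1177, 1428),
    (1445, 1842),
)


def paper_mimic(
    seed: int = 0,
    noise_peaks: int = 0,
    ms1_jitter_ppm: float = 0.0,
    ms2_jitter_ppm: float = 0.0,
    dropout: float = 0.0,
    occupancies: Optional[Dict[str, float]] = None,
) -> SimScenario:
    """The canonical mimic scenario: nine CCGp copies (modified copy at
    1296-1298, isolable by the 1177-1428 window) and a unique UUUCCGp at
    1811-1816, acetylcytidines at 1297 and 1815, three strains
    (WT / mutant / rescue at occupancy 1 / 0 / 1)."""
    occ = occupancies or {"WT": 1.0, "mutant": 0.0, "rescue": 1.0}
    occ_t = tuple(occ.items())
    return SimScenario(
        parent_length=1842,
        gc_content=0.5,
        motif_plants=(
            MotifPlant("CCG", 9, MIMIC_CCG_STARTS),
            MotifPlant("UUUCCG", 1, (MIMIC_UUUCCG_START,)),
        ),
        planted_mods=(
            PlantedMod(1297, "ac4C", occ_t),
            PlantedMod(1815, "ac4C", occ_t),
        ),
        windows=MIMIC_WINDOWS,
        noise_peaks=noise_peaks,
        ms1_jitter_ppm=ms1_jitter_ppm,
        ms2_jitter_ppm=ms2_jitter_ppm,
        dropout=dropout,
        seed=seed,
        parent_id="mimic-18S",
    )


def _noisy(seed: int = 0) -> SimScenario:
    return paper_mimic(seed=seed, noise_peaks=50, ms1_jitter_ppm=10.0, ms2_jitter_ppm=200.0)


PRESETS = {
    "paper-mimic": paper_mimic,
    "clean": paper_mimic,
    "noisy": _noisy,
}
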