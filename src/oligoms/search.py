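"""End-to-end assignment: digest database, precursor match, annotation,
window disambiguation, and reporting.

The search follows the classical RNA-modification-mapping workflow: build
all RNase T1 digest products of the parent (with missed cleavages), expand
each over variable-modification placements, match every MS/MS spectrum's
precursor within a ppm tolerance, annotate backbone ions, keep the best
scoring candidate per spectrum, and lift modified positions to the parent
coordinate frame.  A product whose sequence occurs at several parent
positions can only be pinned down when its spectrum was acquired on an
RNase-H-excised window containing exactly one occurrence; otherwise the
site stays "sequence_redundant".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemistry import (
    ModificationAlphabet,
    Oligonucleotide,
    mz,
    neutral_from_mz,
    neutral_mass,
)
from .digestion import CleavageWindow, DigestProduct, ParentRNA, digest_t1, disambiguate
from .spectra import (
    DEFAULT_MSMS_TOL_PPM,
    DEFAULT_PRECURSOR_TOL_PPM,
    DEFAULT_XIC_PPM,
    MatchResult,
    SpectrumRecord,
    XicCall,
    annotate_spectrum,
    extract_xic,
    ppm_error,
)

__all__ = [
    "SearchParams",
    "Candidate",
    "SpectrumAssignment",
    "SiteAssignment",
    "CoverageReport",
    "SearchError",
    "build_candidates",
    "run_search",
    "differential_presence",
]


class SearchError(ValueError):
    pass


class CombinatorialCapError(SearchError):
    """Variable-modification expansion exceeded the configured hard limit."""


@dataclass
class SearchParams:
    """Database-search settings.

    ``variable_mods`` lists (modification name, max copies per fragment).
    The default searches one methylation and one acetylation per fragment,
    which covers the small-subunit rRNA repertoire targeted here; the set
    is fully user-specifiable.
    """

    max_missed: int = 1
    variable_mods: Tuple[Tuple[str, int], ...] = (("methyl", 1), ("ac4C", 1))
    fixed_mods: Tuple[Tuple[int, str], ...] = ()  # parent-frame position, name
    precursor_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM
    msms_tol_ppm: float = DEFAULT_MSMS_TOL_PPM
    series: Tuple[str, ...] = ("a", "c", "w", "y")
    max_charge: int = 4
    fragment_max_charge: int = 1
    candidate_cap_per_product: int = 5000

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.msms_tol_ppm <= 0:
            raise SearchError("tolerances must be > 0")
        for name, cap in self.variable_mods:
            if cap < 0:
                raise SearchError(f"per-fragment cap for {name!r} must be >= 0")
        if self.max_missed < 0:
            raise SearchError("max_missed must be >= 0")


@dataclass
class Candidate:
    """A digest product with one concrete variable-modification placement."""

    product: DigestProduct
    mods: Tuple[Tuple[int, str], ...]
    neutral_mass: float

    @property
    def oligo(self) -> Oligonucleotide:
        return self.product.oligo.with_mods(dict(self.mods))

    @property
    def sequence(self) -> str:
        return self.product.sequence

    @property
    def n_mods(self) -> int:
        return len(self.mods)


@dataclass
class SpectrumAssignment:
    spectrum: SpectrumRecord
    candidate: Candidate
    match: MatchResult


@dataclass
class SiteAssignment:
    """A modification placed (or tentatively placed) on the parent RNA."""

    parent_id: str
    position: Optional[int]  # parent frame; None while sequence-redundant
    modification: str
    status: str  # localized | sequence_redundant | ambiguous_within_oligo
    fragment: str
    occurrences: List[Tuple[int, int]]
    spectra: List[str] = field(default_factory=list)
    window: Optional[str] = None

    def __post_init__(self):
        if self.status == "localized" and self.position is None:
            raise SearchError("localized site requires a parent-frame position")


@dataclass
class CoverageReport:
    parent_id: str
    covered: np.ndarray  # boolean per position
    assigned_fragments: List[str]
    ptm_rows: pd.DataFrame

    @property
    def covered_fraction(self) -> float:
        return float(self.covered.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": np.arange(1, len(self.covered) + 1), "covered": self.covered}
        )


def _unique_products(products: Sequence[DigestProduct]) -> List[DigestProduct]:
    """Deduplicate positional products to one per (sequence, missed)."""
    seen = {}
    for p in products:
        key = (p.sequence, p.missed_cleavages)
        if key not in seen:
            seen[key] = p
    return [seen[k] for k in sorted(seen)]


def _mod_placements(
    product: DigestProduct,
    params: SearchParams,
    alphabet: ModificationAlphabet,
) -> List[Tuple[Tuple[int, str], ...]]:
    """Every placement of the variable mods on one product, incl. unmodified."""
    seq = product.sequence
    per_mod_choices = []
    for name, cap in params.variable_mods:
        allowed = alphabet[name].allowed_bases
        positions = [i + 1 for i, b in enumerate(seq) if b in allowed]
        choices = [()]  # zero copies
        for k in range(1, cap + 1):
            choices.extend(itertools.combinations(positions, k))
        per_mod_choices.append((name, choices))
    out = []
    for combo in itertools.product(*(c for _, c in per_mod_choices)):
        flat: Dict[int, str] = {}
        clash = False
        for (name, _), positions in zip(per_mod_choices, combo):
            for pos in positions:
                if pos in flat:
                    clash = True
                    break
                flat[pos] = name
            if clash:
                break
        if clash:
            continue
        out.append(tuple(sorted(flat.items())))
        if len(out) > params.candidate_cap_per_product:
            raise CombinatorialCapError(
                f"product {seq}: > {params.candidate_cap_per_product} mod placements"
            )
    return out


def build_candidates(
    parent: ParentRNA,
    params: SearchParams,
    alphabet: Optional[ModificationAlphabet] = None,
) -> List[Candidate]:
    """Digest the parent and expand variable-modification placements.

    Returns deterministically ordered candidates (sequence, missed
    cleavages, number of mods, placement).  Fixed mods given in parent
    frame are applied to every product covering them before expansion.
    """
    if alphabet is None:
        alphabet = ModificationAlphabet.default()
    fixed = dict(params.fixed_mods)
    parent_for_digest = parent
    if fixed:
        merged = dict(parent.known_mods)
        merged.update(fixed)
        parent_for_digest = ParentRNA(
            parent.id, parent.sequence, merged, parent.five_prime, parent.three_prime, parent.origin
        )
    products = _unique_products(
        digest_t1(parent_for_digest, max_missed=params.max_missed, alphabet=alphabet)
    )
    out: List[Candidate] = []
    for prod in products:
        base_mods = dict(prod.oligo.mods)  # fixed/known mods riding along
        for placement in _mod_placements(prod, params, alphabet):
            mods = dict(base_mods)
            ok = True
            for pos, name in placement:
                if pos in mods:
                    ok = False
                    break
                if prod.sequence[pos - 1] not in alphabet[name].allowed_bases:
                    ok = False
                    break
                mods[pos] = name
            if not ok:
                continue
            oligo = prod.oligo.with_mods(mods)
            out.append(
                Candidate(
                    product=prod,
                    mods=tuple(sorted(mods.items())),
                    neutral_mass=neutral_mass(oligo, alphabet),
                )
            )
    out.sort(key=lambda c: (c.sequence, c.product.missed_cleavages, c.n_mods, c.mods))
    return out


def _windows_by_run(windows: Optional[Sequence[CleavageWindow]]) -> Dict[str, CleavageWindow]:
    out = {}
    for w in windows or ():
        if w.run_id is not None:
            out[w.run_id] = w
    return out


def assign_spectra(
    runs: Sequence[SpectrumRecord],
    candidates: Sequence[Candidate],
    params: SearchParams,
    alphabet: ModificationAlphabet,
) -> List[SpectrumAssignment]:
    """Best-scoring candidate per MS/MS spectrum within precursor tolerance.

    Ties break on fewer modifications, then lexicographic sequence, then
    placement — fully deterministic.  Spectra with no candidate in
    tolerance are simply not assigned.
    """
    masses = np.array([c.neutral_mass for c in candidates])
    order = np.argsort(masses)
    masses_sorted = masses[order]
    out = []
    for spectrum in runs:
        if spectrum.ms_level != 2:
            continue
        z = spectrum.precursor_charge
        if z is None or z > params.max_charge:
            continue
        obs_neutral = neutral_from_mz(spectrum.precursor_mz, z)
        tol = params.precursor_tol_ppm * 1e-6 * obs_neutral
        i0, i1 = np.searchsorted(masses_sorted, [obs_neutral - tol, obs_neutral + tol])
        hits = []
        for idx in order[i0:i1]:
            cand = candidates[idx]
            theo_mz = mz(cand.neutral_mass, z)
            if abs(ppm_error(spectrum.precursor_mz, theo_mz)) > params.precursor_tol_ppm:
                continue
            if len(cand.sequence) < 2:
                continue
            match = annotate_spectrum(
                spectrum,
                cand.oligo,
                alphabet,
                tol_ppm=params.msms_tol_ppm,
                series=params.series,
                fragment_max_charge=params.fragment_max_charge,
            )
            hits.append((-match.score, cand.n_mods, cand.sequence, cand.mods, cand, match))
        if hits:
            hits.sort(key=lambda h: h[:4])
            _, _, _, _, cand, match = hits[0]
            out.append(SpectrumAssignment(spectrum, cand, match))
    return out


def _collect_sites(
    assignments: Sequence[SpectrumAssignment],
    parent: ParentRNA,
    window_map: Dict[str, CleavageWindow],
) -> List[SiteAssignment]:
    sites: Dict[Tuple, SiteAssignment] = {}
    for asg in assignments:
        if not asg.candidate.mods:
            continue
        occurrences = asg.candidate.product.occurrences
        window = window_map.get(asg.spectrum.run_id)
        effective = occurrences
        window_name = None
        if window is not None and len(occurrences) > 1:
            restricted = disambiguate(occurrences, window)
            if restricted:
                effective = restricted
                window_name = window.name
        for local_pos, name in asg.candidate.mods:
            if len(effective) == 1 and asg.match.localization == "localized":
                status = "localized"
                position = effective[0][0] + local_pos - 1
            elif asg.match.localization != "localized":
                status = "ambiguous_within_oligo"
                position = effective[0][0] + local_pos - 1 if len(effective) == 1 else None
            else:
                status = "sequence_redundant"
                position = None
            key = (name, asg.candidate.sequence, local_pos, position, status)
            scan = f"{asg.spectrum.run_id}#{asg.spectrum.scan_id}"
            if key in sites:
                sites[key].spectra.append(scan)
            else:
                sites[key] = SiteAssignment(
                    parent_id=parent.id,
                    position=position,
                    modification=name,
                    status=status,
                    fragment=asg.candidate.oligo.notation(),
                    occurrences=list(effective),
                    spectra=[scan],
                    window=window_name,
                )
    out = list(sites.values())
    # Drop redundant/ambiguous duplicates subsumed by a localized call on the
    # same fragment sequence + local placement.
    localized = {
        (s.modification, s.fragment) for s in out if s.status == "localized"
    }
    out = [
        s
        for s in out
        if s.status == "localized" or (s.modification, s.fragment) not in localized
    ]
    out.sort(key=lambda s: (s.position is None, s.position or 0, s.modification))
    return out


def _coverage(
    assignments: Sequence[SpectrumAssignment],
    parent: ParentRNA,
    sites: Sequence[SiteAssignment],
) -> CoverageReport:
    covered = np.zeros(len(parent), dtype=bool)
    fragments = []
    for asg in assignments:
        if len(asg.candidate.sequence) < 2:  # mononucleotides excluded
            continue
        fragments.append(asg.candidate.oligo.notation())
        for s, e in asg.candidate.product.occurrences:
            covered[s - 1 : e] = True
    rows = pd.DataFrame(
        [
            {
                "position": s.position,
                "modification": s.modification,
                "fragment": s.fragment,
                "status": s.status,
                "window": s.window,
                "n_spectra": len(s.spectra),
            }
            for s in sites
        ]
    )
    return CoverageReport(
        parent_id=parent.id,
        covered=covered,
        assigned_fragments=sorted(set(fragments)),
        ptm_rows=rows,
    )


def run_search(
    runs: Sequence[SpectrumRecord],
    parent: ParentRNA,
    params: Optional[SearchParams] = None,
    alphabet: Optional[ModificationAlphabet] = None,
    windows: Optional[Sequence[CleavageWindow]] = None,
    candidates: Optional[Sequence[Candidate]] = None,
) -> Tuple[List[SiteAssignment], CoverageReport, List[SpectrumAssignment]]:
    """Full pipeline: candidates, precursor match, annotation, reporting.

    ``windows`` carry ``run_id`` links: a spectrum acquired on an excised
    window (its ``run_id`` equals the window's) may have its redundant
    product occurrences restricted to those inside the window — the only
    disambiguation mechanism offered.  Precomputed ``candidates`` may be
    passed to amortise the database across conditions.
    """
    if params is None:
        params = SearchParams()
    if alphabet is None:
        alphabet = ModificationAlphabet.default()
    if not runs:
        raise SearchError("no spectra given")
    if candidates is None:
        candidates = build_candidates(parent, params, alphabet)
    assignments = assign_spectra(runs, candidates, params, alphabet)
    window_map = _windows_by_run(windows)
    sites = _collect_sites(assignments, parent, window_map)
    report = _coverage(assignments, parent, sites)
    return sites, report, assignments


def differential_presence(
    runs_by_condition: Dict[str, Sequence[SpectrumRecord]],
    targets: Sequence[Tuple[Oligonucleotide, int]],
    alphabet: Optional[ModificationAlphabet] = None,
    ppm_window: float = DEFAULT_XIC_PPM,
    presence_factor: float = 3.0,
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Per-condition XIC presence calls for target (oligo, charge) pairs.

    Returns a long-format table (target, condition, apex, relative
    intensity, present) and a per-target verdict string joining the
    presence flags in condition order, e.g. ``present/absent/present`` for
    a wild-type / mutant / rescue comparison.  Conditions with no MS1
    scans appear as explicit gaps (``present`` = NA).
    """
    if alphabet is None:
        alphabet = ModificationAlphabet.default()
    if len(runs_by_condition) < 2:
        raise SearchError("differential comparison needs >= 2 conditions")
    rows = []
    verdicts: Dict[str, str] = {}
    for oligo, charge in targets:
        target_mz = mz(neutral_mass(oligo, alphabet), charge)
        label = f"{oligo.notation()} {charge}-"
        flags = []
        for cond, run in runs_by_condition.items():
            ms1 = [s for s in run if s.ms_level == 1]
            if not ms1:
                rows.append(
                    {
                        "target": label,
                        "target_mz": target_mz,
                        "condition": cond,
                        "apex_intensity": np.nan,
                        "relative_intensity": np.nan,
                        "present": pd.NA,
                    }
                )
                flags.append("missing")
                continue
            call = extract_xic(ms1, target_mz, ppm_window, presence_factor)
            rows.append(
                {
                    "target": label,
                    "target_mz": target_mz,
                    "condition": cond,
                    "apex_intensity": call.apex_intensity,
                    "relative_intensity": call.relative_intensity,
                    "present": call.present,
                }
            )
            flags.append("present" if call.present else "absent")
        verdicts[label] = "/".join(flags)
    return pd.DataFrame(rows), verdicts
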