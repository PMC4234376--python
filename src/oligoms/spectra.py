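"""Spectrum records, ppm-tolerance matching, ion annotation and XIC calls.

Peak lists are centroided; all tolerances are relative (ppm).  The default
tolerances mirror standard practice for Orbitrap survey scans with ion-trap
MS/MS of oligonucleotides: +/-20 ppm on the precursor, +/-750 ppm on
fragment ions, and a 3 ppm window for extracted-ion chromatograms.

Within-oligo localization of a modification is decided by placement
enumeration: the reported placement is "localized" only if, for every
alternative arrangement of the same modifications on compatible residues,
at least one matched fragment ion is consistent with the reported placement
but not with the alternative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chemistry import (
    IonSpec,
    ModificationAlphabet,
    Oligonucleotide,
    fragment_ions,
    mz,
    neutral_mass,
)

__all__ = [
    "SpectrumRecord",
    "MatchResult",
    "XicCall",
    "ppm_error",
    "ppm_match",
    "annotate_spectrum",
    "score",
    "extract_xic",
    "enumerate_placements",
    "DEFAULT_PRECURSOR_TOL_PPM",
    "DEFAULT_MSMS_TOL_PPM",
    "DEFAULT_XIC_PPM",
]

DEFAULT_PRECURSOR_TOL_PPM = 20.0
DEFAULT_MSMS_TOL_PPM = 750.0
DEFAULT_XIC_PPM = 3.0
# XIC presence: apex must exceed this multiple of the run's median MS1 peak
# intensity; the expected signals are all-or-none so the exact factor is
# uncritical.
DEFAULT_PRESENCE_FACTOR = 3.0

_SERIES_ORDER = {"a": 0, "a-B": 1, "c": 2, "w": 3, "y": 4}


@dataclass
class SpectrumRecord:
    """One centroided scan (MS1 survey or MS/MS) in negative mode."""

    run_id: str
    scan_id: str
    retention: float
    peaks: np.ndarray  # shape (n, 2): m/z, intensity; sorted by m/z
    ms_level: int = 2
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    polarity: str = "negative"

    def __post_init__(self):
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if len(self.peaks):
            if not np.all(np.isfinite(self.peaks)):
                raise ValueError("peaks must be finite")
            if np.any(self.peaks[:, 1] < 0):
                raise ValueError("intensities must be >= 0")
            order = np.argsort(self.peaks[:, 0], kind="stable")
            self.peaks = self.peaks[order]
        if self.ms_level == 2:
            if self.precursor_mz is None or self.precursor_charge is None:
                raise ValueError("MS2 record needs precursor m/z and charge")
            if self.precursor_charge < 1:
                raise ValueError("precursor charge magnitude must be >= 1")

    @property
    def mzs(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensities(self) -> np.ndarray:
        return self.peaks[:, 1]


@dataclass
class MatchResult:
    """Annotation of one spectrum against one candidate oligonucleotide."""

    oligo: Oligonucleotide
    precursor_ppm_error: float
    matched: List[Tuple[IonSpec, float, float]]  # spec, observed m/z, ppm error
    score: float
    localization: str  # "localized" | "ambiguous_within_oligo"


@dataclass
class XicCall:
    """Presence call from an extracted-ion chromatogram."""

    target_mz: float
    ppm_window: float
    run_id: str
    apex_intensity: float
    relative_intensity: float
    present: bool
    trace: Optional[np.ndarray] = None  # (n_scans, 2): retention, intensity


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def ppm_match(observed: float, theoretical: float, tol_ppm: float) -> Tuple[bool, float]:
    err = ppm_error(observed, theoretical)
    return abs(err) <= tol_ppm, err


def enumerate_placements(
    oligo: Oligonucleotide, alphabet: ModificationAlphabet, cap: int = 2000
) -> List[Oligonucleotide]:
    """All arrangements of the oligo's modification multiset on compatible residues.

    Used for localization: isomeric placements are precursor-indistinguishable
    and must be separated by fragment ions.  The reported placement is always
    element 0.
    """
    names = [name for _, name in oligo.mods]
    if not names:
        return [oligo]
    variants: List[Oligonucleotide] = []
    pools = []
    for name in names:
        allowed = alphabet[name].allowed_bases
        pools.append(
            [i + 1 for i, b in enumerate(oligo.residues) if b in allowed]
        )
    seen = set()
    for combo in itertools.product(*pools):
        if len(set(combo)) != len(combo):
            continue
        key = tuple(sorted(zip(combo, names)))
        if key in seen:
            continue
        seen.add(key)
        variants.append(oligo.with_mods(dict(zip(combo, names))))
        if len(variants) > cap:
            raise ValueError(f"placement enumeration exceeds cap {cap}")
    variants.sort(key=lambda v: (v.mods != oligo.mods, v.mods))
    return variants


def _greedy_assign(
    peaks_mz: np.ndarray,
    ions: Sequence[Tuple[IonSpec, float]],
    tol_ppm: float,
) -> List[Tuple[IonSpec, int, float]]:
    """Global greedy matching by |ppm error|, one peak per ion and vice versa.

    Candidate (ion, peak) pairs within tolerance are processed in order of
    increasing |error|; ties break on series order then index then charge,
    so the assignment is deterministic.  Unmatched peaks never influence the
    outcome, hence removing pure-noise peaks leaves the result unchanged.
    """
    pairs = []
    for k, (spec, theo) in enumerate(ions):
        if not len(peaks_mz):
            break
        lo = theo * (1 - tol_ppm * 1e-6)
        hi = theo * (1 + tol_ppm * 1e-6)
        i0, i1 = np.searchsorted(peaks_mz, [lo, hi])
        for pi in range(i0, i1):
            err = ppm_error(peaks_mz[pi], theo)
            pairs.append((abs(err), _SERIES_ORDER[spec.series], spec.index, spec.charge, k, pi, err))
    pairs.sort()
    used_ions = set()
    used_peaks = set()
    out = []
    for _, _, _, _, k, pi, err in pairs:
        if k in used_ions or pi in used_peaks:
            continue
        used_ions.add(k)
        used_peaks.add(pi)
        out.append((ions[k][0], pi, err))
    out.sort(key=lambda t: (_SERIES_ORDER[t[0].series], t[0].index, t[0].charge))
    return out


def score(matched: Sequence[Tuple[IonSpec, float, float]]) -> float:
    """Deterministic match score: ion count plus series-continuity bonus.

    score = (# matched ions) + 0.25 * sum over series of (longest run of
    consecutive indices - 1).  Monotone: adding a matched ion never lowers
    the score.  This is a documented stand-in ranking, not a probability.
    """
    if not matched:
        return 0.0
    total = float(len(matched))
    by_series: Dict[str, set] = {}
    for spec, _, _ in matched:
        by_series.setdefault(spec.series, set()).add(spec.index)
    for indices in by_series.values():
        run = best = 1
        ordered = sorted(indices)
        for prev, cur in zip(ordered, ordered[1:]):
            run = run + 1 if cur == prev + 1 else 1
            best = max(best, run)
        total += 0.25 * (best - 1)
    return total


def annotate_spectrum(
    spectrum: SpectrumRecord,
    oligo: Oligonucleotide,
    alphabet: ModificationAlphabet,
    tol_ppm: float = DEFAULT_MSMS_TOL_PPM,
    series: Sequence[str] = ("a", "c", "w", "y"),
    fragment_max_charge: int = 1,
) -> MatchResult:
    """Match predicted backbone ions of ``oligo`` against the spectrum.

    The precursor is assumed to have been matched upstream; the reported
    ``precursor_ppm_error`` is informational.  Localization is decided by
    placement enumeration (see module docstring): an alternative placement
    is excluded when some matched ion's observed peak lies within tolerance
    of the reported placement's theoretical m/z but not the alternative's.
    """
    theo = fragment_ions(oligo, alphabet, series=series, max_charge=fragment_max_charge)
    matched_idx = _greedy_assign(spectrum.mzs, theo, tol_ppm)
    matched = [
        (spec, float(spectrum.mzs[pi]), err) for spec, pi, err in matched_idx
    ]
    prec_err = 0.0
    if spectrum.precursor_mz is not None and spectrum.precursor_charge is not None:
        theo_prec = mz(neutral_mass(oligo, alphabet), spectrum.precursor_charge)
        prec_err = ppm_error(spectrum.precursor_mz, theo_prec)

    localization = "localized"
    if oligo.mods:
        placements = enumerate_placements(oligo, alphabet)
        theo_by_spec = {spec: v for spec, v in theo}
        for alt in placements[1:]:
            alt_theo = {
                spec: v
                for spec, v in fragment_ions(
                    alt, alphabet, series=series, max_charge=fragment_max_charge
                )
            }
            discriminated = False
            for spec, obs_mz, _ in matched:
                alt_mz = alt_theo[spec]
                if abs(ppm_error(obs_mz, alt_mz)) > tol_ppm:
                    discriminated = True
                    break
            if not discriminated:
                localization = "ambiguous_within_oligo"
                break
    if not matched and oligo.mods:
        localization = "ambiguous_within_oligo"
    return MatchResult(
        oligo=oligo,
        precursor_ppm_error=prec_err,
        matched=matched,
        score=score(matched),
        localization=localization,
    )


def extract_xic(
    run: Sequence[SpectrumRecord],
    target_mz: float,
    ppm_window: float = DEFAULT_XIC_PPM,
    presence_factor: float = DEFAULT_PRESENCE_FACTOR,
) -> XicCall:
    """Extracted-ion presence call over the MS1 scans of a run.

    Sums, per scan, the intensity of peaks within +/-``ppm_window`` of the
    target; the call is "present" when the trace apex exceeds
    ``presence_factor`` times the median MS1 peak intensity of the run.
    Relative intensity is the apex as a fraction of the run base peak.
    """
    ms1 = [s for s in run if s.ms_level == 1]
    if not ms1:
        raise ValueError("run contains no MS1 scans")
    lo = target_mz * (1 - ppm_window * 1e-6)
    hi = target_mz * (1 + ppm_window * 1e-6)
    trace = np.zeros((len(ms1), 2))
    all_intensities = []
    for i, scan in enumerate(ms1):
        trace[i, 0] = scan.retention
        if len(scan.peaks):
            i0, i1 = np.searchsorted(scan.mzs, [lo, hi])
            trace[i, 1] = scan.intensities[i0:i1].sum()
            all_intensities.append(scan.intensities)
    apex = float(trace[:, 1].max()) if len(trace) else 0.0
    if all_intensities:
        flat = np.concatenate(all_intensities)
        base_peak = float(flat.max())
        threshold = presence_factor * float(np.median(flat))
    else:
        base_peak = 0.0
        threshold = 0.0
    relative = apex / base_peak if base_peak > 0 else 0.0
    present = bool(apex > 0 and apex >= threshold)
    return XicCall(
        target_mz=target_mz,
        ppm_window=ppm_window,
        run_id=ms1[0].run_id,
        apex_intensity=apex,
        relative_intensity=relative,
        present=present,
        trace=trace,
    )
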