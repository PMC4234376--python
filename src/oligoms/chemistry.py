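"""Monoisotopic mass and m/z arithmetic for modified RNA oligonucleotides.

An RNA oligonucleotide is modelled as a residue string over ``ACGU`` with an
optional modification at each position, plus explicit 5'/3' terminal
chemistry.  Masses are built from a single embedded table of monoisotopic
element masses (CODATA/NIST 2018 values), so results are bit-stable across
platforms.  Negative-mode electrospray is assumed throughout: an ion of
charge magnitude z is the neutral molecule minus z protons.

CID backbone fragments follow the McLuckey nomenclature for nucleic acids:
5'-side fragments are the a (3'-OH) and c (3'-phosphate) series, 3'-side
fragments are the w (5'-phosphate) and y (5'-OH) series.  For every cleavage
index the complementary pairs satisfy ``a_i + w_{n-i} = c_i + y_{n-i} =
M + H2O`` in neutral mass.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "PROTON_MASS",
    "Modification",
    "ModificationAlphabet",
    "Oligonucleotide",
    "IonSpec",
    "ChemistryError",
    "neutral_mass",
    "mz",
    "neutral_from_mz",
    "fragment_neutral",
    "fragment_ions",
    "parse_oligo",
    "METHYL_DELTA",
    "ACETYL_DELTA",
    "WATER_MASS",
    "HPO3_MASS",
]

# Fixed proton mass so that m/z output is bit-stable.
PROTON_MASS = 1.0072765

# Monoisotopic element masses, Da (NIST atomic weights, monoisotopic).
_ELEMENT_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}


def _formula_mass(formula: Mapping[str, int]) -> float:
    return sum(_ELEMENT_MASS[el] * n for el, n in formula.items())


# Ribonucleoside-3'-monophosphate compositions (free acid).  A chain of n
# such residues joined by phosphodiester bonds loses one water per bond, so
# a 5'-OH / 3'-phosphate oligonucleotide weighs sum(NMP) - (n-1) * H2O.
_NMP_FORMULA: Dict[str, Counter] = {
    "A": Counter({"C": 10, "H": 14, "N": 5, "O": 7, "P": 1}),
    "C": Counter({"C": 9, "H": 14, "N": 3, "O": 8, "P": 1}),
    "G": Counter({"C": 10, "H": 14, "N": 5, "O": 8, "P": 1}),
    "U": Counter({"C": 9, "H": 13, "N": 2, "O": 9, "P": 1}),
}

# Neutral nucleobases, used for a-B (base loss) ions.
_BASE_FORMULA: Dict[str, Counter] = {
    "A": Counter({"C": 5, "H": 5, "N": 5}),
    "C": Counter({"C": 4, "H": 5, "N": 3, "O": 1}),
    "G": Counter({"C": 5, "H": 5, "N": 5, "O": 1}),
    "U": Counter({"C": 4, "H": 4, "N": 2, "O": 2}),
}

_NMP_MASS = {b: _formula_mass(f) for b, f in _NMP_FORMULA.items()}
_BASE_MASS = {b: _formula_mass(f) for b, f in _BASE_FORMULA.items()}
WATER_MASS = _formula_mass({"H": 2, "O": 1})
HPO3_MASS = _formula_mass({"H": 1, "P": 1, "O": 3})

FIVE_PRIME_STATES = ("OH", "phosphate")
THREE_PRIME_STATES = ("OH", "linear_phosphate", "cyclic_phosphate")


class ChemistryError(ValueError):
    """Invalid oligonucleotide, modification or ion specification."""


@dataclass(frozen=True)
class Modification:
    """A named mass delta with base compatibility.

    ``blocks_t1_cleavage`` marks modifications (2'-O-methylguanosine) that
    prevent RNase T1 from cutting 3' of the carrying residue.
    """

    name: str
    mass_delta: float
    allowed_bases: frozenset
    blocks_t1_cleavage: bool = False

    def __post_init__(self):
        if not self.name:
            raise ChemistryError("modification name must be non-empty")
        if not (-200.0 < self.mass_delta < 400.0):
            raise ChemistryError(
                f"mass delta {self.mass_delta} for {self.name!r} outside (-200, 400) Da"
            )
        bad = set(self.allowed_bases) - set("ACGU")
        if bad or not self.allowed_bases:
            raise ChemistryError(f"allowed_bases for {self.name!r} invalid: {bad or 'empty'}")


# Commonly used monoisotopic deltas.
METHYL_DELTA = _formula_mass({"C": 1, "H": 2})            # +14.015650
ACETYL_DELTA = _formula_mass({"C": 2, "H": 2, "O": 1})    # +42.010565
DIMETHYL_DELTA = 2 * METHYL_DELTA
# 1-methyl-3-(3-amino-3-carboxypropyl)pseudouridine as one composite delta:
# pseudouridine itself is mass-silent; MS sees methyl + aminocarboxypropyl.
M1ACP3Y_DELTA = _formula_mass({"C": 5, "H": 9, "N": 1, "O": 2})


class ModificationAlphabet:
    """Registry of modifications by unique short code.

    The default alphabet covers the ribosomal small-subunit repertoire:
    N4-acetylcytidine (ac4C), the four 2'-O-methylribonucleosides
    (Am/Cm/Gm/Um), 7-methylguanosine (m7G), N6,N6-dimethyladenosine (m66A),
    1-methyl-3-(3-amino-3-carboxypropyl)pseudouridine (m1acp3Y, composite
    delta), plus a generic ``methyl`` usable on any base in searches.
    """

    def __init__(self, entries: Iterable[Modification]):
        self._entries: Dict[str, Modification] = {}
        for mod in entries:
            if mod.name in self._entries:
                raise ChemistryError(f"duplicate modification name {mod.name!r}")
            self._entries[mod.name] = mod

    def __getitem__(self, name: str) -> Modification:
        try:
            return self._entries[name]
        except KeyError:
            raise ChemistryError(f"unknown modification {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self):
        return len(self._entries)

    def names(self) -> List[str]:
        return list(self._entries)

    def compatible(self, name: str, base: str) -> bool:
        return base in self[name].allowed_bases

    @classmethod
    def default(cls) -> "ModificationAlphabet":
        return cls(
            [
                Modification("ac4C", ACETYL_DELTA, frozenset("C")),
                Modification("Am", METHYL_DELTA, frozenset("A")),
                Modification("Cm", METHYL_DELTA, frozenset("C")),
                Modification("Gm", METHYL_DELTA, frozenset("G"), blocks_t1_cleavage=True),
                Modification("Um", METHYL_DELTA, frozenset("U")),
                Modification("m7G", METHYL_DELTA, frozenset("G")),
                Modification("m66A", DIMETHYL_DELTA, frozenset("A")),
                Modification("m1acp3Y", M1ACP3Y_DELTA, frozenset("U")),
                Modification("methyl", METHYL_DELTA, frozenset("ACGU")),
            ]
        )


@dataclass(frozen=True)
class Oligonucleotide:
    """Residue string plus per-position modifications and terminal chemistry.

    ``mods`` maps 1-based positions within the oligo to modification names.
    ``origin`` optionally records (parent id, start, end), 1-based inclusive,
    in the parent coordinate frame.
    """

    residues: str
    mods: Tuple[Tuple[int, str], ...] = ()
    five_prime: str = "OH"
    three_prime: str = "linear_phosphate"
    origin: Optional[Tuple[str, int, int]] = None

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ChemistryError("oligonucleotide must contain at least one residue")
        bad = set(self.residues) - set("ACGU")
        if bad:
            raise ChemistryError(f"unknown residue letter(s): {sorted(bad)}")
        if self.five_prime not in FIVE_PRIME_STATES:
            raise ChemistryError(f"bad 5' state {self.five_prime!r}")
        if self.three_prime not in THREE_PRIME_STATES:
            raise ChemistryError(f"bad 3' state {self.three_prime!r}")
        mods = tuple(sorted(dict(self.mods).items()))
        object.__setattr__(self, "mods", mods)
        for pos, _ in mods:
            if not 1 <= pos <= len(self.residues):
                raise ChemistryError(
                    f"modification position {pos} outside 1..{len(self.residues)}"
                )
        if self.origin is not None:
            pid, start, end = self.origin
            if end - start + 1 != len(self.residues):
                raise ChemistryError("origin interval length disagrees with residues")

    @property
    def mod_map(self) -> Dict[int, str]:
        return dict(self.mods)

    def __len__(self):
        return len(self.residues)

    def without_mods(self) -> "Oligonucleotide":
        return Oligonucleotide(self.residues, (), self.five_prime, self.three_prime, self.origin)

    def with_mods(self, mods: Mapping[int, str]) -> "Oligonucleotide":
        return Oligonucleotide(
            self.residues, tuple(mods.items()), self.five_prime, self.three_prime, self.origin
        )

    def notation(self, alphabet: Optional["ModificationAlphabet"] = None) -> str:
        """Bracketed string form, e.g. ``UUUC[ac4C]G>p`` for UUUC(AcC)Gp.

        A bracket token stands for one modified residue.  When the
        modification's base is ambiguous in the alphabet the base is made
        explicit as ``[base:mod]``.
        """
        if alphabet is None:
            alphabet = ModificationAlphabet.default()
        parts = []
        mm = self.mod_map
        for i, base in enumerate(self.residues, start=1):
            if i in mm:
                name = mm[i]
                unique = name in alphabet and len(alphabet[name].allowed_bases) == 1
                parts.append(f"[{name}]" if unique else f"[{base}:{name}]")
            else:
                parts.append(base)
        suffix = {"OH": "", "linear_phosphate": ">p", "cyclic_phosphate": ">cp"}[self.three_prime]
        prefix = {"OH": "", "phosphate": "p<"}[self.five_prime]
        return prefix + "".join(parts) + suffix


def parse_oligo(
    text: str,
    alphabet: Optional[ModificationAlphabet] = None,
    five_prime: str = "OH",
    three_prime: str = "linear_phosphate",
) -> Oligonucleotide:
    """Parse bracketed-modification notation, e.g. ``UUUC[ac4C]G>p``.

    Each ``[mod]`` token is one modified residue; its base is inferred from
    the alphabet when unambiguous, otherwise write ``[base:mod]`` (e.g.
    ``[C:methyl]``).  A leading ``p<`` forces a 5'-phosphate; trailing
    ``>p`` / ``>cp`` / ``>oh`` force the 3' chemistry, overriding the
    keyword defaults.
    """
    if alphabet is None:
        alphabet = ModificationAlphabet.default()
    if text.startswith("p<"):
        five_prime = "phosphate"
        text = text[2:]
    for suffix, state in ((">cp", "cyclic_phosphate"), (">p", "linear_phosphate"), (">oh", "OH")):
        if text.endswith(suffix):
            three_prime = state
            text = text[: -len(suffix)]
            break
    residues: List[str] = []
    mods: Dict[int, str] = {}
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.index("]", i)
            token = text[i + 1 : j]
            if ":" in token:
                base, name = token.split(":", 1)
                base = base.upper().replace("T", "U")
            else:
                name = token
                allowed = alphabet[name].allowed_bases
                if len(allowed) != 1:
                    raise ChemistryError(
                        f"base of {name!r} is ambiguous; write [base:{name}]"
                    )
                (base,) = allowed
            residues.append(base)
            mods[len(residues)] = name
            i = j + 1
        else:
            residues.append(ch.upper().replace("T", "U"))
            i += 1
    return Oligonucleotide("".join(residues), tuple(mods.items()), five_prime, three_prime)


@dataclass(frozen=True)
class IonSpec:
    """A backbone fragment-ion label: series, cleavage index, charge magnitude."""

    series: str
    index: int
    charge: int = 1

    def __post_init__(self):
        if self.series not in ("a", "a-B", "c", "w", "y"):
            raise ChemistryError(f"unknown ion series {self.series!r}")
        if self.index < 1:
            raise ChemistryError("ion index must be >= 1")
        if self.charge < 1:
            raise ChemistryError("charge magnitude must be >= 1")

    def label(self) -> str:
        z = "" if self.charge == 1 else f"^{self.charge}-"
        return f"{self.series}{self.index}{z}"


def _validate_mods(oligo: Oligonucleotide, alphabet: ModificationAlphabet) -> None:
    for pos, name in oligo.mods:
        base = oligo.residues[pos - 1]
        mod = alphabet[name]
        if base not in mod.allowed_bases:
            raise ChemistryError(
                f"modification {name!r} not allowed on base {base} at position {pos}"
            )


def neutral_mass(oligo: Oligonucleotide, alphabet: ModificationAlphabet) -> float:
    """Monoisotopic neutral mass in Da.

    Sum of nucleoside-3'-monophosphate residues minus one water per
    phosphodiester bond, adjusted for terminal chemistry, plus the sum of
    modification deltas.  Additive and order-independent in the mods.
    """
    _validate_mods(oligo, alphabet)
    n = len(oligo.residues)
    mass = sum(_NMP_MASS[b] for b in oligo.residues) - (n - 1) * WATER_MASS
    # Baseline is 5'-OH / 3'-linear-phosphate (the RNase T1 product form).
    if oligo.five_prime == "phosphate":
        mass += HPO3_MASS
    if oligo.three_prime == "OH":
        mass -= HPO3_MASS
    elif oligo.three_prime == "cyclic_phosphate":
        mass -= WATER_MASS
    mass += sum(alphabet[name].mass_delta for _, name in oligo.mods)
    return mass


def mz(neutral: float, charge_magnitude: int, polarity: str = "negative") -> float:
    """m/z of a multiply deprotonated ion: (M - z * m_p) / z."""
    if charge_magnitude < 1:
        raise ChemistryError("charge magnitude must be >= 1")
    if polarity != "negative":
        raise ChemistryError("only negative mode is supported")
    return (neutral - charge_magnitude * PROTON_MASS) / charge_magnitude


def neutral_from_mz(observed_mz: float, charge_magnitude: int, polarity: str = "negative") -> float:
    """Inverse of :func:`mz`; exact round-trip."""
    if charge_magnitude < 1:
        raise ChemistryError("charge magnitude must be >= 1")
    if polarity != "negative":
        raise ChemistryError("only negative mode is supported")
    return observed_mz * charge_magnitude + charge_magnitude * PROTON_MASS


def _sub_oligo(
    oligo: Oligonucleotide, start: int, end: int, five_prime: str, three_prime: str
) -> Oligonucleotide:
    """Slice residues [start, end] (1-based inclusive); mods travel along."""
    mods = {
        pos - start + 1: name for pos, name in oligo.mods if start <= pos <= end
    }
    return Oligonucleotide(oligo.residues[start - 1 : end], tuple(mods.items()), five_prime, three_prime)


def fragment_neutral(
    oligo: Oligonucleotide, spec: IonSpec, alphabet: ModificationAlphabet
) -> float:
    """Neutral mass of one backbone fragment of ``oligo``.

    5' fragments (a, a-B, c) contain ``index`` residues from the 5' end and
    inherit the precursor's 5' terminus; 3' fragments (w, y) contain
    ``index`` residues counted from the 3' end and inherit the precursor's
    3' terminus, so c_i and y_{n-i} arise from the same backbone cleavage.
    a-B additionally loses the 3'-terminal nucleobase (with its
    modification delta, if any).
    """
    n = len(oligo.residues)
    if not 1 <= spec.index <= n - 1:
        raise ChemistryError(f"ion index {spec.index} invalid for length {n}")
    i = spec.index
    if spec.series in ("a", "a-B"):
        frag = _sub_oligo(oligo, 1, i, oligo.five_prime, "OH")
        mass = neutral_mass(frag, alphabet)
        if spec.series == "a-B":
            mass -= _BASE_MASS[oligo.residues[i - 1]]
            mod = oligo.mod_map.get(i)
            if mod is not None:
                mass -= alphabet[mod].mass_delta
        return mass
    if spec.series == "c":
        return neutral_mass(_sub_oligo(oligo, 1, i, oligo.five_prime, "linear_phosphate"), alphabet)
    if spec.series == "w":
        frag = _sub_oligo(oligo, n - i + 1, n, "phosphate", oligo.three_prime)
        return neutral_mass(frag, alphabet)
    # y
    return neutral_mass(_sub_oligo(oligo, n - i + 1, n, "OH", oligo.three_prime), alphabet)


def fragment_ions(
    oligo: Oligonucleotide,
    alphabet: ModificationAlphabet,
    series: Sequence[str] = ("a", "c", "w", "y"),
    max_charge: int = 1,
) -> List[Tuple[IonSpec, float]]:
    """All requested backbone fragment ions with their m/z values.

    Returns an empty list for a length-1 oligo (no backbone to cleave).
    Charges run 1..max_charge for every fragment; callers wanting a
    phosphate-count cap can filter on the returned specs.
    """
    _validate_mods(oligo, alphabet)
    n = len(oligo.residues)
    out: List[Tuple[IonSpec, float]] = []
    if n < 2:
        return out
    for s in series:
        if s not in ("a", "a-B", "c", "w", "y"):
            raise ChemistryError(f"unknown ion series {s!r}")
        for i in range(1, n):
            neutral = fragment_neutral(oligo, IonSpec(s, i), alphabet)
            for z in range(1, max_charge + 1):
                out.append((IonSpec(s, i, z), mz(neutral, z)))
    return out
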