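"""In-silico ribonuclease digestion and RNase-H window modelling.

RNase T1 cleaves single-stranded RNA 3' of guanosine, leaving 5'-OH and
3'-phosphate termini on the products; the parent molecule's own ends are
retained on the first and last product.  Sequence-directed RNase H
cleavage, guided by a complementary 20-28-mer DNA, is idealised here as
exact excision of a coordinate window, which is how redundant short digest
products (e.g. a CCGp occurring at nine places in an rRNA) are narrowed to
a single parent-frame position.

Coordinates are 1-based inclusive throughout, matching the conventional
"start-end" notation for rRNA fragments; conversion to 0-based half-open
happens only at the BED boundary (see :mod:`oligoms.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .chemistry import ModificationAlphabet, Oligonucleotide

__all__ = [
    "ParentRNA",
    "DigestProduct",
    "CleavageWindow",
    "DigestionError",
    "WindowDesignError",
    "digest_t1",
    "locate_product",
    "apply_windows",
    "disambiguate",
    "propose_windows",
    "verify_window_design",
    "reverse_complement_dna",
]

Interval = Tuple[int, int]


class DigestionError(ValueError):
    pass


class WindowDesignError(DigestionError):
    """Raised when no cut placement can separate two occurrences."""


@dataclass
class ParentRNA:
    """A parent RNA sequence with optional known modification annotations.

    ``known_mods`` maps 1-based positions to modification names.  ``origin``
    records, for an excised sub-RNA, the parent id and the window's
    coordinates in the original frame.
    """

    id: str
    sequence: str
    known_mods: Dict[int, str] = field(default_factory=dict)
    five_prime: str = "OH"
    three_prime: str = "OH"
    origin: Optional[Tuple[str, int, int]] = None

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("T", "U")
        if len(self.sequence) < 1:
            raise DigestionError("parent sequence must be non-empty")
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise DigestionError(f"non-RNA letters in sequence: {sorted(bad)}")
        for pos in self.known_mods:
            if not 1 <= pos <= len(self.sequence):
                raise DigestionError(f"modification position {pos} outside sequence")

    def __len__(self):
        return len(self.sequence)


@dataclass
class DigestProduct:
    """One digestion product with its parent-frame occurrence list.

    ``occurrences`` are all digestion-consistent intervals where the
    product's unmodified sequence occurs in the parent (for T1 products:
    preceded by a G or the parent 5' end), sorted; they always include the
    product's own origin.
    """

    oligo: Oligonucleotide
    missed_cleavages: int
    occurrences: List[Interval]

    def __post_init__(self):
        if self.missed_cleavages < 0:
            raise DigestionError("missed cleavage count must be >= 0")
        if not self.occurrences:
            raise DigestionError("occurrence list must be non-empty")
        self.occurrences = sorted(self.occurrences)
        n = len(self.oligo.residues)
        for s, e in self.occurrences:
            if e - s + 1 != n:
                raise DigestionError(f"occurrence ({s},{e}) length != oligo length {n}")

    @property
    def sequence(self) -> str:
        return self.oligo.residues

    @property
    def start(self) -> int:
        return self.oligo.origin[1]

    @property
    def end(self) -> int:
        return self.oligo.origin[2]


@dataclass
class CleavageWindow:
    """A contiguous parent region isolated by directed RNase H cleavage.

    ``guide`` is the synthetic DNA (20-28 nt) complementary to the RNA
    around a cut site; ``run_id`` optionally names the LC-MS run acquired on
    the excised fragment, which is how window evidence is attached to
    spectra during a search.
    """

    parent_id: str
    start: int
    end: int
    guide: Optional[str] = None
    run_id: Optional[str] = None

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise DigestionError(f"bad window ({self.start},{self.end})")
        if self.guide is not None and not 20 <= len(self.guide) <= 28:
            raise DigestionError("guide length must be within 20..28 nt")

    @property
    def name(self) -> str:
        return f"win{self.start}-{self.end}"

    def contains(self, interval: Interval) -> bool:
        return self.start <= interval[0] and interval[1] <= self.end


_DNA_COMPLEMENT = str.maketrans("ACGU", "TGCA")


def reverse_complement_dna(rna: str) -> str:
    """Reverse-complement of an RNA string, written as DNA (U pairs with A)."""
    return rna.upper().replace("T", "U").translate(_DNA_COMPLEMENT)[::-1]


def _t1_cut_sites(
    parent: ParentRNA,
    respect_blocking: bool,
    alphabet: Optional[ModificationAlphabet],
) -> List[int]:
    """1-based positions p such that T1 cuts between p and p+1."""
    if alphabet is None:
        alphabet = ModificationAlphabet.default()
    sites = []
    seq = parent.sequence
    for p in range(1, len(seq)):  # a cut after the final residue is vacuous
        if seq[p - 1] != "G":
            continue
        if respect_blocking:
            mod = parent.known_mods.get(p)
            if mod is not None and mod in alphabet and alphabet[mod].blocks_t1_cleavage:
                continue
        sites.append(p)
    return sites


def product_occurrences(parent: ParentRNA, product_sequence: str) -> List[Interval]:
    """Digestion-consistent occurrences of a T1 product sequence.

    An occurrence must start at the parent 5' end or immediately after a G
    (i.e. after a T1 cut), and must either end in G or run to the parent
    3' end.  This distinguishes the digest product CCGp from an incidental
    CCG substring inside a longer product such as UUUCCGp.
    """
    seq = parent.sequence
    m = len(product_sequence)
    out = []
    start = 0
    while True:
        idx = seq.find(product_sequence, start)
        if idx == -1:
            break
        s, e = idx + 1, idx + m  # 1-based inclusive
        starts_ok = s == 1 or seq[s - 2] == "G"
        ends_ok = product_sequence.endswith("G") or e == len(seq)
        if starts_ok and ends_ok:
            out.append((s, e))
        start = idx + 1
    return out


def digest_t1(
    parent: ParentRNA,
    max_missed: int = 1,
    respect_blocking: bool = True,
    alphabet: Optional[ModificationAlphabet] = None,
) -> List[DigestProduct]:
    """In-silico RNase T1 digest with up to ``max_missed`` missed cleavages.

    Products carry 5'-OH / 3'-linear-phosphate termini except where they
    retain the parent's own 5' or 3' end.  Known modifications of the
    parent travel with their residues (remapped to oligo-local positions).
    Zero-missed products concatenate exactly to the parent sequence.
    """
    if max_missed < 0:
        raise DigestionError("max_missed must be >= 0")
    n = len(parent)
    cuts = _t1_cut_sites(parent, respect_blocking, alphabet)
    bounds = [0] + cuts + [n]  # segment k spans bounds[k]+1 .. bounds[k+1]
    nseg = len(bounds) - 1
    occ_cache: Dict[str, List[Interval]] = {}
    products: List[DigestProduct] = []
    for k in range(nseg):
        for miss in range(0, max_missed + 1):
            j = k + miss
            if j >= nseg:
                break
            s, e = bounds[k] + 1, bounds[j + 1]
            seq = parent.sequence[s - 1 : e]
            mods = {
                pos - s + 1: name
                for pos, name in parent.known_mods.items()
                if s <= pos <= e
            }
            oligo = Oligonucleotide(
                seq,
                tuple(mods.items()),
                five_prime=parent.five_prime if s == 1 else "OH",
                three_prime=parent.three_prime if e == n else "linear_phosphate",
                origin=(parent.id, s, e),
            )
            if seq not in occ_cache:
                occ_cache[seq] = product_occurrences(parent, seq)
            occs = occ_cache[seq] or [(s, e)]
            products.append(DigestProduct(oligo, miss, occs))
    return products


def locate_product(parent: ParentRNA, product_sequence: str) -> List[Interval]:
    """All (possibly overlapping) substring occurrences, 1-based, sorted."""
    seq = parent.sequence
    query = product_sequence.upper().replace("T", "U")
    out = []
    start = 0
    while True:
        idx = seq.find(query, start)
        if idx == -1:
            return out
        out.append((idx + 1, idx + len(query)))
        start = idx + 1


def apply_windows(
    parent: ParentRNA, windows: Sequence[CleavageWindow]
) -> List[ParentRNA]:
    """Excise each window as a sub-RNA, coordinates kept in the parent frame.

    Windows must be pairwise non-overlapping.  Known modifications inside a
    window are carried over at remapped local positions; the returned
    sub-RNA's ``origin`` preserves the parent-frame interval.
    """
    ordered = sorted(windows, key=lambda w: (w.start, w.end))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start <= prev.end:
            raise DigestionError(
                f"overlapping windows ({prev.start},{prev.end}) and ({cur.start},{cur.end})"
            )
    out = []
    for w in ordered:
        if w.end > len(parent):
            raise DigestionError(f"window ({w.start},{w.end}) outside parent of length {len(parent)}")
        sub_seq = parent.sequence[w.start - 1 : w.end]
        mods = {
            pos - w.start + 1: name
            for pos, name in parent.known_mods.items()
            if w.start <= pos <= w.end
        }
        out.append(
            ParentRNA(
                id=f"{parent.id}:{w.start}-{w.end}",
                sequence=sub_seq,
                known_mods=mods,
                five_prime=parent.five_prime if w.start == 1 else "OH",
                three_prime=parent.three_prime if w.end == len(parent) else "OH",
                origin=(parent.id, w.start, w.end),
            )
        )
    return out


def disambiguate(occurrences: Sequence[Interval], window: CleavageWindow) -> List[Interval]:
    """Occurrence intervals fully contained in the window, sorted.

    A single survivor upgrades a redundant site assignment to "localized":
    observing the product in the excised fragment proves which copy it is.
    """
    return sorted(iv for iv in occurrences if window.contains(iv))


def _guide_for_cut(parent: ParentRNA, cut: int, guide_length: int) -> Optional[str]:
    """DNA guide spanning the cut between positions cut and cut+1, or None."""
    half = guide_length // 2
    s = cut - half + 1
    e = s + guide_length - 1
    if s < 1 or e > len(parent):
        return None
    return reverse_complement_dna(parent.sequence[s - 1 : e])


def propose_windows(
    parent: ParentRNA,
    redundant_products: Sequence[DigestProduct],
    guide_length: int = 24,
) -> List[CleavageWindow]:
    """Greedy non-overlapping window design separating redundant products.

    Scans occurrences left to right and places a cut (leftmost feasible,
    deterministic) whenever a window would otherwise contain a second
    occurrence of the same product.  Each returned window contains at most
    one occurrence of every given product; windows tile the whole parent.
    Each cut carries a reverse-complement DNA guide of ``guide_length`` nt
    centred on the cut site.

    Raises :class:`WindowDesignError` when two occurrences of one product
    leave no feasible cut position between them.
    """
    events = []  # (start, end, product index)
    for pi, prod in enumerate(redundant_products):
        if len(prod.occurrences) < 2:
            raise DigestionError(
                f"product {prod.sequence} is not redundant (single occurrence)"
            )
        for iv in prod.occurrences:
            events.append((iv[0], iv[1], pi))
    events.sort()
    cuts: List[int] = []
    guides: List[str] = []
    window_start = 1
    last_occ_in_window: Dict[int, Interval] = {}
    for s, e, pi in events:
        prev = last_occ_in_window.get(pi)
        if prev is not None:
            # need a cut c with prev_end <= c < s, guide must fit
            placed = False
            for c in range(prev[1], s):
                guide = _guide_for_cut(parent, c, guide_length)
                if guide is not None:
                    cuts.append(c)
                    guides.append(guide)
                    window_start = c + 1
                    last_occ_in_window = {
                        qi: iv for qi, iv in last_occ_in_window.items() if iv[0] >= window_start
                    }
                    placed = True
                    break
            if not placed:
                raise WindowDesignError(
                    f"cannot separate occurrences {prev} and ({s},{e}) of "
                    f"{redundant_products[pi].sequence}: no feasible cut"
                )
        last_occ_in_window[pi] = (s, e)
    bounds = [0] + cuts + [len(parent)]
    windows = []
    for k in range(len(bounds) - 1):
        guide = guides[k] if k < len(guides) else None
        windows.append(
            CleavageWindow(parent.id, bounds[k] + 1, bounds[k + 1], guide=guide)
        )
    return windows


def verify_window_design(
    windows: Sequence[CleavageWindow], products: Sequence[DigestProduct]
) -> Dict[str, Dict[str, int]]:
    """Per-window count of fully contained occurrences of each product.

    A design disambiguates a product when every window holds at most one of
    its occurrences; the caller can check any weaker, site-specific goal
    (e.g. a single window isolating the one modified copy) from the counts.
    """
    report: Dict[str, Dict[str, int]] = {}
    for w in windows:
        counts = {}
        for prod in products:
            counts[prod.sequence] = len(disambiguate(prod.occurrences, w))
        report[w.name] = counts
    return report
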