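"""Independent elemental-composition mass oracle for the test suite.

Computes oligonucleotide and fragment masses by summing CHNOP atom counts
for the whole molecule and multiplying by an independently transcribed
isotope-mass table.  Shares no code with oligoms.chemistry: masses are
assembled from nucleoside + phosphate building blocks rather than
nucleotide-residue increments.
"""

from collections import Counter

# NIST monoisotopic masses.  The oracle's independence is its computational
# path (whole-molecule atom counting from nucleoside + phosphate blocks);
# the physical constants are necessarily the same ones.
MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}

# Ribonucleosides (base + ribose, free molecule).
NUCLEOSIDE = {
    "A": Counter(C=10, H=13, N=5, O=4),
    "C": Counter(C=9, H=13, N=3, O=5),
    "G": Counter(C=10, H=13, N=5, O=5),
    "U": Counter(C=9, H=12, N=2, O=6),
}
H2O = Counter(H=2, O=1)
H3PO4 = Counter(H=3, P=1, O=4)
BASE = {
    "A": Counter(C=5, H=5, N=5),
    "C": Counter(C=4, H=5, N=3, O=1),
    "G": Counter(C=5, H=5, N=5, O=1),
    "U": Counter(C=4, H=4, N=2, O=2),
}
MOD_FORMULA = {
    "ac4C": Counter(C=2, H=2, O=1),
    "methyl": Counter(C=1, H=2),
    "Am": Counter(C=1, H=2),
    "Cm": Counter(C=1, H=2),
    "Gm": Counter(C=1, H=2),
    "Um": Counter(C=1, H=2),
    "m7G": Counter(C=1, H=2),
    "m66A": Counter(C=2, H=4),
    "m1acp3Y": Counter(C=5, H=9, N=1, O=2),
}


def formula_mass(formula):
    return sum(MASS[el] * n for el, n in formula.items())


def _sub(total, formula):
    out = Counter(total)
    for el, n in formula.items():
        out[el] -= n
    return out


def oligo_formula(residues, mods=(), five_prime="OH", three_prime="linear_phosphate"):
    """Full-molecule atom counts assembled from nucleosides and phosphates.

    n nucleosides joined by n-1 phosphodiester bridges (each bridge adds
    H3PO4 and removes two waters), then terminal groups.
    """
    n = len(residues)
    total = Counter()
    for b in residues:
        total += NUCLEOSIDE[b]
    for _ in range(n - 1):
        total += H3PO4
        total = _sub(total, H2O)
        total = _sub(total, H2O)
    if five_prime == "phosphate":
        total += H3PO4
        total = _sub(total, H2O)
    if three_prime in ("linear_phosphate", "cyclic_phosphate"):
        total += H3PO4
        total = _sub(total, H2O)
        if three_prime == "cyclic_phosphate":
            total = _sub(total, H2O)
    for _pos, name in dict(mods).items():
        total += MOD_FORMULA[name]
    return total


def oligo_mass(residues, mods=(), five_prime="OH", three_prime="linear_phosphate"):
    return formula_mass(oligo_formula(residues, mods, five_prime, three_prime))


def fragment_mass(residues, mods, five_prime, three_prime, series, index):
    """Neutral fragment masses by slicing the molecule and re-terminating."""
    n = len(residues)
    mods = dict(mods)
    if series in ("a", "c"):
        sub = residues[:index]
        sub_mods = {p: m for p, m in mods.items() if p <= index}
        term3 = "OH" if series == "a" else "linear_phosphate"
        return oligo_mass(sub, sub_mods, five_prime, term3)
    # w / y: index residues from the 3' end
    start = n - index + 1
    sub = residues[start - 1 :]
    sub_mods = {p - start + 1: m for p, m in mods.items() if p >= start}
    term5 = "phosphate" if series == "w" else "OH"
    return oligo_mass(sub, sub_mods, term5, three_prime)


def substring_occurrences(haystack, needle):
    """Naive O(n*m) overlapping scan, 1-based inclusive intervals."""
    out = []
    for i in range(len(haystack) - len(needle) + 1):
        if haystack[i : i + len(needle)] == needle:
            out.append((i + 1, i + len(needle)))
    return out
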