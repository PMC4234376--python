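"""RNase T1 digestion, occurrence location, and RNase-H window modelling."""

import pytest
from hypothesis import given, strategies as st

import _oracle
from oligoms.digestion import (
    CleavageWindow,
    DigestionError,
    ParentRNA,
    WindowDesignError,
    apply_windows,
    digest_t1,
    disambiguate,
    locate_product,
    product_occurrences,
    propose_windows,
    reverse_complement_dna,
    verify_window_design,
)

SEQ = st.text(alphabet="ACGU", min_size=1, max_size=300)

# The nine published parent-frame intervals of the redundant CCGp product
# and the seven RNase-H windows used to resolve them.
CCG_INTERVALS = [
    (285, 287), (575, 577), (664, 666), (866, 868), (1048, 1050),
    (1296, 1298), (1476, 1478), (1541, 1543), (1758, 1760),
]
RNASEH_WINDOWS = [
    (1, 170), (183, 538), (554, 693), (703, 986),
    (1003, 1162), (1177, 1428), (1445, 1842),
]


class TestDigestT1:
    def test_two_cut_sites(self):
        prods = digest_t1(ParentRNA("t", "ACGUG"), max_missed=0)
        assert [(p.sequence, p.missed_cleavages) for p in prods] == [
            ("ACG", 0), ("UG", 0)
        ]
        assert prods[0].oligo.three_prime == "linear_phosphate"
        assert prods[1].oligo.three_prime == "OH"  # parent 3' end retained
        assert all(p.oligo.five_prime == "OH" for p in prods)

    def test_one_missed_cleavage_adds_skipped_product(self):
        prods = digest_t1(ParentRNA("t", "ACGUG"), max_missed=1)
        assert ("ACGUG", 1) in {(p.sequence, p.missed_cleavages) for p in prods}

    @given(SEQ)
    def test_zero_missed_products_reassemble_parent(self, seq):
        parent = ParentRNA("r", seq)
        prods = [p for p in digest_t1(parent, max_missed=0)]
        prods.sort(key=lambda p: p.start)
        assert "".join(p.sequence for p in prods) == parent.sequence

    def test_missed_cleavage_product_count(self):
        # k internal cut sites -> k+1 segments; (k+1-m) products with m missed
        parent = ParentRNA("t", "AGCGUGAGA")  # cuts after 2, 4, 6, 8
        prods = digest_t1(parent, max_missed=2)
        by_missed = {}
        for p in prods:
            by_missed.setdefault(p.missed_cleavages, 0)
            by_missed[p.missed_cleavages] += 1
        assert by_missed == {0: 5, 1: 4, 2: 3}

    def test_blocking_modification_suppresses_cut(self, alphabet):
        parent = ParentRNA("t", "ACGUG", known_mods={3: "Gm"})
        blocked = digest_t1(parent, max_missed=0, alphabet=alphabet)
        assert [p.sequence for p in blocked] == ["ACGUG"]
        unblocked = digest_t1(
            parent, max_missed=0, respect_blocking=False, alphabet=alphabet
        )
        assert [p.sequence for p in unblocked] == ["ACG", "UG"]

    def test_known_mods_remap_to_local_positions(self, alphabet):
        parent = ParentRNA("t", "ACGUCG", known_mods={5: "ac4C"})
        prods = digest_t1(parent, max_missed=0, alphabet=alphabet)
        ucg = [p for p in prods if p.sequence == "UCG"][0]
        assert dict(ucg.oligo.mods) == {2: "ac4C"}


class TestLocateProduct:
    def test_unique_hexamer(self):
        parent = ParentRNA("t", "AAAGUUUCCGAAA")
        assert locate_product(parent, "UUUCCG") == [(5, 10)]

    def test_double_hit(self):
        assert locate_product(ParentRNA("t", "CCGACCG"), "CCG") == [(1, 3), (5, 7)]

    @given(SEQ, st.text(alphabet="ACGU", min_size=1, max_size=4))
    def test_matches_naive_scan_oracle(self, seq, query):
        parent = ParentRNA("t", seq)
        assert locate_product(parent, query) == _oracle.substring_occurrences(seq, query)

    def test_product_occurrences_require_cleavage_context(self):
        # CCG inside UUUCCG is not a T1 product occurrence (U precedes it);
        # the G-preceded copy is.
        parent = ParentRNA("t", "GCCGAUUUCCGA")
        assert locate_product(parent, "CCG") == [(2, 4), (9, 11)]
        assert product_occurrences(parent, "CCG") == [(2, 4)]


class TestWindows:
    def test_identity_window(self):
        parent = ParentRNA("t", "ACGUACGU", known_mods={})
        [sub] = apply_windows(parent, [CleavageWindow("t", 1, 8)])
        assert sub.sequence == parent.sequence
        assert sub.origin == ("t", 1, 8)

    def test_published_window_set_bounds(self, rng):
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 1842))
        parent = ParentRNA("big", seq)
        windows = [CleavageWindow("big", a, b) for a, b in RNASEH_WINDOWS]
        subs = apply_windows(parent, windows)
        assert [(s.origin[1], s.origin[2]) for s in subs] == RNASEH_WINDOWS
        assert all(len(s) == b - a + 1 for s, (a, b) in zip(subs, RNASEH_WINDOWS))

    def test_overlap_rejected(self):
        parent = ParentRNA("t", "ACGU" * 30)
        with pytest.raises(DigestionError, match="overlap"):
            apply_windows(
                parent,
                [CleavageWindow("t", 1, 50), CleavageWindow("t", 40, 100)],
            )

    def test_mods_remapped_into_window(self, alphabet):
        parent = ParentRNA("t", "AAACCGAAA", known_mods={5: "ac4C"})
        [sub] = apply_windows(parent, [CleavageWindow("t", 4, 9)])
        assert sub.known_mods == {2: "ac4C"}

    def test_window_then_digest_equals_interval_intersection(self, rng):
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 500))
        parent = ParentRNA("t", seq)
        w = CleavageWindow("t", 120, 380)
        [sub] = apply_windows(parent, [w])
        sub_occ = {
            (s + 119, e + 119)
            for s, e in product_occurrences(sub, "CG")
            # interior occurrences only: window-boundary context differs
            if s > 1 and e < len(sub)
        }
        direct = {
            iv
            for iv in product_occurrences(parent, "CG")
            if w.start < iv[0] and iv[1] < w.end
        }
        assert sub_occ == direct


class TestDisambiguate:
    def test_published_nine_ccg_resolve_to_1297(self):
        window = CleavageWindow("rRNA", 1177, 1428)
        surviving = disambiguate(CCG_INTERVALS, window)
        assert surviving == [(1296, 1298)]
        # acetyl on the oligo's second residue -> parent position 1297
        assert surviving[0][0] + 2 - 1 == 1297

    def test_disjoint_window_empty(self):
        assert disambiguate(CCG_INTERVALS, CleavageWindow("r", 2000, 2100)) == []

    def test_published_windows_do_not_fully_separate_ccg(self):
        """Three published windows hold 0, several hold 1, one holds 2 and
        one holds 3 CCG copies — only the 1177-1428 window isolates the
        modified copy, which is all the localization argument needs."""
        counts = [
            len(disambiguate(CCG_INTERVALS, CleavageWindow("r", a, b)))
            for a, b in RNASEH_WINDOWS
        ]
        assert counts == [0, 1, 2, 1, 1, 1, 3]

    @given(st.data())
    def test_matches_containment_oracle_and_is_monotone(self, data):
        ivs = sorted(
            (s, s + data.draw(st.integers(0, 5)))
            for s in data.draw(st.sets(st.integers(1, 200), max_size=12))
        )
        a = data.draw(st.integers(1, 200))
        b = a + data.draw(st.integers(0, 100))
        window = CleavageWindow("r", a, b)
        got = disambiguate(ivs, window)
        assert got == [iv for iv in ivs if a <= iv[0] and iv[1] <= b]
        # idempotent and monotone in window size
        assert disambiguate(got, window) == got
        wider = CleavageWindow("r", max(1, a - 10), b + 10)
        assert set(got) <= set(disambiguate(ivs, wider))


class TestProposeWindows:
    def _parent(self, rng, n=300):
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, n))
        return ParentRNA("t", seq)

    def test_two_occurrences_one_cut(self, rng):
        parent = self._parent(rng)
        prod = _fake_product(parent, [(10, 12), (200, 202)])
        windows = propose_windows(parent, [prod])
        assert len(windows) == 2
        assert windows[0].start == 1 and windows[-1].end == len(parent)
        report = verify_window_design(windows, [prod])
        assert all(c <= 1 for counts in report.values() for c in counts.values())

    def test_guides_are_reverse_complement_dna(self, rng):
        parent = self._parent(rng)
        windows = propose_windows(parent, [_fake_product(parent, [(10, 12), (200, 202)])])
        guide = windows[0].guide
        assert guide is not None and 20 <= len(guide) <= 28
        assert set(guide) <= set("ACGT")
        cut = windows[0].end
        region = parent.sequence[cut - len(guide) // 2 : cut + len(guide) - len(guide) // 2]
        assert reverse_complement_dna(region) == guide

    @given(st.integers(0, 2**31 - 1))
    def test_random_plants_verify_under_disambiguate(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        parent = self._parent(rng, 400)
        starts = sorted(int(s) for s in rng.choice(np.arange(30, 370, 40), 3, replace=False))
        prod = _fake_product(parent, [(s, s + 2) for s in starts])
        windows = propose_windows(parent, [prod])
        report = verify_window_design(windows, [prod])
        assert all(c <= 1 for counts in report.values() for c in counts.values())

    def test_adjacent_occurrences_infeasible(self, rng):
        parent = self._parent(rng, 60)
        # back-to-back occurrences near the 5' edge: no guide can straddle a cut
        prod = _fake_product(parent, [(2, 4), (5, 7)])
        with pytest.raises(WindowDesignError):
            propose_windows(parent, [prod], guide_length=24)

    def test_single_occurrence_rejected(self, rng):
        parent = self._parent(rng)
        with pytest.raises(DigestionError, match="not redundant"):
            propose_windows(parent, [_fake_product(parent, [(10, 12)])])


def _fake_product(parent, intervals):
    from oligoms.chemistry import Oligonucleotide
    from oligoms.digestion import DigestProduct

    s, e = intervals[0]
    return DigestProduct(
        Oligonucleotide(parent.sequence[s - 1 : e], origin=(parent.id, s, e)),
        0,
        intervals,
    )


def test_parent_normalises_dna_letters():
    assert ParentRNA("t", "acgt").sequence == "ACGU"
    with pytest.raises(DigestionError):
        ParentRNA("t", "ACGN")
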