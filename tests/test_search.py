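"""Candidate expansion, end-to-end assignment, and differential presence."""

import itertools

import numpy as np
import pytest

from oligoms.chemistry import ModificationAlphabet, parse_oligo
from oligoms.digestion import ParentRNA
from oligoms.search import (
    CombinatorialCapError,
    SearchError,
    SearchParams,
    build_candidates,
    differential_presence,
    run_search,
)
from oligoms.synthetic import PlantedMod, SimScenario, simulate


class TestBuildCandidates:
    def test_ccg_with_acetyl_cap_one(self, alphabet):
        parent = ParentRNA("t", "AAAGCCGAAA")
        params = SearchParams(max_missed=0, variable_mods=(("ac4C", 1),))
        cands = [c for c in build_candidates(parent, params, alphabet) if c.sequence == "CCG"]
        assert len(cands) == 3  # unmodified, ac4C@1, ac4C@2
        assert sorted(c.mods for c in cands) == [(), ((1, "ac4C"),), ((2, "ac4C"),)]

    def test_cap_zero_gives_unmodified_only(self, alphabet):
        parent = ParentRNA("t", "AAAGCCGAAA")
        params = SearchParams(max_missed=0, variable_mods=(("ac4C", 0),))
        cands = build_candidates(parent, params, alphabet)
        assert all(not c.mods for c in cands)

    def test_counts_match_enumeration_oracle(self, alphabet, rng):
        """Per-product candidate count equals the brute-force count of
        disjoint placements of (methyl up to 1) x (ac4C up to 1)."""
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 60))
        parent = ParentRNA("t", seq)
        params = SearchParams(max_missed=1)
        cands = build_candidates(parent, params, alphabet)
        by_seq = {}
        for c in cands:
            by_seq.setdefault((c.sequence, c.product.missed_cleavages), []).append(c)
        for (s, _), group in by_seq.items():
            L = len(s)
            nC = s.count("C")
            methyl_opts = [()] + [(i,) for i in range(1, L + 1)]
            acetyl_opts = [()] + [(i,) for i in range(1, L + 1) if s[i - 1] == "C"]
            expected = sum(
                1
                for m, a in itertools.product(methyl_opts, acetyl_opts)
                if not (set(m) & set(a))
            )
            assert len(group) == expected

    def test_combinatorial_cap_errors_not_truncates(self, alphabet):
        parent = ParentRNA("t", "ACUACUACUACUACUACUACUG")
        params = SearchParams(
            max_missed=0,
            variable_mods=(("methyl", 3),),
            candidate_cap_per_product=50,
        )
        with pytest.raises(CombinatorialCapError):
            build_candidates(parent, params, alphabet)

    def test_deterministic_ordering(self, alphabet):
        parent = ParentRNA("t", "AAAGCCGAAAG")
        params = SearchParams(max_missed=1)
        a = build_candidates(parent, params, alphabet)
        b = build_candidates(parent, params, alphabet)
        assert [(c.sequence, c.mods) for c in a] == [(c.sequence, c.mods) for c in b]


@pytest.fixture(scope="module")
def dataset(small_scenario):
    return simulate(small_scenario)


class TestRunSearch:
    def test_planted_sites_recovered_with_windows(self, dataset):
        sites, coverage, assignments = run_search(
            dataset.runs["WT"],
            dataset.parent,
            SearchParams(),
            windows=dataset.windows["WT"],
        )
        localized = {(s.position, s.modification) for s in sites if s.status == "localized"}
        assert localized == {(151, "ac4C"), (204, "ac4C")}

    def test_without_windows_redundant_site_downgraded(self, dataset):
        sites, _, _ = run_search(dataset.runs["WT"], dataset.parent, SearchParams())
        by_frag = {s.fragment: s for s in sites}
        assert by_frag["C[ac4C]G>p"].status == "sequence_redundant"
        assert by_frag["C[ac4C]G>p"].position is None
        # the unique hexamer stays localized without any window
        assert by_frag["UUUC[ac4C]G>p"].status == "localized"
        assert by_frag["UUUC[ac4C]G>p"].position == 204

    def test_mutant_has_no_modified_sites(self, dataset):
        sites, _, _ = run_search(
            dataset.runs["mutant"],
            dataset.parent,
            SearchParams(),
            windows=dataset.windows["mutant"],
        )
        assert sites == []

    def test_precursor_tolerance_monotonicity(self, dataset):
        """Widening the precursor tolerance never loses an assigned spectrum."""
        narrow_sites, _, narrow = run_search(
            dataset.runs["WT"], dataset.parent, SearchParams(precursor_tol_ppm=5.0)
        )
        _, _, wide = run_search(
            dataset.runs["WT"], dataset.parent, SearchParams(precursor_tol_ppm=20.0)
        )
        narrow_keys = {(a.spectrum.run_id, a.spectrum.scan_id) for a in narrow}
        wide_keys = {(a.spectrum.run_id, a.spectrum.scan_id) for a in wide}
        assert narrow_keys <= wide_keys

    def test_coverage_equals_interval_union(self, dataset):
        _, coverage, assignments = run_search(
            dataset.runs["WT"], dataset.parent, SearchParams()
        )
        brute = np.zeros(len(dataset.parent), dtype=bool)
        for a in assignments:
            if len(a.candidate.sequence) < 2:
                continue
            for s, e in a.candidate.product.occurrences:
                brute[s - 1 : e] = True
        assert np.array_equal(coverage.covered, brute)
        assert coverage.covered_fraction == pytest.approx(brute.mean())

    def test_rerun_is_bit_identical(self, dataset):
        r1 = run_search(dataset.runs["WT"], dataset.parent, SearchParams())
        r2 = run_search(dataset.runs["WT"], dataset.parent, SearchParams())
        assert [
            (s.position, s.modification, s.status) for s in r1[0]
        ] == [(s.position, s.modification, s.status) for s in r2[0]]
        assert r1[1].ptm_rows.equals(r2[1].ptm_rows)

    def test_empty_run_rejected(self, dataset):
        with pytest.raises(SearchError):
            run_search([], dataset.parent, SearchParams())


class TestDifferentialPresence:
    def _targets(self, alphabet):
        return [
            (parse_oligo("C[ac4C]G>p", alphabet), 1),
            (parse_oligo("UUUC[ac4C]G>p", alphabet), 2),
        ]

    def test_wt_mutant_pattern(self, dataset, alphabet):
        table, verdicts = differential_presence(
            {c: dataset.runs[c] for c in ("WT", "mutant")},
            self._targets(alphabet),
            alphabet,
        )
        assert set(verdicts.values()) == {"present/absent"}
        assert len(table) == 4

    def test_identical_conditions_identical_calls(self, dataset, alphabet):
        table, verdicts = differential_presence(
            {"a": dataset.runs["WT"], "b": dataset.runs["WT"]},
            self._targets(alphabet),
            alphabet,
        )
        assert set(verdicts.values()) == {"present/present"}

    def test_occupancy_sweep_flips_presence_once(self, alphabet):
        """As acetyl occupancy rises 0 -> 1, the XIC presence call for the
        acetylated fragment flips absent -> present exactly once
        (presence is monotone in abundance)."""
        from oligoms.digestion import digest_t1
        from oligoms.synthetic import generate_parent, precursor_charge

        parent, _ = generate_parent(SimScenario(parent_length=150, seed=3))
        # a C inside a multi-nucleotide zero-missed product
        prod = next(
            p
            for p in digest_t1(parent, max_missed=0)
            if len(p.sequence) >= 3 and "C" in p.sequence
        )
        local = prod.sequence.index("C") + 1
        c_pos = prod.start + local - 1
        oligo = prod.oligo.with_mods({local: "ac4C"})
        target = [(oligo, precursor_charge(len(oligo)))]
        calls = []
        for occ in (0.0, 0.25, 0.5, 0.75, 1.0):
            ds = simulate(
                SimScenario(
                    parent_length=150,
                    planted_mods=(PlantedMod(c_pos, "ac4C", (("s", occ),)),),
                    seed=3,
                )
            )
            _, verdicts = differential_presence(
                {"s": ds.runs["s"], "ref": ds.runs["s"]}, target, alphabet
            )
            calls.append(next(iter(verdicts.values())).split("/")[0] == "present")
        flips = sum(1 for a, b in zip(calls, calls[1:]) if a != b)
        assert calls[0] is False and calls[-1] is True and flips == 1

    def test_single_condition_rejected(self, dataset, alphabet):
        with pytest.raises(SearchError):
            differential_presence({"only": dataset.runs["WT"]}, self._targets(alphabet))
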