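"""Identity-by-state, run-of-homozygosity detection, case-shared regions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mendelmap.errors import UndefinedResultError
from mendelmap.roh import (
    RohParams,
    compute_ibs,
    detect_roh,
    exclude_parental,
    shared_case_regions,
)

from .conftest import make_gm
from .oracles import roh_oracle

MB = 1_000_000


class TestComputeIbs:
    def test_identical_vectors_give_100(self):
        gm = make_gm({"a": ["AA", "AB", "BB"] * 4, "b": ["AA", "AB", "BB"] * 4})
        assert compute_ibs(gm, "a", "b") == 100.0

    def test_opposite_homozygotes_give_0(self):
        gm = make_gm({"a": ["AA"] * 6, "b": ["BB"] * 6})
        assert compute_ibs(gm, "a", "b") == 0.0

    def test_hand_enumerated_three_marker_example(self):
        # per-marker sharing: identical=1, one shared allele=0.5, none=0
        # (AA,AA)=1, (AB,BB)=0.5, (BB,AB)=0.5 -> 100*2/3
        gm = make_gm({"a": ["AA", "AB", "BB"], "b": ["AA", "BB", "AB"]})
        assert compute_ibs(gm, "a", "b") == pytest.approx(100 * 2 / 3)

    def test_missing_markers_excluded_from_denominator(self):
        gm = make_gm({"a": ["AA", "..", "BB"], "b": ["AA", "AA", ".."]})
        assert compute_ibs(gm, "a", "b") == 100.0

    def test_no_co_called_markers_is_undefined(self):
        gm = make_gm({"a": ["AA", ".."], "b": ["..", "AA"]})
        with pytest.raises(UndefinedResultError):
            compute_ibs(gm, "a", "b")

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=40), st.data())
    def test_symmetric_self_identity_and_range(self, calls, data):
        other = data.draw(st.lists(st.integers(0, 2), min_size=len(calls), max_size=len(calls)))
        gm = make_gm({"a": calls, "b": other})
        ab = compute_ibs(gm, "a", "b")
        assert ab == compute_ibs(gm, "b", "a")
        assert 0.0 <= ab <= 100.0
        assert compute_ibs(gm, "a", "a") == 100.0


class TestDetectRoh:
    def test_all_heterozygous_yields_nothing(self):
        gm = make_gm({"s": ["AB"] * 50})
        assert detect_roh(gm, "s") == []

    def test_single_flanked_run_found_exactly(self):
        # 30 homozygous markers spanning 1.5 Mb, flanked by hets
        pos = [100_000, 200_000] + [300_000 + i * 50_000 for i in range(30)] + [3 * MB]
        calls = ["AB", "AB"] + ["AA"] * 30 + ["AB"]
        gm = make_gm({"s": calls}, positions=pos)
        runs = detect_roh(gm, "s")
        assert len(runs) == 1
        assert runs[0].n_markers == 30
        assert runs[0].interval.start == 300_000
        assert runs[0].interval.end == 300_000 + 29 * 50_000 + 1

    def test_missing_calls_bridged_within_budget(self):
        pos = [i * 40_000 for i in range(1, 52)]
        calls = ["AA"] * 25 + [".."] + ["AA"] * 25
        gm = make_gm({"s": calls}, positions=pos)
        runs = detect_roh(gm, "s", RohParams(min_length_bp=MB, max_missing_in_run=2))
        assert len(runs) == 1
        assert runs[0].n_markers == 51

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_bruteforce_enumeration_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 200))
        calls = rng.choice([0, 1, 2, -1], size=n, p=[0.42, 0.12, 0.42, 0.04])
        pos = np.cumsum(rng.integers(10_000, 120_000, size=n)).tolist()
        params = RohParams(
            min_length_bp=int(rng.integers(200_000, 1_200_000)),
            min_markers=int(rng.integers(2, 15)),
            max_missing_in_run=int(rng.integers(0, 3)),
            max_het_in_run=int(rng.integers(0, 2)),
        )
        gm = make_gm({"s": calls.tolist()}, positions=pos)
        got = [(r.start_idx, r.end_idx - 1) for r in detect_roh(gm, "s", params)]
        assert got == roh_oracle(calls.tolist(), pos, params)


class TestSharedRegions:
    params = RohParams(min_length_bp=MB, min_markers=5)

    def test_twin_cases_reproduce_their_own_runs(self):
        calls = ["AB"] * 3 + ["AA"] * 20 + ["AB"] * 3
        pos = [i * 100_000 for i in range(1, 27)]
        gm = make_gm({"c1": calls, "c2": calls}, positions=pos)
        runs = {c: detect_roh(gm, c, self.params) for c in ("c1", "c2")}
        regions = shared_case_regions(runs, gm, ["c1", "c2"], self.params)
        assert [(r.interval.start, r.interval.end) for r in regions] == [
            (runs["c1"][0].interval.start, runs["c1"][0].interval.end)
        ]

    def test_partial_overlap_intersected(self):
        # c1 homozygous over markers 0..29, c2 over 15..44; same allele
        pos = [i * 100_000 for i in range(1, 46)]
        c1 = ["AA"] * 30 + ["AB"] * 15
        c2 = ["AB"] * 15 + ["AA"] * 30
        gm = make_gm({"c1": c1, "c2": c2}, positions=pos)
        runs = {c: detect_roh(gm, c, self.params) for c in ("c1", "c2")}
        regions = shared_case_regions(runs, gm, ["c1", "c2"], self.params)
        assert len(regions) == 1
        assert regions[0].interval.start == pos[15]
        assert regions[0].interval.end == pos[29] + 1

    def test_opposite_alleles_yield_no_region(self):
        pos = [i * 100_000 for i in range(1, 31)]
        gm = make_gm({"c1": ["AA"] * 30, "c2": ["BB"] * 30}, positions=pos)
        runs = {c: detect_roh(gm, c, self.params) for c in ("c1", "c2")}
        assert shared_case_regions(runs, gm, ["c1", "c2"], self.params) == []


class TestExcludeParental:
    params = RohParams(min_length_bp=MB, min_markers=5)

    def _regions(self, gm):
        runs = {c: detect_roh(gm, c, self.params) for c in ("c1", "c2")}
        return shared_case_regions(runs, gm, ["c1", "c2"], self.params)

    def test_het_carrier_parent_retained(self):
        pos = [i * 100_000 for i in range(1, 41)]
        gm = make_gm(
            {"c1": ["AA"] * 40, "c2": ["AA"] * 40, "p": ["AB"] * 40}, positions=pos
        )
        kept = exclude_parental(self._regions(gm), gm, ["p"])
        assert len(kept) == 1
        assert kept[0].parent_conflicts["p"] == 0

    def test_homozygous_parent_drops_region(self):
        pos = [i * 100_000 for i in range(1, 41)]
        gm = make_gm(
            {"c1": ["AA"] * 40, "c2": ["AA"] * 40, "p": ["AA"] * 40}, positions=pos
        )
        assert exclude_parental(self._regions(gm), gm, ["p"]) == []

    def test_conflict_fraction_boundary_is_strict(self):
        # parent homozygous for the shared allele at 2 of 40 markers:
        # 2/40 = 0.05 is not > 0.05, so the region survives
        pos = [i * 100_000 for i in range(1, 41)]
        parent = ["AA", "AA"] + ["AB"] * 38
        gm = make_gm({"c1": ["AA"] * 40, "c2": ["AA"] * 40, "p": parent}, positions=pos)
        regions = self._regions(gm)
        assert exclude_parental(regions, gm, ["p"], max_parent_hom_fraction=0.05)
        assert exclude_parental(regions, gm, ["p"], max_parent_hom_fraction=0.049) == []

    def test_opposite_homozygote_parent_is_not_a_conflict(self):
        pos = [i * 100_000 for i in range(1, 41)]
        gm = make_gm(
            {"c1": ["AA"] * 40, "c2": ["AA"] * 40, "p": ["BB"] * 40}, positions=pos
        )
        kept = exclude_parental(self._regions(gm), gm, ["p"])
        assert len(kept) == 1
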