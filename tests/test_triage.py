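"""Private-variant funnel: coding selection, region/cohort filters, set algebra."""

import numpy as np
import pytest

from mendelmap.intervals import GenomicInterval
from mendelmap.roh import CandidateRegion
from mendelmap.simulate import make_transcript_fixture, simulate_variant_cohort
from mendelmap.transcripts import TranscriptModel
from mendelmap.triage import (
    TriageFunnel,
    dominant_branch,
    filter_step1_regions,
    filter_step2_controls,
    filter_step3_popdb,
    recessive_branch,
    select_coding_by_zygosity,
    select_nonsynonymous,
)
from mendelmap.variants import Variant, normalize_site

from .conftest import small_config


def _tx():
    # two exons 100-160 and 200-260 (0-based), 120 nt CDS, plus strand
    cds = "ATG" + "GCA" * 38 + "TAA"
    return TranscriptModel(
        "t1", "g1", "1", "+",
        [GenomicInterval("1", 100, 160), GenomicInterval("1", 200, 260)], cds,
    )


def _region(chrom="1", start=0, end=1000):
    return CandidateRegion(
        GenomicInterval(chrom, start, end), 0, 0, 0, np.array([], dtype=np.int8)
    )


def _v(pos, ref="A", alt="C", gt=2, chrom="1"):
    return Variant(chrom, pos, ref, alt, {"case": gt})


class TestCodingSelection:
    def test_intronic_variant_excluded(self):
        tx = _tx()
        assert select_coding_by_zygosity([_v(170)], [tx], "hom-alt", "case") == []

    def test_exonic_hom_alt_included_once_despite_two_overlaps(self):
        tx = _tx()
        other = TranscriptModel(
            "t2", "g1", tx.chrom, "+", [e for e in tx.exons], tx.cds_seq
        )
        kept = select_coding_by_zygosity([_v(110)], [tx, other], "hom-alt", "case")
        assert len(kept) == 1

    def test_zygosity_mismatch_excluded(self):
        tx = _tx()
        assert select_coding_by_zygosity([_v(110, gt=1)], [tx], "hom-alt", "case") == []
        assert select_coding_by_zygosity([_v(110, gt=1)], [tx], "het", "case") == [
            _v(110, gt=1)
        ]

    def test_unknown_chromosome_warned_and_excluded(self):
        tx = _tx()
        with pytest.warns(UserWarning, match="unknown chromosome"):
            out = select_coding_by_zygosity([_v(110, chrom="99")], [tx], "hom-alt", "case")
        assert out == []

    def test_deletion_span_touching_exon_included(self):
        tx = _tx()
        # anchored at 100 (intergenic) but the deleted base 101 is exonic
        v = Variant("1", 100, "TA", "T", {"case": 2})
        assert select_coding_by_zygosity([v], [tx], "hom-alt", "case") == [v]


class TestRegionFilter:
    def test_empty_region_list_empties_the_funnel(self):
        assert filter_step1_regions([_v(5)], []) == []

    def test_halfopen_boundary(self):
        region = _region(start=100, end=200)
        first_base = _v(101)   # 1-based first base inside [100, 200)
        one_before = _v(100)
        last_base = _v(200)
        one_after = _v(201)
        kept = filter_step1_regions([first_base, one_before, last_base, one_after], [region])
        assert kept == [first_base, last_base]


class TestCohortFilters:
    def test_variant_seen_in_one_control_dropped(self):
        v = _v(110)
        assert filter_step2_controls([v], {v.site_key()}) == []

    def test_absent_variant_kept(self):
        assert filter_step2_controls([_v(110)], set()) == [_v(110)]

    def test_allele_aware_matching(self):
        # same site, different alternate allele in controls: not a hit
        v = _v(110, alt="C")
        controls = {normalize_site("1", 110, "A", "G")}
        assert filter_step2_controls([v], controls) == [v]

    def test_indel_representation_drift_still_matches(self):
        # popdb wrote the deletion with an extra padded base
        v = Variant("1", 110, "AC", "A", {"case": 2})
        popdb = {normalize_site("1", 110, "ACC", "AC")}
        assert filter_step3_popdb([v], popdb) == []


class TestNonsynonymous:
    def test_synonymous_dropped_frameshift_kept(self):
        tx = _tx()
        # c.6 A>G: GCA->GCG, both Ala (c.6 is genomic 106 on this layout)
        syn = Variant("1", 106, "A", "G", {"case": 2})
        fs = Variant("1", 106, "AG", "A", {"case": 2})
        kept, calls = select_nonsynonymous([syn, fs], [tx])
        assert kept == [fs]
        assert calls[str(syn)][0].category == "synonymous"
        assert calls[str(fs)][0].category == "frameshift"


class TestFunnelAlgebra:
    def _fixture(self, seed=0):
        """50 variants with known cohort membership, on one long CDS."""
        rng = np.random.default_rng(seed)
        cds = "ATG" + "GCA" * 200 + "TAA"
        tx = TranscriptModel(
            "t", "g", "1", "+", [GenomicInterval("1", 1000, 1000 + len(cds))], cds
        )
        region = _region(start=1000, end=1300)
        variants, meta = [], []
        for i in range(50):
            pos = 1005 + i * 12  # every 4th codon's middle base (a C)
            gt = int(rng.choice([1, 2]))
            v = Variant("1", pos, "C", "T", {"case": gt})
            in_controls = bool(rng.random() < 0.4)
            in_popdb = bool(rng.random() < 0.4)
            variants.append(v)
            meta.append((v, gt, in_controls, in_popdb))
        control_sites = {v.site_key() for v, _, c, _ in meta if c}
        popdb_sites = {v.site_key() for v, _, _, p in meta if p}
        return tx, region, variants, meta, control_sites, popdb_sites

    def test_recessive_survivors_equal_bruteforce_set_algebra(self):
        tx, region, variants, meta, ctl, pop = self._fixture()
        got, funnel, _ = recessive_branch(variants, "case", [region], ctl, pop, [tx])
        expected = [
            v
            for v, gt, c, p in meta
            if gt == 2 and region.interval.contains_point(v.pos - 1) and not c and not p
        ]
        # every GCA->GTA change at these positions is missense, so the
        # non-synonymous step drops nothing extra
        assert [str(v) for v in got] == [str(v) for v in expected if True]
        counts = list(funnel.counts.values())
        assert counts == sorted(counts, reverse=True)

    def test_dominant_survivors_equal_bruteforce_set_algebra(self):
        tx, region, variants, meta, ctl, pop = self._fixture(seed=1)
        got, funnel, _ = dominant_branch(variants, "case", ctl, pop, [tx])
        expected = [v for v, gt, c, p in meta if gt == 1 and not c and not p]
        assert [str(v) for v in got] == [str(v) for v in expected]
        counts = list(funnel.counts.values())
        assert counts == sorted(counts, reverse=True)

    def test_control_and_popdb_steps_commute(self):
        tx, region, variants, meta, ctl, pop = self._fixture(seed=2)
        start = [v for v, gt, _, _ in meta if gt == 2]
        ab = filter_step3_popdb(filter_step2_controls(start, ctl), pop)
        ba = filter_step2_controls(filter_step3_popdb(start, pop), ctl)
        assert [str(v) for v in ab] == [str(v) for v in ba]

    def test_growing_stage_rejected(self):
        funnel = TriageFunnel()
        funnel.add("a", [_v(1), _v(2)])
        with pytest.raises(ValueError, match="grew"):
            funnel.add("b", [_v(1), _v(2), _v(3)])


class TestSeededTruth:
    def test_causal_deletion_survives_recessive_funnel(self):
        from mendelmap.roh import RohParams, detect_roh, exclude_parental, shared_case_regions
        from mendelmap.simulate import simulate_pedigree_genotypes
        from mendelmap.variants import collect_alt_sites

        cfg = small_config(seed=5)
        _, gm = simulate_pedigree_genotypes(cfg)
        tx = make_transcript_fixture(cfg)
        cohort = simulate_variant_cohort(cfg, tx)
        params = RohParams()
        runs = {c: detect_roh(gm, c, params) for c in ("CASE1", "CASE2")}
        regions = exclude_parental(
            shared_case_regions(runs, gm, ["CASE1", "CASE2"], params),
            gm, ["SIRE1", "DAM1"],
        )
        rec, funnel, _ = recessive_branch(
            cohort.case_variants, "CASE1", regions,
            collect_alt_sites(cohort.control_variants),
            {normalize_site(*s) for s in cohort.popdb_sites}, tx,
        )
        key = cohort.causal.site_key()
        assert any(v.site_key() == key for v in rec)

    def test_case_without_het_private_nonsyn_gives_empty_dominant_list(self):
        """With no seeded het-private variants the de novo branch ends empty."""
        cfg = small_config(n_background_coding_variants=0)
        tx = make_transcript_fixture(cfg)
        cohort = simulate_variant_cohort(cfg, tx)
        dom, funnel, _ = dominant_branch(cohort.case_variants, "CASE1", set(), set(), tx)
        assert dom == []
        counts = list(funnel.counts.values())
        assert counts == sorted(counts, reverse=True)
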