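"""HGVS naming, 3'-normalization, projection, truncation statistics."""

import numpy as np
import pytest

from mendelmap.consequence import (
    FRAMESHIFT,
    MISSENSE,
    STOP_GAIN,
    SYNONYMOUS,
    CdsDeletion,
    CdsSNV,
    annotate_variant,
    normalize_3prime,
    predict_protein_effect,
    truncation_stats,
)
from mendelmap.intervals import GenomicInterval
from mendelmap.transcripts import Domain, TranscriptModel
from mendelmap.variants import Variant

from .oracles import frameshift_oracle


class TestNormalize3Prime:
    def test_deletion_in_repeat_run_shifts_to_last_copy(self):
        # deleting any G of "AGGGT" gives "AGGT": reported at position 4
        for raw in (2, 3, 4):
            assert normalize_3prime("AGGGT", raw) == 4

    def test_no_identical_neighbor_unchanged(self):
        assert normalize_3prime("ACGT", 2) == 2

    def test_idempotent(self):
        pos = normalize_3prime("AAGGGTC", 3)
        assert normalize_3prime("AAGGGTC", pos) == pos

    @pytest.mark.parametrize("seed", range(8))
    def test_never_changes_the_edited_string(self, seed):
        rng = np.random.default_rng(seed)
        cds = "".join(rng.choice(list("ACGT"), size=60))
        raw = int(rng.integers(1, 60))
        shifted = normalize_3prime(cds, raw)
        assert cds[: raw - 1] + cds[raw:] == cds[: shifted - 1] + cds[shifted:]


class TestPredictProteinEffect:
    def test_deletion_making_first_shifted_codon_a_stop(self):
        # ATG AAA GTG ACC TAA; deleting c.7 (G) -> ATG AAA TGA ...: Val3
        # is replaced by an immediate stop
        call = predict_protein_effect("ATGAAAGTGACCTAA", CdsDeletion(7))
        assert call.category == FRAMESHIFT
        assert call.protein_hgvs == "p.Val3*"
        assert call.mutant_protein_length == 2
        assert call.stop_offset == 1

    def test_synonymous_third_position_snv(self):
        # GAA and GAG both encode Glu
        call = predict_protein_effect("ATGGAATAA", CdsSNV(6, "A", "G"))
        assert call.category == SYNONYMOUS
        assert call.mutant_protein_length == call.wildtype_protein_length

    def test_missense_ser_to_cys(self):
        # TCC (Ser) -> TGC (Cys), the shape of a c.#C>G missense call
        call = predict_protein_effect("ATGTCCAAATAA", CdsSNV(5, "C", "G"))
        assert call.category == MISSENSE
        assert call.protein_hgvs == "p.Ser2Cys"

    def test_stop_gain_snv(self):
        call = predict_protein_effect("ATGTACAAATAA", CdsSNV(6, "C", "A"))
        assert call.category == STOP_GAIN
        assert call.protein_hgvs == "p.Tyr2*"
        assert call.mutant_protein_length == 1

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            predict_protein_effect("ATGAAATAA", CdsSNV(4, "C", "G"))

    def test_no_stop_frameshift_reported_not_raised(self):
        # deleting c.4 of ATG AAA TAA: shifted tail has no stop codon
        call = predict_protein_effect("ATGAAATAA", CdsDeletion(6))
        assert call.category == FRAMESHIFT
        assert call.no_stop
        assert call.protein_hgvs.endswith("fs*?")

    def test_engineered_fs9_pattern(self):
        """1-bp deletion at the last base of codon k: first changed residue
        k+1, stop nine codons into the new frame."""
        # codon3 TCG(Ser), codon4 AGT(Ser); delete the G at c.9 -> Ser4Val
        body = "GCT" * 7  # new-frame codons read CTG (Leu): no early stop
        cds = "ATG" + "AAA" + "TCG" + "AGT" + body + "CTA" + "AAA" + "GGGTAA"
        call = predict_protein_effect(cds, CdsDeletion(9))
        assert call.protein_hgvs == "p.Ser4Valfs9*"
        assert call.stop_offset == 9
        assert call.mutant_protein_length == 4 + 9 - 2


class TestFixtureGeneAnnotation:
    """The two-transcript causal gene reproduces the published naming pattern."""

    def test_same_deletion_two_transcripts_two_names(self, fixture_transcripts):
        tx_a, tx_b = fixture_transcripts[:2]
        g = tx_a.cdna_to_genomic(1_881)
        anchor = tx_a.genomic_base(g - 1)
        v = Variant(tx_a.chrom, g - 1, anchor + "G", anchor, {})
        call_a = annotate_variant(v, tx_a)
        call_b = annotate_variant(v, tx_b)
        assert (call_a.cdna_hgvs, call_a.protein_hgvs) == ("c.1881delG", "p.Ser628Valfs9*")
        assert (call_b.cdna_hgvs, call_b.protein_hgvs) == ("c.1782delG", "p.Ser595Valfs9*")
        assert call_a.mutant_protein_length == 635
        assert call_a.wildtype_protein_length == 881
        assert call_a.fraction_lost == pytest.approx(246 / 881)
        assert call_a.lost_domains == ["MBB", "MOSC"]
        assert call_b.lost_domains == ["MBB", "MOSC"]


class TestProjection:
    def _plus_minus_pair(self):
        cds = "ATGCCTGGTTAA"  # 12 nt over two exons
        plus = TranscriptModel(
            "plus", "g1", "1", "+",
            [GenomicInterval("1", 100, 106), GenomicInterval("1", 200, 206)], cds,
        )
        minus = TranscriptModel(
            "minus", "g2", "1", "-",
            [GenomicInterval("1", 200, 206), GenomicInterval("1", 100, 106)], cds,
        )
        return plus, minus

    def test_first_cds_base_is_c1_plus_strand(self):
        plus, _ = self._plus_minus_pair()
        assert plus.genomic_to_cdna(101) == 1

    def test_minus_strand_cds_end_is_c1(self):
        _, minus = self._plus_minus_pair()
        # highest genomic base of the 5'-most exon
        assert minus.genomic_to_cdna(206) == 1
        assert minus.genomic_to_cdna(101) == 12

    @pytest.mark.parametrize("which", ["plus", "minus"])
    def test_roundtrip_both_strands(self, which):
        plus, minus = self._plus_minus_pair()
        tx = plus if which == "plus" else minus
        for c in range(1, 13):
            assert tx.genomic_to_cdna(tx.cdna_to_genomic(c)) == c

    def test_intronic_position_flagged_non_coding(self):
        plus, _ = self._plus_minus_pair()
        v = Variant("1", 150, "A", "C", {})
        assert annotate_variant(v, plus).category == "non-coding"

    def test_deletion_across_exon_boundary_flagged(self):
        plus, _ = self._plus_minus_pair()
        # deleted span runs from inside exon 1 across the intron into exon 2
        call = annotate_variant(Variant("1", 104, "A" * 98, "A", {}), plus)
        assert call.category == "split-span"
        # span ending inside the intron is likewise a boundary signal
        call = annotate_variant(Variant("1", 105, "ACG", "A", {}), plus)
        assert call.category == "split-span"


class TestTruncationStats:
    def _tx(self):
        # 9-residue protein with three domains
        cds = "ATG" + "GCT" * 8 + "TAA"
        return TranscriptModel(
            "t", "g", "1", "+", [GenomicInterval("1", 0, 30)], cds,
            [Domain("D1", 1, 3), Domain("D2", 4, 6), Domain("D3", 8, 9)],
        )

    def _call(self, mutant_length):
        from mendelmap.consequence import ConsequenceCall

        return ConsequenceCall(
            "t", FRAMESHIFT, mutant_protein_length=mutant_length,
            wildtype_protein_length=9,
        )

    def test_full_length_mutant_loses_nothing(self):
        frac, lost, truncated = truncation_stats(self._call(9), self._tx())
        assert frac == 0.0 and lost == [] and truncated == []

    def test_domain_ending_exactly_at_mutant_length_is_intact(self):
        frac, lost, truncated = truncation_stats(self._call(6), self._tx())
        assert lost == ["D3"]
        assert truncated == []
        assert frac == pytest.approx(3 / 9)

    def test_partial_domain_flagged_truncated(self):
        frac, lost, truncated = truncation_stats(self._call(5), self._tx())
        assert lost == ["D3"]
        assert truncated == ["D2"]
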