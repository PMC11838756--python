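"""Fusion integration, enhancer hijacking, ITD tiering and PTD validation."""

import numpy as np
import pytest

from amldx.catalog import ExonModel
from amldx.fusion import (
    FusionThresholds,
    calls_from_orphan_transcripts,
    classify_enhancer_hijacking,
    integrate_fusion_evidence,
    robust_z,
    tier_flt3_itd,
    validate_kmt2a_ptd,
)
from amldx.types import CnvSegment, ExpressionProfile, FusionTranscript, ItdObservation

from conftest import make_sv


def brute_force_in_frame(lengths5, exon5, lengths3, exon3) -> bool:
    """Walk the fused coding sequence codon by codon (independent oracle)."""
    fused = sum(lengths5[:exon5]) + sum(lengths3[exon3 - 1:])
    # frame is preserved iff the acceptor exon starts at the same codon
    # offset it would have in the native transcript
    donor_offset = sum(lengths5[:exon5]) % 3
    native_offset = sum(lengths3[: exon3 - 1]) % 3
    assert fused > 0
    return donor_offset == native_offset


class TestInFrameArithmetic:
    def test_matches_brute_force_on_randomized_toy_models(self, rng):
        for _ in range(60):
            n5, n3 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            lengths5 = [int(x) for x in rng.integers(20, 200, n5)]
            lengths3 = [int(x) for x in rng.integers(20, 200, n3)]
            model = ExonModel({"A": lengths5, "B": lengths3})
            for e5 in range(1, n5 + 1):          # exhaustive junction set
                for e3 in range(1, n3 + 1):
                    assert model.junction_in_frame("A", e5, "B", e3) == \
                        brute_force_in_frame(lengths5, e5, lengths3, e3)

    def test_phase_multiple_of_three_in_frame_and_off_by_one_not(self):
        model = ExonModel({"A": [9, 9], "B": [9, 9], "C": [10, 9]})
        assert model.junction_in_frame("A", 1, "B", 2)
        assert not model.junction_in_frame("C", 1, "B", 2)


class TestIntegrateFusionEvidence:
    def test_single_read_in_frame_transcript_called_with_confirmation_flag(
            self, exon_model):
        # KMT2A intron 11 breakpoint; one read of KMT2A ex11 -> ELL ex2
        sv = make_sv("KMT2A", "ELL", "chr11", 118_470_000, "chr19",
                     18_550_000, region1="intron 11")
        tx = FusionTranscript("KMT2A", 11, "ELL", 2, junction_reads=1)
        call = integrate_fusion_evidence(sv, [tx], exon_model=exon_model)
        assert call.mechanism == "chimeric_fusion"
        assert call.confirmation_needed
        assert call.evidence == {"WGS_SV", "WTS_transcript"}

    def test_sv_without_transcript_stays_unconfirmed(self, exon_model):
        sv = make_sv("KMT2A", "ELL", region1="exon 9")
        call = integrate_fusion_evidence(sv, [], exon_model=exon_model)
        assert call.mechanism == "unconfirmed" and call.confirmation_needed

    def test_adequate_junction_reads_need_no_confirmation(self, exon_model):
        sv = make_sv("CBFB", "MYH11", region1="intron 5")
        tx = FusionTranscript("CBFB", 5, "MYH11", 12, junction_reads=20)
        call = integrate_fusion_evidence(sv, [tx], exon_model=exon_model)
        assert call.mechanism == "chimeric_fusion" and not call.confirmation_needed

    def test_breakpoint_incompatible_transcript_not_matched(self, exon_model):
        sv = make_sv("KMT2A", "ELL", region1="intron 11")
        tx = FusionTranscript("KMT2A", 5, "ELL", 2, junction_reads=10)
        call = integrate_fusion_evidence(sv, [tx], exon_model=exon_model)
        assert call.mechanism == "unconfirmed"

    def test_gene_missing_from_exon_model_unassessable(self, exon_model):
        sv = make_sv("NOVELGENE", "ELL")
        tx = FusionTranscript("NOVELGENE", 2, "ELL", 2, junction_reads=10)
        call = integrate_fusion_evidence(sv, [tx], exon_model=exon_model)
        assert call.mechanism == "unconfirmed"
        assert any("exon model" in r for r in call.reasons)


class TestEnhancerHijacking:
    BASELINE = {"MECOM": np.full(40, 5.0) + np.linspace(-0.5, 0.5, 40),
                "BCL11B": np.full(40, 5.0) + np.linspace(-0.5, 0.5, 40)}

    def test_mecom_breakpoint_upstream_with_overexpression_called(self):
        sv = make_sv("MECOM", "GATA2", consequence="possible_enhancer_hijack",
                     offset1=-3_800)
        expr = ExpressionProfile({"MECOM": 9.2})
        call = classify_enhancer_hijacking(sv, expr, self.BASELINE)
        assert call.mechanism == "enhancer_hijacking"
        assert call.target_gene == "MECOM"
        assert call.evidence == {"WGS_SV", "WTS_overexpression"}
        assert not call.confirmation_needed

    def test_proximity_without_overexpression_unconfirmed(self):
        # t(5;14)-like case: BCL11B expression comparable to baseline
        sv = make_sv("BCL11B", "TLX3", consequence="possible_enhancer_hijack",
                     offset1=-50_000)
        expr = ExpressionProfile({"BCL11B": 5.1})
        call = classify_enhancer_hijacking(sv, expr, self.BASELINE)
        assert call.mechanism == "unconfirmed"
        assert any("comparable to baseline" in r for r in call.reasons)

    def test_breakpoint_outside_window_unconfirmed_even_with_overexpression(self):
        sv = make_sv("MECOM", "GATA2", consequence="possible_enhancer_hijack",
                     offset1=-400_000)
        expr = ExpressionProfile({"MECOM": 9.2})
        call = classify_enhancer_hijacking(sv, expr, self.BASELINE)
        assert call.mechanism == "unconfirmed"
        assert any("outside window" in r for r in call.reasons)

    def test_downstream_window_is_shorter(self):
        expr = ExpressionProfile({"MECOM": 9.2})
        near = make_sv("MECOM", "CDK6", consequence="possible_enhancer_hijack",
                       offset1=140_000)
        far = make_sv("MECOM", "CDK6", consequence="possible_enhancer_hijack",
                      offset1=200_000)
        assert classify_enhancer_hijacking(near, expr, self.BASELINE).mechanism \
            == "enhancer_hijacking"
        assert classify_enhancer_hijacking(far, expr, self.BASELINE).mechanism \
            == "unconfirmed"

    def test_missing_expression_unassessable(self):
        sv = make_sv("MECOM", "GATA2", consequence="possible_enhancer_hijack",
                     offset1=-3_800)
        call = classify_enhancer_hijacking(sv, ExpressionProfile({}), self.BASELINE)
        assert call.mechanism == "unconfirmed"
        assert any("unassessable" in r for r in call.reasons)

    def test_robust_z_uses_median_and_mad(self):
        base = np.array([3.0, 4.0, 5.0, 6.0, 7.0])  # median 5, MAD 1
        z = robust_z(5.0 + 1.4826, base)  # one MAD-scaled unit above median
        assert z == pytest.approx(1.0, rel=1e-6)


class TestFlt3ItdTiers:
    @pytest.mark.parametrize(
        "wgs,wts,tier,flag",
        [
            (8, 12, "confirmed", False),
            (5, 5, "confirmed", False),
            (0, 9, "borderline", True),   # WTS-strong only
            (9, 2, "borderline", True),
            (2, 3, "weak", True),
        ],
    )
    def test_tiering_pattern(self, wgs, wts, tier, flag):
        call = tier_flt3_itd(ItdObservation("FLT3", wgs, wts))
        assert call.tier == tier
        assert call.orthogonal_confirmation_recommended is flag

    def test_no_evidence_on_either_platform_gives_no_call(self):
        assert tier_flt3_itd(ItdObservation("FLT3", 0, 0)) is None


class TestKmt2aPtd:
    DUP = CnvSegment("chr11", 118_446_000, 118_454_000, 0.45, copy_number=3,
                     softclip_left=6, softclip_right=5, gene="KMT2A")

    def test_in_frame_self_fusion_ex8_to_ex2_validates(self, exon_model):
        tx = FusionTranscript("KMT2A", 8, "KMT2A", 2, junction_reads=7)
        call = validate_kmt2a_ptd(self.DUP, [tx], exon_model)
        assert call.status == "validated" and not call.confirmation_recommended

    @pytest.mark.parametrize("e5,e3", [(7, 2), (7, 3), (8, 4)])
    def test_all_documented_exon_combinations_validate(self, exon_model, e5, e3):
        tx = FusionTranscript("KMT2A", e5, "KMT2A", e3, junction_reads=4)
        assert validate_kmt2a_ptd(self.DUP, [tx], exon_model).status == "validated"

    def test_no_self_fusion_transcript_is_dna_only(self, exon_model):
        call = validate_kmt2a_ptd(self.DUP, [], exon_model)
        assert call.status == "dna_only" and call.confirmation_recommended

    def test_acceptor_exon_outside_allowed_set_rejected(self, exon_model):
        tx = FusionTranscript("KMT2A", 8, "KMT2A", 5, junction_reads=7)
        call = validate_kmt2a_ptd(self.DUP, [tx], exon_model)
        assert call.status == "rejected" and call.confirmation_recommended


class TestOrphanTranscripts:
    def test_rna_only_in_frame_fusion_called(self, exon_model):
        tx = FusionTranscript("CBFB", 5, "MYH11", 12, junction_reads=9)
        (call,) = calls_from_orphan_transcripts([tx], [], exon_model)
        assert call.mechanism == "chimeric_fusion"
        assert call.evidence == {"WTS_transcript"} and call.sv is None

    def test_self_fusions_and_matched_transcripts_excluded(self, exon_model):
        ptd = FusionTranscript("KMT2A", 8, "KMT2A", 2, junction_reads=9)
        matched = FusionTranscript("CBFB", 5, "MYH11", 12, junction_reads=9)
        sv = make_sv("CBFB", "MYH11")
        assert calls_from_orphan_transcripts([ptd, matched], [sv], exon_model) == []

    def test_mechanisms_mutually_exclusive_per_call(self, exon_model):
        tx = FusionTranscript("CBFB", 5, "MYH11", 12, junction_reads=9)
        (call,) = calls_from_orphan_transcripts([tx], [], exon_model)
        assert call.mechanism in ("chimeric_fusion", "enhancer_hijacking",
                                  "unconfirmed")
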