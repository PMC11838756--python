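"""Subtype assignment hierarchy, centroid corroboration and cooperating
lesion annotation."""

import numpy as np
import pytest

from amldx import catalog as cat
from amldx.classify import (
    TIER_ORDER,
    expression_centroid_corroboration,
    flag_actionable_cooperating,
    platform_view,
    run_case,
)
from amldx.synthetic import cohort_expression_baseline, generate_cohort
from amldx.types import CaseBundle, CnvSegment, ExpressionProfile, FusionTranscript

from conftest import make_sv, make_variant


def _case(subtype, seed=0, **kw):
    bundles, truths = generate_cohort(
        1, subtype_mix={subtype: 1.0}, seed=seed, noise_free=True, **kw
    )
    return bundles[0], truths[0]


@pytest.fixture(scope="module")
def ctx(subtype_catalog, exon_model):
    bundles, _ = generate_cohort(60, seed=33, noise_free=True)
    return {
        "catalog": subtype_catalog,
        "exon_model": exon_model,
        "baseline": cohort_expression_baseline(bundles),
    }


def _run(bundle, ctx):
    return run_case(bundle, catalog=ctx["catalog"], exon_model=ctx["exon_model"],
                    expression_baseline=ctx["baseline"])


class TestHierarchy:
    def test_dual_fusion_case_keeps_both_with_catalog_rank_primary(self, ctx):
        bundle, _ = _case("CBFB::MYH11", seed=4)
        # add a second, lower-ranked in-frame fusion (KIT partner)
        bundle.sv_calls.append(make_sv("TEC", "MLLT10", region1="intron 10"))
        bundle.fusion_transcripts.append(
            FusionTranscript("TEC", 10, "MLLT10", 9, junction_reads=8))
        call = _run(bundle, ctx).subtype_call
        assert call.subtype == "CBFB::MYH11"
        assert call.tier == "class_defining_fusion"

    def test_cebpa_with_ase_classified_with_supporting_flag(self, ctx):
        bundle = CaseBundle(
            case_id="CEBPA1", blast_pct=70, tumor_purity=0.7,
            snv_indel_calls=[make_variant(
                gene="CEBPA", contig="chr19", pos=33_300_000, vclass="indel",
                WGS=(0.35, 80), WTS=(0.97, 100))],
            expression=ExpressionProfile(
                dict(ctx["catalog"].centroids["CEBPA"])),
        )
        call = _run(bundle, ctx).subtype_call
        assert call.subtype == "CEBPA"
        assert call.tier == "class_defining_mutation"
        assert any("allele-specific" in f for f in call.confirmation_flags)
        assert call.expression_corroboration == "concordant"

    def test_biallelic_tp53_with_adverse_lscnvs_is_aml_mr(self, ctx):
        bundle, truth = _case("AML-MR", seed=8)
        call = _run(bundle, ctx).subtype_call
        assert call.subtype == "AML-MR" and call.tier == "AML_MR"
        assert "TP53" in call.drivers

    def test_aml_mr_vetoed_by_any_potential_driver(self, ctx):
        bundle, _ = _case("AML-MR", seed=8)
        bundle.sv_calls.append(make_sv("TEC", "MLLT10", region1="intron 10"))
        bundle.fusion_transcripts.append(
            FusionTranscript("TEC", 10, "MLLT10", 9, junction_reads=8))
        call = _run(bundle, ctx).subtype_call
        assert call.tier == "novel_rare_fusion"

    def test_down_syndrome_gata1_tier_first(self, ctx):
        bundle, _ = _case("DS-GATA1", seed=2)
        call = _run(bundle, ctx).subtype_call
        assert call.subtype == "DS-GATA1" and call.tier == "DS_GATA1"

    def test_enhancer_hijack_mecom_is_class_defining(self, ctx):
        bundle, _ = _case("MECOM-r", seed=3)
        call = _run(bundle, ctx).subtype_call
        assert call.subtype == "MECOM-r"
        assert call.tier == "class_defining_fusion"

    def test_every_case_gets_exactly_one_tier(self, ctx):
        bundles, _ = generate_cohort(40, seed=77, noise_free=True)
        baseline = cohort_expression_baseline(bundles)
        for b in bundles:
            call = run_case(b, catalog=ctx["catalog"],
                            exon_model=ctx["exon_model"],
                            expression_baseline=baseline).subtype_call
            assert call.tier in TIER_ORDER

    def test_unknown_reachable_only_without_drivers(self, ctx):
        bundle, _ = _case("unknown", seed=12)
        call = _run(bundle, ctx).subtype_call
        assert call.subtype == "unknown" and call.tier == "unknown"


class TestCentroidCorroboration:
    def test_runx1_cbfa2t3_groups_with_runx1t1_profile(self, subtype_catalog):
        # the grouping table treats RUNX1::CBFA2T3 as RUNX1::RUNX1T1-like
        centroid = subtype_catalog.centroids["RUNX1::RUNX1T1"]
        expr = ExpressionProfile({g: v + 0.05 for g, v in centroid.items()})
        status, score, nearest = expression_centroid_corroboration(
            expr, "RUNX1::CBFA2T3", subtype_catalog)
        assert status == "concordant" and nearest == "RUNX1::RUNX1T1"

    def test_exact_centroid_has_correlation_one(self, subtype_catalog):
        expr = ExpressionProfile(dict(subtype_catalog.centroids["NPM1"]))
        status, score, nearest = expression_centroid_corroboration(
            expr, "NPM1", subtype_catalog)
        assert status == "concordant"
        assert score == pytest.approx(1.0)

    def test_subtype_without_centroid_is_unavailable(self, subtype_catalog):
        rng = np.random.default_rng(5)
        expr = ExpressionProfile({
            g: float(rng.normal(5, 2)) for g in subtype_catalog.signature_genes})
        status, score, nearest = expression_centroid_corroboration(
            expr, "RUNX1::ZEB2", subtype_catalog)
        assert status == "unavailable"
        assert score is None or score < 0.9  # far from every centroid

    def test_wrong_profile_is_discordant(self, subtype_catalog):
        expr = ExpressionProfile(dict(subtype_catalog.centroids["NPM1"]))
        status, _, nearest = expression_centroid_corroboration(
            expr, "CEBPA", subtype_catalog)
        assert status == "discordant" and nearest == "NPM1"


class TestCooperating:
    TABLE = cat.default_relevance_table()

    def test_npm1_case_deletions_tagged_risk(self):
        out = dict(flag_actionable_cooperating(
            ["del(5q)", "-13/del(13q)"], self.TABLE))
        assert out["del(5q)"] == ["risk"]
        assert out["-13/del(13q)"] == ["risk"]

    def test_kit_exon17_risk_and_targetable(self):
        out = dict(flag_actionable_cooperating(["KIT exon 17"], self.TABLE))
        assert set(out["KIT exon 17"]) == {"risk", "targetable"}

    def test_unlisted_lesion_has_no_relevance(self):
        ((les, tags),) = flag_actionable_cooperating(["XYZ"], self.TABLE)
        assert les == "XYZ" and tags == []

    def test_cohort_cases_annotate_itds(self, ctx):
        bundles, truths = generate_cohort(
            80, seed=5, noise_free=True,
            coop_rates={"FLT3-ITD": 1.0})
        baseline = cohort_expression_baseline(bundles)
        res = run_case(bundles[0], catalog=ctx["catalog"],
                       exon_model=ctx["exon_model"],
                       expression_baseline=baseline)
        labels = [les for les, _ in res.subtype_call.cooperating]
        assert "FLT3-ITD" in labels


class TestPlatformViews:
    def test_wgs_view_strips_rna_evidence(self, small_cohort):
        bundles, _ = small_cohort
        v = platform_view(bundles[0], "WGS")
        assert v.fusion_transcripts == [] and v.expression.values == {}
        assert all("WTS" not in x.per_platform for x in v.snv_indel_calls)

    def test_wts_view_strips_dna_evidence(self, small_cohort):
        bundles, _ = small_cohort
        v = platform_view(bundles[0], "WTS")
        assert v.sv_calls == [] and v.cnv_segments == []
        assert all(set(x.per_platform) == {"WTS"} for x in v.snv_indel_calls)

    def test_integrated_view_is_identity(self, small_cohort):
        bundles, _ = small_cohort
        assert platform_view(bundles[0], "integrated") is bundles[0]
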