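"""Statistical and structural properties of the synthetic cohort generator."""

import numpy as np
import pytest
from scipy import stats

from amldx.synthetic import (
    DEFAULT_PLATFORM_MODELS,
    PlatformModel,
    colo829_lscnv_truth,
    colo829_variant_fixture,
    generate_cohort,
    generate_dilution_series,
    simulate_karyotype_observation,
)
from amldx.types import GroundTruth


class TestDilutionSeries:
    def test_expected_vaf_is_product_of_original_and_fraction(self):
        bundles = generate_dilution_series(
            [("G1", 0.70, "SNV"), ("G2", 0.29, "SNV")],
            tumor_fractions=[0.25], seed=0,
        )
        # sampled VAFs scatter binomially around the diluted expectation
        (b,) = bundles
        v70, v29 = b.snv_indel_calls
        assert v70.gene == "G1"
        for v, expected in ((v70, 0.175), (v29, 0.0725)):
            o = v.per_platform["WES"]  # deepest platform here
            se = np.sqrt(expected * (1 - expected) / o.total_reads)
            assert abs(o.vaf - expected) < 4 * se + 1 / o.total_reads

    def test_fraction_one_leaves_expectation_unchanged(self):
        bundles = generate_dilution_series([("G", 0.5, "SNV")],
                                           tumor_fractions=[1.0], seed=3)
        o = bundles[0].snv_indel_calls[0].per_platform["WES"]
        se = np.sqrt(0.25 / o.total_reads)
        assert abs(o.vaf - 0.5) < 4 * se

    def test_fraction_zero_rejected(self):
        with pytest.raises(ValueError):
            generate_dilution_series(tumor_fractions=[0.0])

    def test_default_fixture_is_twelve_variants_nine_snv_three_indel(self):
        fixture = colo829_variant_fixture()
        assert len(fixture) == 12
        classes = [c for _, _, c in fixture]
        assert classes.count("SNV") == 9 and classes.count("indel") == 3
        vafs = [v for _, v, _ in fixture]
        assert min(vafs) == pytest.approx(0.29) and max(vafs) == pytest.approx(0.70)

    def test_mean_observed_vaf_monotone_in_tumor_fraction(self):
        fractions = [0.2, 0.4, 0.6, 0.8, 1.0]
        bundles = generate_dilution_series(tumor_fractions=fractions, seed=9)
        means = [
            np.mean([v.per_platform["WES"].vaf for v in b.snv_indel_calls])
            for b in bundles
        ]
        assert all(b > a for a, b in zip(means, means[1:]))


class TestPlatformModel:
    def test_mean_observed_vaf_matches_binomial_expectation(self, rng):
        # clonal driver at purity 0.5: expected heterozygous VAF 0.25
        model = DEFAULT_PLATFORM_MODELS["WGS"]
        obs = [model.sample_observation(rng, 0.25) for _ in range(2000)]
        vafs = np.array([o.vaf for o in obs])
        se = vafs.std(ddof=1) / np.sqrt(len(vafs))
        assert abs(vafs.mean() - 0.25) < 3 * se

    def test_depth_centers_on_platform_mean(self, rng):
        model = PlatformModel("WGS", 61.0)
        depths = np.array([model.sample_depth(rng) for _ in range(3000)])
        assert abs(depths.mean() - 61.0) < 3 * depths.std(ddof=1) / np.sqrt(3000)


class TestKaryotypeObserver:
    def test_event_below_banding_resolution_invisible(self):
        truth = GroundTruth("c", "unknown", true_driver_lesions=[
            {"kind": "lscnv", "label": "del8Mb", "contig": "chr7",
             "start": 0, "end": 8_000_000, "delta": -1, "clone_fraction": 1.0}
        ])
        obs = simulate_karyotype_observation(truth, seed=0)
        assert obs.visible_events == []

    def test_clonal_trisomy_seen_in_all_metaphases(self):
        truth = GroundTruth("c", "unknown", true_driver_lesions=[
            {"kind": "lscnv", "label": "+8", "contig": "chr8",
             "start": 0, "end": 145_100_000, "delta": 1, "clone_fraction": 1.0}
        ])
        obs = simulate_karyotype_observation(truth, seed=0)
        assert len(obs.visible_events) == 1
        event, n = obs.visible_events[0]
        assert event.kind == "gain" and n == 20

    def test_subclonal_detection_matches_binomial_closed_form(self):
        clone, metaphases, min_cells = 0.3, 20, 2
        truth = GroundTruth("c", "unknown", true_driver_lesions=[
            {"kind": "lscnv", "label": "gain30", "contig": "chr3",
             "start": 0, "end": 30_000_000, "delta": 1, "clone_fraction": clone}
        ])
        n_trials = 4000
        hits = sum(
            bool(simulate_karyotype_observation(truth, seed=s).visible_events)
            for s in range(n_trials)
        )
        expected = 1.0 - stats.binom.cdf(min_cells - 1, metaphases, clone)
        se = np.sqrt(expected * (1 - expected) / n_trials)
        assert abs(hits / n_trials - expected) < 4 * se

    def test_cryptic_banding_event_invisible(self):
        truth = GroundTruth("c", "unknown", true_driver_lesions=[
            {"kind": "lscnv", "label": "cryptic", "contig": "chr7",
             "start": 0, "end": 12_000_000, "delta": 1, "clone_fraction": 1.0,
             "cryptic_banding": True}
        ])
        assert simulate_karyotype_observation(truth, seed=1).visible_events == []


class TestGenerateCohort:
    def test_identical_seed_gives_identical_cohort(self):
        a = generate_cohort(15, seed=42)
        b = generate_cohort(15, seed=42)
        assert a == b

    def test_different_seed_gives_different_cohort(self):
        a, _ = generate_cohort(15, seed=42)
        b, _ = generate_cohort(15, seed=43)
        assert a != b

    def test_zero_cases(self):
        with pytest.raises(ValueError):
            generate_cohort(0)
        assert generate_cohort(0, allow_empty=True) == ([], [])

    def test_unknown_subtype_label_rejected(self):
        with pytest.raises(ValueError, match="unknown subtype"):
            generate_cohort(3, subtype_mix={"NOT_A_SUBTYPE": 1.0})

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            generate_cohort(3, subtype_mix={"NPM1": 0.5})

    def test_planted_lesion_conservation(self, small_cohort):
        """Every truth lesion has a corresponding platform observation."""
        bundles, truths = small_cohort
        for b, t in zip(bundles, truths):
            keys = {v.key for v in b.snv_indel_calls}
            for les in t.true_driver_lesions + t.true_cooperating_lesions:
                kind = les["kind"]
                if kind == "mutation":
                    assert tuple(les["key"]) in keys
                elif kind == "fusion":
                    has_sv = any(
                        (s.gene1, s.gene2) == (les["gene5"], les["gene3"])
                        for s in b.sv_calls
                    )
                    has_tx = any(
                        (x.gene5, x.gene3) == (les["gene5"], les["gene3"])
                        for x in b.fusion_transcripts
                    )
                    assert (has_sv or not les["visible_wgs"]) and (
                        has_tx or not les["visible_wts"])
                    assert has_sv or has_tx
                elif kind == "enhancer_hijack":
                    assert any(s.gene1 == les["target"] for s in b.sv_calls)
                elif kind == "lscnv":
                    assert any(
                        s.contig == les["contig"] and s.start == les["start"]
                        for s in b.cnv_segments
                    )
                elif kind == "itd":
                    assert b.itd_observations
                elif kind in ("focal_cnv", "ptd"):
                    assert any(s.gene == les["gene"] for s in b.cnv_segments)

    def test_fusion_case_bundle_structure(self):
        bundles, truths = generate_cohort(
            1, subtype_mix={"RUNX1::RUNX1T1": 1.0}, seed=5
        )
        (b,), (t,) = bundles, truths
        assert t.true_subtype == "RUNX1::RUNX1T1"
        assert len(b.sv_calls) == 1
        assert any(
            (x.gene5, x.gene3) == ("RUNX1", "RUNX1T1") for x in b.fusion_transcripts
        )

    def test_enhancer_hijack_case_has_no_transcript_but_overexpression(self):
        bundles, _ = generate_cohort(4, subtype_mix={"MECOM-r": 1.0}, seed=6)
        for b in bundles:
            assert not any(t.gene3 == "MECOM" for t in b.fusion_transcripts)
            assert b.expression.get("MECOM") > 7.0  # ~16x over baseline

    def test_colo829_lscnv_truth_spans_expected_chromosomes(self):
        events = colo829_lscnv_truth()
        assert {e["contig"] for e in events} == {
            "chr1", "chr2", "chr3", "chr7", "chr12", "chr19"}
        assert all(e["delta_copies"] in (1, 2) for e in events)
        assert all(e["end_mb"] - e["start_mb"] > 5 for e in events)
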