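"""Focal CNV validation, LS-CNV merging, detectability simulation and
AML-MR abnormality mapping."""

import numpy as np
import pytest

from amldx.cnv import (
    CnvThresholds,
    LscnvNoiseModel,
    call_large_scale_cnv,
    map_aml_mr_abnormalities,
    simulate_lscnv_detectability,
    size_bin,
    validate_focal_cnv,
)
from amldx.synthetic import colo829_lscnv_truth
from amldx.types import CnvSegment


def seg(contig="chr7", start=0, end=1_000_000, log2=-0.8, sc_left=3, sc_right=3):
    return CnvSegment(contig=contig, start=start, end=end, log2_ratio=log2,
                      softclip_left=sc_left, softclip_right=sc_right)


class TestFocalDualEvidence:
    def test_depth_plus_bilateral_clips_meets_criteria(self):
        s = CnvSegment("chr11", 119_287_000, 119_293_000, -0.9,
                       softclip_left=5, softclip_right=4, gene="CBL")
        assert validate_focal_cnv(s).diagnostic_status == "meets_criteria"
        assert size_bin(s) == "<=10kb"

    def test_depth_without_softclips_rejected(self):
        s = seg(sc_left=0, sc_right=0)
        assert validate_focal_cnv(s).diagnostic_status == "rejected"

    def test_one_sided_clips_rejected(self):
        s = seg(sc_left=5, sc_right=1)
        assert validate_focal_cnv(s).diagnostic_status == "rejected"

    def test_weak_depth_signal_rejected_despite_clips(self):
        s = seg(log2=-0.1)
        assert validate_focal_cnv(s).diagnostic_status == "rejected"

    def test_no_focal_cnv_without_softclips_is_ever_valid(self, rng):
        for _ in range(200):
            s = seg(
                end=int(rng.integers(1_000, 4_000_000)),
                log2=float(rng.normal(0, 1)),
                sc_left=int(rng.integers(0, 2)), sc_right=int(rng.integers(0, 8)),
            )
            if s.softclip_left < 2 or s.softclip_right < 2:
                assert validate_focal_cnv(s).diagnostic_status == "rejected"

    def test_large_scale_segment_not_accepted(self):
        with pytest.raises(ValueError, match="not focal"):
            validate_focal_cnv(seg(end=6_000_000))


def brute_force_merge(segments, gap):
    """Boolean-array interval-merge oracle at 10 kb resolution."""
    unit = 10_000
    out = []
    for contig in sorted({s.contig for s in segments}):
        for direction in ("gain", "loss"):
            segs = [s for s in segments if s.contig == contig
                    and s.direction == direction and s.log2_ratio != 0]
            if not segs:
                continue
            hi = max(s.end for s in segs) // unit + gap // unit + 2
            mask = np.zeros(hi, dtype=bool)
            for s in segs:
                mask[s.start // unit: s.end // unit] = True
            # close gaps <= gap
            runs, start = [], None
            for i, m in enumerate(mask):
                if m and start is None:
                    start = i
                elif not m and start is not None:
                    runs.append((start, i))
                    start = None
            if start is not None:
                runs.append((start, len(mask)))
            merged = [list(runs[0])]
            for a, b in runs[1:]:
                if (a - merged[-1][1]) * unit <= gap:
                    merged[-1][1] = b
                else:
                    merged.append([a, b])
            out += [(contig, direction, a * unit, b * unit) for a, b in merged]
    return sorted(out)


class TestLargeScaleMerge:
    def test_two_fragments_across_small_gap_merge_to_one_lscnv(self):
        a = seg("chr2", 0, 4_000_000, 0.3)
        b = seg("chr2", 4_500_000, 8_500_000, 0.3)
        (m,) = call_large_scale_cnv([a, b])
        assert (m.start, m.end) == (0, 8_500_000)
        assert m.size_class == "large_scale"
        assert m.diagnostic_status == "meets_criteria"

    def test_single_3mb_deletion_stays_focal(self):
        assert call_large_scale_cnv([seg("chr5", 0, 3_000_000, -0.5)]) == []

    def test_opposite_directions_do_not_merge(self):
        a = seg("chr2", 0, 4_000_000, 0.3)
        b = seg("chr2", 4_500_000, 8_500_000, -0.3)
        assert call_large_scale_cnv([a, b]) == []

    def test_contradictory_overlap_raises(self):
        a = seg("chr2", 0, 4_000_000, 0.3)
        b = seg("chr2", 3_000_000, 8_000_000, -0.3)
        with pytest.raises(ValueError, match="contradictory"):
            call_large_scale_cnv([a, b])

    def test_merge_matches_interval_oracle_and_is_order_insensitive(self, rng):
        for _ in range(40):
            segments = []
            for _ in range(int(rng.integers(2, 9))):
                start = int(rng.integers(0, 3000)) * 10_000
                length = int(rng.integers(30, 900)) * 10_000
                segments.append(seg(
                    contig=str(rng.choice(["chr1", "chr2"])),
                    start=start, end=start + length,
                    log2=float(rng.choice([0.4, -0.4])),
                ))
            try:
                merged = call_large_scale_cnv(segments)
            except ValueError:
                continue  # contradictory overlap: oracle undefined
            expected = [
                e for e in brute_force_merge(segments, 1_000_000)
                if e[3] - e[2] > 5_000_000
            ]
            got = sorted((m.contig, m.direction, m.start, m.end) for m in merged)
            assert got == expected
            shuffled = list(segments)
            rng.shuffle(shuffled)
            reshuffled = sorted(
                (m.contig, m.direction, m.start, m.end)
                for m in call_large_scale_cnv(shuffled)
            )
            assert reshuffled == got

    def test_merge_is_idempotent(self):
        a = seg("chr2", 0, 4_000_000, 0.3)
        b = seg("chr2", 4_500_000, 8_500_000, 0.3)
        once = call_large_scale_cnv([a, b])
        twice = call_large_scale_cnv(once)
        assert [(m.contig, m.start, m.end) for m in twice] == \
            [(m.contig, m.start, m.end) for m in once]


class TestDetectability:
    def test_full_purity_zero_noise_recovers_everything_exactly(self):
        noise = LscnvNoiseModel(white_sd=1e-9, wave_sd=0.0)
        s = simulate_lscnv_detectability(colo829_lscnv_truth(), 1.0, noise, seed=0)
        assert s.all_detected
        assert all(e.recovered_fraction == pytest.approx(1.0, abs=0.02)
                   for e in s.events)

    def test_recovery_monotone_in_purity_for_fixed_noise(self):
        grid = [0.2, 0.25, 0.3, 0.4, 0.6, 1.0]
        for s in range(3):
            rec = [simulate_lscnv_detectability(colo829_lscnv_truth(), p, seed=s)
                   .mean_recovered for p in grid]
            for a, b in zip(rec, rec[1:]):
                assert b >= a - 0.02  # small tolerance for boundary re-splits

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValueError):
            simulate_lscnv_detectability(colo829_lscnv_truth(), 0.0)


class TestAmlMrMapping:
    def test_segmental_7q_deletion_maps_to_del7q(self):
        (f,) = map_aml_mr_abnormalities([seg("chr7", 80_000_000, 140_000_000,
                                             -0.4, 0, 0)])
        assert f.label == "-7/del(7q)"

    def test_gain_in_7q_is_direction_mismatch(self):
        assert map_aml_mr_abnormalities([seg("chr7", 80_000_000, 140_000_000,
                                             0.4, 0, 0)]) == []

    def test_near_whole_chromosome_5_loss_is_monosomy_equivalent(self):
        (f,) = map_aml_mr_abnormalities([seg("chr5", 2_000_000, 178_000_000,
                                             -0.4, 0, 0)])
        assert f.label == "-5"

    def test_11q_deletion_and_non_mr_chromosome(self):
        (f,) = map_aml_mr_abnormalities([seg("chr11", 80_000_000, 130_000_000,
                                             -0.4, 0, 0)])
        assert f.label == "del(11q)"
        assert map_aml_mr_abnormalities([seg("chr8", 0, 145_000_000, 0.4, 0, 0)]) == []
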