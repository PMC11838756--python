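"""Copy-number variant validation, large-scale CNV calling, and the
purity-dependent limit-of-detection simulation.

Focal CNVs (< 5 Mb) require dual WGS evidence: a read-depth shift *and*
boundary soft-clipped reads on both sides. Large-scale CNVs (LS-CNV, > 5 Mb)
are assembled by merging adjacent same-direction segments; events that the
segmentation can only reconstruct partially are marked fragmented and are not
reportable as the full event.

The detectability simulation reproduces the qualitative behaviour of a CNV
pipeline on tumor/normal DNA mixtures: a one-copy gain at tumor fraction p
shifts the expected log2 ratio by log2((2 + p)/2), which approaches the
diagnostic ratio threshold as p drops, so events dissolve into fragments of
which only a portion meets diagnostic criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .catalog import CENTROMERE_MB, GENOME_MB, default_aml_mr_table
from .types import CnvSegment

__all__ = [
    "CnvThresholds",
    "LscnvNoiseModel",
    "EventRecovery",
    "DetectionSummary",
    "AmlMrFinding",
    "validate_focal_cnv",
    "call_large_scale_cnv",
    "simulate_lscnv_detectability",
    "map_aml_mr_abnormalities",
    "segment_log2",
    "size_bin",
]


@dataclass(frozen=True)
class CnvThresholds:
    min_softclip: int = 2            # boundary soft-clipped reads per side
    min_abs_log2_focal: float = 0.3  # read-depth evidence for a focal event
    gap_merge_bp: int = 1_000_000    # merge same-direction segments across gaps
    lscnv_min_bp: int = 5_000_000
    # diagnostic depth-ratio for a merged LS-CNV; one-copy events in clones
    # below ~15% of cells fall under it (WGS misses deeply subclonal CNVs)
    min_abs_log2_lscnv: float = 0.1


def size_bin(seg: CnvSegment) -> str:
    """Size annotation used for reporting focal events."""
    if seg.size_bp <= 10_000:
        return "<=10kb"
    if seg.size_bp <= 50_000:
        return "<=50kb"
    if seg.size_bp < 5_000_000:
        return "<5Mb"
    return ">5Mb"


def validate_focal_cnv(
    seg: CnvSegment, thresholds: CnvThresholds = CnvThresholds()
) -> CnvSegment:
    """Apply the dual-evidence rule to a focal CNV.

    The segment meets criteria only when the depth ratio exceeds the
    threshold AND soft-clipped reads support both boundaries. The input is
    annotated in place (``diagnostic_status``) and returned.
    """
    if seg.size_class != "focal":
        raise ValueError(
            f"segment {seg.contig}:{seg.start}-{seg.end} is not focal "
            f"({seg.size_bp} bp)"
        )
    depth_ok = abs(seg.log2_ratio) >= thresholds.min_abs_log2_focal
    clips_ok = (
        seg.softclip_left >= thresholds.min_softclip
        and seg.softclip_right >= thresholds.min_softclip
    )
    seg.diagnostic_status = "meets_criteria" if (depth_ok and clips_ok) else "rejected"
    return seg


def call_large_scale_cnv(
    segments: Iterable[CnvSegment],
    thresholds: CnvThresholds = CnvThresholds(),
) -> list[CnvSegment]:
    """Merge same-direction segments and emit events larger than 5 Mb.

    Adjacent segments on the same contig with the same direction are merged
    when separated by at most ``gap_merge_bp``; the merged log2 ratio is the
    length-weighted mean. Overlapping segments of contradictory direction
    raise a validation error.
    """
    by_key: dict[tuple[str, str], list[CnvSegment]] = {}
    per_contig: dict[str, list[CnvSegment]] = {}
    for s in segments:
        if s.log2_ratio == 0:
            continue
        by_key.setdefault((s.contig, s.direction), []).append(s)
        per_contig.setdefault(s.contig, []).append(s)

    for contig, segs in per_contig.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end and a.direction != b.direction:
                raise ValueError(
                    f"contradictory overlapping segments on {contig}: "
                    f"{a.start}-{a.end} ({a.direction}) vs {b.start}-{b.end} ({b.direction})"
                )

    merged: list[CnvSegment] = []
    for (contig, _direction), segs in sorted(by_key.items()):
        segs = sorted(segs, key=lambda s: s.start)
        run, run_end = [segs[0]], segs[0].end
        for s in segs[1:]:
            if s.start - run_end <= thresholds.gap_merge_bp:
                run.append(s)
                run_end = max(run_end, s.end)
            else:
                merged.append(_merge_run(run))
                run, run_end = [s], s.end
        merged.append(_merge_run(run))

    out = []
    for m in merged:
        if m.size_bp > thresholds.lscnv_min_bp and \
                abs(m.log2_ratio) >= thresholds.min_abs_log2_lscnv:
            m.diagnostic_status = "meets_criteria"
            out.append(m)
    return sorted(out, key=lambda s: (s.contig, s.start))


def _merge_run(run: list[CnvSegment]) -> CnvSegment:
    start, end = run[0].start, max(s.end for s in run)
    w = np.array([s.size_bp for s in run], dtype=float)
    log2 = float(np.average([s.log2_ratio for s in run], weights=w))
    return CnvSegment(
        contig=run[0].contig, start=start, end=end, log2_ratio=log2,
        copy_number=run[0].copy_number,
        softclip_left=run[0].softclip_left, softclip_right=run[-1].softclip_right,
    )


# ---------------------------------------------------------------------------
# purity-dependent LS-CNV detectability simulation


@dataclass(frozen=True)
class LscnvNoiseModel:
    """Noise and pipeline parameters for the detectability simulation.

    The log2-ratio track combines white per-bin noise with a smooth
    wave component emulating coverage biases (GC waves); the wave is what
    fragments marginal events, because segment means ride on it.
    """

    bin_mb: float = 1.0
    white_sd: float = 0.04
    wave_sd: float = 0.03
    wave_length_mb: float = 10.0
    split_threshold: float = 3.5   # recursive-segmentation split statistic
    min_seg_bins: int = 4
    ratio_min: float = 0.18        # diagnostic |log2| for a gain segment
    min_pass_mb: float = 3.0       # diagnostic minimum segment size
    report_fraction: float = 0.7   # span coverage needed to establish an event


@dataclass
class EventRecovery:
    label: str
    recovered_fraction: float
    n_fragments: int
    status: str  # detected | fragmented | failed
    establishable: bool


@dataclass
class DetectionSummary:
    purity: float
    events: list[EventRecovery] = field(default_factory=list)

    @property
    def all_detected(self) -> bool:
        return all(e.status == "detected" for e in self.events)

    @property
    def any_fragmented(self) -> bool:
        return any(e.status == "fragmented" for e in self.events)

    @property
    def any_below_reporting(self) -> bool:
        return any(not e.establishable for e in self.events)

    @property
    def mean_recovered(self) -> float:
        return float(np.mean([e.recovered_fraction for e in self.events]))

    def to_dict(self) -> dict:
        return {
            "purity": self.purity,
            "events": [vars(e) for e in self.events],
            "all_detected": self.all_detected,
            "any_fragmented": self.any_fragmented,
            "any_below_reporting": self.any_below_reporting,
        }


def segment_log2(values: np.ndarray, noise: LscnvNoiseModel) -> list[tuple[int, int]]:
    """Recursive mean-shift segmentation of a log2-ratio track.

    Splits a region at the position maximizing the standardized difference
    in means, recursing while the statistic exceeds ``split_threshold``.
    Returns half-open (start, end) bin intervals.
    """
    sigma0 = noise.white_sd
    out: list[tuple[int, int]] = []

    def rec(a: int, b: int) -> None:
        n = b - a
        if n < 2 * noise.min_seg_bins:
            out.append((a, b))
            return
        x = values[a:b]
        cums = np.cumsum(x)
        total = cums[-1]
        ks = np.arange(noise.min_seg_bins, n - noise.min_seg_bins + 1)
        mean_l = cums[ks - 1] / ks
        mean_r = (total - cums[ks - 1]) / (n - ks)
        t = np.abs(mean_l - mean_r) / (sigma0 * np.sqrt(1.0 / ks + 1.0 / (n - ks)))
        i = int(np.argmax(t))
        if t[i] > noise.split_threshold:
            k = int(ks[i])
            rec(a, a + k)
            rec(a + k, b)
        else:
            out.append((a, b))

    rec(0, len(values))
    return sorted(out)


def simulate_lscnv_detectability(
    events: list[dict],
    purity: float,
    noise: LscnvNoiseModel = LscnvNoiseModel(),
    seed: int = 0,
) -> DetectionSummary:
    """Score recovery of known large gains/losses at a given tumor fraction.

    ``events``: list of dicts with keys ``contig``, ``start_mb``, ``end_mb``,
    ``delta_copies`` (e.g. +1/+2 for gains) and optional ``label``. For each
    affected contig a noisy log2-ratio track is generated (expected in-event
    shift log2((2 + purity*delta)/2)), segmented by recursive changepoint
    detection, and each truth event is scored by the fraction of its span
    covered by segments meeting diagnostic criteria.

    The noise realization depends only on the seed, never on purity, so
    recovery along a purity grid is compared on identical noise.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity {purity} outside (0, 1]")
    rng = np.random.default_rng(seed)
    by_contig: dict[str, list[dict]] = {}
    for ev in events:
        by_contig.setdefault(ev["contig"], []).append(ev)

    summary = DetectionSummary(purity=purity)
    for contig in sorted(by_contig):
        n_bins = int(math.ceil(GENOME_MB[contig] / noise.bin_mb))
        white = rng.normal(0.0, noise.white_sd, size=n_bins)
        # smooth wave: moving-average-filtered white noise rescaled to wave_sd
        w = max(1, int(round(noise.wave_length_mb / noise.bin_mb)))
        raw = rng.normal(0.0, 1.0, size=n_bins + w)
        kernel = np.ones(w) / w
        wave = np.convolve(raw, kernel, mode="valid")[:n_bins]
        sd = wave.std() or 1.0
        wave = wave * (noise.wave_sd / sd)
        track = white + wave

        shift = np.zeros(n_bins)
        for ev in by_contig[contig]:
            a = int(ev["start_mb"] / noise.bin_mb)
            b = int(math.ceil(ev["end_mb"] / noise.bin_mb))
            shift[a:b] += math.log2((2.0 + purity * ev["delta_copies"]) / 2.0)
        track = track + shift

        segs = segment_log2(track, noise)
        min_pass_bins = noise.min_pass_mb / noise.bin_mb
        passing = []
        for a, b in segs:
            mean = float(track[a:b].mean())
            if (b - a) >= min_pass_bins and abs(mean) >= noise.ratio_min:
                passing.append((a, b, np.sign(mean)))

        for ev in by_contig[contig]:
            ea = int(ev["start_mb"] / noise.bin_mb)
            eb = int(math.ceil(ev["end_mb"] / noise.bin_mb))
            want = np.sign(ev["delta_copies"])
            covered = np.zeros(eb - ea, dtype=bool)
            for a, b, sign in passing:
                if sign != want:
                    continue
                lo, hi = max(a, ea), min(b, eb)
                if hi > lo:
                    covered[lo - ea : hi - ea] = True
            frac = float(covered.mean()) if len(covered) else 0.0
            n_frag = int(np.sum(np.diff(np.concatenate(([0], covered.view(np.int8))))
                                == 1))
            establishable = frac >= noise.report_fraction
            if frac == 0.0:
                status = "failed"
            elif establishable and n_frag == 1:
                status = "detected"
            else:
                status = "fragmented"
            summary.events.append(
                EventRecovery(
                    label=ev.get("label", f"{contig}:{ev['start_mb']}-{ev['end_mb']}"),
                    recovered_fraction=frac, n_fragments=n_frag,
                    status=status, establishable=establishable,
                )
            )
    return summary


# ---------------------------------------------------------------------------
# AML-MR abnormality mapping


@dataclass
class AmlMrFinding:
    label: str
    supporting_segments: list[CnvSegment] = field(default_factory=list)
    source: str = "WGS"  # WGS | cytogenetics | both


def _arm_interval(contig: str, arm: str) -> tuple[int, int]:
    cen = int(CENTROMERE_MB[contig] * 1e6)
    length = int(GENOME_MB[contig] * 1e6)
    if arm == "p":
        return (0, cen)
    if arm == "q":
        return (cen, length)
    return (0, length)


def map_aml_mr_abnormalities(
    lscnvs: Iterable[CnvSegment],
    table: Optional[list[dict]] = None,
    min_overlap: float = 0.5,
    whole_chrom_coverage: float = 0.9,
    source: str = "WGS",
) -> list[AmlMrFinding]:
    """Map large-scale CNVs onto myelodysplasia-related abnormality labels.

    A CNV yields a finding when at least ``min_overlap`` of the event lies
    within a table region with the required direction. Whole-chromosome
    labels (e.g. -7) take precedence when the event covers >= 90% of the
    chromosome.
    """
    table = default_aml_mr_table() if table is None else table
    findings: dict[str, AmlMrFinding] = {}
    for seg in lscnvs:
        matched_label = None
        # whole-chromosome labels first
        for entry in table:
            if entry["arm"] != "whole" or entry["contig"] != seg.contig:
                continue
            if seg.direction != entry["direction"]:
                continue
            a, b = _arm_interval(seg.contig, "whole")
            cov = max(0, min(seg.end, b) - max(seg.start, a)) / (b - a)
            if cov >= whole_chrom_coverage:
                matched_label = entry["label"]
                break
        if matched_label is None:
            for entry in table:
                if entry["arm"] == "whole" or entry["contig"] != seg.contig:
                    continue
                if seg.direction != entry["direction"]:
                    continue
                a, b = _arm_interval(seg.contig, entry["arm"])
                ov = max(0, min(seg.end, b) - max(seg.start, a))
                if seg.size_bp > 0 and ov / seg.size_bp >= min_overlap:
                    matched_label = entry["label"]
                    break
        if matched_label is not None:
            f = findings.setdefault(
                matched_label, AmlMrFinding(matched_label, source=source)
            )
            f.supporting_segments.append(seg)
    return [findings[k] for k in sorted(findings)]
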