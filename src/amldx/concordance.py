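"""Cross-platform comparison statistics: VAF concordance, variant-level
platform agreement with manual-review re-binning, fusion detection
agreement, and LS-CNV agreement against conventional cytogenetics.

"Manual review" of the losing platform is modelled as an oracle query
against that platform's raw (sub-threshold) observation — the programmatic
stand-in for pulling up a BAM in a viewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .types import CaseBundle, CnvSegment, KaryotypeObservation

__all__ = [
    "VafConcordance",
    "AgreementTable",
    "LscnvAgreementTable",
    "vaf_concordance",
    "platform_agreement",
    "cytogenetics_agreement",
    "cohort_platform_calls",
    "cohort_vaf_pairs",
    "raw_observation_oracle",
    "fusion_platform_agreement",
]


@dataclass
class VafConcordance:
    r: Optional[float]
    slope: Optional[float]
    n: int
    note: str = ""


def vaf_concordance(pairs: Sequence[tuple[float, float]]) -> VafConcordance:
    """Pearson correlation and least-squares slope of paired VAF estimates."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 VAF pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
        raise ValueError("VAFs must lie in [0, 1]")
    if np.std(a) == 0 or np.std(b) == 0:
        return VafConcordance(None, None, len(pairs), "zero variance: r undefined")
    res = stats.linregress(a, b)
    return VafConcordance(float(res.rvalue), float(res.slope), len(pairs))


@dataclass
class AgreementTable:
    """Variant-level agreement between two platforms A and B."""

    both: list = field(default_factory=list)
    a_only: list = field(default_factory=list)
    b_only: list = field(default_factory=list)
    # manual-review bins: called by one platform only, but present below
    # threshold in the other platform's raw data
    a_only_present_in_b: list = field(default_factory=list)
    b_only_present_in_a: list = field(default_factory=list)

    @property
    def n_union(self) -> int:
        return len(self.both) + len(self.a_only) + len(self.b_only)

    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "a_only_present_in_b_on_review": len(self.a_only_present_in_b),
            "b_only_present_in_a_on_review": len(self.b_only_present_in_a),
        }


def platform_agreement(
    calls_a: dict,
    calls_b: dict,
    review_oracle: Optional[Callable[[object, str], Optional[float]]] = None,
) -> AgreementTable:
    """Classify the union of two identically-keyed call sets.

    ``calls_a``/``calls_b`` map a variant key to its VAF on that platform.
    ``review_oracle(key, side)`` (side "a" or "b") returns the raw VAF that
    manual review of the named platform would reveal, or None.
    """
    table = AgreementTable()
    for key in sorted(set(calls_a) | set(calls_b), key=repr):
        in_a, in_b = key in calls_a, key in calls_b
        if in_a and in_b:
            table.both.append(key)
        elif in_a:
            table.a_only.append(key)
            if review_oracle is not None and review_oracle(key, "b") is not None:
                table.a_only_present_in_b.append(key)
        else:
            table.b_only.append(key)
            if review_oracle is not None and review_oracle(key, "a") is not None:
                table.b_only_present_in_a.append(key)
    return table


# ---------------------------------------------------------------------------
# cohort helpers


def cohort_platform_calls(
    bundles: Sequence[CaseBundle],
    platform: str,
    vaf_min: float = 0.05,
    min_reads: int = 10,
    plp_only: bool = True,
) -> dict:
    """Variants a platform would call: VAF and depth above the reporting
    thresholds. Keys are (case_id, contig, pos, ref, alt)."""
    calls = {}
    for b in bundles:
        for v in b.snv_indel_calls:
            if plp_only and v.pathogenicity not in ("P", "LP"):
                continue
            o = v.obs(platform)
            if o is None:
                continue
            if o.vaf >= vaf_min and o.total_reads >= min_reads:
                calls[(b.case_id,) + v.key] = o.vaf
    return calls


def raw_observation_oracle(
    bundles: Sequence[CaseBundle], platform_a: str, platform_b: str
) -> Callable:
    """Review oracle over the cohort's raw per-platform observations."""
    raw = {"a": {}, "b": {}}
    for b in bundles:
        for v in b.snv_indel_calls:
            for side, platform in (("a", platform_a), ("b", platform_b)):
                o = v.obs(platform)
                if o is not None and o.alt_reads > 0:
                    raw[side][(b.case_id,) + v.key] = o.vaf

    def oracle(key, side):
        return raw[side].get(key)

    return oracle


def cohort_vaf_pairs(
    bundles: Sequence[CaseBundle], platform_a: str, platform_b: str,
    vaf_min: float = 0.05, min_reads: int = 10,
) -> list[tuple[float, float]]:
    """Paired VAFs for variants reportable on both platforms."""
    a = cohort_platform_calls(bundles, platform_a, vaf_min, min_reads)
    b = cohort_platform_calls(bundles, platform_b, vaf_min, min_reads)
    return [(a[k], b[k]) for k in sorted(set(a) & set(b), key=repr)]


def fusion_platform_agreement(bundles: Sequence[CaseBundle]) -> dict[str, int]:
    """Fusion detection agreement between DNA (SV) and RNA (transcript)
    evidence across a cohort, per gene pair per case."""
    both = wgs_only = wts_only = 0
    for b in bundles:
        dna = {(s.gene1, s.gene2) for s in b.sv_calls
               if s.predicted_consequence == "chimeric_fusion"}
        rna = {(t.gene5, t.gene3) for t in b.fusion_transcripts
               if t.gene5 != t.gene3 and t.junction_reads > 0}
        both += len(dna & rna)
        wgs_only += len(dna - rna)
        wts_only += len(rna - dna)
    return {"both": both, "wgs_only": wgs_only, "wts_only": wts_only}


# ---------------------------------------------------------------------------
# cytogenetics vs WGS LS-CNV agreement


@dataclass
class LscnvAgreementTable:
    both: list = field(default_factory=list)
    wgs_only: list = field(default_factory=list)
    cytogenetics_only: list = field(default_factory=list)
    unmappable: int = 0

    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "wgs_only": len(self.wgs_only),
            "cytogenetics_only": len(self.cytogenetics_only),
        }

    @property
    def agreement_fraction(self) -> float:
        n = len(self.both) + len(self.wgs_only) + len(self.cytogenetics_only)
        return len(self.both) / n if n else float("nan")


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    ov = max(0, min(a_end, b_end) - max(a_start, b_start))
    la, lb = a_end - a_start, b_end - b_start
    if la <= 0 or lb <= 0:
        return 0.0
    return min(ov / la, ov / lb)


def cytogenetics_agreement(
    wgs_lscnvs: Iterable[CnvSegment],
    karyotype: KaryotypeObservation,
    min_reciprocal_overlap: float = 0.5,
) -> LscnvAgreementTable:
    """Match WGS LS-CNVs against karyotype-visible copy-number events.

    Events match at >= 50% reciprocal overlap with the same direction.
    Expected discordance patterns: cytogenetics-only events are typically
    subclonal (below WGS CNV sensitivity); WGS-only events are small or
    banding-cryptic.
    """
    table = LscnvAgreementTable()
    kevents = [e for e, _n in karyotype.visible_events if e.kind in ("gain", "loss")]
    matched_k = set()
    for seg in sorted(wgs_lscnvs, key=lambda s: (s.contig, s.start)):
        hit = None
        for j, e in enumerate(kevents):
            if j in matched_k or e.contig != seg.contig or e.kind != seg.direction:
                continue
            if _reciprocal_overlap(seg.start, seg.end, e.start, e.end) >= min_reciprocal_overlap:
                hit = j
                break
        if hit is None:
            table.wgs_only.append(seg)
        else:
            matched_k.add(hit)
            table.both.append((seg, kevents[hit]))
    for j, e in enumerate(kevents):
        if j not in matched_k:
            table.cytogenetics_only.append(e)
    return table
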