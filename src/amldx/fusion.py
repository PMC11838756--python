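"""Integration of DNA-level rearrangements with RNA-level evidence.

Four evidence-integration problems are handled here:

* joining a WGS structural variant with a compatible WTS chimeric transcript
  into a chimeric-fusion call (reading frame checked by cumulative
  coding-phase arithmetic at the exon junction);
* recognising enhancer hijacking — a breakpoint near a catalog oncogene with
  overexpression of that oncogene but no chimeric transcript;
* tiering FLT3 internal tandem duplications by the strength of WGS and WTS
  junction-read support;
* validating KMT2A partial tandem duplications at the RNA level by the
  characteristic in-frame self-fusion of exon 7/8 onto exon 2/3/4.

Any call not confirmed on both platforms carries a flag recommending
orthogonal confirmation (targeted RNA-seq or PCR fragment analysis).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .catalog import ENHANCER_HIJACK_TARGETS, ExonModel
from .types import (
    CnvSegment,
    ExpressionProfile,
    FusionTranscript,
    IntegratedFusionCall,
    ItdCall,
    ItdObservation,
    StructuralVariant,
)

__all__ = [
    "FusionThresholds",
    "PtdCall",
    "integrate_fusion_evidence",
    "classify_enhancer_hijacking",
    "tier_flt3_itd",
    "validate_kmt2a_ptd",
    "integrate_case_fusions",
    "robust_z",
]


@dataclass(frozen=True)
class FusionThresholds:
    min_junction_reads: int = 3       # confident chimeric transcript support
    eh_window_upstream: int = 300_000   # bp upstream of the oncogene
    eh_window_downstream: int = 150_000  # bp downstream
    eh_z_min: float = 2.0               # robust overexpression z-score
    itd_strong_reads: int = 5           # junction reads for "strong" ITD evidence


@dataclass
class PtdCall:
    gene: str
    status: str  # validated | dna_only | rejected
    transcript: Optional[FusionTranscript] = None
    confirmation_recommended: bool = True
    reason: str = ""


def robust_z(value: float, baseline: np.ndarray) -> float:
    """z-score of ``value`` against a cohort baseline using median/MAD."""
    baseline = np.asarray(baseline, dtype=float)
    med = float(np.median(baseline))
    mad = float(np.median(np.abs(baseline - med)))
    scale = 1.4826 * mad
    if scale == 0.0:
        scale = float(np.std(baseline)) or 1e-9
    return (value - med) / scale


_REGION_RE = re.compile(r"(intron|exon)\s*(\d+)")


def _breakpoint_exon_compatible(region: str, exon5: int) -> bool:
    """Is a transcript's 5' junction exon compatible with the DNA breakpoint?

    A breakpoint in intron k predicts a junction after exon k; a breakpoint
    in exon k can yield junctions at exon k-1 or k. Unannotated regions are
    treated as compatible.
    """
    m = _REGION_RE.search(region or "")
    if not m:
        return True
    kind, k = m.group(1), int(m.group(2))
    if kind == "intron":
        return exon5 == k
    return exon5 in (k - 1, k)


def integrate_fusion_evidence(
    sv: StructuralVariant,
    transcripts: Iterable[FusionTranscript],
    expr: Optional[ExpressionProfile] = None,
    exon_model: Optional[ExonModel] = None,
    thresholds: FusionThresholds = FusionThresholds(),
) -> IntegratedFusionCall:
    """Join a DNA rearrangement with RNA transcript evidence.

    Transcripts are matched by gene pair and breakpoint-compatible exons; the
    reading frame is determined from the exon model (cumulative coding-phase
    arithmetic at the junction). A compatible in-frame transcript upgrades the
    call to ``chimeric_fusion``; support below ``min_junction_reads`` (for
    example a single junction-spanning read) keeps the call but flags it for
    orthogonal confirmation.
    """
    call = IntegratedFusionCall(sv=sv, evidence={"WGS_SV"})
    matched: list[FusionTranscript] = []
    for t in transcripts:
        if (t.gene5, t.gene3) != (sv.gene1, sv.gene2):
            continue
        if not _breakpoint_exon_compatible(sv.region1, t.exon5):
            continue
        matched.append(t)

    best = None
    for t in sorted(matched, key=lambda x: -x.junction_reads):
        if exon_model is not None:
            if t.gene5 not in exon_model or t.gene3 not in exon_model:
                call.mechanism = "unconfirmed"
                call.reasons.append(
                    f"genes {t.gene5}/{t.gene3} absent from exon model: frame unassessable"
                )
                call.confirmation_needed = True
                return call
            t.in_frame = exon_model.junction_in_frame(t.gene5, t.exon5, t.gene3, t.exon3)
        if t.in_frame:
            best = t
            break

    if best is not None and best.junction_reads >= 1:
        call.transcript = best
        call.evidence.add("WTS_transcript")
        call.mechanism = "chimeric_fusion"
        if best.junction_reads < thresholds.min_junction_reads:
            call.confirmation_needed = True
            call.reasons.append(
                f"only {best.junction_reads} junction read(s) "
                f"(< {thresholds.min_junction_reads}): orthogonal confirmation needed"
            )
        return call

    call.mechanism = "unconfirmed"
    call.confirmation_needed = True
    call.reasons.append("no compatible in-frame chimeric transcript observed in WTS")
    return call


def classify_enhancer_hijacking(
    sv: StructuralVariant,
    expr: ExpressionProfile,
    baseline: dict[str, np.ndarray],
    oncogene_catalog: Optional[dict[str, str]] = None,
    thresholds: FusionThresholds = FusionThresholds(),
) -> IntegratedFusionCall:
    """Call enhancer hijacking for a non-coding breakpoint near an oncogene.

    Requires the breakpoint within the proximity window (default 300 kb
    upstream / 150 kb downstream of the catalog oncogene) AND a robust
    overexpression z-score of that oncogene against the cohort baseline of at
    least ``eh_z_min``. Proximity without overexpression stays unconfirmed —
    the predicted mechanism is disproved by the transcriptome.
    """
    oncogene_catalog = ENHANCER_HIJACK_TARGETS if oncogene_catalog is None else oncogene_catalog
    call = IntegratedFusionCall(sv=sv, evidence={"WGS_SV"}, mechanism="unconfirmed")
    candidates = []  # (gene, offset)
    for gene, offset in ((sv.gene1, sv.offset1), (sv.gene2, sv.offset2)):
        if gene in oncogene_catalog:
            candidates.append((gene, offset))
    if not candidates:
        call.reasons.append("no catalog oncogene adjacent to either breakpoint")
        call.confirmation_needed = True
        return call

    for gene, offset in candidates:
        call.target_gene = gene
        upstream = offset < 0
        dist = abs(offset)
        within = (
            dist <= thresholds.eh_window_upstream
            if upstream
            else dist <= thresholds.eh_window_downstream
        )
        if not within:
            call.reasons.append(
                f"breakpoint {dist / 1000:g} kb "
                f"{'upstream' if upstream else 'downstream'} of {gene}: outside window"
            )
            continue
        value = expr.get(gene)
        base = baseline.get(gene)
        if value is None or base is None or len(base) == 0:
            call.reasons.append(f"expression unavailable for {gene}: unassessable")
            call.confirmation_needed = True
            return call
        z = robust_z(value, base)
        if z >= thresholds.eh_z_min:
            call.mechanism = "enhancer_hijacking"
            call.evidence.add("WTS_overexpression")
            call.reasons.append(f"{gene} overexpressed (robust z={z:.1f})")
            call.confirmation_needed = False
            return call
        call.reasons.append(
            f"{gene} expression comparable to baseline (robust z={z:.1f}): "
            "enhancer hijacking not supported"
        )
    call.confirmation_needed = True
    return call


def _evidence_level(reads: int, strong: int) -> str:
    if reads >= strong:
        return "strong"
    if reads >= 1:
        return "weak"
    return "none"


def tier_flt3_itd(
    obs: ItdObservation, thresholds: FusionThresholds = FusionThresholds()
) -> Optional[ItdCall]:
    """Tier an internal tandem duplication by cross-platform read support.

    Confirmed needs strong evidence on both WGS and WTS; exactly one strong
    platform gives a borderline finding; anything else with at least some
    support is weak. Non-confirmed tiers always recommend orthogonal
    PCR-fragment-analysis confirmation. Returns ``None`` when neither
    platform shows any evidence (no call).
    """
    wgs = _evidence_level(obs.wgs_junction_reads, thresholds.itd_strong_reads)
    wts = _evidence_level(obs.wts_junction_reads, thresholds.itd_strong_reads)
    if wgs == "none" and wts == "none":
        return None
    n_strong = (wgs == "strong") + (wts == "strong")
    tier = {2: "confirmed", 1: "borderline", 0: "weak"}[n_strong]
    return ItdCall(
        gene=obs.gene, wgs_evidence=wgs, wts_evidence=wts, tier=tier,
        orthogonal_confirmation_recommended=(tier != "confirmed"),
        itd_wt_ratio=obs.itd_wt_ratio,
    )


KMT2A_PTD_DONOR_EXONS = frozenset({7, 8})
KMT2A_PTD_ACCEPTOR_EXONS = frozenset({2, 3, 4})


def validate_kmt2a_ptd(
    cnv: CnvSegment,
    transcripts: Iterable[FusionTranscript],
    exon_model: Optional[ExonModel] = None,
    gene: str = "KMT2A",
) -> PtdCall:
    """Validate an intragenic KMT2A duplication against RNA self-fusions.

    A partial tandem duplication is validated when WTS shows an in-frame
    self-fusion transcript joining exon 7 or 8 upstream onto exon 2, 3 or 4.
    A self-fusion outside that exon set is rejected; a duplication with no
    self-fusion transcript at all stays a DNA-only finding. Both of the
    latter carry a confirmation recommendation.
    """
    self_fusions = [t for t in transcripts if t.gene5 == gene and t.gene3 == gene]
    for t in self_fusions:
        if t.exon5 not in KMT2A_PTD_DONOR_EXONS or t.exon3 not in KMT2A_PTD_ACCEPTOR_EXONS:
            continue
        in_frame = t.in_frame
        if exon_model is not None and gene in exon_model:
            in_frame = exon_model.junction_in_frame(gene, t.exon5, gene, t.exon3)
        if in_frame:
            return PtdCall(
                gene=gene, status="validated", transcript=t,
                confirmation_recommended=False,
                reason=f"in-frame self-fusion exon {t.exon5} -> exon {t.exon3}",
            )
    if self_fusions:
        t = self_fusions[0]
        return PtdCall(
            gene=gene, status="rejected", transcript=t,
            confirmation_recommended=True,
            reason=(
                f"self-fusion exon {t.exon5} -> exon {t.exon3} outside the "
                "PTD-consistent exon set (7/8 -> 2/3/4) or out of frame"
            ),
        )
    return PtdCall(
        gene=gene, status="dna_only", confirmation_recommended=True,
        reason="duplication seen in WGS only; no self-fusion transcript in WTS",
    )


def calls_from_orphan_transcripts(
    transcripts: Iterable[FusionTranscript],
    svs: Iterable[StructuralVariant],
    exon_model: Optional[ExonModel] = None,
    thresholds: FusionThresholds = FusionThresholds(),
) -> list[IntegratedFusionCall]:
    """Fusion calls from chimeric transcripts with no matching DNA junction.

    Mirrors fusions whose DNA breakpoints are cryptic to WGS (for example
    insertion-mediated rearrangements): an in-frame transcript with adequate
    junction-read support is called on RNA evidence alone. Self-fusion
    transcripts are excluded — they are tandem-duplication evidence, handled
    by :func:`validate_kmt2a_ptd`.
    """
    sv_pairs = {(s.gene1, s.gene2) for s in svs}
    calls = []
    for t in transcripts:
        if t.gene5 == t.gene3 or (t.gene5, t.gene3) in sv_pairs:
            continue
        in_frame = t.in_frame
        if exon_model is not None and t.gene5 in exon_model and t.gene3 in exon_model:
            in_frame = exon_model.junction_in_frame(t.gene5, t.exon5, t.gene3, t.exon3)
        if not in_frame or t.junction_reads < 1:
            continue
        call = IntegratedFusionCall(
            sv=None, transcript=t, mechanism="chimeric_fusion",
            evidence={"WTS_transcript"},
        )
        if t.junction_reads < thresholds.min_junction_reads:
            call.confirmation_needed = True
            call.reasons.append(
                f"only {t.junction_reads} junction read(s) and no DNA breakpoint: "
                "orthogonal confirmation needed"
            )
        else:
            call.reasons.append("RNA-only call: DNA junction cryptic to WGS")
        calls.append(call)
    return calls


def integrate_case_fusions(
    svs: Iterable[StructuralVariant],
    transcripts: list[FusionTranscript],
    expr: ExpressionProfile,
    baseline: dict[str, np.ndarray],
    exon_model: Optional[ExonModel] = None,
    thresholds: FusionThresholds = FusionThresholds(),
) -> list[IntegratedFusionCall]:
    """Integrate every SV of a case; mechanisms are exclusive per SV."""
    calls = []
    for sv in svs:
        if sv.predicted_consequence == "possible_enhancer_hijack":
            call = classify_enhancer_hijacking(
                sv, expr, baseline, thresholds=thresholds
            )
            # an enhancer-hijack prediction can still be explained by a
            # chimeric transcript (e.g. a fusion onto the target gene)
            if call.mechanism == "unconfirmed":
                alt = integrate_fusion_evidence(
                    sv, transcripts, expr, exon_model, thresholds
                )
                if alt.mechanism == "chimeric_fusion":
                    call = alt
        else:
            call = integrate_fusion_evidence(sv, transcripts, expr, exon_model, thresholds)
        calls.append(call)
    return calls
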