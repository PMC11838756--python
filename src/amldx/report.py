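"""Phased clinical report assembly.

Reporting proceeds in three phases with monotone content: a rapid tumor
report (day 7) carrying class-defining drivers and genome-wide large-scale
CNVs; an integrated report (day 14) adding rare/novel fusions and select
cooperating variants; and a comprehensive paired tumor-normal report
(day 21) adding the full tumor variant profile and germline findings.
Turnaround time is metadata (phase labels), not wall-clock logic. Every
borderline, rescued or single-read finding carries its confirmation flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .classify import CaseResults

__all__ = ["PhasedReport", "build_phased_report", "PHASES"]

PHASES = ("rapid_day7", "integrated_day14", "comprehensive_day21")

_RAPID_TIERS = (
    "DS_GATA1", "class_defining_fusion", "class_defining_mutation",
    "newly_proposed_class", "AML_MR",
)


@dataclass
class PhasedReport:
    case_id: str
    phase: str
    sections: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"case_id": self.case_id, "phase": self.phase, "sections": self.sections},
            indent=1, sort_keys=True,
        )

    def to_text(self) -> str:
        lines = [f"Case {self.case_id} — phase {self.phase}", "=" * 40]
        for name, content in sorted(self.sections.items()):
            lines.append(f"[{name}]")
            if isinstance(content, str):
                lines.append(f"  {content}")
            elif isinstance(content, list):
                if not content:
                    lines.append("  (none)")
                for item in content:
                    if isinstance(item, dict):
                        lines.append(
                            "  " + "; ".join(f"{k}={v}" for k, v in sorted(item.items()))
                        )
                    else:
                        lines.append(f"  {item}")
            else:
                lines.append(f"  {content}")
        return "\n".join(lines) + "\n"


def _variant_entry(v) -> dict:
    entry = {
        "gene": v.gene, "locus": f"{v.contig}:{v.pos}", "change": f"{v.ref}>{v.alt}",
        "class": v.variant_class, "pathogenicity": v.pathogenicity,
    }
    o = v.obs("WGS") or v.obs("WES")
    if o is not None:
        entry["vaf"] = round(o.vaf, 4)
    return entry


def build_phased_report(results: CaseResults, phase: str) -> PhasedReport:
    """Assemble the report for one case at the requested phase.

    Content is monotone across phases; serialization is deterministic.
    Requesting the comprehensive phase without germline input yields an
    explicit "germline pending" section rather than an error.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    call = results.subtype_call
    confirmation: list[str] = list(call.confirmation_flags) if call else []

    sections: dict = {}
    # --- rapid (day 7): class-defining drivers + LS-CNVs + QC ---
    drivers: list[dict] = []
    if call is not None and call.tier in _RAPID_TIERS:
        drivers.append(
            {"subtype": call.subtype, "tier": call.tier,
             "evidence": sorted(set(call.drivers)),
             "expression_corroboration": call.expression_corroboration}
        )
    sections["driver_findings"] = drivers
    sections["ls_cnvs"] = [
        {"contig": s.contig, "start": s.start, "end": s.end,
         "direction": s.direction, "size_mb": round(s.size_bp / 1e6, 1)}
        for s in results.lscnvs
    ]
    sections["aml_mr_abnormalities"] = [
        {"label": f.label, "source": f.source} for f in results.aml_mr_findings
    ]
    sections["qc"] = [
        {"platform": q.platform, "verdict": q.verdict} for q in results.qc
    ]
    for d in results.decisions:
        if d.status == "rescued_reportable":
            confirmation.append(
                f"rescued sub-threshold driver {d.variant.gene} ({'; '.join(d.reasons)})"
            )
    for itd in results.itd_calls:
        if itd.orthogonal_confirmation_recommended:
            confirmation.append(f"{itd.gene}-ITD tier {itd.tier}: PCR confirmation recommended")
    for p in results.ptd_calls:
        if p.confirmation_recommended:
            confirmation.append(f"{p.gene}-PTD {p.status}: confirmation recommended")

    if phase != "rapid_day7":
        # --- day 14: rare/novel fusions + cooperating lesions ---
        # drivers already carried by the rapid phase are not re-listed here;
        # a novel-fusion driver is itself a day-14 finding
        claimed = set(call.drivers) if call and call.tier in _RAPID_TIERS else set()
        sections["rare_novel_fusions"] = [
            {"fusion": call_.label, "mechanism": call_.mechanism,
             "evidence": sorted(call_.evidence)}
            for call_ in results.fusion_calls
            if call_.mechanism == "chimeric_fusion" and call_.label not in claimed
        ]
        sections["cooperating_lesions"] = [
            {"lesion": les, "relevance": tags or ["none"]}
            for les, tags in (call.cooperating if call else [])
        ]
        sections["itd_calls"] = [
            {"gene": i.gene, "tier": i.tier, "wgs": i.wgs_evidence, "wts": i.wts_evidence}
            for i in results.itd_calls
        ]

    if phase == "comprehensive_day21":
        # --- day 21: full tumor profile + germline ---
        sections["full_variant_profile"] = [
            dict(_variant_entry(d.variant), status=d.status)
            for d in results.decisions
            if d.status in ("reportable", "rescued_reportable")
        ]
        if results.bundle.germline_candidates or results.germline_findings:
            sections["germline_findings"] = [
                {"gene": g.gene, "category": g.category, "zygosity": g.zygosity,
                 "inheritance": g.inheritance}
                for g in results.germline_findings
            ]
        else:
            sections["germline_findings"] = "germline analysis pending"

    sections["confirmation_recommended"] = sorted(set(confirmation))
    return PhasedReport(results.bundle.case_id, phase, sections)
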