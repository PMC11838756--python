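"""Molecular subtype assignment from integrated evidence.

The driver hierarchy is total and ordered; the first matching tier wins:

1. Down-syndrome context with a reported pathogenic GATA1 variant;
2. a confirmed AML class-defining gene fusion (including enhancer-hijacking
   mechanisms such as MECOM rearrangements);
3. an AML class-defining mutation (NPM1, CEBPA);
4. a newly proposed class-defining lesion (UBTF tandem duplication,
   BCL11B rearrangement, PRDM16 rearrangement);
5. myelodysplasia-related (AML-MR) mutations and/or cytogenetic
   abnormalities, only in the absence of any other known or potential driver;
6. a novel/rare in-frame gene fusion;
7. otherwise the genetic driver remains unknown.

Multiple same-tier drivers are all recorded; the primary is chosen by
catalog rank. Expression-profile corroboration is nearest-centroid by
Pearson correlation over the signature genes, with a grouping table mapping
biologically related fusions onto a shared profile (e.g. RUNX1::CBFA2T3/2 as
RUNX1::RUNX1T1-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import catalog as cat
from .cnv import (
    AmlMrFinding,
    CnvThresholds,
    call_large_scale_cnv,
    map_aml_mr_abnormalities,
    validate_focal_cnv,
)
from .fusion import (
    FusionThresholds,
    PtdCall,
    calls_from_orphan_transcripts,
    integrate_case_fusions,
    tier_flt3_itd,
    validate_kmt2a_ptd,
)
from .reporting import (
    AseResult,
    GermlineFinding,
    QcAssessment,
    ReportingDecision,
    ReportingThresholds,
    assess_qc,
    categorize_germline_finding,
    detect_allele_specific_expression,
    report_case_variants,
)
from .types import CaseBundle, CnvSegment, ExpressionProfile, IntegratedFusionCall, ItdCall

__all__ = [
    "CaseResults",
    "SubtypeCall",
    "run_case",
    "assign_subtype",
    "expression_centroid_corroboration",
    "flag_actionable_cooperating",
    "platform_view",
    "classify_cohort_accuracy",
]

TIER_ORDER = (
    "DS_GATA1",
    "class_defining_fusion",
    "class_defining_mutation",
    "newly_proposed_class",
    "AML_MR",
    "novel_rare_fusion",
    "unknown",
)


@dataclass
class SubtypeCall:
    subtype: str
    tier: str
    drivers: list[str] = field(default_factory=list)  # all same-tier evidence labels
    cooperating: list[tuple[str, list[str]]] = field(default_factory=list)
    expression_corroboration: str = "unavailable"  # concordant | discordant | unavailable
    corroboration_score: Optional[float] = None
    nearest_centroid: Optional[str] = None
    confirmation_flags: list[str] = field(default_factory=list)


@dataclass
class CaseResults:
    """All per-case module outputs feeding classification and reporting."""

    bundle: CaseBundle
    decisions: list[ReportingDecision] = field(default_factory=list)
    ase: dict[tuple, AseResult] = field(default_factory=dict)
    fusion_calls: list[IntegratedFusionCall] = field(default_factory=list)
    itd_calls: list[ItdCall] = field(default_factory=list)
    focal_cnvs: list[CnvSegment] = field(default_factory=list)
    lscnvs: list[CnvSegment] = field(default_factory=list)
    aml_mr_findings: list[AmlMrFinding] = field(default_factory=list)
    ptd_calls: list[PtdCall] = field(default_factory=list)
    germline_findings: list[GermlineFinding] = field(default_factory=list)
    qc: list[QcAssessment] = field(default_factory=list)
    subtype_call: Optional[SubtypeCall] = None

    @property
    def reported_variants(self):
        return [
            d.variant for d in self.decisions
            if d.status in ("reportable", "rescued_reportable")
        ]


def platform_view(bundle: CaseBundle, mode: str) -> CaseBundle:
    """Restrict a case to the evidence one platform would provide.

    ``mode``: ``integrated`` (no-op), ``WGS`` (drop all RNA evidence) or
    ``WTS`` (drop all DNA evidence). Used for head-to-head comparisons of
    single-platform versus integrated classification.
    """
    if mode == "integrated":
        return bundle
    b = replace(bundle)
    if mode == "WGS":
        b.fusion_transcripts = []
        b.expression = ExpressionProfile()
        b.snv_indel_calls = [
            replace(v, per_platform={p: o for p, o in v.per_platform.items() if p != "WTS"})
            for v in bundle.snv_indel_calls
        ]
        b.itd_observations = [
            replace(o, wts_junction_reads=0) for o in bundle.itd_observations
        ]
        return b
    if mode == "WTS":
        b.sv_calls = []
        b.cnv_segments = []
        b.germline_candidates = []
        b.snv_indel_calls = [
            replace(v, per_platform={p: o for p, o in v.per_platform.items() if p == "WTS"})
            for v in bundle.snv_indel_calls
            if "WTS" in v.per_platform
        ]
        b.itd_observations = [
            replace(o, wgs_junction_reads=0) for o in bundle.itd_observations
        ]
        return b
    raise ValueError(f"unknown platform view {mode!r}")


def run_case(
    bundle: CaseBundle,
    catalog: Optional[cat.SubtypeCatalog] = None,
    exon_model: Optional[cat.ExonModel] = None,
    expression_baseline: Optional[dict[str, np.ndarray]] = None,
    germline_panel: Optional[dict] = None,
    reporting_thresholds: ReportingThresholds = ReportingThresholds(),
    fusion_thresholds: FusionThresholds = FusionThresholds(),
    cnv_thresholds: CnvThresholds = CnvThresholds(),
    driver_catalog: Optional[set[str]] = None,
    prior_sample_variants: Optional[set] = None,
) -> CaseResults:
    """Run filtering, fusion integration, CNV validation and classification
    for one case."""
    catalog = cat.default_subtype_catalog() if catalog is None else catalog
    exon_model = cat.default_exon_model() if exon_model is None else exon_model
    germline_panel = cat.default_germline_panel() if germline_panel is None else germline_panel
    driver_catalog = cat.default_driver_gene_catalog() if driver_catalog is None else driver_catalog
    baseline = expression_baseline or {}
    res = CaseResults(bundle=bundle)

    # small-variant reporting (variants not adjudicable on DNA are skipped)
    for v in bundle.snv_indel_calls:
        if v.origin == "germline":
            continue
        try:
            from .reporting import apply_reporting_filter

            res.decisions.append(
                apply_reporting_filter(v, driver_catalog, prior_sample_variants,
                                       reporting_thresholds)
            )
        except ValueError:
            continue

    for v in res.reported_variants:
        ase = detect_allele_specific_expression(v, thresholds=reporting_thresholds)
        if ase.status == "assessed":
            res.ase[v.key] = ase

    # fusions: SV-anchored integration plus RNA-only (orphan-transcript) calls
    res.fusion_calls = integrate_case_fusions(
        bundle.sv_calls, bundle.fusion_transcripts, bundle.expression,
        baseline, exon_model, fusion_thresholds,
    )
    res.fusion_calls += calls_from_orphan_transcripts(
        bundle.fusion_transcripts, bundle.sv_calls, exon_model, fusion_thresholds
    )

    for obs in bundle.itd_observations:
        call = tier_flt3_itd(obs, fusion_thresholds)
        if call is not None:
            res.itd_calls.append(call)

    focal = [s for s in bundle.cnv_segments if s.size_class == "focal"]
    large = [s for s in bundle.cnv_segments if s.size_class == "large_scale"]
    for s in focal:
        validate_focal_cnv(s, cnv_thresholds)
        if s.diagnostic_status == "meets_criteria":
            res.focal_cnvs.append(s)
            if s.gene == "KMT2A" and s.log2_ratio > 0:
                res.ptd_calls.append(
                    validate_kmt2a_ptd(s, bundle.fusion_transcripts, exon_model)
                )
    res.lscnvs = call_large_scale_cnv(large + focal, cnv_thresholds)
    res.aml_mr_findings = map_aml_mr_abnormalities(res.lscnvs)

    for g in bundle.germline_candidates:
        f = categorize_germline_finding(g, germline_panel, bundle.germline_candidates)
        if f is not None:
            res.germline_findings.append(f)

    res.qc = assess_qc(bundle.qc_metrics, reporting_thresholds)
    res.subtype_call = assign_subtype(res, catalog)
    return res


def _fusion_label(call: IntegratedFusionCall) -> str:
    if call.mechanism == "enhancer_hijacking":
        return cat.ENHANCER_HIJACK_TARGETS.get(
            call.target_gene, f"{call.target_gene}-r"
        )
    return call.label


def _fusion_candidates(res: CaseResults) -> list[tuple[str, IntegratedFusionCall, bool]]:
    """(label, call, confirmed) for every plausible chimeric/EH driver.

    A DNA-predicted chimeric fusion without RNA confirmation remains a
    candidate but carries a confirmation flag (the prediction is not
    disproved, merely unconfirmed — unlike enhancer hijacking, which is
    refuted by baseline expression of the target).
    """
    out = []
    for c in res.fusion_calls:
        if c.mechanism in ("chimeric_fusion", "enhancer_hijacking"):
            out.append((_fusion_label(c), c, not c.confirmation_needed))
        elif (
            c.mechanism == "unconfirmed"
            and c.sv is not None
            and c.sv.predicted_consequence == "chimeric_fusion"
        ):
            out.append((_fusion_label(c), c, False))
    return out


def assign_subtype(res: CaseResults, catalog: cat.SubtypeCatalog) -> SubtypeCall:
    """Assign the molecular subtype by the fixed driver hierarchy."""
    reported = res.reported_variants
    reported_plp = [v for v in reported if v.pathogenicity in ("P", "LP")]
    flags: list[str] = []
    candidates = _fusion_candidates(res)
    for label, c, confirmed in candidates:
        if not confirmed:
            flags.append(f"fusion {label}: orthogonal confirmation recommended")

    call: Optional[SubtypeCall] = None

    # 1. Down-syndrome GATA1
    if res.bundle.disease_context == "down_syndrome":
        gata1 = [v for v in reported_plp if v.gene == catalog.ds_gene]
        if gata1:
            call = SubtypeCall("DS-GATA1", "DS_GATA1", drivers=[catalog.ds_gene])

    # 2. class-defining fusions (incl. enhancer hijacking)
    if call is None:
        ranked = [
            (rank, label, c)
            for label, c, _conf in candidates
            if (rank := catalog.fusion_rank(label)) is not None
        ]
        if ranked:
            ranked.sort(key=lambda t: t[0])
            primary = ranked[0][1]
            call = SubtypeCall(
                primary, "class_defining_fusion",
                drivers=[label for _, label, _ in ranked],
            )

    # 3. class-defining mutations
    if call is None:
        hits = [v for v in reported_plp if v.gene in catalog.class_defining_mutations]
        if hits:
            hits.sort(key=lambda v: catalog.class_defining_mutations.index(v.gene))
            gene = hits[0].gene
            if gene == "CEBPA":
                ase = res.ase.get(hits[0].key)
                if ase is not None and ase.flagged:
                    flags.append("CEBPA allele-specific expression supports diagnosis")
            call = SubtypeCall(gene, "class_defining_mutation",
                               drivers=[v.gene for v in hits])

    def _newly_proposed_label(label: str, c: IntegratedFusionCall) -> Optional[str]:
        if label in catalog.newly_proposed:
            return label
        for gene in c.gene_pair:
            if gene in catalog.newly_proposed_fusion_genes:
                return catalog.newly_proposed_fusion_genes[gene]
        return None

    # 4. newly proposed classes
    if call is None:
        labels = []
        if any(v.gene == "UBTF" and v.variant_class in ("indel", "complex_indel")
               for v in reported_plp) and "UBTF-TD" in catalog.newly_proposed:
            labels.append("UBTF-TD")
        for lab, c, _conf in candidates:
            np_lab = _newly_proposed_label(lab, c)
            if np_lab is not None and np_lab not in labels:
                labels.append(np_lab)
        if labels:
            labels.sort(key=lambda x: catalog.newly_proposed.index(x))
            call = SubtypeCall(labels[0], "newly_proposed_class", drivers=labels)

    # potential drivers that would veto AML-MR: any in-frame novel fusion
    novel = [
        (label, c) for label, c, _conf in candidates
        if catalog.fusion_rank(label) is None
        and _newly_proposed_label(label, c) is None
        and c.mechanism == "chimeric_fusion"
    ]

    # 5. AML-MR, only with no other known or potential driver
    if call is None and not novel:
        mut_hits = sorted({v.gene for v in reported_plp if v.gene in catalog.aml_mr_mutations})
        cyto_hits = [f.label for f in res.aml_mr_findings]
        if mut_hits or cyto_hits:
            call = SubtypeCall("AML-MR", "AML_MR", drivers=mut_hits + cyto_hits)

    # 6. novel/rare in-frame fusions
    if call is None and novel:
        call = SubtypeCall(novel[0][0], "novel_rare_fusion",
                           drivers=[lab for lab, _ in novel])

    if call is None:
        call = SubtypeCall("unknown", "unknown")

    call.confirmation_flags = flags
    call.cooperating = flag_actionable_cooperating(
        _cooperating_labels(res, call), cat.default_relevance_table()
    )
    status, score, nearest = expression_centroid_corroboration(
        res.bundle.expression, call.subtype, catalog
    )
    call.expression_corroboration = status
    call.corroboration_score = score
    call.nearest_centroid = nearest
    return call


def _cooperating_labels(res: CaseResults, call: SubtypeCall) -> list[str]:
    """Reported non-driver lesions of a case, as relevance-table labels."""
    labels: list[str] = []
    driver_genes = set(call.drivers)
    for v in res.reported_variants:
        if v.pathogenicity not in ("P", "LP") or v.gene in driver_genes:
            continue
        labels.append(v.gene)
    for itd in res.itd_calls:
        labels.append(f"{itd.gene}-ITD")
    for p in res.ptd_calls:
        if p.status in ("validated", "dna_only"):
            labels.append(f"{p.gene}-PTD")
    for s in res.focal_cnvs:
        if s.gene and s.gene not in driver_genes and s.log2_ratio < 0:
            labels.append(f"{s.gene}-del")
    for f in res.aml_mr_findings:
        if call.tier != "AML_MR":
            labels.append(f.label)
    return labels


def flag_actionable_cooperating(
    lesions: Sequence[str], relevance_table: dict[str, list[str]]
) -> list[tuple[str, list[str]]]:
    """Annotate cooperating lesions with risk/targetable tags (empty = none)."""
    return [(les, list(relevance_table.get(les, []))) for les in lesions]


def expression_centroid_corroboration(
    expr: ExpressionProfile,
    subtype: str,
    catalog: cat.SubtypeCatalog,
) -> tuple[str, Optional[float], Optional[str]]:
    """Nearest-centroid corroboration of a subtype call.

    Correlates the case profile with every group centroid over the signature
    genes; concordant iff the nearest centroid's group equals the called
    subtype's group. Returns (status, score at own group or nearest, nearest
    group).
    """
    if len(catalog.centroids) < 2 or not expr.values:
        return ("unavailable", None, None)
    own_group = catalog.expression_group(subtype)
    genes = [g for g in catalog.signature_genes if expr.get(g) is not None]
    if len(genes) < 3:
        return ("unavailable", None, None)
    x = np.array([expr.values[g] for g in genes])
    best_group, best_r = None, -2.0
    for group, centroid in catalog.centroids.items():
        y = np.array([centroid[g] for g in genes])
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > best_r:
            best_group, best_r = group, r
    if best_group is None:
        return ("unavailable", None, None)
    if own_group not in catalog.centroids:
        return ("unavailable", best_r, best_group)
    status = "concordant" if best_group == own_group else "discordant"
    return (status, best_r, best_group)


def classify_cohort_accuracy(
    bundles: Sequence[CaseBundle],
    truths: Sequence,
    mode: str = "integrated",
    catalog: Optional[cat.SubtypeCatalog] = None,
    **run_kwargs,
) -> float:
    """Fraction of cases whose assigned subtype equals the ground truth."""
    from .synthetic import cohort_expression_baseline

    catalog = cat.default_subtype_catalog() if catalog is None else catalog
    exon_model = cat.default_exon_model()
    views = [platform_view(b, mode) for b in bundles]
    baseline = cohort_expression_baseline(views)
    correct = 0
    for view, truth in zip(views, truths):
        res = run_case(view, catalog=catalog, exon_model=exon_model,
                       expression_baseline=baseline, **run_kwargs)
        if res.subtype_call.subtype == truth.true_subtype:
            correct += 1
    return correct / len(views)
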