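"""Small-variant reporting rules, QC gates, allele-specific expression and
germline-finding categorization.

The primary somatic reporting filter requires, on WGS (or WES when the case
has no WGS), a VAF of at least 5% at a minimum of 10 total reads, for a
variant classified pathogenic or likely pathogenic. Known AML driver variants
below the VAF cut-off are eligible for rescue when corroborated either by
strong RNA-level support (WTS VAF >= 25%) or by concordance with a variant
reported in a prior sample of the same patient — the two corroboration modes
observed in practice (low-blast Down-syndrome GATA1 cases, relapsed NPM1).
Rescued variants are marked distinctly rather than silently promoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from scipy import stats

from .types import CaseBundle, VariantCall

__all__ = [
    "ReportingThresholds",
    "ReportingDecision",
    "QcAssessment",
    "AseResult",
    "GermlineFinding",
    "apply_reporting_filter",
    "assess_qc",
    "detect_allele_specific_expression",
    "categorize_germline_finding",
    "report_case_variants",
]


@dataclass(frozen=True)
class ReportingThresholds:
    """Tunable cut-offs of the reporting engine (defaults as used clinically)."""

    vaf_min: float = 0.05          # primary WGS/WES VAF cut-off
    min_total_reads: int = 10      # minimum total reads at the site
    rescue_wts_vaf: float = 0.25   # RNA corroboration for sub-threshold drivers
    ase_high: float = 0.90         # WTS VAF calling allele-specific expression
    ase_dna_band: tuple[float, float] = (0.25, 0.60)  # heterozygous DNA VAF band
    ase_min_wts_depth: int = 20
    qc_wgs_pct_exons_min: float = 40.0   # below => suboptimal WGS
    qc_wts_min_mapped_reads: float = 50e6
    qc_wts_min_coding_genes: int = 12000


@dataclass
class ReportingDecision:
    variant: VariantCall
    status: str  # reportable | rescued_reportable | not_reportable | manual_review
    reasons: list[str] = field(default_factory=list)


@dataclass
class QcAssessment:
    platform: str
    metrics: dict[str, float]
    verdict: str  # pass | suboptimal | unassessable
    notes: list[str] = field(default_factory=list)


@dataclass
class AseResult:
    status: str  # assessed | unassessable
    flagged: bool = False
    dna_vaf: Optional[float] = None
    wts_vaf: Optional[float] = None
    p_value: Optional[float] = None
    reason: str = ""


@dataclass
class GermlineFinding:
    variant: VariantCall
    gene: str
    inheritance: str         # AD | AR
    disease_domain: str      # hematologic | non_hematologic
    zygosity: str            # heterozygous | biallelic
    category: str            # AD_hematologic_predisposition | AR_biallelic_diagnosis
    #                        | AR_carrier | incidental_non_hematologic


def _dna_observation(variant: VariantCall):
    for platform in ("WGS", "WES"):
        o = variant.obs(platform)
        if o is not None:
            return platform, o
    return None, None


def apply_reporting_filter(
    variant: VariantCall,
    driver_catalog: Iterable[str],
    prior_sample_variants: Optional[set] = None,
    thresholds: ReportingThresholds = ReportingThresholds(),
) -> ReportingDecision:
    """Adjudicate one small variant against the reporting rules.

    Raises ``ValueError`` when the variant has neither a WGS nor a WES
    observation, because the primary filter cannot be evaluated.
    """
    platform, o = _dna_observation(variant)
    if o is None:
        raise ValueError(
            f"variant {variant.gene} {variant.contig}:{variant.pos} has no "
            "WGS or WES observation and cannot be adjudicated"
        )
    reasons: list[str] = []
    pathogenic = variant.pathogenicity in ("P", "LP")
    vaf_ok = o.vaf >= thresholds.vaf_min
    depth_ok = o.total_reads >= thresholds.min_total_reads
    if pathogenic and vaf_ok and depth_ok:
        return ReportingDecision(variant, "reportable", [f"primary_filter_{platform}"])

    if not pathogenic:
        reasons.append(f"pathogenicity_{variant.pathogenicity}_not_reportable")
    if not vaf_ok:
        reasons.append(f"{platform}_vaf_below_{thresholds.vaf_min:g}")
    if not depth_ok:
        reasons.append(f"{platform}_depth_below_{thresholds.min_total_reads}")

    # case-by-case rescue of sub-threshold known drivers
    if pathogenic and depth_ok and not vaf_ok and variant.gene in set(driver_catalog):
        wts = variant.obs("WTS")
        if wts is not None and wts.vaf >= thresholds.rescue_wts_vaf:
            reasons.append(f"rescued_driver_wts_vaf_ge_{thresholds.rescue_wts_vaf:g}")
            return ReportingDecision(variant, "rescued_reportable", reasons)
        if prior_sample_variants and variant.key in prior_sample_variants:
            reasons.append("rescued_driver_prior_sample_concordant")
            return ReportingDecision(variant, "rescued_reportable", reasons)
        reasons.append("driver_below_cutoff_no_corroboration")
    return ReportingDecision(variant, "not_reportable", reasons)


def report_case_variants(
    bundle: CaseBundle,
    driver_catalog: Iterable[str],
    prior_sample_variants: Optional[set] = None,
    thresholds: ReportingThresholds = ReportingThresholds(),
) -> list[ReportingDecision]:
    """Run the reporting filter over every somatic small variant of a case."""
    out = []
    for v in bundle.snv_indel_calls:
        if v.origin == "germline":
            continue
        out.append(
            apply_reporting_filter(v, driver_catalog, prior_sample_variants, thresholds)
        )
    return out


def assess_qc(
    qc_metrics: dict[str, dict[str, float]],
    thresholds: ReportingThresholds = ReportingThresholds(),
) -> list[QcAssessment]:
    """Platform QC verdicts. Suboptimal QC annotates — it never blocks analysis.

    WGS is suboptimal when fewer than 40% of exons are covered above 45x;
    WTS is suboptimal when >= 50M mapped reads yield fewer than 12,000 coding
    genes at >= 1x. Missing metrics give an explicit ``unassessable`` verdict.
    """
    out: list[QcAssessment] = []
    for platform, metrics in sorted(qc_metrics.items()):
        if platform == "WGS":
            pct = metrics.get("pct_exons_gt45x")
            if pct is None:
                out.append(QcAssessment(platform, metrics, "unassessable",
                                        ["missing metric pct_exons_gt45x"]))
            elif pct < thresholds.qc_wgs_pct_exons_min:
                out.append(QcAssessment(platform, metrics, "suboptimal",
                                        [f"pct_exons_gt45x={pct:g} < {thresholds.qc_wgs_pct_exons_min:g}"]))
            else:
                out.append(QcAssessment(platform, metrics, "pass"))
        elif platform == "WTS":
            reads = metrics.get("total_mapped_reads")
            genes = metrics.get("n_coding_genes_ge1x")
            if reads is None or genes is None:
                out.append(QcAssessment(platform, metrics, "unassessable",
                                        ["missing total_mapped_reads or n_coding_genes_ge1x"]))
            elif reads >= thresholds.qc_wts_min_mapped_reads and genes < thresholds.qc_wts_min_coding_genes:
                out.append(QcAssessment(platform, metrics, "suboptimal",
                                        [f"{genes:g} coding genes at >=1x with {reads:g} mapped reads"]))
            else:
                out.append(QcAssessment(platform, metrics, "pass"))
        else:
            out.append(QcAssessment(platform, metrics, "pass"))
    return out


def detect_allele_specific_expression(
    variant: VariantCall,
    dna_platform: str = "WGS",
    thresholds: ReportingThresholds = ReportingThresholds(),
) -> AseResult:
    """Flag exclusive expression of the mutant allele.

    ASE is flagged when the WTS VAF reaches ``ase_high`` (default 0.90) while
    the DNA VAF sits in the heterozygous band (default [0.25, 0.60]). An
    exact two-sided binomial test of the WTS alt reads against the DNA VAF is
    reported as supporting statistic.
    """
    dna = variant.obs(dna_platform)
    wts = variant.obs("WTS")
    if dna is None or wts is None:
        return AseResult("unassessable", reason="missing DNA or WTS observation")
    if wts.total_reads < thresholds.ase_min_wts_depth:
        return AseResult(
            "unassessable", dna_vaf=dna.vaf, wts_vaf=wts.vaf,
            reason=f"WTS depth {wts.total_reads} < {thresholds.ase_min_wts_depth}",
        )
    lo, hi = thresholds.ase_dna_band
    flagged = wts.vaf >= thresholds.ase_high and lo <= dna.vaf <= hi
    p = stats.binomtest(
        wts.alt_reads, wts.total_reads, p=dna.vaf, alternative="two-sided"
    ).pvalue
    return AseResult("assessed", flagged, dna.vaf, wts.vaf, float(p))


def categorize_germline_finding(
    variant: VariantCall,
    panel: dict[str, tuple[str, str]],
    case_variants: Optional[list[VariantCall]] = None,
) -> Optional[GermlineFinding]:
    """Categorize one P/LP germline variant against the predisposition panel.

    Returns ``None`` (filtered) when the gene is not on the panel. Zygosity is
    biallelic when a second P/LP germline allele of the same gene exists in
    the case, or the variant itself is homozygous (VAF >= 0.9).
    """
    if variant.origin != "germline" or variant.pathogenicity not in ("P", "LP"):
        return None
    entry = panel.get(variant.gene)
    if entry is None:
        return None
    inheritance, domain = entry
    second_allele = any(
        v.gene == variant.gene and v.key != variant.key
        and v.origin == "germline" and v.pathogenicity in ("P", "LP")
        for v in (case_variants or [])
    )
    vafs = [o.vaf for o in variant.per_platform.values()]
    homozygous = bool(vafs) and max(vafs) >= 0.9
    zygosity = "biallelic" if (second_allele or homozygous) else "heterozygous"

    if domain == "non_hematologic":
        category = "incidental_non_hematologic"
    elif inheritance == "AD":
        category = "AD_hematologic_predisposition"
    elif zygosity == "biallelic":
        category = "AR_biallelic_diagnosis"
    else:
        category = "AR_carrier"
    return GermlineFinding(
        variant=variant, gene=variant.gene, inheritance=inheritance,
        disease_domain=domain, zygosity=zygosity, category=category,
    )
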