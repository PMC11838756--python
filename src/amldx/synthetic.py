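"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a pediatric AML iWGS-WTS cohort at the
variant level (no reads): tumor purity tracks the marrow blast fraction;
per-platform read support is drawn binomially at platform-specific depths
(WGS ~61x, WES ~137x, targeted panel ~1453x, WTS expression-weighted);
drivers come from an AML subtype catalog with class frequencies matching the
study cohort breakdown; cooperating lesions, focal/large-scale CNVs with
boundary soft-clip support, germline findings and a metaphase-sampling
cytogenetics observer complete each case.

Also provides the COLO829-style dilution fixture used for limit-of-detection
analyses: 12 tumor-acquired variants (9 SNVs, 3 indels, VAFs 0.29-0.70) and a
set of 1-2 copy whole-chromosome/arm gains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import catalog as cat
from .types import (
    Breakpoint,
    CaseBundle,
    CnvSegment,
    ExpressionProfile,
    FusionTranscript,
    GroundTruth,
    ItdObservation,
    KaryotypeEvent,
    KaryotypeObservation,
    PlatformObservation,
    StructuralVariant,
    VariantCall,
)

__all__ = [
    "PlatformModel",
    "DEFAULT_PLATFORM_MODELS",
    "DEFAULT_SUBTYPE_MIX",
    "generate_cohort",
    "generate_dilution_series",
    "simulate_karyotype_observation",
    "colo829_variant_fixture",
    "colo829_lscnv_truth",
    "cohort_expression_baseline",
]


@dataclass(frozen=True)
class PlatformModel:
    """Depth/VAF sampling model for one sequencing platform.

    Depth per site is negative-binomial around the platform mean (only
    median depths are pinned down; dispersion is a knob). The observed VAF
    is binomial at the true allele fraction.
    """

    platform: str
    mean_depth: float
    depth_dispersion: float = 8.0  # NB size; larger = tighter around the mean

    def sample_depth(self, rng: np.random.Generator, weight: float = 1.0) -> int:
        mean = max(1.0, self.mean_depth * weight)
        r = self.depth_dispersion
        return int(max(1, rng.negative_binomial(r, r / (r + mean))))

    def sample_observation(
        self, rng: np.random.Generator, true_af: float, weight: float = 1.0
    ) -> PlatformObservation:
        n = self.sample_depth(rng, weight)
        k = int(rng.binomial(n, min(1.0, max(0.0, true_af))))
        return PlatformObservation(vaf=k / n, alt_reads=k, total_reads=n)


class DeterministicPlatformModel(PlatformModel):
    """Noise-free variant: depth at the platform mean, VAF at expectation."""

    def sample_depth(self, rng, weight: float = 1.0) -> int:
        return int(max(1, round(self.mean_depth * weight)))

    def sample_observation(self, rng, true_af, weight: float = 1.0) -> PlatformObservation:
        n = self.sample_depth(rng, weight)
        k = int(round(n * min(1.0, max(0.0, true_af))))
        return PlatformObservation(vaf=k / n, alt_reads=k, total_reads=n)


DEFAULT_PLATFORM_MODELS = {
    "WGS": PlatformModel("WGS", 61.0),
    "WES": PlatformModel("WES", 137.0),
    "panel": PlatformModel("panel", 1453.0),
    "WTS": PlatformModel("WTS", 60.0),
}

NOISE_FREE_PLATFORM_MODELS = {
    p: DeterministicPlatformModel(p, m.mean_depth, m.depth_dispersion)
    for p, m in DEFAULT_PLATFORM_MODELS.items()
}

# cohort subtype mix: class frequencies follow a representative pediatric
# AML cohort breakdown (91 fusion / 30 mutation / 13 newly proposed /
# 5 AML-MR / 6 novel fusion / 4 unknown / 5 Down-syndrome GATA1 out of 154),
# fusion subtypes weighted by their typical pediatric prevalence
DEFAULT_SUBTYPE_MIX: dict[str, float] = {
    "RUNX1::RUNX1T1": 0.130,
    "CBFB::MYH11": 0.078,
    "KMT2A::MLLT3": 0.078,
    "KMT2A::MLLT10": 0.045,
    "KMT2A::ELL": 0.032,
    "PML::RARA": 0.045,
    "NUP98::NSD1": 0.039,
    "NUP98::KDM5A": 0.026,
    "CBFA2T3::GLIS2": 0.032,
    "RBM15::MRTFA": 0.019,
    "DEK::NUP214": 0.019,
    "MECOM-r": 0.032,
    "HOXA-r": 0.016,
    "NPM1": 0.130,
    "CEBPA": 0.065,
    "UBTF-TD": 0.039,
    "BCL11B-r": 0.026,
    "PRDM16-r": 0.019,
    "AML-MR": 0.032,
    "TEC::MLLT10": 0.013,
    "RUNX1::CBFA2T3": 0.013,
    "RUNX1::ZEB2": 0.013,
    "unknown": 0.026,
    "DS-GATA1": 0.033,
}

# approximate genomic anchors (bp) for planted lesions
GENE_LOCI: dict[str, tuple[str, int]] = {
    "KMT2A": ("chr11", 118_436_000), "ELL": ("chr19", 18_553_000),
    "MLLT3": ("chr9", 20_341_000), "MLLT10": ("chr10", 21_524_000),
    "RUNX1": ("chr21", 34_787_000), "RUNX1T1": ("chr8", 92_003_000),
    "CBFB": ("chr16", 67_029_000), "MYH11": ("chr16", 15_703_000),
    "NUP98": ("chr11", 3_676_000), "NSD1": ("chr5", 177_133_000),
    "KDM5A": ("chr12", 389_000), "CBFA2T3": ("chr16", 88_941_000),
    "GLIS2": ("chr16", 4_382_000), "PML": ("chr15", 73_994_000),
    "RARA": ("chr17", 40_309_000), "RBM15": ("chr1", 110_338_000),
    "MRTFA": ("chr22", 40_406_000), "DEK": ("chr6", 18_225_000),
    "NUP214": ("chr9", 131_125_000), "MECOM": ("chr3", 169_083_000),
    "GATA2": ("chr3", 128_479_000), "CDK6": ("chr7", 92_604_000),
    "HOXA10": ("chr7", 27_170_000), "HOXA13": ("chr7", 27_193_000),
    "PLEK": ("chr2", 68_371_000), "BCL11B": ("chr14", 99_169_000),
    "TLX3": ("chr5", 171_299_000), "PRDM16": ("chr1", 3_069_000),
    "HSPA8": ("chr11", 123_057_000), "NPM1": ("chr5", 171_387_000),
    "CEBPA": ("chr19", 33_299_000), "GATA1": ("chrX", 48_786_000),
    "FLT3": ("chr13", 28_003_000), "KIT": ("chr4", 54_657_000),
    "CNTRL": ("chr9", 121_289_000), "UBTF": ("chr17", 44_210_000),
    "TP53": ("chr17", 7_668_000), "WT1": ("chr11", 32_387_000),
    "CBL": ("chr11", 119_206_000), "TEC": ("chr4", 47_563_000),
    "ZEB2": ("chr2", 144_384_000), "EVX1": ("chr7", 27_282_000),
    "NRAS": ("chr1", 114_704_000), "KRAS": ("chr12", 25_205_000),
    "PTPN11": ("chr12", 112_418_000), "SRSF2": ("chr17", 76_734_000),
    "ASXL1": ("chr20", 32_358_000), "STAG2": ("chrX", 124_048_000),
    "CHEK2": ("chr22", 28_687_000), "ETV6": ("chr12", 11_802_000),
    "SBDS": ("chr7", 66_987_000), "MUTYH": ("chr1", 45_329_000),
    "MITF": ("chr3", 69_739_000), "CDH1": ("chr16", 68_737_000),
    "PALB2": ("chr16", 23_603_000), "UBE2T": ("chr1", 202_330_000),
    "FANCA": ("chr16", 89_739_000), "NBN": ("chr8", 89_933_000),
}

# canonical exon junctions for planted fusions: label -> (exon5, exon3)
FUSION_JUNCTIONS: dict[str, tuple[int, int]] = {
    "PML::RARA": (6, 3),
    "RUNX1::RUNX1T1": (5, 2),
    "CBFB::MYH11": (5, 12),
    "KMT2A::MLLT3": (9, 6),
    "KMT2A::MLLT10": (9, 9),
    "KMT2A::ELL": (11, 2),
    "NUP98::NSD1": (12, 6),
    "NUP98::KDM5A": (13, 9),
    "CBFA2T3::GLIS2": (11, 3),
    "RBM15::MRTFA": (1, 4),
    "DEK::NUP214": (9, 18),
    "TEC::MLLT10": (10, 9),
    "RUNX1::CBFA2T3": (5, 2),
    "RUNX1::ZEB2": (5, 3),
    "HSPA8::PRDM16": (1, 2),
}

# fusions known to be cytogenetically cryptic (invisible to G-banding)
CRYPTIC_BANDING_FUSIONS = {"CBFA2T3::GLIS2", "NUP98::NSD1", "NUP98::KDM5A"}

_EH_PARTNERS = {"MECOM-r": "GATA2", "HOXA-r": "CDK6", "BCL11B-r": "TLX3"}
_EH_TARGETS = {"MECOM-r": "MECOM", "HOXA-r": "HOXA10", "BCL11B-r": "BCL11B"}

# FLT3-ITD cross-platform evidence pattern frequencies (17/10/1 of 28)
_ITD_PATTERN = (("confirmed", 17 / 28), ("borderline", 10 / 28), ("weak", 1 / 28))


# ---------------------------------------------------------------------------
# COLO829-style fixtures

def colo829_variant_fixture() -> list[tuple[str, float, str]]:
    """Twelve tumor-acquired variants (9 SNVs, 3 indels), VAFs 0.29-0.70."""
    snv_vafs = [0.70, 0.65, 0.61, 0.55, 0.50, 0.46, 0.42, 0.37, 0.33]
    indel_vafs = [0.68, 0.44, 0.29]
    out = [(f"COLO_SNV{i + 1}", v, "SNV") for i, v in enumerate(snv_vafs)]
    out += [(f"COLO_INDEL{i + 1}", v, "indel") for i, v in enumerate(indel_vafs)]
    return out


def colo829_lscnv_truth() -> list[dict]:
    """Large-scale 1-2 copy gains (1q and whole chromosomes 2,3,7,12,19)."""
    return [
        {"label": "+1q", "contig": "chr1", "start_mb": 124.0, "end_mb": 248.9, "delta_copies": 1},
        {"label": "+2", "contig": "chr2", "start_mb": 0.0, "end_mb": 242.1, "delta_copies": 1},
        {"label": "+3", "contig": "chr3", "start_mb": 0.0, "end_mb": 198.3, "delta_copies": 2},
        {"label": "+7", "contig": "chr7", "start_mb": 0.0, "end_mb": 159.3, "delta_copies": 1},
        {"label": "+12", "contig": "chr12", "start_mb": 0.0, "end_mb": 133.2, "delta_copies": 1},
        {"label": "+19", "contig": "chr19", "start_mb": 0.0, "end_mb": 58.6, "delta_copies": 2},
    ]


def generate_dilution_series(
    variants: Optional[list[tuple[str, float, str]]] = None,
    tumor_fractions: Sequence[float] = (1.0, 0.4, 0.3, 0.25),
    seed: int = 0,
    models: Optional[dict[str, PlatformModel]] = None,
) -> list[CaseBundle]:
    """Tumor/normal mixture series: expected VAF = original VAF x fraction.

    One CaseBundle per tumor fraction, with WGS and WES observations sampled
    at platform depths around the diluted expectation.
    """
    if variants is None:
        variants = colo829_variant_fixture()
    models = DEFAULT_PLATFORM_MODELS if models is None else models
    rng = np.random.default_rng(seed)
    bundles = []
    for frac in tumor_fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"tumor fraction {frac} outside (0, 1]")
        calls = []
        for i, (gene, vaf_orig, vclass) in enumerate(variants):
            if not 0.0 < vaf_orig <= 1.0:
                raise ValueError(f"original VAF {vaf_orig} outside (0, 1]")
            expected = vaf_orig * frac
            per_platform = {
                p: models[p].sample_observation(rng, expected) for p in ("WGS", "WES")
            }
            calls.append(
                VariantCall(
                    gene=gene, contig="chr1", pos=1_000_000 + 10_000 * i,
                    ref="A", alt="T" if vclass == "SNV" else "TA",
                    variant_class=vclass, per_platform=per_platform,
                    pathogenicity="P", origin="somatic",
                )
            )
        bundles.append(
            CaseBundle(
                case_id=f"DILUTION_{int(round(frac * 100))}",
                disease_context="de_novo",
                blast_pct=100.0 * frac,
                tumor_purity=frac,
                snv_indel_calls=calls,
            )
        )
    return bundles


# ---------------------------------------------------------------------------
# cytogenetics observer

def simulate_karyotype_observation(
    truth: GroundTruth,
    resolution_mb: float = 9.0,
    metaphases: int = 20,
    min_cells: int = 2,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> KaryotypeObservation:
    """Metaphase-sampling observer for conventional G-banded karyotyping.

    A copy-number event is visible only when its span reaches the banding
    resolution (~9 Mb at 400 bands per haploid set) and it is not cryptic by
    banding similarity; presence in each metaphase is Bernoulli in the clone
    fraction, and an event is reported only when seen in at least
    ``min_cells`` metaphases.
    """
    if metaphases < 1:
        raise ValueError("metaphases must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    visible: list[tuple[KaryotypeEvent, int]] = []
    lesions = list(truth.true_driver_lesions) + list(truth.true_cooperating_lesions)
    for les in lesions:
        if les.get("kind") != "lscnv":
            continue
        size_mb = (les["end"] - les["start"]) / 1e6
        if size_mb < resolution_mb or les.get("cryptic_banding", False):
            continue
        clone = float(les.get("clone_fraction", 1.0))
        n_seen = int(rng.binomial(metaphases, clone))
        if n_seen >= min_cells:
            visible.append(
                (
                    KaryotypeEvent(
                        kind="gain" if les["delta"] > 0 else "loss",
                        contig=les["contig"], start=les["start"], end=les["end"],
                        descriptor=les.get("label", ""),
                    ),
                    n_seen,
                )
            )
    return KaryotypeObservation(
        metaphases_analyzed=metaphases,
        visible_events=visible,
        is_complex=len(visible) >= 3,
    )


# ---------------------------------------------------------------------------
# cohort generation

def _sample_variant(
    rng, gene, vclass, pathogenicity, true_af, models, has_panel,
    wts_af=None, wts_weight=1.0, pos_offset=0,
):
    contig, pos = GENE_LOCI[gene]
    per = {
        "WGS": models["WGS"].sample_observation(rng, true_af),
        "WES": models["WES"].sample_observation(rng, true_af),
    }
    if has_panel:
        per["panel"] = models["panel"].sample_observation(rng, true_af)
    if wts_af is not None:
        per["WTS"] = models["WTS"].sample_observation(rng, wts_af, weight=wts_weight)
    ref, alt = ("A", "G") if vclass == "SNV" else ("AT", "A")
    return VariantCall(
        gene=gene, contig=contig, pos=pos + pos_offset, ref=ref, alt=alt,
        variant_class=vclass, per_platform=per,
        pathogenicity=pathogenicity, origin="somatic",
    )


def _af_factor(rng, driver: bool = True) -> float:
    """Allele-fraction multiplier on tumor purity.

    Mostly heterozygous (0.5); a minority of lesions are hemizygous or
    copy-neutral-LOH-like (0.9) or subclonal, giving the cohort the wide
    VAF spread seen in real call sets.
    """
    u = rng.random()
    if driver:
        return 0.9 if u < 0.15 else 0.5
    if u < 0.15:
        return 0.25
    if u < 0.30:
        return 0.8
    return 0.45


def _fusion_sv(rng, label: str) -> StructuralVariant:
    g5, g3 = label.split("::")
    e5, _ = FUSION_JUNCTIONS[label]
    c1, p1 = GENE_LOCI[g5]
    c2, p2 = GENE_LOCI[g3]
    return StructuralVariant(
        bp1=Breakpoint(c1, p1 + int(rng.integers(10_000, 80_000)), "+"),
        bp2=Breakpoint(c2, p2 + int(rng.integers(10_000, 60_000)), "+"),
        gene1=g5, gene2=g3,
        region1=f"intron {e5}", region2="intron 1",
        predicted_consequence="chimeric_fusion",
    )


def _eh_sv(rng, subtype: str) -> tuple[StructuralVariant, str]:
    target = _EH_TARGETS[subtype]
    partner = _EH_PARTNERS[subtype]
    if rng.random() < 0.5:
        offset = -int(rng.integers(4_000, 300_000))  # upstream
    else:
        offset = int(rng.integers(78_000, 146_000))  # downstream
    c1, p1 = GENE_LOCI[target]
    c2, p2 = GENE_LOCI[partner]
    sv = StructuralVariant(
        bp1=Breakpoint(c1, p1 + offset, "+"),
        bp2=Breakpoint(c2, p2 + int(rng.integers(50_000, 200_000)), "-"),
        gene1=target, gene2=partner,
        region1="intergenic", region2="intergenic",
        offset1=offset, offset2=int(rng.integers(50_000, 200_000)),
        predicted_consequence="possible_enhancer_hijack",
    )
    return sv, target


def _lscnv_segment(rng, purity, contig, start, end, delta, noise_sd=0.03):
    log2 = math.log2(max(0.1, (2.0 + purity * delta) / 2.0)) + rng.normal(0, noise_sd)
    return CnvSegment(
        contig=contig, start=start, end=end, log2_ratio=float(log2),
        copy_number=2 + delta,
        softclip_left=int(rng.poisson(5 * purity)),
        softclip_right=int(rng.poisson(5 * purity)),
    )


_LSCNV_COOP = {
    "del(5q)": ("chr5", 70_000_000, 160_000_000, -1),
    "del(7q)": ("chr7", 65_000_000, 155_000_000, -1),
    "-13/del(13q)": ("chr13", 20_000_000, 110_000_000, -1),
    "del(17p)": ("chr17", 0, 24_000_000, -1),
    "+8": ("chr8", 0, 145_100_000, 1),
}


def _plant_lscnv(rng, bundle, truth, purity, label, coop=True, clone_fraction=1.0):
    contig, start, end, delta = _LSCNV_COOP[label]
    seg_af = purity * clone_fraction
    bundle.cnv_segments.append(_lscnv_segment(rng, seg_af, contig, start, end, delta))
    lesion = {
        "kind": "lscnv", "label": label, "contig": contig, "start": start,
        "end": end, "delta": delta, "clone_fraction": clone_fraction,
        "cryptic_banding": False,
    }
    (truth.true_cooperating_lesions if coop else truth.true_driver_lesions).append(lesion)


def _expression_profile(rng, catalog: cat.SubtypeCatalog, subtype: str,
                        noise_sd: float, eh_target: Optional[str] = None,
                        eh_shift: float = 4.0) -> ExpressionProfile:
    group = catalog.expression_group(subtype)
    centroid = catalog.centroids.get(group)
    if centroid is None:
        # rare/novel subtype without a reference profile: its own distinct centroid
        centroid = cat._centroid_for(f"novel::{subtype}", catalog.signature_genes)
    values = {
        g: float(centroid[g] + rng.normal(0, noise_sd)) for g in catalog.signature_genes
    }
    if eh_target is not None:
        values[eh_target] = float(cat._ONCO_BASELINE + eh_shift + rng.normal(0, noise_sd))
    return ExpressionProfile(values)


def generate_cohort(
    n_cases: int,
    subtype_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    catalog: Optional[cat.SubtypeCatalog] = None,
    models: Optional[dict[str, PlatformModel]] = None,
    cryptic_wgs_rate: float = 0.0,
    cryptic_wts_rate: float = 0.0,
    panel_fraction: float = 0.25,
    expression_noise_sd: float = 0.5,
    eh_fold_shift_log2: float = 4.0,
    coop_rates: Optional[dict[str, float]] = None,
    germline_rate: float = 0.13,
    with_karyotype: bool = True,
    allow_empty: bool = False,
    noise_free: bool = False,
) -> tuple[list[CaseBundle], list[GroundTruth]]:
    """Generate a cohort of CaseBundles with ground truth.

    ``cryptic_wgs_rate``/``cryptic_wts_rate`` plant per-platform visibility
    masks on fusion drivers (a WGS-cryptic fusion has no SV call, mirroring
    insertion-mediated rearrangements; a WTS-cryptic fusion has no chimeric
    transcript). Deterministic given ``seed``.
    """
    if n_cases < 1:
        if allow_empty and n_cases == 0:
            return [], []
        raise ValueError("n_cases must be >= 1")
    catalog = cat.default_subtype_catalog() if catalog is None else catalog
    if models is None:
        models = NOISE_FREE_PLATFORM_MODELS if noise_free else DEFAULT_PLATFORM_MODELS
    subtype_mix = DEFAULT_SUBTYPE_MIX if subtype_mix is None else subtype_mix
    labels = list(subtype_mix)
    probs = np.array([subtype_mix[k] for k in labels], dtype=float)
    if not math.isclose(probs.sum(), 1.0, abs_tol=1e-6):
        raise ValueError(f"subtype_mix sums to {probs.sum():.4f}, expected 1")
    known = set(catalog.all_subtype_labels()) | set(FUSION_JUNCTIONS)
    for lab in labels:
        if lab not in known:
            raise ValueError(f"unknown subtype label in mix: {lab}")
    if coop_rates is None:
        coop_rates = {
            "FLT3-ITD": 0.12, "KIT": 0.45, "WT1": 0.08, "NRAS": 0.15,
            "del(5q)": 0.04, "del(7q)": 0.05, "-13/del(13q)": 0.04, "+8": 0.12,
            "CBL-del": 0.03, "KMT2A-PTD": 0.03,
        }
    rng = np.random.default_rng(seed)
    bundles, truths = [], []
    for i in range(n_cases):
        subtype = labels[int(rng.choice(len(labels), p=probs))]
        bundles_i, truth_i = _generate_case(
            rng, f"SYN{i + 1:04d}", subtype, catalog, models,
            cryptic_wgs_rate, cryptic_wts_rate, panel_fraction,
            expression_noise_sd, eh_fold_shift_log2, coop_rates, germline_rate,
            with_karyotype,
        )
        bundles.append(bundles_i)
        truths.append(truth_i)
    return bundles, truths


def _generate_case(
    rng, case_id, subtype, catalog, models, cryptic_wgs_rate, cryptic_wts_rate,
    panel_fraction, expr_noise, eh_shift, coop_rates, germline_rate,
    with_karyotype,
) -> tuple[CaseBundle, GroundTruth]:
    is_ds = subtype == "DS-GATA1"
    if is_ds:
        blast = float(rng.uniform(5, 15))
        context = "down_syndrome"
    else:
        blast = float(np.clip(rng.normal(66, 15), 20, 96))
        context = str(rng.choice(
            ["de_novo", "relapsed", "treatment_related"], p=[0.74, 0.18, 0.08]
        ))
    purity = blast / 100.0
    has_panel = rng.random() < panel_fraction
    bundle = CaseBundle(
        case_id=case_id, disease_context=context, blast_pct=blast,
        tumor_purity=purity,
    )
    truth = GroundTruth(case_id=case_id, true_subtype=subtype, true_purity=purity)
    eh_target: Optional[str] = None

    # --- driver lesion -----------------------------------------------------
    if subtype in FUSION_JUNCTIONS or subtype == "PRDM16-r":
        # PRDM16 rearrangements present as a chimeric fusion preserving the
        # PRDM16 5' exons, with PRDM16 overexpression via its group centroid
        label = "HSPA8::PRDM16" if subtype == "PRDM16-r" else subtype
        e5, e3 = FUSION_JUNCTIONS[label]
        sv = _fusion_sv(rng, label)
        visible_wgs = rng.random() >= cryptic_wgs_rate
        visible_wts = rng.random() >= cryptic_wts_rate
        if not visible_wgs and not visible_wts:
            visible_wts = True  # a fully invisible driver is not plantable
        if visible_wgs:
            bundle.sv_calls.append(sv)
        if visible_wts:
            reads = 1 + int(rng.poisson(14 * purity))
            bundle.fusion_transcripts.append(
                FusionTranscript(sv.gene1, e5, sv.gene2, e3, junction_reads=reads)
            )
        truth.true_driver_lesions.append({
            "kind": "fusion", "label": label, "gene5": sv.gene1, "gene3": sv.gene2,
            "visible_wgs": visible_wgs, "visible_wts": visible_wts,
            "cryptic_banding": (label in CRYPTIC_BANDING_FUSIONS) or not visible_wgs,
        })
    elif subtype in ("MECOM-r", "HOXA-r", "BCL11B-r"):
        sv, eh_target = _eh_sv(rng, subtype)
        bundle.sv_calls.append(sv)
        truth.true_driver_lesions.append({
            "kind": "enhancer_hijack", "label": subtype, "target": eh_target,
            "visible_wgs": True, "visible_wts": False, "cryptic_banding": False,
        })
    elif subtype in ("NPM1", "CEBPA", "UBTF-TD"):
        gene = {"NPM1": "NPM1", "CEBPA": "CEBPA", "UBTF-TD": "UBTF"}[subtype]
        vclass = {"NPM1": "indel", "CEBPA": "indel", "UBTF-TD": "complex_indel"}[subtype]
        true_af = _af_factor(rng, driver=True) * purity
        with_ase = subtype == "CEBPA" and rng.random() < 0.5
        wts_af = 0.95 if with_ase else true_af
        v = _sample_variant(rng, gene, vclass, "P", true_af, models, has_panel,
                            wts_af=wts_af)
        bundle.snv_indel_calls.append(v)
        truth.true_driver_lesions.append({
            "kind": "mutation", "label": subtype, "gene": gene, "key": v.key,
            "true_af": true_af, "with_ase": with_ase,
        })
    elif subtype == "AML-MR":
        # biallelic TP53 plus adverse large-scale CNVs, no other driver
        for off, factor in ((0, 0.5), (500, 0.9)):  # second hit hemizygous
            af = factor * purity
            v = _sample_variant(rng, "TP53", "SNV", "P", af, models,
                                has_panel, wts_af=af, pos_offset=off)
            bundle.snv_indel_calls.append(v)
            truth.true_driver_lesions.append({
                "kind": "mutation", "label": "TP53", "gene": "TP53", "key": v.key,
                "true_af": af,
            })
        _plant_lscnv(rng, bundle, truth, purity, "del(5q)", coop=False)
        _plant_lscnv(rng, bundle, truth, purity, "del(7q)", coop=False)
    elif subtype == "DS-GATA1":
        true_af = 0.5 * purity  # sub-5% in DNA at low blast count
        v = _sample_variant(rng, "GATA1", "indel", "P", true_af, models, has_panel,
                            wts_af=0.40)  # mutant allele enriched in the blast transcriptome
        bundle.snv_indel_calls.append(v)
        truth.true_driver_lesions.append({
            "kind": "mutation", "label": "DS-GATA1", "gene": "GATA1", "key": v.key,
            "true_af": true_af,
        })
    else:  # unknown: no driver planted
        pass

    # --- cooperating lesions ----------------------------------------------
    if rng.random() < coop_rates.get("FLT3-ITD", 0.0):
        pattern = rng.choice(
            [p for p, _ in _ITD_PATTERN], p=[w for _, w in _ITD_PATTERN]
        )
        if pattern == "confirmed":
            wgs_r, wts_r = 5 + int(rng.poisson(4)), 5 + int(rng.poisson(6))
        elif pattern == "borderline":
            wgs_r, wts_r = int(rng.integers(0, 5)), 5 + int(rng.poisson(6))
        else:
            wgs_r, wts_r = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        bundle.itd_observations.append(
            ItdObservation("FLT3", wgs_r, wts_r,
                           itd_wt_ratio=float(np.round(rng.uniform(0.05, 0.8), 2)))
        )
        truth.true_cooperating_lesions.append(
            {"kind": "itd", "label": "FLT3-ITD", "pattern": str(pattern)}
        )
    if subtype in ("RUNX1::RUNX1T1", "CBFB::MYH11") and rng.random() < coop_rates.get("KIT", 0.0):
        exon17 = rng.random() < 0.5
        kit_af = _af_factor(rng, driver=False) * purity
        v = _sample_variant(rng, "KIT", "SNV", "P", kit_af, models, has_panel,
                            wts_af=kit_af, pos_offset=120_000 if exon17 else 60_000)
        bundle.snv_indel_calls.append(v)
        truth.true_cooperating_lesions.append({
            "kind": "mutation", "label": "KIT exon 17" if exon17 else "KIT",
            "gene": "KIT", "key": v.key,
        })
    for gene, rate_key in (("WT1", "WT1"), ("NRAS", "NRAS")):
        if rng.random() < coop_rates.get(rate_key, 0.0):
            af = _af_factor(rng, driver=False) * purity
            v = _sample_variant(rng, gene, "SNV", "P", af, models,
                                has_panel, wts_af=af)
            bundle.snv_indel_calls.append(v)
            truth.true_cooperating_lesions.append(
                {"kind": "mutation", "label": gene, "gene": gene, "key": v.key}
            )
    # adverse deletions are never planted as passengers of a driverless case:
    # they would satisfy the myelodysplasia-related criteria by themselves
    coop_lscnv = ("+8",) if subtype == "unknown" else \
        ("del(5q)", "del(7q)", "-13/del(13q)", "+8")
    if subtype != "AML-MR":
        for label in coop_lscnv:
            if rng.random() < coop_rates.get(label, 0.0):
                clone = 1.0 if rng.random() < 0.8 else float(rng.uniform(0.2, 0.45))
                _plant_lscnv(rng, bundle, truth, purity, label, clone_fraction=clone)
    if rng.random() < coop_rates.get("CBL-del", 0.0):
        c, p = GENE_LOCI["CBL"]
        seg = CnvSegment(
            contig=c, start=p + 81_000, end=p + 87_000,
            log2_ratio=math.log2(max(0.1, (2 - purity) / 2)),
            copy_number=1,
            softclip_left=2 + int(rng.poisson(4 * purity)),
            softclip_right=2 + int(rng.poisson(4 * purity)),
            gene="CBL",
        )
        seg.affected_exons = [8, 9]
        bundle.cnv_segments.append(seg)
        truth.true_cooperating_lesions.append(
            {"kind": "focal_cnv", "label": "CBL del ex8-9", "gene": "CBL"}
        )
    if subtype not in ("KMT2A::MLLT3", "KMT2A::MLLT10", "KMT2A::ELL") and \
            rng.random() < coop_rates.get("KMT2A-PTD", 0.0):
        c, p = GENE_LOCI["KMT2A"]
        bundle.cnv_segments.append(
            CnvSegment(
                contig=c, start=p + 10_000, end=p + 18_000,
                log2_ratio=math.log2((2 + purity) / 2), copy_number=3,
                softclip_left=2 + int(rng.poisson(4 * purity)),
                softclip_right=2 + int(rng.poisson(4 * purity)),
                gene="KMT2A",
            )
        )
        bundle.fusion_transcripts.append(
            FusionTranscript("KMT2A", 8, "KMT2A", 2,
                             junction_reads=1 + int(rng.poisson(8 * purity)))
        )
        truth.true_cooperating_lesions.append(
            {"kind": "ptd", "label": "KMT2A-PTD", "gene": "KMT2A"}
        )

    # passenger VUS variants exercise the pathogenicity gate
    for gene in rng.choice(["PTPN11", "ASXL1", "STAG2", "SRSF2", "KRAS"],
                           size=int(rng.integers(1, 4)), replace=False):
        vus_af = _af_factor(rng, driver=False) * purity
        v = _sample_variant(rng, str(gene), "SNV", "VUS", vus_af, models,
                            has_panel, wts_af=vus_af,
                            pos_offset=int(rng.integers(1_000, 50_000)))
        bundle.snv_indel_calls.append(v)

    # --- germline findings -------------------------------------------------
    if rng.random() < germline_rate:
        pick = rng.random()
        if pick < 0.30:
            genes = [str(rng.choice(["RUNX1", "ETV6", "CHEK2", "TP53"]))]
            category = "AD_hematologic_predisposition"
        elif pick < 0.45:
            genes = ["SBDS", "SBDS"]
            category = "AR_biallelic_diagnosis"
        elif pick < 0.70:
            genes = [str(rng.choice(["FANCA", "SBDS", "NBN"]))]
            category = "AR_carrier"
        else:
            genes = [str(rng.choice(["MUTYH", "MITF", "CDH1"]))]
            category = "incidental_non_hematologic"
        for j, gene in enumerate(genes):
            contig, pos = GENE_LOCI[gene]
            af = float(np.clip(rng.normal(0.5, 0.04), 0.3, 0.7))
            obs = models["WGS"].sample_observation(rng, af)
            bundle.germline_candidates.append(
                VariantCall(
                    gene=gene, contig=contig, pos=pos + 100 + j, ref="C", alt="T",
                    variant_class="SNV", per_platform={"WGS": obs},
                    pathogenicity="P", origin="germline",
                )
            )
        truth.germline_truth.append({"genes": genes, "category": category})

    # --- expression, karyotype, QC ----------------------------------------
    bundle.expression = _expression_profile(
        rng, catalog, subtype, expr_noise, eh_target=eh_target, eh_shift=eh_shift
    )
    if with_karyotype:
        bundle.karyotype_observation = simulate_karyotype_observation(
            truth, rng=rng
        )
    pct_exons = float(np.clip(rng.normal(86.9, 6), 23, 99)) \
        if rng.random() > 0.04 else float(rng.uniform(23, 38))
    bundle.qc_metrics = {
        "WGS": {"pct_exons_gt45x": pct_exons,
                "duplication_rate": float(np.round(rng.normal(7.3, 2), 1))},
        "WTS": {"total_mapped_reads": float(rng.normal(158e6, 25e6)),
                "n_coding_genes_ge1x": float(np.clip(rng.normal(12600, 400), 10500, 14000))},
    }
    return bundle, truth


def cohort_expression_baseline(
    bundles: Sequence[CaseBundle],
) -> dict[str, np.ndarray]:
    """Per-gene arrays of expression values across a cohort (z-score baseline)."""
    genes: dict[str, list[float]] = {}
    for b in bundles:
        for g, v in b.expression.values.items():
            genes.setdefault(g, []).append(v)
    return {g: np.asarray(v) for g, v in genes.items()}
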