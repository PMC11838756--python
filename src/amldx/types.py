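"""Core domain types for integrated WGS/WTS AML diagnostics.

Conventions
-----------
* Point variants (SNVs/indels) use 1-based inclusive coordinates, following
  VCF. Segments and breakpoint intervals use 0-based half-open coordinates,
  following BED/BEDPE. Format readers/writers in :mod:`amldx.io` are the only
  place conversions happen.
* All platform observations for one small variant live on a single
  :class:`VariantCall` (wide form), because the reporting rules compare
  platforms per variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "PLATFORMS",
    "PlatformObservation",
    "VariantCall",
    "Breakpoint",
    "StructuralVariant",
    "FusionTranscript",
    "IntegratedFusionCall",
    "CnvSegment",
    "ItdObservation",
    "ItdCall",
    "ExpressionProfile",
    "KaryotypeEvent",
    "KaryotypeObservation",
    "CaseBundle",
    "GroundTruth",
    "variant_key",
]

PLATFORMS = ("WGS", "WES", "WTS", "panel")

DISEASE_CONTEXTS = ("de_novo", "relapsed", "treatment_related", "down_syndrome")
PATHOGENICITY = ("P", "LP", "VUS", "LB", "B")
ORIGINS = ("somatic", "germline", "unknown")
VARIANT_CLASSES = ("SNV", "indel", "complex_indel")

FOCAL_LSCNV_BOUNDARY_BP = 5_000_000  # focal < 5 Mb <= large-scale


@dataclass(frozen=True)
class PlatformObservation:
    """Read support for one variant on one sequencing platform."""

    vaf: float
    alt_reads: int
    total_reads: int


@dataclass
class VariantCall:
    """A small variant (SNV/indel) with per-platform read support.

    ``pos`` is 1-based; ``per_platform`` maps platform name ->
    :class:`PlatformObservation`.
    """

    gene: str
    contig: str
    pos: int
    ref: str
    alt: str
    variant_class: str = "SNV"
    per_platform: dict[str, PlatformObservation] = field(default_factory=dict)
    pathogenicity: str = "VUS"
    origin: str = "somatic"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    def obs(self, platform: str) -> Optional[PlatformObservation]:
        return self.per_platform.get(platform)

    def vaf(self, platform: str) -> Optional[float]:
        o = self.per_platform.get(platform)
        return None if o is None else o.vaf


def variant_key(v: VariantCall) -> tuple[str, int, str, str]:
    return v.key


@dataclass(frozen=True)
class Breakpoint:
    """One side of a DNA rearrangement junction (1-based position)."""

    contig: str
    pos: int
    strand: str = "+"


@dataclass
class StructuralVariant:
    """A DNA-level rearrangement as a breakpoint pair with gene annotations.

    ``offset1``/``offset2`` are signed distances (bp) from the breakpoint to
    the nearest annotated gene when the breakpoint is intergenic: negative
    means upstream of the gene's transcription start, positive downstream of
    its end, 0 means intragenic.
    """

    bp1: Breakpoint
    bp2: Breakpoint
    gene1: str = ""
    gene2: str = ""
    region1: str = ""  # e.g. "intron 11", "exon 9", "intergenic"
    region2: str = ""
    offset1: int = 0
    offset2: int = 0
    predicted_consequence: str = "other"  # chimeric_fusion | possible_enhancer_hijack | other

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene1, self.gene2)


@dataclass
class FusionTranscript:
    """An RNA-level chimeric transcript candidate from WTS."""

    gene5: str
    exon5: int
    gene3: str
    exon3: int
    junction_reads: int = 0
    in_frame: Optional[bool] = None


@dataclass
class IntegratedFusionCall:
    """A DNA rearrangement joined with RNA evidence and a mechanism call.

    ``sv`` may be None for a call supported by RNA evidence alone (e.g. a
    chimeric transcript whose DNA junction was cryptic to WGS).
    """

    sv: Optional[StructuralVariant] = None
    transcript: Optional[FusionTranscript] = None
    mechanism: str = "unconfirmed"  # chimeric_fusion | enhancer_hijacking | unconfirmed
    evidence: set[str] = field(default_factory=set)  # WGS_SV, WTS_transcript, WTS_overexpression
    confirmation_needed: bool = False
    reasons: list[str] = field(default_factory=list)
    target_gene: str = ""  # dysregulated oncogene for enhancer hijacking

    @property
    def gene_pair(self) -> tuple[str, str]:
        if self.transcript is not None:
            return (self.transcript.gene5, self.transcript.gene3)
        if self.sv is not None:
            return (self.sv.gene1, self.sv.gene2)
        return ("", "")

    @property
    def label(self) -> str:
        if self.mechanism == "enhancer_hijacking":
            return f"{self.target_gene}-r"
        g5, g3 = self.gene_pair
        return f"{g5}::{g3}"


@dataclass
class CnvSegment:
    """A copy-number segment (0-based half-open interval).

    ``softclip_left``/``softclip_right`` count boundary soft-clipped reads,
    the orthogonal WGS evidence used to validate focal events.
    """

    contig: str
    start: int
    end: int
    log2_ratio: float
    copy_number: Optional[int] = None
    softclip_left: int = 0
    softclip_right: int = 0
    gene: str = ""
    diagnostic_status: str = "unevaluated"  # meets_criteria | fragmented | rejected | unevaluated
    affected_exons: list[int] = field(default_factory=list)

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    @property
    def size_class(self) -> str:
        return "focal" if self.size_bp < FOCAL_LSCNV_BOUNDARY_BP else "large_scale"

    @property
    def direction(self) -> str:
        return "gain" if self.log2_ratio > 0 else "loss"


@dataclass
class ItdObservation:
    """Raw internal-tandem-duplication read support on DNA and RNA."""

    gene: str = "FLT3"
    wgs_junction_reads: int = 0
    wts_junction_reads: int = 0
    itd_wt_ratio: Optional[float] = None


@dataclass
class ItdCall:
    gene: str
    wgs_evidence: str  # strong | weak | none
    wts_evidence: str
    tier: str  # confirmed | borderline | weak
    orthogonal_confirmation_recommended: bool
    itd_wt_ratio: Optional[float] = None


@dataclass
class ExpressionProfile:
    """Per-case gene expression (log2-scale values keyed by gene symbol)."""

    values: dict[str, float] = field(default_factory=dict)

    def get(self, gene: str) -> Optional[float]:
        v = self.values.get(gene)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v


@dataclass
class KaryotypeEvent:
    """A cytogenetically visible chromosome abnormality.

    ``start``/``end`` are 0-based half-open genomic coordinates of the
    affected region; ``kind`` is ``gain`` or ``loss``.
    """

    kind: str
    contig: str
    start: int
    end: int
    descriptor: str = ""


@dataclass
class KaryotypeObservation:
    """Result of conventional G-banded karyotyping on cultured metaphases."""

    metaphases_analyzed: int = 20
    visible_events: list[tuple[KaryotypeEvent, int]] = field(default_factory=list)
    is_complex: bool = False


@dataclass
class CaseBundle:
    """All platform observations for one case plus clinical metadata."""

    case_id: str
    disease_context: str = "de_novo"
    blast_pct: float = 0.0
    tumor_purity: Optional[float] = None
    snv_indel_calls: list[VariantCall] = field(default_factory=list)
    sv_calls: list[StructuralVariant] = field(default_factory=list)
    fusion_transcripts: list[FusionTranscript] = field(default_factory=list)
    cnv_segments: list[CnvSegment] = field(default_factory=list)
    itd_observations: list[ItdObservation] = field(default_factory=list)
    expression: ExpressionProfile = field(default_factory=ExpressionProfile)
    germline_candidates: list[VariantCall] = field(default_factory=list)
    karyotype_observation: Optional[KaryotypeObservation] = None
    qc_metrics: dict[str, dict[str, float]] = field(default_factory=dict)

    def sorted_copy(self) -> "CaseBundle":
        """Canonically sorted copy (used for order-insensitivity checks)."""
        b = replace(self)
        b.snv_indel_calls = sorted(self.snv_indel_calls, key=lambda v: v.key)
        b.germline_candidates = sorted(self.germline_candidates, key=lambda v: v.key)
        b.sv_calls = sorted(
            self.sv_calls, key=lambda s: (s.bp1.contig, s.bp1.pos, s.bp2.contig, s.bp2.pos)
        )
        b.cnv_segments = sorted(self.cnv_segments, key=lambda s: (s.contig, s.start, s.end))
        b.fusion_transcripts = sorted(
            self.fusion_transcripts, key=lambda t: (t.gene5, t.exon5, t.gene3, t.exon3)
        )
        b.itd_observations = sorted(self.itd_observations, key=lambda o: o.gene)
        return b


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic case."""

    case_id: str
    true_subtype: str
    true_driver_lesions: list[dict] = field(default_factory=list)
    true_cooperating_lesions: list[dict] = field(default_factory=list)
    true_purity: float = 1.0
    germline_truth: list[dict] = field(default_factory=list)
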