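"""Readers/writers for the per-case file set and bundle validation.

A case is stored as a directory with a JSON manifest referencing:

* per-platform VCF v4.2 files for small variants (VAF from AD/DP; gene,
  variant class, pathogenicity and origin in INFO keys GENE/VCLASS/PCLASS/
  ORIGIN),
* a BEDPE file for SV breakpoint pairs (6 coordinate columns, strands,
  partner-gene annotations),
* a SEG-like TSV for CNV segments (with boundary soft-clip read counts),
* TSVs for chimeric-transcript candidates, FLT3-ITD observations and the
  per-case expression profile,
* a germline-candidate VCF,
* karyotype observation and QC metrics inline in the manifest.

Coordinate conventions follow each format: VCF positions are 1-based,
BEDPE/SEG intervals 0-based half-open; these functions are the only place
conversions happen.
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path
from typing import Optional

import pandas as pd
import pysam

from .types import (
    PLATFORMS,
    Breakpoint,
    CaseBundle,
    CnvSegment,
    ExpressionProfile,
    FusionTranscript,
    ItdObservation,
    KaryotypeEvent,
    KaryotypeObservation,
    PlatformObservation,
    StructuralVariant,
    VariantCall,
)

__all__ = [
    "BundleValidationError",
    "load_case_bundle",
    "write_case_bundle",
    "validate_bundle",
    "read_variant_vcf",
    "write_variant_vcf",
    "read_bedpe",
    "write_bedpe",
    "read_seg",
    "write_seg",
    "write_expression_matrix",
    "read_expression_matrix",
]


class BundleValidationError(ValueError):
    """Raised when on-disk records violate a type invariant at load time."""


# ---------------------------------------------------------------------------
# VCF

_VCF_INFO = [
    ("GENE", "1", "String", "Gene symbol"),
    ("VCLASS", "1", "String", "Variant class (SNV/indel/complex_indel)"),
    ("PCLASS", "1", "String", "Pathogenicity class (P/LP/VUS/LB/B)"),
    ("ORIGIN", "1", "String", "Variant origin (somatic/germline/unknown)"),
]


def _vcf_header(contigs: list[str]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in contigs:
        h.contigs.add(c, length=300_000_000)
    for ident, num, typ, desc in _VCF_INFO:
        h.info.add(ident, num, typ, desc)
    h.formats.add("AD", "R", "Integer", "Allelic depths (ref,alt)")
    h.formats.add("DP", "1", "Integer", "Total read depth")
    h.add_sample("TUMOR")
    return h


def write_variant_vcf(path, variants: list[VariantCall], platform: str) -> None:
    """Write the given platform's observations of ``variants`` as VCF."""
    recs = [v for v in variants if platform in v.per_platform]
    contigs = sorted({v.contig for v in recs}) or ["chr1"]
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(recs, key=lambda x: (x.contig, x.pos, x.ref, x.alt)):
            o = v.per_platform[platform]
            rec = vf.new_record(
                contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.info["GENE"] = v.gene
            rec.info["VCLASS"] = v.variant_class
            rec.info["PCLASS"] = v.pathogenicity
            rec.info["ORIGIN"] = v.origin
            rec.samples["TUMOR"]["AD"] = (o.total_reads - o.alt_reads, o.alt_reads)
            rec.samples["TUMOR"]["DP"] = o.total_reads
            vf.write(rec)


def read_variant_vcf(path, platform: str) -> list[VariantCall]:
    """Read one platform's VCF into VariantCalls (one per_platform entry)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"VCF not found: {path}")
    out: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf):
            try:
                ad = rec.samples["TUMOR"]["AD"]
                dp = int(rec.samples["TUMOR"]["DP"])
                alt_reads = int(ad[1])
            except (KeyError, TypeError, IndexError) as e:
                raise BundleValidationError(
                    f"{path}: record {i + 1}: missing AD/DP fields ({e})"
                ) from e
            if alt_reads > dp:
                raise BundleValidationError(
                    f"{path}: record {i + 1}: alt_reads {alt_reads} > total_reads {dp}"
                )
            vaf = alt_reads / dp if dp > 0 else 0.0
            out.append(
                VariantCall(
                    gene=rec.info.get("GENE", ""),
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else "",
                    variant_class=rec.info.get("VCLASS", "SNV"),
                    pathogenicity=rec.info.get("PCLASS", "VUS"),
                    origin=rec.info.get("ORIGIN", "somatic"),
                    per_platform={
                        platform: PlatformObservation(vaf, alt_reads, dp)
                    },
                )
            )
    return out


def merge_platform_calls(per_platform_lists: dict[str, list[VariantCall]]) -> list[VariantCall]:
    """Merge per-platform variant lists into wide records keyed by
    (contig, pos, ref, alt)."""
    merged: dict[tuple, VariantCall] = {}
    for platform in PLATFORMS:
        for v in per_platform_lists.get(platform, []):
            if v.key not in merged:
                merged[v.key] = VariantCall(
                    gene=v.gene, contig=v.contig, pos=v.pos, ref=v.ref, alt=v.alt,
                    variant_class=v.variant_class, pathogenicity=v.pathogenicity,
                    origin=v.origin,
                )
            merged[v.key].per_platform.update(v.per_platform)
    return sorted(merged.values(), key=lambda v: v.key)


# ---------------------------------------------------------------------------
# BEDPE / SEG / TSV tables

_BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
    "strand1", "strand2", "gene1", "gene2", "region1", "region2",
    "offset1", "offset2", "consequence",
]


def write_bedpe(path, svs: list[StructuralVariant]) -> None:
    rows = []
    for i, s in enumerate(svs):
        rows.append(
            [
                s.bp1.contig, s.bp1.pos - 1, s.bp1.pos,
                s.bp2.contig, s.bp2.pos - 1, s.bp2.pos,
                f"sv{i + 1}", ".", s.bp1.strand, s.bp2.strand,
                s.gene1, s.gene2, s.region1 or ".", s.region2 or ".",
                s.offset1, s.offset2, s.predicted_consequence,
            ]
        )
    pd.DataFrame(rows, columns=_BEDPE_COLS).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bedpe(path) -> list[StructuralVariant]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"BEDPE not found: {path}")
    if os.path.getsize(path) == 0:
        return []
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_BEDPE_COLS)
    except Exception as e:  # noqa: BLE001 - surface parse position
        raise BundleValidationError(f"{path}: malformed BEDPE ({e})") from e
    out = []
    for i, r in df.iterrows():
        try:
            out.append(
                StructuralVariant(
                    bp1=Breakpoint(str(r.chrom1), int(r.end1), str(r.strand1)),
                    bp2=Breakpoint(str(r.chrom2), int(r.end2), str(r.strand2)),
                    gene1=str(r.gene1), gene2=str(r.gene2),
                    region1="" if str(r.region1) == "." else str(r.region1),
                    region2="" if str(r.region2) == "." else str(r.region2),
                    offset1=int(r.offset1), offset2=int(r.offset2),
                    predicted_consequence=str(r.consequence),
                )
            )
        except (ValueError, TypeError) as e:
            raise BundleValidationError(f"{path}: line {i + 1}: {e}") from e
    return out


_SEG_COLS = [
    "case_id", "contig", "start", "end", "log2_ratio", "copy_number",
    "softclip_left", "softclip_right", "gene",
]


def write_seg(path, case_id: str, segments: list[CnvSegment]) -> None:
    rows = [
        [case_id, s.contig, s.start, s.end, s.log2_ratio,
         "" if s.copy_number is None else s.copy_number,
         s.softclip_left, s.softclip_right, s.gene or "."]
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False)


def read_seg(path) -> list[CnvSegment]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"SEG file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    out = []
    for i, r in df.iterrows():
        start, end = int(r.start), int(r.end)
        if end < start:
            raise BundleValidationError(f"{path}: line {i + 2}: end < start")
        cn = None if pd.isna(r.copy_number) else int(r.copy_number)
        out.append(
            CnvSegment(
                contig=str(r.contig), start=start, end=end,
                log2_ratio=float(r.log2_ratio), copy_number=cn,
                softclip_left=int(r.softclip_left),
                softclip_right=int(r.softclip_right),
                gene="" if str(r.gene) == "." else str(r.gene),
            )
        )
    return out


def write_fusion_tsv(path, transcripts: list[FusionTranscript]) -> None:
    rows = [
        [t.gene5, t.exon5, t.gene3, t.exon3, t.junction_reads,
         "" if t.in_frame is None else str(t.in_frame)]
        for t in transcripts
    ]
    pd.DataFrame(
        rows, columns=["gene5", "exon5", "gene3", "exon3", "junction_reads", "in_frame"]
    ).to_csv(path, sep="\t", index=False)


def read_fusion_tsv(path) -> list[FusionTranscript]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"fusion TSV not found: {path}")
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        in_frame = None
        if not pd.isna(r.in_frame) and str(r.in_frame) != "":
            in_frame = str(r.in_frame) == "True"
        out.append(
            FusionTranscript(
                gene5=str(r.gene5), exon5=int(r.exon5),
                gene3=str(r.gene3), exon3=int(r.exon3),
                junction_reads=int(r.junction_reads), in_frame=in_frame,
            )
        )
    return out


def write_itd_tsv(path, obs: list[ItdObservation]) -> None:
    rows = [
        [o.gene, o.wgs_junction_reads, o.wts_junction_reads,
         "" if o.itd_wt_ratio is None else o.itd_wt_ratio]
        for o in obs
    ]
    pd.DataFrame(
        rows, columns=["gene", "wgs_junction_reads", "wts_junction_reads", "itd_wt_ratio"]
    ).to_csv(path, sep="\t", index=False)


def read_itd_tsv(path) -> list[ItdObservation]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"ITD TSV not found: {path}")
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        ratio = None if pd.isna(r.itd_wt_ratio) else float(r.itd_wt_ratio)
        out.append(
            ItdObservation(
                gene=str(r.gene),
                wgs_junction_reads=int(r.wgs_junction_reads),
                wts_junction_reads=int(r.wts_junction_reads),
                itd_wt_ratio=ratio,
            )
        )
    return out


def write_expression_tsv(path, expr: ExpressionProfile) -> None:
    pd.DataFrame(
        sorted(expr.values.items()), columns=["gene", "log2_value"]
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> ExpressionProfile:
    if not os.path.exists(path):
        raise FileNotFoundError(f"expression TSV not found: {path}")
    df = pd.read_csv(path, sep="\t")
    return ExpressionProfile({str(r.gene): float(r.log2_value) for _, r in df.iterrows()})


def write_expression_matrix(path, cohort: dict[str, ExpressionProfile]) -> None:
    """Write a gene x case matrix TSV for a cohort of expression profiles."""
    df = pd.DataFrame({cid: e.values for cid, e in cohort.items()}).sort_index()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_expression_matrix(path) -> dict[str, ExpressionProfile]:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return {c: ExpressionProfile(df[c].dropna().to_dict()) for c in df.columns}


# ---------------------------------------------------------------------------
# Manifest / bundle

def _karyotype_to_json(k: Optional[KaryotypeObservation]):
    if k is None:
        return None
    return {
        "metaphases_analyzed": k.metaphases_analyzed,
        "is_complex": k.is_complex,
        "visible_events": [
            {
                "kind": e.kind, "contig": e.contig, "start": e.start,
                "end": e.end, "descriptor": e.descriptor, "n_metaphases": n,
            }
            for e, n in k.visible_events
        ],
    }


def _karyotype_from_json(d) -> Optional[KaryotypeObservation]:
    if d is None:
        return None
    return KaryotypeObservation(
        metaphases_analyzed=int(d["metaphases_analyzed"]),
        is_complex=bool(d["is_complex"]),
        visible_events=[
            (
                KaryotypeEvent(
                    kind=e["kind"], contig=e["contig"], start=int(e["start"]),
                    end=int(e["end"]), descriptor=e.get("descriptor", ""),
                ),
                int(e["n_metaphases"]),
            )
            for e in d["visible_events"]
        ],
    )


def write_case_bundle(bundle: CaseBundle, out_dir) -> Path:
    """Write the full file set for one case; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    b = bundle.sorted_copy()
    snv_files = {}
    for platform in PLATFORMS:
        if any(platform in v.per_platform for v in b.snv_indel_calls):
            fn = f"snv_{platform.lower()}.vcf"
            write_variant_vcf(out / fn, b.snv_indel_calls, platform)
            snv_files[platform] = fn
    write_bedpe(out / "sv.bedpe", b.sv_calls)
    write_seg(out / "cnv.seg", b.case_id, b.cnv_segments)
    write_fusion_tsv(out / "fusions.tsv", b.fusion_transcripts)
    write_itd_tsv(out / "itd.tsv", b.itd_observations)
    write_expression_tsv(out / "expression.tsv", b.expression)
    write_variant_vcf(out / "germline.vcf", b.germline_candidates, "WGS")
    manifest = {
        "case_id": b.case_id,
        "disease_context": b.disease_context,
        "blast_pct": b.blast_pct,
        "tumor_purity": b.tumor_purity,
        "snv_indel_vcf": snv_files,
        "sv_bedpe": "sv.bedpe",
        "cnv_seg": "cnv.seg",
        "fusion_tsv": "fusions.tsv",
        "itd_tsv": "itd.tsv",
        "expression_tsv": "expression.tsv",
        "germline_vcf": "germline.vcf",
        "karyotype": _karyotype_to_json(b.karyotype_observation),
        "qc_metrics": b.qc_metrics,
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return mpath


def load_case_bundle(manifest_path) -> CaseBundle:
    """Load and validate a case bundle from its JSON manifest.

    Platform records are merged per variant by (contig, pos, ref, alt);
    output lists are canonically sorted so loading is order-insensitive.
    """
    mpath = Path(manifest_path)
    if not mpath.exists():
        raise FileNotFoundError(f"manifest not found: {mpath}")
    with open(mpath) as fh:
        m = json.load(fh)
    base = mpath.parent
    per_platform = {
        p: read_variant_vcf(base / fn, p) for p, fn in m.get("snv_indel_vcf", {}).items()
    }
    germ = read_variant_vcf(base / m["germline_vcf"], "WGS") if m.get("germline_vcf") else []
    for g in germ:
        g.origin = "germline"
    bundle = CaseBundle(
        case_id=m["case_id"],
        disease_context=m.get("disease_context", "de_novo"),
        blast_pct=float(m.get("blast_pct", 0.0)),
        tumor_purity=m.get("tumor_purity"),
        snv_indel_calls=merge_platform_calls(per_platform),
        sv_calls=read_bedpe(base / m["sv_bedpe"]) if m.get("sv_bedpe") else [],
        fusion_transcripts=read_fusion_tsv(base / m["fusion_tsv"]) if m.get("fusion_tsv") else [],
        cnv_segments=read_seg(base / m["cnv_seg"]) if m.get("cnv_seg") else [],
        itd_observations=read_itd_tsv(base / m["itd_tsv"]) if m.get("itd_tsv") else [],
        expression=read_expression_tsv(base / m["expression_tsv"]) if m.get("expression_tsv") else ExpressionProfile(),
        germline_candidates=germ,
        karyotype_observation=_karyotype_from_json(m.get("karyotype")),
        qc_metrics=m.get("qc_metrics", {}),
    )
    return bundle.sorted_copy()


def validate_bundle(bundle: CaseBundle) -> list[str]:
    """Check all type invariants; returns human-readable messages (never throws)."""
    msgs: list[str] = []
    cid = bundle.case_id

    def bad(msg: str) -> None:
        msgs.append(f"{cid}: {msg}")

    if not 0.0 <= bundle.blast_pct <= 100.0:
        bad(f"blast_pct {bundle.blast_pct} outside [0, 100]")
    if bundle.tumor_purity is not None and not 0.0 <= bundle.tumor_purity <= 1.0:
        bad(f"tumor_purity {bundle.tumor_purity} outside [0, 1]")
    for v in list(bundle.snv_indel_calls) + list(bundle.germline_candidates):
        for platform, o in v.per_platform.items():
            tag = f"variant {v.gene} {v.contig}:{v.pos} {v.ref}>{v.alt} [{platform}]"
            if not 0.0 <= o.vaf <= 1.0:
                bad(f"{tag}: VAF {o.vaf} outside [0, 1]")
            elif o.alt_reads > o.total_reads:
                bad(f"{tag}: alt_reads {o.alt_reads} > total_reads {o.total_reads}")
            elif o.total_reads > 0:
                tol = 1.0 / o.total_reads
                if not math.isclose(o.vaf, o.alt_reads / o.total_reads, abs_tol=tol + 1e-9):
                    bad(f"{tag}: VAF {o.vaf} inconsistent with {o.alt_reads}/{o.total_reads}")
        if v.pathogenicity not in ("P", "LP", "VUS", "LB", "B"):
            bad(f"variant {v.gene}: unknown pathogenicity {v.pathogenicity!r}")
    for s in bundle.cnv_segments:
        if s.end < s.start:
            bad(f"CNV segment {s.contig}:{s.start}-{s.end}: end < start")
        if s.softclip_left < 0 or s.softclip_right < 0:
            bad(f"CNV segment {s.contig}:{s.start}-{s.end}: negative soft-clip count")
    for t in bundle.fusion_transcripts:
        if t.junction_reads < 0:
            bad(f"fusion transcript {t.gene5}::{t.gene3}: negative junction_reads")
    k = bundle.karyotype_observation
    if k is not None:
        if k.metaphases_analyzed < 20:
            bad(
                f"karyotype study analyzed {k.metaphases_analyzed} metaphases "
                "(a valid study requires >= 20)"
            )
        for e, n in k.visible_events:
            if n > k.metaphases_analyzed:
                bad(
                    f"karyotype event {e.descriptor or e.kind}: seen in {n} "
                    f"of {k.metaphases_analyzed} metaphases"
                )
    return msgs
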