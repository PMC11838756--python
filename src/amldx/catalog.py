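"""Reference catalogs: AML subtypes, exon models, germline panel, genome.

All catalogs ship as small editable text files under ``amldx/data`` and are
loaded through the functions here; programmatic defaults are provided so the
package works with no external configuration. Expression centroids are
synthetic (deterministically generated per subtype group) — they exercise the
nearest-centroid corroboration logic, they are not trained on real cohorts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "GENOME_MB",
    "CENTROMERE_MB",
    "ExonModel",
    "SubtypeCatalog",
    "default_subtype_catalog",
    "default_exon_model",
    "load_exon_model",
    "default_germline_panel",
    "load_germline_panel",
    "default_aml_mr_table",
    "default_relevance_table",
    "default_driver_gene_catalog",
    "ENHANCER_HIJACK_TARGETS",
]

# hg38 chromosome sizes (Mb) used by the synthetic genome and arm arithmetic
GENOME_MB = {
    "chr1": 248.96, "chr2": 242.19, "chr3": 198.30, "chr4": 190.21,
    "chr5": 181.54, "chr6": 170.81, "chr7": 159.35, "chr8": 145.14,
    "chr9": 138.39, "chr10": 133.80, "chr11": 135.09, "chr12": 133.28,
    "chr13": 114.36, "chr14": 107.04, "chr15": 101.99, "chr16": 90.34,
    "chr17": 83.26, "chr18": 80.37, "chr19": 58.62, "chr20": 64.44,
    "chr21": 46.71, "chr22": 50.82, "chrX": 156.04,
}

# approximate centromere midpoints (Mb)
CENTROMERE_MB = {
    "chr1": 123.4, "chr2": 93.9, "chr3": 90.9, "chr4": 50.0, "chr5": 48.8,
    "chr6": 59.8, "chr7": 60.1, "chr8": 45.2, "chr9": 43.0, "chr10": 39.8,
    "chr11": 53.4, "chr12": 35.5, "chr13": 17.7, "chr14": 17.2, "chr15": 19.0,
    "chr16": 36.8, "chr17": 25.1, "chr18": 18.5, "chr19": 26.2, "chr20": 28.1,
    "chr21": 12.0, "chr22": 15.0, "chrX": 61.0,
}


class ExonModel:
    """Per-gene exon coding lengths with cumulative-phase queries.

    Exons are indexed 1-based. ``phase_after(g, e)`` is the reading-frame
    offset (0/1/2) immediately after the last base of exon ``e``;
    ``phase_before(g, e)`` is the offset expected at the first base of exon
    ``e``. A junction ``(g5, e5) -> (g3, e3)`` preserves the reading frame iff
    ``phase_after(g5, e5) == phase_before(g3, e3)``.
    """

    def __init__(self, lengths: dict[str, list[int]]):
        self._lengths = {g: list(v) for g, v in lengths.items()}
        self._cum = {g: np.cumsum([0] + list(v)) for g, v in lengths.items()}

    def __contains__(self, gene: str) -> bool:
        return gene in self._lengths

    def genes(self) -> list[str]:
        return sorted(self._lengths)

    def n_exons(self, gene: str) -> int:
        return len(self._lengths[gene])

    def exon_length(self, gene: str, exon: int) -> int:
        return self._lengths[gene][exon - 1]

    def phase_after(self, gene: str, exon: int) -> int:
        return int(self._cum[gene][exon]) % 3

    def phase_before(self, gene: str, exon: int) -> int:
        return int(self._cum[gene][exon - 1]) % 3

    def junction_in_frame(self, gene5: str, exon5: int, gene3: str, exon3: int) -> bool:
        return self.phase_after(gene5, exon5) == self.phase_before(gene3, exon3)


def load_exon_model(path) -> ExonModel:
    """Read a GTF-like TSV (gene, exon_index, coding_length) into an ExonModel."""
    rows: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            gene, idx, length = ln.rstrip("\n").split("\t")[:3]
            rows.setdefault(gene, {})[int(idx)] = int(length)
    return ExonModel({g: [d[i] for i in sorted(d)] for g, d in rows.items()})


def default_exon_model() -> ExonModel:
    with resources.as_file(resources.files("amldx.data") / "exon_model.tsv") as p:
        return load_exon_model(p)


@dataclass
class SubtypeCatalog:
    """Ranked driver catalog for molecular subtype assignment.

    Lists are ranked: when multiple same-tier drivers co-occur the earlier
    entry is reported as primary (the others are retained as secondary).
    """

    class_defining_fusions: list[str] = field(default_factory=list)
    fusion_5prime_genes: list[str] = field(default_factory=list)  # any in-frame fusion from these 5' genes is class-defining
    class_defining_mutations: list[str] = field(default_factory=list)
    newly_proposed: list[str] = field(default_factory=list)
    # chimeric fusions involving these genes belong to a newly proposed class
    newly_proposed_fusion_genes: dict[str, str] = field(default_factory=dict)
    aml_mr_mutations: list[str] = field(default_factory=list)
    ds_gene: str = "GATA1"
    groupings: dict[str, str] = field(default_factory=dict)
    signature_genes: list[str] = field(default_factory=list)
    centroids: dict[str, dict[str, float]] = field(default_factory=dict)

    def fusion_rank(self, label: str) -> Optional[int]:
        """Rank of a fusion label among class-defining fusions, else None."""
        if label in self.class_defining_fusions:
            return self.class_defining_fusions.index(label)
        g5 = label.split("::")[0] if "::" in label else label
        if g5 in self.fusion_5prime_genes:
            return len(self.class_defining_fusions) + self.fusion_5prime_genes.index(g5)
        return None

    def expression_group(self, subtype: str) -> str:
        return self.groupings.get(subtype, subtype)

    def all_subtype_labels(self) -> list[str]:
        return (
            list(self.class_defining_fusions)
            + list(self.class_defining_mutations)
            + list(self.newly_proposed)
            + ["AML-MR", "DS-GATA1", "unknown"]
        )


# genes whose overexpression after a nearby non-coding rearrangement is
# interpreted as enhancer hijacking; value = subtype label of the event
ENHANCER_HIJACK_TARGETS = {
    "MECOM": "MECOM-r",
    "HOXA9": "HOXA-r",
    "HOXA10": "HOXA-r",
    "HOXA13": "HOXA-r",
    "BCL11B": "BCL11B-r",
    "TLX3": "BCL11B-r",
    "NKX2-5": "BCL11B-r",
}

_FUSION_SUBTYPES = [
    "PML::RARA",
    "RUNX1::RUNX1T1",
    "CBFB::MYH11",
    "KMT2A::MLLT3",
    "KMT2A::MLLT10",
    "KMT2A::ELL",
    "NUP98::NSD1",
    "NUP98::KDM5A",
    "CBFA2T3::GLIS2",
    "RBM15::MRTFA",
    "DEK::NUP214",
    "MECOM-r",
    "HOXA-r",
]

_SIGNATURE_EXTRA = [f"SIG{i:02d}" for i in range(1, 31)]
_SIGNATURE_ONCO = [
    "MECOM", "PRDM16", "HOXA9", "HOXA10", "HOXA13", "BCL11B", "TLX3",
    "NKX2-5", "CEBPA", "NPM1", "UBTF", "GATA1",
]


# oncogene expression shifts (log2) characteristic of each expression group;
# all other groups keep the flat baseline for these genes
_ONCO_BASELINE = 5.0
_ONCO_SHIFTS: dict[str, dict[str, float]] = {
    "PRDM16/MECOM-r": {"MECOM": 4.0, "PRDM16": 4.0},
    "BCL11B-r": {"BCL11B": 4.0},
    "HOXA-r": {"HOXA9": 3.0, "HOXA10": 4.0, "HOXA13": 4.0},
    "NPM1": {"HOXA9": 2.0, "HOXA10": 2.0},
    "KMT2A::MLLT3": {"HOXA9": 2.5, "HOXA10": 2.5},
    "KMT2A::MLLT10": {"HOXA9": 2.5, "HOXA10": 2.5},
    "KMT2A::ELL": {"HOXA9": 2.5, "HOXA10": 2.5},
    "DS-GATA1": {"GATA1": 2.0},
}


def _centroid_for(group: str, genes: list[str]) -> dict[str, float]:
    """Deterministic synthetic centroid: log2 expression per signature gene.

    Oncogenes carry a flat cross-group baseline (so cohort-wide robust
    z-scores are meaningful) plus group-specific shifts; the remaining
    signature genes take group-specific pseudo-random values.
    """
    seed = int.from_bytes(hashlib.sha256(group.encode()).digest()[:4], "big")
    rng = np.random.default_rng(seed)
    vals: dict[str, float] = {}
    for g in genes:
        if g in _SIGNATURE_ONCO:
            vals[g] = _ONCO_BASELINE
        else:
            vals[g] = float(rng.normal(5.0, 2.0))
    for g, shift in _ONCO_SHIFTS.get(group, {}).items():
        if g in vals:
            vals[g] += shift
    return vals


def default_subtype_catalog() -> SubtypeCatalog:
    groupings = {
        "RUNX1::CBFA2T3": "RUNX1::RUNX1T1",
        "RUNX1::CBFA2T2": "RUNX1::RUNX1T1",
        "MECOM-r": "PRDM16/MECOM-r",
        "PRDM16-r": "PRDM16/MECOM-r",
    }
    genes = _SIGNATURE_ONCO + _SIGNATURE_EXTRA
    groups = set()
    for label in (
        _FUSION_SUBTYPES
        + ["NPM1", "CEBPA", "UBTF-TD", "BCL11B-r", "PRDM16-r", "AML-MR", "DS-GATA1"]
    ):
        groups.add(groupings.get(label, label))
    centroids = {g: _centroid_for(g, genes) for g in sorted(groups)}
    return SubtypeCatalog(
        class_defining_fusions=list(_FUSION_SUBTYPES),
        fusion_5prime_genes=["KMT2A", "NUP98"],
        class_defining_mutations=["NPM1", "CEBPA"],
        newly_proposed=["UBTF-TD", "BCL11B-r", "PRDM16-r"],
        newly_proposed_fusion_genes={"PRDM16": "PRDM16-r"},
        aml_mr_mutations=[
            "TP53", "SRSF2", "SF3B1", "U2AF1", "ZRSR2", "ASXL1", "EZH2",
            "BCOR", "STAG2",
        ],
        ds_gene="GATA1",
        groupings=groupings,
        signature_genes=genes,
        centroids=centroids,
    )


def load_subtype_catalog(path) -> SubtypeCatalog:
    """Load catalog lists from YAML; centroids are regenerated synthetically."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = default_subtype_catalog()
    for key in (
        "class_defining_fusions", "fusion_5prime_genes", "class_defining_mutations",
        "newly_proposed", "aml_mr_mutations", "groupings",
    ):
        if key in cfg:
            setattr(base, key, cfg[key])
    if "ds_gene" in cfg:
        base.ds_gene = cfg["ds_gene"]
    return base


def default_driver_gene_catalog() -> set[str]:
    """Genes whose sub-threshold variants are eligible for low-VAF rescue."""
    return {
        "GATA1", "NPM1", "CEBPA", "FLT3", "KIT", "KRAS", "NRAS", "WT1",
        "TP53", "UBTF", "RUNX1", "PTPN11", "GATA2",
    }


def load_germline_panel(path) -> dict[str, tuple[str, str]]:
    """TSV (gene, inheritance AD/AR, domain hematologic/non_hematologic)."""
    panel = {}
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            gene, inh, dom = ln.rstrip("\n").split("\t")[:3]
            panel[gene] = (inh, dom)
    return panel


def default_germline_panel() -> dict[str, tuple[str, str]]:
    with resources.as_file(resources.files("amldx.data") / "germline_panel.tsv") as p:
        return load_germline_panel(p)


def default_aml_mr_table() -> list[dict]:
    """CNV-type myelodysplasia-related cytogenetic abnormalities.

    Each entry: label, contig, arm ('p'/'q'/'whole'), direction. Balanced
    AML-MR rearrangements are handled by the fusion machinery, not here.
    """
    return [
        {"label": "del(5q)", "contig": "chr5", "arm": "q", "direction": "loss"},
        {"label": "-5", "contig": "chr5", "arm": "whole", "direction": "loss"},
        {"label": "-7/del(7q)", "contig": "chr7", "arm": "q", "direction": "loss"},
        {"label": "-7", "contig": "chr7", "arm": "whole", "direction": "loss"},
        {"label": "del(11q)", "contig": "chr11", "arm": "q", "direction": "loss"},
        {"label": "del(12p)", "contig": "chr12", "arm": "p", "direction": "loss"},
        {"label": "-13/del(13q)", "contig": "chr13", "arm": "q", "direction": "loss"},
        {"label": "del(17p)", "contig": "chr17", "arm": "p", "direction": "loss"},
        {"label": "-17", "contig": "chr17", "arm": "whole", "direction": "loss"},
        {"label": "idic(X)(q13)", "contig": "chrX", "arm": "q", "direction": "loss"},
    ]


def default_relevance_table() -> dict[str, list[str]]:
    """Cooperating-lesion clinical relevance tags (risk / targetable)."""
    return {
        "FLT3-ITD": ["risk", "targetable"],
        "KIT exon 17": ["risk", "targetable"],
        "KIT": ["targetable"],
        "WT1": ["risk"],
        "del(5q)": ["risk"],
        "-5": ["risk"],
        "del(7q)": ["risk"],
        "-7": ["risk"],
        "-7/del(7q)": ["risk"],
        "del(13q)": ["risk"],
        "-13/del(13q)": ["risk"],
        "del(17p)": ["risk"],
        "del(12p)": ["risk"],
    }
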