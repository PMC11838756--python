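import numpy as np
import pytest

from amldx import catalog as cat
from amldx.synthetic import cohort_expression_baseline, generate_cohort
from amldx.types import (
    Breakpoint,
    PlatformObservation,
    StructuralVariant,
    VariantCall,
)


@pytest.fixture(scope="session")
def exon_model():
    return cat.default_exon_model()


@pytest.fixture(scope="session")
def subtype_catalog():
    return cat.default_subtype_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """40 sampled cases with karyotypes — shared read-only fixture."""
    return generate_cohort(40, seed=101)


@pytest.fixture(scope="session")
def small_cohort_baseline(small_cohort):
    bundles, _ = small_cohort
    return cohort_expression_baseline(bundles)


def make_variant(
    gene="NPM1", contig="chr5", pos=171_387_000, ref="A", alt="AT",
    vclass="indel", pathogenicity="P", origin="somatic", **platform_vafs,
):
    """Variant with per-platform observations given as e.g. WGS=(0.3, 100)."""
    per = {}
    for platform, spec in platform_vafs.items():
        vaf, depth = spec
        k = int(round(vaf * depth))
        per[platform] = PlatformObservation(
            vaf=k / depth, alt_reads=k, total_reads=depth
        )
    return VariantCall(
        gene=gene, contig=contig, pos=pos, ref=ref, alt=alt,
        variant_class=vclass, per_platform=per,
        pathogenicity=pathogenicity, origin=origin,
    )


def make_sv(gene1, gene2, contig1="chr1", pos1=1_000_000, contig2="chr2",
            pos2=2_000_000, region1="", region2="", offset1=0, offset2=0,
            consequence="chimeric_fusion"):
    return StructuralVariant(
        bp1=Breakpoint(contig1, pos1, "+"), bp2=Breakpoint(contig2, pos2, "+"),
        gene1=gene1, gene2=gene2, region1=region1, region2=region2,
        offset1=offset1, offset2=offset2, predicted_consequence=consequence,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
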