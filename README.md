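# amldx

Integrated whole-genome + whole-transcriptome (WGS + WTS) evidence
integration for pediatric acute myeloid leukemia (AML) molecular diagnosis.

Pediatric AML diagnosis increasingly relies on comprehensive sequencing:
WGS detects structural variants, copy-number changes and small mutations
genome-wide, while WTS contributes chimeric fusion transcripts, oncogene
expression, allele-specific expression and global expression signatures.
`amldx` implements the evidence-integration layer that sits between primary
variant calling and the clinical report, for molecular pathologists and
pipeline engineers evaluating such workflows:

* **Variant reporting rules** — somatic small variants are reportable when
  the WGS (or WES) VAF ≥ 5% at ≥ 10 total reads for a P/LP call; known AML
  drivers below the cut-off can be *rescued* when corroborated by WTS
  (RNA VAF ≥ 25%) or by a prior sample of the same patient, and are flagged
  as rescued rather than silently promoted.
* **Fusion integration** — DNA breakpoint pairs (BEDPE) are joined with RNA
  chimeric transcripts; the reading frame of a junction (g₅, e₅) → (g₃, e₃)
  is preserved iff Σ len(g₅, 1..e₅) ≡ Σ len(g₃, 1..e₃−1) (mod 3).
  Enhancer hijacking is called when a non-coding breakpoint lies within a
  window (default 300 kb upstream / 150 kb downstream) of a catalog oncogene
  *and* that oncogene's robust z-score, (x − median)/(1.4826·MAD) over the
  cohort baseline, is ≥ 2. FLT3-ITDs are tiered confirmed/borderline/weak by
  cross-platform junction-read support; KMT2A partial tandem duplications
  are validated by an in-frame exon 7/8 → 2/3/4 self-fusion transcript.
* **CNV validation** — focal CNVs (< 5 Mb) need dual WGS evidence (depth
  shift *and* soft-clipped reads at both boundaries); large-scale CNVs
  (> 5 Mb) are assembled by gap-tolerant merging. A limit-of-detection
  simulation models the expected log2 shift log₂((2 + p·Δ)/2) at tumor
  fraction p and reproduces how marginal events fragment as purity drops.
* **Classification** — a fixed driver hierarchy (Down-syndrome GATA1 →
  class-defining fusion → class-defining mutation → newly proposed class →
  myelodysplasia-related → novel/rare fusion → unknown) assigns one subtype
  per case, corroborated by nearest-centroid correlation over signature
  genes.
* **Concordance** — Pearson r and least-squares slope of paired VAFs,
  platform agreement tables with manual-review re-binning, and LS-CNV
  agreement against a metaphase-sampling cytogenetics observer
  (~9 Mb banding resolution, events reported when seen in ≥ 2 of 20
  metaphases).
* **Synthetic cohorts** — a generator plants ground-truth drivers from an
  AML subtype catalog and samples per-platform read support binomially at
  platform depths (WGS 61x, WES 137x, panel 1453x), so every rule is
  testable against known truth without patient data.

## Worked example

```python
from amldx.synthetic import generate_cohort, cohort_expression_baseline
from amldx.classify import run_case
from amldx.report import build_phased_report

bundles, truths = generate_cohort(40, seed=101)
baseline = cohort_expression_baseline(bundles)
res = run_case(bundles[1], expression_baseline=baseline)
call = res.subtype_call
print(call.subtype, call.tier, truths[1].true_subtype)
print(build_phased_report(res, "rapid_day7").to_text())
```

prints

```
RUNX1::RUNX1T1 class_defining_fusion RUNX1::RUNX1T1
Case SYN0002 — phase rapid_day7
========================================
[aml_mr_abnormalities]
  (none)
[confirmation_recommended]
  (none)
[driver_findings]
  evidence=['RUNX1::RUNX1T1']; expression_corroboration=concordant; subtype=RUNX1::RUNX1T1; tier=class_defining_fusion
[ls_cnvs]
  (none)
[qc]
  platform=WGS; verdict=pass
  platform=WTS; verdict=pass
```

i.e. case SYN0002 carries a RUNX1::RUNX1T1 fusion (DNA breakpoint
plus an in-frame transcript), the classifier recovers the planted subtype,
the expression profile sits nearest its own subtype centroid, and the rapid
(day-7) report carries the class-defining driver with passing QC.

The same pipeline is scriptable from the shell:

```sh
amldx simulate --n-cases 40 --seed 101 --out cohort/
amldx analyze --case cohort/SYN0002/manifest.json --cohort-dir cohort/ --out out/
amldx concordance --cohort-dir cohort/ --out concordance.json
amldx report --case cohort/SYN0002/manifest.json --phase comprehensive_day21 --out reports/
```

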