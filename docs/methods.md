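# Methods

This note documents the models behind `amldx`: what each module computes,
the tunable parameters and their defaults, what the synthetic cohort
emulates (and what it does not), and the numerical choices made where the
design was genuinely open.

## Variant reporting

A somatic small variant is **reportable** when, on WGS, its VAF ≥ `vaf_min`
(default 0.05) at `min_total_reads` ≥ 10 and its pathogenicity class is P or
LP. WES substitutes as the primary DNA platform when a case has no WGS.
The cut-offs are inclusive; the QC exon-coverage gate is strict
(< 40% → suboptimal), so 40.0 passes.

Known AML drivers below the VAF cut-off are eligible for **rescue**, which is
formalized as: gene ∈ driver catalog AND (WTS VAF ≥ `rescue_wts_vaf`
[default 0.25] OR the identical variant was reported in a prior sample of
the same patient). These are exactly the two corroboration modes that occur
in practice — low-blast Down-syndrome GATA1 mutations expressed strongly in
the blast transcriptome, and relapse samples with a known diagnostic
mutation. Rescued calls carry a distinct status (`rescued_reportable`) and a
confirmation note rather than being silently promoted; whether rescue needs
manual sign-off is an institutional decision the engine does not make.

**Allele-specific expression** is flagged when the WTS VAF ≥ `ase_high`
(default 0.90) while the DNA VAF lies in the heterozygous band
(default [0.25, 0.60]) and WTS depth ≥ 20. An exact two-sided binomial test
of the WTS alt count against the DNA VAF is attached as the supporting
statistic (it is evidence *strength*; the flag itself is the band rule).

**Germline findings** are categorized from an editable panel TSV
(gene → inheritance, disease domain). The domain check precedes
inheritance/zygosity: a heterozygous variant in an autosomal-recessive
non-hematologic gene (e.g. MUTYH) is an incidental finding, not a carrier
state of the hematologic workflow. Biallelic status is inferred from a
second P/LP allele in the same gene or VAF ≥ 0.9 (homozygosity); trans
configuration cannot be verified without phasing and is assumed.

## Fusion integration

Reading frame at a junction (g₅, e₅) → (g₃, e₃) is preserved iff the
cumulative coding length of g₅ through e₅ and of g₃ through e₃−1 are
congruent mod 3. The shipped exon model is synthetic (coding lengths are
generated, multiples of 3 for the catalog junctions so the documented
fusions are in frame); a real GTF-derived table is a drop-in replacement via
`load_exon_model`. The frame arithmetic itself is exact and is tested
against exhaustive brute-force enumeration on random toy exon models.

A transcript supports an SV when gene pairs match and the 5' junction exon
is compatible with the DNA breakpoint (breakpoint in intron k ⇒ junction
after exon k; in exon k ⇒ after k−1 or k). Junction support below
`min_junction_reads` (default 3, e.g. a single read) keeps the call but sets
`confirmation_needed`, mirroring orthogonal confirmation by targeted
RNA-seq. Transcripts with no matching DNA junction yield RNA-only calls
(cryptic, e.g. insertion-mediated, rearrangements); self-fusion transcripts
are excluded from that path because they are tandem-duplication evidence.

**Enhancer hijacking** requires (i) a breakpoint within
`eh_window_upstream` = 300 kb upstream or `eh_window_downstream` = 150 kb
downstream of a catalog oncogene (the window generalizes the observed
MECOM-rearrangement breakpoint spread of 3.8–300 kb upstream and 78–146 kb
downstream), and (ii) overexpression of that oncogene at robust z ≥ 2,
where z = (x − median)/(1.4826·MAD) over the cohort baseline. Proximity with
baseline expression leaves the prediction *unconfirmed* — for this mechanism
the transcriptome actively refutes the DNA-level hypothesis, which is why
BCL11B-locus translocations without BCL11B/TLX3/NKX2-5 overexpression are
not called.

**FLT3-ITD tiers**: junction-spanning reads ≥ `itd_strong_reads` (default 5)
is strong, 1–4 weak, 0 none; confirmed requires strong on both WGS and WTS,
exactly one strong platform is borderline, anything else with support is
weak. The strong/weak read thresholds are declared defaults, not derived
values. Every non-confirmed tier recommends PCR fragment-analysis
confirmation. **KMT2A-PTD** is validated only by an in-frame self-fusion of
exon 7 or 8 onto exon 2, 3 or 4; a DNA-only duplication or an off-set
junction stays flagged.

## CNV analysis

Focal events (< 5 Mb) obey the dual-evidence rule: |log2 ratio| ≥ 0.3 AND
≥ `min_softclip` (default 2) soft-clipped reads on *each* boundary. No focal
CNV without bilateral clip support is ever reportable. Large-scale events
(> 5 Mb) are built by merging same-direction segments separated by at most
`gap_merge_bp` (default 1 Mb; length-weighted mean ratio), requiring a
merged |log2| ≥ 0.1 — one-copy events in clones below ~15% of cells fall
under this, which is how deeply subclonal gains/losses are missed by WGS.
Overlapping contradictory segments are a validation error.

### Limit-of-detection simulation

Bins of 1 Mb carry log2 ratios: shift log₂((2 + p·Δ)/2) inside a truth
event at tumor fraction p, plus white noise (sd 0.04) plus a smooth "wave"
component (sd 0.03, correlation length ~10 Mb) emulating GC/coverage bias.
Segmentation is recursive binary mean-shift splitting (split when the
standardized mean difference exceeds 3.5; minimum 4 bins). A segment meets
diagnostic criteria at |mean| ≥ 0.18 and ≥ 3 Mb; an event is *detected*
when one contiguous passing span covers ≥ `report_fraction` (0.7) of it,
*fragmented* when coverage is split or partial, *failed* at zero coverage.

The wave component is essential: with iid noise alone a changepoint
segmenter recovers marginal events as single segments and nothing ever
fragments. With the wave, segment means ride on it, so at 40% tumor content
(one-copy shift 0.263) essentially all fragments pass; at 30% (shift 0.202)
events split into partially-passing fragments; at 25% (shift 0.170) most
fragments fall under the ratio criterion and events cannot be established.
These parameters were calibrated once to reproduce that trichotomy for the
1–2-copy whole-chromosome gain fixture; the noise realization depends only
on the seed (never on purity), so recovery is comparable across a purity
grid on identical noise. Recovery is monotone in purity up to small
boundary-resplitting effects (tests allow 0.02).

**AML-MR mapping**: a large-scale CNV yields a myelodysplasia-related
abnormality when ≥ 50% of the event lies in a configured arm region with
the required direction; whole-chromosome labels take precedence at ≥ 90%
chromosome coverage. Only CNV-type entries are auto-mapped; balanced
rearrangements arrive via the fusion machinery. Copy-neutral LOH is out of
scope.

## Classification

The driver hierarchy is total and ordered (DS-GATA1 → class-defining fusion
→ class-defining mutation → newly proposed → AML-MR → novel/rare fusion →
unknown); the first matching tier wins and every case gets exactly one
tier. Within a tier all drivers are recorded and the primary is chosen by
catalog rank. Two asymmetries are deliberate:

* a DNA-predicted chimeric fusion without RNA confirmation remains a
  class-defining *candidate* with a confirmation flag (the prediction is
  unconfirmed, not refuted), whereas an enhancer-hijack prediction without
  overexpression is refuted and never class-defining;
* AML-MR is assigned only in the absence of any other known or *potential*
  driver — an in-frame novel fusion vetoes it.

CEBPA classification accepts the reported mutation by default; detected ASE
is attached as supporting evidence (a configurable stricter mode could
require it). Expression corroboration is nearest-centroid Pearson
correlation over signature genes; a grouping table maps biologically related
subtypes onto shared centroids (RUNX1::CBFA2T3/2 → RUNX1::RUNX1T1-like;
MECOM-r and PRDM16-r share a profile). A called subtype with no centroid
reports `unavailable` rather than guessing.

## Concordance

`vaf_concordance` is plain Pearson r and least-squares slope (via
`scipy.stats.linregress`), undefined under zero variance. Platform
agreement classifies the keyed union into both/A-only/B-only; "manual
review" of the losing platform is modelled as an oracle query against that
platform's raw sub-threshold observation — deterministic and testable,
standing in for BAM inspection. Cytogenetics agreement matches events at
≥ 50% reciprocal overlap with equal direction (the matching rule is our
choice; none is printed in the field's reports). Karyotype/event agreement
is reported per event; a per-case convention can be derived from the same
tables.

## Synthetic cohort

The generator emulates: purity = blast fraction (normal around 66%, clipped
to [20, 96]; Down-syndrome cases 5–15%), per-platform depths
negative-binomial around WGS 61x / WES 137x / panel 1453x / WTS 60x
(dispersion 8), observed VAF binomial at purity × allele-fraction factor
(0.5 heterozygous; a minority hemizygous/LOH-like 0.9 or subclonal — this
mixture gives the cohort a realistic VAF spread, and the WGS–WES regression
then lands near r≈0.87, slope≈0.88 without being targeted). Subtype
frequencies follow the class breakdown 91 fusion / 30 mutation / 13 newly
proposed / 5 AML-MR / 6 novel fusion / 4 unknown / 5 DS-GATA1 per 154.
Enhancer-hijacked targets get a 16× (+4 log2) fold-shift; FLT3-ITD evidence
patterns are drawn 17:10:1 (both-strong : WTS-only-strong : weak). The
cytogenetics observer reports events ≥ 9 Mb, non-cryptic, seen in ≥ 2 of 20
metaphases with per-metaphase presence Bernoulli(clone fraction).
`noise_free=True` swaps in deterministic platform models (depth at the
mean, VAF at expectation) for rule-level checks.

What it does **not** emulate: read-level artifacts (mappability, strand
bias, FFPE damage), germline contamination of somatic calls, clonal
evolution between timepoints, expression heterogeneity beyond one Gaussian
around a group centroid, and real gene coordinates/exon structures
(loci are approximate anchors; the exon model is synthetic). Passing tests
therefore demonstrate that the *rules* behave as specified on inputs with
a real cohort's statistical structure — not that upstream callers achieve these
operating points on real sequencing data.

## Problem sizes and determinism

Default test and acceptance workloads: 500-case noise-free and 300-case
masked cohorts for subtype recovery, 250 sampled cases for concordance,
20 seeds × 3 purities for the LS-CNV simulation, and 1000-trial oracle
comparisons — sizes at which every statistical assertion has comfortable
margin while the whole suite runs in seconds. All randomness flows from
explicit seeds; identical seeds reproduce cohorts exactly (dataclass
equality), and report serialization is deterministic (sorted keys, no
timestamps).
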