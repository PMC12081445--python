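# Methods

## Problem

RNA hybrid-capture panels detect chimeric transcripts joining a 5' partner
gene to the 3' portion of *NTRK1/2/3*. Whether such a fusion is a reportable
oncogenic driver depends on a small set of structural facts: orientation
(the NTRK gene must be the 3' component), retention of the tyrosine-kinase
domain (TKD) in the retained 3' segment, curation status of the 5' partner,
and — for uncurated partners — preservation of the reading frame across the
junction. `trkfusion` implements this decision procedure as auditable code
and the downstream cohort characterization (prevalence, recurrence,
co-occurrence, immunotherapy biomarkers) as reproducible arithmetic.

## Classification model

A candidate fusion (specimen, 5' gene, 3' gene, two breakpoints, unique
supporting reads) passes a read-support filter (`unique_reads >= 5`,
applied per fusion event) and is then classified:

1. **Orientation.** If the NTRK gene is not the 3' component → VUS.
2. **Kinase-domain retention.** If the 3' breakpoint does not leave the
   kinase region intact → VUS.
3. **Known partner.** If the (partner, NTRK gene) pair is in the curated
   registry → ONCOGENIC.
4. **Frame.** Otherwise, if the junction preserves the reading frame →
   LIKELY_ONCOGENIC; else (including indeterminate frame) → VUS.

The known-partner test precedes the frame test by design: curated partners
are oncogenic even when the junction frame cannot be computed (promoter
swap / 5'-UTR breakpoints), because the frame condition applies only to
novel partners. Classification is idempotent, and upgrading a pair from
novel to known can only promote a verdict (VUS→ONCOGENIC or
LIKELY_ONCOGENIC→ONCOGENIC), a monotonicity property the tests enforce.

### Kinase-domain retention

The TKD is annotated on exons 9–17 (*NTRK1*), 16–20 (*NTRK2*) and 15–19
(*NTRK3*). The retention *test*, however, is driven by a separate
per-gene breakpoint-compatible region table shipped with the knowledge
base (defaults: NTRK1 12–17, NTRK2 16–20, NTRK3 15–19): a 3' breakpoint
strictly upstream of the region's first exon retains the kinase fold; an
exonic breakpoint inside the region counts as not retained (partial domain
loss is never assumed functional). The NTRK1 region deliberately starts at
exon 12, not at the annotated domain start: curated fusion diagrams show
*LMNA–NTRK1* fusions with intron-11 breakpoints acting as oncogenic
drivers, so a naive exons-9–17 cutoff would misclassify a clinically
established driver. Because the literature does not reconcile the
annotated domain span with the observed breakpoint spectrum, the region is
data (a `#tkd_region` directive in the KB file), not code, and can be
overridden without touching the classifier. Retention is monotone: moving
a 3' breakpoint 5'-ward never flips retained→lost.

### Reading frame

Frame preservation is pure interval arithmetic over exon structures
(1-based, closed coordinates; exon numbering in transcription order). The
*phase* of an exon is the cumulative coding length of upstream exons mod
3. A junction is in frame iff the retained 5' coding length mod 3 equals
the phase at which the 3' gene's CDS resumes. Exonic breakpoints are
scored at the exact coding offset, so mid-codon joins are handled; the
call is *indeterminate* when the retained 5' segment contains no CDS or
the 3' phase is undefined, and an indeterminate frame never upgrades a
novel-partner fusion. The tests validate this arithmetic against an
independent sequence-level oracle that synthesizes stop-free codon streams
over the same exon models, splices the fused mRNA at the breakpoints,
translates from the 5' start codon, and scans for a marker peptide encoded
by the 3' gene's terminal codons.

### Partner knowledge base

Partner knownness is pair-level — (partner gene, NTRK gene) — never
partner-global: EML4 is curated for NTRK1 and NTRK3 but counts as novel
with NTRK2. Two evidence classes are distinguished: `canonical`
(COSMIC/GENIE or >3 literature reports) and `clinical_validity` (partners
from the trials behind the TRK-inhibitor approvals). The registry is
versioned data (`data/partner_kb.tsv`), and every classification records
the KB version, because the oncogenic/likely-oncogenic boundary moves as
curation grows. Two curation decisions in the shipped default are worth
flagging: KANK1–NTRK3 is deliberately *absent* (treated as novel) so that
recurrent KANK1–NTRK3 fusions classify as likely oncogenic, matching the
reference recurrence table even though some partner lists count KANK1 as
known — the published sources disagree, and the registry reproduces the
verdict-level table; GNAQ–NTRK2 is *present* as canonical on the strength
of a clinically documented oncogenic GNAQ–NTRK2 fusion, although it is
missing from some partner enumerations.

## Cohort analytics

All percentages are decimal half-up rounded at the precision conventional
for each table: prevalence and fusion% to 2 decimals, cohort% to 3,
per-gene co-alteration frequencies to 1, class-level frequencies to 0.
This makes printed tables exact arithmetic (5/69 → 7.25%, 35/69 → 50.7%,
59/69 → 86%). One printed value sits on a rounding boundary (5/19,591 =
0.02552%, printed 0.025%); the tests compare that entry by numerator and
denominator rather than endorsing either rounding.

* **Positivity**: a specimen is positive iff it carries ≥1 ONCOGENIC or
  LIKELY_ONCOGENIC fusion; fusion-level and specimen-level counts are both
  reported (73 fusions vs 69 specimens in the reference screen).
* **Prevalence**: per tumor type and overall, n_positive / n_total over
  the specimens that passed RNA fusion calling.
* **Recurrence**: per distinct fusion, specimens carrying it, % of
  positive specimens, % of the full cohort, verdict, tumor types.
* **Co-occurrence**: only alterations annotated known-pathogenic count; a
  specimen contributes once per gene regardless of how many alteration
  classes hit it; the oncoprint keeps genes with cumulative frequency
  ≥3% (boundary inclusive, tested on the unrounded fraction). The
  "co-occurring driver" summary uses a configurable driver-gene list
  (default ALK, KRAS, BRAF, EGFR, RET, ROS1, MET, ERBB2, PIK3CA), since
  published summaries name examples rather than an exhaustive list; the
  same list governs the overall and the NSCLC-specific breakdown.
* **Biomarkers**: Wilcoxon rank-sum (two-sided Mann-Whitney U), TMB tested
  on log(TMB+1) with medians reported in mutations/Mb (the rank statistic
  is invariant to the monotone transform; the transform matches plotting
  convention), PD-L1 tested on the raw 0–100 score within a single score
  type (TPS and CPS are never pooled); p-values uncorrected and flagged as
  such. MSI-H proportions are reported without a hypothesis test (group
  sizes are too small). Strata that lose a group to missing values are
  skipped with a warning, never silently imputed.

## Synthetic cohort generator

No case-level data from the reference screen are public, so the generator
is the package's test bed. Its defaults are the study conditions:

* tumor-type mix resembling a large real-world solid-tumor cohort (NSCLC
  ≈39%, breast ≈7%, etc.), per-type fusion prevalence 0.19–1.91%
  (overall ≈0.35%);
* qualifying fusions constructed **verdict-first**: the generator picks
  the intended verdict, then searches the simulated transcript geometry
  for breakpoints realizing it (known partner for ONCOGENIC; novel
  partner with phase-matched junction for LIKELY_ONCOGENIC). Decoys —
  wrong orientation, kinase domain lost, out-of-frame junctions,
  sub-threshold read support (1–4 reads against the ≥5 filter) — are
  sprinkled at a low rate. This guarantees label balance regardless of
  the random gene shapes;
* breakpoints are emitted as concrete genomic coordinates consistent with
  the simulated annotation (intronic positions drawn uniformly within the
  intron), so the annotation step is exercised end to end; the ground
  truth records the transcript-relative descriptors;
* co-alteration frequencies per gene conditional on NTRK status (TP53
  0.507 among positives), log-normal TMB specified on the log(TMB+1)
  scale with additive group shifts per tumor type (head & neck shifted
  down for positives, colorectal up, matching the reported group
  medians), zero-inflated PD-L1 mixtures (point mass at 0 plus low/high
  bands — reproducing median-0 strata without claiming any particular
  real-world distribution), MSI-H enriched in colorectal/small-intestine
  positives (0.50 vs 0.066);
* a single mandatory seed drives everything; identical seeds give
  byte-identical files, and every emitted file round-trips through the
  package's own readers.

The simulated transcriptome gives the NTRK genes their real TKD exon
ranges and generates partners with varied exon counts, first-exon coding
phases pinned to cover {0,1,2}, one gene with a fully non-coding first
exon (to exercise indeterminate frame), and curated partners with enough
exons for their literature breakpoints. 5' breakpoint candidates are
restricted to the coding body of the partner — a breakpoint downstream of
the stop codon cannot yield a read-through fusion protein, so "frame" is
not meaningful there.

What the generator does **not** emulate: read-level evidence (no
FASTQ/BAM), fusion-calling errors (calls are taken as given; the filter
models only read support), multi-isoform transcription, inter-gene
correlation of co-alterations beyond NTRK status, and real PD-L1/TMB
distributions beyond their medians and group shifts. Passing tests
therefore validate the classification arithmetic and bookkeeping, not the
upstream caller or assay.

## Problem sizes and numerical choices

The default analysis simulates 10,000 specimens; end-to-end ground-truth
recovery is checked at that size, and prevalence calibration over 100
replicate cohorts of 2,000 specimens (exact Clopper-Pearson 95% intervals
must cover the generator's true prevalence in ≥93% of type × replicate
draws; observed coverage ≈99%, as expected for the conservative exact
interval). The reference-count reproduction is pure arithmetic over the
transcribed tables and runs in well under a second. Oncoprint boundary
inclusion uses a 1e-9 tolerance on the exact fraction. Rounding is
`decimal`-based half-up, never float banker's rounding.

## Known limitations

* The reference fixture expands printed marginal counts into an arbitrary
  consistent case-level layout; only the printed marginals carry
  evidence, and the per-specimen details are synthetic by construction.
* Exon numbering follows whatever canonical transcript the annotation
  provides (longest CDS wins when several are present); published exon
  ordinals implicitly assume a specific reference transcript that the
  literature does not name.
* The ≥5-read threshold is applied per fusion event; whether the original
  pipeline applied it per breakend is unstated.
* No point-based somatic scoring beyond the binary rules, no survival
  modeling, no multiple-testing correction machinery (p-values are
  flagged uncorrected), and no circos/diagram rendering — link tables are
  emitted instead.
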