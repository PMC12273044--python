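# Methods

This note documents the models, parameter choices and numerical conventions
behind `hoxscape`, and what the synthetic cohorts do and do not establish
about real data.

## Coordinates and regions

All internal intervals are 0-based half-open; GTF input/output is 1-based
inclusive, BED output 0-based, and CpG positions in coverage files 1-based
(converted on read).  One canonical transcript is kept per gene; isoform
handling is out of scope.

The putative promoter is the 1 kb upstream plus 100 bp downstream of the
transcription start site, strand-aware and clamped at position 0.  Exons and
introns are numbered 5′→3′ in transcript orientation and exactly tile the
gene span; UTRs are emitted only when the annotation encodes CDS features.
A CpG in the 100 bp post-TSS window belongs to **both** the promoter and
exon 1 (promoter/first-exon methylation is analysed jointly in this
literature); region summaries are computed per key independently, so the
multi-assignment never double-counts within a region.

Natural-antisense (NAT) pairing requires ≥ 1 bp of exonic overlap between a
lncRNA and a coding gene on opposite strands of the same chromosome.  No
larger overlap threshold is imposed — positional complementarity, not
overlap length, is the defining property — and overlapped coding-exon
ordinals plus total overlap bp are reported so users can filter.

## Methylation summaries and classification

Per-CpG methylation is recomputed from read counts
(100·n_meth/(n_meth+n_unmeth)); the percent column of coverage files is
advisory only (a logged warning above 0.5 deviation).  Calls with fewer than
`min_coverage = 5` total reads are dropped — no published floor exists; 5
reads stabilizes the percent estimate and is configurable.

Region methylation is the **unweighted** mean of per-CpG percentages.
Read-count weighting would let sequencing depth masquerade as biology.
Matched differences are tumor − normal per patient, and group values are
pair-first (mean over per-pair deltas), not differences of pooled means.
Hyper/hypomethylation calls use strict inequalities at ±25%; the unmethylated
gate is strictly below 10%.  Regions with no covered CpGs propagate as
missing, never as 0% — "unmethylated" and "unobserved" are different facts.
No hypothesis test backs the region calls (threshold classification only);
none is implied by the classification's source convention.

## CUR scanning

A constitutively unmethylated region is operationally: a maximal run of
≥ `min_cur_cpgs = 3` CpGs, each with across-sample methylation range
(max − min, pooled over *all* samples — which subsumes within-group and
case-vs-control variation) below 10% **and** every sample below the 10%
absolute gate, with inter-CpG gaps ≤ 300 bp, contrasted against flanks: the
nearest 3 ineligible CpGs per available side must average ≥ 20 percentage
points above the run (waived when no flank exists).  Choices worth noting:

- "Variation" is read as the **range**, the strictest common interpretation;
  an SD-based band is available via `band_stat="sd"`.
- The per-CpG (not region-average) reading of the variation criterion is the
  stricter of the two; users comparing against region-average screens should
  expect fewer, tighter calls here.
- The absolute 10% gate is borrowed from the unmethylated-state convention;
  a low-variation but 50%-methylated run is not a CUR.
- Run length, gap and contrast defaults are sized so that unmethylated spans
  of roughly 200–1,650 bp are representable; all are flags on the CLI.
- CpG-island overlap is *not* required; an island BED can annotate but never
  gates calls.
- The screened territory runs from the promoter through the gene 3′ end;
  overlapping territories (e.g. an antisense lncRNA across a coding gene)
  can each report the same physical run under their own gene id — these are
  duplicate views, not distinct regions.

Tightening either threshold provably never enlarges the reported CpG set
(eligibility is an intersection of per-threshold conditions).

## Panel biomarker

The primary per-sample feature is the mean methylation (or matched delta)
over the panel CpGs; a multivariate per-locus mode exists behind a flag.
Scores are in-sample predicted probabilities of a maximum-likelihood
logistic fit.  On perfect separation or non-convergence — the norm at
n = 6–8 per group with a strong marker — the scorer falls back to the rank
of the mean-methylation feature; ROC depends only on score order, so the
curve is unaffected.

The ROC is built by sweeping unique score thresholds; the trapezoid AUC
equals the Mann–Whitney concordance with ties counting half (verified
against an exhaustive pairwise oracle and an independent library
implementation in the tests).  The 95% CI is a stratified percentile
bootstrap (resampling within class, 2000 replicates, seeded), so every
replicate retains both classes.  This is an in-sample, descriptive design
mirroring small matched cohorts — it characterizes separation in the data
at hand and is *not* predictive validation.

Null calibration uses the standard permutation construction: scores are
held fixed while labels shuffle.  Refitting inside each permutation lets the
coefficient sign adapt to the permuted labels and biases the in-sample AUC
to E[max(A, 1−A)] ≈ 0.6 at these sample sizes, which is a property of
refitting, not of the marker.

The random-forest check reports out-of-bag AUC on the per-locus panel.  OOB
probabilities carry a small pessimistic bias at tiny n (in-bag class
composition anti-correlates with the held-out sample's label); with no
splittable feature at all the artifact dominates completely, so that
degenerate input short-circuits to AUC 0.5.

## Expression integration

Upper-quartile normalization scales each sample so its 75th percentile of
nonzero counts equals the geometric mean of per-sample quartiles (zeros stay
zero; idempotent; per-sample scale-invariant).  The geometric-mean reference
and the nonzero-quartile convention are the standard choices where only the
method name is conventionally fixed.  Differential-expression p-values are
not computed internally (count-model dispersion estimation is out of scope);
`fold_change_table` accepts an external per-gene p column and otherwise
applies the |log2FC| ≥ 1.5 threshold alone, labelled as such.  Fold changes
use pseudocount 1 on normalized means (configurable).

Correlations are product-moment r with the two-sided t-transform p (n−2 df)
and tier labels (strong |r| > 0.7, moderate 0.3 < |r| ≤ 0.7).
Benjamini–Hochberg FDR is reported alongside raw p-values; neither replaces
the other.  Methylation–expression association correlates region methylation
with log2(normalized + 1) expression and reports continuous r with a
direction call (inverse/concordant); dichotomizing patients by expression
status is left to the user, since no principled up/down rule is fixed.

## Synthetic cohorts

The generator emulates the *structure* of a matched bisulfite + RNA-seq
oral-cancer cohort: 8/6/8 PMOL/TN0/TN0+ tumor–normal pairs (histology
3 leukoplakia / 8 WDSCC / 5 MDSCC under defaults), a 39-gene four-cluster
HOX-like annotation with six embedded antisense lncRNAs, CpG sites placed by
a geometric-gap process at ~10 bp mean spacing (HOX territory is
CpG-island-dense), mean on-target depth 150× (typical of targeted
methyl-capture), Poisson per-site depth and binomial methylated counts.

Planted structures, each recorded in a truth table:

- **Background** CpGs draw per-sample methylation from Beta(15, 5)
  (mean 75%).
- **CURs** at eight fixed spans carry one shared site-level value from
  Beta(0.5, 30) truncated at 0.02.  The truncation is what makes the planted
  region *constitutively* unmethylated: untruncated Beta(0.5, 30) tail draws
  (a few percent of sites) combined with binomial read noise at realistic
  depth would violate the 10% band at scattered sites and sever runs, i.e.
  the plant would not be a CUR by its own definition.  CpGs are pinned at
  planted interval boundaries so a perfect call (first→last CpG) spans the
  recorded interval exactly.
- The **8-CpG panel** sits in the HOXB9-like intron at the fixture
  coordinates chr17:46702528–46702583 with a shared Beta(10, 90) base
  (~10%) and logit-scale tumor shifts targeting +5/+15/+40 percentage
  points for PMOL/TN0/TN0+ — logit-scale so the group ordering survives
  near the probability boundaries.
- **Hypermethylated tumor regions** (two exonic, two intronic genes,
  +30–35 points at a ~30% base) give the differential table recoverable
  signal.
- **Coupled genes** carry one promoter methylation state per sample
  (Beta(2, 2), shared across the promoter's CpGs) and negative-binomial
  expression whose log2 mean decreases by `coupling_b = 3` per methylation
  fraction — a strong, clean inverse coupling.
- **NAT pairs** (four designated lncRNA–gene pairs) share a latent log2
  factor with SD 1.5, chosen to dominate the combined count and biological
  noise (~0.4 log2) so shared regulation, not noise, sets the correlation.

Fixture coordinates are styled on hg19 so outputs read naturally; the data
are synthetic throughout.

**What passing tests show — and don't.**  Recovery results demonstrate the
pipeline's correctness on data satisfying its own generative assumptions:
independent binomial noise, clean matched pairs, no batch or conversion
artifacts, no copy-number effects, sharply planted effects.  Real cohorts
add bisulfite conversion failure, coverage dropout, cellular heterogeneity
and confounded batches; performance there is an empirical question this
package's tests cannot answer.  Problem sizes in the test-suite and
acceptance-script simulations (25–100 cohorts of 30–44 samples, ~18k CpGs)
are the package's chosen defaults for routine verification.

## Known limitations

- One transcript per gene; no isoform-aware regions.
- Non-CpG contexts (CHG/CHH), smoothing and imputation are out of scope.
- Region hyper/hypo calls are threshold classifications without a test
  statistic.
- The in-sample ROC is descriptive; no cross-validation or held-out
  evaluation is provided.
- The CUR criterion's per-CpG reading is stricter than a region-average
  reading; borderline published regions may differ under the alternative.
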