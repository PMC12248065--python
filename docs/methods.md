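# Methods

## Coordinate and orientation conventions

All intervals are 0-based, half-open (BED convention); GTF input is
converted on read.  Every "upstream"/"downstream" in the package is
transcript-strand-relative: for minus-strand features the downstream
direction runs toward lower reference coordinates, and sequence handed
to motif or filter code is reverse-complemented first.  Peak-vs-feature
overlap requires matching strands because eCLIP is stranded.

## Cluster calling and PAS assignment

Coverage is pooled over *all* samples in the run manifest before
clustering, so cluster boundaries are identical in every sample.  A
cluster is a maximal run of positions with pooled coverage strictly
greater than 10 (i.e. ≥11 reads); clusters with fewer than 20 pooled
reads are removed.  The thresholds follow the strict reading of
"more than 10" and "fewer than 20".  The PAS is the pooled-coverage
argmax, with ties resolved toward the transcript 3' end (highest
coordinate on plus, lowest on minus).

## Internal-priming filters

Four independent filters; a cluster survives only if it passes all of
them, and the result is invariant to the order in which they run.

* **A-run:** >6 consecutive sense-strand adenosines directly downstream
  of the assigned PAS.  No inspection window is inherent in the rule, so
  we use 10 nt, mirroring the A-content window; it is a keyword argument.
* **A-content:** >7 A within the 10 nt directly downstream of the
  cluster's 3' boundary.
* **Hexamer:** the cluster region must contain AAUAAA or AUUAAA (sense
  strand; which one is recorded, AAUAAA preferred when both occur).  The
  search window is the cluster interval extended a configurable margin
  *upstream* (default 25 nt).  Rationale: the hexamer canonically sits
  10–20 nt upstream of the cleavage site, so a cluster must span roughly
  that far upstream of the PAS to physically contain it.  Empirical
  3'-end-seq clusters usually do; clusters simulated with the default
  ±5 nt cleavage jitter are only ~11 nt wide and never would, making
  strict containment (margin 0, also supported and tested) reject every
  genuine site.  The default margin equals the canonical spacing plus
  the hexamer length.
* **Reference:** the cluster must overlap (≥1 nt, same strand) a record
  in a reference PAS database.  Overlap rather than exact coordinate
  match, because reference databases store clustered coordinates.

## Usage and differential calls

Relative usage is cluster reads over summed exon reads per sample;
samples with zero exon reads get NaN (flagged), never 0/0.  Clusters
attach to the terminal exon containing their PAS (the exon may be
extended by a configurable downstream flank, since 3'-end clusters can
pass annotated ends).  Deltas are knockdown − control per matched
replicate pair (pairing by replicate index from the manifest).  The
changing rule — ≥2 of 3 pairs with |Δ| ≥ 10% in a common direction and
no opposite-direction pair — generalises to ⌈2k/3⌉ of k pairs; an
opposite sign at *any* magnitude disqualifies, exact zeros are neutral.
"10%" is an absolute usage-fraction change, matching PDUI-style deltas.
An exon with a missing or unpaired replicate is indeterminate.
Exon-level direction is reported from the distal cluster's mean delta
(negative = shortening on knockdown).

Confident non-changing exons need ≥10 reads in every sample and no
cluster moving more than 5% in any replicate.  Compartment-specific
events are exons changing in one compartment and confidently
non-changing in the other; changing-vs-indeterminate pairs belong to no
set, so the three sets are disjoint by construction.

## dPDUI classification

dPDUI = PDUI_control − PDUI_knockdown.  The sign convention is anchored
so that an RBP which normally promotes distal-site usage (3'UTR
lengthening) yields dPDUI ≥ +20% upon knockdown.  "FDR" and "adjusted
p-value" are treated as the same provided column; no multiple-testing
procedure is re-run.  The simplified `estimate_pdui` (mean extended-
region coverage over mean common-region coverage, clamped to [0,1]) is
plumbing for synthetic coverage tests; it assumes uniform per-isoform
coverage and performs no de-novo PAS inference or regression.

## Binding maps

A 3'UTR is expressed when its gene's median TPM across control
replicates is ≥1 (threshold configurable); it is bound when any
same-strand peak overlaps it by ≥1 nt, using the union-of-replicates
("any") peak tier.  Feature fractions use the reproducible/IDR tier and
assign each peak to exactly one class with priority 3'UTR > 5'UTR > CDS
> non-coding exon > intron > downstream flank > other (the priority is
an argument).  RNA maps count an anchor as bound at position *i* when a
peak interval covers that single nucleotide; a summit-based mode exists
but is off by default.  The per-position enrichment test is the standard
exact two-tail (sum of table probabilities not exceeding the observed
table's); positions with zero bound anchors in both sets are p = 1 by
convention.  No across-position multiple-testing correction is applied
by default; Benjamini–Hochberg is available behind a flag.  Jaccard
indices are base-pair |intersection|/|union| over per-strand merged
intervals.

## Motif architecture

Motifs are declared in the RNA alphabet and scanned in DNA.  Frequency
maps mark the fraction of windows with an occurrence *starting* inside a
w-nt sliding window centered at each position (w = 10 for 4-mers, 20 for
6-mers; window [i − w/2, i + w − w/2)), then a 5 nt running mean; G/C
profiles use a 10 nt running mean.  Running means shrink to the valid
range at window edges, keeping profile length constant (exact mean
conservation therefore holds in the interior, approximately overall).
Spacing is the gap in nt between the 3' end of the upstream motif and
the 5' start of the downstream one (0 = abutting); among multiple pairs
the minimum gap wins, ties going to the pair whose downstream motif is
closest to the anchor.  Spacing CDFs consider only pairs with the
enhancer strictly upstream of the hexamer, consistent with the CFIm
enhancer geometry (canonically 40–60 nt upstream).  Anchors lacking a
pair within the ±150 nt search range are censored and counted.  Peak
"center" is the narrowPeak summit when present, else the midpoint.

## The synthetic generator

Each simulated gene is laid out 5'→3' (250 nt first exon, 100 nt
intron, terminal exon whose 3'UTR carries the planted sites) and written
onto a single chromosome forward or reverse-complemented (strands
alternate).  Per true PAS: hexamer 10–20 nt upstream of the cleavage
nucleotide (AAUAAA/AUUAAA alternating), UGUA at the configured distance
upstream of the hexamer (default 50 nt, the canonical enhancer spacing),
a CA dinucleotide at the cleavage site and a GU-rich downstream element.
Reads per exon per sample are Poisson around the configured depth
(default 500), multinomially split over PAS by the condition's usage
vector, with symmetric discrete-uniform cleavage jitter (default ±5 nt).
Internal-priming decoys are 18 nt genomic A-runs that attract reads at
a configured rate; peaks are planted at a configured transcript-strand
offset from a chosen PAS (default −50 nt, 31 nt wide).  dPDUI tables
derive PDUI from true usage plus Gaussian noise; their adjusted p-values
are *generated* (small for planted events), since the classification
layer only thresholds them.

Two hygiene rules make ground truth exact rather than merely likely:
background A-runs are capped at 3 nt inside gene bodies, and accidental
UGUA/hexamer occurrences are scrubbed (replaced base-wise) from the
motif-analysis window around each planted PAS and from inter-gene
spacers in both orientations.  Consequently planted internal-priming
labels, motif spacings and cluster positions are the only instances the
pipeline can recover.  Real 3'UTRs are messier — background motif hits,
overlapping genes, variable A-content, sequencing error, fragment-level
effects — so passing these tests demonstrates correctness of the
implemented rules, not end-to-end performance on real libraries.

Determinism: all sampling uses integer-seeded numpy generators with
per-sample derived streams; a fixed `rng_seed` reproduces outputs
byte-identically.

## Study-condition sizes

Default scenarios are 200 two-PAS exons at depth 500 reads/exon/sample
with 3 replicate pairs; the differential-usage scenario uses 500 exons;
positional enrichment uses 400 genes (200 regulated + 200 control).
The two-compartment scenario uses depth 4000: the confident
non-changing rule requires every per-replicate delta to stay within 5%,
and at depth 500 binomial sampling noise alone (SD ≈ 3% per delta)
pushes roughly a third of truly flat exons over that bound, so deep
coverage is a prerequisite of the rule itself — consistent with the
multi-million-read depth of real targeted 3'-end-seq libraries.

## Known limitations

* No BAM handling: read 3' ends are consumed as single-nucleotide BED
  records; strand must be resolved upstream.
* The simplified PDUI estimator is not a DaPars replacement (no
  breakpoint regression, no de-novo sites, no statistics).
* No IDR computation: the reproducible peak tier is whatever
  high-confidence file the user provides.
* The generator models neither sequencing error nor realistic base
  composition, and usage vectors are shared across genes of the same
  event class.
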