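# Methods

This note documents the models, conventions and numerical choices
behind `m6aconserve`, in the spirit of a statistical software methods
appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Conservation labeling

Each candidate adenosine carries an occurrence count `c` out of `T`
profiled tissues (default `T = 23`).  The partition rules are:

* conserved (P): `c == T`;
* tissue-specific / non-conserved (N): `1 <= c` and `c/T < 0.30`;
* excluded: `c == 0`, or `0.30 <= c/T < 1`.

The 30% boundary is exclusive ("fewer than 30%"), so with 23 tissues
the split falls between 6/23 ≈ 0.261 and 7/23 ≈ 0.304.  The zero-count
exclusion is checked before the fraction rule.  Raising the
tissue-specific fraction can only move sites from excluded to
non-conserved, never the reverse (a tested invariant).

## Dataset assembly

Dataset N greatly outnumbers P, so N is split into `k = 10` disjoint
sub-datasets by a seeded shuffle followed by round-robin assignment
(sizes differ by at most one; concatenation is a permutation of the
input).  Each sub-dataset is paired 1:1 with the full P (the larger
side seeded-downsampled to the smaller) to train one ensemble member.
The overall train/test split is stratified 80/20, seeded.  A generic
gene-exclusion filter (`exclude_genes`) supports sensitivity analyses
such as removing housekeeping genes.

## Sequence encodings

Windows of odd length `2·flank + 1` (default flank 20, i.e. 41 nt — the
convention of predecessor single-nucleotide m6A predictors; the window
length is configurable) are extracted strand-aware: minus-strand sites
are reverse-complemented so the window reads 5'→3' on the transcribed
strand, T is converted to U, and positions beyond the chromosome edge
pad with N.  The center base is validated as A (error or warning,
configurable).  Encoders:

* **NCP** — ring count, functional group, hydrogen bonding:
  A=(1,1,1), C=(0,1,0), G=(1,0,0), U=(0,0,1); N=(0,0,0).
* **EIIP** — A 0.1260, G 0.0806, C 0.1340, U 0.1335; N=0.
* **ND** — nucleotide density, the prefix frequency of the base at each
  position (N counted as its own symbol).
* **PseKNC** — k-mer frequencies (k = 3) plus `lam = 2` sequence-order
  correlation factors with weight 0.5, jointly normalized to sum to 1.
  The correlation function uses the three NCP indicators as its
  physicochemical property set, keeping the encoder self-contained
  rather than importing an external property table; windows containing
  N encode to zeros with a warning.

NCP and EIIP are position-wise, so encoding a concatenation equals
concatenating encodings (property-tested).  The default strategy is
NCP+EIIP; NCP+ND and EIIP+PseKNC are selectable for comparisons, each
with or without the genomic block.

## Transcript models

From the GTF, only the primary (longest exonic length) transcript per
gene is kept; ties break to the lexicographically smallest transcript
id.  Isoform counts are recorded before pruning.  UTRs are inferred
from the CDS in transcript coordinates.  Coordinates are 0-based
half-open internally (GTF's 1-based inclusive converted on read; BED
consumed natively).  Coordinate lifting between genomic and mature
transcript positions is verified against an exhaustive per-base walk
on toy transcripts.

Sites are assigned to the containing gene on the same strand; for a
single-base query any containing gene overlaps by exactly one base, so
ties resolve to the smallest gene id.  Intergenic sites keep an
all-zero topology block (with a warning) but remain scoreable.

## The 54 genomic feature slots

| slots | group | content |
|-------|-------|---------|
| 1–15 | dummy | binary membership: 5'UTR, 3'UTR, CDS, exon, intron, first/last exon, long exon (> 400 bp), long internal exon, stop codon ± 100 nt, start codon ± 100 nt, TSS ± 100 nt, transcript body, 5'-most 400 nt of last exon, single-exon transcript |
| 16–19 | rel_pos | relative position (offset / region length, in [0,1]) within 5'UTR, CDS, 3'UTR, full transcript |
| 20–27 | region_len | log2(1+len) of 5'UTR, CDS, 3'UTR, containing exon, containing intron, gene span, transcript span, mature mRNA |
| 28–31 | distance | log2(1+d) to the containing exon's 5' and 3' boundaries (splice junctions), log2(1+d) to nearest conserved training site (same chrom/strand, self excluded), indicator d < 2,000 nt |
| 32–33 | conservation | phastCons-style score at the base; mean over the window (uncovered bases = 0) |
| 34–35 | structure | fraction of window positions paired; center-A-unpaired indicator |
| 36–43 | regulator | overlap indicators vs up to 8 configured interval tracks (reader/writer/eraser binding etc.) |
| 44–48 | gene_prop | log2 exon count, log2 isoform count, protein-coding indicator, log2(1+gene span), log2(1+mature length) |
| 49–51 | gc_z | GC z-scores of window, host exon, host transcript |
| 52–54 | omics | overlap indicators vs up to 3 omics tracks (e.g. miRNA target sites) |

Conventions worth noting:

* Counts (slots 44–45) use log2(count) so a single-exon, single-isoform
  gene scores 0; length- and distance-like quantities use log2(1+x)
  because they are heavy-tailed.
* Relative position in the full transcript uses the mature-mRNA
  coordinate for exonic sites; intronic sites, which have no mature
  coordinate, fall back to the relative position within the genomic
  transcript span so the slot stays informative; intergenic sites are 0.
* Junction distances are measured to the containing exon's boundaries
  in transcript orientation; single-exon transcripts and non-exonic
  sites score 0.
* GC z-scores use sample SD (ddof = 1).  The host-transcript and
  window GC standardize against the distribution of mature-transcript
  GC over all kept transcripts (a window has no natural per-transcript
  distribution of its own); the host-exon GC standardizes against all
  exons pooled.  Zero SD yields z = 0 with a warning.
* Any slot whose track or annotation is unavailable defaults to 0 with
  a one-time warning, so partial configurations still run.
* The slot→name registry is data-driven (YAML-overridable) so the
  canonical naming can be swapped without code change.

### Secondary structure

Slots 34–35 use a deliberately simple, fully deterministic folding
model: the Nussinov-style dynamic program maximizing Watson–Crick plus
GU-wobble pairs with a minimum hairpin loop of 3, tracing back by
pairing each position with its smallest admissible partner.  This is a
topological pairing model, not a thermodynamic one: it captures
"how paired is this window / is the center accessible" without free
energies.  A precomputed dot-bracket string (e.g. from a thermodynamic
folder) can be supplied per window to override it.

## Normalization and the ensemble

Features are min–max scaled to [0,1]: constant features map to 0 and
out-of-range values at prediction time clamp.  Every member fits its
own scaler **on its own training pairs only** — no statistic of
held-out data influences any prediction (scaler provenance is the
tested no-leakage property).

Members are RBF-kernel SVMs at library defaults: C = 1, kernel width
γ = 1/n_features.  Probabilities come from a Platt sigmoid fit on the
member's own training decision values; because the sigmoid is monotone
in the SVM margin, member rankings (and AUROC) equal the uncalibrated
margin's.  (The alternative — the backend's internal cross-validated
Platt fit — proved numerically unstable on small balanced member sets,
inverting probabilities outright, and is deprecated upstream.)  The
ensemble probability is the arithmetic mean over members
(permutation-invariant); the class call thresholds at 0.5, appropriate
for 1:1-balanced training.  Naive Bayes and logistic-regression
backends are registered for comparison runs; the SVM is the shipped
model.

One protocol subtlety: the nearest-conserved-site slots (30–31) are
computed once against the conserved sites of the 80% training split and
reused inside cross-validation folds (the query site always excludes
itself).  This mirrors the single-featurization design of the original
protocol but is a mild information path across CV folds; the strict
no-leakage guarantee applies to normalization and model fitting.

## Evaluation

Sn, Sp, ACC and MCC are evaluated exactly from integer confusion counts
(positive call iff score ≥ threshold; MCC defined as 0 when any factor
under the radical vanishes).  AUROC is the trapezoidal area under the
ROC curve traced over all distinct score thresholds; with ties
collapsed into single steps this equals the pairwise ordering statistic
with half credit per tie, verified against a brute-force pairwise
oracle to 1e−9 on random instances.  Cross-validation uses stratified
folds with ensembles (and scalers) fit inside each training fold.

Feature ranking uses permutation importance on a labeled holdout: the
mean AUROC drop over seeded shuffles of each column.  The
feature-selection curve retrains the ensemble on the top-k genomic
slots (keeping selected columns in original schema order, so k = 54
reproduces the full model exactly) and evaluates on a seeded holdout.

## Synthetic data: what it emulates and what it does not

The generator emits every format the pipeline consumes: i.i.d.-base
FASTA at configurable GC, a GTF of non-overlapping genes (1–10 exons,
exon lengths mixing both sides of the 400 bp threshold, CDS with
flanking UTRs, a fraction of genes with a shorter second isoform),
BED6 sites restricted to DRACH-context adenosines on mature
transcripts, a 23-column tissue indicator TSV, a conservation bedGraph
and 8+3 regulator/omics interval BEDs.  All randomness flows from
numpy PCG64 streams derived from a single seed, so bundles are
byte-identical across reruns and platforms.

The planted class signal at effect strength `e ∈ [0,1]`:

* conserved placement weight 1 + 4e per property for long-exon and
  near-stop-codon candidates (non-conserved placement uniform);
* conservation bump at site neighborhoods: mean 0.30 + 0.35e for
  conserved vs 0.30 otherwise, SD 0.15, clipped to [0,1];
* regulator track i overlap probability 0.2 + 0.5e·(1 − 0.08i) for
  conserved vs 0.2; omics tracks 0.15 + 0.3e vs 0.15;
* tissue counts planted exactly: T for conserved, uniform {1..6} for
  tissue-specific, uniform {7..22} for an excluded slice (defaults:
  30% conserved, 15% excluded).

Both classes share the DRACH sequence context by construction, so the
separation must come from the genomic block — matching the biological
setting in which conserved and non-conserved sites have
indistinguishable motifs.  At `e = 0` the class distributions coincide
and cross-validated AUROC sits at chance; AUROC rises monotonically in
`e` (tested at 0, 0.5, 1).

What the generator does **not** emulate: realistic base composition or
isoform usage, expression levels, peak-calling noise, antibody bias,
inter-tissue correlation structure, or the empirical feature
correlations of real transcriptomes.  Passing the synthetic benchmark
therefore demonstrates that the pipeline's machinery is correct and
that it recovers a planted genomic-feature signal of realistic shape —
it does not certify the accuracy figures achievable on real
atlas-derived data, which require the external corpus.

## Reference problem sizes

The reference benchmark (tests and `scripts/acceptance.py`) uses
2,000 sites over 200 genes on two 700 kb chromosomes — comfortably
desk-scale while keeping several hundred sites per class in every CV
fold.  Fivefold CV of the 10-member ensemble on the 1,360-site training
portion completes in seconds.

## Known limitations

* The 54-slot identities follow the scheme's group structure; where an
  upstream canonical slot list differs in naming, the registry can be
  re-mapped via YAML but the extractor semantics are fixed per group.
* The structure features use maximum base pairing, not minimum free
  energy; supply precomputed dot-brackets for thermodynamic structures.
* Single-transcript featurization: sites on minor isoforms are scored
  against the primary isoform's topology.
* The conservation track reader loads bedGraph into memory; genome-wide
  vertebrate tracks should be pre-sliced to the regions of interest.
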