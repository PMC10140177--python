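# Methods

## Scope and model

`ggbe` analyses amplicon deep-sequencing data from dual-function
C·G→G·C / A·T→G·C base-editing experiments. It covers four stages:
synthetic read generation, read-level quantification, derived editing
statistics, and a multi-nucleotide-variant (MNV) targetability screen.
The package computes per-sample point estimates; hypothesis testing
between editors is out of scope, as are read pre-processing (adapter
trimming, paired-end merging — assumed done upstream), base-quality
modelling, and off-target site discovery (the cumulative-editing
computation on supplied off-target amplicons is in scope, finding the
sites is not).

## Coordinates and conventions

Protospacer positions are 1–20, 5'→3' on the protospacer strand, with
position 1 PAM-distal and the NGG PAM at positions 21–23. The SpCas9
blunt cut is taken to lie between protospacer positions 17 and 18 (3 bp
5' of the PAM), the canonical cleavage geometry. Internally all
coordinates are 0-based half-open on the amplicon strand; reports use
1-based positions. For a protospacer on the minus strand of the amplicon,
reads are quantified on the amplicon strand and position/base labels are
mapped through the strand (a C→G conversion at protospacer position 6
appears as G→C at the complementary amplicon position).

## Synthetic read generator

Each read is generated as: (1) a protospacer allele is sampled — either
independent per-position draws from the substitution rate map, or one
explicit genotype from a frequency list; (2) with probability
`indel_rate` the allele outcome is *replaced* by an indel on the
unedited sequence, anchored at the cut site (deletions remove bases
symmetrically around the cut, left-biased for odd sizes; insertions add
random bases at the cut); (3) the allele is embedded in the amplicon;
(4) a uniform per-base sequencing error substitutes each base with
probability `seq_error_rate`, uniformly among the three alternatives.
Reads cover the full amplicon and qualities are constant Q40 ('I'),
since the pipeline ignores base qualities. Generation is reproducible:
one `numpy` generator seeded per call, same seed → byte-identical FASTQ.

Default parameters model a typical deep-sequenced editing experiment:
amplicons of 100–400 nt (the generator enforces this range), 10,000
reads per locus, dual editing at 30% (C→G at position 6) and 20% (A→G
at position 5), 5% indels with a deletion-dominated size spectrum
(sizes −10…−1, +1…+3), and 0.1% per-base sequencing error. These are
the reference conditions of the acceptance run.

What the generator does **not** emulate: PCR duplicates and chimeras,
quality-dependent errors, strand- or position-dependent error profiles,
fragmentation/paired-end structure, and editing outside the protospacer
(e.g. deaminase activity in the flanks). Passing tests therefore
demonstrate correctness of the estimators under the declared generative
model, not robustness to every artefact of real libraries.

Because indel reads replace the substitution allele, the expected
observed conversion frequency at an edited position is
`(1-indel_rate)·rate` (plus the sequencing-error floor `e/3` from
unedited reads), and the analytic expectations used by the tests account
for this.

## Alignment and quantification

Reads are aligned globally (end gaps penalized) with affine gap scoring:
match +5, mismatch −4, gap open −20, gap extend −1, where a gap of
length L costs `20 + (L−1)`. Alignment uses Biopython's
`PairwiseAligner`; the test suite checks its scores against an
independent exhaustive Gotoh dynamic program. When the optimal alignment
is degenerate the aligner's first optimum is taken — indel placement
within a repeat may therefore shift by a column, which does not affect
window-level indel counts. Reads with identity (matches / reference
length) below 60% are discarded and counted; the threshold rejects junk
while retaining reads carrying a 10-nt indel plus sequencing errors.
Identical read sequences share one alignment (memoisation), so run time
scales with the number of distinct reads.

The nucleotide percentage table reports, per reference position, the
fraction of covering reads with each base, N, or a deletion; insertions
do not create positions, and end gaps leave positions uncovered rather
than deleted (denominator = covering reads). Indel-bearing reads remain
in the substitution denominators at positions they cover, with deletion
as its own category — matching the per-position output convention of
standard amplicon quantifiers. The quantification window follows the
`-wc/-w` parameterisation: the centre sits `wc` positions back from the
PAM-proximal protospacer end and `w` positions are taken around it, so
the defaults (10, 20) resolve to protospacer positions 1–20. Indel
frequency is the percentage of retained reads with ≥1 insertion or
deletion overlapping the resolved window (an insertion counts when its
junction touches the window).

The genotype table groups reads by their aligned protospacer-region
sequence (insertions inside the region included, deletions as `-`);
reads not fully covering the region are left unclassified and reported.
Rows are sorted by count descending, ties broken lexicographically.

## Derived statistics

* Total editing sums per-position conversion frequencies over all 20
  protospacer positions (a window-restricted variant is available); it
  is a sum and may exceed 100%.
* The D-value is defined here as the **absolute** difference between
  total A→G and total C→G editing. The statistic is a magnitude-like
  balance measure, so the sign is dropped.
* Window efficiency is the **unweighted mean** over source-base
  positions in the window (not the maximum); windows default to
  positions 4–7 (GGBE1.0) and 5–7 (GGBE1.3), the ranges where these
  editors concentrate their activity.
* Purity at a cytosine divides each product base's fraction by the
  summed edited fraction, excluding deletions and N; it is flagged
  undefined (`None`) when no editing is observed.
* The concurrent fraction counts indel-free alleles only; indel reads
  are reported separately via the indel frequency.
* Cross-locus aggregation averages per-position frequencies over the
  loci whose reference base at that position is the source base;
  positions with no qualifying locus are reported absent (NaN).

## MNV screen

Eligibility is restricted to trinucleotide pairs differing at exactly
two positions where the change decomposes into one A→G plus one C→G
edit: the variant→wild-type direction defines "correcting", wild-type→
variant "creating". This is exactly the 12-pattern space (6 per
direction, closed under arrow reversal); pairs differing at 1 or 3
positions, or needing any other conversion, classify as "none" rather
than being guessed at. Patterns are applied to the trinucleotide as
supplied — no reading-frame inference. Both strand orientations are
evaluated: a reverse-complement match is reported with a strand flag,
which implements the "matching T and G bases" view (a minus-strand
protospacer sees A/C where the plus strand shows T/G). The four base
multisets involved ({G,G}, {C,C}, {A,C}, {T,G} at the differing
positions) are disjoint, so every pair has at most one classification.

Guide search scans every 23-mer (20-nt protospacer + NGG) on both
strands of the context and keeps placements where both edited bases fall
at protospacer positions 5–7 — the restricted high-efficiency window —
reading one A and one C on the protospacer strand. Both MNV bases must
be editable from the *same* protospacer strand, matching the
single-guide design of a dual editor; configurations where the A and C
sit on opposite strands are not reported. Other A/C bases inside
positions 5–7 are reported as bystander warnings, not filtered, since
bystander editing is an observed property of these editors, not a design
error. In the table-level screen the genome is expected to carry the
reference allele; the editable allele (variant for correcting, reference
for creating) is substituted into the fetched context before scanning,
and a mismatch between genome and record is reported as a per-record
error without stopping the screen.

## Numerical and design choices

* Alignment scoring constants and the 60% identity filter are fixed
  package policy (see above); they are deliberately permissive to keep
  large-indel reads.
* Genotype-table tie-break is lexicographic; all report fractions are
  exact ratios of integer counts, so per-position fractions sum to 1 to
  floating-point accuracy.
* Degenerate inputs error early: empty read sets, zero retained reads,
  windows outside the reference, conversion queries at positions whose
  reference base does not match, profiles whose per-site product
  probabilities exceed 1.
* The CLI is a thin layer over the library; every output TSV starts with
  a `#` provenance line (tool version, parameters, seed) and is
  reproducible byte-for-byte for a fixed configuration.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
at desk scale: 10,000 reads for parameter-recovery checks (3-binomial-SE
tolerances), 20,000 for the concurrency product-rule check, 200 random
pairs/contexts for the alignment and guide-search oracle comparisons,
and the exhaustive 4096-pair trinucleotide space for the pattern
classifier. These sizes make every statistical tolerance a property of
the binomial sampling noise, not of the implementation.

## Known limitations

Substitution quantification is alignment-based with a single optimal
alignment per read; heavily repetitive amplicons could mis-place indels
locally. The generator's independence assumption between positions is a
modelling choice — real editors show correlated outcomes — and the
concurrency product-rule check is valid only under that assumption.
Off-target analysis is limited to cumulative editing on user-supplied
amplicons. The MNV screen does not curate clinical significance, fetch
population variant lists, or score guides for off-target risk.
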