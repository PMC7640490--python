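# Methods

This note documents the models, conventions and numerical choices behind
`inschar`, and what its synthetic study conditions do and do not show about
real data.

## Coordinates and record model

An insertion is stored as the 1-based position of the reference base
immediately preceding the inserted sequence (the VCF anchor) plus the
inserted sequence itself. Internally all interval arithmetic is 0-based
half-open; the VCF convention is converted at I/O only. Multi-allelic
records are split into one record per insertion ALT. Symbolic `<INS>`
records are retained, flagged unresolved, and excluded from
sequence-level analyses until resolved. Records are assumed left-normalized
as in VCF; homology is computed at the coordinates as given.

The gold-standard filters retain records that are strictly larger than the
size threshold (default 50 bp), sequence-resolved, on a "core genome"
chromosome allow-list (default: the primary chromosomes; alt/decoy/unplaced
contigs are excluded — the notion is not otherwise standardized, so the
list is configurable), optionally supported in a parent via a configurable
INFO key, and — for callsets following the giab convention — free of the
`LongHomRef` FILTER label. Records with missing discovery-technology tags
are conservatively counted as "other" (they cannot be credited to short
reads) and a warning is collected. The grammar separating discovery from
refinement `Ill` labels inside `ExactMatchID` is not standardized either;
tokens matching a configurable refinement pattern (default: containing
`refine`, case-insensitive) are not counted as short-read discoveries.

## Alignment primitives

The package needs a genome-scale local aligner with a BLAT-like contract
(find all loci similar to a query at ≥ 90% identity), a tandem-array
detector and an end-to-end identity measure. These are provided in-house:

* **Local alignment** is seed-and-extend: exact 11-mer seeds from a 2-bit
  k-mer index, clustered by diagonal (drift ≤ 16 bp, along-target gap
  ≤ 120 bp), each cluster refined by a Smith–Waterman alignment
  (match +2, mismatch −3, affine gap 5/2) of the query against the padded
  candidate window. Both strands are searched. Identity is defined as
  matched columns / alignment columns, gaps counted as columns, and `N`
  never matches anything. A minimum of 30 matched bases per reported
  alignment (reduced proportionally for short queries) plays the
  minimum-score role of a genome-scale aligner; without it, isolated
  chance 11-mer hits accumulate into spurious coverage on long queries.
  Near-duplicate loci (> 90% target overlap) are collapsed keeping the
  highest identity, leftmost on ties.
* **Global identity** is computed from an edit-distance alignment path.
  Optimal paths are not unique, so the pair is ordered canonically before
  alignment; this makes the function exactly symmetric at no cost.
* **Tandem detection** brute-forces all periods up to 64 bp (larger
  candidate periods are proposed from repeated 8-mer spacings), and for
  each period finds the longest window of consecutive copies whose overall
  match fraction against the previous copy is ≥ 90%. Coverage is the
  array span (seed copy included) over the full sequence length; at least
  two copies are required; for near-identical spans the smallest period
  wins. This is a coverage-based contract — it reports what fraction of an
  inserted sequence is tandem-structured — not a reimplementation of any
  particular repeat finder's scoring model.
* **Genomic copy counting** counts disjoint loci with an alignment of
  ≥ 90% identity covering ≥ 80% of the query, merging loci that overlap by
  more than half.

## Classification

Evidence coverages per insertion: tandem coverage from the tandem scan;
mobile-element coverage from alignments to the consensus library; tandem
duplication coverage from aligning the two flank windows (each the
insertion's own length, capped at 10 kb to bound cost) against the inserted
sequence; dispersed-duplication coverage from genome alignments excluding
those flank windows; novel evidence is the fraction covered by nothing.
"Contiguous segment" tolerates gaps of up to 10 bp between merged same-type
blocks, absorbing residual sequencing errors in long-read-derived
sequences. Insertions shorter than the aligner's 20 bp minimum get
tandem-scan evidence only and are flagged.

The decision-tree priority is tandem repeat > mobile element > tandem
duplication > dispersed duplication > novel sequence; the order is
configurable, and the dispersed branch additionally requires genomic copy
count < 50 so that high-copy elements cannot masquerade as dispersed
duplications. Mobile-element evidence uses alignment to consensus
sequences rather than profile-HMM scoring; the contract consumed
downstream — coverage of the inserted sequence — is the same. Mixture
records and segmental-duplication/CNV sub-typing are out of scope.

## Junctional homology

The strict scan compares the 10 bp left of the site with the last 10 bp of
the insertion, and the 10 bp right of the site with its first 10 bp,
counting identical bases outward from the site until the first mismatch
(capped at the insertion length). If either side saturates the cap, the
alignment tier searches local alignments between the flank windows (the
insertion's length, capped at 10 kb — the same alignments the tandem
duplication evidence uses) and the inserted sequence, keeping candidates at
≥ 90% identity whose endpoints lie within 10 bp of the site and within
10 bp of the relevant sequence extremity; among candidates the one closest
to the extremities wins, with the larger homology on ties (a conservative
upper estimate). The reported total is the larger of the two tiers'
overlap-corrected sums. The alignment tier is only consulted when the
strict scan saturates: below that, alignment seeds (11-mers) cannot
represent the homology anyway.

The null model plants `n` uniform-random A/C/G/T insertions of fixed
length at uniform sites and scores them with the identical machinery.
Analytically, each side's strict-scan size is near-geometric with
P(size ≥ k) ≈ 4^−k, so the two-sided total exceeds 7 bp with probability
≈ 1.1 × 10⁻⁴ per insertion; the maximum over 2,000 draws is therefore
usually 6–7 but occasionally 8. The null's maximum is a stochastic
quantity, not a constant.

## Simulation suite

22 datasets of 200 homozygous insertions each (1 baseline + 3 sizes +
5 types + 5 homologies + 5 contexts + 3 real-derived; the non-repeated
context dataset is identified with the baseline, whose exonic sites are
repeat-free — this identification is what makes the suite total 22 rather
than 23). Baseline insertions are 250 bp novel donor sequences placed
inside exons; donor sequences stand in for foreign (non-self) coding
sequence and are random-composition, hence absent from the reference.
Site locations are drawn once per suite seed and shared by the baseline,
size, type and homology scenarios; size-scenario donors are fresh draws at
each size. Tandem-repeat insertions tile a 6 or 25 bp seed taken from the
left junction; tandem duplications copy the 250 bp right flank; mobile
elements are 200–300 bp cuts of annotated element instances; dispersed
duplications are exon segments of the same chromosome. Homology scenarios
replace the first X bases of each baseline insertion with the right-flank
sequence. The proximal dataset takes n/2 baseline sites and adds one
companion insertion 5–150 bp downstream of each.

**Pinning designed homology.** A local aligner will happily extend an
alignment past a single mismatch, or gap-shift onto chance matches, so a
planted X bp homology would measure as X+ε at some sites. The generator
therefore makes the 20 bases following the planted segment *unalignable*
against the flank: every base mismatches at offset 0, and at every offset
within ±10 the block has no match run longer than 3 and at most 45%
matches. This guarantees the designed homology is exactly what the
detector measures, which is what makes the cross-module recovery tests
exact rather than approximate. The same guard enforces zero homology at
baseline junctions.

Read simulation is delegated: the module writes the mutated FASTA and
truth VCF that read simulators and SV callers consume (the study design
this suite supports used 2×150 bp reads at 40× with 300 bp inserts, and
long reads at 40× with 16% error).

## Evaluation

Calls are filtered to PASS (optional) and size > 50 bp; symbolic calls
whose INFO carries duplicated-copy coordinates (configurable keys
`DUP_CHROM`/`DUP_START`/`DUP_END`, 1-based inclusive — no standard
convention exists) are resolved from the reference. Matching is greedy
one-to-one by increasing site distance with leftmost-call tie-breaks; the
one-to-one choice prevents a single call from validating two truth
insertions, which matters for the proximal scenario. Sequence resolution
uses end-to-end identity: the criterion compares one whole predicted
insertion against one whole simulated one, so a free-endpoints local
criterion would be too lenient. False positives are absolute counts among
retained calls only. Multi-caller combination intersects and unites the
per-tool site-TP sets over truth indices. Long-read-style evaluation
(e.g. 80% identity) is expressed through `MatchConfig`.

Cross-callset comparison treats sites less than 1,000 bp apart as the same
variant; the pairwise count uses one-to-one nearest matching and the
multi-way count clusters sites by single-linkage within the window — a
deliberately rough site-level estimate that ignores type and sequence.

## Synthetic study conditions

The synthetic genome (default 1 Mb here; 600 kb in the test suite to keep
full runs in seconds) plants non-overlapping gene models, genuine tandem
arrays (half under, half over 300 bp), SINE-like (300 bp) and LINE-like
(1.2 kb) element instances at ≤ 10% divergence from library consensus, and
an off-library repeat family, over an i.i.d. background at human-like GC
(0.41). Divergence of planted copies stays below 10% so the 90%-identity
rules bind realistically. Labeled callsets construct each record to
satisfy exactly one sub-type definition with ≥ 0.95 evidence coverage.

What this does not emulate: real base composition and repeat phylogeny,
polymorphism between sample and reference, sequencing error in the
inserted sequences, heterozygosity, overlapping/nested repeats at
realistic density, and read-level artefacts. Passing the recovery tests
therefore shows the machinery is correct on its own definitions — each
module measures exactly the property the generator designed — not that
real callsets are this clean; on real data the unassigned fraction is
driven by those unmodelled effects.

## Defaults

| Parameter | Default | Units | Role |
|---|---|---|---|
| min size filter | 50 | bp | strictly-greater retention threshold |
| Min_cov | 0.80 | fraction | minimal evidence coverage per sub-type |
| min identity | 0.90 | fraction | all alignment evidence |
| dispersed copy max | 50 | copies | dispersed-vs-element boundary |
| merge gap | 10 | bp | contiguity tolerance between blocks |
| flank window cap | 10,000 | bp | tandem-dup/homology window bound |
| strict-scan cap | 10 | bp/side | small-homology tier |
| site margin | 10 | bp | site-only recall |
| size tolerance | 0.10 | fraction | sequence-resolved recall |
| comparison window | 1,000 | bp | cross-callset site identity |
| insertions per dataset | 200 | count | simulation suite |
| null insertions | 2,000 × 250 | count × bp | homology null |
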