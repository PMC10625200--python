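# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical conventions.

## Coordinate and format conventions

All internal coordinates are 0-based, half-open. SAM positions (1-based)
are shifted at the parsing boundary; BED is consumed as-is. The alignment
gap character is `-` (`.` is normalised on input). Only the CIGAR
operations M, I, D, N, S are accepted: that is the complete vocabulary of
spliced single-end/paired-end RNA-seq alignments, and rejecting the rest
turns silent misinterpretation into an error. Reference-consumed intervals
are the M/D runs; N gaps denote splice junctions and never contribute to
overlap.

## Promoter signature screen

The screened signature is a TBPL2/TFIIA-type core-promoter element
described by three components:

* an IUPAC consensus (default `TTCTTAA`, mismatch budget 1) expected a
  fixed distance upstream of the TSS — the **offset convention** is motif
  *start* to TSS, default 32 bp, tolerance ±5 bp. The tolerance absorbs
  the empirically observed alternative placement a few bp away from the
  exact element;
* a CT-rich window immediately upstream of the TSS and a GA-rich window
  immediately downstream (default 10 bp each, minimum fraction 0.8 each).
  "Rich" is never quantified in the literature the screen distils, so the
  thresholds are package defaults and fully config-exposed;
* a deletion test: the reference promoter region (motif start through
  TSS + downstream window) is projected through the alignment and a
  species whose projection is ≥ 50% gapped **over reference-residue
  columns** is called `region_deleted`. Restricting to reference columns
  matters: an insertion private to a third species adds columns in which
  everyone else is gapped, and a naive gap fraction would push all species
  toward `region_deleted`.

Classification is anchored: the reference species must carry an exact
consensus hit at the expected offset, otherwise the screen aborts. Every
other species is scanned only in the projected motif neighbourhood
(± tolerance), then called `present` (hit within budget, context passes,
offset within tolerance), `partial` (a hit up to `partial_max` mismatches
— default budget + 2 — with some condition failing; this is the
"conserved to some extent, with multiple mismatches" band), or `absent`.
Setting `partial_max` equal to the mismatch budget collapses the screen to
the three-label mode used against generator truth, whose alphabet is
{present, region_deleted, absent}.

Orientation is the caller's responsibility (`reverse_complement` is
provided); the screen assumes sequences already oriented to the sense of
the screened gene.

## Conservation HMM

A deliberate simplification of phylogenetic conservation segmentation
(phastCons-style): no tree, no substitution model. Each column is reduced
to `(n_nongap, n_match)` where `n_match` counts rows equal to the column's
majority residue (ties to the lexicographically smallest residue;
`N` participates like any residue). A two-state HMM with binomial emissions
— conserved match probability 0.9, background 0.55 by default — is decoded
by forward–backward in log space (underflow raises, never NaNs). The
parameterisation keeps the two knobs that control segmentation behaviour:

* expected conserved run length `L` (default 7): conserved self-transition
  `1 − 1/L`;
* stationary conserved coverage `γ` (default 0.3): background→conserved
  rate `ν = (γ/L)/(1 − γ)`. Validity requires `γ ≤ L/(1+L)` (otherwise
  `ν > 1`), which is enforced at construction.

The initial distribution is the stationary one, `(γ, 1 − γ)`; all-gap
columns emit likelihood 1 in both states, so an uninformative track decodes
to `γ` everywhere. This scorer reproduces the qualitative behaviour the
pipeline needs — localisation of conserved peaks at a chosen length scale —
and is exactly testable against exhaustive path enumeration; it does not
reproduce phastCons numeric scores, and ρ/coverage estimation by EM is out
of scope.

## Identity windows

Longest common exact substring via a suffix automaton of the first
sequence, checked in tests against a quadratic dynamic-programming oracle.
`N` matches nothing, including another `N`: the statistic is a proxy for
whether short reads could cross-map between paralogs, and ambiguity codes
must not inflate it. Ties resolve to the smallest `(pos_a, pos_b)`.
Reverse-complement search is off by default (mRNA-vs-mRNA comparison) and
available by flag.

## Expression quantification

RPKM uses the exon-union length and a library size defaulting to all
primary mapped records (fragments in paired mode) — the library-size
definition is config-exposed because published pipelines vary. A read
overlaps a gene when its M/D blocks intersect the exon union by ≥ 1 bp
(`min_overlap` exposed); gene counting is unstranded, while TSS-window RPM
is always strand-aware (CAGE semantics: the read's 5′ end must fall in the
window on the matching strand; default window 200 bp). Ratios of RPKM
values raise on a zero denominator rather than returning infinity.

## Exon-skipping statistic

For a target exon pair counted from the 3′ end (strand-aware; the pair must
be consecutive and internal), an *exclusion* read carries the junction
joining the two flanking exons with both boundaries exact, and an
*inclusion* read carries any junction with a boundary at either target
exon. Exact matching (slop 0) reflects counting of annotated splice
events; a slop parameter exists for noisy aligners. A read exhibiting both
junction types counts as exclusion — it demonstrates the skipped product.
Whether inclusion evidence should require both target exons rather than
either is genuinely open; the either-boundary reading is implemented and
config-exposable in principle (the boundary set is a local variable by
design — one rule, stated here).

## TE insertion statistics

Eligibility is the strict filter: a subfamily is analysed only with
**more than** 50 insertions outside gene annotation (zero-bp overlap with
any gene body, introns included — TE reads inside genes are confounded by
host transcription) having **more than** 5 reads in either condition.
Classification normalises to counts-per-million with pseudocount 0.5 and
calls fold > 2 up, < 1/2 down, else same.

The differential-expression probability is an explicit resampling
approximation in the spirit of NOISeq-sim, for designs without biological
replicates: each condition is resampled into 5 multinomial technical
replicates at 20% of the library depth; within-condition replicate pairs,
pooled over features, form a noise cloud of (|log2 fold|, |CPM difference|)
pairs; a feature's probability is the fraction of noise points strictly
dominated in both coordinates by its observed between-condition pair.
Numeric agreement with the published tool is not claimed — the contract is
calibration (few null features reach probability 0.95) and power (strong,
well-expressed changes almost always do), both checked by simulation.

## NG86 dN/dS and the LRT

Sites: per codon position, the fraction of non-stop single-nucleotide
changes that are synonymous; each position contributes
(synonymous fraction, 1 − synonymous fraction), so S + N = 3 per compared
codon, averaged over the two sequences. Differences: multi-substitution
codons are averaged over all orderings of minimal mutational paths, with
paths through stop codons excluded (a codon pair whose every path is
blocked is skipped). Proportions are Jukes–Cantor corrected,
`d = −(3/4)·ln(1 − 4p/3)`; `p ≥ 3/4` is reported as saturated rather than
NaN. Codons containing `N` in either sequence are skipped pairwise,
matching the upstream convention of masking internal stops as `NNN`.
Biopython's NG86 serves as an independent cross-check in the test suite;
the two differ a few percent on sequences with stop-adjacent codons
because Biopython weights those sites by a fixed /3 rather than by the
non-stop mutation count.

Maximum-likelihood branch models are out of scope; the likelihood-ratio
utility (`2ΔlnL` against a χ² upper tail) supports comparing externally
fitted models at the conventional 5% and 1% levels.

## Synthetic data: what it emulates, and what it does not

All generators require an explicit seed and are byte-level reproducible.

**Alignment evolution.** Jukes–Cantor substitutions (per-site change
probability `(3/4)(1 − e^(−4rt/3))` per branch), indel events at a per-site
rate with geometric(0.5) lengths capped at 20 bp, half insertions half
deletions. The promoter block is written into the MRCA of the gaining
clade and frozen there (no substitutions, no indels within or into the
block) — modelling a functionally constrained element against a drifting
background; on the root-to-MRCA stem the block's future sites are shielded
from indels so the planting site exists. The lineage-specific deletion
replaces a window (in ancestor coordinates) by gaps. The ready-made
scenario (`promoter_screen_scenario`) uses a balanced 20-leaf tree with a
4-leaf gaining clade, unit branches, substitution rate 0.04/site/branch
(moderate background divergence), indel rate 0.001/site/branch (a
realistic ~1:40 indel:substitution ratio), a 5 kb ancestor, and a G-run
background at the promoter locus so that non-gaining lineages carry no
motif-like sequence — which is the biological situation being emulated.
Not emulated: rate heterogeneity across sites, realistic indel length
tails, alignment error (the generator emits the true alignment).

**Spliced reads.** Single-end reads drawn uniformly along a Bernoulli
mixture of the full-length and the exon-skipping isoform; CIGARs are exact
against the gene model. The default demonstration gene's exon lengths are
chosen so the probability of spanning a discriminating junction is equal
between isoforms (skipped mature length 199 nt vs full 499 nt at read
length 50 with three informative inclusion junctions), making the
read-level exclusion/inclusion ratio a direct estimate of the mixing odds
`f/(1−f)`. Paired-end counting logic is exercised on hand-written records
rather than a fragment simulator. Not emulated: sequencing error, quality
strings, coverage bias.

**TE counts.** Per-insertion Poisson counts around a subfamily mean,
condition B scaled by the subfamily's true fold change; a fixed fraction of
insertions per subfamily is genic. Truth records fold changes and
eligible-insertion counts.

**Codon pairs.** Exactly `n_syn` synonymous and `n_nonsyn` nonsynonymous
single-nucleotide changes at distinct codons, never creating stops —
giving NG86 a known `(Sd, Nd)` before correction.

**HMM columns.** Sampled from the conservation HMM itself (stationary
start), with the true state path returned, for posterior-recovery checks.

Consequently, passing tests demonstrate correctness of the statistics and
their recovery behaviour under the stated generative models; they do not
demonstrate robustness to alignment error, mapping artefacts or
overdispersed counts, which real data exhibit.

## Problem sizes and determinism

The recovery checks run at desk scale: 50 replicate screens of 20 species ×
5 kb, 5,000 HMM columns, 500 identity-window pairs of 300 nt, 10,000
simulated reads, 2,000 TE features. These sizes give the comparisons
comfortable statistical resolution (e.g. 3·binomial-SE bands of ~1.5% on
the splice fraction) while keeping the whole suite and the acceptance
script fast. Every stochastic step derives from an explicit integer seed;
re-running any generator or the full pipeline with the same configuration
reproduces outputs byte for byte.
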