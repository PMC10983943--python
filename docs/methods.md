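# Methods

This note records the models, conventions and numerical choices behind
`editaudit`, and what the synthetic cohorts do and do not establish.

## The audit model

An edited clone's genome differs from the reference by (a) known parental
mutations, (b) the intended edit, and (c) unintended mutations. The audit
operates on variant tables produced by a resequencing pipeline (consensus or
population mode), applies a read-fraction floor, removes (a) and (b) by exact
(position, ref, alt) key, and treats the remainder as unintended. Calls that
are not exact matches but fall within a positional tolerance of an intended
edit are flagged `near_intended` rather than silently dropped, since partial
cassette incorporation produces near-miss calls that deserve inspection.
Identical calls recurring in two or more clones of one experiment are flagged
`possibly_preexisting` (they may have arisen in the shared founder population)
but still count toward per-clone totals.

Coordinates are 1-based on the forward strand throughout the I/O surface,
matching the GenomeDiff/Breseq convention; the read-fraction floor is strict
(`fraction > floor`, default 0.10), so a call at exactly 10% of reads is
dropped.

## Poisson null model

Unintended mutations under no editing stress accumulate as a Poisson process:
with a per-nucleotide rate μ = 2.0×10⁻¹⁰ per generation (the mutation-
accumulation literature value for *E. coli* K-12) and genome length
L = 4,641,652 bp, the per-genome rate is μ_g = μ·L ≈ 9.3×10⁻⁴ per generation,
and the expected fraction of clones with at least one mutation after g
divisions is f = 1 − exp(−μ_g·g) — 7.2% at g = 80. A `linear` variant
(f = μ_g·g, capped at 1) is available for comparison; at these loads the two
agree to first order and `poisson` is the default. The inverse estimator
μ̂_g = −ln(1−f̂)/g is used for parameter recovery.

## Proportion testing

The unit of analysis is the clone (mutated: yes/no), not the mutation count.
Group proportions are compared with the k-proportion chi-square against the
pooled proportion (df = k−1; algebraically the Pearson statistic of the 2×k
table, and the squared two-proportion z statistic at k = 2). Post-hoc pairs
use the Marascuilo procedure: pair (i, j) is significant at family-wise α
when |p_i−p_j| exceeds √(χ²₁₋α,k₋₁)·√(p_i(1−p_i)/n_i + p_j(1−p_j)/n_j).
The procedure natively yields critical ranges, not p-values; the reported
"minimal adjusted alpha" is the smallest family-wise α at which the pair's
flag flips, found by bisection (the flag is monotone in α) to 10⁻¹⁰ and
cross-checked in tests against the closed form χ²-sf((|p_i−p_j|/SE_ij)²,
k−1) via a grid oracle. Degenerate proportions (0 or 1) give a zero variance
term; the critical range remains defined, and a nonzero difference between
two degenerate groups is significant at every α (minimal α reported as 0).

## Off-target scanning

A candidate Cas9 off-target site is a genomic window adjacent to a PAM
(default NGG, 3′ of the protospacer, never counted as mismatch) whose best
alignment to the 20-nt spacer satisfies two bounds: mismatches + gaps ≤ 6
and gaps ≤ 2. Conventions fixed here:

- **Gaps count bulged bases.** Each inserted (DNA-bulge) or deleted
  (RNA-bulge) base costs 1 toward both the gap count and the additive
  mismatch-plus-gap budget. This is the reading under which "six mismatches
  plus gaps" is a single budget and matches bulge-size reporting in
  Cas-OFFinder-style tools. An alternative convention counting bulge
  *events* (a contiguous run costs one gap regardless of length, runs capped
  at 2 bases) is implemented as `gap_mode="events"`; tests demonstrate where
  the two diverge (multi-base bulge runs).
- **Anchoring.** The alignment is anchored at the PAM-proximal end and free
  at the distal end, so windows of 20±2 genomic bases are searched
  implicitly. Per PAM-anchored window the minimal (mismatch+gap, gap)
  alignment is reported, with a deterministic traceback preference
  (match/mismatch, then DNA bulge, then RNA bulge) for rendering.
- **Coordinates.** A hit's position is the 1-based forward-strand coordinate
  of the PAM-proximal protospacer end. Circular genomes are scanned with a
  (window+PAM)-length wraparound pad and hits canonicalized modulo L.
- **Algorithm.** PAM positions are located by IUPAC regex; each candidate
  window is screened with an unconstrained edit-distance prefilter (edlib,
  admissible because the unconstrained optimum never exceeds the constrained
  cost) and survivors are aligned by a banded DP over (spacer position,
  genome position, bulged bases), band ±2. Equivalence with an exhaustive
  window-enumeration oracle (plain recursion, no band, no prefilter) is
  asserted over 200+ seeded random genomes plus planted degenerate sites.

Fixed recognition sites (I-SceI's 18-bp TAGGGATAACAGGGTAAT) are scanned
mismatch-only on both strands with a vectorized Hamming profile. The known
I-SceI off-target inside the IS5 element is published only as a figure; no
machine-readable sequence ships here, so fixed-site scanning is validated on
planted sites.

Activity scoring (CFD/MIT, seed weighting) is deliberately out of scope; the
audit filters by counts only.

## Proximity statistics

Distances are circular (shorter arc), measured from the mutation position to
the nearest *edge* of a site's occupied interval (0 inside the interval). At
kilobase scales the ≤23-bp interval width is immaterial, but the edge
convention makes zero-distance tests exact. Summaries report the arithmetic
mean (rounded to whole kb), the count within 2 kb, and 1-kb histogram bins
(bin i = ⌊d/1000⌋). For m sites placed independently of mutations on a
circle of length L the mean nearest-site distance is ≈ L/(4m), a useful null
reference checked by simulation.

## Pool demultiplexing

Pooling clones at designed fractions (typically 18/32/50%, remainder
unsequenced carrier) lets one sequencing run cover several clones; a
clone-private mutation's read fraction estimates its clone's fraction.
Assignment is by relative distance |f−d|/d (binomial noise scales with the
fraction): the nearest designed fraction within a relative tolerance
(default 25%) wins, ties to the smaller fraction; otherwise the nearest
2-subset sum (flag `shared`) or 1.0 (flag `parental_like`), whichever is
relatively closer within tolerance; otherwise `unassigned`. Single-clone
matches take precedence over sums, so a fraction near 0.50 in an
18/32/50 design reads as the 50% clone, not as 18+32.

**Recovery ceiling.** At total depth 100× the observed fraction of a
private mutation is Binomial(100, d)/100. Exact binomial sums show that
even the Bayes-optimal (maximum-likelihood) assignment to {0.18, 0.32,
0.50} recovers 95.0/91.3/97.2% per clone — 94.5% on average — and the
relative-distance rule at its 25% tolerance recovers 87.6% (the lower
binomial tail of the 18% clone falls outside its tolerance band). Recovery
approaches 100% as depth grows (the suite checks monotonicity and the
noiseless limit); at 100× a ~12% loss on the smallest fraction is
intrinsic, not an implementation artifact. Practical designs wanting ≥95%
clone attribution at these fractions need roughly ≥300× pooled depth.

## Synthetic cohorts

The generator emulates the audited study design: per-clone mutation counts
~ Poisson(μ_g·g) with positions uniform on the circle; class SNV with
probability 0.9 (the observed dominance of single point mutations), else a
1-bp insertion or deletion — finer indel or structural modeling would add
nothing the audit measures. Pools draw read fractions binomially; there is
no sequencing-error model (the 10% read-fraction floor suppresses that
regime in real data) and no read-level (FASTQ) simulation. Planted
protospacer truth stores *intended* mismatch/bulge counts; an edit can
create a cheaper alternative alignment, so tests assert scanner cost ≤
intended with equality enforced against the oracle.

Study conditions used by the analysis scripts, chosen once: baseline
μ_g = 9.28×10⁻⁴ (μ = 2.0×10⁻¹⁰ × 4,641,652 bp), g = 80 divisions (110 for
the I-SceI arm, whose protocol adds ~30 divisions), arm sizes 117/52/48/19,
pool fractions (0.18, 0.32, 0.50) at depth 100×, SNV share 0.9. The edited
arms' elevated rates are solved from the observed mutated-clone proportions
(e.g. −ln(1−31/117)/80 ≈ 3.9×10⁻³), which models the *consequence* (more
Poisson-distributed mutations genome-wide, consistent with SOS-induced
error-prone polymerase activity) without simulating the mechanism. Synthetic
genomes are 200 kb: proportion statistics are scale-free in genome length,
and proximity means scale as L/(4m), so conclusions transfer after scaling;
what the synthetic cohort cannot establish is anything about real off-target
counts on a specific 4.6-Mb genome, which require that genome as input.

Passing tests on synthetic data show the machinery is correct under the
stated statistical model; they do not validate the model against real
sequencing artifacts (mapping errors, repeat regions, contamination), which
the upstream variant caller must handle.

## Numerical choices and degenerate inputs

- Seeds: every stochastic routine takes an explicit seed (numpy
  `default_rng`); identical seeds give byte-identical outputs, and writers
  use canonical formatting (`%.6g` fractions) so write→read→write
  round-trips bytes.
- Scanner ties: minimal (cost, gaps) wins; among equal alignments the
  traceback preference is fixed; duplicate representatives of one
  PAM-anchored window (circular wrap) are canonicalized modulo L.
- Empty inputs error loudly: zero-record genome files, empty spectra, empty
  pool designs, empty hit lists in proximity (the message says to widen the
  scan bounds), groups with zero clones.
- Genomes shorter than spacer+PAM are rejected; non-ACGT spacer characters
  are rejected; genome ambiguity codes count as mismatches to every spacer
  base.
- Start-codon distances use annotated gene starts on either strand in
  circular distance; promoters are not modeled beyond the 100-bp proxy.
  Codon table 11; alternative initiator codons translate as Met at codon 1
  only.

## Known limitations

- The GenomeDiff reader covers SNP/INS/DEL/MOB mutation lines only, and
  `.gd` lines carry no reference base: it is filled from the genome when
  supplied, else written as `N`.
- Joint likelihood deconvolution across pools, haplotype phasing, VCF
  ingestion and spatial clustering tests are out of scope.
- The full-genome off-target count (138 sites for the mCherry spacer on
  MG1655) and the supplementary-data proximity means (38/22 kb) require the
  reference genome and study datasets as external inputs; the corresponding
  tests fail with instructions until those files are provided under
  `data/external/`.
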