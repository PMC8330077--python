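# Methods

This note documents the models behind each `methylatlas` module, the
parameters that matter, the numerical choices, and what the synthetic
generators do and do not emulate.

## CpG o/e statistic and profiling

For a sequence with `CpG` CG-dinucleotide occurrences, `C` and `G`
nucleotide counts and effective length `L` (N residues excluded), the
normalised CpG content is

    o/e = (CpG / (C · G)) · (L² / (L − 1)).

N handling: counts are taken over non-N residues; a CG pair is counted
only when the C and G are adjacent in the original sequence, so a pair
"bridged" by a removed N is not counted. The statistic is reported as
undefined — not an error — when `C = 0`, `G = 0` or `L < 2`. Sequences
shorter than `min_len` (default 200 bp) are excluded from profiling; the
filter removes the high-variance short tail, where a handful of CpGs can
swing o/e by a factor of two.

The o/e distribution is estimated by a Gaussian KDE with Silverman
bandwidth, reflected at 0 (o/e is non-negative; reflection folds kernel
mass leaking below zero back onto the half-line so the density integrates
to 1 within 1e-3). The 512-point grid spans `[0, max(2, max o/e + 3·bw)]`;
the three-bandwidth pad keeps a mode located at the sample maximum
strictly inside the grid, where peak detection can see it. Samples whose
Silverman bandwidth falls below a floor of 0.01 o/e units — point masses,
or numerically degenerate spreads where the standard deviation of
identical floats comes out around 1e-16 — are smoothed manually at the
floor width instead.

Modes are local maxima with topographic prominence at least 10% of the
global maximum (configurable), sorted by height, ties broken toward lower
o/e. The 95% CI is a seeded percentile bootstrap of the **mean**
(`n_boot = 1000` resamples); the mean rather than the mode is
bootstrapped because the mean is the stable location summary of a
unimodal o/e distribution and the quantity the CI is typically drawn
around in published density plots.

Classification maps mode structure to the four gene-body methylation
types: two or more retained modes ⇒ type 4 (mosaic); a single mode `m` ⇒
type 1 if `m ≥ 0.90` (ultra-low methylation), type 2 if `0.70 ≤ m < 0.90`
(low), type 3 if `m < 0.70` (gene-body methylation). The 0.90/0.70 cut
points approximate the published cluster semantics of the four types and
are overridable; every call records a `rule_trace` naming the branch that
fired.

## Restriction digestion and the LUMA estimator

The digestion model is deterministic: MspI cuts every CCGG at `start+1`
(C^CGG); HpaII cuts only CCGG sites whose methylome flag is 0 (internal
CpG methylation blocks it; outer-C sensitivity of MspI is ignored — it is
modelled as the fully insensitive isoschizomer); EcoRI cuts every GAATTC
at `start+1`. A site is a single binary unit (the CCGG palindrome's two
strands coincide; no hemimethylation). Molecules are linear, so `k` cuts
yield `k+1` fragments and fragment lengths always sum to the genome
length. Virtual gels are length-weighted histograms over log-spaced size
bins with out-of-range fragments accumulating at the edges — mass is
conserved across enzymes by construction.

Pyrogram peaks follow the overhang fill-in chemistry: a CCGG cut leaves
two 5'-CG overhangs, incorporating 1 C + 1 G per end (4 dGTP+dCTP light
units per cut); an EcoRI cut leaves two 5'-AATT overhangs (4 dATP and
4 dTTP units per cut). Totals are split evenly across the two
dispensations carrying each label — the estimator sums them, so the split
is observationally irrelevant — and the H2O control peak is 0 in
noise-free pyrograms. The per-reaction ratio `(dGTP+dCTP)/mean(dATP,dTTP)`
then equals `ccgg_cuts / ecori_cuts`, and

    % methylated = 100 · [1 − (HpaII/EcoRI) / (MspI/EcoRI)]

recovers the methylated fraction exactly in the noise-free chain, for any
EcoRI site count (the normaliser cancels). Raw percentages outside
[0, 100] (possible under noise) are clamped, with the raw value retained
and a flag set for QC. Replicates are aggregated by computing percent per
replicate and averaging the percents, not by averaging peak heights
first; the estimator is a ratio of ratios, and averaging inside the ratio
would bias it under multiplicative noise.

## Bisulfite quantification

Per CpG, percent methylation is `100 · #C / #(C or T)` over reads;
residues other than C/T at a CpG are sequencing noise and are excluded
from the denominator rather than counted as unmethylated. The estimator's
expectation is `m + (1 − m)(1 − c)` for true methylation `m` and
conversion rate `c`; raw (uncorrected) percentages are reported by
default, matching standard practice, with an optional inverse correction
`m̂ = (p − (1 − c))/c` clamped to [0, 1]. Conversion QC is the T fraction
at non-CpG reference cytosines; the default warning threshold is 0.95.
Replicate summaries use the arithmetic mean and sample SD (ddof = 1); SD
is undefined, not zero, for a single replicate.

## Dollo parsimony

Each gene family is assumed gained once and only lost thereafter —
appropriate for deeply conserved families (DNA-methylation writers,
readers, NuRD components) whose origins predate the sampled species. The
reconstruction places the gain at the MRCA of all possessing leaves,
scores a node present iff it lies on a path from that origin to a
possessing leaf, and counts one loss per maximal edge into an all-absent
subtree. Polytomies are hard: a present polytomy node that fails to
transmit the family to several children accrues one loss per absent
child. Counts collapse to presence/absence for reconstruction. This
minimises losses among single-gain histories (verified in tests against
an exhaustive Sankoff-style enumeration over gain placements).

Dollo is conservative at the root: a family surviving only inside one
root child clade reconstructs with its origin inside that clade, so a
losses-only simulation recovers the simulated root state exactly only
when possessors span at least two root child clades.

Trees are read as rooted newick (underscores preserved, internal labels
addressable); matrices are species × family count TSVs. The packaged
fixtures encode the 17-family *P. dumerilii* repertoire (single copy
except four Chd3/4/5 members) and a six-species demonstration tree/matrix
labelled synthetic — they are stand-ins distilled from per-clade
statements, not a transcription of any full published species matrix.

## Expression dynamics

A stage transition is upregulated/downregulated when the fold change is
*strictly* greater than 2 in the corresponding direction, otherwise
stable; fold changes are computed on pseudocount-shifted values
(default 0.01 FPKM) so zeros are defined. Genes below 5 FPKM in both
compared stages carry a low-expression flag; summary proportions are
reported both over all genes and restricted to expressed genes, since
pie-chart conventions differ on whether flagged genes enter the
denominator. Spearman correlations use average ranks; the Holm step-down
adjustment runs over all unordered variable pairs of a matrix as one
family; constant columns yield undefined coefficients, flagged and
excluded from the family.

## Synthetic-data generators

All generators are pure functions of parameters + seed.

**Transcriptomes.** A first-order Markov chain with strand-symmetric
stationary composition at the requested GC content; only the C row is
modified, its C→G probability set by a fixed point `q = t · π_G(q)` so
the *expected* o/e under the chain's true stationary distribution equals
the target `t` exactly (naively setting `q = t · p_G` misses the target
by ~10% at `t = 0.55` because modifying the C row shifts the stationary
distribution). Empirical calibration: mean o/e over 5,000 transcripts is
within ±0.03 of `t` for `t ∈ {0.3, 0.55, 1.0}`. Transcript lengths are
uniform on a configurable range (default 500–3000 bp) and GC defaults to
0.40 — plausible round figures for an invertebrate transcriptome, chosen
once and documented as arbitrary since no canonical distribution exists.

**Genomes.** Exact numbers of non-overlapping CCGG and GAATTC motifs are
placed at seeded uniform positions in an iid background, which is then
repaired by point mutations until an independent scan finds exactly the
declared counts and nothing more. Genomes are linear, single-contig and
N-free. Methylomes flag an exact `round(f · n)` subset of sites chosen
without replacement — exact counts, not per-site Bernoulli draws — so
noise-free recovery targets are sharp.

**Bisulfite reads.** Per read and CpG, methylation is Bernoulli with the
site's probability; unmethylated cytosines (CpG and non-CpG alike)
convert to T with probability `conversion_rate`; uniform substitution
noise at `error_rate` follows. Reads are born aligned — no alignment or
PCR-bias simulation.

**Pyrogram noise.** Multiplicative Gaussian factors (mean 1, SD = CV)
per peak, clamped at zero: pyrosequencing light noise scales with
intensity.

**Repertoire evolution.** Counts descend the tree; per edge a surviving
family is lost wholesale with `loss_rate`, else incremented with
`dup_rate`. Loss is absorbing, so outputs are Dollo-compatible by
construction.

What the generators do **not** emulate — and what passing tests therefore
do not establish about real data: isoform redundancy and assembly
artifacts in transcriptomes; repeat structure, chromatin context or CpG
islands in genomes; partial digestion kinetics and internal assay
controls in LUMA; bisulfite PCR bias; gene conversion or horizontal
transfer violating Dollo's single-gain premise.

## Problem sizes and determinism

Default verification runs use 5,000 transcripts (500–3,000 bp), a 200 kb
genome with 300 CCGG / 150 GAATTC sites, a few thousand bisulfite reads
per locus, and exhaustive Dollo checks on trees of up to 8 leaves —
sizes at which every stochastic recovery band in the test suite is
comfortably resolved on a single CPU in seconds. Every random draw flows
from an explicit seed; pipeline stages derive independent sub-streams
from the global seed via CRC-stable stage tags, so reruns with an
identical config are byte-identical.
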