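# Methods

This note records the models implemented in `pprsel`, their assumptions,
the numerical choices behind the fits, what the synthetic-data generator
does and does not emulate, and known limitations.

## Codon substitution model

The likelihood machinery implements the Goldman–Yang codon model on the 61
sense codons of the standard genetic code. The instantaneous rate from
codon *i* to *j* is zero unless the codons differ at exactly one
nucleotide, and otherwise

q<sub>ij</sub> = π<sub>j</sub> · κ<sup>[i→j is a transition]</sup> · ω<sup>[i→j is nonsynonymous]</sup>,

with the diagonal set so rows sum to zero and the matrix rescaled so the
expected number of substitutions per codon per unit time is one at
stationarity. Branch lengths are therefore in expected substitutions per
codon. Changes into stop codons are not modelled (the state space excludes
them). The chain is time-reversible by construction
(π<sub>i</sub>q<sub>ij</sub> = π<sub>j</sub>q<sub>ji</sub>), which is what
makes the likelihood invariant to root placement and lets Q be
diagonalised through its symmetrisation
B = Π<sup>1/2</sup> Q Π<sup>−1/2</sup> — one `eigh` per (ω, κ) evaluation,
after which P(t) = exp(Qt) is a cheap reconstruction for every branch.

Equilibrium frequencies default to F3x4: position-specific nucleotide
frequencies estimated from the alignment (gaps and ambiguity codes
ignored), multiplied across the three codon positions, restricted to sense
codons and renormalised. Frequencies are floored at 10⁻⁶ before
renormalisation so that no sense codon has zero frequency (a zero would
break reversibility and the symmetrised eigendecomposition). Uniform
frequencies are available via configuration.

Likelihoods are computed by Felsenstein pruning with per-pattern
rescaling at every internal node, so deep alignments do not underflow.
Identical codon columns are compressed into patterns once per dataset. A
codon containing `-` or `N` (or, in truncation-tolerant alignments, a stop)
is missing data for that taxon and column and enters the pruning as a
uniform partial-likelihood vector of ones.

## Fitting

Fits follow the statsmodels idiom: `CodonModel(alignment, tree)` holds the
data and `fit()` returns a results object. All fits keep the *relative*
branch lengths of the input tree fixed and optimise a single global rate
scaler together with ω and κ. Full per-branch length optimisation is
deliberately omitted: the scan and partition analyses re-fit windows as
short as nine codons, which cannot identify dozens of branch lengths, and
the tree handed in is expected to come from a dedicated tree-inference
tool.

Optimisation is bounded L-BFGS-B in log-parameter space (bounded Brent
when only one parameter is free, in which case the search is global over
the bracket), with default bounds ω ∈ [10⁻⁴, 50], κ ∈ [0.1, 20],
scaler ∈ [10⁻³, 100]. Three deterministic starts are used: one fixed
(ω = 0.3, κ = 2, scaler = 1) and two drawn from a generator seeded by the
configuration seed, so repeated runs are bit-identical. A fixed ω of
exactly 0 makes amino-acid-changing site patterns impossible; if the data
contain any, the log-likelihood is −∞ and the fit reports that sentinel
rather than a number.

Two-ratio branch models give branches marked as foreground (Newick suffix
token `#1`, or programmatic marking) their own ω, free or clamped. With
the foreground ω clamped to 1 and compared against the free two-ratio fit
by a one-degree-of-freedom likelihood-ratio test, this is the standard
test of purifying selection on a focal branch.

Likelihood-ratio statistics are 2ΔlogL against χ²(df). Statistics in
[−10⁻⁴, 0] are clamped to zero (optimiser noise); anything more negative
raises an error, since a constrained model beating its parent signals an
optimisation failure rather than a result. Fixed-ω tests are reported
two-sided: partitions can sit above as well as below the gene mean, and
both directions are of interest.

## Window scan

Windows of 9 codons advance 3 codons at a time (both configurable); only
full windows are emitted, and the midpoint is the central nucleotide of
the window — for an odd window size, the second nucleotide of the central
codon (nt 14 for codons 1–9). Per window only ω is re-estimated; κ, the
rate scaler and the codon frequencies are fixed at their gene-wide
estimates, because a 27-nucleotide window cannot identify three continuous
parameters. A window with fewer than three informative codons (columns
with ≥ 2 resolved taxa), or with no synonymous divergence across any taxon
pair (dS = 0, ω inestimable), reports ω as undefined — a gap in the
profile, never a capped value, which avoids manufacturing spurious peaks.

## Partition and helix tests

A partition (PPR repeat, helix, domain) is a set of 1-based inclusive
codon ranges; extraction concatenates its columns in coordinate order.
The per-partition test re-fits ω on the extracted columns (κ and scaler
fixed gene-wide) and compares, by χ²(1) LRT, against the same model with ω
clamped to the gene-wide estimate. The gene-wide ω is taken from the full
alignment — coils, linkers and C-terminal domains included — because the
reference point is the mean constraint on the entire gene. No
multiple-testing correction is applied to the per-repeat tables by
default (each repeat is reported as its own hypothesis); a
Benjamini–Hochberg pass can be applied downstream by the user.

The helix comparison concatenates all helix A ranges and all helix B
ranges, gives each concatenation its own full fit (the concatenations are
long enough to identify ω, κ and the scaler, and each gets its own F3x4
frequencies), and tests each helix's data against the other helix's ω by
χ²(1) LRT in both directions. The construction is symmetric: swapping the
class labels swaps the two ω estimates and the two p-values exactly.

Truncation localisation reports the first fully resolved in-frame stop
codon of a taxon in alignment coordinates and lists as lost every
partition starting strictly downstream. Alignment validation normally
rejects internal stops outright; truncation workflows opt in to them with
`allow_stop_codons=True`, which also routes stop codons into the
missing-data path of the likelihood machinery. The reference taxon must
be stop-free.

## Editing sites

Percent editing is 100·T/(C+T) from the two chromatogram peak heights at
the edited position. The raw value is rounded to the nearest multiple of
10 with ties rounding up (25 → 30; the tie direction is arbitrary but
fixed for determinism); raw values below 10 are reported as the flag
`<10` rather than rounded — the below-threshold test applies to the raw
value, not the rounded one. A site is *homogeneous* when every surveyed
species edits it, *heterogeneous* otherwise.

Loss counting is Dollo parsimony: editing is assumed ancestrally present
(a single gain) and transitions are loss-only, because a lost site —
especially one replaced by a genomic T — is not plausibly regained. Both
GENOMIC_T and UNEDITED_C count as lost; the mechanism is reported per
clade (MIXED when a clade contains both). The minimum number of
independent losses is then the number of maximal subtrees whose tips all
lack editing. A loss is an event on a branch, so the root itself can never
be a loss clade; in the degenerate all-tips-lost case each child subtree
of the root counts separately. The count is invariant to rerooting along
any edge with edited tips on both sides; for unrooted input the supplied
(arbitrary) rooting is used as is.

Cis-elements are the 26-nucleotide window spanning −20..+5 around the
edited C (1-based offset 21 within the window), requiring 20 nt upstream
and 5 nt downstream of the site.

## Synthetic data

The generator produces every input with known ground truth. Trees are
Yule (pure-birth) topologies conditioned on the tip count; because the
birth–death simulation stops at the n-th birth, the waiting time to the
next (uncounted) speciation is added to every terminal branch, so no
terminal branch is ever zero. Branch lengths are rescaled to a requested
total tree length, default 4 expected substitutions per codon summed over
the tree — substantial but alignable divergence, comparable to a
family-level sample of a fast-evolving nuclear gene.

Alignments evolve column-by-column under the same codon model the
fitting machinery uses (its generative twin): root codons drawn from π,
branch transitions from exp(Q·t) with the ω of the column's structural
class, per-branch foreground ω optional. The default gene layout mirrors
a PLS-class editing factor: 13 repeats of 35 codons (helix A 12, helix B
12, coil 11) followed by E (34), E+ (32) and DYW (100) domains, with
ω = 0.05 / 0.3 / 0.5 for helix A / helix B / coil, 0.2 for E and E+, and
0.08 for DYW — the helices contrast encodes, as a recoverable planted
truth, the qualitative structure the analyses are designed to detect, and
κ defaults to 2, a typical plant nuclear value. Because the state space
is the 61 sense codons, no stop codon can be generated; truncations are
injected afterwards as a TAA at a requested codon.

What the generator does **not** emulate: indels and alignment error (the
alignment is given, perfectly), recombination, among-site rate variation
beyond the partition structure, codon-usage bias beyond π, sequencing
error in the sequences, and base-composition artefacts of real
chromatograms (peak heights are two clean numbers with multiplicative
Gaussian noise). Passing the recovery and calibration tests therefore
demonstrates correctness of the estimators under the model's own
assumptions — not robustness to misalignment or model violation in real
data.

Editing-state tables plant irreversible losses on chosen non-nested
branches (terminal branches by label, internal branches by the MRCA of a
label set); the loss mechanism per clade is drawn at random. Every
`simulate_*` function is fully determined by its seed.

## Problem sizes used in the checks

The statistical test-suite checks run at sizes chosen to make the
assertions sharp while staying cheap: ω recovery on 12-taxon, 300-codon
alignments (20 replicates per regime at ω ∈ {0.05, 0.2, 1}); the helix
contrast at the full default layout (20 taxa, 13 repeats, 20 replicates);
null LRT calibration on 200 scaled-down replicates (6 taxa, 100 codons);
p-value uniformity over 100 disjoint-partition tests; the two-regime scan
(ω 0.05 | 0.8, 10 replicates of 12 taxa × 100 codons). The acceptance
script repeats the same computations at somewhat smaller replicate counts
so a full from-scratch run stays within a couple of minutes.

## Known limitations

- Site-heterogeneous models (M1a/M2a/M7/M8) and positive-selection site
  identification are out of scope; ω varies only by partition, window or
  branch.
- F61 codon frequencies and non-standard genetic codes are not provided
  (the code table is pluggable in principle but only the standard code is
  wired up).
- Branch lengths are never re-estimated per branch; analyses inherit the
  input tree's relative lengths. A badly wrong input tree will bias ω.
- The pairwise counting estimator applies a single-parameter multiple-hit
  correction; at saturation (p ≥ 3/4) the estimate is reported as
  undefined rather than extrapolated.
- Dollo counting takes the topology as given; uncertainty in the species
  tree is not propagated into the loss counts.
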