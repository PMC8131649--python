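# Methods

This note documents the models behind `erosionscan`, the assumptions they
make, the defaults they ship with, and the numerical choices that a user
re-deriving results will want to know.

## Codon model and the selection-intensity test

Substitution follows MG94xHKY on the 61 sense codons (NCBI table 1 by
default; any table id is accepted and all code-dependent structures —
synonymy, fourfold families, stop exclusion — are derived from the table,
never hard-coded). Off-diagonal rates are nonzero only between codons
differing at one position:

    q(x -> y)  ∝  π_nuc(target) · κ^[transition] · ω^[nonsynonymous]

with stationary codon frequencies the F1×4 product (position-independent
nucleotide frequencies, renormalized over sense codons; estimated
empirically from the alignment at fit time). Each matrix is scaled to one
expected substitution per codon site per unit branch length at
stationarity, so branch lengths have a fixed interpretation in every ω
category; the chain is reversible by construction and transition matrices
are computed from the symmetrized eigendecomposition rather than a
generic matrix exponential (hundreds of times per optimizer run).

The relaxation model fits three ω categories (ω₁ ≤ ω₂ ≤ 1 ≤ ω₃,
weights summing to 1) shared by all branches, and a selection-intensity
exponent k applied on the "test" branch set: effective ω there is ωᵢ^k.
Site categories are fixed across the tree — there is no branch-site
random-effect layer. This is a deliberate simplification: it preserves
the tested hypothesis (k ≠ 1, one extra degree of freedom, χ²(1)
reference distribution) and makes the likelihood exactly computable by
pruning, at the cost of not modeling per-branch category switching. The
simulator uses the identical model class, so recovery tests are
well-specified.

Likelihoods use Felsenstein pruning over compressed site patterns with
gaps/ambiguities as missing data. Because the generator is the same
model, branch lengths are treated as known; the fit functions take a
`branch_scale` factor that converts the tree's unit into expected
substitutions per codon (for the Ma-calibrated study tree this is the
clock, below). Branch-length estimation is intentionally out of scope.

Optimization: bounded L-BFGS-B on transformed parameters
(log κ ∈ [log 0.05, log 50]; stick-breaking weights; ω₁ = u·ω₂ with
u ∈ (0, 1], ω₂ ∈ (0, 1], ω₃ ∈ [1, 100]; log k ∈ [log 0.01, log 50]),
ftol 1e-10, up to 300 iterations. The null (k = 1) model is fitted
first; the alternative starts from the null optimum with k ∈
{1, 0.4, 2.5} plus optional random restarts. Ties between optima break
toward the best lnL, then the smallest |log k|. Per-category transition
matrices and per-pattern likelihood vectors are memoized across
finite-difference evaluations. Nonconvergence and negative LRT values
(beyond −1e−6) are flagged on the result, never silently dropped.

Summaries follow the analysis conventions: genes with proportion-weighted
mean ω > 10 on either branch set are excluded; log₂(k̂) is binned into
(−∞, −2), [−2, 0), [0, 2), [2, ∞) (left-closed, so log₂(1) = 0 lands in
[0, 2)); FDR is Benjamini–Hochberg with significance at q < 0.1, split by
k̂ < 1 (relaxed) vs k̂ > 1 (intensified); the background ω is
(p₁ω₁ + p₂ω₂)/(p₁ + p₂) over the two sub-neutral categories, the test
set using ωᵢ^k. The cap is applied as "strictly greater than 10 is
excluded".

## Gene-family birth–death model

A family of size n gains a gene at rate nλ and loses one at rate nμ,
with (λ, μ) per gene per Ma shared within named branch classes.
Transition matrices come from the matrix exponential of the truncated
generator: state 0 absorbing, births suppressed at the cap N_max so
escaping mass accumulates there. N_max defaults to the observed maximum
count + 10, capped at 100; truncation error is negligible there because
observed counts sit far below the cap.

Observed leaf counts pass through the error channel: with probability
1 − ε the true count is reported, otherwise true ± 1 (equal halves,
floored at 0). This is a deliberately minimal stand-in for
annotation/assembly noise; ε is per species, bounded to [0, 0.5], and
estimated by a coordinate-wise profile-likelihood grid (0 to 0.2 in
steps of 0.01, two sweeps) with all rate parameters held fixed.

The family likelihood prunes over count states with a root prior and is
conditioned on the family being non-extinct in at least one leaf, which
matches how families are constructed from clustering (a family absent
everywhere is unobservable). The default root prior is uniform on
{1..N_max}. Parameter-recovery experiments pass the generator's true
root-size distribution (uniform on {1..5}) instead: with the default
prior the rate estimates absorb the prior misfit (biases of ~25–35% at
5000 families), which is a statement about root-prior sensitivity, not
about the rates. Real analyses should treat the root prior as a
sensitivity axis.

"Two-parameter" model scans fit, for every branch, the model
{focal branch} vs {all others} with each class carrying its own (λ, μ)
(rates untied by default; a `tie_rates` switch constrains λ = μ), each
fit restarted at least eight times from random initial rates. A
root-stem branch participates only when the root carries an edge length,
in which case its "focal" model degenerates to the homogeneous fit. The
per-branch (λ̂, μ̂) pairs are clustered by k-means (scikit-learn's Lloyd
algorithm with n_init random center sets — R's Hartigan–Wong variant is
not available in the Python stack; for the well-separated structures
this procedure is meant to detect, the two algorithms agree) over
k = 2..8, each clustering refit as a shared-rate model and scored by
AIC = 2·(2k) − 2 lnL; smallest AIC wins, ties to smaller k.

Ancestral family sizes are reconstructed by joint max-posterior dynamic
programming (Viterbi over count states, ties toward the smaller count);
expansions/contractions per branch count families with child count
above/below the parent, and the empirical loss rate is
Σ decreases / (Σ parent counts × branch length in kyr), reported absent
on zero-duration branches.

## Synteny

Anchors are orthogroups that are single-copy in both genomes. Chaining
is greedy along genome A: an anchor extends the current block when it
shares the scaffold pair and lies within `gap` intervening genes of the
previous anchor in both genomes (|Δindex| ≤ gap + 1, sign-free in B so
inverted runs stay in one block and depress τ instead of re-orienting).
This detector is deliberately simple and deterministic — a transparent,
oracle-testable replacement for heavyweight collinearity engines whose
settings are not reproducible here; absolute block counts are therefore
not comparable with such tools, while the τ statistics computed on
blocks are. Defaults: gap 5, minimum span 25 genes in each genome
(discarded blocks are counted). τ is Kendall tau-b (tie-aware; anchors
are permutations in the single-copy case, where tau-b equals tau-a).

The host-vs-parasite comparison is a rank-sum test with a Monte-Carlo
permutation p-value ((b + 1)/(R + 1) correction, R = 9999 by default,
minimum 99), alternative "parasite τ stochastically smaller", plus a
tie-corrected normal z that is negative when parasites rank below hosts.

Mutation-count tables (P/I/D/V/U by branch and size bin) are normalized
to events/Ma; the percent deviation is relative to the unweighted mean
rate over all branches, absent when a (type, bin) cell is zero
everywhere.

## Reconciliation

Gene trees are consumed pre-rooted and binary, with species parsed from
leaf labels (`species|gene` by default, or a caller-supplied function).
Each internal node maps to the LCA of its descendant species; a node is
a duplication iff its mapping equals a child's mapping; losses follow
the path-depth rule and are attributed to the species branches hanging
off the mapping path. This is plain duplication–loss parsimony —
coalescent-aware reconciliation is intentionally not reproduced, which
can re-label some deep events on real data. Clade extraction takes the
smallest clades that still hold ≥ `min_size` leaves (descending only
while every child subtree stays at or above the threshold), assigning
every leaf exactly once.

The event-asymmetry test builds the 2×2 table (parasitic vs other
branches) × (duplications vs losses) and uses Pearson χ² with df = 1.
Yates correction is off by default — on the published event table
([[1, 15], [43, 13]]) the uncorrected statistic (26.05) is nearer the
printed value than the corrected one (23.17), and neither printed χ²
is treated as a reproducible target. Expected counts below 5 are
flagged.

## Codon usage

GC1/GC2/GC3 count G or C among unambiguous bases per codon position
after stripping a terminal stop. ENC is Wright's estimator:
ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with per-family homozygosity
F̂ = (nΣp̂² − 1)/(n − 1); the sixfold amino acids (Leu, Ser, Arg) form
their own class, keeping the maximum at 61. Families observed fewer than
twice are imputed with the mean F̂ of their degeneracy class; a missing
threefold class takes the mean of the estimated two- and fourfold means;
classes with no estimate at all fall back to uniform usage (1/m).
Results are clamped to [20, 61]. F̂ is O(1/n) biased, so exact scaling
invariance only emerges for family counts in the hundreds. The
neutrality regression is OLS of GC12 on GC3 (undefined with < 3 CDSs or
zero GC3 variance), and the ENC~GC3 reference curve is
ENC(s) = 2 + s + 29/(s² + (1 − s)²).

## Fourfold-degenerate sites

A third position is retained iff every species' codon in that column is
complete and unambiguous, all species share the identical first two
positions, and that prefix is fourfold under the genetic code (sixfold
amino acids contribute only their fourfold sub-family — CTN for Leu,
TCN for Ser, CGN for Arg). This is the strictest common definition:
deterministic, code-table-driven, and invariant to species order.
Indices are 0-based alignment columns; all internal coordinates are
0-based half-open, with 1-based conversion only at table boundaries.

## The simulator and what it does (not) emulate

The study tree has six taxa: an Atta outgroup splitting 12 Ma ago, and
two parasite origins — one terminal parasite branch splitting from its
host 0.96 Ma ago, and a parasite pair (split 1.63 Ma) whose stem
diverged from its host 2.50 Ma ago. The crown age of the ingroup
radiation is not constrained by those published dates; 8.0 Ma was chosen
once as a realistic value between the 2.50 Ma ingroup split and the
12 Ma outgroup split. The four parasite branches (both terminals of the
pair, their stem, and the young terminal parasite) form the "test" set.

Codon alignments evolve by per-site Gillespie simulation of the exact
jump chain, so true synonymous/nonsynonymous substitution counts per
branch are logged, root states draw from the stationary distribution
(no burn-in), and site categories are fixed per site across the tree —
matching the inference model. The molecular clock converting Ma into
substitutions is 0.02 expected substitutions per codon site per Ma
(~0.007/nt/Ma), giving ~0.76 expected substitutions per codon over the
whole tree — on the generous side of attine divergence, chosen once as
the study condition. Default mixture: ω = (0.1, 0.5, 2.0),
p = (0.6, 0.3, 0.1), κ = 2, uniform nucleotide frequencies, k = 1.

Family counts evolve by exact birth–death simulation per branch
(default λ = μ = 0.002 per gene per Ma in both classes; root size
uniform on {1..5}; ε = 0), dropping and counting families extinct in
every leaf. Gene orders start as a single forward-strand chromosome;
per-branch event counts are Poisson(rate × Ma) per type (defaults per
genome per Ma: inversion 0.5, transposition 0.5, deletion 0.3,
duplication 0.3, insertion 0.3, configurable per branch), with
truncated-geometric segment lengths (mean 5); a deletion may never
empty the genome (resampled and logged). Every event is appended to a
log that an independent replay routine can apply to reproduce each leaf
order byte-exactly.

The generator emulates the *data structures and stochastic processes*
the analyses assume — it does not emulate assembly fragmentation,
annotation error beyond the ±1 count channel, alignment error,
recombination, or rate variation beyond the configured classes. Passing
recovery tests therefore demonstrates correctness and calibration of
the inference machinery under its own model class, not robustness to
the mis-specification real genomes add.

## Problem sizes and observed calibration

The test suite and the acceptance script run at these sizes (chosen as
the package's verification conditions): relaxation-direction check, 20
replicates × 300 codons, k = 0.3; neutral dN/dS check, 20 replicates ×
10,000 codons (single-ω fit with κ held at its known simulation value);
type-I error of the k = 1 LRT, 200 replicates × 100 codons (observed
rejection rate at α = 0.05 within [0.03, 0.08]); rate recovery on 5000
families; k̂ recovery at 1000 codons (20 replicates, median absolute
error on the k scale ≈ 0.12; the median *relative* error at this
alignment length is ~0.3–0.4, falling to ~0.09 by 4000 codons — k̂ at
single-gene lengths is direction-informative rather than precise);
ε̂ recovery within ±0.05; exact recovery of a planted two-cluster
branch-rate structure. Oracle suites compare pruning likelihoods to
exhaustive ancestral-state enumeration (≤ 4 leaves), the family
likelihood to exhaustive state sums (≤ 3 leaves, N_max ≤ 4), LCA
reconciliation to brute-force minimal event search (≤ 4 species), and
Monte-Carlo rank-sum p-values to exact enumeration (n ≤ 6).

## Known limitations

* No branch-site random effects; k acts on all categories uniformly.
* Branch lengths are inputs, not estimated; results inherit their error.
* The ε channel only models ±1 count errors, not systematic annotation
  loss; the birth–death model is linear (no innovation term for de novo
  family birth along branches).
* The block detector is greedy single-linkage; block boundaries (not τ
  values) depend on the scan order along genome A.
* Reconciliation assumes the given rooting; an optional
  minimal-duplication rooting search is provided but off by default.
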