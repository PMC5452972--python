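# Methods

## Models

### Trees

Benchmark phylogenies are complete balanced binary trees with a uniform
edge length `b`, including the two edges below the root, so every pair of
adjacent nodes is separated by the same divergence and a two-taxon tree has
pairwise divergence `2b`. The grids cover `b ∈ {0.0025, 0.01, 0.04, 0.16,
0.64}` and 16–2,048 taxa (powers of two). Leaves are labelled `t1…tn`
deterministically so alignments and trees join reproducibly. Arbitrary
user-supplied rooted trees with branch lengths are accepted by both
inference models; only tree *generation* is restricted to the balanced
case.

### MG94-style codon model

Each site carries a synonymous rate `dS` and a nonsynonymous rate `dN`.
For single-nucleotide codon neighbours `i → j`,

    q_ij = c · dS · π_j   (synonymous)
    q_ij = c · dN · π_j   (nonsynonymous)

with `q_ij = 0` for multi-nucleotide changes and `π` the equilibrium codon
frequencies (uniform over the 61 sense codons by default; configurable).
The constant `c` is chosen once per frequency vector so the *neutral*
process (`dN = dS = 1`) has mean rate 1 substitution per codon site per
unit time. Because `c` never depends on the site's rates, the ratio
`dN/dS` retains its exact parametric meaning at every site, while branch
lengths read as expected substitutions per codon site on the neutral
clock — sites under selection evolve correspondingly slower. We
deliberately do **not** rescale each site's matrix to mean rate 1: per-site
rescaling would equalize total substitution rates across sites and destroy
the rate variation the study is about.

### Halpern–Bruno mutation–selection model

A site is described by a codon fitness vector `f` (population-scaled,
defined up to an additive constant). With a nucleotide mutation process
`μ` lifted to codon space, substitution rates are

    q_ij = c · μ_ij · S_ij / (1 − exp(−S_ij)),   S_ij = f_j − f_i,

where the fixation factor is set to its limit 1 when `|S| < 1e−8`
(removable singularity), and `c` anchors the *neutral* lifted mutation
process to mean rate 1 as above. For reversible `μ` the chain satisfies
detailed balance with stationary distribution `π_i ∝ m_i e^{f_i}`, where
`m` is the stationary distribution of the lifted mutation process
(restricting to the 61 sense codons preserves detailed balance, so `m` is
the product of nucleotide frequencies renormalized over sense codons).

The mutation model is HKY-like with nucleotide frequencies
`(π_A, π_C, π_G, π_T) = (0.32, 0.18, 0.18, 0.32)` by default — unequal
frequencies, matching the benchmark's setting — and a transition/
transversion multiplier `κ` left at 1 (the hook exists but the benchmark
does not use it).

**Expected dN/dS.** For a MutSel site the comparison truth is the expected
dN/dS implied by its selection coefficients: the stationary nonsynonymous
substitution flux `Σ_{i≠j, nonsyn} π_i q_ij` divided by the same flux with
all fixation factors set to 1 and the neutral stationary distribution.
Neutral profiles give exactly 1; the value is invariant to adding a
constant to all fitnesses.

**MutSel profile generation.** The original benchmark reused alignments
whose fitness parameters come from an external prior study, so MutSel
results are matched in pattern, not point values. Our generator draws
per-site target amino-acid frequencies from a symmetric Dirichlet
(concentration 0.5 over 20 amino acids — broad per-site rate spread) and
converts them to codon fitnesses that realize those frequencies exactly
under the mutation model, with equal fitness among synonymous codons
("neutral synonymous codons"). The codon-bias variant adds independent
N(0, 0.5²) offsets (scaled-fitness units) to each codon's fitness, the
minimal mechanism that makes dS site-variable. All three constants are
configurable.

## Simulation

Site rates are drawn per regime: `constant_dS` (dN ~ U(0.1, 1.6), dS = 1),
`variable_dS` (dN/dS ~ U(0.1, 1.6), dS ~ U(0.5, 2), dN = dS·ratio),
`gamma` (dN/dS ~ Gamma(α, rate β); the six HIV-1 protein presets range
from α = 0.230, β = 0.659 to α = 0.647, β = 0.861), and the two MutSel
regimes above. Alignments are 100 codons by default.

Sequences evolve site-independently: the root state is drawn from the
site's stationary distribution and each child state from `exp(Qt)` along
its edge. Transition matrices are computed by symmetrized
eigendecomposition (every model here is reversible), once per distinct
rate matrix and edge length — on a balanced tree that is one
exponentiation per site. Each site consumes its own random substream
spawned from the replicate's generator, so sites are independent and
permuting site models together with their streams permutes the output
columns exactly. Replicates and grid cells get child seeds via
`SeedSequence(master_seed, spawn_key=(cell, replicate))`, making every
output byte-reproducible from one master seed and each cell independently
re-runnable.

What the generator does **not** emulate: indels/gaps, rate change over
time, site interdependence, codon usage estimated from real genes, and
alignment/tree estimation error (inference receives the true tree).
Passing tests therefore demonstrate correctness of the machinery and the
in-model relationships between the two score kinds; they do not bound the
additional noise real data adds through alignment and tree errors.

## Inference

### FEL1 (codon level)

The synonymous rate is shared across sites and fixed at dS = 1, with
branch lengths taken as given — one global scale is unidentifiable from a
ratio, and fixing dS makes the per-site dN equal dN/dS directly. (For
trees not on the codon clock a single global branch-scale factor can
optionally be estimated under the neutral model first.) Each site's dN is
maximized on [0, 10]: a 64-point geometric grid on [1e−4, 10] evaluated
with site-vectorized pruning, then bounded scalar refinement inside the
bracketing grid interval (`xatol` 1e−4); grid ties resolve toward the
smaller dN because site likelihoods can be flat near 0. `dn_max = 10` sits
an order of magnitude above the largest simulated rate (1.6); estimates at
the bound are flagged, not clipped silently. After fitting, sites whose
translated column has a single residue state (synonymous-only variation
included) are set to dN/dS = 0: under a shared nonzero dS, a column with
no amino-acid change carries no evidence of nonsynonymous divergence, but
an unconstrained fit would drift toward dN/dS = 1 there.

### Amino-acid relative rates

Columns are translated and scored under a reversible empirical replacement
matrix — JTT by default (the historical Rate4Site default), LG and WAG
selectable — scaled to mean rate 1. Site rates take K = 16 discretized
gamma categories (equal-probability quantile midpoints, renormalized to a
category mean of exactly 1). The gamma shape is fitted by bounded 1-D
maximization of the summed column log-likelihoods on [0.05, 20] (`xatol`
1e−3); a fixed-shape mode exists for oracle tests. A site's score is its
posterior mean category rate, which is strictly positive. Tree branch
lengths are used as given even though they are on the codon scale: the
`r_k · t_i` decomposition is invariant under `r → Cr, t → t/C`, so the
mean-1 normalization of the scores absorbs any global scale. Gaps are out
of scope for simulated data; on empirical alignments a gap is treated as a
missing observation (all-ones partial likelihood), the standard
convention.

Both inference engines share one pruning implementation with per-node,
per-site rescaling of partial likelihoods, so 2,048-taxon columns evaluate
without underflow.

## Comparison statistics

Correlations (Spearman as the headline — rank-based, hence insensitive to
the normalization the two score kinds differ in — with Pearson also
reported) and RMSD between score vectors, the latter only after both are
normalized to mean 1 so their magnitudes are commensurable. Vectors with
zero variance yield an undefined (NaN) correlation, which aggregation
drops and counts. Per grid cell, replicates aggregate to mean and standard
error `sd/√n`; single-replicate cells are flagged with SE 0. For MutSel
cells the truth vector is the per-site expected dN/dS.

## Numerical choices and degenerate inputs

* Stationary distributions come from a least-squares solve of
  `vQ = 0, Σv = 1`, rejected if the residual exceeds 1e−10 or the
  positive-rate graph is not a single strongly connected class.
* Transition matrices from eigendecomposition are clipped to [0, 1]
  against round-off; non-finite entries abort with the offending edge.
* Mean-1 normalization refuses nonpositive-mean inputs; z-scoring refuses
  constant vectors.
* Codon data containing stop codons, gaps, or ragged rows is rejected at
  parse time; single-leaf trees are legal for likelihoods (the column
  likelihood is the prior) but trees must have strictly positive edge
  lengths — branch length 0 is rejected at tree construction.

## Problem sizes

The published grids run to 2,048 taxa × 50 replicates per condition; the
package ships them as configuration (`benchmark_uniform_design`,
`GridConfig`) but defaults its own test suite and the acceptance script to
desk-scale slices chosen once: 5 replicates at 256 taxa for the
truth-recovery bounds (branch lengths 0.64 and 0.16), 5 replicates × 5
branch lengths at 128 taxa for the inferred-vs-inferred bound, and 2
replicates at 128/256/512 taxa for the error-scaling check. These sizes
keep the full suite in a few minutes while leaving the measured statistics
comfortably clear of the bounds they check.

## Known limitations

* MG94 codon frequencies enter through the target codon's equilibrium
  frequency (an F61-style parameterization); position-specific nucleotide
  (F3x4) variants are not implemented.
* Only the universal genetic code is supported.
* FEL1 here is strictly the one-rate variant: no per-site dS, no
  significance test for dN/dS > 1.
* The amino-acid model's ML (non-Bayesian) scoring mode and per-site
  confidence intervals are not implemented.
* MutSel comparisons reproduce qualitative patterns; the original fitness
  parameter sets are not public, so point values differ by construction.
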