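# Methods

## Model

Expression data are modelled as matrix-normal: the n × p matrix X
(samples × genes) satisfies vec(X) ~ N(vec(DB), I ⊗ Σ), with D the n × r
design, B the r × p treatment effects and Σ the common gene covariance.
Rows (samples) are independent; the covariance acts across genes.  The
precision matrix K = Σ⁻¹ is sparse; its support is the gene network.  All
estimation of B reduces to per-gene ordinary least squares, B̂ =
(DᵀD)⁻¹DᵀX, which is the MLE regardless of Σ; it is computed through a QR
factorisation of D rather than the normal equations for conditioning, and
rank deficiency is reported with the names of the offending columns.

The sample covariance is S = RᵀR/n with R the residuals after the design
fit.  The maximum-likelihood divisor n (not n − 1) is used everywhere,
because the likelihood equations for the precision fit are stated for this
S.  S is exposed through an on-demand entry/block provider and is never
materialised densely inside the fitting paths — at p = 20000 the dense
matrix would have ~2 × 10⁸ unique entries.

## Pattern search

The support of K is estimated gene by gene.  For gene i, greedy forward
stepwise regression on the remaining p − 1 genes runs to a cap `kmax`; at
each step the candidate with the largest residual-sum-of-squares reduction
enters (ties broken to the lowest column index for determinism).  The
engine works on the correlation scale: columns are centered and, by
default, standardized (scale-free selection; the raw-scale option exists).
Internally it maintains V = L⁻¹G[S,·] and w = L⁻¹c for the Cholesky factor
L of the selected Gram block, so a step costs O(kp); for p ≤ 3000 the
p × p Gram matrix is precomputed once, making each path independent of n,
while for larger p Gram rows are formed lazily from the data and the dense
p × p object is never built.

Model size along the path is chosen by minimising a modified BIC,

    BIC_γ(k) = n log σ̂²(k) + k log n + 2γ log C(p, k),   0 ≤ γ ≤ 1,

with σ̂²(k) = RSS(k)/n, or the alternative BIC_2p(k) = n log σ̂²(k)
+ 2k log p.  γ = 0 is the classical BIC; γ = 1 is the default for p ≫ n
because it controls the false-edge rate.  log C(p, k) is evaluated with
log-gamma functions (factorials overflow at p ~ 20000).  A perfect fit
(σ̂² = 0) scores −∞: it cannot be beaten, and the path stops there.  Ties
in the argmin go to the smaller model.  The greedy path itself does not
depend on the criterion, so several criteria can be scored from one pass —
`find_pattern_multi` and the study driver exploit this.

Per-gene selections populate A (Aᵢⱼ = 1 iff j predicts i); the pattern is
N = A + Aᵀ with unit diagonal.  Screening runs on residuals from the
design fit by default (the model defines Σ on residual variation); a flag
allows raw columns.  The default cap is kmax = ⌊n/20⌋ — about 20
observations per parameter in the largest regression — and a warning (not
an error) fires when kmax/n exceeds 1/20.  Per-gene computations are pure
and embarrassingly parallel; results are identical for any worker count.

## Precision fit

Given the pattern, the profile log-likelihood is L = (n/2){log det K −
tr(K S)} and the stationarity conditions are the covariance-selection
likelihood equations: Σ̂ᵢⱼ = sᵢⱼ on every support entry, K̂ᵢⱼ = 0 off
support.  The MLE exists iff every maximal-clique submatrix of S is
positive definite (`mle_exists` checks exactly this; cliques are
enumerated once by Bron–Kerbosch and reused).  Fitting is clique-wise
Iterative Proportional Scaling: cycling over maximal cliques c,

    K[c,c] += inv(S[c,c]) − inv((K⁻¹)[c,c]).

Each update exactly matches the fitted marginal on clique c, maximises the
likelihood over that block, keeps K positive definite when the MLE exists,
and — because updates only touch clique blocks — preserves the structural
zeros exactly (no thresholding anywhere).  Initialisation is
diag(1/sᵢᵢ), which is PD and in the model.  Convergence is declared when
max |Σ̂ᵢⱼ − sᵢⱼ| over the support, measured on the correlation scale
(divided by √(sᵢᵢsⱼⱼ)), drops below `tol` (default 1e-6).  A step-halving
safeguard guards the update against pathological rounding; non-convergence
within `max_iter` returns the best iterate with `converged=False`.  Tests
verify the fit against an independent dense constrained optimiser and
check likelihood monotonicity across sweeps.

The regression-only shortcut (`regression_approx_precision`) — OLS of each
gene on its pattern neighbours, assembled via σ^{ii} = 1/v²ᵢ and σ^{ij} =
−βᵢⱼσ^{ii} — is provided as a labelled approximation: the raw assembly is
generally neither symmetric nor PD, so the result is symmetrised by
averaging and reported with its asymmetry magnitude and definiteness
status.  It is consistent when the neighbour structure is correct, and the
tests confirm its gap to the MLE shrinks with n.

SciPy has no sparse Cholesky, so positive-definiteness tests,
log-determinants and sampling use SuperLU in symmetric mode (natural
diagonal pivoting, symmetric fill-reducing ordering), which yields an
LDLᵀ factorisation of a symmetric permutation of the matrix; congruence
preserves inertia, so the pivot signs decide definiteness exactly.

## Inference

For an r × s contrast C (full column rank; orthonormalised internally if
needed), an orthogonal completion Q = [A C] rotates the design: D̃ = DQ,
Γ̂ = (D̃ᵀD̃)⁻¹D̃ᵀX, and the hypothesis CᵀB = 0 becomes Γ₂ = 0 (last s rows).
With G²² the lower-right block of (D̃ᵀD̃)⁻¹ and LLᵀ = (G²²)⁻¹, the
statistic is T = trace(Γ̃₂KΓ̃₂ᵀ), Γ̃₂ = LᵀΓ̂₂, computed through sparse
products only.  Each contrast row γ decomposes as γᵀKγ =
Σᵢ σ^{ii}γᵢ(γ_N)ᵢ with (γ_N)ᵢ = γᵢ − Σ_{j∈n(i)} βᵢⱼγⱼ; the DE score is γᵢ
and the DC score (γ_N)ᵢ.  For the two-group design the whole construction
collapses to T = n₁n₂/(n₁+n₂) · dᵀKd with d the difference of group
means — asserted to 1e-10 in the tests.

The null distribution is generated by residual permutation: fit the null
mean model on D̃₁, form R = X − F̂, and for each of q draws rebuild X(k) =
F̂ + P_k R with a uniform random row permutation (sampled with
replacement from the permutation group; q ≪ n! in practice), recomputing
Γ̂₂(k) and all statistics with K held fixed — the test is conditional on
the fitted precision.  When D̃₁ is proportional to a column of ones (the
two-group case) the residual projector is permutation invariant and the
procedure is exactly a permutation of the rows of X.  Asymptotic
chi-square p-values are deliberately not offered: K is estimated and
mis-specified in practice, and the permutation null absorbs that.

Empirical p-values use the add-one convention (1 + #{null ≥ obs})/(q + 1),
which can never be zero; per-gene tests are two-sided via absolute values.
For s > 1, per-gene quantities are summed over contrast rows following the
trace structure (DE: Σₖγ²ₖᵢ, one-sided; DC: the summed component,
two-sided).  Multiple testing uses the modified Bonferroni rule over the
union family of DE and DC tests (m = 2p): reject p < α/m, where α > 1 is
allowed and bounds the expected number of false rejections.

## Synthetic data

`generate_precision` emulates sparse expression networks in three steps:
(1) each row of a p × p matrix selects about q partner genes (q may be
fractional — rows draw ⌊q⌋ or ⌈q⌉ so the mean is q), symmetrised into N,
so neighbour sizes vary around 2q; (2) each support entry gets a magnitude
uniform on [0.5, 1] with random sign — values near zero are excluded so
every edge is detectable in principle (the literal asymmetric interval
variant is available as `value_interval="printed"`); (3) the diagonal is d
times the absolute off-diagonal row sum, with d stepped down from 1 in
0.05 steps to the smallest value that keeps the matrix PD — exact
diagonal dominance (d = 1) guarantees the search starts feasible, and
shrinking d lifts the otherwise poor signal-to-noise ratio of dominant
matrices.  `calibrate_q` pilots q against a target median neighbour size
using step (1) only (the median depends on the pattern alone, so
calibration is cheap at any p).  With the median tuned to 5 at p = 5000,
roughly 90% of neighbour sizes land in [3, 8].  Samples are drawn from
N(0, K⁻¹) by one sparse triangular solve per batch; sampling is
bit-reproducible for a fixed seed.

What the generator does **not** emulate: mean structure beyond the
injected group shifts, heavy tails, technical batch effects, or
hub-dominated degree distributions — passing tests demonstrate correctness
of the machinery under Gaussian data with the stated sparsity, not
robustness to real-array artefacts.  Normalising transformations of raw
intensities are out of scope.

`make_fixture` adds known truth for the inference path: a two-group split
with mean shift δ on chosen genes gives γ₀ = LᵀQ₂ᵀB exactly, and the DC
truth follows from the neighbour-corrected mean γ₀ᵢ − Σβᵢⱼγ₀ⱼ.  The
"smooth" mode shifts along a covariance column, which is DE-non-null at
many genes but DC-null away from the seeding gene — the construction that
separates the two test families.

## Problem sizes and numerical choices

The shipped tests run the recovery study at p = 500 (10 repetitions,
n ∈ {100, 500}), generator validation at p = 5000 over 5 seeds,
permutation calibration with 200 replicate null datasets at 200
permutations each, and MLE consistency at p = 50 with n up to 2000 —
sizes chosen so the full suite completes in a couple of minutes while
still exhibiting the qualitative trends (false negatives falling with n,
false positives ordered by γ).  The full-scale study configuration
(p = 20000, median 10, n = 500, 10 repetitions) runs through the same
`run_study` entry point as an opt-in long-running job.

Degenerate inputs: constant gene columns are skipped with a warning in the
stepwise engine; a gene with no neighbours in the generator receives unit
precision; an empty null design block means a zero-mean null model.
Determinism: every stochastic component takes an explicit seed
(`numpy.random.Generator` / `SeedSequence` throughout), stepwise ties
break by index, graph ties break lexicographically, and pattern search is
scheduling-independent under parallelism.

## Known limitations

- Forward-only selection: no deletion steps, so an early wrong pick stays
  on the path (the BIC minimum can still truncate it).
- IPS iterates over maximal cliques; patterns whose clique count explodes
  (dense blocks) make sweeps expensive — the intended regime is sparse
  networks with small cliques.
- The permutation null is conditional on the fitted K; uncertainty in the
  pattern and precision is not propagated.
- L1/penalised joint selection-and-fitting is intentionally not provided.
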