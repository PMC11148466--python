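# Methods

## Embedding and observation matrices

All estimation and the shuffle surrogates operate on delay-embedded
*observation matrices*. For a series of length N and memory order q, the
univariate matrix has N − q rows, row t holding
(x[t+q], x[t+q−1], …, x[t]): present first, then the past lags in order.
The bivariate matrix juxtaposes the X and Y blocks, shape (N − q) × 2(q+1).
The memory order implements a Markov truncation of the process's past;
q = 2 is the default, kept low to limit the curse of dimensionality in the
neighbor searches. Uniform lags 1…q are the tested path; a general strictly
increasing lag vector is accepted.

Series are z-scored (zero mean, unit sample SD) before estimation by
default. The max-norm KNN machinery is exactly invariant under a *common*
affine map of all columns, but not under a rescaling of one process alone —
in a joint space the Chebyshev balls are reshaped when X and Y live on
different scales — so normalization is what makes bivariate estimates
scale-free. A `normalize` flag (CLI `--no-normalize`) disables it.

## KNN estimation

Estimates follow the Kraskov construction with the distance-projection
scheme: a single neighbor search in the highest-dimensional joint space
(max norm, query point excluded) yields per-point ranges ε_n = twice the
distance to the k-th neighbor; every lower-dimensional entropy term is then
evaluated by counting points *strictly* within ε_n/2 in that projection.
Sharing one distance scale across spaces cancels the dimension-dependent
bias that independent per-space searches would introduce. In floating point
the strict count is realized exactly by counting distances
≤ nextafter(ε_n/2, 0).

- IS: search in the (q+1)-dimensional (present, past) space; counts in the
  past-only and present-only projections;
  S_X = ψ(N) + ψ(k) − ⟨ψ(N_past+1) + ψ(N_present+1)⟩, with N the number of
  embedded rows (N_series − q).
- MIR: search in the 2(q+1)-dimensional joint space; five projected counts
  (X past; Y past; X present+past; Y present+past; joint past);
  I_XY = ψ(k) + ⟨ψ(N_Xq+1) + ψ(N_Yq+1) − ψ(N_XXq+1) − ψ(N_YYq+1) − ψ(N_XqYq+1)⟩.
  The digamma terms are grouped symmetrically in X and Y so that
  estimate_mir(x, y) == estimate_mir(y, x) to the last bit.

Defaults k = 10, q = 2 — the usual variance/bias compromise for KNN
information estimates at N ≈ 1000. Estimates are reported in nats and never
clipped: near-zero dependence regularly produces small *negative* IS/MIR
values (finite-sample bias), which is expected and statistically
interpretable under the surrogate distribution.

Tie handling: deterministic maps can produce exactly duplicated embedded
rows, for which ε_n = 0 would be degenerate. When (and only when) duplicate
rows are present, a seeded uniform jitter of amplitude 1e-10 × per-column SD
is added before the search — far below any dynamical scale, reproducible,
and leaving continuous-valued data untouched so the exact invariance
properties (global affine maps, translation) hold bit-exactly there. A
brute-force O(n²) neighbor/count path is kept alongside the k-d tree path
and used as the oracle in the test suite.

Known limitation: the MIR estimator operates in a 6-dimensional space at
q = 2 and visibly underestimates strong coupling at N = 1000 (for the
benchmark VAR at C = 1 the median estimate sits ≈ 0.11 nats below the exact
Gaussian value of 0.352, recovering toward it as N grows). This bias does
not affect test calibration, since original and surrogate statistics share
it.

## Surrogates

- **Present-column shuffle** (null: no self-dependencies). Permute the first
  column of the univariate observation matrix; marginal distribution and the
  past block are conserved exactly, present–past alignment is destroyed.
- **IAAFT** (null: purely linear dynamics). Start from a random permutation
  of the series; iterate [impose the original Fourier amplitude spectrum,
  keeping current phases] then [rank-rescale to the original values]. The
  returned series is the rank-rescaled output after 7 iterations (default):
  amplitude distribution exact, spectrum within a fraction of a percent RMS
  on the benchmark processes. Rank ties break by first occurrence; the DFT
  is taken without detrending, windowing or padding.
- **Row-block shuffle** (null: no coupling). Jointly permute the rows of one
  process's (present+past) block of the bivariate matrix. Each row's tuple
  stays intact, so within-process dynamics are preserved while cross-process
  alignment is destroyed. After shuffling, the matrix no longer corresponds
  to a single consistent time series (overlapping rows shared samples in the
  original); estimation treats the rows as a point set, which is exactly
  what the KNN estimator does anyway. The shuffled block defaults to the
  first process; the choice is statistically immaterial and a selector is
  exposed.
- **Common-phase bivariate IAAFT** (null: purely linear coupling). As IAAFT,
  but initialized by adding the *same* random phase sequence — one uniform
  draw in [0, 2π) per frequency bin, conjugate-symmetrized, DC and Nyquist
  fixed — to both series' spectra, then iterating per series. A shared
  per-bin phase rotation leaves the cross-spectrum invariant, so all linear
  coupling survives while nonlinear joint structure is randomized. (A single
  scalar phase shared by all bins would barely randomize anything; per-bin is
  the established cross-spectrum-preserving construction.)

All methods draw from an explicit generator; each of the M surrogates in a
test uses an independent `SeedSequence` substream, so results are
bit-reproducible and independent of execution order or of M.

## Testing

One-sided percentile tests: reject when the original statistic strictly
exceeds the (1 − α) empirical percentile of the M surrogate values, with the
percentile taken as the nearest-rank order statistic (M = 100, α = 0.05 →
the 95th largest value; no interpolation) and ties resolved conservatively
to non-rejection. Defaults M = 100 and α = 0.05; M ≥ ⌈1/α⌉ − 1 is enforced
so the percentile is estimable. Compatibility is enforced: IS pairs with the
univariate surrogates, MIR with the bivariate ones.

## Benchmark models and oracles

- AR(2): X_n = 2ρ cos(2πf) X_{n−1} − ρ² X_{n−2} + ε_n, unit-variance
  Gaussian innovations; complex-conjugate poles at radius ρ < 1 give a
  stochastic oscillation at normalized frequency f. Burn-in 500 samples
  (transients at ρ ≤ 0.95 decay well within that).
- Noisy Hénon map: X_n = 1 − 1.4X²_{n−1} + 0.3X_{n−2} observed as Y = X + ξ
  with ξ Gaussian of *variance* σ (SD √σ). Burn-in 1000; initial conditions
  0.1 + uniform(±0.05); a trajectory leaving |x| ≤ 10 restarts from fresh
  initial conditions.
- VAR: two AR(2) processes (ρ_x = ρ_y = 0.3, f_x = 0.3, f_y = 0.1) with a
  directed lag-2 connection C·X_{n−2} into Y; independent unit innovations.
- Coupled Hénon–Hénon maps: X_n = 1.4 − X²_{n−1} + 0.3X_{n−2} driving
  Y_n = 1.4 − (C X_{n−1}Y_{n−1} + (1−C) Y²_{n−1}) + 0.3Y_{n−2}; C ≤ 0.5 to
  stay below synchronization. (The two Hénon variants use the map constants
  (1, 1.4) and (1.4, 1) respectively, as their defining equations are
  conventionally written for these experiments.)

Linear-Gaussian ground truth:

- `theoretical_is_ar2`: S_X = ½ ln(σ²_X/σ²_ε) with σ²_X from the Yule–Walker
  equations — exact for q ≥ 2 since the process is Markov of order 2.
- `theoretical_mir_var2`: I_XY = −(1/4π) ∫ ln(1 − |coherency(ω)|²) dω over
  (−π, π], by trapezoidal quadrature (4096 bins; refinement changes the
  value by < 1e-6) of the cross-spectral matrix S(ω) = H(ω)H(ω)* with
  H = (I − A₁z − A₂z²)^{-1}. The spectral integral rather than finite-order
  prediction-error variances is used because the marginal representations of
  a VAR are not finite-order AR; for this lag-2-coupled VAR the q = 2
  truncated Gaussian value coincides with the integral to 4 decimals, so the
  oracle is exact at the estimator's own truncation as well.

## Study conditions and problem sizes

The validation experiments use N = 1000 samples, k = 10, q = 2, α = 0.05,
M = 100 surrogates (M = 50 for the costlier bivariate IAAFT experiment) and
100 realizations for the type-I-error and estimator-agreement checks. The
power/trend checks in the test suite use 25–50 realizations per grid value,
which keeps the suite's full run in the ten-minute range while leaving the
binomial uncertainty of each rate a few percent. Calibration assertions use
exact binomial 99% acceptance bands around the nominal level rather than
fixed percentages.

What the synthetic benchmarks do *not* emulate: nonstationarity, measurement
artifacts, unevenly sampled or short physiological records, and
multivariate (> 2 process) interactions. Passing tests demonstrate correct
behavior of the estimators and tests under the stated stationary, ergodic
model classes; on real data the usual caveats of surrogate testing apply
(rejection speaks only against the specific null embodied by the surrogate
construction).
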