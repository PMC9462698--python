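# Methods

## Model

The semilocal exchange-correlation (XC) energy of a spin-unpolarized
system is assembled from three dimensionless enhancement factors over LDA
energy densities,

    E_xc^sl[rho] = ∫ ( e_x^LDA[rho] F_x
                     + e_c-ss^LDA[rho] F_c-ss
                     + e_c-os^LDA[rho] F_c-os ) dr,

discretized as a quadrature sum over per-system grids.  Each enhancement
factor is a function of the squared reduced density gradient
`x2 = (2^(1/3) |∇rho| / rho^(4/3))^2` and of a bounded
kinetic-energy-density feature `w ∈ [-1, 1]`, and is represented as a short
*instruction program*: an ordered list of elementary operations (add,
subtract, multiply, divide, multiply-accumulate, powers
n ∈ {2, 3, 4, 6, 1/2, 1/3}, and the finite-domain transform
`u = g·x2/(1+g·x2)` whose gamma is bound to the instruction) acting on a
workspace of features, scalar parameters and zero-initialized variables.
The readout is the variable `F` after the last instruction.  This
representation is closed under four mutation rules — insert, remove,
change-operation, change-argument — which is what makes the *form* of the
functional searchable.

The search is regularized evolution: a bounded FIFO population (default
100) of fitted functionals; each step selects the fittest member of a
random tournament (default 25; 10 in the small rediscovery study), mutates
one uniformly chosen channel by one rule, fits the child's scalar
parameters on the training split, scores it as `fitness = -J_validation`,
and appends it, evicting the *oldest* member when the cap is exceeded.
Invalid children (non-finite evaluations) are inserted with fitness −∞
rather than discarded so the aging clock stays faithful.

Parameter fitting minimizes the weighted root-mean-square deviation

    J_S = sqrt( (1/N) Σ_{i∈S} w_i (E_i − E_i^ref)² )   [kcal/mol]

where each data point is a signed combination of system energies
(reaction-energy style) with a per-type sample weight.  All parameters are
treated as nonlinear and optimized by CMA-ES, restarted from initial means
drawn from a unit Gaussian, every parameter box-constrained to [−10, 10];
the restart with the lowest training error wins.  Zero-parameter forms
skip the optimizer.  Only parameters actually referenced by the canonical
program are optimized; declared-but-unused parameters are pinned to zero.

## Equivalence cache

Mutations frequently produce programs that compute the same function
(dead instructions, renamed intermediates, commuted arguments).  Forms are
canonicalized by dead-code elimination (backward dependency slice of `F`)
and fingerprinted by hashing quantized outputs on a fixed pseudo-random
probe set of feature points under several parameter draws, assigned
positionally in order of first use.  Equal digests reuse the cached fit,
so a duplicate step costs no optimizer evaluations; the child is still
inserted, keeping population dynamics faithful.  Probe ranges: `x2`
log-uniform over [1e-4, 1e4], `w` uniform over [−1, 1], parameters
standard normal clipped to [−10, 10]; 64 probe points, 4 parameter draws,
8-decimal quantization.  Equivalence under re-parameterization (two
families that coincide only after a nonlinear change of parameters) is
deliberately *not* detected; such forms are trained independently.  The
probe-seeded construction makes digests deterministic across runs and
platforms.

## CMA-ES

No CMA-ES library is a dependency; `xcevolve.cmaes` implements the
standard (mu/mu_w, lambda) strategy — log-rank recombination weights,
cumulative step-size adaptation, rank-one plus rank-mu covariance update —
with a *batched* objective (`f(X)` over the whole population at once), which
keeps the per-generation Python overhead negligible next to the vectorized
grid evaluation.  Box constraints use repair-plus-penalty: candidates are
clipped into the box, the objective is evaluated at the repaired point, and
a quadratic penalty (weight 100 per squared unit of repair distance) steers
the distribution inward; the reported optimum is always feasible.
Termination: evaluation budget (default 5000·d), step-size or covariance
degeneracy (condition number > 1e14), stagnation of the best value
(relative 1e-12 over 30 generations), or an optional target value.

## Synthetic data

Real training data (molecular quadrature grids plus thousands of typed,
weighted energy differences) is not desk-reproducible, so the generator
emulates its statistical structure: seeded pseudo-random grids with
`rho` log-uniform over [1e-2, 10] a.u., `x2` log-uniform over [1e-4, 1e4],
`w` uniform over [−1, 1], nonnegative quadrature weights summing to ~1
a.u. volume per system; data points are single energies, pairwise
differences, or three-term signed combinations, carrying per-type weights
(TCD 0.1; TCE, AE18 1; NCD, ID, BH 10; NCE, IE 100; RG10 10000); splits
are a seeded 60/20/20 shuffle.  References are computed from a chosen
ground-truth functional; noise defaults to zero so rediscovery is exactly
solvable, and the noise stream is separate from the structure stream so
turning noise on does not change which data points exist.  What this does
*not* emulate: correlations between density, gradient and kinetic-energy
features of real molecules, basis sets, self-consistency, or the
type-partitioned (non-iid) split of the full database — so passing tests
demonstrate the correctness of the search/fit machinery, not chemical
accuracy of any functional it finds.

The default LDA kernel uses full-range LDA exchange
`e_x = −(3/4)(3/π)^(1/3) rho^(4/3)`; the same-/opposite-spin correlation
split is a smooth synthetic surrogate `e_c = −c·rho^(4/3)`
(c_ss = 0.04, c_os = 0.08), an explicit plug-in point, *not* a physical
correlation parameterization.  `w` is taken directly as an input feature
rather than derived from the kinetic energy density.

## The rediscovery study

`b97_demo_fixture` packages the from-scratch experiment: search space of
four operations {add, multiply-accumulate, square, finite-domain
transform}, at most six instructions, workspace of one feature (`x2`),
four parameters and three variables, tournament size 10, population 100,
ten CMA-ES restarts per child.  One of the four parameters (`p3`) is
designated as the transform gamma: it is bound only by transform
instructions and never offered as an ordinary argument, mirroring the
stated role of gamma in the published search space.  (Allowing any
parameter to be bound dynamically lets a single symbol serve as gamma in
one instruction and as a coefficient in another, which pins power-series
coefficients and fills the population with forms that *look* like members
of the quadratic family but cannot represent the target.)

Reference energies are generated from the published B97 exchange
coefficients (c0 = 0.8094, c1 = 0.5073, c2 = 0.7481, gamma = 0.004) with
empty correlation channels.  All data points are reaction-type (two or
three signed terms) because thermochemistry references are energy
differences.  The desk-scale condition numbers are 64 systems × 32 grid
points and 400 data points: the functional is identified only through
per-system aggregate integrals, so too few systems under-constrain the
objective and deepen spurious basins (e.g. linear-in-`x2` forms) relative
to a study with ~10³ molecules.

Success is declared when an individual's exchange program, at its fitted
parameters, is algebraically a member of the family `c0 + c1·u + c2·u²`
(verified as a rational-function identity on a dense `x2` probe grid
against a least-squares quadratic in `u` for each fitted gamma) *and* its
validation error is below 1e-3 of the data scale (the RMS reference
magnitude).  The absolute errors of the original study are not
reproducible without its database; the relative threshold replaces them.
The first-success mutation count is reported as the median over five
seeded runs; a run that exhausts its 4000-mutation budget is counted at
budget + 1.  Under these conditions roughly two runs in three succeed
within budget, so the median is the robust summary; individual runs are
genuinely stochastic.

## Numerical choices and degenerate inputs

* Division by ~0, fractional powers of negative arguments, and any other
  non-finite intermediate mark the whole evaluation invalid (per batch
  row) instead of raising; the fitting layer maps invalid rows to J = ∞
  and evolution inserts such children with fitness −∞.
* Tournament ties break toward the most recent insertion.
* Energies are computed in hartree and converted to kcal/mol
  (627.509474 kcal/mol per hartree) before the objective.
* The opposite-spin channel of the shipped GAS22 table carries an
  `x^(3/2)` term, encoded through the allowed exponents as
  `((x2^(1/2))^3)^(1/2)`; the alternative `x^(2/3)` reading of the printed
  form is supported (`x2^(1/3)`) and selectable in the data file.
* The wB97M-V coefficient table is transcribed from the original
  wB97M-V publication's parameterization and shipped as versioned JSON;
  it is configuration data, not a fitted artifact of this package.
* Expression rendering is deterministic forward substitution in sympy;
  simplification (`together` + `cancel`) is optional and deterministic.
* `workers > 1` evaluates rounds of children selected against one
  population snapshot with atomic ordered insertion — the asynchronous
  contract of a distributed search, executed synchronously; `workers = 1`
  is bit-reproducible for a fixed seed.

## Known limitations

* No self-consistency: energies are single-shot quadrature sums on fixed
  synthetic grids; no basis sets, no nonlocal correlation, no dispersion.
* Spin-unpolarized formalism only.
* The correlation LDA surrogate is non-physical by construction; results
  on synthetic data say nothing about thermochemical accuracy.
* The equivalence check is numeric: hash collisions are astronomically
  unlikely but not impossible, and re-parameterized duplicates are
  retrained by design.
* The rediscovery experiment is stochastic; its per-seed success rate at
  the 4000-mutation budget is ~2/3 under the packaged conditions, which
  is why the reported statistic is a median over five seeds.
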