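# xcevolve

Symbolic evolutionary search for exchange-correlation enhancement factors.

## What this is for

Semilocal exchange-correlation (XC) functionals in Kohn-Sham DFT are, in
practice, three dimensionless *enhancement factors* multiplying LDA energy
densities,

```
E_xc^sl[ρ] = ∫ ( e_x^LDA F_x + e_c-ss^LDA F_c-ss + e_c-os^LDA F_c-os ) dr ,
```

with each factor a closed-form function of the squared reduced density
gradient `x² = (2^(1/3)|∇ρ|/ρ^(4/3))²` and a bounded kinetic-energy-density
feature `w ∈ [−1, 1]`.  Designing such forms has historically been manual.
This package searches for them automatically while keeping the result
*symbolic*: each factor is a short instruction program (add, subtract,
multiply, divide, multiply-accumulate, powers n ∈ {2,3,4,6,½,⅓}, and the
finite-domain transform `u = γx²/(1+γx²)`) over a workspace of features,
scalar parameters, and variables.  The search machinery is:

* **regularized evolution** — a bounded FIFO population; tournament
  selection; one of four mutation rules (insert / remove / change-op /
  change-argument) applied to one randomly chosen channel; the *oldest*
  individual is evicted (aging), not the worst;
* **CMA-ES parameter fitting** — every candidate form's scalars are
  treated as nonlinear and fitted to a weighted-RMSD energy objective
  `J = sqrt(mean(wᵢ (Eᵢ − Eᵢ^ref)²))` in kcal/mol, multi-restart, box
  constrained to [−10, 10];
* **an equivalence cache** — programs are canonicalized by dead-code
  elimination and fingerprinted numerically, so syntactic variants of an
  already-trained form skip the optimizer entirely.

Published closed forms — B97's quadratic gradient correction
`c0 + c1·u + c2·u²`, its algebraically equivalent rediscovered variant
`c0² + c1(c2+u)²`, the ωB97M-V power series in `(w, u)`, and GAS22 — ship
both as direct evaluators and as instruction programs, with coefficient
tables as versioned JSON data files.  A synthetic-data generator produces
grids and reaction-energy data points with the statistical structure the
search assumes, so everything is testable on a desk with no downloads; it
is intended for methodologists studying symbolic functional search, not
for production chemistry.

## Worked example

Evaluate the shipped GAS22 form, generate a synthetic dataset from it, and
confirm the self-fit is exact:

```python
from xcevolve import gas22_functional, evaluate_functional
from xcevolve.synth import SyntheticSpec, generate_dataset
from xcevolve.programs import render_expression

fun, params = gas22_functional()
print(render_expression(fun.programs["x"], simplify=True))
spec = SyntheticSpec(n_systems=12, points_per_system=16, n_datapoints=80, seed=42)
ds = generate_dataset(spec, fun, params)
print(evaluate_functional(fun, params, ds))
```

prints

```
(w*x2*x_a2*x_g + w*x_a2 + x2*x_a0*x_g + x2*x_a1*x_g + x_a0)/(x2*x_g + 1)
{'train': 7.886e-12, 'validation': 1.831e-11, 'test': 2.423e-11}
```

The rendered exchange factor is `0.862 + 0.937·u + 0.318·w` written over a
common denominator (`x_a0 = 0.862`, `x_a1 = 0.937`, `x_a2 = 0.318`,
`x_g = 0.00384`), and the weighted RMSD of the generating form on its own
noiseless data is zero to solver precision on all three splits — the
self-consistency every search run builds on.

The from-scratch rediscovery experiment (four operations, ≤ 6
instructions, one feature `x²`, four parameters, three variables,
tournament 10, population 100, references generated from the published B97
exchange coefficients):

```python
from xcevolve.synth import run_b97_rediscovery
step, result = run_b97_rediscovery(seed=2)
print(step, result.best.expression()["x"])
```

stops at the first individual whose exchange program is algebraically a
quadratic in one finite-domain transform of `x²` with validation error
below 10⁻³ of the data scale — typically after one to three thousand
mutations (the run is stochastic; roughly one seed in three exhausts the
4000-mutation budget first).

The same machinery is scriptable from a shell: `xcevolve synth`,
`xcevolve evolve`, `xcevolve fit`, `xcevolve render`, and
`xcevolve fxc-curves` (tabulates the combined factor
`F_xc = e_xc/e_xc^LDA` over `s ∈ [0,3]`, `r_s`, `w ∈ {−1,0,1}`).

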