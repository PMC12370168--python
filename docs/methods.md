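# Methods note

`nanorheo` simulates and inverts AFM force–distance curves (FDCs) on soft,
finite-thickness samples under power-law rheology, using a supervised
machine-learning regressor with a classical least-squares fit as a baseline.
This note records the model, its assumptions, the numerical choices, and the
known limitations.

## 1. Forward model

### 1.1 Constitutive law

The sample is a power-law rheology (PLR) solid with relaxation modulus

```
psi(t) = E0 / Gamma(1 - gamma) * (t / t0)^(-gamma),      t0 = 1 s
```

with scaling modulus `E0` (Pa) and fluidity exponent `gamma in [0, 1)`:
`gamma = 0` is an elastic solid, `gamma -> 1` approaches a Newtonian fluid.
The implementation caps `gamma` at `GAMMA_MAX = 0.99` because the
`1/Gamma(1-gamma)` prefactor degenerates at `gamma = 1`.

### 1.2 Contact mechanics with bottom-effect correction

For a conical tip (half-angle `theta`) indenting a sample of finite thickness
`h` bonded to a rigid support, the elastic force–indentation relation is a
polynomial

```
F_el(I) = E0 * sum_j alpha_j * I^(beta_j),    beta_j = 2 + j
alpha_j = a_j * tan(theta)^(j+1) / h^j
```

whose `j = 0` term is Sneddon's cone result (`a_0 = 2/pi`) and whose higher
terms correct for the finite thickness through powers of the contact-size
ratio `r_max/h = tan(theta) * I_max / h`. The shipped coefficient table
(`cone-bonded-v1`) keeps three terms with relative coefficients
`(1, 0.360601, 0.520103)`; published bottom-effect series differ in their
higher-order terms, so the table is named, versioned and overridable, and all
internal consistency checks (round trips, limits) are convention-independent.
Validity requires `r_max/h <= 1`.

### 1.3 Viscoelastic force with contact loss

For an arbitrary indentation history `I(t)` with a single maximum at `t_max`,
the force follows the two-branch hereditary (Ting) formulation. During
approach (`t <= t_max`):

```
F(t) = sum_j alpha_j * integral_0^t psi(t - u) d/du [ I(u)^(beta_j) ] du
```

During retraction the upper limit is replaced by the contact time `t1(t) <
t_max`, defined by the balance

```
integral_{t1(t)}^{t} psi(t - u) * v(u) du = 0,     v = dI/dt
```

after which the tip–sample contact radius stops growing; once `t1` reaches
the time at which `I` falls below its initial value, contact is lost and the
force is identically zero. Profiles may enter already indented
(`I(0) = eps > 0`); the hereditary integral then measures force relative to
that initial state, so `F(0) = 0` and the elastic limit of the model is
`E0 * max(P(I) - P(I(0)), 0)` with `P` the polynomial above. This
reference-state convention is exact and is what the elastic-limit oracle
tests verify to 1e-9.

### 1.4 Dimensionless reduction

Writing `s = t/t_tot` and `i(s) = I(t)/I_max`, each monomial term scales out
of the integral, leaving

```
F(t) = E0 * tan(theta) * I_max^2 * (t_tot/t0)^(-gamma) * w * f(s)
```

where `f(s)` is a dimensionless force shape depending only on
(`gamma`, `r_max/h`, profile shape) and `w` is the total variation of `i`
(so `v_bar = I_max * w / t_tot` is the mean absolute speed). The mean of
`F` over the curve, `F_bar`, therefore determines `E0` in closed form given
`gamma` and the mean dimensionless force `f_bar`:

```
E0 = (F_bar / f_bar) * (t_tot/t0)^gamma / (tan(theta) * I_max * v_bar * t_tot)
```

(implemented as `recover_modulus`, using `w = v_bar * t_tot / I_max`).

This identity is exact (round-trip tested to 1e-6 relative) and is the
backbone of both the synthetic-data generator (simulate once per shape,
scale analytically) and the modulus head of the regressor.

## 2. Numerics

- **Grid.** Forces are evaluated on a piecewise-uniform grid split at the
  indentation peak (default 500 points for dimensional simulation, 301 for
  dataset generation). A strictly uniform grid generally misses `t_max` and
  smears the velocity discontinuity of triangular ramps.
- **Quadrature.** The weakly singular convolution `integral psi(t-u) g'(u) du`
  uses first-order product integration (the kernel integrated exactly against
  a piecewise-linear interpolant of `g`), plus a second-order midpoint moment
  correction. The correction is disabled on intervals cut by the moving
  `t1` limit, where the integrand is re-anchored at the interpolated
  crossing point; this keeps the elastic (`gamma = 0`) limit machine-exact.
  Agreement with an independent adaptive-quadrature oracle (scipy `quad`
  with algebraic-singularity weights) is better than 1e-4 relative at 1001
  grid points.
- **Contact-time solver.** On the discrete grid the retraction balance is
  piecewise analytic in `t1`, so the bracketing interval is located by the
  sign change of an exact cumulative sum and `t1` is inverted in closed form
  within it — no iteration, no tolerance. For a symmetric triangular ramp
  this reproduces the closed form
  `t1 = t - 2^(1/(1-gamma)) * (t - t_max)` to 1e-6 of the curve duration.
- **Profiles.** Indentation histories are represented on a clamped cubic
  B-spline basis (40 interior knots, 44 basis functions). Exact Gram
  matrices come from per-span Gauss–Legendre quadrature. Generator shapes:
  triangular ramps, capped sinusoids, and random admissible splines
  (monotone rise to a single interior peak, validated by a 7-condition
  admissibility check with rejection sampling).

## 3. Synthetic data

Each sample draws `gamma ~ U(0, 0.99)`, `r_max/h ~ U(0.001, 1)`, `E0`
log-uniform on 0.1–100 kPa, `I_max` uniform on 0.3–3.5 um, `t_tot`
log-uniform on 0.05–5 s, and one of the three profile families (equal
probability). Curves are simulated once in dimensionless form and scaled
analytically. Features per curve:

- the force resampled at 100 uniform points in `s`, divided by its mean
  (shape only; the amplitude enters through `F_bar` in the closed-form
  modulus step);
- B-spline coefficients of `i(s)` and `di/ds` fitted on a dense grid;
- the thickness feature `r_max/h`.

Force features are *group normalized*: one scalar mean and standard
deviation computed over the whole training force block, not per curve and
not per channel. Per-channel standardization was tried and rejected — it
overfits (worse held-out error).

## 4. Nested functional-basis regressor

Two multilayer perceptrons (scikit-learn `MLPRegressor`, ReLU, adam):

- the **outer network** maps (100 normalized force samples, functional
  indentation block, functional velocity block, standardized `r_max/h`) to
  `gamma`, clipped to `[0, 0.99]`;
- the **inner network** maps (`gamma`, the same functional blocks) to
  `log f_bar`, exponentiated to guarantee positivity; `E0` then follows in
  closed form from `F_bar / f_bar`.

Functional inputs enter through L2 inner products with learned weight
functions. With both expanded on the same B-spline basis the inner product
is `c^T G g` (`G` the Gram matrix), so the fixed map `c -> c_std @ G` is
applied once and the first dense layer's weights become the weight-function
coefficients — the "functional layer" costs nothing at runtime.

Training is staged: (1) outer network on true `gamma` labels; (2) inner
network with the true `gamma` as input (teacher forcing); (3) warm-started
fine-tuning of the inner network on the outer network's own predictions, so
it sees at inference what it saw in training. Each network uses a staged
learning-rate decay (1e-3, then warm-started stages at 2e-4 and 5e-5 with
early stopping patience 40). On a 2,000-curve held-out set this halves the
validation RMSE of `gamma` versus a single constant-rate run.

Trained models serialize to HDF5 (weights, functional layers, normalization
statistics, basis spec, schema version); inference is a pure-NumPy forward
pass, and the loader refuses files whose schema major version or basis spec
does not match.

## 5. Classical fit baseline

`fit_curve` solves the full nonlinear least-squares problem by profile
likelihood: for fixed `gamma` the model force is linear in `E0`, so the
optimal `E0(gamma)` is the exact 1-D projection `<g, F>/<g, g>` (clamped at
zero), reducing the problem to a bounded scalar minimization over `gamma`
(Brent's method). This is exact on noiseless data (recovery to 1e-4 over a
grid of `gamma` and `r_max/h`) and matches a brute-force grid-search oracle
within its resolution under 2% noise.

## 6. Force-volume mapping

Synthetic phantoms (uniform, two-region nucleus/cytoplasm, dome with stiff
ridges and a soft nucleus) generate HDF5 force volumes; pixels whose
thickness would violate `r_max/h <= 0.98` have their commanded indentation
clamped (counted and reported). Curves are stored on the simulation's
peak-split time grid — resampling to a uniform grid was measured to bias the
fit engine's modulus by ~0.5% by smearing the peak sample.

`process_force_volume` runs either engine (`sml` = the trained regressor,
`fit` = the classical baseline) per pixel, independent of pixel order, with
per-pixel failures recorded in a quality channel instead of aborting, and
per-stage timings (loading / preprocessing / inference / other).
Compositional images encode normalized `log10 E0`, normalized height and a
mask byte as three uint8 channels (decodable to 1/255), and render to RGB
through HSV (hue = modulus, luminance = height, masked pixels magenta).

## 7. Problem sizes

The package's default training corpus and the sizes used by
`scripts/acceptance.py` (tens of thousands of curves, one CPU, minutes of
training) are this package's own choice, set to keep a full from-scratch
verification run within a laptop-class budget while meeting the stated
accuracy targets. The generator defaults to `n = 100_000` if you ask for a
production-size corpus; nothing in the code depends on the scaled-down
sizes.

## 8. Limitations

- The inversion is trained for conical tips and the shipped bottom-effect
  table; other tip geometries or correction conventions require retraining.
- Indentation histories must have a single interior maximum; multi-cycle
  (e.g. oscillatory dwell) protocols are out of scope.
- The model assumes ideal contact detection: measured curves must already be
  converted to indentation vs time with the contact point identified.
  Instrumental artifacts (drift, hydrodynamic drag, baseline tilt) are not
  modeled.
- Adhesion is not modeled; the contact-loss criterion is purely the sign of
  the hereditary integral.
- `gamma` is capped at 0.99; materials approaching the fluid limit are
  outside the validated range, and the regressor's clip makes errors there
  asymmetric.
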