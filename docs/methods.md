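# Methods

This note records the model, the defaults, and the numerical choices behind
`vligand`, in enough detail to re-derive or audit every result the package
produces.

## 1. The virtual-ligand model

A phosphine ligand PR3 is replaced by PCl\*3, three chlorine pseudo-atoms
bound to phosphorus, whose behavior is shaped by three penalty energies
(`vligand.vl_model`). All energies are in the backend's energy unit
(kcal/mol for a chemistry backend); lengths are in Å and angles in degrees.

**Keep potential.** `E_keep = k_keep Σ_i (|r_P − r_Cl*_i| − r0)²` holds each
P–Cl\* bond near `r0`. Default `k_keep = 100.0` energy/Å², strong enough to
pin the distance without dominating the Hessian.

**Keep-angle potential.** `E_angle = k_angle Σ_{i<j} (θ_ij − φ0)²` over the
three Cl\*–P–Cl\* angles, with `φ0 = 65°` and `k_angle = 0.1` energy/deg².
Its gradient is analytic; a geometry with a collinear P–Cl\*–Cl\*
arrangement (sin θ below 1e−8) raises `DegenerateGeometryError` rather than
returning a garbage gradient.

**Ovoid steric potential.** Each Cl\* carries a closed ovoid surface:
in a local frame with `u` the unit P→Cl\* vector, origin displaced `d` along
`u`, an environment atom at local coordinates `(x, y, z)` has elliptical
radius `ρ² = (x/α)² + (y/β)² + (z/γ)²`, where the half-axes are
sign-dependent: `α ∈ {c1, c2}` along the axis, `β ∈ {a1, a2}` across, and
`γ ∈ {b1, b2}` through the wall. The pair energy is Lennard-Jones in ρ,
`E = ε (ρ⁻¹² − 2 ρ⁻⁶)`, summed over Cl\*–environment pairs. Defaults:
`c1 = c2 = d = 3.0 Å`, `ε = 0.1`, and the symmetric mode `a2 = a1`,
`b2 = b1`. The functional form is isolated in `ovoid_lj_energy` so an
alternative ovoid parameterization can be swapped in without touching the
rest of the package. Gradients with respect to both coordinates and
`(a1, b1)` are exact, computed with the in-package forward-mode
dual-number type (`vligand._jet`), and verified against central finite
differences in the test suite.

The variable parameter vector is `p = (r0, a1, b1)`. Default physical range
(`DEFAULT_BOUNDS`): `r0 ∈ [1.3, 1.9]`, `a1 ∈ [2.0, 3.5]`, `b1 ∈ [1.5, 3.0]` Å;
an expanded range (`EXPANDED_BOUNDS`: `[1.0, 2.2] × [1.5, 5.5] × [0.5, 2.5]`)
is available for exploratory fits.

## 2. Descriptors and projection

A ligand's electronic/steric character is summarized by its dissociation
energies against a fixed panel of 16 fragments (`vligand.descriptors.FRAGMENTS`;
four are named chemical probes, the remainder are documented synthetic
placeholders — the pipeline treats the panel as an opaque list). PCA
(numpy SVD with a deterministic sign convention: largest-magnitude loading
component positive) maps the 16 energies to descriptor scores `x`. Because
the loadings are orthonormal, Euclidean distances in score space equal
distances in raw energy space.

The VL traces a 3-parameter surface `G(p)` in that space. Projection
(`vligand.projection.project`) solves `min_p ||x − G(p)||²` by conjugate
gradients from `p_init = (1.6, 3.0, 2.0)` with 5 additional perturbed
restarts (scale 0.25, seeded), keeping the best result with deterministic
tie-breaking. The residual `l_min` at the solution is the ligand's
reliability index: it measures the part of the ligand the VL model cannot
represent at all.

## 3. Optimization (VLAO)

`vligand.vlao.optimize` minimizes `sign·y(p) + B(p)` (sign = −1 for
maximization) where `B` is a smooth confinement barrier: zero on the central
90 % of each parameter range, then quartic in the normalized excess with
stiffness 50. A quartic plateau barrier keeps the objective twice
continuously differentiable — important because the optimum's Hessian feeds
the surrogates — while leaving the interior dynamics untouched.

The minimizer (`vligand.optimize.minimize_cg`) is Polak–Ribière+ conjugate
gradients with Armijo backtracking (c = 1e−4, shrink 0.5, ≤ 60 backtracks),
restart on non-descent directions, and two floating-point stopping rules
(line-search stall; step and decrease below machine-level thresholds) so
that runs terminate cleanly when `|f|` is large relative to the achievable
decrease. SciPy's optimizers are used only as independent test oracles,
never in the library path, keeping the runtime dependency set minimal and
the iterate trajectory fully specified.

Every accepted iterate's *uncorrected* objective value and gradient are
recorded in the trajectory. The Hessian of the uncorrected objective at
`p*` is computed by central differences of the analytic gradient
(default step 1e−4, explicitly symmetrized).

## 4. Surrogate predictors

* **Taylor** (`TaylorSurrogate`): second-order expansion at `p*`. The
  Hessian is clipped to positive semidefinite (eigenvalue clipping at zero —
  the Frobenius-nearest PSD matrix) so the model never predicts spurious
  improvement along negative-curvature directions.
* **Trajectory-weighted** (`TrajectorySurrogate`): inverse-square-distance
  weighted average of per-iterate Taylor models, with distances measured in
  the range-normalized metric below; a query within 1e−8 of an anchor
  returns that member exactly. This uses information from the whole
  optimization path, improving accuracy away from `p*`.
* **Direct** (`predict_direct`): evaluate the backend at the ligand's `p` —
  exact but costs one backend call per ligand.

## 5. Reliability filtering and ranking

Deviation from the optimum is measured by
`||Δp'|| = sqrt(Σ_i ((p_i − p*_i)/w_i)²)` with `w_i` the width of parameter
`i`'s range — the same range the barrier enforces — making the metric
dimensionless. Two threshold sets are used throughout:
strict (`l_min < 2.0`, `||Δp'|| < 0.75`) and loose (`2.5`, `1.0`).
Comparisons are **strict** inequalities; a ligand sitting exactly on a
threshold fails. This choice is load-bearing: it reproduces all eight
validation counts from the packaged database. Within each filter, ligands
are ranked by predicted objective (ascending for minimization), with ties
broken by smaller `||Δp'||`, then by id, so reports are byte-identical
across runs.

## 6. The synthetic backend

`SyntheticSurfaceSpec` emulates the *shape* of the problem, not its
chemistry: the objective is a positive-definite quadratic (scale 10)
plus an optional sinusoidal bump (amplitude, default 0) and offset; the
descriptor map is affine (random 16×3 matrix) plus an optional symmetric
quadratic warp. Synthetic ligands are placed on the surface at a known
`p_true` and pushed off it by an orthogonal offset of known norm δ, so the
projection's recovered `p` and `l_min` have exact ground truth. All
randomness flows through `numpy.random.default_rng(seed)`.

What it does **not** emulate: real dissociation-energy magnitudes, chemical
trends across the fragment panel, DFT-level reaction energies or barriers.
The packaged 21-ligand database (fitted parameters and residuals) is an
input fixture; regenerating it requires quantum-chemistry software outside
this package's scope.

## 7. Problem sizes and performance

Default sizes are the package's own choices: 3 VL parameters, 16 fragments,
21 database ligands. At these sizes a full synthetic pipeline run takes
well under a second; the complete test suite (143 tests, including
property-based checks and dense grid-search oracles) runs in a few seconds
on one CPU.

## 8. Limitations

* Three parameters capture one electronic and two steric degrees of
  freedom; ligands whose character needs more (large `l_min`) are flagged,
  not modeled.
* Surrogate accuracy degrades with distance from the trajectory; the
  `||Δp'||` filter bounds, but does not eliminate, extrapolation error.
* The CG minimizer is a local method; multimodal objectives rely on the
  restart strategy (projection) or a sensible `p_init` (VLAO).
* The symmetric ovoid mode (`a2 = a1`, `b2 = b1`) is the default; the
  asymmetric mode is implemented but has no packaged reference data.
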