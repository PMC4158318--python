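# Methods

## Model

A microtubule is idealized as a thin circular cylindrical shell of length `L`,
mid-surface radius `R`, wall thickness `h` and *effective bending thickness*
`h0` (the microtubule wall is a discrete protofilament lattice, so the
thickness that governs bending differs from the membrane thickness).  The
material is orthotropic: Young's moduli `E1` (axial) and `E2`
(circumferential), in-plane shear modulus `G`, Poisson ratios `μ1, μ2`.  The
surrounding filament network acts as a Winkler-type elastic foundation with
constant `ς = 2.7 E_c`, where `E_c` is the elastic modulus of the surrounding
medium; the viscous cytosol can exert a radial pressure `P_YY` that enters the
radial equilibrium equation as a prescribed forcing slot.  The shell carries an
axial compressive membrane force `N` (units N/m).

Constitutively the shell is **nonlocal** in Eringen's sense: on the
dimensionless cylinder (`x = X/R`, `θ`), `(1 − η²∇²)σ = C ε` with
`η = e·a₀/R` the small-scale parameter.  For a single Fourier harmonic
`∝ cos(λx)cos(nθ)` this is the scalar attenuation
`σ = σ_local / (1 + η²(λ²+n²))`: short-wavelength stress is reduced, and
`η = 0` recovers classical elasticity.

All operators consume only dimensionless groups:

| group | definition | role |
|---|---|---|
| `k1` | `E2/E1` | circumferential-to-axial modulus ratio |
| `k2` | `G(1−μ1μ2)/E1` | shear number |
| `c2` | `h0³/(12R²h)` | bending number |
| `K`  | `E1h/(1−μ1μ2)` | membrane stiffness (N/m), the load scale |
| `η`  | `ea₀/R` | small-scale (nonlocal) parameter |
| `l`  | `L/R` | slenderness |
| `μ1` | — | enters the coupling terms `(k2+μ1)`, `(3k2+μ1)`, … |
| `ςR/K` | foundation number | Winkler restoring per membrane stiffness |
| `κR/K` | pressure number | proportional radial-pressure model |

The direction of `k1` is fixed by consistency: after division by `K`, the
hoop-stiffness terms (`k1·v_θθ`, `k1·w_θ`, `c2k1·w_θθθθ`) must carry the
circumferential modulus, hence `k1 = E2/E1`.  The group set is closed by `μ1`
and the foundation/pressure numbers, which is why `DimensionlessGroups`
carries them; the assembly routines take `(groups, mode)` only.

## The variational principle and its verification

The governing system is three coupled PDEs, `D₁ = L₁(u)+M₁(v,w)`,
`D₂ = L₂(v)+M₂(u,w)`, `D₃ = L₃(w)+M₃(u,v)`, with the nonlocal operator
`L(f) = η²∇²f − f` multiplying the load (`(N/K)L(y_xx)`), foundation
(`(ςR/K)L(w)`) and pressure (`(R/K)L(P_YY)`) terms.  The semi-inverse route
posits `V = V₁(u)+V₂(v)+V₃(w)+∬F`, where the `V_i` are the (known) quadratic
functionals of the uncoupled operators and the coupling density `F` is fixed
by requiring `δF/δu = M₁`, `δF/δv = M₂`, `δF/δw = M₃`.  The chain is
constructive: solving `δF/δu = M₁` leaves an unknown `Φ(v,w)` which
`δΦ/δv = k1w_θ − c2(3k2+μ1)w_xxθ` then determines; the resulting `F` also
satisfies the `w` equation.  The trial functional is not unique (any
divergence can be added to `F`); this package uses the `w_xx v_θ` form of the
`Φ` term.

`variational_derivative` implements the higher-order Euler–Lagrange operator
`δF/δy = ∂F/∂y + Σ (−1)^{i+j} ∂ₓ^i ∂_θ^j (∂F/∂y_{x^iθ^j})` over every mixed
order present, the sign alternating with the parity of the total derivative
order; orders beyond the template cap raise an error rather than truncating.
Derivative atoms are canonicalized (`doit`) before differentiation because
sympy treats constructor-ordered and diff-ordered mixed derivatives as
distinct objects, and a silent mismatch would drop terms.

`verify_euler_lagrange` expands `δV/δy − D_y` with **fully symbolic**
parameters (`k1, k2, c2, μ1, η, ςR/K, N/K` and a symbolic pressure field), so
a `zero` verdict holds for every admissible parameter set simultaneously.
Expansion-based cancellation terminates quickly for these polynomial
densities; if it ever failed to produce zero, `simplify` is tried and a
non-zero or inconclusive status is reported — never a claimed zero.  A numeric
shadow always runs: the unsimplified residual is evaluated on seeded random
test fields (low-order polynomials in `x` times truncated Fourier series in
`θ`, `n ≤ 3` — smooth, 2π-periodic, exercising all derivative orders) for ≥ 5
random parameter draws, and the max-abs residual is reported relative to the
magnitude of `δV/δy` itself.  A negative-control hook (`f_scales`) rescales
individual coupling terms; a broken functional yields order-one residuals.

The pressure field enters `V₃` as the literal linear term `2(R/K)L(P_YY)·w`
(inside the global ½) with `P_YY` *prescribed*: its variation is exactly the
governing slot.  A displacement-dependent pressure model must not be
substituted into the functional (the linear term's variation carries no ½, so
substitution would double it); the proportional model therefore joins the
eigenproblem through the Galerkin route below.

## Rayleigh–Ritz solver

The functional splits as `V = −(R₁+R₂+R₃−V₄) + N(S(u)+S(v)+S(w))` with
`S(y) = (1/2K)∬ η²(y_xx²+y_xθ²)+y_x²`, giving the Rayleigh quotient
`N = min (R₁+R₂+R₃−V₄)/ΣS`.  The admissible family is the simply supported
trig ansatz (`u ~ cos λx cos nθ`, `v ~ sin λx sin nθ`, `w ~ sin λx cos nθ`,
`λ = mπ/l`): it satisfies θ-periodicity and the geometric alternatives
`v = w = 0`, `u_x = 0` at both ends, and — as the boundary module verifies —
its conjugate natural conditions as well, so no boundary terms pollute the
projection.  Trig orthogonality makes cross-mode blocks vanish, so a single
harmonic per `(m, n)` is exact within this family and the quotient reduces to
3×3 quadratic forms in the amplitudes `(A, B, C)`.

Assembly is **closed-form**: the energy densities are integrated symbolically
over the cylinder once (sympy, exact `π`-rational arithmetic, with integer
`m, n` assumptions), the Hessians in the amplitudes are lambdified, and
per-mode evaluation is then a cheap numeric call.  No quadrature appears in
the assembly path; quadrature is used only in cross-check tests.  Three
independent routes exist:

- `assemble_mode_matrices` — from the functional densities (`R_i`, `F`, `S`);
- `galerkin_matrices` — substitutes the ansatz into `D₁, D₂, D₃` and projects
  each onto its own basis function, splitting the `N/K` terms into the load
  matrix; this never touches the functional;
- `local_matrices` — hand-coded classical shell entries with the nonlocal
  terms absent at source.

The variational principle guarantees routes one and two agree; the test suite
enforces entrywise agreement to ≤ 1e−12 relative over seeded random parameter
draws across the full `m ≤ 5, n ≤ 8` window, and the η = 0 limit of both
against the third route.  The stiffness matrix is symmetrized as `½(M+Mᵀ)`
(justified by the verified self-adjointness of the operator on admissible
fields); in exact arithmetic the asymmetry is zero and in floating point it is
at rounding level.

Per mode, the buckling load is the **smallest positive eigenvalue** of
`Kq = (N/K)Gq`, solved with the symmetric-definite path (`G` is positive
definite for `λ > 0`; its diagonal is `λ²(1+η²(λ²+n²))·(πl/2)` up to the
`n = 0` norm factor).  Eigenvalues below `1e−12·‖K‖/‖G‖` count as zero.  `K`
is generally **indefinite**: negative eigenvalues correspond to tensile
instabilities outside this model and are excluded.  Consequently the
Courant–Fischer sampling bound (random trial quotients never undercut the
smallest eigenvalue) is only asserted on fixtures whose pencils are fully
positive (the isotropic one); for indefinite pencils a random quotient can
legitimately fall below the smallest *positive* eigenvalue.  Modes with no
positive eigenvalue are recorded as non-buckling; if every searched mode is
non-buckling the result carries an explicit status instead of raising.  Ties
in the critical-mode search break deterministically toward smaller `n`, then
smaller `m`.  For `n = 0` the `v` basis vanishes identically and the system
reduces to the `(A, C)` block, flagged on the result.

Loads are reported both as the dimensionless `N/K` and dimensional `N = K·(N/K)`
in N/m.  With `P_YY = −κw` (proportional model) the Galerkin contribution
`−(κR/K)(1+η²(λ²+n²))` enters the `(w,w)` stiffness entry in *both* assembly
routes — positive `κ` softens the shell under this sign convention.  The
constant pressure model makes the problem inhomogeneous and is rejected for
eigenanalysis with an explicit message; it remains valid for functional
evaluation.

## Boundary conditions

Integrating the first variation by parts leaves edge integrals that group into
five terms `b₁…b₅`; requiring them to vanish yields six natural/geometric
alternative pairs per edge.  The transverse-shear (fifth) alternative has the
most delicate grouping and is isolated in a single function
(`_w_shear_expression`) so any correction is a one-line change.  The v-pair
natural expression includes the twist coupling `c2(3k2+μ1)w_xθ`, which
corresponds to the divergence-equivalent `w_xθ v_x` form of the `Φ` coupling
term (the classical in-plane shear condition); the `w_xx v_θ` form used in the
functional differs from it only by terms multiplying `δv` at the edges, so for
any admissible family enforcing `v = 0` there the two groupings coincide —
the weak-form balance test runs on such fields, where the statement is exact.

Residuals are reported θ-integrated (the weak form, which is what the
variational statement constrains) and pointwise at sampled θ.  The
"satisfied" tolerance is scale-free: `1e−9` relative to the largest magnitude
any single additive term of the expression reaches over the whole shell, so
conditions that hold because every term vanishes at an edge still read as
satisfied for fields of any amplitude.  Periodicity is checked by comparing
`f(x, θ)` against `f(x, θ+2π)` on a sample grid, which also catches
half-integer harmonics whose endpoint values coincide.

The balance check itself exploits that `V` is quadratic: the central
difference `(V(f+z) − V(f−z))/2` equals the exact Gateaux derivative, so
`dV[z] − ∬ D·z` isolates the boundary remainder without truncation error.
Quadrature uses Gauss–Legendre in `x` and the periodic trapezoid rule in `θ`
— machine-precision exact for the trigonometric fields used.

## Synthetic conditions: what they do and do not show

The package generates every input programmatically.  Random *parameter* draws
span `k1 ∈ [0.05, 2]`, `k2 ∈ [0.01, 0.5]`, `c2 ∈ [1e−4, 0.05]`,
`μ1 ∈ [0, 0.45]`, `η ∈ [0, 0.3]`, `l ∈ [5, 40]`, foundation `∈ [0, 0.5]` —
a deliberately wide envelope around physically plausible shells.  The named
fixtures use order-of-magnitude values typical of the microtubule literature
(`E1 = 1 GPa`, `E2 = 4 MPa`, `G = 1 MPa`, `R = 12.7 nm`, `h = 2.7 nm`,
`h0 = 1.6 nm`, `L = 1 μm`, `E_c = 1 kPa`, `ea₀ ∈ [0, 2.5] nm`); they are
illustrative, not measurements, and for them the foundation number
`ςR/K ≈ 1e−5` makes the stiffening trend real but small.  Passing tests
establish the internal mathematics — the variational identity, route
equivalence, limits and monotonicities — for this model class; they say
nothing about whether the continuum shell idealization, the simply supported
family, or any particular parameter set describes a real microtubule, and
multi-term expansions for other end conditions are outside the admissible
family used here.

## Known limitations

- Single-harmonic Ritz per mode; only the simply supported family.  Other edge
  condition sets are *verified* (residual evaluation) but not *solved*.
- Static buckling only: no post-buckling, imperfection sensitivity, vibration
  or viscoelastic time dependence.
- `P_YY` is a user-supplied slot (zero / constant / proportional); computing it
  from cytosol flow is out of scope.
- The constant-pressure model is excluded from eigenanalysis (inhomogeneous).
- Mode ranges are finite; the reported `N_cr` is the minimum over the searched
  window, and enlarging the window can only lower it (a tested invariant).
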