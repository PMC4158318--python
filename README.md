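# mtshell — buckling of microtubules as nonlocal orthotropic shells

Microtubules are the stiffest filaments of the cytoskeleton and carry large
compressive loads because the surrounding elastic filament network braces them
laterally.  `mtshell` models a microtubule as a thin **orthotropic cylindrical
shell** (axial modulus `E1`, circumferential modulus `E2`, shear modulus `G`,
Poisson ratios `μ1, μ2`) with **Eringen nonlocal elasticity** — stress at a
point depends on strain in a neighbourhood through the operator
`L(f) = η²∇²f − f`, `η = e·a₀/R` — embedded in a Winkler-type foundation of
constant `ς = 2.7 E_c` and subject to an axial compressive membrane load `N`.

The package is aimed at researchers in cytoskeletal biomechanics and
nano-structural stability who want a *verified* variational formulation of
this buckling problem rather than a black-box FE run.  It provides:

1. **A symbolic variational engine** (`mtshell.symbolic`): the three governing
   PDEs `L₁(u)+M₁(v,w)=0`, `L₂(v)+M₂(u,w)=0`, `L₃(w)+M₃(u,v)=0` and the
   semi-inverse trial functional `V = V₁(u)+V₂(v)+V₃(w)+∬F dx dθ`, with the
   coupling density

   `F = −(k₂+μ₁)vₓu_θ + μ₁wₓu + c₂wₓₓuₓ + c₂k₂wₓu_θθ − k₁wv_θ + c₂(3k₂+μ₁)wₓₓv_θ`,

   and a higher-order Euler–Lagrange operator that **proves symbolically**
   (with fully symbolic parameters) that `δV/δu, δV/δv, δV/δw` reproduce the
   governing equations, plus a seeded numeric shadow check.
2. **A Rayleigh–Ritz buckling solver** (`mtshell.ritz`): on the simply
   supported ansatz `u = A cos λx cos nθ`, `v = B sin λx sin nθ`,
   `w = C sin λx cos nθ` (`λ = mπ/l`), the Rayleigh quotient

   `N = min (R₁+R₂+R₃−V₄)/(S(u)+S(v)+S(w))`

   becomes a 3×3 symmetric generalized eigenproblem `Kq = (N/K)Gq` per mode;
   the critical load is the minimum of the smallest positive eigenvalues over
   the searched `(m, n)` window.  An independent **Galerkin-on-PDE oracle**
   and a hand-coded **local (η = 0) assembly** cross-check every matrix.
3. **Boundary-condition machinery** (`mtshell.boundary`): the six conjugate
   natural/geometric pairs at each shell end, their weak-form residuals, the
   balance of the first-variation boundary terms, and θ-periodicity checks.
   With `η > 0` the natural conditions depend on the load `N` — the boundary
   conditions are coupled by the nonlocal formulation.

## Worked example

```python
from mtshell import critical_load, fixture

cfg = fixture("microtubule")          # illustrative parameters, not measured data
result = critical_load(cfg.groups(), cfg.m_range, cfg.n_range)
print(result.N_cr, result.N_cr_dimless, result.mode)
```

Running `python examples/04_small_scale_and_foundation_sweeps.py` prints

```
small-scale softening: N_cr vs eta
  eta = 0.00:  N_cr =   2.1015 N/m  (mode m=1, n=6)
  eta = 0.05:  N_cr =   1.9280 N/m  (mode m=1, n=6)
  eta = 0.10:  N_cr =   1.5452 N/m  (mode m=1, n=6)
  eta = 0.20:  N_cr =   0.8612 N/m  (mode m=1, n=6)
```

`N_cr` is the critical axial compressive membrane force per unit circumference
(N/m) of a 1 μm microtubule; the load falls monotonically with the small-scale
parameter because the nonlocal terms magnify the geometric (load-path) energy
`S` but not the elastic resistance — small-scale effects lower the buckling
load.  The `examples/` directory has one short script per capability
(dimensionless groups and nonlocal constitutive attenuation, symbolic
verification, the critical-load search, parameter sweeps, boundary
conditions).

A thin CLI wraps the same library calls:

```bash
mtshell verify --fixture microtubule           # Euler–Lagrange verification
mtshell buckle --fixture microtubule --csv modes.csv --json summary.json
mtshell sweep  --fixture microtubule --axis eta --values 0,0.05,0.1,0.2
mtshell fixtures --show microtubule
```

Configurations are YAML with unit annotations (`E1: 1 GPa`, `R: 12.7 nm`),
converted to SI at parse time.

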