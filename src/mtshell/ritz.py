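"""Rayleigh-Ritz buckling solver for the nonlocal orthotropic shell.

The buckling load is the minimum of the Rayleigh quotient

    N = min_(u,v,w)  [R1(u) + R2(v) + R3(w) - V4(u,v,w)] / [S(u) + S(v) + S(w)]

over admissible displacement fields.  With the simply supported single-harmonic
ansatz

    u = A cos(λx) cos(nθ),  v = B sin(λx) sin(nθ),  w = C sin(λx) cos(nθ),
    λ = mπ/l,

the quotient becomes a ratio of 3x3 quadratic forms in the amplitudes
q = (A, B, C), and the per-mode buckling load is the smallest positive
eigenvalue of the symmetric generalized eigenproblem K q = (N/K) G q.  The
critical load is the minimum over the searched (m, n) modes.

Three independent assembly routes are provided:

- ``assemble_mode_matrices`` integrates the energy densities of the variational
  functional in closed form (trig orthogonality, exact sympy integration,
  evaluated through cached lambdified entries);
- ``galerkin_matrices`` projects the governing PDE operators onto the same
  ansatz — an oracle that never touches the functional;
- ``local_matrices`` is a hand-coded assembly of the classical (local) shell
  with every nonlocal term deleted at source, for the η → 0 cross-check.

The variational principle guarantees the first two agree entrywise; that
agreement is the solver's core correctness test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import sympy as sp

from .parameters import DimensionlessGroups
from . import symbolic as sy
from .symbolic import x, theta

__all__ = [
    "TrialMode",
    "RitzMatrices",
    "BucklingResult",
    "assemble_mode_matrices",
    "galerkin_matrices",
    "local_matrices",
    "rayleigh_quotient",
    "solve_mode",
    "critical_load",
]

#: Relative threshold below which a generalized eigenvalue counts as zero.
POSITIVE_EIG_RTOL = 1e-12


@dataclass(frozen=True)
class TrialMode:
    """One simply supported trial harmonic: m axial half-waves, n circumferential waves."""

    m: int
    n: int

    def __post_init__(self) -> None:
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError(f"m must be an integer >= 1, got {self.m!r}")
        if self.n < 0 or int(self.n) != self.n:
            raise ValueError(f"n must be an integer >= 0, got {self.n!r}")

    def lam(self, l: float) -> float:
        """Dimensionless axial wavenumber λ = mπ/l."""
        return self.m * math.pi / l


@dataclass
class RitzMatrices:
    """Per-mode stiffness-like (K) and geometric/load (G) quadratic forms.

    Both are 3x3 Hessians in the amplitudes (A, B, C); the eigenvalues of
    K q = μ G q are the dimensionless loads N/K.  For n = 0 the v-basis
    vanishes identically and the system reduces to the (A, C) block; ``active``
    lists the live amplitude indices and ``reduced`` flags the reduction.
    """

    Kmat: np.ndarray
    Gmat: np.ndarray
    mode: TrialMode
    active: tuple[int, ...]
    reduced: bool

    @property
    def K_active(self) -> np.ndarray:
        idx = np.ix_(self.active, self.active)
        return self.Kmat[idx]

    @property
    def G_active(self) -> np.ndarray:
        idx = np.ix_(self.active, self.active)
        return self.Gmat[idx]


def _ansatz(amps, nval):
    """Simply supported single-harmonic fields with symbolic l and m."""
    A, B, C = amps
    m = sp.Symbol("m", positive=True, integer=True)
    l = sp.Symbol("l", positive=True)
    lam = m * sp.pi / l
    u = A * sp.cos(lam * x) * sp.cos(nval * theta)
    v = B * sp.sin(lam * x) * sp.sin(nval * theta)
    w = C * sp.sin(lam * x) * sp.cos(nval * theta)
    return sy.DisplacementField(u, v, w), m, l


def _integrate_cylinder(expr: sp.Expr, l: sp.Symbol) -> sp.Expr:
    out = sp.integrate(sp.expand(expr), (theta, 0, 2 * sp.pi))
    out = sp.integrate(sp.expand(out), (x, 0, l))
    return sp.simplify(out)


def _hessian(Q: sp.Expr, amps) -> sp.Matrix:
    return sp.Matrix(
        [[sp.diff(Q, ai, aj) for aj in amps] for ai in amps]
    )


@lru_cache(maxsize=None)
def _ritz_builder(n_is_zero: bool):
    """Closed-form Ritz matrices from the energy densities, lambdified once.

    Returns a callable (k1, k2, c2, mu1, eta, found, m, n, l) -> (K, G); the
    ``n`` argument is ignored in the n = 0 branch.
    """
    amps = sp.symbols("A B C")
    g = sy.symbolic_groups()
    n = sp.S.Zero if n_is_zero else sp.Symbol("n", positive=True, integer=True)
    f, m, l = _ansatz(amps, n)
    numerator = (
        sy.density_R1(f.u, g)
        + sy.density_R2(f.v, g)
        + sy.density_R3(f.w, g)
        - sy.density_F(f, g)
    )
    denominator = sy.density_S(f.u, g) + sy.density_S(f.v, g) + sy.density_S(f.w, g)
    QK = _integrate_cylinder(numerator, l)
    QG = _integrate_cylinder(denominator, l)
    K = _hessian(QK, amps)
    G = _hessian(QG, amps)
    args = (g.k1, g.k2, g.c2, g.mu1, g.eta, g.foundation, m, *(() if n_is_zero else (n,)), l)
    fK = sp.lambdify(args, K, modules="numpy")
    fG = sp.lambdify(args, G, modules="numpy")

    def build(k1, k2, c2, mu1, eta, found, mm, nn, ll):
        a = (k1, k2, c2, mu1, eta, found, mm) + (() if n_is_zero else (nn,)) + (ll,)
        return np.asarray(fK(*a), dtype=float), np.asarray(fG(*a), dtype=float)

    return build


@lru_cache(maxsize=None)
def _galerkin_builder(n_is_zero: bool):
    """PDE-projection (Galerkin) matrices, lambdified once.

    Substitutes the ansatz into the governing expressions D1, D2, D3, projects
    each onto its own basis function, and splits off the terms multiplying the
    load ratio N/K into the geometric matrix.  The proportional radial-pressure
    model P_YY = -κ w is included here through its governing-equation slot
    (R/K) L(P_YY); ``press`` is the pressure number κR/K.
    """
    amps = sp.symbols("A B C")
    g = sy.symbolic_groups()
    NK = sp.Symbol("N_K", real=True)
    press = sp.Symbol("press", nonnegative=True)
    n = sp.S.Zero if n_is_zero else sp.Symbol("n", positive=True, integer=True)
    f, m, l = _ansatz(amps, n)
    lam = m * sp.pi / l
    basis = (
        sp.cos(lam * x) * sp.cos(n * theta),
        sp.sin(lam * x) * sp.sin(n * theta),
        sp.sin(lam * x) * sp.cos(n * theta),
    )
    D = sy.governing_residuals(f, g, NK, pressure=-press * f.w)
    Krows, Grows = [], []
    for D_i, phi_i in zip(D, basis):
        proj = _integrate_cylinder(D_i.doit() * phi_i, l)
        proj0 = proj.subs(NK, 0)
        projN = sp.diff(proj, NK)
        Krows.append([-sp.diff(proj0, a) for a in amps])
        Grows.append([sp.diff(projN, a) for a in amps])
    K = sp.simplify(sp.Matrix(Krows))
    G = sp.simplify(sp.Matrix(Grows))
    args = (
        g.k1, g.k2, g.c2, g.mu1, g.eta, g.foundation, press,
        m, *(() if n_is_zero else (n,)), l,
    )
    fK = sp.lambdify(args, K, modules="numpy")
    fG = sp.lambdify(args, G, modules="numpy")

    def build(k1, k2, c2, mu1, eta, found, pp, mm, nn, ll):
        a = (k1, k2, c2, mu1, eta, found, pp, mm) + (() if n_is_zero else (nn,)) + (ll,)
        return np.asarray(fK(*a), dtype=float), np.asarray(fG(*a), dtype=float)

    return build


def _norm_factor(l: float, n: int) -> float:
    """∫∫ of a squared basis harmonic: (l/2)·π for n >= 1, (l/2)·2π for n = 0."""
    return 0.5 * l * (2.0 * math.pi if n == 0 else math.pi)


def _pressure_stiffness(groups: DimensionlessGroups, lam: float, n: int) -> float:
    """Galerkin contribution of P_YY = -κ w to the (w, w) stiffness entry.

    The governing slot (R/K) L(P_YY) = -(κR/K) L(w) projects, for the single
    harmonic, onto -(κR/K)(1 + η²(λ²+n²)) per unit basis norm; with the
    stiffness sign convention this *reduces* K33 by press·(1+η²Λ)·norm.
    """
    if groups.pressure_kind != "proportional" or groups.pressure_coeff == 0.0:
        return 0.0
    lam2n2 = lam**2 + n**2
    return -groups.pressure_coeff * (1.0 + groups.eta**2 * lam2n2) * _norm_factor(
        groups.l, n
    )


def _check_pressure(groups: DimensionlessGroups) -> None:
    if groups.pressure_kind == "constant":
        raise ValueError(
            "constant radial pressure makes the buckling problem inhomogeneous; "
            "it is accepted for functional evaluation only, not for eigenanalysis"
        )


def _wrap(K: np.ndarray, G: np.ndarray, mode: TrialMode) -> RitzMatrices:
    reduced = mode.n == 0
    active = (0, 2) if reduced else (0, 1, 2)
    if reduced:
        # v-basis sin(0·θ) vanishes identically: zero its row/column outright.
        K = K.copy()
        G = G.copy()
        K[1, :] = K[:, 1] = 0.0
        G[1, :] = G[:, 1] = 0.0
    return RitzMatrices(Kmat=K, Gmat=G, mode=mode, active=active, reduced=reduced)


def assemble_mode_matrices(
    groups: DimensionlessGroups, mode: TrialMode
) -> RitzMatrices:
    """Assemble the Ritz quadratic forms of one mode from the functional.

    The stiffness form is R1 + R2 + R3 - V4 restricted to the amplitudes, the
    geometric form is K·(S(u) + S(v) + S(w)); both integrals are evaluated in
    closed form via trig orthogonality.  The stiffness matrix is symmetrized
    (½(M + Mᵀ)), justified by the self-adjointness of the functional; the
    proportional pressure model joins through its Galerkin term.
    """
    _check_pressure(groups)
    build = _ritz_builder(mode.n == 0)
    K, G = build(
        groups.k1, groups.k2, groups.c2, groups.mu1, groups.eta,
        groups.foundation, mode.m, mode.n, groups.l,
    )
    K = 0.5 * (K + K.T)
    K[2, 2] += _pressure_stiffness(groups, mode.lam(groups.l), mode.n)
    return _wrap(K, G, mode)


def galerkin_matrices(
    groups: DimensionlessGroups, mode: TrialMode, symmetrize: bool = True
) -> RitzMatrices:
    """Independent Galerkin-on-PDE oracle for the same mode.

    Projects the governing operators onto the ansatz without ever touching the
    variational functional; by the verified variational principle the
    (symmetrized) result must equal :func:`assemble_mode_matrices` entrywise.
    """
    _check_pressure(groups)
    build = _galerkin_builder(mode.n == 0)
    K, G = build(
        groups.k1, groups.k2, groups.c2, groups.mu1, groups.eta,
        groups.foundation, groups.pressure_coeff, mode.m, mode.n, groups.l,
    )
    if symmetrize:
        K = 0.5 * (K + K.T)
        G = 0.5 * (G + G.T)
    return _wrap(K, G, mode)


def local_matrices(groups: DimensionlessGroups, mode: TrialMode) -> RitzMatrices:
    """Hand-coded classical (local elasticity) assembly: no nonlocal terms.

    Every small-scale term is absent from these formulas at source — this is a
    third, independent code path used to pin the η → 0 limit of the other two.
    """
    _check_pressure(groups)
    k1, k2, c2, mu1 = groups.k1, groups.k2, groups.c2, groups.mu1
    lam, n = mode.lam(groups.l), mode.n
    norm = _norm_factor(groups.l, n)
    K = np.zeros((3, 3))
    K[0, 0] = k2 * (1 + c2) * n**2 + lam**2
    K[0, 1] = K[1, 0] = -(k2 + mu1) * lam * n
    K[0, 2] = K[2, 0] = -lam * (mu1 + c2 * lam**2 - c2 * k2 * n**2)
    K[1, 1] = k2 * (1 + 3 * c2) * lam**2 + k1 * n**2
    K[1, 2] = K[2, 1] = n * (k1 + c2 * (3 * k2 + mu1) * lam**2)
    K[2, 2] = (
        (1 + c2 * k1)
        - 2 * c2 * k1 * n**2
        + c2 * (lam**4 + k1 * n**4 + (4 * k2 + 2 * mu1) * lam**2 * n**2)
        + groups.foundation
    )
    if groups.pressure_kind == "proportional":
        K[2, 2] -= groups.pressure_coeff
    K *= norm
    G = norm * np.diag([lam**2, lam**2, lam**2])
    return _wrap(K, G, mode)


def rayleigh_quotient(q: Sequence[float], matrices: RitzMatrices) -> float:
    """Rayleigh quotient (qᵀ K q)/(qᵀ G q) of a trial amplitude vector.

    Homogeneous of degree zero in q and stationary exactly at the eigenvectors
    of the pencil; any trial vector therefore bounds the smallest eigenvalue
    from above.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (len(matrices.active),):
        raise ValueError(
            f"expected amplitude vector of length {len(matrices.active)}, "
            f"got shape {q.shape}"
        )
    if not np.any(q):
        raise ValueError("amplitude vector must be nonzero")
    denom = float(q @ matrices.G_active @ q)
    if denom <= 0.0:
        raise ValueError("trial function carries no geometric energy")
    return float(q @ matrices.K_active @ q) / denom


def solve_mode(matrices: RitzMatrices) -> tuple[float | None, np.ndarray | None]:
    """Smallest positive eigenvalue (N/K) of K q = μ G q and its eigenvector.

    Returns (None, None) when the mode admits no positive eigenvalue (a
    non-buckling mode).  G is positive definite for λ > 0 so the symmetric-
    definite solver applies and all eigenpairs are real.
    """
    Ka, Ga = matrices.K_active, matrices.G_active
    if not np.all(np.isfinite(Ka)) or not np.all(np.isfinite(Ga)):
        raise ValueError("non-finite matrix entries")
    if np.linalg.norm(Ga) == 0.0:
        raise ValueError("no load path for this mode")
    vals, vecs = scipy.linalg.eigh(Ka, Ga)
    tol = POSITIVE_EIG_RTOL * np.linalg.norm(Ka, 2) / max(np.linalg.norm(Ga, 2), 1e-300)
    pos = np.where(vals > tol)[0]
    if pos.size == 0:
        return None, None
    i = pos[0]
    vec = vecs[:, i]
    vec = vec / np.linalg.norm(vec)
    return float(vals[i]), vec


@dataclass
class BucklingResult:
    """Mode table and critical load of a buckling search.

    ``table`` has one row per searched mode with the dimensionless (N/K) and
    dimensional (N/m) loads; non-buckling modes carry NaN.  ``N_cr`` is the
    minimum dimensional load, attained at ``mode`` with unit amplitude vector
    ``eigenvector`` (padded over the active amplitudes).  Ties are broken
    toward smaller n, then smaller m.
    """

    table: pd.DataFrame
    N_cr: float | None
    N_cr_dimless: float | None
    mode: TrialMode | None
    eigenvector: np.ndarray | None
    m_range: tuple[int, ...]
    n_range: tuple[int, ...]
    eta: float
    K: float
    route: str = "ritz"

    @property
    def status(self) -> str:
        return "ok" if self.N_cr is not None else "no_buckling"

    def summary_dict(self) -> dict:
        return {
            "status": self.status,
            "N_cr": self.N_cr,
            "N_cr_dimless": self.N_cr_dimless,
            "critical_mode": None if self.mode is None else {"m": self.mode.m, "n": self.mode.n},
            "eigenvector": None if self.eigenvector is None else [float(a) for a in self.eigenvector],
            "m_range": list(self.m_range),
            "n_range": list(self.n_range),
            "eta": self.eta,
            "K": self.K,
            "route": self.route,
        }


_ROUTES = {
    "ritz": assemble_mode_matrices,
    "galerkin": galerkin_matrices,
    "local": local_matrices,
}


def critical_load(
    groups: DimensionlessGroups,
    m_range: Iterable[int] = range(1, 6),
    n_range: Iterable[int] = range(0, 9),
    route: str = "ritz",
) -> BucklingResult:
    """Search (m, n) modes for the critical buckling load N_cr = min N(m, n).

    Modes with no positive eigenvalue are recorded as non-buckling and excluded
    from the minimum; if every searched mode is non-buckling the result carries
    status ``"no_buckling"`` rather than raising.
    """
    m_range = tuple(sorted(set(int(m) for m in m_range)))
    n_range = tuple(sorted(set(int(n) for n in n_range)))
    if not m_range or not n_range:
        raise ValueError("mode search ranges must be nonempty")
    assemble = _ROUTES[route]
    rows = []
    best: tuple[float, TrialMode, np.ndarray] | None = None
    for n in n_range:
        for m in m_range:
            mode = TrialMode(m, n)
            mats = assemble(groups, mode)
            val, vec = solve_mode(mats)
            rows.append(
                {
                    "m": m,
                    "n": n,
                    "lambda": mode.lam(groups.l),
                    "N_dimless": np.nan if val is None else val,
                    "N_dimensional": np.nan if val is None else val * groups.K,
                    "is_critical": False,
                }
            )
            if val is not None and (best is None or val < best[0]):
                full = np.zeros(3)
                full[list(mats.active)] = vec
                best = (val, mode, full)
    table = pd.DataFrame(rows)
    if best is None:
        return BucklingResult(
            table=table, N_cr=None, N_cr_dimless=None, mode=None, eigenvector=None,
            m_range=m_range, n_range=n_range, eta=groups.eta, K=groups.K, route=route,
        )
    val, mode, vec = best
    table.loc[(table["m"] == mode.m) & (table["n"] == mode.n), "is_critical"] = True
    return BucklingResult(
        table=table,
        N_cr=val * groups.K,
        N_cr_dimless=val,
        mode=mode,
        eigenvector=vec,
        m_range=m_range,
        n_range=n_range,
        eta=groups.eta,
        K=groups.K,
        route=route,
    )
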