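"""Physical parameters and dimensionless groups for the nonlocal orthotropic shell model.

A microtubule is modeled as a thin orthotropic cylindrical shell (length L,
mid-surface radius R, wall thickness h, effective bending thickness h0) embedded
in an elastic filament network and subject to an axial compressive load N.  The
constitutive law is Eringen's nonlocal elasticity: the stress at a point depends
on the strain in a neighbourhood through the operator (1 - (ea0/R)^2 ∇²) acting
on the stress field, with ea0 the small-scale (nonlocal) length.

Everything downstream of this module consumes only the dimensionless groups

    k1 = E2/E1                      circumferential-to-axial modulus ratio
    k2 = G (1 - mu1 mu2) / E1       shear number
    c2 = h0^3 / (12 R^2 h)          bending number
    K  = E1 h / (1 - mu1 mu2)       membrane stiffness (N/m)
    eta = ea0 / R                   small-scale parameter
    l  = L / R                      dimensionless length

plus the Poisson ratio mu1 (which enters the coupling terms), the foundation
number ς R / K (ς = 2.7 Ec is the filament-network constraint) and, for the
proportional radial-pressure model, the pressure number κ R / K.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "ShellGeometry",
    "OrthotropicMaterial",
    "PressureModel",
    "Environment",
    "DimensionlessGroups",
    "HarmonicStrainState",
    "HarmonicStressState",
    "derive_groups",
    "attenuation_factor",
    "local_harmonic_stress",
    "nonlocal_harmonic_stress",
    "FOUNDATION_FACTOR",
]

#: ς = 2.7 Ec — elastic constraint of the surrounding filament network.
FOUNDATION_FACTOR = 2.7


class ValidationError(ValueError):
    """A physical parameter violates its invariant."""


class DomainError(ValidationError):
    """Parameters are individually valid but jointly non-physical."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0.0) or not math.isfinite(value):
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ShellGeometry:
    """Cylindrical shell geometry in SI units (meters).

    Parameters
    ----------
    L : float
        Shell length.
    R : float
        Mid-surface radius.
    h : float
        Wall thickness (membrane).
    h0 : float
        Effective thickness for bending; may differ from ``h`` because the
        microtubule wall is not a homogeneous continuum.
    """

    L: float
    R: float
    h: float
    h0: float

    def __post_init__(self) -> None:
        for name in ("L", "R", "h", "h0"):
            _require_positive(name, getattr(self, name))
        if not self.h < self.R:
            raise ValidationError(
                f"wall thickness h={self.h} must be smaller than radius R={self.R}"
            )
        if self.h0 > self.R:
            warnings.warn(
                f"effective bending thickness h0={self.h0} exceeds radius R={self.R}; "
                "thin-shell assumptions are questionable",
                stacklevel=2,
            )


@dataclass(frozen=True)
class OrthotropicMaterial:
    """Orthotropic elastic constants (Pa, except the Poisson ratios).

    ``E1`` acts along the shell axis, ``E2`` along the circumference, ``G`` is
    the in-plane shear modulus; ``mu1``/``mu2`` are the Poisson ratios along the
    circumferential and axial directions.  Thermodynamic symmetry of the
    stiffness matrix requires mu1 E2 = mu2 E1 · (E2/E1) ordering; we only warn
    when mu1/mu2 is far from E2/E1 since published microtubule parameter sets
    do not always enforce reciprocity.
    """

    E1: float
    E2: float
    G: float
    mu1: float
    mu2: float

    def __post_init__(self) -> None:
        for name in ("E1", "E2", "G"):
            _require_positive(name, getattr(self, name))
        for name in ("mu1", "mu2"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValidationError(f"{name} must lie in [0, 1), got {v!r}")
        if self.mu1 * self.mu2 >= 1.0:
            raise DomainError(
                "non-physical Poisson product: mu1*mu2 = "
                f"{self.mu1 * self.mu2} >= 1"
            )


@dataclass(frozen=True)
class PressureModel:
    """Radial cytosol pressure P_YY entering the radial equilibrium equation.

    ``kind`` is one of:

    - ``"zero"`` — no radial pressure (static buckling eigenproblem; default),
    - ``"constant"`` — prescribed uniform pressure ``value`` (Pa); makes the
      problem inhomogeneous, accepted for functional evaluation only,
    - ``"proportional"`` — restoring pressure P_YY = -kappa * w with ``kappa``
      in Pa per unit radial displacement; enters the eigenproblem.
    """

    kind: str = "zero"
    value: float = 0.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "constant", "proportional"):
            raise ValidationError(
                f"unsupported pressure model {self.kind!r}; "
                "expected 'zero', 'constant' or 'proportional'"
            )

    @classmethod
    def zero(cls) -> "PressureModel":
        return cls("zero")

    @classmethod
    def constant(cls, value: float) -> "PressureModel":
        return cls("constant", value=value)

    @classmethod
    def proportional(cls, kappa: float) -> "PressureModel":
        return cls("proportional", kappa=kappa)


@dataclass(frozen=True)
class Environment:
    """Surrounding medium: elastic filament network, nonlocal scale, cytosol.

    ``sigma`` is the foundation constant ς (Pa).  When left ``None`` it is
    resolved to 2.7 · Ec, the filament-network constraint; an explicit value
    overrides Ec.
    """

    Ec: float = 0.0
    sigma: float | None = None
    ea0: float = 0.0
    pressure: PressureModel = field(default_factory=PressureModel.zero)

    def __post_init__(self) -> None:
        if self.Ec < 0.0:
            raise ValidationError(f"Ec must be >= 0, got {self.Ec!r}")
        if self.sigma is not None and self.sigma < 0.0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma!r}")
        if self.ea0 < 0.0:
            raise ValidationError(f"ea0 must be >= 0, got {self.ea0!r}")

    def resolved_sigma(self) -> float:
        """Foundation constant ς: explicit value if set, else 2.7 · Ec."""
        if self.sigma is not None:
            return self.sigma
        return FOUNDATION_FACTOR * self.Ec


@dataclass(frozen=True)
class DimensionlessGroups:
    """The dimensionless numbers consumed by the operators and functionals.

    ``foundation`` is ς R / K and ``pressure_coeff`` is κ R / K for the
    proportional pressure model (0 otherwise); both are needed because the
    foundation and pressure terms in the radial equation are written per unit
    membrane stiffness K.
    """

    k1: float
    k2: float
    c2: float
    K: float
    eta: float
    l: float
    mu1: float
    foundation: float = 0.0
    pressure_coeff: float = 0.0
    pressure_kind: str = "zero"

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "c2", "K", "l"):
            _require_positive(name, getattr(self, name))
        if self.eta < 0.0:
            raise ValidationError(f"eta must be >= 0, got {self.eta!r}")
        if self.foundation < 0.0:
            raise ValidationError(f"foundation must be >= 0, got {self.foundation!r}")

    def local(self) -> "DimensionlessGroups":
        """The same shell in classical (local) elasticity: eta = 0."""
        return replace(self, eta=0.0)


def derive_groups(
    geometry: ShellGeometry,
    material: OrthotropicMaterial,
    env: Environment | None = None,
) -> DimensionlessGroups:
    """Compute the dimensionless groups for one shell problem.

    k1 = E2/E1, k2 = G(1-mu1 mu2)/E1, c2 = h0^3/(12 R^2 h), K = E1 h/(1-mu1 mu2),
    eta = ea0/R, l = L/R.  The foundation number ς R/K uses ς = 2.7 Ec unless an
    explicit ς was supplied in ``env``.
    """
    env = env if env is not None else Environment()
    one_minus = 1.0 - material.mu1 * material.mu2
    if one_minus <= 0.0:
        raise DomainError("non-physical Poisson product")
    K = material.E1 * geometry.h / one_minus
    groups = DimensionlessGroups(
        k1=material.E2 / material.E1,
        k2=material.G * one_minus / material.E1,
        c2=geometry.h0**3 / (12.0 * geometry.R**2 * geometry.h),
        K=K,
        eta=env.ea0 / geometry.R,
        l=geometry.L / geometry.R,
        mu1=material.mu1,
        foundation=env.resolved_sigma() * geometry.R / K,
        pressure_coeff=(
            env.pressure.kappa * geometry.R / K
            if env.pressure.kind == "proportional"
            else 0.0
        ),
        pressure_kind=env.pressure.kind,
    )
    return groups


# ---------------------------------------------------------------------------
# Nonlocal constitutive map for single Fourier harmonics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicStrainState:
    """Strain amplitudes of a single harmonic ∝ cos(λx)cos(nθ).

    ``lam`` is the dimensionless axial wavenumber (per unit x = X/R), ``n`` the
    integer circumferential wavenumber.
    """

    eps_x: float
    eps_theta: float
    eps_xtheta: float
    lam: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 0 or int(self.n) != self.n:
            raise ValidationError(f"n must be a nonnegative integer, got {self.n!r}")


@dataclass(frozen=True)
class HarmonicStressState:
    """Stress amplitudes (Pa) conjugate to :class:`HarmonicStrainState`."""

    sigma_x: float
    sigma_theta: float
    tau_xtheta: float
    lam: float
    n: int


def attenuation_factor(eta: float, lam: float, n: float) -> float:
    """Nonlocal attenuation 1 / (1 + eta^2 (lam^2 + n^2)) of a harmonic.

    For a field ∝ cos(λx)cos(nθ) the Laplacian multiplies by -(λ²+n²), so the
    nonlocal relation (1 - η²∇²)σ = σ_local becomes the scalar division above.
    Equals 1 iff η(λ²+n²) = 0 and is < 1 otherwise.
    """
    return 1.0 / (1.0 + eta**2 * (lam**2 + n**2))


def local_harmonic_stress(
    strain: HarmonicStrainState, material: OrthotropicMaterial
) -> HarmonicStressState:
    """Classical orthotropic Hooke's law (plane stress, shell form)."""
    d = 1.0 - material.mu1 * material.mu2
    sx = (material.E1 * strain.eps_x + material.E2 * material.mu2 * strain.eps_theta) / d
    st = (material.E2 * strain.eps_theta + material.E1 * material.mu1 * strain.eps_x) / d
    tx = material.G * strain.eps_xtheta
    return HarmonicStressState(sx, st, tx, strain.lam, strain.n)


def nonlocal_harmonic_stress(
    strain: HarmonicStrainState,
    groups: DimensionlessGroups,
    material: OrthotropicMaterial,
) -> HarmonicStressState:
    """Nonlocal stress of a single harmonic: Hooke's law times the attenuation.

    Reduces to the local law when eta = 0 or for a uniform strain (λ = n = 0).
    """
    local = local_harmonic_stress(strain, material)
    a = attenuation_factor(groups.eta, strain.lam, strain.n)
    return HarmonicStressState(
        a * local.sigma_x,
        a * local.sigma_theta,
        a * local.tau_xtheta,
        strain.lam,
        strain.n,
    )
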