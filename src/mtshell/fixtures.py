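"""Named illustrative parameter sets.

These fixtures are illustrative defaults assembled from values typical of the
orthotropic-shell microtubule literature (axial modulus ~GPa, circumferential
modulus ~MPa, radius ~13 nm, wall ~2.7 nm, effective bending thickness
~1.6 nm, cytoplasm modulus ~kPa).  They are NOT measurements tied to any single
study and exist to exercise the solver across local/nonlocal, isotropic/
orthotropic and free/embedded regimes; treat the numbers as order-of-magnitude
placeholders to be replaced by problem-specific data.
"""

from __future__ import annotations

from dataclasses import replace

from .config import RunConfig
from .parameters import Environment, OrthotropicMaterial, PressureModel, ShellGeometry

__all__ = ["FIXTURES", "fixture", "list_fixtures"]


def _microtubule() -> RunConfig:
    """Orthotropic microtubule in cytoplasm, nonlocal scale ea0 = 1 nm."""
    return RunConfig(
        geometry=ShellGeometry(L=1.0e-6, R=12.7e-9, h=2.7e-9, h0=1.6e-9),
        material=OrthotropicMaterial(E1=1.0e9, E2=4.0e6, G=1.0e6, mu1=0.3, mu2=0.0012),
        environment=Environment(Ec=1.0e3, ea0=1.0e-9),
    )


def _microtubule_local() -> RunConfig:
    """Same microtubule in classical (local) elasticity: ea0 = 0."""
    base = _microtubule()
    return replace(base, environment=replace(base.environment, ea0=0.0))


def _microtubule_free() -> RunConfig:
    """Microtubule without the surrounding filament network (Ec = 0)."""
    base = _microtubule()
    return replace(base, environment=Environment(Ec=0.0, ea0=1.0e-9))


def _isotropic() -> RunConfig:
    """Isotropic shell, no surroundings, local elasticity; a textbook baseline."""
    E, nu = 1.0e9, 0.3
    return RunConfig(
        geometry=ShellGeometry(L=2.0e-7, R=1.0e-8, h=1.0e-9, h0=1.0e-9),
        material=OrthotropicMaterial(E1=E, E2=E, G=E / (2 * (1 + nu)), mu1=nu, mu2=nu),
        environment=Environment(),
    )


def _isotropic_nonlocal() -> RunConfig:
    """Isotropic shell with a substantial small-scale parameter (eta = 0.1)."""
    base = _isotropic()
    return replace(base, environment=Environment(ea0=0.1 * base.geometry.R))


def _orthotropic_foundation() -> RunConfig:
    """Strongly embedded orthotropic shell (stiff filament network)."""
    base = _microtubule()
    return replace(base, environment=Environment(Ec=1.0e5, ea0=1.0e-9))


def _proportional_pressure() -> RunConfig:
    """Microtubule with a displacement-proportional cytosol pressure term."""
    base = _microtubule()
    return replace(
        base,
        environment=replace(
            base.environment, pressure=PressureModel.proportional(5.0e4)
        ),
    )


FIXTURES = {
    "microtubule": _microtubule,
    "microtubule_local": _microtubule_local,
    "microtubule_free": _microtubule_free,
    "isotropic": _isotropic,
    "isotropic_nonlocal": _isotropic_nonlocal,
    "orthotropic_foundation": _orthotropic_foundation,
    "proportional_pressure": _proportional_pressure,
}


def fixture(name: str) -> RunConfig:
    """Return a fresh copy of a named fixture configuration."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder()


def list_fixtures() -> list[str]:
    return sorted(FIXTURES)
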