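"""Symbolic variational engine: operators, densities, Euler-Lagrange identity."""

import numpy as np
import pytest
import sympy as sp

from helpers import random_groups, ss_field

from mtshell import symbolic as sy
from mtshell.symbolic import (
    DisplacementField,
    UnsupportedOrderError,
    apply_nonlocal_L,
    build_functional_density,
    functional_chain_residuals,
    integrate_cylinder_numeric,
    functional_value,
    governing_residuals,
    symbolic_groups,
    variational_derivative,
    verify_euler_lagrange,
    x,
    theta,
)


class TestNonlocalOperator:
    def test_constant_maps_to_negative(self):
        c = sp.Symbol("c")
        assert apply_nonlocal_L(c, sp.Symbol("eta")) == -c

    def test_local_limit_is_negation(self):
        f = sp.Function("f")(x, theta)
        assert sp.simplify(apply_nonlocal_L(f, 0)) == -f

    def test_harmonic_eigenfunction(self):
        lam, n, eta = sp.symbols("lambda n eta", positive=True)
        f = sp.cos(lam * x) * sp.cos(n * theta)
        out = apply_nonlocal_L(f, eta)
        expected = -(1 + eta**2 * (lam**2 + n**2)) * f
        assert sp.simplify(out - expected) == 0


class TestVariationalDerivative:
    def test_first_order_textbook_term(self):
        a = sp.Symbol("a")
        y = sp.Function("y")(x, theta)
        dens = a * sp.Derivative(y, x) ** 2 / 2
        assert sp.simplify(variational_derivative(dens, y) + a * sp.diff(y, x, 2)) == 0

    def test_fourth_order_beam_term(self):
        a = sp.Symbol("a")
        y = sp.Function("y")(x, theta)
        dens = a * sp.Derivative(y, x, 2) ** 2 / 2
        assert sp.simplify(variational_derivative(dens, y) - a * sp.diff(y, x, 4)) == 0

    def test_mixed_derivative_sign(self):
        # density a y_xθ²/2 -> +a y_xxθθ (even total order: positive sign)
        a = sp.Symbol("a")
        y = sp.Function("y")(x, theta)
        dens = a * sp.Derivative(y, x, theta) ** 2 / 2
        assert (
            sp.simplify(variational_derivative(dens, y) - a * sp.diff(y, x, 2, theta, 2))
            == 0
        )

    def test_linearity_in_density(self, rng):
        y = sp.Function("y")(x, theta)
        a, b = 1.7, -0.4
        d1 = sp.Derivative(y, x) ** 2 + y * sp.Derivative(y, theta, 2)
        d2 = sp.Derivative(y, x, 2) ** 2 + sp.cos(theta) * y
        lhs = variational_derivative(a * d1 + b * d2, y)
        rhs = a * variational_derivative(d1, y) + b * variational_derivative(d2, y)
        assert sp.expand(lhs - rhs) == 0

    def test_order_beyond_template_raises(self):
        y = sp.Function("y")(x, theta)
        dens = sp.Derivative(y, (x, 9)) ** 2
        with pytest.raises(UnsupportedOrderError):
            variational_derivative(dens, y, max_order=8)


class TestGoverningResiduals:
    def test_zero_fields_zero_residuals(self):
        g = symbolic_groups()
        f = DisplacementField(sp.S.Zero, sp.S.Zero, sp.S.Zero)
        assert governing_residuals(f, g, sp.Symbol("N_K")) == (0, 0, 0)

    def test_axial_only_field_reduces_to_rod_equation(self):
        # v = w = 0, u = u(x): D1 = u_xx + (N/K)(η² u_xxxx − u_xx)
        g = symbolic_groups()
        NK = sp.Symbol("N_K")
        u = sp.Function("u")(x)
        f = DisplacementField(u, sp.S.Zero, sp.S.Zero)
        D1, D2, D3 = governing_residuals(f, g, NK)
        expected = sp.diff(u, x, 2) + NK * (
            g.eta**2 * sp.diff(u, x, 4) - sp.diff(u, x, 2)
        )
        assert sp.expand(D1 - expected) == 0
        assert sp.expand(D2) == 0
        # the radial equation keeps the Poisson and bending coupling to u
        assert sp.expand(D3) != 0


class TestFunctionalDensity:
    def test_uncoupled_u_reduces_to_V1(self):
        g = symbolic_groups()
        NK = sp.Symbol("N_K")
        f = DisplacementField(sp.Function("u")(x, theta), sp.S.Zero, sp.S.Zero)
        dens = build_functional_density(f, g, NK)
        assert sp.expand(dens - sy.density_V1(f.u, g, NK)) == 0

    def test_no_load_nonlocal_foundation_terms_when_switched_off(self):
        g0 = sy.SymbolicGroups(
            k1=sp.Symbol("k1", positive=True),
            k2=sp.Symbol("k2", positive=True),
            c2=sp.Symbol("c2", positive=True),
            mu1=sp.Symbol("mu1", positive=True),
            eta=sp.S.Zero,
            foundation=sp.S.Zero,
            l=sp.Symbol("l", positive=True),
        )
        f = DisplacementField.generic()
        dens = build_functional_density(f, g0, NK=0)
        assert sp.Symbol("N_K") not in dens.free_symbols

    def test_coupling_density_example_value(self):
        # F at u = x, v = 0, w = const: only μ1 w_x u could survive and w_x = 0
        g = symbolic_groups()
        f = DisplacementField(x, sp.S.Zero, sp.Symbol("w0"))
        assert sp.simplify(sy.density_F(f, g)) == 0


class TestSemiInverseChain:
    """The coupling density F reproduces the off-diagonal operators."""

    def test_phi_variational_derivative(self):
        g = symbolic_groups()
        v = sp.Function("v")(x, theta)
        w = sp.Function("w")(x, theta)
        phi = sy.density_Phi(v, w, g)
        target = g.k1 * sp.diff(w, theta) - g.c2 * (3 * g.k2 + g.mu1) * sp.diff(
            w, x, 2, theta
        )
        assert sp.expand(variational_derivative(phi, v) - target) == 0

    def test_chain_delta_F_matches_M_operators(self):
        res = functional_chain_residuals()
        assert res["u"] == 0
        assert res["v"] == 0
        assert res["w"] == 0

    def test_delta_F_dv_explicit_form(self):
        g = symbolic_groups()
        f = DisplacementField.generic()
        F = sy.density_F(f, g)
        expected = (
            (g.k2 + g.mu1) * sp.diff(f.u, x, theta)
            + g.k1 * sp.diff(f.w, theta)
            - g.c2 * (3 * g.k2 + g.mu1) * sp.diff(f.w, x, 2, theta)
        )
        assert sp.expand(variational_derivative(F, f.v) - expected) == 0


class TestEulerLagrangeVerification:
    def test_principle_holds_symbolically(self):
        report = verify_euler_lagrange(numeric_fields=2, seed=7)
        assert report.passed
        for c in report.channels.values():
            assert c.status == "zero"
        assert report.max_numeric_relative < 1e-9

    def test_broken_coupling_term_detected(self):
        report = verify_euler_lagrange(
            numeric_fields=1, seed=3, f_scales={"wx_uthth": 0.0}
        )
        assert not report.passed
        assert report.max_numeric_relative > 1e-6

    def test_unknown_coupling_term_rejected(self):
        with pytest.raises(KeyError):
            verify_euler_lagrange(numeric_fields=1, f_scales={"nope": 0.5})

    def test_report_roundtrips_to_dict(self):
        report = verify_euler_lagrange(numeric_fields=1, seed=5)
        d = report.to_dict()
        assert d["passed"] is True
        assert set(d["channels"]) == {"u", "v", "w"}
        assert d["seed"] == 5


class TestSelfAdjointness:
    def test_bilinear_form_symmetric_on_admissible_fields(self, rng, mt_groups):
        """∫∫ z · D(y) = ∫∫ y · D(z) for admissible field pairs (periodic in θ,
        simply supported ends), i.e. the governing operator is self-adjoint."""
        g = mt_groups
        NK = 0.2
        for _ in range(2):
            y = ss_field(rng, g.l)
            z = ss_field(rng, g.l)
            Dy = governing_residuals(y, g, NK)
            Dz = governing_residuals(z, g, NK)
            a_yz = sum(
                integrate_cylinder_numeric(sp.expand((D * comp).doit()), g.l, 48, 64)
                for D, comp in zip(Dy, (z.u, z.v, z.w))
            )
            a_zy = sum(
                integrate_cylinder_numeric(sp.expand((D * comp).doit()), g.l, 48, 64)
                for D, comp in zip(Dz, (y.u, y.v, y.w))
            )
            assert a_yz == pytest.approx(a_zy, rel=1e-9, abs=1e-9)


def test_functional_value_accepts_constant_pressure(rng, mt_groups):
    """The constant pressure model is allowed in functional evaluation: the
    linear 2 L(p) w term shifts V by a w-linear amount."""
    g = mt_groups
    f = ss_field(rng, g.l)
    v0 = functional_value(f, g, NK=0.1, n_x=32, n_theta=32)
    vp = functional_value(f, g, NK=0.1, pressure=sp.Float(0.5), n_x=32, n_theta=32)
    assert vp != pytest.approx(v0)
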