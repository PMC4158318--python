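"""Rayleigh-Ritz assembly, the Galerkin oracle, and the critical-load search."""

import numpy as np
import pytest
import scipy.linalg

from helpers import random_groups, rel_dev

from mtshell import (
    DimensionlessGroups,
    Environment,
    PressureModel,
    TrialMode,
    assemble_mode_matrices,
    critical_load,
    fixture,
    galerkin_matrices,
    local_matrices,
    rayleigh_quotient,
    solve_mode,
)
from mtshell import ritz as ritz_mod


class TestAssembly:
    def test_matrices_symmetric_and_load_form_definite(self, mt_groups):
        for mode in (TrialMode(1, 0), TrialMode(2, 3), TrialMode(5, 8)):
            mats = assemble_mode_matrices(mt_groups, mode)
            assert rel_dev(mats.Kmat, mats.Kmat.T) <= 1e-12
            assert rel_dev(mats.Gmat, mats.Gmat.T) <= 1e-12
            vals = np.linalg.eigvalsh(mats.G_active)
            assert np.all(vals > 0)

    def test_geometric_u_entry_closed_form(self, mt_groups):
        # Hessian of K·S(u) for the cosine ansatz: λ²(1 + η²(λ²+n²)) · (πl/2)
        g = mt_groups
        mode = TrialMode(2, 3)
        lam = mode.lam(g.l)
        mats = assemble_mode_matrices(g, mode)
        expected = (
            lam**2 * (1 + g.eta**2 * (lam**2 + mode.n**2)) * (np.pi * g.l / 2)
        )
        assert mats.Gmat[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_uncoupled_material_gives_diagonal_K(self):
        """With μ1 = 0 and vanishing bending number the off-diagonal coupling
        reduces to the single membrane shear term; at n = 0 even that is gone."""
        g = DimensionlessGroups(
            k1=0.5, k2=0.1, c2=1e-12, K=1.0, eta=0.0, l=10.0, mu1=0.0
        )
        mats = assemble_mode_matrices(g, TrialMode(2, 0))
        off = mats.Kmat - np.diag(np.diag(mats.Kmat))
        assert np.max(np.abs(off)) <= 1e-10 * np.max(np.abs(mats.Kmat))

    def test_n_zero_reduces_to_two_dof(self, mt_groups):
        mats = assemble_mode_matrices(mt_groups, TrialMode(3, 0))
        assert mats.reduced
        assert mats.active == (0, 2)
        assert np.all(mats.Kmat[1, :] == 0) and np.all(mats.Kmat[:, 1] == 0)

    def test_constant_pressure_rejected_for_eigenanalysis(self, mt_config):
        from dataclasses import replace

        env = replace(mt_config.environment, pressure=PressureModel.constant(1.0))
        groups = replace(mt_config, environment=env).groups()
        with pytest.raises(ValueError, match="inhomogeneous"):
            assemble_mode_matrices(groups, TrialMode(1, 1))


class TestGalerkinOracle:
    """Variational consistency: the PDE projection equals the functional route."""

    def test_matrices_match_over_random_draws(self, rng):
        for _ in range(8):
            g = random_groups(rng)
            mode = TrialMode(int(rng.integers(1, 6)), int(rng.integers(0, 9)))
            mr = assemble_mode_matrices(g, mode)
            mg = galerkin_matrices(g, mode)
            assert rel_dev(mr.Kmat, mg.Kmat) <= 1e-12
            assert rel_dev(mr.Gmat, mg.Gmat) <= 1e-12

    def test_geometric_matrices_identical(self, mt_groups):
        for mode in (TrialMode(1, 1), TrialMode(4, 6)):
            mr = assemble_mode_matrices(mt_groups, mode)
            mg = galerkin_matrices(mt_groups, mode)
            assert np.array_equal(np.round(mr.Gmat, 15), np.round(mg.Gmat, 15)) or (
                rel_dev(mr.Gmat, mg.Gmat) <= 1e-14
            )

    def test_local_limit_matches_independent_assembly(self, rng):
        """At η = 0 both routes reproduce a hand-coded local orthotropic shell
        assembly in which the nonlocal terms never existed."""
        for _ in range(5):
            g = random_groups(rng, eta=0.0)
            mode = TrialMode(int(rng.integers(1, 6)), int(rng.integers(0, 9)))
            ml = local_matrices(g, mode)
            for other in (assemble_mode_matrices(g, mode), galerkin_matrices(g, mode)):
                assert rel_dev(ml.Kmat, other.Kmat) <= 1e-12
                assert rel_dev(ml.Gmat, other.Gmat) <= 1e-12

    def test_proportional_pressure_consistent_between_routes(self, mt_config):
        from dataclasses import replace

        env = replace(
            mt_config.environment, pressure=PressureModel.proportional(5e4)
        )
        groups = replace(mt_config, environment=env).groups()
        assert groups.pressure_coeff > 0
        mode = TrialMode(2, 4)
        mr = assemble_mode_matrices(groups, mode)
        mg = galerkin_matrices(groups, mode)
        assert rel_dev(mr.Kmat, mg.Kmat) <= 1e-12
        # the restoring pressure P_YY = −κw with this sign convention softens K33
        base = assemble_mode_matrices(mt_config.groups(), mode)
        assert mr.Kmat[2, 2] < base.Kmat[2, 2]


class TestRayleighQuotient:
    def test_homogeneity_degree_zero(self, mt_groups, rng):
        mats = assemble_mode_matrices(mt_groups, TrialMode(2, 5))
        q = rng.normal(size=3)
        base = rayleigh_quotient(q, mats)
        for alpha in (2.0, -0.3, 1e6):
            assert rayleigh_quotient(alpha * q, mats) == pytest.approx(base, rel=1e-12)

    def test_stationary_at_eigenvectors(self, mt_groups):
        mats = assemble_mode_matrices(mt_groups, TrialMode(1, 6))
        val, vec = solve_mode(mats)
        assert rayleigh_quotient(vec, mats) == pytest.approx(val, rel=1e-12)

    def test_random_sampling_never_beats_smallest_eigenvalue(self, iso_groups, rng):
        """Courant-Fischer: on a positive pencil, every trial quotient bounds
        the smallest eigenvalue from above."""
        for mode in (TrialMode(1, 2), TrialMode(3, 5)):
            mats = assemble_mode_matrices(iso_groups, mode)
            vals = scipy.linalg.eigh(mats.K_active, mats.G_active, eigvals_only=True)
            assert np.all(vals > 0)
            smallest = vals[0]
            for _ in range(100):
                q = rng.normal(size=len(mats.active))
                assert rayleigh_quotient(q, mats) >= smallest * (1 - 1e-12)

    def test_zero_vector_rejected(self, mt_groups):
        mats = assemble_mode_matrices(mt_groups, TrialMode(1, 1))
        with pytest.raises(ValueError, match="nonzero"):
            rayleigh_quotient(np.zeros(3), mats)


class TestCriticalLoad:
    def test_eigenpair_residual_small(self, mt_groups):
        res = critical_load(mt_groups)
        assert res.status == "ok"
        mats = assemble_mode_matrices(mt_groups, res.mode)
        q = res.eigenvector[list(mats.active)]
        r = mats.K_active @ q - res.N_cr_dimless * (mats.G_active @ q)
        assert np.linalg.norm(r) <= 1e-9 * np.linalg.norm(mats.K_active @ q)

    def test_local_limit_of_critical_load(self, mt_groups):
        g0 = mt_groups.local()
        nl = critical_load(g0, route="ritz")
        loc = critical_load(g0, route="local")
        assert nl.N_cr == pytest.approx(loc.N_cr, rel=1e-10)
        assert (nl.mode.m, nl.mode.n) == (loc.mode.m, loc.mode.n)

    def test_small_scale_softening(self, mt_config):
        """Increasing the small-scale parameter never raises the buckling load."""
        from dataclasses import replace

        values = []
        for eta in (0.0, 0.05, 0.1, 0.2):
            cfg = mt_config.with_axis_value("eta", eta)
            values.append(critical_load(cfg.groups()).N_cr)
        diffs = np.diff(values)
        assert np.all(diffs <= 1e-12)
        assert np.any(diffs < 0)

    def test_foundation_stiffening(self, mt_config):
        values = []
        for Ec in (0.0, 1e3, 1e4, 1e5):
            cfg = mt_config.with_axis_value("Ec", Ec)
            values.append(critical_load(cfg.groups()).N_cr)
        assert np.all(np.diff(values) >= -1e-12)
        assert np.any(np.diff(values) > 0)

    def test_enlarging_search_range_never_raises_minimum(self, mt_groups):
        small = critical_load(mt_groups, m_range=range(1, 3), n_range=range(0, 5))
        large = critical_load(mt_groups, m_range=range(1, 6), n_range=range(0, 9))
        assert large.N_cr <= small.N_cr + 1e-15

    def test_axisymmetric_modes_match_full_system_with_v_removed(self, mt_groups):
        mats = assemble_mode_matrices(mt_groups, TrialMode(2, 0))
        K3, G3 = mats.Kmat, mats.Gmat
        idx = [0, 2]
        vals_reduced = scipy.linalg.eigh(
            mats.K_active, mats.G_active, eigvals_only=True
        )
        vals_manual = scipy.linalg.eigh(
            K3[np.ix_(idx, idx)], G3[np.ix_(idx, idx)], eigvals_only=True
        )
        assert vals_reduced == pytest.approx(vals_manual, rel=1e-14)

    def test_mode_table_bookkeeping(self, mt_groups):
        res = critical_load(mt_groups, m_range=range(1, 6), n_range=range(0, 9))
        assert len(res.table) == 5 * 9
        assert res.table["is_critical"].sum() == 1
        row = res.table[res.table["is_critical"]].iloc[0]
        assert (row["m"], row["n"]) == (res.mode.m, res.mode.n)
        assert row["N_dimensional"] == pytest.approx(res.N_cr)

    def test_no_buckling_reported_not_raised(self, mt_groups, monkeypatch):
        def negative_definite(groups, mode):
            mats = assemble_mode_matrices(groups, mode)
            mats.Kmat = -np.eye(3) * np.max(np.abs(mats.Kmat))
            return mats

        monkeypatch.setitem(ritz_mod._ROUTES, "ritz", negative_definite)
        res = critical_load(mt_groups, m_range=[1], n_range=[1])
        assert res.status == "no_buckling"
        assert res.N_cr is None

    def test_empty_range_rejected(self, mt_groups):
        with pytest.raises(ValueError, match="nonempty"):
            critical_load(mt_groups, m_range=[], n_range=[1])

    def test_deterministic_tie_break_prefers_smaller_n_then_m(self):
        """With identical per-mode matrices the first (n, m) in lexicographic
        order is reported as critical."""
        g = fixture("isotropic").groups()
        res = critical_load(g, m_range=range(1, 3), n_range=range(0, 3))
        tab = res.table.dropna(subset=["N_dimless"])
        best = tab["N_dimless"].min()
        candidates = tab[tab["N_dimless"] <= best * (1 + 1e-15)]
        first = candidates.sort_values(["n", "m"]).iloc[0]
        assert (res.mode.m, res.mode.n) == (first["m"], first["n"])
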