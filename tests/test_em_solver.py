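import dataclasses

import numpy as np
import pytest

from conftest import plate_system
from ttfdose import em_solver as em
from ttfdose import synthetic_phantom as sp
from ttfdose.analytic_oracle import SlabStack, slab_solution
from ttfdose.em_solver import (
    AssemblyError,
    ContactFilm,
    SolverConfig,
    SolverConvergenceError,
    assemble_system,
    attach_fields,
    electric_field,
    input_power,
    solve_case_fields,
    solve_potential,
)
from ttfdose.tissue_model import DC, FrequencySpec


def small_head(spacing=6.0, **kw):
    cfg = sp.PhantomConfig(spacing=spacing, **kw)
    ph = sp.build_head_phantom(cfg)
    ph = sp.embed_tumor(ph)
    return ph


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(applied_voltage=0)
        with pytest.raises(ValueError):
            SolverConfig(rel_tol=2.0)
        with pytest.raises(ValueError):
            SolverConfig(mode="fancy")

    def test_film_surface_admittance(self):
        film = ContactFilm()
        Y = film.surface_admittance(FrequencySpec())
        assert Y.real == 0
        assert Y.imag == pytest.approx(2 * np.pi * 2e5 * 8.8541878128e-12 * 2.2 / 1e-6, rel=1e-12)
        with pytest.raises(ValueError):
            ContactFilm(thickness=0)


class TestAssembly:
    def test_interior_rows_sum_to_zero(self):
        kappa = np.full((6, 6, 8), 0.3 + 0.01j)
        system = plate_system(kappa, 4.0)
        rowsum = np.asarray(system.A.sum(axis=1)).ravel()
        # rows without Dirichlet faces conserve flux exactly
        d_rows = set(system.index[np.unravel_index(system.dirichlet.vox, kappa.shape)])
        interior = np.array([i not in d_rows for i in range(system.A.shape[0])])
        assert np.abs(rowsum[interior]).max() < 1e-14

    def test_matrix_complex_symmetric(self):
        kappa = np.full((6, 6, 8), 0.3 + 0.01j)
        kappa[2:4, 2:4, 3:5] = 0.05 + 0.002j
        system = plate_system(kappa, 4.0)
        diff = (system.A - system.A.T).tocoo()
        assert np.abs(diff.data).max() if diff.nnz else 0 < 1e-16

    def test_disconnected_domain_raises(self, props):
        # air gap at DC severs the conductive path
        ph = small_head()
        ph, _ = sp.place_arrays(ph, "LR")
        cfg = SolverConfig(freq=DC)
        with pytest.raises(AssemblyError, match="conductive path|dead"):
            assemble_system(ph, props, cfg)

    def test_missing_label_raises(self, props):
        from ttfdose.tissue_model import TissueTable, UnknownTissueError

        ph = small_head()
        ph, _ = sp.place_arrays(ph, "LR")
        partial = TissueTable([e for e in props if e.label != "tumor_core"])
        with pytest.raises(UnknownTissueError, match="tumor_core"):
            assemble_system(ph, partial, SolverConfig())


class TestSolve:
    def test_homogeneous_slab_linear_profile(self):
        kappa = np.full((5, 5, 20), 0.25 + 0j)
        system = plate_system(kappa, 5.0, voltage=80.0)
        sol = solve_potential(system, SolverConfig())
        attach_fields(system, sol)
        # linear ramp along z: E uniform = 80 V / 0.1 m
        emag = sol.e_magnitude()
        assert emag == pytest.approx(800.0, rel=1e-9)
        # potential decreases linearly from the driven plate
        phi_line = sol.phi[2, 2, :].real
        assert np.allclose(np.diff(phi_line), np.diff(phi_line)[0], atol=1e-9)

    def test_constant_phi_gives_zero_field(self):
        kappa = np.full((5, 5, 6), 0.25 + 0j)
        d = plate_system(kappa, 5.0, voltage=80.0)
        d.dirichlet.value[:] = 80.0  # both plates at 80 V
        system = em.assemble(kappa, np.ones(kappa.shape, bool), 5.0, dirichlet=d.dirichlet)
        sol = solve_potential(system, SolverConfig())
        attach_fields(system, sol)
        assert np.allclose(sol.phi.real, 80.0)
        assert np.abs(sol.E).max() < 1e-9

    def test_two_layer_series_field_ratio(self, props):
        # scalp over skull, equal thickness, DC: |E| ratio = sigma ratio
        kappa = np.zeros((4, 4, 20), complex)
        kappa[:, :, :10] = props.sigma("skull")
        kappa[:, :, 10:] = props.sigma("scalp")
        system = plate_system(kappa, 5.0, voltage=80.0)
        sol = solve_potential(system, SolverConfig())
        attach_fields(system, sol)
        emag = sol.e_magnitude()
        ratio = emag[0, 0, 5] / emag[0, 0, 15]
        assert ratio == pytest.approx(0.25 / 0.0211, rel=1e-9)
        ref = slab_solution(
            SlabStack(layers=((0.05, props.sigma("scalp") + 0j), (0.05, props.sigma("skull") + 0j)))
        )
        assert emag[0, 0, 5] == pytest.approx(abs(ref.E[1]), rel=1e-9)

    def test_dc_maximum_principle(self, props):
        rng = np.random.default_rng(0)
        kappa = rng.uniform(0.02, 2.0, size=(8, 8, 12)).astype(complex)
        system = plate_system(kappa, 4.0, voltage=80.0)
        sol = solve_potential(system, SolverConfig())
        phi = sol.phi.real
        assert phi.min() >= -1e-9
        assert phi.max() <= 80.0 + 1e-9

    def test_direct_and_iterative_agree(self):
        kappa = np.full((8, 8, 10), 0.3 + 0.02j)
        kappa[3:5, 3:5, 4:6] = 0.02 + 0.001j
        system = plate_system(kappa, 4.0)
        a = solve_potential(system, SolverConfig(mode="direct"))
        b = solve_potential(system, SolverConfig(mode="iterative"))
        assert np.allclose(a.phi, b.phi, rtol=1e-6, atol=1e-8)

    def test_nonconvergence_raises(self):
        kappa = np.full((10, 10, 10), 1.0 + 0j)
        system = plate_system(kappa, 4.0)
        with pytest.raises(SolverConvergenceError) as exc:
            solve_potential(system, SolverConfig(mode="iterative", max_iter=1, rel_tol=1e-12))
        assert exc.value.residual > 1e-12

    def test_omega_zero_matches_independent_real_laplace(self, props):
        # complex machinery at omega=0 vs an independent real-valued solve
        import scipy.sparse as sps
        import scipy.sparse.linalg as spla

        kappa = np.zeros((6, 6, 12), complex)
        kappa[:, :, :6] = props.sigma("scalp")
        kappa[:, :, 6:] = props.sigma("skull")
        system = plate_system(kappa, 5.0)
        sol = solve_potential(system, SolverConfig(mode="iterative"))
        x_ref = spla.spsolve(sps.csc_matrix(system.A.real), system.b.real)
        phi_ref = np.full(system.mask.shape, np.nan)
        phi_ref[system.mask] = x_ref
        assert np.allclose(sol.phi.real, phi_ref, rtol=1e-7, atol=1e-9)
        assert np.abs(sol.phi.imag).max() < 1e-9


@pytest.fixture(scope="module")
def solved(props):
    ph, _ = sp.place_arrays(small_head(), "LR")
    system, sol = solve_case_fields(ph, props, SolverConfig())
    return ph, system, sol


class TestHeadSolve:
    def test_dirichlet_faces_exact(self, solved):
        ph, system, sol = solved
        d = system.dirichlet
        assert set(np.unique(d.value.real)) == {0.0, 80.0}
        assert sol.residual <= 1e-8

    def test_J_equals_kappa_E(self, solved):
        _, system, sol = solved
        assert np.allclose(sol.J, system.kappa[..., None] * sol.E)

    def test_swap_roles_preserves_magnitude(self, solved, props):
        ph, system, sol = solved
        ph2 = ph.copy()
        ph2.array_spec = dataclasses.replace(ph.array_spec, roles=("ground", "active"))
        _, sol2 = solve_case_fields(ph2, props, SolverConfig())
        m = system.mask & np.isfinite(sol.phi.real)
        # phi' = 80 - phi up to solver tolerance; |E| unchanged
        assert np.allclose(sol2.phi[m], 80.0 - sol.phi[m], rtol=1e-6, atol=1e-6)
        assert np.allclose(sol2.e_magnitude(), sol.e_magnitude(), rtol=1e-6, atol=1e-6)

    def test_mirror_symmetry_of_potential(self, solved):
        _, _, sol = solved
        phi = np.nan_to_num(sol.phi.real)
        assert np.allclose(phi, np.flip(phi, axis=1), atol=1e-6)
        assert np.allclose(phi, np.flip(phi, axis=2), atol=1e-6)

    def test_power_balance(self, solved):
        from ttfdose.metrics import joule_heating

        _, system, sol = solved
        P = input_power(system, sol).real
        Q = joule_heating(sol).total_power()
        assert Q == pytest.approx(P, rel=1e-9)

    def test_central_difference_field_agrees_in_interior(self, solved):
        # plain central differences match the face-consistent field away
        # from tissue interfaces
        ph, system, sol = solved
        E2 = electric_field(sol, sol.spacing)
        wm = ph.labels == sp.WHITE_MATTER
        interior = wm.copy()
        for a in range(3):
            for s in (1, -1):
                interior &= np.roll(wm, s, axis=a)
        assert interior.any()
        assert np.allclose(sol.E[interior], E2[interior], rtol=1e-10, atol=1e-12)


class TestContactFilm:
    def test_film_limit_recovers_uninsulated(self, props):
        ph0, _ = sp.place_arrays(small_head(), "LR")
        ph1, _ = sp.place_arrays(small_head(), "LR", insulate=True)
        cfg = SolverConfig()
        _, base = solve_case_fields(ph0, props, cfg)
        # vanishing film thickness => Y -> infinity => no insulation effect
        _, thin = solve_case_fields(ph1, props, cfg, film=ContactFilm(thickness=1e-14))
        _, thick = solve_case_fields(ph1, props, cfg, film=ContactFilm())
        m = np.isfinite(base.phi.real)
        assert np.allclose(thin.phi[m], base.phi[m], rtol=1e-6, atol=1e-6)
        # the default film actually does something
        assert not np.allclose(thick.phi[m], base.phi[m], atol=1e-3)

    def test_all_false_flags_identical_to_no_film(self, props):
        ph, _ = sp.place_arrays(small_head(), "LR", insulate=None)
        cfg = SolverConfig()
        s1, a = solve_case_fields(ph, props, cfg)
        s2, b = solve_case_fields(ph, props, cfg, film=ContactFilm())
        assert (s1.A - s2.A).nnz == 0
        assert np.array_equal(a.phi[s1.mask], b.phi[s2.mask])

    def test_insulation_reduces_input_power(self, props):
        ph0, _ = sp.place_arrays(small_head(), "LR")
        ph1, _ = sp.place_arrays(small_head(), "LR", insulate=True)
        cfg = SolverConfig()
        s0, sol0 = solve_case_fields(ph0, props, cfg)
        s1, sol1 = solve_case_fields(ph1, props, cfg, film=ContactFilm())
        assert input_power(s1, sol1).real < input_power(s0, sol0).real
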