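import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import plate_system
from ttfdose import synthetic_phantom as sp
from ttfdose.em_solver import FieldSolution, SolverConfig, attach_fields, solve_potential
from ttfdose.metrics import (
    EmptyMaskError,
    atv,
    gel_power_stats,
    joule_heating,
    max_gel_heating,
    normalized_field_strength,
    tissue_field_stats,
)


def uniform_slab_solution(sigma=0.25, voltage=80.0, nz=20, spacing=5.0):
    kappa = np.full((5, 5, nz), sigma, dtype=complex)
    system = plate_system(kappa, spacing, voltage=voltage)
    sol = solve_potential(system, SolverConfig())
    return system, attach_fields(system, sol)


def synthetic_solution(emag_V_per_m, mask=None, spacing=2.0):
    """A FieldSolution carrying a prescribed |E| along x (no solve)."""
    emag = np.asarray(emag_V_per_m, dtype=float)
    E = np.zeros(emag.shape + (3,), dtype=complex)
    E[..., 0] = emag
    m = np.ones(emag.shape, bool) if mask is None else mask
    return FieldSolution(
        phi=np.zeros(emag.shape, complex), residual=0.0, mask=m, spacing=spacing, E=E, J=E * 0.25
    )


class TestJouleHeating:
    def test_uniform_closed_form(self):
        # sigma 0.25, |E| 800 V/m -> 80 kW/m^3
        _, sol = uniform_slab_solution()
        Q = joule_heating(sol)
        assert Q.Q == pytest.approx(80_000.0, rel=1e-9)

    def test_zero_where_sigma_zero(self):
        sol = synthetic_solution(np.full((4, 4, 4), 800.0))
        sol.J = sol.E * 0.0  # sigma = 0 region
        sol.Q_density = None
        Q = joule_heating(sol)
        assert np.all(Q.Q == 0)

    def test_equals_half_sigma_e_squared_for_real_admittivity(self):
        _, sol = uniform_slab_solution(sigma=0.7, voltage=42.0)
        Q = joule_heating(sol)
        ref = 0.5 * 0.7 * sol.e_magnitude() ** 2
        assert np.allclose(Q.Q, ref, rtol=1e-12)

    def test_nonnegative(self):
        _, sol = uniform_slab_solution()
        assert joule_heating(sol).Q.min() >= 0


class TestGelPowerStats:
    @pytest.fixture()
    def phantom_with_gels(self):
        ph = sp.build_head_phantom(sp.PhantomConfig(spacing=6.0))
        ph, _ = sp.place_arrays(ph, "LR")
        return ph

    def test_uniform_q_max_equals_mean(self, phantom_with_gels):
        ph = phantom_with_gels
        sol = synthetic_solution(np.zeros(ph.shape), spacing=ph.spacing)
        sol.Q_density = np.full(ph.shape, 123.0)
        sol.mask = ph.domain_mask()
        Q = joule_heating(sol)
        df = gel_power_stats(Q, ph)
        assert len(df) == 18
        assert np.allclose(df["max_Q_W_per_m3"], 123.0)
        assert np.allclose(df["mean_Q_W_per_m3"], 123.0)

    def test_integrated_power_brute_force(self, phantom_with_gels):
        ph = phantom_with_gels
        rng = np.random.default_rng(1)
        qmap = rng.uniform(0, 1e5, ph.shape)
        sol = synthetic_solution(np.zeros(ph.shape), spacing=ph.spacing)
        sol.Q_density = qmap
        Q = joule_heating(sol)
        df = gel_power_stats(Q, ph)
        vol = (ph.spacing * 1e-3) ** 3
        for row in df.itertuples():
            voxels = (ph.gel_id == row.gel_id) & (ph.labels == sp.HYDROGEL)
            # brute-force direct summation over the explicit voxel list
            expected = sum(qmap[tuple(v)] for v in np.argwhere(voxels)) * vol
            assert row.power_W == pytest.approx(expected, rel=1e-12)
            assert row.max_Q_W_per_m3 == pytest.approx(qmap[voxels].max())
            assert row.mean_Q_W_per_m3 == pytest.approx(qmap[voxels].mean())

    def test_w_max_lowest_gel_id_on_tie(self, phantom_with_gels):
        ph = phantom_with_gels
        sol = synthetic_solution(np.zeros(ph.shape), spacing=ph.spacing)
        sol.Q_density = np.full(ph.shape, 5.0)
        df = gel_power_stats(joule_heating(sol), ph)
        assert max_gel_heating(df) == 5.0
        top = df[df["max_Q_W_per_m3"] == 5.0]
        assert top["gel_id"].iloc[0] == 0  # sorted ascending: ties -> lowest id

    def test_no_gels_raises(self):
        ph = sp.build_head_phantom(sp.PhantomConfig(spacing=6.0))
        sol = synthetic_solution(np.zeros(ph.shape))
        sol.Q_density = np.zeros(ph.shape)
        with pytest.raises(EmptyMaskError):
            gel_power_stats(joule_heating(sol), ph)


class TestTissueFieldStats:
    def test_uniform_mean_equals_max(self):
        ph = sp.build_head_phantom(sp.PhantomConfig(spacing=6.0))
        sol = synthetic_solution(np.full(ph.shape, 150.0))  # 1.5 V/cm
        stats = tissue_field_stats(sol, ph, ["gray_matter"])
        assert stats["gray_matter"]["mean_V_per_cm"] == pytest.approx(1.5)
        assert stats["gray_matter"]["max_V_per_cm"] == pytest.approx(1.5)

    def test_brute_force_enumeration(self):
        ph = sp.build_head_phantom(sp.PhantomConfig(spacing=6.0))
        rng = np.random.default_rng(2)
        emag = rng.uniform(0, 400, ph.shape)
        sol = synthetic_solution(emag)
        stats = tissue_field_stats(sol, ph, ["skull", "brain"])
        voxels = np.argwhere(ph.labels == sp.SKULL)
        vals = np.array([emag[tuple(v)] for v in voxels]) / 100.0
        assert stats["skull"]["mean_V_per_cm"] == pytest.approx(vals.mean(), rel=1e-12)
        assert stats["skull"]["max_V_per_cm"] == pytest.approx(vals.max(), rel=1e-12)

    def test_brain_union_weighted_mean_identity(self):
        ph = sp.build_head_phantom(sp.PhantomConfig(spacing=6.0))
        rng = np.random.default_rng(3)
        sol = synthetic_solution(rng.uniform(0, 400, ph.shape))
        stats = tissue_field_stats(sol, ph, ["csf", "gray_matter", "white_matter", "brain"])
        parts = ["csf", "gray_matter", "white_matter"]
        ns = {t: int((ph.labels == sp.LABEL_CODES[t]).sum()) for t in parts}
        weighted = sum(stats[t]["mean_V_per_cm"] * ns[t] for t in parts) / sum(ns.values())
        assert stats["brain"]["mean_V_per_cm"] == pytest.approx(weighted, rel=1e-12)

    def test_empty_mask_names_tissue(self):
        ph = sp.build_head_phantom(sp.PhantomConfig(spacing=6.0))
        sol = synthetic_solution(np.zeros(ph.shape))
        with pytest.raises(EmptyMaskError, match="tumor_core"):
            tissue_field_stats(sol, ph, ["tumor_core"])


class TestATV:
    # 10 listed |E| values (V/cm): brute-force count >= 1.0 gives 7/10
    SHELL_VALUES = [0.2, 0.5, 0.99, 1.0, 1.01, 1.3, 2.0, 2.49, 2.5, 3.2]

    def make(self):
        emag_cm = np.array(self.SHELL_VALUES).reshape(1, 1, -1)
        mask = np.ones(emag_cm.shape, bool)
        return emag_cm, mask

    def test_brute_force_list(self):
        emag, mask = self.make()
        assert atv(emag, mask, 1.0) == pytest.approx(100.0 * 7 / 10)
        assert atv(emag, mask, 2.5) == pytest.approx(100.0 * 2 / 10)

    def test_threshold_zero_is_100(self):
        emag, mask = self.make()
        assert atv(emag, mask, 0.0) == 100.0

    def test_above_max_is_0(self):
        emag, mask = self.make()
        assert atv(emag, mask, 100.0) == 0.0

    def test_inclusive_threshold(self):
        emag, mask = self.make()
        assert atv(emag, mask, 3.2) == pytest.approx(10.0)

    def test_empty_mask_raises(self):
        emag, _ = self.make()
        with pytest.raises(EmptyMaskError):
            atv(emag, np.zeros(emag.shape, bool), 1.0)

    @given(
        vals=st.lists(st.floats(min_value=0, max_value=10), min_size=1, max_size=50),
        t1=st.floats(min_value=0, max_value=10),
        t2=st.floats(min_value=0, max_value=10),
    )
    def test_monotone_nonincreasing_in_threshold(self, vals, t1, t2):
        emag = np.array(vals).reshape(1, 1, -1)
        mask = np.ones(emag.shape, bool)
        lo, hi = min(t1, t2), max(t1, t2)
        assert atv(emag, mask, lo) >= atv(emag, mask, hi)

    @given(
        vals=st.lists(st.floats(min_value=0, max_value=10), min_size=1, max_size=50),
        t=st.floats(min_value=0.01, max_value=10),
    )
    def test_scale_equivariance(self, vals, t):
        emag = np.array(vals).reshape(1, 1, -1)
        mask = np.ones(emag.shape, bool)
        assert atv(2 * emag, mask, t) == atv(emag, mask, t / 2)


class TestNormalizedFieldStrength:
    def test_identity_when_powers_equal(self):
        assert normalized_field_strength(1.23, 5e5, 5e5) == pytest.approx(1.23)

    def test_errors_on_nonpositive_power(self):
        with pytest.raises(ValueError):
            normalized_field_strength(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            normalized_field_strength(1.0, 1.0, -2.0)

    @given(
        e2=st.floats(min_value=0.01, max_value=10),
        w1=st.floats(min_value=1.0, max_value=1e7),
        w2=st.floats(min_value=1.0, max_value=1e7),
        c=st.floats(min_value=0.1, max_value=10),
    )
    def test_homogeneous_and_rescaling_invariant(self, e2, w1, w2, c):
        base = normalized_field_strength(e2, w1, w2)
        assert normalized_field_strength(c * e2, w1, w2) == pytest.approx(c * base, rel=1e-9)
        assert normalized_field_strength(e2, c * w1, c * w2) == pytest.approx(base, rel=1e-9)
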