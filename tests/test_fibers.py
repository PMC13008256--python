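import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bivtwin.fibers import (FiberField, RBMAngles, calibrate_rbm_angles,
                            fit_diffusion_tensor, fractional_anisotropy,
                            mean_angle_theta, principal_fiber_direction,
                            rbm_fiber_field)
from bivtwin.synthetic import make_dw_signals, uniform_sphere_gradients


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestTensorFit:
    def test_round_trip_machine_precision(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(30, 3, 3)) * 2e-4
        D = A @ A.transpose(0, 2, 1) + np.eye(3) * 5e-4
        dw = make_dw_signals(D, uniform_sphere_gradients(15), b_value=600.0)
        fit = fit_diffusion_tensor(dw)
        assert np.abs(fit.tensors - D).max() < 1e-10

    def test_isotropic_signals_give_equal_eigenvalues(self):
        D = np.tile(np.eye(3) * 8e-4, (4, 1, 1))
        dw = make_dw_signals(D, uniform_sphere_gradients(12), b_value=1000.0)
        fit = fit_diffusion_tensor(dw)
        assert np.allclose(fit.eigvals, 8e-4, atol=1e-12)

    def test_too_few_gradients_rejected(self):
        D = np.tile(np.eye(3) * 1e-3, (2, 1, 1))
        dw = make_dw_signals(D, uniform_sphere_gradients(6), b_value=1000.0)
        dw.gradients = dw.gradients[:5]
        dw.signals = dw.signals[:, :5]
        with pytest.raises(ValueError):
            fit_diffusion_tensor(dw)

    def test_unbiased_under_log_domain_noise(self):
        """Mean recovered tensor within 2 s.e. of the planted one."""
        rng = np.random.default_rng(7)
        D = np.array([[1.5e-3, 2e-4, 0.0], [2e-4, 1.0e-3, 0.0],
                      [0.0, 0.0, 7e-4]])
        g = uniform_sphere_gradients(15)
        n_rep = 200
        quad = np.einsum("ga,ab,gb->g", g, D, g)
        recovered = np.empty((n_rep, 3, 3))
        for r in range(n_rep):
            # zero-mean noise in the log domain keeps the fit unbiased
            log_noisy = -1000.0 * quad + rng.normal(0, 0.02, size=len(g))
            from bivtwin.synthetic import DWSignalSet
            dw = DWSignalSet(g, 1000.0, 1.0, np.exp(log_noisy)[None, :])
            recovered[r] = fit_diffusion_tensor(dw).tensors[0]
        mean = recovered.mean(axis=0)
        se = recovered.std(axis=0, ddof=1) / np.sqrt(n_rep)
        # 3 s.e. per entry keeps the familywise level sane over 9 entries
        assert np.all(np.abs(mean - D) <= 3.0 * se + 1e-12)


class TestFractionalAnisotropy:
    def test_isotropic_zero(self):
        assert fractional_anisotropy(np.array([1.0, 1.0, 1.0])) == 0.0

    def test_degenerate_limit_one(self):
        assert fractional_anisotropy(np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0)

    def test_printed_formula_oracle(self):
        l1, l2, l3 = 3.0, 2.0, 1.0
        expect = np.sqrt(0.5 * ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2)
                         / (l1 ** 2 + l2 ** 2 + l3 ** 2))
        assert fractional_anisotropy(np.array([l1, l2, l3])) == pytest.approx(expect)

    def test_all_zero_flagged_undefined(self):
        assert np.isnan(fractional_anisotropy(np.array([0.0, 0.0, 0.0])))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 10.0), st.integers(0, 1000))
    def test_rotation_and_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        w = np.sort(rng.uniform(0.1, 2.0, size=3))[::-1]
        R = random_rotation(seed)
        D = R @ np.diag(w) @ R.T
        w_rot = np.sort(np.linalg.eigvalsh(D))[::-1]
        fa_rot = fractional_anisotropy(w_rot)
        fa_scaled = fractional_anisotropy(w * scale)
        fa = fractional_anisotropy(w)
        assert fa_rot == pytest.approx(fa, abs=1e-9)
        assert fa_scaled == pytest.approx(fa, abs=1e-9)


class TestPrincipalDirection:
    def test_diagonal_tensor(self):
        d, amb = principal_fiber_direction(np.diag([3.0, 2.0, 1.0]))
        assert np.allclose(d, [1.0, 0.0, 0.0])
        assert not amb

    def test_rotation_equivariance(self):
        R = random_rotation(3)
        D = np.diag([3.0, 2.0, 1.0])
        d, _ = principal_fiber_direction(R @ D @ R.T)
        expect = R[:, 0]
        if expect[np.flatnonzero(np.abs(expect) > 1e-12)[0]] < 0:
            expect = -expect
        assert np.abs(d - expect).max() < 1e-8

    def test_isotropic_flagged_ambiguous(self):
        _, amb = principal_fiber_direction(np.eye(3))
        assert amb


class TestRBMField:
    def analytic_slab_check(self, slab, slab_coords, angles):
        tm, ab = slab_coords
        field = rbm_fiber_field(slab, tm, ab, None, angles)
        # slab frame: transmural = +z, apicobasal = +x, circumferential = -y
        coord = np.clip(tm.values[slab.tets].mean(axis=1), 0, 1)
        alpha = np.deg2rad(angles.alpha_endo_lv
                           + (angles.alpha_epi_lv - angles.alpha_endo_lv) * coord)
        expect = (np.cos(alpha)[:, None] * np.array([0.0, -1.0, 0.0])
                  + np.sin(alpha)[:, None] * np.array([1.0, 0.0, 0.0]))
        return field, expect

    def test_zero_angles_circumferential(self, slab, slab_coords):
        field, _ = self.analytic_slab_check(slab, slab_coords, RBMAngles(0, 0, 0, 0))
        assert np.abs(np.abs(field.f[:, 1]) - 1.0).max() < 1e-9

    def test_linear_rule_closed_form(self, slab, slab_coords):
        angles = RBMAngles(60, -60, 60, -60)
        field, expect = self.analytic_slab_check(slab, slab_coords, angles)
        assert np.abs(np.abs(np.einsum("ma,ma->m", field.f, expect)) - 1.0).max() < 1e-9

    def test_midwall_angle_is_zero_for_standard_angles(self):
        """At transmural coordinate 0.5 the +60/-60 rule gives 0 degrees."""
        from bivtwin.anatomy import solve_laplace
        from bivtwin.mesh import make_slab_mesh

        # an odd number of layers puts element centroids exactly mid-wall
        mesh = make_slab_mesh((1.0, 1.0, 0.5), 1282.0)
        tm = solve_laplace(mesh, {"endo": 0.0, "epi": 1.0})
        ab = solve_laplace(mesh, {"apex": 0.0, "base": 1.0})
        field = rbm_fiber_field(mesh, tm, ab, None, RBMAngles(60, -60, 60, -60))
        coord = tm.values[mesh.tets].mean(axis=1)
        mid = np.abs(coord - 0.5) < 1e-9
        assert mid.any()
        # helix angle vanishes: purely circumferential fibers there
        assert np.abs(np.abs(field.f[mid, 1]) - 1.0).max() < 1e-9

    def test_orthonormal_frames(self, slab, slab_coords):
        tm, ab = slab_coords
        f = rbm_fiber_field(slab, tm, ab, None, RBMAngles())
        for v in (f.f, f.s, f.n):
            assert np.abs(np.linalg.norm(v, axis=1) - 1.0).max() < 1e-8
        assert np.abs(np.einsum("ma,ma->m", f.f, f.s)).max() < 1e-8
        assert np.abs(np.einsum("ma,ma->m", f.f, f.n)).max() < 1e-8


class TestMeanAngle:
    def test_identical_zero(self):
        f = FiberField(np.tile([1.0, 0.0, 0.0], (5, 1)))
        assert mean_angle_theta(f, f) == 0.0

    def test_orthogonal_ninety(self):
        a = FiberField(np.tile([1.0, 0.0, 0.0], (5, 1)))
        b = FiberField(np.tile([0.0, 1.0, 0.0], (5, 1)))
        assert mean_angle_theta(a, b) == pytest.approx(90.0)

    def test_two_element_mean(self):
        a = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        b = np.array([[np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30)), 0],
                      [np.cos(np.deg2rad(60)), np.sin(np.deg2rad(60)), 0]])
        assert mean_angle_theta(a, b) == pytest.approx(45.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_sign_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        signs = rng.choice([-1.0, 1.0], size=(8, 1))
        t1 = mean_angle_theta(a, b)
        assert mean_angle_theta(b, a) == pytest.approx(t1, abs=1e-9)
        assert mean_angle_theta(a * signs, b) == pytest.approx(t1, abs=1e-9)
        assert 0.0 <= t1 <= 90.0


class TestCalibration:
    @pytest.fixture(scope="class")
    def lv_rv_mask(self, slab):
        # split the slab into an LV half and an RV half along y
        return slab.nodes[:, 1] > 0.5

    def test_self_recovery_of_standard_angles(self, slab, slab_coords, lv_rv_mask):
        tm, ab = slab_coords
        ref = rbm_fiber_field(slab, tm, ab, lv_rv_mask, RBMAngles(60, -60, 60, -60))
        angles, trace = calibrate_rbm_angles(slab, tm, ab, lv_rv_mask, ref)
        assert (angles.alpha_endo_lv, angles.alpha_epi_lv) == (60.0, -60.0)
        assert (angles.alpha_endo_rv, angles.alpha_epi_rv) == (60.0, -60.0)

    def test_stage1_grid_has_324_candidates(self, slab, slab_coords, lv_rv_mask):
        tm, ab = slab_coords
        ref = rbm_fiber_field(slab, tm, ab, lv_rv_mask, RBMAngles())
        _, trace = calibrate_rbm_angles(slab, tm, ab, lv_rv_mask, ref)
        assert trace.n_evaluations(0) == 324

    def test_recovers_planted_off_grid_angles(self, slab, slab_coords, lv_rv_mask):
        """1-degree refinement pins angles planted off the coarse grid."""
        tm, ab = slab_coords
        planted = RBMAngles(53.0, -62.0, 64.0, -51.0)
        ref = rbm_fiber_field(slab, tm, ab, lv_rv_mask, planted)
        angles, trace = calibrate_rbm_angles(slab, tm, ab, lv_rv_mask, ref)
        assert abs(angles.alpha_endo_lv - 53.0) <= 1.0
        assert abs(angles.alpha_epi_lv + 62.0) <= 1.0
        assert abs(angles.alpha_endo_rv - 64.0) <= 1.0
        assert abs(angles.alpha_epi_rv + 51.0) <= 1.0

    def test_argmin_never_exceeds_evaluated_candidates(self, slab, slab_coords,
                                                       lv_rv_mask):
        tm, ab = slab_coords
        rng = np.random.default_rng(4)
        noisy = rbm_fiber_field(slab, tm, ab, lv_rv_mask, RBMAngles(40, -30, 20, -70))
        ref = FiberField(noisy.f + 0.15 * rng.normal(size=noisy.f.shape))
        angles, trace = calibrate_rbm_angles(slab, tm, ab, lv_rv_mask, ref)
        final = rbm_fiber_field(slab, tm, ab, lv_rv_mask, angles)
        theta_final = mean_angle_theta(final, ref)
        all_evals = [c[2] for stage in trace.stages for c in stage]
        assert theta_final <= min(all_evals) + 1e-9
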