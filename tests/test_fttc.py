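import numpy as np
import pytest

from tfmlab.core import GelSubstrate, Point2D
from tfmlab.fields import DisplacementField
from tfmlab.fttc import (
    auto_lambda,
    build_fourier_kernel,
    fill_invalid_nodes,
    forward_displacement,
    forward_displacement_direct,
    green_tensor_real,
    invert_traction,
    tikhonov_functional,
)
from tfmlab.synthetic import make_traction_dipole

SUB = GelSubstrate(2000.0, 0.5)
E = SUB.young_modulus_Pa


def _dipole(n=32, h=1.0, mag=300.0, sigma=2.0, sep=10.0):
    return make_traction_dipole((n, n), h, mag, sigma, sep)


class TestGreenTensorReal:
    def test_printed_formula_on_x_axis(self):
        g = green_tensor_real(Point2D(1.0, 0.0), SUB)
        assert np.allclose(g, 3.0 / (4 * np.pi * E) * np.array([[2.0, 0.0], [0.0, 1.0]]))

    def test_xy_exchange_symmetry(self):
        g = green_tensor_real(Point2D(0.0, 1.0), SUB)
        assert np.allclose(g, 3.0 / (4 * np.pi * E) * np.array([[1.0, 0.0], [0.0, 2.0]]))

    def test_diagonal_point_off_diagonal_term(self):
        a = 0.7
        g = green_tensor_real(Point2D(a, a), SUB)
        r = a * np.sqrt(2.0)
        assert g[0, 1] == pytest.approx(3.0 * a * a / (4 * np.pi * E * r**3), rel=1e-12)
        assert g[0, 1] == pytest.approx(g[1, 0])

    def test_random_points_match_direct_arithmetic(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            x, y = rng.uniform(-50, 50, 2)
            if x == 0 and y == 0:
                continue
            g = green_tensor_real(Point2D(x, y), SUB)
            r = np.hypot(x, y)
            pref = 3.0 / (4.0 * np.pi * E * r**3)
            ref = pref * np.array([[r * r + x * x, x * y], [x * y, r * r + y * y]])
            assert np.allclose(g, ref, rtol=1e-12, atol=0.0)

    def test_origin_singular(self):
        with pytest.raises(ValueError, match="singular"):
            green_tensor_real(Point2D(0.0, 0.0), SUB)

    def test_compressible_substrate_rejected(self):
        with pytest.raises(ValueError, match="incompressible"):
            green_tensor_real(Point2D(1.0, 0.0), GelSubstrate(2000.0, 0.45))


class TestFourierKernel:
    def test_on_axis_modes_have_no_shear_coupling(self):
        op = build_fourier_kernel(16, 16, 1.0, SUB, pad_factor=1)
        # ky = 0 row: khy = 0, so the off-diagonal khx*khy term vanishes
        gxy = (op.g_par - op.g_perp) * op.khx * op.khy
        assert np.allclose(gxy[0, :], 0.0)
        assert np.allclose(gxy[:, 0], 0.0)

    def test_kernel_even_under_k_negation(self):
        op = build_fourier_kernel(12, 12, 0.5, SUB, pad_factor=1)
        for arr in (op.g_par, op.g_perp, op.kmag):
            flipped = np.roll(arr[::-1, ::-1], (1, 1), axis=(0, 1))
            assert np.allclose(arr, flipped)

    def test_eigenvalues_are_boussinesq(self):
        op = build_fourier_kernel(8, 8, 1.0, SUB, pad_factor=1)
        k = op.kmag
        off_nyq = ~op.nyq_line & (k > 0)
        assert np.allclose(op.g_par[off_nyq], 3.0 / (2 * E * k[off_nyq]))
        assert np.allclose(op.g_perp[off_nyq], 3.0 / (E * k[off_nyq]))

    def test_forward_matches_real_space_summation(self):
        t = _dipole(16, 1.0, 300.0, 1.5, 6.0)
        op = build_fourier_kernel(16, 16, 1.0, SUB, pad_factor=4)
        u_fft = forward_displacement(t, op)
        u_dir = forward_displacement_direct(t, SUB)
        num = np.sqrt(np.mean((u_fft.ux - u_dir.ux) ** 2 + (u_fft.uy - u_dir.uy) ** 2))
        den = np.sqrt(np.mean(u_dir.ux**2 + u_dir.uy**2))
        assert num / den < 0.02


class TestForward:
    def test_zero_traction_zero_displacement(self):
        from tfmlab.fields import TractionField

        t = TractionField(np.zeros((16, 16)), np.zeros((16, 16)), 1.0)
        op = build_fourier_kernel(16, 16, 1.0, SUB)
        u = forward_displacement(t, op)
        assert np.all(u.ux == 0) and np.all(u.uy == 0)

    def test_dipole_displacement_antisymmetric(self):
        t = _dipole(33, 1.0, 200.0, 2.0, 10.0)  # odd grid: exact center node
        op = build_fourier_kernel(33, 33, 1.0, SUB, pad_factor=2)
        u = forward_displacement(t, op)
        # point symmetry about the dipole center: u(c+d) = -u(c-d)
        flipped = -u.ux[::-1, ::-1]
        scale = np.abs(u.ux).max()
        assert np.allclose(u.ux, flipped, atol=1e-6 * scale)

    def test_unbalanced_traction_rejected(self):
        from tfmlab.fields import TractionField

        t = TractionField(np.full((16, 16), 10.0), np.zeros((16, 16)), 1.0)
        op = build_fourier_kernel(16, 16, 1.0, SUB)
        with pytest.raises(ValueError, match="force-balanced"):
            forward_displacement(t, op)

    def test_grid_mismatch_rejected(self):
        t = _dipole(32)
        op = build_fourier_kernel(16, 16, 1.0, SUB)
        with pytest.raises(ValueError, match="operator built"):
            forward_displacement(t, op)


class TestInversion:
    def test_noiseless_inverse_is_exact_on_same_lattice(self):
        t = _dipole(32)
        op = build_fourier_kernel(32, 32, 1.0, SUB, pad_factor=1)
        u = forward_displacement(t, op)
        rec = invert_traction(u, op, 0.0)
        err = np.sqrt(np.mean((rec.tx - t.tx) ** 2 + (rec.ty - t.ty) ** 2))
        assert err < 1e-6 * np.sqrt(np.mean(t.tx**2 + t.ty**2))

    def test_huge_lambda_suppresses_solution(self):
        t = _dipole()
        op = build_fourier_kernel(32, 32, 1.0, SUB, pad_factor=1)
        u = forward_displacement(t, op)
        f0 = invert_traction(u, op, 0.0)
        f_inf = invert_traction(u, op, 1e6 * op.gmax)
        assert np.abs(f_inf.magnitude).max() < 1e-6 * np.abs(f0.magnitude).max()

    def test_negative_lambda_rejected(self):
        t = _dipole()
        op = build_fourier_kernel(32, 32, 1.0, SUB)
        u = forward_displacement(t, op)
        with pytest.raises(ValueError):
            invert_traction(u, op, -1.0)

    def test_monotone_norms_and_j_identity(self):
        rng = np.random.default_rng(0)
        t = _dipole()
        op = build_fourier_kernel(32, 32, 1.0, SUB, pad_factor=2)
        u0 = forward_displacement(t, op)
        u = DisplacementField(u0.ux + rng.normal(0, 0.02, u0.ux.shape),
                              u0.uy + rng.normal(0, 0.02, u0.uy.shape), 1.0)
        lams = np.logspace(-6, 2, 20) * op.gmax
        res, sol = [], []
        for lam in lams:
            _, r = invert_traction(u, op, lam, full_output=True)
            res.append(r.residual_norm)
            sol.append(r.solution_norm)
            jj = r.residual_norm**2 + lam**2 * r.solution_norm**2
            assert r.J_value == pytest.approx(jj, rel=1e-10)
        assert np.all(np.diff(res) >= -1e-12)
        assert np.all(np.diff(sol) <= 1e-12)

    def test_returned_solution_is_first_order_optimal(self):
        rng = np.random.default_rng(1)
        t = _dipole(16, 1.0, 300.0, 1.5, 6.0)
        op = build_fourier_kernel(16, 16, 1.0, SUB, pad_factor=2)
        u0 = forward_displacement(t, op)
        u = DisplacementField(u0.ux + rng.normal(0, 0.05, u0.ux.shape),
                              u0.uy + rng.normal(0, 0.05, u0.uy.shape), 1.0)
        lam = 1e-2 * op.gmax
        f_pad = invert_traction(u, op, lam, crop=False)
        j0 = tikhonov_functional(f_pad.tx, f_pad.ty, u, op, lam)
        for _ in range(100):
            dx = rng.normal(0, 1.0, f_pad.tx.shape)
            dy = rng.normal(0, 1.0, f_pad.ty.shape)
            eps = 1e-3 * np.abs(f_pad.tx).max()
            j1 = tikhonov_functional(f_pad.tx + eps * dx, f_pad.ty + eps * dy, u, op, lam)
            assert j1 >= j0 - 1e-9 * j0

    def test_linearity_in_displacement(self):
        t = _dipole()
        op = build_fourier_kernel(32, 32, 1.0, SUB)
        u = forward_displacement(t, op)
        lam = 1e-3 * op.gmax
        f1 = invert_traction(u, op, lam)
        u3 = DisplacementField(3.0 * u.ux, 3.0 * u.uy, u.spacing_um, u.origin_um)
        f3 = invert_traction(u3, op, lam)
        assert np.allclose(f3.tx, 3.0 * f1.tx, rtol=1e-9, atol=1e-9)


class TestAutoLambda:
    def _noisy_forward(self, sigma, seed=0, n=32, pad_factor=2):
        rng = np.random.default_rng(seed)
        t = _dipole(n)
        op = build_fourier_kernel(n, n, 1.0, SUB, pad_factor=pad_factor)
        u0 = forward_displacement(t, op)
        u = DisplacementField(u0.ux + rng.normal(0, sigma, u0.ux.shape),
                              u0.uy + rng.normal(0, sigma, u0.uy.shape), 1.0)
        return t, op, u0, u

    def test_noise_free_data_returns_bracket_floor_and_recovers(self):
        # lattice-matched (no padding): the noiseless limit is exact
        t, op, u0, _ = self._noisy_forward(0.0, pad_factor=1)
        res = auto_lambda(u0, op, noise_sigma_um=1e-12)
        assert res.lambda_opt == pytest.approx(1e-6 * op.gmax)
        rec = res.traction
        err = np.sqrt(np.mean((rec.tx - t.tx) ** 2 + (rec.ty - t.ty) ** 2))
        assert err < 0.01 * np.sqrt(np.mean(t.tx**2 + t.ty**2))

    def test_known_noise_hits_discrepancy_target(self):
        sigma = 0.05
        t, op, u0, u = self._noisy_forward(sigma)
        res = auto_lambda(u, op, noise_sigma_um=sigma)
        n_valid = int(u.valid_mask.sum())
        target = sigma * np.sqrt(2.0 * n_valid)
        assert res.converged and res.n_iterations <= 60
        assert res.residual_norm == pytest.approx(target, rel=1e-3)
        # independent recomputation of the residual from scratch
        _, chk = invert_traction(u, op, res.lambda_opt, full_output=True)
        assert chk.residual_norm == pytest.approx(res.residual_norm, rel=1e-12)

    def test_absurd_noise_level_warns_and_caps(self):
        _, op, _, u = self._noisy_forward(0.05)
        with pytest.warns(RuntimeWarning, match="indistinguishable"):
            res = auto_lambda(u, op, noise_sigma_um=1e6)
        assert not res.converged

    def test_too_few_valid_nodes_rejected(self):
        op = build_fourier_kernel(3, 3, 1.0, SUB)
        u = DisplacementField(np.zeros((3, 3)), np.zeros((3, 3)), 1.0)
        with pytest.raises(ValueError, match="16 valid"):
            auto_lambda(u, op)


class TestInvalidNodeFill:
    def test_holes_filled_with_neighbor_medians(self):
        ux = np.ones((8, 8))
        mask = np.ones((8, 8), bool)
        mask[3, 3] = False
        ux[3, 3] = 999.0
        u = DisplacementField(ux, np.zeros((8, 8)), 1.0, valid_mask=mask)
        filled = fill_invalid_nodes(u)
        assert filled.ux[3, 3] == 1.0
        assert not filled.valid_mask[3, 3]  # provenance preserved
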