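import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfmlab.core import Point2D
from tfmlab.fields import DisplacementField
from tfmlab.focus import focus_score_edf
from tfmlab.synthetic import (
    NoiseModel,
    make_traction_dipole,
    peak_to_total_counts,
    render_beads,
    render_cell_channel,
    render_zstack,
    warp_beads,
)

H = 0.108


class TestTractionDipole:
    def test_zero_magnitude_gives_zero_field(self):
        t = make_traction_dipole((64, 64), 0.2, 0.0, 0.8, 3.0)
        assert np.all(t.tx == 0) and np.all(t.ty == 0)

    @settings(max_examples=25, deadline=None)
    @given(
        mag=st.floats(1.0, 1000.0),
        sigma=st.floats(0.5, 1.5),
        angle=st.floats(0, 2 * np.pi),
    )
    def test_force_balance(self, mag, sigma, angle):
        t = make_traction_dipole((96, 96), 0.2, mag, sigma, 3.2 * sigma, angle)
        fx, fy = t.net_force()
        total = np.sum(t.magnitude) * t.spacing_um**2
        assert abs(fx) < 1e-9 * total and abs(fy) < 1e-9 * total

    def test_peak_magnitude_close_to_nominal(self):
        t = make_traction_dipole((512, 512), H, 300.0, 2.0, 20.0)
        assert t.magnitude.max() == pytest.approx(300.0, rel=0.05)

    def test_boundary_margin_enforced(self):
        with pytest.raises(ValueError, match="3σ"):
            make_traction_dipole((64, 64), 0.1, 100.0, 1.0, 5.0)

    def test_separation_must_exceed_patch_width(self):
        with pytest.raises(ValueError, match="separation"):
            make_traction_dipole((128, 128), 0.2, 100.0, 2.0, 3.0)


class TestRenderBeads:
    def test_no_beads_no_noise_is_all_zero(self):
        img = render_beads([], [], 1.5 * H, (64, 64), H, noise_model=None)
        assert np.all(img.pixels == 0)

    def test_single_bead_centroid_unbiased(self):
        pos = (12.3456 * H, 20.789 * H)
        img = render_beads([pos], 1e4, 1.5 * H, (64, 64), H, noise_model=None)
        w = img.pixels * (img.pixels > 0.01 * img.pixels.max())
        ys, xs = np.mgrid[0:64, 0:64]
        cx = (w * xs).sum() / w.sum()
        cy = (w * ys).sum() / w.sum()
        assert cx == pytest.approx(12.3456, abs=0.02)
        assert cy == pytest.approx(20.789, abs=0.02)

    def test_same_seed_identical_images(self):
        pos = [(2.0, 2.0), (4.0, 3.0)]
        a = render_beads(pos, 5e3, 1.5 * H, (64, 64), H, NoiseModel(), rng_seed=9)
        b = render_beads(pos, 5e3, 1.5 * H, (64, 64), H, NoiseModel(), rng_seed=9)
        assert np.array_equal(a.pixels, b.pixels)

    def test_high_density_warns(self):
        rng = np.random.default_rng(0)
        n = 300  # 300 beads on 64x64 px -> 0.073 beads/px²
        pos = rng.uniform(0.5, 6.0, (n, 2))
        with pytest.warns(RuntimeWarning, match="density"):
            render_beads(pos, 1e3, 1.5 * H, (64, 64), H, noise_model=None)

    def test_undersampled_psf_rejected(self):
        with pytest.raises(ValueError, match="sampling"):
            render_beads([(1, 1)], 1e3, 0.3 * H, (64, 64), H)


class TestWarpBeads:
    def _linear_field(self):
        # u = (0.01*x + 0.02*y, -0.015*x) on a 20x20 grid, spacing 1 µm
        x = np.arange(20.0)[None, :] * np.ones((20, 1))
        y = np.arange(20.0)[:, None] * np.ones((1, 20))
        return DisplacementField(0.01 * x + 0.02 * y, -0.015 * x, 1.0)

    def test_zero_field_identity(self):
        f = DisplacementField(np.zeros((10, 10)), np.zeros((10, 10)), 1.0)
        pos = [Point2D(2.5, 3.5), Point2D(8.0, 1.0)]
        out, dropped = warp_beads(pos, f)
        assert dropped == []
        assert out[0].x == pytest.approx(2.5) and out[1].y == pytest.approx(1.0)

    def test_uniform_field_shifts_exactly(self):
        f = DisplacementField(np.full((10, 10), 0.5), np.zeros((10, 10)), 1.0)
        out, _ = warp_beads([Point2D(4.0, 4.0)], f)
        assert out[0].x == pytest.approx(4.5, abs=1e-12)

    def test_linear_field_interpolates_exactly(self):
        f = self._linear_field()
        pts = [Point2D(3.3, 7.7), Point2D(12.25, 4.5)]
        out, _ = warp_beads(pts, f)
        for p, q in zip(pts, out):
            assert q.x - p.x == pytest.approx(0.01 * p.x + 0.02 * p.y, abs=1e-9)
            assert q.y - p.y == pytest.approx(-0.015 * p.x, abs=1e-9)

    def test_beads_leaving_grid_are_dropped_and_reported(self):
        f = DisplacementField(np.full((10, 10), 2.0), np.zeros((10, 10)), 1.0)
        out, dropped = warp_beads([Point2D(8.5, 5.0), Point2D(1.0, 1.0)], f)
        assert dropped == [0]
        assert len(out) == 1

    def test_uncovered_bead_rejected(self):
        f = DisplacementField(np.zeros((5, 5)), np.zeros((5, 5)), 1.0)
        with pytest.raises(ValueError, match="cover"):
            warp_beads([Point2D(10.0, 1.0)], f)


class TestZStack:
    def test_focus_slice_is_sharpest_by_laplacian_energy(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(2.0, 11.0, (60, 2))
        stack = render_zstack(
            pos, 2e4, 1.5 * H, (128, 128), H, n_slices=14, dz_um=0.2,
            focus_index=7, noise_model=None,
        )
        scores = [focus_score_edf(s) for s in stack]
        assert int(np.argmax(scores)) == 7

    def test_defocus_rate_zero_gives_identical_slices(self):
        stack = render_zstack(
            [(3.0, 3.0)], 1e4, 1.5 * H, (64, 64), H, n_slices=4, dz_um=0.2,
            focus_index=1, defocus_rate=0.0, noise_model=None,
        )
        for s in stack[1:]:
            assert np.array_equal(s.pixels, stack[0].pixels)

    def test_single_slice_stack(self):
        stack = render_zstack([(3.0, 3.0)], 1e4, 1.5 * H, (64, 64), H,
                              n_slices=1, dz_um=0.2, focus_index=0, noise_model=None)
        assert len(stack) == 1

    def test_focus_index_bounds(self):
        with pytest.raises(ValueError):
            render_zstack([(3.0, 3.0)], 1e4, 1.5 * H, (64, 64), H,
                          n_slices=3, dz_um=0.2, focus_index=3)


class TestCellChannel:
    def test_plain_ellipse_mask_matches_analytic(self):
        from tfmlab.cellmetrics import segment_cell

        img, mask, pts = render_cell_channel((128, 128), 0.2, (12.8, 12.8), (8.0, 6.0), 0)
        seg = segment_cell(img)
        jac = (seg.mask & mask).sum() / (seg.mask | mask).sum()
        assert jac > 0.95
        assert pts == []

    def test_adhesion_count_matches_request(self):
        img, mask, pts = render_cell_channel(
            (192, 192), 0.2, (19.2, 19.2), (12.0, 9.0), n_adhesions=10, rng_seed=1
        )
        assert len(pts) == 10
        # puncta are non-overlapping by construction: threshold above the
        # plateau level isolates exactly ten components
        from scipy import ndimage

        _, n = ndimage.label(img.pixels > 900.0)
        assert n == 10

    def test_same_seed_identical(self):
        a = render_cell_channel((64, 64), 0.2, (6.4, 6.4), (4.0, 3.0), 3, rng_seed=5)
        b = render_cell_channel((64, 64), 0.2, (6.4, 6.4), (4.0, 3.0), 3, rng_seed=5)
        assert np.array_equal(a[0].pixels, b[0].pixels)

    def test_ellipse_must_fit(self):
        with pytest.raises(ValueError, match="fit"):
            render_cell_channel((64, 64), 0.2, (6.4, 6.4), (10.0, 3.0), 0)


class TestSceneConsistency:
    def test_displacement_truth_is_forward_model_of_traction_truth(self, small_scene):
        from tfmlab.fttc import build_fourier_kernel, forward_displacement

        op = build_fourier_kernel(
            small_scene.traction_truth.n_rows,
            small_scene.traction_truth.n_cols,
            small_scene.traction_truth.spacing_um,
            small_scene.substrate,
            pad_factor=2,
        )
        u = forward_displacement(small_scene.traction_truth, op)
        assert np.allclose(u.ux, small_scene.displacement_truth.ux, atol=1e-12)
        assert np.allclose(u.uy, small_scene.displacement_truth.uy, atol=1e-12)

    def test_stressed_positions_are_warped_equilibrium(self, small_scene):
        disp = small_scene.displacement_at(small_scene.bead_positions)
        eq = np.array([(p.x, p.y) for p in small_scene.bead_positions])
        st_ = np.array([(p.x, p.y) for p in small_scene.bead_positions_stressed])
        assert np.allclose(eq + disp, st_, atol=1e-9)

    def test_peak_to_total_counts_round_trip(self):
        tot = peak_to_total_counts(2000.0, 1.5)
        img = render_beads([(5.0, 5.0)], tot, 1.5 * 1.0, (11, 11), 1.0, noise_model=None)
        assert img.pixels.max() == pytest.approx(2000.0, rel=1e-6)
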