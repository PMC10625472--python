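import numpy as np
import pytest
from scipy.spatial import cKDTree

from tfmlab.core import GridImage
from tfmlab.displacement import (
    MatchSet,
    detect_particles,
    hybrid_displacement,
    interpolate_to_grid,
    link_particles,
    piv_displacement,
    reject_match_outliers,
)
from tfmlab.synthetic import NoiseModel, render_beads

H = 0.108


def _bead_pair(shift_um=(0.40, -0.25), n=900, shape=(320, 320), seed=8):
    rng = np.random.default_rng(seed)
    lim_x, lim_y = (shape[1] - 10) * H, (shape[0] - 10) * H
    pos = rng.uniform(10 * H, min(lim_x, lim_y) - max(abs(shift_um[0]), abs(shift_um[1])), (n, 2))
    ref = render_beads(pos, 2e4, 1.5 * H, shape, H, NoiseModel(), rng_seed=1)
    moved = render_beads(pos + np.array(shift_um), 2e4, 1.5 * H, shape, H, NoiseModel(), rng_seed=2)
    return moved, ref, pos


class TestPIV:
    def test_self_correlation_is_zero_everywhere(self):
        _, ref, _ = _bead_pair()
        f = piv_displacement(ref, ref, 32, 0.5)
        assert f.valid_mask.all()
        assert np.abs(f.ux).max() < 1e-9 and np.abs(f.uy).max() < 1e-9

    def test_uniform_shift_recovered(self):
        moved, ref, _ = _bead_pair((0.40, -0.25))
        f = piv_displacement(moved, ref, 32, 0.5)
        assert f.valid_mask.mean() >= 0.95
        assert f.ux[f.valid_mask].mean() == pytest.approx(0.40, abs=0.1 * H)
        assert f.uy[f.valid_mask].mean() == pytest.approx(-0.25, abs=0.1 * H)

    def test_dipole_field_matches_forward_truth(self, default_scene):
        ref = default_scene.render_reference()
        frame = default_scene.render_stressed_frame(0)
        f = piv_displacement(frame, ref, 32, 0.5)
        truth = default_scene.displacement_at(
            np.column_stack([f.grid_x.ravel(), f.grid_y.ravel()])
        )
        err = np.hypot(f.ux.ravel() - truth[:, 0], f.uy.ravel() - truth[:, 1])
        rms_t = np.sqrt(np.mean(truth[:, 0] ** 2 + truth[:, 1] ** 2))
        assert np.sqrt(np.mean(err**2)) < 0.15 * rms_t

    def test_too_small_image_rejected(self):
        img = GridImage(np.random.default_rng(0).random((20, 20)), H)
        with pytest.raises(ValueError, match="too small"):
            piv_displacement(img, img, 16, 0.0)

    def test_window_and_overlap_validation(self):
        img = GridImage(np.random.default_rng(0).random((64, 64)), H)
        with pytest.raises(ValueError, match="window"):
            piv_displacement(img, img, 8, 0.5)
        with pytest.raises(ValueError, match="overlap"):
            piv_displacement(img, img, 16, 0.9)


class TestDetection:
    def test_blank_image_gives_empty_set(self):
        img = GridImage(np.zeros((64, 64)), H)
        assert len(detect_particles(img)) == 0

    def test_sparse_fixture_detected_accurately(self, sparse_bead_images):
        img, truth = sparse_bead_images
        det = detect_particles(img)
        tree = cKDTree(truth)
        d, idx = tree.query(det.positions)
        assert len(det) >= 196
        assert (d < 0.15 * H).sum() >= 196
        assert len(np.unique(idx)) == len(det)  # no duplicates
        assert np.all(det.m0 > 0)

    def test_close_pair_merged_to_one(self):
        a = (10 * H, 10 * H)
        b = (11 * H, 10 * H)  # 1 px apart, radius 3 px -> merged
        img = render_beads([a, b], [2e4, 1e4], 1.5 * H, (64, 64), H, noise_model=None)
        det = detect_particles(img)
        assert len(det) == 1

    def test_radius_validation(self):
        img = GridImage(np.zeros((64, 64)), H)
        with pytest.raises(ValueError):
            detect_particles(img, radius_px=0)


class TestLinking:
    def _sets(self, scene):
        ref = scene.render_reference()
        frame = scene.render_stressed_frame(0)
        return detect_particles(ref), detect_particles(frame), ref, frame

    def test_self_match_is_identity(self, sparse_bead_images):
        img, _ = sparse_bead_images
        det = detect_particles(img)
        m = link_particles(det, det, exploration_radius_um=0.5 * H)
        assert len(m) == len(det)
        assert np.abs(m.displacements).max() == 0.0

    def test_seeding_rescues_large_displacements(self, default_scene):
        """With max displacement ~10 px and a 2 px exploration radius, plain
        PTV misses the fast beads while the PIV-seeded search recovers them."""
        ref_set, str_set, ref, frame = self._sets(default_scene)
        piv = piv_displacement(frame, ref, 32, 0.75)
        radius = 2.0 * H
        margin = 16.0 * H
        m_plain = link_particles(ref_set, str_set, radius)
        m_seed = link_particles(ref_set, str_set, radius, seed_field=piv,
                                seed_coverage_margin_um=margin)
        frac_plain = self._true_fraction(m_plain, default_scene, ref_set, str_set)
        frac_seed = self._true_fraction(m_seed, default_scene, ref_set, str_set)
        assert frac_seed >= 0.95
        assert frac_seed > frac_plain
        assert frac_plain < 0.90  # sizeable miss rate; exact value is scene-dependent

    @staticmethod
    def _true_fraction(matches, scene, ref_set, str_set):
        """Fraction of assignable reference detections linked to the
        detection of their true partner bead."""
        eq = np.array([(p.x, p.y) for p in scene.bead_positions])
        st_ = np.array([(p.x, p.y) for p in scene.bead_positions_stressed])
        t_eq = cKDTree(eq)
        t_st = cKDTree(st_)
        _, ri = t_eq.query(ref_set.positions)
        _, si = t_st.query(str_set.positions)
        assignable = np.isin(ri, si).sum()
        ok = (ri[matches.pairs[:, 0]] == si[matches.pairs[:, 1]]).sum()
        return ok / assignable

    def test_empty_sets_rejected(self, sparse_bead_images):
        img, _ = sparse_bead_images
        det = detect_particles(img)
        from tfmlab.displacement import ParticleSet

        empty = ParticleSet(np.empty((0, 2)), np.empty(0), np.empty(0))
        with pytest.raises(ValueError, match="non-empty"):
            link_particles(det, empty, 1.0)

    def test_seed_field_must_cover_particles(self, sparse_bead_images):
        from tfmlab.fields import DisplacementField

        img, _ = sparse_bead_images
        det = detect_particles(img)
        tiny = DisplacementField(np.zeros((3, 3)), np.zeros((3, 3)), 1.0)
        with pytest.raises(ValueError, match="cover"):
            link_particles(det, det, 1.0, seed_field=tiny, seed_coverage_margin_um=0.0)

    def test_hungarian_matches_greedy_on_easy_problem(self, sparse_bead_images):
        img, _ = sparse_bead_images
        det = detect_particles(img)
        g = link_particles(det, det, 0.5 * H, method="greedy")
        h = link_particles(det, det, 0.5 * H, method="hungarian")
        assert len(g) == len(h) == len(det)


class TestGridding:
    def _matches(self, n=600, field=lambda p: 0.1 * p, seed=2):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0.0, 20.0, (n, 2))
        disp = np.apply_along_axis(field, 1, pos)
        pairs = np.column_stack([np.arange(n), np.arange(n)])
        return MatchSet(pairs, pos, disp, 0, 0)

    def test_uniform_scatter_grids_exactly(self):
        m = self._matches(field=lambda p: np.array([0.3, -0.2]))
        f = interpolate_to_grid(m, (2.0, 2.0), 2.0, 8, 8)
        assert np.allclose(f.ux[f.valid_mask], 0.3)
        assert np.allclose(f.uy[f.valid_mask], -0.2)

    def test_linear_field_recovered_on_interior(self):
        # dense structured scatter: Gaussian-weighted averaging of a linear
        # field is exact up to boundary truncation, so interior nodes match
        xy = np.arange(0.1, 20.0, 0.2)
        pos = np.stack(np.meshgrid(xy, xy), axis=-1).reshape(-1, 2)
        disp = np.column_stack([0.02 * pos[:, 0], -0.01 * pos[:, 1]])
        m = MatchSet(np.column_stack([np.arange(len(pos))] * 2), pos, disp, 0, 0)
        f = interpolate_to_grid(m, (4.0, 4.0), 1.0, 12, 12)
        gx, gy = f.grid_x, f.grid_y
        assert f.valid_mask.all()
        assert np.allclose(f.ux, 0.02 * gx, rtol=0.02, atol=1e-4)
        assert np.allclose(f.uy, -0.01 * gy, rtol=0.02, atol=1e-4)

    def test_too_few_matches_rejected(self):
        m = MatchSet(np.array([[0, 0], [1, 1]]), np.array([[0.0, 0], [1, 1]]),
                     np.zeros((2, 2)), 0, 0)
        with pytest.raises(ValueError, match="3 matched"):
            interpolate_to_grid(m, (0, 0), 1.0, 4, 4)

    def test_collinear_matches_rejected(self):
        pos = np.column_stack([np.arange(5.0), np.zeros(5)])
        m = MatchSet(np.column_stack([np.arange(5)] * 2), pos, np.zeros((5, 2)), 0, 0)
        with pytest.raises(ValueError, match="collinear"):
            interpolate_to_grid(m, (0, 0), 1.0, 4, 4)

    def test_outlier_rejection_removes_mislink(self):
        m = self._matches(n=400, field=lambda p: np.array([0.05, 0.0]))
        bad = m.displacements.copy()
        bad[7] = (1.5, -1.2)  # one mislinked pair
        m2 = MatchSet(m.pairs, m.ref_positions, bad, 0, 0)
        kept = reject_match_outliers(m2)
        assert len(kept) == len(m2) - 1
        assert 7 not in kept.pairs[:, 0]


class TestHybridConsistency:
    def test_no_nan_anywhere_and_methods_agree_on_smooth_field(self):
        moved, ref, _ = _bead_pair((0.30, 0.15), n=1200, shape=(384, 384))
        res = hybrid_displacement(moved, ref)
        piv = res.piv
        assert np.isfinite(res.field.ux).all() and np.isfinite(res.field.uy).all()
        # interior agreement between the gridded PTV-hybrid and PIV
        inner = np.zeros(piv.ux.shape, bool)
        inner[2:-2, 2:-2] = True
        d = np.hypot(res.field.ux - piv.ux, res.field.uy - piv.uy)[inner]
        assert np.sqrt(np.mean(d**2)) < 0.2 * H
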