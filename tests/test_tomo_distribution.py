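"""Plane fitting, percent deviation and depth histograms."""

import numpy as np
import pytest

from awifilm.tomo_distribution import (
    ParticleModel,
    Plane,
    deviation_histogram,
    deviation_percent,
    fit_plane,
    recover_adsorbed_fractions,
    slab_select,
)

TOP = Plane(normal=np.array([0.0, 0.0, 1.0]), offset=50.0)
BOTTOM = Plane(normal=np.array([0.0, 0.0, -1.0]), offset=50.0)


def _model(z_values, pixel_size=10.0):
    pts = np.column_stack([np.zeros((len(z_values), 2)), np.asarray(z_values, float)])
    return ParticleModel(points=pts, pixel_size=pixel_size)


class TestFitPlane:
    def test_horizontal_from_three_points(self):
        plane = fit_plane([(0, 0, 7.0), (1, 0, 7.0), (0, 1, 7.0)])
        assert abs(plane.normal[2]) == pytest.approx(1.0)
        assert plane.offset * plane.normal[2] == pytest.approx(7.0)
        assert plane.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_recovers_tilted_plane_under_noise(self):
        rng = np.random.default_rng(3)
        true_n = np.array([0.1, -0.05, 1.0])
        true_n /= np.linalg.norm(true_n)
        xy = rng.uniform(-100, 100, size=(50, 2))
        z = (20.0 - true_n[0] * xy[:, 0] - true_n[1] * xy[:, 1]) / true_n[2]
        pts = np.column_stack([xy, z + rng.normal(0, 1.0, 50)])
        plane = fit_plane(pts)
        angle = np.degrees(np.arccos(min(abs(float(plane.normal @ true_n)), 1.0)))
        assert angle < 1.0
        assert plane.residual_rms == pytest.approx(1.0, rel=0.5)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            fit_plane([(0, 0, 0), (1, 1, 1), (2, 2, 2)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_plane([(0, 0, 0), (1, 0, 0)])


class TestDeviationPercent:
    def test_midplane_is_zero(self):
        dev, _ = deviation_percent(np.array([[3.0, 4.0, 0.0]]), TOP, BOTTOM)
        assert dev[0] == pytest.approx(0.0)

    def test_on_interface_is_100(self):
        dev, side = deviation_percent(np.array([[0.0, 0.0, 50.0]]), TOP, BOTTOM)
        assert dev[0] == pytest.approx(100.0)
        assert side[0] == "top"

    def test_halfway_point(self):
        dev, side = deviation_percent(np.array([[0.0, 0.0, 25.0]]), TOP, BOTTOM)
        assert dev[0] == pytest.approx(50.0)
        assert side[0] == "top"

    def test_beyond_interface_flagged_over_100(self):
        dev, _ = deviation_percent(np.array([[0.0, 0.0, 55.0]]), TOP, BOTTOM)
        assert dev[0] > 100.0

    def test_tie_goes_to_top(self):
        _, side = deviation_percent(np.array([[1.0, 2.0, 0.0]]), TOP, BOTTOM)
        assert side[0] == "top"

    def test_coincident_planes_rejected(self):
        with pytest.raises(ValueError):
            deviation_percent(np.array([[0.0, 0.0, 0.0]]), TOP, TOP)

    def test_rigid_motion_invariance(self):
        """Deviation is unchanged when points and planes move rigidly."""
        rng = np.random.default_rng(17)
        pts = np.column_stack([
            rng.uniform(-50, 50, (100, 2)), rng.uniform(-49, 49, 100)
        ])
        dev0, side0 = deviation_percent(pts, TOP, BOTTOM)
        for _ in range(5):
            # random rotation (QR of a Gaussian matrix) + translation
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            t = rng.uniform(-100, 100, 3)
            moved = pts @ q.T + t
            def move(p: Plane) -> Plane:
                anchor = q @ (p.offset * p.normal) + t
                n = q @ p.normal
                return Plane(normal=n, offset=float(n @ anchor))
            dev, side = deviation_percent(moved, move(TOP), move(BOTTOM))
            np.testing.assert_allclose(dev, dev0, rtol=1e-9, atol=1e-9)
            np.testing.assert_array_equal(side, side0)

    def test_nonparallel_planes_use_local_thickness(self):
        tilted_top = Plane(normal=np.array([np.sin(np.radians(5)), 0.0, np.cos(np.radians(5))]),
                           offset=50.0)
        # a point on the tilted top plane still reads 100%
        p = 50.0 * tilted_top.normal
        dev, side = deviation_percent(p[None, :], tilted_top, BOTTOM)
        assert dev[0] == pytest.approx(100.0)
        assert side[0] == "top"


class TestHistogram:
    def test_even_construction_fills_bins_equally(self):
        # deviations 5,15,...,95 via z = dev/100 * 50
        z = np.array([5, 15, 25, 35, 45, 55, 65, 75, 85, 95]) / 100 * 50
        prof = deviation_histogram(_model(z), TOP, BOTTOM)
        np.testing.assert_allclose(prof.fractions[:-1], 0.2)
        assert prof.fractions[-1] == 0.0
        assert prof.fractions.sum() == pytest.approx(1.0)

    def test_all_on_interface_lands_in_outer_bin(self):
        prof = deviation_histogram(_model([50.0] * 8), TOP, BOTTOM)
        assert prof.fractions[-2] == pytest.approx(1.0)

    def test_uniform_large_sample(self):
        rng = np.random.default_rng(23)
        prof = deviation_histogram(_model(rng.uniform(-50, 50, 100_000)), TOP, BOTTOM)
        np.testing.assert_allclose(prof.fractions[:-1], 0.2, atol=0.005)

    def test_permutation_invariant_and_conserving(self):
        rng = np.random.default_rng(2)
        z = rng.uniform(-55, 55, 500)  # some overflow beyond the film
        p1 = deviation_histogram(_model(z), TOP, BOTTOM)
        p2 = deviation_histogram(_model(rng.permutation(z)), TOP, BOTTOM)
        np.testing.assert_array_equal(np.sort(p1.counts), np.sort(p2.counts))
        np.testing.assert_array_equal(p1.counts, p2.counts)
        assert p1.counts.sum() == 500
        assert p1.fractions.sum() == pytest.approx(1.0)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            deviation_histogram(_model([0.0]), TOP, BOTTOM, bin_width=30.0)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            deviation_histogram(_model([]), TOP, BOTTOM)

    def test_recover_fractions_corrects_for_bulk(self):
        rng = np.random.default_rng(4)
        z = np.concatenate([
            np.full(550, 49.0), np.full(300, -49.0), rng.uniform(-50, 50, 150)
        ])
        prof = deviation_histogram(_model(z), TOP, BOTTOM)
        est = recover_adsorbed_fractions(prof)
        assert est["f_top"] == pytest.approx(0.55, abs=0.03)
        assert est["f_bottom"] == pytest.approx(0.30, abs=0.03)
        assert est["f_bulk"] == pytest.approx(0.15, abs=0.04)


class TestSlabSelect:
    def test_distance_counting(self):
        z = np.array([50.0, 48.0, 47.6, 47.4, 40.0])  # 0, 2, 2.4, 2.6, 10 nm from top
        sel = slab_select(_model(z), TOP, thickness=5.0)
        assert len(sel) == 3

    def test_labels_follow_selection(self):
        m = ParticleModel(
            points=np.array([[0, 0, 50.0], [0, 0, 0.0]]) / 1.0, pixel_size=10.0,
            labels=("a", "b"),
        )
        sel = slab_select(m, TOP, thickness=5.0)
        assert sel.labels == ("a",)

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            slab_select(_model([0.0]), TOP, thickness=-1.0)


def test_pixel_size_conversion():
    m = ParticleModel(points=np.array([[0.0, 0.0, 100.0]]), pixel_size=4.4)
    assert m.points_nm[0, 2] == pytest.approx(44.0)
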