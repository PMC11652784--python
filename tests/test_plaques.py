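"""Plaque neighborhoods, halo intensity and slope comparison."""

import numpy as np
import pytest

from conftest import plane_from
from gliaquant import simgen
from gliaquant.imaging import ImagePlane
from gliaquant.plaques import (
    PlaqueRecord,
    compare_slopes,
    count_plaques_and_clusters,
    default_background,
    detect_plaques,
    exclude_overlaps,
    halo_intensity,
    neighborhood_mask,
    plaques_to_frame,
    regress_intensity_on_area,
)


def square_plaque_scene(size=200, top=95, side=10, value=200):
    img = np.zeros((size, size), bool)
    img[top : top + side, top : top + side] = True
    return plane_from(img, value=value)


class TestDetect:
    def test_blank_channel_empty(self):
        assert detect_plaques(plane_from(np.zeros((64, 64), bool))) == []

    def test_square_plaque_geometry(self):
        records = detect_plaques(square_plaque_scene())
        assert len(records) == 1
        p = records[0]
        assert p.feret_um == pytest.approx(10 * np.sqrt(2))
        assert p.neighborhood_radius_um == pytest.approx(4 * 10 * np.sqrt(2))

    def test_synthetic_scene_count_matches_truth(self):
        spec = simgen.PlaqueSpec(n_plaques=4)
        plane, _, truth = simgen.generate_plaque_scene(spec, seed=21)
        assert len(detect_plaques(plane)) == len(truth) == 4

    def test_neighborhood_disk_area(self):
        records = detect_plaques(square_plaque_scene(size=600, top=295))
        p = records[0]
        disk = neighborhood_mask(p, (600, 600))
        expected = np.pi * p.neighborhood_radius_um**2
        assert disk.sum() == pytest.approx(expected, rel=0.02)


class TestExcludeOverlaps:
    @staticmethod
    def _scene(centers, size=400, side=6):
        img = np.zeros((size, size), bool)
        for r, c in centers:
            img[r : r + side, c : c + side] = True
        return detect_plaques(plane_from(img))

    def test_far_apart_not_excluded(self):
        records = self._scene([(50, 50), (300, 300)])
        exclude_overlaps(records)
        assert not any(p.excluded for p in records)

    def test_coincident_both_excluded(self):
        records = self._scene([(100, 100), (108, 100)])
        exclude_overlaps(records)
        assert all(p.excluded for p in records)

    def test_idempotent_and_order_independent(self):
        import random

        centers = [(40, 40), (60, 60), (250, 250), (330, 60), (60, 330)]
        records = self._scene(centers)
        exclude_overlaps(records)
        flags = [p.excluded for p in records]
        exclude_overlaps(records)
        assert [p.excluded for p in records] == flags
        shuffled = self._scene(centers)
        random.Random(3).shuffle(shuffled)
        exclude_overlaps(shuffled)
        by_id = {p.plaque_id: p.excluded for p in shuffled}
        assert [by_id[p.plaque_id] for p in records] == flags

    def test_survivors_have_pairwise_disjoint_disks(self, rng):
        for trial in range(5):
            centers = [tuple(rng.integers(30, 360, 2)) for _ in range(6)]
            records = self._scene(centers)
            exclude_overlaps(records)
            kept = [p for p in records if not p.excluded]
            for i, a in enumerate(kept):
                for b in kept[i + 1 :]:
                    d = np.hypot(*(np.array(a.centroid) - np.array(b.centroid)))
                    assert d >= a.neighborhood_radius_um + b.neighborhood_radius_um


class TestHaloIntensity:
    def test_uniform_channel_zero(self):
        records = detect_plaques(square_plaque_scene())
        glial = ImagePlane(np.full((200, 200), 40, dtype=np.uint8), 1.0)
        bg = np.zeros((200, 200), bool)
        bg[:10, :10] = True
        assert halo_intensity(glial, records[0], bg) == 0.0

    def test_flat_disk_arithmetic(self):
        records = detect_plaques(square_plaque_scene())
        p = records[0]
        disk = neighborhood_mask(p, (200, 200))
        pixels = np.full((200, 200), 30, dtype=np.uint8)
        pixels[disk] = 130
        glial = ImagePlane(pixels, 1.0)
        bg = ~disk
        # background mean 30, disk at 130 -> 100 per pixel
        assert halo_intensity(glial, p, bg) == pytest.approx(100 * disk.sum())

    def test_subthreshold_pixels_not_counted(self):
        records = detect_plaques(square_plaque_scene())
        p = records[0]
        disk = neighborhood_mask(p, (200, 200))
        pixels = np.full((200, 200), 10, dtype=np.uint8)
        pixels[disk] = 25  # above background but below the 30 threshold
        glial = ImagePlane(pixels, 1.0)
        assert halo_intensity(glial, p, ~disk) == 0.0

    def test_excluded_plaque_rejected(self):
        records = detect_plaques(square_plaque_scene())
        records[0].excluded = True
        glial = ImagePlane(np.zeros((200, 200), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError):
            halo_intensity(glial, records[0], np.ones((200, 200), bool))

    def test_empty_background_rejected(self):
        records = detect_plaques(square_plaque_scene())
        glial = ImagePlane(np.zeros((200, 200), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError):
            halo_intensity(glial, records[0], np.zeros((200, 200), bool))

    def test_monotone_in_pixel_intensity(self):
        records = detect_plaques(square_plaque_scene())
        p = records[0]
        disk = neighborhood_mask(p, (200, 200))
        pixels = np.full((200, 200), 5, dtype=np.uint8)
        pixels[disk] = 100
        lo = halo_intensity(ImagePlane(pixels.copy(), 1.0), p, ~disk)
        pixels[disk] = 150
        hi = halo_intensity(ImagePlane(pixels, 1.0), p, ~disk)
        assert hi > lo >= 0

    def test_truth_recovery_on_synthetic_scene(self):
        spec = simgen.PlaqueSpec(sigma=0.0)
        plaque_plane, glial_plane, truth = simgen.generate_plaque_scene(spec, seed=31)
        records = detect_plaques(plaque_plane)
        exclude_overlaps(records)
        bg = default_background(glial_plane, records)
        for rec, t in zip(records, truth):
            measured = halo_intensity(glial_plane, rec, bg)
            assert measured == pytest.approx(t.painted_excess, abs=1.0)


class TestRegression:
    def test_exact_line(self):
        pts = [(x, 2.0 * x + 5.0) for x in (1.0, 2.0, 3.0, 7.0)]
        fit = regress_intensity_on_area(pts)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        fit = regress_intensity_on_area([(1.0, 3.0), (2.0, 3.0), (4.0, 3.0)])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError):
            regress_intensity_on_area([(1.0, 2.0), (2.0, 3.0)])
        with pytest.raises(ValueError):
            regress_intensity_on_area([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])

    def test_slope_ci_covers_generating_value(self):
        # Vehicle-like parameterization with noise at R^2 ~ 0.6.
        spec = simgen.PlaqueSpec(sigma=0.0)
        areas = simgen.rng_for(1, "areas").uniform(50, 400, 60)
        spec.sigma = simgen.sigma_for_r2(spec.beta1, areas, 0.6)
        hits = 0
        reps = 200
        for rep in range(reps):
            pts = simgen.sample_halo_records(spec, seed=1000 + rep, n=60)
            fit = regress_intensity_on_area(pts)
            hits += int(fit.slope_ci[0] <= spec.beta1 <= fit.slope_ci[1])
        assert 0.90 <= hits / reps <= 0.99


class TestCompareSlopes:
    def test_duplicated_group_zero_difference(self):
        pts = [(float(x), 3.0 * x + 1.0 + (x % 3)) for x in range(12)]
        comps = compare_slopes({"ref": pts, "dup": list(pts)}, reference="ref")
        assert comps[0].slope_difference == pytest.approx(0.0, abs=1e-9)

    def test_distinct_slopes_detected(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(50, 400, 60)
        ref = list(zip(x, 633.8 * x + 276179 + rng.normal(0, 5000, 60)))
        x2 = rng.uniform(50, 400, 60)
        tr = list(zip(x2, 191.5 * x2 + 105632 + rng.normal(0, 5000, 60)))
        comps = compare_slopes({"Veh": ref, "HE-S": tr}, reference="Veh")
        assert comps[0].group == "HE-S"
        assert comps[0].p_value < 0.01
        assert comps[0].slope_difference < 0

    def test_missing_reference(self):
        with pytest.raises(ValueError):
            compare_slopes({"a": [(0, 0)] * 3}, reference="zzz")

    def test_type_i_error_near_alpha(self):
        # Identical generating slopes: the interaction test should reject
        # at about the nominal 5% rate.
        rng = np.random.default_rng(17)
        reps, hits = 300, 0
        for _ in range(reps):
            x1 = rng.uniform(50, 400, 40)
            x2 = rng.uniform(50, 400, 40)
            g1 = list(zip(x1, 600.0 * x1 + 1e5 + rng.normal(0, 2e4, 40)))
            g2 = list(zip(x2, 600.0 * x2 + 1e5 + rng.normal(0, 2e4, 40)))
            comps = compare_slopes({"a": g1, "b": g2}, reference="a")
            hits += int(comps[0].p_value < 0.05)
        assert 0.02 <= hits / reps <= 0.09


class TestCounts:
    def test_blank_channels(self):
        blank = plane_from(np.zeros((64, 64), bool))
        assert count_plaques_and_clusters(blank, blank, blank) == (0, 0, 0)

    def test_shape_mismatch(self):
        a = plane_from(np.zeros((64, 64), bool))
        b = plane_from(np.zeros((32, 32), bool))
        with pytest.raises(ValueError):
            count_plaques_and_clusters(a, b, a)

    def test_one_cluster_per_plaque(self):
        size = 300
        plaque_img = np.zeros((size, size), bool)
        glial_img = np.zeros((size, size), bool)
        for top in (60, 200):
            plaque_img[top : top + 8, top : top + 8] = True
            glial_img[top + 15 : top + 22, top : top + 7] = True  # inside disk
        outside = np.zeros((size, size), bool)
        outside[5:12, 280:287] = True  # far from both neighborhoods
        counts = count_plaques_and_clusters(
            plane_from(plaque_img),
            plane_from(glial_img | outside),
            plane_from(glial_img),
        )
        assert counts == (2, 2, 2)


def test_plaques_to_frame_roundtrip():
    records = detect_plaques(square_plaque_scene())
    df = plaques_to_frame(records)
    assert df.loc[0, "plaque_id"] == 1
    assert df.loc[0, "neighborhood_radius_um"] == pytest.approx(records[0].neighborhood_radius_um)
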