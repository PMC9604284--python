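"""Colony shape descriptors and center-of-mass paths against closed-form
oracles (analytic disks, squares, rectangles, ellipses)."""

import numpy as np
import pytest

from colonytrack import errors, morphology
from colonytrack.io import ColonyMaskStack
from conftest import make_track, make_trackset, rasterize_disk, rasterize_ellipse


def _stack(pages, pixel_size=1.0, frame_interval=60.0):
    return ColonyMaskStack(
        masks=np.stack(pages).astype(np.int32),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
    )


class TestAreaPerimeter:
    def test_square_area_counts_pixels(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[5:15, 5:15] = 1
        assert morphology.colony_area(mask, 1, pixel_size=1.0) == pytest.approx(100.0)
        assert morphology.colony_area(mask, 1, pixel_size=2.0) == pytest.approx(400.0)

    def test_disk_area_within_2pct_of_analytic(self):
        mask = rasterize_disk(20)
        area = morphology.colony_area(mask, 1, pixel_size=1.0)
        assert area == pytest.approx(np.pi * 20**2, rel=0.02)

    def test_disk_perimeter_within_2pct_of_circumference(self):
        mask = rasterize_disk(50)
        perim = morphology.colony_perimeter(mask, 1, pixel_size=1.0)
        assert perim == pytest.approx(2 * np.pi * 50, rel=0.02)

    def test_single_pixel_blob_has_positive_perimeter(self):
        mask = np.zeros((5, 5), dtype=np.int32)
        mask[2, 2] = 1
        perim = morphology.colony_perimeter(mask, 1, pixel_size=1.0)
        assert 0 < perim < 5

    def test_internal_hole_adds_to_perimeter(self):
        solid = np.zeros((30, 30), dtype=np.int32)
        solid[5:25, 5:25] = 1
        holed = solid.copy()
        holed[12:18, 12:18] = 0
        p_solid = morphology.colony_perimeter(solid, 1, pixel_size=1.0)
        p_holed = morphology.colony_perimeter(holed, 1, pixel_size=1.0)
        assert p_holed > p_solid

    def test_absent_label_raises(self):
        mask = rasterize_disk(5)
        with pytest.raises(errors.NotFoundError):
            morphology.colony_area(mask, 9, pixel_size=1.0)
        with pytest.raises(errors.NotFoundError):
            morphology.colony_perimeter(mask, 9, pixel_size=1.0)


class TestCircularity:
    @pytest.mark.parametrize(
        "S,P,expected",
        [
            (np.pi * 7.0**2, 2 * np.pi * 7.0, 1.0),  # analytic disk
            (4.0**2, 4 * 4.0, np.pi / 4),  # square
            (10.0 * 1.0, 22.0, 40 * np.pi / 484),  # 10:1 rectangle
        ],
    )
    def test_closed_forms(self, S, P, expected):
        assert morphology.circularity(S, P) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(errors.DomainError):
            morphology.circularity(0.0, 10.0)
        with pytest.raises(errors.DomainError):
            morphology.circularity(10.0, -1.0)

    @pytest.mark.parametrize("radius", [50, 80])
    def test_rasterized_disk_near_one(self, radius):
        mask = rasterize_disk(radius)
        S = morphology.colony_area(mask, 1, 1.0)
        P = morphology.colony_perimeter(mask, 1, 1.0)
        assert abs(morphology.circularity(S, P) - 1.0) < 0.05

    def test_scale_invariance_in_pixel_size(self):
        mask = rasterize_ellipse(30, 18, angle_deg=20)
        vals = []
        for ps in (1.0, 2.0):
            S = morphology.colony_area(mask, 1, ps)
            P = morphology.colony_perimeter(mask, 1, ps)
            vals.append(morphology.circularity(S, P))
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)

    def test_rotation_robustness_of_ellipse_circularity(self):
        vals = []
        for angle in (0, 30, 45):
            mask = rasterize_ellipse(40, 20, angle_deg=angle)
            S = morphology.colony_area(mask, 1, 1.0)
            P = morphology.colony_perimeter(mask, 1, 1.0)
            vals.append(morphology.circularity(S, P))
        assert (max(vals) - min(vals)) / np.mean(vals) < 0.03


class TestShapeTimeseries:
    def test_growing_disk_area_increases_circularity_near_one(self):
        stack = _stack([rasterize_disk(r, pad=60 - r) for r in (20, 30, 40, 50)])
        records = morphology.shape_timeseries(stack, 1)
        areas = [r.area_um2 for r in records]
        assert all(a < b for a, b in zip(areas, areas[1:]))
        assert all(abs(r.circularity - 1) < 0.05 for r in records)

    def test_disk_to_ellipse_morph_circularity_decreases(self):
        pages = [
            rasterize_ellipse(30 * s, 30 / s, pad=int(100 - 30 * s))
            for s in (1.0, 1.3, 1.6, 2.0)
        ]
        size = max(p.shape[0] for p in pages)
        pages = [np.pad(p, ((0, size - p.shape[0]), (0, size - p.shape[1]))) for p in pages]
        records = morphology.shape_timeseries(_stack(pages), 1)
        circs = [r.circularity for r in records]
        assert all(a > b for a, b in zip(circs, circs[1:]))

    def test_constant_mask_gives_identical_records(self):
        stack = _stack([rasterize_disk(15)] * 3)
        r0, r1, r2 = morphology.shape_timeseries(stack, 1)
        assert r0.area_um2 == r1.area_um2 == r2.area_um2
        assert r0.circularity == r2.circularity

    def test_missing_frames_yield_none_not_zero(self):
        empty = np.zeros_like(rasterize_disk(10))
        stack = _stack([rasterize_disk(10), empty, rasterize_disk(10)])
        records = morphology.shape_timeseries(stack, 1)
        assert records[1] is None and records[0] is not None

    def test_label_absent_everywhere_raises(self):
        stack = _stack([rasterize_disk(10)])
        with pytest.raises(errors.NotFoundError):
            morphology.shape_timeseries(stack, 7)


def _records_with_circularities(circs, t_step=24.0):
    return [
        morphology.ColonyShapeRecord(
            frame=k,
            time_h=k * t_step,
            area_um2=100.0,
            perimeter_um=np.sqrt(400 * np.pi / c),
            circularity=c,
        )
        for k, c in enumerate(circs)
    ]


class TestEndpointComparison:
    def test_all_zero_differences_give_p_one(self):
        colonies = [_records_with_circularities([0.8, 0.8]) for _ in range(4)]
        res = morphology.compare_endpoint_circularity(colonies, 0.0, 24.0)
        assert res["pvalue"] == 1.0
        assert res["mean_difference"] == pytest.approx(0.0)

    def test_halving_circularity_detected_at_n6(self):
        # exact two-sided signed-rank null at n=6: all ranks one-signed -> p = 2/2**6
        colonies = [
            _records_with_circularities([c0, c0 / 2])
            for c0 in (0.9, 0.85, 0.8, 0.75, 0.7, 0.65)
        ]
        res = morphology.compare_endpoint_circularity(colonies, 0.0, 24.0)
        assert res["mean_difference"] == pytest.approx(-np.mean([0.9, 0.85, 0.8, 0.75, 0.7, 0.65]) / 2)
        assert res["pvalue"] == pytest.approx(2 / 64, rel=1e-6)
        assert res["pvalue"] < 0.05

    def test_two_colonies_insufficient(self):
        colonies = [_records_with_circularities([0.8, 0.4]) for _ in range(2)]
        with pytest.raises(errors.InsufficientDataError):
            morphology.compare_endpoint_circularity(colonies, 0.0, 24.0)


class TestCenterOfMass:
    def test_mean_of_two_cells(self):
        ts = make_trackset(
            [make_track([(0, 0), (0, 0)], cell_id="a"), make_track([(2, 4), (2, 4)], cell_id="b")]
        )
        np.testing.assert_allclose(morphology.center_of_mass(ts, 0), [1.0, 2.0])

    def test_single_cell_is_its_position(self):
        ts = make_trackset([make_track([(3, -7), (4, -6)], cell_id="a")])
        np.testing.assert_allclose(morphology.center_of_mass(ts, 1), [4.0, -6.0])

    def test_translation_equivariance_and_permutation_invariance(self, rng):
        pts = rng.normal(0, 20, size=(30, 2))
        tracks = [make_track([p, p + 1.0], cell_id=f"c{k}") for k, p in enumerate(pts)]
        ts = make_trackset(tracks)
        com = morphology.center_of_mass(ts, 0)
        shifted = make_trackset(
            [make_track([p + [5, 5], p + [6, 6]], cell_id=f"c{k}") for k, p in enumerate(pts)]
        )
        np.testing.assert_allclose(
            morphology.center_of_mass(shifted, 0), com + [5, 5], atol=1e-9
        )
        perm = rng.permutation(30)
        permuted = make_trackset(
            [make_track([pts[j], pts[j] + 1.0], cell_id=f"c{k}") for k, j in enumerate(perm)]
        )
        np.testing.assert_allclose(morphology.center_of_mass(permuted, 0), com, atol=1e-12)

    def test_missing_frame_raises(self):
        ts = make_trackset([make_track([(0, 0), (1, 1)], cell_id="a")])
        with pytest.raises(errors.NotFoundError):
            morphology.center_of_mass(ts, 99)


class TestCentroidPath:
    def test_stationary_cells_stay_at_origin(self):
        tracks = [make_track([(5, 5)] * 4, cell_id="a"), make_track([(9, 1)] * 4, cell_id="b")]
        cp = morphology.centroid_path(make_trackset(tracks))
        np.testing.assert_allclose(cp.xy, 0.0, atol=1e-12)

    def test_constant_velocity_gives_straight_line(self):
        v = np.array([1.5, -2.0])  # µm per frame
        tracks = [
            make_track([(k * v[0] + x0, k * v[1] + y0) for k in range(5)], cell_id=f"c{x0}")
            for x0, y0 in [(0, 0), (10, 3)]
        ]
        cp = morphology.centroid_path(make_trackset(tracks, frame_interval=15))
        expected = np.outer(np.arange(5), v)
        np.testing.assert_allclose(cp.xy, expected, atol=1e-9)

    def test_first_point_is_origin_and_empty_raises(self):
        with pytest.raises(errors.EmptyInputError):
            morphology.centroid_path(make_trackset([]))

    def test_equals_mean_of_rebased_tracks_when_all_share_frames(self, rng):
        from colonytrack.migration import rebase_trajectory

        tracks = [
            make_track(np.cumsum(rng.normal(0, 2, size=(6, 2)), axis=0), cell_id=f"c{k}")
            for k in range(8)
        ]
        ts = make_trackset(tracks)
        cp = morphology.centroid_path(ts)
        mean_rebased = np.mean([rebase_trajectory(t).xy for t in tracks], axis=0)
        np.testing.assert_allclose(cp.xy, mean_rebased - mean_rebased[0], atol=1e-9)
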