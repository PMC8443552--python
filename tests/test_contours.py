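"""Contour data model, file dialects, resampling and mask extraction."""

import json
import math

import numpy as np
import pytest

from lvstrain.contours import (
    CineStudy,
    ContourPolygon,
    Layer,
    SliceFrame,
    Timepoint,
    extract_contour_from_mask,
    read_contour_study,
    resample_contour,
    smooth_contour,
    validate_study,
    write_contour_study,
)
from lvstrain.errors import (
    DataError,
    GeometryError,
    ParameterError,
    StudyFormatError,
    StudyValidationError,
)
from lvstrain.strain import border_length
from lvstrain.volumetrics import polygon_area

from .conftest import circle_polygon, square_polygon


class TestContourPolygon:
    def test_closed_needs_three_points(self):
        with pytest.raises(GeometryError):
            ContourPolygon(np.array([[0, 0], [1, 1]]), Layer.ENDOCARDIUM, closed=True)

    def test_open_allows_two_points(self):
        poly = ContourPolygon(np.array([[0, 0], [3, 4]]), Layer.ENDOCARDIUM, closed=False)
        assert len(poly) == 2

    def test_rejects_consecutive_duplicates(self):
        pts = np.array([[0, 0], [1, 0], [1, 0], [0, 1]], float)
        with pytest.raises(GeometryError):
            ContourPolygon(pts, Layer.ENDOCARDIUM)

    def test_rejects_repeated_first_point_when_closed(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 0]], float)
        with pytest.raises(GeometryError):
            ContourPolygon(pts, Layer.ENDOCARDIUM, closed=True)

    def test_simplicity_detection(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)
        assert not ContourPolygon(bowtie, Layer.ENDOCARDIUM).is_simple()
        assert square_polygon().is_simple()


class TestStudyIO:
    def make_study(self, n_slices=2, n_frames=2):
        short_axis = []
        for i in range(n_slices):
            cine = []
            for k in range(n_frames):
                cine.append(
                    SliceFrame(
                        slice_index=i, z_mm=float(i * 8), thickness_mm=8.0,
                        frame_index=k, time_ms=k * 40.0,
                        contours={
                            Layer.ENDOCARDIUM: square_polygon(10.0 - k),
                            Layer.EPICARDIUM: square_polygon(14.0, Layer.EPICARDIUM),
                        },
                    )
                )
            short_axis.append(cine)
        long_axis = [
            SliceFrame(0, 0.0, 1.0, k, k * 40.0,
                       {Layer.ENDOCARDIUM: ContourPolygon(
                           np.array([[0, 0], [5, -40 - k], [10, 0]], float),
                           Layer.ENDOCARDIUM, closed=False)})
            for k in range(n_frames)
        ]
        return CineStudy("pig01", Timepoint.BASELINE, 62.5, short_axis, long_axis)

    def test_minimal_json_study(self, tmp_path):
        doc = {
            "subject_id": "s", "timepoint": "baseline", "weight_kg": 60.0,
            "short_axis": [{
                "slice_index": 0, "z_mm": 0.0, "thickness_mm": 8.0,
                "frames": [
                    {"frame_index": 0, "time_ms": 0.0,
                     "endocardium": [[0, 0], [10, 0], [10, 10], [0, 10]]},
                    {"frame_index": 1, "time_ms": 40.0,
                     "endocardium": [[0, 0], [9, 0], [9, 9], [0, 9]]},
                ],
            }],
        }
        path = tmp_path / "minimal.json"
        path.write_text(json.dumps(doc))
        study = read_contour_study(path)
        assert study.n_slices == 1 and study.n_frames == 2

    @pytest.mark.parametrize("fmt", ["json", "csv"])
    def test_round_trip_identity(self, tmp_path, fmt, healthy_phantom):
        study, _ = healthy_phantom
        path = tmp_path / f"study.{fmt}"
        write_contour_study(study, path)
        back = read_contour_study(path)
        assert back.subject_id == study.subject_id
        assert back.timepoint == study.timepoint
        assert back.weight_kg == study.weight_kg
        assert back.n_slices == study.n_slices and back.n_frames == study.n_frames
        for cine_a, cine_b in zip(study.short_axis, back.short_axis):
            for fa, fb in zip(cine_a, cine_b):
                assert fa.z_mm == fb.z_mm and fa.time_ms == fb.time_ms
                for layer in fa.contours:
                    np.testing.assert_array_equal(
                        fa.contours[layer].points, fb.contours[layer].points
                    )
        for fa, fb in zip(study.long_axis, back.long_axis):
            np.testing.assert_array_equal(
                fa.contour(Layer.ENDOCARDIUM).points,
                fb.contour(Layer.ENDOCARDIUM).points,
            )

    def test_write_read_write_is_byte_stable(self, tmp_path):
        study = self.make_study()
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_contour_study(study, p1)
        write_contour_study(read_contour_study(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_uneven_frame_count_names_slice(self, tmp_path):
        study = self.make_study(n_slices=4, n_frames=3)
        doc = json.loads((lambda p: (write_contour_study(study, p), p.read_text())[1])(
            tmp_path / "s.json"))
        del doc["short_axis"][2]["frames"][2]  # slice 2 now has one frame fewer
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps(doc))
        with pytest.raises(StudyValidationError, match="slice 2"):
            read_contour_study(bad)

    def test_malformed_json_reports_parse_error(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"subject_id": "x", ')
        with pytest.raises(StudyFormatError, match="line"):
            read_contour_study(path)


class TestResample:
    def test_unit_square_preserves_perimeter_and_corners(self):
        out = resample_contour(square_polygon(), 8)
        assert len(out) == 8
        assert border_length(out) == pytest.approx(4.0, abs=1e-9)
        # corners lie on the arc-length walk at multiples of 0.5
        for corner in [(0, 0), (1, 0), (1, 1), (0, 1)]:
            assert np.any(np.all(np.isclose(out.points, corner), axis=1))

    def test_circle_downsampling_matches_chord_formula(self):
        fine = circle_polygon(30.0, 256)
        coarse = resample_contour(fine, 64)
        expected = 2 * 64 * 30.0 * math.sin(math.pi / 64)
        # resampled vertices lie on the fine polygon, not the circle, so
        # allow the fine polygon's own chord error as slack
        assert border_length(coarse) == pytest.approx(expected, rel=1e-3)
        assert border_length(coarse) < border_length(fine)

    def test_open_segment_preserves_length(self):
        seg = ContourPolygon(np.array([[0, 0], [3, 4]], float), Layer.ENDOCARDIUM, closed=False)
        out = resample_contour(seg, 8)
        assert len(out) == 8
        assert border_length(out) == pytest.approx(5.0, abs=1e-12)
        d = out.points[-1] - out.points[0]
        rel = out.points[1:-1] - out.points[0]
        cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
        np.testing.assert_allclose(cross, 0.0, atol=1e-12)

    def test_idempotent_at_fixed_point_count(self):
        # once the polygon's segments are uniform, re-resampling is identity
        poly = circle_polygon(20.0, 64)
        once = resample_contour(poly, 32)
        twice = resample_contour(once, 32)
        np.testing.assert_allclose(once.points, twice.points, atol=1e-9)
        sq = resample_contour(square_polygon(), 8)
        np.testing.assert_allclose(resample_contour(sq, 8).points, sq.points,
                                   atol=1e-9)

    def test_rejects_too_few_points(self):
        with pytest.raises(ParameterError):
            resample_contour(square_polygon(), 7)

    def test_smooth_window_validation(self):
        with pytest.raises(ParameterError):
            smooth_contour(square_polygon(), 4)


class TestMaskExtraction:
    def test_filled_square_area(self):
        mask = np.zeros((10, 10), bool)
        mask[3:7, 2:6] = True
        poly = extract_contour_from_mask(mask, (1.0, 1.0))
        assert poly.closed
        assert polygon_area(poly) == pytest.approx(16.0)

    def test_pixel_spacing_scales_area(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        poly = extract_contour_from_mask(mask, (0.5, 2.0))
        assert polygon_area(poly) == pytest.approx(16 * 0.5 * 2.0)

    def test_empty_mask_raises(self):
        with pytest.raises(DataError):
            extract_contour_from_mask(np.zeros((5, 5), bool))

    def test_two_components_named_in_error(self):
        mask = np.zeros((10, 10), bool)
        mask[1:3, 1:3] = True
        mask[6:8, 6:8] = True
        with pytest.raises(DataError, match="2"):
            extract_contour_from_mask(mask)

    def test_hole_warns_and_returns_outer_boundary(self):
        mask = np.zeros((8, 8), bool)
        mask[1:7, 1:7] = True
        mask[3:5, 3:5] = False
        with pytest.warns(UserWarning, match="holes"):
            poly = extract_contour_from_mask(mask)
        assert polygon_area(poly) == pytest.approx(36.0)

    def test_convex_mask_area_matches_pixel_count(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            h, w = rng.integers(3, 8, 2)
            mask = np.zeros((12, 12), bool)
            mask[2:2 + h, 2:2 + w] = True
            poly = extract_contour_from_mask(mask)
            assert polygon_area(poly) == pytest.approx(float(h * w))


class TestValidateStudy:
    def test_phantom_study_is_clean(self, healthy_phantom):
        study, _ = healthy_phantom
        assert validate_study(study).ok

    def test_non_monotone_z_flagged(self, healthy_phantom):
        study, _ = healthy_phantom
        broken = CineStudy(
            study.subject_id, study.timepoint, study.weight_kg,
            [study.short_axis[0], study.short_axis[2], study.short_axis[1]],
            study.long_axis,
        )
        assert "Z_ORDER" in validate_study(broken).codes()

    def test_missing_layer_on_one_frame_flagged(self, healthy_phantom):
        study, _ = healthy_phantom
        cine = list(study.short_axis[1])
        f = cine[3]
        contours = {Layer.ENDOCARDIUM: f.contours[Layer.ENDOCARDIUM]}
        cine[3] = SliceFrame(f.slice_index, f.z_mm, f.thickness_mm,
                             f.frame_index, f.time_ms, contours)
        broken = CineStudy(
            study.subject_id, study.timepoint, study.weight_kg,
            [study.short_axis[0], cine] + list(study.short_axis[2:]),
            study.long_axis,
        )
        report = validate_study(broken)
        assert "LAYER_GAP" in report.codes()
        assert any(e.frame_index == 3 for e in report.errors)
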