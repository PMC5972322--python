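"""Cross-section vector model: generator, resampling, symmetrization, averaging."""

import math

import numpy as np
import pytest

import cordfit as cf
from cordfit.contours import (
    Contour,
    CrossSection,
    anterior_gray_width,
    dorsal_horn_angle,
    read_geojson,
    write_contours_csv,
    write_geojson,
)


def _circle(r=1.0, n=64):
    # vertex 0 at the dorsal midline crossing (0, r), counter-clockwise
    phi = np.linspace(0, 2 * math.pi, n, endpoint=False) + math.pi / 2
    return Contour(np.column_stack([r * np.cos(phi), r * np.sin(phi)]))


def _mirror(contour: Contour) -> Contour:
    """Mirror image about x=0, re-indexed to stay CCW with a midline start."""
    v = contour.vertices
    n = len(v)
    return Contour(v[(n - np.arange(n)) % n] * np.array([-1.0, 1.0]))


class TestSyntheticGenerator:
    def test_valid_geometry(self):
        cs = cf.generate_synthetic_cross_section(cf.source_params("A"), "T7", seed=1)
        assert len(cs.outer) >= 16 and len(cs.gray) >= 16
        assert cs.outer.polygon.is_valid and cs.gray.polygon.is_valid
        assert cs.outer.polygon.contains(cs.gray.polygon)
        assert cs.gray.area < cs.outer.area

    def test_zero_noise_symmetric(self):
        import dataclasses
        params = dataclasses.replace(cf.source_params("A"), asymmetry_mm=0.0)
        cs = cf.generate_synthetic_cross_section(params, "T7", seed=1)
        for c in (cs.outer, cs.gray):
            v, n = c.vertices, len(c)
            assert np.max(np.abs(v[:, 0] + v[(n - np.arange(n)) % n, 0])) < 1e-9

    def test_dorsal_horn_angle_increases_cranially(self):
        params = cf.source_params("A")
        angles = [dorsal_horn_angle(cf.generate_synthetic_cross_section(params, s, seed=2))
                  for s in ("T12", "T9", "T5", "T2")]
        assert all(a < b for a, b in zip(angles, angles[1:]))

    def test_sources_differ_in_anterior_gray_width(self):
        a = cf.generate_synthetic_cross_section(cf.source_params("A"), "T7", seed=1)
        b = cf.generate_synthetic_cross_section(cf.source_params("B"), "T7", seed=1, source_id="B")
        assert abs(anterior_gray_width(a) - anterior_gray_width(b)) > 0.1

    def test_bad_parameters_fail_with_diagnostic(self):
        import dataclasses
        params = dataclasses.replace(cf.source_params("A"), dorsal_horn_length_mm=12.0)
        with pytest.raises(ValueError):
            cf.generate_synthetic_cross_section(params, "T2", seed=0)


class TestResample:
    def test_square_arc_length_spacing(self):
        square = Contour(np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]]))
        r = cf.resample_contour(square, 8)
        assert r.perimeter == pytest.approx(8.0)
        expected = {(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)}
        got = {tuple(np.round(p, 9)) for p in r.vertices}
        assert got == expected
        seg = np.diff(np.vstack([r.vertices, r.vertices[:1]]), axis=0)
        assert np.allclose(np.hypot(seg[:, 0], seg[:, 1]), 1.0)

    def test_idempotent_on_uniform_input(self):
        c = _circle(r=3.0, n=64)
        r = cf.resample_contour(c, 64)
        assert np.allclose(r.vertices, c.vertices, atol=1e-9)

    def test_circle_perimeter_limit(self):
        c = _circle(r=2.0, n=2048)
        assert c.perimeter == pytest.approx(2 * math.pi * 2.0, rel=1e-3)
        r = cf.resample_contour(c, 512)
        assert r.perimeter == pytest.approx(c.perimeter, rel=0.01)

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError):
            cf.resample_contour(Contour(np.zeros((8, 2))), 16)


class TestSymmetrize:
    def test_symmetric_input_is_fixed_point(self):
        cs = CrossSection(outer=_circle(4.0, 128), gray=_circle(2.0, 128), segment="T7")
        out = cf.symmetrize_cross_section(cs)
        assert np.allclose(out.outer.vertices, cs.outer.vertices, atol=1e-9)
        assert np.allclose(out.gray.vertices, cs.gray.vertices, atol=1e-9)

    def test_output_mirror_symmetric_and_centered(self):
        cs = cf.generate_synthetic_cross_section(cf.source_params("A"), "T5", seed=8)
        shifted = Contour(np.where(cs.outer.vertices[:, [0]] < 0,
                                   cs.outer.vertices - [0.2, 0.0], cs.outer.vertices))
        out = cf.symmetrize_cross_section(CrossSection(outer=shifted, gray=cs.gray, segment="T5"))
        for c in (out.outer, out.gray):
            v, n = c.vertices, len(c)
            assert np.max(np.abs(v[:, 0] + v[(n - np.arange(n)) % n, 0])) < 1e-9
        assert abs(out.outer.polygon.centroid.x) < 1e-9

    def test_idempotence_on_noisy_input(self):
        cs = cf.generate_synthetic_cross_section(cf.source_params("B"), "T3", seed=5, source_id="B")
        once = cf.symmetrize_cross_section(cs)
        twice = cf.symmetrize_cross_section(once)
        assert np.max(np.abs(twice.outer.vertices - once.outer.vertices)) < 1e-12
        assert np.max(np.abs(twice.gray.vertices - once.gray.vertices)) < 1e-12


class TestScale:
    def test_identity_at_current_dimensions(self):
        cs = cf.generate_synthetic_cross_section(cf.source_params("A"), "T7", seed=1)
        w, h = cs.outer.width_height()
        out = cf.scale_cross_section(cs, w, h)
        assert np.allclose(out.outer.vertices, cs.outer.vertices)

    def test_unit_circle_to_ellipse(self):
        cs = CrossSection(outer=_circle(1.0, 512), gray=_circle(0.5, 512))
        out = cf.scale_cross_section(cs, 10.0, 7.0)
        assert out.outer.width_height() == pytest.approx((10.0, 7.0), abs=1e-9)
        assert out.outer.area == pytest.approx(math.pi * 10 * 7 / 4, rel=1e-3)

    def test_exact_bounding_box_and_invertibility(self, table):
        cs = cf.generate_synthetic_cross_section(cf.source_params("A"), "T7", seed=3)
        w, h = cs.outer.width_height()
        out = cf.scale_cross_section(cs, 8.4, 6.3)
        assert out.outer.width_height() == pytest.approx((8.4, 6.3), abs=1e-9)
        back = cf.scale_cross_section(out, w, h)
        assert np.allclose(back.outer.vertices, cs.outer.vertices, atol=1e-12)

    def test_invalid_targets(self):
        cs = CrossSection(outer=_circle(1.0), gray=_circle(0.5))
        with pytest.raises(ValueError):
            cf.scale_cross_section(cs, -1.0, 5.0)


class TestAverage:
    def test_identity_on_identical_inputs(self):
        cs = cf.generate_synthetic_cross_section(cf.source_params("A"), "T7", seed=1)
        out = cf.average_cross_sections([cs, cs, cs])
        assert np.allclose(out.outer.vertices, cs.outer.vertices)
        assert out.segment == "T7"

    def test_mirror_pair_averages_to_symmetric(self):
        cs = cf.generate_synthetic_cross_section(cf.source_params("A"), "T4", seed=9)
        mirrored = CrossSection(outer=_mirror(cs.outer), gray=_mirror(cs.gray), segment="T4")
        out = cf.average_cross_sections([cs, mirrored])
        for c in (out.outer, out.gray):
            v, n = c.vertices, len(c)
            assert np.max(np.abs(v[:, 0] + v[(n - np.arange(n)) % n, 0])) < 1e-9

    def test_mismatched_point_counts_rejected(self):
        a = CrossSection(outer=_circle(1.0, 64), gray=_circle(0.5, 64))
        b = CrossSection(outer=_circle(1.0, 128), gray=_circle(0.5, 128))
        with pytest.raises(ValueError):
            cf.average_cross_sections([a, b])


@pytest.fixture(scope="module")
def model(table):
    return cf.build_average_thoracic_model(table, seed=0, n_points=192)


class TestAveragedModel:
    def test_combined_symmetric_and_contained(self, model):
        comb = model["combined"]
        v, n = comb.outer.vertices, len(comb.outer)
        assert np.max(np.abs(v[:, 0] + v[(n - np.arange(n)) % n, 0])) < 1e-9
        assert comb.outer.polygon.contains(comb.gray.polygon)

    def test_combined_angle_between_sources(self, model):
        # tip-vertex angle measurement is approximate (the argmax vertex can
        # shift between the averaged shapes), so allow a couple of degrees
        a = dorsal_horn_angle(model["A"])
        b = dorsal_horn_angle(model["B"])
        comb = dorsal_horn_angle(model["combined"])
        assert min(a, b) - 2.0 <= comb <= max(a, b) + 2.0


def test_geojson_and_csv_round_trip(tmp_path):
    cs = cf.generate_synthetic_cross_section(cf.source_params("A"), "T7", seed=1)
    path = tmp_path / "sections.geojson"
    write_geojson([cs], path)
    (back,) = read_geojson(path)
    assert back.segment == "T7"
    assert np.allclose(back.outer.vertices, cs.outer.vertices)
    assert np.allclose(back.gray.vertices, cs.gray.vertices)
    write_contours_csv([cs], tmp_path / "contours.csv")
    import pandas as pd
    df = pd.read_csv(tmp_path / "contours.csv")
    assert len(df) == len(cs.outer) + len(cs.gray)
    assert set(df["role"]) == {"outer", "gray"}
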