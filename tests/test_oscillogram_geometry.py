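"""Endplate tilts, oscillogram construction, extrema and Cobb derivation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oscillocobb import (
    CaseViews,
    DegenerateGeometryError,
    Point2D,
    Region,
    RunConfig,
    TiltSeries,
    View,
    apex_of,
    build_oscillogram,
    detect_curves,
    endplate_tilt,
    find_extrema,
    measure_case,
    region_cobb,
    sagittal_kyphosis_T5_T12,
)
from oscillocobb.oscillogram_geometry import N_ENDPLATES, REGION_SPANS, endplate_index

from conftest import set_from_tilts


# ---------------------------------------------------------------------------
# endplate_tilt
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "left,right,expected",
    [
        ((0, 0), (10, 0), 0.0),
        ((0, 0), (10, 10), 45.0),
        ((0, 5), (20, 0), math.degrees(math.atan2(-5, 20))),
    ],
)
def test_endplate_tilt_examples(left, right, expected):
    assert endplate_tilt(Point2D(*left), Point2D(*right)) == pytest.approx(expected)


def test_vertical_endplate_is_degenerate():
    with pytest.raises(DegenerateGeometryError):
        endplate_tilt(Point2D(3, 0), Point2D(3, 9))


def test_rotated_rectangle_recovers_rotation_angle():
    """A rectangle rotated by 17 deg about its centre has 17-deg endplates."""
    phi = math.radians(17.0)
    w, h = 90.0, 60.0
    corners = {}
    for name, (cx, cy) in {"ul": (-w / 2, -h / 2), "ur": (w / 2, -h / 2)}.items():
        corners[name] = Point2D(
            cx * math.cos(phi) - cy * math.sin(phi),
            cx * math.sin(phi) + cy * math.cos(phi),
        )
    assert endplate_tilt(corners["ul"], corners["ur"]) == pytest.approx(17.0, abs=1e-9)


@settings(derandomize=True, deadline=None)
@given(
    tilt=st.floats(-40, 40),
    phi=st.floats(-30, 30),
    scale=st.floats(0.1, 50),
    tx=st.floats(-1e4, 1e4),
    ty=st.floats(-1e4, 1e4),
)
def test_tilt_equivariance_under_similarity_transforms(tilt, phi, scale, tx, ty):
    """Translation and uniform scaling leave the tilt unchanged; rotation by
    phi adds phi."""
    t = math.radians(tilt)
    left, right = Point2D(0.0, 0.0), Point2D(45 * math.cos(t), 45 * math.sin(t))

    def transform(p: Point2D) -> Point2D:
        r = math.radians(phi)
        x = scale * (p.x * math.cos(r) - p.y * math.sin(r)) + tx
        y = scale * (p.x * math.sin(r) + p.y * math.cos(r)) + ty
        return Point2D(x, y)

    assert endplate_tilt(transform(left), transform(right)) == pytest.approx(
        tilt + phi, abs=1e-6
    )


# ---------------------------------------------------------------------------
# build_oscillogram
# ---------------------------------------------------------------------------

def test_straight_spine_gives_34_zeros(straight_set):
    series = build_oscillogram(straight_set)
    assert series.values.shape == (N_ENDPLATES,)
    np.testing.assert_allclose(series.values, 0.0, atol=1e-12)


def test_prescribed_tilts_are_recovered_exactly(tilts_builder):
    rng = np.random.default_rng(11)
    tilts = rng.uniform(-35, 35, 34)
    series = build_oscillogram(tilts_builder(tilts))
    np.testing.assert_allclose(series.values, tilts, atol=1e-9)


def test_oscillogram_invariant_under_translation_and_scale(tilts_builder):
    import dataclasses

    from oscillocobb import LandmarkSet, VertebraCorners

    tilts = np.linspace(-20, 20, 34)
    s = tilts_builder(tilts)

    def remap(s: LandmarkSet, f) -> LandmarkSet:
        verts = tuple(
            VertebraCorners(v.label, f(v.ul), f(v.ur), f(v.ll), f(v.lr))
            for v in s.vertebrae
        )
        return dataclasses.replace(s, vertebrae=verts)

    moved = remap(s, lambda p: Point2D(3.0 * p.x + 500, 3.0 * p.y - 40))
    np.testing.assert_allclose(
        build_oscillogram(moved).values, build_oscillogram(s).values, atol=1e-9
    )


def test_mirroring_negates_tilts(tilts_builder):
    tilts = np.linspace(-20, 20, 34)
    s = tilts_builder(tilts)
    np.testing.assert_allclose(
        build_oscillogram(s.mirrored()).values, -build_oscillogram(s).values, atol=1e-9
    )


# ---------------------------------------------------------------------------
# find_extrema
# ---------------------------------------------------------------------------

def _series(values):
    return TiltSeries(View.CORONAL, np.asarray(values, dtype=float))


def test_flat_series_has_no_extrema():
    assert find_extrema(_series(np.zeros(34)), 5.0) == []


def test_monotone_series_has_terminal_trough_and_peak():
    ext = find_extrema(_series(np.linspace(-20, 20, 34)), 5.0)
    assert [(e.index, e.polarity) for e in ext] == [(0, "trough"), (33, "peak")]


def test_single_curve_series_keeps_only_its_peak_and_trough():
    """0 ... +15 at 8 ... -18 at 22 ... 0: the neutral boundary endplates are
    not curve termini, only the interior peak/trough pair survives."""
    v = np.concatenate(
        [
            np.linspace(0, 15, 9),
            np.linspace(15, -18, 15)[1:],
            np.linspace(-18, 0, 12)[1:],
        ]
    )
    assert v.shape == (34,)
    ext = find_extrema(_series(v), 5.0)
    assert [(e.index, e.polarity) for e in ext] == [(8, "peak"), (22, "trough")]


def test_extrema_alternate_and_meet_prominence():
    rng = np.random.default_rng(4)
    for _ in range(100):
        v = rng.normal(0, 12, 34)
        ext = find_extrema(_series(np.clip(v, -60, 60)), 5.0)
        for a, b in zip(ext, ext[1:]):
            assert a.polarity != b.polarity
            assert abs(a.value - b.value) >= 5.0
        for e in ext:
            assert e.prominence >= 5.0


def test_plateau_extremum_uses_most_cranial_index():
    v = np.zeros(34)
    v[10:13] = 20.0
    ext = find_extrema(_series(v), 5.0)
    assert [(e.index, e.polarity) for e in ext] == [(10, "peak")]


# ---------------------------------------------------------------------------
# region_cobb / apex / kyphosis
# ---------------------------------------------------------------------------

def test_region_cobb_flat_is_zero():
    for region in Region:
        cobb, imax, imin = region_cobb(_series(np.zeros(34)), region)
        assert cobb == 0.0
        assert imax == imin == REGION_SPANS[region][0]  # cranial tie-break


def test_region_cobb_is_span_range():
    v = np.zeros(34)
    v[10], v[20] = 15.0, -18.0
    cobb, imax, imin = region_cobb(_series(v), Region.MT)
    assert (cobb, imax, imin) == (33.0, 10, 20)


def test_apex_of_symmetric_arc_is_middle_vertebra(tilts_builder):
    # arc through T5..T11: lateral displacement peaks at T8
    t = np.arange(34.0)
    tilts = 20 * (t - 16.0) / 8.0 * np.exp(-((t - 16.0) ** 2) / 50.0)
    s = tilts_builder(tilts)
    # rebuild with lateral drift so centroids trace the arc
    from oscillocobb.synthetic_spine import SpineSimParams, CurveSpec, simulate_case

    params = SpineSimParams(
        curves=(CurveSpec("T8", 20.0, width=0.12),), landmark_noise_sd=0.0
    )
    views, _ = simulate_case(params)
    assert apex_of("T5", "T11", views.coronal) == "T8"


def test_apex_of_straight_segment_is_cranial_neighbour(straight_set):
    assert apex_of("T5", "T11", straight_set) == "T6"


def test_kyphosis_t5_t12_arithmetic(tilts_builder):
    tilts = np.zeros(34)
    tilts[endplate_index("T5", "superior")] = -20.0
    tilts[endplate_index("T12", "inferior")] = 25.0
    series = build_oscillogram(tilts_builder(tilts, view=View.SAGITTAL))
    assert sagittal_kyphosis_T5_T12(series) == pytest.approx(45.0, abs=1e-9)


def test_kyphosis_requires_sagittal_view(straight_set):
    with pytest.raises(ValueError, match="sagittal"):
        sagittal_kyphosis_T5_T12(build_oscillogram(straight_set))


# ---------------------------------------------------------------------------
# detect_curves / measure_case
# ---------------------------------------------------------------------------

def test_flat_spine_reports_zero_cobb_fallback(straight_set):
    curves = detect_curves(build_oscillogram(straight_set), straight_set)
    assert [c.region for c in curves] == list(Region)
    assert all(c.cobb == 0.0 and not c.from_extrema for c in curves)


def test_single_thoracic_curve_matches_region_oracle():
    from oscillocobb.synthetic_spine import preset_for_type, simulate_case
    import dataclasses

    params = dataclasses.replace(preset_for_type(1), landmark_noise_sd=0.0)
    views, _ = simulate_case(params)
    series = build_oscillogram(views.coronal)
    curves = {c.region: c for c in detect_curves(series, views.coronal)}
    assert curves[Region.MT].from_extrema
    assert curves[Region.MT].cobb == pytest.approx(
        region_cobb(series, Region.MT)[0], abs=1e-9
    )


def test_detected_cobb_never_exceeds_region_oracle():
    from oscillocobb.synthetic_spine import preset_for_type, simulate_case
    import dataclasses

    for k in range(1, 7):
        params = dataclasses.replace(preset_for_type(k), landmark_noise_sd=0.0)
        views, _ = simulate_case(params)
        series = build_oscillogram(views.coronal)
        for c in detect_curves(series, views.coronal):
            assert c.cobb <= region_cobb(series, c.region)[0] + 1e-9


def test_cobb_invariant_under_mirroring():
    from oscillocobb.synthetic_spine import preset_for_type, simulate_case
    import dataclasses

    params = dataclasses.replace(preset_for_type(3), landmark_noise_sd=0.0)
    views, _ = simulate_case(params)
    orig = {c.region: c for c in detect_curves(build_oscillogram(views.coronal), views.coronal)}
    mirr_set = views.coronal.mirrored()
    mirr = {c.region: c for c in detect_curves(build_oscillogram(mirr_set), mirr_set)}
    for region in Region:
        assert mirr[region].cobb == pytest.approx(orig[region].cobb, abs=1e-9)
        if orig[region].convexity != "none":
            assert mirr[region].convexity != orig[region].convexity


def test_measure_case_coronal_only_degrades_gracefully(straight_set):
    m = measure_case(CaseViews(case_id="c", coronal=straight_set))
    assert m.kyphosis_t5_t12 is None
    assert m.bending_residual is None
    assert m.lenke.curve_type is None
    assert any("bending" in n for n in m.notes + m.lenke.notes)


def test_measure_case_requires_coronal(straight_set):
    with pytest.raises((ValueError, AttributeError)):
        measure_case(CaseViews(case_id="c", coronal=None))


def test_full_case_populates_all_indicators():
    from oscillocobb.synthetic_spine import preset_for_type, simulate_case
    import dataclasses

    params = dataclasses.replace(preset_for_type(1), landmark_noise_sd=0.0)
    views, _ = simulate_case(params)
    m = measure_case(views)
    assert set(m.curves) == set(Region)
    assert m.kyphosis_t5_t12 is not None
    assert set(m.bending_cobb) == {"left_bending", "right_bending"}
    assert m.bending_residual is not None
    assert m.lenke.curve_type == 1
    assert m.lenke.sagittal_modifier is not None
    assert m.lenke.lumbar_modifier is None


def test_locked_bending_ends_use_coronal_end_vertebrae():
    from oscillocobb.synthetic_spine import preset_for_type, simulate_case
    import dataclasses

    params = dataclasses.replace(preset_for_type(1), landmark_noise_sd=0.0)
    views, _ = simulate_case(params)
    cfg = RunConfig(lock_end_vertebrae_on_bending=True)
    m = measure_case(views, cfg)
    series = build_oscillogram(views.right_bending)
    c = m.curves[Region.MT]
    expected = abs(series.values[c.upper_index] - series.values[c.lower_index])
    assert m.bending_cobb["right_bending"][Region.MT] == pytest.approx(expected, abs=1e-9)


def test_measurement_round_trips_through_json():
    from oscillocobb.synthetic_spine import preset_for_type, simulate_case
    from oscillocobb import CaseMeasurement
    import dataclasses, json

    params = dataclasses.replace(preset_for_type(2), landmark_noise_sd=0.0)
    views, _ = simulate_case(params)
    m = measure_case(views)
    restored = CaseMeasurement.from_dict(json.loads(json.dumps(m.to_dict())))
    assert restored.curves[Region.MT].cobb == m.curves[Region.MT].cobb
    assert restored.lenke.curve_type == m.lenke.curve_type
    assert restored.bending_residual == m.bending_residual
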