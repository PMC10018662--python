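import numpy as np
import pytest
from scipy.spatial.distance import cdist

from wbrt_aperture.aperture import ApertureConfig, AperturePolygon, design_aperture
from wbrt_aperture.qa import (
    EvaluationROI,
    compare_approaches,
    densify_boundary,
    evaluation_roi,
    hausdorff,
    mean_surface_distance,
)

from fixture_rect import make_structures


def _square(size=50.0, shift=(0.0, 0.0)):
    u0, v0 = shift
    return AperturePolygon(
        vertices=np.array(
            [[u0, v0], [u0 + size, v0], [u0 + size, v0 + size], [u0, v0 + size]]
        )
    )


def _random_polygon(rng, n=8, radius=40.0):
    """Star-shaped polygon: sorted angles, random radii (always simple)."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    radii = rng.uniform(0.3, 1.0, size=n) * radius
    center = rng.uniform(-20, 20, size=2)
    verts = np.stack(
        [center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)], axis=1
    )
    return AperturePolygon(vertices=verts)


def _brute_force_hd_msd(poly_a, poly_b):
    pa, pb = densify_boundary(poly_a), densify_boundary(poly_b)
    d = cdist(pa, pb)
    a_to_b = d.min(axis=1)
    b_to_a = d.min(axis=0)
    return max(a_to_b.max(), b_to_a.max()), 0.5 * (a_to_b.mean() + b_to_a.mean())


def test_identical_polygons_have_zero_distances():
    sq = _square()
    assert hausdorff(sq, sq) == 0.0
    assert mean_surface_distance(sq, sq) == 0.0


def test_translated_square_closed_forms():
    a, b = _square(), _square(shift=(3.0, 0.0))
    assert hausdorff(a, b) == pytest.approx(3.0, abs=1e-9)
    msd = mean_surface_distance(a, b)
    assert 0.0 < msd <= 3.0


def test_distances_match_brute_force_oracle_on_random_pairs():
    rng = np.random.default_rng(99)
    for _ in range(30):
        a, b = _random_polygon(rng), _random_polygon(rng)
        hd_ref, msd_ref = _brute_force_hd_msd(a, b)
        assert hausdorff(a, b) == pytest.approx(hd_ref, abs=1e-9)
        assert mean_surface_distance(a, b) == pytest.approx(msd_ref, abs=1e-9)


def test_symmetry_and_hd_dominates_msd():
    rng = np.random.default_rng(5)
    for _ in range(10):
        a, b = _random_polygon(rng), _random_polygon(rng)
        assert hausdorff(a, b) == pytest.approx(hausdorff(b, a))
        assert mean_surface_distance(a, b) == pytest.approx(mean_surface_distance(b, a))
        assert hausdorff(a, b) >= mean_surface_distance(a, b)


def test_joint_translation_invariance():
    rng = np.random.default_rng(8)
    a, b = _random_polygon(rng), _random_polygon(rng)
    t = np.array([17.0, -4.0])
    at = AperturePolygon(vertices=a.vertices + t)
    bt = AperturePolygon(vertices=b.vertices + t)
    assert hausdorff(at, bt) == pytest.approx(hausdorff(a, b), abs=1e-9)
    assert mean_surface_distance(at, bt) == pytest.approx(
        mean_surface_distance(a, b), abs=1e-9
    )


def test_roi_clipping_never_increases_hd():
    a, b = _square(), _square(shift=(4.0, 2.0))
    roi = EvaluationROI(u_range=(-10.0, 30.0), v_range=(-10.0, 60.0))
    assert hausdorff(a, b, roi) <= hausdorff(a, b) + 1e-9


def test_roi_that_strips_a_boundary_raises():
    a = _square()
    roi = EvaluationROI(u_range=(200.0, 300.0), v_range=(200.0, 300.0))
    with pytest.raises(ValueError):
        hausdorff(a, _square(shift=(210.0, 210.0)), roi)


# -- evaluation ROI ---------------------------------------------------------


def test_roi_rectangle_fixture_hand_check():
    roi = evaluation_roi(make_structures(), ApertureConfig())
    # vertebra union posterior 20 - 5 ; forehead anterior 110 + 20
    assert roi.u_range == pytest.approx((15.0, 130.0))
    # caudal C1 edge 30 and skin top 130 + flash 15, padded by 5 each way
    assert roi.v_range == pytest.approx((25.0, 150.0))


def test_roi_contains_landmark_b_for_random_phantoms(random_volumes, geometry):
    from wbrt_aperture.projection import project_structures

    for vol in random_volumes[:6]:
        structures = project_structures(vol, geometry)
        roi = evaluation_roi(structures)
        _, landmarks = design_aperture(structures)
        b = np.array([landmarks["B"]])
        assert roi.contains(b).all()


def test_empty_roi_raises():
    with pytest.raises(ValueError, match="empty ROI"):
        EvaluationROI(u_range=(10.0, 10.0), v_range=(0.0, 5.0))


def test_missing_vertebra_raises():
    structures = make_structures()
    structures.masks["C1"][:] = False
    structures.masks["C2"][:] = False
    with pytest.raises(ValueError, match="C1"):
        evaluation_roi(structures)


# -- comparator -------------------------------------------------------------


def test_identical_apertures_pass():
    sq = _square()
    report = compare_approaches(sq, sq)
    assert report.verdict == "pass"
    assert report.hd == 0.0 and report.msd == 0.0


def test_large_translation_flags():
    report = compare_approaches(_square(), _square(shift=(20.0, 0.0)))
    assert report.verdict == "flag"
    assert report.reason


def test_custom_thresholds_change_verdict():
    a, b = _square(), _square(shift=(3.0, 0.0))
    assert compare_approaches(a, b).verdict == "pass"
    strict = compare_approaches(a, b, thresholds={"hd_mm": 1.0, "msd_mm": 0.5})
    assert strict.verdict == "flag"


def test_frame_mismatch_raises():
    a = _square()
    b = _square()
    b.gantry_deg = 90
    with pytest.raises(ValueError, match="frame mismatch"):
        compare_approaches(a, b)
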