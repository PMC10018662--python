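import itertools

import numpy as np
import pytest
from shapely.geometry import Point

from wbrt_aperture.aperture import (
    ApertureConfig,
    bounding_box,
    build_aperture,
    compute_landmarks,
    design_aperture,
    expand_brain,
    fit_mlc,
    mirror_aperture,
)
from wbrt_aperture.projection import (
    BeamGeometry,
    Grid2D,
    mask_to_polyline,
    project_structures,
)

from fixture_rect import (
    GRID,
    check_landmarks,
    expected_landmarks,
    make_structures,
)


# -- bounding_box -----------------------------------------------------------


def test_bounding_box_single_pixel():
    grid = Grid2D(origin=(0.0, 0.0), spacing=(1.0, 1.0), shape=(30, 30))
    mask = np.zeros(grid.shape, dtype=bool)
    mask[10, 20] = True
    assert bounding_box(mask, grid) == (9.5, 10.5, 19.5, 20.5)


def test_bounding_box_matches_exhaustive_scan():
    rng = np.random.default_rng(2)
    grid = Grid2D(origin=(-7.5, 3.0), spacing=(0.5, 2.0), shape=(25, 18))
    mask = rng.random(grid.shape) < 0.1
    umin, umax, vmin, vmax = bounding_box(mask, grid)
    us, vs = [], []
    for iu in range(grid.shape[0]):
        for iv in range(grid.shape[1]):
            if mask[iu, iv]:
                us.append(grid.origin[0] + iu * 0.5)
                vs.append(grid.origin[1] + iv * 2.0)
    assert umin == pytest.approx(min(us) - 0.25)
    assert umax == pytest.approx(max(us) + 0.25)
    assert vmin == pytest.approx(min(vs) - 1.0)
    assert vmax == pytest.approx(max(vs) + 1.0)


def test_bounding_box_empty_mask_raises():
    grid = Grid2D(origin=(0.0, 0.0), spacing=(1.0, 1.0), shape=(5, 5))
    with pytest.raises(ValueError):
        bounding_box(np.zeros(grid.shape, bool), grid)


# -- expand_brain -----------------------------------------------------------


def test_expand_brain_zero_margin_is_identity():
    structures = make_structures()
    expanded, _ = expand_brain(structures.masks["brain"], GRID, 0.0)
    assert np.array_equal(expanded, structures.masks["brain"])


def test_expand_brain_single_pixel_disk_area():
    grid = Grid2D(origin=(0.5, 0.5), spacing=(1.0, 1.0), shape=(40, 40))
    mask = np.zeros(grid.shape, dtype=bool)
    mask[20, 20] = True
    expanded, _ = expand_brain(mask, grid, 10.0)
    assert abs(expanded.sum() - np.pi * 100.0) / (np.pi * 100.0) < 0.05


def test_expand_brain_grows_bounding_box_by_margin():
    structures = make_structures()
    before = bounding_box(structures.masks["brain"], GRID)
    expanded, _ = expand_brain(structures.masks["brain"], GRID, 12.0)
    after = bounding_box(expanded, GRID)
    for i, sign in enumerate((-1, 1, -1, 1)):
        assert after[i] - before[i] == pytest.approx(sign * 12.0, abs=1.0)


def test_expand_brain_negative_margin_raises():
    with pytest.raises(ValueError):
        expand_brain(make_structures().masks["brain"], GRID, -1.0)


# -- landmarks on the hand-checkable rectangle fixture ----------------------


@pytest.mark.parametrize(
    "ab_shape, bc_position, ce_shape, include_orbits",
    list(itertools.product(
        ["horizontal", "diagonal"],
        ["lens", "mid", "eye"],
        ["follow_expansion", "straight"],
        [False, True],
    )),
)
def test_rectangle_fixture_landmarks_match_hand_derivation(
    ab_shape, bc_position, ce_shape, include_orbits
):
    structures = make_structures()
    config = ApertureConfig(
        ab_shape=ab_shape,
        bc_position=bc_position,
        ce_shape=ce_shape,
        include_orbits=include_orbits,
    )
    landmarks = compute_landmarks(structures, config)
    expected = expected_landmarks(ab_shape, bc_position, ce_shape, include_orbits)
    check_landmarks(landmarks, expected, include_orbits)


def test_bc_option_shifts_only_b_and_c():
    structures = make_structures()
    lm_lens = compute_landmarks(structures, ApertureConfig(bc_position="lens"))
    lm_eye = compute_landmarks(structures, ApertureConfig(bc_position="eye"))
    # lens box posterior 98, eye box posterior 84
    assert lm_lens["B"][0] - lm_eye["B"][0] == pytest.approx(14.0)
    for name in ("A", "E", "F", "G", "H", "I"):
        assert lm_lens[name] == pytest.approx(lm_eye[name])


def test_caudal_vertebra_option_moves_fg():
    structures = make_structures()
    lm1 = compute_landmarks(structures, ApertureConfig(caudal_vertebra="C1"))
    lm2 = compute_landmarks(structures, ApertureConfig(caudal_vertebra="C2"))
    assert lm1["F"][1] == pytest.approx(30.0)
    assert lm2["F"][1] == pytest.approx(13.0)
    assert lm2["G"][1] < lm1["G"][1]


def test_missing_structure_is_named():
    structures = make_structures()
    del structures.masks["lens_L"]
    with pytest.raises(ValueError, match="lens_L"):
        compute_landmarks(structures, ApertureConfig())


def test_landmark_c_undefined_is_an_error():
    structures = make_structures()
    # Push the lens box far anterior of the expanded brain's reach.
    structures.masks["lens_L"] = np.roll(structures.masks["lens_L"], 20, axis=0)
    structures.masks["lens_R"] = structures.masks["lens_L"].copy()
    with pytest.raises(ValueError, match="landmark C undefined"):
        compute_landmarks(structures, ApertureConfig(bc_position="lens", brain_margin=10.0))


# -- build_aperture ---------------------------------------------------------


def test_rectangle_fixture_straight_gives_nine_vertex_polygon():
    structures = make_structures()
    config = ApertureConfig(ce_shape="straight")
    _, boundary = expand_brain(structures.masks["brain"], GRID, config.brain_margin)
    landmarks = compute_landmarks(structures, config, expanded_boundary=boundary)
    polygon = build_aperture(landmarks, boundary, config)
    assert len(polygon.vertices) == 9
    order = ["I", "A", "B", "C", "D", "E", "F", "G", "H"]
    np.testing.assert_allclose(
        polygon.vertices, [landmarks[k] for k in order], atol=1e-9
    )


def test_brain_stays_inside_aperture_for_every_config(gt_structures):
    boundary = mask_to_polyline(gt_structures.masks["brain"], gt_structures.grid)[0]
    for config in (
        ApertureConfig(),
        ApertureConfig(ab_shape="horizontal", bc_position="eye", ce_shape="straight"),
        ApertureConfig(include_orbits=True),
        ApertureConfig(brain_margin=10.0, skin_flash=10.0),
        ApertureConfig(caudal_vertebra="C2", brain_margin=20.0, skin_flash=20.0),
    ):
        polygon, _ = design_aperture(gt_structures, config)
        shape = polygon.shapely
        assert all(shape.contains(Point(*q)) for q in boundary[:-1]), config


def _lens_centers(structures):
    out = []
    for side in ("L", "R"):
        iu, iv = np.nonzero(structures.masks[f"lens_{side}"])
        out.append(
            (
                structures.grid.origin[0] + structures.grid.spacing[0] * iu.mean(),
                structures.grid.origin[1] + structures.grid.spacing[1] * iv.mean(),
            )
        )
    return out


def test_lens_centers_out_unless_orbits_included(gt_structures):
    centers = _lens_centers(gt_structures)
    shielded, _ = design_aperture(gt_structures, ApertureConfig(bc_position="lens"))
    treated, _ = design_aperture(gt_structures, ApertureConfig(include_orbits=True))
    for c in centers:
        assert not shielded.shapely.contains(Point(*c))
        assert treated.shapely.contains(Point(*c))


# -- mirror -----------------------------------------------------------------


def test_mirror_is_an_involution_and_preserves_area(gt_structures):
    polygon, _ = design_aperture(gt_structures)
    twice = mirror_aperture(mirror_aperture(polygon))
    np.testing.assert_allclose(twice.vertices, polygon.vertices, atol=1e-9)
    assert mirror_aperture(polygon).area == pytest.approx(polygon.area)
    assert mirror_aperture(polygon).gantry_deg == 90


def test_gantry_90_aperture_equals_mirror_of_gantry_270(default_volume):
    g90 = BeamGeometry(gantry_deg=90, pixel_spacing=(1.0, 1.0))
    structures90 = project_structures(default_volume, g90)
    ap90, _ = design_aperture(structures90)
    g270 = BeamGeometry(gantry_deg=270, pixel_spacing=(1.0, 1.0))
    ap270, _ = design_aperture(project_structures(default_volume, g270))
    mirrored = mirror_aperture(ap270)
    # same polygon up to vertex ordering: compare via symmetric difference
    sym = ap90.shapely.symmetric_difference(mirrored.shapely)
    assert sym.area < 1e-6 * ap90.area


# -- MLC fitting ------------------------------------------------------------


def test_mlc_on_grid_aligned_rectangle():
    from wbrt_aperture.aperture import AperturePolygon

    rect = AperturePolygon(
        vertices=np.array([[0.0, 0.0], [60.0, 0.0], [60.0, 40.0], [0.0, 40.0]])
    )
    fit = fit_mlc(rect, leaf_width=5.0)
    open_leaves = [leaf for leaf in fit.leaves if leaf[3] > leaf[2]]
    assert len(open_leaves) == 8
    for _, _, near, far in open_leaves:
        assert near == pytest.approx(0.0) and far == pytest.approx(60.0)
    assert fit.open_area == pytest.approx(rect.area)


def test_mlc_area_error_is_bounded_and_shrinks_with_leaf_width(gt_structures):
    polygon, _ = design_aperture(gt_structures)
    coarse = fit_mlc(polygon, leaf_width=5.0)
    err_coarse = abs(coarse.open_area - polygon.area)
    assert err_coarse <= polygon.perimeter * 5.0
    fine = fit_mlc(polygon, leaf_width=0.5)
    assert abs(fine.open_area - polygon.area) < err_coarse


def test_mlc_invalid_leaf_width():
    polygon, _ = design_aperture(make_structures())
    with pytest.raises(ValueError):
        fit_mlc(polygon, leaf_width=0.0)


# -- config validation ------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        {"brain_margin": 45.0},
        {"skin_flash": -1.0},
        {"bc_position": "nose"},
        {"caudal_vertebra": "C3"},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        ApertureConfig(**kwargs).validate()
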