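import logging

import numpy as np
import pytest

from wbrt_aperture.phantom import PhantomSpec, generate_phantom
from wbrt_aperture.projection import (
    BeamGeometry,
    Grid2D,
    mask_to_polyline,
    polyline_area,
    project_mask_bev,
    render_drr,
)


def _small_volume(seed=0, shape=(14, 16, 18), spacing=(2.0, 2.0, 2.0)):
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < 0.05
    origin = tuple(-spacing[a] * (shape[a] // 2) for a in range(3))
    return mask, spacing, origin


def _brute_force_project(mask, spacing, origin, grid, gantry):
    """Per-pixel 'any voxel along the ray' loop, the defining oracle."""
    out = np.zeros(grid.shape, dtype=bool)
    sign = -1.0 if gantry == 270 else 1.0
    for iu, u in enumerate(grid.u_coords()):
        y = sign * u
        j = round((y - origin[1]) / spacing[1])
        if not 0 <= j < mask.shape[1]:
            continue
        for iv, v in enumerate(grid.v_coords()):
            k = round((v - origin[2]) / spacing[2])
            if not 0 <= k < mask.shape[2]:
                continue
            out[iu, iv] = any(mask[i, j, k] for i in range(mask.shape[0]))
    return out


def _brute_force_drr(ct, spacing, origin, grid, gantry):
    out = np.zeros(grid.shape)
    mu = np.maximum(ct + 1000.0, 0.0)
    sign = -1.0 if gantry == 270 else 1.0
    for iu, u in enumerate(grid.u_coords()):
        j = round((sign * u - origin[1]) / spacing[1])
        if not 0 <= j < ct.shape[1]:
            continue
        for iv, v in enumerate(grid.v_coords()):
            k = round((v - origin[2]) / spacing[2])
            if not 0 <= k < ct.shape[2]:
                continue
            out[iu, iv] = mu[:, j, k].sum() * spacing[0]
    return out


def test_empty_mask_projects_to_empty_with_warning(caplog):
    mask, spacing, origin = _small_volume()
    with caplog.at_level(logging.WARNING):
        out, _ = project_mask_bev(np.zeros_like(mask), spacing, origin, BeamGeometry())
    assert not out.any()
    assert any("empty" in r.message for r in caplog.records)


def test_projected_sphere_has_analytic_bounding_box():
    spacing = (2.0, 2.0, 2.0)
    coords = [spacing[0] * np.arange(-25, 26) for _ in range(3)]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    sphere = x**2 + y**2 + z**2 <= 20.0**2
    origin = tuple(c[0] for c in coords)
    out, grid = project_mask_bev(sphere, spacing, origin, BeamGeometry())
    iu, iv = np.nonzero(out)
    du = grid.u_coords()[iu.max()] - grid.u_coords()[iu.min()] + grid.spacing[0]
    dv = grid.v_coords()[iv.max()] - grid.v_coords()[iv.min()] + grid.spacing[1]
    assert abs(du - 40.0) <= 2.0 and abs(dv - 40.0) <= 2.0


@pytest.mark.parametrize("gantry", [270, 90])
def test_projection_matches_brute_force_oracle(gantry):
    mask, spacing, origin = _small_volume(seed=3)
    geometry = BeamGeometry(gantry_deg=gantry)
    out, grid = project_mask_bev(mask, spacing, origin, geometry)
    assert np.array_equal(out, _brute_force_project(mask, spacing, origin, grid, gantry))


def test_single_voxel_drr_closed_form():
    ct = np.full((5, 5, 5), -1000.0)
    ct[2, 2, 2] = 0.0
    origin = (-4.0, -4.0, -4.0)
    img = render_drr(ct, (2.0, 2.0, 2.0), origin, BeamGeometry())
    assert img.pixels.max() == pytest.approx(2000.0)
    assert (img.pixels > 0).sum() == 1


def test_uniform_air_renders_to_zero():
    ct = np.full((6, 6, 6), -1000.0)
    img = render_drr(ct, (2.0, 2.0, 2.0), (-5.0, -5.0, -5.0), BeamGeometry())
    assert np.all(img.pixels == 0.0)


@pytest.mark.parametrize("gantry", [270, 90])
def test_drr_matches_brute_force_oracle(gantry):
    rng = np.random.default_rng(11)
    ct = rng.uniform(-1000.0, 1000.0, size=(10, 12, 14))
    spacing, origin = (2.0, 2.0, 2.0), (-10.0, -12.0, -14.0)
    img = render_drr(ct, spacing, origin, BeamGeometry(gantry_deg=gantry))
    oracle = _brute_force_drr(ct, spacing, origin, img.grid, gantry)
    np.testing.assert_allclose(img.pixels, oracle, rtol=1e-6, atol=1e-6)


def test_gantry_90_is_exact_u_mirror_of_270(default_volume):
    vol = default_volume
    for name in ("brain", "C1"):
        m270, _ = project_mask_bev(
            vol.masks[name], vol.spacing, vol.origin, BeamGeometry(gantry_deg=270)
        )
        m90, _ = project_mask_bev(
            vol.masks[name], vol.spacing, vol.origin, BeamGeometry(gantry_deg=90)
        )
        assert np.array_equal(m90, m270[::-1])
    d270 = render_drr(vol.ct, vol.spacing, vol.origin, BeamGeometry(gantry_deg=270))
    d90 = render_drr(vol.ct, vol.spacing, vol.origin, BeamGeometry(gantry_deg=90))
    assert np.array_equal(d90.pixels, d270.pixels[::-1])


def test_projection_is_monotone_and_distributes_over_union():
    mask, spacing, origin = _small_volume(seed=5)
    sub = mask.copy()
    sub[mask.shape[0] // 2:] = False
    geometry = BeamGeometry()
    full, grid = project_mask_bev(mask, spacing, origin, geometry)
    part, _ = project_mask_bev(sub, spacing, origin, geometry, grid)
    assert not (part & ~full).any()

    other, _, _ = _small_volume(seed=6)
    a, _ = project_mask_bev(mask, spacing, origin, geometry, grid)
    b, _ = project_mask_bev(other, spacing, origin, geometry, grid)
    union, _ = project_mask_bev(mask | other, spacing, origin, geometry, grid)
    assert np.array_equal(union, a | b)


def test_divergent_model_approaches_parallel_at_large_sad(default_volume):
    vol = default_volume
    par, grid = project_mask_bev(
        vol.masks["brain"], vol.spacing, vol.origin, BeamGeometry()
    )
    div, _ = project_mask_bev(
        vol.masks["brain"], vol.spacing, vol.origin,
        BeamGeometry(model="divergent", sad=1e6), grid,
    )
    disagree = (par ^ div).sum()
    assert disagree / par.sum() < 0.02


def test_divergent_magnifies_an_off_axis_structure(default_volume):
    vol = default_volume
    par, grid = project_mask_bev(vol.masks["brain"], vol.spacing, vol.origin, BeamGeometry())
    div, _ = project_mask_bev(
        vol.masks["brain"], vol.spacing, vol.origin,
        BeamGeometry(model="divergent", sad=300.0), grid,
    )
    assert div.sum() > par.sum()


# -- boundary extraction ----------------------------------------------------


def test_square_polyline_area_and_closure():
    grid = Grid2D(origin=(0.5, 0.5), spacing=(1.0, 1.0), shape=(20, 20))
    mask = np.zeros(grid.shape, dtype=bool)
    mask[5:15, 5:15] = True  # 10 x 10 mm
    polys = mask_to_polyline(mask, grid)
    assert len(polys) == 1
    p = polys[0]
    assert np.allclose(p[0], p[-1])
    assert polyline_area(p) == pytest.approx(100.0, abs=10.0)
    assert polyline_area(p, signed=True) > 0  # counter-clockwise


def test_two_disjoint_squares_give_two_polylines():
    grid = Grid2D(origin=(0.5, 0.5), spacing=(1.0, 1.0), shape=(30, 20))
    mask = np.zeros(grid.shape, dtype=bool)
    mask[2:8, 4:10] = True
    mask[15:24, 4:12] = True
    assert len(mask_to_polyline(mask, grid)) == 2


def test_random_blob_area_consistency():
    from scipy import ndimage

    rng = np.random.default_rng(7)
    grid = Grid2D(origin=(0.5, 0.5), spacing=(1.0, 1.0), shape=(40, 40))
    blob = ndimage.binary_closing(rng.random(grid.shape) < 0.4, np.ones((5, 5)))
    blob = ndimage.binary_opening(blob, np.ones((3, 3)))
    blob = ndimage.binary_fill_holes(blob)
    polys = mask_to_polyline(blob, grid)
    enclosed = sum(polyline_area(p, signed=True) for p in polys)
    pixel_area = blob.sum() * grid.pixel_area
    perimeter = sum(np.hypot(*np.diff(p, axis=0).T).sum() for p in polys)
    assert abs(enclosed - pixel_area) <= perimeter * grid.spacing[0] / 2.0


def test_empty_mask_has_no_boundary():
    grid = Grid2D(origin=(0.0, 0.0), spacing=(1.0, 1.0), shape=(5, 5))
    with pytest.raises(ValueError):
        mask_to_polyline(np.zeros(grid.shape, dtype=bool), grid)
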