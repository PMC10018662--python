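"""Beam's-eye-view (BEV) projection and DRR rendering.

The BEV frame for the canonical lateral field (gantry 270, source on the
patient's right for a head-first supine patient) is a 2D plane through the
isocenter with

* ``u`` increasing toward the patient's **anterior** (``u = -y``),
* ``v`` increasing toward the patient's **superior** (``v = z``).

The opposed field (gantry 90) is viewed from the other side, so its image is
the exact ``u``-mirror of the gantry-270 image of the same volume.

Two renderers share this frame: a binary structure projector (pixel on iff any
voxel along the ray is on) and a DRR renderer whose pixel value is the line
integral of ``max(HU + 1000, 0)`` (a water-equivalent attenuation proxy, in
HU*mm).  The parallel model is the default; a divergent source-to-axis fan
model (SAD 1000 mm) is available since clinical DRRs diverge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "BeamGeometry",
    "Grid2D",
    "BEVImage",
    "StructureSet2D",
    "project_mask_bev",
    "render_drr",
    "project_structures",
    "mask_to_polyline",
    "polyline_area",
]


@dataclass(frozen=True)
class Grid2D:
    """Regular BEV pixel grid; pixel ``[iu, iv]`` is centred at
    ``(origin[0] + iu * spacing[0], origin[1] + iv * spacing[1])`` mm."""

    origin: tuple[float, float]
    spacing: tuple[float, float]
    shape: tuple[int, int]

    def u_coords(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.shape[0])

    def v_coords(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.shape[1])

    @property
    def pixel_area(self) -> float:
        return self.spacing[0] * self.spacing[1]

    def matches(self, other: "Grid2D") -> bool:
        return self.shape == other.shape and np.allclose(
            (*self.origin, *self.spacing), (*other.origin, *other.spacing)
        )


@dataclass(frozen=True)
class BeamGeometry:
    """Beam and detector description defining the BEV frame.

    ``pixel_spacing``/``image_extent`` may be None, in which case they default
    to the projected volume's voxel spacing and spatial extent.
    """

    gantry_deg: int = 270
    model: str = "parallel"
    sad: float = 1000.0
    pixel_spacing: tuple[float, float] | None = None
    image_extent: tuple[float, float] | None = None

    def __post_init__(self):
        if self.gantry_deg not in (90, 270):
            raise ValueError(f"gantry_deg must be 90 or 270, got {self.gantry_deg}")
        if self.model not in ("parallel", "divergent"):
            raise ValueError(f"model must be 'parallel' or 'divergent', got {self.model!r}")
        if self.pixel_spacing is not None and not all(s > 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if self.model == "divergent" and self.sad <= 0:
            raise ValueError(f"sad must be > 0, got {self.sad}")

    def grid_for(self, spacing3, origin3, shape3) -> Grid2D:
        """BEV grid centred on the isocenter covering the volume footprint.

        Pixel centres lie on the lattice ``spacing * k`` so that, when the
        pixel spacing equals the voxel spacing, BEV pixels coincide exactly
        with projected voxel centres.
        """
        y = origin3[1] + spacing3[1] * np.arange(shape3[1])
        z = origin3[2] + spacing3[2] * np.arange(shape3[2])
        su, sv = self.pixel_spacing or (spacing3[1], spacing3[2])
        if self.image_extent is not None:
            eu, ev = self.image_extent
        else:
            eu = 2.0 * max(abs(y[0]), abs(y[-1]))
            ev = 2.0 * max(abs(z[0]), abs(z[-1]))
        nu_half = int(np.floor(eu / 2.0 / su + 1e-9))
        nv_half = int(np.floor(ev / 2.0 / sv + 1e-9))
        return Grid2D(
            origin=(-su * nu_half, -sv * nv_half),
            spacing=(su, sv),
            shape=(2 * nu_half + 1, 2 * nv_half + 1),
        )

    def validate_against(self, spacing3, origin3, shape3) -> None:
        if self.model == "divergent":
            y = abs(origin3[0]), abs(origin3[0] + spacing3[0] * (shape3[0] - 1))
            if self.sad <= max(y):
                raise ValueError(
                    f"sad {self.sad} must exceed the volume's lateral half-extent"
                )


@dataclass
class BEVImage:
    """Scalar BEV image (a DRR) on a :class:`Grid2D`."""

    pixels: np.ndarray
    grid: Grid2D
    gantry_deg: int = 270

    def validate(self) -> None:
        if self.pixels.shape != self.grid.shape:
            raise ValueError("pixels shape does not match grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("BEV image contains non-finite values")


@dataclass
class StructureSet2D:
    """Named binary masks sharing one BEV grid."""

    masks: dict[str, np.ndarray]
    grid: Grid2D
    gantry_deg: int = 270
    provenance: str = "approach1"

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.masks or not self.masks[n].any()]
        if missing:
            raise ValueError(f"missing or empty BEV structures: {missing}")

    def union(self, names: Iterable[str]) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for n in names:
            out |= self.masks[n]
        return out


def _pixel_world_targets(grid: Grid2D, gantry_deg: int):
    """World (y, z) coordinates of pixel centres in the isocenter plane."""
    u = grid.u_coords()
    v = grid.v_coords()
    sign = -1.0 if gantry_deg == 270 else 1.0
    return sign * u, v  # y along the u axis, z along the v axis


def _nearest_index(coords: np.ndarray, origin: float, step: float, n: int):
    idx = np.rint((coords - origin) / step).astype(int)
    valid = (idx >= 0) & (idx < n)
    return np.clip(idx, 0, n - 1), valid


def _divergent_samples(geometry: BeamGeometry, grid: Grid2D, spacing3, origin3, shape3):
    """Sample points along each fan ray, plus per-ray path length per sample."""
    yq, vq = _pixel_world_targets(grid, geometry.gantry_deg)
    # Source on the patient's right (x = -sad) for gantry 270, left for 90.
    sx = -geometry.sad if geometry.gantry_deg == 270 else geometry.sad
    x0 = origin3[0]
    x1 = origin3[0] + spacing3[0] * (shape3[0] - 1)
    step = min(spacing3) / 2.0
    n_samp = int(np.ceil((x1 - x0) / step)) + 1
    xs = np.linspace(x0, x1, n_samp)  # sample planes along the beam axis
    # Ray through pixel (u, v): passes (0, y, z) at the isocenter plane.
    # Parameterize by x; transverse coordinates scale linearly from the source.
    t = (xs - sx) / (0.0 - sx)  # 0 at source, 1 at isocenter plane
    ys = yq[:, None, None] * t[None, None, :]
    zs = vq[None, :, None] * t[None, None, :]
    dx = xs[1] - xs[0] if n_samp > 1 else spacing3[0]
    # Path length per sample: dx scaled by the ray obliquity.
    obliq = np.sqrt(
        1.0
        + (yq[:, None] / (0.0 - sx)) ** 2
        + (vq[None, :] / (0.0 - sx)) ** 2
    )
    return xs, ys, zs, dx * obliq


def project_mask_bev(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    geometry: BeamGeometry,
    grid: Grid2D | None = None,
) -> tuple[np.ndarray, Grid2D]:
    """Project a 3D binary mask into the BEV: a pixel is on iff any voxel along
    the ray through its centre is on.

    Returns the 2D boolean mask and the grid it lives on.  An empty input mask
    yields an empty output with a logged warning.
    """
    mask = np.asarray(mask, dtype=bool)
    geometry.validate_against(spacing, origin, mask.shape)
    if grid is None:
        grid = geometry.grid_for(spacing, origin, mask.shape)
    if not mask.any():
        logger.warning("projecting an empty mask: BEV output is empty")
        return np.zeros(grid.shape, dtype=bool), grid

    if geometry.model == "parallel":
        any_col = mask.any(axis=0)  # (ny, nz)
        yq, vq = _pixel_world_targets(grid, geometry.gantry_deg)
        j, jv = _nearest_index(yq, origin[1], spacing[1], mask.shape[1])
        k, kv = _nearest_index(vq, origin[2], spacing[2], mask.shape[2])
        out = any_col[np.ix_(j, k)]
        out &= jv[:, None]
        out &= kv[None, :]
        return out, grid

    xs, ys, zs, _ = _divergent_samples(geometry, grid, spacing, origin, mask.shape)
    i, iv = _nearest_index(xs, origin[0], spacing[0], mask.shape[0])
    out = np.zeros(grid.shape, dtype=bool)
    for si in range(xs.size):
        if not iv[si]:
            continue
        j, jv = _nearest_index(ys[:, :, si], origin[1], spacing[1], mask.shape[1])
        k, kv = _nearest_index(zs[:, :, si], origin[2], spacing[2], mask.shape[2])
        out |= mask[i[si]][j, k] & jv & kv
    return out, grid


def render_drr(
    ct: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    geometry: BeamGeometry,
    grid: Grid2D | None = None,
) -> BEVImage:
    """Render a DRR: line integral of ``max(HU + 1000, 0)`` along each ray.

    The integrand is a water-equivalent attenuation proxy (0 for air, 1000 per
    mm for water-like soft tissue); the parallel model is linear in the input.
    """
    ct = np.asarray(ct, dtype=float)
    geometry.validate_against(spacing, origin, ct.shape)
    if grid is None:
        grid = geometry.grid_for(spacing, origin, ct.shape)
    mu = np.maximum(ct + 1000.0, 0.0)

    if geometry.model == "parallel":
        col = mu.sum(axis=0) * spacing[0]  # (ny, nz), HU*mm
        yq, vq = _pixel_world_targets(grid, geometry.gantry_deg)
        j, jv = _nearest_index(yq, origin[1], spacing[1], ct.shape[1])
        k, kv = _nearest_index(vq, origin[2], spacing[2], ct.shape[2])
        pixels = col[np.ix_(j, k)] * jv[:, None] * kv[None, :]
        img = BEVImage(pixels=pixels, grid=grid, gantry_deg=geometry.gantry_deg)
        img.validate()
        return img

    xs, ys, zs, seg = _divergent_samples(geometry, grid, spacing, origin, ct.shape)
    i, iv = _nearest_index(xs, origin[0], spacing[0], ct.shape[0])
    pixels = np.zeros(grid.shape, dtype=float)
    for si in range(xs.size):
        if not iv[si]:
            continue
        j, jv = _nearest_index(ys[:, :, si], origin[1], spacing[1], ct.shape[1])
        k, kv = _nearest_index(zs[:, :, si], origin[2], spacing[2], ct.shape[2])
        pixels += mu[i[si]][j, k] * (jv & kv) * seg
    img = BEVImage(pixels=pixels, grid=grid, gantry_deg=geometry.gantry_deg)
    img.validate()
    return img


def project_structures(volume, geometry: BeamGeometry, grid: Grid2D | None = None) -> StructureSet2D:
    """Project every mask of a :class:`~wbrt_aperture.phantom.StructureVolume`
    (approach 1's structure source)."""
    if grid is None:
        grid = geometry.grid_for(volume.spacing, volume.origin, volume.ct.shape)
    masks = {
        name: project_mask_bev(m, volume.spacing, volume.origin, geometry, grid)[0]
        for name, m in volume.masks.items()
    }
    return StructureSet2D(masks=masks, grid=grid, gantry_deg=geometry.gantry_deg,
                          provenance="approach1")


def mask_to_polyline(mask: np.ndarray, grid: Grid2D) -> list[np.ndarray]:
    """Sub-pixel closed boundary polylines of each connected component.

    Iso-contour of the binary image at level 0.5 with bilinear interpolation;
    the marching-squares saddle ambiguity is resolved toward the foreground.
    Each polyline is an ``(N, 2)`` array of (u, v) mm with the first vertex
    repeated at the end, oriented counter-clockwise in the (u, v) plane.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot extract a boundary from an empty mask")
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5, fully_connected="high")
    out = []
    for c in contours:
        verts = np.empty_like(c)
        verts[:, 0] = grid.origin[0] + (c[:, 0] - 1.0) * grid.spacing[0]
        verts[:, 1] = grid.origin[1] + (c[:, 1] - 1.0) * grid.spacing[1]
        if not np.allclose(verts[0], verts[-1]):
            verts = np.vstack([verts, verts[:1]])
        if polyline_area(verts, signed=True) < 0:
            verts = verts[::-1].copy()
        out.append(verts)
    return out


def polyline_area(vertices: np.ndarray, signed: bool = False) -> float:
    """Shoelace area (mm^2) of a closed polyline; positive when CCW."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
    return float(area if signed else abs(area))
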