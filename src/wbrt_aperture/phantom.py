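"""Parameterized synthetic head-and-neck CT phantoms.

The phantom stands in for a planning CT of a head-first supine patient: an
ellipsoidal head with an ellipsoidal brain surrounded by a thin bony skull
shell, two spherical eyes with small anterior lenses, and the C1/C2 vertebral
bodies stacked in a cylindrical neck inferior-posterior to the skull base.
Every structure is emitted both as a binary mask and as a distinct HU value in
the scalar CT volume, so that the mask-projection path and the DRR-segmentation
path of the aperture pipeline can both be exercised on the same ground truth.

World axes follow the clinical (DICOM-LPS-like) convention:

* ``+x`` patient right -> left,
* ``+y`` anterior -> posterior,
* ``+z`` inferior -> superior,

with the head centre at the origin (which is also the beam isocenter used by
the projection module).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "PhantomSpec",
    "StructureVolume",
    "PhantomSpecError",
    "generate_phantom",
    "sample_spec",
    "REQUIRED_STRUCTURES",
    "DEFAULT_HU_MAP",
]

#: Structures every phantom (and every imported case) must provide.
REQUIRED_STRUCTURES = (
    "external",
    "brain",
    "eye_L",
    "eye_R",
    "lens_L",
    "lens_R",
    "C1",
    "C2",
)

#: Default HU per structure; bone is bright enough to give the DRR segmenter
#: usable contrast, eye/lens differ from soft tissue by -20/+40 HU.
DEFAULT_HU_MAP: Mapping[str, float] = {
    "air": -1000.0,
    "external": 40.0,
    "skull": 700.0,
    "brain": 35.0,
    "eye_L": 20.0,
    "eye_R": 20.0,
    "lens_L": 80.0,
    "lens_R": 80.0,
    "C1": 700.0,
    "C2": 700.0,
}

# Internal anatomy layout constants (mm).  These place the organs relative to
# the head centre; they are deliberately not user parameters so that randomized
# specs stay anatomically coherent.  The brain centre sits well above the
# orbits (as in a real head) so that the expanded brain contour dips below the
# eye-box top at the back-of-lens line, keeping every BC-position option of
# the aperture design well defined.
_BRAIN_CENTER = (0.0, 0.0, 30.0)
_SKULL_INNER_GAP = 2.0   # brain surface -> skull inner surface
_SKULL_OUTER_GAP = 6.0   # brain surface -> skull outer surface
_LENS_POLE_GAP = 0.5     # lens sits this far inside the eye's anterior pole
_NECK_RADIUS = 45.0
_NECK_CENTER_Y = 15.0
_NECK_TOP_Z = -40.0
_VERTEBRA_CENTER_Y = 20.0
_SKULL_BASE_GAP = 11.0   # brain inferior extent -> C1 superior face
_C1_C2_GAP = 2.0
_GRID_PAD = 15.0


class PhantomSpecError(ValueError):
    """Raised when a :class:`PhantomSpec` violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and imaging parameters of the synthetic head phantom.

    All lengths in mm, HU values in Hounsfield units.  ``eye_center_offsets``
    are (left, right) offsets of the eye centres from the head centre.
    """

    head_semi_axes: tuple[float, float, float] = (75.0, 95.0, 85.0)
    brain_semi_axes: tuple[float, float, float] = (60.0, 75.0, 45.0)
    eye_radius: float = 12.0
    lens_radius: float = 4.0
    eye_center_offsets: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (31.0, -70.0, -14.0),
        (-31.0, -70.0, -14.0),
    )
    vertebra_heights: tuple[float, float] = (15.0, 17.0)
    vertebra_radius: float = 12.0
    neck_length: float = 80.0
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    hu_map: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_HU_MAP))
    noise_sd: float = 0.0
    head_tilt_deg: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        def _positive(name: str, values) -> None:
            arr = np.atleast_1d(np.asarray(values, dtype=float))
            if not np.all(arr > 0):
                raise PhantomSpecError(f"{name} must be > 0, got {values!r}")

        _positive("head_semi_axes", self.head_semi_axes)
        _positive("brain_semi_axes", self.brain_semi_axes)
        _positive("eye_radius", self.eye_radius)
        _positive("lens_radius", self.lens_radius)
        _positive("vertebra_heights", self.vertebra_heights)
        _positive("vertebra_radius", self.vertebra_radius)
        _positive("neck_length", self.neck_length)
        _positive("voxel_spacing", self.voxel_spacing)
        if self.lens_radius >= self.eye_radius:
            raise PhantomSpecError(
                "lens_radius must be smaller than eye_radius "
                f"({self.lens_radius} >= {self.eye_radius})"
            )
        if not all(b < h for b, h in zip(self.brain_semi_axes, self.head_semi_axes)):
            raise PhantomSpecError(
                "brain_semi_axes must be strictly smaller than head_semi_axes "
                f"({self.brain_semi_axes} vs {self.head_semi_axes})"
            )
        if len(self.eye_center_offsets) != 2:
            raise PhantomSpecError("eye_center_offsets must give (left, right) offsets")
        if self.noise_sd < 0:
            raise PhantomSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if abs(self.head_tilt_deg) > 15.0:
            raise PhantomSpecError(
                f"head_tilt_deg limited to +-15 degrees, got {self.head_tilt_deg}"
            )
        missing = [s for s in (*REQUIRED_STRUCTURES, "air", "skull") if s not in self.hu_map]
        if missing:
            raise PhantomSpecError(f"hu_map missing entries for {missing}")

    # Derived layout -------------------------------------------------------

    @property
    def brain_center(self) -> tuple[float, float, float]:
        return _BRAIN_CENTER

    @property
    def c1_z_range(self) -> tuple[float, float]:
        top = _BRAIN_CENTER[2] - self.brain_semi_axes[2] - _SKULL_BASE_GAP
        return (top - self.vertebra_heights[0], top)

    @property
    def c2_z_range(self) -> tuple[float, float]:
        c1_bottom = self.c1_z_range[0]
        top = c1_bottom - _C1_C2_GAP
        return (top - self.vertebra_heights[1], top)

    def with_(self, **kwargs) -> "PhantomSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class StructureVolume:
    """A CT volume plus aligned binary structure masks.

    ``ct`` and every mask share the same ``(nx, ny, nz)`` shape; voxel ``[i, j,
    k]`` is centred at ``origin + (i, j, k) * spacing`` in the LPS-like world
    frame documented in this module.
    """

    ct: np.ndarray
    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    axes: str = "LPS"

    def validate(self) -> None:
        for name, mask in self.masks.items():
            if mask.shape != self.ct.shape:
                raise ValueError(f"mask {name!r} shape {mask.shape} != ct {self.ct.shape}")
        for name in REQUIRED_STRUCTURES:
            if name not in self.masks:
                raise ValueError(f"missing required structure {name!r}")
            if not self.masks[name].any():
                raise ValueError(f"structure {name!r} is empty")

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate arrays (1D) along each axis, at voxel centres."""
        return tuple(
            np.asarray(self.origin[a]) + self.spacing[a] * np.arange(self.ct.shape[a])
            for a in range(3)
        )


def sample_spec(rng: np.random.Generator | int, noise_sd: float = 0.0) -> PhantomSpec:
    """Draw a randomized but anatomically coherent phantom spec.

    Sizes vary a few percent around the default adult-head geometry, the
    orbits stay just inside the facial surface, and the head may be tilted a
    few degrees — the scale of patient variability the aperture rules must
    tolerate.  The spec's own ``seed`` (used for CT noise) is drawn from the
    same stream.
    """
    rng = np.random.default_rng(rng)
    base = PhantomSpec()
    scale = rng.uniform(0.95, 1.05, size=3)
    head = tuple(a * s for a, s in zip(base.head_semi_axes, scale))
    brain = tuple(
        a * s * rng.uniform(0.98, 1.02) for a, s in zip(base.brain_semi_axes, scale)
    )
    eye_r = rng.uniform(11.0, 13.0)
    lens_r = rng.uniform(3.6, 4.4)
    eyes = []
    for sign in (1.0, -1.0):
        eyes.append(
            (
                sign * 31.0 * scale[0],
                -70.0 * scale[1] + rng.uniform(-2.0, 2.0),
                -14.0 * scale[2] + rng.uniform(-2.0, 2.0),
            )
        )
    return base.with_(
        head_semi_axes=head,
        brain_semi_axes=brain,
        eye_radius=eye_r,
        lens_radius=lens_r,
        eye_center_offsets=(tuple(eyes[0]), tuple(eyes[1])),
        vertebra_heights=(rng.uniform(13.0, 17.0), rng.uniform(15.0, 19.0)),
        vertebra_radius=rng.uniform(10.5, 13.0),
        head_tilt_deg=rng.uniform(-3.0, 3.0),
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _axis_coords(lo: float, hi: float, step: float) -> np.ndarray:
    """Voxel-centre coordinates on the lattice ``step * k`` covering [lo, hi]."""
    i0 = math.floor(lo / step)
    i1 = math.ceil(hi / step)
    return step * np.arange(i0, i1 + 1)


def _ellipsoid(xa, ya, za, center, semi) -> np.ndarray:
    return (
        ((xa - center[0]) / semi[0]) ** 2
        + ((ya - center[1]) / semi[1]) ** 2
        + ((za - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _sphere(xa, ya, za, center, radius) -> np.ndarray:
    return _ellipsoid(xa, ya, za, center, (radius, radius, radius))


def _cylinder_z(xa, ya, za, cx, cy, radius, z_lo, z_hi) -> np.ndarray:
    radial = ((xa - cx) ** 2 + (ya - cy) ** 2) <= radius**2
    return radial & (za >= z_lo) & (za <= z_hi)


def generate_phantom(spec: PhantomSpec) -> StructureVolume:
    """Rasterize the phantom described by ``spec`` onto its voxel grid.

    Deterministic for a fixed spec (the only randomness is the optional
    Gaussian HU noise, drawn from ``numpy.random.default_rng(spec.seed)``).
    A voxel belongs to a solid when its centre lies inside the analytic
    surface; nested structures are painted innermost-last so the innermost
    label wins in the CT.
    """
    spec.validate()
    sx, sy, sz = spec.voxel_spacing
    hx, hy, hz = spec.head_semi_axes
    neck_bottom = _NECK_TOP_Z - spec.neck_length

    x = _axis_coords(-hx - _GRID_PAD, hx + _GRID_PAD, sx)
    y = _axis_coords(-hy - _GRID_PAD, hy + _GRID_PAD, sy)
    z = _axis_coords(neck_bottom - _GRID_PAD, hz + _GRID_PAD, sz)
    xa = x[:, None, None]
    yw = y[None, :, None]
    zw = z[None, None, :]

    # Anatomy frame = world frame rotated by -tilt about the x axis through the
    # head centre; tilt 0 is exactly the identity.
    if spec.head_tilt_deg != 0.0:
        theta = math.radians(spec.head_tilt_deg)
        c, s = math.cos(theta), math.sin(theta)
        ya = yw * c + zw * s
        za = -yw * s + zw * c
    else:
        ya, za = yw, zw

    head = _ellipsoid(xa, ya, za, (0.0, 0.0, 0.0), spec.head_semi_axes)
    neck = _cylinder_z(xa, ya, za, 0.0, _NECK_CENTER_Y, _NECK_RADIUS, neck_bottom, _NECK_TOP_Z)
    external = head | neck

    bc = spec.brain_center
    brain = _ellipsoid(xa, ya, za, bc, spec.brain_semi_axes)
    skull_outer = _ellipsoid(
        xa, ya, za, bc, tuple(a + _SKULL_OUTER_GAP for a in spec.brain_semi_axes)
    )
    skull_inner = _ellipsoid(
        xa, ya, za, bc, tuple(a + _SKULL_INNER_GAP for a in spec.brain_semi_axes)
    )
    skull = skull_outer & ~skull_inner & external

    eyes: dict[str, np.ndarray] = {}
    lenses: dict[str, np.ndarray] = {}
    for side, offset in zip(("L", "R"), spec.eye_center_offsets):
        center = tuple(offset)
        eye = _sphere(xa, ya, za, center, spec.eye_radius) & external & ~skull
        lens_center = (
            center[0],
            center[1] - (spec.eye_radius - spec.lens_radius - _LENS_POLE_GAP),
            center[2],
        )
        lens = _sphere(xa, ya, za, lens_center, spec.lens_radius) & eye
        eyes[f"eye_{side}"] = eye
        lenses[f"lens_{side}"] = lens

    c1_lo, c1_hi = spec.c1_z_range
    c2_lo, c2_hi = spec.c2_z_range
    c1 = _cylinder_z(xa, ya, za, 0.0, _VERTEBRA_CENTER_Y, spec.vertebra_radius, c1_lo, c1_hi)
    c2 = _cylinder_z(xa, ya, za, 0.0, _VERTEBRA_CENTER_Y, spec.vertebra_radius, c2_lo, c2_hi)
    c1 &= external
    c2 &= external

    brain &= external
    for side in ("L", "R"):
        if (eyes[f"eye_{side}"] & brain).any():
            raise PhantomSpecError(
                f"eye_center_offsets place eye_{side} overlapping the brain"
            )

    hu = spec.hu_map
    ct = np.full(external.shape, float(hu["air"]))
    paint_order = [
        ("external", external),
        ("skull", skull),
        ("brain", brain),
        ("eye_L", eyes["eye_L"]),
        ("eye_R", eyes["eye_R"]),
        ("lens_L", lenses["lens_L"]),
        ("lens_R", lenses["lens_R"]),
        ("C1", c1),
        ("C2", c2),
    ]
    for name, mask in paint_order:
        ct[mask] = float(hu[name])

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ct = ct + rng.normal(0.0, spec.noise_sd, size=ct.shape)

    volume = StructureVolume(
        ct=ct,
        masks={
            "external": external,
            "brain": brain,
            **eyes,
            **lenses,
            "C1": c1,
            "C2": c2,
        },
        spacing=(sx, sy, sz),
        origin=(float(x[0]), float(y[0]), float(z[0])),
    )
    volume.validate()
    return volume
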