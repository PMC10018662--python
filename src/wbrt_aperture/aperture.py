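"""Landmark-based field-aperture construction.

Nine landmarks A-I, computed from bounding boxes of the BEV structures and
from the morphologically expanded brain contour, form the boundaries of a
whole-brain lateral field:

* cranial boundary ``HI`` at the skin top plus the skin flash,
* caudal boundary ``FG`` at the inferior edge of the chosen vertebral body,
* anterior boundaries ``AI`` (forehead plus flash) and ``EF``,
* posterior boundary ``GH`` at the posterior skin extreme plus flash,
* anterior-caudal boundaries ``AB``, ``BC``, ``CD`` and ``DE`` shielding the
  eyes and lenses while covering the expanded brain.

Every placement is constructive so a hand-computed fixture can check it:

* ``H``, ``I`` at ``v =`` skin top + flash; ``G``, ``H`` at ``u =`` posterior
  skin extreme - flash; ``I``, ``A`` at ``u =`` forehead anterior extreme +
  flash (forehead = external restricted to rows at/above the eye-box top, so
  the nose never drives the anterior line).
* ``B`` sits at the eye-box top, with ``u`` at the posterior edge of the lens
  box, of the eye box, or their midpoint (the ``bc_position`` option).
* ``A`` is level with ``B`` (horizontal) or raised by ``ab_diagonal_rise``
  (diagonal).
* ``C`` is where the downward vertical ray from ``B`` first meets the expanded
  brain boundary; ``E`` sits at the vertebra box's anterior edge plus
  ``vertebra_anterior_margin``, on the expanded brain's anterior-inferior arc
  (falling back to ``C``'s level when the arc does not reach it); ``D`` is the
  lowest point of the boundary arc between ``C`` and ``E`` (or the chord
  midpoint when ``ce_shape='straight'``).
* ``include_orbits=True`` collapses the anterior-caudal carve-out: the
  anterior boundary becomes a single vertical at the face's anterior extreme
  plus flash, with A, B, C, D and E reported coincident on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as _ShPolygon

from .projection import Grid2D, StructureSet2D, mask_to_polyline, polyline_area

__all__ = [
    "ApertureConfig",
    "LandmarkSet",
    "AperturePolygon",
    "MLCFit",
    "bounding_box",
    "expand_brain",
    "compute_landmarks",
    "build_aperture",
    "design_aperture",
    "mirror_aperture",
    "fit_mlc",
]

LANDMARK_NAMES = ("A", "B", "C", "D", "E", "F", "G", "H", "I")

_COLLINEAR_TOL = 0.1  # mm, for merging arc vertices
_ARC_STEP = 2.0  # mm, max vertex spacing along the expanded-brain arc


@dataclass(frozen=True)
class ApertureConfig:
    """User options shaping the nine landmarks.

    Defaults are the clinically preferred initial configuration: diagonal AB,
    BC midway between the backs of the lenses and eyes, CD/DE following the
    brain expansion, 15 mm brain expansion and 15 mm skin flash.
    """

    ab_shape: Literal["horizontal", "diagonal"] = "diagonal"
    ab_diagonal_rise: float = 10.0
    bc_position: Literal["lens", "mid", "eye"] = "mid"
    ce_shape: Literal["follow_expansion", "straight"] = "follow_expansion"
    brain_margin: float = 15.0
    skin_flash: float = 15.0
    caudal_vertebra: Literal["C1", "C2"] = "C1"
    include_orbits: bool = False
    vertebra_anterior_margin: float = 5.0

    def validate(self) -> None:
        if self.ab_shape not in ("horizontal", "diagonal"):
            raise ValueError(f"ab_shape: {self.ab_shape!r}")
        if self.bc_position not in ("lens", "mid", "eye"):
            raise ValueError(f"bc_position: {self.bc_position!r}")
        if self.ce_shape not in ("follow_expansion", "straight"):
            raise ValueError(f"ce_shape: {self.ce_shape!r}")
        if self.caudal_vertebra not in ("C1", "C2"):
            raise ValueError(f"caudal_vertebra: {self.caudal_vertebra!r}")
        if not 0.0 <= self.brain_margin <= 30.0:
            raise ValueError(f"brain_margin must be in [0, 30] mm: {self.brain_margin}")
        if not 0.0 <= self.skin_flash <= 30.0:
            raise ValueError(f"skin_flash must be in [0, 30] mm: {self.skin_flash}")
        if self.ab_diagonal_rise < 0 or self.vertebra_anterior_margin < 0:
            raise ValueError("ab_diagonal_rise and vertebra_anterior_margin must be >= 0")

    def with_(self, **kwargs) -> "ApertureConfig":
        return replace(self, **kwargs)


@dataclass
class LandmarkSet:
    """The nine aperture landmarks, (u, v) in mm in the BEV frame."""

    points: dict[str, tuple[float, float]]
    include_orbits: bool = False

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.points[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.points[n] for n in LANDMARK_NAMES])

    def validate(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise ValueError(f"missing landmarks: {missing}")
        p = self.points
        u = {n: p[n][0] for n in p}
        v = {n: p[n][1] for n in p}
        if not np.isclose(v["H"], v["I"]):
            raise ValueError("cranial boundary HI must be level")
        if not np.isclose(v["F"], v["G"]):
            raise ValueError("caudal boundary FG must be level")
        if not np.isclose(u["I"], u["A"]):
            raise ValueError("AI must be vertical")
        if not np.isclose(u["F"], u["E"]):
            raise ValueError("EF must be vertical")
        if not np.isclose(u["G"], u["H"]):
            raise ValueError("GH must be vertical")
        if self.include_orbits:
            ordered = v["I"] > v["A"] >= v["B"] >= v["C"] >= v["F"]
        else:
            ordered = v["I"] > v["A"] >= v["B"] > v["C"] > v["F"]
        if not ordered:
            raise ValueError("landmark vertical ordering I > A >= B > C > F violated")


@dataclass
class AperturePolygon:
    """Closed field-aperture boundary; ``vertices`` is (N, 2) mm without the
    closing duplicate."""

    vertices: np.ndarray
    gantry_deg: int = 270
    config: ApertureConfig | None = None
    provenance: str = "approach1"

    @property
    def area(self) -> float:
        return self.shapely.area

    @property
    def perimeter(self) -> float:
        return self.shapely.length

    @property
    def shapely(self) -> _ShPolygon:
        return _ShPolygon(self.vertices)

    def validate(self) -> None:
        poly = self.shapely
        if not poly.is_valid:
            raise ValueError("aperture polygon is self-intersecting or degenerate")
        if poly.area <= 0:
            raise ValueError("aperture polygon has non-positive area")

    def contains_point(self, u: float, v: float) -> bool:
        from shapely.geometry import Point

        return bool(self.shapely.contains(Point(u, v)))


# ---------------------------------------------------------------------------
# Primitive operations


def bounding_box(mask: np.ndarray, grid: Grid2D) -> tuple[float, float, float, float]:
    """Tight axis-aligned box (umin, umax, vmin, vmax) of the on-pixels, with
    edges at the outer pixel borders."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("bounding_box of an empty mask")
    iu, iv = np.nonzero(mask)
    su, sv = grid.spacing
    u0, v0 = grid.origin
    return (
        u0 + iu.min() * su - su / 2.0,
        u0 + iu.max() * su + su / 2.0,
        v0 + iv.min() * sv - sv / 2.0,
        v0 + iv.max() * sv + sv / 2.0,
    )


def _disk_selem(margin: float, spacing: tuple[float, float]) -> np.ndarray:
    ru = int(round(margin / spacing[0]))
    rv = int(round(margin / spacing[1]))
    if ru == 0 and rv == 0:
        return np.ones((1, 1), dtype=bool)
    du = np.arange(-ru, ru + 1)[:, None] / max(ru, 1e-12)
    dv = np.arange(-rv, rv + 1)[None, :] / max(rv, 1e-12)
    return (du**2 + dv**2) <= 1.0 + 1e-12


def expand_brain(
    brain_mask: np.ndarray, grid: Grid2D, margin: float
) -> tuple[np.ndarray, np.ndarray]:
    """Morphological dilation of the brain BEV mask with a disk structuring
    element of radius ``margin`` mm (rounded to whole pixels).

    Returns the expanded mask and its (largest) closed boundary polyline.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    mask = np.asarray(brain_mask, dtype=bool)
    expanded = ndimage.binary_dilation(mask, structure=_disk_selem(margin, grid.spacing))
    boundaries = mask_to_polyline(expanded, grid)
    boundary = max(boundaries, key=polyline_area)
    return expanded, boundary


def _vertical_crossings(polyline: np.ndarray, u: float) -> list[float]:
    """v values where the closed polyline crosses the vertical line at ``u``."""
    p = np.asarray(polyline, dtype=float)
    out: list[float] = []
    for (u1, v1), (u2, v2) in zip(p[:-1], p[1:]):
        if u1 == u2:
            if u1 == u:
                out.extend([v1, v2])
            continue
        if (u1 - u) * (u2 - u) <= 0:
            t = (u - u1) / (u2 - u1)
            out.append(v1 + t * (v2 - v1))
    return sorted(out)


def _locate_on_polyline(polyline: np.ndarray, point: tuple[float, float]):
    """(segment index, parameter) of the polyline point nearest ``point``."""
    p = np.asarray(polyline, dtype=float)
    a, b = p[:-1], p[1:]
    ab = b - a
    denom = np.maximum((ab**2).sum(axis=1), 1e-300)
    t = np.clip(((np.asarray(point) - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d2 = ((proj - np.asarray(point)) ** 2).sum(axis=1)
    i = int(np.argmin(d2))
    return i, float(t[i])


def _arc_between(polyline: np.ndarray, start, end) -> np.ndarray:
    """The lower (smaller maximum-v) of the two boundary arcs from ``start``
    to ``end`` along a closed polyline, including exact endpoints."""
    p = np.asarray(polyline, dtype=float)[:-1]  # drop closing duplicate
    n = len(p)
    i0, t0 = _locate_on_polyline(polyline, start)
    i1, t1 = _locate_on_polyline(polyline, end)

    def walk(forward: bool) -> np.ndarray:
        verts = [np.asarray(start, dtype=float)]
        i = i0
        t = t0
        while True:
            if forward:
                nxt = (i + 1) % n
                if i == i1 and t <= t1:
                    break
                verts.append(p[nxt])
                i = nxt
                t = 0.0
            else:
                if i == i1 and t >= t1:
                    break
                verts.append(p[i])
                i = (i - 1) % n
                t = 1.0
            if len(verts) > 2 * n + 4:  # safety
                break
        verts.append(np.asarray(end, dtype=float))
        return np.array(verts)

    fwd, bwd = walk(True), walk(False)
    return fwd if fwd[:, 1].max() <= bwd[:, 1].max() else bwd


def _resample(polyline: np.ndarray, step: float) -> np.ndarray:
    """Insert vertices so consecutive spacing is <= ``step`` mm."""
    out = [polyline[0]]
    for a, b in zip(polyline[:-1], polyline[1:]):
        d = float(np.hypot(*(b - a)))
        k = max(1, int(np.ceil(d / step)))
        for j in range(1, k + 1):
            out.append(a + (b - a) * (j / k))
    return np.array(out)


# ---------------------------------------------------------------------------
# Landmarks


def compute_landmarks(
    structures: StructureSet2D,
    config: ApertureConfig | None = None,
    expanded_boundary: np.ndarray | None = None,
) -> LandmarkSet:
    """Compute the nine landmarks A-I from the BEV structures.

    ``expanded_boundary`` (the expanded-brain contour) may be supplied to
    avoid recomputation; otherwise it is derived via :func:`expand_brain`.
    """
    config = config or ApertureConfig()
    config.validate()
    grid = structures.grid
    vertebra = config.caudal_vertebra
    required = ["external", "brain", "eye_L", "eye_R", "lens_L", "lens_R", vertebra]
    structures.require(required)

    if expanded_boundary is None:
        _, expanded_boundary = expand_brain(
            structures.masks["brain"], grid, config.brain_margin
        )

    ext_box = bounding_box(structures.masks["external"], grid)
    eye_box = bounding_box(structures.union(["eye_L", "eye_R"]), grid)
    lens_box = bounding_box(structures.union(["lens_L", "lens_R"]), grid)
    vert_box = bounding_box(structures.masks[vertebra], grid)

    flash = config.skin_flash
    v_cranial = ext_box[3] + flash
    u_post = ext_box[0] - flash
    v_caudal = vert_box[2]

    if config.include_orbits:
        # Single anterior vertical at the face's anterior extreme plus flash;
        # the anterior-caudal carve-out (A..E) collapses onto it.
        u_af = ext_box[1] + flash
        v_b = eye_box[3]
        pts = {
            "I": (u_af, v_cranial),
            "A": (u_af, v_b),
            "B": (u_af, v_b),
            "C": (u_af, v_b),
            "D": (u_af, v_b),
            "E": (u_af, v_b),
            "F": (u_af, v_caudal),
            "G": (u_post, v_caudal),
            "H": (u_post, v_cranial),
        }
        lm = LandmarkSet(points=pts, include_orbits=True)
        lm.validate()
        return lm

    # Forehead: external restricted to rows at/above the eye-box top.
    v_centers = grid.v_coords()
    rows = v_centers >= eye_box[3]
    forehead = structures.masks["external"] & rows[None, :]
    if not forehead.any():
        raise ValueError("no external rows at/above the eye-box top (forehead empty)")
    forehead_box = bounding_box(forehead, grid)
    u_ant = forehead_box[1] + flash

    if config.bc_position == "lens":
        u_b = lens_box[0]
    elif config.bc_position == "eye":
        u_b = eye_box[0]
    else:
        u_b = 0.5 * (lens_box[0] + eye_box[0])
    v_b = eye_box[3]

    v_a = v_b if config.ab_shape == "horizontal" else v_b + config.ab_diagonal_rise

    crossings_b = [v for v in _vertical_crossings(expanded_boundary, u_b) if v <= v_b + 1e-9]
    if not crossings_b:
        raise ValueError("landmark C undefined: vertical ray from B misses the expanded brain")
    v_c = max(crossings_b)

    u_e = vert_box[1] + config.vertebra_anterior_margin
    crossings_e = _vertical_crossings(expanded_boundary, u_e)
    v_e = min(crossings_e) if crossings_e else v_c

    C = (u_b, v_c)
    E = (u_e, v_e)
    if config.ce_shape == "straight":
        D = (0.5 * (u_b + u_e), 0.5 * (v_c + v_e))
    else:
        arc = _resample(_arc_between(expanded_boundary, C, E), _ARC_STEP)
        v_min = arc[:, 1].min()
        candidates = arc[np.isclose(arc[:, 1], v_min, atol=1e-9)]
        mid_u = 0.5 * (u_b + u_e)
        D = tuple(candidates[np.argmin(np.abs(candidates[:, 0] - mid_u))])

    pts = {
        "I": (u_ant, v_cranial),
        "A": (u_ant, v_a),
        "B": (u_b, v_b),
        "C": C,
        "D": (float(D[0]), float(D[1])),
        "E": E,
        "F": (u_e, v_caudal),
        "G": (u_post, v_caudal),
        "H": (u_post, v_cranial),
    }
    lm = LandmarkSet(points=pts, include_orbits=False)
    lm.validate()
    return lm


# ---------------------------------------------------------------------------
# Polygon assembly


def _merge_collinear(vertices: np.ndarray, keep: np.ndarray, tol: float) -> np.ndarray:
    """Drop non-kept vertices within ``tol`` of the line through their
    neighbours; always keep flagged (landmark) vertices."""
    verts = list(map(np.asarray, vertices))
    flags = list(keep)
    changed = True
    while changed and len(verts) > 3:
        changed = False
        for i in range(len(verts)):
            if flags[i]:
                continue
            a = verts[(i - 1) % len(verts)]
            b = verts[i]
            c = verts[(i + 1) % len(verts)]
            ac = c - a
            norm = np.hypot(*ac)
            if norm < 1e-12:
                dist = float(np.hypot(*(b - a)))
            else:
                dist = abs(ac[0] * (b[1] - a[1]) - ac[1] * (b[0] - a[0])) / norm
            if dist <= tol:
                del verts[i], flags[i]
                changed = True
                break
    return np.array(verts)


def build_aperture(
    landmarks: LandmarkSet,
    expanded_boundary: np.ndarray | None,
    config: ApertureConfig | None = None,
    gantry_deg: int = 270,
    provenance: str = "approach1",
) -> AperturePolygon:
    """Assemble the closed aperture polygon I->A->B->C->(arc or chord through
    D)->E->F->G->H.

    With ``ce_shape='follow_expansion'`` the C..E stretch follows the sampled
    expanded-brain boundary arc (vertex spacing <= 2 mm); collinear non-landmark
    vertices are merged with a 0.1 mm tolerance.  Landmark vertices are always
    retained.
    """
    config = config or ApertureConfig()
    landmarks.validate()
    p = landmarks.points

    follow = config.ce_shape == "follow_expansion" and not config.include_orbits
    if follow:
        if expanded_boundary is None:
            raise ValueError("follow_expansion requires the expanded brain boundary")
        arc = _resample(_arc_between(expanded_boundary, p["C"], p["E"]), _ARC_STEP)
        mid = [tuple(q) for q in arc[1:-1]]
    else:
        mid = [p["D"]]

    ordered = (
        [p["I"], p["A"], p["B"], p["C"], *mid, p["E"], p["F"], p["G"], p["H"]]
    )
    keep = [True, True, True, True, *([False] * len(mid)), True, True, True, True]
    if not follow:
        keep[4] = True  # D is a landmark
    # Drop consecutive duplicates (include_orbits collapses A..E).
    verts: list[np.ndarray] = []
    flags: list[bool] = []
    for q, k in zip(ordered, keep):
        q = np.asarray(q, dtype=float)
        if verts and np.allclose(q, verts[-1], atol=1e-9):
            flags[-1] = flags[-1] or k
            continue
        verts.append(q)
        flags.append(k)
    if np.allclose(verts[0], verts[-1], atol=1e-9):
        verts.pop()
        flags.pop()
    merged = _merge_collinear(np.array(verts), np.array(flags), _COLLINEAR_TOL)

    poly = AperturePolygon(
        vertices=merged, gantry_deg=gantry_deg, config=config, provenance=provenance
    )
    poly.validate()
    return poly


def design_aperture(
    structures: StructureSet2D, config: ApertureConfig | None = None
) -> tuple[AperturePolygon, LandmarkSet]:
    """Convenience: expand the brain, compute landmarks, assemble the polygon.

    The landmark rules are written in the canonical gantry-270 frame (u
    increasing toward the patient's anterior); a gantry-90 structure set is
    mirrored into that frame, designed, and mirrored back.
    """
    config = config or ApertureConfig()
    config.validate()
    if structures.gantry_deg == 90:
        g = structures.grid
        u_last = g.origin[0] + (g.shape[0] - 1) * g.spacing[0]
        if not np.isclose(g.origin[0], -u_last):
            raise ValueError("gantry-90 landmarking requires a u-symmetric BEV grid")
        flipped = StructureSet2D(
            masks={k: m[::-1].copy() for k, m in structures.masks.items()},
            grid=g,
            gantry_deg=270,
            provenance=structures.provenance,
        )
        polygon, landmarks = design_aperture(flipped, config)
        mirrored = mirror_aperture(polygon)
        mirrored_lm = LandmarkSet(
            points={k: (-u, v) for k, (u, v) in landmarks.points.items()},
            include_orbits=landmarks.include_orbits,
        )
        return mirrored, mirrored_lm
    structures.require(["brain"])
    _, boundary = expand_brain(structures.masks["brain"], structures.grid, config.brain_margin)
    landmarks = compute_landmarks(structures, config, expanded_boundary=boundary)
    polygon = build_aperture(
        landmarks,
        boundary,
        config,
        gantry_deg=structures.gantry_deg,
        provenance=structures.provenance,
    )
    return polygon, landmarks


def mirror_aperture(polygon: AperturePolygon) -> AperturePolygon:
    """Reflect the aperture about the isocenter axis (u -> -u): the opposed
    lateral field.  An involution: mirroring twice returns the original."""
    verts = polygon.vertices.copy()
    verts[:, 0] = -verts[:, 0]
    out = AperturePolygon(
        vertices=verts,
        gantry_deg=90 if polygon.gantry_deg == 270 else 270,
        config=polygon.config,
        provenance=polygon.provenance,
    )
    out.validate()
    return out


@dataclass
class MLCFit:
    """Per-leaf (near, far) edges along the leaf-travel (u) axis."""

    leaf_width: float
    #: list of (v_lo, v_hi, u_near, u_far); closed leaves have u_near == u_far
    leaves: list[tuple[float, float, float, float]]
    jaw: tuple[float, float, float, float]  # (umin, umax, vmin, vmax)

    @property
    def open_area(self) -> float:
        return sum((f - n) * (hi - lo) for lo, hi, n, f in self.leaves)


def fit_mlc(polygon: AperturePolygon, leaf_width: float = 5.0) -> MLCFit:
    """Fit MLC leaf edges: for each leaf row (a v-band aligned to the
    isocenter), the open edges are the min/max u of the polygon within the
    band; bands missing the polygon get closed leaves."""
    if leaf_width <= 0:
        raise ValueError(f"leaf_width must be > 0, got {leaf_width}")
    shp = polygon.shapely
    umin, vmin, umax, vmax = shp.bounds
    k0 = int(np.floor(vmin / leaf_width))
    k1 = int(np.ceil(vmax / leaf_width))
    leaves = []
    from shapely.geometry import box

    for k in range(k0, k1):
        lo, hi = k * leaf_width, (k + 1) * leaf_width
        band = shp.intersection(box(umin - 1.0, lo, umax + 1.0, hi))
        if band.is_empty or band.area <= 0:
            leaves.append((lo, hi, 0.0, 0.0))
        else:
            bu0, _, bu1, _ = band.bounds
            leaves.append((lo, hi, bu0, bu1))
    return MLCFit(leaf_width=leaf_width, leaves=leaves, jaw=(umin, umax, vmin, vmax))
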