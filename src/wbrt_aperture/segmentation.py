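"""Rule-based structure delineation directly on the DRR (approach 2).

This module is the second, independent structure source for the aperture
pipeline: instead of projecting 3D masks it recovers the BEV structures from
the rendered radiograph alone, using classical intensity and morphology
rules.  It is an exchangeable interface — a learned 2D segmentation model
could be slotted in behind the same signature.

The rules exploit radiographic signatures of a head, in order:

* **external** — any ray through tissue integrates at least ~1 mm of
  water-equivalent attenuation; threshold, fill holes, keep the largest
  component.
* **soft-tissue background** — for a convex, near-ellipsoidal head the
  *squared* soft-tissue line integral is a quadratic function of the BEV
  coordinates, so a robust quadratic fitted to a band 3-12 mm inside the skin
  contour (radiographically bone-free) predicts the bone-free background.
  Everything else is detected on the excess over this model.
* **brain** — bone excess lights up the whole calvaria with a steep outer
  flank; the filled outer skull contour eroded by a nominal vault thickness
  recovers the brain envelope.
* **vertebrae** — narrow bright columns on a background that is unimodal
  along each image row; a 1D grey opening along ``u`` isolates them.  Bone
  components inferior to the brain, split at the inter-body gap when fused
  and ordered superior-to-inferior, give C1 and C2.
* **eyes** — the globes attenuate slightly less than soft tissue, leaving a
  shallow dark pocket below the brain's anterior-inferior surface.  A
  projected-sphere disk model is fitted by area-averaged contrast inside that
  anatomical window (area averaging suppresses background-model ripple).  On
  a lateral view the two globes superimpose, so the shared footprint is
  reported for both ``eye_L`` and ``eye_R`` (idem the lenses).
* **lenses** — the lens is denser than the globe and sits at its anterior
  pole: the strongest positive residual after subtracting the fitted
  projected-sphere eye model.

Intensity rates are supplied as :class:`IntensityHints` derived from the
acquisition's HU calibration, not hard-coded, keeping the rules honest about
being phantom-scoped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import PhantomSpec
from .projection import BEVImage, StructureSet2D

__all__ = ["IntensityHints", "SegmentationError", "segment_drr", "dice"]

# Anatomical priors (mm); properties of heads, not of any one phantom.
_VAULT_THICKNESS = 6.0      # cranial vault: outer table to inner surface
_BAND_INNER = 3.0           # soft-only band: depth range inside the skin
_BAND_OUTER = 12.0
_VERTEBRA_WINDOW = 29       # 1D opening length (mm) > vertebral body width
_EYE_RADII = (9.0, 15.5)    # plausible globe radius range on the DRR
_LENS_RADIUS_MAX = 6.0
_SMOOTH_SIGMA = 1.5         # mm, pre-smoothing of the DRR
_POSTPROC_RADIUS = 3.0      # mm, final opening/closing radius
_MIN_BLOB_AREA = 30.0       # mm^2, discard smaller candidates

# Thresholds expressed as water-equivalent path lengths (mm).
_T_EXTERNAL_MM = 1.0        # of soft tissue
_T_SKULL_MM = 6.0           # of bone excess over the fitted soft background
_T_VERTEBRA_MM = 5.0        # of bone excess over the 1D opening background
_LENS_PEAK_FRACTION = 0.4

_ALL_NAMES = ["external", "brain", "eye_L", "eye_R", "lens_L", "lens_R", "C1", "C2"]


class SegmentationError(RuntimeError):
    """DRR segmentation could not find every required structure."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"structures not found on DRR: {self.missing}")


@dataclass(frozen=True)
class IntensityHints:
    """Attenuation rates (HU-proxy per mm of tissue) driving the thresholds."""

    soft: float = 1040.0        # water-equivalent rate of soft tissue
    bone_excess: float = 660.0  # bone rate minus soft rate
    eye_deficit: float = 20.0   # soft rate minus globe rate
    lens_excess: float = 60.0   # lens rate minus globe rate

    @classmethod
    def from_spec(cls, spec: PhantomSpec) -> "IntensityHints":
        hu = spec.hu_map
        soft = hu["external"] + 1000.0
        return cls(
            soft=soft,
            bone_excess=(hu["C1"] + 1000.0) - soft,
            eye_deficit=soft - (hu["eye_L"] + 1000.0),
            lens_excess=(hu["lens_L"] + 1000.0) - (hu["eye_L"] + 1000.0),
        )

    def validate(self) -> None:
        if min(self.soft, self.bone_excess, self.eye_deficit, self.lens_excess) <= 0:
            raise ValueError("intensity hints must all be positive")


def _disk(radius_mm: float, spacing: tuple[float, float]) -> np.ndarray:
    ru = max(1, int(round(radius_mm / spacing[0])))
    rv = max(1, int(round(radius_mm / spacing[1])))
    du = (np.arange(-ru, ru + 1) / ru)[:, None]
    dv = (np.arange(-rv, rv + 1) / rv)[None, :]
    return (du**2 + dv**2) <= 1.0 + 1e-12


def _largest_cc(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _postprocess(mask: np.ndarray, spacing, external: np.ndarray | None) -> np.ndarray:
    se = _disk(_POSTPROC_RADIUS, spacing)
    out = ndimage.binary_closing(mask, structure=se)
    out = ndimage.binary_opening(out, structure=se)
    if external is not None:
        out &= external
    return out


def _soft_background_excess(img, external, grid, hints: IntensityHints) -> np.ndarray:
    """Excess of the DRR over a bone-free soft-tissue model of the head.

    ``(img / soft_rate)^2`` is quadratic in (u, v) for an ellipsoidal head, so
    a quadratic surface is fitted — with one-sided residual trimming, since
    contamination (bone) only inflates the image — to a 3-12 mm-deep band
    inside the skin, restricted to cranial rows away from the vertex (where
    the calvaria approaches the skin) and the neck (a different solid).
    Returns zero wherever the model does not apply.
    """
    spacing = grid.spacing
    v_centers = grid.v_coords()
    v_widest = v_centers[int(np.argmax(external.sum(axis=0)))]
    v_top = v_centers[np.nonzero(external)[1]].max()
    inner = ndimage.binary_erosion(external, structure=_disk(_BAND_INNER, spacing))
    deep = ndimage.binary_erosion(external, structure=_disk(_BAND_OUTER, spacing))
    zone = (v_centers >= v_widest - 50.0) & (
        v_centers <= v_widest + 0.55 * (v_top - v_widest)
    )
    band = inner & ~deep & zone[None, :]
    if band.sum() < 50:
        return np.zeros_like(img)

    uu = grid.u_coords()[:, None] * np.ones_like(img)
    vv = np.ones_like(img) * v_centers[None, :]
    s = (img / hints.soft) ** 2
    design = np.stack([np.ones_like(uu), uu, vv, uu**2, uu * vv, vv**2], axis=-1)
    sel = band.copy()
    coef = np.zeros(6)
    for _ in range(4):
        coef, *_ = np.linalg.lstsq(design[sel], s[sel], rcond=None)
        resid = s - design @ coef
        hi = np.quantile(resid[sel], 0.85)
        lo = np.quantile(resid[sel], 0.02)
        sel = band & (resid <= hi) & (resid >= lo)
        if sel.sum() < 50:
            break
    q = design @ coef
    background = np.sqrt(np.clip(q, 0.0, None)) * hints.soft
    valid = (q > 0.0) & ((v_centers >= v_widest - 45.0)[None, :])
    return np.where(valid, img - background, 0.0)


def _refine_soft_excess(img, sx, external, skull_region, grid, hints):
    """Second-pass soft-tissue background: re-fit with a cubic surface on
    structure-free interior pixels (bone masked by the first pass), shrinking
    the model ripple that limits faint-structure detection."""
    spacing = grid.spacing
    v_centers = grid.v_coords()
    v_widest = v_centers[int(np.argmax(external.sum(axis=0)))]
    core = ndimage.binary_erosion(external, structure=_disk(4.0, spacing))
    clean = core & ~ndimage.binary_dilation(skull_region, structure=_disk(3.0, spacing))
    clean &= np.abs(sx) < 5.0 * hints.bone_excess
    clean &= (v_centers >= v_widest - 45.0)[None, :]
    if clean.sum() < 200:
        return sx
    uu = grid.u_coords()[:, None] * np.ones_like(img) / 100.0
    vv = np.ones_like(img) * v_centers[None, :] / 100.0
    s = (img / hints.soft) ** 2
    design = np.stack(
        [np.ones_like(uu), uu, vv, uu**2, uu * vv, vv**2,
         uu**3, uu**2 * vv, uu * vv**2, vv**3],
        axis=-1,
    )
    sel = clean.copy()
    coef = None
    for _ in range(4):
        coef, *_ = np.linalg.lstsq(design[sel], s[sel], rcond=None)
        resid = s - design @ coef
        hi = np.quantile(resid[sel], 0.90)
        lo = np.quantile(resid[sel], 0.08)
        sel = clean & (resid <= hi) & (resid >= lo)
        if sel.sum() < 200:
            break
    q = design @ coef
    background = np.sqrt(np.clip(q, 0.0, None)) * hints.soft
    valid = (q > 0.0) & ((v_centers >= v_widest - 45.0)[None, :])
    return np.where(valid, img - background, 0.0)


def _detect_vertebrae(img, external, skull_region, brain, grid, hints):
    """C1/C2 as narrow bone columns below the brain (1D grey opening)."""
    spacing = grid.spacing
    n = 2 * int(round(_VERTEBRA_WINDOW / 2 / spacing[0])) + 1
    background = ndimage.grey_opening(img, footprint=np.ones((n, 1), dtype=bool))
    vert = (img - background > _T_VERTEBRA_MM * hints.bone_excess) & external
    vert &= ~ndimage.binary_dilation(skull_region, structure=_disk(2.0, spacing))
    v_centers = grid.v_coords()
    brain_vmin = v_centers[np.nonzero(brain)[1]].min()

    labels, ncomp = ndimage.label(vert)
    candidates = []
    for idx in range(1, ncomp + 1):
        comp = labels == idx
        if comp.sum() * grid.pixel_area < _MIN_BLOB_AREA:
            continue
        rows = v_centers[np.nonzero(comp)[1]]
        if rows.mean() < brain_vmin:
            candidates.append(comp)
    candidates.sort(key=lambda c: -v_centers[np.nonzero(c)[1]].mean())

    # Adjacent bodies (and, under tilt, the neck itself) may fuse through the
    # blurred inter-body gaps: recursively split any column taller than one
    # vertebral body at its weakest interior row.
    margin = max(2, int(round(6.0 / spacing[1])))

    def split_tall(comp, depth=0):
        rows = np.nonzero(comp.any(axis=0))[0]
        if depth >= 3 or v_centers[rows.max()] - v_centers[rows.min()] <= 24.0:
            return [comp]
        interior = rows[margin:-margin]
        if interior.size == 0:
            return [comp]
        profile = [(img - background)[comp[:, r], r].mean() for r in interior]
        cut = interior[int(np.argmin(profile))]
        upper = comp.copy()
        upper[:, : cut + 1] = False
        lower = comp.copy()
        lower[:, cut:] = False
        if not (upper.any() and lower.any()):
            return [comp]
        return split_tall(upper, depth + 1) + split_tall(lower, depth + 1)

    pieces = [p for c in candidates for p in split_tall(c)]
    pieces = [p for p in pieces if p.sum() * grid.pixel_area >= _MIN_BLOB_AREA]
    pieces.sort(key=lambda c: -v_centers[np.nonzero(c)[1]].mean())
    return [
        _refine_column(c, img, external, grid, hints) for c in pieces[:2]
    ]


def _refine_column(comp, img, external, grid, hints):
    """Sharpen a bone column's lateral extent: per image row, interpolate the
    soft background linearly between the column's flanks and re-threshold the
    bone excess at a 2 mm bone path."""
    su = grid.spacing[0]
    pad = max(2, int(round(4.0 / su)))
    flank = max(3, int(round(5.0 / su)))
    refined = np.zeros_like(comp)
    nu = comp.shape[0]
    for r in np.nonzero(comp.any(axis=0))[0]:
        cols = np.nonzero(comp[:, r])[0]
        i0, i1 = cols.min(), cols.max()
        lo = img[max(i0 - pad - flank, 0): max(i0 - pad, 1), r]
        hi = img[min(i1 + pad, nu - 1): min(i1 + pad + flank, nu), r]
        if lo.size == 0 or hi.size == 0:
            refined[:, r] = comp[:, r]
            continue
        a, b = float(np.median(lo)), float(np.median(hi))
        s0, s1 = max(i0 - pad, 0), min(i1 + pad, nu - 1)
        xs = np.arange(s0, s1 + 1)
        background = a + (b - a) * (xs - s0) / max(s1 - s0, 1)
        refined[s0: s1 + 1, r] = img[s0: s1 + 1, r] - background > 2.0 * hints.bone_excess
    return refined & external


def _fit_disk_by_contrast(
    signal, valid, centers_u, centers_v, radii, uu, vv, ring=4.0, top_k=1
):
    """Maximize mean(signal in disk) - mean(signal in surrounding ring) over a
    grid of candidate disks; means use valid pixels only.

    Returns the best candidate ``(score, cu, cv, r)``, or — with ``top_k > 1``
    — a list of up to ``top_k`` candidates whose centres are mutually at
    least 5 mm apart, best first.
    """
    sig = np.where(valid, signal, np.nan)
    candidates = []
    for cu in centers_u:
        for cv in centers_v:
            d2 = (uu - cu) ** 2 + (vv - cv) ** 2
            for r in radii:
                disk = d2 <= r**2
                shell = (d2 <= (r + ring) ** 2) & ~disk
                n_disk = int(disk.sum())
                if n_disk == 0 or valid[disk].sum() < 0.8 * n_disk:
                    continue  # disk must lie (almost) fully in valid territory
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    dm = np.nanmean(sig[disk])
                    rm = np.nanmean(sig[shell])
                if np.isnan(dm) or np.isnan(rm):
                    continue
                candidates.append((dm - rm, cu, cv, r))
    if not candidates:
        return None if top_k == 1 else []
    candidates.sort(key=lambda c: -c[0])
    if top_k == 1:
        return candidates[0]
    picked = []
    for cand in candidates:
        if all(np.hypot(cand[1] - p[1], cand[2] - p[2]) >= 5.0 for p in picked):
            picked.append(cand)
        if len(picked) == top_k:
            break
    return picked


def _fit_eye(sx, external, skull_region, brain, grid, hints):
    """Locate the superimposed globes: disk-contrast fit of -sx in the
    anatomical window below the brain's anterior-inferior surface."""
    from scipy.ndimage import distance_transform_edt

    spacing = grid.spacing
    uc, vc = grid.u_coords(), grid.v_coords()
    uu = uc[:, None] * np.ones_like(sx)
    vv = np.ones_like(sx) * vc[None, :]
    vault = ndimage.binary_dilation(skull_region, structure=_disk(3.0, spacing))
    valid = (distance_transform_edt(external, sampling=spacing) >= 8.0) & ~vault
    b_umax = uc[np.nonzero(brain)[0]].max()
    b_vmin = vc[np.nonzero(brain)[1]].min()

    # The globes sit at the level of the brain's inferior surface (the
    # orbital roof bounds the anterior cranial fossa) and just posterior of
    # the facial surface — within about a centimetre of the brain mask's
    # anterior-inferior corner on a lateral view.
    coarse = _fit_disk_by_contrast(
        -sx, valid,
        np.arange(b_umax - 14.0, b_umax + 2.1, 2.0),
        np.arange(b_vmin - 7.0, b_vmin + 7.1, 2.0),
        np.arange(_EYE_RADII[0], _EYE_RADII[1], 1.0),
        uu, vv,
        top_k=3,
    )
    # Candidates in contrast order; the first whose radial profile shows a
    # genuine spherical rim wins (ripple pockets fail the rim gate).
    for cand in coarse:
        if cand[0] <= 2.0 * hints.eye_deficit:
            continue
        evaluated = _evaluate_eye_candidate(sx, valid, uu, vv, cand[1], cand[2], hints)
        if evaluated is not None:
            _, score, cu, cv, radius = evaluated
            return (score, cu, cv, radius)
    return None


def _evaluate_eye_candidate(sx, valid, uu, vv, cu0, cv0, hints):
    """Refine one candidate centre and read the globe radius off the radial
    profile; returns (rim slope, contrast, cu, cv, radius) or None."""
    # Fixed mid-range radius while centring: a free radius runs away when the
    # surrounding ring touches bone.
    fine = _fit_disk_by_contrast(
        -sx, valid,
        np.arange(cu0 - 2.5, cu0 + 2.6, 0.5),
        np.arange(cv0 - 2.5, cv0 + 2.6, 0.5),
        (11.0,),
        uu, vv,
    )
    if fine is None:
        return None
    score, cu, cv, _ = fine

    d = np.sqrt((uu - cu) ** 2 + (vv - cv) ** 2)
    sig = np.where(valid, -sx, np.nan)
    bins = np.arange(0.0, _EYE_RADII[1] + 3.0, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.array(
            [np.nanmean(sig[(d >= lo) & (d < lo + 1.0)]) for lo in bins]
        )
    # The deficit rides on a background bowl of unknown depth, so absolute
    # levels are uninformative; but a projected sphere's profile has infinite
    # slope at its rim, so the steepest descent marks the globe radius — and
    # a rim slope well below the deficit rate confirms a globe is present.
    slopes = np.diff(profile)  # slope between bin centres i+0.5 and i+1.5
    lo_i = int(_EYE_RADII[0]) - 1
    hi_i = min(int(_EYE_RADII[1]) + 1, slopes.size)
    window = slopes[lo_i:hi_i]
    if not np.isfinite(window).any():
        return None
    rim = float(np.nanmin(window))
    if rim > -3.0 * hints.eye_deficit:
        return None
    radius = float(bins[lo_i + int(np.nanargmin(window))] + 1.0)
    radius = float(np.clip(radius, _EYE_RADII[0], _EYE_RADII[1]))
    return (rim, score, cu, cv, radius)


def _fit_lens(sx, eye, grid, hints):
    """The lens core: strongest positive residual after removing the fitted
    projected-sphere model of the globes, on the eye's anterior side."""
    _, cu, cv, r = eye
    uc, vc = grid.u_coords(), grid.v_coords()
    uu = uc[:, None] * np.ones_like(sx)
    vv = np.ones_like(sx) * vc[None, :]
    d2 = (uu - cu) ** 2 + (vv - cv) ** 2
    chord = np.sqrt(np.clip(r**2 - d2, 0.0, None))
    interior = d2 <= (r - 1.0) ** 2
    if not interior.any():
        return None
    denom = (chord[interior] ** 2).sum()
    if denom <= 0:
        return None
    amp = -(sx[interior] * chord[interior]).sum() / denom
    resid = sx + amp * chord
    anterior = interior & (uu > cu + 1.0)
    if not anterior.any():
        return None
    vals = np.where(anterior, resid, -np.inf)
    peak = np.unravel_index(np.argmax(vals), vals.shape)
    if vals[peak] <= 2.0 * hints.lens_excess:
        return None
    d2_peak = (uu - uc[peak[0]]) ** 2 + (vv - vc[peak[1]]) ** 2
    cand = (resid > _LENS_PEAK_FRACTION * vals[peak]) & interior
    cand &= d2_peak <= _LENS_RADIUS_MAX**2
    labels, _ = ndimage.label(cand)
    mask = labels == labels[peak]
    mask = ndimage.binary_closing(mask, structure=_disk(1.5, grid.spacing))
    return mask


def segment_drr(drr: BEVImage, hints: IntensityHints | None = None) -> StructureSet2D:
    """Delineate external, brain, eyes, lenses, C1 and C2 on a DRR.

    Raises :class:`SegmentationError` listing every structure that could not
    be found — the trigger condition for the pipeline's QA flag.
    """
    hints = hints or IntensityHints()
    hints.validate()
    drr.validate()
    if drr.gantry_deg == 90:
        # The opposed view is the u-mirror of the canonical one; segment the
        # mirrored image and mirror the masks back.
        flipped = BEVImage(
            pixels=drr.pixels[::-1].copy(),
            grid=drr.grid if drr.grid.shape[0] % 2 == 1 else drr.grid,
            gantry_deg=270,
        )
        out = segment_drr(flipped, hints)
        return StructureSet2D(
            masks={k: m[::-1].copy() for k, m in out.masks.items()},
            grid=drr.grid,
            gantry_deg=90,
            provenance="approach2",
        )

    grid = drr.grid
    spacing = grid.spacing
    sigma = (_SMOOTH_SIGMA / spacing[0], _SMOOTH_SIGMA / spacing[1])
    img = ndimage.gaussian_filter(np.asarray(drr.pixels, dtype=float), sigma)
    # Acquisition noise is rectified by the attenuation proxy, giving
    # through-air rays a pedestal; estimate it from the border frame (air
    # inside the scanned footprint).  It only matters for the air/tissue
    # threshold — inside the head it is smooth and absorbed by the
    # background fits and local contrasts.
    frame = np.zeros_like(img, dtype=bool)
    frame[:3, :] = frame[-3:, :] = True
    frame[:, :3] = frame[:, -3:] = True
    frame &= img > 0
    pedestal = float(np.median(img[frame])) if frame.sum() > 20 else 0.0

    found: dict[str, np.ndarray] = {}
    missing: list[str] = []

    # -- external -----------------------------------------------------------
    ext_raw = img > pedestal + _T_EXTERNAL_MM * hints.soft
    external = _largest_cc(ndimage.binary_fill_holes(ext_raw))
    external = _postprocess(external, spacing, None)
    if not external.any() or external.sum() * grid.pixel_area < 2000.0:
        raise SegmentationError(list(_ALL_NAMES))
    found["external"] = external

    # -- soft-tissue background and calvaria --------------------------------
    soft_excess = _soft_background_excess(img, external, grid, hints)
    v_centers = grid.v_coords()
    v_widest = v_centers[int(np.argmax(external.sum(axis=0)))]
    cranial_zone = (v_centers >= v_widest - 25.0)[None, :]
    ext_core = ndimage.binary_erosion(external, structure=_disk(4.0, spacing))
    skull = (soft_excess > _T_SKULL_MM * hints.bone_excess) & ext_core & cranial_zone
    skull_cc = _largest_cc(skull)
    brain = np.zeros_like(external)
    skull_region = np.zeros_like(external)
    if skull_cc.any():
        skull_region = ndimage.binary_fill_holes(skull_cc)
        brain = ndimage.binary_erosion(
            skull_region, structure=_disk(_VAULT_THICKNESS, spacing)
        )
        brain = _postprocess(_largest_cc(brain), spacing, external)
    if brain.any():
        found["brain"] = brain
    else:
        missing.append("brain")

    # -- vertebrae -----------------------------------------------------------
    if brain.any():
        candidates = _detect_vertebrae(img, external, skull_region, brain, grid, hints)
    else:
        candidates = []
    for name, comp in zip(("C1", "C2"), candidates):
        mask = _postprocess(comp, spacing, external)
        if mask.any():
            found[name] = mask
        else:
            missing.append(name)
    for name in ("C1", "C2"):
        if name not in found and name not in missing:
            missing.append(name)

    # -- eyes and lenses -----------------------------------------------------
    eye_fit = None
    if brain.any():
        soft_excess = _refine_soft_excess(
            img, soft_excess, external, skull_region, grid, hints
        )
        eye_fit = _fit_eye(soft_excess, external, skull_region, brain, grid, hints)
    if eye_fit is not None:
        _, cu, cv, r = eye_fit
        uu = grid.u_coords()[:, None] * np.ones_like(img)
        vv = np.ones_like(img) * v_centers[None, :]
        eye_mask = (((uu - cu) ** 2 + (vv - cv) ** 2) <= r**2) & external
        found["eye_L"] = eye_mask
        found["eye_R"] = eye_mask.copy()
        lens_mask = _fit_lens(soft_excess, eye_fit, grid, hints)
        if lens_mask is not None and lens_mask.any():
            lens_mask &= external
            found["lens_L"] = lens_mask
            found["lens_R"] = lens_mask.copy()
        else:
            missing.extend(["lens_L", "lens_R"])
    else:
        missing.extend(["eye_L", "eye_R", "lens_L", "lens_R"])

    if missing:
        raise SegmentationError(missing)
    return StructureSet2D(
        masks=found, grid=grid, gantry_deg=drr.gantry_deg, provenance="approach2"
    )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A| + |B|)``.

    Returns 0 (with a warning) when both masks are empty.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("dice of two empty masks is 0 by convention", stacklevel=2)
        return 0.0
    return 2.0 * int((a & b).sum()) / denom
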