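"""Serialisation: NIfTI volumes/images and versioned JSON documents.

All lengths are serialized in millimetres and all 2D coordinates in the
documented BEV frame — pixel units never leak into files.  Every JSON
document carries a ``schema_version`` so reports stay comparable across
releases.  ``read(write(x)) == x`` for every type.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .aperture import AperturePolygon, ApertureConfig, LandmarkSet
from .phantom import PhantomSpec, StructureVolume, REQUIRED_STRUCTURES
from .projection import BEVImage, Grid2D, StructureSet2D
from .qa import EvaluationROI, QAReport

SCHEMA_VERSION = "1"

__all__ = [
    "write_case", "read_case",
    "write_bev_image", "read_bev_image",
    "write_structure_set", "read_structure_set",
    "write_landmarks", "read_landmarks",
    "write_aperture", "read_aperture",
    "write_qa_report", "read_qa_report",
    "write_config", "read_config",
    "write_phantom_spec", "read_phantom_spec",
    "dump_json", "load_json",
]


def dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def load_json(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"invalid JSON in {path}: {exc}") from exc


def _require(doc: dict, path, *fields: str) -> None:
    for f in fields:
        if f not in doc:
            raise ValueError(f"{path}: missing field {f!r}")


# --------------------------------------------------------------------------
# Volumes (NIfTI)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def write_case(volume: StructureVolume, directory: str | Path) -> None:
    """Write the CT and every mask as NIfTI files (``ct.nii``,
    ``mask_<name>.nii``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(volume.spacing, volume.origin)
    nib.save(nib.Nifti1Image(volume.ct.astype(np.float32), aff), directory / "ct.nii")
    for name, mask in volume.masks.items():
        nib.save(
            nib.Nifti1Image(mask.astype(np.uint8), aff), directory / f"mask_{name}.nii"
        )


def read_case(directory: str | Path) -> StructureVolume:
    """Load a case directory written by :func:`write_case` (``.nii`` or
    ``.nii.gz``); every required structure must be present."""
    directory = Path(directory)
    ct_path = next((p for p in (directory / "ct.nii", directory / "ct.nii.gz") if p.exists()), None)
    if ct_path is None:
        raise FileNotFoundError(f"{directory}: no ct.nii[.gz]")
    img = nib.load(str(ct_path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    masks = {}
    for p in sorted(directory.glob("mask_*.nii*")):
        name = p.name.split("mask_", 1)[1].split(".nii")[0]
        masks[name] = np.asarray(nib.load(str(p)).dataobj).astype(bool)
    missing = [n for n in REQUIRED_STRUCTURES if n not in masks]
    if missing:
        raise ValueError(f"{directory}: missing structure masks {missing}")
    volume = StructureVolume(
        ct=np.asarray(img.dataobj, dtype=float),
        masks=masks,
        spacing=spacing,
        origin=origin,
    )
    volume.validate()
    return volume


def write_bev_image(image: BEVImage, path: str | Path) -> None:
    """A BEV image as 2D NIfTI; pixel spacing/origin in the affine."""
    aff = _affine((*image.grid.spacing, 1.0), (*image.grid.origin, 0.0))
    nib.save(nib.Nifti1Image(image.pixels.astype(np.float32), aff), str(path))


def read_bev_image(path: str | Path, gantry_deg: int = 270) -> BEVImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    aff = img.affine
    grid = Grid2D(
        origin=(float(aff[0, 3]), float(aff[1, 3])),
        spacing=(float(aff[0, 0]), float(aff[1, 1])),
        shape=data.shape,
    )
    return BEVImage(pixels=data, grid=grid, gantry_deg=gantry_deg)


# --------------------------------------------------------------------------
# BEV structure sets


def write_structure_set(structures: StructureSet2D, directory: str | Path) -> None:
    """Masks as 2D NIfTI plus an index JSON with boundary polylines in mm."""
    from .projection import mask_to_polyline

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine((*structures.grid.spacing, 1.0), (*structures.grid.origin, 0.0))
    polylines = {}
    for name, mask in structures.masks.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), directory / f"bev_{name}.nii")
        if mask.any():
            polylines[name] = [
                {"closed": True, "vertices_mm": p.tolist()}
                for p in mask_to_polyline(mask, structures.grid)
            ]
        else:
            polylines[name] = []
    dump_json(
        {
            "schema_version": SCHEMA_VERSION,
            "gantry_deg": structures.gantry_deg,
            "provenance": structures.provenance,
            "grid": {
                "origin_mm": list(structures.grid.origin),
                "spacing_mm": list(structures.grid.spacing),
                "shape": list(structures.grid.shape),
            },
            "structures": sorted(structures.masks),
            "polylines": polylines,
        },
        directory / "structures.json",
    )


def read_structure_set(directory: str | Path) -> StructureSet2D:
    directory = Path(directory)
    doc = load_json(directory / "structures.json")
    _require(doc, directory / "structures.json", "grid", "structures", "gantry_deg")
    grid = Grid2D(
        origin=tuple(doc["grid"]["origin_mm"]),
        spacing=tuple(doc["grid"]["spacing_mm"]),
        shape=tuple(doc["grid"]["shape"]),
    )
    masks = {}
    for name in doc["structures"]:
        path = directory / f"bev_{name}.nii"
        data = np.asarray(nib.load(str(path)).dataobj)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        masks[name] = data.astype(bool)
    return StructureSet2D(
        masks=masks,
        grid=grid,
        gantry_deg=int(doc["gantry_deg"]),
        provenance=doc.get("provenance", "approach1"),
    )


# --------------------------------------------------------------------------
# JSON documents


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    dump_json(
        {
            "schema_version": SCHEMA_VERSION,
            "include_orbits": landmarks.include_orbits,
            "points_mm": {k: list(map(float, v)) for k, v in landmarks.points.items()},
        },
        path,
    )


def read_landmarks(path: str | Path) -> LandmarkSet:
    doc = load_json(path)
    _require(doc, path, "points_mm")
    lm = LandmarkSet(
        points={k: tuple(v) for k, v in doc["points_mm"].items()},
        include_orbits=bool(doc.get("include_orbits", False)),
    )
    lm.validate()
    return lm


def _config_doc(config: ApertureConfig | None) -> dict | None:
    return dataclasses.asdict(config) if config is not None else None


def write_aperture(polygon: AperturePolygon, path: str | Path) -> None:
    dump_json(
        {
            "schema_version": SCHEMA_VERSION,
            "vertices_mm": [[float(u), float(v)] for u, v in polygon.vertices],
            "gantry_deg": polygon.gantry_deg,
            "provenance": polygon.provenance,
            "config": _config_doc(polygon.config),
        },
        path,
    )


def read_aperture(path: str | Path) -> AperturePolygon:
    doc = load_json(path)
    _require(doc, path, "vertices_mm", "gantry_deg")
    config = ApertureConfig(**doc["config"]) if doc.get("config") else None
    poly = AperturePolygon(
        vertices=np.asarray(doc["vertices_mm"], dtype=float),
        gantry_deg=int(doc["gantry_deg"]),
        config=config,
        provenance=doc.get("provenance", "approach1"),
    )
    poly.validate()
    return poly


def write_qa_report(report: QAReport, path: str | Path) -> None:
    dump_json(
        {
            "schema_version": SCHEMA_VERSION,
            "hd_mm": float(report.hd),
            "msd_mm": float(report.msd),
            "roi": None
            if report.roi is None
            else {
                "u_range_mm": list(map(float, report.roi.u_range)),
                "v_range_mm": list(map(float, report.roi.v_range)),
            },
            "thresholds_mm": {k: float(v) for k, v in report.thresholds.items()},
            "verdict": report.verdict,
            "provenance": list(report.provenance),
            "reason": report.reason,
        },
        path,
    )


def read_qa_report(path: str | Path) -> QAReport:
    doc = load_json(path)
    _require(doc, path, "hd_mm", "msd_mm", "verdict", "thresholds_mm")
    roi = None
    if doc.get("roi"):
        roi = EvaluationROI(
            u_range=tuple(doc["roi"]["u_range_mm"]),
            v_range=tuple(doc["roi"]["v_range_mm"]),
        )
    return QAReport(
        hd=doc["hd_mm"],
        msd=doc["msd_mm"],
        roi=roi,
        thresholds=doc["thresholds_mm"],
        verdict=doc["verdict"],
        provenance=tuple(doc.get("provenance", ("approach1", "approach2"))),
        reason=doc.get("reason", ""),
    )


def write_config(config: ApertureConfig, path: str | Path) -> None:
    dump_json({"schema_version": SCHEMA_VERSION, **dataclasses.asdict(config)}, path)


def read_config(path: str | Path) -> ApertureConfig:
    doc = load_json(path)
    doc.pop("schema_version", None)
    config = ApertureConfig(**doc)
    config.validate()
    return config


def write_phantom_spec(spec: PhantomSpec, path: str | Path) -> None:
    doc = dataclasses.asdict(spec)
    doc["hu_map"] = dict(doc["hu_map"])
    dump_json({"schema_version": SCHEMA_VERSION, **doc}, path)


def read_phantom_spec(path: str | Path) -> PhantomSpec:
    doc = load_json(path)
    doc.pop("schema_version", None)
    for key in ("head_semi_axes", "brain_semi_axes", "voxel_spacing", "vertebra_heights"):
        doc[key] = tuple(doc[key])
    doc["eye_center_offsets"] = tuple(tuple(e) for e in doc["eye_center_offsets"])
    spec = PhantomSpec(**doc)
    spec.validate()
    return spec
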