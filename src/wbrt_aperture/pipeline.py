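"""End-to-end run: phantom/case -> two structure paths -> apertures -> QA.

The pipeline mirrors the clinical workflow: approach 1 projects the 3D
structure masks into the beam's-eye-view, approach 2 renders a DRR and
delineates the same structures on it, both feed the identical landmark-based
aperture design, and the two resulting apertures are cross-checked by HD/MSD
inside the evaluation ROI.  A failure of the second (QA) path never blocks
the primary aperture: the run completes with a ``flag`` verdict and a reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import io as wio
from .aperture import ApertureConfig, AperturePolygon, LandmarkSet, design_aperture, mirror_aperture
from .phantom import PhantomSpec, StructureVolume, generate_phantom
from .projection import BeamGeometry, project_structures, render_drr
from .qa import QAReport, compare_approaches, evaluation_roi
from .segmentation import IntensityHints, SegmentationError, segment_drr

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]

#: 1 mm BEV sampling: fine enough that landmark positions are voxel-limited,
#: coarse enough that a full run takes well under a second.
DEFAULT_GEOMETRY = BeamGeometry(pixel_spacing=(1.0, 1.0))


@dataclass
class PipelineResult:
    volume: StructureVolume
    aperture1: AperturePolygon
    aperture1_mirrored: AperturePolygon
    landmarks1: LandmarkSet
    aperture2: AperturePolygon | None
    aperture2_mirrored: AperturePolygon | None
    landmarks2: LandmarkSet | None
    report: QAReport

    @property
    def exit_status(self) -> int:
        return 0 if self.report.verdict == "pass" else 2


def run_pipeline(
    source: PhantomSpec | StructureVolume | str | Path,
    config: ApertureConfig | None = None,
    geometry: BeamGeometry | None = None,
    output_dir: str | Path | None = None,
    hints: IntensityHints | None = None,
    write_volumes: bool = False,
) -> PipelineResult:
    """Run both aperture-generation approaches and their QA comparison.

    ``source`` is a phantom spec, an in-memory case, or a case directory.
    When ``output_dir`` is given, all artifacts (apertures, landmarks, QA
    report, DRR, BEV structures, config echo and run log) are written there;
    JSON outputs are deterministic byte-for-byte for identical inputs.
    """
    config = config or ApertureConfig()
    config.validate()
    geometry = geometry or DEFAULT_GEOMETRY

    if isinstance(source, PhantomSpec):
        volume = generate_phantom(source)
        if hints is None:
            hints = IntensityHints.from_spec(source)
        spec = source
    elif isinstance(source, StructureVolume):
        volume = source
        volume.validate()
        spec = None
    else:
        volume = wio.read_case(source)
        spec = None
    hints = hints or IntensityHints()

    # Approach 1: project the 3D masks.
    structures1 = project_structures(volume, geometry)
    aperture1, landmarks1 = design_aperture(structures1, config)
    mirrored1 = mirror_aperture(aperture1)

    # Approach 2: render the DRR and delineate on it.
    drr = render_drr(volume.ct, volume.spacing, volume.origin, geometry)
    aperture2 = mirrored2 = landmarks2 = None
    roi = evaluation_roi(structures1, config)
    try:
        structures2 = segment_drr(drr, hints)
        aperture2, landmarks2 = design_aperture(structures2, config)
        mirrored2 = mirror_aperture(aperture2)
        report = compare_approaches(aperture1, aperture2, roi)
    except (SegmentationError, ValueError) as exc:
        logger.warning("approach 2 failed: %s", exc)
        report = QAReport(
            hd=float("nan"),
            msd=float("nan"),
            roi=roi,
            thresholds=dict(),
            verdict="flag",
            provenance=("approach1", "approach2"),
            reason=f"approach 2 failed: {exc}",
        )

    result = PipelineResult(
        volume=volume,
        aperture1=aperture1,
        aperture1_mirrored=mirrored1,
        landmarks1=landmarks1,
        aperture2=aperture2,
        aperture2_mirrored=mirrored2,
        landmarks2=landmarks2,
        report=report,
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        wio.write_config(config, out / "config.json")
        if spec is not None:
            wio.write_phantom_spec(spec, out / "phantom_spec.json")
        wio.write_landmarks(landmarks1, out / "landmarks_approach1.json")
        wio.write_aperture(aperture1, out / "aperture_approach1_g270.json")
        wio.write_aperture(mirrored1, out / "aperture_approach1_g90.json")
        if aperture2 is not None:
            wio.write_landmarks(landmarks2, out / "landmarks_approach2.json")
            wio.write_aperture(aperture2, out / "aperture_approach2_g270.json")
            wio.write_aperture(mirrored2, out / "aperture_approach2_g90.json")
        wio.write_qa_report(report, out / "qa_report.json")
        wio.write_bev_image(drr, out / "drr_g270.nii")
        wio.write_structure_set(structures1, out / "bev_approach1")
        if aperture2 is not None:
            wio.write_structure_set(structures2, out / "bev_approach2")
        if write_volumes:
            wio.write_case(volume, out / "case")
        from . import __version__

        wio.dump_json(
            {
                "schema_version": wio.SCHEMA_VERSION,
                "package_version": __version__,
                "geometry": {
                    "gantry_deg": geometry.gantry_deg,
                    "model": geometry.model,
                    "sad_mm": geometry.sad,
                    "pixel_spacing_mm": list(geometry.pixel_spacing or ()),
                },
                "verdict": report.verdict,
            },
            out / "run_log.json",
        )
    return result
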