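"""End-to-end orchestration: CT volume + landmarks -> 30-variable record."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import anatomy, centerline as cl, ct_io, meshing
from .anatomy import LandmarkSet, MeasurementRecord, RegionPartition
from .centerline import Centerline, CrossSection
from .ct_io import AirwayMask, CTVolume, ThresholdReport
from .meshing import AirwayMesh

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All intermediate artifacts of one morphometry run."""

    volume: CTVolume
    threshold: ThresholdReport
    mask: AirwayMask
    mesh: AirwayMesh
    faired: AirwayMesh
    centerline: Centerline
    sections: list[CrossSection]
    partition: RegionPartition
    record: MeasurementRecord


def run_pipeline(
    volume: CTVolume,
    landmarks: LandmarkSet,
    seed: tuple[int, int, int] | None = None,
    roi_superior: float | None = None,
    roi_inferior: float | None = None,
    threshold: float | None = None,
    lambda_dt: float = meshing.DEFAULT_LAMBDA_DT,
    fairing_iterations: int = meshing.DEFAULT_ITERATIONS,
    contour_spacing: float = cl.DEFAULT_CONTOUR_SPACING,
    resample_step: float = cl.DEFAULT_RESAMPLE_STEP,
) -> PipelineResult:
    """Segment, mesh, fair, extract the centerline and measure one scan.

    When ``seed`` is omitted the darkest voxel (deepest air) is used; when
    the ROI bounds are omitted the full axial extent is used — appropriate
    for volumes already cropped between the choanae and the first tracheal
    ring, and for phantoms.
    """
    if volume.kernel != "standard":
        volume = ct_io.harmonize_kernel(volume)

    report = ct_io.compute_airway_threshold(volume)
    thr = report.upper_threshold if threshold is None else threshold

    if seed is None:
        seed = tuple(int(i) for i in np.unravel_index(np.argmin(volume.voxels), volume.voxels.shape))
    z = volume.axis_positions(2)
    sup = float(z[-1]) if roi_superior is None else roi_superior
    inf = float(z[0]) if roi_inferior is None else roi_inferior

    mask = ct_io.segment_airway(volume, thr, seed, roi_superior=sup, roi_inferior=inf)
    mesh = meshing.extract_surface(mask, hu_volume=volume.voxels, threshold=thr)
    faired = meshing.fair_mesh(mesh, lambda_dt=lambda_dt, iterations=fairing_iterations)
    line = cl.extract_centerline(
        faired, contour_spacing=contour_spacing, resample_step=resample_step
    )
    sections = cl.slice_orthogonal(faired, line)
    partition = anatomy.partition_regions(line, landmarks)
    record = anatomy.measure_all(volume, mask, faired, line, sections, landmarks)
    return PipelineResult(
        volume=volume,
        threshold=report,
        mask=mask,
        mesh=mesh,
        faired=faired,
        centerline=line,
        sections=sections,
        partition=partition,
        record=record,
    )
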