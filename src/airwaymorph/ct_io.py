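"""CT volume I/O, kernel harmonization, histogram thresholding and airway segmentation.

All volumes are held in a single internal convention: array axes (i, j, k)
map to patient Right, Anterior, Superior (RAS), positions in millimeters,
intensities in Hounsfield units (HU).  DICOM series and NIfTI files are
reoriented on load so that every downstream module can reason about
"anterior", "lateral" and "superior" directly on array axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

__all__ = [
    "CTVolume",
    "AirwayMask",
    "ThresholdReport",
    "AIR_WINDOW",
    "TISSUE_WINDOW",
    "load_volume",
    "save_volume_nifti",
    "save_mask_nifti",
    "harmonize_kernel",
    "compute_airway_threshold",
    "segment_airway",
]

#: HU windows searched for the air and soft-tissue histogram peaks.  The
#: tissue window is slightly wider than the textbook +100..+300 HU band so
#: that noisy or low-density tissue still yields a peak.
AIR_WINDOW = (-1100.0, -900.0)
TISSUE_WINDOW = (50.0, 350.0)

_HIST_BIN_WIDTH = 10.0  # HU
_HIST_RANGE = (-1100.0, 400.0)

_KERNEL_TAGS = ("standard", "soft", "bone", "unknown")


@dataclass
class CTVolume:
    """A calibrated HU voxel grid in RAS millimeter patient space.

    ``voxels[i, j, k]`` sits at ``origin + (i, j, k) * spacing``; axis 0
    points patient-Right, axis 1 patient-Anterior, axis 2 patient-Superior.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axes: tuple[str, str, str] = ("R", "A", "S")
    kernel: str = "unknown"
    scan_id: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        if tuple(self.axes) != ("R", "A", "S"):
            raise ValueError("internal volumes must be in RAS order")
        if self.kernel not in _KERNEL_TAGS:
            raise ValueError(f"unknown kernel tag {self.kernel!r}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def axis_positions(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one array axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


@dataclass
class AirwayMask:
    """Boolean lumen mask aligned voxel-for-voxel to a :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    roi_superior: float
    roi_inferior: float
    seed: tuple[int, int, int]
    scan_id: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.roi_inferior >= self.roi_superior:
            raise ValueError("roi_inferior must lie below roi_superior")

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum() * np.prod(self.spacing))


@dataclass(frozen=True)
class ThresholdReport:
    """Histogram peaks and the midpoint segmentation threshold, all in HU."""

    air_peak: float
    tissue_peak: float
    upper_threshold: float

    def __post_init__(self) -> None:
        if not (self.air_peak < self.upper_threshold < self.tissue_peak):
            raise ValueError("threshold must lie between the two peaks")
        if self.upper_threshold != (self.air_peak + self.tissue_peak) / 2.0:
            raise ValueError("upper_threshold must be the exact midpoint")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


# ---------------------------------------------------------------------------
# loading


def load_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` file or a directory of single-frame DICOM
        slices belonging to one series.
    format
        ``"nifti"`` or ``"dicom_series"``; inferred from ``path`` if omitted.
    """
    path = Path(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        img = nib.load(str(path))
        return _from_nifti(img, scan_id=path.name, kernel="unknown")
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _from_nifti(img, scan_id: str | None, kernel: str) -> CTVolume:
    can = nib.as_closest_canonical(img)
    aff = can.affine
    rot = aff[:3, :3]
    spacing = np.sqrt((rot**2).sum(axis=0))
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-3 * spacing.max():
        raise ValueError("oblique volumes are not supported; resample first")
    data = np.asarray(can.dataobj, dtype=float)
    return CTVolume(
        voxels=data,
        spacing=np.diag(rot),
        origin=aff[:3, 3],
        kernel=kernel,
        scan_id=scan_id,
    )


_KERNEL_ALIASES = {
    "standard": "standard",
    "std": "standard",
    "soft": "soft",
    "smooth": "soft",
    "bone": "bone",
    "sharp": "bone",
    "edge": "bone",
}


def _kernel_from_tag(raw: str | None) -> str:
    if not raw:
        return "unknown"
    low = str(raw).lower()
    for key, tag in _KERNEL_ALIASES.items():
        if key in low:
            return tag
    return "unknown"


def _load_dicom_series(directory: Path) -> CTVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {directory}")

    first = slices[0]
    if "RescaleSlope" not in first or "RescaleIntercept" not in first:
        raise ValueError("missing HU calibration metadata (RescaleSlope/Intercept)")
    iop = np.asarray(first.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)

    slices.sort(key=lambda ds: float(np.dot(ds.ImagePositionPatient, normal)))
    pos = np.array([np.dot(np.asarray(ds.ImagePositionPatient, float), normal) for ds in slices])
    if len(slices) > 1:
        steps = np.diff(pos)
        if steps.min() <= 0 or (steps.max() - steps.min()) > 1e-3 * np.abs(steps).mean() + 1e-6:
            raise ValueError("inconsistent slice spacing in DICOM series")

    vol = np.stack(
        [
            ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
            for ds in slices
        ]
    )  # (slice, row, col)
    dr, dc = (float(v) for v in first.PixelSpacing)
    slice_vec = (
        normal * (pos[1] - pos[0]) if len(slices) > 1 else normal * float(getattr(first, "SliceThickness", 1.0))
    )
    ipp0 = np.asarray(first.ImagePositionPatient, dtype=float)

    # Affine over (slice, row, col) index order, LPS patient coordinates.
    aff_lps = np.eye(4)
    aff_lps[:3, 0] = slice_vec
    aff_lps[:3, 1] = col_dir * dr
    aff_lps[:3, 2] = row_dir * dc
    aff_lps[:3, 3] = ipp0
    flip = np.diag([-1.0, -1.0, 1.0, 1.0])  # LPS -> RAS
    img = nib.Nifti1Image(vol, flip @ aff_lps)
    kernel = _kernel_from_tag(getattr(first, "ConvolutionKernel", None))
    scan_id = str(getattr(first, "SeriesInstanceUID", directory.name))
    return _from_nifti(img, scan_id=scan_id, kernel=kernel)


def save_volume_nifti(volume: CTVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.voxels, volume.affine), str(path))


def save_mask_nifti(mask: AirwayMask, path: str | Path) -> None:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(mask.spacing)
    aff[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), aff), str(path))


# ---------------------------------------------------------------------------
# kernel harmonization


def harmonize_kernel(volume: CTVolume, amount: float = 1.0) -> CTVolume:
    """Map soft/bone reconstruction kernels onto the standard kernel.

    Soft-kernel volumes are sharpened with a 5x5 unsharp enhancement per
    axial slice (``out = in + amount * (in - boxmean5(in))``); bone-kernel
    volumes are smoothed with a 3x3 uniform low-pass per axial slice.  The
    standard kernel passes through unchanged.  Boundaries are reflective.
    """
    if volume.kernel == "standard":
        return volume
    if volume.kernel == "unknown":
        raise ValueError(
            "kernel tag is unknown; pass an explicit kernel tag on the volume"
        )
    if volume.kernel == "soft":
        blurred = ndimage.uniform_filter(volume.voxels, size=(5, 5, 1), mode="reflect")
        out = volume.voxels + amount * (volume.voxels - blurred)
    else:  # bone
        out = ndimage.uniform_filter(volume.voxels, size=(3, 3, 1), mode="reflect")
    return replace(volume, voxels=out, kernel="standard")


# ---------------------------------------------------------------------------
# threshold


def compute_airway_threshold(
    volume: CTVolume,
    roi: tuple[slice, slice, slice] | None = None,
) -> ThresholdReport:
    """Image-specific airway threshold from the HU histogram.

    The HU histogram (10-HU bins centered on multiples of 10, smoothed by a
    3-bin moving average) is searched for its modal bin in the air window
    (about -1000 HU) and in the soft-tissue window; the segmentation
    threshold is the exact arithmetic midpoint of the two peak positions.
    """
    data = volume.voxels[roi] if roi is not None else volume.voxels
    values = data.ravel()

    lo, hi = _HIST_RANGE
    edges = np.arange(lo - _HIST_BIN_WIDTH / 2, hi + _HIST_BIN_WIDTH, _HIST_BIN_WIDTH)
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smoothed = np.convolve(counts, np.ones(3) / 3.0, mode="same")

    def peak(window: tuple[float, float], name: str) -> float:
        sel = (centers >= window[0]) & (centers <= window[1])
        if counts[sel].sum() == 0:
            raise ValueError(
                f"no voxels in the {name} search window {window[0]:+.0f}..{window[1]:+.0f} HU"
            )
        idx = np.flatnonzero(sel)
        best = smoothed[idx] == smoothed[idx].max()
        # ties after smoothing (e.g. a delta-like peak) resolve to the bin
        # with the largest raw count
        cand = idx[best]
        return float(centers[cand[np.argmax(counts[cand])]])

    air = peak(AIR_WINDOW, "air")
    tissue = peak(TISSUE_WINDOW, "soft tissue")
    return ThresholdReport(air_peak=air, tissue_peak=tissue, upper_threshold=(air + tissue) / 2.0)


# ---------------------------------------------------------------------------
# segmentation

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_airway(
    volume: CTVolume,
    threshold: float,
    seed: tuple[int, int, int],
    roi_superior: float,
    roi_inferior: float,
) -> AirwayMask:
    """Seeded connected-component segmentation of the airway lumen.

    Voxels with HU <= ``threshold`` inside the axial band
    ``[roi_inferior, roi_superior]`` (mm, superior axis) are labeled with
    26-connectivity; the component containing ``seed`` is the lumen.  Air
    not connected to the seed inside the band (e.g. outside the body) is
    excluded.
    """
    if roi_inferior >= roi_superior:
        raise ValueError("roi_inferior must lie below roi_superior")
    seed = tuple(int(v) for v in seed)
    shape = volume.voxels.shape
    if not all(0 <= s < n for s, n in zip(seed, shape)):
        raise ValueError(f"seed {seed} outside volume of shape {shape}")

    air = volume.voxels <= threshold
    z = volume.axis_positions(2)
    in_band = (z >= roi_inferior) & (z <= roi_superior)
    air[:, :, ~in_band] = False

    if not air[seed]:
        raise ValueError("seed voxel above threshold (or outside the axial ROI)")

    labels, _ = ndimage.label(air, structure=_CONN26)
    mask = labels == labels[seed]
    if not mask.any():
        raise ValueError("segmented component empty after ROI clipping")
    return AirwayMask(
        voxels=mask,
        spacing=volume.spacing,
        origin=volume.origin,
        roi_superior=float(roi_superior),
        roi_inferior=float(roi_inferior),
        seed=seed,
        scan_id=volume.scan_id,
    )
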