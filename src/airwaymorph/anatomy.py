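"""Landmark schema, pharyngeal region partition and the 30 airway variables.

The airway between the choanae and the first tracheal ring is divided into
four contiguous regions — nasopharynx, oropharynx, laryngopharynx and
subglottal — by five planes orthogonal to the centerline: the palatal-plane
(ANS-PNS) crossing, the velum tip, the aryepiglottic-fold midpoint, the
glottis and the tracheal end.  Each region contributes a volume, a
centerline length and the area/AP-distance/width of one bounding
cross-section; vocal-tract, velum and piriform-sinus lengths complete the
30-variable record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .centerline import Centerline, CrossSection, compute_section
from .meshing import AirwayMesh

__all__ = [
    "LANDMARK_NAMES",
    "DERIVED_LANDMARKS",
    "OPTIONAL_LANDMARKS",
    "VARIABLES",
    "VARIABLE_UNITS",
    "LandmarkSet",
    "RegionPartition",
    "MeasurementRecord",
    "resolve_landmarks",
    "partition_regions",
    "measure_partition",
    "vtl_incisor",
    "velum_length",
    "piriform_lengths",
    "average_relative_error",
    "measure_all",
    "write_tidy_csv",
    "write_wide_csv",
]

#: The 26 anatomic landmark abbreviations (20 pharyngeal, 2 reference,
#: 4 maxillary), inferior to superior.
LANDMARK_NAMES = (
    "ga", "gp", "epS", "epBse", "epBsePo",
    "PSInL", "PSInR", "PSSuL", "PSSuR",
    "VaInL", "VaInR",
    "VeAn", "VePo", "MidVe", "VeBa", "VeEnd",
    "NpxAn", "NpxPo", "NpxMid", "NasalS",
    "ANS", "PNS",
    "ABI", "PIC", "PALS", "MMax",
)

#: Landmarks computed from their parents (supplied values are overwritten).
DERIVED_LANDMARKS = {
    "MidVe": ("VeAn", "VePo"),
    "NpxMid": ("NpxAn", "NpxPo"),
    "MMax": ("PIC", "PALS"),
}

#: Unilateral piriform sinus is permitted.
OPTIONAL_LANDMARKS = frozenset({"PSInL", "PSInR"})

_REGION_PREFIX = ("Nasopharynx", "Oropharynx", "Laryngopharynx")

#: The 30 measurement variables, in report order.
VARIABLES = (
    "Nasopharynx", "NasopharynxL", "NasopharynxArea", "NasopharynxAPDist", "NasopharynxWidth",
    "Oropharynx", "OropharynxL", "OropharynxArea", "OropharynxAPDist", "OropharynxWidth",
    "Laryngopharynx", "LaryngopharynxL", "LaryngopharynxArea", "LaryngopharynxAPDist", "LaryngopharynxWidth",
    "PharynxVolume", "PharynxLength",
    "GlottisArea", "GlottisAPDist", "GlottisWidth",
    "Subglottal", "SubglottalL", "TracheaArea", "TracheaAPDist", "TracheaWidth",
    "VTLength_i", "VelumLength", "PSLengthLeft", "PSLengthRight", "AveragePSLength",
)


def _unit_for(name: str) -> str:
    if name in ("Nasopharynx", "Oropharynx", "Laryngopharynx", "PharynxVolume", "Subglottal"):
        return "mm3"
    if name.endswith("Area"):
        return "mm2"
    return "mm"


VARIABLE_UNITS = {name: _unit_for(name) for name in VARIABLES}

_MISSING_ALLOWED = frozenset({"PSLengthLeft", "PSLengthRight"})


@dataclass
class LandmarkSet:
    """Validated mapping of the 26 landmark abbreviations to RAS points (mm)."""

    coordinates: dict[str, np.ndarray]
    scan_id: str | None = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.coordinates[name]

    def __contains__(self, name: str) -> bool:
        return name in self.coordinates and self.coordinates[name] is not None

    def midpoint(self, a: str, b: str) -> np.ndarray:
        return 0.5 * (self[a] + self[b])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {k: (None if v is None else list(map(float, v))) for k, v in self.coordinates.items()},
                indent=2,
            )
        )


def resolve_landmarks(
    raw: Mapping[str, np.ndarray | None] | str | Path,
    scan_id: str | None = None,
) -> LandmarkSet:
    """Validate a raw landmark mapping against the 26-name schema.

    Derived landmarks (MidVe, NpxMid, MMax) are recomputed from their
    parents, overwriting supplied values.  ``raw`` may be a mapping or a
    path to a JSON file / CSV with columns ``name,x,y,z``.
    """
    if isinstance(raw, (str, Path)):
        path = Path(raw)
        if path.suffix.lower() == ".json":
            loaded = json.loads(path.read_text())
            raw = {k: (None if v is None else np.asarray(v, float)) for k, v in loaded.items()}
        else:
            df = pd.read_csv(path)
            raw = {r["name"]: np.array([r.x, r.y, r.z], float) for _, r in df.iterrows()}

    known = set(LANDMARK_NAMES)
    for name in raw:
        if name not in known:
            raise ValueError(f"unknown landmark name: {name}")

    coords: dict[str, np.ndarray | None] = {}
    for name in LANDMARK_NAMES:
        if name in DERIVED_LANDMARKS:
            continue
        val = raw.get(name)
        if val is None:
            if name in OPTIONAL_LANDMARKS:
                coords[name] = None
                continue
            raise ValueError(f"missing required landmark: {name}")
        coords[name] = np.asarray(val, dtype=float).reshape(3)

    for name, (pa, pb) in DERIVED_LANDMARKS.items():
        coords[name] = 0.5 * (coords[pa] + coords[pb])

    if coords["ANS"][1] <= coords["PNS"][1]:
        raise ValueError("ANS must lie anterior to PNS (ANS_y > PNS_y)")
    return LandmarkSet(coordinates=coords, scan_id=scan_id)


@dataclass
class RegionPartition:
    """Five centerline arc-length boundaries defining the four regions.

    ``s_a`` palatal-plane crossing, ``s_b`` velum tip, ``s_c``
    aryepiglottic-fold midpoint, ``s_d`` glottis, ``s_e`` tracheal end.
    """

    s_a: float
    s_b: float
    s_c: float
    s_d: float
    s_e: float

    def __post_init__(self) -> None:
        b = self.bounds
        if any(b[i] > b[i + 1] for i in range(4)):
            raise ValueError(
                "boundaries out of order: "
                + ", ".join(f"{n}={v:.2f}" for n, v in zip("abcde", b))
            )

    @property
    def bounds(self) -> tuple[float, float, float, float, float]:
        return (self.s_a, self.s_b, self.s_c, self.s_d, self.s_e)

    @property
    def regions(self) -> dict[str, tuple[float, float]]:
        return {
            "Nasopharynx": (self.s_a, self.s_b),
            "Oropharynx": (self.s_b, self.s_c),
            "Laryngopharynx": (self.s_c, self.s_d),
            "Subglottal": (self.s_d, self.s_e),
        }


def partition_regions(centerline: Centerline, landmarks: LandmarkSet) -> RegionPartition:
    """Locate the five region boundaries on the centerline.

    The palatal boundary is a true centerline/plane crossing (plane through
    the ANS-PNS line with zero lateral tilt); the velum, aryepiglottic and
    glottal boundaries are the arc lengths of the centerline points closest
    to their anchor landmarks; the tracheal end is the centerline end (the
    segmentation was clipped at the first tracheal ring).
    """
    ans, pns = landmarks["ANS"], landmarks["PNS"]
    direction = ans - pns
    lateral = np.array([1.0, 0.0, 0.0])
    normal = np.cross(lateral, direction)
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        raise ValueError("degenerate palatal plane (ANS-PNS parallel to lateral axis)")
    normal /= nn

    signed = (centerline.points - pns) @ normal
    crossings = np.flatnonzero(np.sign(signed[:-1]) * np.sign(signed[1:]) < 0)
    exact = np.flatnonzero(signed == 0)
    if len(exact):
        s_a = float(centerline.arc_length[exact[0]])
    elif len(crossings):
        i = crossings[0]  # most superior crossing
        w = signed[i] / (signed[i] - signed[i + 1])
        s_a = float((1 - w) * centerline.arc_length[i] + w * centerline.arc_length[i + 1])
    else:
        raise ValueError("centerline does not cross the palatal plane")

    s_b = centerline.project(landmarks["VeEnd"])
    s_c = centerline.project(landmarks.midpoint("PSSuL", "PSSuR"))
    s_d = centerline.project(landmarks.midpoint("ga", "gp"))
    s_e = centerline.length
    return RegionPartition(s_a=s_a, s_b=s_b, s_c=s_c, s_d=s_d, s_e=s_e)


# ---------------------------------------------------------------------------
# measurements

_BOUNDARY_EPS = 0.5  # mm pulled inside the centerline span when a boundary
#                       coincides with an end cap (a plane through the cap
#                       itself has no interior contour)


def _boundary_section(mesh_tm, centerline: Centerline, s: float) -> CrossSection:
    lo = centerline.arc_length[0] + _BOUNDARY_EPS
    hi = centerline.arc_length[-1] - _BOUNDARY_EPS
    point, tangent = centerline.interpolate(float(np.clip(s, lo, hi)))
    return compute_section(mesh_tm, point, tangent)


def measure_partition(
    mesh: AirwayMesh,
    centerline: Centerline,
    sections: list[CrossSection],
    partition: RegionPartition,
) -> dict[str, float]:
    """The 25 regional variables (volumes, lengths, boundary CSAs/extents).

    Region volumes are trapezoidal integrals of the orthogonal section
    areas over arc length; boundary sections falling between centerline
    samples are recomputed at the interpolated plane, not interpolated from
    neighbors.
    """
    tm = mesh.to_trimesh()
    s_of = {sec.centerline_index: centerline.arc_length[sec.centerline_index] for sec in sections}
    interior = [(s_of[sec.centerline_index], sec.area) for sec in sections if not sec.empty]

    bounds = partition.bounds
    bsecs = [_boundary_section(tm, centerline, s) for s in bounds]
    names = ("palatal", "velum-tip", "aryepiglottic", "glottis", "tracheal-end")
    for name, bs in zip(names, bsecs):
        if bs.empty:
            raise ValueError(f"boundary section empty at the {name} plane")

    def region_volume(s0: float, s1: float, a0: float, a1: float) -> float:
        if s1 <= s0:
            return 0.0
        ss = [s0] + [s for s, _ in interior if s0 + 1e-9 < s < s1 - 1e-9] + [s1]
        aa = [a0] + [a for s, a in interior if s0 + 1e-9 < s < s1 - 1e-9] + [a1]
        return float(np.trapezoid(aa, ss))

    out: dict[str, float] = {}
    region_bounds = list(zip(bounds[:-1], bounds[1:]))
    region_names = ("Nasopharynx", "Oropharynx", "Laryngopharynx", "Subglottal")
    for name, (s0, s1), b0, b1 in zip(region_names, region_bounds, bsecs[:-1], bsecs[1:]):
        vol = region_volume(s0, s1, b0.area, b1.area)
        out[name] = vol
        out[name + "L"] = float(s1 - s0)

    # Boundary CSAs: superior border for the three pharyngeal regions, the
    # glottis (superior border of the subglottal region) and the tracheal
    # end (its inferior border).
    for name, bs in zip(_REGION_PREFIX, bsecs[:3]):
        out[name + "Area"] = bs.area
        out[name + "APDist"] = bs.ap_dist
        out[name + "Width"] = bs.width
    out["GlottisArea"] = bsecs[3].area
    out["GlottisAPDist"] = bsecs[3].ap_dist
    out["GlottisWidth"] = bsecs[3].width
    out["TracheaArea"] = bsecs[4].area
    out["TracheaAPDist"] = bsecs[4].ap_dist
    out["TracheaWidth"] = bsecs[4].width

    out["PharynxVolume"] = out["Nasopharynx"] + out["Oropharynx"] + out["Laryngopharynx"]
    out["PharynxLength"] = out["NasopharynxL"] + out["OropharynxL"] + out["LaryngopharynxL"]
    return out


def vtl_incisor(
    centerline: Centerline,
    partition: RegionPartition,
    landmarks: LandmarkSet,
) -> float:
    """Vocal-tract length from the maxillary incisor to the glottis.

    The oral segment is the polyline ABI -> MMax -> PNS -> palatal
    centerline point; the pharyngeal segment follows the centerline from
    the palatal crossing to the glottis.
    """
    for name in ("ABI", "MMax", "PNS"):
        if name not in landmarks:
            raise ValueError(f"missing oral landmark: {name}")
    p_a, _ = centerline.interpolate(partition.s_a)
    path = [landmarks["ABI"], landmarks["MMax"], landmarks["PNS"], p_a]
    oral = sum(float(np.linalg.norm(b - a)) for a, b in zip(path[:-1], path[1:]))
    return oral + (partition.s_d - partition.s_a)


def velum_length(landmarks: LandmarkSet) -> float:
    """Curvilinear velum length from PNS to the velum tip.

    The path is a quadratic Bezier arc with control polygon
    PNS -> VeBa -> VeEnd: VeBa (the supero-posterior bend of the velum)
    controls the curvature, and the arc length always lies between the
    straight PNS-VeEnd chord and the two-segment polyline.  When VeBa is
    the chord midpoint the arc degenerates to the straight line.
    """
    for name in ("PNS", "VeBa", "VeEnd"):
        if name not in landmarks:
            raise ValueError(f"missing velum landmark: {name}")
    p0, p1, p2 = landmarks["PNS"], landmarks["VeBa"], landmarks["VeEnd"]

    def speed(t: float) -> float:
        return float(np.linalg.norm(2.0 * ((1.0 - t) * (p1 - p0) + t * (p2 - p1))))

    length, _ = quad(speed, 0.0, 1.0, limit=200)
    return float(length)


def piriform_lengths(landmarks: LandmarkSet) -> tuple[float | None, float | None, float]:
    """Left/right piriform sinus lengths and their average.

    Each side is the 3D distance from the aryepiglottic-fold midpoint to
    the inferior piriform point; a side with an incomplete pair is missing,
    and the average falls back to the single available side.
    """
    left = right = None
    if "PSSuL" in landmarks and "PSInL" in landmarks:
        left = float(np.linalg.norm(landmarks["PSSuL"] - landmarks["PSInL"]))
    if "PSSuR" in landmarks and "PSInR" in landmarks:
        right = float(np.linalg.norm(landmarks["PSSuR"] - landmarks["PSInR"]))
    if left is None and right is None:
        raise ValueError("both piriform sinus landmark pairs incomplete")
    if left is None:
        return None, right, right
    if right is None:
        return left, None, left
    return left, right, 0.5 * (left + right)


@dataclass
class MeasurementRecord:
    """The full 30-variable morphometric record for one scan."""

    values: dict[str, float | None]
    scan_id: str | None = None
    units: dict[str, str] = field(default_factory=lambda: dict(VARIABLE_UNITS))

    def __post_init__(self) -> None:
        if set(self.values) != set(VARIABLES):
            missing = set(VARIABLES) - set(self.values)
            extra = set(self.values) - set(VARIABLES)
            raise ValueError(f"record must have exactly the 30 variables; missing={sorted(missing)} extra={sorted(extra)}")
        for name, val in self.values.items():
            if val is None:
                if name not in _MISSING_ALLOWED:
                    raise ValueError(f"{name} may not be missing")
                continue
            if not val > 0:
                raise ValueError(f"{name} must be positive, got {val}")
        v = self.values
        if v["PharynxVolume"] != v["Nasopharynx"] + v["Oropharynx"] + v["Laryngopharynx"]:
            raise ValueError("PharynxVolume must equal the sum of its subregions")
        if v["PharynxLength"] != v["NasopharynxL"] + v["OropharynxL"] + v["LaryngopharynxL"]:
            raise ValueError("PharynxLength must equal the sum of its subregions")

    def __getitem__(self, name: str) -> float | None:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in VARIABLES}, name=self.scan_id)


def average_relative_error(
    a: MeasurementRecord | Mapping[str, float | None],
    b: MeasurementRecord | Mapping[str, float | None],
) -> float:
    """Symmetric average relative error over shared non-missing variables.

    ``ARE = mean(|a - b| / mean(a, b))`` — the inter-rater reliability
    statistic, also used as the phantom accuracy bar.
    """
    va = a.values if isinstance(a, MeasurementRecord) else dict(a)
    vb = b.values if isinstance(b, MeasurementRecord) else dict(b)
    shared = [k for k in va if k in vb and va[k] is not None and vb[k] is not None]
    if not shared:
        raise ValueError("records share no non-missing variables")
    errs = []
    for k in shared:
        denom = 0.5 * (va[k] + vb[k])
        if denom == 0:
            raise ValueError(f"zero denominator for variable {k}")
        errs.append(abs(va[k] - vb[k]) / denom)
    return float(np.mean(errs))


def measure_all(
    volume,
    mask,
    mesh: AirwayMesh,
    centerline: Centerline,
    sections: list[CrossSection],
    landmarks: LandmarkSet,
) -> MeasurementRecord:
    """Assemble the complete 30-variable record for one scan."""
    ids = {
        getattr(obj, "scan_id", None)
        for obj in (volume, mask, mesh, centerline, landmarks)
        if getattr(obj, "scan_id", None) is not None
    }
    if len(ids) > 1:
        raise ValueError(f"inconsistent provenance across pipeline artifacts: {sorted(ids)}")
    scan_id = ids.pop() if ids else None

    partition = partition_regions(centerline, landmarks)
    values = measure_partition(mesh, centerline, sections, partition)
    values["VTLength_i"] = vtl_incisor(centerline, partition, landmarks)
    values["VelumLength"] = velum_length(landmarks)
    left, right, avg = piriform_lengths(landmarks)
    values["PSLengthLeft"] = left
    values["PSLengthRight"] = right
    values["AveragePSLength"] = avg
    return MeasurementRecord(values=values, scan_id=scan_id)


def write_tidy_csv(records: list[MeasurementRecord], path: str | Path) -> None:
    rows = [
        {"scan_id": r.scan_id, "variable": k, "value": r.values[k], "units": r.units[k]}
        for r in records
        for k in VARIABLES
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_wide_csv(records: list[MeasurementRecord], path: str | Path) -> None:
    df = pd.DataFrame([r.to_series() for r in records])
    df.index.name = "scan_id"
    df.to_csv(path)
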