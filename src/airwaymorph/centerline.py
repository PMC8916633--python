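"""Centerline extraction and orthogonal cross-sectional morphometry.

The lumen centerline is recovered in three stages: (1) the faired surface is
sliced by parallel planes along the dominant (superior) axis and the area
centroid of each level contour is recorded; (2) a smoothing cubic B-spline
is fitted through the centroid sequence; (3) one refinement pass re-slices
the surface orthogonally to the current tangents, recomputes centroids and
refits, so that obliquely oriented segments (e.g. the subglottal bend) are
centered correctly.  Cross-sections are the intersections of the surface
with planes orthogonal to each centerline segment; their area, anterior-
posterior distance and lateral width are the morphometric primitives used
throughout the regional measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.interpolate import splev, splprep
from shapely.geometry import Polygon

from .meshing import AirwayMesh

__all__ = [
    "Centerline",
    "CrossSection",
    "extract_centerline",
    "slice_orthogonal",
    "section_extents",
    "inplane_axes",
    "compute_section",
]

DEFAULT_CONTOUR_SPACING = 2.0  # mm
DEFAULT_RESAMPLE_STEP = 1.0  # mm

_AP_AXIS = np.array([0.0, 1.0, 0.0])  # patient anterior
_LR_AXIS = np.array([1.0, 0.0, 0.0])  # patient right


@dataclass
class Centerline:
    """Ordered superior-to-inferior polyline through the lumen center.

    ``tangents[i]`` is the unit tangent of the segment from point ``i`` to
    point ``i + 1``; the last entry repeats the final segment tangent.
    """

    points: np.ndarray
    arc_length: np.ndarray
    tangents: np.ndarray
    scan_id: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        if len(self.points) < 2:
            raise ValueError("centerline needs at least two points")
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc_length must be strictly increasing")
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("tangents must be unit vectors")

    @classmethod
    def from_points(cls, points: np.ndarray, scan_id: str | None = None) -> "Centerline":
        points = np.asarray(points, dtype=float)
        seg = np.diff(points, axis=0)
        lengths = np.linalg.norm(seg, axis=1)
        keep = lengths > 1e-12
        if not keep.all():  # drop coincident points
            points = np.vstack([points[:-1][keep], points[-1]])
            seg = np.diff(points, axis=0)
            lengths = np.linalg.norm(seg, axis=1)
        arc = np.concatenate([[0.0], np.cumsum(lengths)])
        tang = seg / lengths[:, None]
        tang = np.vstack([tang, tang[-1]])
        return cls(points=points, arc_length=arc, tangents=tang, scan_id=scan_id)

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def interpolate(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        """Point and unit tangent at arc length ``s`` (linear within segments)."""
        s = float(np.clip(s, self.arc_length[0], self.arc_length[-1]))
        i = int(np.searchsorted(self.arc_length, s, side="right") - 1)
        i = min(max(i, 0), len(self.points) - 2)
        s0, s1 = self.arc_length[i], self.arc_length[i + 1]
        w = (s - s0) / (s1 - s0)
        return (1 - w) * self.points[i] + w * self.points[i + 1], self.tangents[i]

    def project(self, point: np.ndarray) -> float:
        """Arc length of the closest point on the polyline to ``point``."""
        p = np.asarray(point, dtype=float)
        a = self.points[:-1]
        d = self.points[1:] - a
        seg_len2 = (d**2).sum(axis=1)
        t = np.clip(((p - a) * d).sum(axis=1) / seg_len2, 0.0, 1.0)
        proj = a + t[:, None] * d
        dist2 = ((proj - p) ** 2).sum(axis=1)
        i = int(np.argmin(dist2))
        return float(self.arc_length[i] + t[i] * np.sqrt(seg_len2[i]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "points": self.points.tolist(),
                    "arc_length": self.arc_length.tolist(),
                    "tangents": self.tangents.tolist(),
                    "scan_id": self.scan_id,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Centerline":
        d = json.loads(Path(path).read_text())
        return cls(
            points=np.asarray(d["points"]),
            arc_length=np.asarray(d["arc_length"]),
            tangents=np.asarray(d["tangents"]),
            scan_id=d.get("scan_id"),
        )


@dataclass
class CrossSection:
    """One planar cut of the lumen orthogonal to the centerline.

    ``boundary`` is a closed 3D polygon (first vertex not repeated) or
    ``None`` when the plane misses the surface (flagged empty, never
    fabricated).
    """

    centerline_index: int
    plane_point: np.ndarray
    plane_normal: np.ndarray
    boundary: np.ndarray | None
    area: float
    ap_dist: float
    width: float

    @property
    def empty(self) -> bool:
        return self.boundary is None


# ---------------------------------------------------------------------------
# plane geometry helpers


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.zeros(3)
    helper[np.argmin(np.abs(n))] = 1.0
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def _close_loop(loop: np.ndarray) -> np.ndarray:
    if len(loop) > 1 and np.allclose(loop[0], loop[-1]):
        return loop[:-1]
    return loop


def _contours(tm: trimesh.Trimesh, origin: np.ndarray, normal: np.ndarray) -> list[np.ndarray]:
    sec = tm.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return []
    loops = [_close_loop(np.asarray(d)) for d in sec.discrete]
    return [lp for lp in loops if len(lp) >= 3]


def _polygon_area_centroid(loop: np.ndarray, origin: np.ndarray, normal: np.ndarray):
    e1, e2 = _plane_basis(normal)
    rel = loop - origin
    xy = np.column_stack([rel @ e1, rel @ e2])
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    c = poly.centroid
    centroid3 = origin + c.x * e1 + c.y * e2
    return float(poly.area), centroid3


def inplane_axes(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Patient anterior and right axes projected into a section plane.

    Raises if the plane is perpendicular to the anterior axis (the AP
    extent is then undefined).
    """
    n = normal / np.linalg.norm(normal)
    ap = _AP_AXIS - (_AP_AXIS @ n) * n
    if np.linalg.norm(ap) < 1e-6:
        raise ValueError("section plane degenerate with respect to patient axes")
    ap /= np.linalg.norm(ap)
    lr = _LR_AXIS - (_LR_AXIS @ n) * n
    lr -= (lr @ ap) * ap  # exact orthogonality within the plane
    if np.linalg.norm(lr) < 1e-6:
        raise ValueError("section plane degenerate with respect to patient axes")
    return ap, lr / np.linalg.norm(lr)


def section_extents(
    section: CrossSection | np.ndarray,
    ap_axis: np.ndarray,
    lr_axis: np.ndarray,
) -> tuple[float, float]:
    """AP distance and lateral width of a section boundary.

    Extents are ranges of the boundary vertices projected on the two
    (orthonormal) in-plane axes.
    """
    boundary = section.boundary if isinstance(section, CrossSection) else np.asarray(section)
    if boundary is None or len(boundary) == 0:
        raise ValueError("empty section boundary")
    ap_axis = np.asarray(ap_axis, dtype=float)
    lr_axis = np.asarray(lr_axis, dtype=float)
    for v in (ap_axis, lr_axis):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("orientation axes must be unit vectors")
    if abs(ap_axis @ lr_axis) > 1e-6:
        raise ValueError("orientation axes must be orthogonal")
    pa = boundary @ ap_axis
    pl = boundary @ lr_axis
    return float(pa.max() - pa.min()), float(pl.max() - pl.min())


def compute_section(
    mesh: AirwayMesh | trimesh.Trimesh,
    point: np.ndarray,
    normal: np.ndarray,
    index: int = -1,
) -> CrossSection:
    """Cut the surface at one plane and keep the contour nearest ``point``.

    When a plane cuts the lumen in several closed contours (e.g. piriform
    sinuses flanking the laryngeal vestibule) only the contour whose area
    centroid lies nearest the centerline point is kept.
    """
    tm = mesh.to_trimesh() if isinstance(mesh, AirwayMesh) else mesh
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    loops = _contours(tm, point, normal)
    if not loops:
        return CrossSection(index, point, normal, None, float("nan"), float("nan"), float("nan"))
    metrics = [_polygon_area_centroid(lp, point, normal) for lp in loops]
    dists = [np.linalg.norm(c - point) for _, c in metrics]
    best = int(np.argmin(dists))
    area = metrics[best][0]
    try:
        ap_axis, lr_axis = inplane_axes(normal)
        ap, width = section_extents(loops[best], ap_axis, lr_axis)
    except ValueError:
        ap, width = float("nan"), float("nan")
    return CrossSection(index, point, normal, loops[best], area, ap, width)


# ---------------------------------------------------------------------------
# centerline extraction


def _fit_spline(centroids: np.ndarray, smoothing: float):
    chord = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    u /= u[-1]
    k = 3 if len(centroids) > 3 else len(centroids) - 1
    tck, _ = splprep(centroids.T, u=u, k=k, s=smoothing)
    return tck


def _sample_spline(tck, n_dense: int) -> np.ndarray:
    uu = np.linspace(0.0, 1.0, n_dense)
    return np.column_stack(splev(uu, tck))


def _resample_by_arc(points: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(round(total / step)), 2)
    targets = np.linspace(0.0, total, n + 1)
    out = np.column_stack([np.interp(targets, arc, points[:, d]) for d in range(3)])
    return out


def _ray_surface_distance(tm: trimesh.Trimesh, origin: np.ndarray, direction: np.ndarray) -> float | None:
    """Distance to the first surface hit along a ray (Moller-Trumbore)."""
    tri = tm.triangles
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = origin - v0
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    v = (q @ direction) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
    if not hit.any():
        return None
    return float(t[hit].min())


def _end_direction(points: np.ndarray, window: float) -> np.ndarray:
    """Outward direction at ``points[-1]`` from a line fit over ``window`` mm.

    A least-squares line through the trailing points is far more stable
    than the end derivative of a smoothing spline.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    back = arc[-1] - arc
    sel = points[back <= window]
    if len(sel) < 2:
        sel = points[-2:]
    t = np.arange(len(sel), dtype=float)
    t -= t.mean()
    d = (t[:, None] * (sel - sel.mean(axis=0))).sum(axis=0)
    n = np.linalg.norm(d)
    if n < 1e-12:
        d = points[-1] - points[-2]
        n = np.linalg.norm(d)
    return d / n


def _march_to_end(
    tm: trimesh.Trimesh,
    start: np.ndarray,
    direction: np.ndarray,
    step: float,
    roi_z: tuple[float, float] | None,
    max_steps: int = 200,
) -> list[np.ndarray]:
    """March along the tube axis to its end, recentering at every step.

    Each step advances ``step`` mm, cuts an orthogonal section and snaps
    to its area centroid, so the path follows the lumen center around
    bends.  Marching stops exactly at an axial ROI clip plane when the
    mesh records one, otherwise at the surface (end cap) by ray casting;
    a centroid jumping by more than half a step signals a degenerating
    (clipped or cap) section and also ends the march.
    """
    out: list[np.ndarray] = []
    trail = [np.asarray(start, dtype=float)]
    p = trail[0]
    d = np.asarray(direction, dtype=float) / np.linalg.norm(direction)
    for _ in range(max_steps):
        q = p + step * d
        loops = _contours(tm, q, d)
        if not loops:
            break
        metrics = [_polygon_area_centroid(lp, q, d) for lp in loops]
        dists = [np.linalg.norm(c - q) for _, c in metrics]
        best = int(np.argmin(dists))
        if dists[best] > 0.6 * step:
            break
        c = metrics[best][1]
        if roi_z is not None and not (roi_z[0] <= c[2] <= roi_z[1]):
            bound = roi_z[0] if c[2] < roi_z[0] else roi_z[1]
            seg = c - p
            if abs(seg[2]) > 1e-9:
                out.append(p + seg * (bound - p[2]) / seg[2])
            return out
        # direction over a multi-step baseline: on tapering tubes a tilted
        # plane biases the centroid toward the wider side, and a
        # single-step direction update would amplify that tilt
        base = trail[max(len(trail) - 3, 0)]
        step_vec = c - base
        norm = np.linalg.norm(step_vec)
        if norm < 1e-9:
            break
        d = step_vec / norm
        p = c
        trail.append(c)
        out.append(c)
    t_end = _ray_surface_distance(tm, p, d)
    if t_end is not None and t_end > 1e-6:
        end = p + t_end * d
        if roi_z is not None:
            lo_z, hi_z = roi_z
            if end[2] < lo_z or end[2] > hi_z:
                bound = lo_z if end[2] < lo_z else hi_z
                seg = end - p
                if abs(seg[2]) > 1e-9:
                    end = p + seg * (bound - p[2]) / seg[2]
        out.append(end)
    return out


def _extend_to_surface(
    tm: trimesh.Trimesh,
    points: np.ndarray,
    window: float,
    step: float,
    roi_z: tuple[float, float] | None,
) -> np.ndarray:
    """Continue both centerline ends to the lumen end by centroid marching."""
    tail = _march_to_end(tm, points[-1], _end_direction(points, window), step, roi_z)
    head = _march_to_end(tm, points[0], _end_direction(points[::-1], window), step, roi_z)
    parts = []
    if head:
        parts.append(np.asarray(head[::-1]))
    parts.append(points)
    if tail:
        parts.append(np.asarray(tail))
    return np.vstack(parts)


def extract_centerline(
    mesh: AirwayMesh,
    axis_hint: int | str = "z",
    contour_spacing: float = DEFAULT_CONTOUR_SPACING,
    spline_smoothing: float | None = None,
    resample_step: float = DEFAULT_RESAMPLE_STEP,
) -> Centerline:
    """Level-contour centroid centerline with B-spline smoothing.

    Parameters
    ----------
    axis_hint
        Patient axis (``"x"``/``"y"``/``"z"`` or 0/1/2) used for the initial
        parallel slicing; the superior axis matches the airway's dominant
        orientation.
    contour_spacing
        Distance between slicing levels, mm.
    spline_smoothing
        Residual budget of the smoothing spline; defaults to
        ``n * (contour_spacing / 4)**2`` so the RMS centroid deviation is
        about a quarter of the slice spacing.
    resample_step
        Arc-length step of the output polyline, mm.
    """
    axis = {"x": 0, "y": 1, "z": 2}.get(axis_hint, axis_hint) if isinstance(axis_hint, str) else int(axis_hint)
    tm = mesh.to_trimesh()
    lo, hi = tm.bounds[0][axis], tm.bounds[1][axis]
    if hi - lo < 3 * contour_spacing:
        raise ValueError("mesh extent along axis_hint too small for contour slicing")

    normal = np.zeros(3)
    normal[axis] = 1.0
    margin = 0.5 * contour_spacing
    levels = np.arange(hi - margin, lo + margin, -contour_spacing)

    centroids = []
    areas = []
    for lev in levels:
        origin = np.zeros(3)
        origin[axis] = lev
        loops = _contours(tm, origin, normal)
        if not loops:
            continue  # interior gap: level reported skipped
        metrics = [_polygon_area_centroid(lp, origin, normal) for lp in loops]
        best = int(np.argmax([m[0] for m in metrics]))
        centroids.append(metrics[best][1])
        areas.append(metrics[best][0])
    centroids = np.asarray(centroids)
    if len(centroids) < 4:
        raise ValueError("fewer than 4 level centroids; spline underdetermined")

    # Levels within about one lumen radius of the axial extremes cut end
    # caps or clipped oblique rims obliquely; their centroids are biased
    # off-axis, so they are dropped — the orthogonal refinement pass and
    # the tangent extension recover the ends.
    r_med = np.sqrt(np.median(areas) / np.pi)
    near_end = np.minimum(centroids[:, axis] - lo, hi - centroids[:, axis]) < 1.25 * r_med
    if (~near_end).sum() >= 4:
        centroids = centroids[~near_end]

    if spline_smoothing is None:
        spline_smoothing = len(centroids) * (contour_spacing / 4.0) ** 2

    tck = _fit_spline(centroids, spline_smoothing)
    stage1 = _resample_by_arc(_sample_spline(tck, 40 * len(centroids)), contour_spacing)

    # One refinement pass: re-slice orthogonally to the current tangents.
    tang = np.gradient(stage1, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    refined = []
    for p, t in zip(stage1, tang):
        loops = _contours(tm, p, t)
        if not loops:
            continue
        metrics = [_polygon_area_centroid(lp, p, t) for lp in loops]
        dists = [np.linalg.norm(c - p) for _, c in metrics]
        refined.append(metrics[int(np.argmin(dists))][1])
    refined = np.asarray(refined)
    if len(refined) < 4:
        refined = _resample_by_arc(_sample_spline(tck, 40 * len(centroids)), contour_spacing)

    # Extend to the lumen ends by centroid marching, then fit one light
    # smoothing spline through all measured centroids so tangents are
    # stable everywhere (orthogonally recentered points carry little
    # residual noise, hence the small residual budget).
    roi_z = mesh.provenance.get("roi_z") if isinstance(mesh.provenance, dict) else None
    if roi_z is not None:
        roi_z = (float(roi_z[0]), float(roi_z[1]))
    control = _extend_to_surface(
        tm, refined, window=2.0 * contour_spacing, step=0.5 * contour_spacing, roi_z=roi_z
    )
    tck = _fit_spline(control, len(control) * (contour_spacing / 10.0) ** 2)
    dense = _sample_spline(tck, 40 * len(control))
    pts = _resample_by_arc(dense, resample_step)
    return Centerline.from_points(pts, scan_id=mesh.scan_id)


def slice_orthogonal(mesh: AirwayMesh, centerline: Centerline) -> list[CrossSection]:
    """One cross-section per centerline point, orthogonal to its segment.

    The last point reuses the preceding segment's tangent.  Planes that
    miss the surface produce empty sections; leading/trailing empties are
    trimmed.
    """
    tm = mesh.to_trimesh()
    sections = [
        compute_section(tm, centerline.points[i], centerline.tangents[i], index=i)
        for i in range(len(centerline.points))
    ]
    first = 0
    last = len(sections)
    while first < last and sections[first].empty:
        first += 1
    while last > first and sections[last - 1].empty:
        last -= 1
    return sections[first:last]
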