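"""Lumen surface extraction and implicit-fairing smoothing.

The binary airway mask becomes a watertight triangulated surface via
marching cubes; the stair-stepped surface is then smoothed by implicitly
integrated Laplacian diffusion (solve ``(I - lambda_dt * L) x' = x`` per
iteration), which is unconditionally stable and preserves gross geometry
far better than explicit umbrella smoothing at the same step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage, sparse
from scipy.sparse.linalg import splu
from skimage import measure

from .ct_io import AirwayMask

__all__ = [
    "AirwayMesh",
    "extract_surface",
    "fair_mesh",
    "laplacian_energy",
    "enclosed_volume",
]

#: Fairing defaults, calibrated on tubular phantoms: two implicit
#: iterations at lambda_dt = 0.5 remove marching-cubes staircase noise
#: while keeping the cross-sectional area bias from smoothing well under
#: 2 percent; heavier smoothing measurably erodes the clipped tube ends.
DEFAULT_LAMBDA_DT = 0.5
DEFAULT_ITERATIONS = 2


@dataclass
class AirwayMesh:
    """Watertight triangulated lumen surface in RAS millimeters."""

    vertices: np.ndarray
    faces: np.ndarray
    provenance: dict = field(default_factory=dict)
    scan_id: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3) triangles")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @property
    def is_watertight(self) -> bool:
        return self.to_trimesh().is_watertight

    @property
    def euler_characteristic(self) -> int:
        return self.to_trimesh().euler_number

    def save(self, path: str | Path) -> None:
        """Write PLY or OBJ depending on the file suffix."""
        self.to_trimesh().export(str(path))


def enclosed_volume(mesh: AirwayMesh) -> float:
    """Signed enclosed volume (mm^3) by the divergence theorem."""
    v, f = mesh.vertices, mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def extract_surface(
    mask: AirwayMask,
    spacing: np.ndarray | None = None,
    origin: np.ndarray | None = None,
    hu_volume: np.ndarray | None = None,
    threshold: float | None = None,
) -> AirwayMesh:
    """Marching-cubes isosurface of the segmented lumen.

    Without HU data the binary mask is contoured at level 0.5, which puts
    the surface midway between lumen and wall voxel centers (half-voxel
    accuracy).  When the source HU volume and segmentation threshold are
    supplied, the isosurface is taken at the threshold intensity on the HU
    field restricted to the segmented component: linear interpolation of
    the partial-volume intensity ramp then recovers the wall at sub-voxel
    accuracy, which is the rationale of the midpoint-threshold rule.
    The field is padded so the surface closes at the volume boundary; the
    raw triangulation is cleaned (duplicate vertices merged, degenerate
    faces dropped, largest connected component kept) and oriented so the
    enclosed volume is positive.
    """
    if not mask.voxels.any():
        raise ValueError("cannot mesh an empty mask")
    spacing = np.asarray(mask.spacing if spacing is None else spacing, dtype=float)
    origin = np.asarray(mask.origin if origin is None else origin, dtype=float)

    if hu_volume is not None:
        if threshold is None:
            raise ValueError("threshold required when meshing the HU field")
        field = np.asarray(hu_volume, dtype=np.float32).copy()
        # clamp value as far above threshold as lumen air sits below it, so
        # interpolated ROI caps land on the clip plane without bias
        wall = float(threshold) + max(100.0, float(threshold) + 1000.0)
        # suppress air that is not part of the segmented component, keep a
        # one-voxel halo of true HU around the mask for interpolation
        halo = ndimage.binary_dilation(mask.voxels, iterations=2)
        field[~halo] = np.maximum(field[~halo], wall)
        # cap the surface at the axial ROI clip planes
        z = origin[2] + spacing[2] * np.arange(field.shape[2])
        field[:, :, (z < mask.roi_inferior) | (z > mask.roi_superior)] = wall
        padded = np.pad(field, 1, constant_values=wall)
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=float(threshold), spacing=tuple(spacing)
        )
    else:
        padded = np.pad(mask.voxels, 1).astype(np.float32)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    verts = verts + (origin - spacing)  # undo the one-voxel pad offset

    tm = trimesh.Trimesh(verts, faces, process=True)
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda p: abs(p.volume))
    if not tm.is_watertight:
        trimesh.repair.fill_holes(tm)
    tm.fix_normals()
    if tm.volume < 0:
        tm.invert()

    return AirwayMesh(
        vertices=np.asarray(tm.vertices),
        faces=np.asarray(tm.faces),
        provenance={
            "source": "marching_cubes",
            "level": 0.5 if hu_volume is None else float(threshold),
            "mask_scan": mask.scan_id,
            "roi_z": (float(mask.roi_inferior), float(mask.roi_superior)),
        },
        scan_id=mask.scan_id,
    )


def _uniform_laplacian(n_vertices: int, faces: np.ndarray) -> sparse.csr_matrix:
    """Umbrella Laplacian ``L = D^-1 A - I`` on the mesh graph."""
    e = np.vstack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
    )
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    data = np.ones(len(rows))
    adj = sparse.coo_matrix((data, (rows, cols)), shape=(n_vertices, n_vertices)).tocsr()
    adj.data[:] = 1.0  # collapse duplicate edges
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    dinv = sparse.diags(1.0 / deg)
    return (dinv @ adj - sparse.identity(n_vertices)).tocsr()


def fair_mesh(
    mesh: AirwayMesh,
    lambda_dt: float = DEFAULT_LAMBDA_DT,
    iterations: int = DEFAULT_ITERATIONS,
) -> AirwayMesh:
    """Implicit-fairing diffusion smoothing with uniform (umbrella) weights.

    Each iteration solves ``(I - lambda_dt * L) x' = x`` per coordinate
    using a sparse LU factorization (reused across iterations; the system
    matrix is constant).  Vertex count and face topology are unchanged.
    """
    if lambda_dt <= 0:
        raise ValueError("lambda_dt must be positive")
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise ValueError("fair_mesh requires a watertight mesh")
    if iterations == 0:
        return AirwayMesh(
            vertices=mesh.vertices.copy(),
            faces=mesh.faces.copy(),
            provenance={**mesh.provenance, "fairing": {"lambda_dt": lambda_dt, "iterations": 0}},
            scan_id=mesh.scan_id,
        )

    n = len(mesh.vertices)
    lap = _uniform_laplacian(n, mesh.faces)
    system = (sparse.identity(n) - lambda_dt * lap).tocsc()
    solver = splu(system)

    x = mesh.vertices.copy()
    for _ in range(iterations):
        x = np.column_stack([solver.solve(x[:, d]) for d in range(3)])

    return AirwayMesh(
        vertices=x,
        faces=mesh.faces.copy(),
        provenance={**mesh.provenance, "fairing": {"lambda_dt": lambda_dt, "iterations": iterations}},
        scan_id=mesh.scan_id,
    )


def laplacian_energy(mesh: AirwayMesh) -> float:
    """Total umbrella-Laplacian energy ``sum_i ||mean(neighbors_i) - v_i||^2``."""
    lap = _uniform_laplacian(len(mesh.vertices), mesh.faces)
    lx = lap @ mesh.vertices
    return float((lx**2).sum())
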