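"""Surface-mesh data model, I/O, validation, remeshing and mask conversion.

The canonical in-memory container is :class:`trimesh.Trimesh` with vertex
coordinates in millimetres in a right-handed frame.  Voxel masks use 0-based
indices with the world origin at the centre of voxel (0, 0, 0).
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from ._geometry import signed_distance

__all__ = [
    "TriMesh",
    "MeshReport",
    "VoxelMask",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
    "require_pipeline_mesh",
    "remesh_to_edge_length",
    "mesh_from_mask",
]

TriMesh = trimesh.Trimesh

SUPPORTED_FORMATS = ("ply", "stl", "obj")


class MeshFormatError(ValueError):
    """Unknown format or unreadable/corrupt mesh file."""


def _resolve_format(path: str, file_format: str | None) -> str:
    fmt = (file_format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt not in SUPPORTED_FORMATS:
        raise MeshFormatError(
            f"unsupported mesh format {fmt!r}; expected one of {SUPPORTED_FORMATS}"
        )
    return fmt


def read_mesh(path: str, file_format: str | None = None) -> TriMesh:
    """Load a triangulated surface from PLY/STL/OBJ.

    Polygonal faces (e.g. PLY quads) are triangulated on load.  Coordinates
    round-trip losslessly to at least six significant digits.
    """
    fmt = _resolve_format(str(path), file_format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        loaded = trimesh.load(str(path), file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise MeshFormatError(f"could not parse {path!r} as {fmt}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise MeshFormatError(f"{path!r} contains no triangulated surface")
    loaded.metadata["provenance"] = f"read from {path}"
    return loaded


def write_mesh(mesh: TriMesh, path: str, file_format: str | None = None) -> None:
    """Write PLY (binary little-endian), STL or OBJ."""
    fmt = _resolve_format(str(path), file_format)
    if len(mesh.faces) == 0:
        raise ValueError("refusing to write a mesh with no faces")
    mesh.export(str(path), file_type=fmt)


@dataclass(frozen=True)
class MeshReport:
    """Validation summary; purely informational."""

    watertight: bool
    winding_consistent: bool
    n_components: int
    n_vertices: int
    n_faces: int
    min_edge: float
    median_edge: float
    n_degenerate_faces: int

    @property
    def pipeline_ready(self) -> bool:
        return self.watertight and self.winding_consistent and self.n_components == 1


def validate_mesh(mesh: TriMesh) -> MeshReport:
    edges = mesh.edges_unique_length
    areas = mesh.area_faces
    return MeshReport(
        watertight=bool(mesh.is_watertight),
        winding_consistent=bool(mesh.is_winding_consistent),
        n_components=int(mesh.body_count),
        n_vertices=len(mesh.vertices),
        n_faces=len(mesh.faces),
        min_edge=float(edges.min()) if len(edges) else float("nan"),
        median_edge=float(np.median(edges)) if len(edges) else float("nan"),
        n_degenerate_faces=int((areas < 1e-12).sum()),
    )


def require_pipeline_mesh(mesh: TriMesh, name: str = "mesh") -> MeshReport:
    """Reject meshes the analysis pipeline cannot process."""
    report = validate_mesh(mesh)
    if not report.pipeline_ready:
        raise ValueError(
            f"{name} is not pipeline-ready: watertight={report.watertight}, "
            f"components={report.n_components}, "
            f"winding_consistent={report.winding_consistent}"
        )
    return report


def _sdf_isosurface(mesh: TriMesh, pitch: float) -> TriMesh:
    """Resample a surface by marching cubes over its signed-distance field."""
    pad = 3.0 * pitch
    # irrational offset keeps grid nodes off the surface (exact-zero SDF
    # values produce degenerate marching-cubes triangles)
    lo = mesh.bounds[0] - pad + 0.1379 * pitch
    hi = mesh.bounds[1] + pad
    dims = np.ceil((hi - lo) / pitch).astype(int) + 1
    axes = [lo[i] + np.arange(dims[i]) * pitch for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    sdf = signed_distance(mesh, grid).reshape(dims)
    verts, faces, _, _ = marching_cubes(sdf, level=0.0, spacing=(pitch,) * 3)
    out = trimesh.Trimesh(verts + lo, faces, process=True)
    out.fix_normals()
    return out


def remesh_to_edge_length(mesh: TriMesh, target_edge: float) -> TriMesh:
    """Resample a surface to a requested characteristic edge length.

    Refinement uses longest-edge subdivision (surface unchanged); coarsening
    re-extracts an isosurface of the signed-distance field, which bounds the
    deviation from the input surface by roughly one output edge length.
    """
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    extents = mesh.extents
    if target_edge > 0.5 * float(min(extents)):
        raise ValueError(
            f"target edge {target_edge} mm is too coarse for a mesh with "
            f"extents {extents} mm"
        )
    median = float(np.median(mesh.edges_unique_length))
    if target_edge < 0.9 * median:
        verts, faces = trimesh.remesh.subdivide_to_size(
            mesh.vertices, mesh.faces, max_edge=target_edge * 1.2
        )
        out = trimesh.Trimesh(verts, faces, process=True)
        out.metadata["provenance"] = "subdivided"
        return out
    if target_edge <= 1.2 * median:
        return mesh.copy()
    out = _sdf_isosurface(mesh, pitch=1.15 * target_edge)
    out.metadata["provenance"] = "sdf-isosurface"
    return out


@dataclass(frozen=True)
class VoxelMask:
    """Binary voxel mask with anisotropic spacing, emulating a segmentation."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data).astype(bool)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if not data.any():
            raise ValueError("mask has no foreground voxels")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def load_mask(path: str, threshold: float = 0.5) -> VoxelMask:
    """Load a binary voxel mask from NIfTI (.nii/.nii.gz) or NRRD.

    Spacing is taken from the header; the array is binarized at
    ``threshold``.  Orientation metadata beyond voxel spacing is ignored —
    masks are assumed to be in the standardized frame already.
    """
    p = str(path)
    if p.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(p)
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    elif p.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(p)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(float(z) for z in img.GetSpacing())
    else:
        raise MeshFormatError(f"unsupported mask format: {p}")
    return VoxelMask(np.asarray(data) > threshold, spacing)


def _voxel_boundary_surface(mask: VoxelMask) -> TriMesh:
    """Exact axis-aligned boundary surface of the foreground voxels."""
    data = np.pad(mask.data, 1)
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    verts: list[np.ndarray] = []
    faces: list[np.ndarray] = []
    offset = 0
    # face template per axis/direction: quad corners in voxel units
    for axis in range(3):
        for direction in (-1, 1):
            neighbor = np.roll(data, -direction, axis=axis)
            exposed = data & ~neighbor
            idx = np.argwhere(exposed) - 1  # unpad
            if len(idx) == 0:
                continue
            centers = idx.astype(float)
            face_center = centers.copy()
            face_center[:, axis] += 0.5 * direction
            u_axis, v_axis = [a for a in range(3) if a != axis]
            quad = np.zeros((len(idx), 4, 3))
            for ci, (du, dv) in enumerate([(-0.5, -0.5), (0.5, -0.5), (0.5, 0.5), (-0.5, 0.5)]):
                corner = face_center.copy()
                corner[:, u_axis] += du
                corner[:, v_axis] += dv
                quad[:, ci] = corner
            if direction < 0:
                quad = quad[:, ::-1]
            verts.append(quad.reshape(-1, 3))
            tri = np.array([[0, 1, 2], [0, 2, 3]])
            base = offset + 4 * np.arange(len(idx))[:, None, None]
            faces.append((base + tri[None]).reshape(-1, 3))
            offset += 4 * len(idx)
    v = np.concatenate(verts) * spacing + origin
    f = np.concatenate(faces)
    out = trimesh.Trimesh(v, f, process=True)
    out.fix_normals()
    return out


def mesh_from_mask(mask: VoxelMask, iso: float = 0.5, smoothing_sigma: float = 1.0) -> TriMesh:
    """Extract a closed surface around the mask foreground (mm coordinates).

    The binary mask is anti-aliased with a Gaussian (sigma in voxels) before
    isosurface extraction, which removes voxel staircase bias.  Objects too
    thin to survive smoothing (peak below the iso level) fall back to the
    exact voxel-boundary surface.
    """
    smoothed = ndimage.gaussian_filter(
        np.pad(mask.data, 2).astype(float), sigma=smoothing_sigma
    )
    if smoothed.max() <= iso + 0.1:
        return _voxel_boundary_surface(mask)
    verts, faces, _, _ = marching_cubes(smoothed, level=iso)
    verts = (verts - 2.0) * np.asarray(mask.spacing) + np.asarray(mask.origin)
    out = trimesh.Trimesh(verts, faces, process=True)
    out.fix_normals()
    out.metadata["provenance"] = "isosurface from voxel mask"
    return out
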