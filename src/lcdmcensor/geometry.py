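"""Signed distances from voxel centroids to a triangulated GM/WM surface.

The labeled cortical distance map (LCDM) assigns to every gray-matter (GM)
voxel the distance from its centroid to the nearest vertex of the
triangulated GM/white-matter (WM) boundary surface, signed by which side of
the surface the centroid lies on (negative on the WM side).  Distances are
retained inside an anatomically motivated window (default [-0.5, 5.5] mm)
to guard against voxels mislabeled as GM near the boundary.

Two phantom generators (a flat slab and a spherical shell) provide
geometries with analytically known distances for validation.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree


class Label(enum.IntEnum):
    """Tissue label codes for the voxel grid."""

    BG = 0
    GM = 1
    WM = 2
    CSF = 3


@dataclass(frozen=True)
class TriangulatedSurface:
    """A triangulated GM/WM boundary surface.

    Face winding is counter-clockwise when viewed from the GM side, so face
    normals point from white matter toward gray matter.
    """

    vertices: np.ndarray  # (V, 3) float, mm
    faces: np.ndarray  # (F, 3) int vertex indices

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (V, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be an (F, 3) array")
        if v.shape[0] and (v.shape[0] < 3 or f.shape[0] < 1):
            raise ValueError("nonempty surface needs >= 3 vertices and >= 1 face")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertex coordinates must be finite")
        if f.size and (f.min() < 0 or f.max() >= v.shape[0]):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def is_empty(self) -> bool:
        return self.vertices.shape[0] == 0

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average normal of the faces incident to each vertex.

        The returned normals are not unit length; only their direction is
        used (for the side test).  Cross products of the face edge vectors
        are accumulated per vertex, which weights each face by twice its
        area.
        """
        tri = self.vertices[self.faces]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        vn = np.zeros_like(self.vertices)
        for i in range(3):
            np.add.at(vn, self.faces[:, i], fn)
        return vn

    def flipped(self) -> "TriangulatedSurface":
        """Surface with every face orientation reversed."""
        return TriangulatedSurface(self.vertices.copy(), self.faces[:, ::-1].copy())


@dataclass(frozen=True)
class LabeledVoxelGrid:
    """A regular isotropic voxel lattice with tissue labels.

    ``labels`` holds :class:`Label` codes; ``origin`` is the position (mm)
    of the corner of voxel (0, 0, 0), whose centroid sits at
    ``origin + h/2`` per axis.
    """

    spacing: float  # mm, isotropic
    origin: np.ndarray  # (3,) mm
    labels: np.ndarray  # (nx, ny, nz) int

    def __post_init__(self):
        if not (self.spacing > 0):
            raise ValueError("spacing must be > 0")
        o = np.asarray(self.origin, dtype=float)
        lab = np.asarray(self.labels)
        if o.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if lab.ndim != 3 or min(lab.shape) < 1:
            raise ValueError("labels must be a 3D array with >= 1 voxel per axis")
        valid = {int(v) for v in Label}
        if not set(np.unique(lab).tolist()) <= valid:
            raise ValueError(f"labels must be drawn from {sorted(valid)}")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "labels", lab.astype(np.int8))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)


@dataclass
class DistanceSet:
    """Signed LCDM distances for one subject / hemisphere."""

    subject_id: str
    group: str
    hemisphere: str  # 'left' or 'right'
    indices: np.ndarray  # (K, 3) voxel indices (may be empty / dummy for tabular data)
    distances: np.ndarray  # (K,) signed distances, mm

    def __post_init__(self):
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 1:
            raise ValueError("distances must be 1-D")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        idx = np.asarray(self.indices)
        if idx.size and idx.shape != (d.shape[0], 3):
            raise ValueError("indices must be (K, 3) matching distances")
        self.indices = idx
        self.distances = d

    @property
    def count(self) -> int:
        """Number of GM voxels carrying a distance (K_ij)."""
        return int(self.distances.shape[0])


def voxel_centroid(grid: LabeledVoxelGrid, index) -> np.ndarray:
    """Centroid (mm) of the voxel at a 0-based integer ``index``.

    The centroid of voxel ``(i, j, k)`` is ``origin + (index + 0.5) * h``.
    """
    idx = np.asarray(index, dtype=float)
    ii = np.asarray(index, dtype=int)
    if np.any(ii < 0) or np.any(ii >= np.asarray(grid.shape)):
        raise IndexError(f"voxel index {index} out of bounds for grid {grid.shape}")
    return grid.origin + (idx + 0.5) * grid.spacing


def _gm_centroids(grid: LabeledVoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(grid.labels == Label.GM)
    cent = grid.origin + (idx + 0.5) * grid.spacing
    return idx, cent


def nearest_vertex_bruteforce(points: np.ndarray, vertices: np.ndarray):
    """Exhaustive nearest-vertex scan; reference oracle for the k-d tree path.

    Returns (distances, vertex indices) with distances computed as the
    minimum Euclidean norm over all vertices.
    """
    points = np.atleast_2d(points)
    d2 = ((points[:, None, :] - vertices[None, :, :]) ** 2).sum(axis=2)
    j = np.argmin(d2, axis=1)
    return np.sqrt(d2[np.arange(len(points)), j]), j


def compute_lcdm(
    grid: LabeledVoxelGrid,
    surface: TriangulatedSurface,
    subject_id: str = "subject",
    group: str = "group",
    hemisphere: str = "left",
) -> DistanceSet:
    """Signed LCDM distances for every GM voxel of ``grid``.

    The unsigned magnitude is the minimum Euclidean distance from the voxel
    centroid to the set of surface vertices (a k-d tree query whose result
    equals the exhaustive scan).  The sign is negative iff the centroid
    lies on the WM side of the surface, judged by the dot product of
    (centroid - nearest vertex) with the area-weighted normal at that
    vertex; a zero dot product is assigned positive.
    """
    if surface.is_empty:
        raise ValueError("cannot compute distances against an empty surface")
    idx, cent = _gm_centroids(grid)
    if len(idx) == 0:
        return DistanceSet(subject_id, group, hemisphere,
                           np.empty((0, 3), dtype=int), np.empty(0))
    tree = cKDTree(surface.vertices)
    dist, j = tree.query(cent, k=1)
    vn = surface.vertex_normals()
    side = np.einsum("ij,ij->i", cent - surface.vertices[j], vn[j])
    sign = np.where(side < 0.0, -1.0, 1.0)  # ties (side == 0) positive
    return DistanceSet(subject_id, group, hemisphere, idx, sign * dist)


def filter_distance_range(
    ds: DistanceSet, lo: float = -0.5, hi: float = 5.5
) -> tuple[DistanceSet, float]:
    """Retain distances in the closed interval [lo, hi].

    Returns the filtered set and the fraction of records removed.  The
    default window [-0.5, 5.5] mm excludes voxels likely mislabeled as GM
    near the surface and implausibly deep voxels.
    """
    if lo > hi:
        raise ValueError(f"lo ({lo}) must not exceed hi ({hi})")
    keep = (ds.distances >= lo) & (ds.distances <= hi)
    removed = 0.0 if ds.count == 0 else 1.0 - keep.sum() / ds.count
    out = replace(
        ds,
        indices=ds.indices[keep] if ds.indices.size else ds.indices,
        distances=ds.distances[keep],
    )
    return out, float(removed)


# ---------------------------------------------------------------------------
# Phantom geometries


def _plane_mesh(x0, x1, y0, y1, spacing) -> TriangulatedSurface:
    """Densely triangulated z=0 plane with normals toward +z."""
    xs = np.arange(x0, x1 + spacing / 2, spacing)
    ys = np.arange(y0, y1 + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    nx, ny = len(xs), len(ys)
    faces = []
    for i in range(nx - 1):
        for jj in range(ny - 1):
            a = i * ny + jj
            b = (i + 1) * ny + jj
            c = (i + 1) * ny + jj + 1
            d = i * ny + jj + 1
            # CCW seen from +z -> normal +z
            faces.append((a, b, c))
            faces.append((a, c, d))
    return TriangulatedSurface(verts, np.asarray(faces))


def generate_slab_phantom(
    thickness: float = 3.0,
    lateral_extent: float = 10.0,
    h: float = 0.5,
    mesh_spacing: float = 0.1,
    wm_depth: float = 1.0,
) -> tuple[LabeledVoxelGrid, TriangulatedSurface]:
    """Flat-slab phantom: plane z=0 as GM/WM surface, GM above, WM below.

    Voxels with centroid z in (0, thickness) are GM, z < 0 down to
    ``-wm_depth`` are WM, and the remainder CSF.  The mesh extends one
    lateral margin beyond the voxel extent so interior GM distances are the
    perpendicular height up to the vertex-sampling error.
    """
    for name, v in [("thickness", thickness), ("lateral_extent", lateral_extent),
                    ("h", h), ("mesh_spacing", mesh_spacing)]:
        if not (v > 0):
            raise ValueError(f"{name} must be > 0")
    margin = max(2.0, thickness)
    surface = _plane_mesh(-margin, lateral_extent + margin,
                          -margin, lateral_extent + margin, mesh_spacing)
    nxy = int(round(lateral_extent / h))
    nz_wm = int(round(wm_depth / h))
    nz_gm = int(round(thickness / h))
    nz = nz_wm + nz_gm + 1  # one CSF layer on top
    origin = np.array([0.0, 0.0, -nz_wm * h])
    labels = np.full((nxy, nxy, nz), int(Label.CSF), dtype=np.int8)
    zc = origin[2] + (np.arange(nz) + 0.5) * h
    labels[:, :, zc < 0] = int(Label.WM)
    labels[:, :, (zc > 0) & (zc < thickness)] = int(Label.GM)
    return LabeledVoxelGrid(h, origin, labels), surface


def generate_shell_phantom(
    inner_radius: float = 2.0,
    outer_radius: float = 4.0,
    h: float = 0.5,
    subdivisions: int = 4,
) -> tuple[LabeledVoxelGrid, TriangulatedSurface]:
    """Spherical-shell phantom: icosphere of ``inner_radius`` as surface.

    Voxels with centroid radius in (inner, outer) are GM, inside the
    sphere WM; distances approximate (centroid radius - inner) to within
    the chord error of the triangulation.
    """
    if not (0 < inner_radius < outer_radius):
        raise ValueError("require 0 < inner_radius < outer_radius")
    if not (h > 0):
        raise ValueError("h must be > 0")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=inner_radius)
    surface = TriangulatedSurface(np.asarray(ico.vertices), np.asarray(ico.faces))
    half = outer_radius + h
    n = int(np.ceil(2 * half / h))
    origin = np.array([-half, -half, -half])
    ax = origin[0] + (np.arange(n) + 0.5) * h
    cx, cy, cz = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(cx**2 + cy**2 + cz**2)
    labels = np.full((n, n, n), int(Label.CSF), dtype=np.int8)
    labels[r < inner_radius] = int(Label.WM)
    labels[(r > inner_radius) & (r < outer_radius)] = int(Label.GM)
    return LabeledVoxelGrid(h, origin, labels), surface


# ---------------------------------------------------------------------------
# Mesh / volume I/O


def read_surface(path) -> TriangulatedSurface:
    """Read an ASCII OFF or PLY triangle mesh."""
    mesh = trimesh.load(str(path), process=False, force="mesh")
    faces = np.asarray(mesh.faces)
    if faces.size and faces.shape[1] != 3:
        raise ValueError("only triangular meshes are supported")
    return TriangulatedSurface(np.asarray(mesh.vertices, dtype=float), faces)


def write_surface(surface: TriangulatedSurface, path) -> None:
    """Write a mesh as ASCII OFF or PLY, inferred from the file suffix."""
    path = Path(path)
    mesh = trimesh.Trimesh(vertices=surface.vertices, faces=surface.faces,
                           process=False)
    kind = path.suffix.lstrip(".").lower()
    if kind == "ply":
        data = mesh.export(file_type="ply", encoding="ascii")
    elif kind == "off":
        data = mesh.export(file_type="off")
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def read_label_volume(path) -> LabeledVoxelGrid:
    """Read a label volume from NIfTI (.nii/.nii.gz) or the JSON fixture format.

    NIfTI volumes must have isotropic spacing; the affine translation is
    used as the grid origin.  The JSON fixture format stores dims, spacing,
    origin, the label-code mapping, and a flat row-major label array.
    """
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        dims = tuple(doc["dims"])
        labels = np.asarray(doc["labels"], dtype=np.int8).reshape(dims)
        codes = {k.upper(): int(v) for k, v in doc.get("label_codes", {}).items()}
        labels = _remap_labels(labels, codes) if codes else labels
        return LabeledVoxelGrid(float(doc["h"]), np.asarray(doc["origin"], float), labels)
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(f"anisotropic spacing {zooms} not supported")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    data = np.asarray(img.dataobj).astype(np.int8)
    return LabeledVoxelGrid(float(zooms[0]), origin, data)


def write_label_volume_json(grid: LabeledVoxelGrid, path) -> None:
    """Write the plain-text JSON fixture format for a label volume."""
    doc = {
        "dims": list(grid.shape),
        "h": grid.spacing,
        "origin": grid.origin.tolist(),
        "label_codes": {lab.name: int(lab) for lab in Label},
        "labels": grid.labels.ravel().tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _remap_labels(labels: np.ndarray, codes: dict) -> np.ndarray:
    out = np.full(labels.shape, int(Label.BG), dtype=np.int8)
    for name, code in codes.items():
        if name in Label.__members__:
            out[labels == code] = int(Label[name])
    return out
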