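"""Triangle surfaces of binary segmentations.

Meshes are extracted with marching cubes at iso-level 0.5 on {0,1} grids, so
with linear interpolation the surface sits at the half-voxel between foreground
and background voxel centres.  Masks are padded with one background layer
before meshing so surfaces are closed at grid borders.  All vertices are in
world millimetres.

The in-memory container is :class:`trimesh.Trimesh`; a per-vertex scalar
channel (e.g. surface distances in mm) rides in ``mesh.vertex_attributes
['quality']`` and survives PLY round-trips via the writer in this module.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .volume import BinaryMask, LabelVolume

__all__ = [
    "marching_cubes",
    "mesh_volume",
    "mesh_area",
    "voxelize_mesh",
    "write_mesh",
    "read_mesh",
    "TopologyError",
]

QUALITY = "quality"


class TopologyError(ValueError):
    """Raised when an operation requires a closed (watertight) mesh but got an open one."""


def _as_trimesh(vertices, faces) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def marching_cubes(mask: BinaryMask, iso: float = 0.5) -> trimesh.Trimesh:
    """Extract the closed iso-surface of a binary mask in world mm.

    The mask is padded with one background voxel layer so the surface closes at
    the grid border.  Faces are oriented with outward normals (positive signed
    volume).

    Raises
    ------
    ValueError
        If the mask has no foreground voxel or ``iso`` is outside (0, 1).
    """
    if not (0.0 < iso < 1.0):
        raise ValueError(f"iso level must lie in (0, 1), got {iso}")
    if np.count_nonzero(mask.grid) == 0:
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.grid, 1).astype(np.float32)
    verts, faces, _normals, _vals = measure.marching_cubes(padded, level=iso, spacing=tuple(mask.spacing))
    # un-pad: the padded voxel (1,1,1) is the original (0,0,0)
    verts = verts - mask.spacing + mask.origin
    mesh = _as_trimesh(verts, faces)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _require_closed(mesh: trimesh.Trimesh, what: str) -> None:
    if not mesh.is_watertight:
        raise TopologyError(f"{what} requires a closed mesh; boundary edges present")


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem, as an absolute value.

    Invariant under rigid transforms.  Open meshes are rejected.
    """
    _require_closed(mesh, "mesh_volume")
    return float(abs(mesh.volume))


def mesh_area(mesh: trimesh.Trimesh) -> float:
    """Total surface area in mm^2 (degenerate triangles contribute zero)."""
    return float(mesh.area)


def voxelize_mesh(mesh: trimesh.Trimesh, template: LabelVolume) -> BinaryMask:
    """Rasterize a closed mesh onto the template grid: voxel = 1 iff its centre
    lies inside the mesh.

    Inside/outside is decided by crossing parity along the +z axis of rays
    through the voxel centres.  Ray origins are offset in x and y by a fixed
    sub-voxel amount so rays never graze mesh edges or vertices exactly,
    keeping the parity test deterministic.

    Raises
    ------
    TopologyError
        If the mesh is open.
    ValueError
        If the mesh bounding box is not covered by the template grid.
    """
    _require_closed(mesh, "voxelize_mesh")
    nx, ny, nz = template.shape
    lo = template.origin - 0.5 * template.spacing
    hi = template.origin + (np.array([nx, ny, nz]) - 0.5) * template.spacing
    if np.any(mesh.bounds[0] < lo - 1e-9) or np.any(mesh.bounds[1] > hi + 1e-9):
        raise ValueError(
            f"mesh bounds {mesh.bounds.tolist()} exceed template extent [{lo.tolist()}, {hi.tolist()}]"
        )

    sx, sy, sz = template.spacing
    ox, oy, oz = template.origin
    # fixed sub-voxel jitter of the ray grid (deterministic grazing avoidance);
    # the two offsets are irrational and mutually irrational, so a ray can
    # never lie on a line through lattice-rational mesh vertices (which would
    # double-count the shared edge of two adjacent triangles)
    jx, jy = 0.0625 * (np.sqrt(2.0) - 1.0) * sx, 0.125 * (np.sqrt(5.0) - 2.0) * sy
    xs = ox + np.arange(nx) * sx + jx
    ys = oy + np.arange(ny) * sy + jy

    tri = mesh.triangles  # (m, 3, 3)
    crossings: list[list[list[float]]] = [[[] for _ in range(ny)] for _ in range(nx)]
    for a, b, c in tri:
        xmin, xmax = min(a[0], b[0], c[0]), max(a[0], b[0], c[0])
        ymin, ymax = min(a[1], b[1], c[1]), max(a[1], b[1], c[1])
        i0 = max(0, int(np.ceil((xmin - jx - ox) / sx)))
        i1 = min(nx - 1, int(np.floor((xmax - jx - ox) / sx)))
        j0 = max(0, int(np.ceil((ymin - jy - oy) / sy)))
        j1 = min(ny - 1, int(np.floor((ymax - jy - oy) / sy)))
        if i1 < i0 or j1 < j0:
            continue
        gx, gy = np.meshgrid(xs[i0 : i1 + 1], ys[j0 : j1 + 1], indexing="ij")
        # 2-D barycentric test in the xy plane
        d = (b[1] - c[1]) * (a[0] - c[0]) + (c[0] - b[0]) * (a[1] - c[1])
        if d == 0.0:
            continue  # triangle vertical in z: never crossed transversally by a z-ray
        w0 = ((b[1] - c[1]) * (gx - c[0]) + (c[0] - b[0]) * (gy - c[1])) / d
        w1 = ((c[1] - a[1]) * (gx - c[0]) + (a[0] - c[0]) * (gy - c[1])) / d
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        zhit = w0 * a[2] + w1 * b[2] + w2 * c[2]
        ii, jj = np.nonzero(inside)
        for di, dj, zv in zip(ii, jj, zhit[ii, jj]):
            crossings[i0 + di][j0 + dj].append(float(zv))

    grid = np.zeros((nx, ny, nz), dtype=np.uint8)
    zs = oz + np.arange(nz) * sz
    for i in range(nx):
        for j in range(ny):
            zlist = crossings[i][j]
            if not zlist:
                continue
            zarr = np.sort(np.asarray(zlist))
            # parity of crossings below each voxel centre
            counts = np.searchsorted(zarr, zs, side="left")
            grid[i, j, :] = (counts % 2).astype(np.uint8)
    return BinaryMask(grid=grid, spacing=template.spacing, origin=template.origin, axis_names=template.axis_names)


# ---------------------------------------------------------------------------
# mesh file I/O
# ---------------------------------------------------------------------------

_PLY_DTYPE = np.dtype(
    [("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("quality", "<f8")]
)


def _write_ply(mesh: trimesh.Trimesh, path: Path) -> None:
    """Binary little-endian PLY with an optional per-vertex `quality` property."""
    quality = mesh.vertex_attributes.get(QUALITY)
    has_q = quality is not None
    n_v, n_f = len(mesh.vertices), len(mesh.faces)
    header = ["ply", "format binary_little_endian 1.0", f"element vertex {n_v}"]
    header += ["property double x", "property double y", "property double z"]
    if has_q:
        header.append("property double quality")
    header += [f"element face {n_f}", "property list uchar int vertex_indices", "end_header"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if has_q:
            v = np.empty(n_v, dtype=_PLY_DTYPE)
            v["x"], v["y"], v["z"] = mesh.vertices.T
            v["quality"] = np.asarray(quality, dtype=float)
        else:
            v = np.ascontiguousarray(mesh.vertices, dtype="<f8").view(
                np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8")])
            ).reshape(n_v)
        fh.write(v.tobytes())
        f = np.empty(n_f, dtype=np.dtype([("n", "u1"), ("i", "<i4", (3,))]))
        f["n"] = 3
        f["i"] = mesh.faces
        fh.write(f.tobytes())


def _read_ply(path: Path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), file_type="ply", process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path}: not a triangle mesh")
    # trimesh parses unknown vertex properties into metadata['_ply_raw']
    raw = mesh.metadata.get("_ply_raw", {})
    vert = raw.get("vertex", {})
    data = vert.get("data")
    if data is not None and getattr(data, "dtype", None) is not None and data.dtype.names and QUALITY in data.dtype.names:
        mesh.vertex_attributes[QUALITY] = np.asarray(data[QUALITY], dtype=float)
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path, format: str | None = None) -> Path:
    """Write a mesh as PLY, OBJ or STL.

    PLY (binary little-endian) preserves the per-vertex ``quality`` scalar;
    STL and OBJ carry geometry only, and requesting them for a mesh that holds
    a scalar channel raises, so distances are never silently dropped.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "obj", "stl"):
        raise ValueError(f"unsupported mesh format {fmt!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        _write_ply(mesh, path)
    else:
        if mesh.vertex_attributes.get(QUALITY) is not None:
            raise ValueError(
                f"{fmt.upper()} cannot store the per-vertex quality channel; write PLY instead"
            )
        mesh.export(str(path), file_type=fmt)
    return path


def read_mesh(path) -> trimesh.Trimesh:
    """Read PLY/OBJ/STL into a :class:`trimesh.Trimesh` (PLY restores `quality`)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "ply":
        return _read_ply(path)
    # STL stores a triangle soup; merge duplicated vertices so topology
    # (watertightness) is recovered
    mesh = trimesh.load(str(path), file_type=fmt, process=(fmt == "stl"))
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path}: not a triangle mesh")
    return mesh
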