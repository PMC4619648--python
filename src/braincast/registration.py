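"""Rigid superposition of meshes by iterative closest point (ICP).

The variant is point-to-point ICP with exact closest-point-on-surface
correspondences: every iteration (a) projects the moving vertices onto the
fixed surface (closest point on triangle, not nearest vertex) and (b) solves
the closed-form least-squares rigid update (Kabsch/SVD, reflection corrected).
With exact correspondences and the optimal update the RMS correspondence
distance is non-increasing, which :class:`ICPTrace` records and asserts.

No scale is estimated: a brain and its endocast come from the same specimen
and the same scan, so the transform group is proper rigid motions only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .distance import SurfaceQuery

__all__ = [
    "RigidTransform",
    "ICPTrace",
    "kabsch",
    "icp_register",
    "apply_transform",
    "default_init",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1), got a reflection")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler_deg(cls, angles_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation from extrinsic x-y-z Euler angles in degrees plus translation."""
        ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(Rz @ Ry @ Rx, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation, self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @property
    def angle_deg(self) -> float:
        """Total rotation angle in degrees (axis-angle magnitude)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_json(self, path=None) -> str:
        payload = {
            "rotation": [float(x) for x in self.rotation.ravel()],
            "translation_mm": [float(x) for x in self.translation],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RigidTransform":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        R = np.asarray(payload["rotation"], dtype=float).reshape(3, 3)
        t = np.asarray(payload["translation_mm"], dtype=float)
        return cls(R, t)


@dataclass
class ICPTrace:
    """Per-iteration RMS correspondence distance (mm) of an ICP run."""

    rms: list = field(default_factory=list)
    converged: bool = False

    @property
    def iterations(self) -> int:
        return len(self.rms)

    def assert_monotone(self, slack: float = 1e-12) -> None:
        arr = np.asarray(self.rms)
        if arr.size >= 2 and np.any(np.diff(arr) > slack):
            raise AssertionError(f"ICP RMS trace increased: {self.rms}")


def kabsch(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping paired source points
    onto target points (SVD solution; reflections corrected by flipping the
    smallest singular direction).

    Raises
    ------
    ValueError
        For fewer than 3 pairs or (near-)collinear geometry, where the
        rotation is not identifiable.
    """
    P = np.asarray(source_points, dtype=float)
    Q = np.asarray(target_points, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("at least 3 point pairs are required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear configurations leave the rotation about the common axis free
    scale = max(np.linalg.norm(P0), 1e-30)
    if S[1] / scale**2 < 1e-12:
        raise ValueError("point pairs are collinear; rotation is degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return RigidTransform(R, t)


def apply_transform(mesh: trimesh.Trimesh, transform: RigidTransform) -> trimesh.Trimesh:
    """Return a new mesh with vertices mapped by ``R v + t``; faces and any
    per-vertex scalar channel are carried over unchanged."""
    out = trimesh.Trimesh(vertices=transform.apply(mesh.vertices), faces=mesh.faces.copy(), process=False)
    for key, value in mesh.vertex_attributes.items():
        out.vertex_attributes[key] = np.array(value)
    return out


def default_init(moving: trimesh.Trimesh, fixed: trimesh.Trimesh, mode: str = "centroid") -> RigidTransform:
    """Initial transform for ICP.

    ``centroid`` aligns vertex centroids with an identity rotation.
    ``principal_axes`` additionally aligns the principal axes of the vertex
    clouds; each axis sign is disambiguated by pointing it toward the heavier
    half of the cloud (larger third-moment along the axis).
    """
    if len(moving.vertices) == 0 or len(fixed.vertices) == 0:
        raise ValueError("meshes must be non-empty")
    mc = moving.vertices.mean(axis=0)
    fc = fixed.vertices.mean(axis=0)
    if mode == "centroid":
        return RigidTransform(np.eye(3), fc - mc)
    if mode != "principal_axes":
        raise ValueError(f"unknown init mode {mode!r}")

    def signed_axes(verts, centre):
        X = verts - centre
        cov = X.T @ X / len(X)
        w, V = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        V = V[:, order]
        for j in range(3):
            proj = X @ V[:, j]
            if np.sum(proj**3) < 0:
                V[:, j] = -V[:, j]
        if np.linalg.det(V) < 0:
            V[:, 2] = -V[:, 2]
        return V

    Vm = signed_axes(moving.vertices, mc)
    Vf = signed_axes(fixed.vertices, fc)
    R = Vf @ Vm.T
    return RigidTransform(R, fc - R @ mc)


def icp_register(
    moving: trimesh.Trimesh,
    fixed: trimesh.Trimesh,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    trim_fraction: float = 0.0,
    sample: int | None = None,
    seed: int = 0,
) -> tuple[RigidTransform, ICPTrace]:
    """Register ``moving`` onto ``fixed`` by point-to-surface ICP.

    Parameters
    ----------
    init : RigidTransform, optional
        Starting transform (default: centroid alignment).
    max_iter : int
        Maximum iterations; ``0`` returns ``init`` unchanged, not converged.
    tol : float
        Convergence threshold (mm) on the change of RMS correspondence
        distance between successive iterations.
    trim_fraction : float
        Fraction of worst correspondences discarded in each update (robust
        trimming); default 0 — brain and endocast surfaces are expected to be
        near-superimposed already.
    sample : int, optional
        If set, at most this many moving vertices (deterministic seeded
        subsample) drive the registration; the returned transform still
        applies to the full mesh.

    Returns
    -------
    (RigidTransform, ICPTrace)
    """
    if len(moving.vertices) == 0 or len(fixed.vertices) == 0:
        raise ValueError("meshes must be non-empty")
    if not (np.all(np.isfinite(moving.vertices)) and np.all(np.isfinite(fixed.vertices))):
        raise ValueError("mesh coordinates must be finite")
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must lie in [0, 1)")
    T = default_init(moving, fixed) if init is None else init
    trace = ICPTrace()
    if max_iter == 0:
        return T, trace

    pts = np.asarray(moving.vertices, dtype=float)
    if sample is not None and sample < len(pts):
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), size=sample, replace=False)]
    query = SurfaceQuery(fixed)
    prev_rms = None
    for _ in range(max_iter):
        cur = T.apply(pts)
        closest, dist = query.query(cur)
        if trim_fraction > 0.0:
            keep = dist <= np.quantile(dist, 1.0 - trim_fraction)
            cur_k, closest_k, dist_k = cur[keep], closest[keep], dist[keep]
        else:
            cur_k, closest_k, dist_k = cur, closest, dist
        rms = float(np.sqrt(np.mean(dist_k**2)))
        trace.rms.append(rms)
        if prev_rms is not None and abs(prev_rms - rms) < tol:
            trace.converged = True
            break
        prev_rms = rms
        if rms == 0.0:
            trace.converged = True
            break
        update = kabsch(cur_k, closest_k)
        T = update.compose(T)
    return T, trace
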