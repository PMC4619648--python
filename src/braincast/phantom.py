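"""Synthetic brain/endocast phantom pairs with exact ground truth.

The generator emulates the situation the pipeline is built for: a lobed organ
(olfactory bulbs, oblong telencephalon, diencephalon, narrow mesencephalon,
long metencephalon/myelencephalon, lateral labyrinth lobes, sacculolagenar
pouches and a dorsal superior sinus) nested inside a cavity whose wall
clearance is small over the forebrain and labyrinth, larger over the midbrain,
and largest in a dorsal hotspot over the spinal-cord region.  Default
proportions follow the juvenile lungfish morphology the pipeline targets:
organ length 6.0 mm (fore/mid/hindbrain spans about 40/10/50 % of it), width
3.1 mm across the labyrinth, height 1.7 mm, wall clearance peaking at 0.59 mm
in the hotspot, and cavity occupancy a little above four fifths.

Construction is exact and fully seeded:

* the organ is a union of labelled superellipsoid lobes evaluated analytically
  at voxel centres;
* the cavity is the organ generalized-dilated by a spatially varying clearance
  field (Euclidean distance transform thresholded against the field), hence a
  guaranteed superset of the unmisaligned organ;
* the emitted organ volume is evaluated analytically in the misaligned frame
  (no resampling), so the true misalignment transform is known exactly;
* all truth numbers (occupancy, volumes, gap statistics, spans) come from
  exact voxel counting before misalignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .overlap import RegionTable
from .registration import RigidTransform
from .volume import BinaryMask, LabelVolume

__all__ = ["Lobe", "PhantomSpec", "PhantomTruth", "generate_phantom", "analytic_pair", "default_region_table"]

#: Largest wall clearance (mm) the generator will produce; the dorsal-cord
#: hotspot of the emulated specimen reaches this value.
MAX_CLEARANCE_MM = 0.59

#: Clearance (mm) above which a voxel belongs to the generator's designated
#: large-gap region (midbrain band + dorsal hotspot); everything below is
#: "tight" wall contact.
LARGE_GAP_THRESHOLD_MM = 0.12


@dataclass(frozen=True)
class Lobe:
    """One superellipsoid lobe: |x/a|^p + |y/b|^p + |z/c|^p <= 1 (local mm)."""

    name: str
    label: int
    group: str
    center: tuple
    semiaxes: tuple
    exponent: float = 2.0

    def __post_init__(self):
        if any(s <= 0 for s in self.semiaxes):
            raise ValueError(f"lobe {self.name}: semi-axes must be > 0")


def default_lobes() -> list[Lobe]:
    """Blueprint realizing 6.0 x 3.1 x 1.7 mm extents with ~40/10/50 %
    fore/mid/hindbrain antero-posterior spans (z from the anterior tip)."""
    return [
        Lobe("olfactory_bulb_l", 1, "forebrain", (-0.40, 0.00, 0.34), (0.32, 0.28, 0.34)),
        Lobe("olfactory_bulb_r", 2, "forebrain", (+0.40, 0.00, 0.34), (0.32, 0.28, 0.34)),
        Lobe("olfactory_peduncles", 3, "forebrain", (0.00, 0.00, 0.62), (0.45, 0.22, 0.26)),
        Lobe("telencephalon", 4, "forebrain", (0.00, 0.05, 1.30), (0.88, 0.52, 0.92), 2.6),
        Lobe("diencephalon", 5, "forebrain", (0.00, -0.15, 2.00), (0.66, 0.54, 0.42), 2.4),
        Lobe("mesencephalon", 6, "midbrain", (0.00, 0.10, 2.70), (0.50, 0.42, 0.36), 2.2),
        Lobe("metencephalon", 7, "hindbrain", (0.00, 0.15, 3.46), (0.66, 0.54, 0.52), 2.4),
        Lobe("superior_sinus", 8, "hindbrain", (0.00, 0.35, 3.40), (0.34, 0.50, 0.48)),
        Lobe("myelencephalon", 9, "hindbrain", (0.00, 0.00, 4.60), (0.95, 0.57, 1.22), 2.6),
        Lobe("spinal_cord", 10, "hindbrain", (0.00, 0.05, 5.72), (0.34, 0.30, 0.28)),
        Lobe("labyrinth_l", 11, "labyrinth", (-1.05, 0.00, 3.95), (0.50, 0.48, 0.66)),
        Lobe("labyrinth_r", 12, "labyrinth", (+1.05, 0.00, 3.95), (0.50, 0.48, 0.66)),
        Lobe("sacculolagenar_pouch_l", 13, "labyrinth", (-0.45, -0.38, 4.10), (0.38, 0.47, 0.42)),
        Lobe("sacculolagenar_pouch_r", 14, "labyrinth", (+0.45, -0.38, 4.10), (0.38, 0.47, 0.42)),
    ]


def default_region_table(lobes=None) -> RegionTable:
    colors = {"forebrain": "#d95f02", "midbrain": "#7570b3", "hindbrain": "#1b9e77", "labyrinth": "#e7298a"}
    lobes = default_lobes() if lobes is None else lobes
    return RegionTable(
        entries={l.label: {"name": l.name, "group": l.group, "color": colors.get(l.group, "#666666")} for l in lobes}
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Everything that determines a phantom pair; ``seed`` fixes all randomness.

    Clearances are wall gaps in mm per region group; the hotspot is an
    additive Gaussian bump (amplitude mm, sigma mm per axis, centre in
    organ-local mm) over the dorsal spinal-cord region.  ``misalignment_*``
    bounds the seeded random rigid motion applied to the organ (set both to 0
    for perfectly superimposed output).
    """

    spacing: float = 0.04
    lobes: tuple = field(default_factory=lambda: tuple(default_lobes()))
    clearance_mm: dict = field(
        default_factory=lambda: {
            "forebrain": 0.04,
            "midbrain": 0.20,
            "hindbrain": 0.04,
            "labyrinth": 0.04,
        }
    )
    hotspot_center: tuple = (0.0, 0.70, 5.55)
    hotspot_sigma: tuple = (0.38, 0.60, 0.36)
    hotspot_amplitude: float = 1.0
    noise_amplitude: float = 0.012
    noise_scale_mm: float = 0.25
    profile_smooth_mm: float = 0.08
    misalignment_max_deg: float = 5.0
    misalignment_max_mm: float = 0.15
    margin_mm: float = 0.35
    target_occupancy_pct: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(c < 0 for c in self.clearance_mm.values()) or self.hotspot_amplitude < 0:
            raise ValueError("clearances must be >= 0")
        if (
            self.target_occupancy_pct is not None
            and self.target_occupancy_pct < 100.0
            and max(self.clearance_mm.values(), default=0.0) + self.hotspot_amplitude < self.spacing
        ):
            raise ValueError(
                "clearance below one voxel everywhere: the requested occupancy "
                f"{self.target_occupancy_pct}% cannot be realized at spacing {self.spacing} mm"
            )


@dataclass(frozen=True)
class PhantomTruth:
    """Exact ground truth of a generated phantom (computed before misalignment)."""

    occupancy_pct: float
    brain_volume_mm3: float
    endocast_volume_mm3: float
    max_gap_mm: float
    mean_gap_mm: float
    misalignment: RigidTransform
    extents_mm: dict
    region_length_pct: dict
    group_spans_mm: dict
    hotspot_mask: BinaryMask
    brain_aligned: LabelVolume
    regions: RegionTable


def _label_lobes(spec: PhantomSpec, origin: np.ndarray, shape: tuple, transform: RigidTransform | None) -> np.ndarray:
    """Evaluate the lobe union on the grid; overlaps resolved by the smallest
    normalized superellipsoid value.  ``transform`` maps organ-local
    coordinates to the world frame (analytic misalignment, no resampling)."""
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.uint8)
    best = np.full(shape, np.inf, dtype=np.float32)
    h = spec.spacing
    inv = transform.inverse() if transform is not None else None
    for lobe in spec.lobes:
        c = np.asarray(lobe.center, dtype=float)
        s = np.asarray(lobe.semiaxes, dtype=float)
        if inv is None:
            # axis-aligned: restrict to the lobe's bounding subbox
            lo = np.maximum(np.floor((c - s - origin) / h).astype(int) - 1, 0)
            hi = np.minimum(np.ceil((c + s - origin) / h).astype(int) + 1, np.array(shape) - 1)
            if np.any(hi < lo):
                continue
            ax = [origin[d] + np.arange(lo[d], hi[d] + 1) * h for d in range(3)]
            X, Y, Z = np.meshgrid(*ax, indexing="ij")
            local = np.stack([X - c[0], Y - c[1], Z - c[2]], axis=-1)
        else:
            # bounding box of the transformed lobe: centre moves, radius bounded
            cw = transform.apply(c[None, :])[0]
            r = float(np.linalg.norm(s))  # box-diagonal bound valid for any exponent
            lo = np.maximum(np.floor((cw - r - origin) / h).astype(int) - 1, 0)
            hi = np.minimum(np.ceil((cw + r - origin) / h).astype(int) + 1, np.array(shape) - 1)
            if np.any(hi < lo):
                continue
            ax = [origin[d] + np.arange(lo[d], hi[d] + 1) * h for d in range(3)]
            X, Y, Z = np.meshgrid(*ax, indexing="ij")
            world = np.stack([X, Y, Z], axis=-1)
            local = inv.apply(world.reshape(-1, 3)).reshape(world.shape) - c
        f = np.sum(np.abs(local / s) ** lobe.exponent, axis=-1).astype(np.float32)
        sub = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1), slice(lo[2], hi[2] + 1))
        inside = f <= 1.0
        win = inside & (f < best[sub])
        best[sub][win] = f[win]
        labels[sub][win] = lobe.label
    return labels


def _clearance_field(spec: PhantomSpec, origin: np.ndarray, shape: tuple, z_anterior: float, z_posterior: float, rng) -> np.ndarray:
    """Wall-clearance field (mm) on the grid: smoothed per-group AP profile +
    dorsal hotspot bump + seeded band-limited noise, clamped to
    [0, MAX_CLEARANCE_MM]."""
    h = spec.spacing
    nz = shape[2]
    z = origin[2] + np.arange(nz) * h
    length = z_posterior - z_anterior
    rel = (z - z_anterior) / max(length, 1e-9)
    profile = np.empty(nz)
    fore = spec.clearance_mm.get("forebrain", 0.0)
    mid = spec.clearance_mm.get("midbrain", 0.0)
    hind = spec.clearance_mm.get("hindbrain", 0.0)
    profile[:] = np.where(rel < 0.40, fore, np.where(rel < 0.50, mid, hind))
    profile = ndimage.gaussian_filter1d(profile, sigma=max(spec.profile_smooth_mm / h, 1e-6), mode="nearest")
    C = np.broadcast_to(profile[None, None, :], shape).astype(np.float32).copy()

    if spec.hotspot_amplitude > 0:
        cx, cy, cz = np.asarray(spec.hotspot_center) + np.array([0.0, 0.0, z_anterior])
        sx, sy, sz = spec.hotspot_sigma
        gx = np.exp(-0.5 * ((origin[0] + np.arange(shape[0]) * h - cx) / sx) ** 2)
        gy = np.exp(-0.5 * ((origin[1] + np.arange(shape[1]) * h - cy) / sy) ** 2)
        gz = np.exp(-0.5 * ((z - cz) / sz) ** 2)
        C += spec.hotspot_amplitude * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]

    if spec.noise_amplitude > 0:
        noise = rng.standard_normal(shape).astype(np.float32)
        noise = ndimage.gaussian_filter(noise, sigma=spec.noise_scale_mm / h)
        std = float(noise.std())
        if std > 0:
            C += spec.noise_amplitude * noise / std
    return np.clip(C, 0.0, MAX_CLEARANCE_MM)


def generate_phantom(spec: PhantomSpec | None = None, return_field: bool = False):
    """Generate one phantom pair.

    Returns
    -------
    brain : LabelVolume
        Region-labelled organ, evaluated analytically in the *misaligned*
        frame (this is what a real segmentation of a re-oriented specimen
        would look like).
    endocast : BinaryMask
        Cavity mask in the unmisaligned frame; superset of the organ before
        misalignment.
    truth : PhantomTruth
        Exact voxel-count truth plus the applied misalignment transform.

    The same spec and seed give bit-identical volumes.
    """
    spec = PhantomSpec() if spec is None else spec
    rng = np.random.default_rng(spec.seed)
    h = spec.spacing

    centers = np.array([l.center for l in spec.lobes])
    semis = np.array([l.semiaxes for l in spec.lobes])
    lo_mm = (centers - semis).min(axis=0)
    hi_mm = (centers + semis).max(axis=0)
    margin = spec.margin_mm + max(list(spec.clearance_mm.values()) + [0.0]) + spec.hotspot_amplitude
    origin = lo_mm - margin
    shape = tuple(int(np.ceil((hi_mm[d] + margin - origin[d]) / h)) + 1 for d in range(3))

    labels = _label_lobes(spec, origin, shape, transform=None)
    brain_mask = labels > 0
    if not brain_mask.any():
        raise ValueError("phantom blueprint produced an empty organ")

    C = _clearance_field(spec, origin, shape, lo_mm[2], hi_mm[2], rng)
    edt = ndimage.distance_transform_edt(~brain_mask, sampling=(h, h, h))
    endo = brain_mask | (edt <= C)
    endo = ndimage.binary_fill_holes(endo)

    n_brain = int(brain_mask.sum())
    n_endo = int(endo.sum())
    voxvol = h**3
    boundary = endo & ~ndimage.binary_erosion(endo)
    gaps = edt[boundary]
    hotspot = C >= LARGE_GAP_THRESHOLD_MM
    hotspot = ndimage.binary_dilation(hotspot, iterations=2)

    # misalignment drawn from the seeded generator, about the organ centroid
    angles = rng.uniform(-spec.misalignment_max_deg, spec.misalignment_max_deg, size=3)
    shift = rng.uniform(-spec.misalignment_max_mm, spec.misalignment_max_mm, size=3)
    centroid = np.argwhere(brain_mask).mean(axis=0) * h + origin
    rot = RigidTransform.from_euler_deg(angles)
    T = RigidTransform(rot.rotation, centroid - rot.rotation @ centroid + shift)

    brain_moved = _label_lobes(spec, origin, shape, transform=T)

    fg = np.argwhere(brain_mask)
    span_vox = fg.max(axis=0) - fg.min(axis=0) + 1
    extents = {
        "length": float(span_vox[2] * h),
        "width": float(span_vox[0] * h),
        "height": float(span_vox[1] * h),
    }
    regions = default_region_table(spec.lobes)
    from .overlap import region_length_fractions

    aligned_vol = LabelVolume(grid=labels, spacing=(h, h, h), origin=origin)
    fractions = region_length_fractions(aligned_vol, regions, ap_axis=2, mode="partition")
    spans = {}
    for group in ("forebrain", "midbrain", "hindbrain", "labyrinth"):
        lab = regions.labels_for(group)
        sel = np.isin(labels, lab)
        if sel.any():
            occ = np.flatnonzero(np.any(sel, axis=(0, 1)))
            spans[group] = (float(origin[2] + occ.min() * h), float(origin[2] + occ.max() * h))

    truth = PhantomTruth(
        occupancy_pct=100.0 * n_brain / n_endo,
        brain_volume_mm3=n_brain * voxvol,
        endocast_volume_mm3=n_endo * voxvol,
        max_gap_mm=float(gaps.max()),
        mean_gap_mm=float(gaps.mean()),
        misalignment=T,
        extents_mm=extents,
        region_length_pct=fractions,
        group_spans_mm=spans,
        hotspot_mask=BinaryMask(grid=hotspot.astype(np.uint8), spacing=(h, h, h), origin=origin),
        brain_aligned=aligned_vol,
        regions=regions,
    )
    brain = LabelVolume(grid=brain_moved, spacing=(h, h, h), origin=origin)
    endocast = BinaryMask(grid=endo.astype(np.uint8), spacing=(h, h, h), origin=origin)
    if return_field:
        return brain, endocast, truth, C
    return brain, endocast, truth


def _digitize_sphere(shape, center_vox, radius_vox):
    idx = np.indices(shape, dtype=float)
    r2 = sum((idx[d] - center_vox[d]) ** 2 for d in range(3))
    return (r2 <= radius_vox**2).astype(np.uint8)


def analytic_pair(kind: str, **params):
    """Closed-form test fixtures: digitized shape pairs with attached truth.

    ``concentric_spheres(r_inner_mm, r_outer_mm, spacing)``
        truth: uniform wall gap ``r_outer - r_inner`` and the analytic
        volumes/occupancy of the two balls.
    ``nested_cubes(inner_vox, outer_vox, spacing)``
        concentric cubes; truth occupancy is the exact voxel-count ratio.
    ``offset_spheres(radius_vox, offset_vox, spacing)``
        equal spheres, centres ``offset_vox`` apart along x; truth Dice from
        the lens (sphere-sphere intersection) volume
        ``V = (pi/12)(4 r + d)(2 r - d)^2``.
    """
    if kind == "concentric_spheres":
        r_in = float(params.get("r_inner_mm", 5.0))
        r_out = float(params.get("r_outer_mm", 6.0))
        h = float(params.get("spacing", 0.1))
        if not 0 < r_in < r_out:
            raise ValueError("need 0 < r_inner < r_outer")
        n = int(np.ceil(2 * (r_out + 2 * h) / h)) | 1
        c = (n - 1) / 2.0
        inner = _digitize_sphere((n, n, n), (c, c, c), r_in / h)
        outer = _digitize_sphere((n, n, n), (c, c, c), r_out / h)
        origin = -c * h * np.ones(3)
        truth = {
            "gap_mm": r_out - r_in,
            "inner_volume_mm3": 4.0 / 3.0 * np.pi * r_in**3,
            "outer_volume_mm3": 4.0 / 3.0 * np.pi * r_out**3,
            "occupancy_pct": 100.0 * (r_in / r_out) ** 3,
        }
        mk = lambda g: BinaryMask(grid=g, spacing=(h, h, h), origin=origin)
        return mk(inner), mk(outer), truth
    if kind == "nested_cubes":
        inner_vox = int(params.get("inner_vox", 10))
        outer_vox = int(params.get("outer_vox", 20))
        h = float(params.get("spacing", 1.0))
        if not 0 < inner_vox <= outer_vox:
            raise ValueError("need 0 < inner_vox <= outer_vox")
        n = outer_vox + 4
        a = np.zeros((n, n, n), dtype=np.uint8)
        b = np.zeros((n, n, n), dtype=np.uint8)
        s_out = 2
        s_in = 2 + (outer_vox - inner_vox) // 2
        b[s_out : s_out + outer_vox, s_out : s_out + outer_vox, s_out : s_out + outer_vox] = 1
        a[s_in : s_in + inner_vox, s_in : s_in + inner_vox, s_in : s_in + inner_vox] = 1
        truth = {"occupancy_pct": 100.0 * inner_vox**3 / outer_vox**3}
        mk = lambda g: BinaryMask(grid=g, spacing=(h, h, h))
        return mk(a), mk(b), truth
    if kind == "offset_spheres":
        r = float(params.get("radius_vox", 10))
        d = float(params.get("offset_vox", 5))
        h = float(params.get("spacing", 1.0))
        if not (r > 0 and 0 <= d < 2 * r):
            raise ValueError("need r > 0 and 0 <= d < 2r")
        n = int(np.ceil(2 * r + d)) + 6
        c = (n - 1) / 2.0
        a = _digitize_sphere((n, n, n), (c - d / 2.0, c, c), r)
        b = _digitize_sphere((n, n, n), (c + d / 2.0, c, c), r)
        v_sphere = 4.0 / 3.0 * np.pi * r**3
        v_lens = np.pi / 12.0 * (4 * r + d) * (2 * r - d) ** 2
        truth = {"dice": v_lens / v_sphere}
        mk = lambda g: BinaryMask(grid=g, spacing=(h, h, h))
        return mk(a), mk(b), truth
    raise ValueError(f"unknown analytic pair kind {kind!r}")
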