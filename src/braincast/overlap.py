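"""Volumetric overlap and regional morphometrics.

Overlap between the superimposed segmentations is measured on the fixed grid:
the registered moving mask is resampled there (nearest neighbour) and the Dice
similarity coefficient ``2|A ∩ B| / (|A| + |B|)`` is computed by exact voxel
counting.  The occupancy fraction uses the cavity (endocast) volume as the
denominator: the percentage of the endocranial space filled by the organ.

Linear extents are tight bounding boxes of foreground voxel centres plus one
voxel spacing per axis (matching the physical extent of the iso-0.5 surface).
Regional length fractions divide each region group's antero-posterior span by
the whole organ's span; the default partition mode resolves overlapping spans
at their midpoints so the forebrain/midbrain/hindbrain fractions sum to 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .registration import RigidTransform
from .volume import BinaryMask, LabelVolume

__all__ = [
    "RegionTable",
    "dice_coefficient",
    "resample_mask",
    "occupancy_fraction",
    "extent_measurements",
    "region_length_fractions",
    "ComparisonReport",
    "build_report",
]

GROUPS = ("forebrain", "midbrain", "hindbrain", "labyrinth", "other")
LENGTH_GROUPS = ("forebrain", "midbrain", "hindbrain")


@dataclass(frozen=True)
class RegionTable:
    """Mapping of integer labels to named anatomical regions and groups.

    ``entries`` maps label -> {"name": str, "group": one of GROUPS,
    "color": str}.  The labyrinth group is excluded from length accounting.
    """

    entries: dict

    def __post_init__(self):
        for label, rec in self.entries.items():
            if int(label) < 0:
                raise ValueError("labels must be non-negative")
            if rec.get("group") not in GROUPS:
                raise ValueError(f"label {label}: group must be one of {GROUPS}, got {rec.get('group')!r}")

    def labels_for(self, group: str) -> list:
        return sorted(int(l) for l, rec in self.entries.items() if rec["group"] == group)

    def groups_present(self):
        return sorted({rec["group"] for rec in self.entries.values()})

    @classmethod
    def from_yaml(cls, path) -> "RegionTable":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(entries={int(k): dict(v) for k, v in raw.items()})

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump({int(k): dict(v) for k, v in self.entries.items()}, sort_keys=True))
        return path


def _require_same_grid(a: LabelVolume, b: LabelVolume) -> None:
    if not a.same_geometry(b):
        raise ValueError(
            "masks live on different grids (shape/spacing/origin); resample onto a common grid first"
        )


def dice_coefficient(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|) on a common grid.

    1 for identical non-empty masks, 0 for disjoint masks; two empty masks are
    rejected (0/0 is undefined, not zero).
    """
    _require_same_grid(mask_a, mask_b)
    na = int(np.count_nonzero(mask_a.grid))
    nb = int(np.count_nonzero(mask_b.grid))
    if na + nb == 0:
        raise ValueError("Dice is undefined for two empty masks")
    inter = int(np.count_nonzero(mask_a.grid & mask_b.grid))
    return 2.0 * inter / (na + nb)


def resample_mask(mask: BinaryMask, transform: RigidTransform, template: LabelVolume) -> BinaryMask:
    """Resample ``transform`` applied to ``mask`` onto the template grid
    (nearest-neighbour at template voxel centres).

    Raises a bounds error when the transformed mask extends beyond the
    template grid, where foreground would be silently cropped.
    """
    # bounds check on the transformed foreground bounding box
    fg = np.argwhere(mask.grid > 0)
    if len(fg):
        lo_i, hi_i = fg.min(axis=0), fg.max(axis=0)
        corners = np.array([[i, j, k] for i in (lo_i[0], hi_i[0]) for j in (lo_i[1], hi_i[1]) for k in (lo_i[2], hi_i[2])])
        world = transform.apply(mask.world_coords(corners))
        tlo = template.origin - 0.5 * template.spacing
        thi = template.origin + (np.asarray(template.shape) - 0.5) * template.spacing
        if np.any(world < tlo - 0.5 * np.linalg.norm(mask.spacing)) or np.any(
            world > thi + 0.5 * np.linalg.norm(mask.spacing)
        ):
            raise ValueError("transformed mask extends beyond the template grid")
    inv = transform.inverse()
    # world coords of template voxel centres, mapped back into mask index space
    idx = np.indices(template.shape, dtype=float).reshape(3, -1).T
    world = template.origin + idx * template.spacing
    src_idx = (inv.apply(world) - mask.origin) / mask.spacing
    out = ndimage.map_coordinates(mask.grid, src_idx.T, order=0, mode="constant", cval=0)
    return BinaryMask(
        grid=out.reshape(template.shape).astype(np.uint8),
        spacing=template.spacing,
        origin=template.origin,
        axis_names=template.axis_names,
    )


def occupancy_fraction(inner: BinaryMask, outer: BinaryMask) -> tuple[float, int]:
    """Percentage of the outer (cavity) volume occupied by the inner (organ)
    mask, ``100 |inner ∩ outer| / |outer|``, plus the count of inner voxels
    protruding outside the cavity as a QC figure."""
    _require_same_grid(inner, outer)
    n_outer = int(np.count_nonzero(outer.grid))
    if n_outer == 0:
        raise ValueError("occupancy is undefined for an empty outer mask")
    inter = int(np.count_nonzero(inner.grid & outer.grid))
    protrusion = int(np.count_nonzero(inner.grid & ~outer.grid.astype(bool)))
    return 100.0 * inter / n_outer, protrusion


def extent_measurements(mask: BinaryMask, axes: tuple[int, int, int] = (2, 0, 1)) -> tuple[float, float, float]:
    """(length, width, height) in mm of the foreground bounding box.

    ``axes`` maps the anatomical triplet to grid axes; the default follows the
    (x=left-right, y=dorso-ventral, z=antero-posterior) convention, i.e.
    length along z, width along x, height along y.  Extents are voxel-centre
    spans plus one spacing per axis, so a single voxel reports one spacing.
    """
    fg = np.argwhere(mask.grid > 0)
    if len(fg) == 0:
        raise ValueError("cannot measure extents of an empty mask")
    span_vox = fg.max(axis=0) - fg.min(axis=0) + 1
    extent = span_vox * mask.spacing
    return tuple(float(extent[a]) for a in axes)


def region_length_fractions(
    vol: LabelVolume,
    regions: RegionTable,
    ap_axis: int = 2,
    mode: str = "partition",
) -> dict:
    """Antero-posterior length fraction (%) of each brain-division group.

    The span of a group is the range of AP slices its labels occupy, in mm.
    ``mode='raw'`` reports each span over the total organ span (overlapping
    spans may sum past 100); ``mode='partition'`` resolves overlaps between
    consecutive groups at the midpoints of their boundaries, so the fore/mid/
    hindbrain fractions sum to 100.  Labyrinth and other groups are excluded
    from length accounting.
    """
    if mode not in ("raw", "partition"):
        raise ValueError(f"mode must be 'raw' or 'partition', got {mode!r}")
    present = regions.groups_present()
    missing = [g for g in LENGTH_GROUPS if g not in present]
    if missing:
        raise ValueError(f"region table lacks required groups: {missing}")

    spans = {}
    for group in LENGTH_GROUPS:
        labels = regions.labels_for(group)
        sel = np.isin(vol.grid, labels)
        if not sel.any():
            raise ValueError(f"no voxels carry labels of group {group!r}")
        occupied = np.any(sel, axis=tuple(a for a in (0, 1, 2) if a != ap_axis))
        idx = np.flatnonzero(occupied)
        spans[group] = (int(idx.min()), int(idx.max()))

    all_labels = [l for g in LENGTH_GROUPS for l in regions.labels_for(g)]
    sel = np.isin(vol.grid, all_labels)
    occupied = np.any(sel, axis=tuple(a for a in (0, 1, 2) if a != ap_axis))
    idx = np.flatnonzero(occupied)
    total = float(idx.max() - idx.min() + 1)

    if mode == "raw":
        return {g: 100.0 * (hi - lo + 1) / total for g, (lo, hi) in spans.items()}

    ordered = sorted(LENGTH_GROUPS, key=lambda g: spans[g][0])
    bounds = [float(spans[ordered[0]][0]) - 0.5]
    for prev, nxt in zip(ordered, ordered[1:]):
        lo_p, hi_p = spans[prev]
        lo_n, _ = spans[nxt]
        # midpoint of the overlap (or of the gap) between consecutive groups
        bounds.append(0.5 * (hi_p + lo_n))
    bounds.append(float(spans[ordered[-1]][1]) + 0.5)
    total_p = bounds[-1] - bounds[0]
    return {g: 100.0 * (bounds[i + 1] - bounds[i]) / total_p for i, g in enumerate(ordered)}


def _fmt(value):
    if isinstance(value, float):
        return float(format(value, ".9g"))
    return value


@dataclass(frozen=True)
class ComparisonReport:
    """All scalar outputs of an organ-vs-cavity comparison.

    Fractions and percentages are on the 0-100 scale; distances in mm,
    volumes in mm^3.  ``provenance`` records inputs, transform and parameters
    so a run can be reproduced.
    """

    dice: float
    occupancy_pct: float
    protrusion_voxels: int
    mean_abs_mm: float
    max_abs_mm: float
    mean_directed_mm: dict
    brain_volume_mm3: float
    endocast_volume_mm3: float
    extents_mm: dict
    region_length_pct: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError(f"dice out of [0,1]: {self.dice}")
        if not 0.0 <= self.occupancy_pct <= 100.0 + 1e-9:
            raise ValueError(f"occupancy out of [0,100]: {self.occupancy_pct}")
        if self.mean_abs_mm > self.max_abs_mm + 1e-12:
            raise ValueError("mean distance exceeds max distance")
        if self.region_length_pct:
            total = sum(self.region_length_pct.get(g, 0.0) for g in LENGTH_GROUPS)
            if abs(total - 100.0) > 0.5:
                raise ValueError(f"partitioned region fractions sum to {total}, not 100 +- 0.5")

    def to_dict(self) -> dict:
        return {
            "dice": _fmt(self.dice),
            "occupancy_pct": _fmt(self.occupancy_pct),
            "protrusion_voxels": self.protrusion_voxels,
            "mean_abs_mm": _fmt(self.mean_abs_mm),
            "max_abs_mm": _fmt(self.max_abs_mm),
            "mean_directed_mm": {k: _fmt(v) for k, v in sorted(self.mean_directed_mm.items())},
            "brain_volume_mm3": _fmt(self.brain_volume_mm3),
            "endocast_volume_mm3": _fmt(self.endocast_volume_mm3),
            "extents_mm": {k: _fmt(v) for k, v in sorted(self.extents_mm.items())},
            "region_length_pct": {k: _fmt(v) for k, v in sorted(self.region_length_pct.items())},
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_csv(self, path=None):
        import pandas as pd

        d = self.to_dict()
        rows = []
        for key in ("dice", "occupancy_pct", "protrusion_voxels", "mean_abs_mm", "max_abs_mm",
                    "brain_volume_mm3", "endocast_volume_mm3"):
            rows.append({"metric": key, "value": d[key]})
        for k, v in d["mean_directed_mm"].items():
            rows.append({"metric": f"mean_directed_mm.{k}", "value": v})
        for k, v in d["extents_mm"].items():
            rows.append({"metric": f"extent_mm.{k}", "value": v})
        for k, v in d["region_length_pct"].items():
            rows.append({"metric": f"region_length_pct.{k}", "value": v})
        frame = pd.DataFrame(rows)
        if path is not None:
            frame.to_csv(path, index=False)
        return frame

    @classmethod
    def from_json(cls, source) -> "ComparisonReport":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            d = json.loads(Path(source).read_text())
        else:
            d = json.loads(source)
        return cls(
            dice=d["dice"],
            occupancy_pct=d["occupancy_pct"],
            protrusion_voxels=d["protrusion_voxels"],
            mean_abs_mm=d["mean_abs_mm"],
            max_abs_mm=d["max_abs_mm"],
            mean_directed_mm=d["mean_directed_mm"],
            brain_volume_mm3=d["brain_volume_mm3"],
            endocast_volume_mm3=d["endocast_volume_mm3"],
            extents_mm=d["extents_mm"],
            region_length_pct=d["region_length_pct"],
            provenance=d.get("provenance", {}),
        )


_REQUIRED = ("dice", "occupancy", "summary", "brain_volume_mm3", "endocast_volume_mm3", "extents_mm")


def build_report(
    *,
    dice: float,
    occupancy: tuple[float, int],
    summary,
    brain_volume_mm3: float,
    endocast_volume_mm3: float,
    extents_mm: dict,
    region_length_pct: dict | None = None,
    provenance: dict | None = None,
) -> ComparisonReport:
    """Assemble a schema-valid :class:`ComparisonReport` from upstream outputs.

    Serialization uses fixed key order and fixed float formatting, so
    re-running on identical inputs yields byte-identical JSON.
    """
    for name, value in (("dice", dice), ("occupancy", occupancy), ("summary", summary)):
        if value is None:
            raise ValueError(f"missing required metric {name!r}")
    occ_pct, protrusion = occupancy
    return ComparisonReport(
        dice=float(dice),
        occupancy_pct=float(occ_pct),
        protrusion_voxels=int(protrusion),
        mean_abs_mm=float(summary.mean_abs),
        max_abs_mm=float(summary.max_abs),
        mean_directed_mm={"a_to_b": float(summary.mean_a_to_b), "b_to_a": float(summary.mean_b_to_a)},
        brain_volume_mm3=float(brain_volume_mm3),
        endocast_volume_mm3=float(endocast_volume_mm3),
        extents_mm=dict(extents_mm),
        region_length_pct=dict(region_length_pct or {}),
        provenance=dict(provenance or {}),
    )
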