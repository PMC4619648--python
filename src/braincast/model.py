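"""Model/results interface for one organ-vs-cavity comparison.

:class:`BrainEndocastModel` is constructed from the two segmentations (plus an
optional region table) and holds the data and settings; :meth:`fit` runs the
fixed stage order — cleanup, meshing, rigid ICP superposition, surface
distances, resampled Dice, occupancy and morphometrics — and returns a
:class:`ComparisonResults` carrying the estimated transform, its diagnostics
(ICP trace), all scalar metrics, the meshes and the distance maps, with a
``summary()`` table and writers for every artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .distance import (
    CLIP_LOW,
    DistanceMap,
    SurfaceQuery,
    directed_distances,
    make_distance_map,
    symmetric_summary,
)
from .overlap import (
    ComparisonReport,
    RegionTable,
    build_report,
    dice_coefficient,
    extent_measurements,
    occupancy_fraction,
    region_length_fractions,
    resample_mask,
)
from .registration import ICPTrace, RigidTransform, apply_transform, default_init, icp_register
from .surface import marching_cubes, mesh_volume, write_mesh
from .volume import BinaryMask, LabelVolume, extract_mask, largest_component, read_volume

__all__ = ["BrainEndocastModel", "ComparisonResults"]


class BrainEndocastModel:
    """Spatial-relationship model of an organ inside its enclosing cavity.

    Parameters
    ----------
    brain : LabelVolume
        Organ segmentation, optionally region-labelled.
    endocast : LabelVolume or BinaryMask
        Cavity segmentation.
    regions : RegionTable, optional
        Label -> region-group mapping enabling regional length fractions.
    brain_labels, endocast_labels : set, optional
        Labels forming the organ/cavity masks (default: all non-zero).
    iso : float
        Marching-cubes iso level on the {0,1} masks (default 0.5).
    clean : bool
        Keep only the largest connected component of each mask (default True).
    """

    def __init__(
        self,
        brain: LabelVolume,
        endocast: LabelVolume,
        regions: RegionTable | None = None,
        *,
        brain_labels=None,
        endocast_labels=None,
        iso: float = 0.5,
        clean: bool = True,
    ):
        self.brain = brain
        self.endocast = endocast
        self.regions = regions
        self.iso = float(iso)
        labels_b = brain_labels or set(int(l) for l in brain.labels() if l > 0)
        labels_e = endocast_labels or set(int(l) for l in endocast.labels() if l > 0)
        self.brain_mask = extract_mask(brain, labels_b)
        self.endocast_mask = extract_mask(endocast, labels_e)
        if clean:
            self.brain_mask = largest_component(self.brain_mask)
            self.endocast_mask = largest_component(self.endocast_mask)

    @classmethod
    def from_files(cls, brain_path, endocast_path, regions_path=None, **kwargs) -> "BrainEndocastModel":
        regions = RegionTable.from_yaml(regions_path) if regions_path else None
        return cls(read_volume(brain_path), read_volume(endocast_path), regions=regions, **kwargs)

    def fit(
        self,
        *,
        init: str | RigidTransform = "centroid",
        max_iter: int = 100,
        tol: float = 1e-6,
        trim_fraction: float = 0.0,
        icp_sample: int | None = 5000,
        seed: int = 0,
        clip_mm: float = CLIP_LOW,
    ) -> "ComparisonResults":
        """Superimpose the organ on the cavity and compute every metric.

        ``init`` is either a starting :class:`RigidTransform` or an init mode
        (``"centroid"`` / ``"principal_axes"``).  ``icp_sample`` caps the
        number of moving vertices driving the registration (seeded,
        deterministic); the distances themselves always use all vertices.
        """
        brain_mesh_raw = marching_cubes(self.brain_mask, self.iso)
        endo_mesh = marching_cubes(self.endocast_mask, self.iso)

        if isinstance(init, RigidTransform):
            T0 = init
        else:
            T0 = default_init(brain_mesh_raw, endo_mesh, mode=init)
        transform, trace = icp_register(
            brain_mesh_raw,
            endo_mesh,
            init=T0,
            max_iter=max_iter,
            tol=tol,
            trim_fraction=trim_fraction,
            sample=icp_sample,
            seed=seed,
        )
        brain_mesh = apply_transform(brain_mesh_raw, transform)

        endo_query = SurfaceQuery(endo_mesh)
        d_ab = directed_distances(brain_mesh, endo_mesh, query=endo_query)
        d_ba = directed_distances(endo_mesh, brain_mesh)
        summary = symmetric_summary(brain_mesh, endo_mesh, distances=(d_ab, d_ba))

        map_full = make_distance_map(brain_mesh, d_ab)  # full observed range
        map_clip = DistanceMap(mesh=brain_mesh, distances=d_ab, clip_range=(0.0, clip_mm))

        moved_mask = resample_mask(self.brain_mask, transform, self.endocast_mask)
        dice = dice_coefficient(moved_mask, self.endocast_mask)
        occupancy = occupancy_fraction(moved_mask, self.endocast_mask)

        extents = extent_measurements(self.brain_mask)
        fractions = (
            region_length_fractions(self.brain, self.regions, ap_axis=2, mode="partition")
            if self.regions is not None
            else {}
        )

        report = build_report(
            dice=dice,
            occupancy=occupancy,
            summary=summary,
            brain_volume_mm3=mesh_volume(brain_mesh),
            endocast_volume_mm3=mesh_volume(endo_mesh),
            extents_mm={"length": extents[0], "width": extents[1], "height": extents[2]},
            region_length_pct=fractions,
            provenance={
                "software": f"braincast {_version}",
                "iso": self.iso,
                "icp": {
                    "init": init if isinstance(init, str) else "explicit",
                    "max_iter": max_iter,
                    "tol": tol,
                    "trim_fraction": trim_fraction,
                    "sample": icp_sample,
                    "seed": seed,
                    "iterations": trace.iterations,
                    "converged": trace.converged,
                },
                "distance_pooling": "pooled both directions (unweighted)",
                "clip_presets_mm": [0.59, clip_mm],
            },
        )
        return ComparisonResults(
            model=self,
            report=report,
            transform=transform,
            trace=trace,
            brain_mesh=brain_mesh,
            endocast_mesh=endo_mesh,
            distances_brain=d_ab,
            distances_endocast=d_ba,
            map_full=map_full,
            map_clipped=map_clip,
            moved_mask=moved_mask,
        )


@dataclass
class ComparisonResults:
    """Everything :meth:`BrainEndocastModel.fit` estimated and measured."""

    model: BrainEndocastModel
    report: ComparisonReport
    transform: RigidTransform
    trace: ICPTrace
    brain_mesh: "object"
    endocast_mesh: "object"
    distances_brain: np.ndarray
    distances_endocast: np.ndarray
    map_full: DistanceMap
    map_clipped: DistanceMap
    moved_mask: BinaryMask

    def summary(self) -> str:
        """Human-readable summary table of the comparison."""
        r = self.report
        lines = [
            "Brain-endocast spatial relationship",
            "=" * 51,
            f"{'Dice similarity coefficient':38s} {r.dice:10.4f}",
            f"{'Endocast occupancy (%)':38s} {r.occupancy_pct:10.2f}",
            f"{'Symmetric mean abs. distance (mm)':38s} {r.mean_abs_mm:10.4f}",
            f"{'Symmetric max abs. distance (mm)':38s} {r.max_abs_mm:10.4f}",
            f"{'Brain volume (mm^3)':38s} {r.brain_volume_mm3:10.4f}",
            f"{'Endocast volume (mm^3)':38s} {r.endocast_volume_mm3:10.4f}",
            f"{'Brain length/width/height (mm)':38s} "
            f"{r.extents_mm['length']:.3f}/{r.extents_mm['width']:.3f}/{r.extents_mm['height']:.3f}",
        ]
        if r.region_length_pct:
            parts = "/".join(
                f"{r.region_length_pct[g]:.1f}" for g in ("forebrain", "midbrain", "hindbrain")
            )
            lines.append(f"{'Fore/mid/hindbrain length (%)':38s} {parts:>10s}")
        lines += [
            "-" * 51,
            f"ICP: {self.trace.iterations} iterations, "
            f"converged={self.trace.converged}, "
            f"rotation {self.transform.angle_deg:.3f} deg, "
            f"|t| {float(np.linalg.norm(self.transform.translation)):.4f} mm",
        ]
        return "\n".join(lines)

    def save(self, outdir, figures: bool = True) -> dict:
        """Write report (JSON + CSV), transform, meshes with distance channel,
        per-vertex CSV and (optionally) overlay/distance-map figures."""
        from .pipeline import render_overlay
        from .distance import render_distance_map

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["report_json"] = str(outdir / "report.json")
        self.report.to_json(outdir / "report.json")
        self.report.to_csv(outdir / "report.csv")
        paths["report_csv"] = str(outdir / "report.csv")
        self.transform.to_json(outdir / "transform.json")
        paths["transform"] = str(outdir / "transform.json")
        write_mesh(self.brain_mesh, outdir / "brain_distance.ply")
        paths["brain_mesh"] = str(outdir / "brain_distance.ply")
        em = self.endocast_mesh.copy()
        em.vertex_attributes["quality"] = self.distances_endocast
        write_mesh(em, outdir / "endocast_distance.ply")
        paths["endocast_mesh"] = str(outdir / "endocast_distance.ply")
        np.savetxt(
            outdir / "distances_brain_vertices.csv",
            np.column_stack([self.brain_mesh.vertices, self.distances_brain]),
            delimiter=",",
            header="x_mm,y_mm,z_mm,distance_mm",
            comments="",
        )
        paths["distances_csv"] = str(outdir / "distances_brain_vertices.csv")
        if figures:
            for name, view in (("lateral", 0), ("dorsal", 1), ("ventral", 1)):
                render_overlay(
                    self.brain_mesh, self.endocast_mesh, path=outdir / f"overlay_{name}.png", view=name
                )
                render_distance_map(self.map_full, path=outdir / f"distance_full_{name}.png", view_axis=view)
                render_distance_map(self.map_clipped, path=outdir / f"distance_clipped_{name}.png", view_axis=view)
            paths["figures"] = str(outdir)
        return paths
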