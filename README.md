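# braincast

Quantitative analysis of the spatial relationship between an organ and the
skeletal cavity that houses it — built for brain-vs-cranial-endocast
comparisons from micro-CT segmentations (e.g. diceCT soft-tissue scans of
fishes), and useful for any nested organ/cavity pair given two labeled 3-D
volumes with physical voxel spacing.

Palaeoneurologists routinely use the endocast — the mould of the endocranial
cavity — as a proxy for brain size and shape in fossils. How good that proxy
is can only be judged in extant animals where both the brain and the cavity
can be segmented from the same scan. `braincast` turns a pair of such
segmentations into the standard quantitative answers:

* **surface meshes** of both structures (marching cubes at iso-level 0.5, in
  world millimetres),
* a **rigid superposition** of the organ onto the cavity by iterative closest
  point (ICP) registration with an exact closed-form (Kabsch/SVD)
  least-squares step,
* **symmetric unsigned surface distances**: per-vertex exact
  point-to-triangle distances in both directions, pooled into the symmetric
  mean absolute distance, plus the symmetric maximum (vertex-sampled
  symmetric Hausdorff distance), rendered as colour-coded **distance maps**
  (full range and a clipped low-range view),
* the **Dice similarity coefficient** `2|A∩B| / (|A|+|B|)` on the common
  voxel grid,
* the **occupancy fraction** `100·|organ ∩ cavity| / |cavity|` — the
  percentage of the endocranial space the brain fills,
* **morphometrics**: length/width/height extents and antero-posterior length
  fractions of the fore-, mid- and hindbrain divisions.

Because real reference segmentations are rarely shareable, the package ships
a seeded **phantom generator**: a lobed organ (olfactory bulbs through spinal
cord, plus labyrinth lobes) nested in a cavity built by generalized dilation
against a spatially varying wall-clearance field, with exact voxel-count
ground truth for every metric. Every stage of the pipeline is validated
against that truth and against closed-form fixtures (nested cubes, concentric
and offset spheres).

## Worked example

```python
from braincast import BrainEndocastModel, PhantomSpec, generate_phantom

brain, endocast, truth = generate_phantom(PhantomSpec(seed=1))
model = BrainEndocastModel(brain, endocast, regions=truth.regions)
results = model.fit()
print(results.summary())
results.save("out/")   # report.json/.csv, transform.json, PLY meshes, figures
```

prints

```
Brain-endocast spatial relationship
===================================================
Dice similarity coefficient                0.8806
Endocast occupancy (%)                      79.35
Symmetric mean abs. distance (mm)          0.0653
Symmetric max abs. distance (mm)           0.5628
Brain volume (mm^3)                        8.3866
Endocast volume (mm^3)                    10.4570
Brain length/width/height (mm)         6.000/3.120/1.760
Fore/mid/hindbrain length (%)          40.0/10.3/49.7
---------------------------------------------------
ICP: 31 iterations, converged=True, rotation 5.861 deg, |t| 0.4247 mm
```

Reading: the organ fills 79 % of the cavity; over most of the surface the
wall gap is a few hundredths of a millimetre (mean 0.065 mm), but one dorsal
posterior region opens up to 0.56 mm — exactly the structure the phantom was
generated with (true occupancy 80.2 %, true maximum wall gap 0.588 mm, organ
6.0 × 3.1 × 1.7 mm with fore/mid/hindbrain spans near 40/10/50 %). The
distance maps written by `results.save()` show the gap pattern clipped at
0.59 mm (full range) and 0.25 mm (low-range view); darkest colours mean
organ–wall contact, warm colours mean the largest gaps.

The same analysis runs from the shell:

```sh
braincast simulate --seed 1 -o phantom/
braincast compare --brain phantom/brain.nrrd --endocast phantom/endocast.nrrd \
                  --regions phantom/regions.yaml -o run/
```

Volumes are accepted as NRRD (spacing in the header) or multipage TIFF with a
YAML sidecar `{spacing_mm: [x,y,z], origin_mm: [x,y,z]}`; a stack without
stated spacing is refused rather than guessed. Meshes are written as PLY
(binary, with the per-vertex `quality` distance channel), OBJ or STL.

## Layout

| module | contents |
|---|---|
| `braincast.volume` | `LabelVolume`/`BinaryMask`, NRRD/TIFF I/O, mask extraction, connected components |
| `braincast.surface` | marching cubes, mesh volume/area, mesh voxelization, PLY/OBJ/STL I/O |
| `braincast.registration` | `RigidTransform`, Kabsch, point-to-surface ICP |
| `braincast.distance` | exact point-to-triangle distances, symmetric summaries, distance maps |
| `braincast.overlap` | Dice, occupancy, resampling, extents, regional fractions, report |
| `braincast.phantom` | seeded phantom generator and analytic fixture pairs |
| `braincast.model` | `BrainEndocastModel.fit()` → `ComparisonResults.summary()` |
| `braincast.pipeline` / `braincast.cli` | one-shot runs, overlay rendering, `braincast` command |

See `docs/methods.md` for the methods, numerical conventions and known
limitations.
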