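# npcquant

Quantitation of nuclear pore complexes (NPCs) from 3D structured-illumination
microscopy of fission-yeast nuclei — as a tested, reusable pipeline with a
synthetic-nucleus simulator standing in for the microscope.

NPCs appear in 3D-SIM as diffraction-limited puncta on the nuclear envelope
(NE). From a calibrated multi-channel z-stack the pipeline measures, per
nucleus:

- **NPC count** — iterative brightest-voxel detection ("track max, not
  mask"): record the global maximum, zero a 320 nm × 625 nm spheroid around
  it, repeat while the next maximum is ≥ 25% of the original image maximum;
- **NE surface area and volume** — the convex hull of the detected foci,
  with up to 10% of points removed greedily whenever removal increases the
  fraction of points on the hull surface (stray cytoplasmic foci distort the
  hull; removing them is the fix);
- **NPC density** = count / surface area (NPCs/µm²), and background-
  subtracted intensity per unit surface area;
- **co-detection** between two channels (partner focus within 250 nm);
- **cell-cycle stage** from cell length / nucleation / septation, and the
  SPB-duplication stage from the daughter/mother SPB intensity ratio
  (< 0.5 / 0.5–0.8 / ≥ 0.8);
- **single-particle averages (SPA)** around the spindle pole body: the SPB
  pair is fitted as two 3D Gaussians, nuclei with both spots ≥ 400 nm inside
  the projected NE are realigned on the pair axis, averaged with an x-mirror,
  and a 12-pixel-wide axis profile is extracted. A protein is *excluded*
  from the SPB region when the normalised profile drops below 0.8 — a
  threshold anchored to simulations of randomly placed NPCs — and the zone
  width is the FWHM = 2.355 × SD of an inverted-Gaussian fit;
- **nucleolar NE profiles** — two-channel line profiles along the NE,
  aligned at the nucleolar-marker half-max centre and averaged; the mean
  normalised Nup intensity at position 0 measures the nucleolar reduction in
  NPC signal.

The simulator renders spherical nuclei (radius 600–1800 nm) carrying 1–15
NPCs/µm² with ≥ 100 nm spacing as anisotropic 3D Gaussians (FWHM 100 nm
lateral / 300 nm axial, 100 peak photons) on a 40 nm / 125 nm voxel grid,
through a camera with Poisson shot noise, gain 20 and Gaussian read noise
(SD 40), plus an optional second channel with the 180 nm SPB landmark pair.
Ground truth is exact, so every stage of the pipeline is validated by
parameter recovery. See `docs/methods.md` for the models and design choices.

## Worked example

```bash
npcquant simulate --n 125 --radius-nm 1250 --seed 7 --out nucleus.tif
npcquant count --in nucleus.tif --out records.csv --foci-out foci.csv
```

The `simulate` step prints the ground truth:

```json
{"seed": 7, "radius_nm": 1250.0, "n_npcs": 125,
 "true_density_per_um2": 6.366197723675813, "true_sa_um2": 19.634954084936208}
```

(125 pores on a 1.25 µm sphere is a surface density of 6.4 NPCs/µm², the
typical mid-G2 value.) `count` then segments the nucleus, detects foci, fits
the hull and writes one row per nucleus; for this stack:

```
nucleus_id,npc_count,surface_area_um2,volume_um3,density_per_um2,on_hull_fraction,n_removed
nucleus000,108,18.813706235942583,7.431566666666663,5.740495713368361,1.0,5
```

108 of 125 pores are detected — pores closer than the 160 nm masking radius
merge into single detections, a bias that grows with density (the
calibration in `analysis/02_density_calibration.py` maps it: mean density
error stays within ~13% for 4–7 NPCs/µm²). The hull's 18.8 µm² slightly
underestimates the sphere's 19.6 µm² (an inscribed polyhedron), so the
measured density of 5.7 NPCs/µm² sits ~10% below the true 6.4.

The same operations are importable:

```python
from npcquant import SimConfig, simulate_nucleus
from npcquant.experiments import measure_nucleus

truth, volume = simulate_nucleus(SimConfig(n_npcs=125, seed=7))
mask, foci, hull, record = measure_nucleus(volume)
print(record.npc_count, record.surface_area_um2, record.density_per_um2)
```

## Analysis scripts

The numbered drivers under `analysis/` reproduce the validation studies and
write their tables to `results/`:

| script | what it shows |
|---|---|
| `01_simulate_grid.py` | condition-grid manifest (4.52–40.7 µm² spheres) + example stacks |
| `02_density_calibration.py` | density recovery across radii × densities; undercount grows with density |
| `03_spa_null.py` | random-NPC SPA null: profile ≥ 0.8 at the SPB positions |
| `04_exclusion_zone.py` | constructed 300 nm exclusion zone: dip called, FWHM + 95% CI |
| `05_spb_separation.py` | 180 nm SPB pair separation recovered without bias |
| `06_nucleolar_reduction.py` | nucleolar Nup reductions of 0/20/50% recovered at position 0 |

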