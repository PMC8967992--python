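# Methods

`npcquant` quantifies nuclear pore complexes (NPCs) in 3D-SIM-like volumes of
fission-yeast nuclei: how many pores a nucleus has, how densely they cover the
nuclear envelope (NE), whether two tagged proteins mark the same pores, and
how the pore distribution is organised relative to two landmarks — the
spindle pole body (SPB) and the nucleolus. Because validation against real
microscope data is impossible at desk scale, every stage is exercised against
a synthetic-nucleus simulator whose output statistics are known exactly; the
simulator is first-class, tested code, not a fixture.

## The synthetic nucleus

The NE is modelled as a sphere of radius 600–1800 nm. NPCs are points placed
uniformly at random on the sphere, subject to a hard minimum center-to-center
spacing of 100 nm (two pores cannot overlap), at densities of 1–15 NPCs/µm²;
the standard nucleus is 125 pores on a 1.25 µm sphere, i.e. 6.4 NPCs/µm².
Placement is rejection sampling of isotropic directions; a candidate that
violates the spacing (or an optional forbidden zone, below) is redrawn, and
after 10⁴ consecutive failures for one point the generator fails loudly,
naming the achieved count, rather than silently relaxing the spacing.

Each pore is rendered as an anisotropic 3D Gaussian — the effective 3D-SIM
point-spread function, FWHM 100 nm in x–y and 300 nm in z (SD = FWHM/2.355
per axis) — evaluated at voxel centers, with a peak of 100 photons. All
emitters share one peak intensity; no brightness distribution is modelled.
The voxel grid is 40 nm laterally with 125 nm z-steps and extends 3 axial
FWHM (900 nm) beyond the sphere on every side, so the truncated emitter mass
is far below 1%; rendering truncates each Gaussian at 4.5 SD per axis
(≤ 0.02% lost). The camera model is

    counts = gain · Poisson(expected photons) + N(0, read noise SD)

with gain 20 and read-noise SD 40 intensity units. The photon units imply
shot noise, so Poisson sampling defaults on, with a flag to disable; the
validation targets are insensitive to the choice.

A second channel can carry the SPB landmark pair: two spots 180 nm apart,
rendered with the same PSF and camera. The pair midpoint sits on the sphere
in the top polar cap, with the pair axis tangent to the sphere and a uniform
in-plane orientation; the cap is cut so that both projected spots clear the
projected nuclear rim by at least 460 nm, which makes the downstream 400 nm
edge filter pass by construction and fixes the top-down viewing geometry that
single-particle averaging assumes. The mother spot is rendered brighter than
the daughter (ratio 0.7, an interphase-like value), giving the
brightness-based mother/daughter assignment something real to recover.

For exclusion-zone studies the sampler accepts forbidden zones: spheres of a
chosen radius (e.g. 150 nm around the SPB midpoint) inside which no pore may
be placed. The remaining pores are uniform on the allowed region.

A separate generator builds nucleolar test scenes as paired line profiles
along a circular NE trace: a Nup profile equal to 1 everywhere except the
nucleolar arc (default 120°), where it is scaled by 1 − reduction, and a
marker profile shaped as a cos² bump whose half-max run spans exactly that
arc — so half-max alignment centres on the arc midpoint by construction and
a noise-free analysis recovers the reduction exactly. Scenes are randomly
rotated, optionally degraded with Gaussian noise, and can be rasterised to a
two-channel 2D image plus trace polyline for the image-based extraction path.

What the simulator does **not** emulate: SIM reconstruction artifacts
(stripes, haloing), pore clustering into rings, anaphase-bridge geometries,
photobleaching, drift, or cytoplasmic background structures. Passing tests
therefore demonstrate correctness of the measurement chain under the stated
noise and geometry, not robustness to reconstruction artifacts.

## NPC counting and density

Nuclei are segmented on the maximum-intensity projection: pixels above the
local mean (window ≈ 2× the expected 2.5 µm nucleus diameter) plus 6 robust
noise SDs are foreground; a morphological closing with a 300 nm radius
bridges neighbouring puncta into one region (projected pores sit ~400 nm
apart, so a nucleus projects as dots on a rim, not a filled disk); holes are
filled, small components dropped, and the mask dilated by 2 px so rim-hugging
foci are not clipped. Touching nuclei are not split automatically — user ROI
edits (add/remove polygons) are merged instead.

Detection is iterative brightest-voxel picking ("track max, not mask"): the
global maximum of the mask-cropped volume is recorded as a focus and a
spheroid of 8 px (320 nm) lateral diameter and 5 slices (625 nm) axial extent
is zeroed around it; this repeats while the next maximum is at least 25% of
the **original** (pre-masking) maximum of the cropped nucleus. Anchoring the
threshold to the original maximum, computed once, is essential: a
per-iteration maximum would decay with every masking step and the loop would
never terminate cleanly. Foci are voxel centers in nm; sub-voxel centroid
refinement exists but is off by default. Two pores closer than the spheroid
radius (160 nm laterally) merge into one detection — the physical origin of
the density-dependent undercount quantified below.

The NE surface is the convex hull of the detected foci, made tolerant to
stray points: up to 10% of the points may be removed, one at a time, each
time choosing the removal that most increases the fraction of retained points
on the hull surface (a point is "on" the hull if it is a vertex or within
20 nm — half a pixel — of a facet). Candidates include hull vertices, not
only interior points: a cytoplasmic stray is a hull *vertex* that shadows
real NE points, and removing it is precisely what raises the on-hull
fraction. Ties are broken by depth inside the hull, then input index, so the
optimisation is deterministic; for ≤ 12 points (removal budget 1) it provably
matches exhaustive search, which the tests verify. Surface area and volume
come from the final hull; density = count / surface area, with the count by
default including points the optimiser removed (they are real detections;
removal refines the surface model, not the census — a `count_retained_only`
flag gives the stricter census).

Calibration on simulated grids (radii 1.0/1.25/1.5 µm × densities
4–7 NPCs/µm², 20 nuclei per condition; sizes chosen to exercise the realistic
range at desk scale) shows the expected behaviour: mean density error per
condition within ~13%, always within 30%, with the undercount growing
monotonically with true density.

Two-channel co-detection declares a focus co-detected when any focus of the
other channel lies within 250 nm; matching is many-to-one by design, and
empty channels yield an undefined (not zero) fraction. Intensity per unit
surface area sum-projects the raw stack, subtracts the median of pixels
outside all nucleus masks (a robust background estimate unaffected by bright
nuclei), integrates over the mask and divides by the hull surface area.

## Cell-cycle staging

Stages follow fixed morphology rules: septated → G1/S (precedence);
binucleate with length ≥ 11 µm → late mitosis (shorter binucleates have no
stated rule and come back `unclassified`); mononucleate cells split at
9.5 and 11 µm into early G2, mid G2 and late G2/early M. The SPB-duplication
stage uses the daughter/mother intensity ratio with bands [0, 0.5),
[0.5, 0.8), [0.8, ∞); only the upper band is explicitly inclusive (≥ 0.8),
the other boundaries are half-open so the classification is total.

## Single-particle averaging and the exclusion zone

The SPB pair is fitted jointly as two 3D Gaussians with shared lateral/axial
SDs and a shared constant baseline, seeded from user clicks or simulator
truth; fits that collapse (< 20 nm separation) or whose centers cross their
seeds fail loudly. The brighter fitted spot is the mother. Nuclei pass the
edge filter only if both projected centers lie ≥ 400 nm inside the projected
nucleus mask (distance transform), selecting top-down views. Each volume is
then rotated in-plane so the mother→daughter axis lies along +x (mother on
−x) with the pair midpoint at the lateral frame centre (bilinear resampling,
z untouched).

Averaging: each realigned volume is sum-projected over an axial window of
±3 z-steps (375 nm) around its fitted SPB mid-plane and the central 2 µm box
is averaged across nuclei, then averaged with its x-axis mirror image. The
axial window matters: the SPB sits on top of the sphere in these views, and
projecting the whole stack would superimpose the limb-brightened projected
rim of the NE onto the map, swamping the local cap signal around the SPB;
the window isolates the NE sheet the SPB actually sits in. Full-stack
projection remains available (`z_halfwidth_nm=None`).

The axis profile averages a 12-pixel-wide band along x through the frame
centre, restricted to ±500 nm, lightly boxcar-smoothed (3 px) and normalised
to the **profile mean**. The mean — not the maximum — is the NE reference:
with 6.4 pores/µm², each 40 nm profile column receives of order 0.1 pores
per nucleus, so even a 100-nucleus average carries ~5–10% sampling noise,
and dividing by the single highest excursion would push a perfectly random
profile below 0.8. With mean normalisation, simulated random-NPC datasets
stay at 0.87–0.96 at the SPB positions (n = 100 nuclei), which is what
anchors 0.8 as the exclusion threshold.

A protein is called excluded when the normalised profile minimum falls below
0.8. The zone is sized by fitting baseline − amp·Gaussian over the central
1 µm with the baseline pinned to the outer-flank mean (a free baseline chases
the deepest few points with an unrealistically narrow Gaussian);
FWHM = 2.355 × SD, 95% CI from the fit covariance. On constructed zones the
measured FWHM is narrower than the forbidden ball's diameter — the band
average mixes rows beyond the zone, and the projected zone shrinks by the
cosine of the cap tilt — so recovery is validated against an independent
continuum computation of the expected band profile for the identical ground
truth (analytic Gaussian contributions per emitter; no raster, no noise, no
fitting, no interpolation). Pipeline and oracle agree to ~2% at n = 100
nuclei; the test budget is 20%.

Proximal/distal comparison partitions foci by minimum distance to either
fitted SPB centre (100 nm default), normalises intensities by the overall
mean, and applies the two-sided Wilcoxon rank-sum test (normal approximation
with tie and continuity correction, via `scipy.stats.mannwhitneyu`). Type-I
error is verified at 0.05 ± 0.03 under the null by simulation.

## Nucleolar NE profiles

Two-channel profiles along a traced NE (banded bilinear sampling along the
polyline) are anchored on the nucleolar marker: the marker profile is
boxcar-smoothed (default width 5 samples), thresholded at half its maximum,
and the midpoint of the above-threshold run — robust to plateaus, unlike the
argmax — defines position 0. Closed traces are treated as periodic, so runs
may wrap. Nup profiles are normalised per nucleus by their mean outside the
marker run dilated by 2 grid steps, resampled onto a common grid (default
spacing = pixel size) by linear interpolation and averaged. The headline
statistic is the mean normalised Nup value at position 0: 1.0 means no
nucleolar reduction, 0.8 a 20% reduction. Constructed reductions of 0, 20
and 50% are recovered within 3 SE over 50 noisy scenes; the noise-free case
is exact by construction.

## Numerical and design notes

- Coordinates are physical nm, (x, y, z), origin at the volume corner, voxel
  centers at (i + 0.5)·pitch; volumes index as (z, y, x). All physical
  thresholds (250, 320, 625, 400, 100 nm …) are stored in nm and converted
  through each volume's calibration.
- Every random draw descends from a single master seed via
  `numpy.random.SeedSequence`; identical configuration and seed give
  bit-identical outputs, and per-image child seeds stay below 2³¹.
- Gaussian fits that fail to converge or have zero amplitude are returned
  flagged rather than raised, and excluded from averages.
- Degenerate inputs fail with named errors: < 4 or coplanar points for the
  hull, unsatisfiable SPB edge margins on small nuclei, empty marker
  channels (nuclei dropped with logged reasons), empty co-detection channels
  (undefined fraction).
- Problem sizes in the tests and drivers — 20 nuclei per calibration
  condition, 100 nuclei per SPA average, 50 SPB replicates, 50 nucleolar
  scenes — were chosen as the smallest sizes at which the Monte-Carlo error
  of each check is several times smaller than its tolerance.

## Known limitations

- Densities above ~10 NPCs/µm² undercount badly (unresolvable neighbours);
  the calibration quantifies but cannot remove this bias.
- The hull underestimates the sphere's surface area by ~3–5% at 125 points
  (inscribed polyhedron), slightly inflating density; the two biases
  partially cancel.
- Segmentation does not split touching nuclei; ROI edits are the supported
  path, mirroring a semiautomated workflow.
- The exclusion-zone FWHM is a protocol-defined width, not the physical zone
  diameter; comparisons are meaningful within the protocol (12 px band,
  mean normalisation, pinned-baseline fit), which is how it is used.
- Ring-level substructure of NPC clusters, anaphase NE bridges and any
  SIM-reconstruction artifacts are out of scope.
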