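# Methods

## Scope and data model

`bonemorph` quantifies longitudinal micro-CT series of long bones. Its unit
of input is a `Volume`: a 3D grid of linear attenuation coefficients
(mm⁻¹) with an isotropic voxel size (mm) and an acquisition day. Axis 0 is
always the bone's long axis; readers reorder to this convention, and
anisotropic voxels are rejected rather than resampled. A `SeriesManifest`
orders the scans of one specimen by day, starting at the day-0 baseline.

## Segmentation

Bone is separated from soft tissue/marrow/background by Otsu's criterion:
for a histogram with class probabilities ω₀, ω₁ and class means μ₀, μ₁ at a
candidate split, the threshold maximizes the between-class variance
ω₀ω₁(μ₁−μ₀)². The implementation scans every bin boundary; ties keep the
lower threshold, and the threshold is applied inclusively (value ≥ t is
bone). Histograms use 256 bins over the series-wide min/max by default.

For a longitudinal series the threshold is computed **once** from the
pooled (summed) histogram of all scans and applied unchanged to each scan.
This is the property that makes per-day volume differences interpretable:
any per-scan threshold adaptation would convert intensity drift into
apparent volume change. Pooling the histograms is equivalent to
thresholding the concatenated voxel population.

After binarization, connected components smaller than 27 voxels
(26-connectivity) are removed; reconstruction noise produces speckle well
below a 3×3×3 neighbourhood, while genuine trabecular structure is
connected to the lattice. 26-connectivity is used throughout because
6-connectivity under-connects thin rods that touch diagonally.

## Envelope, compartments, regions

The **periosteal envelope** (the TV region) is the bone mask closed with a
ball of radius 5 voxels, hole-filled per axial slice (an open-ended shaft's
marrow cavity is a 2D hole in every cross-section but not a 3D cavity) and
in 3D, keeping the largest component. The envelope is idempotent under
re-application and is a superset of the mask.

**Cortical/trabecular separation** is by morphological opening: a ball of
radius r_open (default 2 voxels, ~1.5× the expected trabecular rod radius)
erases structures thinner than about 2·r_open, leaving cortical cores; the
cores are re-dilated by the same ball and intersected with the mask to
restore the exact cortical boundary, and everything else in the mask is
trabecular. Two details matter in practice:

* The opened shell may lose continuity where it runs steeply relative to
  the image grid (flaring metaphyses, epiphyseal caps), because a tilted
  shell's thickness *perpendicular to its surface* is what erosion sees.
  Cores are therefore kept if they are at least 5 % of the largest core —
  surviving trabecular clumps are orders of magnitude smaller than any
  shell fragment, so this threshold is not delicate.
* The dilate-and-intersect step claims any trabecular voxel within r_open
  of the cortical wall. Wall-adjacent trabeculae are thus systematically
  absorbed into the cortical class; this is an inherent property of
  opening-based separation, quantified below with the phantom.

**Region delineation** splits the axis into proximal EM zone / diaphysis /
distal EM zone. The default area-profile rule computes the envelope
cross-sectional area A(z) and takes the diaphysis to be the maximal
contiguous run with A(z) ≤ A_min + β(A_end − A_min), where A_min is the
mid-shaft minimum, A_end the mean of the two end maxima, and β = 0.5. For
profiles with no interior low-area run (no flared ends) the method falls
back, with a warning, to fixed fractions of the axial extent; fixed
fractions are also available directly for exact reproducibility. The
three slabs are contiguous, disjoint and tile the full axis, so regional
volumes always sum to whole-sample volumes exactly.

Each scan of a series is processed independently — envelope, compartments
and cuts are re-derived per day — because specimen volume itself is a
measurand that changes over time.

## Morphometry

Per region and whole-sample: TV (envelope voxels × voxel volume), Ct.BV,
Tb.BV (class voxels × voxel volume), BV = Ct.BV + Tb.BV,
BV/TV = 100·BV/TV (%), and the median attenuation over each class's
voxels (μ.B over all bone, μ.Ct, μ.Tb). Medians, not means: the median of
a class is exact on noiseless piecewise-constant data and robust to
partial-volume tails; under additive Gaussian noise of sd σ its error is
asymptotically 1.2533·σ/√n for class size n. Whole-sample values are
computed from the full grids, never by summing rounded regional values.
An empty class yields volume 0 and an absent (not zero) median.

Regions whose trabecular volume is below 2 % of the specimen's total
trabecular volume report Tb.BV and μ.Tb as absent: such slivers (the
diaphysis of a long bone) are dominated by segmentation ambiguity at the
endocortical wall rather than by real lattice.

## Longitudinal analysis

Curves are Δ(t) = 100·(x(t) − x(0))/x(0) per specimen, region and
parameter; the baseline point is exactly 0, absent values propagate as
absent (never as zero), and no smoothing or interpolation is applied.
Endpoint tables report (first, last, difference %) with volumes printed to
2 decimals, attenuations to 3 and differences to 2; absent cells print as
"-". Regenerating a difference from its own printed first/last cells
reproduces it within the printed-precision propagation bound
100·½ulp·(1/f + l/f²); for values in the tens printed to 2 decimals that
bound is ≈0.05 percentage points, while small-magnitude rows (volumes
below ~1 mm³) are intrinsically less self-consistent.

Single-specimen series admit no hypothesis testing. As an informal error
band, `experimental_spread` reports the largest absolute excursion of the
control (chemically inert fixative) curves; drifts inside that band are
not interpreted.

## The phantom

The synthetic long bone is held as **continuous geometry** and rasterized
on demand:

* an outer radius profile R(z): wide EM ends (56 voxels by default),
  a diaphysis at 0.70 of that, cosine tapers of 0.18 of the length, and
  quarter-ellipse rounded tips over 0.06 of the length;
* a marrow cavity at R(z) − t (cortical thickness t = 8 voxels) that ramps
  closed before the tip dome begins, leaving solid epiphyseal ends the way
  subchondral plates cap real bones;
* trabecular rods: random segments (radius 1.6 voxels, half-length 8–24)
  seeded in the EM endosteal space until they fill 17 % of the allowed
  space — matching the endosteal fill implied by real gerbil-scale data
  (Tb.BV/(TV−Ct.BV) ≈ 0.17 in a proximal EM zone) — plus ~1 % of the total
  trabecular volume as short rods in the diaphysis, to exercise the
  trabecular-exclusion rule. Rods keep a 2.5-voxel standoff from the
  endocortical wall and are absent where the cavity radius is under 16
  voxels, so the lattice and the shell stay resolvable by the opening; in
  real bone trabeculae merge into the cortex, and that merge zone is
  exactly what opening-based separation cannot attribute.

Voxels take the class attenuations exactly (defaults: cortical 1.288,
trabecular 0.86, marrow 0.20, background 0 mm⁻¹, as for bone at 17.5 keV),
then optional additive Gaussian noise (default σ = 0.05 mm⁻¹, a bone–soft
contrast SNR of ≈22). Generation is deterministic per seed.

**Fixation dynamics.** A `FixationModel` prescribes end-of-experiment
percent changes (volume, μ.Ct, μ.Tb) reached along
Δ(t) = Δ_max·(1−e^(−t/τ))/(1−e^(−T/τ)), τ = 500 days, T = 1565 days — a
monotone saturating course with a single shape parameter. The
formalin-like preset uses +8.6 % volume, −5.3 % μ.Ct, −2.9 % μ.Tb (the
strongest regional changes reported for long-term formalin storage); the
ethanol-like preset is the identity. To evolve a phantom to day t the
*geometry* is scaled uniformly about the grid centre by s = (1+ΔV/100)^⅓
and re-voxelized — every compartment's continuum volume scales by exactly
s³, and each day's voxelization error is independent, as for consecutive
scans of a swelling specimen. (Nearest-neighbour resampling of the label
map was rejected: it inflates volumes by a half-voxel boundary band,
~2 points on an 8.6 % change at these sizes.) Attenuations are scaled per
class; noise is re-drawn per day from a day-derived seed.

`simulate_series` chains these into a scan series with independent per-day
noise. Ground truth (label map, region cuts, label-level morphometry) is
available at every day.

## What the phantom does and does not establish

Passing the recovery tests shows the pipeline's arithmetic, segmentation
and separation logic are unbiased at realistic geometry, contrast and
noise: across seeds the full chain recovers programmed ΔTV, ΔCt.BV and
Δμ.Ct within a few tenths of a percentage point, compartment Dice against
ground truth is ≥0.95 (cortical ≈0.99, trabecular ≈0.96–0.97), and inert
series stay within ±0.2 points. The phantom does **not** emulate
phase-contrast fringes, beam hardening, reconstruction filters, partial
volume at real (non-binary) interfaces, plate-like trabeculae, or
registration error between scans — on real data those effects add to the
error budget, and the common-threshold requirement becomes *more*
important, not less.

## Numerical choices and problem sizes

* Otsu threshold: bin-edge result, lower tie-break, inclusive application.
* Component filtering and labeling: 26-connectivity everywhere.
* Even-count medians: the midpoint average (numpy convention).
* Degenerate inputs: constant histograms raise; out-of-range thresholds
  warn and return trivial masks; an opening that erases the whole mask
  raises a parameterization error with a diagnostic.
* Default test/acceptance phantoms are 172×124×124 voxels (length 160,
  radius 56) with 5 seeds and three time points; compact variants
  (108×88×88) back the unit tests. These sizes put ≥10⁵ voxels in every
  compartment, enough that voxelization jitter on programmed changes is
  well under the ±1-point recovery tolerance.

## Known limitations

* Opening-based separation misattributes the trabecular–cortical merge
  zone (here: the wall standoff makes it visible as a ~3 % trabecular Dice
  deficit); methods based on periosteal/endosteal surface tracking would be
  needed for thin-shell metaphyses with steep flare.
* The area-profile delineation is a documented stand-in for
  anatomically-defined EM-zone boundaries; its cuts land within the flare
  transition zones but are not anatomically exact. Fixed fractions exist
  for studies that need frozen cuts.
* The exclusion rule reports absent trabecular fields; downstream
  statistics must treat absent as missing, not zero.
* TV of the "whole sample" is the union of the three regions — articular
  structures beyond the envelope's axial extent are not modeled.
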