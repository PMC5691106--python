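# Methods

This note documents the measurement model, the numerical choices, the
synthetic-data generator, and the limits of what the test suite shows.

## SUV model

Stored scanner values are mapped to body-weight SUV (g/ml) with

    SUV = SV · RS · W / ((RTD · DF) · e^(−ln2 · Et / HF))

Weight is carried in grams and dose in Bq so the ratio is dimensionally
a tissue concentration normalized by injected dose per body mass. `Et`
is the injection-to-acquisition elapsed time *per slice* when slice
timestamps exist (DICOM), otherwise a scan-level time applied uniformly.
`DF` defaults to 1; exports that pre-apply decay correction must pass
their decay factor explicitly, and avoiding double correction is the
caller's responsibility — the package cannot detect it. The formula is
strictly increasing in `Et`, which is what makes a ~60 min and a ~3 h
acquisition of the same patient comparable on one scale.

## Segmentation

The VOI is the set of voxels inside a user box with SUV ≥ f · max(SUV in
box), f = 0.40 by default. Choices worth stating:

* The comparison is **inclusive** (≥) at the boundary.
* The SUVmax reference is the maximum **inside the box**, not the whole
  image: the box is the manual localization step.
* The two timepoints are segmented **independently**, each against its
  own SUVmax; no inter-timepoint registration is attempted.
* Connectivity is the 26-neighborhood everywhere (components, necrosis
  flood fill), matching the 13-direction texture analysis.
* Enclosed sub-threshold cavities (touching no box face) are counted as
  necrosis and *left out* of the VOI — there is deliberately no hole
  filling. Cold regions open to a box face are background.
* With several components, the one containing the hottest voxel is kept;
  ties go to the larger component, then to the lowest linear voxel index,
  so the result is deterministic. A flag disables the selection.

## Metrics

SUVpeak is the maximum over 3×3×3-voxel cubes centered on VOI voxels of
the cube mean; by default the cube averages every image voxel it covers
(voxels outside the image are dropped from the mean), because a peak
that ignores the physical neighborhood underestimates spill-in; a
`masked_only` switch restricts the mean to VOI voxels. MTV is voxel
count × voxel volume in cm³ (an empty VOI is an error, not 0); TLG is
exactly SUVmean × MTV. Note mean ≤ max and peak ≤ max always hold, but
mean ≤ peak does not in general.

## Texture features

Gray levels: equal-width binning of the masked SUVs into N = 16 classes
between the VOI minimum and maximum (per-lesion relative binning; fixed
bounds are available for cross-image comparisons, and a constant VOI
maps to level 1 by convention). Level = min(N, ⌊N(s−min)/(max−min)⌋+1).

Co-occurrence matrix: ordered pairs of 26-adjacent masked voxels
accumulated into a single N×N matrix (symmetric by construction) and
normalized to probabilities; pairs reaching outside the mask are
ignored. Entropy uses the natural logarithm with 0·ln 0 ≡ 0.

Run-length matrix: maximal runs of equal-level masked voxels along each
of the 13 unsigned directions, accumulated into one N×M matrix (M =
longest observed run). Runs break at the mask boundary — no bridging
across excluded voxels — so Σᵢⱼ RLM(i,j)·j = 13·|mask| is an exact
conservation law, checked on every build. RPC's denominator is that
same voxel-direction count. The builder counts runs with a shifted-AND
recurrence (a handful of vectorized passes per direction); tests verify
exact agreement with a line-scan/groupby enumerator.

Anisotropic voxels: the 13 directions are treated equally in CM/RLM
despite unequal physical lengths (no distance weighting); the energies
*do* use physical spacing.

Energies: per-voxel SUV gradient with central differences in mm, falling
back to a one-sided difference when one axis neighbor leaves the mask
and 0 for the axis when both do; integrals are voxel sums times voxel
volume (mm³). SE = √(Σ|∇u|²dV)/√(Σu²dV) is intensive (the volume element
cancels); TE = √(Σ|∇u|²dV)/SUVmax is extensive and grows with the
domain. The TE normalization is the VOI SUVmax. Both are invariant
under rescaling u → c·u.

## Cohort statistics

Test selection is made explicit: Shapiro–Wilk on the paired differences
at α = 0.05 decides paired *t* (normal) vs Wilcoxon signed-rank
(otherwise; constant nonzero differences also go to Wilcoxon since their
normality is undefined, and all-zero differences are a degenerate-test
error). The Wilcoxon Z is computed from the positive-rank sum of
d = PET1 − PET2 with the tie-corrected normal approximation, so a
negative statistic always means the PET-1 value was lower — the library
convention is overridden deliberately. Multiplicity correction (Holm or
Bonferroni) is available but **off by default**. Spearman correlations
use midranks; |r| > 0.75 is flagged strong; MTV stratification puts the
boundary value 10 cm³ in the low group. Degenerate correlations
(constant input) return NaN with a warning rather than raising.

## Synthetic phantom generator

Each patient is an ellipsoidal lesion (axes ≥ 20 mm) centered in a
128×128×48 grid of 5.47×5.47×3.27 mm voxels, on background uptake 1
SUV. The lesion profile is p(r) = max(0, 1−r²) in normalized ellipsoidal
radius, scaled to a base uptake (default 9 SUV). Heterogeneity is a
Gaussian random field — white noise smoothed to a correlation length
(default 15 mm), unit-normalized, times an amplitude (default 0.3) —
*shared between the two timepoints*, because texture is a property of
the lesion, while acquisition noise (default SD 0.8 before smoothing) is
drawn independently per timepoint. A Gaussian point-spread smoothing
(default 7 mm FWHM) mimics reconstructed PET resolution; it reduces the
apparent noise SD roughly fourfold. An optional necrotic core (radius in
mm) is set to background uptake at both timepoints. Noise and smoothing
are applied in a generous neighborhood of the lesion; the far background
stays at its nominal value, which no analysis box reaches, keeping
generation cost independent of grid size.

Delayed acquisition: uptake gain 1.18 and profile sharpening exponent
1.12. The sharpening steepens the radial falloff so a *fixed-fraction*
threshold captures a smaller volume even as absolute uptake rises. The
exponent was calibrated jointly with the point-spread smoothing (which
partly blunts it): the defaults land near +15% SUVmax and −10% MTV,
with the MTV change negative for every tested seed. These are
interpretable knobs for generating test conditions, not estimates of
tumor kinetics.

The default cohort sampler draws lesion diameters uniformly on 24–56 mm
(mild anisotropy), base uptake 6–14 SUV, texture amplitude 0.15–0.35,
per-patient gain 1.10–1.26 and sharpening 1.06–1.18, a necrotic core in
20% of patients, and an inter-scan delay of 112–138 min — sizes chosen
so the 40%-threshold volumes straddle the 10 cm³ stratification cutoff.
All randomness flows through one seeded generator; identical spec and
seed reproduce volumes bit for bit.

### What the phantoms do and do not emulate

They emulate the acquisition geometry, lesion scale, fixed-fraction
segmentation behavior, the delayed-acquisition directions (SUV up,
threshold MTV down), volume-driven texture associations, and a
PET-like smoothness. They do **not** emulate scanner physics (Poisson
sinogram noise, reconstruction artifacts, PSF anisotropy beyond a
Gaussian), respiratory motion, anatomical background, or clinical
texture magnitudes: in particular the phantom texture is finer-grained
relative to its dynamic range than clinical breast lesions, so
run-length features sit in the short-run regime (RPC ≈ 0.9, mean run
length ≈ 1.1). Passing tests therefore validate directions, invariants
and exact combinatorics — not the clinical magnitudes of texture values.

### Simulation sizes used in validation

The effect-direction study uses 100 cohorts of n = 56 patients at the
default geometry; the type-I study uses 1000 cohorts of n = 20 on a
64×64×32 field of view (cropping empty background changes no feature,
since all analysis happens inside the lesion box). Both sizes are the
package's own validation choices and are stated in the tests.

## Known limitations and degenerate cases

* The heterogeneity dial (texture amplitude ladder → monotone ENT, CON,
  DIS, SE up; HOM, UNI down) holds for the generator's ensemble mean,
  not for every single realization: one texture draw can locally cancel
  the profile gradient, and per-lesion relative binning plus the moving
  40% threshold add confounds. The test averages over realizations with
  a fixed VOI and fixed gray-scale bounds.
* A constant VOI has zero CM heterogeneity by definition (ENT = 0,
  HOM = UNI = 1) but its runs are whole lines, so SRE/LRE/RPC equal 1
  only for a single-voxel VOI.
* A VOI with no adjacent in-mask pair has no co-occurrence texture and
  raises rather than returning arbitrary values.
* Type-I error of the test-selection procedure (Shapiro then t/Wilcoxon)
  is close to nominal but not exact at small n; measured rates over
  1000 null cohorts of n = 20 fall in 0.03–0.07 per variable.
* No partial-volume correction, no scatter/attenuation modeling, no
  inter-observer box variability.
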