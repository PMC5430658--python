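# Methods

This note documents the models, numerical choices and known limitations
of the package.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Phantom model

Red blood cells are modelled as rotationally symmetric discocytes with
an even-polynomial thickness profile under a square-root envelope,

    T(ρ) = sqrt(1 − (ρ/R)²) · (c0 + c2 (ρ/R)² + c4 (ρ/R)⁴),

with all coefficients in μm.  The default coefficients (R = 3.91,
c0 = 0.81, c2 = 7.83, c4 = −4.39 μm) give the classic biconcave shape
(≈94 fL, 2.6 μm rim, 0.8 μm dimple); per-cell target volumes are reached
by isotropic rescaling, which preserves sphericity.  The degenerate case
c2 = c4 = 0, c0 = 2R is an exact sphere and anchors the closed-form
volume/surface/sphericity checks.  The choice c2 = c4 = 0 aside, volume
has the closed form V = 2πR²(c0/3 + 2c2/15 + 8c4/105); surface area is
integrated by adaptive quadrature after the substitution ρ = R sin t,
which removes the rim singularity of T′.

The cytoplasm is treated as a homogeneous haemoglobin solution:
n = n_m + α·[Hb] with refraction increment α = 0.18 mL/g and medium
index n_m = 1.337 (phosphate-buffered saline at 532 nm).  Voxelisation
uses exact fractional fill along z (overlap of each voxel slab with the
cell interval), which keeps voxel-level volume integrals unbiased.

Membrane dynamics are synthesized as the static thickness profile plus a
sum of smooth random spatial modes (Gaussian-filtered white noise,
default correlation length 0.7 μm, 24 modes) with stationary
unit-variance AR(1) temporal amplitudes (Ornstein–Uhlenbeck; correlation
time 0 gives i.i.d. frames for analytic tests).  Mode amplitudes are
scaled once so the *ensemble* per-pixel SD averages to the prescribed
σ_h over the projected support, making the realized spatially averaged
temporal SD converge to the target as frames grow.  Defaults follow the
fluctuation-imaging acquisition: 125 Hz for 2.4 s (300 frames).

The default cohort presets (in `erythrotomo/data/cohort_defaults.yaml`)
are the published group statistics: healthy V ~ N(90.5, 11.4²) fL,
[Hb] ~ N(33.4, 2.8²) g/dL, σ_h ~ N(55.1, 6.9²) nm; diabetic
N(90.2, 10.9²), N(34.6, 2.7²), N(46.6, 4.5²).  A fraction (0.6) of each
SD is attributed to between-subject variation so that subject means
scatter realistically while the per-cell marginals keep the stated mean
and SD.  Subject HbA1c levels are representative clinical values in
increasing order (only the ordering is published).

## Forward optics

Acquisition constants default to the instrument values: λ = 532 nm,
illumination NA 0.9 (circular scan at 0.95× that cone, azimuthally
uniform; a spiral option exists), detection NA 1.42, 300 angles for the
demo profile and 60 for desk-scale tests.  Grids default to 128×128 at
100 nm sample-plane sampling (desk scale) instead of the full 528×512
camera frame; the 64³ demo profile uses 150 nm voxels so a ~8 μm cell
fits its 9.6 μm field of view.

Three field models are available: straight-ray phase projection (the
default; RBC phase delays are ≲1.5 rad, well inside the weak-scattering
regime), and first-Born / first-Rytov synthesis via the Fourier
diffraction theorem.  The Rytov option exists so that reconstruction can
be exercised in its exact validity regime; the pipeline uses it.

Off-axis interferograms are formed against a unit plane reference wave
on an upsampled grid (FFT zero-padding, default 4×, ≈26 nm effective
pixels — the oversampling a real off-axis camera provides).  At 100 nm
sampling no carrier above the na_det/λ band limit fits under Nyquist, so
the upsampling is what makes the off-axis geometry self-consistent.  The
carrier defaults to a diagonal frequency ≥3× the band limit, snapped to
the spectral grid; synthesis → retrieval is then exact (float-level) for
band-limited noise-free fields.  Additive Gaussian and Poisson noise are
optional and seeded.

## Field retrieval

Standard Fourier demodulation: locate the +1-order sideband (known
carrier, or brightest non-DC half-plane peak), crop a disk, recentre,
inverse transform onto the source grid.  The default crop radius is half
the carrier distance, shrunk to |f_c| − 2×band-limit when the half
radius would overlap the DC autocorrelation disk.  Phase unwrapping is
reliability-sorted (quality-guided); background flattening fits and
subtracts a plane over a border region (common-path systems leave only
low-order residuals).

## Reconstruction and the missing cone

With scattering potential f(r) = k0²(n² − n_m²) and Rytov phase
ψ = ln(U/U_in), the theorem used is

    f̂(k⊥ − k_in⊥, kz − k_in,z) = (2 kz / i) · FT₂[U_in ψ](k⊥),
    kz = sqrt(k_m² − |k⊥|²),

assembled by nearest-voxel gridding with coverage-count averaging.  Each
sample's Hermitian partner is deposited at −K (the potential is real),
which symmetrises coverage and keeps the inverse transform real to
float precision.

Missing-cone filling is by alternating projections: clamp Δn < 0 to zero
in real space (the cytoplasm is denser than the medium), restore the
measured samples in Fourier space, repeat.  Class defaults are the plain
scheme (100 iterations, relaxation 1.0, early stop at residual change
< 1e−6), whose data-consistency residual is provably non-increasing.
The pipeline profile uses the over-relaxed update f ← f + β(P(f) − f)
with β = 1.85 and 300 iterations, chosen from a convergence study on
ground-truthed phantoms (β < 2 preserves convergence; ≈3× faster).  An
optional support constraint accepts a user mask.

**Known limitation.**  The non-negativity prior does not make the
missing-cone problem unique: for flat-faced cells a solution with an
axial halo and a reduced interior is itself non-negative and
data-consistent, so the iteration converges to it rather than to the
truth.  Consequences, measured on phantoms by the test suite: spherical
cells at 128³/60 angles recover V, S, [Hb] to within ~4% and SI to
within 0.01; biconcave cells carry systematic biases of roughly +10…15%
in V (the sub-threshold halo above the n > 1.35 isosurface) and −10…15%
in [Hb] (interior dilution), with σ_h inflated by the same relative
amount through the height equation.  These are physics of
limited-angle tomography, not implementation artifacts; the tests
quantify them on the discocyte and demonstrate accuracy on the sphere.

## Measurement

Segmentation thresholds the tomogram at n > 1.35 (the only published
isosurface level; configurable), keeps the largest connected component
and fills holes.  V and S both come from one marching-cubes isosurface
at the segmentation threshold (sub-voxel interpolation); ten Taubin λ|μ
passes denoise the voxel-scale faceting of meshes from reconstructed
(as opposed to analytic) tomograms, which otherwise inflates S by
several percent.  A voxel-count volume is also reported for QC.  Note
that 1.35 sits at ~22% of the cytoplasmic contrast, so even a perfect
reconstruction voxelised with fractional fill measures a fraction of a
voxel outside the half-fill boundary.

Temporal SDs use the population convention (divisor N), matching the
plain temporal average of squared deviations; the sample convention is a
flag.  The projected cell area for the σ_h average is the largest
connected component of pixels whose time-mean phase exceeds the
background mean by 3× the background SD (with a 0.05 rad floor for
noise-free data).  ⟨Δn⟩ for the height equation is taken from the same
cell's reconstructed tomogram over its segmentation mask.

## Statistics

Wilcoxon rank-sum switches to exact enumeration when both groups have
≤10 values and no ties (midranks + normal approximation with continuity
correction otherwise); Student's t is the classic pooled-variance form;
OLS slope CIs come from the t distribution with n−2 df; ANCOVA tests the
group×covariate interaction by an F test of nested models.  The twelve
published per-subject σ_h means ship with the package
(`erythrotomo/data/fluctuation_subject_means.csv`) as the in-study
reference table.  The published Pearson correlation between σ_h and
HbA1c cannot be recomputed exactly because subject HbA1c values are
published only as an ordering; synthetic cohorts demonstrate it
qualitatively.

## What the synthetic data does not capture

No optical aberrations, polarization, speckle or camera noise physics
(noise is generic Gaussian/Poisson); no echinocyte/stomatocyte shapes;
no ATP-driven active fluctuation spectra (the temporal model is a
generic stationary Gaussian process); homogeneous cytoplasm (no
refractive-index texture).  Passing tests therefore validate the
analysis chain and its numerics, not instrument- or biology-specific
effects on real data.

## Problem sizes

Unit tests run at 48³–96³ grids with 8–60 angles; the end-to-end
recovery check runs one cell at 128³ with 60 angles (~2 min); the demo
cohort profile is 64³, 60 angles, 120 fluctuation frames, ~7 s per cell
on one CPU.
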