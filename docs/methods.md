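# Methods

`qspect` rebuilds a multi-site quantitative ¹⁷⁷Lu SPECT/CT phantom exercise
as a fully synthetic pipeline.  Seven hospital protocols — differing in
energy windows, orbit, OSEM settings, scatter correction, resolution
recovery, segmentation and calibration geometry — are run against one
digital phantom, and their reported volumes and activities are compared to
the phantom's exact ground truth.  This note records the models, the
defaults and the choices made where the design was open.

## Digital phantom

The comparison source is a dual-compartment concentric sphere: a hot inner
sphere (nominal diameter 36 mm) inside a warm outer shell (nominal
thickness 11 mm), filled at a 15:1 concentration ratio.  Compartment radii
are derived from the measured volumes of the six physical sources
(26.0–27.2 ml inner, 79.3–81.6 ml shell), not from the nominal diameter:
r_in = (3V_in/4π)^⅓ and (4π/3)(r_out³ − r_in³) = V_out.  Plastic walls are
modelled as zero thickness.  The default fill is 2.0 MBq/ml in the inner
compartment (≈57 MBq total), a typical calibration-solution level that
yields realistic projection count rates (~4 × 10⁵ photopeak counts per
scan at the default sensitivity).

The body is an elliptical cylinder (internal axes 305 × 221 mm, height
186 mm) of water, with two lung inserts (0.3 g/ml, 900 + 1100 ml,
elliptical cylinders spanning 85% of the body height) and a spine insert
(38 mm × 152 mm, 1.33 g/ml — a dipotassium-phosphate bone equivalent).
Insert positions are not critical (the source never overlaps them) and are
fixed anterior-lateral (lungs) and posterior (spine); the builder rejects
any source placement that intersects an insert or leaves the body.  The
source sits at the phantom centre by default (the physical set-up located
it reproducibly but its exact position is configurable here).  Body
contour rings and the couch are not voxelised.

Voxelisation is voxel-centre binary assignment.  **Ground truth is the
phantom as voxelised**: truth volumes are mask volumes on the simulation
grid and truth activities are voxel sums, so protocol percent differences
measure protocol error, not discretisation error.  At 0.5 mm the inner
compartment voxelises to within 0.1% of its specified volume; at the
4.8-mm simulation scale the binary volumes deviate by up to ~12% from the
analytic sphere volumes, which is exactly why the truth convention matters.

Attenuation maps are μ = ρ × (μ/ρ)_water with (μ/ρ) = 0.165 cm²/g at
113 keV and 0.136 cm²/g at 208 keV (configurable); the water coefficient
scaled by density is adequate for water, lung and the phosphate solution
at these energies.

## Camera simulator

Parallel-beam geometry with a medium-energy-collimator-like response:
FWHM(d) = √(4.0² + (0.05·d)²) mm at distance d from the collimator face
(≈9 mm at 10 cm), separately configurable per energy window (the 113-keV
window uses a 1.1× wider response).  System sensitivity defaults to
10 cps/MBq at 208 keV and 6 cps/MBq at 113 keV, scaling with the emission
probabilities (10% vs 6%); absolute sensitivities are free parameters of
the simulation since all quantification is relative to a simulated
calibration.  Orbits are contoured (body-ellipse support function plus a
20-mm clearance) or circular; angles start anterior and step clockwise.

The projector is one exact linear operator per view: a sparse
mass-preserving in-plane rotation (each voxel splats onto the rotated
raster with bilinear weights summing to one), a diagonal of per-voxel
attenuation survival factors (half-voxel convention at the emission
voxel), and a depth-dependent Gaussian blur applied per depth slab in
Fourier space (spectral transfer exp(−2π²σ²f²) on a padded raster: DC gain
exactly one, so blur conserves counts; symmetric, so it is self-adjoint).
Back projection is the exact transpose of this chain, which makes MLEM
provably well behaved on this model.  Internal arithmetic is single
precision; its ~10⁻⁶-relative noise is handled explicitly in the
reconstruction (below).

Scatter is a fraction-and-kernel model, not Monte Carlo: each window
receives a configurable fraction of the unattenuated projection convolved
with a wide (40-mm FWHM) Gaussian.  Photopeak scatter fractions default to
0.15 (208 keV) and 0.30 (113 keV); adjacent scatter windows receive a flat
per-keV density anchored at the photopeak fraction, which makes the
triple-energy-window (TEW) estimator unbiased in expectation under this
model.  Real spectra are not flat, so real TEW is biased — a documented
limitation, as is the absence of spectral overlap between the 214 ± 5%
window and the 208 ± 10% photopeak.  The pre-noise primary and scatter
components are stored per window so that an "ideal" scatter correction is
available; counts are Poisson samples under an explicit seed.

## Reconstruction

OSEM with interleaved angular subsets, uniform positive start, and the
scatter estimate as an additive forward-model term; subsets = 1 is exact
MLEM.  The matched system model (same rotation, attenuation and PSF
operators as the simulator) is the deliberate inverse crime: it is the
best case against which model error is measured by switching the PSF off
in the reconstruction only.  Numerical safeguards, all scaled to the data:
projection pixels below 10⁻⁶ of the data maximum are treated as carrying
no information (they are single-precision noise on true zeros); the same
floor regularises the forward-model denominator; and the per-voxel
multiplicative update factor is clamped to [10⁻², 10²], which prevents the
limit-cycle runaway that small angular subsets otherwise exhibit in
low-count regions.  With these floors the MLEM fixed point and the
monotone-likelihood property hold to ~10⁻⁴ relative.

Dual-photopeak protocols reconstruct each peak with its own attenuation
map and sum the volumes afterwards.  TEW estimates are smoothed in-plane
(2 pixels) before use; one protocol pre-subtracts scatter from the
projections instead of modelling it additively, as its site did.  The
"Monte Carlo" and "ESSE" scatter corrections of three sites are emulated
by the ideal mode (the simulator's true scatter term) — their site-specific
codes cannot be replicated at desk scale and ideal is their best-case
surrogate.  Reconstructed voxel values are count rates (cps/voxel): the
model excludes the system sensitivity, which only the calibration step
knows, exactly as on a real camera.

Noise-free OSEM converges slowly at the inner/outer boundary of the shell
source (the classic slow edge mode of EM with a PSF in the model): the
recovered inner:outer concentration ratio climbs from ~12.3 at 1000
effective updates to ~13.9 at 6000 on the 64³ grid.  End-to-end checks
therefore run thousands of updates with 20 subsets, which noise-free data
tolerates.

## Segmentation

Four families, as used by the sites:

* **CT-geometry spheres** centred on the known source position, at the
  physical diameter plus an optional radial margin.  The "+10 mm in each
  spatial direction" rule is read as a radial margin — the only reading
  consistent with the companion statement that the outermost 1 mm of the
  29-mm physical shell stays outside the 28-mm inner VOI, and that the
  shell VOI is 11 mm thick.  Sites using CT spheres report the physical
  (margin-free) volume while quantifying over the expanded VOI.
* **Relative iso-contours** (35% inner / 10% outer of the in-region
  maximum).  The thresholds are calibrated, as the site did, by sweeping
  the fraction on a calibration image of a shell source with known
  volumes and freezing the best-matching values; the calibration uses the
  both-compartments-filled image (the physical site also acquired an
  outer-only image, which the desk-scale search does not need).
* **Otsu auto-contouring** on the 256-bin in-region histogram (own
  implementation of the between-class-variance maximiser, so the
  convention matches the brute-force definition bin for bin).  The search
  region is a bounding box of twice the source extent.
* **Manual outlining**, emulated by the truth mask optionally dilated or
  eroded by one voxel: operator variability is bracketed, not replicated.

Intensity-based masks keep their largest 6-connected component.  Shell
VOIs are set differences of outer-surface and inner VOIs.

## Calibration and quantification

The cps/MBq factor is (VOI count rate)/(true activity) in each site's
geometry: a large homogeneous volume (130-ml bottle or 6.9-l cylinder), a
16-ml sphere at one or three positions (air/water/off-centre — the
off-centre displacement is 11 cm here so the sphere stays inside the
elliptical body), a shell source of the comparison design imaged at three
depths with the factor chosen at the most similar depth (depth = Euclidean
distance of the source centre to the nearest body surface), or planar
petri-dish images (five ~40-MBq dishes at 10 cm, counts in a 10-cm ROI
minus background).  The two-VOI variant averages factors from one-voxel
eroded and dilated VOIs.  Calibration acquisitions reuse the protocol's
own acquisition settings.

The recovery curve is RC(V) = 1 − exp(−(V/v₀)^p) — a monotone, bounded
two-parameter form chosen by this package (the sites' functional form was
not specified) — least-squares fitted to sphere measurements and applied
as estimate/RC(V), with an extrapolation guard at RC < 0.05.  The
partial-volume threshold utility reports the smallest calibrated sphere
volume with RC ≥ 0.95.

Uncertainty budgets follow each site's stated recipe: Poisson counting
terms (on total attributed counts, approximated as VOI cps × total
acquisition time), calibration-factor spread (sd over positions, VOIs or
dishes), a 2% activity-certificate term where a dispensed activity enters,
and the recovery-curve residual spread — combined in quadrature.  One
protocol reports no uncertainty, faithfully.  No protocol includes a
segmentation-uncertainty term (none of the sites did); the quadrature
accepts extra terms for exploring one.  No decay correction is applied:
all activities refer to one time point, and ¹⁷⁷Lu decay over a session is
below 1%.

## Inter-comparison report

Percent difference is 100 × (measured − truth)/truth; the spread is
max − min of the signed differences, the bias their arithmetic mean, and
the within-threshold table counts |diff| ≤ {5, 10, 20, 50, 75, 100}% as
"k/n (p%)".  A coverage flag records whether each protocol's ±1σ range
includes the truth.  Protocols are seeded independently (one scan per
site, as in reality); the inner-only site omits the outer compartment and
the Otsu site derives its outer activity by subtracting the inner estimate
from a whole-source VOI.

## Problem sizes

Simulation and reconstruction default to a 64-voxel square in-plane grid
at 4.8 mm — half the published 128 matrix at the same pixel size, spanning
the 305-mm body exactly — with 64 axial voxels and 60 angles for
quantitative end-to-end checks; unit and property tests use 48 or fewer
in-plane voxels at 6.5 mm and 24 angles.  These scales keep a full
protocol run to tens of seconds and the long noise-free convergence runs
to minutes while resolving every geometric feature larger than one voxel
(the 11-mm shell is ~2.3 voxels at simulation scale).

## What the synthetic data does and does not show

The generator reproduces the structure of the physical exercise —
attenuation, distance-dependent blur, broad scatter, Poisson statistics,
per-site protocol differences — but not detector energy resolution, septal
penetration, dead time, ¹⁷⁷ᵐLu impurities, CT-SPECT misregistration or
real operator variability.  Passing tests therefore demonstrate that the
protocol logic, the correction chain and the comparison arithmetic behave
as described, and that the qualitative orderings the physical exercise
observed (threshold segmentation strays further than CT geometry; the
total-source error is smaller than the worst compartment; a VOI larger
than the object reports more activity) emerge from the physics model.
They do not certify the absolute accuracy of any clinical system, and the
per-site numeric results of the physical exercise are not reproduced here
— those depended on real cameras.
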