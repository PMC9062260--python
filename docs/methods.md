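# Methods

`petchain` models the complete chain from activity and attenuation
phantoms to quantitative PET images on a Discovery-MI-like four-ring
scanner: Monte Carlo acquisition simulation, sinogram formation, the
standard correction chain, iterative reconstruction, and NEMA NU 2-style
image-quality evaluation.  This note records the models, the parameters
that matter, and the design decisions taken where the design was open.

## Scanner model

The detector is a ring of 34 flat panels (rsectors) at a face-to-face
distance of 744.2 mm.  Each panel carries 4 axial units of 4 transaxial
blocks, each block a 4 (transaxial) x 9 (axial) LYSO array, 19584
crystals in 36 rings of 544.  The crystal cross-section is
3.95 mm transaxial x 5.3 mm axial x 25 mm deep: this is the only
assignment that fits 16 crystals on a 68.9 mm panel face and yields the
nominal 20 cm axial field of view (36 x 5.3 mm = 190.8 mm).  Crystals
are indexed by the Gate-style volume-ID arithmetic (integer division and
modulo over the rsector/module/submodule/crystal hierarchy); the
flattened (ring, in-ring) index pair is bijective with the ID tuple and
is verified exhaustively in the tests.  A 2 mm plastic bore liner sits
at 350 mm radius.

Coordinates are right-handed, z along the bore, rsector 0 centred at +y,
sector number increasing clockwise viewed from the front.

## Sinogram addressing

Bins are addressed geometrically from the crystal front-face centres:
the radial coordinate is the LOR's signed closest approach to the axis,
binned at half the crystal pitch (1.975 mm, 355 bins covering the
+-350 mm transaxial FOV); the azimuthal coordinate is the LOR direction
modulo pi in 272 views; axially either a full span-1 Michelogram (1296
ring pairs) or single-slice rebinning (SSRB, 71 planes at half the ring
pitch) is used.  Crystal pairs are ordered canonically before binning so
the map is exactly swap-symmetric, and a minimum transaxial sector
difference of 4 plus the 350 mm radial cut define acceptance.  The
public organisation of the clinical scanner's sinograms is not
available, so this layout is the package's own; it is recorded in every
sinogram file header.

The end-to-end pipelines bin into the SSRB layout with the azimuthal
views mashed pairwise (136 views) and the ring difference limited to 9,
which keeps the axial blur at the sphere radius below ~3 mm while
reducing the reconstruction problem to desk scale.  The full span-1
path is exercised by the unit tests.

## Phantoms

Three families: a uniform water cylinder (calibration), the NEMA IQ body
phantom (elliptical body 300 x 230 mm, interior length 194 mm, six
spheres of 37/28/22/17/13/10 mm inner diameter on a 114.4 mm circle, a
50 mm low-density cylindrical lung insert), and the Data Spectrum
cylinder (220 mm diameter, spheres 15.43/12.43/9.89/6.23/4.95/3.95 mm).
Bodies carry a 3 mm acrylic wall and rest on an 8 mm carbon-fibre couch
slab (effective mu = 0.05 cm^-1); both are part of the physical
acquisitions being emulated and contribute measurably to the scatter
fraction.  The lung insert defaults to mu = 0.004 cm^-1 (low-density
polystyrene foam).

Attenuation maps are rasterised on a 2 mm grid by centre sampling.
Decay positions are sampled analytically from the solid definitions
(exact sphere boundaries); the voxel-grid sampler exists for externally
supplied activity maps but would quantise the 3.95 mm DS sphere.

## Photon transport

Annihilation pairs are emitted back to back and isotropically.
Acollinearity is a 0.5 degree FWHM Gaussian, off in the bare simulator
default and enabled by the pipeline configurations (it contributes
~2 mm FWHM at this ring diameter); positron range is omitted
(sub-millimetre for the modelled isotope).  Transport uses
Woodcock delta-tracking over the mu grid with the Klein-Nishina angular
law for Compton scattering and a small 1/E^3 photoelectric branch; all
phantom materials are Compton dominated, so mu(E) scales every material
with the water energy ratio.  Photons below 250 keV are terminated (they
cannot reach the 425 keV window even through the energy blur).  The bore
liner is handled analytically as a thin shell: single Compton
interaction sampled on the chord, matching its attenuation term in the
correction chain.  Multiple scatter arises naturally from the tracking.

Detection intersects the exiting ray with the panel ring, picks the
crystal whose front face (or, behind an inter-block gap, whose panel
plane) the ray crosses first, and accepts the photon with the LYSO
interaction probability 1 - exp(-mu_LYSO(E) * 25 mm / cos(incidence)).
The full photon energy is deposited at that crystal: with the readout
summing over an rsector this mimics the vendor's Compton-scatter
recovery, at the price of not modelling energy splitting across
rsectors.

## Digitizer

In order: adder (per decay and rsector, deposits summed), energy-winner
readout at the rsector level, Gaussian energy blur (9.63% FWHM at
511 keV, fractional resolution scaling as 1/sqrt(E)), detection
efficiency 0.98, Gaussian temporal blur (268.7 ps FWHM, giving the
380 ps coincidence timing resolution), energy discriminator
(425-650 keV).  The intrinsic crystal radioactivity is a Poisson stream
at 1142 kHz (decimated with the activity), uniform over crystals, with
a simplified single-crystal deposit spectrum: a beta continuum with
596 keV endpoint plus the 307/202/88 keV cascade photons, each absorbed
in the origin crystal with its LYSO capture probability.  Only the rate
is calibrated; the spectrum shape is a documented approximation.
Coincidences are formed in multi-window mode (tau = 2.45 ns, every pair
of goods within the window kept -- takeAllGoods) with the minimum sector
difference applied.  Deadtime and pile-up are deliberately absent.

Decimation scales the activity and the intrinsic-background rate by the
same factor, so trues and scatters scale linearly while randoms scale
quadratically; all reported image-quality figures are either
randoms-corrected or ratios, so this distortion is benign at desk scale.

## Corrections

**Attenuation.**  acf = exp(integral of mu) along each bin's
representative LOR (Siddon exact radiological path on the phantom grid),
times an analytic two-crossing bore-liner term.

**Normalisation.**  Component-based: crystal efficiencies from fan sums
of a central-cylinder calibration acquisition; axial block profile b and
ring-pair geometric factor g (a function of ring difference) by
alternating fits to the ring-pair count matrix; radial profile r and
crystal-interference factor f from the binned data of both calibration
acquisitions -- the central cylinder (analytic chord profile) inside its
+-90 mm footprint and an annulus just outside the transaxial FOV beyond
it, stitched over the overlap and with each acquisition's expectation
normalised to its own count scale.  The calibration sources are
simulated as non-attenuating emitters with the crystal background off,
so they measure pure detector response; the nominal 5 MBq / 2 h
acquisitions are decimated to 2e7 decays each by default.  The bin-level
sensitivity model sums the per-pair component products over every
crystal pair addressing a bin (so pair multiplicity, including panel
gaps, is exact geometry), and its inverse is the bin correction.

**Randoms.**  2 tau S1 S2 / T from the per-crystal singles counts,
summed over the crystal pairs of each bin.

**Scatter.**  Single scatter simulation: emission and attenuation maps
down-sampled to 32 x 32 x 4, scatter points at coarse cells with
mu >= 0.04 cm^-1 (jittered uniformly within the cell), detectors
down-sampled to 68 x 4.  For each point and detector pair both terms
(emitters on either leg) are evaluated with marched ray sums, the
Compton-shifted energy from the LOR geometry, a detector efficiency
equal to the blurred-window acceptance times the LYSO stopping
probability (the largest modelling choice in the scatter chain), the
solid-angle product, and the Klein-Nishina angular probability.  The
bore liner is represented by an analytic ring of scatter points carrying
its volume-weighted mu, since it lies outside the coarse-grid extent.
Coarse bins hold the mean over the detector pairs that address them;
up-sampling is cubic-spline radial and axial, periodic-linear azimuthal.
The estimate is scaled to the measured prompts by a least-squares fit
over the object-free tails (bins whose forward-projected mu support is
below 1e-3), with the intercept forced to zero for isotopes without
prompt gamma emission, and divided by the bin sensitivity so it lives in
measured-counts space.  The procedure iterates with FBP re-estimates of
the emission image (the corrected sinogram is rebinned 4 x 4 x 6 before
filtering because decimated data are sparse per fine bin, and the
emission estimate is masked to the attenuation support, which suppresses
reconstruction noise outside the object that would otherwise bias the
tail fit); after two iterations the estimate is the average of the two.

Multiple scatter and out-of-FOV scatter are not modelled; the tail fit
compensates them only partially, which is why the chain's estimated
scatter fraction sits a few points below the ground-truth scatter
content of the simulation (the original validation of this chain shows
the same behaviour, 9.5 points for the cold-background NEMA set-up).

**Calibration.**  Well-counter calibration from a uniform 9.5 cm x
20 cm cylinder at 4.4 kBq/mL: WCC = known concentration / mean of
centred per-slice ROIs.  CRC, BV and the residual lung error are ratios
and do not depend on it.

## Reconstruction

OS-EM with 4 iterations x 16 subsets (azimuthal angle modulo 16, fixed
order), Joseph bilinear-interpolation ray sampling, attenuation and
normalisation in the system matrix and in the sensitivity image
(forward model yhat = c A x + randoms + scatter with c = 1/(acf eta)),
and a 4 mm transaxial x 4 mm axial Gaussian post-filter.  The default
image grid is 256 x 256 over the 700 mm FOV (2.73 mm pixels) with one
slice per SSRB plane; the original matrix size is not public and 2.7 mm
pixels are needed to evaluate the 10 mm sphere.  A denominator guard of
1e-10 protects empty regions; reconstruction is deterministic.

Two engines share the model: a binned non-TOF engine operating on any
sinogram layout, and a TOF engine operating on the sparse TOF histogram
of the coincidence list (169 ps bins; kernel sigma from the 380 ps
coincidence timing resolution plus the binning width).  The TOF kernel
is a probability along the LOR, so the non-TOF sensitivity image remains
exact; additive randoms+scatter expectations are spread uniformly over
a 500 mm TOF extent.  The clinical reconstructions being reproduced are
TOF reconstructions, and at desk-scale counts the TOF engine is also
what keeps the cold lung insert from filling with the positivity bias
of low-count EM, so the pipelines use it by default; the binned engine
remains the reference implementation for the projector/EM properties
(adjointness, MLEM conservation, noiseless consistency).

An SSRB + ramp-filter FBP (with optional rebinning) seeds the scatter
iteration only.

Pipeline images are divided by (acquisition duration x decimation), so
their units are rate-like and the well-counter calibration transfers
between acquisitions of different length or decimation; raw engine
output scales with total counts.

## Evaluation

NEMA NU 2-style: twelve background ROI positions replicated on the
central slice and at +-1 cm and +-2 cm (60 ROIs), one concentric set per
sphere diameter, placed deterministically with >= 15 mm clearance from
the body wall (checked against a densely sampled boundary) and clear of
spheres and insert; for the elliptical NEMA body the positions sit near
the long axis where a 37 mm ROI fits.  Sphere ROIs are circles of the
inner diameter on the sphere's central slice at the known centre.
SF = S/(T+S); CRC_i = (S_i/B_i - 1)/(SBR - 1); SNR_i = (S_i - B_i)/
sigma_i with sigma over all voxels of the 60 ROIs; BV_i = SD of the 60
ROI means / B_i; residual lung error = mean over the 60 central slices
of a 30 mm central ROI divided by the 37 mm background mean.  Profiles
are trilinear line samples.

## Desk-scale problem sizes

The published figures come from full-statistics runs (2.6e8 prompts for
the hot-background NEMA acquisition).  The default desk runs decimate
activity to a few million prompts (7e-3 for NEMA-B and 1.2e-2 for CYL-B
in the reproduction script), sizes at which the large-sphere CRC
carries ~4 percentage points of statistical noise while a run stays in
the minutes range.  Background variability and SNR scale with total
counts and are not reproducible at desk scale; they are covered by unit
tests of the formulas instead.

At these sizes the largest-sphere contrast recovery and the simulator's
ground-truth scatter fractions land within a few points of the
full-statistics values.  Two figures do not: the residual lung error
(~15% against ~4%) because unmodelled multiple scatter concentrates on
the central LORs crossing the cold insert and low-count EM adds a
positivity bias there, and the smallest-sphere contrast recovery, which
is sensitive to detector-response details (inter-crystal light sharing
is not modelled) and carries several points of ROI noise at desk
counts.  Both are reported as computed.

## Known limitations

- Energy is deposited whole at the first crystal interaction; energy
  splitting across rsectors and detector-side Compton escape are not
  modelled (the rsector-level winner readout absorbs most of the
  clinical effect).
- Block-edge penetration (a ray crossing an inter-panel gap is assigned
  to the first panel plane it crosses) produces a small (~2 mm at 57 mm
  radius) inward bias of reconstructed positions relative to the
  bin-centre model, a parallax-like effect that slightly depresses the
  contrast of the smallest spheres.
- Single-scatter-only estimation leaves a few percent of prompts
  (multiple scatter) under-corrected; the residual inflates the lung
  error by a few points at desk counts.
- The 176Lu deposit spectrum is an approximation; only its rate is
  calibrated.
- Deadtime and pile-up are absent by design, so simulated prompt counts
  exceed measured ones at high activity.
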