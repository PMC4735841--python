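# Methods

`comptel` is a desk-scale digital twin of a three-layer LaBr3 Compton
telescope developed for treatment monitoring in hadron therapy, operated in
the laboratory with a 22Na point source.  This note documents the physics
model, the instrument response, the reconstruction chain, the numerical
choices, and what the synthetic data do and do not establish about the real
device.

## Coordinate and unit conventions

Right-handed coordinates in millimetres; origin at the centre of the
layer-1 entrance face; +z points from the source toward layer 3.  The
source sits on the axis at z = -35 mm.  Energies are keV, times ns, angles
radians.  A single integer seed drives every stage; per-stage generators
are spawned with `numpy.random.SeedSequence` in a fixed order, so stages
are independently reproducible.

## Physics kernel

Compton kinematics use the standard free-electron formula
E' = E0 / (1 + (E0/m_e c^2)(1 - cos theta)) with m_e c^2 fixed at exactly
511.0 keV so that the annihilation line and the kinematic constant
coincide; the inverse relation and the backscatter limit follow from the
same constant.  Scattering angles are drawn from the Klein-Nishina
distribution with Kahn's composition-rejection method (exact, vectorized);
the sampler is validated against the analytic density by chi-square and by
moment matching, and against the Thomson limit at low energy.

Attenuation in LaBr3 (density 5.08 g/cm^3) is a 16-node log-log
interpolated table over 50-2000 keV with separate Compton and
photoelectric columns.  The Compton column is the Klein-Nishina total
cross-section scaled by the compound's electron density (Z/A_eff = 0.4279)
— accurate to a few percent above ~100 keV where electron binding is
negligible.  The photoelectric column is a Z^4.5/E^3 parametrization
anchored at 1.00 cm^2/g at 100 keV for the compound, rolling over to ~1/E^2
above 511 keV; it is a ~10 % photon-fate correction in the band that
matters here.  Rayleigh scattering, pair production, fluorescence escape,
Doppler broadening and electron transport are deliberately omitted: all are
sub-dominant for 0.3-1.8 MeV photons in 5-10 mm LaBr3 slabs.  A scattered
photon falling below the table minimum (50 keV) is absorbed on the spot, so
energy is conserved exactly on every history.

## Instrument model

The default prototype: layer 1 is 27.2 x 26.8 x 5 mm with 6.4 % FWHM
energy resolution at 511 keV; layers 2 and 3 are 32 x 36 mm, 5 and 10 mm
thick, at 7.4 % and 7.2 %.  Inter-layer distances (60 and 65 mm) are
face-to-face gaps by default (`spacing_convention` switches to
centre-to-centre); the source-to-layer-1 distance is 35 mm, so the layer-3
entrance face is 170 mm from the source.  Trigger thresholds are 50 keV
(inclusive, applied to the measured energy) and the coincidence window is
25 ns.

Energy response: Gaussian blur with FWHM(E) = R_511 * 511 * sqrt(E/511),
i.e. relative resolution scaling as 1/sqrt(E) (photostatistics), anchored
at the measured 511 keV values.  Position response: 1 mm FWHM Gaussian
transverse blur clamped to the crystal; the reported z is the layer
mid-plane because the readout provides no depth-of-interaction (DOI)
information.  The residual depth spread, thickness/sqrt(12) = 1.44 mm
(5 mm crystals) and 2.89 mm (10 mm), is therefore part of the measurement
error and — being larger than the transverse blur — dominates the angular
accuracy of reconstructed cones.

## Monte Carlo simulation

Each decay emits a back-to-back 511 keV pair with probability 0.903
(isotropic common axis) and one 1275 keV photon with probability 0.999
(the 1274.5 keV line rounded to the conventional 1275), from a 0.25 mm
disc; decay times form a Poisson process at the source activity
(700 kBq default).  Photons are ray-traced through the three slabs:
exponential free paths with the total attenuation coefficient,
photoelectric absorption with probability mu_pe/mu_tot, otherwise Compton
with a Klein-Nishina angle; gaps are vacuum.  Positron range and 511 keV
acollinearity are ignored (sub-resolution at 0.25 mm source scale);
detector time jitter is not modelled, so interactions carry the decay time
and accidentals arise from decay pile-up inside the 25 ns window.

Primary photons whose direction lies outside the cone subtending all three
crystals from the source cannot interact; emission accounts for them but
only materializes in-cone photons.  This is an exact acceleration (the
backward partner of an annihilation pair can never reach crystals that lie
entirely forward of the source), worth ~15x in throughput.

Digitization merges same-decay deposits within a layer (summed energy,
energy-weighted centroid) before blurring — the detector sums
scintillation light and cannot separate simultaneous hits.  The
coincidence builder clusters the time-sorted stream, opens a window at the
first interaction of a cluster, merges per-layer pile-up, triggers when
all three layers are above threshold, and re-arms after the window closes.
Truth flags record whether more than one decay contributed (accidental),
whether more than one photon or merged signal contributed (pile-up), and
whether a single photon interacted in layers 1, 2, 3 in that causal order
(the assumption the reconstruction makes; roughly half of the selected
triples violate it, which is an irreducible property of a telescope that
cannot time-order interactions).

## Event processing

A triple event is one measured interaction per layer, taken in layer
order.  The second-scatter angle theta2 is measured geometrically from the
three positions; with the deposits e1 and e2 it closes the kinematics:

    E0 = e1 + e2/2 + sqrt(e2^2/4 + e2 * m_e c^2 / (1 - cos theta2))

The third deposit enters only through the 800-1400 keV total-energy
selection, which brackets the 1275 keV line and excludes the 511 keV
population; the estimator is therefore robust against incomplete
absorption in layer 3.  The Compton cone has its apex at the layer-1
interaction, axis pointing from layer 2 back through layer 1, and
half-angle theta1 from E0 and e1.  Events with |cos theta1| > 1 after
blurring are dropped (counts logged), not clamped.

Per-event angular uncertainties are propagated to first order (central
finite differences) from the two energy blurs and all nine coordinates —
transverse sigma 0.42 mm, depth sigma thickness/sqrt(12) — plus the axis
jitter from the layer-1/2 position errors, combined in quadrature.

## Reconstruction

List-mode ML-EM on a voxel grid (default: 80 x 80 x 1 voxels of 1 mm at
the source plane; full 3D grids are supported).  The system row of a cone
is Gaussian in the angular distance between the voxel direction and the
cone surface, times an inverse-square distance factor; rows are truncated
at 1e-6 of their maximum; the update is the standard multiplicative EM
step, initialized uniform, run for exactly 30 iterations with no stopping
rule, with the list-mode log-likelihood recorded (it is non-decreasing, a
property the tests check numerically).  The sensitivity image defaults to
uniform — adequate for a small on-axis field of view — with a computed
mode available.

**Cone width.**  The Gaussian row width is the critical resolution
parameter.  Three models are provided.  `per_event` uses the propagated
sigma above (floored at 0.01 rad).  It describes the well-ordered core of
the error distribution well, but the true cone-error distribution is a
roughly 50/50 mixture of that narrow core and a broad population from
mis-ordered triples and from the non-linear blow-up of the energy estimate
at small second-scatter angles; against that mixture the per-event sigmas
are overconfident by almost an order of magnitude, and ML-EM then
localizes the consistent core to ~1.5 mm — a digital twin artefact
(reconstructing with the same idealized model that generated the data)
that the physical instrument cannot reproduce.  The default,
`self_calibrated`, instead estimates one global width from the cone set
itself: a plain backprojection locates the most likely point source, and
the RMS of the per-cone angular residuals about that point is used as the
row width (each event takes max(per-event sigma, global width)).  This
mirrors how a resolution model is calibrated on a point-source scan and
uses no ground truth.  The RMS (moment-matched) width is preferred over a
robust scale because the broad mixture component is instrument response,
not outliers: a Gaussian that matches the second moment is the
KL-optimal single-Gaussian approximation of the error law.  A fixed
`global` width is also accepted.  On default simulations the
self-calibrated width is ~0.2 rad and the reconstructed point source
resolves at ~8 mm FWHM, consistent with the prototype's measured 7.8 mm.

## Calibration chain

Spectra are fixed-width histograms; photopeaks are fitted by least squares
with a Gaussian plus constant background (windows of roughly +-3 expected
sigma); the energy calibration is an ordinary least-squares line
keV = slope * ADC + intercept.  The synthetic ADC scale is 5 keV per count
— arbitrary, present only so the chain can be exercised end to end without
electronics modelling.  SiPM gain drift with temperature is modelled as
linear, gain(T) = 1 - 0.05 (T - 25.5 C), valid on 10-40 C; the slope is
recovered by linear regression of photopeak-derived gains, normalized at
the reference temperature.  Channel equalization computes multiplicative
factors grand_mean/channel_mean on an 8 x 8 grid (the hardware adjusts
per-channel bias DACs instead; electronics are out of scope).

## Efficiency accounting

The headline triple-coincidence efficiency divides the number of triples
by the number of 1275 keV photons whose straight path meets the first
layer (the geometric acceptance of the 27.2 x 26.8 mm face at 35 mm is
4.2 % of the sphere).  This "per photon reaching the instrument"
convention is the one consistent with the interaction-chain arithmetic of
the device: about 12 % of incident 1275 keV photons interact in layer 1,
~1 % of those continue into an interacting path in layer 2, and ~2 % of
those again in layer 3, giving ~1e-5 per incident photon.  The
per-emitted-into-4pi, per-decay and sum-windowed variants are reported
alongside in `EfficiencyReport` so alternative denominators remain
inspectable.  Multiplied by the source activity, the per-decay rate
predicts ~0.4 triples per second at 700 kBq.

## Problem sizes

The package's standard analysis runs use: 1.3e9 decays for the imaging
acquisition (about 31 minutes of equivalent source time at 700 kBq,
yielding ~1100 triples of which ~500 pass the sum window), 8e7 emitted
1275 keV photons for the efficiency figure, 1e5 draws for energy-response
recovery, and 11 temperatures x 2e4 draws for the temperature scan.  These
sizes put the Monte Carlo standard errors comfortably inside the
tolerances being checked while keeping a full run in the minutes range on
one CPU.

## What the synthetic data do not show

The generator emulates the geometry, response widths, thresholds, trigger
and source of the physical prototype, but not: electronics non-linearity
and per-channel gain structure (beyond the equalization utilities), SiPM
saturation and crosstalk, DAQ dead time (the measured event rate of the
hardware is therefore not a prediction target), detector time jitter,
Doppler broadening of the Compton response, or beam-line backgrounds.
Passing tests establish the internal consistency of the chain and its
agreement with the published desk measurements; they do not certify
performance under hadron-therapy conditions, where the emission spectrum
is broad and backgrounds are severe.

## Known limitations

- The photoelectric column of the attenuation table is a parametrization,
  not a tabulated dataset; photopeak amplitudes (not positions) inherit a
  ~10-20 % model uncertainty.
- Interaction ordering is taken as layer order; no kinematic sequencing is
  attempted, so ~half of the selected triples carry large cone errors.
  The self-calibrated width model absorbs them statistically rather than
  rejecting them.
- The delta-method per-event sigma is a core-only error estimate; it is
  kept because it is cheap, interpretable, and the floor inside the
  self-calibrated model, but it should not be read as a per-event
  confidence interval.
- 2D source-plane reconstruction is the default; full 3D grids work but
  the cone geometry provides weak depth discrimination at this stand-off.
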