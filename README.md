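# comptel

A desk-scale digital twin of a three-layer LaBr3 Compton telescope for
hadron-therapy treatment monitoring: Monte Carlo simulation of 22Na
imaging with the prototype's geometry and measured response, gamma
spectroscopy calibration utilities, three-interaction Compton-cone
building, and list-mode ML-EM image reconstruction.

## The instrument and the problem

Hadron therapy deposits dose with a sharp distal falloff whose position
should be verified in real time.  Prompt gamma rays (0.5-10 MeV) emitted
by excited tissue nuclei are a candidate signal, but their spectrum is
broad, so a classical two-layer Compton camera — which needs either the
incident energy or full absorption — cannot form its cones.  A
three-layer telescope over-determines the kinematics: if a photon
scatters in layer 1 (deposit e1), scatters again in layer 2 (deposit e2,
deflection theta2 measured from the three interaction positions), and
interacts once more in layer 3, the incident energy follows directly from

    E0 = e1 + e2/2 + sqrt( e2^2/4 + e2 * m_e c^2 / (1 - cos theta2) )

and the first-scatter cone (apex at the layer-1 interaction, axis from
layer 2 through layer 1, half-angle theta1 with
cos theta1 = 1 - m_e c^2 (1/(E0 - e1) - 1/E0)) contains the source
direction.  Many cones are combined by list-mode maximum-likelihood
expectation-maximization (ML-EM): each cone contributes a system-matrix
row Gaussian in the angular distance to the cone surface with an
inverse-square distance factor, and the intensity iterates through the
standard multiplicative update for 30 iterations.

The modelled prototype is three LaBr3 slabs read out by SiPM arrays:
27.2 x 26.8 x 5 mm (6.4 % FWHM at 511 keV), 32 x 36 x 5 mm (7.4 %) and
32 x 36 x 10 mm (7.2 %), with ~1 mm FWHM intrinsic position resolution,
50 keV thresholds, a 25 ns coincidence window, gaps of 60 and 65 mm
between layers, and a 700 kBq 22Na point source 35 mm from the first
layer.  The simulator transports annihilation pairs and the 1275 keV
line photon through the stack (Klein-Nishina Compton scattering +
photoelectric absorption), applies the response, builds coincidences
including accidentals and pile-up, and writes list-mode CSV files that
the reconstruction chain consumes.  See `docs/methods.md` for the model
in detail.

## Worked example

Simulate two hundred million decays (~5 minutes of equivalent source
time), build cones, reconstruct, and report:

```python
from comptel import analysis, default_prototype, events, reconstruction, simulator

geo = default_prototype()
src = simulator.default_na22_source()
ev, truth, summary = simulator.run_experiment(geo, src, 200_000_000, seed=11)
print(summary["n_triples"], "triples from", summary["n_decays"], "decays")

cones = events.cones_from_listmode(ev, geo, events.DEFAULT_SUM_WINDOW)
grid = reconstruction.default_source_plane_grid(geo.source_z_mm)
img = reconstruction.mlem_reconstruct(cones, grid, reconstruction.MLEMConfig())
xs, ys, sl = reconstruction.extract_plane(img, geo.source_z_mm)
prof = analysis.profile_fwhm(xs, ys, sl, "x")
print(f"image FWHM {prof.fwhm_mm:.1f} mm at x = {prof.centroid_mm:.1f} mm")

spec = analysis.sum_spectrum(ev)
peaks = analysis.find_photopeaks(spec, [511.0, 1275.0])
for line, fit in peaks.items():
    print(f"sum-spectrum peak near {line:.0f}: centroid {fit.centroid:.1f} keV")
```

prints

```
193 triples from 200000000 decays
image FWHM 9.4 mm at x = 1.2 mm
sum-spectrum peak near 511: centroid 512.5 keV
sum-spectrum peak near 1275: centroid 1281.5 keV
```

The 193 triples in 286 s of source time are the ~0.7 events/s the
geometry and cross-sections allow; 100 of them fall in the 800-1400 keV
sum window used for imaging.  The image of the 0.25 mm source resolves at
~8-9 mm FWHM — the resolution is set by the cone-error scale of the
telescope (mis-ordered interaction sequences and the missing
depth-of-interaction information), not by the source size.  The two sum
photopeaks sit at their nominal energies within the fit uncertainty of a
few keV.

The same chain is scriptable from the shell:

```bash
comptel simulate --seed 11 --n-decays 200000000 --out run
comptel process --in run_events.csv --sum-window 800:1400 --out run_cones.csv
comptel reconstruct --cones run_cones.csv --grid 80x80x1:1.0 --iters 30 --out run
comptel analyze --img run --events run_events.csv --report run_report.json
```

plus `comptel run` (whole pipeline from a YAML config), `comptel
calibrate` (photopeak fits -> linear ADC/keV calibration) and `comptel
fixture` (deterministic oracle data sets).

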