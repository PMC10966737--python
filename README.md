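# enamelmap

Correlative X-ray micro-tomography and wide-angle X-ray scattering (WAXS)
mapping of dental enamel demineralization, with a virtual beamline so the
whole analysis chain runs — and is tested — without instrument data.

## Who this is for

Beamline users and analysts working with dual-modality instruments that
acquire full-field absorption imaging and raster-scanned transmission
diffraction of the *same* sample in one lab coordinate frame. The
motivating application is enamel caries research: acid dissolves the
hydroxyapatite (HAp) mineral, lowering both the X-ray attenuation seen by
imaging and the crystalline diffraction signal seen by WAXS, and doing so
preferentially along the ~5 µm enamel rods. Linking the two modalities
point-by-point turns qualitative images into a cross-validated,
localized measurement of mineral loss.

## What the package does

- **Virtual beamline** (`enamelmap.phantom`, `enamelmap.simulate`) — a
  time-evolvable enamel-slab phantom (quasi-hexagonal rod packing,
  front-advance demineralization kinetics with preferential rod
  dissolution), Beer–Lambert radiographs with Poisson noise and
  flat/dark structure, analytic Debye–Scherrer WAXS frames (ring radius
  r = D·tan 2θ with λ = 2d·sin θ, axial texture on the basal (002)
  arc, liquid background, detector module gaps), LaB₆-like calibrant
  patterns, and interlaced tomography/diffraction acquisition schedules.
- **Tomography** (`enamelmap.recon`) — flat/dark correction and
  parallel-beam filtered back-projection (frequency-domain ramp/Hann).
- **Diffraction analysis** (`enamelmap.waxs`) — ring-based calibration of
  sample-to-detector distance and beam centre, azimuthal integration to
  I(q), azimuthal (texture) profiles I(φ) over a q annulus, pseudo-Voigt
  (002) peak fitting, per-point scalar maps, and the lookup-table
  correction for beam-raster geometry drift.
- **Correlation** (`enamelmap.correlate`) — raster↔pixel registration,
  map/projection overlays, gauge-volume prisms cut from the
  reconstructed volume, time-lapse curves, and per-point Pearson
  correlation of Δattenuation vs. Δ(002) intensity.
- **Pipelines** (`enamelmap.pipeline`, CLI `enamelmap`) — end-to-end
  static (carious sample) and dynamic (in-situ demineralization)
  experiments, each writing a manifest sufficient to reproduce the run.

## Worked example

A 14.4-hour in-situ demineralization run at desk scale (128×96 px
imaging at 2 µm, an 8×8 diffraction raster, 20 interlaced
tomography/map cycles):

```python
from enamelmap import PipelineConfig, run_dynamic_experiment

cfg = PipelineConfig(seed=1)
bundle = run_dynamic_experiment(cfg, "out_dynamic")
print(f"Pearson r = {bundle['correlation'].coefficient:.3f}"
      f" over n = {bundle['correlation'].n} raster points")
att = bundle["curves"]["imaging"]["roi_attenuation"]
print(f"window attenuation: {att.iloc[0]:.4f} -> {att.iloc[-1]:.4f}")
```

prints

```
Pearson r = 0.893 over n = 54 raster points
window attenuation: 0.0946 -> 0.0482
```

i.e. the mean −log-transmission of the exposed window roughly halves as
the acid front advances ~40 µm, the (002) diffraction amplitude
collapses only at raster points whose beam footprint touches the
window, and the per-point changes of the two modalities agree with
r ≈ 0.89. The same scene in static mode (`run_static_experiment`)
produces the summed-intensity and (002) maps, their overlay on the
registered projection (map/silhouette Jaccard ≈ 0.96 on this scene),
and gauge-volume statistics for lesion vs. sound enamel.

The CLI mirrors both drivers:

```sh
enamelmap init-config my.ini
enamelmap run-dynamic --config my.ini --seed 1 --out out_dynamic
```

## Further reading

`docs/methods.md` documents the phantom and forward models, every
tunable parameter with units and defaults, the numerical choices in the
reconstruction and fitting code, and what the synthetic tests do and do
not demonstrate about real instrument data.
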