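# Methods

This note documents the models behind `enamelmap`: what the virtual
beamline simulates, the analysis algorithms and their numerical
choices, the parameters that matter, and the limits of what the
synthetic tests demonstrate.

## Coordinate conventions

The lab frame is right-handed: `x` horizontal (transverse to the beam),
`y` vertical, `z` along the beam at rotation angle 0. All lengths are
micrometres except the sample-to-detector distance (cm) and lattice
spacings (Å). Angles are degrees in every public interface. Pixel and
voxel indices are 0-based and refer to element centres; the detector
azimuth φ is measured counterclockwise from +x.

## The enamel phantom

Dental enamel is modelled as a slab of mineral (volume fraction
`density` ∈ [0, 1]) composed of *rods* — bundles of co-aligned HAp
crystallites, ~5 µm across — packed quasi-hexagonally in the (y, z)
plane and running along x, embedded in *inter-rod* substance with a
slightly lower mineral fraction and different crystallite orientation.
Defaults: rod pitch 5 µm, rod diameter 0.88 × pitch, rod density 0.95,
inter-rod density 0.80, lattice-centre jitter 4% of pitch, density
noise σ = 0.01. The `window` box marks the area of the +x slab face
left unvarnished and exposed to acid.

**Demineralization** is a geometric front model, not reaction–diffusion
chemistry: after exposure time *t*, material within the window's (y, z)
extent and within `rate·t` of the exposed face has its density
multiplied by `softening` (default 0.12), with the front-straddling
voxel attenuated proportionally to its submerged fraction so the front
position is sub-voxel accurate on average. Rates are per label,
`rate_rod` (default 8×10⁻⁴ µm/s) > `rate_inter` (4×10⁻⁴ µm/s),
encoding preferential rod dissolution; over the default 52 000 s
schedule the rod front reaches ~42 µm. Both rates may be zero (no
acid), but a nonzero tie is rejected as violating preferentiality.
The rate scale was chosen once so that a half-day immersion produces a
lesion tens of micrometres deep, i.e. several imaging pixels and one to
two raster columns. Mineral mass is non-increasing in *t* by
construction, and density outside the window is *t*-invariant.

When `immersed`, liquid fills everything outside the sample support
plus the pore space opened by dissolution — this is what grows the
diffuse WAXS background in the lesion over time.

## Imaging forward model

Radiographs are Beer–Lambert: expected counts
`flat_field · exp(−∫ μ dl) + dark_level`, with
`μ = mu_mineral · density` and `mu_mineral` defaulting to
1.1×10⁻³ µm⁻¹ — an effective monochromatic attenuation coefficient for
dense apatite tissue at the ~22 keV imaging energy (order-of-magnitude
literature value; it is a configuration constant, not a fitted one).
The parallel projector rotates the voxel grid about the vertical axis
and *splats* each voxel onto the detector column with linear weights
that sum to one, so a projection conserves the field integral exactly
(to 1e-8 relative in tests) whenever the rotated footprint stays inside
the detector — the property the mass-conservation and round-trip tests
rely on. Poisson noise is applied per frame from an explicit seed.
Flat fields get a smooth radial vignette (default 5%); darks are
Gaussian about `dark_level`.

## Diffraction forward model

Each raster point's 2-D WAXS frame is built analytically from ring
geometry: for every reflection with d ≥ λ/2, a Gaussian-radial ring at
r = D·tan(2θ), 2θ from Bragg's law at the configured wavelength
(λ[Å] = 12.3984/E[keV]). Ring amplitude is
`ring_gain · (relative intensity/100) · S`, where *S* is the mean
mineral thickness (µm) in the beam prism — the axis-aligned box of the
beam's cross-section through the full sample depth along z, matching
the gauge-volume construction used on the analysis side. This makes
ring amplitude exactly linear in prism mineral content, the property
the time-lapse correlation measures.

Texture: the basal (002) arc is modulated by
`exp(κ·(cos²(φ−φ₀)−1))`, the simplest unimodal axial-texture model
(default κ = 2, φ₀ = 0 — crystallite c-axes along the rod axis, which
lies along lab x). Other reflections are isotropic. The liquid
background is a broad Gaussian bump in q (centre 2.0 Å⁻¹, σ = 0.8)
plus a flat term, scaled by the liquid path length through the prism,
with an optional liquid-independent `container_level`. Detector module
gaps are dead row/column bands carrying the sentinel −1; the default
layout is configurable because real tiled-detector layouts vary.

Reflection lists: HAp uses hexagonal lattice constants a = 9.4218 Å,
c = 6.8813 Å (externally sourced standard apatite structure values —
configuration, not measurement) with approximate powder intensities
for (100), (002), (210), (211), (112), (300), (202), (310); d-spacings
are computed from the lattice at run time, so (002) sits at d = c/2 =
3.4407 Å (q = 1.826 Å⁻¹). The calibrant is a LaB₆-like simple-cubic
list with a = 4.1569 Å.

## Tomographic reconstruction

Classical parallel-beam FBP, written to share geometry with the
forward projector (rotation axis at column (n_u−1)/2, manual
centre-of-rotation offset exposed for real data): −log of corrected
transmission (clipped at 1e-6), discrete ramp filter built from the
real-space kernel (f[0] = 1/4, odd taps −1/(πk)²) evaluated in the
frequency domain with zero-padding to the next power of two, optional
Hann apodization, linear-interpolation back-projection, scaling
π/(2·n_angles). Output voxels are attenuation per µm. It is a
functional reconstruction stage, deliberately minimal: no iterative
methods, ring-artifact suppression, or phase retrieval. Against an
independent FBP implementation (scikit-image's `iradon`) the slice
reconstructions agree to correlation > 0.99 on a shared sinogram.

Flat/dark correction averages the frame stacks, inpaints non-positive
flat−dark pixels with a local median (counted in the log), and clips
the transmission at a positive floor before the log.

## Diffraction analysis

**Calibration.** Ring points are detected by radial centre-of-mass
along (default 180) azimuthal rays — the first pass searches a window
of 8% of the expected radius to survive a poor starting geometry, the
centre-of-mass is restricted to the contiguous region around the peak
so neighbouring rings cannot bias it, and rays crossing gaps or leaving
the detector are dropped. (beam_center_x, beam_center_y, distance) are
then least-squares fitted to r(d) = D·tan(2·asin(λ/2d)) and detection
is repeated with the refined geometry (3 iterations). Recovery on
synthetic calibrant data is ~0.001% in distance with ~0.03 px residual
RMS; ≥2 resolvable rings are required.

**Integration.** Per-pixel q = (4π/λ)·sin(atan(r/D)/2); pixels are
binned by q and *averaged* (not summed), with per-bin coverage stored,
so gap-induced coverage differences do not masquerade as intensity
changes; Σ(intensity·coverage) recovers the masked pixel sum exactly.
Bins with coverage below 10% of the median are flagged invalid. The
azimuthal profile applies the same machinery over a q annulus in φ,
optionally windowed (the 67° default span covers one basal arc). No
solid-angle or polarization corrections are applied — a documented
limitation acceptable at these scattering angles.

**Peak fitting.** Pseudo-Voigt (Gaussian available) plus linear
background, nonlinear least squares with bounds: amplitude ≥ 0, centre
in the window, 0 ≤ η ≤ 1, FWHM between two bin widths (narrower is
unresolvable and would chase single-bin noise) and twice the window.
Initialisation: centre at the argmax after removing the end-point
baseline, FWHM at max(window/5, 2.5 bins). Non-convergence returns a
flagged, map-safe result (amplitude 0, rss = ∞).

**Map validity.** A converged fit counts as a peak *detection* only if
its amplitude exceeds 5× the residual noise and its FWHM is plausible
(between 2 bins and half the window). The amplitude bound at zero makes
the no-peak null one-sided and heavy-tailed — on off-sample points the
fit can latch onto the broad liquid background — so a plain 3σ rule
under-rejects. Invalid points keep their fitted value in the map but
are excluded from cross-modal statistics.

**Lookup correction.** Rastering the beam rather than the stage
perturbs the diffraction geometry point-to-point. Per-point calibrant
fits yield a (Δcentre_x, Δcentre_y, Δdistance) table (missing points
nearest-neighbour filled with a warning) applied before integrating
each point's pattern; under an injected 0.5 px/column centre drift this
collapses the fitted (002) centre spread by well over 5×.

## Registration and correlation

Both modalities share the lab frame, so the raster→pixel transform is
exact from metadata: scale = step/pixel_size (e.g. a 44 µm step on
0.54 µm pixels is 81.48 px per raster step), offset from the origins;
a least-squares scale+offset(+rotation) fit from fiducials is provided
for real data. Map overlays use nearest-neighbour resampling — each
raster cell is a constant block, honestly reflecting the measurement's
support. Gauge volumes are beam- (default, the 25 µm physical probe)
or step-sized prisms through the full depth along the beam at the
mapping rotation; with beam ≤ step they are pairwise disjoint. The
cross-modal statistic is Pearson's r between per-point Δ(−log T)
(averaged over the beam footprint in the first/last corrected
projections) and Δ(002 amplitude) (first/last maps), over points valid
at both times.

## Schedules and the dynamic experiment

`plan_interlaced_acquisition` places `n_tomo` cycles — a tomography
scan immediately followed by a diffraction map (duration = grid points
× dwell) — evenly across the total experiment time; the acid keeps
acting during the idle remainder of each cycle, as in a real immersion
run, and the schedule is infeasible if the cycles alone exceed the
total. During desk-scale dynamic runs each tomography event is
represented by its 0° radiograph; the time-lapse curves only need the
fixed-angle projection, and full per-event reconstructions would
multiply the runtime without changing any tested quantity.

## Problem sizes

The default ("desk-scale") configuration — 128×96 px imaging at 2 µm,
181 angles, a 256² px mapping detector at 9.6 cm, an 8×8 raster with
10 µm beam and 24/20 µm steps, 20 interlaced cycles over 52 000 s —
was chosen so a full dynamic experiment simulates and analyses in under
a minute while every stage still operates far from degenerate regimes
(the lesion spans several pixels and raster columns; all HAp rings land
on the detector). Geometry calibration, by contrast, runs at the
instrument-scale setup (38.4 cm, 172 µm pixels, 1679×1475 detector)
because its target is an instrument number. The full-instrument scan
plan (2560×2160 px, 1801 projections, 20×20 raster) is supported by the
same code paths and config keys but is not a test path.

## What the synthetic data do and do not show

The virtual beamline shares no code with the analysis stages it
exercises (projector vs. FBP are adjoint-style counterparts checked
against an independent reconstruction; integration is checked against
per-pixel brute-force binning; fits against grid-search oracles).
Passing tests therefore demonstrate internal correctness and parameter
recovery under the stated models. They do not demonstrate robustness to
what real instruments add: beam hardening and phase contrast in
imaging, ring texture from large grains, detector point-spread and
polarization in WAXS, sample motion, or registration errors beyond the
fitted affine family. The demineralization model reproduces morphology
(front depth, preferential rod attack, liquid substitution), not
chemical kinetics; its rates are emulation constants, not predictions.

## On-disk formats

TIFF stacks (directory of numbered single-page files, or one
multi-page file) are the interchange dialect for frames and volumes;
1-D curves and maps travel as headered CSV. The HDF5 container layout
(`/projections`, `/flats`, `/darks`, `/waxs/<iy>_<ix>`, `/meta`) is our
own invention — no claim of compatibility with any facility schema —
and is round-trip tested. Timestamps are seconds from experiment start.
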