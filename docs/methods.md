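# Methods

## Canonical frame and conventions

All analysis happens on 1-D depth profiles in a single canonical frame:
depth index 0 is the RGL-adjacent edge of the ROI, the last index the
INL-adjacent edge. The ROI is a standard image rectangle
(`x0,y0,width,height` in columns/rows); its `orientation` names the
edge bordering the RGL and is resolved once, at profile extraction, by
axis choice and reversal. Coordinates are 0-based; depth intervals are
half-open `[start, end)` with the outermost layer's upper bound
inclusive so every pixel center belongs to exactly one layer.

Landmarks and boundaries are real-valued fractions of the IPL depth.
A detected landmark is the pixel-center fraction `(index + 0.5) / L`;
no sub-pixel (parabolic) refinement is performed, which keeps detection
exactly equal to an exhaustive argmax/argmin oracle and bounds the
quantization error at half a pixel. Ties in argmax/argmin break toward
the lowest index, for determinism.

## Landmark detection

The profile used for detection is smoothed by a centered moving average
with truncated edge windows; quantification always uses raw profiles,
so smoothing can never bias intensity statistics. The default window is
scale-aware: the smallest odd integer ≥ max(5, L/50), i.e. 15 px on a
700 px profile. Rationale: after averaging over the ROI height the
residual profile noise is roughly `noise_sd/√height` per pixel; a
window growing with L suppresses that noise enough to hold peak jitter
under ~2.5 px at realistic conditions (10 % per-pixel noise, 80 px ROI
height) while staying an order of magnitude narrower than a neurite
band (~0.1·L full width), so symmetric peaks are not displaced. A fixed
5 px window, by contrast, leaves up to ~3.5 px jitter at L = 700
because its width does not scale with band width. A bare 1-D profile
carrying 10 % iid noise per *profile* pixel (no height averaging) is
not a regime any moving-average argmax can localize to 3 px when the
band SD is 0.04·L at L = 700; the supported noise model is per-pixel
image noise averaged across the ROI height.

ChAT mode realizes "search from the middle": global argmax per half
profile, divider = argmin strictly between the peaks. A dispersed band
with several sub-peaks therefore still yields exactly one landmark per
half (the dominant sub-peak). Calbindin/calretinin mode takes the three
brightest separable stripes — interior, plateau-aware local maxima
(`scipy.signal.find_peaks`) ranked by height with ties to the lowest
index — ordered by depth; the middle stripe stands in for the ChAT
inter-band minimum. A simple argmax between the outer peaks would land
on a band flank, and a half-split search would mistake an equally
bright middle stripe for the OFF band; ranking separable stripes avoids
both failure modes. Fewer than three separable maxima raises a
detection error, as do constant profiles and peaks at profile ends.

The percentile mode returns fixed constants (0.40, 0.60, 0.77) — the
average wild-type mouse SAC-band and divider positions — and never
recomputes them from images. Whether the divider should be the
intensity minimum or the geometric midpoint between the bands is open
in principle; the intensity minimum is implemented, as it is the only
image-derivable realization.

## Binning geometry

`compute_sac_boundaries` implements the ten-layer scheme in closed
form (see README for the boundary list). The reading of the sub-ON
split — seven equal sublayers of `[0, p₁]`, successive pairs of the
first six merged into layers 1–3, the seventh kept for layer 4 — is the
only accounting under which seven sublayers yield three merged
sublaminae plus a peak-adjacent remainder, and under which widths at
wild-type landmarks come out near 10 % (they span 8.5–11.4 %).
Boundaries stay continuous fractions; pixel assignment is deferred to
quantification. The additional analysis region appends one boundary
> 1 in IPL-length units; only one such region is allowed.

## Quantification

Layer means are taken over raw (unsmoothed) profile pixels by center
membership. Three parallel readouts are kept, none clamped at zero:
raw mean; normalized (mean − 0.99 × lowest non-zero layer mean of that
image); and mean − background (3×3 truncated-window sample at a user
point, only when background reduction is enabled). The tool cannot
distinguish labeled pixels from background, so negative values are
reported as computed and users should use one readout consistently.
Intensity % divides each layer's mean by the sum of layer means — the
additional region included when selected, so a misprojection readout is
a share of total measured signal. Note the denominator is a sum of
per-layer *means*: with unequal layer widths this is not a pixel-sum
share, which is why a constructed 10 % misprojection reads 10.28 % under
SAC-anchored widths and exactly 10 % under equal-width bins. With
several images, the combined summary rows average every statistic —
including percents — per layer and channel across images.

## Synthetic sections

`fixtures.SectionSpec` renders each channel as a constant IPL baseline
plus Gaussian bands (centers, SDs, amplitudes in IPL-length fractions),
broadcast across the ROI height with independent additive Gaussian
pixel noise clipped at zero; a fixed seed makes every render
bit-identical. Defaults encode the study conditions: 700 px IPL depth,
80 px ROI height, band SD 0.04·L (full width at half maximum ≈ 10 % of
the IPL, the measured SAC band span), baseline 0.1 of band amplitude.
Presets are noiseless; tests add noise explicitly (10 % of band
amplitude where a noisy condition is exercised).

Two equal symmetric bands alone would put the inter-band minimum at
their midpoint (58.5 % depth), but the wild-type divider sits at 60 %;
the wild-type scenes therefore carry a weak broad component (center
0.25, SD 0.10, amplitude 0.1598) modeling diffuse ON-half cholinergic
neuropil, with the amplitude solved analytically so the continuous
minimum falls at exactly 60 % while the ON peak moves by < 0.15 % of
the IPL. The calbindin preset's middle stripe sits at the 60 % divide
it demarcates. Misprojection is a Gaussian band centered in the
region past the INL edge (which is otherwise dark apart from noise),
scaled so that exactly the requested fraction of the channel's total
noiseless signal lies beyond the IPL.

What the generator does *not* emulate: somata and vasculature, retinal
curvature (which smears lamination across bins — sampling a shorter
IPL span more frequently is the practical workaround), depth-dependent
illumination, and structured (non-Gaussian) noise. Passing tests
therefore demonstrate correctness of the geometry, detection and
bookkeeping under the stated noise model, not robustness to every
real-section artifact.

## Numerical choices and degenerate inputs

- Boundary invariants are enforced at construction: endpoints exactly
  0 and 1, strict monotonicity, widths summing to 1 to 1e-9.
- A layer capturing no pixel centers gets mean 0 and a logged warning
  rather than an error (possible for very narrow layers at low
  resolution).
- All-zero layer means make normalization and percent undefined; both
  raise.
- The 3×3 background window truncates at image borders instead of
  erroring.
- Results files serialize numbers at 6 significant digits so repeated
  runs are byte-identical.
- Problem sizes in tests mirror the defaults above (700 × 80 px
  sections, 100 seeds for noisy-recovery checks, 1000 random profiles
  for the detection oracle), chosen as representative of confocal
  section crops.

## Known limitations

Batch runs apply one ROI to all images (scriptability replaces the
original per-image GUI prompting); zebrafish retinas with three SAC
bands are served by manual mode, not by a dedicated detector; ImageJ
`.roi` files are not read.
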