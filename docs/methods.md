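# Methods

This note documents the models implemented in `thermafoot`, the defaults
and why they were chosen, what the synthetic scenes do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Radiometric model

The camera reports a radiometric signal S (detector digital units) that a
calibrated Planck-law parameterisation links to scene temperature:

    B(T) = R1 / (R2 · (exp(B_c / T) − F)) − O            (radiance, camera units)
    T(S_obj) = B_c / ln( R1 / (R2 · (S_obj + O)) + F ) − 273.15

with calibration constants `PB (B_c), PR1 (R1), PR2 (R2), PO (O), PF (F)`
read from the container metadata. The object signal is recovered from the
vignette-corrected counts S* by removing the path terms:

    S_obj = S*/(ε·τ·W_t) − S_atm − S_opt − S_refl
    S_atm = (1−τ)/(ε·τ) · B(T_air),  S_opt = (1−W_t)/(ε·τ·W_t) · B(T_win),
    S_refl = (1−ε)/ε · B(T_refl)

where ε is the skin emissivity (default 0.98 in the LWIR band), W_t the
window transmission (default 1), and the path-term temperatures are in
kelvin. The atmospheric transmission over the working distance d (m) uses
the two-component empirical form

    τ = X·exp(−√d·(α1 + β1·√ω)) + (1−X)·exp(−√d·(α2 + β2·√ω))

with the water-vapour pressure from air temperature (in °C) and relative
humidity:

    ω = RH · exp(1.5587 + 6.939e-2·T_a − 2.7816e-4·T_a² + 6.8455e-7·T_a³)

The √d/√ω placement in τ follows the standard reference formulation; the
literal linear-in-d variant is available through
`RadiometricParams(atm_formula="linear")` because typeset versions of the
formula are ambiguous. "log" is the natural logarithm throughout. The
temperature-unit boundary is centralised: ω takes °C, the path radiances
take K.

The forward model (`planck_forward`) is the exact algebraic inverse of
this chain and is what the simulator renders scenes through; the
round-trip |invert(forward(T)) − T| is verified below 1e-9 °C across
[−20, 60] °C and randomised calibration constants. Pixels whose radiance
leaves the invertible domain (log argument ≤ 1) raise an error that
identifies them; they are never silently clipped.

## Vignetting correction

Vignetting is modelled as a slowly varying multiplicative gain,
R = G·R*, estimated from flat-field stacks and corrected by division
*before* the non-linear temperature inversion (a multiplicative radiometric
artefact is no longer multiplicative after the Planck map). Per epoch:
pixelwise median over the N_k frames (robust to hot pixels and transient
reflections), an optional symmetric quantile clamp to the [0.02, 0.98]
quantiles of the median image, Gaussian smoothing with σ = 4 px
(3–6 px preserves the spatial structure of real vignetting patterns while
suppressing residual noise; replicate padding avoids darkened borders that
would masquerade as vignetting), then normalisation by the median (mean
selectable) and a positivity floor ε = 1e-6.

Stability across epochs is summarised by the RMS of log(Ĝ_i/Ĝ_j) over
pixels — the natural discrepancy measure for a multiplicative field. When
the largest off-diagonal RMS is at most 0.01 (a configurable threshold;
about 1 % gain drift), the pixelwise-median master gain is used; otherwise
the gain is interpolated geometrically (linearly in the log domain)
between the bracketing epochs, which preserves positivity and the
multiplicative structure. No extrapolation outside the calibrated range.

**On the quantile clamp.** The clamp is an impulse-artefact guard. On
clean flat fields whose only spatial structure is the smooth gain itself,
clamping at fixed quantiles clips the genuine extremes of the vignetting
pattern (the image corners) and leaves a systematic gain bias there of up
to a few tenths of a percent — which the steep Planck slope (~0.6 °C per
percent of gain at body temperatures) turns into a 0.2–0.3 °C corner bias.
The clamp therefore defaults to on for real acquisitions (where hot pixels
exist) but is disabled in the artefact-free accuracy benchmark, whose
error budget is then dominated by the NETD-driven noise, as it should be.

With N_k = 16 frames per epoch and three epochs, the gain-estimation noise
after median-stacking and smoothing is second order: the correction
amplifies per-pixel scene noise by well under 1.1×, and the full-chain RMS
temperature error on the 28–35 °C benchmark scene is 0.08–0.11 °C across
seeds.

## Marker detection

**Visible.** The registration hardware presents 10 mm white disks on
matte-black strips. After luma conversion and subtraction of a large-scale
Gaussian illumination estimate (σ_bg = 25 px ≥ 4× the expected disk
radius, so the disk contrast survives within 10 %), every pixel is scored
by the difference between the mean over a disk of radius r = 5 px and the
mean over the surrounding annulus of width w = 5 px. Local maxima above
5× the robust noise level of the score map (1.4826·MAD) are thinned by
non-maximum suppression at radius r, then validated geometrically: Otsu
segmentation inside a (4r)² region of interest, component area within
[0.4, 2.5]·πr², circularity 4πA/P² ≥ 0.7, minor/major axis ratio ≥ 0.75.
The centre is the component centroid; the radius follows from the
equivalent-disk area and doubles as the in-image mm-per-pixel reference
(10 mm / median detected diameter).

**LWIR.** A heated marker leaves a diffuse single-peaked "thermal hill"
about 10–15 px across in the 160×120 temperature image. The large-scale
anatomical background is estimated by grayscale opening with a disk
structuring element of radius 12 px (about twice the expected marker
radius); the relief T − opening(T) is non-negative by anti-extensivity.
Opening-by-reconstruction is available behind a flag but is unsuitable
here: the hills' own diffuse tails reconnect them to the background under
reconstruction and the relief vanishes. The relief is thresholded at
ΔT_min = 2 °C, cleaned (area opening at 20 px, closing with a 2 px disk,
hole filling), and 8-connected components are kept when their area lies in
[α_min·π·r_min², α_max·π·r_max²] with α_min = 0.4, α_max = 2.5,
r_min = 5, r_max = 7.5 px, their circularity 4πA/(P² + 1e-9) is at least
0.20 (permissive — hills are diffuse), their peak relief reaches ΔT_min,
and their equivalent diameter 2√(A/π) falls in the 10–15 px band.
Perimeters use the chain-code estimator, under which an ideal rasterised
disk scores ≥ 0.9 and a 3:1 bar well under the threshold.

Each retained hill is localised by a relief-weighted barycentre. The
detector weights by the relief *excess* above ΔT_min: pixels that enter a
component only through closing and hole filling carry sub-threshold relief
dominated by residual background slope, and including them at full weight
biases the centre by up to ~0.5 px near the warm feet. The raw-relief
estimator remains available (`weighted_barycenter(..., weight_floor=0)`).
On symmetric hills the barycentre is accurate to better than 0.1 px; on
the full simulated scenes both detectors stay within 0.5 px of truth.

## Matching and registration

Matching assumes rigidly mounted cameras with nearly parallel optical
axes. Candidate pairs are pre-filtered by scale-normalised sorted
distances to the k = 4 nearest same-modality neighbours (shortlist
m = 5 by Euclidean signature distance). RANSAC (2000 iterations,
seeded generator recorded with the result) samples IR triplets paired
with shortlisted VIS triplets and rejects hypotheses whose triangle
orientations disagree, whose affine has non-positive determinant (a
reflection), or whose rotation exceeds 15° / anisotropy exceeds 1.5 —
all physically impossible under the mounting. Projected IR points are
assigned one-to-one to VIS points by optimal rectangular assignment with
an explicit non-assignment cost (a greedy fallback is available for
speed); the permissive inlier radius is 5 LWIR-pixel-equivalents, scaled
into the VIS frame by √|det A|. A hypothesis must explain at least
max(4, 55 % of the smaller point set) markers: three points always fit
their own affine exactly, and with at most ~25 % missing or spurious
detections the true correspondence always covers ≥ 75 % of the smaller
set, so the majority floor costs nothing while eliminating small-subset
coincidental fits (the failure mode of mirrored scenes over symmetric
layouts). If the shortlist-constrained search finds nothing — spurious
detections can corrupt the signatures of their neighbours — a rescue phase
re-runs the sampling with candidates drawn from all VIS points: the
shortlist is a search-space reduction, never a correctness constraint.

Order preservation along both image axes is enforced with Spearman rank
correlations of the matched x and y coordinates (average ranks at ties).
The floor is 0.8 at both the hypothesis and the final stage: with ~8
markers arranged in rows, coordinates within a row are near-tied and
sub-pixel localization noise legitimately scrambles their rank order on
perfectly correct matches (a fully reversed three-marker row costs about
0.1 of ρ), so a stricter floor would misreject valid matches; the strict
assignment radius (2 LWIR-pixel-equivalents) is the discriminating final
filter. The best hypothesis is refitted on all inliers and re-assigned
under the strict thresholds until the pair set is a fixed point.

The final anamorphosis defaults to the affine family (matching the
matcher's model); projective and degree-2 polynomial fits are available
for scenes with residual perspective. The warp maps the visible image
onto the LWIR grid by inverse mapping with bilinear resampling — the
thermal raster is never resampled — and pixels leaving the source domain
are flagged in a validity channel. Fusion (edge overlay or alpha blend)
is pure visualisation.

## Synthetic scenes

The simulator emulates the bedside geometry: a 160×120 LWIR camera
(54°×42° field of view) and a 640×480 visible camera (71.5°×56°; a
stand-in for the 5 MP sensor — full resolution adds nothing at desk
scale) with a 12 mm horizontal baseline, both fronto-parallel to the
marker plane at the 0.5 m protocol distance, which makes the exact
plane-induced VIS→LWIR map an axis-aligned affine recorded in the truth
record. Markers sit on a roughly rectangular ring around the feet with
fixed irregular strip offsets (1–3 cm) plus ±6 mm per-session jitter —
the way hand-placed strips actually land, and deliberately asymmetric: a
perfectly mirror-symmetric ring admits a relabelled orientation-preserving
alias correspondence that no geometric algorithm could reject, so the
mirror-rejection guarantee presumes (realistic) asymmetric placement.

The thermal scene is an ambient field near 23 °C with two broad
anisotropic Gaussian blobs standing in for the feet (peaks ≈ 31 °C) and
Gaussian marker hills of σ = 4.5 px and amplitude 6–9 °C — calibrated so
the ≥ 2 °C relief imprint spans 10–15 LWIR px even where the foot
background overlaps the ring and costs 1–3.7 °C of apparent relief after
opening. Counts are rendered through the exact forward Planck chain,
multiplied by a tilt-plus-radial-quartic gain truth of bounded amplitude
(max/min ≤ (1+a)/(1−a)), and perturbed with Gaussian noise whose standard
deviation equals 70 mK (the detector NETD) times the local Planck slope.
The visible scene renders anti-aliased white disks on dark strips over a
gray background with an illumination gradient and mild sensor noise. All
generators are bit-reproducible per seed.

What the scenes do **not** emulate — and what passing tests therefore do
not show about real data: fixed-pattern and 1/f detector noise beyond the
white NETD term, emissivity variation across skin and wound tissue,
radiative coupling between feet and markers, motion during acquisition,
lens distortion in the rendered fixtures (distortion handling is tested
separately on synthetic warps), JPEG compression of the thermal payload
(the container stores counts losslessly), and the full variety of vendor
metadata dialects.

## Numerical choices and degenerate inputs

- Median of an even number of frames: mean of the two central order
  statistics (NumPy convention).
- Gain floor ε = 1e-6 prevents division blow-ups; gains are validated
  strictly positive at construction.
- Coordinates are 0-based, x = column, y = row, origin top-left, pixel
  centres at integer coordinates, for every module.
- Warp and undistortion validity checks tolerate 1e-6 px of round-off at
  the domain edge so identity transforms do not flag border pixels.
- Collinear RANSAC triplets (oriented area 0) are skipped; degenerate
  affine systems raise rather than return garbage.
- Matching is exactly reproducible given (inputs, seed); the pipeline
  writes deterministic provenance timestamps (stage indices) so reruns
  are bit-identical.
- An all-zero-weight component falls back to the unweighted centroid with
  a warning.

## Benchmark problem sizes

The accuracy benchmarks use the study conditions throughout: 160×120
frames, 3 flat-field epochs × 16 frames, ±10 % gain amplitude, 70 mK
noise for the radiometric figure; 8 markers, 0.3 px centre noise and 50
seeded repetitions for the registration figure. A full benchmark run
completes in seconds on one CPU.

## Known limitations

- The LWIR barycentre bias grows with background slope under the hills;
  markers placed directly against strong thermal gradients (e.g. touching
  the foot silhouette) can exceed the 0.5 px localization envelope.
- The mirror-rejection guarantee relies on layout asymmetry (see above);
  a machined, perfectly symmetric marker frame would defeat it and would
  need an appearance cue instead.
- Off-plane markers degrade the plane-induced transform monotonically
  (verified); the chain detects this only through residuals, it does not
  model the parallax.
- Gain interpolation covers drift between epochs but not within-session
  drift; periodic flat-field acquisition remains necessary.
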