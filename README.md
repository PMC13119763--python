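# thermafoot

Quantitative thermography for low-cost radiometric LWIR cameras, built for
bedside monitoring of the diabetic foot. Consumer thermal cameras (160×120
uncooled microbolometers with an NETD near 70 mK) are cheap enough for
routine clinical screening, but their raw output is not quantitatively
usable: the radiometric signal carries strong multiplicative vignetting,
the counts-to-temperature conversion depends on embedded Planck calibration
constants and atmospheric conditions, and the visible and thermal sensors
see the scene through different optics with parallax at the ~0.5 m working
distance. A bilateral plantar temperature difference of about 2 °C is the
clinically relevant signal, so every one of these artefacts matters.

`thermafoot` implements the full processing chain from raw container file
to a calibrated, registered thermogram, plus a synthetic scene simulator
with exact ground truth for every stage:

- **flir_io** — decode radiometric JPEG containers (embedded 16-bit
  payload + Planck metadata) and maintain a JSON patient record with
  append-only provenance.
- **vignetting** — estimate smooth multiplicative gain fields
  G(x, y, t) from flat-field stacks (pixelwise median → optional quantile
  clamp → Gaussian smoothing → unit-median normalisation), combine epochs
  into a master gain when the inter-epoch log-gain RMS is small, or
  interpolate geometrically in time; correct frames by elementwise
  division R*(x, y) = R(x, y) / Ĝ(x, y).
- **radiometry** — temperature inversion
  T = B / ln(R₁/(R₂(S_obj + O)) + F) − 273.15 with object radiance
  S_obj = R*/(ε·τ·W_t) − S_atm − S_opt − S_refl, atmospheric transmission
  τ(d, ω) from the water-vapour pressure ω(T_a, RH), and the exact forward
  model for simulation.
- **geometry** — application of Brown–Conrady radial/tangential
  undistortion from calibrated intrinsics.
- **marker_vis / marker_lwir** — sub-pixel detection of the hybrid
  10 mm registration markers: disk-minus-ring contrast score with
  geometric validation in the visible image; morphological-opening
  background removal, mask cleaning, component filtering and
  relief-weighted barycentres for the diffuse thermal hills in the LWIR
  image.
- **matching** — one-to-one IR↔VIS correspondence by constrained RANSAC:
  scale-normalised neighbour-distance signatures, triplet sampling with
  orientation and determinant constraints (mirrored matches are physically
  impossible), optimal one-to-one assignment with explicit non-assignment,
  and Spearman rank monotonicity along both axes.
- **registration_fusion** — affine/projective/polynomial anamorphosis
  fitting, inverse-mapped warping of the visible image onto the untouched
  LWIR grid, edge or alpha fusion for display, and the mm-per-pixel scale
  from the known marker diameter.
- **fixtures** — seeded generators for gain fields, flat-field stacks,
  Planck-consistent scenes and bimodal marker scenes with a small stereo
  baseline, all with recorded truth.
- **pipeline** — the end-to-end session runner with per-stage provenance.

## Worked example

Simulate a full bedside session, then run each stage through the CLI:

```sh
thermafoot simulate scene --n-markers 8 --seed 7 --out-dir scene
thermafoot decode scene/scene.jpg -o dec
thermafoot correct dec/raw_counts.tiff --gain scene/gain.tiff -o corr.tiff
thermafoot temperature corr.tiff --params dec/params.json -o T.tiff
thermafoot markers lwir T.tiff -o lwir.json
thermafoot markers vis dec/visible.png -o vis.json
thermafoot match lwir.json vis.json --seed 7
```

which prints

```
decoded 160x120 counts -> dec
corrected counts -> corr.tiff
T in [22.95, 34.62] degC -> T.tiff
8 pairs, residual RMS 0.427 px -> correspondences.json
```

The decoded frame is the camera's 160×120 count raster; after gain
correction and Planck inversion the scene spans 22.95–34.62 °C (ambient
room background, feet near 31 °C, heated markers a few degrees above
their strips). All 8 thermal markers are matched one-to-one to their
visible counterparts, and the fitted affine maps marker centres with a
0.43 px residual in the visible frame — about 0.15 mm at the working
distance, comfortably below the 2 °C / 2 mm scales that matter clinically.

The same chain runs in one step, producing a fused overlay and a complete
patient record:

```sh
thermafoot run --session-dir sess --jpeg scene/scene.jpg --gain scene/gain.tiff
# record with 8 steps -> sess/record.json
```

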