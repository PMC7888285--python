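# Methods

This note records the models, conventions, parameter choices and known
limitations of the pipeline. Nothing here states an empirical result the
tests or `scripts/acceptance.py` do not themselves compute.

## Colorimetry

Conversions run LCH -> Lab -> XYZ -> linear RGB -> companded sRGB and back.
The Lab reference white is configurable:

* `"d65"` (default): Lab referenced directly to the sRGB display white
  (D65, 2 deg observer). This convention reproduces the three published
  stimulus triplets at (L*, C*) = (60, 60) to two decimals, which is the
  only anchor available for the original conversion, so it is the package
  default; the convention is recorded on grid and boundary objects.
* `"d50-bradford"`: Lab referenced to D50 with Bradford adaptation into the
  sRGB matrix — the default behaviour of some colorimetry libraries. It
  changes the red R channel by ~0.02 and does not match the published
  triplets.

The RGB <-> XYZ matrices are derived at run time from the sRGB primaries
and the D65 white rather than copied from rounded tables, so equal
companded channels map exactly onto the achromatic Lab axis and round trips
close to ~1e-12. Hue is undefined at zero chroma; converters return H = 0
there and `LCHColor.is_achromatic` flags the case.

Out-of-gamut conversions raise `GamutError` carrying the raw channel
values; an opt-in clip mode records the largest clipped excursion instead.

**Gamut boundaries.** `max_chroma(L, H)` scans chroma upward at 0.25
C*-unit resolution (sub-JND) and refines the boundary bracket by bisection;
`gamut_boundary(H)` tabulates (L*, maxC*, maxS = maxC*/L*) for L* = 0..100,
with a NaN sentinel for maxS at L* = 0.

## Stimulus and trial design

Level sets follow the experimental design: hue angles
{39.999, 136.016, 306.285} deg (the sRGB primary axes), relief heights
{0.025, 0.05, 0.1, 0.2} (displacement scale, fraction of tile width),
Beckmann roughness {0.01, 0.1, 0.2, 0.3, 0.4} for matching and
{0.01, 0.1, 0.3, 0.4} for paired comparisons, slants {15, 30, 45} deg.
Conditions enumerate in lexicographic (hue, relief, roughness, slant)
order. Paired-comparison blocks contain all n(n-1) ordered pairs of the 16
relief x roughness conditions sharing hue and slant (240 trials), shuffled
by a recorded seed; each condition appears exactly n-1 times per side, so
left/right presentation is exactly balanced within a block.

The matching lattice spans L* 18.75..97.5 and C* 22.5..101.25 in 3.75
steps (22 x 22). Indexing: row = chroma index, column = lightness index,
both ascending.

**Displayability.** The full lattice is *not* wholly inside sRGB: at every
one of the three hues, strict validation flags 172-256 of the 484 cells
(worst channel excursion ~0.6), because the per-lightness maximum chroma
falls below the lattice at high L* — the package's own `gamut_boundary`
tables show this directly. `build_matching_grid` therefore supports a
strict mode (raise, the constructor default) and a clip-tolerant mode that
records the out-of-gamut mask and worst excursion, which is what an 8-bit
sRGB display does with such settings and is the pipeline default. One
acceptance test asserts full displayability and fails by design, keeping
the discrepancy visible rather than silently validated away.

## Rendering

A stimulus tile is a 10 cm square carrying smoothed value noise: an
(8+1)^2 uniform random lattice cubic-upsampled to the pixel grid (about 8
undulations across the tile), box-smoothed (2 passes of 3x3 averaging by
default), min-max normalised to [0, 1] and scaled by the relief height, so
peak-to-peak amplitude equals the displacement scale exactly — 20% of tile
width at the largest level.

Shading is direct illumination only. World frame: the camera looks
horizontally along -z, "up" is +y, and the emitter is a horizontal 2.5 m x
1.0 m rectangle 0.75 m above the tile, sampled on a deterministic 10 x 4
cell-centred grid. The tile is slanted by theta about the horizontal axis;
at 45 deg its mean normal bisects the viewing and lighting directions (the
mirror configuration). Per pixel and light sample:

* diffuse = albedo x (N.L)+ averaged over samples (albedo is the
  decompanded base color);
* specular = 0.2 x D_Beckmann(angle(N, H); alpha) x (N.L)+ averaged over
  samples, H the half-vector of sample direction and view.

The Beckmann density D(theta_m) = exp(-tan^2 theta_m / alpha^2) /
(pi alpha^2 cos^4 theta_m) is used with a scalar specular amplitude (0.2)
and cosine foreshortening; Fresnel and shadow-masking factors are omitted
because the simulated material is specified by a scalar amplitude, not an
index of refraction. The projected-solid-angle integral of D is 1 to
better than 1% across the roughness range, checked by quadrature.
Orthographic projection is used: at 60 cm viewing distance the perspective
field angles are <10 deg and negligible for the statistics computed here.
No interreflection, no room walls, no path tracing — the enclosing room
contributes mostly low-frequency ambient light that the analysis does not
consume.

**Physical specular coverage** is the fraction of pixels whose specular
component exceeds `frac_threshold` x the image's specular peak (default
0.1; sensitivity set {0.05, 0.1, 0.2}; zero-specular images report 0).
This relative-threshold pixel count is a meaningful proxy for highlight
area only while the lobe is sharp enough to produce distinct highlights.
At the default roughness 0.1 the renderer reproduces the characteristic
interaction — mean coverage rises with relief at the 15 deg slant (flat
normals sit far from the mirror band; bumps create aligned facets) and
falls with relief at 45 deg (the flat tile is already mirror-aligned;
bumps disperse it). At roughness >= 0.3 the specular layer of a
near-flat tile becomes nearly uniform, the per-image-relative threshold
saturates toward full coverage, and the statistic stops tracking
highlight area; coverage analyses therefore default to the sharp regime.

## Psychophysics

Matching responses aggregate to per-(observer, condition) means.
Saturation uses mean-of-ratios by default (average of per-trial C/L per
observer, then across observers), matching per-observer averaging before
group averaging; ratio-of-means is available by flag and differs whenever
settings covary. Missing conditions stay missing — never silent zeros.

Win probabilities are wins / presentations per condition within each
(observer, task, hue x slant block), with presentations counted from the
trial structure (optionally from the designed trial list, so partially
recorded sessions keep correct denominators). Probabilities are never
pooled across hue or slant: blocks were run separately.

`rm_anova` implements the classical balanced fully-within-subjects
partitioning: cell means per subject, factorial effect decomposition by
inclusion-exclusion (mean-centering along effect axes, averaging along the
rest), every effect tested against its own interaction with subjects, no
sphericity correction, p values uncorrected for multiple tests. Replicated
cells are averaged within subject; missing cells raise rather than impute.
The implementation agrees with the statsmodels general-linear-model route
to ~1e-10 and yields the textbook df patterns — (4, 32) for one 5-level
factor with 9 subjects, (9, 27) for a 4 x 4 interaction with 4 subjects.

## Cue-combination model

`predict(W, p_gloss, p_coverage) = W p_coverage + (1 - W)(1 - p_gloss)`.
Both dependent variables (saturation, lightness) use this same functional
form with independent weights. The sweep covers W = -1..1 inclusive at
0.01 steps (201 points); the best weight maximises r^2, with the signed r
reported — the correlation's sign is informative (saturation and lightness
can correlate with opposite signs through the same machinery). Exact r^2
ties break toward the smaller |W| (parsimony, deterministic output). Grid
points where the model output is numerically constant (possible when the
two cue vectors coincide) are excluded with a warning. Because the output
is affine in W, r^2(W) is a ratio of quadratics with a single interior
stationary point; the tests exploit the closed form as an independent
oracle and require the grid best within one step of it. Plain Pearson r is
used rather than a fitted affine map — correlation is scale-invariant, so
the two readings of a "linear least-squares fit" give identical |r|.
Correlation p values use the t transform with n - 2 dfs.

Model fits use the 4 x 4 relief x roughness cells shared by the matching
and paired-comparison designs (matching's roughness 0.200 is dropped), 16
points per hue x slant block, 144 pooled. The pooled fit also reports the
gloss-coverage inter-correlation.

## Synthetic observers

The generator emulates the statistical structure the analysis assumes,
with known ground truth; it does not attempt to fit the original figures.

* **Latent cues** are deterministic surfaces over (relief, roughness,
  slant), mapped into [0, 1] with relief and roughness normalised over
  their level ranges. Gloss `0.72 - 0.28 qn + 0.06 (0.5 - rn)` declines
  strictly with roughness; an optional flag makes the lowest-relief rows
  rise with roughness and plateau instead, emulating the near-flat-surface
  inversion. Coverage combines a slant-signed linear trend, `s = (30 -
  slant)/15`, in relief and roughness with a slant-independent inverted-U
  in roughness, so both coverage slopes are positive at 15 deg and
  negative at 45 deg. Two calibrations are deliberate: the two cue
  surfaces have similar within-block spreads, kept within ~1.5x the choice
  noise (the near-linear regime of the Thurstonian probability transform —
  outside it the two win-probability scales compress differently and the
  recovered weight is biased), and the cues carry no slant main effect,
  because win probabilities are centred within each block and a
  between-block cue shift could never be recovered from them.
* **Matching settings**: percepts follow the cue-combination model with
  the true weights (defaults W_sat = 0.41, W_light = 0.34); settings are
  an affine map L* = 60 + 25 (P'_light - 1/2), S = 1 + 0.6 (P'_sat - 1/2),
  C* = L* S, placed inside the grid for cue values in [0.13, 0.93]; a
  warning fires if >10% of condition means leave the grid. Gaussian
  setting noise (default 3.75, one grid step) is added to L* and C* before
  snapping to the nearest grid level, ties to the lower index, edges
  clipped. The chosen-cell distribution matches direct discretization of
  the normal (chi-squared checked at n = 10,000).
* **Choices** follow Thurstone Case V: independent latent noise (default
  SD 0.25 cue units) on each stimulus, choose the first iff its noisy cue
  is larger; the win probability converges to Phi(dcue / (sqrt(2) sd)).
* **Randomness**: one top-level seed spawns labelled substreams (matching /
  gloss choices / coverage choices / trial shuffles), so datasets
  regenerate bit-identically.

Defaults mirror the paired-comparison design — 9 matching observers, 4
choice observers, 3 hues x 3 slants x 16 conditions, 240 trials per block
per observer per task. Hue enters only through optional per-hue weight
offsets; by default the generator produces *no* hue or slant main effects
in the percepts, so a null ANOVA result on those factors in synthetic data
says nothing about real observers — the generator exists to validate the
estimation machinery (weight recovery to ±0.05 median over 100 seeds at
default noise), not to reproduce empirical effect sizes, F statistics, or
the published correlation tables, which require the undeposited human
data.

## Pipeline

`run_pipeline(RunConfig(...))` executes design -> (simulate | load CSVs)
-> aggregate -> ANOVA -> model fits, writing percepts, per-dv fit tables
(9 block rows + 1 pooled row), ANOVA tables, and a JSON report echoing the
config, seed and version; artifact names inside the report are relative so
identical runs are byte-identical. Any stage failure raises `StageError`
naming the stage. All tables regenerate exactly from the echoed config.
There is no console entry point: the library functions and the `analysis/`
scripts are the interface.

## Problem sizes

Default sizes keep a full pipeline run around a second on one core:
render sweeps use 128 x 128 pixels and a 40-sample emitter; recovery
summaries use 100 seeds (tests) or 20 seeds (`analysis/05_fit_model.py`,
adjustable via `--recovery-seeds`). Gamut boundaries scan 0.25 C* steps.

## Known limitations

* The renderer is a single-bounce, orthographic approximation; it shares
  the published setup's geometry and material model but not its global
  illumination, so only qualitative image statistics (coverage directions,
  highlight behaviour) are meaningful, not luminance values.
* The coverage statistic saturates for near-uniform specular layers
  (high roughness on near-flat tiles), as noted above.
* Synthetic observers are affine-Gaussian idealisations: no lapses, no
  learning, no inter-observer weight variability unless configured.
* The within-subjects ANOVA assumes balance and applies no sphericity
  correction by design; it will refuse unbalanced data rather than
  approximate.
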