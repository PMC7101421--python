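# Methods

## Problem and quantity of interest

The choroid — the vascular layer between retina and sclera — thickens or
thins with disease (central serous chorioretinopathy, myopia, age), but
measuring its thickness requires OCT with enhanced depth imaging. In an
ordinary colour fundus photograph the large choroidal vessels are visible
through the retinal pigment epithelium when the choroid is thin (the
striped "tigroid" fundus) and blurred when it is thick. This package
quantifies that visibility as the **choroidal vasculature appearance
index**

```
CVAI = CVR / IR
```

where CVR is the number of pixels classified as choroidal vessel in a
binarised fundus photograph and IR the number of pixels of the circular
illuminated imaging region. CVAI is expected to correlate *negatively*
with sub-foveal choroidal thickness, and to be further depressed in CSC
eyes, where melanin redistribution and subretinal fluid obscure the
choroidal pattern.

## Binarisation pipeline

Stages, in order (all intermediates are retained in the result):

1. **Field of view.** The per-pixel maximum over R, G, B is thresholded at
   an intensity floor (default 10/255); the largest connected component is
   kept and holes are filled. Its pixel count is IR.
2. **Channel separation.** Choroidal vessels are most visible in the R
   plane (deep red light penetrates to the choroid); retinal vessels are
   most visible in the G plane (red-free imaging).
3. **Field extension.** Each channel is continued smoothly into the black
   frame by iterative ring-mean dilation. Without this, every local-mean
   window that straddles the field edge sees the dark frame and the rim of
   the field binarises as a spurious bright ring.
4. **CLAHE on G.** Classic tile-based contrast-limited adaptive histogram
   equalisation (tile side 8 px, clip limit 2.0 in multiples of the
   uniform bin height, bilinear interpolation between tile-centre
   mappings).
5. **Retinal-vessel mask.** Adaptive binarisation of the equalised G plane
   with dark-on-light polarity: a pixel is foreground iff its intensity is
   strictly below the Gaussian-weighted mean of its block x block
   neighbourhood minus C. The Gaussian sigma is tied to the block size
   (`0.3*((block-1)/2 - 1) + 0.8`); borders are reflected symmetrically
   (edge duplicated); ties are background.
6. **Retinal-vessel removal.** Masked pixels of the R plane are infilled
   by deterministic inward ring-mean dilation: repeated one-pixel
   dilations of the valid region, each newly valid pixel set to the mean
   of its already-valid 8-neighbours. A mask covering more than 90% of the
   field is rejected as degenerate.
7. **Choroidal-vessel mask.** Adaptive binarisation of the vessel-free R
   plane with light-on-dark polarity (in a tigroid fundus the choroidal
   vessels are the *light* bands between pigmented stripes).
8. **Optic disc.** Each channel is binarised for its brightest structures
   (adaptive light-on-dark, unioned with a global floor at the channel's
   99th intensity percentile so that flat bright regions wider than the
   adaptive window are captured); the pixel-wise AND of the three masks is
   taken. A candidate component must contain pixels that are
   top-percentile bright in *all three* channels — this rejects the light
   halos that adaptive thresholding draws beside dark retinal vessels,
   which also pass the AND. The winning component is regularised by its
   convex hull (a disc is convex; the AND is patchy where a channel's
   bright floor cuts through the disc interior) and dilated by 5 px. An
   empty result is legal (disc outside the frame). The disc is removed
   from the choroid mask by set difference.
9. **Speckle removal.** Connected components below `min_component_px`
   (default 10) are dropped.
10. **CVAI.** `cvai = |final ∩ fov| / |fov|`. The identity, the bounds
    `0 <= cvai <= 1`, disjointness from the disc mask, and confinement to
    the field of view are asserted on every run.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `clahe_clip_limit` | 2.0 | x uniform bin height | common CLAHE default |
| `clahe_tile` | 8 | px | tile side; small tiles for local contrast |
| `adaptive_block` | 25 | px at 512-px field | must exceed vessel width; scaled proportionally to the detected field diameter, forced odd, min 3 |
| `adaptive_offset_C` | 4 | 8-bit levels | ~2 SD of typical sensor noise |
| `min_component_px` | 10 | px | isolated noise components are smaller |
| `disc_dilation_px` | 5 | px | safety margin around the detected disc |

The source protocol prints none of these values; they are package design
choices, overridable through `BinarisationConfig` or the TOML config file,
and the fully resolved configuration is logged on every run.

### Numerical choices

* Thresholding uses strict inequality; a pixel exactly at the local mean
  plus/minus C is background.
* Border handling is symmetric reflection with edge duplication
  (`...cba|abc...`), the convention of `scipy.ndimage`; the test oracle
  uses the same stated convention computed per pixel.
* Rounding back to 8 bits uses banker's rounding (`np.rint`) everywhere.
* The pipeline is fully deterministic: identical input and configuration
  give bit-identical masks.

## Synthetic fundus generator

The generator renders, over a black frame: a circular field with a smooth
per-channel background gradient; choroidal vessels as broad light bands in
the R plane only, laid out as roughly parallel wiggly chords (the tigroid
stripe pattern — and near-parallel layout also prevents bands from merging
into blobs wider than any adaptive window); retinal vessels as thinner
dark curves in all planes (deepest in G), radiating from the disc; a
bright, slightly soft-edged disc in all three planes; and Gaussian pixel
noise (SD 2) inside the field. A 4-px peripapillary exclusion ring keeps
choroidal bands off the disc margin, mimicking the scleral ring and
preserving the disc's own edge contrast.

The thickness-visibility mechanism is an exponential decay,

```
contrast = base_contrast * exp(-thickness / tau) * (csc_factor if CSC)
```

with `base_contrast = 65` intensity levels, `tau = 300 um`, and
`csc_factor = 0.7`. Exponential decay is the simplest monotone parametric
law; any monotone law preserves the properties the evaluation relies on.
`base_contrast` is sized so that an *unattenuated* vessel interior clears
the detection offset C by several noise SDs even for the widest vessels,
where suppression by the local mean is strongest, while keeping vessels
(R <= 235) dimmer than the disc (R = 250). CSC is modelled purely as extra
multiplicative attenuation — no lesion, fluid pocket or drusen model.

Cohort structure: choroidal thickness is drawn from a normal distribution
truncated to [100, 700] um with (mean, SD) = (267, 100) um for normal eyes
and (343, 96.4) um for CSC eyes; ages and spherical-equivalent refractive
errors are sampled with the matching group means/SDs for completeness
(they do not influence rendering). Default cohort size is 200 eyes per
group.

Ground-truth masks form a partition with precedence disc > choroidal >
retinal: where a retinal vessel crosses a choroidal band the pixel is
labelled *choroidal*, because the vessel exists beneath and the infilling
stage deliberately reconstructs it; the retinal mask therefore labels
retinal vessel over plain background. Geometry and noise draws do not
depend on thickness or group, so eyes generated with the same seed differ
only in vessel contrast — which makes attenuation monotonicity directly
testable.

**What a green test does and does not establish.** The generator has
sharply-bounded, noise-dithered vessels on an almost flat background; real
photographs add media opacity, uneven illumination, drusen/nevus
pigmentation, and camera-specific colour response. Green tests establish
that the pipeline recovers what the generator drew and that the evaluation
statistics behave exactly as defined — not that the pipeline reproduces
the clinical correlations reported on patient data (those images are not
publicly available).

## Evaluation statistics

* Correlations are Pearson by default (the reference analysis shows linear
  scatter fits); Spearman is always computed alongside. Zero variance is a
  degenerate input, not a silent NaN.
* Group comparison uses the two-sided Mann-Whitney U test, `U = min(U_a,
  U_b)`; the p-value is exact (full enumeration) for `n_a + n_b <= 12`
  without ties, otherwise the normal approximation with tie correction and
  *no* continuity correction (so identical samples give p = 1).
* "Thick choroid" is dichotomised at 250/300/350 um; thickness exactly at
  the cut-off counts positive.
* ROC curves sweep all distinct score thresholds; AUC is trapezoidal, so
  ties contribute one half and AUC equals the Mann-Whitney pair statistic
  `U/(n_pos * n_neg)` exactly. Because CVAI falls as the choroid thickens,
  CVAI predicts thick choroid with `score_direction = lower_is_positive`.

## CNN regression protocol (scaled down)

A five-block VGG-shaped regressor: stride-1 same-padding 3x3 convolutions
with ReLU, a stride-2 max-pool closing each block, then flatten and two
fully connected layers ending in a single linear unit (thickness in um).
Two architectures are built from the same pattern: `vgg16` (2-2-3-3-3
convolutions, 64-512 channels) for structural completeness, and
`vgg_small` (one convolution per block, 8/16/32/32/32 channels, 64-px
inputs) for desk-scale training. A literal half-width VGG-16 is far too
slow for a one-CPU numpy trainer, so `vgg_small` keeps the topology
pattern rather than the parameter count. No pretrained weights are
available offline; layers initialise with He-normal draws and a warning is
logged if freezing of initial blocks is requested.

Training: mean-squared error on z-scored targets (statistics from the
training folds only), Adam (lr 1e-3), batch size 32. Each image is
augmented exactly six-fold — original, brightness shift, gamma correction,
global histogram equalisation, Gaussian noise, left-right mirror
("inversion" is read as mirroring; intensity negation would destroy the
tigroid signal). Augmentation is applied to training eyes only, and an
assertion on every fold verifies that no augmented copy of a validation
eye reached the training set. K-fold cross-validation (K = 5) yields
exactly one out-of-fold prediction per eye; per-fold models are discarded.

Grad-CAM: the scalar output is back-propagated with the rectified rule
(each ReLU passes only positive gradients) to a target layer (default:
the pooling of block 3); the map is the channel-wise sum of gradient x
activation, rectified, bilinearly upsampled to the input size and
max-normalised to [0, 1]. The spatial gradient-times-activation weighting
(rather than globally averaged channel weights) is used so that spatially
selective heads localise; an all-zero map is returned flagged as
degenerate rather than renormalised.

## Known limitations

* The generator does not model drusen, nevus, haemorrhage, media opacity
  or photoreceptor sheen; no automated exclusion of such eyes is
  implemented.
* The disc detector assumes the disc, when present, is the brightest
  structure in all three channels; a heavily overexposed frame would
  confuse it.
* CLAHE with an 8-px tile is aggressive on noise; the retinal mask
  therefore over-segments slightly, which is harmless here (infilling
  isolated pixels is a mild smoothing) but would matter if the retinal
  mask itself were the quantity of interest.
* The CNN protocol demonstrates the training/evaluation machinery at desk
  scale; it does not attempt the clinical accuracy of a GPU-scale
  transfer-learning run.
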