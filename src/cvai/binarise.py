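"""Choroidal-vessel binarisation pipeline and CVAI computation.

The core algorithm: a colour fundus photograph is split into its R, G, B
component images; the G component (where retinal vessels are most visible)
is contrast-enhanced with CLAHE and adaptively binarised to obtain a
retinal-vessel mask; those pixels are infilled in the R component (where
choroidal vessels are most visible); the vessel-free R component is
adaptively binarised to obtain the choroidal-vessel candidates; the optic
disc — found as the logical product of the bright regions of all three
channels — is removed; and the choroidal vasculature appearance index is

    CVAI = CVR / IR

where CVR is the pixel count of the final choroidal-vessel mask and IR the
pixel count of the illuminated imaging region.

Adaptive binarisation thresholds every pixel against the Gaussian-weighted
mean of its ``adaptive_block`` x ``adaptive_block`` neighbourhood, offset by
a constant C. Ties at the threshold are background. The Gaussian sigma is
tied to the block size with the conventional ``0.3*((block-1)*0.5 - 1) + 0.8``
rule so that a single parameter controls the window.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .exceptions import DegenerateMaskError, EmptyFieldError, ParameterError
from .image_io import (
    BinaryMask,
    ChannelImage,
    FundusImage,
    detect_field_of_view,
    split_channels,
)

logger = logging.getLogger(__name__)

DARK_ON_LIGHT = "dark_on_light"
LIGHT_ON_DARK = "light_on_dark"
_POLARITIES = (DARK_ON_LIGHT, LIGHT_ON_DARK)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class BinarisationConfig:
    """Free parameters of the binarisation pipeline.

    ``adaptive_block`` is expressed at a reference field diameter of
    ``reference_field_px`` pixels and scaled proportionally to the detected
    field diameter at run time (rounded to the nearest odd size, minimum 3),
    so the same configuration works across image resolutions.
    """

    clahe_clip_limit: float = 2.0
    #: tile side in pixels
    clahe_tile: int = 8
    #: odd window size in pixels, at reference_field_px field diameter
    adaptive_block: int = 25
    #: offset C subtracted from / added to the local weighted mean
    adaptive_offset_C: float = 4.0
    #: polarity of retinal vessels in the (CLAHE'd) G channel
    retinal_polarity: str = DARK_ON_LIGHT
    #: polarity of choroidal vessels in the vessel-free R channel
    choroid_polarity: str = LIGHT_ON_DARK
    #: connected components smaller than this are dropped from the final mask
    min_component_px: int = 10
    #: dilation radius applied to the detected optic disc before removal
    disc_dilation_px: int = 5
    #: field diameter at which adaptive_block is expressed
    reference_field_px: int = 512
    #: intensity floor for field-of-view detection
    intensity_floor: int = 10

    def __post_init__(self) -> None:
        if self.adaptive_block < 3 or self.adaptive_block % 2 == 0:
            raise ParameterError(
                f"adaptive_block must be odd and >= 3, got {self.adaptive_block}"
            )
        if self.clahe_tile < 2:
            raise ParameterError(f"clahe_tile must be >= 2, got {self.clahe_tile}")
        if self.min_component_px < 0:
            raise ParameterError("min_component_px must be >= 0")
        for pol in (self.retinal_polarity, self.choroid_polarity):
            if pol not in _POLARITIES:
                raise ParameterError(f"polarity must be one of {_POLARITIES}, got {pol!r}")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "BinarisationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown binarisation option(s): {sorted(unknown)}")
        return cls(**dict(mapping))

    def scaled_block(self, field_diameter_px: float) -> int:
        """Effective adaptive window for a field of the given diameter."""
        b = int(round(self.adaptive_block * field_diameter_px / self.reference_field_px))
        b = max(3, b)
        return b if b % 2 == 1 else b + 1


@dataclass
class CVAIResult:
    """CVAI for one eye, with all intermediate masks of the pipeline."""

    cvai: float
    cvr_px: int
    ir_px: int
    masks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ir_px <= 0:
            raise EmptyFieldError("IR must be positive")
        if not (0 <= self.cvr_px <= self.ir_px):
            raise ParameterError("CVR must satisfy 0 <= CVR <= IR")


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def _clahe_tile_lut(hist: np.ndarray, clip_limit: float, tile_area: int) -> np.ndarray:
    """Mapping of one tile: clip the histogram, redistribute, equalise.

    ``hist`` has shape (..., 256); the clip limit is expressed as a multiple
    of the uniform bin height ``tile_area / 256`` (OpenCV semantics).
    """
    clip = max(1.0, clip_limit * tile_area / 256.0)
    clipped = np.minimum(hist, clip)
    excess = (hist - clipped).sum(axis=-1, keepdims=True)
    clipped = clipped + excess / 256.0
    cdf = np.cumsum(clipped, axis=-1)
    return np.clip(np.rint(cdf * (255.0 / tile_area)), 0, 255)


def apply_clahe(g: ChannelImage, cfg: BinarisationConfig) -> ChannelImage:
    """Contrast-limited adaptive histogram equalisation.

    Classic tile-based CLAHE: the image is divided into square tiles of
    side ``cfg.clahe_tile``; each tile's histogram is clipped at
    ``clahe_clip_limit`` times the uniform bin height, the excess is
    redistributed uniformly, and the clipped CDF gives the tile's intensity
    mapping. Pixels are transformed by bilinear interpolation between the
    mappings of the four nearest tile centres (pixels outside the outermost
    centres use the nearest tile's mapping alone).
    """
    px = g.pixels
    h, w = px.shape
    t = int(cfg.clahe_tile)
    if t > min(h, w):
        raise ParameterError(
            f"clahe_tile {t} larger than image (min side {min(h, w)})"
        )

    pad_h = (-h) % t
    pad_w = (-w) % t
    padded = np.pad(px, ((0, pad_h), (0, pad_w)), mode="reflect")
    hp, wp = padded.shape
    nty, ntx = hp // t, wp // t

    # per-tile 256-bin histograms in one bincount
    tiles = padded.reshape(nty, t, ntx, t).transpose(0, 2, 1, 3).reshape(nty * ntx, t * t)
    offsets = np.arange(nty * ntx)[:, None] * 256
    hist = np.bincount(
        (tiles.astype(np.int64) + offsets).ravel(), minlength=nty * ntx * 256
    ).reshape(nty, ntx, 256)
    luts = _clahe_tile_lut(hist, cfg.clahe_clip_limit, t * t)

    # bilinear interpolation between tile-centre mappings
    yy = (np.arange(h) - (t - 1) / 2.0) / t
    xx = (np.arange(w) - (t - 1) / 2.0) / t
    y0 = np.clip(np.floor(yy).astype(int), 0, nty - 1)
    x0 = np.clip(np.floor(xx).astype(int), 0, ntx - 1)
    y1 = np.minimum(y0 + 1, nty - 1)
    x1 = np.minimum(x0 + 1, ntx - 1)
    wy = np.clip(yy - y0, 0.0, 1.0)[:, None]
    wx = np.clip(xx - x0, 0.0, 1.0)[None, :]

    v = px[:h, :w]
    g00 = luts[y0[:, None], x0[None, :], v]
    g01 = luts[y0[:, None], x1[None, :], v]
    g10 = luts[y1[:, None], x0[None, :], v]
    g11 = luts[y1[:, None], x1[None, :], v]
    out = (
        (1 - wy) * ((1 - wx) * g00 + wx * g01)
        + wy * ((1 - wx) * g10 + wx * g11)
    )
    return ChannelImage(np.rint(out).astype(np.uint8), "derived")


# ---------------------------------------------------------------------------
# Adaptive binarisation
# ---------------------------------------------------------------------------

def gaussian_kernel(block: int) -> np.ndarray:
    """Normalised 2-D Gaussian kernel of side ``block``, sigma tied to size."""
    sigma = 0.3 * ((block - 1) * 0.5 - 1) + 0.8
    x = np.arange(block, dtype=np.float64) - (block - 1) / 2.0
    k1 = np.exp(-(x * x) / (2.0 * sigma * sigma))
    k1 /= k1.sum()
    return np.outer(k1, k1)


def adaptive_binarise(
    ch: ChannelImage,
    cfg: BinarisationConfig,
    polarity: str,
    *,
    block: int | None = None,
    role_label: str = "choroidal_vessel",
) -> BinaryMask:
    """Per-pixel thresholding against the Gaussian-weighted local mean.

    A pixel is foreground iff its intensity is strictly below
    ``local_mean - C`` (dark_on_light) or strictly above ``local_mean + C``
    (light_on_dark); ties are background. Borders are handled by symmetric
    reflection with edge duplication (``...cba|abc...``).
    ``block`` overrides ``cfg.adaptive_block`` (used by the pipeline after
    scaling the window to the detected field diameter).
    """
    if polarity not in _POLARITIES:
        raise ParameterError(f"polarity must be one of {_POLARITIES}, got {polarity!r}")
    b = cfg.adaptive_block if block is None else int(block)
    if b % 2 == 0:
        raise ParameterError(f"adaptive block size must be odd, got {b}")
    h, w = ch.shape
    if b < 3 or b > min(h, w):
        raise ParameterError(
            f"adaptive block size must be in [3, {min(h, w)}], got {b}"
        )
    px = ch.pixels.astype(np.float64)
    mean = ndimage.correlate(px, gaussian_kernel(b), mode="reflect")
    c = float(cfg.adaptive_offset_C)
    if polarity == DARK_ON_LIGHT:
        fg = px < mean - c
    else:
        fg = px > mean + c
    return BinaryMask(fg, role_label=role_label)


# ---------------------------------------------------------------------------
# Retinal-vessel removal (infilling)
# ---------------------------------------------------------------------------

_NEIGH8 = np.ones((3, 3), dtype=np.float64)


def _ring_mean_infill(
    px: np.ndarray,
    invalid: np.ndarray,
    max_iter: int | None = None,
    fill_value: float | None = None,
) -> np.ndarray:
    """Replace invalid pixels from the outside in.

    Repeated one-pixel dilations of the valid region; each newly valid pixel
    is set to the mean of its already-valid 8-neighbours. Deterministic.
    Pixels still invalid after ``max_iter`` rounds (or unreachable pixels)
    get ``fill_value`` (default: mean of the valid region).
    """
    img = px.astype(np.float64)
    valid = ~invalid
    if valid.all():
        return img
    if not valid.any():
        raise DegenerateMaskError("no valid pixels to infill from")
    it = 0
    while not valid.all():
        if max_iter is not None and it >= max_iter:
            break
        vf = valid.astype(np.float64)
        cnt = ndimage.correlate(vf, _NEIGH8, mode="constant", cval=0.0)
        ssum = ndimage.correlate(img * vf, _NEIGH8, mode="constant", cval=0.0)
        ring = (~valid) & (cnt > 0)
        if not ring.any():
            break
        img[ring] = ssum[ring] / cnt[ring]
        valid |= ring
        it += 1
    if not valid.all():
        img[~valid] = float(px[~invalid].mean()) if fill_value is None else fill_value
    return img


def subtract_retinal_vessels(
    r: ChannelImage,
    retinal_mask: BinaryMask,
    fov: BinaryMask | None = None,
) -> ChannelImage:
    """Infill retinal-vessel pixels of the R channel from their surroundings.

    Every masked pixel is replaced by an estimate propagated inward from the
    mask boundary (ring-mean infilling), so retinal vessels cannot survive
    the subsequent choroidal binarisation. An empty mask returns the input
    bit-exactly.
    """
    if r.shape != retinal_mask.shape:
        raise ParameterError("image and mask dimensions differ")
    region = fov.pixels if fov is not None else np.ones(r.shape, dtype=bool)
    denom = int(region.sum())
    covered = int((retinal_mask.pixels & region).sum())
    if denom and covered / denom > 0.9:
        raise DegenerateMaskError(
            f"retinal mask covers {covered / denom:.0%} of the field (> 90%)"
        )
    if not retinal_mask.pixels.any():
        return ChannelImage(r.pixels.copy(), "derived")
    filled = _ring_mean_infill(r.pixels, retinal_mask.pixels)
    return ChannelImage(np.clip(np.rint(filled), 0, 255).astype(np.uint8), "derived")


def extend_field(
    ch: ChannelImage, fov: BinaryMask, margin_px: int
) -> ChannelImage:
    """Continue the illuminated field smoothly into the dark frame.

    The local-mean windows of adaptive binarisation would otherwise straddle
    the field edge and fire on the rim; extending the field by at least the
    window radius removes that artefact. Pixels beyond ``margin_px`` rounds
    of dilation get the field's mean intensity.
    """
    filled = _ring_mean_infill(ch.pixels, ~fov.pixels, max_iter=margin_px)
    return ChannelImage(np.clip(np.rint(filled), 0, 255).astype(np.uint8), "derived")


# ---------------------------------------------------------------------------
# Optic disc
# ---------------------------------------------------------------------------

def _largest_component(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes))
    if sizes[best] < max(min_px, 1):
        return np.zeros_like(mask)
    return labels == best + 1


def _largest_component_touching(
    mask: np.ndarray, anchor: np.ndarray, min_px: int
) -> np.ndarray:
    """Largest component of ``mask`` (>= min_px) that intersects ``anchor``."""
    labels, n = ndimage.label(mask)
    if n == 0 or not anchor.any():
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    anchored = np.unique(labels[anchor & mask])
    anchored = anchored[anchored > 0]
    candidates = [lab for lab in anchored if sizes[lab - 1] >= max(min_px, 1)]
    if not candidates:
        return np.zeros_like(mask)
    best = max(candidates, key=lambda lab: sizes[lab - 1])
    return labels == best


def _disk(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def detect_optic_disc(
    r: ChannelImage,
    g: ChannelImage,
    b: ChannelImage,
    cfg: BinarisationConfig,
    fov: BinaryMask | None = None,
    *,
    block: int | None = None,
) -> BinaryMask:
    """Optic disc as the logical product of per-channel bright regions.

    Each channel is binarised for its brightest structures: the adaptive
    rule with light_on_dark polarity, unioned with a global floor at the
    99th intensity percentile (computed within the field of view when
    given) so that flat bright regions larger than the adaptive window are
    still captured. The pixel-wise AND of the three channel masks is taken,
    the largest connected component at least ``min_component_px`` big is
    kept and dilated by ``disc_dilation_px``. An empty result is legal
    (disc outside the frame).
    """
    if not (r.shape == g.shape == b.shape):
        raise ParameterError("channel dimensions differ")
    region = fov.pixels if fov is not None else np.ones(r.shape, dtype=bool)
    product = np.ones(r.shape, dtype=bool)
    floor_product = np.ones(r.shape, dtype=bool)
    for ch in (r, g, b):
        adaptive = adaptive_binarise(
            ch, cfg, LIGHT_ON_DARK, block=block, role_label="optic_disc"
        ).pixels
        vals = ch.pixels[region]
        bright = np.zeros(ch.shape, dtype=bool)
        if vals.size and np.ptp(vals) > 0:
            bright = ch.pixels >= np.percentile(vals, 99)
        product &= adaptive | bright
        floor_product &= bright
    product &= region
    floor_product &= region
    # the disc must be top-percentile bright in ALL channels somewhere; this
    # rejects the light halos that adaptive thresholding draws beside dark
    # retinal vessels (they too pass the AND in every channel)
    core = _largest_component_touching(product, floor_product, cfg.min_component_px)
    if core.any():
        # the AND is patchy where a channel's bright floor cuts through the
        # disc interior; the disc is convex, so hull + dilation regularise it
        core = convex_hull_image(core)
        if cfg.disc_dilation_px > 0:
            core = ndimage.binary_dilation(core, structure=_disk(cfg.disc_dilation_px))
    return BinaryMask(core, role_label="optic_disc")


# ---------------------------------------------------------------------------
# CVAI
# ---------------------------------------------------------------------------

def remove_small_components(mask: BinaryMask, min_px: int) -> BinaryMask:
    """Drop connected components smaller than ``min_px`` pixels (speckle)."""
    if min_px <= 1 or not mask.pixels.any():
        return mask
    labels, n = ndimage.label(mask.pixels)
    sizes = ndimage.sum_labels(mask.pixels, labels, index=np.arange(1, n + 1))
    keep = np.concatenate(([False], sizes >= min_px))
    return BinaryMask(keep[labels], role_label=mask.role_label)


def compute_cvai(final_mask: BinaryMask, fov_mask: BinaryMask) -> CVAIResult:
    """CVAI = CVR / IR with CVR = |final ∩ fov| and IR = |fov|."""
    if final_mask.shape != fov_mask.shape:
        raise ParameterError("mask dimensions differ")
    ir = fov_mask.count
    if ir == 0:
        raise EmptyFieldError("field-of-view mask is empty (IR = 0)")
    inter = final_mask.pixels & fov_mask.pixels
    cvr = int(inter.sum())
    return CVAIResult(
        cvai=cvr / ir,
        cvr_px=cvr,
        ir_px=ir,
        masks={
            "final": BinaryMask(inter, "choroidal_vessel"),
            "field_of_view": fov_mask,
        },
    )


def _check_result_invariants(res: CVAIResult) -> None:
    final = res.masks["final"].pixels
    fov = res.masks["field_of_view"].pixels
    disc = res.masks["optic_disc"].pixels
    if res.cvai != res.cvr_px / res.ir_px:
        raise AssertionError("CVAI != CVR/IR")
    if not (0.0 <= res.cvai <= 1.0):
        raise AssertionError("CVAI outside [0, 1]")
    if (final & disc).any():
        raise AssertionError("final mask intersects the optic-disc mask")
    if (final & ~fov).any():
        raise AssertionError("final mask extends outside the field of view")


def run_pipeline(img: FundusImage, cfg: BinarisationConfig | None = None) -> CVAIResult:
    """Run the full binarisation pipeline on one fundus photograph.

    Stages, in order: field-of-view detection; channel split; CLAHE on G;
    adaptive binarisation of G -> retinal mask; retinal-vessel infilling of
    R; adaptive binarisation of the vessel-free R -> choroid candidates;
    optic-disc detection (logical product of bright regions of R, G, B) and
    removal by set difference; speckle removal; CVAI restricted to the
    field of view. Deterministic: identical input and config give identical
    output. All intermediates are retained in ``CVAIResult.masks``.
    """
    cfg = cfg or BinarisationConfig()

    def _stage(name):
        logger.debug("pipeline stage: %s", name)

    _stage("field_of_view")
    try:
        fov = detect_field_of_view(img, cfg.intensity_floor)
    except EmptyFieldError as exc:
        raise EmptyFieldError(f"field_of_view stage: {exc}") from exc
    diameter = 2.0 * np.sqrt(fov.count / np.pi)
    block = cfg.scaled_block(diameter)

    _stage("split_channels")
    r, g, b = split_channels(img)
    margin = block + 2
    r_x = extend_field(r, fov, margin)
    g_x = extend_field(g, fov, margin)
    b_x = extend_field(b, fov, margin)

    _stage("clahe_g")
    g_clahe = apply_clahe(g_x, cfg)

    _stage("retinal_mask")
    retinal = adaptive_binarise(
        g_clahe, cfg, cfg.retinal_polarity, block=block, role_label="retinal_vessel"
    )
    retinal = BinaryMask(retinal.pixels & fov.pixels, "retinal_vessel")

    _stage("subtract_retinal")
    vessel_free = subtract_retinal_vessels(r_x, retinal, fov)

    _stage("choroid_mask")
    choroid = adaptive_binarise(
        vessel_free, cfg, cfg.choroid_polarity, block=block,
        role_label="choroidal_vessel",
    )
    choroid = BinaryMask(choroid.pixels & fov.pixels, "choroidal_vessel")

    _stage("optic_disc")
    disc = detect_optic_disc(r_x, g_x, b_x, cfg, fov, block=block)

    _stage("final_mask")
    final = BinaryMask(choroid.pixels & ~disc.pixels, "choroidal_vessel")
    final = remove_small_components(final, cfg.min_component_px)

    _stage("cvai")
    res = compute_cvai(final, fov)
    res.masks.update(
        {
            "g_clahe": g_clahe,
            "g_binarised": retinal,
            "vessel_free_r": vessel_free,
            "choroid_binary": choroid,
            "optic_disc": disc,
        }
    )
    _check_result_invariants(res)
    return res
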