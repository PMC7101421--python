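"""Synthetic fundus-image generator with ground truth.

Renders fundus-like photographs — an illuminated circular field over a
black frame, a smooth background gradient, broad light choroidal vessels in
the red plane, darker retinal vessels radiating from a bright optic disc —
together with the exact masks used to draw them and the latent choroidal
thickness that produced them. This is what makes every pipeline stage
testable without patient data.

The generator encodes the mechanism under study: choroidal-vessel
visibility falls monotonically with choroidal thickness. The rendered
vessel-to-background contrast is

    contrast = base_contrast * exp(-thickness_um / tau) * (csc_factor if CSC)

an exponential decay chosen as the simplest monotone law; any monotone law
preserves the properties the analysis relies on. Central serous
chorioretinopathy (CSC) is modelled purely as extra multiplicative contrast
attenuation (melanin / subretinal-fluid obscuration), not as a lesion.

Cohort structure follows the clinical table the analysis assumes:
choroidal thickness ~ Normal(267, 100) um in normal eyes and
Normal(343, 96.4) um in CSC eyes, truncated to [100, 700] um.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.draw import line as _draw_line

from .exceptions import ParameterError
from .image_io import BinaryMask, FundusImage, write_cohort

#: (mean, sd) of choroidal thickness in um per group
THICKNESS_PARAMS = {"normal": (267.0, 100.0), "csc": (343.0, 96.4)}
#: truncation bounds of the thickness distribution, um
THICKNESS_BOUNDS = (100.0, 700.0)
#: (mean, sd) of age in years per group
AGE_PARAMS = {"normal": (60.4, 15.2), "csc": (57.2, 11.3)}
#: (mean, sd) of spherical-equivalent refractive error in dioptres per group
SERE_PARAMS = {"normal": (-1.19, 2.95), "csc": (-0.17, 2.28)}


@dataclass
class SyntheticSpec:
    """Rendering parameters of the synthetic eye.

    Defaults are desk-scale: a 256-px field keeps a 400-eye cohort cheap on
    one CPU while leaving the adaptive window (~13 px at this scale) wider
    than the vessels it must capture.
    """

    field_diameter_px: int = 256
    #: black frame margin around the circular field, px
    margin_px: int = 16
    #: background level per channel; R is kept low enough that unattenuated
    #: vessels (R + base_contrast) stay below the disc intensity
    background_rgb: tuple[int, int, int] = (170, 110, 60)
    n_choroidal_vessels: int = 6
    #: inclusive range of choroidal-vessel widths, px
    choroidal_width_px: tuple[int, int] = (5, 7)
    n_retinal_vessels: int = 7
    #: inclusive range of retinal-vessel widths, px
    retinal_width_px: tuple[int, int] = (3, 3)
    disc_radius_px: int = 18
    #: choroidal vessel contrast before attenuation, 8-bit levels; sized so
    #: unattenuated vessel interiors clear the adaptive offset C by several
    #: noise SDs even where local-mean suppression is strongest
    base_contrast: float = 65.0
    #: thickness scale of the visibility decay, um
    attenuation_tau_um: float = 300.0
    #: extra multiplicative attenuation applied to CSC eyes, in (0, 1]
    csc_extra_attenuation: float = 0.7
    #: depth of retinal vessels per channel (R, G, B), 8-bit levels
    retinal_depth_rgb: tuple[float, float, float] = (35.0, 70.0, 40.0)
    #: optic-disc intensity per channel (R, G, B)
    disc_rgb: tuple[int, int, int] = (250, 240, 225)
    #: sd of additive Gaussian pixel noise, 8-bit levels
    noise_sd: float = 2.0
    #: amplitude of the smooth background gradient, 8-bit levels
    gradient_amplitude: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_choroidal_vessels < 0 or self.n_retinal_vessels < 0:
            raise ParameterError("vessel counts must be >= 0")
        if self.attenuation_tau_um <= 0:
            raise ParameterError("attenuation_tau_um must be positive")
        if not (0 < self.csc_extra_attenuation <= 1):
            raise ParameterError("csc_extra_attenuation must be in (0, 1]")
        if self.field_diameter_px < 64:
            raise ParameterError("field_diameter_px must be >= 64")
        if 2 * self.disc_radius_px >= self.field_diameter_px:
            raise ParameterError("geometry error: optic disc does not fit the field")
        if max(self.choroidal_width_px) >= self.field_diameter_px // 4:
            raise ParameterError("geometry error: vessels too wide for the field")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping) -> "SyntheticSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown synthetic option(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in (
            "background_rgb", "choroidal_width_px", "retinal_width_px",
            "retinal_depth_rgb", "disc_rgb",
        ):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class SyntheticEye:
    """One rendered eye plus the ground truth that produced it."""

    image: FundusImage
    truth_choroid: BinaryMask
    truth_retinal: BinaryMask
    truth_disc: BinaryMask
    truth_fov: BinaryMask
    thickness_um: float
    group: str
    true_vessel_fraction: float


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _disk_struct(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def _polyline_mask(shape: tuple[int, int], points: np.ndarray, width: int) -> np.ndarray:
    """Boolean band: a polyline through ``points`` dilated to ``width`` px."""
    mask = np.zeros(shape, dtype=bool)
    pts = np.clip(np.rint(points).astype(int), [0, 0], [shape[0] - 1, shape[1] - 1])
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    radius = max(1, int(width) // 2)
    return ndimage.binary_dilation(mask, structure=_disk_struct(radius))


def _wiggly_path(
    rng: np.random.Generator,
    start: np.ndarray,
    end: np.ndarray,
    wiggle: float,
    n_ctrl: int = 8,
) -> np.ndarray:
    """Control points of a smoothed random-walk polyline from start to end."""
    t = np.linspace(0.0, 1.0, n_ctrl)
    base = start[None, :] * (1 - t)[:, None] + end[None, :] * t[:, None]
    direction = end - start
    norm = np.linalg.norm(direction)
    perp = np.array([-direction[1], direction[0]]) / (norm + 1e-9)
    offsets = rng.normal(0.0, wiggle, n_ctrl)
    offsets = np.convolve(offsets, [0.25, 0.5, 0.25], mode="same")
    offsets *= np.sin(np.pi * t)  # pinned at both ends
    return base + offsets[:, None] * perp[None, :]


def _soft_profile(band: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Band mask -> soft 0..1 intensity profile (anti-aliased edges)."""
    if not band.any():
        return np.zeros(band.shape, dtype=np.float64)
    prof = ndimage.gaussian_filter(band.astype(np.float64), sigma)
    return prof / prof.max()


def contrast_for(spec: SyntheticSpec, thickness_um: float, group: str) -> float:
    """Rendered choroidal-vessel contrast for one eye, 8-bit levels."""
    c = spec.base_contrast * float(np.exp(-thickness_um / spec.attenuation_tau_um))
    if group == "csc":
        c *= spec.csc_extra_attenuation
    return c


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def generate_eye(
    spec: SyntheticSpec,
    thickness_um: float,
    group: str = "normal",
    seed: int | None = None,
    eye_id: str = "synthetic",
) -> SyntheticEye:
    """Render one synthetic eye.

    Identical ``(spec, thickness_um, group, seed)`` give bit-identical
    output. The random geometry and noise do not depend on thickness or
    group, so eyes generated with the same seed differ only in vessel
    contrast — which is what makes attenuation monotonicity directly
    testable.
    """
    if thickness_um <= 0:
        raise ParameterError("thickness_um must be positive")
    if group not in THICKNESS_PARAMS:
        raise ParameterError(f"group must be one of {tuple(THICKNESS_PARAMS)}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    radius = spec.field_diameter_px / 2.0
    side = spec.field_diameter_px + 2 * spec.margin_px
    centre = np.array([side / 2.0, side / 2.0])
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    dist = np.hypot(yy - centre[0], xx - centre[1])
    fov = dist <= radius

    # smooth background gradient, independent per channel
    img = np.empty((side, side, 3), dtype=np.float64)
    for k in range(3):
        gy, gx = rng.uniform(-spec.gradient_amplitude, spec.gradient_amplitude, 2)
        img[..., k] = (
            spec.background_rgb[k]
            + gy * (yy - centre[0]) / radius
            + gx * (xx - centre[1]) / radius
        )

    # optic disc position (drawn last, but geometry fixed up front so the
    # rng stream is independent of vessel counts downstream of it)
    disc_angle = rng.uniform(0, 2 * np.pi)
    disc_centre = centre + 0.62 * radius * np.array([np.sin(disc_angle), np.cos(disc_angle)])
    disc_core = np.hypot(yy - disc_centre[0], xx - disc_centre[1]) <= spec.disc_radius_px

    # choroidal vessels: broad light bands in R only, laid out as roughly
    # parallel chords (the striped tigroid pattern); stratified offsets keep
    # bands from merging into blobs wider than any adaptive window
    choroid_band = np.zeros((side, side), dtype=bool)
    orient = rng.uniform(0, 2 * np.pi)
    tangent = np.array([np.sin(orient), np.cos(orient)])
    normal = np.array([-tangent[1], tangent[0]])
    n_ch = spec.n_choroidal_vessels
    for i in range(n_ch):
        frac = (i + rng.uniform(0.2, 0.8)) / max(n_ch, 1)
        d = (frac - 0.5) * 1.5 * radius
        half = 1.02 * np.sqrt(max(radius * radius - d * d, (0.2 * radius) ** 2))
        start = centre + d * normal - half * tangent
        end = centre + d * normal + half * tangent
        width = int(rng.integers(spec.choroidal_width_px[0], spec.choroidal_width_px[1] + 1))
        path = _wiggly_path(rng, start, end, wiggle=0.05 * radius)
        choroid_band |= _polyline_mask((side, side), path, width)
    # peripapillary ring: choroidal pattern is not visible flush against the
    # disc margin, which also preserves the disc's own edge contrast
    choroid_band &= ~ndimage.binary_dilation(disc_core, iterations=4)
    contrast = contrast_for(spec, thickness_um, group)
    img[..., 0] += contrast * _soft_profile(choroid_band, sigma=0.6)

    # retinal vessels: dark curves radiating from the disc, in all planes
    retinal_band = np.zeros((side, side), dtype=bool)
    for _ in range(spec.n_retinal_vessels):
        ang = rng.uniform(0, 2 * np.pi)
        target = centre + 1.05 * radius * np.array([np.sin(ang), np.cos(ang)])
        width = int(rng.integers(spec.retinal_width_px[0], spec.retinal_width_px[1] + 1))
        path = _wiggly_path(rng, disc_centre.copy(), target, wiggle=0.05 * radius)
        retinal_band |= _polyline_mask((side, side), path, width)
    ret_profile = _soft_profile(retinal_band, sigma=0.8)
    for k in range(3):
        img[..., k] -= spec.retinal_depth_rgb[k] * ret_profile

    # disc painted over everything
    disc_profile = _soft_profile(disc_core)
    for k in range(3):
        img[..., k] = img[..., k] * (1 - disc_profile) + spec.disc_rgb[k] * disc_profile

    # pixel noise inside the field; black frame outside
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img *= fov[..., None]
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # ground-truth partition with disc > choroid > retinal priority: at a
    # crossing the choroidal vessel exists beneath the retinal one, and the
    # infilling step deliberately reconstructs it, so the pixel is choroidal;
    # the retinal mask labels retinal vessel over plain background.
    truth_fov = BinaryMask(fov, "field_of_view")
    truth_disc = BinaryMask(disc_core & fov, "optic_disc")
    truth_choroid = BinaryMask(choroid_band & fov & ~disc_core, "choroidal_vessel")
    truth_retinal = BinaryMask(
        retinal_band & fov & ~disc_core & ~choroid_band, "retinal_vessel"
    )
    fraction = truth_choroid.count / truth_fov.count
    return SyntheticEye(
        image=FundusImage(pixels, eye_id=eye_id),
        truth_choroid=truth_choroid,
        truth_retinal=truth_retinal,
        truth_disc=truth_disc,
        truth_fov=truth_fov,
        thickness_um=float(thickness_um),
        group=group,
        true_vessel_fraction=float(fraction),
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_cohort_table(
    n_per_group: int,
    thickness_params: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample the tabular cohort (no images): thickness, age, refraction."""
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    params = thickness_params or THICKNESS_PARAMS
    rng = np.random.default_rng(seed)
    lo, hi = THICKNESS_BOUNDS
    rows = []
    for group in ("normal", "csc"):
        mean, sd = params[group]
        thick = _truncated_normal(rng, mean, sd, lo, hi, n_per_group)
        ages = rng.normal(*AGE_PARAMS[group], n_per_group)
        sere = rng.normal(*SERE_PARAMS[group], n_per_group)
        for i in range(n_per_group):
            rows.append(
                {
                    "eye_id": f"{group}_{i:04d}",
                    "group": group,
                    "choroidal_thickness_um": round(float(thick[i]), 1),
                    "age_years": round(float(np.clip(ages[i], 10, 95)), 1),
                    "sere_dioptre": round(float(sere[i]), 2),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(
    spec: SyntheticSpec,
    n_per_group: int = 200,
    thickness_params: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    out_csv: str | Path | None = None,
) -> tuple[list[SyntheticEye], pd.DataFrame]:
    """Generate a two-group cohort of rendered eyes plus its cohort table.

    Per-eye render seeds are spawned deterministically from ``seed``; a
    fixed seed therefore reproduces the cohort (and its CSV) byte for byte.
    """
    table = sample_cohort_table(n_per_group, thickness_params, seed)
    seed_seq = np.random.SeedSequence(seed)
    eye_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(len(table))]
    eyes = [
        generate_eye(
            spec,
            row.choroidal_thickness_um,
            row.group,
            seed=eye_seeds[i],
            eye_id=row.eye_id,
        )
        for i, row in enumerate(table.itertuples())
    ]
    if out_csv is not None:
        write_cohort(table, out_csv)
    return eyes, table


def iter_cohort(
    spec: SyntheticSpec,
    table: pd.DataFrame,
    seed: int = 0,
) -> Iterable[SyntheticEye]:
    """Lazily render the eyes of an existing cohort table (memory-friendly)."""
    seed_seq = np.random.SeedSequence(seed)
    eye_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(len(table))]
    for i, row in enumerate(table.itertuples()):
        yield generate_eye(
            spec, row.choroidal_thickness_um, row.group,
            seed=eye_seeds[i], eye_id=row.eye_id,
        )
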