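"""Synthetic screening-cohort generator.

Produces breast phantoms, renders raw (for-processing) mammogram-like
rasters through a two-compartment exponential-attenuation forward model,
and samples two-group cohorts (screen-detected vs interval cancer) whose
age, volumetric-breast-density (VBD) and mass-visibility marginals are
calibrated to a Dutch biennial screening sample: screen-detected exams at
median age 64 y (IQR 59-70) with median VBD 5.9% and an 82% visible-mass
rate; interval-cancer exams at median age 58 y (IQR 53-65) with median VBD
8.3% and a 55% visible-mass rate.

Breast background texture is a power-law (1/f^beta) random field; its
amplitude in the dense-thickness map grows with VBD so that density and
texture complexity co-vary, as in real breasts.  Lesions are Gaussian
bumps of dense-equivalent thickness inserted into the ipsilateral views of
visible-mass exams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, ParameterError, PlacementError

__all__ = [
    "TextureField",
    "Phantom",
    "RawImage",
    "GroupConfig",
    "AcquisitionConfig",
    "CohortConfig",
    "generate_texture",
    "make_phantom",
    "insert_lesion",
    "render_mammogram",
    "sample_cohort",
    "render_exam",
    "default_cohort_config",
    "SCREENING_AGE_RANGE",
]

#: Eligibility window of the screening programme (years).
SCREENING_AGE_RANGE = (50.0, 75.0)

VIEWS = ("CC", "MLO")
LATERALITIES = ("left", "right")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TextureField:
    """Zero-mean power-law random field standing in for breast texture."""

    pixels: np.ndarray
    beta: float
    sigma_tex: float
    seed: int


@dataclass
class Phantom:
    """Breast phantom ground truth: thickness and dense-thickness rasters."""

    breast_mask: np.ndarray          # bool
    thickness_map: np.ndarray        # mm
    dense_thickness_map: np.ndarray  # mm
    lesions: list = field(default_factory=list)  # (row, col, sigma_mm, amp_mm)
    pixel_pitch: float = 0.1         # mm / pixel

    @property
    def true_vbd(self) -> float:
        """Percent dense volume over the breast mask."""
        m = self.breast_mask
        return 100.0 * self.dense_thickness_map[m].sum() / self.thickness_map[m].sum()


@dataclass
class RawImage:
    """Rendered raw mammogram-like raster with acquisition metadata."""

    pixels: np.ndarray
    open_beam_true: float
    saturation_level: float
    pixel_pitch: float
    laterality: str = "left"
    view: str = "CC"


@dataclass(frozen=True)
class GroupConfig:
    """Marginal distributions for one outcome group."""

    n: int
    age_median: float
    age_iqr: tuple  # (q25, q75) years
    vbd_median: float
    vbd_iqr: tuple  # (q25, q75) percent
    visible_mass_prob: float
    lesion_amplitude_mm: float  # dense-equivalent mm at lesion center

    def __post_init__(self):
        if not 0.0 <= self.visible_mass_prob <= 1.0:
            raise ParameterError("visible_mass_prob must be in [0, 1]")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Forward-model and raster parameters shared by all rendered views."""

    image_shape: tuple = (512, 512)
    pixel_pitch: float = 0.1     # mm
    mu_fat: float = 0.05         # 1/mm
    mu_gland: float = 0.09       # 1/mm
    open_beam: float = 5000.0    # detector signal units
    saturation_level: float = 16383.0
    noise_frac: float = 0.001    # Gaussian noise sigma as fraction of open beam
    thickness_mm: float = 50.0   # uniform compressed-breast thickness
    beta: float = 3.0            # texture power-law exponent
    lesion_sigma_mm: float = 2.0


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of a two-group synthetic cohort."""

    screen_detected: GroupConfig
    interval: GroupConfig
    acquisition: AcquisitionConfig = AcquisitionConfig()
    seed: int = 0
    age_range: tuple = SCREENING_AGE_RANGE


def default_cohort_config(
    n_screen: int = 500,
    n_interval: int = 500,
    seed: int = 0,
    image_size: str = "full",
) -> CohortConfig:
    """Shipped default configuration, calibrated to the screening sample.

    ``image_size='small'`` selects 128x128 rasters at 0.4 mm pitch for
    fast repeated-cohort experiments; the cohort marginals are identical.
    """
    if image_size == "full":
        acq = AcquisitionConfig()
    elif image_size == "small":
        acq = AcquisitionConfig(image_shape=(128, 128), pixel_pitch=0.4)
    else:
        raise ParameterError(f"unknown image_size preset: {image_size!r}")
    return CohortConfig(
        screen_detected=GroupConfig(
            n=n_screen,
            age_median=64.0,
            age_iqr=(59.0, 70.0),
            vbd_median=5.9,
            vbd_iqr=(4.3, 8.8),
            visible_mass_prob=0.82,
            lesion_amplitude_mm=4.0,
        ),
        interval=GroupConfig(
            n=n_interval,
            age_median=58.0,
            age_iqr=(53.0, 65.0),
            vbd_median=8.3,
            vbd_iqr=(5.7, 14.2),
            visible_mass_prob=0.55,
            # harder-to-see lesion: present but lower contrast (category 3)
            lesion_amplitude_mm=2.0,
        ),
        acquisition=acq,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# texture and phantom construction
# ---------------------------------------------------------------------------

def generate_texture(
    shape: tuple, beta: float, sigma_tex: float, seed: int
) -> TextureField:
    """Synthesize an isotropic power-law texture by Fourier filtering.

    White Gaussian noise is filtered with the radial transfer function
    f^(-beta/2) (DC bin zeroed), giving a field whose power spectrum falls
    as f^(-beta).  The result is de-meaned and rescaled so the sample
    standard deviation equals ``sigma_tex`` exactly.
    """
    if sigma_tex <= 0:
        raise ParameterError("sigma_tex must be positive")
    if beta < 0:
        raise ParameterError("beta must be non-negative")
    ny, nx = shape
    if ny < 32 or nx < 32:
        raise ParameterError("shape must be at least 32x32")

    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    f = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        filt = np.where(f > 0, f ** (-beta / 2.0), 0.0)
    pix = np.fft.ifft2(np.fft.fft2(white) * filt).real
    pix -= pix.mean()
    sd = pix.std()
    if sd == 0:  # beta extremely large on tiny grids; never with valid input
        raise ConvergenceError("degenerate texture field")
    pix *= sigma_tex / sd
    return TextureField(pixels=pix, beta=beta, sigma_tex=sigma_tex, seed=seed)


def _breast_mask(shape: tuple, laterality: str = "left") -> np.ndarray:
    """Semi-elliptical breast outline with the chest wall at one edge."""
    ny, nx = shape
    rows = np.arange(ny)[:, None]
    cols = np.arange(nx)[None, :]
    a = 0.45 * ny   # vertical semi-axis
    b = 0.85 * nx   # horizontal semi-axis
    mask = ((cols / b) ** 2 + ((rows - ny / 2.0) / a) ** 2) <= 1.0
    if laterality == "right":
        mask = mask[:, ::-1]
    return mask


def make_phantom(
    acquisition: AcquisitionConfig,
    vbd_target: float,
    texture: TextureField,
    laterality: str = "left",
    texture_gain_mm: float | None = None,
) -> Phantom:
    """Build a phantom whose true VBD matches ``vbd_target``.

    The dense-thickness map is a clamped affine monotone map of the
    texture, ``t_d = clip(c + g * texture, 0, T)``; the offset ``c`` is
    solved by bisection so that the volumetric density over the mask hits
    the target to well below 0.1 percentage points.  The gain ``g`` grows
    with the density target (default ``0.1 * T * sqrt(vbd/10)``) so denser
    breasts also carry stronger texture.
    """
    if not 0.0 < vbd_target < 100.0:
        raise ParameterError("vbd_target must be in (0, 100)")
    T = acquisition.thickness_mm
    mask = _breast_mask(acquisition.image_shape, laterality)
    thickness = np.where(mask, T, 0.0)
    tex = texture.pixels
    if tex.shape != acquisition.image_shape:
        raise ParameterError("texture shape must match image shape")
    g = (
        texture_gain_mm
        if texture_gain_mm is not None
        else 0.1 * T * math.sqrt(vbd_target / 10.0)
    )
    tex_in = tex[mask]

    def vbd_of(c: float) -> float:
        td = np.clip(c + g * tex_in, 0.0, T)
        return 100.0 * td.sum() / (T * tex_in.size)

    lo, hi = -abs(g) * 10.0 - T, T + abs(g) * 10.0
    if not vbd_of(lo) <= vbd_target <= vbd_of(hi):
        raise ConvergenceError("vbd_target unreachable after clamping")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if vbd_of(mid) < vbd_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * T:
            break
    c = 0.5 * (lo + hi)
    if abs(vbd_of(c) - vbd_target) > 0.05:
        raise ConvergenceError(
            f"calibration residual {vbd_of(c) - vbd_target:+.3f} pp too large"
        )
    td = np.where(mask, np.clip(c + g * tex, 0.0, T), 0.0)
    return Phantom(
        breast_mask=mask,
        thickness_map=thickness,
        dense_thickness_map=td,
        pixel_pitch=acquisition.pixel_pitch,
    )


def insert_lesion(
    phantom: Phantom, center: tuple, sigma_les_mm: float, amplitude_mm: float
) -> Phantom:
    """Add a Gaussian dense-equivalent lesion; returns a new Phantom.

    ``amplitude_mm`` is the added dense thickness at the lesion center;
    the profile is exp(-r^2 / (2 sigma^2)) with sigma in mm.  The map is
    re-clamped to the physical thickness.
    """
    r0, c0 = center
    if not (
        0 <= int(round(r0)) < phantom.breast_mask.shape[0]
        and 0 <= int(round(c0)) < phantom.breast_mask.shape[1]
        and phantom.breast_mask[int(round(r0)), int(round(c0))]
    ):
        raise PlacementError(f"lesion center {center} outside breast mask")
    ny, nx = phantom.breast_mask.shape
    rows = np.arange(ny)[:, None]
    cols = np.arange(nx)[None, :]
    r2 = ((rows - r0) ** 2 + (cols - c0) ** 2) * phantom.pixel_pitch**2
    bump = amplitude_mm * np.exp(-r2 / (2.0 * sigma_les_mm**2))
    td = np.clip(phantom.dense_thickness_map + bump, 0.0, phantom.thickness_map)
    td = np.where(phantom.breast_mask, td, 0.0)
    return Phantom(
        breast_mask=phantom.breast_mask,
        thickness_map=phantom.thickness_map,
        dense_thickness_map=td,
        lesions=phantom.lesions + [(r0, c0, sigma_les_mm, amplitude_mm)],
        pixel_pitch=phantom.pixel_pitch,
    )


def render_mammogram(
    phantom: Phantom,
    acquisition: AcquisitionConfig,
    rng: np.random.Generator | None = None,
    laterality: str = "left",
    view: str = "CC",
) -> RawImage:
    """Render a raw image through the two-compartment attenuation model.

    Inside the breast the noiseless expectation is
    ``open_beam * exp(-mu_fat * (T - t_d) - mu_gland * t_d)``; outside it
    is the open beam itself.  Optional additive Gaussian noise with sigma
    ``noise_frac * open_beam``; the raster is clipped at the saturation
    level.
    """
    if not acquisition.mu_gland > acquisition.mu_fat > 0:
        raise ParameterError("require mu_gland > mu_fat > 0")
    T = phantom.thickness_map
    td = phantom.dense_thickness_map
    ob = acquisition.open_beam
    atten = np.exp(-acquisition.mu_fat * (T - td) - acquisition.mu_gland * td)
    expect = np.where(phantom.breast_mask, ob * atten, ob)
    if rng is not None and acquisition.noise_frac > 0:
        expect = expect + rng.normal(
            0.0, acquisition.noise_frac * ob, size=expect.shape
        )
    pixels = np.clip(expect, 0.0, acquisition.saturation_level)
    return RawImage(
        pixels=pixels,
        open_beam_true=ob,
        saturation_level=acquisition.saturation_level,
        pixel_pitch=acquisition.pixel_pitch,
        laterality=laterality,
        view=view,
    )


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _truncnorm_loc_for_median(
    target_median: float, sigma: float, lo: float, hi: float
) -> float:
    """Location parameter so the [lo, hi]-truncated normal median hits target.

    An asymmetric truncation window shifts the median away from the
    location parameter, so the location is solved numerically.
    """
    def med(loc: float) -> float:
        a, b = (lo - loc) / sigma, (hi - loc) / sigma
        return stats.truncnorm.ppf(0.5, a, b, loc=loc, scale=sigma)

    return optimize.brentq(
        lambda loc: med(loc) - target_median, lo - 5 * sigma, hi + 5 * sigma
    )


def _sample_truncnorm_median_iqr(
    rng: np.random.Generator,
    n: int,
    median: float,
    iqr: tuple,
    lo: float,
    hi: float,
) -> np.ndarray:
    sigma = (iqr[1] - iqr[0]) / (2.0 * stats.norm.ppf(0.75))
    loc = _truncnorm_loc_for_median(median, sigma, lo, hi)
    a, b = (lo - loc) / sigma, (hi - loc) / sigma
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sigma, size=n, random_state=rng)


def _sample_lognormal_median_iqr(
    rng: np.random.Generator, n: int, median: float, iqr: tuple
) -> np.ndarray:
    """Log-normal with the requested median and interquartile range.

    IQR = 2 * median * sinh(z75 * sigma) with z75 = Phi^-1(0.75), so sigma
    follows in closed form.
    """
    z75 = stats.norm.ppf(0.75)
    sigma = math.asinh((iqr[1] - iqr[0]) / (2.0 * median)) / z75
    x = rng.lognormal(mean=math.log(median), sigma=sigma, size=n)
    # physical VBD support; clipping the far tails does not move the median
    return np.clip(x, 0.5, 70.0)


def sample_cohort(config: CohortConfig) -> pd.DataFrame:
    """Sample per-exam cohort records for both groups.

    Returns a DataFrame with one row per examination: demographics, the
    drawn (ground-truth) VBD target, the visible-mass flag, cancer
    laterality, screening timing fields consumed by the reference-standard
    rules, and a per-exam rendering seed.  Images are rendered separately
    by :func:`render_exam` so that large cohorts can be sampled for
    calibration studies without paying the rendering cost.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    lo, hi = config.age_range
    frames = []
    for group_name, prefix in (("screen_detected", "SD"), ("interval", "IC")):
        gc: GroupConfig = getattr(config, group_name)
        if gc.n < 1:
            raise ParameterError("n per group must be >= 1")
        age = _sample_truncnorm_median_iqr(
            rng, gc.n, gc.age_median, gc.age_iqr, lo, hi
        )
        vbd = _sample_lognormal_median_iqr(rng, gc.n, gc.vbd_median, gc.vbd_iqr)
        visible = rng.random(gc.n) < gc.visible_mass_prob
        lat = np.where(rng.random(gc.n) < 0.5, "left", "right")
        if group_name == "screen_detected":
            months_dx = rng.integers(0, 13, size=gc.n)
        else:
            # time to interval-cancer diagnosis: median 13 months (IQR 7-19)
            m = _sample_truncnorm_median_iqr(
                rng, gc.n, 13.0, (7.0, 19.0), 0.0, 24.0
            )
            months_dx = np.rint(m).astype(int)
        months_prior = rng.integers(22, 27, size=gc.n)
        frames.append(
            pd.DataFrame(
                {
                    "exam_id": [f"{prefix}{i:06d}" for i in range(gc.n)],
                    "group": group_name,
                    "age": age,
                    "vbd": vbd,
                    "mass_visible": visible,
                    "cancer_laterality": lat,
                    "screen_result": (
                        "positive" if group_name == "screen_detected" else "negative"
                    ),
                    "months_to_diagnosis": months_dx,
                    "months_prior_negative": months_prior,
                    "cancer_invasiveness": "invasive",
                    "laterality_cancer": "unilateral",
                    "metachronous": False,
                    "first_round": False,
                    "implant": False,
                    "lesion_amplitude_mm": gc.lesion_amplitude_mm,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    n_total = len(records)
    seeds = [
        int(child.generate_state(1)[0] % (2**31))
        for child in np.random.SeedSequence(config.seed + 1).spawn(n_total)
    ]
    records["exam_seed"] = seeds
    return records


def render_exam(
    config: CohortConfig, record: pd.Series | dict
) -> dict[tuple[str, str], tuple[Phantom, RawImage]]:
    """Deterministically render the four views of one examination.

    Both lateralities x {CC, MLO}; a Gaussian lesion is inserted in both
    ipsilateral views of visible-mass exams.  Fully reproducible from the
    record's ``exam_seed``.
    """
    acq = config.acquisition
    rec = dict(record)
    ss = np.random.SeedSequence(int(rec["exam_seed"]))
    children = iter(ss.spawn(12))
    out = {}
    for lat in LATERALITIES:
        for view in VIEWS:
            tex_seed = int(next(children).generate_state(1)[0] % (2**31))
            texture = generate_texture(acq.image_shape, acq.beta, 1.0, tex_seed)
            phantom = make_phantom(acq, float(rec["vbd"]), texture, laterality=lat)
            if rec["mass_visible"] and lat == rec["cancer_laterality"]:
                place_rng = np.random.default_rng(next(children))
                center = _random_interior_point(
                    phantom, place_rng, margin_mm=3.0 * acq.lesion_sigma_mm
                )
                phantom = insert_lesion(
                    phantom, center, acq.lesion_sigma_mm,
                    float(rec["lesion_amplitude_mm"]),
                )
            noise_rng = np.random.default_rng(next(children))
            raw = render_mammogram(
                phantom, acq, rng=noise_rng, laterality=lat, view=view
            )
            out[(lat, view)] = (phantom, raw)
    return out


def _random_interior_point(
    phantom: Phantom, rng: np.random.Generator, margin_mm: float
) -> tuple:
    """Uniform random pixel inside the mask, away from the boundary."""
    from scipy import ndimage

    margin_px = max(1, int(round(margin_mm / phantom.pixel_pitch)))
    interior = ndimage.binary_erosion(
        phantom.breast_mask, iterations=margin_px
    )
    if not interior.any():
        interior = phantom.breast_mask
    rows, cols = np.nonzero(interior)
    k = rng.integers(len(rows))
    return int(rows[k]), int(cols[k])
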