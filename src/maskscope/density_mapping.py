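"""Open-beam self-calibration and volumetric breast density mapping.

A two-compartment (fat/gland) log-ratio estimator: given the unattenuated
open-beam signal, a uniform compressed thickness T and the linear
attenuation coefficients of fat and glandular tissue, each pixel's dense
thickness follows from inverting the exponential attenuation law.  The
open-beam signal is self-calibrated as the median of the unsaturated
background (non-breast) pixels; images whose background is saturated or
absent cannot be calibrated and are reported as failures, which propagate
to exam-level exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import MaskScopeError, ParameterError, SegmentationError
from .synthetic_cohort import RawImage

__all__ = [
    "DensityMap",
    "CalibrationResult",
    "estimate_open_beam",
    "segment_breast",
    "compute_density_map",
    "vbd_to_birads",
    "BIRADS_THRESHOLDS",
]

#: VBD percent cut points for BI-RADS-like categories A/B/C/D.
BIRADS_THRESHOLDS = (3.5, 7.5, 15.5)

#: Minimum unsaturated background fraction required for calibration.
MIN_BACKGROUND_FRACTION = 0.01


@dataclass
class DensityMap:
    """Per-pixel dense-tissue thickness (mm) and summary VBD (percent)."""

    dense_thickness: np.ndarray
    breast_mask: np.ndarray
    thickness: float | np.ndarray
    vbd: float


@dataclass(frozen=True)
class CalibrationResult:
    open_beam_estimate: float | None
    status: str  # "ok" | "failed_saturated" | "failed_no_background"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def estimate_open_beam(raw: RawImage, breast_mask: np.ndarray) -> CalibrationResult:
    """Self-calibrate the open-beam signal from the image background.

    Returns the median of unsaturated background pixels when at least 1%
    of the image area is unsaturated background; otherwise a failed
    status (``failed_no_background`` when there is no background at all,
    ``failed_saturated`` when the background is clipped).
    """
    if breast_mask.shape != raw.pixels.shape:
        raise ParameterError("mask shape does not match image")
    background = ~breast_mask
    if not background.any():
        return CalibrationResult(None, "failed_no_background")
    unsat = background & (raw.pixels < raw.saturation_level)
    if unsat.sum() < MIN_BACKGROUND_FRACTION * raw.pixels.size:
        return CalibrationResult(None, "failed_saturated")
    return CalibrationResult(float(np.median(raw.pixels[unsat])), "ok")


def segment_breast(raw: RawImage) -> np.ndarray:
    """Segment the breast as the largest connected attenuated region.

    Pixels clearly below the background plateau are thresholded at the
    midpoint between the raster's low and high levels; the largest
    connected component is kept and holes are filled.
    """
    pix = raw.pixels
    lo, hi = float(pix.min()), float(pix.max())
    if hi <= lo:
        raise SegmentationError("constant image: no breast found")
    attenuated = pix < 0.5 * (lo + hi)
    if not attenuated.any():
        raise SegmentationError("no attenuated pixels: empty segmentation")
    labels = measure.label(attenuated, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    return ndimage.binary_fill_holes(mask)


def compute_density_map(
    raw: RawImage,
    open_beam: float,
    mu_fat: float,
    mu_gland: float,
    thickness: float,
    breast_mask: np.ndarray | None = None,
) -> DensityMap:
    """Invert the attenuation law to a dense-thickness map and VBD.

    Per pixel inside the breast::

        t_d = (ln(open_beam / pixel) - mu_fat * T) / (mu_gland - mu_fat)

    clamped to [0, T]; VBD = 100 * sum(t_d) / sum(T) over the mask.
    """
    if open_beam <= 0:
        raise ParameterError("open_beam must be positive")
    if not mu_gland > mu_fat:
        raise ParameterError("require mu_gland > mu_fat")
    mask = segment_breast(raw) if breast_mask is None else breast_mask
    pix = raw.pixels
    if np.any(pix[mask] <= 0):
        raise MaskScopeError("non-positive pixel values inside breast mask")
    td = np.zeros_like(pix, dtype=float)
    td[mask] = (np.log(open_beam / pix[mask]) - mu_fat * thickness) / (
        mu_gland - mu_fat
    )
    td = np.clip(td, 0.0, thickness)
    td[~mask] = 0.0
    vbd = 100.0 * td[mask].sum() / (thickness * mask.sum())
    return DensityMap(
        dense_thickness=td, breast_mask=mask, thickness=thickness, vbd=float(vbd)
    )


def vbd_to_birads(vbd: float) -> str:
    """Map VBD percent to a BI-RADS-like density category A-D.

    Cut points 3.5 / 7.5 / 15.5 percent; a value exactly on a boundary is
    assigned to the higher category.
    """
    if not 0.0 <= vbd <= 100.0:
        raise ParameterError("vbd must be in [0, 100]")
    t1, t2, t3 = BIRADS_THRESHOLDS
    if vbd < t1:
        return "A"
    if vbd < t2:
        return "B"
    if vbd < t3:
        return "C"
    return "D"
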