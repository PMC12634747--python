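"""Model-observer detectability (d') maps.

The detectability index is the detection signal-to-noise ratio of a
prewhitening ideal observer for a known Gaussian lesion profile against
the local background texture:

    d'^2 = sum_{f != 0} |S(f)|^2 / NPS(f)

where S is the unitary DFT of the lesion signal and NPS the local noise
power spectrum estimated from a Hann-windowed, mean-subtracted region of
interest.  Evaluating d' on a stride-spaced grid of ROIs fully inside the
breast yields a detectability map; its spatial variation (standard
deviation over the map) is one of the masking-model features.

A non-prewhitening (NPW) observer is available behind a switch:
d'_NPW = sum|S|^2 / sqrt(sum |S|^2 NPS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .errors import MaskScopeError, ParameterError

__all__ = [
    "DetectabilityMap",
    "NpsResult",
    "gaussian_signal_spectrum",
    "local_nps",
    "radial_power_law_nps",
    "dprime",
    "detectability_map",
]


@dataclass
class DetectabilityMap:
    """d' values on a stride-spaced grid of ROI centers."""

    dprime_values: np.ndarray        # 1-D, row-major grid order
    locations: list                  # (row, col) ROI centers
    roi_size: int
    stride: int
    signal_spec: tuple               # (sigma_les_mm, amplitude)


@dataclass(frozen=True)
class NpsResult:
    nps: np.ndarray
    zero_variance: bool


def gaussian_signal_spectrum(
    amplitude: float, sigma_les_mm: float, roi_size: int, pixel_pitch: float
) -> np.ndarray:
    """Unitary DFT of a sampled Gaussian lesion profile (DC retained)."""
    if sigma_les_mm <= 0:
        raise ParameterError("sigma_les_mm must be positive")
    sigma_px = sigma_les_mm / pixel_pitch
    if roi_size < 8 * sigma_px:
        warnings.warn(
            "ROI smaller than 8 lesion sigmas: signal support is truncated",
            stacklevel=2,
        )
    c = (roi_size - 1) / 2.0
    r = np.arange(roi_size)
    r2 = (r[:, None] - c) ** 2 + (r[None, :] - c) ** 2
    signal = amplitude * np.exp(-r2 / (2.0 * sigma_px**2))
    return np.fft.fft2(signal, norm="ortho")


def local_nps(roi: np.ndarray) -> NpsResult:
    """Local noise power spectrum of one square ROI.

    Modulus-squared unitary DFT of the mean-subtracted, Hann-windowed ROI,
    rescaled so the mean over non-DC bins equals the window-weighted
    sample variance.  A constant ROI is flagged as zero-variance.
    """
    if roi.ndim != 2 or roi.shape[0] != roi.shape[1]:
        raise ParameterError("ROI must be square")
    n = roi.shape[0]
    x = roi - roi.mean()
    w = hann(n, sym=False)
    w2d = np.outer(w, w)
    wx = w2d * x
    wsv = float((wx**2).sum() / (w2d**2).sum())
    if wsv == 0.0:
        return NpsResult(np.zeros((n, n)), True)
    p = np.abs(np.fft.fft2(wx, norm="ortho")) ** 2
    nondc = np.ones((n, n), dtype=bool)
    nondc[0, 0] = False
    mean_nondc = p[nondc].mean()
    if mean_nondc == 0.0:
        return NpsResult(np.zeros((n, n)), True)
    return NpsResult(p * (wsv / mean_nondc), False)


def radial_power_law_nps(nps: np.ndarray) -> np.ndarray:
    """Regularize an NPS estimate by an isotropic power-law regression.

    The raw periodogram has chi-squared(2) fluctuations per bin that make
    the prewhitened d' statistic unstable, especially in the few
    low-frequency bins where a Gaussian lesion concentrates its energy.
    Under the isotropic power-law texture model the NPS is log-log linear
    in radial frequency, so the radially averaged profile is fitted by
    weighted least squares in log-log space and broadcast back to the full
    grid.  The DC bin keeps the fitted radius-1 value (it is excluded from
    d' anyway).  An all-zero (zero-variance) NPS passes through unchanged.
    """
    if nps.max() == 0.0:
        return nps
    n = nps.shape[0]
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(nps.shape[1])[None, :]
    ri = np.rint(np.hypot(fy, fx) * n).astype(int)
    sums = np.bincount(ri.ravel(), nps.ravel())
    cnts = np.bincount(ri.ravel())
    prof = sums / np.maximum(cnts, 1)
    rad = np.arange(len(prof))
    keep = (rad >= 1) & (prof > 0)
    if keep.sum() < 2:  # degenerate spectrum (e.g. single line): no fit
        return nps
    slope, logc = np.polyfit(
        np.log(rad[keep]), np.log(prof[keep]), 1, w=np.sqrt(cnts[keep])
    )
    return np.exp(logc) * np.maximum(ri, 1).astype(float) ** slope


def dprime(
    signal_spectrum: np.ndarray,
    nps: np.ndarray,
    floor_eps: float | None = None,
    observer: str = "pw",
) -> float:
    """Detection SNR of the model observer for one ROI.

    Prewhitening (default): d' = sqrt(sum_{non-DC} |S|^2 / max(NPS, eps)).
    ``floor_eps`` defaults to 1e-8 * max(NPS) and guards near-empty bins.
    """
    if signal_spectrum.shape != nps.shape:
        raise ParameterError("signal spectrum and NPS shapes differ")
    nps_max = float(nps.max())
    if floor_eps is None:
        floor_eps = 1e-8 * nps_max
    if floor_eps <= 0:
        if nps_max == 0.0:
            raise MaskScopeError("zero-variance NPS and no positive floor")
        floor_eps = 1e-8 * nps_max
    s2 = np.abs(signal_spectrum) ** 2
    denom = np.maximum(nps, floor_eps)
    nondc = np.ones(nps.shape, dtype=bool)
    nondc[0, 0] = False
    if observer == "pw":
        return float(np.sqrt((s2[nondc] / denom[nondc]).sum()))
    if observer == "npw":
        num = s2[nondc].sum()
        return float(num / np.sqrt((s2[nondc] * denom[nondc]).sum()))
    raise ParameterError(f"unknown observer: {observer!r}")


def detectability_map(
    image: np.ndarray,
    breast_mask: np.ndarray,
    roi_size: int = 128,
    stride: int = 64,
    sigma_les_mm: float = 2.0,
    amplitude: float = 1.0,
    pixel_pitch: float = 0.1,
    observer: str = "pw",
    nps_mode: str = "powerlaw",
) -> DetectabilityMap:
    """Evaluate d' over all grid ROIs fully inside the breast mask.

    ROIs are placed at stride-spaced top-left corners in row-major order;
    an ROI contributes only if every pixel lies inside the mask.  Raises
    when no valid location exists (breast too small for the ROI).

    ``nps_mode='powerlaw'`` (default) stabilizes each local NPS with
    :func:`radial_power_law_nps` before prewhitening; ``'raw'`` uses the
    windowed periodogram directly.
    """
    if nps_mode not in ("powerlaw", "raw"):
        raise ParameterError(f"unknown nps_mode: {nps_mode!r}")
    if image.shape != breast_mask.shape:
        raise ParameterError("image and mask shapes differ")
    ny, nx = image.shape
    spec = gaussian_signal_spectrum(amplitude, sigma_les_mm, roi_size, pixel_pitch)
    values, locations = [], []
    for r in range(0, ny - roi_size + 1, stride):
        for c in range(0, nx - roi_size + 1, stride):
            sub = breast_mask[r : r + roi_size, c : c + roi_size]
            if not sub.all():
                continue
            roi = image[r : r + roi_size, c : c + roi_size]
            nps = local_nps(roi).nps
            if nps_mode == "powerlaw":
                nps = radial_power_law_nps(nps)
            values.append(dprime(spec, nps, observer=observer))
            locations.append((r + roi_size // 2, c + roi_size // 2))
    if not values:
        raise MaskScopeError("no ROI fits inside the breast mask")
    return DetectabilityMap(
        dprime_values=np.asarray(values),
        locations=locations,
        roi_size=roi_size,
        stride=stride,
        signal_spec=(sigma_les_mm, amplitude),
    )
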