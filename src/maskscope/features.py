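"""Radiomic and clinical predictors of lesion masking.

The final masking model uses three predictors per examination: the
standard deviation of the detectability map, the Haralick correlation of
the gray-level co-occurrence matrix (GLCM) of the density map, and age.
Per-view values are averaged over the available views (both lateralities,
CC and MLO) of the examination; VBD is averaged likewise for the
density-only comparison analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detectability import DetectabilityMap
from .errors import MaskScopeError, ParameterError, ProcessingFailure

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "dmap_std",
    "quantize",
    "glcm",
    "glcm_correlation",
    "glcm_correlation_of_map",
    "extract_exam_features",
    "DEFAULT_OFFSETS",
]

#: Predictors consumed by the masking model, in canonical order.
FEATURE_NAMES = ("dmap_std", "glcm_correlation", "age")

#: Pixel-pair offsets averaged in the GLCM features (radiomics convention:
#: 0, 90, 45 and 135 degrees at distance 1).
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

N_GRAY_LEVELS = 32


@dataclass
class FeatureVector:
    exam_id: str
    dmap_std: float
    glcm_correlation: float
    age: float
    vbd: float
    n_views: int
    view_provenance: list = field(default_factory=list)


def dmap_std(dmap: DetectabilityMap | np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) of the d' map values."""
    values = np.asarray(
        dmap.dprime_values if isinstance(dmap, DetectabilityMap) else dmap,
        dtype=float,
    )
    if values.size < 2:
        raise ParameterError("need at least 2 detectability values")
    return float(values.std(ddof=1))


def quantize(
    raster: np.ndarray,
    n_levels: int = N_GRAY_LEVELS,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Linear quantization of a raster to integer levels [0, n_levels).

    The level edges span the in-mask value range; a constant raster maps
    to level 0 everywhere.
    """
    vals = raster[mask] if mask is not None else raster
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros(raster.shape, dtype=np.intp)
    q = np.floor((raster - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(q, 0, n_levels - 1)


def glcm(
    quantized: np.ndarray,
    offset: tuple,
    n_levels: int = N_GRAY_LEVELS,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized symmetric gray-level co-occurrence matrix at one offset.

    Counts pairs of quantized levels separated by ``offset`` (both pair
    members inside the mask when given), symmetrizes by adding the
    transposed counts, and normalizes to sum 1.
    """
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise ParameterError("offset must be nonzero")
    q = np.asarray(quantized)
    if q.min() < 0 or q.max() >= n_levels:
        raise ParameterError("quantized values must lie in [0, n_levels)")
    ny, nx = q.shape
    r0 = slice(max(0, -dr), min(ny, ny - dr))
    c0 = slice(max(0, -dc), min(nx, nx - dc))
    r1 = slice(max(0, dr), min(ny, ny + dr))
    c1 = slice(max(0, dc), min(nx, nx + dc))
    a = q[r0, c0].ravel()
    b = q[r1, c1].ravel()
    if mask is not None:
        keep = (mask[r0, c0] & mask[r1, c1]).ravel()
        a, b = a[keep], b[keep]
    if a.size == 0:
        raise MaskScopeError("no pixel pairs at this offset")
    counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
    p = counts.reshape(n_levels, n_levels).astype(float)
    p = p + p.T
    return p / p.sum()


def glcm_correlation(p: np.ndarray) -> float:
    """Haralick correlation of a normalized GLCM, in [-1, 1].

    sum_{i,j} (i - mu_i)(j - mu_j) p(i,j) / (sigma_i sigma_j); returns 0
    by convention when either marginal variance vanishes.
    """
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    i = np.arange(n)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = (i * pi).sum()
    mu_j = (i * pj).sum()
    var_i = ((i - mu_i) ** 2 * pi).sum()
    var_j = ((i - mu_j) ** 2 * pj).sum()
    if var_i <= 0 or var_j <= 0:
        return 0.0
    cov = ((i[:, None] - mu_i) * (i[None, :] - mu_j) * p).sum()
    return float(cov / np.sqrt(var_i * var_j))


def glcm_correlation_of_map(
    raster: np.ndarray,
    mask: np.ndarray | None = None,
    n_levels: int = N_GRAY_LEVELS,
    offsets: tuple = DEFAULT_OFFSETS,
) -> float:
    """GLCM correlation of a density map, averaged over the offset set."""
    q = quantize(raster, n_levels, mask)
    return float(
        np.mean([glcm_correlation(glcm(q, off, n_levels, mask)) for off in offsets])
    )


def extract_exam_features(
    view_features: list[dict], exam_id: str, age: float
) -> FeatureVector:
    """Average per-view features over the successfully processed views.

    ``view_features`` holds one dict per surviving view with keys
    ``dmap_std``, ``glcm_correlation``, ``vbd`` and (optionally) ``view``.
    Raises :class:`ProcessingFailure` when no view survived calibration,
    mirroring exam-level exclusion from the analysis.
    """
    views = [v for v in view_features if v is not None]
    if not views:
        raise ProcessingFailure(
            "all_views_failed", f"exam {exam_id}: no processable view"
        )
    return FeatureVector(
        exam_id=exam_id,
        dmap_std=float(np.mean([v["dmap_std"] for v in views])),
        glcm_correlation=float(np.mean([v["glcm_correlation"] for v in views])),
        age=float(age),
        vbd=float(np.mean([v["vbd"] for v in views])),
        n_views=len(views),
        view_provenance=[v.get("view") for v in views],
    )
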