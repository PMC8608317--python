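"""Edge matching and the Hazard Visibility Score (HVS).

Each ground-truth geometry pixel is matched to its nearest luminance
boundary pixel; the pixel separation is mapped to a 0-1 visibility score
that falls off with distance, and the HVS of a region of interest is the
mean score over the geometry pixels inside it.  A score of 1 means the
luminance evidence coincides with the geometry; 0 means no luminance
boundary lies within the falloff range.

Distances are computed in pixels (exact Euclidean distance transform), but
the falloff scale is specified in degrees of visual angle so scores are
invariant to the image's angular resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .boundaries import EdgeMap
from .exceptions import ConfigurationError, EmptyROIError, InvalidInputError
from .filtering import LuminanceImage
from .scene import ROIMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringParams:
    """Distance-to-score mapping parameters.

    ``d_max_deg`` is the visual angle at which visibility reaches zero
    (default 0.5°); ``kernel`` selects the monotone falloff: ``"linear"``
    (1 - d/d_max, the default) or ``"gaussian"`` (exp(-(d/d_max)^2 * ln 4),
    reaching 0.5 at half the falloff range and never exactly zero).
    """

    d_max_deg: float = 0.5
    kernel: str = "linear"

    def __post_init__(self) -> None:
        if self.d_max_deg <= 0:
            raise ConfigurationError("d_max_deg must be > 0")
        if self.kernel not in ("linear", "gaussian"):
            raise ConfigurationError(f"unknown kernel {self.kernel!r}")


@dataclass(frozen=True)
class VisibilityResult:
    """Per-geometry-pixel match distances and scores, plus ROI summaries.

    ``distances``/``scores`` are full-image grids that are meaningful only
    where ``geometry`` is set; ``hvs`` maps ROI label -> mean score over
    geometry pixels inside that ROI.
    """

    geometry: np.ndarray
    distances: np.ndarray
    scores: np.ndarray
    hvs: dict
    params: ScoringParams
    ppd: float


def nearest_boundary_distances(geometry: EdgeMap, boundaries: EdgeMap) -> np.ndarray:
    """Euclidean distance from each geometry pixel to the nearest boundary.

    Returns a full-image grid: at geometry pixels it holds the distance (in
    pixels) to the nearest luminance-boundary pixel, elsewhere NaN.  If the
    boundary map is empty every geometry pixel gets +inf.
    """
    if geometry.shape != boundaries.shape:
        raise InvalidInputError(
            f"shape mismatch: geometry {geometry.shape} vs boundaries {boundaries.shape}"
        )
    out = np.full(geometry.shape, np.nan)
    if boundaries.n_pixels == 0:
        out[geometry.mask] = np.inf
        return out
    # exact EDT of the complement: distance to the nearest boundary pixel
    dist = ndi.distance_transform_edt(~boundaries.mask)
    out[geometry.mask] = dist[geometry.mask]
    return out


def score_from_distance(
    d, ppd: float, params: ScoringParams = ScoringParams()
) -> np.ndarray | float:
    """Map pixel separations to 0-1 visibility scores.

    The falloff range ``d_max_deg`` is converted to pixels via ``ppd``;
    distances at or beyond it (including the +inf no-boundary sentinel)
    score 0.  NaN (non-geometry) passes through as NaN.
    """
    if ppd <= 0:
        raise InvalidInputError("ppd must be > 0")
    d = np.asarray(d, dtype=float)
    if np.any(d[np.isfinite(d)] < 0):
        raise InvalidInputError("distances must be >= 0")
    d_max_px = params.d_max_deg * ppd
    if params.kernel == "linear":
        score = np.clip(1.0 - d / d_max_px, 0.0, 1.0)
    else:
        score = np.exp(-((d / d_max_px) ** 2) * np.log(4.0))
    score = np.where(np.isposinf(d), 0.0, score)
    score = np.where(np.isnan(d), np.nan, score)
    if score.ndim == 0:
        return float(score)
    return score


def hazard_visibility_score(
    scores: np.ndarray, geometry: EdgeMap, roi: ROIMask
) -> float:
    """Mean visibility score over geometry pixels inside the ROI.

    Raises :class:`EmptyROIError` when the ROI contains no geometry pixels
    (a silent zero would be indistinguishable from "present but invisible").
    """
    if scores.shape != geometry.shape or roi.mask.shape != geometry.shape:
        raise InvalidInputError("scores, geometry and ROI must share one grid")
    sel = geometry.mask & roi.mask
    if not sel.any():
        raise EmptyROIError(f"ROI {roi.label!r} contains no geometry pixels")
    return float(np.mean(scores[sel]))


def match_visibility(
    geometry: EdgeMap,
    boundaries: EdgeMap,
    rois: dict,
    ppd: float,
    params: ScoringParams = ScoringParams(),
) -> VisibilityResult:
    """Full matching pass: distances, scores, and HVS per ROI.

    ROIs whose intersection with the geometry is empty are skipped with a
    log notice rather than aborting the scene.
    """
    distances = nearest_boundary_distances(geometry, boundaries)
    scores = score_from_distance(distances, ppd, params)
    hvs = {}
    for label, roi in rois.items():
        try:
            hvs[label] = hazard_visibility_score(scores, geometry, roi)
        except EmptyROIError:
            logger.info("ROI %r has no geometry pixels; no HVS emitted", label)
    return VisibilityResult(
        geometry=geometry.mask.copy(),
        distances=distances,
        scores=scores,
        hvs=hvs,
        params=params,
        ppd=ppd,
    )


def render_visibility_overlay(
    luminance: LuminanceImage, result: VisibilityResult
) -> np.ndarray:
    """Red-to-green visibility overlay on the grayscale scene.

    Geometry pixels are colored on a linear ramp from red (score 0, poor
    match) to green (score 1, good match); everything else shows the
    normalized luminance in gray.  Returns an (H, W, 3) float array in
    [0, 1].
    """
    if luminance.shape != result.geometry.shape:
        raise InvalidInputError("luminance and result grids must be aligned")
    vmax = luminance.values.max()
    gray = luminance.values / vmax if vmax > 0 else luminance.values
    rgb = np.repeat(gray[..., None], 3, axis=2)
    sel = result.geometry
    s = np.nan_to_num(result.scores[sel], nan=0.0)
    rgb[sel] = np.stack([1.0 - s, s, np.zeros_like(s)], axis=1)
    return np.clip(rgb, 0.0, 1.0)
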