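"""Luminance-boundary extraction via Canny edge detection.

Edges are detected on a max-normalized copy of the (typically low-vision
filtered) luminance image, so the map depends only on relative luminance
structure: multiplying all luminances by a positive constant leaves the
result unchanged.  Hysteresis thresholds are expressed as fractions of the
maximum gradient magnitude of the smoothed normalized image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import feature

from .exceptions import InvalidInputError
from .filtering import LuminanceImage


@dataclass(frozen=True)
class EdgeMap:
    """A binary edge mask aligned to a source image.

    ``source`` records whether the edges are luminance boundaries or
    ground-truth geometric edges; ``params`` records how they were made.
    """

    mask: np.ndarray
    source: str = "luminance"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 2:
            raise InvalidInputError("edge mask must be 2-D")
        if mask.dtype != bool:
            if not np.isin(mask, (0, 1)).all():
                raise InvalidInputError("edge mask must be binary")
            mask = mask.astype(bool)
        object.__setattr__(self, "mask", mask)
        if self.source not in ("luminance", "geometry"):
            raise InvalidInputError(f"unknown edge source {self.source!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.mask))

    def params_json(self) -> str:
        """Extraction parameters as a JSON record for reproducibility."""
        return json.dumps({"source": self.source, **self.params}, sort_keys=True)


def _max_gradient(values: np.ndarray, sigma: float, percentile: float = 99.5) -> float:
    """Robust maximum Sobel gradient of the max-normalized, smoothed image.

    A high percentile rather than the absolute maximum: HDR scenes contain
    isolated photometric hot spots (a light's closest approach to a
    surface) whose gradient can dwarf every structural edge; an absolute
    max would push the hysteresis thresholds past genuinely high-contrast
    boundaries.
    """
    vmax = values.max()
    if vmax <= 0:
        return 0.0
    smoothed = ndi.gaussian_filter(values / vmax, sigma, mode="nearest")
    grad = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
    return float(np.percentile(grad, percentile))


def detect_luminance_boundaries(
    img: LuminanceImage,
    sigma: float = 1.0,
    low_frac: float = 0.1,
    high_frac: float = 0.2,
    reference: LuminanceImage | None = None,
) -> EdgeMap:
    """Detect luminance boundaries with the Canny operator.

    The luminance grid is normalized to [0, 1] by its maximum, smoothed with
    a Gaussian of ``sigma`` pixels, and thresholded with hysteresis at
    ``low_frac`` and ``high_frac`` times the maximum Sobel gradient
    magnitude of the smoothed image.  A constant image yields an empty edge
    map rather than an error.

    When ``reference`` is given, the threshold scale comes from *its* max
    gradient instead of the input's.  The pipeline uses the unfiltered
    scene as the reference when detecting edges on a low-vision-filtered
    image: the detection criterion then stays fixed as vision worsens, so
    removing image content can only remove boundaries (without a fixed
    reference, stripping the strongest edge would lower the adaptive
    thresholds and could re-admit weak edges).
    """
    if not 0 < low_frac < high_frac <= 1:
        raise InvalidInputError("need 0 < low_frac < high_frac <= 1")
    if sigma <= 0:
        raise InvalidInputError("sigma must be > 0")
    params = {"sigma": sigma, "low_frac": low_frac, "high_frac": high_frac}
    values = img.values
    vmax = values.max()
    if vmax <= 0:
        return EdgeMap(np.zeros(values.shape, dtype=bool), "luminance", params)
    norm = values / vmax
    gmax = _max_gradient((reference or img).values, sigma)
    params["reference"] = "external" if reference is not None else "self"
    if gmax <= 0:
        return EdgeMap(np.zeros(values.shape, dtype=bool), "luminance", params)
    mask = feature.canny(
        norm,
        sigma=sigma,
        low_threshold=low_frac * gmax,
        high_threshold=high_frac * gmax,
    )
    return EdgeMap(mask, "luminance", params)
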