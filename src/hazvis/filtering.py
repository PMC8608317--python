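"""CSF-based low-vision filtering of luminance images.

The filter simulates what survives an observer's contrast thresholds: the
image is decomposed into octave-spaced band-pass components (a cosine-log
filter bank in the frequency domain), each band is converted to band-limited
local contrast (band / low-pass), and contrast below the observer's
threshold at that band's center frequency is discarded.  Bands centered at
or above the CSF cutoff are removed entirely.  The output is resynthesized
from the retained content plus the low-pass baseband, so the coarse
luminance structure of the scene is always preserved while subthreshold
detail vanishes — a luminance image "as seen" through the clinical
parameters.

All operations work on linear luminance (cd/m²).  Mirror padding is applied
before the frequency-domain filtering to suppress wraparound artefacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError
from .vision import CSF, contrast_threshold

logger = logging.getLogger(__name__)

#: Floor for low-pass luminance in contrast denominators (cd/m²).
LUMINANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class LuminanceImage:
    """A 2-D luminance map with angular-resolution metadata.

    Attributes
    ----------
    values : ndarray
        Luminance in cd/m², finite and >= 0.
    ppd : float
        Pixels per degree of visual angle.
    provenance : str
        ``"synthetic"`` or ``"loaded"``.
    """

    values: np.ndarray
    ppd: float
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise InvalidInputError("luminance grid must be non-empty and 2-D")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("luminance values must be finite")
        if np.any(values < 0):
            raise InvalidInputError("luminance values must be >= 0")
        if self.ppd <= 0:
            raise InvalidInputError("ppd must be > 0")
        if self.provenance not in ("synthetic", "loaded"):
            raise InvalidInputError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nyquist(self) -> float:
        """Highest representable spatial frequency, cycles/degree."""
        return self.ppd / 2.0


@dataclass(frozen=True)
class BandStack:
    """Octave-spaced band-pass decomposition of a luminance image.

    ``bands[k]`` holds the band image centered at ``centers[k]`` cpd
    (ascending); ``lowpasses[k]`` is the corresponding low-pass image
    containing only content below that band, used as the local-contrast
    denominator.  ``baseband`` is the residual low-pass; by construction
    ``baseband + sum(bands)`` reconstructs the input exactly.
    """

    bands: tuple[np.ndarray, ...]
    centers: tuple[float, ...]
    lowpasses: tuple[np.ndarray, ...]
    baseband: np.ndarray
    octave_spacing: float
    ppd: float

    def reconstruct(self) -> np.ndarray:
        out = self.baseband.copy()
        for b in self.bands:
            out = out + b
        return out


def _cosine_log_response(
    f: np.ndarray, center: float, spacing: float, highpass_top: bool = False
) -> np.ndarray:
    """Cosine-log band-pass response on a radial frequency grid.

    Half-cosine in log2 frequency, full support ``spacing`` octaves to each
    side of ``center``; adjacent responses at that spacing sum to 1.  The
    highest band of the bank is built with ``highpass_top=True``: its
    response stays at 1 above its center so that all content up to Nyquist
    belongs to some band (and is therefore subject to thresholding) rather
    than leaking into the low-pass residual.
    """
    out = np.zeros_like(f)
    pos = f > 0
    d = np.log2(f[pos] / center) / spacing
    vals = np.zeros(d.shape)
    inside = np.abs(d) < 1.0
    vals[inside] = 0.5 * (1.0 + np.cos(np.pi * d[inside]))
    if highpass_top:
        vals[d >= 0.0] = 1.0
    out[pos] = vals
    return out


def _lowpass_response(f: np.ndarray, center: float, spacing: float) -> np.ndarray:
    """Complementary low-pass response: 1 below the band, tapering to 0 at
    the band center (the cumulative sum of all lower cosine-log bands plus
    the base low-pass)."""
    out = np.zeros_like(f)
    pos = f > 0
    d = np.log2(f[pos] / center) / spacing  # 0 at center, -1 one band below
    vals = np.zeros(d.shape)
    vals[d <= -1.0] = 1.0
    ramp = (d > -1.0) & (d < 0.0)
    vals[ramp] = 0.5 * (1.0 - np.cos(np.pi * d[ramp]))
    out[pos] = vals
    out[~pos] = 1.0  # DC passes
    return out


def _radial_frequency_grid(shape: tuple[int, int], ppd: float) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0]) * ppd
    fx = np.fft.fftfreq(shape[1]) * ppd
    return np.hypot(fy[:, None], fx[None, :])


def default_band_centers(
    img: LuminanceImage, octave_spacing: float = 1.0, n_bands: int | None = None
) -> tuple[float, ...]:
    """Ascending band-center frequencies for an image.

    The top center sits one spacing below Nyquist so the band's support
    stays representable; centers descend in steps of ``octave_spacing``
    octaves.  With ``n_bands=None`` the bank extends down to roughly four
    cycles per image (coarser structure stays in the baseband).
    """
    top = img.nyquist / 2.0**octave_spacing
    if n_bands is None:
        f_min = 4.0 * img.ppd / min(img.shape)
        if f_min >= top:
            n_bands = 1
        else:
            n_bands = int(math.floor(math.log2(top / f_min) / octave_spacing)) + 1
    centers = [top / 2.0 ** (octave_spacing * k) for k in range(n_bands)]
    return tuple(sorted(centers))


def decompose_bands(
    img: LuminanceImage,
    octave_spacing: float = 1.0,
    n_bands: int | None = None,
    pad: bool = True,
) -> BandStack:
    """Decompose a luminance image into a cosine-log band-pass pyramid.

    Parameters
    ----------
    img : LuminanceImage
        Input image.
    octave_spacing : float
        Spacing between band centers in octaves (default 1).
    n_bands : int, optional
        Number of bands; the default covers four cycles/image up to half
        Nyquist.  A configuration error is raised if the requested bank
        would place a center above Nyquist.
    pad : bool
        Mirror-pad before the FFT (default) to suppress wraparound.

    Returns
    -------
    BandStack
        Bands, per-band low-pass images, and the residual baseband; the sum
        of bands plus baseband reconstructs the input exactly.
    """
    if octave_spacing <= 0:
        raise ConfigurationError("octave_spacing must be > 0")
    centers = default_band_centers(img, octave_spacing, n_bands)
    if centers[-1] > img.nyquist:
        raise ConfigurationError(
            f"highest band center {centers[-1]:.3g} cpd exceeds Nyquist {img.nyquist:.3g} cpd"
        )
    one_cycle = img.ppd / max(img.shape)
    if centers[0] < one_cycle:
        raise ConfigurationError(
            f"lowest band center {centers[0]:.3g} cpd is below one cycle per "
            f"image ({one_cycle:.3g} cpd); reduce n_bands"
        )
    values = img.values
    if pad:
        py, px = values.shape[0] // 2, values.shape[1] // 2
        padded = np.pad(values, ((py, py), (px, px)), mode="reflect")
    else:
        py = px = 0
        padded = values
    f = _radial_frequency_grid(padded.shape, img.ppd)
    spectrum = np.fft.fft2(padded)
    bands = []
    lowpasses = []
    for c in centers:
        response = _cosine_log_response(
            f, c, octave_spacing, highpass_top=(c == centers[-1])
        )
        band = np.real(np.fft.ifft2(spectrum * response))
        low = np.real(np.fft.ifft2(spectrum * _lowpass_response(f, c, octave_spacing)))
        sl = (slice(py, py + values.shape[0]), slice(px, px + values.shape[1]))
        bands.append(band[sl])
        lowpasses.append(low[sl])
    baseband = values - np.sum(bands, axis=0)
    return BandStack(
        bands=tuple(bands),
        centers=tuple(centers),
        lowpasses=tuple(lowpasses),
        baseband=baseband,
        octave_spacing=octave_spacing,
        ppd=img.ppd,
    )


def band_contrast(
    band: np.ndarray, lowpass: np.ndarray, floor: float = LUMINANCE_FLOOR
) -> np.ndarray:
    """Band-limited local contrast: band divided by the low-pass luminance.

    The denominator is floored at ``floor`` cd/m² so the ratio stays finite
    in dark regions; the floor is logged once per call when it engages.
    """
    if band.shape != lowpass.shape:
        raise InvalidInputError("band and lowpass grids must be aligned")
    floored = np.maximum(lowpass, floor)
    n_floored = int(np.count_nonzero(lowpass < floor))
    if n_floored:
        logger.info("band_contrast: %d low-pass pixels floored at %.1e cd/m²", n_floored, floor)
    return band / floored


@dataclass(frozen=True)
class FilterConfig:
    """Settings for :func:`apply_lowvision_filter`.

    ``soft_threshold=True`` (the default) ramps band retention linearly
    from zero at threshold to full at twice threshold instead of a binary
    keep/zero decision.  The hard threshold is available but its
    discontinuity fragments band content around the threshold contour,
    which destabilizes downstream edge detection.
    """

    octave_spacing: float = 1.0
    n_bands: int | None = None
    soft_threshold: bool = True
    log_luminance: bool = False
    luminance_floor: float = LUMINANCE_FLOOR


def apply_lowvision_filter(
    img: LuminanceImage, csf: CSF, config: FilterConfig = FilterConfig()
) -> LuminanceImage:
    """Threshold an image by the observer's CSF, keeping only visible content.

    For each band, pixels whose band-limited contrast magnitude falls below
    the observer's threshold at the band's center frequency contribute
    nothing; bands centered at or above the CSF cutoff are removed outright.
    The output is the baseband plus the retained band content, clamped at
    zero luminance.

    With the default ``soft_threshold=True`` retention ramps linearly from
    0 at threshold to full at twice threshold; ``soft_threshold=False``
    gives the binary keep/zero variant.  In ``log_luminance`` mode the
    decomposition runs on log10 luminance (with the configured floor) and
    the result is exponentiated back.
    """
    work = img
    if config.log_luminance:
        work = LuminanceImage(
            np.log10(np.maximum(img.values, config.luminance_floor)) + 12.0,
            img.ppd,
            img.provenance,
        )  # offset keeps values positive for the container invariant
    stack = decompose_bands(work, config.octave_spacing, config.n_bands)
    out = stack.baseband.copy()
    kept_total = 0
    for band, center, lowpass in zip(stack.bands, stack.centers, stack.lowpasses):
        if center >= csf.cutoff_frequency:
            continue
        thr = contrast_threshold(csf, center)
        if thr >= 1.0:
            continue
        contrast = band_contrast(band, lowpass, config.luminance_floor)
        mag = np.abs(contrast)
        if config.soft_threshold:
            gain = np.clip((mag - thr) / max(thr, np.finfo(float).tiny), 0.0, 1.0)
        else:
            gain = (mag >= thr).astype(float)
        kept_total += int(np.count_nonzero(gain > 0))
        out = out + band * gain
    logger.info(
        "low-vision filter: cutoff %.2f cpd, %d above-threshold band pixels retained",
        csf.cutoff_frequency,
        kept_total,
    )
    if config.log_luminance:
        out = np.power(10.0, out - 12.0)
    return LuminanceImage(np.maximum(out, 0.0), img.ppd, img.provenance)


def count_suprathreshold_pixels(
    img: LuminanceImage, csf: CSF, config: FilterConfig = FilterConfig()
) -> int:
    """Number of band pixels above the observer's contrast threshold.

    A scalar summary of how much oscillatory content the observer retains;
    monotonically non-increasing as acuity worsens (thresholds only rise and
    the cutoff only falls).
    """
    stack = decompose_bands(img, config.octave_spacing, config.n_bands)
    total = 0
    for band, center, lowpass in zip(stack.bands, stack.centers, stack.lowpasses):
        if center >= csf.cutoff_frequency:
            continue
        thr = contrast_threshold(csf, center)
        if thr >= 1.0:
            continue
        mag = np.abs(band_contrast(band, lowpass, config.luminance_floor))
        total += int(np.count_nonzero(mag >= thr))
    return total
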