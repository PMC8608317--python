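"""Clinical vision parameters and the contrast sensitivity function (CSF).

The observer is described by two routine clinical measures: letter acuity in
logMAR units (0 = 20/20; larger is worse) and Pelli-Robson contrast
sensitivity (log10 sensitivity; larger is better).  From these a parametric
CSF is built — sensitivity ``S(f)`` (the reciprocal of Michelson threshold
contrast) as a function of spatial frequency ``f`` in cycles/degree.  The
low-vision CSF is modelled as the normal-shape template rigidly shifted on
the log-frequency and log-sensitivity axes:

* the high-frequency cutoff (where threshold contrast reaches 100%) is
  anchored to acuity as ``f_cut = f0 * 10**(-acuity)`` with ``f0 = 30`` cpd
  at logMAR 0 (the standard letter-acuity correspondence of 30 cpd for a
  20/20 observer);
* the height of the curve is anchored to the Pelli-Robson score, by default
  at the curve's peak: ``S_peak = 10**CS``.  Pelli-Robson letters are large,
  low-frequency stimuli, so the chart score is read as the observer's best
  (peak) log sensitivity.  An alternative anchoring mode pins ``S`` at a
  fixed reference frequency instead; it is only satisfiable while that
  frequency lies below the cutoff.

The template is a truncated log-parabola: flat at the peak sensitivity below
the peak frequency and parabolic in (log f, log S) above it, reaching S = 1
exactly at the cutoff.  The low-frequency plateau reflects that a static
luminance image's coarse structure is not attenuated in this model; the full
two-sided parabola can be enabled via ``low_frequency_plateau=False``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

#: Linear relation from logMAR acuity to Pelli-Robson contrast sensitivity,
#: CS = CS_FROM_ACUITY_INTERCEPT + CS_FROM_ACUITY_SLOPE * VA, an empirical
#: regression on clinical data (R^2 ~ 0.5), used when the chart cannot be
#: administered (very low acuity makes the fixed-size letters unresolvable).
CS_FROM_ACUITY_INTERCEPT = 1.72
CS_FROM_ACUITY_SLOPE = -0.69

#: Cutoff spatial frequency (cpd) of a logMAR-0 observer.
DEFAULT_F0 = 30.0

#: Validated clinical range; values outside warn but are accepted.
ACUITY_RANGE = (-0.3, 2.5)
CS_RANGE = (0.0, 2.5)


def infer_cs_from_acuity(acuity: float) -> float:
    """Estimate Pelli-Robson contrast sensitivity from logMAR acuity.

    Applies the empirical linear relation ``CS = 1.72 - 0.69 * VA``, clamped
    below at 0 (a negative log sensitivity is not meaningful on the chart).

    Parameters
    ----------
    acuity : float
        Visual acuity in logMAR units.

    Returns
    -------
    float
        Estimated Pelli-Robson log contrast sensitivity.
    """
    if not math.isfinite(acuity):
        raise InvalidInputError(f"acuity must be finite, got {acuity!r}")
    return max(0.0, CS_FROM_ACUITY_INTERCEPT + CS_FROM_ACUITY_SLOPE * acuity)


def propagate_acuity_sd(acuity_sd: float) -> float:
    """Standard deviation of inferred CS for a given acuity SD.

    The CS-from-acuity relation is linear, so an acuity spread maps to a CS
    spread of ``|slope| * sd``.
    """
    if not math.isfinite(acuity_sd) or acuity_sd < 0:
        raise InvalidInputError(f"acuity_sd must be finite and >= 0, got {acuity_sd!r}")
    return abs(CS_FROM_ACUITY_SLOPE) * acuity_sd


@dataclass(frozen=True)
class VisionParams:
    """Clinical vision parameters of one observer.

    Attributes
    ----------
    acuity : float
        logMAR visual acuity.
    contrast_sensitivity : float
        Pelli-Robson log10 contrast sensitivity.
    cs_source : str
        ``"measured"`` if CS came from the chart, ``"inferred-from-acuity"``
        if it was estimated via :func:`infer_cs_from_acuity`.
    """

    acuity: float
    contrast_sensitivity: float
    cs_source: str = "measured"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.acuity) and math.isfinite(self.contrast_sensitivity)):
            raise InvalidInputError("acuity and contrast_sensitivity must be finite")
        if self.contrast_sensitivity < 0:
            raise InvalidInputError("contrast_sensitivity must be >= 0")
        if self.cs_source not in ("measured", "inferred-from-acuity"):
            raise InvalidInputError(f"unknown cs_source {self.cs_source!r}")
        if not ACUITY_RANGE[0] <= self.acuity <= ACUITY_RANGE[1]:
            warnings.warn(
                f"acuity {self.acuity} outside the clinical range {ACUITY_RANGE}",
                stacklevel=2,
            )
        if self.contrast_sensitivity > CS_RANGE[1]:
            warnings.warn(
                f"contrast sensitivity {self.contrast_sensitivity} outside {CS_RANGE}",
                stacklevel=2,
            )

    @classmethod
    def from_acuity(cls, acuity: float) -> "VisionParams":
        """Build parameters from acuity alone, inferring CS from the
        empirical linear relation (flagged ``inferred-from-acuity``)."""
        cs = infer_cs_from_acuity(acuity)
        logger.info("contrast sensitivity inferred from acuity %.2f -> %.2f", acuity, cs)
        return cls(acuity=acuity, contrast_sensitivity=cs, cs_source="inferred-from-acuity")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "VisionParams":
        """Read parameters from a config mapping.

        Recognised keys: ``acuity_logmar`` (required), ``cs_pelli_robson``
        (optional — when missing, CS is inferred from acuity with a logged
        notice, mirroring clinical practice when the chart cannot be used).
        """
        if "acuity_logmar" not in mapping:
            raise InvalidInputError("config must provide acuity_logmar")
        acuity = float(mapping["acuity_logmar"])
        cs = mapping.get("cs_pelli_robson")
        if cs is None:
            return cls.from_acuity(acuity)
        return cls(acuity=acuity, contrast_sensitivity=float(cs))


@dataclass(frozen=True)
class CSFTemplate:
    """Shape parameters of the CSF template (fixed across observers).

    ``bandwidth`` is the half-width of the log-parabola in log10-frequency
    units from peak to the S = 1 crossing per unit of log10 sensitivity
    drop — concretely the descending limb is
    ``log10 S(f) = P - ((log10 f - log10 f_peak) / w)^2 * P`` scaled so the
    curve hits 1 at the cutoff; see :func:`build_csf`.
    """

    f0: float = DEFAULT_F0
    cs_anchor: str = "peak"  # "peak" or "reference"
    reference_frequency: float = 1.0  # cpd, used by the "reference" anchor
    bandwidth: float = 1.0  # log10 units; controls low-frequency limb only
    low_frequency_plateau: bool = True

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ConfigurationError("f0 must be > 0")
        if self.cs_anchor not in ("peak", "reference"):
            raise ConfigurationError(f"unknown cs_anchor {self.cs_anchor!r}")
        if self.reference_frequency <= 0:
            raise ConfigurationError("reference_frequency must be > 0")
        if self.bandwidth <= 0:
            raise ConfigurationError("bandwidth must be > 0")


@dataclass(frozen=True)
class CSF:
    """A contrast sensitivity function for one observer.

    ``sensitivity(f)`` is > 0 for all f > 0, unimodal in log f, equals
    ``peak_sensitivity`` at (and, with the plateau template, below)
    ``peak_frequency``, and crosses 1 exactly at ``cutoff_frequency``.
    """

    peak_sensitivity: float
    peak_frequency: float
    cutoff_frequency: float
    template: CSFTemplate = field(default_factory=CSFTemplate)

    def __post_init__(self) -> None:
        if self.peak_sensitivity <= 1:
            raise ConfigurationError("peak_sensitivity must exceed 1")
        if not 0 < self.peak_frequency < self.cutoff_frequency:
            raise ConfigurationError("need 0 < peak_frequency < cutoff_frequency")

    def sensitivity(self, f):
        """Linear contrast sensitivity S(f) at frequency ``f`` (cpd).

        Vectorised over ``f``.  S(cutoff) = 1; S < 1 above cutoff.
        """
        f = np.asarray(f, dtype=float)
        log_s_peak = math.log10(self.peak_sensitivity)
        lf_peak = math.log10(self.peak_frequency)
        lf_cut = math.log10(self.cutoff_frequency)
        with np.errstate(divide="ignore"):
            lf = np.log10(np.maximum(f, np.finfo(float).tiny))
        # descending limb: parabola through (lf_peak, log_s_peak) and
        # (lf_cut, 0) with apex at the peak
        high = log_s_peak * (1.0 - ((lf - lf_peak) / (lf_cut - lf_peak)) ** 2)
        if self.template.low_frequency_plateau:
            low = np.full_like(high, log_s_peak)
        else:
            low = log_s_peak * (
                1.0 - ((lf - lf_peak) / (self.template.bandwidth * math.sqrt(log_s_peak))) ** 2
            )
        log_s = np.where(lf >= lf_peak, high, low)
        out = np.power(10.0, log_s)
        out = np.where(f <= 0, 0.0, out)
        if out.ndim == 0:
            return float(out)
        return out


def build_csf(params: VisionParams, template: CSFTemplate | None = None) -> CSF:
    """Construct the observer's CSF from clinical parameters.

    The cutoff is anchored to acuity (``f0 * 10**-acuity``).  In the default
    ``"peak"`` anchor mode the curve's peak sensitivity is ``10**CS``.  In
    ``"reference"`` mode the curve is instead required to pass through
    ``S(f_ref) = 10**CS`` on its descending limb, which is only satisfiable
    when the reference frequency lies strictly below the cutoff; otherwise a
    :class:`ConfigurationError` names the violated anchor.

    The peak frequency follows the rigid-shift rule: it sits a fixed
    log-frequency distance below the cutoff (set by the template bandwidth
    and the curve height), so worsening acuity translates the whole curve
    leftward without changing its shape.
    """
    template = template or CSFTemplate()
    cutoff = template.f0 * 10.0 ** (-params.acuity)
    cs = params.contrast_sensitivity
    if cs <= 0:
        raise ConfigurationError(
            "contrast sensitivity anchor violated: CS must be > 0 for a CSF "
            "whose peak sensitivity exceeds 1"
        )
    lf_cut = math.log10(cutoff)
    if template.cs_anchor == "peak":
        log_s_peak = cs
    else:
        lf_ref = math.log10(template.reference_frequency)
        if lf_ref >= lf_cut:
            raise ConfigurationError(
                "reference-frequency anchor violated: S("
                f"{template.reference_frequency} cpd) = 10^{cs} is required "
                f"but the cutoff anchored at {cutoff:.3g} cpd lies at or "
                "below the reference frequency; nothing above the cutoff can "
                "exceed threshold"
            )
        # descending limb passes through (lf_ref, cs) and (lf_cut, 0) with
        # apex a fixed bandwidth below the cutoff
        w = template.bandwidth
        lf_peak_guess = lf_cut - w
        if lf_ref <= lf_peak_guess:
            # reference sits on the plateau: peak height is exactly 10^cs
            log_s_peak = cs
        else:
            # solve P * (1 - ((lf_ref - lf_peak)/(lf_cut - lf_peak))^2) = cs
            ratio = (lf_ref - lf_peak_guess) / (lf_cut - lf_peak_guess)
            log_s_peak = cs / (1.0 - ratio**2)
        lf_peak = lf_peak_guess
        return CSF(
            peak_sensitivity=10.0**log_s_peak,
            peak_frequency=10.0**lf_peak,
            cutoff_frequency=cutoff,
            template=template,
        )
    # peak anchor: peak frequency a fixed log distance below the cutoff,
    # scaled with curve height so the template is a rigid shift of the
    # normal-vision curve
    lf_peak = lf_cut - template.bandwidth * math.sqrt(log_s_peak)
    return CSF(
        peak_sensitivity=10.0**log_s_peak,
        peak_frequency=10.0**lf_peak,
        cutoff_frequency=cutoff,
        template=template,
    )


def contrast_threshold(csf: CSF, f) -> float:
    """Michelson threshold contrast 1/S(f) at spatial frequency ``f``.

    Returns a value >= 1 (nothing visible at any contrast) for frequencies
    at or beyond the cutoff; returns ``inf`` at f = 0 (no oscillatory
    content to detect).  Vectorised over ``f``.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise InvalidInputError("spatial frequency must be >= 0")
    s = np.asarray(csf.sensitivity(f), dtype=float)
    with np.errstate(divide="ignore"):
        thr = np.where(s > 0, 1.0 / np.maximum(s, np.finfo(float).tiny), np.inf)
    thr = np.where(f >= csf.cutoff_frequency, np.maximum(thr, 1.0), thr)
    if thr.ndim == 0:
        return float(thr)
    return thr
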