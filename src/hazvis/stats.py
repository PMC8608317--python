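"""Validation statistics: logistic accuracy-vs-HVS models and observer simulation.

The validation question is whether the hazard visibility score X predicts
whether an observer identifies the target correctly.  The model is the
binomial logistic regression

    ln(P / (1 - P)) = A * X + B,

fit by maximum likelihood (IRLS).  Goodness of fit is summarized by the
reduced deviance ratio (D0 - Dr) / D0 — the fraction of the intercept-only
(null) model's deviance removed by adding X — and by a chi-square
likelihood-ratio test of the fitted model against the null.  Two groups'
fits are compared with a Chow-style F test on working residual sums of
squares.  A simulated observer generates binary responses from the same
logistic law, optionally mixed with a guessing floor (chance performance in
a five-alternative task is 0.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit

from .exceptions import DegenerateDesignError, InvalidInputError

logger = logging.getLogger(__name__)

#: |A| beyond which a fit is flagged as (quasi-)separated.
SEPARATION_SLOPE = 1e3


@dataclass(frozen=True)
class TrialRecord:
    """One trial: visibility score, binary outcome, and labels."""

    hvs: float
    correct: int
    subject: str = "S1"
    group: str = "low-vision"
    target: str = ""
    lighting: str = ""
    viewpoint: str = ""
    repetition: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.hvs <= 1.0:
            raise InvalidInputError(f"hvs must be in [0, 1], got {self.hvs}")
        if self.correct not in (0, 1):
            raise InvalidInputError("correct must be 0 or 1")


@dataclass(frozen=True)
class LogisticFit:
    """A fitted accuracy-vs-HVS logistic model.

    ``slope``/``intercept`` are A and B of ln(P/(1-P)) = A X + B;
    deviances are against the saturated model; ``reduced_deviance_ratio``
    is (D0 - Dr)/D0.  ``converged`` is False when separation was detected.
    """

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    null_deviance: float
    residual_deviance: float
    n: int
    converged: bool = True
    diagnostic: str = ""

    @property
    def reduced_deviance_ratio(self) -> float:
        if self.null_deviance <= 0:
            return 0.0
        return (self.null_deviance - self.residual_deviance) / self.null_deviance


@dataclass(frozen=True)
class ChowResult:
    """Chow F test of coefficient equality across two samples."""

    f_statistic: float
    df: tuple[int, int]
    p_value: float


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line with its R²."""

    slope: float
    intercept: float
    r_squared: float


def _as_arrays(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        x = trials["hvs"].to_numpy(float)
        y = trials["correct"].to_numpy(float)
    else:
        x = np.array([t.hvs for t in trials], dtype=float)
        y = np.array([t.correct for t in trials], dtype=float)
    return x, y


def fit_logistic(trials) -> LogisticFit:
    """Maximum-likelihood logistic fit of correctness on HVS.

    Accepts a sequence of :class:`TrialRecord` or a DataFrame with ``hvs``
    and ``correct`` columns.  Degenerate designs (fewer than 2 trials,
    constant predictor, single-class outcome) raise
    :class:`DegenerateDesignError`.  Complete or quasi-complete separation
    is flagged on the returned fit rather than silently diverging.
    """
    x, y = _as_arrays(trials)
    n = x.size
    if n < 2:
        raise DegenerateDesignError("need at least 2 trials")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("HVS is constant across trials; slope undefined")
    if y.min() == y.max():
        raise DegenerateDesignError("all outcomes identical; logistic fit undefined")
    exog = sm.add_constant(x)
    model = sm.GLM(y, exog, family=sm.families.Binomial())
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # separation raises its own flag below
        res = model.fit(maxiter=200)
        intercept, slope = res.params
        se_slope = res.bse[1]
        null_deviance = float(res.null_deviance)
        deviance = float(res.deviance)
    ci = (slope - 1.96 * se_slope, slope + 1.96 * se_slope)
    converged = bool(res.converged)
    diagnostic = ""
    if abs(slope) > SEPARATION_SLOPE or not np.isfinite(se_slope) or se_slope > SEPARATION_SLOPE:
        converged = False
        diagnostic = (
            "separation detected: the outcome is (near-)perfectly predicted by "
            "a threshold on HVS; the ML slope diverges"
        )
        logger.warning("fit_logistic: %s", diagnostic)
    return LogisticFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_ci=(float(ci[0]), float(ci[1])),
        null_deviance=null_deviance,
        residual_deviance=deviance,
        n=int(n),
        converged=converged,
        diagnostic=diagnostic,
    )


def predicted_probability(fit: LogisticFit, x) -> np.ndarray | float:
    """P(correct) at visibility ``x`` under a fitted model (logistic law)."""
    x = np.asarray(x, dtype=float)
    p = expit(fit.slope * x + fit.intercept)
    if p.ndim == 0:
        return float(p)
    return p


def log_likelihood(trials, slope: float, intercept: float) -> float:
    """Bernoulli log-likelihood of (slope, intercept) on a trial set.

    Exposed for oracle-style comparisons against the ML fit.
    """
    x, y = _as_arrays(trials)
    eta = slope * x + intercept
    # log p and log(1-p) in a numerically stable form
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def lr_test_vs_null(fit: LogisticFit) -> tuple[float, int, float]:
    """Likelihood-ratio (analysis-of-deviance) test against the null model.

    The statistic is the deviance drop D0 - Dr, referred to chi-square with
    1 degree of freedom (one added predictor).
    """
    stat = max(0.0, fit.null_deviance - fit.residual_deviance)
    p = float(sps.chi2.sf(stat, df=1))
    return stat, 1, p


def _pearson_rss(trials, fit: LogisticFit) -> float:
    x, y = _as_arrays(trials)
    p = expit(fit.slope * x + fit.intercept)
    resid = (y - p) / np.sqrt(p * (1.0 - p))
    return float(np.sum(resid**2))


def chow_test(trials_1, trials_2, method: str = "lpm") -> ChowResult:
    """Chow F test: do two samples share one accuracy-vs-HVS model?

    The classical Chow test compares residual sums of squares of pooled
    versus separate fits.  The default ``"lpm"`` method runs the textbook
    test on linear-probability (OLS) fits of correctness on HVS, which
    retains the classical F behaviour for a binary outcome.  A
    ``"pearson"`` variant using squared Pearson residuals of the logistic
    fits is provided for comparison, but note its statistic is nearly
    powerless: Pearson residuals are standardized by each model's own
    fitted variance, so pooled-model misfit barely inflates their sum of
    squares.  With k = 2 parameters the degrees of freedom are
    (2, n1 + n2 - 4).
    """
    x1, y1 = _as_arrays(trials_1)
    x2, y2 = _as_arrays(trials_2)
    n1, n2 = x1.size, x2.size
    k = 2
    df2 = n1 + n2 - 2 * k
    if df2 <= 0:
        raise DegenerateDesignError("samples too small for the Chow test")
    pooled = pd.DataFrame({"hvs": np.concatenate([x1, x2]), "correct": np.concatenate([y1, y2])})
    d1 = pd.DataFrame({"hvs": x1, "correct": y1})
    d2 = pd.DataFrame({"hvs": x2, "correct": y2})
    if method == "pearson":
        rss_p = _pearson_rss(pooled, fit_logistic(pooled))
        rss_1 = _pearson_rss(d1, fit_logistic(d1))
        rss_2 = _pearson_rss(d2, fit_logistic(d2))
    elif method == "lpm":
        def ols_rss(df):
            res = sm.OLS(df["correct"], sm.add_constant(df["hvs"])).fit()
            return float(np.sum(res.resid**2))

        rss_p, rss_1, rss_2 = ols_rss(pooled), ols_rss(d1), ols_rss(d2)
    else:
        raise InvalidInputError(f"unknown Chow method {method!r}")
    f = ((rss_p - rss_1 - rss_2) / k) / ((rss_1 + rss_2) / df2)
    f = max(0.0, f)
    p = float(sps.f.sf(f, k, df2))
    return ChowResult(f_statistic=float(f), df=(k, df2), p_value=p)


def bin_trials(trials, bin_width: float = 0.1) -> pd.DataFrame:
    """Count correct/incorrect trials in equal-width HVS bins.

    Bins are half-open [0, w), [w, 2w), ... with the last bin closed at 1
    so an HVS of exactly 1 is counted.  ``bin_width`` must divide 1 evenly.
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise InvalidInputError("bin_width must divide 1 evenly")
    x, y = _as_arrays(trials)
    idx = np.minimum((x / bin_width).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        rows.append(
            {
                "bin_low": b * bin_width,
                "bin_high": (b + 1) * bin_width,
                "correct": int(y[sel].sum()),
                "incorrect": int((sel.sum() - y[sel].sum())),
            }
        )
    return pd.DataFrame(rows)


def slope_vs_vision_regression(slopes, vision_values) -> LinearFit:
    """OLS regression of per-subject logistic slopes on a vision measure.

    Regressing the slopes on logMAR acuity quantifies how the model's
    predictive power degrades with vision loss (a negative trend); on
    Pelli-Robson CS the trend is positive.
    """
    slopes = np.asarray(slopes, dtype=float)
    vision_values = np.asarray(vision_values, dtype=float)
    if slopes.size != vision_values.size or slopes.size < 3:
        raise DegenerateDesignError("need >= 3 paired (vision, slope) observations")
    if np.ptp(vision_values) == 0:
        raise DegenerateDesignError("vision measure has zero variance")
    res = sps.linregress(vision_values, slopes)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def simulate_observer(
    hvs_values,
    slope: float,
    intercept: float,
    guess_floor: float = 0.0,
    seed: int | np.random.Generator = 0,
    subject: str = "sim",
    group: str = "low-vision",
) -> pd.DataFrame:
    """Simulate binary responses from the logistic law with a guessing floor.

    P(correct | X) = g + (1 - g) * logistic(A X + B).  The floor g models
    above-chance guessing in a forced-choice task (0.2 for five
    alternatives); g = 0 recovers the plain logistic observer.  Fully
    reproducible for a given seed.
    """
    if not 0.0 <= guess_floor < 1.0:
        raise InvalidInputError("guess_floor must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(hvs_values, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise InvalidInputError("hvs values must be in [0, 1]")
    p = guess_floor + (1.0 - guess_floor) * expit(slope * x + intercept)
    correct = (rng.random(x.size) < p).astype(int)
    return pd.DataFrame(
        {
            "subject": subject,
            "group": group,
            "hvs": x,
            "correct": correct,
        }
    )


def sample_hvs_distribution(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw visibility scores from a stylized stimulus-set distribution.

    A bimodal Beta mixture (40% Beta(1.6, 4), 60% Beta(5, 2)) spreading
    mass across the whole [0, 1] range with modes near 0.15 and 0.8 —
    the qualitative shape of per-trial HVS histograms for a blurred
    observer viewing the 250-trial design, where many trials are nearly
    invisible and many clearly visible.
    """
    lo = rng.beta(1.6, 4.0, size=n)
    hi = rng.beta(5.0, 2.0, size=n)
    pick_hi = rng.random(n) < 0.6
    return np.where(pick_hi, hi, lo)


def fits_table(fits: dict[str, LogisticFit]) -> pd.DataFrame:
    """Tabulate per-subject fits (slope, CI, deviances, reduced ratio)."""
    rows = []
    for subject, f in fits.items():
        rows.append(
            {
                "subject": subject,
                "n": f.n,
                "slope": f.slope,
                "slope_ci_low": f.slope_ci[0],
                "slope_ci_high": f.slope_ci[1],
                "intercept": f.intercept,
                "null_deviance": f.null_deviance,
                "residual_deviance": f.residual_deviance,
                "reduced_deviance_ratio": f.reduced_deviance_ratio,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
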