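"""The fractional-polynomial mean-SD method for normal-theory centiles.

Assumes the measurement is normal at each gestational age with mean and
SD that vary smoothly with age.  The mean curve mu(t) is fitted by
fractional-polynomial least squares; the SD curve sigma(t) comes from
regressing the absolute residuals |y - mu(t)| on age and scaling the
fitted curve by sqrt(pi/2), since under normality the absolute residuals
are half-normal with mean sigma * sqrt(2/pi).  Any centile is then

    C_100a(t) = mu(t) + z_a * sigma(t)

with z_a the normal equivalent deviate (z = 1.88 for the 97th centile,
-1.88 for the 3rd).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .fracpoly import FPSpec, FractionalPolynomial

logger = logging.getLogger(__name__)

#: half-normal correction: E|r| = sigma * sqrt(2/pi)
HALF_NORMAL_SCALE = float(np.sqrt(np.pi / 2.0))


@dataclass(frozen=True)
class CentileValue:
    """A centile (or z-score) evaluation with an extrapolation flag."""

    value: float
    extrapolated: bool

    def __float__(self) -> float:
        return self.value


class MeanSDModel(BaseEstimator):
    """Normal-theory centile model with separate FP mean and SD curves.

    Parameters
    ----------
    mean_degree : int, default 2
        FP order searched for the mean curve.
    sd_degree : int, default 1
        FP order searched for the absolute-residual (SD) curve.  Fetal
        charts occasionally need 3 (the published fetal-head SD is FP3).
    reweight : bool, default False
        If True, refit the mean once by weighted least squares with
        weights 1/sigma_hat(t)**2 and re-estimate the SD (a single
        iteration; the effect is typically small).
    transform : {"none", "log"} or float, default "none"
        Fit on y, log(y), or log(y + k) for a float shift k; centiles
        are back-transformed.

    Attributes
    ----------
    mean_curve_ : FPSpec
    sd_curve_ : FPSpec
        The absolute-residual curve already scaled by sqrt(pi/2).
    ga_range_ : (float, float)
        Observed GA range; evaluation outside it is flagged.
    """

    def __init__(self, mean_degree: int = 2, sd_degree: int = 1,
                 reweight: bool = False, transform="none"):
        self.mean_degree = mean_degree
        self.sd_degree = sd_degree
        self.reweight = reweight
        self.transform = transform

    # -- transform helpers --------------------------------------------------
    def _shift(self) -> float | None:
        if self.transform == "none":
            return None
        if self.transform == "log":
            return 0.0
        return float(self.transform)

    def _fwd(self, y):
        k = self._shift()
        return y if k is None else np.log(y + k)

    def _inv(self, y):
        k = self._shift()
        return y if k is None else np.exp(y) - k

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y):
        ga = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if ga.size != y.size:
            raise ValueError("GA and measurement vectors must have equal length")
        if ga.size < 30:
            raise ValueError("need at least 30 records to fit a mean-SD model")
        if np.any(ga <= 0):
            raise ValueError("gestational age must be positive")
        yt = self._fwd(y)

        mean_fit = FractionalPolynomial(degree=self.mean_degree).fit(ga, yt)
        sd_spec = self._fit_sd(ga, yt, mean_fit)
        if self.reweight:
            sigma = np.maximum(self._eval_spec(sd_spec, ga), 1e-10)
            mean_fit = FractionalPolynomial(degree=self.mean_degree).fit(
                ga, yt, sample_weight=1.0 / sigma**2)
            sd_spec = self._fit_sd(ga, yt, mean_fit)

        self._check_sd_positive(sd_spec, ga, yt)
        self.mean_curve_ = mean_fit.spec_
        self.sd_curve_ = sd_spec
        self.sd_scale_ = HALF_NORMAL_SCALE
        self.n_obs_ = int(ga.size)
        self.ga_range_ = (float(ga.min()), float(ga.max()))
        return self

    def _fit_sd(self, ga, yt, mean_fit) -> FPSpec:
        resid = yt - mean_fit.predict(ga)
        abs_fit = FractionalPolynomial(degree=self.sd_degree).fit(ga, np.abs(resid))
        spec = abs_fit.spec_
        return FPSpec(powers=spec.powers,
                      coefficients=HALF_NORMAL_SCALE * spec.coefficients,
                      scale_shift=spec.scale_shift)

    @staticmethod
    def _eval_spec(spec: FPSpec, ga):
        return np.atleast_1d(spec(np.atleast_1d(ga)))

    def _check_sd_positive(self, sd_spec, ga, yt) -> None:
        grid = np.linspace(ga.min(), ga.max(), 201)
        sd = self._eval_spec(sd_spec, grid)
        # degenerate (essentially noiseless) fits are allowed: sd ~ 0 everywhere
        tol = 1e-8 * (1.0 + float(np.median(np.abs(yt))))
        if np.any(sd <= 0) and np.max(np.abs(sd)) > tol:
            bad = grid[sd <= 0]
            raise RuntimeError(
                "fitted SD curve is non-positive for GA in "
                f"[{bad.min():.2f}, {bad.max():.2f}] weeks"
            )

    # -- evaluation ----------------------------------------------------------
    def _flag(self, ga) -> bool:
        lo, hi = self.ga_range_
        return bool(np.any((np.atleast_1d(ga) < lo) | (np.atleast_1d(ga) > hi)))

    def mean(self, ga):
        return self._inv(self.mean_curve_(ga))

    def sd(self, ga):
        """SD on the (possibly transformed) analysis scale."""
        return self.sd_curve_(ga)

    def predict(self, X):
        """Median (= mean under normality) at GA."""
        return self.mean(np.asarray(X, dtype=float))

    def centile(self, ga, centile: float):
        """Centile value(s) at GA; flagged if GA is outside the fitted range."""
        if not 0 < centile < 100:
            raise ValueError("centile must be strictly between 0 and 100")
        ga_arr = np.asarray(ga, dtype=float)
        extrapolated = self._flag(ga_arr)
        if extrapolated:
            logger.warning("centile evaluated outside fitted GA range %s", self.ga_range_)
        z = stats.norm.ppf(centile / 100.0)
        val = self._inv(self.mean_curve_(ga_arr) + z * self.sd_curve_(ga_arr))
        if np.isscalar(ga) or ga_arr.ndim == 0:
            return CentileValue(float(np.ravel(val)[0]), extrapolated)
        return val

    def zscore(self, ga, y):
        """SD score of measurement(s) y at GA."""
        ga_arr = np.asarray(ga, dtype=float)
        sigma = self.sd_curve_(ga_arr)
        if np.any(np.atleast_1d(sigma) <= 0):
            raise RuntimeError("fitted SD is non-positive at the requested GA")
        z = (self._fwd(np.asarray(y, dtype=float)) - self.mean_curve_(ga_arr)) / sigma
        return float(np.ravel(z)[0]) if np.isscalar(y) and np.isscalar(ga) else z

    def transform(self, X, y):
        """sklearn-style alias: records -> z-scores."""
        return self.zscore(X, y)


def fit_mean_sd(ga, y, mean_degree=2, sd_degree=1, reweight=False,
                transform="none") -> MeanSDModel:
    """Fit the FP mean-SD model (functional wrapper)."""
    return MeanSDModel(mean_degree=mean_degree, sd_degree=sd_degree,
                       reweight=reweight, transform=transform).fit(ga, y)


def normal_centile(model: MeanSDModel, ga, centile: float):
    return model.centile(ga, centile)


def normal_zscore(model: MeanSDModel, ga, y):
    return model.zscore(ga, y)
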