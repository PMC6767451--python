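"""Multilevel models for longitudinal triplicate growth data.

The design this targets: each subject is scanned at several visits
through pregnancy, and at each visit the measurement (e.g. fetal head
circumference, FHC, in mm) is taken in triplicate from separately
acquired images.  That gives three levels — replicates within visits
within subjects.  Models of increasing complexity:

ri2
    Two-level random intercept: triplicates collapsed to one value per
    visit; subject-specific intercept u0_j plus residual.
ris2
    Two-level random intercept and slope: adds a subject-specific slope
    u1_j on gestational age.
ris3
    Three-level random intercept and slope: keeps all triplicates and
    adds a visit-level random intercept, so replicate error and
    between-visit variation are separated.

The fixed part is a fractional polynomial of GA (FP2 with powers (2, 2)
by default).  Estimation is full maximum likelihood (not REML) so that
deviances are comparable across fixed-effects structures.

The module also carries the published FHC standard equations (mean FP2
and SD FP3 in exact GA weeks, natural logs, mm) for chart evaluation
without refitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLM

from .fracpoly import FPSpec, fit_fp, fp_basis

logger = logging.getLogger(__name__)

GA_WINDOW = (14.0, 42.0)

MODEL_KINDS = ("ri2", "ris2", "ris3")


def collapse_triplicates(records: pd.DataFrame, method: str = "mean",
                         seed=None) -> pd.DataFrame:
    """Collapse replicate measurements to one row per (subject, visit).

    ``method`` is 'mean' (the conventional choice), 'median' (more
    robust to a single aberrant replicate) or 'random' (select one
    replicate uniformly; needs ``seed``).  Missing replicates are
    simply excluded; a visit with no non-missing replicate is dropped
    and counted in the log.
    """
    if method not in ("mean", "random", "median"):
        raise ValueError("method must be 'mean', 'random' or 'median'")
    if method == "random" and seed is None:
        raise ValueError("method='random' requires a seed for reproducibility")
    rng = np.random.default_rng(seed)
    df = records.dropna(subset=["value"])
    n_dropped = records.groupby(["id", "visit"]).ngroups - df.groupby(["id", "visit"]).ngroups
    if n_dropped:
        logger.warning("%d visits had no non-missing replicate and were dropped", n_dropped)

    if method == "random":
        df = df.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
        out = df.groupby(["id", "visit"], as_index=False).first()
    else:
        agg = "mean" if method == "mean" else "median"
        out = df.groupby(["id", "visit"], as_index=False).agg(
            ga_weeks=("ga_weeks", "first"), value=("value", agg))
    return out[["id", "visit", "ga_weeks", "value"]].sort_values(
        ["id", "visit"]).reset_index(drop=True)


class MultilevelGrowthModel(BaseEstimator):
    """Mixed-effects growth curve with an FP fixed part.

    Parameters
    ----------
    kind : {"ri2", "ris2", "ris3"}
    fixed_powers : tuple, default (2, 2)
        FP powers of the fixed mean curve.
    center_ga : bool, default False
        Attach the random slope to (GA - mean GA) instead of raw GA;
        this only reparameterizes the intercept-slope covariance.
    collapse : {"mean", "median", "random"}, default "mean"
        How triplicates are collapsed for the two-level kinds.
    seed : int, optional
        Used only for collapse='random'.

    Attributes
    ----------
    fixed_spec_ : FPSpec
    var_intercept_, var_slope_, cov_int_slope_, var_visit_, var_resid_ : float
    deviance_ : float   (-2 maximized log-likelihood, ML)
    boundary_ : list of str — variance components pinned near zero
    """

    def __init__(self, kind: str = "ri2", fixed_powers: tuple = (2.0, 2.0),
                 center_ga: bool = False, collapse: str = "mean", seed=None):
        self.kind = kind
        self.fixed_powers = fixed_powers
        self.center_ga = center_ga
        self.collapse = collapse
        self.seed = seed

    def fit(self, records: pd.DataFrame, y=None):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")
        df = records.copy()
        if self.kind in ("ri2", "ris2") and "replicate" in df.columns:
            df = collapse_triplicates(df, method=self.collapse, seed=self.seed)
        df = df.dropna(subset=["value"]).reset_index(drop=True)

        ga = df["ga_weeks"].to_numpy(dtype=float)
        self.ga_offset_ = float(ga.mean()) if self.center_ga else 0.0
        basis = fp_basis(ga, self.fixed_powers)
        exog = np.column_stack([np.ones(ga.size), basis])
        slope_x = ga - self.ga_offset_

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.kind == "ri2":
                model = MixedLM(df["value"].to_numpy(float), exog,
                                groups=df["id"].to_numpy())
            elif self.kind == "ris2":
                exog_re = np.column_stack([np.ones(ga.size), slope_x])
                model = MixedLM(df["value"].to_numpy(float), exog,
                                groups=df["id"].to_numpy(), exog_re=exog_re)
            else:
                mdf = pd.DataFrame({
                    "value": df["value"].to_numpy(float), "id": df["id"].to_numpy(),
                    "ga_slope": slope_x,
                    "visit_code": df["visit"].astype(str).to_numpy()})
                for j in range(basis.shape[1]):
                    mdf[f"fpb{j}"] = basis[:, j]
                fixed = "value ~ " + " + ".join(f"fpb{j}" for j in range(basis.shape[1]))
                model = MixedLM.from_formula(
                    fixed, groups="id", re_formula="~ga_slope",
                    vc_formula={"visit": "0 + C(visit_code)"}, data=mdf)
            res, last_exc = None, None
            for method in (None, "powell", "lbfgs"):
                try:
                    cand = model.fit(reml=False, method=method, maxiter=500)
                except Exception as exc:
                    last_exc = exc
                    continue
                # some optimizers report convergence at degenerate points
                if np.isfinite(cand.llf):
                    res = cand
                    break
            if res is None:  # pragma: no cover - statsmodels failure path
                raise RuntimeError(f"multilevel fit ({self.kind}) failed: {last_exc}")

        fe = np.asarray(res.fe_params, dtype=float)
        self.fixed_spec_ = FPSpec(powers=tuple(float(p) for p in self.fixed_powers),
                                  coefficients=fe)
        cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        self.var_intercept_ = float(cov_re[0, 0])
        if self.kind in ("ris2", "ris3"):
            self.var_slope_ = float(cov_re[1, 1])
            self.cov_int_slope_ = float(cov_re[0, 1])
        else:
            self.var_slope_ = 0.0
            self.cov_int_slope_ = 0.0
        self.var_visit_ = float(np.asarray(res.vcomp).ravel()[0]) if self.kind == "ris3" else 0.0
        self.var_resid_ = float(res.scale)
        self.deviance_ = float(-2.0 * res.llf)
        self.n_obs_ = int(df.shape[0])
        self.ga_range_ = (float(ga.min()), float(ga.max()))
        self.converged_ = bool(res.converged)

        yvar = float(np.var(df["value"].to_numpy(float)))
        self.boundary_ = [nm for nm, v in [
            ("var_intercept", self.var_intercept_), ("var_slope", self.var_slope_),
            ("var_visit", self.var_visit_)]
            if self.kind_has(nm) and v < 1e-6 * yvar]
        if self.boundary_:
            logger.warning("variance component(s) at the zero boundary: %s", self.boundary_)

        self.sd_curve_ = marginal_sd_curve(self, df)
        return self

    def kind_has(self, nm: str) -> bool:
        if nm == "var_intercept":
            return True
        if nm == "var_slope":
            return self.kind in ("ris2", "ris3")
        return self.kind == "ris3"

    # -- marginal quantities -------------------------------------------------
    def mean(self, ga):
        return self.fixed_spec_(ga)

    def total_variance(self, ga):
        """Marginal variance of a single measurement at GA, from the
        fitted variance components."""
        t = np.asarray(ga, dtype=float) - self.ga_offset_
        v = (self.var_intercept_ + 2.0 * self.cov_int_slope_ * t
             + self.var_slope_ * t**2 + self.var_visit_ + self.var_resid_)
        if np.any(np.atleast_1d(v) <= 0):
            raise RuntimeError("implied total variance is non-positive; "
                               "variance components are inconsistent")
        return v

    def centile(self, ga, centile: float):
        """Marginal centile: fixed mean + z * smoothed total SD."""
        if not 0 < centile < 100:
            raise ValueError("centile must be strictly between 0 and 100")
        z = stats.norm.ppf(centile / 100.0)
        return self.mean(ga) + z * self.sd_curve_(ga)

    def predict(self, X):
        return self.mean(np.asarray(X, dtype=float))

    def zscore(self, ga, y):
        return (np.asarray(y, dtype=float) - self.mean(ga)) / self.sd_curve_(ga)

    def to_dict(self) -> dict:
        return {
            "model": "multilevel", "kind": self.kind,
            "fixed": self.fixed_spec_.to_dict(), "sd_curve": self.sd_curve_.to_dict(),
            "var_intercept": self.var_intercept_, "var_slope": self.var_slope_,
            "cov_int_slope": self.cov_int_slope_, "var_visit": self.var_visit_,
            "var_resid": self.var_resid_, "deviance": self.deviance_,
            "n_obs": self.n_obs_, "ga_range": list(self.ga_range_),
            "ga_offset": self.ga_offset_,
        }


def fit_multilevel(records: pd.DataFrame, model_kind: str = "ri2",
                   fixed_powers: tuple = (2.0, 2.0), **kw) -> MultilevelGrowthModel:
    """Fit a multilevel growth model (functional wrapper)."""
    return MultilevelGrowthModel(kind=model_kind, fixed_powers=fixed_powers,
                                 **kw).fit(records)


def smooth_sd_curve(ga_grid, sd_values, degree: int = 3) -> FPSpec:
    """FP-smooth an SD curve evaluated on a grid (exact if the curve is
    itself an FP of the requested degree)."""
    return fit_fp(np.asarray(ga_grid, float), np.asarray(sd_values, float),
                  degree=degree).spec_


def marginal_sd_curve(fit: MultilevelGrowthModel, records: pd.DataFrame | None = None,
                      sd_degree: int = 3, n_grid: int = 101) -> FPSpec:
    """Total SD by GA from the variance components, smoothed as an FP.

    The total variance at GA t is var_intercept + 2*cov*t +
    var_slope*t**2 + var_visit + var_resid (terms present according to
    the model kind); its square root is evaluated on a grid spanning
    the training GA range and represented as an FP of ``sd_degree``
    (degree 3 accommodates the published FHC SD shape).
    """
    if records is not None:
        ga = records["ga_weeks"].to_numpy(dtype=float)
        lo, hi = float(ga.min()), float(ga.max())
    else:
        lo, hi = fit.ga_range_
    grid = np.linspace(lo, hi, n_grid)
    sd = np.sqrt(fit.total_variance(grid))
    return smooth_sd_curve(grid, sd, degree=sd_degree)


# --- the published fetal head circumference standard ------------------------

@dataclass(frozen=True)
class PublishedChart:
    """A closed-form mean/SD chart: two FP curves in exact GA weeks."""

    mean_curve: FPSpec
    sd_curve: FPSpec
    units: str = "mm"
    ga_window: tuple = GA_WINDOW

    def _warn_range(self, ga) -> None:
        lo, hi = self.ga_window
        if np.any((np.atleast_1d(ga) < lo) | (np.atleast_1d(ga) > hi)):
            logger.warning("GA outside the chart window [%g, %g] weeks", lo, hi)

    def mean(self, ga):
        return self.mean_curve(ga)

    def sd(self, ga):
        return self.sd_curve(ga)

    def centile(self, ga, centile: float):
        if not 0 < centile < 100:
            raise ValueError("centile must be strictly between 0 and 100")
        self._warn_range(ga)
        z = stats.norm.ppf(centile / 100.0)
        return self.mean_curve(ga) + z * self.sd_curve(ga)

    def zscore(self, ga, value):
        self._warn_range(ga)
        return (np.asarray(value, dtype=float) - self.mean_curve(ga)) / self.sd_curve(ga)


#: International FHC standard: mean = -28.2849 + 1.69267*GA^2 - 0.397485*GA^2*ln(GA);
#: SD = 1.98735 + 0.0136772*GA^3 - 0.00726264*GA^3*ln(GA) + 0.000976253*GA^3*ln(GA)^2
#: (mm, natural logs, exact GA in weeks, valid 14-42 weeks).
FHC_CHART = PublishedChart(
    mean_curve=FPSpec(powers=(2.0, 2.0),
                      coefficients=np.array([-28.2849, 1.69267, -0.397485])),
    sd_curve=FPSpec(powers=(3.0, 3.0, 3.0),
                    coefficients=np.array([1.98735, 0.0136772, -0.00726264,
                                           0.000976253])),
)


def published_fhc(ga, centile: float):
    """Centile of the published FHC standard (mm)."""
    return FHC_CHART.centile(ga, centile)


def published_fhc_zscore(ga, value):
    """Z-score of an FHC value (mm) against the published standard."""
    return FHC_CHART.zscore(ga, value)
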