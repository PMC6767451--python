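"""Synthetic growth datasets with the two study designs this package targets.

Two generators, each returning records plus the generating truth so that
fit-and-recover tests close the loop:

* :func:`gen_newborn` — a cross-sectional newborn anthropometry design:
  one measurement per newborn, gestational age heavily heaped at term
  (very few deliveries before 34 weeks, mode at 39-40 weeks; the default
  per-week weights follow the birthweight study's per-sex counts), and a
  configurable conditional distribution (any supported family) whose
  parameters vary smoothly with GA.

* :func:`gen_fetal` — a longitudinal fetal ultrasound design: visits
  every 5 (+/- 1) weeks from 14 weeks, one to six visits per subject
  (defaults follow the follow-up study's visit-count table, which gives
  93% of subjects at least four visits and reproduces its 20 030 total
  visits in expectation), triplicate measurements per visit, subject
  random intercepts and slopes, visit-level noise, and a small
  completely-at-random replicate missingness.

The default fetal truth curve is the published FHC mean equation, with
variance components chosen so the implied total SD tracks the published
FP3 SD curve — the published standard doubles as the generator's truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .distributions import FAMILIES, family_quantile
from .fracpoly import FPSpec
from .multilevel import FHC_CHART

# --- design facts used as generator defaults --------------------------------

#: newborn cross-sectional study: enrolled vs eligible for the standard
NCSS_ENROLLED = 59_137
NCSS_ELIGIBLE = 20_486

#: per-week birth counts by sex (completed weeks 33..42)
TABLE1_BOYS = {33: 34, 34: 48, 35: 128, 36: 323, 37: 857, 38: 2045,
               39: 3009, 40: 2568, 41: 1179, 42: 206}
TABLE1_GIRLS = {33: 17, 34: 65, 35: 114, 36: 293, 37: 803, 38: 1802,
                39: 2869, 40: 2523, 41: 1195, 42: 224}

#: longitudinal fetal study: women by exact number of follow-up visits
VISIT_COUNTS = {1: 39, 2: 55, 3: 203, 4: 810, 5: 2724, 6: 402}
FGLS_N_WOMEN = 4233
FGLS_N_VISITS = 20_030
FGLS_N_MISSING = 117
FGLS_N_OBSERVATIONS = FGLS_N_VISITS * 3 - FGLS_N_MISSING  # 59 973


def _normalize(weights: dict) -> dict:
    total = float(sum(weights.values()))
    if total <= 0:
        raise ValueError("weights must have positive total")
    return {int(k): v / total for k, v in sorted(weights.items())}


@dataclass
class CrossSecConfig:
    """Configuration of the cross-sectional newborn generator.

    ``truth`` maps distribution parameter names (mu, sigma, nu, tau in
    family order) to callables of GA.  The default emulates mildly
    right-skewed birthweight in grams: BCCG with median 200*GA - 4600,
    CV 0.11 and Box-Cox power 0.5.
    """

    n: int = 10_397
    sex: str = "M"
    ga_weights: dict = field(default_factory=lambda: dict(TABLE1_BOYS))
    family: str = "BCCG"
    truth: dict = field(default_factory=lambda: {
        "mu": lambda t: 200.0 * t - 4600.0,
        "sigma": lambda t: np.full_like(np.asarray(t, float), 0.11),
        "nu": lambda t: np.full_like(np.asarray(t, float), 0.5),
    })
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.ga_weights = _normalize(self.ga_weights)


def _truth_params(family: str, truth: dict, ga: np.ndarray) -> tuple:
    order = ("mu", "sigma", "nu", "tau")[:FAMILIES[family]]
    missing = [p for p in order if p not in truth]
    if missing:
        raise ValueError(f"truth curves missing for parameters {missing}")
    return tuple(np.broadcast_to(np.asarray(truth[p](ga), dtype=float), ga.shape)
                 for p in order)


def gen_newborn(config: CrossSecConfig | None = None, **kw):
    """Simulate one-measurement-per-newborn records.

    GA is drawn as a completed week from ``ga_weights`` plus a uniform
    within-week fraction; the measurement comes from ``family`` at the
    truth parameter curves.  Returns ``(records, truth)`` where records
    has columns id, sex, ga_weeks, value.
    """
    config = config or CrossSecConfig(**kw)
    rng = np.random.default_rng(config.seed)
    weeks = np.array(list(config.ga_weights), dtype=float)
    probs = np.array(list(config.ga_weights.values()))
    week = rng.choice(weeks, size=config.n, p=probs)
    ga = week + rng.uniform(0.0, 1.0, size=config.n)
    params = _truth_params(config.family, config.truth, ga)
    u = rng.uniform(1e-12, 1 - 1e-12, size=config.n)
    value = family_quantile(config.family, params, u)
    records = pd.DataFrame({
        "id": [f"N{i + 1:06d}" for i in range(config.n)],
        "sex": config.sex, "ga_weeks": ga, "value": value,
    })
    truth = {"family": config.family, "curves": config.truth,
             "ga_weights": config.ga_weights, "seed": config.seed}
    return records, truth


# --- longitudinal fetal generator -------------------------------------------

@dataclass
class LongConfig:
    """Configuration of the longitudinal fetal generator.

    Defaults reproduce the follow-up design: visits every
    ``visit_interval`` (+/- ``visit_jitter``, uniform) weeks starting in
    week ``first_visit_ga``, visit counts drawn from ``visits_dist``,
    triplicate measurements with SD ``triplicate_sd`` (mm), and a
    completely-at-random replicate missing rate of 117 / 60 090.  The
    fixed curve defaults to the published FHC mean; var_intercept, cov
    and var_slope are chosen so the implied total SD approximates the
    published FP3 SD curve over 14-42 weeks.
    """

    n_subjects: int = FGLS_N_WOMEN
    first_visit_ga: float = 14.0
    visit_interval: float = 5.0
    visit_jitter: float = 1.0
    visits_dist: dict = field(default_factory=lambda: dict(VISIT_COUNTS))
    triplicate_sd: float = 3.0
    missing_rate: float = FGLS_N_MISSING / (FGLS_N_VISITS * 3)
    fixed_curve: Callable | FPSpec = FHC_CHART.mean_curve
    var_intercept: float = 74.31
    var_slope: float = 0.1872
    cov_int_slope: float = -2.81
    var_visit: float = 4.0
    ga_window: tuple = (14.0, 42.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        self.visits_dist = _normalize(self.visits_dist)
        for v in (self.var_intercept, self.var_slope, self.var_visit):
            if v < 0:
                raise ValueError("variances must be non-negative")
        cov = np.array([[self.var_intercept, self.cov_int_slope],
                        [self.cov_int_slope, self.var_slope]])
        if np.min(np.linalg.eigvalsh(cov)) < -1e-9:
            raise ValueError("random-effects covariance is not positive semi-definite")

    def total_sd(self, ga):
        """Implied marginal SD of a single replicate at GA."""
        t = np.asarray(ga, dtype=float)
        return np.sqrt(self.var_intercept + 2.0 * self.cov_int_slope * t
                       + self.var_slope * t**2 + self.var_visit
                       + self.triplicate_sd**2)


def gen_fetal(config: LongConfig | None = None, **kw):
    """Simulate triplicate longitudinal records.

    Per subject: a visit count from ``visits_dist``; a jittered
    schedule from 14 weeks truncated at the GA window; an intercept and
    slope deviation from the configured covariance; each visit value is
    fixed(GA) + intercept + slope*GA + visit noise, and each of the
    three replicates adds independent measurement error.  Replicates
    are masked (NaN) at ``missing_rate``.  Returns ``(records, truth)``
    with record columns id, visit, replicate, ga_weeks, value.
    """
    config = config or LongConfig(**kw)
    rng = np.random.default_rng(config.seed)
    counts = np.array(list(config.visits_dist))
    probs = np.array(list(config.visits_dist.values()))
    cov = np.array([[config.var_intercept, config.cov_int_slope],
                    [config.cov_int_slope, config.var_slope]])
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    fixed = config.fixed_curve
    lo, hi = config.ga_window

    rows = {"id": [], "visit": [], "replicate": [], "ga_weeks": [], "value": []}
    n_redrawn = 0
    for i in range(config.n_subjects):
        sid = f"F{i + 1:05d}"
        for _attempt in range(100):
            n_visits = int(rng.choice(counts, p=probs))
            ga = config.first_visit_ga + rng.uniform(0.0, 1.0)
            schedule = []
            for _v in range(n_visits):
                if lo <= ga <= hi:
                    schedule.append(ga)
                ga += config.visit_interval + rng.uniform(-config.visit_jitter,
                                                          config.visit_jitter)
            if schedule:
                break
            n_redrawn += 1
        b0, b1 = chol @ rng.standard_normal(2)
        for k, ga_k in enumerate(schedule, start=1):
            visit_val = (float(np.asarray(fixed(ga_k))) + b0 + b1 * ga_k
                         + rng.normal(0.0, np.sqrt(config.var_visit)))
            for rep in range(1, 4):
                val = visit_val + rng.normal(0.0, config.triplicate_sd)
                if rng.uniform() < config.missing_rate:
                    val = np.nan
                rows["id"].append(sid)
                rows["visit"].append(k)
                rows["replicate"].append(rep)
                rows["ga_weeks"].append(ga_k)
                rows["value"].append(val)
    records = pd.DataFrame(rows)
    truth = {
        "fixed_curve": fixed, "var_intercept": config.var_intercept,
        "var_slope": config.var_slope, "cov_int_slope": config.cov_int_slope,
        "var_visit": config.var_visit, "var_resid": config.triplicate_sd**2,
        "missing_rate": config.missing_rate, "n_redrawn": n_redrawn,
        "seed": config.seed, "total_sd": config.total_sd,
    }
    return records, truth
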