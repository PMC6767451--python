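"""LMS / LMST / LMSP-style centile models by penalized maximum likelihood.

Each parameter of a response distribution (mu, sigma, nu, tau) is a
smooth function of gestational age: a fractional polynomial, a penalized
cubic B-spline at a target effective degrees of freedom (edf), or a
constant.  edf = 1 is a constant, edf = 2 a straight line, edf = 3
roughly a quadratic.  sigma and tau are fitted on a log link so they
stay positive; mu is on the identity link, and nu is on the identity
link except for the two-piece SEP3/ST3 families where it must be
positive and uses the log link.

Fitting cycles over the parameters, refitting each curve by damped
Newton steps (with numerically differenced score and curvature) while
the others are held fixed, until the global deviance (-2 log-likelihood)
is stable.  For penalized splines the smoothing constant is solved by
bisection so that the realized edf matches the requested target,
including fractional targets.  Model comparison uses the generalized
Akaike criterion GAIC(k) = deviance + k * total edf, of which AIC (k=2)
and BIC (k = log n) are the special cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator

from . import distributions as dist
from .fracpoly import fp_basis

logger = logging.getLogger(__name__)

_PARAM_NAMES = {
    "NO": ("mu", "sigma"),
    "PE": ("mu", "sigma", "tau"),
    "BCCG": ("mu", "sigma", "nu"),
    "BCT": ("mu", "sigma", "nu", "tau"),
    "BCPE": ("mu", "sigma", "nu", "tau"),
    "SEP3": ("mu", "sigma", "nu", "tau"),
    "ST3": ("mu", "sigma", "nu", "tau"),
}

_ETA_CLIP = 30.0


def _default_link(family: str, param: str) -> str:
    if param in ("sigma", "tau"):
        return "log"
    if param == "nu" and family in ("SEP3", "ST3"):
        return "log"
    return "identity"


@dataclass(frozen=True)
class CurveSpec:
    """Requested shape of one parameter curve.

    kind 'fp' needs ``powers``; 'pspline' needs ``edf`` (>= 2, may be
    fractional); 'constant' needs nothing.
    """

    kind: str
    powers: tuple[float, ...] | None = None
    edf: float | None = None
    n_knots: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("fp", "pspline", "constant"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.kind == "fp" and not self.powers:
            raise ValueError("fp curve needs powers")
        if self.kind == "pspline":
            if self.edf is None or self.edf < 2:
                raise ValueError("pspline curve needs edf >= 2")


def fp(*powers) -> CurveSpec:
    return CurveSpec("fp", powers=tuple(float(p) for p in powers))


def ps(edf: float, n_knots: int = 10) -> CurveSpec:
    return CurveSpec("pspline", edf=float(edf), n_knots=n_knots)


def const() -> CurveSpec:
    return CurveSpec("constant")


@dataclass
class SmoothCurve:
    """A fitted parameter curve with its link and realized edf."""

    kind: str
    link: str
    coefficients: np.ndarray
    edf: float
    fp_powers: tuple[float, ...] | None = None
    knots: np.ndarray | None = None
    lam: float = 0.0

    def design(self, ga: np.ndarray) -> np.ndarray:
        return _design(self.kind, ga, self.fp_powers, self.knots)

    def eta(self, ga) -> np.ndarray:
        ga = np.atleast_1d(np.asarray(ga, dtype=float))
        return self.design(ga) @ self.coefficients

    def __call__(self, ga) -> np.ndarray:
        """Parameter value(s) at GA (link-inverted)."""
        return _invlink(self.link, self.eta(ga))

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "link": self.link, "edf": float(self.edf),
             "coefficients": [float(c) for c in self.coefficients], "lam": float(self.lam)}
        if self.fp_powers is not None:
            d["fp_powers"] = list(self.fp_powers)
        if self.knots is not None:
            d["knots"] = [float(t) for t in self.knots]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothCurve":
        return cls(kind=d["kind"], link=d["link"],
                   coefficients=np.asarray(d["coefficients"], dtype=float),
                   edf=float(d["edf"]),
                   fp_powers=tuple(d["fp_powers"]) if "fp_powers" in d else None,
                   knots=np.asarray(d["knots"], dtype=float) if "knots" in d else None,
                   lam=float(d.get("lam", 0.0)))


def _invlink(link: str, eta: np.ndarray) -> np.ndarray:
    if link == "identity":
        return eta
    if link == "log":
        return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    raise ValueError(f"unknown link {link!r}")


def _design(kind: str, ga: np.ndarray, powers, knots) -> np.ndarray:
    n = ga.shape[0]
    if kind == "constant":
        return np.ones((n, 1))
    if kind == "fp":
        return np.column_stack([np.ones(n), fp_basis(ga, powers)])
    if kind == "pspline":
        x = np.clip(ga, knots[3], knots[-4])  # clamp: linear-ish tails avoided
        m = BSpline.design_matrix(x, knots, 3, extrapolate=True)
        return np.asarray(m.todense())
    raise ValueError(kind)


def _spline_knots(ga: np.ndarray, n_knots: int) -> np.ndarray:
    # uniform knots extended past the range (Eilers-Marx P-spline), so a
    # linear trend has an exactly linear coefficient sequence and lies in
    # the null space of the second-difference penalty
    lo, hi = float(ga.min()), float(ga.max())
    span = max(hi - lo, 1e-6)
    h = span / (n_knots - 1)
    return lo + h * np.arange(-3, n_knots + 3, dtype=float)


def _diff_penalty(ncol: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(ncol), n=order, axis=0)
    return d.T @ d


def gaic(global_deviance: float, df_total: float, k: float) -> float:
    """Generalized AIC: deviance + k * df (k=2 is AIC, k=log n is BIC)."""
    if df_total < 0 or k < 0:
        raise ValueError("df_total and k must be non-negative")
    return float(global_deviance + k * df_total)


@dataclass
class FitReport:
    """Goodness-of-fit summary of a fitted centile model."""

    global_deviance: float
    df_total: float
    n_obs: int
    coverage_3rd: float
    coverage_97th: float
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        self.aic = self.gaic(2.0)
        self.bic = self.gaic(np.log(self.n_obs))

    def gaic(self, k: float) -> float:
        return gaic(self.global_deviance, self.df_total, k)


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, trace: list[float]):
        super().__init__(msg)
        self.deviance_trace = trace


class CentileModel(BaseEstimator):
    """GAMLSS-style age-conditional distribution model.

    Parameters
    ----------
    family : str
        One of NO, PE, BCCG (the LMS model), BCT (LMST), BCPE (LMSP),
        SEP3, ST3.
    curves : dict
        Mapping parameter name -> :class:`CurveSpec` (helpers
        :func:`fp`, :func:`ps`, :func:`const`).  Unlisted parameters
        default to constants.
    tol : float, default 1e-4
        Convergence tolerance on the deviance change per cycle.
    max_cycles : int, default 500

    Attributes
    ----------
    curves_ : dict of SmoothCurve
    report_ : FitReport
    global_deviance_ : float
    ga_range_ : (float, float)
    """

    def __init__(self, family: str = "BCCG", curves: dict | None = None,
                 tol: float = 1e-4, max_cycles: int = 500):
        self.family = family
        self.curves = curves
        self.tol = tol
        self.max_cycles = max_cycles

    # -- likelihood plumbing -------------------------------------------------
    def _nll_terms(self, y, params: dict) -> np.ndarray:
        vals = [params[p] for p in _PARAM_NAMES[self.family]]
        with np.errstate(all="ignore"):
            lp = _raw_logpdf(self.family, vals, y)
        return np.nan_to_num(-lp, nan=1e10, posinf=1e10, neginf=1e10)

    def fit(self, X, y):
        if self.family not in _PARAM_NAMES:
            raise ValueError(f"unknown family {self.family!r}")
        ga = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if ga.size != y.size:
            raise ValueError("GA and measurement vectors must have equal length")
        names = _PARAM_NAMES[self.family]
        specs = {}
        user = dict(self.curves or {})
        for nm in user:
            if nm not in names:
                raise ValueError(f"family {self.family} has no parameter {nm!r}")
        for nm in names:
            specs[nm] = user.get(nm, const())

        state: dict[str, SmoothCurve] = {}
        designs: dict[str, np.ndarray] = {}
        for nm in names:
            sp = specs[nm]
            knots = _spline_knots(ga, sp.n_knots) if sp.kind == "pspline" else None
            B = _design(sp.kind, ga, sp.powers, knots)
            coef = self._init_coef(nm, sp, B, ga, y)
            state[nm] = SmoothCurve(kind=sp.kind, link=_default_link(self.family, nm),
                                    coefficients=coef, edf=float(B.shape[1]),
                                    fp_powers=sp.powers, knots=knots)
            designs[nm] = B

        etas = {nm: designs[nm] @ state[nm].coefficients for nm in names}
        params = {nm: _invlink(state[nm].link, etas[nm]) for nm in names}
        dev = 2.0 * float(np.sum(self._nll_terms(y, params)))
        trace = [dev]
        for cycle in range(self.max_cycles):
            for nm in names:
                self._update_param(nm, specs[nm], state, designs, etas, params, y)
            dev = 2.0 * float(np.sum(self._nll_terms(y, params)))
            trace.append(dev)
            if abs(trace[-2] - trace[-1]) < self.tol:
                break
        else:
            change = trace[-2] - trace[-1] if len(trace) > 1 else float("nan")
            raise ConvergenceError(
                f"centile model did not converge in {self.max_cycles} cycles "
                f"(last deviance change {change:.3g})", trace)

        self.curves_ = state
        self.n_obs_ = int(y.size)
        self.ga_range_ = (float(ga.min()), float(ga.max()))
        self.global_deviance_ = dev
        self.deviance_trace_ = trace
        df = sum(c.edf for c in state.values())
        below = 100.0 * np.mean(y < self.centile(ga, 3.0))
        above = 100.0 * np.mean(y > self.centile(ga, 97.0))
        self.report_ = FitReport(global_deviance=dev, df_total=float(df),
                                 n_obs=self.n_obs_, coverage_3rd=float(below),
                                 coverage_97th=float(above))
        return self

    def _init_coef(self, nm, sp, B, ga, y):
        """Least-squares projection of a sensible starting value."""
        if self.family in ("BCCG", "BCT", "BCPE"):
            cv = np.std(y) / max(np.mean(y), 1e-12)
            start = {"mu": y, "sigma": np.log(np.full_like(ga, max(cv, 1e-4))),
                     "nu": np.ones_like(ga),
                     "tau": np.full_like(ga, np.log(10.0) if self.family == "BCT"
                                         else np.log(2.0))}[nm]
        else:
            sdy = max(np.std(y), 1e-12)
            start = {"mu": y, "sigma": np.log(np.full_like(ga, sdy)),
                     "nu": np.zeros_like(ga),  # log(1) for SEP3/ST3
                     "tau": np.full_like(ga, np.log(10.0) if self.family == "ST3"
                                         else np.log(2.0))}[nm]
        coef, *_ = np.linalg.lstsq(B, start, rcond=None)
        return coef

    def _update_param(self, nm, sp, state, designs, etas, params, y):
        curve = state[nm]
        B = designs[nm]
        ncol = B.shape[1]
        pen = _diff_penalty(ncol) if sp.kind == "pspline" else np.zeros((ncol, ncol))

        def terms_at(eta_vec):
            trial = dict(params)
            trial[nm] = _invlink(curve.link, eta_vec)
            return self._nll_terms(y, trial)

        for _ in range(4):  # inner Newton steps per visit
            eta = etas[nm]
            h = 1e-4 * np.maximum(1.0, np.abs(eta))
            l0 = terms_at(eta)
            lp = terms_at(eta + h)
            lm = terms_at(eta - h)
            u = (lp - lm) / (2.0 * h)
            w = np.clip((lp - 2.0 * l0 + lm) / h**2, 1e-6, 1e8)

            if sp.kind == "pspline":
                lam = _solve_lambda(B, w, pen, sp.edf)
            else:
                lam = 0.0
            bwb = B.T @ (B * w[:, None])
            lhs = bwb + lam * pen + 1e-9 * np.eye(ncol)
            rhs = -(B.T @ u + lam * (pen @ curve.coefficients))
            try:
                step = np.linalg.solve(lhs, rhs)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(lhs, rhs, rcond=None)[0]

            valid0 = bool(np.all(l0 < 1e9))
            obj0 = float(np.sum(l0)) + 0.5 * lam * float(
                curve.coefficients @ pen @ curve.coefficients)
            scale = 1.0
            for _half in range(12):
                cand = curve.coefficients + scale * step
                eta_c = B @ cand
                terms_c = terms_at(eta_c)
                if valid0 and np.any(terms_c >= 1e9):
                    scale *= 0.5  # never step from a valid state into an invalid one
                    continue
                obj = float(np.sum(terms_c)) + 0.5 * lam * float(cand @ pen @ cand)
                if obj <= obj0 + 1e-12:
                    curve.coefficients = cand
                    etas[nm] = eta_c
                    params[nm] = _invlink(curve.link, eta_c)
                    break
                scale *= 0.5
            else:
                break  # no improving step; parameter is at a (local) optimum
            curve.lam = lam
            if sp.kind == "pspline":
                curve.edf = _edf(bwb, lam, pen)
            else:
                curve.edf = float(ncol)

    # -- evaluation ----------------------------------------------------------
    def params_at(self, ga) -> dict[str, np.ndarray]:
        return {nm: c(ga) for nm, c in self.curves_.items()}

    def centile(self, ga, centile: float):
        """Centile value(s) at GA from the fitted conditional distribution."""
        if not 0 < centile < 100:
            raise ValueError("centile must be strictly between 0 and 100")
        p = self.params_at(ga)
        vals = tuple(p[nm] for nm in _PARAM_NAMES[self.family])
        out = dist.family_quantile(self.family, vals, centile / 100.0)
        return float(out) if np.isscalar(ga) else out

    def predict(self, X):
        """Median at GA."""
        return self.centile(X, 50.0)

    def zscore(self, ga, y):
        """Normalized quantile residuals: z = Phi^-1(F(y | GA))."""
        p = self.params_at(ga)
        vals = tuple(p[nm] for nm in _PARAM_NAMES[self.family])
        u = dist.family_cdf(self.family, vals, np.asarray(y, dtype=float))
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        out = stats.norm.ppf(u)
        return float(out) if np.isscalar(y) else out

    def transform(self, X, y):
        return self.zscore(X, y)

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": "centile",
            "family": self.family,
            "n_obs": self.n_obs_,
            "ga_range": list(self.ga_range_),
            "global_deviance": self.global_deviance_,
            "curves": {nm: c.to_dict() for nm, c in self.curves_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CentileModel":
        model = cls(family=d["family"])
        model.curves_ = {nm: SmoothCurve.from_dict(cd) for nm, cd in d["curves"].items()}
        model.n_obs_ = int(d["n_obs"])
        model.ga_range_ = tuple(d["ga_range"])
        model.global_deviance_ = float(d["global_deviance"])
        return model


def _raw_logpdf(family, vals, y):
    """Per-observation log density without parameter validation (the
    optimizer may probe invalid regions; those come back as -inf/nan)."""
    if family == "NO":
        return stats.norm.logpdf(y, loc=vals[0], scale=vals[1])
    if family == "PE":
        mu, sigma, tau = vals
        return dist._pe_logpdf((y - mu) / sigma, tau) - np.log(sigma)
    if family in ("BCCG", "BCT", "BCPE"):
        mu = np.asarray(vals[0], dtype=float)
        if np.any(mu <= 0):
            return np.full_like(y, -np.inf)
        return dist._bc_logpdf(family, y, *vals)
    if family == "SEP3":
        return dist._sep3_logpdf(y, *vals)
    if family == "ST3":
        return dist._st3_logpdf(y, *vals)
    raise ValueError(family)


def _edf(bwb: np.ndarray, lam: float, pen: np.ndarray) -> float:
    ncol = bwb.shape[0]
    try:
        h = np.linalg.solve(bwb + lam * pen + 1e-9 * np.eye(ncol), bwb)
    except np.linalg.LinAlgError:
        return float(ncol)
    return float(np.trace(h))


def _solve_lambda(B, w, pen, target_edf: float) -> float:
    """Bisection on log-lambda so tr of the smoother hat matrix hits the
    requested (possibly fractional) edf.

    The bracket is scaled by tr(B'WB)/tr(P) so the search stays in the
    numerically trustworthy range of the linear solves; at the upper cap
    the edf is within ~1e-3 of the penalty null-space dimension (2 for a
    second-difference penalty), which is the smallest reachable target.
    """
    bwb = B.T @ (B * w[:, None])
    ncol = B.shape[1]
    if target_edf >= ncol:
        return 0.0
    unit = max(np.trace(bwb), 1e-300) / np.trace(pen)
    lo, hi = np.log10(unit) - 8.0, np.log10(unit) + 8.0
    if _edf(bwb, 10.0**lo, pen) < target_edf:
        return 10.0**lo
    if _edf(bwb, 10.0**hi, pen) > target_edf:
        return 10.0**hi
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _edf(bwb, 10.0**mid, pen) > target_edf:
            lo = mid
        else:
            hi = mid
    return 10.0 ** (0.5 * (lo + hi))


def fit_centile_model(ga, y, family: str = "BCCG", curves: dict | None = None,
                      tol: float = 1e-4, max_cycles: int = 500) -> CentileModel:
    """Fit a centile model (functional wrapper); the fit report is in
    ``model.report_``."""
    return CentileModel(family=family, curves=curves, tol=tol,
                        max_cycles=max_cycles).fit(ga, y)


def stepwise_class_selection(ga, y, candidates: dict[int, list], k: float = 2.0,
                             margin: float = 0.0):
    """Add-up stepwise selection across model classes of increasing
    parameter count.

    ``candidates`` maps a class label (number of distribution
    parameters, e.g. 2, 3, 4) to a list of ``(family, curves)`` pairs.
    The best model in each class by GAIC(k) is found; starting from the
    simplest class, a more complex class is adopted only if its best
    GAIC improves on the incumbent by more than ``margin``.

    Returns ``(table, chosen_model)`` where ``table`` is a list of row
    dicts (one per fitted candidate, ranked by GAIC) so that
    non-statistical criteria can override the automatic choice.
    """
    rows = []
    fits = {}
    for label in sorted(candidates):
        group = candidates[label]
        if not group:
            logger.warning("candidate class %s is empty; skipped", label)
            continue
        for family, curves in group:
            try:
                model = fit_centile_model(ga, y, family=family, curves=curves)
            except (ConvergenceError, RuntimeError, ValueError) as exc:
                logger.warning("candidate %s/%s failed: %s", label, family, exc)
                continue
            rep = model.report_
            row = {"class": label, "family": family,
                   "global_deviance": rep.global_deviance, "df": rep.df_total,
                   "aic": rep.aic, "bic": rep.bic, "gaic": rep.gaic(k),
                   "coverage_3rd": rep.coverage_3rd,
                   "coverage_97th": rep.coverage_97th}
            rows.append(row)
            fits[id(row)] = model
    if not rows:
        raise RuntimeError("no candidate model could be fitted")

    best_per_class = {}
    for row in rows:
        cur = best_per_class.get(row["class"])
        if cur is None or row["gaic"] < cur["gaic"]:
            best_per_class[row["class"]] = row
    chosen = None
    for label in sorted(best_per_class):
        row = best_per_class[label]
        if chosen is None or row["gaic"] < chosen["gaic"] - margin:
            chosen = row
    rows.sort(key=lambda r: r["gaic"])
    return rows, fits[id(chosen)]
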