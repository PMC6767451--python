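"""Distribution families for centile modelling, and the LMS equations.

Families follow the GAMLSS parameterizations:

NO(mu, sigma)
    Normal with mean mu and SD sigma.
PE(mu, sigma, tau)
    Power exponential; tau > 0 is the kurtosis power (tau = 2 is normal,
    tau < 2 leptokurtic, tau > 2 platykurtic).  Scaled so Var = sigma**2.
BCCG(mu, sigma, nu)
    Box-Cox Cole-Green: mu > 0 is the median, sigma the coefficient of
    variation, nu the Box-Cox power; the transformed variable

        z = ((y/mu)**nu - 1) / (nu*sigma)      nu != 0
        z = log(y/mu) / sigma                  nu == 0

    is standard normal truncated to the region where y > 0 and
    renormalized.  This is the distributional form of the LMS method.
BCT(mu, sigma, nu, tau)
    As BCCG but z follows a (truncated) t distribution with tau df;
    models leptokurtosis on top of skewness (the LMST method).
BCPE(mu, sigma, nu, tau)
    As BCCG but z follows a (truncated) standard power exponential with
    power tau; models any kurtosis (the LMSP method).
SEP3(mu, sigma, nu, tau)
    Skew exponential power type 3: two-piece power exponential with
    scale factors nu below the mode and 1/nu above (Fernandez-Steel
    skewing); nu = 1, tau = 2 recovers the normal.
ST3(mu, sigma, nu, tau)
    Skew t type 3: two-piece t with tau df, skewed the same way;
    nu = 1 with large tau approaches the normal.

All quantile functions are analytic inverses (via the normal, t and
incomplete-gamma quantiles), so cdf/quantile round-trips hold to near
machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

FAMILIES: dict[str, int] = {
    "NO": 2, "PE": 3, "BCCG": 3, "BCT": 4, "BCPE": 4, "SEP3": 4, "ST3": 4,
}

#: |L| below this is treated as the log-normal (L = 0) branch
_L_TOL = 1e-8


@dataclass(frozen=True)
class ParamVector:
    """Parameter values of one family at one age."""

    family: str
    mu: float
    sigma: float
    nu: float | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        validate_params(self.family, self.mu, self.sigma, self.nu, self.tau)

    def as_tuple(self) -> tuple[float, ...]:
        k = FAMILIES[self.family]
        vals = (self.mu, self.sigma, self.nu, self.tau)[:k]
        return tuple(float(v) for v in vals)


def validate_params(family, mu, sigma, nu=None, tau=None) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    k = FAMILIES[family]
    given = [mu, sigma, nu, tau]
    if any(v is None for v in given[:k]):
        raise ValueError(f"family {family} needs {k} parameters (mu, sigma, nu, tau order)")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be > 0")
    if family in ("BCCG", "BCT", "BCPE") and np.any(np.asarray(mu) <= 0):
        raise ValueError(f"mu must be > 0 for {family}")
    if family == "PE" and np.any(np.asarray(nu) <= 0):
        raise ValueError("PE power parameter must be > 0")
    if k == 4 and np.any(np.asarray(tau) <= 0):
        raise ValueError(f"tau must be > 0 for {family}")
    if family in ("SEP3", "ST3") and np.any(np.asarray(nu) <= 0):
        raise ValueError(f"nu must be > 0 for {family}")


def _unpack(family, params):
    if isinstance(params, ParamVector):
        if params.family != family:
            raise ValueError("ParamVector family does not match")
        params = params.as_tuple()
    k = FAMILIES.get(family)
    if k is None:
        raise ValueError(f"unknown family {family!r}")
    params = tuple(np.asarray(p, dtype=float) for p in params)
    if len(params) != k:
        raise ValueError(f"family {family} takes {k} parameters, got {len(params)}")
    full = params + (None,) * (4 - k)
    validate_params(family, *full)
    return params


# --- power exponential building blocks -------------------------------------

def _pe_c(tau):
    """Scale constant making PE(0, 1, tau) have unit variance."""
    lg = special.gammaln(1.0 / tau) - special.gammaln(3.0 / tau)
    return np.exp(0.5 * lg)


def _pe_logpdf(z, tau):
    c = _pe_c(tau)
    return (np.log(tau) - np.abs(z / c) ** tau
            - np.log(2.0 * c) - special.gammaln(1.0 / tau))


def _pe_cdf(z, tau):
    c = _pe_c(tau)
    g = special.gammainc(1.0 / tau, np.abs(z / c) ** tau)
    return np.where(z >= 0, 0.5 * (1.0 + g), 0.5 * (1.0 - g))


def _pe_ppf(p, tau):
    p = np.asarray(p, dtype=float)
    c = _pe_c(tau)
    g = np.abs(2.0 * p - 1.0)
    z = c * special.gammaincinv(1.0 / tau, g) ** (1.0 / tau)
    return np.where(p >= 0.5, z, -z)


# --- the Box-Cox transform shared by BCCG / BCT / BCPE ----------------------

def _boxcox_z(y, mu, sigma, nu):
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox families are defined for y > 0")
    nu = np.asarray(nu, dtype=float)
    ratio = y / mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z_pow = (ratio**nu - 1.0) / (nu * sigma)
    z_log = np.log(ratio) / sigma
    return np.where(np.abs(nu) < _L_TOL, z_log, z_pow)


def _bc_trunc_bound(sigma, nu):
    """Upper truncation bound 1/(sigma*|nu|) of z (inf when nu ~ 0)."""
    nu = np.asarray(nu, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(np.abs(nu) < _L_TOL, np.inf, 1.0 / (sigma * np.abs(nu)))


def _bc_machinery(family):
    """(cdf, ppf, logpdf) of the un-truncated z distribution."""
    if family == "BCCG":
        return (lambda z, tau: stats.norm.cdf(z),
                lambda p, tau: stats.norm.ppf(p),
                lambda z, tau: stats.norm.logpdf(z))
    if family == "BCT":
        return (lambda z, tau: stats.t.cdf(z, df=tau),
                lambda p, tau: stats.t.ppf(p, df=tau),
                lambda z, tau: stats.t.logpdf(z, df=tau))
    if family == "BCPE":
        return (_pe_cdf, _pe_ppf, _pe_logpdf)
    raise ValueError(family)


def _bc_cdf(family, y, mu, sigma, nu, tau=None):
    zcdf, _, _ = _bc_machinery(family)
    z = _boxcox_z(y, mu, sigma, nu)
    bound = _bc_trunc_bound(sigma, nu)
    lower = np.where(np.asarray(nu) > 0, zcdf(-bound, tau), 0.0)
    return np.clip((zcdf(z, tau) - lower) / zcdf(bound, tau), 0.0, 1.0)


def _bc_ppf(family, p, mu, sigma, nu, tau=None):
    _, zppf, _ = _bc_machinery(family)
    zcdf = _bc_machinery(family)[0]
    p = np.asarray(p, dtype=float)
    bound = _bc_trunc_bound(sigma, nu)
    lower = np.where(np.asarray(nu) > 0, zcdf(-bound, tau), 0.0)
    z = zppf(p * zcdf(bound, tau) + lower, tau)
    return _boxcox_inverse(z, mu, sigma, nu)


def _boxcox_inverse(z, mu, sigma, nu):
    nu = np.asarray(nu, dtype=float)
    with np.errstate(invalid="ignore"):
        inner = 1.0 + nu * sigma * np.asarray(z, dtype=float)
        y_pow = mu * np.sign(inner) * np.abs(inner) ** (1.0 / np.where(nu == 0, 1.0, nu))
    y_log = mu * np.exp(sigma * np.asarray(z, dtype=float))
    out = np.where(np.abs(nu) < _L_TOL, y_log, y_pow)
    if np.any(inner <= 0) and np.any(np.abs(nu) >= _L_TOL):
        bad = (inner <= 0) & (np.abs(nu) >= _L_TOL)
        if np.any(bad):
            raise ValueError("requested quantile falls outside the Box-Cox support")
    return out


def _bc_logpdf(family, y, mu, sigma, nu, tau=None):
    _, _, zlogpdf = _bc_machinery(family)
    zcdf = _bc_machinery(family)[0]
    y = np.asarray(y, dtype=float)
    z = _boxcox_z(y, mu, sigma, nu)
    bound = _bc_trunc_bound(sigma, nu)
    nu = np.asarray(nu, dtype=float)
    # Jacobian: dz/dy = y**(nu-1) / (mu**nu * sigma); nu -> 0 gives 1/(y*sigma)
    with np.errstate(divide="ignore"):
        logjac = np.where(
            np.abs(nu) < _L_TOL,
            -np.log(y) - np.log(sigma),
            (nu - 1.0) * np.log(y) - nu * np.log(mu) - np.log(sigma),
        )
    lower = np.where(nu > 0, zcdf(-bound, tau), 0.0)
    lognorm = np.log(zcdf(bound, tau) - lower)
    return zlogpdf(z, tau) + logjac - lognorm


# --- two-piece (type 3) skew families --------------------------------------

def _sep3_cdf(y, mu, sigma, nu, tau):
    z = (np.asarray(y, dtype=float) - mu) / sigma
    k = 1.0 / (1.0 + nu**2)
    s_lo = special.gammainc(1.0 / tau, 0.5 * np.abs(nu * z) ** tau)
    s_hi = special.gammainc(1.0 / tau, 0.5 * np.abs(z / nu) ** tau)
    return np.where(z < 0, k * (1.0 - s_lo), k + (1.0 - k) * s_hi)


def _sep3_ppf(p, mu, sigma, nu, tau):
    p = np.asarray(p, dtype=float)
    k = 1.0 / (1.0 + nu**2)
    g_lo = special.gammaincinv(1.0 / tau, np.clip(1.0 - p / k, 0.0, 1.0))
    z_lo = -((2.0 * g_lo) ** (1.0 / tau)) / nu
    g_hi = special.gammaincinv(1.0 / tau, np.clip((p - k) / (1.0 - k), 0.0, 1.0))
    z_hi = nu * (2.0 * g_hi) ** (1.0 / tau)
    z = np.where(p < k, z_lo, z_hi)
    return mu + sigma * z


def _sep3_logpdf(y, mu, sigma, nu, tau):
    z = (np.asarray(y, dtype=float) - mu) / sigma
    logc = (np.log(tau) + np.log(nu) - np.log1p(nu**2)
            - (1.0 / tau) * np.log(2.0) - special.gammaln(1.0 / tau))
    core = np.where(z < 0, -0.5 * np.abs(nu * z) ** tau, -0.5 * np.abs(z / nu) ** tau)
    return logc - np.log(sigma) + core


def _st3_cdf(y, mu, sigma, nu, tau):
    z = (np.asarray(y, dtype=float) - mu) / sigma
    k = 1.0 / (1.0 + nu**2)
    lo = 2.0 * k * stats.t.cdf(nu * z, df=tau)
    hi = k + 2.0 * (1.0 - k) * (stats.t.cdf(z / nu, df=tau) - 0.5)
    return np.where(z < 0, lo, hi)


def _st3_ppf(p, mu, sigma, nu, tau):
    p = np.asarray(p, dtype=float)
    k = 1.0 / (1.0 + nu**2)
    z_lo = stats.t.ppf(np.clip(p / (2.0 * k), 0.0, 1.0), df=tau) / nu
    z_hi = nu * stats.t.ppf(np.clip((p - k) / (2.0 * (1.0 - k)) + 0.5, 0.0, 1.0), df=tau)
    z = np.where(p < k, z_lo, z_hi)
    return mu + sigma * z


def _st3_logpdf(y, mu, sigma, nu, tau):
    z = (np.asarray(y, dtype=float) - mu) / sigma
    logc = np.log(2.0) + np.log(nu) - np.log1p(nu**2)
    core = np.where(z < 0, stats.t.logpdf(nu * z, df=tau), stats.t.logpdf(z / nu, df=tau))
    return logc - np.log(sigma) + core


# --- public family interface ------------------------------------------------

def family_logpdf(family, params, y):
    p = _unpack(family, params)
    y = np.asarray(y, dtype=float)
    if family == "NO":
        return stats.norm.logpdf(y, loc=p[0], scale=p[1])
    if family == "PE":
        mu, sigma, tau = p
        return _pe_logpdf((y - mu) / sigma, tau) - np.log(sigma)
    if family in ("BCCG", "BCT", "BCPE"):
        return _bc_logpdf(family, y, *p)
    if family == "SEP3":
        return _sep3_logpdf(y, *p)
    if family == "ST3":
        return _st3_logpdf(y, *p)
    raise ValueError(family)


def family_pdf(family, params, y):
    return np.exp(family_logpdf(family, params, y))


def family_cdf(family, params, y):
    p = _unpack(family, params)
    y = np.asarray(y, dtype=float)
    if family == "NO":
        return stats.norm.cdf(y, loc=p[0], scale=p[1])
    if family == "PE":
        mu, sigma, tau = p
        return _pe_cdf((y - mu) / sigma, tau)
    if family in ("BCCG", "BCT", "BCPE"):
        return _bc_cdf(family, y, *p)
    if family == "SEP3":
        return _sep3_cdf(y, *p)
    if family == "ST3":
        return _st3_cdf(y, *p)
    raise ValueError(family)


def family_quantile(family, params, prob):
    p = _unpack(family, params)
    prob = np.asarray(prob, dtype=float)
    if np.any((prob <= 0) | (prob >= 1)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    if family == "NO":
        return stats.norm.ppf(prob, loc=p[0], scale=p[1])
    if family == "PE":
        mu, sigma, tau = p
        return mu + sigma * _pe_ppf(prob, tau)
    if family in ("BCCG", "BCT", "BCPE"):
        return _bc_ppf(family, prob, *p)
    if family == "SEP3":
        return _sep3_ppf(prob, *p)
    if family == "ST3":
        return _st3_ppf(prob, *p)
    raise ValueError(family)


def family_random(family, params, size, seed=None):
    """Random deviates by inverse-CDF sampling; reproducible from seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(1e-12, 1.0 - 1e-12, size=size)
    return family_quantile(family, params, u)


# --- the LMS equations ------------------------------------------------------

@dataclass(frozen=True)
class LMSTriple:
    """The L (Box-Cox power), M (median) and S (CV) values at one age."""

    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("M (median) must be > 0")
        if self.S <= 0:
            raise ValueError("S (coefficient of variation) must be > 0")


def lms_centile(triple: LMSTriple, centile: float) -> float:
    """Centile value from (L, M, S).

    ``M * (1 + L*S*z)**(1/L)`` for L != 0 and ``M * exp(S*z)`` for L = 0,
    where z is the normal equivalent deviate of the centile.  The two
    branches join continuously as |L| -> 0.
    """
    if not 0 < centile < 100:
        raise ValueError("centile must be strictly between 0 and 100")
    z = stats.norm.ppf(centile / 100.0)
    L, M, S = triple.L, triple.M, triple.S
    if abs(L) < _L_TOL:
        return float(M * np.exp(S * z))
    inner = 1.0 + L * S * z
    if inner <= 0:
        raise ValueError(
            f"centile {centile} is outside the Box-Cox support (1 + L*S*z = {inner:.3g})"
        )
    return float(M * inner ** (1.0 / L))


def lms_sds(y: float, triple: LMSTriple) -> float:
    """SD score of a measurement given (L, M, S); exact inverse of
    :func:`lms_centile`: ``((y/M)**L - 1)/(L*S)`` for L != 0 and
    ``log(y/M)/S`` for L = 0."""
    if y <= 0:
        raise ValueError("measurement must be > 0")
    L, M, S = triple.L, triple.M, triple.S
    if abs(L) < _L_TOL:
        return float(np.log(y / M) / S)
    return float(((y / M) ** L - 1.0) / (L * S))
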