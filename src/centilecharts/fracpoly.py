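"""Fractional polynomials of gestational age.

A fractional polynomial (FP) of degree ``m`` for a positive covariate ``x``
is the linear predictor

    FPm(x) = b0 + b1 * x**p1 + ... + bm * x**pm

with powers drawn from the restricted set {-2, -1, -0.5, 0, 0.5, 1, 2, 3},
where the power 0 denotes ln(x) rather than the constant, and a power
repeated r times contributes the columns x**p * ln(x)**j for j = 0..r-1.
FP1 curves are always monotonic; FP2 curves may have a single turning
point, which is usually ample flexibility for size-for-age curves.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

#: the restricted power set of fractional-polynomial regression
POWER_SET: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FPSpec:
    """A fitted fractional-polynomial curve.

    Parameters
    ----------
    powers : tuple of float
        Non-decreasing powers from :data:`POWER_SET`; 0 means ln(x).
    coefficients : ndarray
        Length ``len(powers) + 1``; intercept first.
    scale_shift : float, default 0
        Offset added to the covariate before powering (must leave it
        positive on the data).
    """

    powers: tuple[float, ...]
    coefficients: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale_shift: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "powers", tuple(float(p) for p in self.powers))
        _validate_powers(self.powers)
        if self.degree < 1:
            raise ValueError("FP degree must be >= 1")
        if self.coefficients is not None:
            coef = np.asarray(self.coefficients, dtype=float)
            if coef.shape != (self.degree + 1,):
                raise ValueError(
                    f"expected {self.degree + 1} coefficients (intercept first), "
                    f"got shape {coef.shape}"
                )
            object.__setattr__(self, "coefficients", coef)
        if self.scale_shift < 0:
            raise ValueError("scale_shift must be non-negative")

    @property
    def degree(self) -> int:
        return len(self.powers)

    def design(self, x: np.ndarray) -> np.ndarray:
        """Design matrix [1, basis columns] at covariate ``x``."""
        x = np.asarray(x, dtype=float)
        basis = fp_basis(x + self.scale_shift, self.powers)
        return np.column_stack([np.ones(basis.shape[0]), basis])

    def __call__(self, x) -> np.ndarray:
        """Evaluate the fitted curve at ``x``."""
        if self.coefficients is None:
            raise ValueError("FPSpec has no coefficients; fit it first")
        scalar = np.isscalar(x)
        out = self.design(np.atleast_1d(np.asarray(x, dtype=float))) @ self.coefficients
        return float(out[0]) if scalar else out

    def to_dict(self) -> dict:
        return {
            "powers": list(self.powers),
            "coefficients": [float(c) for c in self.coefficients],
            "scale_shift": self.scale_shift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FPSpec":
        return cls(
            powers=tuple(d["powers"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            scale_shift=float(d.get("scale_shift", 0.0)),
        )


def _validate_powers(powers: Sequence[float]) -> None:
    for p in powers:
        if not any(np.isclose(p, q) for q in POWER_SET):
            raise ValueError(f"power {p} not in the restricted set {POWER_SET}")
    if any(a > b for a, b in zip(powers, powers[1:])):
        raise ValueError(f"powers must be non-decreasing, got {tuple(powers)}")


def fp_basis(x: np.ndarray, powers: Sequence[float]) -> np.ndarray:
    """Fractional-polynomial basis columns (no intercept).

    Column j is ``x**p_j`` with the convention that power 0 means
    ``ln(x)``, and that a power repeated r times yields the columns
    ``x**p * ln(x)**0 .. ln(x)**(r-1)``; e.g. powers (0, 2, 2) give
    ln(x), x**2, x**2 * ln(x).

    Parameters
    ----------
    x : array-like, strictly positive
    powers : non-decreasing tuple from the restricted power set
    """
    x = np.asarray(x, dtype=float)
    powers = tuple(float(p) for p in powers)
    _validate_powers(powers)
    if x.ndim != 1:
        x = np.ravel(x)
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("fractional polynomials require strictly positive finite x")
    logx = np.log(x)
    cols = []
    rep = 0
    for j, p in enumerate(powers):
        rep = rep + 1 if j > 0 and powers[j - 1] == p else 1
        base = logx if p == 0 else x**p
        cols.append(base * logx ** (rep - 1) if rep > 1 else base)
    return np.column_stack(cols)


def enumerate_fp_models(degree: int) -> list[tuple[float, ...]]:
    """All canonical (non-decreasing) power tuples of the given degree.

    Repeats are allowed, so the counts are C(8+m-1, m): 8 for FP1,
    36 for FP2, 120 for FP3.
    """
    if degree not in (1, 2, 3):
        raise ValueError("FP degree must be 1, 2 or 3")
    return list(itertools.combinations_with_replacement(POWER_SET, degree))


class FractionalPolynomial(RegressorMixin, BaseEstimator):
    """Least-squares fractional-polynomial regression with best-power search.

    Exhaustively fits every canonical power tuple of the requested degree
    (or only ``powers`` if given) by (weighted) ordinary least squares and
    keeps the one with the smallest residual deviance.  Ties are broken by
    the lexicographically smallest power tuple, and candidates whose basis
    is numerically rank-deficient on the data are skipped with a warning.

    Parameters
    ----------
    degree : int, default 2
        FP order m (1, 2 or 3) searched when ``powers`` is None.
    powers : tuple of float, optional
        Fix the powers instead of searching.
    scale_shift : float, default 0
        Offset added to x before powering.

    Attributes
    ----------
    spec_ : FPSpec
        The selected powers and coefficients.
    rss_ : float
        Residual sum of squares of the selected model.
    deviance_ : float
        Gaussian residual deviance, ``n * log(rss / n)`` up to a constant.
    """

    def __init__(self, degree: int = 2, powers: tuple[float, ...] | None = None,
                 scale_shift: float = 0.0):
        self.degree = degree
        self.powers = powers
        self.scale_shift = scale_shift

    def fit(self, X, y, sample_weight=None):
        x = _as_1d(X, "X")
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if self.powers is not None:
            candidates = [tuple(float(p) for p in self.powers)]
            _validate_powers(candidates[0])
        else:
            candidates = enumerate_fp_models(self.degree)
        m = len(candidates[0])
        if x.size < m + 2:
            raise ValueError(f"need at least {m + 2} observations for an FP{m} fit")
        w = None
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float).ravel()
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
        xs = x + self.scale_shift
        if np.any(xs <= 0):
            raise ValueError("covariate must be positive after scale_shift")

        best = None
        for powers in candidates:
            try:
                design = np.column_stack([np.ones(xs.size), fp_basis(xs, powers)])
                coef, rss, rank = _wls(design, y, w)
            except (np.linalg.LinAlgError, ValueError):
                logger.warning("FP candidate %s failed numerically; skipped", powers)
                continue
            if rank < design.shape[1]:
                logger.warning("FP candidate %s rank-deficient; skipped", powers)
                continue
            # strict '<' keeps the lexicographically smallest tuple on ties
            if best is None or rss < best[0] - 1e-12 * max(1.0, best[0]):
                best = (rss, powers, coef)
        if best is None:
            raise RuntimeError("every fractional-polynomial candidate failed to fit")
        rss, powers, coef = best
        n = x.size
        self.spec_ = FPSpec(powers=powers, coefficients=coef,
                            scale_shift=self.scale_shift)
        self.rss_ = float(rss)
        self.deviance_ = float(n * np.log(max(rss, 1e-300) / n))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = _as_1d(X, "X")
        return self.spec_(x)


def _as_1d(X, name: str) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-d (or a single-column 2-d array)")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def _wls(design: np.ndarray, y: np.ndarray, w: np.ndarray | None):
    """Weighted least squares; returns (coef, weighted rss, rank)."""
    if w is None:
        a, b = design, y
    else:
        sw = np.sqrt(w)
        a, b = design * sw[:, None], y * sw
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coef, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    resid = b - a @ coef
    return coef, float(resid @ resid), int(rank)


def fit_fp(x, y, weights=None, degree: int = 2,
           powers: tuple[float, ...] | None = None,
           scale_shift: float = 0.0) -> FractionalPolynomial:
    """Functional wrapper around :class:`FractionalPolynomial`."""
    return FractionalPolynomial(degree=degree, powers=powers,
                                scale_shift=scale_shift).fit(x, y, weights)
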