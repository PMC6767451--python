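"""Model-fit diagnostics for centile models.

Worm plots (detrended normal Q-Q plots by age group), plain Q-Q data,
residual-versus-age data, empirical centile coverage with exact binomial
intervals, and model-comparison tables.  All functions return plain data
structures; rendering is a thin optional layer (:func:`plot_worm`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def blom_positions(n: int) -> np.ndarray:
    """Blom plotting positions (i - 3/8) / (n + 1/4), i = 1..n."""
    i = np.arange(1, n + 1)
    return (i - 0.375) / (n + 0.25)


def qq_data(zscores) -> np.ndarray:
    """Ordered (theoretical, empirical) normal Q-Q pairs at Blom positions."""
    z = np.sort(np.asarray(zscores, dtype=float))
    if z.size < 2:
        raise ValueError("need at least 2 z-scores for a Q-Q plot")
    theo = stats.norm.ppf(blom_positions(z.size))
    return np.column_stack([theo, z])


@dataclass
class WormGroup:
    """One panel of a worm plot."""

    ga_low: float
    ga_high: float
    n: int
    theoretical: np.ndarray
    deviation: np.ndarray          # empirical minus theoretical quantile
    cubic_coef: np.ndarray         # least-squares cubic, highest degree first

    @property
    def max_abs_deviation(self) -> float:
        return float(np.max(np.abs(self.deviation)))


@dataclass
class WormPlotData:
    groups: list[WormGroup]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for t, d in zip(g.theoretical, g.deviation):
                rows.append({"ga_low": g.ga_low, "ga_high": g.ga_high,
                             "theoretical": t, "deviation": d})
        return pd.DataFrame(rows)


def worm_data(zscores, ga, n_groups: int = 9, min_group_size: int = 10) -> WormPlotData:
    """Detrended Q-Q (worm) data by equal-count GA groups.

    Within each group the deviations are ordered z-scores minus the
    theoretical normal quantiles at Blom positions; a flat worm around
    zero indicates the model fits in that age band.  A cubic is fitted
    to each worm by least squares (its leading coefficient picks up
    tail heaviness).  Groups with fewer than ``min_group_size`` points
    are merged with a neighbour.
    """
    z = np.asarray(zscores, dtype=float)
    ga = np.asarray(ga, dtype=float)
    if z.shape != ga.shape:
        raise ValueError("zscores and ga must have the same length")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    edges = np.quantile(ga, np.linspace(0, 1, n_groups + 1))
    edges = np.unique(edges)
    edges[-1] = np.nextafter(edges[-1], np.inf)

    # assign and merge undersized bins with their left neighbour
    idx = np.clip(np.searchsorted(edges, ga, side="right") - 1, 0, len(edges) - 2)
    bins: list[np.ndarray] = [np.flatnonzero(idx == b) for b in range(len(edges) - 1)]
    merged: list[np.ndarray] = []
    for b, members in enumerate(bins):
        if merged and (members.size < min_group_size or
                       (merged and len(merged[-1]) < min_group_size)):
            logger.info("worm group %d merged with neighbour (n=%d)", b, members.size)
            merged[-1] = np.concatenate([merged[-1], members])
        else:
            merged.append(members)
    if len(merged) > 1 and merged[-1].size < min_group_size:
        tail = merged.pop()
        merged[-1] = np.concatenate([merged[-1], tail])

    groups = []
    for members in merged:
        if members.size == 0:
            continue
        zz = np.sort(z[members])
        theo = stats.norm.ppf(blom_positions(zz.size))
        dev = zz - theo
        coef = (np.polyfit(theo, dev, 3) if zz.size >= 4
                else np.zeros(4))
        groups.append(WormGroup(ga_low=float(ga[members].min()),
                                ga_high=float(ga[members].max()),
                                n=int(members.size), theoretical=theo,
                                deviation=dev, cubic_coef=coef))
    return WormPlotData(groups=groups)


def residuals_by_age(ga, residuals) -> pd.DataFrame:
    """Residual-versus-age data (for scatter diagnostics)."""
    ga = np.asarray(ga, dtype=float)
    r = np.asarray(residuals, dtype=float)
    if ga.shape != r.shape:
        raise ValueError("ga and residuals must have the same length")
    return pd.DataFrame({"ga_weeks": ga, "residual": r}).sort_values(
        "ga_weeks").reset_index(drop=True)


def coverage(model_centile_fn, ga, values, centiles=(3.0, 97.0)) -> pd.DataFrame:
    """Empirical centile coverage with exact binomial 95% intervals.

    For each requested centile c the observed percentage strictly below
    the fitted centile is reported (for c > 50 also the percentage
    strictly above, the usual tail check).  ``model_centile_fn(ga, c)``
    must return the fitted centile values at the observation ages.
    """
    ga = np.asarray(ga, dtype=float)
    values = np.asarray(values, dtype=float)
    n = values.size
    rows = []
    for c in centiles:
        fitted = np.asarray(model_centile_fn(ga, float(c)), dtype=float)
        below = int(np.sum(values < fitted))
        above = int(np.sum(values > fitted))
        count = above if c > 50 else below
        tail = "above" if c > 50 else "below"
        expected = (100.0 - c) if c > 50 else c
        ci = stats.binomtest(count, n).proportion_ci(0.95)
        rows.append({"centile": float(c), "tail": tail, "expected_pct": expected,
                     "observed_pct": 100.0 * count / n, "count": count, "n": n,
                     "ci_low_pct": 100.0 * ci.low, "ci_high_pct": 100.0 * ci.high})
    return pd.DataFrame(rows, columns=["centile", "tail", "expected_pct",
                                       "observed_pct", "count", "n",
                                       "ci_low_pct", "ci_high_pct"])


def comparison_table(reports, names=None, criterion: str = "gaic", k: float = 2.0,
                     offset: float = 0.0) -> pd.DataFrame:
    """Rank FitReports by an information criterion.

    All reports must come from the same dataset (same n); ``offset`` is
    subtracted from deviance/AIC/BIC columns at presentation only
    (tables are often printed as 'deviance - 11000').
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no reports given")
    ns = {r.n_obs for r in reports}
    if len(ns) > 1:
        raise ValueError(f"reports come from different datasets (n = {sorted(ns)})")
    if names is None:
        names = [f"model_{i + 1}" for i in range(len(reports))]
    rows = []
    for nm, r in zip(names, reports):
        rows.append({"model": nm, "global_deviance": r.global_deviance - offset,
                     "df": r.df_total, "aic": r.aic - offset, "bic": r.bic - offset,
                     "gaic": r.gaic(k) - offset, "coverage_3rd": r.coverage_3rd,
                     "coverage_97th": r.coverage_97th})
    table = pd.DataFrame(rows)
    key = {"gaic": "gaic", "aic": "aic", "bic": "bic",
           "deviance": "global_deviance"}[criterion]
    return table.sort_values(key, kind="mergesort").reset_index(drop=True)


def plot_worm(data: WormPlotData, path=None):  # pragma: no cover - thin plotting layer
    """Render a worm plot grid to a matplotlib figure (optional layer)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(data.groups)
    ncols = int(np.ceil(np.sqrt(k)))
    nrows = int(np.ceil(k / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.5 * nrows),
                             squeeze=False)
    for ax, g in zip(axes.ravel(), data.groups):
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.plot(g.theoretical, g.deviation, ".", ms=3)
        xs = np.linspace(g.theoretical.min(), g.theoretical.max(), 100)
        ax.plot(xs, np.polyval(g.cubic_coef, xs), "r-", lw=1)
        ax.set_title(f"GA {g.ga_low:.1f}-{g.ga_high:.1f} (n={g.n})", fontsize=8)
    for ax in axes.ravel()[k:]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
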