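"""Reading growth records, and writing chart tables and model files.

Two canonical CSV dialects (no format sniffing):

* cross-sectional — columns ``id, sex, ga_weeks, value`` (one row per
  subject);
* longitudinal — columns ``id, visit, replicate, ga_weeks, value`` (one
  row per individual measurement; replicates of a visit share one GA).

GA is exact decimal weeks throughout; completed weeks appear only in
presentation.  Chart tables are CSV with a ``#``-prefixed metadata
header; model files are JSON and round-trip bit-exact centile
evaluations.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import multilevel
from .fracpoly import FPSpec
from .gamlss import CentileModel
from .meansd import MeanSDModel

logger = logging.getLogger(__name__)

_COLUMNS = {
    "crosssec": ["id", "sex", "ga_weeks", "value"],
    "longitudinal": ["id", "visit", "replicate", "ga_weeks", "value"],
}


class SchemaError(ValueError):
    pass


@dataclass
class ValidationReport:
    n_read: int = 0
    n_valid: int = 0
    row_errors: list = field(default_factory=list)

    def log(self) -> None:
        for line, msg in self.row_errors:
            logger.warning("row %d rejected: %s", line, msg)


def read_records(path, dialect: str = "crosssec"):
    """Read and validate a records CSV.

    Returns ``(records, report)``; rows failing validation are dropped
    and reported with their line numbers.  Missing required columns, or
    duplicate (id, visit, replicate) keys / GA varying within a visit
    in the longitudinal dialect, raise :class:`SchemaError`.
    """
    if dialect not in _COLUMNS:
        raise ValueError("dialect must be 'crosssec' or 'longitudinal'")
    cols = _COLUMNS[dialect]
    df = pd.read_csv(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    df = df[cols]
    report = ValidationReport(n_read=len(df))

    ga = pd.to_numeric(df["ga_weeks"], errors="coerce")
    val = pd.to_numeric(df["value"], errors="coerce")
    bad = ga.isna() | (ga <= 0)
    if dialect == "crosssec":
        bad |= val.isna()
    for i in df.index[bad]:
        reason = "non-numeric or non-positive ga_weeks" if not (ga[i] > 0) \
            else "non-numeric value"
        report.row_errors.append((int(i) + 2, reason))  # +2: header + 1-based
    df = df[~bad].copy()
    df["ga_weeks"] = ga[~bad]
    df["value"] = val[~bad]

    if dialect == "longitudinal":
        key = ["id", "visit", "replicate"]
        dup = df.duplicated(subset=key)
        if dup.any():
            raise SchemaError(f"duplicate (id, visit, replicate) keys: "
                              f"{df.loc[dup, key].values[:5].tolist()}")
        spread = df.groupby(["id", "visit"])["ga_weeks"].nunique()
        if (spread > 1).any():
            offenders = spread[spread > 1].index[:5].tolist()
            raise SchemaError(f"GA varies within a visit for {offenders}")

    report.n_valid = len(df)
    report.log()
    return df.reset_index(drop=True), report


def write_records(df: pd.DataFrame, path) -> None:
    _atomic_write(path, df.to_csv(index=False))


# --- chart tables ------------------------------------------------------------

@dataclass
class ChartTable:
    """Centile values on a GA grid — the exportable chart product."""

    table: pd.DataFrame              # column 'ga_weeks' + one per centile
    metadata: dict

    def __post_init__(self) -> None:
        ga = self.table["ga_weeks"].to_numpy()
        if np.any(np.diff(ga) <= 0):
            raise ValueError("GA grid must be strictly increasing")
        self._check_no_crossing()

    def _check_no_crossing(self) -> None:
        cols = [c for c in self.table.columns if c != "ga_weeks"]
        cents = sorted(cols, key=float)
        vals = self.table[cents].to_numpy(dtype=float)
        bad = np.where(np.diff(vals, axis=1) <= 0)[0]
        if bad.size:
            rows = self.table["ga_weeks"].iloc[np.unique(bad)].tolist()
            raise ValueError(f"centile curves cross at GA rows {rows}")

    def write(self, path) -> None:
        lines = [f"# {k}: {v}" for k, v in sorted(self.metadata.items())]
        _atomic_write(path, "\n".join(lines) + "\n" + self.table.to_csv(index=False))

    @classmethod
    def read(cls, path) -> "ChartTable":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            table = pd.read_csv(fh)
        return cls(table=table, metadata=meta)


def write_chart(model, centiles, ga_grid, path=None, metadata=None) -> ChartTable:
    """Tabulate a fitted model's centiles on a GA grid.

    ``model`` is anything with a ``centile(ga, c)`` method (mean-SD,
    GAMLSS-style, multilevel, or a published chart).  The table refuses
    to materialize crossing centiles.
    """
    ga_grid = np.asarray(ga_grid, dtype=float)
    data = {"ga_weeks": ga_grid}
    for c in sorted(float(c) for c in centiles):
        data[f"{c:g}"] = np.asarray(model.centile(ga_grid, c), dtype=float)
    meta = {"units": "", "centiles": ",".join(f"{float(c):g}" for c in sorted(
        float(c) for c in centiles))}
    meta.update(metadata or {})
    chart = ChartTable(table=pd.DataFrame(data), metadata=meta)
    if path is not None:
        chart.write(path)
    return chart


# --- model files -------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a fitted model to a JSON model file (bit-exact reload)."""
    d = model.to_dict() if hasattr(model, "to_dict") else _meansd_dict(model)
    _atomic_write(path, json.dumps(d, indent=1))


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    kind = d.get("model")
    if kind == "centile":
        return CentileModel.from_dict(d)
    if kind == "multilevel":
        return _multilevel_from_dict(d)
    if kind == "meansd":
        return _meansd_from_dict(d)
    raise ValueError(f"unrecognized model file ({kind!r}) at {path}")


def _meansd_dict(model: MeanSDModel) -> dict:
    return {
        "model": "meansd",
        "mean_curve": model.mean_curve_.to_dict(),
        "sd_curve": model.sd_curve_.to_dict(),
        "transform": model.transform,
        "n_obs": model.n_obs_,
        "ga_range": list(model.ga_range_),
    }


def _meansd_from_dict(d: dict) -> MeanSDModel:
    model = MeanSDModel(transform=d.get("transform", "none"))
    model.mean_curve_ = FPSpec.from_dict(d["mean_curve"])
    model.sd_curve_ = FPSpec.from_dict(d["sd_curve"])
    model.sd_scale_ = float(np.sqrt(np.pi / 2.0))
    model.n_obs_ = int(d["n_obs"])
    model.ga_range_ = tuple(d["ga_range"])
    return model


def _multilevel_from_dict(d: dict):
    model = multilevel.MultilevelGrowthModel(kind=d["kind"])
    model.fixed_spec_ = FPSpec.from_dict(d["fixed"])
    model.sd_curve_ = FPSpec.from_dict(d["sd_curve"])
    for nm in ("var_intercept", "var_slope", "cov_int_slope", "var_visit",
               "var_resid", "deviance"):
        setattr(model, nm + "_", float(d[nm]))
    model.n_obs_ = int(d["n_obs"])
    model.ga_range_ = tuple(d["ga_range"])
    model.ga_offset_ = float(d.get("ga_offset", 0.0))
    model.boundary_ = []
    return model


def _atomic_write(path, text: str) -> None:
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
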