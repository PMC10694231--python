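"""Metrics, nitrogen nutrition index, organ reconstruction and reporting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import ORGAN_NAMES

__all__ = [
    "r2",
    "rmse",
    "CriticalNCurve",
    "nni",
    "reconstruct_organs",
    "MetricReport",
    "report",
    "stackplot_series",
]


def r2(y_true, y_pred) -> float:
    """Determination coefficient 1 - SS_res/SS_tot (unbounded below)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant y_true: R² undefined")
    return 1.0 - float(((y_true - y_pred) ** 2).sum()) / ss_tot


def rmse(y_true, y_pred) -> float:
    """Root mean square error, in trait units."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(((y_true - y_pred) ** 2).mean()))


@dataclass
class CriticalNCurve:
    """Critical %N dilution curve Nc = a * DM^-b, constant below dm_min.

    Defaults are the conventional winter-wheat coefficients; all three are
    configurable.
    """

    a: float = 5.35
    b: float = 0.442
    dm_min: float = 1.55

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")

    def critical_n(self, dm_total) -> np.ndarray:
        dm = np.maximum(np.asarray(dm_total, dtype=float), self.dm_min)
        return self.a * dm ** (-self.b)


def nni(dm_total, n_conc, curve: CriticalNCurve | None = None):
    """Nitrogen nutrition index: measured %N over the critical %N."""
    curve = curve or CriticalNCurve()
    dm = np.asarray(dm_total, dtype=float)
    if np.any(dm <= 0):
        raise ValueError("dm_total must be positive")
    out = np.asarray(n_conc, dtype=float) / curve.critical_n(dm)
    return float(out) if out.ndim == 0 else out


def reconstruct_organs(total: float, proportions) -> np.ndarray:
    """Absolute per-organ values = total x proportions (sum-conserving).

    Proportion vectors whose sum is off by more than 1e-3 are renormalized
    with a warning.
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (4,):
        raise ValueError("proportions must be a 4-vector")
    s = p.sum()
    if abs(s - 1.0) > 1e-3:
        warnings.warn(f"proportions sum to {s:.6f}; renormalizing", stacklevel=2)
    if s != 0:
        p = p / s
    return total * p


@dataclass
class MetricReport:
    """Tidy metric grid over (trait, model, label_source, split)."""

    table: pd.DataFrame  # columns: trait, model, label_source, split, rmse, r2, n

    def row(self, **query) -> pd.Series:
        df = self.table
        for k, v in query.items():
            df = df[df[k] == v]
        if len(df) != 1:
            raise KeyError(f"query {query} matched {len(df)} rows")
        return df.iloc[0]


def report(results: list[dict]) -> MetricReport:
    """Assemble a metric grid from evaluated (y_true, y_pred) result dicts.

    Each entry needs keys ``trait, model, label_source, split, y_true,
    y_pred``.  Splits with no samples are flagged and omitted.
    """
    rows = []
    for res in results:
        y_true = np.asarray(res["y_true"], dtype=float)
        y_pred = np.asarray(res["y_pred"], dtype=float)
        if y_true.size == 0:
            warnings.warn(
                f"no samples for {res['trait']}/{res['split']}; omitted", stacklevel=2
            )
            continue
        rows.append(
            {
                "trait": res["trait"],
                "model": res["model"],
                "label_source": res["label_source"],
                "split": res["split"],
                "rmse": rmse(y_true, y_pred),
                "r2": r2(y_true, y_pred) if y_true.size > 1 and y_true.std() > 0 else np.nan,
                "n": int(y_true.size),
            }
        )
    return MetricReport(table=pd.DataFrame(rows))


def stackplot_series(
    times, totals, proportions
) -> pd.DataFrame:
    """Per-organ absolute series for a partitioning-over-season stackplot.

    Rows sum to the total-trait curve by construction.
    """
    times = np.asarray(times, dtype=float)
    totals = np.asarray(totals, dtype=float)
    props = np.asarray(proportions, dtype=float)
    if props.shape != (len(times), 4):
        raise ValueError("proportions must be (n_times, 4)")
    data = {"thermal_time": times, "total": totals}
    organs = totals[:, None] * props / props.sum(axis=1, keepdims=True)
    for i, name in enumerate(ORGAN_NAMES):
        data[name] = organs[:, i]
    return pd.DataFrame(data)


def scatter_data(y_true, y_pred, thermal_time) -> pd.DataFrame:
    """1:1 scatter table with season-stage coloring value (thermal time)."""
    return pd.DataFrame(
        {
            "y_true": np.asarray(y_true, dtype=float),
            "y_pred": np.asarray(y_pred, dtype=float),
            "stage": np.asarray(thermal_time, dtype=float),
        }
    )
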