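"""Measured concentration time courses → per-day exchange-flux constraints.

Cultures are sampled daily; the net accumulation rate of a measured
component (a metabolite pool or a biomass constituent) at a given day is
the derivative of a curve fitted through the replicate means, in
mmol·gDW⁻¹·day⁻¹.  That rate, with sign convention *positive = net
accumulation in cells*, becomes the equality constraint on the
component's exchange/synthesis reaction for that day's snapshot solve.

Fresh-weight based measurements are converted to a dry-weight basis via
the measured water-content fraction: value_per_gDW =
value_per_gFW / (1 − water_content).

The default curve fit is a not-a-knot interpolating cubic spline through
the replicate means: it reproduces any polynomial of degree ≤ 3 (and in
particular linear accumulation, the generating model of the synthetic
time courses) exactly, so derivative estimates carry no fitting bias on
smooth data.  A generalized-cross-validated smoothing spline
(``method="smooth"``) and low-order polynomial fits are available for
noisier series.  No extrapolation: derivatives are only evaluated inside
the sampled day range, one-sided at the boundary days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline, make_smoothing_spline

from .flux import FluxConstraint

__all__ = [
    "ConcentrationSeries",
    "FittedCurve",
    "GrowthSummary",
    "load_concentration_series",
    "convert_fw_to_dw",
    "replicate_means",
    "fit_concentration_curve",
    "estimate_exchange_flux",
    "summarize_growth",
]

REQUIRED_COLUMNS = ("component", "condition", "replicate", "day", "value")


@dataclass
class ConcentrationSeries:
    """One replicate's time course for one component under one condition."""

    component_id: str
    condition: str
    replicate: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError(
                f"{self.component_id}/{self.condition}/{self.replicate}: "
                "days must be strictly increasing"
            )
        if np.any(self.values < 0):
            raise ValueError(
                f"{self.component_id}/{self.condition}/{self.replicate}: "
                "negative concentration value"
            )
        if len(self.days) < 2:
            raise ValueError(
                f"{self.component_id}/{self.condition}/{self.replicate}: "
                "need at least 2 distinct days"
            )


@dataclass
class FittedCurve:
    component_id: str
    condition: str
    method: str
    spline: object               # callable with .derivative()
    day_min: float
    day_max: float
    residual_rms: float
    n_replicates: int
    # mean-to-derivative weights at probe days are derived on demand
    _grid_days: np.ndarray = field(default=None, repr=False)
    _sem: np.ndarray = field(default=None, repr=False)

    def __call__(self, day: float) -> float:
        self._check_domain(day)
        return float(self.spline(day))

    def derivative(self, day: float) -> float:
        self._check_domain(day)
        return float(self.spline.derivative()(day))

    def derivative_se(self, day: float) -> float:
        """Standard error of the derivative, by propagating the replicate
        SEMs through the (linear) fit + differentiation operator."""
        self._check_domain(day)
        if self._sem is None or self._grid_days is None:
            return math.nan
        k = len(self._grid_days)
        w = np.zeros(k)
        for i in range(k):
            probe = np.zeros(k)
            probe[i] = 1.0
            s = _fit_spline(self._grid_days, probe, self.method)
            w[i] = s.derivative()(day)
        return float(np.sqrt(np.sum((w * self._sem) ** 2)))

    def average_derivative(self, days) -> tuple[float, float]:
        """Derivative averaged over several days, with its standard error.

        Useful when the underlying rate is believed constant: averaging
        suppresses the boundary-day noise amplification of the spline
        derivative.  The SE propagates the replicate SEMs through the
        (linear) fit → differentiate → average operator.
        """
        est = float(np.mean([self.derivative(float(d)) for d in days]))
        if self._sem is None or self._grid_days is None:
            return est, math.nan
        k = len(self._grid_days)
        w = np.zeros(k)
        for i in range(k):
            probe = np.zeros(k)
            probe[i] = 1.0
            s = _fit_spline(self._grid_days, probe, self.method)
            w[i] = np.mean([s.derivative()(float(d)) for d in days])
        return est, float(np.sqrt(np.sum((w * self._sem) ** 2)))

    def _check_domain(self, day: float) -> None:
        if day < self.day_min - 1e-12 or day > self.day_max + 1e-12:
            raise ValueError(
                f"day {day} outside fit domain [{self.day_min}, {self.day_max}]; "
                "no extrapolation"
            )


@dataclass(frozen=True)
class GrowthSummary:
    condition: str
    day_from: float
    day_to: float
    mean_from: float
    mean_to: float
    fold_change: float


def convert_fw_to_dw(value_per_gFW: float, water_content_fraction: float) -> float:
    """Fresh-weight → dry-weight basis: divide by the dry fraction."""
    if not 0 <= water_content_fraction < 1:
        raise ValueError(
            f"water content fraction must be in [0, 1), got {water_content_fraction}"
        )
    return value_per_gFW / (1.0 - water_content_fraction)


def load_concentration_series(source) -> list[ConcentrationSeries]:
    """Read a concentration CSV into validated per-replicate series.

    Required columns: component, condition, replicate, day, value; an
    optional water_content column triggers FW→DW conversion per row.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if not np.issubdtype(pd.to_numeric(df["value"], errors="coerce").dtype, np.number) or (
        pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    ).any():
        bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()].tolist()
        raise ValueError(f"non-numeric value in row(s) {bad}")
    df = df.copy()
    df["value"] = pd.to_numeric(df["value"])
    df["day"] = pd.to_numeric(df["day"])
    neg = df.index[df["value"] < 0].tolist()
    if neg:
        raise ValueError(f"negative value in row(s) {neg}")
    if "water_content" in df.columns:
        df["value"] = [
            convert_fw_to_dw(v, w) if pd.notna(w) else v
            for v, w in zip(df["value"], df["water_content"])
        ]
    dup = df.duplicated(subset=["component", "condition", "replicate", "day"])
    if dup.any():
        raise ValueError(
            f"duplicated (replicate, day) rows at index {df.index[dup].tolist()}"
        )
    out = []
    for (comp, cond, rep), grp in df.groupby(
        ["component", "condition", "replicate"], sort=True
    ):
        grp = grp.sort_values("day")
        out.append(
            ConcentrationSeries(comp, cond, str(rep), grp["day"].values, grp["value"].values)
        )
    return out


def replicate_means(
    series: list[ConcentrationSeries],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Pool replicate series (same component+condition) into per-day means.

    Returns (days, means, sems, n_replicates); days present in only some
    replicates are averaged over the replicates that have them.
    """
    if not series:
        raise ValueError("no series to pool")
    ids = {(s.component_id, s.condition) for s in series}
    if len(ids) > 1:
        raise ValueError(f"series mix components/conditions: {ids}")
    frames = [pd.Series(s.values, index=s.days) for s in series]
    df = pd.concat(frames, axis=1)
    means = df.mean(axis=1)
    counts = df.count(axis=1)
    sems = df.std(axis=1, ddof=1).fillna(0.0) / np.sqrt(counts.clip(lower=1))
    return means.index.values, means.values, sems.values, len(series)


def _fit_spline(days: np.ndarray, values: np.ndarray, method: str):
    if method == "cubic":
        k = min(3, len(days) - 1)
        return make_interp_spline(days, values, k=k)
    if method == "smooth":
        return make_smoothing_spline(days, values)  # λ by GCV
    if method == "poly2":
        coeffs = np.polynomial.Polynomial.fit(days, values, deg=min(2, len(days) - 1))
        return _PolyCurve(coeffs)
    raise ValueError(f"unknown fit method {method!r}")


class _PolyCurve:
    def __init__(self, poly):
        self.poly = poly

    def __call__(self, x):
        return self.poly(x)

    def derivative(self):
        return _PolyCurve(self.poly.deriv())


def fit_concentration_curve(
    series: list[ConcentrationSeries] | ConcentrationSeries,
    method: str = "auto",
) -> FittedCurve:
    """Fit a deterministic curve through the replicate means.

    ``method="auto"`` uses the not-a-knot cubic spline for ≥ 4 days and a
    local quadratic for shorter series.
    """
    if isinstance(series, ConcentrationSeries):
        series = [series]
    days, means, sems, n_rep = replicate_means(series)
    if method == "auto":
        method = "cubic" if len(days) >= 4 else "poly2"
    if method == "smooth" and len(days) < 4:
        raise ValueError("smoothing spline needs >= 4 distinct days")
    if len(days) < 2:
        raise ValueError("need >= 2 distinct days")
    spline = _fit_spline(days, means, method)
    fitted = np.array([float(spline(d)) for d in days])
    rms = float(np.sqrt(np.mean((fitted - means) ** 2)))
    return FittedCurve(
        component_id=series[0].component_id,
        condition=series[0].condition,
        method=method,
        spline=spline,
        day_min=float(days[0]),
        day_max=float(days[-1]),
        residual_rms=rms,
        n_replicates=n_rep,
        _grid_days=days,
        _sem=sems,
    )


def estimate_exchange_flux(
    curve: FittedCurve,
    day: float,
    reaction_id: str | None = None,
    tolerance: float = 0.0,
) -> FluxConstraint:
    """Snapshot constraint: d(content)/d(day) at ``day`` on the fitted curve.

    Positive values mean net accumulation in the cells, mapped onto the
    component's exchange/synthesis reaction (``reaction_id`` defaults to
    the component id).
    """
    rate = curve.derivative(day)
    return FluxConstraint(
        reaction_id=reaction_id or curve.component_id,
        value=rate,
        kind="band" if tolerance > 0 else "equality",
        tolerance=tolerance,
        day=int(day) if float(day).is_integer() else day,
        condition=curve.condition,
    )


def summarize_growth(
    series: list[ConcentrationSeries],
    condition: str,
    day_from: float,
    day_to: float,
) -> GrowthSummary:
    """Fold change of the replicate-mean value between two sampled days,
    rounded half-up to one decimal (the convention used when reporting
    culture fresh-weight gains)."""
    selected = [s for s in series if s.condition == condition]
    if not selected:
        raise ValueError(f"no series for condition {condition!r}")
    days, means, _, _ = replicate_means(selected)
    lookup = dict(zip(days, means))
    for d in (day_from, day_to):
        if d not in lookup:
            raise ValueError(f"day {d} not sampled for condition {condition!r}")
    mean_from, mean_to = lookup[day_from], lookup[day_to]
    if mean_from <= 0:
        raise ValueError("mean at day_from must be positive")
    ratio = mean_to / mean_from
    fold = math.floor(ratio * 10 + 0.5) / 10  # round half-up to 1 decimal
    return GrowthSummary(condition, day_from, day_to, mean_from, mean_to, fold)
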