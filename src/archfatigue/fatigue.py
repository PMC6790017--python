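"""Polynomial fatigue-trajectory fitting, AIC order selection and inflection.

The time-dependent decline of the weight-bearing BAI is approximated by a
polynomial in the cycle index.  The fitting order p is selected by Akaike's
information criterion in its Gaussian least-squares form,

    AIC = n { log(2 pi Se / n) + 1 } + 2 (p + 1),

with n the number of fitted points, Se the residual sum of squares and the
natural logarithm.  The creep stage II -> III transition (inflection point
chi0) is the root of the fitted polynomial's second derivative; for a cubic
this is chi0 = -b2 / (3 b3).

Fits are performed on a scaled abscissa internally (cycles span 1..10,000;
a raw Vandermonde design would be badly conditioned) and coefficients are
reported on the original cycle scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PolyFit",
    "FatigueFit",
    "aic",
    "fit_polynomial",
    "aic_select",
    "inflection_points",
    "primary_inflection",
    "fit_specimens",
    "DEFAULT_ORDERS",
]

DEFAULT_ORDERS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class PolyFit:
    """One least-squares polynomial fit of a (cycle, value) series."""

    order: int
    coef: np.ndarray  # ascending powers, original cycle scale
    se: float  # residual sum of squares
    r2: float
    aic: float
    n: int

    def __call__(self, cycles):
        return np.polynomial.polynomial.polyval(np.asarray(cycles, dtype=float), self.coef)


@dataclass
class FatigueFit:
    """All candidate fits for one series plus the AIC-selected model."""

    series_id: str
    fits: Mapping[int, PolyFit]
    selected_order: int
    cycle_range: tuple[float, float]
    inflection_cycles: np.ndarray = field(default_factory=lambda: np.array([]))
    inflection_cycle: float = float("nan")

    @property
    def selected(self) -> PolyFit:
        return self.fits[self.selected_order]

    def aic_table(self) -> pd.DataFrame:
        rows = [
            {
                "order": p,
                "Se": f.se,
                "AIC": f.aic,
                "R2": f.r2,
                "selected": p == self.selected_order,
            }
            for p, f in sorted(self.fits.items())
        ]
        return pd.DataFrame(rows)


def aic(n: int, se: float, p: int) -> float:
    """Gaussian least-squares AIC: n{log(2 pi Se / n) + 1} + 2(p + 1).

    A vanishing residual sum of squares makes the log undefined; it is
    floored at a tiny positive value with a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if se < 0:
        raise ValueError("residual sum of squares cannot be negative")
    floor = 1e-300
    if se < floor:
        warnings.warn(
            "residual sum of squares is (numerically) zero; AIC computed with an "
            "epsilon floor and is not meaningful for model comparison",
            stacklevel=2,
        )
        se = floor
    return n * (np.log(2.0 * np.pi * se / n) + 1.0) + 2.0 * (p + 1)


def fit_polynomial(cycles, values, order: int) -> PolyFit:
    """Least-squares polynomial fit of ``values`` against ``cycles``.

    Returns coefficients on the raw cycle scale (ascending powers), the
    residual sum of squares Se, R² = 1 - Se/SStot (defined as 1.0, with a
    warning, when the series is constant), and the fit's AIC.
    """
    x = np.asarray(cycles, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("cycles and values must be 1-D arrays of equal length")
    if len(np.unique(x)) != len(x):
        raise ValueError("cycle indices must be distinct")
    n = len(x)
    if n <= order + 1:
        raise ValueError(f"need more than order+1 = {order + 1} points, got {n}")
    # domain-scaled fit; convert back to raw-scale coefficients
    series = np.polynomial.Polynomial.fit(x, y, deg=order)
    coef = series.convert().coef
    if len(coef) < order + 1:  # trailing zero coefficients trimmed by convert()
        coef = np.pad(coef, (0, order + 1 - len(coef)))
    if not np.all(np.isfinite(coef)):
        raise np.linalg.LinAlgError("polynomial fit produced non-finite coefficients")
    resid = y - series(x)
    se = float(resid @ resid)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        warnings.warn(
            "series has zero total variance; R² reported as 1.0 by convention",
            stacklevel=2,
        )
        r2 = 1.0
    else:
        r2 = 1.0 - se / sstot
    return PolyFit(order=order, coef=coef, se=se, r2=r2, aic=aic(n, se, order), n=n)


def inflection_points(coef: Sequence[float], cycle_range: tuple[float, float]) -> np.ndarray:
    """Real roots of the fitted polynomial's second derivative within range.

    Returned in ascending order; repeated roots appear with their
    multiplicity.  Empty when the polynomial has order < 3 or no in-range
    root (e.g. a "cubic" whose leading coefficient vanished).
    """
    coef_arr = np.asarray(coef, dtype=float)
    poly = np.polynomial.Polynomial(coef_arr)
    d2 = poly.deriv(2)
    d2coef = np.trim_zeros(d2.coef, "b")
    if len(d2coef) <= 1:  # constant (or zero) second derivative: no root
        if len(coef_arr) >= 4 and len(np.trim_zeros(coef_arr, "b")) < len(coef_arr):
            warnings.warn(
                "leading coefficient of the selected fit is zero; no inflection point",
                stacklevel=2,
            )
        return np.array([])
    roots = np.polynomial.Polynomial(d2coef).roots()
    real = np.sort(roots[np.abs(roots.imag) < 1e-8 * max(1.0, np.abs(roots).max())].real)
    lo, hi = cycle_range
    return real[(real >= lo) & (real <= hi)]


def primary_inflection(coef: Sequence[float], cycle_range: tuple[float, float]) -> float:
    """The stage II -> III transition: first in-range downward zero of f''.

    The transition of creep-like fatigue is where the trajectory turns from
    convex (decelerating decline) to concave (re-accelerating decline), i.e.
    where f'' crosses zero from positive to negative.  Returns nan when the
    selected fit has no such crossing in range.
    """
    roots = inflection_points(coef, cycle_range)
    if len(roots) == 0:
        return float("nan")
    poly = np.polynomial.Polynomial(np.asarray(coef, dtype=float))
    d3 = poly.deriv(3)
    for r in roots:
        if d3(r) < 0:
            return float(r)
    return float("nan")


def aic_select(
    cycles,
    values,
    orders: Sequence[int] = DEFAULT_ORDERS,
    series_id: str = "",
) -> FatigueFit:
    """Fit all candidate orders and select the AIC-minimizing one.

    Ties are broken toward the smaller order.  The returned
    :class:`FatigueFit` carries the in-range inflection roots of the selected
    fit and the primary (convex-to-concave) inflection cycle.
    """
    orders = sorted(set(int(p) for p in orders))
    if not orders:
        raise ValueError("need at least one candidate order")
    fits = {p: fit_polynomial(cycles, values, p) for p in orders}
    selected = min(orders, key=lambda p: (fits[p].aic, p))
    x = np.asarray(cycles, dtype=float)
    rng = (float(x.min()), float(x.max()))
    coef = fits[selected].coef
    return FatigueFit(
        series_id=series_id,
        fits=fits,
        selected_order=selected,
        cycle_range=rng,
        inflection_cycles=inflection_points(coef, rng),
        inflection_cycle=primary_inflection(coef, rng),
    )


def fit_specimens(
    metrics_by_specimen: Mapping[str, pd.DataFrame],
    checkpoints: Sequence[int],
    orders: Sequence[int] = DEFAULT_ORDERS,
    value_column: str = "bai_wb",
    fit_grid: str = "cycles",
) -> tuple[dict[str, FatigueFit], pd.DataFrame]:
    """Per-specimen AIC-selected fits of a metric's cycle trajectory.

    ``fit_grid="cycles"`` (default) fits every recorded cycle; the inflection
    statistics then carry only the specimen-to-specimen spread, not the large
    coefficient uncertainty a sparse fit would add.  ``fit_grid="checkpoints"``
    fits the checkpoint grid only.

    Returns the fits and a long-format report table (one row per specimen and
    candidate order, with coefficients, Se, AIC, R², the selected flag and the
    selected fit's inflection cycle).
    """
    if fit_grid not in ("cycles", "checkpoints"):
        raise ValueError(f"fit_grid must be 'cycles' or 'checkpoints', got {fit_grid!r}")
    max_order = max(orders)
    fits: dict[str, FatigueFit] = {}
    rows = []
    for sid, metrics in metrics_by_specimen.items():
        if fit_grid == "cycles":
            grid = metrics["cycle"].to_numpy()
            values = metrics[value_column].to_numpy()
        else:
            grid = np.asarray(list(checkpoints))
            values = metrics.set_index("cycle").loc[list(checkpoints), value_column].to_numpy()
        fit = aic_select(grid, values, orders, series_id=sid)
        fits[sid] = fit
        for p, f in sorted(fit.fits.items()):
            row = {"specimen_id": sid, "order": p}
            for k in range(max_order + 1):
                row[f"b{k}"] = f.coef[k] if k < len(f.coef) else 0.0
            row.update(
                {
                    "Se": f.se,
                    "AIC": f.aic,
                    "R2": f.r2,
                    "selected": p == fit.selected_order,
                    "inflection_cycle": fit.inflection_cycle if p == fit.selected_order else np.nan,
                }
            )
            rows.append(row)
    return fits, pd.DataFrame(rows)
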