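"""Dose-response viability modeling and AC90 estimation.

Raw plate-reader signals (e.g. resazurin fluorescence) are normalized to
percent viability against vehicle controls, fitted with a decreasing
four-parameter logistic (4PL)

    v(d) = bottom + (top - bottom) / (1 + (d / midpoint)^hill),  hill > 0,

on log10 dose, and the fitted curve is inverted analytically for the
AC90: the concentration at which 90% viability is retained.  When the
curve never crosses 90% inside the tested range, a configured fallback
concentration is carried forward instead and the status records that.

The top is left free rather than pinned to 100% because low doses often
show mildly elevated viability; a free top absorbs that while the
decreasing limb keeps a unique 90% crossing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .mixture import STATUS_ESTIMATED, STATUS_FALLBACK, Ac90Entry, Ac90Table

logger = logging.getLogger(__name__)

__all__ = [
    "FourPLFit",
    "Ac90Estimate",
    "four_pl",
    "normalize_viability",
    "fit_4pl",
    "estimate_ac90",
    "ac90_table_from_viability",
]


def four_pl(dose: np.ndarray | float, top: float, bottom: float, midpoint: float,
            hill: float) -> np.ndarray | float:
    """Decreasing 4PL response at ``dose`` (µM); ``hill > 0``."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        v = bottom + (top - bottom) / (1.0 + (d / midpoint) ** hill)
    return v if v.ndim else float(v)


def normalize_viability(
    df: pd.DataFrame,
    *,
    dose_col: str = "dose_um",
    signal_col: str = "signal",
    signal_is_percent: bool = False,
) -> pd.DataFrame:
    """Convert raw signals to percent viability against vehicle controls.

    ``% viability = 100 * signal / mean(signal at dose 0)``, computed per
    chemical when a ``chemical_id`` column is present.  Inputs already on
    the percent scale pass through (``signal_is_percent=True``).  Vehicle
    observations therefore normalize to mean 100% exactly.
    """
    out = df.copy()
    if signal_is_percent:
        out["pct_viability"] = out[signal_col].astype(float)
        return out

    def _norm(group: pd.DataFrame) -> pd.DataFrame:
        vehicle = group.loc[group[dose_col] == 0, signal_col].astype(float)
        if vehicle.empty:
            raise ValueError("no vehicle (dose 0) observations to normalize against")
        vmean = float(vehicle.mean())
        if vmean <= 0:
            raise ValueError(f"vehicle mean signal must be positive, got {vmean}")
        group = group.copy()
        group["pct_viability"] = 100.0 * group[signal_col].astype(float) / vmean
        return group

    if "chemical_id" in out.columns:
        parts = [_norm(g) for _, g in out.groupby("chemical_id", sort=False)]
        return pd.concat(parts, ignore_index=True)
    return _norm(out)


@dataclass
class FourPLFit:
    """Fitted decreasing 4PL with convergence diagnostics."""

    top: float
    bottom: float
    midpoint_um: float
    hill: float
    converged: bool
    rss: float
    n_obs: int
    n_starts: int

    def __post_init__(self) -> None:
        if self.converged:
            if self.midpoint_um <= 0:
                raise ValueError("midpoint must be positive")
            if self.bottom > self.top + 1e-9:
                raise ValueError("bottom must not exceed top")

    def predict(self, dose):
        return four_pl(dose, self.top, self.bottom, self.midpoint_um, self.hill)


def fit_4pl(
    df: pd.DataFrame,
    *,
    dose_col: str = "dose_um",
    response_col: str = "pct_viability",
    pin_top: float | None = None,
) -> FourPLFit:
    """Least-squares fit of the decreasing 4PL on log10 dose.

    Dose-0 observations are excluded (log10(0) is undefined; they serve
    normalization only).  Requires >= 4 distinct positive doses.  The fit
    is multi-start for determinism: the midpoint starts at the geometric
    mean of the doses and at each tested dose, the hill slope at
    {0.5, 1, 2}; the lowest-SSE converged start wins.  ``pin_top``
    constrains the top plateau (e.g. to 100%) instead of leaving it free.
    """
    sub = df[df[dose_col] > 0]
    doses = sub[dose_col].astype(float).to_numpy()
    y = sub[response_col].astype(float).to_numpy()
    if np.unique(doses).size < 4:
        raise ValueError("need >= 4 distinct positive doses to fit a 4PL")
    if np.ptp(y) < 1e-9:
        raise ValueError(
            "constant response across doses; no curve to fit - handle as not-reached"
        )
    x = np.log10(doses)

    def residuals(theta: np.ndarray) -> np.ndarray:
        top, span, lmid, hill = theta
        if pin_top is not None:
            top = pin_top
        pred = (top - span) + span / (1.0 + 10.0 ** (hill * (x - lmid)))
        return pred - y

    lmid_lo, lmid_hi = x.min() - 2.0, x.max() + 2.0
    span0 = max(float(y.max() - y.min()), 1.0)
    top0 = float(y.max()) if pin_top is None else pin_top
    starts = []
    mid_starts = [float(np.mean(x))] + sorted(set(np.round(x, 12)))
    for lmid in mid_starts:
        for hill in (0.5, 1.0, 2.0):
            starts.append(np.array([top0, span0, lmid, hill]))

    lower = np.array([0.0, 0.0, lmid_lo, 0.01])
    upper = np.array([1e3, 1e3, lmid_hi, 10.0])
    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lower, upper)
        sol = least_squares(residuals, theta0, bounds=(lower, upper), method="trf")
        if not sol.success:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError(
            f"4PL fit failed to converge from any of {len(starts)} starts"
        )
    rss, (top, span, lmid, hill) = best
    if pin_top is not None:
        top = pin_top
    return FourPLFit(
        top=float(top),
        bottom=float(top - span),
        midpoint_um=float(10.0**lmid),
        hill=float(hill),
        converged=True,
        rss=rss,
        n_obs=int(len(y)),
        n_starts=len(starts),
    )


@dataclass
class Ac90Estimate:
    """AC90 (µM) with status and the dose range it was estimated over."""

    value_um: float
    status: str  # STATUS_ESTIMATED or STATUS_FALLBACK
    tested_range_um: tuple[float, float]
    fallback_um: float | None = None

    def as_entry(self, chemical: str, casrn: str = "") -> Ac90Entry:
        return Ac90Entry(chemical, self.value_um, self.status, casrn)


def estimate_ac90(
    fit: FourPLFit,
    tested_range: tuple[float, float],
    fallback_um: float | None = None,
    target_pct: float = 90.0,
) -> Ac90Estimate:
    """Invert the fitted curve for the dose retaining ``target_pct`` viability.

    The decreasing 4PL has the unique closed-form inverse

        d = midpoint * ((top - t) / (t - bottom))^(1 / hill)

    valid when ``bottom < t < top``.  If the curve never crosses the
    target inside ``tested_range`` (flat fits, bottom >= target, or a
    crossing extrapolated beyond the tested doses), the configured
    ``fallback_um`` is carried forward with status
    ``not_reached_fallback``.
    """
    lo, hi = tested_range
    if hi <= lo:
        raise ValueError("tested_range must be (low, high) with high > low")

    def _fallback() -> Ac90Estimate:
        if fallback_um is None:
            raise ValueError(
                f"viability never reaches {target_pct}% within ({lo}, {hi}] µM "
                "and no fallback concentration was configured"
            )
        return Ac90Estimate(float(fallback_um), STATUS_FALLBACK, (lo, hi), float(fallback_um))

    if not fit.converged:
        return _fallback()
    top, bottom, hill = fit.top, fit.bottom, fit.hill
    if not (bottom < target_pct < top) or math.isclose(top, bottom):
        return _fallback()
    d = fit.midpoint_um * ((top - target_pct) / (target_pct - bottom)) ** (1.0 / hill)
    if not (lo < d <= hi) or not math.isfinite(d):
        return _fallback()
    return Ac90Estimate(float(d), STATUS_ESTIMATED, (lo, hi))


def ac90_table_from_viability(
    df: pd.DataFrame,
    tested_range: tuple[float, float],
    fallback_um: float | None = None,
    *,
    signal_is_percent: bool = False,
    casrns: dict[str, str] | None = None,
) -> tuple[Ac90Table, dict[str, FourPLFit]]:
    """Per-chemical normalize -> fit -> invert over a long-format dataset.

    ``df`` holds columns ``chemical_id, dose_um, signal, replicate``.
    Chemicals whose fit cannot be produced (constant response) fall back
    when ``fallback_um`` is given.  Returns the AC90 table plus the fits
    for reporting.
    """
    casrns = casrns or {}
    norm = normalize_viability(df, signal_is_percent=signal_is_percent)
    table = Ac90Table()
    fits: dict[str, FourPLFit] = {}
    for chem, group in norm.groupby("chemical_id", sort=True):
        try:
            fit = fit_4pl(group)
            fits[str(chem)] = fit
            est = estimate_ac90(fit, tested_range, fallback_um)
        except ValueError as exc:
            if fallback_um is None:
                raise
            logger.warning("chemical %s: %s; using fallback %.3g µM", chem, exc, fallback_um)
            est = Ac90Estimate(float(fallback_um), STATUS_FALLBACK, tested_range,
                               float(fallback_um))
        table[str(chem)] = est.as_entry(str(chem), casrns.get(str(chem), ""))
    return table, fits
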