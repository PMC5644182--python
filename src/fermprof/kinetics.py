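"""Growth kinetics: specific growth rate, CO2 production rate, yield.

The maximum specific growth rate mu_max (1/h) is the slope of an ordinary
least-squares fit of ln(dry weight) against time on samples inside the
exponential window, accepted only with at least three points and R^2 at or
above a quality threshold (default 0.96).  When too few dry-weight samples
fall inside the window — common for short exponential phases — mu_max is
reported absent with an explicit flag, and the slope of ln(accumulated
CO2), available on every run with a working off-gas line, serves as the
alternative growth-rate measure: CO2 evolution is proportional to the
amount of metabolically active biomass, so both logarithms share the same
slope during balanced exponential growth.

The biomass yield on substrate Y_sx (g dry weight per g glucose) is the
ratio of biomass gained to glucose consumed over the growth phase,
evaluated between the samples nearest the window endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .segmentation import ExponentialFit


@dataclass(frozen=True)
class MuFit:
    """Accepted log-linear dry-weight fit."""

    mu_per_h: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class KineticsResult:
    """Per-run kinetic parameters; absent values carry a reason flag."""

    mu_max_per_h: Optional[float]
    mu_r2: Optional[float]
    mu_n: int
    co2_rate_per_h: float
    y_sx: Optional[float]
    flags: tuple = ()


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean / sample SD / CV over replicate values of one parameter.

    ``n`` counts the values actually used; ``n_excluded`` the absent ones.
    With a single value the SD is reported as 0 by convention and flagged.
    """

    mean: float
    sd: float
    n: int
    n_excluded: int = 0
    flags: tuple = ()

    @property
    def cv(self) -> Optional[float]:
        return self.sd / self.mean if self.mean != 0 else None


def mu_from_dryweight(
    dw_time_h: Sequence[float],
    dw_g_l: Sequence[float],
    window: tuple[float, float],
    r2_min: float = 0.96,
) -> Optional[MuFit]:
    """OLS of ln(dry weight) vs time inside ``window`` (inclusive).

    Returns ``None`` when fewer than three samples fall inside the window
    or the fit quality is below ``r2_min`` — never a number from an
    unacceptable fit.  Non-positive dry weight inside the window is a data
    error (the logarithm is undefined) and is rejected.
    """
    t = np.asarray(dw_time_h, dtype=float)
    w = np.asarray(dw_g_l, dtype=float)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if int(mask.sum()) < 3:
        return None
    t, w = t[mask], w[mask]
    if np.any(w <= 0):
        raise ValueError("non-positive dry weight inside the fit window")
    y = np.log(w)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    if r2 < r2_min:
        return None
    return MuFit(mu_per_h=float(slope), r2=r2, n_points=int(len(t)))


def _nearest(t: np.ndarray, v: np.ndarray, at: float, tol_h: float) -> float:
    i = int(np.argmin(np.abs(t - at)))
    if abs(t[i] - at) > tol_h:
        raise ValueError(
            f"no sample within {tol_h} h of window endpoint at {at:.2f} h"
        )
    return float(v[i])


def yield_sx(
    dw_time_h: Sequence[float],
    dw_g_l: Sequence[float],
    glucose_time_h: Sequence[float],
    glucose_g_l: Sequence[float],
    growth_window: tuple[float, float],
    match_tol_h: float = 2.0,
) -> float:
    """Biomass yield on substrate over the growth phase.

    Y_sx = (DW_end - DW_start) / (S_start - S_end), with each endpoint
    taken from the sample nearest the window bound (within ``match_tol_h``).
    Requires measurable consumption (S_start > S_end).
    """
    td = np.asarray(dw_time_h, float)
    wd = np.asarray(dw_g_l, float)
    tg = np.asarray(glucose_time_h, float)
    sg = np.asarray(glucose_g_l, float)
    if td.size == 0 or tg.size == 0:
        raise ValueError("dry-weight and glucose series must be non-empty")
    lo, hi = growth_window
    dw0 = _nearest(td, wd, lo, match_tol_h)
    dw1 = _nearest(td, wd, hi, match_tol_h)
    s0 = _nearest(tg, sg, lo, match_tol_h)
    s1 = _nearest(tg, sg, hi, match_tol_h)
    if not s0 > s1:
        raise ValueError("no measurable consumption over the growth window")
    return (dw1 - dw0) / (s0 - s1)


def co2_rate(fit: ExponentialFit) -> float:
    """Maximum CO2 production rate (1/h): the slope of the accepted
    log-linear fit of accumulated CO2.  Pass-through with unit annotation.
    """
    return fit.slope_per_h


def summarize_replicates(values: Sequence[Optional[float]]) -> Optional[ReplicateSummary]:
    """Mean, sample SD (n-1 denominator) and CV over replicates.

    Absent values (``None``/NaN) are excluded but counted in
    ``n_excluded``; with nothing left the summary itself is absent.
    """
    kept = [v for v in values if v is not None and not math.isnan(v)]
    n_excl = len(values) - len(kept)
    if not kept:
        return None
    arr = np.asarray(kept, dtype=float)
    flags = ("n_excluded",) if n_excl else ()
    if arr.size == 1:
        return ReplicateSummary(
            mean=float(arr[0]), sd=0.0, n=1, n_excluded=n_excl, flags=flags + ("n=1",)
        )
    return ReplicateSummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=int(arr.size),
        n_excluded=n_excl,
        flags=flags,
    )
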