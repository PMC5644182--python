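"""Growth-phase segmentation from the CO2 off-gas signal.

A batch fermentation of a filamentous fungus passes through a lag phase
(spore germination, negligible gas evolution), an exponential phase in
which accumulated CO2 grows as e^(mu*t), and — for pellet- or clump-forming
morphologies — a non-exponential phase in which CO2 output keeps rising but
the log-linear fit no longer holds, ending at the CO2 off-gas maximum when
the carbon source is exhausted.

The segmentation rules are operational, i.e. each phase boundary is defined
by the detection procedure itself:

* lag end — first sample of the earliest run of >= k consecutive samples
  with exhaust CO2 strictly above a threshold;
* exponential window — the longest contiguous sample window, starting at or
  after the lag end, whose ordinary-least-squares fit of ln(accumulated
  CO2) against time reaches R^2 >= r2_min with at least ``min_points``
  samples (earliest start wins among equal lengths).  The fitted slope is
  the maximum CO2 production rate in 1/h;
* CO2 maximum — argmax of the moving-average-smoothed exhaust CO2 trace,
  earliest sample on ties;
* non-exponential duration — time from the end of the exponential fit to
  the CO2 maximum, floored at zero.

Because the exponential window is defined through a fit-quality threshold,
its end is a property of the procedure, not an unbiased estimate of a
latent regime-switch time; see docs/methods.md for the quantitative
read-through analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .gas import INLET_CO2_PCT, compute_cer, smooth_offgas
from .series import CerSeries, FermentationRun, OffGasSeries


class SegmentationError(RuntimeError):
    """A segmentation stage failed; ``stage`` labels which one."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class LagNotDetectedError(SegmentationError):
    """The exhaust CO2 never stayed above the threshold long enough."""

    def __init__(self, threshold_pct: float, k_consecutive: int):
        super().__init__(
            "lag",
            f"no run of >= {k_consecutive} consecutive samples above "
            f"{threshold_pct}% CO2; lag end not detected",
        )


class ExponentialWindowError(SegmentationError):
    """No sample window met the fit-acceptance criteria."""

    def __init__(self, best_n: int, best_r2: float):
        super().__init__(
            "exponential-fit",
            f"no window met the R^2/min-points criteria; best achieved "
            f"n={best_n}, R^2={best_r2:.4f}",
        )
        self.best_n = best_n
        self.best_r2 = best_r2


@dataclass(frozen=True)
class ExponentialFit:
    """Accepted OLS fit of ln(accumulated CO2) vs time."""

    slope_per_h: float
    intercept: float
    r2: float
    n_points: int
    start_h: float
    end_h: float
    start_idx: int
    end_idx: int  # inclusive


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable rules; defaults follow the reference workflow."""

    lag_threshold_pct: float = 6.0
    k_consecutive: int = 3
    r2_min: float = 0.99
    min_points: int = 3
    smooth_window_h: float = 1.0
    inlet_co2_pct: float = INLET_CO2_PCT

    def __post_init__(self):
        if self.lag_threshold_pct <= 0:
            raise ValueError("lag_threshold_pct must be > 0")
        if self.k_consecutive < 1:
            raise ValueError("k_consecutive must be >= 1")
        if not 0 < self.r2_min < 1:
            raise ValueError("r2_min must be in (0, 1)")
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")
        if self.smooth_window_h < 0:
            raise ValueError("smooth_window_h must be >= 0")


@dataclass(frozen=True)
class PhaseSegmentation:
    """Phase boundaries of one run, all at sample timestamps.

    ``exp_end_h`` is clamped to ``t_co2max_h`` so that
    ``nonexp_duration_h = t_co2max_h - exp_end_h`` is never negative; the
    raw end of the accepted fit window is available as ``fit.end_h``.
    """

    lag_end_h: float
    exp_start_h: float
    exp_end_h: float
    t_co2max_h: float
    nonexp_duration_h: float
    fit: ExponentialFit

    def __post_init__(self):
        if not (
            self.lag_end_h <= self.exp_start_h <= self.exp_end_h <= self.t_co2max_h
        ):
            raise ValueError("phase boundaries out of order")


def detect_lag_end(
    gas: OffGasSeries, threshold_pct: float = 6.0, k_consecutive: int = 3
) -> float:
    """Time of the first sample of the earliest run of >= k consecutive
    samples with CO2 strictly above ``threshold_pct``.

    Raises :class:`LagNotDetectedError` when no such run exists — the
    caller must handle the failure explicitly; a silent 0 h would fake a
    missing lag phase.
    """
    if k_consecutive < 1:
        raise ValueError("k_consecutive must be >= 1")
    if threshold_pct <= 0:
        raise ValueError("threshold_pct must be > 0")
    above = gas.co2_pct > threshold_pct
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run == k_consecutive:
            return float(gas.time_h[i - k_consecutive + 1])
    raise LagNotDetectedError(threshold_pct, k_consecutive)


def _window_stats(t: np.ndarray, y: np.ndarray):
    """Prefix sums enabling O(1) OLS statistics for any index window."""
    z = lambda a: np.concatenate(([0.0], np.cumsum(a)))
    return z(t), z(t * t), z(y), z(y * y), z(t * y)


def _ols_window(sums, s: int, e: int):
    """Slope, intercept and R^2 of the OLS line over indices [s, e]."""
    S1, S2, Sy, Syy, Sty = sums
    n = e - s + 1
    st = S1[e + 1] - S1[s]
    stt = S2[e + 1] - S2[s]
    sy = Sy[e + 1] - Sy[s]
    syy = Syy[e + 1] - Syy[s]
    sty = Sty[e + 1] - Sty[s]
    sxx = stt - st * st / n
    sxy = sty - st * sy / n
    syy_c = syy - sy * sy / n
    slope = sxy / sxx
    intercept = (sy - slope * st) / n
    if syy_c <= 0:
        return slope, intercept, 1.0
    return slope, intercept, 1.0 - (syy_c - sxy * sxy / sxx) / syy_c


def fit_exponential_window(
    cer: CerSeries,
    after_h: float,
    r2_min: float = 0.99,
    min_points: int = 3,
    fixed_start: bool = False,
) -> ExponentialFit:
    """Longest R^2-qualifying log-linear window of accumulated CO2.

    Scans every contiguous index window starting at or after ``after_h``
    (restricted to samples with positive accumulated CO2, since the fit is
    on its logarithm) and returns the longest one whose OLS fit of
    ln(acc_co2) vs time reaches ``r2_min`` with at least ``min_points``
    samples; among equal lengths the earliest start wins.  Equivalent to
    exhaustive enumeration of all O(n^2) windows, implemented with prefix
    sums and a length-bound prune.

    With ``fixed_start=True`` only windows beginning at the first usable
    sample at or after ``after_h`` compete (the farthest qualifying end
    wins).  This is the variant :func:`segment_run` uses: when starts may
    float, a slow maintenance-driven post-transition segment — nearly
    log-linear and much longer than the exponential phase — can win on
    length and select the wrong phase entirely.

    Raises :class:`ExponentialWindowError` (reporting the best achieved
    window length and R^2) when no window qualifies.
    """
    if not 0 < r2_min < 1:
        raise ValueError("r2_min must be in (0, 1)")
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    if cer.acc_co2 is None:
        raise ValueError("CerSeries must carry acc_co2 (see accumulate_co2)")
    t_all = cer.time_h
    anchor = int(np.searchsorted(t_all, after_h, side="left"))
    if anchor >= len(t_all):
        raise ValueError("after_h beyond the end of the series")

    valid = (cer.acc_co2 > 0) & (np.arange(len(t_all)) >= anchor)
    best = None  # (length, start, end, slope, intercept, r2)
    best_n, best_r2 = 0, -np.inf

    # contiguous runs of usable samples
    idx = np.flatnonzero(valid)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        if fixed_start:
            # only the validity run containing the first usable sample
            first = idx[0]
            keep = [(rs, re) for rs, re in zip(idx[starts], idx[ends]) if rs == first]
            run_bounds = keep
        else:
            run_bounds = list(zip(idx[starts], idx[ends]))
        for rs, re in run_bounds:
            if re - rs + 1 < min_points:
                continue
            t = t_all[rs : re + 1]
            y = np.log(cer.acc_co2[rs : re + 1])
            sums = _window_stats(t, y)
            m = len(t)
            s_range = range(0, 1) if fixed_start else range(0, m - min_points + 1)
            for s in s_range:
                if best is not None and m - s <= best[0]:
                    break  # no strictly longer window can start here
                e_lo = s + min_points - 1
                n = np.arange(e_lo + 1, m + 1) - s  # lengths
                st = sums[0][e_lo + 1 : m + 1] - sums[0][s]
                stt = sums[1][e_lo + 1 : m + 1] - sums[1][s]
                sy = sums[2][e_lo + 1 : m + 1] - sums[2][s]
                syy = sums[3][e_lo + 1 : m + 1] - sums[3][s]
                sty = sums[4][e_lo + 1 : m + 1] - sums[4][s]
                sxx = stt - st * st / n
                sxy = sty - st * sy / n
                syy_c = syy - sy * sy / n
                with np.errstate(divide="ignore", invalid="ignore"):
                    r2 = np.where(
                        syy_c <= 0, 1.0, 1.0 - (syy_c - sxy * sxy / sxx) / syy_c
                    )
                qual = np.flatnonzero(r2 >= r2_min)
                if r2.size:
                    j = int(np.argmax(r2))
                    if r2[j] > best_r2:
                        best_r2, best_n = float(r2[j]), int(n[j])
                if qual.size == 0:
                    continue
                e = int(qual[-1]) + e_lo  # farthest qualifying end
                length = e - s + 1
                if best is None or length > best[0]:
                    slope, intercept, r2v = _ols_window(sums, s, e)
                    best = (length, s, e, slope, intercept, r2v, rs)

    if best is None:
        raise ExponentialWindowError(best_n, best_r2 if np.isfinite(best_r2) else 0.0)
    length, s, e, slope, intercept, r2v, rs = best
    return ExponentialFit(
        slope_per_h=float(slope),
        intercept=float(intercept),
        r2=float(min(r2v, 1.0)),
        n_points=length,
        start_h=float(t_all[rs + s]),
        end_h=float(t_all[rs + e]),
        start_idx=rs + s,
        end_idx=rs + e,
    )


def find_co2_max(gas: OffGasSeries, smooth_window_h: float = 1.0) -> float:
    """Time of the maximum of the smoothed CO2 trace (earliest on ties)."""
    smoothed = smooth_offgas(gas, smooth_window_h)
    return float(gas.time_h[int(np.argmax(smoothed.co2_pct))])


def segment_run(
    run: FermentationRun,
    params: Optional[SegmentationParams] = None,
    cer: Optional[CerSeries] = None,
) -> PhaseSegmentation:
    """Full segmentation of one run: lag end, exponential window, CO2
    maximum, non-exponential duration.

    A precomputed :class:`CerSeries` may be passed to avoid recomputing the
    gas balance.  Stage failures propagate as :class:`SegmentationError`
    with the failing stage in the message.
    """
    params = params or SegmentationParams()
    gas = run.offgas
    lag_end = detect_lag_end(gas, params.lag_threshold_pct, params.k_consecutive)
    if cer is None:
        cer = compute_cer(gas, inlet_co2_pct=params.inlet_co2_pct)
    try:
        fit = fit_exponential_window(
            cer,
            after_h=lag_end,
            r2_min=params.r2_min,
            min_points=params.min_points,
            fixed_start=True,
        )
    except ValueError as err:
        raise SegmentationError("exponential-fit", str(err)) from err
    t_max = find_co2_max(gas, params.smooth_window_h)
    exp_end = min(fit.end_h, t_max)
    return PhaseSegmentation(
        lag_end_h=lag_end,
        exp_start_h=fit.start_h,
        exp_end_h=exp_end,
        t_co2max_h=t_max,
        nonexp_duration_h=max(0.0, t_max - exp_end),
        fit=fit,
    )
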