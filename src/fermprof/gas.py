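"""Gas balance: from exhaust composition to CO2 evolution rate.

The carbon dioxide evolution rate (CER) follows from a steady-state molar
balance over the head space: the molar flow of CO2 leaving with the exhaust,
minus what entered with the sparging air, normalised per litre of broth.
Under the ideal-gas law at the cultivation temperature (25 degC, 1 atm) one
mole of gas occupies 24.465 L, so

    CER [mmol/L/h] = airflow_vvm * 60 [L air / L broth / h]
                     * (co2_pct - inlet_co2_pct) / 100  -> L CO2 / L broth / h
                     / 24.465 [L/mol] * 1000            -> mmol

The working volume cancels; rates are volume-independent.  Accumulated CO2
is the trapezoidal time-integral of CER and is the signal on which the
exponential-phase regression operates.
"""

from __future__ import annotations

import numpy as np

from .series import CerSeries, OffGasSeries

#: molar volume of an ideal gas at 25 degC and 1 atm, L/mol
MOLAR_VOLUME_25C = 24.465

#: atmospheric CO2 fraction of the sparging air, % v/v
INLET_CO2_PCT = 0.04


def compute_cer(
    gas: OffGasSeries,
    inlet_co2_pct: float = INLET_CO2_PCT,
    molar_volume_l: float = MOLAR_VOLUME_25C,
) -> CerSeries:
    """CO2 evolution rate from off-gas composition and airflow.

    Negative rates (exhaust below inlet, e.g. from sensor noise before
    growth starts) are floored at zero.  Pass ``inlet_co2_pct=0`` to skip
    inlet correction.

    Returns a :class:`CerSeries` with the accumulated integral filled in.
    """
    if inlet_co2_pct < 0:
        raise ValueError("inlet_co2_pct must be >= 0")
    air_l_per_l_h = gas.airflow_vvm * 60.0
    cer = air_l_per_l_h * (gas.co2_pct - inlet_co2_pct) / 100.0 / molar_volume_l * 1e3
    cer = np.maximum(cer, 0.0)
    return accumulate_co2(CerSeries(time_h=gas.time_h, cer=cer))


def accumulate_co2(cer: CerSeries) -> CerSeries:
    """Fill ``acc_co2`` with the running trapezoidal integral of ``cer``.

    The trapezoid rule is exact for piecewise-linear rates and starts at 0
    at the first time point.
    """
    t, c = cer.time_h, cer.cer
    acc = np.concatenate(([0.0], np.cumsum(np.diff(t) * (c[1:] + c[:-1]) / 2.0)))
    return CerSeries(time_h=t, cer=c, acc_co2=acc)


def smooth_offgas(gas: OffGasSeries, window_h: float) -> OffGasSeries:
    """Centred moving average of the CO2 trace over a time window.

    Each point is replaced by the mean of all samples within
    ``window_h / 2`` of it, so windows truncate naturally at the ends of
    the series and the grid need not be uniform.  ``window_h = 0`` returns
    the input unchanged.
    """
    if window_h < 0:
        raise ValueError("window_h must be >= 0")
    if window_h == 0:
        return gas
    t, c = gas.time_h, gas.co2_pct
    half = window_h / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate(([0.0], np.cumsum(c)))
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return gas.with_co2(smoothed)
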