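"""Core data containers for batch-fermentation runs.

A run is described by three mutually registered time series: the off-gas
composition (the dense signal, measured every few minutes by a process gas
analyser), and the sparse dry-weight and substrate sample tables drawn from
the broth.  All times are hours since inoculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class OffGasSeries:
    """Exhaust-gas composition of one reactor over time.

    Parameters
    ----------
    time_h : array-like
        Hours since inoculation, strictly increasing, at least two points.
    co2_pct : array-like
        CO2 in the exhaust, % v/v, in [0, 100].
    airflow_vvm : array-like
        Sparging rate in volumes of air per volume of liquid per minute.
    volume_l : float
        Working volume in litres, constant over the run.
    o2_pct : array-like, optional
        O2 in the exhaust, % v/v.
    """

    time_h: np.ndarray
    co2_pct: np.ndarray
    airflow_vvm: np.ndarray
    volume_l: float
    o2_pct: Optional[np.ndarray] = None

    def __post_init__(self):
        t = _as_float_array(self.time_h, "time_h")
        c = _as_float_array(self.co2_pct, "co2_pct")
        a = _as_float_array(self.airflow_vvm, "airflow_vvm")
        if t.size < 2:
            raise ValueError("off-gas series needs at least 2 points")
        if not (len(t) == len(c) == len(a)):
            raise ValueError("time_h, co2_pct and airflow_vvm lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing")
        if np.any((c < 0) | (c > 100)):
            raise ValueError("co2_pct outside [0, 100]")
        if np.any(a < 0):
            raise ValueError("airflow_vvm must be >= 0")
        if not self.volume_l > 0:
            raise ValueError("volume_l must be positive")
        o2 = self.o2_pct
        if o2 is not None:
            o2 = _as_float_array(o2, "o2_pct")
            if len(o2) != len(t):
                raise ValueError("o2_pct length differs from time_h")
        for n, v in (("time_h", t), ("co2_pct", c), ("airflow_vvm", a), ("o2_pct", o2)):
            object.__setattr__(self, n, v)

    def __len__(self) -> int:
        return self.time_h.size

    def with_co2(self, co2_pct: np.ndarray) -> "OffGasSeries":
        return replace(self, co2_pct=np.asarray(co2_pct, dtype=float))


@dataclass(frozen=True)
class CerSeries:
    """CO2 evolution rate and its running integral.

    ``cer`` is in mmol CO2 per litre of broth per hour; ``acc_co2`` is the
    trapezoidal integral from the first time point, in mmol/L, and is 0 at
    the first point by construction.
    """

    time_h: np.ndarray
    cer: np.ndarray
    acc_co2: Optional[np.ndarray] = None

    def __post_init__(self):
        t = _as_float_array(self.time_h, "time_h")
        c = _as_float_array(self.cer, "cer")
        if len(t) != len(c):
            raise ValueError("time_h and cer lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing")
        acc = self.acc_co2
        if acc is not None:
            acc = _as_float_array(acc, "acc_co2")
            if len(acc) != len(t):
                raise ValueError("acc_co2 length differs from time_h")
            if acc[0] != 0:
                raise ValueError("acc_co2 must start at 0")
        for n, v in (("time_h", t), ("cer", c), ("acc_co2", acc)):
            object.__setattr__(self, n, v)

    def __len__(self) -> int:
        return self.time_h.size


@dataclass(frozen=True)
class SampleSeries:
    """Sparse broth samples: dry weight and substrate concentration.

    Each series is a pair of aligned arrays (time_h, value); the two series
    need not share a grid.  Concentrations are g/L and must be >= 0.
    """

    dw_time_h: np.ndarray = field(default_factory=lambda: np.empty(0))
    dw_g_l: np.ndarray = field(default_factory=lambda: np.empty(0))
    glucose_time_h: np.ndarray = field(default_factory=lambda: np.empty(0))
    glucose_g_l: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        for tn, vn in (("dw_time_h", "dw_g_l"), ("glucose_time_h", "glucose_g_l")):
            t = _as_float_array(getattr(self, tn), tn)
            v = _as_float_array(getattr(self, vn), vn)
            if len(t) != len(v):
                raise ValueError(f"{tn} and {vn} lengths differ")
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"{tn} must be strictly increasing")
            if np.any(v < 0):
                raise ValueError(f"{vn} must be >= 0")
            object.__setattr__(self, tn, t)
            object.__setattr__(self, vn, v)


@dataclass(frozen=True)
class FermentationRun:
    """One reactor run: off-gas plus sparse samples plus metadata."""

    run_id: str
    offgas: OffGasSeries
    samples: SampleSeries = field(default_factory=SampleSeries)
    species: str = ""
    medium: str = ""
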