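"""Model/Results interface tying the physiology stages together.

:class:`FermentationKinetics` is constructed from a
:class:`~fermprof.series.FermentationRun` (or from dataframes) and its
``fit()`` runs the full chain — gas balance, phase segmentation, growth
kinetics — returning a :class:`FermentationKineticsResults` object that
carries the estimates, their fit diagnostics, and a ``summary()`` table.
:func:`summarize_condition` aggregates replicate results into per-parameter
mean/SD summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gas import compute_cer
from .kinetics import (
    KineticsResult,
    mu_from_dryweight,
    summarize_replicates,
    yield_sx,
)
from .segmentation import PhaseSegmentation, SegmentationParams, segment_run
from .series import CerSeries, FermentationRun, OffGasSeries, SampleSeries


@dataclass(frozen=True)
class KineticsParams:
    """All stage parameters of the physiology pipeline."""

    segmentation: SegmentationParams = SegmentationParams()
    mu_r2_min: float = 0.96
    yield_match_tol_h: float = 2.0

    def __post_init__(self):
        if not 0 < self.mu_r2_min < 1:
            raise ValueError("mu_r2_min must be in (0, 1)")


class FermentationKinetics:
    """Growth-kinetics model for one fermentation run.

    Parameters
    ----------
    run : FermentationRun
        Off-gas series plus (optionally sparse or empty) dry-weight and
        glucose samples.
    params : KineticsParams, optional
        Stage parameters; defaults follow the reference workflow
        (lag threshold 6% CO2, R^2 >= 0.99 for the CO2 fit, >= 0.96 for
        the dry-weight fit).
    """

    def __init__(self, run: FermentationRun, params: Optional[KineticsParams] = None):
        self.run = run
        self.params = params or KineticsParams()

    @classmethod
    def from_dataframes(
        cls,
        offgas: pd.DataFrame,
        volume_l: float,
        samples: Optional[pd.DataFrame] = None,
        run_id: str = "run",
        species: str = "",
        medium: str = "",
        params: Optional[KineticsParams] = None,
    ) -> "FermentationKinetics":
        """Build from an off-gas frame (time_h, co2_pct, airflow_vvm
        [, o2_pct]) and an optional samples frame (time_h,
        dry_weight_g_l and/or glucose_g_l, NaN where unsampled)."""
        gas = OffGasSeries(
            time_h=offgas["time_h"].to_numpy(),
            co2_pct=offgas["co2_pct"].to_numpy(),
            airflow_vvm=offgas["airflow_vvm"].to_numpy(),
            volume_l=volume_l,
            o2_pct=offgas["o2_pct"].to_numpy() if "o2_pct" in offgas else None,
        )
        samp = SampleSeries()
        if samples is not None:
            def series(col):
                if col not in samples:
                    return np.empty(0), np.empty(0)
                sub = samples[["time_h", col]].dropna()
                return sub["time_h"].to_numpy(), sub[col].to_numpy()

            td, vd = series("dry_weight_g_l")
            tg, vg = series("glucose_g_l")
            samp = SampleSeries(
                dw_time_h=td, dw_g_l=vd, glucose_time_h=tg, glucose_g_l=vg
            )
        return cls(
            FermentationRun(
                run_id=run_id, offgas=gas, samples=samp, species=species, medium=medium
            ),
            params,
        )

    def fit(self) -> "FermentationKineticsResults":
        """Run gas balance, segmentation and kinetics for this run."""
        p = self.params
        cer = compute_cer(self.run.offgas, inlet_co2_pct=p.segmentation.inlet_co2_pct)
        seg = segment_run(self.run, p.segmentation, cer=cer)
        flags: list[str] = []

        samples = self.run.samples
        mu_fit = None
        if samples.dw_time_h.size:
            try:
                mu_fit = mu_from_dryweight(
                    samples.dw_time_h,
                    samples.dw_g_l,
                    (seg.exp_start_h, seg.exp_end_h),
                    r2_min=p.mu_r2_min,
                )
            except ValueError as err:
                flags.append(f"mu: {err}")
            if mu_fit is None and not flags:
                flags.append("mu: <3 in-window dry-weight samples or R^2 below threshold")
        else:
            flags.append("mu: no dry-weight samples")

        ysx = None
        if samples.dw_time_h.size and samples.glucose_time_h.size:
            try:
                ysx = yield_sx(
                    samples.dw_time_h,
                    samples.dw_g_l,
                    samples.glucose_time_h,
                    samples.glucose_g_l,
                    (seg.lag_end_h, seg.t_co2max_h),
                    match_tol_h=p.yield_match_tol_h,
                )
            except ValueError as err:
                flags.append(f"yield: {err}")
        else:
            flags.append("yield: missing dry-weight or glucose samples")

        result = KineticsResult(
            mu_max_per_h=mu_fit.mu_per_h if mu_fit else None,
            mu_r2=mu_fit.r2 if mu_fit else None,
            mu_n=mu_fit.n_points if mu_fit else 0,
            co2_rate_per_h=seg.fit.slope_per_h,
            y_sx=ysx,
            flags=tuple(flags),
        )
        return FermentationKineticsResults(
            model=self, segmentation=seg, kinetics=result, cer=cer
        )


@dataclass(frozen=True)
class FermentationKineticsResults:
    """Fitted phase boundaries and kinetic parameters for one run."""

    model: FermentationKinetics
    segmentation: PhaseSegmentation
    kinetics: KineticsResult
    cer: CerSeries

    @property
    def run(self) -> FermentationRun:
        return self.model.run

    def to_row(self) -> dict:
        """One flat record, the unit of the per-run results CSV."""
        s, k = self.segmentation, self.kinetics
        return {
            "run_id": self.run.run_id,
            "species": self.run.species,
            "medium": self.run.medium,
            "lag_end_h": s.lag_end_h,
            "exp_start_h": s.exp_start_h,
            "exp_end_h": s.exp_end_h,
            "t_co2max_h": s.t_co2max_h,
            "nonexp_duration_h": s.nonexp_duration_h,
            "co2_rate_h": k.co2_rate_per_h,
            "r2": s.fit.r2,
            "n_points": s.fit.n_points,
            "mu_max_h": k.mu_max_per_h if k.mu_max_per_h is not None else np.nan,
            "mu_r2": k.mu_r2 if k.mu_r2 is not None else np.nan,
            "mu_n": k.mu_n,
            "y_sx": k.y_sx if k.y_sx is not None else np.nan,
            "flags": "; ".join(k.flags),
        }

    def summary(self) -> str:
        s, k = self.segmentation, self.kinetics
        lines = [
            f"Fermentation kinetics: {self.run.run_id}"
            + (f" ({self.run.species}, {self.run.medium})" if self.run.species else ""),
            "-" * 58,
            f"lag end (CO2 threshold rule)      {s.lag_end_h:10.2f} h",
            f"exponential window                {s.exp_start_h:6.2f} - {s.exp_end_h:.2f} h"
            f"  (n={s.fit.n_points}, R^2={s.fit.r2:.4f})",
            f"CO2 off-gas maximum               {s.t_co2max_h:10.2f} h",
            f"non-exponential phase             {s.nonexp_duration_h:10.2f} h",
            f"max CO2 production rate           {k.co2_rate_per_h:10.4f} 1/h",
        ]
        if k.mu_max_per_h is not None:
            lines.append(
                f"mu_max (dry weight)               {k.mu_max_per_h:10.4f} 1/h"
                f"  (n={k.mu_n}, R^2={k.mu_r2:.4f})"
            )
        else:
            lines.append("mu_max (dry weight)                    absent")
        if k.y_sx is not None:
            lines.append(f"yield Y_sx                        {k.y_sx:10.4f} g DW/g")
        else:
            lines.append("yield Y_sx                             absent")
        for f in k.flags:
            lines.append(f"  note: {f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_run  # deferred: matplotlib import is slow

        return plot_run(self, ax=ax)


#: parameters aggregated over replicates, in reporting order
SUMMARY_PARAMS = (
    ("mu_max_h", "mu"),
    ("co2_rate_h", "co2rate"),
    ("y_sx", "ysx"),
    ("lag_end_h", "lag"),
    ("nonexp_duration_h", "nonexp"),
)


def summarize_condition(
    results: Sequence[FermentationKineticsResults],
    species: str = "",
    medium: str = "",
) -> dict:
    """Mean/SD/n per parameter over replicate runs of one condition
    (species x medium) — one row of the condition summary CSV."""
    rows = pd.DataFrame([r.to_row() for r in results])
    out: dict = {
        "species": species or (rows["species"].iloc[0] if len(rows) else ""),
        "medium": medium or (rows["medium"].iloc[0] if len(rows) else ""),
        "n_runs": len(rows),
    }
    for col, short in SUMMARY_PARAMS:
        vals = [None if pd.isna(v) else float(v) for v in rows[col]]
        summ = summarize_replicates(vals)
        out[f"{short}_mean"] = summ.mean if summ else np.nan
        out[f"{short}_sd"] = summ.sd if summ else np.nan
        out[f"{short}_n"] = summ.n if summ else 0
    return out
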