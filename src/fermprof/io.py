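"""CSV readers and writers for all pipeline inputs and outputs.

Formats (all plain CSV with a one-line header):

* off-gas:       time_h, co2_pct, airflow_vvm [, o2_pct]; run metadata
                 (volume_l, run_id, species, medium) in a YAML sidecar
                 ``<stem>.meta.yaml`` or passed explicitly;
* samples:       time_h, dry_weight_g_l, glucose_g_l (blank where unsampled);
* feature table: sample_id, mz, rt_min, area, intensity;
* library:       name, formula, monoisotopic_mass, rt_min, standard_confirmed;
* segmentation:  one row per run (see model.FermentationKineticsResults.to_row);
* ground truth:  one row per simulated replicate.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import FermentationKinetics, FermentationKineticsResults, KineticsParams
from .profiling import FeatureTable
from .series import FermentationRun, OffGasSeries, SampleSeries
from .simulate import GroundTruth


def write_offgas_csv(run: FermentationRun, path) -> None:
    path = Path(path)
    gas = run.offgas
    df = pd.DataFrame(
        {"time_h": gas.time_h, "co2_pct": gas.co2_pct, "airflow_vvm": gas.airflow_vvm}
    )
    if gas.o2_pct is not None:
        df["o2_pct"] = gas.o2_pct
    df.to_csv(path, index=False)
    meta = {
        "run_id": run.run_id,
        "species": run.species,
        "medium": run.medium,
        "volume_l": float(gas.volume_l),
    }
    path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_offgas_csv(path, volume_l: Optional[float] = None) -> FermentationRun:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(".meta.yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    if volume_l is None:
        volume_l = meta.get("volume_l")
    if volume_l is None:
        raise ValueError(
            f"working volume for {path} not given and no {meta_path.name} sidecar found"
        )
    gas = OffGasSeries(
        time_h=df["time_h"].to_numpy(),
        co2_pct=df["co2_pct"].to_numpy(),
        airflow_vvm=df["airflow_vvm"].to_numpy(),
        volume_l=float(volume_l),
        o2_pct=df["o2_pct"].to_numpy() if "o2_pct" in df else None,
    )
    return FermentationRun(
        run_id=str(meta.get("run_id", path.stem)),
        offgas=gas,
        species=str(meta.get("species", "")),
        medium=str(meta.get("medium", "")),
    )


def write_samples_csv(samples: SampleSeries, path) -> None:
    times = np.union1d(samples.dw_time_h, samples.glucose_time_h)
    def col(t_src, v_src):
        out = np.full(times.shape, np.nan)
        idx = np.searchsorted(times, t_src)
        out[idx] = v_src
        return out

    pd.DataFrame(
        {
            "time_h": times,
            "dry_weight_g_l": col(samples.dw_time_h, samples.dw_g_l),
            "glucose_g_l": col(samples.glucose_time_h, samples.glucose_g_l),
        }
    ).to_csv(path, index=False)


def read_samples_csv(path) -> SampleSeries:
    df = pd.read_csv(path)
    def series(col):
        if col not in df:
            return np.empty(0), np.empty(0)
        sub = df[["time_h", col]].dropna()
        return sub["time_h"].to_numpy(), sub[col].to_numpy()

    td, vd = series("dry_weight_g_l")
    tg, vg = series("glucose_g_l")
    return SampleSeries(dw_time_h=td, dw_g_l=vd, glucose_time_h=tg, glucose_g_l=vg)


def load_run(
    offgas_path, samples_path=None, volume_l: Optional[float] = None
) -> FermentationRun:
    run = read_offgas_csv(offgas_path, volume_l=volume_l)
    if samples_path is not None:
        run = dataclasses.replace(run, samples=read_samples_csv(samples_path))
    return run


def write_feature_table_csv(table: FeatureTable, path) -> None:
    df = table.features.copy()
    df.insert(0, "sample_id", table.sample_id)
    df.to_csv(path, index=False)


def read_feature_table_csv(path) -> FeatureTable:
    df = pd.read_csv(path)
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else Path(path).stem
    return FeatureTable(
        sample_id=sample_id,
        features=df[["mz", "rt_min", "area", "intensity"]],
    )


def write_segmentation_csv(
    results: Sequence[FermentationKineticsResults], path
) -> None:
    pd.DataFrame([r.to_row() for r in results]).to_csv(path, index=False)


def write_summary_csv(rows: Sequence[dict], path) -> None:
    pd.DataFrame(list(rows)).to_csv(path, index=False)


def write_ground_truth_csv(truths: Sequence[GroundTruth], path) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in truths]).to_csv(path, index=False)


def fit_run_files(
    offgas_path,
    samples_path=None,
    volume_l: Optional[float] = None,
    params: Optional[KineticsParams] = None,
) -> FermentationKineticsResults:
    """Convenience: load one run from CSV and fit the kinetics model."""
    run = load_run(offgas_path, samples_path, volume_l=volume_l)
    return FermentationKinetics(run, params).fit()
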