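"""LC-MS molecular-feature counting and accurate-mass dereplication.

A molecular feature is an (m/z, retention time) peak with an integrated
area and an apex intensity, the proxy for one compound/adduct in an
untargeted LC-MS run.  The workflow mirrors untargeted screening practice
for fungal secondary metabolites in positive electrospray:

1. candidate compounds are the features of the *latest* sample of a
   cultivation with area strictly above 500,000 counts and intensity
   strictly above 10,000 counts;
2. each candidate is searched for in the other samples by m/z (ppm
   tolerance) and retention time — with *no* area/intensity threshold on
   the search side;
3. a candidate counts as reproducibly present when found in at least two
   of the three biological replicates;
4. identification (dereplication) matches candidate m/z against the
   adduct masses of a compound library; every qualifying match is reported
   with its signed ppm error — ambiguity between isobaric entries is
   preserved, not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass

#: mass of a proton, Da (adds on protonation in ESI+)
PROTON = 1.00727646688
#: common positive-mode adduct mass shifts, Da
ADDUCTS_ESI_POS = {
    "[M+H]+": PROTON,
    "[M+Na]+": 22.98922070,
    "[M+NH4]+": 18.03382555,
}

FEATURE_COLUMNS = ("mz", "rt_min", "area", "intensity")


@dataclass(frozen=True)
class FeatureTable:
    """Molecular features of one LC-MS sample.

    ``sample_id`` identifies (run, time point, replicate); ``features`` is
    a DataFrame with columns mz, rt_min, area, intensity.
    """

    sample_id: str
    features: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.features).reset_index(drop=True)
        missing = set(FEATURE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        df = df.loc[:, list(FEATURE_COLUMNS)].astype(float)
        if len(df) and not ((df["area"] > 0).all() and (df["intensity"] > 0).all()):
            raise ValueError("area and intensity must be positive")
        object.__setattr__(self, "features", df)

    def __len__(self) -> int:
        return len(self.features)


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of a neutral elemental formula, Da."""
    try:
        return float(_pt_mass.calculate_mass(formula=formula))
    except Exception as err:  # pyteomics raises several parse error types
        raise ValueError(f"cannot parse elemental formula {formula!r}: {err}") from err


@dataclass(frozen=True)
class CompoundLibrary:
    """Reference compounds for dereplication.

    ``entries`` columns: name (unique), monoisotopic_mass (Da), rt_min
    (NaN when unknown), standard_confirmed (bool).  Formulas are resolved
    to masses at load time; an unparseable formula rejects the entry by
    name rather than silently dropping it.
    """

    entries: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.entries).reset_index(drop=True)
        if "name" not in df.columns:
            raise ValueError("library needs a 'name' column")
        if df["name"].duplicated().any():
            dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate library entry name: {dup!r}")
        if "monoisotopic_mass" not in df.columns:
            df["monoisotopic_mass"] = np.nan
        need = df["monoisotopic_mass"].isna()
        if need.any():
            if "formula" not in df.columns:
                raise ValueError("entries without mass need a 'formula' column")
            for i in df.index[need]:
                f = df.at[i, "formula"]
                name = df.at[i, "name"]
                if not isinstance(f, str) or not f:
                    raise ValueError(
                        f"library entry {name!r} has neither mass nor formula"
                    )
                try:
                    df.at[i, "monoisotopic_mass"] = monoisotopic_mass(f)
                except ValueError as err:
                    raise ValueError(f"library entry {name!r}: {err}") from err
        if not (df["monoisotopic_mass"] > 0).all():
            raise ValueError("monoisotopic masses must be positive")
        if "rt_min" not in df.columns:
            df["rt_min"] = np.nan
        if "standard_confirmed" not in df.columns:
            df["standard_confirmed"] = False
        df["standard_confirmed"] = df["standard_confirmed"].astype(bool)
        object.__setattr__(self, "entries", df)

    @classmethod
    def from_csv(cls, path) -> "CompoundLibrary":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.entries)

    def mass_of(self, name: str) -> float:
        row = self.entries.loc[self.entries["name"] == name]
        if row.empty:
            raise KeyError(f"compound {name!r} not in library")
        return float(row["monoisotopic_mass"].iloc[0])


def threshold_features(
    final_table: FeatureTable,
    min_area: float = 500_000.0,
    min_intensity: float = 10_000.0,
) -> pd.DataFrame:
    """Candidate compounds: features of the latest-time sample with area
    strictly above ``min_area`` AND intensity strictly above
    ``min_intensity``.  An empty table yields an empty candidate list.
    """
    if min_area < 0 or min_intensity < 0:
        raise ValueError("thresholds must be >= 0")
    df = final_table.features
    keep = (df["area"] > min_area) & (df["intensity"] > min_intensity)
    return df.loc[keep].reset_index(drop=True)


def match_feature(
    query_mz: float,
    query_rt_min: float,
    table: FeatureTable,
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.1,
) -> Optional[pd.Series]:
    """Nearest feature of ``table`` within both tolerances, or ``None``.

    Candidates within the m/z ppm window and the retention-time window are
    ranked by absolute ppm error; ties go to the earlier retention time.
    """
    if mz_tol_ppm <= 0 or rt_tol_min <= 0:
        raise ValueError("tolerances must be > 0")
    df = table.features
    if df.empty:
        return None
    ppm = (df["mz"] - query_mz) / query_mz * 1e6
    ok = (ppm.abs() <= mz_tol_ppm) & ((df["rt_min"] - query_rt_min).abs() <= rt_tol_min)
    if not ok.any():
        return None
    cand = df.loc[ok].copy()
    cand["ppm_error"] = ppm[ok]
    cand = cand.sort_values(
        by=["ppm_error", "rt_min"], key=lambda s: s.abs() if s.name == "ppm_error" else s
    )
    return cand.iloc[0]


def count_reproducible(
    tables: Sequence[FeatureTable],
    candidates: pd.DataFrame,
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.1,
    min_present: int = 2,
) -> int:
    """Number of candidates present in >= ``min_present`` of the replicate
    tables (matched at any area/intensity — deliberately no threshold on
    the search side).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 replicate tables")
    count = 0
    for _, row in candidates.iterrows():
        hits = sum(
            match_feature(row["mz"], row["rt_min"], t, mz_tol_ppm, rt_tol_min)
            is not None
            for t in tables
        )
        if hits >= min_present:
            count += 1
    return count


def dereplicate(
    features: pd.DataFrame,
    library: CompoundLibrary,
    adducts: Optional[dict] = None,
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.1,
) -> pd.DataFrame:
    """Accurate-mass identification of features against a library.

    Every (feature, library entry, adduct) combination whose theoretical
    adduct m/z lies within ``mz_tol_ppm`` is reported with its signed ppm
    error; when the library entry carries a retention time it acts as a
    secondary filter.  Matches are mass matches only — chromatographic or
    spectral confirmation is outside this function's scope, so downstream
    reports should treat identities as putative.

    Returns a DataFrame with columns feature_index, mz, rt_min, compound,
    adduct, theoretical_mz, ppm_error, standard_confirmed.
    """
    adducts = dict(adducts) if adducts is not None else dict(ADDUCTS_ESI_POS)
    if not adducts:
        raise ValueError("adduct list must be non-empty")
    lib = library.entries
    rows = []
    for i, feat in features.iterrows():
        for _, entry in lib.iterrows():
            for adduct, shift in adducts.items():
                theo = entry["monoisotopic_mass"] + shift
                ppm = (feat["mz"] - theo) / theo * 1e6
                if abs(ppm) > mz_tol_ppm:
                    continue
                if np.isfinite(entry["rt_min"]) and (
                    abs(feat["rt_min"] - entry["rt_min"]) > rt_tol_min
                ):
                    continue
                rows.append(
                    {
                        "feature_index": i,
                        "mz": feat["mz"],
                        "rt_min": feat["rt_min"],
                        "compound": entry["name"],
                        "adduct": adduct,
                        "theoretical_mz": theo,
                        "ppm_error": ppm,
                        "standard_confirmed": bool(entry["standard_confirmed"]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_index",
            "mz",
            "rt_min",
            "compound",
            "adduct",
            "theoretical_mz",
            "ppm_error",
            "standard_confirmed",
        ],
    )


@dataclass(frozen=True)
class StageProfile:
    """Per-condition metabolite dynamics over the sampled stages."""

    condition: str
    counts_per_stage: tuple
    first_stage: dict  # compound/feature key -> first stage observed (1-based)
    rising_final: Optional[bool]  # summed matched area stage3 > stage2


@dataclass(frozen=True)
class ProfileReport:
    """Stage profiles for a set of conditions plus the rising-level tally."""

    profiles: tuple

    @property
    def n_rising(self) -> int:
        return sum(1 for p in self.profiles if p.rising_final)

    @property
    def n_conditions(self) -> int:
        return len(self.profiles)


def stage_profile(
    per_stage: dict,
) -> ProfileReport:
    """Assemble a :class:`ProfileReport` from per-condition stage data.

    ``per_stage`` maps condition name -> list (one entry per time point, in
    chronological order) of DataFrames with at least a ``key`` column (a
    compound or feature identity) and an ``area`` column.  For each
    condition the report carries the per-stage counts, the first stage at
    which each key appears, and — when at least two stages exist — whether
    the summed area of the last stage exceeds the previous stage's.
    """
    profiles = []
    for cond, stages in per_stage.items():
        if len(stages) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 time points")
        counts = tuple(len(df) for df in stages)
        first: dict = {}
        for s_idx, df in enumerate(stages, start=1):
            for key in df["key"] if len(df) else []:
                first.setdefault(key, s_idx)
        last = stages[-1]["area"].sum() if len(stages[-1]) else 0.0
        prev = stages[-2]["area"].sum() if len(stages[-2]) else 0.0
        profiles.append(
            StageProfile(
                condition=cond,
                counts_per_stage=counts,
                first_stage=first,
                rising_final=bool(last > prev),
            )
        )
    return ProfileReport(profiles=tuple(profiles))
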