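"""Subjects and NONMEM-style dataset I/O.

The on-disk layout is a flat CSV with one row per event, chronological within
subject: dose rows carry AMT (mg) and DUR (h) with DV empty and MDV = 1;
observation rows carry DV (mg/L) with AMT empty and MDV = 0.  Covariate
columns (AGE, SEX, TBW, SCR, SCR_UNIT, ICU, and optionally SHOCK, MOF) repeat
on every row of a subject, as is conventional for nonlinear mixed-effects
datasets.

Creatinine clearance is recomputed row-wise from SCR via Cockcroft-Gault and
averaged per subject, so datasets with multiple creatinine records per
admission are summarized by the per-subject mean CLcr.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .pk_core import Covariates, DoseEvent, cockcroft_gault

__all__ = ["Subject", "read_dataset", "write_dataset", "DatasetError"]

COLUMNS = [
    "ID", "TIME", "AMT", "DUR", "DV", "MDV",
    "AGE", "SEX", "TBW", "SCR", "SCR_UNIT", "ICU", "SHOCK", "MOF",
]

_UNIT_ALIASES = {
    "mg/dl": "mg/dL",
    "mg/dL": "mg/dL",
    "umol/l": "umol/L",
    "umol/L": "umol/L",
    "µmol/l": "umol/L",
    "µmol/L": "umol/L",
}


class DatasetError(ValueError):
    """Malformed dataset file."""


@dataclass(frozen=True)
class Subject:
    """Covariates plus dosing history and concentration observations."""

    id: int
    covariates: Covariates
    doses: tuple[DoseEvent, ...]
    obs_times: np.ndarray  # h, sorted
    obs_dv: np.ndarray  # mg/L

    def __post_init__(self) -> None:
        object.__setattr__(self, "obs_times", np.asarray(self.obs_times, dtype=float))
        object.__setattr__(self, "obs_dv", np.asarray(self.obs_dv, dtype=float))
        if self.obs_times.shape != self.obs_dv.shape:
            raise DatasetError("observation times and values must align")

    @property
    def n_obs(self) -> int:
        return self.obs_times.size

    def time_after_dose(self) -> np.ndarray:
        """Time since the start of the most recent infusion, per observation."""
        starts = np.array([d.start_time for d in self.doses])
        tad = np.empty(self.n_obs)
        for j, t in enumerate(self.obs_times):
            prior = starts[starts <= t]
            tad[j] = t - prior.max() if prior.size else np.nan
        return tad


def _int_or_zero(v) -> int:
    return 0 if v is None or (isinstance(v, float) and np.isnan(v)) else int(v)


def _normalize_unit(u: str) -> str:
    key = str(u).strip()
    unit = _UNIT_ALIASES.get(key) or _UNIT_ALIASES.get(key.lower())
    if unit is None:
        raise DatasetError(f"unknown SCR_UNIT {u!r} (expected mg/dL or umol/L)")
    return unit


def read_dataset(path) -> list[Subject]:
    """Read a NONMEM-style CSV into a list of :class:`Subject`."""
    df = pd.read_csv(path)
    missing = {"ID", "TIME", "AMT", "DUR", "DV", "AGE", "SEX", "TBW", "SCR", "SCR_UNIT", "ICU"} - set(df.columns)
    if missing:
        raise DatasetError(f"missing required columns: {sorted(missing)}")
    if (df["TIME"] < 0).any():
        raise DatasetError("negative event times")
    subjects = []
    for sid, g in df.groupby("ID", sort=True):
        g = g.sort_values("TIME", kind="stable")
        first = g.iloc[0]
        # per-row CLcr from creatinine, averaged over the admission
        clcrs = []
        for _, row in g.iterrows():
            cov_row = Covariates(
                age=float(row["AGE"]),
                sex="female" if int(row["SEX"]) == 0 else "male",
                tbw=float(row["TBW"]),
                scr=float(row["SCR"]),
                scr_unit=_normalize_unit(row["SCR_UNIT"]),
            )
            clcrs.append(cockcroft_gault(cov_row))
        cov = Covariates(
            age=float(first["AGE"]),
            sex="female" if int(first["SEX"]) == 0 else "male",
            tbw=float(first["TBW"]),
            scr=float(first["SCR"]),
            scr_unit=_normalize_unit(first["SCR_UNIT"]),
            icu=bool(int(first["ICU"])),
            clcr=float(np.mean(clcrs)),
            shock=bool(_int_or_zero(first.get("SHOCK"))),
            mof=bool(_int_or_zero(first.get("MOF"))),
        )
        dose_rows = g[g["AMT"].notna() & (g["AMT"] > 0)]
        obs_rows = g[g["DV"].notna()]
        if "MDV" in g.columns:
            obs_rows = obs_rows[obs_rows["MDV"].fillna(0).astype(int) == 0]
        doses = tuple(
            DoseEvent(float(r["TIME"]), float(r["AMT"]), float(r["DUR"]))
            for _, r in dose_rows.iterrows()
        )
        subjects.append(
            Subject(
                id=int(sid),
                covariates=cov,
                doses=doses,
                obs_times=obs_rows["TIME"].to_numpy(float),
                obs_dv=obs_rows["DV"].to_numpy(float),
            )
        )
    return subjects


def write_dataset(subjects: Sequence[Subject], path) -> None:
    """Write subjects to the NONMEM-style CSV layout (chronological rows)."""
    rows = []
    for s in subjects:
        cov = s.covariates
        base = {
            "ID": s.id,
            "AGE": cov.age,
            "SEX": 0 if cov.sex == "female" else 1,
            "TBW": cov.tbw,
            "SCR": cov.scr if cov.scr is not None else np.nan,
            "SCR_UNIT": cov.scr_unit,
            "ICU": int(cov.icu),
            "SHOCK": int(cov.shock),
            "MOF": int(cov.mof),
        }
        events = [
            {"TIME": d.start_time, "AMT": d.amount, "DUR": d.duration,
             "DV": np.nan, "MDV": 1, **base}
            for d in s.doses
        ]
        events += [
            {"TIME": t, "AMT": np.nan, "DUR": np.nan, "DV": y, "MDV": 0, **base}
            for t, y in zip(s.obs_times, s.obs_dv)
        ]
        events.sort(key=lambda r: (r["TIME"], r["MDV"] == 0))
        rows.extend(events)
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
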