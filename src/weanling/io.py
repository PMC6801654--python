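"""CSV ingestion and validation for the three input table formats.

All files are comma-separated, UTF-8, '.' decimal, header required.  Times
are days since weaning (t = 0 at weaning); an age-based weights table can be
converted with :func:`ages_to_days_since_weaning`.
"""

from __future__ import annotations

import logging
from typing import Dict, List

import numpy as np
import pandas as pd

from .calibration import WeightTrajectory
from .phenotypes import HAEMOGRAM_TRAITS, FaecalScoreSeries

__all__ = [
    "write_csv",
    "load_weights",
    "load_faecal_scores",
    "load_haemograms",
    "ages_to_days_since_weaning",
]


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a CSV whose floats round-trip exactly (shortest repr)."""
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))

log = logging.getLogger("weanling")

WEIGHT_COLUMNS = ("animal_id", "time_days", "weight_kg")
FAECAL_COLUMNS = ("animal_id", "day", "score")


def _read_csv(path, required) -> pd.DataFrame:
    # round_trip parser: loaded floats equal the written ones to the last bit
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: file contains no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def load_weights(path) -> List[WeightTrajectory]:
    """Parse a weights CSV into per-animal trajectories.

    Rows with non-positive weight or negative time are rejected (logged with
    their line numbers); animals without a t = 0 record are skipped with a
    warning, since calibration fixes W0 at the weaning weighing.
    """
    df = _read_csv(path, WEIGHT_COLUMNS)
    bad = (df["weight_kg"] <= 0) | (df["time_days"] < 0)
    if bad.any():
        for idx in df.index[bad]:
            log.warning(
                "%s: rejected row %d (animal %s, t=%s, w=%s)",
                path, idx + 2, df.at[idx, "animal_id"],
                df.at[idx, "time_days"], df.at[idx, "weight_kg"],
            )
        df = df[~bad]
    out = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("time_days", kind="mergesort")
        times = grp["time_days"].to_numpy(dtype=float)
        if times.size < 2 or times[0] != 0.0:
            log.warning("%s: animal %s lacks a t=0 weaning record; skipped",
                        path, animal_id)
            continue
        out.append(
            WeightTrajectory(str(animal_id), times,
                             grp["weight_kg"].to_numpy(dtype=float))
        )
    if not out:
        raise ValueError(f"{path}: no usable trajectories")
    return out


def load_faecal_scores(path) -> List[FaecalScoreSeries]:
    """Parse a faecal-score CSV (animal_id, day, score) per animal."""
    df = _read_csv(path, FAECAL_COLUMNS)
    out = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("day", kind="mergesort")
        out.append(
            FaecalScoreSeries(str(animal_id),
                              grp["day"].to_numpy(dtype=int),
                              grp["score"].to_numpy(dtype=int))
        )
    return out


def load_haemograms(path) -> pd.DataFrame:
    """Parse a haemogram CSV; derives N_Lym when absent."""
    df = _read_csv(path, ("animal_id", "age_days"))
    present = [c for c in HAEMOGRAM_TRAITS if c in df.columns]
    if not present:
        raise ValueError(f"{path}: no recognised haemogram trait columns")
    if "N_Lym" not in df.columns and {"N", "Lym"} <= set(df.columns):
        lym = df["Lym"].to_numpy(dtype=float)
        n = df["N"].to_numpy(dtype=float)
        df = df.copy()
        df["N_Lym"] = np.where(lym > 0, n / np.where(lym > 0, lym, 1.0), np.nan)
    df["animal_id"] = df["animal_id"].astype(str)
    return df


def ages_to_days_since_weaning(
    df: pd.DataFrame, weaning_ages: Dict[str, float],
    age_column: str = "age_days",
) -> pd.DataFrame:
    """Convert an age-based weights table to days since weaning per animal."""
    out = df.copy()
    out["time_days"] = [
        row[age_column] - weaning_ages[str(row["animal_id"])]
        for _, row in df.iterrows()
    ]
    return out.drop(columns=[age_column])
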