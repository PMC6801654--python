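"""Synthetic piglet cohorts: weights, faecal scores and haemograms.

Generates cohorts with the statistical structure the analysis pipeline
assumes, so every stage can be exercised and scored against known ground
truth.  The defaults emulate the study conditions the package targets:

* weaning at 28 days of age, weaning weight ~ Normal(8.91, 0.49) kg;
* weighings twice a week until 50 days of age (3/4-day alternation) and
  weekly until 100 days, i.e. 13 post-weaning records within the 75-day
  analysis horizon plus the weaning weighing itself;
* a perturbation of depth C (uniform on [0, 0.12] 1/d, so high-C animals
  lose weight in the first days) with recovery switching on average 9 days
  after weaning (Normal(9, 3) truncated to (2, 30) d);
* multiplicative lognormal measurement noise (default CV 1.5%), which keeps
  weights positive and scales the error with the weight;
* faecal scores on days 0, 2, 6, 8, 12, 15, 20, 27, 34 post-weaning, with
  diarrhoea probability increasing in C and decaying after recovery;
* haemograms at 28 and 34 days of age whose traits load on the growth
  parameters with the signs observed in weaned piglets (e.g. haematocrit
  and haemoglobin decreasing with perturbation depth).

Per-animal random substreams are spawned from the cohort seed, so cohorts
are reproducible animal-by-animal and output CSVs are byte-identical across
runs with the same configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .calibration import WeightTrajectory
from .growth import PerturbedParams, TimeGrid, perturbed_weight
from .phenotypes import (FAECAL_PANEL_DAYS, HAEMOGRAM_TRAITS,
                         FaecalScoreSeries, derive_n_lym)

__all__ = [
    "CohortConfig",
    "SyntheticAnimal",
    "Cohort",
    "build_schedule",
    "sample_animal_params",
    "simulate_trajectory",
    "simulate_faecal_scores",
    "simulate_haemogram",
    "generate_cohort",
]

#: Baseline (mean, residual SD) per haemogram trait, healthy weaned piglets.
DEFAULT_BASELINES: Dict[str, Tuple[float, float]] = {
    "Bas": (0.5, 0.3),      # %
    "Plt": (500.0, 120.0),  # m/mm^3
    "Eos": (2.0, 1.0),      # %
    "Ery": (6.3, 0.6),      # m/mm^3
    "Hct": (33.0, 3.5),     # %
    "Hgb": (10.5, 1.2),     # g/dl
    "Leu": (15.0, 4.0),     # m/mm^3
    "Lym": (55.0, 8.0),     # %
    "MCHC": (32.0, 1.5),    # g/dl
    "MCH": (17.5, 1.5),     # pg
    "MCV": (55.0, 4.0),     # fl
    "Mon": (5.0, 2.0),      # %
    "N": (35.0, 8.0),       # %
}

#: Default trait loadings: (age_days, trait) -> (driver parameter, target r).
#: Signs follow the associations reported for weaned piglets: at weaning
#: (28 d) red-cell traits fall with perturbation depth while MCHC rises; a
#: week later (34 d) Hgb/MCH/Plt track the growth-decay parameter D and
#: monocytes/eosinophils track the perturbation.
DEFAULT_LINKAGE: Dict[Tuple[int, str], Tuple[str, float]] = {
    (28, "Hct"): ("C", -0.24),
    (28, "Hgb"): ("C", -0.21),
    (28, "MCV"): ("C", -0.23),
    (28, "MCHC"): ("C", 0.32),
    (28, "Ery"): ("C", -0.20),
    (34, "Hgb"): ("D", -0.23),
    (34, "MCH"): ("D", -0.22),
    (34, "Plt"): ("D", 0.22),
    (34, "Mon"): ("C", -0.30),
    (34, "Eos"): ("C", 0.20),
}

#: Traits measured in percent are truncated at zero after noise.
_PERCENT_TRAITS = {"Bas", "Eos", "Hct", "Lym", "Mon", "N"}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_animals: int = 325
    seed: int = 0
    weaning_age_days: int = 28
    age_cap_days: int = 100
    # weaning weight, kg
    w0_mean: float = 8.91
    w0_sd: float = 0.49
    # growth-law parameter distributions
    mu0_median: float = 0.05     # 1/d, lognormal median
    mu0_sigma_log: float = 0.10
    d_median: float = 0.02       # 1/d, lognormal median
    d_sigma_log: float = 0.10
    c_max: float = 0.12          # 1/d, uniform upper bound
    c_zero_fraction: float = 0.0  # optional point mass at C = 0
    ts_mean: float = 9.0         # d
    ts_sd: float = 3.0
    ts_bounds: Tuple[float, float] = (2.0, 30.0)
    # measurement noise
    noise_cv: float = 0.015
    # faecal-score linkage: P(score 2 on day d) =
    #   logistic(intercept + slope_c * C - recovery_decay * max(0, d - ts))
    faecal_days: Tuple[int, ...] = FAECAL_PANEL_DAYS
    faecal_intercept: float = -2.2
    faecal_slope_c: float = 25.0
    faecal_recovery_decay: float = 0.3
    soft_faeces_prob: float = 0.2  # P(score 1 | not diarrhoea)
    # haemogram linkage
    haemogram_ages: Tuple[int, ...] = (28, 34)
    baselines: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    linkage: Dict[Tuple[int, str], Tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_LINKAGE)
    )

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (0.0 <= self.c_zero_fraction <= 1.0):
            raise ValueError("c_zero_fraction must be in [0, 1]")
        for name in ("w0_mean", "w0_sd", "mu0_median", "d_median", "ts_mean",
                     "ts_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weaning_age_days >= 50:
            raise ValueError("weaning must occur before 50 days of age")


@dataclass(frozen=True)
class SyntheticAnimal:
    """One simulated animal with its ground truth and observed records."""

    animal_id: str
    true_params: PerturbedParams
    trajectory: WeightTrajectory
    faecal: FaecalScoreSeries
    haemograms: Dict[int, Dict[str, float]]  # age_days -> trait -> value


@dataclass(frozen=True)
class Cohort:
    """A generated cohort plus its ground-truth parameter table."""

    animals: List[SyntheticAnimal]
    truth: pd.DataFrame
    config: CohortConfig

    def weights_frame(self) -> pd.DataFrame:
        rows = [
            {"animal_id": a.animal_id, "time_days": t, "weight_kg": w}
            for a in self.animals
            for t, w in zip(a.trajectory.times, a.trajectory.weights)
        ]
        return pd.DataFrame(rows)

    def faecal_frame(self) -> pd.DataFrame:
        rows = [
            {"animal_id": a.animal_id, "day": int(d), "score": int(s)}
            for a in self.animals
            for d, s in zip(a.faecal.days, a.faecal.scores)
        ]
        return pd.DataFrame(rows)

    def haemogram_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.animals:
            for age, traits in sorted(a.haemograms.items()):
                row = {"animal_id": a.animal_id, "age_days": age}
                row.update(traits)
                rows.append(row)
        return pd.DataFrame(rows)

    def write_csvs(self, out_dir) -> Dict[str, str]:
        """Write weights/faecal/haemogram/truth CSVs; returns the paths."""
        from pathlib import Path

        from .io import write_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("weights", self.weights_frame()),
            ("faecal_scores", self.faecal_frame()),
            ("haemograms", self.haemogram_frame()),
            ("truth", self.truth),
        ]:
            path = out / f"{name}.csv"
            write_csv(df, path)
            paths[name] = str(path)
        return paths


def build_schedule(cfg: CohortConfig = CohortConfig()) -> TimeGrid:
    """Post-weaning weighing grid, days since weaning.

    Day 0 (the weaning weighing), then twice-weekly (alternating 3- and
    4-day gaps) until 50 days of age, then weekly until the age cap.
    """
    times = [0]
    step = 3
    t = 0
    while cfg.weaning_age_days + t + step <= 50:
        t += step
        times.append(t)
        step = 4 if step == 3 else 3
    while cfg.weaning_age_days + t + 7 <= cfg.age_cap_days:
        t += 7
        times.append(t)
    return TimeGrid(np.asarray(times, dtype=float))


def sample_animal_params(
    cfg: CohortConfig, rng: np.random.Generator
) -> PerturbedParams:
    """Draw one animal's true growth parameters from the cohort priors."""
    w0 = max(float(rng.normal(cfg.w0_mean, cfg.w0_sd)), 0.5)
    mu0 = float(cfg.mu0_median * math.exp(rng.normal(0.0, cfg.mu0_sigma_log)))
    d = float(cfg.d_median * math.exp(rng.normal(0.0, cfg.d_sigma_log)))
    if cfg.c_zero_fraction and rng.random() < cfg.c_zero_fraction:
        c = 0.0
    else:
        c = float(rng.uniform(0.0, cfg.c_max))
    lo, hi = cfg.ts_bounds
    ts = float(rng.normal(cfg.ts_mean, cfg.ts_sd))
    while not (lo < ts < hi):  # truncation by rejection
        ts = float(rng.normal(cfg.ts_mean, cfg.ts_sd))
    return PerturbedParams(W0=w0, mu0=mu0, D=d, C=c, ts=ts)


def simulate_trajectory(
    p: PerturbedParams,
    grid: TimeGrid,
    noise_cv: float,
    rng: np.random.Generator,
    animal_id: str = "sim",
) -> WeightTrajectory:
    """Observed weights: truth times multiplicative lognormal noise.

    ``W_obs(t) = W_true(t) * exp(eps_t)`` with eps_t iid Normal(0, sigma),
    sigma = sqrt(ln(1 + CV^2)).  CV = 0 returns the exact curve (including
    at t = 0, so the observed weaning weight carries the same noise as any
    other weighing).
    """
    truth = perturbed_weight(p, grid.times)
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv**2))
        truth = truth * np.exp(rng.normal(0.0, sigma, size=truth.shape))
    return WeightTrajectory(animal_id, grid.times.copy(), truth)


def simulate_faecal_scores(
    p: PerturbedParams, cfg: CohortConfig, rng: np.random.Generator,
    animal_id: str = "sim",
) -> FaecalScoreSeries:
    """Panel-day faecal scores linked to the perturbation.

    On day d the diarrhoea probability is
    ``logistic(a + b C - c max(0, d - ts))``: deeper perturbations raise the
    risk, recovery lowers it.  Conditional on no diarrhoea, soft faeces
    (score 1) occur with a fixed probability.
    """
    days = np.asarray(cfg.faecal_days, dtype=int)
    lin = (cfg.faecal_intercept + cfg.faecal_slope_c * p.C
           - cfg.faecal_recovery_decay * np.maximum(0.0, days - p.ts))
    p2 = expit(lin)
    u = rng.random(days.size)
    scores = np.where(u < p2, 2, np.where(rng.random(days.size)
                                          < cfg.soft_faeces_prob, 1, 0))
    return FaecalScoreSeries(animal_id, days, scores)


def _standardised_driver(name: str, p: PerturbedParams, cfg: CohortConfig) -> float:
    """z-score of a growth parameter under its cohort prior."""
    if name == "C":
        return (p.C - cfg.c_max / 2.0) / (cfg.c_max / math.sqrt(12.0))
    if name == "ts":
        return (p.ts - cfg.ts_mean) / cfg.ts_sd
    if name == "mu0":
        return math.log(p.mu0 / cfg.mu0_median) / cfg.mu0_sigma_log
    if name == "D":
        return math.log(p.D / cfg.d_median) / cfg.d_sigma_log
    raise ValueError(f"unknown linkage driver {name!r}")


def simulate_haemogram(
    p: PerturbedParams, cfg: CohortConfig, rng: np.random.Generator,
    age_days: int,
) -> Dict[str, float]:
    """One haemogram (13 traits + derived N/Lym) at 28 or 34 days of age.

    Each linked trait is ``mean + sd * (r * z_driver + sqrt(1 - r^2) * eps)``
    with eps ~ N(0,1), which yields a population correlation of about ``r``
    with the standardised driver parameter; unlinked traits are pure noise.
    Percentage traits are truncated at zero.
    """
    if age_days not in cfg.haemogram_ages:
        raise ValueError(f"age_days must be one of {cfg.haemogram_ages}")
    out: Dict[str, float] = {}
    for trait in HAEMOGRAM_TRAITS:
        mean, sd = cfg.baselines[trait]
        driver_r = cfg.linkage.get((age_days, trait))
        eps = float(rng.normal())
        if driver_r is None:
            val = mean + sd * eps
        else:
            driver, r = driver_r
            z = _standardised_driver(driver, p, cfg)
            val = mean + sd * (r * z + math.sqrt(1.0 - r * r) * eps)
        if trait in _PERCENT_TRAITS:
            val = max(val, 0.0)
        out[trait] = val
    out["N_Lym"] = derive_n_lym(out["N"], out["Lym"])
    return out


def generate_cohort(cfg: CohortConfig = CohortConfig()) -> Cohort:
    """Generate a full cohort with per-animal reproducible substreams."""
    grid = build_schedule(cfg)
    n_digits = max(3, len(str(cfg.n_animals)))
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_animals)
    animals = []
    truth_rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        animal_id = f"A{i + 1:0{n_digits}d}"
        p = sample_animal_params(cfg, rng)
        traj = simulate_trajectory(p, grid, cfg.noise_cv, rng, animal_id)
        faecal = simulate_faecal_scores(p, cfg, rng, animal_id)
        haemo = {
            age: simulate_haemogram(p, cfg, rng, age)
            for age in cfg.haemogram_ages
        }
        animals.append(SyntheticAnimal(animal_id, p, traj, faecal, haemo))
        truth_rows.append(
            {
                "animal_id": animal_id,
                "W0": p.W0,
                "mu0": p.mu0,
                "D": p.D,
                "C": p.C,
                "ts": p.ts,
            }
        )
    return Cohort(animals=animals, truth=pd.DataFrame(truth_rows), config=cfg)
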