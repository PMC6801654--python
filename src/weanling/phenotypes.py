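"""Faecal-score aggregation, haemogram derivations and correlation screening.

Faecal consistency is scored 0 (normal), 1 (soft, without diarrhoea) or
2 (evident diarrhoea) on a fixed panel of post-weaning days.  Per animal the
series is reduced to three aggregates:

* ``FS_sum``  - diarrhoea records divided by the number of observations,
* ``FS_gr``   - group level 0 (no diarrhoea), 1 (one record), 2 (two or more),
* ``FS_p_a``  - presence/absence of any diarrhoea record.

A "diarrhoea record" is a score of 2 by default (the scale calls score 1
explicitly "without diarrhoea"); the threshold is configurable.

Haemograms carry 13 blood traits plus the derived neutrophil/lymphocyte
ratio (N/Lym, a stress indicator).  Correlations between fitted growth
parameters and phenotype traits are screened with Pearson and Spearman
coefficients (two-sided t-approximation p-values, pairwise deletion of
missing values); pairs with p below alpha are flagged significant.  No
multiple-testing correction is applied in the screen itself, matching the
raw p < 0.05 convention; a Benjamini-Hochberg q-value column is emitted
alongside as a clearly labelled extension.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HAEMOGRAM_TRAITS",
    "FAECAL_PANEL_DAYS",
    "FaecalScoreSeries",
    "FaecalAggregates",
    "CorrelationResult",
    "aggregate_faecal_scores",
    "derive_n_lym",
    "normalize_trait",
    "correlate",
    "correlation_report",
]

#: The 13 measured haemogram traits (percent or concentration units) in the
#: order they appear in input tables.  N_Lym is derived, not measured.
HAEMOGRAM_TRAITS = (
    "Bas", "Plt", "Eos", "Ery", "Hct", "Hgb", "Leu",
    "Lym", "MCHC", "MCH", "MCV", "Mon", "N",
)

#: Faecal observation panel, days since weaning.
FAECAL_PANEL_DAYS = (0, 2, 6, 8, 12, 15, 20, 27, 34)

VALID_SCORES = frozenset({0, 1, 2})


@dataclass(frozen=True)
class FaecalScoreSeries:
    """One animal's faecal scores on its observation days."""

    animal_id: str
    days: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        scores = np.asarray(self.scores, dtype=int)
        if days.shape != scores.shape or days.ndim != 1 or days.size == 0:
            raise ValueError("days and scores must be equal-length 1-D arrays")
        if np.any(days < 0):
            raise ValueError("observation days must be non-negative")
        if np.unique(days).size != days.size:
            raise ValueError("observation days must be unique per animal")
        bad = [i for i, s in enumerate(scores) if int(s) not in VALID_SCORES]
        if bad:
            i = bad[0]
            raise ValueError(
                f"{self.animal_id}: invalid faecal score {scores[i]} "
                f"on day {days[i]} (allowed: 0, 1, 2)"
            )
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "scores", scores)


@dataclass(frozen=True)
class FaecalAggregates:
    """FS_sum (fraction of diarrhoea records), FS_gr (0/1/2), FS_p_a (0/1)."""

    animal_id: str
    FS_sum: float
    FS_gr: int
    FS_p_a: int
    n_obs: int


def aggregate_faecal_scores(
    series: FaecalScoreSeries, diarrhoea_scores: Sequence[int] = (2,)
) -> FaecalAggregates:
    """Reduce a faecal-score series to its three per-animal aggregates."""
    is_d = np.isin(series.scores, list(diarrhoea_scores))
    n_d = int(is_d.sum())
    n = series.scores.size
    fs_gr = 0 if n_d == 0 else (1 if n_d == 1 else 2)
    return FaecalAggregates(
        animal_id=series.animal_id,
        FS_sum=n_d / n,
        FS_gr=fs_gr,
        FS_p_a=int(n_d > 0),
        n_obs=n,
    )


def derive_n_lym(n_pct: float, lym_pct: float) -> float:
    """Neutrophil/lymphocyte ratio, a haematological stress indicator.

    Returns NaN (undefined) when the lymphocyte percentage is zero.
    """
    if lym_pct < 0 or n_pct < 0:
        raise ValueError("percentages must be non-negative")
    if lym_pct == 0:
        return math.nan
    return n_pct / lym_pct


def normalize_trait(values, base=None) -> np.ndarray:
    """Optional log2/log10 normalisation of a trait vector.

    ``base`` is 2, 10 or None (identity).  Log bases require strictly
    positive values; offenders are listed in the error.
    """
    values = np.asarray(values, dtype=float)
    if base is None or base == "none":
        return values.copy()
    if base not in (2, 10):
        raise ValueError(f"base must be 2, 10 or None, got {base!r}")
    bad = np.flatnonzero(~(values > 0))
    if bad.size:
        raise ValueError(
            f"log{base} normalisation requires positive values; "
            f"non-positive at indices {bad.tolist()}"
        )
    return np.log2(values) if base == 2 else np.log10(values)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    defined: bool = True


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with two-sided t-approximation p.

    Missing values are removed pairwise; at least 4 complete pairs are
    required.  Zero variance in either vector yields an undefined (NaN)
    result with ``defined=False`` rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, n, defined=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "pearson":
            res = stats.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        elif method == "spearman":
            r, p = stats.spearmanr(x, y)
            r, p = float(r), float(p)
        else:
            raise ValueError(f"unknown method {method!r}")
    if not math.isfinite(r):
        return CorrelationResult(math.nan, math.nan, n, defined=False)
    return CorrelationResult(r, p, n)


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (extension column, NaN-safe)."""
    q = np.full(pvals.shape, math.nan)
    ok = np.isfinite(pvals)
    p = pvals[ok]
    m = p.size
    if m == 0:
        return q
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def correlation_report(
    params_table: pd.DataFrame,
    phenotype_table: pd.DataFrame,
    alpha: float = 0.05,
    methods: Sequence[str] = ("pearson", "spearman"),
    min_n: int = 4,
    key: str = "animal_id",
) -> pd.DataFrame:
    """Screen every model-parameter x phenotype-trait pair.

    Both tables must share the ``animal_id`` key; rows are matched by an
    inner join, so row order is irrelevant.  Every pair is retained in the
    output with its r, p, n and a ``significant`` flag (p < alpha); a
    ``q_bh`` false-discovery-rate column is added as an extension and plays
    no role in the flag.
    """
    if key not in params_table.columns or key not in phenotype_table.columns:
        raise ValueError(f"both tables must carry an {key!r} column")
    merged = params_table.merge(phenotype_table, on=key, how="inner",
                                suffixes=("_param", "_trait"))
    if merged.empty:
        raise ValueError("no overlapping animal_id keys between tables")
    merged = merged.sort_values(key, kind="mergesort")

    def numeric_cols(df):
        return [c for c in df.columns
                if c != key and pd.api.types.is_numeric_dtype(df[c])]

    param_cols = numeric_cols(params_table)
    trait_cols = numeric_cols(phenotype_table)

    def col(df_name, c):
        return merged[c] if c in merged.columns else merged[c + df_name]

    rows = []
    for method in methods:
        for pcol in param_cols:
            xv = col("_param", pcol).to_numpy(dtype=float)
            for tcol in trait_cols:
                yv = col("_trait", tcol).to_numpy(dtype=float)
                n_complete = int(np.sum(np.isfinite(xv) & np.isfinite(yv)))
                if n_complete < min_n:
                    res = CorrelationResult(math.nan, math.nan, n_complete,
                                            defined=False)
                else:
                    res = correlate(xv, yv, method=method)
                rows.append(
                    {
                        "parameter": pcol,
                        "trait": tcol,
                        "method": method,
                        "r": res.r,
                        "p": res.p,
                        "n": res.n,
                        "significant": bool(res.defined and res.p < alpha),
                    }
                )
    report = pd.DataFrame(rows)
    report["q_bh"] = math.nan
    for method in methods:
        sel = report["method"] == method
        report.loc[sel, "q_bh"] = _bh_qvalues(report.loc[sel, "p"].to_numpy())
    return report
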