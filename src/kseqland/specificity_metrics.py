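"""Substrate-specificity metrics: promiscuity index, aromatic preference,
pairwise substrate regressions, and activity-specificity correlations.

The promiscuity index of a sequence is the normalized Shannon entropy of
its catalytic-enhancement proportions across the N assayed substrates:

    I_s = -(1 / log N) * sum_i p_i log p_i,   p_i = r_i / sum_j r_j

so I_s = 1 for a sequence equally active on every substrate and I_s = 0
for one active on a single substrate.  Aromatic preference is the fraction
of summed enhancement on the aromatic substrates (BWO, BFO).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

AROMATIC_SUBSTRATES = ("BWO", "BFO")


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. all-zero enhancement vector)."""


def promiscuity_index(r: Sequence[float] | np.ndarray) -> float:
    """Normalized entropy of an enhancement vector; in [0, 1].

    Zero entries contribute nothing (0 log 0 := 0).  The logarithm base
    cancels through the 1/log(N) normalization.
    """
    r = np.asarray(r, dtype=float)
    if r.size < 2:
        raise UndefinedMetricError("promiscuity needs at least two substrates")
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise UndefinedMetricError("enhancements must be finite and non-negative")
    total = r.sum()
    if total <= 0:
        raise UndefinedMetricError("total enhancement is zero")
    p = r[r > 0] / total
    return float(-(p @ np.log(p)) / np.log(r.size)) + 0.0  # avoid -0.0


def aromatic_preference(
    r: pd.Series | dict[str, float],
    aromatic: Iterable[str] = AROMATIC_SUBSTRATES,
) -> float:
    """Fraction of summed enhancement on the aromatic substrates; in [0, 1]."""
    r = pd.Series(r, dtype=float)
    total = r.sum()
    if total <= 0:
        raise UndefinedMetricError("total enhancement is zero")
    return float(r.reindex(list(aromatic), fill_value=0.0).sum() / total)


def specificity_table(
    enhancement: pd.DataFrame,
    aromatic: Iterable[str] = AROMATIC_SUBSTRATES,
) -> pd.DataFrame:
    """Per-sequence specificity summary of an enhancement matrix.

    Columns: promiscuity_index, aromatic_preference, total_activity (sum of
    r over substrates), n_substrates.  Rows whose metrics are undefined
    (all-zero or non-finite) carry NaN.
    """
    r = enhancement.to_numpy(dtype=float)
    n = r.shape[1]
    total = r.sum(axis=1)
    valid = np.isfinite(r).all(axis=1) & (r >= 0).all(axis=1) & (total > 0)

    safe_total = np.where(total > 0, total, 1.0)
    p = np.where(np.isfinite(r), r, 0.0) / safe_total[:, None]
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    I = np.where(valid, -plogp.sum(axis=1) / np.log(n), np.nan)
    arom_cols = [c for c in enhancement.columns if c in set(aromatic)]
    arom_sum = np.nan_to_num(r)[:, [enhancement.columns.get_loc(c) for c in arom_cols]].sum(axis=1)
    arom = np.where(valid, arom_sum / safe_total, np.nan)
    return pd.DataFrame(
        {
            "promiscuity_index": I,
            "aromatic_preference": arom,
            "total_activity": np.where(valid, total, np.nan),
            "n_substrates": n,
        },
        index=enhancement.index,
    )


@dataclass
class PairwiseComparison:
    """OLS relation between enhancements on two substrates."""

    substrate_x: str
    substrate_y: str
    slope: float
    intercept: float
    r_squared: float
    slope_through_origin: float
    n: int


def pairwise_regression(
    rx: pd.Series | np.ndarray,
    ry: pd.Series | np.ndarray,
    substrate_x: str = "x",
    substrate_y: str = "y",
) -> PairwiseComparison:
    """Linear regression of substrate-y enhancement on substrate-x.

    A slope above 1 indicates a preference for the y substrate.  The default
    fit includes an intercept; the through-origin slope is reported
    alongside since the intercept treatment of such comparisons is a free
    choice.
    """
    x = np.asarray(rx, dtype=float)
    y = np.asarray(ry, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: zero variance in x")
    res = stats.linregress(x, y)
    slope0 = float((x @ y) / (x @ x))
    return PairwiseComparison(
        substrate_x, substrate_y,
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), slope_through_origin=slope0, n=int(x.size),
    )


def pairwise_matrices(
    enhancement: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """R-squared and slope matrices for all ordered substrate pairs.

    Entry (row=y, col=x) holds the fit of substrate y on substrate x, so
    slopes above 1 mark a preference for the row substrate.
    """
    subs = list(enhancement.columns)
    r2 = pd.DataFrame(np.nan, index=subs, columns=subs)
    slope = pd.DataFrame(np.nan, index=subs, columns=subs)
    for sx in subs:
        for sy in subs:
            cmp_ = pairwise_regression(enhancement[sx], enhancement[sy], sx, sy)
            r2.loc[sy, sx] = cmp_.r_squared
            slope.loc[sy, sx] = cmp_.slope
    return r2, slope


def activity_specificity_correlation(
    spec_table: pd.DataFrame,
    family: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson and Spearman correlations of total activity with specificity.

    For each family (or the whole table if ``family`` is None) correlates
    total activity against promiscuity index and against aromatic
    preference, with two-sided p-values.  Constant inputs yield NaN rows.
    """
    df = spec_table.dropna(subset=["promiscuity_index", "total_activity"])
    groups = (
        df.groupby(family.reindex(df.index)) if family is not None else [("all", df)]
    )
    rows = []
    for name, grp in groups:
        row: dict = {"family": name, "n": len(grp)}
        for metric, tag in (
            ("promiscuity_index", "promiscuity"),
            ("aromatic_preference", "aromatic"),
        ):
            x = grp["total_activity"].to_numpy()
            y = grp[metric].to_numpy()
            if len(grp) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                row.update({f"pearson_{tag}": np.nan, f"pearson_{tag}_p": np.nan,
                            f"spearman_{tag}": np.nan, f"spearman_{tag}_p": np.nan})
                continue
            pr = stats.pearsonr(x, y)
            sp = stats.spearmanr(x, y)
            row.update({
                f"pearson_{tag}": float(pr.statistic), f"pearson_{tag}_p": float(pr.pvalue),
                f"spearman_{tag}": float(sp.statistic), f"spearman_{tag}_p": float(sp.pvalue),
            })
        rows.append(row)
    return pd.DataFrame(rows)
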