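"""Developmental statistics: one-way ANOVA, linear-trend posttest,
Bonferroni-corrected pairwise comparisons and per-group correlation matrices.

The analysis stage mirrors a standard cross-sectional developmental design:
age group (e.g. P20/P40/P90/P250) is the fixed factor; the omnibus test is a
one-way ANOVA; a posttest for linear trend uses a contrast on the ordered
group means with the pooled within-group mean square (so a small regular
change with age can be detected even when the omnibus test is not
significant); pairwise group differences use pooled-variance t tests with
Bonferroni adjustment (adjusted p = min(1, raw p × number of pairs));
correlations are Pearson, reported as (r, R², p).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "TrendAnova",
    "CorrelationResult",
    "anova_with_trend",
    "bonferroni_posthoc",
    "correlation_matrix",
]


@dataclass(frozen=True)
class TrendAnova:
    anova_f: float
    anova_p: float
    trend_t: float
    trend_p: float
    slope: float
    df_between: int
    df_within: int


def _grouped(
    table: pd.DataFrame, quantity: str, group_col: str, order: Sequence[str] | None
) -> tuple[list[str], list[np.ndarray]]:
    if quantity not in table.columns:
        raise ParameterError(f"quantity '{quantity}' not in table")
    if group_col not in table.columns:
        raise ParameterError(f"group column '{group_col}' not in table")
    labels = list(order) if order is not None else list(pd.unique(table[group_col]))
    groups = []
    too_small = []
    for g in labels:
        v = table.loc[table[group_col] == g, quantity].dropna().to_numpy(float)
        if len(v) < 2:
            too_small.append(g)
        groups.append(v)
    if len(labels) < 2:
        raise ParameterError("ANOVA requires at least 2 groups")
    if too_small:
        raise ParameterError(f"groups with fewer than 2 observations: {too_small}")
    return labels, groups


def anova_with_trend(
    table: pd.DataFrame,
    quantity: str,
    group_col: str = "group",
    order: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
    age_col: str | None = "age_days",
) -> TrendAnova:
    """One-way fixed-factor ANOVA with a posttest for linear trend.

    ``scores`` are the trend-contrast values per ordered group; by default
    equally spaced ordinal scores are used (actual age spacing can be passed
    instead).  The trend statistic is L = Σ cᵢ·ȳᵢ with centred contrast
    coefficients cᵢ, tested against the pooled within-group mean square.
    The slope is an ordinary regression of the observations on age (from
    ``age_col`` when present, otherwise on the ordinal scores).
    """
    labels, groups = _grouped(table, quantity, group_col, order)
    k = len(groups)
    n_i = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    # omnibus one-way ANOVA
    f_stat, p_omnibus = sps.f_oneway(*groups)
    df_between = k - 1
    df_within = int(n_i.sum()) - k
    mse = sum(((g - m) ** 2).sum() for g, m in zip(groups, means)) / df_within
    # linear-trend contrast
    raw_scores = np.asarray(scores if scores is not None else np.arange(k), dtype=float)
    if len(raw_scores) != k:
        raise ParameterError("scores length must equal the number of groups")
    c = raw_scores - raw_scores.mean()
    L = float(c @ means)
    se = np.sqrt(mse * np.sum(c**2 / n_i))
    t_stat = L / se if se > 0 else 0.0
    trend_p = 2.0 * sps.t.sf(abs(t_stat), df_within) if se > 0 else 1.0
    # regression slope along age
    if age_col is not None and age_col in table.columns:
        x = table[age_col].to_numpy(float)
        y = table[quantity].to_numpy(float)
    else:
        score_of = dict(zip(labels, raw_scores))
        x = table[group_col].map(score_of).to_numpy(float)
        y = table[quantity].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    slope = float(sps.linregress(x[ok], y[ok]).slope) if ok.sum() >= 2 else np.nan
    if np.allclose(mse, 0) and np.allclose(means, means[0]):
        f_stat, t_stat, slope = 0.0, 0.0, 0.0
        p_omnibus, trend_p = 1.0, 1.0
    return TrendAnova(float(f_stat), float(p_omnibus), float(t_stat), float(trend_p),
                      slope, df_between, df_within)


def bonferroni_posthoc(
    table: pd.DataFrame,
    quantity: str,
    group_col: str = "group",
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """All pairwise comparisons with Bonferroni adjustment.

    Pairwise t statistics use the pooled within-group variance from *all*
    groups (the classical post-ANOVA form); adjusted p = min(1, raw p × m)
    where m is the number of pairs.
    """
    labels, groups = _grouped(table, quantity, group_col, order)
    n_i = {g: len(v) for g, v in zip(labels, groups)}
    means = {g: v.mean() for g, v in zip(labels, groups)}
    df_within = sum(n_i.values()) - len(labels)
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups) / df_within
    pairs = list(combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(mse * (1.0 / n_i[a] + 1.0 / n_i[b]))
        t = (means[a] - means[b]) / se if se > 0 else 0.0
        raw = 2.0 * sps.t.sf(abs(t), df_within) if se > 0 else 1.0
        rows.append({
            "group_a": a, "group_b": b, "mean_diff": means[a] - means[b],
            "t": float(t), "raw_p": float(raw),
            "adj_p": float(min(1.0, raw * m)), "n_pairs": m,
        })
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations: r, R², p and pairwise-complete n."""

    r: pd.DataFrame
    r2: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def correlation_matrix(
    table: pd.DataFrame,
    quantities: Sequence[str],
    group: str | None = None,
    group_col: str = "group",
    min_n: int = 3,
) -> CorrelationResult:
    """Pairwise linear correlations among ``quantities`` (one group or all).

    Missing pairs are dropped pairwise (counts reported in ``n``); a constant
    column yields an undefined (NaN) cell rather than zero.
    """
    data = table if group is None else table[table[group_col] == group]
    missing = [q for q in quantities if q not in data.columns]
    if missing:
        raise ParameterError(f"quantities not in table: {missing}")
    k = len(quantities)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i, qa in enumerate(quantities):
        for j, qb in enumerate(quantities):
            x = data[qa].to_numpy(float)
            y = data[qb].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n[i, j] = int(ok.sum())
            if n[i, j] < min_n:
                continue
            if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue  # constant column: undefined, not zero
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            rr, pp = sps.pearsonr(x[ok], y[ok])
            r[i, j], p[i, j] = rr, pp
    idx = list(quantities)
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        r2=pd.DataFrame(r**2, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )
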