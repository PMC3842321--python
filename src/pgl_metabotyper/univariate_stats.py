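"""Nonparametric univariate layer: Mann-Whitney U tests and Spearman R.

The U statistic is computed from rank sums with average ranks for ties.
Exact two-sided p-values are obtained from the standard count recursion for
the tie-free null distribution; tied pooled samples fall back to full
permutation enumeration for small totals, otherwise to the normal
approximation with tie and continuity corrections.  The two-sided p is
``min(1, 2 x one-sided tail including the observed U)``.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: largest tie-free total for which the exact recursion is used in auto mode
EXACT_LIMIT = 25
#: largest total for which full permutation enumeration is used with ties
PERMUTATION_LIMIT = 14


@dataclasses.dataclass(frozen=True)
class MWUResult:
    u: float  # min(U_x, U_y)
    u_x: float
    p: float
    method: str


@dataclasses.dataclass
class GroupComparison:
    metabolite: str
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    range_a: tuple[float, float]
    range_b: tuple[float, float]
    u: float
    p_two_sided: float


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    feature_a: str
    feature_b: str
    spearman_r: float
    n: int


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    m, n = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    u_x = float(ranks[:m].sum() - m * (m + 1) / 2.0)
    return u_x, m * n - u_x


def _exact_counts(m: int, n: int) -> np.ndarray:
    """Null counts of U over all C(m+n, m) tie-free labelings.

    Recursion: f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u).
    """
    table: list[list[np.ndarray | None]] = [[None] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        for j in range(n + 1):
            arr = np.zeros(i * j + 1)
            if i == 0 or j == 0:
                arr[0] = 1.0
            else:
                a = table[i - 1][j]  # shift by j
                b = table[i][j - 1]
                arr[j : j + a.size] += a
                arr[: b.size] += b
            table[i][j] = arr
    return table[m][n]


def _p_exact(u_x: float, m: int, n: int) -> float:
    counts = _exact_counts(m, n)
    total = counts.sum()
    u_int = int(round(u_x))
    lower = counts[: u_int + 1].sum() / total
    upper = counts[u_int:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def _p_permutation(x: np.ndarray, y: np.ndarray, u_x_obs: float) -> float:
    m = x.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    offset = m * (m + 1) / 2.0
    u_all = np.array(
        [ranks[list(sel)].sum() - offset for sel in combinations(range(pooled.size), m)]
    )
    eps = 1e-9
    lower = float(np.mean(u_all <= u_x_obs + eps))
    upper = float(np.mean(u_all >= u_x_obs - eps))
    return min(1.0, 2.0 * min(lower, upper))


def _p_asymptotic(u_x: float, x: np.ndarray, y: np.ndarray) -> float:
    m, n = x.size, y.size
    total = m + n
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (total * (total - 1))
    var = m * n / 12.0 * ((total + 1) - tie_term)
    if var <= 0:
        return 1.0
    mu = m * n / 2.0
    z = (abs(u_x - mu) - 0.5) / sqrt(var)  # continuity correction
    z = max(z, 0.0)
    return min(1.0, erfc(z / sqrt(2.0)))


def mann_whitney(x, y, mode: str = "auto") -> MWUResult:
    """Two-sided Mann-Whitney U test.

    Modes: ``exact`` (recursion without ties; permutation enumeration with
    ties when m+n <= 14, else asymptotic), ``asymptotic`` (normal
    approximation with tie and continuity corrections), ``auto`` (exact when
    m+n <= 25 and tie-free, else the applicable fallback).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = x.size, y.size
    u_x, u_y = _rank_sum_u(x, y)
    u_min = min(u_x, u_y)
    has_ties = np.unique(np.concatenate([x, y])).size < m + n
    if mode not in ("exact", "asymptotic", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and not has_ties and m + n <= EXACT_LIMIT)
    if use_exact:
        if not has_ties:
            return MWUResult(u_min, u_x, _p_exact(u_x, m, n), "exact")
        if m + n <= PERMUTATION_LIMIT:
            return MWUResult(u_min, u_x, _p_permutation(x, y, u_x), "permutation")
        # exact requested but infeasible with ties -> asymptotic fallback
    return MWUResult(u_min, u_x, _p_asymptotic(u_x, x, y), "asymptotic")


def spearman(x, y) -> float | None:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Returns ``None`` (not available) when either vector is constant.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("spearman needs n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return None
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / sqrt((rx @ rx) * (ry @ ry)))


def group_table(
    quant: pd.DataFrame,
    metabolites: tuple[str, ...] = ("succinate", "glutathione", "glutamate", "atp_adp_amp"),
    group_col: str = "group",
    mode: str = "auto",
) -> list[GroupComparison]:
    """Pairwise group comparisons per metabolite (medians, ranges, MWU p).

    Empty groups are skipped with a warning; a single-group table carries no
    comparisons (use :func:`group_summary` for the medians).
    """
    import warnings

    groups = [g for g in quant[group_col].dropna().unique()]
    groups = sorted(map(str, groups))
    present = []
    for g in groups:
        if (quant[group_col] == g).sum() == 0:
            warnings.warn(f"group {g!r} has no samples; skipped", stacklevel=2)
            continue
        present.append(g)
    if len(present) < 1:
        raise ValueError("no non-empty groups present")
    comparisons: list[GroupComparison] = []
    for met in metabolites:
        for ga, gb in combinations(present, 2):
            a = quant.loc[quant[group_col] == ga, met].to_numpy(dtype=float)
            b = quant.loc[quant[group_col] == gb, met].to_numpy(dtype=float)
            res = mann_whitney(a, b, mode=mode)
            comparisons.append(
                GroupComparison(
                    metabolite=met,
                    group_a=ga,
                    group_b=gb,
                    median_a=float(np.median(a)),
                    median_b=float(np.median(b)),
                    range_a=(float(a.min()), float(a.max())),
                    range_b=(float(b.min()), float(b.max())),
                    u=res.u,
                    p_two_sided=res.p,
                )
            )
    return comparisons


def group_summary(
    quant: pd.DataFrame,
    metabolites: tuple[str, ...] = ("succinate", "glutathione", "glutamate", "atp_adp_amp"),
    group_col: str = "group",
) -> pd.DataFrame:
    """Median and range per metabolite per group, one row per metabolite."""
    rows = []
    groups = sorted(map(str, quant[group_col].dropna().unique()))
    for met in metabolites:
        row: dict[str, object] = {"metabolite": met}
        for g in groups:
            vals = quant.loc[quant[group_col] == g, met].to_numpy(dtype=float)
            if vals.size == 0:
                continue
            row[f"{g}_median"] = float(np.median(vals))
            row[f"{g}_min"] = float(vals.min())
            row[f"{g}_max"] = float(vals.max())
        rows.append(row)
    return pd.DataFrame(rows)


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tabular rendering of :func:`group_table` output."""
    return pd.DataFrame(
        [
            {
                "metabolite": c.metabolite,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "median_a": c.median_a,
                "median_b": c.median_b,
                "min_a": c.range_a[0],
                "max_a": c.range_a[1],
                "min_b": c.range_b[0],
                "max_b": c.range_b[1],
                "U": c.u,
                "p_two_sided": c.p_two_sided,
            }
            for c in comparisons
        ]
    )


def correlation_table(
    quant: pd.DataFrame,
    metabolites: tuple[str, ...] = ("succinate", "glutathione", "glutamate", "atp_adp_amp"),
    unsigned: bool = False,
) -> list[CorrelationResult]:
    """Pairwise Spearman correlations among the selected metabolites.

    Signed values are always stored; ``unsigned=True`` renders magnitudes.
    """
    results = []
    for fa, fb in combinations(metabolites, 2):
        a = quant[fa].to_numpy(dtype=float)
        b = quant[fb].to_numpy(dtype=float)
        r = spearman(a, b)
        if r is None:
            continue
        results.append(
            CorrelationResult(fa, fb, abs(r) if unsigned else r, n=int(a.size))
        )
    return results


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature_a": r.feature_a, "feature_b": r.feature_b, "spearman_r": r.spearman_r, "n": r.n}
            for r in results
        ]
    )
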