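"""Balanced factorial ANOVA with a conservative error-df adjustment.

The experiment's local patches are not fully independent: the three patches
of a metacommunity exchange 5% of their volume weekly through dispersal.
Rather than a mixed model, significance of local-scale F ratios is judged
against an F distribution whose error degrees of freedom are divided by 3
(the number of dependent patches per metacommunity).  The adjusted df is
kept continuous — F quantiles accept non-integer df, and flooring would add
unstated conservatism.  An effect is significant when the observed F
exceeds the upper-alpha critical value of F(df_num, df_err / 3).

Only balanced, fully crossed designs are in scope (the experiment is
balanced by construction); unbalanced input is rejected rather than
silently reweighted, which also makes the type-I/III sums-of-squares
distinction moot.  Sums of squares are computed from marginal and cell
means by Möbius (inclusion–exclusion) recursion over factor subsets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "AdjustedTest",
    "balanced_anova",
    "adjusted_df_test",
    "treatment_residuals",
    "pearson_r",
    "CorrelationResult",
]


@dataclass(frozen=True)
class AnovaRow:
    term: str
    df: int
    ss: float
    ms: float
    f: float
    df_err_adj: float
    f_crit: float
    significant: bool


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    error_df: int
    error_ss: float
    error_ms: float
    n_obs: int
    total_ss: float
    alpha: float
    df_adjustment: float

    def __getitem__(self, term: str) -> AnovaRow:
        for row in self.rows:
            if row.term == term:
                return row
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "term": r.term,
                "df": r.df,
                "ss": r.ss,
                "ms": r.ms,
                "F": r.f,
                "df_err_adj": r.df_err_adj,
                "F_crit": r.f_crit,
                "significant": r.significant,
            }
            for r in self.rows
        ]
        records.append(
            {
                "term": "Error",
                "df": self.error_df,
                "ss": self.error_ss,
                "ms": self.error_ms,
                "F": np.nan,
                "df_err_adj": np.nan,
                "F_crit": np.nan,
                "significant": np.nan,
            }
        )
        return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class AdjustedTest:
    df_adj: float
    f_crit: float
    significant: bool


def adjusted_df_test(
    f_value: float,
    df_num: float,
    df_err: float,
    adjustment: float = 3.0,
    alpha: float = 0.05,
) -> AdjustedTest:
    """Significance of an F ratio with error df divided by ``adjustment``.

    Raises ``ValueError`` when the adjusted df drops below 1 (the test is
    then meaningless).
    """
    if not df_err > 0:
        raise ValueError("df_err must be > 0")
    df_adj = df_err / adjustment
    if df_adj < 1:
        raise ValueError(
            f"adjusted error df {df_adj:.3g} < 1: effect is untestable"
        )
    f_crit = float(stats.f.ppf(1.0 - alpha, df_num, df_adj))
    return AdjustedTest(df_adj=df_adj, f_crit=f_crit, significant=f_value > f_crit)


def _check_balanced(data: pd.DataFrame, factors: Sequence[str]) -> int:
    sizes = data.groupby(list(factors), observed=True).size()
    n_cells = 1
    for f in factors:
        n_cells *= data[f].nunique()
    if len(sizes) != n_cells:
        raise ValueError("design is not fully crossed: empty cells present")
    if sizes.nunique() != 1:
        raise ValueError(f"design is unbalanced: cell sizes {sorted(sizes.unique())}")
    return int(sizes.iloc[0])


def balanced_anova(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    df_adjustment: float = 1.0,
    alpha: float = 0.05,
) -> AnovaTable:
    """Fixed-effects ANOVA of a balanced full factorial (1–3 factors).

    All main effects and interactions are fitted.  ``df_adjustment`` > 1
    applies the conservative error-df division when judging significance
    (use 3.0 for local-scale analyses of this design).  Any missing
    responses must be dropped by the caller; the design must stay balanced.
    """
    factors = list(factors)
    if not 1 <= len(factors) <= 3:
        raise ValueError("balanced_anova supports 1 to 3 factors")
    work = data[factors + [response]].copy()
    if work[response].isna().any():
        raise ValueError("response contains missing values")
    n_per_cell = _check_balanced(work, factors)
    y = work[response].to_numpy(dtype=float)
    n_obs = y.size
    grand = y.mean()

    # Per-observation effect arrays by inclusion-exclusion over subsets.
    marginal: dict[frozenset, np.ndarray] = {frozenset(): np.full(n_obs, grand)}
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            key = frozenset(combo)
            marginal[key] = work.groupby(list(combo), observed=True)[
                response
            ].transform("mean").to_numpy()

    effect: dict[frozenset, np.ndarray] = {}
    rows: list[tuple[str, int, float]] = []
    levels = {f: work[f].nunique() for f in factors}
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            key = frozenset(combo)
            e = marginal[key].copy()
            for sub_r in range(r):
                for sub in itertools.combinations(combo, sub_r):
                    sub_key = frozenset(sub)
                    e -= effect[sub_key] if sub_key else marginal[frozenset()]
            # subtract lower-order effects (grand mean handled above)
            effect[key] = e
            df = 1
            for f in combo:
                df *= levels[f] - 1
            rows.append(("*".join(combo), df, float((e**2).sum())))

    cell_mean = marginal[frozenset(factors)]
    error_ss = float(((y - cell_mean) ** 2).sum())
    error_df = n_obs - int(np.prod([levels[f] for f in factors]))
    total_ss = float(((y - grand) ** 2).sum())
    if error_df <= 0:
        raise ValueError(
            "no within-cell replication: error df is 0, F ratios undefined"
        )
    error_ms = error_ss / error_df

    table_rows = []
    for term, df, ss in rows:
        ms = ss / df
        f_val = ms / error_ms
        adj = adjusted_df_test(
            f_val, df, error_df, adjustment=df_adjustment, alpha=alpha
        )
        table_rows.append(
            AnovaRow(
                term=term,
                df=df,
                ss=ss,
                ms=ms,
                f=f_val,
                df_err_adj=adj.df_adj,
                f_crit=adj.f_crit,
                significant=adj.significant,
            )
        )
    return AnovaTable(
        rows=table_rows,
        error_df=error_df,
        error_ss=error_ss,
        error_ms=error_ms,
        n_obs=n_obs,
        total_ss=total_ss,
        alpha=alpha,
        df_adjustment=df_adjustment,
    )


def treatment_residuals(
    data: pd.DataFrame, response: str, factors: Sequence[str]
) -> np.ndarray:
    """Residuals after removing full-factorial treatment-cell means.

    Equivalent to the residuals of the fully saturated factorial model.
    Singleton cells yield residuals identically zero (a warning is issued).
    """
    factors = list(factors)
    n_per_cell = _check_balanced(data[factors + [response]], factors)
    if n_per_cell == 1:
        warnings.warn(
            "singleton treatment cells: residuals are identically zero",
            stacklevel=2,
        )
    cell_mean = data.groupby(factors, observed=True)[response].transform("mean")
    return (data[response] - cell_mean).to_numpy(dtype=float)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with its two-sided t-based p.

    Requires n >= 3 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("pearson_r requires at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r requires non-constant inputs")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))
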