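"""Baseline-characteristics comparisons between cohort groups.

Continuous variables are compared by one-way fixed-effects ANOVA;
categorical variables by Pearson's chi-squared test (no continuity
correction) or, for 2x2 tables with any expected cell count below 5, by a
two-sided Fisher exact test using point-probability ordering (the p-value
sums hypergeometric probabilities of all tables, with the observed margins,
whose probability does not exceed the observed table's).  Missing values
are excluded per variable with the excluded counts reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist, hypergeom

from .errors import InvalidInputError, SchemaError

__all__ = [
    "ContingencyTable2x2",
    "BaselineRow",
    "anova_p",
    "fisher_exact_p",
    "chi_squared_p",
    "baseline_table",
]

EXPECTED_COUNT_RULE = 5.0  # Fisher when any expected 2x2 cell is below this


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = outcome yes/no, columns = groups."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidInputError("contingency counts must be non-negative")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class BaselineRow:
    variable: str
    summaries: dict
    test: str  # "anova" | "chi_squared" | "fisher" | "not_available"
    p_value: float | None
    n_missing: int


def anova_p(groups: Sequence[Sequence[float]]) -> float | None:
    """One-way fixed-effects ANOVA p-value; ``None`` for degenerate variance."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise InvalidInputError("ANOVA needs >= 2 groups with >= 2 values each")
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    if np.ptp(pooled) == 0:
        return None  # zero total variance: F undefined
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = pooled.size - len(arrays)
    if ss_within == 0:
        return 0.0 if ss_between > 0 else None
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    return float(f_dist.sf(f_stat, df_between, df_within))


def fisher_exact_p(table: ContingencyTable2x2) -> float | None:
    """Two-sided Fisher exact p by point-probability ordering.

    Conditions on the observed margins; ``None`` when a margin is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    n = row1 + row2
    if min(row1, row2, col1, col2) == 0:
        return None
    rv = hypergeom(n, row1, col1)  # count in cell (1,1) given margins
    support = np.arange(max(0, col1 - row2), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(1.0, p)


def chi_squared_p(counts) -> float | None:
    """Pearson chi-squared p for an r x c table, no continuity correction.

    ``None`` when any expected count is zero.
    """
    obs = np.asarray(counts, dtype=float)
    if isinstance(counts, ContingencyTable2x2):
        obs = counts.counts
    if obs.ndim != 2 or np.any(obs < 0):
        raise InvalidInputError("need a non-negative 2D count table")
    total = obs.sum()
    if total == 0:
        return None
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.any(expected == 0):
        return None
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if dof == 0:
        return None
    return float(chi2.sf(stat, dof))


def _expected_counts(obs: np.ndarray) -> np.ndarray:
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()


def _categorical_row(name: str, series: pd.Series, group: pd.Series) -> BaselineRow:
    mask = series.notna() & group.notna()
    n_missing = int((~mask).sum())
    sub, grp = series[mask], group[mask]
    crosstab = pd.crosstab(sub, grp)
    summaries = {
        str(g): {str(level): int(v) for level, v in crosstab[g].items()}
        for g in crosstab.columns
    }
    obs = crosstab.to_numpy(dtype=float)
    if obs.size == 0 or obs.sum() == 0 or 0 in obs.shape or 1 in obs.shape:
        return BaselineRow(name, summaries, "not_available", None, n_missing)
    expected = _expected_counts(obs)
    if obs.shape == (2, 2) and (expected < EXPECTED_COUNT_RULE).any():
        p = fisher_exact_p(ContingencyTable2x2(*obs.astype(int).ravel()))
        test = "fisher"
    else:
        p = chi_squared_p(obs)
        test = "chi_squared"
    if p is None:
        test = "not_available"
    return BaselineRow(name, summaries, test, p, n_missing)


def _continuous_row(name: str, series: pd.Series, group: pd.Series) -> BaselineRow:
    mask = series.notna() & group.notna()
    n_missing = int((~mask).sum())
    sub, grp = series[mask].astype(float), group[mask]
    groups, summaries = [], {}
    for g, vals in sub.groupby(grp, observed=True):
        summaries[str(g)] = {
            "n": int(vals.size),
            "mean": float(vals.mean()) if vals.size else None,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else None,
        }
        groups.append(vals.to_numpy())
    if len(groups) < 2 or any(v.size < 2 for v in groups):
        return BaselineRow(name, summaries, "not_available", None, n_missing)
    p = anova_p(groups)
    return BaselineRow(name, summaries, "anova" if p is not None else "not_available",
                       p, n_missing)


def baseline_table(
    manifest: pd.DataFrame,
    group_column: str,
    variables: Sequence[str] | None = None,
) -> list[BaselineRow]:
    """Table-1 style group comparison for every requested manifest column.

    Numeric columns use ANOVA; boolean/object/categorical columns use the
    chi-squared/Fisher rule.  Defaults to all columns except the group
    column and identifier/path columns.
    """
    if group_column not in manifest.columns:
        raise SchemaError(f"group column {group_column!r} not in manifest")
    group = manifest[group_column]
    if group.dropna().nunique() < 2:
        raise SchemaError("group column must have at least two levels")
    if variables is None:
        skip = {group_column, "sample_id", "chromatogram_path"}
        variables = [c for c in manifest.columns if c not in skip]
    rows = []
    for name in variables:
        if name not in manifest.columns:
            raise SchemaError(f"unknown variable {name!r}")
        series = manifest[name]
        if pd.api.types.is_bool_dtype(series) or not pd.api.types.is_numeric_dtype(series):
            rows.append(_categorical_row(name, series, group))
        else:
            rows.append(_continuous_row(name, series, group))
    return rows


def baseline_table_frame(rows: Sequence[BaselineRow]) -> pd.DataFrame:
    """Flatten BaselineRows into a writable table."""
    out = []
    for r in rows:
        out.append(
            {
                "variable": r.variable,
                "test": r.test,
                "p_value": None if r.p_value is None else round(r.p_value, 4),
                "n_missing": r.n_missing,
                "summaries": str(r.summaries),
            }
        )
    return pd.DataFrame(out)
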