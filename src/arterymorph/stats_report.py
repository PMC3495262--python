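"""Group-comparison statistics and cohort report assembly.

Group measurements are compared with two-way ANOVA (condition × week, or
group × dose with the vessel as a repeated-measures blocking unit),
Bonferroni-adjusted pairwise comparisons and the conventional significance
stars (* 0.01 < p < 0.05, ** 0.001 < p < 0.01, *** p < 0.001; boundary
values map to the weaker code).  Unbalanced designs use type-II sums of
squares.  ``build_report`` joins the per-stage tables on the
(condition, week, animal) key into one long-format cohort report.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.formula.api import ols

from .errors import DesignError, JoinError

__all__ = [
    "GroupComparison",
    "CohortReport",
    "two_way_anova",
    "bonferroni_adjust",
    "star_code",
    "build_report",
]


@dataclass
class GroupComparison:
    """Two-way ANOVA result with cell summaries and pairwise comparisons."""

    anova_table: pd.DataFrame  # index: effect; columns: sum_sq, df, F, PR(>F)
    cell_means: pd.DataFrame  # (a, b, mean, sem, n)
    pairwise: pd.DataFrame  # (level_1, level_2, p_raw, p_adj, stars)
    repeated: bool = False
    flags: list[str] = field(default_factory=list)

    def effect_p(self, effect: str) -> float:
        return float(self.anova_table.loc[effect, "PR(>F)"])


def two_way_anova(
    values: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    repeated: bool = False,
    subject: np.ndarray | None = None,
) -> GroupComparison:
    """Two-way ANOVA of ``values`` over two crossed factors.

    ``repeated=True`` adds ``subject`` (e.g. the vessel, measured at every
    dose) as an additive blocking factor, the classical randomized-block
    treatment of repeated measures.  Effects named ``"a"``, ``"b"`` and
    ``"a:b"`` in the returned table.  Pairwise comparisons are Welch
    t-tests between all cells, Bonferroni-adjusted over the family of all
    cell pairs.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a).astype(str),
            "b": np.asarray(factor_b).astype(str),
        }
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise DesignError("each factor needs at least two levels")
    if repeated:
        if subject is None:
            raise DesignError("repeated-measures ANOVA requires subject labels")
        df["subject"] = np.asarray(subject).astype(str)
        formula = "value ~ C(subject) + C(a) * C(b)"
    else:
        formula = "value ~ C(a) * C(b)"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance fixtures divide by 0
        model = ols(formula, data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
    rename = {"C(a)": "a", "C(b)": "b", "C(a):C(b)": "a:b", "C(subject)": "subject"}
    table = table.rename(index=rename)
    # degenerate fixtures: no variance anywhere -> F = 0, p = 1 by convention
    zero_effect = table["sum_sq"].abs() < 1e-12
    table.loc[zero_effect, "F"] = 0.0
    table.loc[zero_effect, "PR(>F)"] = 1.0
    table.loc["Residual", ["F", "PR(>F)"]] = np.nan

    flags: list[str] = []
    cells = (
        df.groupby(["a", "b"])["value"]
        .agg(
            mean="mean",
            sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
            n="count",
        )
        .reset_index()
    )
    counts = cells["n"].unique()
    if len(counts) > 1:
        flags.append("unbalanced design; type-II sums of squares used")

    pairs = []
    cell_groups = {(r.a, r.b): df[(df.a == r.a) & (df.b == r.b)]["value"].to_numpy()
                   for r in cells.itertuples()}
    combos = list(itertools.combinations(sorted(cell_groups), 2))
    raw = []
    for g1, g2 in combos:
        x, y = cell_groups[g1], cell_groups[g2]
        if len(x) > 1 and len(y) > 1 and (x.std() > 0 or y.std() > 0):
            p = float(sps.ttest_ind(x, y, equal_var=False).pvalue)
        else:
            p = 1.0
        raw.append(p)
    adj = bonferroni_adjust(np.array(raw) if raw else np.empty(0), len(combos) or 1)
    for (g1, g2), p, pa in zip(combos, raw, adj):
        pairs.append(
            {
                "level_1": "/".join(g1),
                "level_2": "/".join(g2),
                "p_raw": p,
                "p_adj": float(pa),
                "stars": star_code(float(pa)),
            }
        )
    return GroupComparison(
        anova_table=table,
        cell_means=cells,
        pairwise=pd.DataFrame(pairs),
        repeated=repeated,
        flags=flags,
    )


def bonferroni_adjust(p_values, k: int):
    """Bonferroni correction over ``k`` comparisons: min(1, p·k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * k)


def star_code(p: float) -> str:
    """Significance stars; boundary p maps to the less significant code."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CohortReport:
    """Joined long-format cohort table plus per-group summary blocks."""

    long: pd.DataFrame  # condition, week, animal, measure, value
    summary: pd.DataFrame  # condition, week, measure, mean, sem, n
    flags: list[str] = field(default_factory=list)


KEY = ["condition", "week", "animal"]


def _to_long(table: pd.DataFrame, section: str) -> pd.DataFrame:
    missing = [k for k in KEY if k not in table.columns]
    if missing:
        raise JoinError(f"{section} table lacks key columns {missing}")
    value_cols = [c for c in table.columns if c not in KEY]
    long = table.melt(id_vars=KEY, value_vars=value_cols, var_name="measure")
    long["measure"] = section + "." + long["measure"]
    return long


def build_report(
    geometry: pd.DataFrame | None = None,
    fractions: pd.DataFrame | None = None,
    nuclei: pd.DataFrame | None = None,
    curves: pd.DataFrame | None = None,
    drop_conditions: tuple[str, ...] = (),
) -> CohortReport:
    """Assemble stage tables into one cohort report.

    Each input table carries the (condition, week, animal) key plus numeric
    measure columns.  Missing tables are flagged, not fatal.  Duplicate
    (key, measure) rows raise, so every phantom appears exactly once per
    measure.  ``drop_conditions`` removes designated groups (e.g. excluded
    sham controls) from the report.
    """
    sections = {
        "geometry": geometry,
        "fractions": fractions,
        "nuclei": nuclei,
        "curves": curves,
    }
    flags: list[str] = []
    parts = []
    for name, table in sections.items():
        if table is None or len(table) == 0:
            flags.append(f"section {name!r} missing or empty")
            continue
        parts.append(_to_long(table, name))
    if not parts:
        raise JoinError("no tables supplied")
    long = pd.concat(parts, ignore_index=True)
    if drop_conditions:
        dropped = long["condition"].isin(drop_conditions)
        if dropped.any():
            flags.append(
                f"dropped {int(dropped.sum())} rows for conditions {drop_conditions}"
            )
        long = long[~dropped]
    dup = long.duplicated(subset=KEY + ["measure"])
    if dup.any():
        raise JoinError("duplicate (condition, week, animal, measure) rows")
    long = long.sort_values(KEY + ["measure"], kind="mergesort").reset_index(drop=True)
    summary = (
        long.groupby(["condition", "week", "measure"])["value"]
        .agg(
            mean="mean",
            sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
            n="count",
        )
        .reset_index()
        .sort_values(["measure", "condition", "week"], kind="mergesort")
        .reset_index(drop=True)
    )
    return CohortReport(long=long, summary=summary, flags=flags)
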