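"""Tank-level inference: blocked one-way ANOVA, Levene's test,
Tukey-Kramer HSD and mean +/- SEM summaries with a compact letter
display.

The experimental unit is the tank.  Tanks sit in recirculation systems,
handled as an additive block factor: with a balanced design and no
interaction term, treating the block as fixed gives the identical F
test for diet as a random-block analysis, so the fixed form is used.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "anova_block",
    "levene",
    "tukey_hsd",
    "letter_display",
    "summarize",
]

_REQUIRED = ("diet", "value")


def _check_table(table: pd.DataFrame) -> None:
    for col in _REQUIRED:
        if col not in table.columns:
            raise ValueError(f"measurement table needs a {col!r} column")
    if table["value"].isna().any():
        raise ValueError("measurement table contains missing values")
    counts = table.groupby("diet")["value"].count()
    if len(counts) < 2:
        raise ValueError("need at least two diet groups")
    if (counts < 2).any():
        thin = list(counts.index[counts < 2])
        raise ValueError(f"diet(s) {thin} observed in fewer than two tanks")


def anova_block(table: pd.DataFrame) -> dict[str, float]:
    """Two-factor additive ANOVA (diet + system block, no interaction).

    ``table`` has columns diet, value and optionally system_id; without
    a block column this reduces to one-way ANOVA.  Returns F and p for
    diet (and for system when present) plus the degrees of freedom.
    """
    _check_table(table)
    data = table.copy()
    has_block = "system_id" in data.columns and data["system_id"].nunique() > 1
    formula = "value ~ C(diet) + C(system_id)" if has_block else "value ~ C(diet)"
    fit = ols(formula, data=data).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    if aov.loc["Residual", "df"] < 1:
        raise ValueError("no residual degrees of freedom (rank-deficient design)")
    # zero-variance corner: on (near-)constant data the decomposition is
    # numerical noise; an effect with no sum of squares has F = 0
    scale = len(data) * max(1.0, float(np.abs(data["value"]).max())) ** 2
    for term in aov.index:
        if term == "Residual":
            continue
        if aov.loc[term, "sum_sq"] <= 1e-12 * scale:
            aov.loc[term, ["F", "PR(>F)"]] = (0.0, 1.0)
        elif not np.isfinite(aov.loc[term, "F"]):
            aov.loc[term, ["F", "PR(>F)"]] = (np.inf, 0.0)
    out = {
        "F_diet": float(aov.loc["C(diet)", "F"]),
        "p_diet": float(aov.loc["C(diet)", "PR(>F)"]),
        "df_diet": float(aov.loc["C(diet)", "df"]),
        "df_resid": float(aov.loc["Residual", "df"]),
        "ms_resid": float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"]),
    }
    if has_block:
        out["F_system"] = float(aov.loc["C(system_id)", "F"])
        out["p_system"] = float(aov.loc["C(system_id)", "PR(>F)"])
        out["df_system"] = float(aov.loc["C(system_id)", "df"])
    return out


def levene(table: pd.DataFrame, center: str = "mean") -> dict[str, float]:
    """Levene's test of homogeneity of variance across diet groups.

    ``center="mean"`` is the classic test (one-way ANOVA on absolute
    deviations from group means); ``"median"`` gives the
    Brown-Forsythe variant.
    """
    _check_table(table)
    groups = [g["value"].to_numpy(float) for _, g in table.groupby("diet")]
    w, p = stats.levene(*groups, center=center)
    return {"W": float(w), "p": float(p)}


def tukey_hsd(table: pd.DataFrame, use_block: bool = True) -> pd.DataFrame:
    """Tukey-Kramer HSD pairwise comparisons among diets.

    q = |mean_i - mean_j| / sqrt(MS_res/2 x (1/n_i + 1/n_j)), with the
    Kramer form handling unequal group sizes; the residual mean square
    comes from the (blocked, if requested and available) ANOVA.
    Adjusted p-values use the studentized-range distribution with k
    groups and the residual df.
    """
    _check_table(table)
    data = table if (use_block and "system_id" in table.columns) else table[["diet", "value"]]
    aov = anova_block(data)
    ms_res, df_res = aov["ms_resid"], aov["df_resid"]
    grp = table.groupby("diet")["value"]
    means, ns = grp.mean(), grp.count()
    k = len(means)
    if k < 2:
        raise ValueError("need at least two groups")
    rows = []
    for a, b in itertools.combinations(means.index, 2):
        diff = means[a] - means[b]
        se = math.sqrt(ms_res / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else math.inf)
        p = float(stats.studentized_range.sf(q, k, df_res)) if math.isfinite(q) else 0.0
        rows.append({"group_1": a, "group_2": b, "difference": diff, "q": q, "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)


def letter_display(
    pairwise: pd.DataFrame | Mapping[tuple[str, str], float],
    alpha: float = 0.05,
    order: Sequence[str] | None = None,
) -> dict[str, str]:
    """Compact letter display from pairwise adjusted p-values.

    Groups sharing any letter are not significantly different at
    ``alpha``.  Uses the insert-and-absorb algorithm: start from one
    letter covering every group; for each significant pair split any
    letter containing both; absorb redundant (subset) letters.  Letters
    are assigned in ``order`` (default: first appearance).
    """
    if isinstance(pairwise, pd.DataFrame):
        pairs = {
            (r["group_1"], r["group_2"]): r["p_adj"] for _, r in pairwise.iterrows()
        }
    else:
        pairs = dict(pairwise)
    groups: list[str] = list(order) if order is not None else []
    for a, b in pairs:
        for g in (a, b):
            if g not in groups:
                groups.append(g)

    columns: list[set[str]] = [set(groups)]
    for (a, b), p in pairs.items():
        if p >= alpha:
            continue
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend((col - {a}, col - {b}))
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another
        columns = [
            c
            for i, c in enumerate(new_cols)
            if c and not any(i != j and c < other or (c == other and i > j)
                             for j, other in enumerate(new_cols))
        ]
    # stable ordering of letters by the first member they contain
    def col_key(col: set[str]) -> int:
        return min(groups.index(g) for g in col)

    columns.sort(key=col_key)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in groups:
            if g in col:
                out[g] += letter
    return out


def summarize(
    table: pd.DataFrame, alpha: float = 0.05, use_block: bool = True
) -> pd.DataFrame:
    """Mean +/- SEM per diet with compact letters from Tukey-Kramer HSD."""
    _check_table(table)
    grp = table.groupby("diet")["value"]
    out = pd.DataFrame(
        {
            "mean": grp.mean(),
            "sem": grp.std(ddof=1) / np.sqrt(grp.count()),
            "n": grp.count(),
        }
    )
    letters = letter_display(tukey_hsd(table, use_block=use_block), alpha=alpha,
                             order=list(out.sort_values("mean", ascending=False).index))
    out["letters"] = [letters[g] for g in out.index]
    return out
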