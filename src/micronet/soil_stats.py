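"""Soil-property summary machinery: two-factor block ANOVA, marginal
means, percent differences and Fisher's-LSD compact letter displays.

The design is the balanced factorial of the field trial: sampling
location (bulk vs rhizosphere) x cropping system (W, SW, S) x block,
one observation per cell.  Blocks are treated as a fixed additive term.
Because the design is balanced, the factor sums of squares are
orthogonal and are computed directly from cell means; the decomposition
SS_block + SS_L + SS_T + SS_LxT + SS_resid = SS_total holds exactly.

The post-hoc is unprotected Fisher's LSD (pairwise t with the pooled
residual mean square), with compact letters assigned by the
insert-and-absorb algorithm so that two groups share a letter exactly
when their pairwise test is non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .tables_io import GROUP_ORDER

ANOVA_TERMS = ("block", "location", "treatment", "location:treatment")


@dataclass
class AnovaTable:
    """Per-term df, SS, MS, F and p of the two-factor block ANOVA.

    ``degenerate`` is set when the residual mean square is zero, in
    which case F and p are undefined (NaN) rather than infinite.
    """

    table: pd.DataFrame  # rows: terms + residual + total
    degenerate: bool = False

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    def summary(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")

    @property
    def ms_residual(self) -> float:
        return float(self.table.loc["residual", "MS"])

    @property
    def df_residual(self) -> int:
        return int(self.table.loc["residual", "df"])


def _check_balanced(meta: pd.DataFrame) -> None:
    cells = meta.groupby(
        ["location", "treatment", "block"], observed=True
    ).size()
    expected = (
        meta["location"].nunique()
        * meta["treatment"].nunique()
        * meta["block"].nunique()
    )
    if len(cells) != expected or cells.nunique() != 1:
        raise ValidationError(
            "unbalanced design: every location x treatment x block cell "
            "must contain the same number of samples"
        )


def two_factor_block_anova(
    values: Sequence[float] | pd.Series, metadata: pd.DataFrame
) -> AnovaTable:
    """Fixed-effects ANOVA: response ~ block + location * treatment.

    ``values`` is one number per sample, aligned with ``metadata`` (a
    frame with treatment/location/block columns, e.g. from
    :func:`micronet.tables_io.read_metadata`).  Requires a complete
    balanced design and positive residual df.
    """
    y = np.asarray(
        values.reindex(metadata.index) if isinstance(values, pd.Series)
        else values,
        dtype=float,
    )
    if y.shape[0] != len(metadata):
        raise ValidationError("values length does not match metadata")
    _check_balanced(metadata)
    df = pd.DataFrame(
        {
            "y": y,
            "block": metadata["block"].to_numpy(),
            "L": metadata["location"].to_numpy(),
            "T": metadata["treatment"].to_numpy(),
        }
    )
    n = len(df)
    grand = df["y"].mean()
    ss_total = float(((df["y"] - grand) ** 2).sum())

    def main_ss(factor: str) -> float:
        means = df.groupby(factor, observed=True)["y"].agg(["mean", "size"])
        return float((means["size"] * (means["mean"] - grand) ** 2).sum())

    ss_block = main_ss("block")
    ss_l = main_ss("L")
    ss_t = main_ss("T")
    cell = df.groupby(["L", "T"], observed=True)["y"].agg(["mean", "size"])
    l_means = df.groupby("L", observed=True)["y"].mean()
    t_means = df.groupby("T", observed=True)["y"].mean()
    ss_lt = float(
        sum(
            row["size"]
            * (row["mean"] - l_means[l] - t_means[t] + grand) ** 2
            for (l, t), row in cell.iterrows()
        )
    )
    ss_resid = max(ss_total - ss_block - ss_l - ss_t - ss_lt, 0.0)

    n_b = df["block"].nunique()
    n_l = df["L"].nunique()
    n_t = df["T"].nunique()
    df_terms = {
        "block": n_b - 1,
        "location": n_l - 1,
        "treatment": n_t - 1,
        "location:treatment": (n_l - 1) * (n_t - 1),
    }
    df_resid = n - 1 - sum(df_terms.values())
    if df_resid <= 0:
        raise ValidationError("zero residual degrees of freedom")

    ss_terms = {
        "block": ss_block,
        "location": ss_l,
        "treatment": ss_t,
        "location:treatment": ss_lt,
    }
    ms_resid = ss_resid / df_resid
    degenerate = ms_resid <= 1e-12 * max(ss_total / max(n - 1, 1), 1e-300)

    tol = 1e-12 * max(ss_total / max(n - 1, 1), 1e-300)
    rows = []
    for term in ANOVA_TERMS:
        ms = ss_terms[term] / df_terms[term]
        if degenerate:
            # zero residual variance: a term is either exactly absent
            # (F = 0, p = 1) or infinitely significant (F = inf, p = 0)
            f_stat = np.inf if ms > tol else 0.0
            p = 0.0 if ms > tol else 1.0
        else:
            f_stat = ms / ms_resid
            p = float(stats.f.sf(f_stat, df_terms[term], df_resid))
        rows.append((term, df_terms[term], ss_terms[term], ms, f_stat, p))
    rows.append(("residual", df_resid, ss_resid, ms_resid, np.nan, np.nan))
    rows.append(("total", n - 1, ss_total, np.nan, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "SS", "MS", "F", "p"]
    ).set_index("term")
    return AnovaTable(table=table, degenerate=bool(degenerate))


def marginal_means(
    values: Sequence[float] | pd.Series,
    metadata: pd.DataFrame,
    factor: str,
) -> pd.Series:
    """Unweighted mean of the location x treatment cell means per level
    of ``factor`` ("location" or "treatment")."""
    if factor not in ("location", "treatment"):
        raise ValidationError(
            f"unknown factor {factor!r}; allowed: location, treatment"
        )
    y = np.asarray(
        values.reindex(metadata.index) if isinstance(values, pd.Series)
        else values,
        dtype=float,
    )
    _check_balanced(metadata)
    df = pd.DataFrame(
        {
            "y": y,
            "location": metadata["location"].to_numpy(),
            "treatment": metadata["treatment"].to_numpy(),
        }
    )
    cells = df.groupby(["location", "treatment"], observed=True)["y"].mean()
    return cells.groupby(level=factor).mean()


def percent_difference(mean_a: float, mean_b: float,
                       ndigits: int | None = 1) -> float:
    """100 * (a - b) / b, rounded to the report precision (1 decimal)."""
    if mean_b == 0:
        raise ValidationError("reference mean is zero")
    value = 100.0 * (mean_a - mean_b) / mean_b
    return round(value, ndigits) if ndigits is not None else value


def fold_ratio(a: float, b: float, ndigits: int | None = 1) -> float:
    """a / b as a fold change (e.g. vulnerability comparisons)."""
    if b == 0:
        raise ValidationError("reference value is zero")
    value = a / b
    return round(value, ndigits) if ndigits is not None else value


@dataclass
class LetterDisplay:
    """Per-group mean, SD and compact letter set.

    Two groups share a letter iff their pairwise LSD test is
    non-significant at the chosen alpha.
    """

    table: pd.DataFrame  # index group, columns mean, sd, n, letters
    alpha: float

    def letters(self) -> dict[str, str]:
        return dict(self.table["letters"])


def _insert_absorb(
    order: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display via insert-and-absorb.

    ``order`` lists groups best-first; ``significant`` holds unordered
    pairs that must NOT share a letter.  Every non-significant pair ends
    up sharing at least one column.
    """
    columns: list[set[str]] = [set(order)]
    for g1, g2 in sorted(significant):
        new_cols: list[set[str]] = []
        for col in columns:
            if g1 in col and g2 in col:
                new_cols.append(col - {g1})
                new_cols.append(col - {g2})
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another column
        columns = [
            col
            for i, col in enumerate(new_cols)
            if not any(
                col < other or (col == other and i > j)
                for j, other in enumerate(new_cols)
            )
        ]
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in order}
    for letter, col in zip(alphabet, columns):
        for g in order:
            if g in col:
                out[g] += letter
    return out


def lsd_letters(
    values: Sequence[float] | pd.Series,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    ms_residual: float | None = None,
    df_residual: int | None = None,
) -> LetterDisplay:
    """Fisher's-LSD compact letter display over the six groups.

    Pairwise t statistics use the pooled residual mean square of the
    two-factor block ANOVA (computed here unless supplied).  Groups are
    sorted descending by mean; letters are assigned so that sharing a
    letter is equivalent to pairwise non-significance at ``alpha``.
    """
    y = pd.Series(
        np.asarray(
            values.reindex(metadata.index) if isinstance(values, pd.Series)
            else values,
            dtype=float,
        ),
        index=metadata.index,
    )
    groups = metadata["group"]
    levels = [g for g in GROUP_ORDER if g in set(groups)]
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups for letters")
    if ms_residual is None or df_residual is None:
        anova = two_factor_block_anova(y, metadata)
        ms_residual = anova.ms_residual
        df_residual = anova.df_residual

    stats_by_group = {
        g: (y[groups == g].mean(), y[groups == g].std(ddof=1),
            int((groups == g).sum()))
        for g in levels
    }
    order = sorted(levels, key=lambda g: -stats_by_group[g][0])
    significant: set[tuple[str, str]] = set()
    if ms_residual > 0:
        for i, g1 in enumerate(order):
            for g2 in order[i + 1:]:
                m1, _, n1 = stats_by_group[g1]
                m2, _, n2 = stats_by_group[g2]
                se = np.sqrt(ms_residual * (1.0 / n1 + 1.0 / n2))
                t = (m1 - m2) / se
                p = 2 * stats.t.sf(abs(t), df_residual)
                if p < alpha:
                    significant.add((g1, g2))
    letters = _insert_absorb(order, significant)
    table = pd.DataFrame(
        {
            "mean": [stats_by_group[g][0] for g in levels],
            "sd": [stats_by_group[g][1] for g in levels],
            "n": [stats_by_group[g][2] for g in levels],
            "letters": [letters[g] for g in levels],
        },
        index=pd.Index(levels, name="group"),
    )
    return LetterDisplay(table=table, alpha=alpha)
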