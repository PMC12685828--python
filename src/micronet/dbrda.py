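"""Distance-based redundancy analysis (dbRDA).

Community composition enters as a distance matrix (Bray-Curtis here);
its principal coordinates over the positive-eigenvalue axes carry the
total (positive) inertia.  The constrained step is the least-squares
projection of those coordinates onto the standardized environmental
design, followed by an eigendecomposition of the fitted values; each
constrained axis is reported as a percent of total positive inertia.
Negative PCoA eigenvalues are dropped (no Lingoes/Cailliez correction)
and their total magnitude is reported.

Per-variable "explanatory degree" is the envfit-style squared multiple
correlation (r^2) of the standardized variable with the first two
principal-coordinate axes, with a row-permutation p-value.  These r^2
are marginal (one variable at a time) and are not a partition of the
constrained inertia.  The signed correlation with axis 1 is reported
alongside, since a multivariate r^2 itself carries no sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix, pcoa
from .exceptions import ValidationError

CONDITION_LIMIT = 1e8


def _standardize(env: pd.DataFrame, variables: Sequence[str]) -> np.ndarray:
    missing = [v for v in variables if v not in env.columns]
    if missing:
        raise ValidationError(f"soil variables not in table: {missing}")
    x = env[list(variables)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("missing values among selected soil variables")
    sd = x.std(axis=0, ddof=1)
    zero = [v for v, s in zip(variables, sd) if s == 0]
    if zero:
        raise ValidationError(f"zero-variance soil variables: {zero}")
    return (x - x.mean(axis=0)) / sd


@dataclass
class DbrdaResult:
    """Constrained ordination plus per-variable marginal statistics."""

    sample_ids: list[str]
    axis_eigenvalues: np.ndarray
    axis_percent: np.ndarray        # of total positive inertia
    site_scores: np.ndarray         # samples x constrained axes
    biplot_scores: pd.DataFrame     # variables x constrained axes
    constrained_inertia: float
    total_inertia: float            # positive part
    negative_inertia: float         # |sum of dropped negative eigenvalues|
    variable_tests: pd.DataFrame | None = None

    @property
    def constrained_percent(self) -> float:
        return float(self.axis_percent.sum())

    def summary(self) -> str:
        lines = [
            "dbRDA: constrained "
            f"{self.constrained_percent:.2f}% of total inertia",
        ]
        for i, pct in enumerate(self.axis_percent, start=1):
            lines.append(f"  axis {i}: {pct:.2f}%")
        if self.variable_tests is not None:
            lines.append(self.variable_tests.to_string(
                float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def dbrda_fit(
    dm: DistanceMatrix,
    env: pd.DataFrame,
    variables: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
    run_variable_tests: bool = True,
) -> DbrdaResult:
    """Fit a dbRDA of a distance matrix on soil variables.

    ``env`` must be indexed by sample_id and complete for ``variables``
    (standardized internally, so results are invariant to affine
    rescaling).  Collinear variable sets (condition number above 1e8)
    raise an error naming the most correlated pair.
    """
    env = env.loc[dm.sample_ids]
    x = _standardize(env, variables)
    n = x.shape[0]
    cond = np.linalg.cond(x)
    if cond > CONDITION_LIMIT:
        corr = np.corrcoef(x.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValidationError(
            f"collinear environmental variables (condition number "
            f"{cond:.3g}); most correlated pair: "
            f"{variables[i]!r}, {variables[j]!r}"
        )

    ordination = pcoa(dm)
    coords = ordination.coordinates  # n x k, positive axes, centered
    total = float(ordination.eigenvalues[ordination.eigenvalues > 0].sum())
    negative = float(
        -ordination.eigenvalues[ordination.eigenvalues < 0].sum()
    )

    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, coords, rcond=None)
    fitted = design @ beta - coords.mean(axis=0)  # centered fitted values
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    rank = min(len(variables), coords.shape[1])
    eigvals = (s ** 2)[:rank]
    keep = eigvals > max(eigvals[0] if len(eigvals) else 0.0, 1.0) * 1e-12
    eigvals = eigvals[keep]
    site_scores = (u * s)[:, : len(eigvals)]
    percent = 100.0 * eigvals / total if total > 0 else eigvals * 0.0

    biplot = pd.DataFrame(
        [
            [
                float(np.corrcoef(x[:, vi], site_scores[:, ai])[0, 1])
                if site_scores[:, ai].std() > 0 else 0.0
                for ai in range(site_scores.shape[1])
            ]
            for vi in range(len(variables))
        ],
        index=list(variables),
        columns=[f"dbRDA{i + 1}" for i in range(site_scores.shape[1])],
    )

    tests = None
    if run_variable_tests:
        rows = []
        for offset, var in enumerate(variables):
            r2, p, sign = variable_tests(
                dm, env, var,
                n_permutations=n_permutations,
                seed=None if seed is None else seed + offset,
                _ordination=ordination,
            )
            rows.append((var, r2, sign, p))
        tests = pd.DataFrame(
            rows, columns=["variable", "r2", "axis1_correlation", "p"]
        ).set_index("variable")

    return DbrdaResult(
        sample_ids=list(dm.sample_ids),
        axis_eigenvalues=eigvals,
        axis_percent=np.asarray(percent),
        site_scores=site_scores,
        biplot_scores=biplot,
        constrained_inertia=float(eigvals.sum()),
        total_inertia=total,
        negative_inertia=negative,
        variable_tests=tests,
    )


def variable_tests(
    dm: DistanceMatrix,
    env: pd.DataFrame,
    variable: str,
    n_permutations: int = 999,
    seed: int | None = None,
    n_axes: int = 2,
    _ordination=None,
) -> tuple[float, float, float]:
    """Marginal envfit-style test of one soil variable.

    Returns (r2, p, signed axis-1 correlation) where r2 is the squared
    multiple correlation of the standardized variable with the first
    ``n_axes`` principal-coordinate axes and p comes from permuting the
    variable's sample rows.
    """
    if n_permutations < 99:
        warnings.warn(
            f"{n_permutations} permutations give a coarse p resolution",
            stacklevel=2,
        )
    env = env.loc[dm.sample_ids]
    v = _standardize(env, [variable])[:, 0]
    ordination = _ordination if _ordination is not None else pcoa(dm)
    axes = ordination.coordinates[:, :n_axes]
    n = len(v)
    design = np.column_stack([np.ones(n), axes])

    def r_squared(values: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(design, values, rcond=None)
        resid = values - design @ beta
        ss_tot = float(np.sum((values - values.mean()) ** 2))
        return 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0

    r2_obs = r_squared(v)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if r_squared(v[rng.permutation(n)]) >= r2_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    sd1 = axes[:, 0].std()
    sign = float(np.corrcoef(v, axes[:, 0])[0, 1]) if sd1 > 0 else 0.0
    return float(r2_obs), float(p), sign
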