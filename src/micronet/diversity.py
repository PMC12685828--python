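"""Alpha and beta diversity: Shannon, Gini-Simpson, Chao1, Bray-Curtis,
principal coordinates analysis and permutational MANOVA.

All of these operate on :class:`~micronet.tables_io.FeatureTable` counts.
Shannon entropy uses natural log by default (``base=2`` available); the
Gini-Simpson index is 1 - sum(p^2); Chao1 is the classic bias-corrected
richness estimator S_obs + F1(F1-1)/(2(F2+1)) built from singleton and
doubleton counts, which requires raw (unnormalised) counts.

The PERMANOVA here is the distance-based pseudo-F of Anderson (the
adonis-style one-way partition): SS_total from all squared pairwise
distances, SS_within from within-group pair sums, permutation p-value
with the (1 + #{F_perm >= F_obs}) / (1 + n_permutations) estimator so p
is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import ValidationError
from .tables_io import FeatureTable


# ---------------------------------------------------------------------------
# alpha diversity


def shannon(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over nonzero proportions."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("sample has zero total count")
    p = counts[counts > 0] / total
    h = -np.sum(p * np.log(p))
    if base is not None:
        h /= np.log(base)
    return float(h)


def gini_simpson(counts: np.ndarray) -> float:
    """Gini-Simpson diversity 1 - sum p_i^2 (0 for a single taxon)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("sample has zero total count")
    p = counts / total
    return float(1.0 - np.sum(p * p))

def chao1(counts: np.ndarray) -> float:
    """Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1/F2 are singleton/doubleton counts; always >= observed richness.
    """
    counts = np.asarray(counts)
    s_obs = int(np.sum(counts > 0))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def rarefy(
    table: FeatureTable, depth: int, seed: int | None = None
) -> FeatureTable:
    """Subsample each sample to ``depth`` reads without replacement."""
    totals = table.counts.sum(axis=0)
    for sid, total in zip(table.sample_ids, totals):
        if total < depth:
            raise ValidationError(
                f"rarefaction depth {depth} exceeds total {total} of "
                f"sample {sid!r}"
            )
    rng = np.random.default_rng(seed)
    cols = [
        rng.multivariate_hypergeometric(col, depth)
        for col in table.counts.T
    ]
    return FeatureTable(
        list(table.taxon_ids), list(table.sample_ids),
        np.array(cols, dtype=np.int64).T,
    )


def alpha_diversity(
    table: FeatureTable,
    rarefy_depth: int | None = None,
    seed: int | None = None,
    base: float | None = None,
) -> pd.DataFrame:
    """Per-sample Shannon, Gini-Simpson and Chao1.

    If ``rarefy_depth`` is given, samples are rarefied first (seeded);
    by default indices are computed on the raw counts.
    """
    if rarefy_depth is not None:
        table = rarefy(table, rarefy_depth, seed=seed)
    records = {
        sid: {
            "shannon": shannon(col, base=base),
            "simpson": gini_simpson(col),
            "chao1": chao1(col),
        }
        for sid, col in zip(table.sample_ids, table.counts.T)
    }
    return pd.DataFrame.from_dict(records, orient="index")


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.data)) > 1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(self.data < -1e-12):
            raise ValidationError("negative distances")


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y) on relative
    abundances (so it is invariant to per-sample count scaling)."""
    rel = table.relative_abundance().T  # samples x taxa
    dm = squareform(pdist(rel, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), dm)


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class OrdinationResult:
    """Metric embedding of a distance matrix.

    ``coordinates`` holds one row per sample over the positive-eigenvalue
    axes (scaled by sqrt eigenvalue); ``eigenvalues`` are all of them in
    descending order (negative ones reported but excluded from the
    coordinates); ``proportion_explained`` is over positive eigenvalues.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids,
                            columns=cols)


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Principal coordinates analysis (Gower double-centering of -d^2/2)."""
    d2 = dm.data ** 2
    n = d2.shape[0]
    centerer = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centerer @ d2 @ centerer
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = np.max(np.abs(eigvals)) if n else 1.0
    positive = eigvals > eps * max(scale, 1.0)
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    prop = (
        eigvals[positive] / pos_sum if pos_sum > 0
        else np.zeros(int(positive.sum()))
    )
    return OrdinationResult(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    df_between: int
    df_within: int

    def summary(self) -> str:
        return (
            f"PERMANOVA: F = {self.pseudo_f:.3g}, R2 = {self.r_squared:.3g}, "
            f"p = {self.p_value:.4g} ({self.n_permutations} permutations)"
        )


def _ss_within(d2: np.ndarray, codes: np.ndarray, group_sizes: np.ndarray
               ) -> float:
    ss = 0.0
    for g, n_g in enumerate(group_sizes):
        idx = np.flatnonzero(codes == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * n_g)
    return ss


def permanova(
    dm: DistanceMatrix,
    labels: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against group labels.

    Samples are processed in canonical (sorted sample-id) order, so the
    result is invariant to the input ordering and to renaming the groups,
    given the same seed.
    """
    labels = list(labels)
    if len(labels) != len(dm.sample_ids):
        raise ValidationError("labels length does not match distance matrix")
    order = np.argsort(np.asarray(dm.sample_ids, dtype=object))
    d2 = dm.data[np.ix_(order, order)] ** 2
    # canonical group codes: by first appearance in canonical sample order
    ordered_labels = [labels[i] for i in order]
    uniq: dict[str, int] = {}
    for lab in ordered_labels:
        uniq.setdefault(lab, len(uniq))
    codes = np.array([uniq[lab] for lab in ordered_labels])
    k = len(uniq)
    n = len(codes)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    sizes = np.bincount(codes, minlength=k)
    if np.any(sizes < 2):
        small = [g for g, s in uniq.items() if sizes[s] < 2]
        raise ValidationError(f"groups with fewer than 2 samples: {small}")

    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = _ss_within(d2, codes, sizes)
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, n - k

    def pseudo_f(ss_w: float) -> float:
        return ((ss_total - ss_w) / df_b) / (ss_w / df_w)

    f_obs = pseudo_f(ss_within)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if pseudo_f(_ss_within(d2, codes[perm], sizes)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(ss_between / ss_total) if ss_total > 0 else 0.0,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        df_between=df_b,
        df_within=df_w,
    )
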