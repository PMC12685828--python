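"""LEfSe-style biomarker discovery.

Two stages, following the published LEfSe convention: a per-feature
Kruskal-Wallis screen across classes (p < alpha passes), then a
bootstrap linear-discriminant effect size on the passing features.  Per
bootstrap subsample a one-axis LDA is fitted on the passing features
(relative abundance x 1e6, the tool's parts-per-million convention);
the per-feature score is the average of the class-mean difference
attributed to the feature along the discriminant axis and the raw
class-mean difference, and the reported effect is log10(1 + mean score).
Features are reported when p < alpha AND effect >= the log10 threshold
(default 2).

The original tool's subclass (within-class Wilcoxon) stage is omitted:
the factorial design here has no subclass factor within a comparison.
For more than two classes the per-feature score is the maximum over
class pairs, and the enriched class is the class with the highest mean
among reported features (one-vs-rest semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .exceptions import ValidationError
from .tables_io import RANKS, UNCLASSIFIED, FeatureTable


def aggregate_to_rank(
    table: FeatureTable, taxonomy: pd.DataFrame, rank: str
) -> FeatureTable:
    """Sum counts within each label of a taxonomic rank.

    Taxa missing from the taxonomy, or annotated with the sentinel, are
    pooled under ``unclassified``.  Column sums are conserved.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; allowed: {RANKS}")
    labels = [
        str(taxonomy.loc[t, rank]) if t in taxonomy.index else UNCLASSIFIED
        for t in table.taxon_ids
    ]
    frame = table.to_frame()
    frame.index = pd.Index(labels, name=rank)
    agg = frame.groupby(level=0, sort=False).sum()
    return FeatureTable.from_frame(agg)


def kruskal_wallis_screen(
    table: FeatureTable, labels: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis H test (tie-corrected) across classes.

    Returns a frame indexed by feature with columns H, p, passed.
    A feature constant across all samples has p = 1 by definition.
    """
    labels = np.asarray(labels)
    if len(labels) != len(table.sample_ids):
        raise ValidationError("labels length does not match samples")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    counts_per_class = [np.sum(labels == c) for c in classes]
    if min(counts_per_class) < 2:
        raise ValidationError("every class needs at least 2 samples")
    rel = table.relative_abundance()
    rows = []
    for feature, values in zip(table.taxon_ids, rel):
        if np.ptp(values) == 0:
            rows.append((feature, 0.0, 1.0))
            continue
        groups = [values[labels == c] for c in classes]
        h, p = stats.kruskal(*groups)
        rows.append((feature, float(h), float(p)))
    out = pd.DataFrame(rows, columns=["feature", "H", "p"]).set_index(
        "feature"
    )
    out["passed"] = out["p"] < alpha
    return out


@dataclass
class LefseResult:
    """Per-feature class assignment, p-value and LDA effect size."""

    table: pd.DataFrame  # index feature; columns class, p, effect, reported
    alpha: float
    lda_threshold: float

    def reported(self) -> pd.DataFrame:
        return self.table[self.table["reported"]]


def _pair_scores(
    x: np.ndarray, y: np.ndarray, classes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One bootstrap round: per-feature LDA-attributed score (ppm units)."""
    # jitter breaks exact collinearity between features, as the original
    # tool does before fitting the discriminant
    xb = x + rng.normal(0.0, 1e-6 * max(x.std(), 1.0), size=x.shape)
    lda = LinearDiscriminantAnalysis(n_components=1)
    lda.fit(xb, y)
    w = lda.scalings_[:, 0]
    w = w / np.sqrt(np.sum(w ** 2))
    means = np.stack([xb[y == c].mean(axis=0) for c in classes])
    best = np.zeros(x.shape[1])
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            delta = means[a] - means[b]
            score = 0.5 * (np.abs(w * delta) + np.abs(delta))
            best = np.maximum(best, score)
    return best


def lda_effect_size(
    table: FeatureTable,
    labels: Sequence[str],
    passing: Sequence[str] | None = None,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    boot_fraction: float = 2.0 / 3.0,
    seed: int | None = None,
) -> LefseResult:
    """Bootstrap LDA effect size for features that passed the screen.

    ``passing`` defaults to the Kruskal-Wallis screen at ``alpha``.
    Effect = log10(1 + mean bootstrap score) on relative abundance x 1e6.
    """
    labels = np.asarray(labels)
    screen = kruskal_wallis_screen(table, labels, alpha=alpha)
    if passing is None:
        passing = list(screen.index[screen["passed"]])
    classes = np.unique(labels)
    rel = table.relative_abundance() * 1e6  # ppm, the LEfSe convention
    frame = pd.DataFrame(rel.T, columns=table.taxon_ids)

    effects: dict[str, float] = {}
    enriched: dict[str, str] = {}
    if passing:
        feat_idx = [table.taxon_ids.index(f) for f in passing]
        x_all = rel[feat_idx].T  # samples x features
        class_means = np.stack(
            [x_all[labels == c].mean(axis=0) for c in classes]
        )
        rng = np.random.default_rng(seed)
        scores = np.zeros(len(passing))
        for _ in range(n_boot):
            for attempt in range(10):
                idx = []
                for c in classes:
                    members = np.flatnonzero(labels == c)
                    take = max(int(np.ceil(boot_fraction * len(members))), 2)
                    idx.extend(
                        rng.choice(members, size=min(take, len(members)),
                                   replace=False)
                    )
                idx = np.array(idx)
                yb = labels[idx]
                if all(np.sum(yb == c) >= 2 for c in classes):
                    break
            else:
                raise ValidationError(
                    "could not draw a bootstrap with >= 2 samples per class"
                )
            scores += _pair_scores(x_all[idx], yb, classes, rng)
        scores /= n_boot
        for f, s, means in zip(passing, scores, class_means.T):
            effects[f] = float(np.log10(1.0 + s))
            enriched[f] = str(classes[int(np.argmax(means))])

    rows = []
    for feature in table.taxon_ids:
        effect = effects.get(feature, 0.0)
        p = float(screen.loc[feature, "p"])
        reported = (
            feature in effects and p < alpha and effect >= lda_threshold
        )
        rows.append(
            (feature, enriched.get(feature, ""), p, effect, reported)
        )
    out = pd.DataFrame(
        rows, columns=["feature", "class", "p", "effect", "reported"]
    ).set_index("feature")
    return LefseResult(table=out, alpha=alpha, lda_threshold=lda_threshold)


def run_lefse(
    table: FeatureTable,
    labels: Sequence[str],
    taxonomy: pd.DataFrame | None = None,
    ranks: Sequence[str] | None = None,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    boot_fraction: float = 2.0 / 3.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Screen + effect size, optionally per taxonomic rank.

    Without a taxonomy the features are tested as-is (one row per
    feature); with one, every rank in ``ranks`` (default all five) is
    aggregated and tested, and the output gains a ``rank`` column.
    """
    if taxonomy is None:
        res = lda_effect_size(
            table, labels, alpha=alpha, lda_threshold=lda_threshold,
            n_boot=n_boot, boot_fraction=boot_fraction, seed=seed,
        )
        out = res.table.reset_index()
        out.insert(1, "rank", "feature")
        return out
    frames = []
    for rank in (ranks if ranks is not None else RANKS):
        agg = aggregate_to_rank(table, taxonomy, rank)
        res = lda_effect_size(
            agg, labels, alpha=alpha, lda_threshold=lda_threshold,
            n_boot=n_boot, boot_fraction=boot_fraction, seed=seed,
        )
        frame = res.table.reset_index()
        frame.insert(1, "rank", rank)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
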