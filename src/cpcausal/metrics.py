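"""Multi-label ranking metrics and batch-effect diagnostics.

mAP and macro ROC-AUC are written threshold-indexed, directly from their
precision/recall and TPR/FPR definitions, with tied scores grouped into a
single threshold step. The label-shuffling control permutes the
sample-to-relevance assignment while keeping scores fixed, giving the
chance-level null both metrics are compared against.

Diagnostics: silhouette over batch labels (how strongly profiles cluster
by batch), and the UMAP + HDBSCAN within-cluster compound-variance score
(how evenly compounds distribute over phenotype clusters), plus a one-way
ANOVA / Tukey HSD wrapper for comparing metric tables across data types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .utils import as_rng


@dataclass
class RankingScores:
    """Score and binary relevance matrices for multi-label ranking."""

    scores: np.ndarray  # (n_samples, n_labels)
    relevance: np.ndarray  # binary, same shape
    sample_ids: list | None = None
    label_ids: list | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.relevance = np.asarray(self.relevance)
        if self.scores.shape != self.relevance.shape:
            raise ValueError("scores and relevance shapes differ")
        if not np.isin(self.relevance, (0, 1)).all():
            raise ValueError("relevance must be binary")
        if (self.relevance.sum(axis=1) == 0).any():
            raise ValueError("every sample needs at least one relevant label")


# ---------------------------------------------------------------------------
# average precision (per sample)
# ---------------------------------------------------------------------------


def average_precision(relevance_row: np.ndarray, score_row: np.ndarray) -> float:
    """AP = sum_n (R_n - R_{n-1}) P_n over descending unique score thresholds."""
    y = np.asarray(relevance_row).astype(int)
    s = np.asarray(score_row, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without a relevant label")
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    ap = 0.0
    prev_recall = 0.0
    tp = fp = 0
    i = 0
    n = y.size
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # tied scores form one threshold step
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def mean_average_precision(ranking: RankingScores) -> float:
    """Unweighted mean of per-sample AP."""
    return float(
        np.mean(
            [
                average_precision(ranking.relevance[i], ranking.scores[i])
                for i in range(ranking.scores.shape[0])
            ]
        )
    )


# ---------------------------------------------------------------------------
# ROC-AUC (per label)
# ---------------------------------------------------------------------------


def roc_auc_label(relevance_col: np.ndarray, score_col: np.ndarray) -> float:
    """Trapezoidal area under the (FPR, TPR) curve over all thresholds."""
    y = np.asarray(relevance_col).astype(int)
    s = np.asarray(score_col, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    while i < y.size:
        j = i
        while j < y.size and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    return float(np.trapezoid(tpr, fpr))


def macro_roc_auc(ranking: RankingScores) -> float:
    """Mean per-label AUC; labels lacking both classes are excluded with a warning."""
    aucs = []
    skipped = 0
    for j in range(ranking.scores.shape[1]):
        col = ranking.relevance[:, j]
        if col.sum() == 0 or col.sum() == col.size:
            skipped += 1
            continue
        aucs.append(roc_auc_label(col, ranking.scores[:, j]))
    if skipped:
        warnings.warn(f"{skipped} single-class labels excluded from macro ROC-AUC")
    if not aucs:
        raise ValueError("no label with both positive and negative samples")
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# label-shuffling control
# ---------------------------------------------------------------------------


def shuffle_labels_control(
    ranking: RankingScores,
    n_permutations: int = 100,
    rng: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Null distribution of (mAP, macro ROC-AUC) under permuted labels.

    Permutes which relevance row belongs to which sample while keeping the
    score matrix fixed. Returns one row per permutation; the caller takes
    mean +/- sd. Permutation 0 onward are random; the observed (identity)
    metrics are recomputable by passing the ranking straight to the metric
    functions.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = as_rng(rng)
    rows = []
    for p in range(n_permutations):
        perm = rng.permutation(ranking.scores.shape[0])
        shuffled = RankingScores(ranking.scores, ranking.relevance[perm])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(
                {
                    "permutation": p,
                    "mAP": mean_average_precision(shuffled),
                    "roc_auc": macro_roc_auc(shuffled),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# batch-effect diagnostics
# ---------------------------------------------------------------------------


def silhouette_by_batch(profiles: np.ndarray, batch_labels) -> float:
    """Mean silhouette of profiles with batch labels as cluster identifiers.

    High values mean profiles cluster by batch — i.e. strong residual
    batch effects; values near zero mean batches are intermixed.
    """
    from sklearn.metrics import silhouette_score

    profiles = np.asarray(profiles, dtype=float)
    batch_labels = np.asarray(batch_labels)
    uniq, counts = np.unique(batch_labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("silhouette needs >= 2 batches")
    if counts.min() < 2:
        raise ValueError("every batch needs >= 2 profiles")
    return float(silhouette_score(profiles, batch_labels, metric="euclidean"))


def within_cluster_compound_variance(
    datasets: dict[str, tuple[np.ndarray, np.ndarray]],
    umap_params: dict | None = None,
    hdbscan_params: dict | None = None,
    n_seeds: int = 5,
) -> pd.DataFrame:
    """UMAP -> HDBSCAN -> variance of unique-compound counts per cluster.

    ``datasets`` maps a dataset name to (profile matrix, compound labels).
    Per seed and dataset: embed with UMAP, cluster with HDBSCAN (noise
    excluded), count unique compounds per cluster and take the variance of
    those counts; variances are then min-max normalized *across the
    datasets compared in this run*. Returns per-dataset mean +/- sd over
    seeds. Seeds with fewer than 2 clusters are flagged undefined.
    """
    import umap
    from sklearn.cluster import HDBSCAN

    up = {"n_neighbors": 15, "min_dist": 0.1, "n_components": 2, **(umap_params or {})}
    hp = {"min_cluster_size": 5, "copy": True, **(hdbscan_params or {})}
    raw = {name: [] for name in datasets}
    for seed in range(n_seeds):
        per_seed = {}
        for name, (profiles, compound_labels) in datasets.items():
            emb = umap.UMAP(random_state=seed, **up).fit_transform(
                np.asarray(profiles, dtype=float)
            )
            labels = HDBSCAN(**hp).fit_predict(emb)
            clusters = [c for c in np.unique(labels) if c != -1]
            if len(clusters) < 2:
                warnings.warn(
                    f"dataset {name!r}, seed {seed}: HDBSCAN found < 2 clusters"
                )
                per_seed[name] = np.nan
                continue
            compound_labels = np.asarray(compound_labels)
            counts = [
                np.unique(compound_labels[labels == c]).size for c in clusters
            ]
            per_seed[name] = float(np.var(counts))
        vals = np.array([per_seed[n] for n in datasets], dtype=float)
        finite = np.isfinite(vals)
        if finite.sum() >= 1:
            lo, hi = np.nanmin(vals), np.nanmax(vals)
            span = hi - lo
            vals = (vals - lo) / span if span > 0 else np.where(finite, 0.0, np.nan)
        for name, v in zip(datasets, vals):
            raw[name].append(v)
    return pd.DataFrame(
        {
            "dataset": list(datasets),
            "mean": [float(np.nanmean(raw[n])) for n in datasets],
            "sd": [float(np.nanstd(raw[n])) for n in datasets],
            "n_valid_seeds": [int(np.isfinite(raw[n]).sum()) for n in datasets],
        }
    )


# ---------------------------------------------------------------------------
# group comparison (ANOVA + Tukey HSD)
# ---------------------------------------------------------------------------


def compare_groups(
    per_fold_metrics: pd.DataFrame,
    group_column: str = "group",
    metric_columns: tuple[str, ...] = ("mAP", "roc_auc"),
) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD pairwise comparisons per metric.

    ``per_fold_metrics`` has one row per (group, fold) with one column per
    metric. The output follows the two-column comparison layout:
    (Group 1, Group 2, metric, anova_p, p_adjusted).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = sorted(per_fold_metrics[group_column].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    rows = []
    for metric in metric_columns:
        samples = [
            per_fold_metrics.loc[per_fold_metrics[group_column] == g, metric].to_numpy()
            for g in groups
        ]
        if any(len(s) < 2 for s in samples):
            raise ValueError("every group needs >= 2 folds")
        if np.var(np.concatenate(samples)) == 0:
            raise ValueError(f"metric {metric!r} has degenerate (zero) variance")
        anova_p = float(stats.f_oneway(*samples).pvalue)
        tukey = pairwise_tukeyhsd(
            per_fold_metrics[metric].to_numpy(),
            per_fold_metrics[group_column].to_numpy(),
        )
        res = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        for _, r in res.iterrows():
            rows.append(
                {
                    "Group 1": r["group1"],
                    "Group 2": r["group2"],
                    "metric": metric,
                    "anova_p": anova_p,
                    "p_adjusted": float(r["p-adj"]),
                }
            )
    return pd.DataFrame(rows)
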