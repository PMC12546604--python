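"""MoA / target identification via reference subprofiles and Biosimilarity.

For each class (an MoA or a molecular target), a *reference subprofile* is
the class consensus over a handful of reference compounds: only features
whose normalized response has a consistent sign in strictly more than a
threshold fraction (default 85%) of the reference profiles are retained,
valued at their median. Query compounds are scored against every class
subprofile with the Biosimilarity

    B(u, v) = (u - u_bar) . (v - v_bar) / (||u - u_bar|| ||v - v_bar||)

(the centered cosine, algebraically the Pearson correlation), and the full
ranked score list feeds mAP / macro ROC-AUC evaluation. Cross-validation
re-samples the reference compounds per fold; compounds never seen during
generator training form a separate query split to probe structural
generalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import feature_columns
from .scm import CompoundRecord
from .utils import as_rng


# ---------------------------------------------------------------------------
# Biosimilarity
# ---------------------------------------------------------------------------


def biosimilarity(u: np.ndarray, v: np.ndarray) -> float:
    """Centered cosine similarity of two profiles over a shared feature subset."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1-D vectors over the same features")
    if u.size < 2:
        raise ValueError("need at least 2 features")
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise ValueError("Biosimilarity undefined for a constant profile")
    return float(np.dot(uc, vc) / (nu * nv))


# ---------------------------------------------------------------------------
# reference subprofiles
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSubprofile:
    class_label: str
    task: str  # "moa" or "target"
    feature_subset: list[str]
    median_values: np.ndarray
    n_reference_compounds: int
    consistency_threshold: float = 0.85


def build_subprofile(
    reference_profiles: pd.DataFrame,
    threshold: float = 0.85,
    class_label: str = "",
    task: str = "moa",
) -> ReferenceSubprofile:
    """Consensus subprofile from normalized reference profiles.

    A feature is retained iff max(fraction positive, fraction negative)
    strictly exceeds ``threshold``; exact zeros (the control reference
    point) count toward neither sign. Retained values are the median across
    all reference profiles.
    """
    feats = feature_columns(reference_profiles)
    if len(reference_profiles) < 2:
        raise ValueError("need >= 2 reference profiles")
    vals = reference_profiles[feats].to_numpy(dtype=float)
    n = vals.shape[0]
    frac_pos = (vals > 0).sum(axis=0) / n
    frac_neg = (vals < 0).sum(axis=0) / n
    retained = np.maximum(frac_pos, frac_neg) > threshold
    if not retained.any():
        raise ValueError(
            f"no feature passed the {threshold:.0%} sign-consistency filter for "
            f"class {class_label!r}; consider reviewing the threshold"
        )
    subset = [f for f, r in zip(feats, retained) if r]
    medians = np.median(vals[:, retained], axis=0)
    return ReferenceSubprofile(class_label, task, subset, medians, n, threshold)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


class SubprofileClassifier(BaseEstimator):
    """Nearest-centroid classifier over Biosimilarity to class subprofiles.

    ``fit`` consumes normalized reference profiles plus their class labels
    and builds one :class:`ReferenceSubprofile` per class;
    ``decision_function`` returns the full (samples x classes) Biosimilarity
    score matrix — no thresholding, so ranking metrics see every class.
    Scoring restricts each comparison to the subprofile's feature subset.
    """

    def __init__(self, threshold: float = 0.85, task: str = "moa"):
        self.threshold = threshold
        self.task = task

    def fit(self, X: pd.DataFrame, y: list | np.ndarray):
        """X: normalized reference profiles (rows), y: class label per row.

        For multi-label tasks pass one row per (compound, class) membership.
        """
        y = np.asarray(y, dtype=object)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_ = sorted(set(y))
        self.subprofiles_ = {}
        for label in self.classes_:
            self.subprofiles_[label] = build_subprofile(
                X[y == label], self.threshold, class_label=label, task=self.task
            )
        return self

    def decision_function(self, X: pd.DataFrame) -> pd.DataFrame:
        feats = set(feature_columns(X))
        scores = np.full((len(X), len(self.classes_)), np.nan)
        for j, label in enumerate(self.classes_):
            sp = self.subprofiles_[label]
            common = [f for f in sp.feature_subset if f in feats]
            if len(common) < 2:
                warnings.warn(
                    f"class {label!r}: feature intersection with queries < 2; "
                    "scores flagged missing"
                )
                continue
            idx = [sp.feature_subset.index(f) for f in common]
            ref = sp.median_values[idx]
            q = X[common].to_numpy(dtype=float)
            for i in range(len(X)):
                try:
                    scores[i, j] = biosimilarity(q[i], ref)
                except ValueError:
                    scores[i, j] = np.nan
        return pd.DataFrame(scores, columns=self.classes_, index=X.index)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        # deterministic tie-break: argmax takes the first class in sorted name order
        best = self.decision_function(X).fillna(-np.inf).to_numpy().argmax(axis=1)
        return np.array([self.classes_[k] for k in best], dtype=object)


def score_compound(
    query_profile: pd.Series | pd.DataFrame,
    subprofiles: dict[str, ReferenceSubprofile] | list[ReferenceSubprofile],
) -> pd.Series:
    """Biosimilarity of one query profile against each class subprofile."""
    if isinstance(subprofiles, list):
        subprofiles = {sp.class_label: sp for sp in subprofiles}
    if isinstance(query_profile, pd.Series):
        query_profile = query_profile.to_frame().T
    clf = SubprofileClassifier.__new__(SubprofileClassifier)
    clf.threshold = next(iter(subprofiles.values())).consistency_threshold
    clf.task = next(iter(subprofiles.values())).task
    clf.classes_ = sorted(subprofiles)
    clf.subprofiles_ = subprofiles
    return clf.decision_function(query_profile).iloc[0]


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    fold_id: int
    task: str
    reference_ids: dict[str, list[str]]  # class -> reference compound ids
    query_seen_ids: list[str]
    query_unseen_ids: list[str]

    def __post_init__(self):
        refs = {i for ids in self.reference_ids.values() for i in ids}
        overlap = refs & (set(self.query_seen_ids) | set(self.query_unseen_ids))
        if overlap:
            raise ValueError(f"compounds in both reference and query sets: {overlap}")


def _labels_of(record: CompoundRecord, task: str) -> list[str]:
    if task == "moa":
        return [record.moa_label] if record.moa_label else []
    return sorted(record.target_labels)


def make_folds(
    compounds: list[CompoundRecord],
    task: str = "moa",
    n_ref_per_class: int = 5,
    n_folds: int = 10,
    unseen_ids: set[str] | None = None,
    min_class_size: int = 10,
    rng: int | np.random.Generator = 0,
) -> list[FoldSplit]:
    """Cross-validation folds with re-sampled reference compounds.

    Classes with fewer than ``min_class_size`` member compounds are dropped
    with a warning. References are drawn only from compounds seen during
    training; a compound referenced by any class in a fold never appears in
    that fold's query sets. For the multi-label target task, one compound
    may back several class subprofiles.
    """
    rng = as_rng(rng)
    unseen_ids = set(unseen_ids or ())
    members: dict[str, list[str]] = {}
    for rec in compounds:
        if rec.is_control:
            continue
        for label in _labels_of(rec, task):
            members.setdefault(label, []).append(rec.compound_id)
    kept = {}
    for label, ids in sorted(members.items()):
        if len(ids) < min_class_size:
            warnings.warn(
                f"class {label!r} has {len(ids)} < {min_class_size} compounds; dropped"
            )
            continue
        kept[label] = ids

    if not kept:
        raise ValueError("no class meets the minimum size requirement")

    all_ids = sorted({i for ids in kept.values() for i in ids})
    folds = []
    for fold in range(n_folds):
        refs: dict[str, list[str]] = {}
        for label, ids in sorted(kept.items()):
            eligible = [i for i in sorted(ids) if i not in unseen_ids]
            if len(eligible) < n_ref_per_class:
                raise ValueError(
                    f"class {label!r}: only {len(eligible)} seen compounds for "
                    f"{n_ref_per_class} references"
                )
            pick = rng.choice(len(eligible), n_ref_per_class, replace=False)
            refs[label] = [eligible[k] for k in sorted(pick)]
        ref_ids = {i for ids in refs.values() for i in ids}
        query = [i for i in all_ids if i not in ref_ids]
        folds.append(
            FoldSplit(
                fold_id=fold,
                task=task,
                reference_ids=refs,
                query_seen_ids=[i for i in query if i not in unseen_ids],
                query_unseen_ids=[i for i in query if i in unseen_ids],
            )
        )
    return folds


# ---------------------------------------------------------------------------
# dataset-level classification
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    fold_id: int
    task: str
    split: str  # "seen" or "unseen"
    scores: pd.DataFrame  # rows: query compounds, columns: classes
    relevance: pd.DataFrame  # binary, same shape


def classify_dataset(
    profiles: pd.DataFrame,
    compounds: list[CompoundRecord],
    folds: list[FoldSplit],
    threshold: float = 0.85,
) -> list[FoldResult]:
    """Run the full per-fold subprofile classification.

    ``profiles`` must be normalized treatment-level profiles indexed by a
    ``Metadata_Compound`` column. Per fold: build one subprofile per class
    from the reference compounds only, score every query compound, and emit
    score plus binary relevance matrices for the seen and unseen splits.
    """
    if "Metadata_Compound" not in profiles.columns:
        raise ValueError("profiles must carry Metadata_Compound")
    prof = profiles.set_index("Metadata_Compound")
    by_id = {c.compound_id: c for c in compounds}
    results = []
    for fold in folds:
        rows = []
        labels = []
        for cls, ids in sorted(fold.reference_ids.items()):
            for i in ids:
                if i not in prof.index:
                    raise KeyError(f"reference compound {i!r} has no profile")
                rows.append(prof.loc[i])
                labels.append(cls)
        clf = SubprofileClassifier(threshold=threshold, task=fold.task).fit(
            pd.DataFrame(rows), labels
        )
        for split, ids in (("seen", fold.query_seen_ids), ("unseen", fold.query_unseen_ids)):
            ids = [i for i in ids if i in prof.index]
            if not ids:
                continue
            X = prof.loc[ids]
            scores = clf.decision_function(X)
            scores.index = ids
            relevance = pd.DataFrame(
                [
                    [int(cls in _labels_of(by_id[i], fold.task)) for cls in clf.classes_]
                    for i in ids
                ],
                index=ids,
                columns=clf.classes_,
            )
            results.append(FoldResult(fold.fold_id, fold.task, split, scores, relevance))
    return results
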