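"""Class-weighted random forests, grouped cross-validation, recursive feature
elimination with persistence scoring, and outlier-based protein selection.

The forest itself is scikit-learn's; everything around it (weighting, grouped
folds, MDI recomputed from the stored trees, the elimination/scoring loop) is
implemented here so each piece can be audited against its closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .cohort import SampleRecord


@dataclass(frozen=True)
class ForestParams:
    """Capacity and weighting configuration of one forest."""

    n_trees: int = 50
    max_depth: int = 3
    min_samples_leaf: int = 30
    class_weighting: str = "inverse_class_size"
    features_per_split: int | str = "sqrt"  # "sqrt" -> ceil(sqrt(n_features))
    bootstrap_rows: bool = True
    seed: int | None = None

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")

    def max_features(self, n_features: int) -> int:
        if self.features_per_split == "sqrt":
            return int(math.ceil(math.sqrt(n_features)))
        return min(int(self.features_per_split), n_features)


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of patients into near-equal folds (indices 1..n_folds)."""

    n_folds: int
    fold_of_patient: Mapping[str, int]

    def test_mask(self, records: Sequence[SampleRecord], fold: int) -> np.ndarray:
        return np.array([self.fold_of_patient[r.patient_id] == fold
                         for r in records])

    def iter_splits(self, records: Sequence[SampleRecord]
                    ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (train_indices, test_indices) row-index arrays per fold."""
        for fold in range(1, self.n_folds + 1):
            mask = self.test_mask(records, fold)
            yield np.where(~mask)[0], np.where(mask)[0]


@dataclass
class ProteinScoreTable:
    """Persistence scores summed over cycles, plus the selection flags."""

    score: dict[str, float]
    n_cycles: int = 30
    selected: dict[str, bool] = field(default_factory=dict)

    def top(self, n: int) -> list[str]:
        order = sorted(self.score, key=lambda k: (-self.score[k], k))
        return order[:n]


@dataclass
class RfecvResult:
    optimal_feature_count: int
    per_protein_cycle_score: dict[str, float]
    per_fold_balanced_accuracy: list[float]
    mean_accuracy_by_count: dict[int, float]


@dataclass
class ForestModel:
    """A fitted ensemble plus the metadata needed to audit it."""

    classifier: RandomForestClassifier
    feature_ids: list[str]
    params: ForestParams

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(np.asarray(X, dtype=float))

    @property
    def trees(self):
        return [est.tree_ for est in self.classifier.estimators_]


# -- elementary pieces --------------------------------------------------------


def gini_impurity(weight_per_class: Mapping[str, float]) -> float:
    """Sum over classes of p(1-p) with weighted relative frequencies p."""
    weights = np.array([float(w) for w in weight_per_class.values()])
    if np.any(weights < 0):
        raise ValueError("class weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total class weight must be positive")
    p = weights / total
    return float(np.sum(p * (1.0 - p)))


def class_weights(labels: Sequence[str]) -> np.ndarray:
    """Per-row weights inversely proportional to class size.

    Each class's total weight equals 1 before any common rescaling; rejects
    single-class inputs.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    count_of = dict(zip(classes, counts))
    return np.array([1.0 / count_of[lab] for lab in labels])


def grouped_kfold(records: Sequence[SampleRecord], n_folds: int = 20,
                  seed: int | None = None) -> FoldAssignment:
    """Randomly partition patients into folds whose sizes differ by <= 1."""
    patients = sorted({r.patient_id for r in records})
    if len(patients) < n_folds:
        raise ValueError(
            f"need at least {n_folds} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    fold_of = {patients[idx]: (pos % n_folds) + 1
               for pos, idx in enumerate(order)}
    return FoldAssignment(n_folds=n_folds, fold_of_patient=fold_of)


def balanced_accuracy(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    """Mean of per-class recalls; requires both classes in ``y_true``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    classes = np.unique(y_true)
    if len(classes) < 2:
        raise ValueError("y_true must contain both classes")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


def _fold_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    # lenient variant for small grouped test folds that may hold one class
    classes = np.unique(y_true)
    return float(np.mean([np.mean(y_pred[y_true == c] == c) for c in classes]))


# -- forest training and importances ------------------------------------------


def train_forest(X: np.ndarray, y: Sequence[str], weights: Sequence[float],
                 params: ForestParams,
                 feature_ids: Sequence[str] | None = None) -> ForestModel:
    """Fit the capacity-limited weighted ensemble.

    Row weights are rescaled so their total equals the row count; the leaf
    occupancy threshold is enforced both on raw counts and on the rescaled
    weighted counts (via ``min_weight_fraction_leaf``).
    """
    params.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    w = np.asarray(weights, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(w) != X.shape[0]:
        raise ValueError("X, y and weights must be row-aligned")
    n, p = X.shape
    if feature_ids is None:
        feature_ids = [str(j) for j in range(p)]
    w = w * (n / w.sum())
    clf = RandomForestClassifier(
        n_estimators=params.n_trees,
        criterion="gini",
        max_depth=params.max_depth,
        min_samples_leaf=params.min_samples_leaf,
        min_weight_fraction_leaf=min(0.5, params.min_samples_leaf / n),
        max_features=params.max_features(p),
        bootstrap=params.bootstrap_rows,
        random_state=None if params.seed is None else int(params.seed) % (2 ** 32),
        n_jobs=1,
    )
    clf.fit(X, y, sample_weight=w)
    return ForestModel(classifier=clf, feature_ids=list(feature_ids),
                       params=params)


def _mdi_array(model: ForestModel) -> np.ndarray:
    """Per-feature weighted impurity decrease, averaged over trees and
    normalized to sum to one when any split exists."""
    p = len(model.feature_ids)
    total = np.zeros(p)
    for tree in model.trees:
        imp = np.zeros(p)
        w_root = tree.weighted_n_node_samples[0]
        for node in range(tree.node_count):
            left = tree.children_left[node]
            right = tree.children_right[node]
            if left == -1:
                continue
            gain = (tree.weighted_n_node_samples[node] * tree.impurity[node]
                    - tree.weighted_n_node_samples[left] * tree.impurity[left]
                    - tree.weighted_n_node_samples[right] * tree.impurity[right])
            imp[tree.feature[node]] += gain / w_root
        total += imp
    total /= len(model.trees)
    s = total.sum()
    if s > 0:
        total = total / s
    return total


def mdi_importances(model: ForestModel) -> dict[str, float]:
    """Mean-decrease-in-impurity importances keyed by feature id."""
    return dict(zip(model.feature_ids, _mdi_array(model)))


def audit_forest(model: ForestModel) -> list[dict[str, float]]:
    """Post-hoc structural audit: depth and minimum leaf occupancy per tree."""
    out = []
    for est, tree in zip(model.classifier.estimators_, model.trees):
        leaves = tree.children_left == -1
        out.append({
            "depth": est.get_depth(),
            "min_leaf_rows": int(tree.n_node_samples[leaves].min()),
            "min_leaf_weight": float(tree.weighted_n_node_samples[leaves].min()),
        })
    return out


# -- recursive elimination with persistence scoring ---------------------------


def _n_to_remove(n_active: int, step: int | float | str,
                 importances: np.ndarray | None = None,
                 fine_from: int = 0) -> int:
    """Features to drop this round.

    ``step`` may be an absolute count, a fraction of the active set, or
    ``"auto"``: drop every feature the current forest assigned zero importance
    (at least one) — uninformative features then fall in the first rounds and
    persistence concentrates on features the forests keep using.  Once the
    active set is at or below ``fine_from`` features, elimination switches to
    one per round so the surviving candidates are resolved at full depth.
    """
    if step == "auto":
        if importances is None:
            raise ValueError("step='auto' needs the current importances")
        k = max(1, int(np.sum(importances == 0.0)))
    elif isinstance(step, float) and 0 < step < 1:
        k = int(math.ceil(step * n_active))
    else:
        k = int(step)
    if fine_from and n_active - k < fine_from:
        k = max(1, n_active - fine_from) if n_active > fine_from else 1
    return max(1, min(k, n_active - 1))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0])


def _eliminate(active: np.ndarray, importances: np.ndarray, k: int,
               tie_rank: np.ndarray) -> np.ndarray:
    """Drop the k lowest-importance features.

    Ties are broken by a fixed random rank drawn once per scoring run: a
    capacity-limited forest leaves a large mass of exactly-zero importances,
    and a shared arbitrary order spreads those features' persistence scores
    uniformly instead of piling them onto whichever features a per-round coin
    flip favours — a uniform background is exactly what the
    median + k*IQR outlier rule ignores."""
    order = np.lexsort((tie_rank[active], importances))
    drop = set(active[order[:k]])
    return np.array([j for j in active if j not in drop])


def rfecv_run(X: np.ndarray, y: Sequence[str], records: Sequence[SampleRecord],
              params: ForestParams, n_folds: int = 20,
              step: int | float | str = 1,
              feature_ids: Sequence[str] | None = None,
              count_rule: str = "1se",
              score_mode: str = "rounds",
              fine_from: int = 0,
              tie_rank: np.ndarray | None = None) -> RfecvResult:
    """One elimination cycle.

    Per fold, features are recursively eliminated on the training rows and the
    held-out balanced accuracy is recorded at every feature count; the optimal
    count maximises the mean held-out accuracy (ties go to the smaller count).

    Each feature's persistence score for the cycle counts the elimination
    rounds it survives once the surviving set has shrunk to the optimal count:
    features eliminated before that point score 0, every member of the first
    optimal-sized set scores at least 1, and a feature retained to the very
    end of a path scores that path's full post-optimum round count.  Scores
    are averaged over the per-fold elimination paths, which concentrates the
    background at zero and makes persistent features stand out as outliers.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 features")
    if feature_ids is None:
        feature_ids = [str(j) for j in range(p)]

    ss = np.random.SeedSequence(params.seed)
    fold_ss, tie_ss, *fit_ss = ss.spawn(2 + n_folds)
    if tie_rank is None:
        tie_rank = np.random.default_rng(tie_ss).permutation(p)
    folds = grouped_kfold(records, n_folds, seed=_seed_int(fold_ss))
    splits = list(folds.iter_splits(records))

    acc_by_count: dict[int, list[float]] = {}
    fold_acc_by_count: list[dict[int, float]] = []
    fold_counts: list[list[int]] = []
    survived = np.zeros((n_folds, p), dtype=int)
    for fold, ((train_idx, test_idx), fss) in enumerate(zip(splits, fit_ss)):
        w_train = class_weights(y[train_idx])
        active = np.arange(p)
        fold_curve: dict[int, float] = {}
        counts = [p]
        while True:
            fit_params = replace(params, seed=_seed_int(fss.spawn(1)[0]))
            model = train_forest(X[np.ix_(train_idx, active)], y[train_idx],
                                 w_train, fit_params)
            pred = model.predict(X[np.ix_(test_idx, active)])
            score = _fold_accuracy(y[test_idx], pred)
            fold_curve[len(active)] = score
            acc_by_count.setdefault(len(active), []).append(score)
            if len(active) == 1:
                break
            imp = _mdi_array(model)
            k = _n_to_remove(len(active), step, imp, fine_from)
            active = _eliminate(active, imp, k, tie_rank)
            survived[fold, active] += 1
            counts.append(len(active))
        fold_acc_by_count.append(fold_curve)
        fold_counts.append(counts)

    # elimination schedules may differ across folds (step="auto"), so evaluate
    # every candidate count per fold as a step function: the accuracy at count
    # c is the fold's accuracy at the largest evaluated count <= c
    grid = sorted(acc_by_count)
    per_fold_at = []
    for curve in fold_acc_by_count:
        own = sorted(curve)  # ascending counts this fold evaluated
        at = {}
        for c in grid:
            pos = np.searchsorted(own, c, side="right") - 1
            at[c] = curve[own[max(pos, 0)]]
        per_fold_at.append(at)
    mean_acc = {c: float(np.mean([at[c] for at in per_fold_at]))
                for c in grid}
    best_count = min(c for c, a in mean_acc.items()
                     if a == max(mean_acc.values()))
    if count_rule == "max":
        optimal = best_count
    elif count_rule == "1se":
        # smallest count within one standard error of the best mean accuracy;
        # a raw argmax drifts far into the flat part of the curve and lets
        # uninformative features into the post-optimum scoring zone
        vals = [at[best_count] for at in per_fold_at]
        se = (float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
              if len(vals) > 1 else 0.0)
        cutoff = mean_acc[best_count] - se
        optimal = min(c for c, a in mean_acc.items() if a >= cutoff)
    else:
        raise ValueError("count_rule must be 'max' or '1se'")

    if score_mode == "rounds":
        cycle_score = survived.sum(axis=0) / n_folds
    elif score_mode == "beyond_optimal":
        # per fold: rounds elapsed before that path's surviving set first
        # shrank to the optimal size; only later survival earns score
        beyond = np.zeros_like(survived)
        for fold, counts in enumerate(fold_counts):
            r_opt = next(t for t, c in enumerate(counts) if c <= optimal)
            beyond[fold] = np.clip(survived[fold] - max(0, r_opt - 1), 0, None)
        cycle_score = beyond.sum(axis=0) / n_folds
    else:
        raise ValueError("score_mode must be 'rounds' or 'beyond_optimal'")

    return RfecvResult(
        optimal_feature_count=int(optimal),
        per_protein_cycle_score={fid: float(s)
                                 for fid, s in zip(feature_ids, cycle_score)},
        per_fold_balanced_accuracy=[at[optimal] for at in per_fold_at],
        mean_accuracy_by_count=mean_acc,
    )


def accumulate_scores(X: np.ndarray, y: Sequence[str],
                      records: Sequence[SampleRecord], params: ForestParams,
                      n_folds: int = 20, n_cycles: int = 30,
                      step: int | float | str = 1,
                      feature_ids: Sequence[str] | None = None,
                      seed: int | None = None,
                      count_rule: str = "1se",
                      score_mode: str = "rounds",
                      fine_from: int = 0) -> ProteinScoreTable:
    """Sum persistence scores over ``n_cycles`` independent elimination cycles.

    Each cycle gets its own derived seed (fold assignment, row bootstraps and
    feature subsets all re-randomise); the master seed makes the whole table
    reproducible.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    p = np.asarray(X).shape[1]
    if feature_ids is None:
        feature_ids = [str(j) for j in range(p)]
    master = seed if seed is not None else params.seed
    master_ss = np.random.SeedSequence(master)
    tie_ss, *cycle_seeds = master_ss.spawn(1 + n_cycles)
    # one tie-break order for the whole run so features the forests never use
    # accumulate a uniform, outlier-free persistence baseline
    tie_rank = np.random.default_rng(tie_ss).permutation(np.asarray(X).shape[1])
    total: dict[str, float] = {fid: 0.0 for fid in feature_ids}
    for css in cycle_seeds:
        cycle_params = replace(params, seed=_seed_int(css))
        result = rfecv_run(X, y, records, cycle_params, n_folds=n_folds,
                           step=step, feature_ids=feature_ids,
                           count_rule=count_rule, score_mode=score_mode,
                           fine_from=fine_from, tie_rank=tie_rank)
        for fid, s in result.per_protein_cycle_score.items():
            total[fid] += s
    return ProteinScoreTable(score=total, n_cycles=n_cycles)


def select_outlier_proteins(table: ProteinScoreTable,
                            k: float = 1.5) -> set[str]:
    """Proteins whose score exceeds median + k * IQR of the score distribution."""
    ids = list(table.score)
    if len(ids) < 4:
        raise ValueError("need at least 4 scored proteins")
    scores = np.array([table.score[i] for i in ids])
    q25, med, q75 = np.percentile(scores, [25, 50, 75])
    threshold = med + k * (q75 - q25)
    selected = {i for i, s in zip(ids, scores) if s > threshold}
    table.selected = {i: (i in selected) for i in ids}
    return selected


def evaluate_final_classifier(X: np.ndarray, y: Sequence[str],
                              records: Sequence[SampleRecord],
                              params: ForestParams, n_folds: int = 20,
                              seed: int | None = None) -> float:
    """Grouped-CV mean balanced accuracy of a forest on the given features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] < 1:
        raise ValueError("selected feature set must be nonempty")
    ss = np.random.SeedSequence(seed if seed is not None else params.seed)
    fold_ss, *fit_ss = ss.spawn(1 + n_folds)
    folds = grouped_kfold(records, n_folds, seed=_seed_int(fold_ss))
    scores = []
    for (train_idx, test_idx), fss in zip(folds.iter_splits(records), fit_ss):
        w_train = class_weights(y[train_idx])
        model = train_forest(X[train_idx], y[train_idx], w_train,
                             replace(params, seed=_seed_int(fss)))
        scores.append(_fold_accuracy(y[test_idx], model.predict(X[test_idx])))
    return float(np.mean(scores))
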