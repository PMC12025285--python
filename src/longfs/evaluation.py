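"""Outer cross-validation, classification metrics and stability reporting.

Each outer fold is fully self-contained: features are standardized with
training-fold statistics, hypergraphs are built on training subjects only,
the solver is fitted and features selected on the training fold, kernel
mixing weights are tuned by inner CV on the training fold, and only then is
the held-out fold scored — no information flows from test subjects into the
fitted model.  Metrics are reported both pooled (from the summed confusion
matrix and pooled decision scores) and per fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import kernels as K
from . import solver as S

__all__ = [
    "MetricsReport",
    "StabilityReport",
    "FoldResult",
    "compute_metrics",
    "run_fold",
    "cross_validate",
    "ablation_run",
    "ablation_table",
    "sweep",
    "REGULARIZATION_GRID",
    "KNN_GRID",
]

# Default hyperparameter search sets for `sweep`.
REGULARIZATION_GRID = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0)
KNN_GRID = (3, 5, 7, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class MetricsReport:
    """Classification metrics as fractions in [0, 1].

    Pooled values come from the summed confusion matrix across folds and the
    pooled decision scores; ``per_fold`` carries the same metrics per outer
    fold (AUC is NaN for a fold whose truth is single-class).
    """

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    roc_points: np.ndarray
    per_fold: pd.DataFrame
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        s = 100.0 if percent else 1.0
        return {
            "accuracy": self.accuracy * s,
            "sensitivity": self.sensitivity * s,
            "specificity": self.specificity * s,
            "f1": self.f1 * s,
            "auc": self.auc,
        }


@dataclass(frozen=True)
class StabilityReport:
    """How often each feature was selected across outer folds."""

    counts: np.ndarray  # (M, d) selection counts per modality
    n_folds: int

    def top_k(self, k: int = 10, roi_names: list[str] | None = None) -> pd.DataFrame:
        """Top-k features by total selection count (count desc, index asc)."""
        total = self.counts.sum(axis=0)
        order = np.lexsort((np.arange(total.size), -total))[:k]
        df = pd.DataFrame({"feature": order, "count": total[order].astype(int)})
        if roi_names is not None:
            df["roi"] = [roi_names[j] for j in order]
        return df

    def as_frame(self, roi_names: list[str] | None = None) -> pd.DataFrame:
        M, d = self.counts.shape
        rows = []
        for m in range(M):
            for j in range(d):
                rows.append({"modality": m, "feature": j,
                             "count": int(self.counts[m, j])})
        df = pd.DataFrame(rows)
        if roi_names is not None:
            df["roi"] = [roi_names[j] for j in df["feature"]]
        return df


def _single_fold_metrics(y_true, y_pred, scores) -> dict[str, float]:
    y_true = np.asarray(y_true)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == -1)).sum())
    tn = int(((y_pred == -1) & (y_true == -1)).sum())
    fn = int(((y_pred == -1) & (y_true == 1)).sum())
    acc = (tp + tn) / max(1, tp + fp + tn + fn)
    sen = tp / (tp + fn) if tp + fn else np.nan
    spe = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    if len(set(np.unique(y_true))) == 2:
        fpr, tpr, _ = roc_curve(y_true, scores, pos_label=1)
        auc = float(np.trapezoid(tpr, fpr))
    else:
        auc = np.nan
    return dict(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=acc, sensitivity=sen,
                specificity=spe, f1=f1, auc=auc)


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray
) -> MetricsReport:
    """Accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP), F1 and
    trapezoidal AUC over the empirical ROC.  Positive class is +1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise ValueError("inputs must have equal length")
    if len(set(np.unique(y_true))) < 2:
        raise ValueError("AUC undefined: truth contains a single class")
    m = _single_fold_metrics(y_true, y_pred, scores)
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=1)
    return MetricsReport(
        accuracy=m["accuracy"], sensitivity=m["sensitivity"],
        specificity=m["specificity"], f1=m["f1"], auc=m["auc"],
        roc_points=np.column_stack([fpr, tpr]),
        per_fold=pd.DataFrame([m]),
        confusion=(m["tp"], m["fp"], m["tn"], m["fn"]),
    )


@dataclass
class FoldResult:
    """Everything one outer fold produced."""

    test_idx: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    selection: S.FeatureSelection
    mix_weights: np.ndarray
    solver_state: S.SolverState


def run_fold(
    data: S.CohortTable,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    hp: S.Hyperparams,
    seed: int = 0,
    weight_grid_step: float = 0.1,
    svm_c: float = 1.0,
    threshold: float = 1e-8,
    inner_folds: int = 10,
) -> FoldResult:
    """Fit on the training subjects and score the held-out subjects.

    Exposed so leakage properties can be checked directly: nothing in the
    fitted model depends on test-fold labels.
    """
    # standardize every cell on training statistics
    tr_cells, te_cells = {}, {}
    for key, X in data.features.items():
        mean, sd = S.zscore_fit(X[train_idx])
        tr_cells[key] = S.zscore_apply(X[train_idx], mean, sd)
        te_cells[key] = S.zscore_apply(X[test_idx], mean, sd)
    train = S.CohortTable(tr_cells, np.asarray(data.labels)[train_idx],
                          data.modality_names, data.timepoint_names,
                          data.feature_names)

    W, state = S.fit(train, hp, seed=seed)
    selection = S.select_features(W, threshold)
    if all(len(s) == 0 for s in selection.per_modality):
        # fully shrunk fit: fall back to all features so the fold still scores
        allf = tuple(range(data.n_features))
        selection = S.FeatureSelection(
            tuple(tuple((j, t) for j in allf for t in range(data.n_timepoints))
                  for _ in range(data.n_modalities)),
            tuple(allf for _ in range(data.n_modalities)),
        )

    train_vecs = K.modality_vectors(train, selection)
    clf = K.tune_and_train(train_vecs, train.labels, weight_grid_step,
                           C=svm_c, n_folds=inner_folds, seed=seed)

    test_tbl = S.CohortTable(te_cells, _dummy_labels(len(test_idx)),
                             data.modality_names, data.timepoint_names,
                             data.feature_names)
    test_vecs = K.modality_vectors(test_tbl, selection)
    cross = [K.linear_gram(tv, sv) for tv, sv in zip(train_vecs, test_vecs)]
    mixed = K.combine(cross, clf.mix_weights)
    y_pred, scores = K.predict(clf, mixed)
    return FoldResult(test_idx, y_pred, scores, selection, clf.mix_weights, state)


def _dummy_labels(n: int) -> np.ndarray:
    """Placeholder {-1,+1} vector so a test-only table passes validation."""
    y = -np.ones(n, dtype=int)
    y[: max(1, n // 2)] = 1
    return y


def cross_validate(
    data: S.CohortTable,
    hp: S.Hyperparams,
    folds: int = 10,
    seed: int = 0,
    weight_grid_step: float = 0.1,
    svm_c: float = 1.0,
    threshold: float = 1e-8,
    inner_folds: int = 10,
) -> tuple[MetricsReport, StabilityReport]:
    """Stratified outer CV of the full pipeline."""
    y = np.asarray(data.labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("too few subjects per class for the requested folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sel_counts = np.zeros((data.n_modalities, data.n_features), dtype=int)
    fold_rows = []
    y_pred_all = np.empty_like(y)
    scores_all = np.empty(y.size, dtype=float)
    for i, (tr, te) in enumerate(skf.split(np.zeros(y.size), y)):
        res = run_fold(data, tr, te, hp, seed=(seed * 1009 + i) % (2**31),
                       weight_grid_step=weight_grid_step, svm_c=svm_c,
                       threshold=threshold, inner_folds=inner_folds)
        y_pred_all[te] = res.y_pred
        scores_all[te] = res.scores
        for m, feats in enumerate(res.selection.per_modality):
            sel_counts[m, list(feats)] += 1
        fold_rows.append(_single_fold_metrics(y[te], res.y_pred, res.scores))

    pooled = _single_fold_metrics(y, y_pred_all, scores_all)
    fpr, tpr, _ = roc_curve(y, scores_all, pos_label=1)
    report = MetricsReport(
        accuracy=pooled["accuracy"], sensitivity=pooled["sensitivity"],
        specificity=pooled["specificity"], f1=pooled["f1"], auc=pooled["auc"],
        roc_points=np.column_stack([fpr, tpr]),
        per_fold=pd.DataFrame(fold_rows),
        confusion=(pooled["tp"], pooled["fp"], pooled["tn"], pooled["fn"]),
    )
    return report, StabilityReport(sel_counts, folds)


def ablation_run(
    data: S.CohortTable,
    hp: S.Hyperparams,
    which: set[str],
    seed: int = 0,
    **cv_kwargs,
) -> MetricsReport:
    """Cross-validate with the named regularization weights forced to 0.

    ``which`` is a subset of {"beta", "lam", "mu"}.
    """
    bad = set(which) - {"beta", "lam", "mu"}
    if bad:
        raise ValueError(f"unknown coefficients: {sorted(bad)}")
    hp0 = hp.replace(**{name: 0.0 for name in which})
    report, _ = cross_validate(data, hp0, seed=seed, **cv_kwargs)
    return report


# The four regularization configurations compared in the ablation study:
# no regularization, group sparsity only, group + hypergraph, full model.
ABLATION_CONFIGS: dict[str, set[str]] = {
    "none": {"beta", "lam", "mu"},
    "group_sparsity": {"lam", "mu"},
    "group+hypergraph": {"mu"},
    "full": set(),
}


def ablation_table(
    data: S.CohortTable, hp: S.Hyperparams, seed: int = 0, **cv_kwargs
) -> pd.DataFrame:
    """Tidy comparison of the four regularization configurations."""
    rows = []
    for name, zeroed in ABLATION_CONFIGS.items():
        rep = ablation_run(data, hp, zeroed, seed=seed, **cv_kwargs)
        rows.append({"config": name, **rep.as_dict()})
    return pd.DataFrame(rows)


def sweep(
    data: S.CohortTable,
    grid: dict[str, list] | None = None,
    seed: int = 0,
    hp: S.Hyperparams | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """Exhaustive hyperparameter grid evaluation.

    ``grid`` maps any of {"beta", "lam", "mu", "k"} to candidate values;
    omitted names fall back to the defaults: the ten-point regularization
    set for beta/lam/mu and the eight-point neighbour set for k.  The full
    default product is 8000 cross-validations — pass smaller grids for
    routine use.
    """
    grid = dict(grid or {})
    grid.setdefault("beta", list(REGULARIZATION_GRID))
    grid.setdefault("lam", list(REGULARIZATION_GRID))
    grid.setdefault("mu", list(REGULARIZATION_GRID))
    grid.setdefault("k", list(KNN_GRID))
    base = hp or S.Hyperparams()
    rows = []
    for beta in grid["beta"]:
        for lam in grid["lam"]:
            for mu in grid["mu"]:
                for k in grid["k"]:
                    hp_i = base.replace(beta=beta, lam=lam, mu=mu, k=int(k))
                    rep, _ = cross_validate(data, hp_i, seed=seed, **cv_kwargs)
                    rows.append({"beta": beta, "lam": lam, "mu": mu, "k": k,
                                 **rep.as_dict()})
    return pd.DataFrame(rows)
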