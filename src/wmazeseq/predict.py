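"""Trial-by-trial classifiers.

Choice from per-trial theta-sequence counts (actual vs alternative) and
correct/incorrect outcome from pre-trial reactivation strength, both with
RBF-kernel C-SVMs, random-search hyperparameter selection under
leave-one-out cross-validation, and trial-label permutation nulls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneGroupOut, LeaveOneOut
from sklearn.svm import SVC

N_HYPER_DRAWS = 50
C_RANGE = (1e-2, 1e3)
GAMMA_RANGE = (1e-3, 1e1)
N_PERMUTATIONS = 500


def _loo_predictions(X: np.ndarray, y: np.ndarray, C: float, gamma: float) -> np.ndarray:
    pred = np.empty(len(y), dtype=y.dtype)
    for train, test in LeaveOneOut().split(X):
        if len(np.unique(y[train])) < 2:
            pred[test] = y[train][0]
            continue
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(X[train], y[train])
        pred[test] = clf.predict(X[test])
    return pred


def _random_search_loo(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
    n_draws: int = N_HYPER_DRAWS,
) -> Tuple[float, float, float]:
    """(best accuracy, best C, best gamma) under leave-one-out."""
    logc = rng.uniform(np.log10(C_RANGE[0]), np.log10(C_RANGE[1]), n_draws)
    logg = rng.uniform(np.log10(GAMMA_RANGE[0]), np.log10(GAMMA_RANGE[1]), n_draws)
    best = (-np.inf, 1.0, 1.0)
    for C, g in zip(10.0**logc, 10.0**logg):
        acc = float(np.mean(_loo_predictions(X, y, C, g) == y))
        if acc > best[0]:
            best = (acc, C, g)
    return best


@dataclass
class ChoicePredictionResult:
    accuracy: float
    C: float
    gamma: float
    p_value: float
    null_accuracies: np.ndarray
    chance_band: Tuple[float, float]   # 2.5/97.5 percentiles of the null
    n_trials: int
    nested_accuracy: float = np.nan    # robustness check, not headline

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


def predict_choice(
    features: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = N_PERMUTATIONS,
    seed: int = 0,
    min_trials: int = 10,
    nested: bool = False,
) -> ChoicePredictionResult:
    """RBF C-SVM leave-one-out choice prediction with a permutation null.

    ``features`` is (n_trials, 2): counts of sequences representing the
    actual vs the alternative choice; ``labels`` the chosen side.
    The reported accuracy shares one leave-one-out loop between
    hyperparameter selection and evaluation (as printed); ``nested=True``
    additionally reports a nested-CV accuracy whose hyperparameters are
    re-selected inside each outer fold (robustness output).
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    if len(y) < min_trials:
        raise ValueError(f"need >= {min_trials} usable trials, got {len(y)}")
    rng = np.random.default_rng(seed)
    acc, C, gamma = _random_search_loo(X, y, rng)

    nested_acc = np.nan
    if nested:
        hits = 0
        for train, test in LeaveOneOut().split(X):
            _, Ci, gi = _random_search_loo(
                X[train], y[train], np.random.default_rng(seed), n_draws=20
            )
            clf = SVC(C=Ci, gamma=gi, kernel="rbf")
            clf.fit(X[train], y[train])
            hits += int(clf.predict(X[test])[0] == y[test][0])
        nested_acc = hits / len(y)

    null = np.empty(n_permutations)
    for i in range(n_permutations):
        yp = rng.permutation(y)
        if len(np.unique(yp)) < 2:
            null[i] = np.nan
            continue
        null[i] = float(np.mean(_loo_predictions(X, yp, C, gamma) == yp))
    ok = np.isfinite(null)
    p = float((np.sum(null[ok] >= acc) + 1) / (ok.sum() + 1))
    lo, hi = np.percentile(null[ok], [2.5, 97.5])
    return ChoicePredictionResult(
        accuracy=acc, C=C, gamma=gamma, p_value=p,
        null_accuracies=null[ok], chance_band=(float(lo), float(hi)),
        n_trials=len(y), nested_accuracy=nested_acc,
    )


@dataclass
class OutcomePredictionResult:
    auc: float
    p_value: float
    null_aucs: np.ndarray
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    n_correct: int
    n_incorrect: int

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


def predict_outcome(
    features: np.ndarray,
    correct: np.ndarray,
    n_permutations: int = N_PERMUTATIONS,
    seed: int = 0,
    min_incorrect: int = 5,
) -> OutcomePredictionResult:
    """Correct/incorrect prediction from reactivation features via ROC/AUC.

    Incorrect trials are resampled with replacement to match the correct
    count before training.  Cross-validation leaves out all copies of one
    original trial at a time (group-aware), so resampled duplicates never
    straddle the train/test split; AUC comes from the held-out decision
    values and is compared to trial-label permutations (permuted at the
    original-trial level).
    """
    X = np.asarray(features, float)
    y = np.asarray(correct, bool)
    n_inc = int((~y).sum())
    if n_inc == 0:
        raise ValueError("no incorrect trials")
    if n_inc < min_incorrect:
        raise ValueError(f"need >= {min_incorrect} incorrect trials, got {n_inc}")
    rng = np.random.default_rng(seed)

    idx_cor = np.flatnonzero(y)
    idx_inc = np.flatnonzero(~y)
    res_inc = rng.choice(idx_inc, size=len(idx_cor), replace=True)
    idx = np.concatenate([idx_cor, res_inc])      # rows of the balanced set
    groups = idx                                   # original-trial identity
    Xb = X[idx]
    uniq = np.unique(groups)

    def _scores_for(labels_by_trial: dict) -> Tuple[np.ndarray, np.ndarray]:
        yb = np.array([labels_by_trial[g] for g in groups], dtype=int)
        scores = np.empty(len(yb))
        for train, test in LeaveOneGroupOut().split(Xb, yb, groups):
            if len(np.unique(yb[train])) < 2:
                scores[test] = 0.0
                continue
            clf = SVC(C=C, gamma=gamma, kernel="rbf")
            clf.fit(Xb[train], yb[train])
            scores[test] = clf.decision_function(Xb[test])
        return yb, scores

    true_labels = {g: int(y[g]) for g in uniq}
    yb_true = np.array([true_labels[g] for g in groups], dtype=int)
    _, C, gamma = _random_search_loo(Xb, yb_true, rng)

    yb, scores = _scores_for(true_labels)
    auc = float(roc_auc_score(yb, scores))
    fpr, tpr, _ = roc_curve(yb, scores)

    null = np.empty(n_permutations)
    trial_labels = np.array([true_labels[g] for g in uniq])
    for i in range(n_permutations):
        perm = dict(zip(uniq, rng.permutation(trial_labels)))
        yp = np.array([perm[g] for g in groups], dtype=int)
        if len(np.unique(yp)) < 2:
            null[i] = np.nan
            continue
        _, sc = _scores_for(perm)
        null[i] = float(roc_auc_score(yp, sc))
    ok = np.isfinite(null)
    p = float((np.sum(null[ok] >= auc) + 1) / (ok.sum() + 1))
    return OutcomePredictionResult(
        auc=auc, p_value=p, null_aucs=null[ok], roc_fpr=fpr, roc_tpr=tpr,
        n_correct=len(idx_cor), n_incorrect=n_inc,
    )
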