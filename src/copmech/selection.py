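"""Forward feature selection with nested cross-validation and resampling.

The wrapper approach: starting from an empty set, greedily add the
feature whose inclusion maximizes inner cross-validated accuracy of a
small classifier (logistic regression or KNN), stopping at a target size
(default 3). All folding and resampling is blocked at the subject level
so that the pre and post sessions of one subject never straddle a
train/test split. Generalization is assessed three ways:

* nested CV — selection is re-run inside every outer training fold and
  scored on the held-out subject(s);
* case bootstrap — out-of-fold predictions are resampled (by subject) to
  give percentile confidence intervals for accuracy / F1 / AUC;
* permutation test — subject labels are permuted and the cross-validated
  accuracy recomputed, p = (1 + #{perm >= obs}) / (B + 1).

Discriminative adequacy of a selected set is summarized by McFadden's
pseudo-R^2 of a logistic fit, 1 - lnL(model)/lnL(intercept-only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as sps
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neighbors import KNeighborsClassifier

from .features import FeatureTable

__all__ = [
    "ClassifierSpec", "SelectionResult", "ValidationReport",
    "forward_select", "nested_cv_evaluate", "bootstrap_metrics",
    "permutation_test", "mcfadden_r2",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Wrapper classifier: 'logistic_regression' (C) or 'k_nearest_neighbors' (k)."""

    kind: str = "logistic_regression"
    C: float = 1.0
    k: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("logistic_regression", "k_nearest_neighbors"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "k_nearest_neighbors" and (self.k < 1 or self.k % 2 == 0):
            raise ValueError("KNN neighbor count must be odd and >= 1")

    def build(self):
        if self.kind == "logistic_regression":
            return LogisticRegression(C=self.C, max_iter=1000)
        return KNeighborsClassifier(n_neighbors=self.k)


@dataclass
class SelectionResult:
    features: list[str]
    score_trace: list[float]
    spec: ClassifierSpec
    tie_log: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    metrics: dict[str, float]
    metric_sds: dict[str, float] = field(default_factory=dict)
    cis: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_value: float | None = None
    fold_scores: np.ndarray | None = None
    n_replicates: int = 0
    n_redrawn: int = 0
    seed: int = 0


def _as_xy(table, labels, selected=None):
    if hasattr(table, "df"):  # FeatureTable or any table-like with a df
        df = table.df
        X = df[selected].to_numpy(float) if selected else df.to_numpy(float)
        groups = np.asarray([ix[0] for ix in df.index])
        cols = list(selected or df.columns)
    else:
        X = np.asarray(table, float)
        groups = np.arange(len(X)).astype(str)
        cols = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ValueError("labels and table length differ")
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    return X, y, groups, cols


def _knn_fold_accuracy(X, y, tr, te, k) -> float:
    """Brute-force uniform-weight KNN accuracy for one fold.

    Equivalent to :class:`~sklearn.neighbors.KNeighborsClassifier` with
    odd k on binary labels (no vote ties); vectorized for the tight
    permutation loop.
    """
    Xtr, Xte = X[tr], X[te]
    d2 = (
        np.sum(Xte * Xte, axis=1)[:, None]
        + np.sum(Xtr * Xtr, axis=1)[None, :]
        - 2.0 * Xte @ Xtr.T
    )
    kk = min(k, len(Xtr))
    nn = np.argpartition(d2, kk - 1, axis=1)[:, :kk]
    votes = y[tr][nn].mean(axis=1)
    pred = (votes > 0.5).astype(y.dtype)
    return float(np.mean(pred == y[te]))


def _grouped_cv_accuracy(X, y, groups, spec, n_splits, seed) -> float:
    """Mean accuracy over subject-blocked stratified folds."""
    uniq = np.unique(groups)
    n_splits = min(n_splits, len(uniq))
    if n_splits < 2:
        raise ValueError("need at least two subject groups for CV")
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    classes = np.unique(y)
    scores = []
    for tr, te in cv.split(X, y, groups):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold contains a single class")
        if spec.kind == "k_nearest_neighbors" and len(classes) == 2:
            y01 = (y == classes[1]).astype(int)
            scores.append(_knn_fold_accuracy(X, y01, tr, te, spec.k))
        else:
            model = spec.build().fit(X[tr], y[tr])
            scores.append(accuracy_score(y[te], model.predict(X[te])))
    return float(np.mean(scores))


def forward_select(
    table,
    labels,
    spec: ClassifierSpec = ClassifierSpec(),
    target_size: int = 3,
    inner_cv: int = 3,
    seed: int = 0,
) -> SelectionResult:
    """Greedy forward selection maximizing inner-CV accuracy.

    Ties are broken by column order and logged.
    """
    X, y, groups, cols = _as_xy(table, labels)
    if target_size > len(cols):
        raise ValueError("target_size exceeds the number of features")
    selected: list[int] = []
    trace: list[float] = []
    tie_log: list[str] = []
    remaining = list(range(len(cols)))
    for _ in range(target_size):
        scores = np.array([
            _grouped_cv_accuracy(X[:, selected + [j]], y, groups, spec,
                                 inner_cv, seed)
            for j in remaining
        ])
        best = float(scores.max())
        winners = [remaining[i] for i in np.nonzero(scores == best)[0]]
        if len(winners) > 1:
            tie_log.append(
                f"step {len(selected) + 1}: tie at accuracy {best:.4f} among "
                f"{[cols[w] for w in winners]}; kept {cols[winners[0]]}")
        pick = winners[0]
        selected.append(pick)
        remaining.remove(pick)
        trace.append(best)
    return SelectionResult(features=[cols[i] for i in selected],
                           score_trace=trace, spec=spec, tie_log=tie_log)


def nested_cv_evaluate(
    table,
    labels,
    spec: ClassifierSpec = ClassifierSpec(),
    target_size: int = 3,
    inner_cv: int = 3,
    outer_cv: str | int = "loso",
    seed: int = 0,
) -> ValidationReport:
    """Nested CV: selection re-run inside each outer training fold.

    ``outer_cv='loso'`` leaves one subject out per fold; an integer gives
    subject-blocked stratified k-fold instead.
    """
    X, y, groups, cols = _as_xy(table, labels)
    uniq = np.unique(groups)
    if outer_cv == "loso":
        folds = [(groups != g, groups == g) for g in uniq]
    else:
        cv = StratifiedGroupKFold(n_splits=int(outer_cv), shuffle=True,
                                  random_state=seed)
        folds = [(np.isin(np.arange(len(y)), tr), np.isin(np.arange(len(y)), te))
                 for tr, te in cv.split(X, y, groups)]
    scores = []
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("an outer training fold contains a single class")
        sel = forward_select(
            _SubTable(X[tr], cols, groups[tr]), y[tr], spec=spec,
            target_size=target_size, inner_cv=inner_cv, seed=seed)
        idx = [cols.index(f) for f in sel.features]
        model = spec.build().fit(X[tr][:, idx], y[tr])
        scores.append(accuracy_score(y[te], model.predict(X[te][:, idx])))
    scores = np.array(scores)
    return ValidationReport(
        metrics={"accuracy": float(scores.mean())},
        metric_sds={"accuracy": float(scores.std(ddof=1)) if len(scores) > 1 else 0.0},
        fold_scores=scores, seed=seed,
    )


class _SubTable:
    """Array-backed stand-in exposing the FeatureTable interface bits
    the selection loop needs (matrix + subject groups)."""

    def __init__(self, X, cols, groups):
        import pandas as pd

        self.df = pd.DataFrame(
            X, columns=cols,
            index=pd.MultiIndex.from_arrays(
                [groups, ["s"] * len(X)], names=["subject_id", "session"]),
        )


def _oof_predictions(X, y, groups, spec, seed):
    """Leave-one-subject-out out-of-fold class probabilities."""
    proba = np.empty(len(y), float)
    for g in np.unique(groups):
        tr, te = groups != g, groups == g
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold contains a single class")
        model = spec.build().fit(X[tr], y[tr])
        if hasattr(model, "predict_proba"):
            proba[te] = model.predict_proba(X[te])[:, 1]
        else:
            proba[te] = model.predict(X[te])
    return proba


def _metric_values(y, proba) -> dict[str, float]:
    pred = (proba >= 0.5).astype(int)
    out = {"accuracy": float(accuracy_score(y, pred)),
           "f1": float(f1_score(y, pred, zero_division=0))}
    if len(np.unique(y)) == 2:
        out["auc"] = float(roc_auc_score(y, proba))
    return out


def bootstrap_metrics(
    table,
    labels,
    spec: ClassifierSpec = ClassifierSpec(),
    selected: list[str] | None = None,
    B: int = 1000,
    seed: int = 0,
    max_redraw_factor: int = 20,
) -> ValidationReport:
    """Subject-level case bootstrap of out-of-fold evaluation metrics.

    Out-of-fold probabilities come from leave-one-subject-out fits on the
    full data; each replicate resamples subjects with replacement and
    recomputes accuracy/F1/AUC. Single-class resamples are redrawn
    (counted, capped at ``max_redraw_factor * B`` total draws).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X, y, groups, cols = _as_xy(table, labels, selected)
    proba = _oof_predictions(X, y, groups, spec, seed)
    point = _metric_values(y, proba)
    rng = np.random.default_rng(seed)
    uniq = np.unique(groups)
    by_subject = {g: np.nonzero(groups == g)[0] for g in uniq}
    reps: dict[str, list[float]] = {k: [] for k in point}
    redrawn, draws = 0, 0
    while len(reps["accuracy"]) < B:
        draws += 1
        if draws > max_redraw_factor * B:
            raise RuntimeError("too many single-class bootstrap redraws")
        pick = rng.choice(uniq, size=len(uniq), replace=True)
        idx = np.concatenate([by_subject[g] for g in pick])
        if len(np.unique(y[idx])) < 2:
            redrawn += 1
            continue
        for k, v in _metric_values(y[idx], proba[idx]).items():
            reps[k].append(v)
    cis = {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
           for k, v in reps.items()}
    return ValidationReport(metrics=point, cis=cis, n_replicates=B,
                            n_redrawn=redrawn, seed=seed)


def _loso_knn_proba_matrix(X, groups, label_matrix, k) -> np.ndarray:
    """Leave-one-subject-out KNN vote fractions for many label vectors.

    The neighbor structure depends only on X (same-subject columns are
    excluded), so every row of ``label_matrix`` — each a label assignment
    over samples — shares one argsort. Returns (n_rows, n_samples) vote
    fractions.
    """
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(X * X, axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    same = groups[:, None] == groups[None, :]
    d2[same] = np.inf
    kk = min(k, len(X) - same.sum(axis=1).max())
    nn = np.argsort(d2, axis=1)[:, :kk]
    return label_matrix[:, nn].mean(axis=2)


def _auc_rows(label_matrix, score_matrix) -> np.ndarray:
    """Mann-Whitney AUC per row via midranks (tie-aware)."""
    r = sps.rankdata(score_matrix, axis=1)
    pos = label_matrix == 1
    n1 = pos.sum(axis=1)
    n0 = label_matrix.shape[1] - n1
    rank_sum = np.where(pos, r, 0.0).sum(axis=1)
    return (rank_sum - n1 * (n1 + 1) / 2) / (n1 * n0)


def permutation_test(
    table,
    labels,
    spec: ClassifierSpec = ClassifierSpec(),
    selected: list[str] | None = None,
    B: int = 199,
    seed: int = 0,
    cv: int | str = 3,
    metric: str = "accuracy",
) -> float:
    """Permutation p-value: p = (1 + #{permuted metric >= observed}) / (B + 1).

    Labels are permuted at the subject level (sessions move together).
    The statistic is the subject-blocked cross-validated metric:
    ``metric='accuracy'`` with ``cv=<k>`` stratified folds, or
    ``metric='auc'`` of leave-one-subject-out (``cv='loso'``) out-of-fold
    vote fractions / probabilities. The AUC statistic is nearly tie-free,
    which keeps the test close to exact at small n; the KNN + LOSO
    combination is evaluated in one vectorized pass because the neighbor
    structure does not depend on the labels.
    """
    if B < 19:
        raise ValueError("B must be >= 19 for a meaningful p-value")
    X, y, groups, cols = _as_xy(table, labels, selected)
    rng = np.random.default_rng(seed)
    uniq = np.unique(groups)
    subj_label = np.array([y[groups == g][0] for g in uniq])
    classes = np.unique(y)

    if cv == "loso" and spec.kind == "k_nearest_neighbors":
        # vectorized: identity assignment first, then B permutations
        subj01 = (subj_label == classes[1]).astype(int)
        perms = np.vstack([subj01] + [rng.permutation(subj01) for _ in range(B)])
        pos = {g: np.nonzero(groups == g)[0] for g in uniq}
        label_matrix = np.empty((B + 1, len(y)), int)
        for gi, g in enumerate(uniq):
            label_matrix[:, pos[g]] = perms[:, gi][:, None]
        proba = _loso_knn_proba_matrix(X, groups, label_matrix, spec.k)
        if metric == "auc":
            stat = _auc_rows(label_matrix, proba)
        elif metric == "accuracy":
            stat = np.mean((proba > 0.5).astype(int) == label_matrix, axis=1)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        return float((1 + np.sum(stat[1:] >= stat[0])) / (B + 1))

    def statistic(y_vec):
        if cv == "loso":
            proba = _oof_predictions(X, y_vec, groups, spec, seed)
            if metric == "auc":
                return float(_auc_rows(y_vec[None, :] == classes[1],
                                       proba[None, :])[0])
            return float(np.mean((proba >= 0.5) == (y_vec == classes[1])))
        if metric != "accuracy":
            raise ValueError("fold-based permutation supports metric='accuracy'")
        return _grouped_cv_accuracy(X, y_vec, groups, spec, int(cv), seed)

    observed = statistic(y)
    count = 0
    for _ in range(B):
        perm = rng.permutation(subj_label)
        y_perm = np.empty_like(y)
        for g, lab in zip(uniq, perm):
            y_perm[groups == g] = lab
        try:
            score = statistic(y_perm)
        except ValueError:
            # single-class fold under an extreme permutation: no evidence
            # against the null from this draw
            score = observed
        if score >= observed:
            count += 1
    return (1 + count) / (B + 1)


def mcfadden_r2(table, labels, selected: list[str] | None = None
                ) -> tuple[float, bool]:
    """McFadden pseudo-R^2 = 1 - lnL(model) / lnL(intercept-only).

    Returns ``(value, separable_flag)``. Under (quasi-)perfect separation
    the unpenalized likelihood is unbounded; the fit is then replaced by
    a lightly ridge-penalized one and flagged.
    """
    X, y, groups, cols = _as_xy(table, labels, selected)
    y01 = (y == np.unique(y)[1]).astype(float)
    p0 = y01.mean()
    ll0 = float(len(y01) * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))
    flag = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y01, sm.add_constant(X)).fit(disp=0, maxiter=200)
            llm = float(fit.llf)
            if not np.isfinite(llm) or np.any(np.abs(fit.params) > 50):
                raise RuntimeError("separation suspected")
        except Exception:
            flag = True
            model = LogisticRegression(C=1.0, max_iter=1000).fit(X, y01)
            proba = np.clip(model.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
            llm = float(np.sum(y01 * np.log(proba) + (1 - y01) * np.log(1 - proba)))
    return 1.0 - llm / ll0, flag
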