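"""At-risk vs control classification with nested cross-validation.

A random forest distinguishes genetically at-risk subjects from age-matched
controls using the static and dynamic network features.  The protocol is
leakage-free nested CV: an outer stratified 5-fold split estimates
generalization from pooled out-of-fold probabilities, while inner 5-fold
splits tune hyperparameters (randomized search) and select features
(top-k by impurity importance, k chosen by inner ROC AUC).  AUC confidence
intervals use DeLong's structural-components variance for ROC and a
stratified bootstrap for PR.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_curve, roc_curve
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold, cross_val_score

__all__ = [
    "FeatureTable",
    "ClassifierReport",
    "assemble_features",
    "match_controls",
    "nested_cv_classify",
    "roc_pr_confusion",
    "delong_ci",
    "mann_whitney_auc",
]


@dataclass
class FeatureTable:
    """Feature matrix with namespaced column names and binary labels."""

    matrix: np.ndarray  # (N, D)
    feature_names: list
    labels: np.ndarray  # (N,) 0 = control, 1 = at-risk
    subject_ids: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite feature values after assembly")
        if len(self.feature_names) != len(set(self.feature_names)):
            raise ValueError("duplicate feature names")
        if self.matrix.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if any(n in {"label", "labels", "subject", "subject_id"} for n in self.feature_names):
            raise ValueError("label/id columns must not appear among features")


@dataclass
class ClassifierReport:
    oof_probabilities: np.ndarray
    labels: np.ndarray
    roc_points: np.ndarray  # (n, 2): FPR, TPR
    pr_points: np.ndarray  # (n, 2): recall, precision
    roc_auc: float
    roc_ci: tuple
    pr_auc: float
    pr_ci: tuple
    confusion: np.ndarray  # 2x2 at threshold 0.5
    sensitivity: float
    specificity: float
    selected_features: list = field(default_factory=list)  # per outer fold
    train_index_hashes: list = field(default_factory=list)
    seed: int | None = None


def _pivot(table: pd.DataFrame, index_cols: list, value_col: str, prefix: str) -> pd.DataFrame:
    wide = table.pivot_table(index="subject", columns=index_cols, values=value_col)
    wide.columns = [
        f"{prefix}:" + ":".join(str(c) for c in (col if isinstance(col, tuple) else (col,)))
        for col in wide.columns
    ]
    return wide


def assemble_features(
    power: pd.DataFrame | None = None,
    shape: pd.DataFrame | None = None,
    dyn_summary: pd.DataFrame | None = None,
    dyn_pairs: pd.DataFrame | None = None,
    dyn_connectedness: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
) -> FeatureTable:
    """Concatenate the metric tables into one namespaced feature matrix.

    Inputs are the tidy frames produced by the spectral and dynamics
    stages; ``labels`` is a subject-indexed binary series.  Subjects must
    be present in every supplied table; the column order is deterministic.
    """
    blocks = []
    if power is not None:
        blocks.append(_pivot(power, ["band", "parcel"], "power", "power"))
    if shape is not None:
        sh = shape.melt(
            id_vars=["subject", "parcel"],
            value_vars=["exponent", "coe"],
            var_name="metric",
        )
        blocks.append(_pivot(sh, ["metric", "parcel"], "value", "shape"))
    if dyn_summary is not None:
        value_vars = ["strength", "variability", "concentration"]
        if "coactivation_mean" in dyn_summary.columns:
            value_vars.append("coactivation_mean")
        sm = dyn_summary.melt(
            id_vars=["subject", "mode"], value_vars=value_vars, var_name="metric"
        )
        blocks.append(_pivot(sm, ["metric", "mode"], "value", "dyn"))
    if dyn_pairs is not None:
        blocks.append(_pivot(dyn_pairs, ["mode_a", "mode_b"], "coactivation", "coact"))
    if dyn_connectedness is not None:
        blocks.append(
            _pivot(dyn_connectedness, ["mode", "parcel"], "connectedness", "dconn")
        )
    if not blocks:
        raise ValueError("no feature tables supplied")
    if labels is None:
        raise ValueError("labels are required")
    subjects = sorted(labels.index)
    for b in blocks:
        missing = set(subjects) - set(b.index)
        if missing:
            raise ValueError(f"subject(s) missing from a feature table: {sorted(missing)}")
    wide = pd.concat([b.loc[subjects] for b in blocks], axis=1)
    wide = wide[sorted(wide.columns)]
    return FeatureTable(
        matrix=wide.to_numpy(dtype=float),
        feature_names=list(wide.columns),
        labels=labels.loc[subjects].to_numpy(dtype=int),
        subject_ids=subjects,
    )


def match_controls(
    hc_ages: np.ndarray,
    risk_ages: np.ndarray,
    n_controls: int = 40,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Greedy nearest-age control selection without replacement.

    Cycles through the at-risk ages (in seeded random order) picking the
    nearest unused control until ``n_controls`` are chosen, then runs
    swap-refinement sweeps that exchange a chosen control for an unused one
    whenever that shrinks the absolute mean-age difference.  Returns the
    chosen control indices and the resulting mean-age difference.
    """
    hc_ages = np.asarray(hc_ages, dtype=float)
    risk_ages = np.asarray(risk_ages, dtype=float)
    if n_controls > hc_ages.size:
        raise ValueError("target exceeds the control pool")
    rng = np.random.default_rng(seed)
    order = rng.permutation(risk_ages.size)
    available = np.ones(hc_ages.size, dtype=bool)
    chosen: list[int] = []
    i = 0
    while len(chosen) < n_controls:
        target = risk_ages[order[i % order.size]]
        idx_avail = np.flatnonzero(available)
        pick = idx_avail[np.argmin(np.abs(hc_ages[idx_avail] - target))]
        chosen.append(int(pick))
        available[pick] = False
        i += 1
    risk_mean = risk_ages.mean()
    for _ in range(20):
        improved = False
        cur = abs(hc_ages[chosen].mean() - risk_mean)
        for ci, c in enumerate(list(chosen)):
            for u in np.flatnonzero(available):
                trial = chosen.copy()
                trial[ci] = int(u)
                new = abs(hc_ages[trial].mean() - risk_mean)
                if new < cur - 1e-12:
                    available[u] = False
                    available[c] = True
                    chosen = trial
                    cur = new
                    improved = True
        if not improved:
            break
    chosen_arr = np.asarray(sorted(chosen))
    diff = float(hc_ages[chosen_arr].mean() - risk_mean)
    return chosen_arr, diff


DEFAULT_PARAM_SPACE = {
    "n_estimators": [50, 100, 200, 300],
    "max_depth": [None, 4, 8, 16, 32],
    "max_features": ["sqrt", "log2", 0.2, 0.5],
}


def nested_cv_classify(
    ft: FeatureTable,
    seed: int = 0,
    n_outer: int = 5,
    n_inner: int = 5,
    n_search_iter: int = 15,
    feature_k: tuple = (8, 16, 32, 64, 128, None),
    param_space: dict | None = None,
) -> ClassifierReport:
    """Nested cross-validated random forest with feature selection.

    Within each outer training fold: randomized hyperparameter search
    scored by inner ROC AUC with balanced class weights, then impurity
    importances rank the features and the best top-k subset (by inner AUC)
    is kept.  The tuned model predicts its held-out outer fold; pooled
    out-of-fold probabilities yield the report.
    """
    if param_space is None:
        param_space = DEFAULT_PARAM_SPACE
    X, y = ft.matrix, ft.labels
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    oof = np.full(y.shape, np.nan)
    selected_all, hashes = [], []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        if len(np.unique(y[tr])) != 2 or len(np.unique(y[te])) != 2:
            raise ValueError("a class is absent from an outer fold")
        hashes.append(hashlib.sha256(tr.tobytes()).hexdigest())
        inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed + fold)
        base = RandomForestClassifier(
            class_weight="balanced", random_state=seed + fold, n_jobs=1
        )
        search = RandomizedSearchCV(
            base,
            param_space,
            n_iter=n_search_iter,
            scoring="roc_auc",
            cv=inner,
            random_state=seed + fold,
            n_jobs=1,
        )
        search.fit(X[tr], y[tr])
        best = search.best_estimator_
        importances = best.feature_importances_
        ranking = np.argsort(importances)[::-1]
        ks = sorted({X.shape[1] if k is None else min(k, X.shape[1]) for k in feature_k})
        best_k, best_score = None, -np.inf
        for kk in ks:
            cols = ranking[:kk]
            score = cross_val_score(
                RandomForestClassifier(
                    class_weight="balanced",
                    random_state=seed + fold,
                    n_jobs=1,
                    **search.best_params_,
                ),
                X[tr][:, cols],
                y[tr],
                scoring="roc_auc",
                cv=inner,
            ).mean()
            if score > best_score:
                best_score, best_k = score, kk
        cols = ranking[:best_k]
        selected_all.append([ft.feature_names[c] for c in cols])
        final = RandomForestClassifier(
            class_weight="balanced",
            random_state=seed + fold,
            n_jobs=1,
            **search.best_params_,
        ).fit(X[tr][:, cols], y[tr])
        oof[te] = final.predict_proba(X[te][:, cols])[:, 1]

    report = roc_pr_confusion(oof, y)
    roc_auc, lo, hi = delong_ci(oof, y)
    pr_lo, pr_hi = _pr_bootstrap_ci(oof, y, seed=seed)
    report.roc_ci = (lo, hi)
    report.pr_ci = (pr_lo, pr_hi)
    report.selected_features = selected_all
    report.train_index_hashes = hashes
    report.seed = seed
    return report


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Empirical ROC AUC as the Mann-Whitney U statistic / (n1*n0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))


def _average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    precision, recall, _ = precision_recall_curve(labels, scores)
    # step-wise interpolated average precision (sum of P * delta recall)
    return float(-np.sum(np.diff(recall) * precision[:-1]))


def roc_pr_confusion(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ClassifierReport:
    """ROC and PR curves, AUCs, and the 0.5-threshold confusion matrix."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels contain a single class")
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    roc_auc = mann_whitney_auc(scores, labels)
    pr_auc = _average_precision(scores, labels)
    pred = (scores >= threshold).astype(int)
    cm = confusion_matrix(labels, pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return ClassifierReport(
        oof_probabilities=scores,
        labels=labels,
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall, precision]),
        roc_auc=roc_auc,
        roc_ci=(float("nan"), float("nan")),
        pr_auc=pr_auc,
        pr_ci=(float("nan"), float("nan")),
        confusion=cm,
        sensitivity=float(sens),
        specificity=float(spec),
    )


def delong_ci(
    scores: np.ndarray, labels: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """DeLong variance-based confidence interval for the ROC AUC.

    Uses the per-positive and per-negative placement values; the normal
    approximation interval is truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise ValueError("each class needs at least two members")
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    auc = float(cmp.mean())
    v10 = cmp.mean(axis=1)  # placement of each positive among negatives
    v01 = cmp.mean(axis=0)  # placement of each negative among positives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def _pr_bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the PR AUC."""
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, pos_idx.size, replace=True),
                rng.choice(neg_idx, neg_idx.size, replace=True),
            ]
        )
        vals[b] = _average_precision(scores[idx], labels[idx])
    lo, hi = np.percentile(vals, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
    return float(lo), float(hi)
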