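"""Top-k signature evaluation across four classifiers.

For each candidate signature size k (top-k SNPs of the ensemble
ranking) and each model — random forest, linear SVM, L1-logistic
("LASSO") and a depth-capped decision tree — the model is fit on every
training split and scored on the matching validation split.  Accuracy
uses each model's default decision rule; AUC is rank-based
(Mann–Whitney with tie correction), so any monotone score works and no
probability calibration is needed.  Stage B is the positive class
throughout.  Metrics are averaged over replicates; the confusion matrix
for a (k, model) pair is summed over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .selection import SplitPlan, fit_l1_logistic_cv

MODELS = ("rf", "svm", "lasso", "tree")


def auc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) AUC with tie correction.

    Equals P(score_case > score_control) + 0.5 P(equal); invariant
    under strictly monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ConfusionMatrix:
    """Validation counts with Stage B as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def confusion(predictions, labels) -> ConfusionMatrix:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    return ConfusionMatrix(
        tp=int(((predictions == 1) & (labels == 1)).sum()),
        fp=int(((predictions == 1) & (labels == 0)).sum()),
        tn=int(((predictions == 0) & (labels == 0)).sum()),
        fn=int(((predictions == 0) & (labels == 1)).sum()),
    )


@dataclass
class EvaluationCurve:
    """Mean/SD accuracy and AUC per (k, model) over the B replicates."""

    table: pd.DataFrame                  # k, model, mean_acc, sd_acc, mean_auc, sd_auc, n_ok
    B: int
    confusions: dict = field(repr=False)  # (k, model) -> ConfusionMatrix (summed)

    def best(self) -> pd.Series:
        t = self.table.sort_values(
            ["mean_auc", "mean_acc", "model"], ascending=[False, False, True]
        )
        return t.iloc[0]


def _standardize(train, valid):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (valid - mu) / sd


def _fit_score(model: str, Xt, yt, Xv, seed: int, tree_depth: int):
    """Fit one model; return (predicted labels, continuous scores) on Xv."""
    if model == "rf":
        clf = RandomForestClassifier(n_estimators=100, class_weight="balanced",
                                     random_state=seed, n_jobs=1)
        clf.fit(Xt, yt)
        return clf.predict(Xv), clf.predict_proba(Xv)[:, 1]
    if model == "svm":
        Zt, Zv = _standardize(Xt, Xv)
        clf = SVC(kernel="linear", C=1.0, class_weight="balanced",
                  random_state=seed)
        clf.fit(Zt, yt)
        score = clf.decision_function(Zv)
        return (score > 0).astype(int), score
    if model == "lasso":
        Zt, Zv = _standardize(Xt, Xv)
        n_folds = min(5, int(np.bincount(yt).min()))
        if n_folds < 2:
            raise ValueError("minority class too small for CV")
        clf = fit_l1_logistic_cv(Zt, yt, seed, n_folds)
        prob = clf.predict_proba(Zv)[:, 1]
        return (prob >= 0.5).astype(int), prob
    if model == "tree":
        clf = DecisionTreeClassifier(max_depth=tree_depth,
                                     class_weight="balanced", random_state=seed)
        clf.fit(Xt, yt)
        return clf.predict(Xv), clf.predict_proba(Xv)[:, 1]
    raise ValueError(f"unknown model {model!r}")


def evaluate_topk(
    dosages: pd.DataFrame,
    phenotype: np.ndarray,
    ranked: pd.DataFrame,
    plan: SplitPlan,
    k_grid=None,
    models=MODELS,
    tree_depth: int = 4,
    max_failure_fraction: float = 0.10,
) -> EvaluationCurve:
    """Accuracy/AUC curve over signature sizes and models.

    A replicate where a model fails to fit is excluded from that
    (k, model) cell's averages; if more than ``max_failure_fraction`` of
    replicates fail for any cell the whole run fails.
    """
    phenotype = np.asarray(phenotype)
    snp_order = ranked["snp_id"].tolist()
    if not snp_order:
        raise ValueError("ranked SNP list is empty")
    if k_grid is None:
        k_grid = list(range(1, min(30, len(snp_order)) + 1))
    k_grid = sorted(set(int(k) for k in k_grid))
    if k_grid[0] < 1 or k_grid[-1] > len(snp_order):
        raise ValueError("k_grid must lie within [1, number of ranked SNPs]")

    rows = []
    confusions: dict = {}
    for k in k_grid:
        feats = snp_order[:k]
        Xk = dosages[feats].values
        for model in models:
            accs, aucs = [], []
            cm = ConfusionMatrix(0, 0, 0, 0)
            failures = 0
            for r, (tr, va) in enumerate(plan.splits):
                seed = plan.replicate_seeds[r]
                yt, yv = phenotype[tr], phenotype[va]
                try:
                    pred, score = _fit_score(model, Xk[tr], yt, Xk[va],
                                             seed, tree_depth)
                    aucs.append(auc(score, yv))
                except Exception:
                    failures += 1
                    continue
                c = confusion(pred, yv)
                cm = cm + c
                accs.append(c.accuracy)
            if failures > max_failure_fraction * plan.B:
                raise RuntimeError(
                    f"{failures}/{plan.B} replicates failed for "
                    f"(k={k}, model={model})"
                )
            rows.append({
                "k": k, "model": model,
                "mean_acc": float(np.mean(accs)), "sd_acc": float(np.std(accs)),
                "mean_auc": float(np.mean(aucs)), "sd_auc": float(np.std(aucs)),
                "n_ok": len(accs), "n_failed": failures,
            })
            confusions[(k, model)] = cm
    table = pd.DataFrame(rows)
    return EvaluationCurve(table=table, B=plan.B, confusions=confusions)


def choose_signature(curve: EvaluationCurve, tolerance: float = 0.005):
    """Smallest signature whose AUC is within ``tolerance`` of the best.

    The model is chosen first (highest mean AUC at its best k; ties go
    to higher accuracy, then model-name order), then k* is the smallest
    k whose mean AUC is within tolerance of that model's best mean AUC.
    Returns (k_star, model_star).
    """
    if curve.table.empty:
        raise ValueError("empty evaluation curve")
    best = curve.best()
    model = best["model"]
    sub = curve.table[curve.table["model"] == model].sort_values("k")
    target = sub["mean_auc"].max() - tolerance
    k_star = int(sub.loc[sub["mean_auc"] >= target, "k"].iloc[0])
    return k_star, str(model)
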