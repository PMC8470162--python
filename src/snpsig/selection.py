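"""Bootstrap ensemble feature selection over screened SNPs.

The cohort is resampled B times (default 100) into stratified 80:20
train/validation splits.  On each training split three selectors run —
random-forest impurity importance (top k), absolute linear-SVM weight
(top k), and the nonzero support of a cross-validated L1 logistic
LASSO — and every SNP accumulates one count per (replicate, selector)
that picked it.  SNPs are ranked by total count, with the full-cohort
screen p-value and then the SNP id breaking ties, which makes the
ranking total and reproducible from the master seed.

Default mode mirrors the original workflow: the association screen runs
once on the full cohort before resampling (so validation subjects
influence the candidate pool — a documented leakage).  A nested,
leakage-free variant that re-screens inside each training split is
provided by :mod:`snpsig.pipeline`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


def fit_l1_logistic_cv(Z, y, seed: int, n_folds: int) -> LogisticRegressionCV:
    """L1-penalised logistic fit with the penalty chosen by stratified CV
    (minimum CV deviance).  liblinear handles the small-n L1 path well;
    the transition warnings about the future penalty API are silenced."""
    model = LogisticRegressionCV(
        Cs=np.logspace(-3, 2, 12),
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        cv=StratifiedKFold(n_folds, shuffle=True, random_state=seed),
        class_weight="balanced",
        max_iter=1000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(Z, y)
    return model


@dataclass
class SplitPlan:
    """B reproducible stratified train/validation partitions."""

    B: int
    train_fraction: float
    stratified: bool
    master_seed: int
    bootstrap: bool
    splits: list[tuple[np.ndarray, np.ndarray]] = field(repr=False)
    replicate_seeds: list[int] = field(repr=False, default_factory=list)


def make_splits(
    phenotype: np.ndarray,
    B: int = 100,
    train_fraction: float = 0.80,
    master_seed: int = 0,
    bootstrap: bool = False,
) -> SplitPlan:
    """Draw B stratified 80:20 partitions of the subjects.

    Within each class the training count is round(fraction * class size)
    (so it is within one subject of the exact target).  With
    ``bootstrap=True`` the training side is additionally resampled with
    replacement from the drawn training subjects; the validation side
    stays a clean holdout either way.
    """
    phenotype = np.asarray(phenotype)
    n = phenotype.size
    classes, class_counts = np.unique(phenotype, return_counts=True)
    if classes.size != 2 or (class_counts < 2).any():
        raise ValueError("need two classes with at least 2 subjects each")
    train_counts = {
        c: int(np.floor(train_fraction * k + 0.5))
        for c, k in zip(classes, class_counts)
    }
    for c, k in zip(classes, class_counts):
        if train_counts[c] == 0 or train_counts[c] == k:
            raise ValueError(
                f"train_fraction={train_fraction} leaves class {c} without "
                "both a training and a validation subject"
            )
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(master_seed).spawn(B)]
    splits = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        train_idx, valid_idx = [], []
        for c in classes:
            members = np.nonzero(phenotype == c)[0]
            perm = rng.permutation(members)
            k = train_counts[c]
            train_idx.append(perm[:k])
            valid_idx.append(perm[k:])
        tr = np.sort(np.concatenate(train_idx))
        va = np.sort(np.concatenate(valid_idx))
        if bootstrap:
            tr = np.sort(rng.choice(tr, size=tr.size, replace=True))
        splits.append((tr, va))
        assert set(np.unique(tr)) | set(va) <= set(range(n))
    return SplitPlan(B=B, train_fraction=train_fraction, stratified=True,
                     master_seed=master_seed, bootstrap=bootstrap,
                     splits=splits, replicate_seeds=seeds)


@dataclass
class SelectionCounts:
    counts: pd.Series                     # per-SNP int, index = snp_id
    B: int
    methods: tuple[str, ...]
    archive: dict = field(repr=False)     # (replicate, method) -> tuple of snp_ids

    def __post_init__(self) -> None:
        upper = len(self.methods) * self.B
        if ((self.counts < 0) | (self.counts > upper)).any():
            raise ValueError(f"counts must lie in [0, {upper}]")


def _check_train(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")


def _topk_by_score(scores, snp_ids, screen_p, k):
    """Top-k features by score, ties broken by screen p then snp_id."""
    order = np.lexsort((snp_ids, screen_p, -np.asarray(scores, dtype=float)))
    k = min(k, len(snp_ids))
    return set(np.asarray(snp_ids)[order[:k]])


def select_rf(X: pd.DataFrame, y, k_select: int, screen_p=None, seed: int = 0):
    """k features with highest random-forest impurity importance."""
    y = np.asarray(y)
    _check_train(y)
    if X.shape[1] < 2:
        raise ValueError("need at least two features")
    rf = RandomForestClassifier(
        n_estimators=100, class_weight="balanced", random_state=seed, n_jobs=1
    )
    rf.fit(X.values, y)
    p = screen_p if screen_p is not None else np.zeros(X.shape[1])
    return _topk_by_score(rf.feature_importances_, list(X.columns), p, k_select)


def select_svm(X: pd.DataFrame, y, k_select: int, screen_p=None, seed: int = 0):
    """k features with largest |weight| of a linear soft-margin SVM.

    Features are standardised to the training mean/SD first; a feature
    with zero training variance is zeroed out (weight 0 by contract).
    """
    y = np.asarray(y)
    _check_train(y)
    if X.shape[1] < 2:
        raise ValueError("need at least two features")
    mu = X.values.mean(axis=0)
    sd = X.values.std(axis=0)
    zero_var = sd == 0
    sd = np.where(zero_var, 1.0, sd)
    Z = (X.values - mu) / sd
    Z[:, zero_var] = 0.0
    svm = SVC(kernel="linear", C=1.0, class_weight="balanced", random_state=seed)
    svm.fit(Z, y)
    w = np.abs(np.ravel(svm.coef_))
    w[zero_var] = 0.0
    p = screen_p if screen_p is not None else np.zeros(X.shape[1])
    return _topk_by_score(w, list(X.columns), p, k_select)


def select_lasso(X: pd.DataFrame, y, seed: int = 0):
    """Nonzero support of an L1 logistic model at the CV-chosen penalty.

    The penalty is picked by 5-fold stratified cross-validation on the
    training split, minimising CV deviance (log loss).  The empty set
    is a legitimate outcome when the null model wins.
    """
    y = np.asarray(y)
    _check_train(y)
    n_folds = min(5, int(np.bincount(y).min()))
    if n_folds < 2:
        raise ValueError("minority class too small for cross-validation")
    mu = X.values.mean(axis=0)
    sd = X.values.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X.values - mu) / sd
    model = fit_l1_logistic_cv(Z, y, seed, n_folds)
    support = np.ravel(model.coef_) != 0
    return set(np.asarray(X.columns)[support])


METHODS = ("rf", "svm", "lasso")


def accumulate_and_rank(
    plan: SplitPlan,
    dosages: pd.DataFrame,
    phenotype: np.ndarray,
    screen_results: pd.DataFrame,
    k_select: int = 20,
) -> tuple[SelectionCounts, pd.DataFrame]:
    """Run the three selectors on every training split and rank by count.

    Only SNPs with ``passes_screen`` enter selection.  Returns the
    per-SNP :class:`SelectionCounts` (with the per-replicate archive)
    and the ranked table (rank, snp_id, count, screen_p).
    """
    phenotype = np.asarray(phenotype)
    passed = screen_results.loc[screen_results["passes_screen"], ["snp_id", "p"]]
    snp_ids = passed["snp_id"].tolist()
    if not snp_ids:
        raise ValueError("no SNPs passed the screen; nothing to select from")
    screen_p = passed["p"].values
    X = dosages[snp_ids]

    counts = pd.Series(0, index=snp_ids, dtype=int)
    archive: dict = {}
    for r, (tr, _va) in enumerate(plan.splits):
        seed = plan.replicate_seeds[r]
        Xt, yt = X.iloc[tr], phenotype[tr]
        try:
            picks = {
                "rf": select_rf(Xt, yt, k_select, screen_p, seed=seed),
                "svm": select_svm(Xt, yt, k_select, screen_p, seed=seed),
                "lasso": select_lasso(Xt, yt, seed=seed),
            }
        except Exception as e:
            raise RuntimeError(f"selector failure in replicate {r}: {e}") from e
        for method, chosen in picks.items():
            archive[(r, method)] = tuple(sorted(chosen))
            counts[list(chosen)] += 1

    sel = SelectionCounts(counts=counts, B=plan.B, methods=METHODS, archive=archive)
    ranked = pd.DataFrame(
        {"snp_id": snp_ids, "count": counts.values, "screen_p": screen_p}
    )
    ranked = ranked.sort_values(
        ["count", "screen_p", "snp_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return sel, ranked
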