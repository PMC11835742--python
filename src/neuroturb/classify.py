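"""Treatment-response classification from baseline turbulence features.

A Gaussian-kernel support vector machine consumes exactly seven baseline
features per patient — turbulence at lam in {0.01, 0.03, 0.06}, information
transfer at the same three scales, and the information cascade — and is
evaluated by repeated balanced 90/10 splits with fold-local standardization.
Significance is assessed by retraining on label-shuffled data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .turbulence import REPORT_LAMBDAS, TurbulenceProfile

RESPONDER, NON_RESPONDER = "responder", "non_responder"

FEATURE_COLUMNS: tuple[str, ...] = (
    "turbulence_lam0.01",
    "turbulence_lam0.03",
    "turbulence_lam0.06",
    "information_transfer_lam0.01",
    "information_transfer_lam0.03",
    "information_transfer_lam0.06",
    "information_cascade",
)


@dataclass(frozen=True)
class FeatureTable:
    """Patients x 7 feature matrix with binary response labels."""

    X: pd.DataFrame
    y: pd.Series  # values in {responder, non_responder}

    def __post_init__(self) -> None:
        if tuple(self.X.columns) != FEATURE_COLUMNS:
            raise ValueError(f"feature columns must be exactly {FEATURE_COLUMNS}")
        if not np.all(np.isfinite(self.X.to_numpy())):
            raise ValueError("feature table contains non-finite values")
        bad = set(self.y.unique()) - {RESPONDER, NON_RESPONDER}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if len(self.y) != len(self.X):
            raise ValueError("labels must align with rows")


@dataclass(frozen=True)
class ClassifierReport:
    """Validation performance over repetitions, plus permutation p-values."""

    auc_mean: float
    auc_sd: float
    acc_mean: float
    acc_sd: float
    n_repetitions: int
    p_auc: float | None = None
    p_acc: float | None = None

    def __post_init__(self) -> None:
        for v in (self.auc_mean, self.acc_mean):
            if not 0.0 <= v <= 1.0:
                raise ValueError("mean metrics must lie in [0, 1]")
        if self.auc_sd < 0 or self.acc_sd < 0:
            raise ValueError("metric SDs must be non-negative")


def assemble_features(
    profiles: Mapping[str, TurbulenceProfile],
    labels: Mapping[str, str],
) -> FeatureTable:
    """Build the canonical 7-column feature table from per-patient profiles.

    Patients are sorted by id; missing scales fail loudly naming the patient.
    """
    ids = sorted(profiles)
    rows = []
    for pid in ids:
        prof = profiles[pid]
        row = {}
        for lam in REPORT_LAMBDAS:
            try:
                row[f"turbulence_lam{lam:g}"] = prof.at_scale(prof.turbulence, lam)
            except KeyError as exc:
                raise KeyError(
                    f"patient {pid}: turbulence missing scale {lam}"
                ) from exc
            try:
                row[f"information_transfer_lam{lam:g}"] = prof.at_scale(
                    prof.information_transfer, lam
                )
            except KeyError as exc:
                raise KeyError(
                    f"patient {pid}: information transfer missing scale {lam}"
                ) from exc
        row["information_cascade"] = prof.information_cascade
        rows.append(row)
    X = pd.DataFrame(rows, index=ids)[list(FEATURE_COLUMNS)]
    y = pd.Series([labels[pid] for pid in ids], index=ids, name="response")
    return FeatureTable(X=X, y=y)


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise distance of the (standardized) data."""
    d = pdist(X)
    d = d[d > 0]
    med = np.median(d) if d.size else 1.0
    return 1.0 / (2.0 * med**2)


def _fit_score(X_tr, y_tr, X_va, y_va) -> tuple[float, float]:
    """Train scaler + RBF-SVM on the training fold; return (acc, auc)."""
    scaler = StandardScaler().fit(X_tr)
    Xs_tr, Xs_va = scaler.transform(X_tr), scaler.transform(X_va)
    clf = SVC(kernel="rbf", C=1.0, gamma=_median_heuristic_gamma(Xs_tr))
    clf.fit(Xs_tr, y_tr)
    acc = float(np.mean(clf.predict(Xs_va) == y_va))
    # decision_function is signed w.r.t. clf.classes_[1]
    scores = clf.decision_function(Xs_va)
    auc = float(roc_auc_score((y_va == clf.classes_[1]).astype(int), scores))
    return acc, auc


def repeated_split_eval(
    table: FeatureTable,
    n_reps: int = 100,
    train_frac: float = 0.9,
    balance_to: int = 32,
    seed: int = 0,
    mode: str = "repeated_split",
) -> ClassifierReport:
    """Balanced repeated-split evaluation of the RBF-SVM.

    Per repetition the larger class is subsampled to ``balance_to`` (clipped
    to the smaller class size with a warning), the balanced set is split
    stratified into ``train_frac`` training / rest validation, features are
    standardized with training statistics only, and validation accuracy and
    ROC-AUC (from decision values) are recorded.  Means and SDs are taken
    over repetitions.

    ``mode="kfold"`` instead runs 10-fold stratified cross-validation on the
    balanced sample in each repetition and averages the folds.
    """
    if mode not in ("repeated_split", "kfold"):
        raise ValueError("mode must be 'repeated_split' or 'kfold'")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    X = table.X.to_numpy()
    y = table.y.to_numpy()
    idx_pos = np.flatnonzero(y == RESPONDER)
    idx_neg = np.flatnonzero(y == NON_RESPONDER)
    n_min = min(idx_pos.size, idx_neg.size)
    if n_min < 4:
        raise ValueError("need at least 4 patients per class")
    b = balance_to
    if b > n_min:
        warnings.warn(
            f"balance_to={balance_to} exceeds the smaller class ({n_min}); clipped",
            stacklevel=2,
        )
        b = n_min

    rng = np.random.default_rng(seed)
    accs, aucs = [], []
    for _ in range(n_reps):
        sel = np.concatenate(
            [
                rng.choice(idx_pos, size=b, replace=False),
                rng.choice(idx_neg, size=b, replace=False),
            ]
        )
        Xb, yb = X[sel], y[sel]
        if mode == "kfold":
            splitter = StratifiedKFold(
                n_splits=10, shuffle=True, random_state=int(rng.integers(2**31))
            )
            fold_scores = [
                _fit_score(Xb[tr], yb[tr], Xb[va], yb[va])
                for tr, va in splitter.split(Xb, yb)
            ]
            acc = float(np.mean([s[0] for s in fold_scores]))
            auc = float(np.mean([s[1] for s in fold_scores]))
        else:
            for _attempt in range(10):
                sss = StratifiedShuffleSplit(
                    n_splits=1,
                    test_size=1.0 - train_frac,
                    random_state=int(rng.integers(2**31)),
                )
                tr, va = next(sss.split(Xb, yb))
                if len(np.unique(yb[va])) == 2:
                    break
                warnings.warn("single-class validation fold redrawn", stacklevel=2)
            else:
                raise RuntimeError("could not draw a two-class validation fold")
            acc, auc = _fit_score(Xb[tr], yb[tr], Xb[va], yb[va])
        accs.append(acc)
        aucs.append(auc)
    return ClassifierReport(
        auc_mean=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs, ddof=1)) if n_reps > 1 else 0.0,
        acc_mean=float(np.mean(accs)),
        acc_sd=float(np.std(accs, ddof=1)) if n_reps > 1 else 0.0,
        n_repetitions=n_reps,
    )


def permutation_significance(
    table: FeatureTable,
    observed: ClassifierReport,
    n_null: int = 1000,
    seed: int = 0,
    n_reps_null: int | None = None,
    strict_greater: bool = False,
    **eval_kwargs,
) -> ClassifierReport:
    """Label-shuffling significance of the observed AUC and accuracy.

    ``n_null`` evaluations are run on the same features with shuffled labels,
    each with the observed repetition count unless ``n_reps_null`` overrides
    it; ``p = (1 + #{null >= observed}) / (1 + n_null)`` separately for AUC
    and accuracy (``strict_greater`` switches to a strict inequality).
    Returns the observed report with p-values attached.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    if n_reps_null is None:
        n_reps_null = observed.n_repetitions
    rng = np.random.default_rng(seed)
    null_auc = np.empty(n_null)
    null_acc = np.empty(n_null)
    for i in range(n_null):
        perm_y = pd.Series(
            rng.permutation(table.y.to_numpy()), index=table.y.index, name="response"
        )
        shuffled = FeatureTable(X=table.X, y=perm_y)
        rep = repeated_split_eval(
            shuffled, n_reps=n_reps_null, seed=int(rng.integers(2**31)), **eval_kwargs
        )
        null_auc[i] = rep.auc_mean
        null_acc[i] = rep.acc_mean
    if strict_greater:
        k_auc = int(np.sum(null_auc > observed.auc_mean))
        k_acc = int(np.sum(null_acc > observed.acc_mean))
    else:
        k_auc = int(np.sum(null_auc >= observed.auc_mean - 1e-12))
        k_acc = int(np.sum(null_acc >= observed.acc_mean - 1e-12))
    return replace(
        observed,
        p_auc=(1.0 + k_auc) / (1.0 + n_null),
        p_acc=(1.0 + k_acc) / (1.0 + n_null),
    )
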