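"""Feature selection and classification: SVM-RFE + grid-searched SVM under
subject-wise stratified 5-fold cross-validation.

Features are ranked by recursive feature elimination with a linear-kernel SVM
(importance = squared weight), the accuracy-optimal feature count is picked on
the training folds, and the final classifier is an SVM grid-searched over
C = 2^n (n = -4..13) for the linear kernel and additionally gamma = 2^m
(m = -7..6) for the RBF kernel (18 + 18*14 = 270 configurations). Folds are
stratified at the subject level: every segment of a subject shares its fold, so
no identity leaks between training and evaluation. Metrics are accuracy,
sensitivity, specificity and F1, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class GridSpec:
    kernels: tuple = ("linear", "rbf")
    C_exponents: tuple = tuple(range(-4, 14))
    gamma_exponents: tuple = tuple(range(-7, 7))

    def configurations(self) -> list[tuple[str, float, float | None]]:
        """All (kernel, C, gamma) triples, ordered for tie-breaking:
        smaller C first, then linear before RBF, then smaller gamma."""
        out: list[tuple[str, float, float | None]] = []
        for n in sorted(self.C_exponents):
            C = 2.0**n
            if "linear" in self.kernels:
                out.append(("linear", C, None))
            if "rbf" in self.kernels:
                for m in sorted(self.gamma_exponents):
                    out.append(("rbf", C, 2.0**m))
        return out


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    metrics: dict
    selected_k: int
    selected_features: np.ndarray
    hyperparams: tuple
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    ranking: np.ndarray | None = None


@dataclass
class CVReport:
    folds: list = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)
    fold_subjects: list = field(default_factory=list)


def compute_metrics(counts: ConfusionCounts) -> dict:
    """ACC/SEN/SPE/F1 in percent; a zero-denominator metric is None (undefined)."""

    def pct(num: float, den: float) -> float | None:
        return None if den == 0 else 100.0 * num / den

    c = counts
    total = c.tp + c.fp + c.tn + c.fn
    return {
        "ACC": pct(c.tp + c.tn, total),
        "SEN": pct(c.tp, c.tp + c.fn),
        "SPE": pct(c.tn, c.tn + c.fp),
        "F1": pct(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def make_folds(
    subjects: list[tuple[str, int]], k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Subject-level stratified partition: subject_id -> fold index."""
    sids = [s for s, _ in subjects]
    labels = np.array([l for _, l in subjects], dtype=int)
    if len(set(sids)) != len(sids):
        raise ValueError("duplicate subject ids")
    for cls in np.unique(labels):
        if np.sum(labels == cls) < k:
            raise ValueError(f"class {cls} has fewer than {k} subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(sids)), labels)):
        for i in test_idx:
            assignment[sids[i]] = fold
    return assignment


def rfe_rank(features: np.ndarray, labels: np.ndarray, step: int = 1) -> np.ndarray:
    """SVM-RFE ranking (1 = most important; eliminated last).

    Repeatedly fits a linear-kernel SVM and removes the ``step`` features with
    the smallest squared weights.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class labels")
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    rfe = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=1, step=step)
    rfe.fit(features, labels)
    return rfe.ranking_.copy()


def _default_k_schedule(d: int) -> list[int]:
    """Dense at the start (where the accuracy curve moves), strided later."""
    ks = list(range(1, min(d, 20) + 1))
    k = 25
    while k < d:
        ks.append(k)
        k += 5 if k < 60 else 20
    if d not in ks:
        ks.append(d)
    return ks


def select_k(
    features: np.ndarray,
    labels: np.ndarray,
    ranking: np.ndarray,
    inner_folds: int = 3,
    seed: int = 0,
    k_schedule: list[int] | None = None,
) -> tuple[int, dict[int, float]]:
    """Accuracy-vs-feature-count curve via inner CV; best (smallest on ties) k.

    The curve is evaluated with a fixed linear SVM (C = 1); the full hyper-
    parameter grid is only run once, on the selected subset.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    d = features.shape[1]
    order = np.argsort(ranking, kind="stable")  # best-ranked first
    ks = k_schedule or _default_k_schedule(d)
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(features, labels))
    curve: dict[int, float] = {}
    for k in ks:
        cols = order[:k]
        accs = []
        for tr, te in splits:
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(features[np.ix_(tr, cols)], labels[tr])
            accs.append(np.mean(clf.predict(features[np.ix_(te, cols)]) == labels[te]))
        curve[k] = float(np.mean(accs))
    best_k = min(curve, key=lambda k: (-curve[k], k))
    return best_k, curve


def svm_grid_fit(
    features: np.ndarray,
    labels: np.ndarray,
    grid: GridSpec | None = None,
    inner_folds: int = 3,
    seed: int = 0,
) -> tuple[SVC, tuple[str, float, float | None]]:
    """Exhaustive grid search by inner-CV accuracy; refit on all training data.

    Ties break toward smaller C, then the linear kernel (enforced by the
    configuration ordering plus strict improvement).
    """
    grid = grid or GridSpec()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class training data")
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(features, labels))
    best_acc, best_cfg = -1.0, None
    for kernel, C, gamma in grid.configurations():
        accs = []
        for tr, te in splits:
            clf = _make_svc(kernel, C, gamma)
            clf.fit(features[tr], labels[tr])
            accs.append(np.mean(clf.predict(features[te]) == labels[te]))
        acc = float(np.mean(accs))
        if acc > best_acc:  # strict: first (lowest-C / linear) config wins ties
            best_acc, best_cfg = acc, (kernel, C, gamma)
    clf = _make_svc(*best_cfg)
    clf.fit(features, labels)
    return clf, best_cfg


def _make_svc(kernel: str, C: float, gamma: float | None) -> SVC:
    if kernel == "linear":
        return SVC(kernel="linear", C=C)
    return SVC(kernel="rbf", C=C, gamma=gamma)


def run_cv(
    features: np.ndarray,
    labels: np.ndarray,
    subject_ids: list[str],
    grid: GridSpec | None = None,
    k: int = 5,
    seed: int = 0,
    rfe_step: int = 1,
    compressor=None,
    per_fold_features: np.ndarray | None = None,
) -> CVReport:
    """Subject-wise stratified k-fold CV of the full selection+classification stack.

    Per fold: (optionally) fit a feature compressor on training-fold rows and
    transform both sides; standardize on train; SVM-RFE rank on train; pick the
    feature count by inner CV on train; grid-fit the SVM on train; evaluate on
    the held-out fold. ``compressor`` is a callable
    ``(train_X, train_y, fold_seed) -> transform`` used to plug in per-fold
    autoencoder compression without leaking evaluation data.

    ``per_fold_features`` ([k, n, d]) overrides ``features`` with a
    fold-specific feature matrix — used when the upstream encoder itself is
    trained per fold, so evaluation rows are encoded by weights fitted on the
    other folds.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    subject_ids = [str(s) for s in subject_ids]
    subj_label = {}
    for sid, lab in zip(subject_ids, labels):
        if subj_label.setdefault(sid, lab) != lab:
            raise ValueError(f"inconsistent labels for subject {sid}")
    assignment = make_folds(sorted(subj_label.items()), k=k, seed=seed)
    fold_of_row = np.array([assignment[s] for s in subject_ids])

    report = CVReport()
    metric_rows = []
    for fold in range(k):
        tr = fold_of_row != fold
        te = ~tr
        X = features if per_fold_features is None else np.asarray(per_fold_features[fold], dtype=float)
        Xtr, ytr = X[tr], labels[tr]
        Xte, yte = X[te], labels[te]
        if compressor is not None:
            transform = compressor(Xtr, ytr, seed * 1000 + fold)
            Xtr, Xte = transform(Xtr), transform(Xte)
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        ranking = rfe_rank(Xtr, ytr, step=rfe_step)
        best_k, _ = select_k(Xtr, ytr, ranking, seed=seed)
        cols = np.argsort(ranking, kind="stable")[:best_k]
        clf, cfg = svm_grid_fit(Xtr[:, cols], ytr, grid, seed=seed)
        counts = ConfusionCounts.from_predictions(yte, clf.predict(Xte[:, cols]))
        metrics = compute_metrics(counts)
        metric_rows.append(metrics)
        report.folds.append(
            FoldResult(
                fold=fold,
                counts=counts,
                metrics=metrics,
                selected_k=best_k,
                selected_features=cols,
                hyperparams=cfg,
                scaler_mean=scaler.mean_.copy(),
                scaler_scale=scaler.scale_.copy(),
                ranking=ranking,
            )
        )
        report.fold_subjects.append(sorted({s for s, f in zip(subject_ids, fold_of_row) if f == fold}))
    for key in ("ACC", "SEN", "SPE", "F1"):
        vals = [m[key] for m in metric_rows if m[key] is not None]
        report.mean[key] = float(np.mean(vals)) if vals else None
        report.std[key] = float(np.std(vals)) if vals else None
    return report
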