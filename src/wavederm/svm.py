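"""C-SVM cross-validated AUC evaluation.

A binary soft-margin SVM (L1 penalty, box constraint C) with a linear,
polynomial or gaussian kernel is scored by stratified 10-fold cross-validation
on standardized (N(0, 1)) predictors.  The solver is libsvm's SMO via
scikit-learn, configured with convergence tolerance 1e-3 and dual
coefficients initialized at zero; AUC is computed per held-out fold from the
decision function (melanoma/positive as target class) and averaged over
folds, and the mean number of support vectors is reported as a stability
diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

DEFAULT_SEED = 20190206

KERNELS = ("linear", "polynomial", "gaussian")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and its hyperparameters.

    Only the parameters relevant to the kernel are consulted: ``gamma`` for
    gaussian, ``degree`` and ``offset`` (the polynomial's r, fixed default 1)
    for polynomial.  ``C`` is the box constraint of the soft margin.
    """

    kernel: str
    C: float
    gamma: float | None = None
    degree: int | None = None
    offset: float = 1.0

    def __post_init__(self):
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel == "gaussian" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("gaussian kernel requires gamma > 0")
        if self.kernel == "polynomial" and (self.degree is None or self.degree < 1):
            raise ValueError("polynomial kernel requires integer degree >= 1")

    @property
    def param_label(self) -> str:
        """The kernel's own parameter, formatted for report tables."""
        if self.kernel == "gaussian":
            return f"{self.gamma:.3g}"
        if self.kernel == "polynomial":
            return str(self.degree)
        return "-"


@dataclass
class CVResult:
    """Cross-validated performance of one (features, kernel) cell."""

    mean_auc: float
    auc_sd: float
    mean_n_support_vectors: float
    kernel_spec: KernelSpec
    n_folds: int
    seed: int
    fold_aucs: tuple[float, ...] = field(default=(), repr=False)
    converged: bool = True


def standardize(
    train: np.ndarray, apply: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Column-wise N(0, 1) scaling fit on ``train``, applied to both matrices.

    Uses the population standard deviation (ddof = 0); zero-variance columns
    map to all-zeros.  Returns (train_std, apply_std, mean, sd).
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("training matrix must have at least 2 rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    train_std = (train - mean) / safe_sd
    train_std[:, sd == 0] = 0.0
    apply_std = None
    if apply is not None:
        apply = np.asarray(apply, dtype=float)
        if apply.shape[1] != train.shape[1]:
            raise ValueError("column counts differ between train and apply matrices")
        apply_std = (apply - mean) / safe_sd
        apply_std[:, sd == 0] = 0.0
    return train_std, apply_std, mean, sd


def _make_svc(spec: KernelSpec, max_iter: int) -> SVC:
    kwargs = dict(C=spec.C, tol=1e-3, max_iter=max_iter, cache_size=200)
    if spec.kernel == "linear":
        return SVC(kernel="linear", **kwargs)
    if spec.kernel == "gaussian":
        return SVC(kernel="rbf", gamma=spec.gamma, **kwargs)
    return SVC(kernel="poly", degree=spec.degree, coef0=spec.offset, gamma="scale", **kwargs)


def cv_auc(
    features: np.ndarray,
    labels: np.ndarray,
    spec: KernelSpec,
    n_folds: int = 10,
    seed: int = DEFAULT_SEED,
    leakage_mode: str = "fold_safe",
    max_iter: int = 1_000_000,
) -> CVResult:
    """Stratified k-fold cross-validated AUC of a C-SVM.

    ``leakage_mode='fold_safe'`` (default) fits the standardization on each
    training fold and applies it to the held-out fold; ``'whole_dataset'``
    standardizes once on all rows before splitting.  Folds are assigned by a
    seeded stratified shuffle, so identical inputs give identical results.
    Non-convergence within ``max_iter`` is flagged on the result; the fold is
    still scored with the attained solution.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if leakage_mode not in ("fold_safe", "whole_dataset"):
        raise ValueError(f"unknown leakage_mode {leakage_mode!r}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds or len(np.unique(y)) != 2:
        raise ValueError(
            f"both classes need >= {n_folds} members for {n_folds}-fold stratification; "
            f"got counts {counts.tolist()}"
        )
    if leakage_mode == "whole_dataset":
        X, _, _, _ = standardize(X)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs, sv_counts = [], []
    converged = True
    for train_idx, test_idx in skf.split(X, y):
        X_tr, X_te = X[train_idx], X[test_idx]
        if leakage_mode == "fold_safe":
            X_tr, X_te, _, _ = standardize(X_tr, X_te)
        clf = _make_svc(spec, max_iter)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X_tr, y[train_idx])
        if any(issubclass(c.category, ConvergenceWarning) for c in caught):
            converged = False
        scores = clf.decision_function(X_te)
        aucs.append(roc_auc_score(y[test_idx], scores))
        sv_counts.append(clf.n_support_.sum())
    aucs = np.array(aucs)
    return CVResult(
        mean_auc=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)),
        mean_n_support_vectors=float(np.mean(sv_counts)),
        kernel_spec=spec,
        n_folds=n_folds,
        seed=seed,
        fold_aucs=tuple(float(a) for a in aucs),
        converged=converged,
    )


def subsample_majority(
    labels: np.ndarray, ratio: float, seed: int = DEFAULT_SEED
) -> np.ndarray:
    """Indices keeping all minority rows and a seeded fraction of the majority.

    ``ratio`` is the target majority:minority size ratio (e.g. 1.0 balances
    the classes).  Used to probe sensitivity to class imbalance.
    """
    y = np.asarray(labels).astype(int)
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    majority = 1 - minority
    n_keep = min(int(round(ratio * counts[minority])), counts[majority])
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(y == majority)
    keep_maj = rng.choice(maj_idx, size=n_keep, replace=False)
    idx = np.concatenate([np.flatnonzero(y == minority), np.sort(keep_maj)])
    return np.sort(idx)
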