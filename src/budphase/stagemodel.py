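"""Bud-stage classification from a small marker-gene panel.

The classifier reproduces a cross-platform staging workflow: marker-gene
expression (TPM on the training side, qPCR relative expression on the
prediction side) is normalized per cultivar by the October reference
sample (the beginning of endodormancy, available for every cultivar),
projected onto the top-2 principal components fitted on the RNA-seq
data, and classified into the five dormancy stages by an L2-regularized
multinomial (softmax) logistic regression whose penalty is chosen by
stratified k-fold cross-validation.

The softmax fit minimizes the penalized negative log-likelihood

    f(W, b) = -sum_i log softmax(W x_i + b)_{y_i} + (lambda/2) ||W||^2

(intercepts unpenalized) with L-BFGS-B and an analytic gradient at
gradient-norm tolerance 1e-8; the problem is convex, so the fit is
deterministic. Penalty ties in cross-validation resolve toward the
stronger regularization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split

from .containers import STAGE_INDEX, STAGES, BudphaseError

DEFAULT_REG_GRID = tuple(np.logspace(-4, 4, 10))


# ---------------------------------------------------------------------------
# October normalization
# ---------------------------------------------------------------------------

def october_normalize(panel: pd.DataFrame,
                      metadata: pd.DataFrame,
                      reference_dates: dict | None = None,
                      reference_month: int = 10,
                      log2: bool = False) -> pd.DataFrame:
    """Divide each sample's expression by its cultivar's October reference.

    ``panel`` is genes x samples. The reference for a cultivar is the
    replicate mean at ``reference_dates[cultivar]`` when given, otherwise
    at the cultivar's earliest date in ``reference_month``. Reference
    samples map to 1 for every gene. With ``log2=True`` the log2 of the
    ratio is returned.
    """
    meta = metadata.set_index("sample_id").loc[panel.columns]
    out = pd.DataFrame(index=panel.index, columns=panel.columns, dtype=float)
    for cultivar, sub in meta.groupby("cultivar", sort=False):
        if reference_dates and cultivar in reference_dates:
            ref_date = pd.Timestamp(reference_dates[cultivar])
        else:
            in_month = sub[pd.to_datetime(sub["date"]).dt.month == reference_month]
            if in_month.empty:
                raise BudphaseError(
                    f"cultivar {cultivar!r} has no sample in month "
                    f"{reference_month} to use as reference")
            ref_date = pd.to_datetime(in_month["date"]).min()
        ref_samples = sub.index[pd.to_datetime(sub["date"]) == ref_date]
        if len(ref_samples) == 0:
            raise BudphaseError(
                f"cultivar {cultivar!r} has no sample at reference date "
                f"{ref_date.date()}")
        ref = panel[ref_samples].mean(axis=1)
        zero = ref.index[~(ref > 0)]
        if len(zero):
            raise BudphaseError(
                f"zero reference expression for gene(s) {zero.tolist()[:5]} "
                f"in cultivar {cultivar!r}")
        cols = sub.index
        out[cols] = panel[cols].div(ref, axis=0)
    return np.log2(out) if log2 else out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Two-component PCA: per-feature centering plus orthonormal loadings."""

    feature_ids: list
    center: np.ndarray
    loadings: np.ndarray  # features x 2, orthonormal columns
    explained_variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.explained_variance_fraction = np.asarray(
            self.explained_variance_fraction, dtype=float)
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.loadings.shape[1]), atol=1e-9):
            raise BudphaseError("PCA loadings must be orthonormal")


def fit_pca(X: pd.DataFrame, n_components: int = 2) -> PCAModel:
    """Mean-centered (unscaled) PCA via SVD, keeping the top components.

    Sign convention: in each component the loading entry of largest
    magnitude is positive, which makes the decomposition deterministic.
    """
    X = pd.DataFrame(X)
    arr = X.to_numpy(dtype=float)
    if arr.shape[0] < 3:
        raise BudphaseError("fit_pca needs >= 3 samples")
    if arr.shape[1] < n_components:
        raise BudphaseError(f"fit_pca needs >= {n_components} features")
    center = arr.mean(axis=0)
    centered = arr - center
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s.size < n_components or s[0] <= 1e-12:
        raise BudphaseError("no variance after centering; PCA plane undefined")
    # rank-1 data (samples on a line) are allowed: the second loading is
    # an arbitrary orthonormal complement with explained fraction 0
    loadings = vt[:n_components].T.copy()
    for j in range(n_components):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] = -loadings[:, j]
    total_var = float((s ** 2).sum())
    explained = s[:n_components] ** 2 / total_var if total_var > 0 else \
        np.zeros(n_components)
    return PCAModel(feature_ids=list(X.columns), center=center,
                    loadings=loadings, explained_variance_fraction=explained)


def project(pca: PCAModel, X: pd.DataFrame) -> np.ndarray:
    """Project samples x features data onto the fitted plane: (X - center) @ L."""
    X = pd.DataFrame(X)
    missing = [f for f in pca.feature_ids if f not in X.columns]
    if missing:
        raise BudphaseError(f"missing marker features: {missing}")
    arr = X[pca.feature_ids].to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise BudphaseError("non-finite values in projection input")
    return (arr - pca.center) @ pca.loadings


# ---------------------------------------------------------------------------
# Multinomial logistic regression
# ---------------------------------------------------------------------------

def _softmax(eta: np.ndarray) -> np.ndarray:
    eta = eta - eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def _penalized_nll_grad(w_flat: np.ndarray, X: np.ndarray, Y: np.ndarray,
                        lam: float):
    n, d = X.shape
    c = Y.shape[1]
    W = w_flat.reshape(c, d + 1)
    weights, intercept = W[:, :d], W[:, d]
    eta = X @ weights.T + intercept
    p = _softmax(eta)
    # NLL with the log-sum-exp trick already applied inside _softmax.
    ll = np.log(np.clip((p * Y).sum(axis=1), 1e-300, None)).sum()
    f = -ll + 0.5 * lam * float((weights ** 2).sum())
    resid = p - Y
    grad_w = resid.T @ X + lam * weights
    grad_b = resid.sum(axis=0)
    grad = np.concatenate([grad_w, grad_b[:, None]], axis=1).ravel()
    return f, grad


def _fit_softmax(X: np.ndarray, y_idx: np.ndarray, n_classes: int,
                 lam: float, gtol: float = 1e-8):
    n, d = X.shape
    Y = np.zeros((n, n_classes))
    Y[np.arange(n), y_idx] = 1.0
    x0 = np.zeros(n_classes * (d + 1))
    res = minimize(_penalized_nll_grad, x0, args=(X, Y, lam), jac=True,
                   method="L-BFGS-B",
                   options={"gtol": gtol, "ftol": 1e-17, "maxiter": 10000})
    W = res.x.reshape(n_classes, d + 1)
    return W[:, :d], W[:, d], res


def softmax_gradient_norm(coef: np.ndarray, intercept: np.ndarray,
                          X: np.ndarray, y_idx: np.ndarray, lam: float) -> float:
    """Euclidean norm of the penalized-NLL gradient at given coefficients."""
    n_classes, d = coef.shape
    Y = np.zeros((X.shape[0], n_classes))
    Y[np.arange(X.shape[0]), y_idx] = 1.0
    w_flat = np.concatenate([coef, intercept[:, None]], axis=1).ravel()
    _, grad = _penalized_nll_grad(w_flat, X, Y, lam)
    return float(np.linalg.norm(grad))


def penalized_nll(coef: np.ndarray, intercept: np.ndarray,
                  X: np.ndarray, y_idx: np.ndarray, lam: float) -> float:
    n_classes, d = coef.shape
    Y = np.zeros((X.shape[0], n_classes))
    Y[np.arange(X.shape[0]), y_idx] = 1.0
    w_flat = np.concatenate([coef, intercept[:, None]], axis=1).ravel()
    f, _ = _penalized_nll_grad(w_flat, X, Y, lam)
    return float(f)


def _order_classes(labels) -> list:
    uniq = sorted(set(labels))
    if set(uniq) <= set(STAGES):
        return sorted(uniq, key=lambda s: STAGE_INDEX[s])
    return uniq


class StageClassifier(BaseEstimator, ClassifierMixin):
    """PCA projection plus CV-regularized multinomial logistic regression.

    Fits a 2-D PCA on the (normalized) marker panel and a softmax
    regression on the scores. Class probability ties at prediction
    resolve by chronological stage order.

    Parameters
    ----------
    n_components : int, default 2
        PCA dimensionality.
    reg_grid : sequence of float
        Candidate L2 penalty strengths (lambda); chosen by stratified
        ``n_folds``-fold CV accuracy, ties toward the larger lambda.
    n_folds : int, default 5
        CV folds; shrunk (with a warning) when the rarest class has
        fewer members.
    fit_pca_ : bool-like via ``precomputed_scores`` — pass
        ``precomputed_scores=True`` to skip PCA and treat the input as
        ready-made coordinates.

    Attributes
    ----------
    pca_ : PCAModel or None
    classes_ : ndarray of class labels in chronological order
    coef_ : ndarray (n_classes, n_components)
    intercept_ : ndarray (n_classes,)
    lambda_ : float, the selected penalty
    cv_accuracy_ : dict lambda -> mean CV accuracy
    """

    def __init__(self, n_components: int = 2, reg_grid=DEFAULT_REG_GRID,
                 n_folds: int = 5, precomputed_scores: bool = False,
                 cv_random_state: int = 0):
        self.n_components = n_components
        self.reg_grid = reg_grid
        self.n_folds = n_folds
        self.precomputed_scores = precomputed_scores
        self.cv_random_state = cv_random_state

    # -- core ------------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y)
        if len(set(y)) < 2:
            raise BudphaseError("need >= 2 classes to fit the stage model")
        X = pd.DataFrame(X)
        if len(X) != len(y):
            raise BudphaseError("X and y lengths differ")
        if self.precomputed_scores:
            self.pca_ = None
            scores = X.to_numpy(dtype=float)
        else:
            self.pca_ = fit_pca(X, n_components=self.n_components)
            scores = project(self.pca_, X)
        self.classes_ = np.asarray(_order_classes(y))
        class_pos = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.asarray([class_pos[v] for v in y])

        counts = np.bincount(y_idx)
        n_folds = min(self.n_folds, int(counts.min()))
        if n_folds < self.n_folds:
            warnings.warn(
                f"rarest class has {counts.min()} samples; shrinking CV to "
                f"{n_folds} folds", stacklevel=2)
        grid = sorted(float(l) for l in self.reg_grid)
        if n_folds >= 2:
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=self.cv_random_state)
            folds = list(skf.split(scores, y_idx))
            acc = {}
            for lam in grid:
                correct = 0
                for train_idx, test_idx in folds:
                    coef, intercept, _ = _fit_softmax(
                        scores[train_idx], y_idx[train_idx],
                        len(self.classes_), lam)
                    pred = np.argmax(
                        scores[test_idx] @ coef.T + intercept, axis=1)
                    correct += int((pred == y_idx[test_idx]).sum())
                acc[lam] = correct / len(y_idx)
            best = max(acc.values())
            # ties -> stronger regularization (largest lambda at the max)
            self.lambda_ = max(l for l, a in acc.items() if a == best)
            self.cv_accuracy_ = acc
        else:
            self.lambda_ = min(grid)
            self.cv_accuracy_ = {}

        self.coef_, self.intercept_, res = _fit_softmax(
            scores, y_idx, len(self.classes_), self.lambda_)
        self.n_iter_ = int(res.nit)
        self.training_scores_ = scores
        self.training_y_idx_ = y_idx
        self.training_summary_ = {"n_samples": int(len(y)),
                                  "cv_folds": int(n_folds),
                                  "lambda": float(self.lambda_)}
        return self

    def _scores(self, X) -> np.ndarray:
        if self.pca_ is None:
            arr = pd.DataFrame(X).to_numpy(dtype=float)
            if not np.isfinite(arr).all():
                raise BudphaseError("non-finite scores")
            return arr
        return project(self.pca_, pd.DataFrame(X))

    def predict_proba(self, X) -> np.ndarray:
        scores = self._scores(X)
        return _softmax(scores @ self.coef_.T + self.intercept_)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax takes the first maximum; classes_ is in chronological
        # stage order, so ties resolve to the earlier stage.
        return self.classes_[np.argmax(proba, axis=1)]

    # -- serialization ---------------------------------------------------
    def to_json(self, path) -> None:
        if self.pca_ is None:
            raise BudphaseError("only PCA-backed models are serializable")
        payload = {
            "feature_ids": list(self.pca_.feature_ids),
            "center": self.pca_.center.tolist(),
            "loadings": self.pca_.loadings.tolist(),
            "explained_variance_fraction":
                self.pca_.explained_variance_fraction.tolist(),
            "classes": list(map(str, self.classes_)),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
            "lambda": float(self.lambda_),
            "training_summary": self.training_summary_,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StageClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls()
        model.pca_ = PCAModel(
            feature_ids=payload["feature_ids"],
            center=np.asarray(payload["center"]),
            loadings=np.asarray(payload["loadings"]),
            explained_variance_fraction=np.asarray(
                payload["explained_variance_fraction"]))
        model.classes_ = np.asarray(payload["classes"])
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.intercept_ = np.asarray(payload["intercept"], dtype=float)
        model.lambda_ = float(payload["lambda"])
        model.training_summary_ = payload.get("training_summary", {})
        return model


def fit_multinomial_lr(scores: np.ndarray, labels,
                       n_folds: int = 5,
                       reg_grid=DEFAULT_REG_GRID) -> StageClassifier:
    """Fit the softmax stage model on precomputed 2-D coordinates."""
    clf = StageClassifier(reg_grid=reg_grid, n_folds=n_folds,
                          precomputed_scores=True)
    return clf.fit(pd.DataFrame(np.asarray(scores, dtype=float)), labels)


def predict_stage(model: StageClassifier, scores) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class probabilities for 2-D coordinates."""
    df = pd.DataFrame(np.asarray(scores, dtype=float))
    return model.predict(df), model.predict_proba(df)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def weighted_f1(y_true, y_pred) -> float:
    """Support-weighted mean of per-class F1 = 2PR/(P+R) (0 when P+R=0)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise BudphaseError("y_true and y_pred must be non-empty and aligned")
    total = 0.0
    for cls in np.unique(y_true):
        support = int((y_true == cls).sum())
        tp = int(((y_true == cls) & (y_pred == cls)).sum())
        fp = int(((y_true != cls) & (y_pred == cls)).sum())
        fn = support - tp
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        total += f1 * support / y_true.size
    return float(total)


@dataclass
class EvaluationReport:
    """Repeated stratified train/test evaluation of the stage model."""

    f1_scores: np.ndarray
    n_splits: int
    confusion: pd.DataFrame
    n_resampled: int = 0

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1_scores))

    @property
    def sd_f1(self) -> float:
        return float(np.std(self.f1_scores, ddof=1)) if len(self.f1_scores) > 1 \
            else 0.0


def evaluate_splits(scores, labels, n_splits: int = 500,
                    test_fraction: float = 0.3, seed: int = 0,
                    n_folds: int = 5,
                    reg_grid=DEFAULT_REG_GRID) -> EvaluationReport:
    """Repeatedly split into stratified train/test sets, refit, and score.

    Each split refits the CV-regularized softmax model on the training
    coordinates and records the weighted F1 on the test set; splits where
    a class would vanish from the training set are redrawn (counted in
    ``n_resampled``). Reproducible given ``seed``.
    """
    scores = np.asarray(pd.DataFrame(scores), dtype=float)
    labels = np.asarray(labels)
    classes = _order_classes(labels)
    rng = np.random.default_rng(seed)
    f1s = []
    agg = np.zeros((len(classes), len(classes)), dtype=int)
    n_resampled = 0
    for _ in range(n_splits):
        for _attempt in range(20):
            split_seed = int(rng.integers(0, 2 ** 31 - 1))
            X_tr, X_te, y_tr, y_te = train_test_split(
                scores, labels, test_size=test_fraction,
                stratify=labels, random_state=split_seed)
            if set(y_tr) == set(classes):
                break
            n_resampled += 1
        clf = fit_multinomial_lr(X_tr, y_tr, n_folds=n_folds, reg_grid=reg_grid)
        pred = clf.predict(pd.DataFrame(X_te))
        f1s.append(weighted_f1(y_te, pred))
        agg += confusion_matrix(y_te, pred, labels=classes)
    confusion = pd.DataFrame(agg, index=classes, columns=classes)
    confusion.index.name, confusion.columns.name = "true", "predicted"
    return EvaluationReport(f1_scores=np.asarray(f1s), n_splits=n_splits,
                            confusion=confusion, n_resampled=n_resampled)


def stage_chronology_consistency(metadata: pd.DataFrame,
                                 predictions: pd.Series) -> float:
    """Fraction of consecutive same-tree sample pairs (date-ordered) whose
    predicted stages are non-decreasing in chronological stage order."""
    meta = metadata.set_index("sample_id").loc[predictions.index]
    ok = 0
    total = 0
    for _, sub in meta.groupby(["cultivar", "tree"], sort=False):
        ordered = sub.sort_values("date").index
        ranks = [STAGE_INDEX[predictions.loc[s]] for s in ordered]
        for a, b in zip(ranks, ranks[1:]):
            total += 1
            ok += int(b >= a)
    return ok / total if total else 1.0


def crossplatform_predict(model: StageClassifier,
                          relative_expression: pd.DataFrame,
                          metadata: pd.DataFrame,
                          reference_dates: dict | None = None,
                          reference_month: int = 10) -> pd.DataFrame:
    """Predict stages for qPCR-quantified samples with an RNA-seq model.

    October-normalizes the relative expression (genes x samples),
    projects with the RNA-seq-fitted PCA, and applies the softmax model.
    Returns per-sample predictions with class probabilities; the returned
    frame carries the chronology-consistency fraction in
    ``.attrs["chronology_consistency"]``.
    """
    if model.pca_ is None:
        raise BudphaseError("cross-platform prediction needs a PCA-backed model")
    missing = [g for g in model.pca_.feature_ids
               if g not in relative_expression.index]
    if missing:
        raise BudphaseError(f"qPCR data missing marker genes: {missing}")
    panel = relative_expression.loc[model.pca_.feature_ids]
    normalized = october_normalize(panel, metadata,
                                   reference_dates=reference_dates,
                                   reference_month=reference_month)
    X = normalized.T
    labels = model.predict(X)
    proba = model.predict_proba(X)
    out = pd.DataFrame({"sample_id": X.index, "predicted_stage": labels})
    for j, cls in enumerate(model.classes_):
        out[f"p_{cls}"] = proba[:, j]
    preds = pd.Series(labels, index=X.index)
    out.attrs["chronology_consistency"] = stage_chronology_consistency(
        metadata, preds)
    return out
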