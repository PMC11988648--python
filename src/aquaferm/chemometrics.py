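"""PCA, PCA-LDA fermentation-time classification and PLS regression.

The multivariate core of the pipeline, authored in-package:

* :class:`SpectralPCA` — mean-centered SVD with a fixed sign convention;
* :class:`PCALDAClassifier` — linear discriminant (pooled within-class
  covariance, equal priors) on PCA scores, the classifier used to
  discriminate fermentation times;
* :class:`PLSRegressor` — univariate-response NIPALS partial least squares
  for pH and log cell-count calibration.

Cross-validation follows the measurement design: a grouped three-fold plan
in which all consecutive scans of one (sample, replicate) block share a
fold (fold = replicate), so scans of the same pour never leak between
training and validation.  Model-order selection scans candidate counts
(NrPCs up to 30 for PCA-LDA, NrLVs by minimal RMSECV for PLS) under that
plan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, TransformerMixin

from .exceptions import AquafermError
from .spectra_io import SpectraSet


def _as_matrix(spectra) -> np.ndarray:
    if isinstance(spectra, SpectraSet):
        return spectra.absorbance
    return np.atleast_2d(np.asarray(spectra, float))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class SpectralPCA(TransformerMixin, BaseEstimator):
    """Column-mean-centered PCA via SVD.

    Sign convention: in each loading vector the element of largest
    magnitude is positive, so fitted models are bit-reproducible.

    Attributes (after fit): ``mean_``, ``components_`` (k x p),
    ``explained_variance_ratio_``, ``singular_values_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = _as_matrix(X)
        n, p = X.shape
        if n < 2:
            raise AquafermError("PCA needs at least two spectra")
        k_max = min(n - 1, p)
        k = k_max if self.n_components is None else int(self.n_components)
        if k < 1 or k > k_max:
            raise AquafermError(f"n_components={k} not in [1, {k_max}]")
        self.mean_ = X.mean(axis=0)
        U, s, Vt = np.linalg.svd(X - self.mean_, full_matrices=False)
        # deterministic sign: largest-|element| loading entry positive
        flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
        flip[flip == 0] = 1.0
        Vt = Vt * flip[:, None]
        var = s**2
        total = var.sum()
        self.components_ = Vt[:k]
        self.singular_values_ = s[:k]
        self.explained_variance_ratio_ = (
            var[:k] / total if total > 0 else np.zeros(k)
        )
        return self

    def transform(self, X):
        X = _as_matrix(X)
        return (X - self.mean_) @ self.components_.T


@dataclass
class PCAModel:
    """Fitted PCA: center, orthonormal loadings (p x k), scores, variance ratios."""

    center: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    wavelengths: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(spectra, max_pcs: int | None = None) -> PCAModel:
    """Fit PCA on a SpectraSet (or matrix) and package the model."""
    est = SpectralPCA(n_components=max_pcs).fit(spectra)
    X = _as_matrix(spectra)
    wl = spectra.wavelengths if isinstance(spectra, SpectraSet) else None
    return PCAModel(
        center=est.mean_,
        loadings=est.components_.T,
        scores=est.transform(X),
        explained_variance_ratio=est.explained_variance_ratio_,
        wavelengths=wl,
    )


def _peak_wavelengths(vector: np.ndarray, wavelengths: np.ndarray, k: int, min_frac: float) -> list:
    """Top-k |vector| wavelengths plus local |vector| maxima above min_frac of max."""
    a = np.abs(np.asarray(vector, float))
    vmax = a.max()
    if vmax == 0:
        return []
    order = np.argsort(a)[::-1]
    picked = set(order[:k].tolist())
    interior = np.flatnonzero((a[1:-1] >= a[:-2]) & (a[1:-1] >= a[2:])) + 1
    picked |= {int(i) for i in interior if a[i] >= min_frac * vmax}
    idx = sorted(picked, key=lambda i: -a[i])
    return [float(wavelengths[i]) for i in idx]


def top_loading_wavelengths(model: PCAModel, pc: int, k: int, min_frac: float = 0.5) -> list:
    """Most influential wavelengths of one PC (1-based index).

    The k largest |loading| entries, augmented with all local maxima of
    |loading| above ``min_frac`` of its global maximum, magnitude-sorted.
    """
    if pc < 1 or pc > model.n_components:
        raise AquafermError(f"pc={pc} outside fitted components 1..{model.n_components}")
    if k < 1 or k > model.loadings.shape[0]:
        raise AquafermError(f"k={k} outside [1, {model.loadings.shape[0]}]")
    if model.wavelengths is None:
        raise AquafermError("model carries no wavelength axis")
    return _peak_wavelengths(model.loadings[:, pc - 1], model.wavelengths, k, min_frac)


# ---------------------------------------------------------------------------
# Grouped fold plan
# ---------------------------------------------------------------------------


def make_fold_plan(spectra: SpectraSet, n_folds: int = 3) -> np.ndarray:
    """Fold index per row; all scans of one (sample_id, replicate) share a fold.

    With the standard three-replicate design, fold = replicate, so every
    fold holds one complete measurement repetition of every sample.  Other
    replicate counts fall back to a round-robin over replicates (warned).
    """
    meta = spectra.meta
    reps = np.sort(meta["replicate"].unique())
    if len(reps) == n_folds:
        fold_of = {r: i + 1 for i, r in enumerate(reps)}
    else:
        warnings.warn(
            f"{len(reps)} replicate level(s) for {n_folds} folds; using round-robin by replicate",
            stacklevel=2,
        )
        fold_of = {r: (i % n_folds) + 1 for i, r in enumerate(reps)}
    plan = meta["replicate"].map(fold_of).to_numpy(int)
    _assert_no_block_split(meta, plan)
    return plan


def _assert_no_block_split(meta: pd.DataFrame, plan: np.ndarray) -> None:
    per_block = pd.DataFrame(
        {"b": meta["sample_id"].astype(str) + "/" + meta["replicate"].astype(str), "f": plan}
    ).groupby("b")["f"].nunique()
    if (per_block > 1).any():
        raise AquafermError("fold plan splits a (sample_id, replicate) scan block")


def iter_folds(plan: np.ndarray):
    """Yield (fold_id, train_idx, val_idx) over the plan."""
    plan = np.asarray(plan)
    for f in np.unique(plan):
        val = np.flatnonzero(plan == f)
        train = np.flatnonzero(plan != f)
        yield int(f), train, val


# ---------------------------------------------------------------------------
# PCA-LDA
# ---------------------------------------------------------------------------


class PCALDAClassifier(ClassifierMixin, BaseEstimator):
    """Linear discriminant on PCA scores with equal class priors.

    PCA is fit on the training spectra only; a pooled within-class
    covariance in score space defines a Mahalanobis discriminant (ridge
    ``ridge * mean-diagonal`` is added when the pooled covariance is
    singular).  ``transform_canonical`` projects onto the Fisher canonical
    axes for score plots.
    """

    def __init__(self, n_components: int = 2, ridge: float = 1e-8):
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y)
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise AquafermError("PCA-LDA needs at least two classes")
        self.classes_ = classes
        self.pca_ = SpectralPCA(n_components=self.n_components).fit(X)
        Z = self.pca_.transform(X)
        k = Z.shape[1]
        means = np.vstack([Z[y_idx == c].mean(axis=0) for c in range(classes.size)])
        Sw = np.zeros((k, k))
        for c in range(classes.size):
            R = Z[y_idx == c] - means[c]
            Sw += R.T @ R
        dof = max(len(y) - classes.size, 1)
        Sw /= dof
        scale = np.trace(Sw) / k if np.trace(Sw) > 0 else 1.0
        try:
            cho = sla.cho_factor(Sw)
            self.ridge_used_ = 0.0
        except np.linalg.LinAlgError:
            Sw = Sw + self.ridge * scale * np.eye(k)
            cho = sla.cho_factor(Sw)
            self.ridge_used_ = self.ridge * scale
        self.means_ = means
        self._cho = cho
        self.pooled_cov_ = Sw
        # Fisher canonical axes: eigenvectors of Sw^-1 Sb
        Sb = np.zeros((k, k))
        grand = Z.mean(axis=0)
        for c in range(classes.size):
            d = (means[c] - grand)[:, None]
            Sb += (np.sum(y_idx == c)) * (d @ d.T)
        evals, evecs = sla.eigh(Sb, Sw + 1e-12 * scale * np.eye(k))
        order = np.argsort(evals)[::-1][: classes.size - 1]
        axes = evecs[:, order]
        flip = np.sign(axes[np.argmax(np.abs(axes), axis=0), np.arange(axes.shape[1])])
        flip[flip == 0] = 1.0
        self.canonical_axes_ = axes * flip
        return self

    def _mahalanobis2(self, X) -> np.ndarray:
        Z = self.pca_.transform(_as_matrix(X))
        d2 = np.empty((Z.shape[0], self.means_.shape[0]))
        for c in range(self.means_.shape[0]):
            R = Z - self.means_[c]
            d2[:, c] = np.sum(R * sla.cho_solve(self._cho, R.T).T, axis=1)
        return d2

    def decision_function(self, X) -> np.ndarray:
        return -0.5 * self._mahalanobis2(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def transform_canonical(self, X) -> np.ndarray:
        Z = self.pca_.transform(_as_matrix(X))
        return Z @ self.canonical_axes_


@dataclass
class ClassificationResult:
    """PCA-LDA outcome under the grouped fold plan."""

    nrpcs: int
    train_accuracy: float  # percent, mean over folds
    cv_accuracy: float  # percent, pooled held-out predictions
    confusion: pd.DataFrame  # rows = actual class, cols = predicted
    canonical_scores: np.ndarray  # all-data model, rows align with input
    classes: np.ndarray
    candidate_table: pd.DataFrame | None = None


def _accuracy(y_true, y_pred) -> float:
    return 100.0 * float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


def _lda_fold_accuracies(X, y, plan, nrpcs, ridge=1e-8):
    train_accs, pooled_true, pooled_pred = [], [], []
    for _, tr, va in iter_folds(plan):
        clf = PCALDAClassifier(n_components=nrpcs, ridge=ridge).fit(X[tr], y[tr])
        train_accs.append(_accuracy(y[tr], clf.predict(X[tr])))
        pooled_true.append(y[va])
        pooled_pred.append(clf.predict(X[va]))
    y_true = np.concatenate(pooled_true)
    y_pred = np.concatenate(pooled_pred)
    return float(np.mean(train_accs)), _accuracy(y_true, y_pred), y_true, y_pred


def select_nrpcs(
    spectra, labels, plan: np.ndarray, max_pcs: int = 30
) -> tuple[int, pd.DataFrame]:
    """Scan NrPC candidates 1..max_pcs under the fold plan.

    Selection precedence: highest validation accuracy, then smallest
    |train - validation| gap, then the smallest candidate.  The full
    candidate table is returned for audit.
    """
    X = _as_matrix(spectra)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise AquafermError("need at least two classes")
    min_train = min(len(tr) for _, tr, _ in iter_folds(plan))
    cap = min(max_pcs, min_train - 1, X.shape[1])
    if cap < max_pcs:
        warnings.warn(f"max_pcs capped at {cap} by data size", stacklevel=2)
    records = []
    for nrpcs in range(1, cap + 1):
        try:
            train, val, *_ = _lda_fold_accuracies(X, y, plan, nrpcs)
        except (AquafermError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"NrPC={nrpcs} skipped: {exc}", stacklevel=2)
            continue
        records.append({"nrpcs": nrpcs, "train_accuracy": train, "cv_accuracy": val,
                        "gap": abs(train - val)})
    if not records:
        raise AquafermError("no usable NrPC candidate")
    table = pd.DataFrame(records)
    best = table.sort_values(
        ["cv_accuracy", "gap", "nrpcs"], ascending=[False, True, True], kind="mergesort"
    ).iloc[0]
    return int(best["nrpcs"]), table


def pca_lda_classify(spectra, labels, nrpcs: int, plan: np.ndarray) -> ClassificationResult:
    """Grouped-CV PCA-LDA at a fixed NrPC plus an all-data model for plotting."""
    X = _as_matrix(spectra)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise AquafermError("need at least two classes")
    if isinstance(spectra, SpectraSet):
        _assert_no_block_split(spectra.meta, plan)
    train, val, y_true, y_pred = _lda_fold_accuracies(X, y, plan, nrpcs)
    conf = pd.crosstab(
        pd.Categorical(y_true, categories=classes),
        pd.Categorical(y_pred, categories=classes),
        dropna=False,
    )
    conf.index.name, conf.columns.name = "actual", "predicted"
    final = PCALDAClassifier(n_components=nrpcs).fit(X, y)
    return ClassificationResult(
        nrpcs=nrpcs,
        train_accuracy=train,
        cv_accuracy=val,
        confusion=conf,
        canonical_scores=final.transform_canonical(X),
        classes=classes,
    )


# ---------------------------------------------------------------------------
# PLS regression
# ---------------------------------------------------------------------------


class PLSRegressor(RegressorMixin, BaseEstimator):
    """Univariate-response NIPALS partial least squares.

    Deflation stops early if a component's score norm collapses (rank
    exhausted), so ``n_components`` is an upper bound on noiseless data.
    Attributes: ``x_mean_``, ``y_mean_``, ``x_weights_``, ``x_loadings_``,
    ``y_loadings_``, ``coef_`` (p,), ``n_components_``.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-12):
        self.n_components = n_components
        self.tol = tol

    def fit(self, X, y):
        X = _as_matrix(X).copy()
        y = np.asarray(y, float).ravel().copy()
        n, p = X.shape
        if y.size != n:
            raise AquafermError(f"y has {y.size} entries for {n} spectra")
        if np.ptp(y) == 0:
            raise AquafermError("constant response: PLS undefined")
        if not (1 <= self.n_components < n):
            raise AquafermError(f"n_components must be in [1, {n - 1}]")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        x_scale = float(np.sqrt((Xc**2).sum()))
        W, P, Q = [], [], []
        for _ in range(self.n_components):
            w = Xc.T @ yc
            wn = np.linalg.norm(w)
            if wn <= self.tol * max(x_scale, 1.0):
                break
            w /= wn
            t = Xc @ w
            tt = float(t @ t)
            if tt <= (self.tol * max(x_scale, 1.0)) ** 2:
                break
            pvec = (Xc.T @ t) / tt
            q = float(yc @ t) / tt
            Xc = Xc - np.outer(t, pvec)
            yc = yc - q * t
            W.append(w)
            P.append(pvec)
            Q.append(q)
        if not W:
            raise AquafermError("no usable PLS component (X orthogonal to y)")
        Wm, Pm, Qv = np.array(W).T, np.array(P).T, np.array(Q)
        self.n_components_ = Wm.shape[1]
        self.x_weights_, self.x_loadings_, self.y_loadings_ = Wm, Pm, Qv
        self.coef_ = Wm @ np.linalg.solve(Pm.T @ Wm, Qv)
        return self

    def predict(self, X):
        X = _as_matrix(X)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


@dataclass
class PLSModel:
    """Fitted PLS calibration with grouped-CV metrics."""

    nrlv: int
    regression_vector: np.ndarray
    y_center: float
    wavelengths: np.ndarray | None
    r2c: float = np.nan
    rmsec: float = np.nan
    r2cv: float = np.nan
    rmsecv: float = np.nan
    predictions: pd.DataFrame | None = None
    estimator: PLSRegressor | None = field(default=None, repr=False)


def fit_plsr(spectra, y, nrlv: int) -> PLSModel:
    """All-data PLS calibration at a fixed latent-variable count."""
    est = PLSRegressor(n_components=nrlv).fit(spectra, y)
    wl = spectra.wavelengths if isinstance(spectra, SpectraSet) else None
    y = np.asarray(y, float).ravel()
    fitted = est.predict(spectra)
    return PLSModel(
        nrlv=est.n_components_,
        regression_vector=est.coef_,
        y_center=est.y_mean_,
        wavelengths=wl,
        r2c=r2_score(y, fitted),
        rmsec=rmse(y, fitted),
        predictions=pd.DataFrame({"actual": y, "fitted": fitted}),
        estimator=est,
    )


def rmse(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r2_score(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true, float), np.asarray(y_pred, float)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def _cv_predictions(X, y, plan, nrlv) -> np.ndarray:
    yhat = np.full(len(y), np.nan)
    for _, tr, va in iter_folds(plan):
        est = PLSRegressor(n_components=min(nrlv, len(tr) - 1)).fit(X[tr], y[tr])
        yhat[va] = est.predict(X[va])
    return yhat


def select_nrlvs(spectra, y, plan: np.ndarray, max_lv: int = 10) -> tuple[int, pd.DataFrame]:
    """Pick the latent-variable count with minimal RMSECV (ties -> smaller)."""
    X = _as_matrix(spectra)
    y = np.asarray(y, float).ravel()
    if max_lv < 1:
        raise AquafermError("max_lv must be >= 1")
    min_train = min(len(tr) for _, tr, _ in iter_folds(plan))
    cap = min(max_lv, min_train - 1)
    rows = []
    for nrlv in range(1, cap + 1):
        yhat = _cv_predictions(X, y, plan, nrlv)
        rows.append({"nrlv": nrlv, "rmsecv": rmse(y, yhat)})
    curve = pd.DataFrame(rows)
    best = int(curve.loc[curve["rmsecv"].idxmin(), "nrlv"])  # idxmin keeps first on ties
    return best, curve


def evaluate_plsr(spectra, y, nrlv: int, plan: np.ndarray) -> PLSModel:
    """Calibration (all-data fit) plus pooled held-out validation metrics."""
    X = _as_matrix(spectra)
    y = np.asarray(y, float).ravel()
    if isinstance(spectra, SpectraSet):
        _assert_no_block_split(spectra.meta, plan)
    model = fit_plsr(spectra, y, nrlv)
    ycv = _cv_predictions(X, y, plan, nrlv)
    model.r2cv = r2_score(y, ycv)
    model.rmsecv = rmse(y, ycv)
    model.predictions = model.predictions.assign(cv_predicted=ycv)
    return model


def regression_vector_peaks(model: PLSModel | np.ndarray, k: int, min_frac: float = 0.1,
                            wavelengths: np.ndarray | None = None) -> list:
    """Local extrema of |regression vector| above min_frac of max, top k by magnitude."""
    if k < 1:
        raise AquafermError("k must be >= 1")
    if isinstance(model, PLSModel):
        vector, wl = model.regression_vector, model.wavelengths
    else:
        vector, wl = np.asarray(model, float), wavelengths
    if wl is None:
        wl = np.arange(vector.size, dtype=float)
    a = np.abs(vector)
    if a.max() == 0:
        return []
    interior = np.flatnonzero((a[1:-1] >= a[:-2]) & (a[1:-1] >= a[2:])) + 1
    cand = [int(i) for i in interior if a[i] >= min_frac * a.max()]
    for edge in (0, a.size - 1):  # edge extrema count too
        if a[edge] >= min_frac * a.max() and (edge not in cand):
            neighbor = 1 if edge == 0 else a.size - 2
            if a[edge] >= a[neighbor]:
                cand.append(edge)
    cand.sort(key=lambda i: -a[i])
    return [float(wl[i]) for i in cand[:k]]
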