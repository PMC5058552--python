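"""Six-class multinomial logit vegetation model.

Workflow: screen collinear predictors (Spearman |rs| > 0.7, keeping the one
with lower univariate AIC), fit a lightly ridged multinomial logit with the
alder class as reference, prune it by stepwise backward AIC, evaluate each
class one-vs-rest with Cohen's Kappa-maximum, ROC-AUC and sensitivity at the
Kappa-max threshold (on the training plots and under stratified k-fold
cross-validation), and finally extrapolate the model over the raster stack
into six probability surfaces and a hard argmax class map.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .raster import RasterGrid, RasterStack

__all__ = [
    "MultinomialVegetationClassifier",
    "extract_predictors",
    "screen_collinear",
    "fit_multinomial",
    "stepwise_backward_aic",
    "kappa_max",
    "auc",
    "sensitivity_at",
    "evaluate_vegclass",
    "predict_vegetation",
]


def extract_predictors(
    stack: RasterStack, x, y, predictors: list[str]
) -> pd.DataFrame:
    """Sample stack layers at point locations into a predictor table."""
    data = {name: stack[name].sample(x, y) for name in predictors}
    return pd.DataFrame(data)


class MultinomialVegetationClassifier(BaseEstimator, ClassifierMixin):
    """Multinomial logit over standardized predictors, reference class ALNUS.

    The coefficients maximize the multinomial log-likelihood with a tiny
    ridge (``ridge * ||w||^2`` on the standardized scale) for numerical
    stability under quasi-separation.  Reported coefficients are on the
    original predictor scale in the reference-class parameterization (the
    reference class's implicit coefficients are zero).

    Parameters
    ----------
    predictors : column names to use; ``None`` = all columns of ``X``.
    ridge : ridge strength on standardized coefficients (default 1e-6).
    reference_class : label whose coefficients are pinned at zero; falls back
        to the last class when absent from the training labels.
    required_classes : optional class vocabulary; fitting errors if any is
        missing from the training data.

    Attributes (after ``fit``)
    --------------------------
    classes_, coef_, intercept_ : reference-parameterized coefficients,
        rows aligned with ``classes_``.
    log_likelihood_, aic_, n_parameters_.
    """

    def __init__(
        self,
        predictors: list[str] | None = None,
        ridge: float = 1e-6,
        reference_class: str = "ALNUS",
        required_classes: tuple[str, ...] | None = None,
        max_iter: int = 2000,
        tol: float = 1e-10,
    ):
        self.predictors = predictors
        self.ridge = ridge
        self.reference_class = reference_class
        self.required_classes = required_classes
        self.max_iter = max_iter
        self.tol = tol

    # -- helpers ----------------------------------------------------------
    def _columns(self, X) -> list[str]:
        if self.predictors is not None:
            return list(self.predictors)
        if hasattr(X, "columns"):
            return list(X.columns)
        return [f"x{i}" for i in range(np.asarray(X).shape[1])]

    def _matrix(self, X) -> np.ndarray:
        cols = self.predictors_
        if hasattr(X, "columns"):
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise KeyError(f"missing predictor column(s): {missing}")
            return X[cols].to_numpy(dtype=float)
        A = np.asarray(X, dtype=float)
        if A.shape[1] != len(cols):
            raise ValueError("predictor count mismatch")
        return A

    def fit(self, X, y):
        self.predictors_ = self._columns(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if self.required_classes is not None:
            missing = [c for c in self.required_classes if c not in classes]
            if missing:
                raise ValueError(f"missing vegetation class(es) in training data: {missing}")
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        self.classes_ = classes
        A = self._matrix(X)
        if np.isnan(A).any():
            raise ValueError("NaN in predictor table (points on masked cells?)")
        self._mean_ = A.mean(axis=0)
        sd = A.std(axis=0, ddof=0)
        self._scale_ = np.where(sd > 0, sd, 1.0)
        Z = (A - self._mean_) / self._scale_
        # sklearn minimizes sum-logloss + (1/(2C)) ||w||^2  ==  -lnL + ridge ||w||^2
        self._lr_ = LogisticRegression(
            C=1.0 / (2.0 * self.ridge),
            solver="lbfgs",
            max_iter=self.max_iter,
            tol=self.tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._lr_.fit(Z, y)
        # reference-class parameterization on the original predictor scale
        ref = self.reference_class if self.reference_class in classes else classes[-1]
        self.reference_class_ = ref
        coef_std = self._lr_.coef_
        icpt_std = self._lr_.intercept_
        if coef_std.shape[0] == 1:  # sklearn binary convention: row is classes_[1]
            coef_std = np.vstack([-coef_std[0] / 2, coef_std[0] / 2])
            icpt_std = np.array([-icpt_std[0] / 2, icpt_std[0] / 2])
        ridx = int(np.where(self._lr_.classes_ == ref)[0][0])
        coef_ref = coef_std - coef_std[ridx]
        icpt_ref = icpt_std - icpt_std[ridx]
        self.coef_ = coef_ref / self._scale_
        self.intercept_ = icpt_ref - (coef_ref * self._mean_ / self._scale_).sum(axis=1)
        # order rows by self.classes_ (== sklearn's sorted unique labels)
        order = [int(np.where(self._lr_.classes_ == c)[0][0]) for c in self.classes_]
        self.coef_ = self.coef_[order]
        self.intercept_ = self.intercept_[order]
        P = self.predict_proba(X)
        idx = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([idx[v] for v in y])
        self.log_likelihood_ = float(np.log(np.clip(P[np.arange(len(y)), yi], 1e-300, None)).sum())
        self.n_parameters_ = int((len(classes) - 1) * (len(self.predictors_) + 1))
        self.aic_ = 2.0 * self.n_parameters_ - 2.0 * self.log_likelihood_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        A = self._matrix(X)
        eta = A @ self.coef_.T + self.intercept_
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def predict(self, X) -> np.ndarray:
        P = self.predict_proba(X)
        return self.classes_[np.argmax(P, axis=1)]

    def coef_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "coef_")
        df = pd.DataFrame(self.coef_, index=self.classes_, columns=self.predictors_)
        df.insert(0, "(intercept)", self.intercept_)
        return df


def fit_multinomial(
    plots_X: pd.DataFrame, y, predictors=None, ridge: float = 1e-6, **kwargs
) -> MultinomialVegetationClassifier:
    """Functional wrapper over :class:`MultinomialVegetationClassifier`."""
    return MultinomialVegetationClassifier(
        predictors=predictors, ridge=ridge, **kwargs
    ).fit(plots_X, y)


def _univariate_aic(X: pd.DataFrame, y, col: str) -> float:
    m = MultinomialVegetationClassifier(predictors=[col]).fit(X, y)
    return m.aic_


def screen_collinear(
    X: pd.DataFrame, y, rs_threshold: float = 0.7
) -> list[str]:
    """Drop one member of each highly rank-correlated predictor pair.

    Among pairs with Spearman |rs| > ``rs_threshold`` the survivor is the
    predictor with the lower univariate multinomial AIC ("higher explanatory
    power").  Constant predictors have undefined rank correlation; they are
    treated as uncorrelated and flagged with a warning.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        return cols
    rho = stats.spearmanr(X.to_numpy(dtype=float), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    if np.isnan(rho).any():
        warnings.warn("constant predictor(s): undefined Spearman rho treated as 0")
        rho = np.nan_to_num(rho, nan=0.0)
    aics: dict[str, float] = {}

    def aic_of(c: str) -> float:
        if c not in aics:
            aics[c] = _univariate_aic(X, y, c)
        return aics[c]

    retained = list(cols)
    while True:
        worst = None
        worst_r = rs_threshold
        for ai in range(len(retained)):
            for bi in range(ai + 1, len(retained)):
                i, j = cols.index(retained[ai]), cols.index(retained[bi])
                r = abs(rho[i, j])
                if r > worst_r:
                    worst, worst_r = (retained[ai], retained[bi]), r
        if worst is None:
            return retained
        a, b = worst
        drop = a if aic_of(a) > aic_of(b) else b
        retained.remove(drop)


def stepwise_backward_aic(
    model: MultinomialVegetationClassifier, X: pd.DataFrame, y
) -> MultinomialVegetationClassifier:
    """Iteratively remove the predictor whose removal most lowers the AIC.

    Stops when no single removal lowers the AIC; the returned model's AIC is
    <= the starting model's.
    """
    check_is_fitted(model, "aic_")
    current = model
    while len(current.predictors_) > 1:
        best = None
        for drop in current.predictors_:
            cand_cols = [c for c in current.predictors_ if c != drop]
            cand = MultinomialVegetationClassifier(
                predictors=cand_cols,
                ridge=current.ridge,
                reference_class=current.reference_class,
                max_iter=current.max_iter,
                tol=current.tol,
            ).fit(X, y)
            if cand.aic_ < current.aic_ and (best is None or cand.aic_ < best.aic_):
                best = cand
        if best is None:
            break
        current = best
    return current


def kappa_max(scores, labels, grid_step: float = 0.005) -> tuple[float, float]:
    """Cohen's kappa maximized over a fine threshold grid.

    Thresholds run 0, step, ..., 1; a point is predicted present when its
    score >= threshold.  Returns ``(kappa, threshold)`` with the smallest
    threshold attaining the maximum.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    n = len(labels)
    thresholds = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    pred = scores[None, :] >= thresholds[:, None]
    pos = labels[None, :]
    tp = (pred & pos).sum(axis=1).astype(float)
    fp = (pred & ~pos).sum(axis=1).astype(float)
    fn = ((~pred) & pos).sum(axis=1).astype(float)
    tn = ((~pred) & ~pos).sum(axis=1).astype(float)
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(pe < 1.0, (po - pe) / (1.0 - pe), 0.0)
    i = int(np.argmax(kappa))
    return float(kappa[i]), float(thresholds[i])


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) ROC-AUC; ties count one half."""
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def sensitivity_at(scores, labels, threshold: float) -> float:
    """Proportion of true presences with score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    return float((scores[labels] >= threshold).mean())


def _per_class_metrics(P: np.ndarray, y, classes, grid_step: float) -> pd.DataFrame:
    rows = {}
    for k, c in enumerate(classes):
        lab = np.asarray(y) == c
        kap, thr = kappa_max(P[:, k], lab, grid_step)
        rows[c] = {
            "kappa_max": kap,
            "threshold": thr,
            "auc": auc(P[:, k], lab),
            "sensitivity": sensitivity_at(P[:, k], lab, thr),
        }
    return pd.DataFrame(rows).T


def evaluate_vegclass(
    model: MultinomialVegetationClassifier,
    X: pd.DataFrame,
    y,
    k: int = 3,
    grid_step: float = 0.005,
    random_state: int = 0,
) -> dict:
    """Per-class fit and cross-validated accuracy of the vegetation model.

    ``fit`` metrics come from the model refitted on all plots; ``cv`` metrics
    are the mean and SD over stratified folds of Kappa-max, AUC and
    sensitivity computed one-vs-rest from held-out class probabilities.
    """
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    k_eff = int(min(k, counts.min()))
    if k_eff < k:
        warnings.warn(f"rarest class has {counts.min()} plots; using {k_eff} folds")
    fitted = MultinomialVegetationClassifier(**model.get_params()).fit(X, y)
    fit_tab = _per_class_metrics(fitted.predict_proba(X), y, fitted.classes_, grid_step)

    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=random_state)
    fold_tabs = []
    for train, test in skf.split(X, y):
        m = MultinomialVegetationClassifier(**model.get_params()).fit(X.iloc[train], y[train])
        P = m.predict_proba(X.iloc[test])
        # held-out folds may miss a rare class entirely; evaluate present ones
        present = [c for c in m.classes_ if (y[test] == c).any() and not (y[test] == c).all()]
        cols = [int(np.where(m.classes_ == c)[0][0]) for c in present]
        fold_tabs.append(_per_class_metrics(P[:, cols], y[test], present, grid_step))
    cv_concat = pd.concat(fold_tabs, keys=range(len(fold_tabs)), names=["fold"])
    cv_mean = cv_concat.groupby(level=1).mean()
    cv_sd = cv_concat.groupby(level=1).std(ddof=1)
    return {"fit": fit_tab, "cv_mean": cv_mean, "cv_sd": cv_sd, "model": fitted, "k": k_eff}


def predict_vegetation(
    model: MultinomialVegetationClassifier,
    stack: RasterStack,
    irrelevant_mask: np.ndarray | None = None,
) -> tuple[RasterStack, RasterGrid]:
    """Extrapolate the model over the study area.

    Returns a stack of per-class probability grids (summing to one at every
    unmasked cell) and the hard argmax class map (values = indices into
    ``model.classes_``).  Cells flagged irrelevant (lakes, glaciers, rocks,
    dense forest) or masked in any predictor layer are masked in the output.
    """
    check_is_fitted(model, "coef_")
    ref = stack[model.predictors_[0]]
    valid = np.ones(ref.shape, dtype=bool)
    for name in model.predictors_:
        valid &= stack[name].valid
    if irrelevant_mask is not None:
        valid &= ~np.asarray(irrelevant_mask, dtype=bool)
    X = pd.DataFrame({n: stack[n].values[valid] for n in model.predictors_})
    probs = RasterStack()
    hard_vals = np.zeros(ref.shape)
    if len(X):
        P = model.predict_proba(X)
        hard_vals[valid] = np.argmax(P, axis=1)
        for k, c in enumerate(model.classes_):
            vals = np.zeros(ref.shape)
            vals[valid] = P[:, k]
            probs.add(str(c), ref.like(vals, mask=~valid))
    else:
        for c in model.classes_:
            probs.add(str(c), ref.like(np.zeros(ref.shape), mask=~valid))
    hard = ref.like(hard_vals, mask=~valid)
    return probs, hard
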