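"""Presence-background maximum-entropy habitat model.

The model contrasts environmental conditions at species presence points with
a large uniform background sample of the landscape.  Over a feature
expansion of the predictors (linear, quadratic, and forward/reverse hinge
features, all scaled to [0, 1] by the background range) it fits the Gibbs
density

    q_lambda(x) = exp(lambda . f(x)) / Z_lambda,   Z over the background,

maximizing the penalized presence log-likelihood

    (1/m) sum_presences lambda . f  -  log Z_lambda  -  sum_j beta_j |lambda_j|

with per-feature regularization beta_j proportional to the presence-sample
standard deviation of the feature over sqrt(m) — the "stay within the
confidence interval of the empirical feature mean" rationale.  At the
optimum every feature satisfies |presence mean - model mean| <= beta_j, the
defining maximum-entropy property, which the fitted model records.

The solver splits lambda into positive and negative parts and runs L-BFGS-B
on the resulting smooth bound-constrained problem, to a projected-gradient
tolerance that is strictly stronger than the historical "log-likelihood gain
below 1e-5" rule; both the gain-based convergence iteration and the final
stationarity gap are exposed.  The objective trajectory is monotone.

Raw Gibbs densities are mapped to a [0, 1] "relative suitability" score via
the logistic-style transform c*q/(1 + c*q), with c calibrated so that the
mean score over the training presences is 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .raster import (
    RasterGrid,
    RasterStack,
    WindowSpec,
    focal_density,
    focal_mean,
    focal_proportion,
    focal_std,
    simpson_diversity,
)

__all__ = [
    "Feature",
    "FeatureSet",
    "MaxentSDM",
    "HabitatMaps",
    "assemble_sdm_predictors",
    "background_table",
    "presence_table",
    "make_features",
    "fit_maxent",
    "cv_auc",
    "jackknife_select",
    "threshold_max_ss",
    "predict_suitability",
    "response_curve",
    "curve_optimum",
    "permutation_importance",
    "SDM_LAYER_CODES",
]

#: Habitat-model predictor codes, in canonical order.
SDM_LAYER_CODES = (
    "SLOPE",
    "NORTH",
    "EAST",
    "ROUGH",
    "ROCK",
    "TAVE6",
    "PREC6",
    "SOLR6",
    "SOLD6",
    "ROAD",
    "SETTLE",
    "OFOREST",
    "DFOREST",
    "TREE",
    "MEADOW",
    "RHODO",
    "JUNI",
    "MIXED",
    "ALNUS",
    "SIDI",
)


# -- predictor assembly ----------------------------------------------------


def _bool_proportion(grid: RasterGrid, window: WindowSpec) -> RasterGrid:
    return focal_mean(grid, window)


def _class_proportion(
    class_map: RasterGrid, code: int, window: WindowSpec
) -> RasterGrid:
    present = np.any(class_map.values[class_map.valid] == code)
    if not present:
        s, = np.broadcast_shapes(class_map.shape),
        return class_map.like(np.zeros(class_map.shape), mask=class_map.mask.copy())
    return focal_proportion(class_map, [code], window)


def assemble_sdm_predictors(
    stack: RasterStack,
    veg_class_map: RasterGrid,
    class_names,
    window: WindowSpec = WindowSpec(100.0),
) -> RasterStack:
    """Summarize raw layers into the habitat-model predictor set at 100 m.

    Continuous layers become focal means, boolean layers focal proportions,
    point/line layers focal densities (per hectare), the vegetation classes
    of ``veg_class_map`` (codes indexing ``class_names``) become focal cover
    proportions — the pasture class is exposed under the code MEADOW, forest
    under DFOREST — and SIDI is Simpson's diversity of the five non-forest
    vegetation proportions.
    """
    class_names = list(class_names)
    code_of = {c: i for i, c in enumerate(class_names)}
    for needed in ("PASTURE", "RHODO", "JUNI", "MIXED", "ALNUS", "FOREST"):
        if needed not in code_of:
            raise ValueError(f"class vocabulary lacks {needed}")
    out = RasterStack()
    for name in ("SLOPE", "NORTH", "EAST"):
        out.add(name, focal_mean(stack[name], window))
    out.add("ROUGH", focal_std(stack["DEM"], window))
    out.add("ROCK", _bool_proportion(stack["ROCK"], window))
    for name in ("TAVE6", "PREC6", "SOLR6", "SOLD6"):
        out.add(name, focal_mean(stack[name], window))
    out.add("ROAD", focal_density(stack["ROAD"], window))
    out.add("SETTLE", _bool_proportion(stack["SETTLE"], window))
    out.add("OFOREST", _bool_proportion(stack["OFOREST"], window))
    out.add("DFOREST", _class_proportion(veg_class_map, code_of["FOREST"], window))
    out.add("TREE", focal_density(stack["TREE"], window))
    veg_layers = []
    for layer, cls in zip(
        ("MEADOW", "RHODO", "JUNI", "MIXED", "ALNUS"),
        ("PASTURE", "RHODO", "JUNI", "MIXED", "ALNUS"),
    ):
        g = _class_proportion(veg_class_map, code_of[cls], window)
        out.add(layer, g)
        veg_layers.append(g)
    out.add("SIDI", simpson_diversity(veg_layers))
    return RasterStack({code: out[code] for code in SDM_LAYER_CODES})


def background_table(
    pred_stack: RasterStack,
    n: int = 10000,
    random_state=None,
    exclude_mask: np.ndarray | None = None,
    variables: list[str] | None = None,
):
    """Uniform background sample (without replacement) from unmasked cells.

    Returns ``(table, (rows, cols))``.  If fewer than ``n`` cells are
    available, all of them are used (with a warning).
    """
    rng = np.random.default_rng(random_state)
    variables = list(variables) if variables is not None else pred_stack.names
    valid = np.ones(pred_stack[variables[0]].shape, dtype=bool)
    for v in variables:
        valid &= pred_stack[v].valid
    if exclude_mask is not None:
        valid &= ~np.asarray(exclude_mask, dtype=bool)
    idx = np.argwhere(valid)
    if len(idx) == 0:
        raise ValueError("no valid cells to sample background from")
    if len(idx) < n:
        warnings.warn(f"only {len(idx)} valid cells; using all as background")
        take = np.arange(len(idx))
    else:
        take = rng.choice(len(idx), size=n, replace=False)
    rows, cols = idx[take, 0], idx[take, 1]
    tab = pd.DataFrame({v: pred_stack[v].values[rows, cols] for v in variables})
    return tab, (rows, cols)


def presence_table(
    pred_stack: RasterStack,
    presences: pd.DataFrame,
    variables: list[str] | None = None,
    max_precision_m: float = 100.0,
) -> pd.DataFrame:
    """Predictor values at presence points.

    Enforces the precision filter when the table carries a ``precision_m``
    column; points falling on masked cells are dropped with a warning.
    """
    variables = list(variables) if variables is not None else pred_stack.names
    pres = presences
    if "precision_m" in presences.columns:
        pres = presences[presences["precision_m"] <= max_precision_m]
    tab = pd.DataFrame(
        {v: pred_stack[v].sample(pres["x"].to_numpy(), pres["y"].to_numpy()) for v in variables}
    )
    bad = tab.isna().any(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} presence point(s) on masked cells dropped")
        tab = tab[~bad].reset_index(drop=True)
    return tab


# -- features --------------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    """One scaled feature of a source variable; values always in [0, 1]."""

    kind: str  # linear | quadratic | hinge_fwd | hinge_rev
    var: str
    knot: float | None
    lo: float
    hi: float

    def transform(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        span = self.hi - self.lo
        if span <= 0:
            return np.zeros_like(v)
        if self.kind == "linear":
            return np.clip((v - self.lo) / span, 0.0, 1.0)
        if self.kind == "quadratic":
            return np.clip((v - self.lo) / span, 0.0, 1.0) ** 2
        if self.kind == "hinge_fwd":
            return np.clip((v - self.knot) / (self.hi - self.knot), 0.0, 1.0)
        if self.kind == "hinge_rev":
            return np.clip((self.knot - v) / (self.knot - self.lo), 0.0, 1.0)
        raise ValueError(f"unknown feature kind {self.kind!r}")


class FeatureSet:
    """Ordered collection of features with their scaling bounds."""

    def __init__(self, features: list[Feature]):
        self.features = list(features)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            if f.var not in seen:
                seen.append(f.var)
        return seen

    def bounds(self, var: str) -> tuple[float, float]:
        for f in self.features:
            if f.var == var:
                return f.lo, f.hi
        raise KeyError(var)

    @classmethod
    def from_background(
        cls,
        background: pd.DataFrame,
        n_hinge_knots: int = 10,
        feature_types: str = "lqh",
    ) -> "FeatureSet":
        """Build features with scaling bounds and knots from the background.

        Per variable: one linear and one quadratic feature, plus forward and
        reverse hinges at ``n_hinge_knots`` interior knots — half at interior
        quantiles of the background distribution (resolution where the data
        mass sits) and half evenly spaced over the background range (so
        zero-inflated variables such as cover proportions keep flexibility at
        rarely-observed high values).  Zero-variance variables keep only
        their (identically zero) linear/quadratic features and are flagged.
        """
        feats: list[Feature] = []
        for var in background.columns:
            v = background[var].to_numpy(dtype=float)
            lo, hi = float(np.min(v)), float(np.max(v))
            if hi <= lo:
                warnings.warn(f"variable {var!r} has zero variance over the background")
                if "l" in feature_types:
                    feats.append(Feature("linear", var, None, lo, hi))
                if "q" in feature_types:
                    feats.append(Feature("quadratic", var, None, lo, hi))
                continue
            if "l" in feature_types:
                feats.append(Feature("linear", var, None, lo, hi))
            if "q" in feature_types:
                feats.append(Feature("quadratic", var, None, lo, hi))
            if "h" in feature_types and n_hinge_knots > 0:
                nq = (n_hinge_knots + 1) // 2
                ne = n_hinge_knots - nq
                qknots = np.quantile(v, np.arange(1, nq + 1) / (nq + 1))
                eknots = lo + (hi - lo) * np.arange(1, ne + 1) / (ne + 1)
                for t in np.unique(np.concatenate([qknots, eknots])):
                    t = float(t)
                    if lo < t < hi:
                        feats.append(Feature("hinge_fwd", var, t, lo, hi))
                        feats.append(Feature("hinge_rev", var, t, lo, hi))
        return cls(feats)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        cols = [f.transform(X[f.var].to_numpy(dtype=float)) for f in self.features]
        return np.column_stack(cols) if cols else np.zeros((len(X), 0))

    def subset(self, variables: list[str]) -> tuple["FeatureSet", np.ndarray]:
        keep = [i for i, f in enumerate(self.features) if f.var in set(variables)]
        return FeatureSet([self.features[i] for i in keep]), np.asarray(keep, dtype=int)

    def to_list(self) -> list[dict]:
        return [
            {"kind": f.kind, "var": f.var, "knot": f.knot, "lo": f.lo, "hi": f.hi}
            for f in self.features
        ]

    @classmethod
    def from_list(cls, items: list[dict]) -> "FeatureSet":
        return cls([Feature(**it) for it in items])


def make_features(
    background: pd.DataFrame, n_hinge_knots: int = 10, feature_types: str = "lqh"
) -> tuple[FeatureSet, np.ndarray]:
    """Build the feature set from a background table and return its matrix."""
    fs = FeatureSet.from_background(background, n_hinge_knots, feature_types)
    return fs, fs.transform(background)


# -- the model -------------------------------------------------------------


class MaxentSDM(BaseEstimator):
    """Presence-background maximum-entropy model (scikit-learn estimator).

    ``fit(X, y)`` takes a predictor table with binary ``y`` (1 = presence,
    0 = background).  Feature scaling bounds and hinge knots come from the
    background rows; regularization per feature is
    ``beta_multiplier * max(sd_presence, beta_floor) / sqrt(n_presence)``.

    Attributes (after fit)
    ----------------------
    feature_set_, lambda_, beta_ : features, weights, penalties.
    log_z_ : log of the mean Gibbs factor over the background (so that a
        weightless model scores 0 everywhere).
    loglik_path_ : penalized log-likelihood per accepted iteration
        (monotone non-decreasing).
    converged_, n_iter_, gain_converged_iter_ : solver accounting; the last
        is the first iteration at which the gain dropped below ``tol``.
    stationarity_gap_ : per-feature |presence mean - model mean| - beta
        (<= ~0 everywhere at the optimum).
    presence_means_ : raw variable means over presences (for response curves
        and counterfactual maps).
    suitability_c_ : constant of the [0,1] output transform.
    """

    def __init__(
        self,
        feature_types: str = "lqh",
        n_hinge_knots: int = 10,
        beta_multiplier: float = 1.0,
        beta_floor: float = 0.05,
        max_iter: int = 500,
        tol: float = 1e-5,
        stationarity_tol: float = 1e-8,
    ):
        self.feature_types = feature_types
        self.n_hinge_knots = n_hinge_knots
        self.beta_multiplier = beta_multiplier
        self.beta_floor = beta_floor
        self.max_iter = max_iter
        self.tol = tol
        self.stationarity_tol = stationarity_tol

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y).astype(int)
        pres = X[y == 1]
        bg = X[y == 0]
        m, n = len(pres), len(bg)
        if m < 5:
            raise ValueError("need at least 5 presence records")
        if n < 10:
            raise ValueError("background sample too small")
        self.variables_ = list(X.columns)
        fs = FeatureSet.from_background(bg, self.n_hinge_knots, self.feature_types)
        if len(fs) == 0:
            raise ValueError("empty feature set")
        Fp = fs.transform(pres)
        Fb = fs.transform(bg)
        pbar = Fp.mean(axis=0)
        s = Fp.std(axis=0, ddof=1) if m > 1 else np.zeros(len(fs))
        beta = self.beta_multiplier * np.maximum(s, self.beta_floor) / np.sqrt(m)
        d = len(fs)
        path: list[float] = []

        def objective(theta):
            lam = theta[:d] - theta[d:]
            eta = Fb @ lam
            ll = pbar @ lam - (logsumexp(eta) - np.log(n))
            pen = beta @ (theta[:d] + theta[d:])
            # gradient of the smooth part wrt lambda
            w = np.exp(eta - logsumexp(eta))
            g = pbar - w @ Fb
            grad = np.concatenate([-g + beta, g + beta])
            return -(ll) + pen, grad

        def callback(theta):
            lam = theta[:d] - theta[d:]
            eta = Fb @ lam
            ll = pbar @ lam - (logsumexp(eta) - np.log(n))
            path.append(float(ll - beta @ np.abs(lam)))

        theta0 = np.zeros(2 * d)
        callback(theta0)
        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * d),
            callback=callback,
            options={
                "maxiter": self.max_iter,
                "maxfun": 20 * self.max_iter,
                "ftol": 1e-14,
                "gtol": self.stationarity_tol,
                "maxcor": 100,
            },
        )
        lam = res.x[:d] - res.x[d:]
        self.feature_set_ = fs
        self.lambda_ = lam
        self.beta_ = beta
        self.n_presence_ = m
        self.n_background_ = n
        self.loglik_path_ = np.asarray(path)
        self.n_iter_ = int(res.nit)
        self.converged_ = bool(res.status == 0)
        gains = np.diff(self.loglik_path_)
        below = np.nonzero(gains < self.tol)[0]
        self.gain_converged_iter_ = int(below[0] + 1) if len(below) else self.n_iter_
        eta_b = Fb @ lam
        self.log_z_ = float(logsumexp(eta_b) - np.log(n))
        w = np.exp(eta_b - logsumexp(eta_b))
        self.model_feature_means_ = w @ Fb
        self.presence_feature_means_ = pbar
        self.stationarity_gap_ = np.abs(pbar - self.model_feature_means_) - beta
        self.presence_means_ = pres.mean(axis=0)
        # calibrate the [0,1] output transform: mean presence score = 0.5
        qp = np.exp(np.clip(Fp @ lam - self.log_z_, -500, 500))
        self.suitability_c_ = _calibrate_c(qp)
        return self

    # -- scoring ----------------------------------------------------------
    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Log relative density lambda.f - log Z (0 = background average)."""
        check_is_fitted(self, "lambda_")
        F = self.feature_set_.transform(X[self.variables_])
        return F @ self.lambda_ - self.log_z_

    def suitability(self, X: pd.DataFrame) -> np.ndarray:
        """Relative suitability in [0, 1] via the calibrated logistic transform."""
        q = np.exp(np.clip(self.decision_function(X), -500, 500))
        cq = self.suitability_c_ * q
        return cq / (1.0 + cq)

    def score(self, X: pd.DataFrame, y) -> float:
        """Presence-vs-background ROC-AUC of the raw scores."""
        return float(roc_auc_score(np.asarray(y).astype(int), self.decision_function(X)))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "lambda_")
        return {
            "params": self.get_params(),
            "variables": self.variables_,
            "features": self.feature_set_.to_list(),
            "lambda": self.lambda_.tolist(),
            "beta": self.beta_.tolist(),
            "log_z": self.log_z_,
            "suitability_c": self.suitability_c_,
            "presence_means": {k: float(v) for k, v in self.presence_means_.items()},
            "n_presence": self.n_presence_,
            "n_background": self.n_background_,
            "converged": self.converged_,
            "n_iter": self.n_iter_,
            "gain_converged_iter": self.gain_converged_iter_,
            "stationarity_gap_max": float(np.max(self.stationarity_gap_)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentSDM":
        model = cls(**d["params"])
        model.variables_ = list(d["variables"])
        model.feature_set_ = FeatureSet.from_list(d["features"])
        model.lambda_ = np.asarray(d["lambda"], dtype=float)
        model.beta_ = np.asarray(d["beta"], dtype=float)
        model.log_z_ = float(d["log_z"])
        model.suitability_c_ = float(d["suitability_c"])
        model.presence_means_ = pd.Series(d["presence_means"])
        model.n_presence_ = d["n_presence"]
        model.n_background_ = d["n_background"]
        model.converged_ = d["converged"]
        model.n_iter_ = d["n_iter"]
        model.gain_converged_iter_ = d["gain_converged_iter"]
        model.stationarity_gap_ = np.array([d["stationarity_gap_max"]])
        return model

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "MaxentSDM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _calibrate_c(q_presence: np.ndarray) -> float:
    """Solve mean(c q / (1 + c q)) = 0.5 over presences by bisection on log c."""
    q = np.clip(np.asarray(q_presence, dtype=float), 1e-300, None)

    def mean_score(logc):
        cq = np.exp(logc) * q
        return float(np.mean(cq / (1.0 + cq)))

    lo, hi = -60.0, 60.0
    if mean_score(lo) >= 0.5:
        return float(np.exp(lo))
    if mean_score(hi) <= 0.5:
        return float(np.exp(hi))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_score(mid) < 0.5:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))


def fit_maxent(
    presences: pd.DataFrame, background: pd.DataFrame, **params
) -> MaxentSDM:
    """Functional wrapper: fit on stacked presence + background tables."""
    X = pd.concat([presences, background], ignore_index=True)
    y = np.concatenate([np.ones(len(presences), int), np.zeros(len(background), int)])
    return MaxentSDM(**params).fit(X, y)


# -- evaluation ------------------------------------------------------------


def cv_auc(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    k: int = 5,
    random_state=0,
    **params,
) -> dict:
    """Presence-only k-fold cross-validated AUC (held-out presences vs background).

    Folds partition the presences; every fold model sees the full background.
    Returns mean and SD of the fold AUCs, the fold models, and the per-fold
    max(sens+spec) thresholds on the suitability scale.
    """
    if len(presences) < k:
        raise ValueError("fewer presences than folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=random_state)
    aucs, models, thresholds = [], [], []
    for train, test in kf.split(presences):
        model = fit_maxent(presences.iloc[train], background, **params)
        s_test = model.decision_function(presences.iloc[test])
        s_bg = model.decision_function(background)
        scores = np.concatenate([s_test, s_bg])
        labels = np.concatenate([np.ones(len(s_test), int), np.zeros(len(s_bg), int)])
        aucs.append(float(roc_auc_score(labels, scores)))
        thresholds.append(
            threshold_max_ss(
                model.suitability(presences.iloc[test]), model.suitability(background)
            )
        )
        models.append(model)
    aucs = np.asarray(aucs)
    return {
        "mean": float(aucs.mean()),
        "sd": float(aucs.std(ddof=1)),
        "fold_aucs": aucs.tolist(),
        "fold_models": models,
        "fold_thresholds": thresholds,
        "threshold": float(np.mean(thresholds)),
    }


def threshold_max_ss(presence_scores, background_scores) -> float:
    """Smallest threshold maximizing sensitivity + specificity.

    Candidates are the unique observed scores; a point counts as predicted
    present when its score >= threshold.
    """
    ps = np.asarray(presence_scores, dtype=float)
    bs = np.asarray(background_scores, dtype=float)
    if len(ps) == 0 or len(bs) == 0:
        raise ValueError("empty score vector")
    candidates = np.unique(np.concatenate([ps, bs]))
    sens = (ps[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (bs[None, :] < candidates[:, None]).mean(axis=1)
    total = sens + spec
    # smallest candidate within numerical tolerance of the maximum
    best = np.nonzero(total >= total.max() - 1e-12)[0][0]
    return float(candidates[int(best)])


def jackknife_select(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    variables: list[str] | None = None,
    k: int = 5,
    random_state=0,
    **params,
) -> tuple[list[str], pd.DataFrame]:
    """Leave-one-predictor-out stepwise elimination on mean CV-AUC.

    Repeatedly refits with each single predictor excluded; the exclusion with
    the best mean CV-AUC is adopted whenever it does not lower the current
    accuracy (an exact tie means the predictor contributes nothing and is
    discarded); stops when every exclusion hurts.  Fold partitions are shared
    across candidates, so comparisons are paired.  Returns the retained
    predictor names and the acceptance history (whose recorded AUC is
    monotone non-decreasing).
    """
    variables = list(variables) if variables is not None else list(presences.columns)
    current = list(variables)
    base = cv_auc(presences[current], background[current], k=k, random_state=random_state, **params)
    history = [{"dropped": None, "n_vars": len(current), "cv_auc": base["mean"]}]
    while len(current) > 1:
        best_var, best_auc = None, -np.inf
        for var in current:
            cand = [v for v in current if v != var]
            r = cv_auc(
                presences[cand], background[cand], k=k, random_state=random_state, **params
            )
            if r["mean"] > best_auc:
                best_var, best_auc = var, r["mean"]
        if best_auc < history[-1]["cv_auc"]:
            break
        current.remove(best_var)
        history.append({"dropped": best_var, "n_vars": len(current), "cv_auc": best_auc})
    return current, pd.DataFrame(history)


# -- prediction ------------------------------------------------------------


@dataclass
class HabitatMaps:
    """Continuous suitability plus its thresholded binary habitat map."""

    suitability: RasterGrid
    binary: RasterGrid | None
    threshold: float | None


def predict_suitability(
    model: MaxentSDM, pred_stack: RasterStack, threshold: float | None = None
) -> HabitatMaps:
    """Map the fitted model over a predictor stack.

    The binary map marks cells with suitability >= threshold (skipped when
    ``threshold`` is None); masked wherever any predictor is masked.
    """
    check_is_fitted(model, "lambda_")
    ref = pred_stack[model.variables_[0]]
    valid = np.ones(ref.shape, dtype=bool)
    for v in model.variables_:
        valid &= pred_stack[v].valid
    X = pd.DataFrame({v: pred_stack[v].values[valid] for v in model.variables_})
    suit = np.zeros(ref.shape)
    if len(X):
        suit[valid] = model.suitability(X)
    sgrid = ref.like(suit, mask=~valid)
    if threshold is None:
        return HabitatMaps(sgrid, None, None)
    binary = ref.like((suit >= threshold).astype(float) * valid, mask=~valid)
    return HabitatMaps(sgrid, binary, float(threshold))


def response_curve(
    models,
    variable: str,
    presences: pd.DataFrame,
    n_points: int = 100,
) -> pd.DataFrame:
    """Marginal response: sweep one variable, others held at presence means.

    Evaluates every replicate model over the variable's background range and
    returns the mean curve with a 95% normal band (mean +/- 1.96 SD across
    replicates; zero-width for a single replicate).
    """
    models = list(models)
    if variable not in models[0].variables_:
        raise KeyError(f"{variable!r} not a model variable")
    lo, hi = models[0].feature_set_.bounds(variable)
    grid = np.linspace(lo, hi, n_points)
    base = presences[models[0].variables_].mean(axis=0)
    X = pd.DataFrame({v: np.full(n_points, base[v]) for v in models[0].variables_})
    X[variable] = grid
    Y = np.column_stack([m.suitability(X[m.variables_]) for m in models])
    mean = Y.mean(axis=1)
    sd = Y.std(axis=1, ddof=1) if Y.shape[1] > 1 else np.zeros(n_points)
    return pd.DataFrame(
        {
            "value": grid,
            "mean": mean,
            "lo": np.clip(mean - 1.96 * sd, 0.0, 1.0),
            "hi": np.clip(mean + 1.96 * sd, 0.0, 1.0),
        }
    )


def curve_optimum(curve: pd.DataFrame) -> float:
    """Variable value at the maximum of the mean response curve."""
    return float(curve["value"].iloc[int(np.argmax(curve["mean"].to_numpy()))])


def permutation_importance(
    model: MaxentSDM,
    presences: pd.DataFrame,
    background: pd.DataFrame,
    random_state=0,
) -> pd.Series:
    """Per-variable AUC drop under value permutation, normalized to percent.

    The variable's raw values are permuted jointly over the evaluation sample
    (presences + background), features recomputed, and the presence-vs-
    background AUC drop recorded; drops are scaled to sum to 100.
    """
    rng = np.random.default_rng(random_state)
    X = pd.concat([presences, background], ignore_index=True)[model.variables_]
    y = np.concatenate([np.ones(len(presences), int), np.zeros(len(background), int)])
    base = roc_auc_score(y, model.decision_function(X))
    drops = {}
    for var in model.variables_:
        Xp = X.copy()
        Xp[var] = rng.permutation(Xp[var].to_numpy())
        drops[var] = max(0.0, base - roc_auc_score(y, model.decision_function(Xp)))
    s = pd.Series(drops)
    total = s.sum()
    return 100.0 * s / total if total > 0 else s
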