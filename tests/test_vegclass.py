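"""Vegetation model: collinearity screening, multinomial fitting against an
independent optimizer, stepwise AIC, and the Kappa-max / AUC metrics against
exhaustive oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

import oracle_utils as oracle
from encroach.synth import SceneConfig, VEG_CLASSES, build_scene
from encroach.vegclass import (
    MultinomialVegetationClassifier,
    auc,
    evaluate_vegclass,
    extract_predictors,
    kappa_max,
    predict_vegetation,
    screen_collinear,
    stepwise_backward_aic,
)


def _multinomial_sample(rng, n, coef, icpt):
    """Labels drawn from softmax(X @ coef.T + icpt); X standard normal."""
    X = rng.normal(size=(n, coef.shape[1]))
    eta = X @ coef.T + icpt
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    u = rng.uniform(size=n)
    y = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(coef.shape[1])]), y


# -- screening -------------------------------------------------------------


def test_screening_drops_one_of_a_duplicated_pair(rng):
    x = rng.normal(size=300)
    X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=300)})
    y = np.where(x + 0.5 * X["c"] > 0, "P", "A")
    kept = screen_collinear(X, y)
    assert "c" in kept
    assert ("a" in kept) != ("b" in kept)


def test_screening_is_invariant_to_monotone_transforms(rng):
    x = rng.normal(size=250)
    X = pd.DataFrame({"x": x, "expx": np.exp(x)})
    y = np.where(x > 0, "P", "A")
    kept = screen_collinear(X, y)
    assert len(kept) == 1


def test_screening_keeps_independent_noise(rng):
    X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
    y = rng.choice(["P", "A"], size=200)
    assert screen_collinear(X, y) == ["a", "b"]


def test_screening_flags_constant_predictor(rng):
    X = pd.DataFrame({"a": rng.normal(size=60), "b": np.ones(60)})
    y = np.where(X["a"] > 0, "P", "A")
    with pytest.warns(UserWarning, match="constant"):
        kept = screen_collinear(X, y)
    assert set(kept) == {"a", "b"}


# -- fitting ---------------------------------------------------------------


def test_two_class_fit_matches_independent_likelihood_maximizer(rng):
    x = rng.normal(size=400)
    p = 1 / (1 + np.exp(-(0.4 + 1.3 * x)))
    y = np.where(rng.uniform(size=400) < p, "B", "A")
    X = pd.DataFrame({"x": x})
    model = MultinomialVegetationClassifier(reference_class="A").fit(X, y)

    def negll(theta):
        eta = theta[0] + theta[1] * x
        return np.sum(np.log1p(np.exp(eta))) - eta[y == "B"].sum()

    res = minimize(negll, [0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 10000})
    b_idx = list(model.classes_).index("B")
    assert abs(model.intercept_[b_idx] - res.x[0]) < 1e-4
    assert abs(model.coef_[b_idx, 0] - res.x[1]) < 1e-4


def test_parameter_recovery_from_known_coefficients():
    """Estimates averaged over 5 simulation seeds recover the generative
    coefficients within 10% relative or 0.1 absolute."""
    coef = np.array([[1.2, -0.8, 0.0], [0.0, 0.9, -1.1], [0.0, 0.0, 0.0]])
    icpt = np.array([0.2, -0.3, 0.0])
    estimates = {"B": [], "C": []}
    for seed in range(5):
        rng = np.random.default_rng(seed)
        X, y = _multinomial_sample(rng, 2000, coef, icpt)
        labels = np.array(["B", "C", "REF"])[y]
        model = MultinomialVegetationClassifier(reference_class="REF").fit(X, labels)
        for i, c in enumerate(model.classes_):
            if c in estimates:
                estimates[c].append(model.coef_[i])
    for truth_row, cls in zip(coef[:2], ["B", "C"]):
        est = np.mean(estimates[cls], axis=0)
        err = np.abs(est - truth_row)
        tol = np.maximum(0.1, 0.1 * np.abs(truth_row))
        assert np.all(err <= tol)


def test_probabilities_sum_to_one_and_aic_identity(rng):
    X, y = _multinomial_sample(rng, 300, np.array([[1.0, 0.5], [0.0, 0.0]]), np.zeros(2))
    model = MultinomialVegetationClassifier().fit(X, y)
    P = model.predict_proba(X)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    assert np.isclose(model.aic_, 2 * model.n_parameters_ - 2 * model.log_likelihood_)
    assert model.n_parameters_ == (2 - 1) * (2 + 1)


def test_missing_required_class_is_named(rng):
    X = pd.DataFrame({"x": rng.normal(size=50)})
    y = np.repeat(["PASTURE", "ALNUS"], 25)
    with pytest.raises(ValueError, match="FOREST"):
        MultinomialVegetationClassifier(required_classes=VEG_CLASSES).fit(X, y)


# -- stepwise AIC ----------------------------------------------------------


def test_stepwise_removes_pure_noise_predictor():
    """A pure-noise predictor appended to a six-class generative model is
    dropped by backward AIC in nearly every run (it frees 5 parameters, and
    its likelihood contribution is chi-square with 5 df)."""
    coef = np.array(
        [
            [1.5, -1.0],
            [-1.0, 0.8],
            [0.6, 1.2],
            [-0.8, -1.1],
            [1.1, 0.9],
            [0.0, 0.0],
        ]
    )
    removed = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X, y = _multinomial_sample(rng, 600, coef, np.zeros(6))
        X["noise"] = rng.normal(size=600)
        full = MultinomialVegetationClassifier().fit(X, y)
        final = stepwise_backward_aic(full, X, y)
        assert final.aic_ <= full.aic_ + 1e-9
        if "noise" not in final.predictors_:
            removed += 1
    assert removed >= 18


def test_stepwise_keeps_generative_predictors_at_large_n():
    rng = np.random.default_rng(0)
    coef = np.array([[1.0, -0.8], [-0.6, 1.2], [0.0, 0.0]])
    X, y = _multinomial_sample(rng, 5000, coef, np.zeros(3))
    full = MultinomialVegetationClassifier().fit(X, y)
    final = stepwise_backward_aic(full, X, y)
    assert final.predictors_ == full.predictors_


# -- metrics ---------------------------------------------------------------


def test_kappa_perfect_and_null(rng):
    scores = np.r_[np.full(20, 0.9), np.full(20, 0.1)]
    labels = np.r_[np.ones(20), np.zeros(20)].astype(bool)
    k, t = kappa_max(scores, labels)
    assert np.isclose(k, 1.0)
    scores = rng.integers(0, 201, size=1000) * 0.005
    labels = rng.uniform(size=1000) < 0.5
    k, _ = kappa_max(scores, labels)
    assert abs(k) < 0.1
    with pytest.raises(ValueError):
        kappa_max(scores, np.ones(1000, bool))


@pytest.mark.parametrize("seed", range(20))
def test_kappa_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 30))
    scores = rng.integers(0, 201, size=n) * 0.005
    labels = np.zeros(n, bool)
    labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
    if labels.all():
        labels[0] = False
    k_got, t_got = kappa_max(scores, labels)
    thresholds = np.arange(0, 1.0 + 0.0025, 0.005)
    k_exp, t_exp = oracle.kappa_bruteforce(scores, labels, thresholds)
    assert np.isclose(k_got, k_exp)
    assert np.isclose(t_got, t_exp)


@pytest.mark.parametrize("seed", range(10))
def test_auc_matches_pairwise_count(seed):
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 10, size=12) / 10.0  # force ties
    labels = np.r_[np.ones(5), np.zeros(7)].astype(bool)
    assert np.isclose(auc(scores, labels), oracle.auc_bruteforce(scores, labels))


def test_auc_trivial_cases():
    labels = np.r_[np.ones(4), np.zeros(4)].astype(bool)
    assert auc(np.r_[np.ones(4), np.zeros(4)], labels) == 1.0
    assert auc(np.full(8, 0.3), labels) == 0.5


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=30)
    labels = np.zeros(30, bool)
    labels[:11] = True
    assert np.isclose(auc(scores, labels), auc(np.exp(scores), labels))


# -- evaluation and mapping -------------------------------------------------


@pytest.fixture(scope="module")
def noiseless_scene():
    return build_scene(
        SceneConfig(shape=(80, 80), seed=4, band_noise_sd=0.0, n_plots=300, n_presences=10)
    )


def test_noiseless_scene_is_perfectly_classified(noiseless_scene):
    scene = noiseless_scene
    X = extract_predictors(
        scene.stack,
        scene.plots["x"].to_numpy(),
        scene.plots["y"].to_numpy(),
        ["BAND1", "BAND2", "BAND3", "BAND4"],
    )
    y = scene.plots["veg_class"].to_numpy()
    ev = evaluate_vegclass(MultinomialVegetationClassifier(), X, y, k=3)
    assert (ev["fit"]["auc"] >= 1.0 - 1e-9).all()

    probs, hard = predict_vegetation(ev["model"], scene.stack, scene.irrelevant_mask)
    valid = hard.valid
    total = np.zeros(hard.shape)
    for name in probs.names:
        total += probs[name].values
    assert np.allclose(total[valid], 1.0, atol=1e-10)
    predicted = np.array([ev["model"].classes_[int(v)] for v in hard.values[valid]])
    truth = np.array([VEG_CLASSES[int(c)] for c in scene.class_map.values[valid]])
    assert (predicted == truth).mean() >= 0.99


def test_predict_vegetation_fully_masked_when_all_irrelevant(noiseless_scene):
    scene = noiseless_scene
    model = MultinomialVegetationClassifier(predictors=["BAND1", "BAND2"]).fit(
        extract_predictors(
            scene.stack,
            scene.plots["x"].to_numpy(),
            scene.plots["y"].to_numpy(),
            ["BAND1", "BAND2"],
        ),
        scene.plots["veg_class"].to_numpy(),
    )
    _, hard = predict_vegetation(model, scene.stack, np.ones(scene.class_map.shape, bool))
    assert hard.mask.all()


def test_fit_metrics_bound_cv_metrics_on_average(scene150):
    X = extract_predictors(
        scene150.stack,
        scene150.plots["x"].to_numpy(),
        scene150.plots["y"].to_numpy(),
        ["BAND1", "BAND2", "BAND3", "BAND4", "NDVI8"],
    )
    y = scene150.plots["veg_class"].to_numpy()
    ev = evaluate_vegclass(MultinomialVegetationClassifier(), X, y, k=3)
    assert ev["fit"]["auc"].mean() >= ev["cv_mean"]["auc"].mean() - 1e-6
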