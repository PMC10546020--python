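import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from cottonphys.exceptions import ConfigError, DegenerateInputError
from cottonphys.glm import (
    FittedModel,
    ModelScore,
    ModelSpec,
    SplitPlan,
    cross_validate,
    fit_glm,
    fit_null_model,
    generalized_r2_cox_snell,
    mechanistic_rue,
    predict_response,
    rank_models,
    remove_outliers,
    score_train,
    stratified_split,
    wald_intervals,
)


# --- independent likelihood oracles (hand-written, no package code) ---------

def beta_loglik(y, X, beta, phi):
    mu = special.expit(X @ beta)
    return float(
        np.sum(
            special.gammaln(phi)
            - special.gammaln(mu * phi)
            - special.gammaln((1 - mu) * phi)
            + (mu * phi - 1) * np.log(y)
            + ((1 - mu) * phi - 1) * np.log1p(-y)
        )
    )


def gamma_loglik(y, X, beta, alpha):
    mu = np.exp(X @ beta)
    return float(
        np.sum(
            alpha * np.log(alpha) - special.gammaln(alpha)
            + (alpha - 1) * np.log(y) - alpha * np.log(mu) - alpha * y / mu
        )
    )


def _training_frame(seed=11, n=120):
    rng = np.random.default_rng(seed)
    vi = rng.uniform(0.2, 0.9, n)
    gdd = rng.uniform(300.0, 1900.0, n)
    X = np.column_stack([np.ones(n), vi, gdd, vi * gdd])
    beta_i = np.array([-3.0, 2.5, 0.002, 0.0005])
    mu_i = special.expit(X @ beta_i)
    ipar = rng.beta(mu_i * 60.0, (1 - mu_i) * 60.0)
    beta_b = np.array([0.8, 2.4, 0.0011, 0.0009])
    mu_b = np.exp(X @ beta_b)
    biomass = rng.gamma(25.0, mu_b / 25.0)
    rue = 1.5 + 2.0 * vi + rng.normal(0, 0.2, n)
    return pd.DataFrame(
        {"VI": vi, "gdd": gdd, "ipar_f": ipar, "biomass": biomass, "rue": rue,
         "date": np.tile(np.arange(5), n // 5)}
    ), X


def _is_local_max(loglik_fn, theta_hat, scales, seed=0, n_trials=200):
    """The fitted parameters beat random nearby alternatives on the likelihood."""
    best = loglik_fn(theta_hat)
    rng = np.random.default_rng(seed)
    for _ in range(n_trials):
        delta = rng.normal(0, 1, theta_hat.size) * scales
        assert loglik_fn(theta_hat + delta) <= best + 1e-6
    return True


# --- ModelSpec validation ---------------------------------------------------

def test_modelspec_defaults_by_response():
    spec = ModelSpec(response="ipar_f", predictor="NDVI")
    assert (spec.family, spec.link) == ("beta", "logit")
    assert spec.terms == ("intercept", "vi", "gdd", "vi_gdd")
    spec = ModelSpec(response="biomass", predictor="NDVI")
    assert (spec.family, spec.link) == ("gamma", "log")
    spec = ModelSpec(response="rue", predictor="NDVI")
    assert (spec.family, spec.link) == ("gaussian", "identity")
    assert spec.terms == ("intercept", "vi")


def test_modelspec_rejects_mismatches():
    with pytest.raises(ConfigError):
        ModelSpec(response="ipar_f", predictor="NDVI", family="gamma")
    with pytest.raises(ConfigError):
        ModelSpec(response="biomass", predictor="NDVI", link="identity")
    with pytest.raises(ConfigError):
        ModelSpec(response="rue", predictor="NDVI", terms=("intercept", "vi", "gdd"))
    with pytest.raises(ConfigError):
        ModelSpec(response="lint", predictor="NDVI")


# --- outliers and split -----------------------------------------------------

def test_remove_outliers_oracle():
    values = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 100.0])
    keep, removed = remove_outliers(values)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
    np.testing.assert_array_equal(keep, (values >= lo) & (values <= hi))
    assert removed.tolist() == [8]


def test_remove_outliers_keeps_clean_data():
    keep, removed = remove_outliers([1.0, 2.0, 3.0, 4.0])
    assert keep.all() and removed.size == 0


def test_remove_outliers_needs_four_records():
    with pytest.raises(DegenerateInputError):
        remove_outliers([1.0, 2.0, 3.0])


def test_stratified_split_counts_and_determinism():
    df, _ = _training_frame()
    plan = SplitPlan(train_fraction=0.6, seed=4)
    train, valid = stratified_split(df, plan)
    assert len(train) + len(valid) == len(df)
    assert set(train.index).isdisjoint(valid.index)
    for date, grp in df.groupby("date"):
        expected = round(0.6 * len(grp))
        assert (train["date"] == date).sum() == expected
    train2, valid2 = stratified_split(df, plan)
    pd.testing.assert_frame_equal(train, train2)
    pd.testing.assert_frame_equal(valid, valid2)


def test_stratified_split_singleton_goes_to_train():
    df = pd.DataFrame({"date": [1, 1, 1, 2], "y": [1.0, 2.0, 3.0, 4.0]})
    train, valid = stratified_split(df, SplitPlan(seed=0))
    assert 3 in train.index  # the lone date-2 record trains


def test_stratified_split_requires_column():
    with pytest.raises(ConfigError):
        stratified_split(pd.DataFrame({"y": [1.0]}), SplitPlan())


# --- fitting ----------------------------------------------------------------

def test_gaussian_fit_equals_ols():
    df, _ = _training_frame()
    model = fit_glm(ModelSpec(response="rue", predictor="VI"), df)
    X = np.column_stack([np.ones(len(df)), df["VI"]])
    y = df["rue"].to_numpy()
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(model.coefficients, beta_ols, atol=1e-8)
    resid = y - X @ beta_ols
    assert model.dispersion == pytest.approx(resid @ resid / len(df), rel=1e-10)


def test_beta_fit_is_maximum_likelihood():
    df, X = _training_frame()
    model = fit_glm(ModelSpec(response="ipar_f", predictor="VI"), df)
    assert model.converged
    y = df["ipar_f"].to_numpy()
    # reported log-likelihood matches the hand-written density
    hand = beta_loglik(y, X, model.coefficients, model.dispersion)
    assert model.loglik == pytest.approx(hand, abs=1e-6)
    # the estimate beats nearby alternatives on the hand-written likelihood
    se = np.sqrt(np.diag(model.cov_beta))
    theta = np.append(model.coefficients, model.dispersion)
    scales = np.append(0.3 * se, 0.05 * model.dispersion)

    def ll(t):
        return beta_loglik(y, X, t[:4], t[4]) if t[4] > 0 else -np.inf

    assert _is_local_max(ll, theta, scales, seed=1)


def test_gamma_fit_is_maximum_likelihood():
    df, X = _training_frame()
    model = fit_glm(ModelSpec(response="biomass", predictor="VI"), df)
    assert model.converged
    y = df["biomass"].to_numpy()
    hand = gamma_loglik(y, X, model.coefficients, model.dispersion)
    assert model.loglik == pytest.approx(hand, abs=1e-6)
    # score equations: mean part X'(y/mu - 1) = 0, shape part at the profile root
    mu = np.exp(X @ model.coefficients)
    np.testing.assert_allclose(X.T @ (y / mu - 1.0), 0.0, atol=1e-4)
    a = model.dispersion
    n = len(y)
    shape_score = n * (math.log(a) + 1) - n * special.digamma(a) + float(
        np.sum(np.log(y / mu) - y / mu)
    )
    assert shape_score == pytest.approx(0.0, abs=1e-6)
    se = np.sqrt(np.diag(model.cov_beta))
    theta = np.append(model.coefficients, a)
    scales = np.append(0.3 * se, 0.05 * a)

    def ll(t):
        return gamma_loglik(y, X, t[:4], t[4]) if t[4] > 0 else -np.inf

    assert _is_local_max(ll, theta, scales, seed=2)


def test_fit_rejects_out_of_support_response():
    df, _ = _training_frame()
    bad = df.copy()
    bad.loc[3, "ipar_f"] = 1.0
    with pytest.raises(DegenerateInputError, match=r"\(0, 1\)"):
        fit_glm(ModelSpec(response="ipar_f", predictor="VI"), bad)
    bad = df.copy()
    bad.loc[5, "biomass"] = -2.0
    with pytest.raises(DegenerateInputError, match="positive"):
        fit_glm(ModelSpec(response="biomass", predictor="VI"), bad)


def test_fit_drops_nan_predictor_rows():
    df, _ = _training_frame()
    df.loc[df.index[:7], "VI"] = np.nan
    model = fit_glm(ModelSpec(response="rue", predictor="VI"), df)
    assert model.n_train == len(df) - 7


def test_fit_needs_enough_records():
    df, _ = _training_frame()
    with pytest.raises(DegenerateInputError, match="need more than"):
        fit_glm(ModelSpec(response="ipar_f", predictor="VI"), df.head(5))


def test_null_model_all_families():
    df, _ = _training_frame()
    for response in ("ipar_f", "biomass", "rue"):
        spec = ModelSpec(response=response, predictor="VI")
        null = fit_null_model(spec, df)
        assert len(null.coefficients) == 1
        assert null.n_train == len(df)


# --- scoring ----------------------------------------------------------------

def test_generalized_r2_zero_for_null_model():
    df, _ = _training_frame()
    for response in ("ipar_f", "biomass", "rue"):
        spec = ModelSpec(response=response, predictor="VI")
        null = fit_null_model(spec, df)
        r2, _, _ = score_train(null, null)
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert generalized_r2_cox_snell(null, null) == pytest.approx(0.0, abs=1e-12)


def test_gaussian_aicc_bic_closed_form():
    df, _ = _training_frame()
    spec = ModelSpec(response="rue", predictor="VI")
    model = fit_glm(spec, df)
    null = fit_null_model(spec, df)
    _, aicc, bic = score_train(model, null)
    n = len(df)
    X = np.column_stack([np.ones(n), df["VI"]])
    y = df["rue"].to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    sigma2 = float(np.sum((y - X @ beta) ** 2)) / n
    ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = 3  # two mean coefficients + the variance
    assert aicc == pytest.approx(-2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1), abs=1e-9)
    assert bic == pytest.approx(-2 * ll + k * math.log(n), abs=1e-9)


def test_score_train_counts_dispersion_in_k():
    df, _ = _training_frame()
    spec = ModelSpec(response="rue", predictor="VI")
    model = fit_glm(spec, df)
    _, aicc_full, _ = score_train(model, fit_null_model(spec, df))
    # recompute with k = coefficients only: must differ
    n, ll = model.n_train, model.loglik
    k_wrong = len(model.coefficients)
    aicc_wrong = -2 * ll + 2 * k_wrong + 2 * k_wrong * (k_wrong + 1) / (n - k_wrong - 1)
    assert aicc_full != pytest.approx(aicc_wrong)


def test_cross_validate_perfect_predictions():
    df, _ = _training_frame()
    spec = ModelSpec(response="rue", predictor="VI")
    model = fit_glm(spec, df)
    valid = df.copy()
    valid["rue"] = predict_response(model, valid)
    r2_cv, rmse_cv = cross_validate(model, valid)
    assert r2_cv == pytest.approx(1.0, abs=1e-12)
    assert rmse_cv == pytest.approx(0.0, abs=1e-12)


def test_cross_validate_empty_validation():
    df, _ = _training_frame()
    model = fit_glm(ModelSpec(response="rue", predictor="VI"), df)
    with pytest.raises(DegenerateInputError):
        cross_validate(model, df.head(0))


def test_predict_refuses_unconverged():
    df, _ = _training_frame()
    model = fit_glm(ModelSpec(response="rue", predictor="VI"), df)
    model.converged = False
    with pytest.raises(DegenerateInputError, match="converge"):
        predict_response(model, df)


# --- ranking ----------------------------------------------------------------

def _score(name, rmse, r2=0.5, aicc=10.0):
    return ModelScore(
        predictor=name, r2_train=0.5, aicc=aicc, bic=0.0, r2_cv=r2, rmse_cv=rmse
    )


def test_rank_models_ordering_keys():
    scores = [
        _score("c", rmse=2.0),
        _score("a", rmse=1.0, r2=0.9),
        _score("b", rmse=1.0, r2=0.9, aicc=5.0),  # AICc breaks the final tie
        _score("d", rmse=1.0, r2=0.5),
    ]
    ranked = rank_models(scores)
    assert [s.predictor for s in ranked] == ["b", "a", "d", "c"]


def test_rank_models_permutation_invariant():
    rng = np.random.default_rng(7)
    scores = [_score(f"p{i}", rmse=float(r)) for i, r in enumerate(rng.uniform(0, 1, 12))]
    ranked = rank_models(scores)
    for _ in range(5):
        perm = list(scores)
        rng.shuffle(perm)
        assert rank_models(perm) == ranked


def test_rank_models_empty():
    with pytest.raises(DegenerateInputError):
        rank_models([])


def test_rank_models_nan_r2cv_sorts_last_within_ties():
    scores = [_score("nanny", rmse=1.0, r2=float("nan")), _score("ok", rmse=1.0, r2=0.1)]
    assert [s.predictor for s in rank_models(scores)] == ["ok", "nanny"]


# --- Wald intervals ---------------------------------------------------------

def test_wald_intervals_shape_and_width():
    df, _ = _training_frame()
    model = fit_glm(ModelSpec(response="rue", predictor="VI"), df)
    ci = wald_intervals(model, level=0.95)
    assert ci.shape == (2, 2)
    se = np.sqrt(np.diag(model.cov_beta))
    z = stats.norm.ppf(0.975)
    np.testing.assert_allclose(ci[:, 1] - ci[:, 0], 2 * z * se, rtol=1e-10)
    assert np.all(ci[:, 0] < model.coefficients) and np.all(model.coefficients < ci[:, 1])


# --- mechanistic RUE --------------------------------------------------------

def _exact_ipar_model():
    spec = ModelSpec(response="ipar_f", predictor="VI")
    beta = np.array([-2.0, 3.0, 0.001, 0.0002])
    return FittedModel(
        spec=spec, coefficients=beta, dispersion=60.0, loglik=0.0,
        n_train=10, converged=True, cov_beta=np.eye(4),
    )


def test_mechanistic_rue_measured_biomass_reduces_to_rue_series():
    model = _exact_ipar_model()
    records = pd.DataFrame(
        {
            "plot_id": ["p1"] * 3,
            "date": [1, 2, 3],
            "VI": [0.4, 0.6, 0.8],
            "gdd": [400.0, 900.0, 1400.0],
            "cum_par": [200.0, 500.0, 900.0],
            "biomass": [50.0, 200.0, 420.0],
        }
    )
    out = mechanistic_rue(None, model, records, use_measured_biomass=True)
    pred = predict_response(model, records)
    cum_ipar = pred * records["cum_par"].to_numpy()
    bio = records["biomass"].to_numpy()
    expected = [(bio[i] - bio[0]) / (cum_ipar[i] - cum_ipar[0]) for i in (1, 2)]
    np.testing.assert_allclose(out["rue"].to_numpy(), expected, rtol=1e-12)


def test_mechanistic_rue_single_date_errors():
    model = _exact_ipar_model()
    records = pd.DataFrame(
        {"plot_id": ["p1"], "date": [1], "VI": [0.5], "gdd": [500.0],
         "cum_par": [300.0], "biomass": [100.0]}
    )
    with pytest.raises(DegenerateInputError, match="two dates"):
        mechanistic_rue(None, model, records, use_measured_biomass=True)


def test_mechanistic_rue_requires_biomass_source():
    model = _exact_ipar_model()
    records = pd.DataFrame(
        {"plot_id": ["p1"] * 2, "date": [1, 2], "VI": [0.4, 0.6],
         "gdd": [400.0, 900.0], "cum_par": [200.0, 500.0]}
    )
    with pytest.raises(ConfigError):
        mechanistic_rue(None, model, records)
    with pytest.raises(ConfigError, match="biomass"):
        mechanistic_rue(None, model, records, use_measured_biomass=True)
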