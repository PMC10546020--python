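"""Generalized linear models for IPAR_f, biomass and RUE, with ranking.

Three response-specific families are used:

* IPAR_f — a fraction in (0, 1): beta distribution with a logit mean link.
* above-ground biomass — positive and right-skewed: gamma with a log link.
* RUE — approximately linear in the period-averaged index with constant
  variance (and possibly negative): gaussian with identity link, which is
  ordinary least squares.

The default linear predictor for IPAR_f and biomass is
η = β₀ + β₁·VI + β₂·GDD + β₃·VI·GDD (the VI–response relationship shifts
slope and intercept with thermal time, hence the interaction; a
main-effects-only form is available). RUE models use intercept + the
average VI over the RUE calculation period.

Candidate predictors are compared on training data by a likelihood-ratio
generalized R² (Nagelkerke form), small-sample AICc, and BIC — with the
parameter count k including the dispersion parameter — and on held-out
validation data by R²cv (squared Pearson correlation of predicted vs
measured) and RMSEcv in response units. Ranking is by ascending RMSEcv,
ties broken by descending R²cv then ascending AICc.

The beta fit is full maximum likelihood (statsmodels ``BetaModel``). The
gamma fit maximizes the likelihood in two exact stages: the mean
coefficients by IRLS (their ML estimate does not depend on the shape) and
then the shape parameter by solving its profile score equation. The
gaussian fit is OLS with the ML variance RSS/n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.othermod.betareg import BetaModel

from cottonphys.exceptions import ConfigError, DegenerateInputError

logger = logging.getLogger(__name__)

FAMILY_BY_RESPONSE = {"ipar_f": "beta", "biomass": "gamma", "rue": "gaussian"}
LINK_BY_FAMILY = {"beta": "logit", "gamma": "log", "gaussian": "identity"}

TERMS_FULL = ("intercept", "vi", "gdd", "vi_gdd")
TERMS_MAIN = ("intercept", "vi", "gdd")
TERMS_VI_ONLY = ("intercept", "vi")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, family/link, predictor index, and terms."""

    response: str
    predictor: str
    family: str = ""
    link: str = ""
    terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.response not in FAMILY_BY_RESPONSE:
            raise ConfigError(f"unknown response {self.response!r}")
        family = self.family or FAMILY_BY_RESPONSE[self.response]
        if family != FAMILY_BY_RESPONSE[self.response]:
            raise ConfigError(
                f"response {self.response!r} requires family "
                f"{FAMILY_BY_RESPONSE[self.response]!r}, got {family!r}"
            )
        link = self.link or LINK_BY_FAMILY[family]
        if link != LINK_BY_FAMILY[family]:
            raise ConfigError(f"family {family!r} requires link {LINK_BY_FAMILY[family]!r}")
        terms = self.terms or (TERMS_VI_ONLY if self.response == "rue" else TERMS_FULL)
        if self.response == "rue" and terms not in (TERMS_VI_ONLY, ("intercept",)):
            raise ConfigError("rue models use terms (intercept, vi) only")
        unknown = set(terms) - set(TERMS_FULL)
        if unknown:
            raise ConfigError(f"unknown terms: {sorted(unknown)}")
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "link", link)
        object.__setattr__(self, "terms", tuple(terms))


@dataclass
class FittedModel:
    """Maximum-likelihood fit of a :class:`ModelSpec`."""

    spec: ModelSpec
    coefficients: np.ndarray  # one per term, in spec.terms order
    dispersion: float  # beta precision φ, gamma shape α, or gaussian σ² (ML)
    loglik: float
    n_train: int
    converged: bool
    cov_beta: np.ndarray = field(repr=False, default=None)  # ML covariance of β̂


@dataclass(frozen=True)
class ModelScore:
    """Train and validation scores for one candidate predictor."""

    predictor: str
    r2_train: float
    aicc: float
    bic: float
    r2_cv: float
    rmse_cv: float


@dataclass(frozen=True)
class SplitPlan:
    """Stratified train/validation split settings."""

    train_fraction: float = 0.6
    stratify_by: str = "date"
    seed: int = 0


def remove_outliers(
    values: Sequence[float] | pd.Series, factor: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Interquartile-range outlier rule on a response variable.

    Returns (keep_mask, removed_indices). A value is removed when it lies
    outside [Q1 − factor·IQR, Q3 + factor·IQR], quartiles by linear
    interpolation (type 7). Applied once on the pooled pre-split data.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise DegenerateInputError("outlier rule needs at least 4 records")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    keep = (arr >= lo) & (arr <= hi)
    removed = np.flatnonzero(~keep)
    if removed.size:
        logger.info("IQR rule removed %d of %d records", removed.size, arr.size)
    return keep, removed


def stratified_split(
    records: pd.DataFrame, plan: SplitPlan
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random train/validation partition stratified by sampling date.

    Within each stratum the train count is round(train_fraction × size);
    size-1 strata go to train (logged). Deterministic given the seed.
    """
    if plan.stratify_by not in records.columns:
        raise ConfigError(f"records lack stratification column {plan.stratify_by!r}")
    rng = np.random.default_rng(plan.seed)
    train_idx: list = []
    valid_idx: list = []
    for key in sorted(records[plan.stratify_by].unique()):
        idx = records.index[records[plan.stratify_by] == key].to_numpy()
        if idx.size == 1:
            logger.info("stratum %s has a single record; assigned to train", key)
            train_idx.extend(idx)
            continue
        n_train = round(plan.train_fraction * idx.size)
        perm = rng.permutation(idx.size)
        train_idx.extend(idx[perm[:n_train]])
        valid_idx.extend(idx[perm[n_train:]])
    return records.loc[train_idx], records.loc[valid_idx]


def design_matrix(spec: ModelSpec, records: pd.DataFrame) -> np.ndarray:
    """Build the design matrix for ``spec`` from predictor/GDD columns."""
    if spec.predictor not in records.columns:
        raise ConfigError(f"records lack predictor column {spec.predictor!r}")
    vi = records[spec.predictor].to_numpy(dtype=float)
    cols = []
    for term in spec.terms:
        if term == "intercept":
            cols.append(np.ones(len(records)))
        elif term == "vi":
            cols.append(vi)
        elif term == "gdd":
            if "gdd" not in records.columns:
                raise ConfigError("records lack column 'gdd'")
            cols.append(records["gdd"].to_numpy(dtype=float))
        elif term == "vi_gdd":
            if "gdd" not in records.columns:
                raise ConfigError("records lack column 'gdd'")
            cols.append(vi * records["gdd"].to_numpy(dtype=float))
    return np.column_stack(cols)


def _validate_response(spec: ModelSpec, y: np.ndarray) -> None:
    if spec.family == "beta":
        bad = np.flatnonzero((y <= 0) | (y >= 1))
        if bad.size:
            raise DegenerateInputError(
                f"beta response must lie in (0, 1); bad rows: {bad.tolist()}"
            )
    elif spec.family == "gamma":
        bad = np.flatnonzero(y <= 0)
        if bad.size:
            raise DegenerateInputError(
                f"gamma response must be positive; bad rows: {bad.tolist()}"
            )


def _drop_incomplete(spec: ModelSpec, records: pd.DataFrame) -> pd.DataFrame:
    cols = [spec.response, spec.predictor]
    if "gdd" in spec.terms or "vi_gdd" in spec.terms:
        cols.append("gdd")
    complete = records.dropna(subset=cols)
    n_dropped = len(records) - len(complete)
    if n_dropped:
        logger.info(
            "%s/%s: dropped %d rows with undefined values",
            spec.response, spec.predictor, n_dropped,
        )
    return complete


def _standardize_design(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale non-constant columns; return (Z, A) with β = A·γ.

    Z has the same column span as X, so the fit is unchanged; A maps the
    standardized-scale coefficients back to the raw scale.
    """
    n, k = X.shape
    Z = X.copy().astype(float)
    means = np.zeros(k)
    scales = np.ones(k)
    for j in range(k):
        col = X[:, j]
        if np.ptp(col) == 0:  # intercept or constant column
            continue
        means[j] = col.mean()
        sd = col.std()
        scales[j] = sd if sd > 0 else 1.0
        Z[:, j] = (col - means[j]) / scales[j]
    A = np.zeros((k, k))
    const_idx = [j for j in range(k) if np.ptp(X[:, j]) == 0]
    anchor = const_idx[0] if const_idx else None
    for j in range(k):
        if j == anchor:
            A[j, j] = 1.0
            for m in range(k):
                if m != anchor:
                    A[j, m] = -means[m] / scales[m]
        else:
            A[j, j] = 1.0 / scales[j]
    return Z, A


def _gamma_profile_shape(y: np.ndarray, mu: np.ndarray) -> float:
    """ML shape α given fitted means, via the profile score equation."""
    n = y.size
    c = float(np.sum(np.log(y / mu) - y / mu))

    def score(a: float) -> float:
        return n * (math.log(a) + 1.0) - n * special.digamma(a) + c

    # score is decreasing in a; bracket geometrically.
    lo, hi = 1e-8, 1.0
    while score(hi) > 0 and hi < 1e12:
        hi *= 10.0
    return float(optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-14))


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    return float(
        np.sum(
            alpha * np.log(alpha * y / mu)
            - alpha * y / mu
            - np.log(y)
            - special.gammaln(alpha)
        )
    )


def fit_glm(spec: ModelSpec, records: pd.DataFrame) -> FittedModel:
    """Maximum-likelihood fit of ``spec`` on training records.

    ``records`` must have a column named after the response, the predictor,
    and (for full-term models) ``gdd``. Rows with undefined (NaN) predictor
    values are dropped with a logged count; invalid response values raise a
    :class:`DegenerateInputError` listing the row indices.
    """
    records = _drop_incomplete(spec, records)
    y = records[spec.response].to_numpy(dtype=float)
    X = design_matrix(spec, records)
    n, k_beta = X.shape
    if n <= k_beta + 1:
        raise DegenerateInputError(
            f"need more than {k_beta + 1} records to fit {k_beta} terms, got {n}"
        )
    _validate_response(spec, y)

    if spec.family == "beta":
        # Standardize non-intercept columns for the optimizer; the logit
        # model is equivariant under this affine reparameterization, so the
        # coefficients and covariance are transformed back exactly.
        Z, transform = _standardize_design(X)
        model = BetaModel(y, Z)
        res = model.fit(disp=False, maxiter=500)
        converged = bool(res.mle_retvals.get("converged", True))
        gamma = np.asarray(res.params[:k_beta], dtype=float)
        phi = float(np.exp(res.params[k_beta]))  # precision is log-linked
        cov_gamma = np.asarray(res.cov_params())[:k_beta, :k_beta]
        beta = transform @ gamma
        cov = transform @ cov_gamma @ transform.T
        return FittedModel(spec, beta, phi, float(res.llf), n, converged, cov)

    if spec.family == "gamma":
        model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
        res = model.fit()
        converged = bool(res.converged)
        beta = np.asarray(res.params, dtype=float)
        mu = np.exp(X @ beta)
        alpha = _gamma_profile_shape(y, mu)
        llf = _gamma_loglik(y, mu, alpha)
        # IRLS covariance is scaled by the Pearson dispersion; rescale to
        # the ML dispersion 1/alpha.
        cov = np.asarray(res.cov_params()) * ((1.0 / alpha) / res.scale)
        return FittedModel(spec, beta, alpha, llf, n, converged, cov)

    # gaussian / identity == OLS with ML variance RSS/n
    res = sm.OLS(y, X).fit()
    beta = np.asarray(res.params, dtype=float)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    llf = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    cov = np.asarray(res.cov_params())
    return FittedModel(spec, beta, sigma2, llf, n, True, cov)


def fit_null_model(spec: ModelSpec, records: pd.DataFrame) -> FittedModel:
    """Intercept-only fit of the same family, for generalized R²."""
    null_spec = replace(spec, terms=("intercept",))
    return fit_glm(null_spec, records)


def predict_response(model: FittedModel, records: pd.DataFrame) -> np.ndarray:
    """Inverse-link predictions in response units."""
    if not model.converged:
        raise DegenerateInputError("model did not converge; refusing to predict")
    X = design_matrix(model.spec, records)
    eta = X @ model.coefficients
    if model.spec.link == "logit":
        return special.expit(eta)
    if model.spec.link == "log":
        return np.exp(eta)
    return eta


def score_train(
    model: FittedModel, null_model: FittedModel
) -> tuple[float, float, float]:
    """(generalized R², AICc, BIC) on the training data.

    Generalized R² is the Nagelkerke form
    [1 − exp(−(2/n)(ℓ₁ − ℓ₀))] / [1 − exp((2/n)ℓ₀)]; the parameter count k
    includes the dispersion parameter.
    """
    if model.n_train != null_model.n_train:
        raise DegenerateInputError("model and null model fit on different n")
    n = model.n_train
    ll1, ll0 = model.loglik, null_model.loglik
    k = len(model.coefficients) + 1
    if n <= k + 1:
        raise DegenerateInputError(f"AICc undefined for n={n}, k={k}")
    cox_snell = 1.0 - math.exp(-(2.0 / n) * (ll1 - ll0))
    denom = 1.0 - math.exp((2.0 / n) * ll0)
    # The Nagelkerke ceiling 1 − exp((2/n)ℓ₀) is only a valid maximum when
    # the null likelihood is below 1 (ℓ₀ < 0), as for discrete responses.
    # For continuous densities ℓ₀ can be positive, making the "ceiling"
    # negative; the likelihood-ratio R² is then used uncorrected.
    r2 = cox_snell / denom if 0.0 < denom <= 1.0 else cox_snell
    aicc = -2.0 * ll1 + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    bic = -2.0 * ll1 + k * math.log(n)
    return r2, aicc, bic


def generalized_r2_cox_snell(model: FittedModel, null_model: FittedModel) -> float:
    """Cox–Snell R² (sensitivity alternative to the Nagelkerke default)."""
    n = model.n_train
    return 1.0 - math.exp(-(2.0 / n) * (model.loglik - null_model.loglik))


def cross_validate(
    model: FittedModel, validation: pd.DataFrame
) -> tuple[float, float]:
    """(R²cv, RMSEcv) on held-out records.

    R²cv is the squared Pearson correlation between predicted and measured;
    RMSEcv is in response units. Zero variance in either side yields an
    undefined (NaN) R²cv.
    """
    validation = _drop_incomplete(model.spec, validation)
    if len(validation) == 0:
        raise DegenerateInputError("empty validation set")
    pred = predict_response(model, validation)
    meas = validation[model.spec.response].to_numpy(dtype=float)
    rmse = float(np.sqrt(np.mean((pred - meas) ** 2)))
    if np.std(meas) == 0 or np.std(pred) == 0:
        return float("nan"), rmse
    r = float(np.corrcoef(pred, meas)[0, 1])
    return r * r, rmse


def rank_models(scores: Iterable[ModelScore]) -> list[ModelScore]:
    """Order candidates: ascending RMSEcv, then descending R²cv, then AICc."""
    def key(s: ModelScore):
        r2 = s.r2_cv if math.isfinite(s.r2_cv) else -math.inf
        return (s.rmse_cv, -r2, s.aicc)

    ranked = sorted(scores, key=key)
    if not ranked:
        raise DegenerateInputError("no converged models to rank")
    return ranked


def wald_intervals(model: FittedModel, level: float = 0.95) -> np.ndarray:
    """Wald confidence intervals for the mean coefficients, (k, 2)."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(np.diag(model.cov_beta))
    beta = model.coefficients
    return np.column_stack([beta - z * se, beta + z * se])


def mechanistic_rue(
    biomass_model: FittedModel | None,
    ipar_model: FittedModel,
    records: pd.DataFrame,
    use_measured_biomass: bool = False,
) -> pd.DataFrame:
    """Derive RUE mechanistically from model outputs.

    For each plot's date series, predicted cumulative IPAR is
    (predicted IPAR_f) × (cumulative incident PAR); biomass is either
    model-predicted or, with ``use_measured_biomass``, the measured column.
    RUE is then the first-date-referenced difference quotient.

    ``records`` needs columns plot_id, date, cum_par, the predictors, and
    (for measured mode) biomass. Returns plot_id, date, rue rows for every
    non-reference date.
    """
    required = {"plot_id", "date", "cum_par"}
    missing = required - set(records.columns)
    if missing:
        raise ConfigError(f"records missing columns: {sorted(missing)}")
    if use_measured_biomass:
        if "biomass" not in records.columns:
            raise ConfigError("measured-biomass mode needs a 'biomass' column")
    elif biomass_model is None:
        raise ConfigError("biomass model required unless use_measured_biomass")

    records = records.copy()
    records["_ipar_pred"] = predict_response(ipar_model, records)
    if use_measured_biomass:
        records["_bio"] = records["biomass"].to_numpy(dtype=float)
    else:
        records["_bio"] = predict_response(biomass_model, records)
    records["_cum_ipar"] = records["_ipar_pred"] * records["cum_par"]

    rows = []
    for plot_id, grp in records.groupby("plot_id", sort=True):
        grp = grp.sort_values("date")
        if len(grp) < 2:
            raise DegenerateInputError(
                f"plot {plot_id}: RUE needs at least two dates"
            )
        rues = rue_series_arrays(
            grp["_bio"].to_numpy(), grp["_cum_ipar"].to_numpy()
        )
        for date, rue in zip(grp["date"].iloc[1:], rues):
            rows.append({"plot_id": plot_id, "date": date, "rue": rue})
    return pd.DataFrame(rows)


def rue_series_arrays(biomass: np.ndarray, cum_ipar: np.ndarray) -> np.ndarray:
    """Vector form of the first-date-referenced RUE difference quotient."""
    from cottonphys.radiation import rue_series

    return np.asarray(rue_series(list(biomass), list(cum_ipar))[1:], dtype=float)
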