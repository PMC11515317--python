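"""Model fitting backends.

Three estimator backends are provided, one per modelling tradition:

``fit_glm_sequence``
    Per-wave (or pooled-over-waves) generalised linear models for the
    mediator given ``(X, M_{t-1}, Y_{t-1})`` and the outcome given
    ``(X, M_t, M_{t-1}, Y_{t-1})`` — the conditional densities the
    mediational g-formula needs.
``fit_mixed``
    Linear mixed-effect models with a random intercept in the mediator
    equation and random intercept + random slopes on ``M_t`` and
    ``M_{t-1}`` in the outcome equation, via statsmodels ``MixedLM``.
``fit_lgm``
    The parallel-process latent growth model by Gaussian maximum
    likelihood on the model-implied mean vector and covariance matrix
    of the stacked ``(M_1..M_T, Y_1..Y_T)`` given ``X``, with fixed
    time loadings.

Wave-1 models carry no lagged regressors.  Pooled fits implement this
by zero-filling the lag columns at wave 1, which leaves the wave-1
linear predictor untouched (the coefficient multiplies zero) while
letting a single coefficient vector be shared across waves — exactly
the likelihood of the structural model in which the lagged terms are
absent at wave 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .model_spec import (
    FAMILIES,
    InvalidSpecError,
    LGMMediationSpec,
    MixedMediationSpec,
)
from .simulate import PanelData

__all__ = [
    "WaveModel",
    "FittedSequenceModels",
    "FittedMixed",
    "FittedLGM",
    "fit_glm_sequence",
    "fit_mixed",
    "fit_lgm",
    "FitError",
]


class FitError(RuntimeError):
    """A backend failed to converge or produced a degenerate fit."""


_SM_FAMILY = {
    "gaussian-identity": lambda: sm.families.Gaussian(),
    "binomial-logit": lambda: sm.families.Binomial(),
    "gamma-log": lambda: sm.families.Gamma(link=sm.families.links.Log()),
}


@dataclass
class WaveModel:
    """One fitted conditional model: family, coefficients, scale.

    ``coefs`` maps regressor names (``const, x, m, m_lag, y_lag``) to
    coefficients; regressors absent from the mapping act as zero.  For
    the Gaussian family ``scale`` is the residual standard deviation
    (root of the residual mean squared error); for the Gamma family it
    is the square-root dispersion, so that Var = scale^2 * mean^2.
    """

    family: str
    coefs: dict[str, float]
    scale: float


@dataclass
class FittedSequenceModels:
    """Per-wave mediator and outcome GLMs for the g-formula (step 1)."""

    mediator: list[WaveModel]
    outcome: list[WaveModel]
    pooled: bool = True

    @property
    def n_waves(self) -> int:
        return len(self.mediator)


@dataclass
class FittedMixed:
    """Estimates of the cross-lagged mixed mechanism."""

    spec: MixedMediationSpec
    converged: bool = True
    singular: bool = False
    loglik: float = np.nan

    @property
    def n_waves(self) -> int:  # waves are not fixed by the mixed spec
        return 0


@dataclass
class FittedLGM:
    """Estimates of the latent growth mechanism.

    ``psi_intercept_slope`` is the free disturbance covariance between
    the mediator latent intercept and the outcome latent slope that
    replaces the structural path when ``include_intercept_path`` is
    switched off at fit time (see :func:`fit_lgm`).
    """

    spec: LGMMediationSpec
    psi_intercept_slope: float = 0.0
    include_intercept_path: bool = True
    converged: bool = True
    loglik: float = np.nan
    implied_mean: dict = field(default_factory=dict)
    implied_cov: Optional[np.ndarray] = None

    @property
    def n_waves(self) -> int:
        return self.spec.n_waves


# ---------------------------------------------------------------------------
# JSON serialisation of fitted objects (for reuse by the g-formula engine)


def fitted_to_dict(fitted) -> dict:
    from .model_spec import spec_to_dict

    if isinstance(fitted, FittedSequenceModels):
        return {
            "kind": "sequence",
            "pooled": fitted.pooled,
            "mediator": [vars(w) for w in fitted.mediator],
            "outcome": [vars(w) for w in fitted.outcome],
        }
    if isinstance(fitted, FittedMixed):
        return {
            "kind": "mixed", "spec": spec_to_dict(fitted.spec),
            "converged": fitted.converged, "singular": fitted.singular,
            "loglik": fitted.loglik,
        }
    if isinstance(fitted, FittedLGM):
        return {
            "kind": "lgm", "spec": spec_to_dict(fitted.spec),
            "psi_intercept_slope": fitted.psi_intercept_slope,
            "include_intercept_path": fitted.include_intercept_path,
            "converged": fitted.converged, "loglik": fitted.loglik,
        }
    raise TypeError(f"cannot serialise {type(fitted).__name__}")


def fitted_from_dict(d: dict):
    from .model_spec import spec_from_dict

    kind = d["kind"]
    if kind == "sequence":
        return FittedSequenceModels(
            mediator=[WaveModel(**w) for w in d["mediator"]],
            outcome=[WaveModel(**w) for w in d["outcome"]],
            pooled=d["pooled"],
        )
    if kind == "mixed":
        return FittedMixed(
            spec=spec_from_dict(d["spec"]), converged=d["converged"],
            singular=d["singular"], loglik=d["loglik"],
        )
    if kind == "lgm":
        return FittedLGM(
            spec=spec_from_dict(d["spec"]),
            psi_intercept_slope=d["psi_intercept_slope"],
            include_intercept_path=d["include_intercept_path"],
            converged=d["converged"], loglik=d["loglik"],
        )
    raise ValueError(f"unknown fitted kind {kind!r}")


# ---------------------------------------------------------------------------
# design-matrix helpers


def _lagged_frame(panel: PanelData) -> pd.DataFrame:
    """Long frame with zero-filled lag-1 columns ``m_lag``/``y_lag``."""
    df = panel.df.copy()
    g = df.groupby("id")
    df["m_lag"] = g["m"].shift(1).fillna(0.0)
    df["y_lag"] = g["y"].shift(1).fillna(0.0)
    return df


def _glm_fit(endog, exog_df, family, label):
    if family == "gaussian-identity":
        # closed-form least squares; much faster than the IRLS machinery
        # and called thousands of times by the bootstrap
        X = exog_df.to_numpy(dtype=float)
        y = np.asarray(endog, dtype=float)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1] or not np.all(np.isfinite(coef)):
            raise FitError(f"rank-deficient design for {label}")
        resid = y - X @ coef
        return WaveModel(
            family=family,
            coefs=dict(zip(exog_df.columns, coef)),
            scale=float(np.sqrt(np.mean(resid**2))),
        )
    fam = _SM_FAMILY[family]()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, exog_df, family=fam).fit()
    except Exception as exc:  # separation, non-convergence, ...
        raise FitError(f"GLM fit failed for {label} ({family}): {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError(f"non-finite coefficients for {label} ({family})")
    coefs = dict(zip(exog_df.columns, np.asarray(res.params, dtype=float)))
    if family == "gaussian-identity":
        scale = float(np.sqrt(np.mean(res.resid_response**2)))
    elif family == "gamma-log":
        scale = float(np.sqrt(res.scale))
    else:
        scale = 1.0
    return WaveModel(family=family, coefs=coefs, scale=scale)


def fit_glm_sequence(
    panel: PanelData,
    families: Sequence[str] = ("gaussian-identity", "gaussian-identity"),
    lag_order: int = 1,
    pooled: bool = True,
    mediator_lag_y: bool = True,
    covariates: Sequence[str] = (),
) -> FittedSequenceModels:
    """Fit the per-wave conditional mediator/outcome models.

    With ``pooled=True`` (default) one coefficient vector is shared
    across waves; ``pooled=False`` fits each wave separately, wave 1
    without lag columns.  ``mediator_lag_y=False`` drops ``Y_{t-1}``
    from the mediator model (the harness's moderate misspecification
    for the mixed mechanism).  For Gaussian families the stored scale
    is the root residual mean squared error.
    """
    fam_m, fam_y = families
    for f in (fam_m, fam_y):
        if f not in FAMILIES:
            raise InvalidSpecError(f"unknown family {f!r}")
    if lag_order != 1:
        raise NotImplementedError("only lag order 1 is supported")
    df = _lagged_frame(panel)
    df["const"] = 1.0
    T = panel.n_waves
    cov = list(covariates)
    m_terms = ["const", "x", "m_lag"] + (["y_lag"] if mediator_lag_y else []) + cov
    y_terms = ["const", "x", "m", "m_lag", "y_lag"] + cov

    def strip_wave1(terms):
        return [t for t in terms if t not in ("m_lag", "y_lag")]

    mediator, outcome = [], []
    if pooled:
        wm = _glm_fit(df["m"], df[m_terms], fam_m, "mediator (pooled)")
        wy = _glm_fit(df["y"], df[y_terms], fam_y, "outcome (pooled)")
        mediator = [wm] * T
        outcome = [wy] * T
    else:
        for t in range(1, T + 1):
            sub = df[df["wave"] == t]
            mt = strip_wave1(m_terms) if t == 1 else m_terms
            yt = strip_wave1(y_terms) if t == 1 else y_terms
            mediator.append(_glm_fit(sub["m"], sub[mt], fam_m, f"mediator wave {t}"))
            outcome.append(_glm_fit(sub["y"], sub[yt], fam_y, f"outcome wave {t}"))
    return FittedSequenceModels(mediator=mediator, outcome=outcome, pooled=pooled)


# ---------------------------------------------------------------------------
# mixed-effect backend


def fit_mixed(
    panel: PanelData,
    cov_pattern: str = "diagonal",
    mediator_lag_y: bool = True,
) -> FittedMixed:
    """ML fit of the cross-lagged mixed mechanism via ``MixedLM``.

    The mediator equation carries a random intercept; the outcome
    equation a random intercept plus random slopes on the concurrent
    and lagged mediator.  ``cov_pattern='diagonal'`` (default)
    constrains the outcome random effects to be mutually uncorrelated;
    ``'block'`` lets them covary freely.  Cross-equation (mediator vs
    outcome) covariances are structurally zero, which is exactly the
    regime in which the separable effects remain identified.
    """
    if cov_pattern not in ("diagonal", "block"):
        raise ValueError("cov_pattern must be diagonal|block")
    df = _lagged_frame(panel)
    df["const"] = 1.0
    m_terms = ["const", "x", "m_lag"] + (["y_lag"] if mediator_lag_y else [])
    y_terms = ["const", "x", "m", "m_lag", "y_lag"]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod_m = sm.MixedLM(
            df["m"], df[m_terms], groups=df["id"], exog_re=df[["const"]]
        )
        try:
            res_m = mod_m.fit(reml=False)
        except Exception as exc:
            raise FitError(f"mediator mixed model failed: {exc}") from exc

        exog_re = df[["const", "m", "m_lag"]]
        mod_y = sm.MixedLM(df["y"], df[y_terms], groups=df["id"], exog_re=exog_re)
        free = None
        if cov_pattern == "diagonal":
            from statsmodels.regression.mixed_linear_model import MixedLMParams

            free = MixedLMParams.from_components(
                fe_params=np.ones(len(y_terms)), cov_re=np.eye(3)
            )
        try:
            res_y = mod_y.fit(reml=False, free=free)
        except Exception as exc:
            raise FitError(f"outcome mixed model failed: {exc}") from exc

    phi = np.zeros((4, 4))
    phi[0, 0] = float(res_m.cov_re.iloc[0, 0])
    cov_re_y = np.asarray(res_y.cov_re, dtype=float)
    phi[1:, 1:] = cov_re_y if cov_pattern == "block" else np.diag(np.diag(cov_re_y))

    pm = res_m.fe_params
    py = res_y.fe_params
    spec = MixedMediationSpec(
        beta0=float(pm["const"]),
        beta_x=float(pm["x"]),
        beta_lag_m=float(pm["m_lag"]),
        beta_lag_y=float(pm["y_lag"]) if mediator_lag_y else 0.0,
        gamma0=float(py["const"]),
        gamma_x=float(py["x"]),
        gamma_m=float(py["m"]),
        gamma_lag_m=float(py["m_lag"]),
        gamma_lag_y=float(py["y_lag"]),
        phi=phi,
        sigma_eps_m=float(np.sqrt(res_m.scale)),
        sigma_eps_y=float(np.sqrt(res_y.scale)),
    )
    converged = bool(res_m.converged and res_y.converged)
    singular = bool(
        phi[0, 0] < 1e-8 or np.any(np.diag(cov_re_y) < 1e-8)
    )
    ll = float(res_m.llf + res_y.llf)
    if not converged:
        warnings.warn("mixed backend did not fully converge", RuntimeWarning)
    return FittedMixed(spec=spec, converged=converged, singular=singular, loglik=ll)


# ---------------------------------------------------------------------------
# latent growth backend: ML on implied Gaussian moments


def _lgm_implied(theta: np.ndarray, lam: np.ndarray, include_path: bool):
    """Implied (mu0, mu1, Sigma) of stacked (M_1..M_T, Y_1..Y_T) given X.

    ``theta`` = 10 structural coefficients (gamma12 position reused for
    the free disturbance covariance when the path is excluded) followed
    by log zeta sds (4) and log measurement sds (2).
    """
    b00, b01, b10, b11, g00, g01, g10, g11, p12, g13 = theta[:10]
    s0, s1, s2, s3 = np.exp(theta[10:14])
    em, ey = np.exp(theta[14:16])
    g12 = p12 if include_path else 0.0
    psi = 0.0 if include_path else p12

    T = len(lam)
    L = np.zeros((2 * T, 4))
    L[:T, 0] = 1.0
    L[:T, 1] = lam
    L[T:, 2] = 1.0
    L[T:, 3] = lam

    Psi = np.zeros((4, 4))
    Psi[0, 0] = s0**2
    Psi[1, 1] = s1**2
    Psi[2, 2] = s2**2
    Psi[0, 3] = Psi[3, 0] = g12 * s0**2 + psi
    Psi[1, 3] = Psi[3, 1] = g13 * s1**2
    Psi[3, 3] = g12**2 * s0**2 + g13**2 * s1**2 + s3**2 + 2.0 * g12 * psi

    def mu_eta(x):
        e0m = b00 + b01 * x
        e1m = b10 + b11 * x
        return np.array(
            [e0m, e1m, g00 + g01 * x,
             g10 + g11 * x + g12 * e0m + g13 * e1m]
        )

    Sigma = L @ Psi @ L.T
    diag = np.concatenate([np.full(T, em**2), np.full(T, ey**2)])
    Sigma[np.diag_indices_from(Sigma)] += diag
    return L @ mu_eta(0.0), L @ mu_eta(1.0), Sigma


def _group_stats(panel: PanelData):
    """Per-exposure-group count, mean vector and scatter of stacked data."""
    M = panel.wide("m")
    Y = panel.wide("y")
    Z = np.hstack([M, Y])
    x = panel.exposure
    stats = []
    for g in (0, 1):
        Zg = Z[x == g]
        ng = len(Zg)
        if ng == 0:
            stats.append((0, None, None))
            continue
        mean = Zg.mean(axis=0)
        C = Zg - mean
        stats.append((ng, mean, (C.T @ C) / ng))
    return stats


def _lgm_nll(theta, lam, include_path, stats):
    mu0, mu1, Sigma = _lgm_implied(theta, lam, include_path)
    try:
        c, low = np.linalg.cholesky(Sigma), True
    except np.linalg.LinAlgError:
        return 1e12
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    nll = 0.0
    for (ng, mean, S), mu in zip(stats, (mu0, mu1)):
        if ng == 0:
            continue
        d = mean - mu
        sol_S = np.linalg.solve(Sigma, S) if S is not None else 0.0
        quad = d @ np.linalg.solve(Sigma, d)
        nll += 0.5 * ng * (logdet + np.trace(sol_S) + quad)
    return nll if np.isfinite(nll) else 1e12


def _lgm_start(panel: PanelData, lam: np.ndarray, include_path: bool) -> np.ndarray:
    """Method-of-moments starting values from per-subject OLS factor scores."""
    T = len(lam)
    D = np.column_stack([np.ones(T), lam])
    H = np.linalg.solve(D.T @ D, D.T)  # 2 x T
    M = panel.wide("m")
    Y = panel.wide("y")
    x = panel.exposure.astype(float)
    sm_scores = M @ H.T  # n x 2: intercept, slope scores
    sy_scores = Y @ H.T

    X1 = np.column_stack([np.ones_like(x), x])

    def ols(y, X):
        return np.linalg.lstsq(X, y, rcond=None)[0]

    b00, b01 = ols(sm_scores[:, 0], X1)
    b10, b11 = ols(sm_scores[:, 1], X1)
    g00, g01 = ols(sy_scores[:, 0], X1)
    Xs = np.column_stack([np.ones_like(x), x, sm_scores])
    g_slope = ols(sy_scores[:, 1], Xs)
    g10, g11, g12s, g13s = g_slope

    res_m = M - sm_scores @ D.T
    res_y = Y - sy_scores @ D.T
    dof = max(T - 2, 1)
    em2 = max(float(np.mean(res_m**2)) * T / dof, 1e-3)
    ey2 = max(float(np.mean(res_y**2)) * T / dof, 1e-3)
    noise = H @ H.T  # sampling covariance factor of the scores
    s0_2 = max(float(np.var(sm_scores[:, 0] - X1 @ [b00, b01])) - em2 * noise[0, 0], 0.05)
    s1_2 = max(float(np.var(sm_scores[:, 1] - X1 @ [b10, b11])) - em2 * noise[1, 1], 0.05)
    s2_2 = max(float(np.var(sy_scores[:, 0] - X1 @ [g00, g01])) - ey2 * noise[0, 0], 0.05)
    s3_2 = max(float(np.var(sy_scores[:, 1] - Xs @ g_slope)) - ey2 * noise[1, 1], 0.05)

    p12 = g12s if include_path else 0.0
    theta = np.array(
        [b00, b01, b10, b11, g00, g01, g10, g11, p12, g13s,
         0.5 * np.log(s0_2), 0.5 * np.log(s1_2),
         0.5 * np.log(s2_2), 0.5 * np.log(s3_2),
         0.5 * np.log(em2), 0.5 * np.log(ey2)]
    )
    return theta


def fit_lgm(
    panel: PanelData,
    lam: Optional[np.ndarray] = None,
    include_intercept_path: bool = True,
    max_restarts: int = 5,
    gtol: float = 1e-8,
    seed: int = 0,
) -> FittedLGM:
    """Gaussian ML fit of the parallel-process latent growth model.

    Maximises the likelihood of the model-implied joint Gaussian of
    the stacked observations given X (quasi-Newton from
    method-of-moments starting values).  Loadings are fixed at
    ``lam`` (default ``t - 1``), never estimated.

    ``include_intercept_path=False`` removes the mediator latent
    intercept from the outcome latent-slope equation.  The deleted
    path's covariance contribution is then carried by a free
    disturbance covariance between ``eta0M`` and ``zeta_eta1Y`` so
    that the covariance structure stays saturated and the remaining
    structural coefficients converge to their omitted-variable
    regression limits; effects computed from such a fit use only the
    analyst's structural equations (which exclude the path).
    """
    T = panel.n_waves
    lam = np.arange(T, dtype=float) if lam is None else np.asarray(lam, dtype=float)
    if len(lam) != T:
        raise InvalidSpecError(f"lam has {len(lam)} loadings but panel has {T} waves")
    stats = _group_stats(panel)
    theta0 = _lgm_start(panel, lam, include_intercept_path)

    bounds = [(None, None)] * 10 + [(np.log(1e-3), np.log(1e3))] * 6
    best = None
    rng = np.random.default_rng(seed)
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + 0.2 * rng.standard_normal(16)
        res = optimize.minimize(
            _lgm_nll,
            start,
            args=(lam, include_intercept_path, stats),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success:
            break
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("latent growth fit failed to produce finite estimates")
    th = best.x
    spec = LGMMediationSpec(
        beta00=th[0], beta01=th[1], beta10=th[2], beta11=th[3],
        gamma00=th[4], gamma01=th[5], gamma10=th[6], gamma11=th[7],
        gamma12=th[8] if include_intercept_path else 0.0,
        gamma13=th[9],
        lam=lam,
        zeta_sd=np.exp(th[10:14]),
        eps_sd_m=float(np.exp(th[14])),
        eps_sd_y=float(np.exp(th[15])),
    )
    mu0, mu1, Sigma = _lgm_implied(th, lam, include_intercept_path)
    return FittedLGM(
        spec=spec,
        psi_intercept_slope=0.0 if include_intercept_path else float(th[8]),
        include_intercept_path=include_intercept_path,
        converged=bool(best.success),
        loglik=-float(best.fun),
        implied_mean={0: mu0, 1: mu1},
        implied_cov=Sigma,
    )
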