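"""Parametric mediational g-formula Monte-Carlo estimator.

The estimand at wave t is the interventional mean
``E[Y_t(X^Y = x_y, X^M = x_m)]``: the exposure is split into a
mediator component and an outcome component, the fitted mediator laws
are evaluated under ``x_m`` and the fitted outcome laws under ``x_y``.
The engine simulates S subjects forward through the fitted conditional
models, sampling intermediate mediators and outcomes and averaging the
*conditional mean* of the outcome at each wave over simulated subjects
(a variance-reduced estimator of the interventional mean).

Contrasts of these means give the separable direct effect
(switch ``x_y`` holding ``x_m`` at the reference level) and the
separable indirect effect (switch ``x_m`` holding ``x_y`` at the
treated level).  The three interventional means needed for both
effects share one random-number stream (common random numbers), so
SDE + SIE equals the total-effect contrast exactly by construction.

Uncertainty comes from a non-parametric cluster bootstrap: subjects
are resampled with replacement, the backend is refitted on each
resample, and percentile intervals are taken over the B replicate
effect estimates.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .fit import (
    FitError,
    FittedLGM,
    FittedMixed,
    FittedSequenceModels,
    fit_glm_sequence,
    fit_lgm,
    fit_mixed,
)
from .model_spec import (
    Intervention,
    InvalidSpecError,
    LGMMediationSpec,
    MixedMediationSpec,
    psd_factor,
)
from .simulate import PanelData

__all__ = [
    "EstimatorConfig",
    "EffectEstimate",
    "gformula_mean",
    "estimate_effects",
    "proportion_mediated",
]

Models = Union[FittedSequenceModels, FittedMixed, FittedLGM,
               MixedMediationSpec, LGMMediationSpec]


@dataclass
class EstimatorConfig:
    """Configuration of the g-formula estimator.

    ``S`` is the number of Monte-Carlo subjects per interventional
    mean (production runs should keep S >= 10,000; smaller values are
    accepted with a warning).  ``B`` is the number of cluster-bootstrap
    resamples; ``B = 0`` skips the bootstrap and returns point
    estimates only.
    """

    S: int = 10_000
    B: int = 500
    ci_level: float = 0.95
    seed: Optional[int] = None
    backend: str = "glm"
    families: tuple[str, str] = ("gaussian-identity", "gaussian-identity")
    fit_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be positive")
        if self.S < 10_000:
            warnings.warn(
                f"S = {self.S} < 10,000: fine for tests, too coarse for "
                "production estimates",
                RuntimeWarning,
                stacklevel=3,
            )
        if self.B < 0:
            raise ValueError("B must be >= 0")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.backend not in ("glm", "mixed", "lgm"):
            raise ValueError("backend must be glm|mixed|lgm")


@dataclass
class EffectEstimate:
    """Per-wave separable effect estimates with bootstrap uncertainty."""

    waves: np.ndarray
    sde: np.ndarray
    sie: np.ndarray
    sde_se: Optional[np.ndarray] = None
    sie_se: Optional[np.ndarray] = None
    sde_ci: Optional[np.ndarray] = None  # (T, 2)
    sie_ci: Optional[np.ndarray] = None
    prop_mediated: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.sde + self.sie

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"wave": self.waves, "sde": self.sde, "sie": self.sie})
        if self.sde_se is not None:
            out["sde_se"] = self.sde_se
            out["sie_se"] = self.sie_se
            out["sde_ci_low"] = self.sde_ci[:, 0]
            out["sde_ci_high"] = self.sde_ci[:, 1]
            out["sie_ci_low"] = self.sie_ci[:, 0]
            out["sie_ci_high"] = self.sie_ci[:, 1]
        out["prop_mediated"] = self.prop_mediated
        return out


# ---------------------------------------------------------------------------
# forward engines per backend


def _mean(family: str, lin: np.ndarray) -> np.ndarray:
    if family == "gaussian-identity":
        return lin
    if family == "binomial-logit":
        return expit(lin)
    if family == "gamma-log":
        return np.exp(lin)
    raise InvalidSpecError(f"unknown family {family!r}")


def _sample(family: str, lin: np.ndarray, scale: float,
            rng: np.random.Generator) -> np.ndarray:
    if family == "gaussian-identity":
        return lin + scale * rng.standard_normal(lin.shape)
    if family == "binomial-logit":
        return (rng.random(lin.shape) < expit(lin)).astype(float)
    if family == "gamma-log":
        shape = 1.0 / scale**2
        return rng.gamma(shape, np.exp(lin) / shape)
    raise InvalidSpecError(f"unknown family {family!r}")


def _linpred(coefs: dict, wave_idx: int, x: float, m=None, m_lag=None, y_lag=None):
    lin = coefs.get("const", 0.0) + coefs.get("x", 0.0) * x
    if m is not None:
        lin = lin + coefs.get("m", 0.0) * m
    if wave_idx > 0:
        if m_lag is not None:
            lin = lin + coefs.get("m_lag", 0.0) * m_lag
        if y_lag is not None:
            lin = lin + coefs.get("y_lag", 0.0) * y_lag
    return lin


def _engine_sequence(
    models: FittedSequenceModels,
    x_m: float,
    x_y: float,
    S: int,
    T: int,
    rng: np.random.Generator,
    re_draws: Optional[dict] = None,
) -> np.ndarray:
    """Per-wave interventional means; optional random-effect draws.

    ``re_draws`` (mixed backend) supplies per-subject additive terms:
    ``b0`` on the mediator linear predictor, ``g0``/``gM``/``gLM`` on
    the outcome one.
    """
    b0 = g0 = gM = gLM = 0.0
    if re_draws is not None:
        b0, g0, gM, gLM = (re_draws[k] for k in ("b0", "g0", "gM", "gLM"))
    means = np.empty(T)
    m_prev = y_prev = None
    zeros = np.zeros(S)
    for t in range(T):
        wm = models.mediator[t]
        lin_m = _linpred(wm.coefs, t, x_m, m_lag=m_prev, y_lag=y_prev) + b0 + zeros
        m_t = _sample(wm.family, lin_m, wm.scale, rng)
        wy = models.outcome[t]
        lin_y = _linpred(wy.coefs, t, x_y, m=m_t, m_lag=m_prev, y_lag=y_prev)
        lin_y = lin_y + g0 + gM * m_t
        if t > 0:
            lin_y = lin_y + gLM * m_prev
        cond_mean = _mean(wy.family, lin_y)
        if not np.all(np.isfinite(cond_mean)):
            raise FitError(f"non-finite simulated outcome means at wave {t + 1}")
        means[t] = cond_mean.mean()
        y_t = _sample(wy.family, lin_y, wy.scale, rng)
        m_prev, y_prev = m_t, y_t
    return means


def _mixed_to_sequence(spec: MixedMediationSpec) -> FittedSequenceModels:
    """View a mixed spec's fixed part as per-wave conditional models."""
    wm = {
        "const": spec.beta0, "x": spec.beta_x,
        "m_lag": spec.beta_lag_m, "y_lag": spec.beta_lag_y,
    }
    wy = {
        "const": spec.gamma0, "x": spec.gamma_x, "m": spec.gamma_m,
        "m_lag": spec.gamma_lag_m, "y_lag": spec.gamma_lag_y,
    }
    from .fit import WaveModel

    return FittedSequenceModels(
        mediator=[WaveModel(spec.family_m, wm, spec.sigma_eps_m)],
        outcome=[WaveModel(spec.family_y, wy, spec.sigma_eps_y)],
        pooled=True,
    )


def _engine_mixed(
    spec: MixedMediationSpec, x_m, x_y, S, T, rng
) -> np.ndarray:
    L = psd_factor(spec.phi)
    u = rng.standard_normal((S, 4)) @ L.T
    re = dict(zip(("b0", "g0", "gM", "gLM"), u.T))
    seq = _mixed_to_sequence(spec)
    seq = FittedSequenceModels(
        mediator=seq.mediator * T, outcome=seq.outcome * T, pooled=True
    )
    return _engine_sequence(seq, x_m, x_y, S, T, rng, re_draws=re)


def _engine_lgm(
    fitted: FittedLGM | LGMMediationSpec, x_m, x_y, S, T, rng
) -> np.ndarray:
    """Draw latent factors from the fitted structural laws.

    Mediator-side factors are drawn under ``x_m``, outcome-side under
    ``x_y``; the outcome slope equation uses the analyst's structural
    specification (so an excluded intercept path contributes nothing).
    """
    spec = fitted.spec if isinstance(fitted, FittedLGM) else fitted
    include = fitted.include_intercept_path if isinstance(fitted, FittedLGM) else True
    if T != spec.n_waves:
        raise InvalidSpecError("T must match the number of loadings")
    s0, s1, s2, s3 = spec.zeta_sd
    e0m = spec.beta00 + spec.beta01 * x_m + s0 * rng.standard_normal(S)
    e1m = spec.beta10 + spec.beta11 * x_m + s1 * rng.standard_normal(S)
    e0y = spec.gamma00 + spec.gamma01 * x_y + s2 * rng.standard_normal(S)
    lin = spec.gamma10 + spec.gamma11 * x_y + spec.gamma13 * e1m
    if include:
        lin = lin + spec.gamma12 * e0m
    e1y = lin + s3 * rng.standard_normal(S)
    means = np.array(
        [np.mean(e0y + spec.lam[t] * e1y) for t in range(T)]
    )
    return means


def gformula_mean(
    models: Models,
    intervention: Intervention,
    config: EstimatorConfig,
    T: Optional[int] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Per-wave interventional outcome means under ``intervention``.

    ``models`` may be fitted objects from any backend or a true
    specification plugged in directly (no fitting), which turns the
    estimator into an oracle for testing.  ``seed`` overrides
    ``config.seed`` (used internally for common random numbers).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    x_m, x_y = float(intervention.x_m), float(intervention.x_y)
    S = config.S
    if isinstance(models, FittedSequenceModels):
        known = {"const", "x", "m", "m_lag", "y_lag"}
        for wm in (*models.mediator, *models.outcome):
            extra = set(wm.coefs) - known
            if extra:
                raise NotImplementedError(
                    "g-formula over baseline covariates is not implemented; "
                    f"unexpected regressors: {sorted(extra)}"
                )
        T = models.n_waves if T is None else T
        return _engine_sequence(models, x_m, x_y, S, T, rng)
    if isinstance(models, FittedMixed):
        if T is None:
            raise ValueError("T is required for the mixed backend")
        return _engine_mixed(models.spec, x_m, x_y, S, T, rng)
    if isinstance(models, MixedMediationSpec):
        if T is None:
            raise ValueError("T is required for the mixed backend")
        return _engine_mixed(models, x_m, x_y, S, T, rng)
    if isinstance(models, (FittedLGM, LGMMediationSpec)):
        spec = models.spec if isinstance(models, FittedLGM) else models
        T = spec.n_waves if T is None else T
        return _engine_lgm(models, x_m, x_y, S, T, rng)
    raise TypeError(f"unsupported models object {type(models).__name__}")


# ---------------------------------------------------------------------------
# effect estimation with cluster bootstrap


def _fit_backend(panel: PanelData, config: EstimatorConfig):
    if config.backend == "glm":
        return fit_glm_sequence(panel, families=config.families, **config.fit_options)
    if config.backend == "mixed":
        return fit_mixed(panel, **config.fit_options)
    return fit_lgm(panel, **config.fit_options)


def _effects_from_models(models, config, T, seed, x=1, xp=0):
    """SDE/SIE per wave via three interventional means with shared draws."""
    mean_ref = gformula_mean(models, Intervention(x_m=xp, x_y=xp), config, T, seed)
    mean_sde = gformula_mean(models, Intervention(x_m=xp, x_y=x), config, T, seed)
    mean_all = gformula_mean(models, Intervention(x_m=x, x_y=x), config, T, seed)
    return mean_sde - mean_ref, mean_all - mean_sde


def estimate_effects(
    panel: PanelData,
    config: EstimatorConfig,
    x: int = 1,
    x_ref: int = 0,
) -> EffectEstimate:
    """Fit the configured backend and estimate per-wave SDE and SIE.

    SDE compares ``(X^Y = x, X^M = x_ref)`` with ``(x_ref, x_ref)``;
    SIE compares ``(x, x)`` with ``(x, x_ref)``.  The three
    interventional means share one random-number stream.  With
    ``config.B > 0``, subjects are resampled with replacement B times,
    the backend refitted per resample, and percentile intervals
    attached.
    """
    t_start = time.perf_counter()
    T = panel.n_waves
    ss = np.random.SeedSequence(config.seed)
    point_seed = int(ss.generate_state(1)[0] % (2**31))
    models = _fit_backend(panel, config)
    sde, sie = _effects_from_models(models, config, T, point_seed, x, x_ref)

    meta = {
        "backend": config.backend, "S": config.S, "B": config.B,
        "seed": config.seed, "n_subjects": panel.n_subjects,
        "ci_level": config.ci_level, "x": x, "x_ref": x_ref,
    }
    est = EffectEstimate(
        waves=np.arange(1, T + 1),
        sde=sde,
        sie=sie,
        prop_mediated=_pm_array(sde, sie),
        metadata=meta,
    )
    if config.B == 0:
        est.metadata["runtime_s"] = round(time.perf_counter() - t_start, 3)
        return est

    ids = panel.df["id"].unique()
    n = len(ids)
    wide = panel.df.set_index(["id", "wave"])
    boot_sde = np.empty((config.B, T))
    boot_sie = np.empty((config.B, T))
    children = ss.spawn(config.B)
    failures = 0
    for b, child in enumerate(children):
        bseed = int(child.generate_state(1)[0] % (2**31))
        brng = np.random.default_rng(bseed)
        take = brng.choice(ids, size=n, replace=True)
        frames = wide.loc[take].reset_index()
        frames["id"] = np.repeat(np.arange(n), T)
        bpanel = PanelData(frames)
        try:
            bmodels = _fit_backend(bpanel, config)
            boot_sde[b], boot_sie[b] = _effects_from_models(
                bmodels, config, T, bseed, x, x_ref
            )
        except FitError as exc:
            failures += 1
            if failures > max(1, config.B // 20):
                raise FitError(
                    f"bootstrap replicate {b}: too many failures ({exc})"
                ) from exc
            boot_sde[b] = boot_sie[b] = np.nan
    alpha = 1.0 - config.ci_level
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    est.sde_se = np.nanstd(boot_sde, axis=0, ddof=1)
    est.sie_se = np.nanstd(boot_sie, axis=0, ddof=1)
    est.sde_ci = np.nanpercentile(boot_sde, qs, axis=0).T
    est.sie_ci = np.nanpercentile(boot_sie, qs, axis=0).T
    est.metadata["bootstrap_failures"] = failures
    est.metadata["runtime_s"] = round(time.perf_counter() - t_start, 3)
    return est


def _pm_array(sde: np.ndarray, sie: np.ndarray) -> np.ndarray:
    total = sde + sie
    with np.errstate(divide="ignore", invalid="ignore"):
        pm = np.where(total != 0, sie / total, np.nan)
    return pm


def proportion_mediated(estimate: EffectEstimate, wave: int) -> float:
    """SIE / (SDE + SIE) at ``wave``; NaN when the total effect is zero."""
    idx = int(np.where(estimate.waves == wave)[0][0])
    sde, sie = estimate.sde[idx], estimate.sie[idx]
    total = sde + sie
    if total == 0:
        warnings.warn("total effect is zero; proportion mediated undefined")
        return float("nan")
    return float(sie / total)
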