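"""True separable effects implied by a specification.

This module is the package's ground-truth oracle.  For the latent
growth mechanism the effects have exact closed forms obtained by path
tracing:

    SDE_t = (gamma01 + gamma11 * lambda_t) * (x - x')
    SIE_t = lambda_t * (beta01*gamma12 + beta11*gamma13) * (x - x')

For the mixed mechanism, closed forms are derived here for waves 1-2
by path-tracing the generating recursion and taking expectations over
the random effects.  Because the wave-2 indirect effect contains the
squared random slope ``(gamma_m + gM)^2``, its expectation carries the
second-moment correction ``gamma_m**2 + Var(gM)`` rather than the naive
plug-in ``gamma_m**2``.  Beyond wave 2 the number of open paths (and of
random-coefficient products) grows quickly, so the truth is evaluated
*asymptotically*: a large-sample Monte-Carlo forward simulation of the
generating recursion with the exposure split into its two components
(mediator equations see ``x_m``, outcome equations see ``x_y``),
averaging the conditional outcome mean over simulated subjects.

The asymptotic oracle is coded directly against the generating
equations and shares no machinery with the g-formula estimator, so the
two can cross-validate each other in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .model_spec import (
    Intervention,
    InvalidSpecError,
    LGMMediationSpec,
    MixedMediationSpec,
    NotIdentifiedError,
    check_identifiability,
    validate_spec,
    psd_factor,
)

__all__ = [
    "EffectPair",
    "lgm_effects",
    "mixed_effects_closed",
    "mixed_effects_asymptotic",
    "total_effect",
]


@dataclass(frozen=True)
class EffectPair:
    """Separable direct/indirect effect at one wave, on the difference scale."""

    wave: int
    sde: float
    sie: float
    contrast: Intervention
    sde_mc_se: float = 0.0
    sie_mc_se: float = 0.0

    @property
    def total(self) -> float:
        return self.sde + self.sie


def _contrast_delta(contrast: Intervention) -> float:
    """The (x - x') multiplier: x = x_y, x' = x_m by convention."""
    return float(contrast.x_y - contrast.x_m)


def _check_wave(wave: int, T: int) -> None:
    if not 1 <= wave <= T:
        raise ValueError(f"wave must be in 1..{T}, got {wave}")


def lgm_effects(
    spec: LGMMediationSpec, wave: int, contrast: Intervention
) -> EffectPair:
    """Exact separable effects of the latent growth mechanism at ``wave``."""
    problems = validate_spec(spec)
    if problems:
        raise InvalidSpecError("; ".join(problems))
    _check_wave(wave, spec.n_waves)
    d = _contrast_delta(contrast)
    lam = spec.lam[wave - 1]
    sde = (spec.gamma01 + spec.gamma11 * lam) * d
    sie = lam * (spec.beta01 * spec.gamma12 + spec.beta11 * spec.gamma13) * d
    return EffectPair(wave=wave, sde=sde, sie=sie, contrast=contrast)


def mixed_effects_closed(
    spec: MixedMediationSpec, wave: int, contrast: Intervention
) -> EffectPair:
    """Closed-form separable effects of the mixed mechanism, waves 1-2.

    Requires a diagonal or block-diagonal ``phi`` (otherwise the
    effects are not identified) and Gaussian families.  The wave-2
    indirect effect averages ``(gamma_m + gM)^2`` over the random
    slope, contributing ``gamma_m**2 + Var(gM)``; a within-block
    covariance between ``gM`` and ``g_lag_m`` first enters at wave 3
    and is therefore absent from these two-wave formulas.
    """
    status = check_identifiability(spec)
    if status.status == "not_identified":
        raise NotIdentifiedError(status.rationale)
    if spec.family_m != "gaussian-identity" or spec.family_y != "gaussian-identity":
        raise InvalidSpecError("closed forms require Gaussian families")
    if wave not in (1, 2):
        raise ValueError("closed forms are available for waves 1 and 2 only")
    d = _contrast_delta(contrast)
    gm, var_gm = spec.gamma_m, spec.phi[2, 2]
    if wave == 1:
        sde = spec.gamma_x * d
        sie = spec.beta_x * gm * d
    else:
        # SDE paths: X^Y -> Y2;  X^Y -> Y1 -> M2 -> Y2;  X^Y -> Y1 -> Y2
        sde = spec.gamma_x * (1.0 + spec.beta_lag_y * gm + spec.gamma_lag_y) * d
        # SIE paths out of X^M: M2->Y2, M1->M2->Y2, M1->Y1->M2->Y2 (with
        # E[(gamma_m+gM)^2] = gamma_m^2 + Var(gM)), M1->Y2, M1->Y1->Y2
        sie = (
            spec.beta_x
            * (
                gm * (1.0 + spec.beta_lag_m)
                + spec.beta_lag_y * (gm**2 + var_gm)
                + spec.gamma_lag_m
                + spec.gamma_lag_y * gm
            )
            * d
        )
    return EffectPair(wave=wave, sde=sde, sie=sie, contrast=contrast)


# ---------------------------------------------------------------------------
# asymptotic Monte-Carlo oracle


def _inv_link_mean(family: str, lin: np.ndarray) -> np.ndarray:
    if family == "gaussian-identity":
        return lin
    if family == "binomial-logit":
        return expit(lin)
    if family == "gamma-log":
        return np.exp(lin)
    raise InvalidSpecError(f"unknown family {family!r}")


def _draw_from(family: str, lin: np.ndarray, scale: float,
               rng: np.random.Generator) -> np.ndarray:
    if family == "gaussian-identity":
        return lin + scale * rng.standard_normal(lin.shape)
    if family == "binomial-logit":
        return (rng.random(lin.shape) < expit(lin)).astype(float)
    if family == "gamma-log":
        shape = 1.0 / scale**2
        mu = np.exp(lin)
        return rng.gamma(shape, mu / shape)
    raise InvalidSpecError(f"unknown family {family!r}")


def _forward_means(
    spec: MixedMediationSpec,
    x_m: float,
    x_y: float,
    T: int,
    draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-draw conditional outcome means at every wave, split exposure.

    Mediator equations see ``x_m`` and outcome equations see ``x_y``.
    Intermediate mediators and outcomes are sampled draws; the recorded
    quantity at each wave is the conditional mean of Y given the
    simulated history (the variance-reduced estimator of the
    interventional mean).
    """
    L = psd_factor(spec.phi)
    u = rng.standard_normal((draws, 4)) @ L.T
    b0, g0, gM, gLM = u.T
    means = np.empty((draws, T))
    m_prev = y_prev = None
    for t in range(T):
        lin_m = spec.beta0 + b0 + spec.beta_x * x_m
        if t > 0:
            lin_m = lin_m + spec.beta_lag_m * m_prev + spec.beta_lag_y * y_prev
        m_t = _draw_from(spec.family_m, lin_m, spec.sigma_eps_m, rng)

        lin_y = spec.gamma0 + g0 + spec.gamma_x * x_y + (spec.gamma_m + gM) * m_t
        if t > 0:
            lin_y = lin_y + (spec.gamma_lag_m + gLM) * m_prev + spec.gamma_lag_y * y_prev
        means[:, t] = _inv_link_mean(spec.family_y, lin_y)
        y_t = _draw_from(spec.family_y, lin_y, spec.sigma_eps_y, rng)
        m_prev, y_prev = m_t, y_t
    return means


def mixed_effects_asymptotic(
    spec: MixedMediationSpec,
    wave: int,
    contrast: Intervention,
    draws: int = 1_000_000,
    seed: Optional[int] = None,
    T: Optional[int] = None,
) -> EffectPair:
    """Monte-Carlo evaluation of the true mixed-mechanism effects.

    Simulates ``draws`` subjects forward under each of the three
    component interventions sharing one random-number stream (common
    random numbers), and reports the SDE/SIE contrasts with their
    Monte-Carlo standard errors.
    """
    problems = validate_spec(spec)
    if problems:
        raise InvalidSpecError("; ".join(problems))
    if draws < 1000:
        raise ValueError("draws < 1000 would make a poor oracle; increase draws")
    T = T if T is not None else max(wave, 2)
    _check_wave(wave, T)
    x, xp = contrast.x_y, contrast.x_m
    if contrast.is_null:
        return EffectPair(wave=wave, sde=0.0, sie=0.0, contrast=contrast)
    ss = np.random.SeedSequence(seed)
    base = ss.generate_state(1)[0] % (2**31)
    # common random numbers: identical stream per intervention
    mm = {}
    for (ixm, ixy) in [(xp, xp), (xp, x), (x, x)]:
        mm[(ixm, ixy)] = _forward_means(
            spec, ixm, ixy, T, draws, np.random.default_rng(base)
        )
    w = wave - 1
    sde_draws = mm[(xp, x)][:, w] - mm[(xp, xp)][:, w]
    sie_draws = mm[(x, x)][:, w] - mm[(xp, x)][:, w]
    return EffectPair(
        wave=wave,
        sde=float(sde_draws.mean()),
        sie=float(sie_draws.mean()),
        contrast=contrast,
        sde_mc_se=float(sde_draws.std(ddof=1) / np.sqrt(draws)),
        sie_mc_se=float(sie_draws.std(ddof=1) / np.sqrt(draws)),
    )


def total_effect(
    spec: MixedMediationSpec | LGMMediationSpec,
    wave: int,
    contrast: Intervention,
    draws: int = 100_000,
    seed: Optional[int] = None,
    T: Optional[int] = None,
) -> float:
    """Total effect E[Y_t(X=x)] - E[Y_t(X=x')].

    Closed form for the latent growth mechanism; independent forward
    simulation (its own random stream, no common random numbers with
    any other oracle call) for the mixed mechanism.  Equals SDE + SIE
    of the same spec and wave.
    """
    if contrast.is_null:
        return 0.0
    if isinstance(spec, LGMMediationSpec):
        pair = lgm_effects(spec, wave, contrast)
        return pair.total
    T = T if T is not None else max(wave, 2)
    _check_wave(wave, T)
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    hi = _forward_means(
        spec, contrast.x_y, contrast.x_y, T, draws, np.random.default_rng(s1)
    )
    lo = _forward_means(
        spec, contrast.x_m, contrast.x_m, T, draws, np.random.default_rng(s2)
    )
    return float(hi[:, wave - 1].mean() - lo[:, wave - 1].mean())
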