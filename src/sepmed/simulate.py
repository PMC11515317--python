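"""Synthetic panel generators for the two mediation mechanisms.

Both generators produce balanced long-format panels (one row per
subject x wave) with a binary baseline exposure randomised with
probability 0.5, a per-wave mediator and a per-wave outcome.  They are
first-class, tested components: every downstream stage of the package
(fitting, g-formula estimation, replication studies) runs on panels
produced here, so no external data are required anywhere.

Assumption-violation variants add an unobserved subject-level
confounder ``U ~ Normal(0, u_sd)``:

* mixed mechanism — ``u_effect * U`` enters the wave-1 mediator and
  wave-1 outcome linear predictors only, confounding ``M_1`` and
  ``Y_1``;
* latent growth mechanism — ``u_effect * U`` enters the mediator
  latent-intercept equation and every outcome measurement equation,
  confounding the mediator process with the whole outcome series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .model_spec import (
    InvalidSpecError,
    LGMMediationSpec,
    MixedMediationSpec,
    validate_spec,
    psd_factor,
)

__all__ = ["PanelData", "ScenarioConfig", "simulate_mixed", "simulate_lgm"]


@dataclass
class PanelData:
    """A validated balanced long-format panel.

    Wraps a :class:`pandas.DataFrame` with columns ``id, wave, x, m, y``
    (plus optional baseline covariate columns), sorted by ``(id, wave)``.
    Every subject has exactly ``T`` waves and a constant exposure.
    """

    df: pd.DataFrame
    covariates: tuple[str, ...] = ()

    REQUIRED = ("id", "wave", "x", "m", "y")

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"panel is missing column(s): {', '.join(missing)}")
        df = df.sort_values(["id", "wave"]).reset_index(drop=True)
        if df[list(self.REQUIRED)].isna().any().any():
            raise ValueError("panel contains missing cells")
        counts = df.groupby("id")["wave"].agg(["size", "nunique"])
        if counts["size"].nunique() != 1 or (counts["size"] != counts["nunique"]).any():
            raise ValueError("panel is unbalanced: unequal or duplicated waves")
        if not set(np.unique(df["x"])) <= {0, 1}:
            raise ValueError("exposure x must be binary 0/1")
        if (df.groupby("id")["x"].nunique() > 1).any():
            raise ValueError("exposure x must be constant within subject")
        self.df = df
        self.covariates = tuple(
            c for c in df.columns if c not in self.REQUIRED
        )

    @property
    def n_subjects(self) -> int:
        return self.df["id"].nunique()

    @property
    def n_waves(self) -> int:
        return int(self.df.groupby("id")["wave"].size().iloc[0])

    def wide(self, col: str) -> np.ndarray:
        """Values of ``col`` as an (n_subjects, T) array in wave order."""
        return self.df.pivot(index="id", columns="wave", values=col).to_numpy()

    @property
    def exposure(self) -> np.ndarray:
        """Per-subject exposure vector, in subject-id order."""
        return self.df.groupby("id")["x"].first().to_numpy()


@dataclass
class ScenarioConfig:
    """Configuration of one simulation scenario.

    ``misspecification`` selects the structural deviation applied at
    *fitting* time by the study harness (the generator itself always
    simulates the true mechanism); ``confounded`` adds the unobserved
    confounder described in the module docstring.
    """

    mechanism: str = "mixed"
    misspecification: str = "none"
    confounded: bool = False
    n: int = 1000
    T: int = 5
    seed: Optional[int] = None
    u_effect: float = 1.0
    u_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("mixed", "lgm"):
            raise ValueError(f"mechanism must be mixed|lgm, got {self.mechanism!r}")
        if self.misspecification not in ("none", "moderate", "severe"):
            raise ValueError(
                "misspecification must be none|moderate|severe, "
                f"got {self.misspecification!r}"
            )
        if self.n < 2 or self.T < 2:
            raise ValueError("need n >= 2 subjects and T >= 2 waves")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")


def _rng(scenario: ScenarioConfig) -> np.random.Generator:
    return np.random.default_rng(scenario.seed)


def _draw(family: str, mean_lin: np.ndarray, scale: float,
          rng: np.random.Generator) -> np.ndarray:
    """Draw observations given a linear predictor under a family/link."""
    if family == "gaussian-identity":
        return mean_lin + scale * rng.standard_normal(mean_lin.shape)
    if family == "binomial-logit":
        return (rng.random(mean_lin.shape) < expit(mean_lin)).astype(float)
    if family == "gamma-log":
        # scale acts as the dispersion: Var = dispersion * mean^2
        shape = 1.0 / scale**2
        mu = np.exp(mean_lin)
        return rng.gamma(shape, mu / shape)
    raise InvalidSpecError(f"unknown family {family!r}")


def _assemble(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> PanelData:
    n, T = m.shape
    df = pd.DataFrame(
        {
            "id": np.repeat(np.arange(n), T),
            "wave": np.tile(np.arange(1, T + 1), n),
            "x": np.repeat(x.astype(int), T),
            "m": m.ravel(),
            "y": y.ravel(),
        }
    )
    return PanelData(df)


def simulate_mixed(spec: MixedMediationSpec, scenario: ScenarioConfig) -> PanelData:
    """Generate a panel from the cross-lagged mixed-effect mechanism.

    Exposure is Bernoulli(0.5) per subject; random effects
    ``(b0, g0, gM, g_lag_m)`` are MVN(0, phi) per subject; waves are
    generated forward, the wave-1 equations carrying no lagged terms.
    """
    problems = validate_spec(spec)
    if problems:
        raise InvalidSpecError("; ".join(problems))
    if scenario.mechanism != "mixed":
        raise ValueError("scenario.mechanism must be 'mixed'")
    rng = _rng(scenario)
    n, T = scenario.n, scenario.T

    x = (rng.random(n) < 0.5).astype(float)
    L = psd_factor(spec.phi)
    u = rng.standard_normal((n, 4)) @ L.T
    b0, g0, gM, gLM = u.T
    conf = (
        scenario.u_effect * scenario.u_sd * rng.standard_normal(n)
        if scenario.confounded
        else np.zeros(n)
    )

    m = np.empty((n, T))
    y = np.empty((n, T))
    for t in range(T):
        lin_m = spec.beta0 + b0 + spec.beta_x * x
        if t == 0:
            lin_m = lin_m + conf
        else:
            lin_m = lin_m + spec.beta_lag_m * m[:, t - 1] + spec.beta_lag_y * y[:, t - 1]
        m[:, t] = _draw(spec.family_m, lin_m, spec.sigma_eps_m, rng)

        lin_y = spec.gamma0 + g0 + spec.gamma_x * x + (spec.gamma_m + gM) * m[:, t]
        if t == 0:
            lin_y = lin_y + conf
        else:
            lin_y = (
                lin_y
                + (spec.gamma_lag_m + gLM) * m[:, t - 1]
                + spec.gamma_lag_y * y[:, t - 1]
            )
        y[:, t] = _draw(spec.family_y, lin_y, spec.sigma_eps_y, rng)
    return _assemble(x, m, y)


def simulate_lgm(spec: LGMMediationSpec, scenario: ScenarioConfig) -> PanelData:
    """Generate a panel from the parallel-process latent growth mechanism.

    Latent factors are drawn in topological order (eta0M, eta1M, eta0Y,
    then eta1Y given the mediator factors); measurements add
    independent Gaussian errors.
    """
    problems = validate_spec(spec)
    if problems:
        raise InvalidSpecError("; ".join(problems))
    if scenario.mechanism != "lgm":
        raise ValueError("scenario.mechanism must be 'lgm'")
    if scenario.T != spec.n_waves:
        raise InvalidSpecError(
            f"scenario.T = {scenario.T} but spec has {spec.n_waves} loadings"
        )
    rng = _rng(scenario)
    n, T = scenario.n, scenario.T
    lam = spec.lam
    s0, s1, s2, s3 = spec.zeta_sd

    x = (rng.random(n) < 0.5).astype(float)
    conf = (
        scenario.u_sd * rng.standard_normal(n)
        if scenario.confounded
        else np.zeros(n)
    )
    eta0m = spec.beta00 + spec.beta01 * x + s0 * rng.standard_normal(n)
    if scenario.confounded:
        eta0m = eta0m + scenario.u_effect * conf
    eta1m = spec.beta10 + spec.beta11 * x + s1 * rng.standard_normal(n)
    eta0y = spec.gamma00 + spec.gamma01 * x + s2 * rng.standard_normal(n)
    eta1y = (
        spec.gamma10
        + spec.gamma11 * x
        + spec.gamma12 * eta0m
        + spec.gamma13 * eta1m
        + s3 * rng.standard_normal(n)
    )

    m = eta0m[:, None] + lam[None, :] * eta1m[:, None]
    m = m + spec.eps_sd_m * rng.standard_normal((n, T))
    y = eta0y[:, None] + lam[None, :] * eta1y[:, None]
    if scenario.confounded:
        y = y + scenario.u_effect * conf[:, None]
    y = y + spec.eps_sd_y * rng.standard_normal((n, T))
    return _assemble(x, m, y)
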