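"""Synthetic data generation for the Monte-Carlo study and the CLI fit path.

Doses follow a two-part (semicontinuous) mixture: exactly 0 with probability
``p_zero``, otherwise ``gamma_X`` times a Beta(``alpha_X``, ``beta_X``) draw.
Two dose scenarios are studied:

* scenario 1: alpha_X = 1, beta_X = 5, gamma_X = 2 (doses dense near zero);
* scenario 2: alpha_X = 6, beta_X = 5, gamma_X = 1 (low-dose range sparse).

Outcomes come from a quadratic model with a spike at zero,

    Y = 10 + beta1 * 1(X > 0) - 2.4 X + 4.8 X^2 + eps,   eps ~ N(0, 1.5^2),

with the spike effect beta1 set to 0.5 (spike present) or 0 (no spike).

``generate_applied_fixture`` produces a purely synthetic claims-like table
(opioid-dose-style semicontinuous exposure in morphine milligram equivalents,
semicontinuous outcome, repeated cluster ids, two covariates) to exercise the
fit pipeline end to end; it mimics qualitative shape only and stands in for
administrative data that cannot be redistributed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InvalidInputError

__all__ = [
    "ScenarioConfig",
    "SimulatedSample",
    "scenario_config",
    "draw_doses",
    "draw_outcomes",
    "draw_sample",
    "true_delta",
    "generate_applied_fixture",
    "write_fixture_csv",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """All generating-mechanism parameters for one simulation scenario."""

    p_zero: float = 0.25
    alpha_X: float = 1.0
    beta_X: float = 5.0
    gamma_X: float = 2.0
    beta1_true: float = 0.5
    intercept_true: float = 10.0
    slope_true: float = -2.4
    quad_true: float = 4.8
    sigma_Y: float = 1.5
    N: int = 1000
    M: int = 5000
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_zero <= 1.0:
            raise ConfigError(f"p_zero must be in [0, 1], got {self.p_zero}")
        for fname in ("alpha_X", "beta_X", "gamma_X", "sigma_Y"):
            v = getattr(self, fname)
            if not v > 0 and not (fname == "sigma_Y" and v == 0):
                raise ConfigError(f"{fname} must be positive, got {v}")
        if self.N < 1:
            raise ConfigError(f"N must be >= 1, got {self.N}")
        if self.M < 1:
            raise ConfigError(f"M must be >= 1, got {self.M}")

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


def scenario_config(dose_scenario: int = 1, spike: bool = True, **overrides) -> ScenarioConfig:
    """Preset configs for the four dose x spike study scenarios."""
    if dose_scenario == 1:
        base = dict(alpha_X=1.0, beta_X=5.0, gamma_X=2.0)
    elif dose_scenario == 2:
        base = dict(alpha_X=6.0, beta_X=5.0, gamma_X=1.0)
    else:
        raise ConfigError(f"dose_scenario must be 1 or 2, got {dose_scenario}")
    base["beta1_true"] = 0.5 if spike else 0.0
    base["name"] = f"scenario{dose_scenario}_{'spike' if spike else 'nospike'}"
    base.update(overrides)
    return ScenarioConfig(**base)


@dataclass
class SimulatedSample:
    """One replicate: doses X and outcomes Y of equal length."""

    doses: np.ndarray
    outcomes: np.ndarray


def draw_doses(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Semicontinuous mixture draw: 0 w.p. p_zero, else gamma_X * Beta(a, b).

    A Beta draw that underflows to exactly 0 (possible when alpha_X < 1) is
    redrawn so the exposure indicator 1(X > 0) stays exact for the mixture.
    """
    n = config.N
    zero = rng.random(n) < config.p_zero
    pos = config.gamma_X * rng.beta(config.alpha_X, config.beta_X, size=n)
    while True:
        bad = (~zero) & (pos == 0.0)
        if not bad.any():
            break
        pos[bad] = config.gamma_X * rng.beta(config.alpha_X, config.beta_X, size=int(bad.sum()))
    x = np.where(zero, 0.0, pos)
    return x


def draw_outcomes(doses, config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Quadratic-with-spike outcome model with independent Gaussian errors."""
    x = np.asarray(doses, dtype=float)
    if np.any(x < 0):
        raise InvalidInputError("doses must be nonnegative")
    mean = (
        config.intercept_true
        + config.beta1_true * (x > 0)
        + config.slope_true * x
        + config.quad_true * x**2
    )
    return mean + rng.normal(0.0, config.sigma_Y, size=x.shape)


def draw_sample(config: ScenarioConfig, rng: np.random.Generator) -> SimulatedSample:
    x = draw_doses(config, rng)
    y = draw_outcomes(x, config, rng)
    return SimulatedSample(doses=x, outcomes=y)


def true_delta(x, config: ScenarioConfig):
    """True dose-response difference Delta(x) = E[Y|X=x] - E[Y|X=0].

    Zero by definition at x = 0; for positive doses the spike effect plus the
    polynomial dose terms.
    """
    x = np.asarray(x, dtype=float)
    d = config.beta1_true + config.slope_true * x + config.quad_true * x**2
    return np.where(x == 0, 0.0, d)


def generate_applied_fixture(
    n_patients: int = 2000,
    repeat_fraction: float = 0.1,
    seed: int = 0,
    p_zero: float = 0.45,
) -> pd.DataFrame:
    """SYNTHETIC claims-like table for exercising the fit pipeline.

    Emulates the qualitative shape of a pharmacy-claims analysis -- an
    initial opioid dose in morphine milligram equivalents (MME) with a large
    mass at zero and a right-skewed positive part, a semicontinuous
    subsequent-dose outcome, cluster ids with a configurable fraction of
    repeat deliveries, and two covariates (age, parity). All values are
    generated from simple parametric forms; nothing is derived from real
    administrative data.
    """
    if n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    if not 0.0 <= repeat_fraction < 1.0:
        raise ConfigError("repeat_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = n_patients
    # cluster ids: repeat_fraction of rows reuse an earlier id (same mother)
    n_unique = max(1, int(round(n * (1.0 - repeat_fraction))))
    ids = np.arange(n_unique)
    extra = rng.choice(ids, size=n - n_unique, replace=True) if n > n_unique else np.empty(0, int)
    cluster = rng.permutation(np.concatenate([ids, extra]))
    zero = rng.random(n) < p_zero
    dose = np.where(zero, 0.0, rng.gamma(shape=2.0, scale=75.0, size=n))
    age = rng.normal(26.0, 5.5, size=n).clip(15, 45)
    parity = rng.poisson(1.2, size=n).astype(float)
    # outcome: semicontinuous subsequent dose; level rises nonlinearly in dose,
    # with a jump for any exposure and noise; floored at zero
    mean = 20.0 * (dose > 0) + 0.5 * dose - 5e-4 * dose**2 + 1.5 * (age - 26.0) + 4.0 * parity
    outcome = np.maximum(mean + rng.normal(0.0, 40.0, size=n), 0.0)
    subsequent_zero = rng.random(n) < 0.55
    outcome = np.where(subsequent_zero, 0.0, outcome)
    return pd.DataFrame(
        {
            "dose": dose,
            "outcome": outcome,
            "cluster": cluster,
            "age": age,
            "parity": parity,
        }
    )


def write_fixture_csv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write the fixture with a commented metadata header recording provenance."""
    buf = io.StringIO()
    buf.write("# synthetic claims-like fixture generated by slabspline.simgen\n")
    for k, v in (params or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
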