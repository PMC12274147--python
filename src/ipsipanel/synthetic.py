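"""Synthetic recurring-exposure cohorts with known structural truth.

The generator draws, per individual, baseline binaries C, then sequentially
L_t -> X_t -> Y_t for t = 1..T (exposure-first ordering), with first-order
dependence on the previous wave.  Two variants:

* continuous (default): Gaussian L_t and Y_t;
* ``discrete=True``: binary L_t and Y_t with linear-probability means, so the
  intervention mean can be computed exactly by path enumeration.

An optional latent confounder U ~ N(0,1) loads on every X_t linear predictor
(``u_strength``) and every Y_t mean (``u_outcome``); it is drawn but never
included in the returned panel, which breaks the sequential-ignorability
structure on purpose for sensitivity-analysis testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product as _iproduct

import numpy as np
import pandas as pd
from scipy.special import expit

from .panel import PanelDataset, PanelSchema
from .propensity import shift

__all__ = [
    "LCoef", "XCoef", "YCoef", "SyntheticConfig", "TrueIpsice",
    "generate_panel", "true_ipsice", "default_config", "discrete_config",
    "ConfigError", "UnsupportedMethodError",
]


class ConfigError(ValueError):
    pass


class UnsupportedMethodError(ValueError):
    pass


@dataclass(frozen=True)
class LCoef:
    """Time-varying covariate equation: linear in (C, L_{t-1}, X_{t-1}, Y_{t-1})."""

    intercept: float = 0.0
    c: tuple[float, ...] = ()
    l_prev: float = 0.0
    x_prev: float = 0.0
    y_prev: float = 0.0
    sd: float = 1.0  # ignored when discrete


@dataclass(frozen=True)
class XCoef:
    """Exposure logit: linear in (C, L_t, X_{t-1}, Y_{t-1})."""

    intercept: float = 0.0
    c: tuple[float, ...] = ()
    l: float = 0.0
    x_prev: float = 0.0
    y_prev: float = 0.0


@dataclass(frozen=True)
class YCoef:
    """Outcome mean: linear in (X_t, C, L_t, X_{t-1}, Y_{t-1}) plus X_t*L_t."""

    intercept: float = 0.0
    x: float = 0.0
    c: tuple[float, ...] = ()
    l: float = 0.0
    x_prev: float = 0.0
    y_prev: float = 0.0
    x_l: float = 0.0
    sd: float = 1.0  # ignored when discrete


@dataclass(frozen=True)
class SyntheticConfig:
    n: int
    T: int
    p_c: tuple[float, ...] = ()
    coef_l: LCoef = field(default_factory=LCoef)
    coef_x: XCoef = field(default_factory=XCoef)
    coef_y: YCoef = field(default_factory=YCoef)
    u_strength: float = 0.0        # loading of latent U on every X_t logit
    u_outcome: float | None = None  # loading of U on every Y_t mean (default: u_strength)
    discrete: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.T < 1:
            raise ConfigError("n and T must be >= 1")
        if any(not 0 <= p <= 1 for p in self.p_c):
            raise ConfigError("p_c entries must be probabilities")
        if not self.discrete and (self.coef_l.sd <= 0 or self.coef_y.sd <= 0):
            raise ConfigError("noise sds must be positive for continuous configs")
        for name, coef in (("coef_l", self.coef_l.c), ("coef_x", self.coef_x.c),
                           ("coef_y", self.coef_y.c)):
            if len(coef) not in (0, len(self.p_c)):
                raise ConfigError(f"{name}.c must have one entry per baseline covariate")

    @property
    def u_y(self) -> float:
        return self.u_strength if self.u_outcome is None else self.u_outcome

    def schema(self) -> PanelSchema:
        return PanelSchema.from_dict({
            "id": "id", "T": self.T,
            "C": [f"c{j + 1}" for j in range(len(self.p_c))],
            "L": "l", "X": "x", "Y": "y",
        })


@dataclass(frozen=True)
class TrueIpsice:
    """Structural-truth intervention mean; ``se`` is 0 for exact enumeration."""

    value: float
    se: float = 0.0

    def __float__(self) -> float:
        return self.value


def _clip01(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 0.0, 1.0)


def _cdot(coefs: tuple[float, ...], C: np.ndarray) -> np.ndarray:
    if len(coefs) == 0:
        return np.zeros(C.shape[0])
    return C[:, : len(coefs)] @ np.asarray(coefs)


def _l_mean(cfg: SyntheticConfig, C, l_prev, x_prev, y_prev):
    a = cfg.coef_l
    return a.intercept + _cdot(a.c, C) + a.l_prev * l_prev + a.x_prev * x_prev + a.y_prev * y_prev


def _x_logit(cfg: SyntheticConfig, C, l, x_prev, y_prev, u):
    b = cfg.coef_x
    return (b.intercept + _cdot(b.c, C) + b.l * l + b.x_prev * x_prev
            + b.y_prev * y_prev + cfg.u_strength * u)


def _y_mean(cfg: SyntheticConfig, C, x, l, x_prev, y_prev, u):
    g = cfg.coef_y
    return (g.intercept + g.x * x + _cdot(g.c, C) + g.l * l + g.x_prev * x_prev
            + g.y_prev * y_prev + g.x_l * x * l + cfg.u_y * u)


def generate_panel(config: SyntheticConfig, seed: int | None = None,
                   delta: float | None = None,
                   fixed_exposures: tuple[int, ...] | None = None,
                   return_latent: bool = False):
    """Simulate a cohort; identical seed gives a bit-identical panel.

    ``delta`` draws each X_t from the odds-shifted version of the *structural*
    propensity (the intervention the truth oracle targets); ``fixed_exposures``
    instead forces the exposure path, yielding counterfactual outcomes for
    consistency checks.  The latent U is returned only when asked.
    """
    if delta is not None and fixed_exposures is not None:
        raise ConfigError("delta and fixed_exposures are mutually exclusive")
    if fixed_exposures is not None and len(fixed_exposures) != config.T:
        raise ConfigError("fixed_exposures must have length T")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, T = config.n, config.T
    k = len(config.p_c)
    C = (rng.random((n, k)) < np.asarray(config.p_c)).astype(float) if k else np.zeros((n, 0))
    needs_u = config.u_strength != 0.0 or config.u_y != 0.0
    U = rng.standard_normal(n) if needs_u else np.zeros(n)

    cols: dict[str, np.ndarray] = {f"c{j + 1}": C[:, j] for j in range(k)}
    l_prev = np.zeros(n)
    x_prev = np.zeros(n)
    y_prev = np.zeros(n)
    for t in range(1, T + 1):
        lm = _l_mean(config, C, l_prev, x_prev, y_prev)
        if config.discrete:
            l = (rng.random(n) < _clip01(lm)).astype(float)
        else:
            l = lm + config.coef_l.sd * rng.standard_normal(n)
        pi = expit(_x_logit(config, C, l, x_prev, y_prev, U))
        if fixed_exposures is not None:
            x = np.full(n, float(fixed_exposures[t - 1]))
            rng.random(n)  # keep the draw stream aligned across policies
        else:
            p = shift(pi, delta) if delta is not None else pi
            x = (rng.random(n) < p).astype(float)
        ym = _y_mean(config, C, x, l, x_prev, y_prev, U)
        if config.discrete:
            y = (rng.random(n) < _clip01(ym)).astype(float)
        else:
            y = ym + config.coef_y.sd * rng.standard_normal(n)
        cols[f"l_{t}"] = l
        cols[f"x_{t}"] = x
        cols[f"y_{t}"] = y
        l_prev, x_prev, y_prev = l, x, y

    df = pd.DataFrame({"id": np.arange(1, n + 1), **cols})
    panel = PanelDataset(df, config.schema())
    if return_latent:
        return panel, U
    return panel


def _enumerate_truth(config: SyntheticConfig, delta: float, outcome_time: int) -> float:
    # exact path sum over (c, l_1, x_1, y_1, ..., l_s, x_s); E[Y_s | path] closes it
    k = len(config.p_c)
    total = 0.0
    C1 = np.ones(1)  # scalar helpers reuse the vectorized mean functions

    def c_weight(combo) -> float:
        w = 1.0
        for p, v in zip(config.p_c, combo):
            w *= p if v == 1 else 1.0 - p
        return w

    def rec(C_row, t, l_prev, x_prev, y_prev, w) -> float:
        if w == 0.0:
            return 0.0
        acc = 0.0
        lm = float(_clip01(_l_mean(config, C_row, np.array([l_prev]), np.array([x_prev]),
                                   np.array([y_prev])))[0])
        for l in (0.0, 1.0):
            wl = lm if l == 1.0 else 1.0 - lm
            if wl == 0.0:
                continue
            pi = float(expit(_x_logit(config, C_row, np.array([l]), np.array([x_prev]),
                                      np.array([y_prev]), np.zeros(1)))[0])
            q = shift(pi, delta)
            for x in (0.0, 1.0):
                wx = q if x == 1.0 else 1.0 - q
                if wx == 0.0:
                    continue
                ym = float(_clip01(_y_mean(config, C_row, np.array([x]), np.array([l]),
                                           np.array([x_prev]), np.array([y_prev]),
                                           np.zeros(1)))[0])
                if t == outcome_time:
                    acc += w * wl * wx * ym
                else:
                    for y in (0.0, 1.0):
                        wy = ym if y == 1.0 else 1.0 - ym
                        if wy == 0.0:
                            continue
                        acc += rec(C_row, t + 1, l, x, y, w * wl * wx * wy)
        return acc

    for combo in _iproduct((0, 1), repeat=k):
        C_row = np.asarray(combo, dtype=float).reshape(1, k)
        total += rec(C_row, 1, 0.0, 0.0, 0.0, c_weight(combo))
    return total


def true_ipsice(config: SyntheticConfig, delta: float, outcome_time: int,
                method: str = "enumerate", mc_size: int = 10 ** 5,
                seed: int = 0) -> TrueIpsice:
    """Structural truth E[Y_s] under the odds-shift intervention.

    ``enumerate`` is exact but needs a discrete config without a latent
    confounder and outcome_time <= 3; ``monte_carlo`` simulates ``mc_size``
    individuals with X_t drawn from the shifted structural propensity.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if not 1 <= outcome_time <= config.T:
        raise IndexError(f"outcome_time out of range 1..{config.T}")
    if method == "enumerate":
        if not config.discrete:
            raise UnsupportedMethodError("enumeration requires a discrete config; "
                                         "use method='monte_carlo'")
        if config.u_strength != 0.0 or config.u_y != 0.0:
            raise UnsupportedMethodError("enumeration does not support a latent confounder")
        if outcome_time > 3:
            raise UnsupportedMethodError("enumeration supports outcome_time <= 3")
        return TrueIpsice(_enumerate_truth(config, delta, outcome_time))
    if method == "monte_carlo":
        if mc_size < 1:
            raise ConfigError("mc_size must be >= 1")
        big = replace(config, n=mc_size)
        panel = generate_panel(big, seed=seed, delta=delta)
        y = panel.y(outcome_time)
        return TrueIpsice(float(np.mean(y)), float(np.std(y, ddof=1) / np.sqrt(len(y))))
    raise UnsupportedMethodError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# stock configurations
# ---------------------------------------------------------------------------

def default_config(n: int = 1000, T: int = 3, seed: int = 0,
                   u_strength: float = 0.0, exposure_effect: float = 0.3) -> SyntheticConfig:
    """Continuous cohort shaped like a stress/affect panel study: baseline
    binaries, one Gaussian stress-like covariate per wave, Gaussian outcomes.

    Coefficients are moderate on purpose: propensities stay away from 0/1 so
    the interaction-rich propensity model is well identified at n ~ 1000.
    """
    return SyntheticConfig(
        n=n, T=T, seed=seed,
        p_c=(0.5, 0.7),
        coef_l=LCoef(intercept=0.0, c=(0.1, -0.1),
                     l_prev=0.3, x_prev=0.25, y_prev=0.1, sd=0.8),
        coef_x=XCoef(intercept=-0.2, c=(0.2, 0.15),
                     l=0.3, x_prev=0.5, y_prev=0.15),
        coef_y=YCoef(intercept=1.5, x=exposure_effect, c=(0.05, 0.15),
                     l=0.2, x_prev=0.15, y_prev=0.35, x_l=0.0, sd=0.6),
        u_strength=u_strength,
    )


def discrete_config(n: int = 5000, T: int = 2, seed: int = 7,
                    u_strength: float = 0.0) -> SyntheticConfig:
    """Fully binary cohort with linear-probability L/Y equations kept inside
    (0, 1) over the whole path space, so enumeration is exact and the linear
    outcome system is correctly specified."""
    return SyntheticConfig(
        n=n, T=T, seed=seed,
        p_c=(0.5,),
        coef_l=LCoef(intercept=0.35, c=(0.15,), l_prev=0.15, x_prev=0.2, y_prev=0.1),
        coef_x=XCoef(intercept=-0.4, c=(0.4,), l=0.6, x_prev=0.8, y_prev=0.3),
        coef_y=YCoef(intercept=0.2, x=0.25, c=(0.1,), l=0.15, x_prev=0.1, y_prev=0.1),
        u_strength=u_strength, discrete=True,
    )
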