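"""Intervention-mean estimation over a grid of odds-shift parameters.

Three routes to the same estimand (the average outcome at a wave when every
individual's exposure odds are multiplied by ``delta`` at all waves up to it):

* ``ipw`` — inverse-probability weighting with per-wave weight ratios from the
  fitted propensities; Hajek-normalized by default.
* ``gformula`` — plug-in simulation: propagate each individual's baseline
  covariates through the fitted covariate/outcome equations with exposures
  drawn from the shifted propensities.
* ``enumerate`` — exact path sum over discrete covariate/outcome supports with
  fitted probabilities substituted; no Monte-Carlo error.

Curves add nonparametric-bootstrap percentile intervals (models refitted in
every replicate) and flag shift values whose interval does not overlap the
observed-regime (delta = 1) interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .outcomes import (OutcomeSystemFit, OutcomeSystemSpec, default_system_spec,
                       fit_outcome_system)
from .panel import PanelDataset, TemporalOrdering
from .propensity import (DegenerateExposureError, DeltaGrid, PropensityFit,
                         default_delta_grid, fit_propensity, shift)
from .synthetic import UnsupportedMethodError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IpsiceEstimate:
    delta: float
    outcome_time: int
    estimate: float
    se: float | None
    method: str
    mc_size: int | None = None


@dataclass
class IpsiceCurve:
    """Per-delta estimates for one outcome wave, with bootstrap intervals."""

    outcome_time: int
    grid: DeltaGrid
    estimates: list[IpsiceEstimate]
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    reference_mean: float
    reference_ci: tuple[float, float] | None
    flagged: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, est in enumerate(self.estimates):
            rows.append({
                "outcome_time": self.outcome_time,
                "delta": est.delta,
                "estimate": est.estimate,
                "se": est.se if est.se is not None else np.nan,
                "ci_low": self.ci_low[i] if self.ci_low is not None else np.nan,
                "ci_high": self.ci_high[i] if self.ci_high is not None else np.nan,
                "flagged": bool(self.flagged[i]),
                "method": self.method,
                "reference_mean": self.reference_mean,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IPW
# ---------------------------------------------------------------------------

def ipw_weights(panel: PanelDataset, ps_fits: Sequence[PropensityFit], delta: float,
                outcome_time: int, weight_cap: float | None = None) -> np.ndarray:
    """Cumulative-product intervention weights through ``outcome_time``."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    if delta == 1.0:
        return np.ones(panel.n)
    fits = {f.t: f for f in ps_fits}
    w = np.ones(panel.n)
    for t in range(1, outcome_time + 1):
        if t not in fits:
            raise ValueError(f"no propensity fit for wave {t}")
        x = panel.x(t)
        pi = fits[t].fitted_pi
        w *= (delta * x + (1.0 - x)) / (delta * pi + (1.0 - pi))
    if weight_cap is not None:
        w = np.minimum(w, weight_cap)
    return w


def estimate_ipw(panel: PanelDataset, ps_fits: Sequence[PropensityFit], delta: float,
                 outcome_time: int, normalization: str = "hajek",
                 weight_cap: float | None = None) -> IpsiceEstimate:
    """Weighted mean of the wave-``outcome_time`` outcome under the shift.

    Hajek (ratio) normalization makes the delta=1 estimate equal the plain
    sample mean exactly; Horvitz-Thompson divides by n instead.
    """
    y = panel.y(outcome_time)
    w = ipw_weights(panel, ps_fits, delta, outcome_time, weight_cap=weight_cap)
    n = len(y)
    if normalization == "hajek":
        est = float(np.sum(w * y) / np.sum(w))
        infl = w * (y - est) / np.mean(w)
        se = float(np.sqrt(np.sum(infl ** 2)) / n)
    elif normalization == "horvitz_thompson":
        est = float(np.mean(w * y))
        se = float(np.std(w * y, ddof=1) / np.sqrt(n))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return IpsiceEstimate(delta, outcome_time, est, se, "ipw")


# ---------------------------------------------------------------------------
# g-formula simulation
# ---------------------------------------------------------------------------

def _simulate_forward(panel: PanelDataset, system_fit: OutcomeSystemFit,
                      ps_fits: Mapping[int, PropensityFit], delta: float,
                      outcome_time: int, mc_size: int, rng: np.random.Generator,
                      ) -> np.ndarray:
    """Simulate ``mc_size`` trajectories (baseline rows cycled from the panel)."""
    schema = panel.schema
    ordering = system_fit.spec.ordering
    idx = np.arange(mc_size) % panel.n
    values: dict[str, np.ndarray] = {c: panel.column(c)[idx] for c in schema.C}

    def draw_from(eq_name: str) -> np.ndarray:
        eq = system_fit.equations[eq_name]
        lp = eq.linpred(values, n=mc_size)
        if eq.binary_response:
            return (rng.random(mc_size) < np.clip(lp, 0.0, 1.0)).astype(float)
        return lp + eq.resid_sd * rng.standard_normal(mc_size)

    def draw_exposure(t: int) -> np.ndarray:
        pi = ps_fits[t].predict(values, n=mc_size)
        q = shift(pi, delta)
        return (rng.random(mc_size) < q).astype(float)

    for t in range(1, outcome_time + 1):
        for lcol in schema.L[t]:
            values[lcol] = draw_from(lcol)
        if ordering is TemporalOrdering.EXPOSURE_FIRST:
            values[schema.X[t]] = draw_exposure(t)
            values[schema.Y[t]] = draw_from(schema.Y[t])
        else:
            values[schema.Y[t]] = draw_from(schema.Y[t])
            values[schema.X[t]] = draw_exposure(t)
    return values[schema.Y[outcome_time]]


def estimate_gformula(panel: PanelDataset, system_fit: OutcomeSystemFit,
                      ps_fits: Sequence[PropensityFit], delta: float,
                      outcome_time: int, mc_size: int = 100_000,
                      seed: int | np.random.SeedSequence = 0) -> IpsiceEstimate:
    """Plug-in simulation estimate with Monte-Carlo standard error.

    ``mc_size`` is the total number of simulated trajectories; baseline
    covariate rows are cycled from the observed panel so their empirical
    distribution is preserved.  Trajectories are independent, so the reported
    SE is the plain standard error of the simulated outcome mean.
    """
    if mc_size < 1:
        raise ValueError("mc_size must be >= 1")
    if delta <= 0:
        raise ValueError("delta must be positive")
    fits = {f.t: f for f in ps_fits}
    rng = np.random.default_rng(seed)
    y_sim = _simulate_forward(panel, system_fit, fits, delta, outcome_time, mc_size, rng)
    est = float(np.mean(y_sim))
    se = float(np.std(y_sim, ddof=1) / np.sqrt(mc_size)) if mc_size > 1 else None
    return IpsiceEstimate(delta, outcome_time, est, se, "gformula", mc_size=mc_size)


# ---------------------------------------------------------------------------
# exact enumeration with fitted models
# ---------------------------------------------------------------------------

def _check_discrete(panel: PanelDataset, outcome_time: int) -> None:
    schema = panel.schema
    cols: list[str] = []
    for t in range(1, outcome_time + 1):
        cols.extend(schema.L[t])
        if t < outcome_time:
            cols.append(schema.Y[t])
    for c in cols:
        v = panel.column(c)
        if not np.isin(v, (0.0, 1.0)).all():
            raise UnsupportedMethodError(
                f"column {c!r} is not binary; exact enumeration needs discrete "
                f"supports — use estimate_gformula instead")


def estimate_enumeration(panel: PanelDataset, system_fit: OutcomeSystemFit,
                         ps_fits: Sequence[PropensityFit], delta: float,
                         outcome_time: int) -> IpsiceEstimate:
    """Exact path sum of the identification formula with fitted models.

    Requires binary covariate/outcome supports through ``outcome_time``;
    linear-probability means are clipped to [0, 1].  Averages over the
    observed baseline covariate rows.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if outcome_time > 3:
        raise UnsupportedMethodError("enumeration supports outcome_time <= 3")
    _check_discrete(panel, outcome_time)
    schema = panel.schema
    ordering = system_fit.spec.ordering
    fits = {f.t: f for f in ps_fits}
    n = panel.n
    base = {c: panel.column(c) for c in schema.C}

    def prob_one(eq_name: str, values: dict[str, np.ndarray]) -> np.ndarray:
        lp = system_fit.equations[eq_name].linpred(values, n=n)
        return np.clip(lp, 0.0, 1.0)

    total = np.zeros(n)

    def recurse(t: int, values: dict[str, np.ndarray], w: np.ndarray) -> None:
        nonlocal total
        lcols = schema.L[t]
        if len(lcols) != 1:
            raise UnsupportedMethodError("enumeration supports one L column per wave")
        lcol = lcols[0]
        p_l = prob_one(lcol, values)
        for lval in (0.0, 1.0):
            wl = w * (p_l if lval == 1.0 else 1.0 - p_l)
            vals_l = {**values, lcol: np.full(n, lval)}
            if ordering is TemporalOrdering.EXPOSURE_FIRST:
                pi = fits[t].predict(vals_l, n=n)
                q = shift(pi, delta)
                for xval in (0.0, 1.0):
                    wx = wl * (q if xval == 1.0 else 1.0 - q)
                    vals_x = {**vals_l, schema.X[t]: np.full(n, xval)}
                    if t == outcome_time:
                        ey = system_fit.equations[schema.Y[t]].linpred(vals_x, n=n)
                        total = total + wx * np.clip(ey, 0.0, 1.0)
                    else:
                        p_y = prob_one(schema.Y[t], vals_x)
                        for yval in (0.0, 1.0):
                            wy = wx * (p_y if yval == 1.0 else 1.0 - p_y)
                            recurse(t + 1, {**vals_x, schema.Y[t]: np.full(n, yval)}, wy)
            else:  # outcome before exposure within the wave
                if t == outcome_time:
                    ey = system_fit.equations[schema.Y[t]].linpred(vals_l, n=n)
                    total = total + wl * np.clip(ey, 0.0, 1.0)
                else:
                    p_y = prob_one(schema.Y[t], vals_l)
                    for yval in (0.0, 1.0):
                        wy = wl * (p_y if yval == 1.0 else 1.0 - p_y)
                        vals_y = {**vals_l, schema.Y[t]: np.full(n, yval)}
                        pi = fits[t].predict(vals_y, n=n)
                        q = shift(pi, delta)
                        for xval in (0.0, 1.0):
                            wx = wy * (q if xval == 1.0 else 1.0 - q)
                            recurse(t + 1, {**vals_y, schema.X[t]: np.full(n, xval)}, wx)

    recurse(1, dict(base), np.ones(n))
    return IpsiceEstimate(delta, outcome_time, float(np.mean(total)), None, "enumerate")


# ---------------------------------------------------------------------------
# curves with bootstrap intervals
# ---------------------------------------------------------------------------

def _point_estimates(panel: PanelDataset, grid: DeltaGrid, outcome_times: Sequence[int],
                     method: str, ordering: TemporalOrdering,
                     system_spec: OutcomeSystemSpec | None, mc_size: int,
                     normalization: str, seed_tuple: tuple[int, ...],
                     ) -> dict[tuple[int, float], IpsiceEstimate]:
    max_t = max(outcome_times)
    ps_fits = [fit_propensity(panel, t, ordering) for t in range(1, max_t + 1)]
    system_fit = None
    if method in ("gformula", "enumerate"):
        spec = system_spec or default_system_spec(panel.schema, ordering)
        system_fit = fit_outcome_system(panel, spec)
    out: dict[tuple[int, float], IpsiceEstimate] = {}
    for si, s in enumerate(outcome_times):
        for di, d in enumerate(grid):
            if method == "ipw":
                out[(s, d)] = estimate_ipw(panel, ps_fits, d, s, normalization=normalization)
            elif method == "gformula":
                ss = np.random.SeedSequence(seed_tuple + (si, di))
                out[(s, d)] = estimate_gformula(panel, system_fit, ps_fits, d, s,
                                                mc_size=mc_size, seed=ss)
            elif method == "enumerate":
                out[(s, d)] = estimate_enumeration(panel, system_fit, ps_fits, d, s)
            else:
                raise ValueError(f"unknown method {method!r}")
    return out


def ipsice_curve(panel: PanelDataset, grid: DeltaGrid | None = None,
                 outcome_times: Sequence[int] | None = None, method: str = "gformula",
                 B: int = 500, seed: int = 0, mc_size: int = 1000,
                 ordering: TemporalOrdering = TemporalOrdering.EXPOSURE_FIRST,
                 system_spec: OutcomeSystemSpec | None = None,
                 normalization: str = "hajek",
                 ci_level: float = 0.95) -> list[IpsiceCurve]:
    """Estimate curves over the shift grid, one per outcome wave.

    With ``B > 0``, percentile bootstrap intervals resample individuals with
    replacement and refit all models inside each replicate (seeded
    deterministic substreams).  Each curve carries the observed-regime
    reference (delta = 1 sample mean and its bootstrap CI) and flags deltas
    whose CI does not overlap the reference CI.
    """
    if B < 0:
        raise ValueError("B must be >= 0")
    grid = grid or default_delta_grid()
    ordering = TemporalOrdering(ordering)
    outcome_times = list(outcome_times) if outcome_times else list(range(1, panel.T + 1))

    points = _point_estimates(panel, grid, outcome_times, method, ordering,
                              system_spec, mc_size, normalization, (seed, 0))

    boot: dict[tuple[int, float], list[float]] = {(s, d): [] for s in outcome_times for d in grid}
    boot_ref: dict[int, list[float]] = {s: [] for s in outcome_times}
    if B > 0:
        n = panel.n
        for b in range(1, B + 1):
            rng_b = np.random.default_rng(np.random.SeedSequence((seed, 1, b)))
            sub = None
            for _attempt in range(100):
                idx = rng_b.integers(0, n, n)
                sub = panel.subset(idx)
                try:
                    reps = _point_estimates(sub, grid, outcome_times, method, ordering,
                                            system_spec, mc_size, normalization,
                                            (seed, 2, b))
                    break
                except DegenerateExposureError:
                    continue
            else:
                raise RuntimeError("bootstrap could not draw a non-degenerate resample")
            for key, est in reps.items():
                boot[key].append(est.estimate)
            for s in outcome_times:
                boot_ref[s].append(float(np.mean(sub.y(s))))

    alpha = (1.0 - ci_level) / 2.0
    curves: list[IpsiceCurve] = []
    for s in outcome_times:
        ests = [points[(s, d)] for d in grid]
        ref_mean = float(np.mean(panel.y(s)))
        if B > 0:
            lo = np.array([np.percentile(boot[(s, d)], 100 * alpha) for d in grid])
            hi = np.array([np.percentile(boot[(s, d)], 100 * (1 - alpha)) for d in grid])
            ref_ci = (float(np.percentile(boot_ref[s], 100 * alpha)),
                      float(np.percentile(boot_ref[s], 100 * (1 - alpha))))
            flagged = (hi < ref_ci[0]) | (lo > ref_ci[1])
        else:
            lo = hi = None
            ref_ci = None
            flagged = np.zeros(len(grid), dtype=bool)
        curves.append(IpsiceCurve(outcome_time=s, grid=grid, estimates=ests,
                                  ci_low=lo, ci_high=hi, reference_mean=ref_mean,
                                  reference_ci=ref_ci, flagged=flagged, method=method))
    return curves


def curves_to_frame(curves: Sequence[IpsiceCurve]) -> pd.DataFrame:
    return pd.concat([c.to_frame() for c in curves], ignore_index=True)


# ---------------------------------------------------------------------------
# sensitivity sweep over fixed residual correlations
# ---------------------------------------------------------------------------

DEFAULT_RHO_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def sensitivity_sweep(panel: PanelDataset, rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
                      grid: DeltaGrid | None = None,
                      outcome_times: Sequence[int] | None = None,
                      B: int = 0, seed: int = 0, mc_size: int = 1000,
                      ordering: TemporalOrdering = TemporalOrdering.EXPOSURE_FIRST,
                      equality_constraints: Sequence[Sequence[tuple[str, str]]] = (),
                      ) -> pd.DataFrame:
    """Recompute the g-formula curve under each fixed residual correlation.

    For each rho, every (exposure wave s, outcome wave t >= s) residual
    correlation is fixed at rho in the jointly fitted system; rho = 0
    reproduces the unconstrained analysis exactly (same seed, same draws).
    """
    grid = grid or default_delta_grid()
    ordering = TemporalOrdering(ordering)
    outcome_times = list(outcome_times) if outcome_times else list(range(1, panel.T + 1))
    schema = panel.schema
    frames = []
    for rho in rho_grid:
        if not -1.0 < rho < 1.0:
            raise ValueError(f"rho={rho} outside (-1, 1)")
        pairs = [(s, t, float(rho)) for s in range(1, schema.T + 1)
                 for t in range(s, schema.T + 1)]
        spec = default_system_spec(schema, ordering,
                                   equality_constraints=equality_constraints,
                                   fixed_residual_correlations=pairs)
        curves = ipsice_curve(panel, grid=grid, outcome_times=outcome_times,
                              method="gformula", B=B, seed=seed, mc_size=mc_size,
                              ordering=ordering, system_spec=spec)
        df = curves_to_frame(curves)
        df.insert(0, "rho", rho)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
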