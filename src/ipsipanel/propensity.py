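"""Per-wave propensity models and the incremental odds-shift intervention.

The shift maps a propensity ``pi`` to ``delta*pi / (1 + (delta-1)*pi)``, i.e.
it multiplies the odds of exposure by ``delta``.  Propensity models are
logistic with main effects and all pairwise interactions of the history
columns; a small ridge penalty is engaged automatically on separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product as _iproduct
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import LinearDesign, main_effects, pairwise_interactions
from .panel import PanelDataset, TemporalOrdering, build_history

logger = logging.getLogger(__name__)

RIDGE_FALLBACK = 1e-4  # on the standardized design; engaged only on separation


class DegenerateExposureError(ValueError):
    """The exposure at some wave has a single observed class."""


# ---------------------------------------------------------------------------
# the odds shift
# ---------------------------------------------------------------------------

def shift(pi, delta: float):
    """Shift propensity ``pi`` so its odds are multiplied by ``delta``.

    Vectorized; preserves the boundary values 0 and 1 for every ``delta``.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    pi = np.asarray(pi, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must lie in [0, 1]")
    out = delta * pi / (1.0 + (delta - 1.0) * pi)
    out = np.where(pi == 0.0, 0.0, np.where(pi == 1.0, 1.0, out))
    return float(out) if out.ndim == 0 else out


def implied_delta(q, pi):
    """Odds ratio odds(q)/odds(pi); the inverse of :func:`shift` in delta."""
    q = np.asarray(q, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any((q <= 0) | (q >= 1)) or np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("q and pi must lie strictly inside (0, 1)")
    out = (q / (1.0 - q)) / (pi / (1.0 - pi))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DeltaGrid:
    """Strictly increasing grid of positive shift parameters."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0 or np.any(v <= 0):
            raise ValueError("delta grid must contain positive values")
        if np.any(np.diff(v) <= 0):
            raise ValueError("delta grid must be strictly increasing")

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def default_delta_grid() -> DeltaGrid:
    """The dyadic grid {2^k : k = -9..9} (19 values, symmetric about 1)."""
    return DeltaGrid(tuple(2.0 ** k for k in range(-9, 10)))


# ---------------------------------------------------------------------------
# propensity model
# ---------------------------------------------------------------------------

def propensity_terms(history_columns: Sequence[str]) -> list[tuple[str, ...]]:
    """Main effects plus all pairwise interactions, deterministically ordered."""
    cols = sorted(history_columns)
    return main_effects(cols) + pairwise_interactions(cols)


@dataclass
class PropensityFit:
    """Fitted logistic propensity model for one wave."""

    t: int
    design: LinearDesign
    coef: np.ndarray
    se: np.ndarray
    fitted_pi: np.ndarray
    regularization: float = 0.0
    converged: bool = True
    history_columns: tuple[str, ...] = ()

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.design.term_names, self.coef.tolist()))

    def predict(self, values: Mapping[str, np.ndarray], n: int | None = None) -> np.ndarray:
        """Propensities for (possibly simulated) column values."""
        X = self.design.matrix(values, n=n)
        return expit(X @ self.coef)


def _logistic_irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                   max_iter: int = 100, tol: float = 1e-10):
    """Newton/IRLS logistic fit with an optional ridge penalty.

    The penalty applies in the standardized column space (intercept exempt),
    so `ridge` is scale-free.  Returns (coef, se, converged).
    """
    n, p = X.shape
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    pen = np.zeros(p)
    if ridge > 0:
        pen = ridge * scale ** 2  # beta_std = beta*scale -> penalty ridge*(beta*scale)^2
        pen[np.all(X == X[0, :], axis=0)] = 0.0  # constant cols (intercept) exempt
        if np.ptp(X[:, 0]) == 0:
            pen[0] = 0.0
    beta = np.zeros(p)
    converged = False
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = (X * w[:, None]).T @ X + np.diag(pen + 1e-12)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving on the penalized log-likelihood
        def pll(b):
            e = X @ b
            return float(np.sum(y * e - np.logaddexp(0.0, e)) - 0.5 * np.sum(pen * b * b))
        lam = 1.0
        ll_new = pll(beta + step)
        while not np.isfinite(ll_new) or ll_new < pll(beta):
            lam *= 0.5
            if lam < 1e-8:
                break
            ll_new = pll(beta + lam * step)
        beta = beta + lam * step
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll_new
    mu = expit(X @ beta)
    w = mu * (1 - mu)
    H = (X * w[:, None]).T @ X + np.diag(pen + 1e-12)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, converged


def fit_propensity(panel: PanelDataset, t: int,
                   ordering: TemporalOrdering = TemporalOrdering.EXPOSURE_FIRST,
                   ridge: float = 0.0) -> PropensityFit:
    """ML logistic fit of X_t on main effects + pairwise interactions of H_t.

    On separation or non-convergence the fit is repeated with a small ridge
    penalty (recorded in ``regularization``) so fitted probabilities stay
    inside (0, 1).
    """
    hist = build_history(panel, t, ordering)
    y = panel.x(t)
    if len(np.unique(y)) < 2:
        raise DegenerateExposureError(f"exposure at wave {t} is constant")
    values = panel.columns_dict()
    design = LinearDesign(propensity_terms(hist.columns)).prune(values, n=panel.n)
    X = design.matrix(values, n=panel.n)

    coef, se, converged = _logistic_irls(X, y, ridge=ridge)
    used_ridge = ridge
    eta = X @ coef
    separated = (not converged) or np.max(np.abs(eta)) > 15.0
    if separated and ridge == 0.0:
        logger.warning("wave %d propensity fit looks separated/non-converged; "
                       "refitting with ridge %.0e", t, RIDGE_FALLBACK)
        coef, se, converged = _logistic_irls(X, y, ridge=RIDGE_FALLBACK)
        used_ridge = RIDGE_FALLBACK
    fitted = expit(X @ coef)
    fitted = np.clip(fitted, 1e-12, 1 - 1e-12)
    return PropensityFit(t=t, design=design, coef=coef, se=se, fitted_pi=fitted,
                         regularization=used_ridge, converged=converged,
                         history_columns=hist.columns)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def summarize_shifted(panel: PanelDataset, fits: Sequence[PropensityFit],
                      grid: DeltaGrid | None = None,
                      threshold: float = 0.05) -> pd.DataFrame:
    """Distribution summaries of the shifted propensities per (wave, delta).

    Columns: t, delta, mean_q, p10, p90 (the symmetric 80% interval) and the
    fraction of individuals with shifted propensity above ``threshold``.
    """
    grid = grid or default_delta_grid()
    rows = []
    for fit in fits:
        pi = fit.fitted_pi
        for d in grid:
            q = shift(pi, d)
            rows.append({
                "t": fit.t, "delta": d, "mean_q": float(np.mean(q)),
                "p10": float(np.percentile(q, 10)),
                "p90": float(np.percentile(q, 90)),
                "frac_above": float(np.mean(q > threshold)),
            })
    return pd.DataFrame(rows)


def overlap_diagnostics(panel: PanelDataset, fit: PropensityFit, t: int) -> pd.DataFrame:
    """Fitted-propensity quartiles by past-exposure stratum and current group.

    One row per (stratum of X_1..X_{t-1}, current X_t group): five-number
    summary of fitted propensities, cell proportion of the sample, and a flag
    set when the two groups' interquartile ranges in that stratum do not
    overlap (or one group is empty while the other is not).
    """
    if t < 2:
        raise ValueError("overlap diagnostics require t >= 2")
    past = [panel.x(u) for u in range(1, t)]
    cur = panel.x(t)
    pi = fit.fitted_pi
    rows = []
    strata = list(_iproduct((0, 1), repeat=t - 1))
    for combo in strata:
        mask = np.ones(panel.n, dtype=bool)
        for u, v in enumerate(combo):
            mask &= past[u] == v
        label = ",".join(f"x{u + 1}={v}" for u, v in enumerate(combo))
        for g in (0, 1):
            cell = mask & (cur == g)
            k = int(cell.sum())
            if k == 0:
                rows.append({"stratum": label, "group": g, "n": 0, "prop": 0.0,
                             "min": np.nan, "q1": np.nan, "median": np.nan,
                             "q3": np.nan, "max": np.nan})
                continue
            v = pi[cell]
            q1, med, q3 = np.percentile(v, (25, 50, 75))
            rows.append({"stratum": label, "group": g, "n": k,
                         "prop": k / panel.n,
                         "min": float(v.min()), "q1": float(q1),
                         "median": float(med), "q3": float(q3),
                         "max": float(v.max())})
    df = pd.DataFrame(rows)
    flags = []
    for combo in strata:
        label = ",".join(f"x{u + 1}={v}" for u, v in enumerate(combo))
        sub = df[df["stratum"] == label]
        g0 = sub[sub["group"] == 0].iloc[0]
        g1 = sub[sub["group"] == 1].iloc[0]
        present = (g0["n"] > 0, g1["n"] > 0)
        if not any(present):
            flag = False  # wholly empty stratum: reported, not flagged
        elif not all(present):
            flag = True
        else:
            flag = (g0["q3"] < g1["q1"]) or (g1["q3"] < g0["q1"])
        flags.append((label, flag))
    flag_map = dict(flags)
    df["no_overlap"] = df["stratum"].map(flag_map)
    if df["no_overlap"].any():
        bad = sorted({s for s, f in flags if f})
        logger.warning("wave %d: interquartile non-overlap in stratum(s): %s", t, bad)
    return df
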