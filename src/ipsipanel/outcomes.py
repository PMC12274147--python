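"""Jointly fitted linear system for time-varying covariates and outcomes.

The system is recursive: each covariate L_t and outcome Y_t is regressed on
everything causally preceding it.  Without constraints the joint Gaussian ML
factorizes, so equations are fitted by ordinary least squares.  Cross-time
equality constraints on coefficients and *fixed* exposure-outcome residual
correlations (the unmeasured-confounding sensitivity parameter) require joint
ML, implemented as iterated feasible GLS on the stacked system with a
structured residual covariance: free standard deviations around a fully fixed
correlation pattern (identity plus the user-fixed entries).  Exposure
indicators enter the residual block as numeric (linear-probability) variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import LinearDesign, Term, main_effects, term_name
from .panel import (PanelDataset, PanelSchema, SchemaError, TemporalOrdering,
                    history_columns)

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


class ConstraintError(ValueError):
    """Fixed residual-correlation pattern is infeasible (non-PSD)."""


class NonConvergenceError(RuntimeError):
    def __init__(self, msg: str, loglik: float | None = None, delta_ll: float | None = None):
        super().__init__(msg)
        self.loglik = loglik
        self.delta_ll = delta_ll


class DesignError(KeyError):
    """A prediction row is missing a term the fitted design requires."""


@dataclass(frozen=True)
class EquationSpec:
    name: str                  # response column
    role: str                  # "l" | "y" | "x"
    wave: int
    terms: tuple[Term, ...]


@dataclass(frozen=True)
class OutcomeSystemSpec:
    """Equations, equality constraints, and fixed residual correlations.

    ``equality_constraints`` is a tuple of groups; each group is a tuple of
    ``(equation_name, term_name)`` pairs whose coefficients are tied.
    ``fixed_residual_correlations`` is a tuple of ``(s, t, rho)`` fixing the
    correlation between the X_s and Y_t residuals at ``rho``.
    """

    T: int
    ordering: TemporalOrdering
    equations: tuple[EquationSpec, ...]
    equality_constraints: tuple[tuple[tuple[str, str], ...], ...] = ()
    fixed_residual_correlations: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        names = [e.name for e in self.equations]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate equation names in system spec")
        for s, t, rho in self.fixed_residual_correlations:
            if not -1.0 < rho < 1.0:
                raise ConstraintError(f"fixed correlation rho={rho} outside (-1, 1)")
            if t < s:
                raise ConstraintError(
                    f"outcome wave {t} is not downstream of exposure wave {s}")

    @property
    def needs_joint(self) -> bool:
        return bool(self.equality_constraints) or bool(self.fixed_residual_correlations)

    def equation(self, name: str) -> EquationSpec:
        for e in self.equations:
            if e.name == name:
                return e
        raise KeyError(name)


def _y_equation_terms(schema: PanelSchema, t: int, ordering: TemporalOrdering) -> list[Term]:
    """Main effects of everything preceding Y_t plus, for each exposure in that
    set, its pairwise interactions with the remaining predictors."""
    pred: list[str] = list(schema.C)
    for u in range(1, t):
        pred.extend(schema.L[u])
        if ordering is TemporalOrdering.EXPOSURE_FIRST:
            pred.extend([schema.X[u], schema.Y[u]])
        else:
            pred.extend([schema.Y[u], schema.X[u]])
    pred.extend(schema.L[t])
    if ordering is TemporalOrdering.EXPOSURE_FIRST:
        pred.append(schema.X[t])
    pred = sorted(pred)
    exposures = [schema.X[u] for u in range(1, t + 1) if schema.X[u] in pred]
    terms: list[Term] = main_effects(pred)
    for xs in exposures:
        for other in pred:
            if other != xs:
                terms.append(tuple(sorted((xs, other))))
    return terms


def _l_equation_terms(schema: PanelSchema, t: int, ordering: TemporalOrdering) -> list[Term]:
    pred: list[str] = list(schema.C)
    for u in range(1, t):
        pred.extend(schema.L[u])
        pred.extend([schema.X[u], schema.Y[u]])
    return main_effects(sorted(pred))


def _x_equation_terms(schema: PanelSchema, s: int, ordering: TemporalOrdering) -> list[Term]:
    return main_effects(sorted(history_columns(schema, s, ordering)))


def default_system_spec(schema: PanelSchema,
                        ordering: TemporalOrdering = TemporalOrdering.EXPOSURE_FIRST,
                        equality_constraints: Sequence[Sequence[tuple[str, str]]] = (),
                        fixed_residual_correlations: Sequence[tuple[int, int, float]] = (),
                        ) -> OutcomeSystemSpec:
    """Standard system: one equation per L column and per Y, in causal order.

    Exposure (linear-probability) equations are added only for waves that
    participate in a fixed residual correlation.
    """
    ordering = TemporalOrdering(ordering)
    fixed = tuple((int(s), int(t), float(r)) for s, t, r in fixed_residual_correlations)
    x_waves = sorted({s for s, _, _ in fixed})
    eqs: list[EquationSpec] = []
    for t in range(1, schema.T + 1):
        for lcol in schema.L[t]:
            eqs.append(EquationSpec(lcol, "l", t, tuple(_l_equation_terms(schema, t, ordering))))
        y_eq = EquationSpec(schema.Y[t], "y", t, tuple(_y_equation_terms(schema, t, ordering)))
        x_eq = (EquationSpec(schema.X[t], "x", t, tuple(_x_equation_terms(schema, t, ordering)))
                if t in x_waves else None)
        if ordering is TemporalOrdering.EXPOSURE_FIRST:
            if x_eq is not None:
                eqs.append(x_eq)
            eqs.append(y_eq)
        else:
            eqs.append(y_eq)
            if x_eq is not None:
                eqs.append(x_eq)
    return OutcomeSystemSpec(T=schema.T, ordering=ordering, equations=tuple(eqs),
                             equality_constraints=tuple(tuple(g) for g in equality_constraints),
                             fixed_residual_correlations=fixed)


@dataclass
class EquationFit:
    name: str
    role: str
    wave: int
    design: LinearDesign
    coef: np.ndarray
    se: np.ndarray
    resid_sd: float
    binary_response: bool

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.design.term_names, self.coef.tolist()))

    @property
    def standard_errors(self) -> dict[str, float]:
        return dict(zip(self.design.term_names, self.se.tolist()))

    def linpred(self, values: Mapping[str, np.ndarray], n: int | None = None) -> np.ndarray:
        try:
            X = self.design.matrix(values, n=n)
        except KeyError as exc:
            raise DesignError(f"equation {self.name!r} requires column {exc.args[0]}") from exc
        return X @ self.coef


@dataclass
class OutcomeSystemFit:
    spec: OutcomeSystemSpec
    equations: dict[str, EquationFit]
    order: tuple[str, ...]              # equation names in causal order
    residual_correlation: np.ndarray    # fixed pattern R actually used
    loglik: float
    method: str                         # per_equation_ls | joint_ml
    converged: bool = True
    n_iter: int = 0

    @property
    def residual_sds(self) -> dict[str, float]:
        return {name: self.equations[name].resid_sd for name in self.order}

    def residual_correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.residual_correlation, index=self.order, columns=self.order)

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for name in self.order:
            eq = self.equations[name]
            for term, est, se in zip(eq.design.term_names, eq.coef, eq.se):
                rows.append({"equation": name, "term": term,
                             "estimate": float(est), "se": float(se)})
        return pd.DataFrame(rows)


def _is_binary(v: np.ndarray) -> bool:
    return bool(np.isin(v, (0.0, 1.0)).all())


def _gaussian_loglik(resid: np.ndarray, sd: float) -> float:
    n = len(resid)
    return float(-0.5 * n * (_LOG2PI + 2.0 * np.log(sd)) - 0.5 * np.sum(resid ** 2) / sd ** 2)


def _build_R(order: Sequence[str], spec: OutcomeSystemSpec, schema: PanelSchema) -> np.ndarray:
    m = len(order)
    R = np.eye(m)
    idx = {name: j for j, name in enumerate(order)}
    for s, t, rho in spec.fixed_residual_correlations:
        xs, yt = schema.X[s], schema.Y[t]
        if xs not in idx or yt not in idx:
            raise SchemaError(f"fixed correlation references missing equation ({xs}, {yt})")
        R[idx[xs], idx[yt]] = R[idx[yt], idx[xs]] = rho
    w = np.linalg.eigvalsh(R)
    if w.min() <= 1e-10:
        bad = [(s, t, r) for s, t, r in spec.fixed_residual_correlations]
        raise ConstraintError(
            f"fixed residual-correlation pattern is not positive definite "
            f"(min eigenvalue {w.min():.2e}); offending entries: {bad}")
    return R


def fit_outcome_system(panel: PanelDataset, spec: OutcomeSystemSpec | None = None,
                       method: str = "auto", max_iter: int = 500,
                       tol: float = 1e-10) -> OutcomeSystemFit:
    """Fit all L/Y (and, if referenced, X) equations.

    Unconstrained systems factorize and are fitted per equation by least
    squares; equality constraints or fixed residual correlations trigger joint
    Gaussian ML via iterated GLS.  An all-zero fixed-correlation pattern
    decouples and reproduces the least-squares coefficients bit-for-bit.
    """
    schema = panel.schema
    if spec is None:
        spec = default_system_spec(schema)
    values = panel.columns_dict()
    n = panel.n

    order = tuple(e.name for e in spec.equations)
    designs: dict[str, LinearDesign] = {}
    X_mats: dict[str, np.ndarray] = {}
    y_vecs: dict[str, np.ndarray] = {}
    for eq in spec.equations:
        d = LinearDesign(list(eq.terms)).prune(values, n=n)
        designs[eq.name] = d
        X_mats[eq.name] = d.matrix(values, n=n)
        y_vecs[eq.name] = np.asarray(values[eq.name], dtype=float)

    for group in spec.equality_constraints:
        for eq_name, tname in group:
            if eq_name not in designs:
                raise SchemaError(f"constraint references unknown equation {eq_name!r}")
            if tname not in designs[eq_name].term_names:
                raise SchemaError(
                    f"constraint references term {tname!r} absent from equation {eq_name!r}")

    R = _build_R(order, spec, schema)
    want_joint = spec.needs_joint or method == "joint_ml"
    if method == "per_equation_ls":
        want_joint = False
        if spec.needs_joint:
            raise ValueError("spec has constraints/fixed correlations; per-equation LS invalid")

    decoupled = (not spec.equality_constraints) and np.array_equal(R, np.eye(len(order)))

    if not want_joint or decoupled:
        fits: dict[str, EquationFit] = {}
        loglik = 0.0
        for eq in spec.equations:
            X, v = X_mats[eq.name], y_vecs[eq.name]
            coef, *_ = np.linalg.lstsq(X, v, rcond=None)
            resid = v - X @ coef
            sd = float(np.sqrt(np.sum(resid ** 2) / n))
            sd = max(sd, 1e-12)
            try:
                cov = np.linalg.inv(X.T @ X) * (np.sum(resid ** 2) / max(n - X.shape[1], 1))
                se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
            except np.linalg.LinAlgError:
                se = np.full(X.shape[1], np.nan)
            loglik += _gaussian_loglik(resid, sd)
            fits[eq.name] = EquationFit(eq.name, eq.role, eq.wave, designs[eq.name],
                                        coef, se, sd, _is_binary(v))
        return OutcomeSystemFit(spec=spec, equations=fits, order=order,
                                residual_correlation=R, loglik=loglik,
                                method="joint_ml" if want_joint else "per_equation_ls")

    return _fit_joint_ml(panel, spec, order, designs, X_mats, y_vecs, R,
                         max_iter=max_iter, tol=tol)


def _fit_joint_ml(panel, spec, order, designs, X_mats, y_vecs, R, max_iter, tol):
    n = panel.n
    m = len(order)
    p_sizes = [X_mats[name].shape[1] for name in order]
    offsets = np.concatenate([[0], np.cumsum(p_sizes)])
    P = int(offsets[-1])

    # parameter-tying map: column j of T selects the free parameter each
    # stacked coefficient equals
    tie = np.arange(P)
    for group in spec.equality_constraints:
        idxs = []
        for eq_name, tname in group:
            j = order.index(eq_name)
            k = designs[eq_name].term_names.index(tname)
            idxs.append(offsets[j] + k)
        root = min(tie[i] for i in idxs)
        for i in idxs:
            tie[np.flatnonzero(tie == tie[i])] = root
    uniq, inv = np.unique(tie, return_inverse=True)
    q = len(uniq)
    Tmat = np.zeros((P, q))
    Tmat[np.arange(P), inv] = 1.0

    Rinv = np.linalg.inv(R)
    logdetR = float(np.linalg.slogdet(R)[1])

    # precompute cross-moment blocks
    XtX = {}
    Xty = {}
    for j, nj in enumerate(order):
        for k, nk in enumerate(order):
            XtX[(j, k)] = X_mats[nj].T @ X_mats[nk]
            Xty[(j, k)] = X_mats[nj].T @ y_vecs[nk]

    # initialize from per-equation OLS
    beta = np.zeros(P)
    d = np.zeros(m)
    for j, name in enumerate(order):
        X, v = X_mats[name], y_vecs[name]
        b, *_ = np.linalg.lstsq(X, v, rcond=None)
        beta[offsets[j]:offsets[j + 1]] = b
        d[j] = max(float(np.sqrt(np.mean((v - X @ b) ** 2))), 1e-8)

    def residual_matrix(beta_vec):
        E = np.empty((n, m))
        for j, name in enumerate(order):
            b = beta_vec[offsets[j]:offsets[j + 1]]
            E[:, j] = y_vecs[name] - X_mats[name] @ b
        return E

    def loglik_of(S, dvec):
        Dinv = 1.0 / dvec
        trace = float(np.sum(Rinv * (S * np.outer(Dinv, Dinv))))
        logdet = logdetR + 2.0 * float(np.sum(np.log(dvec)))
        return -0.5 * n * (m * _LOG2PI + logdet + trace)

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # GLS step for beta given Sigma
        Dinv = 1.0 / d
        W = Rinv * np.outer(Dinv, Dinv)  # Sigma^{-1}
        A = np.zeros((P, P))
        bvec = np.zeros(P)
        for j in range(m):
            sl_j = slice(offsets[j], offsets[j + 1])
            for k in range(m):
                if W[j, k] == 0.0:
                    continue
                A[sl_j, offsets[k]:offsets[k + 1]] += W[j, k] * XtX[(j, k)]
                bvec[sl_j] += W[j, k] * Xty[(j, k)]
        At = Tmat.T @ A @ Tmat
        bt = Tmat.T @ bvec
        theta = np.linalg.solve(At, bt)
        beta = Tmat @ theta

        # Sigma step: free sds around the fixed correlation pattern
        E = residual_matrix(beta)
        S = (E.T @ E) / n

        def neg_profile(logd):
            dd = np.exp(logd)
            Minv = Rinv * (S / np.outer(dd, dd))
            val = 2.0 * np.sum(logd) + float(np.sum(Minv))
            grad = 2.0 - 2.0 * Minv.sum(axis=1)
            return val, grad

        res = minimize(neg_profile, np.log(d), jac=True, method="L-BFGS-B")
        d = np.exp(res.x)

        ll = loglik_of(S, d)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    if not converged:
        raise NonConvergenceError(
            f"joint ML did not converge in {max_iter} iterations", loglik=ll_old)

    # standard errors from the GLS information at the solution
    cov_theta = np.linalg.inv(At)
    se_full = np.sqrt(np.clip(np.diag(Tmat @ cov_theta @ Tmat.T), 0, np.inf))

    fits: dict[str, EquationFit] = {}
    for j, name in enumerate(order):
        eq = spec.equation(name)
        sl = slice(offsets[j], offsets[j + 1])
        fits[name] = EquationFit(name, eq.role, eq.wave, designs[name],
                                 beta[sl].copy(), se_full[sl].copy(), float(d[j]),
                                 _is_binary(y_vecs[name]))
    return OutcomeSystemFit(spec=spec, equations=fits, order=order,
                            residual_correlation=R, loglik=float(ll_old),
                            method="joint_ml", converged=True, n_iter=it)


def predict_outcome(fit: OutcomeSystemFit, t: int, row: Mapping[str, float],
                    schema: PanelSchema | None = None) -> float:
    """Linear predictor of the wave-t outcome equation at one covariate row.

    The row must provide a value for every column the fitted design uses
    (including the exposure value whose effect is being probed).
    """
    name = None
    for eq_name, eq in fit.equations.items():
        if eq.role == "y" and eq.wave == t:
            name = eq_name
            break
    if name is None:
        raise KeyError(f"no outcome equation for wave {t}")
    values = {k: np.atleast_1d(float(v)) for k, v in row.items()}
    return float(fit.equations[name].linpred(values, n=1)[0])
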