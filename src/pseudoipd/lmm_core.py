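"""ML/REML estimation for linear mixed models on (pseudo) participant data.

Three effect structures are supported —

* ``FF``: fixed study-specific intercepts + common fixed treatment effect
* ``FR``: fixed study-specific intercepts + random treatment effects
* ``RR``: random intercepts + random treatment effects (2x2 G, unstructured
  by default)

— crossed with four residual-variance structures (``FREE`` = one variance
per study-arm, ``STUDY`` = per study, ``ARM`` = per arm, ``POOLED`` = one
overall).  Likelihoods are exact Gaussian marginal (ML) or restricted (REML)
log-likelihoods with all constants, so the reported -2LL values are directly
comparable across software.

Two independent evaluation routes exist: the fit path works on the raw
participant-level response (Woodbury identities on the per-study covariance
``V_i = Z_i G Z_i' + R_i``), while :func:`loglik_from_sufficient_stats`
evaluates the same quantity from per-arm (mean, sd, n) only, via the
factorisation of the Gaussian likelihood into within-arm deviations and the
bivariate distribution of the two arm means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .aggregate_data import AggregateDataset
from .pseudo_ipd import PseudoIPD

__all__ = [
    "EFFECT_STRUCTURES",
    "RESIDUAL_STRUCTURES",
    "LMMSpec",
    "LMMParams",
    "LMMFit",
    "DomainError",
    "SingularModelError",
    "ConvergenceError",
    "fit_lmm",
    "m2loglik_ipd",
    "loglik_from_sufficient_stats",
    "lrt_compare",
    "model_grid",
    "n_fixed_effects",
    "n_variance_parameters",
]

EFFECT_STRUCTURES = ("FF", "FR", "RR")
RESIDUAL_STRUCTURES = ("FREE", "STUDY", "ARM", "POOLED")

_BOUNDARY_TOL = 1e-8
_VAR_FLOOR = 1e-12


class DomainError(ValueError):
    """A parameter value outside its domain (e.g. negative variance)."""


class SingularModelError(ValueError):
    """The requested model is singular for these data (e.g. zero-sd arm)."""


class ConvergenceError(RuntimeError):
    """Optimizer failed after all restarts; carries the trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class LMMSpec:
    """Model configuration: effects x residual structure x estimation."""

    effects: str = "FR"
    residual: str = "FREE"
    estimation: str = "REML"
    df_method: str = "containment"
    rr_unstructured: bool = True   # RR only: fit the intercept/slope covariance
    max_iter: int = 500
    rel_tol: float = 1e-10
    n_starts: int = 3

    def __post_init__(self) -> None:
        if self.effects not in EFFECT_STRUCTURES:
            raise ValueError(f"effects must be one of {EFFECT_STRUCTURES}")
        if self.residual not in RESIDUAL_STRUCTURES:
            raise ValueError(f"residual must be one of {RESIDUAL_STRUCTURES}")
        if self.estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")
        if self.df_method not in ("containment", "residual"):
            raise ValueError("df_method must be 'containment' or 'residual'")


def n_residual_parameters(residual: str, m: int) -> int:
    return {"FREE": 2 * m, "STUDY": m, "ARM": 2, "POOLED": 1}[residual]


def n_variance_parameters(spec: LMMSpec, m: int) -> int:
    extra = {"FF": 0, "FR": 1, "RR": 3 if spec.rr_unstructured else 2}
    return n_residual_parameters(spec.residual, m) + extra[spec.effects]


def n_fixed_effects(effects: str, m: int) -> int:
    return 2 if effects == "RR" else m + 1


@dataclass(frozen=True)
class LMMParams:
    """Explicit parameter values for likelihood evaluation.

    ``beta`` is the fixed-effects vector in design order (study intercepts
    then treatment for FF/FR; overall intercept then treatment for RR); it is
    ignored by REML evaluation, where the fixed effects are integrated out.
    ``residual_variances`` has one entry per residual parameter of the
    structure.  ``tau1_sq`` is used for FR; ``G`` (2x2 PSD) for RR.
    """

    beta: np.ndarray | None
    residual_variances: np.ndarray
    tau1_sq: float | None = None
    G: np.ndarray | None = None


@dataclass(frozen=True)
class LMMFit:
    spec: LMMSpec
    beta1_hat: float
    se_beta1: float
    ci: tuple[float, float]
    df: float
    tau1_sq: float | None
    tau0_sq: float | None
    tau01: float | None
    residual_variances: Mapping[tuple[str, int], float]
    m2loglik_ml: float
    m2loglik_reml: float
    aic_ml: float
    aic_reml: float
    n_fe: int
    n_re: int
    converged: bool
    boundary: bool
    n_obs: int
    m: int
    beta: np.ndarray = field(repr=False, default=None)
    n_iter: int = 0


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def _residual_index(spec: LMMSpec, study_idx: int, arm: int, m: int) -> int:
    if spec.residual == "FREE":
        return 2 * study_idx + arm
    if spec.residual == "STUDY":
        return study_idx
    if spec.residual == "ARM":
        return arm
    return 0


class _IPDModel:
    """Per-study design matrices built from raw participant rows."""

    def __init__(self, pipd: PseudoIPD, spec: LMMSpec):
        self.spec = spec
        df = pipd.to_frame()
        self.study_ids = list(dict.fromkeys(df["study_id"]))
        self.m = len(self.study_ids)
        self.p = n_fixed_effects(spec.effects, self.m)
        self.q = {"FF": 0, "FR": 1, "RR": 2}[spec.effects]
        self.studies = []
        n_total = 0
        for i, sid in enumerate(self.study_ids):
            grp = df[df["study_id"] == sid]
            y = grp["y"].to_numpy(dtype=float)
            x = grp["arm"].to_numpy(dtype=float)
            n = len(y)
            n_total += n
            X = np.zeros((n, self.p))
            if spec.effects == "RR":
                X[:, 0] = 1.0
            else:
                X[:, i] = 1.0
            X[:, -1] = x
            if spec.effects == "FF":
                Z = np.zeros((n, 0))
            elif spec.effects == "FR":
                Z = x[:, None]
            else:
                Z = np.column_stack([np.ones(n), x])
            ridx = np.array(
                [_residual_index(spec, i, int(a), self.m) for a in x], dtype=int
            )
            self.studies.append((sid, y, X, Z, ridx))
        self.N = n_total
        self.k_res = n_residual_parameters(spec.residual, self.m)

    # -- likelihood -------------------------------------------------------

    def m2ll(
        self,
        res_var: np.ndarray,
        G: np.ndarray | None,
        estimation: str,
        beta: np.ndarray | None = None,
        want_grad: bool = False,
        dG: Sequence[np.ndarray] | None = None,
    ):
        """-2 log-likelihood (and optionally its gradient).

        With ``beta=None`` the fixed effects are profiled by GLS (for ML this
        is the ML maximiser at fixed variances; for REML beta never enters).
        The gradient is taken with respect to the *raw* residual variances
        followed by the G parameters whose derivative matrices are ``dG``.
        """
        if np.any(res_var <= 0) or not np.all(np.isfinite(res_var)):
            raise DomainError("residual variances must be positive and finite")
        L = None
        if G is not None and self.q:
            G = np.atleast_2d(np.asarray(G, dtype=float))
            try:
                L = np.linalg.cholesky(G)
            except np.linalg.LinAlgError:
                w, Q = np.linalg.eigh(G)
                if np.any(w < -1e-10 * max(1.0, w.max(initial=0.0))):
                    raise DomainError("G must be positive semidefinite")
                L = Q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        yViy = 0.0
        logdet = 0.0
        cache = []
        for sid, y, X, Z, ridx in self.studies:
            r = res_var[ridx]
            rinv = 1.0 / r
            if L is None or L.size == 0:
                logdet += np.log(r).sum()
                Viy = rinv * y
                ViX = rinv[:, None] * X
                dii = rinv
                K = W = None
            else:
                U = Z @ L
                W = U * rinv[:, None]
                A = np.eye(U.shape[1]) + U.T @ W
                sign, ldA = np.linalg.slogdet(A)
                if sign <= 0:
                    raise DomainError("indefinite covariance encountered")
                logdet += np.log(r).sum() + ldA
                K = np.linalg.inv(A)
                Viy = rinv * y - W @ (K @ (W.T @ y))
                ViX = rinv[:, None] * X - W @ (K @ (W.T @ X))
                dii = rinv - np.einsum("ij,jk,ik->i", W, K, W)
            XtViX += X.T @ ViX
            XtViy += X.T @ Viy
            yViy += y @ Viy
            cache.append((y, X, Z, ridx, rinv, W, K, Viy, ViX, dii))

        sign, ld_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise SingularModelError("singular fixed-effects information")
        C = np.linalg.inv(XtViX)
        beta_gls = C @ XtViy

        if beta is None:
            b = beta_gls
            quad = yViy - b @ XtViy
        else:
            b = np.asarray(beta, dtype=float)
            quad = yViy - 2.0 * b @ XtViy + b @ XtViX @ b

        if estimation == "ML":
            val = self.N * np.log(2 * np.pi) + logdet + quad
        else:
            val = ((self.N - self.p) * np.log(2 * np.pi)
                   + logdet + ld_xvx + quad)

        if not want_grad:
            return val, beta_gls, C

        # gradient wrt raw residual variances + G parameters
        reml = estimation == "REML"
        n_g = len(dG) if dG else 0
        grad = np.zeros(self.k_res + n_g)
        for (y, X, Z, ridx, rinv, W, K, Viy, ViX, dii) in cache:
            rres = Viy - ViX @ beta_gls          # V^{-1} (y - X beta)
            for g in np.unique(ridx):
                mask = ridx == g
                term = dii[mask].sum() - (rres[mask] ** 2).sum()
                if reml:
                    Xg = ViX[mask]
                    term -= np.einsum("ij,jk,ik->", Xg, C, Xg)
                grad[g] += term * res_var[g]
            if n_g:
                ViZ = rinv[:, None] * Z
                if W is not None:
                    ViZ = ViZ - W @ (K @ (W.T @ Z))
                S = Z.T @ ViZ                      # Z' V^{-1} Z
                u = Z.T @ rres                     # Z' V^{-1} (y - X beta)
                T = Z.T @ ViX                      # Z' V^{-1} X
                for k, Gd in enumerate(dG):
                    term = np.trace(Gd @ S) - u @ Gd @ u
                    if reml:
                        term -= np.trace(Gd @ (T @ C @ T.T))
                    grad[self.k_res + k] += term
        return val, beta_gls, C, grad


# --------------------------------------------------------------------------
# optimisation parameterisation
# --------------------------------------------------------------------------

def _unpack_theta(theta: np.ndarray, spec: LMMSpec, k_res: int):
    """theta -> (residual variances, G or None, dG list for the chain rule)."""
    res_var = np.exp(theta[:k_res])
    if spec.effects == "FF":
        return res_var, None, []
    if spec.effects == "FR":
        t1 = np.exp(theta[k_res])
        return res_var, np.array([[t1]]), [np.array([[t1]])]
    if spec.rr_unstructured:
        l00 = np.exp(theta[k_res])
        l10 = theta[k_res + 1]
        l11 = np.exp(theta[k_res + 2])
        Lm = np.array([[l00, 0.0], [l10, l11]])
        G = Lm @ Lm.T
        dG = []
        for dL in (np.array([[l00, 0.0], [0.0, 0.0]]),
                   np.array([[0.0, 0.0], [1.0, 0.0]]),
                   np.array([[0.0, 0.0], [0.0, l11]])):
            dG.append(dL @ Lm.T + Lm @ dL.T)
        return res_var, G, dG
    g0, g1 = np.exp(theta[k_res]), np.exp(theta[k_res + 1])
    G = np.diag([g0, g1])
    return res_var, G, [np.diag([g0, 0.0]), np.diag([0.0, g1])]


def _start_values(model: _IPDModel, spec: LMMSpec) -> list[np.ndarray]:
    """Moment-based starting points (plus rescaled variants for restarts)."""
    m = model.m
    ss = np.zeros(model.k_res)
    cnt = np.zeros(model.k_res)
    study_means = []
    study_diffs = []
    diff_vars = []
    for sid, y, X, Z, ridx in model.studies:
        arm = X[:, -1]
        mdiff = None
        means = {}
        for g in np.unique(ridx):
            mask = ridx == g
            # SS within each arm present in this residual group
            for a in (0.0, 1.0):
                am = mask & (arm == a)
                if am.sum() >= 1:
                    ss[g] += ((y[am] - y[am].mean()) ** 2).sum()
                    cnt[g] += am.sum() - 1
        y0, y1 = y[arm == 0], y[arm == 1]
        if len(y0) and len(y1):
            study_diffs.append(y1.mean() - y0.mean())
            dv = 0.0
            if len(y0) > 1:
                dv += y0.var(ddof=1) / len(y0)
            if len(y1) > 1:
                dv += y1.var(ddof=1) / len(y1)
            diff_vars.append(dv)
        study_means.append(y.mean())
    cnt = np.maximum(cnt, 1.0)
    res0 = np.maximum(ss / cnt, _VAR_FLOOR)
    if np.any(ss <= 0):
        bad = int(np.argmin(ss))
        raise SingularModelError(
            f"residual group {bad} has zero within-arm variation; the "
            f"{spec.residual} structure is singular for these data"
        )
    base = np.log(res0)

    extras = []
    if spec.effects in ("FR", "RR"):
        d = np.asarray(study_diffs)
        v = np.asarray(diff_vars)
        # crude DL-style moment start for the slope variance
        w = 1.0 / np.maximum(v, 1e-12)
        if len(d) >= 2:
            mu = (w * d).sum() / w.sum()
            q = (w * (d - mu) ** 2).sum()
            denom = w.sum() - (w ** 2).sum() / w.sum()
            tau1 = max((q - (len(d) - 1)) / max(denom, 1e-12), 0.0)
        else:
            tau1 = 0.0
        tau1 = max(tau1, 0.05 * float(np.mean(res0)))
        if spec.effects == "FR":
            extras = [np.log(tau1)]
        else:
            tau0 = max(np.var(study_means, ddof=1) if m > 1 else 1.0,
                       0.05 * float(np.mean(res0)))
            if spec.rr_unstructured:
                extras = [0.5 * np.log(tau0), 0.0, 0.5 * np.log(tau1)]
            else:
                extras = [np.log(tau0), np.log(tau1)]

    t0 = np.concatenate([base, extras])
    starts = [t0]
    if extras:
        for scale in (np.log(0.1), np.log(10.0)):
            t = t0.copy()
            t[model.k_res:] = t0[model.k_res:] + scale
            if spec.effects == "RR" and spec.rr_unstructured:
                t[model.k_res + 1] = 0.0
                t[model.k_res] = t0[model.k_res] + 0.5 * scale
                t[model.k_res + 2] = t0[model.k_res + 2] + 0.5 * scale
            starts.append(t)
    else:
        starts.append(t0 + np.log(2.0))
        starts.append(t0 - np.log(2.0))
    return starts


def _optimize(model: _IPDModel, spec: LMMSpec, estimation: str):
    k_res = model.k_res
    n_par = k_res + {"FF": 0, "FR": 1,
                     "RR": 3 if spec.rr_unstructured else 2}[spec.effects]

    def objective(theta):
        res_var, G, dG = _unpack_theta(theta, spec, k_res)
        try:
            val, _, _, grad = model.m2ll(res_var, G, estimation,
                                         want_grad=True, dG=dG)
        except (DomainError, SingularModelError, np.linalg.LinAlgError):
            return np.inf, np.zeros(n_par)
        # chain rule: residual entries already multiplied by sigma^2 inside
        return val, grad

    bounds = [(-34.0, 34.0)] * n_par
    if spec.effects == "RR" and spec.rr_unstructured:
        bounds[k_res + 1] = (-1e6, 1e6)

    trace = []
    best = None
    for start in _start_values(model, spec)[: spec.n_starts]:
        res = optimize.minimize(
            objective, start, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": spec.max_iter, "ftol": 1e-14, "gtol": 1e-8},
        )
        trace.append((estimation, res.fun, res.status, res.message,
                      res.nit))
        ok = np.isfinite(res.fun)
        if ok and (best is None or res.fun < best.fun - 1e-12):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(
            f"{estimation} optimisation failed for {spec.effects}x"
            f"{spec.residual}", trace)
    converged = bool(best.success)
    # Nelder-Mead polish for low-dimensional problems that stalled
    if n_par <= 8 and not converged:
        nm = optimize.minimize(
            lambda t: objective(t)[0], best.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if np.isfinite(nm.fun) and nm.fun <= best.fun:
            best = nm
            converged = True
    return best, converged, trace


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def fit_lmm(pipd: PseudoIPD, spec: LMMSpec,
            both_likelihoods: bool = True) -> LMMFit:
    """Fit one mixed model to participant-level data.

    Returns estimates under ``spec.estimation``; when ``both_likelihoods``
    the model is additionally optimised under the other estimation method so
    that both -2LL / AIC columns are populated (as in a full results table).
    """
    model = _IPDModel(pipd, spec)
    if model.m < 2 and spec.effects != "FF":
        raise ValueError("random-effects structures require at least 2 studies")
    if spec.effects == "RR" and model.m < 3:
        warnings.warn("RR structure with fewer than 3 studies is fragile",
                      stacklevel=2)

    best, converged, trace = _optimize(model, spec, spec.estimation)
    res_var, G, _ = _unpack_theta(best.x, spec, model.k_res)
    val, beta_gls, C = model.m2ll(res_var, G, spec.estimation)

    other = "ML" if spec.estimation == "REML" else "REML"
    if both_likelihoods:
        best_o, conv_o, _ = _optimize(model, spec, other)
        val_o = best_o.fun
        converged = converged and conv_o
    else:
        val_o = np.nan

    m2_ml = val if spec.estimation == "ML" else val_o
    m2_reml = val if spec.estimation == "REML" else val_o

    n_fe = n_fixed_effects(spec.effects, model.m)
    n_re = n_variance_parameters(spec, model.m)
    aic_ml = m2_ml + 2 * (n_fe + n_re)
    aic_reml = m2_reml + 2 * n_re

    beta1 = float(beta_gls[-1])
    se = float(np.sqrt(C[-1, -1]))
    if spec.df_method == "containment" and spec.effects in ("FR", "RR"):
        df = model.m - 1
    else:
        df = model.N - n_fe
    tq = stats.t.ppf(0.975, df)
    ci = (beta1 - tq * se, beta1 + tq * se)

    tau1_sq = tau0_sq = tau01 = None
    boundary = False
    if spec.effects == "FR":
        tau1_sq = float(G[0, 0])
        boundary = tau1_sq < _BOUNDARY_TOL
        if boundary:
            tau1_sq = 0.0
    elif spec.effects == "RR":
        tau0_sq, tau1_sq = float(G[0, 0]), float(G[1, 1])
        tau01 = float(G[1, 0]) if spec.rr_unstructured else 0.0
        boundary = min(tau0_sq, tau1_sq) < _BOUNDARY_TOL
        tau0_sq = 0.0 if tau0_sq < _BOUNDARY_TOL else tau0_sq
        tau1_sq = 0.0 if tau1_sq < _BOUNDARY_TOL else tau1_sq

    resid_map = {}
    for i, sid in enumerate(model.study_ids):
        for arm in (0, 1):
            resid_map[(sid, arm)] = float(
                res_var[_residual_index(spec, i, arm, model.m)])

    return LMMFit(
        spec=spec, beta1_hat=beta1, se_beta1=se, ci=ci, df=float(df),
        tau1_sq=tau1_sq, tau0_sq=tau0_sq, tau01=tau01,
        residual_variances=resid_map,
        m2loglik_ml=float(m2_ml), m2loglik_reml=float(m2_reml),
        aic_ml=float(aic_ml), aic_reml=float(aic_reml),
        n_fe=n_fe, n_re=n_re, converged=converged, boundary=boundary,
        n_obs=model.N, m=model.m, beta=beta_gls,
        n_iter=int(getattr(best, "nit", 0)),
    )


def _params_to_G(spec: LMMSpec, params: LMMParams) -> np.ndarray | None:
    if spec.effects == "FF":
        return None
    if spec.effects == "FR":
        if params.tau1_sq is None:
            raise DomainError("FR evaluation requires tau1_sq")
        if params.tau1_sq < 0:
            raise DomainError("tau1_sq must be >= 0")
        return np.array([[float(params.tau1_sq)]])
    if params.G is None:
        raise DomainError("RR evaluation requires G")
    G = np.asarray(params.G, dtype=float)
    if G.shape != (2, 2):
        raise DomainError("G must be 2x2")
    return G


def m2loglik_ipd(pipd: PseudoIPD, spec: LMMSpec, params: LMMParams) -> float:
    """-2 log-likelihood at explicit parameter values, participant-level path."""
    model = _IPDModel(pipd, spec)
    res_var = np.asarray(params.residual_variances, dtype=float)
    if len(res_var) != model.k_res:
        raise DomainError(
            f"expected {model.k_res} residual variances, got {len(res_var)}")
    if np.any(res_var < 0):
        raise DomainError("residual variances must be >= 0")
    G = _params_to_G(spec, params)
    beta = params.beta if spec.estimation == "ML" else None
    val, _, _ = model.m2ll(res_var, G, spec.estimation, beta=beta)
    return float(val)


def loglik_from_sufficient_stats(
    data: AggregateDataset, spec: LMMSpec, params: LMMParams
) -> float:
    """-2 log-likelihood from per-arm (mean, sd, n) only.

    Independent oracle for the participant-level path: the Gaussian
    likelihood factors into (a) the within-arm deviations, entering only
    through the corrected sums of squares (n-1)*sd^2, and (b) the bivariate
    normal distribution of the two arm means per study with covariance
    ``Zbar G Zbar' + diag(sigma^2 / n)``.
    """
    m = data.m
    k_res = n_residual_parameters(spec.residual, m)
    res_var = np.asarray(params.residual_variances, dtype=float)
    if len(res_var) != k_res:
        raise DomainError(f"expected {k_res} residual variances")
    if np.any(res_var < 0) or not np.all(np.isfinite(res_var)):
        raise DomainError("residual variances must be >= 0 and finite")
    G = _params_to_G(spec, params)

    p = n_fixed_effects(spec.effects, m)
    if spec.effects == "FR":
        Zbar = np.array([[0.0], [1.0]])
    elif spec.effects == "RR":
        Zbar = np.array([[1.0, 0.0], [1.0, 1.0]])
    else:
        Zbar = None

    N = data.n_total
    dev_term = 0.0
    logdet = 0.0
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    yViy = 0.0
    blocks = []
    for i, study in enumerate(data):
        sig = np.array([res_var[_residual_index(spec, i, j, m)]
                        for j in (0, 1)])
        if np.any(sig <= 0):
            raise DomainError("residual variances must be positive")
        ns = np.array([study.control.n, study.treated.n], dtype=float)
        ybar = np.array([study.control.mean, study.treated.mean])
        ssq = np.array([study.control.ss, study.treated.ss])
        dev_term += float(
            ((ns - 1) * np.log(sig)).sum() + np.log(ns).sum()
            + (ssq / sig).sum()
        )
        Vbar = np.diag(sig / ns)
        if Zbar is not None:
            Vbar = Vbar + Zbar @ G @ Zbar.T
        sign, ld = np.linalg.slogdet(Vbar)
        if sign <= 0:
            raise DomainError("arm-mean covariance not positive definite")
        logdet += ld
        Vinv = np.linalg.inv(Vbar)
        Xbar = np.zeros((2, p))
        if spec.effects == "RR":
            Xbar[:, 0] = 1.0
        else:
            Xbar[:, i] = 1.0
        Xbar[:, -1] = [0.0, 1.0]
        XtViX += Xbar.T @ Vinv @ Xbar
        XtViy += Xbar.T @ Vinv @ ybar
        yViy += ybar @ Vinv @ ybar
        blocks.append((Xbar, Vinv, ybar))

    if spec.estimation == "ML":
        if params.beta is None:
            beta = np.linalg.solve(XtViX, XtViy)
        else:
            beta = np.asarray(params.beta, dtype=float)
        quad = yViy - 2 * beta @ XtViy + beta @ XtViX @ beta
        return float(N * np.log(2 * np.pi) + dev_term + logdet + quad)

    sign, ld_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise SingularModelError("singular fixed-effects information")
    beta = np.linalg.solve(XtViX, XtViy)
    quad = yViy - beta @ XtViy
    return float((N - p) * np.log(2 * np.pi) + dev_term + logdet
                 + ld_xvx + quad)


def _fixed_part(effects: str) -> str:
    return "study_intercepts+treatment" if effects in ("FF", "FR") else \
        "intercept+treatment"


def lrt_compare(full: LMMFit, reduced: LMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a fuller one.

    Under REML only models sharing the same fixed part are comparable; the
    statistic is the difference of the -2 (restricted) log-likelihoods and
    the reference distribution chi-square with df equal to the difference in
    variance-parameter counts (plus fixed-effect counts under ML).
    """
    est_f, est_r = full.spec.estimation, reduced.spec.estimation
    if est_f != est_r:
        raise ValueError("both fits must use the same estimation method")
    if est_f == "REML" and _fixed_part(full.spec.effects) != _fixed_part(
            reduced.spec.effects):
        raise ValueError(
            "REML deviances are comparable only for models with the same "
            "fixed part; refit with ML to compare these models")
    if est_f == "REML":
        stat = reduced.m2loglik_reml - full.m2loglik_reml
        df = full.n_re - reduced.n_re
    else:
        stat = reduced.m2loglik_ml - full.m2loglik_ml
        df = (full.n_re + full.n_fe) - (reduced.n_re + reduced.n_fe)
    if df < 0:
        raise ValueError("reduced model has more parameters than full model")
    if df == 0:
        return float(stat), 0, 1.0 if abs(stat) < 1e-6 else float("nan")
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return float(stat), int(df), p


def model_grid(pipd: PseudoIPD, estimation: str = "REML",
               df_method: str = "containment") -> pd.DataFrame:
    """Fit all 3x4 effect x residual combinations; failures are annotated.

    Returns a data frame with one row per model and an ``object`` column
    ``fit`` carrying the :class:`LMMFit` (or None on failure).
    """
    if len(pipd) == 0:
        raise ValueError("empty dataset")
    rows = []
    for eff in EFFECT_STRUCTURES:
        for res in RESIDUAL_STRUCTURES:
            spec = LMMSpec(effects=eff, residual=res, estimation=estimation,
                           df_method=df_method)
            row = {"effects": eff, "residual": res}
            try:
                fit = fit_lmm(pipd, spec)
                row.update(
                    estimate=fit.beta1_hat, se=fit.se_beta1,
                    ci_low=fit.ci[0], ci_high=fit.ci[1],
                    aic_reml=fit.aic_reml, m2loglik_reml=fit.m2loglik_reml,
                    n_fe=fit.n_fe, n_re=fit.n_re,
                    aic_ml=fit.aic_ml, m2loglik_ml=fit.m2loglik_ml,
                    tau1_sq=fit.tau1_sq, converged=fit.converged,
                    boundary=fit.boundary, error="", fit=fit,
                )
            except Exception as exc:  # per-cell failures are not fatal
                row.update(estimate=np.nan, se=np.nan, ci_low=np.nan,
                           ci_high=np.nan, aic_reml=np.nan,
                           m2loglik_reml=np.nan, n_fe=np.nan, n_re=np.nan,
                           aic_ml=np.nan, m2loglik_ml=np.nan, tau1_sq=np.nan,
                           converged=False, boundary=False,
                           error=f"{type(exc).__name__}: {exc}", fit=None)
            rows.append(row)
    return pd.DataFrame(rows)
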