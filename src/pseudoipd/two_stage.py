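"""Two-stage aggregate-data random-effects meta-analysis comparators.

Stage one computes a mean difference and its variance per study; stage two
pools them under the normal-normal random-effects model with the
between-study variance estimated by the DerSimonian-Laird moment method or
by restricted maximum likelihood, optionally with the Hartung-Knapp
small-sample variance correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .aggregate_data import AggregateDataset

__all__ = [
    "StudyEffect",
    "TwoStageResult",
    "study_effects",
    "fit_dl",
    "fit_reml_meta",
]


@dataclass(frozen=True)
class StudyEffect:
    study_id: str
    d: float       # mean difference, treated - control
    var_d: float   # squared standard error of d

    def __post_init__(self) -> None:
        if not self.var_d > 0:
            raise ValueError(
                f"study {self.study_id!r}: var_d must be > 0, got {self.var_d}")


@dataclass(frozen=True)
class TwoStageResult:
    method: str               # "DL", "REML" or "REML_HK"
    mu_hat: float
    se: float
    ci: tuple[float, float]
    tau_sq: float
    k: int


def study_effects(data: AggregateDataset) -> list[StudyEffect]:
    """Per-study mean differences with variance sd1^2/n1 + sd0^2/n0."""
    out = []
    for s in data:
        d = s.treated.mean - s.control.mean
        v = s.treated.sd**2 / s.treated.n + s.control.sd**2 / s.control.n
        out.append(StudyEffect(s.study_id, float(d), float(v)))
    return out


def _pool(d: np.ndarray, v: np.ndarray, tau_sq: float):
    w = 1.0 / (v + tau_sq)
    mu = float((w * d).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return mu, se, w


def fit_dl(effects: Sequence[StudyEffect]) -> TwoStageResult:
    """DerSimonian-Laird moment estimator with a normal-quantile 95% CI."""
    k = len(effects)
    if k < 2:
        raise ValueError("need at least 2 studies to pool")
    d = np.array([e.d for e in effects])
    v = np.array([e.var_d for e in effects])
    w = 1.0 / v
    mu_fe = (w * d).sum() / w.sum()
    q = (w * (d - mu_fe) ** 2).sum()
    denom = w.sum() - (w**2).sum() / w.sum()
    tau_sq = max(0.0, (q - (k - 1)) / denom)
    mu, se, _ = _pool(d, v, tau_sq)
    z = stats.norm.ppf(0.975)
    return TwoStageResult("DL", mu, se, (mu - z * se, mu + z * se),
                          float(tau_sq), k)


def _reml_m2ll(tau_sq: float, d: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau_sq)
    mu = (w * d).sum() / w.sum()
    return float(np.log(v + tau_sq).sum() + np.log(w.sum())
                 + (w * (d - mu) ** 2).sum())


def fit_reml_meta(effects: Sequence[StudyEffect],
                  hk: bool = False,
                  max_iter: int = 100,
                  tol: float = 1e-10) -> TwoStageResult:
    """Random-effects pooling with tau^2 estimated by restricted ML.

    Fisher scoring on tau^2 starting from the DL estimate, floored at zero;
    a bounded golden-section fallback guards against a non-converging
    iteration.  Without ``hk`` the CI uses a t distribution with k-1 df on
    the usual inverse-variance standard error; with ``hk`` the
    Hartung-Knapp variance estimator replaces it (same t reference).
    """
    k = len(effects)
    if k < 2:
        raise ValueError("need at least 2 studies to pool")
    d = np.array([e.d for e in effects])
    v = np.array([e.var_d for e in effects])

    tau_sq = fit_dl(effects).tau_sq
    converged = False
    trace = []
    for _ in range(max_iter):
        w = 1.0 / (v + tau_sq)
        sw = w.sum()
        mu = (w * d).sum() / sw
        r2 = (d - mu) ** 2
        # restricted score and expected information in tau^2
        score = 0.5 * ((w**2 * r2).sum() - w.sum() + (w**2).sum() / sw)
        info = 0.5 * ((w**2).sum() - 2 * (w**3).sum() / sw
                      + ((w**2).sum() / sw) ** 2)
        if info <= 0:
            break
        step = score / info
        new = max(tau_sq + step, 0.0)
        trace.append((tau_sq, score))
        if abs(new - tau_sq) <= tol * (1.0 + tau_sq):
            tau_sq = new
            converged = True
            break
        tau_sq = new
    if not converged:
        upper = max(10.0 * (v.max() + d.var() + 1.0), 1.0)
        from scipy.optimize import minimize_scalar
        opt = minimize_scalar(_reml_m2ll, args=(d, v), bounds=(0.0, upper),
                              method="bounded",
                              options={"xatol": 1e-12})
        if not opt.success:
            raise RuntimeError(
                f"REML tau^2 iteration failed to converge; trace={trace[-5:]}")
        cand = float(opt.x)
        if _reml_m2ll(0.0, d, v) <= opt.fun:
            cand = 0.0
        tau_sq = cand

    mu, se, w = _pool(d, v, tau_sq)
    tq = stats.t.ppf(0.975, k - 1)
    if hk:
        hk_var = float((w * (d - mu) ** 2).sum() / ((k - 1) * w.sum()))
        se = np.sqrt(hk_var)
    return TwoStageResult(
        "REML_HK" if hk else "REML", mu, float(se),
        (mu - tq * se, mu + tq * se), float(tau_sq), k)
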