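"""Cox proportional-hazards fits and fixed-effect meta-analysis.

Per cohort, the log hazard is modelled as a linear function of a gene's
expression (per expression unit), optionally adjusted for debulking
surgery (optimal vs suboptimal residual tumour) and FIGO stage (three
levels encoded as two indicators).  The partial likelihood is maximized by
Newton-Raphson with step-halving, Breslow handling of tied event times
(Efron available behind a flag) and standard errors from the inverse
observed information.  Study-level expression coefficients are pooled
with inverse-variance fixed-effect weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

STAGE_LEVELS = ("I", "II", "III/IV")
DEBULKING_LEVELS = ("optimal", "suboptimal")
COVARIATES = ("expression", "debulking", "stage")

Z_95 = 1.959963984540054


@dataclass
class CoxFit:
    params: pd.Series  # coefficient per design column
    se: pd.Series
    n: int
    events: int
    loglik: float
    converged: bool
    n_iter: int
    target: str = "expression"

    @property
    def beta(self) -> float:
        return float(self.params[self.target])

    @property
    def se_beta(self) -> float:
        return float(self.se[self.target])

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - Z_95 * self.se_beta)),
            float(np.exp(self.beta + Z_95 * self.se_beta)),
        )


@dataclass
class MetaResult:
    beta: float
    se: float
    weights: pd.Series  # normalized inverse-variance weights, sum to 1
    z: float
    p: float

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - Z_95 * self.se)),
            float(np.exp(self.beta + Z_95 * self.se)),
        )


def build_design(
    cohort: pd.DataFrame, covariates: Sequence[str] = ("expression",)
) -> pd.DataFrame:
    """Expand requested covariates into a numeric design frame.

    ``debulking`` becomes an indicator for suboptimal surgery; ``stage``
    becomes indicators for II and III/IV against the level-I reference.
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "expression":
            cols["expression"] = cohort["expression"].to_numpy(dtype=float)
        elif cov == "debulking":
            cols["debulking_suboptimal"] = (
                cohort["debulking"].astype(str) == "suboptimal"
            ).to_numpy(dtype=float)
        elif cov == "stage":
            stage = cohort["stage"].astype(str)
            cols["stage_II"] = (stage == "II").to_numpy(dtype=float)
            cols["stage_III/IV"] = (stage == "III/IV").to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=cohort.index)


def cox_partial_loglik(
    beta: np.ndarray, times: np.ndarray, events: np.ndarray, X: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Breslow/Efron partial log-likelihood (used directly by the oracle tests)."""
    ll, _, _ = _loglik_grad_hess(beta, times, events, X, ties, need_derivs=False)
    return ll


def _loglik_grad_hess(beta, times, events, X, ties, need_derivs=True):
    order = np.argsort(-times, kind="stable")  # descending time
    t = times[order]
    d = events[order].astype(bool)
    Xo = X[order]
    eta = Xo @ beta
    w = np.exp(eta)
    p = beta.size

    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * Xo, axis=0)
    cum_wxx = np.cumsum(w[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    n = t.size
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        # risk set for time t[i] = indices 0..j (times >= t[i])
        ev = np.nonzero(d[i : j + 1])[0] + i
        if ev.size:
            S0 = cum_w[j]
            S1 = cum_wx[j]
            S2 = cum_wxx[j]
            m = ev.size
            sum_x = Xo[ev].sum(axis=0)
            if ties == "breslow" or m == 1:
                ll += eta[ev].sum() - m * np.log(S0)
                if need_derivs:
                    xbar = S1 / S0
                    grad += sum_x - m * xbar
                    hess += m * (S2 / S0 - np.outer(xbar, xbar))
            elif ties == "efron":
                wd = w[ev].sum()
                wdx = (w[ev, None] * Xo[ev]).sum(axis=0)
                wdxx = (w[ev, None, None] * (Xo[ev, :, None] * Xo[ev, None, :])).sum(
                    axis=0
                )
                ll += eta[ev].sum()
                if need_derivs:
                    grad += sum_x
                for r in range(m):
                    f = r / m
                    s0 = S0 - f * wd
                    ll -= np.log(s0)
                    if need_derivs:
                        s1 = S1 - f * wdx
                        s2 = S2 - f * wdxx
                        xbar = s1 / s0
                        grad -= xbar
                        hess += s2 / s0 - np.outer(xbar, xbar)
            else:
                raise ValueError(f"unknown tie method {ties!r}")
        i = j + 1
    return ll, grad, hess


class CoxConvergenceWarning(UserWarning):
    """Newton iterations did not converge (e.g. monotone likelihood)."""


def fit_cox(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("expression",),
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Maximize the Cox partial likelihood for one cohort.

    ``cohort`` needs columns ``time`` (>0), ``event`` (0/1) and the
    requested covariates.  Convergence is declared when the score norm
    falls below ``tol``; a monotone likelihood (perfect separation) leaves
    ``converged`` False after ``max_iter`` iterations with a warning.
    """
    times = cohort["time"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=int)
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    design = build_design(cohort, covariates)
    X = design.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        constant = [c for c in design.columns if design[c].std() == 0]
        raise ValueError(f"constant covariate(s): {constant}")
    X = X - X.mean(axis=0)  # centring improves conditioning; beta unchanged

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _loglik_grad_hess(beta, times, events, X, ties)
    # absolute score tolerance, relaxed by the rounding floor of the
    # score accumulation for large cohorts
    score_tol = max(tol, 1e-12 * len(times) * max(1.0, np.abs(X).max()))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) < score_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break  # singular information: monotone likelihood
        factor = 1.0
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(30):
                cand = beta + factor * step
                ll_new = cox_partial_loglik(cand, times, events, X, ties)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                factor /= 2.0
            new_beta = beta + factor * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(
                new_beta, times, events, X, ties
            )
        if not (np.isfinite(ll_new) and np.all(np.isfinite(grad_new))
                and np.all(np.isfinite(hess_new))):
            break  # diverging estimate: keep the last finite iterate
        ll_prev = ll
        beta, ll, grad, hess = new_beta, ll_new, grad_new, hess_new
        # secondary criterion for large cohorts, where the score's floating
        # point rounding floor can sit above the absolute tolerance
        if (abs(ll - ll_prev) < 1e-9 * (1.0 + abs(ll))
                and np.linalg.norm(grad) < 1e-4):
            converged = True
            break
    else:
        it = max_iter
    if not converged and np.linalg.norm(grad) < score_tol:
        converged = True
    if converged and np.abs(beta).max() > 10.0:
        # a log hazard beyond +-10 per (centred) covariate unit is the
        # signature of a monotone likelihood, not a finite optimum
        converged = False
    if not converged:
        warnings.warn(
            "Cox fit did not converge (possible monotone likelihood)",
            CoxConvergenceWarning,
            stacklevel=2,
        )
    try:
        se = np.sqrt(np.diag(np.linalg.inv(hess)))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
    target = design.columns[0]
    return CoxFit(
        params=pd.Series(beta, index=design.columns),
        se=pd.Series(se, index=design.columns),
        n=len(cohort),
        events=int(events.sum()),
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        target=str(target),
    )


def fixed_effect_meta(fits: Sequence[CoxFit]) -> MetaResult:
    """Inverse-variance fixed-effect pooling of study expression coefficients."""
    if not fits:
        raise ValueError("need at least one fit")
    betas = np.array([f.beta for f in fits])
    ses = np.array([f.se_beta for f in fits])
    if not np.all(np.isfinite(betas)) or not np.all(np.isfinite(ses)):
        raise ValueError("non-finite study estimates")
    if (ses <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    pooled_beta = float(np.sum(w * betas) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled_beta / pooled_se
    p = 2.0 * float(norm.sf(abs(z)))
    weights = pd.Series(w / w.sum(), index=[f"study_{i}" for i in range(len(fits))])
    return MetaResult(beta=pooled_beta, se=pooled_se, weights=weights, z=z, p=p)


def forest_table(meta: MetaResult, fits: Sequence[CoxFit],
                 names: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-study HR/CI/weight rows plus a flagged pooled row (weights in %)."""
    if names is None:
        names = [f"study_{i}" for i in range(len(fits))]
    rows = []
    for name, f, w in zip(names, fits, meta.weights):
        lo, hi = f.ci
        rows.append(
            {"study": name, "HR": f.hr, "ci_low": lo, "ci_high": hi,
             "weight_pct": 100.0 * float(w), "pooled": False}
        )
    lo, hi = meta.ci
    rows.append(
        {"study": "pooled", "HR": meta.hr, "ci_low": lo, "ci_high": hi,
         "weight_pct": 100.0, "pooled": True}
    )
    return pd.DataFrame(rows)


def meta_analyse_gene(
    survival: pd.DataFrame, covariates: Sequence[str] = ("expression",),
    ties: str = "breslow",
) -> tuple[MetaResult, list[CoxFit], pd.DataFrame]:
    """Fit each study in a stacked survival table and pool the results.

    ``survival`` needs a ``study`` column plus the per-patient fields.
    Returns the pooled result, the per-study fits, and the forest table.
    """
    fits = []
    names = []
    for study, grp in survival.groupby("study", sort=True):
        fits.append(fit_cox(grp, covariates=covariates, ties=ties))
        names.append(str(study))
    meta = fixed_effect_meta(fits)
    return meta, fits, forest_table(meta, fits, names)
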