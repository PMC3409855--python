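"""Cox proportional-hazards modelling, risk classification, and mediation comparison.

The Cox engine is implemented from the partial likelihood up: Newton–Raphson
maximisation with Efron or Breslow handling of tied event times, Wald
standard errors from the inverse observed information, and a Breslow
baseline cumulative hazard for covariate-adjusted survival curves.

Hazard ratios are ``exp(beta)`` per unit of the fitted covariate; a 95%
confidence interval is ``exp(beta ± 1.959964·SE)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RiskProfile",
    "CoxFit",
    "AttenuationSummary",
    "classify_risk",
    "dichotomize_cesd",
    "fit_cox",
    "hr_table",
    "adjusted_survival",
    "compare_mediation",
    "cohort_summary",
]

_Z95 = 1.959964

RISK_FACTOR_NAMES = (
    "karnofsky_lt80",
    "calcium_ge10",
    "low_hemoglobin",
    "high_ldh",
    "prior_radiation",
    "mets_ge2",
    "interval_le1yr",
)


@dataclass(frozen=True)
class RiskProfile:
    """The seven binary clinical risk factors used for risk-group staging."""

    karnofsky_lt80: bool = False
    calcium_ge10: bool = False
    low_hemoglobin: bool = False
    high_ldh: bool = False
    prior_radiation: bool = False
    mets_ge2: bool = False
    interval_le1yr: bool = False

    def count(self) -> int:
        return sum(int(getattr(self, f)) for f in RISK_FACTOR_NAMES)


def classify_risk(profile: RiskProfile | int) -> str:
    """Map a risk-factor profile (or a raw count) to low/intermediate/high.

    0–1 factors → ``"low"``, exactly 2 → ``"intermediate"``, 3 or more →
    ``"high"``.
    """
    n = profile.count() if isinstance(profile, RiskProfile) else int(profile)
    if n < 0:
        raise ValueError(f"risk factor count must be >= 0, got {n}")
    if n <= 1:
        return "low"
    if n == 2:
        return "intermediate"
    return "high"


def dichotomize_cesd(score: float) -> int:
    """1 if the CES-D total meets the depressive-symptom screening cutoff (>=16)."""
    if score < 0:
        raise ValueError(f"CES-D score must be >= 0, got {score}")
    return int(score >= 16)


@dataclass
class CoxFit:
    """A fitted proportional-hazards model."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    ties: str
    converged: bool
    n: int
    n_events: int
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n_iter: int
    message: str = ""
    cov: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)


def _prepare(time, event, X):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(time <= 0):
        raise ValueError("all survival times must be > 0")
    if not event.any():
        raise ValueError("at least one event is required to fit a Cox model")
    order = np.argsort(time, kind="stable")
    return time[order], event[order], X[order]


def _partial_loglik(beta, time, event, X, ties):
    """Log partial likelihood with gradient and (negative) Hessian.

    Inputs must be sorted ascending by time. Risk set at an event time t is
    every subject with time >= t (censored at t included).
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard overflow; partial likelihood invariant to shifts
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])
    # suffix (risk-set) sums
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))  # observed information (neg Hessian of ll)
    ev_times = time[event]
    uniq = np.unique(ev_times)
    if uniq.size == ev_times.size:
        # no tied event times: Efron and Breslow coincide; fully vectorised
        idx = np.searchsorted(time, ev_times, side="left")
        s0 = S0[idx]
        s1 = S1[idx]
        s2 = S2[idx]
        ll = float(eta[event].sum() - np.log(s0).sum())
        mean1 = s1 / s0[:, None]
        grad = X[event].sum(axis=0) - mean1.sum(axis=0)
        info = (s2 / s0[:, None, None]).sum(axis=0) - np.einsum(
            "ki,kj->ij", mean1, mean1
        )
        return ll, grad, info
    for t in uniq:
        i0 = np.searchsorted(time, t, side="left")
        D = np.flatnonzero(event & (time == t))
        d = len(D)
        ll += eta[D].sum()
        if ties == "breslow" or d == 1:
            denom = S0[i0]
            z1 = S1[i0]
            z2 = S2[i0]
            ll -= d * np.log(denom)
            grad += X[D].sum(axis=0) - d * z1 / denom
            info += d * (z2 / denom - np.outer(z1, z1) / denom**2)
        else:  # Efron
            wD = w[D].sum()
            s1D = wx[D].sum(axis=0)
            s2D = wxx[D].sum(axis=0)
            frac = np.arange(d) / d
            denom = S0[i0] - frac * wD                       # (d,)
            z1 = S1[i0][None, :] - frac[:, None] * s1D       # (d,p)
            z2 = S2[i0][None, :, :] - frac[:, None, None] * s2D
            ll -= np.log(denom).sum()
            grad += X[D].sum(axis=0) - (z1 / denom[:, None]).sum(axis=0)
            info += (z2 / denom[:, None, None]).sum(axis=0)
            info -= np.einsum("li,lj,l->ij", z1, z1, 1.0 / denom**2)
    return ll, grad, info


def fit_cox(
    time,
    event,
    X,
    names: list[str] | None = None,
    ties: str = "efron",
    max_iter: int = 60,
    tol: float = 1e-8,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Parameters
    ----------
    time, event
        Follow-up times (>0) and event indicators (True = death observed).
    X
        Covariate matrix (n × p) or a single covariate vector; no missing
        values (the caller applies its complete-case policy).
    ties
        ``"efron"`` (default) or ``"breslow"`` handling of tied event times.
    names
        Covariate names for reporting; defaults to ``x1..xp``.

    Convergence requires the gradient norm to fall below `tol`. A diverging
    coefficient norm (monotone likelihood / separation) is flagged as
    non-convergent rather than silently reported.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method: {ties!r}")
    time, event, X = _prepare(time, event, X)
    n, p = X.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    if len(names) != p:
        raise ValueError("names length must match number of covariates")
    col_sd = X[event].std(axis=0) + X.std(axis=0)
    if np.any(col_sd == 0):
        bad = [names[i] for i in np.flatnonzero(col_sd == 0)]
        raise ValueError(f"covariates constant across the risk set: {bad}")

    beta = np.zeros(p)
    ll, grad, info = _partial_loglik(beta, time, event, X, ties)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving line search on the partial likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _partial_loglik(cand, time, event, X, ties)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        # scale-invariant divergence check: |beta_j|·sd(x_j) > 10 means a
        # hazard ratio beyond e^10 per SD — monotone likelihood in practice
        if np.max(np.abs(beta) * X.std(axis=0)) > 10:
            message = "diverging coefficients (monotone likelihood / separation)"
            break
        if np.linalg.norm(grad) < tol:
            converged = True
            break
    if not converged and not message:
        message = f"gradient norm {np.linalg.norm(grad):.2e} after {it} iterations"

    if converged:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        # a flat likelihood can satisfy the gradient criterion at an absurd
        # coefficient; an SD-scaled standard error above 5 marks it
        if np.max(se * X.std(axis=0)) > 5:
            converged = False
            message = "near-flat partial likelihood (suspected separation)"
            cov = np.full((p, p), np.nan)
            se = np.full(p, np.nan)
    else:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)

    bl_t, bl_H = _breslow_baseline(beta, time, event, X)
    return CoxFit(
        names=list(names),
        beta=beta,
        se=se,
        loglik=ll,
        ties=ties,
        converged=converged,
        n=n,
        n_events=int(event.sum()),
        baseline_times=bl_t,
        baseline_cumhaz=bl_H,
        n_iter=it,
        message=message,
        cov=cov,
    )


def _breslow_baseline(beta, time, event, X):
    """Breslow estimator of the baseline cumulative hazard at the fitted beta."""
    w = np.exp(X @ beta)
    S0 = np.cumsum(w[::-1])[::-1]
    uniq = np.unique(time[event])
    steps = np.empty(uniq.size)
    for k, t in enumerate(uniq):
        i0 = np.searchsorted(time, t, side="left")
        d = int((event & (time == t)).sum())
        steps[k] = d / S0[i0]
    return uniq, np.cumsum(steps)


def hr_table(fit: CoxFit, level: float = 0.95) -> pd.DataFrame:
    """Per-covariate hazard ratios, Wald confidence intervals, and p-values."""
    if not fit.converged:
        raise ValueError(f"refusing to report a non-converged fit: {fit.message}")
    z = stats.norm.ppf(0.5 + level / 2)
    wald = fit.beta / fit.se
    return pd.DataFrame(
        {
            "covariate": fit.names,
            "coef": fit.beta,
            "se": fit.se,
            "hr": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - z * fit.se),
            "ci_high": np.exp(fit.beta + z * fit.se),
            "p": 2 * stats.norm.sf(np.abs(wald)),
        }
    )


def adjusted_survival(fit: CoxFit, profile: dict[str, float]) -> pd.DataFrame:
    """Survival curve S(t) = exp(−Λ₀(t)·exp(xβ)) for a covariate profile.

    `profile` must supply a value for every fitted covariate (extra keys are
    an error). The returned step function starts at S(0)=1.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    unknown = set(profile) - set(fit.names)
    if unknown:
        raise KeyError(f"profile covariates not in the fitted model: {sorted(unknown)}")
    missing = set(fit.names) - set(profile)
    if missing:
        raise KeyError(f"profile missing fitted covariates: {sorted(missing)}")
    x = np.array([profile[nm] for nm in fit.names])
    risk = float(np.exp(x @ fit.beta))
    t = np.concatenate([[0.0], fit.baseline_times])
    S = np.concatenate([[1.0], np.exp(-fit.baseline_cumhaz * risk)])
    return pd.DataFrame({"time": t, "survival": S})


@dataclass(frozen=True)
class AttenuationSummary:
    """Nested-model comparison of an exposure with and without a mediator."""

    exposure: str
    beta_unadjusted: float
    beta_adjusted: float
    hr_unadjusted: float
    hr_adjusted: float
    attenuation: float  # 1 − beta_adj/beta_unadj on the log-HR scale
    p_unadjusted: float
    p_adjusted: float


def compare_mediation(
    fit_exposure_only: CoxFit, fit_with_mediator: CoxFit, exposure: str
) -> AttenuationSummary:
    """Quantify how much an exposure's log-hazard shrinks once a mediator enters.

    Attenuation of 0 means no change; 1 means the adjusted coefficient is
    zero; values can exceed 1 if the sign flips.
    """
    for fit in (fit_exposure_only, fit_with_mediator):
        if not fit.converged:
            raise ValueError("both fits must be converged")
        if exposure not in fit.names:
            raise KeyError(f"exposure {exposure!r} not in fit covariates {fit.names}")
    i = fit_exposure_only.names.index(exposure)
    j = fit_with_mediator.names.index(exposure)
    b0 = float(fit_exposure_only.beta[i])
    b1 = float(fit_with_mediator.beta[j])
    p0 = 2 * stats.norm.sf(abs(b0 / fit_exposure_only.se[i]))
    p1 = 2 * stats.norm.sf(abs(b1 / fit_with_mediator.se[j]))
    atten = np.nan if b0 == 0 else 1.0 - b1 / b0
    return AttenuationSummary(
        exposure=exposure,
        beta_unadjusted=b0,
        beta_adjusted=b1,
        hr_unadjusted=float(np.exp(b0)),
        hr_adjusted=float(np.exp(b1)),
        attenuation=float(atten),
        p_unadjusted=float(p0),
        p_adjusted=float(p1),
    )


def cohort_summary(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptive statistics and pairwise-complete Pearson correlations.

    Numeric columns are summarised as mean (SD); binary 0/1 columns also
    report the percentage positive. Non-numeric columns are ignored with a
    warning.
    """
    num = table.select_dtypes(include=[np.number, bool]).astype(float)
    dropped = [c for c in table.columns if c not in num.columns]
    if dropped:
        warnings.warn(f"ignoring non-numeric columns in summary: {dropped}")
    desc = pd.DataFrame(
        {
            "mean": num.mean(),
            "sd": num.std(ddof=1),
            "n": num.notna().sum(),
        }
    )
    binary = num.apply(lambda c: set(c.dropna().unique()) <= {0.0, 1.0})
    desc["percent"] = np.where(binary, 100 * num.mean(), np.nan)
    corr = num.corr(method="pearson")  # pairwise-complete by construction
    return desc, corr
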