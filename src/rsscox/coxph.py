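"""Cox proportional-hazards estimation from the partial likelihood.

Implements the log partial likelihood, its score and observed
information, a Newton–Raphson maximizer with step-halving, Wald tests
and hazard-ratio confidence intervals, plus the full likelihood of the
exponential sub-model (used to validate the data generator).

For events at times t_(1) < t_(2) < ... with covariate rows v_i, the log
partial likelihood is

    L(beta) = sum_events [ v_i' beta - log sum_{h in R(t_i)} exp(v_h' beta) ]

with risk set R(t) = {h : t_h >= t}.  Ties are handled by Breslow's
approximation (tied events share one denominator); with continuous times
ties have probability zero.  The score subtracts, for each event, the
g_h-weighted mean of the covariates over the risk set, where
g_h = exp(v_h' beta) / sum_R exp(v' beta) are normalized risk weights;
the observed information accumulates the g_h-weighted covariate
covariance per risk set and equals the negative Hessian of L.

All risk-set sums are computed in a single pass over the time-sorted
sample using suffix cumulative sums, after subtracting the maximum
linear predictor so the exponentials never overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "SurvivalDataset",
    "CoxFit",
    "WaldResult",
    "CoxPH",
    "log_partial_likelihood",
    "score",
    "observed_information",
    "fit_coxph",
    "wald",
    "parametric_loglik",
    "NoEventsError",
    "SingularInformationError",
    "NotConvergedError",
]


class NoEventsError(ValueError):
    """Dataset has no uncensored records; the partial likelihood is flat."""


class SingularInformationError(np.linalg.LinAlgError):
    """Observed information is singular (e.g. a constant covariate)."""


class NotConvergedError(RuntimeError):
    """Inference requested from a fit that did not converge."""


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival data with a fixed covariate layout.

    ``covariates`` is an (n, p) array whose columns are ordered as in
    ``names``; by convention the risk factor comes first and the
    auxiliary ranking covariate second.
    """

    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray
    names: tuple[str, ...] = ("x", "y")

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        status = np.asarray(self.status)
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status.astype(int))
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "names", tuple(self.names))
        if time.ndim != 1 or cov.shape[0] != time.size or status.size != time.size:
            raise ValueError("time, status and covariates must have matching length")
        if cov.shape[1] != len(self.names):
            raise ValueError(
                f"{cov.shape[1]} covariate columns but {len(self.names)} names"
            )
        if np.any(time <= 0):
            raise ValueError("times must be strictly positive")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0/1")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates: tuple[str, ...] = ("x", "y"),
        duration_col: str = "time",
        event_col: str = "status",
    ) -> "SurvivalDataset":
        return cls(
            time=df[duration_col].to_numpy(dtype=float),
            status=df[event_col].to_numpy(),
            covariates=df[list(covariates)].to_numpy(dtype=float),
            names=tuple(covariates),
        )


@dataclass(frozen=True)
class CoxFit:
    """Result of a Newton–Raphson partial-likelihood maximization."""

    beta: np.ndarray
    information: np.ndarray
    se: np.ndarray
    loglik: float
    n_events: int
    converged: bool
    n_iter: int
    names: tuple[str, ...]


@dataclass(frozen=True)
class WaldResult:
    """Wald test and hazard-ratio confidence interval for one coefficient."""

    name: str
    beta: float
    se: float
    z: float
    p: float
    reject: bool
    hr: float
    ci_low: float
    ci_high: float
    ci_length: float
    level: float


def _breslow_pass(data: SurvivalDataset, beta: np.ndarray):
    """Log partial likelihood, score and observed information in one pass."""
    beta = np.asarray(beta, dtype=float).ravel()
    p = data.covariates.shape[1]
    if beta.size != p:
        raise ValueError(f"beta has length {beta.size}, expected {p}")
    if data.n_events == 0:
        raise NoEventsError("dataset contains no events (status == 1)")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")

    order = np.argsort(data.time, kind="stable")
    t = data.time[order]
    d = data.status[order].astype(bool)
    X = data.covariates[order]

    lp = X @ beta
    c = lp.max()  # global shift keeps every exponential <= 1
    w = np.exp(lp - c)

    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2 = np.cumsum(
        (w[:, None, None] * X[:, :, None] * X[:, None, :])[::-1], axis=0
    )[::-1]

    # risk set {h: t_h >= t_i} starts at the first index sharing t_i,
    # which also gives Breslow's shared denominator under ties
    start = np.searchsorted(t, t, side="left")
    ev = np.nonzero(d)[0]
    f = start[ev]
    s0 = S0[f]
    xbar = S1[f] / s0[:, None]

    loglik = float(np.sum(lp[ev] - c - np.log(s0)))
    score_vec = np.sum(X[ev] - xbar, axis=0)
    info = np.sum(S2[f] / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :], axis=0)
    info = 0.5 * (info + info.T)  # enforce exact symmetry
    return loglik, score_vec, info


def log_partial_likelihood(data: SurvivalDataset, beta) -> float:
    """Breslow log partial likelihood at ``beta``."""
    return _breslow_pass(data, beta)[0]


def score(data: SurvivalDataset, beta) -> np.ndarray:
    """Gradient of the log partial likelihood at ``beta``."""
    return _breslow_pass(data, beta)[1]


def observed_information(data: SurvivalDataset, beta) -> np.ndarray:
    """Observed information (negative Hessian of the log partial
    likelihood) at ``beta``; symmetric positive semi-definite."""
    return _breslow_pass(data, beta)[2]


def fit_coxph(
    data: SurvivalDataset,
    init=None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Newton–Raphson maximization of the partial likelihood.

    Convergence is declared when the sup-norm of the score drops below
    ``tol``; each Newton step is halved (up to 30 times) whenever it
    fails to increase the log partial likelihood.  Hitting the iteration
    cap flags ``converged=False`` rather than raising; a singular
    information matrix raises :class:`SingularInformationError`.
    """
    p = data.covariates.shape[1]
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).ravel().copy()
    ll, sc, info = _breslow_pass(data, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(sc)) < tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(info, sc)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError(
                f"singular observed information at beta={beta} (collinear or "
                f"constant covariate?)"
            ) from exc
        accepted = False
        for _ in range(30):
            cand = beta + step
            ll_c, sc_c, info_c = _breslow_pass(data, cand)
            if ll_c >= ll - 1e-12:
                beta, ll, sc, info = cand, ll_c, sc_c, info_c
                accepted = True
                break
            step = step / 2.0
        if not accepted:
            break  # cannot improve: report non-convergence
    else:
        it = max_iter
    if not converged and np.max(np.abs(sc)) < tol:
        converged = True

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SingularInformationError(
            "observed information singular at the optimum"
        ) from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return CoxFit(
        beta=beta,
        information=info,
        se=se,
        loglik=ll,
        n_events=data.n_events,
        converged=converged,
        n_iter=it,
        names=data.names,
    )


def wald(fit: CoxFit, j: int = 0, level: float = 0.95) -> WaldResult:
    """Two-sided Wald test of ``beta_j = 0`` and the hazard-ratio
    confidence interval ``exp(beta_j -/+ z* se_j)`` at ``level``."""
    if not fit.converged:
        raise NotConvergedError("refusing Wald inference from a non-convergent fit")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    b = float(fit.beta[j])
    s = float(fit.se[j])
    zstar = float(stats.norm.ppf(0.5 + level / 2.0))
    z = b / s
    with np.errstate(over="ignore"):  # inf bound on a degenerate tiny sample
        lo, hi = np.exp(b - zstar * s), np.exp(b + zstar * s)
    return WaldResult(
        name=fit.names[j],
        beta=b,
        se=s,
        z=z,
        p=float(2.0 * stats.norm.sf(abs(z))),
        reject=bool(abs(z) > zstar),
        hr=float(np.exp(b)),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_length=float(hi - lo),
        level=level,
    )


def parametric_loglik(
    data: SurvivalDataset, rate: float, hazard_family: str = "exponential"
) -> float:
    """Full log likelihood of type-I right-censored data under a constant
    hazard: sum of ``delta*log f(t) + (1-delta)*log S(t)`` for the
    exponential family.  Its maximizer over ``rate`` is the closed form
    ``sum(delta) / sum(t)``."""
    if hazard_family != "exponential":
        raise ValueError(f"unsupported hazard family {hazard_family!r}")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    d = data.status
    t = data.time
    return float(np.sum(d) * np.log(rate) - rate * np.sum(t))


class CoxPH(BaseEstimator):
    """Cox proportional-hazards model as a scikit-learn style estimator.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the sup-norm of the score.
    max_iter : int
        Newton–Raphson iteration cap.

    ``fit(X, y)`` accepts ``y`` either as a structured array with fields
    ``event`` (bool/int) and ``time`` (float) — the scikit-survival
    convention — or as an (n, 2) array of ``(time, status)`` columns.

    Attributes (after fitting)
    --------------------------
    coef_ : ndarray of shape (p,)
        Log-hazard coefficient estimates.
    se_ : ndarray of shape (p,)
        Standard errors from the inverse observed information.
    information_ : ndarray of shape (p, p)
        Observed information at the optimum.
    log_likelihood_ : float
        Log partial likelihood at the optimum.
    n_events_, n_iter_, converged_ : fit diagnostics.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 50):
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _unpack_y(y):
        y = np.asarray(y)
        if y.dtype.names:
            fields = set(y.dtype.names)
            event_f = "event" if "event" in fields else sorted(fields)[0]
            time_f = "time" if "time" in fields else sorted(fields)[1]
            return y[time_f].astype(float), y[event_f].astype(int)
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[1] != 2:
            raise ValueError("y must be structured (event, time) or an (n, 2) array")
        return y[:, 0], y[:, 1].astype(int)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        time, status = self._unpack_y(y)
        names = tuple(f"x{j}" for j in range(X.shape[1]))
        data = SurvivalDataset(time=time, status=status, covariates=X, names=names)
        res = fit_coxph(data, tol=self.tol, max_iter=self.max_iter)
        self.coef_ = res.beta
        self.se_ = res.se
        self.information_ = res.information
        self.log_likelihood_ = res.loglik
        self.n_events_ = res.n_events
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.n_features_in_ = X.shape[1]
        self.result_ = res
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard) for new covariate rows."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def wald_test(self, j: int = 0, level: float = 0.95) -> WaldResult:
        """Wald test / HR confidence interval for fitted coefficient j."""
        return wald(self.result_, j=j, level=level)
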