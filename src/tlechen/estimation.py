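"""Maximum-likelihood fitting for the Chen family, statsmodels-style.

:class:`ParametricMLE` is the model object: it is built from a sample of
strictly positive observations plus a :class:`~tlechen.distributions.ModelSpec`
and exposes ``loglike``/``score``/``fit``.  ``fit`` maximises the
log-likelihood by Nelder-Mead over log-transformed parameters (so every
proposal is automatically positive) from a deterministic cascade of starts —
Chen fit, then Topp-Leone Chen and exponentiated Chen fits seeded from it,
then the four-parameter model seeded from both — plus seeded random
restarts.  The result object, :class:`FitResult`, carries the estimates on
the natural scale, observed-information standard errors, Wald intervals and
convergence diagnostics, and prints a summary table.

A hard floor of ``PARAM_FLOOR`` = 1e-8 is applied on the natural scale; an
estimate within 10x the floor is flagged as a boundary solution (the scale
parameter of the Chen kernel routinely collapses towards zero on data with
values in the thousands, because exp(x**beta) is enormous there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .distributions import (
    CHEN,
    EC,
    PARAM_FLOOR,
    TLC,
    TLEC,
    ModelSpec,
    TlecParams,
    get_model_spec,
    tlec_logpdf,
)

__all__ = [
    "ParametricMLE",
    "FitResult",
    "InfoCriteria",
    "loglik",
    "score",
    "fit_mle",
    "observed_information",
    "wald_ci",
    "information_criteria",
]

_LOG_FLOOR = np.log(PARAM_FLOOR)
_LOG_CEIL = np.log(1e8)
_BOUNDARY = 10.0 * PARAM_FLOOR


# --------------------------------------------------------------------------
# pure likelihood pieces (TLEC)


def _check_data(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("data must be non-empty")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("data must consist of finite, strictly positive values")
    return arr


def loglik(params: TlecParams, data) -> float:
    """TLEC log-likelihood: the summed log-density over the observations.

    Propagates -inf if any observation sits where the density underflows.
    """
    arr = _check_data(data)
    return float(np.sum(tlec_logpdf(arr, params)))


def score(params: TlecParams, data) -> np.ndarray:
    """Analytic score vector (d/d alpha, d/d lam, d/d beta, d/d b).

    Derived by differentiating the log-likelihood written in the stable
    kernel variables s = x**beta, t = -lam*expm1(s), G = -expm1(t),
    H = G**b, D = 1 - H.  Raises if any observation is saturated (density
    zero), naming the offending value.
    """
    arr = _check_data(data)
    a, lam, beta, b = params.alpha, params.lam, params.beta, params.b
    logx = np.log(arr)
    s = np.power(arr, beta)
    if np.any(s > 700.0):
        bad = arr[s > 700.0][0]
        raise FloatingPointError(f"observation x={bad!r} is saturated (x**beta > 700)")
    es = np.exp(s)
    t = -lam * np.expm1(s)
    et = np.exp(t)
    G = -np.expm1(t)
    if np.any(G <= 0.0) or np.any(G >= 1.0):
        bad = arr[(G <= 0.0) | (G >= 1.0)][0]
        raise FloatingPointError(f"density degenerate at observation x={bad!r}")
    logG = np.log(G)
    H = np.exp(b * logG)
    D = -np.expm1(b * logG)
    n = arr.size

    # d loglik / d t, per observation (t carries lam and beta)
    A = (
        1.0
        - (b - 1.0) * et / G
        + b * H * et / (G * D)
        + (a - 1.0) * b * (et / G) * (H / (1.0 + D) - 1.0)
    )
    dt_dlam = -np.expm1(s)
    dt_dbeta = -lam * es * s * logx

    d_alpha = n / a + np.sum(b * logG + np.log1p(D))
    d_lam = n / lam + np.sum(A * dt_dlam)
    d_beta = n / beta + np.sum(logx) + np.sum(s * logx) + np.sum(A * dt_dbeta)
    d_b = (
        n / b
        + np.sum(logG)
        - np.sum(H * logG / D)
        + (a - 1.0) * np.sum(logG * (1.0 - H / (1.0 + D)))
    )
    return np.array([d_alpha, d_lam, d_beta, d_b])


# --------------------------------------------------------------------------
# information criteria


@dataclass(frozen=True)
class InfoCriteria:
    """Penalised -2 log-likelihood criteria; smaller is better."""

    k: int
    n: int
    aic: float
    caic: float
    bic: float
    hqic: float


def information_criteria(minus2loglik: float, k: int, n: int) -> InfoCriteria:
    """AIC, CAIC, BIC and HQIC from -2 log L, parameter count k, sample size n.

    AIC  = -2 log L + 2k
    BIC  = -2 log L + k log n
    CAIC = -2 log L + k (log n + 1)
    HQIC = -2 log L + 2k log log n
    """
    if n <= 1:
        raise ValueError(f"n must exceed 1 for information criteria, got {n}")
    if k < 0:
        raise ValueError(f"parameter count must be nonnegative, got {k}")
    m2 = float(minus2loglik)
    ln_n = np.log(n)
    return InfoCriteria(
        k=int(k),
        n=int(n),
        aic=m2 + 2.0 * k,
        caic=m2 + k * (ln_n + 1.0),
        bic=m2 + k * ln_n,
        hqic=m2 + 2.0 * k * np.log(ln_n),
    )


# --------------------------------------------------------------------------
# results container


@dataclass
class FitResult:
    """MLE output for one model on one sample.

    Interval endpoints are the untruncated Wald limits (they may be
    negative even though the parameters are positive); ``ci_lower_trunc``
    offers the zero-truncated view.
    """

    model_label: str
    param_names: tuple
    params_hat: np.ndarray
    loglik_max: float
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float
    n_obs: int
    converged: bool
    n_restarts_used: int
    boundary_flags: np.ndarray
    cov_warning: bool = False
    spec: ModelSpec | None = field(default=None, repr=False)

    @property
    def minus2loglik(self) -> float:
        return -2.0 * self.loglik_max

    @property
    def ci_lower_trunc(self) -> np.ndarray:
        return np.maximum(self.ci_lower, 0.0)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def info_criteria(self, k: int | None = None) -> InfoCriteria:
        return information_criteria(self.minus2loglik, k or self.n_params, self.n_obs)

    def params_dict(self) -> dict:
        return dict(zip(self.param_names, map(float, self.params_hat)))

    def summary(self) -> str:
        ic = self.info_criteria()
        lines = [
            f"{self.model_label} maximum-likelihood fit",
            "=" * 58,
            f"n_obs {self.n_obs:>6d}    log-lik {self.loglik_max:12.4f}    "
            f"-2 log-lik {self.minus2loglik:10.4f}",
            f"AIC {ic.aic:10.3f}  CAIC {ic.caic:10.3f}  BIC {ic.bic:10.3f}  "
            f"HQIC {ic.hqic:10.3f}",
            f"converged: {self.converged}   restarts used: {self.n_restarts_used}",
            "-" * 58,
            f"{'param':>8s} {'estimate':>12s} {'std err':>10s} "
            f"{'[' + format(self.level, '.3g'):>9s} {']':>10s} {'bdry':>5s}",
        ]
        for j, name in enumerate(self.param_names):
            lines.append(
                f"{name:>8s} {self.params_hat[j]:12.6g} {self.se[j]:10.4g} "
                f"{self.ci_lower[j]:10.4g} {self.ci_upper[j]:10.4g} "
                f"{'*' if self.boundary_flags[j] else '':>5s}"
            )
        if self.cov_warning:
            lines.append("warning: observed information not positive definite")
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.summary()


# --------------------------------------------------------------------------
# observed information / Wald machinery


def observed_information(params, data, model: ModelSpec | str = TLEC) -> np.ndarray:
    """Negative Hessian of the log-likelihood at ``params`` (natural scale).

    Central finite differences with per-parameter relative steps; the raw
    matrix is symmetrised as (H + H')/2.
    """
    spec = get_model_spec(model)
    theta = params.as_array() if isinstance(params, TlecParams) else np.asarray(params, float)
    arr = _check_data(data)

    def ll(th):
        with np.errstate(all="ignore"):
            return float(np.sum(spec.log_density(arr, th)))

    k = theta.size
    h = 1e-3 * np.maximum(np.abs(theta), 1e-6)
    f0 = ll(theta)
    hess = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        hess[i, i] = (ll(theta + ei) + ll(theta - ei) - 2.0 * f0) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                ll(theta + ei + ej) + ll(theta - ei - ej) - ll(theta + ei - ej) - ll(theta - ei + ej)
            ) / (4.0 * h[i] * h[j])
    info = -0.5 * (hess + hess.T)
    return info


def _se_from_information(info: np.ndarray):
    """Standard errors from the inverse observed information; NaN where invalid."""
    k = info.shape[0]
    warn = False
    try:
        cov = np.linalg.inv(info)
        var = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        var = np.full(k, np.nan)
        warn = True
    if np.any(~np.isfinite(var)) or np.any(var <= 0):
        warn = True
        var = np.where(np.isfinite(var) & (var > 0), var, np.nan)
    return np.sqrt(var), cov, warn


def wald_ci(fit: FitResult, level: float = 0.95) -> FitResult:
    """Refresh the Wald intervals of ``fit`` at a (possibly new) level.

    Endpoints are estimate +/- z_(1-gamma/2) * se, untruncated.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level!r}")
    z = norm.ppf(0.5 + level / 2.0)
    fit.level = float(level)
    fit.ci_lower = fit.params_hat - z * fit.se
    fit.ci_upper = fit.params_hat + z * fit.se
    return fit


# --------------------------------------------------------------------------
# the model object


class ParametricMLE:
    """Maximum-likelihood model for a positive-support lifetime distribution.

    Parameters
    ----------
    endog : array-like
        Strictly positive observations.
    model : str or ModelSpec
        One of ``{"tlec", "ec", "chen", "tlc"}`` or a user-supplied spec.
    """

    def __init__(self, endog, model: ModelSpec | str = "tlec"):
        self.endog = _check_data(endog)
        self.spec = get_model_spec(model)
        if self.endog.size < self.spec.n_params:
            raise ValueError(
                f"need at least {self.spec.n_params} observations to fit "
                f"{self.spec.label}, got {self.endog.size}"
            )

    @classmethod
    def from_dataframe(cls, df, column: str, model: ModelSpec | str = "tlec"):
        return cls(np.asarray(df[column], dtype=float), model=model)

    # -- likelihood surface -------------------------------------------------

    def loglike(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        with np.errstate(all="ignore"):
            ll = np.sum(self.spec.log_density(self.endog, theta))
        return float(ll)

    def score(self, theta) -> np.ndarray:
        """Score vector: analytic for the TLEC spec, finite differences otherwise."""
        theta = np.asarray(theta, dtype=float)
        if self.spec is TLEC:
            return score(TlecParams.from_array(theta), self.endog)
        h = 1e-6 * np.maximum(np.abs(theta), 1e-6)
        out = np.empty(theta.size)
        for j in range(theta.size):
            e = np.zeros(theta.size)
            e[j] = h[j]
            out[j] = (self.loglike(theta + e) - self.loglike(theta - e)) / (2.0 * h[j])
        return out

    # -- optimisation -------------------------------------------------------

    def _neg_ll_log(self, eta: np.ndarray) -> float:
        theta = np.exp(np.clip(eta, _LOG_FLOOR, _LOG_CEIL))
        ll = self.loglike(theta)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    def _run_simplex(self, start_theta: np.ndarray):
        eta0 = np.log(np.clip(start_theta, PARAM_FLOOR, 1e8))
        res = minimize(
            self._neg_ll_log,
            eta0,
            method="Nelder-Mead",
            options=dict(fatol=1e-10, xatol=1e-8, maxiter=5000, maxfev=8000),
        )
        theta = np.exp(np.clip(res.x, _LOG_FLOOR, _LOG_CEIL))
        return theta, -res.fun, bool(res.success)

    def _cascade_starts(self, seed: int) -> list:
        """Deterministic warm starts: Chen -> {EC, TLC} -> four-parameter seeds."""
        spec = self.spec
        starts: list = []
        if spec is CHEN:
            starts += [np.array([1.0, 1.0]), np.array([0.01, 0.3]), np.array([0.1, 0.7])]
            return starts
        chen_fit = ParametricMLE(self.endog, CHEN).fit(n_restarts=5, seed=seed)
        lam_c, beta_c = chen_fit.params_hat
        if spec is EC:
            starts.append(np.array([lam_c, beta_c, 1.0]))
        elif spec is TLC:
            # alpha = 1 makes TLC a Chen law with doubled scale
            starts.append(np.array([1.0, lam_c / 2.0, beta_c]))
        elif spec is TLEC:
            ec_fit = ParametricMLE(self.endog, EC).fit(
                n_restarts=5, seed=seed + 1, _cascade=False,
                extra_starts=[np.array([lam_c, beta_c, 1.0])],
            )
            tlc_fit = ParametricMLE(self.endog, TLC).fit(
                n_restarts=5, seed=seed + 2, _cascade=False,
                extra_starts=[np.array([1.0, lam_c / 2.0, beta_c])],
            )
            a_t, lam_t, beta_t = tlc_fit.params_hat
            lam_e, beta_e, b_e = ec_fit.params_hat
            starts.append(np.array([a_t, lam_t, beta_t, 1.0]))  # exact b=1 embedding
            starts.append(np.array([1.0, lam_e, beta_e, b_e]))
            starts.append(np.array([1.0, lam_c, beta_c, 1.0]))
        else:  # user-supplied model: neutral start
            starts.append(np.ones(spec.n_params))
        return starts

    def fit(
        self,
        n_restarts: int = 20,
        seed: int = 0,
        level: float = 0.95,
        extra_starts=None,
        _cascade: bool = True,
    ) -> FitResult:
        """Multi-start Nelder-Mead MLE over log-transformed parameters.

        ``n_restarts`` seeded random starts are drawn log-uniform over
        [1e-3, 10] per parameter on top of the deterministic cascade and any
        ``extra_starts`` (natural-scale vectors).  Deterministic for fixed
        inputs.  Never raises on optimisation failure: ``converged`` is
        False when no restart met tolerance.
        """
        if not (0.0 < level < 1.0):
            raise ValueError(f"level must lie in (0, 1), got {level!r}")
        spec = self.spec
        starts = [np.asarray(s, dtype=float) for s in (extra_starts or [])]
        if _cascade:
            starts += self._cascade_starts(seed)
        if not starts:
            starts.append(np.ones(spec.n_params))
        rng = np.random.default_rng(seed)
        for _ in range(int(n_restarts)):
            starts.append(np.exp(rng.uniform(np.log(1e-3), np.log(10.0), spec.n_params)))

        best_theta, best_ll, best_ok = None, -np.inf, False
        for s in starts:
            theta, ll, ok = self._run_simplex(s)
            if ll > best_ll:
                best_theta, best_ll, best_ok = theta, ll, ok
        assert best_theta is not None

        info = observed_information(best_theta, self.endog, spec)
        se, _, warn = _se_from_information(info)
        flags = best_theta <= _BOUNDARY
        fit = FitResult(
            model_label=spec.label,
            param_names=spec.param_names,
            params_hat=best_theta,
            loglik_max=best_ll,
            se=se,
            ci_lower=np.full(spec.n_params, np.nan),
            ci_upper=np.full(spec.n_params, np.nan),
            level=level,
            n_obs=self.endog.size,
            converged=best_ok and np.isfinite(best_ll),
            n_restarts_used=len(starts),
            boundary_flags=flags,
            cov_warning=warn,
            spec=spec,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wald_ci(fit, level)
        return fit


def fit_mle(
    data,
    model: ModelSpec | str = "tlec",
    n_restarts: int = 20,
    seed: int = 0,
    level: float = 0.95,
    extra_starts=None,
) -> FitResult:
    """Functional wrapper: ``ParametricMLE(data, model).fit(...)``."""
    return ParametricMLE(data, model).fit(
        n_restarts=n_restarts, seed=seed, level=level, extra_starts=extra_starts
    )
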