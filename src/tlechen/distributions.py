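"""Core distribution functions for the Chen family and its Topp-Leone extensions.

The Chen distribution is a two-parameter lifetime law with CDF

    F_C(x; lam, beta) = 1 - exp(lam * (1 - exp(x**beta))),   x > 0,

whose hazard can be bathtub-shaped (beta < 1) or increasing (beta >= 1).
Raising ``F_C`` to a power ``b > 0`` gives the exponentiated Chen (EC)
distribution, and pushing the EC CDF through the Topp-Leone generator

    F(x) = [1 - (1 - G(x))**2]**alpha

produces the four-parameter Topp-Leone exponentiated Chen (TLEC)
distribution implemented here, with ``G = F_C**b``:

    F_TLEC(x; alpha, lam, beta, b) = [1 - (1 - F_C(x)**b)**2]**alpha.

All kernels are evaluated in log space.  Writing s = x**beta,
t = lam*(1 - e**s) = -lam*expm1(s) <= 0 and G = -expm1(t) in (0, 1), no
intermediate ever forms e**(x**beta) directly, so the functions stay finite
far beyond the point where the naive formulas overflow (s ~ 709).  Where the
distribution genuinely saturates in double precision (s > 700) the CDF is 1
and the log-density is -inf by construction, never NaN.

Every function accepts a scalar or an array-like of evaluation points and
returns a matching shape.  Parameters are scalars only; there is no implicit
broadcasting across parameter collections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TlecParams",
    "ModelSpec",
    "SaturationError",
    "PARAM_FLOOR",
    "tlec_cdf",
    "tlec_logpdf",
    "tlec_pdf",
    "tlec_survival",
    "tlec_hazard",
    "tlec_quantile",
    "tlec_rvs",
    "chen_cdf",
    "chen_logpdf",
    "chen_pdf",
    "chen_quantile",
    "ec_cdf",
    "ec_logpdf",
    "ec_pdf",
    "ec_quantile",
    "tlc_cdf",
    "tlc_logpdf",
    "tlc_pdf",
    "tlc_quantile",
    "tl_cdf",
    "tl_pdf",
    "get_model_spec",
    "TLEC",
    "EC",
    "CHEN",
    "TLC",
]

_LOG2 = 0.6931471805599453
_S_MAX = 700.0  # exp(s) overflows near s = 709.78; past 700 the CDF is 1 in doubles
PARAM_FLOOR = 1e-8


class SaturationError(FloatingPointError):
    """A survival probability underflowed to zero where a finite ratio was needed."""


# --------------------------------------------------------------------------
# parameter container


@dataclass(frozen=True)
class TlecParams:
    """Parameter vector (alpha, lam, beta, b) of the TLEC distribution.

    ``lam`` is a scale parameter; ``alpha`` (Topp-Leone), ``beta`` (Chen) and
    ``b`` (exponentiation) are shape parameters.  All must be strictly
    positive and finite.
    """

    alpha: float
    lam: float
    beta: float
    b: float

    def __post_init__(self) -> None:
        for name in ("alpha", "lam", "beta", "b"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"TlecParams.{name} must be strictly positive and finite, got {v!r}"
                )
            object.__setattr__(self, name, float(v))

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.lam, self.beta, self.b])

    @classmethod
    def from_array(cls, theta) -> "TlecParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (4,):
            raise ValueError(f"expected 4 parameters, got shape {theta.shape}")
        return cls(*theta)


# --------------------------------------------------------------------------
# numerics helpers


def _as_array(x, name: str = "x"):
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    return np.atleast_1d(arr), scalar


def _restore(arr: np.ndarray, scalar: bool):
    return float(arr[0]) if scalar else arr


def _log1mexp(a: np.ndarray) -> np.ndarray:
    """log(1 - exp(a)) for a <= 0, accurate at both ends."""
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        lo = np.log1p(-np.exp(np.minimum(a, -_LOG2)))
        hi = np.log(-np.expm1(np.maximum(a, -_LOG2)))
    return np.where(a < -_LOG2, lo, hi)


def _check_positive(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")
    return value


def _chen_kernel(x: np.ndarray, lam: float, beta: float):
    """Shared building blocks: s = x**beta, t = lam*(1-e^s), log G = log F_C."""
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    s = np.power(x, beta)
    sat = s > _S_MAX
    t = np.where(sat, -np.inf, -lam * np.expm1(np.minimum(s, _S_MAX)))
    logG = _log1mexp(t)  # log of the Chen CDF, in [-inf, 0]
    return logx, s, t, logG, sat


# --------------------------------------------------------------------------
# TLEC


def tlec_cdf(x, params: TlecParams):
    """CDF [1 - (1 - F_C(x)**b)**2]**alpha of the TLEC distribution."""
    arr, scalar = _as_array(x)
    if np.any(arr < 0) or np.any(np.isnan(arr)):
        raise ValueError("x must be nonnegative")
    _, _, _, logG, _ = _chen_kernel(arr, params.lam, params.beta)
    logH = params.b * logG  # log of G = F_C**b
    D = -np.expm1(logH)  # 1 - F_C**b, in [0, 1]
    with np.errstate(invalid="ignore"):
        logF = params.alpha * (logH + np.log1p(D))
    out = np.exp(logF)
    out = np.where(logG == 0.0, 1.0, out)  # saturated region
    return _restore(out, scalar)


def tlec_logpdf(x, params: TlecParams):
    """Log-density of the TLEC distribution, evaluated fully in log space.

    Returns -inf where the density underflows to zero (including the
    saturated region x**beta > 700).
    """
    arr, scalar = _as_array(x)
    if np.any(arr <= 0) or np.any(np.isnan(arr)):
        raise ValueError("x must be strictly positive")
    a, lam, beta, b = params.alpha, params.lam, params.beta, params.b
    logx, s, t, logG, sat = _chen_kernel(arr, lam, beta)
    logH = b * logG
    logD = _log1mexp(logH)  # log(1 - F_C**b)
    D = np.exp(logD)
    const = np.log(2.0 * a * b * beta * lam)
    with np.errstate(invalid="ignore"):
        out = (
            const
            + (beta - 1.0) * logx
            + s
            + t
            + (b - 1.0) * logG
            + logD
            + (a - 1.0) * (logH + np.log1p(D))
        )
    out = np.where(sat | (logG == 0.0), -np.inf, out)
    return _restore(out, scalar)


def tlec_pdf(x, params: TlecParams):
    """Density of the TLEC distribution (``exp`` of :func:`tlec_logpdf`)."""
    res = tlec_logpdf(x, params)
    return np.exp(res) if not np.isscalar(res) else float(np.exp(res))


def tlec_survival(x, params: TlecParams):
    """Survival (reliability) function 1 - F(x), accurate near 1 and near 0."""
    arr, scalar = _as_array(x)
    if np.any(arr < 0) or np.any(np.isnan(arr)):
        raise ValueError("x must be nonnegative")
    _, _, _, logG, _ = _chen_kernel(arr, params.lam, params.beta)
    logH = params.b * logG
    D = -np.expm1(logH)
    with np.errstate(invalid="ignore"):
        logF = params.alpha * (logH + np.log1p(D))
    out = -np.expm1(logF)
    out = np.where(logG == 0.0, 0.0, out)
    return _restore(out, scalar)


def tlec_hazard(x, params: TlecParams):
    """Hazard rate f(x) / (1 - F(x)).

    Raises :class:`SaturationError` where the survival underflows to zero,
    rather than silently returning ``inf``.
    """
    arr, scalar = _as_array(x)
    sf, _ = _as_array(tlec_survival(arr, params))
    if np.any(sf == 0.0):
        bad = arr[np.asarray(sf) == 0.0]
        raise SaturationError(
            f"survival underflows to 0 at x={bad[:5]!r}; hazard not representable"
        )
    lp, _ = _as_array(tlec_logpdf(arr, params))
    out = np.exp(lp - np.log(sf))
    return _restore(out, scalar)


def _quantile_bisect(p: float, cdf: Callable[[float], float]) -> float:
    if p <= 0.0:
        return 0.0
    hi = 1.0
    while cdf(hi) < p:
        hi *= 2.0
        if hi > 1e154:  # pragma: no cover - inverse always brackets before this
            raise FloatingPointError("failed to bracket quantile")
    return brentq(lambda z: cdf(z) - p, 0.0, hi, xtol=1e-14, rtol=1e-14)


def tlec_quantile(p, params: TlecParams):
    """Quantile function of the TLEC distribution.

    Closed form obtained by inverting the CDF layer by layer:

        u = p**(1/alpha);  D = sqrt(1 - u);  G = (1 - D)**(1/b);
        x = [log(1 - log(1 - G)/lam)]**(1/beta).

    The cancellations 1 - D and 1 - G are computed in stable forms
    (u / (1 + D) and -expm1 respectively).  Should rounding push an
    intermediate out of its valid domain, the affected entries fall back to
    bracketed root-finding on the CDF.
    """
    arr, scalar = _as_array(p, "p")
    if np.any(arr < 0) or np.any(arr >= 1) or np.any(np.isnan(arr)):
        raise ValueError("p must lie in [0, 1)")
    a, lam, beta, b = params.alpha, params.lam, params.beta, params.b
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.log(arr)
        r = logP / a
        D = np.sqrt(-np.expm1(r))  # sqrt(1 - p**(1/alpha))
        logH = r - np.log1p(D)  # log(1 - D) without cancellation
        logG = logH / b
        t = _log1mexp(logG)  # log(1 - G) <= 0
        s = np.log1p(-t / lam)
        out = np.exp(np.log(s) / beta)
    out = np.where(arr == 0.0, 0.0, out)
    bad = ~np.isfinite(out) & (arr > 0.0)
    if np.any(bad):
        cdf = lambda z: tlec_cdf(z, params)  # noqa: E731
        for i in np.flatnonzero(bad):
            out[i] = _quantile_bisect(float(arr[i]), cdf)
    return _restore(out, scalar)


def tlec_rvs(n: int, params: TlecParams, seed: int):
    """Draw ``n`` inverse-transform variates Q(U_i) with a seeded generator."""
    if not isinstance(n, (int, np.integer)) or n <= 0:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=int(n))
    return tlec_quantile(u, params)


# --------------------------------------------------------------------------
# Chen baseline


def chen_cdf(x, lam: float, beta: float):
    """Chen CDF 1 - exp(lam*(1 - exp(x**beta)))."""
    lam = _check_positive(lam, "lam")
    beta = _check_positive(beta, "beta")
    arr, scalar = _as_array(x)
    if np.any(arr < 0) or np.any(np.isnan(arr)):
        raise ValueError("x must be nonnegative")
    _, _, t, _, sat = _chen_kernel(arr, lam, beta)
    out = np.where(sat, 1.0, -np.expm1(t))
    return _restore(out, scalar)


def chen_logpdf(x, lam: float, beta: float):
    lam = _check_positive(lam, "lam")
    beta = _check_positive(beta, "beta")
    arr, scalar = _as_array(x)
    if np.any(arr <= 0) or np.any(np.isnan(arr)):
        raise ValueError("x must be strictly positive")
    logx, s, t, _, sat = _chen_kernel(arr, lam, beta)
    out = np.log(lam * beta) + (beta - 1.0) * logx + s + t
    out = np.where(sat, -np.inf, out)
    return _restore(out, scalar)


def chen_pdf(x, lam: float, beta: float):
    res = chen_logpdf(x, lam, beta)
    return np.exp(res) if not np.isscalar(res) else float(np.exp(res))


def chen_quantile(p, lam: float, beta: float):
    """Inverse Chen CDF: x = [log(1 - log(1-p)/lam)]**(1/beta)."""
    lam = _check_positive(lam, "lam")
    beta = _check_positive(beta, "beta")
    arr, scalar = _as_array(p, "p")
    if np.any(arr < 0) or np.any(arr >= 1) or np.any(np.isnan(arr)):
        raise ValueError("p must lie in [0, 1)")
    with np.errstate(divide="ignore"):
        t = np.log1p(-arr)
        s = np.log1p(-t / lam)
        out = np.exp(np.log(s) / beta)
    return _restore(np.where(arr == 0.0, 0.0, out), scalar)


# --------------------------------------------------------------------------
# exponentiated Chen


def ec_cdf(x, lam: float, beta: float, b: float):
    """Exponentiated Chen CDF F_C**b; b = 1 recovers Chen exactly."""
    b = _check_positive(b, "b")
    lam = _check_positive(lam, "lam")
    beta = _check_positive(beta, "beta")
    arr, scalar = _as_array(x)
    if np.any(arr < 0) or np.any(np.isnan(arr)):
        raise ValueError("x must be nonnegative")
    _, _, _, logG, _ = _chen_kernel(arr, lam, beta)
    return _restore(np.exp(b * logG), scalar)


def ec_logpdf(x, lam: float, beta: float, b: float):
    b = _check_positive(b, "b")
    lam = _check_positive(lam, "lam")
    beta = _check_positive(beta, "beta")
    arr, scalar = _as_array(x)
    if np.any(arr <= 0) or np.any(np.isnan(arr)):
        raise ValueError("x must be strictly positive")
    logx, s, t, logG, sat = _chen_kernel(arr, lam, beta)
    out = np.log(b * lam * beta) + (beta - 1.0) * logx + s + t + (b - 1.0) * logG
    out = np.where(sat | (logG == 0.0), -np.inf, out)
    return _restore(out, scalar)


def ec_pdf(x, lam: float, beta: float, b: float):
    res = ec_logpdf(x, lam, beta, b)
    return np.exp(res) if not np.isscalar(res) else float(np.exp(res))


def ec_quantile(p, lam: float, beta: float, b: float):
    b = _check_positive(b, "b")
    arr, scalar = _as_array(p, "p")
    if np.any(arr < 0) or np.any(arr >= 1) or np.any(np.isnan(arr)):
        raise ValueError("p must lie in [0, 1)")
    with np.errstate(divide="ignore"):
        logG = np.log(arr) / b
        t = _log1mexp(logG)
        s = np.log1p(-t / lam)
        out = np.exp(np.log(s) / beta)
    return _restore(np.where(arr == 0.0, 0.0, out), scalar)


# --------------------------------------------------------------------------
# Topp-Leone Chen (b = 1 specialisation)


def tlc_cdf(x, alpha: float, lam: float, beta: float):
    """Topp-Leone Chen CDF [1 - exp(2*lam*(1 - exp(x**beta)))]**alpha."""
    alpha = _check_positive(alpha, "alpha")
    arr, scalar = _as_array(x)
    if np.any(arr < 0) or np.any(np.isnan(arr)):
        raise ValueError("x must be nonnegative")
    _, _, t, _, sat = _chen_kernel(arr, lam, beta)
    with np.errstate(invalid="ignore"):
        out = np.exp(alpha * _log1mexp(2.0 * t))
    return _restore(np.where(sat, 1.0, out), scalar)


def tlc_logpdf(x, alpha: float, lam: float, beta: float):
    alpha = _check_positive(alpha, "alpha")
    lam = _check_positive(lam, "lam")
    beta = _check_positive(beta, "beta")
    arr, scalar = _as_array(x)
    if np.any(arr <= 0) or np.any(np.isnan(arr)):
        raise ValueError("x must be strictly positive")
    logx, s, t, _, sat = _chen_kernel(arr, lam, beta)
    log1m = _log1mexp(2.0 * t)
    out = (
        np.log(2.0 * alpha * lam * beta)
        + (beta - 1.0) * logx
        + s
        + 2.0 * t
        + (alpha - 1.0) * log1m
    )
    out = np.where(sat | (log1m == 0.0), -np.inf, out)
    return _restore(out, scalar)


def tlc_pdf(x, alpha: float, lam: float, beta: float):
    res = tlc_logpdf(x, alpha, lam, beta)
    return np.exp(res) if not np.isscalar(res) else float(np.exp(res))


def tlc_quantile(p, alpha: float, lam: float, beta: float):
    return tlec_quantile(p, TlecParams(alpha, lam, beta, 1.0))


# --------------------------------------------------------------------------
# Topp-Leone on (0, 1): the generator itself


def tl_cdf(v, alpha: float):
    """Topp-Leone CDF v**alpha * (2 - v)**alpha on (0, 1)."""
    alpha = _check_positive(alpha, "alpha")
    arr, scalar = _as_array(v, "v")
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise ValueError("v must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.exp(alpha * (np.log(arr) + np.log(2.0 - arr)))
    return _restore(np.where(arr == 0.0, 0.0, out), scalar)


def tl_pdf(v, alpha: float):
    """Topp-Leone density 2*alpha*v**(alpha-1)*(1-v)*(2-v)**(alpha-1)."""
    alpha = _check_positive(alpha, "alpha")
    arr, scalar = _as_array(v, "v")
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise ValueError("v must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            2.0
            * alpha
            * np.exp((alpha - 1.0) * (np.log(arr) + np.log(2.0 - arr)))
            * (1.0 - arr)
        )
    return _restore(out, scalar)


# --------------------------------------------------------------------------
# pluggable model contract


@dataclass(frozen=True)
class ModelSpec:
    """Uniform contract for a positive-support lifetime model.

    ``log_density``, ``cdf`` and ``quantile`` take an array of evaluation
    points and a 1-D parameter vector ordered as ``param_names``.  Used by
    the fitting, simulation and comparison layers for the bundled family and
    for user-supplied competitor models.
    """

    label: str
    param_names: tuple
    log_density: Callable
    cdf: Callable
    quantile: Callable
    support_lower: float = 0.0

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __post_init__(self) -> None:
        if len(self.param_names) < 1:
            raise ValueError("a model needs at least one parameter")


TLEC = ModelSpec(
    label="TLEC",
    param_names=("alpha", "lam", "beta", "b"),
    log_density=lambda x, th: tlec_logpdf(x, TlecParams.from_array(th)),
    cdf=lambda x, th: tlec_cdf(x, TlecParams.from_array(th)),
    quantile=lambda p, th: tlec_quantile(p, TlecParams.from_array(th)),
)

EC = ModelSpec(
    label="EC",
    param_names=("lam", "beta", "b"),
    log_density=lambda x, th: ec_logpdf(x, th[0], th[1], th[2]),
    cdf=lambda x, th: ec_cdf(x, th[0], th[1], th[2]),
    quantile=lambda p, th: ec_quantile(p, th[0], th[1], th[2]),
)

CHEN = ModelSpec(
    label="CHEN",
    param_names=("lam", "beta"),
    log_density=lambda x, th: chen_logpdf(x, th[0], th[1]),
    cdf=lambda x, th: chen_cdf(x, th[0], th[1]),
    quantile=lambda p, th: chen_quantile(p, th[0], th[1]),
)

TLC = ModelSpec(
    label="TLC",
    param_names=("alpha", "lam", "beta"),
    log_density=lambda x, th: tlc_logpdf(x, th[0], th[1], th[2]),
    cdf=lambda x, th: tlc_cdf(x, th[0], th[1], th[2]),
    quantile=lambda p, th: tlc_quantile(p, th[0], th[1], th[2]),
)

_REGISTRY = {"tlec": TLEC, "ec": EC, "chen": CHEN, "tlc": TLC}


def get_model_spec(name) -> ModelSpec:
    """Look up a bundled :class:`ModelSpec` by name, or pass one through."""
    if isinstance(name, ModelSpec):
        return name
    key = str(name).lower()
    if key not in _REGISTRY:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(_REGISTRY)}")
    return _REGISTRY[key]
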