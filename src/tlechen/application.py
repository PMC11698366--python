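"""COVID-19 case-count datasets, multi-model comparison and diagnostic curves.

Two daily-count series from Saudi Arabia (1 January - 6 March 2022, 65 days
each, Ministry of Health surveillance data) ship with the package: daily
infected and daily recovered cases.  The counts are modelled directly as
continuous positive observations, with no continuity correction.

``compare_models`` fits a list of candidate lifetime models by multi-start
MLE and ranks them by information criteria.  ``k_policy`` controls the
penalty: ``"individual"`` (default) charges each model its own parameter
count; ``"uniform"`` charges every model the largest parameter count in the
comparison, the convention under which the original four-model comparison
tables for these data were computed.

The remaining functions emit plot-ready data (no figure rendering):
probability-probability pairs, empirical/fitted CDF curves and the fitted
reliability (survival) curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .distributions import ModelSpec, get_model_spec
from .estimation import FitResult, ParametricMLE, information_criteria

__all__ = [
    "Dataset",
    "load_dataset",
    "compare_models",
    "pp_plot_data",
    "ecdf_and_fitted_cdf",
    "reliability_curve",
]

_SOURCE = "Saudi Ministry of Health COVID-19 surveillance, https://covid19.moh.gov.sa"


@dataclass(frozen=True)
class Dataset:
    """A bundled one-column sample of daily counts."""

    label: str
    values: np.ndarray
    source: str = _SOURCE

    @property
    def n(self) -> int:
        return self.values.size


def load_dataset(label: str) -> Dataset:
    """Load a bundled dataset: ``"infected"`` or ``"recovered"`` daily cases."""
    key = str(label).lower()
    if key not in ("infected", "recovered"):
        raise ValueError(f"unknown dataset {label!r}; choose 'infected' or 'recovered'")
    with resources.files("tlechen.data").joinpath(f"{key}.csv").open("r") as fh:
        values = pd.read_csv(fh)[key].to_numpy(dtype=float)
    return Dataset(label=key, values=values)


def _data_values(data) -> np.ndarray:
    if isinstance(data, Dataset):
        return data.values
    return np.asarray(data, dtype=float).ravel()


def compare_models(
    data,
    models=("tlec", "ec", "chen", "tlc"),
    seed: int = 0,
    n_restarts: int = 20,
    level: float = 0.95,
    k_policy: str = "individual",
) -> pd.DataFrame:
    """Fit every candidate model and rank by AIC (ties broken by BIC).

    Returns one row per model with the estimates, -2 log-likelihood and the
    four information criteria; the fitted :class:`FitResult` objects are
    attached under ``df.attrs["fits"]``.  A model whose optimiser failed is
    kept in the table with ``converged=False``, never dropped.
    """
    if k_policy not in ("individual", "uniform"):
        raise ValueError(f"k_policy must be 'individual' or 'uniform', got {k_policy!r}")
    specs = [get_model_spec(m) for m in models]
    if not specs:
        raise ValueError("at least one model is required for a comparison")
    values = _data_values(data)
    k_max = max(s.n_params for s in specs)
    rows, fits = [], {}
    for spec in specs:
        fit = ParametricMLE(values, spec).fit(n_restarts=n_restarts, seed=seed, level=level)
        fits[spec.label] = fit
        k = k_max if k_policy == "uniform" else spec.n_params
        ic = information_criteria(fit.minus2loglik, k, fit.n_obs)
        rows.append(
            {
                "model_label": spec.label,
                "params_hat": tuple(map(float, fit.params_hat)),
                "se": tuple(map(float, fit.se)),
                "minus2loglik": fit.minus2loglik,
                "aic": ic.aic,
                "caic": ic.caic,
                "bic": ic.bic,
                "hqic": ic.hqic,
                "k": k,
                "converged": fit.converged,
            }
        )
    df = pd.DataFrame(rows).sort_values(["aic", "bic"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["fits"] = fits
    df.attrs["n_obs"] = int(values.size)
    return df


def _fit_cdf(fit: FitResult, x):
    if fit.spec is None:
        raise ValueError("FitResult carries no ModelSpec; cannot evaluate its CDF")
    return fit.spec.cdf(np.asarray(x, dtype=float), fit.params_hat)


def pp_plot_data(fit: FitResult, data):
    """Probability-probability pairs for a fitted model.

    For the sorted sample, pairs the plotting position (i - 0.5)/n with the
    fitted CDF at each order statistic.
    """
    values = np.sort(_data_values(data))
    n = values.size
    empirical = (np.arange(1, n + 1) - 0.5) / n
    theoretical = np.asarray(_fit_cdf(fit, values))
    return empirical, theoretical


def ecdf_and_fitted_cdf(fit: FitResult, data, n_grid: int = 200):
    """Empirical CDF step knots plus the fitted CDF on a regular grid.

    Returns a dict with ``ecdf_x``/``ecdf_y`` (knots at sorted unique values)
    and ``grid``/``cdf`` (fitted CDF on ``n_grid`` points over
    [0, 1.05 * max]).
    """
    values = _data_values(data)
    xs, counts = np.unique(values, return_counts=True)
    ys = np.cumsum(counts) / values.size
    grid = np.linspace(0.0, 1.05 * values.max(), int(n_grid))
    return {
        "ecdf_x": xs,
        "ecdf_y": ys,
        "grid": grid,
        "cdf": np.asarray(_fit_cdf(fit, grid)),
    }


def reliability_curve(fit: FitResult, grid):
    """Fitted survival (reliability) values 1 - F on the given grid."""
    grid = np.asarray(grid, dtype=float)
    return 1.0 - np.asarray(_fit_cdf(fit, grid))
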