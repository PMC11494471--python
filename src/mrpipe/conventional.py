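"""Conventional multivariable linear regression of annual cost on a smoking
exposure — the observational benchmark the IV analyses are compared against.
Subject to confounding by anything outside the covariate set."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConvEstimate", "multivariable_ols"]


@dataclass
class ConvEstimate:
    exposure: str
    beta: float
    se: float
    ci: tuple[float, float]
    n: int
    covariates: list[str]


def multivariable_ols(cost: np.ndarray, exposure: np.ndarray,
                      covariates: pd.DataFrame | np.ndarray | None = None,
                      exposure_label: str = "",
                      subset: np.ndarray | None = None) -> ConvEstimate:
    """OLS of cost on exposure plus covariates; ``subset`` (boolean mask)
    restricts the fit, e.g. to ever-smokers for the CSI-among-smokers
    estimate."""
    import statsmodels.api as sm

    y = np.asarray(cost, float)
    x = np.asarray(exposure, float)
    cov_names: list[str] = []
    if isinstance(covariates, pd.DataFrame):
        cov_names = list(covariates.columns)
        covariates = covariates.to_numpy(dtype=float)
    if subset is not None:
        subset = np.asarray(subset, bool)
        if subset.sum() == 0:
            raise ValueError("empty subset")
        y, x = y[subset], x[subset]
        if covariates is not None:
            covariates = covariates[subset]
    if x.std() == 0:
        raise ValueError("exposure is constant in the analysis sample")
    n = y.shape[0]
    X = np.column_stack([np.ones(n), x]) if covariates is None \
        else np.column_stack([np.ones(n), x, covariates])
    fit = sm.OLS(y, X).fit()
    b, s = float(fit.params[1]), float(fit.bse[1])
    return ConvEstimate(exposure=exposure_label, beta=b, se=s,
                        ci=(b - 1.96 * s, b + 1.96 * s), n=n,
                        covariates=cov_names)
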