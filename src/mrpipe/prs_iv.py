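"""Polygenic risk scores and one-sample two-stage least squares.

The PRS is the weighted sum of effect-allele dosages (weights = per-SNP GWAS
coefficients from the *other* split half, to avoid sample-overlap bias); the
IV model is standard 2SLS with first-stage F and partial R^2 diagnostics and
a fixed-effect inverse-variance meta-analysis to pool the two split halves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic_cohort import GenotypeMatrix
from .association_scan import harmonize

__all__ = [
    "WeakInstrumentWarning",
    "IVEstimate",
    "MetaEstimate",
    "build_prs",
    "variance_explained",
    "two_stage_least_squares",
    "fixed_effect_meta",
]

WEAK_F_THRESHOLD = 10.0


class WeakInstrumentWarning(UserWarning):
    """First-stage F below the conventional threshold of 10."""


@dataclass
class IVEstimate:
    beta: float
    se: float
    ci: tuple[float, float]
    first_stage_F: float
    first_stage_R2: float
    n: int
    exposure: str = ""

    @classmethod
    def _make(cls, beta, se, F, R2, n, exposure=""):
        return cls(beta=float(beta), se=float(se),
                   ci=(float(beta - 1.96 * se), float(beta + 1.96 * se)),
                   first_stage_F=float(F), first_stage_R2=float(R2),
                   n=int(n), exposure=exposure)


@dataclass
class MetaEstimate:
    beta: float
    se: float
    ci: tuple[float, float]
    components: list = field(default_factory=list)


def build_prs(G: GenotypeMatrix, weights: pd.DataFrame) -> np.ndarray:
    """score_i = sum_j w_j * dosage_ij over the SNPs in ``weights``.

    ``weights`` needs columns snp_id, effect_allele, other_allele, beta;
    alleles are harmonized to the genotype file (flipping beta and dosage
    orientation where swapped), and any SNP that cannot be harmonized raises.
    """
    w = harmonize(weights, G)
    cols = [G.snp_ids.index(s) for s in w["snp_id"]]
    dos = G.dosages[:, cols].astype(float)
    return dos @ w["beta"].to_numpy(dtype=float)


def variance_explained(score: np.ndarray, phenotype: np.ndarray,
                       binary: bool = False) -> float:
    """Proportion of phenotype variance the score explains: OLS R^2 for
    continuous phenotypes, McFadden pseudo-R^2 from a logistic fit for
    binary ones."""
    score = np.asarray(score, float)
    y = np.asarray(phenotype, float)
    if score.std() == 0:
        raise ValueError("score is constant")
    if y.std() == 0:
        raise ValueError("phenotype is constant")
    if binary:
        import statsmodels.api as sm
        X = np.column_stack([np.ones_like(score), score])
        fit = sm.Logit(y, X).fit(disp=0)
        return float(1.0 - fit.llf / fit.llnull)
    r = np.corrcoef(score, y)[0, 1]
    return float(r ** 2)


def _as_2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def two_stage_least_squares(outcome: np.ndarray, exposure: np.ndarray,
                            instruments: np.ndarray,
                            covariates: np.ndarray | pd.DataFrame | None = None,
                            robust: bool = False,
                            exposure_label: str = "") -> IVEstimate:
    """One-sample 2SLS of ``outcome`` on ``exposure`` instrumented by
    ``instruments`` with exogenous ``covariates``.

    First stage regresses the exposure on instruments + covariates; the
    fitted exposure replaces the observed one in the second stage. Standard
    errors use the IV asymptotic formula with residuals from the *observed*
    exposure (homoskedastic by default, HC1 sandwich with ``robust=True``).
    ``first_stage_F`` is the joint F of the instruments partialling out the
    covariates; ``first_stage_R2`` the corresponding partial R^2. F below 10
    triggers a weak-instrument warning.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    Z = _as_2d(instruments)
    n = y.shape[0]
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.to_numpy(dtype=float)
    C = np.column_stack([np.ones(n)]) if covariates is None \
        else np.column_stack([np.ones(n), np.asarray(covariates, float)])
    k = Z.shape[1]

    # first stage and instrument-strength diagnostics
    ZC = np.column_stack([C, Z])
    if np.linalg.matrix_rank(ZC) < ZC.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient first stage design")
    coef1, *_ = np.linalg.lstsq(ZC, x, rcond=None)
    xhat = ZC @ coef1
    rss_u = float(np.sum((x - xhat) ** 2))
    coef0, *_ = np.linalg.lstsq(C, x, rcond=None)
    rss_r = float(np.sum((x - C @ coef0) ** 2))
    df2 = n - ZC.shape[1]
    F = ((rss_r - rss_u) / k) / (rss_u / df2) if rss_u > 0 else np.inf
    R2 = (rss_r - rss_u) / rss_r if rss_r > 0 else 0.0
    if F < WEAK_F_THRESHOLD:
        warnings.warn(f"first-stage F = {F:.2f} < 10: weak instrument(s)",
                      WeakInstrumentWarning)

    # second stage with fitted exposure; exposure coefficient is last
    Xhat = np.column_stack([C, xhat])
    X = np.column_stack([C, x])
    XtX = Xhat.T @ Xhat
    beta_all = np.linalg.solve(XtX, Xhat.T @ y)
    resid = y - X @ beta_all  # structural residuals use the observed exposure
    p = Xhat.shape[1]
    XtX_inv = np.linalg.inv(XtX)
    if robust:
        meat = Xhat.T @ (Xhat * (resid ** 2)[:, None])
        cov = XtX_inv @ meat @ XtX_inv * n / (n - p)
    else:
        sigma2 = float(resid @ resid) / (n - p)
        cov = sigma2 * XtX_inv
    beta = beta_all[-1]
    se = float(np.sqrt(cov[-1, -1]))
    return IVEstimate._make(beta, se, F, R2, n, exposure_label)


def fixed_effect_meta(estimates: list) -> MetaEstimate:
    """Inverse-variance fixed-effect pooling: beta = sum(w b)/sum(w),
    se = sum(w)^(-1/2) with w = 1/se^2. A single estimate passes through
    (with a note)."""
    if len(estimates) == 0:
        raise ValueError("no estimates to pool")
    betas = np.array([e.beta for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    if len(estimates) == 1:
        warnings.warn("single estimate: meta-analysis is a passthrough")
        b, s = float(betas[0]), float(ses[0])
    else:
        w = 1.0 / ses ** 2
        b = float(np.sum(w * betas) / np.sum(w))
        s = float(np.sum(w) ** -0.5)
    return MetaEstimate(beta=b, se=s, ci=(b - 1.96 * s, b + 1.96 * s),
                        components=list(estimates))
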