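"""Sensitivity battery: Steiger directionality filtering, the ever/never
heaviness-SNP interaction check, and multivariable MR with conditional
instrument-strength diagnostics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association_scan import InstrumentSet

__all__ = [
    "SteigerResult",
    "InteractionResult",
    "MVMRResult",
    "steiger_filter",
    "interaction_test",
    "mvmr_estimate",
]


# ---------------------------------------------------------------------------
# Steiger directionality
# ---------------------------------------------------------------------------

@dataclass
class SteigerResult:
    snp_id: str
    r_exposure: float
    r_outcome: float
    direction_correct: bool
    steiger_p: float


def _r_from_stats(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> np.ndarray:
    """SNP-trait correlation recovered from the regression t-statistic:
    r = t / sqrt(t^2 + n - 2). For a binary trait fitted by a linear model
    this is the point-biserial correlation."""
    t = beta / se
    return t / np.sqrt(t ** 2 + n - 2)


def steiger_filter(exposure_stats: pd.DataFrame, outcome_stats: pd.DataFrame,
                   n_exp: int | None = None, n_out: int | None = None
                   ) -> tuple[list[SteigerResult], InstrumentSet]:
    """Per SNP, compare the variance explained in exposure vs outcome.

    A SNP is directionally consistent with exposure -> outcome when
    r_exposure^2 > r_outcome^2. The two-sided p-value comes from the Fisher
    z difference z = (atanh|r_e| - atanh|r_o|) / sqrt(1/(n_e-3) + 1/(n_o-3)).
    Ties (r_e = r_o) are kept with a warning. Returns the per-SNP results and
    the filtered instrument set.
    """
    merged = exposure_stats.merge(outcome_stats, on="snp_id",
                                  suffixes=("_exp", "_out"))
    ne = np.asarray(merged["n_exp"] if n_exp is None else n_exp, dtype=float)
    no = np.asarray(merged["n_out"] if n_out is None else n_out, dtype=float)
    if np.any(ne <= 3) or np.any(no <= 3):
        raise ValueError("sample sizes must exceed 3")
    r_e = _r_from_stats(merged["beta_exp"].to_numpy(), merged["se_exp"].to_numpy(), ne)
    r_o = _r_from_stats(merged["beta_out"].to_numpy(), merged["se_out"].to_numpy(), no)
    z = (np.arctanh(np.abs(r_e)) - np.arctanh(np.abs(r_o))) \
        / np.sqrt(1.0 / (ne - 3) + 1.0 / (no - 3))
    p = 2 * sps.norm.sf(np.abs(z))
    results = []
    keep = []
    for i, sid in enumerate(merged["snp_id"]):
        correct = bool(r_e[i] ** 2 > r_o[i] ** 2)
        results.append(SteigerResult(snp_id=sid, r_exposure=float(r_e[i]),
                                     r_outcome=float(r_o[i]),
                                     direction_correct=correct,
                                     steiger_p=float(p[i])))
        if correct:
            keep.append(i)
        elif r_e[i] ** 2 == r_o[i] ** 2:
            warnings.warn(f"SNP {sid}: tied variance explained, kept")
            keep.append(i)
    cols = [c for c in exposure_stats.columns]
    kept_ids = set(merged["snp_id"].iloc[keep])
    filtered = exposure_stats[exposure_stats["snp_id"].isin(kept_ids)]
    inst = InstrumentSet(stats=filtered.reset_index(drop=True)[cols],
                         p_threshold=np.nan, r2_threshold=np.nan)
    return results, inst


# ---------------------------------------------------------------------------
# ever/never interaction check (CHRNA5-style)
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    beta_ever: float
    se_ever: float
    beta_never: float
    se_never: float
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    n_ever: int
    n_never: int


def _ols_beta_se(y: np.ndarray, X: np.ndarray, col: int) -> tuple[float, float]:
    import statsmodels.api as sm
    fit = sm.OLS(y, X).fit()
    return float(fit.params[col]), float(fit.bse[col])


def interaction_test(cost: np.ndarray, dosage: np.ndarray,
                     initiation: np.ndarray,
                     covariates: np.ndarray | pd.DataFrame | None = None,
                     min_stratum: int = 30) -> InteractionResult:
    """Cost on a smoking-heaviness SNP, stratified by ever/never smoking.

    A variant that affects costs only through smoking heaviness should show
    an effect among ever-smokers and none among never-smokers; both the
    stratified coefficients and the full-sample dosage x initiation product
    term are reported.
    """
    y = np.asarray(cost, float)
    d = np.asarray(dosage, float)
    init = np.asarray(initiation, float)
    n = y.shape[0]
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.to_numpy(dtype=float)
    Xc = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    ever = init > 0
    n_ever, n_never = int(ever.sum()), int((~ever).sum())
    if n_ever < min_stratum or n_never < min_stratum:
        raise ValueError(
            f"degenerate stratum: ever={n_ever}, never={n_never} "
            f"(minimum {min_stratum})")
    for mask, name in ((ever, "ever"), (~ever, "never")):
        if d[mask].std() == 0:
            raise ValueError(f"dosage constant within {name} stratum")
    def stratum(mask):
        X = np.column_stack([np.ones(mask.sum()), d[mask], Xc[mask]])
        return _ols_beta_se(y[mask], X, 1)
    b_e, s_e = stratum(ever)
    b_n, s_n = stratum(~ever)
    X = np.column_stack([np.ones(n), d, init, d * init, Xc])
    import statsmodels.api as sm
    fit = sm.OLS(y, X).fit()
    b_i, s_i = float(fit.params[3]), float(fit.bse[3])
    p_i = 2 * sps.norm.sf(abs(b_i / s_i))
    return InteractionResult(beta_ever=b_e, se_ever=s_e, beta_never=b_n,
                             se_never=s_n, beta_interaction=b_i,
                             se_interaction=s_i, p_interaction=float(p_i),
                             n_ever=n_ever, n_never=n_never)


# ---------------------------------------------------------------------------
# multivariable MR
# ---------------------------------------------------------------------------

@dataclass
class MVMRResult:
    exposures: list[str]
    betas: np.ndarray
    ses: np.ndarray
    cis: list[tuple[float, float]]
    conditional_F: np.ndarray
    weak: bool
    n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": self.exposures,
            "beta": self.betas,
            "se": self.ses,
            "ci_low": [c[0] for c in self.cis],
            "ci_high": [c[1] for c in self.cis],
            "conditional_F": self.conditional_F,
            "weak": self.weak,
        })


def mvmr_estimate(outcome: np.ndarray, exposures: np.ndarray,
                  instruments: np.ndarray,
                  covariates: np.ndarray | pd.DataFrame | None = None,
                  exposure_labels: list[str] | None = None,
                  weak_threshold: float = 10.0) -> MVMRResult:
    """Individual-level multivariable MR: all exposures jointly instrumented
    in a single 2SLS, giving each exposure's direct effect (not via the
    others).

    Conditional instrument strength per exposure uses the regression-
    partialling form: exposure k is residualized on the instrument-predicted
    values of the other exposures (and covariates), the residual regressed
    on the instruments, and the joint F computed with numerator df
    J - (m - 1) for J instruments and m exposures. Any conditional F below
    ``weak_threshold`` sets the weak flag.
    """
    y = np.asarray(outcome, float)
    E = np.asarray(exposures, float)
    if E.ndim == 1:
        E = E[:, None]
    Z = np.asarray(instruments, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, m = E.shape
    J = Z.shape[1]
    if m < 2:
        raise ValueError("multivariable MR needs >= 2 exposures")
    if J < m:
        raise ValueError("need at least as many instruments as exposures")
    if np.linalg.matrix_rank(E - E.mean(axis=0)) < m:
        raise np.linalg.LinAlgError("exposures are collinear")
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.to_numpy(dtype=float)
    C = np.column_stack([np.ones(n)]) if covariates is None \
        else np.column_stack([np.ones(n), np.asarray(covariates, float)])
    labels = exposure_labels or [f"exposure{k + 1}" for k in range(m)]

    ZC = np.column_stack([C, Z])
    coef1, *_ = np.linalg.lstsq(ZC, E, rcond=None)
    Ehat = ZC @ coef1
    if np.linalg.matrix_rank(Ehat - Ehat.mean(axis=0)) < m:
        raise np.linalg.LinAlgError(
            "instrument-predicted exposures are collinear")
    Xhat = np.column_stack([C, Ehat])
    X = np.column_stack([C, E])
    XtX = Xhat.T @ Xhat
    beta_all = np.linalg.solve(XtX, Xhat.T @ y)
    resid = y - X @ beta_all
    p = Xhat.shape[1]
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(XtX)
    betas = beta_all[-m:]
    ses = np.sqrt(np.diag(cov))[-m:]

    # Sanderson-Windmeijer-style conditional F per exposure
    condF = np.empty(m)
    df1 = J - (m - 1)
    if df1 < 1:
        raise ValueError("too few instruments for conditional F")
    for k in range(m):
        others = Ehat[:, [j for j in range(m) if j != k]]
        base = np.column_stack([C, others])
        coef_b, *_ = np.linalg.lstsq(base, E[:, k], rcond=None)
        rss_r = float(np.sum((E[:, k] - base @ coef_b) ** 2))
        full = np.column_stack([base, Z])
        coef_f, *_ = np.linalg.lstsq(full, E[:, k], rcond=None)
        rss_u = float(np.sum((E[:, k] - full @ coef_f) ** 2))
        df2 = n - full.shape[1]
        condF[k] = ((rss_r - rss_u) / df1) / (rss_u / df2) if rss_u > 0 else np.inf
    weak = bool(np.any(condF < weak_threshold))
    if weak:
        warnings.warn("conditional F below 10 for at least one exposure: "
                      "inference may be unreliable")
    return MVMRResult(exposures=labels, betas=betas, ses=ses,
                      cis=[(float(b - 1.96 * s), float(b + 1.96 * s))
                           for b, s in zip(betas, ses)],
                      conditional_F=condF, weak=weak, n=n)
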