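"""Summary-statistic MR estimators: per-SNP Wald ratios, inverse-variance
weighting with Cochran's Q, MR-Egger, the (penalized) weighted median and
the weighted mode, each returning a tagged estimate with 95% CI.

All estimators operate on per-SNP exposure/outcome association statistics and
differ in which subset of instruments they require to be valid: IVW needs all
(or balanced pleiotropy), Egger tolerates directional pleiotropy under
InSIDE, the weighted median needs >= 50% of weight from valid SNPs, and the
mode only the largest homogeneous cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "QResult",
    "wald_ratio",
    "wald_ratios",
    "ivw",
    "cochran_q",
    "egger",
    "weighted_median",
    "mode_estimate",
]


@dataclass
class RatioEstimate:
    """Single-SNP Wald ratio beta_out/beta_exp with delta-method SE."""

    snp_id: str
    ratio: float
    se: float
    order: int = 1


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    ci: tuple[float, float]
    nsnp: int
    auxiliary: dict = field(default_factory=dict)

    @classmethod
    def _make(cls, method, beta, se, nsnp, **aux):
        return cls(method=method, beta=float(beta), se=float(se),
                   ci=(float(beta - 1.96 * se), float(beta + 1.96 * se)),
                   nsnp=int(nsnp), auxiliary=aux)


@dataclass
class QResult:
    Q: float
    df: int
    p: float


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               snp_id: str = "", order: int = 1) -> RatioEstimate:
    """ratio = beta_out / beta_exp.

    First-order SE: se_out/|beta_exp|. Second order adds the exposure
    uncertainty term beta_out^2 se_exp^2 / beta_exp^4 under the delta method.
    """
    if beta_exp == 0:
        raise ValueError("Wald ratio undefined for beta_exp = 0")
    if se_out <= 0 or se_exp < 0:
        raise ValueError("standard errors must be positive")
    ratio = beta_out / beta_exp
    var = se_out ** 2 / beta_exp ** 2
    if order == 2:
        var = var + beta_out ** 2 * se_exp ** 2 / beta_exp ** 4
    elif order != 1:
        raise ValueError("order must be 1 or 2")
    return RatioEstimate(snp_id=snp_id, ratio=float(ratio),
                         se=float(np.sqrt(var)), order=order)


def wald_ratios(exposure_stats, outcome_stats, order: int = 1) -> list[RatioEstimate]:
    """Per-SNP ratios from two aligned summary-stat tables (inner join on
    snp_id; alleles assumed already harmonized)."""
    merged = exposure_stats.merge(outcome_stats, on="snp_id",
                                  suffixes=("_exp", "_out"))
    return [wald_ratio(r.beta_exp, r.se_exp, r.beta_out, r.se_out,
                       snp_id=r.snp_id, order=order)
            for r in merged.itertuples()]


def _arrays(ratios) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    b = np.array([r.ratio for r in ratios], dtype=float)
    s = np.array([r.se for r in ratios], dtype=float)
    return b, s, 1.0 / s ** 2


def cochran_q(ratios, pooled: float) -> QResult:
    """Q = sum_j (1/sigma_j^2)(beta_j - pooled)^2, upper chi^2_{J-1} tail."""
    b, s, w = _arrays(ratios)
    Q = float(np.sum(w * (b - pooled) ** 2))
    df = max(len(b) - 1, 1)
    return QResult(Q=Q, df=df, p=float(sps.chi2.sf(Q, df)))


def ivw(ratios, random_effects: bool = True) -> tuple[MREstimate, QResult]:
    """Inverse-variance-weighted pooling of Wald ratios.

    Fixed effect: beta = sum(w b)/sum(w), se = sum(w)^(-1/2), w = 1/se^2.
    The random-effects variant (default) inflates the SE multiplicatively by
    max(1, sqrt(Q/(J-1))) — a multiplicative-overdispersion model that nests
    the fixed-effect estimator when the ratios are homogeneous.
    """
    if len(ratios) < 2:
        raise ValueError("IVW requires >= 2 ratios; use wald_ratio for one SNP")
    b, s, w = _arrays(ratios)
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = cochran_q(ratios, beta)
    se = se_fixed
    method = "IVW-FE"
    if random_effects:
        se = se_fixed * max(1.0, np.sqrt(q.Q / q.df))
        method = "IVW-RE"
    est = MREstimate._make(method, beta, se, len(b), se_fixed=se_fixed,
                           Q=q.Q, Q_df=q.df, Q_p=q.p)
    return est, q


def egger(beta_exp, se_exp, beta_out, se_out,
          floor_dispersion: bool = False) -> MREstimate:
    """MR-Egger: WLS of outcome betas on exposure betas with an intercept,
    weights 1/se_out^2, exposure betas oriented positive.

    The slope is the causal estimate; the intercept estimates the average
    directional pleiotropic effect, and an intercept significantly different
    from zero indicates horizontal pleiotropy. SEs use the estimated
    multiplicative WLS dispersion with t inference on J-2 df, which keeps
    the intercept test exactly calibrated at the 10-20-SNP instrument counts
    typical here; ``floor_dispersion=True`` instead floors the dispersion at
    1 (the convention of several summary-MR packages, slightly conservative).
    """
    bx = np.asarray(beta_exp, float)
    by = np.asarray(beta_out, float)
    sy = np.asarray(se_out, float)
    J = bx.size
    if J < 3:
        raise ValueError("MR-Egger requires >= 3 SNPs")
    if np.any(bx == 0):
        raise ValueError("exposure betas must be non-zero")
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(J), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ by)
    resid = by - X @ coef
    dispersion = float(np.sum(w * resid ** 2) / (J - 2))
    scale = max(dispersion, 1.0) if floor_dispersion else dispersion
    cov = np.linalg.inv(XtWX) * scale
    inter, slope = coef
    se_inter, se_slope = np.sqrt(np.diag(cov))
    p_inter = 2 * sps.t.sf(abs(inter / se_inter), J - 2) if se_inter > 0 else np.nan
    return MREstimate._make("Egger", slope, se_slope, J,
                            intercept=float(inter),
                            intercept_se=float(se_inter),
                            intercept_p=float(p_inter),
                            dispersion=dispersion)


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b)
    b, w = b[order], w[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weight per SNP
    return float(np.interp(0.5, cum, b))


def weighted_median(ratios, penalized: bool = False, n_boot: int = 1000,
                    rng: np.random.Generator | int | None = 0,
                    penalty_scale: float = 20.0) -> MREstimate:
    """Weighted median of ordered Wald ratios, consistent when >= 50% of the
    weight comes from valid instruments.

    Weights are 1/se^2, cumulated to their midpoints and interpolated at
    cumulative weight 0.5. The penalized variant down-weights outlying SNPs
    by min(1, penalty_scale * p_j) where p_j is the upper chi^2_1 tail of the
    SNP's contribution to Cochran's Q. SE by seeded parametric bootstrap.
    """
    if len(ratios) < 3:
        raise ValueError("weighted median requires >= 3 SNPs")
    b, s, w = _arrays(ratios)
    if penalized:
        ivw_beta = float(np.sum(w * b) / np.sum(w))
        qj = w * (b - ivw_beta) ** 2
        w = w * np.minimum(1.0, penalty_scale * sps.chi2.sf(qj, 1))
    est = _weighted_median(b, w)
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    draws = rng.normal(b, s, size=(n_boot, b.size))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bi = draws[i]
        wi = 1.0 / s ** 2
        if penalized:
            ivw_b = float(np.sum(wi * bi) / np.sum(wi))
            qj = wi * (bi - ivw_b) ** 2
            wi = wi * np.minimum(1.0, penalty_scale * sps.chi2.sf(qj, 1))
        boots[i] = _weighted_median(bi, wi)
    se = float(boots.std(ddof=1))
    method = "weighted-median-penalized" if penalized else "weighted-median"
    return MREstimate._make(method, est, se, b.size)


def _mode_bandwidth(b: np.ndarray) -> float:
    """Modified Silverman rule: 0.9 min(sd, mad/0.6745) J^(-1/5), falling
    back to the sd when the MAD degenerates to 0."""
    sd = float(np.std(b, ddof=1))
    mad = float(np.median(np.abs(b - np.median(b)))) / 0.6745
    spread = min(sd, mad) if mad > 0 else sd
    return 0.9 * spread * b.size ** (-1 / 5)


def _kde_mode(b: np.ndarray, w: np.ndarray, h: float, grid_size: int = 512) -> float:
    lo, hi = b.min() - 3 * h, b.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def mode_estimate(ratios, phi: float = 1.0, n_boot: int = 1000,
                  rng: np.random.Generator | int | None = 0) -> MREstimate:
    """Weighted mode of the Wald ratios: the maximum of an inverse-variance
    weighted Gaussian kernel density, consistent when the largest homogeneous
    cluster of SNPs is valid.

    Bandwidth = phi * 0.9 * min(sd, mad/0.6745) * J^(-1/5) (modified
    Silverman rule); SE by seeded parametric bootstrap.
    """
    if len(ratios) < 3:
        raise ValueError("mode estimator requires >= 3 SNPs")
    b, s, w = _arrays(ratios)
    w = w / w.sum()
    if np.ptp(b) == 0:
        # all ratios identical: the mode is that value exactly
        return MREstimate._make("mode", b[0], float(np.min(s)), b.size,
                                bandwidth=0.0)
    h = phi * _mode_bandwidth(b)
    est = _kde_mode(b, w, h)
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    draws = rng.normal(b, s, size=(n_boot, b.size))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bi = draws[i]
        hi = phi * max(_mode_bandwidth(bi), 1e-12)
        boots[i] = _kde_mode(bi, w, hi)
    se = float(boots.std(ddof=1))
    return MREstimate._make("mode", est, se, b.size, bandwidth=float(h),
                            phi=float(phi))
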