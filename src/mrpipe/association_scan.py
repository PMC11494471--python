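"""Split-sample instrument discovery: per-SNP association scans,
genome-wide-significance selection and greedy LD clumping, plus
GWAS-SSF-style summary-statistic I/O with allele harmonization."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic_cohort import Cohort, GenotypeMatrix

__all__ = [
    "SUMMARY_COLUMNS",
    "InstrumentSet",
    "split_sample",
    "snp_association",
    "select_and_clump",
    "ld_r2_matrix",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
]

SUMMARY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "eaf",
                   "beta", "se", "p", "n"]


@dataclass
class InstrumentSet:
    """Summary statistics of the retained instruments plus selection metadata."""

    stats: pd.DataFrame
    p_threshold: float
    r2_threshold: float
    dropped: list[str] = field(default_factory=list)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.stats["snp_id"])

    def __len__(self) -> int:
        return len(self.stats)


def split_sample(cohort: Cohort, fraction: float = 0.5,
                 seed: int | np.random.Generator = 0,
                 return_indices: bool = False):
    """Random disjoint, exhaustive split; first part has ceil(fraction*n) rows.

    Splitting the cohort before instrument discovery avoids the bias toward
    the observational association that arises when the same sample both
    selects the SNPs and estimates the IV model. With ``return_indices`` the
    row indices of each half are returned alongside the cohorts.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = cohort.n
    perm = rng.permutation(n)
    k = int(np.ceil(fraction * n))
    a, b = np.sort(perm[:k]), np.sort(perm[k:])
    halves = (cohort.subset(a), cohort.subset(b))
    if return_indices:
        return halves, (a, b)
    return halves


def _residualize(y: np.ndarray, X: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Residuals of y on [1, X]; returns residuals and number of fitted cols."""
    n = y.shape[0]
    if X is None or X.size == 0:
        return y - y.mean(axis=0), 1
    design = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef, design.shape[1]


def snp_association(G: GenotypeMatrix, phenotype: np.ndarray,
                    covariates: np.ndarray | pd.DataFrame | None = None,
                    model: str = "linear",
                    n_label: int | None = None) -> pd.DataFrame:
    """Per-SNP regression of phenotype on dosage plus covariates.

    The linear scan (default, used for both continuous and 0/1 phenotypes)
    exploits Frisch-Waugh-Lovell partialling: phenotype and dosages are
    residualized on the covariates once, then each SNP is a simple
    regression — identical point estimates and standard errors to per-SNP
    multiple OLS, at O(nJ) cost. Two-sided p-values use the normal
    approximation. ``model="logistic"`` fits per-SNP logistic regressions
    (slower; binary phenotypes only).

    Constant dosage columns are excluded with a warning.
    """
    y = np.asarray(phenotype, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.to_numpy(dtype=float)
    n, J = G.n, G.n_snps
    if y.shape[0] != n:
        raise ValueError("phenotype length must match genotypes")
    dos = G.dosages.astype(float)
    keep = dos.std(axis=0) > 0
    if not keep.all():
        bad = [G.snp_ids[j] for j in np.flatnonzero(~keep)]
        warnings.warn(f"excluding constant dosage columns: {bad}")
    eaf = dos.mean(axis=0) / 2.0

    if model == "logistic":
        rows = []
        import statsmodels.api as sm
        Xc = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
        for j in range(J):
            if not keep[j]:
                continue
            X = np.column_stack([np.ones(n), dos[:, j], Xc])
            fit = sm.Logit(y, X).fit(disp=0)
            b, s = fit.params[1], fit.bse[1]
            rows.append((G.snp_ids[j], G.effect_allele[j], G.other_allele[j],
                         eaf[j], b, s, 2 * sps.norm.sf(abs(b / s)), n))
        return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)

    if model != "linear":
        raise ValueError("model must be 'linear' or 'logistic'")
    y_r, k_cov = _residualize(y, covariates)
    d_r, _ = _residualize(dos, covariates)
    ss_d = np.einsum("ij,ij->j", d_r, d_r)
    ss_d_safe = np.where(keep, ss_d, 1.0)
    beta = (d_r * y_r[:, None]).sum(axis=0) / ss_d_safe
    rss = y_r @ y_r - beta ** 2 * ss_d_safe
    dof = n - k_cov - 1
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / ss_d_safe)
    z = beta / se
    p = 2 * sps.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "snp_id": G.snp_ids,
        "effect_allele": G.effect_allele,
        "other_allele": G.other_allele,
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "p": p,
        "n": n_label if n_label is not None else n,
    })
    return out[keep].reset_index(drop=True)


def ld_r2_matrix(G: GenotypeMatrix, snp_ids: list[str] | None = None) -> pd.DataFrame:
    """Pairwise dosage-correlation r^2 within the sample (no reference panel)."""
    ids = snp_ids if snp_ids is not None else G.snp_ids
    cols = [G.snp_ids.index(s) for s in ids]
    dos = G.dosages[:, cols].astype(float)
    sd = dos.std(axis=0)
    if np.any(sd == 0):
        const = [ids[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant dosage for SNPs {const}: LD undefined")
    r = np.corrcoef(dos, rowvar=False)
    if r.ndim == 0:  # single SNP
        r = np.array([[1.0]])
    return pd.DataFrame(r ** 2, index=ids, columns=ids)


def select_and_clump(stats: pd.DataFrame, p_threshold: float = 5e-8,
                     ld_matrix: pd.DataFrame | None = None,
                     r2_threshold: float = 0.001) -> InstrumentSet:
    """Greedy p-value-ranked clumping: keep a significant SNP iff its LD r^2
    with every already-kept SNP is below ``r2_threshold``. An empty result is
    valid and signals no usable instruments."""
    cand = stats[stats["p"] < p_threshold].sort_values(
        ["p", "snp_id"], kind="mergesort").reset_index(drop=True)
    kept: list[int] = []
    dropped: list[str] = []
    for i in range(len(cand)):
        sid = cand.at[i, "snp_id"]
        ok = True
        if ld_matrix is not None:
            for j in kept:
                other = cand.at[j, "snp_id"]
                if float(ld_matrix.loc[sid, other]) >= r2_threshold:
                    ok = False
                    break
        if ok:
            kept.append(i)
        else:
            dropped.append(sid)
    return InstrumentSet(stats=cand.iloc[kept].reset_index(drop=True),
                         p_threshold=p_threshold, r2_threshold=r2_threshold,
                         dropped=dropped)


# ---------------------------------------------------------------------------
# summary-statistic I/O and harmonization
# ---------------------------------------------------------------------------

def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a GWAS-SSF-style TSV and validate se > 0, p in [0, 1]."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats missing columns: {missing}")
    if (df["se"] <= 0).any():
        raise ValueError("summary stats contain non-positive standard errors")
    if ((df["p"] < 0) | (df["p"] > 1)).any():
        raise ValueError("summary stats contain p-values outside [0, 1]")
    return df[SUMMARY_COLUMNS]


def harmonize(stats: pd.DataFrame, G: GenotypeMatrix) -> pd.DataFrame:
    """Align summary statistics to the genotype file's effect alleles.

    When effect/other alleles are swapped relative to the genotype matrix the
    beta is negated and the EAF reflected (1 - eaf); allele pairs that match
    neither orientation raise."""
    out = stats.copy()
    alleles = {sid: (ea, oa) for sid, ea, oa in
               zip(G.snp_ids, G.effect_allele, G.other_allele)}
    for i in out.index:
        sid = out.at[i, "snp_id"]
        if sid not in alleles:
            raise ValueError(f"SNP {sid} absent from genotype matrix")
        ea, oa = alleles[sid]
        if (out.at[i, "effect_allele"], out.at[i, "other_allele"]) == (ea, oa):
            continue
        if (out.at[i, "effect_allele"], out.at[i, "other_allele"]) == (oa, ea):
            out.at[i, "beta"] = -out.at[i, "beta"]
            out.at[i, "eaf"] = 1.0 - out.at[i, "eaf"]
            out.at[i, "effect_allele"], out.at[i, "other_allele"] = ea, oa
        else:
            raise ValueError(f"allele mismatch for SNP {sid}: cannot harmonize")
    return out
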