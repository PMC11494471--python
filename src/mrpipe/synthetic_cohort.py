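"""Synthetic cohort generator calibrated to UK-Biobank-style smoking/cost data.

Generates genotypes, covariates, smoking phenotypes and annual inpatient
hospital costs with the statistical structure a Mendelian-randomization
analysis of smoking on costs assumes: genetic liability to smoking initiation,
a composite smoking index (CSI) on [0, 4] that is zero iff never-smoker, a
zero-inflated lognormal cost outcome, confounding through risk tolerance and
deprivation, and optional horizontal pleiotropy and participation selection so
that the sensitivity analyses have something real to detect.

Calibration anchors (population descriptives the defaults reproduce):
mean annual cost ~ GBP 478, median ~ GBP 87, 45% zero costs, ever-smoker
prevalence 29.2%, mean CSI among smokers ~ 1.14 (sd 0.78).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PleiotropySpec",
    "ConfounderEffects",
    "CostModel",
    "SelectionSpec",
    "SimulationConfig",
    "GenotypeMatrix",
    "Cohort",
    "compute_csi",
    "generate_genotypes",
    "generate_covariates",
    "assign_smoking",
    "generate_costs",
    "apply_selection",
    "simulate_cohort",
]

# Fraction of ever-smokers: 87,651 of 300,045 analyzed individuals.
DEFAULT_PREVALENCE = 0.29213
# Zero-inflated lognormal solved so that the marginal cost distribution has
# mean 478 and median 87 with a 45% zero mass:
#   0.55 * exp(mu + sigma^2/2) = 478,  exp(mu - 1.3352 sigma) = 87.
DEFAULT_ZERO_MASS = 0.45
DEFAULT_LOG_MEAN = 6.0569
DEFAULT_LOG_SD = 1.1918
# Gamma moment-matched to smoker CSI mean 1.14, sd 0.78.
DEFAULT_CSI_SHAPE = 2.136
DEFAULT_CSI_SCALE = 0.5337


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PleiotropySpec:
    """Direct (exclusion-restriction-violating) SNP effects on cost.

    ``fraction_invalid`` of the causal (instrument-eligible) SNPs receive a
    direct additive effect of ``mean_direct_effect`` GBP per effect allele;
    with ``balanced`` the sign of each effect is randomized so the net bias
    is approximately zero.
    """

    fraction_invalid: float = 0.0
    mean_direct_effect: float = 0.0
    balanced: bool = False


@dataclass
class ConfounderEffects:
    """Paths from non-genetic covariates into liability and cost (GBP per SD
    for the continuous confounders, GBP per year of age, GBP for female sex)."""

    risk_tolerance_to_liability: float = 0.3
    risk_tolerance_to_cost: float = 30.0
    deprivation_to_liability: float = 0.1
    deprivation_to_cost: float = 20.0
    # kept small and centred/positive so additive shifts rarely drive costs
    # negative: the floor at 0 would otherwise distort the never-smoker mean
    age_to_cost: float = 2.0
    sex_to_cost: float = 20.0


@dataclass
class CostModel:
    """Zero-inflated lognormal baseline plus additive causal shifts.

    ``theta_init`` is the total causal effect (GBP/person/year) of ever
    smoking; ``theta_csi`` the effect per unit of the composite smoking
    index. Both are additive on the cost scale (an additive structural mean
    model), so they are exactly the estimands the IV stages target.
    """

    zero_mass: float = DEFAULT_ZERO_MASS
    log_mean: float = DEFAULT_LOG_MEAN
    log_sd: float = DEFAULT_LOG_SD
    theta_init: float = 477.0
    theta_csi: float = 204.0


@dataclass
class SelectionSpec:
    """Participation model: Bernoulli(logistic(alpha - g1*liability - g2*cost)).

    Liability and cost enter standardized; positive gammas mean smokers and
    high-cost individuals are less likely to participate.
    """

    alpha: float = 1.0
    gamma_smoking: float = 0.0
    gamma_cost: float = 0.0


@dataclass
class SimulationConfig:
    n_individuals: int = 300_045
    n_snps: int = 60
    maf_vector: Sequence[float] | None = None
    ld_block_corr: float = 0.0
    ld_block_size: int = 1
    liability_betas: Sequence[float] | None = None
    csi_betas: Sequence[float] | None = None
    risk_tolerance_betas: Sequence[float] | None = None
    heaviness_snp: int = 20
    prevalence: float = DEFAULT_PREVALENCE
    csi_gamma_shape: float = DEFAULT_CSI_SHAPE
    csi_gamma_scale: float = DEFAULT_CSI_SCALE
    half_life: float = 18.0
    cap: float = 4.0
    n_pcs: int = 10
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    confounders: ConfounderEffects = field(default_factory=ConfounderEffects)
    cost_model: CostModel = field(default_factory=CostModel)
    selection: SelectionSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.liability_betas is None:
            b = np.zeros(self.n_snps)
            b[: min(20, self.n_snps)] = 0.11
            self.liability_betas = b
        if self.csi_betas is None:
            b = np.zeros(self.n_snps)
            b[min(20, self.n_snps) : min(40, self.n_snps)] = 0.25
            self.csi_betas = b
        if self.risk_tolerance_betas is None:
            b = np.zeros(self.n_snps)
            b[min(40, self.n_snps) : min(50, self.n_snps)] = 0.02
            self.risk_tolerance_betas = b
        self.liability_betas = np.asarray(self.liability_betas, dtype=float)
        self.csi_betas = np.asarray(self.csi_betas, dtype=float)
        self.risk_tolerance_betas = np.asarray(self.risk_tolerance_betas, dtype=float)
        if self.maf_vector is not None:
            self.maf_vector = np.asarray(self.maf_vector, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("n_individuals and n_snps must be positive")
        if self.maf_vector is not None:
            mv = np.asarray(self.maf_vector, dtype=float)
            if mv.shape != (self.n_snps,):
                raise ValueError("maf_vector length must equal n_snps")
            if np.any(mv <= 0) or np.any(mv > 0.5):
                raise ValueError("minor allele frequencies must lie in (0, 0.5]")
        if not 0 <= self.ld_block_corr < 1:
            raise ValueError("ld_block_corr must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        for name in ("liability_betas", "csi_betas", "risk_tolerance_betas"):
            if np.asarray(getattr(self, name)).shape != (self.n_snps,):
                raise ValueError(f"{name} length must equal n_snps")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        cm = self.cost_model
        if not 0 <= cm.zero_mass <= 1:
            raise ValueError("cost zero mass must lie in [0, 1]")
        if cm.log_sd <= 0:
            raise ValueError("cost log_sd must be positive")
        if not 0 <= self.pleiotropy.fraction_invalid <= 1:
            raise ValueError("pleiotropy fraction_invalid must lie in [0, 1]")
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")
        if self.cap <= 0:
            raise ValueError("cap must be positive")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            return obj

        out = {}
        for f in dataclasses.fields(self):
            out[f.name] = conv(getattr(self, f.name))
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "pleiotropy" in d and isinstance(d["pleiotropy"], dict):
            d["pleiotropy"] = PleiotropySpec(**d["pleiotropy"])
        if "confounders" in d and isinstance(d["confounders"], dict):
            d["confounders"] = ConfounderEffects(**d["confounders"])
        if "cost_model" in d and isinstance(d["cost_model"], dict):
            d["cost_model"] = CostModel(**d["cost_model"])
        if d.get("selection") is not None and isinstance(d["selection"], dict):
            d["selection"] = SelectionSpec(**d["selection"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def desk_scale(cls, n: int = 20_000, seed: int = 0, **overrides) -> "SimulationConfig":
        """Reduced-n configuration for simulation studies on one CPU."""
        return cls(n_individuals=n, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Additive effect-allele dosage matrix (n individuals x J SNPs)."""

    dosages: np.ndarray  # int8, values 0/1/2
    snp_ids: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    maf: np.ndarray

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[idx], self.snp_ids, self.effect_allele,
                              self.other_allele, self.maf)

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snp_ids.index(snp_id)
        return self.dosages[:, j].astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, columns=self.snp_ids)


@dataclass
class Cohort:
    """Row-aligned bundle of genotypes, covariates, smoking phenotypes, costs."""

    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    smoking: pd.DataFrame
    cost: np.ndarray
    selected: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.genotypes.n

    def subset(self, idx: np.ndarray) -> "Cohort":
        return Cohort(
            genotypes=self.genotypes.subset(idx),
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            smoking=self.smoking.iloc[idx].reset_index(drop=True),
            cost=self.cost[idx],
            selected=None if self.selected is None else self.selected[idx],
        )

    def filter_selected(self) -> "Cohort":
        if self.selected is None:
            return self
        return self.subset(np.flatnonzero(self.selected))

    def covariate_design(self, names: Sequence[str]) -> np.ndarray:
        return self.covariates[list(names)].to_numpy(dtype=float)

    def to_dir(self, out: str | Path) -> None:
        """Write genotype dosage TSV (PLINK-.raw-style column layout) plus a
        phenotype/covariate TSV."""
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        geno = self.genotypes.to_frame()
        geno.insert(0, "IID", np.arange(self.n))
        geno.to_csv(out / "genotypes.tsv", sep="\t", index=False)
        pheno = pd.concat([self.covariates, self.smoking], axis=1)
        pheno.insert(0, "IID", np.arange(self.n))
        pheno["annual_cost"] = self.cost
        if self.selected is not None:
            pheno["selected"] = self.selected.astype(int)
        pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        alleles = pd.DataFrame({
            "snp_id": self.genotypes.snp_ids,
            "effect_allele": self.genotypes.effect_allele,
            "other_allele": self.genotypes.other_allele,
            "maf": self.genotypes.maf,
        })
        alleles.to_csv(out / "snps.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        geno = pd.read_csv(path / "genotypes.tsv", sep="\t")
        geno = geno.drop(columns=["IID"], errors="ignore")
        snps = pd.read_csv(path / "snps.tsv", sep="\t")
        pheno = pd.read_csv(path / "phenotypes.tsv", sep="\t")
        gm = GenotypeMatrix(
            dosages=geno.to_numpy(dtype=np.int8),
            snp_ids=list(snps["snp_id"]),
            effect_allele=list(snps["effect_allele"]),
            other_allele=list(snps["other_allele"]),
            maf=snps["maf"].to_numpy(),
        )
        smoking_cols = [c for c in ("initiation", "cigs_per_day", "duration_years",
                                    "years_since_cessation", "csi", "liability")
                        if c in pheno.columns]
        cov_cols = [c for c in pheno.columns
                    if c not in smoking_cols + ["IID", "annual_cost", "selected"]]
        selected = pheno["selected"].to_numpy(bool) if "selected" in pheno else None
        return cls(gm, pheno[cov_cols].copy(), pheno[smoking_cols].copy(),
                   pheno["annual_cost"].to_numpy(float), selected)


# ---------------------------------------------------------------------------
# composite smoking index
# ---------------------------------------------------------------------------

def compute_csi(cigs_per_day, duration_years, years_since_cessation,
                half_life: float = 18.0, cap: float = 4.0,
                scale: float = 1.0):
    """Composite smoking index combining heaviness, duration and cessation.

    csi = min(cap, scale * ln(1 + cpd/2) * (1 - 0.5^(dur/tau)) * 0.5^(tsc/tau))

    The half-life ``tau`` encodes the exponentially declining impact of past
    smoking: duration accrues with saturation, and each ``tau`` years since
    cessation halves the remaining index. Zero for never-smokers (cpd = 0);
    increasing in cigarettes/day and duration, decreasing in time since
    cessation.
    """
    cpd = np.asarray(cigs_per_day, dtype=float)
    dur = np.asarray(duration_years, dtype=float)
    tsc = np.asarray(years_since_cessation, dtype=float)
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    if np.any(cpd < 0) or np.any(dur < 0) or np.any(tsc < 0):
        raise ValueError("smoking components must be non-negative")
    raw = scale * np.log1p(cpd / 2.0) * (1.0 - 0.5 ** (dur / half_life)) \
        * 0.5 ** (tsc / half_life)
    out = np.minimum(raw, cap)
    if out.ndim == 0:
        return float(out)
    return out


def _invert_csi_cpd(csi, duration_years, years_since_cessation, half_life):
    """Cigarettes/day that reproduces ``csi`` given the other components."""
    decay = (1.0 - 0.5 ** (np.asarray(duration_years) / half_life)) \
        * 0.5 ** (np.asarray(years_since_cessation) / half_life)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        cpd = 2.0 * np.expm1(np.where(decay > 0, csi / np.maximum(decay, 1e-12), 0.0))
    return cpd


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def _resolve_maf(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.maf_vector is not None:
        return np.asarray(config.maf_vector, dtype=float)
    # deterministic per config seed: draw from a child stream
    child = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    return child.uniform(0.1, 0.5, size=config.n_snps)


def generate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Hardy-Weinberg dosages, optionally with block-structured LD.

    Each gamete's alleles come from latent standard normals thresholded at
    the allele-frequency quantile; within an LD block the latents share an
    equicorrelated component (correlation ``ld_block_corr``), across blocks
    they are independent. Dosage = sum of the two independent gametes, so
    marginals are exactly binomial(2, maf).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, J = config.n_individuals, config.n_snps
    maf = _resolve_maf(config, rng)
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    thresh = sps.norm.ppf(maf)
    rho = config.ld_block_corr
    bs = config.ld_block_size
    dos = np.zeros((n, J), dtype=np.int8)
    for _gamete in range(2):
        if rho > 0 and bs > 1:
            z = np.empty((n, J))
            for start in range(0, J, bs):
                stop = min(start + bs, J)
                shared = rng.standard_normal(n)
                eps = rng.standard_normal((n, stop - start))
                z[:, start:stop] = np.sqrt(rho) * shared[:, None] \
                    + np.sqrt(1 - rho) * eps
            alleles = z < thresh
        else:
            alleles = rng.standard_normal((n, J)) < thresh
        dos += alleles.astype(np.int8)
    ids = [f"snp_{j:04d}" for j in range(J)]
    return GenotypeMatrix(dosages=dos, snp_ids=ids,
                          effect_allele=["A"] * J, other_allele=["G"] * J,
                          maf=maf)


def generate_covariates(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Age (uniform 39-72), sex (P(female)=0.54), a standardized risk-tolerance
    score built from simulated sub-behaviors, deprivation, and ancestry-like
    principal components. Risk tolerance carries a genetic component from
    ``risk_tolerance_betas`` so it can be instrumented in multivariable MR.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    age = rng.uniform(39.0, 72.0, size=n)
    sex = (rng.random(n) < 0.54).astype(int)  # 1 = female
    # composite of risky sub-behaviors, then standardized
    sub = rng.standard_normal((n, 4))
    raw = sub @ np.array([0.5, 0.3, 0.4, 0.6])
    risk = (raw - raw.mean()) / raw.std()
    deprivation = rng.standard_normal(n)
    pcs = rng.standard_normal((n, config.n_pcs))
    df = pd.DataFrame({"age": age, "sex": sex, "risk_tolerance": risk,
                       "deprivation": deprivation})
    for k in range(config.n_pcs):
        df[f"pc{k + 1}"] = pcs[:, k]
    return df


def assign_smoking(G: GenotypeMatrix, C: pd.DataFrame, config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Liability-threshold smoking initiation plus behavioral components.

    Latent liability = G @ liability_betas + confounder paths + N(0,1); the
    threshold is the empirical (1 - prevalence) liability quantile, so the
    realized ever-smoker share matches the target prevalence exactly up to
    integer rounding. Among initiators the CSI is drawn from the calibrated
    gamma plus a mean-centred per-SNP genetic shift, clipped to [0, cap];
    duration/cessation are drawn and cigarettes/day back-solved so that
    ``compute_csi`` on the components reproduces the CSI. Never-smokers get
    CSI exactly 0.
    """
    if G.n != len(C):
        raise ValueError("genotypes and covariates must be row-aligned")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = G.n
    dos = G.dosages.astype(float)
    conf = config.confounders
    liab = dos @ config.liability_betas
    liab = liab + conf.risk_tolerance_to_liability * C["risk_tolerance"].to_numpy()
    liab = liab + conf.deprivation_to_liability * C["deprivation"].to_numpy()
    liab = liab + rng.standard_normal(n)
    threshold = np.quantile(liab, 1.0 - config.prevalence)
    init = liab > threshold

    csi = np.zeros(n)
    cpd = np.zeros(n)
    dur = np.zeros(n)
    tsc = np.zeros(n)
    idx = np.flatnonzero(init)
    if idx.size:
        base = rng.gamma(config.csi_gamma_shape, config.csi_gamma_scale,
                         size=idx.size)
        shift = dos[idx] @ config.csi_betas \
            - float(config.csi_betas @ (2.0 * G.maf))
        # max CSI reachable through the index formula at <= 60 cigs/day
        reach = np.log1p(30.0)
        target = np.clip(base + shift, 0.0, min(config.cap, 0.99 * reach))
        # 40% current smokers (tsc = 0); former smokers quit 1-25 years ago,
        # truncated so the target index stays reachable
        former = rng.random(idx.size) < 0.6
        tsc_s = np.where(former, rng.uniform(1.0, 25.0, size=idx.size), 0.0)
        with np.errstate(divide="ignore"):
            tsc_max = config.half_life * np.log2(
                np.maximum(reach / np.maximum(target, 1e-9), 1.0 + 1e-9))
        tsc_s = np.minimum(tsc_s, 0.95 * tsc_max)
        # minimum duration for the index to be reachable, then uniform above
        frac_needed = target / (reach * 0.5 ** (tsc_s / config.half_life))
        dur_min = -config.half_life * np.log2(np.maximum(1.0 - frac_needed, 1e-12))
        dur_s = rng.uniform(np.minimum(np.maximum(dur_min, 3.0), 45.0), 45.0)
        cpd_s = _invert_csi_cpd(target, dur_s, tsc_s, config.half_life)
        cpd_s = np.clip(cpd_s, 0.5, 60.0)
        csi_s = compute_csi(cpd_s, dur_s, tsc_s, config.half_life, config.cap)
        csi[idx] = csi_s
        cpd[idx] = cpd_s
        dur[idx] = dur_s
        tsc[idx] = tsc_s
    return pd.DataFrame({
        "initiation": init.astype(int),
        "cigs_per_day": cpd,
        "duration_years": dur,
        "years_since_cessation": tsc,
        "csi": csi,
        "liability": liab,
    })


def generate_costs(G: GenotypeMatrix, C: pd.DataFrame, S: pd.DataFrame,
                   config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Annual inpatient cost: zero-inflated lognormal baseline plus additive
    causal, confounder and (optional) direct pleiotropic SNP shifts.

    The causal shift is parameterized as
    ``(theta_init - theta_csi * mean_smoker_csi) * initiation + theta_csi * csi``
    so that ``theta_init`` is the *total* mean cost effect of ever smoking and
    ``theta_csi`` the effect per CSI unit - the two estimands the IV analyses
    report. Negative post-shift draws are floored at 0.
    """
    if not (G.n == len(C) == len(S)):
        raise ValueError("cohort components must be row-aligned")
    cm = config.cost_model
    if not 0 <= cm.zero_mass <= 1:
        raise ValueError("zero mass must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = G.n
    nonzero = rng.random(n) >= cm.zero_mass
    base = np.where(nonzero,
                    np.exp(cm.log_mean + cm.log_sd * rng.standard_normal(n)),
                    0.0)
    init = S["initiation"].to_numpy(float)
    csi = S["csi"].to_numpy(float)
    mean_smoker_csi = csi[init > 0].mean() if np.any(init > 0) else 0.0
    shift = (cm.theta_init - cm.theta_csi * mean_smoker_csi) * init \
        + cm.theta_csi * csi
    conf = config.confounders
    shift = shift + conf.risk_tolerance_to_cost * C["risk_tolerance"].to_numpy()
    shift = shift + conf.deprivation_to_cost * C["deprivation"].to_numpy()
    shift = shift + conf.age_to_cost * (C["age"].to_numpy() - C["age"].mean())
    shift = shift + conf.sex_to_cost * C["sex"].to_numpy()
    ple = config.pleiotropy
    if ple.fraction_invalid > 0 and ple.mean_direct_effect != 0:
        causal = np.flatnonzero((config.liability_betas != 0)
                                | (config.csi_betas != 0))
        k = int(np.ceil(ple.fraction_invalid * causal.size))
        invalid = rng.choice(causal, size=k, replace=False)
        effects = np.full(k, float(ple.mean_direct_effect))
        if ple.balanced:
            effects *= rng.choice([-1.0, 1.0], size=k)
        shift = shift + G.dosages[:, invalid].astype(float) @ effects
    return np.maximum(base + shift, 0.0)


def apply_selection(cohort: Cohort, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> Cohort:
    """Flag study participation with probability
    logistic(alpha - g1 * std(liability) - g2 * std(cost))."""
    sel = config.selection
    if sel is None:
        raise ValueError("selection_spec must be provided")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    liab = cohort.smoking["liability"].to_numpy()
    liab_z = (liab - liab.mean()) / liab.std()
    cost = cohort.cost
    cost_z = (cost - cost.mean()) / max(cost.std(), 1e-12)
    eta = sel.alpha - sel.gamma_smoking * liab_z - sel.gamma_cost * cost_z
    p = 1.0 / (1.0 + np.exp(-eta))
    flag = rng.random(cohort.n) < p
    return Cohort(cohort.genotypes, cohort.covariates, cohort.smoking,
                  cohort.cost, selected=flag)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Run all generation stages under a single seeded stream; bit-identical
    output for identical (config, seed)."""
    rng = np.random.default_rng(config.seed)
    G = generate_genotypes(config, rng)
    C = generate_covariates(config, rng)
    S = assign_smoking(G, C, config, rng)
    cost = generate_costs(G, C, S, config, rng)
    cohort = Cohort(G, C, S, cost)
    if config.selection is not None:
        cohort = apply_selection(cohort, config, rng)
    return cohort
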