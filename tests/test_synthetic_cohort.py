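"""Generator behaviour: Hardy-Weinberg moments, LD blocks, the composite
smoking index, liability-threshold initiation, cost calibration, selection
and determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mrpipe import (SimulationConfig, apply_selection, assign_smoking,
                    compute_csi, generate_covariates, generate_genotypes,
                    generate_costs, simulate_cohort)
from mrpipe.synthetic_cohort import (ConfounderEffects, CostModel,
                                     SelectionSpec)
from conftest import null_cost_config


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("overrides", [
    {"maf_vector": [0.6, 0.3]},
    {"maf_vector": [0.0, 0.3]},
    {"maf_vector": [0.3]},          # wrong length
    {"ld_block_corr": 1.0},
    {"prevalence": 0.0},
    {"half_life": -1.0},
    {"cap": 0.0},
    {"cost_model": CostModel(zero_mass=1.2)},
    {"cost_model": CostModel(log_sd=0.0)},
])
def test_invalid_config_rejected(overrides):
    with pytest.raises(ValueError):
        SimulationConfig(n_individuals=10, n_snps=2, **overrides)


def test_config_roundtrip_and_hash(tmp_path):
    cfg = SimulationConfig.desk_scale(n=500, seed=3)
    d = cfg.to_dict()
    cfg2 = SimulationConfig.from_dict(d)
    assert cfg2.config_hash() == cfg.config_hash()
    import json
    p = tmp_path / "cfg.json"
    p.write_text(json.dumps(d))
    assert SimulationConfig.from_file(p).config_hash() == cfg.config_hash()


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def test_hwe_dosage_moments():
    n = 100_000
    cfg = SimulationConfig(n_individuals=n, n_snps=3,
                           maf_vector=[0.5, 0.2, 0.35], seed=0)
    G = generate_genotypes(cfg)
    for j, p in enumerate([0.5, 0.2, 0.35]):
        dos = G.dosages[:, j].astype(float)
        var = 2 * p * (1 - p)
        se_mean = np.sqrt(var / n)
        assert abs(dos.mean() - 2 * p) < 3 * se_mean
        # variance of the sample variance of a binomial(2, p) via 4th moment
        assert abs(dos.var() - var) < 4 * var / np.sqrt(n) + 0.01


def test_unlinked_snps_uncorrelated():
    cfg = SimulationConfig(n_individuals=100_000, n_snps=6,
                           maf_vector=[0.3] * 6, ld_block_corr=0.0, seed=1)
    G = generate_genotypes(cfg)
    r = np.corrcoef(G.dosages.T.astype(float))
    off = r[~np.eye(6, dtype=bool)]
    assert np.max(np.abs(off)) < 0.02


def test_ld_blocks_structured():
    cfg = SimulationConfig(n_individuals=50_000, n_snps=6,
                           maf_vector=[0.3] * 6, ld_block_corr=0.6,
                           ld_block_size=3, seed=2)
    G = generate_genotypes(cfg)
    r = np.corrcoef(G.dosages.T.astype(float))
    within = [r[0, 1], r[0, 2], r[1, 2], r[3, 4], r[3, 5], r[4, 5]]
    across = [r[0, 3], r[1, 4], r[2, 5], r[0, 5]]
    assert min(within) > 0.2
    assert np.max(np.abs(across)) < 0.03


def test_bad_maf_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_individuals=100, n_snps=1, maf_vector=[0.7])


# ---------------------------------------------------------------------------
# composite smoking index
# ---------------------------------------------------------------------------

def test_csi_formula_values():
    assert compute_csi(0, 0, 0) == 0.0
    # 20/day for 18 years, current smoker, half-life 18:
    # ln(11) * (1 - 0.5) * 1
    val = compute_csi(20, 18, 0, half_life=18)
    assert val == pytest.approx(np.log(11) * 0.5, abs=1e-12)
    with pytest.raises(ValueError):
        compute_csi(-1, 10, 0)
    with pytest.raises(ValueError):
        compute_csi(10, 10, 0, half_life=0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(cpd=st.floats(0.1, 80), dur=st.floats(0.1, 60), tsc=st.floats(0, 50),
       delta=st.floats(0.1, 5))
def test_csi_monotone_and_capped(cpd, dur, tsc, delta):
    base = compute_csi(cpd, dur, tsc)
    assert 0 <= base <= 4.0
    assert compute_csi(cpd + delta, dur, tsc) >= base
    assert compute_csi(cpd, dur + delta, tsc) >= base
    assert compute_csi(cpd, dur, tsc + delta) <= base


def test_csi_zero_iff_never_smoker(desk_cohort):
    S = desk_cohort.smoking
    never = S["initiation"] == 0
    assert (S.loc[never, "csi"] == 0).all()
    assert (S.loc[~never, "csi"] > 0).all()
    assert S["csi"].max() <= 4.0


def test_csi_components_reproduce_index(desk_cohort):
    S = desk_cohort.smoking
    smk = S[S["initiation"] == 1]
    recomputed = compute_csi(smk["cigs_per_day"], smk["duration_years"],
                             smk["years_since_cessation"])
    assert np.allclose(recomputed, smk["csi"], atol=1e-10)


def test_csi_mean_among_smokers(big_cohort):
    # gamma(2.136, 0.5337) calibration target 1.14; the additive genetic
    # shift plus clipping perturbs the realized mean slightly
    S = big_cohort.smoking
    smk = S.loc[S["initiation"] == 1, "csi"]
    assert smk.mean() == pytest.approx(2.136 * 0.5337, abs=0.1)


# ---------------------------------------------------------------------------
# smoking assignment
# ---------------------------------------------------------------------------

def test_prevalence_matches_target(big_cohort):
    assert big_cohort.smoking["initiation"].mean() == pytest.approx(
        0.29213, abs=0.005)


def test_null_liability_gives_uniform_association_p():
    # no genetic or confounder path into liability: SNP-initiation p-values
    # are uniform
    from mrpipe import snp_association
    n, J = 20_000, 40
    cfg = SimulationConfig(
        n_individuals=n, n_snps=J, seed=9,
        liability_betas=np.zeros(J), csi_betas=np.zeros(J),
        risk_tolerance_betas=np.zeros(J),
        confounders=ConfounderEffects(0, 0, 0, 0, 0, 0))
    cohort = simulate_cohort(cfg)
    stats = snp_association(cohort.genotypes,
                            cohort.smoking["initiation"].to_numpy(float))
    ks = sps.kstest(stats["p"], "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

def test_cost_zero_inflated_lognormal_calibration():
    # under the null cost model the printed descriptives are reproduced:
    # mean ~ 478, median ~ 87, 45% zeros
    n = 300_045
    cohort = simulate_cohort(null_cost_config(n, seed=17))
    cost = cohort.cost
    mc_se = cost.std() / np.sqrt(n)
    assert abs(cost.mean() - 478) < 3 * mc_se
    assert abs(np.median(cost) - 87) <= 2.0
    zero_se = np.sqrt(0.45 * 0.55 / n)
    assert abs((cost == 0).mean() - 0.45) < 3 * zero_se


def test_cost_additive_initiation_shift():
    # pure initiation effect: ever-never mean difference ~ theta_init
    n = 200_000
    cfg = SimulationConfig(
        n_individuals=n, n_snps=2, seed=23,
        liability_betas=np.zeros(2), csi_betas=np.zeros(2),
        risk_tolerance_betas=np.zeros(2), heaviness_snp=0,
        confounders=ConfounderEffects(0, 0, 0, 0, 0, 0),
        cost_model=CostModel(theta_init=477.0, theta_csi=0.0))
    cohort = simulate_cohort(cfg)
    init = cohort.smoking["initiation"].to_numpy(bool)
    diff = cohort.cost[init].mean() - cohort.cost[~init].mean()
    se = np.sqrt(cohort.cost[init].var() / init.sum()
                 + cohort.cost[~init].var() / (~init).sum())
    assert abs(diff - 477) < 3 * se


def test_cost_rejects_bad_zero_mass(desk_cohort):
    cfg = SimulationConfig.desk_scale(n=100, seed=0)
    cfg.cost_model.zero_mass = 1.5
    small = simulate_cohort(SimulationConfig.desk_scale(n=100, seed=0))
    with pytest.raises(ValueError):
        generate_costs(small.genotypes, small.covariates, small.smoking, cfg)


# ---------------------------------------------------------------------------
# covariates, selection, determinism
# ---------------------------------------------------------------------------

def test_covariate_distributions(big_cohort):
    C = big_cohort.covariates
    n = len(C)
    assert C["age"].between(39, 72).all()
    assert C["age"].mean() == pytest.approx(55.5, abs=3 * 9.5 / np.sqrt(n))
    assert C["sex"].mean() == pytest.approx(0.54, abs=3 * 0.5 / np.sqrt(n))
    assert C["risk_tolerance"].mean() == pytest.approx(0, abs=1e-8)
    assert C["risk_tolerance"].std() == pytest.approx(1, abs=1e-3)


def test_selection_null_and_monotone():
    base = SimulationConfig.desk_scale(n=40_000, seed=31).to_dict()
    # null selection: participation ~ logistic(alpha), smoker share unchanged
    base["selection"] = {"alpha": 0.5, "gamma_smoking": 0.0, "gamma_cost": 0.0}
    cohort = simulate_cohort(SimulationConfig.from_dict(base))
    frac = cohort.selected.mean()
    assert frac == pytest.approx(1 / (1 + np.exp(-0.5)), abs=0.01)
    full_share = cohort.smoking["initiation"].mean()
    sel_share = cohort.filter_selected().smoking["initiation"].mean()
    assert sel_share == pytest.approx(full_share, abs=0.012)
    # smoking-liability selection: smokers underrepresented
    base["selection"] = {"alpha": 0.5, "gamma_smoking": 1.0, "gamma_cost": 0.0}
    cohort2 = simulate_cohort(SimulationConfig.from_dict(base))
    assert cohort2.filter_selected().smoking["initiation"].mean() \
        < full_share - 0.02
    # alpha -> +inf: everyone participates
    base["selection"] = {"alpha": 50.0, "gamma_smoking": 1.0, "gamma_cost": 0.0}
    cohort3 = simulate_cohort(SimulationConfig.from_dict(base))
    assert cohort3.selected.all()


def test_selection_requires_spec(desk_cohort):
    with pytest.raises(ValueError):
        apply_selection(desk_cohort, SimulationConfig.desk_scale(n=100))


def test_seed_determinism():
    cfg = SimulationConfig.desk_scale(n=3000, seed=42)
    a = simulate_cohort(cfg)
    b = simulate_cohort(SimulationConfig.desk_scale(n=3000, seed=42))
    assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
    assert a.covariates.equals(b.covariates)
    assert a.smoking.equals(b.smoking)
    assert np.array_equal(a.cost, b.cost)
    c = simulate_cohort(SimulationConfig.desk_scale(n=3000, seed=43))
    assert not np.array_equal(a.cost, c.cost)


def test_cohort_tsv_roundtrip(tmp_path):
    from mrpipe.synthetic_cohort import Cohort
    cohort = simulate_cohort(SimulationConfig.desk_scale(n=200, seed=8))
    cohort.to_dir(tmp_path / "cohort")
    back = Cohort.from_dir(tmp_path / "cohort")
    assert np.array_equal(back.genotypes.dosages, cohort.genotypes.dosages)
    assert np.allclose(back.cost, cohort.cost)
    assert list(back.smoking.columns) == list(cohort.smoking.columns)
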