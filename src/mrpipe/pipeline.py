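"""End-to-end orchestration of the split-sample MR design on a synthetic
cohort: simulate -> split -> GWAS in both halves -> cross-weighted PRS 2SLS
-> per-SNP estimator suite -> sensitivity battery -> fixed-effect
meta-analysis -> report tables.

Instrument weights always come from the half the estimation did *not* use
(swapped-half weighting), so instrument discovery and IV estimation never
share individuals.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthetic_cohort import Cohort, SimulationConfig, simulate_cohort
from .association_scan import (InstrumentSet, ld_r2_matrix, select_and_clump,
                               snp_association, split_sample)
from .prs_iv import (IVEstimate, build_prs, fixed_effect_meta,
                     two_stage_least_squares, variance_explained)
from .summary_mr import egger, ivw, mode_estimate, wald_ratios, weighted_median
from .sensitivity import interaction_test, mvmr_estimate, steiger_filter
from .conventional import multivariable_ols

__all__ = ["PipelineOptions", "ReportBundle", "run_pipeline"]

log = logging.getLogger("mrpipe")

EXPOSURES = ("initiation", "csi")


@dataclass
class PipelineOptions:
    split_fraction: float = 0.5
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    robust_se: bool = False
    n_boot: int = 1000
    run_summary_mr: bool = True
    run_sensitivity: bool = True
    risk_fallback_k: int = 5
    wald_se_order: int = 1


@dataclass
class ReportBundle:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    sensitivity_mr: pd.DataFrame
    steiger: pd.DataFrame
    interaction: pd.DataFrame
    mvmr: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("table1", "table2", "table3", "table4", "sensitivity_mr",
                     "steiger", "interaction", "mvmr"):
            df = getattr(self, name)
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.10g")
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True))


def _gwas_covariates(cohort: Cohort) -> np.ndarray:
    names = ["age", "sex"] + [c for c in cohort.covariates.columns
                              if c.startswith("pc")]
    return cohort.covariate_design(names)


def _discover(cohort: Cohort, exposure: str, opts: PipelineOptions
              ) -> tuple[pd.DataFrame, InstrumentSet]:
    covars = _gwas_covariates(cohort)
    pheno = cohort.smoking[exposure].to_numpy(float)
    stats = snp_association(cohort.genotypes, pheno, covars)
    cand_ids = list(stats.loc[stats["p"] < opts.p_threshold, "snp_id"])
    ld = ld_r2_matrix(cohort.genotypes, cand_ids) if cand_ids else None
    inst = select_and_clump(stats, opts.p_threshold, ld, opts.clump_r2)
    return stats, inst


def run_pipeline(config: SimulationConfig,
                 options: PipelineOptions | None = None) -> ReportBundle:
    """Execute all analysis stages in design order on one simulated cohort."""
    opts = options or PipelineOptions()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    cohort = simulate_cohort(config)
    if cohort.selected is not None:
        cohort = cohort.filter_selected()
    timings["simulate"] = time.perf_counter() - t0

    # -- conventional multivariable analysis (Table 1 analog) ---------------
    t = time.perf_counter()
    conv_cov = cohort.covariates[["age", "sex", "deprivation"]]
    init = cohort.smoking["initiation"].to_numpy(float)
    csi = cohort.smoking["csi"].to_numpy(float)
    rows1 = []
    for label, expo, subset in (
            ("initiation", init, None),
            ("csi", csi, None),
            ("csi_among_smokers", csi, init > 0)):
        est = multivariable_ols(cohort.cost, expo, conv_cov,
                                exposure_label=label, subset=subset)
        rows1.append({"exposure": label, "n": est.n, "beta": est.beta,
                      "se": est.se, "ci_low": est.ci[0], "ci_high": est.ci[1]})
    table1 = pd.DataFrame(rows1)
    timings["conventional"] = time.perf_counter() - t

    # -- split-sample design -------------------------------------------------
    split_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    (half_a, half_b), (idx_a, idx_b) = split_sample(
        cohort, opts.split_fraction, split_rng, return_indices=True)
    overlap = np.intersect1d(idx_a, idx_b)
    if overlap.size:
        raise AssertionError("discovery and estimation samples overlap")
    halves = {"1": half_a, "2": half_b}
    other = {"1": "2", "2": "1"}

    # per-half cost and risk-tolerance scans, reused across exposures
    t = time.perf_counter()
    cost_stats = {h: snp_association(c.genotypes, c.cost, _gwas_covariates(c))
                  for h, c in halves.items()}
    risk_stats = {h: snp_association(
        c.genotypes, c.covariates["risk_tolerance"].to_numpy(float),
        _gwas_covariates(c)) for h, c in halves.items()}
    timings["outcome_scans"] = time.perf_counter() - t

    rows2, rows3, rows4 = [], [], []
    sens_rows, steiger_rows, inter_rows, mvmr_rows = [], [], [], []
    inst_counts: dict[str, int] = {}
    boot_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))

    for exposure in EXPOSURES:
        t = time.perf_counter()
        discovered = {h: _discover(halves[h], exposure, opts)
                      for h in halves}
        timings[f"gwas_{exposure}"] = time.perf_counter() - t
        half_estimates: list[IVEstimate] = []
        for est_h in halves:
            disc_h = other[est_h]
            est_cohort = halves[est_h]
            _, inst = discovered[disc_h]
            inst_counts[f"{exposure}_sample{est_h}"] = len(inst)
            if len(inst) == 0:
                log.warning("no instruments for %s (discovery half %s)",
                            exposure, disc_h)
                continue
            covars = _gwas_covariates(est_cohort)
            pheno = est_cohort.smoking[exposure].to_numpy(float)
            prs = build_prs(est_cohort.genotypes, inst.stats)
            r2 = variance_explained(prs, pheno,
                                    binary=(exposure == "initiation"))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                iv = two_stage_least_squares(
                    est_cohort.cost, pheno, prs, covars,
                    robust=opts.robust_se, exposure_label=exposure)
            half_estimates.append(iv)
            rows2.append({"exposure": exposure, "sample": est_h,
                          "n": iv.n, "n_snps": len(inst),
                          "prs_r2": r2, "first_stage_F": iv.first_stage_F})

            if opts.run_summary_mr:
                out_stats = cost_stats[est_h]
                ratios = wald_ratios(inst.stats, out_stats,
                                     order=opts.wald_se_order)
                if len(ratios) >= 2:
                    est_ivw, q = ivw(ratios, random_effects=True)
                    rows4.append({"exposure": exposure, "sample": est_h,
                                  "n_snps": len(ratios), "Q": q.Q,
                                  "df": q.df, "p": q.p})
                    suite = [est_ivw]
                    if len(ratios) >= 3:
                        eg = egger(
                            inst.stats["beta"].to_numpy(),
                            inst.stats["se"].to_numpy(),
                            out_stats.set_index("snp_id").loc[
                                inst.snp_ids, "beta"].to_numpy(),
                            out_stats.set_index("snp_id").loc[
                                inst.snp_ids, "se"].to_numpy())
                        wm = weighted_median(ratios, penalized=True,
                                             n_boot=opts.n_boot, rng=boot_rng)
                        mo = mode_estimate(ratios, n_boot=opts.n_boot,
                                           rng=boot_rng)
                        suite += [eg, wm, mo]
                    for e in suite:
                        row = {"exposure": exposure, "sample": est_h,
                               "method": e.method, "beta": e.beta,
                               "se": e.se, "ci_low": e.ci[0],
                               "ci_high": e.ci[1], "nsnp": e.nsnp}
                        if "intercept" in e.auxiliary:
                            row["egger_intercept"] = e.auxiliary["intercept"]
                            row["egger_intercept_p"] = e.auxiliary["intercept_p"]
                        sens_rows.append(row)

            if opts.run_sensitivity and len(inst) > 0:
                results, _kept = steiger_filter(
                    inst.stats, cost_stats[est_h])
                for r in results:
                    steiger_rows.append({
                        "exposure": exposure, "sample": est_h,
                        "snp_id": r.snp_id, "r_exposure": r.r_exposure,
                        "r_outcome": r.r_outcome,
                        "direction_correct": r.direction_correct,
                        "steiger_p": r.steiger_p})

            if opts.run_sensitivity:
                # multivariable MR: smoking exposure + risk tolerance,
                # instruments = discovered smoking SNPs plus the strongest
                # risk-tolerance SNPs from the discovery half
                rstats = risk_stats[disc_h]
                risk_inst = list(rstats.loc[rstats["p"] < opts.p_threshold,
                                            "snp_id"])
                if not risk_inst:
                    risk_inst = list(rstats.nsmallest(
                        opts.risk_fallback_k, "p")["snp_id"])
                z_ids = list(dict.fromkeys(inst.snp_ids + risk_inst))
                cols = [est_cohort.genotypes.snp_ids.index(s) for s in z_ids]
                Z = est_cohort.genotypes.dosages[:, cols].astype(float)
                exposures2 = np.column_stack([
                    pheno,
                    est_cohort.covariates["risk_tolerance"].to_numpy(float)])
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        mv = mvmr_estimate(
                            est_cohort.cost, exposures2, Z, covars,
                            exposure_labels=[exposure, "risk_tolerance"])
                    df_mv = mv.as_frame()
                    df_mv.insert(0, "sample", est_h)
                    df_mv.insert(0, "model", exposure)
                    mvmr_rows.append(df_mv)
                except np.linalg.LinAlgError as err:
                    log.warning("MVMR failed (%s, half %s): %s",
                                exposure, est_h, err)

        if half_estimates:
            meta = fixed_effect_meta(half_estimates) \
                if len(half_estimates) > 1 else None
            if meta is None:
                e = half_estimates[0]
                b, s, ci = e.beta, e.se, e.ci
            else:
                b, s, ci = meta.beta, meta.se, meta.ci
            rows3.append({"exposure": exposure, "beta": b, "se": s,
                          "ci_low": ci[0], "ci_high": ci[1],
                          "n_samples": len(half_estimates)})

    # ever/never interaction check at the designated heaviness SNP
    if opts.run_sensitivity:
        heav_id = cohort.genotypes.snp_ids[config.heaviness_snp]
        for h, c in halves.items():
            try:
                res = interaction_test(
                    c.cost, c.genotypes.column(heav_id),
                    c.smoking["initiation"].to_numpy(float),
                    _gwas_covariates(c))
                inter_rows.append({
                    "sample": h, "snp_id": heav_id,
                    "beta_ever": res.beta_ever, "se_ever": res.se_ever,
                    "beta_never": res.beta_never, "se_never": res.se_never,
                    "beta_interaction": res.beta_interaction,
                    "se_interaction": res.se_interaction,
                    "p_interaction": res.p_interaction})
            except ValueError as err:
                log.warning("interaction test failed (half %s): %s", h, err)

    timings["total"] = time.perf_counter() - t0
    provenance = {
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "version": __version__,
        "n_analyzed": int(cohort.n),
        "instrument_counts": inst_counts,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    return ReportBundle(
        table1=table1,
        table2=pd.DataFrame(rows2),
        table3=pd.DataFrame(rows3),
        table4=pd.DataFrame(rows4),
        sensitivity_mr=pd.DataFrame(sens_rows),
        steiger=pd.DataFrame(steiger_rows),
        interaction=pd.DataFrame(inter_rows),
        mvmr=pd.concat(mvmr_rows, ignore_index=True) if mvmr_rows
        else pd.DataFrame(),
        provenance=provenance,
    )
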