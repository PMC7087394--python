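"""End-to-end orchestration: simulate -> instruments -> scan -> MR -> power.

The pipeline is deterministic given a RunConfig: the single seed expands into
per-stage substreams, and rerunning the same config reproduces every output
table bit for bit.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import instruments, io, mr, phenome_scan, power, synthetic
from .errors import MRPheWASError

log = logging.getLogger("mrphewas")


def default_trait_specs(n_traits: int, effect_fraction: float = 0.1,
                        effect_size: float = -0.15) -> list:
    """Deterministic mixed phenome recipe.

    Kinds cycle continuous/binary/ordered/unordered in a 4:3:2:1 ratio; every
    tenth trait (by default) carries a real exposure effect, half of it
    routed through adult BMI for every second affected trait.
    """
    kinds = (["continuous"] * 4 + ["binary"] * 3 + ["ordered"] * 2 + ["unordered"])
    specs = []
    step = max(int(round(1.0 / effect_fraction)), 1)
    for i in range(n_traits):
        kind = kinds[i % len(kinds)]
        affected = (i % step) == 0
        specs.append(synthetic.TraitSpec(
            name=f"trait_{i:04d}",
            kind=kind,
            beta_menarche=effect_size if affected else 0.0,
            mediation_via_bmi=0.5 if (affected and (i // step) % 2 == 1) else 0.0,
            category="affected" if affected else "null",
        ))
    return specs


def _pleiotropy_assignment(panel: pd.DataFrame, child_frac: float = 0.02,
                           adult_frac: float = 0.15):
    """Designate variant subsets with BMI paths, mirroring the study's
    proportions (roughly 7/360 childhood-BMI and 206/360 any-BMI hits)."""
    m = len(panel)
    n_child = max(1, int(round(child_frac * m)))
    n_adult = max(n_child, int(round(adult_frac * m)))
    child_rsids = list(panel["rsid"][:n_child])
    adult_rsids = list(panel["rsid"][n_child:n_adult])
    gamma = {r: 0.15 for r in child_rsids}
    child_hits = panel[panel["rsid"].isin(child_rsids)][["rsid", "chrom", "pos"]]
    adult_hits = panel[panel["rsid"].isin(adult_rsids)][["rsid", "chrom", "pos"]]
    return gamma, child_hits, adult_hits


def run_pipeline(config: io.RunConfig) -> Path:
    """Execute the full analysis and write all outputs under the out dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.echo(out_dir)
    meta = {"config_hash": config.digest(), "seed": config.seed}
    seed = int(config.seed)

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except MRPheWASError as exc:
            raise MRPheWASError(f"stage {name!r} failed: {exc}") from exc

    # --- simulate -----------------------------------------------------------
    if config.panel_path:
        panel = stage("panel", io.read_weight_table, config.panel_path)
    else:
        panel = stage("panel", synthetic.simulate_panel, config.n_variants,
                      seed=seed, target_r2=config.target_r2,
                      exposure_sd=config.exposure_sd)
    io.write_panel(panel, out_dir / "panel.tsv", **meta)
    log.info("panel: %d variants", len(panel))

    gamma, child_hits, adult_hits = _pleiotropy_assignment(panel)
    params = synthetic.CohortParams(
        exposure_mean=config.exposure_mean, exposure_sd=config.exposure_sd,
        bmi_pleiotropy=gamma)
    cohort = stage("cohort", synthetic.simulate_cohort, panel,
                   config.n_individuals, params, seed=seed)
    cohort = synthetic.attach_panel(cohort, panel)
    specs = default_trait_specs(config.n_traits)
    cohort = stage("phenome", synthetic.simulate_phenome, cohort, specs, seed=seed)
    io.write_cohort(cohort, out_dir / "cohort", config)
    log.info("cohort: n=%d, %d traits", cohort.n, len(specs))

    # --- instruments --------------------------------------------------------
    sets = stage("instruments", instruments.build_instrument_sets, panel, cohort,
                 child_hits, adult_hits, window_bp=config.proximity_window_bp)
    covariates = cohort.default_covariates()
    strength_rows = []
    scores = {}
    for label in config.instrument_sets:
        vset = sets[label]
        io.write_table(vset.to_frame(panel), out_dir / f"instrument_set_{label}.tsv",
                       **meta)
        sub = vset.subset(panel)
        score = instruments.compute_grs(cohort.dosages,
                                        sub.set_index("rsid")["beta_exposure"])
        scores[label] = score
        s = instruments.instrument_strength(score, cohort.exposure, covariates)
        strength_rows.append({"set": label, "n_snps": len(sub),
                              "r_squared": s.r_squared,
                              "f_statistic": s.f_statistic, "n": s.n})
        log.info("set %s: %d SNPs, R2=%.4f F=%.1f", label, len(sub),
                 s.r_squared, s.f_statistic)
    io.write_table(pd.DataFrame(strength_rows), out_dir / "instrument_strength.tsv",
                   **meta)

    # --- phenome scan -------------------------------------------------------
    options = phenome_scan.ScanOptions(
        case_floor=config.case_floor, max_ordered_levels=config.max_ordered_levels,
        int_offset=config.int_offset, q_fdr=config.q_fdr, alpha=config.alpha)
    reports = {}
    for label in config.instrument_sets:
        results, report = stage(f"phewas[{label}]", phenome_scan.run_phewas,
                                cohort, scores[label], covariates=covariates,
                                options=options)
        reports[label] = report
        io.write_table(phenome_scan.results_frame(results, report),
                       out_dir / f"phewas_{label}.tsv", **meta)
        io.write_table(
            pd.DataFrame(list(report.__dict__.items()), columns=["key", "value"]),
            out_dir / f"thresholds_{label}.tsv", **meta)
        tested_p = [r.pval for r in results if r.tested]
        io.write_table(phenome_scan.qq_data(tested_p),
                       out_dir / f"qq_{label}.tsv", **meta)
        log.info("phewas[%s]: %d tests, %d FDR, %d Bonferroni", label,
                 report.n_tests, report.n_fdr, report.n_bonf)

    # --- MR follow-up -------------------------------------------------------
    followup = list(config.followup_traits) or [
        s.name for s in specs if s.category == "affected"
        and s.kind == "continuous"][:2]
    outcome_cohort = stage("outcome_cohort", synthetic.simulate_cohort, panel,
                           config.n_individuals, params, seed=seed + 100_003)
    outcome_cohort = synthetic.attach_panel(outcome_cohort, panel)
    outcome_cohort = stage("outcome_phenome", synthetic.simulate_phenome,
                           outcome_cohort, specs, seed=seed + 100_003)
    mr_rows = []
    for trait in followup:
        out_stats = synthetic.gwas_summarize(outcome_cohort, trait)
        for label in ("all", "steiger", "bmi"):
            if label not in config.instrument_sets:
                continue
            sub = sets[label].subset(panel)
            mri = mr.harmonize(sub, out_stats,
                               palindrome_eaf_window=config.palindrome_eaf_window)
            ests = [
                mr.ivw(mri, "fixed"), mr.ivw(mri, "random"), mr.mr_egger(mri),
                mr.weighted_median(mri, config.bootstrap_reps, seed),
                mr.mode_estimate(mri, weighted=False,
                                 bootstrap_reps=config.bootstrap_reps, seed=seed),
                mr.mode_estimate(mri, weighted=True,
                                 bootstrap_reps=config.bootstrap_reps, seed=seed),
            ]
            presso = mr.mr_presso(mri, n_sim=config.presso_sims, seed=seed)
            tsls = mr.one_sample_mr(cohort, scores[label], trait,
                                    covariates, config.bootstrap_reps, seed)
            for est in ests + [tsls]:
                rep = mr.per_year_decrease(est)
                mr_rows.append({
                    "trait": trait, "set": label, "method": rep.method,
                    "beta_per_year_decrease": rep.beta, "se": rep.se,
                    "ci_low": rep.ci_low, "ci_high": rep.ci_high,
                    "pval": rep.pval, "n_snps": rep.n_snps,
                    **{f"extra_{k}": v for k, v in rep.extras.items()
                       if np.isscalar(v)},
                })
            mr_rows.append({
                "trait": trait, "set": label, "method": "presso_global",
                "pval": presso.global_p, "n_snps": len(mri),
                "extra_outliers": ";".join(presso.outliers) or "none",
                "extra_distortion_p": presso.distortion_p,
                "extra_report_adjusted": presso.report_adjusted,
            })
    if mr_rows:
        io.write_table(pd.DataFrame(mr_rows), out_dir / "mr_followup.tsv", **meta)

    # --- power --------------------------------------------------------------
    r2_main = strength_rows[0]["r_squared"]
    power_rows = []
    for n_rep in (4566, 22990, 60552, 79055):
        pr = power.mde_continuous(n_rep, 0.05)
        power_rows.append({"cohort": f"replication_n{n_rep}", "n": pr.n,
                           "r2": pr.r2_xz, "alpha": pr.alpha,
                           "power": pr.power, "mde": pr.mde})
    pr = power.mde_continuous(config.n_individuals, max(min(r2_main, 0.99), 1e-6))
    power_rows.append({"cohort": "synthetic", "n": pr.n, "r2": pr.r2_xz,
                       "alpha": pr.alpha, "power": pr.power, "mde": pr.mde})
    io.write_table(pd.DataFrame(power_rows), out_dir / "power.tsv", **meta)

    log.info("pipeline complete: %s", out_dir)
    return out_dir
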