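"""End-to-end orchestration: instrument processing, the four-step ladder,
mediation analysis, multiple-testing correction and report generation.

The four re-estimation steps are:

1. MR with the complete instrument set after significance selection, LD
   clumping, palindrome removal and harmonization;
2. step 1 minus SNPs significant in the MR-PRESSO outlier test
   (Bonferroni-adjusted p < alpha);
3. step 1 minus *every* SNP whose adjusted outlier p-value is below 1
   (any simulated-exceedance signal at all);
4. step 3 minus the user-supplied confounder-associated SNPs.

The SNP sets are nested by construction (step 1 ⊇ 2 ⊇ 3 ⊇ 4) and the ladder
never iterates beyond step 4.  Significance uses the Bonferroni-adjusted
threshold alpha/n_outcomes with strict inequality.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators, mediation, presso
from .gwas_io import SummaryDataset, load_config, write_report, write_run_metadata
from .instruments import (
    HarmonizedSet,
    LDMatrix,
    drop_palindromic,
    exclude_snps,
    harmonize,
    ld_clump,
    select_by_pvalue,
)

logger = logging.getLogger("mrmediate")

DEFAULT_CONFIG = {
    "pval_threshold": 5e-8,
    "clump_r2": 0.001,
    "clump_kb": 10_000,
    "palindrome_window": 0.08,
    "presso_nsim": 2000,
    "presso_outlier_alpha": 0.05,
    "wm_boot": 1000,
    "ivw_mode": "multiplicative_random",
    "alpha": 0.05,
    "n_outcomes": 4,
    "seed": 0,
}


def bonferroni_threshold(alpha: float = 0.05, n_outcomes: int = 1) -> float:
    """Bonferroni-adjusted significance threshold alpha / n_outcomes."""
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_outcomes


@dataclass
class StepResult:
    """All estimates and diagnostics for one step of the ladder."""

    step: int
    snp_ids: list
    estimates: dict           # method -> MREstimate
    q_ivw: estimators.QResult
    q_egger: estimators.QResult | None
    egger_intercept: estimators.EggerIntercept | None
    presso: presso.PressoResult | None

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)


def prepare_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix | None = None,
    mediators: list | None = None,
    config: dict | None = None,
) -> HarmonizedSet:
    """Selection → clumping → palindrome removal → harmonization."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    sel = select_by_pvalue(exposure, cfg["pval_threshold"])
    if ld is not None:
        sel = ld_clump(sel, ld, cfg["clump_r2"], cfg["clump_kb"])
    return harmonize(sel, outcome, mediators=mediators, maf_window=cfg["palindrome_window"])


def _run_step(h: HarmonizedSet, step: int, cfg: dict) -> StepResult:
    est_ivw, q_ivw = estimators.ivw(h, cfg["ivw_mode"])
    ests = {"ivw": est_ivw}
    q_egger = intercept = None
    if h.n_snp >= 3:
        est_egger, intercept, q_egger = estimators.mr_egger(h)
        ests["egger"] = est_egger
        ests["weighted_median"] = estimators.weighted_median(
            h, n_boot=cfg["wm_boot"], seed=cfg["seed"] + step
        )
    pres = None
    if h.n_snp >= 4:
        pres = presso.mr_presso(
            h,
            K=cfg["presso_nsim"],
            seed=cfg["seed"] + 100 + step,
            alpha_outlier=cfg["presso_outlier_alpha"],
        )
    return StepResult(
        step=step,
        snp_ids=list(h.snp_ids),
        estimates=ests,
        q_ivw=q_ivw,
        q_egger=q_egger,
        egger_intercept=intercept,
        presso=pres,
    )


def run_four_steps(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix | None = None,
    confounder_list=(),
    config: dict | None = None,
) -> list:
    """Run the four-step outlier/confounder-removal ladder.

    Outlier classification for steps 2 and 3 comes from the step-1 MR-PRESSO
    outlier test; step 4 additionally removes the confounder list.  Any step
    that would empty the instrument set raises, naming the step.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    h1 = prepare_instruments(exposure, outcome, ld, config=cfg)
    results = [_run_step(h1, 1, cfg)]

    pres1 = results[0].presso
    if pres1 is not None and pres1.outlier_pvals is not None:
        adjusted = pres1.outlier_pvals
        sig_ids = {h1.snp_ids[i] for i in np.flatnonzero(adjusted < cfg["presso_outlier_alpha"])}
        any_ids = {h1.snp_ids[i] for i in np.flatnonzero(adjusted < 1.0)}
    else:
        sig_ids, any_ids = set(), set()

    def drop(h, ids, step):
        if not ids:
            return h
        mask = np.array([s not in ids for s in h.snp_ids])
        if not mask.any():
            raise RuntimeError(f"step {step} would remove every instrument")
        return h.subset(mask)

    h2 = drop(h1, sig_ids, 2)
    results.append(_run_step(h2, 2, cfg))
    h3 = drop(h1, any_ids, 3)
    results.append(_run_step(h3, 3, cfg))
    h4 = drop(h3, set(confounder_list), 4)
    results.append(_run_step(h4, 4, cfg))

    sets = [set(r.snp_ids) for r in results]
    for a, b in zip(sets, sets[1:]):
        if not b.issubset(a):
            raise AssertionError("SNP sets are not nested across steps")
    logger.info("four-step ladder SNP counts: %s", [r.n_snp for r in results])
    return results


def steps_report(steps: list, outcome_name: str) -> pd.DataFrame:
    """Table-shaped report: one row per (outcome, step, method)."""
    rows = []
    for sr in steps:
        for method, est in sr.estimates.items():
            q = sr.q_egger if method == "egger" else sr.q_ivw
            rows.append(
                {
                    "outcome": outcome_name,
                    "step": sr.step,
                    "method": method,
                    "n_snp": sr.n_snp,
                    "beta": est.beta,
                    "se": est.se,
                    "pval": est.pval,
                    "Q": q.Q if (q and method in ("ivw", "egger")) else np.nan,
                    "Q_pval": q.pval if (q and method in ("ivw", "egger")) else np.nan,
                    "egger_intercept": sr.egger_intercept.intercept
                    if (method == "egger" and sr.egger_intercept)
                    else np.nan,
                    "egger_intercept_se": sr.egger_intercept.se
                    if (method == "egger" and sr.egger_intercept)
                    else np.nan,
                    "egger_intercept_pval": sr.egger_intercept.pval
                    if (method == "egger" and sr.egger_intercept)
                    else np.nan,
                    "presso_global_pval": sr.presso.global_pval
                    if (method == "ivw" and sr.presso)
                    else np.nan,
                    "presso_distortion_pval": sr.presso.distortion_pval
                    if (method == "ivw" and sr.presso)
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_mediation_analysis(
    exposure: SummaryDataset,
    mediators: list,
    outcome: SummaryDataset,
    ld: LDMatrix | None = None,
    config: dict | None = None,
    mode: str = "product",
):
    """Two-step + MVMR mediation for one outcome and one or more mediators.

    Univariable legs use each trait's own genome-wide-significant, clumped
    instruments; the MVMR leg uses the union of the per-trait instrument
    sets (each clumped by its own p-values).  Returns a dict with the
    Table-2-style univariable estimates, per-mediator MediationResults, and
    the joint adjustment when two or more mediators are given.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}

    def instruments_for(ds):
        sel = select_by_pvalue(ds, cfg["pval_threshold"])
        if ld is not None:
            sel = ld_clump(sel, ld, cfg["clump_r2"], cfg["clump_kb"])
        return sel

    def uni(ds_exp, ds_out, seed_shift):
        sel = instruments_for(ds_exp)
        h = harmonize(sel, ds_out, maf_window=cfg["palindrome_window"])
        est, q = estimators.ivw(h, cfg["ivw_mode"])
        return est, q, h

    exp_sel = instruments_for(exposure)
    beta3, _, _ = uni(exposure, outcome, 0)

    twostep_rows = []
    beta1s = {}
    for m in mediators:
        b1, _, _ = uni(exposure, m, 1)
        beta1s[m.trait_name] = b1
        b_mo, _, _ = uni(m, outcome, 2)
        twostep_rows.append(
            {"exposure": exposure.trait_name, "outcome": m.trait_name, **_row(b1)}
        )
        twostep_rows.append({"exposure": m.trait_name, "outcome": outcome.trait_name, **_row(b_mo)})

    def mvmr_for(meds):
        union_ids = list(exp_sel.snp_ids)
        seen = set(union_ids)
        for m in meds:
            for s in instruments_for(m).snp_ids:
                if s not in seen:
                    seen.add(s)
                    union_ids.append(s)
        h = harmonize(
            exposure.subset(union_ids),
            outcome,
            mediators=[m.subset(union_ids) for m in meds],
            maf_window=cfg["palindrome_window"],
        )
        return mediation.mvmr_fit(h)

    results = []
    for m in mediators:
        mv = mvmr_for([m])
        results.append(
            mediation.two_step_mediation(
                beta1s[m.trait_name],
                beta3,
                mv,
                m.trait_name,
                mode=mode,
                seed=cfg["seed"] + 7,
            )
        )
    joint = None
    joint_prop = None
    if len(mediators) >= 2:
        joint = mvmr_for(mediators)
        joint_prop = mediation.joint_proportion(beta1s, joint, beta3, mode=mode)

    adjusted_rows = [
        {
            "label": f"Adjusted for {r.mediator}",
            "outcome": outcome.trait_name,
            "estimate": r.beta3_prime,
            "proportion_pct": r.proportion_pct,
        }
        for r in results
    ]
    if joint is not None:
        adjusted_rows.append(
            {
                "label": "Adjusted for " + " + ".join(m.trait_name for m in mediators),
                "outcome": outcome.trait_name,
                "estimate": joint.as_estimate("exposure"),
                "proportion_pct": 100.0 * joint_prop,
            }
        )
    report = mediation.mediation_report({outcome.trait_name: beta3}, adjusted_rows)
    return {
        "beta3": beta3,
        "mediation_results": results,
        "joint_mvmr": joint,
        "joint_proportion_pct": None if joint_prop is None else 100.0 * joint_prop,
        "twostep": pd.DataFrame(twostep_rows),
        "report": report,
    }


def _row(est):
    return {
        "method": est.method,
        "n_snp": est.n_snp,
        "beta": est.beta,
        "se": est.se,
        "pval": est.pval,
    }


def run_full_analysis(config, out_dir: str | None = None) -> dict:
    """Run the complete analysis described by a configuration mapping.

    ``config`` is a dict or YAML path.  Inputs come either from a synthetic
    preset (``simulate: {preset, seed}``) or from files (``exposure``,
    ``outcome``, optional ``mediators``, ``ld_r2``+``ld_pos``, ``exclude``).
    Writes results.tsv (step ladder), twostep.tsv and mediation.tsv when a
    mediator is present, and a run.json metadata sidecar.  Deterministic for
    a fixed config and seed.
    """
    from .gwas_io import read_sumstats
    from .synthetic import preset_truth, simulate_study

    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**DEFAULT_CONFIG, **{k: v for k, v in config.items() if k in DEFAULT_CONFIG}}

    mediators = []
    if "simulate" in config:
        sim = config["simulate"]
        study = simulate_study(preset_truth(sim["preset"], seed=sim.get("seed", cfg["seed"])))
        exposure, outcome, ld = study.exposure, study.outcome, study.ld
        confounders = study.exclusion_list
        if study.mediator is not None:
            mediators = [study.mediator]
    else:
        exposure = read_sumstats(config["exposure"], trait_name="exposure")
        outcome = read_sumstats(config["outcome"], trait_name="outcome")
        for i, mpath in enumerate(config.get("mediators", [])):
            mediators.append(read_sumstats(mpath, trait_name=f"mediator{i + 1}"))
        ld = (
            LDMatrix.from_tsv(config["ld_r2"], config["ld_pos"])
            if "ld_r2" in config
            else None
        )
        confounders = []
        if config.get("exclude"):
            with open(config["exclude"]) as fh:
                confounders = [line.strip() for line in fh if line.strip()]

    steps = run_four_steps(exposure, outcome, ld, confounders, cfg)
    report = steps_report(steps, outcome.trait_name)
    threshold = bonferroni_threshold(cfg["alpha"], cfg["n_outcomes"])
    report["significant"] = report["pval"] < threshold

    bundle = {"steps": steps, "results": report, "bonferroni_threshold": threshold}
    if mediators:
        med = run_mediation_analysis(exposure, mediators, outcome, ld, cfg)
        bundle["mediation"] = med

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        write_report(report, os.path.join(out_dir, "results.tsv"))
        if mediators:
            write_report(bundle["mediation"]["twostep"], os.path.join(out_dir, "twostep.tsv"))
            write_report(bundle["mediation"]["report"], os.path.join(out_dir, "mediation.tsv"))
        write_run_metadata(os.path.join(out_dir, "run.json"), seed=cfg["seed"], config=cfg)
    return bundle
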