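"""Seeded replication experiments over the synthetic study conditions.

Each function repeatedly simulates a study under a named preset, runs the
relevant part of the analysis, and summarises the behaviour of interest —
type-I error calibration, parameter recovery, mediated-share recovery,
robustness to directional pleiotropy, and outlier detection.  These are the
computations behind the reproducibility script and the statistical tests in
the suite; all randomness is driven by a single integer seed.
"""
from __future__ import annotations

import math

import numpy as np

from . import estimators, mediation, presso
from .instruments import harmonize, select_by_pvalue
from .pipeline import prepare_instruments, run_four_steps
from .synthetic import SimTruth, preset_truth, simulate_study, structured_count_study

TOTAL_EFFECT = math.log(1.35)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def _harmonized(preset: str, seed: int):
    study = simulate_study(preset_truth(preset, seed=int(seed)))
    return prepare_instruments(study.exposure, study.outcome, study.ld), study


def null_calibration(n_rep: int = 500, seed: int = 0, presso_K: int = 1000, alpha: float = 0.05):
    """Rejection rates of IVW, Cochran's Q and the MR-PRESSO global test
    under the null preset (θ = 0, no pleiotropy, J = 75)."""
    seeds = _spawn_seeds(seed, n_rep)
    rej_ivw = rej_q = rej_presso = 0
    for s in seeds:
        h, _ = _harmonized("null", s)
        est, q = estimators.ivw(h)
        rej_ivw += est.pval < alpha
        rej_q += q.pval < alpha
        g = presso.presso_global(h, K=presso_K, seed=int(s) + 1)
        rej_presso += g.global_pval < alpha
    return {
        "ivw_type1": rej_ivw / n_rep,
        "q_rejection": rej_q / n_rep,
        "presso_rejection": rej_presso / n_rep,
        "n_rep": n_rep,
    }


def ivw_recovery(n_rep: int = 500, seed: int = 0, theta: float = TOTAL_EFFECT):
    """Mean IVW estimate, Monte-Carlo SE and 95% CI coverage under the
    causal preset (θ = ln 1.35, 75 valid instruments, consortium n's)."""
    seeds = _spawn_seeds(seed, n_rep)
    betas = np.empty(n_rep)
    covered = 0
    for i, s in enumerate(seeds):
        h, _ = _harmonized("causal", s)
        est, _ = estimators.ivw(h)
        betas[i] = est.beta
        covered += est.ci_low <= theta <= est.ci_high
    return {
        "mean_beta": float(betas.mean()),
        "mc_se": float(betas.std(ddof=1) / np.sqrt(n_rep)),
        "coverage": covered / n_rep,
        "theta": theta,
        "n_rep": n_rep,
    }


def mediation_recovery(n_rep: int = 500, seed: int = 0):
    """Product-mode proportion mediated under the mediation preset
    (implied mediated share exactly 35%)."""
    seeds = _spawn_seeds(seed, n_rep)
    props = np.empty(n_rep)
    truth = preset_truth("mediation")
    for i, s in enumerate(seeds):
        study = simulate_study(preset_truth("mediation", seed=int(s)))
        exp_sel = select_by_pvalue(study.exposure)
        med_sel = select_by_pvalue(study.mediator)
        # beta1: exposure -> mediator on the exposure's instruments
        b1, _ = estimators.ivw(harmonize(exp_sel, study.mediator))
        # beta3: total effect on the exposure's instruments
        b3, _ = estimators.ivw(harmonize(exp_sel, study.outcome))
        # MVMR on the union of both traits' instruments
        union = list(exp_sel.snp_ids) + [
            s_ for s_ in med_sel.snp_ids if s_ not in set(exp_sel.snp_ids)
        ]
        h_mv = harmonize(
            study.exposure.subset(union), study.outcome, mediators=[study.mediator.subset(union)]
        )
        mv = mediation.mvmr_fit(h_mv)
        b2, _, _ = mv.coefficient("mediator")
        props[i] = b1.beta * b2 / b3.beta
    return {
        "mean_proportion_pct": float(100 * props.mean()),
        "mc_se_pct": float(100 * props.std(ddof=1) / np.sqrt(n_rep)),
        "true_pct": float(100 * truth.implied_proportion_mediated),
        "n_rep": n_rep,
    }


def pleiotropy_robustness(n_rep: int = 200, seed: int = 0, n_boot: int = 200):
    """IVW vs weighted median under 40% directional pleiotropy.

    Reports each estimator's mean estimate and mean reported SE so the bias
    of IVW (driven by the invalid instruments) can be contrasted with the
    weighted median's robustness.
    """
    seeds = _spawn_seeds(seed, n_rep)
    ivw_b = np.empty(n_rep)
    ivw_se = np.empty(n_rep)
    wm_b = np.empty(n_rep)
    wm_se = np.empty(n_rep)
    for i, s in enumerate(seeds):
        h, _ = _harmonized("pleiotropy", s)
        est, _ = estimators.ivw(h)
        ivw_b[i], ivw_se[i] = est.beta, est.se
        wm = estimators.weighted_median(h, n_boot=n_boot, seed=int(s) + 3)
        wm_b[i], wm_se[i] = wm.beta, wm.se
    return {
        "theta": TOTAL_EFFECT,
        "ivw_mean_beta": float(ivw_b.mean()),
        "ivw_mean_se": float(ivw_se.mean()),
        "wm_mean_beta": float(wm_b.mean()),
        "wm_mean_se": float(wm_se.mean()),
        "n_rep": n_rep,
    }


def outlier_detection(n_rep: int = 100, seed: int = 0, K: int = 2000, alpha: float = 0.05):
    """Detection rate of a planted 10-SE pleiotropic outlier by the
    MR-PRESSO outlier test, plus the step-1→step-2 heterogeneity change."""
    seeds = _spawn_seeds(seed, n_rep)
    detected = 0
    q_reduced = 0
    for s in seeds:
        h, study = _harmonized("outlier", s)
        res = presso.presso_outlier(h, K=K, seed=int(s) + 11, alpha_outlier=alpha)
        flagged = set(res.outlier_snp_ids)
        detected += study.outlier_ids[0] in flagged
        if flagged:
            mask = np.array([sid not in flagged for sid in h.snp_ids])
            _, q1 = estimators.ivw(h)
            _, q2 = estimators.ivw(h.subset(mask))
            q_reduced += q2.pval > q1.pval
    return {
        "detection_rate": detected / n_rep,
        "q_pval_increased_rate": q_reduced / n_rep,
        "n_rep": n_rep,
    }


def count_ladder(seed: int = 0, K: int = 2000):
    """SNP counts of the four-step ladder on the count-mirroring fixture."""
    study = structured_count_study(seed)
    steps = run_four_steps(
        study.exposure,
        study.outcome,
        study.ld,
        study.exclusion_list,
        {"presso_nsim": K, "seed": seed, "wm_boot": 200},
    )
    return {"counts": [s.n_snp for s in steps], "steps": steps}
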