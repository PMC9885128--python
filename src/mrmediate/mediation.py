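"""Multivariable MR and two-step mediation analysis.

Multivariable MR (MVMR) regresses per-SNP outcome effects on the matrix of
exposure effects (primary exposure plus mediators), weights σY⁻², without an
intercept, yielding each exposure's *direct* effect adjusted for the others.

Two-step mediation combines

* β1 — exposure→mediator effect (univariable MR),
* β2 — mediator→outcome effect (by default the mediator's MVMR-adjusted
  direct coefficient; a univariable estimate can be supplied instead),
* β3 — total exposure→outcome effect (univariable MR),
* β3′ — direct exposure→outcome effect (MVMR),

into the proportion mediated, β1·β2/β3 (product mode) or (β3−β3′)/β3
(difference mode), reported as a percentage.  Mediation is considered
present when four conditions hold: β1 significant, β3 significant without
adjustment, β2 significant, and |β3′| < |β3|.  Out-of-range proportions
(negative or above 100%) are reported as computed, with a warning flag.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, QResult, Z95, _estimate, ivw
from .instruments import HarmonizedSet

logger = logging.getLogger("mrmediate")


@dataclass
class MVMRResult:
    """Direct (mutually adjusted) effects of several exposures on the outcome."""

    exposures: list
    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    n_snp: int
    q: QResult

    def coefficient(self, name: str) -> tuple:
        i = self.exposures.index(name)
        return float(self.betas[i]), float(self.ses[i]), float(self.pvals[i])

    def as_estimate(self, name: str, method: str = "mvmr") -> MREstimate:
        b, s, p = self.coefficient(name)
        return MREstimate(method, b, s, b - Z95 * s, b + Z95 * s, p, self.n_snp)


@dataclass
class MediationResult:
    """β1, β2, β3, β3′, the four mediation conditions, and the mediated share."""

    mediator: str
    beta1: MREstimate
    beta2: MREstimate
    beta3: MREstimate
    beta3_prime: MREstimate
    proportion_mediated: float
    proportion_pct: float
    proportion_se_pct: float
    condition_flags: tuple
    mode: str
    out_of_range: bool

    @property
    def mediation_present(self) -> bool:
        return all(self.condition_flags)


def mvmr_fit(h: HarmonizedSet, exposure_name: str = "exposure") -> MVMRResult:
    """Weighted least squares of βY on the exposure-beta matrix, no intercept.

    Requires instruments harmonized across all exposures and the outcome,
    with n_snp exceeding the number of exposures.  SEs carry a multiplicative
    overdispersion factor max(1, sqrt(Q_mv/(n−p))); p-values are two-sided
    normal.  A rank-deficient design raises, naming the exposures.
    """
    X = h.exposure_matrix()
    names = h.exposure_names(exposure_name)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"MVMR needs more SNPs ({n}) than exposures ({p})")
    w = h.se_outcome**-2
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(Xw) < p:
        raise ValueError(f"collinear exposure effect matrix: {names}")

    import statsmodels.api as sm

    fit = sm.WLS(h.beta_outcome, X, weights=w).fit()
    q = float(fit.ssr)
    df = n - p
    factor = max(1.0, np.sqrt(q / df))
    se = (fit.bse / np.sqrt(fit.scale)) * factor
    pvals = 2.0 * stats.norm.sf(np.abs(fit.params / se))
    return MVMRResult(
        exposures=names,
        betas=np.asarray(fit.params, dtype=float),
        ses=np.asarray(se, dtype=float),
        pvals=np.asarray(pvals, dtype=float),
        n_snp=n,
        q=QResult(q, df, float(stats.chi2.sf(q, df))),
    )


def proportion_mediated(beta1: float, beta2: float, beta3: float) -> float:
    """Product-of-coefficients mediated share, β1·β2/β3."""
    if beta3 == 0:
        raise ValueError("proportion mediated undefined for beta3 = 0")
    return beta1 * beta2 / beta3


def two_step_mediation(
    beta1: MREstimate,
    beta3: MREstimate,
    mvmr: MVMRResult,
    mediator: str,
    mode: str = "product",
    beta2_univariable: MREstimate | None = None,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    seed: int = 0,
) -> MediationResult:
    """Assemble a mediation result from the two-step and MVMR estimates.

    ``beta1`` is the univariable exposure→mediator estimate, ``beta3`` the
    univariable (total) exposure→outcome estimate; β2 and β3′ are read from
    ``mvmr`` (β2 from ``beta2_univariable`` instead when supplied).  The
    proportion's SE comes from seeded normal draws of (β1, β2, β3, β3′).
    """
    if mode not in ("product", "difference"):
        raise ValueError(f"unknown mediation mode {mode!r}")
    beta3_prime = mvmr.as_estimate("exposure" if "exposure" in mvmr.exposures else mvmr.exposures[0])
    beta2 = beta2_univariable if beta2_univariable is not None else mvmr.as_estimate(mediator)

    flags = (
        bool(beta1.pval < alpha),
        bool(beta3.pval < alpha),
        bool(beta2.pval < alpha),
        bool(abs(beta3_prime.beta) < abs(beta3.beta)),
    )
    if beta3.beta == 0:
        logger.warning("two_step_mediation: beta3 = 0; condition flags %s", flags)
        raise ValueError("proportion mediated undefined for beta3 = 0")

    if mode == "product":
        prop = beta1.beta * beta2.beta / beta3.beta
    else:
        prop = (beta3.beta - beta3_prime.beta) / beta3.beta

    rng = np.random.default_rng(seed)
    b1 = rng.normal(beta1.beta, beta1.se, n_sim)
    b2 = rng.normal(beta2.beta, beta2.se, n_sim)
    b3 = rng.normal(beta3.beta, beta3.se, n_sim)
    b3p = rng.normal(beta3_prime.beta, beta3_prime.se, n_sim)
    sims = b1 * b2 / b3 if mode == "product" else (b3 - b3p) / b3
    se_prop = float(np.std(sims, ddof=1))

    out_of_range = not (0.0 <= prop <= 1.0)
    if out_of_range:
        logger.warning(
            "two_step_mediation(%s): proportion mediated %.1f%% outside [0, 100]%%",
            mediator,
            100 * prop,
        )
    return MediationResult(
        mediator=mediator,
        beta1=beta1,
        beta2=beta2,
        beta3=beta3,
        beta3_prime=beta3_prime,
        proportion_mediated=float(prop),
        proportion_pct=float(100.0 * prop),
        proportion_se_pct=100.0 * se_prop,
        condition_flags=flags,
        mode=mode,
        out_of_range=out_of_range,
    )


def joint_proportion(
    beta1s: dict, mvmr: MVMRResult, beta3: MREstimate, mode: str = "product"
) -> float:
    """Mediated share of several mediators adjusted jointly.

    Product mode sums β1_m·β2_m over mediators (β2_m from the joint MVMR);
    difference mode uses (β3 − β3′_joint)/β3.
    """
    if beta3.beta == 0:
        raise ValueError("proportion mediated undefined for beta3 = 0")
    if mode == "difference":
        b3p = mvmr.as_estimate("exposure").beta
        return (beta3.beta - b3p) / beta3.beta
    total = 0.0
    for m, b1 in beta1s.items():
        b2, _, _ = mvmr.coefficient(m)
        total += b1.beta * b2
    return total / beta3.beta


def mediation_report(
    univariable: dict,
    adjusted_rows: list,
) -> pd.DataFrame:
    """Tabulate univariable estimates and each adjustment set.

    ``univariable`` maps outcome name -> total-effect MREstimate;
    ``adjusted_rows`` is a list of dicts with keys ``label``, ``outcome``,
    ``estimate`` (the adjusted exposure MREstimate) and ``proportion_pct``.
    """
    rows = []
    for outcome, est in univariable.items():
        rows.append(
            {
                "model": "Univariable IVW",
                "outcome": outcome,
                "beta": est.beta,
                "se": est.se,
                "or": est.odds_ratio,
                "ci_low": est.or_ci[0],
                "ci_high": est.or_ci[1],
                "pval": est.pval,
                "mediation_pct": np.nan,
            }
        )
    for row in adjusted_rows:
        est = row["estimate"]
        rows.append(
            {
                "model": row["label"],
                "outcome": row["outcome"],
                "beta": est.beta,
                "se": est.se,
                "or": est.odds_ratio,
                "ci_low": est.or_ci[0],
                "ci_high": est.or_ci[1],
                "pval": est.pval,
                "mediation_pct": row.get("proportion_pct", np.nan),
            }
        )
    return pd.DataFrame(rows)
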