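"""Univariable two-sample MR estimators and heterogeneity diagnostics.

All estimators consume a :class:`~mrmediate.instruments.HarmonizedSet` of
per-SNP exposure effects (βX_j, σX_j) and outcome effects (βY_j, σY_j):

* Wald ratio — per-SNP estimate βY/βX with first-order SE |σY/βX|.
* IVW — inverse-variance-weighted meta-analysis of Wald ratios, i.e.
  weighted regression of βY on βX through the origin with weights σY⁻².
  The default SE mode is multiplicative random effects: the fixed-effect SE
  is inflated by max(1, sqrt(Q/(n−1))) and never shrinks below it.
* MR-Egger — weighted regression of βY on βX with an intercept, probing
  directional pleiotropy; instruments are oriented so that βX_j >= 0.
* Weighted median — median of the ratio distribution weighted by
  (βX/σY)², consistent when more than half of the weight is valid;
  SE by seeded parametric bootstrap.
* Cochran's Q, leave-one-out and funnel-plot data as diagnostics.

p-values are two-sided: normal for IVW/Wald/weighted median, Student t with
n−2 degrees of freedom for the MR-Egger slope and intercept (small-sample
convention).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import HarmonizedSet

logger = logging.getLogger("mrmediate")

Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """One method's causal estimate on the log odds-ratio scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    @property
    def significant(self) -> bool:
        return self.pval < 0.05


@dataclass
class QResult:
    """Cochran's Q heterogeneity statistic with its chi-square p-value."""

    Q: float
    df: int
    pval: float


@dataclass
class EggerIntercept:
    """MR-Egger intercept: the average directional pleiotropy per SNP."""

    intercept: float
    se: float
    pval: float


def _estimate(method, beta, se, pval=None, n_snp=1, df=None) -> MREstimate:
    if pval is None:
        if df is None:
            pval = 2.0 * stats.norm.sf(abs(beta) / se)
        else:
            pval = 2.0 * stats.t.sf(abs(beta) / se, df)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(pval),
        n_snp=int(n_snp),
    )


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MREstimate:
    """Single-SNP causal estimate by/bx with first-order SE |sy/bx|."""
    if bx == 0:
        raise ValueError("wald_ratio undefined for bx = 0")
    beta = by / bx
    se = abs(sy / bx)
    return _estimate("wald", beta, se, n_snp=1)


def ivw(h: HarmonizedSet, re_mode: str = "multiplicative_random") -> tuple:
    """Inverse-variance-weighted estimate and Cochran's Q.

    Returns ``(MREstimate, QResult)``.  With a single SNP the estimate falls
    back to the Wald ratio (Q undefined, df 0).  ``re_mode`` is ``"fixed"``
    or ``"multiplicative_random"`` (default); the latter multiplies the
    fixed-effect SE by max(1, sqrt(Q/(n−1))).
    """
    if re_mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown re_mode {re_mode!r}")
    bx, by = h.beta_exposure, h.beta_outcome
    sy = h.se_outcome
    n = h.n_snp
    if n == 1:
        est = wald_ratio(bx[0], h.se_exposure[0], by[0], sy[0])
        return _estimate("ivw", est.beta, est.se, n_snp=1), QResult(0.0, 0, float("nan"))
    if np.all(bx == 0):
        raise ValueError("all exposure betas are zero")
    w = sy**-2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = n - 1
    qres = QResult(q, df, float(stats.chi2.sf(q, df)))
    se = se_fixed
    if re_mode == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(q / df))
    return _estimate("ivw", beta, se, n_snp=n), qres


def mr_egger(h: HarmonizedSet) -> tuple:
    """MR-Egger regression: slope (causal), intercept (pleiotropy) and Q'.

    Instruments are oriented so every βX_j >= 0 (flipping βX and βY signs
    together), then βY is regressed on βX with an intercept, weights σY⁻².
    SEs carry a multiplicative overdispersion factor max(1, sqrt(Q'/(n−2)));
    p-values use Student t with n−2 df.  Requires >= 3 SNPs.
    """
    n = h.n_snp
    if n < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    flip = np.sign(h.beta_exposure)
    flip[flip == 0] = 1.0
    bx = h.beta_exposure * flip
    by = h.beta_outcome * flip
    w = h.se_outcome**-2

    import statsmodels.api as sm

    X = sm.add_constant(bx, has_constant="add")
    fit = sm.WLS(by, X, weights=w).fit()
    q = float(fit.ssr)  # weighted residual sum of squares
    df = n - 2
    scale = np.sqrt(fit.scale)  # = sqrt(Q'/(n-2))
    factor = max(1.0, np.sqrt(q / df))
    se_unscaled = fit.bse / scale
    se_int, se_slope = se_unscaled * factor
    b_int, b_slope = fit.params
    est = _estimate("egger", b_slope, se_slope, n_snp=n, df=df)
    intercept = EggerIntercept(
        intercept=float(b_int),
        se=float(se_int),
        pval=float(2.0 * stats.t.sf(abs(b_int) / se_int, df)),
    )
    qres = QResult(q, df, float(stats.chi2.sf(q, df)))
    return est, intercept, qres


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the standardized CDF."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Ratio estimates r_j = βY_j/βX_j are weighted by (βX_j/σY_j)²; SNPs with
    βX_j = 0 are excluded with a warning.  The SE is the standard deviation
    of ``n_boot`` seeded replicates in which βX and βY are redrawn from
    normals centred on their observed values.
    """
    keep = h.beta_exposure != 0
    if not keep.all():
        logger.warning("weighted_median: excluding %d SNPs with bx=0", int((~keep).sum()))
    if not keep.any():
        raise ValueError("weighted_median: no SNPs with non-zero exposure beta")
    hh = h.subset(keep)
    if hh.n_snp < 3:
        raise ValueError("weighted_median requires at least 3 usable SNPs")
    bx, by = hh.beta_exposure, hh.beta_outcome
    sx, sy = hh.se_exposure, hh.se_outcome
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, hh.n_snp))
    by_b = rng.normal(by, sy, size=(n_boot, hh.n_snp))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxi = bx_b[i]
        ok = bxi != 0
        boots[i] = _weighted_median(by_b[i][ok] / bxi[ok], (bxi[ok] / sy[ok]) ** 2)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", beta, se, n_snp=hh.n_snp)


def leave_one_out(h: HarmonizedSet, re_mode: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-estimates omitting each SNP in turn.

    A row is flagged when dropping that SNP changes the significance/sign
    conclusion relative to the full-set IVW estimate.
    """
    if h.n_snp < 3:
        raise ValueError("leave_one_out requires at least 3 SNPs")
    full, _ = ivw(h, re_mode)
    full_sig = full.ci_low > 0 or full.ci_high < 0
    rows = []
    for j in range(h.n_snp):
        mask = np.ones(h.n_snp, dtype=bool)
        mask[j] = False
        est, _ = ivw(h.subset(mask), re_mode)
        sig = est.ci_low > 0 or est.ci_high < 0
        flagged = (sig != full_sig) or (sig and np.sign(est.beta) != np.sign(full.beta))
        rows.append(
            {
                "snp_id": h.snp_ids[j],
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "flagged": bool(flagged),
            }
        )
    return pd.DataFrame(rows)


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald estimates and precisions (1/SE) for funnel plotting."""
    keep = h.beta_exposure != 0
    hh = h.subset(keep) if keep.any() else None
    if hh is None:
        raise ValueError("funnel_data: no SNPs with non-zero exposure beta")
    wald = hh.beta_outcome / hh.beta_exposure
    se = np.abs(hh.se_outcome / hh.beta_exposure)
    return pd.DataFrame({"snp_id": hh.snp_ids, "wald": wald, "precision": 1.0 / se})
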