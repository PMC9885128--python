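"""MR-PRESSO: parametric-bootstrap pleiotropy residual sum and outlier tests.

Three tests on a harmonized instrument set:

* **global test** — the observed residual sum of squares
  RSS = Σ_j w_j (βY_j − β̂₍₋j₎ βX_j)², with β̂₍₋j₎ the leave-one-out
  fixed-effect IVW estimate and w_j = σY_j⁻², is compared with K parametric
  simulations in which βX*_j ~ N(βX_j, σX_j) and βY*_j ~ N(β̂₍₋j₎ βX_j, σY_j);
  the p-value is the add-one exceedance fraction (1 + #{RSS* >= RSS})/(K+1).
* **outlier test** — each SNP's observed weighted residual is compared with
  its own simulated distribution; per-SNP p-values are Bonferroni-multiplied
  by the number of SNPs and capped at 1.
* **distortion test** — the relative change of the IVW estimate after
  removing the flagged outliers, referenced against removals of equally many
  random SNPs.  Reported as missing when no outlier is flagged.

Note the granularity limit: with K simulations the smallest attainable
Bonferroni-adjusted outlier p-value is n_snp/(K+1), so K must exceed
n_snp/alpha for the outlier test to be able to flag anything at that alpha.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .instruments import HarmonizedSet

logger = logging.getLogger("mrmediate")


@dataclass
class PressoResult:
    """Global, per-SNP outlier and distortion results of MR-PRESSO."""

    rss_obs: float
    global_pval: float
    outlier_pvals_raw: np.ndarray | None = None
    outlier_pvals: np.ndarray | None = None  # Bonferroni-adjusted, capped at 1
    outlier_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    outlier_snp_ids: list = field(default_factory=list)
    distortion_pval: float = float("nan")
    distortion_obs: float = float("nan")
    beta_raw: float = float("nan")
    beta_outlier_corrected: float = float("nan")
    K: int = 0

    @property
    def has_outliers(self) -> bool:
        return len(self.outlier_indices) > 0


def _loo_betas(bx, by, w):
    """Fixed-effect IVW estimates leaving each SNP out, vectorised."""
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _weighted_residuals(bx, by, w):
    loo = _loo_betas(bx, by, w)
    return w * (by - loo * bx) ** 2


def _ivw_fixed(bx, by, w) -> float:
    return float(np.sum(w * bx * by) / np.sum(w * bx * bx))


def _simulate_residuals(h: HarmonizedSet, K: int, rng) -> tuple:
    """Observed residuals plus a (K, n_snp) matrix of simulated residuals."""
    bx, by = h.beta_exposure, h.beta_outcome
    sx, sy = h.se_exposure, h.se_outcome
    w = sy**-2
    loo_obs = _loo_betas(bx, by, w)
    resid_obs = w * (by - loo_obs * bx) ** 2
    bx_sim = rng.normal(bx, sx, size=(K, h.n_snp))
    by_sim = rng.normal(loo_obs * bx, sy, size=(K, h.n_snp))
    resid_sim = _weighted_residuals(bx_sim, by_sim, w)
    return resid_obs, resid_sim


def presso_global(h: HarmonizedSet, K: int = 1000, seed: int = 0) -> PressoResult:
    """Global heterogeneity test; see module docstring for the procedure."""
    if h.n_snp < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    resid_obs, resid_sim = _simulate_residuals(h, K, rng)
    rss_obs = float(resid_obs.sum())
    rss_sim = resid_sim.sum(axis=1)
    global_pval = (1.0 + int(np.sum(rss_sim >= rss_obs))) / (K + 1.0)
    w = h.se_outcome**-2
    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        beta_raw=_ivw_fixed(h.beta_exposure, h.beta_outcome, w),
        K=K,
    )


def presso_outlier(
    h: HarmonizedSet, K: int = 1000, seed: int = 0, alpha_outlier: float = 0.05
) -> PressoResult:
    """Global plus per-SNP outlier test (Bonferroni-adjusted p-values)."""
    if h.n_snp < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    rng = np.random.default_rng(seed)
    resid_obs, resid_sim = _simulate_residuals(h, K, rng)
    rss_obs = float(resid_obs.sum())
    rss_sim = resid_sim.sum(axis=1)
    global_pval = (1.0 + int(np.sum(rss_sim >= rss_obs))) / (K + 1.0)
    raw = (1.0 + np.sum(resid_sim >= resid_obs, axis=0)) / (K + 1.0)
    adjusted = np.minimum(1.0, raw * h.n_snp)
    outliers = np.flatnonzero(adjusted < alpha_outlier)
    if h.n_snp / (K + 1.0) >= alpha_outlier > 0:
        logger.warning(
            "presso_outlier: K=%d cannot reach adjusted p < %g with %d SNPs "
            "(minimum attainable %.4f); increase K",
            K,
            alpha_outlier,
            h.n_snp,
            h.n_snp / (K + 1.0),
        )
    w = h.se_outcome**-2
    res = PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals_raw=raw,
        outlier_pvals=adjusted,
        outlier_indices=outliers,
        outlier_snp_ids=[h.snp_ids[i] for i in outliers],
        beta_raw=_ivw_fixed(h.beta_exposure, h.beta_outcome, w),
        K=K,
    )
    return res


def presso_distortion(
    h: HarmonizedSet, outlier_indices, K: int = 1000, seed: int = 0
) -> tuple:
    """Distortion test: does removing the outliers change the IVW estimate?

    Returns ``(distortion_pval, beta_corrected, distortion_obs)``.  With an
    empty outlier set the distortion is undefined and NaN is returned
    (reported as "NA").  The null distribution removes equally many SNPs at
    random; the two-sided p-value is the add-one exceedance fraction of
    |distortion|.
    """
    outlier_indices = np.asarray(outlier_indices, dtype=int)
    n_out = len(outlier_indices)
    if n_out == 0:
        return float("nan"), float("nan"), float("nan")
    n = h.n_snp
    if n - n_out < 2:
        raise ValueError("removing the outliers leaves fewer than 2 SNPs")
    w = h.se_outcome**-2
    bx, by = h.beta_exposure, h.beta_outcome
    beta_all = _ivw_fixed(bx, by, w)
    keep = np.ones(n, dtype=bool)
    keep[outlier_indices] = False
    beta_no = _ivw_fixed(bx[keep], by[keep], w[keep])
    d_obs = (beta_no - beta_all) / beta_no
    rng = np.random.default_rng(seed)
    d_null = np.empty(K)
    for k in range(K):
        drop = rng.choice(n, size=n_out, replace=False)
        m = np.ones(n, dtype=bool)
        m[drop] = False
        b = _ivw_fixed(bx[m], by[m], w[m])
        d_null[k] = (b - beta_all) / b
    pval = (1.0 + int(np.sum(np.abs(d_null) >= abs(d_obs)))) / (K + 1.0)
    return float(pval), float(beta_no), float(d_obs)


def mr_presso(
    h: HarmonizedSet,
    K: int = 1000,
    seed: int = 0,
    alpha_outlier: float = 0.05,
    run_distortion: bool = True,
) -> PressoResult:
    """Full MR-PRESSO: global, outlier and distortion tests in one pass."""
    res = presso_outlier(h, K=K, seed=seed, alpha_outlier=alpha_outlier)
    if run_distortion and res.has_outliers:
        pval, beta_no, d_obs = presso_distortion(h, res.outlier_indices, K=K, seed=seed + 1)
        res.distortion_pval = pval
        res.beta_outlier_corrected = beta_no
        res.distortion_obs = d_obs
    return res
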