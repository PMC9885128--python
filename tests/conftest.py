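import numpy as np
import pandas as pd
import pytest

from mrmediate.gwas_io import SummaryDataset
from mrmediate.instruments import HarmonizedSet


def make_harmonized(bx, by, sy, sx=None, snp_ids=None, eaf=None, mediators=None):
    """Build a HarmonizedSet directly from arrays (test helper)."""
    bx = np.asarray(bx, dtype=float)
    n = len(bx)
    return HarmonizedSet(
        snp_ids=np.asarray(snp_ids if snp_ids is not None else [f"rs{i}" for i in range(n)]),
        beta_exposure=bx,
        se_exposure=np.asarray(sx if sx is not None else np.full(n, 1e-6), dtype=float),
        beta_outcome=np.asarray(by, dtype=float),
        se_outcome=np.asarray(sy, dtype=float),
        eaf=None if eaf is None else np.asarray(eaf, dtype=float),
        mediators=mediators or {},
    )


def make_dataset(rows, trait_name="trait", trait_type="continuous", n=None):
    """SummaryDataset from a list of (snp_id, ea, oa, eaf, beta, se, pval) tuples."""
    tab = pd.DataFrame(
        rows, columns=["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval"]
    )
    tab["n"] = np.nan
    return SummaryDataset(trait_name, trait_type, tab, sample_size_default=n)


def random_harmonized(rng, n_snp=20, theta=0.3):
    """A generic well-behaved harmonized set for oracle comparisons."""
    bx = rng.uniform(0.02, 0.08, n_snp) * rng.choice([-1, 1], n_snp)
    sx = rng.uniform(0.001, 0.004, n_snp)
    sy = rng.uniform(0.004, 0.01, n_snp)
    by = theta * bx + rng.normal(0, sy)
    return make_harmonized(bx, by, sy, sx=sx, eaf=rng.uniform(0.1, 0.5, n_snp))


@pytest.fixture
def rng():
    return np.random.default_rng(20260)


# -- independent weighted-least-squares oracle ------------------------------


def wls_oracle(X, y, w):
    """Brute-force WLS via the weighted normal equations.

    Returns (coefficients, fixed SEs from (X'WX)^-1, weighted RSS).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    A = X.T @ (X * w[:, None])
    b = np.linalg.solve(A, X.T @ (w * y))
    resid = y - X @ b
    q = float(np.sum(w * resid**2))
    se = np.sqrt(np.diag(np.linalg.inv(A)))
    return b, se, q


def weighted_median_oracle(ratios, weights):
    """Explicit crossing-point weighted median (independent of the estimator)."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    cdf = np.cumsum(w) - 0.5 * w
    if cdf[0] >= 0.5:
        return float(r[0])
    for j in range(1, len(r)):
        if cdf[j] >= 0.5:
            frac = (0.5 - cdf[j - 1]) / (cdf[j] - cdf[j - 1])
            return float(r[j - 1] + frac * (r[j] - r[j - 1]))
    return float(r[-1])
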