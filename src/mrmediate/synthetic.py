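"""Synthetic GWAS summary statistics with known ground truth.

Emulates the structure of the consortium-scale datasets used in a
GERD→lung-cancer style analysis — a large binary exposure GWAS (n ≈ 602,604),
a case-control outcome GWAS (n ≈ 85,716; 29,266 cases), and mediator GWAS of
comparable size — so that every pipeline stage can be exercised without any
download.

Generative model, per instrument j (effect allele oriented
exposure-increasing, so true b_j > 0):

* minor-allele frequency maf_j ~ U(maf_range);
* per-SNP explained variance R²_j ~ U(r2_snp_range), giving
  b_j = sqrt(R²_j / (2·maf_j·(1−maf_j))).  The default range reproduces
  per-SNP instrument F values spanning roughly 210–670 at n = 602,604;
* mediator effect  γ1·b_j + u_j  (u_j nonzero only for the J_med
  mediator-specific instruments, which carry no direct exposure effect);
* outcome effect  θ·b_j + γ2·(γ1·b_j + u_j) + a_j  on the log-OR scale,
  where a_j is a horizontal-pleiotropy offset (directional mean mu_a, sd
  sigma_a, expressed in units of that SNP's outcome SE) on a fraction
  pi_invalid of instruments, plus optional single-SNP outlier offsets;
* observed betas = true betas + N(0, se), se = 1/sqrt(2·maf(1−maf)·n) per
  trait; p-values two-sided normal.

Structural decorations for the instrument-processing stages: palindromic
A/T / C/G records at intermediate frequency, allele-swapped outcome records,
LD-correlated decoy blocks with positions exercising both the r² and the
10,000-kb clumping rules, and a labelled confounder-associated subset.
Binary-trait effects are generated directly on the log-OR scale; no
individual-level liability simulation is performed.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import SummaryDataset, write_sumstats
from .instruments import LDMatrix

logger = logging.getLogger("mrmediate")

NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
PALINDROMIC_ALLELES = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimTruth:
    """Ground-truth parameters of a simulated study.

    ``theta`` is the *direct* exposure→outcome log-OR; the total effect is
    ``theta + gamma1*gamma2`` and the implied proportion mediated is
    ``gamma1*gamma2 / (theta + gamma1*gamma2)``.
    """

    theta: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    J: int = 75
    J_med: int = 0
    n_exp: int = 602_604
    n_out: int = 85_716
    n_med: int = 607_291
    maf_range: tuple = (0.1, 0.5)
    r2_snp_range: tuple = (3.5e-4, 1.11e-3)
    pi_invalid: float = 0.0
    mu_a: float = 0.0      # directional pleiotropy mean, in outcome-SE units
    sigma_a: float = 0.0   # pleiotropy spread, in outcome-SE units
    n_outliers: int = 0
    outlier_offset_se: float = 10.0
    n_palindromic: int = 0
    n_swapped: int = 0
    n_ld_blocks: int = 0
    n_decoys_per_block: int = 2
    n_far_decoys_per_block: int = 0
    decoy_r2: float = 0.9
    n_confounder: int = 0
    seed: int = 0

    @property
    def total_effect(self) -> float:
        return self.theta + self.gamma1 * self.gamma2

    @property
    def implied_proportion_mediated(self) -> float:
        tot = self.total_effect
        return self.gamma1 * self.gamma2 / tot if tot != 0 else float("nan")


@dataclass
class SimStudy:
    """Simulated summary datasets plus a complete ground-truth echo."""

    exposure: SummaryDataset
    outcome: SummaryDataset
    mediator: SummaryDataset | None
    ld: LDMatrix
    exclusion_list: list
    truth: SimTruth
    instrument_ids: list
    mediator_instrument_ids: list
    palindromic_ids: list
    decoy_ids: list
    outlier_ids: list
    invalid_ids: list
    true_beta_exposure: np.ndarray
    true_beta_outcome: np.ndarray
    true_beta_mediator: np.ndarray | None


def _se(maf, n):
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvals(beta, se):
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), np.nextafter(0.0, 1.0))


def _dataset(name, trait_type, ids, ea, oa, eaf, beta, se, n):
    tab = pd.DataFrame(
        {
            "snp_id": ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": float(n),
        }
    )
    return SummaryDataset(name, trait_type, tab, sample_size_default=int(n))


def simulate_study(truth: SimTruth) -> SimStudy:
    """Draw one study (exposure, optional mediator, outcome, LD, exclusions)."""
    rng = np.random.default_rng(truth.seed)
    J, Jm, Jp = truth.J, truth.J_med, truth.n_palindromic
    n_main = J + Jm + Jp

    maf = rng.uniform(*truth.maf_range, n_main)
    r2 = rng.uniform(*truth.r2_snp_range, n_main)
    eff = np.sqrt(r2 / (2.0 * maf * (1.0 - maf)))

    # roles: exposure instruments, mediator-specific instruments, palindromes
    b = eff.copy()
    u = np.zeros(n_main)
    if Jm:
        b[J : J + Jm] = 0.0
        u[J : J + Jm] = eff[J : J + Jm]
    # palindromic extras behave like ordinary exposure instruments
    if Jp:
        maf[J + Jm :] = rng.uniform(0.45, 0.55, Jp)
        b[J + Jm :] = np.sqrt(r2[J + Jm :] / (2.0 * maf[J + Jm :] * (1.0 - maf[J + Jm :])))

    ids = [f"rs{100000 + i}" for i in range(n_main)]
    pair_idx = rng.integers(0, len(NON_PALINDROMIC_PAIRS), n_main)
    ea = np.array([NON_PALINDROMIC_PAIRS[i][0] for i in pair_idx], dtype=object)
    oa = np.array([NON_PALINDROMIC_PAIRS[i][1] for i in pair_idx], dtype=object)
    for k in range(Jp):
        a1, a2 = PALINDROMIC_ALLELES[k % len(PALINDROMIC_ALLELES)]
        ea[J + Jm + k], oa[J + Jm + k] = a1, a2
    palindromic_ids = ids[J + Jm :]

    # horizontal pleiotropy on exposure instruments
    se_y = _se(maf, truth.n_out)
    a = np.zeros(n_main)
    n_invalid_exact = truth.pi_invalid * J
    n_invalid = int(round(n_invalid_exact))
    if abs(n_invalid_exact - n_invalid) > 1e-9:
        logger.warning("pi_invalid*J = %.2f not integer; rounded to %d", n_invalid_exact, n_invalid)
    invalid_idx = rng.choice(J, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    if n_invalid:
        a[invalid_idx] = (truth.mu_a + truth.sigma_a * rng.standard_normal(n_invalid)) * se_y[
            invalid_idx
        ]
    outlier_idx = (
        rng.choice(np.setdiff1d(np.arange(J), invalid_idx), size=truth.n_outliers, replace=False)
        if truth.n_outliers
        else np.array([], int)
    )
    a[outlier_idx] += truth.outlier_offset_se * se_y[outlier_idx]

    bm_true = truth.gamma1 * b + u
    by_true = truth.theta * b + truth.gamma2 * bm_true + a

    se_x = _se(maf, truth.n_exp)
    bx_obs = b + rng.normal(0.0, se_x)
    by_obs = by_true + rng.normal(0.0, se_y)
    make_mediator = Jm > 0 or truth.gamma1 != 0 or truth.gamma2 != 0
    if make_mediator:
        se_m = _se(maf, truth.n_med)
        bm_obs = bm_true + rng.normal(0.0, se_m)

    # ---- LD decoy blocks around the first n_ld_blocks exposure instruments
    all_ids = list(ids)
    chrom = [str(1 + (i % 22)) for i in range(n_main)]
    pos = [1_000_000 + 20_001_000 * (i // 22) for i in range(n_main)]
    decoy_rows_exp, decoy_rows_out, decoy_rows_med = [], [], []
    decoy_ids, decoy_links = [], []
    n_blocks = min(truth.n_ld_blocks, J)
    r = math.sqrt(truth.decoy_r2)
    for bi in range(n_blocks):
        lead = bi
        n_near = truth.n_decoys_per_block
        n_far = truth.n_far_decoys_per_block
        for di in range(n_near + n_far):
            did = f"rs{900000 + bi * 10 + di}"
            far = di >= n_near
            dpos = pos[lead] + (15_000_000 if far else 1_000 * (di + 1))
            dmaf = maf[lead]
            d_bx_true = r * b[lead]
            d_by_true = r * by_true[lead]
            d_sx, d_sy = se_x[lead], se_y[lead]
            dbx = d_bx_true + rng.normal(0.0, d_sx)
            dby = d_by_true + rng.normal(0.0, d_sy)
            decoy_rows_exp.append((did, ea[lead], oa[lead], dmaf, dbx, d_sx))
            decoy_rows_out.append((did, ea[lead], oa[lead], dmaf, dby, d_sy))
            if make_mediator:
                d_sm = se_m[lead]
                dbm = r * bm_true[lead] + rng.normal(0.0, d_sm)
                decoy_rows_med.append((did, ea[lead], oa[lead], dmaf, dbm, d_sm))
            all_ids.append(did)
            chrom.append(chrom[lead])
            pos.append(dpos)
            decoy_ids.append(did)
            decoy_links.append((lead, len(all_ids) - 1, far))

    n_all = len(all_ids)
    r2m = np.eye(n_all)
    for lead, di, far in decoy_links:
        r2m[lead, di] = r2m[di, lead] = truth.decoy_r2
    # decoys of the same lead are mutually correlated too
    by_lead: dict = {}
    for lead, di, far in decoy_links:
        for dj in by_lead.get(lead, []):
            r2m[di, dj] = r2m[dj, di] = truth.decoy_r2
        by_lead.setdefault(lead, []).append(di)
    ld = LDMatrix(all_ids, r2m, np.array(chrom, dtype=object), np.array(pos))

    def assemble(name, trait_type, beta_obs, se_arr, n, extra_rows, eaf_arr):
        ids_full = list(ids) + [row[0] for row in extra_rows]
        ea_full = np.concatenate([ea, np.array([row[1] for row in extra_rows], dtype=object)]) if extra_rows else ea
        oa_full = np.concatenate([oa, np.array([row[2] for row in extra_rows], dtype=object)]) if extra_rows else oa
        eaf_full = np.concatenate([eaf_arr, [row[3] for row in extra_rows]]) if extra_rows else eaf_arr
        beta_full = np.concatenate([beta_obs, [row[4] for row in extra_rows]]) if extra_rows else beta_obs
        se_full = np.concatenate([se_arr, [row[5] for row in extra_rows]]) if extra_rows else se_arr
        return _dataset(name, trait_type, ids_full, ea_full, oa_full, eaf_full, beta_full, se_full, n)

    exposure = assemble("exposure", "binary", bx_obs, se_x, truth.n_exp, decoy_rows_exp, maf)
    outcome = assemble("outcome", "binary", by_obs, se_y, truth.n_out, decoy_rows_out, maf)
    mediator = (
        assemble("mediator", "binary", bm_obs, se_m, truth.n_med, decoy_rows_med, maf)
        if make_mediator
        else None
    )

    # allele-swapped outcome records (harmonization must flip them back)
    if truth.n_swapped:
        swap_idx = rng.choice(J, size=min(truth.n_swapped, J), replace=False)
        tab = outcome.table
        for i in swap_idx:
            tab.loc[i, ["effect_allele", "other_allele"]] = (
                tab.loc[i, "other_allele"],
                tab.loc[i, "effect_allele"],
            )
            tab.loc[i, "beta"] = -tab.loc[i, "beta"]
            tab.loc[i, "eaf"] = 1.0 - tab.loc[i, "eaf"]

    exclusion = (
        [ids[i] for i in rng.choice(J, size=min(truth.n_confounder, J), replace=False)]
        if truth.n_confounder
        else []
    )

    return SimStudy(
        exposure=exposure,
        outcome=outcome,
        mediator=mediator,
        ld=ld,
        exclusion_list=sorted(exclusion),
        truth=truth,
        instrument_ids=ids[:J],
        mediator_instrument_ids=ids[J : J + Jm],
        palindromic_ids=palindromic_ids,
        decoy_ids=decoy_ids,
        outlier_ids=[ids[i] for i in outlier_idx],
        invalid_ids=[ids[i] for i in invalid_idx],
        true_beta_exposure=b,
        true_beta_outcome=by_true,
        true_beta_mediator=bm_true if make_mediator else None,
    )


# ---------------------------------------------------------------------------
# presets — the canonical study conditions used throughout the test suite

TOTAL_EFFECT = math.log(1.35)  # headline exposure→outcome log-OR
GAMMA1 = math.log(2.16)        # exposure→mediator log-OR (smoking-initiation scale)


def preset_truth(name: str, seed: int = 0) -> SimTruth:
    """Named study conditions: null, causal, pleiotropy, outlier, mediation, structural."""
    if name == "null":
        return SimTruth(theta=0.0, seed=seed)
    if name == "causal":
        return SimTruth(theta=TOTAL_EFFECT, seed=seed)
    if name == "pleiotropy":
        # 40% invalid instruments with a common directional offset of 0.7
        # outcome-SEs: biases IVW visibly while the weighted median (60% of
        # the weight valid) stays near the truth.
        return SimTruth(theta=TOTAL_EFFECT, pi_invalid=0.4, mu_a=0.7, sigma_a=0.0, seed=seed)
    if name == "outlier":
        return SimTruth(theta=TOTAL_EFFECT, n_outliers=1, outlier_offset_se=10.0, seed=seed)
    if name == "mediation":
        # direct + mediated decomposition with an implied mediated share of
        # exactly 35%: gamma1*gamma2 = 0.35 * total.
        gamma2 = 0.35 * TOTAL_EFFECT / GAMMA1
        return SimTruth(
            theta=0.65 * TOTAL_EFFECT,
            gamma1=GAMMA1,
            gamma2=gamma2,
            J_med=40,
            seed=seed,
        )
    if name == "structural":
        # exercises every filtering rule: 77 clean + 3 intermediate-frequency
        # palindromes (the 80→77 arithmetic), swapped outcome alleles, LD
        # decoy blocks (near and far), and eleven confounder-linked SNPs.
        return SimTruth(
            theta=TOTAL_EFFECT,
            J=77,
            n_palindromic=3,
            n_swapped=10,
            n_ld_blocks=5,
            n_decoys_per_block=2,
            n_far_decoys_per_block=1,
            n_confounder=11,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("null", "causal", "pleiotropy", "outlier", "mediation", "structural")
FIXTURE_PRESETS = ("null", "pleiotropy", "outlier", "mediation")


def write_fixture_suite(out_dir, seed: int = 0) -> list:
    """Write the canonical seeded fixtures (null, pleiotropy, outlier, mediation).

    Deterministic: re-running with the same seed reproduces every file
    byte-for-byte.  Returns the list of directories written.
    """
    import os

    written = []
    for name in FIXTURE_PRESETS:
        d = os.path.join(out_dir, name)
        os.makedirs(d, exist_ok=True)
        study = simulate_study(preset_truth(name, seed=seed))
        write_sumstats(study.exposure, os.path.join(d, "exposure.tsv"))
        write_sumstats(study.outcome, os.path.join(d, "outcome.tsv"))
        if study.mediator is not None:
            write_sumstats(study.mediator, os.path.join(d, "mediator.tsv"))
        study.ld.to_tsv(os.path.join(d, "ld_r2.tsv"), os.path.join(d, "positions.tsv"))
        with open(os.path.join(d, "exclude.txt"), "w") as fh:
            fh.write("".join(s + "\n" for s in study.exclusion_list))
        with open(os.path.join(d, "truth.json"), "w") as fh:
            json.dump(asdict(study.truth), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(d)
    return written


def structured_count_study(seed: int = 0) -> SimStudy:
    """Synthetic noise-free fixture mirroring a 75→72→68→60 four-step ladder.

    Observed betas equal their true values; three instruments carry huge
    (±12 SE) pleiotropic offsets that the outlier test flags at the
    Bonferroni-adjusted 0.05 level, four carry moderate (±2.8 SE) offsets
    flagged only by the any-signal (adjusted p < 1) rule, and eight clean
    instruments are listed as confounder-associated.  Offsets are
    sign-balanced so the clean instruments' residuals stay near zero and the
    step counts are stable across analysis seeds.
    """
    J = 75
    theta = TOTAL_EFFECT
    maf = np.full(J, 0.3)
    b = np.linspace(0.04, 0.06, J)
    se_x = _se(maf, 602_604)
    se_y = _se(maf, 85_716)
    offsets = np.zeros(J)
    strong = [0, 1, 2]
    moderate = [3, 4, 5, 6]
    offsets[strong] = np.array([12.0, -12.0, 12.0]) * se_y[strong]
    offsets[moderate] = np.array([2.8, 2.8, -2.8, -2.8]) * se_y[moderate]
    by = theta * b + offsets
    ids = [f"rs{200000 + i}" for i in range(J)]
    ea = np.array(["A"] * J, dtype=object)
    oa = np.array(["G"] * J, dtype=object)
    exposure = _dataset("exposure", "binary", ids, ea, oa, maf, b, se_x, 602_604)
    outcome = _dataset("outcome", "binary", ids, ea, oa, maf, by, se_y, 85_716)
    ld = LDMatrix(
        ids,
        np.eye(J),
        np.array([str(1 + i % 22) for i in range(J)], dtype=object),
        np.array([1_000_000 + 20_001_000 * (i // 22) for i in range(J)]),
    )
    confounders = [ids[i] for i in range(10, 18)]
    truth = SimTruth(theta=theta, J=J, n_outliers=7, seed=seed)
    return SimStudy(
        exposure=exposure,
        outcome=outcome,
        mediator=None,
        ld=ld,
        exclusion_list=confounders,
        truth=truth,
        instrument_ids=ids,
        mediator_instrument_ids=[],
        palindromic_ids=[],
        decoy_ids=[],
        outlier_ids=[ids[i] for i in strong + moderate],
        invalid_ids=[],
        true_beta_exposure=b,
        true_beta_outcome=by,
        true_beta_mediator=None,
    )
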