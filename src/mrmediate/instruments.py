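"""Instrument selection, LD clumping, allele harmonization and strength.

Implements the instrument-processing stages of a two-sample MR analysis:

* genome-wide significance filtering (default p < 5e-8, strict),
* greedy LD clumping (r² < 0.001 within a 10,000 kb window),
* removal of palindromic (A/T, C/G) variants with intermediate allele
  frequency, where the strand cannot be inferred,
* harmonization of outcome (and mediator) effects onto the exposure's
  effect allele,
* instrument-strength F statistics, F = ((n−k−1)/k) · R²/(1−R²).

No strand inference is attempted: ambiguity is always resolved by dropping.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gwas_io import SummaryDataset

logger = logging.getLogger("mrmediate")

PALINDROMIC_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


# ---------------------------------------------------------------------------
# containers


@dataclass
class LDMatrix:
    """Squared-correlation matrix with genomic positions for clumping.

    ``r2`` is symmetric with unit diagonal and entries in [0, 1]; positions
    are 1-based base-pair coordinates, one chromosome label per SNP.
    """

    snp_ids: list
    r2: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def index(self, snp_id: str) -> int:
        return self._index[snp_id]

    def to_tsv(self, r2_path, pos_path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            r2_path, sep="\t", index_label="snp_id"
        )
        pd.DataFrame({"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos}).to_csv(
            pos_path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, r2_path, pos_path) -> "LDMatrix":
        r2 = pd.read_csv(r2_path, sep="\t", index_col=0)
        pos = pd.read_csv(pos_path, sep="\t", dtype={"chrom": str}).set_index("snp_id")
        ids = [str(s) for s in r2.index]
        pos = pos.loc[ids]
        return cls(ids, r2.to_numpy(dtype=float), pos["chrom"].to_numpy(), pos["pos"].to_numpy())


@dataclass
class HarmonizedSet:
    """Exposure/outcome (and mediator) effects aligned to a shared effect allele.

    This is the unit every estimator consumes: per-SNP exposure betas/SEs
    (βX, σX), outcome betas/SEs (βY, σY) and optionally one beta/SE pair per
    mediator, all expressed relative to the exposure's effect allele.
    """

    snp_ids: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None
    eaf: np.ndarray | None = None
    flipped: np.ndarray | None = None
    mediators: dict = field(default_factory=dict)
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.snp_ids)
        if n < 1:
            raise ValueError("harmonized set must contain at least one SNP")
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be positive")
        if self.flipped is None:
            self.flipped = np.zeros(n, dtype=bool)
        if self.eaf is not None:
            self.eaf = np.asarray(self.eaf, dtype=float)
        for m, (b, s) in self.mediators.items():
            b, s = np.asarray(b, dtype=float), np.asarray(s, dtype=float)
            if len(b) != n or len(s) != n or np.any(s <= 0):
                raise ValueError(f"mediator {m}: bad beta/se arrays")
            self.mediators[m] = (b, s)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask) -> "HarmonizedSet":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_snp, dtype=bool)
            idx[mask] = True
            mask = idx
        return HarmonizedSet(
            snp_ids=self.snp_ids[mask],
            beta_exposure=self.beta_exposure[mask],
            se_exposure=self.se_exposure[mask],
            beta_outcome=self.beta_outcome[mask],
            se_outcome=self.se_outcome[mask],
            effect_allele=None if self.effect_allele is None else self.effect_allele[mask],
            other_allele=None if self.other_allele is None else self.other_allele[mask],
            eaf=None if self.eaf is None else self.eaf[mask],
            flipped=self.flipped[mask],
            mediators={m: (b[mask], s[mask]) for m, (b, s) in self.mediators.items()},
        )

    def exclude(self, snp_ids, reason: str = "") -> "HarmonizedSet":
        return exclude_snps(self, snp_ids, reason)

    def exposure_matrix(self) -> np.ndarray:
        """Column-stacked exposure betas: primary exposure first, then mediators."""
        cols = [self.beta_exposure] + [b for b, _ in self.mediators.values()]
        return np.column_stack(cols)

    def exposure_names(self, primary: str = "exposure") -> list:
        return [primary] + list(self.mediators.keys())

    def as_datasets(self, exposure_name="exposure", outcome_name="outcome"):
        """Re-export as (exposure, outcome) SummaryDatasets in exposure coding."""
        from scipy.stats import norm

        def mk(name, beta, se):
            tab = pd.DataFrame(
                {
                    "snp_id": self.snp_ids,
                    "effect_allele": self.effect_allele,
                    "other_allele": self.other_allele,
                    "eaf": self.eaf if self.eaf is not None else np.nan,
                    "beta": beta,
                    "se": se,
                    "pval": np.maximum(2 * norm.sf(np.abs(beta / se)), np.nextafter(0, 1)),
                    "n": np.nan,
                }
            )
            return SummaryDataset(name, "continuous", tab)

        if self.effect_allele is None:
            raise ValueError("allele codes not retained in this set")
        return (
            mk(exposure_name, self.beta_exposure, self.se_exposure),
            mk(outcome_name, self.beta_outcome, self.se_outcome),
        )


@dataclass
class FStatReport:
    """Instrument-strength summary: per-SNP and overall F statistics."""

    per_snp_F: np.ndarray
    per_snp_r2: np.ndarray
    r2_total: float
    k: int
    n: int
    F_overall: float
    weak: bool  # F_overall <= 10


# ---------------------------------------------------------------------------
# operations


def select_by_pvalue(dataset: SummaryDataset, threshold: float = 5e-8) -> SummaryDataset:
    """Keep SNPs with p strictly below ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    keep = dataset.table["pval"] < threshold
    if not keep.any():
        raise ValueError(
            f"{dataset.trait_name}: no SNP passes p < {threshold:g}; relax the threshold"
        )
    return replace(dataset, table=dataset.table.loc[keep].reset_index(drop=True), n_dropped=0)


def ld_clump(
    dataset: SummaryDataset,
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> SummaryDataset:
    """Greedy LD clumping by p-value.

    Repeatedly retain the remaining SNP with the smallest p-value and discard
    every other remaining SNP on the same chromosome within ``window_kb`` of
    it whose r² with it is >= ``r2_max``.  Ties on p are broken by smaller
    position, then lexicographic snp_id, for determinism.
    """
    ids = dataset.table["snp_id"].tolist()
    missing = [s for s in ids if s not in ld._index]
    if missing:
        raise ValueError(f"SNPs absent from LD matrix: {missing}")
    window_bp = int(window_kb * 1000)
    idx = np.array([ld.index(s) for s in ids])
    pval = dataset.table["pval"].to_numpy(dtype=float)
    pos = ld.pos[idx]
    chrom = ld.chrom[idx]
    order = sorted(range(len(ids)), key=lambda i: (pval[i], pos[i], ids[i]))
    alive = np.ones(len(ids), dtype=bool)
    kept = []
    for i in order:
        if not alive[i]:
            continue
        kept.append(ids[i])
        near = (
            alive
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
            & (ld.r2[idx[i], idx] >= r2_max)
        )
        alive &= ~near
        alive[i] = False
    kept_set = set(kept)
    keep_mask = dataset.table["snp_id"].isin(kept_set)
    logger.info("ld_clump: kept %d of %d SNPs", len(kept), len(ids))
    return replace(dataset, table=dataset.table.loc[keep_mask].reset_index(drop=True), n_dropped=0)


def is_palindromic(effect_allele, other_allele) -> np.ndarray:
    ea = np.asarray(effect_allele, dtype=object)
    oa = np.asarray(other_allele, dtype=object)
    return np.array([frozenset((a, b)) in PALINDROMIC_PAIRS for a, b in zip(ea, oa)])


def drop_palindromic(dataset: SummaryDataset, maf_window: float = 0.08) -> SummaryDataset:
    """Remove A/T and C/G variants with intermediate (or missing) allele frequency.

    A palindromic variant whose eaf lies within ``maf_window`` of 0.5 cannot
    be strand-resolved and is dropped; palindromic variants with missing eaf
    are dropped conservatively.  Non-palindromic variants always pass.
    """
    tab = dataset.table
    pal = is_palindromic(tab["effect_allele"], tab["other_allele"])
    eaf = tab["eaf"].to_numpy(dtype=float)
    intermediate = np.abs(eaf - 0.5) <= maf_window
    ambiguous = pal & (intermediate | np.isnan(eaf))
    if ambiguous.any():
        logger.info(
            "%s: dropped %d palindromic intermediate-frequency SNPs",
            dataset.trait_name,
            int(ambiguous.sum()),
        )
    return replace(dataset, table=tab.loc[~ambiguous].reset_index(drop=True), n_dropped=0)


def _align(exp_tab: pd.DataFrame, other: pd.DataFrame):
    """Align ``other`` (indexed like exp_tab) onto the exposure allele coding.

    Returns (beta, se, flipped mask, compatible mask).
    """
    same = (other["effect_allele"] == exp_tab["effect_allele"]) & (
        other["other_allele"] == exp_tab["other_allele"]
    )
    swapped = (other["effect_allele"] == exp_tab["other_allele"]) & (
        other["other_allele"] == exp_tab["effect_allele"]
    )
    beta = np.where(swapped, -other["beta"], other["beta"]).astype(float)
    se = other["se"].to_numpy(dtype=float)
    return beta, se, swapped.to_numpy(), (same | swapped).to_numpy()


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    mediators: list | None = None,
    maf_window: float = 0.08,
) -> HarmonizedSet:
    """Inner-join exposure and outcome (and mediators) on snp_id and align alleles.

    Outcome records whose effect/other alleles are swapped relative to the
    exposure have their beta sign flipped (and eaf reflected); records whose
    alleles cannot be reconciled are dropped.  Palindromic variants with
    intermediate or missing frequency are dropped per :func:`drop_palindromic`.
    Every retained SNP is expressed on the exposure's effect allele.
    """
    mediators = mediators or []
    exp_i = exposure.indexed()
    ids = [s for s in exposure.snp_ids if s in set(outcome.snp_ids)]
    for m in mediators:
        mset = set(m.snp_ids)
        ids = [s for s in ids if s in mset]
    if not ids:
        raise ValueError(
            f"no shared SNPs between {exposure.trait_name} and {outcome.trait_name}"
        )
    exp_tab = exp_i.loc[ids]

    # palindromic policy on the joined set, using the exposure's eaf
    pal = is_palindromic(exp_tab["effect_allele"], exp_tab["other_allele"])
    eaf = exp_tab["eaf"].to_numpy(dtype=float)
    ambiguous = pal & ((np.abs(eaf - 0.5) <= maf_window) | np.isnan(eaf))
    n_pal = int(ambiguous.sum())
    keep = ~ambiguous
    exp_tab = exp_tab.loc[keep]
    ids = [s for s, k in zip(ids, keep) if k]

    out_tab = outcome.indexed().loc[ids]
    by, sy, flipped, compatible = _align(exp_tab, out_tab)
    med_aligned = {}
    for m in mediators:
        bm, sm, _, comp_m = _align(exp_tab, m.indexed().loc[ids])
        compatible = compatible & comp_m
        med_aligned[m.trait_name] = (bm, sm)
    n_bad = int((~compatible).sum())
    if n_bad:
        logger.info("harmonize: dropped %d allele-incompatible SNPs", n_bad)
    c = compatible
    return HarmonizedSet(
        snp_ids=np.asarray(ids, dtype=object)[c],
        beta_exposure=exp_tab["beta"].to_numpy(dtype=float)[c],
        se_exposure=exp_tab["se"].to_numpy(dtype=float)[c],
        beta_outcome=by[c],
        se_outcome=sy[c],
        effect_allele=exp_tab["effect_allele"].to_numpy(dtype=object)[c],
        other_allele=exp_tab["other_allele"].to_numpy(dtype=object)[c],
        eaf=eaf[keep][c],
        flipped=flipped[c],
        mediators={k: (b[c], s[c]) for k, (b, s) in med_aligned.items()},
        n_dropped_palindromic=n_pal,
        n_dropped_incompatible=n_bad,
    )


def exclude_snps(obj, exclusion_list, reason: str = ""):
    """Remove the listed SNPs from a SummaryDataset or HarmonizedSet.

    An empty list is a no-op; IDs absent from the set are logged and ignored.
    """
    excl = set(exclusion_list)
    if not excl:
        return obj
    if isinstance(obj, HarmonizedSet):
        present = set(obj.snp_ids)
        absent = excl - present
        if absent:
            logger.warning("exclude_snps: %d listed SNPs not present", len(absent))
        mask = np.array([s not in excl for s in obj.snp_ids])
        logger.info("exclude_snps: removed %d SNPs (%s)", int((~mask).sum()), reason or "unspecified")
        if not mask.any():
            raise ValueError("exclusion list removes every SNP")
        return obj.subset(mask)
    present = set(obj.snp_ids)
    absent = excl - present
    if absent:
        logger.warning("exclude_snps: %d listed SNPs not present", len(absent))
    keep = ~obj.table["snp_id"].isin(excl)
    logger.info("exclude_snps: removed %d SNPs (%s)", int((~keep).sum()), reason or "unspecified")
    return replace(obj, table=obj.table.loc[keep].reset_index(drop=True), n_dropped=0)


def f_statistics(obj, n: int | None = None) -> FStatReport:
    """Instrument-strength F statistics, F = ((n−k−1)/k) · R²/(1−R²).

    Per-SNP explained variance is approximated from summary data as
    R²_j = 2·eaf_j·(1−eaf_j)·beta_j² (unit-variance trait); the total R² is
    their sum.  Per-SNP F uses k = 1.  ``weak`` flags F_overall <= 10.
    """
    if isinstance(obj, HarmonizedSet):
        beta = obj.beta_exposure
        eaf = obj.eaf
    else:
        beta = obj.table["beta"].to_numpy(dtype=float)
        eaf = obj.table["eaf"].to_numpy(dtype=float)
        if n is None:
            n = obj.sample_size_default
    if n is None:
        raise ValueError("exposure sample size n is required")
    if eaf is None or np.isnan(np.asarray(eaf, dtype=float)).any():
        raise ValueError("eaf is required for every SNP to compute R²")
    eaf = np.asarray(eaf, dtype=float)
    k = len(beta)
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    r2_snp = 2.0 * eaf * (1.0 - eaf) * beta**2
    r2 = float(r2_snp.sum())
    if r2 >= 1:
        raise ValueError(f"total R² = {r2:.3f} >= 1: inconsistent inputs")
    f_overall = ((n - k - 1) / k) * (r2 / (1 - r2))
    per_snp_F = (n - 2) * (r2_snp / (1 - r2_snp))
    return FStatReport(
        per_snp_F=per_snp_F,
        per_snp_r2=r2_snp,
        r2_total=r2,
        k=k,
        n=int(n),
        F_overall=float(f_overall),
        weak=bool(f_overall <= 10),
    )
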