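"""Reading and writing GWAS summary-statistic tables and analysis reports.

Summary statistics are exchanged as delimited text tables with a mandatory
header, one row per SNP.  The canonical internal column names are

    snp_id, effect_allele, other_allele, eaf, beta, se, pval, n

``snp_id``, both alleles, ``beta`` and ``se`` are mandatory; ``eaf``,
``pval`` and ``n`` may be missing.  External files with different headers
are adapted through a column map (``{"snp_id": "rsid", ...}``).
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("mrmediate")

CANONICAL_COLUMNS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")
MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se")
VALID_ALLELES = frozenset("ACGT")

#: smallest positive double; p-values of exactly 0 are clamped here
TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class SummaryDataset:
    """A single trait's per-SNP association table.

    ``table`` holds the canonical columns above with one row per SNP;
    ``snp_id`` is unique within the dataset.  ``trait_type`` is ``"binary"``
    (betas are log odds ratios) or ``"continuous"``.
    """

    trait_name: str
    trait_type: str
    table: pd.DataFrame
    sample_size_default: int | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"trait_type must be binary/continuous, got {self.trait_type!r}")
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_id values in {self.trait_name}: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Series:
        return self.table["snp_id"]

    def subset(self, snp_ids) -> "SummaryDataset":
        """Restrict to the given SNPs, preserving the table's row order."""
        keep = self.table["snp_id"].isin(set(snp_ids))
        return replace(self, table=self.table.loc[keep].reset_index(drop=True), n_dropped=0)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("snp_id", drop=False)


def _coerce_numeric(s: pd.Series) -> pd.Series:
    return pd.to_numeric(s, errors="coerce")


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait_name: str = "trait",
    trait_type: str = "continuous",
    sep: str = "\t",
    sample_size: int | None = None,
) -> SummaryDataset:
    """Read a delimited summary-statistics file into a :class:`SummaryDataset`.

    Rows violating the per-record invariants (se > 0, valid distinct A/C/G/T
    alleles, eaf in [0,1] when present, parseable numerics) are dropped with a
    logged count.  Missing mandatory columns raise ``ValueError``.  p-values of
    exactly 0 are clamped to the smallest positive double.  A missing or
    unparseable ``pval`` is rederived from ``beta/se`` under normality.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA", ""], keep_default_na=True)
    if column_map:
        rename = {src: dst for dst, src in column_map.items()}
        raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")

    n_in = len(raw)
    df = pd.DataFrame({"snp_id": raw["snp_id"].astype(str).str.strip()})
    for col in ("effect_allele", "other_allele"):
        df[col] = raw[col].astype(str).str.strip().str.upper()
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = _coerce_numeric(raw[col]) if col in raw.columns else np.nan

    # p-values: clamp exact zeros, rederive missing ones from the z score
    zero_p = df["pval"] == 0
    if zero_p.any():
        logger.warning("%s: clamped %d zero p-values to %g", trait_name, int(zero_p.sum()), TINY_P)
        df.loc[zero_p, "pval"] = TINY_P
    from scipy.stats import norm

    derive = df["pval"].isna() & (df["se"] > 0)
    if derive.any():
        z = (df.loc[derive, "beta"] / df.loc[derive, "se"]).abs()
        df.loc[derive, "pval"] = np.maximum(2.0 * norm.sf(z), TINY_P)

    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
    )
    dropped = int(n_in - ok.sum())
    if dropped:
        logger.warning("%s: dropped %d/%d malformed rows", trait_name, dropped, n_in)
    df = df.loc[ok].reset_index(drop=True)
    return SummaryDataset(
        trait_name=trait_name,
        trait_type=trait_type,
        table=df[list(CANONICAL_COLUMNS)],
        sample_size_default=sample_size,
        n_dropped=dropped,
    )


def write_sumstats(dataset: SummaryDataset, path, sep: str = "\t") -> None:
    """Write a dataset back to a delimited file (missing values as NA).

    Floats are serialised with shortest round-trip repr so that
    ``read_sumstats(write_sumstats(d))`` is bit-identical on finite values.
    """
    dataset.table.to_csv(path, sep=sep, index=False, na_rep="NA")


def write_report(results: pd.DataFrame, path, sep: str = "\t") -> pd.DataFrame:
    """Write an estimate/diagnostics report with odds-ratio columns.

    ``results`` must be non-empty and carry numeric ``beta`` and ``se``
    columns; ``OR`` and ``OR 95% CI`` string columns are derived as
    ``exp(beta)`` and ``exp(beta ± 1.96·se)`` formatted to two decimals.
    Returns the decorated frame that was written.
    """
    if results is None or len(results) == 0:
        raise ValueError("write_report: empty results")
    out = results.copy()
    if "beta" in out.columns:
        z = 1.959963984540054
        or_ = np.exp(out["beta"].astype(float))
        out["OR"] = [f"{v:.2f}" for v in or_]
        if "se" in out.columns:
            lo = np.exp(out["beta"].astype(float) - z * out["se"].astype(float))
            hi = np.exp(out["beta"].astype(float) + z * out["se"].astype(float))
            out["OR 95% CI"] = [f"({a:.2f}-{b:.2f})" for a, b in zip(lo, hi)]
    out.to_csv(path, sep=sep, index=False, na_rep="NA")
    return out


def write_run_metadata(path, seed: int | None = None, config: dict | None = None) -> None:
    """JSON sidecar recording the seed, thresholds and library versions."""
    import scipy
    import statsmodels

    meta = {
        "seed": seed,
        "config": config or {},
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
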