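import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_dataset
from mrmediate.instruments import (
    LDMatrix,
    drop_palindromic,
    exclude_snps,
    f_statistics,
    harmonize,
    ld_clump,
    select_by_pvalue,
)


def simple_dataset(pvals, **kw):
    rows = [(f"rs{i}", "A", "G", 0.3, 0.05, 0.01, p) for i, p in enumerate(pvals)]
    return make_dataset(rows, **kw)


# ---------------------------------------------------------------- selection


def test_pvalue_selection_is_strict():
    ds = simple_dataset([1e-9, 1e-7])
    sel = select_by_pvalue(ds, 5e-8)
    assert list(sel.snp_ids) == ["rs0"]


def test_pvalue_selection_empty_result_raises():
    with pytest.raises(ValueError, match="relax"):
        select_by_pvalue(simple_dataset([0.5, 0.5]), 5e-8)


@given(t=st.floats(min_value=1e-10, max_value=0.99))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_selection_monotone_in_threshold(t):
    ds = simple_dataset([1e-9, 1e-7, 1e-4, 0.03, 0.4])
    wide = set(select_by_pvalue(ds, 0.999).snp_ids)
    try:
        narrow = set(select_by_pvalue(ds, t).snp_ids)
    except ValueError:
        narrow = set()
    assert narrow <= wide


# ----------------------------------------------------------------- clumping


def ld_of(ids, r2, pos, chrom=None):
    k = len(ids)
    return LDMatrix(ids, r2, np.array(chrom or ["1"] * k, dtype=object), np.array(pos))


def test_clump_drops_dominated_neighbour():
    ds = simple_dataset([1e-10, 1e-9])
    ld = ld_of(["rs0", "rs1"], np.array([[1, 0.9], [0.9, 1]]), [100, 1100])
    assert list(ld_clump(ds, ld).snp_ids) == ["rs0"]


def test_clump_keeps_correlated_pair_outside_window():
    ds = simple_dataset([1e-10, 1e-9])
    ld = ld_of(["rs0", "rs1"], np.array([[1, 0.9], [0.9, 1]]), [100, 20_000_100])
    assert list(ld_clump(ds, ld).snp_ids) == ["rs0", "rs1"]


def test_clump_missing_snp_raises_with_offenders():
    ds = simple_dataset([1e-10, 1e-9])
    ld = ld_of(["rs0"], np.eye(1), [100])
    with pytest.raises(ValueError, match="rs1"):
        ld_clump(ds, ld)


def brute_force_clump(ids, pvals, pos, chrom, r2, r2_max, window_bp):
    """Independent greedy oracle over explicit candidate lists."""
    remaining = sorted(range(len(ids)), key=lambda i: (pvals[i], pos[i], ids[i]))
    kept = []
    removed = set()
    for i in remaining:
        if i in removed:
            continue
        kept.append(ids[i])
        for j in remaining:
            if j == i or j in removed:
                continue
            if chrom[j] == chrom[i] and abs(pos[j] - pos[i]) <= window_bp and r2[i, j] >= r2_max:
                removed.add(j)
        removed.add(i)
    return kept


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_clump_matches_bruteforce_oracle_on_block_fixture(seed):
    rng = np.random.default_rng(seed)
    n = 50
    ids = [f"rs{i}" for i in range(n)]
    # 10 blocks of 5; high LD within a block, none across
    r2 = np.eye(n)
    for b in range(10):
        for i in range(5):
            for j in range(5):
                if i != j:
                    r2[b * 5 + i, b * 5 + j] = rng.uniform(0.0, 1.0)
    r2 = np.clip((r2 + r2.T) / 2, 0, 1)
    np.fill_diagonal(r2, 1.0)
    pos = np.concatenate([b * 3_000_000 + np.sort(rng.integers(0, 2_000_000, 5)) for b in range(10)])
    chrom = np.array(["1"] * n, dtype=object)
    pvals = rng.uniform(1e-12, 1e-8, n)
    ds = make_dataset([(ids[i], "A", "G", 0.3, 0.05, 0.01, pvals[i]) for i in range(n)])
    ld = LDMatrix(ids, r2, chrom, pos)
    got = list(ld_clump(ds, ld, r2_max=0.3, window_kb=1_000).snp_ids)
    want = brute_force_clump(ids, pvals, pos, chrom, r2, 0.3, 1_000_000)
    assert sorted(got) == sorted(want)


# -------------------------------------------------------------- palindromes


@pytest.mark.parametrize(
    "ea,oa,eaf,kept",
    [
        ("A", "T", 0.50, False),  # exactly intermediate
        ("A", "T", 0.10, True),   # strand inferable
        ("C", "G", 0.45, False),
        ("A", "G", 0.50, True),   # not palindromic
        ("A", "T", np.nan, False),  # missing frequency: conservative drop
    ],
)
def test_palindromic_filter_cases(ea, oa, eaf, kept):
    ds = make_dataset([("rs1", ea, oa, eaf, 0.05, 0.01, 1e-9)])
    out = drop_palindromic(ds, maf_window=0.08)
    assert (len(out) == 1) == kept


def test_eighty_with_three_intermediate_palindromes_leaves_77():
    rows = [(f"rs{i}", "A", "G", 0.3, 0.05, 0.01, 1e-9) for i in range(77)]
    rows += [(f"rsP{i}", "A", "T", 0.48, 0.05, 0.01, 1e-9) for i in range(3)]
    out = drop_palindromic(make_dataset(rows))
    assert len(make_dataset(rows)) == 80 and len(out) == 77


# ------------------------------------------------------------ harmonization


def paired_datasets():
    """10 aligned + 10 swapped + 2 incompatible outcome records."""
    exp_rows, out_rows = [], []
    for i in range(22):
        sid = f"rs{i}"
        exp_rows.append((sid, "A", "G", 0.3, 0.05, 0.01, 1e-9))
        if i < 10:
            out_rows.append((sid, "A", "G", 0.3, 0.2, 0.02, 0.01))
        elif i < 20:
            out_rows.append((sid, "G", "A", 0.7, 0.2, 0.02, 0.01))
        else:
            out_rows.append((sid, "T", "C", 0.3, 0.2, 0.02, 0.01))
    return make_dataset(exp_rows, trait_name="exp"), make_dataset(out_rows, trait_name="out")


def test_harmonize_flips_swapped_and_drops_incompatible():
    exp, out = paired_datasets()
    h = harmonize(exp, out)
    assert h.n_snp == 20
    assert h.n_dropped_incompatible == 2
    assert int(h.flipped.sum()) == 10
    flipped_betas = h.beta_outcome[h.flipped]
    assert np.allclose(flipped_betas, -0.2)
    assert np.allclose(h.beta_outcome[~h.flipped], 0.2)


def test_harmonize_is_idempotent():
    exp, out = paired_datasets()
    h1 = harmonize(exp, out)
    e2, o2 = h1.as_datasets()
    h2 = harmonize(e2, o2)
    assert np.allclose(h1.beta_outcome, h2.beta_outcome)
    assert np.allclose(h1.beta_exposure, h2.beta_exposure)
    assert not h2.flipped.any()


def test_harmonize_involution_under_global_allele_flip():
    exp, out = paired_datasets()
    flipped = out.table.copy()
    flipped[["effect_allele", "other_allele"]] = flipped[["other_allele", "effect_allele"]].values
    flipped["beta"] = -flipped["beta"]
    flipped["eaf"] = 1 - flipped["eaf"]
    out2 = make_dataset([], trait_name="out")
    out2.table = flipped
    h1, h2 = harmonize(exp, out), harmonize(exp, out2)
    assert np.allclose(h1.beta_outcome, h2.beta_outcome)


def test_harmonize_empty_intersection_raises():
    exp = make_dataset([("rs1", "A", "G", 0.3, 0.05, 0.01, 1e-9)])
    out = make_dataset([("rs2", "A", "G", 0.3, 0.05, 0.01, 1e-9)])
    with pytest.raises(ValueError, match="no shared"):
        harmonize(exp, out)


# ---------------------------------------------------------------- exclusion


def test_exclude_snps_set_arithmetic_and_noops():
    ds = simple_dataset([1e-9] * 68)
    assert len(exclude_snps(ds, [])) == 68
    assert len(exclude_snps(ds, [f"rs{i}" for i in range(11)], "confounders")) == 57
    assert len(exclude_snps(ds, ["rs_absent"])) == 68


# -------------------------------------------------------------- F statistic


def test_f_statistic_hand_arithmetic():
    # single SNP contributing R^2 = 0.01 at n = 1001
    beta = np.sqrt(0.01 / (2 * 0.5 * 0.5))
    ds = make_dataset([("rs1", "A", "G", 0.5, beta, 0.01, 1e-9)], n=1001)
    rep = f_statistics(ds)
    assert rep.F_overall == pytest.approx(999 * 0.01 / 0.99, rel=1e-12)
    assert not rep.weak

    # ten SNPs each R^2 = 0.001 at n = 10011
    beta = np.sqrt(0.001 / (2 * 0.5 * 0.5))
    ds = make_dataset([(f"rs{i}", "A", "G", 0.5, beta, 0.01, 1e-9) for i in range(10)], n=10011)
    rep = f_statistics(ds)
    assert rep.F_overall == pytest.approx(1000 * 0.01 / 0.99, rel=1e-12)


def test_f_zero_effect_gives_zero():
    ds = make_dataset([("rs1", "A", "G", 0.5, 0.0, 0.01, 1e-9)], n=1001)
    rep = f_statistics(ds)
    assert rep.F_overall == 0.0 and rep.weak


def test_f_monotone_in_r2_and_n():
    def f(b, n):
        ds = make_dataset([("rs1", "A", "G", 0.5, b, 0.01, 1e-9)], n=n)
        return f_statistics(ds).F_overall

    assert f(0.2, 1001) > f(0.1, 1001) > f(0.05, 1001)
    assert f(0.1, 2001) > f(0.1, 1001)


def test_f_inconsistent_r2_raises():
    ds = make_dataset([("rs1", "A", "G", 0.5, 2.0, 0.01, 1e-9)], n=1001)
    with pytest.raises(ValueError, match="R²|R2|inconsistent"):
        f_statistics(ds)
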