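"""VCF reading and QC: call rate, MAF, LD pruning, PI-HAT relatedness."""

import numpy as np
import pandas as pd
import pytest

from rohscan.genotype_io import (
    QcReport,
    filter_maf,
    filter_sample_call_rate,
    ld_prune,
    pi_hat,
    read_vcf,
    remove_related,
)
from rohscan.matrix import MISSING
from rohscan.sim import SimConfig, duplicate_sample, simulate_genotypes

from conftest import make_matrix
from oracles import brute_force_ld_prune


# ---------------------------------------------------------------- read_vcf

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2\n"
)
SAMPLE_MAP = {"s0": "alpaca", "s1": "alpaca", "s2": "llama"}


def _write_vcf(tmp_path, body):
    p = tmp_path / "toy.vcf"
    p.write_text(VCF_HEADER + body)
    return str(p)


def test_read_vcf_toy_round_trip(tmp_path):
    body = (
        "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1\n"
        "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\t1/1\t0/0\n"
        "chr2\t150\t.\tT\tC\t.\tPASS\t.\tGT\t0/1\t0/1\t0/1\n"
        "chr2\t250\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t./.\t1/1\n"
    )
    m = read_vcf(_write_vcf(tmp_path, body), SAMPLE_MAP)
    assert m.sample_ids == ["s0", "s1", "s2"]
    expected = np.array(
        [[0, -1, 2, 1, 0], [1, 0, 2, 1, -1], [2, 1, 0, 1, 2]], dtype=np.int8
    )
    assert np.array_equal(m.calls, expected)
    assert m.species_of["s2"] == "llama"


def test_read_vcf_skips_multiallelic_and_counts(tmp_path):
    body = (
        "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "chr1\t200\t.\tC\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2\t1/2\n"
        "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\n"
    )
    report = QcReport()
    m = read_vcf(_write_vcf(tmp_path, body), SAMPLE_MAP, report)
    assert m.n_variants == 2
    assert report.n_multiallelic_skipped == 1


def test_read_vcf_unsorted_raises(tmp_path):
    body = (
        "chr1\t300\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "chr1\t100\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\n"
    )
    with pytest.raises(ValueError, match="sorted"):
        read_vcf(_write_vcf(tmp_path, body), SAMPLE_MAP)


def test_read_vcf_sample_missing_from_map_raises(tmp_path):
    body = "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
    with pytest.raises(ValueError, match="sample map"):
        read_vcf(_write_vcf(tmp_path, body), {"s0": "alpaca"})


# ------------------------------------------------------- call-rate filter

def test_call_rate_boundary_is_inclusive():
    """1,000 variants: 10 missing (rate 0.990) retained, 11 (0.989) removed."""
    calls = np.zeros((3, 1000), dtype=np.int8)
    calls[1, :11] = MISSING
    calls[2, :10] = MISSING
    m = make_matrix(calls)
    out, report = filter_sample_call_rate(m, min_rate=0.99)
    assert out.sample_ids == ["s0", "s2"]
    assert [s for s, _ in report.samples_removed] == ["s1"]


def test_call_rate_all_removed_raises():
    calls = np.full((2, 100), MISSING, dtype=np.int8)
    with pytest.raises(ValueError, match="every sample"):
        filter_sample_call_rate(make_matrix(calls), min_rate=0.99)


# -------------------------------------------------------------- MAF filter

def test_maf_filter_boundaries_and_monomorphic():
    calls = np.zeros((10, 3), dtype=np.int8)
    # variant 0: all hom-ref -> MAF 0, removed
    calls[0, 1] = 1  # variant 1: one het among 10 -> MAF 1/20 = 0.05, retained
    calls[:, 2] = 2  # variant 2: monomorphic ALT -> minor allele is REF, MAF 0
    m = make_matrix(calls)
    out, report = filter_maf(m, min_maf=0.05)
    assert out.n_variants == 1
    assert out.variants["pos"].tolist() == [2000]
    assert report.n_variants_removed_maf == 2


def test_maf_all_missing_variant_counted_separately():
    calls = np.array([[0, MISSING], [1, MISSING], [2, MISSING]], dtype=np.int8)
    out, report = filter_maf(make_matrix(calls), min_maf=0.05)
    assert out.n_variants == 1
    assert report.n_variants_removed_all_missing == 1
    assert report.n_variants_removed_maf == 0


# --------------------------------------------------------------- LD prune

def test_identical_and_opposite_dosage_vectors_pruned():
    calls = np.array(
        [[0, 0, 2], [1, 1, 1], [2, 2, 0], [0, 0, 2]], dtype=np.int8
    )
    m = make_matrix(calls)
    out, report = ld_prune(m, window_n_variants=10, step=5, r2_threshold=0.1)
    # variants 2 and 3 are perfectly (anti-)correlated with variant 1
    assert out.n_variants == 1
    assert report.n_variants_removed_ld == 2


def test_ld_prune_matches_brute_force_oracle():
    rng = np.random.default_rng(17)
    n_samples, n_variants = 60, 200
    dosage = rng.integers(0, 3, size=(n_samples, n_variants)).astype(np.int8)
    # plant correlated blocks: copies of a neighbour with small perturbation
    for j in range(1, n_variants, 7):
        dosage[:, j] = dosage[:, j - 1]
        flip = rng.random(n_samples) < 0.05
        dosage[flip, j] = rng.integers(0, 3, size=int(flip.sum()))
    miss = rng.random(dosage.shape) < 0.02
    dosage[miss] = MISSING
    chroms = ["chr1"] * 120 + ["chr2"] * 80
    m = make_matrix(
        dosage,
        positions=np.concatenate([np.arange(1, 121), np.arange(1, 81)]) * 500,
        chrom=chroms,
    )
    out, report = ld_prune(m, window_n_variants=50, step=10, r2_threshold=0.2)
    expected = brute_force_ld_prune(m.dosage(), chroms, 50, 10, 0.2)
    kept_expected = [i for i in range(n_variants) if not expected[i]]
    assert out.n_variants == len(kept_expected)
    assert report.n_variants_removed_ld == int(expected.sum())


def test_independent_variants_rarely_pruned():
    rng = np.random.default_rng(23)
    dosage = rng.binomial(2, 0.5, size=(500, 300)).astype(np.int8)
    m = make_matrix(dosage, positions=np.arange(1, 301) * 1000)
    out, _ = ld_prune(m, window_n_variants=50, step=10, r2_threshold=0.1)
    # with 500 samples, independent pairs essentially never reach r^2 > 0.1
    assert out.n_variants >= 290


def test_ld_prune_window_too_small():
    with pytest.raises(ValueError):
        ld_prune(make_matrix(np.zeros((2, 5), dtype=np.int8)), window_n_variants=1)


# ------------------------------------------------------------------ PI-HAT

def test_pi_hat_duplicate_pair(single_pop_matrix):
    matrix, _ = single_pop_matrix
    dup = duplicate_sample(matrix, matrix.sample_ids[0], "dup")
    small = dup.subset_samples([matrix.sample_ids[0], matrix.sample_ids[1], "dup"])
    tab = pi_hat(small)
    row = tab[(tab.sample_i == matrix.sample_ids[0]) & (tab.sample_j == "dup")]
    # frequencies come from 3 samples only, so allow the clamped top range
    assert 0.95 <= float(row.pi_hat.iloc[0]) <= 1.0


def test_pi_hat_unrelated_pair_near_zero(single_pop_matrix):
    matrix, _ = single_pop_matrix
    tab = pi_hat(matrix)
    sub = tab.head(20)
    assert (sub.pi_hat <= 0.1).all()
    assert sub.reliable.all()


def test_pi_hat_parent_offspring_near_half(single_pop_matrix):
    matrix, _ = single_pop_matrix
    rng = np.random.default_rng(31)
    parent = matrix.calls[0].copy()
    freq = matrix.alt_frequencies()
    transmitted = np.where(
        parent == 1, rng.integers(0, 2, parent.size), (parent // 2)
    ).astype(np.int8)
    other = (rng.random(parent.size) < freq).astype(np.int8)
    child = transmitted + other
    calls = np.vstack([matrix.calls, child[None, :]])
    m2 = make_matrix(
        calls,
        positions=matrix.variants["pos"].to_numpy(),
        chrom=matrix.variants["chrom"].tolist(),
        sample_ids=matrix.sample_ids + ["child"],
    )
    tab = pi_hat(m2)
    row = tab[(tab.sample_i == matrix.sample_ids[0]) & (tab.sample_j == "child")]
    assert 0.4 <= float(row.pi_hat.iloc[0]) <= 0.6


def test_pi_hat_symmetric_under_sample_reordering(single_pop_matrix):
    matrix, _ = single_pop_matrix
    sub = matrix.subset_samples(matrix.sample_ids[:6])
    rev = matrix.subset_samples(list(reversed(matrix.sample_ids[:6])))
    t1 = pi_hat(sub).set_index(["sample_i", "sample_j"])["pi_hat"]
    t2 = pi_hat(rev).set_index(["sample_i", "sample_j"])["pi_hat"]
    for (a, b), v in t1.items():
        key = (a, b) if (a, b) in t2.index else (b, a)
        assert t2[key] == pytest.approx(v, abs=1e-12)


def test_pi_hat_sparse_pair_flagged_unreliable():
    rng = np.random.default_rng(2)
    calls = rng.integers(0, 3, size=(3, 60)).astype(np.int8)
    calls[0, 40:] = MISSING
    calls[1, :20] = MISSING  # pair (s0, s1) shares only variants 20..39
    tab = pi_hat(make_matrix(calls))
    row = tab[(tab.sample_i == "s0") & (tab.sample_j == "s1")]
    assert row.n_joint.iloc[0] == 20
    assert not bool(row.reliable.iloc[0])


# ---------------------------------------------------------- remove_related

def test_remove_related_no_pair_above_threshold(single_pop_matrix):
    matrix, _ = single_pop_matrix
    sub = matrix.subset_samples(matrix.sample_ids[:5])
    tab = pi_hat(sub)
    out, report = remove_related(sub, tab, pi_hat_max=0.5)
    assert out.sample_ids == sub.sample_ids
    assert report.samples_removed == []


def test_remove_related_duplicate_pair_removes_exactly_one(single_pop_matrix):
    matrix, _ = single_pop_matrix
    base = matrix.subset_samples(matrix.sample_ids[:5])
    dup = duplicate_sample(base, base.sample_ids[0], "zz_dup")
    tab = pi_hat(dup)
    out, report = remove_related(dup, tab, pi_hat_max=0.5)
    assert len(out.sample_ids) == 5
    # equal call rates: the lexicographically larger ID is removed
    assert [s for s, _ in report.samples_removed] == ["zz_dup"]


def test_remove_related_triangle_of_duplicates_keeps_one(single_pop_matrix):
    matrix, _ = single_pop_matrix
    base = matrix.subset_samples(matrix.sample_ids[:4])
    m = duplicate_sample(base, base.sample_ids[0], "dup_b")
    m = duplicate_sample(m, base.sample_ids[0], "dup_c")
    tab = pi_hat(m)
    out, report = remove_related(m, tab, pi_hat_max=0.5)
    trio = {base.sample_ids[0], "dup_b", "dup_c"}
    survivors = trio & set(out.sample_ids)
    assert len(survivors) == 1
    assert len([s for s, _ in report.samples_removed]) == 2


def test_qc_counts_reconcile(single_pop_matrix):
    matrix, _ = single_pop_matrix
    report = QcReport()
    m1, report = filter_sample_call_rate(matrix, 0.99, report)
    n_before = m1.n_variants
    m2, report = filter_maf(m1, 0.05, report)
    assert (
        n_before
        == m2.n_variants
        + report.n_variants_removed_maf
        + report.n_variants_removed_all_missing
    )
    m3, report = ld_prune(m2, 200, 50, 0.1, report)
    assert m2.n_variants == m3.n_variants + report.n_variants_removed_ld
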