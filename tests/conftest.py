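import numpy as np
import pandas as pd
import pytest

from rohscan.matrix import GenotypeMatrix


def make_matrix(calls, positions=None, chrom="chr1", sample_ids=None, species=None):
    """Small genotype matrix from a 2-D call array (samples x variants)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_variants = calls.shape
    if positions is None:
        positions = np.arange(1, n_variants + 1) * 1000
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    if isinstance(chrom, str):
        chroms = [chrom] * n_variants
    else:
        chroms = list(chrom)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        variants=variants,
        calls=calls,
        species_of=species or {},
    )


def random_roh_instance(rng, max_variants=300):
    """One randomised single-sample, single-chromosome ROH instance.

    Mixes heterozygous background, planted homozygous tracts, missing
    calls and occasional large gaps so every caller rule is exercised.
    """
    n = int(rng.integers(20, max_variants + 1))
    positions = np.sort(rng.choice(np.arange(1, 3_000_000), size=n, replace=False))
    if rng.random() < 0.3:  # inject a large gap
        k = int(rng.integers(1, n))
        positions[k:] += int(rng.integers(400_000, 900_000))
    calls = rng.choice(
        np.array([0, 1, 2, -1], dtype=np.int8), size=n, p=[0.35, 0.35, 0.25, 0.05]
    )
    for _ in range(int(rng.integers(0, 3))):  # plant homozygous tracts
        a = int(rng.integers(0, n))
        b = min(n, a + int(rng.integers(10, 120)))
        hom = rng.choice(np.array([0, 2], dtype=np.int8), size=b - a)
        calls[a:b] = hom
        err = rng.random(b - a) < 0.02
        calls[a:b][err] = 1
    from rohscan.roh import RohParams

    params = RohParams(
        min_kb=float(rng.choice([10.0, 50.0, 100.0])),
        min_snp=int(rng.choice([5, 10, 15])),
        max_gap_kb=float(rng.choice([100.0, 500.0])),
        window_missing=int(rng.choice([0, 1, 2])),
        window_het=int(rng.choice([1, 2, 3])),
        window_snp=int(rng.choice([5, 10, 25, 50])),
        window_threshold=float(rng.choice([0.05, 0.5])),
        density_kb_per_snp=float(rng.choice([20.0, 50.0])),
    )
    return calls, positions, params


@pytest.fixture(scope="session")
def single_pop_matrix():
    """One-population cohort for relatedness tests (no structure)."""
    from rohscan.sim import SimConfig, simulate_genotypes

    cfg = SimConfig(
        n_populations=1,
        n_per_population=40,
        n_chromosomes=2,
        n_variants_per_chrom=5_000,
        fst=0.0,
        het_error_rate=0.0,
        missing_rate=0.0,
        seed=7,
    )
    matrix, truth = simulate_genotypes(cfg)
    return matrix, truth
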