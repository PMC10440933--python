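"""Synthetic multi-population genotype simulator with planted autozygosity.

Population allele frequencies follow the Balding-Nichols model: around an
ancestral frequency p drawn uniform on [0.05, 0.95], each population's
frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) where F is the divergence
(FST-like) parameter.  Outside planted segments genotypes are
Hardy-Weinberg draws from the individual's population frequencies;
inside a planted segment both haplotypes are copies of a single
population haplotype, so every call is homozygous up to a configurable
heterozygous miscall rate.  Missingness is overlaid uniformly.  The
truth object records population labels, planted intervals and admixture
weights so downstream callers can be scored against ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from rohscan.matrix import GenotypeMatrix, HET, MISSING

_DEFAULT_POP_NAMES = ["alpaca", "llama", "vicugna", "guanaco"]
_BASES = np.array(list("ACGT"))


class PlantedRoh(NamedTuple):
    """A shared autozygous tract planted in a fraction of one population."""

    population: str
    fraction_of_carriers: float
    chrom: str
    start_bp: int
    end_bp: int


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    Defaults describe the standard study design used throughout the test
    suite: four diverged populations (named after the four South American
    camelid species), eight diploid individuals each, two 25-Mb
    chromosomes with 5,000 variants apiece (mean spacing 5 kb), a 0.5%
    heterozygous miscall rate inside true ROHs and 0.2% baseline
    missingness — well inside the 1% per-sample budget of the default
    call-rate filter, as expected of a cohort of passing samples.
    """

    n_populations: int = 4
    n_per_population: int = 8
    n_chromosomes: int = 2
    chrom_length_bp: int = 25_000_000
    n_variants_per_chrom: int = 5_000
    fst: float = 0.2
    planted_roh: list[PlantedRoh] = field(default_factory=list)
    roh_per_individual: int = 0
    roh_length_bp: tuple[int, int] = (100_000, 10_000_000)
    het_error_rate: float = 0.005
    missing_rate: float = 0.002
    n_admixed: int = 0
    admix_sources: tuple[int, int] = (0, 1)
    admix_weight: float = 0.5
    population_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in [
            ("het_error_rate", self.het_error_rate),
            ("missing_rate", self.missing_rate),
            ("admix_weight", self.admix_weight),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if self.population_names is None:
            if self.n_populations <= len(_DEFAULT_POP_NAMES):
                self.population_names = _DEFAULT_POP_NAMES[: self.n_populations]
            else:
                self.population_names = [f"pop{i}" for i in range(self.n_populations)]
        if len(self.population_names) != self.n_populations:
            raise ValueError("population_names length must equal n_populations")
        for tract in self.planted_roh:
            if not 0.0 <= tract.fraction_of_carriers <= 1.0:
                raise ValueError("fraction_of_carriers must be in [0, 1]")
            if tract.population not in self.population_names:
                raise ValueError(f"unknown population {tract.population!r}")
            if not (1 <= tract.start_bp <= tract.end_bp <= self.chrom_length_bp):
                raise ValueError(
                    f"planted interval {tract} outside [1, {self.chrom_length_bp}]"
                )
            if tract.fraction_of_carriers * self.n_per_population < 1:
                raise ValueError(f"{tract}: carrier fraction yields < 1 carrier")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated cohort."""

    population_of: dict[str, str]
    planted_intervals: dict[str, list[tuple[str, int, int]]]
    admixture_fractions: dict[str, dict[str, float]]


def _merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping/abutting 1-based inclusive intervals per chromosome."""
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted({c for c, _, _ in intervals}):
        chrom_ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = chrom_ivs[0]
        for s, e in chrom_ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def simulate_allele_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ancestral and per-population allele frequencies.

    Returns
    -------
    ancestral : ndarray, shape (n_variants,)
        Ancestral ALT frequencies, uniform on [0.05, 0.95].
    pop_freq : ndarray, shape (n_populations, n_variants)
        Balding-Nichols draws around the ancestral frequency; equal to it
        exactly when ``fst == 0``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_var = config.n_chromosomes * config.n_variants_per_chrom
    ancestral = rng.uniform(0.05, 0.95, size=n_var)
    if config.fst == 0.0:
        pop_freq = np.tile(ancestral, (config.n_populations, 1))
    else:
        ratio = (1.0 - config.fst) / config.fst
        a = ancestral * ratio
        b = (1.0 - ancestral) * ratio
        pop_freq = rng.beta(a, b, size=(config.n_populations, n_var))
        # keep frequencies strictly inside (0, 1) so HW draws stay polymorphic
        pop_freq = np.clip(pop_freq, 1e-6, 1.0 - 1e-6)
    return ancestral, pop_freq


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Unique sorted 1-based positions, uniform over the chromosome."""
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n]


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a full cohort: genotype matrix plus ground truth."""
    rng = np.random.default_rng(config.seed)
    _, pop_freq = simulate_allele_frequencies(config, rng)
    n_var = config.n_chromosomes * config.n_variants_per_chrom

    chroms = np.repeat(config.chrom_names, config.n_variants_per_chrom)
    positions = np.concatenate(
        [
            _draw_positions(rng, config.n_variants_per_chrom, config.chrom_length_bp)
            for _ in range(config.n_chromosomes)
        ]
    )
    ref = rng.choice(_BASES, size=n_var)
    alt = np.array([_BASES[(list(_BASES).index(r) + 1) % 4] for r in ref])
    variants = pd.DataFrame({"chrom": chroms, "pos": positions, "ref": ref, "alt": alt})

    sample_ids: list[str] = []
    population_of: dict[str, str] = {}
    sample_pop_idx: list[int] = []
    for p, name in enumerate(config.population_names):
        for i in range(config.n_per_population):
            sid = f"{name}_{i:02d}"
            sample_ids.append(sid)
            population_of[sid] = name
            sample_pop_idx.append(p)

    admixture_fractions: dict[str, dict[str, float]] = {}
    a_idx, b_idx = config.admix_sources
    for i in range(config.n_admixed):
        sid = f"hybrid_{i:02d}"
        sample_ids.append(sid)
        pa = config.population_names[a_idx]
        pb = config.population_names[b_idx]
        population_of[sid] = f"{pa}x{pb}"
        admixture_fractions[sid] = {pa: config.admix_weight, pb: 1.0 - config.admix_weight}
        sample_pop_idx.append(-1)

    n_samples = len(sample_ids)
    calls = np.empty((n_samples, n_var), dtype=np.int8)
    for s in range(n_samples):
        p_idx = sample_pop_idx[s]
        if p_idx >= 0:
            freqs = pop_freq[p_idx]
        else:
            # admixed: each variant's population of origin drawn independently
            origin = rng.random(n_var) < config.admix_weight
            freqs = np.where(origin, pop_freq[a_idx], pop_freq[b_idx])
        calls[s] = rng.binomial(2, freqs).astype(np.int8)

    # --- planted autozygous segments -------------------------------------
    planted: dict[str, list[tuple[str, int, int]]] = {sid: [] for sid in sample_ids}
    pop_members = {
        name: [sid for sid in sample_ids if population_of[sid] == name]
        for name in config.population_names
    }
    for tract in config.planted_roh:
        members = pop_members[tract.population]
        n_carriers = int(np.ceil(tract.fraction_of_carriers * len(members)))
        carriers = rng.choice(members, size=n_carriers, replace=False)
        for sid in carriers:
            planted[sid].append((tract.chrom, tract.start_bp, tract.end_bp))

    if config.roh_per_individual > 0:
        lo, hi = config.roh_length_bp
        for sid in sample_ids:
            for _ in range(config.roh_per_individual):
                chrom = config.chrom_names[rng.integers(config.n_chromosomes)]
                length = int(rng.integers(lo, hi + 1))
                length = min(length, config.chrom_length_bp)
                start = int(rng.integers(1, config.chrom_length_bp - length + 2))
                planted[sid].append((chrom, start, start + length - 1))

    planted = {sid: _merge_intervals(ivs) if ivs else [] for sid, ivs in planted.items()}

    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()
    for s, sid in enumerate(sample_ids):
        p_idx = sample_pop_idx[s]
        freqs_pop = pop_freq[max(p_idx, 0)]  # hybrids copy from first source
        for chrom, start, end in planted[sid]:
            inside = np.flatnonzero((chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end))
            # one haplotype drawn from the population, then doubled
            hap = (rng.random(inside.size) < freqs_pop[inside]).astype(np.int8)
            calls[s, inside] = 2 * hap
            if config.het_error_rate > 0:
                err = rng.random(inside.size) < config.het_error_rate
                calls[s, inside[err]] = HET

    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    matrix = GenotypeMatrix(
        sample_ids=sample_ids, variants=variants, calls=calls, species_of=population_of
    )
    truth = SimTruth(
        population_of=population_of,
        planted_intervals=planted,
        admixture_fractions=admixture_fractions,
    )
    return matrix, truth


def resolvable_intervals(
    intervals: list[tuple[str, int, int]],
    matrix: GenotypeMatrix,
    max_gap_variants: int = 3,
) -> list[tuple[str, int, int]]:
    """Merge planted intervals indistinguishable at marker resolution.

    Two autozygous tracts separated by a gap containing at most
    ``max_gap_variants`` variants cannot be told apart by a window scan
    that tolerates that many heterozygous calls per window (the scan
    bridges them into one run), so for scoring purposes they count as
    one ground-truth tract.
    """
    pos_by_chrom = {
        chrom: matrix.variants["pos"].to_numpy()[matrix.variant_indices(chrom)]
        for chrom in matrix.chromosomes
    }
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        pos = pos_by_chrom.get(chrom, np.array([], dtype=int))
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            in_gap = int(((pos > cur_e) & (pos < s)).sum())
            if in_gap <= max_gap_variants:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def duplicate_sample(matrix: GenotypeMatrix, sample_id: str, new_id: str) -> GenotypeMatrix:
    """Append a byte-identical copy of one individual under a new ID.

    Useful for exercising relatedness filters: the duplicated pair has
    IBS2 at every jointly observed variant, hence PI-HAT ~ 1.
    """
    if new_id in matrix.sample_ids:
        raise ValueError(f"sample id {new_id!r} already present")
    idx = matrix.sample_index(sample_id)
    calls = np.vstack([matrix.calls, matrix.calls[idx : idx + 1]])
    species = dict(matrix.species_of)
    if sample_id in species:
        species[new_id] = species[sample_id]
    return GenotypeMatrix(
        sample_ids=matrix.sample_ids + [new_id],
        variants=matrix.variants.copy(),
        calls=calls,
        species_of=species,
    )


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCFv4.2 with GT-only FORMAT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        chrom = matrix.variants["chrom"].to_numpy()
        pos = matrix.variants["pos"].to_numpy()
        ref = matrix.variants["ref"].to_numpy()
        alt = matrix.variants["alt"].to_numpy()
        for j in range(matrix.n_variants):
            gts = "\t".join(_GT_STRING[int(g)] for g in matrix.calls[:, j])
            fh.write(f"{chrom[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def write_fixture_set(config: SimConfig, out_dir: str, n_background_genes: int = 20) -> dict[str, str]:
    """Simulate a cohort and serialise it as a complete fixture set.

    Emits a multi-sample VCF, sample->population TSV, chromosome-length
    TSV, one truth BED (0-based half-open) per sample, and a gene BED in
    which each planted shared tract contains one named gene plus
    ``n_background_genes`` decoys scattered uniformly.
    """
    os.makedirs(out_dir, exist_ok=True)
    matrix, truth = simulate_genotypes(config)
    chrom_lengths = {c: config.chrom_length_bp for c in config.chrom_names}
    paths: dict[str, str] = {}

    paths["vcf"] = os.path.join(out_dir, "cohort.vcf")
    write_vcf(matrix, paths["vcf"], chrom_lengths)

    paths["sample_map"] = os.path.join(out_dir, "samples.tsv")
    with open(paths["sample_map"], "w") as fh:
        for sid in matrix.sample_ids:
            fh.write(f"{sid}\t{truth.population_of[sid]}\n")

    paths["chrom_lengths"] = os.path.join(out_dir, "chrom_lengths.tsv")
    with open(paths["chrom_lengths"], "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")

    truth_dir = os.path.join(out_dir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    for sid in matrix.sample_ids:
        p = os.path.join(truth_dir, f"{sid}.bed")
        with open(p, "w") as fh:
            for chrom, start, end in truth.planted_intervals[sid]:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{sid}\n")  # BED half-open
        paths[f"truth:{sid}"] = p

    gene_rng = np.random.default_rng((config.seed + 1) % 2**31)
    paths["genes"] = os.path.join(out_dir, "genes.bed")
    with open(paths["genes"], "w") as fh:
        for i, tract in enumerate(config.planted_roh):
            span = tract.end_bp - tract.start_bp + 1
            g_start = tract.start_bp + span // 4
            g_end = tract.start_bp + (3 * span) // 4
            fh.write(f"{tract.chrom}\t{g_start - 1}\t{g_end}\tSHARED_GENE_{i}\n")
        for i in range(n_background_genes):
            chrom = config.chrom_names[int(gene_rng.integers(config.n_chromosomes))]
            start = int(gene_rng.integers(1, config.chrom_length_bp - 50_000))
            fh.write(f"{chrom}\t{start - 1}\t{start + 20_000}\tGENE_{i:03d}\n")

    return paths
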