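"""VCF input and cohort-level quality control.

Implements the QC stages applied before ROH detection and structure
analysis: per-sample call-rate filtering, minor-allele-frequency
filtering, windowed LD pruning (PLINK ``--indep-pairwise`` semantics)
and relatedness filtering on the method-of-moments PI-HAT estimate of
identity by descent.  The ROH branch of the pipeline deliberately skips
the MAF/LD filters; the structure branch applies them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from rohscan.matrix import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

logger = logging.getLogger(__name__)

MIN_RELIABLE_PAIR_VARIANTS = 50


@dataclass
class QcReport:
    """Bookkeeping of everything QC removed and why.

    At every stage the retained plus removed counts reconcile exactly
    with the input counts.
    """

    sample_call_rates: dict[str, float] = field(default_factory=dict)
    samples_removed: list[tuple[str, str]] = field(default_factory=list)  # (sample, reason)
    n_multiallelic_skipped: int = 0
    n_variants_removed_maf: int = 0
    n_variants_removed_all_missing: int = 0
    n_variants_removed_ld: int = 0
    pi_hat_pairs: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("multiallelic_records_skipped", self.n_multiallelic_skipped),
            ("samples_removed", len(self.samples_removed)),
            ("variants_removed_maf", self.n_variants_removed_maf),
            ("variants_removed_all_missing", self.n_variants_removed_all_missing),
            ("variants_removed_ld", self.n_variants_removed_ld),
        ]
        return pd.DataFrame(rows, columns=["item", "count"])

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _load_sample_map(sample_map) -> dict[str, str]:
    if isinstance(sample_map, dict):
        return dict(sample_map)
    df = pd.read_csv(sample_map, sep="\t", header=None, names=["sample", "species"])
    return dict(zip(df["sample"], df["species"]))


def read_vcf(path: str, sample_map, report: QcReport | None = None) -> GenotypeMatrix:
    """Read a sorted multi-sample VCF into a genotype matrix.

    Multi-allelic records are skipped (counted in the report); half
    calls and non-diploid genotypes are treated as missing.  Raises on
    unsorted input or on a VCF sample absent from the sample map.
    """
    species_of = _load_sample_map(sample_map)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    for s in samples:
        if s not in species_of:
            raise ValueError(f"sample {s!r} in VCF but not in sample map")

    rows = []
    calls_cols = []
    n_multi = 0
    last_pos: dict[str, int] = {}
    seen_order: list[str] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        chrom, pos = rec.CHROM, rec.POS
        if chrom not in last_pos:
            if chrom in seen_order:
                raise ValueError(f"VCF not sorted: chromosome {chrom} appears twice")
            seen_order.append(chrom)
        elif pos <= last_pos[chrom]:
            raise ValueError(f"VCF not sorted at {chrom}:{pos}")
        last_pos[chrom] = pos
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        calls_cols.append(g)
        rows.append((chrom, pos, rec.REF, rec.ALT[0]))

    if n_multi:
        logger.warning("skipped %d multi-allelic records", n_multi)
    if report is not None:
        report.n_multiallelic_skipped += n_multi

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    calls = (
        np.stack(calls_cols, axis=1)
        if calls_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=samples,
        variants=variants,
        calls=calls,
        species_of={s: species_of[s] for s in samples},
    )


def filter_sample_call_rate(
    matrix: GenotypeMatrix, min_rate: float = 0.99, report: QcReport | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples whose genotyping (call) rate falls below ``min_rate``.

    The boundary is inclusive on the retained side: a sample with rate
    exactly ``min_rate`` stays.
    """
    if not 0.0 < min_rate <= 1.0:
        raise ValueError(f"min_rate must be in (0, 1], got {min_rate}")
    report = report or QcReport()
    rates = matrix.call_rates()
    report.sample_call_rates.update(rates.to_dict())
    keep = [s for s in matrix.sample_ids if rates[s] >= min_rate]
    for s in matrix.sample_ids:
        if s not in keep:
            report.samples_removed.append((s, f"call_rate={rates[s]:.4f}<{min_rate}"))
    if not keep:
        raise ValueError("call-rate filter removed every sample")
    out = matrix.subset_samples(keep) if len(keep) < matrix.n_samples else matrix
    return out, report


def filter_maf(
    matrix: GenotypeMatrix, min_maf: float = 0.05, report: QcReport | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop variants with minor allele frequency below ``min_maf``.

    MAF is computed from non-missing calls pooled over all samples;
    variants at exactly ``min_maf`` are retained.  Variants with every
    call missing are removed and counted separately.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    report = report or QcReport()
    freq = matrix.alt_frequencies()
    all_missing = np.isnan(freq)
    maf = np.minimum(freq, 1.0 - freq)
    keep = ~all_missing & (maf >= min_maf)
    report.n_variants_removed_all_missing += int(all_missing.sum())
    report.n_variants_removed_maf += int((~keep & ~all_missing).sum())
    return matrix.subset_variants(keep), report


def _pairwise_r2(dj: np.ndarray, dk: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosage column ``dj`` against each
    column of ``dk``, over samples non-missing in both (NaN-aware)."""
    valid = ~np.isnan(dj)[:, None] & ~np.isnan(dk)
    n = valid.sum(axis=0)
    xj = np.where(valid, dj[:, None], 0.0)
    xk = np.where(valid, dk, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mj = xj.sum(axis=0) / n
        mk = xk.sum(axis=0) / n
        cov = (xj * xk).sum(axis=0) / n - mj * mk
        vj = (xj**2).sum(axis=0) / n - mj**2
        vk = (xk**2).sum(axis=0) / n - mk**2
        r2 = cov**2 / (vj * vk)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(
    matrix: GenotypeMatrix,
    window_n_variants: int = 1500,
    step: int = 150,
    r2_threshold: float = 0.1,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Windowed greedy LD pruning (PLINK ``--indep-pairwise`` semantics).

    Within each window of ``window_n_variants`` consecutive variants on
    one chromosome, every pair of surviving variants with dosage r^2
    strictly above the threshold has its later (higher-index) member
    pruned; the window then slides by ``step`` variants.
    """
    if window_n_variants < 2:
        raise ValueError("window must span at least 2 variants")
    report = report or QcReport()
    dosage = matrix.dosage()
    pruned = np.zeros(matrix.n_variants, dtype=bool)
    for chrom in matrix.chromosomes:
        idx = matrix.variant_indices(chrom)
        n = idx.size
        for start in range(0, n, step):
            win = idx[start : start + window_n_variants]
            if win.size < 2:
                continue
            kept: list[int] = []
            for j in win:
                if pruned[j]:
                    continue
                if kept:
                    r2 = _pairwise_r2(dosage[:, j], dosage[:, kept])
                    if np.any(r2 > r2_threshold):
                        pruned[j] = True
                        continue
                kept.append(j)
            if start + window_n_variants >= n:
                break
    report.n_variants_removed_ld += int(pruned.sum())
    return matrix.subset_variants(~pruned), report


def pi_hat(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments PI-HAT relatedness for every sample pair.

    For each pair, IBS 0/1/2 states are counted over jointly non-missing
    variants; the expected IBS-state probabilities under each IBD state
    Z in {0,1,2}, given the cohort allele frequencies, give a linear
    system solved for P(Z=0..2) (clamped to [0,1] and renormalised).
    PI-HAT = P(Z=2) + 0.5 P(Z=1).  Pairs sharing fewer than 50 observed
    variants are flagged unreliable.
    """
    p = matrix.alt_frequencies()
    q = 1.0 - p
    # expected per-variant IBS-state probabilities given IBD state
    e_ibs0_z0 = 2 * p**2 * q**2
    e_ibs1_z0 = 4 * p**3 * q + 4 * p * q**3
    e_ibs2_z0 = 1.0 - e_ibs0_z0 - e_ibs1_z0
    e_ibs1_z1 = 2 * p * q
    e_ibs2_z1 = 1.0 - e_ibs1_z1

    calls = matrix.calls
    obs = calls != MISSING
    rows = []
    for i, j in itertools.combinations(range(matrix.n_samples), 2):
        joint = obs[i] & obs[j]
        n_joint = int(joint.sum())
        gi, gj = calls[i, joint], calls[j, joint]
        diff = np.abs(gi.astype(np.int16) - gj.astype(np.int16))
        n_ibs0 = int((diff == 2).sum())
        n_ibs2 = int((diff == 0).sum())
        n_ibs1 = n_joint - n_ibs0 - n_ibs2
        s0 = e_ibs0_z0[joint].sum()
        pz0 = n_ibs0 / s0 if s0 > 0 else 0.0
        s1 = e_ibs1_z1[joint].sum()
        pz1 = (n_ibs1 - pz0 * e_ibs1_z0[joint].sum()) / s1 if s1 > 0 else 0.0
        pz2 = (
            (n_ibs2 - pz0 * e_ibs2_z0[joint].sum() - pz1 * e_ibs2_z1[joint].sum()) / n_joint
            if n_joint > 0
            else 0.0
        )
        z = np.clip([pz0, pz1, pz2], 0.0, 1.0)
        total = z.sum()
        z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
        rows.append(
            {
                "sample_i": matrix.sample_ids[i],
                "sample_j": matrix.sample_ids[j],
                "n_joint": n_joint,
                "ibs0": n_ibs0,
                "ibs1": n_ibs1,
                "ibs2": n_ibs2,
                "pi_hat": z[2] + 0.5 * z[1],
                "reliable": n_joint >= MIN_RELIABLE_PAIR_VARIANTS,
            }
        )
    return pd.DataFrame(rows)


def remove_related(
    matrix: GenotypeMatrix,
    table: pd.DataFrame,
    pi_hat_max: float = 0.5,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Iteratively break up related pairs with PI-HAT >= ``pi_hat_max``.

    At each step the worst remaining pair loses its member with the
    lower call rate (ties resolved by removing the lexicographically
    larger sample ID), until no pair exceeds the bound.
    """
    report = report or QcReport()
    report.pi_hat_pairs = table.copy()
    rates = matrix.call_rates()
    removed: set[str] = set()
    active = table.copy()
    while True:
        live = active[
            ~active["sample_i"].isin(removed)
            & ~active["sample_j"].isin(removed)
            & (active["pi_hat"] >= pi_hat_max)
        ]
        if live.empty:
            break
        worst = live.loc[live["pi_hat"].idxmax()]
        a, b = worst["sample_i"], worst["sample_j"]
        if rates[a] < rates[b]:
            victim = a
        elif rates[b] < rates[a]:
            victim = b
        else:
            victim = max(a, b)
        removed.add(victim)
        report.samples_removed.append((victim, f"pi_hat={worst['pi_hat']:.3f}>={pi_hat_max}"))
    keep = [s for s in matrix.sample_ids if s not in removed]
    out = matrix.subset_samples(keep) if removed else matrix
    return out, report
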