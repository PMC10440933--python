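"""In-memory diploid genotype matrix.

Calls are coded as small integers: 0 hom-ref, 1 het, 2 hom-alt, -1
missing.  Variants are held in a pandas DataFrame with columns
``chrom``, ``pos`` (1-based), ``ref``, ``alt``; positions are strictly
increasing within a chromosome and every record carries exactly one ALT
allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid genotype calls.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample labels.
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, pos, ref, alt``.
    calls : ndarray of int8, shape (n_samples, n_variants)
        Genotype codes (0/1/2, -1 for missing).
    species_of : dict, optional
        Sample -> population/species label.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray
    species_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.variants["chrom"]))

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def call_rates(self) -> pd.Series:
        """Fraction of non-missing calls per sample."""
        rates = (self.calls != MISSING).mean(axis=1)
        return pd.Series(rates, index=self.sample_ids, name="call_rate")

    def dosage(self) -> np.ndarray:
        """ALT allele dosage (0/1/2) as float with NaN for missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def alt_frequencies(self) -> np.ndarray:
        """Per-variant ALT allele frequency over non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return GenotypeMatrix(
            sample_ids=list(keep),
            variants=self.variants.copy(),
            calls=self.calls[idx, :].copy(),
            species_of={s: self.species_of[s] for s in keep if s in self.species_of},
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask].copy(),
            species_of=dict(self.species_of),
        )

    def variant_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.variants["chrom"] == chrom).to_numpy())
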