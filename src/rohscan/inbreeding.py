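"""Genomic inbreeding (F_ROH), per-species summaries and ANOVA.

F_ROH is the fraction of the autosomal genome covered by an
individual's ROHs: F_ROH = L_ROH / L_aut, with L_ROH the summed segment
length and L_aut the total autosome length.  Species-level summary
tables report mean/sd/min/max of segment count, total kb, F_ROH and
mean segment size, and a one-way ANOVA compares these statistics across
species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rohscan.roh import RohSegment


def f_roh(segments: list[RohSegment], autosome_length_bp: int) -> float:
    """Fraction of the autosomal genome covered by the given segments.

    Segments must belong to one sample and be disjoint per chromosome
    (the caller guarantees this); overlap raises.
    """
    if autosome_length_bp <= 0:
        raise ValueError("autosome_length_bp must be positive")
    by_chrom: dict[str, list[RohSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    total = 0
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(f"overlapping segments on {chrom} for one sample")
        total += sum(s.end_bp - s.start_bp + 1 for s in segs)
    return total / autosome_length_bp


@dataclass
class InbreedingRecord:
    sample: str
    species: str
    n_segments: int
    total_kb: float
    f_roh: float


def inbreeding_records(
    segment_table: pd.DataFrame,
    species_of: dict[str, str],
    autosome_length_bp: int,
) -> pd.DataFrame:
    """Per-sample segment count, total kb and F_ROH from a segment table.

    Every sample in ``species_of`` is reported, including samples with
    zero segments (F_ROH = 0).
    """
    rows = []
    for sample, species in species_of.items():
        sub = segment_table[segment_table["SAMPLE"] == sample]
        total_bp = int((sub["POS2"] - sub["POS1"] + 1).sum()) if len(sub) else 0
        rows.append(
            {
                "sample": sample,
                "species": species,
                "n_segments": len(sub),
                "total_kb": total_bp / 1000.0,
                "f_roh": total_bp / autosome_length_bp,
            }
        )
    return pd.DataFrame(rows)


_SUMMARY_STATS = ["n_segments", "total_kb", "f_roh", "mean_segment_kb"]


def summarize(records: pd.DataFrame, variant_counts: dict[str, int] | None = None) -> pd.DataFrame:
    """Species-level summary table (one row per species).

    Reports N and mean/sd/min/max for segment count, total kb, F_ROH
    and mean segment size (the per-sample average of total kb over
    segment count; samples without segments are excluded from that
    statistic).  The sample standard deviation (n-1 denominator) is
    reported as 0, with ``sd_defined = False``, for single-sample
    species.  ``variant_counts`` optionally supplies the number of
    variants entering the caller per species.
    """
    rows = []
    for species, grp in records.groupby("species", sort=False):
        n = len(grp)
        if n == 0:
            continue
        vals = grp.copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            vals["mean_segment_kb"] = np.where(
                vals["n_segments"] > 0, vals["total_kb"] / vals["n_segments"], np.nan
            )
        row: dict[str, object] = {"species": species, "N": n, "sd_defined": n > 1}
        for stat in _SUMMARY_STATS:
            x = vals[stat].dropna().to_numpy(dtype=float)
            if x.size == 0:
                row.update({f"{stat}_mean": np.nan, f"{stat}_sd": 0.0,
                            f"{stat}_min": np.nan, f"{stat}_max": np.nan})
                continue
            row[f"{stat}_mean"] = float(x.mean())
            row[f"{stat}_sd"] = float(x.std(ddof=1)) if x.size > 1 else 0.0
            row[f"{stat}_min"] = float(x.min())
            row[f"{stat}_max"] = float(x.max())
        if variant_counts is not None:
            row["n_variants"] = variant_counts.get(species, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def anova_one_way(groups: list[list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and upper-tail p-value.

    F = (between-group SS / (k-1)) / (within-group SS / (n-k)) referred
    to the F(k-1, n-k) distribution.  Degenerate cases: identical
    constant groups give F = 0, p = 1; zero within-group variance with
    unequal means gives F = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    n = sum(a.size for a in arrays)
    k = len(arrays)
    if n <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def anova_table(records: pd.DataFrame) -> pd.DataFrame:
    """ANOVA across species for segment count, mean segment length and F_ROH."""
    vals = records.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        vals["mean_segment_kb"] = np.where(
            vals["n_segments"] > 0, vals["total_kb"] / vals["n_segments"], np.nan
        )
    rows = []
    for stat in ["n_segments", "mean_segment_kb", "f_roh"]:
        groups = [
            grp[stat].dropna().to_list()
            for _, grp in vals.groupby("species", sort=False)
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            rows.append({"statistic": stat, "F": np.nan, "p_value": np.nan})
            continue
        f, p = anova_one_way(groups)
        rows.append({"statistic": stat, "F": f, "p_value": p})
    return pd.DataFrame(rows)
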