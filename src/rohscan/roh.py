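"""Sliding-window detection of runs of homozygosity (ROHs).

The scan mirrors PLINK's ``--homozyg`` logic.  A window of
``window_snp`` consecutive variants slides along each chromosome; a
window is "homozygous" iff it contains at most ``window_het``
heterozygous and at most ``window_missing`` missing calls.  Each
variant's hit fraction is the share of windows containing it that are
homozygous; variants whose fraction reaches ``window_threshold`` are
ROH-eligible.  Maximal runs of consecutive eligible variants are split
at inter-variant gaps above ``max_gap_kb``, trimmed so both ends are
homozygous non-missing calls, and emitted when they satisfy the minimum
variant count, minimum length and maximum kb-per-variant density.

Segment coordinates are the positions of the first and last variant of
the run, 1-based inclusive; length_kb = (end - start + 1) / 1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rohscan.matrix import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING


@dataclass(frozen=True)
class RohParams:
    """Thresholds of the ROH caller.

    Defaults follow a consensus parameterisation for medium-density
    livestock panels: segments of at least 100 kb and 15 variants, split
    at gaps above 500 kb, scanned with 50-variant windows tolerating 3
    heterozygous and 1 missing call each.
    """

    min_kb: float = 100.0
    min_snp: int = 15
    max_gap_kb: float = 500.0
    window_missing: int = 1
    window_het: int = 3
    window_snp: int = 50
    window_threshold: float = 0.05
    density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        for name in (
            "min_kb", "min_snp", "max_gap_kb", "window_snp",
            "window_threshold", "density_kb_per_snp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_missing < 0 or self.window_het < 0:
            raise ValueError("window limits must be non-negative")
        if self.window_het >= self.window_snp:
            raise ValueError("window_het must be < window_snp")
        if self.window_missing >= self.window_snp:
            raise ValueError("window_missing must be < window_snp")


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run of a single sample."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_variants: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


def window_scan(calls: np.ndarray, params: RohParams) -> np.ndarray:
    """ROH eligibility of each variant of one sample on one chromosome.

    Returns a boolean array: variant i is eligible iff the fraction of
    homozygous windows among all windows containing it reaches
    ``window_threshold``.  Chromosomes with fewer variants than the
    window span are scanned with a single all-variants window.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    is_het = calls == HET
    is_miss = calls == MISSING
    w = params.window_snp
    if n < w:
        ok = is_het.sum() <= params.window_het and is_miss.sum() <= params.window_missing
        return np.full(n, bool(ok))

    het_cum = np.concatenate([[0], np.cumsum(is_het)])
    miss_cum = np.concatenate([[0], np.cumsum(is_miss)])
    starts = np.arange(n - w + 1)
    win_ok = (het_cum[starts + w] - het_cum[starts] <= params.window_het) & (
        miss_cum[starts + w] - miss_cum[starts] <= params.window_missing
    )
    ok_cum = np.concatenate([[0], np.cumsum(win_ok)])

    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n - w)
    n_windows = hi - lo + 1
    n_ok = ok_cum[hi + 1] - ok_cum[lo]
    return n_ok / n_windows >= params.window_threshold


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs (inclusive) of maximal True runs."""
    padded = np.concatenate([[False], mask, [False]])
    change = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(change[k]), int(change[k + 1] - 1)) for k in range(0, change.size, 2)]


def _emit_runs(
    calls: np.ndarray,
    positions: np.ndarray,
    eligible: np.ndarray,
    params: RohParams,
    sample: str,
    chrom: str,
) -> list[RohSegment]:
    gap_bp = params.max_gap_kb * 1000.0
    homozygous = (calls == HOM_REF) | (calls == HOM_ALT)
    segments: list[RohSegment] = []
    for run_start, run_end in _runs_of_true(eligible):
        # split wherever adjacent variants are further apart than the gap cap
        pieces = []
        piece_start = run_start
        for k in range(run_start, run_end):
            if positions[k + 1] - positions[k] > gap_bp:
                pieces.append((piece_start, k))
                piece_start = k + 1
        pieces.append((piece_start, run_end))
        for a, b in pieces:
            while a <= b and not homozygous[a]:
                a += 1
            while b >= a and not homozygous[b]:
                b -= 1
            if a > b:
                continue
            n_var = int((calls[a : b + 1] != MISSING).sum())
            length_kb = (positions[b] - positions[a] + 1) / 1000.0
            if (
                n_var >= params.min_snp
                and length_kb >= params.min_kb
                and length_kb / n_var <= params.density_kb_per_snp
            ):
                segments.append(
                    RohSegment(sample, chrom, int(positions[a]), int(positions[b]), n_var)
                )
    return segments


def call_roh(
    matrix: GenotypeMatrix, sample_id: str, params: RohParams | None = None
) -> list[RohSegment]:
    """Call ROH segments for one sample across all chromosomes."""
    params = params or RohParams()
    s = matrix.sample_index(sample_id)
    segments: list[RohSegment] = []
    for chrom in matrix.chromosomes:
        idx = matrix.variant_indices(chrom)
        calls = matrix.calls[s, idx]
        positions = matrix.variants["pos"].to_numpy()[idx]
        eligible = window_scan(calls, params)
        segments.extend(_emit_runs(calls, positions, eligible, params, sample_id, chrom))
    return segments


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    """PLINK ``.hom``-like table: SAMPLE, CHR, POS1, POS2, KB, NSNP."""
    return pd.DataFrame(
        [
            {
                "SAMPLE": seg.sample,
                "CHR": seg.chrom,
                "POS1": seg.start_bp,
                "POS2": seg.end_bp,
                "KB": seg.length_kb,
                "NSNP": seg.n_variants,
            }
            for seg in segments
        ],
        columns=["SAMPLE", "CHR", "POS1", "POS2", "KB", "NSNP"],
    )


def classify_length(kb: float, boundary_kb: float = 500.0) -> str:
    """Length class of a segment: the short class is closed at both ends
    ([min_kb, boundary]); the long class is strictly above the boundary."""
    return "100-500" if kb <= boundary_kb else ">500"


def call_roh_cohort(
    matrix: GenotypeMatrix,
    params: RohParams | None = None,
    boundary_kb: float = 500.0,
) -> pd.DataFrame:
    """Call ROHs for every sample and stratify by length class.

    Runs the caller once at the configured ``min_kb`` (100 kb by
    default) and bins segments into the [100, 500] kb and > 500 kb
    classes; a segment of exactly 500 kb belongs to the short class.
    """
    params = params or RohParams()
    all_segments: list[RohSegment] = []
    for sid in matrix.sample_ids:
        all_segments.extend(call_roh(matrix, sid, params))
    df = segments_to_frame(all_segments)
    df["CLASS"] = [classify_length(kb, boundary_kb) for kb in df["KB"]] if len(df) else []
    df["SPECIES"] = [matrix.species_of.get(s, "NA") for s in df["SAMPLE"]] if len(df) else []
    return df
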