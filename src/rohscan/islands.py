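"""ROH islands: regions shared by a large fraction of a population.

A coverage profile (carrier count as a step function of position) is
built per species by an event sweep over segment endpoints.  Islands
are the maximal intervals where the carrier count reaches
ceil(threshold * N); the reported carrier count of an island is the
minimum over the interval, and the displayed percentage rounds half up
to the nearest integer.  Islands are annotated with every gene interval
overlapping them by at least one base pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rohscan.matrix import GenotypeMatrix
from rohscan.roh import RohSegment

logger = logging.getLogger(__name__)


@dataclass
class RohIsland:
    species: str
    chrom: str
    start_bp: int
    end_bp: int
    n_carriers: int
    pct_population: int
    n_variants: int = 0
    genes: list[str] = field(default_factory=list)

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def coverage_profile(
    segments: list[RohSegment],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Carrier-count step function per chromosome.

    Returns, per chromosome, ``(breakpoints, counts)`` where
    ``counts[k]`` is the number of distinct samples whose ROHs cover
    positions in ``[breakpoints[k], breakpoints[k+1] - 1]``.  Each
    sample contributes at most 1 at any position; a sample's segments
    are expected disjoint (merged defensively).
    """
    events: dict[str, dict[int, int]] = {}
    per_sample_chrom: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for seg in segments:
        per_sample_chrom.setdefault((seg.sample, seg.chrom), []).append(
            (seg.start_bp, seg.end_bp)
        )
    for (_, chrom), ivs in per_sample_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        ev = events.setdefault(chrom, {})
        for s, e in merged:
            ev[s] = ev.get(s, 0) + 1
            ev[e + 1] = ev.get(e + 1, 0) - 1
    profile = {}
    for chrom, ev in events.items():
        breakpoints = np.array(sorted(ev), dtype=np.int64)
        counts = np.cumsum([ev[b] for b in breakpoints])
        profile[chrom] = (breakpoints, counts)
    return profile


def find_islands(
    profile: dict[str, tuple[np.ndarray, np.ndarray]],
    n_species: int,
    threshold: float = 0.70,
    species: str = "NA",
) -> list[RohIsland]:
    """Maximal intervals where the carrier count reaches ceil(threshold*N).

    The island's carrier count is the minimum over the interval and its
    percentage is round-half-up of 100 * n_carriers / N.  Island
    coordinates are the sweep breakpoints, i.e. segment (variant)
    positions.
    """
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    min_carriers = math.ceil(threshold * n_species)
    islands: list[RohIsland] = []
    for chrom in sorted(profile):
        breakpoints, counts = profile[chrom]
        eligible = counts >= min_carriers
        k = 0
        while k < eligible.size:
            if not eligible[k]:
                k += 1
                continue
            j = k
            while j + 1 < eligible.size and eligible[j + 1]:
                j += 1
            start = int(breakpoints[k])
            end = int(breakpoints[j + 1] - 1) if j + 1 < breakpoints.size else int(breakpoints[j])
            n_carriers = int(counts[k : j + 1].min())
            islands.append(
                RohIsland(
                    species=species,
                    chrom=chrom,
                    start_bp=start,
                    end_bp=end,
                    n_carriers=n_carriers,
                    pct_population=_round_half_up(100.0 * n_carriers / n_species),
                )
            )
            k = j + 1
    return islands


def count_variants_in(island: RohIsland, matrix: GenotypeMatrix) -> int:
    """Number of analysis-set variants inside the island (inclusive)."""
    if island.chrom not in matrix.chromosomes:
        raise ValueError(f"unknown chromosome {island.chrom!r}")
    idx = matrix.variant_indices(island.chrom)
    pos = matrix.variants["pos"].to_numpy()[idx]
    return int(((pos >= island.start_bp) & (pos <= island.end_bp)).sum())


def read_gene_intervals(path: str) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) or GFF3
    (1-based inclusive), normalised to 1-based inclusive coordinates.

    Malformed lines are skipped with a warning.  GFF3 gene names come
    from the ``Name=`` or ``ID=`` attribute.
    """
    rows = []
    is_gff = path.endswith((".gff", ".gff3", ".gtf"))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if is_gff:
                    chrom, start, end = parts[0], int(parts[3]), int(parts[4])
                    attrs = dict(
                        kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                    )
                    name = attrs.get("Name", attrs.get("ID", f"feature_{lineno}"))
                else:
                    chrom, start, end = parts[0], int(parts[1]) + 1, int(parts[2])
                    name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            except (IndexError, ValueError):
                logger.warning("skipping malformed annotation line %d of %s", lineno, path)
                continue
            if end < start:
                logger.warning("skipping inverted interval at line %d of %s", lineno, path)
                continue
            rows.append({"chrom": chrom, "start": start, "end": end, "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def annotate_islands(islands: list[RohIsland], gene_intervals: pd.DataFrame) -> list[RohIsland]:
    """Attach to each island every gene overlapping it by >= 1 bp."""
    for island in islands:
        if len(gene_intervals) == 0:
            island.genes = []
            continue
        sub = gene_intervals[gene_intervals["chrom"] == island.chrom]
        hit = (sub["start"].to_numpy() <= island.end_bp) & (
            sub["end"].to_numpy() >= island.start_bp
        )
        island.genes = sub["name"].to_numpy()[hit].tolist()
    return islands


def islands_for_species(
    segment_table: pd.DataFrame,
    species_of: dict[str, str],
    threshold: float = 0.70,
    matrix: GenotypeMatrix | None = None,
    gene_intervals: pd.DataFrame | None = None,
) -> list[RohIsland]:
    """End-to-end island detection for every species in a cohort."""
    islands: list[RohIsland] = []
    species_list = list(dict.fromkeys(species_of.values()))
    for species in species_list:
        members = [s for s, sp in species_of.items() if sp == species]
        segs = [
            RohSegment(r.SAMPLE, r.CHR, int(r.POS1), int(r.POS2), int(r.NSNP))
            for r in segment_table.itertuples()
            if r.SAMPLE in members
        ]
        if not segs:
            continue
        found = find_islands(coverage_profile(segs), len(members), threshold, species)
        islands.extend(found)
    if matrix is not None:
        for island in islands:
            island.n_variants = count_variants_in(island, matrix)
    if gene_intervals is not None:
        annotate_islands(islands, gene_intervals)
    return islands


def islands_to_frame(islands: list[RohIsland]) -> pd.DataFrame:
    """Island table with the standard report columns."""
    return pd.DataFrame(
        [
            {
                "SPECIES": isl.species,
                "PCT": isl.pct_population,
                "N": isl.n_carriers,
                "CHR": isl.chrom,
                "BP1": isl.start_bp,
                "BP2": isl.end_bp,
                "KB": isl.length_kb,
                "NVARIANTS": isl.n_variants,
                "GENES": ",".join(isl.genes) if isl.genes else "---",
            }
            for isl in islands
        ],
        columns=["SPECIES", "PCT", "N", "CHR", "BP1", "BP2", "KB", "NVARIANTS", "GENES"],
    )
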