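"""Brute-force reference implementations used only by the tests.

Each oracle follows the operation's definition with plain Python loops
and no shared code with the package, so agreement is evidence the
vectorised implementations apply the rules correctly.
"""

from __future__ import annotations

import numpy as np


def brute_force_roh(calls, positions, params):
    """Direct enumeration ROH caller for one sample on one chromosome.

    Returns (start_bp, end_bp, n_variants) tuples.
    """
    calls = list(calls)
    positions = list(positions)
    n = len(calls)
    if n == 0:
        return []
    w = params.window_snp
    if n < w:
        windows = [(0, n - 1)]
    else:
        windows = [(s, s + w - 1) for s in range(n - w + 1)]
    win_ok = []
    for a, b in windows:
        hets = sum(1 for k in range(a, b + 1) if calls[k] == 1)
        miss = sum(1 for k in range(a, b + 1) if calls[k] == -1)
        win_ok.append(hets <= params.window_het and miss <= params.window_missing)
    eligible = []
    for i in range(n):
        containing = [k for k, (a, b) in enumerate(windows) if a <= i <= b]
        frac = sum(win_ok[k] for k in containing) / len(containing)
        eligible.append(frac >= params.window_threshold)

    segments = []
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        pieces = []
        start = i
        for k in range(i, j):
            if positions[k + 1] - positions[k] > params.max_gap_kb * 1000:
                pieces.append((start, k))
                start = k + 1
        pieces.append((start, j))
        for a, b in pieces:
            while a <= b and calls[a] not in (0, 2):
                a += 1
            while b >= a and calls[b] not in (0, 2):
                b -= 1
            if a > b:
                continue
            n_var = sum(1 for k in range(a, b + 1) if calls[k] != -1)
            kb = (positions[b] - positions[a] + 1) / 1000.0
            if (
                n_var >= params.min_snp
                and kb >= params.min_kb
                and kb / n_var <= params.density_kb_per_snp
            ):
                segments.append((int(positions[a]), int(positions[b]), n_var))
        i = j + 1
    return segments


def brute_force_window_eligibility(calls, params):
    """Eligibility flags only, by direct window enumeration."""
    calls = list(calls)
    n = len(calls)
    w = params.window_snp
    if n == 0:
        return []
    if n < w:
        windows = [(0, n - 1)]
    else:
        windows = [(s, s + w - 1) for s in range(n - w + 1)]
    win_ok = []
    for a, b in windows:
        hets = sum(1 for k in range(a, b + 1) if calls[k] == 1)
        miss = sum(1 for k in range(a, b + 1) if calls[k] == -1)
        win_ok.append(hets <= params.window_het and miss <= params.window_missing)
    out = []
    for i in range(n):
        containing = [k for k, (a, b) in enumerate(windows) if a <= i <= b]
        frac = sum(win_ok[k] for k in containing) / len(containing)
        out.append(frac >= params.window_threshold)
    return out


def brute_force_ld_prune(dosage, chrom_of, window, step, r2_threshold):
    """Greedy windowed pruning with explicit pair loops.

    dosage: samples x variants float array with NaN for missing.
    Returns the boolean pruned mask.
    """
    n_variants = dosage.shape[1]
    pruned = [False] * n_variants
    chroms = []
    for c in chrom_of:
        if c not in chroms:
            chroms.append(c)
    for chrom in chroms:
        idx = [j for j in range(n_variants) if chrom_of[j] == chrom]
        for start in range(0, len(idx), step):
            win = idx[start : start + window]
            for a_pos in range(len(win)):
                for b_pos in range(a_pos + 1, len(win)):
                    i, j = win[a_pos], win[b_pos]
                    if pruned[i] or pruned[j]:
                        continue
                    x, y = dosage[:, i], dosage[:, j]
                    ok = ~np.isnan(x) & ~np.isnan(y)
                    if ok.sum() < 2:
                        continue
                    xv, yv = x[ok], y[ok]
                    if xv.std() == 0 or yv.std() == 0:
                        continue
                    r = np.corrcoef(xv, yv)[0, 1]
                    if r * r > r2_threshold:
                        pruned[j] = True
            if start + window >= len(idx):
                break
    return np.array(pruned)


def per_base_coverage(segments, chrom, lo, hi):
    """Carrier count at every base of [lo, hi] by direct counting.

    segments: (sample, chrom, start, end) tuples, 1-based inclusive.
    """
    counts = np.zeros(hi - lo + 1, dtype=int)
    by_sample = {}
    for sample, c, s, e in segments:
        if c == chrom:
            by_sample.setdefault(sample, []).append((s, e))
    for ivs in by_sample.values():
        covered = np.zeros(hi - lo + 1, dtype=bool)
        for s, e in ivs:
            a = max(s, lo) - lo
            b = min(e, hi) - lo
            if a <= b:
                covered[a : b + 1] = True
        counts += covered
    return counts


def hudson_fst(geno_a, geno_b):
    """Hudson FST estimator (ratio of averages) from two genotype
    matrices (samples x variants, dosage 0/1/2, no missing)."""
    n1 = 2 * geno_a.shape[0]
    n2 = 2 * geno_b.shape[0]
    p1 = geno_a.sum(axis=0) / n1
    p2 = geno_b.sum(axis=0) / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return num[keep].sum() / den[keep].sum()
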