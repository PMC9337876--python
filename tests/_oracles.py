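"""Brute-force reference implementations used only by the test suite.

These are deliberately written as direct transcriptions of the detection
rules, independent of the package's algorithms: every candidate interval
is enumerated and checked, then selection proceeds longest-first.
"""

from __future__ import annotations

import numpy as np


def roh_classify(length_bp: int) -> str | None:
    mb = 1_000_000
    if length_bp < 2 * mb:
        return None
    if length_bp < 4 * mb:
        return "2-4Mb"
    if length_bp < 8 * mb:
        return "4-8Mb"
    if length_bp < 16 * mb:
        return "8-16Mb"
    return ">16Mb"


def brute_force_roh(pos: np.ndarray, g: np.ndarray, params) -> list[tuple[int, int]]:
    """All maximal constraint-satisfying runs on one chromosome, selected
    longest-first (ties leftmost), overlaps dropped.  O(n^2) enumeration."""
    n = len(pos)
    cum_het = np.concatenate([[0], np.cumsum(g == 1)])
    cum_miss = np.concatenate([[0], np.cumsum(g == -1)])
    big_gap = np.concatenate([np.diff(pos) > params.max_gap_bp, [False]])
    hom = (g == 0) | (g == 2)

    candidates = []
    for i in range(n):
        if not hom[i]:
            continue
        for j in range(i + params.l_min_snps - 1, n):
            if not hom[j]:
                continue
            length = int(pos[j] - pos[i]) + 1
            if length < params.min_length_bp:
                continue
            if big_gap[i:j].any():
                continue
            n_snps = j - i + 1
            if n_snps * params.max_bp_per_snp < length:
                continue
            label = roh_classify(length)
            if label is None:
                continue
            if cum_het[j + 1] - cum_het[i] > params.het_allow[label]:
                continue
            if cum_miss[j + 1] - cum_miss[i] > params.miss_allow[label]:
                continue
            candidates.append((i, j, length))

    candidates.sort(key=lambda t: (-t[2], t[0]))
    chosen: list[tuple[int, int]] = []
    for i, j, _ in candidates:
        if all(j < a or i > b for a, b in chosen):
            chosen.append((i, j))
    return sorted(chosen)


def random_roh_chromosome(rng: np.random.Generator, n_snps: int,
                          het_rate: float = 0.35):
    """Random genotype/position fixture with planted homozygous tracts."""
    gaps = rng.integers(5_000, 90_000, size=n_snps - 1)
    # occasional over-sized gap to exercise run splitting
    for k in np.flatnonzero(rng.random(n_snps - 1) < 0.01):
        gaps[k] = rng.integers(260_000, 500_000)
    pos = np.concatenate([[1], 1 + np.cumsum(gaps)])

    g = rng.choice([0, 1, 2], size=n_snps, p=[(1 - het_rate) / 2, het_rate,
                                              (1 - het_rate) / 2]).astype(np.int8)
    g[rng.random(n_snps) < 0.02] = -1
    # plant 0-3 homozygous tracts, lightly contaminated
    for _ in range(rng.integers(0, 4)):
        width = min(int(rng.integers(20, 200)), n_snps)
        start = int(rng.integers(0, max(n_snps - width, 1)))
        allele = rng.choice([0, 2])
        g[start:start + width] = allele
        for k in range(int(rng.integers(0, 4))):
            g[start + int(rng.integers(0, width))] = rng.choice([1, -1])
    return pos.astype(np.int64), g


def greedy_ld_prune_oracle(geno: np.ndarray, threshold: float) -> list[int]:
    """Single-window pruning reference: repeatedly find the largest
    pairwise r^2 among retained SNPs and drop one member (higher
    missingness, then larger index)."""
    m = geno.shape[1]
    retained = list(range(m))
    miss = (geno == -1).mean(axis=0)

    def r2(i, j):
        ok = (geno[:, i] != -1) & (geno[:, j] != -1)
        if ok.sum() < 10:
            return np.nan
        x = geno[ok, i].astype(float)
        y = geno[ok, j].astype(float)
        if x.std() == 0 or y.std() == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    while True:
        best = (threshold, None)
        for a in range(len(retained)):
            for b in range(a + 1, len(retained)):
                v = r2(retained[a], retained[b])
                if not np.isnan(v) and v > best[0]:
                    best = (v, (retained[a], retained[b]))
        if best[1] is None:
            return retained
        i, j = best[1]
        if miss[i] > miss[j]:
            retained.remove(i)
        elif miss[j] > miss[i]:
            retained.remove(j)
        else:
            retained.remove(max(i, j))
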