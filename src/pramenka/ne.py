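"""Effective population size from recombination-binned linkage disequilibrium.

The LD signal at recombination fraction c reflects effective population
size roughly t = 1/(2c) generations ago.  Squared genotype correlations
(r^2) between within-chromosome SNP pairs are aggregated into bins of c,
where physical distance is mapped to Morgans at a uniform rate (default
1 cM/Mb) and to recombination fraction through Haldane's function
c = (1 - exp(-2d)) / 2.  Each usable bin is inverted through the
Sved/Hill relation

    E[r^2] ~ 1 / (1 + 4 N c) + 1/n

so that Ne = (1 / (r2_mean - 1/n) - 1) / (4 c), with 1/n the sampling
contribution of n diploid individuals to the unphased genotype
correlation.  Bins where the corrected r^2 is non-positive yield a
flagged, undefined estimate.  This transparent bin-by-bin inversion is a
deliberately simple alternative to genetic-algorithm demographic fits
(GONE and relatives); absolute agreement with such software is not
expected, and the estimator is validated by simulation recovery instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, DataError, GenotypeMatrix

#: Default recombination-fraction bin edges.
DEFAULT_BIN_EDGES = (0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.25)

#: Bins with fewer SNP pairs than this are flagged unusable.
MIN_PAIRS_PER_BIN = 500


def haldane_c(d_morgans: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction from map distance (Morgans), no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=np.float64)))


def inverse_haldane(c: float) -> float:
    """Map distance (Morgans) at which Haldane's function equals ``c``."""
    if not 0 <= c < 0.5:
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return -0.5 * math.log(1.0 - 2.0 * c)


@dataclass
class RecombinationBin:
    c_low: float
    c_high: float
    c_mid: float          # mean c of the aggregated pairs
    r2_mean: float
    n_pairs: int
    n_samples: int
    usable: bool

    @property
    def generations(self) -> float:
        return 1.0 / (2.0 * self.c_mid)


@dataclass
class NeTrajectory:
    """(generations ago, Ne) points, one per usable bin, plus the current
    (largest-c) estimate."""

    points: pd.DataFrame  # columns: generations, ne, c_mid, r2_mean, n_pairs
    ne_current: float

    def to_frame(self) -> pd.DataFrame:
        return self.points


def _pair_r2(dos: np.ndarray, ia: np.ndarray, ib: np.ndarray, min_complete: int = 10) -> np.ndarray:
    """Vectorised pairwise-complete squared Pearson correlation for pair lists."""
    X = dos[:, ia]
    Y = dos[:, ib]
    ok = (X != MISSING) & (Y != MISSING)
    n = ok.sum(axis=0).astype(np.float64)
    Xf = np.where(ok, X, 0).astype(np.float64)
    Yf = np.where(ok, Y, 0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx, sy = Xf.sum(axis=0), Yf.sum(axis=0)
        sxx = (Xf * Xf).sum(axis=0)
        syy = (Yf * Yf).sum(axis=0)
        sxy = (Xf * Yf).sum(axis=0)
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = np.where((vx > 0) & (vy > 0), cov * cov / (vx * vy), np.nan)
    r2[n < min_complete] = np.nan
    return r2


def binned_r2(
    data: GenotypeMatrix,
    breed: str,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    max_pairs_per_bin: int = 50_000,
    seed: int = 0,
    rate_cm_per_mb: float = 1.0,
    min_pairs: int = MIN_PAIRS_PER_BIN,
) -> list[RecombinationBin]:
    """Mean r^2 of within-chromosome SNP pairs, binned by recombination fraction.

    Pairs exceeding ``max_pairs_per_bin`` are subsampled uniformly with the
    given seed.  r^2 is computed on pairwise-complete dosages; pairs with
    fewer than 10 complete samples or a monomorphic member are discarded.
    """
    idx = data.breed_index(breed)
    if idx.size < 10:
        raise DataError(f"breed {breed!r} has {idx.size} individuals, need >= 10 for LD Ne")
    dos = data.genotypes[idx]
    chrom = data.markers["chrom"].to_numpy()
    pos = data.markers["pos_bp"].to_numpy()
    # bp separation bounds per bin through the inverse genetic map
    morgans_per_bp = rate_cm_per_mb / 100.0 / 1e6
    bp_edges = [inverse_haldane(c) / morgans_per_bp for c in bin_edges]

    rng = np.random.default_rng(seed)
    n_bins = len(bin_edges) - 1
    pair_a: list[list[np.ndarray]] = [[] for _ in range(n_bins)]
    pair_b: list[list[np.ndarray]] = [[] for _ in range(n_bins)]
    for c in np.unique(chrom):
        cidx = np.flatnonzero(chrom == c)
        cpos = pos[cidx]
        for k in range(n_bins):
            lo_bp, hi_bp = bp_edges[k], bp_edges[k + 1]
            lo = np.searchsorted(cpos, cpos + lo_bp, side="left")
            hi = np.searchsorted(cpos, cpos + hi_bp, side="left")
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            ia = np.repeat(np.arange(cidx.size), counts)
            ib = np.concatenate(
                [np.arange(l, h) for l, h in zip(lo, hi) if h > l]
            ) if total else np.empty(0, dtype=np.int64)
            pair_a[k].append(cidx[ia])
            pair_b[k].append(cidx[ib])

    bins: list[RecombinationBin] = []
    any_usable = False
    for k in range(n_bins):
        if pair_a[k]:
            ia = np.concatenate(pair_a[k])
            ib = np.concatenate(pair_b[k])
        else:
            ia = ib = np.empty(0, dtype=np.int64)
        if ia.size > max_pairs_per_bin:
            take = rng.choice(ia.size, size=max_pairs_per_bin, replace=False)
            take.sort()
            ia, ib = ia[take], ib[take]
        if ia.size:
            d = np.abs(pos[ib] - pos[ia]) * morgans_per_bp
            cvals = haldane_c(d)
            r2 = _pair_r2(dos, ia, ib)
            good = ~np.isnan(r2)
            n_pairs = int(good.sum())
            r2_mean = float(r2[good].mean()) if n_pairs else float("nan")
            c_mid = float(cvals[good].mean()) if n_pairs else float(
                0.5 * (bin_edges[k] + bin_edges[k + 1])
            )
        else:
            n_pairs, r2_mean = 0, float("nan")
            c_mid = 0.5 * (bin_edges[k] + bin_edges[k + 1])
        usable = n_pairs >= min_pairs
        any_usable = any_usable or usable
        bins.append(
            RecombinationBin(
                c_low=bin_edges[k], c_high=bin_edges[k + 1], c_mid=c_mid,
                r2_mean=r2_mean, n_pairs=n_pairs, n_samples=int(idx.size),
                usable=usable,
            )
        )
    if not any_usable:
        raise DataError(f"no recombination bin has usable SNP pairs for breed {breed!r}")
    return bins


def ne_from_bin(bin: RecombinationBin) -> float:
    """Sved/Hill inversion of one bin; NaN (flagged undefined) when the
    sampling-corrected r^2 is non-positive."""
    if bin.c_mid == 0:
        raise ValueError("bin with zero recombination fraction")
    if not bin.usable:
        return float("nan")
    r2_adj = bin.r2_mean - 1.0 / bin.n_samples
    if r2_adj <= 0:
        return float("nan")
    return (1.0 / r2_adj - 1.0) / (4.0 * bin.c_mid)


def ne_trajectory(bins: list[RecombinationBin], t_max: float = 50.0) -> NeTrajectory:
    """Ne-versus-generation curve, one point per usable bin (t = 1/(2c)).

    Truncated to t <= ``t_max`` for comparability across datasets; the
    current Ne is the estimate from the largest usable c bin regardless of
    truncation.
    """
    usable = [b for b in bins if b.usable]
    if not usable:
        raise DataError("all recombination bins are unusable")
    if len(usable) < 3:
        raise DataError(f"only {len(usable)} usable bins; need >= 3 for a trajectory")
    rows = []
    for b in usable:
        rows.append(
            {"generations": b.generations, "ne": ne_from_bin(b), "c_mid": b.c_mid,
             "r2_mean": b.r2_mean, "n_pairs": b.n_pairs}
        )
    points = pd.DataFrame(rows).sort_values("generations", ignore_index=True)
    current_bin = max(usable, key=lambda b: b.c_mid)
    ne_current = ne_from_bin(current_bin)
    points = points[points["generations"] <= t_max].reset_index(drop=True)
    return NeTrajectory(points=points, ne_current=ne_current)


def estimate_ne(
    data: GenotypeMatrix,
    breed: str,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    seed: int = 0,
    rate_cm_per_mb: float = 1.0,
    t_max: float = 50.0,
    max_pairs_per_bin: int = 50_000,
    min_pairs: int = MIN_PAIRS_PER_BIN,
) -> NeTrajectory:
    """Convenience composition: binned r^2 then the trajectory."""
    bins = binned_r2(
        data, breed, bin_edges=bin_edges, max_pairs_per_bin=max_pairs_per_bin,
        seed=seed, rate_cm_per_mb=rate_cm_per_mb, min_pairs=min_pairs,
    )
    return ne_trajectory(bins, t_max=t_max)
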