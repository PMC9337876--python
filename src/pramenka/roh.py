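"""Runs of homozygosity and the F_ROH genomic inbreeding coefficient.

Detection criteria (per individual, per autosome):

I.   a run must contain at least ``l_min_snps`` markers, where the
     threshold is derived from the false-positive bound
     ``l = ln(alpha / (n_s * n_i)) / ln(1 - het)`` (floored, minimum 1);
II.  no gap between adjacent markers inside a run may exceed
     ``max_gap_bp`` (250 kb);
III. marker density inside a run must be at least one SNP per 50 kb;
IV.  a run must span at least ``min_length_bp`` (2 Mb).

Runs are classified by physical length into half-open classes
[2, 4), [4, 8), [8, 16), [16, inf) Mb; each class carries an allowance of
heterozygous and missing calls that grows with length (genotyping-error
tolerance).  Run endpoints must be homozygous non-missing calls.

Detection semantics are deterministic: among all intervals satisfying
every criterion, segments are selected longest-first (ties: leftmost),
dropping any interval that overlaps an already selected one.  The
implementation picks the globally longest valid interval and recurses on
the free flanks, which yields exactly that selection without enumerating
the full interval set.

F_ROH is the summed segment length divided by the SNP-covered autosomal
genome length (per chromosome: last minus first marker position + 1), with
the same denominator for every length class of one individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import AUTOSOMES, MISSING, DataError, GenotypeMatrix

MB = 1_000_000

#: (label, low_bp, high_bp) for the disjoint length classes.
LENGTH_CLASSES = (
    ("2-4Mb", 2 * MB, 4 * MB),
    ("4-8Mb", 4 * MB, 8 * MB),
    ("8-16Mb", 8 * MB, 16 * MB),
    (">16Mb", 16 * MB, None),
)

DEFAULT_HET_ALLOW = {"2-4Mb": 0, "4-8Mb": 1, "8-16Mb": 2, ">16Mb": 4}
DEFAULT_MISS_ALLOW = {"2-4Mb": 2, "4-8Mb": 4, "8-16Mb": 8, ">16Mb": 16}


def min_snp_threshold(alpha: float, n_s: int, n_i: int, het: float) -> int:
    """Minimum number of SNPs constituting a run, from the false-positive bound.

    ``floor( ln(alpha / (n_s * n_i)) / ln(1 - het) )``, clamped to >= 1.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 < het < 1:
        raise ValueError("het must lie strictly between 0 and 1")
    if n_s < 1 or n_i < 1:
        raise ValueError("n_s and n_i must be positive counts")
    value = math.log(alpha / (n_s * n_i)) / math.log(1.0 - het)
    return max(int(math.floor(value)), 1)


def classify_length(length_bp: int) -> str | None:
    """Length-class label for a segment, or None below the 2 Mb floor."""
    for label, low, high in LENGTH_CLASSES:
        if length_bp >= low and (high is None or length_bp < high):
            return label
    return None


@dataclass
class ROHParams:
    """Detection parameters; ``from_data`` derives l_min_snps from a dataset."""

    l_min_snps: int
    alpha: float = 0.05
    max_gap_bp: int = 250_000
    max_bp_per_snp: int = 50_000        # density: >= 1 SNP per this many bp
    min_length_bp: int = 2 * MB
    het_allow: dict = field(default_factory=lambda: dict(DEFAULT_HET_ALLOW))
    miss_allow: dict = field(default_factory=lambda: dict(DEFAULT_MISS_ALLOW))

    @classmethod
    def from_data(
        cls, data: GenotypeMatrix, alpha: float = 0.05, het: float | None = None, **kw
    ) -> "ROHParams":
        """Derive l_min_snps from the dataset's own size and heterozygosity.

        ``het`` defaults to the mean observed heterozygosity across SNPs
        (fraction of heterozygous calls among non-missing calls per SNP,
        averaged over SNPs).
        """
        if het is None:
            g = data.genotypes
            obs = g != MISSING
            n = obs.sum(axis=0)
            with np.errstate(invalid="ignore"):
                het_snp = (g == 1).sum(axis=0) / n
            het = float(np.nanmean(het_snp[n > 0]))
        l_min = min_snp_threshold(alpha, data.n_snps, data.n_samples, het)
        return cls(l_min_snps=l_min, alpha=alpha, **kw)

    def max_het(self) -> int:
        return max(self.het_allow.values())

    def max_miss(self) -> int:
        return max(self.miss_allow.values())


@dataclass
class ROHSegment:
    sample_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_class(self) -> str:
        return classify_length(self.length_bp) or "<2Mb"


def _detect_chromosome(
    pos: np.ndarray, g: np.ndarray, params: ROHParams
) -> list[tuple[int, int]]:
    """Selected (start_index, end_index) runs on one sorted chromosome."""
    n = pos.size
    if n < max(params.l_min_snps, 2):
        return []
    hom = (g == 0) | (g == 2)
    het = g == 1
    miss = g == MISSING
    cum_het = np.concatenate([[0], np.cumsum(het)])
    cum_miss = np.concatenate([[0], np.cumsum(miss)])
    # Index of the next over-sized gap at or after each marker: a run
    # starting at i may not extend past gap_bound[i].
    gaps = np.diff(pos)
    break_after = np.flatnonzero(gaps > params.max_gap_bp)
    gap_bound = np.full(n, n - 1, dtype=np.int64)
    prev = n - 1
    bi = len(break_after) - 1
    for i in range(n - 1, -1, -1):
        while bi >= 0 and break_after[bi] >= i:
            prev = min(prev, break_after[bi])
            bi -= 1
        gap_bound[i] = prev
    # Budget bounds: the run may contain at most max_het hets / max_miss
    # missing overall (class-specific checks are applied per interval).
    het_idx = np.flatnonzero(het)
    miss_idx = np.flatnonzero(miss)

    max_het, max_miss = params.max_het(), params.max_miss()

    def budget_bound(i: int) -> int:
        # largest j such that [i, j] holds within the loosest budgets
        k = np.searchsorted(het_idx, i) + max_het
        hb = het_idx[k] - 1 if k < het_idx.size else n - 1
        k = np.searchsorted(miss_idx, i) + max_miss
        mb = miss_idx[k] - 1 if k < miss_idx.size else n - 1
        return min(hb, mb)

    def valid(i: int, j: int) -> bool:
        if not (hom[i] and hom[j]):
            return False
        n_snps = j - i + 1
        if n_snps < params.l_min_snps:
            return False
        length = int(pos[j] - pos[i]) + 1
        if length < params.min_length_bp:
            return False
        if n_snps * params.max_bp_per_snp < length:
            return False
        label = classify_length(length)
        if label is None:
            return False
        if cum_het[j + 1] - cum_het[i] > params.het_allow[label]:
            return False
        if cum_miss[j + 1] - cum_miss[i] > params.miss_allow[label]:
            return False
        return True

    def best_for_start(i: int, hi: int) -> int | None:
        """Longest valid end index for start i, confined to [i, hi]."""
        jmax = min(hi, int(gap_bound[i]), budget_bound(i))
        lo_j = i + params.l_min_snps - 1
        for j in range(jmax, lo_j - 1, -1):
            if int(pos[j] - pos[i]) + 1 < params.min_length_bp:
                return None  # lengths only shrink as j decreases
            if valid(i, j):
                return j
        return None

    selected: list[tuple[int, int]] = []

    def scan(lo: int, hi: int) -> None:
        if hi - lo + 1 < params.l_min_snps:
            return
        best_len, best = -1, None
        i = lo
        while i <= hi:
            if hom[i]:
                j = best_for_start(i, hi)
                if j is not None:
                    length = int(pos[j] - pos[i]) + 1
                    if length > best_len:
                        best_len, best = length, (i, j)
            i += 1
        if best is None:
            return
        selected.append(best)
        scan(lo, best[0] - 1)
        scan(best[1] + 1, hi)

    scan(0, n - 1)
    return sorted(selected)


def detect_roh(
    genotypes: np.ndarray, markers: pd.DataFrame, params: ROHParams,
    sample_id: str = "sample",
) -> list[ROHSegment]:
    """Detect runs of homozygosity for one individual across all autosomes.

    ``genotypes`` is the individual's dosage vector aligned with
    ``markers`` (sorted by chromosome, position).  Chromosomes outside
    1..26 are ignored.
    """
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos_bp"].to_numpy()
    segments: list[ROHSegment] = []
    for c in sorted(set(int(x) for x in np.unique(chrom)) & AUTOSOMES):
        sel = chrom == c
        cpos = pos[sel]
        if np.any(np.diff(cpos) <= 0):
            raise DataError(f"marker map not strictly sorted on chromosome {c}")
        cg = genotypes[sel]
        for i, j in _detect_chromosome(cpos, cg, params):
            g_run = cg[i:j + 1]
            segments.append(
                ROHSegment(
                    sample_id=sample_id,
                    chromosome=c,
                    start_bp=int(cpos[i]),
                    end_bp=int(cpos[j]),
                    n_snps=j - i + 1,
                    n_het=int((g_run == 1).sum()),
                    n_missing=int((g_run == MISSING).sum()),
                )
            )
    return segments


def covered_genome_bp(markers: pd.DataFrame) -> int:
    """SNP-covered autosomal genome length: sum over chromosomes of
    (last position - first position + 1)."""
    if len(markers) == 0:
        raise DataError("empty marker map")
    total = 0
    for c, grp in markers.groupby("chrom"):
        if int(c) not in AUTOSOMES:
            continue
        total += int(grp["pos_bp"].max() - grp["pos_bp"].min()) + 1
    if total == 0:
        raise DataError("marker map covers no autosomal sequence")
    return total


FROH_COLUMNS = ["froh_total", "froh_2_4", "froh_4_8", "froh_8_16", "froh_gt16"]
_CLASS_TO_COLUMN = {"2-4Mb": "froh_2_4", "4-8Mb": "froh_4_8",
                    "8-16Mb": "froh_8_16", ">16Mb": "froh_gt16"}


def froh(segments: list[ROHSegment], markers: pd.DataFrame) -> dict[str, float]:
    """F_ROH by length class for one individual's segments.

    The total (>2 Mb) equals the sum over the four disjoint classes; all
    classes share the same covered-genome denominator.
    """
    denom = covered_genome_bp(markers)
    sums = {col: 0 for col in FROH_COLUMNS}
    for seg in segments:
        col = _CLASS_TO_COLUMN.get(seg.length_class)
        if col is None:
            continue
        sums[col] += seg.length_bp
        sums["froh_total"] += seg.length_bp
    return {col: sums[col] / denom for col in FROH_COLUMNS}


def froh_table(data: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Per-individual F_ROH table (plus segment counts) for a whole dataset."""
    if params is None:
        params = ROHParams.from_data(data)
    rows = []
    for i in range(data.n_samples):
        sid = data.samples["sample_id"].iat[i]
        segs = detect_roh(data.genotypes[i], data.markers, params, sample_id=sid)
        row = {"sample_id": sid, "breed": data.samples["breed"].iat[i],
               "n_segments": len(segs)}
        row.update(froh(segs, data.markers))
        rows.append(row)
    return pd.DataFrame(rows)


def breed_froh(table: pd.DataFrame) -> pd.DataFrame:
    """Per-breed mean and standard error of each F_ROH class."""
    out = []
    for breed, grp in table.groupby("breed", sort=False):
        if len(grp) == 0:
            raise DataError(f"breed {breed!r} has zero individuals")
        row = {"breed": breed, "n_samples": len(grp)}
        for col in FROH_COLUMNS:
            vals = grp[col].to_numpy(dtype=np.float64)
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)


def segments_to_bed_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """BED-like export: 0-based half-open coordinates (start_bp-1, end_bp)."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chromosome,
                "start": s.start_bp - 1,
                "end": s.end_bp,
                "sample_id": s.sample_id,
                "n_snps": s.n_snps,
                "n_het": s.n_het,
                "n_missing": s.n_missing,
                "length_bp": s.length_bp,
                "length_class": s.length_class,
            }
            for s in segments
        ],
        columns=["chrom", "start", "end", "sample_id", "n_snps", "n_het",
                 "n_missing", "length_bp", "length_class"],
    )
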