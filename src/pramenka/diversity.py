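"""Per-breed diversity statistics, F_ST, genetic distances, and PCA.

Estimator conventions
---------------------
* Observed heterozygosity (Ho) is the per-individual fraction of
  heterozygous calls among non-missing calls, averaged over the breed's
  individuals; its standard error is taken over individuals.
* Expected heterozygosity (He) is the per-SNP unbiased estimate
  ``2*p*(1-p) * 2n/(2n-1)`` from the breed's allele frequencies (n =
  individuals observed at the SNP), averaged over SNPs (monomorphic SNPs
  included); the standard error is taken over SNPs, which is why it is
  vanishingly small on array-scale data.
* F_IS is the per-individual method-of-moments inbreeding coefficient
  ``(O_hom - E_hom) / (L_obs - E_hom)`` (the PLINK ``--het`` statistic),
  averaged over individuals.
* F_ST defaults to the Weir & Cockerham (1984) estimator with the
  ratio-of-averages combination sum(a) / sum(a+b+c); the Hudson estimator
  (Bhatia et al. 2013 ratio-of-averages) is available via ``method``.
  Negative estimates are reported as computed.
* Nei's (1972) standard distance D = -ln( Jxy / sqrt(Jx * Jy) ) with the
  gene identities summed over loci before the ratio; a Reynolds
  (drift-only coancestry) variant is provided for comparison.
* PCA uses Patterson scaling: dosages centred at 2*p and scaled by
  sqrt(p*(1-p)); missing cells contribute zero after centring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, DataError, GenotypeMatrix


@dataclass
class DiversityRow:
    """Table-1-style diversity summary for one breed."""

    breed: str
    n_samples: int
    ho_mean: float
    ho_se: float
    he_mean: float
    he_se: float
    fis_mean: float
    fis_se: float


def _se(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


def _breed_genotypes(data: GenotypeMatrix, breed: str, min_samples: int = 2) -> np.ndarray:
    idx = data.breed_index(breed)
    if idx.size < min_samples:
        raise DataError(f"breed {breed!r} has {idx.size} samples, need >= {min_samples}")
    return data.genotypes[idx]


def allele_frequencies(data: GenotypeMatrix, breeds: list[str] | None = None) -> pd.DataFrame:
    """a2 allele frequency per breed (rows) and SNP (columns); NaN where unobserved."""
    breeds = breeds or data.breeds()
    rows = {}
    for b in breeds:
        g = data.genotypes[data.breed_index(b)]
        obs = g != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            rows[b] = np.where(n > 0, np.where(obs, g, 0).sum(axis=0) / (2 * n), np.nan)
    return pd.DataFrame(rows, index=data.markers["snp_id"]).T


def expected_het_per_snp(g: np.ndarray) -> np.ndarray:
    """Unbiased per-SNP expected heterozygosity 2p(1-p) * 2n/(2n-1).

    NaN for SNPs observed in fewer than one individual or exactly one
    allele (2n-1 = 0 never occurs for diploids with n >= 1).
    """
    obs = g != MISSING
    n = obs.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, g, 0).sum(axis=0) / (2 * n)
        he = 2 * p * (1 - p) * (2 * n) / (2 * n - 1)
    he[n < 1] = np.nan
    return he


def breed_diversity(data: GenotypeMatrix, breed: str) -> DiversityRow:
    """Observed/expected heterozygosity and F_IS for one breed."""
    g = _breed_genotypes(data, breed)
    obs = g != MISSING
    l_obs = obs.sum(axis=1).astype(np.float64)
    if np.any(l_obs == 0):
        raise DataError(f"breed {breed!r} contains an individual with no called genotypes")

    het = (g == 1).sum(axis=1)
    ho_i = het / l_obs

    he_snp = expected_het_per_snp(g)
    usable = ~np.isnan(he_snp)
    if not usable.any():
        raise DataError(f"breed {breed!r} has no SNP with any called genotype")

    # Per-individual F: observed vs expected homozygote counts over the SNPs
    # that individual actually observed.
    e_hom_i = obs[:, usable] @ (1.0 - he_snp[usable])
    l_i = obs[:, usable].sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        o_hom_usable = ((g[:, usable] == 0) | (g[:, usable] == 2)).sum(axis=1)
        fis_i = (o_hom_usable - e_hom_i) / (l_i - e_hom_i)

    return DiversityRow(
        breed=breed,
        n_samples=g.shape[0],
        ho_mean=float(ho_i.mean()),
        ho_se=_se(ho_i),
        he_mean=float(np.nanmean(he_snp)),
        he_se=_se(he_snp[usable]),
        fis_mean=float(np.nanmean(fis_i)),
        fis_se=_se(fis_i),
    )


def diversity_table(data: GenotypeMatrix, breeds: list[str] | None = None) -> pd.DataFrame:
    breeds = breeds or data.breeds()
    rows = [breed_diversity(data, b).__dict__ for b in breeds]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _pop_summaries(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (n individuals observed, a2 frequency, observed-het frequency)."""
    obs = g != MISSING
    n = obs.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, g, 0).sum(axis=0) / (2 * n)
        h = np.where(obs, g == 1, False).sum(axis=0) / n
    return n, p, h


def weir_cockerham_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Weir & Cockerham (1984) variance components (a, b, c) for r=2."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    return a, b, c


def pairwise_fst(
    data: GenotypeMatrix, breed_a: str, breed_b: str, method: str = "weir-cockerham"
) -> float:
    """Two-population F_ST, ratio of averages across SNPs.

    SNPs monomorphic across the pooled pair, or unobserved in either breed,
    are excluded.
    """
    ga = _breed_genotypes(data, breed_a)
    gb = _breed_genotypes(data, breed_b)
    n1, p1, h1 = _pop_summaries(ga)
    n2, p2, h2 = _pop_summaries(gb)
    with np.errstate(invalid="ignore"):
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    usable = (n1 > 0) & (n2 > 0) & (pbar > 0) & (pbar < 1)
    if not usable.any():
        raise DataError(f"no usable SNPs between breeds {breed_a!r} and {breed_b!r}")
    if method == "weir-cockerham":
        a, b, c = weir_cockerham_components(
            n1[usable], p1[usable], h1[usable], n2[usable], p2[usable], h2[usable]
        )
        num, den = np.nansum(a), np.nansum(a + b + c)
    elif method == "hudson":
        m1, m2 = 2 * n1[usable], 2 * n2[usable]  # allele counts
        q1, q2 = p1[usable], p2[usable]
        num_snp = (q1 - q2) ** 2 - q1 * (1 - q1) / (m1 - 1) - q2 * (1 - q2) / (m2 - 1)
        den_snp = q1 * (1 - q2) + q2 * (1 - q1)
        num, den = np.nansum(num_snp), np.nansum(den_snp)
    else:
        raise ValueError(f"unknown F_ST method {method!r}")
    if den == 0:
        raise DataError("F_ST denominator is zero")
    return float(num / den)


@dataclass
class FstMatrix:
    """Symmetric pairwise F_ST with per-breed means (MF_ST)."""

    breeds: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def mean_fst(self, breed: str) -> float:
        if breed not in self.breeds:
            raise DataError(f"breed {breed!r} not in F_ST matrix")
        if len(self.breeds) < 2:
            raise DataError("mean F_ST undefined for a single-breed matrix")
        i = self.breeds.index(breed)
        row = np.delete(self.values[i], i)
        return float(row.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.breeds, columns=self.breeds)
        df["MFst"] = [self.mean_fst(b) for b in self.breeds]
        return df


def fst_matrix(
    data: GenotypeMatrix, breeds: list[str] | None = None, method: str = "weir-cockerham"
) -> FstMatrix:
    breeds = breeds or data.breeds()
    k = len(breeds)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = pairwise_fst(data, breeds[i], breeds[j], method)
    return FstMatrix(breeds=breeds, values=values)


def mean_fst(m: FstMatrix, breed: str) -> float:
    """Arithmetic mean of a breed's off-diagonal pairwise F_ST values."""
    return m.mean_fst(breed)


# ---------------------------------------------------------------------------
# Genetic distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    populations: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)

    def to_phylip(self) -> str:
        lines = [f"{len(self.populations)}"]
        for name, row in zip(self.populations, self.values):
            label = f"{name:<10s}"[:10]
            lines.append(label + "  " + "  ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"

    def to_nexus(self) -> str:
        n = len(self.populations)
        lines = [
            "#NEXUS", "", "BEGIN TAXA;", f"  DIMENSIONS NTAX={n};",
            "  TAXLABELS " + " ".join(self.populations) + ";", "END;", "",
            "BEGIN DISTANCES;", "  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;", "  MATRIX",
        ]
        for name, row in zip(self.populations, self.values):
            lines.append(f"    {name} " + " ".join(f"{v:.6f}" for v in row))
        lines += ["  ;", "END;"]
        return "\n".join(lines) + "\n"


def nei_distance(freqs: pd.DataFrame, variant: str = "nei1972") -> DistanceMatrix:
    """Genetic distances from a populations x loci table of a2 frequencies.

    ``nei1972``: standard distance D = -ln( Jxy / sqrt(Jx * Jy) ) with the
    gene identities J summed over both alleles and all pairwise-complete
    loci before taking the ratio.  ``reynolds``: drift-only coancestry
    distance theta = sum (p1-p2)^2 / sum (1 - p1*p2 - q1*q2) on the same
    loci (no sample-size correction).
    """
    pops = list(freqs.index)
    P = freqs.to_numpy(dtype=np.float64)
    if np.nanmin(P) < -1e-9 or np.nanmax(P) > 1 + 1e-9:
        raise ValueError("allele frequencies must lie in [0, 1]")
    for name, row in zip(pops, P):
        if np.all(np.isnan(row)):
            raise DataError(f"population {name!r} has undefined frequencies at all loci")
    k = len(pops)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pi, pj = P[i], P[j]
            ok = ~np.isnan(pi) & ~np.isnan(pj)
            if not ok.any():
                raise DataError(
                    f"populations {pops[i]!r} and {pops[j]!r} share no typed loci"
                )
            p1, p2 = pi[ok], pj[ok]
            q1, q2 = 1 - p1, 1 - p2
            if variant == "nei1972":
                jx = np.sum(p1 * p1 + q1 * q1)
                jy = np.sum(p2 * p2 + q2 * q2)
                jxy = np.sum(p1 * p2 + q1 * q2)
                d = -np.log(jxy / np.sqrt(jx * jy))
                d = max(d, 0.0)  # clip float noise on identical vectors
            elif variant == "reynolds":
                num = np.sum((p1 - p2) ** 2)
                den = np.sum(1 - p1 * p2 - q1 * q2)
                d = num / den if den > 0 else 0.0
            else:
                raise ValueError(f"unknown distance variant {variant!r}")
            values[i, j] = values[j, i] = d
    return DistanceMatrix(populations=pops, values=values)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    coordinates: pd.DataFrame     # samples x components
    variance_fraction: np.ndarray  # percent of total variance per component


def pca(data: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Sample PCA of Patterson-scaled dosages.

    Eigendecomposition of the sample-by-sample covariance of the scaled
    genotype matrix; missing cells are zero after centring (mean
    imputation).  Monomorphic SNPs are dropped.  Variance fractions are
    percentages of the total (non-negative) spectrum and sum to <= 100.
    """
    if data.n_samples < 3:
        raise DataError("PCA requires at least 3 samples")
    g = data.genotypes
    obs = g != MISSING
    n_obs = obs.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, g, 0).sum(axis=0) / (2 * n_obs)
    poly = (n_obs > 0) & (p > 0) & (p < 1)
    if int(poly.sum()) < 2:
        raise DataError("PCA requires at least 2 polymorphic SNPs")
    p = p[poly]
    X = np.where(obs[:, poly], g[:, poly], 2 * p).astype(np.float64)
    X = (X - 2 * p) / np.sqrt(p * (1 - p))
    cov = X @ X.T / X.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.clip(eigval, 0, None)
    total = pos.sum()
    k = min(n_components, len(eigval))
    coords = eigvec[:, :k] * np.sqrt(pos[:k])
    frame = pd.DataFrame(
        coords,
        index=data.samples["sample_id"],
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    frame.insert(0, "breed", data.samples["breed"].to_numpy())
    var_frac = 100.0 * pos[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(coordinates=frame, variance_fraction=var_frac)
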