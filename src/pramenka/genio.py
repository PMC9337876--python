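"""Genotype I/O, quality control, merging, and LD pruning for PLINK datasets.

Genotypes are held as a samples x SNPs matrix of small integers counting
copies of the second allele (``a2``) of each marker: 0 (hom a1), 1 (het),
2 (hom a2), with :data:`MISSING` (-1) for no-calls.  Missing genotypes are
never imputed.  The matrix is tied to a marker map (one row per SNP, sorted
by chromosome then position) and a sample table (one row per individual,
carrying a three-letter breed code).

The binary PLINK codec follows the v1 .bed specification: three magic bytes
``0x6C 0x1B 0x01`` (SNP-major), then ceil(n_samples / 4) bytes per SNP with
two bits per sample, least-significant pair first: ``00`` hom a1, ``10``
het, ``11`` hom a2, ``01`` missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

#: Sheep autosomes occupy chromosome codes 1..26 on the OAR assemblies.
AUTOSOMES = frozenset(range(1, 27))

#: Breed codes of the study populations, by geographic group.  Codes not in
#: this registry (e.g. simulated fixtures) are auto-declared with group
#: "unknown" and logged.
BREED_GROUPS = {
    "ISS": "island", "CIS": "island", "KIS": "island",
    "RIS": "island", "PIS": "island",
    "LPS": "mainland", "DPS": "mainland", "DRS": "mainland",
    "EMC": "outgroup",
}

_SEX_TO_CODE = {"male": 1, "female": 2, "unknown": 0}
_CODE_TO_SEX = {1: "male", 2: "female", 0: "unknown"}

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit pair -> a2 dosage (01 is the PLINK missing code).
_PAIR_TO_CODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CODE_TO_PAIR = {0: 0b00, 1: 0b10, 2: 0b11, int(MISSING): 0b01}

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DataError(Exception):
    """Base class for data-level failures (CLI exit status 1)."""


class PlinkFileMissingError(DataError):
    """A member of the .bed/.bim/.fam (or .ped/.map) set does not exist."""


class PlinkMagicError(DataError):
    """The .bed file does not start with the SNP-major magic bytes."""


class PlinkDimensionError(DataError):
    """The .bed payload size disagrees with the .bim/.fam row counts."""


class MergeError(DataError):
    """Datasets cannot be merged (duplicate samples or empty intersection)."""


class QCError(DataError):
    """Quality control removed every SNP or every sample."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

def _as_marker_frame(markers: pd.DataFrame) -> pd.DataFrame:
    required = ["snp_id", "chrom", "pos_bp", "a1", "a2"]
    missing = [c for c in required if c not in markers.columns]
    if missing:
        raise ValueError(f"marker map lacks columns {missing}")
    out = markers[required].reset_index(drop=True)
    return out.astype(
        {"snp_id": str, "chrom": np.int64, "pos_bp": np.int64, "a1": str, "a2": str}
    )


def _as_sample_frame(samples: pd.DataFrame) -> pd.DataFrame:
    out = samples.copy().reset_index(drop=True)
    if "sample_id" not in out.columns:
        raise ValueError("sample table lacks a sample_id column")
    if "breed" not in out.columns:
        out["breed"] = "UNK"
    if "sex" not in out.columns:
        out["sex"] = "unknown"
    if "group" not in out.columns:
        out["group"] = [BREED_GROUPS.get(b, "unknown") for b in out["breed"]]
    return out[["sample_id", "breed", "sex", "group"]]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes with their marker map and sample table.

    Attributes
    ----------
    genotypes : ndarray of int8, shape (n_samples, n_snps)
        a2-allele dosages; -1 marks missing calls.
    markers : DataFrame with columns snp_id, chrom, pos_bp, a1, a2.
    samples : DataFrame with columns sample_id, breed, sex, group.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.markers = _as_marker_frame(self.markers)
        self.samples = _as_sample_frame(self.samples)
        self.validate()

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError(f"sample table has {len(self.samples)} rows for {n} genotype rows")
        if len(self.markers) != m:
            raise ValueError(f"marker map has {len(self.markers)} rows for {m} genotype columns")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if self.markers["snp_id"].duplicated().any():
            dup = self.markers["snp_id"][self.markers["snp_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")
        bad = (self.genotypes < -1) | (self.genotypes > 2)
        if bad.any():
            raise ValueError("genotype codes outside {-1, 0, 1, 2}")

    def is_sorted(self) -> bool:
        key = self.markers["chrom"].to_numpy() * np.int64(2**40) + self.markers["pos_bp"].to_numpy()
        return bool(np.all(np.diff(key) > 0))

    # -- subsetting ----------------------------------------------------------
    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.genotypes[index], self.markers.copy(), self.samples.iloc[index]
        )

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.genotypes[:, index], self.markers.iloc[index], self.samples.copy()
        )

    def sort_markers(self) -> "GenotypeMatrix":
        order = np.lexsort(
            (self.markers["pos_bp"].to_numpy(), self.markers["chrom"].to_numpy())
        )
        return self.take_snps(order)

    def breed_index(self, breed: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["breed"] == breed).to_numpy())
        if idx.size == 0:
            raise DataError(f"breed {breed!r} absent from sample table")
        return idx

    def breeds(self) -> list[str]:
        seen: list[str] = []
        for b in self.samples["breed"]:
            if b not in seen:
                seen.append(b)
        return seen

    # -- missingness ---------------------------------------------------------
    def snp_missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def sample_missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.markers.equals(other.markers)
            and self.samples.equals(other.samples)
        )


# ---------------------------------------------------------------------------
# PLINK binary codec
# ---------------------------------------------------------------------------

_EMPTY_BIM = pd.DataFrame(
    {"snp_id": pd.Series(dtype=str), "chrom": pd.Series(dtype=np.int64),
     "pos_bp": pd.Series(dtype=np.int64), "a1": pd.Series(dtype=str),
     "a2": pd.Series(dtype=str)}
)


def _read_bim(path: Path) -> pd.DataFrame:
    if path.stat().st_size == 0:
        return _EMPTY_BIM.copy()
    bim = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": np.int64, "snp_id": str, "pos_bp": np.int64, "a1": str, "a2": str},
    )
    return pd.DataFrame(
        {"snp_id": bim["snp_id"], "chrom": bim["chrom"], "pos_bp": bim["pos_bp"],
         "a1": bim["a1"], "a2": bim["a2"]}
    )


def _read_fam(path: Path) -> pd.DataFrame:
    fam = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str, "sex": np.int64},
    )
    return pd.DataFrame(
        {
            "sample_id": fam["iid"],
            "breed": fam["fid"],
            "sex": [_CODE_TO_SEX.get(s, "unknown") for s in fam["sex"]],
            "group": [BREED_GROUPS.get(b, "unknown") for b in fam["fid"]],
        }
    )


def _apply_sidecar(samples: pd.DataFrame, sidecar: Path) -> pd.DataFrame:
    side = pd.read_csv(sidecar, sep="\t", dtype=str)
    side = side.set_index("sample_id")
    out = samples.set_index("sample_id")
    for col in ("breed_code", "breed"):
        if col in side.columns:
            out.loc[side.index, "breed"] = side[col]
    for col in ("sex", "group"):
        if col in side.columns:
            out.loc[side.index, col] = side[col]
    return out.reset_index()


def read_plink(prefix: str | Path, sidecar: str | Path | None = None) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triplet.

    ``prefix.samples.tsv`` (or an explicit ``sidecar`` TSV with columns
    sample_id, breed_code, sex, group) overrides the breed/sex/group pulled
    from the .fam columns.
    """
    prefix = Path(prefix)
    paths = {ext: prefix.with_suffix(prefix.suffix + ext) for ext in (".bed", ".bim", ".fam")}
    for ext, p in paths.items():
        if not p.exists():
            raise PlinkFileMissingError(f"missing {p}")
    markers = _read_bim(paths[".bim"])
    samples = _read_fam(paths[".fam"])
    raw = np.fromfile(paths[".bed"], dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise PlinkMagicError(f"{paths['.bed']} lacks SNP-major magic bytes 6c 1b 01")
    n, m = len(samples), len(markers)
    bytes_per_snp = (n + 3) // 4
    payload = raw[3:]
    if payload.size != m * bytes_per_snp:
        raise PlinkDimensionError(
            f"{paths['.bed']}: payload of {payload.size} bytes, expected "
            f"{m} SNPs x {bytes_per_snp} bytes for {n} samples"
        )
    # Unpack two-bit pairs, least significant first, then keep n samples.
    mat = payload.reshape(m, bytes_per_snp)
    pairs = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        pairs[:, k::4] = (mat >> (2 * k)) & 0b11
    geno = _PAIR_TO_CODE[pairs[:, :n]].T  # -> (n_samples, n_snps)

    if sidecar is None:
        default = Path(str(prefix) + ".samples.tsv")
        sidecar = default if default.exists() else None
    if sidecar is not None:
        samples = _apply_sidecar(samples, Path(sidecar))
    unknown = sorted(set(samples["breed"]) - set(BREED_GROUPS))
    if unknown:
        logger.info("auto-declaring breed codes outside the registry: %s", unknown)
    return GenotypeMatrix(geno, markers, samples)


def write_plink(data: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a bit-exact PLINK .bed/.bim/.fam triplet (SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = data.n_samples, data.n_snps
    bytes_per_snp = (n + 3) // 4

    code_to_pair = np.zeros(4, dtype=np.uint8)
    for code, pair in _CODE_TO_PAIR.items():
        code_to_pair[code & 0b11] = pair  # -1 -> index 3
    pairs = code_to_pair[data.genotypes.T & 0b11]  # (m, n), padding handled below
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = pairs
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)

    with open(str(prefix) + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": data.markers["chrom"],
            "snp_id": data.markers["snp_id"],
            "cm": 0,
            "pos_bp": data.markers["pos_bp"],
            "a1": data.markers["a1"],
            "a2": data.markers["a2"],
        }
    )
    bim.to_csv(str(prefix) + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": data.samples["breed"],
            "iid": data.samples["sample_id"],
            "father": 0,
            "mother": 0,
            "sex": [_SEX_TO_CODE.get(s, 0) for s in data.samples["sex"]],
            "pheno": -9,
        }
    )
    fam.to_csv(str(prefix) + ".fam", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# PLINK text codec (.ped/.map)
# ---------------------------------------------------------------------------

def read_plink_text(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK .ped/.map pair.

    Allele columns are re-coded per SNP: a1 is the minor allele (ties broken
    alphabetically) and the genotype counts copies of a2, mirroring PLINK's
    default when importing text pedigrees.
    """
    prefix = Path(prefix)
    ped_path, map_path = Path(str(prefix) + ".ped"), Path(str(prefix) + ".map")
    for p in (ped_path, map_path):
        if not p.exists():
            raise PlinkFileMissingError(f"missing {p}")
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "pos_bp"],
        dtype={"chrom": np.int64, "snp_id": str, "pos_bp": np.int64},
    )
    m = len(mp)
    rows, alleles = [], []
    with open(ped_path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PlinkDimensionError(
                    f"{ped_path}: row with {len(fields)} fields, expected {6 + 2 * m}"
                )
            rows.append(fields[:6])
            alleles.append(fields[6:])
    allele_mat = np.array(alleles, dtype="U2").reshape(len(rows), m, 2)

    geno = np.zeros((len(rows), m), dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(m):
        col = allele_mat[:, j, :]
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if uniq.size > 2:
            raise DataError(f"SNP {mp['snp_id'][j]!r} has {uniq.size} alleles")
        if uniq.size == 0:
            a1, a2 = "0", "0"
        elif uniq.size == 1:
            a1, a2 = "0", str(uniq[0])
        else:
            order = np.lexsort((uniq, counts))  # minor (ties: alphabetical) first
            a1, a2 = str(uniq[order[0]]), str(uniq[order[1]])
        a1_list.append(a1)
        a2_list.append(a2)
        miss = (col == "0").any(axis=1)
        geno[:, j] = (col == a2).sum(axis=1).astype(np.int8)
        geno[miss, j] = MISSING

    fam = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex", "pheno"])
    samples = pd.DataFrame(
        {
            "sample_id": fam["iid"],
            "breed": fam["fid"],
            "sex": [_CODE_TO_SEX.get(int(s) if s.isdigit() else 0, "unknown") for s in fam["sex"]],
            "group": [BREED_GROUPS.get(b, "unknown") for b in fam["fid"]],
        }
    )
    markers = pd.DataFrame(
        {"snp_id": mp["snp_id"], "chrom": mp["chrom"], "pos_bp": mp["pos_bp"],
         "a1": a1_list, "a2": a2_list}
    )
    return GenotypeMatrix(geno, markers, samples)


def write_plink_text(data: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK .ped/.map pair."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mp = data.markers
    with open(str(prefix) + ".map", "w") as fh:
        for _, r in mp.iterrows():
            fh.write(f"{r['chrom']}\t{r['snp_id']}\t0\t{r['pos_bp']}\n")
    a1 = mp["a1"].to_numpy()
    a2 = mp["a2"].to_numpy()
    with open(str(prefix) + ".ped", "w") as fh:
        for i in range(data.n_samples):
            s = data.samples.iloc[i]
            fields = [s["breed"], s["sample_id"], "0", "0",
                      str(_SEX_TO_CODE.get(s["sex"], 0)), "-9"]
            g = data.genotypes[i]
            for j in range(data.n_snps):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 0:
                    fields += [a1[j], a1[j]]
                elif g[j] == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

@dataclass
class MergeReport:
    n_shared: int
    n_flipped: int
    dropped_conflict: list = field(default_factory=list)
    dropped_ambiguous: list = field(default_factory=list)


def _is_strand_flip(pair_a: tuple, pair_b: tuple) -> bool:
    comp = tuple(a.translate(_DNA_COMPLEMENT) for a in pair_b)
    return set(pair_a) == set(comp)


def merge_datasets(a: GenotypeMatrix, b: GenotypeMatrix) -> tuple[GenotypeMatrix, MergeReport]:
    """Concatenate samples over the intersection of marker sets.

    Markers whose alleles in ``b`` are swapped relative to ``a`` are recoded
    (g -> 2-g); markers with conflicting alleles, or where the two datasets
    differ only by strand complement (A/T with T/A etc., unresolvable), are
    dropped and listed in the report.
    """
    dup = set(a.samples["sample_id"]) & set(b.samples["sample_id"])
    if dup:
        raise MergeError(f"duplicate sample_ids across datasets: {sorted(dup)[:5]}")
    a_idx = {s: i for i, s in enumerate(a.markers["snp_id"])}
    keep_a, keep_b, flip_b = [], [], []
    report = MergeReport(n_shared=0, n_flipped=0)
    b_m = b.markers
    for j, sid in enumerate(b_m["snp_id"]):
        i = a_idx.get(sid)
        if i is None:
            continue
        report.n_shared += 1
        pa = (a.markers["a1"].iat[i], a.markers["a2"].iat[i])
        pb = (b_m["a1"].iat[j], b_m["a2"].iat[j])
        if pa == pb:
            keep_a.append(i); keep_b.append(j); flip_b.append(False)
        elif pa == pb[::-1]:
            keep_a.append(i); keep_b.append(j); flip_b.append(True)
            report.n_flipped += 1
        elif _is_strand_flip(pa, pb):
            report.dropped_ambiguous.append(sid)
        else:
            report.dropped_conflict.append(sid)
    if not keep_a:
        raise MergeError("zero overlapping SNPs after allele reconciliation")
    keep_a = np.array(keep_a)
    keep_b = np.array(keep_b)
    flip_b = np.array(flip_b)

    ga = a.genotypes[:, keep_a]
    gb = b.genotypes[:, keep_b].copy()
    flip_cols = np.flatnonzero(flip_b)
    for c in flip_cols:
        col = gb[:, c]
        obs = col != MISSING
        col[obs] = 2 - col[obs]
    geno = np.vstack([ga, gb])
    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    merged = GenotypeMatrix(geno, a.markers.iloc[keep_a], samples).sort_markers()
    logger.info(
        "merge: %d shared SNPs, %d flipped, %d conflicting dropped, %d strand-ambiguous dropped",
        report.n_shared, report.n_flipped,
        len(report.dropped_conflict), len(report.dropped_ambiguous),
    )
    return merged, report


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_snps_in: int
    n_samples_in: int
    n_snps_nonautosomal: int = 0
    n_snps_no_position: int = 0
    n_snps_missingness: int = 0
    n_samples_missingness: int = 0
    n_snps_out: int = 0
    n_samples_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": ["snps_in", "samples_in", "snps_nonautosomal_removed",
                      "snps_no_position_removed", "snps_missingness_removed",
                      "samples_missingness_removed", "snps_out", "samples_out"],
             "count": [self.n_snps_in, self.n_samples_in, self.n_snps_nonautosomal,
                       self.n_snps_no_position, self.n_snps_missingness,
                       self.n_samples_missingness, self.n_snps_out, self.n_samples_out]}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def qc_filter(
    data: GenotypeMatrix,
    max_snp_missing: float = 0.10,
    max_sample_missing: float = 0.05,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the study's marker/sample quality filters.

    Order of operations (documented, reproducible): non-autosomal and
    position-less SNPs are dropped, then SNPs with missingness above
    ``max_snp_missing``, then samples with missingness above
    ``max_sample_missing`` re-evaluated on the surviving SNPs.  Because
    removing a sample can raise the missing fraction of a SNP (and vice
    versa), the SNP/sample passes repeat until stable, so the filter is
    idempotent; the report carries cumulative counts.
    """
    if not (0 <= max_snp_missing <= 1 and 0 <= max_sample_missing <= 1):
        raise ValueError("missingness thresholds must lie in [0, 1]")
    report = QCReport(n_snps_in=data.n_snps, n_samples_in=data.n_samples)

    keep = np.ones(data.n_snps, dtype=bool)
    if autosomes_only:
        chrom = data.markers["chrom"].to_numpy()
        auto = np.isin(chrom, list(AUTOSOMES))
        report.n_snps_nonautosomal = int((~auto).sum())
        keep &= auto
    has_pos = data.markers["pos_bp"].to_numpy() > 0
    report.n_snps_no_position = int((keep & ~has_pos).sum())
    keep &= has_pos
    out = data.take_snps(np.flatnonzero(keep))

    while True:
        snp_ok = out.snp_missing_fraction() <= max_snp_missing
        report.n_snps_missingness += int((~snp_ok).sum())
        out = out.take_snps(np.flatnonzero(snp_ok))
        if out.n_snps == 0:
            raise QCError("quality control removed every SNP")

        sample_ok = out.sample_missing_fraction() <= max_sample_missing
        report.n_samples_missingness += int((~sample_ok).sum())
        out = out.take_samples(np.flatnonzero(sample_ok))
        if out.n_samples == 0:
            raise QCError("quality control removed every sample")
        if snp_ok.all() and sample_ok.all():
            break

    report.n_snps_out = out.n_snps
    report.n_samples_out = out.n_samples
    logger.info(
        "qc: %d/%d SNPs and %d/%d samples retained",
        out.n_snps, data.n_snps, out.n_samples, data.n_samples,
    )
    return out, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def pairwise_r2(x: np.ndarray, y: np.ndarray, min_complete: int = 10) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples (both calls non-missing),
    unphased Rogers-Huff style.  Returns NaN when fewer than
    ``min_complete`` complete pairs remain or either SNP is monomorphic on
    the complete subset.
    """
    ok = (x != MISSING) & (y != MISSING)
    if int(ok.sum()) < min_complete:
        return float("nan")
    xs = x[ok].astype(np.float64)
    ys = y[ok].astype(np.float64)
    xs -= xs.mean()
    ys -= ys.mean()
    denom = (xs @ xs) * (ys @ ys)
    if denom == 0:
        return float("nan")
    r = (xs @ ys) / np.sqrt(denom)
    return float(r * r)


def ld_prune(
    data: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.1,
    min_complete: int = 10,
) -> GenotypeMatrix:
    """Sliding-window LD pruning within chromosomes.

    Windows of ``window_snps`` markers advance by ``step_snps``.  Within a
    window, while any retained pair exceeds ``r2_threshold``, the pair with
    the largest r-squared is found (ties: first in index order) and one
    member removed: the SNP with higher missingness, or the larger index on
    a tie.  SNP pairs whose r-squared is undefined (monomorphic, or fewer
    than ``min_complete`` complete samples) never trigger removal.
    """
    if window_snps < step_snps:
        raise ValueError("window_snps must be >= step_snps")
    if not data.is_sorted():
        raise DataError("ld_prune requires markers sorted by (chromosome, position)")
    miss = data.snp_missing_fraction()
    chrom = data.markers["chrom"].to_numpy()
    keep = np.ones(data.n_snps, dtype=bool)

    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        n = idx.size
        start = 0
        while start < n:
            window = idx[start:start + window_snps]
            _prune_window(data.genotypes, window, keep, miss, r2_threshold, min_complete)
            if start + window_snps >= n:
                break
            start += step_snps
    logger.info("ld_prune: retained %d of %d SNPs", int(keep.sum()), data.n_snps)
    return data.take_snps(np.flatnonzero(keep))


def r2_matrix(geno: np.ndarray, cols: np.ndarray, min_complete: int = 10) -> np.ndarray:
    """Pairwise-complete squared Pearson correlation among dosage columns.

    NaN marks pairs that are unusable (too few complete samples, or a
    monomorphic member on the complete subset) and the diagonal.
    """
    X = geno[:, cols].astype(np.float64)
    obs = X != MISSING
    X0 = np.where(obs, X, 0.0)
    O = obs.astype(np.float64)
    n = O.T @ O
    sx = X0.T @ O          # sum of x over pairs where both present
    sxx = (X0 * X0).T @ O
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx * sx / n
        denom = varx * varx.T
        r2 = np.where(denom > 0, cov * cov / denom, np.nan)
        r2[n < min_complete] = np.nan
    np.fill_diagonal(r2, np.nan)
    return r2


def _prune_window(
    geno: np.ndarray,
    window: np.ndarray,
    keep: np.ndarray,
    miss: np.ndarray,
    threshold: float,
    min_complete: int,
) -> None:
    active = window[keep[window]]
    if active.size < 2:
        return
    r2 = r2_matrix(geno, active, min_complete)
    alive = np.ones(active.size, dtype=bool)
    while True:
        sub = np.where(alive[:, None] & alive[None, :], r2, np.nan)
        iu = np.triu_indices(active.size, k=1)
        vals = sub[iu]
        if np.all(np.isnan(vals)) or np.nanmax(vals) <= threshold:
            break
        best = np.nanmax(vals)
        k = int(np.flatnonzero(vals == best)[0])  # first pair in row-major order
        ai, bi = int(iu[0][k]), int(iu[1][k])
        i, j = int(active[ai]), int(active[bi])
        if miss[i] > miss[j]:
            drop = ai
        elif miss[j] > miss[i]:
            drop = bi
        else:
            drop = bi if j > i else ai
        alive[drop] = False
        keep[active[drop]] = False
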