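"""Forward-in-time Wright-Fisher simulator for genotype fixtures with truth.

The simulator produces PLINK-format fixtures whose population history is
known exactly, so that every analysis stage (QC, diversity, F_ST, ROH,
LD-Ne) can be validated without external data:

* discrete non-overlapping generations, N diploids per epoch, each
  offspring drawing two parents uniformly at random (selfing permitted, as
  in the canonical Wright-Fisher model, so per-generation drift variance is
  exactly p(1-p)/(2N));
* recombination by Poisson crossover counts per gamete at a uniform rate
  (default 1 cM/Mb), positions uniform along the genetic map, no
  interference; chromosomes assort independently;
* no mutation: fixtures start from standing variation, mirroring the
  ascertained standing variation of SNP arrays, with founder allele
  frequencies drawn from U(0.05, 0.95) by default;
* population splits produce isolated descendant populations whose expected
  differentiation under pure drift is F_ST = 1 - (1 - 1/(2N))^t;
* planted close-relative matings (parent-offspring or full-sib) create
  individuals with pedigree inbreeding F = 1/4 whose genomes carry genuine
  identity-by-descent tracts shaped by the same recombination process.

All randomness derives from one seed through ``numpy.random.SeedSequence``
spawning, so every product is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genio import GenotypeMatrix, MISSING, write_plink


@dataclass
class SimConfig:
    """Truth specification for a simulated fixture.

    ``ne_schedule`` is a list of (generations, diploid N) epochs applied in
    order, oldest first.  Sizes and rates default to a sheep-like genome:
    26 autosomes of 100 Mb at 1 cM/Mb with ~1,500 array markers per
    chromosome.
    """

    seed: int
    n_chromosomes: int = 26
    chromosome_length_bp: int = 100_000_000
    n_snps_per_chromosome: int = 1500
    recomb_rate_cm_per_mb: float = 1.0
    founder_freq_low: float = 0.05
    founder_freq_high: float = 0.95
    ne_schedule: list = field(default_factory=lambda: [[50, 100]])
    missing_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length_bp < 2:
            raise ValueError("genome dimensions must be positive")
        if self.n_snps_per_chromosome < 2:
            raise ValueError("need at least 2 SNPs per chromosome")
        if not 0 <= self.missing_rate <= 0.05:
            raise ValueError("missing_rate must lie in [0, 0.05]")
        for epoch in self.ne_schedule:
            g, n = epoch
            if g < 0 or n < 2:
                raise ValueError(f"invalid epoch {epoch!r} in ne_schedule")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length_bp": self.chromosome_length_bp,
            "n_snps_per_chromosome": self.n_snps_per_chromosome,
            "recomb_rate_cm_per_mb": self.recomb_rate_cm_per_mb,
            "founder_freq_low": self.founder_freq_low,
            "founder_freq_high": self.founder_freq_high,
            "ne_schedule": [list(e) for e in self.ne_schedule],
            "missing_rate": self.missing_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth accompanying a fixture.

    ``individuals``: flagged samples with their pedigree inbreeding F.
    ``pairs``: population pairs with split time and expected drift F_ST.
    ``founder_freq`` / ``final_freq``: realized allele frequencies at the
    start and end of the (single-population) simulation, for drift checks.
    """

    individuals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "mating_type", "f_pedigree"])
    )
    pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["pop_a", "pop_b", "t_split", "n_diploid", "expected_fst"]
        )
    )
    founder_freq: np.ndarray | None = None
    final_freq: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for _, r in self.individuals.iterrows():
            rows.append(
                {"record_type": "individual", "id_a": r["sample_id"], "id_b": "",
                 "mating_type": r["mating_type"], "f_pedigree": r["f_pedigree"],
                 "t_split": "", "expected_fst": ""}
            )
        for _, r in self.pairs.iterrows():
            rows.append(
                {"record_type": "pair", "id_a": r["pop_a"], "id_b": r["pop_b"],
                 "mating_type": "", "f_pedigree": "",
                 "t_split": r["t_split"], "expected_fst": r["expected_fst"]}
            )
        return pd.DataFrame(
            rows, columns=["record_type", "id_a", "id_b", "mating_type",
                           "f_pedigree", "t_split", "expected_fst"]
        )


# ---------------------------------------------------------------------------
# Core machinery
# ---------------------------------------------------------------------------

class _Genome:
    """Marker coordinates shared by every individual of a simulation."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        morgans_per_bp = cfg.recomb_rate_cm_per_mb / 100.0 / 1e6
        self.chrom_length_m = cfg.chromosome_length_bp * morgans_per_bp
        chroms, positions = [], []
        for c in range(1, cfg.n_chromosomes + 1):
            # distinct uniform bp positions; top up the rare collisions
            m = cfg.n_snps_per_chromosome
            pos = np.unique(rng.integers(1, cfg.chromosome_length_bp, size=m, dtype=np.int64))
            while pos.size < m:
                extra = rng.integers(1, cfg.chromosome_length_bp,
                                     size=m - pos.size, dtype=np.int64)
                pos = np.unique(np.concatenate([pos, extra]))
            pos = np.sort(pos)
            chroms.append(np.full(cfg.n_snps_per_chromosome, c, dtype=np.int64))
            positions.append(pos)
        self.chrom = np.concatenate(chroms)
        self.pos_bp = np.concatenate(positions)
        self.n_snps = self.pos_bp.size
        # Global genetic-map coordinate: chromosome c occupies
        # [(c-1) * L_m, c * L_m); crossovers never straddle chromosomes
        # because each SNP's coordinate stays inside its chromosome span.
        self.pos_morgan = (self.chrom - 1) * self.chrom_length_m + self.pos_bp * morgans_per_bp
        self.chrom_starts_m = np.arange(cfg.n_chromosomes) * self.chrom_length_m
        self.total_morgans = cfg.n_chromosomes * self.chrom_length_m

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [f"snp{c}_{p}" for c, p in zip(self.chrom, self.pos_bp)],
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "a1": "A",
                "a2": "B",
            }
        )


def _gamete(genome: _Genome, hap_a: np.ndarray, hap_b: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a parent's two haplotypes.

    Crossovers: Poisson(total map length) events uniform on the map, plus
    an independent fair phase flip at each chromosome start (independent
    assortment).  The transmitted haplotype at each marker follows the
    parity of events preceding it.
    """
    k = rng.poisson(genome.total_morgans)
    events = rng.uniform(0.0, genome.total_morgans, size=k)
    flips = genome.chrom_starts_m[rng.random(genome.cfg.n_chromosomes) < 0.5]
    if flips.size:
        events = np.concatenate([events, flips])
    events.sort()
    parity = np.searchsorted(events, genome.pos_morgan, side="right") & 1
    return np.where(parity == 0, hap_a, hap_b)


def _advance(genome: _Genome, haps: np.ndarray, n_children: int,
             rng: np.random.Generator) -> np.ndarray:
    """One Wright-Fisher generation: ``haps`` is (2N, n_snps) int8.

    Random draws are batched per generation; the per-gamete work is one
    sort/searchsorted over its few crossover events.
    """
    n_parents = haps.shape[0] // 2
    n_gametes = 2 * n_children
    out = np.empty((n_gametes, genome.n_snps), dtype=np.int8)
    parents = rng.integers(0, n_parents, size=n_gametes)
    counts = rng.poisson(genome.total_morgans, size=n_gametes)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    all_events = rng.uniform(0.0, genome.total_morgans, size=int(offsets[-1]))
    flip_mask = rng.random((n_gametes, genome.cfg.n_chromosomes)) < 0.5
    starts = genome.chrom_starts_m
    for g in range(n_gametes):
        events = all_events[offsets[g]:offsets[g + 1]]
        flips = starts[flip_mask[g]]
        if flips.size:
            events = np.concatenate([events, flips])
        events.sort()
        parity = np.searchsorted(events, genome.pos_morgan, side="right") & 1
        p = parents[g]
        out[g] = np.where(parity == 0, haps[2 * p], haps[2 * p + 1])
    return out


def _evolve(genome: _Genome, haps: np.ndarray, schedule: list,
            rng: np.random.Generator) -> np.ndarray:
    for gens, n in schedule:
        for _ in range(int(gens)):
            haps = _advance(genome, haps, int(n), rng)
    return haps


def _founders(genome: _Genome, n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    freq = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, size=genome.n_snps)
    return (rng.random((2 * n, genome.n_snps)) < freq).astype(np.int8)


def _emit(
    genome: _Genome, haps: np.ndarray, which: np.ndarray,
    sample_ids: list[str], breed_codes: list[str],
    missing_rate: float, rng: np.random.Generator,
) -> GenotypeMatrix:
    geno = (haps[2 * which] + haps[2 * which + 1]).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = MISSING
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "breed": breed_codes,
         "sex": "unknown", "group": "unknown"}
    )
    return GenotypeMatrix(geno, genome.marker_frame(), samples)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_cohort(genome: _Genome, haps: np.ndarray, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Haplotypes of n sampled individuals, drawn as a random-union
    offspring cohort of the final generation.

    Sampling by fresh gametes (parents with replacement) rather than by
    picking population members keeps estimator sampling corrections exact:
    picking members without replacement from a small population removes
    part of the final generation's drift from what an F-statistic can see.
    """
    return _advance(genome, haps, n, rng)


def _hap_freq(haps: np.ndarray) -> np.ndarray:
    return haps.mean(axis=0)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def simulate_population(
    cfg: SimConfig, n_sample: int | None = None, breed_code: str = "SIM"
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Single population evolved through ``cfg.ne_schedule``.

    Returns genotypes for ``n_sample`` individuals drawn without
    replacement from the final generation (default: min(N_final, 50)), and
    a truth record holding the realized founder and final allele
    frequencies of the whole population.
    """
    rng_map, rng_founder, rng_evolve, rng_emit = _rngs(cfg.seed, 4)
    genome = _Genome(cfg, rng_map)
    n0 = int(cfg.ne_schedule[0][1])
    haps = _founders(genome, n0, cfg, rng_founder)
    founder_freq = _hap_freq(haps)
    haps = _evolve(genome, haps, cfg.ne_schedule, rng_evolve)
    n_final = haps.shape[0] // 2
    if n_sample is None:
        n_sample = min(n_final, 50)
    sample_haps = _sample_cohort(genome, haps, n_sample, rng_emit)
    ids = [f"{breed_code}{i:04d}" for i in range(n_sample)]
    data = _emit(genome, sample_haps, np.arange(n_sample), ids,
                 [breed_code] * n_sample, cfg.missing_rate, rng_emit)
    truth = TruthRecord(founder_freq=founder_freq, final_freq=_hap_freq(haps))
    return data, truth


def simulate_split_pair(
    cfg: SimConfig, t_split: int, n_per_pop: int,
    breed_codes: tuple[str, str] = ("PPA", "PPB"),
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Ancestral population split into two isolated descendants.

    The ancestor evolves through ``cfg.ne_schedule``; both descendants then
    evolve independently for ``t_split`` generations at the final epoch
    size N.  Expected drift differentiation 1 - (1 - 1/(2N))^t is recorded
    in the truth.  At t_split = 0, the two "populations" are disjoint
    samples of the ancestor.
    """
    if t_split < 0:
        raise ValueError("t_split must be >= 0")
    rng_map, rng_founder, rng_evolve, rng_a, rng_b, rng_emit = _rngs(cfg.seed, 6)
    genome = _Genome(cfg, rng_map)
    n0 = int(cfg.ne_schedule[0][1])
    haps = _founders(genome, n0, cfg, rng_founder)
    haps = _evolve(genome, haps, cfg.ne_schedule, rng_evolve)
    n_anc = haps.shape[0] // 2
    n_desc = int(cfg.ne_schedule[-1][1])

    if t_split == 0:
        haps_a = haps_b = haps
    else:
        haps_a = _evolve(genome, haps, [[t_split, n_desc]], rng_a)
        haps_b = _evolve(genome, haps, [[t_split, n_desc]], rng_b)
    sample_a = _sample_cohort(genome, haps_a, n_per_pop, rng_a)
    sample_b = _sample_cohort(genome, haps_b, n_per_pop, rng_b)

    ca, cb = breed_codes
    ids = [f"{ca}{i:04d}" for i in range(n_per_pop)] + [f"{cb}{i:04d}" for i in range(n_per_pop)]
    codes = [ca] * n_per_pop + [cb] * n_per_pop
    even = np.arange(0, 2 * n_per_pop, 2)
    geno_a = sample_a[even] + sample_a[even + 1]
    geno_b = sample_b[even] + sample_b[even + 1]
    geno = np.vstack([geno_a, geno_b]).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng_emit.random(geno.shape) < cfg.missing_rate
        geno[mask] = MISSING
    samples = pd.DataFrame(
        {"sample_id": ids, "breed": codes, "sex": "unknown", "group": "unknown"}
    )
    data = GenotypeMatrix(geno, genome.marker_frame(), samples)
    expected = 1.0 - (1.0 - 1.0 / (2.0 * n_desc)) ** t_split
    truth = TruthRecord(
        pairs=pd.DataFrame(
            [{"pop_a": ca, "pop_b": cb, "t_split": t_split,
              "n_diploid": n_desc, "expected_fst": expected}]
        )
    )
    return data, truth


def plant_inbred_offspring(
    cfg: SimConfig, mating_type: str = "parent-offspring",
    count: int = 20, n_controls: int = 20,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Offspring of close-relative matings with pedigree F = 1/4, plus
    outbred controls from the same base population.

    parent-offspring: a child of (sire, dam) is mated back to the sire.
    full-sib: two children of the same pair are mated together.
    """
    if mating_type not in ("parent-offspring", "full-sib"):
        raise ValueError(f"unknown mating type {mating_type!r}")
    rng_map, rng_founder, rng_evolve, rng_mate, rng_emit = _rngs(cfg.seed, 5)
    genome = _Genome(cfg, rng_map)
    n0 = int(cfg.ne_schedule[0][1])
    haps = _founders(genome, n0, cfg, rng_founder)
    haps = _evolve(genome, haps, cfg.ne_schedule, rng_evolve)
    n_base = haps.shape[0] // 2
    if count > n_base or n_controls > n_base:
        raise ValueError("count exceeds base population size")

    def cross(pa: tuple[np.ndarray, np.ndarray], pb: tuple[np.ndarray, np.ndarray]):
        return (_gamete(genome, pa[0], pa[1], rng_mate),
                _gamete(genome, pb[0], pb[1], rng_mate))

    def base_parent(i: int) -> tuple[np.ndarray, np.ndarray]:
        return haps[2 * i], haps[2 * i + 1]

    out_haps = []
    ids, codes, f_ped, types = [], [], [], []
    for k in range(count):
        s, d = rng_mate.choice(n_base, size=2, replace=False)
        sire, dam = base_parent(s), base_parent(d)
        if mating_type == "parent-offspring":
            child = cross(sire, dam)
            final = cross(sire, child)
        else:
            c1 = cross(sire, dam)
            c2 = cross(sire, dam)
            final = cross(c1, c2)
        out_haps += [final[0], final[1]]
        ids.append(f"INB{k:03d}")
        codes.append("INB")
        f_ped.append(0.25)
        types.append(mating_type)
    for k in range(n_controls):
        s, d = rng_mate.choice(n_base, size=2, replace=False)
        child = cross(base_parent(s), base_parent(d))
        out_haps += [child[0], child[1]]
        ids.append(f"CTL{k:03d}")
        codes.append("CTL")
        f_ped.append(0.0)
        types.append("outbred-control")

    all_haps = np.vstack(out_haps)
    data = _emit(genome, all_haps, np.arange(len(ids)), ids, codes,
                 cfg.missing_rate, rng_emit)
    truth = TruthRecord(
        individuals=pd.DataFrame(
            {"sample_id": ids, "mating_type": types, "f_pedigree": f_ped}
        )
    )
    return data, truth


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------

_SCENARIO_BUILDERS = {
    "population": lambda cfg, kw: simulate_population(cfg, **kw),
    "split_pair": lambda cfg, kw: simulate_split_pair(cfg, **kw),
    "inbred": lambda cfg, kw: plant_inbred_offspring(cfg, **kw),
}


def write_fixture(
    data: GenotypeMatrix, truth: TruthRecord, prefix: str | Path,
    cfg: SimConfig | None = None, scenario: str | None = None,
    scenario_args: dict | None = None,
) -> None:
    """PLINK triplet + truth TSV + (optionally) regenerable config YAML."""
    prefix = Path(prefix)
    write_plink(data, prefix)
    truth.to_frame().to_csv(str(prefix) + ".truth.tsv", sep="\t", index=False)
    if cfg is not None:
        doc = {"config": cfg.to_dict()}
        if scenario is not None:
            doc["scenario"] = scenario
            doc["scenario_args"] = scenario_args or {}
        with open(str(prefix) + ".config.yaml", "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def regenerate_fixture(yaml_path: str | Path, prefix: str | Path) -> tuple[GenotypeMatrix, TruthRecord]:
    """Rebuild a fixture from its stored YAML; identical bytes for the same seed."""
    with open(yaml_path) as fh:
        doc = yaml.safe_load(fh)
    cfg = SimConfig.from_dict(doc["config"])
    scenario = doc.get("scenario", "population")
    kw = doc.get("scenario_args", {}) or {}
    if "breed_codes" in kw:
        kw["breed_codes"] = tuple(kw["breed_codes"])
    data, truth = _SCENARIO_BUILDERS[scenario](cfg, kw)
    write_fixture(data, truth, prefix, cfg=cfg, scenario=scenario, scenario_args=kw)
    return data, truth
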