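"""Shared fixtures.

The expensive forward simulations (drift recovery, pedigree inbreeding,
constant-Ne recovery, the three-breed pipeline fixture) are session-scoped
so that module tests and the acceptance-criteria tests measure the same
runs instead of recomputing them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pramenka as pk


def make_matrix(genotypes, chrom=None, pos=None, breeds=None, sample_ids=None):
    """Small-matrix factory for hand-built toys."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    chrom = chrom if chrom is not None else np.ones(m, dtype=int)
    pos = pos if pos is not None else (np.arange(m) + 1) * 1000
    markers = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(m)], "chrom": chrom, "pos_bp": pos,
         "a1": "A", "a2": "B"}
    )
    breeds = breeds if breeds is not None else ["TOY"] * n
    sample_ids = sample_ids if sample_ids is not None else [f"i{k}" for k in range(n)]
    samples = pd.DataFrame({"sample_id": sample_ids, "breed": breeds})
    return pk.GenotypeMatrix(g, markers, samples)


# ---------------------------------------------------------------------------
# Heavy simulation studies (shared with the acceptance suite)
# ---------------------------------------------------------------------------

FST_DRIFT_N = 100
FST_DRIFT_T = 10
FST_DRIFT_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def fst_drift_runs():
    """Weir-Cockerham F_ST from five pure-drift splits (N=100, t=10)."""
    vals = []
    for seed in FST_DRIFT_SEEDS:
        cfg = pk.SimConfig(
            seed=seed, n_chromosomes=10, n_snps_per_chromosome=500,
            ne_schedule=[[0, FST_DRIFT_N]], missing_rate=0.0,
        )
        data, truth = pk.simulate_split_pair(cfg, t_split=FST_DRIFT_T, n_per_pop=50)
        vals.append(pk.pairwise_fst(data, "PPA", "PPB"))
    expected = float(truth.pairs["expected_fst"].iloc[0])
    return np.array(vals), expected


@pytest.fixture(scope="session")
def pedigree_fixture():
    """20 parent-offspring matings plus 20 outbred controls on a
    20 x 100 Mb genome, with the detected per-individual F_ROH table."""
    cfg = pk.SimConfig(
        seed=3, n_chromosomes=20, n_snps_per_chromosome=2500,
        ne_schedule=[[2, 100]], missing_rate=0.0,
    )
    data, truth = pk.plant_inbred_offspring(cfg, count=20, n_controls=20)
    params = pk.ROHParams.from_data(data)
    table = pk.froh_table(data, params)
    return data, truth, params, table


NE_RECOVERY_TRUE = (50, 100, 500)
NE_RECOVERY_SEEDS = (1, 2, 3, 4, 5)


def _recover_ne(n_true: int, seed: int) -> float:
    cfg = pk.SimConfig(
        seed=seed, n_chromosomes=26, n_snps_per_chromosome=300,
        ne_schedule=[[150, n_true]], missing_rate=0.0,
    )
    data, _ = pk.simulate_population(cfg, n_sample=100)
    bins = pk.binned_r2(
        data, "SIM", bin_edges=(0.01, 0.02, 0.035), seed=seed, min_pairs=300
    )
    estimates = [pk.ne_from_bin(b) for b in bins if b.usable]
    return float(np.nanmedian(estimates))


@pytest.fixture(scope="session")
def ne_recovery():
    """Median Ne estimate over 5 replicates for each true constant Ne."""
    out = {}
    for n_true in NE_RECOVERY_TRUE:
        reps = [_recover_ne(n_true, s) for s in NE_RECOVERY_SEEDS]
        out[n_true] = (reps, float(np.median(reps)))
    return out


# ---------------------------------------------------------------------------
# Three-breed pipeline fixture
# ---------------------------------------------------------------------------

def _three_breed_data(seed: int = 11) -> pk.GenotypeMatrix:
    cfg = pk.SimConfig(
        seed=seed, n_chromosomes=6, n_snps_per_chromosome=250,
        ne_schedule=[[20, 60]], missing_rate=0.005,
    )
    pair, _ = pk.simulate_split_pair(cfg, t_split=10, n_per_pop=15)
    solo, _ = pk.simulate_population(cfg, n_sample=15, breed_code="PPC")
    merged, _ = pk.merge_datasets(pair, solo)
    return merged


PIPELINE_CONFIG = {
    "input": {"prefix": "unused"},
    "qc": {"max_snp_missing": 0.10, "max_sample_missing": 0.05},
    "prune": {"window_snps": 50, "step_snps": 5, "r2_threshold": 0.1},
    "roh": {"alpha": 0.05},
    "ne": {"bin_edges": [0.02, 0.05, 0.1, 0.2], "min_pairs": 100},
    "pca": {"n_components": 5},
    "seed": 7,
}


@pytest.fixture(scope="session")
def three_breed_data():
    return _three_breed_data()


@pytest.fixture(scope="session")
def pipeline_bundles(three_breed_data, tmp_path_factory):
    """The same characterization run twice into separate directories."""
    cfg = pk.RunConfig.from_dict(dict(PIPELINE_CONFIG))
    dirs = []
    for tag in ("run1", "run2"):
        bundle = pk.run_characterization(cfg, data=three_breed_data)
        out = tmp_path_factory.mktemp("pipeline") / tag
        pk.write_bundle(bundle, out)
        dirs.append(out)
    return dirs
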