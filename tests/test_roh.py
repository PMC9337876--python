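"""Runs of homozygosity and F_ROH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pramenka as pk
from pramenka.roh import ROHParams, classify_length, covered_genome_bp, segments_to_bed_frame

from conftest import make_matrix
from _oracles import brute_force_roh, random_roh_chromosome


def _markers(pos, chrom=1):
    return pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(len(pos))], "chrom": chrom,
         "pos_bp": np.asarray(pos, dtype=np.int64), "a1": "A", "a2": "B"}
    )


# ---------------------------------------------------------------------------
# Minimum-SNP threshold
# ---------------------------------------------------------------------------

def test_min_snp_threshold_study_inputs():
    """alpha=0.05 over 470,962 SNPs x 211 individuals at het 0.343 -> 50."""
    assert pk.min_snp_threshold(0.05, 470_962, 211, 0.343) == 50


def test_min_snp_threshold_derived_example():
    # floor( ln(0.05/10000) / ln(0.5) ) = floor(17.61) = 17
    assert pk.min_snp_threshold(0.05, 1000, 10, 0.5) == 17


def test_min_snp_threshold_clamps_to_one():
    assert pk.min_snp_threshold(0.999999, 1, 1, 0.5) == 1


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    alpha=st.floats(1e-6, 0.999),
    n_s=st.integers(1, 10**6),
    n_i=st.integers(1, 10**4),
    het=st.floats(0.01, 0.99),
)
def test_min_snp_threshold_positive_and_monotone_in_het(alpha, n_s, n_i, het):
    l1 = pk.min_snp_threshold(alpha, n_s, n_i, het)
    assert l1 >= 1
    # higher heterozygosity makes long all-homozygous runs less likely by
    # chance, so the required SNP count cannot increase
    l2 = pk.min_snp_threshold(alpha, n_s, n_i, min(het + 0.2, 0.995))
    assert l2 <= l1


def test_min_snp_threshold_degenerate_het_rejected():
    with pytest.raises(ValueError):
        pk.min_snp_threshold(0.05, 100, 10, 0.0)
    with pytest.raises(ValueError):
        pk.min_snp_threshold(0.05, 100, 10, 1.0)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _params(l_min=15, **kw):
    return ROHParams(l_min_snps=l_min, **kw)


def test_all_heterozygous_yields_nothing():
    pos = np.arange(1, 101) * 40_000
    g = np.ones(100, dtype=np.int8)
    assert pk.detect_roh(g, _markers(pos), _params()) == []


def test_single_planted_tract_detected_exactly():
    """100 SNPs at 40 kb spacing; SNPs 20..80 homozygous (2.4 Mb span)
    surrounded by heterozygotes -> one segment with those endpoints."""
    pos = np.arange(1, 101) * 40_000
    g = np.ones(100, dtype=np.int8)
    g[20:81] = 2
    segs = pk.detect_roh(g, _markers(pos), _params())
    assert len(segs) == 1
    (seg,) = segs
    assert (seg.start_bp, seg.end_bp) == (pos[20], pos[80])
    assert seg.n_snps == 61
    assert seg.length_class == "2-4Mb"
    # agrees with the exhaustive oracle
    assert brute_force_roh(pos, g, _params()) == [(20, 80)]


def test_oversized_gap_splits_tract_and_pieces_retested():
    """Widening one internal gap beyond 250 kb splits the run; both pieces
    fall under 2 Mb and are rejected."""
    pos = np.arange(1, 101) * 40_000
    pos = pos.copy()
    pos[51:] += 300_000  # gap between SNP 50 and 51 becomes 340 kb
    g = np.ones(100, dtype=np.int8)
    g[20:81] = 2
    segs = pk.detect_roh(g, _markers(pos), _params())
    assert segs == []
    assert brute_force_roh(pos, g, _params()) == []


def test_density_criterion_rejects_sparse_runs():
    pos = np.arange(1, 41) * 60_000  # 1 SNP per 60 kb < 1 per 50 kb
    g = np.full(40, 2, dtype=np.int8)
    assert pk.detect_roh(g, _markers(pos), _params()) == []


def test_het_allowance_grows_with_length_class():
    """A heterozygote inside a 2-4 Mb run disqualifies it (allowance 0),
    but one inside an 8-16 Mb run is tolerated (allowance 2)."""
    p = _params()
    pos_short = np.arange(1, 76) * 40_000   # 3 Mb span available
    g_short = np.full(75, 2, dtype=np.int8)
    g_short[40] = 1
    segs_short = pk.detect_roh(g_short, _markers(pos_short), p)
    assert all(s.n_het == 0 for s in segs_short)

    pos_long = np.arange(1, 251) * 40_000   # 10 Mb span
    g_long = np.full(250, 2, dtype=np.int8)
    g_long[120] = 1
    segs_long = pk.detect_roh(g_long, _markers(pos_long), p)
    assert len(segs_long) == 1
    assert segs_long[0].n_het == 1
    assert segs_long[0].length_class == "8-16Mb"


def test_unsorted_map_rejected():
    pos = np.array([1_000, 500, 2_000])
    g = np.full(3, 2, dtype=np.int8)
    with pytest.raises(pk.DataError):
        pk.detect_roh(g, _markers(pos), _params(l_min=2))


def test_detection_invariant_to_chromosome_labelling():
    """Two chromosomes with swapped labels give the same segments."""
    rng = np.random.default_rng(0)
    pos1, g1 = random_roh_chromosome(rng, 150)
    pos2, g2 = random_roh_chromosome(rng, 150)
    p = _params()

    m12 = pd.concat([_markers(pos1, 1), _markers(pos2, 2)], ignore_index=True)
    m12["snp_id"] = [f"s{j}" for j in range(len(m12))]
    g12 = np.concatenate([g1, g2])
    m21 = pd.concat([_markers(pos2, 1), _markers(pos1, 2)], ignore_index=True)
    m21["snp_id"] = [f"s{j}" for j in range(len(m21))]
    g21 = np.concatenate([g2, g1])

    segs12 = {(s.chromosome, s.start_bp, s.end_bp) for s in pk.detect_roh(g12, m12, p)}
    segs21 = {(3 - s.chromosome, s.start_bp, s.end_bp) for s in pk.detect_roh(g21, m21, p)}
    assert segs12 == segs21


def test_oracle_equivalence_on_random_fixtures():
    """Exhaustive interval enumeration with longest-first selection equals
    the production scan on 100 random chromosomes (up to 2,000 SNPs)."""
    rng = np.random.default_rng(2024)
    sizes = [int(rng.integers(40, 260)) for _ in range(96)] + [1000, 1500, 2000, 2000]
    params = _params()
    for k, n_snps in enumerate(sizes):
        pos, g = random_roh_chromosome(rng, n_snps)
        got = [(s.start_bp, s.end_bp)
               for s in pk.detect_roh(g, _markers(pos), params)]
        want = [(int(pos[i]), int(pos[j])) for i, j in brute_force_roh(pos, g, params)]
        assert got == want, f"fixture {k} (n={n_snps})"


# ---------------------------------------------------------------------------
# F_ROH
# ---------------------------------------------------------------------------

def _segment(start, end, chrom=1, sample="x"):
    return pk.ROHSegment(sample_id=sample, chromosome=chrom, start_bp=start,
                         end_bp=end, n_snps=100, n_het=0, n_missing=0)


def test_froh_no_segments_is_zero():
    markers = _markers(np.array([1, 100_000_000]))
    out = pk.froh([], markers)
    assert all(v == 0.0 for v in out.values())


def test_froh_full_coverage_single_chromosome():
    markers = _markers(np.array([1, 3_000_000]))
    seg = _segment(1, 3_000_000)
    out = pk.froh([seg], markers)
    assert out["froh_total"] == 1.0
    assert out["froh_2_4"] == 1.0


def test_froh_length_class_partition_arithmetic():
    """3 Mb and 10 Mb segments on a 100 Mb covered genome."""
    markers = _markers(np.array([1, 100_000_000]))
    segs = [_segment(1, 3_000_000), _segment(20_000_001, 30_000_000)]
    out = pk.froh(segs, markers)
    assert out["froh_total"] == pytest.approx(0.13)
    assert out["froh_2_4"] == pytest.approx(0.03)
    assert out["froh_8_16"] == pytest.approx(0.10)
    assert out["froh_4_8"] == 0.0 and out["froh_gt16"] == 0.0


def test_froh_classes_additive_for_simulated_individuals(pedigree_fixture):
    _, _, _, table = pedigree_fixture
    total = table[["froh_2_4", "froh_4_8", "froh_8_16", "froh_gt16"]].sum(axis=1)
    assert np.allclose(table["froh_total"], total, atol=1e-12)


def test_covered_genome_ignores_non_autosomes():
    markers = pd.concat(
        [_markers(np.array([1, 1_000_000]), 1), _markers(np.array([1, 9_000_000]), 27)],
        ignore_index=True,
    )
    markers["snp_id"] = [f"s{j}" for j in range(4)]
    assert covered_genome_bp(markers) == 1_000_000


def test_breed_froh_two_point_stats():
    table = pd.DataFrame(
        {"sample_id": ["a", "b"], "breed": ["XXX", "XXX"], "n_segments": [1, 1],
         "froh_total": [0.02, 0.04], "froh_2_4": [0.02, 0.04],
         "froh_4_8": [0.0, 0.0], "froh_8_16": [0.0, 0.0], "froh_gt16": [0.0, 0.0]}
    )
    out = pk.breed_froh(table)
    row = out.iloc[0]
    assert row["froh_total_mean"] == pytest.approx(0.03)
    assert row["froh_total_se"] == pytest.approx(0.01)


def test_breed_froh_identical_individuals_zero_se():
    table = pd.DataFrame(
        {"sample_id": ["a", "b", "c"], "breed": ["YYY"] * 3, "n_segments": [0] * 3,
         "froh_total": [0.05] * 3, "froh_2_4": [0.05] * 3,
         "froh_4_8": [0.0] * 3, "froh_8_16": [0.0] * 3, "froh_gt16": [0.0] * 3}
    )
    assert pk.breed_froh(table).iloc[0]["froh_total_se"] == pytest.approx(0.0, abs=1e-15)


# ---------------------------------------------------------------------------
# Pedigree recovery (simulation truth)
# ---------------------------------------------------------------------------

def test_inbred_offspring_froh_recovers_pedigree_f(pedigree_fixture):
    """Parent-offspring matings: mean F_ROH>2Mb within 0.05 of F = 0.25."""
    _, truth, _, table = pedigree_fixture
    inb = table[table["breed"] == "INB"]
    assert len(inb) == 20
    assert abs(inb["froh_total"].mean() - 0.25) < 0.05


def test_outbred_controls_nearly_roh_free(pedigree_fixture):
    _, _, _, table = pedigree_fixture
    ctl = table[table["breed"] == "CTL"]
    assert ctl["froh_total"].mean() < 0.02


def test_inbred_offspring_carry_long_roh(pedigree_fixture):
    """At least one segment of 8 Mb or more in >90% of flagged individuals."""
    data, _, params, _ = pedigree_fixture
    inb_idx = data.breed_index("INB")
    with_long = 0
    for i in inb_idx:
        segs = pk.detect_roh(data.genotypes[i], data.markers, params)
        if any(s.length_bp >= 8_000_000 for s in segs):
            with_long += 1
    assert with_long / len(inb_idx) > 0.9


def test_bed_export_is_zero_based_half_open():
    frame = segments_to_bed_frame([_segment(1_000_001, 3_000_000)])
    assert frame.loc[0, "start"] == 1_000_000
    assert frame.loc[0, "end"] == 3_000_000
    assert frame.loc[0, "length_bp"] == 2_000_000


def test_classify_length_half_open_edges():
    mb = 1_000_000
    assert classify_length(2 * mb) == "2-4Mb"
    assert classify_length(4 * mb) == "4-8Mb"
    assert classify_length(16 * mb) == ">16Mb"
    assert classify_length(2 * mb - 1) is None
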