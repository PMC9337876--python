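"""PLINK I/O, QC, merging, and LD pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pramenka as pk
from pramenka.genio import MISSING, r2_matrix

from conftest import make_matrix
from _oracles import greedy_ld_prune_oracle


# ---------------------------------------------------------------------------
# Binary codec
# ---------------------------------------------------------------------------

def test_bed_bytes_decode_hand_crafted(tmp_path):
    """A hand-packed 2-sample x 3-SNP .bed decodes per the two-bit spec:
    00 hom a1, 10 het, 11 hom a2, 01 missing (LSB pair = first sample)."""
    prefix = tmp_path / "hand"
    # SNP1: s1=00 (0), s2=10 (1) -> byte 0b1000
    # SNP2: s1=11 (2), s2=01 (missing) -> byte 0b0111
    # SNP3: s1=01 (missing), s2=00 (0) -> byte 0b0001
    (tmp_path / "hand.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b1000, 0b0111, 0b0001]))
    (tmp_path / "hand.bim").write_text("1\ts1\t0\t100\tA\tB\n1\ts2\t0\t200\tA\tB\n1\ts3\t0\t300\tA\tB\n")
    (tmp_path / "hand.fam").write_text("TOY\ti1\t0\t0\t1\t-9\nTOY\ti2\t0\t0\t2\t-9\n")
    data = pk.read_plink(prefix)
    assert np.array_equal(data.genotypes, np.array([[0, 2, -1], [1, -1, 0]], dtype=np.int8))
    assert list(data.samples["sex"]) == ["male", "female"]


def test_write_encodes_missing_as_01_bit_pair(tmp_path):
    data = make_matrix([[MISSING, 2], [1, 0]])
    pk.write_plink(data, tmp_path / "m")
    raw = (tmp_path / "m.bed").read_bytes()
    assert raw[:3] == bytes([0x6C, 0x1B, 0x01])
    # SNP1: s1 missing (01), s2 het (10) -> 0b1001; SNP2: s1 hom a2 (11), s2 hom a1 (00)
    assert raw[3] == 0b1001
    assert raw[4] == 0b0011


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    n=st.integers(1, 9),
    m=st.integers(0, 12),
    seed=st.integers(0, 10_000),
)
def test_roundtrip_identity_random(tmp_path_factory, n, m, seed):
    """write_plink then read_plink reproduces matrix, map, and table exactly,
    including the 0-SNP degenerate case."""
    rng = np.random.default_rng(seed)
    g = rng.choice([-1, 0, 1, 2], size=(n, m), p=[0.05, 0.4, 0.3, 0.25])
    data = make_matrix(g)
    prefix = tmp_path_factory.mktemp("rt") / "fix"
    pk.write_plink(data, prefix)
    back = pk.read_plink(prefix)
    assert back.equals(data)


def test_empty_dataset_roundtrip(tmp_path):
    data = make_matrix(np.zeros((3, 0), dtype=np.int8))
    pk.write_plink(data, tmp_path / "empty")
    assert (tmp_path / "empty.bed").read_bytes() == bytes([0x6C, 0x1B, 0x01])
    assert (tmp_path / "empty.bim").read_text() == ""
    assert pk.read_plink(tmp_path / "empty").n_snps == 0


def test_ped_map_text_roundtrip(tmp_path):
    g = np.array([[0, 1, 2], [2, -1, 1], [1, 0, 0]], dtype=np.int8)
    data = make_matrix(g)
    pk.write_plink_text(data, tmp_path / "txt")
    back = pk.read_plink_text(tmp_path / "txt")
    # a1 is re-derived as the minor allele, so compare allele counts of the
    # major allele which is invariant under that relabeling
    assert back.n_samples == 3 and back.n_snps == 3
    for j in range(3):
        orig = g[:, j]
        got = back.genotypes[:, j]
        assert np.array_equal(got == MISSING, orig == MISSING)
        obs = orig != MISSING
        assert (np.array_equal(got[obs], orig[obs])
                or np.array_equal(got[obs], 2 - orig[obs]))


@pytest.mark.parametrize(
    "breakage, err",
    [
        ("missing_file", pk.PlinkFileMissingError),
        ("bad_magic", pk.PlinkMagicError),
        ("bad_dims", pk.PlinkDimensionError),
    ],
)
def test_read_errors_are_distinct(tmp_path, breakage, err):
    data = make_matrix(np.zeros((3, 4), dtype=np.int8))
    pk.write_plink(data, tmp_path / "x")
    if breakage == "missing_file":
        (tmp_path / "x.fam").unlink()
    elif breakage == "bad_magic":
        raw = bytearray((tmp_path / "x.bed").read_bytes())
        raw[0] = 0x00
        (tmp_path / "x.bed").write_bytes(bytes(raw))
    else:
        (tmp_path / "x.bed").write_bytes((tmp_path / "x.bed").read_bytes() + b"\x00")
    with pytest.raises(err):
        pk.read_plink(tmp_path / "x")


def test_sidecar_overrides_breed(tmp_path):
    data = make_matrix(np.zeros((2, 2), dtype=np.int8), breeds=["AAA", "AAA"])
    pk.write_plink(data, tmp_path / "s")
    (tmp_path / "s.samples.tsv").write_text(
        "sample_id\tbreed_code\tgroup\ni0\tISS\tisland\ni1\tDPS\tmainland\n"
    )
    back = pk.read_plink(tmp_path / "s")
    assert list(back.samples["breed"]) == ["ISS", "DPS"]
    assert list(back.samples["group"]) == ["island", "mainland"]


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

def test_self_merge_doubles_samples_keeps_snps():
    g = np.array([[0, 1, 2], [2, 1, 0]], dtype=np.int8)
    a = make_matrix(g, sample_ids=["a1", "a2"])
    b = make_matrix(g, sample_ids=["b1", "b2"])
    merged, report = pk.merge_datasets(a, b)
    assert merged.n_samples == 4
    assert set(merged.markers["snp_id"]) == set(a.markers["snp_id"])
    assert report.n_flipped == 0


def test_merge_intersects_marker_sets():
    a = make_matrix(np.zeros((2, 3), dtype=np.int8))
    b_markers = pd.DataFrame(
        {"snp_id": ["s1", "s2", "s9"], "chrom": 1, "pos_bp": [2000, 3000, 9000],
         "a1": "A", "a2": "B"}
    )
    b = pk.GenotypeMatrix(
        np.zeros((2, 3), dtype=np.int8), b_markers,
        pd.DataFrame({"sample_id": ["b1", "b2"], "breed": "TOY"}),
    )
    merged, _ = pk.merge_datasets(a, b)
    assert sorted(merged.markers["snp_id"]) == ["s1", "s2"]


def test_merge_recodes_swapped_alleles():
    """If b's a1/a2 are swapped at a SNP, b's codes there become 2-g."""
    a = make_matrix(np.array([[0, 0], [2, 2]], dtype=np.int8))
    b_markers = a.markers.copy()
    b_markers.loc[1, ["a1", "a2"]] = ["B", "A"]  # swap at SNP s1
    b = pk.GenotypeMatrix(
        np.array([[0, 0], [2, MISSING]], dtype=np.int8), b_markers,
        pd.DataFrame({"sample_id": ["b1", "b2"], "breed": "TOY"}),
    )
    merged, report = pk.merge_datasets(a, b)
    assert report.n_flipped == 1
    col = merged.markers["snp_id"].tolist().index("s1")
    got = merged.genotypes[2:, col]
    assert list(got) == [2, MISSING]  # 2-0 = 2; missing untouched


def test_merge_drops_conflicting_and_ambiguous():
    a = make_matrix(np.zeros((2, 3), dtype=np.int8))  # all A/B alleles
    b_markers = a.markers.copy()
    b_markers.loc[0, ["a1", "a2"]] = ["C", "G"]  # conflict with A/B
    b = pk.GenotypeMatrix(
        np.zeros((2, 3), dtype=np.int8), b_markers,
        pd.DataFrame({"sample_id": ["b1", "b2"], "breed": "TOY"}),
    )
    merged, report = pk.merge_datasets(a, b)
    assert report.dropped_conflict == ["s0"]
    assert merged.n_snps == 2


def test_merge_duplicate_samples_rejected():
    a = make_matrix(np.zeros((2, 2), dtype=np.int8))
    with pytest.raises(pk.MergeError):
        pk.merge_datasets(a, a)


def test_merge_marker_content_symmetric():
    rng = np.random.default_rng(5)
    a = make_matrix(rng.choice([0, 1, 2], size=(3, 5)))
    b_markers = a.markers.iloc[1:4].reset_index(drop=True)
    b = pk.GenotypeMatrix(
        rng.choice([0, 1, 2], size=(3, 3)).astype(np.int8), b_markers,
        pd.DataFrame({"sample_id": ["b0", "b1", "b2"], "breed": "TOY"}),
    )
    ab, _ = pk.merge_datasets(a, b)
    ba, _ = pk.merge_datasets(b, a)
    assert list(ab.markers["snp_id"]) == list(ba.markers["snp_id"])


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def test_qc_noop_on_complete_data():
    data = make_matrix(np.ones((4, 5), dtype=np.int8))
    out, report = pk.qc_filter(data)
    assert out.equals(data)
    assert report.n_snps_missingness == 0
    assert report.n_samples_missingness == 0


def test_qc_cascade_snp_then_sample():
    """SNP filter first, then samples re-evaluated on surviving SNPs:
    a 25%-missing SNP is dropped; two samples whose remaining missingness
    (1 of 4 SNPs = 25%) exceeds 5% are then dropped."""
    g = np.ones((20, 5), dtype=np.int8)
    g[:5, 0] = MISSING                  # SNP 0: 25% missing -> removed
    g[0, 1] = MISSING                   # sample 0: 2/5 = 40% before QC
    g[1, 1] = MISSING                   # SNP 1: 2/20 = 10%, kept (rule is >10%)
    data = make_matrix(g)
    out, report = pk.qc_filter(data)
    assert report.n_snps_missingness == 1
    assert report.n_samples_missingness == 2
    assert out.n_snps == 4 and out.n_samples == 18
    assert "i0" not in list(out.samples["sample_id"])


def test_qc_removes_non_autosomes():
    data = make_matrix(np.ones((3, 3), dtype=np.int8), chrom=[1, 27, 26])
    out, report = pk.qc_filter(data)
    assert report.n_snps_nonautosomal == 1
    assert list(out.markers["chrom"]) == [1, 26]
    all_chrom, _ = pk.qc_filter(data, autosomes_only=False)
    assert all_chrom.n_snps == 3


def test_qc_idempotent():
    rng = np.random.default_rng(17)
    g = rng.choice([-1, 0, 1, 2], size=(30, 40), p=[0.04, 0.32, 0.32, 0.32])
    data = make_matrix(g)
    once, _ = pk.qc_filter(data)
    twice, report = pk.qc_filter(once)
    assert twice.equals(once)
    assert report.n_snps_missingness == 0 and report.n_samples_missingness == 0


def test_qc_all_removed_is_error():
    data = make_matrix(np.full((3, 3), MISSING))
    with pytest.raises(pk.QCError):
        pk.qc_filter(data)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_prune_keeps_independent_snps():
    rng = np.random.default_rng(42)
    g = rng.binomial(2, 0.5, size=(200, 10)).astype(np.int8)
    data = make_matrix(g)
    pruned = pk.ld_prune(data)
    assert pruned.n_snps == 10


def test_prune_removes_one_of_duplicated_column():
    rng = np.random.default_rng(1)
    col = rng.binomial(2, 0.4, size=60).astype(np.int8)
    g = np.column_stack([col, rng.binomial(2, 0.5, size=60), col]).astype(np.int8)
    data = make_matrix(g)
    pruned = pk.ld_prune(data)
    assert pruned.n_snps == 2
    # the larger-index duplicate goes (equal missingness tie-break)
    assert list(pruned.markers["snp_id"]) == ["s0", "s1"]


def test_prune_matches_greedy_oracle_single_window():
    """6-SNP matrix with a mix of correlated and independent columns."""
    rng = np.random.default_rng(7)
    base = rng.binomial(2, 0.5, size=(80, 2)).astype(np.int8)
    noisy = base[:, 0].copy()
    noisy[:8] = 2 - noisy[:8]           # strong but imperfect LD with col 0
    g = np.column_stack([
        base[:, 0], noisy, rng.binomial(2, 0.5, 80),
        base[:, 1], np.clip(base[:, 1] + rng.binomial(1, 0.1, 80) - 0, 0, 2),
        rng.binomial(2, 0.5, 80),
    ]).astype(np.int8)
    data = make_matrix(g)
    expected = greedy_ld_prune_oracle(g, 0.1)
    pruned = pk.ld_prune(data, window_snps=6, step_snps=3)
    got = [int(s[1:]) for s in pruned.markers["snp_id"]]
    assert got == expected


def test_prune_never_compares_across_chromosomes():
    rng = np.random.default_rng(3)
    col = rng.binomial(2, 0.5, size=50).astype(np.int8)
    g = np.column_stack([col, col]).astype(np.int8)  # r2=1 but different chrom
    data = make_matrix(g, chrom=[1, 2], pos=[1000, 1000])
    assert pk.ld_prune(data).n_snps == 2


def test_prune_window_smaller_than_step_rejected():
    data = make_matrix(np.zeros((12, 4), dtype=np.int8))
    with pytest.raises(ValueError):
        pk.ld_prune(data, window_snps=2, step_snps=5)


def test_pruned_output_has_no_high_r2_pair_within_window():
    """Exhaustive re-check of the output invariant on a simulated dataset."""
    cfg = pk.SimConfig(seed=21, n_chromosomes=2, n_snps_per_chromosome=150,
                       ne_schedule=[[30, 40]], missing_rate=0.01)
    data, _ = pk.simulate_population(cfg, n_sample=40)
    data = data.sort_markers()
    pruned = pk.ld_prune(data, window_snps=50, step_snps=5)
    kept = data.markers["snp_id"].isin(set(pruned.markers["snp_id"])).to_numpy()
    chrom = data.markers["chrom"].to_numpy()
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        for start in range(0, len(idx), 5):
            window = idx[start:start + 50]
            window = window[kept[window]]
            if len(window) < 2:
                continue
            r2 = r2_matrix(data.genotypes, window)
            assert np.nanmax(np.where(np.isnan(r2), 0, r2)) <= 0.1 + 1e-12
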