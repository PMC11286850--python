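"""caRNA feature engineering: MAPQ filter, tracks, groups, proportions."""

import numpy as np
import pandas as pd
import pytest

from carnafold import carna, pairs as pairsio
from carnafold.carna import GeneModel, RnaDnaContacts
from carnafold.mapsio import BinGrid


def _contacts(rows):
    df = pd.DataFrame(rows, columns=["rna_chrom", "rna_pos", "rna_strand",
                                     "dna_chrom", "dna_pos", "dna_strand", "mapq"])
    return RnaDnaContacts(df)


def _write_pairs(tmp_path, rows):
    df = pd.DataFrame(rows, columns=["readID", "chrom1", "pos1", "chrom2",
                                     "pos2", "strand1", "strand2", "mapq1", "mapq2"])
    path = tmp_path / "t.pairs"
    pairsio.write_pairs(path, df, {"chr1": 2**17, "chr2": 2**17})
    return path


# ---------------------------------------------------------------------------
# parsing + MAPQ
# ---------------------------------------------------------------------------

def test_mapq_30_dropped_31_retained(tmp_path):
    path = _write_pairs(tmp_path, [
        ("r1", "chr1", 10, "chr1", 20, "+", "+", 30, 60),
        ("r2", "chr1", 10, "chr1", 20, "+", "+", 31, 60),
        ("r3", "chr1", 10, "chr1", 20, "+", "+", 60, 29),
    ])
    c = carna.parse_rna_dna_pairs(path)
    assert len(c) == 1
    assert c.n_dropped_mapq == 2
    assert c.records["mapq"].iloc[0] == 31


def test_retained_count_matches_truth_table(contacts, rna_dna_fixture):
    _, truth = rna_dna_fixture
    assert len(contacts) == int(truth["mapq_pass"].sum())


def test_missing_columns_rejected(tmp_path):
    path = tmp_path / "bad.pairs"
    path.write_text("## pairs format v1.0\n#columns: readID chrom1 pos1\nr1\tchr1\t5\n")
    with pytest.raises(ValueError, match="required"):
        carna.parse_rna_dna_pairs(path)


# ---------------------------------------------------------------------------
# nascent track
# ---------------------------------------------------------------------------

def test_nascent_track_counts_rna_ends():
    c = _contacts([("chr1", 100 + i, "+", "chr2", 50_000, "+", 60)
                   for i in range(5)])
    grid = BinGrid({"chr1": 2**17, "chr2": 2**17}, 2048)
    t = carna.nascent_track(c, grid)
    assert t[0] == 5
    assert t.sum() == 5


def test_nascent_track_coarse_equals_block_sum_of_fine(contacts, grid):
    fine = carna.nascent_track(contacts, grid, resolution=256)
    coarse = carna.nascent_track(contacts, grid, resolution=2048)
    # chromosome bin counts are exact multiples here, so block-sum is exact
    assert np.allclose(fine.reshape(-1, 8).sum(axis=1), coarse)


def test_nascent_track_empty():
    c = _contacts([])
    grid = BinGrid({"chr1": 2**17}, 2048)
    assert carna.nascent_track(c, grid).sum() == 0


# ---------------------------------------------------------------------------
# trans filter
# ---------------------------------------------------------------------------

def test_trans_filter_rules():
    c = _contacts([
        ("chr1", 100, "+", "chr1", 500_000, "+", 60),    # <= 2**20 apart: cis
        ("chr1", 100, "+", "chr2", 100, "+", 60),        # inter-chrom: trans
        ("chr1", 100, "+", "chr1", 100 + 2**20 + 1, "+", 60),  # > 2**20: trans
    ])
    out = carna.trans_filter(c)
    assert len(out) == 2
    assert (out.records["dna_chrom"] == "chr2").sum() == 1


def test_long_gene_self_interaction_removed():
    genes = GeneModel.from_table(pd.DataFrame({
        "gene_id": ["big"], "chrom": ["chr1"], "start": [0], "end": [2_200_000],
        "strand": ["+"], "biotype": ["protein_coding"]}))
    c = _contacts([
        ("chr1", 100_000, "+", "chr1", 1_700_000, "+", 60),   # both inside big
        ("chr1", 100_000, "+", "chr1", 2_500_000, "+", 60),   # DNA end outside
    ])
    out = carna.trans_filter(c, genes)
    assert len(out) == 1
    assert out.records["dna_pos"].iloc[0] == 2_500_000


def test_trans_filter_idempotent(contacts, genes):
    once = carna.trans_filter(contacts, genes)
    twice = carna.trans_filter(once, genes)
    assert len(once) == len(twice)
    assert once.records.equals(twice.records)


# ---------------------------------------------------------------------------
# group classification + tracks
# ---------------------------------------------------------------------------

def test_classify_inside_snoRNA_gene(genes):
    sno = genes.table[genes.table["group"] == "snoRNA"].iloc[0]
    label = carna.classify_rna_group(sno["chrom"], sno["start"] + 5, genes)
    assert label == "snoRNA"


def test_classify_intergenic_is_unannotated(genes):
    assert carna.classify_rna_group("chr1", 2**17 - 10, genes) == "unannotated"


def test_nested_snoRNA_beats_protein_coding_host():
    genes = GeneModel.from_table(pd.DataFrame({
        "gene_id": ["host", "sno"],
        "chrom": ["chr1", "chr1"],
        "start": [1000, 5000], "end": [20_000, 5200],
        "strand": ["+", "+"],
        "biotype": ["protein_coding", "snoRNA"]}))
    assert carna.classify_rna_group("chr1", 5100, genes) == "snoRNA"
    assert carna.classify_rna_group("chr1", 1500, genes) == "protein_coding"


def test_group_tracks_conservation(contacts, genes, grid):
    tc = carna.trans_filter(contacts, genes)
    tracks = carna.group_tracks(tc, genes, grid)
    assert set(tracks) == set(carna.RNA_GROUPS)
    assert sum(t.sum() for t in tracks.values()) == len(tc)


def test_group_tracks_log_zero_is_zero(genes, grid):
    empty = _contacts([])
    tracks = carna.group_tracks(empty, genes, grid, log=True)
    assert all((t == 0).all() for t in tracks.values())


def test_single_lncRNA_counts_land_in_lncRNA_track(genes, grid):
    lnc = genes.table[genes.table["group"] == "lncRNA"].iloc[0]
    c = _contacts([(lnc["chrom"], lnc["start"] + 1, "+", "chr2", 4096 + i, "+", 60)
                   for i in range(10)])
    tracks = carna.group_tracks(c, genes, grid)
    target_bin = grid.bin_index("chr2", 4096)
    assert tracks["lncRNA"][target_bin] >= 9  # all ten land in 1-2 bins
    assert sum(t.sum() for t in tracks.values()) == 10


# ---------------------------------------------------------------------------
# external signals
# ---------------------------------------------------------------------------

def test_constant_track_gives_constant_feature():
    grid = BinGrid({"chr1": 2**14}, 2048)
    track = np.full(grid.n_bins, 3.0)
    f = carna.external_signal_features(track, grid, libsize=1000)
    assert np.allclose(f, f[0])


def test_doubling_libsize_adds_log2_for_large_signals():
    grid = BinGrid({"chr1": 2**14}, 2048)
    track = np.full(grid.n_bins, 1e9)
    f1 = carna.external_signal_features(track, grid, libsize=10_000_000)
    f2 = carna.external_signal_features(track, grid, libsize=20_000_000)
    assert np.allclose(f2 - f1, np.log(2), atol=1e-6)


def test_empty_track_gives_zero_feature():
    grid = BinGrid({"chr1": 2**14}, 2048)
    f = carna.external_signal_features(np.zeros(grid.n_bins), grid, libsize=100)
    assert (f == 0).all()


# ---------------------------------------------------------------------------
# trans proportions
# ---------------------------------------------------------------------------

def _gene_model_simple():
    return GeneModel.from_table(pd.DataFrame({
        "gene_id": ["g1"], "chrom": ["chr1"], "start": [1000], "end": [2000],
        "strand": ["+"], "biotype": ["lncRNA"]}))


def test_proportion_simple_arithmetic():
    genes = _gene_model_simple()
    rows = [("chr1", 1500, "+", "chr1", 1500 + 10_000, "+", 60)] * 6 + \
           [("chr1", 1500, "+", "chr2", 99, "+", 60)] * 4
    tp = carna.trans_proportion(_contacts(rows), genes)
    row = tp.set_index("gene_id").loc["g1"]
    assert row["nascent_reads"] == 10
    assert row["trans_reads"] == 4
    assert row["proportion"] == pytest.approx(0.4)


def test_host_subtraction_for_nested_gene():
    genes = GeneModel.from_table(pd.DataFrame({
        "gene_id": ["host", "sno"],
        "chrom": ["chr1", "chr1"],
        "start": [1000, 5000], "end": [20_000, 5200],
        "strand": ["+", "+"],
        "biotype": ["protein_coding", "snoRNA"]}))
    rows = [("chr1", 2000, "+", "chr2", 1, "+", 60)] * 7 + \
           [("chr1", 5100, "+", "chr2", 1, "+", 60)] * 5
    tp = carna.trans_proportion(_contacts(rows), genes).set_index("gene_id")
    assert tp.loc["host", "nascent_reads"] == 7
    assert tp.loc["sno", "nascent_reads"] == 5


def test_zero_read_gene_flagged_undefined():
    genes = _gene_model_simple()
    tp = carna.trans_proportion(_contacts([]), genes).set_index("gene_id")
    assert tp.loc["g1", "nascent_reads"] == 0
    assert tp.loc["g1", "proportion"] is None


# ---------------------------------------------------------------------------
# signal matrices
# ---------------------------------------------------------------------------

def test_signal_matrix_constant_track():
    grid = BinGrid({"chr1": 2**15}, 2048)
    track = np.full(grid.n_bins, 2.0)
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [12_000], "end": [14_000]})
    m = carna.signal_matrix(track, grid, regions, flank=4096, resolution=1024)
    assert np.allclose(m, 2.0)


def test_signal_matrix_delta_at_center():
    grid = BinGrid({"chr1": 2**15}, 2048)
    track = np.zeros(grid.n_bins)
    center_bin = grid.bin_index("chr1", 13_000)
    track[center_bin] = 5.0
    regions = pd.DataFrame({"chrom": ["chr1"],
                            "start": [center_bin * 2048],
                            "end": [(center_bin + 1) * 2048]})
    m = carna.signal_matrix(track, grid, regions, flank=3072, resolution=2048)
    # 3 columns; the middle one covers exactly the delta bin
    assert m.shape == (1, 3)
    assert m[0, 1] == pytest.approx(5.0)
    assert m[0, 0] == pytest.approx(0.0)
    assert m[0, 2] == pytest.approx(0.0)


def test_signal_matrix_matches_brute_force(rng):
    grid = BinGrid({"chr1": 2**15}, 2048)
    track = rng.random(grid.n_bins)
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [10_000]})
    res, flank = 512, 2048
    m = carna.signal_matrix(track, grid, regions, flank=flank, resolution=res)
    center = 10_000
    for col in range(m.shape[1]):
        lo = center - flank + col * res
        vals = [track[grid.bin_index("chr1", p)] for p in range(lo, lo + res)]
        assert m[0, col] == pytest.approx(np.mean(vals))


def test_signal_matrix_edge_padded_with_nan():
    grid = BinGrid({"chr1": 2**15}, 2048)
    track = np.ones(grid.n_bins)
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [0]})
    m = carna.signal_matrix(track, grid, regions, flank=4096, resolution=2048)
    assert np.isnan(m[0, 0])
    assert m[0, -1] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# feature assembly variants
# ---------------------------------------------------------------------------

def test_build_feature_matrices_variants(contacts, genes, grid, genome, tmp_path):
    from carnafold import synthio
    windows = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2**17],
                            "split": ["train"]})
    atac, _ = synthio.make_signal_tracks(genome, tmp_path)
    trans = carna.build_feature_matrices("trans", grid, windows,
                                         contacts=contacts, genes=genes)
    assert trans[0].matrix.shape == (64, 8)
    assert trans[0].channels == carna.RNA_GROUPS
    nasc = carna.build_feature_matrices("nascent", grid, windows,
                                        contacts=contacts)
    assert nasc[0].matrix.shape == (64, 1)
    seq = carna.build_feature_matrices("seq", grid, windows)
    assert seq[0].matrix.shape == (64, 0)
    at = carna.build_feature_matrices("atac", grid, windows, contacts=contacts,
                                      atac=atac)
    assert at[0].matrix.shape == (64, 1)
    assert np.isfinite(at[0].matrix).all()


def test_random_variant_is_seeded_standard_normal(grid):
    windows = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2**17]})
    a = carna.build_feature_matrices("random", grid, windows, seed=5)
    b = carna.build_feature_matrices("random", grid, windows, seed=5)
    c = carna.build_feature_matrices("random", grid, windows, seed=6)
    assert np.array_equal(a[0].matrix, b[0].matrix)
    assert not np.array_equal(a[0].matrix, c[0].matrix)
    assert a[0].matrix.shape == (64, 8)
    assert abs(a[0].matrix.mean()) < 0.2  # standard normal draws
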