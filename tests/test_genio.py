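"""Genotype I/O, marker filtering, gene windows and SNP-set construction."""
import numpy as np
import pandas as pd
import pytest

import pathblup as pb
from pathblup import genio

from conftest import make_geno


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def test_tsv_round_trip(tmp_path):
    g = make_geno([[0, 2], [2, 0], [0, 0]])  # minor-coded columns round-trip
    genio.write_genotypes_tsv(g, tmp_path / "g.tsv", tmp_path / "m.tsv")
    g2 = genio.load_genotypes(tmp_path / "g.tsv", fmt="tsv",
                              marker_map=tmp_path / "m.tsv")
    assert np.array_equal(g.A, g2.A)
    assert g.line_ids == g2.line_ids
    assert list(g.marker_ids) == list(g2.marker_ids)
    assert np.array_equal(g.pos, g2.pos)


def test_vcf_round_trip_and_het_call(tmp_path):
    path = tmp_path / "x.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
        "2L\t100\ts1\tA\tT\t.\t.\t.\tGT\t0/1\t0/0\t0/0\n")
    g = genio.load_genotypes(path)
    assert g.A.tolist() == [[1.0], [0.0], [0.0]]  # heterozygote counts one


def test_multiallelic_records_skipped(tmp_path):
    path = tmp_path / "x.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
        "2L\t100\ts1\tA\tT,C\t.\t.\t.\tGT\t0/1\t0/0\n"
        "2L\t200\ts2\tA\tT\t.\t.\t.\tGT\t1/1\t0/0\n")
    g = genio.load_genotypes(path)
    assert g.n_markers == 1
    assert g.pos.tolist() == [200]


def test_minor_allele_orientation_flips(tmp_path):
    """ALT counts [2,2,0] have ALT frequency 2/3, so coding flips to [0,0,2]
    and the reported frequency is the minor allele's 1/3."""
    g = make_geno([[2], [2], [0]])
    genio.write_vcf(g, tmp_path / "g.vcf")
    loaded = genio.load_genotypes(tmp_path / "g.vcf")
    assert loaded.A[:, 0].tolist() == [0.0, 0.0, 2.0]
    assert loaded.maf[0] == pytest.approx(1 / 3)


def test_unsorted_input_is_genome_sorted():
    g = make_geno([[0, 2, 0], [2, 0, 2]],
                  chrom=np.array(["2R", "2L", "2L"], dtype=object),
                  pos=np.array([100, 300, 100]))
    s = g.genome_sorted()
    assert s.chrom.tolist() == ["2L", "2L", "2R"]
    assert s.pos.tolist() == [100, 300, 100]
    assert s.A[0].tolist() == [0.0, 2.0, 0.0]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _filter_fixture():
    """25 lines, 10 markers: 3 monomorphic, 1 below the MAF cut, 6 clean."""
    n = 25
    A = np.zeros((n, 10))
    A[:, 0] = 2                       # monomorphic (all 2)
    A[:, 1] = 0                       # monomorphic (all 0)
    A[:, 2] = 2                       # monomorphic (all 2)
    A[0, 3] = 2                       # p = 1/25 = 0.04 <= 0.05 -> dropped
    for j in range(4, 10):            # p = 5/25 = 0.2 -> kept
        A[:5, j] = 2
    return make_geno(A)


def test_monomorphic_and_low_maf_markers_removed():
    out = pb.filter_markers(_filter_fixture(), maf_min=0.05)
    assert out.n_markers == 6
    assert (out.maf > 0.05).all()


def test_maf_zero_removes_only_monomorphic():
    out = pb.filter_markers(_filter_fixture(), maf_min=0.0)
    assert out.n_markers == 7


def test_filtering_is_idempotent():
    once = pb.filter_markers(_filter_fixture(), maf_min=0.05)
    twice = pb.filter_markers(once, maf_min=0.05)
    assert np.array_equal(once.A, twice.A)


def test_all_markers_removed_is_an_error():
    g = make_geno(np.full((4, 3), 2.0))
    with pytest.raises(ValueError, match="all markers removed"):
        pb.filter_markers(g)


# ---------------------------------------------------------------------------
# gene windows
# ---------------------------------------------------------------------------

def test_gene_window_boundary_is_inclusive():
    g = make_geno([[0, 0], [2, 2]], pos=np.array([7000, 7001]))
    genes = pd.DataFrame({"gene_id": ["gA"], "chrom": ["2L"],
                          "start": [1000], "end": [2000]})
    gm = pb.map_snps_to_genes(g, genes, window_bp=5000)
    assert gm["gA"].tolist() == [0]   # 7000 in, 7001 out


def test_marker_in_overlapping_genes_maps_to_both():
    g = make_geno([[0], [2]], pos=np.array([1500]))
    genes = pd.DataFrame({"gene_id": ["gA", "gB"], "chrom": ["2L", "2L"],
                          "start": [1000, 1400], "end": [2000, 2400]})
    gm = pb.map_snps_to_genes(g, genes, window_bp=0)
    assert gm["gA"].tolist() == [0]
    assert gm["gB"].tolist() == [0]


def test_chromosome_name_mismatch_errors():
    g = make_geno([[0], [2]])
    genes = pd.DataFrame({"gene_id": ["gA"], "chrom": ["chr2L"],
                          "start": [1], "end": [10]})
    with pytest.raises(ValueError, match="chr2L"):
        pb.map_snps_to_genes(g, genes)


def test_bed_round_trip_preserves_coordinates(tmp_path):
    genes = pd.DataFrame({"gene_id": ["gA", "gB"], "chrom": ["2L", "3R"],
                          "start": [101, 501], "end": [200, 700]})
    genio.write_genes_bed(genes, tmp_path / "g.bed")
    loaded = genio.load_genes_bed(tmp_path / "g.bed")
    pd.testing.assert_frame_equal(
        loaded[["gene_id", "chrom", "start", "end"]],
        genes[["gene_id", "chrom", "start", "end"]])


# ---------------------------------------------------------------------------
# SNP-set construction
# ---------------------------------------------------------------------------

def _go_rows(go_id, genes, go_class="BP"):
    return [(g, go_id, go_class) for g in genes]


def test_set_size_thresholds_are_strict():
    """Exactly 10 genes is too few; 11 genes with 199 markers is too few;
    200 markers is enough."""
    gene_map = {}
    rows = []
    # small: 10 genes x 30 markers = 300 markers but only 10 genes -> dropped
    for i in range(10):
        gid = f"s{i}"
        gene_map[gid] = np.arange(i * 30, (i + 1) * 30)
        rows += _go_rows("GO:SMALL", [gid])
    # sparse: 11 genes all sharing the same 199 markers -> dropped on markers
    for i in range(11):
        gid = f"p{i}"
        gene_map[gid] = np.arange(1000, 1199)
        rows += _go_rows("GO:SPARSE", [gid])
    # ok: 11 genes, union exactly 200 markers (last gene duplicates the first)
    for i in range(10):
        gid = f"k{i}"
        gene_map[gid] = np.arange(2000 + i * 20, 2000 + (i + 1) * 20)
        rows += _go_rows("GO:OK", [gid])
    gene_map["k10"] = gene_map["k0"]
    rows += _go_rows("GO:OK", ["k10"])
    go = pd.DataFrame(rows, columns=["gene_id", "go_id", "go_class"])
    cat = pb.build_snpsets(gene_map, go, min_genes=11, min_markers=200)
    assert set(cat.sets) == {"GO:OK"}
    assert cat["GO:OK"].n_genes == 11
    assert cat["GO:OK"].n_markers == 200


def test_shared_markers_counted_once():
    gene_map = {"gA": np.arange(0, 10), "gB": np.arange(5, 15)}
    go = pd.DataFrame(_go_rows("GO:X", ["gA", "gB"]),
                      columns=["gene_id", "go_id", "go_class"])
    cat = pb.build_snpsets(gene_map, go, min_genes=2, min_markers=1)
    assert cat["GO:X"].n_markers == 15


def test_unknown_gene_ids_ignored():
    gene_map = {"gA": np.arange(5)}
    go = pd.DataFrame(_go_rows("GO:X", ["gA", "ghost"]),
                      columns=["gene_id", "go_id", "go_class"])
    cat = pb.build_snpsets(gene_map, go, min_genes=1, min_markers=1)
    assert cat["GO:X"].genes == ("gA",)


def test_catalog_invariant_under_go_row_order(small_geno, small_annot):
    genes, go = small_annot
    gene_map = pb.map_snps_to_genes(small_geno, genes)
    cat1 = pb.build_snpsets(gene_map, go, min_genes=5, min_markers=20)
    shuffled = go.sample(frac=1.0, random_state=4).reset_index(drop=True)
    cat2 = pb.build_snpsets(gene_map, shuffled, min_genes=5, min_markers=20)
    assert set(cat1.sets) == set(cat2.sets)
    for go_id in cat1.sets:
        assert cat1[go_id].genes == cat2[go_id].genes
        assert np.array_equal(cat1[go_id].markers, cat2[go_id].markers)


def test_set_markers_strictly_increasing(small_catalog):
    for s in small_catalog:
        assert (np.diff(s.markers) > 0).all()


def test_empty_catalog_is_an_error():
    gene_map = {"gA": np.arange(5)}
    go = pd.DataFrame(_go_rows("GO:X", ["gA"]),
                      columns=["gene_id", "go_id", "go_class"])
    with pytest.raises(ValueError, match="no SNP-set"):
        pb.build_snpsets(gene_map, go, min_genes=11, min_markers=200)
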