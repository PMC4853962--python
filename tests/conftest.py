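import numpy as np
import pandas as pd
import pytest

import pathblup as pb
from pathblup.genio import GenotypeMatrix


def make_geno(A, chrom=None, pos=None, line_prefix="L"):
    """Hand-built GenotypeMatrix for toy examples (markers on one arm)."""
    A = np.asarray(A, dtype=float)
    n, m = A.shape
    if chrom is None:
        chrom = np.array(["2L"] * m, dtype=object)
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    ids = np.array([f"{c}:{p}" for c, p in zip(chrom, pos)], dtype=object)
    return GenotypeMatrix([f"{line_prefix}{i}" for i in range(n)], ids,
                          np.asarray(chrom, dtype=object),
                          np.asarray(pos, dtype=np.int64), A)


@pytest.fixture(scope="session")
def small_cfg():
    return pb.SimConfig(
        n_lines=20,
        n_markers_per_chrom={c: 100 for c in pb.CHROM_ORDER},
        n_genes=24, go_size_range=(5, 10),
        n_go_sets={"BP": 10, "MF": 4, "CC": 3},
        seed=11)


@pytest.fixture(scope="session")
def small_geno(small_cfg):
    return pb.generate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_annot(small_cfg):
    return pb.generate_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_catalog(small_geno, small_annot):
    genes, go = small_annot
    gene_map = pb.map_snps_to_genes(small_geno, genes, window_bp=5000)
    return pb.build_snpsets(gene_map, go, min_genes=5, min_markers=20)


@pytest.fixture(scope="session")
def small_fit(small_cfg, small_geno, small_annot):
    """Simulated trait + REML fit + scaled genotypes, shared across tests."""
    genes, go = small_annot
    pheno, truth = pb.simulate_trait(small_geno, genes, go, small_cfg)
    w = pb.scale_genotypes(small_geno)
    grm = pb.compute_grm(w)
    X, names = pb.gblup.build_design(
        pheno, ["wolbachia", "inv1", "inv2", "inv3", "inv4", "inv5", "block"])
    line_index = pheno["line_id"].map(
        {l: i for i, l in enumerate(grm.line_ids)}).to_numpy()
    fit = pb.reml_fit(pheno["value"].to_numpy(), X, grm, line_index,
                      x_names=names)
    return {"pheno": pheno, "truth": truth, "w": w, "grm": grm, "X": X,
            "line_index": line_index, "fit": fit}
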