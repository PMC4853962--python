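"""Genotype scaling, GRM, REML variance components, bootstrap and correlations."""
import numpy as np
import pandas as pd
import pytest

import pathblup as pb
from pathblup import gblup
from pathblup.gblup import GRM, LMMFit

from conftest import make_geno


# ---------------------------------------------------------------------------
# scaling and GRM
# ---------------------------------------------------------------------------

def test_scaling_formula_at_half_frequency():
    g = make_geno(np.array([[0], [1], [2], [1]]))
    w = pb.scale_genotypes(g)
    np.testing.assert_allclose(w.W[:, 0], [-1.4142, 0, 1.4142, 0], atol=1e-4)


def test_scaling_formula_at_third_frequency():
    g = make_geno(np.array([[0], [0], [2]]))
    w = pb.scale_genotypes(g)       # p=1/3, denom sqrt(2*1/3*2/3) = 2/3
    np.testing.assert_allclose(w.W[:, 0], [-1, -1, 2], atol=1e-12)


def test_scaled_columns_are_centred(small_geno):
    w = pb.scale_genotypes(small_geno)
    np.testing.assert_allclose(w.W.mean(axis=0), 0, atol=1e-12)


def test_empirical_scaling_gives_unit_variance(small_geno):
    w = pb.scale_genotypes(small_geno, empirical=True)
    np.testing.assert_allclose(w.W.var(axis=0), 1.0, atol=1e-10)


def test_scaling_rejects_monomorphic():
    g = make_geno(np.array([[2, 0], [2, 2]]))
    with pytest.raises(ValueError, match="monomorphic"):
        pb.scale_genotypes(g)


def test_grm_hand_example():
    w = gblup.ScaledGenotypes(np.array([[1.0, -1.0], [-1.0, 1.0]]),
                              np.array([0.5, 0.5]), ["a", "b"],
                              np.array(["m1", "m2"], dtype=object))
    grm = pb.compute_grm(w)
    np.testing.assert_allclose(grm.G, [[1, -1], [-1, 1]], atol=1e-12)


def test_grm_positive_semidefinite(small_geno):
    grm = pb.compute_grm(pb.scale_genotypes(small_geno))
    assert np.linalg.eigvalsh(grm.G).min() >= -1e-8
    np.testing.assert_allclose(grm.G, grm.G.T, atol=0)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def test_reml_agrees_with_coarse_grid(small_cfg):
    """Optimiser log-likelihood dominates a brute-force (sg2, se2) lattice."""
    cfg = pb.SimConfig(**{**small_cfg.__dict__, "n_lines": 8,
                          "n_reps_per_line": 2})
    g = pb.generate_genotypes(cfg)
    pheno, _ = pb.simulate_trait(g, None, None, cfg)
    grm = pb.compute_grm(pb.scale_genotypes(g))
    y = pheno["value"].to_numpy()
    X = np.ones((len(y), 1))
    li = pheno["line_id"].map({l: i for i, l in enumerate(grm.line_ids)}).to_numpy()
    fit = pb.reml_fit(y, X, grm, li)
    K = grm.G[np.ix_(li, li)]
    a, b, ll = gblup.grid_search_reml(y, X, K, n_grid=40, refine=2)
    assert fit.loglik >= ll - 1e-8
    assert fit.h2 == pytest.approx(a / (a + b), abs=1e-3)


def test_reml_flags_unidentifiable_model():
    """G = I with one observation per line leaves only sg2+se2 identified."""
    rng = np.random.default_rng(3)
    grm = GRM(np.eye(10), 1, [f"L{i}" for i in range(10)])
    y = rng.normal(size=10)
    with pytest.warns(UserWarning, match="jointly identifiable"):
        fit = pb.reml_fit(y, np.ones((10, 1)), grm, np.arange(10))
    assert not fit.identifiable


def test_reml_invariant_to_observation_order(small_fit):
    pheno, grm = small_fit["pheno"], small_fit["grm"]
    X, li = small_fit["X"], small_fit["line_index"]
    y = pheno["value"].to_numpy()
    perm = np.random.default_rng(9).permutation(len(y))
    fit2 = pb.reml_fit(y[perm], X[perm], grm, li[perm])
    assert fit2.h2 == pytest.approx(small_fit["fit"].h2, abs=1e-8)
    assert fit2.loglik == pytest.approx(small_fit["fit"].loglik, abs=1e-6)


def test_reml_prunes_collinear_fixed_effects(small_fit):
    pheno, grm, li = small_fit["pheno"], small_fit["grm"], small_fit["line_index"]
    X = small_fit["X"]
    X2 = np.column_stack([X, X[:, 1]])  # duplicated covariate column
    fit2 = pb.reml_fit(pheno["value"].to_numpy(), X2, grm, li)
    assert fit2.h2 == pytest.approx(small_fit["fit"].h2, abs=1e-8)


def test_blup_shrinkage_bound(small_fit):
    fit, grm = small_fit["fit"], small_fit["grm"]
    assert fit.g_blup.var() <= fit.sigma_g2 * np.diag(grm.G).max() + 1e-9


@pytest.mark.parametrize("sg2, se2, expected", [(2, 2, 0.5), (0, 3, 0.0),
                                                (3, 1, 0.75)])
def test_heritability_ratio(sg2, se2, expected):
    fit = LMMFit(pd.Series(dtype=float), pd.Series(dtype=float), sg2, se2,
                 expected, 0.0, True, True, 10)
    assert pb.heritability(fit) == pytest.approx(expected)


def test_heritability_undefined_when_no_variance():
    fit = LMMFit(pd.Series(dtype=float), pd.Series(dtype=float), 0.0, 0.0,
                 0.0, 0.0, True, True, 10)
    with pytest.raises(ValueError):
        pb.heritability(fit)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_requires_replicates():
    grm = GRM(np.eye(3), 1, ["a", "b", "c"])
    with pytest.raises(ValueError):
        pb.bootstrap_ci(np.zeros(3), np.ones((3, 1)), grm, np.arange(3),
                        n_boot=0)


def test_bootstrap_deterministic_given_seed(small_fit):
    pheno, grm = small_fit["pheno"], small_fit["grm"]
    args = (pheno["value"].to_numpy(), small_fit["X"], grm,
            small_fit["line_index"])
    a = pb.bootstrap_ci(*args, n_boot=25, seed=42)
    b = pb.bootstrap_ci(*args, n_boot=25, seed=42)
    assert (a.lower, a.upper) == (b.lower, b.upper)
    assert np.array_equal(a.h2_samples, b.h2_samples)


def test_bootstrap_null_trait_ci_reaches_zero(small_cfg, small_geno):
    cfg = pb.SimConfig(**{**small_cfg.__dict__, "h2_target": 0.0})
    pheno, _ = pb.simulate_trait(small_geno, None, None, cfg)
    grm = pb.compute_grm(pb.scale_genotypes(small_geno))
    X, _ = gblup.build_design(pheno, ["wolbachia", "block"])
    li = pheno["line_id"].map({l: i for i, l in enumerate(grm.line_ids)}).to_numpy()
    ci = pb.bootstrap_ci(pheno["value"].to_numpy(), X, grm, li, n_boot=60,
                         seed=7)
    assert ci.lower < 0.1


# ---------------------------------------------------------------------------
# genomic correlation
# ---------------------------------------------------------------------------

def test_genomic_correlation_examples():
    idx = [f"L{i}" for i in range(5)]
    a = pd.Series([1.0, 2, 3, 4, 5], index=idx)
    assert pb.genomic_correlation(a, a)[0] == pytest.approx(1.0)
    assert pb.genomic_correlation(a, -a)[0] == pytest.approx(-1.0)
    b = pd.Series([1.0, 3, 2, 5, 4], index=idx)
    assert pb.genomic_correlation(a, b)[0] == pytest.approx(0.8)


def test_genomic_correlation_needs_four_shared_lines():
    a = pd.Series([1.0, 2, 3], index=["a", "b", "c"])
    b = pd.Series([1.0, 2, 3], index=["a", "b", "d"])
    with pytest.raises(ValueError, match="shared lines"):
        pb.genomic_correlation(a, b)
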