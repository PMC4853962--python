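"""Synthetic inbred-line panel with blockwise LD, GO annotation, and traits.

Emulates the structure of a small inbred reference panel (tens of fully inbred
lines, genotypes in {0, 2}, MAF bounded away from zero, local LD in blocks,
genes laid along chromosome arms, GO sets of heterogeneous size) so that every
downstream stage — marker filtering, GBLUP, marker-effect back-solving, the
rotation SNP-set test, overlap testing and variance partitioning — can be
exercised with known ground truth.

LD model: within each block of ``ld_block_len`` consecutive markers there are
two ancestral haplotypes; each line copies one of them for the whole block,
with a small per-call mutation probability.  Adjacent markers within a block
are therefore strongly correlated while markers in different blocks are
essentially independent.  This is deliberately simpler than a coalescent
simulation — it is enough to give the rotation test's LD-preservation argument
something real to preserve.

Traits follow y = Xb + Zg + e with g = W s: marker effects s are iid normal on
the markers of the chosen causal GO sets (all markers when no causal set is
named) and zero elsewhere, and the residual variance is chosen from the
realised genetic variance so that the realised heritability matches
``h2_target``.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gblup, genio
from .genio import CHROM_ORDER, GenotypeMatrix

DEFAULT_MARKERS: dict[str, int] = {c: 500 for c in CHROM_ORDER}
DEFAULT_GO_SETS: dict[str, int] = {"BP": 30, "MF": 12, "CC": 8}

_STAGE_GENO, _STAGE_ANNOT, _STAGE_TRAIT = 0, 1, 2


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic panel.

    Defaults describe a small inbred panel: 30 lines, 3,000 markers on six
    chromosome arms, LD blocks of 10 markers, MAF in (0.05, 0.5], fully inbred
    genotypes, 120 genes of 2 kb spaced 8 kb apart, 50 GO sets of 11-25 genes
    across the three classes, five replicate observations per line, and binary
    Wolbachia / five inversion / block covariates with modest effects.
    """

    n_lines: int = 30
    n_markers_per_chrom: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS))
    chrom_names: Sequence[str] = CHROM_ORDER
    marker_spacing: int = 500           # bp between adjacent markers
    ld_block_len: int = 10              # markers per LD block
    maf_range: tuple[float, float] = (0.05, 0.5)
    mutation_rate: float = 0.01         # per-call haplotype copying error
    het_rate: float = 0.0               # fraction of heterozygous calls; 0 -> {0,2}
    n_genes: int = 120
    gene_len: int = 2000                # bp
    intergenic_len: int = 8000          # bp
    n_go_sets: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GO_SETS))
    go_size_range: tuple[int, int] = (11, 25)   # genes per GO set, inclusive
    causal_sets: tuple[str, ...] = ()   # GO ids carrying signal; () -> all markers
    h2_target: float = 0.5
    n_reps_per_line: int = 5
    n_blocks: int = 3                   # experimental blocks (round-robin over reps)
    effect_wolbachia: float = 0.25
    effect_inversion: float = 0.15
    effect_block: float = 0.2
    window_bp: int = 5000               # gene window used to define causal markers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must lie in [0, 1]")
        if self.ld_block_len < 1:
            raise ValueError("ld_block_len must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < min < max <= 0.5")
        for name in ("marker_spacing", "n_genes", "gene_len", "intergenic_len",
                     "n_reps_per_line", "n_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if min(self.n_markers_per_chrom.values()) < 1:
            raise ValueError("each chromosome needs at least one marker")
        if self.go_size_range[0] < 1 or self.go_size_range[0] > self.go_size_range[1]:
            raise ValueError("invalid go_size_range")


@dataclass
class GroundTruth:
    """Simulated architecture underlying one trait."""

    s: np.ndarray                 # per-marker effects (nonzero only on causal markers)
    g: np.ndarray                 # per-line genomic values, exactly W @ s
    sigma_g2: float               # realised genetic variance on the G scale (g' G+ g / rank)
    sigma_e2: float               # residual variance used
    h2: float                     # realised heritability sigma_g2/(sigma_g2+sigma_e2)
    causal_set_ids: tuple[str, ...]
    causal_markers: np.ndarray
    covariates: pd.DataFrame      # per-line covariate values


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, stage)))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def generate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None
                       ) -> GenotypeMatrix:
    """Simulate minor-allele counts for an inbred panel with blockwise LD.

    Per-marker sample MAF is constrained to ``cfg.maf_range`` by construction
    (mutations that would push a marker out of range are repaired), and each
    marker is coded on its sample minor allele.  Deterministic given the seed.
    """
    if rng is None:
        rng = _rng(cfg, _STAGE_GENO)
    n = cfg.n_lines
    lo, hi = cfg.maf_range
    k_lo = max(1, math.ceil(lo * n))
    k_hi = min(n // 2, math.floor(hi * n))
    if k_lo > k_hi:
        raise ValueError(
            f"maf_range {cfg.maf_range} admits no minor-allele count for {n} lines")

    chroms, poss, cols = [], [], []
    for chrom in cfg.chrom_names:
        m_c = int(cfg.n_markers_per_chrom[chrom])
        pos = (np.arange(m_c) + 1) * cfg.marker_spacing
        allele = np.empty((n, m_c), dtype=np.int8)
        for start in range(0, m_c, cfg.ld_block_len):
            width = min(cfg.ld_block_len, m_c - start)
            k = int(rng.integers(k_lo, k_hi + 1))
            carriers = rng.choice(n, size=k, replace=False)
            block = np.zeros((n, width), dtype=np.int8)
            block[carriers, :] = 1
            flips = rng.random((n, width)) < cfg.mutation_rate
            block ^= flips.astype(np.int8)
            allele[:, start:start + width] = block
        _repair_maf(allele, k_lo, k_hi, rng)
        chroms.append(np.full(m_c, chrom, dtype=object))
        poss.append(pos)
        cols.append(allele)

    allele = np.concatenate(cols, axis=1)
    A = 2.0 * allele
    if cfg.het_rate > 0:
        het = rng.random(A.shape) < cfg.het_rate
        A[het] = 1.0
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss).astype(np.int64)
    ids = np.array([f"{c}:{p}" for c, p in zip(chrom, pos)], dtype=object)
    return GenotypeMatrix(
        [f"line{i + 1:03d}" for i in range(n)], ids, chrom, pos,
        A.astype(float), tuple(cfg.chrom_names))


def _repair_maf(allele: np.ndarray, k_lo: int, k_hi: int,
                rng: np.random.Generator) -> None:
    """Clamp each column's minor-allele carrier count into [k_lo, k_hi] in place."""
    n = allele.shape[0]
    counts = allele.sum(axis=0)
    # orient to minor allele first
    flip = counts > n - counts
    allele[:, flip] ^= 1
    counts = allele.sum(axis=0)
    for j in np.nonzero((counts < k_lo) | (counts > k_hi))[0]:
        c = int(counts[j])
        if c < k_lo:
            zeros = np.nonzero(allele[:, j] == 0)[0]
            allele[rng.choice(zeros, k_lo - c, replace=False), j] = 1
        else:
            ones = np.nonzero(allele[:, j] == 1)[0]
            allele[rng.choice(ones, c - k_hi, replace=False), j] = 0


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(cfg: SimConfig, rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay non-overlapping genes along the chromosomes and draw GO sets.

    Genes are distributed over chromosome arms proportionally to arm length
    and placed end to end with ``intergenic_len`` spacing; GO sets draw
    ``go_size_range`` genes each without replacement within a set.  Returns
    (gene table, GO membership table).
    """
    if rng is None:
        rng = _rng(cfg, _STAGE_ANNOT)
    spans = {c: int(cfg.n_markers_per_chrom[c]) * cfg.marker_spacing
             for c in cfg.chrom_names}
    total = sum(spans.values())
    alloc = {c: int(round(cfg.n_genes * spans[c] / total)) for c in cfg.chrom_names}
    # fix rounding so the total is exactly n_genes
    diff = cfg.n_genes - sum(alloc.values())
    for c in sorted(spans, key=spans.get, reverse=True):
        if diff == 0:
            break
        step = 1 if diff > 0 else -1
        alloc[c] += step
        diff -= step

    pitch = cfg.gene_len + cfg.intergenic_len
    rows = []
    serial = 0
    for c in cfg.chrom_names:
        if alloc[c] * pitch > spans[c]:
            raise ValueError(
                f"{alloc[c]} genes of pitch {pitch} bp exceed chromosome {c} "
                f"span of {spans[c]} bp")
        for i in range(alloc[c]):
            serial += 1
            start = i * pitch + cfg.intergenic_len // 2 + 1
            rows.append((f"gene{serial:04d}", c, start, start + cfg.gene_len - 1))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    go_rows = []
    go_serial = 0
    gene_ids = genes["gene_id"].to_numpy()
    lo, hi = cfg.go_size_range
    if hi > len(gene_ids):
        raise ValueError("go_size_range exceeds the number of genes")
    for go_class in ("BP", "MF", "CC"):
        for _ in range(int(cfg.n_go_sets.get(go_class, 0))):
            go_serial += 1
            go_id = f"GO:{go_serial:07d}"
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(gene_ids, size=size, replace=False)
            go_rows.extend((m, go_id, go_class) for m in sorted(members))
    go = pd.DataFrame(go_rows, columns=["gene_id", "go_id", "go_class"])
    return genes, go


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_trait(geno: GenotypeMatrix, genes: pd.DataFrame | None,
                   go: pd.DataFrame | None, cfg: SimConfig,
                   trait_name: str = "trait",
                   rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate replicated observations y = Xb + Zg + e with known architecture.

    Marker effects are iid N(0, 1) on causal markers (the union of markers
    within ``cfg.window_bp`` of genes in ``cfg.causal_sets``; all markers when
    no causal set is named) and zero elsewhere.  g = W s uses the same
    centred/scaled W as the downstream model.  The residual variance is set
    from the realised genetic variance on the G scale,
    sigma_g2 = g' G^+ g / rank(G), so that the realised heritability
    sigma_g2 / (sigma_g2 + sigma_e2) equals ``h2_target``.
    """
    if rng is None:
        rng = _rng(cfg, _STAGE_TRAIT)
    m = geno.n_markers
    s = np.zeros(m)
    causal_ids: tuple[str, ...] = ()
    if cfg.h2_target > 0:
        if cfg.causal_sets:
            if genes is None or go is None:
                raise ValueError("causal_sets given but no annotation supplied")
            known = set(go["go_id"])
            missing = [c for c in cfg.causal_sets if c not in known]
            if missing:
                raise ValueError(f"causal sets not in GO table: {missing}")
            gene_map = genio.map_snps_to_genes(geno, genes, cfg.window_bp)
            members = go.loc[go["go_id"].isin(cfg.causal_sets), "gene_id"].unique()
            causal = np.unique(np.concatenate(
                [gene_map[g] for g in members if g in gene_map]
                or [np.array([], dtype=int)]))
            causal_ids = tuple(cfg.causal_sets)
        else:
            causal = np.arange(m)
        if len(causal) == 0:
            raise ValueError("causal sets contain no markers")
        s[causal] = rng.normal(0.0, 1.0, size=len(causal))
    else:
        causal = np.array([], dtype=int)

    w = gblup.scale_genotypes(geno)
    g = w.W @ s                      # exact linear identity, by construction
    grm = gblup.compute_grm(w)

    if cfg.h2_target > 0:
        d, U = np.linalg.eigh(grm.G)
        tol = d.max() * 1e-10
        nz = d > tol
        proj = U.T @ g
        sigma_g2 = float(np.sum(proj[nz] ** 2 / d[nz]) / nz.sum())
        if cfg.h2_target >= 1.0:
            warnings.warn("h2_target=1 with replicates makes the residual "
                          "variance exactly zero (degenerate)")
            sigma_e2 = 0.0
        else:
            sigma_e2 = sigma_g2 * (1.0 - cfg.h2_target) / cfg.h2_target
        h2 = sigma_g2 / (sigma_g2 + sigma_e2) if sigma_g2 + sigma_e2 > 0 else 0.0
    else:
        sigma_g2, sigma_e2, h2 = 0.0, 1.0, 0.0

    n = geno.n_lines
    wolbachia = rng.integers(0, 2, size=n)
    inversions = rng.integers(0, 2, size=(n, 5))
    inv_signs = np.array([1, -1, 1, -1, 1])
    cov = pd.DataFrame({"line_id": geno.line_ids, "wolbachia": wolbachia})
    for k in range(5):
        cov[f"inv{k + 1}"] = inversions[:, k]

    rows = []
    block_effects = cfg.effect_block * (np.arange(cfg.n_blocks)
                                        - (cfg.n_blocks - 1) / 2)
    for i, line in enumerate(geno.line_ids):
        fixed = (cfg.effect_wolbachia * wolbachia[i]
                 + float(cfg.effect_inversion * (inv_signs * inversions[i]).sum()))
        for rep in range(cfg.n_reps_per_line):
            block = rep % cfg.n_blocks               # round-robin over replicates
            eps = rng.normal(0.0, math.sqrt(sigma_e2)) if sigma_e2 > 0 else 0.0
            value = fixed + block_effects[block] + g[i] + eps
            rows.append((line, rep + 1, trait_name, value, wolbachia[i],
                         *inversions[i], block + 1))
    pheno = pd.DataFrame(rows, columns=["line_id", "rep", "trait", "value",
                                        "wolbachia", "inv1", "inv2", "inv3",
                                        "inv4", "inv5", "block"])
    truth = GroundTruth(s, g, sigma_g2, sigma_e2, h2, causal_ids,
                        causal.astype(int), cov)
    return pheno, truth
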