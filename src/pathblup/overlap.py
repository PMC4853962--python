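"""Cross-trait overlap of sub-threshold SNP-sets via incidence-matrix permutation.

For one GO class, build a binary incidence matrix (rows = SNP-sets, columns =
traits) marking sets with empirical p below a lenient threshold (0.05 by
default).  The observed pairwise overlap between two traits is compared to the
distribution obtained by independently permuting each column 10,000 times
(margins preserved); under independence that distribution is hypergeometric,
which serves as the exact oracle for the permutation scheme.

Analytic helpers give the expected number of false-positive sets per trait
(n_sets * alpha) and the expected pairwise overlap under independence
(n_sets * alpha^2).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def build_incidence(results: Mapping[str, pd.DataFrame],
                    threshold: float = 0.05) -> pd.DataFrame:
    """Binary set x trait incidence matrix: 1 iff empirical p < threshold.

    ``results`` maps trait name to a pathway-test result table (must cover the
    same sets in every trait).  Thresholding is strict (<).
    """
    traits = list(results)
    if not traits:
        raise ValueError("no per-trait results supplied")
    base = list(results[traits[0]]["go_id"])
    cols = {}
    for trait in traits:
        df = results[trait].set_index("go_id")
        if sorted(df.index) != sorted(base):
            raise ValueError(
                f"trait {trait!r} covers a different set list than {traits[0]!r}")
        cols[trait] = (df.loc[base, "p"] < threshold).astype(int)
    inc = pd.DataFrame(cols, index=pd.Index(base, name="go_id"))
    return inc


@dataclass
class OverlapResult:
    trait_a: str
    trait_b: str
    observed: int
    n_a: int
    n_b: int
    n_perm: int
    p: float


def overlap_test(inc: pd.DataFrame, n_perm: int = 10_000,
                 seed: int | None = None) -> pd.DataFrame:
    """Permutation test of pairwise overlap between trait columns.

    Each of ``n_perm`` rounds independently permutes the entries within every
    column (column sums are invariant) and records the pairwise overlap
    (rows that are 1 in both columns).  The one-tailed p is the fraction of
    permutations with overlap >= the observed overlap.  A column of all zeros
    trivially gives overlap 0 and p = 1.
    """
    if inc.shape[1] < 2:
        raise ValueError("need at least two trait columns")
    B = inc.to_numpy(dtype=int)
    n, t = B.shape
    traits = list(inc.columns)
    obs = B.T @ B                       # pairwise observed overlaps
    margins = B.sum(axis=0)
    for j, trait in enumerate(traits):
        if margins[j] == 0:
            log.info("overlap_test: trait %r has no sub-threshold sets", trait)
    rng = np.random.default_rng(seed)
    count_ge = np.zeros((t, t), dtype=int)
    P = np.empty_like(B)
    for _ in range(n_perm):
        for j in range(t):
            P[:, j] = B[rng.permutation(n), j]
        count_ge += (P.T @ P) >= obs
    rows = []
    for a, b in combinations(range(t), 2):
        rows.append(OverlapResult(traits[a], traits[b], int(obs[a, b]),
                                  int(margins[a]), int(margins[b]), n_perm,
                                  count_ge[a, b] / n_perm))
    return pd.DataFrame([r.__dict__ for r in rows])


def all_traits_intersection(inc: pd.DataFrame) -> int:
    """Number of sets sub-threshold in every trait simultaneously (not used by
    the default pairwise reporting)."""
    return int(inc.all(axis=1).sum())


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ExpectedCounts:
    """Expected false-positive and pairwise-overlap counts under the null."""

    n_sets: int
    alpha: float
    expected_fp: float                  # n_sets * alpha
    expected_pairwise_overlap: float    # n_sets * alpha^2
    expected_fp_rounded: int
    expected_pairwise_overlap_rounded: int


def expected_counts(n_sets: int, alpha: float) -> ExpectedCounts:
    """Analytic expected counts at significance level alpha.

    Per trait, ``n_sets * alpha`` sets are expected below the threshold by
    chance; under independence, a pair of traits is expected to share
    ``n_sets * alpha**2`` sets.  Both are returned unrounded and rounded to
    the nearest integer (half away from zero).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    fp = n_sets * alpha
    ov = n_sets * alpha * alpha
    return ExpectedCounts(n_sets, alpha, fp, ov,
                          _round_half_away(fp), _round_half_away(ov))
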