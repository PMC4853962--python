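"""Partition a SNP-set's genetic signal into per-gene contributions.

For an associated GO set, the gene-level genetic value of line l is
f_gene[l] = sum over the gene's markers (restricted to the set) of
W[l, i] * s_hat[i].  When the member genes partition the set's markers, the
gene vectors sum exactly to the set-level effect vector W_set s_set.  The
per-gene variance measure is VarF = Var(f_gene across lines) / m_gene
(adjusting for the number of markers in the gene), and shares are VarF
normalised over the set.  Genes whose share exceeds 20% are flagged as the
set's dominant contributors.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .gblup import ScaledGenotypes
from .genio import SNPSet
from .markerfx import MarkerEffects

log = logging.getLogger(__name__)


def _w_matrix(w) -> np.ndarray:
    return w.W if isinstance(w, ScaledGenotypes) else np.asarray(w, dtype=float)


def _s_vector(s) -> np.ndarray:
    return s.s if isinstance(s, MarkerEffects) else np.asarray(s, dtype=float)


def gene_effects(w, s_hat, gene_map: Mapping[str, np.ndarray],
                 set_markers: np.ndarray, genes: Iterable[str]
                 ) -> dict[str, tuple[np.ndarray, int]]:
    """Per-line gene-level genetic values within one set.

    Returns ``gene_id -> (f vector over lines, m_gene)`` where each gene's
    markers are intersected with the set's markers.  Genes with no markers in
    the set are excluded with a log message.  Markers shared by two member
    genes contribute to both genes' vectors (consistent with the multi-gene
    marker assignment upstream); the exact additivity identity with the
    set-level vector holds whenever the genes partition the set's markers.
    """
    W = _w_matrix(w)
    s = _s_vector(s_hat)
    set_markers = np.asarray(set_markers, dtype=int)
    out: dict[str, tuple[np.ndarray, int]] = {}
    for gene in genes:
        idx = np.intersect1d(np.asarray(gene_map[gene], dtype=int), set_markers)
        if idx.size == 0:
            log.info("gene_effects: gene %s has no markers in the set; excluded", gene)
            continue
        out[gene] = (W[:, idx] @ s[idx], int(idx.size))
    return out


def variance_shares(fx: Mapping[str, tuple[np.ndarray, int]],
                    go_id: str = "", flag_threshold: float = 0.20) -> pd.DataFrame:
    """VarF = Var(f)/m_gene per gene, normalised to shares within the set.

    Sample variance across lines uses the n-1 denominator (any consistent
    choice cancels in the shares).  Shares are non-negative and sum to one;
    genes with share strictly greater than ``flag_threshold`` are flagged.
    Raises if fewer than two lines or if all VarF are zero.
    """
    if not fx:
        raise ValueError("no genes with markers in the set")
    rows = []
    for gene, (f, m_gene) in fx.items():
        if len(f) < 2:
            raise ValueError("variance_shares requires >= 2 lines")
        rows.append((gene, m_gene, float(np.var(f, ddof=1)) / m_gene))
    df = pd.DataFrame(rows, columns=["gene_id", "m_gene", "varF"])
    total = df["varF"].sum()
    if total <= 0:
        raise ValueError("all per-gene variances are zero; shares undefined")
    df["share"] = df["varF"] / total
    df["flag_gt20"] = df["share"] > flag_threshold
    df.insert(0, "go_id", go_id)
    return df.sort_values("share", ascending=False).reset_index(drop=True)


def partition_set(w, s_hat, gene_map: Mapping[str, np.ndarray],
                  snpset: SNPSet, flag_threshold: float = 0.20) -> pd.DataFrame:
    """Convenience wrapper: gene effects + variance shares for one SNP-set."""
    fx = gene_effects(w, s_hat, gene_map, snpset.markers, snpset.genes)
    return variance_shares(fx, snpset.go_id, flag_threshold)
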