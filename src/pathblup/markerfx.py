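"""Back-solve per-marker effects from line-level genomic BLUPs.

Given the scaled genotype matrix W (lines x markers) and predicted genomic
values g_hat, the marker effects are the minimum-norm solution of W s = g_hat,

    s_hat = W' (W W')^+ g_hat,

which equals the Moore-Penrose pseudoinverse solution.  W W' is m * G, so the
GRM can be reused.  The genome ordering of s_hat matches the marker ordering
of W, which the rotation test downstream relies on.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .gblup import ScaledGenotypes

log = logging.getLogger(__name__)


@dataclass
class MarkerEffects:
    """Genome-ordered per-marker effects for one trait."""

    s: np.ndarray
    marker_ids: np.ndarray | None = None
    trait: str | None = None
    resid_rel: float = np.nan   # ||W s - g|| / ||g||, reconstruction check

    def __len__(self) -> int:
        return len(self.s)


def backsolve(w: ScaledGenotypes | np.ndarray, g_hat: np.ndarray,
              trait: str | None = None) -> MarkerEffects:
    """Compute s_hat = W'(WW')^+ g_hat, the minimum-norm solution of W s = g.

    The pseudoinverse uses the standard spectral cutoff
    (eps * max(n, m) * largest eigenvalue).  When g_hat lies in the row space
    of W the reconstruction W s_hat reproduces g_hat exactly (up to numerical
    error); the relative residual is recorded on the result.
    """
    if isinstance(w, ScaledGenotypes):
        W, marker_ids = w.W, w.marker_ids
    else:
        W, marker_ids = np.asarray(w, dtype=float), None
    g_hat = np.asarray(g_hat, dtype=float)
    if W.shape[0] != len(g_hat):
        raise ValueError(
            f"W has {W.shape[0]} rows but g_hat has {len(g_hat)} entries")
    WWt = W @ W.T
    s = W.T @ (linalg.pinvh(WWt) @ g_hat)
    g_norm = np.linalg.norm(g_hat)
    resid = np.linalg.norm(W @ s - g_hat) / g_norm if g_norm > 0 else 0.0
    if resid > 1e-6:
        log.info("backsolve: relative reconstruction residual %.3g "
                 "(g_hat not fully in the row space of W)", resid)
    return MarkerEffects(s, marker_ids, trait, float(resid))
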