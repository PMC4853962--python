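"""Genomic BLUP: genotype scaling, GRM, REML variance components, heritability.

Model
-----
For replicated observations on inbred lines,

    y = X b + Z g + e,   g ~ N(0, G sigma_g^2),   e ~ N(0, I sigma_e^2),

where G = W W' / m is the genomic relationship matrix built from the centred
and scaled allele-count matrix, w_i = (a_i - 2 p_i) / sqrt(2 p_i (1 - p_i)),
with p_i the sample minor allele frequency of marker i.  SNP heritability is
h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

Note that on fully inbred {0,2} genotypes the 2p(1-p) denominator leaves each
column with empirical variance near 2 (allele counts are twice a Bernoulli
draw), so diag(G) is near 2 rather than 1.  The printed scaling is the default;
``scale_genotypes(..., empirical=True)`` offers unit-variance columns for
comparison.

REML is maximised by profiling the likelihood on the variance ratio
lambda = sigma_g^2 / sigma_e^2 through an eigendecomposition of Z G Z'.  The
criterion itself is exposed as :func:`reml_loglik` (a direct, Cholesky-based
evaluation) so that grid searches can audit the optimiser independently.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .genio import GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scaling and GRM
# ---------------------------------------------------------------------------

@dataclass
class ScaledGenotypes:
    """Centred/scaled genotypes W with the scaling record (p per marker)."""

    W: np.ndarray          # lines x markers
    p: np.ndarray          # minor allele frequency used per column
    line_ids: list[str]
    marker_ids: np.ndarray

    @property
    def m(self) -> int:
        return self.W.shape[1]


@dataclass
class GRM:
    """Genomic relationship matrix G = W W' / m."""

    G: np.ndarray
    m: int
    line_ids: list[str]

    @property
    def n_lines(self) -> int:
        return self.G.shape[0]


def scale_genotypes(g: GenotypeMatrix, empirical: bool = False) -> ScaledGenotypes:
    """Centre and scale allele counts column-wise.

    Default scaling divides by sqrt(2 p (1-p)); ``empirical=True`` divides by
    the empirical column standard deviation instead (unit-variance columns).
    Monomorphic markers must be filtered first.
    """
    p = g.maf
    if np.any(p <= 0) or np.any(np.ptp(g.A, axis=0) == 0):
        raise ValueError("monomorphic markers present; run filter_markers first")
    centred = g.A - g.A.mean(axis=0)
    if empirical:
        denom = g.A.std(axis=0)
    else:
        denom = np.sqrt(2.0 * p * (1.0 - p))
    W = centred / denom
    return ScaledGenotypes(W, p, list(g.line_ids), g.marker_ids)


def compute_grm(w: ScaledGenotypes) -> GRM:
    """G = W W' / m; symmetric and positive semi-definite by construction."""
    G = w.W @ w.W.T / w.m
    G = (G + G.T) / 2.0
    return GRM(G, w.m, list(w.line_ids))


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(pheno: pd.DataFrame, covariates: list[str],
                 factor_covariates: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design matrix from a phenotype table.

    Covariates listed in ``factor_covariates`` (default: any non-numeric
    column, plus ``block``) are dummy-coded with the first level dropped;
    the rest enter as numeric columns.
    """
    if factor_covariates is None:
        factor_covariates = [c for c in covariates
                             if c == "block" or not pd.api.types.is_numeric_dtype(pheno[c])]
    cols = [pd.Series(np.ones(len(pheno)), name="intercept", index=pheno.index)]
    for c in covariates:
        if c in factor_covariates:
            d = pd.get_dummies(pheno[c].astype("category"), prefix=c, drop_first=True)
            cols.extend(d[col].astype(float) for col in d.columns)
        else:
            cols.append(pheno[c].astype(float))
    X = pd.concat(cols, axis=1)
    return X.to_numpy(dtype=float), list(X.columns)


def prune_collinear(X: np.ndarray, names: list[str] | None = None,
                    tol: float = 1e-8) -> tuple[np.ndarray, list[int]]:
    """Drop linearly dependent columns (QR with pivoting); returns kept indices."""
    if X.shape[1] == 0:
        return X, []
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * max(diag[0], 1.0)).sum())
    keep = sorted(piv[:rank])
    if len(keep) < X.shape[1] and names is not None:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        log.info("pruned collinear fixed-effect columns: %s", dropped)
    return X[:, keep], keep


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """REML fit of y = Xb + Zg + e with g ~ N(0, G sigma_g^2)."""

    beta: pd.Series
    g_blup: pd.Series
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    converged: bool
    identifiable: bool
    n_obs: int
    messages: list[str] = field(default_factory=list)


def reml_loglik(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                sigma_g2: float, sigma_e2: float) -> float:
    """Direct REML log-likelihood (up to an additive constant) at (sg2, se2).

    V = sg2 K + se2 I;  ll = -1/2 [ log|V| + log|X'V^-1 X| + r'V^-1 r ] with
    r the GLS residual.  Evaluated by Cholesky factorisation, independently of
    the eigendecomposition route the optimiser uses.  Returns -inf when V is
    not positive definite.
    """
    n = len(y)
    V = sigma_g2 * K + sigma_e2 * np.eye(n)
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = linalg.cho_solve((c, low), X)
    Vi_y = linalg.cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = r @ linalg.cho_solve((c, low), r)
    return float(-0.5 * (logdet_v + logdet_x + quad))


def _profile(lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profiled REML criterion at variance ratio lam = sg2/se2.

    Returns (ll, se2_hat, beta).  Identical (same constant) to
    :func:`reml_loglik` evaluated at (lam*se2_hat, se2_hat).
    """
    n, p = Xt.shape
    w = lam * d + 1.0
    Xw = Xt / w[:, None]
    A = Xt.T @ Xw
    b = Xw.T @ yt
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, None
    r = yt - Xt @ beta
    rss = float(np.sum(r * r / w))
    se2 = rss / (n - p)
    if se2 <= 0:
        return -np.inf, np.nan, None
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf, np.nan, None
    ll = -0.5 * ((n - p) * np.log(se2) + float(np.log(w).sum()) + logdet_a + (n - p))
    return ll, se2, beta


def reml_fit(y: np.ndarray, X: np.ndarray, grm: GRM | np.ndarray,
             line_index: np.ndarray, x_names: list[str] | None = None,
             lam_grid: np.ndarray | None = None) -> LMMFit:
    """Fit the genomic mixed model by REML.

    Parameters
    ----------
    y, X : observation vector and fixed-effect design (pruned for collinearity
        internally).
    grm : GRM over all lines (or a raw square matrix).
    line_index : integer index of each observation's line into the GRM.

    The likelihood is profiled on lambda = sigma_g^2/sigma_e^2 over a wide
    log-spaced scan followed by bounded refinement; the boundary lambda = 0
    (sigma_g^2 = 0) is always evaluated.  Non-negativity is therefore enforced
    by the parametrisation, not by post-hoc clipping.
    """
    G = grm.G if isinstance(grm, GRM) else np.asarray(grm)
    line_ids = grm.line_ids if isinstance(grm, GRM) else [str(i) for i in range(G.shape[0])]
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    line_index = np.asarray(line_index, dtype=int)
    if len(y) != X.shape[0] or len(y) != len(line_index):
        raise ValueError("y, X and line_index must have matching lengths")
    if line_index.max() >= G.shape[0]:
        raise ValueError("line_index refers to lines outside the GRM")

    names = x_names if x_names is not None else [f"x{j}" for j in range(X.shape[1])]
    X, keep = prune_collinear(X, names)
    names = [names[j] for j in keep]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"too few observations ({n}) for {p} fixed effects")

    messages: list[str] = []
    K = G[np.ix_(line_index, line_index)]
    d, U = linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    identifiable = bool(np.ptp(d) > 1e-8 * max(1.0, d.max()))
    if not identifiable:
        msg = ("Z G Z' is proportional to the identity: sigma_g^2 and sigma_e^2 "
               "are only jointly identifiable; reporting a boundary fit")
        warnings.warn(msg)
        messages.append(msg)

    yt = U.T @ y
    Xt = U.T @ X

    if lam_grid is None:
        lam_grid = np.concatenate([[0.0], np.logspace(-6, 8, 141)])
    lls = np.array([_profile(l, d, yt, Xt)[0] for l in lam_grid])
    i = int(np.nanargmax(lls))
    lam_hat = lam_grid[i]
    # bounded refinement in log-lambda around the best scan point
    if 0 < i < len(lam_grid) - 1 and np.isfinite(lls[i]):
        lo = max(lam_grid[i - 1], 1e-12)
        hi = lam_grid[i + 1]
        res = optimize.minimize_scalar(
            lambda t: -_profile(np.exp(t), d, yt, Xt)[0],
            bounds=(np.log(lo), np.log(hi)), method="bounded",
            options={"xatol": 1e-10})
        if np.isfinite(res.fun) and -res.fun >= lls[i]:
            lam_hat = float(np.exp(res.x))
    converged = bool(np.isfinite(lls[i]))
    if not converged:
        raise RuntimeError(f"REML did not converge; scan log-likelihoods: {lls}")

    ll, se2, beta = _profile(lam_hat, d, yt, Xt)
    sg2 = lam_hat * se2
    if sg2 + se2 <= 0:
        raise RuntimeError("degenerate fit: both variance components zero")
    h2 = sg2 / (sg2 + se2)

    # BLUPs: g_hat = sg2 * G Z' V^-1 (y - X beta)
    r = yt - Xt @ beta
    vinv_r = U @ (r / (sg2 * d + se2))
    ztv = np.bincount(line_index, weights=vinv_r, minlength=G.shape[0])
    g_blup = sg2 * (G @ ztv)

    return LMMFit(
        beta=pd.Series(beta, index=names),
        g_blup=pd.Series(g_blup, index=line_ids),
        sigma_g2=float(sg2), sigma_e2=float(se2), h2=float(h2),
        loglik=float(ll), converged=converged, identifiable=identifiable,
        n_obs=n, messages=messages)


def heritability(fit: LMMFit) -> float:
    """h2_SNP = sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
    tot = fit.sigma_g2 + fit.sigma_e2
    if tot <= 0:
        raise ValueError("heritability undefined: both variance components are zero")
    return fit.sigma_g2 / tot


def grid_search_reml(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                     n_grid: int = 100, refine: int = 2,
                     span: float = 3.0) -> tuple[float, float, float]:
    """Brute-force REML grid search over (sigma_g^2, sigma_e^2).

    Evaluates :func:`reml_loglik` on an ``n_grid x n_grid`` lattice spanning
    [0, span*var(y)] x (0, span*var(y)], then zooms ``refine`` times around the
    argmax.  Returns (sg2, se2, loglik) of the best lattice point.  Intended as
    an independent audit of the profiled optimiser on small problems.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    hi = span * float(np.var(y))
    a_lo, a_hi, b_lo, b_hi = 0.0, hi, hi / n_grid, hi
    best = (np.nan, np.nan, -np.inf)
    for _ in range(refine + 1):
        a_grid = np.linspace(a_lo, a_hi, n_grid)
        b_grid = np.linspace(max(b_lo, 1e-12), b_hi, n_grid)
        for a in a_grid:
            for b in b_grid:
                ll = reml_loglik(y, X, K, a, b)
                if ll > best[2]:
                    best = (float(a), float(b), float(ll))
        da = (a_hi - a_lo) / (n_grid - 1)
        db = (b_hi - b_lo) / (n_grid - 1)
        a_lo, a_hi = max(0.0, best[0] - da), best[0] + da
        b_lo, b_hi = max(1e-12, best[1] - db), best[1] + db
    return best


# ---------------------------------------------------------------------------
# bootstrap confidence interval for h2
# ---------------------------------------------------------------------------

@dataclass
class BootstrapCI:
    """Observation-level bootstrap distribution of h2 with percentile CI."""

    h2_samples: np.ndarray
    lower: float
    upper: float
    n_boot: int
    n_failed: int
    seed: int | None


def bootstrap_ci(y: np.ndarray, X: np.ndarray, grm: GRM | np.ndarray,
                 line_index: np.ndarray, n_boot: int = 10_000,
                 seed: int | None = None, alpha: float = 0.05,
                 line_means: bool = False) -> BootstrapCI:
    """Bootstrap the heritability by resampling observations with replacement.

    Each replicate draws n observations with replacement, rebuilds the line
    incidence (lines absent from a replicate simply drop out of that fit), and
    re-estimates h2.  The CI is the (alpha/2, 1-alpha/2) empirical
    (nearest-observation) quantile pair.  ``line_means=True`` resamples whole
    lines of their mean phenotype instead of raw observations.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    line_index = np.asarray(line_index, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(y)
    if line_means:
        lines = np.unique(line_index)
        ym = np.array([y[line_index == l].mean() for l in lines])
        Xm = np.vstack([X[line_index == l].mean(axis=0) for l in lines])
        y, X, line_index, n = ym, Xm, lines, len(lines)
    h2s = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            fit = reml_fit(y[idx], X[idx], grm, line_index[idx])
            h2s.append(fit.h2)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > 0.1 * n_boot:
        warnings.warn(f"bootstrap: {n_failed}/{n_boot} replicate fits failed")
    h2s = np.asarray(h2s)
    if len(h2s) == 0:
        raise RuntimeError("all bootstrap replicates failed")
    lo, hi = np.quantile(h2s, [alpha / 2, 1 - alpha / 2], method="closest_observation")
    return BootstrapCI(h2s, float(lo), float(hi), n_boot, n_failed, seed)


# ---------------------------------------------------------------------------
# genomic correlation
# ---------------------------------------------------------------------------

def genomic_correlation(g_a: pd.Series, g_b: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation of two line-level genomic value vectors.

    Vectors are aligned on shared line ids; at least four shared lines are
    required.  Returns (rho, two-sided p) using the t approximation.
    """
    shared = g_a.index.intersection(g_b.index)
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared lines; need >= 4")
    rho, p = stats.spearmanr(g_a.loc[shared], g_b.loc[shared])
    return float(rho), float(p)
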