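"""Connectome-transcriptome association via partial least squares.

A region x gene expression matrix (predictors) is regressed on the
per-region t map of nodal-entropy differences (response) with PLS.  The
analysis focuses on the first component (PLS1): its significance comes from
a permutation test whose surrogate maps preserve the response's spatial
autocorrelation when a region-region distance matrix is available
(variogram-matched randomization; plain permutation otherwise), and each
gene's weight is stabilized into a bootstrap Z score (weight divided by its
bootstrap standard error).  Genes with FDR-significant Z split by sign into
the PLS1+ and PLS1- sets, which can be tested for overlap against named
cell-type gene sets by permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .group_stats import TStatMap, bh_fdr


@dataclass
class PlsResult:
    scores: np.ndarray  # PLS1 region scores
    weights: np.ndarray  # per-gene raw PLS1 weights
    explained_variance: np.ndarray  # fraction of response variance, per comp.
    gene_ids: list[str]
    n_components: int
    score_tmap_correlation: float  # sign convention: fixed non-negative
    permutation_p: float | None = None
    bootstrap_z: np.ndarray | None = None
    pls1_pos: list[str] = field(default_factory=list)
    pls1_neg: list[str] = field(default_factory=list)


@dataclass
class CellTypeSets:
    """Named cell-class gene sets over a background gene universe."""

    sets: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            extra = genes - self.background
            if extra:
                raise ValueError(
                    f"set '{name}' has genes outside the background: "
                    f"{sorted(extra)[:5]}")


def _standardize_columns(X: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = ", ".join(gene_ids[j] for j in dead[:5])
        raise ValueError(f"constant expression column(s): {names}")
    return (X - X.mean(axis=0)) / sd


def fit_pls(
    X: pd.DataFrame | np.ndarray,
    y: TStatMap | np.ndarray,
    n_components: int = 15,
    gene_ids: list[str] | None = None,
) -> PlsResult:
    """PLS regression of the t map on gene expression.

    Columns of X are standardized and y is centered internally.  The
    per-component explained variance is the fraction of response variance
    carried by each (mutually orthogonal) score vector.  PLS1 is oriented
    so that its region scores correlate non-negatively with the response;
    this is a reporting convention only and is recorded on the result.
    """
    if isinstance(X, pd.DataFrame):
        gene_ids = list(X.columns)
        X = X.to_numpy(dtype=float)
    elif gene_ids is None:
        gene_ids = [f"G{j:04d}" for j in range(X.shape[1])]
    yv = np.asarray(y.values if isinstance(y, TStatMap) else y, dtype=float)
    n = X.shape[0]
    if yv.shape[0] != n:
        raise ValueError("t map length must equal the region count")
    if n < n_components + 2:
        raise ValueError(f"need >= {n_components + 2} regions for "
                         f"{n_components} components")
    Xs = _standardize_columns(np.asarray(X, dtype=float), gene_ids)
    yc = yv - yv.mean()
    if np.all(yc == 0):
        raise ValueError("constant response map")

    pls = PLSRegression(n_components=n_components, scale=False).fit(
        Xs, yc[:, None])
    T = pls.x_scores_
    ss_y = float(yc @ yc)
    ss_t = (T * T).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        expl = np.where(ss_t > 0, (T.T @ yc) ** 2 / (ss_t * ss_y), 0.0)
    scores = T[:, 0].copy()
    weights = pls.x_weights_[:, 0].copy()
    r = float(np.corrcoef(scores, yc)[0, 1])
    if r < 0:
        scores, weights, r = -scores, -weights, -r
    return PlsResult(scores, weights, expl, gene_ids, n_components, r)


def pls1_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """First-component weight vector only (fast path for resampling loops)."""
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    yc = y - y.mean()
    w = Xs.T @ yc
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("degenerate response")
    return w / nrm


class VariogramSurrogates:
    """Spatial-autocorrelation-preserving surrogate maps.

    Implements a smoothed-permutation scheme: the map is randomly permuted,
    kernel-smoothed at a set of candidate bandwidths, and affinely rescaled
    so its empirical variogram matches the original's (gamma_surr ~ alpha *
    gamma_smooth + beta, fit by least squares); the bandwidth with the best
    variogram fit wins.  ``last_fit_sse`` exposes the achieved variogram
    mismatch for diagnostics.
    """

    def __init__(self, distance_matrix: np.ndarray, n_bins: int = 20,
                 bandwidths: tuple[float, ...] = (0.1, 0.2, 0.4, 0.7, 1.0)):
        D = np.asarray(distance_matrix, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
            raise ValueError("distance matrix must be symmetric with zero "
                             "diagonal")
        self.D = D
        self.n = D.shape[0]
        iu = np.triu_indices(self.n, k=1)
        self._iu = iu
        d = D[iu]
        self._bin_edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
        self._bin_idx = np.clip(
            np.searchsorted(self._bin_edges, d, side="right") - 1, 0,
            n_bins - 1)
        self._n_bins = n_bins
        dmax = d.max()
        self._kernels = [np.exp(-(D / (b * dmax)) ** 2) for b in bandwidths]
        self._kernels = [K / K.sum(axis=1, keepdims=True)
                         for K in self._kernels]
        self.last_fit_sse: float | None = None

    def _variogram(self, y: np.ndarray) -> np.ndarray:
        sq = 0.5 * (y[self._iu[0]] - y[self._iu[1]]) ** 2
        out = np.zeros(self._n_bins)
        cnt = np.bincount(self._bin_idx, minlength=self._n_bins)
        np.add.at(out, self._bin_idx, sq)
        return out / np.maximum(cnt, 1)

    def __call__(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        gamma_obs = self._variogram(y)
        perm = rng.permutation(y)
        noise = rng.standard_normal(self.n)
        best, best_sse = None, np.inf
        for K in self._kernels:
            smooth = K @ perm
            gs = self._variogram(smooth)
            gn = self._variogram(noise)
            A = np.column_stack([gs, gn])
            coef, *_ = np.linalg.lstsq(A, gamma_obs, rcond=None)
            a, b = np.abs(coef)
            cand = np.sqrt(a) * smooth + np.sqrt(b) * noise
            sse = float(np.sum((self._variogram(cand) - gamma_obs) ** 2))
            if sse < best_sse:
                best, best_sse = cand, sse
        self.last_fit_sse = best_sse
        return best


def permutation_test_pls(
    X: pd.DataFrame | np.ndarray,
    y: TStatMap | np.ndarray,
    n_perm: int = 1000,
    distance_matrix: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p value for PLS1's explained response variance.

    With a distance matrix, surrogate response maps are variogram-matched
    randomizations (preserving spatial autocorrelation); without one they
    are plain region permutations.  p = (1 + #{surrogate >= observed}) /
    (1 + n_perm).  Returns (p, null statistics).
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else \
        np.asarray(X, dtype=float)
    yv = np.asarray(y.values if isinstance(y, TStatMap) else y, dtype=float)
    if distance_matrix is not None and \
            np.asarray(distance_matrix).shape != (Xv.shape[0], Xv.shape[0]):
        raise ValueError("distance matrix shape mismatch")
    rng = np.random.default_rng(seed)
    gen = VariogramSurrogates(distance_matrix) \
        if distance_matrix is not None else None

    def stat(resp: np.ndarray) -> float:
        w = pls1_weights(Xv, resp)
        sd = Xv.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        t = ((Xv - Xv.mean(axis=0)) / sd) @ w
        rc = resp - resp.mean()
        return float((t @ rc) ** 2 / ((t @ t) * (rc @ rc)))

    observed = stat(yv)
    null = np.empty(n_perm)
    for i in range(n_perm):
        surr = gen(yv, rng) if gen is not None else rng.permutation(yv)
        null[i] = stat(surr)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return p, null


def bootstrap_gene_weights(
    X: pd.DataFrame | np.ndarray,
    y: TStatMap | np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, int]:
    """Bootstrap Z score per gene: original PLS1 weight / bootstrap SD.

    Regions are resampled with replacement; each refit weight vector is
    sign-aligned to the original by the sign of their inner product.
    Degenerate resamples (constant response) are redrawn; the count of
    redraws is returned alongside Z.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else \
        np.asarray(X, dtype=float)
    yv = np.asarray(y.values if isinstance(y, TStatMap) else y, dtype=float)
    n = Xv.shape[0]
    if n < 10:
        raise ValueError("need >= 10 regions for bootstrap")
    rng = np.random.default_rng(seed)
    w0 = pls1_weights(Xv, yv)
    boots = np.empty((n_boot, Xv.shape[1]))
    skipped = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = yv[idx]
        if np.all(yb == yb[0]):
            skipped += 1
            continue
        wb = pls1_weights(Xv[idx], yb)
        if wb @ w0 < 0:
            wb = -wb
        boots[i] = wb
        i += 1
    sd = boots.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return w0 / sd, skipped


def select_gene_sets(
    z: np.ndarray, gene_ids: list[str], alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Split FDR-significant genes by Z sign into PLS1+ / PLS1- lists.

    Two-sided normal p values from Z, BH-FDR at ``alpha``; each list is
    ranked by descending |Z|.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite Z scores")
    p = 2 * stats.norm.sf(np.abs(z))
    padj = bh_fdr(p)
    sig = padj < alpha
    order = np.argsort(-np.abs(z))
    pos = [gene_ids[j] for j in order if sig[j] and z[j] > 0]
    neg = [gene_ids[j] for j in order if sig[j] and z[j] < 0]
    return pos, neg


def celltype_overlap_test(
    gene_list: list[str],
    sets: CellTypeSets,
    n_perm: int = 10000,
    seed: int | None = None,
) -> dict[str, dict[str, float]]:
    """Permutation test of gene-list overlap with each cell-type set.

    The null draws random gene lists of the same size from the background;
    p = (1 + #{null overlap >= observed}) / (1 + n_perm), BH-corrected
    across the cell-type sets.
    """
    background = sorted(sets.background)
    if not background:
        raise ValueError("empty background gene universe")
    outside = set(gene_list) - sets.background
    if outside:
        raise ValueError(f"gene list outside background: {sorted(outside)[:5]}")
    rng = np.random.default_rng(seed)
    glist = set(gene_list)
    names = list(sets.sets)
    observed = {m: len(glist & sets.sets[m]) for m in names}
    exceed = dict.fromkeys(names, 0)
    bg = np.array(background)
    for _ in range(n_perm):
        draw = set(rng.choice(bg, size=len(glist), replace=False))
        for m in names:
            if len(draw & sets.sets[m]) >= observed[m]:
                exceed[m] += 1
    raw = {m: (1 + exceed[m]) / (1 + n_perm) for m in names}
    adj = bh_fdr([raw[m] for m in names])
    return {m: {"overlap": float(observed[m]), "p_raw": raw[m],
                "p_fdr": float(a)} for m, a in zip(names, adj)}
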