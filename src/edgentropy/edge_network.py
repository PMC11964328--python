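"""Edge-centric functional brain networks and nodal entropy.

The edge-centric view unfolds the Pearson correlation between two regions
into an *edge time series* (eTS): the per-timepoint product of the two
regions' z-scored BOLD signals, whose time average is exactly the Pearson
correlation of the pair.  Clustering the eTS rows with K-means yields edge
communities; mapping those back onto regions gives each region a
distribution over communities whose normalized Shannon entropy (nodal
entropy) quantifies how evenly the region's connections are spread across
communities — 0 for a region whose incident edges all share one community,
1 for a perfectly even spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: Canonical resting-state subnetwork labels (Yeo 7-network scheme).
SUBNETWORK_LABELS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "salience_ventral_attention",
    "limbic",
    "frontoparietal_control",
    "default_mode",
)


@dataclass
class RoiTimeSeries:
    """One subject's region x time signal matrix."""

    values: np.ndarray  # shape (n_regions, n_time)
    region_ids: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region x time matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if len(self.region_ids) != self.values.shape[0]:
            raise ValueError("region_ids length must match number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass
class EdgeTimeSeries:
    """Co-fluctuation time series for every region pair (upper triangle)."""

    values: np.ndarray  # shape (n_edges, n_time)
    edge_index: np.ndarray  # shape (n_edges, 2), pairs (m, n) with m < n

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeCommunityLabels:
    """K-means edge-community assignment of the selected (min-SSE) run."""

    labels: np.ndarray  # per-edge community in 1..k
    k: int
    sse: float
    restart_sse: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class CommunityProfile:
    """Per-region frequency distribution over edge communities."""

    values: np.ndarray  # shape (n_regions, k)
    n_regions: int


@dataclass
class NodalEntropy:
    """Normalized per-region entropy of the community profile, in [0, 1]."""

    values: np.ndarray
    k: int


def zscore_timeseries(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Z-score each region's time series, Z(t) = (X(t) - mu) / sigma.

    Uses the population (divide-by-T) standard deviation so that the time
    average of each edge time series equals the Pearson correlation of the
    region pair exactly.
    """
    mu = ts.values.mean(axis=1, keepdims=True)
    sigma = ts.values.std(axis=1, ddof=0, keepdims=True)
    flat = np.where(sigma.ravel() == 0)[0]
    if flat.size:
        names = ", ".join(ts.region_ids[i] for i in flat[:5])
        raise ValueError(f"constant (zero-variance) region(s): {names}")
    return RoiTimeSeries((ts.values - mu) / sigma, list(ts.region_ids), ts.subject_id)


def compute_edge_time_series(z: RoiTimeSeries) -> EdgeTimeSeries:
    """Edge time series e_mn(t) = z_m(t) * z_n(t) for every pair m < n.

    Edges are ordered as the upper triangle in row-major order, so for N
    regions there are N(N-1)/2 edges.
    """
    if z.n_regions < 2:
        raise ValueError("need at least 2 regions to form edges")
    iu, ju = np.triu_indices(z.n_regions, k=1)
    values = z.values[iu] * z.values[ju]
    return EdgeTimeSeries(values, np.column_stack([iu, ju]))


def cluster_edges(
    ets: EdgeTimeSeries,
    k: int = 10,
    n_restarts: int = 25,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> EdgeCommunityLabels:
    """K-means over edge rows; keep the restart with the lowest SSE.

    Each restart is an independent k-means++ run; the labeling with the
    minimal within-community sum of squares wins (ties broken by lowest
    restart index).  All restart SSE values are retained and logged.
    """
    if ets.n_edges == 0:
        raise ValueError("empty edge time series")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ets.n_edges:
        raise ValueError(f"k={k} exceeds number of edges ({ets.n_edges})")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best_labels, best_sse, all_sse = None, np.inf, np.empty(n_restarts)
    for i, rs in enumerate(restart_seeds):
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
            tol=tol, random_state=int(rs),
        ).fit(ets.values)
        all_sse[i] = km.inertia_
        if km.inertia_ < best_sse:  # strict: ties keep the earlier restart
            best_sse = float(km.inertia_)
            best_labels = km.labels_
    logger.debug("k-means restart SSE values: %s", all_sse.tolist())
    return EdgeCommunityLabels(best_labels + 1, k, best_sse, all_sse)


def community_profile(labels: EdgeCommunityLabels, n_regions: int) -> CommunityProfile:
    """Fraction P_ms of region m's N-1 incident edges in community s."""
    n_edges_expected = n_regions * (n_regions - 1) // 2
    if labels.labels.shape[0] != n_edges_expected:
        raise ValueError(
            f"{labels.labels.shape[0]} labels do not cover the upper triangle "
            f"of {n_regions} regions ({n_edges_expected} edges)"
        )
    if labels.labels.min() < 1 or labels.labels.max() > labels.k:
        raise ValueError("labels outside 1..k")
    iu, ju = np.triu_indices(n_regions, k=1)
    counts = np.zeros((n_regions, labels.k))
    np.add.at(counts, (iu, labels.labels - 1), 1.0)
    np.add.at(counts, (ju, labels.labels - 1), 1.0)
    return CommunityProfile(counts / (n_regions - 1), n_regions)


def nodal_entropy(profile: CommunityProfile, k: int | None = None) -> NodalEntropy:
    """Normalized Shannon entropy E_u = -sum_s P_us log2 P_us / log2 k.

    The normalization constant k defaults to the number of edge communities,
    so a point-mass profile scores 0 and a uniform spread scores 1.  For
    k = 1 the entropy is defined as 0.
    """
    p = profile.values
    if np.any(p < -1e-12):
        raise ValueError("profile contains negative frequencies")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("profile rows must sum to 1")
    if k is None:
        k = p.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return NodalEntropy(np.zeros(p.shape[0]), k)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    ent = -terms.sum(axis=1) / np.log2(k)
    return NodalEntropy(np.clip(ent, 0.0, 1.0), k)


@dataclass
class SubnetworkMap:
    """Assignment of each region to one of the 7 canonical subnetworks."""

    assignment: dict[str, str]  # region_id -> subnetwork label

    def __post_init__(self) -> None:
        bad = {v for v in self.assignment.values()} - set(SUBNETWORK_LABELS)
        if bad:
            raise ValueError(f"unknown subnetwork label(s): {sorted(bad)}")

    def members(self, label: str) -> list[str]:
        return [r for r, s in self.assignment.items() if s == label]


def aggregate_entropy(
    entropy: NodalEntropy, region_ids: list[str], subnets: SubnetworkMap
) -> dict[str, float]:
    """Global (all-region mean) and per-subnetwork mean nodal entropy."""
    missing = [r for r in region_ids if r not in subnets.assignment]
    if missing:
        raise ValueError(f"regions without subnetwork assignment: {missing[:5]}")
    by_region = dict(zip(region_ids, entropy.values))
    out = {"global": float(np.mean(entropy.values))}
    for label in SUBNETWORK_LABELS:
        members = [r for r in subnets.members(label) if r in by_region]
        if not members:
            raise ValueError(f"subnetwork '{label}' has no member regions")
        out[label] = float(np.mean([by_region[r] for r in members]))
    return out


def residualize_covariates(
    features: np.ndarray, covariates: np.ndarray
) -> np.ndarray:
    """OLS-residualize each feature column on [intercept | covariates].

    The fitted intercept is added back, so group means under null covariates
    are preserved while residuals are exactly orthogonal to every covariate.
    """
    Y = np.atleast_2d(np.asarray(features, dtype=float))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != Y.shape[0]:
        raise ValueError("features and covariates must have equal row counts")
    n, p = C.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} subjects for {p} covariates")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        collinear = [
            j for j in range(p)
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), C[:, j]])) < 2
            or np.linalg.matrix_rank(np.delete(X, j + 1, axis=1))
            == np.linalg.matrix_rank(X)
        ]
        raise ValueError(
            f"rank-deficient covariate design; collinear column(s): {collinear}"
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid + beta[0]  # add the intercept back


def subject_entropy(
    ts: RoiTimeSeries,
    k: int = 10,
    n_restarts: int = 25,
    seed: int | None = None,
) -> tuple[NodalEntropy, EdgeCommunityLabels]:
    """Full per-subject pipeline: z-score -> eTS -> K-means -> entropy."""
    z = zscore_timeseries(ts)
    ets = compute_edge_time_series(z)
    labels = cluster_edges(ets, k=k, n_restarts=n_restarts, seed=seed)
    profile = community_profile(labels, ts.n_regions)
    return nodal_entropy(profile, k), labels


def build_entropy_table(
    subjects: list[RoiTimeSeries],
    manifest: pd.DataFrame,
    subnets: SubnetworkMap,
    k: int = 10,
    n_restarts: int = 25,
    seed: int | None = None,
    covariate_mode: str = "features",
    covariate_columns: tuple[str, ...] = ("sex", "age", "education"),
    clustering_scope: str = "subject",
) -> pd.DataFrame:
    """Compute the per-subject entropy table for a cohort.

    One row per subject: global entropy, 7 subnetwork entropies, then the
    per-region nodal entropies, joined with group labels and covariates from
    the manifest.  ``covariate_mode`` controls confound removal:

    - ``"features"`` (default): OLS-residualize the entropy columns across
      subjects on the covariate columns;
    - ``"bold"``: residualize each (region, timepoint) BOLD value across
      subjects before the edge pipeline (requires equal T across subjects);
    - ``"off"``: no residualization.

    ``clustering_scope="subject"`` (default) runs K-means on each subject's
    own eTS; ``"group"`` fits one set of centroids on the pooled edge rows
    of all subjects (equal T required) and labels each subject's edges with
    those shared centroids, so communities are comparable across subjects.
    """
    if covariate_mode not in ("features", "bold", "off"):
        raise ValueError(f"unknown covariate_mode: {covariate_mode!r}")
    if clustering_scope not in ("subject", "group"):
        raise ValueError(f"unknown clustering_scope: {clustering_scope!r}")
    manifest = manifest.set_index("subject_id", drop=False)
    order = [ts.subject_id for ts in subjects]
    if set(order) != set(manifest.index):
        raise ValueError("manifest subjects do not match supplied time series")
    manifest = manifest.loc[order]

    if covariate_mode == "bold":
        T = {ts.n_time for ts in subjects}
        if len(T) != 1:
            raise ValueError("bold covariate mode requires equal time length")
        stack = np.stack([ts.values for ts in subjects])  # subj x region x time
        C = manifest[list(covariate_columns)].to_numpy(dtype=float)
        flat = stack.reshape(len(subjects), -1)
        flat = residualize_covariates(flat, C)
        subjects = [
            RoiTimeSeries(flat[i].reshape(stack.shape[1:]),
                          subjects[i].region_ids, subjects[i].subject_id)
            for i in range(len(subjects))
        ]

    group_centroids = None
    if clustering_scope == "group":
        if len({ts.n_time for ts in subjects}) != 1:
            raise ValueError("group clustering scope requires equal T")
        pooled = np.vstack([
            compute_edge_time_series(zscore_timeseries(ts)).values
            for ts in subjects])
        pooled_labels = cluster_edges(
            EdgeTimeSeries(pooled, np.empty((0, 2))), k=k,
            n_restarts=n_restarts, seed=seed)
        # recover the fitted centroids from the pooled labeling
        group_centroids = np.vstack([
            pooled[pooled_labels.labels == s + 1].mean(axis=0)
            for s in range(k)])

    rows = []
    rng = np.random.default_rng(seed)
    for ts in subjects:
        subj_seed = int(rng.integers(0, 2**31 - 1))
        if group_centroids is None:
            ent, _ = subject_entropy(ts, k=k, n_restarts=n_restarts,
                                     seed=subj_seed)
        else:
            ets = compute_edge_time_series(zscore_timeseries(ts))
            d2 = ((ets.values[:, None, :] - group_centroids[None]) ** 2).sum(-1)
            lab = EdgeCommunityLabels(d2.argmin(axis=1) + 1, k,
                                      float(d2.min(axis=1).sum()))
            ent = nodal_entropy(community_profile(lab, ts.n_regions), k)
        agg = aggregate_entropy(ent, ts.region_ids, subnets)
        row = {"subject_id": ts.subject_id, **agg}
        row.update({f"nodal_{r}": v for r, v in zip(ts.region_ids, ent.values)})
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject_id")
    meta_cols = [c for c in manifest.columns if c != "subject_id"]
    table = manifest[meta_cols].join(table, how="inner").reset_index()

    if covariate_mode == "features":
        ent_cols = [c for c in table.columns
                    if c == "global" or c in SUBNETWORK_LABELS
                    or c.startswith("nodal_")]
        C = table[list(covariate_columns)].to_numpy(dtype=float)
        table[ent_cols] = residualize_covariates(
            table[ent_cols].to_numpy(dtype=float), C
        )
    return table
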