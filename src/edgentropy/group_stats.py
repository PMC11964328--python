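"""Three-group nonparametric statistics on entropy measures.

Kruskal-Wallis across HC / MDDNSI / MDDSI, Mann-Whitney U post-hoc tests
gated on FDR-significant omnibus results, Benjamini-Hochberg FDR control,
brain-behavior Pearson correlations within patient groups, and the
per-region two-sample t map (MDDSI minus MDDNSI) that feeds the
transcriptome association step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .edge_network import SUBNETWORK_LABELS

ENTROPY_MEASURES = ("global",) + SUBNETWORK_LABELS


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    p_fdr: float | None = None
    n_per_group: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)


@dataclass
class TStatMap:
    """Per-region two-sample t statistics, MDDSI minus MDDNSI direction."""

    values: np.ndarray
    df: int
    region_ids: list[str] = field(default_factory=list)


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H with tie correction; all-tied input gives H=0, p=1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, n_per_group=tuple(g.size for g in groups))
    H, p = stats.kruskal(*groups)
    return TestResult(float(H), float(p),
                      n_per_group=tuple(g.size for g in groups))


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact null distribution when the smaller sample has <= 8 observations
    and there are no ties; normal approximation with tie and continuity
    correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      n_per_group=(a.size, b.size), extra={"method": method})


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson r with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), float(p), n_per_group=(x.size,))


def two_sample_tmap(
    entropy_si: np.ndarray, entropy_nsi: np.ndarray,
    region_ids: list[str] | None = None,
) -> TStatMap:
    """Pooled-variance two-sample t per region, sign = mean(SI) - mean(NSI)."""
    A = np.atleast_2d(np.asarray(entropy_si, dtype=float))
    B = np.atleast_2d(np.asarray(entropy_nsi, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs >= 2 subjects")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the region count")
    nA, nB = A.shape[0], B.shape[0]
    sp2 = ((nA - 1) * A.var(axis=0, ddof=1) + (nB - 1) * B.var(axis=0, ddof=1)) \
        / (nA + nB - 2)
    if np.any(sp2 == 0):
        bad = np.where(sp2 == 0)[0]
        raise ValueError(f"zero pooled variance in region index {bad[:5]}")
    t = (A.mean(axis=0) - B.mean(axis=0)) / np.sqrt(sp2 * (1 / nA + 1 / nB))
    return TStatMap(t, nA + nB - 2, region_ids or [])


def run_group_analysis(
    table: pd.DataFrame,
    behavior_columns: list[str] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Omnibus + post-hoc + correlation analysis of an entropy table.

    Kruskal-Wallis over global and the 7 subnetwork entropies with BH-FDR
    across those 8 tests; for FDR-significant measures, the 3 pairwise
    Mann-Whitney tests with BH across all post-hoc p values; Pearson
    correlations of FDR-significant subnetwork entropies with the behavior
    columns within each patient group, BH-corrected within that family.
    """
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    behavior_columns = behavior_columns or []

    omnibus: dict[str, TestResult] = {}
    for m in ENTROPY_MEASURES:
        vals = [table.loc[table["group"] == g, m].to_numpy() for g in groups]
        omnibus[m] = kruskal_wallis(vals)
    adj = bh_fdr([omnibus[m].p_raw for m in ENTROPY_MEASURES])
    for m, pa in zip(ENTROPY_MEASURES, adj):
        omnibus[m].p_fdr = float(pa)
    significant = [m for m in ENTROPY_MEASURES if omnibus[m].p_fdr < alpha]

    posthoc: dict[str, dict[str, TestResult]] = {m: {} for m in significant}
    flat: list[TestResult] = []
    for m in significant:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = groups[i], groups[j]
                res = mann_whitney_u(
                    table.loc[table["group"] == gi, m].to_numpy(),
                    table.loc[table["group"] == gj, m].to_numpy())
                posthoc[m][f"{gi}_vs_{gj}"] = res
                flat.append(res)
    if flat:
        for res, pa in zip(flat, bh_fdr([r.p_raw for r in flat])):
            res.p_fdr = float(pa)

    correlations: dict[str, dict[str, TestResult]] = {}
    sig_subnets = [m for m in significant if m != "global"]
    patient_groups = [g for g in groups if g != "HC"]
    for g in patient_groups:
        fam: list[TestResult] = []
        correlations[g] = {}
        sub = table[table["group"] == g]
        for m in sig_subnets:
            for b in behavior_columns:
                res = pearson_correlation(sub[m].to_numpy(), sub[b].to_numpy())
                correlations[g][f"{m}~{b}"] = res
                fam.append(res)
        if fam:
            for res, pa in zip(fam, bh_fdr([r.p_raw for r in fam])):
                res.p_fdr = float(pa)

    return {
        "groups": groups,
        "alpha": alpha,
        "omnibus": omnibus,
        "significant_measures": significant,
        "posthoc": posthoc,
        "correlations": correlations,
    }


def report_to_dict(report: dict) -> dict:
    """JSON-serializable view of a group-analysis report."""
    def conv(r: TestResult) -> dict:
        return {"statistic": r.statistic, "p_raw": r.p_raw, "p_fdr": r.p_fdr,
                "n_per_group": list(r.n_per_group)}

    return {
        "groups": report["groups"],
        "alpha": report["alpha"],
        "omnibus": {m: conv(r) for m, r in report["omnibus"].items()},
        "significant_measures": report["significant_measures"],
        "posthoc": {m: {c: conv(r) for c, r in d.items()}
                    for m, d in report["posthoc"].items()},
        "correlations": {g: {c: conv(r) for c, r in d.items()}
                         for g, d in report["correlations"].items()},
    }


def tmap_from_table(table: pd.DataFrame) -> TStatMap:
    """Convenience: build the MDDSI-minus-MDDNSI nodal t map from a table."""
    nodal = [c for c in table.columns if c.startswith("nodal_")]
    A = table.loc[table["group"] == "MDDSI", nodal].to_numpy()
    B = table.loc[table["group"] == "MDDNSI", nodal].to_numpy()
    return two_sample_tmap(A, B, [c.removeprefix("nodal_") for c in nodal])
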