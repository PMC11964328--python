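"""Synthetic cohorts with planted edge-community structure.

Each region's signal is a mixture of a small number of latent module
signals, x_r(t) = sum_s w_rs c_s(t) + noise.  The mixing weights w_r are
Dirichlet draws whose concentration controls membership overlap: small
concentration gives one-hot rows (a region locked to one module, low nodal
entropy downstream), large concentration gives near-uniform rows (an
overlapping region, high entropy).  Module signals are piecewise-stationary:
their pairwise coupling switches across equal-length temporal states so the
edge time series carry non-trivial, clusterable co-fluctuation patterns.

Group effects are planted by shifting the log-concentration of regions in
targeted subnetworks, which moves those regions' expected mixing entropy.
Gene-expression maps are spatially smooth Gaussian-process draws; a known
subset of "signal" genes additionally tracks a supplied target brain map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .edge_network import SUBNETWORK_LABELS, RoiTimeSeries, SubnetworkMap

_GROUPS = ("HC", "MDDNSI", "MDDSI")


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic cohort generator."""

    n_regions: int = 50
    n_time: int = 440
    n_latent_modules: int = 8
    n_states: int = 8
    mixing_concentration: float = 0.5  # geometric-mean Dirichlet concentration
    mixing_spread: float = 10.0  # per-region conc. log-uniform in [c/spread, c*spread]
    noise_sd: float = 0.5
    state_boost: float = 4.0  # amplitude boost of each state's salient module
    state_damp: float = 0.3  # amplitude of the non-salient modules per state
    ar1: float = 0.0  # optional temporal autocorrelation of the noise
    group_sizes: tuple[int, int, int] = (98, 60, 90)  # HC, MDDNSI, MDDSI
    # per-group, per-subnetwork additive shift of log-concentration
    effect_map: dict[str, dict[str, float]] = field(default_factory=dict)
    behavior_r: float = -0.5  # target corr(score, planted subnetwork entropy)
    behavior_subnetwork: str = "dorsal_attention"
    covariate_leakage: float = 0.02  # amplitude leakage of covariates
    n_genes: int = 200
    n_signal_genes: int = 10
    spatial_smoothness: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_regions=self.n_regions, n_time=self.n_time,
                      n_latent_modules=self.n_latent_modules,
                      n_states=self.n_states, n_genes=self.n_genes)
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if any(g < 2 for g in self.group_sizes):
            raise ValueError("every group size must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.mixing_concentration <= 0 or self.mixing_spread < 1:
            raise ValueError("invalid mixing concentration/spread")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes cannot exceed n_genes")
        for g, sub in self.effect_map.items():
            if g not in _GROUPS:
                raise ValueError(f"unknown group in effect_map: {g!r}")
            for s in sub:
                if s not in SUBNETWORK_LABELS:
                    raise ValueError(f"unknown subnetwork in effect_map: {s!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth for a synthetic subject or cohort."""

    region_mixing_weights: np.ndarray  # region x module, rows sum to 1
    planted_entropy: np.ndarray  # per-region normalized mixing entropy
    signal_gene_ids: list[str] = field(default_factory=list)
    planted_group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    per_subject_entropy: pd.DataFrame | None = None


def mixing_entropy(weights: np.ndarray) -> np.ndarray:
    """Normalized Shannon entropy of each mixing-weight row, in [0, 1]."""
    w = np.asarray(weights, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(w > 0, w * np.log2(np.where(w > 0, w, 1.0)), 0.0)
    if w.shape[1] == 1:
        return np.zeros(w.shape[0])
    return np.clip(-terms.sum(axis=1) / np.log2(w.shape[1]), 0.0, 1.0)


def default_subnetwork_map(n_regions: int) -> SubnetworkMap:
    """Contiguous assignment of regions to the 7 canonical subnetworks."""
    labels = [SUBNETWORK_LABELS[(7 * i) // n_regions] for i in range(n_regions)]
    return SubnetworkMap({f"R{i:03d}": labels[i] for i in range(n_regions)})


def _state_mixers(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-state Cholesky factors coupling the latent module signals."""
    S = config.n_latent_modules
    mixers = np.empty((config.n_states, S, S))
    for st in range(config.n_states):
        cov = np.eye(S)
        if S >= 2:
            # couple one random module pair per state, modest strength
            i, j = rng.choice(S, size=2, replace=False)
            rho = rng.uniform(0.2, 0.5) * rng.choice([-1.0, 1.0])
            cov[i, j] = cov[j, i] = rho
        mixers[st] = np.linalg.cholesky(cov)
    return mixers


def _latent_signals(config: SyntheticConfig, mixers: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Piecewise-stationary module signals, shape (n_modules, n_time)."""
    S, T = config.n_latent_modules, config.n_time
    raw = rng.standard_normal((S, T))
    bounds = np.linspace(0, T, config.n_states + 1).astype(int)
    c = np.empty_like(raw)
    for st in range(config.n_states):
        a, b = bounds[st], bounds[st + 1]
        c[:, a:b] = mixers[st] @ raw[:, a:b]
        # each state foregrounds one module, so edge co-fluctuation carries a
        # module-specific temporal signature that K-means can pick up
        scale = np.full(S, config.state_damp)
        scale[st % S] = config.state_boost
        c[:, a:b] *= scale[:, None]
    return c


def _ar1_noise(shape: tuple[int, int], sd: float, phi: float,
               rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(shape) * sd
    if phi == 0:
        return eps
    innov_sd = np.sqrt(1.0 - phi**2)  # keeps marginal variance at sd^2
    out = np.empty_like(eps)
    out[:, 0] = eps[:, 0]
    for t in range(1, shape[1]):
        out[:, t] = phi * out[:, t - 1] + innov_sd * eps[:, t]
    return out


def _draw_weights(concentrations: np.ndarray, n_modules: int,
                  rng: np.random.Generator) -> np.ndarray:
    w = np.empty((concentrations.size, n_modules))
    for r, c in enumerate(concentrations):
        w[r] = rng.dirichlet(np.full(n_modules, c))
    return w


def region_concentrations(config: SyntheticConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-region Dirichlet concentrations, log-uniform around the mean."""
    lo = np.log(config.mixing_concentration / config.mixing_spread)
    hi = np.log(config.mixing_concentration * config.mixing_spread)
    return np.exp(rng.uniform(lo, hi, size=config.n_regions))


def simulate_bold(
    config: SyntheticConfig,
    subject_seed: int,
    weights: np.ndarray | None = None,
    subject_id: str = "S000",
    amplitude: float = 1.0,
) -> tuple[RoiTimeSeries, SyntheticTruth]:
    """Simulate one subject's region x time BOLD matrix.

    Identical (config, subject_seed) pairs reproduce bit-identical output.
    Pre-drawn mixing ``weights`` may be supplied (the cohort generator does
    this so that group effects live in the weights, not the seed stream).
    """
    config.validate()
    rng = np.random.default_rng((config.seed, subject_seed))
    mixers = _state_mixers(config, np.random.default_rng((config.seed, 777)))
    if weights is None:
        conc = region_concentrations(config, rng)
        weights = _draw_weights(conc, config.n_latent_modules, rng)
    c = _latent_signals(config, mixers, rng)
    noise = _ar1_noise((config.n_regions, config.n_time), config.noise_sd,
                       config.ar1, rng)
    # scale rows to unit signal norm so one-hot vs uniform rows see equal SNR
    row_scale = np.linalg.norm(weights, axis=1, keepdims=True)
    x = amplitude * ((weights / row_scale) @ c + noise)
    ts = RoiTimeSeries(x, [f"R{i:03d}" for i in range(config.n_regions)],
                       subject_id)
    truth = SyntheticTruth(weights, mixing_entropy(weights))
    return ts, truth


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[list[RoiTimeSeries], pd.DataFrame, SyntheticTruth]:
    """Simulate a three-group cohort with planted subnetwork effects.

    Returns the per-subject time series, a manifest (subject_id, group, sex,
    age, education, score) and the cohort truth.  The synthetic cognitive
    score correlates with each subject's planted entropy of the targeted
    subnetwork at approximately ``config.behavior_r``.
    """
    config.validate()
    if sum(config.group_sizes) == 0:
        raise ValueError("group sizes sum to zero")
    rng = np.random.default_rng((config.seed, 12345))
    base_conc = region_concentrations(config, rng)
    subnets = default_subnetwork_map(config.n_regions)
    region_ids = [f"R{i:03d}" for i in range(config.n_regions)]
    sub_of = [subnets.assignment[r] for r in region_ids]

    # demographic models per group: (age mean/sd, education mean/sd, p(female))
    demo = {"HC": (22.0, 2.6, 13.8, 2.5, 0.50),
            "MDDNSI": (25.0, 4.9, 14.9, 2.7, 0.68),
            "MDDSI": (22.0, 2.6, 16.0, 2.1, 0.67)}

    subjects: list[RoiTimeSeries] = []
    rows = []
    target = config.behavior_subnetwork
    target_idx = [i for i, s in enumerate(sub_of) if s == target]
    per_subject_ent = []
    counter = 0
    for group, size in zip(_GROUPS, config.group_sizes):
        shift = config.effect_map.get(group, {})
        conc = base_conc * np.exp([shift.get(s, 0.0) for s in sub_of])
        for _ in range(size):
            sid = f"S{counter:03d}"
            w = _draw_weights(conc, config.n_latent_modules,
                              np.random.default_rng((config.seed, 2, counter)))
            ent = mixing_entropy(w)
            a_mu, a_sd, e_mu, e_sd, p_f = demo[group]
            drng = np.random.default_rng((config.seed, 3, counter))
            age = a_mu + a_sd * drng.standard_normal()
            edu = e_mu + e_sd * drng.standard_normal()
            sex = int(drng.random() < p_f)  # 1 = female
            amplitude = 1.0 + config.covariate_leakage * (
                (age - a_mu) / a_sd + (edu - e_mu) / e_sd + (sex - 0.5)
            )
            ts, _ = simulate_bold(config, counter, weights=w, subject_id=sid,
                                  amplitude=amplitude)
            rows.append(dict(subject_id=sid, group=group, sex=sex,
                             age=round(age, 1), education=round(edu, 1)))
            per_subject_ent.append(
                dict(subject_id=sid, **{r: e for r, e in zip(region_ids, ent)}))
            subjects.append(ts)
            counter += 1

    manifest = pd.DataFrame(rows)
    ent_df = pd.DataFrame(per_subject_ent).set_index("subject_id")
    # behavioral score with configured correlation to the planted entropy of
    # the targeted subnetwork
    tgt_ent = ent_df.iloc[:, target_idx].mean(axis=1).to_numpy()
    srng = np.random.default_rng((config.seed, 4))
    zs = (tgt_ent - tgt_ent.mean()) / (tgt_ent.std() or 1.0)
    r = config.behavior_r
    score = r * zs + np.sqrt(max(0.0, 1 - r**2)) * srng.standard_normal(len(zs))
    manifest["score"] = 50 + 10 * score

    cohort_w = _draw_weights(base_conc, config.n_latent_modules,
                             np.random.default_rng((config.seed, 5)))
    truth = SyntheticTruth(
        region_mixing_weights=cohort_w,
        planted_entropy=mixing_entropy(cohort_w),
        planted_group_effects={g: dict(m) for g, m in config.effect_map.items()},
        per_subject_entropy=ent_df,
    )
    return subjects, manifest, truth


def simulate_expression(
    n_regions: int,
    n_genes: int,
    signal_gene_ids: list[int],
    target_map: np.ndarray,
    smoothness: float = 0.3,
    seed: int = 0,
    noise_amplitude: float = 1.0,
    signal_strength: float = 1.5,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Region x gene expression with spatially smooth maps.

    Signal genes are ``signal_strength * standardized(target_map)`` plus
    smooth spatial noise; the rest are smooth noise only.  All columns are
    standardized (zero mean, unit population SD).  Returns the expression
    DataFrame (index = region ids, columns = gene ids), region coordinates,
    and the Euclidean distance matrix.
    """
    target_map = np.asarray(target_map, dtype=float)
    if target_map.shape[0] != n_regions:
        raise ValueError("target_map length must equal n_regions")
    bad = [g for g in signal_gene_ids if not 0 <= g < n_genes]
    if bad:
        raise ValueError(f"signal gene ids outside 0..{n_genes - 1}: {bad}")
    rng = np.random.default_rng(seed)
    coords = rng.random((n_regions, 3))
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    kernel = np.exp(-d / smoothness) + 1e-8 * np.eye(n_regions)
    L = np.linalg.cholesky(kernel)
    noise = L @ rng.standard_normal((n_regions, n_genes))

    t = target_map - target_map.mean()
    sd = t.std()
    if sd > 0:
        t = t / sd
    X = noise_amplitude * noise
    X[:, list(signal_gene_ids)] += signal_strength * t[:, None]
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma == 0] = 1.0
    X = (X - mu) / sigma
    gene_ids = [f"G{j:04d}" for j in range(n_genes)]
    region_ids = [f"R{i:03d}" for i in range(n_regions)]
    df = pd.DataFrame(X, index=region_ids, columns=gene_ids)
    return df, coords, d


def write_cohort(
    outdir: str | Path,
    subjects: list[RoiTimeSeries],
    manifest: pd.DataFrame,
    truth: SyntheticTruth,
    subnets: SubnetworkMap,
    expression: pd.DataFrame | None = None,
    distance: np.ndarray | None = None,
) -> None:
    """Write a cohort as delimited text files plus a JSON truth record."""
    outdir = Path(outdir)
    tsdir = outdir / "timeseries"
    tsdir.mkdir(parents=True, exist_ok=True)
    for ts in subjects:
        pd.DataFrame(ts.values, index=ts.region_ids).to_csv(
            tsdir / f"{ts.subject_id}.tsv", sep="\t", header=False)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(
        {"region_id": list(subnets.assignment),
         "subnetwork": list(subnets.assignment.values())}
    ).to_csv(outdir / "subnetworks.csv", index=False)
    if expression is not None:
        expression.to_csv(outdir / "expression.csv", index_label="region_id")
    if distance is not None:
        np.savetxt(outdir / "distance.csv", distance, delimiter=",")
    record = dict(
        region_mixing_weights=truth.region_mixing_weights.tolist(),
        planted_entropy=truth.planted_entropy.tolist(),
        signal_gene_ids=truth.signal_gene_ids,
        planted_group_effects=truth.planted_group_effects,
    )
    (outdir / "truth.json").write_text(json.dumps(record, indent=1))


def read_subject_tsv(path: str | Path) -> RoiTimeSeries:
    """Read one subject's tab-separated regions x time matrix."""
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return RoiTimeSeries(df.to_numpy(dtype=float),
                         [str(r) for r in df.index], Path(path).stem)
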