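# edgentropy

Edge-centric analysis of resting-state functional brain networks: nodal
entropy from overlapping edge communities, three-group nonparametric
statistics, SVM classification, and connectome–transcriptome association —
implemented as a tested pipeline driven by synthetic cohorts with known
ground truth.

## The problem

Classical functional-connectivity analyses summarize each region pair by a
single Pearson correlation, discarding when two regions co-fluctuate.  The
edge-centric view unfolds the correlation in time: for z-scored signals
`z_m(t)`, the **edge time series** of the pair (m, n) is

```
e_mn(t) = z_m(t) · z_n(t),         mean_t e_mn(t) = Pearson r(m, n)
```

K-means clustering of the edge rows (k = 10 communities, 25 restarts,
minimum within-community sum of squares) groups edges with similar
co-fluctuation. Mapping edge communities back onto regions makes node
communities *overlapping*: region m participates in community s with
frequency

```
P_ms = 1/(N−1) · Σ_{n≠m} δ(g_mn, s)
```

(the fraction of its N−1 incident edges labelled s), and its **nodal
entropy**

```
E_m = − Σ_s P_ms log2 P_ms / log2 k   ∈ [0, 1]
```

quantifies how evenly the region's connections spread across communities:
0 = functionally integrated (one community), 1 = maximally overlapping.
Global and subnetwork entropy are means of `E_m` over all regions or over
the seven canonical resting-state subnetworks (visual, somatomotor, dorsal
attention, salience/ventral attention, limbic, frontoparietal control,
default mode).

Downstream, the pipeline compares entropy across three groups (healthy
controls, depressed patients without suicidal ideation, and with suicidal
ideation: HC / MDDNSI / MDDSI) with Kruskal–Wallis + Mann–Whitney tests
under BH-FDR, classifies groups with RFE + linear SVM, and regresses the
per-region patient-contrast t map on a region × gene expression matrix with
PLS — permutation-tested against spatial-autocorrelation-preserving
surrogate maps and stabilized with bootstrap gene-weight Z scores.

Because the corresponding clinical fMRI and donor-brain expression data are
restricted, the package ships a first-class synthetic generator: region
signals are Dirichlet-weighted mixtures of latent module signals with
state-switching dynamics, so every region has a *known* planted mixing
entropy, groups get planted subnetwork effects, and a known subset of genes
tracks the planted group-difference map.

## Worked example

```python
import edgentropy as eg

cfg = eg.SyntheticConfig(seed=0)           # 50 regions x 440 time points
ts, truth = eg.simulate_bold(cfg, 0)       # one subject + planted truth
ent, labels = eg.subject_entropy(ts, k=10, n_restarts=25, seed=1)

from scipy.stats import spearmanr
print(round(spearmanr(ent.values, truth.planted_entropy).statistic, 3))
```

prints `0.868` — the rank agreement between the nodal entropy estimated
from the simulated BOLD matrix and the entropy of the planted mixing
weights, i.e. the pipeline recovers the planted overlap structure.

The `analysis/` scripts run the full study at desk scale (30 subjects per
group, 50 regions):

```
python analysis/01_simulate.py      # cohort + expression -> scratch/cohort/
python analysis/02_entropy.py       # entropy table       -> results/
python analysis/03_group_stats.py   # KW / MWU / correlations + t map
python analysis/04_classify.py      # RFE + SVM, both tasks
python analysis/05_transcriptome.py # PLS + bootstrap + cell types
```

On the default seeds this reports, among other things: dorsal-attention
entropy significantly *lower* and default-mode entropy significantly
*higher* in the MDDSI group (Kruskal–Wallis p_FDR < 1e−4, both post-hoc
MDDNSI-vs-MDDSI p_FDR < 1e−4), MDDNSI-vs-MDDSI classification accuracy
93.3%, PLS1 explaining 81% of the t-map variance (permutation p ≈ 0.001)
and all 10 planted signal genes recovered in the PLS1± lists, with the
signal-bearing cell-type set the only significant overlap (p_FDR ≈ 0.0007).

The same stages are available as a CLI
(`edgentropy simulate|entropy|stats|classify|pls|celltype|run-all`).

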