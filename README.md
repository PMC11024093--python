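# calshape

Analysis pipeline for calcium signaling in geometrically confined breast
cancer cells, together with an epithelial–mesenchymal (EPI–MES) tumor
signature score.

Cells grown on adhesive micropatterns adopt a prescribed geometry — a
round disc ("O") or an elongated triangle ("L") of equal area — and the
shape of their cytosolic Ca²⁺ response to the PIEZO1 agonist YODA 1,
reported by a fluorescent indicator (GCaMP6m), changes with that
geometry: elongated cells sustain the Ca²⁺ rise longer. `calshape`
implements the quantitative machinery behind that comparison:

- **Kinetic model.** Each single-cell transient, baseline-subtracted so
  it starts at zero, is fitted with a constrained rise–decay model

      f(t) = −(b+c)·e^(−(τ_decay+τ_Δ)t) + b·e^(−τ_decay t) + c,

  where τ_rise = τ_decay + τ_Δ ≥ τ_decay guarantees a rise followed by
  a slower decay, a = b + c forces f(0) = 0, and c is the steady-state
  plateau. Fitting is bounded trust-region-reflective least squares
  restarted from a deterministic 10 × 6 × 5 grid of 300 initial points
  (decay time constants 15–1500 s, rate gaps 10⁻⁶–10⁻¹, decay
  amplitudes 0.1–1000; the plateau always starts at the median of the
  transient). Cells are fitted only when they pass three eligibility
  criteria: non-negative median, responsiveness by a one-sided Wilcoxon
  rank-sum test (α = 0.005, post-stimulus frames vs the 8 baseline
  frames), and a peak in the first half of the transient window.
- **Shape space.** Pooled trajectories are treated as vectors and
  decomposed by full-SVD PCA; the top three components define a PC
  space in which group means are compared per agonist concentration by
  Wilks'-lambda MANOVA (Bonferroni-adjusted across concentrations),
  with LDA providing the separation direction and centroid
  back-projection the average response per geometry.
- **Single-cell QC.** The four per-well object tables exported by
  high-content segmentation are merged per region and filtered by five
  rules (circularity window per geometry, exactly one nucleus, ≥ 20 px
  nucleus spacing, nucleus area < 300 μm², centroid agreement ≤ 30 μm).
- **EPI–MES score.** Tumor log2 expression is z-scored per gene;
  curated epithelial and mesenchymal gene lists are refined by
  correlation with their list-average z (Pearson r > 0.5); each tumor's
  score is mean EPI z − mean MES z, and tumors are stratified into
  rank quintiles (H-MES … H-EPI). Marker-correlation panels,
  average-linkage/Manhattan clustering of correlation matrices and
  comparative-Ct (2^−ΔΔCt) quantitation are included.
- **Synthetic data.** Seeded generators produce everything the pipeline
  consumes — model-based transients with group-dependent decay rates,
  object tables with planted QC violations and ground truth, and
  expression matrices with a latent EPI↔MES axis — so the full analysis
  runs with no downloads.

## Worked example

```python
import numpy as np
from calshape import (CohortSpec, simulate_cohort, drop_first_frame,
                      normalize_dff, baseline_split, check_fit_criteria,
                      fit_transient, fit_pca, compare_groups, summary_stats)

spec = CohortSpec(n_cells={"O": 30, "L": 30}, concentrations=(3.0,),
                  noise_sd=2.0, nonresponder_fraction=0.1, seed=42)
traces, truth = simulate_cohort(spec)
kept = drop_first_frame(traces)   # 61 raw frames -> 60 analyzed
dff = normalize_dff(kept)         # (F - F0)/F0, F0 = mean of frames 0..7

model = fit_pca(dff.values)
comp = compare_groups(model.scores, kept.metadata["shape_group"],
                      kept.metadata["concentration_uM"])[3.0]
```

Running the full loop (per-cell eligibility, fitting, summaries) prints:

```
cells x frames: (60, 60)
cell L0001: auc_early=286, auc_late=402, max_dff=0.75, last_dff=0.36
eligible responders: 49/60
mean fitted decay time  O: 66 s   L: 388 s
top-3 explained variance: [0.925 0.053 0.017] sum=0.994
MANOVA at 3 uM: Wilks lambda=0.488, F=19.6, p_bonf=8.49e-09
```

Reading the numbers: the example cell's ΔF/F₀ trace integrates to 286
(ΔF/F₀·s) before 750 s and 402 after, peaks at 0.75 and is still at
0.36 at the last frame — a sustained response. Elongated cells fit with
a mean decay time of ~388 s against ~66 s for round cells, the gap the
cohort generator plants. Three principal components carry 99.4% of the
trajectory variance, and the MANOVA separates the two geometries
decisively at 3 μM agonist.

The same workflow is scriptable from a shell:

```sh
calshape simulate traces --seed 1 --out runs/demo
calshape preprocess --in runs/demo/traces.tsv --out runs/demo/summary.tsv
calshape fit --in runs/demo/traces.tsv --out runs/demo/fits.tsv
calshape pca --in runs/demo/summary.tsv.normalized.tsv --out runs/demo/scores.tsv
calshape geometry --shape O --area 1100
```

## Layout

```
src/calshape/
  synthetic_data.py    seeded generators (transients, object tables, expression)
  trace_preprocess.py  frame dropping, dF/F0, baseline split, AUC summaries
  transient_model.py   rise-decay model, eligibility criteria, grid-restart fitting
  shape_space.py       trajectory PCA, MANOVA/LDA, centroid back-projection
  singlecell_qc.py     object-table merging and the five inclusion rules
  epimes.py            z-scoring, signature refinement, EPI-MES score, quintiles
  geometry.py          micropattern maximum-distance utilities
  cli.py               `calshape` console script
```

See `docs/methods.md` for the modelling assumptions, parameter
defaults and known limitations.
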