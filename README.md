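# agmfs — anchor-graph multi-modal feature selection

`agmfs` selects informative features from several feature tables ("modalities")
that describe the same subjects — the motivating setting is early diagnosis of
Alzheimer's disease from region-level MRI features, PET features, and CSF
biomarkers, where a few hundred subjects are described by ~93 + 93 + 3
features and only a small subset carries diagnostic signal.  It is written
for methodologists and applied researchers who have tabular multi-modal
biomarker data with class labels and want a joint, structure-aware feature
ranking rather than per-modality univariate filters.

## The model

With per-modality data `X_v ∈ R^{n×d_v}`, one-hot labels `Y ∈ R^{k×n}`,
per-modality weights `W_v ∈ R^{d_v×k}`, a shared bias `b ∈ R^k`, and a
feature-weight vector `θ ∈ R^d` (d = Σ d_v) on the probability simplex, the
selector minimizes

    min_{W,b,θ}  Σ_v ‖W_vᵀ Θ_v X_vᵀ + b 1ᵀ − Y‖_F²
                 + α Σ_v ‖W_v‖_{2,1}
                 + β Σ_v tr(W_vᵀ X_vᵀ (I − B_v B_vᵀ) X_v W_v)
    s.t.  θ ≥ 0,  θᵀ1 = 1

* the **ℓ2,1 norm** (sum of row norms) drives whole feature rows of `W_v`
  to zero — feature elimination;
* `Θ_v = diag(θ_v)` is a learned nonnegative weight per feature; its
  within-modality sums are reported as modality importance;
* the graph term uses a per-modality **anchor graph**: `m` anchor points are
  sampled, each sample is linked to its `k` nearest anchors with closed-form
  weights `z_ij = (d_{i,k+1} − d_ij)/(k·d_{i,k+1} − Σ_l d_il)`, and the
  implied row-stochastic similarity `S = ZΔ⁻¹Zᵀ = BBᵀ` (with
  `B = ZΔ^{-1/2}`) gives the graph Laplacian `L = I − BBᵀ` without ever
  forming an `n×n` matrix.

Optimization alternates exact block updates: a closed-form bias, a
reweighted (IRLS) linear solve per `W_v`, and an augmented-Lagrangian
solver with slack variable and `pos(·)` projection for the simplex-
constrained quadratic program in `θ`, finished to machine precision by an
active-set step.  In the default `additive` coupling the recorded objective
is provably non-increasing; `independent` coupling replicates the
per-modality update equations verbatim.  Downstream evaluation is
stratified k-fold cross-validation with a linear SVM on the selected
features (accuracy, sensitivity, specificity, AUC).

## Worked example

```python
import numpy as np
import agmfs

spec = agmfs.SyntheticSpec(seed=0)          # n=200, dims [93, 93, 3]
data, truth = agmfs.generate_dataset(spec)  # known informative support
state = agmfs.fit(data, agmfs.Hyperparams(seed=0))
print("converged:", state.converged, "sweeps:", state.n_sweeps)
print("objective: %.3f -> %.3f"
      % (state.objective_history[0], state.objective_history[-1]))

ranking = agmfs.rank_features(state, n_select=10)
print("modality importance:", np.round(ranking.modality_importance, 3))
print("top-10 global indices:", ranking.selected)
print("true informative (mod1):", truth.informative_index_sets[0])
```

prints

```
converged: True sweeps: 41
objective: 99.997 -> 28.593
modality importance: [0.584 0.416 0.   ]
top-10 global indices: [1, 3, 6, 31, 42, 54, 79, 92, 127, 145]
true informative (mod1): [1, 3, 6, 9, 28, 42, 45, 54, 79, 92]
```

The objective decreases monotonically from the zero-model value (≈ n/2 per
class, here ~100) until the relative change drops below 1e-5.  The learned
modality importances put most weight on the two imaging-style modalities, in
the order of their simulated signal strength, and 7 of the 10 top-ranked
features are planted informative features of modality 1 (two more are from
modality 2's true support).

## Command line

```bash
agmfs simulate  --config cfg.yaml --out-dir data/    # CSVs + ground truth
agmfs build-graph --modality data/modality_mod1.csv --m 60 --k 5 --seed 1 --out g.npz
agmfs fit       --data-dir data/ --config cfg.yaml --out model.json
agmfs select    --model model.json --n 20 --out ranking.tsv
agmfs evaluate  --data-dir data/ --config cfg.yaml --out results.json
agmfs grid      --data-dir data/ --config cfg.yaml --out grid.tsv
```

Data interchange is plain CSV (header row, sample-ID first column, one file
per modality, plus `labels.csv`); models and results are schema-versioned
JSON.  All commands are deterministic given `--seed`.

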