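# longfs

Longitudinal multimodal feature selection and classification for
case–control neuroimaging cohorts.

Studies of progressive brain disease (e.g. Alzheimer's disease vs. healthy
controls) typically summarise each subject as a vector of region-of-interest
(ROI) features — one matrix per imaging modality (fMRI, sMRI) and per visit
(baseline, 6, 12, 24 months). `longfs` identifies the small set of regions
that discriminate the diagnostic groups *jointly across visits and
modalities*, and classifies subjects by fusing the modalities with a
multi-kernel SVM. It is aimed at methodologists who need a tested, fully
reproducible implementation of this class of model, exercised end-to-end on
synthetic cohorts.

## The model

For modality $m = 1..M$ and visit $t = 1..T$, let $X_{mt} \in
\mathbb{R}^{N \times d}$ be the subject × ROI feature matrix and $Y \in
\{-1,+1\}^N$ the shared diagnosis. One coefficient vector $w_{mt}$ per cell
is estimated by minimizing

$$
\tfrac12 \sum_{m,t} \lVert Y - X_{mt} w_{mt} \rVert_2^2
\;+\; \beta \lVert W \rVert_{2,1}
\;+\; \lambda \sum_{m,t} (X_{mt} w_{mt})^\top L_{mt} (X_{mt} w_{mt})
\;+\; \mu \sum_{m} \sum_{t=1}^{T-1} \lVert w_{m,t+1} - w_{m,t} \rVert_1
$$

* $\lVert W\rVert_{2,1}$ sums the Euclidean norms of the rows of the stacked
  (modality·feature) × visit coefficient matrix, so each ROI is kept or
  dropped jointly across visits (group sparsity).
* $L_{mt}$ is the normalized Laplacian of a KNN **hypergraph** over subjects
  ($N$ hyperedges, one centred on each subject with its $k$ nearest
  neighbours, unit weights): the quadratic form penalizes prediction scores
  that disagree among neighbourhood co-members, preserving higher-order
  cohort structure.
* The fused-lasso term makes coefficient profiles piecewise-constant in
  time (smooth disease progression).

The objective is minimized by accelerated proximal gradient (FISTA search
points $S_i = W_i + \Delta_i (W_i - W_{i-1})$, $p_i = (1+\sqrt{1+4p_{i-1}^2})/2$,
backtracking line search) with an exact two-stage proximal operator: 1-D
total-variation denoising per row, then group soft-thresholding. ROIs with
non-zero coefficient rows are the selected features; each modality's
selected features are concatenated across visits, turned into a linear Gram
matrix, and the per-modality kernels are fused as $K = \sum_m \beta_m K_m$
with simplex weights tuned by inner tenfold cross-validation before a final
SVM (precomputed kernel, default $C=1$).

## Worked example

Simulate a small two-modality, four-visit cohort with 6 informative ROIs
out of 30 and evaluate the full pipeline by stratified cross-validation:

```sh
cat > spec.yaml <<'YAML'
n_per_class: 30
d: 30
T: 4
M: 2
n_informative: 6
effect_base: 1.0
effect_slope: 0.25
seed: 7
YAML
longfs simulate --spec spec.yaml --out cohort

cat > config.yaml <<'YAML'
data:
  dir: cohort
  modalities: [mod1, mod2]
  timepoints: [t1, t2, t3, t4]
hyperparams: {beta: 20, lam: 0.01, mu: 0.5, k: 5}
folds: 5
inner_folds: 5
seed: 0
output_dir: results
YAML
longfs evaluate --config config.yaml
```

prints the pooled metrics (percentages; AUC as a fraction):

```json
{
  "accuracy": 98.33333333333333,
  "sensitivity": 96.66666666666667,
  "specificity": 100.0,
  "f1": 98.3050847457627,
  "auc": 0.9933333333333334
}
```

and writes `metrics.csv`, `roc_points.csv`, `stability.csv`,
`top_features.csv` and a reproducibility `manifest.json` under `results/`.
The head of `top_features.csv`,

```
feature,count
14,10
16,10
27,10
4,5
6,5
```

counts in how many of the 5 outer folds × 2 modalities each feature was
selected; features 14, 16 and 27 — selected in every fold — are exactly the
ROIs planted in both modalities of this cohort (`cohort/ground_truth.json`:
mod1 {4, 7, 14, 16, 26, 27}, mod2 {6, 14, 15, 16, 21, 27}). Accuracy ~98%
with 100% specificity says the two classes are almost perfectly separated
once the informative regions are found.

Other subcommands: `longfs fit` (weights, selected features, objective
trace), `longfs ablate` (the four regularization configurations),
`longfs sweep` (hyperparameter grids; defaults are the ten-point
regularization set {0.0001, …, 5} and k ∈ {3, 5, 7, 10, 15, 20, 25, 30}).
Everything is also available as a library (`import longfs`).

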