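# Methods

## Model and assumptions

`longfs` implements longitudinal multimodal feature selection by penalized
multi-task regression followed by multi-kernel SVM classification. The
tasks are the (modality, visit) cells: each cell's coefficient vector
regresses the shared, time-invariant diagnosis $Y \in \{-1,+1\}^N$ on that
cell's subject × ROI matrix. Three penalties encode the structural
assumptions:

* **Group sparsity** ($\beta\,\lVert W\rVert_{2,1}$): disease-relevant
  regions are few and persist across visits, so sparsity is imposed on
  whole (modality, feature) rows spanning the $T$ visits. Groups do *not*
  span modalities: a region may matter in one modality only.
* **Hypergraph smoothness** ($\lambda$): prediction scores should vary
  smoothly over the cohort's neighbourhood structure. Each cell gets its
  own KNN hypergraph over *subjects* — one hyperedge per subject containing
  the subject plus its $k$ nearest neighbours (Euclidean distance on
  z-scored features), all hyperedge weights 1. The penalty is the quadratic
  form of the normalized hypergraph Laplacian
  $L = I - D_v^{-1/2} H W_e D_e^{-1} H^\top D_v^{-1/2}$, which is symmetric
  PSD and annihilates $D_v^{1/2}\mathbf{1}$.
* **Fused lasso** ($\mu$): coefficients change slowly between adjacent
  visits; the $\ell_1$ penalty on successive differences yields
  piecewise-constant temporal profiles. The empirical-risk term sums (not
  averages) over cells, so $\beta$ scales roughly with
  $\sqrt{N}\times$ the per-cell residual norm.

Vertices are subjects, not features: the penalty $w^\top X^\top L X w$
requires an $N \times N$ Laplacian. Diagnosis is treated as time-invariant
(one $Y$ for all cells). Binary classification only.

## Optimization

The smooth part (squared loss + hypergraph quadratic) is precomputed per
cell as $A_{mt} = X^\top X + 2\lambda X^\top L X$ and $b_{mt} = X^\top Y$,
making each gradient a $d\times d$ mat-vec. The non-smooth part's proximal
operator decomposes exactly per row: (1) 1-D total-variation denoising
across the $T$ entries (direct taut-string scan, exact in $O(T)$), then
(2) group soft-thresholding $\mathrm{row} \cdot \max(0, 1 -
\mathrm{step}\,\beta/\lVert\mathrm{row}\rVert_2)$. Fused-then-group is the
known exact order for this composite penalty; the test suite validates the
composition against a generic convex solver rather than assuming it.

The solver is FISTA with momentum $p_i = (1+\sqrt{1+4p_{i-1}^2})/2$,
$\Delta_i = (p_{i-1}-1)/p_i$, search point $S_i = W_i + \Delta_i (W_i -
W_{i-1})$, and backtracking (step halved until the quadratic model
upper-bounds the smooth part; the step may grow again by a factor 2 per
iteration, capped at `step_init`). Because plain FISTA is not monotone, a
safeguard retakes the step from $W_i$ with momentum restarted whenever the
extrapolated step would raise the objective — the recorded trace is
therefore non-increasing by construction. Convergence is declared after the
relative objective change stays below `tol` for three consecutive
iterations (a single flat step can be a momentum restart); hitting
`max_iter` sets a warning flag rather than raising. $W$ is initialized at
zero.

Defaults: `tol=1e-5`, `max_iter=1000`, `step_init=1.0`, `step_shrink=0.5`,
selection threshold `1e-8` (numerical zero, exposed as a flag).
Hyperparameter defaults `beta=0.1, lam=0.01, mu=0.1, k=7` are mid-grid
starting points; real use should sweep them (`longfs sweep`).

## Classification

Selected features per modality are concatenated across visits
(per-modality union of selected features, so every visit contributes the
same columns), linear Grams are fused as $\sum_m \beta_m K_m$ with simplex
weights on a grid (step 0.1 by default → 11 candidates for $M=2$, ties
broken toward the first candidate, first coordinate descending), scored by
stratified inner 10-fold CV accuracy on the training fold, and the winner
is refit as a precomputed-kernel SVM with default cost $C=1$. Kernels are
not trace-normalized: features are z-scored upstream. In the outer CV every
step — standardization statistics, hypergraph construction, fitting,
selection, kernel-weight tuning — uses the training fold only; the test
fold is only ever scored. If a fold's fit shrinks everything to zero, that
fold falls back to all features so it still produces predictions.

## Synthetic cohorts

`SimSpec` emulates the shape of the motivating study: two modalities, four
visits, 90 ROI features, balanced two-class cohorts. Entry model:

    x[i,j,t,m] = u_i + c_i * delta(j,t,m) + e,   e ~ N(0, noise_sd^2)

with subject random effect $u_i \sim N(0, 0.5^2)$ shared across all
features, visits and modalities (the simplest structure that induces
temporal correlation and satisfies the fused-lasso smoothness assumption —
deliberately not an AR process), case indicator $c_i \in \{0,1\}$, and
planted effect $\delta = \texttt{effect\_base} + (t-1)\,
\texttt{effect\_slope}$ on informative features. Defaults: 200 subjects per
class, 10 informative features, `effect_base=1.5` SD, `noise_sd=1`,
`effect_slope=0.25` (a progressive separation of ~0.25 SD per visit, so the
last visit separates best), `cross_modality_overlap=0.5` (half the
informative regions shared between modalities — modalities complement
rather than duplicate each other). `degrade` adds reproducible label flips
and extra feature noise for stress tests.

What the generator does **not** emulate: spatially correlated ROI noise,
site/scanner effects, missing visits (out of scope — missing cells are a
hard error, not imputed), non-Gaussian tails, and class imbalance. Passing
benchmarks on these cohorts demonstrates correctness of the machinery and
the direction of its qualitative behaviour, not clinical performance on
real imaging data.

## Benchmark study conditions

The acceptance benchmarks (`scripts/acceptance.py`, `tests/test_acceptance.py`)
use two frozen operating points:

* **Support recovery** — the default study-scale cohort (400 subjects,
  90 features, 10 informative, effect 1.5 SD). Selection penalties tuned
  once for this design: `beta=150, mu=1, lam=0.01, k=7, tol=1e-8` (the
  large `beta` reflects the summed, unaveraged loss at $N=400$, $T=4$).
  Reported: mean selection F1 against the planted support over 10 seeds.
* **Directional comparisons** — scaled-down cohorts chosen so the
  comparisons have room to move in both directions: 20 subjects per class,
  90 features, 3 informative with effect 1.0 SD growing 0.15/visit,
  subject effect 0.3; pipeline `beta=12, lam=0.01, mu=0.5, k=5`, 5 outer
  and 5 inner folds; 5–8 seeds per comparison. At this weak, concentrated
  signal the 87 irrelevant regions genuinely dilute an unregularized
  classifier, which is the regime where feature selection earns its keep;
  with stronger or denser signal a linear SVM on all features is already
  near-optimal and regularization cannot help.

Numerical tolerances in the suite: proximal operator vs. generic convex
solver 1e-4 (the oracle smooths the norms with an eps-continuation down to
1e-12; its own argmin error is bounded via strong convexity well below the
tolerance); Laplacian identities 1e-8–1e-10; APG vs. 20k-step subgradient
descent 1e-4; penalty-free reduction vs. pseudo-inverse least squares 1e-6.

## Design choices and limitations

* KNN hyperedges include the centre vertex (degree $k+1$); distance ties
  break toward the lower subject index, so builds are deterministic.
  Duplicate subjects are allowed.
* Scaling all hyperedge weights by a constant leaves the Laplacian
  unchanged (cancels between the weight matrix and vertex degrees);
  weighted or adaptive hyperedges are out of scope.
* The fused penalty differences are taken within each modality's weight
  matrix; the summed loss is not averaged over cells.
* Pooled metrics come from the summed confusion matrix and pooled decision
  scores across outer folds; per-fold values are reported alongside, since
  conventions differ. AUC is the trapezoid rule over the empirical ROC.
* Stratified folds throughout (plain k-fold risks single-class folds at
  small n); all fold assignments and inner seeds derive from the single
  run seed, and identical manifests reproduce outputs bit for bit.
* Dense linear algebra only; intended for cohorts up to a few thousand
  subjects. Multi-class problems, minibatch solvers and nonlinear kernels
  are out of scope.
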