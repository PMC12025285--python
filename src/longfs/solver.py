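"""Longitudinal multimodal group-sparse feature selection.

The model regresses a shared binary diagnosis ``Y`` in {-1, +1} on ROI
feature matrices ``X_mt`` (one per modality ``m`` and visit ``t``) with one
coefficient vector ``w_mt`` per cell, minimizing

    1/2 sum_{m,t} ||Y - X_mt w_mt||^2
      + beta * ||W||_{2,1}
      + lambda * sum_{m,t} (X_mt w_mt)^T L_mt (X_mt w_mt)
      + mu * sum_m sum_{t<T} ||w_m,t+1 - w_m,t||_1

where ``||W||_{2,1}`` sums Euclidean norms of the rows of the stacked
(modality x feature) x time coefficient matrix — so a feature is kept or
dropped jointly across visits — ``L_mt`` is the KNN-hypergraph Laplacian
built on the training subjects of cell (m, t), and the fused-lasso term
makes coefficient profiles piecewise-constant in time.

The objective splits into a smooth quadratic part (squared loss +
hypergraph penalty) and a non-smooth part (group sparsity + fused lasso)
whose proximal operator decomposes exactly row-by-row: 1-D total-variation
denoising across time, then group soft-thresholding.  Minimization is by
accelerated proximal gradient (FISTA search points, backtracking line
search), with a monotone safeguard: if an extrapolated step would raise the
objective, the step is retaken from the current iterate with momentum
restarted, so the objective trace never increases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hypergraph import HypergraphLaplacian, build_knn_hypergraph, laplacian

__all__ = [
    "CohortTable",
    "Hyperparams",
    "SolverState",
    "FeatureSelection",
    "objective",
    "smooth_gradient",
    "prox_nonsmooth",
    "fit",
    "select_features",
    "tv1d_denoise",
    "zscore_fit",
    "zscore_apply",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortTable:
    """A longitudinal multimodal cohort.

    ``features[(m, t)]`` is the N x d matrix of modality ``m`` at time point
    ``t`` (both 0-based); ``labels`` is the shared length-N diagnosis vector
    with entries in {-1, +1}.  Every cell must share the same subjects in
    the same order.
    """

    features: dict[tuple[int, int], np.ndarray]
    labels: np.ndarray
    modality_names: tuple[str, ...] = ()
    timepoint_names: tuple[str, ...] = ()
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("empty cohort")
        mods = sorted({m for m, _ in self.features})
        tps = sorted({t for _, t in self.features})
        if set(self.features) != {(m, t) for m in mods for t in tps}:
            raise ValueError("missing (modality, timepoint) cell")
        shapes = {X.shape for X in self.features.values()}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent cell shapes: {sorted(shapes)}")
        n, _ = shapes.pop()
        y = np.asarray(self.labels)
        if y.shape != (n,):
            raise ValueError("labels length does not match subject count")
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("labels must be in {-1, +1}")
        if len(set(np.unique(y))) < 2:
            raise ValueError("labels must contain both classes")
        for X in self.features.values():
            if not np.isfinite(X).all():
                raise ValueError("non-finite feature values")

    @property
    def n_modalities(self) -> int:
        return 1 + max(m for m, _ in self.features)

    @property
    def n_timepoints(self) -> int:
        return 1 + max(t for _, t in self.features)

    @property
    def n_subjects(self) -> int:
        return next(iter(self.features.values())).shape[0]

    @property
    def n_features(self) -> int:
        return next(iter(self.features.values())).shape[1]

    def cell(self, m: int, t: int) -> np.ndarray:
        return self.features[(m, t)]

    def subset(self, idx: np.ndarray) -> "CohortTable":
        """Row-subset every cell and the labels (e.g. one CV fold)."""
        return CohortTable(
            {k: X[idx] for k, X in self.features.items()},
            np.asarray(self.labels)[idx],
            self.modality_names,
            self.timepoint_names,
            self.feature_names,
        )

    def restrict(
        self,
        modalities: list[int] | None = None,
        timepoints: list[int] | None = None,
    ) -> "CohortTable":
        """Keep only the named modalities / time points (re-indexed from 0).

        Supports the single-time-point and single-modality comparison
        experiments: e.g. ``restrict(timepoints=[3])`` is the visit-4-only
        cohort, ``restrict(modalities=[0])`` the first modality alone.
        """
        mods = list(modalities) if modalities is not None else list(range(self.n_modalities))
        tps = list(timepoints) if timepoints is not None else list(range(self.n_timepoints))
        cells = {
            (mi, ti): self.features[(m, t)]
            for mi, m in enumerate(mods)
            for ti, t in enumerate(tps)
        }
        name = lambda names, ix: tuple(names[i] for i in ix) if names else ()
        return CohortTable(
            cells, self.labels,
            name(self.modality_names, mods),
            name(self.timepoint_names, tps),
            self.feature_names,
        )


@dataclass(frozen=True)
class Hyperparams:
    """Regularization weights and solver controls.

    beta  -- group-sparsity (l2,1) weight; larger -> fewer features kept.
    lam   -- hypergraph smoothness weight on prediction scores.
    mu    -- fused-lasso weight on adjacent-visit coefficient differences.
    k     -- KNN neighbourhood size for hypergraph construction.
    """

    beta: float = 0.1
    lam: float = 0.01
    mu: float = 0.1
    k: int = 7
    max_iter: int = 1000
    tol: float = 1e-5
    step_init: float = 1.0
    step_shrink: float = 0.5

    def __post_init__(self) -> None:
        if min(self.beta, self.lam, self.mu) < 0:
            raise ValueError("regularization weights must be >= 0")
        if not 0 < self.step_shrink < 1:
            raise ValueError("step_shrink must lie in (0, 1)")
        if self.tol <= 0 or self.step_init <= 0:
            raise ValueError("tol and step_init must be positive")
        if self.k < 1:
            raise ValueError("k must be a positive integer")

    def replace(self, **kw) -> "Hyperparams":
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d.update(kw)
        return Hyperparams(**d)


@dataclass
class SolverState:
    """Final APG internals, kept for diagnostics and reproducibility."""

    iterate: np.ndarray
    previous_iterate: np.ndarray
    search_point: np.ndarray
    momentum_scalar: float
    momentum_coeff: float
    step: float
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True


@dataclass(frozen=True)
class FeatureSelection:
    """Nonzero coefficients of a fitted weight tensor.

    ``per_timepoint[m]`` lists (feature, timepoint) pairs with
    ``|w_mt[j]| > threshold``; ``per_modality[m]`` is the union of selected
    features over time points, sorted.
    """

    per_timepoint: tuple[tuple[tuple[int, int], ...], ...]
    per_modality: tuple[tuple[int, ...], ...]


# ---------------------------------------------------------------------------
# Standardization helpers (training statistics only — reused by evaluation)
# ---------------------------------------------------------------------------


def zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and SDs of a training matrix; zero SDs become 1."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def zscore_apply(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mean) / sd


# ---------------------------------------------------------------------------
# Objective and gradient
# ---------------------------------------------------------------------------


def _as_tensor(W: np.ndarray, M: int, d: int, T: int) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.shape != (M, d, T):
        raise ValueError(f"weight tensor must have shape {(M, d, T)}, got {W.shape}")
    return W


def _nonsmooth_value(W: np.ndarray, beta: float, mu: float) -> float:
    rows = W.reshape(-1, W.shape[-1])  # (M*d, T): one group per (m, feature)
    val = beta * np.linalg.norm(rows, axis=1).sum()
    if W.shape[-1] > 1:
        val += mu * np.abs(np.diff(W, axis=2)).sum()
    return float(val)


def objective(
    data: CohortTable,
    laps: dict[tuple[int, int], HypergraphLaplacian],
    W: np.ndarray,
    hp: Hyperparams,
) -> float:
    """Full objective value at weight tensor ``W`` (shape M x d x T)."""
    M, T, d = data.n_modalities, data.n_timepoints, data.n_features
    W = _as_tensor(W, M, d, T)
    y = np.asarray(data.labels, dtype=float)
    val = 0.0
    for m in range(M):
        for t in range(T):
            X = data.cell(m, t)
            s = X @ W[m, :, t]
            val += 0.5 * float(np.sum((y - s) ** 2))
            if hp.lam > 0:
                val += hp.lam * float(s @ laps[(m, t)].matrix @ s)
    return val + _nonsmooth_value(W, hp.beta, hp.mu)


def smooth_gradient(
    data: CohortTable,
    laps: dict[tuple[int, int], HypergraphLaplacian],
    W: np.ndarray,
    hp: Hyperparams,
) -> np.ndarray:
    """Gradient of the smooth part, block (m, t):
    ``X^T (X w - Y) + 2 lambda X^T L X w``."""
    M, T, d = data.n_modalities, data.n_timepoints, data.n_features
    W = _as_tensor(W, M, d, T)
    y = np.asarray(data.labels, dtype=float)
    G = np.zeros_like(W)
    for m in range(M):
        for t in range(T):
            X = data.cell(m, t)
            s = X @ W[m, :, t]
            g = X.T @ (s - y)
            if hp.lam > 0:
                g = g + 2.0 * hp.lam * (X.T @ (laps[(m, t)].matrix @ s))
            G[m, :, t] = g
    return G


# ---------------------------------------------------------------------------
# Proximal operator of the non-smooth part
# ---------------------------------------------------------------------------


def tv1d_denoise(y: np.ndarray, lam: float) -> np.ndarray:
    """Exact 1-D total-variation denoising (fused-lasso signal approximator):
    ``argmin_x 1/2 ||x - y||^2 + lam * sum_t |x_{t+1} - x_t|``.

    Direct taut-string style scan: O(T), exact.  Used per coefficient row
    across time points.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= 1 or lam <= 0:
        return y.copy()
    x = np.empty(n)
    k = k0 = km = kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k < n - 1:
            if y[k + 1] + umin < vmin - lam:  # negative jump confirmed at km
                x[k0 : km + 1] = vmin
                k = k0 = km = kp = km + 1
                vmin = y[k]
                vmax = y[k] + 2.0 * lam
                umin = lam
                umax = -lam
            elif y[k + 1] + umax > vmax + lam:  # positive jump confirmed at kp
                x[k0 : kp + 1] = vmax
                k = k0 = km = kp = kp + 1
                vmin = y[k] - 2.0 * lam
                vmax = y[k]
                umin = lam
                umax = -lam
            else:  # no jump yet: extend the current segment
                k += 1
                umin += y[k] - vmin
                umax += y[k] - vmax
                if umin >= lam:
                    vmin += (umin - lam) / (k - k0 + 1)
                    umin = lam
                    km = k
                if umax <= -lam:
                    vmax += (umax + lam) / (k - k0 + 1)
                    umax = -lam
                    kp = k
        else:  # last sample reached: flush remaining segments
            if umin < 0.0:
                x[k0 : km + 1] = vmin
                k = k0 = km = km + 1
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
            elif umax > 0.0:
                x[k0 : kp + 1] = vmax
                k = k0 = kp = kp + 1
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
            else:
                x[k0:] = vmin + umin / (k - k0 + 1)
                return x


def prox_nonsmooth(V: np.ndarray, step: float, hp: Hyperparams) -> np.ndarray:
    """Proximal operator of ``step * (beta ||W||_{2,1} + mu * fused)``.

    Exact two-stage decomposition per (modality, feature) row: first the 1-D
    fused-lasso signal approximator across the T time points with penalty
    ``step * mu``, then group soft-thresholding of the row with
    ``step * beta``.  Fused-then-group is the known exact order for this
    composite penalty.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    V = np.asarray(V, dtype=float)
    T = V.shape[-1]
    rows = V.reshape(-1, T)
    out = np.empty_like(rows)
    lam_tv = step * hp.mu
    for i in range(rows.shape[0]):
        out[i] = tv1d_denoise(rows[i], lam_tv)
    if hp.beta > 0:
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        scale = np.maximum(0.0, 1.0 - step * hp.beta / np.where(norms > 0, norms, 1.0))
        out *= np.where(norms > 0, scale, 0.0)
    return out.reshape(V.shape)


# ---------------------------------------------------------------------------
# Accelerated proximal gradient
# ---------------------------------------------------------------------------


class _SmoothModel:
    """Precomputed quadratic form of the smooth part.

    Per cell (m, t): h contribution = 1/2 w^T A w - b^T w + 1/2 ||Y||^2
    with A = X^T X + 2 lam X^T L X and b = X^T Y, so each gradient
    evaluation is a d x d matrix-vector product.
    """

    def __init__(self, data: CohortTable, laps, lam: float):
        M, T = data.n_modalities, data.n_timepoints
        y = np.asarray(data.labels, dtype=float)
        self.M, self.T = M, T
        self.const = 0.5 * float(y @ y) * M * T
        self.A = {}
        self.b = {}
        for m in range(M):
            for t in range(T):
                X = data.cell(m, t)
                A = X.T @ X
                if lam > 0:
                    A = A + 2.0 * lam * (X.T @ laps[(m, t)].matrix @ X)
                    A = 0.5 * (A + A.T)
                self.A[(m, t)] = A
                self.b[(m, t)] = X.T @ y

    def value(self, W: np.ndarray) -> float:
        val = self.const
        for (m, t), A in self.A.items():
            w = W[m, :, t]
            val += 0.5 * float(w @ A @ w) - float(self.b[(m, t)] @ w)
        return val

    def gradient(self, W: np.ndarray) -> np.ndarray:
        G = np.empty_like(W)
        for (m, t), A in self.A.items():
            G[m, :, t] = A @ W[m, :, t] - self.b[(m, t)]
        return G


def fit(
    data: CohortTable,
    hp: Hyperparams,
    seed: int | None = None,
    laps: dict[tuple[int, int], HypergraphLaplacian] | None = None,
) -> tuple[np.ndarray, SolverState]:
    """Fit the model by accelerated proximal gradient.

    Builds one KNN-hypergraph Laplacian per (modality, time point) on the
    given subjects (features z-scored per column before distance
    computation, since Euclidean KNN is scale-sensitive), then iterates
    FISTA: search point ``S_i = W_i + Delta_i (W_i - W_{i-1})`` with
    ``Delta_i = (p_{i-1} - 1) / p_i`` and
    ``p_i = (1 + sqrt(1 + 4 p_{i-1}^2)) / 2``, a backtracking gradient step
    at ``S_i``, and the exact prox of the non-smooth part.  If the
    extrapolated step would increase the objective, the step is retaken from
    ``W_i`` with momentum restarted, making the recorded objective trace
    non-increasing.  The fit is deterministic; ``seed`` is accepted for
    interface symmetry and ignored.

    Returns the weight tensor (M x d x T) and the final :class:`SolverState`
    (``converged`` is False when ``max_iter`` was exhausted).
    """
    M, T, d = data.n_modalities, data.n_timepoints, data.n_features
    if laps is None:
        laps = {}
        for m in range(M):
            for t in range(T):
                X = data.cell(m, t)
                Z = zscore_apply(X, *zscore_fit(X)) if hp.lam > 0 else X
                laps[(m, t)] = (
                    laplacian(build_knn_hypergraph(Z, hp.k))
                    if hp.lam > 0
                    else HypergraphLaplacian(np.zeros((X.shape[0], X.shape[0])))
                )

    model = _SmoothModel(data, laps, hp.lam)
    F = lambda W: model.value(W) + _nonsmooth_value(W, hp.beta, hp.mu)

    W = np.zeros((M, d, T))
    W_prev = W.copy()
    p_prev = 1.0
    step = hp.step_init
    delta = 0.0
    S = W.copy()
    trace = [F(W)]
    converged = False

    def prox_step(point: np.ndarray, step: float) -> tuple[np.ndarray, float]:
        """Backtracking gradient+prox step from ``point``."""
        g = model.gradient(point)
        h_pt = model.value(point)
        while True:
            Z = prox_nonsmooth(point - step * g, step, hp)
            diff = Z - point
            quad = h_pt + float((g * diff).sum()) + float((diff**2).sum()) / (2 * step)
            if model.value(Z) <= quad + 1e-12 * max(1.0, abs(quad)):
                return Z, step
            step *= hp.step_shrink

    flat = 0
    for it in range(1, hp.max_iter + 1):
        p = (1.0 + np.sqrt(1.0 + 4.0 * p_prev**2)) / 2.0
        delta = (p_prev - 1.0) / p
        S = W + delta * (W - W_prev)
        # let the step recover from earlier backtracking shrinkage
        step = min(2.0 * step, hp.step_init)
        Z, step = prox_step(S, step)
        fz = F(Z)
        if fz > trace[-1] + 1e-12 * max(1.0, abs(trace[-1])):
            # extrapolation overshot: retake from W_i, restart momentum
            Z, step = prox_step(W, step)
            fz = F(Z)
            p = 1.0
        W_prev, W = W, Z
        p_prev = p
        trace.append(min(fz, trace[-1]))
        rel = abs(trace[-2] - trace[-1]) / max(1.0, abs(trace[-2]))
        # require sustained flatness: a single flat step can be a momentum
        # restart rather than convergence
        flat = flat + 1 if rel < hp.tol else 0
        if flat >= 3:
            converged = True
            break

    if not converged:
        warnings.warn("APG reached max_iter without meeting tol", RuntimeWarning)
    state = SolverState(
        iterate=W,
        previous_iterate=W_prev,
        search_point=S,
        momentum_scalar=p_prev,
        momentum_coeff=delta,
        step=step,
        objective_trace=trace,
        n_iter=len(trace) - 1,
        converged=converged,
    )
    return W, state


def select_features(W: np.ndarray, threshold: float = 1e-8) -> FeatureSelection:
    """Indices of coefficients exceeding ``threshold`` in magnitude."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    W = np.asarray(W)
    per_tp = []
    per_mod = []
    for m in range(W.shape[0]):
        mask = np.abs(W[m]) > threshold
        js, ts = np.nonzero(mask)
        per_tp.append(tuple(zip(js.tolist(), ts.tolist())))
        per_mod.append(tuple(sorted(set(js.tolist()))))
    return FeatureSelection(tuple(per_tp), tuple(per_mod))
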