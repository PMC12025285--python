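"""Independent oracles used by the test suite.

Each oracle takes a route disjoint from the implementation it checks:
brute-force enumeration for KNN membership, elementwise loops for Laplacian
quadratic forms and confusion matrices, a smoothed generic convex solver
for the proximal operator, and diminishing-step subgradient descent for the
full objective.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def knn_members_bruteforce(X: np.ndarray, k: int) -> list[set[int]]:
    """Hyperedge membership by sorting the full pairwise distance matrix."""
    n = X.shape[0]
    out = []
    for i in range(n):
        dists = [(float(np.linalg.norm(X[i] - X[j])), j) for j in range(n) if j != i]
        dists.sort()
        out.append({i} | {j for _, j in dists[:k]})
    return out


def theta_double_sum(hg) -> np.ndarray:
    """Theta entries by explicit summation over hyperedges."""
    n, ne = hg.incidence.shape
    theta = np.zeros((n, n))
    H, w = hg.incidence, hg.edge_weights
    dv, de = hg.vertex_degrees, hg.edge_degrees
    for i in range(n):
        for j in range(n):
            s = 0.0
            for e in range(ne):
                s += w[e] * H[i, e] * H[j, e] / de[e]
            theta[i, j] = s / np.sqrt(dv[i] * dv[j])
    return theta


def prox_oracle(V: np.ndarray, step: float, beta: float, mu: float) -> np.ndarray:
    """Generic convex solver for the prox problem.

    Minimizes 1/2||W - V||^2 + step*(beta*sum_row ||row||_2 + mu*fused)
    after smoothing the norms with sqrt(.^2 + eps), driving eps to zero by
    continuation with warm starts; the strong convexity of the quadratic
    bounds the argmin error by ~sqrt(penalty_mass * eps), far below test
    tolerances.
    """
    shape = V.shape
    T = shape[-1]
    v = V.reshape(-1, T)

    def solve(eps, x0):
        def fg(x):
            w = x.reshape(v.shape)
            diff = w - v
            f = 0.5 * (diff**2).sum()
            g = diff.copy()
            rn = np.sqrt((w**2).sum(axis=1) + eps)
            f += step * beta * rn.sum()
            g += step * beta * w / rn[:, None]
            if T > 1:
                dw = np.diff(w, axis=1)
                ad = np.sqrt(dw**2 + eps)
                f += step * mu * ad.sum()
                gd = step * mu * dw / ad
                g[:, 1:] += gd
                g[:, :-1] -= gd
            return f, g.ravel()

        return minimize(fg, x0, jac=True, method="L-BFGS-B",
                        options=dict(maxiter=20000, ftol=1e-18, gtol=1e-12)).x

    x = v.ravel()
    for eps in (1e-4, 1e-6, 1e-8, 1e-10, 1e-12):
        x = solve(eps, x)
    return x.reshape(shape)


def objective_loops(data, laps, W, beta, lam, mu) -> float:
    """Objective value by scalar loops (no matrix algebra)."""
    M, T = data.n_modalities, data.n_timepoints
    d, n = data.n_features, data.n_subjects
    y = np.asarray(data.labels, dtype=float)
    val = 0.0
    for m in range(M):
        for t in range(T):
            X = data.cell(m, t)
            s = np.zeros(n)
            for i in range(n):
                for j in range(d):
                    s[i] += X[i, j] * W[m, j, t]
            for i in range(n):
                val += 0.5 * (y[i] - s[i]) ** 2
            L = laps[(m, t)].matrix
            for i in range(n):
                for j in range(n):
                    val += lam * s[i] * L[i, j] * s[j]
    for m in range(M):
        for j in range(d):
            val += beta * float(np.sqrt(sum(W[m, j, t] ** 2 for t in range(T))))
        for t in range(T - 1):
            for j in range(d):
                val += mu * abs(W[m, j, t + 1] - W[m, j, t])
    return val


def subgradient_descent(data, laps, beta, lam, mu, n_steps=20000,
                        step_scale=None) -> float:
    """Diminishing-step subgradient descent on the full objective; returns
    the best objective value seen."""
    from longfs import solver as S

    M, T, d = data.n_modalities, data.n_timepoints, data.n_features
    hp = S.Hyperparams(beta=beta, lam=lam, mu=mu)
    W = np.zeros((M, d, T))
    if step_scale is None:
        lip = max(np.linalg.norm(data.cell(m, t), 2) ** 2
                  for m in range(M) for t in range(T))
        step_scale = 1.0 / lip
    best = S.objective(data, laps, W, hp)
    cur = W
    for k in range(1, n_steps + 1):
        g = S.smooth_gradient(data, laps, cur, hp)
        rows = cur.reshape(-1, T)
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        g21 = np.where(norms > 0, rows / np.where(norms > 0, norms, 1.0), 0.0)
        g = g + beta * g21.reshape(cur.shape)
        if T > 1:
            sgn = np.sign(np.diff(cur, axis=2))
            gf = np.zeros_like(cur)
            gf[:, :, 1:] += sgn
            gf[:, :, :-1] -= sgn
            g = g + mu * gf
        cur = cur - (step_scale / np.sqrt(k)) * g
        val = S.objective(data, laps, cur, hp)
        if val < best:
            best = val
    return best


def confusion_loop(y_true, y_pred, scores):
    """Metrics from an explicit element-by-element confusion count and a
    threshold-sweep ROC."""
    tp = fp = tn = fn = 0
    for yt, yp in zip(y_true, y_pred):
        if yt == 1 and yp == 1:
            tp += 1
        elif yt == -1 and yp == 1:
            fp += 1
        elif yt == -1 and yp == -1:
            tn += 1
        else:
            fn += 1
    acc = (tp + tn) / len(y_true)
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    # ROC by sweeping every score threshold, AUC by trapezoid
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    ys = np.asarray(y_true)[order]
    P = (ys == 1).sum()
    N = (ys == -1).sum()
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == -1)
    tpr = np.concatenate([[0], tps / P])
    fpr = np.concatenate([[0], fps / N])
    auc = float(np.trapezoid(tpr, fpr))
    return dict(accuracy=acc, sensitivity=sen, specificity=spe, f1=f1, auc=auc)


def selection_f1(selection, truth) -> float:
    """Mean F1 of selected vs planted feature sets across modalities."""
    f1s = []
    for m, planted in enumerate(truth):
        s = set(selection.per_modality[m])
        t = set(np.asarray(planted).tolist())
        tp = len(s & t)
        prec = tp / len(s) if s else 0.0
        rec = tp / len(t) if t else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return float(np.mean(f1s))


def random_hypergraph(rng, n=None, ne=None, weighted=True):
    """A random valid hypergraph: every vertex covered, no empty edge."""
    from longfs.hypergraph import Hypergraph

    n = n or int(rng.integers(3, 10))
    ne = ne or int(rng.integers(2, 8))
    H = (rng.random((n, ne)) < 0.4).astype(np.int8)
    for e in range(ne):  # no empty hyperedge
        if H[:, e].sum() == 0:
            H[rng.integers(n), e] = 1
    for v in range(n):  # no isolated vertex
        if H[v].sum() == 0:
            H[v, rng.integers(ne)] = 1
    w = rng.uniform(0.2, 3.0, size=ne) if weighted else np.ones(ne)
    return Hypergraph(H, w, (H @ w).astype(float), H.sum(axis=0))
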