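"""Independent brute-force oracles used to cross-check the fit engine.

These deliberately avoid the package's optimizer path: the grid oracle scans
lifetimes on a dense lattice and solves the amplitudes linearly at every
node, so its best objective bounds what any correct optimizer should reach.
"""

import numpy as np
from scipy.optimize import nnls

from flimkit.decay import IRFModel
from flimkit.fitting import _conv_exp


def grid_search_wls(counts: np.ndarray, bin_width_ps: float, irf: IRFModel,
                    shift_ps: float,
                    tau1_grid=np.arange(0.10, 1.50 + 1e-9, 0.01),
                    tau2_grid=np.arange(1.50, 4.00 + 1e-9, 0.01),
                    oversample: int = 4) -> tuple[float, float, float]:
    """Best weighted-least-squares objective over a dense lifetime lattice.

    At every (tau1, tau2) node the amplitudes (a0, a1, a2) >= 0 are solved by
    weighted linear estimation (unconstrained normal equations with an NNLS
    fallback when a coefficient goes negative). Returns (objective, tau1,
    tau2) at the best node; the objective is the sum of squared Neyman-
    weighted residuals over the full histogram.
    """
    n = counts.size
    y = counts.astype(float)
    w = 1.0 / np.maximum(y, 1.0)

    taus = np.concatenate([tau1_grid, tau2_grid])
    curves = np.stack([_conv_exp(t, irf, n, bin_width_ps, oversample, False,
                                 shift_ps) for t in taus])
    n1 = tau1_grid.size
    C1, C2 = curves[:n1], curves[n1:]
    ones = np.ones(n)

    # weighted inner products reused across the lattice
    g00 = float(w.sum())
    g01 = C1 @ w                      # (n1,)
    g02 = C2 @ w                      # (n2,)
    g11 = ((C1 * w) * C1).sum(axis=1)
    g22 = ((C2 * w) * C2).sum(axis=1)
    g12 = (C1 * w) @ C2.T             # (n1, n2)
    b0 = float((w * y).sum())
    b1 = (C1 * w) @ y
    b2 = (C2 * w) @ y
    yy = float((w * y) @ y)

    best = (np.inf, np.nan, np.nan)
    for i in range(n1):
        G = np.zeros((tau2_grid.size, 3, 3))
        G[:, 0, 0] = g00
        G[:, 0, 1] = G[:, 1, 0] = g01[i]
        G[:, 0, 2] = G[:, 2, 0] = g02
        G[:, 1, 1] = g11[i]
        G[:, 1, 2] = G[:, 2, 1] = g12[i]
        G[:, 2, 2] = g22
        rhs = np.stack([np.full(tau2_grid.size, b0),
                        np.full(tau2_grid.size, b1[i]), b2], axis=1)
        try:
            coef = np.linalg.solve(G, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # degenerate nodes (e.g. tau1 == tau2) solved via pseudoinverse
            coef = np.einsum("kij,kj->ki", np.linalg.pinv(G), rhs)
        neg = (coef < 0).any(axis=1)
        obj = yy - np.einsum("ki,ki->k", coef, rhs)
        for j in np.flatnonzero(neg):
            A = np.column_stack([ones, C1[i], C2[j]]) * np.sqrt(w)[:, None]
            c, rnorm = nnls(A, y * np.sqrt(w))
            obj[j] = rnorm**2
        j = int(np.argmin(obj))
        if obj[j] < best[0]:
            best = (float(obj[j]), float(tau1_grid[i]), float(tau2_grid[j]))
    return best


def exhaustive_kmeans_inertia(X: np.ndarray, k: int) -> float:
    """Global minimum k-means inertia by enumerating every assignment.

    Feasible only for tiny instances (k**n assignments).
    """
    n = X.shape[0]
    best = np.inf
    for code in range(k**n):
        labels = np.empty(n, dtype=int)
        c = code
        for i in range(n):
            labels[i] = c % k
            c //= k
        inertia = 0.0
        for j in range(k):
            pts = X[labels == j]
            if len(pts):
                inertia += ((pts - pts.mean(axis=0)) ** 2).sum()
        if inertia < best:
            best = inertia
    return float(best)
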