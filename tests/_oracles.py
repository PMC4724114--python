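"""Independent brute-force oracles for the test suite.

Everything here is deliberately built on a different route than the package:
the discrete gradient is materialized as an explicit matrix by applying
forward differences to basis vectors, the divergence is its exact negative
transpose, and the (weighted) ROF problem is solved by an accelerated
projected-gradient method on the dual — an explicit-projection algorithm,
not the semi-implicit fixed point used by the implementation under test.
"""

from __future__ import annotations

import numpy as np


def grad_matrix(shape: tuple[int, int]) -> np.ndarray:
    """Dense matrix G of the forward-difference gradient, rows [gx; gy]."""
    m, n = shape
    npx = m * n
    G = np.zeros((2 * npx, npx))

    def idx(i, j):
        return i * n + j

    for i in range(m):
        for j in range(n):
            if j < n - 1:  # horizontal difference
                G[idx(i, j), idx(i, j + 1)] += 1.0
                G[idx(i, j), idx(i, j)] -= 1.0
            if i < m - 1:  # vertical difference
                G[npx + idx(i, j), idx(i + 1, j)] += 1.0
                G[npx + idx(i, j), idx(i, j)] -= 1.0
    return G


def objective(u, v, lam, weights=None) -> np.ndarray:
    """(Weighted) ROF energy evaluated via the matrix gradient."""
    shape = u.shape[-2:]
    npx = shape[0] * shape[1]
    G = grad_matrix(shape)
    uf = u.reshape(u.shape[:-2] + (npx,))
    vf = v.reshape(v.shape[:-2] + (npx,))
    w = np.ones(npx) if weights is None else np.asarray(weights, float).reshape(npx)
    g = uf @ G.T
    tvn = np.sqrt(g[..., :npx] ** 2 + g[..., npx:] ** 2).sum(axis=-1)
    return 0.5 * ((uf - vf) ** 2 * w).sum(axis=-1) + np.asarray(lam) * tvn


def rof_oracle(v, lam, weights=None, iters: int = 4000):
    """Accelerated projected-gradient solver of the dual (weighted) ROF.

    Minimizes h(p) = 1/2 || lam * D^-1 div(p) - v ||_W^2 over |p_ij| <= 1
    with FISTA momentum and an explicit radial projection, then recovers
    u = v - lam * D^-1 div(p).  ``lam`` may be batched (trailing singleton).

    Returns (u, objective) with the objective computed by :func:`objective`.
    """
    v = np.asarray(v, float)
    shape = v.shape[-2:]
    npx = shape[0] * shape[1]
    G = grad_matrix(shape)
    w = np.ones(npx) if weights is None else np.asarray(weights, float).reshape(npx)
    vf = v.reshape(v.shape[:-2] + (npx,))
    lam_f = np.asarray(lam, float)
    if lam_f.ndim:
        lam_f = lam_f.reshape(lam_f.shape[: vf.ndim - 1] + (1,))
    lmax = float(np.max(lam_f))
    step = min(w.min(), 1.0) / (8.0 * lmax**2)

    def proj(q):
        q2 = q.reshape(q.shape[:-1] + (2, npx))
        mag = np.sqrt(q2[..., 0, :] ** 2 + q2[..., 1, :] ** 2)
        q2 = q2 / np.maximum(mag, 1.0)[..., None, :]
        return q2.reshape(q.shape)

    p = np.zeros(vf.shape[:-1] + (2 * npx,))
    y = p.copy()
    tk = 1.0
    for _ in range(iters):
        r = lam_f * (-(y @ G)) / w - vf  # residual of the primal recovery
        gradh = -lam_f * (r @ G.T)
        p_new = proj(y - step * gradh)
        tk1 = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        y = p_new + ((tk - 1.0) / tk1) * (p_new - p)
        p, tk = p_new, tk1
    u = vf - lam_f * (-(p @ G)) / w
    u = u.reshape(v.shape)
    return u, objective(u, v, np.squeeze(lam_f, -1) if lam_f.ndim else lam_f,
                        weights=weights)


def two_pixel_weighted_oracle(v, weights, lam, grid_n: int = 4001):
    """Dense 2-variable grid search (with refinement) for the weighted model.

    Minimizes 1/2 [w1 (u1-v1)^2 + w2 (u2-v2)^2] + lam |u2 - u1| to ~1e-6 by
    two rounds of grid refinement.
    """
    v1, v2 = v
    w1, w2 = weights

    def f(u1, u2):
        return 0.5 * (w1 * (u1 - v1) ** 2 + w2 * (u2 - v2) ** 2) + lam * np.abs(u2 - u1)

    lo1, hi1 = min(v) - 1.0, max(v) + 1.0
    lo2, hi2 = lo1, hi1
    for _ in range(3):
        u1 = np.linspace(lo1, hi1, grid_n)
        u2 = np.linspace(lo2, hi2, grid_n)
        vals = f(u1[:, None], u2[None, :])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        d1, d2 = (hi1 - lo1) / (grid_n - 1), (hi2 - lo2) / (grid_n - 1)
        lo1, hi1 = u1[i] - 2 * d1, u1[i] + 2 * d1
        lo2, hi2 = u2[j] - 2 * d2, u2[j] + 2 * d2
        best = (u1[i], u2[j], vals[i, j])
    return np.array(best[:2]), best[2]
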