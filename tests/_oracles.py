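"""Independent brute-force / quadrature oracles used by the tests.

These deliberately re-derive results by the most transparent method
available (per-cell scans, O(n^3) geometry, numerical quadrature) and
stay independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize, minimize_scalar


def shannon_entropy(proportions) -> float:
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def brute_force_shannon_focal(values, cell_size, radius, rows_cols=None):
    """Per-cell window scan Shannon diversity (centre-inclusion buffer)."""
    ny, nx = values.shape
    r = int(np.floor(radius / cell_size))
    out = {}
    targets = rows_cols or [(i, j) for i in range(ny) for j in range(nx)]
    for i, j in targets:
        members = []
        for di in range(-r, r + 1):
            for dj in range(-r, r + 1):
                if np.hypot(di, dj) * cell_size <= radius + 1e-9:
                    ii, jj = i + di, j + dj
                    if 0 <= ii < ny and 0 <= jj < nx and np.isfinite(values[ii, jj]):
                        members.append(values[ii, jj])
        if not members:
            out[(i, j)] = np.nan
            continue
        members = np.asarray(members)
        _, counts = np.unique(members, return_counts=True)
        out[(i, j)] = shannon_entropy(counts / counts.sum())
    return out


def brute_force_tri(values):
    """Root-sum-of-squares elevation difference to available 8 neighbours."""
    ny, nx = values.shape
    out = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            if not np.isfinite(values[i, j]):
                out[i, j] = np.nan
                continue
            s = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < ny and 0 <= jj < nx and np.isfinite(values[ii, jj]):
                        s += (values[i, j] - values[ii, jj]) ** 2
            out[i, j] = np.sqrt(s)
    return out


def brute_force_distance(mask, cell_size):
    """Centre-to-centre distance to the nearest True cell, full scan."""
    ny, nx = mask.shape
    rivers = np.argwhere(mask)
    out = np.empty((ny, nx))
    for i in range(ny):
        for j in range(nx):
            d2 = (rivers[:, 0] - i) ** 2 + (rivers[:, 1] - j) ** 2
            out[i, j] = np.sqrt(d2.min()) * cell_size
    return out


def brute_force_hull(points):
    """O(n^3) convex hull: an edge (i, j) is on the hull iff every other
    point lies on one side. Returns hull vertex set."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    hull_vertices = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            cross = d[0] * (pts[:, 1] - pts[i, 1]) - d[1] * (pts[:, 0] - pts[i, 0])
            if (cross >= -1e-9).all() or (cross <= 1e-9).all():
                hull_vertices.add(i)
                hull_vertices.add(j)
    return {tuple(np.round(pts[i], 9)) for i in hull_vertices}


def agq_loglik(df, beta, log_sigma, n_nodes=25):
    """Adaptive Gauss-Hermite marginal log-likelihood, single grouping
    factor named 'g', covariates x1..xk, Bernoulli-logit."""
    nodes, wts = hermegauss(n_nodes)
    sigma = np.exp(log_sigma)
    xcols = [c for c in df.columns if c.startswith("x")]
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in xcols])
    y = df["response"].to_numpy(dtype=float)
    eta0 = X @ np.asarray(beta, dtype=float)
    codes = df["g"].astype("category").cat.codes.to_numpy()
    total = 0.0
    for g in np.unique(codes):
        sel = codes == g
        e, yy = eta0[sel], y[sel]

        def neg_joint(u):
            eta = e + u
            return -(np.sum(yy * eta - np.logaddexp(0, eta)) - 0.5 * u * u / sigma**2)

        uhat = minimize_scalar(neg_joint, bounds=(-15, 15), method="bounded").x
        h = 1e-4
        curv = (neg_joint(uhat + h) - 2 * neg_joint(uhat) + neg_joint(uhat - h)) / h**2
        s = 1.0 / np.sqrt(max(curv, 1e-10))
        u = uhat + s * nodes
        eta = e[:, None] + u[None, :]
        ll = np.sum(yy[:, None] * eta - np.logaddexp(0, eta), axis=0)
        # integrand of exp(ll) N(u; 0, sigma^2) du under the quadrature's
        # exp(-x^2/2) weight, after the adaptive change of variables
        integrand = ll - 0.5 * u**2 / sigma**2 + 0.5 * nodes**2
        m = integrand.max()
        total += (
            np.log(np.sum(wts * np.exp(integrand - m)))
            + m
            + np.log(s)
            - np.log(sigma)
            - 0.5 * np.log(2 * np.pi)
        )
    return total


def agq_fit(df, start, n_nodes=25):
    """Maximize the AGQ marginal likelihood over (beta, log sigma)."""
    res = minimize(
        lambda p: -agq_loglik(df, p[:-1], p[-1], n_nodes=n_nodes),
        np.asarray(start, dtype=float),
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000},
    )
    return res.x[:-1], res.x[-1], -res.fun
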