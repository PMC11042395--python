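"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths of the package: closed-form
generalized eigenproblem for canonical correlations, brute-force angle
scanning for the 2-variable case, literal step-up FDR, and loop-based
graph-metric summation.
"""

import numpy as np
from scipy import linalg


def eig_oracle_rhos(X, Y):
    """Canonical correlations as sqrt-eigenvalues of
    Sxx^-1 Sxy Syy^-1 Syx (generalized-eigenproblem closed form)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    n = X.shape[0]
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    M = linalg.solve(Sxx, Sxy) @ linalg.solve(Syy, Sxy.T)
    ev = np.sort(np.real(linalg.eigvals(M)))[::-1]
    ev = np.clip(ev, 0.0, 1.0)
    K = min(X.shape[1], Y.shape[1])
    return np.sqrt(ev[:K])


def angle_scan_rho1(X, Y, grid=600, refinements=3):
    """First canonical correlation of two 2-column blocks by scanning
    both weight angles on a coarse-to-fine grid (final resolution well
    below 1e-4 radians)."""
    Xc = np.asarray(X, float)
    Yc = np.asarray(Y, float)
    Xc = Xc - Xc.mean(axis=0)
    Yc = Yc - Yc.mean(axis=0)

    lo_t, hi_t, lo_p, hi_p = 0.0, np.pi, 0.0, np.pi
    best_c = -1.0
    best_t = best_p = 0.0
    for _ in range(refinements + 1):
        ts = np.linspace(lo_t, hi_t, grid)
        ps = np.linspace(lo_p, hi_p, grid)
        U = Xc @ np.vstack([np.cos(ts), np.sin(ts)])   # (n, grid)
        V = Yc @ np.vstack([np.cos(ps), np.sin(ps)])
        U /= np.linalg.norm(U, axis=0)
        V /= np.linalg.norm(V, axis=0)
        C = np.abs(U.T @ V)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] > best_c:
            best_c = float(C[i, j])
            best_t, best_p = ts[i], ps[j]
        st = (hi_t - lo_t) / grid
        sp = (hi_p - lo_p) / grid
        lo_t, hi_t = best_t - 2 * st, best_t + 2 * st
        lo_p, hi_p = best_p - 2 * sp, best_p + 2 * sp
    return best_c


def brute_force_bh(p, q):
    """Benjamini-Hochberg step-up definition evaluated literally."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def brute_module_degree_z(W, modules):
    n = W.shape[0]
    k = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and modules[j] == modules[i]:
                k[i] += W[i, j]
    z = np.zeros(n)
    for m in set(modules):
        idx = [i for i in range(n) if modules[i] == m]
        if len(idx) < 2:
            continue
        mu = np.mean([k[i] for i in idx])
        sd = np.sqrt(np.mean([(k[i] - mu) ** 2 for i in idx]))
        for i in idx:
            z[i] = (k[i] - mu) / sd if sd > 0 else 0.0
    return z


def brute_participation(W, modules):
    n = W.shape[0]
    pc = np.zeros(n)
    for i in range(n):
        k_tot = sum(W[i, j] for j in range(n) if j != i)
        if k_tot == 0:
            continue
        s = 0.0
        for m in set(modules):
            k_m = sum(W[i, j] for j in range(n) if j != i and modules[j] == m)
            s += (k_m / k_tot) ** 2
        pc[i] = 1.0 - s
    return pc
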