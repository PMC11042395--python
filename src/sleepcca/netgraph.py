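"""Node-level segregation/integration metrics on weighted networks.

Given a symmetric weighted matrix (typically the edge-wise GLM beta
matrix of one latent component) and a module assignment (functional
networks), compute per node:

* module-degree z-score — within-module strength standardized against
  the module's distribution (segregation proxy);
* participation coefficient — 1 - sum over modules of the squared
  fraction of the node's strength placed in that module (integration
  proxy; 0 = fully within-module, upper bound 1 - 1/M for M modules);
* the ratio of min-max-normalized within:between module strength,
  summarizing each node's balance of segregation vs integration.

The stated formulas presuppose nonnegative strengths; signed input is
handled by a negative-weight policy (zero them out by default, or take
absolute values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def normalize_weights(W: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Scale a symmetric matrix by its largest absolute entry so weights
    lie in [-1, 1].  A zero matrix is returned unchanged with a warning."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.isfinite(W).all():
        raise ValueError("weight matrix must be finite")
    if not np.allclose(W, W.T, atol=tol):
        raise ValueError("weight matrix is not symmetric (tolerance 1e-8)")
    m = np.abs(W).max()
    if m == 0:
        warnings.warn("zero weight matrix; normalization skipped", RuntimeWarning)
        return W.copy()
    return W / m


def apply_negative_policy(W: np.ndarray, policy: str = "zero") -> np.ndarray:
    if policy == "zero":
        return np.where(W > 0, W, 0.0)
    if policy == "abs":
        return np.abs(W)
    raise ValueError(f"unknown negative-weight policy: {policy}")


def _check_map(W: np.ndarray, modules) -> np.ndarray:
    modules = np.asarray(modules)
    if len(modules) != W.shape[0]:
        raise ValueError("module labels do not cover all nodes")
    return modules


def module_degree_z(W: np.ndarray, modules) -> np.ndarray:
    """Within-module strength z-score per node.

    k_i is node i's summed strength to nodes of its own module;
    z_i = (k_i - mean_m) / sd_m over the module's nodes (population sd).
    A module with sd 0 (including size-1 modules) gets z = 0.
    """
    W = np.asarray(W, dtype=float)
    modules = _check_map(W, modules)
    Wd = W.copy()
    np.fill_diagonal(Wd, 0.0)
    z = np.zeros(W.shape[0])
    for m in np.unique(modules):
        idx = np.flatnonzero(modules == m)
        if len(idx) == 1:
            warnings.warn(f"module {m} has a single node; z set to 0", RuntimeWarning)
            continue
        k = Wd[np.ix_(idx, idx)].sum(axis=1)
        sd = k.std()
        z[idx] = (k - k.mean()) / sd if sd > 0 else 0.0
    return z


def participation_coefficient(W: np.ndarray, modules) -> np.ndarray:
    """PC_i = 1 - sum_m (k_im / k_i)^2, with k_i the node's total
    strength and k_im its strength into module m; k_i = 0 gives PC 0."""
    W = np.asarray(W, dtype=float)
    modules = _check_map(W, modules)
    Wd = W.copy()
    np.fill_diagonal(Wd, 0.0)
    k_tot = Wd.sum(axis=1)
    frac_sq = np.zeros(W.shape[0])
    for m in np.unique(modules):
        idx = np.flatnonzero(modules == m)
        k_m = Wd[:, idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_sq += np.where(k_tot != 0, (k_m / np.where(k_tot != 0, k_tot, 1.0))**2, 0.0)
    return np.where(k_tot != 0, 1.0 - frac_sq, 0.0)


def _minmax(v: np.ndarray) -> np.ndarray:
    rng = v.max() - v.min()
    if rng == 0:
        warnings.warn("zero range in min-max scaling; values set to 0.5", RuntimeWarning)
        return np.full_like(v, 0.5)
    return (v - v.min()) / rng


@dataclass
class NodeGraphMetrics:
    """Per-node graph metrics and the per-module median summary."""

    table: pd.DataFrame             # node, module, z, pc, ratio
    network_medians: pd.DataFrame   # module, median z / pc / ratio
    epsilon: float


def integration_segregation_ratio(W: np.ndarray, modules,
                                  node_labels=None,
                                  negative_policy: str = "zero",
                                  normalized: bool = False,
                                  epsilon: float = 1e-6) -> NodeGraphMetrics:
    """Per-node within:between balance on a weighted network.

    The input is normalized by its maximal |weight| (unless it already
    was: pass ``normalized=True``), negatives handled per policy, then
    module-degree z and participation coefficient are each min-max
    scaled to [0, 1] across nodes and the ratio
    (scaled z + eps) / (scaled PC + eps) is reported per node, with
    module-level medians for the network summary.
    """
    W = np.asarray(W, dtype=float)
    modules = _check_map(W, modules)
    if not normalized:
        W = normalize_weights(W)
    Wp = apply_negative_policy(W, negative_policy)
    z = module_degree_z(Wp, modules)
    pc = participation_coefficient(Wp, modules)
    sz = _minmax(z)
    spc = _minmax(pc)
    ratio = (sz + epsilon) / (spc + epsilon)
    if node_labels is None:
        node_labels = [f"node{i:03d}" for i in range(W.shape[0])]
    table = pd.DataFrame({
        "node": node_labels, "module": modules,
        "module_degree_z": z, "participation_coefficient": pc,
        "scaled_z": sz, "scaled_pc": spc, "ratio": ratio,
    })
    med = table.groupby("module", sort=False)[
        ["module_degree_z", "participation_coefficient", "ratio"]
    ].median().rename(columns=lambda c: f"median_{c}").reset_index()
    return NodeGraphMetrics(table=table, network_medians=med, epsilon=epsilon)
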