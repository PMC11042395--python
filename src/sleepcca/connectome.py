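"""Resting-state functional connectivity (RSFC) assembly and GLMs.

From per-run parcel time series: motion censoring (FD/DVARS thresholds
with dilation and minimum-segment rules), Pearson correlation over the
kept frames, Fisher z-transform, run averaging.  From per-subject
connectivity matrices: confound residualization, edge-wise and
network-wise linear models of connectivity on a composite score, with
BH-FDR over the network-wise tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class SchemaError(ValueError):
    pass


@dataclass
class ParcelNetworkMap:
    """Parcel -> network assignment (e.g. 400 cortical parcels into 17
    networks plus one subcortical group = 18)."""

    parcel_labels: np.ndarray
    network_labels: np.ndarray

    def __post_init__(self):
        self.parcel_labels = np.asarray(self.parcel_labels)
        self.network_labels = np.asarray(self.network_labels)
        if len(self.parcel_labels) != len(self.network_labels):
            raise SchemaError("parcel and network label arrays differ in length")
        if len(np.unique(self.parcel_labels)) != len(self.parcel_labels):
            raise SchemaError("duplicate parcel labels")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_labels)

    @property
    def networks(self) -> list:
        seen = []
        for n in self.network_labels:
            if n not in seen:
                seen.append(n)
        return seen

    def indices(self, network) -> np.ndarray:
        return np.flatnonzero(self.network_labels == network)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parcel_label": self.parcel_labels,
                             "network_label": self.network_labels})


@dataclass
class ConnectivityMatrix:
    """Symmetric parcels x parcels matrix of Fisher-z connectivity."""

    matrix: np.ndarray
    parcel_labels: np.ndarray
    subject_id: str = ""
    n_runs_averaged: int = 1

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise SchemaError("connectivity matrix must be square")
        if not np.isfinite(M).all():
            raise SchemaError("connectivity matrix contains non-finite entries")
        if not np.allclose(M, M.T, atol=1e-8):
            raise SchemaError("connectivity matrix is not symmetric")
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 0.0)
        self.matrix = M
        self.parcel_labels = np.asarray(self.parcel_labels)
        if len(self.parcel_labels) != M.shape[0]:
            raise SchemaError("parcel labels do not match matrix dimension")


@dataclass
class CensorMask:
    keep: np.ndarray                # per-frame: True = kept
    fd_max: float
    dvars_max: float
    run_excluded: bool

    @property
    def censored_fraction(self) -> float:
        return float(1.0 - self.keep.mean())


def build_censor_mask(fd, dvars, fd_max: float = 0.2,
                      dvars_max: float = 75.0,
                      min_segment: int = 5,
                      max_censored_fraction: float = 0.5) -> CensorMask:
    """Motion-censoring mask for one run.

    Frames with FD > ``fd_max`` (mm) or DVARS > ``dvars_max`` are marked
    as outliers and censored together with 1 frame before and 2 frames
    after; any surviving contiguous segment shorter than ``min_segment``
    frames is also censored; the run is excluded when more than
    ``max_censored_fraction`` of its frames end up censored.
    """
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.size == 0 or fd.shape != dvars.shape:
        raise SchemaError("FD and DVARS traces must be equal-length and nonempty")
    if fd_max <= 0 or dvars_max <= 0:
        raise ValueError("thresholds must be positive")
    n = fd.size
    censored = (fd > fd_max) | (dvars > dvars_max)
    dilated = censored.copy()
    for i in np.flatnonzero(censored):
        dilated[max(i - 1, 0): min(i + 3, n)] = True
    keep = ~dilated
    # drop kept segments shorter than min_segment
    i = 0
    while i < n:
        if keep[i]:
            j = i
            while j < n and keep[j]:
                j += 1
            if j - i < min_segment:
                keep[i:j] = False
            i = j
        else:
            i += 1
    frac = 1.0 - keep.mean()
    excluded = frac > max_censored_fraction
    return CensorMask(keep=keep, fd_max=fd_max, dvars_max=dvars_max,
                      run_excluded=bool(excluded))


def compute_rsfc(runs, parcel_labels=None, subject_id: str = "",
                 clip: float = 1e-7) -> ConnectivityMatrix:
    """Subject-level RSFC from per-run (parcels x time) series.

    ``runs`` is a list of (timeseries, CensorMask) pairs.  Per
    non-excluded run, Pearson correlation is computed over the kept
    frames, clipped to +/-(1 - ``clip``), Fisher z-transformed, and the
    z-matrices are averaged across runs.
    """
    z_mats = []
    p = None
    for ts, mask in runs:
        if mask.run_excluded:
            continue
        ts = np.asarray(ts, dtype=float)
        if p is None:
            p = ts.shape[0]
        elif ts.shape[0] != p:
            raise SchemaError("runs have inconsistent parcel counts")
        kept = ts[:, mask.keep]
        if kept.shape[1] < 3:
            raise SchemaError("fewer than 3 kept frames in a non-excluded run")
        sd = kept.std(axis=1)
        if (sd == 0).any():
            bad = np.flatnonzero(sd == 0)
            raise SchemaError(f"zero-variance parcel(s) in kept frames: {bad.tolist()}")
        r = np.corrcoef(kept)
        r = np.clip(r, -(1 - clip), 1 - clip)
        z = np.arctanh(r)
        np.fill_diagonal(z, 0.0)
        z_mats.append(z)
    if not z_mats:
        raise SchemaError("all runs excluded; subject has no usable RSFC data")
    avg = np.mean(z_mats, axis=0)
    if parcel_labels is None:
        parcel_labels = np.array([f"P{i + 1:03d}" for i in range(avg.shape[0])])
    return ConnectivityMatrix(matrix=avg, parcel_labels=parcel_labels,
                              subject_id=subject_id,
                              n_runs_averaged=len(z_mats))


# --- GLM machinery -------------------------------------------------------


def _edge_vectors(matrices: list[ConnectivityMatrix]) -> tuple[np.ndarray, tuple]:
    p = matrices[0].matrix.shape[0]
    iu = np.triu_indices(p, k=1)
    E = np.stack([m.matrix[iu] for m in matrices])
    return E, iu


def residualize_confounds(matrices: list[ConnectivityMatrix],
                          covariates) -> list[ConnectivityMatrix]:
    """Regress covariates (plus an intercept) out of every edge (OLS);
    residuals replace the edge values."""
    E, iu = _edge_vectors(matrices)
    C = np.asarray(covariates, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        C = covariates.to_numpy(dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = E.shape[0]
    if C.shape[0] != n:
        raise SchemaError("covariates do not match the number of subjects")
    if n <= C.shape[1] + 1:
        raise ValueError("need more subjects than covariates")
    Z = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        warnings.warn("collinear covariates; using pseudo-inverse", RuntimeWarning)
    beta = np.linalg.pinv(Z) @ E
    R = E - Z @ beta
    p = matrices[0].matrix.shape[0]
    out = []
    for i, m in enumerate(matrices):
        W = np.zeros((p, p))
        W[iu] = R[i]
        W = W + W.T
        out.append(ConnectivityMatrix(matrix=W, parcel_labels=m.parcel_labels,
                                      subject_id=m.subject_id,
                                      n_runs_averaged=m.n_runs_averaged))
    return out


@dataclass
class EdgeGLMResult:
    """Per-edge (or per network pair) simple-regression statistics of
    connectivity on a composite score: slope beta, its T statistic,
    F = T^2, p-value, and (for network-wise tests) BH q-value."""

    beta: np.ndarray
    tstat: np.ndarray
    fstat: np.ndarray
    pval: np.ndarray
    qval: np.ndarray | None
    exact_fit: np.ndarray
    df_resid: int
    n_subjects: int
    labels: np.ndarray | None = None
    table: pd.DataFrame | None = None


def _simple_glm(E: np.ndarray, x: np.ndarray):
    """Vectorized per-column regression E_j ~ 1 + x.

    Returns beta, t, F, p, exact-fit flag; columns with (numerically)
    zero residual variance are flagged and get p = 0.
    """
    n = E.shape[0]
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("constant composite score; cannot fit the GLM")
    Ec = E - E.mean(axis=0)
    sxy = xc @ Ec
    beta = sxy / sxx
    syy = np.einsum("ij,ij->j", Ec, Ec)
    df = n - 2
    rss = np.maximum(syy - beta**2 * sxx, 0.0)
    exact = rss <= 1e-12 * np.maximum(syy, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx)
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                     np.inf * np.sign(beta))
    t = np.where(exact & (beta == 0), 0.0, t)
    pv = np.where(exact, 0.0, 2 * stats.t.sf(np.abs(t), df))
    pv = np.where(exact & (beta == 0), 1.0, pv)
    return beta, t, t**2, pv, exact, df


def edgewise_glm(matrices: list[ConnectivityMatrix],
                 composite) -> EdgeGLMResult:
    """Simple linear model ``edge ~ intercept + composite`` for every
    parcel pair; betas are reported unthresholded (uncorrected)."""
    scores = np.asarray(composite, dtype=float)
    if len(scores) != len(matrices):
        raise SchemaError("one composite score per subject required")
    E, iu = _edge_vectors(matrices)
    beta, t, F, pv, exact, df = _simple_glm(E, scores)
    p = matrices[0].matrix.shape[0]

    def _full(v):
        M = np.zeros((p, p))
        M[iu] = v
        return M + M.T

    return EdgeGLMResult(beta=_full(beta), tstat=_full(t), fstat=_full(F),
                         pval=_full(pv), qval=None, exact_fit=_full(exact.astype(float)),
                         df_resid=df, n_subjects=len(scores),
                         labels=matrices[0].parcel_labels)


def network_average(matrix: np.ndarray | ConnectivityMatrix,
                    pmap: ParcelNetworkMap) -> pd.DataFrame:
    """Average a parcel-level matrix within and between networks.

    Off-diagonal block (A, B): mean over all parcel pairs (a in A, b in
    B).  Diagonal block (A, A): mean over unique unordered within-A
    pairs, excluding self-pairs; single-parcel networks get NaN there.
    """
    W = matrix.matrix if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, dtype=float)
    if W.shape[0] != pmap.n_parcels:
        raise SchemaError("matrix dimension does not match the parcel map")
    nets = pmap.networks
    out = pd.DataFrame(np.zeros((len(nets), len(nets))), index=nets, columns=nets)
    for a_i, a in enumerate(nets):
        ia = pmap.indices(a)
        for b in nets[a_i:]:
            ib = pmap.indices(b)
            if a == b:
                if len(ia) < 2:
                    val = np.nan
                else:
                    sub = W[np.ix_(ia, ia)]
                    val = sub[np.triu_indices(len(ia), k=1)].mean()
            else:
                val = W[np.ix_(ia, ib)].mean()
            out.loc[a, b] = val
            out.loc[b, a] = val
    return out


def networkwise_glm(matrices: list[ConnectivityMatrix], composite,
                    pmap: ParcelNetworkMap, q: float = 0.05) -> EdgeGLMResult:
    """Network-pair GLM with FDR.

    Per subject the connectivity matrix is first averaged within and
    between networks (for 18 networks: 18*19/2 = 171 unique pairs
    including diagonal blocks); each pair's averaged connectivity is
    regressed on the composite score, and BH-FDR is applied across the
    pairs.  The tidy table carries thresholded betas (0 unless q < q).
    """
    scores = np.asarray(composite, dtype=float)
    if len(scores) != len(matrices):
        raise SchemaError("one composite score per subject required")
    nets = pmap.networks
    subj_nets = np.stack([network_average(m, pmap).to_numpy() for m in matrices])
    iu = np.triu_indices(len(nets), k=0)
    E = subj_nets[:, iu[0], iu[1]]
    keep = ~np.isnan(E).any(axis=0)   # single-parcel within-network blocks
    beta = np.full(E.shape[1], np.nan)
    t = np.full_like(beta, np.nan)
    F = np.full_like(beta, np.nan)
    pv = np.full_like(beta, np.nan)
    exact = np.zeros_like(beta)
    b_, t_, F_, p_, ex_, df = _simple_glm(E[:, keep], scores)
    beta[keep], t[keep], F[keep], pv[keep], exact[keep] = b_, t_, F_, p_, ex_

    from .inference import fdr_bh
    qv = np.full_like(beta, np.nan)
    qv_k, _ = fdr_bh(pv[keep])
    qv[keep] = qv_k

    m = len(nets)

    def _full(v, fill=np.nan):
        M = np.full((m, m), fill)
        M[iu] = v
        M[(iu[1], iu[0])] = v
        return M

    table = pd.DataFrame({
        "network_a": [nets[i] for i in iu[0]],
        "network_b": [nets[j] for j in iu[1]],
        "beta": beta, "T": t, "F": F, "p": pv, "q": qv,
        "beta_thresholded": np.where(np.nan_to_num(qv, nan=1.0) < q, beta, 0.0),
    })
    return EdgeGLMResult(beta=_full(beta), tstat=_full(t), fstat=_full(F),
                         pval=_full(pv), qval=_full(qv),
                         exact_fit=_full(exact, fill=0.0),
                         df_resid=df, n_subjects=len(scores),
                         labels=np.array(nets), table=table)
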