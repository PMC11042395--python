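"""Significance and stability for two-block CCA.

* restricted permutation test: canonical correlations refit after
  permuting one block's rows by family-structure-preserving
  permutations; p = (1 + #{null >= observed}) / (1 + n_perm)
* Benjamini-Hochberg FDR
* bootstrap resampling of subjects with component re-alignment, giving
  loading standard deviations / CIs / q-values
* family-aware k-fold cross-validation: whole families are dealt to
  folds, training weights are projected onto held-out data, and the
  held-out sleep-behavior score correlation measures generalization.

The permutation refit exploits the fact that permuting rows of Y
commutes with column standardization and whitening: the k-th null
canonical correlation is the k-th singular value of Ux' P Uy, so each
draw costs one small SVD instead of a full refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cca import CCAResults, TwoBlockCCA, structure_loadings
from .families import (ExchangeabilityBlocks, FamilyStructure, build_blocks,
                       draw_permutation)
from .preprocess import DegenerateInputError, standardize


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (q-values, rejection mask at level ``q``).  q-values are the
    monotone adjusted p-values; the mask rejects all p_(i) with i up to
    the largest i such that p_(i) <= i*q/m.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    qvals_sorted = ranked * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(qvals_sorted[::-1])[::-1]
    qvals_sorted = np.minimum(qvals_sorted, 1.0)
    qvals = np.empty(m)
    qvals[order] = qvals_sorted
    thresh = ranked <= np.arange(1, m + 1) * q / m
    k = np.max(np.flatnonzero(thresh)) + 1 if thresh.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return qvals, reject


@dataclass
class PermutationResult:
    observed: np.ndarray            # K canonical correlations
    null: np.ndarray                # (n_perm, K) null canonical correlations
    perm_p: np.ndarray
    perm_q: np.ndarray
    seed: int
    n_perm: int
    scheme: str


def permutation_test(results: CCAResults, families: FamilyStructure,
                     n_perm: int = 10000, seed=0,
                     scheme: str = "two_level") -> PermutationResult:
    """Restricted permutation test of the canonical correlations.

    Rows of the behavioral block are permuted by admissible
    (family-preserving) permutations; the CCA is refit and the k-th
    canonical correlation of each refit forms the null for component k.
    Note the null is not centered at zero: the maximal correlation over
    weight vectors is positive even for unrelated blocks.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    model = results.model
    if families.n_subjects != model.X.shape[0]:
        raise ValueError("family table does not cover the model's subjects")
    blocks = build_blocks(families)
    rng = np.random.default_rng(seed)
    K = results.n_components

    Xs, _ = standardize(model.X)
    Ys, _ = standardize(model.Y)
    Ux, _, _ = model._whiten(Xs)
    Uy, _, _ = model._whiten(Ys)

    null = np.empty((n_perm, K))
    for b in range(n_perm):
        perm = draw_permutation(blocks, rng, scheme=scheme,
                                role_vector=families.role)
        d = np.linalg.svd(Ux.T @ Uy[perm], compute_uv=False)
        null[b] = np.clip(d[:K], 0.0, 1.0)

    obs = results.rho
    perm_p = (1.0 + np.sum(null >= obs[None, :], axis=0)) / (1.0 + n_perm)
    perm_q, _ = fdr_bh(perm_p)
    return PermutationResult(observed=obs.copy(), null=null, perm_p=perm_p,
                             perm_q=perm_q, seed=int(seed) if np.isscalar(seed) else 0,
                             n_perm=n_perm, scheme=scheme)


@dataclass
class BootstrapResult:
    x_mean: np.ndarray              # (p_x, K) bootstrap-mean loadings
    x_sd: np.ndarray
    x_ci_low: np.ndarray
    x_ci_high: np.ndarray
    x_z: np.ndarray
    x_p: np.ndarray
    x_q: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    y_ci_low: np.ndarray
    y_ci_high: np.ndarray
    y_z: np.ndarray
    y_p: np.ndarray
    y_q: np.ndarray
    n_boot: int
    n_sign_flips: int
    n_component_swaps: int
    n_redraws: int

    def significant(self, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        return self.x_q < q, self.y_q < q


def _align_components(W_ref: np.ndarray, W_rep: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match replicate components to reference components by maximal
    |correlation| of (concatenated) weight vectors, greedily, then
    sign-flip so the matched correlation is positive.

    Returns (order, signs): replicate component ``order[k]`` with sign
    ``signs[k]`` corresponds to reference component k.
    """
    K = W_ref.shape[1]
    C = np.corrcoef(W_ref.T, W_rep.T)[:K, K:]
    C = np.nan_to_num(C)
    order = np.full(K, -1)
    signs = np.ones(K)
    absC = np.abs(C).copy()
    for _ in range(K):
        i, j = np.unravel_index(np.argmax(absC), absC.shape)
        order[i] = j
        signs[i] = 1.0 if C[i, j] >= 0 else -1.0
        absC[i, :] = -1
        absC[:, j] = -1
    return order, signs


def bootstrap_loadings(results: CCAResults, n_boot: int = 1000, seed=0,
                       families: FamilyStructure | None = None,
                       resample: str = "subjects",
                       max_retries: int = 10) -> BootstrapResult:
    """Bootstrap stability of the structure coefficients.

    Per replicate, subjects are resampled with replacement (whole
    families when ``resample="families"``), the CCA refit, the
    replicate's components aligned to the original fit (greedy match on
    weight-vector |correlation|, then sign flip), and loadings
    recomputed on the replicate sample.  Each loading's significance is
    z = mean/sd against a standard normal, BH-corrected within each
    component's family of loadings.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    model = results.model
    n = model.X.shape[0]
    rng = np.random.default_rng(seed)
    K = results.n_components
    W_ref = np.vstack([results.x_weights, results.y_weights])

    if resample == "families":
        if families is None:
            raise ValueError('resample="families" requires a family table')
        fam_ids = np.asarray(families.family_id)
        uniq = np.unique(fam_ids)
        fam_members = {f: np.flatnonzero(fam_ids == f) for f in uniq}

    x_reps = np.empty((n_boot, model.X.shape[1], K))
    y_reps = np.empty((n_boot, model.Y.shape[1], K))
    n_flips = 0
    n_swaps = 0
    n_redraws = 0
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            if resample == "subjects":
                idx = rng.integers(0, n, size=n)
            else:
                fams = rng.choice(uniq, size=len(uniq), replace=True)
                idx = np.concatenate([fam_members[f] for f in fams])
            try:
                rep = TwoBlockCCA(model.X[idx], model.Y[idx],
                                  rank_tol=model.rank_tol).fit()
                break
            except DegenerateInputError:
                n_redraws += 1
                if attempt == max_retries:
                    raise
        Kr = min(K, rep.n_components)
        W_rep = np.vstack([rep.x_weights, rep.y_weights])[:, :rep.n_components]
        order, signs = _align_components(W_ref[:, :Kr], W_rep)
        n_flips += int(np.sum(signs < 0))
        n_swaps += int(np.sum(order[:Kr] != np.arange(Kr)))
        x_reps[b] = rep.x_loadings[:, order] * signs
        y_reps[b] = rep.y_loadings[:, order] * signs

    zcrit = stats.norm.ppf(0.975)

    def _stats(reps):
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0),
                         np.where(mean != 0, np.inf * np.sign(mean), 0.0))
        p = 2 * stats.norm.sf(np.abs(z))
        return mean, sd, mean - zcrit * sd, mean + zcrit * sd, z, p

    xm, xs, xlo, xhi, xz, xp = _stats(x_reps)
    ym, ys, ylo, yhi, yz, yp = _stats(y_reps)
    xq = np.empty_like(xp)
    yq = np.empty_like(yp)
    for k in range(K):
        pooled = np.concatenate([xp[:, k], yp[:, k]])
        qv, _ = fdr_bh(pooled)
        xq[:, k] = qv[: xp.shape[0]]
        yq[:, k] = qv[xp.shape[0]:]
    return BootstrapResult(
        x_mean=xm, x_sd=xs, x_ci_low=xlo, x_ci_high=xhi, x_z=xz, x_p=xp, x_q=xq,
        y_mean=ym, y_sd=ys, y_ci_low=ylo, y_ci_high=yhi, y_z=yz, y_p=yp, y_q=yq,
        n_boot=n_boot, n_sign_flips=n_flips, n_component_swaps=n_swaps,
        n_redraws=n_redraws,
    )


@dataclass
class CrossValResult:
    fold_assignment: np.ndarray     # per-subject fold index
    fold_corr: np.ndarray           # (k, K) held-out score correlations
    mean_corr: np.ndarray           # (K,)
    perm_p: np.ndarray | None
    k: int
    seed: int


def assign_folds(families: FamilyStructure, k: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Deal whole families round-robin into k folds after a seeded
    shuffle, so no family ever spans two folds and fold sizes differ by
    at most one family."""
    fam_ids = np.asarray(families.family_id)
    uniq = np.unique(fam_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(uniq) < k:
        raise ValueError(f"only {len(uniq)} families for {k} folds")
    shuffled = uniq[rng.permutation(len(uniq))]
    fold_of_family = {f: i % k for i, f in enumerate(shuffled)}
    return np.array([fold_of_family[f] for f in fam_ids])


def crossval(X, Y, families: FamilyStructure, k: int = 5, n_perm: int = 1000,
             seed=0, rank_tol: float = 1e-10) -> CrossValResult:
    """Family-aware k-fold cross-validation of CCA generalization.

    Per fold: fit on the training families, standardize the held-out
    data with the TRAINING means/sds, project onto the training weights,
    and correlate the held-out sleep and behavior scores per component.
    The permutation p-value permutes the held-out pairings by admissible
    within-fold permutations and compares the mean cross-fold
    correlation.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    folds = assign_folds(families, k, rng)

    fold_x_scores = []
    fold_y_scores = []
    fold_blocks = []
    Ks = []
    for f in range(k):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        if len(test) == 0:
            raise ValueError(f"fold {f} is empty")
        res = TwoBlockCCA(X[train], Y[train], rank_tol=rank_tol).fit()
        if len(test) <= res.n_components:
            raise ValueError(
                f"fold {f} has {len(test)} subjects, fewer than "
                f"{res.n_components}+1 needed to correlate scores"
            )
        xs, ys = res.project(X[test], Y[test])
        fold_x_scores.append(xs)
        fold_y_scores.append(ys)
        fold_blocks.append(build_blocks(families.subset(test)))
        Ks.append(res.n_components)
    K = min(Ks)

    def _corr_cols(a, b):
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        denom = np.linalg.norm(ac, axis=0) * np.linalg.norm(bc, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (ac * bc).sum(axis=0) / denom, 0.0)

    fold_corr = np.array([
        _corr_cols(fold_x_scores[f][:, :K], fold_y_scores[f][:, :K])
        for f in range(k)
    ])
    mean_corr = fold_corr.mean(axis=0)

    perm_p = None
    if n_perm and n_perm > 0:
        fam_sub = [families.subset(np.flatnonzero(folds == f)) for f in range(k)]
        null = np.empty((n_perm, K))
        for b in range(n_perm):
            acc = np.zeros(K)
            for f in range(k):
                perm = draw_permutation(fold_blocks[f], rng,
                                        role_vector=fam_sub[f].role)
                acc += _corr_cols(fold_x_scores[f][:, :K],
                                  fold_y_scores[f][perm][:, :K])
            null[b] = acc / k
        perm_p = (1.0 + np.sum(null >= mean_corr[None, :], axis=0)) / (1.0 + n_perm)

    return CrossValResult(fold_assignment=folds, fold_corr=fold_corr,
                          mean_corr=mean_corr, perm_p=perm_p, k=k,
                          seed=int(seed) if np.isscalar(seed) else 0)
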