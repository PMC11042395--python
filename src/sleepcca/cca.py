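"""Two-block canonical correlation analysis (CCA).

CCA finds pairs of linear combinations — one per block — whose
correlation is maximal, subject to orthogonality with earlier pairs.
Each pair is a *latent component* (LC): a canonical correlation rho_k,
weight vectors for both blocks, and per-subject canonical scores.
Interpretation uses *structure coefficients* (loadings): the Pearson
correlation between each original variable and its block's canonical
score, which remains meaningful under multicollinearity where raw
weights do not.

The fit whitens each block by a thin SVD (dropping singular values
below ``rank_tol`` times the largest) and takes the SVD of the
cross-product of the whitened bases — the numerically stable route to
the same solution as the generalized eigenproblem on the joint
covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import DegenerateInputError, Standardizer, standardize


class RankError(ValueError):
    pass


def structure_loadings(block_data, scores) -> np.ndarray:
    """Structure coefficients: Pearson correlation of every column of
    ``block_data`` with each score vector.

    Returns a (p, K) array when ``scores`` is (n, K), or (p,) for a
    single score vector.
    """
    X = np.asarray(block_data, dtype=float)
    if isinstance(block_data, pd.DataFrame):
        X = block_data.to_numpy(dtype=float)
    S = np.asarray(scores, dtype=float)
    single = S.ndim == 1
    if single:
        S = S[:, None]
    if X.shape[0] != S.shape[0]:
        raise ValueError("data and scores must cover the same subjects")
    Xc = X - X.mean(axis=0)
    Sc = S - S.mean(axis=0)
    xn = np.linalg.norm(Xc, axis=0)
    sn = np.linalg.norm(Sc, axis=0)
    if (xn == 0).any() or (sn == 0).any():
        raise DegenerateInputError("zero-variance column or score in loading computation")
    L = (Xc / xn).T @ (Sc / sn)
    L = np.clip(L, -1.0, 1.0)
    return L[:, 0] if single else L


def composite_scores(sleep_scores, behavior_scores, mode: str = "averaged") -> np.ndarray:
    """Per-subject composite for one LC.

    mode="averaged" (default): (sleep + behavior)/2, the composite used
    as the predictor in connectome GLMs.  mode="sleep" / "behavior":
    use a single block's canonical scores (control-analysis variant).
    """
    s = np.asarray(sleep_scores, dtype=float)
    b = np.asarray(behavior_scores, dtype=float)
    if s.shape != b.shape:
        raise ValueError(f"score length mismatch: {s.shape} vs {b.shape}")
    if mode == "averaged":
        return (s + b) / 2.0
    if mode == "sleep":
        return s.copy()
    if mode == "behavior":
        return b.copy()
    raise ValueError(f"unknown composite mode: {mode}")


class TwoBlockCCA:
    """Canonical correlation model between a sleep block X and a
    behavioral block Y.

    Parameters
    ----------
    X, Y : (n, p_x) and (n, p_y) arrays or DataFrames
        Raw (unstandardized) blocks over the same subjects.
    rank_tol : float
        Relative singular-value cutoff for the effective rank of each
        block.
    ridge : float
        Optional ridge regularization added to the block covariances
        (off by default; the intended regime is n >> p).
    """

    def __init__(self, X, Y, x_names=None, y_names=None,
                 rank_tol: float = 1e-10, ridge: float = 0.0):
        if isinstance(X, pd.DataFrame):
            x_names = list(X.columns)
        if isinstance(Y, pd.DataFrame):
            y_names = list(Y.columns)
        self.X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float)
        self.Y = np.asarray(Y, dtype=float) if not isinstance(Y, pd.DataFrame) else Y.to_numpy(float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("blocks must be 2-D")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("blocks must have the same number of subjects")
        self.x_names = x_names if x_names is not None else [f"x{j}" for j in range(self.X.shape[1])]
        self.y_names = y_names if y_names is not None else [f"y{j}" for j in range(self.Y.shape[1])]
        self.rank_tol = float(rank_tol)
        self.ridge = float(ridge)

    @classmethod
    def from_dataframes(cls, sleep: pd.DataFrame, behavior: pd.DataFrame, **kwargs) -> "TwoBlockCCA":
        """Build the model from two subject-aligned DataFrames (indexes
        must agree; rows with any missing value are rejected, mirroring
        complete-case analysis)."""
        if not sleep.index.equals(behavior.index):
            common = sleep.index.intersection(behavior.index)
            if len(common) == 0:
                raise ValueError("no common subjects between blocks")
            sleep, behavior = sleep.loc[common], behavior.loc[common]
        return cls(sleep, behavior, **kwargs)

    def fit(self) -> "CCAResults":
        n, px = self.X.shape
        py = self.Y.shape[1]
        if n <= px or n <= py:
            raise RankError(
                f"need more subjects than variables per block (n={n}, p_x={px}, "
                f"p_y={py}); reduce dimensionality first"
            )
        Xs, std_x = standardize(self.X)
        Ys, std_y = standardize(self.Y)

        Ux, wx_basis, rx = self._whiten(Xs)
        Uy, wy_basis, ry = self._whiten(Ys)
        if rx < px or ry < py:
            warnings.warn(
                f"rank-deficient block(s): effective ranks ({rx}, {ry}) below "
                f"({px}, {py}); components reduced", RuntimeWarning,
            )
        K = min(rx, ry)
        A, d, Bt = np.linalg.svd(Ux.T @ Uy, full_matrices=False)
        rho = np.clip(d[:K], 0.0, 1.0)
        scale = np.sqrt(n - 1)
        Wx = wx_basis @ A[:, :K] * scale
        Wy = wy_basis @ Bt.T[:, :K] * scale
        x_scores = Xs @ Wx
        y_scores = Ys @ Wy

        x_loadings = structure_loadings(Xs, x_scores)
        y_loadings = structure_loadings(Ys, y_scores)
        # deterministic sign convention: per component, the sleep variable
        # with the largest |loading| gets a positive loading
        flips = np.ones(K)
        for k in range(K):
            j = int(np.argmax(np.abs(x_loadings[:, k])))
            if x_loadings[j, k] < 0:
                flips[k] = -1.0
        Wx *= flips
        Wy *= flips
        x_scores *= flips
        y_scores *= flips
        x_loadings *= flips
        y_loadings *= flips

        # covariance explained: squared score-covariance fractions.
        # with unit-variance scores cov(score_x_k, score_y_k) = rho_k.
        cov_k = np.array([np.cov(x_scores[:, k], y_scores[:, k], ddof=1)[0, 1]
                          for k in range(K)])
        cov_explained = cov_k**2 / np.sum(cov_k**2)

        return CCAResults(
            model=self, rho=rho, x_weights=Wx, y_weights=Wy,
            x_scores=x_scores, y_scores=y_scores,
            x_loadings=x_loadings, y_loadings=y_loadings,
            cov_explained=cov_explained,
            x_standardizer=std_x, y_standardizer=std_y,
            sign_flips=flips, n_obs=n,
        )

    def _whiten(self, Zs: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        U, s, Vt = np.linalg.svd(Zs, full_matrices=False)
        r = int(np.sum(s > self.rank_tol * s[0]))
        s_eff = s[:r]
        if self.ridge > 0:
            s_eff = np.sqrt(s_eff**2 + self.ridge)
            U = Zs @ (Vt[:r].T / s_eff)
        else:
            U = U[:, :r]
        basis = Vt[:r].T / s_eff
        return U, basis, r


def fit_cca(X, Y, rank_tol: float = 1e-10, **kwargs) -> "CCAResults":
    """Functional wrapper: fit a :class:`TwoBlockCCA` on two blocks."""
    return TwoBlockCCA(X, Y, rank_tol=rank_tol, **kwargs).fit()


@dataclass
class CCAResults:
    """Fitted CCA: canonical correlations, weights, scores, loadings and
    covariance-explained fractions, plus the training standardizers
    needed for out-of-sample projection.

    Inference (permutation significance, bootstrap loading stability,
    family-aware cross-validation) hangs off this object; see the
    corresponding methods.
    """

    model: TwoBlockCCA
    rho: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    cov_explained: np.ndarray
    x_standardizer: Standardizer
    y_standardizer: Standardizer
    sign_flips: np.ndarray
    n_obs: int
    perm_p: np.ndarray | None = None
    perm_q: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return len(self.rho)

    def project(self, X_new=None, Y_new=None):
        """Project new blocks onto the trained weights.

        New data are standardized with the TRAINING means/sds, then
        multiplied by the canonical weights.  Applying to the training
        blocks reproduces the training scores exactly.
        """
        out = []
        for block, std, W, names in (
            (X_new, self.x_standardizer, self.x_weights, self.model.x_names),
            (Y_new, self.y_standardizer, self.y_weights, self.model.y_names),
        ):
            if block is None:
                out.append(None)
                continue
            if isinstance(block, pd.DataFrame):
                missing = [c for c in names if c not in block.columns]
                extra = [c for c in block.columns if c not in names]
                if missing or extra:
                    raise ValueError(
                        f"column mismatch: missing={missing}, extra={extra}"
                    )
                block = block[names]
            Z = std.transform(block)
            flip_correction = 1.0  # flips already folded into the weights
            out.append(Z @ W * flip_correction)
        return tuple(out)

    def composite_scores(self, k: int = 0, mode: str = "averaged") -> np.ndarray:
        return composite_scores(self.x_scores[:, k], self.y_scores[:, k], mode=mode)

    # --- inference entry points (implemented in sleepcca.inference) ----

    def permutation_test(self, families, n_perm: int = 10000, seed=0,
                         scheme: str = "two_level"):
        from .inference import permutation_test

        res = permutation_test(self, families, n_perm=n_perm, seed=seed, scheme=scheme)
        self.perm_p, self.perm_q = res.perm_p, res.perm_q
        return res

    def bootstrap_loadings(self, n_boot: int = 1000, seed=0,
                           families=None, resample: str = "subjects"):
        from .inference import bootstrap_loadings

        return bootstrap_loadings(self, n_boot=n_boot, seed=seed,
                                  families=families, resample=resample)

    def cross_validate(self, families, k: int = 5, n_perm: int = 1000, seed=0):
        from .inference import crossval

        return crossval(self.model.X, self.model.Y, families, k=k,
                        n_perm=n_perm, seed=seed,
                        rank_tol=self.model.rank_tol)

    def summary(self) -> str:
        rows = []
        for k in range(self.n_components):
            row = {
                "LC": k + 1,
                "rho": round(float(self.rho[k]), 4),
                "cov_explained_%": round(float(self.cov_explained[k] * 100), 1),
            }
            if self.perm_p is not None:
                row["perm_p"] = round(float(self.perm_p[k]), 5)
                row["perm_q"] = round(float(self.perm_q[k]), 5)
            rows.append(row)
        df = pd.DataFrame(rows).set_index("LC")
        head = (
            f"Two-block CCA: n={self.n_obs}, p_x={self.x_weights.shape[0]}, "
            f"p_y={self.y_weights.shape[0]}, K={self.n_components}\n"
        )
        return head + df.to_string()
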