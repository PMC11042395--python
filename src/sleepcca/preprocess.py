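"""Column standardization and rank-based inverse-normal transforms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateInputError(ValueError):
    """Raised for inputs the model cannot meaningfully process
    (constant columns, zero-variance scores, ...)."""


def _as_array(block) -> tuple[np.ndarray, list]:
    if isinstance(block, pd.DataFrame):
        return block.to_numpy(dtype=float), list(block.columns)
    arr = np.asarray(block, dtype=float)
    return arr, list(range(arr.shape[1]))


@dataclass
class Standardizer:
    """Column means/sds of a training block, retained so held-out data
    can be put on the training scale before projection."""

    means: np.ndarray
    sds: np.ndarray

    def transform(self, block) -> np.ndarray:
        arr, _ = _as_array(block)
        if arr.shape[1] != len(self.means):
            raise ValueError(
                f"block has {arr.shape[1]} columns, expected {len(self.means)}"
            )
        return (arr - self.means) / self.sds


def standardize(block) -> tuple[np.ndarray, Standardizer]:
    """Z-score each column (sample sd, n-1 denominator).

    Returns the standardized array and a :class:`Standardizer` holding
    the transform parameters for out-of-sample projection.  Missing
    values and constant columns are rejected.
    """
    arr, names = _as_array(block)
    if np.isnan(arr).any():
        raise ValueError("block contains missing values; drop incomplete subjects first")
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise DegenerateInputError(
            f"constant column(s): {[names[j] for j in bad]}"
        )
    return (arr - means) / sds, Standardizer(means=means, sds=sds)


def quantile_normalize(block) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform, column-wise.

    Each column is replaced by Phi^{-1}((r - 3/8) / (n + 1/4)) where r is
    the column rank (ties get the average rank).  Monotone within each
    column; a column of all ties maps to 0.
    """
    arr, _ = _as_array(block)
    n = arr.shape[0]
    out = np.empty_like(arr, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out
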