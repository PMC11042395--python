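"""Synthetic two-block cohorts with family structure and connectomes.

The generator plants known structure so every downstream stage —
CCA fit, restricted permutation, bootstrap, cross-validation, edge-wise
GLM — can be validated without access to any restricted cohort:

* subjects belong to families (MZ/DZ twins, siblings, singletons);
* K latent score pairs (u_k, v_k) are jointly Gaussian with correlation
  ``planted_rho[k]``; each block is an invertible linear mixing of its
  latents, a small number of structured noise dimensions and (optionally)
  a family-effect direction, so the *population* canonical correlations
  equal ``planted_rho`` exactly;
* the family effect has intra-class correlation ``family_icc[role]``
  within twin pairs / sibships (MZ >= DZ >= SIB), drawn independently
  per block by default so it shapes the exchangeability structure
  without planting a cross-block signal;
* connectivity matrices get a linear effect of a per-subject composite
  score on chosen network-pair edge blocks, plus Gaussian edge noise.

Everything is deterministic for a fixed config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, ParcelNetworkMap
from .families import (FAMILY_TEMPLATES, HCP_LIKE_MIX, FamilyStructure,
                       make_family_structure)

SLEEP_COLUMNS = (
    "satisfaction", "latency", "duration", "efficiency",
    "disturbance", "medication", "daytime_dysfunction",
)

BEHAVIOR_CATEGORIES = (
    "mental_health", "cognition", "substance_use", "personality",
    "affect", "physical_health", "demographics",
)


class ConfigurationError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    family_icc gives the intra-class correlation of the family effect
    within MZ pairs, DZ pairs and sibling pairs; family_scale is the
    standard-deviation multiple with which the (unit-variance) family
    effect enters every phenotype column.
    """

    n_subjects: int = 500
    family_mix: dict = field(default_factory=lambda: dict(HCP_LIKE_MIX))
    p_sleep: int = 7
    p_behavior: int = 20
    planted_rho: tuple = (0.7, 0.4, 0.1)
    family_icc: dict = field(default_factory=lambda: {"MZ": 0.5, "DZ": 0.3, "SIB": 0.2})
    family_scale: float = 0.4
    shared_family_effect: bool = False
    ordinal_sleep: bool = False
    n_parcels: int = 50
    n_networks: int = 8
    edge_effects: tuple = ()          # ((network_a, network_b, slope), ...)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        rho = np.asarray(self.planted_rho, dtype=float)
        if rho.size and ((rho < 0).any() or (rho > 1).any()):
            raise ConfigurationError("planted_rho must lie in [0, 1]")
        nz = rho[rho > 0]
        if nz.size > 1 and not (np.diff(nz) < 0).all():
            raise ConfigurationError("nonzero planted_rho must be strictly descending")
        if rho.size > min(self.p_sleep, self.p_behavior):
            raise ConfigurationError("more planted components than block columns")
        icc = self.family_icc
        mz, dz, sib = icc.get("MZ", 0.0), icc.get("DZ", 0.0), icc.get("SIB", 0.0)
        for v in (mz, dz, sib):
            if not (0.0 <= v < 1.0):
                raise ConfigurationError("family_icc values must lie in [0, 1)")
        if not (mz >= dz >= sib >= 0.0):
            raise ConfigurationError("family_icc must satisfy MZ >= DZ >= SIB >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")

    @property
    def n_components(self) -> int:
        return len(self.planted_rho)

    def sleep_names(self) -> list[str]:
        if self.p_sleep == len(SLEEP_COLUMNS):
            return list(SLEEP_COLUMNS)
        return [f"sleep_{j + 1:02d}" for j in range(self.p_sleep)]

    def behavior_names(self) -> list[str]:
        cats = BEHAVIOR_CATEGORIES
        return [f"{cats[j % len(cats)]}_{j + 1:03d}" for j in range(self.p_behavior)]

    def loading_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Sparse sign patterns (p, K) per block, deterministic for the
        config seed: each component loads on roughly a third of the
        variables (at least two) with signs +/-1."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
        K = self.n_components

        def _one(p):
            # patterns must stay linearly independent of each other and
            # of the all-ones family direction for the mixing to be
            # invertible
            P = np.zeros((p, K))
            ones = np.ones((p, 1))
            for k in range(K):
                for _ in range(100):
                    m = max(2, p // 3)
                    idx = rng.choice(p, size=m, replace=False)
                    col = np.zeros(p)
                    col[idx] = rng.choice([-1.0, 1.0], size=m)
                    trial = np.column_stack([P[:, :k], col, ones])
                    if np.linalg.matrix_rank(trial) == k + 2:
                        P[:, k] = col
                        break
                else:
                    raise ConfigurationError(
                        "could not draw independent loading patterns")
            return P

        return _one(self.p_sleep), _one(self.p_behavior)

    def network_map(self) -> ParcelNetworkMap:
        """Parcels dealt evenly into ``n_networks`` labelled networks."""
        labels = [f"P{i + 1:03d}" for i in range(self.n_parcels)]
        nets = [f"net{(i % self.n_networks) + 1}" for i in range(self.n_parcels)]
        return ParcelNetworkMap(np.array(labels), np.array(nets))


def family_effect(families: FamilyStructure, icc: dict,
                  rng: np.random.Generator) -> np.ndarray:
    """One unit-variance family-effect draw per subject.

    Correlation between two members of the same family equals
    icc["MZ"] / icc["DZ"] for co-twins and icc["SIB"] otherwise,
    realised by nesting family-, twin-pair- and individual-level
    Gaussian components.
    """
    mz = icc.get("MZ", 0.0)
    dz = icc.get("DZ", 0.0)
    sib = icc.get("SIB", 0.0)
    n = families.n_subjects
    g = np.zeros(n)
    df = families.to_frame().reset_index()
    for _, grp in df.groupby("family_id", sort=True):
        idx = grp["index"].to_numpy()
        roles = grp["role"].to_numpy()
        f_fam = rng.standard_normal()
        twin_boost = {"MZ": np.sqrt(max(mz - sib, 0.0)) * rng.standard_normal(),
                      "DZ": np.sqrt(max(dz - sib, 0.0)) * rng.standard_normal()}
        for i, role in zip(idx, roles):
            pair_icc = mz if role == "MZ" else dz if role == "DZ" else sib
            val = np.sqrt(sib) * f_fam
            if role in ("MZ", "DZ"):
                val += twin_boost[role]
            val += np.sqrt(1.0 - pair_icc) * rng.standard_normal()
            g[i] = val
    return g


def _mixing_matrix(P: np.ndarray, q_noise: int, with_family: bool,
                   rng: np.random.Generator) -> np.ndarray:
    """Full-rank (p, p) mixing of [latents | noise dims | family dir]."""
    p, K = P.shape
    cols = [P]
    if q_noise > 0:
        cols.append(rng.standard_normal((p, q_noise)))
    if with_family:
        cols.append(np.ones((p, 1)))
    M = np.hstack(cols)
    for _ in range(20):
        if np.linalg.matrix_rank(M) == p:
            return M
        if q_noise > 0:  # regenerate the noise block on the rare rank failure
            M[:, K:K + q_noise] = rng.standard_normal((p, q_noise))
    raise ConfigurationError("could not build a full-rank mixing matrix")


def simulate_two_block(config: SynthConfig, families: FamilyStructure,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the standardized sleep and behavior blocks.

    Returns two DataFrames indexed by subject_id.  Columns are exactly
    standardized (mean 0, sd 1).  With ``ordinal_sleep=True`` the sleep
    columns are additionally discretized to the 0-3 Likert scale by
    Gaussian quartile cuts (and are then ordinal, not standardized).
    """
    n = families.n_subjects
    if n != config.n_subjects:
        raise ConfigurationError("family table does not match config.n_subjects")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    K = config.n_components
    rho = np.asarray(config.planted_rho, dtype=float)

    U = rng.standard_normal((n, K))
    V = rho * U + np.sqrt(1.0 - rho**2) * rng.standard_normal((n, K))

    with_family = config.family_scale > 0
    Px, Py = config.loading_patterns()

    def _block(p, P, latents, h):
        q_noise = p - K - (1 if with_family else 0)
        if q_noise < 0:
            raise ConfigurationError(
                f"block with {p} columns cannot host {K} components"
                + (" plus a family effect" if with_family else "")
            )
        M = _mixing_matrix(P, q_noise, with_family, rng)
        sources = [latents]
        if q_noise > 0:
            sources.append(rng.standard_normal((n, q_noise)))
        if with_family:
            sources.append(config.family_scale * h[:, None])
        S = np.hstack(sources)
        Z = S @ M.T
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
        return Z

    if with_family:
        h_x = family_effect(families, config.family_icc, rng)
        h_y = h_x if config.shared_family_effect else family_effect(
            families, config.family_icc, rng)
    else:
        h_x = h_y = np.zeros(n)
    X = _block(config.p_sleep, Px, U, h_x)
    Y = _block(config.p_behavior, Py, V, h_y)

    if config.ordinal_sleep:
        from scipy.stats import norm
        cuts = norm.ppf([0.25, 0.5, 0.75])
        X = np.digitize(X, cuts).astype(float)

    idx = pd.Index(families.subject_id, name="subject_id")
    return (
        pd.DataFrame(X, index=idx, columns=config.sleep_names()),
        pd.DataFrame(Y, index=idx, columns=config.behavior_names()),
    )


def simulate_cohort(config: SynthConfig):
    """Convenience: families + two blocks in one call."""
    fam = make_family_structure(
        config.n_subjects, config.family_mix,
        seed=np.random.default_rng(np.random.SeedSequence([config.seed, 77])),
    )
    X, Y = simulate_two_block(config, fam)
    return fam, X, Y


def simulate_connectomes(config: SynthConfig, composite_scores,
                         subject_ids=None) -> list[ConnectivityMatrix]:
    """Per-subject symmetric connectivity matrices with planted
    composite-score effects.

    Every edge of a planted (network_a, network_b) block gets
    ``slope * score_i`` added on top of iid Gaussian edge noise with sd
    ``noise_sd``; matrices are symmetric with zero diagonal.
    """
    scores = np.asarray(composite_scores, dtype=float)
    pmap = config.network_map()
    networks = set(pmap.network_labels)
    for (na, nb, _slope) in config.edge_effects:
        if na not in networks or nb not in networks:
            raise ConfigurationError(f"network pair ({na}, {nb}) absent from map")
    p = config.n_parcels
    iu = np.triu_indices(p, k=1)
    net = np.asarray(pmap.network_labels)
    block_masks = []
    for (na, nb, slope) in config.edge_effects:
        in_block = ((net[iu[0]] == na) & (net[iu[1]] == nb)) | \
                   ((net[iu[0]] == nb) & (net[iu[1]] == na))
        block_masks.append((in_block, slope))

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    if subject_ids is None:
        subject_ids = [f"S{i + 1:06d}" for i in range(len(scores))]
    out = []
    for i, s in enumerate(scores):
        vec = config.noise_sd * rng.standard_normal(len(iu[0]))
        for mask, slope in block_masks:
            vec[mask] += slope * s
        W = np.zeros((p, p))
        W[iu] = vec
        W = W + W.T
        out.append(ConnectivityMatrix(matrix=W, parcel_labels=pmap.parcel_labels,
                                      subject_id=str(subject_ids[i])))
    return out
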