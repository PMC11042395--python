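"""End-to-end pipeline runner with a reproducibility manifest.

Stages, in order: generate (or load) the cohort -> standardize + fit the
two-block CCA -> loadings and covariance-explained -> restricted
permutation test -> bootstrap loading stability -> family-aware
cross-validation -> composite scores -> connectivity (simulated or
loaded) -> confound residualization (optional) -> edge-wise and
network-wise GLMs -> graph metrics on the LC beta matrix.

Every stochastic stage draws from an independent named seed stream
derived from the master seed, so adding a stage never perturbs the
draws of earlier stages.  The manifest records the config, seeds and
SHA-256 digests of every written table; re-running with the same config
reproduces all outputs bitwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cca import TwoBlockCCA
from .connectome import edgewise_glm, networkwise_glm, residualize_confounds
from .inference import bootstrap_loadings, crossval, permutation_test
from .io import (FLOAT_FMT, read_connectivity, read_phenotypes,
                 write_connectivity, write_parcel_map, write_phenotypes,
                 write_table)
from .netgraph import integration_segregation_ratio
from .simulate import SynthConfig, simulate_connectomes, simulate_two_block
from .families import make_family_structure, HCP_LIKE_MIX

#: fixed stage -> seed-stream registry; append-only so existing stages'
#: streams never move
STAGE_KEYS = {
    "families": 0,
    "twoblock": 1,
    "connectomes": 2,
    "permutation": 3,
    "bootstrap": 4,
    "crossval": 5,
    "glm": 6,
    "graph": 7,
}


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=[int(master_seed), STAGE_KEYS[stage]])


@dataclass
class RunConfig:
    """Pipeline settings.  The analysis defaults (10,000 permutations,
    1,000 bootstrap samples, 5 folds, q = 0.05) reproduce the intended
    study settings; synthetic-cohort fields are forwarded to
    :class:`~sleepcca.simulate.SynthConfig`."""

    # inputs: either file paths ...
    sleep_path: str | None = None
    behavior_path: str | None = None
    family_path: str | None = None
    connectivity_dir: str | None = None
    parcel_map_path: str | None = None
    # ... or a synthetic cohort
    n_subjects: int = 300
    p_sleep: int = 7
    p_behavior: int = 20
    planted_rho: tuple = (0.7, 0.4, 0.1)
    family_mix: dict = field(default_factory=lambda: dict(HCP_LIKE_MIX))
    n_parcels: int = 50
    n_networks: int = 8
    edge_effects: tuple = ()
    noise_sd: float = 1.0
    # analysis settings
    n_perm: int = 10000
    n_boot: int = 1000
    k_folds: int = 5
    q: float = 0.05
    perm_scheme: str = "two_level"
    negative_policy: str = "zero"
    composite_mode: str = "averaged"
    component_for_glm: int = 0
    covariate_paths: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not (0 < self.q < 1):
            raise ValueError("q must lie in (0, 1)")
        if self.composite_mode not in ("averaged", "sleep", "behavior"):
            raise ValueError(f"unknown composite mode: {self.composite_mode}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("planted_rho") is not None:
            raw["planted_rho"] = tuple(raw["planted_rho"])
        if raw.get("edge_effects") is not None:
            raw["edge_effects"] = tuple(tuple(e) for e in raw["edge_effects"])
        return cls(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full pipeline and write all result tables plus a
    manifest under ``outdir``.  Returns the result bundle in memory."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        # --- inputs -----------------------------------------------------
        stage = "families"
        synth = None
        if config.sleep_path is not None:
            sleep, behavior, families, load_report = read_phenotypes(
                config.sleep_path, config.behavior_path, config.family_path)
        else:
            synth = SynthConfig(
                n_subjects=config.n_subjects, family_mix=config.family_mix,
                p_sleep=config.p_sleep, p_behavior=config.p_behavior,
                planted_rho=config.planted_rho, n_parcels=config.n_parcels,
                n_networks=config.n_networks, edge_effects=config.edge_effects,
                noise_sd=config.noise_sd, seed=config.seed,
            )
            families = make_family_structure(
                config.n_subjects, config.family_mix,
                seed=np.random.default_rng(stage_seed(config.seed, "families")))
            stage = "twoblock"
            sleep, behavior = simulate_two_block(synth, families)
            load_report = {"n_loaded": config.n_subjects, "synthetic": True}

        # --- CCA fit ----------------------------------------------------
        stage = "fit"
        results = TwoBlockCCA(sleep, behavior).fit()
        K = results.n_components

        stage = "permutation"
        perm = permutation_test(
            results, families, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "permutation"), scheme=config.perm_scheme)
        results.perm_p, results.perm_q = perm.perm_p, perm.perm_q

        stage = "bootstrap"
        boot = bootstrap_loadings(results, n_boot=config.n_boot,
                                  seed=stage_seed(config.seed, "bootstrap"))

        stage = "crossval"
        cv = crossval(results.model.X, results.model.Y, families,
                      k=config.k_folds, n_perm=min(config.n_perm, 1000),
                      seed=stage_seed(config.seed, "crossval"))

        # --- connectivity ----------------------------------------------
        stage = "connectomes"
        lc = config.component_for_glm
        composite = results.composite_scores(k=lc, mode=config.composite_mode)
        if config.connectivity_dir is not None:
            matrices, pmap = read_connectivity(config.connectivity_dir,
                                               config.parcel_map_path)
        elif synth is not None:
            matrices = simulate_connectomes(synth, composite,
                                            subject_ids=families.subject_id)
            pmap = synth.network_map()
        else:
            matrices, pmap = None, None

        glm_edge = glm_net = graph = None
        if matrices is not None:
            if config.covariate_paths is not None:
                stage = "residualize"
                cov = pd.read_csv(config.covariate_paths).set_index("subject_id")
                cov = cov.loc[[m.subject_id for m in matrices]]
                matrices = residualize_confounds(matrices, cov)
            stage = "glm"
            glm_edge = edgewise_glm(matrices, composite)
            glm_net = networkwise_glm(matrices, composite, pmap, q=config.q)
            stage = "graph"
            graph = integration_segregation_ratio(
                glm_edge.beta, pmap.network_labels,
                node_labels=pmap.parcel_labels,
                negative_policy=config.negative_policy)

        # --- write tables ----------------------------------------------
        stage = "write"
        comp = pd.DataFrame({
            "LC": np.arange(1, K + 1),
            "rho": results.rho,
            "cov_explained": results.cov_explained,
            "perm_p": perm.perm_p,
            "perm_q": perm.perm_q,
            "cv_mean_corr": np.pad(cv.mean_corr, (0, K - len(cv.mean_corr)),
                                   constant_values=np.nan),
            "cv_perm_p": np.pad(cv.perm_p, (0, K - len(cv.perm_p)),
                                constant_values=np.nan)
            if cv.perm_p is not None else np.nan,
        })
        _write(comp, out / "components.csv", written)

        for name, labels, mean, sd, lo, hi, qv, obs in (
            ("loadings_sleep", results.model.x_names, boot.x_mean, boot.x_sd,
             boot.x_ci_low, boot.x_ci_high, boot.x_q, results.x_loadings),
            ("loadings_behavior", results.model.y_names, boot.y_mean, boot.y_sd,
             boot.y_ci_low, boot.y_ci_high, boot.y_q, results.y_loadings),
        ):
            rows = []
            for k in range(K):
                for j, lab in enumerate(labels):
                    rows.append({"LC": k + 1, "variable": lab,
                                 "loading": obs[j, k], "boot_mean": mean[j, k],
                                 "boot_sd": sd[j, k], "ci_low": lo[j, k],
                                 "ci_high": hi[j, k], "q": qv[j, k]})
            _write(pd.DataFrame(rows), out / f"{name}.csv", written)

        scores = pd.DataFrame(
            {"subject_id": families.subject_id}
            | {f"sleep_score_{k + 1}": results.x_scores[:, k] for k in range(K)}
            | {f"behavior_score_{k + 1}": results.y_scores[:, k] for k in range(K)}
        )
        _write(scores, out / "scores.csv", written)

        if glm_net is not None:
            _write(glm_net.table, out / "network_glm.csv", written)
            np.savetxt(out / "edge_glm_beta.csv", glm_edge.beta,
                       delimiter=",", fmt=FLOAT_FMT)
            written["edge_glm_beta"] = out / "edge_glm_beta.csv"
            _write(graph.table, out / "graph_metrics.csv", written)
            _write(graph.network_medians, out / "network_medians.csv", written)

        manifest = {
            "version": __version__,
            "config": asdict(config),
            "stage_seeds": {s: [int(config.seed), k] for s, k in STAGE_KEYS.items()},
            "load_report": load_report,
            "n_components": int(K),
            "outputs": {k: {"path": str(p), "sha256": _digest(p)}
                        for k, p in written.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as err:
        partial = {"failed_stage": stage, "error": str(err),
                   "outputs_written": sorted(str(p) for p in written.values())}
        with open(out / "manifest.partial.json", "w") as fh:
            json.dump(partial, fh, indent=2)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    return {
        "results": results, "permutation": perm, "bootstrap": boot,
        "crossval": cv, "edge_glm": glm_edge, "network_glm": glm_net,
        "graph": graph, "manifest": manifest, "families": families,
    }


def _write(df: pd.DataFrame, path: Path, written: dict) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    written[path.stem] = path


def write_synthetic_inputs(config: RunConfig, directory) -> dict:
    """Materialize a synthetic cohort (phenotypes, family table,
    connectivity stack, parcel map) as delimited text files."""
    synth = SynthConfig(
        n_subjects=config.n_subjects, family_mix=config.family_mix,
        p_sleep=config.p_sleep, p_behavior=config.p_behavior,
        planted_rho=config.planted_rho, n_parcels=config.n_parcels,
        n_networks=config.n_networks, edge_effects=config.edge_effects,
        noise_sd=config.noise_sd, seed=config.seed,
    )
    families = make_family_structure(
        config.n_subjects, config.family_mix,
        seed=np.random.default_rng(stage_seed(config.seed, "families")))
    sleep, behavior = simulate_two_block(synth, families)
    d = Path(directory)
    paths = write_phenotypes(sleep, behavior, families, d)
    results = TwoBlockCCA(sleep, behavior).fit()
    composite = results.composite_scores(k=0, mode=config.composite_mode)
    matrices = simulate_connectomes(synth, composite,
                                    subject_ids=families.subject_id)
    conn_dir = d / "connectivity"
    write_connectivity(matrices, conn_dir)
    write_parcel_map(synth.network_map(), d / "parcel_map.tsv")
    paths.update({"connectivity_dir": str(conn_dir),
                  "parcel_map": str(d / "parcel_map.tsv")})
    return paths
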