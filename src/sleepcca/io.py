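"""Delimited-text readers/writers for phenotypes, family tables,
connectivity matrices and parcel maps.

All on-disk formats are plain text: CSV with a header row and
``subject_id`` as the first column for tables; one dense comma-delimited
square matrix per subject for connectivity; a two-column TSV
(parcel_label, network_label) for the parcel map.  Floats are written
with 17 significant digits so round-trips are bitwise-exact.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, ParcelNetworkMap, SchemaError
from .families import FamilyStructure

FLOAT_FMT = "%.17g"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, float_format=FLOAT_FMT,
              index=df.index.name == "subject_id")


def write_phenotypes(sleep: pd.DataFrame, behavior: pd.DataFrame,
                     families: FamilyStructure, directory) -> dict:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "sleep": d / "sleep.csv",
        "behavior": d / "behavior.csv",
        "family": d / "family.csv",
    }
    write_table(sleep, paths["sleep"])
    write_table(behavior, paths["behavior"])
    families.to_frame().to_csv(paths["family"], index=False)
    return {k: str(v) for k, v in paths.items()}


def read_phenotypes(sleep_path, behavior_path, family_path=None):
    """Load the two phenotype blocks (and optionally the family table),
    align them on the subject-id intersection, and drop subjects with
    any missing value (complete-case rule).

    Returns (sleep, behavior, families_or_None, report); the report
    lists dropped subjects with the rule that dropped them.
    """
    def _read(path):
        df = pd.read_csv(path, float_precision="round_trip")
        if "subject_id" not in df.columns:
            raise SchemaError(f"{path}: missing subject_id column")
        df = df.set_index("subject_id")
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[coerced.isna() & df[col].notna()]
                if len(bad):
                    raise SchemaError(
                        f"{path}: non-numeric value in column {col!r}, "
                        f"subject(s) {list(bad[:3])}"
                    )
                df[col] = coerced
        return df

    sleep = _read(sleep_path)
    behavior = _read(behavior_path)
    common = sleep.index.intersection(behavior.index)
    if len(common) == 0:
        raise SchemaError("no common subjects between the sleep and behavior blocks")
    report = {
        "n_sleep_only": int(len(sleep.index.difference(behavior.index))),
        "n_behavior_only": int(len(behavior.index.difference(sleep.index))),
        "dropped_missing": [],
    }
    sleep, behavior = sleep.loc[common], behavior.loc[common]
    incomplete = sleep.isna().any(axis=1) | behavior.isna().any(axis=1)
    report["dropped_missing"] = [str(s) for s in common[incomplete]]
    sleep, behavior = sleep.loc[~incomplete], behavior.loc[~incomplete]
    report["n_loaded"] = int(len(sleep))

    families = None
    if family_path is not None:
        fam_df = pd.read_csv(family_path)
        fam_df = fam_df[fam_df["subject_id"].astype(str).isin(
            sleep.index.astype(str))]
        fam_df = fam_df.set_index("subject_id").loc[sleep.index].reset_index()
        families = FamilyStructure.from_frame(fam_df)
    return sleep, behavior, families, report


def write_parcel_map(pmap: ParcelNetworkMap, path) -> None:
    pmap.to_frame().to_csv(path, sep="\t", index=False)


def read_parcel_map(path) -> ParcelNetworkMap:
    df = pd.read_csv(path, sep="\t")
    return ParcelNetworkMap(df["parcel_label"].to_numpy(),
                            df["network_label"].to_numpy())


def write_connectivity(matrices: list[ConnectivityMatrix], directory) -> list[str]:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in matrices:
        path = d / f"conn_{m.subject_id}.csv"
        np.savetxt(path, m.matrix, delimiter=",", fmt=FLOAT_FMT)
        paths.append(str(path))
    return paths


def read_connectivity(directory, parcel_map_path,
                      subject_ids=None,
                      atol: float = 1e-8) -> tuple[list[ConnectivityMatrix], ParcelNetworkMap]:
    """Load per-subject dense matrices (``conn_<subject_id>.csv``) and
    the parcel map; enforce consistent dimensions and symmetry
    (symmetrizing silently below ``atol``)."""
    d = Path(directory)
    pmap = read_parcel_map(parcel_map_path)
    files = sorted(d.glob("conn_*.csv"))
    if subject_ids is not None:
        wanted = {str(s) for s in subject_ids}
        files = [f for f in files if f.stem[len("conn_"):] in wanted]
    out = []
    dim = None
    for f in files:
        M = np.loadtxt(f, delimiter=",")
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise SchemaError(f"{f.name}: not a square matrix")
        if dim is None:
            dim = M.shape[0]
        elif M.shape[0] != dim:
            raise SchemaError(
                f"{f.name}: dimension {M.shape[0]} differs from {dim}")
        asym = np.abs(M - M.T).max()
        if asym > atol:
            warnings.warn(f"{f.name}: asymmetry {asym:.2e} symmetrized",
                          RuntimeWarning)
        M = (M + M.T) / 2.0
        out.append(ConnectivityMatrix(matrix=M, parcel_labels=pmap.parcel_labels,
                                      subject_id=f.stem[len("conn_"):]))
    if dim is not None and dim != pmap.n_parcels:
        raise SchemaError(
            f"parcel map covers {pmap.n_parcels} parcels but matrices are {dim}x{dim}")
    return out, pmap
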