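"""Family structure and restricted (exchangeability-block) permutations.

Twin cohorts contain monozygotic (MZ) twins, dizygotic (DZ) twins,
non-twin siblings and singletons.  Subjects are then not freely
exchangeable under the null hypothesis: a valid permutation may only

* swap subjects holding the same role *within* a family, and
* swap whole families whose role composition is identical
  (slot-wise, so an MZ member always lands on an MZ slot).

This is the two-level scheme used by permutation toolboxes for
heritability-structured cohorts.  A simpler "stratified by role across
the whole sample" scheme is also provided as an option.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

ROLES = ("MZ", "DZ", "SIB", "SINGLETON")


@dataclass(frozen=True)
class FamilyStructure:
    """Subject -> (family, role) assignment.

    Parameters
    ----------
    subject_id : array of identifiers, one per subject
    family_id : array of identifiers, same length
    role : array of strings drawn from {"MZ", "DZ", "SIB", "SINGLETON"}
    """

    subject_id: np.ndarray
    family_id: np.ndarray
    role: np.ndarray

    def __post_init__(self):
        sid = np.asarray(self.subject_id)
        fid = np.asarray(self.family_id)
        rol = np.asarray(self.role, dtype=object)
        if not (len(sid) == len(fid) == len(rol)):
            raise ValueError("subject_id, family_id and role must have equal length")
        if len(np.unique(sid)) != len(sid):
            raise ValueError("duplicate subject_id in family table")
        bad = set(rol) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        # twin roles must occur in pairs within a family
        df = pd.DataFrame({"fid": fid, "role": rol})
        for role in ("MZ", "DZ"):
            counts = df[df["role"] == role].groupby("fid").size()
            if (counts % 2 != 0).any():
                raise ValueError(f"{role} subjects must occur in pairs within a family")
        sizes = df.groupby("fid").size()
        if (sizes > 5).any():
            raise ValueError("families larger than 5 subjects are not supported")
        object.__setattr__(self, "subject_id", sid)
        object.__setattr__(self, "family_id", fid)
        object.__setattr__(self, "role", rol)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "family_id": self.family_id,
                "role": self.role,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FamilyStructure":
        return cls(
            df["subject_id"].to_numpy(),
            df["family_id"].to_numpy(),
            df["role"].to_numpy(),
        )

    def subset(self, indices: np.ndarray) -> "FamilyStructure":
        idx = np.asarray(indices)
        return FamilyStructure(
            self.subject_id[idx], self.family_id[idx], self.role[idx]
        )


# --- family composition templates used by the synthetic generator -------

FAMILY_TEMPLATES: dict[str, tuple[str, ...]] = {
    "singleton": ("SINGLETON",),
    "mz_pair": ("MZ", "MZ"),
    "dz_pair": ("DZ", "DZ"),
    "sib_pair": ("SIB", "SIB"),
    "sib_trio": ("SIB", "SIB", "SIB"),
    "mz_plus_sib": ("MZ", "MZ", "SIB"),
    "dz_plus_sib": ("DZ", "DZ", "SIB"),
}

#: Rough mix of family compositions in a young-adult twin cohort in which
#: most subjects have one or more siblings/twins enrolled.
HCP_LIKE_MIX: dict[str, float] = {
    "singleton": 0.20,
    "mz_pair": 0.20,
    "dz_pair": 0.15,
    "sib_pair": 0.25,
    "sib_trio": 0.10,
    "mz_plus_sib": 0.05,
    "dz_plus_sib": 0.05,
}


def make_family_structure(
    n_subjects: int,
    family_mix: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> FamilyStructure:
    """Partition ``n_subjects`` into families with roles.

    ``family_mix`` gives probabilities over the family templates in
    :data:`FAMILY_TEMPLATES` (by *family*, not by subject).  Families are
    drawn until the subject budget is filled; a remainder smaller than
    the drawn family becomes singletons so the count is exact.
    Deterministic for a fixed seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if family_mix is None:
        family_mix = HCP_LIKE_MIX
    unknown = set(family_mix) - set(FAMILY_TEMPLATES)
    if unknown:
        raise ValueError(f"unknown family templates: {sorted(unknown)}")
    probs = np.array([float(v) for v in family_mix.values()])
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("family_mix proportions must be nonnegative and sum to 1")
    names = list(family_mix.keys())
    rng = np.random.default_rng(seed)

    subject_ids: list[str] = []
    family_ids: list[str] = []
    roles: list[str] = []
    remaining = n_subjects
    fam_counter = 0
    while remaining > 0:
        name = names[rng.choice(len(names), p=probs)]
        template = FAMILY_TEMPLATES[name]
        if len(template) > remaining:
            template = ("SINGLETON",)
        fam_counter += 1
        fid = f"F{fam_counter:05d}"
        for role in template:
            subject_ids.append(f"S{len(subject_ids) + 1:06d}")
            family_ids.append(fid)
            roles.append(role)
        remaining -= len(template)
    return FamilyStructure(
        np.array(subject_ids), np.array(family_ids), np.array(roles, dtype=object)
    )


# --- exchangeability blocks ----------------------------------------------


@dataclass
class ExchangeabilityBlocks:
    """Admissible-permutation structure derived from a family table.

    ``within_groups`` lists, per family, the index groups of same-role
    members (only groups of size > 1 matter for shuffling but all are
    kept for the slot bookkeeping).  ``swap_classes`` groups families
    whose role multiset is identical; whole families in one class may be
    exchanged slot-wise.
    """

    n_subjects: int
    families: list[np.ndarray]  # per family: member indices in slot order
    within_groups: list[list[np.ndarray]]  # per family: same-role index groups
    swap_classes: list[list[int]]  # indices into `families`
    signatures: list[tuple]  # per family: sorted role multiset

    @classmethod
    def from_families(cls, fam: FamilyStructure) -> "ExchangeabilityBlocks":
        df = fam.to_frame().reset_index()
        families = []
        within_groups = []
        signatures = []
        for _, grp in df.groupby("family_id", sort=True):
            # slot order: sort members by role name then original position,
            # so slot-wise family exchange maps role onto identical role
            grp = grp.sort_values(["role", "index"])
            members = grp["index"].to_numpy()
            families.append(members)
            groups = [
                g["index"].to_numpy() for _, g in grp.groupby("role", sort=True)
            ]
            within_groups.append(groups)
            signatures.append(tuple(sorted(grp["role"])))
        sig_to_class: dict[tuple, list[int]] = {}
        for i, sig in enumerate(signatures):
            sig_to_class.setdefault(sig, []).append(i)
        return cls(
            n_subjects=fam.n_subjects,
            families=families,
            within_groups=within_groups,
            swap_classes=list(sig_to_class.values()),
            signatures=signatures,
        )


def build_blocks(fam: FamilyStructure) -> ExchangeabilityBlocks:
    """Build exchangeability blocks (within-family role groups and
    whole-family swap classes) from a family table."""
    return ExchangeabilityBlocks.from_families(fam)


def draw_permutation(
    blocks: ExchangeabilityBlocks,
    rng: np.random.Generator,
    scheme: str = "two_level",
    role_vector: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one admissible permutation as an index vector ``perm`` such
    that ``Y[perm]`` realises the permuted assignment.

    scheme="two_level" (default): shuffle same-role members within each
    family, then exchange whole families slot-wise within classes of
    identical role composition.  scheme="role_stratified": permute
    subjects freely within each role stratum across the whole sample
    (requires ``role_vector``).
    """
    n = blocks.n_subjects
    perm = np.arange(n)
    if scheme == "role_stratified":
        if role_vector is None:
            raise ValueError("role_stratified scheme needs the role vector")
        for role in np.unique(role_vector):
            idx = np.flatnonzero(role_vector == role)
            perm[idx] = idx[rng.permutation(len(idx))]
        return perm
    if scheme != "two_level":
        raise ValueError(f"unknown permutation scheme: {scheme}")

    # level 1: within-family, same-role shuffles
    for groups in blocks.within_groups:
        for g in groups:
            if len(g) > 1:
                perm[g] = g[rng.permutation(len(g))]
    # level 2: whole-family exchange within identical-signature classes
    out = perm.copy()
    for cls_ in blocks.swap_classes:
        if len(cls_) > 1:
            order = rng.permutation(len(cls_))
            for dst_pos, src_pos in enumerate(order):
                dst = blocks.families[cls_[dst_pos]]
                src = blocks.families[cls_[src_pos]]
                out[dst] = perm[src]
    return out


def enumerate_permutations(blocks: ExchangeabilityBlocks) -> list[tuple[int, ...]]:
    """Exhaustively enumerate all admissible permutations (small designs
    only).  Serves as the oracle for the sampler's support."""
    from itertools import permutations as iperm, product

    n = blocks.n_subjects

    def family_within_options(fi: int) -> list[np.ndarray]:
        opts: list[np.ndarray] = []
        groups = blocks.within_groups[fi]
        per_group = [list(iperm(range(len(g)))) for g in groups]
        for combo in product(*per_group):
            mapping = np.arange(n)
            for g, p in zip(groups, combo):
                mapping[g] = g[np.array(p, dtype=int)]
            opts.append(mapping)
        return opts

    results: set[tuple[int, ...]] = set()
    class_orders = [list(iperm(cls_)) for cls_ in blocks.swap_classes]
    within_opts = [family_within_options(fi) for fi in range(len(blocks.families))]
    for withins in product(*within_opts):
        base = np.arange(n)
        for m in withins:
            changed = m != np.arange(n)
            base[changed] = m[changed]
        for orders in product(*class_orders):
            out = base.copy()
            for cls_, order in zip(blocks.swap_classes, orders):
                for dst_fi, src_fi in zip(cls_, order):
                    dst = blocks.families[dst_fi]
                    src = blocks.families[src_fi]
                    out[dst] = base[src]
            results.add(tuple(int(i) for i in out))
    return sorted(results)


def assert_admissible(blocks: ExchangeabilityBlocks, perm: np.ndarray,
                      fam: FamilyStructure) -> None:
    """Raise if ``perm`` violates role/family-signature preservation."""
    perm = np.asarray(perm)
    if sorted(perm) != list(range(blocks.n_subjects)):
        raise AssertionError("permutation is not a bijection")
    role = fam.role
    if not (role[perm] == role).all():
        raise AssertionError("a subject was mapped onto a different role")
    fid = fam.family_id
    # each family must be mapped onto exactly one family with equal signature
    df = pd.DataFrame({"dst": fid, "src": fid[perm], "role": role})
    for dst, grp in df.groupby("dst"):
        if grp["src"].nunique() != 1:
            raise AssertionError(f"family {dst} split across source families")
        sig_dst = tuple(sorted(grp["role"]))
        src = grp["src"].iloc[0]
        sig_src = tuple(sorted(df.loc[df["dst"] == src, "role"]))
        if sig_dst != sig_src:
            raise AssertionError("families with different signatures exchanged")
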