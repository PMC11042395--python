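import numpy as np
import pandas as pd
import pytest

import sleepcca as sc


@pytest.fixture(scope="session")
def small_cohort():
    """n=300 cohort with three planted components, family structure."""
    cfg = sc.SynthConfig(n_subjects=300, seed=42)
    fam, X, Y = sc.simulate_cohort(cfg)
    return cfg, fam, X, Y


@pytest.fixture(scope="session")
def fitted(small_cohort):
    _, _, X, Y = small_cohort
    return sc.TwoBlockCCA(X, Y).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_mz_pairs_plus_singleton():
    """The canonical tiny design: 2 MZ-pair families + 1 singleton,
    which admits exactly 8 permutations."""
    return sc.FamilyStructure(
        subject_id=np.array(["a1", "a2", "b1", "b2", "s"]),
        family_id=np.array(["A", "A", "B", "B", "S"]),
        role=np.array(["MZ", "MZ", "MZ", "MZ", "SINGLETON"], dtype=object),
    )
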