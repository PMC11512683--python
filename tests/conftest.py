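import numpy as np
import pytest

import ampliclone as ac


@pytest.fixture(scope="session")
def default_cfg():
    return ac.RunConfig()


@pytest.fixture(scope="session")
def tet2_thresholds():
    """Thresholds from the worked-example control moments of the
    TET2 p.R1261C gDNA amplicon (mean 0.000719, SD 0.000472)."""
    return ac.thresholds_from_moments(0.000719, 0.000472, "TET2_pR1261C_gDNA")


@pytest.fixture(scope="session")
def sim_dataset():
    """A medium two-mutation linear-clone simulated sample, shared across
    tests that only read from it."""
    cfg = ac.default_config(n_cells=1500)
    result = ac.simulate_cells(cfg, seed=2024)
    ds = ac.validate_dataset(result.counts, result.manifest, result.meta)
    return cfg, result, ds


@pytest.fixture(scope="session")
def sim_calls(sim_dataset):
    cfg, result, ds = sim_dataset
    thresholds = ac.derive_all_thresholds(ds)
    calls = ac.call_dataset(ds, thresholds)
    return thresholds, calls


def make_genotype_matrix(rng, clone_truth, tree_sets, fd, ad, missing=0.0):
    """Observed {1,0,-1} matrix from true per-cell clone labels.

    Independent per-entry errors: a true MUT is observed WT with probability
    ``ad``, a true WT observed MUT with probability ``fd``; entries are
    MISSING with probability ``missing``.
    """
    n = len(clone_truth)
    mutations = sorted({m for s in tree_sets.values() for m in s})
    mat = np.zeros((n, len(mutations)), dtype=int)
    for i, clone in enumerate(clone_truth):
        for j, mut in enumerate(mutations):
            true = 1 if mut in tree_sets[clone] else 0
            if true == 1:
                obs = 0 if rng.random() < ad else 1
            else:
                obs = 1 if rng.random() < fd else 0
            if rng.random() < missing:
                obs = -1
            mat[i, j] = obs
    return mat, mutations
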