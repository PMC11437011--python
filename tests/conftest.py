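import numpy as np
import pandas as pd
import pytest

from seascape_biogeo import (CountMatrix, RarefactionEnsemble, SyntheticSpec,
                             HABITATS)


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 ASVs x 2 samples with column sums (6, 3)."""
    return CountMatrix(np.array(["a1", "a2", "a3"], object),
                       np.array(["s1", "s2"], object),
                       np.array([[5, 0], [0, 2], [1, 1]]))


def make_ensemble(members: list, depth: int,
                  sample_ids=None, asv_ids=None) -> RarefactionEnsemble:
    """Hand-built ensemble from explicit member arrays (no rarefaction)."""
    members = [np.asarray(m) for m in members]
    n_asv, n_samp = members[0].shape
    return RarefactionEnsemble(
        depth=depth,
        asv_ids=np.asarray(asv_ids if asv_ids is not None
                           else [f"asv{i}" for i in range(n_asv)], object),
        sample_ids=np.asarray(sample_ids if sample_ids is not None
                              else [f"s{j}" for j in range(n_samp)], object),
        members=members,
        dropped_sample_ids=np.array([], object),
        member_seeds=[None] * len(members),
    )


@pytest.fixture
def small_spec() -> SyntheticSpec:
    """Desk-scale synthetic community: 3 x 20 samples, 150 taxa."""
    return SyntheticSpec(
        n_samples_per_habitat={h: 20 for h in HABITATS},
        n_taxa={"endemic": 20, "endemic_affinity": 20,
                "generalist": 20, "generalist_affinity": 10,
                "cosmopolitan": 20, "cosmopolitan_affinity": 10,
                "random_rare": 50},
        library_mu=float(np.log(3000)), library_sigma=0.2,
        seed=7)


def labels_series(labels, sample_ids) -> pd.Series:
    return pd.Series(list(labels), index=list(sample_ids), name="habitat")
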