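import numpy as np
import pytest

from correlognet.association import association_pipeline
from correlognet.network import build_mrs, correlog_groups
from correlognet.profile_io import ProfileMatrix
from correlognet.synthetic import PlantedModel, generate_profiles

# seed chosen once for the planted-recovery fixture; recorded here so every
# test that relies on the realization agrees on it
PLANTED_SEED = 7


@pytest.fixture(scope="session")
def planted_model():
    return PlantedModel.regular(
        20, 5, 600, module_activity=0.5, fp_rate=0.05, fn_rate=0.05,
        seed=PLANTED_SEED,
    )


@pytest.fixture(scope="session")
def planted_run(planted_model):
    """Full pipeline on the planted model: profiles -> w -> MRS -> groups."""
    pm, labels = generate_profiles(planted_model)
    result, report = association_pipeline(pm, x_th=30)
    mrs = build_mrs(result.w, result.gene_ids)
    groups = correlog_groups(mrs)
    return {
        "model": planted_model,
        "pm": pm,
        "labels": labels,
        "result": result,
        "report": report,
        "mrs": mrs,
        "groups": groups,
    }


@pytest.fixture
def small_pm():
    """4 genes x 6 species, hand-checkable."""
    x = np.array(
        [
            [1, 1, 1, 0, 0, 0],
            [1, 1, 0, 0, 0, 0],
            [0, 0, 1, 1, 1, 0],
            [1, 0, 1, 0, 1, 0],
        ],
        dtype=np.int8,
    )
    return ProfileMatrix(["g1", "g2", "g3", "g4"], [f"s{k}" for k in range(6)], x)


def random_binary_pm(rng, n_genes, n_species):
    """Random informative profile matrix (no constant rows)."""
    while True:
        x = rng.integers(0, 2, size=(n_genes, n_species), dtype=np.int8)
        e = x.sum(axis=1)
        if ((e > 0) & (e < n_species)).all():
            return ProfileMatrix(
                [f"g{i:03d}" for i in range(n_genes)],
                [f"s{k:03d}" for k in range(n_species)],
                x,
            )
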