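import numpy as np
import pytest

from mirmet import synthetic_data as sd


@pytest.fixture(scope="session")
def refs():
    """Small mixed-clade mature miRNA reference."""
    return sd.generate_reference(10, 3, seed=1)


@pytest.fixture(scope="session")
def target_refs(refs):
    return [r for r in refs if r.clade_tag == "target"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def null_two_group_design(seed, n_per_group=20, n_mirnas=500, dispersion=0.1,
                          tissues=("pCRC", "nCR")):
    """Two tissues with identical cell-type mixing: a pure NB null."""
    design = sd.study_design(
        seed=seed,
        tissues={tissues[0]: n_per_group, tissues[1]: n_per_group},
        n_mirnas=n_mirnas,
        n_celltype_specific=0,
        dispersion=dispersion,
    )
    design.mixing_mean[tissues[1]] = dict(design.mixing_mean[tissues[0]])
    return design


plant_abundance = sd.plant_abundance
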