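import numpy as np
import pytest

from stabgp import CascadeConfig, SyntheticSpec, generate_dataset, prepare


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared across tests (seeded)."""
    spec = SyntheticSpec(
        n_cations=12, n_ligands=40, pairs_per_ligand=3, seed=1
    )
    records, cation_table, ligands = generate_dataset(spec)
    kept, dropped = prepare(records)
    return {
        "spec": spec,
        "records": records,
        "kept": kept,
        "dropped": dropped,
        "cation_table": cation_table,
        "ligands": ligands,
    }


@pytest.fixture(scope="session")
def fast_cascade_config():
    return CascadeConfig(
        select_features=False, n_restarts=2, maxiter=100, max_rows=300
    )


@pytest.fixture(scope="session")
def fitted_cascade(small_dataset, fast_cascade_config):
    from stabgp import fit_cascade

    return fit_cascade(
        small_dataset["kept"],
        small_dataset["cation_table"],
        fast_cascade_config,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
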