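import numpy as np
import pandas as pd
import pytest

from hausflow.io_formats import COMPARTMENTS, FeatureTable
from hausflow.synthetic_data import SimParams, generate_experiment


def make_table(values, feature_ids=None, n_reps=1, kind="gene", compartments=COMPARTMENTS):
    """Build a FeatureTable from a (features x samples) array laid out as
    n_reps consecutive replicates per compartment."""
    values = np.asarray(values, dtype=float)
    sample_ids, mapping = [], {}
    for comp in compartments:
        for r in range(1, n_reps + 1):
            sid = f"{comp}_{r}" if n_reps > 1 else comp
            sample_ids.append(sid)
            mapping[sid] = comp
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return FeatureTable(frame=frame, sample_to_compartment=mapping, feature_kind=kind)


@pytest.fixture(scope="session")
def experiment():
    """Default-size synthetic experiment, shared across the session."""
    return generate_experiment(SimParams(seed=1))


@pytest.fixture(scope="session")
def small_experiment():
    """A cheap experiment for I/O and CLI tests."""
    params = SimParams(
        n_genes=80,
        n_metabolites=60,
        n_mobile_th_to_p=5,
        n_mobile_p_to_th=2,
        n_transferred_host_to_parasite=2,
        n_transferred_parasite_to_host=1,
        n_haustoria_genes=4,
        n_common_dams=6,
        n_correlated_pairs=3,
        genome_length=5000,
        unigene_length=(200, 400),
        seed=11,
    )
    return generate_experiment(params)
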