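import numpy as np
import pandas as pd
import pytest

import tinstab as ts


@pytest.fixture(scope="session")
def default_sim() -> ts.SimulatedDataset:
    """One default-sized synthetic cohort shared across the session."""
    return ts.simulate_dataset(seed=42)


@pytest.fixture(scope="session")
def firma_default(default_sim) -> ts.FirmaResults:
    return ts.FirmaModel(default_sim.intensities, default_sim.chipdef,
                         background_correction=False).fit()


@pytest.fixture(scope="session")
def tin_default(firma_default) -> ts.TinResults:
    return ts.TinModel(firma_default.scores).fit(pseudocount=0.5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_chipdef() -> ts.ChipDefinition:
    """Two genes: gene A with 3 probe sets of 2 probes, gene B with 2 sets."""
    rows = []
    for gene, n_sets in (("GA", 3), ("GB", 2)):
        for j in range(n_sets):
            ps = f"{gene}:PS{j + 1}"
            for k in range(2):
                rows.append((f"{ps}:P{k + 1}", ps, gene))
    return ts.ChipDefinition(
        pd.DataFrame(rows, columns=["probe_id", "probe_set_id", "gene_id"]))
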