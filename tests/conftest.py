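import numpy as np
import pytest

import marshtransplant as mt


@pytest.fixture(scope="session")
def sites():
    """The packaged five-marsh site table."""
    return mt.paper_sites()


@pytest.fixture(scope="session")
def site_lookup(sites):
    return mt.site_map(sites)


@pytest.fixture
def tiny_table():
    """4 OTUs x 3 samples with taxonomy, hand-checkable."""
    counts = np.array([
        [4, 1, 0],
        [2, 2, 0],
        [0, 3, 5],
        [1, 0, 0],
    ])
    tax = [
        "Bacteria;Proteobacteria;Gammaproteobacteria",
        "Bacteria;Proteobacteria;Deltaproteobacteria",
        "Bacteria;Chloroflexi;Anaerolineae",
        "",
    ]
    return mt.OTUTable(["otu1", "otu2", "otu3", "otu4"], ["S1", "S2", "S3"], counts, tax)


@pytest.fixture(scope="session")
def simulated():
    """One default-condition simulated experiment, shared across tests."""
    cfg = mt.default_config(seed=11)
    table, metadata, sim_sites, truth = mt.simulate_experiment(cfg)
    return {"config": cfg, "table": table, "metadata": metadata,
            "sites": sim_sites, "truth": truth}
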