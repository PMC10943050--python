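import numpy as np
import pytest

import sigprog as sp
from sigprog.simulate import planted_biomarker_config


@pytest.fixture(scope="session")
def default_cohort():
    """A 100-sample cohort from the default three-signature model."""
    config = sp.SimulationConfig(seed=11, n_samples=100)
    records, clinical, truth = sp.simulate_cohort(config)
    return config, records, clinical, truth


@pytest.fixture(scope="session")
def default_catalog(default_cohort):
    _, records, _, _ = default_cohort
    return sp.build_catalog(records)


@pytest.fixture(scope="session")
def factorization(default_catalog):
    return sp.factorize(default_catalog, rank=3, n_restarts=4, seed=7)


@pytest.fixture(scope="session")
def fixture_panel():
    return sp.make_fixture_panel()


@pytest.fixture(scope="session")
def planted_run():
    """Planted-biomarker cohort taken through catalog, NMF and CCA."""
    config = planted_biomarker_config(seed=5)
    records, clinical, truth = sp.simulate_cohort(config)
    catalog = sp.build_catalog(records)
    result = sp.factorize(catalog, rank=3, n_restarts=4, seed=7)
    matches = sp.match_panel(result.signatures, sp.make_fixture_panel())
    table = sp.compute_cca(records, result.signatures, result.exposures)
    features = sp.cca_feature_matrix(table, genes=list(config.gene_panel))
    groups = sp.assign_groups(clinical).set_index("sample_id")["group"]
    # planted feature names in extracted-signature coordinates
    by_ref = {m.assigned_name: m.extracted_id for m in matches if not m.novel}
    truth_names = config.signature_names
    planted_features = [
        f"{gene}|{by_ref[truth_names[sig_i] + '*']}"
        for gene, sig_i in config.planted.pairs
    ]
    return {
        "config": config,
        "records": records,
        "clinical": clinical,
        "truth": truth,
        "catalog": catalog,
        "result": result,
        "table": table,
        "features": features,
        "groups": groups,
        "planted_features": planted_features,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
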