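"""Shared fixtures: one default synthetic experiment, quantified and QC'd,
reused read-only across test modules."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import scduet as sd

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def sim_cfg() -> sd.SimulationConfig:
    return sd.SimulationConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def experiment(sim_cfg):
    """(wells, truth, expr, met_true, standards, peak_areas) at default scale."""
    return sd.simulate_experiment(sim_cfg)


@pytest.fixture(scope="session")
def curves(experiment):
    _, _, _, _, standards, _ = experiment
    return sd.fit_all_calibrations(standards)


@pytest.fixture(scope="session")
def met_matrix(experiment, curves):
    wells, _, _, _, _, areas = experiment
    results = sd.quantify_plate(areas, curves, wells)
    return sd.assemble_metabolite_matrix(results, wells)


@pytest.fixture(scope="session")
def kept_expr(experiment):
    wells, _, expr, _, _, _ = experiment
    kept, report = sd.qc_filter(expr, wells)
    sd.compute_tpm(kept)
    sd.log_normalize(kept)
    sd.select_variable_genes(kept, 500)
    return kept, report


@pytest.fixture(scope="session")
def dataset(kept_expr, met_matrix):
    kept, _ = kept_expr
    ds = sd.join_by_well(kept, met_matrix)
    ds.met_log10, ds.met_batch_z = sd.normalize_metabolites(ds.met)
    return ds


@pytest.fixture(scope="session")
def marker_rules():
    pc = sd.PipelineConfig()
    return sd.MarkerRules.from_config(pc.rna_marker_rules, pc.met_marker_rules)


@pytest.fixture(scope="session")
def truth_series(experiment, dataset):
    _, truth, _, _, _, _ = experiment
    return pd.Series({c: truth.type_of_well[c] for c in dataset.cells})


# expected labels per true cell type under the default marker rules
EXPECTED_RNA_LABEL = {
    "epidermis_A": "epidermis",
    "epidermis_B": "epidermis",
    "idioblast": "idioblast",
    "ipap": "ipap",
    "parenchyma": "unassigned",
}
EXPECTED_MET_LABEL = {
    "epidermis_A": "epidermis",
    "epidermis_B": "epidermis_mauritianin",
    "idioblast": "idioblast",
    "ipap": "unassigned",
    "parenchyma": "loganic_acid_cell",
}
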