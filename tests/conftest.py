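import numpy as np
import pytest

from bootcua.costing import DelphiPanelData, UnitCostTable
from bootcua.markov import ModelConfig
from bootcua.synthetic import (
    SYNTHETIC_SOC_MATRIX,
    GeneratorConfig,
    generate_delphi_panel,
    generate_trial,
)
from bootcua.trial_data import PatientRecord, Stratum, TrialDataset


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def trial(gen_config):
    return generate_trial(gen_config, seed=1)


@pytest.fixture(scope="session")
def panel_and_tariffs(gen_config):
    return generate_delphi_panel(gen_config, seed=2)


@pytest.fixture(scope="session")
def model_config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def soc_matrix() -> np.ndarray:
    return SYNTHETIC_SOC_MATRIX


@pytest.fixture
def degenerate_inputs():
    """All patients identical, all experts identical: zero sampling variance.

    Strata are still populated (2/2/2) so the stratified bootstrap runs.
    """
    patients = []
    for i, stratum in enumerate(
        [Stratum.SINGLE_BLIND_ONLY] * 2 + [Stratum.DB_SATIVEX] * 2 + [Stratum.DB_PLACEBO] * 2
    ):
        n_cycles = 2 if stratum == Stratum.SINGLE_BLIND_ONLY else 6
        nrs = {c: {0: 2.0, 1: 5.0, 2: 8.0}[c % 3] for c in range(1, n_cycles + 1)}
        util = {c: 0.5 for c in range(1, n_cycles + 1)}
        patients.append(PatientRecord(f"P{i}", stratum, nrs, util))
    trial = TrialDataset.from_patients(patients)
    panel = DelphiPanelData(
        [f"E{i}" for i in range(8)],
        ["visit"],
        np.tile(np.array([[1.0], [2.0], [3.0]]), (8, 1, 1)),
    )
    tariffs = UnitCostTable({"visit": 50.0})
    return trial, panel, tariffs
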