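import numpy as np
import pandas as pd
import pytest

from synertri.models import AssayDataset
from synertri.pipeline import RunConfig, run_analysis
from synertri.synthetic import (
    GeneratorConfig,
    all_active_config,
    generate_assay,
    make_table1_fixture,
)


def make_mediator_rows(endpoint="IL6", compartment="macrophage_basolateral"):
    """Minimal well-formed 3-row mediator table: s, ua and one treated well."""
    return pd.DataFrame(
        {
            "endpoint": [endpoint] * 3,
            "compartment": [compartment] * 3,
            "treatment": ["control", "control", "myrrh"],
            "control_class": ["s", "ua", "treated"],
            "concentration_ug_ml": [0.0, 0.0, 10.0],
            "time_h": [48.0] * 3,
            "replicate": [1, 1, 1],
            "value": [850.0, 100.0, 400.0],
            "value_before": [np.nan] * 3,
            "value_after": [np.nan] * 3,
        }
    )


@pytest.fixture
def tiny_dataset():
    return AssayDataset(df=make_mediator_rows())


@pytest.fixture(scope="session")
def noisefree_assay():
    """All-active truth, zero noise: every 7 x 4 cell has a defined potency."""
    cfg = all_active_config(noise_cv=0.0, seed=1)
    return generate_assay(cfg)


@pytest.fixture(scope="session")
def table1_assay():
    """Low-noise plate whose true potencies equal the published estimates."""
    return make_table1_fixture(seed=0)


@pytest.fixture(scope="session")
def table1_run(tmp_path_factory, table1_assay):
    """Full pipeline run on the low-noise fixture (computed once per session),
    with its CSV/JSON outputs written to a session temp dir."""
    ds, _ = table1_assay
    outdir = tmp_path_factory.mktemp("table1_run")
    report = run_analysis(ds, RunConfig(seed=0, outdir=outdir))
    return report, outdir


@pytest.fixture(scope="session")
def table1_report(table1_run):
    return table1_run[0]


@pytest.fixture(scope="session")
def default_noisy_assay():
    return generate_assay(GeneratorConfig(noise_cv=0.15, seed=3))
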