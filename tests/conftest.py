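import numpy as np
import pytest

import nf1mod as nm


@pytest.fixture(scope="session")
def default_study():
    """One default-sized synthetic study shared across the suite."""
    return nm.simulate_study(nm.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def study_dir(default_study, tmp_path_factory):
    d = tmp_path_factory.mktemp("study")
    nm.write_study(default_study, d)
    return d


@pytest.fixture(scope="session")
def qc_study(default_study):
    """QC'd genotypes + report for the shared study."""
    samples = [
        nm.SampleRecord(i, r["age"], r["sex"], r["cohort"])
        for i, r in default_study["samples"].iterrows()
    ]
    filtered, report = nm.qc_genotypes(default_study["genotypes"], samples=samples)
    return filtered, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
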