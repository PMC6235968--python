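import numpy as np
import pytest

from prmquantkit import assay_design, simdata


@pytest.fixture(scope="session")
def reference_panel():
    return assay_design.load_reference_panel()


@pytest.fixture(scope="session")
def toy_proteome():
    return [
        assay_design.ProteinEntry("P1", "MKDSSFNSAYNLPIPRVLPESVSRK"),
        assay_design.ProteinEntry("P2", "AAAKPGGGRISPNSPVAR"),
        assay_design.ProteinEntry("P3", "GGGGGGRPEPTIDEK"),
    ]


@pytest.fixture(scope="session")
def noise_free_config():
    return simdata.SimulationConfig(noise_sd=0.0, rt_jitter_sd=0.0,
                                    mz_error_ppm_sd=0.0)


@pytest.fixture(scope="session")
def default_truth(reference_panel):
    return simdata.default_ground_truth(reference_panel, seed=7)


@pytest.fixture(scope="session")
def noise_free_run(noise_free_config, default_truth, reference_panel):
    return simdata.simulate_run(noise_free_config, default_truth,
                                reference_panel, seed=11, stage="MG")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
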