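import numpy as np
import pytest

from kdprof.design import TitrationDesign, default_design
from kdprof.simulate import NoiseModel, generate_quant_tables


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def single_probe_design(design):
    """One probe, one condition -- the smallest unit the fitter sees."""
    return TitrationDesign(
        design.channel_concentrations, 3, ("probe",), (("nuclear", "Mg"),)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noiseless_binders(single_probe_design):
    """Small all-binder dataset with no noise and no dropout."""
    return generate_quant_tables(
        design=single_probe_design,
        n_proteins=40,
        binder_fraction=1.0,
        kd_range=(0.1, 30.0),
        noise=NoiseModel(cv=0.0, missing_rate_low=0.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def noisy_dataset(single_probe_design):
    """Default-noise mixed binder/non-binder dataset."""
    return generate_quant_tables(
        design=single_probe_design,
        n_proteins=120,
        binder_fraction=0.5,
        kd_range=(0.1, 30.0),
        seed=8,
    )
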