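import pytest
from hypothesis import settings

import emuflux as ef

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def glycolysis():
    """Steady-state upper-glycolysis bundle at the reference fluxes."""
    return ef.build_upper_glycolysis()


@pytest.fixture(scope="session")
def printed_fbp_measurement():
    """The FBP MID as printed to four decimals, 1% SD per fraction."""
    return ef.read_measurements(
        "emu,mass_shift,fraction,sd\n"
        "FBP[1-6],0,0.0500,0.01\n"
        "FBP[1-6],2,0.8333,0.01\n"
        "FBP[1-6],4,0.1167,0.01\n"
    )


@pytest.fixture(scope="session")
def exact_fbp_measurement(glycolysis):
    """Noiseless FBP MID generated from the reference fluxes (1% weights)."""
    b = glycolysis
    return ef.generate_synthetic_measurements(
        b.model, b.fluxes, b.tracer, ["FBP[1-6]"], sd=0.0, record_sd=0.01
    )


@pytest.fixture(scope="session")
def printed_fit(glycolysis, printed_fbp_measurement):
    return ef.fit(
        glycolysis.model,
        printed_fbp_measurement,
        glycolysis.tracer,
        fixed={"f1": 100.0},
        n_starts=4,
        seed=11,
    )
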