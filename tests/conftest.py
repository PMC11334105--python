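import numpy as np
import pytest

from covkin import reference_data as ref
from covkin.kinetics import TwoStepParams
from covkin.thermo import ThermoContext


@pytest.fixture(scope="session")
def ctx() -> ThermoContext:
    """Default physical context: 298.15 K, 5 mM GSH, pH 7.4, pKa 8.7."""
    return ThermoContext()


@pytest.fixture(scope="session")
def params_1a() -> TwoStepParams:
    """Kinetic constants of the acrylamide lead (K_I 34.8 uM, k_inact 10.1e-3/s)."""
    return TwoStepParams(K_I=34.8e-6, k_inact=10.1e-3)


@pytest.fixture(scope="session")
def panel():
    """(compound, TwoStepParams, schedule class) for the full nine-compound panel."""
    out = []
    for cpd in ref.COMPOUNDS:
        row = ref.KINETICS[cpd]
        out.append((
            cpd,
            TwoStepParams(K_I=row["KI_um"] * 1e-6, k_inact=row["kinact_mili"] * 1e-3),
            ref.OCCUPANCY_SCHEDULE_CLASS[cpd],
        ))
    return out


@pytest.fixture(scope="session")
def noiseless_study():
    """Complete synthetic study with every noise source switched off."""
    from covkin.synthetic import generate_study

    return generate_study(seed=0, occupancy_noise_sd=0.0, gsh_noise_sd=0.0,
                          exchange_noise_sd=0.0, viability_noise_sd=0.0)
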