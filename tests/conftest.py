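import pytest
from hypothesis import settings

from aromatherm import benson, calorimetry

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from aromatherm.workbench import _data_path


@pytest.fixture(scope="session")
def tmac_experiments():
    """The seven packaged bomb-calorimetry runs for trimellitic acid."""
    with _data_path("tmac_combustion.csv").open() as fh:
        return calorimetry.read_experiments_csv(fh)


@pytest.fixture(scope="session")
def calibration():
    return calorimetry.CalorimeterCalibration()


@pytest.fixture(scope="session")
def tmac_compound():
    return calorimetry.CompoundPhysical(
        formula={"C": 9, "H": 6, "O": 6},
        M=210.140,
        density=1.580,
        cp_massic=1.18,
        name="trimellitic acid",
    )


@pytest.fixture(scope="session")
def catalog_gas_cr():
    return benson.load_default_catalog("benson_original")
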