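import pytest

from ngra import datasets
from ngra.pbpk import DosingSchedule, one_compartment_params


@pytest.fixture(scope="session")
def rat_oral_genistein():
    return datasets.load_pbpk_config("genistein-rat-oral")


@pytest.fixture(scope="session")
def rat_oral_daidzein():
    return datasets.load_pbpk_config("daidzein-rat-oral")


@pytest.fixture(scope="session")
def human_dermal_daidzein():
    return datasets.load_pbpk_config("daidzein-human-dermal")


@pytest.fixture(scope="session")
def rat_noael_schedule():
    return DosingSchedule(route="oral", dose=0.3, n_doses=7)


@pytest.fixture(scope="session")
def body_lotion_schedule():
    return DosingSchedule(route="dermal", dose=0.5, area_cm2=15670.0, n_doses=7)


@pytest.fixture(scope="session")
def one_comp():
    return one_compartment_params(volume=0.8, k_elim=0.15)


@pytest.fixture(scope="session")
def assay_table():
    return datasets.assay_panel_table()
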