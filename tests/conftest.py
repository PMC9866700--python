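import pathlib

import pytest

from chemopheno.library import SPECIES_ORDER, load_library, load_table2
from chemopheno.simulate import AcquisitionSettings, GroundTruth, generate_run, write_run


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def table2():
    """Published normalized AUC matrix (species columns only)."""
    return load_table2()[SPECIES_ORDER]


@pytest.fixture(scope="session")
def low_noise_truth():
    return GroundTruth.from_table2(seed=1).low_noise()


@pytest.fixture(scope="session")
def run_dir(tmp_path_factory, library, low_noise_truth) -> pathlib.Path:
    """Five low-noise synthetic runs (one per species), written once."""
    d = tmp_path_factory.mktemp("runs")
    settings = AcquisitionSettings()
    for species in SPECIES_ORDER:
        write_run(generate_run(library, low_noise_truth, settings, species), d)
    return d


@pytest.fixture(scope="session")
def morpho_table():
    from chemopheno.morpho import generate_morphometrics

    return generate_morphometrics(seed=0)
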