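import numpy as np
import pytest

from phagegeo import (
    CurveTruth,
    PlateTruth,
    chloride_salt,
    gen_environment_profiles,
    gen_ion_array_plate,
    series_from_plate,
)


@pytest.fixture(scope="session")
def cytoplasm_profile():
    return next(p for p in gen_environment_profiles() if p.category == "cytoplasm")


@pytest.fixture(scope="session")
def seawater_profile():
    return next(p for p in gen_environment_profiles() if p.name == "seawater")


def make_series(
    ec50=10.0,
    hill=2.0,
    top=1.0,
    bottom=0.0,
    noise_sd=0.0,
    seed=0,
    top_conc=None,
    n_replicates=2,
    ion="X+",
    phage="none",
):
    """One normalized dose series from the plate generator."""
    truth = PlateTruth(
        curves={(ion, phage): CurveTruth(ec50=ec50, hill=hill, top=top, bottom=bottom)},
        noise_sd=noise_sd,
        seed=seed,
    )
    plate = gen_ion_array_plate(
        [chloride_salt(ion, 1)],
        truth,
        top_conc=top_conc if top_conc is not None else 32 * ec50,
        n_replicates=n_replicates,
        phage_conditions=(phage,),
    )
    return series_from_plate(plate)[0]


@pytest.fixture
def noiseless_series():
    return make_series()
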