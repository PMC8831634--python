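import numpy as np
import pandas as pd
import pytest

import enmrisk as e


@pytest.fixture(scope="session")
def small_stack():
    spec = e.GridSpec(50, 50, 0.1, -50.0, -30.0)
    return e.make_climate_stack(spec, ["bio01", "bio12", "bio15"],
                                autocorr_range=5, seed=11)


@pytest.fixture(scope="session")
def selective_species(small_stack):
    """Strongly unimodal niche: suitable only in a narrow climate band."""
    return e.make_virtual_species(small_stack,
                                  {"bio01": 10.0, "bio12": 6.0},
                                  {"bio01": -25.0, "bio12": -15.0})


@pytest.fixture(scope="session")
def clustered_species(small_stack):
    """Spatially compact species: a single Gaussian bump of suitability.

    Useful where the test needs geographic clustering (outlier detection)
    or an exactly known concentrated sampling target.
    """
    ii, jj = np.mgrid[0:small_stack.grid.n_rows, 0:small_stack.grid.n_cols]
    suit = np.exp(-(((ii - 30) ** 2 + (jj - 20) ** 2) / (2 * 2.5 ** 2)))
    return e.VirtualSpecies({}, {}, suit, small_stack)


@pytest.fixture(scope="session")
def presence_sample(selective_species):
    return e.sample_occurrences(selective_species, 200, seed=7)


def make_occ(lonlat, species_id="sp", growth_form="herb"):
    lonlat = np.asarray(lonlat, dtype=float)
    return e.OccurrenceSet(
        species_id=species_id, growth_form=growth_form,
        records=pd.DataFrame({"decimalLongitude": lonlat[:, 0],
                              "decimalLatitude": lonlat[:, 1]}))


@pytest.fixture
def occ_factory():
    return make_occ
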