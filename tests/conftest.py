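import numpy as np
import pytest

from mudflat.design import DesignSpec, generate_design
from mudflat.processing import DEFAULT_PROTOCOL
from mudflat.raster import full_mask
from mudflat.worldgen import (
    SpeciesTruth,
    WorldConfig,
    build_world,
    individuals_to_frame,
    simulate_campaign,
)


@pytest.fixture(scope="session")
def protocol():
    return DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def small_world():
    """A 3 x 3 km world with two contrasting species on 100-m cells."""
    cfg = WorldConfig(
        extent=(3000.0, 3000.0),
        cell_size=100.0,
        intertidal_fraction=1.0,
        n_basins=2,
        species_params=(
            SpeciesTruth(
                sibes_id=1,
                name="Macoma synthetica",
                mean_log_density=np.log(200.0),
                sill=0.4,
                range_m=500.0,
                length_meanlog=np.log(12.0),
                length_sdlog=0.35,
                noise_sd=0.15,
            ),
            SpeciesTruth(
                sibes_id=2,
                name="Peringia synthetica",
                mean_log_density=np.log(600.0),
                sill=0.6,
                range_m=800.0,
                length_meanlog=np.log(3.0),
                length_sdlog=0.3,
                small_species=True,
                subsampling_eligible=True,
                noise_sd=0.15,
            ),
        ),
        seed=11,
    )
    return build_world(cfg)


@pytest.fixture(scope="session")
def small_campaign(small_world):
    stations = generate_design(
        small_world.intertidal_mask,
        DesignSpec(spacing=500.0, random_fraction=0.2, seed=4),
        basin_map=small_world.basin_id,
    )
    events, individuals, spectra = simulate_campaign(
        small_world, stations, year=2015, seed=7
    )
    return stations, events, individuals, spectra


@pytest.fixture(scope="session")
def small_tables(small_world, small_campaign):
    from mudflat.worldgen import campaign_to_tables

    _, events, individuals, spectra = small_campaign
    return campaign_to_tables(small_world, events, individuals, spectra)


@pytest.fixture(scope="session")
def individuals_frame(small_world, small_campaign):
    _, events, individuals, _ = small_campaign
    return individuals_to_frame(small_world, events, individuals)
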