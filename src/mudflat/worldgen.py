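"""Virtual mudflat worlds and simulated sampling campaigns.

A world is a set of co-registered rasters on a metric grid: a boolean
intertidal mask, a tidal-basin map, one latent density surface per species
(the exponential of a Gaussian random field, so densities are log-Gaussian),
and two sediment surfaces (log median grain size of the sand mode, and the
mud fraction on the logit scale). A campaign visits a list of stations and
draws what the field and laboratory protocol would record there:

* per-species counts are Poisson with mean latent density x core area;
* each individual gets a lognormal length; individuals below the 1-mm sieve
  mesh are lost;
* abundant subsampling-eligible taxa are subsampled (about 30 individuals
  measured, the fraction noted down);
* ash-free dry mass follows the species' power-law allometry with lognormal
  noise; lengths, masses and whole shells go missing with configured
  probabilities, and "broken" individuals carry only a shell width;
* a grain-size spectrum is drawn as a two-mode (mud/sand) lognormal mixture
  weighted by the local mud-fraction field, binned onto the 126 instrument
  classes.

Every stochastic step runs off one seeded generator, so identical
(config, seed) reproduces identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import geo
from .errors import ConfigurationError, SpatialError
from .processing import (
    DEFAULT_PROTOCOL,
    IndividualRecord,
    ProtocolConstants,
    SedimentSpectrum,
    reduce_sediment_spectrum,
    standardize,
)
from .random_fields import simulate_on_raster
from .raster import Raster

__all__ = [
    "SpeciesTruth",
    "SedimentFieldParams",
    "WorldConfig",
    "SyntheticWorld",
    "SampleEvent",
    "build_world",
    "simulate_campaign",
    "campaign_to_tables",
    "individuals_to_frame",
    "write_truth_sidecar",
    "load_world_config",
]


@dataclass(frozen=True)
class SpeciesTruth:
    """Generative parameters of one species: the ground truth tests recover."""

    sibes_id: int
    name: str
    mean_log_density: float = np.log(100.0)  # log individuals per m^2
    nugget: float = 0.0                      # micro-scale variance of log density
    sill: float = 0.5                        # structured variance of log density
    range_m: float = 500.0                   # e-folding range of the log-density GRF
    allometry_a: float = 1e-5                # AFDM(g) = a * L(mm)^b
    allometry_b: float = 3.0
    noise_sd: float = 0.15                   # lognormal mass noise (log scale)
    length_meanlog: float = np.log(10.0)     # lognormal length law (mm)
    length_sdlog: float = 0.4
    small_species: bool = False              # lengths predominantly < 11 mm
    p_missing_length: float = 0.0
    p_missing_afdm: float = 0.0
    p_broken: float = 0.0
    subsampling_eligible: bool = False
    taxonomic_group: str = "bivalve"
    count_whole_only: bool = False

    def __post_init__(self) -> None:
        if self.sill < 0 or self.nugget < 0:
            raise ConfigurationError("sill and nugget must be non-negative")
        if self.range_m <= 0:
            raise ConfigurationError("range_m must be positive")
        if self.allometry_a <= 0:
            raise ConfigurationError("allometry coefficient a must be positive")
        for p in (self.p_missing_length, self.p_missing_afdm, self.p_broken):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SedimentFieldParams:
    """GRF parameters for log median grain size and logit mud fraction."""

    mgs_mean_log: float = np.log(150.0)  # sand-mode median, um
    mgs_sill: float = 0.05
    mgs_range_m: float = 1500.0
    mud_mean_logit: float = -1.5         # mean mud fraction ~ 0.18
    mud_sill: float = 0.8
    mud_range_m: float = 1500.0


@dataclass(frozen=True)
class WorldConfig:
    extent: tuple[float, float] = (8000.0, 8000.0)  # width, height in m
    cell_size: float = 100.0
    intertidal_fraction: float = 1.0
    n_basins: int = 2
    species_params: tuple[SpeciesTruth, ...] = ()
    sediment_params: SedimentFieldParams = field(default_factory=SedimentFieldParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ConfigurationError("extent must be positive")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if not (0.0 <= self.intertidal_fraction <= 1.0):
            raise ConfigurationError("intertidal_fraction must lie in [0, 1]")
        if self.n_basins < 1:
            raise ConfigurationError("need at least one tidal basin")
        object.__setattr__(self, "species_params", tuple(self.species_params))


@dataclass
class SyntheticWorld:
    config: WorldConfig
    intertidal_mask: Raster
    basin_id: Raster
    density: dict[int, Raster]      # sibes_id -> individuals per m^2
    mgs_sand_um: Raster             # sand-mode median grain size, um
    mud_fraction: Raster            # in [0, 1]

    @property
    def truth(self) -> WorldConfig:
        return self.config

    def basin_name(self, x: float, y: float) -> str:
        return f"basin_{int(self.basin_id.value_at(x, y)) + 1:02d}"


@dataclass
class SampleEvent:
    """One visit to a station: links a sample_id to place, date and platform."""

    sample_id: str
    sampling_station_id: str
    sampling_type: str
    date: str
    platform: str
    year: int
    x_m: float
    y_m: float
    tidal_basin_name: str
    sampled_area_m2: float


def build_world(config: WorldConfig) -> SyntheticWorld:
    """Realize a virtual mudflat world from its configuration (deterministic)."""
    rng = np.random.default_rng(config.seed)
    w, h = config.extent
    nx = max(int(round(w / config.cell_size)), 1)
    ny = max(int(round(h / config.cell_size)), 1)
    shape = (ny, nx)

    # intertidal mask: threshold a smooth field at the requested area fraction
    if config.intertidal_fraction >= 1.0:
        mask = np.ones(shape, dtype=bool)
    elif config.intertidal_fraction <= 0.0:
        mask = np.zeros(shape, dtype=bool)
    else:
        relief = simulate_on_raster(
            shape, config.cell_size, 0.0, 1.0, 0.25 * min(w, h), rng
        )
        cut = np.quantile(relief, 1.0 - config.intertidal_fraction)
        mask = relief >= cut

    basin = np.zeros(shape, dtype=int)
    band = nx / config.n_basins
    for col in range(nx):
        basin[:, col] = min(int(col / band), config.n_basins - 1)

    density: dict[int, Raster] = {}
    for sp in config.species_params:
        # the latent *surface* carries the structured component only; the
        # nugget is micro-scale noise realized when values are drawn at points
        g = simulate_on_raster(shape, config.cell_size, 0.0, sp.sill, sp.range_m, rng)
        density[sp.sibes_id] = Raster(
            np.exp(sp.mean_log_density + g), config.cell_size
        )

    sed = config.sediment_params
    g_mgs = simulate_on_raster(shape, config.cell_size, 0.0, sed.mgs_sill, sed.mgs_range_m, rng)
    g_mud = simulate_on_raster(shape, config.cell_size, 0.0, sed.mud_sill, sed.mud_range_m, rng)
    mgs = Raster(np.exp(sed.mgs_mean_log + g_mgs), config.cell_size)
    mud = Raster(1.0 / (1.0 + np.exp(-(sed.mud_mean_logit + g_mud))), config.cell_size)

    return SyntheticWorld(
        config=config,
        intertidal_mask=Raster(mask, config.cell_size),
        basin_id=Raster(basin, config.cell_size),
        density=density,
        mgs_sand_um=mgs,
        mud_fraction=mud,
    )


def _draw_spectrum(
    mud_fraction: float,
    sand_mgs_um: float,
    rng: np.random.Generator,
    constants: ProtocolConstants,
    n_particles: int = 20000,
) -> np.ndarray:
    """Two-mode lognormal grain-size mixture binned to the instrument classes."""
    edges = constants.grain_class_edges_um
    log_edges = np.log(edges)
    from scipy.stats import norm

    mud_cdf = norm.cdf(log_edges, loc=np.log(15.0), scale=0.8)
    sand_cdf = norm.cdf(log_edges, loc=np.log(max(sand_mgs_um, 70.0)), scale=0.45)
    p = mud_fraction * np.diff(mud_cdf) + (1.0 - mud_fraction) * np.diff(sand_cdf)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    counts = rng.multinomial(n_particles, p)
    return counts / counts.sum()


def simulate_campaign(
    world: SyntheticWorld,
    stations: Sequence,
    year: int,
    protocol: ProtocolConstants = DEFAULT_PROTOCOL,
    seed: int = 0,
    p_boat: float = 0.92,
) -> tuple[list[SampleEvent], list[IndividualRecord], list[SedimentSpectrum]]:
    """Simulate one field season at the given stations.

    ``stations`` are :class:`mudflat.design.Station` objects (anything with
    station_id, sampling_type, x, y works). Inactive stations are skipped.
    """
    if seed < 0:
        raise ConfigurationError("seed must be non-negative")
    rng = np.random.default_rng(seed)
    events: list[SampleEvent] = []
    individuals: list[IndividualRecord] = []
    spectra: list[SedimentSpectrum] = []

    active = [s for s in stations if getattr(s, "active", True)]
    for i, st in enumerate(active):
        if not world.intertidal_mask.contains(st.x, st.y):
            raise SpatialError(f"station {st.station_id} outside world extent")
        platform = "boat" if rng.random() < p_boat else "walk"
        area = protocol.area_m2(platform)
        sample_id = f"{year}_{i + 1:05d}"
        day = int(rng.integers(0, 90))  # June-August window
        date = (pd.Timestamp(f"{year}-06-01") + pd.Timedelta(days=day)).date().isoformat()
        basin = world.basin_name(st.x, st.y)
        events.append(
            SampleEvent(
                sample_id=sample_id,
                sampling_station_id=st.station_id,
                sampling_type=getattr(st, "sampling_type", "grid"),
                date=date,
                platform=platform,
                year=year,
                x_m=st.x,
                y_m=st.y,
                tidal_basin_name=basin,
                sampled_area_m2=area,
            )
        )

        for sp in world.config.species_params:
            dens = float(world.density[sp.sibes_id].value_at(st.x, st.y))
            if sp.nugget > 0:
                dens *= np.exp(rng.normal(0.0, np.sqrt(sp.nugget)))
            n = int(rng.poisson(dens * area))
            if n == 0:
                continue
            lengths = rng.lognormal(sp.length_meanlog, sp.length_sdlog, size=n)
            lengths = lengths[lengths >= protocol.sieve_mesh_mm]
            count = lengths.size
            if count == 0:
                continue
            fraction = 1.0
            if sp.subsampling_eligible and count > protocol.subsample_trigger:
                fraction = protocol.subsample_min / count
                keep = rng.random(count) < fraction
                lengths = lengths[keep]
                if lengths.size == 0:
                    continue
            for L in lengths:
                afdm = sp.allometry_a * L**sp.allometry_b * np.exp(
                    rng.normal(0.0, sp.noise_sd)
                )
                rec = IndividualRecord(
                    sample_id=sample_id,
                    sibes_id=sp.sibes_id,
                    count_unit="whole",
                    length_mm=float(L),
                    afdm_g=float(afdm),
                    subsample_fraction=fraction,
                    era=year,
                )
                if rng.random() < sp.p_broken:
                    # broken shell: only a width survives, on the top or bottom
                    rec.length_mm = None
                    if rng.random() < 0.5:
                        rec.width_top_mm = float(L / protocol.ensis_coef_top)
                    else:
                        rec.width_bottom_mm = float(L / protocol.ensis_coef_bottom)
                    rec.count_unit = "fragment"
                elif rng.random() < sp.p_missing_length:
                    rec.length_mm = None
                if rng.random() < sp.p_missing_afdm:
                    rec.afdm_g = None
                individuals.append(rec)

        spec = _draw_spectrum(
            float(world.mud_fraction.value_at(st.x, st.y)),
            float(world.mgs_sand_um.value_at(st.x, st.y)),
            rng,
            protocol,
        )
        spectra.append(SedimentSpectrum(sample_id=sample_id, volume_fraction=spec))

    return events, individuals, spectra


def _species_table(config: WorldConfig) -> pd.DataFrame:
    rows = []
    for sp in config.species_params:
        rows.append(
            {
                "sibes_id": sp.sibes_id,
                "name": sp.name,
                "short_name": sp.name[:8],
                "aphia_id": 100000 + sp.sibes_id,
                "taxonomic_group": sp.taxonomic_group,
                "taxonomic_indentification_level": "species",
                "year_added": 2008,
                "occurance": np.nan,
                "occupancy": np.nan,
                "weight_is_measured": True,
                "length_measuring_method_id": 1,
                "min_shell_length_to_separate_flesh": np.nan,
                "missing_afdm_method_id": 24,
                "remarks": "synthetic taxon",
            }
        )
    return pd.DataFrame(rows)


def campaign_to_tables(
    world: SyntheticWorld,
    events: Sequence[SampleEvent],
    individuals: Sequence[IndividualRecord],
    spectra: Sequence[SedimentSpectrum],
    protocol: ProtocolConstants = DEFAULT_PROTOCOL,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Serialize a simulated campaign into the published three-file schemas.

    Returns (samples, species, biota) DataFrames with exactly the published
    columns. Individual densities are standardized by core area and subsample
    fraction and summed per (sample_id, sibes_id); absent species yield no row.
    """
    sed = {s.sample_id: reduce_sediment_spectrum(s, protocol) for s in spectra}
    sample_rows = []
    for ev in events:
        lon, lat = geo.to_lonlat(ev.x_m, ev.y_m)
        mgs, mud = sed.get(ev.sample_id, (np.nan, np.nan))
        sample_rows.append(
            {
                "sample_id": ev.sample_id,
                "sampling_station_id": ev.sampling_station_id,
                "sampling_type": ev.sampling_type,
                "date": ev.date,
                "platform": ev.platform,
                "tidal_basin_name": ev.tidal_basin_name,
                "tidal_flat_name": ev.tidal_basin_name + "_flat",
                "x": lon,
                "y": lat,
                "median_grain_size": mgs,
                "percentage_mud": mud,
            }
        )
    samples = pd.DataFrame(sample_rows)

    area = {ev.sample_id: ev.sampled_area_m2 for ev in events}
    platform = {ev.sample_id: ev.platform for ev in events}
    agg: dict[tuple[str, int], list[float]] = {}
    for rec in individuals:
        ab, af = standardize(
            1.0,
            rec.afdm_g,
            rec.subsample_fraction,
            platform[rec.sample_id],
            protocol,
        )
        key = (rec.sample_id, rec.sibes_id)
        cur = agg.setdefault(key, [0.0, 0.0, False])
        cur[0] += ab
        if af is not None:
            cur[1] += af
            cur[2] = True
    biota = pd.DataFrame(
        [
            {
                "sample_id": k[0],
                "sibes_id": k[1],
                "abundance_m2": v[0],
                "afdm_m2": v[1] if v[2] else np.nan,
            }
            for k, v in sorted(agg.items())
        ],
        columns=["sample_id", "sibes_id", "abundance_m2", "afdm_m2"],
    )
    return samples, _species_table(world.config), biota


def individuals_to_frame(
    world: SyntheticWorld,
    events: Sequence[SampleEvent],
    individuals: Sequence[IndividualRecord],
) -> pd.DataFrame:
    """Individual records as the long-format frame the imputer consumes.

    Adds year, tidal basin and region per record; the region is the default
    west/east split of the basins (configurable groupings belong to the
    caller).
    """
    ev = {e.sample_id: e for e in events}
    n_basins = world.config.n_basins
    rows = []
    for rec in individuals:
        e = ev[rec.sample_id]
        basin_no = int(e.tidal_basin_name.rsplit("_", 1)[-1])
        rows.append(
            {
                "sample_id": rec.sample_id,
                "sibes_id": rec.sibes_id,
                "length_mm": rec.length_mm,
                "afdm_g": rec.afdm_g,
                "subsample_fraction": rec.subsample_fraction,
                "year": e.year,
                "tidal_basin_name": e.tidal_basin_name,
                "region": "west" if basin_no <= (n_basins + 1) // 2 else "east",
            }
        )
    return pd.DataFrame(rows)


def write_truth_sidecar(path, config: WorldConfig) -> None:
    """Write the generator parameters next to the CSVs as structured text."""

    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=encode)


def load_world_config(path) -> WorldConfig:
    """Load a :class:`WorldConfig` from a YAML or JSON text file."""
    import yaml

    with open(path) as fh:
        text = fh.read()
    try:  # JSON first: PyYAML mis-parses exponent notation like 1e-05
        raw = json.loads(text)
    except json.JSONDecodeError:
        raw = yaml.safe_load(text)
    species = tuple(SpeciesTruth(**sp) for sp in raw.pop("species_params", []))
    sed = raw.pop("sediment_params", None)
    kwargs = dict(raw)
    if "extent" in kwargs:
        kwargs["extent"] = tuple(kwargs["extent"])
    if sed is not None:
        kwargs["sediment_params"] = SedimentFieldParams(**sed)
    return WorldConfig(species_params=species, **kwargs)
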