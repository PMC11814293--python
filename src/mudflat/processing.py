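"""Field/laboratory protocol rules: counting, standardization, sediment reduction.

These are the deterministic bookkeeping rules that turn raw sample contents
into per-square-metre records: fragment-aware counting of polychaetes,
subsample correction, core-area standardization (boat cores 0.0173 m^2, walk
cores 0.0177 m^2), razor-clam (Ensis) length estimation from shell-top or
shell-bottom width, and the reduction of a 126-class laser-diffraction
grain-size spectrum to median grain size and mud content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import SchemaError

__all__ = [
    "ProtocolConstants",
    "DEFAULT_PROTOCOL",
    "IndividualRecord",
    "SedimentSpectrum",
    "count_individuals",
    "standardize",
    "estimate_ensis_length",
    "reduce_sediment_spectrum",
]


def _grain_class_edges(lo: float, hi: float, n_classes: int) -> np.ndarray:
    return np.geomspace(lo, hi, n_classes + 1)


@dataclass(frozen=True)
class ProtocolConstants:
    """Survey protocol constants; defaults are the published field/lab values."""

    area_boat_m2: float = 0.0173      # combined area of the two boat cores
    area_walk_m2: float = 0.0177      # single core taken by foot
    sieve_mesh_mm: float = 1.0        # round mesh used in the field
    mud_threshold_um: float = 63.0    # mud = volume % of grains below this
    grain_class_lo_um: float = 0.04
    grain_class_hi_um: float = 2000.0
    n_grain_classes: int = 126
    subsample_min: int = 30           # individuals measured when subsampling
    subsample_trigger: int = 100      # counts above this trigger a subsample
    ensis_coef_top: float = 6.5       # length = 6.5 x width of shell top
    ensis_coef_bottom: float = 6.6    # length = 6.6 x width of shell bottom
    loess_span: float = 0.6
    scale_threshold_standard: int = 75   # records needed for a LOESS fit
    scale_threshold_small: int = 45      # ... for taxa predominantly < 11 mm
    scale_threshold_mean: int = 30       # ... for a hierarchical-mean fallback
    small_species_length_mm: float = 11.0
    map_resolution_m: float = 25.0
    grid_spacing_m: float = 500.0
    polychaete_head_count_year: int = 2011  # heads-only counting from this year

    def __post_init__(self) -> None:
        for name in (
            "area_boat_m2", "area_walk_m2", "sieve_mesh_mm", "mud_threshold_um",
            "grain_class_lo_um", "grain_class_hi_um", "subsample_min",
            "ensis_coef_top", "ensis_coef_bottom", "loess_span",
            "map_resolution_m", "grid_spacing_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.area_boat_m2 == self.area_walk_m2:
            raise ValueError("boat and walk core areas must differ")
        if self.grain_class_lo_um >= self.grain_class_hi_um:
            raise ValueError("grain class edges must increase")

    @property
    def grain_class_edges_um(self) -> np.ndarray:
        """127 geometrically spaced class edges spanning the instrument range."""
        return _grain_class_edges(
            self.grain_class_lo_um, self.grain_class_hi_um, self.n_grain_classes
        )

    def area_m2(self, platform: str) -> float:
        if platform == "boat":
            return self.area_boat_m2
        if platform == "walk":
            return self.area_walk_m2
        raise ValueError(f"unknown platform {platform!r} (expected 'boat' or 'walk')")


DEFAULT_PROTOCOL = ProtocolConstants()


@dataclass
class IndividualRecord:
    """One organism (or fragment set) as recorded in the laboratory."""

    sample_id: str
    sibes_id: int
    count_unit: str = "whole"  # whole | head | tail | fragment
    length_mm: Optional[float] = None
    length_estimated: bool = False
    width_top_mm: Optional[float] = None
    width_bottom_mm: Optional[float] = None
    afdm_g: Optional[float] = None
    subsample_fraction: float = 1.0
    era: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.afdm_g is not None and self.afdm_g < 0:
            raise ValueError("afdm_g must be non-negative")
        if self.length_mm is not None and self.length_mm <= 0:
            raise ValueError("length_mm must be positive")


@dataclass
class SedimentSpectrum:
    """Volume fractions over the 126 grain-size classes of one sample."""

    sample_id: str
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)

    def validate(self, constants: ProtocolConstants = DEFAULT_PROTOCOL) -> None:
        v = self.volume_fraction
        if v.shape != (constants.n_grain_classes,):
            raise SchemaError(
                f"spectrum must have {constants.n_grain_classes} classes, got {v.shape}"
            )
        if np.any(v < 0):
            raise SchemaError("volume fractions must be non-negative")
        if abs(v.sum() - 1.0) > 1e-6:
            raise SchemaError(f"volume fractions must sum to 1 (got {v.sum():.8f})")


def count_individuals(
    fragments: Mapping[str, int],
    taxon,
    year: int,
    constants: ProtocolConstants = DEFAULT_PROTOCOL,
) -> int:
    """Count individuals from a tally of body parts.

    Fragmenting polychaetes are counted as heads (plus wholes) from the
    heads-only era onward; before that, loose heads and tails were both
    tallied and the count takes max(heads, tails) so one fragmented animal is
    not counted twice. Taxa counted whole-only (the tube worm Lanice
    conchilega) ignore every fragment tally. Everything else counts wholes.
    """
    tallies = {k: int(fragments.get(k, 0)) for k in ("whole", "head", "tail", "fragment")}
    if any(v < 0 for v in tallies.values()):
        raise ValueError("fragment tallies must be non-negative")
    if getattr(taxon, "count_whole_only", False):
        return tallies["whole"]
    if getattr(taxon, "taxonomic_group", "") == "polychaete":
        if year >= constants.polychaete_head_count_year:
            return tallies["head"] + tallies["whole"]
        return max(tallies["head"], tallies["tail"]) + tallies["whole"]
    return tallies["whole"]


def standardize(
    count: float,
    afdm_total_g: Optional[float],
    subsample_fraction: float,
    platform: str,
    constants: ProtocolConstants = DEFAULT_PROTOCOL,
) -> tuple[float, Optional[float]]:
    """Convert a (sub)sample count and summed mass to per-m^2 densities.

    abundance_m2 = count / subsample_fraction / core_area(platform); the
    biomass column is standardized identically when a mass is present.
    """
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must be in (0, 1]")
    if count < 0:
        raise ValueError("count must be non-negative")
    area = constants.area_m2(platform)
    abundance_m2 = count / subsample_fraction / area
    afdm_m2 = None
    if afdm_total_g is not None:
        afdm_m2 = afdm_total_g / subsample_fraction / area
    return abundance_m2, afdm_m2


def estimate_ensis_length(
    width_mm: float, part: str, constants: ProtocolConstants = DEFAULT_PROTOCOL
) -> float:
    """Estimate razor-clam length (mm) from a shell-top or shell-bottom width."""
    if width_mm < 0:
        raise ValueError("width must be non-negative")
    if part == "top":
        return constants.ensis_coef_top * width_mm
    if part == "bottom":
        return constants.ensis_coef_bottom * width_mm
    raise ValueError(f"unknown shell part {part!r} (expected 'top' or 'bottom')")


def reduce_sediment_spectrum(
    spectrum: SedimentSpectrum, constants: ProtocolConstants = DEFAULT_PROTOCOL
) -> tuple[float, float]:
    """Reduce a grain-size spectrum to (median_grain_size_um, percentage_mud).

    Mud is the volume percentage below the 63-um threshold; the class
    straddling the threshold is split log-linearly. The median is the grain
    size at which the cumulative volume curve first reaches 0.5, interpolated
    log-linearly inside the crossing class.
    """
    spectrum.validate(constants)
    edges = constants.grain_class_edges_um
    v = spectrum.volume_fraction
    log_edges = np.log(edges)

    thr = constants.mud_threshold_um
    below = edges[1:] <= thr
    mud = v[below].sum()
    straddle = (edges[:-1] < thr) & (edges[1:] > thr)
    if straddle.any():
        i = int(np.flatnonzero(straddle)[0])
        frac = (np.log(thr) - log_edges[i]) / (log_edges[i + 1] - log_edges[i])
        mud += v[i] * frac
    percentage_mud = 100.0 * mud

    cum = np.concatenate([[0.0], np.cumsum(v)])
    j = int(np.searchsorted(cum, 0.5) - 1)
    j = min(max(j, 0), len(v) - 1)
    if v[j] > 0:
        frac = (0.5 - cum[j]) / v[j]
    else:  # cumulative sits exactly at 0.5 on a class edge
        frac = 0.0
    log_mgs = log_edges[j] + frac * (log_edges[j + 1] - log_edges[j])
    return float(np.exp(log_mgs)), float(percentage_mud)
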