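"""Planar <-> geographic coordinate conversion.

Survey geometry is done in a local metric plane (metres east/north of a
reference point). Output tables carry WGS84 decimal degrees, obtained with a
local tangent-plane (equirectangular) approximation anchored at a reference
longitude/latitude. Over a domain of ~100 km the distortion of this
approximation is far below the 500-m station spacing.
"""

from __future__ import annotations

import math

#: WGS84 mean Earth radius (m) — adequate for the tangent-plane approximation.
EARTH_RADIUS_M = 6_371_000.0

#: Default anchor: a point in the western Dutch Wadden Sea.
DEFAULT_REF_LONLAT = (5.20, 53.30)


def to_lonlat(
    x: float, y: float, ref_lonlat: tuple[float, float] = DEFAULT_REF_LONLAT
) -> tuple[float, float]:
    """Convert planar metres (east, north of the anchor) to WGS84 degrees."""
    lon0, lat0 = ref_lonlat
    lat = lat0 + math.degrees(y / EARTH_RADIUS_M)
    lon = lon0 + math.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
    return lon, lat


def to_planar(
    lon: float, lat: float, ref_lonlat: tuple[float, float] = DEFAULT_REF_LONLAT
) -> tuple[float, float]:
    """Inverse of :func:`to_lonlat`."""
    lon0, lat0 = ref_lonlat
    y = math.radians(lat - lat0) * EARTH_RADIUS_M
    x = math.radians(lon - lon0) * EARTH_RADIUS_M * math.cos(math.radians(lat0))
    return x, y
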