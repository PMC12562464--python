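"""Average-weighted (inverse-distance) interpolation of haplogroup
frequencies onto a geographic grid.

Each grid value is the weighted mean of the observed population frequencies
within a search radius, with weights ``1 / d^power`` (distance floored at
half the grid spacing to keep coincident points finite).  Grid points with
no observation in radius are NA.  Default parameters: 400 km search radius,
weight power 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
KM_PER_DEGREE = np.pi * EARTH_RADIUS_KM / 180.0


def great_circle_km(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    lat1, lon1 = float(p1[0]), float(p1[1])
    lat2, lon2 = float(p2[0]), float(p2[1])
    for lat in (lat1, lat2):
        if abs(lat) > 90:
            raise ValueError(f"invalid latitude {lat}")
    return float(_haversine(np.radians([lat1]), np.radians([lon1]),
                            np.radians(lat2), np.radians(lon2))[0])


def _haversine(lat1, lon1, lat2, lon2):
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class FrequencySurface:
    """Interpolated frequency raster: NaN marks grid cells with no
    observation inside the search radius."""

    lats: np.ndarray   # (ny,)
    lons: np.ndarray   # (nx,)
    values: np.ndarray  # (ny, nx), percent or NaN
    radius_km: float
    power: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(float(lon), float(lat), float(self.values[i, j]))
                for i, lat in enumerate(self.lats)
                for j, lon in enumerate(self.lons)]
        return pd.DataFrame(rows, columns=["lon", "lat", "value"])

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")


def interpolate_surface(obs: Sequence[tuple[float, float, float]],
                        *, lat_range: tuple[float, float],
                        lon_range: tuple[float, float],
                        spacing_deg: float = 0.5,
                        radius_km: float = 400.0,
                        power: float = 2.0) -> FrequencySurface:
    """Interpolate (lat, lon, frequency%) observations onto a lat/lon grid.

    ``value(g) = sum w_i f_i / sum w_i`` over observations within
    ``radius_km`` of g, ``w_i = 1 / max(d_i, d_floor)^power`` with the
    distance floor at half the grid spacing (in km).  Being a weighted
    average, every value lies within the range of its contributing
    observations.
    """
    if len(obs) == 0:
        raise ValueError("need at least one observation")
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    if power < 0:
        raise ValueError("power must be non-negative")
    pts = np.asarray(obs, dtype=float)
    if np.any(np.abs(pts[:, 0]) > 90):
        raise ValueError("invalid latitude in observations")

    lats = np.arange(lat_range[0], lat_range[1] + spacing_deg / 2, spacing_deg)
    lons = np.arange(lon_range[0], lon_range[1] + spacing_deg / 2, spacing_deg)
    glat, glon = np.meshgrid(np.radians(lats), np.radians(lons), indexing="ij")

    d_floor = 0.5 * spacing_deg * KM_PER_DEGREE
    values = np.full(glat.shape, np.nan)
    wsum = np.zeros(glat.shape)
    fsum = np.zeros(glat.shape)
    for lat, lon, f in pts:
        d = _haversine(glat, glon, np.radians(lat), np.radians(lon))
        inside = d <= radius_km
        wgt = 1.0 / np.maximum(d, d_floor) ** power
        wsum[inside] += wgt[inside]
        fsum[inside] += wgt[inside] * f
    covered = wsum > 0
    values[covered] = fsum[covered] / wsum[covered]
    return FrequencySurface(lats=lats, lons=lons, values=values,
                            radius_km=radius_km, power=power)
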