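"""Pairwise geographic distance matrices from longitude/latitude."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

METRICS = ("great_circle_km", "euclidean_degrees")


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must have shape (n, 2) as (longitude, latitude)")
    lon, lat = coords[:, 0], coords[:, 1]
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise ValueError("coordinates out of range (|lon|<=180, |lat|<=90)")
    return coords


def great_circle_km(coords: np.ndarray) -> np.ndarray:
    """Haversine great-circle distance matrix in km (Earth radius 6371 km)."""
    coords = _check_coords(coords)
    lon = np.radians(coords[:, 0])[:, None]
    lat = np.radians(coords[:, 1])[:, None]
    dlon = lon - lon.T
    dlat = lat - lat.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return d


def euclidean_degrees(coords: np.ndarray) -> np.ndarray:
    """Plain Euclidean distance on raw (longitude, latitude) degrees."""
    coords = _check_coords(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return d


def geo_distance_matrix(coords: np.ndarray, metric: str = "great_circle_km") -> np.ndarray:
    """Symmetric, zero-diagonal pairwise distance matrix.

    Parameters
    ----------
    coords : array of shape (n, 2)
        Columns are (longitude, latitude) in decimal degrees.
    metric : {"great_circle_km", "euclidean_degrees"}
    """
    if metric == "great_circle_km":
        return great_circle_km(coords)
    if metric == "euclidean_degrees":
        return euclidean_degrees(coords)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
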