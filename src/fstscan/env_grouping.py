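"""Assign samples to thermal-environment groups from flock/station geography.

Each flock is matched to its nearest weather station by great-circle
distance; flocks farther than ``max_distance_km`` (default 50 km) from every
station stay unassigned.  A matched flock is labelled ``HE`` ("hot
environment") when the station's 20-year mean maximum temperature is strictly
above ``breaking_temp`` (default 21 degC) and ``CE`` ("cold environment")
otherwise.  All samples of a flock share its label; unassigned samples are
dropped from downstream differentiation analysis, and the exclusion is
logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

GROUP_COLD = "CE"
GROUP_HOT = "HE"
GROUP_UNASSIGNED = "UNASSIGNED"


def haversine_km(lat1, lon1, lat2, lon2) -> float | np.ndarray:
    """Great-circle distance in km on a 6,371 km sphere.

    Accepts scalars or broadcastable arrays of decimal degrees; symmetric,
    non-negative and zero only for identical points.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180):
            raise ValueError("longitude outside [-180, 180]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if d.ndim == 0 else d


def assign_groups(
    samples: pd.DataFrame,
    flocks: pd.DataFrame,
    stations: pd.DataFrame,
    breaking_temp: float = 21.0,
    max_distance_km: float = 50.0,
) -> pd.DataFrame:
    """Label every sample CE / HE / UNASSIGNED via its flock's nearest station.

    Parameters
    ----------
    samples:
        DataFrame with ``sample_id`` and ``flock_id``.
    flocks:
        DataFrame with ``flock_id``, ``lat``, ``lon``.
    stations:
        DataFrame with ``station_id``, ``lat``, ``lon``, ``mean_tmax_c``.

    Returns a DataFrame with columns ``sample_id, flock_id, station_id,
    distance_km, group``; ``station_id`` is empty for unassigned samples.
    Distance ties between stations break by lexicographic ``station_id``.
    """
    if len(stations) == 0:
        raise ValueError("station table is empty")
    missing = set(samples["flock_id"].astype(str)) - set(flocks["flock_id"].astype(str))
    if missing:
        raise ValueError(f"flocks referenced by samples but absent from flock table: {sorted(missing)}")

    stations = stations.sort_values("station_id", kind="stable").reset_index(drop=True)
    st_lat = stations["lat"].to_numpy(float)
    st_lon = stations["lon"].to_numpy(float)

    flock_rows = []
    for rec in flocks.itertuples(index=False):
        dists = haversine_km(rec.lat, rec.lon, st_lat, st_lon)
        j = int(np.argmin(dists))  # stations sorted by id -> ties pick lexicographic min
        dist = float(dists[j])
        if dist > max_distance_km:
            flock_rows.append((str(rec.flock_id), "", dist, GROUP_UNASSIGNED))
        else:
            tmax = float(stations["mean_tmax_c"].iloc[j])
            group = GROUP_HOT if tmax > breaking_temp else GROUP_COLD
            flock_rows.append((str(rec.flock_id), stations["station_id"].iloc[j], dist, group))
    flock_assign = pd.DataFrame(
        flock_rows, columns=["flock_id", "station_id", "distance_km", "group"]
    )

    out = samples[["sample_id", "flock_id"]].copy()
    out["flock_id"] = out["flock_id"].astype(str)
    out = out.merge(flock_assign, on="flock_id", how="left", validate="many_to_one")
    n_un = int((out["group"] == GROUP_UNASSIGNED).sum())
    if n_un:
        logger.info(
            "%d samples in flocks farther than %.0f km from every station are UNASSIGNED "
            "and excluded from differentiation analysis",
            n_un,
            max_distance_km,
        )
    return out
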