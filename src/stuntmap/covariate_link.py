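"""Raster covariate extraction at cluster locations and survey linkage.

DHS publishes displaced cluster coordinates; to compensate, covariates
are extracted as the mean of raster cells whose centers fall within a
great-circle circular buffer around the displaced point — 2 km radius
for urban clusters, 10 km for rural — and then joined to the child table
by cluster id.  Continuous extractions are banded into the categorical
schemes used in the regression models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geoutils import haversine_km
from .raster import Raster

log = logging.getLogger(__name__)

BUFFER_KM_URBAN = 2.0
BUFFER_KM_RURAL = 10.0


def extract_buffer_mean(raster: Raster, lon: float, lat: float, urban: bool, radius_km: float | None = None) -> float:
    """Mean of raster cells whose centers lie within the circular buffer.

    The buffer is great-circle (haversine) with radius 2 km (urban) or
    10 km (rural).  Nodata cells are excluded.  Returns NaN (and logs)
    if no valid cell center falls inside the buffer and the containing
    cell is also invalid; a buffer smaller than one cell degrades to the
    containing cell's value.
    """
    r_km = radius_km if radius_km is not None else (BUFFER_KM_URBAN if urban else BUFFER_KM_RURAL)
    # candidate window: buffer radius in degrees, padded by one cell
    deg_lat = r_km / 111.19
    deg_lon = r_km / (111.19 * max(math.cos(math.radians(lat)), 0.01))
    lon0, lat0, lon1, lat1 = raster.bounds
    lons, lats = raster.cell_centers()
    ci = np.where((lons >= lon - deg_lon - raster.cellsize) & (lons <= lon + deg_lon + raster.cellsize))[0]
    ri = np.where((lats >= lat - deg_lat - raster.cellsize) & (lats <= lat + deg_lat + raster.cellsize))[0]
    if len(ci) == 0 or len(ri) == 0:
        log.warning("buffer at (%.4f, %.4f) outside raster extent", lon, lat)
        return float("nan")
    LO, LA = np.meshgrid(lons[ci], lats[ri])
    dist = haversine_km(lon, lat, LO, LA)
    vals = raster.data[np.ix_(ri, ci)]
    inside = (dist <= r_km) & (vals != raster.nodata)
    if not inside.any():
        # degenerate buffer: fall back to the containing cell
        v = raster.value_at(lon, lat)
        if np.isnan(v):
            log.warning("buffer at (%.4f, %.4f) entirely nodata", lon, lat)
        return v
    return float(vals[inside].mean())


def link_geocovariates(clusters: pd.DataFrame, rasters: list[Raster]) -> pd.DataFrame:
    """One covariate column per raster, extracted per cluster.

    `clusters` must carry unique `cluster_id`, displaced `lon`/`lat`
    and a boolean `urban` flag.  Clusters falling outside a raster keep
    a missing value with a warning; duplicate ids are a hard error.
    """
    if clusters["cluster_id"].duplicated().any():
        dup = clusters.loc[clusters["cluster_id"].duplicated(), "cluster_id"].iloc[0]
        raise ValueError(f"duplicate cluster id {dup!r}")
    out = clusters.copy()
    for rast in rasters:
        if not rast.name:
            raise ValueError("raster must carry a name to become a column")
        vals = [
            extract_buffer_mean(rast, row.lon, row.lat, bool(row.urban))
            for row in out.itertuples()
        ]
        out[rast.name] = vals
        n_miss = int(np.isnan(vals).sum())
        if n_miss:
            log.warning("%d clusters missing %s", n_miss, rast.name)
    return out


@dataclass(frozen=True)
class Band:
    label: str
    low: float  # inclusive
    high: float  # exclusive (np.inf for the top band)


#: Categorization schemes for the climatic covariates.  Band edges are
#: half-open [low, high); the upper DLST edge of the middle band is 35.0
#: so the scale has no gap (the printed band labels "30-34.9" / "+35.0"
#: leave [34.9, 35) formally unassigned; it is folded into the middle
#: band here).  Rainfall uses [142, 1200).  Aridity uses 17.5 and 32.5.
CLIMATE_SCHEMES: dict[str, list[Band]] = {
    "dlst": [Band("lt_30C", -np.inf, 30.0), Band("30-34.9C", 30.0, 35.0), Band("ge_35C", 35.0, np.inf)],
    "rainfall": [Band("low", 0.0, 142.0), Band("medium", 142.0, 1200.0), Band("high", 1200.0, np.inf)],
    "aridity": [Band("wet", 32.5, np.inf), Band("semi_arid", 17.5, 32.5), Band("arid", 0.0, 17.5)],
    "urbanization": [
        Band("rural_villages", -np.inf, 1.5),
        Band("urban_clusters", 1.5, 2.5),
        Band("urban_centres", 2.5, np.inf),
    ],
}

#: Declared domains; values outside them are a validation error.
_DOMAINS = {"dlst": (-np.inf, np.inf), "rainfall": (0.0, np.inf), "aridity": (0.0, 300.0), "urbanization": (0.5, 3.5)}


def categorize_climate(values, scheme: str):
    """Band continuous extractions into the model's categorical levels.

    ``scheme`` is one of dlst / rainfall / aridity / urbanization.
    Aridity bands are wet (>32.5), semi-arid [17.5, 32.5], arid (<17.5);
    note 32.5 falls in the semi-arid band (closed upper end), matching
    the inclusive "17.5 up to 32.5" definition.
    """
    if scheme not in CLIMATE_SCHEMES:
        raise ValueError(f"unknown categorization scheme {scheme!r}")
    vals = np.asarray(values, dtype=float)
    scalar = vals.ndim == 0
    vals = np.atleast_1d(vals)
    lo, hi = _DOMAINS[scheme]
    finite = np.isfinite(vals)
    if np.any((vals[finite] < lo) | (vals[finite] > hi)):
        bad = vals[finite][(vals[finite] < lo) | (vals[finite] > hi)][0]
        raise ValueError(f"value {bad} outside declared domain of {scheme!r}")
    out = np.array([None] * len(vals), dtype=object)
    for band in CLIMATE_SCHEMES[scheme]:
        if scheme == "aridity" and band.label == "semi_arid":
            m = finite & (vals >= band.low) & (vals <= band.high)
        elif scheme == "aridity" and band.label == "wet":
            m = finite & (vals > band.low)
        else:
            m = finite & (vals >= band.low) & (vals < band.high)
        out[m] = band.label
    return out[0] if scalar else out


def categorize_linked_table(linked: pd.DataFrame) -> pd.DataFrame:
    """Apply every applicable categorization scheme; continuous columns
    are kept and categorical ones appended with a `_cat` suffix stripped
    to the schema covariate name."""
    out = linked.copy()
    for scheme in CLIMATE_SCHEMES:
        raw = f"{scheme}_raw"
        if raw not in out.columns and scheme in out.columns and out[scheme].dtype.kind in "fc":
            out[raw] = out.pop(scheme)
        if raw in out.columns:
            out[scheme] = categorize_climate(out[raw].to_numpy(), scheme)
    return out


def join_children(children: pd.DataFrame, linked_clusters: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Attach cluster-level covariates to the child table by cluster id only."""
    cols = ["cluster_id"] + columns
    return children.merge(linked_clusters[cols], on="cluster_id", how="left", validate="many_to_one")
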