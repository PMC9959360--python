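"""Gridded prevalence prediction and administrative aggregation.

For each retained posterior draw d and grid pixel g the prevalence is
p_dg = invlogit(x_g' beta_d + (A_grid S_d)_g), where x_g holds the
raster-derived covariates at the pixel (child-level survey covariates
sit at their reference levels for surface prediction) and A_grid
projects the sampled mesh field to pixel centers.  Pixel, admin-unit and
national summaries are all computed at draw level, so credible intervals
are coherent under aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.special import expit

from .covariate_link import CLIMATE_SCHEMES, categorize_climate
from .geoutils import AdminMap
from .inference import PosteriorSamples
from .mesh_spde import Mesh, projector
from .raster import Raster

log = logging.getLogger(__name__)


@dataclass
class GridSpec:
    cellsize: float = 0.05
    max_draws: int = 200


@dataclass
class PrevalenceSurface:
    """Posterior prevalence surface on a regular grid.

    mean/low/high are rasters (2.5/97.5 percentile bounds); p_draws keeps
    the (draw, valid-pixel) matrix for coherent aggregation.
    """

    mean: Raster
    low: Raster
    high: Raster
    p_draws: np.ndarray
    valid_idx: np.ndarray  # flat indices of valid pixels into the grid

    @property
    def grid(self) -> Raster:
        return self.mean


def _grid_design(
    lons: np.ndarray, lats: np.ndarray, rasters: dict[str, Raster], beta_names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix over pixels for the raster-available covariates.

    Returns (X, valid_mask); pixels where any required raster is nodata
    are masked out.
    """
    npix = len(lons)
    valid = np.ones(npix, dtype=bool)
    cats: dict[str, np.ndarray] = {}
    for scheme in CLIMATE_SCHEMES:
        if scheme in rasters:
            vals = rasters[scheme].value_at(lons, lats)
            ok = np.isfinite(vals)
            valid &= ok
            labels = np.array([None] * npix, dtype=object)
            labels[ok] = categorize_climate(vals[ok], scheme)
            cats[scheme] = labels
    X = np.zeros((npix, len(beta_names)))
    for j, name in enumerate(beta_names):
        if name == "intercept":
            X[:, j] = 1.0
        elif "[" in name:
            term, level = name[:-1].split("[", 1)
            if term in cats:
                X[:, j] = (cats[term] == level).astype(float)
            # survey-only covariates stay at reference (0)
    return X, valid


def predict_grid(
    samples: PosteriorSamples,
    rasters: dict[str, Raster],
    mesh: Mesh,
    admin_map: AdminMap,
    grid_spec: GridSpec | None = None,
) -> PrevalenceSurface:
    """Posterior prevalence surface over the admin-map domain.

    Pixels outside the country polygon or missing a required raster
    covariate are nodata.
    """
    gs = grid_spec or GridSpec()
    x0, y0, x1, y1 = admin_map.bbox
    cs = gs.cellsize
    ncols = max(1, int(round((x1 - x0) / cs)))
    nrows = max(1, int(round((y1 - y0) / cs)))
    lon_c = x0 + (np.arange(ncols) + 0.5) * cs
    lat_c = y1 - (np.arange(nrows) + 0.5) * cs
    LO, LA = np.meshgrid(lon_c, lat_c)
    lons, lats = LO.ravel(), LA.ravel()

    inside = shapely.contains_xy(admin_map.domain, lons, lats)
    X, valid = _grid_design(lons, lats, rasters, samples.beta_names)
    n_masked = int(inside.sum() - (inside & valid).sum())
    if n_masked:
        log.info("%d pixels masked for missing covariates", n_masked)
    valid &= inside
    vidx = np.where(valid)[0]

    ndraw = samples.n_draws
    take = np.linspace(0, ndraw - 1, min(gs.max_draws, ndraw)).astype(int)
    beta = samples.beta[take]
    eta = beta @ X[vidx].T
    if samples.field is not None:
        A = projector(mesh, np.column_stack([lons[vidx], lats[vidx]]))
        eta = eta + (A @ samples.field[take].T).T
    p = expit(eta)

    def to_raster(vals_1d, name):
        data = np.full(nrows * ncols, -9999.0)
        data[vidx] = vals_1d
        return Raster(
            data=data.reshape(nrows, ncols),
            lon_min=x0,
            lat_min=y0,
            cellsize=cs,
            nodata=-9999.0,
            name=name,
            units="proportion",
        )

    lo, hi = np.percentile(p, [2.5, 97.5], axis=0)
    return PrevalenceSurface(
        mean=to_raster(p.mean(axis=0), "prevalence_mean"),
        low=to_raster(lo, "prevalence_low"),
        high=to_raster(hi, "prevalence_high"),
        p_draws=p,
        valid_idx=vidx,
    )


def aggregate_admin(
    surface: PrevalenceSurface,
    admin_map: AdminMap,
    level: int,
    pop_raster: Raster | None = None,
) -> pd.DataFrame:
    """Per-unit prevalence (percent) with 95% CrI, draw-level aggregation.

    Unit prevalence per draw is the (population-weighted, else equal)
    mean of pixel prevalences inside the unit; mean and percentiles are
    then taken over draws.  Units containing no valid pixel are flagged
    with missing estimates.
    """
    grid = surface.grid
    lons_c, lats_c = grid.cell_centers()
    LO, LA = np.meshgrid(lons_c, lats_c)
    lons = LO.ravel()[surface.valid_idx]
    lats = LA.ravel()[surface.valid_idx]
    if pop_raster is not None:
        w_all = pop_raster.value_at(lons, lats)
        w_all = np.where(np.isfinite(w_all) & (w_all > 0), w_all, 0.0)
    else:
        w_all = np.ones(len(lons))
    rows = []
    for unit in admin_map.units(level):
        in_unit = shapely.contains_xy(unit.geometry, lons, lats)
        w = w_all[in_unit]
        if not in_unit.any() or w.sum() == 0:
            log.warning("admin unit %s contains no valid pixel", unit.unit_id)
            rows.append(
                {
                    "level": level,
                    "unit_id": unit.unit_id,
                    "name": unit.name,
                    "prevalence_pct": float("nan"),
                    "cri_low_pct": float("nan"),
                    "cri_high_pct": float("nan"),
                    "n_pixels": 0,
                }
            )
            continue
        unit_draws = surface.p_draws[:, in_unit] @ (w / w.sum())
        lo, hi = np.percentile(unit_draws, [2.5, 97.5])
        rows.append(
            {
                "level": level,
                "unit_id": unit.unit_id,
                "name": unit.name,
                "prevalence_pct": 100.0 * float(unit_draws.mean()),
                "cri_low_pct": 100.0 * float(lo),
                "cri_high_pct": 100.0 * float(hi),
                "n_pixels": int(in_unit.sum()),
            }
        )
    return pd.DataFrame(rows)


def national_summary(
    surface: PrevalenceSurface, admin_map: AdminMap, pop_raster: Raster | None = None
) -> dict:
    """Country-level prevalence (percent) with 95% CrI, same draw-level
    aggregation over all valid pixels."""
    grid = surface.grid
    lons_c, lats_c = grid.cell_centers()
    LO, LA = np.meshgrid(lons_c, lats_c)
    lons = LO.ravel()[surface.valid_idx]
    lats = LA.ravel()[surface.valid_idx]
    if pop_raster is not None:
        w = pop_raster.value_at(lons, lats)
        w = np.where(np.isfinite(w) & (w > 0), w, 0.0)
    else:
        w = np.ones(len(lons))
    draws = surface.p_draws @ (w / w.sum())
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {
        "level": 0,
        "unit_id": "national",
        "prevalence_pct": 100.0 * float(draws.mean()),
        "cri_low_pct": 100.0 * float(lo),
        "cri_high_pct": 100.0 * float(hi),
        "n_pixels": int(len(lons)),
    }


def render_maps(estimates: pd.DataFrame, admin_map: AdminMap, out_path, title: str = "") -> None:
    """Choropleth of admin-unit prevalence; missing units hatched grey."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Polygon as MplPolygon

    level = int(estimates["level"].iloc[0])
    lookup = estimates.set_index("unit_id")["prevalence_pct"]
    vals, patches, missing = [], [], []
    for unit in admin_map.units(level):
        geoms = getattr(unit.geometry, "geoms", [unit.geometry])
        v = lookup.get(unit.unit_id, float("nan"))
        for g in geoms:
            patch = MplPolygon(np.asarray(g.exterior.coords))
            if np.isfinite(v):
                patches.append(patch)
                vals.append(v)
            else:
                missing.append(patch)
    fig, ax = plt.subplots(figsize=(7, 6))
    coll = PatchCollection(patches, edgecolor="white", linewidth=0.3, cmap="viridis")
    coll.set_array(np.asarray(vals))
    ax.add_collection(coll)
    if missing:
        miss = PatchCollection(missing, facecolor="lightgrey", hatch="//", edgecolor="grey")
        ax.add_collection(miss)
    fig.colorbar(coll, ax=ax, label="stunting prevalence (%)")
    x0, y0, x1, y1 = admin_map.bbox
    ax.set_xlim(x0, x1)
    ax.set_ylim(y0, y1)
    ax.set_aspect("equal")
    ax.set_title(title or f"Stunting prevalence, admin level {level}")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
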