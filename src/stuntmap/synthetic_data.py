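"""DHS-like synthetic survey generator.

Emulates the design of the 2018 Nigeria DHS stunting sample so the whole
geostatistical pipeline is testable without restricted microdata:

* a two-level administrative map (Voronoi partition of the domain box;
  Nigeria-like defaults: 37 level-1 units, ~21 level-2 units each);
* two-stage stratified cluster sampling — clusters allocated to
  admin-1 x urban/rural strata proportionally to simulated stratum size,
  ~30 households per cluster with the analysed child count per cluster
  Poisson-distributed (mean 12627/1377 ~ 9.2 by default);
* geo-masking displacement of cluster coordinates (uniform bearing,
  distance uniform on [0, 2 km] urban / [0, 10 km] rural, redrawn until
  inside the country polygon);
* a latent Matérn (nu = 1) cluster-level risk field simulated from the
  SPDE precision on a simulation mesh (default truth kappa = 7.33 per
  degree, marginal variance 0.24);
* child covariates drawn from marginals and climatic covariates read
  back off smooth synthetic rasters, with true log-odds effects from the
  default effect structure in :mod:`stuntmap.schema`;
* stunting ~ Bernoulli(invlogit(intercept + x'beta + S(cluster))), with
  a height-for-age z-score back-filled consistently (stunted iff
  HAZ < -2).

Same seed => byte-identical output tables.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import shapely
from scipy.special import expit
from scipy.stats import truncnorm

from . import schema
from .covariate_link import categorize_linked_table, link_geocovariates
from .geoutils import AdminMap, AdminUnit, destination_point, haversine_km, voronoi_partition
from .mesh_spde import Mesh, SPDEParams, build_mesh, projector, sample_field, spde_precision
from .raster import Raster

#: Default true spatial hyperparameters: kappa per degree and marginal
#: variance of the latent risk field.
DEFAULT_KAPPA = 7.33
DEFAULT_FIELD_VARIANCE = 0.24
#: Intercept calibrated so the simulated national crude prevalence sits
#: near the 2018 Nigerian design-based figure (~37%).
DEFAULT_INTERCEPT = -0.47


def _default_betas() -> dict[str, dict[str, float]]:
    return {name: dict(cov["beta"]) for name, cov in schema.ALL_COVARIATES.items()}


@dataclass
class SimulationConfig:
    """Study-design knobs for one synthetic survey.

    Defaults reproduce the scale of the real survey: 1377 clusters,
    ~9.2 analysed children per cluster (N ~ 12,627), 37 x ~21 admin
    units over a Nigeria-sized lon/lat box.
    """

    seed: int = 0
    n_admin1: int = 37
    n_admin2_per_admin1: int = 21
    n_clusters: int = 1377
    urban_fraction: float = 0.41
    households_per_cluster: int = 30
    children_per_cluster_mean: float = 12627 / 1377
    poisson_children: bool = True
    field_kappa: float = DEFAULT_KAPPA
    field_tau: float = dc_field(default=0.0)  # 0 -> derived from variance below
    field_variance: float = DEFAULT_FIELD_VARIANCE
    betas: dict = dc_field(default_factory=_default_betas)
    intercept: float = DEFAULT_INTERCEPT
    domain_bbox: tuple = (3.0, 4.0, 14.0, 14.0)
    displacement_km_urban: float = 2.0
    displacement_km_rural: float = 10.0
    raster_cellsize: float = 0.05
    sim_mesh_edge: float = 0.0  # 0 -> range/3
    n_cities: int = 0  # 0 -> max(3, n_admin1)
    city_radius: float = 0.0  # degrees; 0 -> 3% of the longer bbox side
    covariates: tuple = tuple(schema.ALL_COVARIATES)

    def __post_init__(self):
        if min(self.n_admin1, self.n_admin2_per_admin1, self.n_clusters, self.households_per_cluster) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ValueError("urban_fraction must be in [0, 1]")
        if self.field_kappa <= 0:
            raise ValueError("field_kappa must be positive")
        if self.field_tau == 0.0:
            self.field_tau = SPDEParams.from_range_variance(
                math.sqrt(8.0) / self.field_kappa, self.field_variance
            ).tau
        if self.field_tau <= 0:
            raise ValueError("field_tau must be positive")
        x0, y0, x1, y1 = self.domain_bbox
        if not (x1 > x0 and y1 > y0):
            raise ValueError("domain_bbox has zero area")

    @property
    def spde_params(self) -> SPDEParams:
        return SPDEParams(kappa=self.field_kappa, tau=self.field_tau)

    def city_layout(self, rng: np.random.Generator) -> tuple[np.ndarray, float]:
        """(city centers, core radius in degrees) for urban settlement
        structure, shared by cluster placement and the urbanization raster."""
        x0, y0, x1, y1 = self.domain_bbox
        n = self.n_cities if self.n_cities > 0 else max(3, self.n_admin1)
        r = self.city_radius if self.city_radius > 0 else 0.03 * max(x1 - x0, y1 - y0)
        pad = min(r, 0.1 * min(x1 - x0, y1 - y0))
        centers = rng.uniform([x0 + pad, y0 + pad], [x1 - pad, y1 - pad], size=(n, 2))
        return centers, r

    def unknown_beta_levels(self) -> list[str]:
        bad = []
        for name, levels in self.betas.items():
            if name not in schema.ALL_COVARIATES:
                bad.append(name)
                continue
            for lvl in levels:
                if lvl not in schema.ALL_COVARIATES[name]["levels"]:
                    bad.append(f"{name}:{lvl}")
        return bad


def generate_admin_map(config: SimulationConfig, rng: np.random.Generator | None = None) -> AdminMap:
    """Voronoi two-level partition of the domain box.

    Level-1 cells tile the bbox; each is subdivided into level-2 cells by
    a Voronoi partition of seeds inside it.  Polygons are valid,
    non-overlapping and cover the bbox exactly (up to GEOS tolerance).
    """
    rng = rng or np.random.default_rng(config.seed)
    x0, y0, x1, y1 = config.domain_bbox
    domain = shapely.box(x0, y0, x1, y1)
    if domain.area <= 0:
        raise ValueError("degenerate domain bbox")
    amap = AdminMap(bbox=tuple(config.domain_bbox))
    if config.n_admin1 == 1:
        cells1 = [domain]
    else:
        seeds1 = rng.uniform([x0, y0], [x1, y1], size=(config.n_admin1, 2))
        cells1 = voronoi_partition(seeds1, domain)
    for i, cell in enumerate(cells1):
        uid1 = f"A{i + 1:02d}"
        amap.admin1.append(AdminUnit(unit_id=uid1, level=1, geometry=cell, name=f"State {i + 1}"))
        n2 = config.n_admin2_per_admin1
        if n2 == 1:
            cells2 = [cell]
        else:
            sub_seeds = _points_in_polygon(cell, n2, rng)
            cells2 = voronoi_partition(sub_seeds, cell)
        for j, sub in enumerate(cells2):
            amap.admin2.append(
                AdminUnit(
                    unit_id=f"{uid1}-L{j + 1:02d}",
                    level=2,
                    geometry=sub,
                    parent_id=uid1,
                    name=f"LGA {i + 1}.{j + 1}",
                )
            )
    return amap


def _points_in_polygon(poly, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by bbox rejection."""
    x0, y0, x1, y1 = poly.bounds
    out = []
    while len(out) < n:
        cand = rng.uniform([x0, y0], [x1, y1], size=(max(4 * n, 16), 2))
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        out.extend(cand[keep].tolist())
    return np.array(out[:n])


def sample_clusters(
    admin_map: AdminMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    cities: tuple[np.ndarray, float] | None = None,
) -> pd.DataFrame:
    """Allocate clusters to admin-1 x urban/rural strata and place them.

    Stratum sizes are simulated as admin-1 area shares split by the urban
    fraction; allocation is proportional with largest remainders.  Cluster
    coordinates are uniform within the admin-1 polygon (urban clusters are
    drawn near the shared city centers when a layout is given); each cluster gets
    its analysed child count (Poisson around the configured mean, min 1)
    and a design weight = stratum population share / stratum sample share.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n_strata_units = len(admin_map.admin1)
    sides = []
    if config.urban_fraction > 0:
        sides.append(("urban", config.urban_fraction))
    if config.urban_fraction < 1:
        sides.append(("rural", 1.0 - config.urban_fraction))
    if not sides:
        raise ValueError("no strata requested")
    areas = np.array([u.geometry.area for u in admin_map.admin1])
    shares = []
    labels = []
    for u, area_share in zip(admin_map.admin1, areas / areas.sum()):
        for side, frac in sides:
            labels.append((u.unit_id, side))
            shares.append(area_share * frac)
    shares = np.asarray(shares)
    if config.n_clusters < len(labels):
        raise ValueError(
            f"n_clusters={config.n_clusters} is below the number of strata {len(labels)}"
        )
    alloc = _proportional_allocation(shares, config.n_clusters)

    a1_geoms = {u.unit_id: u.geometry for u in admin_map.admin1}
    a2_by_parent: dict[str, list[AdminUnit]] = {}
    for u in admin_map.admin2:
        a2_by_parent.setdefault(u.parent_id, []).append(u)

    rows = []
    cid = 0
    for (a1_id, side), n_h, share in zip(labels, alloc, shares):
        if n_h == 0:
            continue
        if side == "urban" and cities is not None:
            pts = _points_near_cities(a1_geoms[a1_id], n_h, cities, rng)
        else:
            pts = _points_in_polygon(a1_geoms[a1_id], n_h, rng)
        # design weight: population share over sample share (PPS proxy)
        weight = (share / (n_h / config.n_clusters))
        for lon, lat in pts:
            cid += 1
            a2_id = next(
                (u.unit_id for u in a2_by_parent.get(a1_id, []) if u.geometry.covers(shapely.Point(lon, lat))),
                a2_by_parent.get(a1_id, [AdminUnit(a1_id, 2, a1_geoms[a1_id])])[0].unit_id,
            )
            if config.poisson_children:
                n_child = max(1, int(rng.poisson(config.children_per_cluster_mean)))
            else:
                n_child = int(round(config.children_per_cluster_mean))
            rows.append(
                {
                    "cluster_id": f"C{cid:05d}",
                    "admin1_id": a1_id,
                    "admin2_id": a2_id,
                    "stratum_id": f"{a1_id}_{side}",
                    "urban": side == "urban",
                    "true_lon": lon,
                    "true_lat": lat,
                    "n_children": n_child,
                    "weight": weight,
                }
            )
    return pd.DataFrame(rows)


def _points_near_cities(poly, n: int, cities: tuple[np.ndarray, float], rng: np.random.Generator) -> np.ndarray:
    """Urban cluster placement: uniform in city core discs clipped to the
    admin polygon; falls back to uniform-in-polygon where no city core
    intersects the unit."""
    centers, radius = cities
    out: list[list[float]] = []
    tries = 0
    while len(out) < n and tries < 400 * n:
        tries += 1
        c = centers[rng.integers(len(centers))]
        ang = rng.uniform(0, 2 * np.pi)
        # spill slightly past the core so town/suburb (middle class) EAs occur
        rad = 1.2 * radius * np.sqrt(rng.uniform())
        p = (c[0] + rad * np.cos(ang), c[1] + rad * np.sin(ang))
        if shapely.contains_xy(poly, p[0], p[1]):
            out.append([p[0], p[1]])
    if len(out) < n:
        out.extend(_points_in_polygon(poly, n - len(out), rng).tolist())
    return np.array(out)


def _proportional_allocation(shares: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation with at least 1 per stratum."""
    raw = shares / shares.sum() * (total - len(shares)) + 1.0
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def displace_coordinates(
    clusters: pd.DataFrame,
    config: SimulationConfig,
    country_polygon,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """DHS geo-masking: uniform bearing, distance uniform on [0, cap],
    cap 2 km urban / 10 km rural; redraw until inside the country polygon.
    True coordinates are retained (for validation only)."""
    rng = rng or np.random.default_rng(config.seed + 2)
    out = clusters.copy()
    lon = out["true_lon"].to_numpy(float).copy()
    lat = out["true_lat"].to_numpy(float).copy()
    caps = np.where(out["urban"].to_numpy(bool), config.displacement_km_urban, config.displacement_km_rural)
    new_lon, new_lat = lon.copy(), lat.copy()
    todo = caps > 0
    for _ in range(200):
        if not todo.any():
            break
        n = int(todo.sum())
        bearing = rng.uniform(0.0, 2.0 * np.pi, n)
        dist = rng.uniform(0.0, caps[todo])
        dl, dp = destination_point(lon[todo], lat[todo], bearing, dist)
        inside = shapely.contains_xy(country_polygon, dl, dp)
        idx = np.where(todo)[0]
        ok = idx[inside]
        new_lon[ok], new_lat[ok] = dl[inside], dp[inside]
        todo[ok] = False
    if todo.any():
        # pathological site hugging a concave border: fall back to truth
        new_lon[todo], new_lat[todo] = lon[todo], lat[todo]
    out["lon"], out["lat"] = new_lon, new_lat
    out["displacement_km"] = haversine_km(lon, lat, new_lon, new_lat)
    return out


def simulate_spatial_field(mesh: Mesh, params: SPDEParams, seed: int | np.random.Generator) -> np.ndarray:
    """One zero-mean Gaussian draw at mesh vertices with the SPDE
    precision Q(kappa, tau); reproducible under the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = spde_precision(mesh, params)
    return sample_field(Q, rng)


def build_simulation_mesh(config: SimulationConfig) -> Mesh:
    """Mesh for simulating the truth field: fills the domain at roughly a
    third of the correlation range, with a coarse extension ring."""
    x0, y0, x1, y1 = config.domain_bbox
    rng_len = math.sqrt(8.0) / config.field_kappa
    edge = config.sim_mesh_edge if config.sim_mesh_edge > 0 else rng_len / 4.0
    corners = np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]])
    # the extension ring must exceed the correlation range, else boundary
    # variance inflation leaks into the domain
    return build_mesh(corners, max_edge=edge, cutoff=0.0, boundary_extension=max(1.5 * rng_len, 2 * edge))


def rasterize_covariates(
    admin_map: AdminMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    cities: tuple[np.ndarray, float] | None = None,
) -> dict[str, Raster]:
    """Smooth synthetic climate rasters spanning all category bands.

    Each continuous surface is a planar gradient plus random Gaussian
    bumps, affinely mapped so that the category band edges fall at the
    calibrated cumulative proportions of the covariate's marginal
    distribution.  Urbanization is a 3-class surface built from random
    city centers.  Pixels outside the country polygon are nodata.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    x0, y0, x1, y1 = config.domain_bbox
    cs = config.raster_cellsize
    if cs < max(x1 - x0, y1 - y0) / 10_000.0:
        raise ValueError("raster resolution finer than 1/10000 of the domain — refusing")
    ncols = max(2, int(math.ceil((x1 - x0) / cs)))
    nrows = max(2, int(math.ceil((y1 - y0) / cs)))
    lons = x0 + (np.arange(ncols) + 0.5) * cs
    lats = y1 - (np.arange(nrows) + 0.5) * cs
    LO, LA = np.meshgrid(lons, lats)
    domain = admin_map.domain
    mask = shapely.contains_xy(domain, LO.ravel(), LA.ravel()).reshape(LO.shape)

    def smooth_surface(north_hot: float) -> np.ndarray:
        f = north_hot * (LA - y0) / (y1 - y0)
        for _ in range(6):
            cx, cy = rng.uniform([x0, y0], [x1, y1])
            s = rng.uniform(0.1, 0.35) * max(x1 - x0, y1 - y0)
            f = f + rng.normal(0, 0.35) * np.exp(-((LO - cx) ** 2 + (LA - cy) ** 2) / (2 * s * s))
        return f

    def to_edges(f: np.ndarray, edges: list[float], cum_props: list[float]) -> np.ndarray:
        q = np.quantile(f[mask], cum_props)
        if len(edges) == 1 or abs(q[1] - q[0]) < 1e-12:
            return f - q[0] + edges[0]
        m = (edges[1] - edges[0]) / (q[1] - q[0])
        return edges[0] + m * (f - q[0])

    out: dict[str, Raster] = {}

    def finish(name, vals, units):
        data = np.where(mask, vals, -9999.0)
        out[name] = Raster(data=data, lon_min=x0, lat_min=y0, cellsize=cs, nodata=-9999.0, name=name, units=units)

    p = schema.CLUSTER_COVARIATES
    # DLST: hotter in the north; edges 30 / 35 C at the calibrated shares
    pr = [p["dlst"]["probs"][l] for l in p["dlst"]["levels"]]
    finish("dlst", to_edges(smooth_surface(1.0), [30.0, 35.0], [pr[0], pr[0] + pr[1]]), "degC")
    # rainfall: wetter in the south; edges 142 / 1200 mm
    pr = [p["rainfall"]["probs"][l] for l in p["rainfall"]["levels"]]
    finish("rainfall", np.maximum(to_edges(smooth_surface(-1.0), [142.0, 1200.0], [pr[0], pr[0] + pr[1]]), 0.0), "mm")
    # aridity: 0 (arid) .. 300 (wet), wetter in the south; edges 17.5 / 32.5
    pr = [p["aridity"]["probs"][l] for l in p["aridity"]["levels"]]
    arid = to_edges(smooth_surface(-1.0), [17.5, 32.5], [pr[2], pr[2] + pr[1]])
    finish("aridity", np.clip(arid, 0.0, 300.0), "index")
    # urbanization classes from the city layout
    urb = np.ones_like(LO)
    centers, r_core = cities if cities is not None else config.city_layout(rng)
    for cx, cy in centers:
        d = np.hypot(LO - cx, LA - cy)
        urb = np.maximum(urb, np.where(d < r_core, 3.0, np.where(d < 2.5 * r_core, 2.0, 1.0)))
    finish("urbanization", urb, "class")
    return out


_TRUNC_STUNTED = (-6.0, -2.0, -2.9, 0.8)  # (lo, hi, mu, sd) of HAZ given stunted
_TRUNC_HEALTHY = (-2.0, 6.0, -0.9, 1.1)


def _backfill_haz(stunted: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """HAZ consistent with the stunting indicator (truncated normals)."""
    haz = np.empty(len(stunted))
    for flag, (lo, hi, mu, sd) in ((1, _TRUNC_STUNTED), (0, _TRUNC_HEALTHY)):
        m = stunted == flag
        n = int(m.sum())
        if n:
            a, b = (lo - mu) / sd, (hi - mu) / sd
            haz[m] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    return haz


def simulate_children(
    clusters: pd.DataFrame,
    field_at_cluster: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Child records: covariates from marginals, outcome from the logistic
    risk model, HAZ back-filled consistently with the outcome.

    `clusters` may already carry cluster-level covariate columns (from
    raster linkage); those feed the linear predictor via the configured
    betas, as do the child-level draws.
    """
    bad = config.unknown_beta_levels()
    if bad:
        raise ValueError(f"betas reference unknown covariate levels: {bad}")
    rng = rng or np.random.default_rng(config.seed + 4)
    reps = clusters["n_children"].to_numpy(int)
    base = clusters.loc[clusters.index.repeat(reps)].reset_index(drop=True)
    n = len(base)
    eta = np.full(n, config.intercept, dtype=float)
    eta += np.repeat(np.asarray(field_at_cluster, float), reps)

    data = {
        "child_id": [f"K{i + 1:06d}" for i in range(n)],
        "cluster_id": base["cluster_id"].to_numpy(),
        "stratum_id": base["stratum_id"].to_numpy(),
        "weight": base["weight"].to_numpy(float),
    }
    for name in config.covariates:
        cov = schema.ALL_COVARIATES[name]
        beta = config.betas.get(name, {})
        if cov["cluster_level"]:
            if name not in base.columns:
                continue  # raster covariate not linked in this run
            cats = base[name].to_numpy()
        else:
            levels = cov["levels"]
            probs = np.array([cov["probs"][l] for l in levels])
            cats = np.array(levels, dtype=object)[rng.choice(len(levels), size=n, p=probs)]
        data[name] = cats
        bmap = {lvl: beta.get(lvl, 0.0) for lvl in cov["levels"]}
        eta += np.array([bmap.get(c, 0.0) for c in cats])

    p = expit(eta)
    stunted = rng.binomial(1, p)
    data["stunted"] = stunted
    data["haz"] = _backfill_haz(stunted, rng)
    data["true_p"] = p
    return pd.DataFrame(data)


@dataclass
class SyntheticSurvey:
    """One complete synthetic study: tables, map, rasters, and the truth."""

    config: SimulationConfig
    admin_map: AdminMap
    clusters: pd.DataFrame
    children: pd.DataFrame
    rasters: dict[str, Raster]
    mesh: Mesh
    field: np.ndarray
    field_at_cluster: np.ndarray

    def truth(self) -> dict:
        return {
            "seed": self.config.seed,
            "intercept": self.config.intercept,
            "kappa": self.config.field_kappa,
            "tau": self.config.field_tau,
            "range": self.config.spde_params.range,
            "variance": self.config.spde_params.variance,
            "betas": self.config.betas,
            "n_clusters": int(len(self.clusters)),
            "n_children": int(len(self.children)),
        }

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        os.makedirs(os.path.join(outdir, "covariates"), exist_ok=True)
        self.children.drop(columns=["true_p"]).to_csv(os.path.join(outdir, "children.csv"), index=False)
        self.clusters.to_csv(os.path.join(outdir, "clusters.csv"), index=False)
        self.admin_map.write_geojson(os.path.join(outdir, "admin1.geojson"), level=1)
        self.admin_map.write_geojson(os.path.join(outdir, "admin2.geojson"), level=2)
        for name, rast in self.rasters.items():
            rast.write_ascii(os.path.join(outdir, "covariates", f"{name}.asc"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.truth(), fh, indent=1)


def simulate_survey(config: SimulationConfig, with_rasters: bool = True) -> SyntheticSurvey:
    """End-to-end generation of one synthetic survey under `config`."""
    rng = np.random.default_rng(config.seed)
    admin_map = generate_admin_map(config, rng)
    cities = config.city_layout(rng)
    clusters = sample_clusters(admin_map, config, rng, cities=cities)
    clusters = displace_coordinates(clusters, config, admin_map.domain, rng)

    if with_rasters:
        rasters = rasterize_covariates(admin_map, config, rng, cities=cities)
        linked = link_geocovariates(clusters, list(rasters.values()))
        clusters = categorize_linked_table(linked)
    else:
        rasters = {}

    mesh = build_simulation_mesh(config)
    field = simulate_spatial_field(mesh, config.spde_params, rng)
    A = projector(mesh, clusters[["true_lon", "true_lat"]].to_numpy())
    field_at_cluster = np.asarray(A @ field)

    children = simulate_children(clusters, field_at_cluster, config, rng)
    return SyntheticSurvey(
        config=config,
        admin_map=admin_map,
        clusters=clusters,
        children=children,
        rasters=rasters,
        mesh=mesh,
        field=field,
        field_at_cluster=field_at_cluster,
    )
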