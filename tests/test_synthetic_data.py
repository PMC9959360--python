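"""Synthetic survey generator: admin maps, sampling, displacement, field,
children, rasters, determinism."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from stuntmap.geoutils import haversine_km
from stuntmap.mesh_spde import SPDEParams
from stuntmap.synthetic_data import (
    SimulationConfig,
    build_simulation_mesh,
    displace_coordinates,
    generate_admin_map,
    rasterize_covariates,
    sample_clusters,
    simulate_children,
    simulate_spatial_field,
    simulate_survey,
)


class TestAdminMap:
    def test_single_unit_is_the_bbox(self):
        cfg = small_config(n_admin1=1, n_admin2_per_admin1=1, n_clusters=4)
        amap = generate_admin_map(cfg)
        assert len(amap.admin1) == 1 and len(amap.admin2) == 1
        assert amap.admin1[0].geometry.equals(amap.domain)

    def test_nigeria_scale_structure(self):
        cfg = SimulationConfig(seed=1, n_admin1=37, n_admin2_per_admin1=21, n_clusters=1377)
        amap = generate_admin_map(cfg)
        assert len(amap.admin1) == 37
        assert len(amap.admin2) == 37 * 21

    def test_level2_areas_partition_bbox(self):
        """Shoelace-area oracle: level-2 polygon areas sum to bbox area."""
        cfg = small_config(n_admin1=5, n_admin2_per_admin1=3)
        amap = generate_admin_map(cfg)
        x0, y0, x1, y1 = cfg.domain_bbox
        total = sum(u.geometry.area for u in amap.admin2)
        assert total == pytest.approx((x1 - x0) * (y1 - y0), rel=1e-6)
        assert all(u.geometry.is_valid for u in amap.admin2)

    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, domain_bbox=(10.0, 6.0, 10.0, 8.0))

    def test_geojson_roundtrip(self, survey, tmp_path):
        from stuntmap.geoutils import AdminMap

        survey.admin_map.write_geojson(tmp_path / "a1.geojson", 1)
        survey.admin_map.write_geojson(tmp_path / "a2.geojson", 2)
        back = AdminMap.from_geojson(tmp_path / "a1.geojson", tmp_path / "a2.geojson")
        assert len(back.admin1) == len(survey.admin_map.admin1)
        assert len(back.admin2) == len(survey.admin_map.admin2)


class TestSampleClusters:
    def test_requested_cluster_count(self):
        cfg = small_config(n_clusters=200)
        amap = generate_admin_map(cfg)
        sites = sample_clusters(amap, cfg)
        assert len(sites) == 200
        assert sites["cluster_id"].is_unique

    def test_all_urban_when_fraction_one(self):
        cfg = small_config(urban_fraction=1.0, n_clusters=30)
        amap = generate_admin_map(cfg)
        assert sample_clusters(amap, cfg)["urban"].all()

    def test_deterministic_under_seed(self):
        cfg = small_config(n_clusters=50)
        amap = generate_admin_map(cfg)
        a = sample_clusters(amap, cfg, np.random.default_rng(9))
        b = sample_clusters(amap, cfg, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_clusters_for_strata_rejected(self):
        cfg = small_config(n_clusters=60)
        amap = generate_admin_map(cfg)
        cfg.n_clusters = 5
        with pytest.raises(ValueError):
            sample_clusters(amap, cfg)

    def test_points_fall_in_their_admin1(self):
        cfg = small_config(n_clusters=80)
        amap = generate_admin_map(cfg)
        sites = sample_clusters(amap, cfg)
        import shapely

        geoms = {u.unit_id: u.geometry for u in amap.admin1}
        ok = [
            shapely.contains_xy(geoms[r.admin1_id].buffer(1e-9), r.true_lon, r.true_lat)
            for r in sites.itertuples()
        ]
        assert all(ok)


class TestDisplacement:
    def test_caps_by_stratum_and_nondegenerate(self):
        """Rural displacement <= 10 km, urban <= 2 km, distances spread out."""
        cfg = small_config(n_clusters=10_000, children_per_cluster_mean=1)
        amap = generate_admin_map(cfg)
        sites = sample_clusters(amap, cfg)
        out = displace_coordinates(sites, cfg, amap.domain)
        d = haversine_km(out["true_lon"], out["true_lat"], out["lon"], out["lat"])
        rural = ~out["urban"].to_numpy()
        assert d[rural].max() <= 10.0 + 1e-6
        assert d[~rural].max() <= 2.0 + 1e-6
        assert d[rural].std() > 0.5
        import shapely

        assert shapely.contains_xy(amap.domain, out["lon"], out["lat"]).all()

    def test_zero_cap_keeps_truth(self):
        cfg = small_config(displacement_km_urban=0.0, displacement_km_rural=0.0, n_clusters=20)
        amap = generate_admin_map(cfg)
        sites = sample_clusters(amap, cfg)
        out = displace_coordinates(sites, cfg, amap.domain)
        np.testing.assert_array_equal(out["lon"], out["true_lon"])
        np.testing.assert_array_equal(out["lat"], out["true_lat"])


class TestSpatialField:
    def test_variance_shrinks_with_tau(self):
        cfg = small_config()
        mesh = build_simulation_mesh(cfg)
        huge_tau = SPDEParams(kappa=7.33, tau=1e4)
        f = simulate_spatial_field(mesh, huge_tau, seed=1)
        assert np.abs(f).max() < 1e-2

    def test_mc_variance_matches_closed_form(self):
        """500 replicate draws at interior vertices vs 1/(4 pi k^2 t^2)."""
        from stuntmap.mesh_spde import sample_field, spde_precision

        cfg = small_config()
        mesh = build_simulation_mesh(cfg)
        params = cfg.spde_params
        Q = spde_precision(mesh, params)
        draws = sample_field(Q, np.random.default_rng(0), n_draws=500)
        interior = mesh.interior_mask(margin=params.range)
        emp = draws[:, interior].var(axis=0).mean()
        assert emp == pytest.approx(params.variance, rel=0.10)

    def test_reproducible(self):
        cfg = small_config()
        mesh = build_simulation_mesh(cfg)
        a = simulate_spatial_field(mesh, cfg.spde_params, seed=5)
        b = simulate_spatial_field(mesh, cfg.spde_params, seed=5)
        np.testing.assert_array_equal(a, b)


class TestSimulateChildren:
    def test_null_model_gives_half_prevalence(self):
        cfg = small_config(n_clusters=300, children_per_cluster_mean=20, poisson_children=False)
        cfg.intercept = 0.0
        cfg.betas = {k: {l: 0.0 for l in v} for k, v in cfg.betas.items()}
        amap = generate_admin_map(cfg)
        sites = sample_clusters(amap, cfg)
        kids = simulate_children(sites, np.zeros(len(sites)), cfg)
        n = len(kids)
        assert kids["stunted"].mean() == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(n))

    def test_intercept_recovered_by_plain_logistic(self):
        """With no covariate or field effects the logit intercept is
        recovered within 3 MC standard errors."""
        import statsmodels.api as sm

        cfg = small_config(n_clusters=400, children_per_cluster_mean=25, poisson_children=False)
        cfg.intercept = -0.8
        cfg.betas = {k: {l: 0.0 for l in v} for k, v in cfg.betas.items()}
        amap = generate_admin_map(cfg)
        sites = sample_clusters(amap, cfg)
        kids = simulate_children(sites, np.zeros(len(sites)), cfg)
        fit = sm.GLM(kids["stunted"], np.ones(len(kids)), family=sm.families.Binomial()).fit()
        assert abs(fit.params.iloc[0] - (-0.8)) < 3 * fit.bse.iloc[0]

    def test_haz_consistent_with_outcome(self, survey):
        kids = survey.children
        assert (kids.loc[kids["stunted"] == 1, "haz"] < -2.0).all()
        assert (kids.loc[kids["stunted"] == 0, "haz"] >= -2.0).all()
        assert kids["haz"].between(-6, 6).all()

    def test_unknown_beta_level_is_schema_error(self):
        cfg = small_config()
        cfg.betas["diarrhoea"]["sometimes"] = 0.5
        amap = generate_admin_map(cfg)
        sites = sample_clusters(amap, cfg)
        with pytest.raises(ValueError, match="unknown covariate levels"):
            simulate_children(sites, np.zeros(len(sites)), cfg)

    def test_crude_diarrhoea_or_recovers_truth_over_replicates(self):
        """Average crude OR across replicates approaches the simulated 1.35."""
        import statsmodels.api as sm

        ors = []
        for rep in range(12):
            cfg = small_config(seed=900 + rep, n_clusters=120, children_per_cluster_mean=25, poisson_children=False)
            cfg.betas = {k: {l: 0.0 for l in v} for k, v in cfg.betas.items()}
            cfg.betas["diarrhoea"]["yes"] = np.log(1.35)
            cfg.intercept = -0.6
            amap = generate_admin_map(cfg)
            sites = sample_clusters(amap, cfg)
            kids = simulate_children(sites, np.zeros(len(sites)), cfg)
            x = (kids["diarrhoea"] == "yes").astype(float)
            X = np.column_stack([np.ones(len(kids)), x])
            fit = sm.GLM(kids["stunted"], X, family=sm.families.Binomial()).fit()
            ors.append(np.exp(fit.params.iloc[1]))
        assert np.mean(ors) == pytest.approx(1.35, rel=0.08)


class TestRasters:
    def test_dlst_spans_all_bands(self, survey):
        vals = survey.rasters["dlst"].masked()
        assert np.nanmin(vals) < 30.0 < 35.0 < np.nanmax(vals)

    def test_finite_inside_country(self, survey):
        for rast in survey.rasters.values():
            assert np.isfinite(rast.masked()[rast.data != rast.nodata]).all()

    def test_resolution_guard(self):
        cfg = small_config(raster_cellsize=1e-6)
        amap = generate_admin_map(cfg)
        with pytest.raises(ValueError, match="resolution"):
            rasterize_covariates(amap, cfg)

    def test_ascii_roundtrip(self, survey, tmp_path):
        from stuntmap.raster import Raster

        r = survey.rasters["rainfall"]
        r.write_ascii(tmp_path / "r.asc")
        back = Raster.read_ascii(tmp_path / "r.asc")
        np.testing.assert_array_equal(back.data, r.data)
        assert back.cellsize == r.cellsize


class TestDeterminism:
    def test_same_seed_byte_identical_tables(self, tmp_path):
        cfg = small_config(n_clusters=40, seed=77)
        a = simulate_survey(cfg)
        b = simulate_survey(small_config(n_clusters=40, seed=77))
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for fn in ("children.csv", "clusters.csv", "truth.json"):
            assert (tmp_path / "a" / fn).read_bytes() == (tmp_path / "b" / fn).read_bytes()

    def test_different_seed_differs(self):
        a = simulate_survey(small_config(n_clusters=40, seed=1), with_rasters=False)
        b = simulate_survey(small_config(n_clusters=40, seed=2), with_rasters=False)
        assert not a.clusters["true_lon"].equals(b.clusters["true_lon"])


def test_survey_scale_defaults_match_study_design():
    """Default config reproduces the real survey's scale: 1377 clusters,
    ~12.6k children, 37 states, 30 households per cluster."""
    cfg = SimulationConfig(seed=0)
    assert cfg.n_clusters == 1377
    assert cfg.n_admin1 == 37
    assert cfg.households_per_cluster == 30
    assert cfg.n_clusters * cfg.children_per_cluster_mean == pytest.approx(12627)
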