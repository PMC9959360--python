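"""Pólya-Gamma Gibbs samplers: sanity, oracles, invariants, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from stuntmap.inference import (
    MCMCConfig,
    ModelSpec,
    build_design,
    fit_geospatial,
    fit_nonspatial,
    summarize_or,
)


def bernoulli_table(y, diarrhoea=None):
    df = pd.DataFrame({"stunted": y})
    df["child_id"] = np.arange(len(df))
    df["cluster_id"] = "c1"
    df["weight"] = 1.0
    if diarrhoea is not None:
        df["diarrhoea"] = np.where(np.asarray(diarrhoea) == 1, "yes", "no")
    return df


QUAD_Y0 = np.array([1] * 10 + [0] * 20)  # outcomes among unexposed
QUAD_Y1 = np.array([1] * 18 + [0] * 12)  # outcomes among exposed


def quadrature_posterior_means(y0, y1, prior_sd=10.0, lim=6.0, npts=241):
    """Dense trapezoid integration of the 2-parameter logistic posterior."""
    b0 = np.linspace(-lim, lim, npts)
    b1 = np.linspace(-lim, lim, npts)
    B0, B1 = np.meshgrid(b0, b1, indexing="ij")
    n0, s0 = len(y0), y0.sum()
    n1, s1 = len(y1), y1.sum()
    ll = (
        s0 * B0 - n0 * np.logaddexp(0, B0)
        + s1 * (B0 + B1) - n1 * np.logaddexp(0, B0 + B1)
    )
    lp = ll - (B0**2 + B1**2) / (2 * prior_sd**2)
    w = np.exp(lp - lp.max())
    Z = np.trapezoid(np.trapezoid(w, b1, axis=1), b0)
    m0 = np.trapezoid(np.trapezoid(w * B0, b1, axis=1), b0) / Z
    m1 = np.trapezoid(np.trapezoid(w * B1, b1, axis=1), b0) / Z
    return m0, m1


class TestNonspatial:
    def test_intercept_only_matches_observed_rate(self):
        table = bernoulli_table(np.array([1] * 30 + [0] * 70))
        spec = ModelSpec(terms=(), spatial=False)
        mcmc = MCMCConfig(n_iter=1500, burn_in=500, thin=1, chains=2, seed=1)
        s = fit_nonspatial(table, spec, mcmc)
        p_hat = expit(s.beta[:, 0]).mean()
        assert p_hat == pytest.approx(0.30, abs=0.02)

    def test_matches_quadrature_oracle(self):
        """Gibbs posterior means vs dense trapezoid integration (n=60)."""
        y = np.concatenate([QUAD_Y0, QUAD_Y1])
        x = np.concatenate([np.zeros(30), np.ones(30)])
        table = bernoulli_table(y, diarrhoea=x)
        spec = ModelSpec(terms=("diarrhoea",), spatial=False)
        mcmc = MCMCConfig(n_iter=4000, burn_in=1000, thin=1, chains=2, seed=3)
        s = fit_nonspatial(table, spec, mcmc)
        m0, m1 = quadrature_posterior_means(QUAD_Y0, QUAD_Y1)
        assert s.beta[:, 0].mean() == pytest.approx(m0, abs=0.05)
        assert s.beta[:, 1].mean() == pytest.approx(m1, abs=0.05)

    def test_two_seeds_agree_within_mc_error(self):
        y = np.concatenate([QUAD_Y0, QUAD_Y1])
        x = np.concatenate([np.zeros(30), np.ones(30)])
        table = bernoulli_table(y, diarrhoea=x)
        spec = ModelSpec(terms=("diarrhoea",), spatial=False)
        runs = []
        for seed in (11, 22):
            s = fit_nonspatial(table, spec, MCMCConfig(n_iter=3000, burn_in=1000, thin=1, chains=1, seed=seed))
            runs.append(s.beta[:, 1])
        se = np.sqrt(runs[0].var() / len(runs[0]) + runs[1].var() / len(runs[1]))
        # autocorrelation inflates the naive SE; allow a generous factor
        assert abs(runs[0].mean() - runs[1].mean()) < 3 * 5 * se

    def test_reference_level_swap_inverts_or(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 400)
        y = rng.binomial(1, expit(-0.3 + 0.8 * x))
        spec = ModelSpec(terms=("diarrhoea",), spatial=False)
        mcmc = MCMCConfig(n_iter=2000, burn_in=500, thin=1, chains=1, seed=0)
        a = fit_nonspatial(bernoulli_table(y, diarrhoea=x), spec, mcmc)
        b = fit_nonspatial(bernoulli_table(y, diarrhoea=1 - x), spec, mcmc)
        or_a = np.exp(np.median(a.beta[:, 1]))
        or_b = np.exp(np.median(b.beta[:, 1]))
        assert or_a == pytest.approx(1.0 / or_b, rel=0.10)

    def test_separation_warns(self):
        y = np.array([1] * 20 + [0] * 20)
        x = y.copy()
        table = bernoulli_table(y, diarrhoea=x)
        spec = ModelSpec(terms=("diarrhoea",), spatial=False)
        with pytest.warns(UserWarning, match="separation"):
            fit_nonspatial(table, spec, MCMCConfig(n_iter=300, burn_in=100, thin=1, chains=1, seed=0))

    def test_convergence_diagnostics_reported(self):
        table = bernoulli_table(np.array([1] * 30 + [0] * 70))
        spec = ModelSpec(terms=(), spatial=False)
        s = fit_nonspatial(table, spec, MCMCConfig(n_iter=2000, burn_in=500, thin=1, chains=2, seed=1))
        assert s.diagnostics["rhat"]["intercept"] <= 1.05
        assert s.diagnostics["ess"]["intercept"] >= 200


@pytest.fixture(scope="module")
def spatial_fixture():
    from conftest import small_config
    from stuntmap.mesh_spde import build_mesh
    from stuntmap.synthetic_data import simulate_survey

    cfg = small_config(seed=21, n_clusters=150, children_per_cluster_mean=15, poisson_children=False)
    sv = simulate_survey(cfg)
    children = sv.children.merge(sv.clusters[["cluster_id", "lon", "lat"]], on="cluster_id")
    mesh = build_mesh(
        sv.clusters[["lon", "lat"]].to_numpy(), max_edge=0.18, cutoff=0.1, boundary_extension=0.5
    )
    return sv, children, mesh


class TestGeospatial:
    def test_collapses_to_nonspatial_when_field_suppressed(self, spatial_fixture):
        """tau fixed huge (field variance ~ 0) reproduces the non-spatial
        fixed-effect posteriors within MC error."""
        sv, children, mesh = spatial_fixture
        terms = ("diarrhoea", "wealth")
        mcmc_s = MCMCConfig(
            n_iter=1200, burn_in=400, thin=1, chains=1, seed=2,
            kappa_init=7.0, tau_init=1e4, fix_hyperparameters=True,
        )
        s_sp = fit_geospatial(children, ModelSpec(terms=terms, spatial=True), mesh, mcmc_s)
        s_ns = fit_nonspatial(children, ModelSpec(terms=terms, spatial=False),
                              MCMCConfig(n_iter=1200, burn_in=400, thin=1, chains=1, seed=2))
        assert np.abs(s_sp.field).max() < 0.01
        for j in range(s_ns.beta.shape[1]):
            assert s_sp.beta[:, j].mean() == pytest.approx(s_ns.beta[:, j].mean(), abs=0.08)

    def test_predictions_track_cluster_prevalence(self, spatial_fixture):
        """Posterior in-sample cluster predictions correlate with the
        empirical cluster prevalences under a strong spatial field."""
        sv, children, mesh = spatial_fixture
        terms = ("diarrhoea",)
        s = fit_geospatial(
            children, ModelSpec(terms=terms, spatial=True), mesh,
            MCMCConfig(n_iter=1200, burn_in=400, thin=2, chains=1, seed=4),
        )
        X, _ = build_design(children, terms)
        from stuntmap.mesh_spde import projector

        A = projector(mesh, children[["lon", "lat"]].to_numpy())
        p = expit(s.eta(X, A)).mean(axis=0)
        df = pd.DataFrame({"cluster_id": children["cluster_id"], "p": p, "y": children["stunted"]})
        agg = df.groupby("cluster_id").mean()
        r = np.corrcoef(agg["p"], agg["y"])[0, 1]
        assert r > 0.5

    def test_monotone_link(self, spatial_fixture):
        """For draws with a positive diarrhoea coefficient, switching the
        covariate on never lowers the fitted probability."""
        sv, children, mesh = spatial_fixture
        s = fit_geospatial(
            children, ModelSpec(terms=("diarrhoea",), spatial=True), mesh,
            MCMCConfig(n_iter=600, burn_in=200, thin=2, chains=1, seed=6),
        )
        j = s.beta_names.index("diarrhoea[yes]")
        pos = s.beta[:, j] > 0
        base = np.zeros((1, len(s.beta_names)))
        base[0, 0] = 1.0
        on = base.copy()
        on[0, j] = 1.0
        assert (expit(s.beta[pos] @ on.T) >= expit(s.beta[pos] @ base.T)).all()

    def test_locations_outside_mesh_rejected(self, spatial_fixture):
        sv, children, mesh = spatial_fixture
        bad = children.copy()
        bad.loc[bad.index[:5], "lon"] = 99.0
        with pytest.raises(ValueError, match="outside the mesh"):
            fit_geospatial(bad, ModelSpec(terms=(), spatial=True), mesh,
                           MCMCConfig(n_iter=10, burn_in=0, thin=1, chains=1, seed=0))


class TestGaussianBlock:
    def test_sample_mean_solves_precision_system(self, rng):
        from stuntmap.inference import _sample_gaussian

        A = rng.standard_normal((8, 8))
        P = A @ A.T + 8 * np.eye(8)
        b = rng.standard_normal(8)
        draws = np.array([_sample_gaussian(P, b, rng) for _ in range(4000)])
        m = np.linalg.solve(P, b)
        assert np.abs(P @ m - b).max() < 1e-8
        np.testing.assert_allclose(draws.mean(axis=0), m, atol=0.1)
        np.testing.assert_allclose(np.cov(draws.T), np.linalg.inv(P), atol=0.05)


class TestSummarizeOr:
    def _samples(self, draws):
        from stuntmap.inference import PosteriorSamples

        return PosteriorSamples(
            beta=draws, beta_names=["intercept", "diarrhoea[yes]"], field=None,
            kappa=None, tau=None, chains=1, seed=0, n_iter=0, burn_in=0, thin=1,
        )

    def test_zero_draws_give_unit_or(self):
        s = self._samples(np.zeros((200, 2)))
        row = summarize_or(s).iloc[1]
        assert row.OR == 1.0 and row.cri_low == 1.0 and row.cri_high == 1.0
        assert not row.significant

    def test_concentrated_draws_near_target(self, rng):
        draws = np.column_stack([np.zeros(500), rng.normal(np.log(1.35), 1e-4, 500)])
        row = summarize_or(self._samples(draws)).iloc[1]
        assert row.OR == pytest.approx(1.35, rel=1e-3)
        assert row.significant

    def test_percentiles_match_sort_oracle(self, rng):
        draws = rng.standard_normal((1000, 2))
        row = summarize_or(self._samples(draws)).iloc[1]
        srt = np.sort(draws[:, 1])
        lo = np.percentile(srt, 2.5)
        hi = np.percentile(srt, 97.5)
        assert row.cri_low == pytest.approx(np.exp(lo), rel=1e-12)
        assert row.cri_high == pytest.approx(np.exp(hi), rel=1e-12)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_or(self._samples(np.zeros((50, 2))))


def test_build_design_reference_coding(survey):
    X, names = build_design(survey.children, ("wealth",))
    assert names[0] == "intercept"
    assert "wealth[poor]" not in names  # reference level
    assert set(names[1:]) <= {"wealth[middle]", "wealth[rich]"}
    assert X[:, 0].min() == 1.0
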