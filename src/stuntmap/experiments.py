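"""Simulation studies exercising the whole pipeline at desk scale.

The real survey behind this kind of analysis is restricted-access, so
the pipeline's statistical behaviour is demonstrated on synthetic
surveys drawn from its own generative model: parameter recovery
(credible-interval coverage of the true spatial variance and a known
odds ratio), directional model comparison (the spatial model should beat
the non-spatial one on DIC/WAIC when a spatial field is present), and
cluster hold-out validation (observed-vs-predicted correlation under
signal and under pure noise).

The study conditions are scaled down from the real design (1377 clusters
x ~9 children) to 300 clusters x 20 children on a 2x2-degree domain,
with the true hyperparameters kept at the fitted full-scale values
(kappa 7.33 per degree, spatial variance 0.24, diarrhoea OR 1.35).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import schema
from .inference import (
    MCMCConfig,
    ModelSpec,
    fit_geospatial,
    fit_nonspatial,
    hyperparameter_summary,
    summarize_or,
)
from .mesh_spde import Mesh, build_mesh, projector
from .model_compare import compute_dic, compute_waic
from .synthetic_data import SimulationConfig, simulate_survey
from .validate import SplitSpec, evaluate_holdout, split_clusters

#: Truth values the recovery study targets.
TRUE_VARIANCE = 0.24
TRUE_DIARRHOEA_OR = 1.35

#: Scaled study design (see module docstring).
STUDY_BBOX = (10.0, 6.0, 12.0, 8.0)
STUDY_CLUSTERS = 300
STUDY_CHILDREN = 20

#: MCMC schedule for replicate fits: single chain, enough draws for
#: stable 95% interval endpoints at these data sizes.
REPLICATE_MCMC = dict(n_iter=1500, burn_in=500, thin=2, chains=1)


def study_config(seed: int, n_clusters: int = STUDY_CLUSTERS, children: int = STUDY_CHILDREN, null: bool = False) -> SimulationConfig:
    cfg = SimulationConfig(
        seed=int(seed),
        n_admin1=6,
        n_admin2_per_admin1=4,
        n_clusters=n_clusters,
        children_per_cluster_mean=children,
        poisson_children=False,
        domain_bbox=STUDY_BBOX,
        raster_cellsize=0.02,
    )
    if null:
        cfg.betas = {k: {l: 0.0 for l in v} for k, v in cfg.betas.items()}
        cfg.field_tau = 1e6  # spatial variance ~ 0
    return cfg


def study_tables(cfg: SimulationConfig):
    sv = simulate_survey(cfg)
    children = sv.children.merge(
        sv.clusters[["cluster_id", "lon", "lat", "admin1_id"]], on="cluster_id"
    )
    return sv, children


def study_mesh(clusters: pd.DataFrame) -> Mesh:
    return build_mesh(
        clusters[["lon", "lat"]].to_numpy(), max_edge=0.15, cutoff=0.09, boundary_extension=0.5
    )


def _pointwise_loglik(samples, table, terms, mesh=None):
    from .validate import _design_matching

    X, _ = _design_matching(table, type("S", (), {"terms": terms})(), samples)
    A = None
    if samples.field is not None and mesh is not None:
        A = projector(mesh, table[["lon", "lat"]].to_numpy())
    y = (table["stunted"] == 1).to_numpy(float)
    ll = samples.pointwise_loglik(X, y, A)
    # log-lik at posterior-mean parameters (for the DIC plug-in deviance)
    eta_bar = X @ samples.beta.mean(axis=0)
    if A is not None:
        eta_bar = eta_bar + A @ samples.field.mean(axis=0)
    ll_bar = y * eta_bar - np.logaddexp(0.0, eta_bar)
    return ll, ll_bar


def recovery_replicate(seed: int, mcmc_kwargs: dict | None = None) -> dict:
    """One full replicate: simulate, fit both models, score everything.

    Returns coverage indicators for the spatial variance and diarrhoea
    OR, DIC/WAIC for both models, and the hold-out Pearson r from a
    75/25 cluster split refit.
    """
    mk = dict(REPLICATE_MCMC)
    if mcmc_kwargs:
        mk.update(mcmc_kwargs)
    cfg = study_config(seed)
    sv, children = study_tables(cfg)
    mesh = study_mesh(sv.clusters)
    terms = tuple(c for c in children.columns if c in schema.ALL_COVARIATES)
    spec_sp = ModelSpec(terms=terms, spatial=True)
    spec_ns = ModelSpec(terms=terms, spatial=False)

    fit_sp = fit_geospatial(children, spec_sp, mesh, MCMCConfig(seed=seed, **mk))
    fit_ns = fit_nonspatial(children, spec_ns, MCMCConfig(seed=seed, **mk))

    hyper = hyperparameter_summary(fit_sp).set_index("param")
    ors = summarize_or(fit_sp).set_index(["term", "level"])
    d_row = ors.loc[("diarrhoea", "yes")]

    ll_sp, llb_sp = _pointwise_loglik(fit_sp, children, terms, mesh)
    ll_ns, llb_ns = _pointwise_loglik(fit_ns, children, terms)
    dic_sp, _ = compute_dic(ll_sp, llb_sp)
    dic_ns, _ = compute_dic(ll_ns, llb_ns)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        waic_sp, _, _ = compute_waic(ll_sp)
        waic_ns, _, _ = compute_waic(ll_ns)

    train, test = split_clusters(children, SplitSpec(seed=seed))
    fit_tr = fit_geospatial(train, spec_sp, mesh, MCMCConfig(seed=seed + 1, **mk))
    report = evaluate_holdout(fit_tr, test, spec_sp, mesh, seed=seed)

    return {
        "seed": seed,
        "variance_median": float(hyper.loc["variance", "median"]),
        "variance_low": float(hyper.loc["variance", "cri_low"]),
        "variance_high": float(hyper.loc["variance", "cri_high"]),
        "covers_variance": bool(
            hyper.loc["variance", "cri_low"] <= TRUE_VARIANCE <= hyper.loc["variance", "cri_high"]
        ),
        "or_median": float(d_row["OR"]),
        "covers_or": bool(d_row["cri_low"] <= TRUE_DIARRHOEA_OR <= d_row["cri_high"]),
        "dic_spatial": float(dic_sp),
        "dic_nonspatial": float(dic_ns),
        "waic_spatial": float(waic_sp),
        "waic_nonspatial": float(waic_ns),
        "spatial_wins_dic": bool(dic_sp < dic_ns),
        "spatial_wins_waic": bool(waic_sp < waic_ns),
        "holdout_pearson_r": float(report["pearson_r"]),
        "holdout_coverage": float(report["coverage_95"]),
    }


def recovery_study(n_replicates: int = 20, seed: int = 0, mcmc_kwargs: dict | None = None) -> pd.DataFrame:
    rows = [recovery_replicate(int(seed) * 1000 + rep, mcmc_kwargs) for rep in range(n_replicates)]
    return pd.DataFrame(rows)


def null_replicate(seed: int, n_clusters: int = 400, children: int = 10) -> float:
    """Hold-out Pearson r on pure-noise data (no covariate or spatial
    effect); short chains.

    The cluster count matters: with ~100 held-out clusters the null
    sampling distribution of r has sd ~ 0.1, so |r| < 0.2 is a meaningful
    no-signal check; with very few clusters it would fail by pure noise.
    """
    cfg = study_config(seed, n_clusters=n_clusters, children=children, null=True)
    sv, table = study_tables(cfg)
    mesh = build_mesh(
        sv.clusters[["lon", "lat"]].to_numpy(), max_edge=0.25, cutoff=0.15, boundary_extension=0.5
    )
    terms = tuple(c for c in table.columns if c in schema.ALL_COVARIATES)
    spec = ModelSpec(terms=terms, spatial=True)
    train, test = split_clusters(table, SplitSpec(seed=seed))
    fit = fit_geospatial(
        train, spec, mesh, MCMCConfig(n_iter=700, burn_in=300, thin=2, chains=1, seed=seed)
    )
    report = evaluate_holdout(fit, test, spec, mesh, seed=seed)
    return float(report["pearson_r"])


def null_study(n_replicates: int = 20, seed: int = 0) -> np.ndarray:
    return np.array([null_replicate(int(seed) * 2000 + 7 + rep) for rep in range(n_replicates)])
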