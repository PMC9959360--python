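"""Cluster-level hold-out validation of the geospatial model.

Whole clusters (never individual children) are partitioned into a 75%
training and 25% test set, stratified by admin-1 unit to preserve
geographic spread.  The model fitted on the training children predicts
each test cluster's prevalence (posterior mean of the cluster-average
invlogit(x'beta + A S)); agreement is reported as Pearson and Spearman
correlation, mean (absolute) error, and coverage of 95% posterior
predictive intervals for the observed prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import pearsonr, spearmanr

from .inference import ModelSpec, PosteriorSamples
from .mesh_spde import Mesh, projector


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.75
    seed: int = 0
    stratify_admin1: bool = True

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def split_clusters(
    table: pd.DataFrame, spec: SplitSpec, cluster_col: str = "cluster_id", admin1_col: str = "admin1_id"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition children by whole clusters at the training fraction.

    Train size uses the floor convention per stratum (at least one test
    cluster overall).  Children follow their cluster; the two tables are
    disjoint and their union is the input.
    """
    clusters = table[cluster_col].unique()
    if len(clusters) < 8:
        raise ValueError("need >= 8 clusters to split")
    rng = np.random.default_rng(spec.seed)
    if spec.stratify_admin1 and admin1_col in table.columns:
        groups = (
            table[[cluster_col, admin1_col]].drop_duplicates().groupby(admin1_col)[cluster_col]
        )
        strata = [g.to_numpy() for _, g in groups]
    else:
        strata = [clusters]
    train_ids: list = []
    for ids in strata:
        ids = np.sort(ids)
        rng.shuffle(ids)
        # floor convention on the test share: 1377 clusters -> 344 test, 1033 train
        n_test = int(np.floor((1.0 - spec.train_fraction) * len(ids)))
        train_ids.extend(ids[: len(ids) - n_test])
    train_set = set(train_ids)
    if len(train_set) == len(clusters):
        raise ValueError("split left an empty test set")
    is_train = table[cluster_col].isin(train_set)
    return table[is_train].copy(), table[~is_train].copy()


def evaluate_holdout(
    samples: PosteriorSamples,
    test: pd.DataFrame,
    spec: ModelSpec,
    mesh: Mesh | None = None,
    cluster_coords: pd.DataFrame | None = None,
    seed: int = 0,
) -> dict:
    """Observed-vs-predicted prevalence agreement on held-out clusters.

    Predicted prevalence per test cluster is the posterior mean of the
    cluster-average child probability; the 95% predictive interval adds
    binomial sampling noise at the cluster size.  Test clusters with no
    children with a non-missing outcome are excluded.
    """
    sub = test.dropna(subset=[spec.outcome, *spec.terms]).reset_index(drop=True)
    if cluster_coords is not None:
        sub = sub.merge(cluster_coords[["cluster_id", "lon", "lat"]], on="cluster_id", how="left")
    X, _ = _design_matching(sub, spec, samples)
    A = None
    if samples.field is not None:
        if mesh is None:
            mesh = samples.mesh
        A = projector(mesh, sub[["lon", "lat"]].to_numpy())
    eta = samples.eta(X, A)  # (ndraw, n_children)
    p = expit(eta)

    rng = np.random.default_rng(seed)
    obs, pred, lo, hi, n_sizes = [], [], [], [], []
    for cid, idx in sub.groupby("cluster_id", sort=True).indices.items():
        n_c = len(idx)
        if n_c == 0:
            continue
        y_c = (sub.loc[idx, spec.outcome] == 1).to_numpy(float)
        p_draws = p[:, idx].mean(axis=1)  # cluster-average probability per draw
        y_rep = rng.binomial(n_c, np.clip(p_draws, 0.0, 1.0)) / n_c
        obs.append(y_c.mean())
        pred.append(float(p_draws.mean()))
        qlo, qhi = np.percentile(y_rep, [2.5, 97.5])
        lo.append(qlo)
        hi.append(qhi)
        n_sizes.append(n_c)
    obs = np.asarray(obs)
    pred = np.asarray(pred)
    lo = np.asarray(lo)
    hi = np.asarray(hi)
    if len(obs) >= 2 and obs.std() > 0 and pred.std() > 0:
        r_p = float(pearsonr(obs, pred).statistic)
        r_s = float(spearmanr(obs, pred).statistic)
    else:
        r_p = r_s = float("nan")
    return {
        "n_test_clusters": int(len(obs)),
        "pearson_r": r_p,
        "spearman_r": r_s,
        "mean_error": float(np.mean(pred - obs)),
        "mean_abs_error": float(np.mean(np.abs(pred - obs))),
        "coverage_95": float(np.mean((obs >= lo) & (obs <= hi))),
        "observed": obs.tolist(),
        "predicted": pred.tolist(),
    }


def _design_matching(sub: pd.DataFrame, spec: ModelSpec, samples: PosteriorSamples):
    """Design matrix with columns aligned to the fitted coefficient names
    (a test split can lack rare categories)."""
    from . import schema

    n = len(sub)
    X = np.zeros((n, len(samples.beta_names)))
    for j, name in enumerate(samples.beta_names):
        if name == "intercept":
            X[:, j] = 1.0
        else:
            term, level = name[:-1].split("[", 1)
            if term in sub.columns:
                X[:, j] = (sub[term].to_numpy() == level).astype(float)
    return X, list(samples.beta_names)


def scatter_plot(report: dict, out_path, title: str = "Hold-out validation") -> None:
    """Observed vs predicted cluster prevalence scatter with the 1:1 line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = np.asarray(report["observed"])
    pred = np.asarray(report["predicted"])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(obs, pred, s=14, alpha=0.6, edgecolor="none")
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("observed cluster prevalence")
    ax.set_ylabel("predicted cluster prevalence")
    ax.set_title(f"{title} (Pearson r = {report['pearson_r']:.2f})")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
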