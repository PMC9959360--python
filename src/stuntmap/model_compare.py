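"""DIC and WAIC model comparison from pointwise log-likelihood matrices.

Both criteria consume a (draws x observations) matrix of Bernoulli
log-likelihood values.  DIC uses the classic effective-parameter count
pD = Dbar - D(theta_bar); WAIC uses the variance penalty (pWAIC2).  For
the spatial model the pointwise likelihood conditions on the sampled
latent field (the conditional likelihood, comparable to what INLA
reports for these models).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Per-observation log-lik variance above which WAIC is unreliable.
WAIC_VAR_WARN = 0.4


def _check(pointwise: np.ndarray) -> np.ndarray:
    ll = np.asarray(pointwise, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, observations)")
    if ll.shape[0] < 2:
        raise ValueError("need >= 2 posterior draws")
    if not np.all(np.isfinite(ll)):
        d, o = np.argwhere(~np.isfinite(ll))[0]
        raise ValueError(f"non-finite log-likelihood at draw {d}, observation {o}")
    return ll


def compute_dic(pointwise: np.ndarray, theta_bar_loglik: np.ndarray) -> tuple[float, float]:
    """(DIC, pD) with Dbar = E_draws[-2 sum_i ll], D(theta_bar) from the
    log-likelihood at the posterior-mean parameters."""
    ll = _check(pointwise)
    tb = np.asarray(theta_bar_loglik, dtype=float).ravel()
    if tb.shape[0] != ll.shape[1]:
        raise ValueError("theta_bar log-likelihood length mismatch")
    if not np.all(np.isfinite(tb)):
        raise ValueError("non-finite log-likelihood at posterior mean")
    d_bar = float(np.mean(-2.0 * ll.sum(axis=1)))
    d_hat = float(-2.0 * tb.sum())
    p_d = d_bar - d_hat
    return d_bar + p_d, p_d


def compute_waic(pointwise: np.ndarray) -> tuple[float, float, float]:
    """(WAIC, p_waic, elpd) with the pWAIC2 variance penalty.

    elpd_i = log mean_d exp(ll_di) - var_d(ll_di), computed with a
    max-shifted log-mean-exp so arbitrarily small log-likelihoods are
    safe.
    """
    ll = _check(pointwise)
    ndraw = ll.shape[0]
    m = ll.max(axis=0)
    lme = m + np.log(np.mean(np.exp(ll - m[None, :]), axis=0))
    v = ll.var(axis=0, ddof=1)
    n_high = int((v > WAIC_VAR_WARN).sum())
    if n_high:
        import warnings

        warnings.warn(
            f"{n_high} observations with log-lik variance > {WAIC_VAR_WARN}; WAIC may be unstable",
            stacklevel=2,
        )
    elpd = float(np.sum(lme - v))
    p_waic = float(np.sum(v))
    return -2.0 * elpd, p_waic, elpd


@dataclass
class CandidateFit:
    name: str
    pointwise: np.ndarray
    theta_bar_loglik: np.ndarray
    n_parameters: int


def select_model(candidates: list[CandidateFit], criterion: str = "waic") -> pd.DataFrame:
    """Rank candidate fits by DIC/WAIC (ascending), ties broken by fewer
    parameters.  All candidates must share the observation set."""
    if not candidates:
        raise ValueError("no candidates")
    n_obs = {c.pointwise.shape[1] for c in candidates}
    if len(n_obs) > 1:
        raise ValueError(f"candidates have mismatched observation counts {sorted(n_obs)}")
    if criterion not in {"dic", "waic"}:
        raise ValueError("criterion must be 'dic' or 'waic'")
    rows = []
    for c in candidates:
        dic, p_d = compute_dic(c.pointwise, c.theta_bar_loglik)
        waic, p_waic, elpd = compute_waic(c.pointwise)
        rows.append(
            {
                "model": c.name,
                "DIC": dic,
                "pD": p_d,
                "WAIC": waic,
                "p_waic": p_waic,
                "elpd": elpd,
                "n_parameters": c.n_parameters,
            }
        )
    report = pd.DataFrame(rows)
    if len(report) > 1:
        report = report.sort_values(
            [criterion.upper() if criterion == "dic" else "WAIC", "n_parameters"],
            kind="stable",
        ).reset_index(drop=True)
        report["rank"] = np.arange(1, len(report) + 1)
    return report
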