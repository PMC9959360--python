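"""Survey table validation, the stunting outcome, and descriptive prevalence.

Descriptives mirror the standard DHS reporting table: per covariate
category, counts and percentages of stunted / not-stunted children,
either crude (unweighted cross-tabulation) or design-based
(Horvitz-Thompson ratio estimator with Taylor-linearized standard errors
under the stratified one-stage cluster approximation, the same estimator
R's ``survey::svydesign`` uses with with-replacement PSU sampling).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema

log = logging.getLogger(__name__)

#: Stunting threshold on the height-for-age z-score (WHO growth standards).
HAZ_CUTOFF = -2.0
#: WHO biological-plausibility flag: |HAZ| beyond this is treated as missing.
HAZ_FLAG_LIMIT = 6.0


@dataclass(frozen=True)
class SurveyDesign:
    """Column names identifying the complex-survey design."""

    stratum: str = "stratum_id"
    cluster: str = "cluster_id"
    weight: str = "weight"

    def check(self, table: pd.DataFrame) -> None:
        for col in (self.stratum, self.cluster, self.weight):
            if col not in table.columns:
                raise ValueError(f"design column {col!r} missing from table")
        w = table[self.weight]
        if (w.dropna() <= 0).any():
            raise ValueError("sampling weights must be strictly positive")


def classify_stunting(haz, flag_limit: float = HAZ_FLAG_LIMIT):
    """Binary stunting indicator: 1 iff HAZ < -2.0 (strict).

    Implausible scores (|HAZ| > flag_limit) and missing values return NaN
    so they drop out of prevalence denominators.
    """
    haz = np.asarray(haz, dtype=float)
    out = np.where(haz < HAZ_CUTOFF, 1.0, 0.0)
    out = np.where(np.isfinite(haz) & (np.abs(haz) <= flag_limit), out, np.nan)
    return float(out) if out.ndim == 0 else out


def _round_half_up(x, decimals=1):
    factor = 10.0**decimals
    return np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor


def prevalence_from_counts(stunted_n: int, not_stunted_n: int) -> float:
    """Report-scale percentage 100*stunted/(stunted+not), half-up to 1 dp."""
    total = stunted_n + not_stunted_n
    if total == 0:
        return float("nan")
    return float(_round_half_up(100.0 * stunted_n / total, 1))


def crude_prevalence(table: pd.DataFrame, covariate: str, outcome: str = "stunted") -> pd.DataFrame:
    """Unweighted per-category stunting cross-tabulation.

    Returns one row per category with columns n, pct, stunted_n,
    stunted_pct, not_stunted_n, not_stunted_pct.  Percentages are
    half-up rounded to one decimal; unrounded proportions are kept in
    `stunted_prop`.  Records missing the outcome or the covariate are
    excluded from this covariate's denominators.
    """
    if covariate not in table.columns:
        raise KeyError(f"covariate column {covariate!r} not in table")
    sub = table[[covariate, outcome]].dropna()
    total_n = len(sub)
    rows = []
    levels = (
        schema.ALL_COVARIATES[covariate]["levels"]
        if covariate in schema.ALL_COVARIATES
        else sorted(sub[covariate].unique())
    )
    for lvl in levels:
        grp = sub[sub[covariate] == lvl]
        n = len(grp)
        s = int((grp[outcome] == 1).sum())
        ns = n - s
        prop = s / n if n else float("nan")
        rows.append(
            {
                "covariate": covariate,
                "category": lvl,
                "n": n,
                "pct": float(_round_half_up(100.0 * n / total_n, 1)) if total_n else float("nan"),
                "stunted_n": s,
                "stunted_pct": float(_round_half_up(100.0 * prop, 1)) if n else float("nan"),
                "not_stunted_n": ns,
                "not_stunted_pct": float(_round_half_up(100.0 * (1 - prop), 1)) if n else float("nan"),
                "stunted_prop": prop,
            }
        )
        if n == 0:
            log.warning("covariate %s category %s is empty", covariate, lvl)
    return pd.DataFrame(rows)


def weighted_prevalence(
    table: pd.DataFrame,
    design: SurveyDesign,
    covariate: str,
    outcome: str = "stunted",
) -> pd.DataFrame:
    """Design-based per-category prevalence with Taylor-linearized SEs.

    The point estimate is the Horvitz-Thompson ratio
    p = sum(w y) / sum(w) over the category domain.  The variance uses
    the linearized residual u_i = w_i (y_i - p) / W aggregated to PSU
    totals, with the with-replacement between-PSU estimator
    sum_h n_h/(n_h-1) sum_j (z_hj - zbar_h)^2.  Strata containing a
    single PSU contribute zero variance (certainty-unit convention) with
    a warning.
    """
    design.check(table)
    if covariate not in table.columns:
        raise KeyError(f"covariate column {covariate!r} not in table")
    sub = table.dropna(subset=[covariate, outcome])
    levels = (
        schema.ALL_COVARIATES[covariate]["levels"]
        if covariate in schema.ALL_COVARIATES
        else sorted(sub[covariate].unique())
    )
    rows = []
    for lvl in levels:
        dom = sub[covariate] == lvl
        w = sub[design.weight].to_numpy(dtype=float)
        y = (sub[outcome] == 1).to_numpy(dtype=float)
        d = dom.to_numpy(dtype=float)
        W = float(np.sum(w * d))
        if W == 0:
            rows.append(
                {"covariate": covariate, "category": lvl, "n": 0, "stunted_pct": float("nan"), "se_pct": float("nan"), "stunted_prop": float("nan")}
            )
            continue
        p = float(np.sum(w * d * y) / W)
        u = w * d * (y - p) / W
        z = pd.DataFrame(
            {"u": u, "stratum": sub[design.stratum].to_numpy(), "psu": sub[design.cluster].to_numpy()}
        )
        psu_tot = z.groupby(["stratum", "psu"], sort=False)["u"].sum()
        var = 0.0
        for _, zh in psu_tot.groupby(level="stratum", sort=False):
            nh = len(zh)
            if nh < 2:
                warnings.warn(
                    "stratum with a single PSU contributes zero variance", stacklevel=2
                )
                continue
            var += nh / (nh - 1) * float(np.sum((zh - zh.mean()) ** 2))
        rows.append(
            {
                "covariate": covariate,
                "category": lvl,
                "n": int(dom.sum()),
                "stunted_pct": float(_round_half_up(100.0 * p, 1)),
                "se_pct": 100.0 * float(np.sqrt(var)),
                "stunted_prop": p,
            }
        )
    return pd.DataFrame(rows)


def read_child_table(path, flag_limit: float = HAZ_FLAG_LIMIT) -> pd.DataFrame:
    """Read and validate a child-level survey CSV.

    Derives `stunted` from `haz` when absent, validates category labels
    against the covariate vocabulary, rejects non-positive weights (by
    row index), and logs a missingness report.
    """
    table = pd.read_csv(path)
    for col in ("child_id", "cluster_id", "weight"):
        if col not in table.columns:
            raise ValueError(f"required column {col!r} missing")
    bad_w = table.index[table["weight"] <= 0].tolist()
    if bad_w:
        raise ValueError(f"non-positive weights at rows {bad_w[:10]}")
    if "stunted" not in table.columns:
        if "haz" not in table.columns:
            raise ValueError("need either a 'stunted' or a 'haz' column")
        table["stunted"] = classify_stunting(table["haz"], flag_limit=flag_limit)
    for name in table.columns:
        if name in schema.ALL_COVARIATES:
            schema.validate_labels(name, table[name])
    n_miss = int(table["stunted"].isna().sum())
    log.info("read %d children (%d with missing/flagged outcome)", len(table), n_miss)
    return table


def descriptive_table(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    design: SurveyDesign | None = None,
) -> pd.DataFrame:
    """Stacked descriptive prevalence over a list of covariates (the
    standard reporting table surface); weighted columns are appended when
    a design is given."""
    if covariates is None:
        covariates = [c for c in table.columns if c in schema.ALL_COVARIATES]
    parts = []
    for cov in covariates:
        crude = crude_prevalence(table, cov)
        if design is not None:
            wtd = weighted_prevalence(table, design, cov)[
                ["covariate", "category", "stunted_pct", "se_pct"]
            ].rename(columns={"stunted_pct": "weighted_stunted_pct", "se_pct": "weighted_se_pct"})
            crude = crude.merge(wtd, on=["covariate", "category"])
        parts.append(crude)
    return pd.concat(parts, ignore_index=True)
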