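"""Covariate vocabulary for the stunting analysis.

Categories follow the proximal/contextual determinant taxonomy used in
DHS-based stunting studies: immediate proximal factors (child illness),
proximal contextual factors (maternal, household, health-service) and
environmental/climatic contextual factors extracted from rasters at
cluster locations.

Each covariate carries:

* ``levels`` — category labels, reference level first;
* ``probs`` — default marginal probabilities used by the synthetic
  generator, calibrated to the descriptive distribution of the 2018
  Nigeria DHS stunting sample;
* ``beta`` — default true log-odds effects (relative to the reference)
  for the generator, calibrated to the adjusted odds ratios estimated on
  that survey (e.g. diarrhoea OR 1.35, clean cooking fuel OR 0.79);
* ``cluster_level`` — True for climatic covariates that attach to the
  cluster via raster extraction rather than to the child.
"""

from __future__ import annotations

import math

_L = math.log


def _cov(levels, probs, ors, cluster_level=False):
    # ors: odds ratios for non-reference levels, in level order
    beta = {lvl: 0.0 for lvl in levels}
    for lvl, or_ in zip(levels[1:], ors):
        beta[lvl] = _L(or_)
    total = sum(probs)
    return {
        "levels": list(levels),
        "reference": levels[0],
        "probs": {lvl: p / total for lvl, p in zip(levels, probs)},
        "beta": beta,
        "cluster_level": cluster_level,
    }


#: Child/household-level covariates (drawn per child in the generator).
CHILD_COVARIATES: dict[str, dict] = {
    "diarrhoea": _cov(["no", "yes"], [87.4, 12.6], [1.35]),
    "ari": _cov(["no", "yes"], [94.5, 5.5], [0.99]),
    "maternal_nutrition": _cov(
        ["normal", "underweight", "overweight", "obese"],
        [61.4, 9.4, 19.5, 9.7],
        [1.14, 0.79, 0.63],
    ),
    "maternal_education": _cov(
        ["no_schooling", "primary", "secondary_or_higher"],
        [38.8, 15.9, 45.3],
        [0.92, 0.69],
    ),
    "wealth": _cov(["poor", "middle", "rich"], [37.8, 20.7, 41.5], [0.94, 0.75]),
    "anc_visits": _cov(["none", "1-3_visits", "4+_visits"], [20.9, 16.0, 63.1], [1.08, 1.04]),
    "place_of_birth": _cov(["home", "health_facility"], [54.5, 45.5], [0.86]),
    "birth_size": _cov(
        ["very_large", "larger_than_average", "average", "smaller_than_average", "very_small"],
        [9.1, 24.3, 54.3, 9.9, 2.5],
        [1.27, 1.32, 1.64, 2.39],
    ),
    "cooking_fuel": _cov(["not_clean", "clean"], [74.6, 25.4], [0.79]),
    "drinking_water": _cov(["not_protected", "protected"], [52.1, 47.9], [0.97]),
    "toilet": _cov(["not_improved", "improved"], [45.0, 55.0], [1.04]),
}

#: Cluster-level climatic covariates (categorized raster extractions).
CLUSTER_COVARIATES: dict[str, dict] = {
    "dlst": _cov(["lt_30C", "30-34.9C", "ge_35C"], [27.1, 49.7, 23.2], [1.01, 1.11], True),
    "rainfall": _cov(["low", "medium", "high"], [61.1, 35.2, 3.7], [0.78, 0.77], True),
    "aridity": _cov(["wet", "semi_arid", "arid"], [14.2, 33.3, 52.5], [1.16, 1.50], True),
    "urbanization": _cov(
        ["rural_villages", "urban_clusters", "urban_centres"],
        [63.7, 4.7, 31.6],
        [0.83, 0.69],
        True,
    ),
}

ALL_COVARIATES: dict[str, dict] = {**CHILD_COVARIATES, **CLUSTER_COVARIATES}

#: Core (non-covariate) columns of a child table.
CORE_COLUMNS = ["child_id", "cluster_id", "stratum_id", "weight", "haz", "stunted"]


def validate_labels(name: str, values) -> None:
    """Raise if any value is not a declared category of covariate `name`."""
    if name not in ALL_COVARIATES:
        raise ValueError(f"unknown covariate {name!r}")
    allowed = set(ALL_COVARIATES[name]["levels"])
    import pandas as pd

    bad = set(pd.Series(values).dropna().unique()) - allowed
    if bad:
        raise ValueError(f"column {name!r} contains unknown categories: {sorted(bad)}")
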