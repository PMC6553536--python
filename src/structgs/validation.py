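"""Independent-set validation of genomic predictions against geography.

Population-level adjusted GEBVs (least-squares means of a one-way
individual-within-population model) are correlated with the 30-yr minimum
temperature of the coldest month, latitude and longitude of each
population's site of origin, and regressed on latitude + longitude by
ordinary least squares.  Minimum temperature is excluded from the multiple
regression when it is collinear with latitude.  Phenotype-based accuracies
are Pearson correlations at the individual or the population level.

Longitude is signed (degrees East; negative across the USA), so a breeding
value that rises from west to east correlates *negatively* with |longitude|
but positively with the signed value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = ["adjust_gebv", "critical_r", "geo_correlations", "geo_regression",
           "prediction_accuracy"]


def adjust_gebv(gebv, pop_labels) -> pd.DataFrame:
    """Population-level adjusted GEBV.

    Fits the one-way model GEBV ~ population and reports each population's
    least-squares mean (for a one-way classification this equals the
    within-population arithmetic mean).  Shifting every GEBV by a constant
    shifts every adjusted value by the same constant.
    """
    gebv = np.asarray(gebv, dtype=float)
    pop_labels = np.asarray(pop_labels)
    if len(gebv) != len(pop_labels):
        raise ValueError("gebv and labels must align")
    df = pd.DataFrame({"population": pop_labels, "gebv": gebv})
    counts = df.groupby("population", sort=False).size()
    if (counts < 1).any():
        raise ValueError("every population needs at least one individual")
    means = df.groupby("population", sort=False)["gebv"].mean()
    return pd.DataFrame({"population": means.index,
                         "adjusted_gebv": means.to_numpy()})


def critical_r(n: int, alpha: float = 0.01) -> float:
    """Two-sided critical |r| from the t distribution with n - 2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(t * t + n - 2))


def geo_correlations(adjusted: pd.DataFrame, meta: pd.DataFrame,
                     variables=("min_temp", "latitude", "longitude"),
                     alpha: float = 0.01) -> pd.DataFrame:
    """Pearson correlations of adjusted GEBV with climatic/geographic variables.

    Returns a table with columns ``variable, r, n, critical_r, significant``;
    a zero-variance variable yields r = NaN and is flagged not significant.
    """
    df = adjusted.merge(meta, on="population", how="inner")
    n = len(df)
    if n < 4:
        raise ValueError("need at least 4 populations")
    rc = critical_r(n, alpha)
    rows = []
    g = df["adjusted_gebv"].to_numpy(dtype=float)
    for var in variables:
        x = df[var].to_numpy(dtype=float)
        if np.std(x) < 1e-14 or np.std(g) < 1e-14:
            rows.append((var, np.nan, n, rc, False))
            continue
        r = float(np.corrcoef(g, x)[0, 1])
        rows.append((var, r, n, rc, abs(r) > rc))
    return pd.DataFrame(rows, columns=["variable", "r", "n",
                                       "critical_r", "significant"])


def geo_regression(adjusted: pd.DataFrame, meta: pd.DataFrame,
                   collinearity_threshold: float = 0.8) -> pd.DataFrame:
    """OLS of adjusted GEBV on latitude and longitude.

    Minimum temperature is deliberately left out of the design whenever
    |r(min_temp, latitude)| exceeds ``collinearity_threshold`` (it always is
    in the data this models, so the default design is lat + long).  Returns
    a table of coefficients with t statistics, two-sided p-values, and the
    model R^2 / adjusted R^2 on the last rows.
    """
    df = adjusted.merge(meta, on="population", how="inner")
    if len(df) < 4:
        raise ValueError("need at least 4 populations")
    predictors = ["latitude", "longitude"]
    if "min_temp" in df.columns:
        r_ml = abs(np.corrcoef(df["min_temp"], df["latitude"])[0, 1])
        if r_ml <= collinearity_threshold:
            predictors.append("min_temp")
    X = sm.add_constant(df[predictors].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient regression design")
    fit = sm.OLS(df["adjusted_gebv"].to_numpy(dtype=float), X).fit()
    rows = []
    names = ["intercept"] + predictors
    for i, name in enumerate(names):
        rows.append((name, fit.params[i], fit.tvalues[i], fit.pvalues[i]))
    rows.append(("r_squared", fit.rsquared, np.nan, np.nan))
    rows.append(("adj_r_squared", fit.rsquared_adj, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["term", "estimate", "t_value", "p_value"])


def prediction_accuracy(predicted: pd.DataFrame, phenotype: pd.DataFrame,
                        level: str = "individual") -> float:
    """Pearson accuracy of predictions against phenotypes.

    ``predicted`` has columns ``id, gebv`` (+ ``population`` for the
    population level); ``phenotype`` has ``id, value`` (or ``population,
    value`` at the population level, e.g. per-location population BLUPs).
    """
    if level == "individual":
        merged = predicted.merge(phenotype, on="id", how="outer", indicator=True)
        bad = merged[merged["_merge"] != "both"]["id"].tolist()
        if bad:
            raise ValueError(f"unmatched ids: {bad}")
        if len(merged) < 3:
            raise ValueError("need at least 3 matched records")
        return float(np.corrcoef(merged["gebv"], merged["value"])[0, 1])
    if level == "population":
        if "population" in predicted.columns and "gebv" in predicted.columns \
                and "adjusted_gebv" not in predicted.columns:
            adj = adjust_gebv(predicted["gebv"], predicted["population"])
        else:
            adj = predicted[["population", "adjusted_gebv"]]
        merged = adj.merge(phenotype, on="population", how="outer",
                           indicator=True)
        bad = merged[merged["_merge"] != "both"]["population"].tolist()
        if bad:
            raise ValueError(f"unmatched populations: {bad}")
        if len(merged) < 3:
            raise ValueError("need at least 3 matched populations")
        return float(np.corrcoef(merged["adjusted_gebv"], merged["value"])[0, 1])
    raise ValueError(f"unknown level {level!r}")
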