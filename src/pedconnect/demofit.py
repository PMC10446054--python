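"""Demographic growth rates and the migrant-vs-resident fitness analysis.

Growth rates follow the census convention λ(patch, T) = N_T / N_{T−1}, with
the cell undefined whenever the previous year's count is 0 or 1 (a single
plant gives no meaningful rate). λ > 1 means the patch is expanding.

Reproductive success compares triad offspring that themselves resulted from
a between-patch dispersal event ("migrant-derived") against triad offspring
with two resident parents. The response is the number of retained triads in
which the focal plant later appears as a parent. Plants first sampled in the
last years of the survey are excluded (their offspring cannot have been
observed yet). Counts are overdispersed, so the effect is estimated by
negative-binomial regression of offspring number on dispersal status with
patch fixed effects and cluster-robust standard errors grouped on the seed
parent (random-intercept NB mixed models are not available in the Python
stack; the fixed-effect fallback is recorded in the result's ``method``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotype_io import records_to_frame

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# growth rates
# ---------------------------------------------------------------------------


def census_counts(records) -> pd.DataFrame:
    """Patch × year counts of plants first sampled that year (new recruits)."""
    rec = records_to_frame(records)
    tab = (
        rec.groupby(["first_year", "patch"]).size().unstack(fill_value=0).sort_index()
    )
    tab.index.name = "year"
    return tab


@dataclass
class GrowthRateTable:
    rates: pd.DataFrame  # year × patch, NaN where undefined
    medians: pd.Series  # per patch, over defined cells

    def to_frame(self) -> pd.DataFrame:
        out = self.rates.copy()
        out.loc["median"] = self.medians
        return out


def median_growth_rates(rates: pd.DataFrame) -> pd.Series:
    """Per-patch median λ over the defined (non-NaN) cells."""
    return rates.median(axis=0, skipna=True)


def growth_rates(census: pd.DataFrame) -> GrowthRateTable:
    """λ(patch, T) = N_T / N_{T−1}; undefined when N_{T−1} ∈ {0, 1}."""
    census = census.sort_index()
    if len(census.index) < 2:
        raise ValueError("need at least 2 census years")
    years = census.index.to_numpy()
    rates = pd.DataFrame(np.nan, index=years[1:], columns=census.columns)
    for t_prev, t in zip(years[:-1], years[1:]):
        prev = census.loc[t_prev]
        cur = census.loc[t]
        ok = prev >= 2
        rates.loc[t, ok] = (cur[ok] / prev[ok]).astype(float)
    return GrowthRateTable(rates=rates, medians=median_growth_rates(rates))


# ---------------------------------------------------------------------------
# fitness records
# ---------------------------------------------------------------------------


def fitness_records(
    ped,
    events,
    last_years_excluded: int = 2,
    max_year: int | None = None,
) -> pd.DataFrame:
    """One row per triad offspring eligible for the fitness comparison.

    Columns: ``status`` ("migrant" when the plant's own triad was a
    between-patch event, else "resident"), ``n_offspring`` (retained triads
    listing the plant as a parent, over the whole survey), ``patch``,
    ``seed_parent``, ``pollen_parent``, ``year``. Plants first sampled after
    ``max_year − last_years_excluded`` are dropped to avoid censoring their
    offspring counts.
    """
    from .connectivity import events_to_frame  # local import, no cycle

    ev = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if max_year is None:
        max_year = int(ped.records["first_year"].max())
    cutoff = max_year - last_years_excluded
    n_off: dict[str, int] = {}
    for p1, p2 in ped.parents.values():
        n_off[p1] = n_off.get(p1, 0) + 1
        n_off[p2] = n_off.get(p2, 0) + 1
    rows = []
    for e in ev.itertuples(index=False):
        if e.year > cutoff:
            continue
        rows.append(
            {
                "id": e.offspring,
                "status": "migrant" if e.between_patch else "resident",
                "n_offspring": n_off.get(e.offspring, 0),
                "patch": e.offspring_patch,
                "seed_parent": e.seed_parent,
                "pollen_parent": e.pollen_parent,
                "year": e.year,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["id", "status", "n_offspring", "patch", "seed_parent",
                 "pollen_parent", "year"],
    ).sort_values("id").reset_index(drop=True)
    logger.info(
        "%d fitness records (%d migrant-derived), cohorts up to %d",
        len(df), int((df["status"] == "migrant").sum()) if len(df) else 0, cutoff,
    )
    return df


# ---------------------------------------------------------------------------
# negative-binomial model
# ---------------------------------------------------------------------------


class ModelConvergenceError(RuntimeError):
    pass


@dataclass
class FitnessModelResult:
    rate_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    nb_alpha: float  # NB dispersion parameter (0 = Poisson)
    group_means: dict[str, float]
    prop_reproducing: dict[str, float]
    poisson_overdispersion: float  # Pearson chi2 / df of a Poisson fit
    n: int
    method: str

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [
                    self.rate_ratio, self.ci_low, self.ci_high, self.p_value,
                    self.nb_alpha,
                    self.group_means.get("migrant", np.nan),
                    self.group_means.get("resident", np.nan),
                    self.prop_reproducing.get("migrant", np.nan),
                    self.prop_reproducing.get("resident", np.nan),
                    self.poisson_overdispersion, self.n,
                ]
            },
            index=[
                "rate_ratio", "ci_low", "ci_high", "p_value", "nb_alpha",
                "mean_offspring_migrant", "mean_offspring_resident",
                "prop_reproducing_migrant", "prop_reproducing_resident",
                "poisson_overdispersion", "n_records",
            ],
        )


def fitness_model(records: pd.DataFrame, cluster_on: str = "seed_parent") -> FitnessModelResult:
    """Negative-binomial regression of offspring number on dispersal status.

    The back-transformed status coefficient is the migrant/resident rate
    ratio. Patch enters as fixed-effect dummies; standard errors are
    cluster-robust on ``cluster_on`` (default: the seed parent). Raises
    :class:`ModelConvergenceError` when the optimizer fails.
    """
    df = records.copy()
    for grp in ("migrant", "resident"):
        if (df["status"] == grp).sum() == 0:
            raise ValueError(f"no records with status {grp!r}")
    y = df["n_offspring"].to_numpy(dtype=float)
    status = (df["status"] == "migrant").astype(float).to_numpy()
    X = pd.DataFrame({"const": 1.0, "migrant": status})
    patches = sorted(df["patch"].unique().tolist())
    for p in patches[1:]:
        X[f"patch_{p}"] = (df["patch"] == p).astype(float).to_numpy()
    X = X.to_numpy()
    groups = df[cluster_on].astype("category").cat.codes.to_numpy()

    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    overdisp = float(pois.pearson_chi2 / pois.df_resid) if pois.df_resid > 0 else np.nan

    method = "NB2 MLE, patch fixed effects, cluster-robust SE"
    try:
        nb = sm.NegativeBinomial(y, X).fit(
            disp=False, maxiter=200, cov_type="cluster", cov_kwds={"groups": groups}
        )
        converged = bool(nb.mle_retvals.get("converged", True))
    except Exception as exc:  # noqa: BLE001 - surfaced as a model error
        raise ModelConvergenceError(f"negative-binomial fit failed: {exc}") from exc
    if not converged or not np.isfinite(nb.params).all():
        raise ModelConvergenceError(
            f"negative-binomial fit did not converge: {nb.mle_retvals}"
        )
    beta = float(nb.params[1])
    se = float(nb.bse[1])
    z = 1.959963984540054
    pval = float(nb.pvalues[1])
    alpha = float(nb.params[-1])  # statsmodels appends the dispersion parameter

    means = df.groupby("status")["n_offspring"].mean().to_dict()
    props = df.groupby("status")["n_offspring"].apply(lambda s: float((s > 0).mean())).to_dict()
    result = FitnessModelResult(
        rate_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=pval,
        nb_alpha=alpha,
        group_means={k: float(v) for k, v in means.items()},
        prop_reproducing=props,
        poisson_overdispersion=overdisp,
        n=len(df),
        method=method,
    )
    logger.info(
        "fitness model: rate ratio %.3f [%.2f, %.2f], p=%.3g (%s)",
        result.rate_ratio, result.ci_low, result.ci_high, result.p_value, method,
    )
    return result
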