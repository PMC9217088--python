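"""Comparison of estimated diet δ15N against literature compilations.

Literature observations arrive at mixed granularity: some rows are single
individuals (n = 1, no SD), others summarize a group with mean, SD and n.
Family-level pooling therefore uses the standard pooled-moments identity —
the pooled mean is the n-weighted mean of observation means, and the pooled
variance combines within-observation variance with the between-observation
spread, so that pooled moments equal the moments of the fully expanded
individual-level data.

``compare_diet`` places each observation (as a point mass of weight n at its
mean) relative to the per-specimen diet-δ15N range and reports n-weighted
coverage fractions plus the sorted list of observations exceeding the diet
maximum.  ``density_curve`` gives the n-weighted Gaussian kernel density of
observation means used for distribution plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError

LITERATURE_GROUPS = ("shark", "marine_mammal")


def _check_observations(obs: pd.DataFrame) -> pd.DataFrame:
    needed = {"group", "family", "mean_d15n", "n_individuals"}
    if missing := needed - set(obs.columns):
        raise SchemaError(f"literature observations: missing column(s) {sorted(missing)}")
    if len(obs) == 0:
        raise SchemaError("literature observations: empty table")
    bad = ~obs["group"].isin(LITERATURE_GROUPS)
    if bad.any():
        raise SchemaError(
            f"literature observations: unknown group value(s) "
            f"{sorted(obs.loc[bad, 'group'].unique())}; expected {LITERATURE_GROUPS}"
        )
    if (obs["n_individuals"] < 1).any():
        raise SchemaError("literature observations: n_individuals must be >= 1")
    if not np.isfinite(obs["mean_d15n"]).all():
        raise SchemaError("literature observations: mean_d15n must be finite")
    return obs


def pool_family_stats(obs: pd.DataFrame) -> pd.DataFrame:
    """Pooled mean, SD and total n per (group, family).

    Within-observation variance enters via the given SDs (taken as sample
    SDs over n individuals); observations with missing SD contribute only
    their between-observation spread.  With all individual-level rows the
    result equals the plain sample moments of the expanded data.
    """
    obs = _check_observations(obs)
    rows = []
    for (group, family), g in obs.groupby(["group", "family"], sort=True):
        n = g["n_individuals"].to_numpy(float)
        m = g["mean_d15n"].to_numpy(float)
        sd = g["sd_d15n"].to_numpy(float) if "sd_d15n" in g.columns else np.full(len(g), np.nan)
        ntot = n.sum()
        mean = float(np.dot(n, m) / ntot)
        # total sum of squares about the pooled mean
        within = np.where(np.isfinite(sd) & (n > 1), (n - 1) * sd**2, 0.0)
        between = n * (m - mean) ** 2
        ss = float(within.sum() + between.sum())
        pooled_sd = float(np.sqrt(ss / (ntot - 1))) if ntot > 1 else np.nan
        rows.append(
            dict(group=group, family=family, pooled_mean=mean,
                 pooled_sd=pooled_sd, total_n=int(ntot), n_observations=len(g))
        )
    return pd.DataFrame(rows)


@dataclass
class DietComparison:
    """Placement of literature δ15N observations against a diet-δ15N range."""

    diet_mean: float
    diet_min: float
    diet_max: float
    n_diet_values: int
    frac_below: float  # n-weighted fraction of observations below diet_min
    frac_within: float
    frac_above: float
    exceedances: pd.DataFrame  # observations with mean_d15n > diet_max, sorted desc
    family_stats: pd.DataFrame = field(repr=False, default=None)

    def fractions(self) -> tuple[float, float, float]:
        return (self.frac_below, self.frac_within, self.frac_above)


def compare_diet(diet_values, obs: pd.DataFrame) -> DietComparison:
    """Compare per-specimen diet δ15N estimates with literature observations.

    ``diet_values`` are the specimen-level diet δ15N estimates (‰); the
    observation table is n-weighted, each observation sitting at its mean.
    """
    diet = np.asarray(diet_values, dtype=float)
    diet = diet[np.isfinite(diet)]
    if len(diet) == 0:
        raise SchemaError("compare_diet: no finite diet values")
    obs = _check_observations(obs)

    lo, hi = float(diet.min()), float(diet.max())
    w = obs["n_individuals"].to_numpy(float)
    m = obs["mean_d15n"].to_numpy(float)
    wtot = w.sum()
    below = float(w[m < lo].sum() / wtot)
    above = float(w[m > hi].sum() / wtot)
    within = float(w[(m >= lo) & (m <= hi)].sum() / wtot)

    exceed = obs[m > hi].sort_values("mean_d15n", ascending=False, ignore_index=True)
    return DietComparison(
        diet_mean=float(diet.mean()),
        diet_min=lo,
        diet_max=hi,
        n_diet_values=int(len(diet)),
        frac_below=below,
        frac_within=within,
        frac_above=above,
        exceedances=exceed,
        family_stats=pool_family_stats(obs),
    )


def density_curve(
    obs: pd.DataFrame,
    group: str | None = None,
    grid=None,
    weighted: bool = True,
    bw_method="scott",
):
    """n-weighted Gaussian kernel density of literature observation means.

    Returns ``(grid, density)``.  Bandwidth follows scipy's rule given by
    ``bw_method`` (Scott's rule by default); set ``weighted=False`` to weight
    every observation equally regardless of its n.
    """
    obs = _check_observations(obs)
    if group is not None:
        obs = obs[obs["group"] == group]
        if len(obs) == 0:
            raise SchemaError(f"density_curve: no observations in group {group!r}")
    m = obs["mean_d15n"].to_numpy(float)
    w = obs["n_individuals"].to_numpy(float) if weighted else None
    kde = stats.gaussian_kde(m, bw_method=bw_method, weights=w)
    if grid is None:
        pad = 3.0
        grid = np.linspace(m.min() - pad, m.max() + pad, 256)
    return grid, kde(grid)
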