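"""Baseline-referenced trophic-level and diet-δ15N reconstruction.

For each epoch, the mean enameloid-bound δ15N of all piscivorous-shark teeth
defines the food-web reference ("piscivore baseline"), assumed to hold a
constant trophic level through time — anchored at 4.4, the estimated trophic
level of the modern sand tiger shark.  For every other species × epoch group:

* Δδ15N = group mean − baseline mean, with SDs combined in quadrature;
* trophic offset = Δδ15N / TDF for each trophic discrimination factor in the
  configured range (default mid 2.5‰, range 2.3–5.5‰);
* absolute trophic level = 4.4 + offset;
* diet δ15N = group mean − 1.7‰ (EB − dentin offset) − 2.5‰ (dentin TDF);
* a Welch's t-test of the group's teeth against the contemporaneous
  piscivore pool.

Two screens guard the interpretation: a diagenesis screen (N-content means by
preservation class and δ15N–N-content correlations, flagging the
loss-with-fractionation signature of a significantly negative correlation)
and a baseline-consistency screen (across-epoch and across-region mean
differences per genus, flagged above a threshold, default 3‰).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, SchemaError
from .tissue import pearson_test

#: Genera of the megatooth-shark lineage, used by the diagenesis screen.
MEGATOOTH_GENERA = ("Otodus", "Cretalamna")


@dataclass
class TDFModel:
    """Trophic discrimination factors and tissue offsets used for inference."""

    tdf_mid: float = 2.5  # ‰ per trophic level (mid-range shark muscle TDF)
    tdf_range: tuple[float, float] = (2.3, 5.5)  # ‰, literature TDF range
    eb_dentin_offset: float = 1.7  # ‰, EB − dentin collagen
    dentin_muscle_offset: float = 1.9  # ‰, muscle − dentin collagen
    anchor_species: str = "Carcharias taurus"
    anchor_trophic_level: float = 4.4

    def __post_init__(self):
        lo, hi = self.tdf_range
        if not (0 < lo <= self.tdf_mid <= hi):
            raise FitError("tdf_range must satisfy 0 < lo <= tdf_mid <= hi")


def summarize_groups(teeth: pd.DataFrame) -> pd.DataFrame:
    """Per species × epoch: n, mean and sample SD of δ15N_EB."""
    if len(teeth) == 0:
        raise SchemaError("summarize_groups: empty tooth table")
    out = (
        teeth.groupby(["species", "epoch"], sort=True)
        .agg(
            genus=("genus", "first"),
            is_piscivore=("is_piscivore", "first"),
            n=("d15n_eb", "size"),
            mean_d15n=("d15n_eb", "mean"),
            sd_d15n=("d15n_eb", lambda v: np.std(v, ddof=1) if len(v) >= 2 else np.nan),
        )
        .reset_index()
    )
    return out


def piscivore_baseline(teeth: pd.DataFrame, epoch: str):
    """Mean, SD and n over all piscivore teeth of one epoch (pooled)."""
    pool = teeth[(teeth["epoch"] == epoch) & teeth["is_piscivore"].astype(bool)]
    if len(pool) == 0:
        raise FitError(f"no piscivore teeth in epoch {epoch!r}")
    vals = pool["d15n_eb"].to_numpy(float)
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan
    if len(vals) == 1:
        warnings.warn(f"epoch {epoch!r}: baseline rests on a single piscivore tooth",
                      stacklevel=2)
    return float(vals.mean()), sd, len(vals)


def delta_vs_baseline(mean_d15n, sd_d15n, baseline_mean, baseline_sd):
    """Δδ15N vs. the piscivore baseline with quadrature error propagation."""
    delta = float(mean_d15n - baseline_mean)
    if np.isnan(sd_d15n) or np.isnan(baseline_sd):
        warnings.warn("missing SD on one side; Δ returned without an error",
                      stacklevel=2)
        return delta, np.nan
    return delta, float(np.hypot(sd_d15n, baseline_sd))


def trophic_offset(delta: float, tdf: float) -> float:
    """Trophic-level offset implied by a δ15N difference at a given TDF."""
    if not tdf > 0:
        raise FitError(f"TDF must be > 0, got {tdf}")
    return delta / tdf


def absolute_trophic_level(offset_levels: float, model: TDFModel) -> float:
    """Anchor trophic level plus the baseline-referenced offset."""
    return model.anchor_trophic_level + offset_levels


def diet_d15n(species_mean_eb: float, model: TDFModel) -> float:
    """Diet δ15N implied by an EB value: EB − (EB − dentin offset) − dentin TDF."""
    return species_mean_eb - model.eb_dentin_offset - model.tdf_mid


def welch_test(a, b):
    """Two-sided Welch's t-test with Welch–Satterthwaite degrees of freedom."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise FitError("Welch's t-test needs >= 2 observations per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    if va + vb == 0:
        return 0.0, float(len(a) + len(b) - 2), 1.0
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def welch_tests(teeth: pd.DataFrame, epoch: str, alpha: float = 0.05) -> pd.DataFrame:
    """Per-species Welch tests against the contemporaneous piscivore pool."""
    sub = teeth[teeth["epoch"] == epoch]
    pool = sub[sub["is_piscivore"].astype(bool)]["d15n_eb"].to_numpy(float)
    rows = []
    for species, grp in sub[~sub["is_piscivore"].astype(bool)].groupby("species"):
        vals = grp["d15n_eb"].to_numpy(float)
        if len(vals) < 2 or len(pool) < 2:
            rows.append(dict(species=species, epoch=epoch, t=np.nan, df=np.nan,
                             p=np.nan, significant=False,
                             skipped="fewer than 2 teeth on one side"))
            continue
        t, df, p = welch_test(vals, pool)
        rows.append(dict(species=species, epoch=epoch, t=t, df=df, p=p,
                         significant=bool(p < alpha), skipped=""))
    return pd.DataFrame(
        rows, columns=["species", "epoch", "t", "df", "p", "significant", "skipped"]
    )


def reconstruct(
    teeth: pd.DataFrame,
    model: TDFModel | None = None,
    tdf_values: tuple[float, ...] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full reconstruction: one row per species × epoch × TDF value.

    Requires tooth-level columns ``species, genus, epoch, is_piscivore,
    d15n_eb``.  Piscivore species are carried through (their Δ is taken
    against the pooled baseline that includes them) and flagged.
    """
    model = model or TDFModel()
    if tdf_values is None:
        lo, hi = model.tdf_range
        tdf_values = (lo, model.tdf_mid, hi)
    groups = summarize_groups(teeth)

    rows = []
    for epoch, egroups in groups.groupby("epoch", sort=False):
        base_mean, base_sd, base_n = piscivore_baseline(teeth, epoch)
        wt = welch_tests(teeth, epoch, alpha=alpha).set_index("species")
        for _, g in egroups.iterrows():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                delta, delta_sd = delta_vs_baseline(
                    g["mean_d15n"], g["sd_d15n"], base_mean, base_sd
                )
            diet = diet_d15n(g["mean_d15n"], model)
            w = wt.loc[g["species"]] if g["species"] in wt.index else None
            for tdf in tdf_values:
                off = trophic_offset(delta, tdf)
                rows.append(
                    dict(
                        species=g["species"],
                        genus=g["genus"],
                        epoch=epoch,
                        is_piscivore=bool(g["is_piscivore"]),
                        n=int(g["n"]),
                        mean_d15n=g["mean_d15n"],
                        sd_d15n=g["sd_d15n"],
                        baseline_mean=base_mean,
                        baseline_sd=base_sd,
                        baseline_n=base_n,
                        delta_vs_baseline=delta,
                        delta_sd=delta_sd,
                        tdf=tdf,
                        trophic_offset=off,
                        trophic_offset_sd=(delta_sd / tdf) if np.isfinite(delta_sd) else np.nan,
                        trophic_level=absolute_trophic_level(off, model),
                        diet_d15n=diet,
                        diet_sd=g["sd_d15n"],
                        welch_t=w["t"] if w is not None else np.nan,
                        welch_df=w["df"] if w is not None else np.nan,
                        welch_p=w["p"] if w is not None else np.nan,
                        significant=bool(w["significant"]) if w is not None else False,
                    )
                )
    return pd.DataFrame(rows)


def _corr_entry(sub: pd.DataFrame, label: str):
    sub = sub.dropna(subset=["d15n_eb", "n_content"])
    if len(sub) < 3:
        return {"label": label, "n": len(sub), "skipped": "fewer than 3 points"}
    try:
        res = pearson_test(sub["n_content"].to_numpy(), sub["d15n_eb"].to_numpy())
    except FitError as exc:
        return {"label": label, "n": len(sub), "skipped": str(exc)}
    return {
        "label": label,
        "n": res.n,
        "r": res.r,
        "t": res.t_statistic,
        "df": res.df,
        "p": res.p_two_sided,
        "significant_negative": bool(res.r < 0 and res.p_two_sided < 0.05),
    }


def diagenesis_screen(teeth: pd.DataFrame, alpha: float = 0.05) -> dict:
    """N-content preservation screen.

    Reports modern vs. fossil N-content means ± SD and the δ15N–N-content
    Pearson correlation overall (fossil), in the megatooth lineage, and in
    the fossil piscivores.  The "alteration-suspect" flag is raised only for
    a significantly *negative* correlation — the signature of organic-matter
    loss with isotopic fractionation.
    """
    if "n_content" not in teeth.columns:
        raise SchemaError("diagenesis_screen: teeth need an n_content column")
    out = {"n_content": {}, "correlations": [], "alteration_suspect": False}
    for cls, grp in teeth.groupby("preservation"):
        vals = grp["n_content"].dropna().to_numpy(float)
        out["n_content"][cls] = dict(
            mean=float(vals.mean()) if len(vals) else np.nan,
            sd=float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan,
            n=int(len(vals)),
        )
    fossil = teeth[teeth["preservation"] == "fossil"]
    subsets = {
        "fossil_overall": fossil,
        "megatooth": fossil[fossil["genus"].isin(MEGATOOTH_GENERA)],
        "piscivore": fossil[fossil["is_piscivore"].astype(bool)],
    }
    for label, sub in subsets.items():
        entry = _corr_entry(sub, label)
        out["correlations"].append(entry)
        if entry.get("significant_negative"):
            out["alteration_suspect"] = True
    return out


def baseline_consistency(teeth: pd.DataFrame, threshold: float = 3.0) -> dict:
    """Across-epoch and across-region consistency of genus-level δ15N_EB.

    For every genus sampled in ≥2 epochs (or ≥2 regions within an epoch),
    reports pairwise mean differences with Welch tests; the summary flag is
    raised when any absolute difference exceeds ``threshold`` (default 3‰).
    """
    report = {"threshold": threshold, "epoch": [], "region": [], "flagged": False}

    def compare(grp_iter, keys, section):
        groups = {k: g["d15n_eb"].to_numpy(float) for k, g in grp_iter if len(g)}
        for k1, k2 in itertools.combinations(sorted(groups), 2):
            a, b = groups[k1], groups[k2]
            diff = float(a.mean() - b.mean())
            entry = dict(**keys, group_a=k1, group_b=k2,
                         n_a=len(a), n_b=len(b), mean_diff=diff,
                         exceeds_threshold=bool(abs(diff) > threshold))
            if len(a) >= 2 and len(b) >= 2:
                t, df, p = welch_test(a, b)
                entry.update(t=t, df=df, p=p)
            report[section].append(entry)
            if entry["exceeds_threshold"]:
                report["flagged"] = True

    for genus, g in teeth.groupby("genus"):
        if g["epoch"].nunique() >= 2:
            compare(g.groupby("epoch"), dict(genus=genus), "epoch")
        for epoch, ge in g.groupby("epoch"):
            if "region" in ge.columns and ge["region"].nunique() >= 2:
                compare(ge.groupby("region"), dict(genus=genus, epoch=epoch), "region")
    return report
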