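"""Reduction of raw per-analysis isotope measurements.

A batch of analyses on the oxidation–denitrifier system is reduced in three
steps, applied in this order:

1. **Scale calibration** — a two-point line through the batch-mean measured
   values of the nitrate references IAEA-NO3 (4.7‰) and USGS34 (−1.8‰) maps
   the instrument scale onto the air scale.
2. **Blank estimation** — the oxidation blank's δ15N is the value that, under
   the mass-balance mixing model
   δ_meas = (n_s·δ_true + n_b·δ_b) / (n_s + n_b),
   minimizes squared misfit across the amino-acid references USGS40 (−4.5‰)
   and USGS65 (20.68‰); the blank size n_b is the mean of the measured blank
   analyses.
3. **Blank correction** — each sample's calibrated value is un-mixed:
   δ_s = (δ_meas·n_tot − δ_b·n_b) / (n_tot − n_b), and N content is
   (n_tot − n_b) / dissolved mass (nmol/mg ≡ μmol N/g).

In-house standard replicates run with every batch yield the QC statistics:
within-batch SD per batch, their average, and the long-term SD pooled over
all replicate values across batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AMINO_ACID_REFERENCES, NITRATE_REFERENCES
from .errors import BlankError, CalibrationError, SchemaError

#: Warn when the blank exceeds this fraction of total N in a sample analysis.
BLANK_FRACTION_WARN = 0.10


@dataclass
class CalibrationLine:
    """Linear map from the instrument δ15N scale to the air scale."""

    batch_id: str
    slope: float
    intercept: float

    def apply(self, measured):
        return self.slope * np.asarray(measured, dtype=float) + self.intercept


@dataclass
class BlankEstimate:
    batch_id: str
    blank_nmol: float
    blank_d15n: float
    no_detectable_blank: bool = False
    rms_misfit: float = np.nan


@dataclass
class QCReport:
    """Precision statistics of in-house standards, per batch and long-term."""

    per_batch: pd.DataFrame  # standard, batch_id, n, sd_d15n, sd_n_content
    summary: pd.DataFrame  # standard, avg_within_sd_*, longterm_sd_*, n_*
    warnings: list = field(default_factory=list)


def fit_calibration(refs: pd.DataFrame, batch_id: str = "") -> CalibrationLine:
    """Two-point calibration through the mean measured value of each nitrate
    reference; with replicates this equals the least-squares line through the
    two mean points.
    """
    refs = refs[refs["role"] == "nitrate_reference"]
    means = {}
    for name, cert in NITRATE_REFERENCES.items():
        vals = refs.loc[refs["specimen_id"] == name, "measured_d15n"]
        if len(vals):
            means[cert] = float(vals.mean())
    if len(means) < 2:
        raise CalibrationError(
            f"batch {batch_id or '?'}: cannot two-point calibrate — need both "
            f"nitrate references, found {len(means)}"
        )
    (c1, m1), (c2, m2) = means.items()
    if m1 == m2:
        raise CalibrationError(f"batch {batch_id or '?'}: reference means coincide")
    slope = (c1 - c2) / (m1 - m2)
    intercept = c1 - slope * m1
    return CalibrationLine(batch_id=batch_id, slope=slope, intercept=intercept)


def estimate_blank(
    aa_refs: pd.DataFrame,
    blanks: pd.DataFrame,
    batch_id: str = "",
    misfit_tol: float = 1e-9,
) -> BlankEstimate:
    """Estimate the oxidation blank's δ15N from amino-acid reference misfits.

    ``aa_refs`` must hold calibrated (air-scale) measured values with their
    certified values; ``blanks`` hold the measured blank sizes.  Solves the
    weighted least-squares problem implied by mass balance:
    δ_meas,i = (1 − f_i)·δ_true,i + f_i·δ_b with f_i = n_b / n_tot,i.
    """
    aa = aa_refs[aa_refs["role"] == "amino_acid_reference"]
    if len(aa) == 0:
        raise BlankError(f"batch {batch_id or '?'}: no amino-acid reference analyses")
    if aa["certified_d15n"].isna().any():
        raise SchemaError("amino-acid reference analyses must carry certified_d15n")

    bl = blanks[blanks["role"] == "blank"] if len(blanks) else blanks
    blank_nmol = float(bl["n_amount"].mean()) if len(bl) else 0.0

    n_amounts = aa["n_amount"].round(9).nunique()
    n_certs = aa["certified_d15n"].round(9).nunique()
    # replication at one amount and one certified value cannot separate a
    # blank from a calibration offset; a single analysis is the direct
    # mass-balance solution and is allowed
    if len(aa) > 1 and n_amounts < 2 and n_certs < 2:
        raise BlankError(
            f"batch {batch_id or '?'}: blank δ15N unidentifiable — amino-acid "
            "references span a single N amount and certified value"
        )

    if blank_nmol == 0.0:
        resid = aa["measured_d15n"] - aa["certified_d15n"]
        return BlankEstimate(batch_id, 0.0, np.nan, True, float(np.sqrt(np.mean(resid**2))))

    f = blank_nmol / aa["n_amount"].to_numpy(float)
    if np.any(f >= 1.0):
        raise BlankError(f"batch {batch_id or '?'}: blank dominates a reference analysis")
    y = aa["measured_d15n"].to_numpy(float) - (1.0 - f) * aa["certified_d15n"].to_numpy(float)
    # least squares for δ_b in y = f·δ_b
    blank_d15n = float(np.dot(f, y) / np.dot(f, f))
    resid = y - f * blank_d15n
    rms = float(np.sqrt(np.mean(resid**2)))

    # zero misfit of the uncorrected references ⇒ nothing the blank explains
    raw_misfit = aa["measured_d15n"].to_numpy(float) - aa["certified_d15n"].to_numpy(float)
    no_blank = float(np.max(np.abs(raw_misfit))) <= misfit_tol
    return BlankEstimate(batch_id, blank_nmol, blank_d15n, no_blank, rms)


def blank_correct(measured_d15n: float, total_nmol: float, blank: BlankEstimate) -> float:
    """Remove the blank contribution by mass balance.

    Re-mixing the returned value with the blank reproduces ``measured_d15n``
    to numerical precision.
    """
    n_b = blank.blank_nmol
    if n_b == 0.0 or blank.no_detectable_blank:
        return float(measured_d15n)
    if n_b >= total_nmol:
        raise BlankError(
            f"blank dominates analysis: blank {n_b} nmol >= total {total_nmol} nmol"
        )
    return float((measured_d15n * total_nmol - blank.blank_d15n * n_b) / (total_nmol - n_b))


def n_content(total_nmol: float, blank_nmol: float, dissolved_mass: float) -> float:
    """Blank-corrected N content in μmol N per g of enameloid."""
    if not dissolved_mass > 0:
        raise SchemaError(f"dissolved_mass must be > 0, got {dissolved_mass}")
    net = total_nmol - blank_nmol
    if net < 0:
        raise BlankError(
            f"blank over-subtraction: blank {blank_nmol} nmol exceeds total {total_nmol} nmol"
        )
    return net / dissolved_mass  # nmol/mg == μmol/g


def _sd(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1)) if len(x) >= 2 else np.nan


def batch_qc(standards: pd.DataFrame) -> QCReport:
    """Within-batch and long-term precision of repeated standards.

    * within-batch SD: sample SD (n−1) of the replicates in each batch;
    * average within-batch variability: mean of the per-batch SDs;
    * long-term SD: sample SD of all replicate values pooled across batches.

    The same statistics are computed for N content where dissolved mass is
    available.
    """
    std = standards[standards["role"] == "inhouse_standard"].copy()
    if len(std) == 0:
        raise SchemaError("batch_qc: no in-house standard analyses")
    if "n_content" not in std.columns:
        std["n_content"] = np.where(
            std["dissolved_mass"] > 0, std["n_amount"] / std["dissolved_mass"], np.nan
        )

    warns = []
    per_rows = []
    for (name, batch), grp in std.groupby(["specimen_id", "batch_id"]):
        per_rows.append(
            dict(
                standard=name,
                batch_id=batch,
                n=len(grp),
                sd_d15n=_sd(grp["measured_d15n"]),
                sd_n_content=_sd(grp["n_content"].dropna()),
            )
        )
    per_batch = pd.DataFrame(per_rows)

    sum_rows = []
    for name, grp in std.groupby("specimen_id"):
        pb = per_batch[per_batch["standard"] == name]
        within = pb["sd_d15n"].dropna()
        if within.empty:
            warns.append(
                f"standard {name!r}: no batch has >= 2 replicates; "
                "within-batch SD undefined"
            )
        sum_rows.append(
            dict(
                standard=name,
                n_analyses=len(grp),
                n_batches=pb.shape[0],
                avg_within_sd_d15n=float(within.mean()) if len(within) else np.nan,
                longterm_sd_d15n=_sd(grp["measured_d15n"]),
                avg_within_sd_n_content=(
                    float(pb["sd_n_content"].dropna().mean())
                    if pb["sd_n_content"].notna().any()
                    else np.nan
                ),
                longterm_sd_n_content=_sd(grp["n_content"].dropna()),
            )
        )
    report = QCReport(per_batch=per_batch, summary=pd.DataFrame(sum_rows), warnings=warns)
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return report


@dataclass
class ReductionResult:
    samples: pd.DataFrame  # one row per specimen, corrected values
    qc: QCReport
    calibrations: dict
    blanks: dict
    warnings: list


def reduce_dataset(raw: pd.DataFrame, pooled_blank: bool = False) -> ReductionResult:
    """Full reduction: calibrate, estimate and remove blanks, average replicates.

    Parameters
    ----------
    raw
        Raw analyses table (see ``paleotroph.io.RAW_COLUMNS``).
    pooled_blank
        If True, one blank δ15N pooled over all batches is applied instead of
        the per-batch estimate.
    """
    required = {"analysis_id", "batch_id", "specimen_id", "role", "measured_d15n", "n_amount"}
    missing = required - set(raw.columns)
    if missing:
        raise SchemaError(f"raw analyses: missing column(s) {sorted(missing)}")

    warns: list[str] = []
    calibrations: dict[str, CalibrationLine] = {}
    blanks: dict[str, BlankEstimate] = {}
    calibrated_parts = []

    for batch_id, grp in raw.groupby("batch_id", sort=True):
        line = fit_calibration(grp, batch_id=str(batch_id))
        calibrations[str(batch_id)] = line
        grp = grp.copy()
        # blanks record a size, not an isotope measurement on the sample scale
        grp["d15n_cal"] = line.apply(grp["measured_d15n"])
        aa = grp[grp["role"] == "amino_acid_reference"].copy()
        aa["measured_d15n"] = aa["d15n_cal"]
        bl = grp[grp["role"] == "blank"]
        blanks[str(batch_id)] = estimate_blank(aa, bl, batch_id=str(batch_id))
        calibrated_parts.append(grp)

    if pooled_blank:
        sizes = [b.blank_nmol for b in blanks.values()]
        deltas = [b.blank_d15n for b in blanks.values() if np.isfinite(b.blank_d15n)]
        pooled = BlankEstimate(
            "pooled",
            float(np.mean(sizes)) if sizes else 0.0,
            float(np.mean(deltas)) if deltas else np.nan,
            no_detectable_blank=all(b.no_detectable_blank for b in blanks.values()),
        )
        blanks = {k: pooled for k in blanks}

    cal = pd.concat(calibrated_parts, ignore_index=True)

    sample_rows = []
    samples = cal[cal["role"] == "sample"]
    for (specimen, batch_id), grp in samples.groupby(["specimen_id", "batch_id"]):
        blank = blanks[str(batch_id)]
        vals, contents, fracs = [], [], []
        for _, a in grp.iterrows():
            vals.append(blank_correct(a["d15n_cal"], a["n_amount"], blank))
            frac = blank.blank_nmol / a["n_amount"] if a["n_amount"] > 0 else np.nan
            fracs.append(frac)
            if np.isfinite(frac) and frac > BLANK_FRACTION_WARN:
                warns.append(
                    f"specimen {specimen} ({a['analysis_id']}): blank is "
                    f"{frac:.1%} of total N (> {BLANK_FRACTION_WARN:.0%})"
                )
            mass = a.get("dissolved_mass", np.nan)
            contents.append(
                n_content(a["n_amount"], blank.blank_nmol, mass)
                if np.isfinite(mass) and mass > 0
                else np.nan
            )
        vals = np.asarray(vals)
        contents = np.asarray(contents, dtype=float)
        sample_rows.append(
            dict(
                specimen_id=specimen,
                batch_id=batch_id,
                d15n_eb=float(np.mean(vals)),
                sd_d15n=_sd(vals),
                n_replicates=len(vals),
                n_content=(
                    float(np.nanmean(contents)) if np.isfinite(contents).any() else np.nan
                ),
                blank_fraction=float(np.mean(fracs)),
            )
        )

    std = cal[cal["role"] == "inhouse_standard"].copy()
    if len(std):
        corrected = []
        contents = []
        for _, a in std.iterrows():
            blank = blanks[str(a["batch_id"])]
            corrected.append(blank_correct(a["d15n_cal"], a["n_amount"], blank))
            mass = a.get("dissolved_mass", np.nan)
            contents.append(
                n_content(a["n_amount"], blank.blank_nmol, mass)
                if np.isfinite(mass) and mass > 0
                else np.nan
            )
        std["measured_d15n"] = corrected
        std["n_content"] = contents
        qc = batch_qc(std)
    else:
        qc = QCReport(per_batch=pd.DataFrame(), summary=pd.DataFrame(), warnings=[])

    for w in warns:
        warnings.warn(w, stacklevel=2)

    reduced = pd.DataFrame(sample_rows)
    if len(reduced):
        reduced = reduced.sort_values("specimen_id", ignore_index=True)
    return ReductionResult(
        samples=reduced, qc=qc, calibrations=calibrations, blanks=blanks, warnings=warns
    )
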