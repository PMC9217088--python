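"""Synthetic food webs, teeth and raw measurement batches.

The generator produces data with exactly the statistical structure the
analysis pipeline assumes, so that every downstream stage can be tested
against known ground truth:

* species dentin collagen δ15N means sit at ``baseline + (TL − 1) × TDF``;
  enameloid-bound organic N (EB) is dentin + 1.7‰, muscle is dentin + 1.9‰,
  and diet δ15N is one TDF step below dentin on the same scale,
* individual teeth scatter around the species mean with Gaussian biological
  noise, and measured values add independent Gaussian analytical noise
  (0.7‰ EB, 0.2‰ dentin by default),
* each raw analysis is a mass-balance mixture of sample N and a per-batch
  oxidation blank (0.3–0.5 nmol), pushed through a linear instrument-scale
  distortion, alongside the nitrate and amino-acid reference materials and
  in-house standard triplicates a real batch carries,
* crown heights are inverse-linear functions of true total length plus noise.

All randomness flows through :func:`numpy.random.default_rng`; a fixed config
seed yields bit-identical tables.  Columns prefixed ``true_`` are ground-truth
carriers for parameter-recovery tests and are never read by the reduction
code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    AMINO_ACID_REFERENCES,
    NITRATE_REFERENCES,
    SyntheticConfig,
)
from .errors import ConfigError

# Per-function salts so independent stages draw independent streams from one
# config seed while staying reproducible call-by-call.
_SALT_FOODWEB = 1
_SALT_RAW = 2
_SALT_CROWN = 3
_SALT_LIT = 4

#: N amounts (nmol) at which the amino-acid references are oxidized per batch.
AA_REF_SIZES_NMOL = (5.0, 12.0, 25.0, 50.0)


@dataclass
class TrueEcology:
    """Ground truth of a simulated food web (pre-noise, exact)."""

    species: pd.DataFrame  # species, genus, epoch, trophic_level, tissue means
    baseline_d15n: float
    tdf_per_level: float
    eb_dentin_offset: float
    dentin_muscle_offset: float


def _rng(config: SyntheticConfig, salt: int, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng([int(config.seed), salt])


def simulate_foodweb(config: SyntheticConfig, rng=None):
    """Simulate species tissue means and per-tooth records.

    Returns ``(TrueEcology, teeth)`` where ``teeth`` is one row per tooth with
    the true (pre-measurement) enameloid-bound δ15N, a directly observed
    ``d15n_eb`` (true + analytical noise), dentin collagen δ15N for modern
    teeth, and a true N content drawn by preservation class.
    """
    config.validate()
    rng = _rng(config, _SALT_FOODWEB, rng)

    sp_rows = []
    tooth_rows = []
    tooth_idx = 0
    for sp in config.species_list:
        # dentin collagen carries the trophic chain; EB and muscle are fixed
        # offsets from it, and diet is one TDF step down the same scale, so
        # the EB − offset − TDF diet estimator is exact pre-noise.
        dentin = config.baseline_d15n + (sp.trophic_level - 1.0) * config.tdf_per_level
        muscle = dentin + config.dentin_muscle_offset
        eb = dentin + config.eb_dentin_offset
        diet = dentin - config.tdf_per_level
        sp_rows.append(
            dict(
                species=sp.name,
                genus=sp.genus,
                epoch=sp.epoch,
                trophic_level=sp.trophic_level,
                is_piscivore=sp.is_piscivore,
                d15n_muscle=muscle,
                d15n_eb=eb,
                d15n_dentin=dentin,
                d15n_diet=diet,
            )
        )
        preservation = "modern" if sp.epoch == "Modern" else "fossil"
        nc_mean = config.n_content_mean[preservation]
        nc_sd = config.n_content_sd[preservation]
        for i in range(sp.n_teeth):
            region = sp.regions[i % len(sp.regions)]
            shift = config.region_shifts.get(region, 0.0)
            eb_true = eb + shift + rng.normal(0.0, config.biological_sd)
            eb_obs = eb_true + rng.normal(0.0, config.meas_sd_eb)
            dentin_true = eb_true - config.eb_dentin_offset
            dentin_obs = (
                dentin_true + rng.normal(0.0, config.meas_sd_dentin)
                if preservation == "modern"
                else np.nan
            )
            # truncate N content away from zero; mild, rarely binding
            n_content = max(rng.normal(nc_mean, nc_sd), 0.5)
            tooth_idx += 1
            tooth_rows.append(
                dict(
                    specimen_id=f"T{tooth_idx:04d}",
                    species=sp.name,
                    genus=sp.genus,
                    epoch=sp.epoch,
                    region=region,
                    is_piscivore=sp.is_piscivore,
                    preservation=preservation,
                    true_trophic_level=sp.trophic_level,
                    true_d15n_eb=eb_true,
                    d15n_eb=eb_obs,
                    d15n_dentin=dentin_obs,
                    true_n_content=n_content,
                    crown_height=np.nan,
                    tooth_position="",
                    true_total_length=np.nan,
                )
            )

    ecology = TrueEcology(
        species=pd.DataFrame(sp_rows),
        baseline_d15n=config.baseline_d15n,
        tdf_per_level=config.tdf_per_level,
        eb_dentin_offset=config.eb_dentin_offset,
        dentin_muscle_offset=config.dentin_muscle_offset,
    )
    return ecology, pd.DataFrame(tooth_rows)


def _to_instrument(d15n_air, config: SyntheticConfig):
    """Invert the calibration line air = slope·inst + intercept."""
    return (np.asarray(d15n_air, dtype=float) - config.cal_intercept) / config.cal_slope


def simulate_raw_batch(teeth: pd.DataFrame, config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Turn tooth records into raw per-analysis measurement batches.

    Teeth are grouped into batches of ``config.batch_size``.  Every batch
    carries duplicate nitrate references, amino-acid references at N amounts
    spanning 5–50 nmol (blank-affected, like the samples), one blank-size
    analysis, and in-house standard triplicates with a batch-level cleaning
    effect.  Sample analyses mix sample N (dissolved mass × true N content)
    with the batch oxidation blank by exact mass balance before instrument
    distortion and analytical noise.
    """
    if len(teeth) == 0:
        raise ConfigError("simulate_raw_batch: empty tooth list")
    if "true_d15n_eb" not in teeth.columns:
        raise ConfigError("simulate_raw_batch: teeth must carry true_d15n_eb")
    config.validate()
    rng = _rng(config, _SALT_RAW, rng)

    rows = []
    counter = 0

    def add(batch_id, specimen_id, role, d15n_air_true, n_sample, n_blank,
            blank_d15n, noise_sd, dissolved_mass=np.nan, certified=np.nan):
        nonlocal counter
        counter += 1
        n_total = n_sample + n_blank
        mix = (
            (n_sample * d15n_air_true + n_blank * blank_d15n) / n_total
            if n_total > 0
            else np.nan
        )
        measured_air = mix + rng.normal(0.0, noise_sd)
        rows.append(
            dict(
                analysis_id=f"A{counter:05d}",
                batch_id=batch_id,
                specimen_id=specimen_id,
                role=role,
                measured_d15n=float(_to_instrument(measured_air, config)),
                n_amount=n_total,
                dissolved_mass=dissolved_mass,
                certified_d15n=certified,
                true_component_d15n=d15n_air_true,
                true_n_sample_nmol=n_sample,
                true_n_blank_nmol=n_blank,
                true_mix_d15n=mix,
            )
        )

    n_batches = int(np.ceil(len(teeth) / config.batch_size))
    blo, bhi = config.blank_nmol_range
    for b in range(n_batches):
        batch_id = f"B{b + 1:03d}"
        chunk = teeth.iloc[b * config.batch_size : (b + 1) * config.batch_size]
        n_blank = float(rng.uniform(blo, bhi)) if bhi > 0 else 0.0

        # Nitrate references calibrate the denitrifier/mass-spec step only:
        # they bypass the oxidation, hence carry no blank.
        for name, cert in NITRATE_REFERENCES.items():
            for _ in range(2):
                add(batch_id, name, "nitrate_reference", cert, 20.0, 0.0,
                    config.blank_d15n, config.ref_meas_sd, certified=cert)

        # Amino-acid references are oxidized with the samples → blank-mixed.
        for name, cert in AMINO_ACID_REFERENCES.items():
            for size in AA_REF_SIZES_NMOL:
                add(batch_id, name, "amino_acid_reference", cert, size, n_blank,
                    config.blank_d15n, config.ref_meas_sd, certified=cert)

        # The blank analysis records the measured size of the oxidation blank.
        add(batch_id, "oxidation-blank", "blank", config.blank_d15n, 0.0, n_blank,
            config.blank_d15n, config.ref_meas_sd)

        # In-house enameloid standard triplicates, with batch cleaning effect.
        batch_shift = rng.normal(0.0, config.standard_between_sd)
        nc_shift = rng.normal(0.0, config.standard_ncontent_between_sd)
        for _ in range(3):
            true = (
                config.standard_true_d15n
                + batch_shift
                + rng.normal(0.0, config.standard_within_sd)
            )
            mass = 3.0
            content = (
                config.standard_n_content
                + nc_shift
                + rng.normal(0.0, config.standard_ncontent_within_sd)
            )
            add(batch_id, "enameloid-standard", "inhouse_standard", true,
                mass * max(content, 0.5), n_blank, config.blank_d15n, 0.0,
                dissolved_mass=mass)

        # Samples: replicate analyses of each tooth in the chunk.
        mlo, mhi = config.dissolved_mass_range_mg
        for _, tooth in chunk.iterrows():
            for _ in range(config.replicates_per_sample):
                mass = float(rng.uniform(mlo, mhi))
                n_sample = mass * float(tooth["true_n_content"])
                add(batch_id, tooth["specimen_id"], "sample",
                    float(tooth["true_d15n_eb"]), n_sample, n_blank,
                    config.blank_d15n, config.meas_sd_eb, dissolved_mass=mass)

    return pd.DataFrame(rows)


def simulate_crown_heights(
    teeth: pd.DataFrame,
    config: SyntheticConfig,
    rng=None,
    species: str = "Otodus megalodon",
    n_teeth: int | None = None,
) -> pd.DataFrame:
    """Assign true total lengths, tooth positions and noisy crown heights.

    Target teeth (by default the first ``length_sim.n_teeth_with_heights``
    teeth of *Otodus megalodon*) receive a true length from a truncated
    normal, a position class cycling through the configured length functions,
    and a crown height obtained by inverting L = intercept + slope × CH and
    adding Gaussian noise.  Returns an updated copy of ``teeth``.
    """
    config.validate()
    ls = config.length_sim
    rng = _rng(config, _SALT_CROWN, rng)

    teeth = teeth.copy()
    mask = teeth["species"] == species if species else np.ones(len(teeth), dtype=bool)
    idx = teeth.index[mask]
    if n_teeth is None:
        n_teeth = ls.n_teeth_with_heights
    idx = idx[:n_teeth]
    if len(idx) == 0:
        raise ConfigError(f"simulate_crown_heights: no teeth for species {species!r}")

    classes = sorted(ls.functions)
    lo, hi = ls.true_length_bounds
    for k, i in enumerate(idx):
        cls = classes[k % len(classes)]
        slope, intercept = ls.functions[cls]
        length = float(np.clip(rng.normal(ls.true_length_mean, ls.true_length_sd), lo, hi))
        ch = (length - intercept) / slope + rng.normal(0.0, ls.crown_height_noise_sd)
        teeth.loc[i, "true_total_length"] = length
        teeth.loc[i, "crown_height"] = ch
        teeth.loc[i, "tooth_position"] = cls
    return teeth


def extract_tissue_pairs(teeth: pd.DataFrame, species: str = "Carcharias taurus") -> pd.DataFrame:
    """Paired EB / dentin collagen δ15N for modern teeth of one species."""
    sub = teeth[(teeth["species"] == species) & teeth["d15n_dentin"].notna()]
    return sub[["specimen_id", "d15n_eb", "d15n_dentin"]].reset_index(drop=True)


# Family-level centers for the synthetic literature compilation (‰).  These
# emulate the shape of modern shark / marine-mammal δ15N compilations: most
# taxa between 10 and 18‰, eared seals and polar bears reaching the low 20s.
_LIT_FAMILIES = {
    "shark": {
        "Carcharhinidae": 13.5,
        "Lamnidae": 16.5,
        "Carchariidae": 15.8,
        "Sphyrnidae": 13.0,
        "Triakidae": 12.0,
    },
    "marine_mammal": {
        "Otariidae": 20.5,
        "Phocidae": 17.5,
        "Delphinidae": 16.5,
        "Ursidae": 21.8,
        "Balaenopteridae": 12.0,
        "Balaenidae": 13.5,
        "Physeteridae": 16.0,
    },
}


def simulate_literature(config: SyntheticConfig, rng=None, obs_per_family: int = 6) -> pd.DataFrame:
    """Synthetic literature δ15N observation table (group, family, mean, SD, n)."""
    rng = _rng(config, _SALT_LIT, rng)
    rows = []
    for group, families in _LIT_FAMILIES.items():
        for family, center in families.items():
            for j in range(obs_per_family):
                mean = center + rng.normal(0.0, 1.5)
                n = int(rng.integers(1, 30))
                sd = float(rng.uniform(0.3, 1.5)) if n > 1 else np.nan
                rows.append(
                    dict(
                        group=group,
                        family=family,
                        species=f"{family.lower()}_sp{j + 1}",
                        tissue="muscle" if group == "shark" else "skin",
                        mean_d15n=mean,
                        sd_d15n=sd,
                        n_individuals=n,
                    )
                )
    return pd.DataFrame(rows)
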