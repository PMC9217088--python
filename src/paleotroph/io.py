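"""Tabular I/O: documented CSV schemas, validating readers, stable writers.

All files are comma-separated, UTF-8, "." decimal, with a mandatory header
row.  Readers reject missing columns and unknown enum values with messages
naming the file and column; writers emit a fixed float format so that a
fixed-seed pipeline run is byte-reproducible.  ``SCHEMAS`` is the shipped
machine-readable schema (column → description with units); see also
docs/schemas.md.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import EPOCHS, ROLES
from .errors import SchemaError

FLOAT_FORMAT = "%.9g"

SCHEMAS: dict[str, dict[str, str]] = {
    "teeth": {
        "specimen_id": "unique tooth identifier",
        "species": "binomial or open-nomenclature species name",
        "genus": "genus name",
        "epoch": f"one of {', '.join(EPOCHS)}",
        "region": "broad collecting region label",
        "is_piscivore": "bool; True for fish-eating baseline taxa",
        "preservation": "modern | fossil",
        "d15n_eb": "enameloid-bound organic matter d15N, permil vs. air",
        "d15n_dentin": "dentin collagen d15N, permil vs. air (modern teeth; may be empty)",
        "n_content": "enameloid N content, umol N per g (may be empty pre-reduction)",
        "crown_height": "tooth crown height, cm (optional)",
        "tooth_position": "position label, e.g. U, L, L2, l2 (optional)",
    },
    "raw_analyses": {
        "analysis_id": "unique analysis identifier",
        "batch_id": "measurement batch identifier",
        "specimen_id": "tooth specimen id, or reference/standard name",
        "role": f"one of {', '.join(ROLES)}",
        "measured_d15n": "measured d15N on the instrument scale, permil",
        "n_amount": "total N in the analysis, nmol",
        "dissolved_mass": "dissolved enameloid mass, mg (samples/standards)",
        "certified_d15n": "certified d15N, permil vs. air (references only)",
    },
    "reduced": {
        "specimen_id": "tooth specimen id",
        "batch_id": "measurement batch identifier",
        "d15n_eb": "calibrated, blank-corrected d15N_EB, permil vs. air",
        "sd_d15n": "SD over replicate analyses, permil (empty if n=1)",
        "n_replicates": "number of replicate analyses averaged",
        "n_content": "blank-corrected N content, umol N per g",
        "blank_fraction": "blank share of total N in the analysis",
    },
    "pairs": {
        "specimen_id": "tooth specimen id",
        "d15n_eb": "enameloid-bound d15N, permil vs. air",
        "d15n_dentin": "dentin collagen d15N, permil vs. air",
    },
    "literature": {
        "group": "shark | marine_mammal",
        "family": "taxonomic family",
        "species": "species name",
        "tissue": "tissue type of the observation",
        "mean_d15n": "observation mean d15N, permil vs. air",
        "sd_d15n": "observation SD, permil (empty when n=1)",
        "n_individuals": "number of individuals behind the observation",
    },
    "length_functions": {
        "position_class": "tooth position class label (e.g. U, L, L2, l2)",
        "slope": "m total length per cm crown height",
        "intercept": "m",
        "source": "provenance tag for the coefficients",
    },
}

_ENUMS = {
    ("teeth", "epoch"): set(EPOCHS),
    ("teeth", "preservation"): {"modern", "fossil"},
    ("raw_analyses", "role"): set(ROLES),
    ("literature", "group"): {"shark", "marine_mammal"},
}

# columns that may be absent entirely (written by later stages)
_OPTIONAL = {
    ("teeth", "d15n_dentin"),
    ("teeth", "n_content"),
    ("teeth", "crown_height"),
    ("teeth", "tooth_position"),
    ("teeth", "region"),
    ("raw_analyses", "dissolved_mass"),
    ("raw_analyses", "certified_d15n"),
    ("literature", "sd_d15n"),
    ("literature", "tissue"),
    ("literature", "species"),
    ("length_functions", "source"),
    ("reduced", "batch_id"),
    ("reduced", "blank_fraction"),
}


def validate_table(df: pd.DataFrame, schema: str, source: str = "<frame>") -> pd.DataFrame:
    """Check required columns and enum values for a named schema."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    for col in SCHEMAS[schema]:
        if col not in df.columns and (schema, col) not in _OPTIONAL:
            raise SchemaError(f"{source}: missing required column {col!r} ({schema} schema)")
    for (sch, col), allowed in _ENUMS.items():
        if sch != schema or col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = sorted(set(vals.astype(str)) - {str(a) for a in allowed})
        if bad:
            raise SchemaError(
                f"{source}: column {col!r} has unknown value(s) {bad}; "
                f"expected one of {sorted(str(a) for a in allowed)}"
            )
    return df


def read_table(path, schema: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path)
    return validate_table(df, schema, source=str(path))


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> Path:
    """Write a CSV with the package's stable dialect (sorted by nothing;
    callers fix row order).  Validates against ``schema`` when given."""
    path = Path(path)
    if schema is not None:
        validate_table(df, schema, source=str(path))
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable({k: getattr(obj, k) for k in obj.__dataclass_fields__})
    return obj


def write_json(obj, path) -> Path:
    """Deterministic JSON dump (sorted keys, NaN → null)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
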