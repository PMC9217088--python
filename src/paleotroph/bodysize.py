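"""Body-length estimation from tooth crown height.

Total length is estimated with position-specific linear functions
L = intercept + slope × CH (L in m, CH in cm).  When a tooth's position
cannot be pinned to a single function — the common case for mesially located
lateral teeth of fragmentary fossils — the *most conservative* candidate is
used: the function yielding the smallest length at that crown height, with
ties broken deterministically by position-class name.

The numeric coefficients of the published crown-height regressions are not
bundled; they are configuration data (``length_functions.csv``).  The
defaults shipped for testing are synthetic placeholders and tagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError, SchemaError
from .tissue import CorrelationResult, pearson_test


@dataclass(frozen=True)
class LengthFunction:
    """Linear crown-height → total-length model for one tooth position."""

    position_class: str
    slope: float  # m per cm of crown height
    intercept: float  # m
    source: str = ""

    def __post_init__(self):
        if not self.slope > 0:
            raise FitError(
                f"length function {self.position_class!r}: slope must be > 0"
            )


@dataclass
class LengthEstimate:
    specimen_id: str
    position_class: str
    crown_height: float  # cm
    total_length: float  # m


def select_length_function(
    position_label: str,
    candidates: list[LengthFunction],
    crown_height: float,
) -> LengthFunction:
    """Pick the function for a tooth position.

    An exact ``position_class`` match wins.  Otherwise the label is treated
    as ambiguous among all supplied candidates and the conservative rule
    applies: the candidate giving the smallest length at ``crown_height``;
    exact ties fall to the lexicographically first class name.
    """
    if not candidates:
        raise FitError("no candidate length functions supplied")
    for fn in candidates:
        if fn.position_class == position_label:
            return fn
    known = sorted(fn.position_class for fn in candidates)
    if crown_height is None or not np.isfinite(crown_height):
        raise FitError(
            f"position {position_label!r} matches no class exactly "
            f"(known: {known}) and no crown height was given for the "
            "conservative rule"
        )
    return min(
        candidates,
        key=lambda fn: (estimate_length(crown_height, fn), fn.position_class),
    )


def estimate_length(crown_height: float, fn: LengthFunction) -> float:
    """Total length (m) from crown height (cm): intercept + slope × CH."""
    if not crown_height > 0:
        raise FitError(f"crown height must be > 0, got {crown_height}")
    length = fn.intercept + fn.slope * crown_height
    if length <= 0:
        raise FitError(
            f"function {fn.position_class!r} yields nonpositive length "
            f"{length:.3f} m at CH {crown_height} cm"
        )
    return float(length)


def estimate_lengths(teeth: pd.DataFrame, functions: list[LengthFunction]) -> pd.DataFrame:
    """Apply position-aware length estimation to every tooth with a crown height."""
    needed = {"specimen_id", "crown_height"}
    if missing := needed - set(teeth.columns):
        raise SchemaError(f"estimate_lengths: missing column(s) {sorted(missing)}")
    rows = []
    for _, t in teeth.iterrows():
        ch = t["crown_height"]
        if not np.isfinite(ch):
            continue
        label = t.get("tooth_position", "") or ""
        fn = select_length_function(label, functions, ch)
        rows.append(
            dict(
                specimen_id=t["specimen_id"],
                position_class=fn.position_class,
                crown_height=float(ch),
                total_length=estimate_length(float(ch), fn),
            )
        )
    return pd.DataFrame(rows, columns=["specimen_id", "position_class", "crown_height", "total_length"])


def summarize_lengths(estimates: pd.DataFrame) -> dict:
    """Range, mean and sample SD of the estimated total lengths."""
    if len(estimates) == 0:
        raise FitError("summarize_lengths: no estimates")
    v = estimates["total_length"].to_numpy(float)
    return dict(
        n=int(len(v)),
        min=float(v.min()),
        max=float(v.max()),
        mean=float(v.mean()),
        sd=float(np.std(v, ddof=1)) if len(v) >= 2 else np.nan,
    )


def length_isotope_correlation(
    estimates: pd.DataFrame, teeth: pd.DataFrame
) -> CorrelationResult | None:
    """Pearson correlation between estimated total length and δ15N_EB.

    Returns ``None`` (skipped) when fewer than 3 joined records exist.
    """
    joined = estimates.merge(teeth[["specimen_id", "d15n_eb"]], on="specimen_id")
    joined = joined.dropna(subset=["total_length", "d15n_eb"])
    if len(joined) < 3:
        return None
    return pearson_test(
        joined["total_length"].to_numpy(float), joined["d15n_eb"].to_numpy(float)
    )


def functions_from_frame(df: pd.DataFrame) -> list[LengthFunction]:
    """Build LengthFunction objects from a coefficients table."""
    needed = {"position_class", "slope", "intercept"}
    if missing := needed - set(df.columns):
        raise SchemaError(f"length functions: missing column(s) {sorted(missing)}")
    return [
        LengthFunction(
            position_class=str(r["position_class"]),
            slope=float(r["slope"]),
            intercept=float(r["intercept"]),
            source=str(r.get("source", "")),
        )
        for _, r in df.iterrows()
    ]
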