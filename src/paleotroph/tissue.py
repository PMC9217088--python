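"""Ground-truthing of enameloid-bound δ15N against dentin collagen δ15N.

Paired measurements on modern teeth are compared three ways:

* an errors-in-variables (Deming) regression of EB on dentin collagen, with
  the error-variance ratio fixed from the two analytical SDs (default SD
  ratio 3.5 = 0.7‰/0.2‰, i.e. variance ratio 12.25) and percentile
  case-resampling bootstrap confidence intervals;
* a Pearson correlation with its exact t-test;
* the mean ± SD tissue offset (EB − dentin).

The Deming slope minimizes Σ (y − a − bx)² / (λ + b²), λ = (σ_y/σ_x)², which
has the closed form b = [s_yy − λ s_xx + √((s_yy − λ s_xx)² + 4 λ s_xy²)] /
(2 s_xy).  In the λ → ∞ limit (error only on the EB axis) it reduces to the
ordinary least-squares fit of EB on dentin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError


def _extract_xy(pairs, x_col="d15n_dentin", y_col="d15n_eb"):
    if isinstance(pairs, pd.DataFrame):
        x = pairs[x_col].to_numpy(float)
        y = pairs[y_col].to_numpy(float)
    else:
        arr = np.asarray(pairs, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise FitError("tissue pairs contain non-finite values")
    return x, y


@dataclass
class DemingFit:
    slope: float
    intercept: float
    slope_ci_95: tuple[float, float]
    intercept_ci_95: tuple[float, float]
    error_sd_ratio: float
    n_bootstrap: int
    seed: int
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class CorrelationResult:
    r: float
    t_statistic: float
    df: int
    p_two_sided: float
    n: int


@dataclass
class OffsetSummary:
    mean_offset: float
    sd_offset: float
    n: int


def deming_slope_intercept(x, y, lam):
    """Closed-form Deming estimates for error-variance ratio ``lam`` (y:x)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = np.mean((x - xm) ** 2)
    syy = np.mean((y - ym) ** 2)
    sxy = np.mean((x - xm) * (y - ym))
    if sxx == 0:
        raise FitError("Deming slope undefined: all x values identical")
    if sxy == 0:
        slope = 0.0
    else:
        d = syy - lam * sxx
        slope = (d + np.sqrt(d * d + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)
    return slope, ym - slope * xm


def _boot_slopes(x, y, lam, n_boot, rng):
    """Vectorized case-resampling bootstrap of the Deming fit."""
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    yb = y[idx]
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    sxx = np.mean((xb - xm) ** 2, axis=1)
    syy = np.mean((yb - ym) ** 2, axis=1)
    sxy = np.mean((xb - xm) * (yb - ym), axis=1)
    d = syy - lam * sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (d + np.sqrt(d * d + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)
    slope = np.where(sxy == 0, 0.0, slope)
    slope = np.where(sxx == 0, np.nan, slope)  # degenerate resample
    intercept = ym.ravel() - slope * xm.ravel()
    return slope, intercept


def deming_fit(
    pairs,
    error_sd_ratio: float = 3.5,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    ratio_is_variance: bool = False,
) -> DemingFit:
    """Bootstrapped Deming regression of EB (y) on dentin collagen (x).

    Parameters
    ----------
    pairs
        DataFrame with ``d15n_dentin`` / ``d15n_eb`` columns, or an (n, 2)
        array of (x, y) pairs.
    error_sd_ratio
        Ratio of analytical SDs, y-axis : x-axis (default 3.5 = 0.7/0.2).
        The Deming variance-ratio parameter is its square unless
        ``ratio_is_variance`` is set, in which case the value is used as the
        variance ratio directly.
    """
    x, y = _extract_xy(pairs)
    if len(x) < 3:
        raise FitError(f"Deming regression needs >= 3 pairs, got {len(x)}")
    if not error_sd_ratio > 0:
        raise FitError("error_sd_ratio must be > 0")
    if n_bootstrap < 100:
        warnings.warn(
            f"n_bootstrap={n_bootstrap} < 100 gives unreliable CIs", stacklevel=2
        )
    lam = error_sd_ratio if ratio_is_variance else error_sd_ratio**2

    slope, intercept = deming_slope_intercept(x, y, lam)

    rng = np.random.default_rng(seed)
    slopes, intercepts = _boot_slopes(x, y, lam, n_bootstrap, rng)
    ok = np.isfinite(slopes)
    s_ci = tuple(np.percentile(slopes[ok], [2.5, 97.5]))
    i_ci = tuple(np.percentile(intercepts[ok], [2.5, 97.5]))
    return DemingFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_ci_95=(float(s_ci[0]), float(s_ci[1])),
        intercept_ci_95=(float(i_ci[0]), float(i_ci[1])),
        error_sd_ratio=error_sd_ratio,
        n_bootstrap=n_bootstrap,
        seed=seed,
        n=len(x),
    )


def t_from_r(r: float, n: int) -> float:
    """Exact t-statistic of a Pearson correlation: t = r·√((n−2)/(1−r²))."""
    if abs(r) >= 1.0:
        return float(np.inf) if r > 0 else float(-np.inf)
    return float(r * np.sqrt((n - 2) / (1.0 - r * r)))


def pearson_test(pairs, y=None) -> CorrelationResult:
    """Pearson product-moment correlation with its two-sided t-test.

    Accepts a tissue-pair DataFrame (dentin as x, EB as y), an (n, 2) array,
    or two separate arrays.
    """
    if y is not None:
        x = np.asarray(pairs, float)
        y = np.asarray(y, float)
    else:
        x, y = _extract_xy(pairs)
    n = len(x)
    if n < 3:
        raise FitError(f"Pearson test needs >= 3 pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise FitError("Pearson correlation undefined: zero variance on an axis")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if 1.0 - abs(r) < 1e-12:  # numerically perfect correlation
        r = float(np.sign(r))
    t = t_from_r(r, n)
    p = 0.0 if np.isinf(t) else float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, t_statistic=t, df=df, p_two_sided=p, n=n)


def tissue_offset(pairs) -> OffsetSummary:
    """Mean and sample SD of the per-pair offset EB − dentin collagen."""
    x, y = _extract_xy(pairs)
    if len(x) == 0:
        raise FitError("tissue_offset needs at least one pair")
    diff = y - x
    sd = float(np.std(diff, ddof=1)) if len(diff) >= 2 else np.nan
    return OffsetSummary(mean_offset=float(np.mean(diff)), sd_offset=sd, n=len(diff))
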