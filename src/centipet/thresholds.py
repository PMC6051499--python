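"""Amyloid-positivity threshold estimators.

Three estimators are provided for one quantification method at a time:

1. conversion of a legacy native-unit threshold through the method's CL
   equation,
2. the specificity threshold — an upper percentile (default 95th) of the
   young-control CL distribution, and
3. a modified reliable-worsening (RW) rule — the first integer CL at which
   the LOESS-smoothed annualized-rate-versus-baseline curve rises strictly
   above zero after passing its minimum, with bootstrap uncertainty bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .calibrate import ConversionEquation, apply_equation
from .errors import InsufficientDataError, ParameterError

__all__ = [
    "LongitudinalPair",
    "LoessRateCurve",
    "ThresholdSet",
    "ThresholdConfig",
    "convert_native_threshold",
    "specificity_threshold",
    "annualized_rate",
    "loess_rate_curve",
    "rw_threshold",
    "build_threshold_set",
]


@dataclass(frozen=True)
class LongitudinalPair:
    """Baseline/follow-up CL measurement pair for one subject."""

    subject_id: str
    baseline_cl: float
    followup_cl: float
    interval: float

    def __post_init__(self) -> None:
        if not self.interval > 0:
            raise ParameterError(f"interval must be > 0, got {self.interval}")


def pairs_from_frame(df: pd.DataFrame) -> list:
    """Build LongitudinalPair objects from a cohort table with columns
    subject_id, baseline_cl, followup_cl, interval."""
    return [
        LongitudinalPair(str(r.subject_id), float(r.baseline_cl), float(r.followup_cl), float(r.interval))
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class LoessRateCurve:
    """Smoothed annualized-rate curve on an integer CL grid.

    Unsupported grid points (outside the data range of a given fit) are NaN,
    never extrapolated.  ``boot_fits`` holds the per-resample fitted curves
    (n_boot x n_grid) used for the bands and the RW bootstrap.
    """

    grid: np.ndarray
    fitted_rate: np.ndarray
    lower_band: np.ndarray
    upper_band: np.ndarray
    span: float
    n_boot: int
    ci_level: float
    boot_fits: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=int)
        if g.size < 2 or np.any(np.diff(g) <= 0):
            raise ParameterError("grid must be strictly increasing integers")
        if not 0 < self.span <= 1:
            raise ParameterError("span must lie in (0, 1]")
        object.__setattr__(self, "grid", g)
        for name in ("fitted_rate", "lower_band", "upper_band"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size != g.size:
                raise ParameterError(f"{name} must match grid length")
            object.__setattr__(self, name, v)

    @property
    def supported(self) -> np.ndarray:
        return ~np.isnan(self.fitted_rate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid_cl": self.grid,
                "fitted_rate": self.fitted_rate,
                "lower_band": self.lower_band,
                "upper_band": self.upper_band,
            }
        )


@dataclass(frozen=True)
class ThresholdSet:
    """All three positivity thresholds (CL) for one method."""

    method_label: str
    specificity_cl: float
    rw_cl: Optional[int]
    empirical_cl: Optional[float] = None
    rw_band: Optional[tuple] = None

    def to_dict(self) -> dict:
        return {
            "method_label": self.method_label,
            "empirical_cl": self.empirical_cl,
            "specificity_cl": self.specificity_cl,
            "rw_cl": self.rw_cl,
            "rw_band": list(self.rw_band) if self.rw_band is not None else None,
        }


@dataclass(frozen=True)
class ThresholdConfig:
    """Settings shared by the three estimators."""

    span: float = 0.75
    n_boot: int = 1000
    ci_level: float = 0.95
    percentile: float = 0.95
    native_threshold: Optional[float] = None
    grid_min: Optional[int] = None
    grid_max: Optional[int] = None
    seed: int = 0


def convert_native_threshold(eq: ConversionEquation, native_threshold: float) -> float:
    """Convert a legacy native-unit positivity threshold to CL."""
    return float(apply_equation(eq, float(native_threshold)))


def specificity_threshold(yc_values_cl, percentile: float = 0.95) -> float:
    """Upper percentile of the young-control CL distribution.

    Uses linear interpolation between order statistics (the ``linear``
    quantile rule: at probability p the value sits at rank 1 + p*(n-1)).
    """
    vals = np.asarray(yc_values_cl, dtype=float)
    if vals.size < 5:
        raise InsufficientDataError(f"specificity threshold needs n >= 5, got {vals.size}")
    if not 0 < percentile < 1:
        raise ParameterError("percentile must lie in (0, 1)")
    return float(np.quantile(vals, percentile, method="linear"))


def annualized_rate(pair: LongitudinalPair) -> float:
    """(follow-up − baseline) / interval, in CL/yr."""
    return (pair.followup_cl - pair.baseline_cl) / pair.interval


def _loess_at(x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float) -> np.ndarray:
    """Locally-linear tricube LOESS evaluated at grid points; NaN outside
    the support of (x, y)."""
    out = np.full(grid.size, np.nan)
    inside = (grid >= x.min()) & (grid <= x.max())
    if np.any(inside):
        out[inside] = lowess(
            y, x, frac=span, it=0, xvals=grid[inside].astype(float)
        )
    return out


def loess_rate_curve(
    pairs: Sequence[LongitudinalPair],
    span: float = 0.75,
    grid_min: Optional[int] = None,
    grid_max: Optional[int] = None,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> LoessRateCurve:
    """LOESS fit of annualized rate against baseline CL on an integer grid.

    Parameters
    ----------
    pairs
        Longitudinal measurement pairs (>= 20 required).
    span
        LOESS span (fraction of points in each local fit), tricube weights,
        locally linear.
    grid_min, grid_max
        Integer CL grid bounds; default to the central 98% of baseline
        values (1st and 99th percentiles, rounded inward) to avoid
        edge-dominated fits.
    n_boot, ci_level, seed
        Subjects are resampled with replacement ``n_boot`` times; bands are
        pointwise percentile intervals at ``ci_level``.

    Grid points outside the support of the data (or of a resample) are NaN.
    """
    if len(pairs) < 20:
        raise InsufficientDataError(f"LOESS curve needs >= 20 pairs, got {len(pairs)}")
    x = np.array([p.baseline_cl for p in pairs])
    y = np.array([annualized_rate(p) for p in pairs])
    if grid_min is None:
        grid_min = int(np.ceil(np.quantile(x, 0.01)))
    if grid_max is None:
        grid_max = int(np.floor(np.quantile(x, 0.99)))
    if not grid_min < grid_max:
        raise ParameterError(f"grid_min ({grid_min}) must be < grid_max ({grid_max})")
    grid = np.arange(grid_min, grid_max + 1)

    fitted = _loess_at(x, y, grid, span)
    boot = np.full((n_boot, grid.size), np.nan)
    rng = np.random.default_rng(seed)
    n = x.size
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[b] = _loess_at(x[idx], y[idx], grid, span)
    alpha = 1.0 - ci_level
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN columns
        lower = np.nanpercentile(boot, 100 * alpha / 2, axis=0)
        upper = np.nanpercentile(boot, 100 * (1 - alpha / 2), axis=0)
    return LoessRateCurve(
        grid=grid,
        fitted_rate=fitted,
        lower_band=lower,
        upper_band=upper,
        span=span,
        n_boot=n_boot,
        ci_level=ci_level,
        boot_fits=boot,
    )


def _rw_from_arrays(grid: np.ndarray, fitted: np.ndarray, warn: bool = False) -> Optional[int]:
    supported = ~np.isnan(fitted)
    if np.count_nonzero(supported) < 3:
        return None
    m = int(np.nanargmin(fitted))
    if fitted[m] > 0:
        if warn:
            warnings.warn(
                "rate curve is positive at its minimum; returning the left-most "
                "supported grid point",
                UserWarning,
                stacklevel=3,
            )
        return int(grid[m])
    after = np.arange(m, grid.size)
    positive = after[(~np.isnan(fitted[after])) & (fitted[after] > 0)]
    if positive.size == 0:
        if warn:
            warnings.warn(
                "rate curve never rises above zero after its minimum; no reliable-"
                "worsening threshold",
                UserWarning,
                stacklevel=3,
            )
        return None
    return int(grid[positive[0]])


def rw_threshold(curve: LoessRateCurve) -> Optional[int]:
    """Modified reliable-worsening threshold.

    Finds the grid index of the minimum fitted rate and returns the smallest
    grid CL at or after it with a strictly positive fitted rate.  If the
    minimum itself is positive the curve is positive everywhere after it, so
    the minimum's grid point is returned (with a warning).  Returns None
    (with a warning) when the curve never rises above zero after its
    minimum — the returned threshold therefore always carries a positive
    accumulation rate.
    """
    if np.count_nonzero(curve.supported) < 3:
        raise InsufficientDataError("RW threshold needs >= 3 supported grid points")
    return _rw_from_arrays(curve.grid, curve.fitted_rate, warn=True)


def _rw_bootstrap_band(curve: LoessRateCurve, ci_level: float) -> Optional[tuple]:
    if curve.boot_fits is None:
        return None
    ths = [
        t
        for row in curve.boot_fits
        if (t := _rw_from_arrays(curve.grid, row)) is not None
    ]
    if len(ths) < max(2, curve.boot_fits.shape[0] // 2):
        return None  # threshold undefined in most resamples
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(ths, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return (int(round(lo)), int(round(hi)))


def build_threshold_set(
    eq: ConversionEquation,
    yc_values_cl,
    pairs: Sequence[LongitudinalPair],
    config: ThresholdConfig = ThresholdConfig(),
    curve: Optional[LoessRateCurve] = None,
) -> ThresholdSet:
    """Assemble all three thresholds for one method.

    ``curve`` may be passed to reuse a precomputed LOESS curve (with its
    bootstrap fits); otherwise one is fitted here from ``pairs``.
    """
    empirical = (
        convert_native_threshold(eq, config.native_threshold)
        if config.native_threshold is not None
        else None
    )
    spec_cl = specificity_threshold(yc_values_cl, config.percentile)
    if curve is None:
        curve = loess_rate_curve(
            pairs,
            span=config.span,
            grid_min=config.grid_min,
            grid_max=config.grid_max,
            n_boot=config.n_boot,
            ci_level=config.ci_level,
            seed=config.seed,
        )
    rw = rw_threshold(curve)
    band = _rw_bootstrap_band(curve, config.ci_level) if rw is not None else None
    return ThresholdSet(
        method_label=eq.method_label,
        empirical_cl=empirical,
        specificity_cl=spec_cl,
        rw_cl=rw,
        rw_band=band,
    )
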