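"""Synthetic cohort and signal generators.

Everything downstream of the quantification/calibration/threshold/statistics
stages can be exercised without external data: paired calibration cohorts
with a linear method-to-standard relation, longitudinal cohorts with a
baseline-dependent accumulation rate, reference-tissue-model time–activity
curves with known binding potential, and regional-mixing phantoms with a
known mixing matrix.

Every generator takes an explicit seed and draws from its own
``numpy.random.Generator``; no global RNG state is touched.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError
from .quantify import TimeActivityCurve

__all__ = [
    "CohortParams",
    "LongitudinalSimParams",
    "RateFunction",
    "SrtmParams",
    "PhantomSpec",
    "gen_calibration_cohort",
    "gen_longitudinal_cohort",
    "gen_srtm_tacs",
    "gen_pvc_phantom",
    "write_cohort",
]

_MIN_INTERVAL_YR = 0.5  # truncation floor for follow-up intervals


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class CohortParams:
    """Parameters for a paired calibration cohort (YC + AD groups).

    The standard SUVr of each subject is drawn from a per-group normal
    distribution; the method-specific value is an affine function of the
    standard SUVr plus independent normal noise.
    """

    n_yc: int = 18
    n_ad: int = 18
    yc_mean_std_suvr: float = 1.10
    ad_mean_std_suvr: float = 2.10
    yc_sd: float = 0.06
    ad_sd: float = 0.25
    method_slope: float = 1.0
    method_intercept: float = 0.0
    method_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_yc >= 2, "n_yc must be >= 2")
        _require(self.n_ad >= 2, "n_ad must be >= 2")
        _require(self.yc_sd >= 0, "yc_sd must be >= 0")
        _require(self.ad_sd >= 0, "ad_sd must be >= 0")
        _require(self.method_noise_sd >= 0, "method_noise_sd must be >= 0")
        _require(
            self.ad_mean_std_suvr > self.yc_mean_std_suvr,
            "ad_mean_std_suvr must exceed yc_mean_std_suvr",
        )


def gen_calibration_cohort(params: CohortParams) -> pd.DataFrame:
    """Generate a paired calibration table.

    Returns a DataFrame with columns ``subject_id``, ``group`` ("YC"/"AD"),
    ``standard_suvr`` and ``method_value``; exactly ``n_yc + n_ad`` rows,
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    std_yc = rng.normal(params.yc_mean_std_suvr, params.yc_sd, params.n_yc)
    std_ad = rng.normal(params.ad_mean_std_suvr, params.ad_sd, params.n_ad)
    standard = np.concatenate([std_yc, std_ad])
    noise = rng.normal(0.0, params.method_noise_sd, standard.size)
    method_value = params.method_slope * standard + params.method_intercept + noise
    n = standard.size
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "group": ["YC"] * params.n_yc + ["AD"] * params.n_ad,
            "standard_suvr": standard,
            "method_value": method_value,
        }
    )


@dataclass(frozen=True)
class RateFunction:
    """Annualized accumulation rate (CL/yr) as a function of baseline CL.

    Shapes
    ------
    piecewise_linear
        ``max(floor, slope * (cl - zero_crossing))``; parameters
        ``slope`` (CL/yr per CL), ``zero_crossing`` (CL) and optional
        ``floor`` (CL/yr, default -inf).
    quadratic_dip
        ``a * (cl - cl_min)**2 + c`` with ``a > 0`` and ``c < 0`` for a
        negative dip; upward zero crossing at ``cl_min + sqrt(-c/a)``.
    logistic
        ``height / (1 + exp(-steepness * (cl - midpoint))) + offset``.
    """

    shape: str
    parameters: dict = field(default_factory=dict)
    true_zero_crossing: Optional[float] = None

    _SHAPES = ("piecewise_linear", "quadratic_dip", "logistic")

    def __post_init__(self) -> None:
        _require(self.shape in self._SHAPES, f"shape must be one of {self._SHAPES}")
        if self.true_zero_crossing is None:
            object.__setattr__(self, "true_zero_crossing", self._implied_zero())

    def _implied_zero(self) -> Optional[float]:
        """Upward zero crossing implied by the parameters, when one exists."""
        p = self.parameters
        if self.shape == "piecewise_linear":
            if p.get("slope", 0.0) > 0 and p.get("floor", -np.inf) < 0:
                return float(p.get("zero_crossing", 0.0))
        elif self.shape == "quadratic_dip":
            if p.get("a", 0) > 0 and p.get("c", 0) < 0:
                return p.get("cl_min", 0.0) + float(np.sqrt(-p["c"] / p["a"]))
        else:  # logistic
            height, offset = p.get("height", 0.0), p.get("offset", 0.0)
            if height > 0 > offset and height > -offset:
                return p.get("midpoint", 0.0) - float(
                    np.log(height / -offset - 1.0) / p.get("steepness", 0.2)
                )
        return None

    def __call__(self, cl):
        cl = np.asarray(cl, dtype=float)
        p = self.parameters
        if self.shape == "piecewise_linear":
            raw = p.get("slope", 0.0) * (cl - p.get("zero_crossing", 0.0))
            out = np.maximum(raw, p.get("floor", -np.inf))
        elif self.shape == "quadratic_dip":
            out = p["a"] * (cl - p.get("cl_min", 0.0)) ** 2 + p["c"]
        else:  # logistic
            out = p["height"] / (
                1.0 + np.exp(-p.get("steepness", 0.2) * (cl - p.get("midpoint", 0.0)))
            ) + p.get("offset", 0.0)
        return out if out.ndim else float(out)


#: zero-rate convenience instance (follow-up equals baseline)
ZERO_RATE = RateFunction("piecewise_linear", {"slope": 0.0, "zero_crossing": 0.0})


@dataclass(frozen=True)
class LongitudinalSimParams:
    """Parameters for a two-visit longitudinal cohort on the CL scale.

    ``baseline_distribution`` is a mixture spec ``(weights, means, sds)``
    in CL; intervals are truncated-normal (> 0.5 yr); the accumulation rate
    is applied at baseline over the whole interval (single Euler step).
    """

    n_subjects: int = 243
    baseline_weights: Sequence[float] = (0.75, 0.25)
    baseline_means: Sequence[float] = (0.0, 60.0)
    baseline_sds: Sequence[float] = (5.0, 30.0)
    interval_mean: float = 3.2
    interval_sd: float = 1.5
    rate_function: RateFunction = ZERO_RATE
    measurement_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_subjects >= 1, "n_subjects must be >= 1")
        _require(self.interval_mean > 0, "interval_mean must be > 0")
        _require(self.interval_sd >= 0, "interval_sd must be >= 0")
        _require(self.measurement_noise_sd >= 0, "measurement_noise_sd must be >= 0")
        w = np.asarray(self.baseline_weights, dtype=float)
        _require(abs(w.sum() - 1.0) < 1e-9, "baseline_weights must sum to 1")
        _require(np.all(w >= 0), "baseline_weights must be nonnegative")
        _require(
            len(self.baseline_weights) == len(self.baseline_means) == len(self.baseline_sds),
            "baseline mixture weights/means/sds must have equal length",
        )


def _truncated_normal(rng, mean, sd, low, size):
    if sd == 0:
        if mean <= low:
            raise ParameterError("interval_mean must exceed the 0.5 yr floor when sd=0")
        return np.full(size, mean)
    a = (low - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def gen_longitudinal_cohort(params: LongitudinalSimParams) -> pd.DataFrame:
    """Generate a two-visit cohort with noise-free truth retained.

    Returns a DataFrame with columns ``subject_id``, ``baseline_true``,
    ``followup_true``, ``baseline_cl``, ``followup_cl``, ``interval``.
    Truth satisfies ``followup_true = baseline_true +
    rate_function(baseline_true) * interval`` exactly; observed values add
    independent normal measurement noise at each visit.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    comp = rng.choice(
        len(params.baseline_weights), size=n, p=np.asarray(params.baseline_weights, float)
    )
    means = np.asarray(params.baseline_means, float)[comp]
    sds = np.asarray(params.baseline_sds, float)[comp]
    baseline_true = rng.normal(means, sds)
    interval = _truncated_normal(
        rng, params.interval_mean, params.interval_sd, _MIN_INTERVAL_YR, n
    )
    followup_true = baseline_true + np.asarray(
        params.rate_function(baseline_true), float
    ) * interval
    noise = rng.normal(0.0, params.measurement_noise_sd, size=(2, n))
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "baseline_true": baseline_true,
            "followup_true": followup_true,
            "baseline_cl": baseline_true + noise[0],
            "followup_cl": followup_true + noise[1],
            "interval": interval,
        }
    )


# --- simplified reference tissue model -----------------------------------

_REFERENCE_SHAPES = ("constant", "bolus_biexp")


@dataclass(frozen=True)
class SrtmParams:
    """Ground-truth kinetic parameters for a target/reference TAC pair.

    The target follows the simplified reference tissue model

        dC_t/dt = R1 * dC_ref/dt + k2 * C_ref - k2a * C_t,
        k2a = k2 / (1 + bp_true),

    so the true distribution volume ratio is ``1 + bp_true``.

    ``reference_input`` selects the reference-region activity:
    ``{"shape": "constant", "value": v}`` (step at t=0) or
    ``{"shape": "bolus_biexp", "amplitude": A, "lam1": l1, "lam2": l2}``
    giving ``A * (exp(-l1 t) - exp(-l2 t))`` with ``l2 > l1``.
    """

    R1: float = 1.0
    k2: float = 0.25
    bp_true: float = 0.5
    frame_mid_times: Sequence[float] = tuple(np.arange(2.5, 90.0, 5.0))
    frame_durations: Sequence[float] = tuple(np.full(18, 5.0))
    reference_input: dict = field(
        default_factory=lambda: {
            "shape": "bolus_biexp",
            "amplitude": 100.0,
            "lam1": 0.01,
            "lam2": 0.25,
        }
    )

    def __post_init__(self) -> None:
        _require(self.k2 > 0, "k2 must be > 0")
        _require(self.R1 > 0, "R1 must be > 0")
        _require(self.bp_true >= 0, "bp_true must be >= 0")
        t = np.asarray(self.frame_mid_times, float)
        _require(t.size >= 3, "frame_mid_times must have >= 3 frames")
        _require(bool(np.all(np.diff(t) > 0)), "frame_mid_times must be strictly increasing")
        shape = self.reference_input.get("shape")
        _require(shape in _REFERENCE_SHAPES, f"reference shape must be one of {_REFERENCE_SHAPES}")

    def reference_function(self) -> Callable[[np.ndarray], np.ndarray]:
        spec = self.reference_input
        if spec["shape"] == "constant":
            v = float(spec.get("value", 1.0))
            return lambda t: np.full_like(np.asarray(t, float), v)
        a = float(spec.get("amplitude", 100.0))
        l1, l2 = float(spec.get("lam1", 0.015)), float(spec.get("lam2", 0.25))
        _require(l2 > l1 > 0, "bolus_biexp requires lam2 > lam1 > 0")
        return lambda t: a * (np.exp(-l1 * np.asarray(t, float)) - np.exp(-l2 * np.asarray(t, float)))


def gen_srtm_tacs(params: SrtmParams, dt: float = 0.01):
    """Solve the reference-tissue model and sample both TACs on the frame grid.

    The convolution integral is evaluated on a fine grid (step ``dt`` min)
    with an exact exponential-decay recursion plus trapezoidal source terms,
    then linearly interpolated at frame mid-times.  Noiseless.

    Returns
    -------
    (TimeActivityCurve, TimeActivityCurve)
        Target and reference curves on the requested frame grid.
    """
    mid = np.asarray(params.frame_mid_times, float)
    dur = np.asarray(params.frame_durations, float)
    cref_fun = params.reference_function()
    t_end = mid[-1] + dur[-1]
    grid = np.arange(0.0, t_end + dt, dt)
    cref = cref_fun(grid)
    k2a = params.k2 / (1.0 + params.bp_true)
    coef = params.k2 - params.R1 * k2a
    # I(t) = int_0^t cref(s) exp(-k2a (t - s)) ds, exact decay + trapezoid source
    decay = np.exp(-k2a * dt)
    conv = np.empty_like(cref)
    conv[0] = 0.0
    half_dt = 0.5 * dt
    for i in range(1, grid.size):
        conv[i] = conv[i - 1] * decay + half_dt * (cref[i] + cref[i - 1] * decay)
    ct = params.R1 * cref + coef * conv
    target = TimeActivityCurve(mid, dur, np.interp(mid, grid, ct))
    reference = TimeActivityCurve(mid, dur, np.interp(mid, grid, cref))
    return target, reference


@dataclass(frozen=True)
class PhantomSpec:
    """Regional-mixing phantom: true means blurred by a row-stochastic matrix."""

    true_means: Sequence[float]
    mixing_matrix: Sequence[Sequence[float]]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.true_means, float)
        m = np.asarray(self.mixing_matrix, float)
        n = means.size
        _require(n >= 1, "need at least one region")
        _require(bool(np.all(means >= 0)), "true_means must be >= 0")
        _require(m.shape == (n, n), f"mixing_matrix must be {n}x{n}")
        _require(bool(np.all(m >= 0)), "mixing_matrix must be nonnegative")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ParameterError("mixing_matrix rows must sum to 1 (tolerance 1e-9)")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")

    @property
    def n_regions(self) -> int:
        return len(self.true_means)


def gen_pvc_phantom(spec: PhantomSpec) -> np.ndarray:
    """Observed regional means: ``mixing_matrix @ true_means + noise``."""
    rng = np.random.default_rng(spec.seed)
    m = np.asarray(spec.mixing_matrix, float)
    observed = m @ np.asarray(spec.true_means, float)
    if spec.noise_sd > 0:
        observed = observed + rng.normal(0.0, spec.noise_sd, observed.size)
    return observed


def write_cohort(df: pd.DataFrame, path, params=None) -> None:
    """Write a cohort table as CSV (header, UTF-8, '.' decimal) with a JSON
    sidecar recording the generating parameters, seed included."""
    df.to_csv(path, index=False)
    if params is not None:
        sidecar = str(path) + ".json"
        d = dataclasses.asdict(params) if dataclasses.is_dataclass(params) else dict(params)
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(d), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
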