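"""Native amyloid-burden quantification primitives.

Operates on regional time–activity curves (TACs) and regional mean values:
duration-weighted window means, target/reference SUVr, reference-tissue Logan
graphical binding potential, mixing-matrix partial-volume correction (GTM
form), a mean cortical summary index, and an optional NIfTI region-mean
entry point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import (
    ConditioningError,
    EmptyWindowError,
    InsufficientDataError,
    NumericalDomainError,
    ParameterError,
    RegionLookupError,
)

__all__ = [
    "TimeActivityCurve",
    "TimeWindow",
    "MethodSpec",
    "RegionalValues",
    "window_mean",
    "suvr",
    "logan_bp",
    "pvc_correct",
    "mean_cortical_index",
    "regional_mean_from_volume",
]

#: maximum acceptable mixing-matrix condition number
_COND_LIMIT = 1e8


@dataclass(frozen=True)
class TimeActivityCurve:
    """A regional tracer concentration curve sampled on scan frames.

    Parameters
    ----------
    frame_mid_times : array-like
        Frame mid-times in minutes post-injection, strictly increasing.
    frame_durations : array-like
        Frame durations in minutes, all positive.
    activity : array-like
        Tracer concentration per frame (any consistent unit).
    """

    frame_mid_times: np.ndarray
    frame_durations: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_mid_times, dtype=float)
        d = np.asarray(self.frame_durations, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        if not (t.ndim == d.ndim == a.ndim == 1):
            raise ParameterError("TAC fields must be one-dimensional vectors")
        if not (t.size == d.size == a.size):
            raise ParameterError(
                "frame_mid_times, frame_durations and activity must have equal length"
            )
        if t.size == 0:
            raise ParameterError("TAC must contain at least one frame")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("frame_mid_times must be strictly increasing")
        if np.any(d <= 0):
            raise ParameterError("frame_durations must be positive")
        if not np.all(np.isfinite(a)):
            raise ParameterError("activity must be finite")
        object.__setattr__(self, "frame_mid_times", t)
        object.__setattr__(self, "frame_durations", d)
        object.__setattr__(self, "activity", a)

    def __len__(self) -> int:
        return self.frame_mid_times.size


@dataclass(frozen=True)
class TimeWindow:
    """Closed post-injection time window [start, end] in minutes."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ParameterError(
                f"window requires 0 <= start < end, got [{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class MethodSpec:
    """One quantification variant: metric, PVC flag, reference region, window."""

    metric: str  # "SUVr" | "BP"
    pvc: bool
    reference: str  # "cerebellar_cortex" | "brainstem" | "whole_cerebellum"
    window: TimeWindow
    label: str

    _METRICS = ("SUVr", "BP")
    _REFERENCES = ("cerebellar_cortex", "brainstem", "whole_cerebellum")

    def __post_init__(self) -> None:
        if self.metric not in self._METRICS:
            raise ParameterError(f"metric must be one of {self._METRICS}")
        if self.reference not in self._REFERENCES:
            raise ParameterError(f"reference must be one of {self._REFERENCES}")
        if not self.label:
            raise ParameterError("label must be non-empty")


@dataclass(frozen=True)
class RegionalValues:
    """Per-region metric values with unique region names."""

    names: tuple
    values: np.ndarray
    metric: str = "SUVr"

    def __post_init__(self) -> None:
        names = tuple(self.names)
        vals = np.asarray(self.values, dtype=float)
        if len(names) != vals.size:
            raise ParameterError("names and values must have equal length")
        if len(set(names)) != len(names):
            raise ParameterError("region names must be unique")
        if not np.all(np.isfinite(vals)):
            raise ParameterError("values must be finite")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "values", vals)

    def value_of(self, name: str) -> float:
        try:
            return float(self.values[self.names.index(name)])
        except ValueError:
            raise RegionLookupError(f"region {name!r} not found") from None


def window_mean(tac: TimeActivityCurve, window: TimeWindow) -> float:
    """Duration-weighted mean activity over frames whose mid-time lies in the
    closed window.

    Raises
    ------
    EmptyWindowError
        If no frame mid-time falls inside the window.
    """
    inside = (tac.frame_mid_times >= window.start) & (tac.frame_mid_times <= window.end)
    if not np.any(inside):
        raise EmptyWindowError(
            f"no frames with mid-time in [{window.start}, {window.end}] min"
        )
    w = tac.frame_durations[inside]
    return float(np.sum(w * tac.activity[inside]) / np.sum(w))


def suvr(
    target: TimeActivityCurve, reference: TimeActivityCurve, window: TimeWindow
) -> float:
    """Standard uptake value ratio: target window mean over reference window mean.

    Both TACs must share the same frame grid; the reference window mean must
    be positive.
    """
    if not np.array_equal(target.frame_mid_times, reference.frame_mid_times):
        raise ParameterError("target and reference TACs must share the frame grid")
    ref_mean = window_mean(reference, window)
    if ref_mean <= 0:
        raise NumericalDomainError(
            f"reference window mean must be positive, got {ref_mean}"
        )
    return window_mean(target, window) / ref_mean


def _cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Trapezoidal integral of activity from time 0 to each frame mid-time.

    The leading segment from t=0 to the first mid-time is a triangle from
    zero activity (injection starts at zero concentration).
    """
    t = np.concatenate([[0.0], tac.frame_mid_times])
    a = np.concatenate([[0.0], tac.activity])
    return cumulative_trapezoid(a, t)


def logan_bp(
    target: TimeActivityCurve, reference: TimeActivityCurve, t_star: float
) -> float:
    """Reference-tissue Logan graphical binding potential.

    Fits an ordinary least-squares line to

        y(t) = int_0^t C_target / C_target(t)   versus
        x(t) = int_0^t C_reference / C_target(t)

    for frames with mid-time >= ``t_star``; returns slope - 1 (the slope
    estimates the distribution volume ratio).  The reference-region efflux
    correction term is omitted.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 frames at or beyond ``t_star``.
    NumericalDomainError
        Non-positive target activity in the fitted tail.
    """
    if not np.array_equal(target.frame_mid_times, reference.frame_mid_times):
        raise ParameterError("target and reference TACs must share the frame grid")
    tail = target.frame_mid_times >= t_star
    if np.count_nonzero(tail) < 3:
        raise InsufficientDataError(
            f"need >= 3 frames with mid-time >= t_star={t_star}, "
            f"got {np.count_nonzero(tail)}"
        )
    ct = target.activity[tail]
    if np.any(ct <= 0):
        raise NumericalDomainError("target activity must be positive beyond t_star")
    int_t = _cumulative_integral(target)[tail]
    int_r = _cumulative_integral(reference)[tail]
    y = int_t / ct
    x = int_r / ct
    slope = np.polyfit(x, y, 1)[0]
    return float(slope - 1.0)


def pvc_correct(observed: RegionalValues, mixing_matrix) -> RegionalValues:
    """Invert a row-stochastic regional mixing matrix to recover true means.

    Solves ``mixing_matrix @ corrected = observed`` by a dense linear solve.
    The matrix must be square with rows summing to 1 (tolerance 1e-6) and a
    condition number below 1e8.
    """
    m = np.asarray(mixing_matrix, dtype=float)
    n = len(observed.names)
    if m.shape != (n, n):
        raise ParameterError(
            f"mixing matrix must be {n}x{n} to match the regions, got {m.shape}"
        )
    if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-6):
        raise ParameterError("mixing matrix rows must sum to 1 (tolerance 1e-6)")
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise ConditioningError(
            f"mixing matrix condition number {cond:.3g} exceeds {_COND_LIMIT:.0e}"
        )
    corrected = np.linalg.solve(m, observed.values)
    return RegionalValues(observed.names, corrected, observed.metric)


def mean_cortical_index(
    regional: RegionalValues, region_set, weights=None
) -> float:
    """Weighted mean of a subset of regional values (unweighted by default).

    Raises
    ------
    RegionLookupError
        If any requested region name is missing (all missing names listed).
    ParameterError
        If weights are negative or all zero.
    """
    region_set = list(region_set)
    missing = [r for r in region_set if r not in regional.names]
    if missing:
        raise RegionLookupError(f"regions not found: {missing}")
    vals = np.array([regional.value_of(r) for r in region_set])
    if weights is None:
        return float(vals.mean())
    w = np.asarray(weights, dtype=float)
    if w.size != vals.size:
        raise ParameterError("weights must match region_set in length")
    if np.any(w < 0) or not np.any(w > 0):
        raise ParameterError("weights must be nonnegative and not all zero")
    return float(np.sum(w * vals) / np.sum(w))


def regional_mean_from_volume(image, labels, label_id: int) -> float:
    """Mean image intensity over voxels carrying ``label_id`` in a label volume.

    Accepts nibabel spatial images or plain arrays; when both inputs are
    nibabel images their affines must match (no resampling is performed).
    """
    img_data, img_affine = _volume_data(image)
    lab_data, lab_affine = _volume_data(labels)
    if img_data.shape != lab_data.shape:
        raise ParameterError(
            f"image grid {img_data.shape} does not match label grid {lab_data.shape}"
        )
    if img_affine is not None and lab_affine is not None:
        if not np.allclose(img_affine, lab_affine, atol=1e-4):
            raise ParameterError("image and label affines differ; resample first")
    mask = lab_data == label_id
    if not np.any(mask):
        raise RegionLookupError(f"label {label_id} absent from label volume")
    return float(img_data[mask].mean())


def _volume_data(vol):
    if hasattr(vol, "get_fdata"):  # nibabel image
        return np.asarray(vol.get_fdata()), np.asarray(vol.affine)
    return np.asarray(vol, dtype=float), None
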