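"""Centiloid anchor equation and level-2 calibration.

The standard scale maps the young-control group mean to 0 and the typical-AD
group mean to 100.  Level-2 calibration regresses standard SUVr on a
method-specific value and composes the fitted line with the anchor map,
yielding an affine conversion from native units to Centiloid (CL) units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import (
    AnchorOrderError,
    DegenerateFitError,
    InsufficientDataError,
    ParameterError,
)

__all__ = [
    "AnchorSet",
    "ConversionEquation",
    "CalibrationQC",
    "standard_cl",
    "fit_anchors",
    "fit_level2",
    "apply_equation",
    "calibration_report",
]

#: level-2 guideline quality gate on the calibration fit
R2_QUALITY_GATE = 0.70


@dataclass(frozen=True)
class AnchorSet:
    """Group-mean standard SUVr values anchoring CL = 0 and CL = 100."""

    mu_yc: float
    mu_ad: float

    def __post_init__(self) -> None:
        if not self.mu_ad > self.mu_yc:
            raise AnchorOrderError(
                f"mu_ad ({self.mu_ad}) must exceed mu_yc ({self.mu_yc})"
            )


@dataclass(frozen=True)
class ConversionEquation:
    """Affine map CL(v) = slope * v + intercept for one quantification method."""

    method_label: str
    slope: float
    intercept: float
    r_squared: float
    n_fit: int
    anchors: AnchorSet
    quality_flag: bool = False

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ParameterError("conversion slope must be nonzero")
        if self.n_fit < 4:
            raise ParameterError(f"n_fit must be >= 4, got {self.n_fit}")
        if not 0 <= self.r_squared <= 1:
            raise ParameterError("r_squared must lie in [0, 1]")

    def invert(self, cl) -> np.ndarray:
        """Native value(s) producing the given CL value(s)."""
        return (np.asarray(cl, dtype=float) - self.intercept) / self.slope

    def to_dict(self) -> dict:
        return {
            "method_label": self.method_label,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_fit": self.n_fit,
            "anchors": {"mu_yc": self.anchors.mu_yc, "mu_ad": self.anchors.mu_ad},
            "quality_flag": self.quality_flag,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ConversionEquation":
        return cls(
            method_label=d["method_label"],
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            r_squared=float(d["r_squared"]),
            n_fit=int(d["n_fit"]),
            anchors=AnchorSet(float(d["anchors"]["mu_yc"]), float(d["anchors"]["mu_ad"])),
            quality_flag=bool(d.get("quality_flag", False)),
        )

    @classmethod
    def from_json(cls, path) -> "ConversionEquation":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CalibrationQC:
    """Converted-group summary for a calibration cohort."""

    yc_mean_cl: float
    yc_sd_cl: float
    ad_mean_cl: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.yc_sd_cl < 0:
            raise ParameterError("yc_sd_cl must be >= 0")


def standard_cl(value, anchors: AnchorSet):
    """Map standard SUVr value(s) to the Centiloid scale.

    ``100 * (value - mu_yc) / (mu_ad - mu_yc)``; exact 0/100 at the anchors.
    """
    v = np.asarray(value, dtype=float)
    out = 100.0 * (v - anchors.mu_yc) / (anchors.mu_ad - anchors.mu_yc)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def fit_anchors(yc_values, ad_values) -> AnchorSet:
    """Anchor set from group arithmetic means of standard SUVr values."""
    yc = np.asarray(yc_values, dtype=float)
    ad = np.asarray(ad_values, dtype=float)
    if yc.size < 2 or ad.size < 2:
        raise InsufficientDataError("each anchor group needs n >= 2")
    return AnchorSet(mu_yc=float(yc.mean()), mu_ad=float(ad.mean()))


def fit_level2(paired, anchors: AnchorSet, method_label: str) -> ConversionEquation:
    """Level-2 calibration of one method against the standard SUVr.

    Parameters
    ----------
    paired : sequence of (method_value, standard_suvr)
        Per-subject paired measurements; standard SUVr is the regression
        response, the method value the predictor.
    anchors : AnchorSet
        Standard-scale anchors used to compose the CL map.
    method_label : str
        Label carried onto the resulting equation.

    Returns
    -------
    ConversionEquation
        With ``quality_flag`` set when the fit r-squared falls below 0.70
        (warning, not fatal).
    """
    arr = np.asarray(list(paired), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParameterError("paired must be a sequence of (method_value, standard_suvr)")
    if arr.shape[0] < 4:
        raise InsufficientDataError(f"level-2 fit needs n >= 4, got {arr.shape[0]}")
    method_value, standard = arr[:, 0], arr[:, 1]
    if np.ptp(method_value) == 0:
        raise DegenerateFitError("method values are constant; cannot calibrate")
    fit = sps.linregress(method_value, standard)
    a, b = fit.slope, fit.intercept
    span = anchors.mu_ad - anchors.mu_yc
    r2 = float(fit.rvalue**2)
    return ConversionEquation(
        method_label=method_label,
        slope=100.0 * a / span,
        intercept=100.0 * (b - anchors.mu_yc) / span,
        r_squared=r2,
        n_fit=int(arr.shape[0]),
        anchors=anchors,
        quality_flag=r2 < R2_QUALITY_GATE,
    )


def apply_equation(eq: ConversionEquation, values):
    """Elementwise affine conversion of native value(s) to CL."""
    v = np.asarray(values, dtype=float)
    out = eq.slope * v + eq.intercept
    return float(out) if np.isscalar(values) or out.ndim == 0 else out


def calibration_report(eq: ConversionEquation, cohort) -> CalibrationQC:
    """Converted YC mean/SD and AD mean for a paired calibration table.

    ``cohort`` is a DataFrame with columns ``group`` (values "YC"/"AD") and
    ``method_value``.
    """
    groups = set(cohort["group"])
    missing = {"YC", "AD"} - groups
    if missing:
        raise ParameterError(f"cohort is missing group(s): {sorted(missing)}")
    yc = apply_equation(eq, cohort.loc[cohort["group"] == "YC", "method_value"].to_numpy())
    ad = apply_equation(eq, cohort.loc[cohort["group"] == "AD", "method_value"].to_numpy())
    return CalibrationQC(
        yc_mean_cl=float(np.mean(yc)),
        yc_sd_cl=float(np.std(yc, ddof=1)),
        ad_mean_cl=float(np.mean(ad)),
        r_squared=eq.r_squared,
    )
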