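"""End-to-end orchestration: simulate → calibrate → thresholds → statistics.

A :class:`RunConfig` describes a fully deterministic run over a set of
quantification-method variants that share the same simulated subjects: each
method observes the same standard SUVr values through its own affine
relation and noise level, is level-2 calibrated, has its three positivity
thresholds estimated, and contributes to cross-method comparison tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import calibrate, stats, synthetic, thresholds
from .errors import ParameterError

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

__all__ = ["MethodSimConfig", "RunConfig", "RunReport", "run_pipeline", "write_report", "default_config"]


@dataclass(frozen=True)
class MethodSimConfig:
    """Simulated relation between one method's native values and the standard.

    ``slope``/``intercept``/``noise_sd`` define the native↔standard relation
    used for the calibration cohort; ``longitudinal_noise_sd_cl`` is the
    per-visit measurement noise this method adds on the CL scale;
    ``native_threshold`` is an optional legacy positivity threshold in
    native units.
    """

    label: str
    slope: float = 1.0
    intercept: float = 0.0
    noise_sd: float = 0.05
    longitudinal_noise_sd_cl: float = 2.5
    native_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ParameterError("method label must be non-empty")
        if self.slope == 0:
            raise ParameterError(f"method {self.label}: slope must be nonzero")
        if self.noise_sd < 0 or self.longitudinal_noise_sd_cl < 0:
            raise ParameterError(f"method {self.label}: noise SDs must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a pipeline run."""

    seed: int = 0
    methods: Sequence[MethodSimConfig] = ()
    anchors: Optional[calibrate.AnchorSet] = None
    cohort: synthetic.CohortParams = synthetic.CohortParams()
    longitudinal: synthetic.LongitudinalSimParams = synthetic.LongitudinalSimParams()
    threshold: thresholds.ThresholdConfig = thresholds.ThresholdConfig()
    classification: stats.ClassificationRule = stats.ClassificationRule(10.7)
    trial: stats.TrialDesign = stats.TrialDesign()
    n_planned_comparisons: int = 100
    family_alpha: float = 0.05

    def __post_init__(self) -> None:
        labels = [m.label for m in self.methods]
        if len(labels) != len(set(labels)):
            raise ParameterError("method labels must be unique")
        if not self.methods:
            raise ParameterError("at least one method must be configured")

    @property
    def corrected_alpha(self) -> float:
        return stats.corrected_alpha(self.family_alpha, self.n_planned_comparisons)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = [dataclasses.asdict(m) for m in self.methods]
        return synthetic._jsonable(d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        methods = tuple(MethodSimConfig(**m) for m in d.pop("methods", []))
        anchors = d.pop("anchors", None)
        if anchors is not None:
            anchors = calibrate.AnchorSet(**anchors)
        kwargs = {}
        if "cohort" in d:
            kwargs["cohort"] = synthetic.CohortParams(**d.pop("cohort"))
        if "longitudinal" in d:
            ld = dict(d.pop("longitudinal"))
            if "rate_function" in ld:
                ld["rate_function"] = synthetic.RateFunction(**ld["rate_function"])
            kwargs["longitudinal"] = synthetic.LongitudinalSimParams(**ld)
        if "threshold" in d:
            kwargs["threshold"] = thresholds.ThresholdConfig(**d.pop("threshold"))
        if "classification" in d:
            kwargs["classification"] = stats.ClassificationRule(**d.pop("classification"))
        if "trial" in d:
            kwargs["trial"] = stats.TrialDesign(**d.pop("trial"))
        return cls(methods=methods, anchors=anchors, **kwargs, **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a YAML or JSON config (auto-detected by content)."""
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
        return cls.from_dict(data)


def default_config(seed: int = 0) -> RunConfig:
    """Shipped demo configuration: four method variants with distinct
    native scales and noise levels, an accumulation-rate dip crossing zero
    at 15 CL, and defaults mirroring the analysis conventions (95th
    percentile, 95% CI, 50% reduction, 80% power, alpha 0.05, tiers
    0.05 / 0.0005)."""
    # saturating rate curve: small negative floor at low CL, ~5 CL/yr at
    # high CL, upward zero crossing near 15 CL
    rate = synthetic.RateFunction(
        "logistic",
        {"height": 5.5, "offset": -0.5, "steepness": 0.08, "midpoint": 43.8},
    )
    return RunConfig(
        seed=seed,
        methods=(
            MethodSimConfig("BP_noPVC", slope=0.55, intercept=-0.55, noise_sd=0.05,
                            longitudinal_noise_sd_cl=3.0, native_threshold=0.18),
            MethodSimConfig("BP_PVC", slope=0.80, intercept=-0.80, noise_sd=0.03,
                            longitudinal_noise_sd_cl=2.2, native_threshold=0.18),
            MethodSimConfig("SUVr_noPVC", slope=1.0, intercept=0.0, noise_sd=0.06,
                            longitudinal_noise_sd_cl=3.3, native_threshold=1.42),
            MethodSimConfig("SUVr_PVC", slope=1.4, intercept=-0.4, noise_sd=0.04,
                            longitudinal_noise_sd_cl=2.6, native_threshold=1.42),
        ),
        longitudinal=synthetic.LongitudinalSimParams(rate_function=rate),
        threshold=thresholds.ThresholdConfig(n_boot=200),
    )


@dataclass
class MethodResult:
    """Everything computed for one configured method."""

    label: str
    equation: calibrate.ConversionEquation
    qc: calibrate.CalibrationQC
    threshold_set: thresholds.ThresholdSet
    curve: thresholds.LoessRateCurve
    n_stable_negative: int
    n_accumulator: int
    intra_individual_sd: float
    mean_annual_rate: Optional[float]
    effect_size: Optional[float]
    sample_size_per_arm: Optional[int]
    longitudinal_change: Optional[stats.ComparisonResult]
    yc_cl: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "equation": self.equation.to_dict(),
            "calibration_qc": dataclasses.asdict(self.qc),
            "thresholds": self.threshold_set.to_dict(),
            "curve": {
                "grid_cl": self.curve.grid.tolist(),
                "fitted_rate": _nan_to_none(self.curve.fitted_rate),
                "lower_band": _nan_to_none(self.curve.lower_band),
                "upper_band": _nan_to_none(self.curve.upper_band),
            },
            "n_stable_negative": self.n_stable_negative,
            "n_accumulator": self.n_accumulator,
            "intra_individual_sd": self.intra_individual_sd,
            "mean_annual_rate": self.mean_annual_rate,
            "effect_size": self.effect_size,
            "sample_size_per_arm": self.sample_size_per_arm,
            "longitudinal_change": _comparison_dict(self.longitudinal_change),
        }


@dataclass
class RunReport:
    """Full pipeline output: per-method results, cross-method comparisons,
    and provenance (config hash, seed, version)."""

    methods: dict
    comparisons: list
    failures: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "methods": {k: v.to_dict() for k, v in self.methods.items()},
            "comparisons": self.comparisons,
            "failures": self.failures,
            "provenance": self.provenance,
        }


def _nan_to_none(arr) -> list:
    return [None if not np.isfinite(v) else float(v) for v in np.asarray(arr, float)]


def _comparison_dict(c: Optional[stats.ComparisonResult]):
    if c is None:
        return None
    return {
        "statistic": None if not np.isfinite(c.statistic) else float(c.statistic),
        "p_value": c.p_value,
        "tier": c.tier,
        "test": c.test,
        **c.extra,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full chain for every configured method.

    Deterministic for a fixed config (per-method seeds are spawned from the
    master seed); a failure in one method is recorded and does not abort the
    others.
    """
    master = np.random.SeedSequence(config.seed)
    base_seed, long_seed, *method_seeds = [
        s.generate_state(1)[0] for s in master.spawn(2 + 2 * len(config.methods))
    ]

    # shared standard-scale calibration cohort (noise-free method channel)
    base_params = dataclasses.replace(
        config.cohort, method_slope=1.0, method_intercept=0.0,
        method_noise_sd=0.0, seed=int(base_seed),
    )
    base_cohort = synthetic.gen_calibration_cohort(base_params)
    standard = base_cohort["standard_suvr"].to_numpy()
    anchors = config.anchors or calibrate.fit_anchors(
        standard[base_cohort["group"] == "YC"], standard[base_cohort["group"] == "AD"]
    )

    # shared longitudinal truth on the CL scale
    long_params = dataclasses.replace(
        config.longitudinal, measurement_noise_sd=0.0, seed=int(long_seed)
    )
    long_truth = synthetic.gen_longitudinal_cohort(long_params)

    methods: dict = {}
    failures: dict = {}
    for i, m in enumerate(config.methods):
        try:
            methods[m.label] = _run_method(
                m, config, base_cohort, standard, anchors, long_truth,
                seed_cal=int(method_seeds[2 * i]), seed_long=int(method_seeds[2 * i + 1]),
            )
        except Exception as exc:  # isolate per-method failures
            logger.exception("method %s failed", m.label)
            failures[m.label] = f"{type(exc).__name__}: {exc}"

    comparisons = _cross_method_comparisons(config, methods, base_cohort, anchors)
    provenance = {
        "seed": config.seed,
        "config_sha256": config.hash(),
        "version": __version__,
        "corrected_alpha": config.corrected_alpha,
        "anchors": {"mu_yc": anchors.mu_yc, "mu_ad": anchors.mu_ad},
    }
    return RunReport(methods=methods, comparisons=comparisons, failures=failures, provenance=provenance)


def _run_method(m, config, base_cohort, standard, anchors, long_truth, seed_cal, seed_long):
    rng = np.random.default_rng(seed_cal)
    method_value = (
        m.slope * standard + m.intercept + rng.normal(0.0, m.noise_sd, standard.size)
    )
    cohort = base_cohort.assign(method_value=method_value)
    eq = calibrate.fit_level2(
        np.column_stack([method_value, standard]), anchors, m.label
    )
    qc = calibrate.calibration_report(eq, cohort)
    yc_cl = calibrate.apply_equation(
        eq, cohort.loc[cohort["group"] == "YC", "method_value"].to_numpy()
    )

    rng_long = np.random.default_rng(seed_long)
    noise = rng_long.normal(0.0, m.longitudinal_noise_sd_cl, size=(2, len(long_truth)))
    observed = long_truth.assign(
        baseline_cl=long_truth["baseline_true"] + noise[0],
        followup_cl=long_truth["followup_true"] + noise[1],
    )
    pairs = thresholds.pairs_from_frame(observed)

    tcfg = dataclasses.replace(
        config.threshold, native_threshold=m.native_threshold, seed=seed_long
    )
    curve = thresholds.loess_rate_curve(
        pairs, span=tcfg.span, grid_min=tcfg.grid_min, grid_max=tcfg.grid_max,
        n_boot=tcfg.n_boot, ci_level=tcfg.ci_level, seed=tcfg.seed,
    )
    tset = thresholds.build_threshold_set(eq, yc_cl, pairs, tcfg, curve=curve)

    groups = stats.longitudinal_groups(pairs, config.classification)
    intra = stats.intra_individual_sd(groups.stable_negative)
    rate = eff = n_arm = change = None
    if len(groups.accumulator) >= 2:
        rate = stats.mean_annual_rate(groups.accumulator)
        eff = stats.effect_size(rate, intra)
        if rate > 0:
            n_arm = stats.trial_sample_size(rate, intra, config.trial)
        change = stats.paired_t_test(
            [p.followup_cl for p in groups.accumulator],
            [p.baseline_cl for p in groups.accumulator],
        )
    return MethodResult(
        label=m.label, equation=eq, qc=qc, threshold_set=tset, curve=curve,
        n_stable_negative=len(groups.stable_negative),
        n_accumulator=len(groups.accumulator),
        intra_individual_sd=intra, mean_annual_rate=rate, effect_size=eff,
        sample_size_per_arm=n_arm, longitudinal_change=change, yc_cl=np.asarray(yc_cl),
    )


def _cross_method_comparisons(config, methods, base_cohort, anchors):
    """Pairwise comparisons of converted YC values between methods (same
    subjects seen through each method): variance F with Pitman–Morgan, and
    paired t on the means."""
    out = []
    labels = list(methods)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = methods[labels[i]].yc_cl
            b = methods[labels[j]].yc_cl
            out.append(
                {
                    "pair": [labels[i], labels[j]],
                    "variance_F": _comparison_dict(stats.variance_f_test(a, b, paired=True)),
                    "paired_t": _comparison_dict(stats.paired_t_test(a, b)),
                }
            )
    return out


def write_report(report: RunReport, outdir) -> dict:
    """Serialize a run report to a directory tree.

    Writes the JSON bundle, per-method equation and threshold JSON files,
    rate-curve tables, and Table-shaped delimited summaries; returns a
    manifest mapping each relative path to its SHA-256 checksum (also
    written as ``manifest.json``).  Absent values are empty cells in CSV and
    nulls in JSON.
    """
    outdir = Path(outdir)
    (outdir / "equations").mkdir(parents=True, exist_ok=True)
    (outdir / "thresholds").mkdir(exist_ok=True)
    (outdir / "curves").mkdir(exist_ok=True)

    bundle = report.to_dict()
    _write_json(outdir / "report.json", bundle)
    for label, res in report.methods.items():
        _write_json(outdir / "equations" / f"{label}.json", res.equation.to_dict())
        _write_json(outdir / "thresholds" / f"{label}.json", res.threshold_set.to_dict())
        res.curve.to_frame().to_csv(outdir / "curves" / f"{label}_rate_curve.csv", index=False)

    _write_table(
        outdir / "calibration_table.csv",
        report.methods,
        rows=[
            ("YC mean", lambda r: r.qc.yc_mean_cl),
            ("YC SD", lambda r: r.qc.yc_sd_cl),
            ("AD mean", lambda r: r.qc.ad_mean_cl),
            ("R2", lambda r: r.qc.r_squared),
            ("Specificity threshold (95%)", lambda r: r.threshold_set.specificity_cl),
        ],
    )
    _write_table(
        outdir / "longitudinal_table.csv",
        report.methods,
        rows=[
            ("Intra-individual variability", lambda r: r.intra_individual_sd),
            ("Annualized rate of change in A+ group", lambda r: r.mean_annual_rate),
            ("Effect size of annual change", lambda r: r.effect_size),
            ("Sample size (50% reduction in rate)", lambda r: r.sample_size_per_arm),
            ("RW threshold", lambda r: r.threshold_set.rw_cl),
            ("Empirical threshold (CL)", lambda r: r.threshold_set.empirical_cl),
        ],
    )

    manifest = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            rel = str(path.relative_to(outdir))
            manifest[rel] = hashlib.sha256(path.read_bytes()).hexdigest()
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def _write_json(path: Path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def _write_table(path: Path, methods: dict, rows) -> None:
    labels = list(methods)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("quantity," + ",".join(labels) + "\n")
        for name, getter in rows:
            cells = []
            for lbl in labels:
                v = getter(methods[lbl])
                cells.append("" if v is None else repr(v) if isinstance(v, float) else str(v))
            fh.write(name + "," + ",".join(cells) + "\n")
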