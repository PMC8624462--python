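"""End-to-end orchestration: configuration, the full analysis run, and
simulation output writing.

``run_analysis`` executes read -> outlier screening -> per-subject mean-FH
frames -> position R&R -> vertical R&R (both FH planes) -> parallelism ->
report bundle, logging every removed observation and skipped stratum.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from .dataset import AnnotationDataset, write_annotations
from .exceptions import ValidationError
from .model import LandmarkRRModel, LandmarkRRResults
from .rr import DEFAULT_GROSS_MM, DEFAULT_GRUBBS_ALPHA, DEFAULT_MANDEL_ALPHA
from .simulate import SimulationTruth

logger = logging.getLogger("cephrr")


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs."""

    input_path: str
    dialect: str = "csv"
    superior_hint: tuple[float, float, float] = (0.0, 0.0, 1.0)
    gross_mm: float = DEFAULT_GROSS_MM
    grubbs_alpha: float = DEFAULT_GRUBBS_ALPHA
    mandel_alpha: float = DEFAULT_MANDEL_ALPHA
    reliability_thresholds: tuple[float, float] = (1.0, 2.0)
    out_dir: str = "cephrr_report"
    plots: bool = False
    bland_altman_landmarks: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gross_mm", "grubbs_alpha", "mandel_alpha"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        lo, hi = self.reliability_thresholds
        if not (0 < lo < hi):
            raise ValidationError(
                "reliability thresholds must be positive and strictly increasing"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        if "superior_hint" in raw:
            raw["superior_hint"] = tuple(float(v) for v in raw["superior_hint"])
        if "reliability_thresholds" in raw:
            raw["reliability_thresholds"] = tuple(
                float(v) for v in raw["reliability_thresholds"]
            )
        if "bland_altman_landmarks" in raw:
            raw["bland_altman_landmarks"] = tuple(raw["bland_altman_landmarks"])
        return cls(**raw)


def _resolve_input(path: str) -> tuple[str, str]:
    """Accept a file, or a directory containing annotations.csv/xml."""
    if os.path.isdir(path):
        for dialect in ("csv", "xml"):
            candidate = os.path.join(path, f"annotations.{dialect}")
            if os.path.exists(candidate):
                return candidate, dialect
        raise ValidationError(f"no annotations.csv or annotations.xml in {path}")
    if not os.path.exists(path):
        raise ValidationError(f"input path does not exist: {path}")
    dialect = "xml" if str(path).endswith(".xml") else "csv"
    return str(path), dialect


def run_analysis(config: AnalysisConfig) -> LandmarkRRResults:
    """Run the full pipeline and write the report bundle to
    ``config.out_dir``.  Returns the fitted results."""
    input_path, detected = _resolve_input(config.input_path)
    dialect = config.dialect or detected
    if os.path.isdir(config.input_path):
        dialect = detected
    logger.info("reading %s (%s dialect)", input_path, dialect)
    model = LandmarkRRModel.from_files(
        input_path,
        dialect,
        superior_hint=config.superior_hint,
        gross_mm=config.gross_mm,
        grubbs_alpha=config.grubbs_alpha,
        mandel_alpha=config.mandel_alpha,
        reliability_thresholds=config.reliability_thresholds,
    )
    results = model.fit()
    results.save(
        config.out_dir,
        plots=config.plots,
        bland_altman_landmarks=config.bland_altman_landmarks or None,
    )
    summary = results.summary_dict()
    validate_summary(summary)
    logger.info("report bundle written to %s", config.out_dir)
    return results


def write_simulation(
    dataset: AnnotationDataset,
    truth: SimulationTruth,
    out_dir,
    dialect: str = "csv",
) -> None:
    """Write a simulated dataset plus its generative truth to ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    write_annotations(dataset, os.path.join(out_dir, f"annotations.{dialect}"), dialect)
    payload = {
        "seed": truth.seed,
        "sigma_r_default": truth.sigma_r_default,
        "sigma_L_default": truth.sigma_L_default,
        "sigma_r": {k: list(v) for k, v in truth.sigma_r.items()},
        "sigma_L": {k: list(v) for k, v in truth.sigma_L.items()},
        "subject_sd": truth.subject_sd,
        "pose_rot_deg": truth.pose_rot_deg,
        "pose_trans_mm": truth.pose_trans_mm,
        "cant": {"kind": truth.cant.kind, "value": truth.cant.value},
        "outlier_spec": [dataclasses.asdict(inj) for inj in truth.outlier_spec],
        "realized_cant_deg": truth.realized_cant_deg,
    }
    with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


# -- summary schema ------------------------------------------------------------

#: Structural schema of summary.json (types by example); kept minimal and
#: validated with :func:`validate_summary`.
SUMMARY_SCHEMA: dict = {
    "design": {
        "n_subjects": int,
        "n_operators": int,
        "n_sessions": int,
        "n_landmarks": int,
    },
    "outliers_removed": int,
    "position_records": int,
    "reliability_class_counts": dict,
    "worst_record": (dict, type(None)),
    "vertical": dict,
    "parallelism": {
        "angle_mean_deg": float,
        "angle_sd_deg": float,
        "iaf_abs_mean_mm": dict,
        "iaf_abs_sd_mm": dict,
    },
    "thresholds": dict,
}


def validate_summary(obj: dict, schema: dict = SUMMARY_SCHEMA, path: str = "") -> None:
    """Check a summary dict against the structural schema; raises
    :class:`ValidationError` naming the offending key."""
    for key, expected in schema.items():
        where = f"{path}.{key}" if path else key
        if key not in obj:
            raise ValidationError(f"summary lacks key {where!r}")
        value = obj[key]
        if isinstance(expected, dict):
            if not isinstance(value, dict):
                raise ValidationError(f"summary key {where!r} must be an object")
            validate_summary(value, expected, where)
        elif not isinstance(value, expected):
            raise ValidationError(
                f"summary key {where!r} has type {type(value).__name__}"
            )
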