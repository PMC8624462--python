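"""Model / Results interface tying the analysis stages together.

``LandmarkRRModel`` is built from an :class:`AnnotationDataset` (or a tidy
DataFrame, or annotation files); ``fit()`` screens outliers, constructs each
subject's mean-FH frame, estimates the per-landmark/axis variance
components, the vertical-measurement reliability under both FH planes, and
the inter-plane parallelism, returning a ``LandmarkRRResults`` carrying all
of it plus a ``summary()`` table.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from .catalog import LandmarkCatalog
from .dataset import AnnotationDataset, read_annotations
from .geometry import Frame, subject_frames
from .rr import (
    DEFAULT_GROSS_MM,
    DEFAULT_GRUBBS_ALPHA,
    DEFAULT_MANDEL_ALPHA,
    DEFAULT_RELIABILITY_THRESHOLDS,
    AXES,
    BlandAltmanSeries,
    OutlierReport,
    RRTable,
    apply_outliers,
    bland_altman,
    rr_table,
    screen_outliers,
)
from .vertical import ParallelismResult, parallelism, vertical_rr

logger = logging.getLogger("cephrr")


class LandmarkRRModel:
    """Repeatability & reproducibility model for a multi-operator 3D
    landmarking study.

    Parameters
    ----------
    dataset : AnnotationDataset
        One row per (subject, operator, session, landmark).
    superior_hint : 3-vector
        Direction pointing toward the head in scanner coordinates, used to
        orient the FH normal (default scanner +z).
    gross_mm, grubbs_alpha, mandel_alpha
        Outlier-screening thresholds; see :func:`cephrr.rr.screen_outliers`.
    reliability_thresholds : (float, float)
        Boundaries (mm) of the acceptable / useful / caution classes.
    screen : bool
        Whether to run outlier screening before estimation.
    """

    def __init__(
        self,
        dataset: AnnotationDataset,
        *,
        superior_hint=(0.0, 0.0, 1.0),
        gross_mm: float = DEFAULT_GROSS_MM,
        grubbs_alpha: float = DEFAULT_GRUBBS_ALPHA,
        mandel_alpha: float = DEFAULT_MANDEL_ALPHA,
        reliability_thresholds: tuple[float, float] = DEFAULT_RELIABILITY_THRESHOLDS,
        screen: bool = True,
    ) -> None:
        self.dataset = dataset
        self.superior_hint = tuple(float(v) for v in superior_hint)
        self.gross_mm = gross_mm
        self.grubbs_alpha = grubbs_alpha
        self.mandel_alpha = mandel_alpha
        self.reliability_thresholds = tuple(reliability_thresholds)
        self.screen = screen

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, catalog: LandmarkCatalog | None = None, **kwargs
    ) -> "LandmarkRRModel":
        from .catalog import default_catalog

        return cls(AnnotationDataset(frame, catalog or default_catalog()), **kwargs)

    @classmethod
    def from_files(cls, path, dialect: str = "csv", **kwargs) -> "LandmarkRRModel":
        return cls(read_annotations(path, dialect), **kwargs)

    def fit(self) -> "LandmarkRRResults":
        if self.screen:
            report = screen_outliers(
                self.dataset, self.gross_mm, self.grubbs_alpha, self.mandel_alpha
            )
            clean = apply_outliers(self.dataset, report)
        else:
            report = OutlierReport(
                pd.DataFrame(
                    columns=["subject_id", "operator_id", "session_id", "landmark",
                             "rule", "axis", "statistic", "advisory"]
                )
            )
            clean = self.dataset
        frames = subject_frames(clean, self.superior_hint)
        position = rr_table(clean, frames, self.reliability_thresholds)
        vertical = vertical_rr(clean, self.superior_hint, self.reliability_thresholds)
        par = parallelism(clean, self.superior_hint)
        return LandmarkRRResults(
            model=self,
            dataset=clean,
            outliers=report,
            frames=frames,
            position=position,
            vertical=vertical,
            parallelism=par,
        )


@dataclass
class LandmarkRRResults:
    """Fitted reliability estimates and diagnostics."""

    model: LandmarkRRModel
    dataset: AnnotationDataset  # after outlier removal
    outliers: OutlierReport
    frames: dict[str, Frame]
    position: RRTable
    vertical: dict[str, RRTable]
    parallelism: ParallelismResult

    # -- derived --------------------------------------------------------------

    def bland_altman(self, landmark: str, axis: str) -> BlandAltmanSeries:
        """Per-repetition deviations from the subject mean for one landmark
        coordinate, with +/- 2 s_R limits."""
        return bland_altman(self.dataset, landmark, axis, self.frames)

    def class_counts(self) -> pd.Series:
        """Number of (landmark, axis) position records per reliability class."""
        return self.position.records["reliability_class"].value_counts()

    # -- reporting ------------------------------------------------------------

    def summary_dict(self) -> dict:
        records = self.position.records
        worst = records.loc[records["repro_2sd"].idxmax()] if len(records) else None
        return {
            "design": {
                "n_subjects": self.dataset.design[0],
                "n_operators": self.dataset.design[1],
                "n_sessions": self.dataset.design[2],
                "n_landmarks": len(self.dataset.catalog),
            },
            "outliers_removed": int(len(self.outliers.removal_keys)),
            "position_records": int(len(records)),
            "reliability_class_counts": {
                k: int(v) for k, v in sorted(self.class_counts().items())
            },
            "worst_record": (
                None
                if worst is None
                else {
                    "landmark": worst["landmark"],
                    "axis": worst["axis"],
                    "repro_2sd_mm": float(worst["repro_2sd"]),
                }
            ),
            "vertical": {
                name: {
                    "max_repet_2sd_mm": float(tab.records["repet_2sd"].max()),
                    "max_repro_2sd_mm": float(tab.records["repro_2sd"].max()),
                }
                for name, tab in sorted(self.vertical.items())
            },
            "parallelism": {
                "angle_mean_deg": self.parallelism.angle_mean_deg,
                "angle_sd_deg": self.parallelism.angle_sd_deg,
                "iaf_abs_mean_mm": self.parallelism.iaf_abs_mean_mm,
                "iaf_abs_sd_mm": self.parallelism.iaf_abs_sd_mm,
            },
            "thresholds": {
                "gross_mm": self.model.gross_mm,
                "grubbs_alpha": self.model.grubbs_alpha,
                "mandel_alpha": self.model.mandel_alpha,
                "reliability_mm": list(self.model.reliability_thresholds),
            },
        }

    def summary(self) -> str:
        d = self.summary_dict()
        lines = [
            "Landmark repeatability & reproducibility (ISO 5725-type analysis)",
            "=" * 66,
            "Design: {n_subjects} subjects x {n_operators} operators x "
            "{n_sessions} sessions, {n_landmarks} landmarks".format(**d["design"]),
            f"Outlier observations removed: {d['outliers_removed']}",
            "",
            "Position reliability (per landmark/axis, 2xSD in mm):",
        ]
        for cls in ("acceptable", "useful", "caution"):
            n = d["reliability_class_counts"].get(cls, 0)
            lines.append(f"  {cls:<11}: {n:3d} records")
        if d["worst_record"]:
            w = d["worst_record"]
            lines.append(
                f"  worst      : {w['landmark']} ({w['axis']}) "
                f"repro 2xSD = {w['repro_2sd_mm']:.2f} mm"
            )
        lines.append("")
        lines.append("Vertical measurements (2xSD in mm):")
        for name, v in d["vertical"].items():
            lines.append(
                f"  {name:<12}: max repet {v['max_repet_2sd_mm']:.2f}, "
                f"max repro {v['max_repro_2sd_mm']:.2f}"
            )
        p = d["parallelism"]
        lines.append("")
        lines.append(
            "FH-plane parallelism: |angle| = "
            f"{p['angle_mean_deg']:.2f} deg (SD {p['angle_sd_deg']:.2f})"
        )
        for side in sorted(p["iaf_abs_mean_mm"]):
            lines.append(
                f"  {side} |vertical|: {p['iaf_abs_mean_mm'][side]:.2f} mm "
                f"(SD {p['iaf_abs_sd_mm'][side]:.2f})"
            )
        return "\n".join(lines)

    def save(self, out_dir, plots: bool = False, bland_altman_landmarks=None) -> None:
        """Write the full report bundle to ``out_dir``.

        ``rr_table.csv``, ``vertical_conventional.csv``, ``vertical_novel.csv``,
        ``outliers.csv``, ``parallelism.json``, ``summary.json``,
        ``summary.txt`` and (optionally) per-landmark Bland-Altman series
        under ``bland_altman/``.
        """
        os.makedirs(out_dir, exist_ok=True)
        self.position.to_csv(os.path.join(out_dir, "rr_table.csv"))
        for name, tab in self.vertical.items():
            tab.to_csv(os.path.join(out_dir, f"vertical_{name}.csv"))
        self.outliers.to_csv(os.path.join(out_dir, "outliers.csv"))
        self.parallelism.to_json(os.path.join(out_dir, "parallelism.json"))
        with open(os.path.join(out_dir, "summary.json"), "w", encoding="utf-8") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
        with open(os.path.join(out_dir, "summary.txt"), "w", encoding="utf-8") as fh:
            fh.write(self.summary() + "\n")

        if bland_altman_landmarks is None and plots:
            bland_altman_landmarks = self.dataset.catalog.names
        if bland_altman_landmarks:
            ba_dir = os.path.join(out_dir, "bland_altman")
            os.makedirs(ba_dir, exist_ok=True)
            for lm in bland_altman_landmarks:
                for axis in AXES:
                    try:
                        series = self.bland_altman(lm, axis)
                    except Exception as exc:  # stratum may be empty
                        logger.warning("Bland-Altman %s/%s skipped: %s", lm, axis, exc)
                        continue
                    series.to_csv(os.path.join(ba_dir, f"{lm}_{axis}.csv"))
                    if plots:
                        import matplotlib

                        matplotlib.use("Agg", force=False)
                        import matplotlib.pyplot as plt

                        ax = series.plot()
                        ax.figure.savefig(
                            os.path.join(ba_dir, f"{lm}_{axis}.png"), dpi=100,
                            bbox_inches="tight",
                        )
                        plt.close(ax.figure)
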