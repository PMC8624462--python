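"""Vertical-measurement reliability under two Frankfort Horizontal planes,
and parallelism between them.

For every subject, operator and session, two reference planes are built from
that session's own landmarks:

* conventional FH: Or-L, Po-R, Po-L;
* novel FH: Or-R, Or-L, mid-IAF (midpoint of the internal acoustic foramina).

Each landmark's *vertical measurement* is its signed orthogonal distance to
the reference plane; repeatability/reproducibility of these scalars is then
computed per landmark exactly as for coordinates.  Parallelism between the
two planes is assessed per subject from the 6-repetition mean landmarks: the
signed distances of the IAF points to the mean conventional plane, and the
absolute angle between the two mean planes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import AnnotationDataset
from .exceptions import MissingLandmarkError, ValidationError
from .geometry import (
    Plane,
    angle_between_planes,
    mean_landmark,
    midpoint,
    plane_from_points,
    signed_vertical_distance,
)
from .rr import DEFAULT_RELIABILITY_THRESHOLDS, RRTable, _records_from_long

logger = logging.getLogger("cephrr")

CONVENTIONAL_FH_LANDMARKS = ("Or-L", "Po-R", "Po-L")
NOVEL_FH_LANDMARKS = ("Or-R", "Or-L", "IAF-L", "IAF-R")
PLANES = ("conventional", "novel")


def _session_points(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        row.landmark: np.array([row.x_mm, row.y_mm, row.z_mm])
        for row in df.itertuples(index=False)
    }


def _planes_from_points(points: dict[str, np.ndarray], superior_hint) -> tuple[Plane, Plane]:
    conventional = plane_from_points(
        points["Or-L"], points["Po-R"], points["Po-L"], orient_hint=superior_hint
    )
    novel = plane_from_points(
        points["Or-R"],
        points["Or-L"],
        midpoint(points["IAF-L"], points["IAF-R"]),
        orient_hint=superior_hint,
    )
    return conventional, novel


def session_planes(
    dataset: AnnotationDataset,
    subject: str,
    operator: str,
    session: str,
    superior_hint=(0.0, 0.0, 1.0),
) -> tuple[Plane, Plane]:
    """(conventional, novel) FH planes from one session's raw landmarks."""
    df = dataset.active
    sel = df[
        (df["subject_id"] == str(subject))
        & (df["operator_id"] == str(operator))
        & (df["session_id"] == str(session))
    ]
    points = _session_points(sel)
    required = set(CONVENTIONAL_FH_LANDMARKS) | set(NOVEL_FH_LANDMARKS)
    missing = sorted(required - set(points))
    if missing:
        raise MissingLandmarkError(
            f"session {subject}/{operator}/{session} lacks plane landmarks: {missing}"
        )
    return _planes_from_points(points, superior_hint)


def vertical_measurements(
    dataset: AnnotationDataset, superior_hint=(0.0, 0.0, 1.0)
) -> pd.DataFrame:
    """Signed vertical distances of every landmark to both session planes.

    Long table with columns ``subject, operator, session, landmark, plane,
    value`` (mm).  Sessions lacking a required plane landmark are skipped
    with a logged reason.
    """
    df = dataset.active
    rows = []
    for (subject, operator, session), grp in df.groupby(
        ["subject_id", "operator_id", "session_id"]
    ):
        points = _session_points(grp)
        required = set(CONVENTIONAL_FH_LANDMARKS) | set(NOVEL_FH_LANDMARKS)
        missing = sorted(required - set(points))
        if missing:
            logger.info(
                "session %s/%s/%s skipped for vertical analysis: missing %s",
                subject, operator, session, missing,
            )
            continue
        conventional, novel = _planes_from_points(points, superior_hint)
        names = list(points)
        pts = np.array([points[n] for n in names])
        for plane_name, plane in (("conventional", conventional), ("novel", novel)):
            dists = signed_vertical_distance(plane, pts)
            for name, d in zip(names, dists):
                rows.append(
                    {
                        "subject": subject,
                        "operator": operator,
                        "session": session,
                        "landmark": name,
                        "plane": plane_name,
                        "value": float(d),
                    }
                )
    return pd.DataFrame(
        rows, columns=["subject", "operator", "session", "landmark", "plane", "value"]
    )


def vertical_rr(
    dataset: AnnotationDataset,
    superior_hint=(0.0, 0.0, 1.0),
    thresholds: tuple[float, float] = DEFAULT_RELIABILITY_THRESHOLDS,
) -> dict[str, RRTable]:
    """Vertical-measurement R&R per landmark, one table per reference plane.

    The measurand is the *signed* distance (folding to absolute values would
    turn sign noise near zero into spurious bias); records carry
    ``axis="vertical"``.
    """
    long = vertical_measurements(dataset, superior_hint)
    if long.empty:
        raise ValidationError("no session had all plane-defining landmarks")
    tables: dict[str, RRTable] = {}
    for plane_name in PLANES:
        sub = long[long["plane"] == plane_name].copy()
        sub["axis"] = "vertical"
        records = _records_from_long(sub, thresholds)
        tables[plane_name] = RRTable(records, design=dataset.design, reference=plane_name)
    return tables


@dataclass
class ParallelismResult:
    """Per-subject parallelism between the two mean FH planes.

    ``distances`` holds the signed vertical distance of every IAF
    observation to its subject's mean conventional plane; ``per_subject``
    the absolute-mean distances and the inter-plane angle; the cohort
    summary is the mean and SD of the absolute angles.
    """

    distances: pd.DataFrame  # subject, operator, session, landmark, value
    per_subject: pd.DataFrame  # subject, angle_deg, abs_iaf_l_mm, abs_iaf_r_mm
    angle_mean_deg: float
    angle_sd_deg: float
    iaf_abs_mean_mm: dict
    iaf_abs_sd_mm: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "angle_mean_deg": self.angle_mean_deg,
                "angle_sd_deg": self.angle_sd_deg,
                "iaf_abs_mean_mm": self.iaf_abs_mean_mm,
                "iaf_abs_sd_mm": self.iaf_abs_sd_mm,
                "per_subject": self.per_subject.to_dict(orient="records"),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    def plot(self, ax=None):
        """IAF vertical distances per subject (both sides, all repetitions)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        subjects = sorted(self.distances["subject"].unique())
        pos = {s: i + 1 for i, s in enumerate(subjects)}
        for side, color in (("IAF-L", "tab:blue"), ("IAF-R", "tab:orange")):
            sel = self.distances[self.distances["landmark"] == side]
            ax.scatter(
                sel["subject"].map(pos), sel["value"], s=12, alpha=0.7,
                color=color, label=side,
            )
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel("subject")
        ax.set_ylabel("vertical distance to mean conventional FH (mm)")
        ax.legend()
        return ax


def parallelism(
    dataset: AnnotationDataset, superior_hint=(0.0, 0.0, 1.0)
) -> ParallelismResult:
    """Assess parallelism between the conventional and novel FH planes.

    Per subject (mean landmarks over all usable repetitions): the angle
    between the mean conventional and mean novel planes, and the signed
    vertical distances of every IAF observation to the mean conventional
    plane.  Subjects lacking the required landmarks are excluded (logged).
    """
    dist_rows = []
    subj_rows = []
    df = dataset.active
    for subject in dataset.subjects:
        try:
            means = {
                name: mean_landmark(dataset, subject, name)
                for name in ("Or-L", "Or-R", "Po-R", "Po-L", "IAF-L", "IAF-R")
            }
        except MissingLandmarkError as exc:
            logger.info("subject %s excluded from parallelism: %s", subject, exc)
            continue
        conventional, novel = _planes_from_points(means, superior_hint)
        angle = angle_between_planes(conventional, novel)

        sel = df[
            (df["subject_id"] == subject) & (df["landmark"].isin(["IAF-L", "IAF-R"]))
        ]
        pts = sel[["x_mm", "y_mm", "z_mm"]].to_numpy()
        dists = signed_vertical_distance(conventional, pts)
        for (_, rec), d in zip(sel.iterrows(), dists):
            dist_rows.append(
                {
                    "subject": subject,
                    "operator": rec["operator_id"],
                    "session": rec["session_id"],
                    "landmark": rec["landmark"],
                    "value": float(d),
                }
            )
        by_side = (
            pd.DataFrame(dist_rows)
            .query("subject == @subject")
            .assign(absval=lambda d: d["value"].abs())
            .groupby("landmark")["absval"]
            .mean()
        )
        subj_rows.append(
            {
                "subject": subject,
                "angle_deg": angle,
                "abs_iaf_l_mm": float(by_side.get("IAF-L", np.nan)),
                "abs_iaf_r_mm": float(by_side.get("IAF-R", np.nan)),
            }
        )

    if not subj_rows:
        raise ValidationError("no subject had the landmarks required for parallelism")
    per_subject = pd.DataFrame(subj_rows)
    distances = pd.DataFrame(
        dist_rows, columns=["subject", "operator", "session", "landmark", "value"]
    )
    abs_d = distances.assign(absval=distances["value"].abs())
    grp = abs_d.groupby("landmark")["absval"]
    angles = per_subject["angle_deg"]
    return ParallelismResult(
        distances=distances,
        per_subject=per_subject,
        angle_mean_deg=float(angles.mean()),
        angle_sd_deg=float(angles.std(ddof=1)) if len(angles) > 1 else 0.0,
        iaf_abs_mean_mm={k: float(v) for k, v in grp.mean().items()},
        iaf_abs_sd_mm={k: float(v) for k, v in grp.std(ddof=1).fillna(0.0).items()},
    )
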