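"""Synthetic multi-operator landmark annotation datasets with known truth.

The generator follows the variance-component model the analysis estimates:

    y = m_j + B_i + e_ijk

* ``m_j`` — subject j's true landmark positions: a template skull plus
  per-landmark anatomical offsets and a random rigid pose;
* ``B_i`` — a persistent operator bias per landmark/axis, shared across
  subjects and sessions (the "laboratory" effect), SD ``sigma_L``;
* ``e_ijk`` — independent session noise, SD ``sigma_r``.

Operator bias and session noise are drawn in the subject's anatomical frame
and the rigid pose is applied afterwards, so per-axis components stated in
anatomical coordinates are the ones the FH-reoriented analysis estimates.

Optionally the internal-acoustic-foramen (IAF) pair is tilted about the
inter-orbital axis so the novel FH plane makes a known *cant* angle with the
conventional FH plane, and gross-error offsets can be injected for chosen
operators/sessions/subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .catalog import default_catalog
from .dataset import ALL_COLUMNS, AnnotationDataset
from .exceptions import ValidationError

import pandas as pd


# -- template ------------------------------------------------------------------

#: Plausible adult craniofacial coordinates, mm, in a scanner-like frame:
#: +x left, +y posterior, +z superior, origin near mid-porion.  Synthetic
#: values chosen to satisfy anatomical ordering (FH plane near-horizontal,
#: IAF medial to porion, dental landmarks inferior-anterior); not measured
#: from any subject.
_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "Po-R": (-33.0, 0.0, 0.0),
    "Po-L": (33.0, 0.0, 0.0),
    "Or-R": (-30.0, -68.0, -3.0),
    "Or-L": (30.0, -68.0, -3.0),
    "IAF-R": (-12.0, -6.0, 1.0),
    "IAF-L": (12.0, -6.0, 1.0),
    "Na": (0.0, -72.0, 18.0),
    "S": (0.0, -22.0, 12.0),
    "ANS": (0.0, -82.0, -25.0),
    "PNS": (0.0, -38.0, -26.0),
    "A": (0.0, -80.0, -32.0),
    "B": (0.0, -78.0, -60.0),
    "Pog": (0.0, -80.0, -72.0),
    "Gn": (0.0, -79.0, -76.0),
    "Me": (0.0, -76.0, -80.0),
    "Go-R": (-45.0, -12.0, -55.0),
    "Go-L": (45.0, -12.0, -55.0),
    "IF-R": (-25.0, -65.0, -12.0),
    "IF-L": (25.0, -65.0, -12.0),
    "MF-R": (-22.0, -70.0, -62.0),
    "MF-L": (22.0, -70.0, -62.0),
    "11E": (-4.0, -84.0, -45.0),
    "21E": (4.0, -84.0, -45.0),
    "31E": (4.0, -83.0, -47.0),
    "41E": (-4.0, -83.0, -47.0),
    "11A": (-4.0, -80.0, -33.0),
    "21A": (4.0, -80.0, -33.0),
    "31A": (4.0, -79.0, -60.0),
    "41A": (-4.0, -79.0, -60.0),
    "16O": (-28.0, -52.0, -43.0),
    "26O": (28.0, -52.0, -43.0),
    "36O": (30.0, -50.0, -46.0),
    "46O": (-30.0, -50.0, -46.0),
}


def default_template() -> dict[str, np.ndarray]:
    """Template skull: one 3-vector (mm, scanner-like frame) per landmark."""
    return {k: np.array(v, dtype=float) for k, v in _TEMPLATE.items()}


# -- specification -------------------------------------------------------------


@dataclass(frozen=True)
class CantSpec:
    """Injected tilt of the IAF pair against the conventional FH plane.

    ``kind`` is ``"none"`` (leave the template's natural IAF positions),
    ``"fixed"`` (every subject gets exactly ``value`` degrees) or
    ``"half_normal"`` (per-subject |N(0, value^2)| degrees).
    """

    kind: str = "none"
    value: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "fixed", "half_normal"):
            raise ValidationError(f"unknown cant kind {self.kind!r}")
        if self.value < 0:
            raise ValidationError("cant value must be >= 0")


@dataclass(frozen=True)
class OutlierInjection:
    """A gross-error offset added to chosen observations (anatomical frame)."""

    operator_id: str
    session_id: str
    landmarks: tuple[str, ...]
    offset: tuple[float, float, float]
    subjects: tuple[str, ...]


@dataclass
class SimulationTruth:
    """Generative parameters for one simulated study.

    ``sigma_r`` / ``sigma_L`` map landmark name -> per-axis SD 3-vector
    (mm); landmarks absent from the map fall back to ``sigma_r_default`` /
    ``sigma_L_default``.  ``subject_sd`` is the SD of per-landmark
    anatomical offsets; the rigid pose draws rotations within
    ``pose_rot_deg`` degrees per axis and translations within
    ``pose_trans_mm`` mm.  ``realized_cant_deg`` is filled in by
    :func:`simulate` with the angle actually achieved per subject.
    """

    template: dict[str, np.ndarray] = field(default_factory=default_template)
    sigma_r_default: float = 0.15
    sigma_L_default: float = 0.10
    sigma_r: dict[str, np.ndarray] = field(default_factory=dict)
    sigma_L: dict[str, np.ndarray] = field(default_factory=dict)
    subject_sd: float = 4.0
    pose_rot_deg: float = 10.0
    pose_trans_mm: float = 20.0
    cant: CantSpec = field(default_factory=CantSpec)
    outlier_spec: tuple[OutlierInjection, ...] = ()
    seed: int = 0
    realized_cant_deg: dict[str, float] | None = None

    def __post_init__(self):
        catalog = default_catalog()
        missing = sorted(set(catalog.names) - set(self.template))
        if missing:
            raise ValidationError(f"template lacks landmarks: {missing}")
        if self.sigma_r_default < 0 or self.sigma_L_default < 0 or self.subject_sd < 0:
            raise ValidationError("SDs must be non-negative")
        for name, table in (("sigma_r", self.sigma_r), ("sigma_L", self.sigma_L)):
            for lm, v in table.items():
                arr = np.asarray(v, dtype=float)
                if arr.shape != (3,) or (arr < 0).any():
                    raise ValidationError(
                        f"{name}[{lm!r}] must be a non-negative 3-vector"
                    )
                table[lm] = arr
        # bilateral template points should be mirror-plausible about x=0
        for d in catalog:
            if d.name.endswith("-L"):
                other = d.name[:-2] + "-R"
                if other in self.template:
                    x_sum = self.template[d.name][0] + self.template[other][0]
                    if abs(x_sum) >= 10.0:
                        raise ValidationError(
                            f"template {d.name}/{other} not mirror-plausible "
                            f"(|x_L + x_R| = {abs(x_sum):.1f} mm)"
                        )

    def sigma_arrays(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(n_landmarks, 3) arrays of sigma_r and sigma_L in catalog order."""
        s_r = np.array(
            [self.sigma_r.get(n, np.full(3, self.sigma_r_default)) for n in names]
        )
        s_L = np.array(
            [self.sigma_L.get(n, np.full(3, self.sigma_L_default)) for n in names]
        )
        return s_r, s_L


# -- geometry helpers ----------------------------------------------------------


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation from per-axis angles in radians (applied x, then y, then z)."""
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _rotate_about_axis(points: np.ndarray, axis_point: np.ndarray,
                       axis_dir: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of points about the line (axis_point, axis_dir)."""
    k = axis_dir / np.linalg.norm(axis_dir)
    p = points - axis_point
    cos, sin = math.cos(angle_rad), math.sin(angle_rad)
    rotated = p * cos + np.cross(k, p) * sin + np.outer(p @ k, k) * (1 - cos)
    return rotated + axis_point


def _plane_normal(p1, p2, p3) -> np.ndarray:
    n = np.cross(p2 - p1, p3 - p1)
    return n / np.linalg.norm(n)


def _apply_cant(points: dict[str, np.ndarray], angle_deg: float) -> None:
    """Tilt the IAF pair so the novel FH plane makes exactly ``angle_deg``
    with the subject's conventional FH plane.

    The subject's true Or-R is constrained onto the conventional plane (both
    orbitale points are near-coplanar with FH by anatomical definition), so
    the inter-orbital axis lies in that plane; the IAF points are projected
    onto the plane (zero-cant baseline) and rotated about the axis, giving a
    dihedral angle equal to ``angle_deg`` to machine precision.
    """
    n = _plane_normal(points["Or-L"], points["Po-R"], points["Po-L"])
    anchor = points["Or-L"]
    points["Or-R"] = points["Or-R"] - ((points["Or-R"] - anchor) @ n) * n
    iaf = np.vstack([points["IAF-L"], points["IAF-R"]])
    iaf = iaf - np.outer((iaf - anchor) @ n, n)  # project onto conventional plane
    iaf = _rotate_about_axis(
        iaf, points["Or-R"], points["Or-L"] - points["Or-R"], math.radians(angle_deg)
    )
    points["IAF-L"], points["IAF-R"] = iaf[0], iaf[1]


def _realized_cant(points: dict[str, np.ndarray]) -> float:
    n_conv = _plane_normal(points["Or-L"], points["Po-R"], points["Po-L"])
    mid_iaf = (points["IAF-L"] + points["IAF-R"]) / 2.0
    n_novel = _plane_normal(points["Or-R"], points["Or-L"], mid_iaf)
    c = abs(float(n_conv @ n_novel))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# -- generator -----------------------------------------------------------------


def simulate(
    truth: SimulationTruth,
    n_subjects: int = 20,
    n_operators: int = 3,
    n_sessions: int = 2,
) -> tuple[AnnotationDataset, SimulationTruth]:
    """Draw a full annotation dataset from ``truth``.

    Returns the dataset and a copy of the truth with the realized
    per-subject cant angles filled in.  Fully deterministic given
    ``truth.seed`` and the design counts.
    """
    if min(n_subjects, n_operators, n_sessions) < 1:
        raise ValidationError("design counts must be >= 1")
    rng = np.random.default_rng(truth.seed)
    catalog = default_catalog()
    names = catalog.names
    n_lm = len(names)
    template = np.array([truth.template[n] for n in names])
    s_r, s_L = truth.sigma_arrays(names)

    width = max(2, len(str(n_subjects)))
    subjects = [f"S{i + 1:0{width}d}" for i in range(n_subjects)]
    operators = [f"O{i + 1}" for i in range(n_operators)]
    sessions = [f"{i + 1}" for i in range(n_sessions)]
    name_index = {n: i for i, n in enumerate(names)}

    # persistent operator biases (anatomical frame)
    biases = {op: rng.normal(0.0, s_L) for op in operators}

    rows = []
    realized: dict[str, float] = {}
    for subject in subjects:
        offsets = (
            rng.normal(0.0, truth.subject_sd, (n_lm, 3))
            if truth.subject_sd > 0
            else np.zeros((n_lm, 3))
        )
        true_pts = {n: template[i] + offsets[i] for i, n in enumerate(names)}

        if truth.cant.kind == "fixed":
            _apply_cant(true_pts, truth.cant.value)
        elif truth.cant.kind == "half_normal":
            _apply_cant(true_pts, abs(rng.normal(0.0, truth.cant.value)))
        realized[subject] = _realized_cant(true_pts)

        true_arr = np.array([true_pts[n] for n in names])

        if truth.pose_rot_deg > 0:
            rx, ry, rz = np.radians(
                rng.uniform(-truth.pose_rot_deg, truth.pose_rot_deg, 3)
            )
            R = _rotation_matrix(rx, ry, rz)
        else:
            R = np.eye(3)
        t = (
            rng.uniform(-truth.pose_trans_mm, truth.pose_trans_mm, 3)
            if truth.pose_trans_mm > 0
            else np.zeros(3)
        )

        for operator in operators:
            for session in sessions:
                noise = rng.normal(0.0, s_r) if s_r.any() else np.zeros((n_lm, 3))
                obs = true_arr + biases[operator] + noise
                for inj in truth.outlier_spec:
                    if (
                        inj.operator_id == operator
                        and inj.session_id == session
                        and subject in inj.subjects
                    ):
                        for lm in inj.landmarks:
                            obs[name_index[lm]] = obs[name_index[lm]] + np.asarray(
                                inj.offset, dtype=float
                            )
                scanner = obs @ R.T + t
                for i, name in enumerate(names):
                    rows.append(
                        (subject, operator, session, name,
                         scanner[i, 0], scanner[i, 1], scanner[i, 2], False, False)
                    )

    frame = pd.DataFrame(rows, columns=ALL_COLUMNS)
    dataset = AnnotationDataset(frame, catalog)
    return dataset, replace(truth, realized_cant_deg=realized)


# -- packaged scenario ---------------------------------------------------------


def paperlike_scenario(seed: int = 0) -> SimulationTruth:
    """A study-like scenario: 20 subjects x 3 operators x 2 sessions.

    Anisotropic noise echoes the qualitative pattern of a real landmarking
    study — orbitale and porion are poorly localized along the rim/canal
    direction (x), gonion along y/z, B point along z — while dental and
    foraminal landmarks are precise.  One operator misread the mental
    foramen definition in their first session for subjects 4-20, producing
    an 8 mm gross error, and the IAF pair carries a per-subject cant of
    |N(0, 2.4 deg)| against the conventional FH plane.
    """

    def v(x, y, z):
        return np.array([x, y, z])

    sigma_r = {
        "Or-L": v(1.00, 0.50, 0.20), "Or-R": v(1.00, 0.50, 0.20),
        "Po-L": v(1.15, 0.50, 0.30), "Po-R": v(1.15, 0.50, 0.30),
        "Go-L": v(0.30, 0.70, 0.95), "Go-R": v(0.30, 0.70, 0.95),
        "B": v(0.32, 0.28, 1.20),
        "IAF-L": v(0.26, 0.42, 0.40), "IAF-R": v(0.26, 0.42, 0.40),
    }
    sigma_L = {
        "Or-L": v(1.35, 0.75, 0.20), "Or-R": v(1.35, 0.75, 0.20),
        "Po-L": v(0.75, 0.50, 0.20), "Po-R": v(0.75, 0.50, 0.20),
        "Go-L": v(0.30, 0.65, 0.90), "Go-R": v(0.30, 0.65, 0.90),
        "B": v(0.45, 0.15, 0.75),
        "IAF-L": v(0.30, 0.35, 0.40), "IAF-R": v(0.30, 0.35, 0.40),
    }
    mf_outlier = OutlierInjection(
        operator_id="O3",
        session_id="1",
        landmarks=("MF-R", "MF-L"),
        offset=(0.0, 8.0, 0.0),
        subjects=tuple(f"S{i:02d}" for i in range(4, 21)),
    )
    return SimulationTruth(
        sigma_r=sigma_r,
        sigma_L=sigma_L,
        sigma_r_default=0.15,
        sigma_L_default=0.10,
        subject_sd=4.0,
        pose_rot_deg=10.0,
        pose_trans_mm=20.0,
        cant=CantSpec("half_normal", 2.4),
        outlier_spec=(mf_outlier,),
        seed=seed,
    )
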