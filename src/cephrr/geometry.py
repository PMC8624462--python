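"""Planes, frames and rigid transforms for Frankfort-Horizontal reorientation.

The Frankfort Horizontal (FH) plane is the standard horizontal reference for
craniofacial imaging.  Two constructions are used here:

* the *conventional* FH plane through left orbitale and both porions
  (Or-L, Po-R, Po-L);
* a *novel* FH plane through both orbitale points and the midpoint of the
  internal acoustic foramina (Or-R, Or-L, mid-IAF).

A subject-specific orthonormal frame is anchored at mid-porion with the
x axis running right-to-left along the porion axis, the z axis along the FH
normal (superior), and y = z x x (front-to-back).  Transforming landmark
coordinates into this frame is a rigid map, so distances and angles are
preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import AnnotationDataset
from .exceptions import (
    DegenerateGeometryError,
    MissingLandmarkError,
    OrientationAmbiguousError,
)

_AREA_TOL = 1e-6  # mm^2; triangles smaller than this are treated as degenerate
_HINT_TOL = 1e-6  # |hint . normal| below this cannot fix the normal's sign


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class Plane:
    """An oriented plane: a point on it plus a unit normal."""

    anchor: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", _as_vec(self.anchor))
        n = _as_vec(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise DegenerateGeometryError("plane normal must be a unit vector")
        object.__setattr__(self, "normal", n)

    def to_json(self) -> str:
        return json.dumps({"anchor": self.anchor.tolist(), "normal": self.normal.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Plane":
        d = json.loads(text)
        return cls(np.array(d["anchor"]), np.array(d["normal"]))


@dataclass(frozen=True)
class Frame:
    """A right-handed orthonormal coordinate frame (origin + axis triad)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", _as_vec(self.origin))
        axes = [_as_vec(a) for a in (self.x_axis, self.y_axis, self.z_axis)]
        for name, a in zip(("x_axis", "y_axis", "z_axis"), axes):
            if abs(np.linalg.norm(a) - 1.0) > 1e-10:
                raise DegenerateGeometryError(f"{name} must be a unit vector")
            object.__setattr__(self, name, a)
        x, y, z = axes
        if (
            abs(x @ y) > 1e-10
            or abs(y @ z) > 1e-10
            or abs(x @ z) > 1e-10
            or np.linalg.norm(np.cross(x, y) - z) > 1e-10
        ):
            raise DegenerateGeometryError("axes must form a right-handed orthonormal triad")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with the axes as rows; maps world to frame coordinates."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])

    def to_json(self) -> str:
        return json.dumps(
            {
                "origin": self.origin.tolist(),
                "x_axis": self.x_axis.tolist(),
                "y_axis": self.y_axis.tolist(),
                "z_axis": self.z_axis.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Frame":
        d = json.loads(text)
        return cls(*(np.array(d[k]) for k in ("origin", "x_axis", "y_axis", "z_axis")))


def midpoint(p, q) -> np.ndarray:
    """Componentwise midpoint (p + q) / 2."""
    return (_as_vec(p) + _as_vec(q)) / 2.0


def plane_from_points(p1, p2, p3, orient_hint=None) -> Plane:
    """Plane through three non-collinear points.

    The anchor is the centroid; without ``orient_hint`` the normal sign
    follows the right-hand rule on (p2-p1, p3-p1), with a hint it is chosen
    so that ``normal . orient_hint > 0``.
    """
    p1, p2, p3 = _as_vec(p1), _as_vec(p2), _as_vec(p3)
    cross = np.cross(p2 - p1, p3 - p1)
    area = np.linalg.norm(cross) / 2.0
    if area <= _AREA_TOL:
        raise DegenerateGeometryError(
            f"points are collinear or coincident (triangle area {area:.3g} mm^2)"
        )
    normal = cross / np.linalg.norm(cross)
    if orient_hint is not None:
        d = normal @ _as_vec(orient_hint)
        if abs(d) < _HINT_TOL:
            raise OrientationAmbiguousError(
                "orient_hint is orthogonal to the plane normal"
            )
        if d < 0:
            normal = -normal
    return Plane((p1 + p2 + p3) / 3.0, normal)


def signed_vertical_distance(plane: Plane, p) -> float | np.ndarray:
    """Signed orthogonal distance from ``p`` to ``plane`` (positive along the
    normal, i.e. superior for a head-oriented FH plane).

    ``p`` may be a single 3-vector or an (n, 3) array of points.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        return float((p - plane.anchor) @ plane.normal)
    return (p - plane.anchor) @ plane.normal


def angle_between_planes(a: Plane, b: Plane) -> float:
    """Absolute dihedral angle between two planes, degrees in [0, 90]."""
    c = abs(float(a.normal @ b.normal))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def build_fh_frame(por_r, por_l, orb_l, superior_hint=(0.0, 0.0, 1.0)) -> Frame:
    """FH-based subject frame from right/left porion and left orbitale.

    Origin at mid-porion; x from Po-R toward Po-L (right-to-left); z along
    the FH-plane normal, signed so ``z . superior_hint > 0``; y = z x x.
    """
    por_r, por_l, orb_l = _as_vec(por_r), _as_vec(por_l), _as_vec(orb_l)
    plane = plane_from_points(orb_l, por_r, por_l)  # unsigned normal
    normal = plane.normal
    d = normal @ _as_vec(superior_hint)
    if abs(d) < _HINT_TOL:
        raise OrientationAmbiguousError(
            "superior_hint is orthogonal to the FH normal; cannot orient the frame"
        )
    z = normal if d > 0 else -normal
    x = por_l - por_r
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise DegenerateGeometryError("porions coincide; x axis undefined")
    x = x / nx
    # x lies in the FH plane, hence orthogonal to z; y completes the triad.
    y = np.cross(z, x)
    return Frame(midpoint(por_r, por_l), x, y, z)


def to_frame(frame: Frame, p) -> np.ndarray:
    """Express ``p`` (3-vector or (n, 3) array) in ``frame`` coordinates.

    Rigid: pairwise distances are preserved to machine precision.
    """
    p = np.asarray(p, dtype=float)
    return (p - frame.origin) @ frame.rotation.T


def mean_landmark(dataset: AnnotationDataset, subject: str, landmark: str) -> np.ndarray:
    """Componentwise mean position of a landmark over all usable repetitions
    (non-missing, non-outlier) for one subject."""
    df = dataset.active
    sel = df[(df["subject_id"] == str(subject)) & (df["landmark"] == landmark)]
    if sel.empty:
        raise MissingLandmarkError(
            f"no usable observation of {landmark!r} for subject {subject!r}"
        )
    return sel[["x_mm", "y_mm", "z_mm"]].to_numpy().mean(axis=0)


def subject_fh_frame(
    dataset: AnnotationDataset,
    subject: str,
    superior_hint=(0.0, 0.0, 1.0),
) -> Frame:
    """The subject's mean-FH frame: built from the 6-repetition mean Po-R,
    Po-L and Or-L (after outlier removal).

    If ``superior_hint`` is orthogonal to the FH normal the sign is fixed by
    the anatomical fallback: mean Menton must come out inferior (z < 0).
    """
    por_r = mean_landmark(dataset, subject, "Po-R")
    por_l = mean_landmark(dataset, subject, "Po-L")
    orb_l = mean_landmark(dataset, subject, "Or-L")
    try:
        return build_fh_frame(por_r, por_l, orb_l, superior_hint)
    except OrientationAmbiguousError:
        menton = mean_landmark(dataset, subject, "Me")
        plane = plane_from_points(orb_l, por_r, por_l)
        # pick the sign that puts Menton below the FH plane
        hint = -plane.normal if (menton - plane.anchor) @ plane.normal > 0 else plane.normal
        return build_fh_frame(por_r, por_l, orb_l, hint)


def subject_frames(
    dataset: AnnotationDataset, superior_hint=(0.0, 0.0, 1.0)
) -> dict[str, Frame]:
    """Mean-FH frame for every subject in the dataset."""
    return {
        s: subject_fh_frame(dataset, s, superior_hint) for s in dataset.subjects
    }


def transform_dataset(dataset: AnnotationDataset, frames: dict[str, Frame]) -> pd.DataFrame:
    """Active observations with coordinates expressed in each subject's frame.

    Returns a DataFrame with the key columns plus ``x_mm, y_mm, z_mm`` in
    frame coordinates.
    """
    df = dataset.active.copy()
    out = np.empty((len(df), 3))
    for subject, idx in df.groupby("subject_id").indices.items():
        pts = df.iloc[idx][["x_mm", "y_mm", "z_mm"]].to_numpy()
        out[idx] = to_frame(frames[subject], pts)
    df[["x_mm", "y_mm", "z_mm"]] = out
    return df
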