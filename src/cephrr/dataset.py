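"""Annotation datasets: one located landmark per subject x operator x session.

The canonical in-memory container is a pandas DataFrame with columns
``subject_id, operator_id, session_id, landmark, x_mm, y_mm, z_mm`` plus two
boolean flag columns ``missing`` and ``outlier_removed``.  Identifiers are
strings; coordinates are millimetres in the scanner frame.

Two plain-text dialects are supported:

* CSV with header ``subject_id,operator_id,session_id,landmark,x_mm,y_mm,z_mm``
  (UTF-8, ``.`` decimal separator, one observation per row).  A trailing
  ``flags`` column (semicolon-separated flag names) is written only when some
  observation carries a flag, and accepted on read.
* A minimal self-describing XML dialect::

      <study>
        <subject id="S01">
          <operator id="O1">
            <session id="1">
              <landmark name="Na" x="0.0" y="-72.0" z="18.0"/>
              ...

Missing annotations are represented by absent rows; the ``missing`` /
``outlier_removed`` flags are produced internally by outlier screening.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .catalog import LandmarkCatalog, default_catalog
from .exceptions import ParseError, ValidationError

KEY_COLUMNS = ["subject_id", "operator_id", "session_id", "landmark"]
COORD_COLUMNS = ["x_mm", "y_mm", "z_mm"]
FLAG_COLUMNS = ["missing", "outlier_removed"]
ALL_COLUMNS = KEY_COLUMNS + COORD_COLUMNS + FLAG_COLUMNS

#: Floating-point format used when serializing coordinates (round-trip exact
#: for doubles, and comfortably above the 9-significant-digit contract).
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class LandmarkObservation:
    """A single located landmark."""

    subject_id: str
    operator_id: str
    session_id: str
    landmark: str
    position: tuple[float, float, float]
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.flags) - set(FLAG_COLUMNS)
        if bad:
            raise ValidationError(f"unknown observation flags: {sorted(bad)}")
        if "missing" not in self.flags and not np.all(np.isfinite(self.position)):
            raise ValidationError(
                f"non-finite position for {self.landmark} "
                f"({self.subject_id}/{self.operator_id}/{self.session_id}) "
                "without the 'missing' flag"
            )


@dataclass
class AnnotationDataset:
    """The full study table plus its landmark catalog.

    ``frame`` holds one row per observation; the dataset validates on
    construction (known landmark names, unique keys, finite coordinates
    unless flagged missing).
    """

    frame: pd.DataFrame
    catalog: LandmarkCatalog = field(default_factory=default_catalog)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in FLAG_COLUMNS:
            if col not in df.columns:
                df[col] = False
            df[col] = df[col].astype(bool)
        missing_cols = [c for c in KEY_COLUMNS + COORD_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"dataset frame lacks columns: {missing_cols}")
        for col in KEY_COLUMNS:
            df[col] = df[col].astype(str)
        for col in COORD_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        df = df[ALL_COLUMNS].reset_index(drop=True)
        self.frame = df
        self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_observations(
        cls,
        observations: Iterable[LandmarkObservation],
        catalog: LandmarkCatalog | None = None,
    ) -> "AnnotationDataset":
        rows = []
        for obs in observations:
            rows.append(
                {
                    "subject_id": obs.subject_id,
                    "operator_id": obs.operator_id,
                    "session_id": obs.session_id,
                    "landmark": obs.landmark,
                    "x_mm": obs.position[0],
                    "y_mm": obs.position[1],
                    "z_mm": obs.position[2],
                    "missing": "missing" in obs.flags,
                    "outlier_removed": "outlier_removed" in obs.flags,
                }
            )
        frame = pd.DataFrame(rows, columns=ALL_COLUMNS)
        return cls(frame, catalog or default_catalog())

    # -- contracts ------------------------------------------------------------

    def validate(self) -> None:
        df = self.frame
        unknown = sorted(set(df["landmark"]) - set(self.catalog.names))
        if unknown:
            raise ValidationError(f"landmarks not in catalog: {unknown}")
        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            offenders = (
                df.loc[dup, KEY_COLUMNS].drop_duplicates().to_records(index=False).tolist()
            )
            raise ValidationError(
                f"duplicate (subject, operator, session, landmark) keys: {offenders[:10]}"
            )
        usable = ~df["missing"]
        coords = df.loc[usable, COORD_COLUMNS].to_numpy()
        if coords.size and not np.all(np.isfinite(coords)):
            bad = df.loc[usable].loc[
                ~np.all(np.isfinite(df.loc[usable, COORD_COLUMNS]), axis=1), KEY_COLUMNS
            ]
            raise ValidationError(
                "non-finite coordinates without 'missing' flag: "
                f"{bad.to_records(index=False).tolist()[:10]}"
            )

    # -- views ----------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[LandmarkObservation]:
        for row in self.frame.itertuples(index=False):
            flags = set()
            if row.missing:
                flags.add("missing")
            if row.outlier_removed:
                flags.add("outlier_removed")
            yield LandmarkObservation(
                row.subject_id,
                row.operator_id,
                row.session_id,
                row.landmark,
                (row.x_mm, row.y_mm, row.z_mm),
                frozenset(flags),
            )

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject_id"].unique())

    @property
    def operators(self) -> list[str]:
        return sorted(self.frame["operator_id"].unique())

    @property
    def sessions(self) -> list[str]:
        return sorted(self.frame["session_id"].unique())

    @property
    def design(self) -> tuple[int, int, int]:
        """(n_subjects, n_operators, n_sessions) actually present."""
        return (len(self.subjects), len(self.operators), len(self.sessions))

    @property
    def active(self) -> pd.DataFrame:
        """Observations usable for statistics: neither missing nor removed."""
        df = self.frame
        return df.loc[~df["missing"] & ~df["outlier_removed"]]

    def mark_outliers(self, keys: pd.DataFrame | Sequence[tuple]) -> "AnnotationDataset":
        """Return a copy with the given (subject, operator, session, landmark)
        observations flagged ``outlier_removed`` and ``missing``."""
        if not isinstance(keys, pd.DataFrame):
            keys = pd.DataFrame(list(keys), columns=KEY_COLUMNS)
        keys = keys[KEY_COLUMNS].astype(str).drop_duplicates()
        df = self.frame.copy()
        idx = df.reset_index().merge(keys, on=KEY_COLUMNS)["index"]
        df.loc[idx, "outlier_removed"] = True
        df.loc[idx, "missing"] = True
        return AnnotationDataset(df, self.catalog)


# -- CSV dialect ---------------------------------------------------------------


def _write_csv(dataset: AnnotationDataset, path) -> None:
    df = dataset.frame.copy()
    any_flags = bool(df["missing"].any() or df["outlier_removed"].any())
    if any_flags:
        df["flags"] = [
            ";".join(n for n in FLAG_COLUMNS if row[n]) for _, row in df.iterrows()
        ]
    out = df.drop(columns=FLAG_COLUMNS)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype={c: str for c in KEY_COLUMNS + ["flags"]})
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"cannot parse CSV {path}: {exc}") from exc
    required = KEY_COLUMNS + COORD_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"CSV {path} lacks required columns: {missing}")
    if "flags" in df.columns:
        flag_lists = df["flags"].fillna("").str.split(";")
        df["missing"] = flag_lists.apply(lambda fl: "missing" in fl)
        df["outlier_removed"] = flag_lists.apply(lambda fl: "outlier_removed" in fl)
        df = df.drop(columns=["flags"])
    return df


# -- XML dialect ---------------------------------------------------------------


def _write_xml(dataset: AnnotationDataset, path) -> None:
    root = etree.Element("study")
    df = dataset.frame
    for subject_id, sdf in df.groupby("subject_id", sort=True):
        subj = etree.SubElement(root, "subject", id=subject_id)
        for operator_id, odf in sdf.groupby("operator_id", sort=True):
            oper = etree.SubElement(subj, "operator", id=operator_id)
            for session_id, ssdf in odf.groupby("session_id", sort=True):
                sess = etree.SubElement(oper, "session", id=session_id)
                for row in ssdf.itertuples(index=False):
                    attrs = {
                        "name": row.landmark,
                        "x": _FLOAT_FMT % row.x_mm,
                        "y": _FLOAT_FMT % row.y_mm,
                        "z": _FLOAT_FMT % row.z_mm,
                    }
                    flags = [n for n in FLAG_COLUMNS if getattr(row, n)]
                    if flags:
                        attrs["flags"] = ";".join(flags)
                    etree.SubElement(sess, "landmark", **attrs)
    tree = etree.ElementTree(root)
    if isinstance(path, os.PathLike):
        path = os.fspath(path)
    tree.write(path, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _read_xml(path) -> pd.DataFrame:
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"cannot parse XML {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "study":
        raise ParseError(f"XML {path}: root element is <{root.tag}>, expected <study>")
    rows = []
    for subj in root.iterchildren("subject"):
        for oper in subj.iterchildren("operator"):
            for sess in oper.iterchildren("session"):
                for lm in sess.iterchildren("landmark"):
                    try:
                        rows.append(
                            {
                                "subject_id": subj.get("id"),
                                "operator_id": oper.get("id"),
                                "session_id": sess.get("id"),
                                "landmark": lm.get("name"),
                                "x_mm": float(lm.get("x")),
                                "y_mm": float(lm.get("y")),
                                "z_mm": float(lm.get("z")),
                                "missing": "missing" in (lm.get("flags") or ""),
                                "outlier_removed": "outlier_removed"
                                in (lm.get("flags") or ""),
                            }
                        )
                    except (TypeError, ValueError) as exc:
                        raise ParseError(
                            f"XML {path} line {lm.sourceline}: bad <landmark> element "
                            f"({exc})"
                        ) from exc
    return pd.DataFrame(rows, columns=ALL_COLUMNS)


# -- public I/O ----------------------------------------------------------------

DIALECTS = ("csv", "xml")


def read_annotations(
    path: str | os.PathLike | io.IOBase,
    dialect: str = "csv",
    catalog: LandmarkCatalog | None = None,
) -> AnnotationDataset:
    """Read an annotation dataset from ``path`` in the given dialect.

    Unknown landmark names and duplicate (subject, operator, session,
    landmark) keys are rejected with :class:`ValidationError`; malformed
    files raise :class:`ParseError` naming the offending line or element.
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    df = _read_csv(path) if dialect == "csv" else _read_xml(path)
    return AnnotationDataset(df, catalog or default_catalog())


def write_annotations(
    dataset: AnnotationDataset,
    path: str | os.PathLike | io.IOBase,
    dialect: str = "csv",
) -> None:
    """Write ``dataset`` to ``path``; the file round-trips through
    :func:`read_annotations` with coordinates exact to double precision."""
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "csv":
        _write_csv(dataset, path)
    else:
        _write_xml(dataset, path)
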