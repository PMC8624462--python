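"""ISO 5725-style repeatability & reproducibility variance components.

Operators play the role of the standard's "laboratories" and subjects its
"levels".  For a given measurand (one landmark coordinate, or one vertical
distance) measured by operator i on subject j with replicates k:

    y_ijk = m_j + B_i + e_ijk,   B_i ~ N(0, s_L^2),   e_ijk ~ N(0, s_r^2)

* repeatability s_r: pooled within-cell SD (same operator, same subject);
* between-operator s_L: SD of the persistent operator effect;
* reproducibility s_R: sqrt(s_r^2 + s_L^2).

The study reports 95% confidence intervals as 2 x SD, and classifies each
landmark/axis as clinically *acceptable* (CI <= 1 mm), *useful* in most
analyses (1 mm < CI <= 2 mm) or to be used with *caution* (CI > 2 mm).

Outlier screening follows the standard's spirit: a deterministic gross-error
rule against the cross-operator median, a Grubbs test on operator cell means,
and advisory Mandel h/k consistency statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import KEY_COLUMNS, AnnotationDataset
from .exceptions import MissingLandmarkError, ValidationError
from .geometry import Frame, transform_dataset

logger = logging.getLogger("cephrr")

AXES = ("x", "y", "z")
_AXIS_COLUMN = {"x": "x_mm", "y": "y_mm", "z": "z_mm"}

#: Reliability class boundaries in mm (acceptable / useful / caution).
DEFAULT_RELIABILITY_THRESHOLDS = (1.0, 2.0)

#: Gross-error screening threshold, mm: distance from the cross-operator
#: median beyond which an observation is a gross error.  Far above localization
#: noise (sub-millimetre), far below genuine mislocalizations (several mm).
DEFAULT_GROSS_MM = 5.0
DEFAULT_GRUBBS_ALPHA = 0.01
DEFAULT_MANDEL_ALPHA = 0.01


class RRComponents(NamedTuple):
    """Variance-component estimates for a single measurand stratum."""

    s_r: float
    s_L: float
    s_R: float
    n_cells_used: int
    #: pre-truncation between-operator variance (may be negative); diagnostic
    s_L_sq_raw: float = 0.0


def _normalize_values(values: pd.DataFrame) -> pd.DataFrame:
    df = values.rename(
        columns={"subject_id": "subject", "operator_id": "operator", "session_id": "session"}
    )
    missing = [c for c in ("subject", "operator", "value") if c not in df.columns]
    if missing:
        raise ValidationError(f"rr_components input lacks columns: {missing}")
    return df


def rr_components(values: pd.DataFrame) -> RRComponents:
    """Estimate (s_r, s_L, s_R) from a long table of scalar measurements.

    ``values`` needs columns ``subject``, ``operator``, ``value`` (a
    ``session`` column, if present, is ignored — rows within a cell are
    replicates).  Handles unbalanced data: cells with a single replicate
    contribute to operator means but not to the repeatability pooling;
    subjects seen by fewer than two operators contribute nothing to s_L.
    """
    df = _normalize_values(values)
    if df.empty:
        raise ValidationError("rr_components: empty input")

    cells = df.groupby(["subject", "operator"])["value"]
    n_ij = cells.size()
    cell_means = cells.mean()
    cell_vars = cells.var(ddof=1)

    replicated = n_ij >= 2
    dof = (n_ij[replicated] - 1).to_numpy(dtype=float)
    if dof.sum() == 0:
        raise ValidationError(
            "rr_components: every cell has a single replicate; "
            "repeatability is not estimable"
        )
    s_r_sq = float((dof * cell_vars[replicated].to_numpy()).sum() / dof.sum())
    n_cells_used = int(replicated.sum())

    ops_per_subject = cell_means.groupby(level="subject").size()
    multi_op = ops_per_subject[ops_per_subject >= 2].index
    if len(multi_op) == 0:
        logger.warning(
            "rr_components: single operator per subject; s_L set to 0"
        )
        s_L_sq_raw = 0.0
        s_L_sq = 0.0
    else:
        s_d_sq = (
            cell_means.loc[list(multi_op)].groupby(level="subject").var(ddof=1)
        )
        # mean replicate count over the cells entering the between-operator
        # variances; equals n for balanced designs
        n_bar = float(n_ij.loc[list(multi_op)].mean())
        s_L_sq_raw = float(s_d_sq.mean() - s_r_sq / n_bar)
        s_L_sq = max(0.0, s_L_sq_raw)

    s_r = math.sqrt(s_r_sq)
    s_L = math.sqrt(s_L_sq)
    s_R = math.sqrt(s_r_sq + s_L_sq)
    return RRComponents(s_r, s_L, s_R, n_cells_used, s_L_sq_raw)


def sample_size(relative_uncertainty: float, repetitions: int, z: float = 1.96) -> int:
    """Minimum number of subjects so the repeatability-SD estimate has the
    given 95% relative uncertainty when each subject is measured
    ``repetitions`` times.

    Uses the large-sample approximation  p = z^2 / (2 A^2 (n - 1))  and
    rounds to the *nearest* integer (e.g. A=0.15, n=6 gives 17.07 -> 17).
    """
    if not (0.0 < relative_uncertainty < 1.0):
        raise ValidationError("relative_uncertainty must be in (0, 1)")
    if repetitions < 2:
        raise ValidationError("repetitions must be at least 2")
    if z <= 0:
        raise ValidationError("z must be positive")
    p = z**2 / (2.0 * relative_uncertainty**2 * (repetitions - 1))
    return int(math.floor(p + 0.5))


def classify_reliability(
    ci_repeat: float,
    ci_repro: float,
    thresholds: tuple[float, float] = DEFAULT_RELIABILITY_THRESHOLDS,
) -> str:
    """Clinical reliability class from the two 2xSD confidence intervals."""
    if ci_repeat < 0 or ci_repro < 0:
        raise ValidationError("confidence intervals must be non-negative")
    lo, hi = thresholds
    if not (0 < lo < hi):
        raise ValidationError("reliability thresholds must be positive and increasing")
    worst = max(ci_repeat, ci_repro)
    if worst <= lo:
        return "acceptable"
    if worst <= hi:
        return "useful"
    return "caution"


# -- outlier screening ---------------------------------------------------------


@dataclass
class OutlierReport:
    """Observations flagged by the screening rules.

    ``flagged`` has one row per (observation, rule) with the rule name, the
    axis it fired on (empty for the 3D gross rule), the test statistic, and
    whether the rule is advisory (advisory rules do not remove data).
    """

    flagged: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def removal_keys(self) -> pd.DataFrame:
        """Unique observation keys flagged by non-advisory rules."""
        df = self.flagged
        if df.empty:
            return pd.DataFrame(columns=KEY_COLUMNS)
        return df.loc[~df["advisory"], KEY_COLUMNS].drop_duplicates()

    def to_csv(self, path) -> None:
        self.flagged.to_csv(path, index=False)


_REPORT_COLUMNS = KEY_COLUMNS + ["rule", "axis", "statistic", "advisory"]

_CRITICAL_CACHE: dict[tuple, float] = {}


def _grubbs_critical(n: int, alpha: float) -> float:
    key = ("grubbs", n, alpha)
    if key not in _CRITICAL_CACHE:
        t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
        _CRITICAL_CACHE[key] = (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))
    return _CRITICAL_CACHE[key]


def _mandel_h_critical(p: int, alpha: float) -> float:
    key = ("mandel_h", p, alpha)
    if key not in _CRITICAL_CACHE:
        t = stats.t.ppf(1.0 - alpha / 2.0, p - 2)
        _CRITICAL_CACHE[key] = (p - 1) * t / math.sqrt(p * (t**2 + p - 2))
    return _CRITICAL_CACHE[key]


def _mandel_k_critical(p: int, nu: int, alpha: float) -> float:
    key = ("mandel_k", p, nu, alpha)
    if key not in _CRITICAL_CACHE:
        f = stats.f.ppf(1.0 - alpha, nu, (p - 1) * nu)
        _CRITICAL_CACHE[key] = math.sqrt(p / (1.0 + (p - 1) / f))
    return _CRITICAL_CACHE[key]


def screen_outliers(
    dataset: AnnotationDataset,
    gross_mm: float = DEFAULT_GROSS_MM,
    grubbs_alpha: float = DEFAULT_GRUBBS_ALPHA,
    mandel_alpha: float = DEFAULT_MANDEL_ALPHA,
    mandel_advisory: bool = True,
    rules: tuple[str, ...] = ("gross", "grubbs", "mandel"),
) -> OutlierReport:
    """Screen a dataset for measurement-system outliers.

    Three rules, mirroring interlaboratory practice:

    * **gross** — an observation farther than ``gross_mm`` (3D Euclidean)
      from the cross-operator median position of that landmark for that
      subject.  Deterministic and the primary removal rule.
    * **grubbs** — per subject/landmark/axis, a two-sided Grubbs test on the
      operator cell means at ``grubbs_alpha``; needs >= 3 operators, else the
      stratum is skipped (logged).  Flags the whole offending cell.
    * **mandel_h** / **mandel_k** — ISO consistency statistics on cell means
      and cell SDs at ``mandel_alpha``; advisory by default (reported, not
      removed).
    """
    for name, v in (("gross_mm", gross_mm), ("grubbs_alpha", grubbs_alpha),
                    ("mandel_alpha", mandel_alpha)):
        if v <= 0:
            raise ValidationError(f"{name} must be positive")

    unknown = set(rules) - {"gross", "grubbs", "mandel"}
    if unknown:
        raise ValidationError(f"unknown screening rules: {sorted(unknown)}")

    df = dataset.active
    rows: list[dict] = []

    # -- gross rule (vectorized: distance to the cross-operator median)
    if "gross" in rules:
        coords = df[["x_mm", "y_mm", "z_mm"]]
        medians = coords.groupby(
            [df["subject_id"], df["landmark"]]
        ).transform("median")
        dist = np.linalg.norm(coords.to_numpy() - medians.to_numpy(), axis=1)
        for pos in np.flatnonzero(dist > gross_mm):
            rec = df.iloc[pos]
            rows.append(
                {
                    "subject_id": rec["subject_id"],
                    "operator_id": rec["operator_id"],
                    "session_id": rec["session_id"],
                    "landmark": rec["landmark"],
                    "rule": "gross",
                    "axis": "",
                    "statistic": float(dist[pos]),
                    "advisory": False,
                }
            )

    if not ({"grubbs", "mandel"} & set(rules)):
        return _finish_report(rows, gross_mm, grubbs_alpha, mandel_alpha,
                              mandel_advisory)

    # -- per-axis cell statistics for Grubbs and Mandel
    long = df.melt(
        id_vars=KEY_COLUMNS,
        value_vars=list(_AXIS_COLUMN.values()),
        var_name="axis",
        value_name="value",
    )
    long["axis"] = long["axis"].str[0]
    cells = long.groupby(["subject_id", "landmark", "axis", "operator_id"])["value"]
    stats_df = cells.agg(mean="mean", sd="std", n="size").reset_index()

    for (subject, landmark, axis), grp in stats_df.groupby(
        ["subject_id", "landmark", "axis"]
    ):
        p = len(grp)
        if p < 3:
            logger.debug(
                "Grubbs/Mandel skipped for %s/%s axis %s: only %d operators",
                subject, landmark, axis, p,
            )
            continue
        means = grp["mean"].to_numpy()
        sd = means.std(ddof=1)
        if sd > 0:
            if "grubbs" in rules:
                g_stat = np.abs(means - means.mean()) / sd
                g_crit = _grubbs_critical(p, grubbs_alpha)
                for i in np.flatnonzero(g_stat > g_crit):
                    _flag_cell(rows, df, subject, grp.iloc[i]["operator_id"], landmark,
                               "grubbs", axis, float(g_stat[i]), advisory=False)
            if "mandel" in rules:
                h_crit = _mandel_h_critical(p, mandel_alpha)
                h = (means - means.mean()) / sd
                for i in np.flatnonzero(np.abs(h) > h_crit):
                    _flag_cell(rows, df, subject, grp.iloc[i]["operator_id"], landmark,
                               "mandel_h", axis, float(h[i]), advisory=mandel_advisory)
        repl = grp[grp["n"] >= 2]
        if "mandel" in rules and len(repl) >= 2 and (repl["sd"] > 0).any():
            pooled = math.sqrt(float((repl["sd"] ** 2).mean()))
            if pooled > 0:
                nu = int(repl["n"].mean()) - 1
                if nu >= 1:
                    k_crit = _mandel_k_critical(len(repl), nu, mandel_alpha)
                    k = repl["sd"].to_numpy() / pooled
                    for i in np.flatnonzero(k > k_crit):
                        _flag_cell(rows, df, subject, repl.iloc[i]["operator_id"],
                                   landmark, "mandel_k", axis, float(k[i]),
                                   advisory=mandel_advisory)

    return _finish_report(rows, gross_mm, grubbs_alpha, mandel_alpha, mandel_advisory)


def _finish_report(rows, gross_mm, grubbs_alpha, mandel_alpha, mandel_advisory):
    flagged = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    report = OutlierReport(
        flagged,
        thresholds={
            "gross_mm": gross_mm,
            "grubbs_alpha": grubbs_alpha,
            "mandel_alpha": mandel_alpha,
            "mandel_advisory": mandel_advisory,
        },
    )
    n_removed = len(report.removal_keys)
    if n_removed:
        logger.info("outlier screening flags %d observation(s) for removal", n_removed)
    return report


def _flag_cell(rows, df, subject, operator, landmark, rule, axis, statistic, advisory):
    cell = df[
        (df["subject_id"] == subject)
        & (df["operator_id"] == operator)
        & (df["landmark"] == landmark)
    ]
    for _, rec in cell.iterrows():
        rows.append(
            {
                "subject_id": subject,
                "operator_id": operator,
                "session_id": rec["session_id"],
                "landmark": landmark,
                "rule": rule,
                "axis": axis,
                "statistic": statistic,
                "advisory": advisory,
            }
        )


def apply_outliers(dataset: AnnotationDataset, report: OutlierReport) -> AnnotationDataset:
    """Return a dataset with the report's non-advisory flags marked missing."""
    keys = report.removal_keys
    if keys.empty:
        return dataset
    return dataset.mark_outliers(keys)


# -- R&R tables ----------------------------------------------------------------


@dataclass(frozen=True)
class RRRecord:
    """Repeatability & reproducibility of one landmark along one axis."""

    landmark: str
    axis: str
    s_r: float
    s_L: float
    s_R: float
    n_cells_used: int
    reliability_class: str

    @property
    def ci_repeat(self) -> float:
        return 2.0 * self.s_r

    @property
    def ci_repro(self) -> float:
        return 2.0 * self.s_R


@dataclass
class RRTable:
    """One RRRecord per (landmark, axis), in tidy DataFrame form."""

    records: pd.DataFrame
    design: tuple[int, int, int] = (0, 0, 0)
    reference: str = ""  # e.g. "frame", "conventional", "novel"

    def get(self, landmark: str, axis: str) -> RRRecord:
        df = self.records
        sel = df[(df["landmark"] == landmark) & (df["axis"] == axis)]
        if sel.empty:
            raise KeyError((landmark, axis))
        row = sel.iloc[0]
        return RRRecord(
            landmark, axis, row["s_r"], row["s_L"], row["s_R"],
            int(row["n_cells_used"]), row["reliability_class"],
        )

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def to_json(self) -> str:
        return self.records.to_json(orient="records")


def rr_by(values: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Vectorized :func:`rr_components` over every stratum defined by ``by``.

    Returns one row per stratum with columns ``by + [s_r, s_L, s_R,
    n_cells_used, s_L_sq_raw]``.  Strata in which no cell has two replicates
    are dropped with a logged warning; numerically identical to calling
    ``rr_components`` stratum by stratum.
    """
    df = _normalize_values(values)
    cell = (
        df.groupby(by + ["subject", "operator"], sort=True)["value"]
        .agg(n="size", mean="mean", var="var")
        .reset_index()
    )

    repl = cell[cell["n"] >= 2].copy()
    repl["w"] = repl["n"] - 1.0
    repl["wvar"] = repl["w"] * repl["var"]
    pooled = repl.groupby(by)[["wvar", "w"]].sum()
    pooled["s_r_sq"] = pooled["wvar"] / pooled["w"]
    pooled["n_cells_used"] = repl.groupby(by).size()

    dropped = cell.groupby(by).size().index.difference(pooled.index)
    for key in dropped:
        logger.warning("stratum %s skipped: no cell has two replicates", key)

    per_subject = (
        cell.groupby(by + ["subject"])["mean"].agg(p="size", s_d_sq="var").reset_index()
    )
    multi = per_subject[per_subject["p"] >= 2]
    mean_sdsq = multi.groupby(by)["s_d_sq"].mean()
    cell_multi = cell.merge(multi[by + ["subject"]], on=by + ["subject"])
    n_bar = cell_multi.groupby(by)["n"].mean()

    out = pooled[["s_r_sq", "n_cells_used"]].copy()
    out["mean_sdsq"] = mean_sdsq.reindex(out.index)
    out["n_bar"] = n_bar.reindex(out.index)
    single_op = out["mean_sdsq"].isna()
    if single_op.any():
        logger.warning(
            "rr_by: %d stratum/strata with a single operator; s_L set to 0",
            int(single_op.sum()),
        )
    out["s_L_sq_raw"] = (out["mean_sdsq"] - out["s_r_sq"] / out["n_bar"]).fillna(0.0)
    out["s_L_sq"] = out["s_L_sq_raw"].clip(lower=0.0)
    out["s_r"] = np.sqrt(out["s_r_sq"])
    out["s_L"] = np.sqrt(out["s_L_sq"])
    out["s_R"] = np.sqrt(out["s_r_sq"] + out["s_L_sq"])
    return out.reset_index()[
        by + ["s_r", "s_L", "s_R", "n_cells_used", "s_L_sq_raw"]
    ]


def _records_from_long(
    long: pd.DataFrame,
    thresholds: tuple[float, float],
) -> pd.DataFrame:
    """R&R records per (landmark, axis) stratum of a long value table."""
    if long.empty:
        return pd.DataFrame(
            columns=["landmark", "axis", "s_r", "s_L", "s_R", "repet_2sd",
                     "repro_2sd", "n_cells_used", "s_L_sq_raw", "reliability_class"]
        )
    records = rr_by(long, ["landmark", "axis"])
    records["repet_2sd"] = 2.0 * records["s_r"]
    records["repro_2sd"] = 2.0 * records["s_R"]
    records["reliability_class"] = [
        classify_reliability(r, p, thresholds)
        for r, p in zip(records["repet_2sd"], records["repro_2sd"])
    ]
    return records[
        ["landmark", "axis", "s_r", "s_L", "s_R", "repet_2sd", "repro_2sd",
         "n_cells_used", "s_L_sq_raw", "reliability_class"]
    ]


def dataset_to_long(dataset: AnnotationDataset, frames: dict[str, Frame]) -> pd.DataFrame:
    """Transform active observations into subject frames and melt to a long
    (subject, operator, session, landmark, axis, value) table."""
    tdf = transform_dataset(dataset, frames)
    long = tdf.melt(
        id_vars=KEY_COLUMNS,
        value_vars=list(_AXIS_COLUMN.values()),
        var_name="axis",
        value_name="value",
    )
    long["axis"] = long["axis"].str[0]
    return long.rename(columns={"subject_id": "subject", "operator_id": "operator",
                                "session_id": "session"})


def rr_table(
    dataset: AnnotationDataset,
    frame_per_subject: dict[str, Frame],
    thresholds: tuple[float, float] = DEFAULT_RELIABILITY_THRESHOLDS,
) -> RRTable:
    """Landmark-position R&R per axis, after reorientation into each
    subject's mean-FH frame.  Outlier screening is expected to have been
    applied to ``dataset`` already."""
    missing = set(dataset.subjects) - set(frame_per_subject)
    if missing:
        raise ValidationError(f"no frame for subjects: {sorted(missing)}")
    long = dataset_to_long(dataset, frame_per_subject)
    records = _records_from_long(long, thresholds)
    return RRTable(records, design=dataset.design, reference="frame")


# -- Bland-Altman --------------------------------------------------------------


@dataclass
class BlandAltmanSeries:
    """Deviation of each repetition from its subject mean, for one landmark
    and axis, with +/- 2 s_R agreement limits."""

    landmark: str
    axis: str
    deviations: pd.DataFrame  # subject, operator, session, deviation
    limit: float  # 2 * s_R, mm

    def plot(self, ax=None):
        """Deviation-vs-subject scatter with the +/- 2 s_R limits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        subjects = sorted(self.deviations["subject"].unique())
        pos = {s: i + 1 for i, s in enumerate(subjects)}
        ax.scatter(
            self.deviations["subject"].map(pos),
            self.deviations["deviation"],
            s=12, color="tab:blue", alpha=0.7,
        )
        ax.axhline(0.0, color="tab:blue", lw=0.8)
        ax.axhline(self.limit, color="tab:red", lw=1.0)
        ax.axhline(-self.limit, color="tab:red", lw=1.0)
        ax.set_xlabel("subject")
        ax.set_ylabel(f"deviation from mean ({self.axis}, mm)")
        ax.set_title(f"{self.landmark} — {self.axis} axis")
        return ax

    def to_csv(self, path) -> None:
        self.deviations.to_csv(path, index=False)


def bland_altman(
    dataset: AnnotationDataset,
    landmark: str,
    axis: str,
    frame_per_subject: dict[str, Frame],
) -> BlandAltmanSeries:
    """Modified Bland-Altman series: per-repetition deviations of one
    landmark coordinate from its subject mean, with limits at +/- 2 s_R."""
    if axis not in AXES:
        raise ValidationError(f"axis must be one of {AXES}")
    long = dataset_to_long(dataset, frame_per_subject)
    stratum = long[(long["landmark"] == landmark) & (long["axis"] == axis)].copy()
    if stratum.empty:
        raise MissingLandmarkError(f"no observations of {landmark!r}")
    stratum["deviation"] = stratum["value"] - stratum.groupby("subject")[
        "value"
    ].transform("mean")
    comp = rr_components(stratum)
    dev = stratum[["subject", "operator", "session", "deviation"]].reset_index(drop=True)
    return BlandAltmanSeries(landmark, axis, dev, 2.0 * comp.s_R)
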