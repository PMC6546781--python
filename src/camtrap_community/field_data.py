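"""Input tables: detection records, deployments, site covariates.

Three comma-separated tables drive the pipeline:

``detections.csv``
    site_id, species_id, timestamp (ISO-8601, minute resolution),
    individual_id (optional, may be empty).

``deployments.csv``
    site_id, camera_brand, kind (``active`` | ``malfunction``),
    start_date, end_date (ISO dates, inclusive on both ends). A site may
    have several rows; all rows of a site must share one camera brand.

``covariates.csv``
    site_id, x, y (projected meters), dist_settlement_m, dist_water_m,
    elevation_m, slope_deg, solar_radiation, vegetation.

Timestamps are naive local clock times: the diel analysis only needs
time of day and the study is confined to a single park.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CAMERA_BRANDS = ("KeepGuard", "Cuddeback", "Reconyx")
VEGETATION_CLASSES = ("herbaceous", "broadleaf", "mixed")

DETECTION_COLUMNS = ("site_id", "species_id", "timestamp", "individual_id")
DEPLOYMENT_COLUMNS = ("site_id", "camera_brand", "kind", "start_date", "end_date")
COVARIATE_COLUMNS = (
    "site_id",
    "x",
    "y",
    "dist_settlement_m",
    "dist_water_m",
    "elevation_m",
    "slope_deg",
    "solar_radiation",
    "vegetation",
)


class SchemaError(ValueError):
    """A table is structurally wrong (missing column, unknown category)."""


class ValidationError(ValueError):
    """A table is structurally fine but internally inconsistent."""


class Season(str, Enum):
    """Four-month seasons; every calendar month maps to exactly one."""

    DEC_MAR = "DEC_MAR"
    APR_JUL = "APR_JUL"
    AUG_NOV = "AUG_NOV"

    @classmethod
    def from_month(cls, month: int) -> "Season":
        if month in (12, 1, 2, 3):
            return cls.DEC_MAR
        if 4 <= month <= 7:
            return cls.APR_JUL
        if 8 <= month <= 11:
            return cls.AUG_NOV
        raise ValueError(f"invalid month: {month}")


def assign_season(date: dt.date | dt.datetime | pd.Timestamp) -> Season:
    """Map a calendar date to its season (colder Dec-Mar, hot-dry Apr-Jul, hot-wet Aug-Nov)."""
    return Season.from_month(date.month)


@dataclass(frozen=True)
class DetectionRecord:
    """One camera trigger."""

    site_id: str
    species_id: str
    timestamp: dt.datetime
    individual_id: str = ""


@dataclass
class Deployment:
    """A site's camera effort: active date ranges minus malfunction gaps.

    Intervals are (start, end) date pairs, inclusive on both ends; one
    trap-night per calendar date covered.
    """

    site_id: str
    camera_brand: str
    active_intervals: list[tuple[dt.date, dt.date]] = field(default_factory=list)
    malfunction_intervals: list[tuple[dt.date, dt.date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.camera_brand not in CAMERA_BRANDS:
            raise SchemaError(
                f"unknown camera_brand {self.camera_brand!r} for site {self.site_id};"
                f" expected one of {CAMERA_BRANDS}"
            )
        for name in ("active_intervals", "malfunction_intervals"):
            ivals = getattr(self, name)
            for start, end in ivals:
                if end < start:
                    raise ValidationError(
                        f"{name} of site {self.site_id}: end {end} before start {start}"
                    )
            _check_non_overlapping(ivals, f"site {self.site_id} {name}")
        active = self.active_dates()
        bad = self.malfunction_dates() - active
        if bad:
            raise ValidationError(
                f"site {self.site_id}: malfunction dates outside active intervals: "
                f"{sorted(bad)[:5]}"
            )

    def active_dates(self) -> set[dt.date]:
        return _interval_dates(self.active_intervals)

    def malfunction_dates(self) -> set[dt.date]:
        return _interval_dates(self.malfunction_intervals)

    def effort_dates(self) -> set[dt.date]:
        """Calendar dates of functioning effort (active minus malfunction)."""
        return self.active_dates() - self.malfunction_dates()

    def covers(self, timestamp: dt.datetime) -> bool:
        d = timestamp.date()
        return any(start <= d <= end for start, end in self.active_intervals)


@dataclass(frozen=True)
class SiteCovariates:
    site_id: str
    x: float
    y: float
    dist_settlement_m: float
    dist_water_m: float
    elevation_m: float
    slope_deg: float
    solar_radiation: float
    vegetation: str

    def __post_init__(self) -> None:
        if self.vegetation not in VEGETATION_CLASSES:
            raise SchemaError(
                f"unknown vegetation class {self.vegetation!r} for site {self.site_id};"
                f" expected one of {VEGETATION_CLASSES}"
            )
        for name in ("dist_settlement_m", "dist_water_m"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"site {self.site_id}: {name} must be finite and >= 0, got {v}"
                )


def _interval_dates(intervals: Iterable[tuple[dt.date, dt.date]]) -> set[dt.date]:
    out: set[dt.date] = set()
    for start, end in intervals:
        out.update(start + dt.timedelta(days=k) for k in range((end - start).days + 1))
    return out


def _check_non_overlapping(
    intervals: Sequence[tuple[dt.date, dt.date]], what: str
) -> None:
    ivals = sorted(intervals)
    for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
        if s2 <= e1:
            raise ValidationError(f"{what}: overlapping intervals {(s1, e1)} and {(s2, e2)}")


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def _parse_date(value: str, table: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise SchemaError(f"{table}: bad date {value!r}") from exc


def read_detections(path: str | Path) -> list[DetectionRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DETECTION_COLUMNS[:3], "detections")
    if "individual_id" not in df.columns:
        df["individual_id"] = ""
    try:
        stamps = pd.to_datetime(df["timestamp"], format="ISO8601")
    except ValueError as exc:
        raise SchemaError(f"detections: unparseable timestamp ({exc})") from exc
    return [
        DetectionRecord(
            site_id=row.site_id,
            species_id=row.species_id,
            timestamp=ts.to_pydatetime(),
            individual_id=row.individual_id,
        )
        for row, ts in zip(df.itertuples(index=False), stamps)
    ]


def read_deployments(path: str | Path) -> dict[str, Deployment]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DEPLOYMENT_COLUMNS, "deployments")
    bad_kind = set(df["kind"]) - {"active", "malfunction"}
    if bad_kind:
        raise SchemaError(f"deployments: unknown kind value(s) {sorted(bad_kind)}")
    deployments: dict[str, Deployment] = {}
    for site_id, grp in df.groupby("site_id", sort=True):
        brands = sorted(set(grp["camera_brand"]))
        if len(brands) != 1:
            raise ValidationError(
                f"deployments: site {site_id} lists multiple camera brands {brands}"
            )
        active = []
        malfunction = []
        for row in grp.itertuples(index=False):
            ival = (
                _parse_date(row.start_date, "deployments"),
                _parse_date(row.end_date, "deployments"),
            )
            (active if row.kind == "active" else malfunction).append(ival)
        deployments[str(site_id)] = Deployment(
            site_id=str(site_id),
            camera_brand=brands[0],
            active_intervals=active,
            malfunction_intervals=malfunction,
        )
    return deployments


def read_covariates(path: str | Path) -> dict[str, SiteCovariates]:
    df = pd.read_csv(path, dtype={"site_id": str, "vegetation": str})
    _require_columns(df, COVARIATE_COLUMNS, "covariates")
    if df["site_id"].duplicated().any():
        dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValidationError(f"covariates: duplicated site_id(s) {dupes}")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.site_id)] = SiteCovariates(
            site_id=str(row.site_id),
            x=float(row.x),
            y=float(row.y),
            dist_settlement_m=float(row.dist_settlement_m),
            dist_water_m=float(row.dist_water_m),
            elevation_m=float(row.elevation_m),
            slope_deg=float(row.slope_deg),
            solar_radiation=float(row.solar_radiation),
            vegetation=str(row.vegetation),
        )
    return out


def load_dataset(
    detections_path: str | Path,
    deployments_path: str | Path,
    covariates_path: str | Path,
    species_registry: Iterable[str] | None = None,
) -> tuple[list[DetectionRecord], dict[str, Deployment], dict[str, SiteCovariates]]:
    """Read and cross-validate the three input tables.

    Every record must belong to a site with a deployment and covariates,
    and fall within one of the site's active intervals. If a
    ``species_registry`` is supplied, species ids are validated against it.
    """
    records = read_detections(detections_path)
    deployments = read_deployments(deployments_path)
    covariates = read_covariates(covariates_path)

    missing_cov = sorted(set(deployments) - set(covariates))
    if missing_cov:
        raise ValidationError(f"sites without covariates: {missing_cov}")

    registry = set(species_registry) if species_registry is not None else None
    problems: list[str] = []
    for i, rec in enumerate(records):
        dep = deployments.get(rec.site_id)
        if dep is None:
            problems.append(f"row {i}: site {rec.site_id} has no deployment")
        elif not dep.covers(rec.timestamp):
            problems.append(
                f"row {i}: timestamp {rec.timestamp.isoformat()} outside active"
                f" intervals of site {rec.site_id}"
            )
        if registry is not None and rec.species_id not in registry:
            problems.append(f"row {i}: species {rec.species_id} not in registry")
    if problems:
        shown = "; ".join(problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        raise ValidationError(f"detections failed validation: {shown}{more}")
    return records, deployments, covariates


def write_dataset(
    records: Sequence[DetectionRecord],
    deployments: Mapping[str, Deployment],
    covariates: Mapping[str, SiteCovariates],
    detections_path: str | Path,
    deployments_path: str | Path,
    covariates_path: str | Path,
) -> None:
    """Write the three tables back out; inverse of :func:`load_dataset`."""
    pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "species_id": [r.species_id for r in records],
            "timestamp": [r.timestamp.isoformat() for r in records],
            "individual_id": [r.individual_id for r in records],
        }
    ).to_csv(detections_path, index=False)

    rows = []
    for site_id in sorted(deployments):
        dep = deployments[site_id]
        for kind, ivals in (
            ("active", dep.active_intervals),
            ("malfunction", dep.malfunction_intervals),
        ):
            for start, end in ivals:
                rows.append(
                    {
                        "site_id": site_id,
                        "camera_brand": dep.camera_brand,
                        "kind": kind,
                        "start_date": start.isoformat(),
                        "end_date": end.isoformat(),
                    }
                )
    pd.DataFrame(rows, columns=list(DEPLOYMENT_COLUMNS)).to_csv(
        deployments_path, index=False
    )

    cov_rows = [
        {c: getattr(covariates[sid], c) for c in COVARIATE_COLUMNS}
        for sid in sorted(covariates)
    ]
    pd.DataFrame(cov_rows, columns=list(COVARIATE_COLUMNS)).to_csv(
        covariates_path, index=False
    )


def nearest_settlement_distance(
    site_xy: tuple[float, float] | Sequence[float],
    settlement_points: Sequence[tuple[float, float]] | np.ndarray,
) -> float:
    """Minimum Euclidean distance (m) from a site to any settlement point.

    Coordinates must share a projected CRS in meters; at park scale the
    projection error is negligible relative to camera spacing.
    """
    pts = np.asarray(settlement_points, dtype=float)
    if pts.size == 0:
        raise ValueError("settlement point set is empty")
    pts = pts.reshape(-1, 2)
    xy = np.asarray(site_xy, dtype=float)
    return float(np.min(np.hypot(pts[:, 0] - xy[0], pts[:, 1] - xy[1])))
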