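"""Vital-sign anomaly elimination and deviation diagnosis.

Records of blood pressure, body temperature and pulse are turned into
feature-space points (one coordinate per vital, raw units), clustered with
DBSCAN (optionally partitioned), and the noise points are eliminated as
anomalous readings.  The surviving clusters are taken as the true
embodiment of the patient's physiological state: the per-vital mean of the
largest retained cluster is compared against standard reference ranges,
and each out-of-range vital yields a diagnostic finding with a signed
deviation from the range target.

Clustering parameters adapt to the patient's condition: for severe
patients ``min_pts`` is raised and ``eps`` shrunk (stricter density
demands flag more readings as anomalous); for chronic patients the record
stream is split into several consecutive time windows and the analysis is
repeated per window to follow the state over a long period.

The :class:`VitalSignsModel` / :class:`VitalSignsResults` pair is the
high-level entry point; the module-level functions expose each stage.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Hashable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    NOISE,
    ClusteringResult,
    DataPoint,
    DBSCANParams,
    PointRole,
)
from .partition import PartitionConfig, partitioned_dbscan

logger = logging.getLogger(__name__)

__all__ = [
    "VITAL_NAMES",
    "VitalRecord",
    "ReferenceRange",
    "DEFAULT_RANGES",
    "DeviationEntry",
    "DeviationReport",
    "Severity",
    "SeverityProfile",
    "Finding",
    "Featurized",
    "featurize",
    "remove_anomalies",
    "deviation_report",
    "adapt_parameters",
    "windowed_analysis",
    "diagnose",
    "VitalSignsModel",
    "VitalSignsResults",
]

VITAL_NAMES = ("systolic", "diastolic", "temperature", "pulse")


@dataclass(frozen=True)
class VitalRecord:
    """One timestamped physiological measurement vector for a subject.

    Units: systolic/diastolic pressure in mmHg, temperature in °C, pulse
    in beats/min.
    """

    subject_id: Hashable
    time: datetime
    systolic: float
    diastolic: float
    temperature: float
    pulse: float

    def vital(self, name: str) -> float:
        if name not in VITAL_NAMES:
            raise KeyError(f"unknown vital {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class ReferenceRange:
    """Standard-health band and target value for one vital."""

    vital_name: str
    low: float
    high: float
    target: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.vital_name}: low must be < high")
        if not (self.low <= self.target <= self.high):
            raise ValueError(f"{self.vital_name}: target must lie within [low, high]")


#: Standard adult resting reference ranges (systolic/diastolic mmHg, °C, bpm).
DEFAULT_RANGES: dict[str, ReferenceRange] = {
    "systolic": ReferenceRange("systolic", 90.0, 140.0, 120.0),
    "diastolic": ReferenceRange("diastolic", 60.0, 90.0, 80.0),
    "temperature": ReferenceRange("temperature", 36.1, 37.3, 36.8),
    "pulse": ReferenceRange("pulse", 60.0, 100.0, 72.0),
}


@dataclass(frozen=True)
class DeviationEntry:
    """Per-vital comparison of the cluster representative with its reference range."""

    vital_name: str
    cluster_representative: float
    deviation: float  # representative - target, signed, same units
    in_range: bool


@dataclass
class DeviationReport:
    """Deviation of the retained-cluster representative from standard health data.

    ``n_retained + n_anomalies`` equals the number of clustered input
    records.  ``insufficient`` marks a window with too few records to
    cluster meaningfully (no entries in that case).
    """

    entries: dict[str, DeviationEntry]
    n_retained: int
    n_anomalies: int
    window: tuple[datetime, datetime] | None = None
    insufficient: bool = False


class Severity(enum.Enum):
    NORMAL = "normal"
    SEVERE = "severe"
    CHRONIC = "chronic"


@dataclass(frozen=True)
class SeverityProfile:
    """How the analysis adapts to the patient's condition.

    SEVERE tightens density demands (``min_pts`` scaled up by
    ``minpts_scale``, ``eps`` scaled down by ``eps_scale``); CHRONIC keeps
    the parameters but repeats the analysis over ``n_windows`` consecutive
    time windows.
    """

    level: Severity = Severity.NORMAL
    window_length: timedelta | None = None
    n_windows: int = 1
    minpts_scale: float = 1.5
    eps_scale: float = 0.8

    def __post_init__(self) -> None:
        if self.minpts_scale < 1:
            raise ValueError("minpts_scale must be >= 1")
        if not (0 < self.eps_scale <= 1):
            raise ValueError("eps_scale must lie in (0, 1]")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.level is Severity.SEVERE and not (self.minpts_scale > 1 and self.eps_scale < 1):
            raise ValueError("SEVERE requires minpts_scale > 1 and eps_scale < 1")
        if self.level is Severity.CHRONIC and self.n_windows <= 1:
            raise ValueError("CHRONIC requires n_windows > 1")


@dataclass(frozen=True)
class Finding:
    """One out-of-range vital: which bound was crossed and by how much."""

    vital_name: str
    direction: str  # "above" | "below"
    magnitude: float  # distance beyond the violated bound, same units
    deviation: float  # signed deviation from the range target


# ---------------------------------------------------------------------------
# Featurization


class Featurized(NamedTuple):
    points: list[DataPoint]
    rejected: list[tuple[Hashable, str]]  # (record index, reason)


def featurize(
    records: Sequence[VitalRecord],
    selected_vitals: Sequence[str] = VITAL_NAMES,
    standardize: bool = False,
) -> Featurized:
    """Convert records into feature-space points, one coordinate per vital.

    Coordinates are the raw measurement values in the declared vital order
    (acquisition time rides along as metadata).  Records with a missing or
    non-finite vital are rejected with a logged reason, never silently
    dropped.  With ``standardize`` each coordinate is z-scored; a constant
    column makes the scaling degenerate and is an error.
    """
    if not records:
        raise ValueError("no records to featurize")
    for v in selected_vitals:
        if v not in VITAL_NAMES:
            raise KeyError(f"unknown vital {v!r}")

    rows: list[tuple[int, VitalRecord, list[float]]] = []
    rejected: list[tuple[Hashable, str]] = []
    for idx, rec in enumerate(records):
        vals = []
        reason = None
        for v in selected_vitals:
            x = rec.vital(v)
            if x is None or not np.isfinite(x):
                reason = f"non-finite {v}"
                break
            if x <= 0:
                reason = f"non-positive {v}"
                break
            vals.append(float(x))
        if reason is None:
            rows.append((idx, rec, vals))
        else:
            logger.warning("record %d (subject %r) rejected: %s", idx, rec.subject_id, reason)
            rejected.append((idx, reason))

    if not rows:
        raise ValueError("every record was rejected at featurization")

    X = np.asarray([vals for _, _, vals in rows], dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        flat = [selected_vitals[j] for j in np.flatnonzero(sd == 0)]
        if flat:
            raise ValueError(f"cannot standardize constant column(s): {flat}")
        X = (X - X.mean(axis=0)) / sd

    points = [
        DataPoint(id=idx, coords=tuple(X[k]), time=rec.time)
        for k, (idx, rec, _) in enumerate(rows)
    ]
    return Featurized(points=points, rejected=rejected)


# ---------------------------------------------------------------------------
# Anomaly elimination


def remove_anomalies(
    points: Sequence[DataPoint],
    params: DBSCANParams,
    partitioning: PartitionConfig | None = None,
) -> tuple[dict[int, set[Hashable]], set[Hashable], ClusteringResult]:
    """Cluster the points and eliminate the noise as anomalous readings.

    Returns ``(retained clusters by label, anomaly ids, full clustering)``.
    The isolated few points DBSCAN cannot attach to any dense region are
    the anomalies; the remaining clusters are the useful data.  If every
    point is judged noise the retained set is empty (a warning, not an
    error — the caller should review eps/min_pts).
    """
    result = partitioned_dbscan(points, params, partitioning)
    clusters = result.clusters()
    anomalies = result.noise_ids
    if not clusters:
        warnings.warn(
            "all points were judged noise; review eps/min_pts", stacklevel=2
        )
    return clusters, anomalies, result


def deviation_report(
    retained: Mapping[int, set[Hashable]],
    records_by_id: Mapping[Hashable, VitalRecord],
    ranges: Mapping[str, ReferenceRange] = DEFAULT_RANGES,
    n_anomalies: int = 0,
    window: tuple[datetime, datetime] | None = None,
) -> DeviationReport:
    """Compare the dominant retained cluster against standard health data.

    The cluster representative is the per-vital mean over the largest
    retained cluster (ties broken toward the lower label), taken to
    reflect the patient's dominant physiological state; the deviation is
    the signed difference from each range's target value.
    """
    if not retained:
        raise ValueError(
            "no retained clusters: every point was anomalous; review eps/min_pts"
        )
    label = max(retained, key=lambda l: (len(retained[l]), -l))
    members = [records_by_id[i] for i in retained[label]]
    entries = {}
    for name, rng in ranges.items():
        rep = float(np.mean([m.vital(name) for m in members]))
        entries[name] = DeviationEntry(
            vital_name=name,
            cluster_representative=rep,
            deviation=rep - rng.target,
            in_range=rng.low <= rep <= rng.high,
        )
    n_retained = sum(len(v) for v in retained.values())
    return DeviationReport(
        entries=entries,
        n_retained=n_retained,
        n_anomalies=n_anomalies,
        window=window,
    )


def adapt_parameters(base: DBSCANParams, profile: SeverityProfile) -> DBSCANParams:
    """Adapt clustering parameters to the severity profile.

    SEVERE raises ``min_pts`` (ceil of the scaled value) and shrinks
    ``eps``, so fewer points qualify as core and anomalies are flagged
    more aggressively; NORMAL and CHRONIC leave the parameters unchanged
    (CHRONIC changes the windowing instead).
    """
    if profile.level is not Severity.SEVERE:
        return base
    min_pts = math.ceil(base.min_pts * profile.minpts_scale)
    if min_pts < 1:
        raise ValueError("adapted min_pts fell below 1")
    return DBSCANParams(eps=base.eps * profile.eps_scale, min_pts=min_pts)


def diagnose(report: DeviationReport, rules: Mapping[str, ReferenceRange] | None = None) -> list[Finding]:
    """One finding per out-of-range vital; empty when everything is in range."""
    if report.insufficient:
        return []
    rules = rules or DEFAULT_RANGES
    findings = []
    for name, entry in report.entries.items():
        if entry.in_range:
            continue
        rng = rules[name]
        rep = entry.cluster_representative
        if rep > rng.high:
            findings.append(Finding(name, "above", rep - rng.high, entry.deviation))
        else:
            findings.append(Finding(name, "below", rng.low - rep, entry.deviation))
    return findings


def windowed_analysis(
    records: Sequence[VitalRecord],
    profile: SeverityProfile,
    params: DBSCANParams,
    ranges: Mapping[str, ReferenceRange] = DEFAULT_RANGES,
    selected_vitals: Sequence[str] = VITAL_NAMES,
    partitioning: PartitionConfig | None = None,
    standardize: bool = False,
) -> list[DeviationReport]:
    """Repeat the analysis over consecutive time windows.

    The record span is cut into ``profile.n_windows`` contiguous,
    non-overlapping windows (of ``window_length`` each when given,
    otherwise equal divisions of the observed span) and the full
    eliminate-then-compare pipeline runs once per window, chronologically.
    A window with fewer than ``min_pts`` records is reported as
    insufficient rather than failing the whole analysis.
    """
    if not records:
        raise ValueError("no records")
    params = adapt_parameters(params, profile)
    times = [r.time for r in records]
    t0, t1 = min(times), max(times)
    n_win = profile.n_windows
    if profile.window_length is not None:
        length = profile.window_length
    else:
        span = t1 - t0
        length = span / n_win if span > timedelta(0) else timedelta(seconds=1)

    reports: list[DeviationReport] = []
    for k in range(n_win):
        lo = t0 + k * length
        hi = t0 + (k + 1) * length
        last = k == n_win - 1
        sub = [r for r in records if lo <= r.time < hi or (last and r.time == hi)]
        win = (lo, hi)
        if len(sub) < params.min_pts:
            reports.append(
                DeviationReport(entries={}, n_retained=0, n_anomalies=len(sub), window=win, insufficient=True)
            )
            continue
        feats = featurize(sub, selected_vitals, standardize=standardize)
        retained, anomalies, _ = remove_anomalies(feats.points, params, partitioning)
        if not retained:
            reports.append(
                DeviationReport(entries={}, n_retained=0, n_anomalies=len(anomalies), window=win, insufficient=True)
            )
            continue
        rep = deviation_report(
            retained, {p.id: sub[p.id] for p in feats.points}, ranges, n_anomalies=len(anomalies), window=win
        )
        reports.append(rep)
    return reports


# ---------------------------------------------------------------------------
# Model / Results facade


class VitalSignsModel:
    """Density-clustering model of a stream of vital-sign records.

    Fitting eliminates anomalous readings, measures the deviation of the
    dominant retained cluster from standard reference ranges, and derives
    diagnostic findings.  The familiar construction routes::

        model = VitalSignsModel.from_dataframe(df, params=DBSCANParams(18.0, 5))
        res = model.fit()
        print(res.summary())

    Parameters
    ----------
    records : sequence of VitalRecord
    params : DBSCANParams, default (eps=18.0, min_pts=5)
        Base neighbourhood radius and core threshold, in raw vital units;
        adapted by the severity profile at fit time.
    ranges : mapping, optional
        Per-vital reference ranges; defaults to standard adult values.
    profile : SeverityProfile, optional
        NORMAL by default; SEVERE tightens parameters, CHRONIC windows.
    partitioning : PartitionConfig, optional
        Enables partitioned clustering with cross-partition merging.
    """

    #: eps near the top of the preset data's 5-NN distance curve; see docs
    DEFAULT_PARAMS = DBSCANParams(eps=18.0, min_pts=5)

    def __init__(
        self,
        records: Sequence[VitalRecord],
        params: DBSCANParams | None = None,
        selected_vitals: Sequence[str] = VITAL_NAMES,
        ranges: Mapping[str, ReferenceRange] | None = None,
        profile: SeverityProfile | None = None,
        partitioning: PartitionConfig | None = None,
        standardize: bool = False,
    ):
        if not records:
            raise ValueError("no records")
        self.records = list(records)
        self.params = params or self.DEFAULT_PARAMS
        self.selected_vitals = tuple(selected_vitals)
        self.ranges = dict(ranges or DEFAULT_RANGES)
        self.profile = profile or SeverityProfile()
        self.partitioning = partitioning
        self.standardize = standardize

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "VitalSignsModel":
        """Build from a frame with columns subject_id, time and the four vitals."""
        required = {"subject_id", "time", *VITAL_NAMES}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        records = [
            VitalRecord(
                subject_id=row.subject_id,
                time=pd.Timestamp(row.time).to_pydatetime(),
                systolic=float(row.systolic),
                diastolic=float(row.diastolic),
                temperature=float(row.temperature),
                pulse=float(row.pulse),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "VitalSignsModel":
        from .io import load_records

        return cls(load_records(path), **kwargs)

    def fit(self) -> "VitalSignsResults":
        """Run the eliminate-then-diagnose pipeline (windowed when chronic)."""
        effective = adapt_parameters(self.params, self.profile)
        reports = windowed_analysis(
            self.records,
            self.profile,
            self.params,
            self.ranges,
            self.selected_vitals,
            self.partitioning,
            self.standardize,
        )
        # keep the full-span clustering for labels/anomaly ids when unwindowed
        feats = featurize(self.records, self.selected_vitals, standardize=self.standardize)
        retained, anomalies, clustering = remove_anomalies(feats.points, effective, self.partitioning)
        return VitalSignsResults(
            model=self,
            effective_params=effective,
            reports=reports,
            clustering=clustering,
            retained=retained,
            anomaly_ids=anomalies,
            rejected=feats.rejected,
        )


class VitalSignsResults:
    """Fitted results: clustering labels, anomaly ids, deviation reports, findings."""

    def __init__(
        self,
        model: VitalSignsModel,
        effective_params: DBSCANParams,
        reports: list[DeviationReport],
        clustering: ClusteringResult,
        retained: dict[int, set],
        anomaly_ids: set,
        rejected: list[tuple[Hashable, str]],
    ):
        self.model = model
        self.effective_params = effective_params
        self.reports = reports
        self.clustering = clustering
        self.retained = retained
        self.anomaly_ids = anomaly_ids
        self.rejected = rejected

    @property
    def report(self) -> DeviationReport:
        """The deviation report (first window's when windowed)."""
        return self.reports[0]

    @property
    def findings(self) -> list[Finding]:
        out: list[Finding] = []
        for rep in self.reports:
            out.extend(diagnose(rep, self.model.ranges))
        return out

    @property
    def n_anomalies(self) -> int:
        return len(self.anomaly_ids)

    def labels_frame(self) -> pd.DataFrame:
        """Per-record cluster label and role (NOISE spelled literally)."""
        rows = []
        for pid in sorted(self.clustering.labels):
            lab = self.clustering.labels[pid]
            rows.append(
                {
                    "record_id": pid,
                    "cluster_label": "NOISE" if lab == NOISE else lab,
                    "role": self.clustering.roles[pid].value,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Vital-sign density clustering results",
            "=" * 53,
            f"records: {len(m.records):>5}    rejected: {len(self.rejected)}",
            f"eps: {self.effective_params.eps:g}    min_pts: {self.effective_params.min_pts}"
            f"    severity: {m.profile.level.value}",
            f"clusters retained: {self.clustering.n_clusters}    anomalies eliminated: {self.n_anomalies}",
            "",
            f"{'vital':<12}{'representative':>15}{'target':>9}{'deviation':>11}{'in range':>10}",
            "-" * 57,
        ]
        for k, rep in enumerate(self.reports):
            if len(self.reports) > 1:
                w = rep.window
                tag = f"window {k + 1}"
                if w:
                    tag += f" [{w[0].isoformat()} .. {w[1].isoformat()})"
                lines.append(tag)
            if rep.insufficient:
                lines.append("  insufficient records for clustering")
                continue
            for name in m.selected_vitals:
                if name not in rep.entries:
                    continue
                e = rep.entries[name]
                rng = m.ranges[name]
                lines.append(
                    f"{name:<12}{e.cluster_representative:>15.2f}{rng.target:>9.1f}"
                    f"{e.deviation:>+11.2f}{'yes' if e.in_range else 'NO':>10}"
                )
        findings = self.findings
        lines.append("")
        if findings:
            lines.append("findings:")
            for f in findings:
                lines.append(
                    f"  {f.vital_name} {f.direction} range by {f.magnitude:.2f}"
                    f" (deviation from target {f.deviation:+.2f})"
                )
        else:
            lines.append("findings: all vitals within reference ranges")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<VitalSignsResults: {self.clustering.n_clusters} clusters, "
            f"{self.n_anomalies} anomalies, {len(self.reports)} window(s)>"
        )
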