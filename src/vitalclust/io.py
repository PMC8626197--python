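"""CSV/YAML input-output and run configuration.

Record files are plain CSV with header
``subject_id,time,systolic,diastolic,temperature,pulse`` and ISO-8601
times.  Malformed rows are logged and counted, not fatal, up to a
configurable rejection fraction.  Label files are CSV
``record_id,cluster_label,role`` with NOISE spelled literally.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import NOISE, ClusteringResult, DBSCANParams
from .partition import PartitionConfig
from .pipeline import (
    DEFAULT_RANGES,
    VITAL_NAMES,
    DeviationReport,
    Finding,
    ReferenceRange,
    Severity,
    SeverityProfile,
    VitalRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "RunConfig",
    "load_records",
    "save_records",
    "save_truth",
    "save_labels",
    "load_ranges",
    "load_config",
    "report_to_dict",
    "save_report",
]

REQUIRED_COLUMNS = ("subject_id", "time", *VITAL_NAMES)


def load_records(path, max_reject_fraction: float = 0.2) -> list[VitalRecord]:
    """Read and validate a vital-sign CSV.

    Rows with unparseable or non-positive values are rejected with a
    logged reason; the load fails only when the header is wrong, the file
    is empty, or more than ``max_reject_fraction`` of rows are bad.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")

    records: list[VitalRecord] = []
    n_bad = 0
    for idx, row in df.iterrows():
        try:
            time = pd.Timestamp(str(row["time"])).to_pydatetime()
            vitals = {v: float(row[v]) for v in VITAL_NAMES}
        except (ValueError, TypeError) as exc:
            logger.warning("%s row %d rejected: %s", path.name, idx, exc)
            n_bad += 1
            continue
        if any(not np.isfinite(x) or x <= 0 for x in vitals.values()):
            logger.warning("%s row %d rejected: non-finite or non-positive vital", path.name, idx)
            n_bad += 1
            continue
        records.append(VitalRecord(subject_id=row["subject_id"], time=time, **vitals))

    if n_bad / len(df) > max_reject_fraction:
        raise ValueError(
            f"{path}: {n_bad}/{len(df)} rows rejected, above the "
            f"{max_reject_fraction:.0%} tolerance"
        )
    if not records:
        raise ValueError(f"{path}: no valid rows")
    return records


def save_records(records: Sequence[VitalRecord], path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "time": [r.time.isoformat() for r in records],
            **{v: [getattr(r, v) for r in records] for v in VITAL_NAMES},
        }
    )
    df.to_csv(path, index=False)


def save_truth(truth: Mapping[int, object], path) -> None:
    pd.DataFrame(
        {"record_id": list(truth), "label": [str(truth[k]) for k in truth]}
    ).to_csv(path, index=False)


def save_labels(result: ClusteringResult, path) -> None:
    rows = []
    for pid in sorted(result.labels):
        lab = result.labels[pid]
        rows.append(
            {
                "record_id": pid,
                "cluster_label": "NOISE" if lab == NOISE else lab,
                "role": result.roles[pid].value,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_ranges(mapping: Mapping) -> dict[str, ReferenceRange]:
    out = {}
    for name, spec in mapping.items():
        out[name] = ReferenceRange(
            vital_name=name,
            low=float(spec["low"]),
            high=float(spec["high"]),
            target=float(spec["target"]),
        )
    return out


@dataclass
class RunConfig:
    """Validated run configuration assembled from a YAML/JSON file and flags."""

    params: DBSCANParams = field(default_factory=lambda: DBSCANParams(eps=18.0, min_pts=5))
    partitioning: PartitionConfig | None = None
    profile: SeverityProfile = field(default_factory=SeverityProfile)
    ranges: dict[str, ReferenceRange] = field(default_factory=lambda: dict(DEFAULT_RANGES))
    seed: int = 0

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "RunConfig":
        kwargs: dict = {}
        if "eps" in cfg or "min_pts" in cfg:
            kwargs["params"] = DBSCANParams(
                eps=float(cfg.get("eps", 18.0)), min_pts=int(cfg.get("min_pts", 5))
            )
        if "partitioning" in cfg:
            p = cfg["partitioning"]
            kwargs["partitioning"] = PartitionConfig(
                n_partitions=int(p.get("n_partitions", 1)),
                overlap_width=p.get("overlap_width"),
                eps_per_partition=p.get("eps_per_partition"),
            )
        if "severity" in cfg:
            s = cfg["severity"]
            wl = s.get("window_length_hours")
            kwargs["profile"] = SeverityProfile(
                level=Severity(s.get("level", "normal")),
                window_length=timedelta(hours=float(wl)) if wl is not None else None,
                n_windows=int(s.get("n_windows", 1)),
                minpts_scale=float(s.get("minpts_scale", 1.5)),
                eps_scale=float(s.get("eps_scale", 0.8)),
            )
        if "ranges" in cfg:
            kwargs["ranges"] = load_ranges(cfg["ranges"])
        if "seed" in cfg:
            kwargs["seed"] = int(cfg["seed"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(cfg, Mapping):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls.from_mapping(cfg)


def report_to_dict(report: DeviationReport, findings: Sequence[Finding] = ()) -> dict:
    d = {
        "n_retained": report.n_retained,
        "n_anomalies": report.n_anomalies,
        "insufficient": report.insufficient,
        "vitals": {
            name: {
                "representative": e.cluster_representative,
                "deviation": e.deviation,
                "in_range": e.in_range,
            }
            for name, e in report.entries.items()
        },
        "findings": [
            {
                "vital": f.vital_name,
                "direction": f.direction,
                "magnitude": f.magnitude,
                "deviation": f.deviation,
            }
            for f in findings
        ],
    }
    if report.window:
        d["window"] = [report.window[0].isoformat(), report.window[1].isoformat()]
    return d


def save_report(report: DeviationReport, findings: Sequence[Finding], path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report, findings), indent=2) + "\n")
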