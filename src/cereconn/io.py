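"""Readers and writers for the plain-text interchange formats.

Atlas maps, ROI time series and FD traces travel as TSV; clinical tables as
CSV (empty cell = missing).  Subject metadata rides either in a JSON sidecar
(same stem, ``.json``) or in a BIDS-like filename convention
``sub-<id>_group-<g>_task-<c>.tsv``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AtlasMap,
    ClinicalTable,
    FdTrace,
    FormatError,
    NETWORKS,
    RoiTimeSeries,
)

# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------


def read_atlas_map(path: str | Path) -> AtlasMap:
    """Read a TSV atlas map with columns ``roi_id`` and ``network``.

    ROI order follows file order.  Networks are listed in first-appearance
    order, unless exactly the six default networks are present, in which
    case the canonical order (DMN, FP, CO, SM, OCC, CER) is used so feature
    indices stay stable across differently sorted files.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("roi_id", "network"):
        if col not in df.columns:
            raise FormatError(f"{path}: atlas map missing column {col!r}")
    if df["roi_id"].duplicated().any():
        dup = df.loc[df["roi_id"].duplicated(), "roi_id"].iloc[0]
        raise FormatError(f"{path}: duplicate ROI {dup!r}")
    if df["network"].isna().any() or (df["network"].str.strip() == "").any():
        raise FormatError(f"{path}: empty network field")
    rois = tuple(df["roi_id"])
    network_of = dict(zip(df["roi_id"], df["network"]))
    seen = list(dict.fromkeys(df["network"]))
    networks = tuple(NETWORKS) if set(seen) == set(NETWORKS) else tuple(seen)
    return AtlasMap(rois, network_of, networks)


def write_atlas_map(atlas: AtlasMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {"roi_id": atlas.roi_labels, "network": [atlas.network_of[r] for r in atlas.roi_labels]}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ROI time series
# ---------------------------------------------------------------------------

_TS_NAME_RE = re.compile(r"sub-(?P<sub>[^_]+)_group-(?P<group>.+)_task-(?P<task>.+)\.tsv$")


def timeseries_filename(ts: RoiTimeSeries) -> str:
    """Canonical filename for a time-series table."""
    return f"sub-{ts.subject_id}_group-{ts.group}_task-{ts.condition}.tsv"


def _parse_ts_name(path: Path) -> dict[str, str]:
    m = _TS_NAME_RE.search(path.name)
    if m is None:
        raise FormatError(
            f"{path}: no JSON sidecar and filename does not follow "
            "sub-<id>_group-<g>_task-<c>.tsv"
        )
    return {"subject_id": m["sub"], "group": m["group"], "condition": m["task"]}


def read_timeseries(path: str | Path, atlas: AtlasMap) -> RoiTimeSeries:
    """Read a TSV ROI-by-time table and reorder rows to atlas order.

    First column is ``roi_id``; remaining columns are time points.  Subject
    metadata comes from a ``.json`` sidecar if present, else from the
    filename convention.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "roi_id":
        raise FormatError(f"{path}: first column must be roi_id")
    df = df.set_index("roi_id")
    missing = [r for r in atlas.roi_labels if r not in df.index]
    if missing:
        raise FormatError(f"{path}: missing ROI {missing[0]!r} relative to atlas")
    try:
        data = df.loc[list(atlas.roi_labels)].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell in time series ({exc})") from exc

    sidecar = path.with_suffix(".json")
    sampling_interval = 2.5
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sampling_interval = float(meta.get("sampling_interval", sampling_interval))
    else:
        meta = _parse_ts_name(path)
    return RoiTimeSeries(
        subject_id=str(meta["subject_id"]),
        group=str(meta["group"]),
        condition=str(meta["condition"]),
        data=data,
        sampling_interval=sampling_interval,
        roi_labels=atlas.roi_labels,
    )


def write_timeseries(
    ts: RoiTimeSeries, path: str | Path, *, sidecar: bool = True
) -> Path:
    """Write a time-series TSV (and JSON sidecar) under the naming convention.

    ``path`` may be a directory (canonical filename is appended) or a full
    file path.
    """
    path = Path(path)
    if path.is_dir():
        path = path / timeseries_filename(ts)
    labels = ts.roi_labels if ts.roi_labels is not None else tuple(
        f"ROI_{i + 1:03d}" for i in range(ts.n_rois)
    )
    cols = [f"t{j + 1:04d}" for j in range(ts.n_volumes)]
    df = pd.DataFrame(ts.data, index=pd.Index(labels, name="roi_id"), columns=cols)
    df.to_csv(path, sep="\t")
    if sidecar:
        meta = {
            "subject_id": ts.subject_id,
            "group": ts.group,
            "condition": ts.condition,
            "sampling_interval": ts.sampling_interval,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


# ---------------------------------------------------------------------------
# FD traces
# ---------------------------------------------------------------------------


def read_fd_trace(path: str | Path, subject_id: str | None = None) -> FdTrace:
    """Read a TSV FD trace with columns ``volume`` and ``fd_mm``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "fd_mm" not in df.columns:
        raise FormatError(f"{path}: FD trace missing column 'fd_mm'")
    if subject_id is None:
        m = re.search(r"sub-([^_]+)", path.name)
        subject_id = m.group(1) if m else path.stem
    return FdTrace(subject_id=subject_id, fd=df["fd_mm"].to_numpy(dtype=float))


def write_fd_trace(trace: FdTrace, path: str | Path) -> Path:
    path = Path(path)
    if path.is_dir():
        path = path / f"sub-{trace.subject_id}_fd.tsv"
    df = pd.DataFrame({"volume": np.arange(1, trace.fd.size + 1), "fd_mm": trace.fd})
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read a CSV clinical-cognitive table; empty cells mark missing values.

    An optional JSON sidecar may declare theoretical per-column bounds; the
    SAPS/SANS 0-5 scale is declared automatically for symptom columns.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: clinical table missing column 'subject_id'")
    df = df.set_index("subject_id")
    bounds: dict[str, tuple[float, float]] = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text()).get("column_bounds", {})
        bounds = {k: (float(v[0]), float(v[1])) for k, v in raw.items()}
    return ClinicalTable(data=df, column_bounds=bounds)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> Path:
    path = Path(path)
    table.data.to_csv(path)
    if table.column_bounds:
        path.with_suffix(".json").write_text(
            json.dumps({"column_bounds": {k: list(v) for k, v in table.column_bounds.items()}},
                       indent=1)
        )
    return path
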