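"""File formats: time series, metadata, connectivity tables and reports.

Time series are stored in HDF5 (datasets ``/data`` ROI-by-sample,
``/roi_ids``, ``/sampling_rate``, ``/epoch_flags``) with a plain-CSV
fallback (rows = samples, columns = ROIs, plus a JSON sidecar carrying
the sampling rate and epoch flags).  Tabular outputs are TSV; reports are
JSON.  All readers validate schemas and report the offending column or
row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .containers import ConnectivityRecord, RoiTimeSeries
from .outcomes import SubjectOutcome

METADATA_COLUMNS = (
    "subject_id", "group", "lead_hemispheres", "lead_lobes",
    "baseline_sz_per_wk", "followup1_sz_per_wk", "followup2_sz_per_wk",
    "stim_enabled", "concurrent_resection",
)


# ---------------------------------------------------------------------------
# time series

def write_timeseries(ts: RoiTimeSeries, path: str | Path, fmt: str = "hdf5") -> Path:
    path = Path(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=ts.data)
            f.create_dataset("roi_ids", data=np.array(ts.roi_ids, dtype="S"))
            f.create_dataset("sampling_rate", data=float(ts.sampling_rate))
            f.create_dataset("epoch_flags", data=ts.epoch_flags.astype(bool))
            f.attrs["subject_id"] = ts.subject_id
    elif fmt == "csv":
        pd.DataFrame(ts.data.T, columns=ts.roi_ids).to_csv(path, index=False)
        meta = {
            "subject_id": ts.subject_id,
            "sampling_rate": ts.sampling_rate,
            "epoch_flags": ts.epoch_flags.astype(int).tolist(),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"format must be 'hdf5' or 'csv', got {fmt!r}")
    return path


def read_timeseries(path: str | Path) -> RoiTimeSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time-series file not found: {path}")
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return RoiTimeSeries(
                subject_id=str(f.attrs["subject_id"]),
                sampling_rate=float(f["sampling_rate"][()]),
                roi_ids=[r.decode() for r in f["roi_ids"][()]],
                data=f["data"][()],
                epoch_flags=f["epoch_flags"][()],
            )
    frame = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"CSV time series requires sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    return RoiTimeSeries(
        subject_id=str(meta["subject_id"]),
        sampling_rate=float(meta["sampling_rate"]),
        roi_ids=list(frame.columns),
        data=frame.to_numpy().T,
        epoch_flags=np.asarray(meta["epoch_flags"], dtype=bool),
    )


# ---------------------------------------------------------------------------
# subject metadata

def _join(items: Sequence[str]) -> str:
    return "|".join(items)


def metadata_frame(
    outcomes: Sequence[SubjectOutcome], control_ids: Sequence[str]
) -> pd.DataFrame:
    rows = [
        {
            "subject_id": cid,
            "group": "control",
            "lead_hemispheres": "",
            "lead_lobes": "",
            "baseline_sz_per_wk": np.nan,
            "followup1_sz_per_wk": np.nan,
            "followup2_sz_per_wk": np.nan,
            "stim_enabled": "",
            "concurrent_resection": "",
        }
        for cid in control_ids
    ]
    rows += [
        {
            "subject_id": o.subject_id,
            "group": "patient",
            "lead_hemispheres": _join(o.lead_hemispheres),
            "lead_lobes": _join(o.lead_lobes),
            "baseline_sz_per_wk": o.baseline_sz_per_wk,
            "followup1_sz_per_wk": o.followup1_sz_per_wk,
            "followup2_sz_per_wk": o.followup2_sz_per_wk,
            "stim_enabled": o.stim_enabled,
            "concurrent_resection": o.concurrent_resection,
        }
        for o in outcomes
    ]
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


def write_metadata(
    outcomes: Sequence[SubjectOutcome], control_ids: Sequence[str], path: str | Path
) -> Path:
    path = Path(path)
    metadata_frame(outcomes, control_ids).to_csv(path, index=False)
    return path


def read_metadata(path: str | Path) -> tuple[list[str], list[SubjectOutcome]]:
    """Read the cohort metadata CSV into control ids and patient outcomes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    frame = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"metadata CSV missing columns {missing}")
    dup = frame["subject_id"][frame["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id entries: {sorted(set(dup))}")
    controls: list[str] = []
    outcomes: list[SubjectOutcome] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        if row.group == "control":
            controls.append(row.subject_id)
            continue
        if row.group != "patient":
            raise ValueError(
                f"line {row_no}: group must be 'control' or 'patient', "
                f"got {row.group!r}"
            )
        if not row.baseline_sz_per_wk > 0:
            raise ValueError(
                f"line {row_no} (column baseline_sz_per_wk): baseline seizure "
                f"frequency must be > 0, got {row.baseline_sz_per_wk}"
            )
        outcomes.append(
            SubjectOutcome(
                subject_id=row.subject_id,
                baseline_sz_per_wk=float(row.baseline_sz_per_wk),
                followup1_sz_per_wk=float(row.followup1_sz_per_wk),
                followup2_sz_per_wk=float(row.followup2_sz_per_wk),
                lead_hemispheres=tuple(str(row.lead_hemispheres).split("|")),
                lead_lobes=tuple(str(row.lead_lobes).split("|")),
                stim_enabled=str(row.stim_enabled) in ("True", "true", "1"),
                concurrent_resection=str(row.concurrent_resection)
                in ("True", "true", "1"),
            )
        )
    return controls, outcomes


# ---------------------------------------------------------------------------
# connectivity and feature tables

def connectivity_to_tsv(
    records: Iterable[ConnectivityRecord], path: str | Path
) -> Path:
    """Long-form TSV (subject_id, band, level, i, j, imcoh), upper triangle."""
    rows = []
    for rec in records:
        n = len(rec.ids)
        for a in range(n):
            for b in range(a, n):
                v = rec.values[a, b]
                if np.isnan(v):
                    continue
                rows.append(
                    (rec.subject_id, rec.band, rec.level, rec.ids[a], rec.ids[b], v)
                )
    frame = pd.DataFrame(
        rows, columns=["subject_id", "band", "level", "i", "j", "imcoh"]
    )
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def connectivity_from_tsv(path: str | Path) -> list[ConnectivityRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"connectivity file not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    needed = ["subject_id", "band", "level", "i", "j", "imcoh"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"connectivity TSV missing columns {missing}")
    records = []
    for (sid, band, level), df in frame.groupby(
        ["subject_id", "band", "level"], sort=False
    ):
        ids = sorted(set(df["i"]) | set(df["j"]))
        pos = {m: k for k, m in enumerate(ids)}
        mat = np.full((len(ids), len(ids)), np.nan)
        for i, j, v in zip(df["i"], df["j"], df["imcoh"]):
            mat[pos[i], pos[j]] = mat[pos[j], pos[i]] = v
        records.append(
            ConnectivityRecord(
                subject_id=sid, band=band, level=level, ids=ids, values=mat
            )
        )
    return records


def zscores_to_tsv(nfcs: Sequence, path: str | Path) -> Path:
    """Long-form connection z-scores (subject_id, band, module_i, module_j, z)."""
    rows = []
    for nfc in nfcs:
        for band, z in nfc.z.items():
            for (i, j), v in zip(nfc.pairs, z):
                rows.append((nfc.subject_id, band, i, j, v))
    frame = pd.DataFrame(
        rows, columns=["subject_id", "band", "module_i", "module_j", "z"]
    )
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def features_to_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def features_from_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    needed = ["subject_id", "band", "global_mean", "global_sd"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"feature TSV missing columns {missing}")
    return frame


# ---------------------------------------------------------------------------
# reports

def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json_report(report: Mapping, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return path
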