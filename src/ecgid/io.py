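"""Readers and writers for the on-disk artifacts.

Signal files are plain text, one voltage (mV) per line at 9 significant
digits, with a JSON sidecar ``<stem>.json`` carrying {fs, subject_id,
record_id}.  Fiducials are JSON with 0-based sample indices.  Manifests,
frames, templates and results are comma-separated UTF-8 CSV with a header
row and "." decimals.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SignalFormatError
from .frames import SegmentType, StandardFrame
from .matching import Template
from .peaks import FiducialSet
from .synthetic import RawRecording

__all__ = [
    "read_recording",
    "write_recording",
    "read_fiducials",
    "write_fiducials",
    "read_manifest",
    "write_manifest",
    "validate_manifest_for_evaluation",
    "read_frames",
    "write_frames",
    "read_templates",
    "write_templates",
    "write_results",
    "write_run_config",
]

_SIGNAL_FMT = "%.9g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: RawRecording, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.samples, fmt=_SIGNAL_FMT)
    _sidecar(path).write_text(
        json.dumps(
            {"fs": rec.fs, "subject_id": rec.subject_id, "record_id": rec.record_id},
            indent=2,
        )
    )


def read_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    if not path.exists():
        raise SignalFormatError(f"signal file not found: {path}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise SignalFormatError(f"missing JSON sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "subject_id", "record_id"):
        if key not in meta:
            raise SignalFormatError(f"sidecar {sidecar} missing field {key!r}")
    if meta["fs"] <= 0:
        raise SignalFormatError(f"sidecar {sidecar}: fs must be positive")
    samples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                samples.append(float(line))
            except ValueError:
                raise SignalFormatError(
                    f"{path}: non-numeric value {line!r} on line {lineno}"
                ) from None
    if len(samples) < 2 * meta["fs"]:
        raise SignalFormatError(f"{path}: insufficient samples ({len(samples)})")
    return RawRecording(np.asarray(samples), meta["fs"], meta["subject_id"], meta["record_id"])


def write_fiducials(fid: FiducialSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {
                "r_indices": fid.r_indices.tolist(),
                "t_indices": fid.t_indices.tolist(),
                "cycle_valid": fid.cycle_valid.tolist(),
            },
            indent=2,
        )
    )


def read_fiducials(path: str | Path) -> FiducialSet:
    path = Path(path)
    if not path.exists():
        raise SignalFormatError(f"fiducials file not found: {path}")
    data = json.loads(path.read_text())
    r = np.asarray(data["r_indices"], dtype=int)
    t = np.asarray(data["t_indices"], dtype=int)
    valid = np.asarray(data.get("cycle_valid", [True] * len(t)), dtype=bool)
    return FiducialSet(r, t, valid)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SignalFormatError(f"manifest not found: {path}")
    manifest = pd.read_csv(path, dtype=str)
    required = {"subject_id", "record_id", "path"}
    if not required.issubset(manifest.columns):
        raise SignalFormatError(f"manifest must have columns {sorted(required)}")
    dups = manifest.duplicated(subset=["subject_id", "record_id"])
    if dups.any():
        bad = manifest[dups][["subject_id", "record_id"]].to_records(index=False)
        raise SignalFormatError(f"duplicate (subject_id, record_id) entries: {list(bad)}")
    return manifest


def validate_manifest_for_evaluation(manifest: pd.DataFrame, n_folds: int = 4) -> None:
    """The CV protocol needs exactly n_folds records per subject and real paths."""
    counts = manifest.groupby("subject_id").size()
    bad = counts[counts != n_folds]
    if len(bad):
        raise ConfigurationError(
            "subjects without exactly "
            f"{n_folds} records: {', '.join(f'{s} ({n})' for s, n in bad.items())}"
        )
    missing = [p for p in manifest["path"] if p and not Path(p).exists()]
    if missing:
        raise SignalFormatError(f"missing signal files: {missing}")


def write_frames(frames: list[StandardFrame], path: str | Path) -> None:
    if not frames:
        raise ConfigurationError("no frames to write")
    length = len(frames[0].values)
    rows = []
    for f in frames:
        if len(f.values) != length:
            raise ConfigurationError("all frames in one file must share one length")
        row = {
            "subject_id": f.subject_id,
            "record_id": f.record_id,
            "segment_type": f.segment_type.value,
            "n_cycles": f.n_cycles,
        }
        row.update({f"v{i + 1}": v for i, v in enumerate(f.values)})
        rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_frames(path: str | Path) -> list[StandardFrame]:
    path = Path(path)
    if not path.exists():
        raise SignalFormatError(f"frames file not found: {path}")
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c.startswith("v")]
    frames = []
    for _, row in df.iterrows():
        frames.append(
            StandardFrame(
                row[value_cols].to_numpy(dtype=float),
                int(row["n_cycles"]),
                SegmentType(row["segment_type"]),
                str(row["subject_id"]),
                str(row["record_id"]),
            )
        )
    return frames


def write_templates(templates: list[Template], path: str | Path) -> None:
    rows = []
    for t in templates:
        row = {"subject_id": t.subject_id, "n_sources": t.n_sources}
        row.update({f"v{i + 1}": v for i, v in enumerate(t.mean_frame)})
        rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_templates(path: str | Path) -> list[Template]:
    path = Path(path)
    if not path.exists():
        raise SignalFormatError(f"templates file not found: {path}")
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c.startswith("v")]
    return [
        Template(
            row[value_cols].to_numpy(dtype=float),
            int(row["n_sources"]),
            str(row["subject_id"]),
        )
        for _, row in df.iterrows()
    ]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if hasattr(obj, "value"):  # enums
        return obj.value
    return obj


def write_run_config(config: object, path: str | Path) -> None:
    """Serialize the resolved run configuration next to its outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(config), indent=2, default=str))
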