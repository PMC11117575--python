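"""File formats for sequences, field archives, curves, features and reports.

Image sequences are multi-page TIFF (or a directory of numbered PNG/TIFF
frames) with a JSON sidecar carrying the frame interval, scale and provenance.
Field histories go into compressed ``.npz`` archives with an embedded JSON
header (grid, units, validity, config hash) because no established on-disk
standard exists for DIC fields.  Curves, feature tables and ROC points are
plain CSV; reports are JSON with sorted keys so byte-identical reruns diff
cleanly.

Every artifact records the hash of the configuration that produced it;
downstream stages refuse to mix artifacts with different hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .dic import DisplacementField, ImageSequence, MeasurementGrid
from .features import CURVE_NAMES, EvolutionCurves, FeatureMatrix
from .kinematics import RateField, StrainField

__all__ = [
    "config_hash",
    "read_sequence",
    "write_sequence",
    "save_displacement_field",
    "load_displacement_field",
    "save_kinematics",
    "load_kinematics",
    "write_curves_csv",
    "read_curves_csv",
    "write_feature_csv",
    "read_feature_csv",
    "write_manifest",
    "read_manifest",
    "write_report_json",
    "write_roc_csv",
]

DEFAULT_FRAME_INTERVAL = 30.0 / 139.0  # ms; 140 frames spanning ~30 ms

_LUMA = np.array([0.2989, 0.5870, 0.1140])


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config) -> str:
    """Short stable hash of a configuration object (dataclass or dict)."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ----------------------------------------------------------------------------
# Sequences
# ----------------------------------------------------------------------------


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        return frame[..., :3].astype(float) @ _LUMA
    return frame


def read_sequence(
    path: str | Path,
    frame_interval: float | None = None,
    scale: float | None = None,
) -> ImageSequence:
    """Load a multi-page TIFF or a directory of lexicographically ordered frames.

    RGB frames are converted to grayscale by luminance.  The frame interval is
    taken from the JSON sidecar (``<path>.json`` or ``meta.json`` in a frame
    directory) unless given explicitly; the fallback default assumes 140
    frames spanning ~30 ms.
    """
    path = Path(path)
    meta: dict = {}
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if len(files) < 2:
            raise ValueError(f"{path}: need at least 2 frames, found {len(files)}")
        frames = [_to_gray(np.asarray(iio.imread(f))) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"{path}: frames have mixed shapes {sorted(shapes)}")
        stack = np.stack(frames)
        sidecar = path / "meta.json"
    else:
        stack = np.asarray(tifffile.imread(path))
        if stack.ndim == 2:
            raise ValueError(f"{path}: single-frame file; a sequence needs >= 2 frames")
        if stack.ndim == 4:  # multi-page RGB
            stack = np.stack([_to_gray(f) for f in stack])
        sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fi = frame_interval or meta.get("frame_interval") or DEFAULT_FRAME_INTERVAL
    return ImageSequence(
        frames=stack,
        frame_interval=float(fi),
        scale=scale if scale is not None else meta.get("scale"),
        exam_id=meta.get("exam_id", path.stem),
    )


def write_sequence(
    seq: ImageSequence,
    path: str | Path,
    config=None,
    extra: dict | None = None,
) -> Path:
    """Write a multi-page TIFF plus a JSON sidecar with config and provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = seq.frames
    if frames.dtype != np.uint8:
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, frames)
    meta = {
        "exam_id": seq.exam_id,
        "frame_interval": seq.frame_interval,
        "scale": seq.scale,
        "n_frames": int(seq.n_frames),
    }
    if config is not None:
        meta["config"] = _jsonable(config)
        meta["config_hash"] = config_hash(config)
    if extra:
        meta.update(_jsonable(extra))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, sort_keys=True, indent=2))
    return path


# ----------------------------------------------------------------------------
# Field archives
# ----------------------------------------------------------------------------


def _grid_header(grid: MeasurementGrid) -> dict:
    return {"step": grid.step, "subset_size": grid.subset_size}


def save_displacement_field(field: DisplacementField, path: str | Path, config=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "kind": "displacement_field",
        "units": {"U": "px", "V": "px"},
        "exam_id": field.exam_id,
        "frame_interval": field.frame_interval,
        "rigid_compensated": field.rigid_compensated,
        "grid": _grid_header(field.grid),
        "config_hash": config_hash(config) if config is not None else None,
    }
    np.savez_compressed(
        path,
        U=field.U,
        V=field.V,
        dU=field.dU,
        dV=field.dV,
        quality=field.quality,
        valid=field.valid,
        filled=field.filled,
        points=field.grid.points,
        header=np.array(json.dumps(header, sort_keys=True)),
    )
    return path


def load_displacement_field(path: str | Path) -> tuple[DisplacementField, dict]:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        grid = MeasurementGrid(
            points=z["points"],
            step=header["grid"]["step"],
            subset_size=header["grid"]["subset_size"],
        )
        field = DisplacementField(
            U=z["U"],
            V=z["V"],
            dU=z["dU"],
            dV=z["dV"],
            quality=z["quality"],
            valid=z["valid"],
            filled=z["filled"],
            grid=grid,
            frame_interval=header["frame_interval"],
            exam_id=header["exam_id"],
            rigid_compensated=header.get("rigid_compensated", False),
        )
    return field, header


def save_kinematics(
    path: str | Path,
    field: DisplacementField,
    strain: StrainField,
    rates: RateField,
    config=None,
) -> Path:
    """One archive holding the displacement, strain and rate histories of an exam."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "kind": "kinematics",
        "units": {"U": "px", "V": "px", "UR": "px/ms", "strain": "1", "strain_rate": "1/ms"},
        "exam_id": field.exam_id,
        "frame_interval": field.frame_interval,
        "window_radius": strain.window_radius,
        "grid": _grid_header(field.grid),
        "config_hash": config_hash(config) if config is not None else None,
    }
    np.savez_compressed(
        path,
        U=field.U,
        V=field.V,
        quality=field.quality,
        valid=field.valid,
        filled=field.filled,
        points=field.grid.points,
        exx=strain.exx,
        eyy=strain.eyy,
        gxy=strain.gxy,
        strain_valid=strain.valid,
        UR=rates.UR,
        VR=rates.VR,
        exxR=rates.exxR,
        eyyR=rates.eyyR,
        gxyR=rates.gxyR,
        header=np.array(json.dumps(header, sort_keys=True)),
    )
    return path


def load_kinematics(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        arrays = {k: z[k] for k in z.files if k != "header"}
    return arrays, header


# ----------------------------------------------------------------------------
# Curves / features / manifests / reports
# ----------------------------------------------------------------------------


def write_curves_csv(curves: EvolutionCurves, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curves.to_frame().to_csv(path, index=False)
    return path


def read_curves_csv(
    path: str | Path, exam_id: str = "", frame_interval: float = DEFAULT_FRAME_INTERVAL
) -> EvolutionCurves:
    df = pd.read_csv(path)
    missing = set(CURVE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing curve columns {sorted(missing)}")
    return EvolutionCurves.from_frame(df, exam_id=exam_id or Path(path).stem, frame_interval=frame_interval)


def write_feature_csv(matrix: FeatureMatrix, path: str | Path) -> Path:
    """Feature table: exam_id index plus one column per curve@frame feature.

    Labels live in the cohort manifest, not here.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.X.to_csv(path)
    return path


def read_feature_csv(path: str | Path, manifest: pd.DataFrame) -> FeatureMatrix:
    X = pd.read_csv(path, index_col="exam_id")
    labels = manifest.set_index("exam_id")["label"]
    missing = set(X.index) - set(labels.index)
    if missing:
        raise ValueError(f"exams missing from manifest: {sorted(missing)[:5]}")
    y = labels.loc[X.index].to_numpy(dtype=int)
    curves = sorted({c.split("@")[0] for c in X.columns})
    k = max(int(c.split("@")[1]) for c in X.columns) + 1
    return FeatureMatrix(X=X, y=y, curve_subset=tuple(curves), k=k)


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["exam_id", "label", "path"]).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"exam_id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: manifest needs exam_id and label columns")
    return df


def write_report_json(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(report), sort_keys=True, indent=2) + "\n")
    return path


def write_roc_csv(reports: dict, path: str | Path) -> Path:
    """ROC points of every model in one diff-able CSV (model, fpr, tpr, threshold)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, rep in reports.items():
        if rep.roc is None:
            continue
        for f, t, thr in zip(rep.roc.fpr, rep.roc.tpr, rep.roc.thresholds):
            rows.append({"model": name, "fpr": f, "tpr": t, "threshold": thr})
    pd.DataFrame(rows, columns=["model", "fpr", "tpr", "threshold"]).to_csv(path, index=False)
    return path
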