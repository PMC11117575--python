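"""Evolution curves and cohort feature matrices.

Each exam's field histories are reduced to eight scalar time series: the
maximum and the average over the valid grid points of |V| (vertical
displacement), |gamma_xy| (shear strain), |VR| (vertical velocity) and
|gamma_xy_R| (shear strain rate), one value per frame.  Magnitudes are used
because the sign of V depends only on the imaging convention and signed maxima
are dominated by noise polarity; pass ``magnitude=False`` for signed curves.

Feature matrices flatten a chosen subset of curves over the first ``k`` time
points, one row per exam, with deterministic ``curve@frame`` column names.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CURVE_NAMES",
    "AVE_CURVES",
    "MAX_CURVES",
    "EvolutionCurves",
    "FeatureMatrix",
    "extract_evolution_curves",
    "assemble_feature_matrix",
]

CURVE_NAMES = (
    "max_V",
    "max_gxy",
    "max_VR",
    "max_gxyR",
    "ave_V",
    "ave_gxy",
    "ave_VR",
    "ave_gxyR",
)
MAX_CURVES = CURVE_NAMES[:4]
AVE_CURVES = CURVE_NAMES[4:]


@dataclasses.dataclass
class EvolutionCurves:
    """Eight named scalar time series of equal length for one exam."""

    exam_id: str
    frame_interval: float
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.data) != set(CURVE_NAMES):
            missing = set(CURVE_NAMES) ^ set(self.data)
            raise ValueError(f"curves must be exactly {CURVE_NAMES}; mismatch: {sorted(missing)}")
        lengths = {len(v) for v in self.data.values()}
        if len(lengths) != 1:
            raise ValueError("all curves must have the same length")
        self.data = {k: np.asarray(self.data[k], dtype=float) for k in CURVE_NAMES}

    @property
    def n_frames(self) -> int:
        return len(self.data[CURVE_NAMES[0]])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({k: self.data[k] for k in CURVE_NAMES})
        df.insert(0, "frame", np.arange(self.n_frames))
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, exam_id: str = "", frame_interval: float = 30.0 / 139.0
    ) -> "EvolutionCurves":
        return cls(
            exam_id=exam_id,
            frame_interval=frame_interval,
            data={k: df[k].to_numpy(dtype=float) for k in CURVE_NAMES},
        )


def _field_stats(Q: np.ndarray, valid: np.ndarray, magnitude: bool) -> tuple[np.ndarray, np.ndarray]:
    vals = np.where(valid, np.abs(Q) if magnitude else Q, np.nan)
    counts = valid.sum(axis=1)
    if (counts == 0).any():
        bad = int(np.nonzero(counts == 0)[0][0])
        raise ValueError(f"frame {bad} has zero valid grid points")
    return np.nanmean(vals, axis=1), np.nanmax(vals, axis=1)


def extract_evolution_curves(
    V: np.ndarray,
    gxy: np.ndarray,
    VR: np.ndarray,
    gxyR: np.ndarray,
    valid: np.ndarray | None = None,
    exam_id: str = "",
    frame_interval: float = 30.0 / 139.0,
    magnitude: bool = True,
) -> EvolutionCurves:
    """Per-frame max and average (over valid points) of the four quantities.

    Invalid grid points are excluded from both statistics rather than
    in-filled, matching the validity semantics of the tracking stage.
    """
    V, gxy, VR, gxyR = (np.asarray(a, dtype=float) for a in (V, gxy, VR, gxyR))
    if not (V.shape == gxy.shape == VR.shape == gxyR.shape) or V.ndim != 2:
        raise ValueError("all fields must share one (T, N) shape")
    if valid is None:
        valid = np.ones(V.shape, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != V.shape:
        raise ValueError("valid flags must match the field shape")

    data: dict[str, np.ndarray] = {}
    for name, Q in (("V", V), ("gxy", gxy), ("VR", VR), ("gxyR", gxyR)):
        ave, mx = _field_stats(Q, valid, magnitude)
        data[f"ave_{name}"] = ave
        data[f"max_{name}"] = mx
    return EvolutionCurves(exam_id=exam_id, frame_interval=frame_interval, data=data)


@dataclasses.dataclass
class FeatureMatrix:
    """Exam-by-feature table with class labels (0 = normal, 1 = FFKC)."""

    X: pd.DataFrame  # rows indexed by exam_id, columns 'curve@frame'
    y: np.ndarray
    curve_subset: tuple[str, ...]
    k: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != self.y.size:
            raise ValueError("label count must match row count")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X.iloc[idx], self.y[idx], self.curve_subset, self.k)


def _as_items(items: Iterable) -> list[tuple[EvolutionCurves, int]]:
    out = []
    for it in items:
        if isinstance(it, tuple):
            curves, label = it
        else:
            curves, label = it.curves, it.label
        if curves is None:
            raise ValueError("item has no evolution curves")
        out.append((curves, int(label)))
    if not out:
        raise ValueError("empty cohort")
    return out


def assemble_feature_matrix(
    items: Iterable,
    curve_subset: Sequence[str] = AVE_CURVES,
    k: int | None = None,
) -> FeatureMatrix:
    """Flatten the first ``k`` frames of the selected curves into a matrix.

    ``items`` is a sequence of ``(EvolutionCurves, label)`` pairs or objects
    with ``.curves`` / ``.label`` attributes (e.g. cohort exams).  The default
    subset is the four average curves; with the full 140-frame series that
    yields 560 features per exam.  Feature count is exactly
    ``len(curve_subset) * k``; columns are ordered curve-major and named
    ``curve@frame``.
    """
    pairs = _as_items(items)
    unknown = set(curve_subset) - set(CURVE_NAMES)
    if unknown:
        raise ValueError(f"unknown curve names: {sorted(unknown)}")
    if not curve_subset:
        raise ValueError("curve_subset must not be empty")
    T = pairs[0][0].n_frames
    if any(c.n_frames != T for c, _ in pairs):
        raise ValueError("all exams must share the same number of frames")
    if k is None:
        k = T
    if not 1 <= k <= T:
        raise ValueError(f"k must be in [1, {T}]")

    columns = [f"{name}@{t}" for name in curve_subset for t in range(k)]
    rows = np.stack(
        [np.concatenate([c[name][:k] for name in curve_subset]) for c, _ in pairs]
    )
    if not np.isfinite(rows).all():
        raise ValueError("feature matrix contains missing values")
    index = pd.Index([c.exam_id for c, _ in pairs], name="exam_id")
    X = pd.DataFrame(rows, index=index, columns=columns)
    y = np.array([label for _, label in pairs], dtype=int)
    return FeatureMatrix(X=X, y=y, curve_subset=tuple(curve_subset), k=k)
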