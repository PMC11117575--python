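"""Strain and rate kinematics derived from tracked displacement fields.

Cauchy strain components come from a pointwise least-squares plane fit of the
displacements over a local window: with u = a0 + a1*x + a2*y and
v = b0 + b1*x + b2*y fitted by ordinary least squares over valid neighbours,

    eps_xx = a1,   eps_yy = b2,   gamma_xy = a2 + b1,

where gamma_xy is the engineering shear (sum of the cross-derivatives, the
standard DIC convention; set ``engineering_shear=False`` for the tensor
half-shear).  Strains are dimensionless and invariant to adding a constant to
U or V; on affine displacement fields the plane fit is an interpolant, so the
strains are exact to machine precision.

Temporal velocities (UR, VR, px/ms) and strain rates (1/ms) use central
differences at interior frames and first-order one-sided differences at the
two ends, which is linear, reproducible and endpoint-complete.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .dic import DisplacementField, MeasurementGrid

__all__ = [
    "StrainField",
    "RateField",
    "pointwise_ls_strain",
    "temporal_rate",
    "rate_scheme",
    "compute_rates",
    "compensate_rigid_motion",
]


@dataclasses.dataclass
class StrainField:
    exx: np.ndarray  # (T, N), dimensionless
    eyy: np.ndarray
    gxy: np.ndarray
    valid: np.ndarray  # bool (T, N)
    window_radius: float
    grid: MeasurementGrid | None = None


@dataclasses.dataclass
class RateField:
    UR: np.ndarray  # px/ms
    VR: np.ndarray
    exxR: np.ndarray  # 1/ms
    eyyR: np.ndarray
    gxyR: np.ndarray
    scheme: np.ndarray  # per-frame marker: forward/central/backward
    frame_interval: float


def pointwise_ls_strain(
    field: DisplacementField,
    grid: MeasurementGrid | None = None,
    window_radius: float | None = None,
    min_neighbors: int = 6,
    engineering_shear: bool = True,
) -> StrainField:
    """Pointwise least-squares strain on the measurement grid.

    A point is valid at a frame when its window holds at least
    ``min_neighbors`` valid displacement samples (itself included) spanning a
    full-rank plane fit; rank-deficient (collinear) neighbourhoods are flagged
    invalid, never extrapolated.
    """
    grid = grid or field.grid
    wr = window_radius if window_radius is not None else 2.0 * grid.step
    pts = grid.points
    T, N = field.U.shape
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r=wr + 1e-9)

    exx = np.zeros((T, N))
    eyy = np.zeros((T, N))
    gxy = np.zeros((T, N))
    valid = np.zeros((T, N), dtype=bool)
    shear_factor = 1.0 if engineering_shear else 0.5

    for i in range(N):
        nbi = np.asarray(neighbors[i], dtype=int)
        dx = pts[nbi, 0] - pts[i, 0]
        dy = pts[nbi, 1] - pts[i, 1]
        A = np.column_stack([np.ones(nbi.size), dx, dy])
        nb_valid = field.valid[:, nbi]  # (T, k)
        all_ok = nb_valid.all(axis=1)

        if nbi.size >= min_neighbors and np.linalg.matrix_rank(A) == 3:
            pinv = np.linalg.pinv(A)  # (3, k)
            if all_ok.any():
                sel = np.nonzero(all_ok)[0]
                cu = field.U[np.ix_(sel, nbi)] @ pinv.T  # (t, 3)
                cv = field.V[np.ix_(sel, nbi)] @ pinv.T
                exx[sel, i] = cu[:, 1]
                eyy[sel, i] = cv[:, 2]
                gxy[sel, i] = shear_factor * (cu[:, 2] + cv[:, 1])
                valid[sel, i] = True

        # frames with partially invalid neighbourhoods: refit on the valid subset
        for t in np.nonzero(~all_ok)[0]:
            m = nb_valid[t]
            if m.sum() < min_neighbors:
                continue
            Am = A[m]
            if np.linalg.matrix_rank(Am) < 3:
                continue
            cu, *_ = np.linalg.lstsq(Am, field.U[t, nbi[m]], rcond=None)
            cv, *_ = np.linalg.lstsq(Am, field.V[t, nbi[m]], rcond=None)
            exx[t, i] = cu[1]
            eyy[t, i] = cv[2]
            gxy[t, i] = shear_factor * (cu[2] + cv[1])
            valid[t, i] = True

    return StrainField(exx=exx, eyy=eyy, gxy=gxy, valid=valid, window_radius=wr, grid=grid)


def temporal_rate(series: np.ndarray, frame_interval: float, axis: int = 0) -> np.ndarray:
    """Finite-difference time derivative of a per-point series.

    Central differences (f[t+1] - f[t-1]) / (2 dt) at interior frames and
    first-order one-sided differences at the two ends.  Exact for series
    linear in time, including the endpoints.
    """
    series = np.asarray(series, dtype=float)
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if series.shape[axis] < 2:
        raise ValueError("need at least 2 frames to differentiate")
    return np.gradient(series, frame_interval, axis=axis, edge_order=1)


def rate_scheme(n_frames: int) -> np.ndarray:
    """Differencing scheme marker per frame."""
    scheme = np.full(n_frames, "central", dtype=object)
    scheme[0] = "forward"
    scheme[-1] = "backward"
    return scheme


def compute_rates(
    field: DisplacementField,
    strain: StrainField,
    frame_interval: float | None = None,
) -> RateField:
    """Velocities UR, VR and strain rates from the tracked histories."""
    dt = frame_interval if frame_interval is not None else field.frame_interval
    return RateField(
        UR=temporal_rate(field.U, dt),
        VR=temporal_rate(field.V, dt),
        exxR=temporal_rate(strain.exx, dt),
        eyyR=temporal_rate(strain.eyy, dt),
        gxyR=temporal_rate(strain.gxy, dt),
        scheme=rate_scheme(field.n_frames),
        frame_interval=dt,
    )


def compensate_rigid_motion(
    field: DisplacementField,
    grid: MeasurementGrid | None = None,
    fraction: float = 0.1,
    apex_x: float | None = None,
) -> DisplacementField:
    """Subtract the per-frame whole-eye translation from the field.

    The uniform translation is the mean displacement over a peripheral band of
    grid points (the outermost ``fraction`` of points by |x - apex|), where the
    air-puff deformation is negligible and any residual motion is rigid drift
    of the whole eye.  Returns a flagged copy; the pipeline default is OFF.
    """
    grid = grid or field.grid
    pts = grid.points
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 grid points")
    ax = apex_x if apex_x is not None else 0.5 * (pts[:, 0].min() + pts[:, 0].max())
    dist = np.abs(pts[:, 0] - ax)
    cut = np.quantile(dist, 1.0 - fraction)
    band = dist >= cut
    if not band.any():
        raise ValueError("peripheral band is empty")

    U = field.U.copy()
    V = field.V.copy()
    for t in range(field.n_frames):
        sel = band & field.valid[t]
        if not sel.any():
            sel = band
        U[t] -= U[t, sel].mean()
        V[t] -= V[t, sel].mean()
    # re-anchor so the frame-0 field stays identically zero
    U -= U[0]
    V -= V[0]
    return dataclasses.replace(field, U=U, V=V, rigid_compensated=True)
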