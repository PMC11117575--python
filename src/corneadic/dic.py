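"""Incremental subset-based digital image correlation.

Tracks full-field horizontal (U) and vertical (V) displacements of a
speckle-textured corneal cross-section across an air-puff image sequence.
Matching is frame-to-frame (incremental referencing): each measurement point's
subset is re-extracted from the previous frame at its current accumulated
position, matched into the next frame, and the increments are accumulated.
This tolerates the large total deformation of the air-puff test while keeping
each per-increment motion small enough for a translation-only shape function.

The matching criterion is ZNSSD (zero-normalised sum of squared differences):
an exhaustive integer-pixel search inside a radius around the initial guess,
followed by inverse-compositional Gauss-Newton refinement on a bicubic
B-spline interpolant of the deformed frame (with a paraboloid fit of the 3x3
correlation surface as fallback).  Reported quality is the ZNCC at the
optimum, so it lives in [-1, 1] and is invariant to affine intensity changes.

Coordinates: x = column (rightward), y = row (downward); V is positive
downward; the origin is the top-left pixel of frame 0; all grid coordinates
are 0-based.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import filters, measure, morphology

__all__ = [
    "ImageSequence",
    "MeasurementGrid",
    "DICConfig",
    "MatchResult",
    "DisplacementField",
    "TrackingError",
    "segment_cornea",
    "build_grid",
    "match_subset",
    "track_incremental",
]

_SPLINE_MODE = "mirror"


@dataclasses.dataclass
class ImageSequence:
    """Ordered grayscale frames of one air-puff exam."""

    frames: np.ndarray  # (T, H, W)
    frame_interval: float = 30.0 / 139.0  # ms between frames
    scale: float | None = None  # mm per pixel, if known
    exam_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if not np.isfinite(self.frames.astype(np.float64, copy=False)).all():
            raise ValueError("frame intensities must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclasses.dataclass
class MeasurementGrid:
    """Regular lattice of measurement points in frame-0 coordinates."""

    points: np.ndarray  # (N, 2) as (x, y)
    step: int
    subset_size: int
    roi_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclasses.dataclass
class DICConfig:
    """Engine parameters (all pixel units)."""

    subset_size: int = 25
    step: int = 8
    search_radius: int = 6
    quality_threshold: float = 0.8  # minimum ZNCC to keep a point alive
    max_iterations: int = 25
    convergence_tol: float = 1e-4
    mask_dilation: int = 3

    def __post_init__(self) -> None:
        if self.subset_size < 11 or self.subset_size % 2 == 0:
            raise ValueError("subset_size must be odd and >= 11")
        if self.step < 1 or self.search_radius < 1:
            raise ValueError("step and search_radius must be >= 1")


@dataclasses.dataclass
class MatchResult:
    du: float
    dv: float
    quality: float
    valid: bool
    on_border: bool = False


@dataclasses.dataclass
class DisplacementField:
    """Accumulated and incremental displacements on the measurement grid.

    ``U[t, i]`` is the accumulated horizontal displacement of point ``i`` at
    frame ``t`` relative to frame 0; ``dU`` are the per-frame increments.
    ``valid`` marks points still tracked at each frame; ``filled`` marks
    values in-filled from neighbours after a point was lost.
    """

    U: np.ndarray  # (T, N)
    V: np.ndarray
    dU: np.ndarray
    dV: np.ndarray
    quality: np.ndarray
    valid: np.ndarray  # bool (T, N)
    filled: np.ndarray  # bool (T, N)
    grid: MeasurementGrid
    frame_interval: float
    exam_id: str = ""
    rigid_compensated: bool = False

    @property
    def n_frames(self) -> int:
        return self.U.shape[0]

    @property
    def n_points(self) -> int:
        return self.U.shape[1]


class TrackingError(RuntimeError):
    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


# ----------------------------------------------------------------------------
# ROI and grid construction
# ----------------------------------------------------------------------------


def segment_cornea(frame: np.ndarray, closing_radius: int = 3) -> np.ndarray:
    """Binary mask of the bright corneal band in a single frame.

    Otsu threshold, largest connected component, morphological closing, hole
    filling (dark speckles inside the band belong to the band).  Users with
    difficult exams can supply their own mask instead.
    """
    img = np.asarray(frame, dtype=float)
    thr = filters.threshold_otsu(img)
    mask = img > thr
    lab = measure.label(mask)
    if lab.max() == 0:
        raise ValueError("segmentation found no foreground")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = lab == np.argmax(sizes)
    mask = ndi.binary_closing(mask, structure=morphology.disk(closing_radius))
    return ndi.binary_fill_holes(mask)


def build_grid(
    mask: np.ndarray,
    step: int = 8,
    subset_size: int = 25,
    mask_dilation: int = 3,
) -> MeasurementGrid:
    """Regular lattice restricted to centres whose full subset fits the ROI.

    A centre is admissible when it lies on the mask and its whole
    ``subset_size`` window is inside both the image (with one pixel of slack,
    so the subset can move) and the mask dilated by ``mask_dilation`` pixels.
    Ordering is deterministic (row-major).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("mask must be a non-empty 2-D boolean image")
    if subset_size % 2 == 0 or subset_size < 11:
        raise ValueError("subset_size must be odd and >= 11")
    half = subset_size // 2
    allowed = ndi.binary_dilation(mask, iterations=mask_dilation) if mask_dilation else mask
    ok = ndi.minimum_filter(
        allowed.astype(np.uint8), size=subset_size, mode="constant", cval=0
    ).astype(bool)
    ok &= mask
    h, w = mask.shape
    ys = np.arange(half + 1, h - half - 1, step)
    xs = np.arange(half + 1, w - half - 1, step)
    pts = [(float(x), float(y)) for y in ys for x in xs if ok[y, x]]
    if not pts:
        raise ValueError("empty measurement grid: ROI too thin for the subset size")
    return MeasurementGrid(np.array(pts), step=step, subset_size=subset_size, roi_mask=mask)


# ----------------------------------------------------------------------------
# Subset matching
# ----------------------------------------------------------------------------


def _spline(img: np.ndarray) -> np.ndarray:
    return ndi.spline_filter(np.asarray(img, dtype=np.float64), order=3, mode=_SPLINE_MODE)


def _sample(coef: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return ndi.map_coordinates(coef, [ys, xs], order=3, prefilter=False, mode=_SPLINE_MODE)


def match_subset(
    ref_frame: np.ndarray | None = None,
    cur_frame: np.ndarray | None = None,
    point: tuple[float, float] = (0.0, 0.0),
    init_guess: tuple[float, float] = (0.0, 0.0),
    subset_size: int = 25,
    search_radius: int = 6,
    max_iterations: int = 25,
    convergence_tol: float = 1e-4,
    ref_coef: np.ndarray | None = None,
    cur_coef: np.ndarray | None = None,
) -> MatchResult:
    """ZNSSD match of one subset between two frames.

    Integer-pixel exhaustive search in ``search_radius`` around ``init_guess``
    followed by IC-Gauss-Newton subpixel refinement (translation-only shape
    function).  ``ref_coef``/``cur_coef`` accept precomputed cubic-spline
    coefficients so callers tracking many points pay the prefilter once.

    A flat (zero-variance) reference subset yields an invalid flagged result
    rather than an exception; an optimum on the search border is flagged.
    """
    if ref_coef is None:
        if ref_frame is None:
            raise ValueError("either ref_frame or ref_coef is required")
        ref_coef = _spline(ref_frame)
    if cur_coef is None:
        if cur_frame is None:
            raise ValueError("either cur_frame or cur_coef is required")
        cur_coef = _spline(cur_frame)

    px, py = float(point[0]), float(point[1])
    gx, gy = float(init_guess[0]), float(init_guess[1])
    half = subset_size // 2
    h, w = ref_coef.shape
    n = subset_size * subset_size

    oy, ox = np.mgrid[-half : half + 1, -half : half + 1].astype(float)

    # reference subset must lie inside the reference frame
    if px - half < 0 or px + half > w - 1 or py - half < 0 or py + half > h - 1:
        return MatchResult(0.0, 0.0, 0.0, valid=False)
    f = _sample(ref_coef, px + ox, py + oy)
    fm = f.mean()
    fc = f - fm
    normf = float(np.sqrt((fc**2).sum()))
    if normf < 1e-8 * (1.0 + abs(fm)) * np.sqrt(n):
        return MatchResult(0.0, 0.0, 0.0, valid=False)  # flat subset

    # --- integer search around the initial guess ------------------------------
    r = search_radius
    # admissible integer offsets keeping the deformed subset inside the image
    i_lo = int(np.ceil(max(-r, -(px + gx - half))))
    i_hi = int(np.floor(min(r, (w - 1) - (px + gx + half))))
    j_lo = int(np.ceil(max(-r, -(py + gy - half))))
    j_hi = int(np.floor(min(r, (h - 1) - (py + gy + half))))
    if i_lo > i_hi or j_lo > j_hi:
        return MatchResult(0.0, 0.0, 0.0, valid=False)

    wys, wxs = np.mgrid[j_lo - half : j_hi + half + 1, i_lo - half : i_hi + half + 1]
    window = _sample(cur_coef, px + gx + wxs.astype(float), py + gy + wys.astype(float))
    sw = sliding_window_view(window, (subset_size, subset_size))
    num = np.einsum("abij,ij->ab", sw, fc)
    s1 = sw.sum(axis=(-1, -2))
    s2 = np.einsum("abij,abij->ab", sw, sw)
    var = np.maximum(s2 - s1 * s1 / n, 0.0)
    denom = np.sqrt(var) * normf
    zncc = np.where(denom > 1e-12, num / denom, -1.0)
    bj, bi = np.unravel_index(int(np.argmax(zncc)), zncc.shape)
    # low confidence only when the optimum sits at the requested search radius
    # (an image-bound clip of the window is not in itself suspicious)
    on_border = abs(i_lo + bi) >= r or abs(j_lo + bj) >= r
    du0 = gx + i_lo + bi
    dv0 = gy + j_lo + bj

    # --- subpixel refinement: IC Gauss-Newton on the spline interpolant -------
    patch = _sample(
        ref_coef,
        px + np.mgrid[-half - 1 : half + 2, -half - 1 : half + 2][1].astype(float),
        py + np.mgrid[-half - 1 : half + 2, -half - 1 : half + 2][0].astype(float),
    )
    gy_, gx_ = np.gradient(patch)
    fx = gx_[1:-1, 1:-1].ravel()
    fy = gy_[1:-1, 1:-1].ravel()
    J = np.stack([fx, fy], axis=1)  # (n, 2)
    H = J.T @ J
    p = np.array([du0, dv0], dtype=float)
    refined = False
    if np.linalg.cond(H) < 1e10:
        for _ in range(max_iterations):
            xs = px + p[0] + ox
            ys = py + p[1] + oy
            if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
                break
            g = _sample(cur_coef, xs, ys)
            gc = g - g.mean()
            normg = float(np.sqrt((gc**2).sum()))
            if normg < 1e-12:
                break
            rvec = (gc / normg - fc / normf).ravel()
            delta = np.linalg.solve(H, J.T @ rvec) * normf
            p -= delta
            if np.hypot(*delta) < convergence_tol:
                refined = True
                break
        if np.hypot(p[0] - du0, p[1] - dv0) > 1.5:
            refined = False  # diverged away from the integer optimum

    if not refined:
        # fallback: separable paraboloid fit of the 3x3 ZNCC surface
        p = np.array([du0, dv0], dtype=float)
        if 0 < bi < zncc.shape[1] - 1:
            l, m, rr = zncc[bj, bi - 1], zncc[bj, bi], zncc[bj, bi + 1]
            den = l - 2 * m + rr
            if den < 0:
                p[0] += 0.5 * (l - rr) / den
        if 0 < bj < zncc.shape[0] - 1:
            u, m, dwn = zncc[bj - 1, bi], zncc[bj, bi], zncc[bj + 1, bi]
            den = u - 2 * m + dwn
            if den < 0:
                p[1] += 0.5 * (u - dwn) / den

    xs = px + p[0] + ox
    ys = py + p[1] + oy
    if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
        return MatchResult(float(p[0]), float(p[1]), 0.0, valid=False, on_border=True)
    g = _sample(cur_coef, xs, ys)
    gc = g - g.mean()
    normg = float(np.sqrt((gc**2).sum()))
    quality = float((fc * gc).sum() / (normf * normg)) if normg > 1e-12 else 0.0
    return MatchResult(float(p[0]), float(p[1]), quality, valid=True, on_border=on_border)


# ----------------------------------------------------------------------------
# Incremental tracking
# ----------------------------------------------------------------------------


def track_incremental(
    sequence: ImageSequence,
    grid: MeasurementGrid,
    config: DICConfig | None = None,
) -> DisplacementField:
    """Track every grid point through the sequence, accumulating increments.

    For each consecutive frame pair the reference subset is re-extracted from
    the earlier frame at the point's current accumulated position (incremental
    referencing) and matched into the later frame with the previous increment
    as the initial guess (spatial median of already-solved neighbours when a
    point has no history yet).  Points whose ZNCC drops below the quality
    threshold, or whose optimum hits the search border, are invalidated from
    that frame onward and in-filled with the median of valid neighbours within
    one grid step (the fill is flagged, not silent).

    Raises :class:`TrackingError` when more than half the points are invalid
    at any frame.
    """
    cfg = config or DICConfig(subset_size=grid.subset_size, step=grid.step)
    ss = grid.subset_size
    frames = sequence.frames.astype(np.float64, copy=False)
    T = sequence.n_frames
    N = grid.n_points
    pts = grid.points

    U = np.zeros((T, N))
    V = np.zeros((T, N))
    dU = np.zeros((T, N))
    dV = np.zeros((T, N))
    quality = np.zeros((T, N))
    quality[0] = 1.0
    valid = np.ones((T, N), dtype=bool)
    filled = np.zeros((T, N), dtype=bool)

    tree = cKDTree(pts)
    fill_nb = tree.query_ball_point(pts, r=1.5 * grid.step)
    init_nb = tree.query_ball_point(pts, r=2.0 * grid.step + 1e-9)

    alive = np.ones(N, dtype=bool)
    prev_inc = np.zeros((N, 2))
    has_history = np.zeros(N, dtype=bool)
    coef_prev = _spline(frames[0])

    for t in range(1, T):
        coef_cur = _spline(frames[t])
        solved = np.zeros(N, dtype=bool)
        h, w = frames[t].shape
        guard = ss // 2 + 1  # subset must keep >= 1 px of slack inside the frame
        for i in range(N):
            if not alive[i]:
                continue
            cx = pts[i, 0] + U[t - 1, i]
            cy = pts[i, 1] + V[t - 1, i]
            if not (guard <= cx <= w - 1 - guard and guard <= cy <= h - 1 - guard):
                alive[i] = False  # material point is leaving the field of view
                valid[t:, i] = False
                continue
            if has_history[i]:
                init = prev_inc[i]
            else:
                nb = [j for j in init_nb[i] if solved[j]]
                init = np.median(prev_inc[nb], axis=0) if nb else np.zeros(2)
            res = match_subset(
                point=(cx, cy),
                init_guess=tuple(init),
                subset_size=ss,
                search_radius=cfg.search_radius,
                max_iterations=cfg.max_iterations,
                convergence_tol=cfg.convergence_tol,
                ref_coef=coef_prev,
                cur_coef=coef_cur,
            )
            ok = res.valid and res.quality >= cfg.quality_threshold and not res.on_border
            quality[t, i] = res.quality
            if ok:
                dU[t, i] = res.du
                dV[t, i] = res.dv
                U[t, i] = U[t - 1, i] + res.du
                V[t, i] = V[t - 1, i] + res.dv
                prev_inc[i] = (res.du, res.dv)
                has_history[i] = True
                solved[i] = True
            else:
                alive[i] = False
                valid[t:, i] = False

        dead = np.nonzero(~alive)[0]
        for i in dead:
            nb = [j for j in fill_nb[i] if alive[j] and j != i]
            if nb:
                U[t, i] = np.median(U[t, nb])
                V[t, i] = np.median(V[t, nb])
            else:
                U[t, i] = U[t - 1, i]
                V[t, i] = V[t - 1, i]
            filled[t, i] = True

        if dead.size > 0.5 * N:
            raise TrackingError(
                f"{dead.size}/{N} points invalid at frame {t}", frame=t
            )
        coef_prev = coef_cur

    return DisplacementField(
        U=U,
        V=V,
        dU=dU,
        dV=dV,
        quality=quality,
        valid=valid,
        filled=filled,
        grid=grid,
        frame_interval=sequence.frame_interval,
        exam_id=sequence.exam_id,
    )
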