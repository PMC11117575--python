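"""Synthetic air-puff corneal image sequences with analytic ground truth.

Clinical air-puff exams film a bright, curved corneal cross-section on a dark
background while a short air pulse pushes the cornea inward and the tissue
viscoelastically recovers.  This module emulates that acquisition with a
phenomenological (not physical) deformation model so that every downstream
stage — tracking, strain, features, classification — can be tested against
closed-form fields:

    V(x, y, t) = -P(t) * S(x) + drift_y * t
    U(x, y, t) =  drift_x * t + c * dV/dx

with a rise-fall pulse ``P(t) = (t/t_peak)^p`` for ``t <= t_peak`` and
``exp(-(t - t_peak)/lag)`` afterwards, and a spatial envelope ``S(x)`` that is
a Gaussian bump of width ``spatial_sigma`` centred on the corneal apex, plus
an optional second, narrower bump modelling a focal weakening.  The recovery
lag encodes the viscoelastic asymmetry of the response; disease-like exams get
a larger lag, a slightly larger amplitude and a focal weakening.  V is
positive toward the image bottom (the direction of the puff).

Frames are rendered by inverse-mapping every pixel through the analytic field
(fixed-point inversion of the forward map, then bicubic sampling), so a DIC
engine tracking a frame-0 grid point should recover exactly the analytic
displacement at that point.  Sensor noise is i.i.d. Gaussian per frame,
clipped to the 8-bit gray range.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from .dic import ImageSequence
from .features import CURVE_NAMES, EvolutionCurves, extract_evolution_curves

__all__ = [
    "LocalWeakening",
    "SimulationConfig",
    "GroundTruth",
    "ClassPriors",
    "CohortPriors",
    "CohortExam",
    "SizingError",
    "analytic_displacement",
    "render_reference",
    "render_sequence",
    "band_grid",
    "default_priors",
    "demo_config",
    "demo_priors",
    "generate_cohort",
]

GRAY_MAX = 255.0


class SizingError(ValueError):
    """The configured band or deformation does not fit inside the image."""


@dataclasses.dataclass(frozen=True)
class LocalWeakening:
    """Focal extra compliance: a second, narrower deformation bump."""

    center_x: float
    extra_amplitude: float  # px, added to the apex bump
    sigma: float  # px


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines one synthetic exam (seed included)."""

    image_height: int = 200
    image_width: int = 576
    n_frames: int = 140
    frame_interval: float = 30.0 / 139.0  # ms; 140 frames span ~30 ms
    band_apex_row: float = 60.0  # row of the corneal arc at the apex
    band_curvature: float = 3.0e-4  # px^-1; rows increase downward
    band_thickness: float = 48.0  # px
    speckle_density: float = 0.45  # fraction of band area covered by speckles
    speckle_radius: float = 2.0  # px (mean)
    noise_sd: float = 2.0  # gray levels
    class_label: str = "normal"
    amplitude_peak: float = 7.0  # px, vertical deformation at the apex
    peak_frame: int = 65
    spatial_sigma: float = 60.0  # px, width of the deformation bump
    rise_power: float = 2.0
    recovery_lag: float = 12.0  # frames; viscoelastic recovery time constant
    lateral_coupling: float = 2.0  # px; U gains c * dV/dx
    local_weakening: LocalWeakening | None = None
    rigid_drift: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px/frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.amplitude_peak < 0:
            raise ValueError("amplitude_peak must be >= 0")
        if not 0 < self.peak_frame < self.n_frames:
            raise ValueError("peak_frame must lie strictly inside the sequence")
        if self.recovery_lag <= 0 or self.rise_power < 1:
            raise ValueError("recovery_lag must be > 0 and rise_power >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not 0 <= self.speckle_density <= 1:
            raise ValueError("speckle_density must be in [0, 1]")
        top = self.band_apex_row - self.band_thickness / 2
        bottom = self.band_center(0.0) + self.band_thickness / 2
        if top < 1 or bottom > self.image_height - 2:
            raise SizingError("corneal band does not fit inside the image")

    @property
    def apex_x(self) -> float:
        return self.image_width / 2.0

    def band_center(self, x) -> np.ndarray:
        """Row of the band centreline at column x (quadratic corneal arc)."""
        return self.band_apex_row + self.band_curvature * (np.asarray(x, float) - self.apex_x) ** 2

    def max_deflection(self) -> float:
        """Largest possible vertical excursion of any band pixel (px)."""
        extra = self.local_weakening.extra_amplitude if self.local_weakening else 0.0
        return self.amplitude_peak + extra + abs(self.rigid_drift[1]) * (self.n_frames - 1)


# ----------------------------------------------------------------------------
# Analytic deformation model
# ----------------------------------------------------------------------------


def _pulse(t, config: SimulationConfig) -> np.ndarray:
    """Unit rise-fall pulse: (t/t_peak)^p up to the peak, exponential after."""
    t = np.asarray(t, dtype=float)
    tp, lag, p = config.peak_frame, config.recovery_lag, config.rise_power
    rising = np.where(t > 0, np.power(np.clip(t, 0, None) / tp, p), 0.0)
    falling = np.exp(-(t - tp) / lag)
    return np.where(t <= tp, rising, falling)


def _pulse_rate(t, config: SimulationConfig) -> np.ndarray:
    """dP/dt in 1/frame (right derivative at the kink)."""
    t = np.asarray(t, dtype=float)
    tp, lag, p = config.peak_frame, config.recovery_lag, config.rise_power
    rising = np.where(t > 0, (p / tp) * np.power(np.clip(t, 0, None) / tp, p - 1), 0.0)
    falling = -np.exp(-(t - tp) / lag) / lag
    return np.where(t < tp, rising, falling)


def _envelope(x, config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatial amplitude S(x) in px and its first two derivatives."""
    x = np.asarray(x, dtype=float)
    S = np.zeros_like(x)
    S1 = np.zeros_like(x)
    S2 = np.zeros_like(x)
    bumps = [(config.apex_x, config.spatial_sigma, config.amplitude_peak)]
    if config.local_weakening is not None:
        w = config.local_weakening
        bumps.append((w.center_x, w.sigma, w.extra_amplitude))
    for c, s, a in bumps:
        u = (x - c) / s
        g = a * np.exp(-0.5 * u**2)
        S += g
        S1 += -g * u / s
        S2 += g * (u**2 - 1.0) / s**2
    return S, S1, S2


def analytic_displacement(x, y, t, config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact (U, V) in px for material point (x, y) at frame t.

    Pure function of the configuration; zero at t = 0 and identically zero when
    the amplitude, weakening and drift all vanish.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    P = _pulse(t, config)
    S, S1, _ = _envelope(x, config)
    V = -P * S + config.rigid_drift[1] * t
    U = config.rigid_drift[0] * t - config.lateral_coupling * P * S1
    return U + np.zeros_like(np.asarray(y, float)), V + np.zeros_like(np.asarray(y, float))


@dataclasses.dataclass
class GroundTruth:
    """Closed-form displacement, strain and rate fields on a measurement grid.

    All quantities are evaluated from the analytic deformation model, so they
    are consistent with each other to machine precision; strains come from
    spatial derivatives, rates from temporal derivatives (px/ms and 1/ms).
    """

    config: SimulationConfig
    grid: np.ndarray  # (N, 2) frame-0 (x, y)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float).reshape(-1, 2)

    @property
    def n_points(self) -> int:
        return self.grid.shape[0]

    def displacement(self, t, points: np.ndarray | None = None):
        pts = self.grid if points is None else np.asarray(points, float).reshape(-1, 2)
        return analytic_displacement(pts[:, 0], pts[:, 1], t, self.config)

    def strains(self, t, points: np.ndarray | None = None):
        pts = self.grid if points is None else np.asarray(points, float).reshape(-1, 2)
        P = _pulse(t, self.config)
        _, S1, S2 = _envelope(pts[:, 0], self.config)
        exx = -self.config.lateral_coupling * P * S2
        eyy = np.zeros_like(exx)
        gxy = -P * S1  # dU/dy = 0, so engineering shear reduces to dV/dx
        return exx, eyy, gxy

    def rates(self, t, points: np.ndarray | None = None):
        pts = self.grid if points is None else np.asarray(points, float).reshape(-1, 2)
        dt = self.config.frame_interval
        Pr = _pulse_rate(t, self.config) / dt  # 1/ms
        S, S1, S2 = _envelope(pts[:, 0], self.config)
        UR = self.config.rigid_drift[0] / dt - self.config.lateral_coupling * Pr * S1
        VR = -Pr * S + self.config.rigid_drift[1] / dt
        exxR = -self.config.lateral_coupling * Pr * S2
        eyyR = np.zeros_like(exxR)
        gxyR = -Pr * S1
        return UR, VR, exxR, eyyR, gxyR

    def sample_fields(self, points: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """All per-frame, per-point arrays, keyed U,V,exx,eyy,gxy,UR,VR,exxR,eyyR,gxyR."""
        pts = self.grid if points is None else np.asarray(points, float).reshape(-1, 2)
        T = self.config.n_frames
        keys = ("U", "V", "exx", "eyy", "gxy", "UR", "VR", "exxR", "eyyR", "gxyR")
        out = {k: np.zeros((T, pts.shape[0])) for k in keys}
        for t in range(T):
            out["U"][t], out["V"][t] = self.displacement(t, pts)
            out["exx"][t], out["eyy"][t], out["gxy"][t] = self.strains(t, pts)
            (
                out["UR"][t],
                out["VR"][t],
                out["exxR"][t],
                out["eyyR"][t],
                out["gxyR"][t],
            ) = self.rates(t, pts)
        return out

    def curves(self, exam_id: str = "", points: np.ndarray | None = None) -> EvolutionCurves:
        f = self.sample_fields(points)
        return extract_evolution_curves(
            f["V"],
            f["gxy"],
            f["VR"],
            f["gxyR"],
            exam_id=exam_id,
            frame_interval=self.config.frame_interval,
        )

    def summary(self) -> dict:
        f = self.sample_fields()
        return {
            "max_abs_V": float(np.abs(f["V"]).max()),
            "max_abs_gxy": float(np.abs(f["gxy"]).max()),
            "n_points": self.n_points,
            "n_frames": self.config.n_frames,
        }


# ----------------------------------------------------------------------------
# Rendering
# ----------------------------------------------------------------------------


def band_grid(config: SimulationConfig, step: int = 8, margin: int = 20) -> np.ndarray:
    """Default measurement lattice inside the corneal band (row-major order)."""
    span = config.band_thickness / 2 - 4.0
    n_rows = max(1, int(2 * span / step) + 1)
    offsets = (np.arange(n_rows) - (n_rows - 1) / 2) * step
    pts = []
    for x in np.arange(margin, config.image_width - margin, step, dtype=float):
        yc = float(config.band_center(x))
        for off in offsets:
            pts.append((x, yc + off))
    return np.array(pts)


def render_reference(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Undeformed speckled band: hard dark disks on a smooth bright band profile,
    blurred by a 0.5 px Gaussian so bicubic interpolation sees smooth gradients."""
    h, w = config.image_height, config.image_width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    u = (yy - config.band_center(xx)) / (config.band_thickness / 2)
    img = 15.0 + 195.0 * np.exp(-(u**4))

    area = w * config.band_thickness
    n_spk = int(config.speckle_density * area / (np.pi * config.speckle_radius**2))
    cx = rng.uniform(0, w, n_spk)
    off = rng.uniform(-config.band_thickness / 2, config.band_thickness / 2, n_spk)
    rad = rng.uniform(0.6, 1.4, n_spk) * config.speckle_radius
    depth = rng.uniform(0.45, 0.85, n_spk)
    for k in range(n_spk):
        cyk = float(config.band_center(cx[k])) + off[k]
        x0 = max(0, int(np.floor(cx[k] - rad[k] - 1)))
        x1 = min(w, int(np.ceil(cx[k] + rad[k] + 2)))
        y0 = max(0, int(np.floor(cyk - rad[k] - 1)))
        y1 = min(h, int(np.ceil(cyk + rad[k] + 2)))
        if x0 >= x1 or y0 >= y1:
            continue
        py, px = np.mgrid[y0:y1, x0:x1]
        m = (px - cx[k]) ** 2 + (py - cyk) ** 2 <= rad[k] ** 2
        img[y0:y1, x0:x1][m] *= 1.0 - depth[k]

    img = ndi.gaussian_filter(img, 0.5)
    return np.clip(np.rint(img), 0, GRAY_MAX)


def _check_sizing(config: SimulationConfig) -> None:
    pad = 3.0
    d = config.max_deflection()
    top = config.band_apex_row - config.band_thickness / 2
    bottom = config.band_center(0.0) + config.band_thickness / 2
    if top - d < pad or bottom + d > config.image_height - 1 - pad:
        raise SizingError(
            "deformation would push the corneal band outside the image; "
            "reduce amplitude/drift or enlarge the image"
        )


def render_sequence(
    config: SimulationConfig,
    grid: np.ndarray | None = None,
    grid_step: int = 8,
) -> tuple[ImageSequence, GroundTruth]:
    """Render one exam and its ground truth.

    Frame 0 is the undeformed speckled band quantised to 8 bits; frame t is
    produced by inverting the forward map x = X + d(X, t) per pixel (fixed
    point iteration, which converges because the field's gradients are well
    below 1) and sampling frame 0 with bicubic interpolation.  Per-frame
    i.i.d. Gaussian sensor noise (sd ``noise_sd``) is added to every frame and
    clipped to [0, 255].  Identical config+seed gives bit-identical output.
    """
    _check_sizing(config)
    rng = np.random.default_rng(config.seed)
    base = render_reference(config, rng)
    h, w = base.shape
    T = config.n_frames
    frames = np.empty((T, h, w), dtype=np.uint8)

    def finalize(img: np.ndarray) -> np.ndarray:
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
        return np.clip(np.rint(img), 0, GRAY_MAX).astype(np.uint8)

    frames[0] = finalize(base)
    coef = ndi.spline_filter(base, order=3, mode="mirror")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for t in range(1, T):
        X, Y = xx, yy
        for _ in range(12):
            Ud, Vd = analytic_displacement(X, Y, float(t), config)
            X = xx - Ud
            Y = yy - Vd
        img = ndi.map_coordinates(coef, [Y, X], order=3, prefilter=False, mode="mirror")
        frames[t] = finalize(img)

    truth = GroundTruth(config, band_grid(config, grid_step) if grid is None else grid)
    seq = ImageSequence(
        frames,
        frame_interval=config.frame_interval,
        exam_id=f"sim-{config.class_label}-seed{config.seed}",
    )
    return seq, truth


# ----------------------------------------------------------------------------
# Cohorts
# ----------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ClassPriors:
    """Class-conditional (mean, sd) draws for the deformation parameters."""

    amplitude_peak: tuple[float, float] = (7.0, 1.5)
    peak_frame: tuple[float, float] = (65.0, 5.0)
    recovery_lag: tuple[float, float] = (11.0, 3.5)
    weakening_prob: float = 0.0
    weakening_amp: tuple[float, float] = (1.2, 0.4)
    weakening_sigma: tuple[float, float] = (25.0, 5.0)
    weakening_offset_sd: float = 40.0


@dataclasses.dataclass(frozen=True)
class CohortPriors:
    """Study-condition fixture: normal vs disease-like parameter distributions.

    The disease-like class has a modestly larger amplitude, a roughly doubled
    viscoelastic recovery lag, and a focal weakening bump; within-class spread
    creates overlap.  Two nuisance terms emulate features of real exams in
    fast (curves) mode: ``curve_noise_frac`` adds per-frame Gaussian noise
    scaled to each curve's own maximum (DIC measurement noise), and
    ``scale_jitter_sd`` applies one log-normal gain per exam to all of its
    curves (between-exam variation of puff pressure and intraocular pressure,
    a class-independent common factor across features).
    """

    normal: ClassPriors
    ffkc: ClassPriors
    curve_noise_frac: float = 0.05
    scale_jitter_sd: float = 0.0


def default_priors() -> CohortPriors:
    """The frozen study-condition fixture.

    The disease-like class draws a ~15% larger deformation amplitude, a
    roughly doubled viscoelastic recovery lag and a focal weakening bump;
    within-class spreads are wide enough that cohorts contain borderline
    exams, and 15% curve noise emulates the measurement noise of the tracking
    stage.  These distributions are a documented fixture, not a claim about
    physiology.
    """
    return CohortPriors(
        normal=ClassPriors(),
        ffkc=ClassPriors(
            amplitude_peak=(8.0, 1.5),
            peak_frame=(68.0, 5.0),
            recovery_lag=(22.0, 7.0),
            weakening_prob=1.0,
            weakening_amp=(1.2, 0.5),
        ),
        curve_noise_frac=0.15,
    )


@dataclasses.dataclass
class CohortExam:
    exam_id: str
    label: int  # 0 = normal, 1 = FFKC-like
    class_name: str
    config: SimulationConfig
    curves: EvolutionCurves | None = None
    sequence: ImageSequence | None = None
    truth: GroundTruth | None = None


def _sample_config(
    priors: ClassPriors,
    class_name: str,
    seed: int,
    rng: np.random.Generator,
    base: SimulationConfig,
) -> SimulationConfig:
    amp = max(0.5, rng.normal(*priors.amplitude_peak))
    peak = int(np.clip(round(rng.normal(*priors.peak_frame)), 2, base.n_frames - 3))
    lag = max(2.0, rng.normal(*priors.recovery_lag))
    weakening = None
    if rng.random() < priors.weakening_prob:
        weakening = LocalWeakening(
            center_x=base.apex_x + rng.normal(0.0, priors.weakening_offset_sd),
            extra_amplitude=max(0.0, rng.normal(*priors.weakening_amp)),
            sigma=max(8.0, rng.normal(*priors.weakening_sigma)),
        )
    return dataclasses.replace(
        base,
        class_label=class_name,
        amplitude_peak=amp,
        peak_frame=peak,
        recovery_lag=lag,
        local_weakening=weakening,
        seed=seed,
    )


def generate_cohort(
    n_normal: int,
    n_ffkc: int,
    priors: CohortPriors | None = None,
    seed: int = 0,
    mode: str = "curves",
    base_config: SimulationConfig | None = None,
    grid_step: int = 8,
) -> list[CohortExam]:
    """Reproducible labelled cohort of synthetic exams.

    ``mode='curves'`` (fast) evaluates the ground-truth fields on the band
    grid and emits evolution curves directly, skipping image rendering;
    ``mode='images'`` renders full sequences (slow) with ground truth attached.
    """
    if n_normal <= 0 or n_ffkc <= 0:
        raise ValueError("cohort counts must be positive")
    if mode not in ("curves", "images"):
        raise ValueError("mode must be 'curves' or 'images'")
    priors = priors or default_priors()
    base = base_config or SimulationConfig()
    rng = np.random.default_rng(seed)

    exams: list[CohortExam] = []
    groups = (("normal", n_normal, priors.normal, 0), ("ffkc", n_ffkc, priors.ffkc, 1))
    for class_name, n, cp, label in groups:
        for j in range(n):
            child_seed = int(rng.integers(0, 2**31))
            cfg = _sample_config(cp, class_name, child_seed, rng, base)
            exam_id = f"{class_name}-{j:03d}"
            exam = CohortExam(exam_id=exam_id, label=label, class_name=class_name, config=cfg)
            if mode == "curves":
                truth = GroundTruth(cfg, band_grid(cfg, grid_step))
                curves = truth.curves(exam_id=exam_id)
                nrng = np.random.default_rng([child_seed, 1])
                gain = float(np.exp(nrng.normal(0.0, priors.scale_jitter_sd)))
                for name in CURVE_NAMES:
                    arr = curves.data[name] * gain
                    scale = priors.curve_noise_frac * np.abs(arr).max()
                    if scale > 0:
                        arr = arr + nrng.normal(0.0, scale, arr.size)
                    curves.data[name] = arr
                exam.curves = curves
                exam.truth = truth
            else:
                seq, truth = render_sequence(cfg, grid_step=grid_step)
                exam.sequence = seq
                exam.truth = truth
            exams.append(exam)
    return exams


# ----------------------------------------------------------------------------
# Small frozen demo conditions (used by the CLI demo and quick examples)
# ----------------------------------------------------------------------------


def demo_config() -> SimulationConfig:
    """Scaled-down geometry for quick end-to-end demonstrations."""
    return SimulationConfig(
        image_height=120,
        image_width=288,
        n_frames=16,
        frame_interval=2.0,
        band_apex_row=42.0,
        band_thickness=36.0,
        spatial_sigma=40.0,
        amplitude_peak=5.0,
        peak_frame=7,
        recovery_lag=3.0,
        noise_sd=1.5,
    )


def demo_priors() -> CohortPriors:
    return CohortPriors(
        normal=ClassPriors(
            amplitude_peak=(5.0, 0.8), peak_frame=(7.0, 1.0), recovery_lag=(3.0, 0.8)
        ),
        ffkc=ClassPriors(
            amplitude_peak=(6.0, 1.0),
            peak_frame=(8.0, 1.0),
            recovery_lag=(6.0, 1.2),
            weakening_prob=1.0,
            weakening_amp=(1.0, 0.3),
            weakening_sigma=(15.0, 3.0),
            weakening_offset_sd=25.0,
        ),
    )
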