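"""Synthetic MR / fluorescence scenes with known ground truth.

Everything the pipeline consumes can be generated here: cylindrical
calibration phantoms with sparse sensor dark spots, multi-session tumor
volumes with drifting and growing sensor constellations under prescribed
stress trajectories, paired MR/fluorescence point clouds related by a known
rigid-plus-smooth warp, and patchy fluorescence-positive label regions.

Rendering emulates the measurement chain rather than the MR physics: each
sensor is an isotropic Gaussian intensity dip whose amplitude is calibrated
so that the 3 x 3 x 2-voxel ROI statistic (see
:mod:`mechanomap.mrsignal`) reports an SBR following the biexponential
stress-signal law exactly on noiseless volumes, after which Rician (or
Gaussian) voxel noise is applied.  Default noise figures are chosen to
reproduce the reported single-particle signal quality of the real sensor
(contrast-to-noise ratio ~9.5 per 3 x 3 x 2 ROI).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .calibration import (
    DEFAULT_MODEL,
    DEFAULT_STRAIN_MODEL,
    CalibrationModel,
    ParticleStrainModel,
    strain_from_stress,
)
from .errors import CapacityError, ScheduleRangeError, ValidationError
from .mrsignal import MRVolume, sbr_roi_voxels
from .registration import LabelVolume, PointCloud

__all__ = [
    "NoiseSpec",
    "WarpSpec",
    "Warp",
    "LoadingProfile",
    "SceneParticle",
    "Scene",
    "RegistrationScene",
    "TwoRegionScene",
    "generate_calibration_phantom",
    "generate_tumor_timeseries",
    "generate_registration_scene",
    "generate_two_region_scene",
    "generate_cfm_observations",
    "render_session",
]

HOURS_PER_DAY = 24.0
#: minimum pairwise sensor separation: 3 x the nominal 0.3 mm spot width
MIN_SEPARATION_MM = 0.9


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Voxel noise and spot-contrast model for rendered MR volumes.

    ``spot_depth`` is the nominal ROI contrast (background minus sensor ROI
    mean, intensity units) of an unstressed sensor; with ``sigma`` it fixes
    the single-particle contrast-to-noise ratio, 9.5 by default.
    ``psf_sigma`` is the Gaussian spot scale in mm (0.127 mm ~= 300 um
    full width at half maximum, the resolved particle size).
    """

    model: str = "rician"
    sigma: float = 1.0
    background_mean: float = 100.0
    spot_depth: float = 9.5
    psf_sigma: float = 0.1274

    def __post_init__(self) -> None:
        if self.model not in ("rician", "gaussian"):
            raise ValidationError(f"noise model must be rician|gaussian, got {self.model!r}")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if not (0 < self.spot_depth < self.background_mean):
            raise ValidationError("need 0 < spot_depth < background_mean")
        if self.psf_sigma <= 0:
            raise ValidationError("psf_sigma must be positive")

    @property
    def sbr0(self) -> float:
        """Design zero-stress SBR implied by spot_depth and background."""
        return self.spot_depth / (self.background_mean - self.spot_depth)


@dataclass(frozen=True)
class WarpSpec:
    """Parameters of the MR -> fluorescence frame deformation.

    Rotation angles in degrees (about x, y, z); the non-rigid part is a
    mixture of Gaussian-kernel displacements of RMS amplitude
    ``nonrigid_amplitude`` (mm) and kernel width ``nonrigid_length_scale``
    (mm).  Small amplitude relative to the length scale keeps the field
    smooth and invertible.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0
    nonrigid_amplitude: float = 0.0
    nonrigid_length_scale: float = 5.0
    n_kernels: int = 8

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("scale must be positive")
        if self.nonrigid_amplitude < 0 or self.nonrigid_length_scale <= 0:
            raise ValidationError("invalid nonrigid warp parameters")

    def realize(self, rng: np.random.Generator, center, radius: float) -> "Warp":
        """Draw the non-rigid kernel mixture and freeze the full transform."""
        angles = np.deg2rad(self.rotation)
        cx, cy, cz = np.cos(angles)
        sx, sy, sz = np.sin(angles)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        R = Rz @ Ry @ Rx
        K = self.n_kernels
        centers = np.asarray(center) + rng.uniform(-radius, radius, size=(K, 3))
        if self.nonrigid_amplitude > 0:
            vecs = rng.normal(size=(K, 3))
            vecs *= self.nonrigid_amplitude / np.sqrt(K)
        else:
            vecs = np.zeros((K, 3))
        return Warp(
            rotation=R,
            translation=np.asarray(self.translation, dtype=float),
            scale=self.scale,
            center=np.asarray(center, dtype=float),
            kernel_centers=centers,
            kernel_vectors=vecs,
            length_scale=self.nonrigid_length_scale,
        )


@dataclass(frozen=True)
class Warp:
    """A realized warp: similarity about ``center`` plus a smooth field."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float
    center: np.ndarray
    kernel_centers: np.ndarray
    kernel_vectors: np.ndarray
    length_scale: float

    def apply(self, points_xyz) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        out = self.scale * (p - self.center) @ self.rotation.T + self.center
        out = out + self.translation
        if np.any(self.kernel_vectors):
            d2 = np.sum((p[:, None, :] - self.kernel_centers[None]) ** 2, axis=2)
            out = out + np.exp(-d2 / (2 * self.length_scale**2)) @ self.kernel_vectors
        return out if np.asarray(points_xyz).ndim > 1 else out[0]


@dataclass(frozen=True)
class LoadingProfile:
    """A prescribed stress schedule (times in hours, stress in kPa).

    Stress between schedule points is linearly interpolated; evaluation
    outside the schedule raises :class:`ScheduleRangeError`.
    """

    kind: str
    schedule: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.kind not in ("gradual", "acute", "constant", "custom"):
            raise ValidationError(f"unknown profile kind {self.kind!r}")
        times = [t for t, _ in self.schedule]
        if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("schedule times must be strictly increasing")

    @classmethod
    def gradual(cls, peak_kPa: float = 5.0, step_hours: float = 6.0,
                duration_hours: float = 48.0) -> "LoadingProfile":
        """Stepwise escalation every ``step_hours`` to the peak at the end."""
        n = int(round(duration_hours / step_hours))
        sched = tuple((i * step_hours, peak_kPa * i / n) for i in range(n + 1))
        return cls(kind="gradual", schedule=sched)

    @classmethod
    def acute(cls, baseline_kPa: float = 0.5, peak_kPa: float = 5.0,
              hold_hours: float = 48.0, ramp_hours: float = 1.0) -> "LoadingProfile":
        """Low baseline for ``hold_hours``, then a rapid ramp to the peak."""
        return cls(kind="acute", schedule=(
            (0.0, baseline_kPa), (hold_hours, baseline_kPa),
            (hold_hours + ramp_hours, peak_kPa),
        ))

    @classmethod
    def constant(cls, level_kPa: float, duration_hours: float = 48.0) -> "LoadingProfile":
        return cls(kind="constant", schedule=((0.0, level_kPa), (duration_hours, level_kPa)))

    def stress_at(self, t_hours):
        t = np.asarray(t_hours, dtype=float)
        times = np.array([p[0] for p in self.schedule])
        vals = np.array([p[1] for p in self.schedule])
        if np.any(t < times[0]) or np.any(t > times[-1]):
            raise ScheduleRangeError(
                f"time outside schedule range [{times[0]}, {times[-1]}] h"
            )
        out = np.interp(t, times, vals)
        return out if out.ndim else float(out)

    def max_interval_rate(self) -> float:
        """Largest stress slope between consecutive schedule points, kPa/day."""
        times = np.array([p[0] for p in self.schedule]) / HOURS_PER_DAY
        vals = np.array([p[1] for p in self.schedule])
        return float(np.max(np.diff(vals) / np.diff(times)))


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class SceneParticle:
    id: int
    positions: np.ndarray          # (n_sessions, 3) mm, (x, y, z)
    true_stress: np.ndarray        # (n_sessions,) kPa
    is_aggregate_cluster: bool = False


@dataclass
class Scene:
    """Ground truth for one synthetic experiment."""

    particles: list[SceneParticle]
    session_times: np.ndarray      # days
    noise: NoiseSpec
    seed: int
    volume_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    model: CalibrationModel = DEFAULT_MODEL
    region_labels: LabelVolume | None = None
    warp: Warp | None = None
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        n_s = len(self.session_times)
        for p in self.particles:
            if p.positions.shape != (n_s, 3) or p.true_stress.shape != (n_s,):
                raise ValidationError("particle arrays inconsistent with session count")
            lo, hi = self.model.stress_range
            if np.any(p.true_stress < lo) or np.any(p.true_stress > hi):
                raise ValidationError(
                    f"true stress outside calibration range [{lo}, {hi}] kPa"
                )

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def positions_at(self, session: int) -> np.ndarray:
        return np.array([p.positions[session] for p in self.particles])

    def stresses_at(self, session: int) -> np.ndarray:
        return np.array([p.true_stress[session] for p in self.particles])

    @property
    def aggregate_flags(self) -> np.ndarray:
        return np.array([p.is_aggregate_cluster for p in self.particles])


@dataclass
class RegistrationScene:
    source: PointCloud
    target: PointCloud
    labels: LabelVolume
    truth: Warp
    sensor_source: np.ndarray      # sensor positions, MR frame (mm)
    sensor_target: np.ndarray      # same sensors, fluorescence frame (mm)
    sensor_labels: np.ndarray      # 0 / 1 per sensor


@dataclass
class TwoRegionScene:
    """End-to-end two-region tumor scenario (MR volume + paired clouds)."""

    mr_volume: MRVolume
    scene: Scene
    registration: RegistrationScene
    sensor_stress: np.ndarray


# ---------------------------------------------------------------------------
# placement and rendering
# ---------------------------------------------------------------------------

def _margins_mm(noise: NoiseSpec, voxel_size) -> np.ndarray:
    """(z, y, x) placement margin: SBR windows plus the rendered spot tail."""
    dz, dy, dx = voxel_size
    spot = 4.0 * noise.psf_sigma
    inplane = 7  # background window center offset (5) + halfwidth (1) + 1
    return np.array([2 * dz + spot, inplane * dy + spot, inplane * dx + spot])


def _place_points(
    rng: np.random.Generator,
    n: int,
    volume_shape,
    voxel_size,
    noise: NoiseSpec,
    min_separation: float,
    max_tries: int = 20000,
    shrink: float = 1.0,
) -> np.ndarray:
    """Uniform positions (mm, (x, y, z)) with margins and min separation."""
    extent = np.array(volume_shape) * np.array(voxel_size)      # (z, y, x)
    margin = _margins_mm(noise, voxel_size)
    lo = margin.copy()
    hi = extent - margin
    if shrink != 1.0:
        mid = 0.5 * (lo + hi)
        lo = mid + (lo - mid) * shrink
        hi = mid + (hi - mid) * shrink
    if np.any(hi <= lo):
        raise CapacityError(
            f"volume extent {extent} mm leaves no room inside margins {margin} mm"
        )
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise CapacityError(
                f"placed only {len(placed)}/{n} particles at separation "
                f">= {min_separation} mm in a {extent} mm volume"
            )
        tries += 1
        cand = rng.uniform(lo, hi)                               # (z, y, x)
        if all(np.linalg.norm(cand - p) >= min_separation for p in placed):
            placed.append(cand)
    zyx = np.array(placed)
    return zyx[:, ::-1].copy()                                   # -> (x, y, z)


def _spot_lobes(position_xyz, is_aggregate, rng) -> np.ndarray:
    """Sub-spot lobe centers; aggregates are three merged lobes in-plane."""
    if not is_aggregate:
        return np.atleast_2d(position_xyz)
    side = 0.25  # mm, below the resolved spot size -> one merged dark blob
    theta = rng.uniform(0, 2 * np.pi)
    angles = theta + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    r = side / np.sqrt(3.0)
    offsets = np.column_stack(
        [r * np.cos(angles), r * np.sin(angles), np.zeros(3)]
    )
    return np.asarray(position_xyz) + offsets


def render_session(
    scene: Scene,
    session: int,
    seed: int | None,
    *,
    noiseless: bool = False,
    depth_model: str = "sbr_exact",
) -> MRVolume:
    """Render one session of a scene into an MR volume.

    ``depth_model="sbr_exact"`` (default) calibrates each spot's amplitude
    so the measured noiseless SBR equals ``sbr0 * f(S)/f(0)`` under the
    stress-signal law f; ``"linear"`` scales the spot depth itself by
    ``f(S)/f(0)``.  ``seed`` controls the voxel noise only, so a fixed scene
    can be re-rendered under independent noise realizations.
    """
    if depth_model not in ("sbr_exact", "linear"):
        raise ValidationError(f"unknown depth_model {depth_model!r}")
    noise = scene.noise
    shape = scene.volume_shape
    dz, dy, dx = scene.voxel_size
    vol = np.full(shape, noise.background_mean, dtype=float)
    rng = np.random.default_rng(seed)
    f0 = scene.model.signal_at_zero
    sig = noise.psf_sigma

    for p in scene.particles:
        pos = p.positions[session]
        S = p.true_stress[session]
        ratio = (
            scene.model.a1 * np.exp(-scene.model.b1 * S)
            + scene.model.a2 * np.exp(-scene.model.b2 * S)
        ) / f0
        centroid = np.array([pos[2] / dz, pos[1] / dy, pos[0] / dx])
        if depth_model == "sbr_exact":
            t = noise.sbr0 * ratio
            roi_idx, _ = sbr_roi_voxels(shape, centroid)
            roi_mm = np.column_stack(
                [roi_idx[:, 2] * dx, roi_idx[:, 1] * dy, roi_idx[:, 0] * dz]
            )
            d2 = np.sum((roi_mm - pos) ** 2, axis=1)
            g = float(np.mean(np.exp(-d2 / (2 * sig * sig))))
            amplitude = noise.background_mean * t / (1.0 + t) / g
        else:
            amplitude = noise.spot_depth / 0.47 * ratio  # nominal peak depth

        for lobe in _spot_lobes(pos, p.is_aggregate_cluster, rng):
            cz, cy, cx = lobe[2] / dz, lobe[1] / dy, lobe[0] / dx
            hz, hy, hx = (int(np.ceil(4 * sig / d)) for d in (dz, dy, dx))
            z0, z1 = max(int(cz) - hz, 0), min(int(cz) + hz + 2, shape[0])
            y0, y1 = max(int(cy) - hy, 0), min(int(cy) + hy + 2, shape[1])
            x0, x1 = max(int(cx) - hx, 0), min(int(cx) + hx + 2, shape[2])
            zz = (np.arange(z0, z1) * dz - lobe[2])[:, None, None]
            yy = (np.arange(y0, y1) * dy - lobe[1])[None, :, None]
            xx = (np.arange(x0, x1) * dx - lobe[0])[None, None, :]
            vol[z0:z1, y0:y1, x0:x1] -= amplitude * np.exp(
                -(zz**2 + yy**2 + xx**2) / (2 * sig * sig)
            )

    if not noiseless:
        if noise.model == "gaussian":
            vol = vol + rng.normal(0.0, noise.sigma, size=vol.shape)
        else:
            n1 = rng.normal(0.0, noise.sigma, size=vol.shape)
            n2 = rng.normal(0.0, noise.sigma, size=vol.shape)
            vol = np.sqrt((vol + n1) ** 2 + n2**2)
    vol = np.clip(vol, 0.0, None)
    time = float(scene.session_times[session]) if len(scene.session_times) else None
    return MRVolume(intensities=vol, voxel_size=scene.voxel_size, session_time=time)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_calibration_phantom(
    n_particles: int,
    stresses,
    *,
    noise: NoiseSpec = NoiseSpec(),
    volume_shape: tuple[int, int, int] = (60, 90, 90),
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1),
    seed: int = 0,
    model: CalibrationModel = DEFAULT_MODEL,
    noiseless: bool = False,
) -> tuple[MRVolume, Scene]:
    """A single-session agarose phantom with sensors at known stresses.

    ``stresses`` is one value per particle or a single value broadcast to
    all.  Particles are placed uniformly with pairwise separation of at
    least three spot widths; the Scene records exact continuous positions.
    """
    stresses = np.atleast_1d(np.asarray(stresses, dtype=float))
    if stresses.size == 1:
        stresses = np.full(n_particles, stresses[0])
    if stresses.size != n_particles:
        raise ValidationError(
            f"stresses length {stresses.size} incompatible with n_particles={n_particles}"
        )
    seeds = np.random.SeedSequence(seed).generate_state(2)
    rng = np.random.default_rng(seeds[0])
    positions = (
        _place_points(rng, n_particles, volume_shape, voxel_size, noise,
                      MIN_SEPARATION_MM)
        if n_particles
        else np.empty((0, 3))
    )
    particles = [
        SceneParticle(
            id=i,
            positions=positions[i][None, :],
            true_stress=np.array([stresses[i]]),
        )
        for i in range(n_particles)
    ]
    scene = Scene(
        particles=particles,
        session_times=np.array([0.0]),
        noise=noise,
        seed=seed,
        volume_shape=tuple(volume_shape),
        voxel_size=tuple(voxel_size),
        model=model,
        noise_seed=int(seeds[1]),
    )
    volume = render_session(scene, 0, int(seeds[1]), noiseless=noiseless)
    return volume, scene


def generate_tumor_timeseries(
    n_particles: int,
    session_days,
    trajectories,
    *,
    growth_rate: float = 0.0,
    motion_sigma: float = 0.0,
    aggregate_fraction: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
    volume_shape: tuple[int, int, int] = (60, 110, 110),
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1),
    seed: int = 0,
    model: CalibrationModel = DEFAULT_MODEL,
    noiseless: bool = False,
) -> tuple[list[MRVolume], Scene]:
    """Longitudinal tumor volumes with growing, drifting constellations.

    ``trajectories`` is a :class:`LoadingProfile` shared by all particles
    (evaluated at each session day, in hours) or an (n_particles,
    n_sessions) array of per-particle stresses.  ``growth_rate`` scales the
    constellation about its centroid by (1 + rate) per day;
    ``aggregate_fraction`` of particles are rendered as merged clusters.
    """
    sessions = np.asarray(session_days, dtype=float)
    if sessions.ndim != 1 or len(sessions) < 1 or np.any(np.diff(sessions) <= 0):
        raise ValidationError("session_days must be strictly increasing")
    n_s = len(sessions)

    if isinstance(trajectories, LoadingProfile):
        stress = np.tile(
            trajectories.stress_at(sessions * HOURS_PER_DAY), (n_particles, 1)
        )
    else:
        stress = np.asarray(trajectories, dtype=float)
        if stress.shape != (n_particles, n_s):
            raise ValidationError(
                f"per-particle stress array must be {(n_particles, n_s)}, "
                f"got {stress.shape}"
            )
    if not (0 <= aggregate_fraction <= 1):
        raise ValidationError("aggregate_fraction must lie in [0, 1]")

    seeds = np.random.SeedSequence(seed).generate_state(3)
    rng = np.random.default_rng(seeds[0])
    scales = (1.0 + growth_rate) ** (sessions - sessions[0])
    base = _place_points(
        rng, n_particles, volume_shape, voxel_size, noise, MIN_SEPARATION_MM,
        shrink=1.0 / float(scales.max()),
    )
    centroid = base.mean(axis=0) if n_particles else np.zeros(3)
    n_agg = int(round(aggregate_fraction * n_particles))
    agg_ids = set(rng.choice(n_particles, size=n_agg, replace=False)) if n_agg else set()

    particles = []
    for i in range(n_particles):
        pos = centroid + (base[i] - centroid) * scales[:, None]
        if motion_sigma > 0:
            jitter = rng.normal(0.0, motion_sigma, size=(n_s, 3))
            jitter[0] = 0.0
            pos = pos + jitter
        particles.append(
            SceneParticle(
                id=i,
                positions=pos,
                true_stress=stress[i],
                is_aggregate_cluster=i in agg_ids,
            )
        )
    scene = Scene(
        particles=particles,
        session_times=sessions,
        noise=noise,
        seed=seed,
        volume_shape=tuple(volume_shape),
        voxel_size=tuple(voxel_size),
        model=model,
        noise_seed=int(seeds[1]),
    )
    session_seeds = np.random.SeedSequence(seeds[1]).generate_state(n_s)
    volumes = [
        render_session(scene, s, int(session_seeds[s]), noiseless=noiseless)
        for s in range(n_s)
    ]
    return volumes, scene


def _ellipsoid_surface(rng, n, center, radii) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center) + v * np.asarray(radii)


def _ellipsoid_interior(rng, n, center, radii, min_separation, max_tries=100000):
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise CapacityError(f"placed only {len(pts)}/{n} sensors in ellipsoid")
        tries += 1
        u = rng.uniform(-1, 1, size=3)
        if np.sum(u * u) > 1:
            continue
        cand = np.asarray(center) + u * np.asarray(radii) * 0.92
        if all(np.linalg.norm(cand - p) >= min_separation for p in pts):
            pts.append(cand)
    return np.array(pts)


def _patchy_labels(
    rng,
    warp: Warp,
    center,
    radii,
    vimentin_fraction: float,
    voxel_mm: float = 0.15,
    patch_scale_mm: float = 1.5,
) -> LabelVolume:
    """Thresholded smoothed random field over the warped tumor ellipsoid."""
    corners = _ellipsoid_surface(np.random.default_rng(0), 200, center, radii)
    warped = warp.apply(corners)
    lo = warped.min(axis=0) - 1.0
    hi = warped.max(axis=0) + 1.0
    nx, ny, nz = (int(np.ceil((h - l) / voxel_mm)) + 1 for l, h in zip(lo, hi))
    field_ = rng.normal(size=(nz, ny, nx))
    field_ = ndimage.gaussian_filter(field_, sigma=patch_scale_mm / voxel_mm)

    # tumor mask in the fluorescence frame: pull grid points back through the
    # warp would need the inverse; instead use the warped surface's convex
    # support approximated by the forward-warped ellipsoid equation on a
    # dense sample of interior points.
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    grid_mm = np.column_stack(
        [lo[0] + xx.ravel() * voxel_mm, lo[1] + yy.ravel() * voxel_mm,
         lo[2] + zz.ravel() * voxel_mm]
    )
    # approximate inverse warp by the rigid part (nonrigid amplitude is small)
    Rinv = warp.rotation.T
    back = (grid_mm - warp.translation - warp.center) @ Rinv.T / warp.scale + warp.center
    u = (back - np.asarray(center)) / np.asarray(radii)
    mask = (np.sum(u * u, axis=1) <= 1.0).reshape(nz, ny, nx)

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    if vimentin_fraction > 0 and mask.any():
        thr = np.quantile(field_[mask], 1.0 - vimentin_fraction)
        labels[mask & (field_ >= thr)] = 1
    intensity = np.where(mask, field_ - field_.min(), 0.0)
    return LabelVolume(
        labels=labels,
        voxel_size=(voxel_mm, voxel_mm, voxel_mm),
        origin=(float(lo[0]), float(lo[1]), float(lo[2])),
        intensity=intensity,
    )


def generate_registration_scene(
    n_surface_points: int = 400,
    n_sensors: int = 40,
    *,
    warp: WarpSpec = WarpSpec(),
    vimentin_fraction: float = 0.5,
    jitter: float = 0.05,
    center=(6.8, 6.8, 4.8),
    radii=(4.2, 4.2, 2.9),
    seed: int = 0,
) -> RegistrationScene:
    """Paired MR/fluorescence point clouds with a known warp and labels.

    The source cloud samples the tumor surface in the MR frame; the target
    is the warped surface plus isotropic point ``jitter`` (mm).  Sensors are
    placed inside the tumor; their positions are carried in both frames and
    labeled by the patchy fluorescence field (fraction ``vimentin_fraction``
    of the tumor volume positive).
    """
    if not (0 <= vimentin_fraction < 1):
        raise ValidationError(
            f"vimentin_fraction must lie in [0, 1), got {vimentin_fraction}"
        )
    seeds = np.random.SeedSequence(seed).generate_state(4)
    rng_warp = np.random.default_rng(seeds[0])
    rng_cloud = np.random.default_rng(seeds[1])
    rng_field = np.random.default_rng(seeds[2])
    rng_sens = np.random.default_rng(seeds[3])

    truth = warp.realize(rng_warp, center, float(max(radii)))
    source_pts = _ellipsoid_surface(rng_cloud, n_surface_points, center, radii)
    target_pts = truth.apply(source_pts)
    if jitter > 0:
        target_pts = target_pts + rng_cloud.normal(0.0, jitter, size=target_pts.shape)

    labels = _patchy_labels(rng_field, truth, center, radii, vimentin_fraction)
    sensor_src = _ellipsoid_interior(rng_sens, n_sensors, center, radii,
                                     MIN_SEPARATION_MM)
    sensor_tgt = truth.apply(sensor_src)
    vox = labels.mm_to_voxel(sensor_tgt)
    idx = np.clip(
        np.round(vox).astype(int), 0, np.array(labels.labels.shape) - 1
    )
    sensor_labels = labels.labels[idx[:, 0], idx[:, 1], idx[:, 2]].astype(int)

    return RegistrationScene(
        source=PointCloud(source_pts, frame_label="mr"),
        target=PointCloud(target_pts, frame_label="cfm"),
        labels=labels,
        truth=truth,
        sensor_source=sensor_src,
        sensor_target=sensor_tgt,
        sensor_labels=sensor_labels,
    )


DEFAULT_TUMOR_WARP = WarpSpec(
    rotation=(4.0, -3.0, 5.0),
    translation=(1.5, -1.0, 0.8),
    scale=1.03,
    nonrigid_amplitude=0.4,
    nonrigid_length_scale=4.0,
)


def generate_two_region_scene(
    n_per_region: int = 60,
    *,
    stress_positive: tuple[float, float] = (3.5, 2.8),
    stress_negative: tuple[float, float] = (7.4, 2.8),
    vimentin_fraction: float = 0.5,
    warp: WarpSpec = DEFAULT_TUMOR_WARP,
    noise: NoiseSpec = NoiseSpec(),
    n_surface_points: int = 400,
    volume_shape: tuple[int, int, int] = (48, 136, 136),
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1),
    seed: int = 0,
    model: CalibrationModel = DEFAULT_MODEL,
) -> TwoRegionScene:
    """Two-region tumor: region membership sets each sensor's true stress.

    Sensors falling in fluorescence-positive regions draw their stress from
    ``N(stress_positive)`` and the rest from ``N(stress_negative)``;
    sampling continues until each region holds ``n_per_region`` sensors.
    Each group's draws are moment-matched (standardized to the nominal mean
    and s.d.) before clamping to the calibration range, so the rendered
    scene realizes the stated region parameters rather than a finite-sample
    fluctuation of them — the scenario probes the pipeline's recovery
    error, not the generator's sampling noise.  Returns the rendered MR
    volume, the ground-truth scene, and the paired registration scene.
    """
    seeds = np.random.SeedSequence(seed).generate_state(3)
    center = (
        volume_shape[2] * voxel_size[2] / 2,
        volume_shape[1] * voxel_size[1] / 2,
        volume_shape[0] * voxel_size[0] / 2,
    )
    radii = (
        center[0] - _margins_mm(noise, voxel_size)[2] - 0.5,
        center[1] - _margins_mm(noise, voxel_size)[1] - 0.5,
        center[2] - _margins_mm(noise, voxel_size)[0] - 0.3,
    )
    reg = generate_registration_scene(
        n_surface_points=n_surface_points,
        n_sensors=1,  # sensors are drawn below with region quotas
        warp=warp,
        vimentin_fraction=vimentin_fraction,
        center=center,
        radii=radii,
        seed=int(seeds[0]),
    )
    rng = np.random.default_rng(seeds[1])
    lo, hi = model.stress_range
    shape_arr = np.array(reg.labels.labels.shape)

    placed: list[np.ndarray] = []
    labels_kept: list[int] = []
    counts = {0: 0, 1: 0}
    tries = 0
    while min(counts.values()) < n_per_region:
        if tries > 200000:
            raise CapacityError(
                f"could not place {n_per_region} sensors per region "
                f"(placed {counts})"
            )
        tries += 1
        u = rng.uniform(-1, 1, size=3)
        if np.sum(u * u) > 1:
            continue
        cand = np.asarray(center) + u * np.asarray(radii) * 0.92
        if any(np.linalg.norm(cand - p) < 1.0 for p in placed):
            continue
        tgt = reg.truth.apply(cand)
        vox = np.round(reg.labels.mm_to_voxel(tgt)).astype(int)[0]
        if np.any(vox < 0) or np.any(vox >= shape_arr):
            continue
        lab = int(reg.labels.labels[vox[0], vox[1], vox[2]])
        if counts[lab] >= n_per_region:
            continue
        placed.append(cand)
        labels_kept.append(lab)
        counts[lab] += 1

    positions = np.array(placed)
    sensor_labels = np.array(labels_kept)
    sensor_stress = np.empty(len(positions))
    for lab, (mu, sd) in ((1, stress_positive), (0, stress_negative)):
        idx = np.where(sensor_labels == lab)[0]
        z = rng.normal(size=idx.size)
        z = (z - z.mean()) / z.std()        # moment-matched group draws
        sensor_stress[idx] = np.clip(mu + sd * z, lo, hi)
    particles = [
        SceneParticle(
            id=i, positions=positions[i][None, :],
            true_stress=np.array([sensor_stress[i]]),
        )
        for i in range(len(positions))
    ]
    scene = Scene(
        particles=particles,
        session_times=np.array([0.0]),
        noise=noise,
        seed=seed,
        volume_shape=tuple(volume_shape),
        voxel_size=tuple(voxel_size),
        model=model,
        region_labels=reg.labels,
        warp=reg.truth,
        noise_seed=int(seeds[2]),
    )
    mr_volume = render_session(scene, 0, int(seeds[2]))
    reg = replace(
        reg,
        sensor_source=positions,
        sensor_target=reg.truth.apply(positions),
        sensor_labels=sensor_labels,
    )
    return TwoRegionScene(
        mr_volume=mr_volume, scene=scene, registration=reg,
        sensor_stress=sensor_stress,
    )


def generate_cfm_observations(
    scene: Scene,
    particle_material: ParticleStrainModel = DEFAULT_STRAIN_MODEL,
    *,
    optical_noise: float = 0.02,
    seed: int = 0,
):
    """Optical-arm observations: per-sensor axial strain with readout noise.

    Returns a list of ``(particle_id, session_index, axial_strain)`` where
    strain follows the saturating strain-stress law with multiplicative
    Gaussian noise of fractional s.d. ``optical_noise``.
    """
    if optical_noise < 0:
        raise ValidationError("optical_noise must be nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    for p in scene.particles:
        for s in range(len(scene.session_times)):
            strain = strain_from_stress(particle_material, float(p.true_stress[s]))
            if optical_noise > 0:
                strain *= 1.0 + rng.normal(0.0, optical_noise)
            out.append((p.id, s, float(strain)))
    return out
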