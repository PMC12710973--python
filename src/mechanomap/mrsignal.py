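"""Single-particle dark-spot quantification in T2*-weighted MR volumes.

Each hydrogel stress sensor appears as a localized dark spot.  Its
per-particle statistic is the inverse-intensity signal-to-background ratio

    SBR = (1/roi_mean - 1/background_mean) / (1/background_mean)
        = background_mean / roi_mean - 1,

where ``roi_mean`` is the mean over a 3 x 3 in-plane window on the two
axial slices bracketing the spot center, and ``background_mean`` averages
four 3 x 3 windows offset diagonally from the spot.  The reciprocal makes
the statistic proportional to the relaxation rate, which is what stress
modulates.  Clumped (aggregated) sensors are excluded by an SBR / dark-area
filter before quantitative analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .calibration import CalibrationModel, DEFAULT_MODEL
from .errors import BoundaryError, ValidationError

__all__ = [
    "MRVolume",
    "Detection",
    "SBRMeasurement",
    "sbr_roi_voxels",
    "compute_sbr",
    "dark_area",
    "detect_particles",
    "filter_aggregates",
    "normalize_signal",
]

#: default in-plane offset (pixels) of the four diagonal background windows
BACKGROUND_GAP_PX = 5
#: aggregation-exclusion defaults
SBR_MAX_DEFAULT = 2.5
AREA_MAX_PX_DEFAULT = 9


@dataclass
class MRVolume:
    """A 3D MR intensity volume with voxel geometry.

    ``intensities`` is indexed (z, y, x); ``voxel_size`` is the matching
    (dz, dy, dx) in mm (default 0.2 x 0.1 x 0.1 mm axial-first, i.e. the
    acquisition's 0.1 x 0.1 mm in-plane, 0.2 mm slices).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)
    session_time: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be a 3D array (z, y, x)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be nonnegative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"invalid voxel_size {self.voxel_size}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def voxel_to_mm(self, centroid_zyx) -> np.ndarray:
        """(z, y, x) voxel coordinates -> (x, y, z) position in mm."""
        c = np.atleast_2d(np.asarray(centroid_zyx, dtype=float))
        dz, dy, dx = self.voxel_size
        out = np.column_stack([c[:, 2] * dx, c[:, 1] * dy, c[:, 0] * dz])
        return out[0] if np.asarray(centroid_zyx).ndim == 1 else out

    def mm_to_voxel(self, points_xyz) -> np.ndarray:
        """(x, y, z) mm positions -> (z, y, x) voxel coordinates."""
        p = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        dz, dy, dx = self.voxel_size
        out = np.column_stack([p[:, 2] / dz, p[:, 1] / dy, p[:, 0] / dx])
        return out[0] if np.asarray(points_xyz).ndim == 1 else out


@dataclass
class SBRMeasurement:
    roi_mean: float
    background_mean: float
    sbr: float
    roi_min: float
    noise_sd: float

    def __iter__(self):  # allow tuple unpacking (roi, bg, sbr)
        return iter((self.roi_mean, self.background_mean, self.sbr))


@dataclass
class Detection:
    """One candidate particle in one MR volume."""

    centroid: np.ndarray                 # continuous (z, y, x) voxel coords
    position_mm: np.ndarray              # (x, y, z) mm
    roi_mean: float
    background_mean: float
    sbr: float
    dark_area_px: int
    is_aggregate: bool
    noise_sd: float
    normalized_signal: float | None = None
    stress_kPa: float | None = None
    stress_in_range: bool = True
    id: int | None = None

    @property
    def contrast(self) -> float:
        """ROI contrast: background mean minus spot ROI mean."""
        return self.background_mean - self.roi_mean

    @property
    def snr(self) -> float:
        """Spot contrast over the per-voxel background noise s.d."""
        return self.contrast / self.noise_sd


def sbr_roi_voxels(shape, centroid_zyx, *, gap_px: int = BACKGROUND_GAP_PX):
    """Voxel index arrays of the sensor ROI and the four background windows.

    Returns ``(roi_idx, bg_idx)`` as integer arrays of shape (18, 3) and
    (72, 3) in (z, y, x) order.  The ROI is the 3 x 3 in-plane window at the
    rounded in-plane center, taken on the two axial slices bracketing the
    centroid's axial position; the background windows are identical windows
    offset by (+-gap, +-gap) pixels diagonally.  Raises
    :class:`BoundaryError` if any window leaves the volume.
    """
    nz, ny, nx = shape
    zc, yc, xc = (float(v) for v in centroid_zyx)
    z0 = int(np.floor(zc))
    if zc == z0 and z0 == nz - 1:     # centroid exactly on the last slice
        z0 -= 1
    z1 = z0 + 1
    if z0 < 0 or z1 > nz - 1:
        raise BoundaryError(
            f"axial slices ({z0}, {z1}) outside volume of {nz} slices"
        )
    yi, xi = int(round(yc)), int(round(xc))

    def window(cy, cx, name):
        if cy - 1 < 0 or cy + 1 >= ny or cx - 1 < 0 or cx + 1 >= nx:
            raise BoundaryError(
                f"{name} window at (y={cy}, x={cx}) leaves the {ny}x{nx} plane"
            )
        zz, yy, xx = np.meshgrid(
            [z0, z1], [cy - 1, cy, cy + 1], [cx - 1, cx, cx + 1], indexing="ij"
        )
        return np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])

    roi = window(yi, xi, "sensor ROI")
    bgs = [
        window(yi + sy * gap_px, xi + sx * gap_px, f"background({sy:+d},{sx:+d})")
        for sy in (-1, 1)
        for sx in (-1, 1)
    ]
    return roi, np.vstack(bgs)


def compute_sbr(volume: MRVolume, centroid_zyx, *, gap_px: int = BACKGROUND_GAP_PX):
    """ROI mean, background mean, and inverse-intensity SBR at a centroid."""
    vol = volume.intensities
    roi_idx, bg_idx = sbr_roi_voxels(vol.shape, centroid_zyx, gap_px=gap_px)
    roi_vals = vol[roi_idx[:, 0], roi_idx[:, 1], roi_idx[:, 2]].astype(float)
    bg_vals = vol[bg_idx[:, 0], bg_idx[:, 1], bg_idx[:, 2]].astype(float)
    roi_mean = float(roi_vals.mean())
    bg_mean = float(bg_vals.mean())
    if roi_mean <= 0:
        raise ValidationError("ROI mean intensity is nonpositive; SBR undefined")
    sbr = bg_mean / roi_mean - 1.0
    return SBRMeasurement(
        roi_mean=roi_mean,
        background_mean=bg_mean,
        sbr=float(sbr),
        roi_min=float(roi_vals.min()),
        noise_sd=float(bg_vals.std(ddof=1)),
    )


def dark_area(
    volume: MRVolume,
    centroid_zyx,
    *,
    background_mean: float,
    roi_min: float,
    patch_halfwidth: int = 15,
) -> int:
    """Contiguous dark-pixel count around the spot on its central slice.

    Pixels count as dark below ``background_mean - 0.5 * (background_mean -
    roi_min)`` (half the spot's depth); contiguity is 8-connected in-plane,
    and only the component containing the spot center is counted.  The
    slice is median-filtered (3 x 3) so single-voxel noise at the blob
    boundary does not flip the count across the aggregation threshold, and
    the spot depth / area are measured on a 2x bilinear upsampling so the
    count does not depend on where the spot center falls within a pixel.
    """
    vol = volume.intensities
    nz, ny, nx = vol.shape
    zc, yc, xc = (float(v) for v in centroid_zyx)
    z = int(np.clip(round(zc), 0, nz - 1))
    yi, xi = int(round(yc)), int(round(xc))
    y0, y1 = max(yi - patch_halfwidth, 0), min(yi + patch_halfwidth + 1, ny)
    x0, x1 = max(xi - patch_halfwidth, 0), min(xi + patch_halfwidth + 1, nx)
    patch = ndimage.median_filter(vol[z, y0:y1, x0:x1], size=3)
    up = ndimage.zoom(patch, 2, order=1)
    depth_ref = background_mean - min(float(up.min()), roi_min)
    thr = background_mean - 0.5 * depth_ref
    labels = measure.label(up < thr, connectivity=2)
    lab = labels[2 * (yi - y0), 2 * (xi - x0)]
    if lab == 0:
        return 0
    return int(round(np.sum(labels == lab) / 4.0))


def detect_particles(
    volume: MRVolume,
    *,
    min_contrast: float = 0.02,
    min_separation: float = 0.9,
    spot_fwhm_mm: float = 0.3,
    sbr_max: float = SBR_MAX_DEFAULT,
    area_max_px: int = AREA_MAX_PX_DEFAULT,
    gap_px: int = BACKGROUND_GAP_PX,
) -> list[Detection]:
    """Detect candidate dark spots in an MR volume.

    The volume is matched-filtered with a Gaussian of the nominal spot scale
    (``spot_fwhm_mm``); local minima whose smoothed fractional dip below the
    global background estimate (volume median) exceeds ``min_contrast`` are
    kept, non-maximum-suppressed at ``min_separation`` (mm), refined to
    sub-voxel centroids by the center of mass of the intensity deficit, and
    quantified via :func:`compute_sbr` and :func:`dark_area`.  Candidates
    whose quantification windows would leave the volume are dropped.  An
    empty or constant volume yields an empty list.
    """
    if not (0 < min_contrast < 1):
        raise ValidationError(f"min_contrast must lie in (0, 1), got {min_contrast}")
    vol = volume.intensities.astype(float)
    bg_est = float(np.median(vol))
    if bg_est <= 0 or np.ptp(vol) == 0:
        return []

    sigma_mm = spot_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v for v in volume.voxel_size]
    smoothed = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="nearest")
    dip = (bg_est - smoothed) / bg_est

    # local maxima of the dip; the box half-extent stays below
    # suppress/sqrt(3) so no axis-aligned box can contain a pair of spots
    # at the guaranteed separation (greedy NMS below handles the rest)
    suppress = 0.75 * min_separation
    foot = tuple(
        max(3, 2 * int(np.ceil(0.5 * suppress / v)) + 1)
        for v in volume.voxel_size
    )
    local_max = ndimage.maximum_filter(dip, size=foot, mode="nearest")
    cand = np.argwhere((dip >= min_contrast) & (dip == local_max))
    if cand.size == 0:
        return []

    # greedy non-maximum suppression in mm; the suppression radius is kept
    # slightly below min_separation so spots placed right at the separation
    # limit are not lost to voxel-grid quantization of their peaks
    order = np.argsort(-dip[cand[:, 0], cand[:, 1], cand[:, 2]])
    cand = cand[order]
    scale = np.array(volume.voxel_size)
    kept: list[np.ndarray] = []
    for c in cand:
        if all(np.linalg.norm((c - k) * scale) >= suppress for k in kept):
            kept.append(c)

    detections: list[Detection] = []
    halfwin = [max(1, int(np.ceil(2 * s))) for s in sigma_vox]
    for det_id, peak in enumerate(kept):
        # sub-voxel refinement: center of mass of the deficit near the peak
        sl = tuple(
            slice(max(p - h, 0), min(p + h + 1, n))
            for p, h, n in zip(peak, halfwin, vol.shape)
        )
        deficit = np.clip(bg_est - vol[sl], 0, None)
        if deficit.sum() == 0:
            centroid = peak.astype(float)
        else:
            com = ndimage.center_of_mass(deficit)
            centroid = np.array([s.start for s in sl], dtype=float) + np.asarray(com)
        try:
            m = compute_sbr(volume, centroid, gap_px=gap_px)
        except BoundaryError:
            continue
        area = dark_area(
            volume, centroid, background_mean=m.background_mean, roi_min=m.roi_min
        )
        detections.append(
            Detection(
                centroid=centroid,
                position_mm=volume.voxel_to_mm(centroid),
                roi_mean=m.roi_mean,
                background_mean=m.background_mean,
                sbr=m.sbr,
                dark_area_px=area,
                is_aggregate=(m.sbr > sbr_max) or (area > area_max_px),
                noise_sd=m.noise_sd,
                id=det_id,
            )
        )
    return detections


def filter_aggregates(
    detections,
    *,
    sbr_max: float = SBR_MAX_DEFAULT,
    area_max_px: int = AREA_MAX_PX_DEFAULT,
    combine: str = "or",
) -> tuple[list[Detection], list[Detection]]:
    """Split detections into (retained, excluded) by the aggregation rule.

    A detection is excluded when its SBR exceeds ``sbr_max`` or its
    contiguous dark area exceeds ``area_max_px`` (values exactly at a
    threshold are retained).  ``combine="and"`` requires both symptoms, the
    stricter literal reading; either symptom alone indicates clumping, so
    "or" is the default.
    """
    if combine not in ("or", "and"):
        raise ValidationError(f"combine must be 'or' or 'and', got {combine!r}")
    retained, excluded = [], []
    for det in detections:
        over_sbr = det.sbr > sbr_max
        over_area = det.dark_area_px > area_max_px
        bad = (over_sbr or over_area) if combine == "or" else (over_sbr and over_area)
        (excluded if bad else retained).append(det)
    return retained, excluded


def normalize_signal(
    sbr: float, reference_sbr0: float, model: CalibrationModel = DEFAULT_MODEL
):
    """Scale a raw SBR onto the calibration curve's normalized-signal axis.

    The cohort-mean SBR of unstressed sensors (``reference_sbr0``) maps to
    the model's zero-stress signal, so
    ``normalized = sbr / reference_sbr0 * model.signal_at_zero``.
    """
    if reference_sbr0 <= 0:
        raise ValidationError("reference_sbr0 must be positive")
    out = np.asarray(sbr, dtype=float) / reference_sbr0 * model.signal_at_zero
    return out if out.ndim else float(out)
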