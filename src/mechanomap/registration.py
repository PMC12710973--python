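"""Coherent point drift (CPD) registration and region assignment.

In vivo MR volumes and ex vivo cleared-tissue fluorescence volumes of the
same tumor are related by a rigid pose change plus smooth tissue
deformation.  Both surfaces are segmented to point clouds and registered by
CPD: the source cloud is treated as a Gaussian mixture whose centroids move
coherently (rigid similarity transform, or a kernel-regularized
displacement field in non-rigid mode) to explain the target cloud, with a
uniform component absorbing outliers; EM alternates soft correspondence
with a closed-form motion update.  The fitted transform is then applied to
the sensor coordinates, each sensor is assigned to a fluorescence-defined
region, and region-wise stress statistics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateCloudError, ValidationError

__all__ = [
    "PointCloud",
    "LabelVolume",
    "RegistrationResult",
    "RegionAssignment",
    "register_cpd",
    "transform_points",
    "assign_regions",
    "region_stats",
]

POSITIVE_LABEL = "vimentin_positive"
NEGATIVE_LABEL = "vimentin_negative"


@dataclass
class PointCloud:
    """A set of 3D points (mm, (x, y, z)) with a frame label."""

    points: np.ndarray
    frame_label: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("points must be an (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class LabelVolume:
    """A volumetric region-label map on a regular grid.

    ``labels`` is (z, y, x) with 0 = negative, 1 = positive;
    ``intensity`` optionally carries the fluorescence channel on the same
    grid.  ``origin`` is the (x, y, z) mm position of voxel (0, 0, 0)'s
    center.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3D array (z, y, x)")
        if self.intensity is not None and self.intensity.shape != self.labels.shape:
            raise ValidationError("intensity grid must match label grid")

    def mm_to_voxel(self, points_xyz) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        dz, dy, dx = self.voxel_size
        ox, oy, oz = self.origin
        return np.column_stack(
            [(p[:, 2] - oz) / dz, (p[:, 1] - oy) / dy, (p[:, 0] - ox) / dx]
        )


@dataclass
class RegistrationResult:
    """Fitted CPD transform: similarity part plus optional displacement field.

    The rigid part maps source-frame points p to ``scale * R @ p + t``.  In
    non-rigid mode a Gaussian-kernel displacement field (width ``beta``,
    coefficients ``coefficients`` anchored at ``control_points``, the
    rigidly aligned source) is added on top.
    """

    mode: str
    rotation: np.ndarray
    translation: np.ndarray
    scale: float
    beta: float | None = None
    regularization: float | None = None
    coefficients: np.ndarray | None = None
    control_points: np.ndarray | None = None
    final_sigma2: float = np.nan
    iterations_run: int = 0
    converged: bool = False
    objective_history: list = field(default_factory=list)
    registered: np.ndarray | None = None


def _gauss_kernel(a: np.ndarray, b: np.ndarray, beta: float) -> np.ndarray:
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
    return np.exp(-d2 / (2.0 * beta * beta))


def _estep(X, TY, sigma2, w):
    """Posterior correspondence matrix P (M, N) and the data log-likelihood."""
    N, D = X.shape
    M = TY.shape[0]
    d2 = np.sum((X[None, :, :] - TY[:, None, :]) ** 2, axis=2)
    gauss = np.exp(-d2 / (2.0 * sigma2))
    span = np.ptp(X, axis=0)
    volume = float(np.prod(np.where(span > 0, span, 1.0)))
    # uniform outlier density 1/volume gives the mixing constant below
    c = (2.0 * np.pi * sigma2) ** (D / 2.0) * (w / max(1.0 - w, 1e-12)) * M / volume
    den = gauss.sum(axis=0) + c
    den = np.where(den > 0, den, np.finfo(float).tiny)
    P = gauss / den
    # negative log-likelihood of the mixture (uniform outlier density 1/volume)
    norm = (1.0 - w) / (M * (2.0 * np.pi * sigma2) ** (D / 2.0))
    mix = norm * gauss.sum(axis=0) + w / volume
    nll = -float(np.sum(np.log(np.where(mix > 0, mix, np.finfo(float).tiny))))
    return P, nll


def register_cpd(
    source: PointCloud,
    target: PointCloud,
    *,
    mode: str = "rigid",
    w: float = 0.1,
    beta: float = 2.0,
    lam: float = 3.0,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> RegistrationResult:
    """Register ``source`` onto ``target`` by coherent point drift.

    ``mode="rigid"`` fits a similarity transform (rotation, translation,
    isotropic scale).  ``mode="nonrigid"`` first runs the rigid stage, then
    fits a Gaussian-kernel displacement field (width ``beta`` mm,
    regularization weight ``lam``) on top; both parts are recorded in one
    result.  Both clouds are centered to a common origin internally.
    Convergence: relative change of sigma^2 below ``tol``.
    """
    if mode not in ("rigid", "nonrigid"):
        raise ValidationError(f"mode must be 'rigid' or 'nonrigid', got {mode!r}")
    if not (0 <= w < 1):
        raise ValidationError(f"outlier weight w must lie in [0, 1), got {w}")
    min_pts = 4 if mode == "rigid" else 10
    if len(source) < min_pts or len(target) < min_pts:
        raise ValidationError(f"{mode} registration needs >= {min_pts} points")

    Y0 = source.points
    X0 = target.points
    mu_y0, mu_x0 = Y0.mean(axis=0), X0.mean(axis=0)
    # degeneracy check (collinear clouds cannot fix a rotation)
    sv = np.linalg.svd(Y0 - mu_y0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateCloudError("source cloud is (near-)collinear")

    Y = Y0 - mu_y0
    X = X0 - mu_x0
    N, D = X.shape
    M = Y.shape[0]

    # ---------------- rigid similarity stage ----------------------------
    R = np.eye(D)
    s = 1.0
    t = np.zeros(D)
    sigma2 = float(np.sum((X[None] - Y[:, None]) ** 2) / (D * N * M))
    sigma2 = max(sigma2, 1e-12)
    history: list[float] = []
    iters = 0
    converged = False
    for iters in range(1, max_iter + 1):
        TY = s * Y @ R.T + t
        P, nll = _estep(X, TY, sigma2, w)
        history.append(nll)
        Np = float(P.sum())
        if Np <= 0:
            break
        P1 = P.sum(axis=1)
        Pt1 = P.sum(axis=0)
        mu_x = (Pt1 @ X) / Np
        mu_y = (P1 @ Y) / Np
        Xh = X - mu_x
        Yh = Y - mu_y
        A = Xh.T @ P.T @ Yh
        U, _, Vt = np.linalg.svd(A)
        C = np.eye(D)
        C[-1, -1] = np.sign(np.linalg.det(U @ Vt))
        R = U @ C @ Vt
        denom = float(np.sum(P1 * np.sum(Yh * Yh, axis=1)))
        s = float(np.trace(A.T @ R)) / denom if denom > 0 else 1.0
        t = mu_x - s * R @ mu_y
        sigma2_new = (
            float(np.sum(Pt1 * np.sum(Xh * Xh, axis=1))) - s * float(np.trace(A.T @ R))
        ) / (Np * D)
        sigma2_new = max(sigma2_new, 1e-12)
        if abs(sigma2 - sigma2_new) / max(sigma2, 1e-12) < tol:
            sigma2 = sigma2_new
            converged = True
            break
        sigma2 = sigma2_new

    # fold the internal centering into the reported similarity transform:
    # p -> s R (p - mu_y0) + t + mu_x0
    translation = t + mu_x0 - s * R @ mu_y0
    result = RegistrationResult(
        mode=mode,
        rotation=R,
        translation=translation,
        scale=s,
        final_sigma2=sigma2,
        iterations_run=iters,
        converged=converged,
        objective_history=history,
    )

    if mode == "rigid":
        result.registered = s * Y0 @ R.T + translation
        return result

    # ---------------- non-rigid stage on the rigidly aligned source ------
    Z = s * Y0 @ R.T + translation          # control points, target frame
    G = _gauss_kernel(Z, Z, beta)
    W = np.zeros_like(Z)
    sigma2 = float(np.sum((X0[None] - Z[:, None]) ** 2) / (D * N * M))
    sigma2 = max(sigma2, 1e-12)
    nr_history: list[float] = []
    converged = False
    for iters in range(1, max_iter + 1):
        TY = Z + G @ W
        P, nll = _estep(X0, TY, sigma2, w)
        penalty = 0.5 * lam * float(np.trace(W.T @ G @ W))
        nr_history.append(nll + penalty)
        P1 = P.sum(axis=1)
        Pt1 = P.sum(axis=0)
        Np = float(P.sum())
        if Np <= 0:
            break
        dP1_inv = 1.0 / np.maximum(P1, 1e-12)
        LHS = G + lam * sigma2 * np.diag(dP1_inv)
        RHS = dP1_inv[:, None] * (P @ X0) - Z
        W = np.linalg.solve(LHS, RHS)
        TY = Z + G @ W
        xPx = float(np.sum(Pt1 * np.sum(X0 * X0, axis=1)))
        trPXT = float(np.sum((P @ X0) * TY))
        trTdT = float(np.sum(P1 * np.sum(TY * TY, axis=1)))
        sigma2_new = max((xPx - 2.0 * trPXT + trTdT) / (Np * D), 1e-12)
        if abs(sigma2 - sigma2_new) / max(sigma2, 1e-12) < tol:
            sigma2 = sigma2_new
            converged = True
            break
        sigma2 = sigma2_new

    result.beta = beta
    result.regularization = lam
    result.coefficients = W
    result.control_points = Z
    result.final_sigma2 = sigma2
    result.iterations_run = iters
    result.converged = converged
    result.objective_history = nr_history
    result.registered = Z + G @ W
    return result


def transform_points(result: RegistrationResult, points: PointCloud) -> PointCloud:
    """Apply a fitted registration to arbitrary points (e.g. sensor coords).

    The similarity part is applied exactly; in non-rigid mode the
    displacement field is evaluated at the rigidly aligned positions with
    the same Gaussian kernel against the control points.
    """
    p = points.points
    z = result.scale * p @ result.rotation.T + result.translation
    if result.mode == "nonrigid" and result.coefficients is not None:
        z = z + _gauss_kernel(z, result.control_points, result.beta) @ result.coefficients
    return PointCloud(points=z, frame_label="registered")


@dataclass
class RegionAssignment:
    sensor_id: int
    registered_position: np.ndarray
    region_label: str | None
    local_fluorescence: float
    assigned: bool


def assign_regions(
    points: PointCloud,
    labels: LabelVolume,
    *,
    sampling_radius: float = 0.3,
) -> list[RegionAssignment]:
    """Assign each registered sensor to a region of the label volume.

    The label is the majority vote over voxels within ``sampling_radius``
    (mm, about one particle diameter) of the registered position;
    ``local_fluorescence`` is the mean intensity over the same ball.
    Points whose ball lies entirely outside the volume are flagged
    unassigned.
    """
    dz, dy, dx = labels.voxel_size
    rz, ry, rx = (max(1, int(np.ceil(sampling_radius / d))) for d in (dz, dy, dx))
    zz, yy, xx = np.meshgrid(
        np.arange(-rz, rz + 1), np.arange(-ry, ry + 1), np.arange(-rx, rx + 1),
        indexing="ij",
    )
    ball = (zz * dz) ** 2 + (yy * dy) ** 2 + (xx * dx) ** 2 <= sampling_radius**2
    offsets = np.column_stack([zz[ball], yy[ball], xx[ball]])

    intensity = labels.intensity if labels.intensity is not None else labels.labels
    out: list[RegionAssignment] = []
    vox = labels.mm_to_voxel(points.points)
    shape = np.array(labels.labels.shape)
    for i, v in enumerate(np.atleast_2d(vox)):
        idx = np.round(v).astype(int) + offsets
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        if not np.any(ok):
            out.append(
                RegionAssignment(i, points.points[i], None, np.nan, assigned=False)
            )
            continue
        idx = idx[ok]
        lab_vals = labels.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        fluo = float(np.mean(intensity[idx[:, 0], idx[:, 1], idx[:, 2]]))
        label = POSITIVE_LABEL if np.mean(lab_vals > 0) > 0.5 else NEGATIVE_LABEL
        out.append(RegionAssignment(i, points.points[i], label, fluo, assigned=True))
    return out


def region_stats(assignments, stresses) -> pd.DataFrame:
    """Descriptive per-region stress statistics.

    Returns a DataFrame indexed by region label with columns ``mean_kPa``,
    ``sd_kPa`` and ``n`` (empty regions reported with n = 0), plus the
    attribute-style row ``difference`` = negative-region mean minus
    positive-region mean in ``df.attrs["mean_difference_kPa"]``.
    """
    stresses = np.asarray(stresses, dtype=float)
    if len(stresses) != len(assignments):
        raise ValidationError("one stress value per assignment required")
    rows = {}
    for label in (NEGATIVE_LABEL, POSITIVE_LABEL):
        vals = np.array(
            [s for a, s in zip(assignments, stresses) if a.region_label == label]
        )
        rows[label] = {
            "mean_kPa": float(vals.mean()) if vals.size else np.nan,
            "sd_kPa": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            "n": int(vals.size),
        }
    df = pd.DataFrame(rows).T
    df["n"] = df["n"].astype(int)
    df.attrs["mean_difference_kPa"] = float(
        df.loc[NEGATIVE_LABEL, "mean_kPa"] - df.loc[POSITIVE_LABEL, "mean_kPa"]
    )
    return df
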