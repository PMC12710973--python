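"""Stress-signal calibration for hydrogel MR stress microsensors.

The normalized T2* signal of a single compressible hydrogel sensor decays
with the compressive stress ``S`` (kPa) it experiences.  Empirically the
relationship is well described by a biexponential decay

    signal(S) = a1 * exp(-b1 * S) + a2 * exp(-b2 * S),

with a fast component (b1, sub-kPa scale) and a slow component (b2) that
carries most of the dynamic range over the physiological 0-15 kPa window.
This module houses the forward law, its numerical inversion (Newton-Raphson
with a bisection safeguard), nonlinear least-squares fitting of the four
coefficients from calibration measurements, and the saturating strain-stress
model used for the optical (confocal) readout arm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, NumericalError, SignalRangeError, ValidationError

__all__ = [
    "CalibrationModel",
    "ParticleStrainModel",
    "DEFAULT_MODEL",
    "DEFAULT_STRAIN_MODEL",
    "forward_signal",
    "invert_signal",
    "estimate_stress",
    "fit_calibration",
    "strain_from_stress",
    "stress_from_strain",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Biexponential stress-signal law with its validity range.

    Coefficients follow the fast/slow ordering convention ``b1 > b2 > 0``;
    amplitudes are positive.  ``reference_sbr0`` is the cohort-mean raw SBR of
    unstressed sensors used to normalize measured SBR onto the calibration
    scale (see :func:`mechanomap.mrsignal.normalize_signal`).
    """

    a1: float
    b1: float
    a2: float
    b2: float
    stress_range: tuple[float, float] = (0.0, 15.0)
    reference_sbr0: float | None = None

    def __post_init__(self) -> None:
        if not (self.a1 > 0 and self.a2 > 0):
            raise ValidationError("amplitudes a1, a2 must be positive")
        if not (self.b1 > self.b2 > 0):
            raise ValidationError(
                f"rate ordering b1 > b2 > 0 violated: b1={self.b1}, b2={self.b2}"
            )
        lo, hi = self.stress_range
        if not (0 <= lo < hi):
            raise ValidationError(f"invalid stress_range {self.stress_range}")

    @property
    def signal_at_zero(self) -> float:
        """Signal at S = 0, i.e. a1 + a2."""
        return self.a1 + self.a2

    def with_reference(self, reference_sbr0: float) -> "CalibrationModel":
        return replace(self, reference_sbr0=reference_sbr0)

    def to_json(self, path) -> None:
        payload = {
            "a1": self.a1,
            "b1": self.b1,
            "a2": self.a2,
            "b2": self.b2,
            "stress_range": list(self.stress_range),
            "reference_sbr0": self.reference_sbr0,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            a1=d["a1"], b1=d["b1"], a2=d["a2"], b2=d["b2"],
            stress_range=tuple(d.get("stress_range", (0.0, 15.0))),
            reference_sbr0=d.get("reference_sbr0"),
        )


#: Default calibration instance carrying the published coefficients.
DEFAULT_MODEL = CalibrationModel(a1=0.1344, b1=0.926, a2=0.864, b2=0.0405)


def forward_signal(model: CalibrationModel, S, *, extrapolation_tol: float = 0.0):
    """Evaluate the biexponential law at stress ``S`` (kPa).

    Negative stresses are a domain error (solid stress here is compressive,
    >= 0 by convention).  Stresses above the calibrated range are permitted
    but raise a warning once they exceed ``extrapolation_tol`` kPa past the
    upper bound: in vivo values near the top of the range do occur and a hard
    error would be wrong, but the law is only empirical inside it.
    """
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValidationError(f"negative stress not allowed (got {S!r})")
    hi = model.stress_range[1]
    if np.any(S_arr > hi + extrapolation_tol):
        warnings.warn(
            f"stress above calibrated range [{model.stress_range[0]}, {hi}] kPa; "
            "signal is an extrapolation",
            stacklevel=2,
        )
    out = model.a1 * np.exp(-model.b1 * S_arr) + model.a2 * np.exp(-model.b2 * S_arr)
    return out if out.ndim else float(out)


def _forward_deriv(model: CalibrationModel, S: float) -> float:
    return -(model.a1 * model.b1 * np.exp(-model.b1 * S)
             + model.a2 * model.b2 * np.exp(-model.b2 * S))


def invert_signal(
    model: CalibrationModel,
    signal,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Solve ``forward_signal(model, S) = signal`` for S (kPa).

    Newton-Raphson from the midpoint of the stress range; any iterate that
    escapes the current bracket, or failure to converge in ``max_iter``
    steps, falls back to bisection (the forward law is strictly decreasing,
    so the root is always bracketed).  Accepts scalars or arrays.
    """
    sig_arr = np.asarray(signal, dtype=float)
    if sig_arr.ndim:
        return np.array([invert_signal(model, s, tol=tol, max_iter=max_iter)
                         for s in sig_arr.ravel()]).reshape(sig_arr.shape)

    sig = float(sig_arr)
    lo, hi = model.stress_range
    f_lo = forward_signal(model, lo)   # largest attainable signal
    f_hi = forward_signal(model, hi)   # smallest attainable signal
    if not (f_hi <= sig <= f_lo):
        raise SignalRangeError(
            f"signal {sig:.6g} outside attainable range [{f_hi:.6g}, {f_lo:.6g}] "
            f"for stress in [{lo}, {hi}] kPa"
        )

    a, b = lo, hi                      # bracket: g(a) >= 0 >= g(b)
    S = 0.5 * (lo + hi)
    for _ in range(max_iter):
        g = forward_signal(model, S) - sig
        if abs(g) < tol:
            break
        if g > 0:
            a = S
        else:
            b = S
        step = g / _forward_deriv(model, S)
        S_new = S - step
        if not (a < S_new < b):       # Newton escaped the bracket: bisect
            S_new = 0.5 * (a + b)
        S = S_new
    else:
        # bisection fallback to full tolerance
        for _ in range(200):
            S = 0.5 * (a + b)
            g = forward_signal(model, S) - sig
            if abs(g) < tol:
                break
            if g > 0:
                a = S
            else:
                b = S
        else:
            raise NumericalError(f"inversion did not converge for signal {sig}")
    # clamp sub-tolerance overshoot only
    return float(min(max(S, lo), hi))


def estimate_stress(model: CalibrationModel, signal: float, *, clip: bool = True):
    """Invert a (possibly noisy) normalized signal into stress.

    Returns ``(stress_kPa, in_range)``.  Noisy measurements of unstressed
    sensors routinely exceed the zero-stress signal; with ``clip=True`` such
    signals are mapped to the nearest range endpoint and flagged
    ``in_range=False`` instead of raising.
    """
    lo, hi = model.stress_range
    f_lo, f_hi = forward_signal(model, lo), forward_signal(model, hi)
    if f_hi <= signal <= f_lo:
        return invert_signal(model, signal), True
    if not clip:
        raise SignalRangeError(
            f"signal {signal:.6g} outside attainable range [{f_hi:.6g}, {f_lo:.6g}]"
        )
    return (lo, False) if signal > f_lo else (hi, False)


def _biexp(S, a1, b1, a2, b2):
    return a1 * np.exp(-b1 * S) + a2 * np.exp(-b2 * S)


def fit_calibration(points, *, stress_range=(0.0, 15.0)) -> CalibrationModel:
    """Fit the four biexponential coefficients by nonlinear least squares.

    ``points`` is a sequence of ``(stress_kPa, signal)`` pairs covering at
    least 6 distinct stress levels over at least half the stress range.
    Initialization: a log-linear fit of the slow tail (upper half of the
    stress range) seeds (a2, b2); a log-linear fit of the positive part of
    the residual seeds (a1, b1).  Coefficients are constrained positive and
    reordered to the fast/slow convention after convergence.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array of (stress, signal)")
    S, y = pts[:, 0], pts[:, 1]
    levels = np.unique(S)
    if levels.size < 6:
        raise FitError(f"need >= 6 distinct stress levels, got {levels.size}")
    span = levels.max() - levels.min()
    if span < 0.5 * (stress_range[1] - stress_range[0]):
        raise FitError(
            f"stress levels span {span:.3g} kPa; need at least half of "
            f"{stress_range[1] - stress_range[0]:.3g} kPa"
        )

    # --- initialization from the slow tail -------------------------------
    tail = S >= levels.min() + 0.5 * span
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.polyfit(S[tail & (y > 0)], np.log(y[tail & (y > 0)]), 1)
    b2_0 = max(-coef[0], 1e-4)
    a2_0 = float(np.clip(np.exp(coef[1]), 1e-6, None))
    resid = y - a2_0 * np.exp(-b2_0 * S)
    pos = resid > np.finfo(float).eps
    if pos.sum() >= 2:
        coef = np.polyfit(S[pos], np.log(resid[pos]), 1)
        b1_0 = max(-coef[0], b2_0 * 5)
        a1_0 = float(np.clip(np.exp(coef[1]), 1e-6, None))
    else:
        a1_0, b1_0 = 0.1 * a2_0, 10 * b2_0

    p0 = (a1_0, b1_0, a2_0, b2_0)
    bounds = (0.0, np.inf)
    try:
        popt, _ = curve_fit(_biexp, S, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        # retry from a perturbed start before giving up
        p0b = tuple(max(p * 1.5 + 1e-3, 1e-4) for p in p0)
        try:
            popt, _ = curve_fit(_biexp, S, y, p0=p0b, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"biexponential fit failed to converge: {exc}") from exc

    a1, b1, a2, b2 = popt
    if b1 < b2:                       # resolve label-swap symmetry
        a1, b1, a2, b2 = a2, b2, a1, b1
    if b1 == b2:                      # degenerate: split rates minimally
        b1 = b2 * (1 + 1e-9)
    a1 = max(a1, 1e-12)
    a2 = max(a2, 1e-12)
    return CalibrationModel(a1=float(a1), b1=float(b1), a2=float(a2), b2=float(b2),
                            stress_range=tuple(stress_range))


# ---------------------------------------------------------------------------
# Optical (confocal) readout arm: axial strain of the sensor vs. stress.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticleStrainModel:
    """Saturating strain-stress law for the deformable sensor particle.

    ``strain(S) = max_strain * S / (S + particle_modulus)`` -- zero at zero
    stress, strictly increasing, asymptotic to ``max_strain``.  This is a
    two-parameter surrogate for the measured single-particle compression
    curve; ``particle_modulus`` (kPa) is the stress at half-saturation.
    """

    particle_modulus: float = 8.0
    max_strain: float = 0.6

    def __post_init__(self) -> None:
        if self.particle_modulus <= 0 or not (0 < self.max_strain < 1):
            raise ValidationError("need particle_modulus > 0 and 0 < max_strain < 1")


DEFAULT_STRAIN_MODEL = ParticleStrainModel()


def strain_from_stress(model: ParticleStrainModel, S):
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValidationError("negative stress not allowed")
    out = model.max_strain * S_arr / (S_arr + model.particle_modulus)
    return out if out.ndim else float(out)


def stress_from_strain(model: ParticleStrainModel, strain):
    """Closed-form inverse of :func:`strain_from_stress`."""
    e = np.asarray(strain, dtype=float)
    if np.any(e < 0) or np.any(e >= model.max_strain):
        raise ValidationError(
            f"strain must lie in [0, {model.max_strain}) to be invertible"
        )
    out = model.particle_modulus * e / (model.max_strain - e)
    return out if out.ndim else float(out)
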