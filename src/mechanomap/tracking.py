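"""Longitudinal single-particle linking and loading-rate statistics.

Sensors are sparse (tens per tumor) and move slowly between imaging
sessions apart from bulk tumor growth, so linking uses greedy
mutual-nearest-neighbor matching between consecutive sessions, optionally
after a similarity (scale + translation) alignment of the constellations
to absorb growth.  Linked trajectories carry per-session stress estimates;
the change over a time window (delta-stress) and its rate distinguish
gradual from acute mechanical loading, the quantity that separates tissue
regions that later undergo EMT from those that do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, estimate_stress
from .errors import ValidationError, WindowError
from .mrsignal import Detection, normalize_signal

__all__ = [
    "TrackRecord",
    "Trajectory",
    "link_particles",
    "trajectory_stress",
    "compute_loading_rate",
    "classify_loading",
    "trajectories_to_frame",
]


@dataclass
class TrackRecord:
    session_time: float                  # days
    position_mm: np.ndarray              # (x, y, z)
    sbr: float
    normalized_signal: float | None = None
    stress_kPa: float | None = None
    stress_in_range: bool = True


@dataclass
class Trajectory:
    """One physical particle followed across imaging sessions."""

    particle_id: int
    records: list[TrackRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [r.session_time for r in self.records]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("trajectory records must be time-sorted")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.session_time for r in self.records])

    @property
    def stresses(self) -> np.ndarray:
        return np.array(
            [np.nan if r.stress_kPa is None else r.stress_kPa for r in self.records]
        )

    @property
    def delta_stress(self) -> list[tuple[tuple[float, float], float]]:
        """Per-interval stress changes [((t0, t1), S(t1) - S(t0)), ...]."""
        t, s = self.times, self.stresses
        return [((t[i], t[i + 1]), s[i + 1] - s[i]) for i in range(len(t) - 1)]

    @property
    def loading_rate(self) -> list[float]:
        """Per-interval loading rates, kPa/day."""
        return [d / (t1 - t0) for (t0, t1), d in self.delta_stress]


def _record_from_detection(det: Detection, time: float) -> TrackRecord:
    return TrackRecord(
        session_time=float(time),
        position_mm=np.asarray(det.position_mm, dtype=float),
        sbr=det.sbr,
        normalized_signal=det.normalized_signal,
        stress_kPa=det.stress_kPa,
        stress_in_range=det.stress_in_range,
    )


def _similarity_align(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Map constellation A onto B's frame by centroid + RMS-radius matching."""
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    ra = np.sqrt(np.mean(np.sum((A - ca) ** 2, axis=1)))
    rb = np.sqrt(np.mean(np.sum((B - cb) ** 2, axis=1)))
    s = rb / ra if ra > 0 else 1.0
    return cb + s * (A - ca)


def link_particles(
    detections_per_session,
    session_times,
    *,
    max_displacement: float = 1.0,
    growth_correction: bool = False,
) -> list[Trajectory]:
    """Link detections of the same particle across sessions.

    Consecutive sessions are matched by greedy mutual nearest neighbors,
    gated at ``max_displacement`` (mm) after the optional similarity
    alignment (``growth_correction``).  Unmatched detections start or
    terminate trajectories; nothing is ever force-linked.  Aggregates
    should be filtered out beforehand.
    """
    times = np.asarray(session_times, dtype=float)
    if len(detections_per_session) != len(times):
        raise ValidationError("one detection list per session time required")
    if len(times) < 2:
        raise ValidationError("need at least 2 sessions to link")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("session times must be strictly increasing")

    next_id = 0
    trajectories: list[Trajectory] = []
    active: list[Trajectory] = []
    for det in detections_per_session[0]:
        traj = Trajectory(particle_id=next_id,
                          records=[_record_from_detection(det, times[0])])
        next_id += 1
        trajectories.append(traj)
        active.append(traj)

    for s in range(1, len(times)):
        dets = list(detections_per_session[s])
        B = (
            np.array([np.asarray(d.position_mm, dtype=float) for d in dets])
            if dets else np.empty((0, 3))
        )
        A = (
            np.array([t.records[-1].position_mm for t in active])
            if active else np.empty((0, 3))
        )
        if len(A) and len(B):
            A_al = (
                _similarity_align(A, B)
                if growth_correction and len(A) > 1 and len(B) > 1
                else A
            )
            d = np.linalg.norm(A_al[:, None, :] - B[None, :, :], axis=2)
            nn_ab = np.argmin(d, axis=1)
            nn_ba = np.argmin(d, axis=0)
            matches = [
                (i, j)
                for i, j in enumerate(nn_ab)
                if nn_ba[j] == i and d[i, j] <= max_displacement
            ]
        else:
            matches = []
        matched_a = {i for i, _ in matches}
        matched_b = {j for _, j in matches}
        for i, j in matches:
            active[i].records.append(_record_from_detection(dets[j], times[s]))
        survivors = [t for i, t in enumerate(active) if i in matched_a]
        for j, det in enumerate(dets):
            if j not in matched_b:
                traj = Trajectory(particle_id=next_id,
                                  records=[_record_from_detection(det, times[s])])
                next_id += 1
                trajectories.append(traj)
                survivors.append(traj)
        active = survivors
    return trajectories


def trajectory_stress(
    traj: Trajectory,
    model: CalibrationModel,
    *,
    reference_sbr0: float | None = None,
) -> Trajectory:
    """Populate per-record stress by inverting the calibration model.

    Records lacking a normalized signal are normalized first using
    ``reference_sbr0`` (or the model's stored reference).  Signals outside
    the attainable range are clamped to the nearest range endpoint and
    flagged via ``stress_in_range``, never dropped.
    """
    ref = reference_sbr0 if reference_sbr0 is not None else model.reference_sbr0
    for rec in traj.records:
        if rec.normalized_signal is None:
            if ref is None:
                raise ValidationError(
                    "no normalized signal and no reference_sbr0 available"
                )
            rec.normalized_signal = normalize_signal(rec.sbr, ref, model)
        rec.stress_kPa, rec.stress_in_range = estimate_stress(
            model, rec.normalized_signal, clip=True
        )
    return traj


def compute_loading_rate(
    traj: Trajectory,
    window="pre-induction",
    *,
    induction_day: float | None = None,
) -> tuple[float, float]:
    """Delta-stress (kPa) and loading rate (kPa/day) over a time window.

    ``window`` is a (t_start, t_end) day pair matching record times, or
    ``"pre-induction"``: the interval spanned by the two sessions
    immediately preceding ``induction_day`` (the retrospective window used
    to ask what loading preceded a cell-state transition).
    """
    if len(traj) < 2:
        raise WindowError("trajectory has fewer than 2 records")
    t = traj.times
    s = traj.stresses
    if isinstance(window, str):
        if window != "pre-induction":
            raise ValidationError(f"unknown window {window!r}")
        if induction_day is None:
            raise ValidationError("pre-induction window requires induction_day")
        pre = np.where(t < induction_day)[0]
        if len(pre) < 2:
            raise WindowError(
                f"fewer than 2 sessions precede induction day {induction_day}"
            )
        i0, i1 = pre[-2], pre[-1]
    else:
        t0, t1 = window
        m0 = np.where(np.isclose(t, t0))[0]
        m1 = np.where(np.isclose(t, t1))[0]
        if not len(m0) or not len(m1):
            raise WindowError(
                f"window ({t0}, {t1}) not covered by trajectory times {t.tolist()}"
            )
        i0, i1 = m0[0], m1[0]
        if i1 <= i0:
            raise WindowError("window end must follow window start")
    if np.isnan(s[i0]) or np.isnan(s[i1]):
        raise ValidationError("stress not populated; run trajectory_stress first")
    delta = float(s[i1] - s[i0])
    return delta, delta / float(t[i1] - t[i0])


def classify_loading(traj: Trajectory, rate_threshold: float) -> str:
    """Classify a stress trajectory as ``"acute"`` or ``"gradual"``.

    Acute means any single inter-session loading rate exceeds
    ``rate_threshold`` (kPa/day); there is no canonical threshold, so it is
    always explicit.
    """
    if len(traj) < 2:
        raise ValidationError("cannot classify a trajectory with < 2 records")
    if np.any(np.isnan(traj.stresses)):
        raise ValidationError("stress not populated; run trajectory_stress first")
    return "acute" if max(traj.loading_rate) > rate_threshold else "gradual"


def trajectories_to_frame(trajectories) -> pd.DataFrame:
    """Long-format table: one row per (trajectory, session)."""
    rows = []
    for traj in trajectories:
        for rec in traj.records:
            rows.append(
                {
                    "particle_id": traj.particle_id,
                    "session_time_days": rec.session_time,
                    "x_mm": rec.position_mm[0],
                    "y_mm": rec.position_mm[1],
                    "z_mm": rec.position_mm[2],
                    "sbr": rec.sbr,
                    "normalized_signal": rec.normalized_signal,
                    "stress_kPa": rec.stress_kPa,
                    "stress_in_range": rec.stress_in_range,
                }
            )
    return pd.DataFrame(rows)
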