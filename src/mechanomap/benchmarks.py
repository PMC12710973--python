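"""Reference benchmark scenarios computed end-to-end through the pipeline.

Each function regenerates its synthetic inputs from a seed, runs the full
measurement chain (render -> detect -> quantify -> invert -> register),
and returns summary numbers.  They are shared by the analysis drivers, the
acceptance checks, and the test suite so every reported figure comes from
one code path.
"""

from __future__ import annotations

import numpy as np

from .calibration import DEFAULT_MODEL, DEFAULT_STRAIN_MODEL, estimate_stress, \
    fit_calibration, forward_signal, stress_from_strain
from .mrsignal import compute_sbr, detect_particles, filter_aggregates, normalize_signal
from .registration import PointCloud, assign_regions, region_stats, register_cpd, \
    transform_points
from .synthetic import generate_calibration_phantom, generate_cfm_observations, \
    generate_two_region_scene, render_session

_MASK31 = 0x7FFFFFFF


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) & _MASK31 for s in np.random.SeedSequence(seed).generate_state(n)]


def calibration_self_recovery(n_levels: int = 31) -> dict:
    """Fit the biexponential law to its own noiseless samples (0-15 kPa)."""
    S = np.linspace(0.0, 15.0, n_levels)
    fit = fit_calibration(np.column_stack([S, forward_signal(DEFAULT_MODEL, S)]))
    return {"a1": fit.a1, "b1": fit.b1, "a2": fit.a2, "b2": fit.b2, "n": n_levels}


def measure_reference_sbr0(seed: int, n_particles: int = 30) -> float:
    """Cohort-mean SBR of a zero-stress phantom, via the detection module."""
    volume, _ = generate_calibration_phantom(n_particles, 0.0, seed=seed)
    retained, _ = filter_aggregates(detect_particles(volume))
    return float(np.mean([d.sbr for d in retained]))


def phantom_snr(seed: int, n_particles: int = 30) -> dict:
    """Mean single-particle contrast-to-noise ratio on a zero-stress phantom."""
    volume, _ = generate_calibration_phantom(n_particles, 0.0, seed=seed)
    dets, _ = filter_aggregates(detect_particles(volume))
    return {"snr": float(np.mean([d.snr for d in dets])), "n": len(dets)}


def phantom_sbr_cv(seed: int, n_particles: int = 30, n_realizations: int = 10) -> dict:
    """Repeat-measurement CV (%) of per-particle SBR over noise realizations.

    One phantom geometry is fixed and re-rendered under independent noise;
    each particle's SBR is measured with the standard two-slice ROI at its
    ground-truth position, and the mean over particles of (s.d./mean) x 100
    is returned.
    """
    sub = _subseeds(seed, n_realizations + 1)
    _, scene = generate_calibration_phantom(n_particles, 0.0, seed=sub[0])
    sbrs = np.empty((n_realizations, n_particles))
    for k in range(n_realizations):
        volume = render_session(scene, 0, seed=sub[k + 1])
        for i, p in enumerate(scene.particles):
            sbrs[k, i] = compute_sbr(volume, volume.mm_to_voxel(p.positions[0])).sbr
    cv = float(np.mean(sbrs.std(axis=0, ddof=1) / sbrs.mean(axis=0)) * 100.0)
    return {"cv_percent": cv, "n": n_particles, "realizations": n_realizations}


def two_region_recovery(seed: int, n_per_region: int = 60) -> dict:
    """Recover the per-region mean stresses of the two-region tumor scenario.

    Full chain: render the MR volume, detect and filter, invert SBR to
    stress against a phantom-measured reference, register the MR surface
    onto the fluorescence surface by non-rigid CPD, carry the sensor
    coordinates across, assign regions, and summarize per region.
    """
    sub = _subseeds(seed, 2)
    scene = generate_two_region_scene(n_per_region, seed=sub[0])
    retained, _ = filter_aggregates(detect_particles(scene.mr_volume))
    ref = measure_reference_sbr0(sub[1])
    model = DEFAULT_MODEL
    for det in retained:
        det.normalized_signal = normalize_signal(det.sbr, ref, model)
        det.stress_kPa, det.stress_in_range = estimate_stress(
            model, det.normalized_signal
        )
    result = register_cpd(
        scene.registration.source, scene.registration.target, mode="nonrigid"
    )
    registered = transform_points(
        result, PointCloud(np.array([d.position_mm for d in retained]))
    )
    assignments = assign_regions(registered, scene.registration.labels)
    stats = region_stats(assignments, [d.stress_kPa for d in retained])
    return {
        "positive_mean_kPa": float(stats.loc["vimentin_positive", "mean_kPa"]),
        "negative_mean_kPa": float(stats.loc["vimentin_negative", "mean_kPa"]),
        "positive_n": int(stats.loc["vimentin_positive", "n"]),
        "negative_n": int(stats.loc["vimentin_negative", "n"]),
        "n": n_per_region,
        "cpd_converged": bool(result.converged),
    }


def dual_readout_slope(seed: int, n_particles: int = 150) -> dict:
    """OLS slope of MR-derived on optics-derived stress, one phantom cohort.

    True stresses are uniform on [0, 10] kPa; the MR arm inverts the
    measured normalized signal, the optical arm inverts the noisy axial
    strain through the strain-stress law.
    """
    from scipy.spatial import cKDTree

    sub = _subseeds(seed, 4)
    rng = np.random.default_rng(sub[0])
    S = rng.uniform(0.0, 10.0, n_particles)
    volume, scene = generate_calibration_phantom(
        n_particles, S, volume_shape=(60, 120, 120), seed=sub[1]
    )
    retained, _ = filter_aggregates(detect_particles(volume))
    ref = measure_reference_sbr0(sub[2])
    model = DEFAULT_MODEL
    strains = {
        pid: strain
        for pid, _, strain in generate_cfm_observations(scene, seed=sub[3])
    }
    tree = cKDTree(scene.positions_at(0))
    mr, cfm = [], []
    for det in retained:
        dist, idx = tree.query(det.position_mm)
        if dist > 0.3:
            continue
        sig = normalize_signal(det.sbr, ref, model)
        s_mr, _ = estimate_stress(model, sig)
        mr.append(s_mr)
        cfm.append(stress_from_strain(DEFAULT_STRAIN_MODEL, strains[idx]))
    slope, intercept = np.polyfit(cfm, mr, 1)
    return {"slope": float(slope), "intercept": float(intercept), "n": len(mr)}
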