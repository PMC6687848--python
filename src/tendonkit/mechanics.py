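"""Tendon mechanical outcomes from isometric ramp-contraction records.

A ramp trial is a synchronized record of dynamometer moment, knee angle,
antagonist EMG envelope and tendon elongation while the participant ramps
from rest toward maximum effort. The reduction chain is:

1. gravity correction — the passive gravity moment, modeled as a low-order
   polynomial of knee angle fitted to a dynamometer-driven passive trial, is
   subtracted sample-wise;
2. antagonist correction — the knee-flexion moment produced by antagonist
   co-contraction, predicted from the EMG envelope via a line calibrated on
   dedicated flexion trials, is added back to the extension moment;
3. tendon force — corrected extension moment divided by the tendon moment
   arm (adjusted to the trial's knee angle when an angle-scaling profile is
   supplied);
4. the per-trial force-elongation curves are averaged at common relative
   force levels up to 80 % of the maximum tendon force (TFmax), the highest
   common relative force reached by all participants;
5. stiffness is the regression slope of force on elongation between 50 and
   80 % TFmax; strain is the elongation at 80 % TFmax over rest length;
   stress divides TFmax by regional CSA; the elastic modulus is the
   stress-strain slope between 50 and 80 % of maximum stress (full-tendon
   mean CSA); the extrapolated maximum strain linearly continues the curve
   from 80 % to 100 % TFmax with slope 1/k.

Units: moments N*m, forces N, lengths/elongations mm, areas mm^2, stress and
modulus MPa (N/mm^2), strain in percent unless noted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RampTrial",
    "EMGMomentModel",
    "ForceElongationCurve",
    "TendonMechanics",
    "gravity_correct",
    "fit_emg_moment",
    "antagonist_correct",
    "moment_arm_at_angle",
    "tendon_force",
    "average_force_elongation",
    "stiffness",
    "derived_outcomes",
    "analyze_trials",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RampTrial:
    """Synchronized time series of one ramp (or calibration) trial."""

    time_s: np.ndarray
    dyn_moment_Nm: np.ndarray
    knee_angle_deg: np.ndarray
    antagonist_emg: np.ndarray
    elongation_mm: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("time_s", "dyn_moment_Nm", "knee_angle_deg",
                     "antagonist_emg", "elongation_mm"):
            a = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite values")
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError("all series must have equal length")
            arrays[name] = a
            object.__setattr__(self, name, a)
        if np.any(np.diff(arrays["time_s"]) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class EMGMomentModel:
    """OLS line mapping an antagonist EMG envelope to a flexion moment."""

    slope_Nm_per_emg: float
    intercept_Nm: float
    r2: float

    def predict(self, emg) -> np.ndarray:
        return self.slope_Nm_per_emg * np.asarray(emg, dtype=float) + self.intercept_Nm


def gravity_correct(trial: RampTrial, passive: RampTrial, poly_order: int = 2) -> np.ndarray:
    """Net moment after removing the angle-dependent gravity moment.

    The gravity moment is a degree-``poly_order`` polynomial of knee angle
    fitted to the passive trial; angles outside the passive range are clamped
    to the nearest endpoint (with a warning).
    """
    ang_p = passive.knee_angle_deg
    lo, hi = float(ang_p.min()), float(ang_p.max())
    if hi > lo:
        coeffs = np.polyfit(ang_p, passive.dyn_moment_Nm, poly_order)
    else:  # constant-angle passive record: constant offset
        coeffs = np.array([float(passive.dyn_moment_Nm.mean())])
    ang = trial.knee_angle_deg
    if np.any(ang < lo - 1e-9) or np.any(ang > hi + 1e-9):
        if hi > lo:
            warnings.warn("trial angles outside passive range; clamped to endpoints")
    ang_c = np.clip(ang, lo, hi)
    return trial.dyn_moment_Nm - np.polyval(coeffs, ang_c)


def fit_emg_moment(flexion_trials: list) -> EMGMomentModel:
    """Pooled OLS of flexion moment on EMG envelope across calibration trials."""
    if len(flexion_trials) < 1:
        raise ValueError("need at least one flexion trial")
    emg = np.concatenate([t.antagonist_emg for t in flexion_trials])
    mom = np.concatenate([t.dyn_moment_Nm for t in flexion_trials])
    if np.var(emg) == 0:
        raise ValueError("EMG envelope has zero variance; cannot calibrate")
    slope, intercept = np.polyfit(emg, mom, 1)
    pred = slope * emg + intercept
    ss_res = float(np.sum((mom - pred) ** 2))
    ss_tot = float(np.sum((mom - mom.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return EMGMomentModel(float(slope), float(intercept), float(r2))


def antagonist_correct(net_moment_Nm, emg, model: EMGMomentModel) -> np.ndarray:
    """Extension moment plus the predicted antagonist flexion moment.

    Negative predictions are clamped to zero (a flexor cannot assist
    extension); the clamp count is logged.
    """
    pred = model.predict(emg)
    n_clamped = int(np.sum(pred < 0))
    if n_clamped:
        logger.info("antagonist model predicted < 0 for %d samples; clamped", n_clamped)
    return np.asarray(net_moment_Nm, dtype=float) + np.clip(pred, 0.0, None)


def moment_arm_at_angle(
    ma_ref_mm: float,
    ref_angle_deg: float,
    target_angle_deg: float,
    profile: tuple | None = None,
) -> float:
    """Scale a reference moment arm to another knee angle.

    ``profile`` is a ``(angles_deg, relative_values)`` monotone-interpolated
    table; the result is ``ma_ref * profile(target) / profile(ref)``. With no
    profile the moment arm is angle-independent (identity).
    """
    if profile is None:
        return float(ma_ref_mm)
    ang, val = (np.asarray(a, dtype=float) for a in profile)
    for a in (ref_angle_deg, target_angle_deg):
        if a < ang.min() - 1e-9 or a > ang.max() + 1e-9:
            raise ValueError(f"angle {a} outside profile domain [{ang.min()}, {ang.max()}]")
    v_ref = float(np.interp(ref_angle_deg, ang, val))
    v_tgt = float(np.interp(target_angle_deg, ang, val))
    return float(ma_ref_mm) * v_tgt / v_ref


def tendon_force(corrected_moment_Nm, moment_arm_mm: float) -> np.ndarray:
    """Tendon force: extension moment divided by the moment arm (in meters)."""
    if moment_arm_mm <= 0:
        raise ValueError("moment arm must be positive")
    return np.asarray(corrected_moment_Nm, dtype=float) / (moment_arm_mm / 1000.0)


@dataclass(frozen=True)
class ForceElongationCurve:
    """Trial-averaged elongation sampled at common force levels up to 0.8 TFmax."""

    force_N: np.ndarray
    elongation_mm: np.ndarray
    tfmax_N: float
    n_trials_averaged: int

    def __post_init__(self) -> None:
        f = np.asarray(self.force_N, dtype=float)
        e = np.asarray(self.elongation_mm, dtype=float)
        object.__setattr__(self, "force_N", f)
        object.__setattr__(self, "elongation_mm", e)
        if np.any(np.diff(f) <= 0):
            raise ValueError("force grid must be strictly increasing")

    def elongation_at(self, force: float) -> float:
        return float(np.interp(force, self.force_N, self.elongation_mm))


def _monotone_ramp(force: np.ndarray, elongation: np.ndarray):
    """Restrict a trial to its increasing-force envelope for interpolation."""
    env = np.maximum.accumulate(force)
    keep = force >= env  # samples on the rising envelope
    f, e = force[keep], elongation[keep]
    f, idx = np.unique(f, return_index=True)
    return f, e[idx]


def average_force_elongation(
    trials: list,
    tfmax_N: float,
    n_levels: int = 100,
) -> ForceElongationCurve:
    """Average per-trial force-elongation curves at common relative force levels.

    ``trials`` is a list of ``(force_N, elongation_mm)`` array pairs. Each
    trial's elongation is linearly interpolated at ``n_levels`` equally
    spaced force levels from just above zero to ``0.8 * tfmax_N`` and
    averaged level-wise. Trials not reaching 80 % TFmax are excluded with a
    warning; if all are excluded an error is raised.
    """
    if tfmax_N <= 0:
        raise ValueError("tfmax must be positive")
    top = 0.8 * tfmax_N
    levels = np.linspace(top / n_levels, top, n_levels)
    stacks = []
    for i, (force, elong) in enumerate(trials):
        force = np.asarray(force, dtype=float)
        elong = np.asarray(elong, dtype=float)
        if force.max() < top - 1e-9 * tfmax_N:
            warnings.warn(f"trial {i} peaks below 80 % TFmax; excluded from averaging")
            continue
        f, e = _monotone_ramp(force, elong)
        stacks.append(np.interp(levels, f, e))
    if not stacks:
        raise ValueError("no trial reaches 80 % TFmax; cannot average")
    mean_e = np.mean(np.vstack(stacks), axis=0)
    return ForceElongationCurve(
        force_N=levels, elongation_mm=mean_e,
        tfmax_N=float(tfmax_N), n_trials_averaged=len(stacks),
    )


def stiffness(curve: ForceElongationCurve, lo: float = 0.5, hi: float = 0.8) -> float:
    """OLS slope of force on elongation between ``lo`` and ``hi`` of TFmax (N/mm)."""
    f, e = curve.force_N, curve.elongation_mm
    band = (f >= lo * curve.tfmax_N - 1e-9) & (f <= hi * curve.tfmax_N + 1e-9)
    if band.sum() < 2:
        raise ValueError("fewer than 2 grid points in the stiffness band")
    eb, fb = e[band], f[band]
    return float(np.polyfit(eb, fb, 1)[0])


@dataclass(frozen=True)
class TendonMechanics:
    """Scalar mechanical outcome set for one participant."""

    tfmax_N: float
    stiffness_N_per_mm: float
    normalized_stiffness_kN_per_strain: float
    strain80_pct: float
    stress_proximal_MPa: float
    stress_distal_MPa: float
    elastic_modulus_MPa: float
    strain_max_extrapolated_pct: float
    rest_length_mm: float
    moment_arm_mm: float

    def __post_init__(self) -> None:
        if self.strain_max_extrapolated_pct < self.strain80_pct - 1e-12:
            raise ValueError("extrapolated maximum strain cannot be below strain at 80 %")


def derived_outcomes(
    curve: ForceElongationCurve,
    k_N_per_mm: float,
    rest_length_mm: float,
    csa_proximal_mm2: float,
    csa_distal_mm2: float,
    csa_full_mm2: float,
    moment_arm_mm: float = float("nan"),
    lo: float = 0.5,
    hi: float = 0.8,
) -> TendonMechanics:
    """All scalar outcomes from the averaged curve, stiffness and geometry.

    * strain at 80 % TFmax: ``100 * e(0.8 TFmax) / L0``;
    * normalized stiffness: ``k * L0 / 1000`` (kN per unit strain);
    * regional stress: ``TFmax / CSA_region`` (MPa);
    * elastic modulus: stress-strain regression slope between ``lo`` and
      ``hi`` of maximum stress, with stress from the full-tendon mean CSA;
    * extrapolated maximum strain: ``strain80 + 100 * (0.2 TFmax / k) / L0``.
    """
    for name, v in (("stiffness", k_N_per_mm), ("rest length", rest_length_mm),
                    ("proximal CSA", csa_proximal_mm2), ("distal CSA", csa_distal_mm2),
                    ("full CSA", csa_full_mm2)):
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    tfmax = curve.tfmax_N
    e80 = curve.elongation_at(hi * tfmax)
    strain80 = 100.0 * e80 / rest_length_mm
    sigma = curve.force_N / csa_full_mm2          # MPa
    eps = curve.elongation_mm / rest_length_mm    # unit strain
    smax = tfmax / csa_full_mm2                   # stress at TFmax
    band = (sigma >= lo * smax - 1e-12) & (sigma <= hi * smax + 1e-12)
    if band.sum() < 2:
        raise ValueError("fewer than 2 points in the modulus band")
    modulus = float(np.polyfit(eps[band], sigma[band], 1)[0])
    strain_max = strain80 + 100.0 * ((1.0 - hi) * tfmax / k_N_per_mm) / rest_length_mm
    return TendonMechanics(
        tfmax_N=float(tfmax),
        stiffness_N_per_mm=float(k_N_per_mm),
        normalized_stiffness_kN_per_strain=float(k_N_per_mm * rest_length_mm / 1000.0),
        strain80_pct=float(strain80),
        stress_proximal_MPa=float(tfmax / csa_proximal_mm2),
        stress_distal_MPa=float(tfmax / csa_distal_mm2),
        elastic_modulus_MPa=modulus,
        strain_max_extrapolated_pct=float(strain_max),
        rest_length_mm=float(rest_length_mm),
        moment_arm_mm=float(moment_arm_mm),
    )


def analyze_trials(
    ramp_trials: list,
    passive: RampTrial,
    flexion_trials: list,
    moment_arm_mm: float,
    rest_length_mm: float,
    csa_proximal_mm2: float,
    csa_distal_mm2: float,
    csa_full_mm2: float,
    ma_reference_angle_deg: float = 10.0,
    ma_profile: tuple | None = None,
    n_levels: int = 100,
    lo: float = 0.5,
    hi: float = 0.8,
    gravity_poly_order: int = 2,
) -> TendonMechanics:
    """Full reduction chain from raw trials to :class:`TendonMechanics`.

    TFmax is the maximum tendon force over all ramp trials (the trial with
    the highest corrected moment is the participant's best maximum effort).
    """
    model = fit_emg_moment(flexion_trials)
    force_elong = []
    tfmax = 0.0
    for trial in ramp_trials:
        net = gravity_correct(trial, passive, gravity_poly_order)
        corrected = antagonist_correct(net, trial.antagonist_emg, model)
        ma = moment_arm_at_angle(
            moment_arm_mm, ma_reference_angle_deg,
            float(np.median(trial.knee_angle_deg)), ma_profile,
        )
        force = tendon_force(corrected, ma)
        tfmax = max(tfmax, float(force.max()))
        force_elong.append((force, trial.elongation_mm))
    curve = average_force_elongation(force_elong, tfmax, n_levels)
    k = stiffness(curve, lo, hi)
    return derived_outcomes(
        curve, k, rest_length_mm, csa_proximal_mm2, csa_distal_mm2,
        csa_full_mm2, moment_arm_mm, lo, hi,
    )
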