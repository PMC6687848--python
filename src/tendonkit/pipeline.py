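"""Per-participant and cohort orchestration of the analysis stages.

``run_participant`` executes whichever stages a participant's inputs allow —
geometry (CSA, line of action, knee axis, moment arm), mechanics (tendon
force, stiffness, strain, stress, modulus), micromorphology (proximal and
distal PSF) and Doppler area — in dependency order, capturing per-stage
errors without aborting the rest. ``run_cohort`` assembles the participant
outcomes into a cohort table and runs the full correlation battery
(normality-gated), the maturity-controlled partial correlation and the
Welch group contrast, emitting a tidy results table.

Everything is deterministic given the configuration; the configuration
hash is embedded in reports for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import doppler as dop
from . import geometry as geo
from . import mechanics as mech
from . import micromorphology as micro
from . import stats as st

__all__ = [
    "RunConfig",
    "ParticipantRecord",
    "run_participant",
    "run_cohort",
    "simulate_participant_strain_psf",
    "simulate_cohort_run",
    "power_study",
]


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters of one reproducible pipeline run."""

    psf_cutoff_mm_inv: float = 1.23
    kernel_px: int = 32
    pad_to: int = 128
    stride_px: int = 16
    hann_window: bool = False
    stiffness_band: tuple[float, float] = (0.5, 0.8)
    n_levels: int = 100
    gravity_poly_order: int = 2
    doppler_threshold: int = 30
    recovery_threshold: float = 85.0
    alpha: float = 0.05
    ma_reference_angle_deg: float = 10.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stiffness_band"] = list(d["stiffness_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stiffness_band" in d:
            d["stiffness_band"] = tuple(d["stiffness_band"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ParticipantRecord:
    """Inputs and derived outcomes for one participant.

    Input fields left ``None`` cause the corresponding stage to be skipped
    (recorded in ``skipped``); a stage failure is captured in ``errors``
    without affecting the other stages.
    """

    pid: str
    # imaging inputs
    image_proximal: object = None
    roi_proximal: object = None
    image_distal: object = None
    roi_distal: object = None
    doppler_sequence: object = None
    # geometry inputs
    stack: object = None
    condyle_medial_points: object = None
    condyle_medial_placement: object = None
    condyle_lateral_points: object = None
    condyle_lateral_placement: object = None
    moment_arm_mm: float | None = None  # may be supplied directly
    # mechanics inputs
    ramp_trials: object = None
    passive_trial: object = None
    flexion_trials: object = None
    rest_length_mm: float | None = None
    # cohort metadata
    age_y: float | None = None
    sitting_height_cm: float | None = None
    visap_baseline: float | None = None
    visap_followup: float | None = None
    # derived
    psf_proximal: object = None
    psf_distal: object = None
    doppler_result: object = None
    csa_proximal40_mm2: float | None = None
    csa_distal40_mm2: float | None = None
    csa_full_mm2: float | None = None
    tendon_length_mm: float | None = None
    mechanics: object = None
    phv_offset_y: float | None = None
    group: str | None = None
    skipped: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)
    config_hash: str | None = None


def _stage(record: ParticipantRecord, name: str, fn) -> None:
    try:
        fn()
    except Exception as exc:  # isolation contract: one stage cannot sink the rest
        record.errors[name] = f"{type(exc).__name__}: {exc}"


def run_participant(
    record: ParticipantRecord,
    config: RunConfig = RunConfig(),
    maturity_coefficients: st.MaturityCoefficients | None = None,
) -> ParticipantRecord:
    """Execute all stages the record's inputs allow, in dependency order."""
    record.config_hash = config.config_hash()

    # --- geometry ---------------------------------------------------------
    if record.stack is not None:
        def geometry_stage():
            line = geo.fit_line_of_action(record.stack)
            record.csa_proximal40_mm2 = geo.regional_csa(record.stack, line, "proximal40")
            record.csa_distal40_mm2 = geo.regional_csa(record.stack, line, "distal40")
            record.csa_full_mm2 = geo.regional_csa(record.stack, line, "full")
            record.tendon_length_mm = geo.tendon_length_mm(record.stack, line)
            if (record.moment_arm_mm is None
                    and record.condyle_medial_points is not None
                    and record.condyle_lateral_points is not None):
                med = geo.fit_circle(record.condyle_medial_points)
                lat = geo.fit_circle(record.condyle_lateral_points)
                axis = geo.knee_axis(med, record.condyle_medial_placement,
                                     lat, record.condyle_lateral_placement)
                record.moment_arm_mm = geo.moment_arm(
                    line, axis, config.ma_reference_angle_deg).value_mm
        _stage(record, "geometry", geometry_stage)
    else:
        record.skipped.append("geometry")

    # --- micromorphology --------------------------------------------------
    for site in ("proximal", "distal"):
        image = getattr(record, f"image_{site}")
        roi = getattr(record, f"roi_{site}")
        if image is None or roi is None:
            record.skipped.append(f"psf_{site}")
            continue

        def psf_stage(image=image, roi=roi, site=site):
            res = micro.image_psf(
                image, roi,
                cutoff_mm_inv=config.psf_cutoff_mm_inv,
                kernel_px=config.kernel_px, pad_to=config.pad_to,
                stride_px=config.stride_px, hann_window=config.hann_window,
            )
            setattr(record, f"psf_{site}", res)
        _stage(record, f"psf_{site}", psf_stage)

    # --- Doppler ----------------------------------------------------------
    if record.doppler_sequence is not None:
        _stage(record, "doppler", lambda: setattr(
            record, "doppler_result",
            dop.sequence_max_area(record.doppler_sequence, config.doppler_threshold)))
    else:
        record.skipped.append("doppler")

    # --- mechanics --------------------------------------------------------
    mech_inputs = (record.ramp_trials, record.passive_trial, record.flexion_trials,
                   record.moment_arm_mm, record.rest_length_mm,
                   record.csa_proximal40_mm2, record.csa_distal40_mm2,
                   record.csa_full_mm2)
    if all(v is not None for v in mech_inputs):
        def mechanics_stage():
            lo, hi = config.stiffness_band
            record.mechanics = mech.analyze_trials(
                record.ramp_trials, record.passive_trial, record.flexion_trials,
                record.moment_arm_mm, record.rest_length_mm,
                record.csa_proximal40_mm2, record.csa_distal40_mm2,
                record.csa_full_mm2,
                ma_reference_angle_deg=config.ma_reference_angle_deg,
                n_levels=config.n_levels, lo=lo, hi=hi,
                gravity_poly_order=config.gravity_poly_order,
            )
        _stage(record, "mechanics", mechanics_stage)
    else:
        record.skipped.append("mechanics")

    # --- maturity / grouping ----------------------------------------------
    if (maturity_coefficients is not None and record.age_y is not None
            and record.sitting_height_cm is not None):
        _stage(record, "maturity", lambda: setattr(
            record, "phv_offset_y",
            st.maturity_offset(record.age_y, record.sitting_height_cm,
                               maturity_coefficients)))
    if record.visap_baseline is not None and record.visap_followup is not None:
        _stage(record, "grouping", lambda: setattr(
            record, "group",
            st.classify_symptoms(record.visap_baseline, record.visap_followup,
                                 config.recovery_threshold)))
    return record


def cohort_table(records: list) -> pd.DataFrame:
    """Tidy per-participant outcome table from completed records."""
    rows = []
    for r in records:
        m = r.mechanics
        rows.append({
            "pid": r.pid,
            "strain80_pct": getattr(m, "strain80_pct", np.nan),
            "tfmax_N": getattr(m, "tfmax_N", np.nan),
            "stiffness_N_per_mm": getattr(m, "stiffness_N_per_mm", np.nan),
            "normalized_stiffness_kN_per_strain":
                getattr(m, "normalized_stiffness_kN_per_strain", np.nan),
            "stress_proximal_MPa": getattr(m, "stress_proximal_MPa", np.nan),
            "stress_distal_MPa": getattr(m, "stress_distal_MPa", np.nan),
            "elastic_modulus_MPa": getattr(m, "elastic_modulus_MPa", np.nan),
            "strain_max_extrapolated_pct":
                getattr(m, "strain_max_extrapolated_pct", np.nan),
            "psf_proximal_mm_inv":
                r.psf_proximal.mean_psf_mm_inv if r.psf_proximal else np.nan,
            "psf_distal_mm_inv":
                r.psf_distal.mean_psf_mm_inv if r.psf_distal else np.nan,
            "doppler_max_mm2":
                r.doppler_result.max_area_mm2 if r.doppler_result else np.nan,
            "phv_offset_y": r.phv_offset_y if r.phv_offset_y is not None else np.nan,
            "group": r.group,
        })
    return pd.DataFrame(rows)


#: Correlation pairs of the cohort battery: mechanics vs micromorphology and
#: vascularity, plus the stiffness-force association.
BATTERY_PAIRS = [
    ("strain80_pct", "psf_proximal_mm_inv"),
    ("strain80_pct", "psf_distal_mm_inv"),
    ("tfmax_N", "psf_proximal_mm_inv"),
    ("tfmax_N", "psf_distal_mm_inv"),
    ("stress_proximal_MPa", "psf_proximal_mm_inv"),
    ("stress_distal_MPa", "psf_distal_mm_inv"),
    ("tfmax_N", "normalized_stiffness_kN_per_strain"),
    ("strain80_pct", "doppler_max_mm2"),
    ("tfmax_N", "doppler_max_mm2"),
]


def run_cohort(
    records: list,
    config: RunConfig = RunConfig(),
    pairs: list | None = None,
) -> dict:
    """Cohort report: outcome table, correlation battery, group contrast.

    Correlations with fewer than 3 complete pairs are skipped and reported.
    The partial correlation (strain vs proximal PSF controlling PHV offset)
    runs when maturity offsets are available; the Welch contrast (strain and
    proximal PSF by symptom group) when group labels are.
    """
    table = cohort_table(records)
    tests = []
    for x_col, y_col in (pairs if pairs is not None else BATTERY_PAIRS):
        sub = table[[x_col, y_col]].dropna()
        if len(sub) < 3:
            tests.append({"x": x_col, "y": y_col, "method": "skipped",
                          "estimate": np.nan, "p_value": np.nan, "n": len(sub)})
            continue
        try:
            res = st.correlate(sub[x_col].to_numpy(), sub[y_col].to_numpy(),
                               config.alpha)
        except ValueError:  # e.g. a constant variable: correlation undefined
            tests.append({"x": x_col, "y": y_col, "method": "skipped",
                          "estimate": np.nan, "p_value": np.nan, "n": len(sub)})
            continue
        tests.append({"x": x_col, "y": y_col, "method": res.method,
                      "estimate": res.estimate, "p_value": res.p_value, "n": res.n})

    partial = None
    sub = table[["strain80_pct", "psf_proximal_mm_inv", "phv_offset_y"]].dropna()
    if len(sub) >= 4:
        partial = st.partial_correlation(
            sub["strain80_pct"].to_numpy(),
            sub["psf_proximal_mm_inv"].to_numpy(),
            sub["phv_offset_y"].to_numpy(),
        )

    welch = {}
    if table["group"].notna().any():
        for col in ("strain80_pct", "psf_proximal_mm_inv"):
            a = table.loc[table["group"] == "symptomatic", col].dropna().to_numpy()
            b = table.loc[table["group"] == "asymptomatic", col].dropna().to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                t, df, p = st.welch_t(a, b)
                welch[col] = {"t": t, "df": df, "p_value": p,
                              "n_symptomatic": len(a), "n_asymptomatic": len(b)}

    descriptives = table.drop(columns=["pid", "group"]).agg(["mean", "std"])
    return {
        "table": table,
        "tests": pd.DataFrame(tests),
        "n_tests": len(tests),
        "partial_correlation": partial,
        "welch": welch,
        "descriptives": descriptives,
        "config_hash": config.config_hash(),
    }


# ---------------------------------------------------------------------------
# end-to-end synthetic cohort studies


def simulate_participant_strain_psf(
    strain_target_pct: float,
    disorganization: float,
    seed: int,
    config: RunConfig = RunConfig(),
    image_size_px: tuple[int, int] = (96, 160),
    elongation_noise_mm: float = 0.05,
) -> tuple[float, float]:
    """Measured (strain, proximal PSF) for one synthetic participant.

    The ramp session is generated with a toe exponent solved so the true
    strain at 80 % TFmax equals ``strain_target_pct``; the proximal image is
    a speckle pattern at the given disorganization. Both outcomes are then
    *measured* by the full pipeline (mechanics reduction and kernel PSF), so
    measurement noise enters exactly as it would with real inputs.
    """
    from . import synthetic as syn

    toe = syn.toe_exponent_for_strain80(4399.0, 1338.0, 52.9, strain_target_pct)
    spec = syn.RampSpec(toe_exponent=toe, noise_sd=elongation_noise_mm, seed=seed)
    ramps = syn.gen_ramp_trials(spec)
    lo, hi = config.stiffness_band
    mechanics = mech.analyze_trials(
        ramps.trials, ramps.passive, ramps.flexion_trials,
        spec.moment_arm_mm, spec.rest_length_mm,
        118.0, 119.0, 118.5,
        n_levels=config.n_levels, lo=lo, hi=hi,
        gravity_poly_order=config.gravity_poly_order,
    )
    image = syn.gen_speckle_image(syn.SpeckleSpec(
        image_size_px=image_size_px, pixel_size_mm=(0.05, 0.05),
        band_spacing_mm=0.5, disorganization=disorganization,
        speckle_contrast=0.4, seed=seed + 1,
    ))
    from .image import PolygonROI
    roi = PolygonROI.rectangle(-0.5, -0.5, image_size_px[0] - 0.5, image_size_px[1] - 0.5)
    psf = micro.image_psf(image, roi, cutoff_mm_inv=config.psf_cutoff_mm_inv,
                          kernel_px=config.kernel_px, pad_to=config.pad_to,
                          stride_px=config.stride_px)
    return mechanics.strain80_pct, psf.mean_psf_mm_inv


def simulate_cohort_run(
    n: int = 16,
    seed: int = 0,
    coupled: bool = True,
    config: RunConfig = RunConfig(),
) -> st.CorrelationResult:
    """One synthetic cohort: strain-coupled (or decoupled) disorganization.

    Strain targets are drawn around the 6.6 +/- 1.2 % regime (truncated to
    the range the toe-law supports) and mapped linearly onto disorganization
    in [0.1, 0.9]. Under the null (``coupled=False``) the disorganization
    values are assigned from an independent draw, severing the link while
    keeping both marginals. Returns the normality-gated correlation between
    measured strain and measured proximal PSF.
    """
    rng = np.random.default_rng(seed)
    strains = np.clip(rng.normal(6.6, 1.2, n), 5.0, 9.8)
    basis = strains if coupled else np.clip(rng.normal(6.6, 1.2, n), 5.0, 9.8)
    disorg = 0.1 + 0.8 * (basis - 5.0) / 4.8
    seeds = rng.integers(0, 2 ** 31 - 1000, size=n)
    measured = [
        simulate_participant_strain_psf(s, d, int(sd), config)
        for s, d, sd in zip(strains, disorg, seeds)
    ]
    arr = np.asarray(measured)
    return st.correlate(arr[:, 0], arr[:, 1], config.alpha)


def power_study(
    n_cohorts: int = 100,
    n: int = 16,
    seed: int = 0,
    coupled: bool = True,
    alpha: float = 0.05,
    config: RunConfig = RunConfig(),
) -> dict:
    """Fraction of synthetic cohorts with a significant negative strain-PSF link."""
    rng = np.random.default_rng(seed)
    cohort_seeds = rng.integers(0, 2 ** 31 - 1000, size=n_cohorts)
    results = [simulate_cohort_run(n, int(s), coupled, config) for s in cohort_seeds]
    hits = sum(1 for r in results if r.p_value < alpha and r.estimate < 0)
    return {
        "n_cohorts": n_cohorts,
        "fraction_significant_negative": hits / n_cohorts,
        "mean_estimate": float(np.mean([r.estimate for r in results])),
        "results": results,
    }
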