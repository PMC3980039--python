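"""Forward simulator for FS-MMTT trial datasets.

Generates two-visit, multi-arm trials with the statistical structure the
analysis pipeline assumes: meal-driven glucose excursions from diabetic
fasting levels, insulin secretion from a known dose-response x potentiation
+ rate-component truth, plasma C-peptide through population two-compartment
kinetics, plasma insulin through single-compartment kinetics with the
hepatic extraction folded into the truth clearance, and urinary glucose
excretion from a renal threshold model (excretion rate proportional to
glucose above the threshold — the mechanism an SGLT2 inhibitor shifts).

Measurement noise is multiplicative log-normal with percent SDs matching
the assay errors the analysis targets (1 % glucose, 4 % C-peptide; insulin
is not assay-characterised in the source studies, 6 % is the default).

One global seed expands into per-subject substreams through
``numpy.random.SeedSequence(seed, spawn_key=(arm, subject, stream))`` so
growing the trial does not reshuffle existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .kinetics import kinetic_parameters, simulate_cpeptide
from .profiles import SCHEDULE, MealSpec, MmttProfile, body_surface_area
from .secretion import DoseResponse

__all__ = [
    "SubjectTruth",
    "ArmEffect",
    "TrialConfig",
    "SimulatedTrial",
    "draw_subject_truth",
    "simulate_glucose_profile",
    "simulate_subject",
    "simulate_trial",
    "simulate_uge",
    "truth_indices",
    "load_trial_config",
]

_FINE_STEP = 1.0  # min, internal simulation grid
_PULSE_SHAPE = 2.0  # gamma-like exponent of the meal glucose pulse
_PULSE_PEAK_MIN = 45.0  # time of the glucose peak
_INSULIN_VOLUME = 7.0  # l/m^2, single-compartment insulin distribution


#: glucose knots (mmol/l) of the true piecewise-linear dose-response; the
#: 7-17 mmol/l segment covers the glucose range a diabetic MMTT visits, with
#: flattening toward basal secretion below 7 and steepening above 17
_TRUTH_KNOTS = np.array([4.0, 7.0, 17.0, 21.0])
#: per-segment slope multipliers (convex overall)
_TRUTH_SLOPE_MULT = np.array([0.6, 1.0, 1.4])


@dataclass
class SubjectTruth:
    """Ground-truth physiology for one simulated subject.

    The true dose-response is piecewise linear in glucose (knots at 4, 7, 17
    and 21 mmol/l, mildly convex slope profile around ``glucose_slope``);
    the true potentiation factor is a unit-mean linear ramp parameterised by
    its end-to-start ratio. Both lie inside the class the fitting model can
    represent, so noise-free recovery is limited only by the estimation
    procedure, not by representation error.
    """

    fasting_glucose: float  # mmol/l
    glucose_amplitude: float  # mmol/l peak excursion for a 100 g meal
    isr_at_9: float  # pmol min^-1 m^-2, dose-response at 9 mmol/l
    glucose_slope: float  # pmol min^-1 m^-2 (mmol/l)^-1 over 7-17 mmol/l
    potentiation_ratio: float  # P(180)/P(0)
    rate_sensitivity: float  # pmol m^-2 (mmol/l)^-1
    insulin_clearance: float  # l min^-1 m^-2
    renal_threshold: float  # mmol/l
    renal_rate: float  # l/min, excretion per mmol/l above threshold
    weight: float
    height: float
    age: float
    sex: str
    hba1c_high: bool = False
    diabetic: bool = True

    def __post_init__(self) -> None:
        if not (4.0 <= self.renal_threshold <= 14.0):
            raise ValueError("renal threshold outside [4, 14] mmol/l")
        for name in ("fasting_glucose", "isr_at_9", "insulin_clearance", "renal_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def dose_response(self) -> DoseResponse:
        """True piecewise-linear f(G), anchored at ISR@9 on the central
        segment (slope = glucose_slope between 7 and 17 mmol/l)."""
        slopes = self.glucose_slope * _TRUTH_SLOPE_MULT
        k = _TRUTH_KNOTS
        values = np.empty(k.size)
        values[1] = self.isr_at_9 - slopes[1] * (9.0 - k[1])  # f(7)
        values[0] = values[1] - slopes[0] * (k[1] - k[0])
        values[2] = values[1] + slopes[1] * (k[2] - k[1])
        values[3] = values[2] + slopes[2] * (k[3] - k[2])
        return DoseResponse(k, np.clip(values, 1.0, None))

    def potentiation(self, t: np.ndarray) -> np.ndarray:
        """True P(t): linear ramp with P(180)/P(0) = potentiation_ratio and
        exact unit time-average over [0, 180]; P(t<0) = P(0)."""
        t = np.clip(np.asarray(t, dtype=float), 0.0, 180.0)
        rho = self.potentiation_ratio
        beta = 2.0 * (rho - 1.0) / (rho + 1.0)
        return 1.0 + beta * (t / 180.0 - 0.5)

    def bsa(self) -> float:
        return body_surface_area(self.weight, self.height)


@dataclass(frozen=True)
class ArmEffect:
    """Endpoint treatment effects applied to a subject's truth."""

    glucose_lowering_frac: float = 0.0  # fractional drop of fasting level and excursion
    threshold_shift: float = 0.0  # mmol/l added to the renal threshold
    secretion_multiplier: float = 1.0  # scales the dose-response f (GS and ISR@9 alike)


@dataclass
class TrialConfig:
    arms: dict = field(
        default_factory=lambda: {
            "placebo": ArmEffect(),
            "treated": ArmEffect(
                glucose_lowering_frac=0.12, threshold_shift=-5.5, secretion_multiplier=1.15
            ),
        }
    )
    n_per_arm: int = 40
    noise_glucose_pct: float = 1.0
    noise_cpeptide_pct: float = 4.0
    noise_insulin_pct: float = 6.0
    seed: int = 0
    schedule: tuple = SCHEDULE
    meal: MealSpec = field(default_factory=MealSpec)

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if min(self.noise_glucose_pct, self.noise_cpeptide_pct, self.noise_insulin_pct) < 0:
            raise ValueError("noise SDs must be non-negative")


def load_trial_config(path) -> TrialConfig:
    """Read a scenario config from YAML (keys mirror TrialConfig fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "arms" in raw:
        raw["arms"] = {name: ArmEffect(**(eff or {})) for name, eff in raw["arms"].items()}
    if "meal" in raw:
        raw["meal"] = MealSpec(**raw["meal"])
    if "schedule" in raw:
        raw["schedule"] = tuple(raw["schedule"])
    return TrialConfig(**raw)


# ---------------------------------------------------------------------------
# population draws — defaults emulate the trials' FS-MMTT subpopulations
# (fasting glucose ~9-10 mmol/l; glucose sensitivity ~25-60, ISR@9 ~100-200,
# rate sensitivity ~200-600 in the units above)
# ---------------------------------------------------------------------------

def draw_subject_truth(rng: np.random.Generator) -> SubjectTruth:
    def lognorm(median, sigma, lo, hi):
        return float(np.clip(median * np.exp(sigma * rng.standard_normal()), lo, hi))

    def norm(mu, sd, lo, hi):
        return float(np.clip(mu + sd * rng.standard_normal(), lo, hi))

    gs = lognorm(35.0, 0.35, 15.0, 90.0)
    # ISR@9 scales with glucose sensitivity (better-preserved beta cell
    # function raises both), keeping the dose-response positive at low glucose
    return SubjectTruth(
        fasting_glucose=norm(9.5, 1.2, 7.0, 13.0),
        glucose_amplitude=norm(4.0, 0.8, 2.0, 7.0),
        isr_at_9=gs * lognorm(4.0, 0.20, 2.5, 6.5),
        glucose_slope=gs,
        potentiation_ratio=lognorm(1.5, 0.20, 1.05, 2.2),
        rate_sensitivity=lognorm(350.0, 0.50, 100.0, 900.0),
        insulin_clearance=norm(1.2, 0.2, 0.7, 2.0),
        renal_threshold=norm(10.0, 0.8, 7.0, 13.0),
        renal_rate=norm(0.10, 0.015, 0.05, 0.15),
        weight=norm(90.0, 15.0, 55.0, 140.0),
        height=norm(170.0, 10.0, 150.0, 195.0),
        age=norm(57.0, 8.0, 30.0, 75.0),
        sex="M" if rng.random() < 0.6 else "F",
        hba1c_high=bool(rng.random() < 0.12),
    )


def _apply_effect(truth: SubjectTruth, effect: ArmEffect) -> SubjectTruth:
    frac = 1.0 - effect.glucose_lowering_frac
    return replace(
        truth,
        fasting_glucose=truth.fasting_glucose * frac,
        glucose_amplitude=truth.glucose_amplitude * frac,
        renal_threshold=float(np.clip(truth.renal_threshold + effect.threshold_shift, 4.0, 14.0)),
        isr_at_9=truth.isr_at_9 * effect.secretion_multiplier,
        glucose_slope=truth.glucose_slope * effect.secretion_multiplier,
    )


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_glucose_profile(truth: SubjectTruth, meal: MealSpec, schedule) -> np.ndarray:
    """Noise-free plasma glucose at the ``schedule`` times: fasting level
    before the meal, then a smooth unimodal (gamma-like) excursion peaking
    near 45 min and decaying toward baseline by 180 min, with amplitude
    scaled by carbohydrate content."""
    t = np.asarray(schedule, dtype=float)
    x = np.clip(t, 0.0, None) / _PULSE_PEAK_MIN
    pulse = np.where(
        t <= 0, 0.0, x**_PULSE_SHAPE * np.exp(_PULSE_SHAPE * (1.0 - x))
    )
    amp = truth.glucose_amplitude * meal.carbohydrate_g / 100.0
    return truth.fasting_glucose + amp * pulse


def _true_isr(truth: SubjectTruth, meal: MealSpec, tt: np.ndarray) -> np.ndarray:
    g = simulate_glucose_profile(truth, meal, tt)
    dg = np.gradient(g, tt)
    f = truth.dose_response()
    isr = truth.potentiation(tt) * f(g) + truth.rate_sensitivity * np.clip(dg, 0.0, None)
    return np.clip(isr, 0.0, None)


def simulate_uge(truth: SubjectTruth, meal: MealSpec) -> float:
    """Urinary glucose over [0, 180] min, grams: excretion rate
    renal_rate * max(G - threshold, 0), threshold in mmol/l."""
    tt = np.arange(0.0, 180.0 + _FINE_STEP / 2, _FINE_STEP)
    g = simulate_glucose_profile(truth, meal, tt)
    excess = np.clip(g - truth.renal_threshold, 0.0, None)
    mmol = truth.renal_rate * np.trapezoid(excess, tt)
    return float(mmol * 0.18016)


def simulate_subject(
    truth: SubjectTruth,
    config: TrialConfig,
    seed,
    subject_id: str = "S000",
    visit: str = "baseline",
    arm: str = "simulated",
) -> MmttProfile:
    """One observed MMTT profile for a subject with known truth.

    Glucose noise is applied to the measured samples only; C-peptide and
    insulin are generated from the noise-free glucose (the physiology does
    not see assay error) and then perturbed. ``seed`` may be an int or a
    ``numpy.random.SeedSequence``.
    """
    rng = np.random.default_rng(seed)
    meal = config.meal
    schedule = np.asarray(config.schedule, dtype=float)
    tt = np.arange(-15.0, 180.0 + _FINE_STEP / 2, _FINE_STEP)

    bsa = truth.bsa()
    kin = kinetic_parameters(truth.age, truth.sex, bsa, truth.diabetic)
    isr = _true_isr(truth, meal, tt)
    c0 = isr[0] * bsa / (kin.k01 * kin.volume * 1000.0)
    cp_fine = simulate_cpeptide(isr, tt, kin, bsa, c0)

    # single-compartment plasma insulin; hepatic extraction folded into the
    # truth clearance, so insulin AUC ~ total secretion / clearance
    k = truth.insulin_clearance / _INSULIN_VOLUME
    h = _FINE_STEP
    e = np.exp(-k * h)
    phi1 = (1 - e) / k
    phi2 = (h - phi1) / k
    u = isr / _INSULIN_VOLUME
    ins_fine = np.empty_like(u)
    ins_fine[0] = isr[0] / truth.insulin_clearance
    for n in range(1, tt.size):
        du = (u[n] - u[n - 1]) / h
        ins_fine[n] = e * ins_fine[n - 1] + phi1 * u[n - 1] + phi2 * du

    def sample(fine: np.ndarray) -> np.ndarray:
        return np.interp(schedule, tt, fine)

    def noisy(values: np.ndarray, pct: float) -> np.ndarray:
        if pct == 0:
            return values.copy()
        return values * np.exp(pct / 100.0 * rng.standard_normal(values.size))

    glucose = noisy(simulate_glucose_profile(truth, meal, schedule), config.noise_glucose_pct)
    cpeptide = noisy(sample(cp_fine), config.noise_cpeptide_pct)
    insulin = noisy(sample(ins_fine), config.noise_insulin_pct)

    return MmttProfile(
        subject_id=subject_id,
        visit=visit,
        arm=arm,
        times=schedule,
        glucose=glucose,
        insulin=insulin,
        cpeptide=cpeptide,
        uge_0_3h=simulate_uge(truth, meal),
        weight=truth.weight,
        height=truth.height,
        age=truth.age,
        sex=truth.sex,
        diabetic=truth.diabetic,
    )


def truth_indices(truth: SubjectTruth, meal: MealSpec, schedule=SCHEDULE) -> dict:
    """Ground-truth values of the indices the pipeline estimates: glucose
    sensitivity as the chord slope of the true f over the noise-free observed
    glucose range, ISR@9, rate sensitivity, total secretion and clearance."""
    g = simulate_glucose_profile(truth, meal, np.asarray(schedule, float))
    g_min, g_max = float(g.min()), float(g.max())
    f = truth.dose_response()
    tt = np.arange(0.0, 180.0 + _FINE_STEP / 2, _FINE_STEP)
    isr = _true_isr(truth, meal, tt)
    return dict(
        glucose_sensitivity=float((f(g_max) - f(g_min)) / (g_max - g_min)),
        isr_at_9=float(f(9.0)),
        rate_sensitivity=truth.rate_sensitivity,
        total_secretion=float(np.trapezoid(isr, tt)) / 1000.0,
        insulin_clearance=truth.insulin_clearance,
        uge_0_3h=simulate_uge(truth, meal),
        fasting_glucose=truth.fasting_glucose,
        glucose_range=(g_min, g_max),
    )


@dataclass
class SimulatedTrial:
    profiles: list  # MmttProfile, baseline + endpoint per subject
    truth: pd.DataFrame  # one row per subject-visit, never read by the pipeline


def simulate_trial(config: TrialConfig) -> SimulatedTrial:
    """Simulate a two-visit multi-arm trial.

    Baseline visits draw from the untreated population; endpoint visits
    apply the arm's configured effects to the same subject truth. Returns
    the observable profiles and a hidden truth table for recovery scoring.
    """
    profiles: list[MmttProfile] = []
    rows = []
    for ai, (arm, effect) in enumerate(config.arms.items()):
        for si in range(config.n_per_arm):
            sid = f"{arm[:3].upper()}{si:03d}"
            truth_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(ai, si, 0))
            )
            truth = draw_subject_truth(truth_rng)
            for vi, visit in enumerate(("baseline", "endpoint")):
                vtruth = truth if visit == "baseline" else _apply_effect(truth, effect)
                noise_seed = np.random.SeedSequence(config.seed, spawn_key=(ai, si, 1 + vi))
                profiles.append(
                    simulate_subject(vtruth, config, noise_seed, sid, visit, arm)
                )
                idx = truth_indices(vtruth, config.meal, config.schedule)
                idx.pop("glucose_range")
                rows.append(
                    dict(subject_id=sid, arm=arm, visit=visit,
                         hba1c_high=truth.hba1c_high, **idx)
                )
    return SimulatedTrial(profiles=profiles, truth=pd.DataFrame(rows))
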