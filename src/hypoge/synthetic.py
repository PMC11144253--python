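"""Synthetic T1DM cohorts: 5-minute multichannel traces with controllable
hypoglycemia prevalence, sensor dropouts, and optional planted predictive
structure.

The generator is phenomenological, not a physiological simulator.  Glucose
is a mean-reverting baseline plus meal excursion kernels, minus an
activity-coupled decline, plus autocorrelated (AR(1)) noise, clamped to
[40, 400] mg/dL; heart rate is a circadian baseline plus activity bursts;
steps are bursty counts; calories are basal expenditure plus a per-step
coefficient.  The baseline is auto-tuned by bisection so that the fraction
of time below 70 mg/dL hits a per-patient prevalence target — the study
cohort spans patients from under 4% to over 20% of time in hypoglycemia.

Missing values are inserted in contiguous stretches (sensor dropouts
affecting all channels at once), which is how CGM data actually fails and
what exercises the discard-incomplete-windows rule downstream.

``generate_cohort_with_planted_rule`` additionally makes the hypoglycemia
labels at a chosen horizon consistent with a known, grammar-expressible
rule by nudging future glucose across the 70 mg/dL boundary wherever the
rule fires; the rule is returned as the recovery target for
identifiability experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expressions import RuleModel
from .glucodata import (
    GRID_MINUTES,
    HYPO_THRESHOLD_MGDL,
    PatientSeries,
    build_windows,
)

__all__ = [
    "DynamicsParams",
    "SyntheticConfig",
    "generate_patient",
    "generate_cohort",
    "generate_cohort_with_planted_rule",
    "cohort_manifest",
]

SAMPLES_PER_DAY = 24 * 60 // GRID_MINUTES  # 288


@dataclass
class DynamicsParams:
    """Shape parameters of the simulated physiology (units in names)."""

    meal_times_h: tuple[float, ...] = (8.0, 13.0, 20.0)
    meal_jitter_h: float = 0.75
    meal_amp_mean: float = 70.0  # mg/dL peak excursion
    meal_amp_sd: float = 15.0
    meal_rise_min: float = 30.0
    meal_decay_min: float = 90.0
    glucose_noise_sd: float = 20.0  # stationary AR(1) sd, mg/dL
    glucose_corr_min: float = 45.0  # noise correlation time
    glucose_circadian_amp: float = 8.0
    glucose_trend_mgdl_per_day: float = 0.0  # slow drift in control quality
    hr_base: float = 70.0  # bpm
    hr_circadian_amp: float = 8.0
    hr_noise_sd: float = 3.0
    hr_per_step: float = 0.05  # bpm per step/5min
    bursts_per_day: float = 3.0
    burst_mean_min: float = 30.0
    burst_steps_mean: float = 400.0  # steps per 5-min sample in a bout
    step_glucose_drop: float = 0.04  # mg/dL per step, spread over the decay
    activity_decay_min: float = 40.0
    cal_basal: float = 6.0  # kcal per 5 min at rest
    cal_per_step: float = 0.04
    cal_noise_sd: float = 0.3


@dataclass
class SyntheticConfig:
    n_patients: int = 24
    days_per_patient: float = 14.0
    hypo_prevalence_target: float = 0.10
    prevalence_range: tuple[float, float] = (0.03, 0.22)
    missing_rate: float = 0.05
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    planted_rule: RuleModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days_per_patient <= 0:
            raise ValueError("days_per_patient must be positive")
        if not (0.0 <= self.missing_rate < 0.5):
            raise ValueError("missing_rate must be in [0, 0.5)")


def _kernel_profile(n: int, dyn: DynamicsParams) -> np.ndarray:
    """Unit meal excursion: linear rise then exponential decay."""
    rise = max(1, int(round(dyn.meal_rise_min / GRID_MINUTES)))
    decay_tau = max(1e-9, dyn.meal_decay_min / GRID_MINUTES)
    length = rise + int(6 * decay_tau) + 1
    k = np.empty(min(length, n))
    for i in range(len(k)):
        if i < rise:
            k[i] = (i + 1) / rise
        else:
            k[i] = math.exp(-(i - rise) / decay_tau)
    return k


def _simulate_channels(
    n: int, dyn: DynamicsParams, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Deterministic-shape components for one patient (glucose sans baseline)."""
    t_idx = np.arange(n)
    hour = (t_idx * GRID_MINUTES / 60.0) % 24.0

    # --- activity: bursts of walking/exercise during waking hours
    steps = np.zeros(n)
    days = int(np.ceil(n / SAMPLES_PER_DAY))
    n_bursts = rng.poisson(dyn.bursts_per_day * days)
    for _ in range(n_bursts):
        day = rng.integers(days)
        start_h = rng.uniform(7.0, 22.0)
        start = int(day * SAMPLES_PER_DAY + start_h * 60 / GRID_MINUTES)
        length = max(1, rng.geometric(GRID_MINUTES / dyn.burst_mean_min))
        intensity = rng.gamma(4.0, dyn.burst_steps_mean / 4.0)
        end = min(n, start + length)
        if start < n:
            steps[start:end] += rng.poisson(intensity, size=end - start)
    # light ambient movement during the day
    daytime = (hour >= 7.5) & (hour <= 23.0)
    casual = rng.random(n) < 0.15
    steps[daytime & casual] += rng.integers(5, 80, size=int((daytime & casual).sum()))

    # --- glucose shape: circadian + meals - activity + AR(1) noise
    circadian = dyn.glucose_circadian_amp * np.sin(2 * np.pi * (hour - 4.0) / 24.0)
    meals = np.zeros(n)
    kernel = _kernel_profile(n, dyn)
    for day in range(days):
        for mt in dyn.meal_times_h:
            when = mt + rng.normal(0.0, dyn.meal_jitter_h)
            start = int(day * SAMPLES_PER_DAY + when * 60 / GRID_MINUTES)
            amp = max(20.0, rng.normal(dyn.meal_amp_mean, dyn.meal_amp_sd))
            if 0 <= start < n:
                end = min(n, start + len(kernel))
                meals[start:end] += amp * kernel[: end - start]
    # exercise pulls glucose down with a lag/decay
    act_tau = max(1e-9, dyn.activity_decay_min / GRID_MINUTES)
    act_kernel = np.exp(-np.arange(int(6 * act_tau) + 1) / act_tau)
    activity_drop = dyn.step_glucose_drop * np.convolve(steps, act_kernel)[:n]
    rho = math.exp(-GRID_MINUTES / dyn.glucose_corr_min)
    eps = rng.normal(0.0, dyn.glucose_noise_sd * math.sqrt(1 - rho**2), size=n)
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, dyn.glucose_noise_sd)
    for i in range(1, n):
        noise[i] = rho * noise[i - 1] + eps[i]
    trend = dyn.glucose_trend_mgdl_per_day * t_idx / SAMPLES_PER_DAY
    gluc_shape = circadian + meals - activity_drop + noise + trend

    # --- heart rate and calories, coupled to activity
    hr = (
        dyn.hr_base
        + dyn.hr_circadian_amp * np.sin(2 * np.pi * (hour - 14.0) / 24.0)
        + dyn.hr_per_step * steps
        + rng.normal(0.0, dyn.hr_noise_sd, size=n)
    )
    hr = np.clip(hr, 40.0, 200.0)
    cal = (
        dyn.cal_basal
        + dyn.cal_per_step * steps
        + rng.normal(0.0, dyn.cal_noise_sd, size=n)
    )
    cal = np.clip(cal, 0.0, None)
    return {"gluc_shape": gluc_shape, "hr": hr, "steps": steps, "cal": cal}


def _tune_baseline(gluc_shape: np.ndarray, target: float) -> float:
    """Bisect the baseline so the clamped trace spends ``target`` below 70.

    Prevalence is monotone non-increasing in the baseline, so bisection on
    [0, 400] converges to the achievable prevalence closest to the target.
    """

    def prevalence(b: float) -> float:
        g = np.clip(b + gluc_shape, 40.0, 400.0)
        return float((g < HYPO_THRESHOLD_MGDL).mean())

    lo, hi = 0.0, 400.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) > target:
            lo = mid
        else:
            hi = mid
    return hi if abs(prevalence(hi) - target) <= abs(prevalence(lo) - target) else lo


def _insert_dropouts(
    df: pd.DataFrame, missing_rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    if missing_rate <= 0:
        return df
    n = len(df)
    mean_block = 8  # samples, i.e. 40-minute dropouts on average
    n_blocks = rng.poisson(missing_rate * n / mean_block)
    mask = np.zeros(n, dtype=bool)
    for _ in range(n_blocks):
        start = int(rng.integers(n))
        length = rng.geometric(1.0 / mean_block)
        mask[start : min(n, start + length)] = True
    out = df.copy()
    out.loc[out.index[mask]] = np.nan
    return out


def generate_patient(
    cfg: SyntheticConfig,
    patient_index: int = 0,
    prevalence_target: float | None = None,
    baseline_override: float | None = None,
) -> PatientSeries:
    """One fully seed-reproducible synthetic patient.

    ``baseline_override`` skips the prevalence auto-tuning and fixes the
    glucose baseline directly (lowering it monotonically raises the time in
    hypoglycemia).
    """
    rng = np.random.default_rng([cfg.seed, patient_index])
    n = int(round(cfg.days_per_patient * SAMPLES_PER_DAY))
    if n <= 0:
        raise ValueError("nonpositive series length")
    target = (
        cfg.hypo_prevalence_target if prevalence_target is None else prevalence_target
    )
    parts = _simulate_channels(n, cfg.dynamics, rng)
    if baseline_override is None:
        base = _tune_baseline(parts["gluc_shape"], target)
    else:
        base = baseline_override
    gluc = np.clip(base + parts["gluc_shape"], 40.0, 400.0)
    index = pd.date_range("2024-01-01", periods=n, freq=f"{GRID_MINUTES}min")
    df = pd.DataFrame(
        {
            "gluc": gluc,
            "hr": parts["hr"],
            "steps": parts["steps"],
            "cal": parts["cal"],
        },
        index=index,
    )
    df = _insert_dropouts(df, cfg.missing_rate, rng)
    return PatientSeries(patient_id=f"SYN{patient_index + 1:03d}", data=df)


def generate_cohort(cfg: SyntheticConfig) -> list[PatientSeries]:
    """A cohort whose per-patient hypoglycemia prevalence spans the study
    envelope (under 4% to over 20% of time, spread across patients)."""
    lo, hi = cfg.prevalence_range
    targets = np.linspace(lo, hi, cfg.n_patients) if cfg.n_patients > 1 else [lo]
    # deterministic shuffle so prevalence is not ordered by patient id
    order = np.random.default_rng([cfg.seed, 999_983]).permutation(cfg.n_patients)
    return [
        generate_patient(cfg, i, prevalence_target=float(targets[order[i]]))
        for i in range(cfg.n_patients)
    ]


def cohort_manifest(cohort: list[PatientSeries]) -> pd.DataFrame:
    """Achieved prevalence and completeness per patient, recomputed from data."""
    rows = []
    for series in cohort:
        g = series.data["gluc"]
        rows.append(
            {
                "patient_id": series.patient_id,
                "n_samples": len(series.data),
                "missing_fraction": float(series.data["gluc"].isna().mean()),
                "hypo_prevalence": float((g.dropna() < HYPO_THRESHOLD_MGDL).mean()),
            }
        )
    return pd.DataFrame(rows)


def generate_cohort_with_planted_rule(
    cfg: SyntheticConfig,
    rule: RuleModel | None = None,
    ph: int = 30,
    max_passes: int = 6,
) -> tuple[list[PatientSeries], RuleModel]:
    """A cohort whose hypoglycemia labels at horizon ``ph`` follow ``rule``.

    Wherever the rule fires on a complete window, the glucose value at
    ``t + ph`` is nudged below 70 mg/dL (and above it where the rule does
    not fire).  Because nudged values re-enter later windows as history,
    nudging is iterated to a fixed point; rules over lagged glucose can
    cascade and may need several passes.  Raises if the rule never fires or
    if at least 95% label/rule consistency cannot be reached.
    """
    rule = rule or cfg.planted_rule
    if rule is None:
        raise ValueError("no planted rule given")
    cohort = generate_cohort(cfg)
    nudge_rng = np.random.default_rng([cfg.seed, 424_243])
    total_fires = 0
    for series in cohort:
        for _ in range(max_passes):
            ds = build_windows(series, ph)
            if len(ds) == 0:
                break
            fire = rule.predict(ds.arrays())
            total_fires += int(fire.sum())
            target_times = ds.X.index + pd.Timedelta(minutes=ph)
            targets = series.data.loc[target_times, "gluc"].to_numpy()
            want_low = fire & (targets >= HYPO_THRESHOLD_MGDL)
            want_high = ~fire & (targets < HYPO_THRESHOLD_MGDL)
            if not want_low.any() and not want_high.any():
                break
            g = series.data["gluc"].copy()
            g.loc[target_times[want_low]] = nudge_rng.uniform(
                50.0, 65.0, size=int(want_low.sum())
            )
            g.loc[target_times[want_high]] = nudge_rng.uniform(
                85.0, 140.0, size=int(want_high.sum())
            )
            series.data["gluc"] = g
    if total_fires == 0:
        raise ValueError(
            "planted rule never fires on the generated cohort; widen its"
            " thresholds or adjust the dynamics parameters"
        )
    consistency = planted_consistency(cohort, rule, ph)
    if consistency < 0.95:
        raise RuntimeError(
            f"planted labels only {consistency:.1%} consistent with the rule"
            " after nudging; the rule feeds back on its own inputs too"
            " strongly — prefer non-glucose predictors or fewer passes"
        )
    return cohort, rule


def planted_consistency(
    cohort: list[PatientSeries], rule: RuleModel, ph: int
) -> float:
    """Fraction of complete windows whose label matches the planted rule."""
    agree = 0
    total = 0
    for series in cohort:
        ds = build_windows(series, ph)
        if len(ds) == 0:
            continue
        fire = rule.predict(ds.arrays())
        agree += int((fire == ds.y).sum())
        total += len(ds)
    return agree / total if total else math.nan
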