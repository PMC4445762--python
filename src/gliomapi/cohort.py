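"""Virtual patients, noisy observation series, and virtual trials.

Everything downstream of the solver is exercised on synthetic cohorts:
patients are drawn from log-normal (D, ρ) distributions (positive and
right-skewed, like the clinical spread), "scanned" by simulating their
growth and reading the T1Gd/T2 threshold radii with additive measurement
noise, treated per arm, and followed to a fatal-size survival surrogate.
A seed fixes every random draw, so a trial is reproducible byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .calibration import RadiusObservation
from .errors import GliomaPIError
from .radiotherapy import RadiationPlan
from .resection import (
    DEFAULT_FATAL_RADIUS,
    ResectionEvent,
    resolve_margin,
    time_to_fatal_radius,
)
from .response import build_uvc, days_gained
from .solver import (
    Kinetics,
    SolverSettings,
    extract_radius,
    front_profile,
    simulate,
)

__all__ = ["CohortSpec", "SurvivalCurve", "TherapyArm", "sample_patients",
           "synthesize_observations", "kaplan_meier", "run_virtual_trial",
           "logrank_p_value"]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a virtual cohort.

    Kinetic rates are log-normal, parameterized by median and coefficient of
    variation (defaults span the diffuse-to-nodular clinical range; they are
    placeholders for population values published elsewhere, not measurements).
    Scans happen at ``scan_times`` (days from detection of a
    ``detection_radius`` T1Gd lesion) in both modalities, with additive
    Gaussian radius noise truncated at zero.
    """

    seed: int
    n: int = 20
    D_median: float = 10.0      # mm²/year
    D_cv: float = 1.0
    rho_median: float = 10.0    # 1/year
    rho_cv: float = 1.0
    K: float = 1e5              # cells/mm³
    noise_sd: float = 1.0       # mm
    scan_times: tuple = (0.0, 60.0, 120.0, 180.0)
    detection_radius: float = 15.0  # mm, T1Gd-equivalent

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if min(self.D_median, self.rho_median, self.K) <= 0:
            raise ValueError("distribution medians and K must be > 0")
        if self.D_cv < 0 or self.rho_cv < 0 or self.noise_sd < 0:
            raise ValueError("spreads must be >= 0")
        if len(self.scan_times) < 1:
            raise ValueError("need at least one scan time")


@dataclass
class SurvivalCurve:
    """Kaplan–Meier product-limit curve: step-wise, non-increasing from 1."""

    times: np.ndarray
    survival_probability: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival_probability = np.asarray(self.survival_probability, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=int)
        s = self.survival_probability
        if s.size == 0 or s[0] > 1.0 + 1e-12 or np.any(np.diff(s) > 1e-12):
            raise GliomaPIError("survival must start at <= 1 and be non-increasing")
        if np.any((s < -1e-12) | (s > 1 + 1e-12)):
            raise GliomaPIError("survival probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class TherapyArm:
    """One treatment strategy applied uniformly to an arm.

    ``resection_extent`` in {GTR, STR, biopsy, None}; ``radiation`` is a
    fraction schedule with its LQ parameters (times in days from detection).
    """

    name: str
    resection_extent: str | None = None
    resection_day: float = 0.0
    radiation: RadiationPlan | None = None


def _lognormal(rng, median: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, median)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=size)


def sample_patients(spec: CohortSpec) -> list[Kinetics]:
    """Draw the cohort's kinetics, reproducibly from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    D = _lognormal(rng, spec.D_median, spec.D_cv, spec.n)
    rho = _lognormal(rng, spec.rho_median, spec.rho_cv, spec.n)
    return [Kinetics(D=float(d), rho=float(r), K=spec.K) for d, r in zip(D, rho)]


def synthesize_observations(
    kinetics: Kinetics,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    f_t1: float = 0.8,
    f_t2: float = 0.16,
    settle: float = 120.0,
    patient_id: str | None = None,
) -> list[RadiusObservation]:
    """Emulate serial two-modality imaging of one virtual patient.

    The patient's growth is simulated from a wave-matched profile detected at
    ``spec.detection_radius`` (after a ``settle`` burn-in so the front is
    fully developed); T1Gd/T2 radii are read at the threshold level sets and
    perturbed with truncated Gaussian noise, resampling any draw that breaks
    radius >= 0 or T2 >= T1Gd.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    v_day = kinetics.velocity / 365.25
    span = settle + max(spec.scan_times)
    r_max = spec.detection_radius + v_day * span + 14 * kinetics.gradient_length + 10.0
    settings = SolverSettings.auto(kinetics, r_max=r_max)
    f0 = front_profile(kinetics, settings, spec.detection_radius, f_t1)
    snaps = simulate(kinetics, f0, span, settings,
                     snapshot_times=[settle + t for t in spec.scan_times])
    obs: list[RadiusObservation] = []
    for t, f in zip(spec.scan_times, snaps):
        r1 = extract_radius(f, f_t1)
        r2 = extract_radius(f, f_t2)
        n1, n2 = r1, r2
        if spec.noise_sd > 0:
            for _ in range(1000):
                n1 = r1 + rng.normal(0.0, spec.noise_sd)
                n2 = r2 + rng.normal(0.0, spec.noise_sd)
                if n1 >= 0 and n2 >= n1:
                    break
            else:  # pathological geometry; fall back to noiseless
                n1, n2 = r1, r2
        obs.append(RadiusObservation(t, "T1Gd", float(n1), patient_id))
        obs.append(RadiusObservation(t, "T2", float(n2), patient_id))
    return obs


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Product-limit survival estimate with right censoring.

    ``events[i]`` True means the endpoint occurred at ``times[i]``; False
    means the observation was censored there.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill().to_numpy()
    return SurvivalCurve(times=t, survival_probability=s, at_risk=at_risk)


def logrank_p_value(times_a, events_a, times_b, events_b) -> float:
    """Thin reporting utility: two-sample log-rank test p-value."""
    res = logrank_test(times_a, times_b, event_observed_A=events_a,
                       event_observed_B=events_b)
    return float(res.p_value)


def run_virtual_trial(
    spec: CohortSpec,
    arms: Sequence[TherapyArm],
    fatal_radius: float = DEFAULT_FATAL_RADIUS,
    horizon: float = 3650.0,
    post_scan_day: float = 75.0,
    uvc_mode: str = "simulated",
) -> dict:
    """Sample → simulate → treat → score → survival curves, one seed end to end.

    Every patient passes through every arm (matched design, isolating the
    therapy effect from between-patient kinetic spread).  Returns
    ``{"patients": DataFrame, "curves": {arm: SurvivalCurve}}``; the table
    has one row per patient × arm with (D, ρ, ρ/D, days_gained,
    time_to_fatal, censored).
    """
    if not arms:
        raise ValueError("need at least one arm")
    patients = sample_patients(spec)
    rows = []
    for i, kin in enumerate(patients):
        settings = SolverSettings.auto(
            kin, r_max=fatal_radius + 14 * kin.gradient_length + 10.0)
        initial = front_profile(kin, settings, spec.detection_radius, 0.8)
        anchor = RadiusObservation(0.0, "T1Gd", spec.detection_radius, f"vp{i:03d}")
        uvc = build_uvc(kin, anchor, horizon=max(post_scan_day * 2, 240.0),
                        mode=uvc_mode, settings=settings)
        for arm in arms:
            resection = None
            if arm.resection_extent is not None:
                resection = resolve_margin(initial, arm.resection_extent,
                                           time=arm.resection_day)
            surr = time_to_fatal_radius(
                kin, initial, fatal_radius=fatal_radius, settings=settings,
                resection=resection, radiation=arm.radiation, horizon=horizon)
            # post-treatment scan for the response score
            from .radiotherapy import _kill, surviving_fraction
            sim_events = {}
            if resection is not None:
                sim_events[resection.time] = \
                    lambda c, r=resection, g=initial: _resect_density(c, g, r)
            if arm.radiation is not None:
                for t, d in _clip_plan(arm.radiation, post_scan_day).fractions:
                    S = surviving_fraction(arm.radiation.alpha,
                                           arm.radiation.alpha_beta_ratio, d)
                    prev = sim_events.get(t)
                    if prev is None:
                        sim_events[t] = lambda c, S=S: _kill(c, kin.K, S)
                    else:
                        sim_events[t] = lambda c, S=S, p=prev: _kill(p(c), kin.K, S)
            treated = simulate(kin, initial, post_scan_day, settings,
                               events=sim_events or None)[-1]
            post = RadiusObservation(post_scan_day, "T1Gd",
                                     extract_radius(treated, 0.8), f"vp{i:03d}")
            dg = days_gained(uvc, post)
            rows.append({
                "patient_id": f"vp{i:03d}", "arm": arm.name,
                "D_mm2_per_year": kin.D, "rho_per_year": kin.rho,
                "rho_over_D_per_mm2": kin.rho_over_D,
                "days_gained": dg.dg,
                "time_to_fatal_days": surr.time_to_fatal,
                "censored": surr.censored,
            })
    table = pd.DataFrame(rows)
    curves = {
        arm.name: kaplan_meier(
            table.loc[table.arm == arm.name, "time_to_fatal_days"],
            ~table.loc[table.arm == arm.name, "censored"])
        for arm in arms
    }
    return {"patients": table, "curves": curves}


def _clip_plan(plan: RadiationPlan, t_max: float) -> RadiationPlan:
    kept = [(t, d) for t, d in plan.fractions if t <= t_max]
    if not kept:
        return RadiationPlan([], plan.alpha, plan.alpha_beta_ratio)
    return RadiationPlan(kept, plan.alpha, plan.alpha_beta_ratio)


def _resect_density(c: np.ndarray, template, event: ResectionEvent) -> np.ndarray:
    out = c.copy()
    out[template.grid <= event.margin_radius] = 0.0
    return out
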