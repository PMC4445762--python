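"""Untreated virtual control (UVC) and the Days Gained response score.

The calibrated model can simulate how a patient's tumor would have grown with
no therapy — the untreated virtual control.  Days Gained compares the first
post-treatment scan against that curve along the time axis: it is the number
of days of untreated growth the therapy deflected.  A post-treatment radius
equal to the UVC prediction scores 0; a radius the UVC had already reached
long ago scores large and positive; a tumor that outgrew its UVC scores
negative (hyper-progression — permitted and reported, not an error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import RadiusObservation
from .errors import GliomaPIError
from .solver import (
    Kinetics,
    SolverSettings,
    extract_radius,
    front_profile,
    simulate,
)
from .units import DAYS_PER_YEAR

__all__ = ["UVCTrajectory", "DaysGainedScore", "build_uvc", "days_gained",
           "classify_response"]


@dataclass
class UVCTrajectory:
    """Model-predicted untreated radius-versus-time curve.

    Anchored at a pre-treatment observation; radii are T1Gd-equivalent mm.
    The curve is non-decreasing and its asymptotic slope is the model
    velocity 2·sqrt(Dρ).
    """

    times: np.ndarray
    radii: np.ndarray
    anchor: RadiusObservation
    kinetics: Kinetics

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.times.size < 2 or self.times.size != self.radii.size:
            raise GliomaPIError("UVC needs matching times/radii arrays (>= 2 points)")
        if np.any(np.diff(self.times) <= 0):
            raise GliomaPIError("UVC times must be strictly increasing")
        if np.any(np.diff(self.radii) < -1e-9):
            raise GliomaPIError("UVC radii must be non-decreasing")

    def radius_at(self, t: float) -> float:
        """Linearly interpolated UVC radius; extrapolates with the end slopes."""
        if t <= self.times[0]:
            return float(self.radii[0])
        if t >= self.times[-1]:
            slope = (self.radii[-1] - self.radii[-2]) / (self.times[-1] - self.times[-2])
            return float(self.radii[-1] + slope * (t - self.times[-1]))
        return float(np.interp(t, self.times, self.radii))

    def time_at_radius(self, radius: float) -> float:
        """Earliest time the UVC reaches ``radius`` (linear interpolation;
        linear extrapolation beyond the horizon with the final slope)."""
        if radius <= self.radii[0]:
            return float(self.times[0])
        if radius > self.radii[-1]:
            slope = (self.radii[-1] - self.radii[-2]) / (self.times[-1] - self.times[-2])
            return float(self.times[-1] + (radius - self.radii[-1]) / slope)
        idx = int(np.searchsorted(self.radii, radius, side="left"))
        r0, r1 = self.radii[idx - 1], self.radii[idx]
        t0, t1 = self.times[idx - 1], self.times[idx]
        if r1 == r0:
            return float(t0)
        return float(t0 + (radius - r0) / (r1 - r0) * (t1 - t0))


@dataclass
class DaysGainedScore:
    """Days Gained: dg = post-scan date − date the UVC reached that size."""

    dg: float
    post_obs: RadiusObservation
    uvc_time_at_radius: float
    saturated: bool = False      # post radius below the UVC's anchor radius
    extrapolated: bool = False   # post radius beyond the UVC horizon

    def __post_init__(self) -> None:
        if not math.isclose(self.dg, self.post_obs.t - self.uvc_time_at_radius,
                            rel_tol=0, abs_tol=1e-9):
            raise GliomaPIError("dg must equal post_obs.t - uvc_time_at_radius")


def build_uvc(
    kinetics: Kinetics,
    anchor: RadiusObservation,
    horizon: float,
    mode: str = "simulated",
    settings: SolverSettings | None = None,
    n_points: int = 200,
    threshold_fraction: float = 0.8,
) -> UVCTrajectory:
    """Simulate future untreated growth anchored at a pre-treatment scan.

    ``simulated`` runs the reaction–diffusion model from a traveling-wave
    profile matched to the anchor radius; ``linear`` uses the asymptotic
    straight line r(t) = r₀ + 2·sqrt(Dρ)·(t − t₀).  ``horizon`` is in days
    past the anchor time.
    """
    if anchor.radius <= 0:
        raise GliomaPIError("UVC anchor radius must be > 0")
    if horizon <= 0:
        raise GliomaPIError("UVC horizon must be > 0")
    if mode == "linear":
        times = anchor.t + np.linspace(0.0, horizon, n_points)
        v_day = kinetics.velocity / DAYS_PER_YEAR
        radii = anchor.radius + v_day * (times - anchor.t)
    elif mode == "simulated":
        if settings is None:
            r_max = anchor.radius + kinetics.velocity / DAYS_PER_YEAR * horizon + \
                12 * kinetics.gradient_length + 10.0
            settings = SolverSettings.auto(kinetics, r_max=r_max)
        if anchor.radius >= settings.r_max:
            raise GliomaPIError("anchor radius exceeds the solver domain")
        f0 = front_profile(kinetics, settings, anchor.radius,
                           threshold_fraction, time=anchor.t)
        # sample on the solver's time grid so stored times match snapshots
        every = max(1, round(horizon / (n_points * settings.dt)))
        rel = np.arange(1, int(horizon / settings.dt) + 1, every) * settings.dt
        snaps = simulate(kinetics, f0, horizon, settings, snapshot_times=list(rel))
        times = np.concatenate(([anchor.t], [f.time for f in snaps]))
        radii = np.empty_like(times)
        radii[0] = extract_radius(f0, threshold_fraction)
        radii[1:] = [extract_radius(f, threshold_fraction) for f in snaps]
        radii = np.maximum.accumulate(radii)  # remove sub-dr interpolation dips
    else:
        raise ValueError(f"unknown UVC mode {mode!r}")
    return UVCTrajectory(times=times, radii=radii, anchor=anchor, kinetics=kinetics)


def days_gained(uvc: UVCTrajectory, post_obs: RadiusObservation) -> DaysGainedScore:
    """Score a post-treatment scan against the untreated virtual control.

    dg = post_obs.t − t*, where t* is the earliest (interpolated) time the
    UVC reaches the post-treatment radius.  A radius smaller than the UVC's
    starting radius saturates at t* = anchor time (dg capped at the elapsed
    time, flagged); a radius beyond the UVC horizon extrapolates the final
    slope and typically yields a negative score (flagged).
    """
    if post_obs.radius < 0:
        raise GliomaPIError("post-treatment radius must be >= 0")
    if post_obs.t < uvc.times[0] or post_obs.t > uvc.times[-1]:
        raise GliomaPIError("post-treatment scan falls outside the UVC window")
    saturated = post_obs.radius < uvc.radii[0]
    extrapolated = post_obs.radius > uvc.radii[-1]
    t_star = uvc.time_at_radius(post_obs.radius)
    return DaysGainedScore(
        dg=post_obs.t - t_star,
        post_obs=post_obs,
        uvc_time_at_radius=t_star,
        saturated=bool(saturated),
        extrapolated=bool(extrapolated),
    )


def classify_response(score: DaysGainedScore, cutoff: float) -> str:
    """'responder' iff dg >= cutoff (boundary counts as response).

    The cutoff is deliberately a required argument: response thresholds are
    cohort- and endpoint-specific and no universal default exists.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return "responder" if score.dg >= cutoff else "non-responder"
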