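"""Surgical resection and time-to-fatal-size survival surrogates.

Resection removes the density inside a spherical margin.  Gross total
resection (GTR) takes the imageable T1Gd lesion; subtotal resection (STR) a
configurable fraction of that margin; biopsy removes nothing.  Because the
model places tumor cells far beyond any imaging margin, even a GTR leaves
the invasive tail, which regrows a front at the same asymptotic speed — the
"tip of the iceberg": the more diffuse the tumor (low ρ/D), the smaller the
fraction of cells the visible lesion contains and the less surgery helps.

Survival is surrogated by the time for the T1Gd-equivalent radius to reach a
uniform fatal size (default 35 mm), with censoring at the simulation horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GliomaPIError
from .radiotherapy import RadiationPlan, simulate_pirt
from .solver import (
    Kinetics,
    RadialField,
    SolverSettings,
    cell_volumes,
    extract_radius,
    simulate,
)

__all__ = ["ResectionEvent", "SurvivalSurrogate", "resolve_margin",
           "apply_resection", "margin_for_fraction_removed",
           "time_to_fatal_radius", "DEFAULT_FATAL_RADIUS", "STR_MARGIN_FRACTION"]

EXTENTS = ("GTR", "STR", "biopsy")

#: uniform fatal T1Gd-equivalent radius, mm (configurable everywhere)
DEFAULT_FATAL_RADIUS = 35.0
#: STR margin as a fraction of the GTR (T1Gd) margin
STR_MARGIN_FRACTION = 0.75


@dataclass(frozen=True)
class ResectionEvent:
    """A resection at ``time`` (days) removing everything within
    ``margin_radius`` (mm); ``extent`` records the surgical category."""

    time: float
    extent: str
    margin_radius: float

    def __post_init__(self) -> None:
        if self.extent not in EXTENTS:
            raise ValueError(f"extent must be one of {EXTENTS}")
        if self.margin_radius < 0:
            raise ValueError("margin_radius must be >= 0")
        if self.extent == "biopsy" and self.margin_radius != 0:
            raise ValueError("biopsy must have margin_radius = 0")


@dataclass
class SurvivalSurrogate:
    """Time for the lesion to reach the fatal radius, or censored at horizon."""

    fatal_radius: float
    time_to_fatal: float
    censored: bool
    already_fatal: bool = False

    def __post_init__(self) -> None:
        if self.time_to_fatal < 0:
            raise GliomaPIError("time_to_fatal must be >= 0")


def resolve_margin(
    field: RadialField,
    extent: str,
    time: float = 0.0,
    f_t1: float = 0.8,
    str_fraction: float = STR_MARGIN_FRACTION,
) -> ResectionEvent:
    """Build a ResectionEvent whose margin follows the current T1Gd lesion:
    GTR resects to the T1Gd-threshold radius, STR to ``str_fraction`` of it,
    biopsy to nothing."""
    if extent == "biopsy":
        margin = 0.0
    else:
        r_t1 = extract_radius(field, f_t1)
        margin = r_t1 if extent == "GTR" else str_fraction * r_t1
    return ResectionEvent(time=time, extent=extent, margin_radius=margin)


def apply_resection(
    field: RadialField,
    event: ResectionEvent,
    residual_fraction: float = 0.0,
) -> tuple[RadialField, float]:
    """Zero the density within the margin; returns (field, removed_cells).

    ``residual_fraction`` optionally leaves that fraction of the pre-surgical
    density inside the cavity (sensitivity analyses); the default removes
    everything within the margin.  The invasive tail beyond the margin is
    untouched.
    """
    if event.margin_radius >= field.r_max:
        raise GliomaPIError("resection margin exceeds the solver domain")
    if not 0.0 <= residual_fraction < 1.0:
        raise ValueError("residual_fraction must be in [0, 1)")
    out = field.copy()
    if event.margin_radius == 0.0:  # biopsy: nothing removed
        return out, 0.0
    removed = (1.0 - residual_fraction) * ball_cell_count(field,
                                                          event.margin_radius)
    inside = out.grid <= event.margin_radius
    out.density[inside] *= residual_fraction
    return out, float(removed)


def ball_cell_count(field: RadialField, radius: float) -> float:
    """4π ∫₀ᴿ r² c(r) dr for the piecewise-linear density profile (exact
    per-segment antiderivative, so it agrees with continuum quadrature)."""
    if radius <= 0:
        return 0.0
    grid, dens = field.grid, field.density
    radius = min(radius, field.r_max)
    total = 0.0
    for i in range(grid.size - 1):
        r0, r1 = grid[i], min(grid[i + 1], radius)
        if r1 <= r0:
            break
        c0, c1 = dens[i], dens[i + 1]
        b = (c1 - c0) / (grid[i + 1] - grid[i])
        a = c0 - b * grid[i]
        total += a * (r1 ** 3 - r0 ** 3) / 3.0 + b * (r1 ** 4 - r0 ** 4) / 4.0
    return 4.0 * math.pi * total


def margin_for_fraction_removed(field: RadialField, fraction: float) -> float:
    """Smallest radius enclosing ``fraction`` of the total cell count.

    The 99% margin of a diffuse tumor lies far beyond its T1Gd radius; for a
    nodular tumor the two nearly coincide.  Interpolated within the grid cell
    where the cumulative volume-weighted mass crosses the target.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    vols = cell_volumes(field.grid)
    mass = vols * field.density
    total = mass.sum()
    if total <= 0:
        raise GliomaPIError("field has no cells")
    cum = np.cumsum(mass)
    target = fraction * total
    i = int(np.searchsorted(cum, target, side="left"))
    if i == 0:
        return float(field.grid[0] + (target / cum[0]) * (field.grid[1] - field.grid[0]) / 2)
    prev = cum[i - 1]
    frac_in_cell = (target - prev) / (cum[i] - prev)
    # faces of cell i sit at the midpoints
    lo = 0.5 * (field.grid[i - 1] + field.grid[i])
    hi = field.r_max if i == field.grid.size - 1 else 0.5 * (field.grid[i] + field.grid[i + 1])
    return float(lo + frac_in_cell * (hi - lo))


def time_to_fatal_radius(
    kinetics: Kinetics,
    initial: RadialField,
    fatal_radius: float = DEFAULT_FATAL_RADIUS,
    settings: SolverSettings | None = None,
    resection: ResectionEvent | None = None,
    radiation: RadiationPlan | None = None,
    horizon: float = 3650.0,
    f_t1: float = 0.8,
    check_every: int = 5,
) -> SurvivalSurrogate:
    """First time (days) the T1Gd radius reaches the fatal size under therapy.

    Therapy may include one resection event and/or a radiation plan; with no
    therapy this is the untreated survival surrogate.  If the lesion never
    reaches the fatal radius before ``horizon``, the surrogate is censored.
    If it is already fatal at t = 0, time 0 is returned with a flag.
    """
    if settings is None:
        settings = SolverSettings.auto(
            kinetics, r_max=fatal_radius + 12 * kinetics.gradient_length + 10.0)
    if fatal_radius >= settings.r_max:
        raise GliomaPIError("fatal radius exceeds the solver domain")
    if extract_radius(initial, f_t1) >= fatal_radius:
        return SurvivalSurrogate(fatal_radius, 0.0, censored=False,
                                 already_fatal=True)
    field = initial
    t0 = initial.time
    # apply resection at its scheduled time by splitting the run
    segments: list[tuple[float, float]] = []
    if resection is not None and resection.time > 0:
        segments.append((0.0, resection.time))
    start_of_growth = segments[-1][1] if segments else 0.0

    def run(fld, t_start, t_end, plan):
        """Simulate [t_start, t_end] and return (crossing_time|None, final)."""
        n_snap = max(3, int(math.ceil((t_end - t_start) / (settings.dt * check_every))))
        rel = np.linspace(0.0, t_end - t_start, n_snap + 1)[1:]
        if plan is not None and plan.fractions:
            shifted = RadiationPlan(
                [(t - t_start, d) for t, d in plan.fractions
                 if t_start <= t <= t_end], plan.alpha, plan.alpha_beta_ratio) \
                if any(t_start <= t <= t_end for t, _ in plan.fractions) else None
        else:
            shifted = None
        if shifted is not None:
            snaps = simulate_pirt(kinetics, fld, shifted, t_end - t_start,
                                  settings, snapshot_times=list(rel))
        else:
            snaps = simulate(kinetics, fld, t_end - t_start, settings,
                             snapshot_times=list(rel))
        prev_t, prev_r = fld.time, extract_radius(fld, f_t1)
        for f in snaps:
            r = extract_radius(f, f_t1)
            if r >= fatal_radius:
                if r > prev_r:
                    t_hit = prev_t + (fatal_radius - prev_r) / (r - prev_r) * (f.time - prev_t)
                else:
                    t_hit = f.time
                return t_hit, f
            prev_t, prev_r = f.time, r
        return None, snaps[-1]

    if resection is not None and resection.time > 0:
        hit, field = run(field, 0.0, resection.time, radiation)
        if hit is not None:
            return SurvivalSurrogate(fatal_radius, hit - t0, censored=False)
    if resection is not None:
        field, _removed = apply_resection(field, resection)
    hit, field = run(field, start_of_growth, horizon, radiation)
    if hit is not None:
        return SurvivalSurrogate(fatal_radius, hit - t0, censored=False)
    return SurvivalSurrogate(fatal_radius, horizon, censored=True)
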