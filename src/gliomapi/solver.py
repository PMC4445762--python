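"""Proliferation–invasion reaction–diffusion solver in spherical symmetry.

The model is the Fisher–KPP equation for glioma cell density c(r, t)

    ∂c/∂t = ∇·(D ∇c) + ρ c (1 − c/K)

with net invasion rate D (mm²/year), net proliferation rate ρ (1/year) and
carrying capacity K (cells/mm³).  Under spherical symmetry the diffusion
operator is (1/r²) ∂/∂r (r² ∂c/∂r); the removable singularity at the origin
reduces to the symmetric limit 3·∂²c/∂r².

Discretization is finite-volume on a uniform radial grid with zero-flux faces
at r = 0 and r = r_max, so the volume-weighted cell count Σ Vᵢ cᵢ is conserved
exactly under pure diffusion.  Time stepping is Strang splitting: the logistic
reaction is advanced with its exact solution map, the diffusion operator either
backward Euler ("implicit", unconditionally stable, non-negativity preserving)
or forward Euler ("explicit", stability-checked before stepping).

Two consequences worth knowing about:

* with D → 0 the scheme reduces to the exact logistic solution at every node;
* with ρ = 0 the implicit scheme conserves mass to linear-solver roundoff.

The density stays in [0, K] by construction (M-matrix property of backward
Euler plus the invariant interval of the logistic map); any excursion beyond
roundoff is treated as a bug and raised, never clipped silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import solve_banded

from . import _wave
from .errors import InvalidFieldError, UnstableSettingsError
from .units import DAYS_PER_YEAR, per_year_to_per_day

__all__ = [
    "Kinetics",
    "RadialField",
    "SolverSettings",
    "simulate",
    "extract_radius",
    "logistic_reference",
    "wavefront_speed",
    "gaussian_bolus",
    "front_profile",
    "cell_volumes",
    "total_cells",
]

# roundoff slack on the [0, K] saturation bound, as a fraction of K
_SATURATION_SLACK = 1e-9


@dataclass(frozen=True)
class Kinetics:
    """Patient-specific growth kinetics of the proliferation–invasion model.

    Parameters
    ----------
    D : float
        Net invasion (dispersal) rate, mm²/year.
    rho : float
        Net proliferation rate, 1/year.
    K : float
        Carrying capacity, cells/mm³.
    """

    D: float
    rho: float
    K: float

    def __post_init__(self) -> None:
        for name in ("D", "rho", "K"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def velocity(self) -> float:
        """Asymptotic radial growth velocity 2·sqrt(D·rho), mm/year."""
        return 2.0 * math.sqrt(self.D * self.rho)

    @property
    def gradient_length(self) -> float:
        """Traveling-wave e-folding length sqrt(D/rho), mm."""
        return math.sqrt(self.D / self.rho)

    @property
    def rho_over_D(self) -> float:
        """Aggressiveness ratio ρ/D, 1/mm² (high = nodular, low = diffuse)."""
        return self.rho / self.D

    # internal-unit views
    @property
    def D_day(self) -> float:
        return per_year_to_per_day(self.D)

    @property
    def rho_day(self) -> float:
        return per_year_to_per_day(self.rho)


@dataclass
class RadialField:
    """Spherically symmetric cell-density profile c(r) at one instant.

    ``grid`` is strictly increasing and starts at 0 (mm); ``density`` holds
    cells/mm³ per node; ``time`` is the simulation clock in days.  ``K`` is
    carried along so the saturation bound 0 ≤ c ≤ K is checkable in place.
    """

    grid: np.ndarray
    density: np.ndarray
    time: float
    K: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.grid.ndim != 1 or self.grid.size < 3:
            raise InvalidFieldError("grid must be 1-D with at least 3 nodes")
        if self.grid[0] != 0.0:
            raise InvalidFieldError("grid must start at r = 0")
        if np.any(np.diff(self.grid) <= 0):
            raise InvalidFieldError("grid must be strictly increasing")
        if self.density.shape != self.grid.shape:
            raise InvalidFieldError("density and grid shapes differ")
        if self.K <= 0:
            raise InvalidFieldError("carrying capacity K must be > 0")
        slack = _SATURATION_SLACK * self.K
        if np.any(self.density < -slack) or np.any(self.density > self.K + slack):
            raise InvalidFieldError("density outside [0, K]")

    def copy(self) -> "RadialField":
        return RadialField(self.grid.copy(), self.density.copy(), self.time, self.K)

    @property
    def r_max(self) -> float:
        return float(self.grid[-1])

    @property
    def dr(self) -> float:
        return float(self.grid[1] - self.grid[0])


@dataclass(frozen=True)
class SolverSettings:
    """Numerical parameters: spatial step dr (mm), time step dt (days),
    domain extent r_max (mm) and time-stepping scheme."""

    dr: float = 0.2
    dt: float = 0.5
    r_max: float = 100.0
    scheme: str = "implicit"

    def __post_init__(self) -> None:
        if self.dr <= 0 or self.dt <= 0 or self.r_max <= 0:
            raise ValueError("dr, dt, r_max must be positive")
        if self.scheme not in ("implicit", "explicit"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.r_max / self.dr < 3:
            raise ValueError("domain must span at least 3 grid cells")

    @classmethod
    def auto(cls, kinetics: Kinetics, r_max: float = 100.0,
             scheme: str = "implicit") -> "SolverSettings":
        """Resolution adapted to the front width sqrt(D/rho): dr at ~1/8 of
        the e-folding length (capped to [0.05, 0.5] mm), dt at ~1/20 of the
        proliferation time scale (capped to [0.1, 1] day)."""
        lam = kinetics.gradient_length
        dr = float(min(0.5, max(0.05, lam / 8.0)))
        dt = float(min(1.0, max(0.1, 0.05 / kinetics.rho_day)))
        return cls(dr=dr, dt=dt, r_max=r_max, scheme=scheme)

    def grid(self) -> np.ndarray:
        n = int(round(self.r_max / self.dr)) + 1
        return np.arange(n) * self.dr


def cell_volumes(grid: np.ndarray) -> np.ndarray:
    """Finite-volume cell volumes (mm³) around each node, faces at midpoints.

    Σ cell_volumes(grid) equals the volume of the ball of radius r_max, and
    Σ Vᵢ cᵢ is the discrete total cell count used throughout the package.
    """
    grid = np.asarray(grid, dtype=float)
    faces = np.empty(grid.size + 1)
    faces[0] = grid[0]
    faces[-1] = grid[-1]
    faces[1:-1] = 0.5 * (grid[:-1] + grid[1:])
    return (4.0 * np.pi / 3.0) * np.diff(faces ** 3)


def total_cells(field: RadialField) -> float:
    """Volume-weighted total cell count 4π ∫ r² c dr (finite-volume sum)."""
    return float(cell_volumes(field.grid) @ field.density)


def _diffusion_tridiag(grid: np.ndarray, D_day: float, geometry: str = "spherical"):
    """Tridiagonal operator L with dc/dt = L c, zero-flux at both ends.

    Returns (lower, diag, upper) such that
    (L c)[i] = lower[i-1]*c[i-1] + diag[i]*c[i] + upper[i]*c[i+1].
    """
    n = grid.size
    dr = grid[1] - grid[0]
    faces = np.empty(n + 1)
    faces[0] = grid[0]
    faces[-1] = grid[-1]
    faces[1:-1] = 0.5 * (grid[:-1] + grid[1:])
    if geometry == "spherical":
        area = faces ** 2          # face area / 4π
        vol = np.diff(faces ** 3) / 3.0   # cell volume / 4π
    elif geometry == "planar":
        area = np.ones(n + 1)
        vol = np.diff(faces)
    else:  # pragma: no cover
        raise ValueError(f"unknown geometry {geometry!r}")
    # conductance across interior faces 1..n-1
    g = D_day * area[1:-1] / dr
    upper = np.zeros(n)
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper[:-1] = g / vol[:-1]
    lower[:-1] = g / vol[1:]      # lower[i-1] couples c[i-1] into node i
    diag[:-1] -= g / vol[:-1]
    diag[1:] -= g / vol[1:]
    return lower, diag, upper, vol


def _logistic_map(c: np.ndarray, K: float, growth: float) -> np.ndarray:
    """Exact logistic flow over one (sub)step; ``growth`` = exp(rho*dt)."""
    return K * c * growth / (K + c * (growth - 1.0))


def logistic_reference(c0, kinetics: Kinetics, t_days: float):
    """Closed-form logistic solution c(t) = K c0 e^{ρt} / (K + c0 (e^{ρt}−1)).

    Exact solution of the reaction term alone; serves as the D → 0 oracle.
    """
    c0 = np.asarray(c0, dtype=float)
    if np.any(c0 < 0) or np.any(c0 > kinetics.K):
        raise ValueError("c0 must lie in [0, K]")
    g = math.exp(kinetics.rho_day * t_days)
    out = kinetics.K * c0 * g / (kinetics.K + c0 * (g - 1.0))
    return out if out.ndim else float(out)


def _check_bounds(c: np.ndarray, K: float) -> np.ndarray:
    slack = _SATURATION_SLACK * K
    lo, hi = c.min(), c.max()
    if lo < -slack or hi > K + slack:
        raise InvalidFieldError(
            f"density left [0, K]: min {lo:.3e}, max {hi:.3e}, K {K:.3e} "
            "(scheme instability, not clipped)"
        )
    # roundoff-level excursions only
    np.clip(c, 0.0, K, out=c)
    return c


def simulate(
    kinetics: Kinetics,
    initial: RadialField,
    duration: float,
    settings: SolverSettings,
    snapshot_times: Sequence[float] | None = None,
    events: dict[float, Callable[[np.ndarray], np.ndarray]] | None = None,
    geometry: str = "spherical",
) -> list[RadialField]:
    """Integrate the proliferation–invasion equation for ``duration`` days.

    Parameters
    ----------
    snapshot_times : sequence of float, optional
        Times (days, relative to ``initial.time``) at which to return the
        field; each is rounded to the nearest time-step boundary.  Defaults
        to the final time only.
    events : dict, optional
        Map from event time (days, relative) to a callable applied to the
        density array at the nearest step boundary — the hook used for
        instantaneous therapy (radiation kill, resection).

    Returns
    -------
    list of RadialField, one per snapshot time, in chronological order.
    """
    initial.validate()
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if initial.density.max() > kinetics.K * (1 + _SATURATION_SLACK):
        raise InvalidFieldError("initial density exceeds carrying capacity")

    dt = settings.dt
    D_day, rho_day = kinetics.D_day, kinetics.rho_day
    dr = initial.dr
    if settings.scheme == "explicit":
        # origin cell of the spherical stencil carries weight 6 D/dr²
        dt_max = dr * dr / (6.0 * D_day) if D_day > 0 else math.inf
        if dt > dt_max:
            raise UnstableSettingsError(
                f"explicit scheme requires dt <= dr²/(6 D) = {dt_max:.4g} d, got {dt} d"
            )

    n_steps = max(1, int(round(duration / dt)))
    if snapshot_times is None:
        snapshot_times = [duration]
    snap_steps: dict[int, list[float]] = {}
    for t in snapshot_times:
        k = min(n_steps, max(0, int(round(t / dt))))
        snap_steps.setdefault(k, []).append(t)
    event_steps: dict[int, list[Callable]] = {}
    for t, fn in (events or {}).items():
        if t < 0:
            raise ValueError(f"event at negative time {t}")
        k = min(n_steps, max(0, int(round(t / dt))))
        event_steps.setdefault(k, []).append(fn)

    lower, diag, upper, _ = _diffusion_tridiag(initial.grid, D_day, geometry)
    n = initial.grid.size
    if settings.scheme == "implicit":
        # banded form of (I - dt L) for solve_banded
        ab = np.zeros((3, n))
        ab[0, 1:] = -dt * upper[:-1]
        ab[1, :] = 1.0 - dt * diag
        ab[2, :-1] = -dt * lower[:-1]

    g_half = math.exp(rho_day * dt / 2.0)
    K = kinetics.K
    c = initial.density.astype(float).copy()
    out: list[RadialField] = []

    def emit(step: int) -> None:
        for _ in snap_steps.get(step, ()):  # one snapshot per requested time
            out.append(RadialField(initial.grid.copy(), c.copy(),
                                   initial.time + step * dt, K))

    for fn in event_steps.get(0, ()):
        c = _check_bounds(np.asarray(fn(c), dtype=float), K)
    emit(0)
    for step in range(1, n_steps + 1):
        c = _logistic_map(c, K, g_half)
        if settings.scheme == "implicit":
            c = solve_banded((1, 1), ab, c, overwrite_b=True)
        else:
            lap = diag * c
            lap[1:] += lower[:-1] * c[:-1]
            lap[:-1] += upper[:-1] * c[1:]
            c = c + dt * lap
        c = _logistic_map(c, K, g_half)
        c = _check_bounds(c, K)
        for fn in event_steps.get(step, ()):
            c = _check_bounds(np.asarray(fn(c), dtype=float), K)
        emit(step)
    return out


def extract_radius(field: RadialField, threshold_fraction: float) -> float:
    """Imageable tumor radius: outermost radius where c/K crosses a threshold.

    MRI sequences visualize the lesion down to a modality-specific cell
    density; the model-equivalent lesion radius is the outermost crossing of
    c/K through ``threshold_fraction``, linearly interpolated between nodes.
    Returns 0 when the density is everywhere below threshold, and r_max when
    the density at the boundary still exceeds it.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    thr = threshold_fraction * field.K
    c = field.density
    if c.max() < thr:
        return 0.0
    if c[-1] >= thr:
        return field.r_max
    above = np.flatnonzero(c >= thr)
    i = above[-1]  # outermost node above threshold
    r0, r1 = field.grid[i], field.grid[i + 1]
    c0, c1 = c[i], c[i + 1]
    return float(r0 + (thr - c0) / (c1 - c0) * (r1 - r0))


def wavefront_speed(
    snapshots: Sequence[RadialField],
    threshold_fraction: float = 0.5,
    boundary_margin: float = 2.0,
) -> float:
    """Front speed (mm/year) as the least-squares slope of radius vs time.

    Rejects fits whose front has reached within ``boundary_margin`` grid
    steps of r_max (boundary contamination).
    """
    if len(snapshots) < 3:
        raise ValueError("need at least 3 snapshots to fit a front speed")
    radii = np.array([extract_radius(f, threshold_fraction) for f in snapshots])
    times = np.array([f.time for f in snapshots])
    limit = snapshots[0].r_max - boundary_margin * snapshots[0].dr
    if np.any(radii >= limit):
        raise ValueError("front reached the outer boundary during the fit window")
    slope_per_day = np.polyfit(times, radii, 1)[0]
    return float(slope_per_day * DAYS_PER_YEAR)


def gaussian_bolus(
    kinetics: Kinetics,
    settings: SolverSettings,
    width: float = 2.0,
    amplitude_fraction: float = 1.0,
) -> RadialField:
    """Localized seed: c(r) = a·K·exp(−r²/width²), the default initial lesion."""
    grid = settings.grid()
    c = amplitude_fraction * kinetics.K * np.exp(-((grid / width) ** 2))
    return RadialField(grid, c, 0.0, kinetics.K)


def front_profile(
    kinetics: Kinetics,
    settings: SolverSettings,
    radius: float,
    threshold_fraction: float = 0.8,
    time: float = 0.0,
    shape: str = "wave",
) -> RadialField:
    """Developed-tumor initial condition with a prescribed lesion radius.

    ``shape="wave"`` (default) places the minimal-speed traveling-wave
    profile — the shape an established front actually has — so that c/K
    equals ``threshold_fraction`` exactly at ``radius``; simulations started
    from it settle onto the asymptotic regime with essentially no transient.
    ``shape="exp_tail"`` uses a saturated core with a bare exponential tail
    of e-folding length sqrt(D/rho), a cruder textbook sketch retained for
    transient studies.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    grid = settings.grid()
    if radius >= grid[-1]:
        raise ValueError("requested radius exceeds the solver domain")
    lam = kinetics.gradient_length
    if shape == "wave":
        xi0 = _wave.level_crossing(threshold_fraction)
        c = kinetics.K * _wave.profile_fraction((grid - radius) / lam + xi0)
    elif shape == "exp_tail":
        r_edge = radius - lam * math.log(1.0 / threshold_fraction)
        c = kinetics.K * np.minimum(1.0, np.exp(-(grid - r_edge) / lam))
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return RadialField(grid, c, time, kinetics.K)
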