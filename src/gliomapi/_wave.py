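"""Minimal-speed traveling-wave profile of the Fisher–KPP front.

In units of the e-folding length λ = sqrt(D/ρ), the wave profile U(ξ)
satisfies U'' + 2U' + U(1 − U) = 0 with U(−∞) = 1, U(+∞) = 0 (minimal speed
2).  The profile is computed once by integrating off the unstable manifold
of U = 1 and cached; both the calibration inverter (level-set distances) and
the developed-tumor initial condition draw on it.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp

_U_FLOOR = 1e-12  # integrate until the tail is numerically zero


@lru_cache(maxsize=1)
def _wave_solution():
    """Dense (xi, U) samples of the wave profile, shifted so U(0) = 1/2."""
    eps = 1e-9
    mu = math.sqrt(2.0) - 1.0  # unstable-manifold rate at U = 1

    def rhs(_x, y):
        u, up = y
        return [up, -2.0 * up - u * (1.0 - u)]

    def floor_ev(_x, y):
        return y[0] - _U_FLOOR
    floor_ev.terminal = True
    floor_ev.direction = -1

    sol = solve_ivp(
        rhs, (0.0, 500.0), [1.0 - eps, -mu * eps],
        events=(floor_ev,), rtol=1e-11, atol=1e-14, dense_output=True,
        max_step=0.05,
    )
    xi = sol.t
    u = sol.y[0]
    # monotone decreasing by construction; anchor xi = 0 at U = 1/2
    xi_half = float(np.interp(0.5, u[::-1], xi[::-1]))
    return xi - xi_half, u


def level_crossing(level: float) -> float:
    """ξ (in units of λ, with U(0) = 1/2) where the wave profile crosses
    ``level``; monotone decreasing in ``level``."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    xi, u = _wave_solution()
    if level < u[-1]:
        raise ValueError("level below resolved tail of the wave profile")
    return float(np.interp(level, u[::-1], xi[::-1]))


def level_gap(f_hi: float, f_lo: float) -> float:
    """Distance (units of λ) between the f_hi and f_lo level sets."""
    if not 0.0 < f_lo < f_hi < 1.0:
        raise ValueError("need 0 < f_lo < f_hi < 1")
    return level_crossing(f_lo) - level_crossing(f_hi)


def profile_fraction(xi: np.ndarray) -> np.ndarray:
    """U(ξ) evaluated at arbitrary ξ (units of λ); 1 far behind, 0 far ahead."""
    xs, u = _wave_solution()
    out = np.interp(xi, xs, u, left=1.0, right=0.0)
    return out
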