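"""Suprabasal oxygen-uptake kinetics driven by piecewise-constant exercise.

PVO2max(t), the suprabasal oxygen consumption in %VO2max, follows first-order
kinetics toward the current intensity input u(t):

    dPVO2max/dt = -rate·PVO2max + rate·u(t)

with rate 0.8 min⁻¹ by default, so the target intensity is reached in
roughly 5-6 minutes after onset and decays back on the same timescale after
the session ends. Valid below the lactate threshold, where a single kinetic
component suffices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .prescription import ExerciseProtocol

__all__ = [
    "OxygenKineticsParameters",
    "exercise_input",
    "pvo2max_derivative",
    "pvo2max_closed_form",
    "protocol_breakpoints",
]


@dataclass(frozen=True)
class OxygenKineticsParameters:
    """Single tunable: the first-order rate constant (min⁻¹)."""

    rate: float = 0.8

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("oxygen kinetics rate must be positive")


def exercise_input(t: float, protocol: ExerciseProtocol) -> float:
    """The step input u(t): the active segment's Tv on [t_start, t_end], else 0.

    Segment boundaries are included (closed intervals); between and outside
    segments the input is zero.
    """
    for seg in protocol.segments:
        if seg.t_start <= t <= seg.t_end:
            return seg.tv
    return 0.0


def pvo2max_derivative(
    p: float, u: float, params: OxygenKineticsParameters | None = None
) -> float:
    """Right-hand side of the oxygen-uptake ODE: −rate·p + rate·u."""
    rate = (params or OxygenKineticsParameters()).rate
    return -rate * p + rate * u


def protocol_breakpoints(
    protocol: ExerciseProtocol, t0: float, t_end: float
) -> np.ndarray:
    """Sorted breakpoint grid: t0, every segment boundary inside (t0, t_end), t_end.

    The input u(t) is discontinuous exactly at these points; integrators must
    restart there so a step never straddles a jump.
    """
    pts = {float(t0), float(t_end)}
    for seg in protocol.segments:
        for b in (seg.t_start, seg.t_end):
            if t0 < b < t_end:
                pts.add(float(b))
    return np.array(sorted(pts))


def pvo2max_closed_form(
    t: float | np.ndarray,
    protocol: ExerciseProtocol,
    params: OxygenKineticsParameters | None = None,
    p0: float = 0.0,
    t0: float = 0.0,
) -> float | np.ndarray:
    """Exact solution of the oxygen-uptake ODE for a piecewise-constant input.

    Within each interval where u is constant, p(t) = u + (p_k − u)·e^(−rate·Δt);
    the solution is chained across segment breakpoints. Serves as the analytic
    oracle for any numerical integration of the same equation.
    """
    rate = (params or OxygenKineticsParameters()).rate
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < t0):
        raise ValueError("evaluation times must be >= t0")
    t_max = float(t_arr.max()) if t_arr.size else t0
    breaks = protocol_breakpoints(protocol, t0, max(t_max, t0) + 1.0)
    out = np.empty_like(t_arr)
    order = np.argsort(t_arr, kind="stable")
    p_k, t_k = float(p0), float(t0)
    idx = 0
    for j in order:
        tj = t_arr[j]
        # advance the chained state across breakpoints up to tj
        while idx < len(breaks) - 1 and breaks[idx + 1] <= tj:
            a, b = breaks[idx], breaks[idx + 1]
            u = exercise_input((a + b) / 2.0, protocol)
            p_k = u + (p_k - u) * math.exp(-rate * (b - t_k))
            t_k = b
            idx += 1
        u = exercise_input((t_k + tj) / 2.0 if tj > t_k else tj, protocol)
        out[j] = u + (p_k - u) * math.exp(-rate * (tj - t_k))
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out
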