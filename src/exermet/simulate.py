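"""Coupled integration of oxygen uptake, epinephrine and the hormone controller.

The simulated state is (PVO2max, CE, CI, CG) — suprabasal oxygen consumption
plus plasma epinephrine, insulin and glucagon — driven by a piecewise-constant
exercise protocol. Arterial glucose enters through a pluggable provider: the
multi-organ metabolic core that would generate it dynamically is outside this
package's scope, so the provider is either constant (fasting 5 mmol/l),
a tabulated time series, or a deliberately simple toy feedback loop.

Integration uses a stiff-capable adaptive solver (LSODA) restarted at every
segment boundary so the discontinuous input never straddles a solver step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import SolverFailure
from .hormones import ModelParameters, calibrate_h, elimination_constant
from .oxygen import exercise_input, protocol_breakpoints
from .prescription import ExerciseProtocol
from .subject import SubjectProfile

__all__ = [
    "GlucoseProvider",
    "ConstantGlucose",
    "TabulatedGlucose",
    "FeedbackGlucose",
    "SimulationSettings",
    "Trajectory",
    "SimulationScenario",
    "simulate",
    "to_suprabasal",
    "sweep_parameter",
    "SWEEPABLE",
]


class GlucoseProvider:
    """Contract: arterial glucose Ca,g(t) in mmol/l over the simulation horizon."""

    #: dynamic providers add Ca,g as an extra ODE state instead of a t->value map
    dynamic: bool = False

    def __call__(self, t: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def basal(self) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class ConstantGlucose(GlucoseProvider):
    """Fixed arterial glucose; default is the fasting value 5 mmol/l."""

    def __init__(self, value: float = 5.0):
        if not (np.isfinite(value) and value > 0):
            raise ValueError("glucose must be finite and positive")
        self.value = float(value)

    def __call__(self, t: float) -> float:
        return self.value

    @property
    def basal(self) -> float:
        return self.value


class TabulatedGlucose(GlucoseProvider):
    """Linear interpolation through a measured (time, glucose) series.

    Values outside the tabulated span are clamped to the end points.
    """

    def __init__(self, times: Sequence[float], values: Sequence[float]):
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("need matching 1-D time and glucose arrays, length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("glucose values must be finite and positive")
        self.times, self.values = t, v

    @classmethod
    def from_csv(cls, path) -> "TabulatedGlucose":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def __call__(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))

    @property
    def basal(self) -> float:
        return float(self.values[0])


class FeedbackGlucose(GlucoseProvider):
    """Toy closed-loop glucose dynamics (NOT part of the published model).

    dCa,g/dt = a·(CG/CI − CG0/CI0) − b·PVO2max·Ca,g: hepatic production rises
    with the glucagon-to-insulin ratio, uptake with exercise intensity. This is
    a qualitative stand-in for the out-of-scope multi-organ metabolic core so
    that the glucose-dependent epinephrine term can be exercised in closed
    loop; it makes no claim to quantitative realism.
    """

    dynamic = True

    def __init__(self, a: float = 0.05, b: float = 2e-4, basal: float = 5.0):
        if not (a >= 0 and b >= 0 and basal > 0):
            raise ValueError("need a, b >= 0 and basal > 0")
        self.a, self.b, self._basal = float(a), float(b), float(basal)

    def derivative(self, ca_g: float, cg: float, ci: float, pvo2max: float,
                   cg0: float, ci0: float) -> float:
        return self.a * (cg / ci - cg0 / ci0) - self.b * pvo2max * ca_g

    def __call__(self, t: float) -> float:  # initial value only
        return self._basal

    @property
    def basal(self) -> float:
        return self._basal


@dataclass(frozen=True)
class SimulationSettings:
    """Integration horizon, output grid and solver tolerances."""

    t0: float = 0.0
    t_end: float = 180.0
    output_grid: float = 1.0
    rel_tol: float = 1e-9
    abs_tol: float = 1e-11
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_end > self.t0:
            raise ValueError("t_end must exceed t0")
        if not (self.output_grid > 0 and self.rel_tol > 0 and self.abs_tol > 0):
            raise ValueError("output_grid and tolerances must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed model output.

    ``pvo2max`` is already suprabasal by construction; hormone columns are
    absolute concentrations (pM) and glucose is mmol/l. ``basal`` records the
    basal levels used, so suprabasal views can be formed exactly.
    """

    times: np.ndarray
    pvo2max: np.ndarray
    ce: np.ndarray
    ci: np.ndarray
    cg: np.ndarray
    ca_g: np.ndarray
    basal: dict = field(default_factory=dict)
    suprabasal: bool = False

    def __post_init__(self) -> None:
        n = self.times.size
        for name in ("pvo2max", "ce", "ci", "cg", "ca_g"):
            arr = getattr(self, name)
            if arr.size != n:
                raise ValueError("trajectory columns must have equal length")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in trajectory column {name}")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        suffix = "_suprabasal" if self.suprabasal else ""
        return pd.DataFrame(
            {
                "time_min": self.times,
                "pvo2max_pct": self.pvo2max,
                f"ce_pM{suffix}": self.ce,
                f"ci_pM{suffix}": self.ci,
                f"cg_pM{suffix}": self.cg,
                "cag_mM": self.ca_g,
            }
        )

    def to_csv(self, path) -> None:
        # repr round-trip precision so re-read values are bit-identical
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def interp(self, times: Sequence[float]) -> "Trajectory":
        """Linear interpolation onto a new time grid inside the span."""
        t = np.asarray(times, dtype=float)
        if t.min() < self.times[0] or t.max() > self.times[-1]:
            raise ValueError("requested times outside the trajectory span")
        cols = {
            name: np.interp(t, self.times, getattr(self, name))
            for name in ("pvo2max", "ce", "ci", "cg", "ca_g")
        }
        return Trajectory(times=t, basal=dict(self.basal),
                          suprabasal=self.suprabasal, **cols)


def _output_times(settings: SimulationSettings) -> np.ndarray:
    n = int(round((settings.t_end - settings.t0) / settings.output_grid))
    times = settings.t0 + settings.output_grid * np.arange(n + 1)
    if times[-1] < settings.t_end - 1e-12:
        times = np.append(times, settings.t_end)
    times[-1] = min(times[-1], settings.t_end)
    return times


def simulate(
    subject: SubjectProfile,
    protocol: ExerciseProtocol,
    params: ModelParameters | None = None,
    glucose: GlucoseProvider | None = None,
    settings: SimulationSettings | None = None,
    t_eval: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the coupled 4-state system from the basal fixed point.

    The initial condition is always basal (PVO2max = 0, CE = CE0, CI = CI0,
    CG = CG0); the derived constants k and h are recomputed here from the
    subject's body weight and the glucose provider's basal level, so changing
    any constant never leaves stale calibrations behind. Segment boundaries
    are mandatory solver restart points.

    ``t_eval`` optionally replaces the regular output grid with explicit
    sample times (used by the estimation module); it must lie within
    [t0, t_end] and does not influence the adaptive stepping.
    """
    params = params if params is not None else ModelParameters()
    glucose = glucose if glucose is not None else ConstantGlucose(5.0)
    if settings is None:
        end = (protocol.t_end or 60.0) + 120.0
        settings = SimulationSettings(t0=0.0, t_end=end)

    epi, ctrl = params.epinephrine, params.controller
    bw = subject.body_weight
    k = elimination_constant(bw, epi)
    h = calibrate_h(ctrl, epi.cag_star)

    rate = params.oxygen_rate
    vd, f1 = epi.vd, epi.f1
    ce0, ci0, cg0 = epi.ce0, ctrl.ci0, ctrl.cg0
    k1, k2, k3, k4, k5, d_rate = ctrl.k1, ctrl.k2, ctrl.k3, ctrl.k4, ctrl.k5, ctrl.d_rate
    f2, f3 = epi.f2, epi.f3
    phi_at, psi_at = ctrl.phi_at, ctrl.psi_at
    dynamic = glucose.dynamic

    def rhs(t: float, y: np.ndarray, u: float) -> list[float]:
        p, ce, ci, cg = y[0], y[1], y[2], y[3]
        cag = y[4] if dynamic else glucose(t)
        dp = rate * (u - p)
        dce = (f1 + f2(cag) + f3(p)) * bw / vd - k * ce
        br_i = h - k3 * (cg - cg0) - k4 * (ci - ci0) - k5 * (ce - ce0)
        dci = ci * (psi_at(cag) * br_i - d_rate)
        br_g = h - k1 * (cg - cg0) - k2 * (ci - ci0)
        dcg = cg * (phi_at(cag) * br_g - d_rate)
        out = [dp, dce, dci, dcg]
        if dynamic:
            out.append(glucose.derivative(cag, cg, ci, p, cg0, ci0))
        return out

    if t_eval is not None:
        times = np.asarray(t_eval, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0):
            raise ValueError("t_eval must be non-empty and strictly increasing")
        if times[0] < settings.t0 or times[-1] > settings.t_end:
            raise ValueError("t_eval must lie within [t0, t_end]")
    else:
        times = _output_times(settings)

    breaks = protocol_breakpoints(protocol, settings.t0, settings.t_end)
    y = [0.0, ce0, ci0, cg0] + ([glucose.basal] if dynamic else [])
    rows = []
    if times[0] == settings.t0:
        rows.append((settings.t0, list(y)))

    for a, b in zip(breaks[:-1], breaks[1:]):
        u = exercise_input((a + b) / 2.0, protocol)
        inner = times[(times > a + 1e-12) & (times < b - 1e-12)]
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
            t_eval=np.append(inner, b),
            args=(u,),
        )
        if not sol.success:
            last = float(sol.t[-1]) if sol.t.size else a
            raise SolverFailure(
                f"integration failed on [{a}, {b}]: {sol.message}", last_time=last
            )
        for j, tj in enumerate(sol.t):
            keep = tj < b - 1e-12 or np.any(np.abs(times - b) < 1e-9)
            if keep and (not rows or tj > rows[-1][0] + 1e-12):
                rows.append((float(tj), list(sol.y[:, j])))
        y = list(sol.y[:, -1])

    t_out = np.array([r[0] for r in rows])
    states = np.array([r[1] for r in rows])
    basal = {"ce": ce0, "ci": ci0, "cg": cg0, "ca_g": glucose.basal}
    return Trajectory(
        times=t_out,
        pvo2max=states[:, 0],
        ce=states[:, 1],
        ci=states[:, 2],
        cg=states[:, 3],
        ca_g=states[:, 4] if dynamic else np.array([glucose(t) for t in t_out]),
        basal=basal,
    )


def to_suprabasal(traj: Trajectory, params: ModelParameters | None = None) -> Trajectory:
    """Express hormone series as deviations from basal (figure convention).

    PVO2max is already suprabasal and glucose is left absolute; only the
    epinephrine, insulin and glucagon columns are shifted. Basal levels are
    taken from the trajectory itself (recorded at simulation time) or, if
    absent, from ``params``.
    """
    if traj.suprabasal:
        return traj
    basal = dict(traj.basal)
    if not basal:
        p = params if params is not None else ModelParameters()
        basal = {"ce": p.epinephrine.ce0, "ci": p.controller.ci0,
                 "cg": p.controller.cg0, "ca_g": p.epinephrine.cag_star}
    return Trajectory(
        times=traj.times,
        pvo2max=traj.pvo2max,
        ce=traj.ce - basal["ce"],
        ci=traj.ci - basal["ci"],
        cg=traj.cg - basal["cg"],
        ca_g=traj.ca_g,
        basal=basal,
        suprabasal=True,
    )


@dataclass(frozen=True)
class SimulationScenario:
    """Everything one simulation needs; the unit a parameter sweep perturbs."""

    subject: SubjectProfile
    protocol: ExerciseProtocol
    params: ModelParameters = field(default_factory=ModelParameters)
    glucose: GlucoseProvider = field(default_factory=ConstantGlucose)
    settings: SimulationSettings | None = None

    def run(self, t_eval: Sequence[float] | None = None) -> Trajectory:
        return simulate(self.subject, self.protocol, self.params,
                        self.glucose, self.settings, t_eval=t_eval)


SWEEPABLE = ("BW", "Tv", "k5")


def sweep_parameter(
    name: str, values: Sequence[float], base: SimulationScenario
) -> List[Trajectory]:
    """One simulation per value of a sweepable parameter, all else fixed.

    Sweepables: BW (body weight, kg), Tv (intensity of every segment,
    %VO2max), k5 (epinephrine→insulin coupling, pM⁻¹·min⁻¹). Derived
    constants (k, h) are recomputed inside every run.
    """
    key = name.lower()
    if key not in {s.lower() for s in SWEEPABLE}:
        raise ValueError(f"parameter {name!r} is not sweepable; choose from {SWEEPABLE}")
    out = []
    for v in values:
        scen = base
        if key == "bw":
            scen = replace(base, subject=base.subject.model_copy(
                update={"body_weight": float(v)}))
        elif key == "tv":
            segs = [s.model_copy(update={"tv": float(v)}) for s in base.protocol.segments]
            scen = replace(base, protocol=base.protocol.model_copy(
                update={"segments": segs}))
        else:
            scen = replace(base, params=base.params.with_updates(k5=float(v)))
        out.append(scen.run())
    return out
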