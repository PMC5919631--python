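"""Epinephrine kinetics and the epinephrine-modulated insulin/glucagon controller.

Epinephrine (pM) is secreted at a basal rate f1 plus two sigmoidal
contributions — f2, falling with arterial glucose (hypoglycaemia-triggered
release), and f3, rising with relative exercise intensity — and eliminated
first-order with constant k:

    dCE/dt = (1/Vd)·(f1 + f2(Ca,g) + f3(PVO2max))·BW − k·CE

k is not a free parameter: it is derived by imposing the resting steady state
(CE = CE0 at fasting glucose Ca,g* and zero exercise), giving
k = BW/(Vd·CE0)·(f1 + f2* + f3*).

Insulin and glucagon follow a multiplicative cross-inhibition controller in
which suprabasal epinephrine enters the insulin equation bilinearly through
the coupling k5:

    dCI/dt = CI·[ψ·(h − k3·(CG−CG0) − k4·(CI−CI0) − k5·(CE−CE0)) − D]
    dCG/dt = CG·[φ·(h − k1·(CG−CG0) − k2·(CI−CI0)) − D]

φ and ψ are glucose-dependent modulation hooks (constant 1 by default); the
offset h is derived so that the all-basal state is a fixed point at fasting
glucose (h = D/φ(Ca,g*), with a consistency check against ψ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from .exceptions import CalibrationError

__all__ = [
    "EpinephrineParameters",
    "HormoneControllerParameters",
    "ModelParameters",
    "f2_glucose_term",
    "f3_exercise_term",
    "elimination_constant",
    "epinephrine_derivative",
    "insulin_derivative",
    "glucagon_derivative",
    "calibrate_h",
]

GlucoseModulation = Callable[[float], float]


def _bounded_sigmoid(amplitude: float, x: float) -> float:
    """amplitude / (1 + exp(x)), safe against overflow for any finite x."""
    if x > 0:
        e = math.exp(-x)
        return amplitude * e / (1.0 + e)
    return amplitude / (1.0 + math.exp(x))


@dataclass(frozen=True)
class EpinephrineParameters:
    """Constants of the epinephrine secretion/elimination model.

    vd: volume of distribution (L); f1: basal secretion (pmol·kg⁻¹·min⁻¹);
    c1/c2/c3: glucose sigmoid amplitude (pmol·kg⁻¹·min⁻¹), steepness
    (L·mmol⁻¹) and midpoint (mmol·L⁻¹); d1/d2/d3: exercise sigmoid amplitude,
    steepness ((%VO2max)⁻¹) and midpoint (%VO2max); ce0: basal plasma
    epinephrine (pM); cag_star: fasting arterial glucose (mmol·L⁻¹).
    The elimination constant k is derived, never set (see
    :func:`elimination_constant`).
    """

    vd: float = 20.0
    f1: float = 10.0
    c1: float = 40.0
    c2: float = 2.0
    c3: float = 3.0
    d1: float = 115.0
    d2: float = 0.1
    d3: float = 60.0
    ce0: float = 400.0
    cag_star: float = 5.0

    def __post_init__(self) -> None:
        for name in ("vd", "c1", "d1", "ce0", "cag_star"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.f1 < 0:
            raise ValueError("f1 must be non-negative")

    def f2(self, ca_g: float) -> float:
        return _bounded_sigmoid(self.c1, self.c2 * (ca_g - self.c3))

    def f3(self, pvo2max: float) -> float:
        return _bounded_sigmoid(self.d1, self.d2 * (self.d3 - pvo2max))

    @property
    def f2_star(self) -> float:
        """f2 at fasting glucose — the resting value used to calibrate k."""
        return self.f2(self.cag_star)

    @property
    def f3_star(self) -> float:
        """f3 at zero exercise — the resting value used to calibrate k."""
        return self.f3(0.0)


@dataclass(frozen=True)
class HormoneControllerParameters:
    """Constants of the insulin/glucagon controller.

    ci0/cg0: basal insulin and glucagon (pM); k1..k4: glucagon/insulin
    cross- and self-interaction gains; k5: epinephrine→insulin coupling
    (pM⁻¹·min⁻¹); d_rate: the first-order turnover rate D (min⁻¹). phi/psi
    are glucose-dependent modulation hooks (None means constant 1). The
    offset h is derived from steady state, never set (see :func:`calibrate_h`).
    """

    ci0: float = 60.0
    cg0: float = 30.0
    k1: float = 0.008
    k2: float = 0.004
    k3: float = 0.002
    k4: float = 0.004
    k5: float = 3.6e-5
    d_rate: float = 0.1
    phi: Optional[GlucoseModulation] = field(default=None, compare=False)
    psi: Optional[GlucoseModulation] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("ci0", "cg0", "d_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.k5 < 0:
            raise ValueError("k5 must be non-negative")

    def phi_at(self, ca_g: float) -> float:
        return 1.0 if self.phi is None else float(self.phi(ca_g))

    def psi_at(self, ca_g: float) -> float:
        return 1.0 if self.psi is None else float(self.psi(ca_g))


def f2_glucose_term(ca_g: float, params: EpinephrineParameters) -> float:
    """Glucose-dependent epinephrine secretion: c1/(1 + e^(c2·(Ca,g − c3)))."""
    if ca_g < 0:
        raise ValueError("arterial glucose must be non-negative")
    return params.f2(ca_g)


def f3_exercise_term(pvo2max: float, params: EpinephrineParameters) -> float:
    """Exercise-dependent epinephrine secretion: d1/(1 + e^(d2·(d3 − PVO2max)))."""
    if pvo2max < 0:
        raise ValueError("pvo2max must be non-negative")
    return params.f3(pvo2max)


def elimination_constant(bw: float, params: EpinephrineParameters) -> float:
    """Epinephrine elimination constant from the resting steady state.

    k = BW/(Vd·CE0)·(f1 + f2* + f3*) in min⁻¹, with f2*, f3* evaluated at
    fasting glucose and zero exercise, so that dCE/dt = 0 at CE = CE0.
    """
    if not bw > 0:
        raise ValueError("body weight must be positive")
    k = bw / (params.vd * params.ce0) * (params.f1 + params.f2_star + params.f3_star)
    if not k > 0:
        raise CalibrationError("derived elimination constant is non-positive")
    return k


def epinephrine_derivative(
    ce: float,
    ca_g: float,
    pvo2max: float,
    bw: float,
    params: EpinephrineParameters,
    k: float | None = None,
) -> float:
    """dCE/dt = (1/Vd)·(f1 + f2 + f3)·BW − k·CE (pM·min⁻¹).

    ``k`` may be passed in when precomputed (e.g. inside an ODE right-hand
    side); otherwise it is derived from the resting steady state.
    """
    if k is None:
        k = elimination_constant(bw, params)
    secretion = (params.f1 + params.f2(ca_g) + params.f3(pvo2max)) * bw / params.vd
    return secretion - k * ce


def calibrate_h(
    params: HormoneControllerParameters, cag_basal: float | None = None
) -> float:
    """Controller offset h making the all-basal state a fixed point.

    h = D/φ(Ca,g basal); the glucagon and insulin equations share the fixed
    point only if ψ agrees with φ at basal glucose, which is verified to
    1e-9 and raises otherwise rather than silently preferring one equation.
    """
    cag = 5.0 if cag_basal is None else cag_basal
    phi_val = params.phi_at(cag)
    if not phi_val > 0:
        raise CalibrationError(f"phi({cag}) = {phi_val} is not positive")
    h = params.d_rate / phi_val
    if abs(params.psi_at(cag) * h - params.d_rate) >= 1e-9:
        raise CalibrationError(
            "phi and psi disagree at basal glucose: the insulin and glucagon "
            "equations would not share the basal fixed point"
        )
    return h


def insulin_derivative(
    ci: float,
    cg: float,
    ce: float,
    params: HormoneControllerParameters,
    h: float | None = None,
    ca_g: float = 5.0,
    ce0: float = 400.0,
) -> float:
    """dCI/dt = CI·[ψ·(h − k3·ΔCG − k4·ΔCI − k5·ΔCE) − D] (pM·min⁻¹).

    ``ce0`` is the basal epinephrine the suprabasal deviation is measured
    against; it belongs to the epinephrine block and defaults to the
    reference value.
    """
    if h is None:
        h = calibrate_h(params, ca_g)
    bracket = h - params.k3 * (cg - params.cg0) - params.k4 * (ci - params.ci0)
    bracket -= params.k5 * (ce - ce0)
    return ci * (params.psi_at(ca_g) * bracket - params.d_rate)


def glucagon_derivative(
    cg: float,
    ci: float,
    params: HormoneControllerParameters,
    h: float | None = None,
    ca_g: float = 5.0,
) -> float:
    """dCG/dt = CG·[φ·(h − k1·ΔCG − k2·ΔCI) − D] (pM·min⁻¹)."""
    if h is None:
        h = calibrate_h(params, ca_g)
    bracket = h - params.k1 * (cg - params.cg0) - params.k2 * (ci - params.ci0)
    return cg * (params.phi_at(ca_g) * bracket - params.d_rate)


@dataclass(frozen=True)
class ModelParameters:
    """Bundle of all model constants: epinephrine, controller, oxygen kinetics."""

    epinephrine: EpinephrineParameters = field(default_factory=EpinephrineParameters)
    controller: HormoneControllerParameters = field(
        default_factory=HormoneControllerParameters
    )
    oxygen_rate: float = 0.8

    def with_updates(self, **updates: float) -> "ModelParameters":
        """Return a copy with named scalar constants replaced.

        Accepted names are any field of the epinephrine or controller blocks
        (e.g. ``k5``, ``d1``, ``vd``) plus ``oxygen_rate``.
        """
        epi_fields = {f for f in EpinephrineParameters.__dataclass_fields__}
        ctrl_fields = {f for f in HormoneControllerParameters.__dataclass_fields__}
        epi_updates, ctrl_updates, rest = {}, {}, {}
        for name, value in updates.items():
            if name == "oxygen_rate":
                rest[name] = value
            elif name in ctrl_fields:
                ctrl_updates[name] = value
            elif name in epi_fields:
                epi_updates[name] = value
            else:
                raise KeyError(
                    f"unknown model parameter {name!r}; known: oxygen_rate, "
                    f"{sorted(ctrl_fields | epi_fields)}"
                )
        return ModelParameters(
            epinephrine=replace(self.epinephrine, **epi_updates)
            if epi_updates
            else self.epinephrine,
            controller=replace(self.controller, **ctrl_updates)
            if ctrl_updates
            else self.controller,
            oxygen_rate=rest.get("oxygen_rate", self.oxygen_rate),
        )
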