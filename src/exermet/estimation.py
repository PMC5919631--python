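"""Weighted nonlinear least-squares estimation of controller parameters.

The primary use is fitting the epinephrine→insulin coupling k5 to plasma
insulin and glucagon time courses measured around an exercise bout. Residuals
are weighted by the measurement error model — Gaussian with zero mean and a
constant percent coefficient of variation (4% by default) — and minimized by
Levenberg–Marquardt. Estimate precision is reported as the percent
coefficient of variation CV% = 100·SDe/|e|, with SDe the standard deviation
from the inverse of the Fisher information matrix JᵀJ formed from the
weighted sensitivity (Jacobian) at the optimum.

The module follows a Model/Results layout: build an
:class:`ExerciseHormoneModel` from an :class:`ObservationSet` plus the
subject/protocol context, call :meth:`~ExerciseHormoneModel.fit`, and read
estimates, CV%, residuals and the summary table off the returned
:class:`ExerciseHormoneResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import IdentifiabilityError, SolverFailure
from .hormones import ModelParameters
from .prescription import ExerciseProtocol
from .simulate import (
    ConstantGlucose,
    GlucoseProvider,
    SimulationSettings,
    simulate,
)
from .subject import SubjectProfile

__all__ = [
    "ObservationSet",
    "ExerciseHormoneModel",
    "ExerciseHormoneResults",
    "EstimationResult",
    "FITTABLE_PARAMETERS",
    "weighted_residuals",
    "fit_parameters",
    "cv_percent",
]

#: Parameters the objective knows how to vary (scalar model constants).
FITTABLE_PARAMETERS = (
    "k1", "k2", "k3", "k4", "k5",
    "c1", "c2", "c3", "d1", "d2", "d3", "f1", "vd",
)


@dataclass(frozen=True)
class ObservationSet:
    """Paired insulin/glucagon observations with their error model.

    times are minutes on the simulation clock, sorted strictly increasing;
    concentrations are pM and must be positive; ``cv`` is the fractional
    measurement coefficient of variation shared by both hormones.
    """

    times: np.ndarray
    insulin_obs: np.ndarray
    glucagon_obs: np.ndarray
    cv: float = 0.04
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be 1-D, non-empty, strictly increasing")
        for name in ("insulin_obs", "glucagon_obs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} must match times in length")
            if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be positive and finite")
        if not self.cv > 0:
            raise ValueError("cv must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "insulin_obs",
                           np.asarray(self.insulin_obs, dtype=float))
        object.__setattr__(self, "glucagon_obs",
                           np.asarray(self.glucagon_obs, dtype=float))

    def __len__(self) -> int:
        return int(self.times.size)

    def to_csv(self, path, sidecar: str | Path | None = None) -> None:
        pd.DataFrame(
            {"time_min": self.times, "insulin_pM": self.insulin_obs,
             "glucagon_pM": self.glucagon_obs}
        ).to_csv(path, index=False, float_format="%.17g")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump({"cv": self.cv, **self.meta}, fh, indent=1, default=str)

    @classmethod
    def from_csv(cls, path, cv: float = 0.04) -> "ObservationSet":
        df = pd.read_csv(path, float_precision="round_trip")
        required = ("time_min", "insulin_pM", "glucagon_pM")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"observation CSV missing columns: {missing}")
        bad = df[list(required)].isna().any(axis=1)
        if bad.any():
            raise ValueError(
                f"observation CSV has missing values at row(s) "
                f"{df.index[bad].tolist()}"
            )
        return cls(
            times=df["time_min"].to_numpy(),
            insulin_obs=df["insulin_pM"].to_numpy(),
            glucagon_obs=df["glucagon_pM"].to_numpy(),
            cv=cv,
        )


class ExerciseHormoneModel:
    """Hormone-controller model bound to observations, ready to fit.

    Parameters
    ----------
    obs : ObservationSet
    subject, protocol : the exercise context the data were collected under.
    params : ModelParameters, optional
        Fixed values for everything not being estimated.
    glucose : GlucoseProvider, optional
        Arterial glucose source (constant fasting level by default).
    settings : SimulationSettings, optional
        Solver settings; the horizon must cover the observation times.
    weight_by : {"observed", "predicted"}
        Denominator of the CV weights. "observed" (default) is the
        measurement-CV convention; "predicted" re-weights by the model value.
    """

    def __init__(
        self,
        obs: ObservationSet,
        subject: SubjectProfile,
        protocol: ExerciseProtocol,
        params: ModelParameters | None = None,
        glucose: GlucoseProvider | None = None,
        settings: SimulationSettings | None = None,
        weight_by: str = "observed",
    ):
        if weight_by not in ("observed", "predicted"):
            raise ValueError("weight_by must be 'observed' or 'predicted'")
        self.obs = obs
        self.subject = subject
        self.protocol = protocol
        self.params = params if params is not None else ModelParameters()
        self.glucose = glucose if glucose is not None else ConstantGlucose(5.0)
        t_end = max(float(obs.times[-1]), (protocol.t_end or 0.0))
        t0 = min(0.0, float(obs.times[0]))
        self.settings = settings or SimulationSettings(t0=t0, t_end=t_end)
        self.weight_by = weight_by

    # -- forward model -----------------------------------------------------
    def predict(self, overrides: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Simulated (insulin, glucagon) at the observation times."""
        params = self.params.with_updates(**overrides) if overrides else self.params
        traj = simulate(
            self.subject, self.protocol, params, self.glucose, self.settings,
            t_eval=self.obs.times,
        )
        return traj.ci, traj.cg

    def resid(self, overrides: dict | None = None) -> np.ndarray:
        """Weighted residuals (observed − simulated)/(cv·weight), insulin then glucagon."""
        ci, cg = self.predict(overrides)
        obs = self.obs
        if self.weight_by == "observed":
            wi, wg = obs.insulin_obs, obs.glucagon_obs
        else:
            wi, wg = ci, cg
        r_i = (obs.insulin_obs - ci) / (obs.cv * wi)
        r_g = (obs.glucagon_obs - cg) / (obs.cv * wg)
        return np.concatenate([r_i, r_g])

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        free: Sequence[str] = ("k5",),
        start: Sequence[float] | None = None,
        bounds: tuple | None = None,
        max_nfev: int = 200,
    ) -> "ExerciseHormoneResults":
        """Minimize the weighted SSE over ``free`` by Levenberg–Marquardt.

        ``start`` defaults to the bound parameter values. With ``bounds``
        the trust-region-reflective variant is used (Levenberg–Marquardt
        proper does not support box constraints). Non-convergence does not
        raise: the best point is returned with ``converged=False``.
        """
        free = tuple(free)
        for name in free:
            if name not in FITTABLE_PARAMETERS:
                raise ValueError(
                    f"{name!r} is not fittable; choose from {FITTABLE_PARAMETERS}"
                )
        if start is None:
            x0 = np.array([self._current_value(n) for n in free], dtype=float)
        else:
            x0 = np.asarray(start, dtype=float)
            if x0.shape != (len(free),):
                raise ValueError("start must provide one value per free parameter")

        def fun(x: np.ndarray) -> np.ndarray:
            try:
                return self.resid(dict(zip(free, x)))
            except SolverFailure as err:
                raise SolverFailure(
                    f"simulation failed at {dict(zip(free, x))}: {err}",
                    last_time=err.last_time,
                ) from err

        x_scale = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
        kwargs = dict(diff_step=1e-6, x_scale=x_scale, max_nfev=max_nfev,
                      xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if bounds is None:
            sol = least_squares(fun, x0, method="lm", **kwargs)
        else:
            sol = least_squares(fun, x0, method="trf", bounds=bounds, **kwargs)

        estimates = dict(zip(free, sol.x))
        resid = sol.fun
        sde, cvp = self._precision(free, sol.x)
        return ExerciseHormoneResults(
            model=self,
            free=free,
            params=pd.Series(estimates, dtype=float),
            bse=pd.Series(dict(zip(free, sde)), dtype=float),
            cv_percent=pd.Series(dict(zip(free, cvp)), dtype=float),
            weighted_residuals=resid,
            converged=bool(sol.status > 0),
            n_iter=int(sol.nfev),
            objective=float(np.sum(resid**2)),
            message=str(sol.message),
        )

    def _current_value(self, name: str) -> float:
        for block in (self.params.controller, self.params.epinephrine):
            if hasattr(block, name):
                return float(getattr(block, name))
        raise ValueError(f"unknown parameter {name!r}")  # pragma: no cover

    # -- precision ---------------------------------------------------------
    def jacobian(
        self, free: Sequence[str], x: np.ndarray, scheme: str = "forward",
        rel_step: float = 1e-6,
    ) -> np.ndarray:
        """Finite-difference Jacobian of the weighted residuals at ``x``.

        Forward differences by default; ``scheme="central"`` is a slower
        verification mode.
        """
        free = tuple(free)
        x = np.asarray(x, dtype=float)
        r0 = self.resid(dict(zip(free, x))) if scheme == "forward" else None
        cols = []
        for j, name in enumerate(free):
            hj = rel_step * max(abs(x[j]), 1e-300)
            xp = x.copy()
            xp[j] += hj
            rp = self.resid(dict(zip(free, xp)))
            if scheme == "central":
                xm = x.copy()
                xm[j] -= hj
                rm = self.resid(dict(zip(free, xm)))
                cols.append((rp - rm) / (2 * hj))
            else:
                cols.append((rp - r0) / hj)
        return np.column_stack(cols)

    def _precision(
        self, free: Sequence[str], x: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        jac = self.jacobian(free, x)
        fisher = jac.T @ jac
        svals = np.linalg.svd(fisher, compute_uv=False)
        if svals[-1] <= svals[0] * 1e-12 or svals[0] == 0:
            _, _, vt = np.linalg.svd(fisher)
            worst = tuple(free)[int(np.argmax(np.abs(vt[-1])))]
            raise IdentifiabilityError(
                f"Fisher information is singular; parameter {worst!r} is not "
                "identifiable from this design"
            )
        cov = np.linalg.inv(fisher)
        sde = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore"):
            cvp = 100.0 * sde / np.abs(x)
        return sde, cvp


@dataclass(frozen=True)
class ExerciseHormoneResults:
    """Estimates with Fisher-information precision and fit diagnostics."""

    model: ExerciseHormoneModel
    free: tuple
    params: pd.Series
    bse: pd.Series
    cv_percent: pd.Series
    weighted_residuals: np.ndarray
    converged: bool
    n_iter: int
    objective: float
    message: str = ""

    @property
    def estimates(self) -> dict:
        return self.params.to_dict()

    @property
    def resid(self) -> np.ndarray:
        return self.weighted_residuals

    def predict(self) -> tuple[np.ndarray, np.ndarray]:
        """Fitted (insulin, glucagon) at the observation times."""
        return self.model.predict(dict(zip(self.free, self.params.to_numpy())))

    def summary(self) -> str:
        lines = [
            "Exercise hormone controller — weighted nonlinear least squares",
            "=" * 64,
            f"Observations: {2 * len(self.model.obs)} "
            f"({len(self.model.obs)} time points x insulin, glucagon)",
            f"Measurement CV: {self.model.obs.cv:.2%}   "
            f"weights: {self.model.weight_by}",
            f"Converged: {self.converged}   evaluations: {self.n_iter}",
            f"Weighted SSE: {self.objective:.6g}",
            "-" * 64,
            f"{'parameter':<12}{'estimate':>16}{'SDe':>16}{'CV%':>10}",
        ]
        for name in self.free:
            lines.append(
                f"{name:<12}{self.params[name]:>16.6g}"
                f"{self.bse[name]:>16.6g}{self.cv_percent[name]:>10.3g}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable fit report."""
        r = self.weighted_residuals
        return {
            "estimates": self.params.to_dict(),
            "sde": self.bse.to_dict(),
            "cv_percent": self.cv_percent.to_dict(),
            "objective": self.objective,
            "converged": self.converged,
            "n_evaluations": self.n_iter,
            "residuals": {
                "n": int(r.size),
                "mean": float(np.mean(r)),
                "rms": float(np.sqrt(np.mean(r**2))),
                "max_abs": float(np.max(np.abs(r))),
            },
            "message": self.message,
        }


#: The spec-level name for the results object.
EstimationResult = ExerciseHormoneResults


# -- functional wrappers ----------------------------------------------------

def weighted_residuals(
    obs: ObservationSet,
    params: ModelParameters,
    subject: SubjectProfile,
    protocol: ExerciseProtocol,
    glucose: GlucoseProvider | None = None,
    settings: SimulationSettings | None = None,
    weight_by: str = "observed",
) -> np.ndarray:
    """Weighted residual vector at fixed parameters (insulin block then glucagon)."""
    model = ExerciseHormoneModel(obs, subject, protocol, params, glucose,
                                 settings, weight_by)
    return model.resid()


def fit_parameters(
    obs: ObservationSet,
    subject: SubjectProfile,
    protocol: ExerciseProtocol,
    free: Sequence[str] = ("k5",),
    init: Sequence[float] | None = None,
    bounds: tuple | None = None,
    params: ModelParameters | None = None,
    glucose: GlucoseProvider | None = None,
    settings: SimulationSettings | None = None,
) -> ExerciseHormoneResults:
    """Convenience wrapper: build the model and fit in one call."""
    model = ExerciseHormoneModel(obs, subject, protocol, params, glucose, settings)
    return model.fit(free=free, start=init, bounds=bounds)


def cv_percent(
    model: ExerciseHormoneModel,
    free: Sequence[str],
    estimates: Sequence[float],
    scheme: str = "forward",
) -> np.ndarray:
    """Fisher-information CV% (per free parameter) at given estimates."""
    x = np.asarray(estimates, dtype=float)
    jac = model.jacobian(free, x, scheme=scheme)
    fisher = jac.T @ jac
    svals = np.linalg.svd(fisher, compute_uv=False)
    if svals[-1] <= svals[0] * 1e-12 or svals[0] == 0:
        _, _, vt = np.linalg.svd(fisher)
        worst = tuple(free)[int(np.argmax(np.abs(vt[-1])))]
        raise IdentifiabilityError(
            f"Fisher information is singular at the estimate; parameter "
            f"{worst!r} is not identifiable from this design"
        )
    sde = np.sqrt(np.diag(np.linalg.inv(fisher)))
    return 100.0 * sde / np.abs(x)
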