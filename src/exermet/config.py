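"""Configuration handling: parameter files, run configs, hashing.

Parameter files are JSON with three blocks (``epinephrine``, ``controller``,
``oxygen``). A ``derived`` block (elimination constant k, controller offset h)
is emitted alongside for provenance but never read back — both constants are
recomputed from steady-state calibration at run time.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, Field

from .hormones import (
    EpinephrineParameters,
    HormoneControllerParameters,
    ModelParameters,
    calibrate_h,
    elimination_constant,
)
from .prescription import ExerciseProtocol
from .subject import SubjectProfile

__all__ = [
    "reference_parameters",
    "load_parameters",
    "parameters_from_dict",
    "parameters_to_dict",
    "parameters_hash",
    "RunConfig",
]

_SCALAR_FIELDS = {
    "epinephrine": tuple(EpinephrineParameters.__dataclass_fields__),
    "controller": tuple(
        f for f in HormoneControllerParameters.__dataclass_fields__
        if f not in ("phi", "psi")
    ),
}


def parameters_from_dict(data: dict[str, Any]) -> ModelParameters:
    """Build :class:`ModelParameters` from a parameter-file dictionary.

    Unknown keys (other than comment/derived blocks) are rejected so typos
    cannot silently fall back to defaults.
    """
    known = {"epinephrine", "controller", "oxygen", "derived", "_comment"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter blocks: {sorted(unknown)}")

    def block(name: str, allowed: tuple[str, ...]) -> dict[str, float]:
        raw = dict(data.get(name, {}))
        bad = set(raw) - set(allowed)
        if bad:
            raise ValueError(f"unknown keys in {name!r} block: {sorted(bad)}")
        return raw

    epi = EpinephrineParameters(**block("epinephrine", _SCALAR_FIELDS["epinephrine"]))
    ctrl = HormoneControllerParameters(**block("controller", _SCALAR_FIELDS["controller"]))
    oxy = block("oxygen", ("rate",))
    return ModelParameters(
        epinephrine=epi, controller=ctrl, oxygen_rate=float(oxy.get("rate", 0.8))
    )


def parameters_to_dict(
    params: ModelParameters, bw: float | None = None
) -> dict[str, Any]:
    """Serialize parameters, appending the derived (k, h) block for provenance."""
    out: dict[str, Any] = {
        "epinephrine": {
            f: getattr(params.epinephrine, f) for f in _SCALAR_FIELDS["epinephrine"]
        },
        "controller": {
            f: getattr(params.controller, f) for f in _SCALAR_FIELDS["controller"]
        },
        "oxygen": {"rate": params.oxygen_rate},
    }
    derived: dict[str, float] = {
        "h": calibrate_h(params.controller, params.epinephrine.cag_star)
    }
    if bw is not None:
        derived["k_per_min"] = elimination_constant(bw, params.epinephrine)
        derived["at_body_weight_kg"] = bw
    out["derived"] = derived
    return out


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a parameter JSON file."""
    with open(path) as fh:
        return parameters_from_dict(json.load(fh))


def reference_parameters() -> ModelParameters:
    """The packaged reference configuration (see the file's comment block)."""
    res = resources.files("exermet.data") / "reference_params.json"
    return parameters_from_dict(json.loads(res.read_text()))


def parameters_hash(params: ModelParameters) -> str:
    """Stable short hash of the scalar parameter values (for sidecars)."""
    payload = parameters_to_dict(params)
    payload.pop("derived", None)
    canon = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


class SimulationSettingsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    t0: float = 0.0
    t_end: Optional[float] = None
    output_grid: float = Field(default=1.0, gt=0)
    rel_tol: float = Field(default=1e-9, gt=0)
    abs_tol: float = Field(default=1e-11, gt=0)
    seed: int = 0


class RunConfig(BaseModel):
    """Validated run configuration for the command-line interface.

    Unknown keys anywhere in the document are rejected before any computation.
    """

    model_config = ConfigDict(extra="forbid")

    subject: SubjectProfile
    protocol: ExerciseProtocol
    params_file: Optional[str] = None
    glucose: str = "constant:5"
    settings: SimulationSettingsConfig = Field(default_factory=SimulationSettingsConfig)
    out_dir: str = "."
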