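"""Behavioral parameters of the living-bridge model.

The model is governed by ten parameters: four controlling the probability
that a passing ant stops to join the bridge (``alpha``, ``beta``, ``gamma``,
``theta``), two controlling how long a member stays as a function of the
traffic over its body (``rho``, ``sigma``), three shaping the fraction of
trail traffic an individual member intercepts (``phi``, ``psi``, ``omega``),
and the memory length ``m`` over which ants integrate the traffic they
experience.  The defaults are the field-fitted values for *Eciton
burchellii* bridges.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["BehaviorParams", "DEFAULT_PARAMS", "load_params", "save_params"]


@dataclass(frozen=True)
class BehaviorParams:
    """Parameter set of the individual-based bridge model.

    Parameters
    ----------
    alpha : float
        Lower asymptote of the join probability (dimensionless, in [0, 1]).
        Even under very heavy traffic a passing ant joins with this
        residual probability.
    beta : float
        Scale of the join sigmoid (dimensionless, > 0).  Large ``beta``
        pushes the join probability toward 1 on an empty, quiet gap.
    gamma : float
        Slope of the join sigmoid in trail traffic (per ants/s).
    theta : float
        Slope of the join sigmoid in bridge packing density (per ants/mm).
    rho : float
        Residence-time scale (seconds, > 0): the expected time an ant stays
        in the bridge when no traffic passes over it.
    sigma : float
        Residence-time exponent (per ants/s, >= 0): sensitivity of the
        residence time to the local traffic over the ant's body.
    phi, psi, omega : float
        Parameters of the traffic-share function mapping the packing
        density at the moment an ant joined to the fraction of bridge
        traffic passing over its body.
    m : int
        Memory length in seconds (>= 1) over which ants integrate the
        per-second traffic over their body.
    """

    alpha: float = 0.02
    beta: float = 144.5
    gamma: float = 3.258
    theta: float = 12.97
    rho: float = 1.959
    sigma: float = 2.789
    phi: float = -0.52
    psi: float = 3.0
    omega: float = 2.0
    m: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not self.rho > 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be an integer >= 1, got {self.m}")
        for name in ("alpha", "beta", "gamma", "theta", "rho", "sigma",
                     "phi", "psi", "omega"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        object.__setattr__(self, "m", int(self.m))

    def replace(self, **kwargs: Any) -> "BehaviorParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "BehaviorParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown parameter name(s): {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        return cls(**d)


DEFAULT_PARAMS = BehaviorParams()


def load_params(path: str | Path) -> BehaviorParams:
    """Read a :class:`BehaviorParams` from a YAML or JSON file.

    Missing fields fall back to the field-fitted defaults; unknown keys
    raise a ``ValueError`` naming the key.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    return BehaviorParams.from_dict(data)


def save_params(params: BehaviorParams, path: str | Path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
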