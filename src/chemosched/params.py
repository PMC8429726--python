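"""Model parameters and treatment configuration.

The package ships the literature rate constants for bone marrow, breast
cancer and ovarian cancer cells in ``data/parameters.yaml`` together with
the global treatment defaults (chemotherapeutic strength ``s``, penalty
weight ``b``, horizon ``T`` and the discrete action set).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "CompartmentParams",
    "ObjectiveConfig",
    "InvalidParameterError",
    "load_parameter_table",
    "load_tissue",
    "default_config",
    "TISSUES",
]

TISSUES = ("bone_marrow", "breast", "ovarian")

RATE_NAMES = ("gamma", "delta", "alpha", "beta", "lam")


class InvalidParameterError(ValueError):
    """Raised when a parameter set admits no valid steady state or is malformed."""


@dataclass(frozen=True)
class CompartmentParams:
    """Rate constants of one cell type plus the relative drug strength.

    Parameters
    ----------
    gamma : float
        Proliferation (self-renewal) rate of cycling cells, days^-1.
    delta : float
        Apoptosis rate of cycling cells, days^-1.
    alpha : float
        Transfer rate from the proliferative into the quiescent pool, days^-1.
    beta : float
        Transfer rate from the quiescent back into the proliferative pool,
        days^-1.
    lam : float
        Apoptosis rate of quiescent cells, days^-1.
    s : float
        Dimensionless relative strength of the chemotherapeutic; the drug
        kills proliferative cells at rate ``s * f(t)``.
    """

    gamma: float
    delta: float
    alpha: float
    beta: float
    lam: float
    s: float = 1.0

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise InvalidParameterError(f"rate {name!r} must be finite and >= 0, got {value}")
        if not np.isfinite(self.s) or self.s < 0:
            raise InvalidParameterError(f"drug strength s must be finite and >= 0, got {self.s}")

    def rates(self) -> dict[str, float]:
        """The five rate constants as a plain dict (without ``s``)."""
        return {name: getattr(self, name) for name in RATE_NAMES}

    def with_rate(self, name: str, value: float) -> "CompartmentParams":
        """A copy with one rate constant replaced (used by sensitivity runs)."""
        if name not in RATE_NAMES:
            raise KeyError(f"unknown rate {name!r}")
        return replace(self, **{name: value})


@dataclass(frozen=True)
class ObjectiveConfig:
    """Treatment horizon, decision interval, penalty weight and action set.

    The objective rewards bone-marrow mass while penalising withheld dose
    with weight ``b/2 * (1 - f)^2`` per unit time; ``actions`` is the
    admissible set of daily dose fractions.
    """

    b: float = 1.0
    T: int = 21
    dt: float = 1.0
    actions: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))

    def __post_init__(self) -> None:
        if self.b < 0:
            raise InvalidParameterError(f"penalty weight b must be >= 0, got {self.b}")
        if self.dt <= 0:
            raise InvalidParameterError(f"decision interval dt must be > 0, got {self.dt}")
        steps = self.T / self.dt
        if self.T <= 0 or abs(steps - round(steps)) > 1e-9:
            raise InvalidParameterError(
                f"horizon T={self.T} must be a positive integer multiple of dt={self.dt}"
            )
        acts = np.asarray(self.actions, dtype=float)
        if acts.ndim != 1 or len(acts) < 1:
            raise InvalidParameterError("actions must be a non-empty 1-d sequence")
        if np.any(acts < 0) or np.any(acts > 1):
            raise InvalidParameterError("actions must lie in [0, 1]")
        if len(acts) > 1:
            if np.any(np.diff(acts) <= 0):
                raise InvalidParameterError("actions must be strictly increasing")
            if acts[0] != 0.0 or acts[-1] != 1.0:
                raise InvalidParameterError("a multi-level action set must contain 0 and 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))

    @property
    def n_actions(self) -> int:
        return len(self.actions)


def _read_table() -> dict:
    path = resources.files("chemosched.data").joinpath("parameters.yaml")
    with path.open("r") as fh:
        return yaml.safe_load(fh)


def load_parameter_table() -> dict:
    """The packaged parameter file as nested dicts (tissues + defaults)."""
    return _read_table()


def load_tissue(name: str, s: float | None = None) -> CompartmentParams:
    """Rate constants for one tissue; ``s`` defaults to the packaged value."""
    table = _read_table()
    try:
        raw: Mapping[str, float] = table["tissues"][name]
    except KeyError:
        raise KeyError(f"unknown tissue {name!r}; available: {sorted(table['tissues'])}")
    if s is None:
        s = float(table["defaults"]["s"])
    return CompartmentParams(
        gamma=float(raw["gamma"]),
        delta=float(raw["delta"]),
        alpha=float(raw["alpha"]),
        beta=float(raw["beta"]),
        lam=float(raw["lambda"]),
        s=float(s),
    )


def default_config(**overrides) -> ObjectiveConfig:
    """The packaged :class:`ObjectiveConfig`, with optional field overrides."""
    defaults = _read_table()["defaults"]
    kwargs = dict(
        b=float(defaults["b"]),
        T=int(defaults["T"]),
        dt=float(defaults["dt"]),
        actions=tuple(float(a) for a in defaults["actions"]),
    )
    kwargs.update(overrides)
    return ObjectiveConfig(**kwargs)
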