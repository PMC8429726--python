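"""Two-compartment proliferative/quiescent growth model under chemotherapy.

The dynamics of one cell type are the linear system

    P' = (gamma - delta - alpha - s f(t)) P + beta Q
    Q' = alpha P - (beta + lam) Q

where ``f(t) in [0, 1]`` is the dose fraction.  Treatment quality over a
horizon ``T`` is scored by the functional

    J_b(f) = int_0^T [ P_bm + Q_bm - b/2 (1 - f)^2 ] dt

evaluated on the bone-marrow parameterization: the integrand rewards
surviving healthy marrow while the quadratic term penalises *withholding*
dose, so ``b`` trades drug delivery against toxicity.

Within one decision interval the dose is constant, so every step is an
exact linear map.  All propagation in this module therefore goes through
the matrix exponential of the (optionally integral-augmented) rate matrix;
adaptive ODE integration appears only as an independent oracle in the test
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .params import CompartmentParams, InvalidParameterError, ObjectiveConfig

__all__ = [
    "PopulationState",
    "AgentState",
    "steady_state_fraction",
    "initial_state",
    "rate_matrix",
    "propagate",
    "StepKernel",
    "step_reward",
    "episode_objective",
    "alt_objective",
    "simulate_schedule",
    "observation",
    "sensitivity_table",
]


@dataclass(frozen=True)
class PopulationState:
    """Relative proliferative (P) and quiescent (Q) cell mass.

    Masses are normalized so that P + Q = 1 at treatment start.
    """

    P: float
    Q: float

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0:
            raise InvalidParameterError(f"cell masses must be >= 0, got P={self.P}, Q={self.Q}")

    @property
    def total(self) -> float:
        return self.P + self.Q

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.Q], dtype=float)


@dataclass(frozen=True)
class AgentState:
    """Observable state of a feedback controller: the day index plus a
    most-recent-first window of relative bone-marrow totals.

    Pre-treatment slots are padded with 1.0 (the normalized mass before
    treatment), so at day 0 the vector reads <0, 1, 1, ..., 1>.
    """

    t: int
    window: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"day index must be >= 0, got {self.t}")
        if any(w <= 0 for w in self.window):
            raise ValueError("window entries must be > 0")

    @property
    def vector(self) -> np.ndarray:
        """The flat <t, w_0, ..., w_{wl-1}> vector fed to policies."""
        return np.array([float(self.t), *self.window], dtype=float)

    def __len__(self) -> int:
        return 1 + len(self.window)


def steady_state_fraction(params: CompartmentParams) -> float:
    """Steady-state proliferative fraction rho* of the untreated system.

    rho* is the root in (0, 1) of the quadratic

        (delta - gamma - lam) rho^2 + (gamma + lam - beta - alpha - delta) rho + beta = 0,

    the stationarity condition of the ratio P/(P+Q) with f = 0.

    Raises
    ------
    InvalidParameterError
        If no real root lies strictly inside (0, 1) — e.g. beta = 0, where
        the quiescent pool never feeds back and the fraction collapses to 0.
    """
    a = params.delta - params.gamma - params.lam
    b = params.gamma + params.lam - params.beta - params.alpha - params.delta
    c = params.beta

    if abs(a) < 1e-300:
        roots = [] if b == 0 else [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            raise InvalidParameterError("steady-state quadratic has no real root")
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]

    inside = [r for r in roots if 0.0 < r < 1.0]
    if len(inside) != 1:
        raise InvalidParameterError(
            f"expected exactly one steady-state fraction in (0, 1), found {inside!r} "
            f"for rates {params.rates()!r}"
        )
    rho = inside[0]
    residual = a * rho * rho + b * rho + c
    if abs(residual) > 1e-10:
        raise InvalidParameterError(f"steady-state root residual {residual:.3e} exceeds 1e-10")
    return rho


def initial_state(params: CompartmentParams) -> PopulationState:
    """Pre-treatment state (P, Q) = (rho*, 1 - rho*), normalized to total 1.

    The tumour (or marrow) is assumed to have grown untreated until the
    P/(P+Q) ratio equilibrated, then the total mass is scaled to 1.
    """
    rho = steady_state_fraction(params)
    return PopulationState(P=rho, Q=1.0 - rho)


def rate_matrix(params: CompartmentParams, dose: float = 0.0) -> np.ndarray:
    """The 2x2 rate matrix of the linear system at constant dose fraction."""
    return np.array(
        [
            [params.gamma - params.delta - params.alpha - params.s * dose, params.beta],
            [params.alpha, -(params.beta + params.lam)],
        ]
    )


def _augmented_step(params: CompartmentParams, dose: float, dt: float) -> np.ndarray:
    """exp(dt * M) for the 3x3 system augmented with the running integral
    of P + Q as a third coordinate."""
    M = np.zeros((3, 3))
    M[:2, :2] = rate_matrix(params, dose)
    M[2, 0] = M[2, 1] = 1.0
    return expm(dt * M)


def _check_dose(dose: float) -> None:
    if not 0.0 <= dose <= 1.0:
        raise ValueError(f"dose fraction must lie in [0, 1], got {dose}")


def propagate(
    state: PopulationState, params: CompartmentParams, dose: float, dt: float
) -> PopulationState:
    """Evolve (P, Q) for ``dt`` days at constant dose fraction.

    The system is linear and time-invariant within the step, so the result
    is the exact matrix-exponential solution.
    """
    _check_dose(dose)
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if dt == 0:
        return state
    E = expm(dt * rate_matrix(params, dose))
    P, Q = E @ state.as_array()
    return PopulationState(P=float(P), Q=float(Q))


class StepKernel:
    """Precomputed exact one-step operators for every action level.

    For each dose ``a`` in the action set, holding ``f = a`` for one
    decision interval ``dt`` maps the state ``x = (P, Q)`` to ``M_a x`` and
    accrues the running reward

        r(x, a) = w_a . x - b/2 (1 - a)^2 dt,

    where ``w_a . x`` is the exact integral of P + Q over the step (third
    row of the matrix exponential of the integral-augmented system).  The
    kernel is the single propagation backend shared by the optimal-control
    solver, the RL environment and the Monte-Carlo baselines.
    """

    def __init__(self, params: CompartmentParams, cfg: ObjectiveConfig):
        self.params = params
        self.cfg = cfg
        self.actions = np.asarray(cfg.actions, dtype=float)
        n = len(self.actions)
        self.M = np.empty((n, 2, 2))
        self.w = np.empty((n, 2))
        self.penalty = np.empty(n)
        for i, a in enumerate(self.actions):
            E = _augmented_step(params, float(a), cfg.dt)
            self.M[i] = E[:2, :2]
            self.w[i] = E[2, :2]
            self.penalty[i] = -cfg.b / 2.0 * (1.0 - a) ** 2 * cfg.dt
        self.x0 = initial_state(params).as_array()

    @property
    def n_steps(self) -> int:
        return self.cfg.n_steps

    def step(self, x: np.ndarray, action: int) -> tuple[np.ndarray, float]:
        """One decision step from state ``x``: returns (next state, reward)."""
        reward = float(self.w[action] @ x) + self.penalty[action]
        return self.M[action] @ x, reward

    def action_index(self, dose: float) -> int:
        idx = int(np.argmin(np.abs(self.actions - dose)))
        if abs(self.actions[idx] - dose) > 1e-9:
            raise ValueError(f"dose {dose} is not in the action set")
        return idx

    def rollout(self, actions: Sequence[int]) -> float:
        """Total objective of an action-index schedule from the initial state."""
        x = self.x0.copy()
        total = 0.0
        for a in actions:
            x, r = self.step(x, int(a))
            total += r
        return total


def step_reward(
    state: PopulationState,
    params_bm: CompartmentParams,
    dose: float,
    b: float,
    dt: float = 1.0,
) -> float:
    """Immediate reward of holding dose ``dose`` for one decision interval:
    the exact integral of bone-marrow mass minus the withheld-dose penalty

        R = int_t^{t+dt} (P_bm + Q_bm) ds - b/2 (1 - dose)^2 dt.
    """
    _check_dose(dose)
    E = _augmented_step(params_bm, dose, dt)
    integral = float(E[2, :2] @ state.as_array())
    return integral - b / 2.0 * (1.0 - dose) ** 2 * dt


def episode_objective(
    schedule: Sequence[float], params_bm: CompartmentParams, cfg: ObjectiveConfig
) -> float:
    """The objective J_b(f) of a piecewise-constant dose schedule.

    ``schedule`` lists dose fractions, one per decision interval, applied
    from the steady-state initial condition.  By linearity of the running
    integral this equals the sum of the per-step rewards exactly.
    """
    schedule = np.asarray(schedule, dtype=float)
    if len(schedule) != cfg.n_steps:
        raise ValueError(f"schedule length {len(schedule)} != T/dt = {cfg.n_steps}")
    x = np.append(initial_state(params_bm).as_array(), 0.0)
    penalty = 0.0
    steps = {}
    for dose in schedule:
        _check_dose(float(dose))
        key = float(dose)
        if key not in steps:
            steps[key] = _augmented_step(params_bm, key, cfg.dt)
        x = steps[key] @ x
        penalty += cfg.b / 2.0 * (1.0 - key) ** 2 * cfg.dt
    return float(x[2]) - penalty


def alt_objective(
    schedule: Sequence[float],
    params_bm: CompartmentParams,
    params_cancer: CompartmentParams,
    cfg: ObjectiveConfig,
) -> float:
    """Alternative objective: bone-marrow mass minus ``b`` times tumour mass,

        int_0^T [ P_bm + Q_bm - b (P_c + Q_c) ] dt,

    with the two decoupled model copies driven by the same schedule.
    """
    schedule = np.asarray(schedule, dtype=float)
    if len(schedule) != cfg.n_steps:
        raise ValueError(f"schedule length {len(schedule)} != T/dt = {cfg.n_steps}")
    integrals = []
    for params in (params_bm, params_cancer):
        x = np.append(initial_state(params).as_array(), 0.0)
        cache = {}
        for dose in schedule:
            _check_dose(float(dose))
            key = float(dose)
            if key not in cache:
                cache[key] = _augmented_step(params, key, cfg.dt)
            x = cache[key] @ x
        integrals.append(float(x[2]))
    return integrals[0] - cfg.b * integrals[1]


def simulate_schedule(
    params: CompartmentParams, cfg: ObjectiveConfig, schedule: Sequence[float]
) -> pd.DataFrame:
    """Daily trajectory under a dose schedule.

    Returns one row per day 0..T with columns P, Q, total and the dose
    applied over the following interval (NaN on the final day).
    """
    schedule = np.asarray(schedule, dtype=float)
    if len(schedule) != cfg.n_steps:
        raise ValueError(f"schedule length {len(schedule)} != T/dt = {cfg.n_steps}")
    x = initial_state(params).as_array()
    rows = [(0.0, x[0], x[1])]
    for dose in schedule:
        _check_dose(float(dose))
        x = expm(cfg.dt * rate_matrix(params, float(dose))) @ x
        rows.append((rows[-1][0] + cfg.dt, x[0], x[1]))
    df = pd.DataFrame(rows, columns=["day", "P", "Q"])
    df["total"] = df["P"] + df["Q"]
    df["dose"] = np.append(schedule, np.nan)
    return df


def observation(history: Sequence[float], t: int, wl: int = 10) -> AgentState:
    """Build the controller observation at day ``t`` from the list of daily
    relative bone-marrow totals for days 0..t (``history[d]`` = total at
    day d).  Entries for negative days are the pre-treatment value 1.0.
    """
    if t < 0:
        raise ValueError(f"day index must be >= 0, got {t}")
    if len(history) <= t:
        raise ValueError(f"history covers days 0..{len(history) - 1}, need day {t}")
    window = []
    for back in range(wl):
        day = t - back
        window.append(float(history[day]) if day >= 0 else 1.0)
    return AgentState(t=t, window=tuple(window))


def sensitivity_table(
    params: CompartmentParams, T: float = 21.0, dp: float = 0.01
) -> pd.DataFrame:
    """Local relative sensitivities of the untreated populations at day T.

    Each non-zero rate constant is scaled one-at-a-time by ``1 + dp``, the
    initial condition is re-derived from the perturbed steady state, the
    untreated system (f = 0) is run to day ``T``, and the relative
    sensitivity

        R_{x,p} = ((x - x0) / x0) / (dp)

    is recorded for x in {P(T), Q(T)}.  Rates whose nominal value is zero
    are excluded (a multiplicative perturbation cannot move them).

    Returns a DataFrame indexed by rate name with columns ``P`` and ``Q``.
    """
    if dp == 0:
        raise ValueError("perturbation fraction dp must be non-zero")

    def _final(p: CompartmentParams) -> np.ndarray:
        x0 = initial_state(p).as_array()
        return expm(T * rate_matrix(p, 0.0)) @ x0

    x_nom = _final(params)
    rows = {}
    for name, value in params.rates().items():
        if value == 0.0:
            continue
        perturbed = params.with_rate(name, value * (1.0 + dp))
        x = _final(perturbed)
        rows[name] = (x - x_nom) / x_nom / dp
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["P", "Q"])
    df.index.name = "parameter"
    return df
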