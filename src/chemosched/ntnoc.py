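"""Nearest-training-neighbour optimal controller (NTNOC).

A feedback baseline that gives the classical optimal controller access to
the same bone-marrow observations as the RL agent: the discrete optimal
control problem is solved for every training patient (whose parameters are
treated as known), the observation window and optimal dose are logged at
every treatment day, and at evaluation time each day's dose is replayed
from the training patient whose logged same-day state window is closest in
Euclidean distance to the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discrete_oc import solve
from .growth_model import AgentState, StepKernel, observation
from .params import CompartmentParams, InvalidParameterError, ObjectiveConfig
from .virtual_patients import Cohort, VirtualPatient

__all__ = ["StateLibrary", "build_library", "ntnoc_dose", "run_ntnoc"]

WINDOW_LENGTH = 10


@dataclass(frozen=True)
class StateLibrary:
    """Per-day bank of (observation window, optimal dose) pairs.

    ``windows[t]`` has one row per training patient: the ``wl`` most recent
    relative bone-marrow totals observed on day ``t`` while that patient
    followed its own optimal schedule; ``doses[t]`` holds the dose it took.
    Patient ids are stored sorted ascending so that distance ties resolve
    to the lowest id.
    """

    wl: int
    windows: tuple[np.ndarray, ...]  # per day: (n_patients, wl)
    doses: tuple[np.ndarray, ...]  # per day: (n_patients,)
    patient_ids: tuple[np.ndarray, ...]  # per day: (n_patients,)
    k: float = 0.0

    @property
    def n_days(self) -> int:
        return len(self.windows)

    @property
    def n_entries(self) -> int:
        return int(sum(len(d) for d in self.doses))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(self.n_days):
            for pid, win, dose in zip(self.patient_ids[t], self.windows[t], self.doses[t]):
                row = {"day": t, "patient_id": int(pid), "dose": float(dose)}
                row.update({f"w{j + 1}": float(w) for j, w in enumerate(win)})
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, k: float = 0.0) -> "StateLibrary":
        wl = sum(c.startswith("w") and c[1:].isdigit() for c in df.columns)
        wcols = [f"w{j + 1}" for j in range(wl)]
        windows, doses, ids = [], [], []
        for t in sorted(df["day"].unique()):
            sub = df[df["day"] == t].sort_values("patient_id")
            windows.append(sub[wcols].to_numpy(dtype=float))
            doses.append(sub["dose"].to_numpy(dtype=float))
            ids.append(sub["patient_id"].to_numpy(dtype=int))
        return cls(wl=wl, windows=tuple(windows), doses=tuple(doses), patient_ids=tuple(ids), k=k)

    @classmethod
    def from_csv(cls, path, k: float = 0.0) -> "StateLibrary":
        return cls.from_frame(pd.read_csv(path), k=k)


def build_library(training: Cohort, cfg: ObjectiveConfig, wl: int = WINDOW_LENGTH) -> StateLibrary:
    """Solve the discrete optimal control problem for every training
    patient, simulate each patient under its own optimal schedule, and log
    the (observation window, dose) pair at every day.

    A patient on which the solver fails is excluded with a warning; the
    exact backward-DP solver does not fail on valid parameter sets.
    """
    steps = cfg.n_steps
    per_day_windows: list[list[np.ndarray]] = [[] for _ in range(steps)]
    per_day_doses: list[list[float]] = [[] for _ in range(steps)]
    per_day_ids: list[list[int]] = [[] for _ in range(steps)]

    for patient in sorted(training, key=lambda p: p.id):
        try:
            sol = solve(patient.params, cfg)
        except InvalidParameterError as exc:  # pragma: no cover - defensive
            warnings.warn(f"excluding patient {patient.id}: optimal control failed ({exc})")
            continue
        kernel = StepKernel(patient.params, cfg)
        x = kernel.x0.copy()
        history = [float(x[0] + x[1])]
        for t, dose in enumerate(sol.schedule):
            obs = observation(history, t, wl)
            per_day_windows[t].append(np.array(obs.window))
            per_day_doses[t].append(float(dose))
            per_day_ids[t].append(patient.id)
            x, _ = kernel.step(x, kernel.action_index(dose))
            history.append(float(x[0] + x[1]))

    return StateLibrary(
        wl=wl,
        windows=tuple(np.array(w) for w in per_day_windows),
        doses=tuple(np.array(d) for d in per_day_doses),
        patient_ids=tuple(np.array(i) for i in per_day_ids),
        k=training.k,
    )


def ntnoc_dose(library: StateLibrary, obs: AgentState) -> float:
    """Dose of the Euclidean-nearest same-day training entry.

    Matching is restricted to entries logged at the observation's own day
    (so the day component of the state vector is constant and drops out of
    the distance); ties resolve to the lowest patient id.
    """
    t = obs.t
    if not 0 <= t < library.n_days:
        raise ValueError(f"day {t} outside library range 0..{library.n_days - 1}")
    bank = library.windows[t]
    if len(bank) == 0:
        raise ValueError(f"library has no entries for day {t}")
    query = np.asarray(obs.window, dtype=float)
    d2 = np.einsum("nj,nj->n", bank - query, bank - query)
    return float(library.doses[t][int(d2.argmin())])


def run_ntnoc(
    library: StateLibrary,
    patient: VirtualPatient | CompartmentParams,
    cfg: ObjectiveConfig,
) -> tuple[tuple[float, ...], float]:
    """Closed-loop NTNOC treatment of one test patient.

    Simulate the patient day by day, observe the bone-marrow window, query
    the library for the nearest neighbour's dose, apply it, repeat.
    Returns the realised schedule and its objective value.
    """
    params = patient.params if isinstance(patient, VirtualPatient) else patient
    kernel = StepKernel(params, cfg)
    x = kernel.x0.copy()
    history = [float(x[0] + x[1])]
    schedule = []
    score = 0.0
    for t in range(cfg.n_steps):
        obs = observation(history, t, library.wl)
        dose = ntnoc_dose(library, obs)
        x, r = kernel.step(x, kernel.action_index(dose))
        score += r
        schedule.append(dose)
        history.append(float(x[0] + x[1]))
    return tuple(schedule), score
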