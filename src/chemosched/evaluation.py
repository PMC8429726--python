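"""Controller evaluation on virtual-patient cohorts and robustness statistics.

Every controller is scored per patient by the treatment objective sigma and
normalised by that patient's theoretical maximum sigma(theta) (the exact
discrete optimal-control value with the parameters known), giving the
scaled score sigma_hat = sigma / sigma(theta) in (0, 1].  Open-loop
controllers apply one fixed schedule to every patient; feedback controllers
observe only the day index and the window of relative bone-marrow totals —
never the patient's rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ddqn import Policy
from .growth_model import AgentState, StepKernel, observation
from .ntnoc import StateLibrary, ntnoc_dose
from .params import CompartmentParams, ObjectiveConfig
from .virtual_patients import Cohort, VirtualPatient

__all__ = [
    "Controller",
    "FixedScheduleController",
    "PolicyController",
    "NTNOCController",
    "run_controller",
    "evaluate_controller",
    "random_baseline",
    "wilcoxon_one_sided",
    "ks_two_sample",
    "summarize",
    "HIST_BIN_WIDTH",
]

HIST_BIN_WIDTH = 0.025
SCALE_TOLERANCE = 1e-8  # slack on sigma_hat <= 1 (solver is exact; float noise only)


class Controller(Protocol):
    """A dosing agent: maps the current observation to a dose fraction."""

    tag: str

    def dose(self, obs: AgentState) -> float: ...


@dataclass(frozen=True)
class FixedScheduleController:
    """Open loop: the same pre-computed schedule for every patient."""

    schedule: tuple[float, ...]
    tag: str = "OC-nominal"

    def dose(self, obs: AgentState) -> float:
        return float(self.schedule[obs.t])


@dataclass(frozen=True)
class PolicyController:
    """Feedback: a trained greedy Q-policy fed the observation vector."""

    policy: Policy
    tag: str = "RL"

    def dose(self, obs: AgentState) -> float:
        return self.policy.dose(obs.vector)


@dataclass(frozen=True)
class NTNOCController:
    """Feedback: nearest-training-neighbour replay of logged optimal doses."""

    library: StateLibrary
    tag: str = "NTNOC"

    def dose(self, obs: AgentState) -> float:
        return ntnoc_dose(self.library, obs)


def run_controller(
    controller: Controller,
    params: CompartmentParams,
    cfg: ObjectiveConfig,
    wl: int = 10,
) -> tuple[tuple[float, ...], float]:
    """Closed-loop episode of one controller on one patient.

    Returns the realised schedule and its objective value.  The controller
    sees only observations; the parameters drive the simulation.
    """
    kernel = StepKernel(params, cfg)
    x = kernel.x0.copy()
    history = [float(x[0] + x[1])]
    schedule = []
    score = 0.0
    for t in range(cfg.n_steps):
        obs = observation(history, t, wl)
        dose = controller.dose(obs)
        x, r = kernel.step(x, kernel.action_index(dose))
        score += r
        schedule.append(float(dose))
        history.append(float(x[0] + x[1]))
    return tuple(schedule), score


def evaluate_controller(
    controller: Controller,
    cohort: Cohort,
    cfg: ObjectiveConfig,
    sigma_max: Mapping[int, float],
    wl: int = 10,
) -> pd.DataFrame:
    """Score a controller on every patient of a cohort.

    Returns one row per patient with the raw score sigma, the theoretical
    maximum sigma(theta) and the scaled score sigma_hat.  A scaled score
    above 1 (beyond float tolerance) indicates an inconsistent sigma_max
    table and raises.
    """
    rows = []
    for patient in cohort:
        if patient.id not in sigma_max:
            raise KeyError(f"no sigma_max entry for patient {patient.id}")
        _, sigma = run_controller(controller, patient.params, cfg, wl)
        smax = sigma_max[patient.id]
        sigma_hat = sigma / smax
        if sigma_hat > 1.0 + SCALE_TOLERANCE:
            raise ValueError(
                f"scaled score {sigma_hat} > 1 for patient {patient.id}: "
                "sigma_max is not the true per-patient optimum"
            )
        rows.append(
            {
                "patient_id": patient.id,
                "k": patient.k,
                "controller": controller.tag,
                "sigma": sigma,
                "sigma_max": smax,
                "sigma_hat": sigma_hat,
            }
        )
    return pd.DataFrame(rows)


def random_baseline(
    params: CompartmentParams,
    cfg: ObjectiveConfig,
    n_sims: int,
    seed: int,
    sigma_max: float | None = None,
) -> dict[str, float]:
    """Monte-Carlo score of the uniformly random dosing agent.

    Simulates ``n_sims`` episodes drawing an i.i.d. uniform action each
    day.  Reports the mean, the sample standard deviation and the standard
    error of the mean of the raw objective, plus the same three on the
    max-normalised scale when ``sigma_max`` is given.
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    kernel = StepKernel(params, cfg)
    rng = np.random.default_rng(seed)
    x = np.tile(kernel.x0, (n_sims, 1))
    scores = np.zeros(n_sims)
    for _ in range(cfg.n_steps):
        a = rng.integers(cfg.n_actions, size=n_sims)
        scores += np.einsum("nj,nj->n", kernel.w[a], x) + kernel.penalty[a]
        x = np.einsum("nij,nj->ni", kernel.M[a], x)
    out = {
        "mean": float(scores.mean()),
        "std": float(scores.std(ddof=1)) if n_sims > 1 else 0.0,
        "stderr": float(scores.std(ddof=1) / np.sqrt(n_sims)) if n_sims > 1 else 0.0,
        "n_sims": n_sims,
    }
    if sigma_max is not None:
        out["mean_scaled"] = out["mean"] / sigma_max
        out["std_scaled"] = out["std"] / sigma_max
        out["stderr_scaled"] = out["stderr"] / sigma_max
    return out


def wilcoxon_one_sided(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test on paired scaled scores.

    The statistic is the sum of the ranks of the positive differences
    ``x - y`` (average ranks on tied magnitudes); zero differences are
    discarded, the classical convention.  ``alternative='greater'`` tests
    whether the median of ``x`` exceeds that of ``y``.  Raises if all
    differences are zero (the test is degenerate there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(x - y == 0.0):
        raise ValueError("all paired differences are zero; the signed-rank test is degenerate")
    n_nonzero = int(np.sum(x - y != 0.0))
    method = "exact" if n_nonzero <= 25 else "approx"
    res = stats.wilcoxon(x, y, alternative=alternative, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: sup-distance of the empirical
    CDFs with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    res = stats.ks_2samp(x, y)
    return float(res.statistic), float(res.pvalue)


def score_histogram(sigma_hat: Sequence[float], bin_width: float = HIST_BIN_WIDTH) -> pd.DataFrame:
    """Histogram of scaled scores with bin edges at multiples of
    ``bin_width`` covering (0, 1]."""
    n_bins = int(round(1.0 / bin_width))
    edges = np.round(np.linspace(0.0, 1.0, n_bins + 1), 10)
    vals = np.clip(np.asarray(sigma_hat, dtype=float), None, 1.0)
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame({"left": edges[:-1], "right": edges[1:], "count": counts})


def summarize(records: pd.DataFrame) -> dict:
    """Cross-controller summary of an evaluation table.

    Expects the concatenated output of :func:`evaluate_controller` for one
    cohort and several controllers.  Returns per-controller medians, means
    and standard deviations of the scaled scores, per-patient paired
    differences for every controller pair, and 0.025-wide score
    histograms.
    """
    required = {"patient_id", "controller", "sigma_hat"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    controllers = list(records["controller"].unique())
    stats_table = (
        records.groupby("controller")["sigma_hat"].agg(["median", "mean", "std", "count"])
    )
    pivot = records.pivot(index="patient_id", columns="controller", values="sigma_hat")
    if pivot.isna().any().any():
        raise ValueError("cohorts are not matched: some patients lack scores for a controller")
    differences = {}
    gaps = {}
    for i, a in enumerate(controllers):
        for b in controllers[i + 1 :]:
            diff = (pivot[a] - pivot[b]).rename(f"{a}-{b}")
            differences[(a, b)] = diff
            gaps[(a, b)] = {
                "median_gap": float(pivot[a].median() - pivot[b].median()),
                "mean_gap": float(pivot[a].mean() - pivot[b].mean()),
            }
    histograms = {
        tag: score_histogram(records.loc[records["controller"] == tag, "sigma_hat"])
        for tag in controllers
    }
    return {
        "stats": stats_table,
        "differences": differences,
        "gaps": gaps,
        "histograms": histograms,
    }
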