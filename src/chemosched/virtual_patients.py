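"""Virtual-patient cohorts by Latin hypercube perturbation.

A virtual patient is the bone-marrow parameter set with the four non-zero
rates (gamma, alpha, beta, lam) scaled by independent factors drawn
uniformly from [1-k, 1+k] via Latin hypercube sampling; delta is zero for
bone marrow and is never perturbed.  Training cohorts (1000 patients, used
to build the nearest-neighbour controller) and testing cohorts (200
patients, used only for evaluation) are generated at k = 0.15, 0.20, 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .growth_model import steady_state_fraction
from .params import CompartmentParams, load_tissue

__all__ = [
    "VirtualPatient",
    "Cohort",
    "nominal_patient",
    "sample_cohort",
    "sample_training_cohort",
    "sample_testing_cohort",
    "PERTURBATION_LEVELS",
    "TRAINING_SIZE",
    "TESTING_SIZE",
]

PERTURBED_RATES = ("gamma", "alpha", "beta", "lam")
PERTURBATION_LEVELS = (0.15, 0.20, 0.25)
TRAINING_SIZE = 1000
TESTING_SIZE = 200
ROLES = ("nominal", "training", "testing")


@dataclass(frozen=True)
class VirtualPatient:
    """One bone-marrow parameterization, nominal or perturbed."""

    id: int
    k: float
    factors: tuple[float, float, float, float]  # scales for gamma, alpha, beta, lam
    params: CompartmentParams

    def __post_init__(self) -> None:
        lo, hi = 1.0 - self.k, 1.0 + self.k
        if any(not lo <= f <= hi for f in self.factors):
            raise ValueError(f"factors {self.factors} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class Cohort:
    """An ordered, reproducible set of virtual patients."""

    role: str
    k: float
    seed: int
    patients: tuple[VirtualPatient, ...]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def factor_matrix(self) -> np.ndarray:
        return np.array([p.factors for p in self.patients])

    def to_frame(self) -> pd.DataFrame:
        """Tabular form with both factors and derived rates, replayable."""
        rows = []
        for p in self.patients:
            r = p.params.rates()
            rows.append(
                {
                    "id": p.id,
                    "k": p.k,
                    "factor_gamma": p.factors[0],
                    "factor_alpha": p.factors[1],
                    "factor_beta": p.factors[2],
                    "factor_lambda": p.factors[3],
                    "gamma": r["gamma"],
                    "delta": r["delta"],
                    "alpha": r["alpha"],
                    "beta": r["beta"],
                    "lambda": r["lam"],
                    "s": p.params.s,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, role: str = "testing", seed: int = -1) -> "Cohort":
        df = pd.read_csv(path)
        patients = []
        for _, row in df.iterrows():
            params = CompartmentParams(
                gamma=row["gamma"],
                delta=row["delta"],
                alpha=row["alpha"],
                beta=row["beta"],
                lam=row["lambda"],
                s=row.get("s", 1.0),
            )
            patients.append(
                VirtualPatient(
                    id=int(row["id"]),
                    k=float(row["k"]),
                    factors=(
                        row["factor_gamma"],
                        row["factor_alpha"],
                        row["factor_beta"],
                        row["factor_lambda"],
                    ),
                    params=params,
                )
            )
        k = float(df["k"].iloc[0]) if len(df) else 0.0
        return cls(role=role, k=k, seed=seed, patients=tuple(patients))


def nominal_patient(s: float | None = None) -> VirtualPatient:
    """The mean-value bone-marrow patient from the packaged parameter table."""
    params = load_tissue("bone_marrow", s=s)
    return VirtualPatient(id=0, k=0.0, factors=(1.0, 1.0, 1.0, 1.0), params=params)


def sample_cohort(
    n: int,
    k: float,
    seed: int,
    role: str = "testing",
    s: float | None = None,
) -> Cohort:
    """Draw ``n`` virtual patients at perturbation strength ``k``.

    Factors for (gamma, alpha, beta, lam) come from a 4-dimensional Latin
    hypercube over [1-k, 1+k]^4: each dimension is split into ``n`` equal
    strata containing exactly one sample, with uniform placement within a
    stratum and independent per-dimension stratum permutations.  k = 0
    reproduces the nominal patient n times.  Every sampled patient is
    checked to admit a valid steady-state fraction in (0, 1); at k <= 0.25
    this never requires resampling, and a failure raises rather than being
    silently fixed.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if not 0.0 <= k < 1.0:
        raise ValueError(f"perturbation strength k must lie in [0, 1), got {k}")
    base = nominal_patient(s=s)
    rates = base.params.rates()

    if k == 0.0:
        factors = np.ones((n, 4))
    else:
        sampler = qmc.LatinHypercube(d=4, seed=seed)
        factors = qmc.scale(sampler.random(n), 1.0 - k, 1.0 + k)

    patients = []
    for i in range(n):
        f = factors[i]
        params = CompartmentParams(
            gamma=rates["gamma"] * f[0],
            delta=0.0,
            alpha=rates["alpha"] * f[1],
            beta=rates["beta"] * f[2],
            lam=rates["lam"] * f[3],
            s=base.params.s,
        )
        steady_state_fraction(params)  # raises if the patient is invalid
        patients.append(
            VirtualPatient(id=i, k=k, factors=tuple(float(x) for x in f), params=params)
        )
    return Cohort(role=role, k=k, seed=seed, patients=tuple(patients))


def sample_training_cohort(k: float, seed: int, n: int = TRAINING_SIZE, s: float | None = None) -> Cohort:
    """A training cohort (reference size: 1000 patients)."""
    return sample_cohort(n, k, seed, role="training", s=s)


def sample_testing_cohort(k: float, seed: int, n: int = TESTING_SIZE, s: float | None = None) -> Cohort:
    """A testing cohort (reference size: 200 patients)."""
    return sample_cohort(n, k, seed, role="testing", s=s)
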