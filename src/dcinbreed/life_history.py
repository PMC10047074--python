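"""Individual life histories and the Leslie-matrix growth-rate statistic.

Each sampled female contributes a realized life table: the ages at which she
produced a pup, her last observed age, and the study horizon (19 years for
this population — the shortest complete observation window across birth
cohorts). The individual fitness statistic r_i is the natural log of the
dominant eigenvalue of a Leslie matrix built from her pupping schedule with
unit survival through the last pup age and fecundity one at each pup age, so
that a female with a single pup has r_i = 0 exactly and the maximal
19-year schedule (maturity at 4, a pup every year to 19) attains the
censoring bound.

The matrix convention places the fecundity for a pup at maternal age ``a`` at
age class ``a - 1`` (1-indexed), making the characteristic equation

    sum_{a in pup_ages} lambda^-(a-1) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

#: log dominant eigenvalue of the maximal 19-year schedule under this
#: convention; responses at or above this value are treated as censored.
MAX_RI_19 = 0.3819509

MIN_AFR = 4  # youngest recorded age at first reproduction in the population
DEFAULT_HORIZON = 19


@dataclass
class LifeHistory:
    id: str
    birth_year: int
    dellbridge: int  # 1 if born in a Dellbridge Islands colony
    pup_ages: list[int]
    last_observed_age: int
    horizon: int = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        self.pup_ages = sorted(int(a) for a in self.pup_ages)
        if not self.pup_ages:
            raise ValueError(f"{self.id}: only reproductive females are sampled")
        if self.pup_ages[0] < MIN_AFR or self.pup_ages[-1] > self.horizon:
            raise ValueError(
                f"{self.id}: pup ages must lie in [{MIN_AFR}, {self.horizon}]"
            )
        if len(set(self.pup_ages)) != len(self.pup_ages):
            raise ValueError(f"{self.id}: duplicate pup ages")
        if self.last_observed_age < self.pup_ages[-1]:
            raise ValueError(f"{self.id}: last observation precedes last pup")
        if self.dellbridge not in (0, 1):
            raise ValueError(f"{self.id}: dellbridge must be 0/1")


@dataclass
class FitnessRecord:
    """The four model responses derived from one life history."""

    id: str
    r_i: float
    death_age: int  # meaningful only when not censored
    death_censored: bool
    afr: int
    waits: list[tuple[int, int]]  # (interval_years, first_flag)
    dellbridge: int
    birth_year: int


def leslie_matrix(pup_ages: list[int], horizon: int = DEFAULT_HORIZON) -> np.ndarray:
    """Leslie matrix for one pupping schedule.

    Age classes run up to the last pup age minus one; survival is 1 on the
    sub-diagonal and fecundity 1 is placed at class ``a - 1`` for each pup at
    maternal age ``a``.
    """
    if not pup_ages:
        raise ValueError("empty pupping schedule")
    ages = sorted(set(int(a) for a in pup_ages))
    if ages[0] < 2 or ages[-1] > horizon:
        raise ValueError(f"pup ages must lie in [2, {horizon}]")
    dim = ages[-1] - 1
    M = np.zeros((dim, dim))
    for a in ages:
        M[0, a - 2] = 1.0
    for j in range(1, dim):
        M[j, j - 1] = 1.0
    return M


def dominant_eigenvalue(M: np.ndarray, tol: float = 1e-14, max_iter: int = 200000) -> float:
    """Dominant eigenvalue by power iteration (Perron root of a non-negative matrix).

    Iterates on M + I: the shift makes the matrix primitive even for
    periodic schedules (e.g. a pup exactly every k-th year), where plain
    power iteration would oscillate, and leaves the dominant eigenvector
    unchanged.
    """
    A = M + np.eye(M.shape[0])
    v = np.ones(M.shape[0])
    lam = 1.0
    quiet = 0
    for _ in range(max_iter):
        w = A @ v
        new = float(np.linalg.norm(w))
        if new == 0.0:
            raise ValueError("matrix is nilpotent; no positive dominant eigenvalue")
        w /= new
        # slowly-converging subdominant modes (complex pairs) make single-step
        # stationarity unreliable; demand it persist across many iterations
        quiet = quiet + 1 if abs(new - lam) < tol * max(1.0, new) else 0
        if quiet >= 50:
            return new - 1.0
        lam, v = new, w
    return lam - 1.0


def growth_rate_root(pup_ages: list[int]) -> float:
    """Dominant eigenvalue via the characteristic equation (bisection cross-check).

    Solves ``sum lambda^-(a-1) = 1`` by Brent's method; independent of the
    matrix/eigenvalue route.
    """
    ages = sorted(set(int(a) for a in pup_ages))

    def f(lam: float) -> float:
        return sum(lam ** -(a - 1) for a in ages) - 1.0

    return brentq(f, 0.5, 4.0, xtol=1e-14)


def individual_growth_rate(pup_ages: list[int], horizon: int = DEFAULT_HORIZON) -> float:
    """r_i: natural log of the dominant eigenvalue of the individual Leslie matrix."""
    lam = dominant_eigenvalue(leslie_matrix(pup_ages, horizon))
    return float(np.log(lam))


def max_growth_rate_bound(horizon: int = DEFAULT_HORIZON, min_afr: int = MIN_AFR) -> float:
    """Maximum observable r_i: a pup every year from ``min_afr`` to ``horizon``."""
    if min_afr > horizon:
        raise ValueError("min_afr must not exceed the horizon")
    return individual_growth_rate(list(range(min_afr, horizon + 1)), horizon)


def derive_responses(lh: LifeHistory) -> FitnessRecord:
    """Convert a life history to the four model responses.

    afr is the first pup age; waits are successive pup-age differences with a
    flag marking the interval that follows the first pup; death age is the
    last observed age, censored when the female was still alive at the
    horizon; r_i comes from the Leslie matrix.
    """
    afr = lh.pup_ages[0]
    waits = [
        (b - a, 1 if i == 0 else 0)
        for i, (a, b) in enumerate(zip(lh.pup_ages[:-1], lh.pup_ages[1:]))
    ]
    censored = lh.last_observed_age >= lh.horizon
    return FitnessRecord(
        id=lh.id,
        r_i=individual_growth_rate(lh.pup_ages, lh.horizon),
        death_age=min(lh.last_observed_age, lh.horizon),
        death_censored=censored,
        afr=afr,
        waits=waits,
        dellbridge=lh.dellbridge,
        birth_year=lh.birth_year,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_life_histories(path: str, horizon: int = DEFAULT_HORIZON) -> list[LifeHistory]:
    """Read the life-history CSV (id, birth_year, dellbridge, pup_ages, last_observed_age).

    ``pup_ages`` is a semicolon-separated list of integer ages.
    """
    df = pd.read_csv(path, dtype={"id": str})
    out = []
    for rec in df.itertuples(index=False):
        ages = [int(a) for a in str(rec.pup_ages).split(";") if a != ""]
        out.append(
            LifeHistory(
                id=str(rec.id),
                birth_year=int(rec.birth_year),
                dellbridge=int(rec.dellbridge),
                pup_ages=ages,
                last_observed_age=int(rec.last_observed_age),
                horizon=horizon,
            )
        )
    return out


def write_life_histories(histories: list[LifeHistory], path: str) -> None:
    pd.DataFrame(
        {
            "id": [h.id for h in histories],
            "birth_year": [h.birth_year for h in histories],
            "dellbridge": [h.dellbridge for h in histories],
            "pup_ages": [";".join(map(str, h.pup_ages)) for h in histories],
            "last_observed_age": [h.last_observed_age for h in histories],
        }
    ).to_csv(path, index=False)


def records_to_frame(records: list[FitnessRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "r_i": [r.r_i for r in records],
            "death_age": [r.death_age for r in records],
            "death_censored": [r.death_censored for r in records],
            "afr": [r.afr for r in records],
            "waits": [";".join(f"{w}:{f}" for w, f in r.waits) for r in records],
            "dellbridge": [r.dellbridge for r in records],
            "birth_year": [r.birth_year for r in records],
        }
    )
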