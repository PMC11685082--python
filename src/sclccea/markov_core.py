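"""Time-varying three-state Markov cohort engine (PFS / PD / Death).

A cohort starting 100% progression-free is pushed through 21-day cycles using
transition probabilities derived from the extrapolated OS and PFS curves:

    p_death(t)    = max(1 - S_OS(t+1)/S_OS(t), background mortality for the
                        cohort's current age),
    p_exit_pfs(t) = 1 - S_PFS(t+1)/S_PFS(t),
    p_pfs->pd(t)  = max(0, p_exit_pfs - p_death).

The death hazard applies equally from PFS and PD, which makes the Markov
trace reproduce partitioned-survival state membership exactly whenever the
background-mortality floor does not bind.  PD is subdivided into tunnel
compartments indexed by cycles since progression (the last compartment
pools), so per-cycle costs that depend on time in PD — the 24-month cap on
post-progression immunotherapy — can be attached exactly.  State membership
used for accumulation is the life-table (half-cycle) average of cycle start
and end occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CYCLE_DAYS",
    "ModelClock",
    "LifeTable",
    "TransitionRow",
    "CohortTrace",
    "background_cycle_prob",
    "transition_row",
    "transition_rows",
    "run_cohort",
]

CYCLE_DAYS = 21.0


@dataclass(frozen=True)
class ModelClock:
    """Cycle/horizon bookkeeping: 21-day cycles, 10-year horizon, start age 62."""

    cycle_days: float = CYCLE_DAYS
    horizon_years: float = 10.0
    start_age_years: float = 62.0

    @property
    def n_cycles(self) -> int:
        return math.ceil(self.horizon_years * 365.25 / self.cycle_days)

    def age_at(self, cycle: int | np.ndarray) -> float | np.ndarray:
        """Age advances continuously with model time."""
        return self.start_age_years + np.asarray(cycle) * self.cycle_days / 365.25

    def day_at(self, cycle) -> np.ndarray:
        return np.asarray(cycle) * self.cycle_days


@dataclass
class LifeTable:
    """Age-indexed annual all-cause mortality probabilities q_x."""

    age_years: np.ndarray
    annual_mortality: np.ndarray

    def __post_init__(self) -> None:
        self.age_years = np.asarray(self.age_years, dtype=int)
        self.annual_mortality = np.asarray(self.annual_mortality, dtype=float)
        if np.any((self.annual_mortality < 0) | (self.annual_mortality > 1)):
            raise ValueError("annual mortality must lie in [0, 1]")
        if np.any(np.diff(self.age_years) != 1):
            raise ValueError("life table ages must be consecutive integers")

    def annual_q(self, age_years: float) -> float:
        a = int(math.floor(age_years))
        if a < self.age_years[0] or a > self.age_years[-1]:
            raise ValueError(f"age {age_years:.1f} outside life table range "
                             f"[{self.age_years[0]}, {self.age_years[-1]}]")
        return float(self.annual_mortality[a - self.age_years[0]])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    @classmethod
    def bundled_china_2022(cls) -> "LifeTable":
        """Synthetic stand-in for the China 2022 national life table
        (Gompertz approximation calibrated to plausible all-cause rates)."""
        with resources.files("sclccea.data").joinpath(
            "lifetable_china2022_synthetic.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())


def background_cycle_prob(lifetable: LifeTable, age_years: float,
                          cycle_days: float = CYCLE_DAYS) -> float:
    """Per-cycle background death probability from the annual rate:
    q_cycle = 1 - (1 - q_annual)^(cycle_days/365.25)."""
    q = lifetable.annual_q(age_years)
    return 1.0 - (1.0 - q) ** (cycle_days / 365.25)


@dataclass(frozen=True)
class TransitionRow:
    """Transition probabilities for one cycle; death is absorbing."""

    cycle_index: int
    p_pfs_pfs: float
    p_pfs_pd: float
    p_pfs_death: float
    p_pd_pd: float
    p_pd_death: float

    def __post_init__(self) -> None:
        probs = (self.p_pfs_pfs, self.p_pfs_pd, self.p_pfs_death,
                 self.p_pd_pd, self.p_pd_death)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in probs):
            raise ValueError(f"cycle {self.cycle_index}: probabilities outside [0, 1]")
        if abs(self.p_pfs_pfs + self.p_pfs_pd + self.p_pfs_death - 1) > 1e-9:
            raise ValueError(f"cycle {self.cycle_index}: PFS row does not sum to 1")
        if abs(self.p_pd_pd + self.p_pd_death - 1) > 1e-9:
            raise ValueError(f"cycle {self.cycle_index}: PD row does not sum to 1")


def transition_row(t: int, curves, strategy: str, lifetable: LifeTable | None,
                   clock: ModelClock) -> TransitionRow:
    """Time-varying transition probabilities for cycle t from the curve set."""
    s_os, s_pfs = curves.evaluate(strategy, clock.day_at(np.array([t, t + 1])))
    s_os0, s_os1 = s_os
    s_pfs0, s_pfs1 = s_pfs
    if s_os0 <= 0:
        return TransitionRow(t, 0.0, 0.0, 1.0, 0.0, 1.0)
    p_death = 1.0 - s_os1 / s_os0
    if lifetable is not None:
        p_death = max(p_death, background_cycle_prob(
            lifetable, float(clock.age_at(t)), clock.cycle_days))
    p_death = min(max(p_death, 0.0), 1.0)
    p_exit = 1.0 - (s_pfs1 / s_pfs0 if s_pfs0 > 0 else 1.0)
    p_pd = min(max(p_exit - p_death, 0.0), 1.0 - p_death)
    return TransitionRow(
        t,
        p_pfs_pfs=1.0 - p_pd - p_death,
        p_pfs_pd=p_pd,
        p_pfs_death=p_death,
        p_pd_pd=1.0 - p_death,
        p_pd_death=p_death,
    )


def transition_rows(curves, strategy: str, lifetable: LifeTable | None,
                    clock: ModelClock) -> list[TransitionRow]:
    return [transition_row(t, curves, strategy, lifetable, clock)
            for t in range(clock.n_cycles)]


@dataclass
class CohortTrace:
    """Per-cycle state membership with PD tunnel compartments.

    State arrays have ``n_cycles + 1`` entries (cycle boundaries); the
    ``*_bar`` arrays are the life-table corrected memberships (average of
    start and end of each of the ``n_cycles`` cycles) used for accumulation.
    ``tunnel[t, j]`` is occupancy of the PD compartment j cycles after
    progression; the last column pools everything beyond.
    """

    pfs: np.ndarray
    tunnel: np.ndarray
    death: np.ndarray
    new_deaths: np.ndarray
    new_progressions: np.ndarray
    clock: ModelClock = field(default_factory=ModelClock)

    @property
    def pd_total(self) -> np.ndarray:
        return self.tunnel.sum(axis=1)

    @property
    def alive(self) -> np.ndarray:
        return self.pfs + self.pd_total

    @property
    def pfs_bar(self) -> np.ndarray:
        return 0.5 * (self.pfs[:-1] + self.pfs[1:])

    @property
    def pd_bar(self) -> np.ndarray:
        return 0.5 * (self.pd_total[:-1] + self.pd_total[1:])

    @property
    def alive_bar(self) -> np.ndarray:
        return self.pfs_bar + self.pd_bar

    @property
    def tunnel_bar(self) -> np.ndarray:
        return 0.5 * (self.tunnel[:-1] + self.tunnel[1:])

    def to_frame(self) -> pd.DataFrame:
        n = len(self.new_deaths)
        return pd.DataFrame({
            "cycle": np.arange(n),
            "pfs": self.pfs[:-1], "pd": self.pd_total[:-1], "death": self.death[:-1],
            "pfs_bar": self.pfs_bar, "pd_bar": self.pd_bar,
            "new_deaths": self.new_deaths, "new_progressions": self.new_progressions,
        })


def run_cohort(rows: list[TransitionRow], clock: ModelClock,
               n_tunnel: int = 35) -> CohortTrace:
    """Forward cohort simulation from 100% PFS with PD tunnel bookkeeping.

    ``n_tunnel`` compartments track cycles since progression (24 months is
    about 34.8 cycles, rounded up to 35); one extra pooled compartment
    collects the cohort beyond that.
    """
    n = len(rows)
    if n < clock.n_cycles:
        raise ValueError(f"{n} transition rows for {clock.n_cycles} cycles")
    width = n_tunnel + 1
    pfs = np.zeros(n + 1)
    tunnel = np.zeros((n + 1, width))
    death = np.zeros(n + 1)
    new_deaths = np.zeros(n)
    new_prog = np.zeros(n)
    pfs[0] = 1.0
    for t in range(n):
        r = rows[t]
        dying = pfs[t] * r.p_pfs_death + tunnel[t].sum() * r.p_pd_death
        prog = pfs[t] * r.p_pfs_pd
        pfs[t + 1] = pfs[t] * r.p_pfs_pfs
        tunnel[t + 1, 0] = prog
        tunnel[t + 1, 1:-1] = tunnel[t, :-2] * r.p_pd_pd
        tunnel[t + 1, -1] = (tunnel[t, -2] + tunnel[t, -1]) * r.p_pd_pd
        death[t + 1] = death[t] + dying
        new_deaths[t] = dying
        new_prog[t] = prog
        total = pfs[t + 1] + tunnel[t + 1].sum() + death[t + 1]
        if abs(total - 1.0) > 1e-9:
            raise RuntimeError(f"cycle {t}: membership sums to {total}, not 1")
    return CohortTrace(pfs=pfs, tunnel=tunnel, death=death,
                       new_deaths=new_deaths, new_progressions=new_prog, clock=clock)
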