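"""Costing, utilities, discounting, and incremental cost-effectiveness ratios.

Costs are attached per cycle to the life-table-corrected trace membership:

* PFS drug costs: the EC backbone (etoposide + carboplatin) is given for the
  first four cycles only; benmelstobart and/or anlotinib continue every cycle
  until progression, per arm definition.
* PD drug costs: each tunnel compartment pays the mix-weighted per-cycle cost
  of subsequent treatment categories; the immunotherapy (pembrolizumab)
  fraction switches to best-supportive-care cost after 24 months in PD.
* Adverse-event management costs and disutilities are one-off, applied to the
  full cohort in the first cycle at the trial incidence rates (grade >= 3,
  incidence >= 5%).
* Follow-up visits (laboratory + imaging) follow the guideline schedule
  (every 2 months in year 1, every 3 months in years 2-3, every 6 months in
  years 4-5, annually beyond), costed per visit and prorated per cycle.
* End-of-life (palliative) care is a lump sum at the death transition.

Utilities: state utilities (PFS 0.84, PD 0.473) are uplifted by the per-arm
EQ-VAS improvement rate up to the trial-cutoff horizon, unadjusted after.
Both streams discount at 5%/year at cycle midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov_core import CYCLE_DAYS, CohortTrace, ModelClock

__all__ = [
    "AdverseEvent",
    "SubsequentMix",
    "StrategyEconomics",
    "DiscountRates",
    "CEResult",
    "ICERComparison",
    "discount_factor",
    "followup_interval_days",
    "accumulate",
    "icer",
    "nmb",
]

CYCLES_PER_YEAR = 365.25 / CYCLE_DAYS


def discount_factor(t_days, annual_rate: float):
    """Continuous-time discount factor (1 + r)^(-t/365.25)."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + annual_rate) ** (-np.asarray(t_days, dtype=float) / 365.25)


def followup_interval_days(t_days: float) -> float:
    """Guideline follow-up visit interval at a given time since model start."""
    years = t_days / 365.25
    if years <= 1.0:
        return 2 * 365.25 / 12
    if years <= 3.0:
        return 3 * 365.25 / 12
    if years <= 5.0:
        return 6 * 365.25 / 12
    return 365.25


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    incidence: float
    cost: float
    disutility: float  # negative

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError(f"AE {self.name}: incidence outside [0, 1]")
        if self.cost < 0:
            raise ValueError(f"AE {self.name}: negative cost")


@dataclass
class SubsequentMix:
    """Post-progression treatment category proportions (must sum to 1)."""

    radiotherapy: float
    chemotherapy: float
    targeted: float
    immunotherapy: float
    best_supportive: float

    def __post_init__(self) -> None:
        if abs(self.total() - 1.0) > 1e-9:
            raise ValueError(f"subsequent-treatment mix sums to {self.total()}, not 1")

    def total(self) -> float:
        return (self.radiotherapy + self.chemotherapy + self.targeted
                + self.immunotherapy + self.best_supportive)

    def normalized(self) -> "SubsequentMix":
        s = self.total()
        return SubsequentMix(*(v / s for v in (
            self.radiotherapy, self.chemotherapy, self.targeted,
            self.immunotherapy, self.best_supportive)))


@dataclass
class StrategyEconomics:
    """Cost and utility inputs for one treatment strategy."""

    name: str
    ec_cost_per_cycle: float          # etoposide + carboplatin, cycles 1-4
    continuous_cost_per_cycle: float  # benmelstobart and/or anlotinib while in PFS
    ec_n_cycles: int
    subsequent_mix: SubsequentMix
    subsequent_costs: dict[str, float]   # per-cycle cost per category
    adverse_events: list[AdverseEvent]
    followup_visit_cost: float
    end_of_life_cost: float
    u_pfs: float
    u_pd: float
    uplift_rate: float
    uplift_cutoff_years: float = 2.0
    immunotherapy_cap_cycles: int = 35

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_pfs <= 1.0 and 0.0 <= self.u_pd <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")
        for v in (self.ec_cost_per_cycle, self.continuous_cost_per_cycle,
                  self.followup_visit_cost, self.end_of_life_cost):
            if v < 0:
                raise ValueError("costs must be >= 0")

    def ae_cost_total(self) -> float:
        return sum(ae.incidence * ae.cost for ae in self.adverse_events)

    def ae_disutility_total(self) -> float:
        return sum(ae.incidence * abs(ae.disutility) for ae in self.adverse_events)


@dataclass(frozen=True)
class DiscountRates:
    cost: float = 0.05
    qaly: float = 0.05


@dataclass
class CEResult:
    """Discounted totals and cost breakdown for one strategy."""

    strategy: str
    total_cost_usd: float
    total_qalys: float
    total_life_years: float
    cost_pfs_drugs: float
    cost_pd_drugs: float
    cost_ae: float
    cost_followup: float
    cost_end_of_life: float

    def breakdown(self) -> dict[str, float]:
        return {
            "pfs_drugs": self.cost_pfs_drugs,
            "pd_drugs": self.cost_pd_drugs,
            "adverse_events": self.cost_ae,
            "followup": self.cost_followup,
            "end_of_life": self.cost_end_of_life,
        }


@dataclass(frozen=True)
class ICERComparison:
    strategy_a: str
    strategy_b: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominant: bool = False
    dominated: bool = False


def _per_member_pd_cost(strategy: StrategyEconomics, compartment: int) -> float:
    """Per-cycle PD cost for one cohort member in a given tunnel compartment."""
    mix, costs = strategy.subsequent_mix, strategy.subsequent_costs
    immu = (costs["immunotherapy"] if compartment < strategy.immunotherapy_cap_cycles
            else costs["best_supportive"])
    return (mix.radiotherapy * costs["radiotherapy"]
            + mix.chemotherapy * costs["chemotherapy"]
            + mix.targeted * costs["targeted"]
            + mix.immunotherapy * immu
            + mix.best_supportive * costs["best_supportive"])


def accumulate(trace: CohortTrace, strategy: StrategyEconomics,
               clock: ModelClock | None = None,
               rates: DiscountRates = DiscountRates(),
               ae_at_pd_entry: bool = False,
               life_years_discounted: bool = False) -> CEResult:
    """Attach costs and utilities to a cohort trace and total them.

    ``ae_at_pd_entry`` additionally re-applies the one-off adverse-event cost
    and disutility to each cohort fraction entering PD (scenario analysis).
    """
    clock = clock or trace.clock
    n = len(trace.new_deaths)
    cyc = np.arange(n)
    mid_days = (cyc + 0.5) * clock.cycle_days
    df_cost = discount_factor(mid_days, rates.cost)
    df_qaly = discount_factor(mid_days, rates.qaly)
    cycle_years = clock.cycle_days / 365.25

    # --- drug costs in PFS: EC backbone first `ec_n_cycles` cycles + continuous drugs
    per_cycle_pfs = np.where(cyc < strategy.ec_n_cycles, strategy.ec_cost_per_cycle, 0.0)
    per_cycle_pfs = per_cycle_pfs + strategy.continuous_cost_per_cycle
    cost_pfs = float(np.sum(trace.pfs_bar * per_cycle_pfs * df_cost))

    # --- PD costs via tunnel compartments (immunotherapy capped at 24 months)
    width = trace.tunnel.shape[1]
    comp_cost = np.array([_per_member_pd_cost(strategy, j) for j in range(width)])
    cost_pd = float(np.sum((trace.tunnel_bar @ comp_cost) * df_cost))

    # --- adverse events: one-off, full cohort, first cycle
    cost_ae = strategy.ae_cost_total() * float(df_cost[0])
    ae_qaly_loss = strategy.ae_disutility_total() * cycle_years * float(df_qaly[0])
    if ae_at_pd_entry:
        cost_ae += strategy.ae_cost_total() * float(
            np.sum(trace.new_progressions * df_cost))
        ae_qaly_loss += strategy.ae_disutility_total() * cycle_years * float(
            np.sum(trace.new_progressions * df_qaly))

    # --- follow-up visits prorated per cycle by the guideline interval
    intervals = np.array([followup_interval_days(t) for t in mid_days])
    cost_fu = float(np.sum(
        trace.alive_bar * strategy.followup_visit_cost
        * (clock.cycle_days / intervals) * df_cost))

    # --- end-of-life lump sum at the death transition
    cost_eol = float(np.sum(trace.new_deaths * strategy.end_of_life_cost * df_cost))

    # --- QALYs with the EQ-VAS uplift before the trial cutoff
    uplift = np.where(mid_days / 365.25 <= strategy.uplift_cutoff_years,
                      1.0 + strategy.uplift_rate, 1.0)
    u_pfs = np.minimum(strategy.u_pfs * uplift, 1.0)
    u_pd = np.minimum(strategy.u_pd * uplift, 1.0)
    qalys = float(np.sum(
        (trace.pfs_bar * u_pfs + trace.pd_bar * u_pd) * cycle_years * df_qaly))
    qalys -= ae_qaly_loss

    ly_weights = df_qaly if life_years_discounted else np.ones(n)
    life_years = float(np.sum(trace.alive_bar * cycle_years * ly_weights))

    total = cost_pfs + cost_pd + cost_ae + cost_fu + cost_eol
    return CEResult(
        strategy=strategy.name,
        total_cost_usd=total, total_qalys=qalys, total_life_years=life_years,
        cost_pfs_drugs=cost_pfs, cost_pd_drugs=cost_pd, cost_ae=cost_ae,
        cost_followup=cost_fu, cost_end_of_life=cost_eol,
    )


def icer(a: CEResult, b: CEResult) -> ICERComparison:
    """Incremental cost-effectiveness of strategy a over comparator b."""
    dc = a.total_cost_usd - b.total_cost_usd
    dq = a.total_qalys - b.total_qalys
    dominant = dc < 0 and dq > 0
    dominated = dc > 0 and dq < 0
    ratio = dc / dq if dq != 0 else None
    return ICERComparison(a.strategy, b.strategy, dc, dq, ratio,
                          dominant=dominant, dominated=dominated)


def nmb(result: CEResult, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.total_qalys - result.total_cost_usd


def results_table(results: list[CEResult], comparisons: list[ICERComparison]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"strategy": r.strategy, "total_cost_usd": r.total_cost_usd,
               "qalys": r.total_qalys, "life_years": r.total_life_years}
        row.update({f"cost_{k}": v for k, v in r.breakdown().items()})
        for c in comparisons:
            if c.strategy_a == r.strategy:
                row[f"icer_vs_{c.strategy_b}"] = c.icer
        rows.append(row)
    return pd.DataFrame(rows)
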