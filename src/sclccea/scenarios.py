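"""Scenario analyses: alternative model settings re-run through the base pipeline.

Supported overrides mirror the study's scenario suite: drug price multipliers,
discounting one or neither stream, shorter horizons (5 y, 2 y), removing the
best-supportive-care cost assumption, removing end-of-life care, leaving the
utility values unadjusted, repeating the adverse-event hit on entry to PD, and
regenerating an arm's OS curve from the reference arm under a hazard ratio.

Removing best supportive care zeroes its cost while keeping the mix weights:
the untreated fraction of progressed patients simply accrues no cost, which is
the counterfactual to the assumption that everyone not on active subsequent
therapy received costed supportive care.

The price-threshold search bisects a drug's price multiplier until the chosen
pair's ICER hits the willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import econ, survcurves
from .config import RunConfig, ScenarioConfig
from .pipeline import (PipelineState, build_traces, evaluate_strategies,
                       pairwise_icers)

__all__ = ["ScenarioResult", "PriceThresholdResult", "run_scenario",
           "run_scenario_suite", "price_threshold"]


@dataclass
class ScenarioResult:
    name: str
    results: dict[str, econ.CEResult]
    comparisons: list[econ.ICERComparison]
    icer_direction: dict[str, str]  # comparison key -> "up" | "down" | "="


def _discount_rates(config: RunConfig, mode: str | None) -> econ.DiscountRates:
    base = econ.DiscountRates(cost=config.discount.cost, qaly=config.discount.qaly)
    if mode in (None, "both"):
        return base
    if mode == "utilities_only":
        return econ.DiscountRates(cost=0.0, qaly=base.qaly)
    if mode == "costs_only":
        return econ.DiscountRates(cost=base.cost, qaly=0.0)
    if mode == "none":
        return econ.DiscountRates(cost=0.0, qaly=0.0)
    raise ValueError(f"unknown discount mode {mode!r}")


def run_scenario(spec: ScenarioConfig, state: PipelineState,
                 base_results: dict[str, econ.CEResult] | None = None) -> ScenarioResult:
    """Re-run the economic model with one scenario's overrides applied.

    The pipeline state is never mutated; horizon and hazard-ratio overrides
    rebuild clocks/traces locally.
    """
    config = state.config
    values: dict[str, float] = {}
    for drug, mult in (spec.price_multipliers or {}).items():
        key = f"cost.{drug}"
        if mult < 0:
            raise ValueError(f"{spec.name}: negative price multiplier")
        values[key] = config.param_value(key) * mult
    if spec.drop_best_supportive:
        values["cost.best_supportive"] = 0.0
    if spec.drop_end_of_life:
        values["cost.end_of_life"] = 0.0
    if spec.uplift_rates_zeroed:
        for name in config.strategies:
            values[f"uplift.{name}"] = 0.0

    rates = _discount_rates(config, spec.discount_mode)

    clock = state.clock
    traces = state.traces
    curves = state.curves
    if spec.os_from_hr is not None:
        tgt, ref, hr = (spec.os_from_hr["strategy"], spec.os_from_hr["reference"],
                        float(spec.os_from_hr["hr"]))
        new_curves = {n: dict(p) for n, p in curves.curves.items()}
        new_curves[tgt]["os"] = survcurves.apply_hr(curves.curves[ref]["os"], hr)
        curves = survcurves.CurveSet(curves=new_curves, horizon_days=curves.horizon_days)
        traces = None  # must rebuild
    if spec.horizon_years is not None:
        clock = replace(clock, horizon_years=spec.horizon_years)
        traces = None
    if traces is None:
        traces = build_traces(curves, state.lifetable, clock,
                              n_tunnel=config.immunotherapy_cap_cycles)

    results = evaluate_strategies(
        state, values=values, rates=rates, traces=traces, clock=clock,
        ae_at_pd_entry=spec.ae_repeat_at_pd_entry,
    )
    comparisons = pairwise_icers(results, config.reference)

    if base_results is None:
        base_results = evaluate_strategies(state)
    base_cmp = {(c.strategy_a, c.strategy_b): c
                for c in pairwise_icers(base_results, config.reference)}
    direction = {}
    for c in comparisons:
        b = base_cmp.get((c.strategy_a, c.strategy_b))
        key = f"{c.strategy_a}_vs_{c.strategy_b}"
        if b is None or b.icer is None or c.icer is None:
            direction[key] = "="
        else:
            direction[key] = "up" if c.icer > b.icer else ("down" if c.icer < b.icer else "=")
    return ScenarioResult(spec.name, results, comparisons, direction)


def run_scenario_suite(state: PipelineState) -> pd.DataFrame:
    """Run every configured scenario; one table row per scenario/strategy."""
    base_results = evaluate_strategies(state)
    rows = []
    for spec in state.config.scenarios:
        res = run_scenario(spec, state, base_results=base_results)
        for name, r in res.results.items():
            row = {"scenario": spec.name, "strategy": name,
                   "total_cost_usd": r.total_cost_usd, "qalys": r.total_qalys}
            for c in res.comparisons:
                if c.strategy_a == name and c.strategy_b == state.config.reference:
                    row["icer_vs_reference"] = c.icer
                    row["direction"] = res.icer_direction[
                        f"{c.strategy_a}_vs_{c.strategy_b}"]
            rows.append(row)
    return pd.DataFrame(rows)


def bisect_multiplier(icer_fn, wtp: float, tol_usd: float = 1.0,
                      max_iter: int = 100) -> tuple[float, float | None]:
    """Bisect a price multiplier in [0, 1] until icer_fn(m) meets the WTP.

    ``icer_fn`` must be non-decreasing in the multiplier (more expensive drug,
    higher ICER); -inf encodes dominance.  Returns (multiplier, ICER there).
    """
    lo, hi = 0.0, 1.0  # invariant: icer(lo) <= wtp < icer(hi)
    mult, icer_mid = 1.0, None
    for _ in range(max_iter):
        mult = 0.5 * (lo + hi)
        icer_mid = icer_fn(mult)
        if icer_mid is None:
            break
        if icer_mid > wtp:
            hi = mult
        else:
            lo = mult
        if abs(icer_mid - wtp) < tol_usd:
            break
    return mult, icer_mid


@dataclass
class PriceThresholdResult:
    drug: str
    strategy: str
    comparator: str
    wtp: float
    multiplier: float
    percent_reduction: float
    icer_at_multiplier: float | None
    already_cost_effective: bool = False


def price_threshold(
    drug: str,
    pair: tuple[str, str],
    wtp: float,
    state: PipelineState,
    tol_usd: float = 1.0,
) -> PriceThresholdResult:
    """Bisection on a drug's price multiplier until ICER(pair) meets the WTP.

    Returns multiplier 1 / 0% reduction (flagged) when the pair is already
    cost-effective at full price.
    """
    target, comparator = pair
    key = f"cost.{drug}"
    base_price = state.config.param_value(key)

    def icer_at(mult: float) -> float | None:
        res = evaluate_strategies(state, values={key: base_price * mult})
        c = econ.icer(res[target], res[comparator])
        if c.icer is None:
            return None
        # a dominant strategy is better than any finite threshold
        return -np.inf if c.dominant else c.icer

    at_full = icer_at(1.0)
    if at_full is None:
        raise RuntimeError("ICER undefined (zero incremental QALYs)")
    if at_full <= wtp:
        return PriceThresholdResult(drug, target, comparator, wtp, 1.0, 0.0,
                                    at_full, already_cost_effective=True)
    at_zero = icer_at(0.0)
    if at_zero is not None and at_zero > wtp:
        raise RuntimeError(
            "no bracket: ICER exceeds the threshold even at price zero")

    mult, icer_mid = bisect_multiplier(icer_at, wtp, tol_usd)
    return PriceThresholdResult(drug, target, comparator, wtp, mult,
                                100.0 * (1.0 - mult), icer_mid)
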