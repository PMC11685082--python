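"""End-to-end orchestration: synthetic trial -> reconstruction -> fitting ->
Markov traces -> economics -> sensitivity and scenario analyses."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import econ, km_ipd, markov_core, survcurves, synthetic_trial, uncertainty
from .config import RunConfig
from .km_ipd import DAYS_PER_MONTH

log = logging.getLogger("sclccea")

__all__ = ["PipelineState", "build_strategy_economics", "build_curves_from_synthetic",
           "build_traces", "evaluate_strategies", "base_case", "run_psa", "run_dsa",
           "run_all"]

_MIX_CATEGORIES = ("radiotherapy", "chemotherapy", "targeted", "immunotherapy",
                   "best_supportive")


def build_strategy_economics(
    config: RunConfig, values: dict[str, float] | None = None,
) -> dict[str, econ.StrategyEconomics]:
    """Construct per-strategy cost/utility inputs from the parameter table.

    ``values`` overrides individual parameter values (DSA/PSA/scenarios);
    anything not named keeps its base value.
    """
    v = {name: config.param_value(name) for name in config.parameters}
    if values:
        unknown = set(values) - set(v)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        v.update(values)

    out = {}
    for name, scfg in config.strategies.items():
        raw_mix = {c: v[f"mix.{name}.{c}"] for c in _MIX_CATEGORIES}
        tot = sum(raw_mix.values())  # printed proportions can be off by ~1e-4
        mix = econ.SubsequentMix(**{c: p / tot for c, p in raw_mix.items()})
        aes = [
            econ.AdverseEvent(
                name=ev, incidence=v[f"ae_inc.{name}.{ev}"],
                cost=v[f"ae_cost.{ev}"], disutility=v[f"disutility.{ev}"],
            )
            for ev in scfg.ae_events
        ]
        out[name] = econ.StrategyEconomics(
            name=name,
            ec_cost_per_cycle=v["cost.etoposide"] + v["cost.carboplatin"],
            continuous_cost_per_cycle=sum(v[f"cost.{d}"] for d in scfg.continuous_drugs),
            ec_n_cycles=config.ec_n_cycles,
            subsequent_mix=mix,
            subsequent_costs={
                "radiotherapy": v["cost.radiotherapy"],
                "chemotherapy": v["cost.chemotherapy"],
                "targeted": v["cost.anlotinib"],
                "immunotherapy": v["cost.immunotherapy"],
                "best_supportive": v["cost.best_supportive"],
            },
            adverse_events=aes,
            followup_visit_cost=v["cost.laboratory"] + v["cost.imaging"],
            end_of_life_cost=v["cost.end_of_life"],
            u_pfs=v["utility.pfs"],
            u_pd=v["utility.pd"],
            uplift_rate=v[f"uplift.{name}"],
            uplift_cutoff_years=config.uplift_cutoff_years,
            immunotherapy_cap_cycles=config.immunotherapy_cap_cycles,
        )
    return out


def build_curves_from_synthetic(
    config: RunConfig, seed: int, families: list[str] | None = None,
) -> tuple[survcurves.CurveSet, pd.DataFrame]:
    """Simulate the ETER701-like trial, digitize, reconstruct, fit, and select.

    Returns the selected curve set and the concatenated model-selection table.
    """
    st = config.synthetic_trial
    clock = markov_core.ModelClock(**config.clock.model_dump())
    horizon_days = clock.n_cycles * clock.cycle_days
    families = families or config.survival.families

    curves: dict[str, dict[str, object]] = {}
    tables = []
    for i, arm_name in enumerate(config.strategies):
        shape_os, shape_pfs = 1.3, 1.6
        truth = synthetic_trial.ArmTruth(
            name=arm_name,
            os_family="weibull",
            os_params=[shape_os, st.os_median_months[arm_name] * DAYS_PER_MONTH
                       / np.log(2.0) ** (1 / shape_os)],
            pfs_family="weibull",
            pfs_params=[shape_pfs, st.pfs_median_months[arm_name] * DAYS_PER_MONTH
                        / np.log(2.0) ** (1 / shape_pfs)],
            n_patients=st.n_patients[arm_name],
            max_followup_days=st.max_followup_months * DAYS_PER_MONTH,
            censor_rate=st.censor_rate_per_day,
        )
        os_ipd, pfs_ipd = synthetic_trial.simulate_ipd(truth, seed=seed + 31 * i)
        pair = {}
        for endpoint, ipd in (("os", os_ipd), ("pfs", pfs_ipd)):
            tmax = float(ipd.times_days.max())
            grid = np.arange(0.0, tmax + st.digitize_grid_step_days,
                             st.digitize_grid_step_days)
            risk_times = np.arange(0.0, tmax + 1,
                                   st.risk_table_interval_months * DAYS_PER_MONTH)
            dig = synthetic_trial.digitize(ipd, grid, risk_times,
                                           noise=st.digitize_noise,
                                           seed=seed + 31 * i + 7)
            rec = km_ipd.reconstruct_ipd(dig)
            fits = []
            for fam in families:
                try:
                    fits.append(survcurves.fit(rec, fam))
                except (RuntimeError, ValueError) as exc:
                    log.warning("%s/%s: %s failed: %s", arm_name, endpoint, fam, exc)
            if len(fits) >= 2:
                table = survcurves.select(fits)
            else:  # single-family run: nothing to rank
                f = fits[0]
                table = pd.DataFrame(
                    {"family": [f.family], "k": [f.k], "loglik": [f.loglik],
                     "aic": [f.aic], "bic": [f.bic], "bic_rank": [1]},
                    index=pd.Index([1], name="aic_rank"))
            table.insert(0, "endpoint", endpoint)
            table.insert(0, "arm", arm_name)
            tables.append(table.reset_index())
            best_family = table.iloc[0]["family"]
            pair[endpoint] = next(f for f in fits if f.family == best_family)
            log.info("%s/%s: selected %s", arm_name, endpoint, best_family)
        curves[arm_name] = pair
    return (survcurves.CurveSet(curves=curves, horizon_days=horizon_days),
            pd.concat(tables, ignore_index=True))


def build_traces(
    curves: survcurves.CurveSet, lifetable: markov_core.LifeTable | None,
    clock: markov_core.ModelClock, n_tunnel: int = 35,
) -> dict[str, markov_core.CohortTrace]:
    return {
        name: markov_core.run_cohort(
            markov_core.transition_rows(curves, name, lifetable, clock),
            clock, n_tunnel=n_tunnel)
        for name in curves.strategies()
    }


@dataclass
class PipelineState:
    """Everything the economic model needs, fixed across PSA draws."""

    config: RunConfig
    curves: survcurves.CurveSet
    lifetable: markov_core.LifeTable | None
    clock: markov_core.ModelClock
    traces: dict[str, markov_core.CohortTrace]
    selection_table: pd.DataFrame | None = None

    @classmethod
    def from_synthetic(cls, config: RunConfig, seed: int,
                       lifetable: markov_core.LifeTable | None = None) -> "PipelineState":
        clock = markov_core.ModelClock(**config.clock.model_dump())
        if lifetable is None:
            lifetable = (markov_core.LifeTable.from_csv(config.lifetable_path)
                         if config.lifetable_path
                         else markov_core.LifeTable.bundled_china_2022())
        curves, table = build_curves_from_synthetic(config, seed)
        traces = build_traces(curves, lifetable, clock,
                              n_tunnel=config.immunotherapy_cap_cycles)
        return cls(config=config, curves=curves, lifetable=lifetable, clock=clock,
                   traces=traces, selection_table=table)


def evaluate_strategies(
    state: PipelineState,
    values: dict[str, float] | None = None,
    rates: econ.DiscountRates | None = None,
    ae_at_pd_entry: bool = False,
    traces: dict[str, markov_core.CohortTrace] | None = None,
    clock: markov_core.ModelClock | None = None,
) -> dict[str, econ.CEResult]:
    """Evaluate all strategies for one parameter assignment."""
    rates = rates or econ.DiscountRates(cost=state.config.discount.cost,
                                        qaly=state.config.discount.qaly)
    traces = traces or state.traces
    clock = clock or state.clock
    strategies = build_strategy_economics(state.config, values)
    return {
        name: econ.accumulate(traces[name], strategies[name], clock, rates,
                              ae_at_pd_entry=ae_at_pd_entry)
        for name in strategies
    }


def pairwise_icers(results: dict[str, econ.CEResult],
                   reference: str) -> list[econ.ICERComparison]:
    names = list(results)
    out = [econ.icer(results[n], results[reference]) for n in names if n != reference]
    # also each non-reference pair (three-strategy comparison)
    non_ref = [n for n in names if n != reference]
    for i, a in enumerate(non_ref):
        for b in non_ref[i + 1:]:
            out.append(econ.icer(results[a], results[b]))
    return out


def base_case(state: PipelineState) -> tuple[dict[str, econ.CEResult], pd.DataFrame]:
    results = evaluate_strategies(state)
    comparisons = pairwise_icers(results, state.config.reference)
    return results, econ.results_table(list(results.values()), comparisons)


# ---------------------------------------------------------------------------
# sensitivity analyses wired to the pipeline

def _icer_model(state: PipelineState, target: str):
    ref = state.config.reference

    def model(overrides: dict[str, float]) -> float:
        res = evaluate_strategies(state, values=overrides)
        return econ.icer(res[target], res[ref]).icer

    return model


def run_dsa(state: PipelineState, target: str | None = None) -> pd.DataFrame:
    """One-way (tornado) sensitivity of the target strategy's ICER vs reference."""
    targets = ([target] if target else
               [n for n in state.config.strategies if n != state.config.reference])
    frames = []
    for tg in targets:
        df = uncertainty.dsa(state.config.param_specs(), _icer_model(state, tg))
        df.insert(0, "comparison", f"{tg}_vs_{state.config.reference}")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def psa_correlation_rules(config: RunConfig) -> list[tuple[str, str, float]]:
    rules = []
    uplifts = [f"uplift.{n}" for n in config.strategies]
    rho = config.psa.uplift_correlation
    for i, a in enumerate(uplifts):
        for b in uplifts[:i]:
            rules.append((a, b, rho))
    for name in config.strategies:
        rules.append((f"mix.{name}.chemotherapy", f"mix.{name}.best_supportive",
                      config.psa.chemo_bsc_correlation))
    return rules


def psa_simplex_groups(config: RunConfig) -> list[list[str]]:
    return [[f"mix.{name}.{c}" for c in _MIX_CATEGORIES] for name in config.strategies]


def run_psa(state: PipelineState, n_draws: int | None = None,
            seed: int | None = None) -> uncertainty.PSAResult:
    cfg = state.config
    draws = uncertainty.correlated_sample(
        cfg.param_specs(),
        psa_correlation_rules(cfg),
        n=n_draws or cfg.psa.n_draws,
        seed=cfg.psa.seed if seed is None else seed,
        simplex_groups=psa_simplex_groups(cfg),
    )

    def model(row: dict[str, float]) -> dict[str, tuple[float, float]]:
        res = evaluate_strategies(state, values=row)
        return {n: (r.total_cost_usd, r.total_qalys) for n, r in res.items()}

    return uncertainty.psa(draws, model, strategies=list(cfg.strategies),
                           reference=cfg.reference,
                           wtp_summary=tuple(cfg.wtp_summary))


def run_all(config: RunConfig, seed: int, outdir: str | Path,
            psa_draws: int | None = None) -> dict:
    """Execute the full pipeline and write every result table as delimited text."""
    from . import scenarios as scen

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log.info("run_all: seed=%d outdir=%s", seed, outdir)

    state = PipelineState.from_synthetic(config, seed)
    state.selection_table.to_csv(outdir / "model_selection.csv", index=False)

    results, table = base_case(state)
    table.to_csv(outdir / "base_case.csv", index=False)
    for name, trace in state.traces.items():
        trace.to_frame().to_csv(outdir / f"trace_{name}.csv", index=False)

    dsa_table = run_dsa(state)
    dsa_table.to_csv(outdir / "tornado.csv", index=False)

    psa_res = run_psa(state, n_draws=psa_draws)
    psa_res.ceac_pairwise.to_csv(outdir / "ceac_pairwise.csv", index=False)
    psa_res.ceac_winner.to_csv(outdir / "ceac_winner.csv", index=False)
    psa_res.summary.to_csv(outdir / "psa_summary.csv", index=False)

    scen_table = scen.run_scenario_suite(state)
    scen_table.to_csv(outdir / "scenarios.csv", index=False)

    thresh = scen.price_threshold(
        "benmelstobart", ("benmel_anlo_ec", config.reference),
        config.wtp_threshold, state)
    pd.DataFrame([thresh.__dict__]).to_csv(outdir / "price_threshold.csv", index=False)

    return {
        "state": state, "base_case": table, "dsa": dsa_table, "psa": psa_res,
        "scenarios": scen_table, "price_threshold": thresh,
    }
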