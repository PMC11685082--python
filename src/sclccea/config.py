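"""Run configuration: schema validation and the bundled default parameter set."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .uncertainty import ParamSpec

__all__ = ["RunConfig", "load_config", "default_config_path"]


class ClockConfig(BaseModel):
    cycle_days: float = 21.0
    horizon_years: float = 10.0
    start_age_years: float = 62.0


class DiscountConfig(BaseModel):
    cost: float = Field(0.05, ge=0)
    qaly: float = Field(0.05, ge=0)


class StrategyConfig(BaseModel):
    label: str
    continuous_drugs: list[str]
    ae_events: list[str]


class PSAConfig(BaseModel):
    n_draws: int = Field(10_000, ge=1)
    seed: int = 20240001
    uplift_correlation: float = 0.9
    chemo_bsc_correlation: float = -0.9


class SurvivalConfig(BaseModel):
    families: list[str]


class SyntheticTrialConfig(BaseModel):
    os_median_months: dict[str, float]
    pfs_median_months: dict[str, float]
    n_patients: dict[str, int]
    max_followup_months: float = 30.0
    censor_rate_per_day: float = Field(4e-4, ge=0)
    digitize_grid_step_days: float = 7.0
    risk_table_interval_months: float = 3.0
    digitize_noise: float = Field(0.0, ge=0, le=0.005)


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    price_multipliers: dict[str, float] | None = None
    discount_mode: str | None = None  # both | utilities_only | costs_only | none
    horizon_years: float | None = None
    drop_best_supportive: bool = False
    drop_end_of_life: bool = False
    uplift_rates_zeroed: bool = False
    ae_repeat_at_pd_entry: bool = False
    os_from_hr: dict | None = None  # {strategy, reference, hr}

    @field_validator("discount_mode")
    @classmethod
    def _check_mode(cls, v):
        if v is not None and v not in ("both", "utilities_only", "costs_only", "none"):
            raise ValueError(f"unknown discount mode {v!r}")
        return v

    @field_validator("os_from_hr")
    @classmethod
    def _check_hr(cls, v):
        if v is not None:
            missing = {"strategy", "reference", "hr"} - set(v)
            if missing:
                raise ValueError(f"os_from_hr missing keys {sorted(missing)}")
            if v["hr"] <= 0:
                raise ValueError("hr must be > 0")
        return v


class RunConfig(BaseModel):
    """Validated model configuration (see data/defaults.yaml for the bundled base case)."""

    model_config = ConfigDict(extra="forbid")

    clock: ClockConfig = ClockConfig()
    discount: DiscountConfig = DiscountConfig()
    wtp_threshold: float = 37_598.0
    wtp_summary: list[float] = [12_533.0, 25_065.0, 37_598.0]
    uplift_cutoff_years: float = 2.0
    ec_n_cycles: int = 4
    immunotherapy_cap_cycles: int = 35
    strategies: dict[str, StrategyConfig]
    reference: str
    parameters: dict[str, list]
    psa: PSAConfig = PSAConfig()
    survival: SurvivalConfig
    synthetic_trial: SyntheticTrialConfig
    scenarios: list[ScenarioConfig] = []
    lifetable_path: str | None = None

    @field_validator("parameters")
    @classmethod
    def _check_params(cls, v):
        for name, entry in v.items():
            if len(entry) != 4:
                raise ValueError(f"parameter {name}: expected [base, low, high, distribution]")
        return v

    def model_post_init(self, __context) -> None:
        if self.reference not in self.strategies:
            raise ValueError(f"reference strategy {self.reference!r} not defined")

    def param_value(self, name: str) -> float:
        return float(self.parameters[name][0])

    def param_spec(self, name: str) -> ParamSpec:
        base, low, high, dist = self.parameters[name]
        # a handful of printed ranges do not bracket the base value; widen so
        # that low <= base <= high always holds
        lo = min(float(low), float(base))
        hi = max(float(high), float(base))
        return ParamSpec(name=name, base=float(base), low=lo, high=hi,
                         distribution=str(dist))

    def param_specs(self) -> list[ParamSpec]:
        return [self.param_spec(name) for name in self.parameters]


def default_config_path():
    return resources.files("sclccea.data").joinpath("defaults.yaml")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a run configuration (bundled defaults when no path given)."""
    if path is None:
        with default_config_path().open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if overrides:
        raw = _deep_update(raw, overrides)
    return RunConfig(**raw)


def _deep_update(base: dict, upd: dict) -> dict:
    out = dict(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out
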