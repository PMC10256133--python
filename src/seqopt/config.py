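"""Run configuration: schema, validation, YAML round-trip."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .designs import SpendingSpec
from .priors import HistoricalCohort, MixtureEffectPrior, inflate_variance
from .search import SchemeGrid
from .simulate import TrialAssumptions

__all__ = ["RunConfig", "load_config", "save_config"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class AssumptionsBlock(_Model):
    n_total: int = Field(gt=0)
    accrual_duration: float = Field(gt=0)
    median_control: float = Field(gt=0)
    design_hr: float = Field(gt=0)
    allocation_ratio: float = Field(default=1.0, gt=0)
    weibull_shape: float = Field(default=2.0, gt=0)
    alpha: float = Field(default=0.025, gt=0, lt=1,
                         description="per-side type-I error")
    power: float = Field(default=0.90, gt=0, lt=1)
    sides: Literal[1, 2] = 1

    @model_validator(mode="after")
    def _check_hr(self):
        if self.design_hr == 1.0:
            raise ValueError("design_hr must differ from 1")
        return self

    @property
    def alpha_one_sided(self) -> float:
        # two-sided symmetric designs use half the nominal alpha per side
        return self.alpha / 2.0 if self.sides == 2 else self.alpha

    def to_assumptions(self) -> TrialAssumptions:
        return TrialAssumptions(
            n_total=self.n_total,
            accrual_duration=self.accrual_duration,
            median_control=self.median_control,
            design_hr=self.design_hr,
            allocation_ratio=self.allocation_ratio,
            weibull_shape=self.weibull_shape,
            alpha_total=self.alpha_one_sided,
            beta_total=1.0 - self.power,
        )


class HistoricalBlock(_Model):
    n_control: int = Field(gt=0)
    n_treated: int = Field(gt=0)
    median_control: float = Field(gt=0)
    median_treated: float = Field(gt=0)
    follow_up: float = Field(gt=0)
    weibull_shape: float = Field(default=2.0, gt=0)

    def to_cohort(self) -> HistoricalCohort:
        return HistoricalCohort(self.n_control, self.n_treated,
                                self.median_control, self.median_treated,
                                self.follow_up, self.weibull_shape)


class PriorBlock(_Model):
    p_success: float = Field(ge=0, le=1)
    design_hr: Optional[float] = Field(default=None, gt=0,
                                       description="defaults to assumptions.design_hr")
    se_success: Optional[float] = Field(default=None, gt=0)
    se_futility: Optional[float] = Field(default=None, gt=0)
    futility_hr: Optional[float] = Field(
        default=None, gt=0,
        description="center of the ineffective component; default = design HR")
    historical: Optional[HistoricalBlock] = None
    variance_inflation: float = Field(default=10.0, gt=0)

    @model_validator(mode="after")
    def _check_sources(self):
        if self.se_success is None and self.historical is None:
            raise ValueError(
                "prior needs either explicit se_success or a historical block")
        return self

    def to_prior(self, design_hr_default: float) -> MixtureEffectPrior:
        design_hr = self.design_hr or design_hr_default
        if self.historical is not None:
            base = self.historical.to_cohort().se_loghr
        else:
            base = None
        se_s = self.se_success if self.se_success is not None else base
        se_f = (self.se_futility if self.se_futility is not None
                else inflate_variance(se_s, self.variance_inflation))
        theta_f = (math.log(self.futility_hr)
                   if self.futility_hr is not None else None)
        return MixtureEffectPrior(
            p_success=self.p_success,
            theta_design=math.log(design_hr),
            se_success=se_s,
            se_futility=se_f,
            theta_futility=theta_f,
        )


class GridBlock(_Model):
    n_futility_looks: list[int] = Field(default=[4, 5])
    candidate_fractions: list[float] = Field(
        default=[0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
    superiority_fraction: float = 0.6
    gamma_beta: list[float] = Field(
        default_factory=lambda: [round(float(x), 2) for x in
                                 np.arange(0.75, 3.001, 0.25)])
    gamma_alpha: list[float] = Field(
        default_factory=lambda: [round(float(x), 2) for x in
                                 np.arange(2.00, 3.001, 0.25)])
    max_duration_inflation: float = Field(default=1.10, ge=1.0)

    def to_grid(self) -> SchemeGrid:
        return SchemeGrid(
            n_futility_looks=tuple(self.n_futility_looks),
            candidate_fractions=tuple(self.candidate_fractions),
            superiority_fraction=self.superiority_fraction,
            gamma_beta_grid=tuple(self.gamma_beta),
            gamma_alpha_grid=tuple(self.gamma_alpha),
            max_duration_inflation=self.max_duration_inflation,
        )


class ExecutionBlock(_Model):
    replicates: int = Field(default=10_000, ge=1)
    seed: int = 2023
    workers: int = Field(default=1, ge=1)
    output_dir: str = "results"


class RunConfig(_Model):
    """Full, schema-validated input of one optimizer run."""

    assumptions: AssumptionsBlock
    prior: PriorBlock
    grid: GridBlock = Field(default_factory=GridBlock)
    execution: ExecutionBlock = Field(default_factory=ExecutionBlock)
    criterion: Literal["duration", "sample_size", "exposure"] = "duration"
    name: str = "trial"
    notes: list[str] = Field(default_factory=list)

    def spending_spec(self, gamma_alpha: float = 2.5,
                      gamma_beta: float = 2.5) -> SpendingSpec:
        return SpendingSpec(self.assumptions.alpha_one_sided,
                            1.0 - self.assumptions.power,
                            gamma_alpha, gamma_beta)

    def resolved_prior(self) -> MixtureEffectPrior:
        return self.prior.to_prior(self.assumptions.design_hr)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (defaults filled) to YAML."""
    data = config.model_dump(exclude_none=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
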