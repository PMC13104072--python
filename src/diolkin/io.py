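"""CSV/JSON/YAML input and output plus the validated run configuration."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .fitting import FitResult, ModelComparison, StagedFitOutcome, TimeSeriesData
from .kinetics import (
    SPECIES_ORDER,
    ConfigurationError,
    ModelVariant,
    Species,
    default_initial_state,
)
from .metrics import mass_to_molar_conc
from .simulate import Trajectory

__all__ = [
    "read_timecourse_csv",
    "write_timecourse_csv",
    "write_trajectory_csv",
    "RunConfig",
    "load_config",
    "fit_result_to_dict",
    "comparison_to_dict",
    "staged_outcome_to_dict",
]

TIMECOURSE_COLUMNS = ("time_h", "species", "value_mM")


def _parse_species(raw: str, row: int) -> Species:
    try:
        return Species[str(raw).strip().upper()]
    except KeyError:
        raise ConfigurationError(
            f"row {row}: unknown species {raw!r}; expected one of "
            f"{[s.name for s in SPECIES_ORDER]} (case-insensitive)"
        ) from None


def read_timecourse_csv(path: str | Path) -> TimeSeriesData:
    """Read a long-format time course CSV into a validated dataset.

    Expects the header ``time_h,species,value_mM`` with species from the
    pathway vocabulary (case-insensitive). Duplicate (time, species)
    rows, negative values and non-numeric fields are rejected with the
    offending row named.
    """
    df = pd.read_csv(path)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        species = _parse_species(row["species"], i)
        try:
            t = float(row["time_h"])
            v = float(row["value_mM"])
        except (TypeError, ValueError):
            raise ConfigurationError(
                f"row {i}: non-numeric time_h/value_mM "
                f"({row['time_h']!r}, {row['value_mM']!r})"
            ) from None
        if v < 0:
            raise ConfigurationError(f"row {i}: negative value_mM {v}")
        records.append((t, species, v))
    try:
        return TimeSeriesData.from_records(records)
    except ConfigurationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from None


def write_timecourse_csv(data: TimeSeriesData, path: str | Path) -> None:
    """Write a dataset as long-format CSV (12 significant digits)."""
    df = pd.DataFrame(
        {
            "time_h": [o.time for o in data.observations],
            "species": [o.species.name for o in data.observations],
            "value_mM": [o.value for o in data.observations],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as long-format CSV, time-major, species in
    state-vector order."""
    rows = {
        "time_h": np.repeat(trajectory.times, len(SPECIES_ORDER)),
        "species": [s.name for _ in trajectory.times for s in SPECIES_ORDER],
        "value_mM": trajectory.states.reshape(-1),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


class ParamSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    value: float = Field(ge=0)
    free: bool = False
    lower: float = Field(default=0.0, ge=0)
    upper: float = Field(default=1.0e3, ge=0)


class InitialStateSpec(BaseModel):
    """Either glucose in g/L (converted via its molar mass) or explicit
    per-species mM (which wins if both are given). Defaults to the 40 g/L
    medium glucose."""

    model_config = ConfigDict(extra="forbid")
    glucose_gL: Optional[float] = Field(default=40.0, ge=0)
    species_mM: Optional[dict[str, float]] = None

    def to_vector(self) -> np.ndarray:
        if self.species_mM is None:
            return default_initial_state(
                mass_to_molar_conc(self.glucose_gL, "glucose")
            )
        state = np.zeros(len(SPECIES_ORDER))
        for name, value in (self.species_mM or {}).items():
            state[_parse_species(name, -1)] = float(value)
        return state


class GridSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: float = 0.0
    stop: float = 96.0
    step: float = Field(default=1.0, gt=0)

    def to_array(self) -> np.ndarray:
        return np.arange(self.start, self.stop + self.step / 2, self.step)


class FitSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    restarts: int = Field(default=8, ge=1)
    xatol: float = Field(default=1e-8, gt=0)
    fatol: float = Field(default=1e-12, gt=0)
    maxiter: int = Field(default=2000, ge=1)


class NoiseSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["none", "additive_sd", "proportional_cv"] = "proportional_cv"
    sd: float = Field(default=0.0, ge=0)
    cv: float = Field(default=0.05, ge=0)
    floor: float = Field(default=0.2, ge=0)
    seed: int = 0


class RunConfig(BaseModel):
    """Validated configuration for the CLI; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    variant: str
    params: dict[str, ParamSpec]
    initial_state: InitialStateSpec = Field(default_factory=InitialStateSpec)
    t_grid: GridSpec = Field(default_factory=GridSpec)
    rtol: float = Field(default=1e-8, gt=0)
    atol: float = Field(default=1e-10, gt=0)
    fit: FitSpec = Field(default_factory=FitSpec)
    noise: NoiseSpec = Field(default_factory=NoiseSpec)

    def model_variant(self) -> ModelVariant:
        try:
            return ModelVariant[self.variant.upper()]
        except KeyError:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of "
                f"{[v.value for v in ModelVariant]}"
            ) from None


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON (or YAML, by extension) run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return RunConfig.model_validate(raw)


def fit_result_to_dict(result: FitResult) -> dict:
    return {
        "variant": result.variant.value,
        "params": result.params.value_dict(),
        "free": list(result.free_names),
        "rss": result.rss,
        "n": result.n,
        "k": result.k,
        "aic": result.aic,
        "converged": result.converged,
        "n_evaluations": result.n_evaluations,
        "restarts": result.restarts,
        "seed": result.seed,
    }


def comparison_to_dict(comparison: ModelComparison) -> dict:
    return {
        "preferred": comparison.preferred,
        "inconclusive": comparison.inconclusive,
        "entries": [
            {
                "label": e.label,
                "rss": e.rss,
                "n": e.n,
                "k": e.k,
                "aic": e.aic,
                "delta_aic": e.delta_aic,
            }
            for e in comparison.entries
        ],
    }


def staged_outcome_to_dict(outcome: StagedFitOutcome) -> dict:
    return {
        "stage1_mr40": fit_result_to_dict(outcome.stage1_mr40),
        "stage2_dko_linear": fit_result_to_dict(outcome.stage2_dko_linear),
        "stage3_dko_inhibition": fit_result_to_dict(outcome.stage3_dko_inhibition),
        "stage4_fadb": fit_result_to_dict(outcome.stage4_fadb),
        "comparison": comparison_to_dict(outcome.comparison),
    }
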