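"""Pathway species, model variants, rate laws and ODE right-hand sides.

The pathway is a lumped irreversible chain

    glucose -> butyryl-CoA -> butanal -> hexane-2,3-diol

with an optional first-order drain of butyryl-CoA to butyrate
(thioesterase activity) and with the butyryl-CoA -> butanal step modelled
either as first-order mass action or as a substrate-inhibition rate law.
All concentrations are carried in mM and all times in hours; first-order
constants are h^-1, Vmax is mM/h, Km and Ki are mM.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Species",
    "SPECIES_ORDER",
    "ModelVariant",
    "Param",
    "KineticParams",
    "DomainError",
    "ConfigurationError",
    "GLUCOSE_MW",
    "DEFAULT_G0_MM",
    "DEFAULT_KM_MM",
    "NEGATIVE_STATE_TOL",
    "mass_action_rate",
    "michaelis_menten_rate",
    "substrate_inhibition_rate",
    "saturation_fraction",
    "evaluate_rhs",
    "default_initial_state",
]


class DomainError(ValueError):
    """An argument is outside the mathematical domain of a rate law."""


class ConfigurationError(ValueError):
    """A parameter set or run configuration is incomplete or inconsistent."""


class Species(enum.IntEnum):
    """The five pathway species, in the fixed state-vector order."""

    GLUCOSE = 0
    BUTYRYL_COA = 1
    BUTANAL = 2
    BUTYRATE = 3
    HDO = 4


SPECIES_ORDER: tuple[Species, ...] = tuple(Species)

#: molar mass of glucose, g/mol
GLUCOSE_MW = 180.16

#: default initial glucose, mM (40 g/L medium glucose)
DEFAULT_G0_MM = 40.0 / GLUCOSE_MW * 1000.0

#: literature Km of the CoA-acylating aldehyde dehydrogenase step,
#: 0.87 uM expressed in mM
DEFAULT_KM_MM = 8.7e-4

#: states more negative than this (mM) are treated as an integrator failure
#: rather than round-off; smaller negatives are clamped to 0 for rate
#: evaluation
NEGATIVE_STATE_TOL = 1e-6


class ModelVariant(enum.Enum):
    """The four lumped ODE model variants.

    MR40_PHABJ
        Parent strain, PhaB-PhaJ inflow, first-order butanal formation and
        a first-order butyrate drain.
    DKO_PHABJ
        Thioesterase double knockout: butyrate drain removed, butanal
        formation first-order (constant ``Km2``).
    DKO_PHABJ_INHIB
        As DKO_PHABJ but with the butanal-forming step under substrate
        inhibition (``Vmax``, ``Km``, ``Ki``).
    DKO_FADB_INHIB
        As DKO_PHABJ_INHIB with the slower FadB-route inflow constant
        ``Kb1`` in place of ``Ka1``.
    """

    MR40_PHABJ = "MR40_PHABJ"
    DKO_PHABJ = "DKO_PHABJ"
    DKO_PHABJ_INHIB = "DKO_PHABJ_INHIB"
    DKO_FADB_INHIB = "DKO_FADB_INHIB"

    @property
    def param_names(self) -> tuple[str, ...]:
        return _VARIANT_PARAMS[self]

    @property
    def has_butyrate_drain(self) -> bool:
        return self is ModelVariant.MR40_PHABJ


_VARIANT_PARAMS: dict[ModelVariant, tuple[str, ...]] = {
    ModelVariant.MR40_PHABJ: ("Ka1", "Km1", "Ka2", "Ka3"),
    ModelVariant.DKO_PHABJ: ("Ka1", "Km2", "Ka3"),
    ModelVariant.DKO_PHABJ_INHIB: ("Ka1", "Ka3", "Vmax", "Km", "Ki"),
    ModelVariant.DKO_FADB_INHIB: ("Kb1", "Ka3", "Vmax", "Km", "Ki"),
}

#: default box bounds for rate constants, in each parameter's own unit
DEFAULT_BOUNDS = (0.0, 1.0e3)


@dataclass(frozen=True)
class Param:
    """One named rate constant with a free/fixed flag and box bounds."""

    value: float
    free: bool = False
    lower: float = DEFAULT_BOUNDS[0]
    upper: float = DEFAULT_BOUNDS[1]

    def __post_init__(self) -> None:
        if self.value < 0 or self.lower < 0 or self.upper < 0:
            raise DomainError("rate constants and bounds must be nonnegative")
        if self.free and not (self.lower <= self.value <= self.upper):
            raise DomainError(
                f"free parameter value {self.value} outside bounds "
                f"[{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class KineticParams:
    """A complete, validated parameter set for one model variant."""

    variant: ModelVariant
    params: Mapping[str, Param] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = set(self.variant.param_names)
        got = set(self.params)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ConfigurationError(
                f"parameter set for {self.variant.value} must be exactly "
                f"{sorted(expected)}; missing {missing}, unexpected {extra}"
            )

    @classmethod
    def for_variant(
        cls,
        variant: ModelVariant,
        values: Mapping[str, float],
        free: Iterable[str] = (),
        bounds: Mapping[str, tuple[float, float]] | None = None,
    ) -> "KineticParams":
        """Build a parameter set from plain numbers.

        Parameters
        ----------
        variant
            Which model the set belongs to; the key set of ``values`` must
            equal the variant's declared parameter names.
        values
            Parameter name -> value (nonnegative, in that parameter's unit).
        free
            Names to mark as free (fitted); all others are fixed.
        bounds
            Optional per-name ``(lower, upper)`` overrides of the default
            box ``[0, 1e3]``.
        """
        free_set = set(free)
        unknown = free_set - set(variant.param_names)
        if unknown:
            raise ConfigurationError(f"free names not in variant: {sorted(unknown)}")
        if set(values) != set(variant.param_names):
            raise ConfigurationError(
                f"parameter set for {variant.value} must be exactly "
                f"{sorted(variant.param_names)}, got {sorted(values)}"
            )
        bounds = bounds or {}
        built = {
            name: Param(
                value=float(values[name]),
                free=name in free_set,
                lower=bounds.get(name, DEFAULT_BOUNDS)[0],
                upper=bounds.get(name, DEFAULT_BOUNDS)[1],
            )
            for name in variant.param_names
        }
        return cls(variant=variant, params=built)

    def value_dict(self) -> dict[str, float]:
        return {name: p.value for name, p in self.params.items()}

    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.variant.param_names if self.params[n].free)

    @property
    def k(self) -> int:
        """Number of free (adjustable) parameters."""
        return len(self.free_names())

    def with_values(self, updates: Mapping[str, float]) -> "KineticParams":
        """Return a copy with some parameter values replaced."""
        new = dict(self.params)
        for name, value in updates.items():
            if name not in new:
                raise ConfigurationError(f"unknown parameter {name!r}")
            new[name] = replace(new[name], value=float(value))
        return KineticParams(variant=self.variant, params=new)

    def with_free(self, free: Iterable[str]) -> "KineticParams":
        """Return a copy with exactly the given names marked free."""
        free_set = set(free)
        unknown = free_set - set(self.params)
        if unknown:
            raise ConfigurationError(f"unknown parameter(s) {sorted(unknown)}")
        new = {
            name: replace(p, free=name in free_set) for name, p in self.params.items()
        }
        return KineticParams(variant=self.variant, params=new)


def mass_action_rate(k: float, S: float) -> float:
    """First-order mass-action flux ``k * S`` (mM/h)."""
    if k < 0 or S < 0:
        raise DomainError("mass_action_rate requires k >= 0 and S >= 0")
    return k * S


def michaelis_menten_rate(Vmax: float, Km: float, S: float) -> float:
    """Michaelis-Menten flux ``Vmax * S / (Km + S)`` (mM/h).

    Monotone nondecreasing in S and bounded above by Vmax.
    """
    if Vmax < 0 or S < 0:
        raise DomainError("michaelis_menten_rate requires Vmax >= 0 and S >= 0")
    if Km <= 0:
        raise DomainError("michaelis_menten_rate requires Km > 0")
    return Vmax * S / (Km + S)


def substrate_inhibition_rate(Vmax: float, Km: float, Ki: float, S: float) -> float:
    """Substrate-inhibition flux ``Vmax * S / (Km + S + S^2/Ki)`` (mM/h).

    Dominated pointwise by the Michaelis-Menten rate with the same Vmax and
    Km; unimodal in S with its maximum at ``S = sqrt(Km * Ki)`` where the
    value is ``Vmax / (1 + 2*sqrt(Km/Ki))``.
    """
    if Vmax < 0 or S < 0:
        raise DomainError("substrate_inhibition_rate requires Vmax >= 0 and S >= 0")
    if Km <= 0 or Ki <= 0:
        raise DomainError("substrate_inhibition_rate requires Km > 0 and Ki > 0")
    return Vmax * S / (Km + S + S * S / Ki)


def saturation_fraction(Km: float, S: float) -> float:
    """Fraction of Vmax reached at substrate S: ``S / (Km + S)``, in [0, 1)."""
    if Km <= 0:
        raise DomainError("saturation_fraction requires Km > 0")
    if S < 0:
        raise DomainError("saturation_fraction requires S >= 0")
    return S / (Km + S)


def inhibition_peak_substrate(Km: float, Ki: float) -> float:
    """Maximizer of the substrate-inhibition rate over S: ``sqrt(Km*Ki)``."""
    if Km <= 0 or Ki <= 0:
        raise DomainError("Km and Ki must be positive")
    return math.sqrt(Km * Ki)


def default_initial_state(glucose_mm: float = DEFAULT_G0_MM) -> np.ndarray:
    """State vector with the given glucose (mM) and all other species at 0."""
    if glucose_mm < 0:
        raise DomainError("initial glucose must be nonnegative")
    state = np.zeros(len(SPECIES_ORDER))
    state[Species.GLUCOSE] = glucose_mm
    return state


def _clamped_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (len(SPECIES_ORDER),):
        raise ConfigurationError(
            f"state must have {len(SPECIES_ORDER)} components, got {state.shape}"
        )
    if np.any(state < -NEGATIVE_STATE_TOL):
        raise DomainError(
            f"state has a concentration below -{NEGATIVE_STATE_TOL} mM: {state}"
        )
    return np.maximum(state, 0.0)


def evaluate_rhs(
    variant: ModelVariant,
    state: np.ndarray,
    params: KineticParams | Mapping[str, float],
) -> np.ndarray:
    """Evaluate the ODE right-hand side of one model variant (mM/h).

    The five components (glucose, butyryl-CoA, butanal, butyrate, diol)
    always sum to zero: every outflow of one species is an inflow of
    another, so total concentration is conserved along exact trajectories.

    Concentrations within ``NEGATIVE_STATE_TOL`` below zero are clamped to
    zero before rate evaluation; larger negatives raise ``DomainError``.
    """
    if isinstance(params, KineticParams):
        if params.variant is not variant:
            raise ConfigurationError(
                f"params are for {params.variant.value}, not {variant.value}"
            )
        values = params.value_dict()
    else:
        values = dict(params)
        missing = [n for n in variant.param_names if n not in values]
        if missing:
            raise ConfigurationError(
                f"missing parameter(s) for {variant.value}: {missing}"
            )

    c = _clamped_state(state)
    G = c[Species.GLUCOSE]
    B = c[Species.BUTYRYL_COA]
    A = c[Species.BUTANAL]

    if variant is ModelVariant.DKO_FADB_INHIB:
        inflow = mass_action_rate(values["Kb1"], G)
    else:
        inflow = mass_action_rate(values["Ka1"], G)

    if variant is ModelVariant.MR40_PHABJ:
        to_butanal = mass_action_rate(values["Km1"], B)
        to_butyrate = mass_action_rate(values["Ka2"], B)
    elif variant is ModelVariant.DKO_PHABJ:
        to_butanal = mass_action_rate(values["Km2"], B)
        to_butyrate = 0.0
    else:
        to_butanal = substrate_inhibition_rate(
            values["Vmax"], values["Km"], values["Ki"], B
        )
        to_butyrate = 0.0

    to_diol = mass_action_rate(values["Ka3"], A)

    deriv = np.empty(len(SPECIES_ORDER))
    deriv[Species.GLUCOSE] = -inflow
    deriv[Species.BUTYRYL_COA] = inflow - to_butanal - to_butyrate
    deriv[Species.BUTANAL] = to_butanal - to_diol
    deriv[Species.BUTYRATE] = to_butyrate
    deriv[Species.HDO] = to_diol
    return deriv


def butyryl_coa_flows(
    variant: ModelVariant,
    state: np.ndarray,
    values: Mapping[str, float],
) -> tuple[float, float]:
    """Instantaneous (inflow, total outflow) of butyryl-CoA, mM/h."""
    c = _clamped_state(state)
    G = c[Species.GLUCOSE]
    B = c[Species.BUTYRYL_COA]
    if variant is ModelVariant.DKO_FADB_INHIB:
        inflow = values["Kb1"] * G
    else:
        inflow = values["Ka1"] * G
    if variant is ModelVariant.MR40_PHABJ:
        outflow = (values["Km1"] + values["Ka2"]) * B
    elif variant is ModelVariant.DKO_PHABJ:
        outflow = values["Km2"] * B
    else:
        outflow = substrate_inhibition_rate(
            values["Vmax"], values["Km"], values["Ki"], B
        )
    return inflow, outflow
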