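"""Fermentation performance metrics: titer unit conversion, substrate
yield and volumetric productivity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetics import DomainError

__all__ = [
    "CompoundInfo",
    "FermentationRecord",
    "COMPOUNDS",
    "get_compound",
    "molar_to_mass_conc",
    "mass_to_molar_conc",
    "substrate_yield",
    "volumetric_productivity",
    "metrics_report",
]


@dataclass(frozen=True)
class CompoundInfo:
    name: str
    formula: str
    molar_mass: float  # g/mol

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise DomainError("molar mass must be positive")


# Molar masses from standard atomic weights, 2 decimals.
COMPOUNDS: dict[str, CompoundInfo] = {
    c.name: c
    for c in (
        CompoundInfo("hexane-2,3-diol", "C6H14O2", 118.17),
        CompoundInfo("pentane-2,3-diol", "C5H12O2", 104.15),
        CompoundInfo("butyric acid", "C4H8O2", 88.11),
        CompoundInfo("butanal", "C4H8O", 72.11),
        CompoundInfo("butane-2,3-diol", "C4H10O2", 90.12),
        CompoundInfo("glucose", "C6H12O6", 180.16),
        CompoundInfo("3-hydroxypentan-2-one", "C5H10O2", 102.13),
    )
}

_ALIASES = {
    "2,3-hdo": "hexane-2,3-diol",
    "hdo": "hexane-2,3-diol",
    "2,3-pdo": "pentane-2,3-diol",
    "pdo": "pentane-2,3-diol",
    "butyrate": "butyric acid",
    "2,3-bdo": "butane-2,3-diol",
    "bdo": "butane-2,3-diol",
    "3-h-p-one": "3-hydroxypentan-2-one",
}


def get_compound(name: str | CompoundInfo) -> CompoundInfo:
    """Look a compound up by canonical name or alias (case-insensitive)."""
    if isinstance(name, CompoundInfo):
        return name
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    try:
        return COMPOUNDS[key]
    except KeyError:
        raise KeyError(
            f"unknown compound {name!r}; known: {sorted(COMPOUNDS)}"
        ) from None


@dataclass(frozen=True)
class FermentationRecord:
    """One fermentation run's summary quantities."""

    compound: str
    titer: float
    titer_unit: str  # "mM" or "g/L"
    substrate_consumed_gL: float
    duration_h: float

    def __post_init__(self) -> None:
        if self.titer < 0 or self.substrate_consumed_gL < 0:
            raise DomainError("titer and substrate consumed must be nonnegative")
        if self.duration_h <= 0:
            raise DomainError("duration must be positive")
        if self.titer_unit not in ("mM", "g/L"):
            raise DomainError(f"titer_unit must be 'mM' or 'g/L', got {self.titer_unit!r}")


def molar_to_mass_conc(conc_mm: float, compound: str | CompoundInfo) -> float:
    """Convert mM to g/L: ``conc * M / 1000``."""
    if conc_mm < 0:
        raise DomainError("concentration must be nonnegative")
    return conc_mm * get_compound(compound).molar_mass / 1000.0


def mass_to_molar_conc(conc_gl: float, compound: str | CompoundInfo) -> float:
    """Convert g/L to mM (exact inverse of ``molar_to_mass_conc``)."""
    if conc_gl < 0:
        raise DomainError("concentration must be nonnegative")
    return conc_gl * 1000.0 / get_compound(compound).molar_mass


def substrate_yield(titer_gl: float, substrate_consumed_gl: float) -> float:
    """Product yield in g product per g substrate consumed."""
    if substrate_consumed_gl <= 0:
        raise DomainError("substrate consumed must be positive")
    if titer_gl < 0:
        raise DomainError("titer must be nonnegative")
    return titer_gl / substrate_consumed_gl


def volumetric_productivity(titer_gl: float, duration_h: float) -> float:
    """Volumetric productivity in g/L/h."""
    if duration_h <= 0:
        raise DomainError("duration must be positive")
    if titer_gl < 0:
        raise DomainError("titer must be nonnegative")
    return titer_gl / duration_h


def metrics_report(record: FermentationRecord) -> dict[str, float]:
    """Full metric set for one run, via the single molar-mass table.

    The yield denominator is the record's ``substrate_consumed_gL``
    exactly as supplied (consumed glucose for bioreactor runs, initial
    medium glucose for shake flasks) — the caller decides, not this
    function.
    """
    if record.titer_unit == "mM":
        titer_mm = record.titer
        titer_gl = molar_to_mass_conc(record.titer, record.compound)
    else:
        titer_gl = record.titer
        titer_mm = mass_to_molar_conc(record.titer, record.compound)
    return {
        "titer_mM": titer_mm,
        "titer_gL": titer_gl,
        "yield_gg": substrate_yield(titer_gl, record.substrate_consumed_gL),
        "productivity_gLh": volumetric_productivity(titer_gl, record.duration_h),
    }
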