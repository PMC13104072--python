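"""Least-squares fitting of rate constants to sparse time courses, the
RSS/AIC machinery, the staged four-model fitting protocol and AIC-based
model comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .kinetics import (
    DEFAULT_KM_MM,
    ConfigurationError,
    DomainError,
    KineticParams,
    ModelVariant,
    Species,
    default_initial_state,
)
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL, integrate

__all__ = [
    "Observation",
    "TimeSeriesData",
    "FitResult",
    "ComparisonEntry",
    "ModelComparison",
    "OptimizerConfig",
    "StagedFitConfig",
    "StagedFitOutcome",
    "compute_rss",
    "aic",
    "infer_n_k",
    "fit_params",
    "staged_fit_protocol",
    "compare_models",
    "AIC_RSS_ZERO",
]

#: sentinel AIC for a zero-RSS (interpolating) fit, where ln(RSS/n) is
#: undefined; such entries are excluded from comparisons with a warning
AIC_RSS_ZERO = float("-inf")

#: default observation grid, hours (n = 5 per observed species)
DEFAULT_OBS_TIMES = (0.0, 24.0, 48.0, 72.0, 96.0)


@dataclass(frozen=True)
class Observation:
    """A single (time, species, concentration) record."""

    time: float
    species: Species
    value: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DomainError("observation time must be nonnegative")
        if self.value < 0:
            raise DomainError("observed concentration must be nonnegative")


@dataclass(frozen=True)
class TimeSeriesData:
    """Sparse observations used as the fitting target.

    ``n`` (the number of records) is the sample size that enters the AIC
    formula.
    """

    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        if len(self.observations) < 1:
            raise ConfigurationError("a dataset needs at least one observation")
        keys = [(o.time, o.species) for o in self.observations]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate (time, species) observation")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[float, Species | str, float]]
    ) -> "TimeSeriesData":
        obs = []
        for time, species, value in records:
            if isinstance(species, str):
                species = Species[species.upper()]
            obs.append(Observation(float(time), species, float(value)))
        return cls(tuple(sorted(obs, key=lambda o: (o.time, o.species))))

    @property
    def n(self) -> int:
        return len(self.observations)

    def times(self) -> np.ndarray:
        return np.unique([o.time for o in self.observations])

    def species_set(self) -> set[Species]:
        return {o.species for o in self.observations}

    def subset(self, species: Species) -> "TimeSeriesData":
        kept = tuple(o for o in self.observations if o.species is species)
        return TimeSeriesData(kept)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one least-squares fit.

    Invariant: ``aic == n*ln(rss/n) + 2*k`` exactly as stored (or the
    ``-inf`` sentinel when ``rss == 0``).
    """

    variant: ModelVariant
    params: KineticParams
    free_names: tuple[str, ...]
    rss: float
    n: int
    k: int
    aic: float
    converged: bool
    n_evaluations: int
    restarts: int
    seed: int


@dataclass(frozen=True)
class ComparisonEntry:
    label: str
    rss: float
    n: int
    k: int
    aic: float
    delta_aic: float


@dataclass(frozen=True)
class ModelComparison:
    """AIC ranking of candidate fits (ascending; first entry preferred)."""

    entries: tuple[ComparisonEntry, ...]
    preferred: str
    inconclusive: bool


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for the bounded derivative-free simplex optimizer.

    Restart starting points are drawn log-uniformly per free parameter
    from the intersection of the parameter's box with ``draw_window``
    (rate constants of this pathway live within a few decades of 1, so
    restarts are concentrated there rather than across the whole default
    [0, 1e3] box).
    """

    seed: int = 0
    restarts: int = 8
    xatol: float = 1e-6
    fatol: float = 1e-10
    maxiter: int = 1000
    draw_window: tuple[float, float] = (1e-4, 1e2)


@dataclass(frozen=True)
class StagedFitConfig:
    initial_state: np.ndarray = field(
        default_factory=lambda: default_initial_state()
    )
    km_mm: float = DEFAULT_KM_MM
    # fitting needs predictions good to ~1e-4 mM, not the tight simulation
    # defaults; looser tolerances roughly halve the protocol's runtime
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    rtol: float = 1e-6
    atol: float = 1e-8


@dataclass(frozen=True)
class StagedFitOutcome:
    """Ordered results of the four-stage fitting protocol."""

    stage1_mr40: FitResult
    stage2_dko_linear: FitResult
    stage3_dko_inhibition: FitResult
    stage4_fadb: FitResult
    comparison: ModelComparison


def compute_rss(
    variant: ModelVariant,
    params: KineticParams | Mapping[str, float],
    initial_state: Sequence[float],
    data: TimeSeriesData,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Residual sum of squares between data and the model prediction.

    The model is integrated over a grid containing every observation time
    and the squared residuals are summed over all records (mM^2).
    """
    obs_times = data.times()
    t_grid = np.unique(np.concatenate([[0.0], obs_times]))
    traj = integrate(variant, params, initial_state, t_grid, rtol=rtol, atol=atol)
    time_index = {t: i for i, t in enumerate(t_grid)}
    rss = 0.0
    for obs in data.observations:
        pred = traj.states[time_index[obs.time], obs.species]
        rss += (obs.value - pred) ** 2
    return float(rss)


def aic(RSS: float, n: int, k: int) -> float:
    """Akaike information criterion ``n * ln(RSS/n) + 2k``.

    No small-sample correction is applied. ``RSS == 0`` returns the
    ``-inf`` sentinel with a warning, since the log is undefined.
    """
    if RSS < 0:
        raise DomainError("RSS must be nonnegative")
    if n < 1:
        raise DomainError("n must be >= 1")
    if k < 0:
        raise DomainError("k must be >= 0")
    if RSS == 0:
        warnings.warn(
            "RSS is exactly 0; AIC is undefined and reported as -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return AIC_RSS_ZERO
    return n * math.log(RSS / n) + 2 * k


def infer_n_k(
    RSS: float,
    AIC_target: float,
    n_range: Iterable[int] = range(3, 11),
    k_range: Iterable[int] = range(0, 6),
    tol: float = 0.01,
) -> list[tuple[int, int]]:
    """All (n, k) integer pairs whose AIC matches a target within ``tol``.

    Exhaustive grid oracle used to validate printed RSS/AIC pairs when the
    sample size and parameter count are not stated explicitly.
    """
    if RSS <= 0:
        raise DomainError("RSS must be positive")
    hits = []
    for n in n_range:
        for k in k_range:
            if abs(n * math.log(RSS / n) + 2 * k - AIC_target) < tol:
                hits.append((n, k))
    return hits


def _loguniform_draw(
    rng: np.random.Generator, lower: float, upper: float, window: tuple[float, float]
) -> float:
    lo = max(lower, window[0])
    hi = min(upper, window[1])
    if hi <= lo:  # box does not intersect the window; fall back to the box
        lo, hi = max(lower, 1e-12), max(upper, 1e-11)
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def fit_params(
    variant: ModelVariant,
    data: TimeSeriesData,
    params: KineticParams,
    initial_state: Sequence[float],
    optimizer: OptimizerConfig | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> FitResult:
    """Minimize RSS over the free parameters of ``params``.

    Optimization runs in log10 parameter space with a bounded Nelder-Mead
    simplex, restarted from the supplied values plus ``restarts - 1``
    log-uniform draws; the best restart wins. Deterministic for a given
    seed and configuration.

    With zero free parameters the model is simply evaluated (k = 0).
    """
    optimizer = optimizer or OptimizerConfig()
    free = params.free_names()
    k = len(free)
    n = data.n
    if k > 0 and n < k:
        raise ConfigurationError(f"need n >= k, got n={n}, k={k}")

    def rss_for(values: Mapping[str, float]) -> float:
        return compute_rss(
            variant,
            params.with_values(values).value_dict(),
            initial_state,
            data,
            rtol=rtol,
            atol=atol,
        )

    if k == 0:
        rss = rss_for({})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            score = aic(rss, n, 0) if rss > 0 else AIC_RSS_ZERO
        return FitResult(
            variant=variant,
            params=params,
            free_names=(),
            rss=rss,
            n=n,
            k=0,
            aic=score,
            converged=True,
            n_evaluations=1,
            restarts=0,
            seed=optimizer.seed,
        )

    bounds = [(params.params[name].lower, params.params[name].upper) for name in free]
    log_bounds = [
        (math.log10(max(lo, 1e-12)), math.log10(max(hi, 1e-11))) for lo, hi in bounds
    ]

    def objective(x: np.ndarray) -> float:
        values = {name: 10.0 ** xi for name, xi in zip(free, x)}
        try:
            return rss_for(values)
        except (DomainError, RuntimeError):
            return 1e30  # failed integration: repel the simplex

    rng = np.random.default_rng(optimizer.seed)
    starts = [
        np.array(
            [
                math.log10(np.clip(params.params[name].value, 10 ** lb, 10 ** ub))
                if params.params[name].value > 0
                else (lb + ub) / 2
                for name, (lb, ub) in zip(free, log_bounds)
            ]
        )
    ]
    for _ in range(max(optimizer.restarts - 1, 0)):
        starts.append(
            np.array(
                [
                    math.log10(
                        _loguniform_draw(rng, lo, hi, optimizer.draw_window)
                    )
                    for lo, hi in bounds
                ]
            )
        )

    best = None
    n_eval = 0
    any_converged = False
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=log_bounds,
            options={
                "xatol": optimizer.xatol,
                "fatol": optimizer.fatol,
                "maxiter": optimizer.maxiter,
                "maxfev": optimizer.maxiter,
            },
        )
        n_eval += res.nfev
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    # polish: restart the simplex at the winner with tighter tolerances;
    # recovers slow progress along nearly flat valleys (weakly identified
    # directions) where a first pass can stall on fatol
    polish = minimize(
        objective,
        best.x,
        method="Nelder-Mead",
        bounds=log_bounds,
        options={
            "xatol": optimizer.xatol * 1e-2,
            "fatol": optimizer.fatol * 1e-4,
            "maxiter": optimizer.maxiter,
            "maxfev": optimizer.maxiter,
        },
    )
    n_eval += polish.nfev
    if polish.fun <= best.fun:
        best = polish

    fitted_values = {name: 10.0 ** xi for name, xi in zip(free, best.x)}
    fitted = params.with_values(fitted_values)
    rss = float(best.fun)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        score = aic(rss, n, k) if rss > 0 else AIC_RSS_ZERO
    return FitResult(
        variant=variant,
        params=fitted,
        free_names=free,
        rss=rss,
        n=n,
        k=k,
        aic=score,
        converged=any_converged,
        n_evaluations=n_eval,
        restarts=optimizer.restarts,
        seed=optimizer.seed,
    )


def compare_models(
    entries: Sequence[FitResult | tuple[str, float, int, int]],
) -> ModelComparison:
    """Rank candidate fits by AIC (recomputed from stored RSS, n, k).

    Zero-RSS entries are excluded with a warning (their AIC is undefined).
    The result is flagged inconclusive when the runner-up's delta-AIC is
    below 2, or when every entry had to be excluded.
    """
    if len(entries) < 1:
        raise ConfigurationError("compare_models needs at least one entry")
    scored: list[tuple[str, float, int, int, float]] = []
    for entry in entries:
        if isinstance(entry, FitResult):
            label, rss, n, k = entry.variant.value, entry.rss, entry.n, entry.k
        else:
            label, rss, n, k = entry
        if rss == 0:
            warnings.warn(
                f"entry {label!r} has RSS = 0; excluded from AIC comparison",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        scored.append((label, rss, n, k, aic(rss, n, k)))

    if not scored:
        only = entries[0]
        label = only.variant.value if isinstance(only, FitResult) else only[0]
        return ModelComparison(entries=(), preferred=label, inconclusive=True)

    scored.sort(key=lambda e: e[4])
    best_aic = scored[0][4]
    ranked = tuple(
        ComparisonEntry(label=l, rss=r, n=n, k=k, aic=a, delta_aic=a - best_aic)
        for l, r, n, k, a in scored
    )
    inconclusive = len(ranked) > 1 and ranked[1].delta_aic < 2.0
    return ModelComparison(
        entries=ranked, preferred=ranked[0].label, inconclusive=inconclusive
    )


def staged_fit_protocol(
    mr40_data: TimeSeriesData,
    dko_data: TimeSeriesData,
    fadb_data: TimeSeriesData,
    config: StagedFitConfig | None = None,
) -> StagedFitOutcome:
    """Run the four-stage fitting protocol and the stage-2/3 comparison.

    Stage 1
        Fit the parent-strain model (free Ka1, Km1, Ka2, Ka3) jointly to
        the butyrate and diol observations of ``mr40_data`` (equal
        weighting, mM^2).
    Stage 2
        Fix Ka1 and Ka3 at their stage-1 values; fit the linear knockout
        model (free Km2) to the diol observations of ``dko_data``.
    Stage 3
        Fix Ka1, Ka3 (stage 1) and Km (config, default 8.7e-4 mM); fit the
        substrate-inhibition knockout model (free Vmax, Ki) to the same
        data. Compare stage 2 vs stage 3 by AIC.
    Stage 4
        Fix Ka3, Vmax, Km, Ki at stage-3 values; fit the FadB-route model
        (free Kb1) to the diol observations of ``fadb_data``.
    """
    config = config or StagedFitConfig()
    for name, dataset in (
        ("mr40_data", mr40_data),
        ("dko_data", dko_data),
        ("fadb_data", fadb_data),
    ):
        if dataset is None:
            raise ConfigurationError(f"missing dataset: {name}")
    if Species.BUTYRATE not in mr40_data.species_set():
        raise ConfigurationError("stage 1 needs butyrate observations")
    if Species.HDO not in mr40_data.species_set():
        raise ConfigurationError("stage 1 needs diol observations")

    y0 = np.asarray(config.initial_state, dtype=float)
    opt = config.optimizer

    # Stage 1: parent strain, all four constants free.
    s1_params = KineticParams.for_variant(
        ModelVariant.MR40_PHABJ,
        {"Ka1": 0.01, "Km1": 0.05, "Ka2": 0.05, "Ka3": 0.05},
        free=("Ka1", "Km1", "Ka2", "Ka3"),
    )
    stage1 = fit_params(
        ModelVariant.MR40_PHABJ, mr40_data, s1_params, y0, opt,
        rtol=config.rtol, atol=config.atol,
    )
    ka1 = stage1.params.params["Ka1"].value
    ka3 = stage1.params.params["Ka3"].value

    dko_hdo = dko_data.subset(Species.HDO)

    # Stage 2: linear knockout model, only Km2 free.
    s2_params = KineticParams.for_variant(
        ModelVariant.DKO_PHABJ, {"Ka1": ka1, "Km2": 0.05, "Ka3": ka3}, free=("Km2",)
    )
    stage2 = fit_params(
        ModelVariant.DKO_PHABJ, dko_hdo, s2_params, y0, opt,
        rtol=config.rtol, atol=config.atol,
    )

    # Stage 3: substrate-inhibition knockout model, Vmax and Ki free.
    s3_params = KineticParams.for_variant(
        ModelVariant.DKO_PHABJ_INHIB,
        {"Ka1": ka1, "Ka3": ka3, "Vmax": 1.0, "Km": config.km_mm, "Ki": 1.0},
        free=("Vmax", "Ki"),
    )
    stage3 = fit_params(
        ModelVariant.DKO_PHABJ_INHIB, dko_hdo, s3_params, y0, opt,
        rtol=config.rtol, atol=config.atol,
    )

    comparison = compare_models(
        [
            ("DKO_PHABJ", stage2.rss, stage2.n, stage2.k),
            ("DKO_PHABJ_INHIB", stage3.rss, stage3.n, stage3.k),
        ]
    )

    # Stage 4: FadB route, only the inflow constant free.
    s4_params = KineticParams.for_variant(
        ModelVariant.DKO_FADB_INHIB,
        {
            "Kb1": 0.01,
            "Ka3": ka3,
            "Vmax": stage3.params.params["Vmax"].value,
            "Km": config.km_mm,
            "Ki": stage3.params.params["Ki"].value,
        },
        free=("Kb1",),
    )
    stage4 = fit_params(
        ModelVariant.DKO_FADB_INHIB, fadb_data.subset(Species.HDO), s4_params, y0,
        opt, rtol=config.rtol, atol=config.atol,
    )

    return StagedFitOutcome(
        stage1_mr40=stage1,
        stage2_dko_linear=stage2,
        stage3_dko_inhibition=stage3,
        stage4_fadb=stage4,
        comparison=comparison,
    )
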