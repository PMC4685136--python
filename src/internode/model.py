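"""Daily-step simulator of cucumber main-stem internode growth.

The model tracks two coupled processes on a 1-day time step:

* **Development** — a continuous accumulator advances each day by the
  appearance rate ``F_av(T_today) / Da20`` (reciprocal of the phyllochron);
  every integer threshold crossed creates a new internode at 3 cm.

* **Elongation** — each internode approaches its final length target with
  first-order kinetics, ``dL = k * (FIL_T - L)`` per day, for a fixed
  duration ``De(T) = De20 / F_av(T4d)``, after which its length freezes.

The target length combines a light response,
``FIL(PAR, R:FR) = 13.4 - 0.014 * PAR4d + f(R:FR)`` (cm), with the
temperature factor: ``FIL_T = F_av(T4d) * FIL``.  PAR4d and T4d are means
over the 4-day window starting 6 days before the internode appeared; they,
the target and the duration are fixed once at appearance.

Two scenarios share this code path: the temperature-sensitive model (MA-T)
uses F_av(T), the temperature-insensitive reference (MA-20, the original
model) sets F_av identically to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import pandas as pd

from .arrhenius import ArrheniusParams, normalized_response
from .climate import ClimateSeries, SignalWindow, window_mean

__all__ = [
    "ModelConfig",
    "InternodeState",
    "PlantState",
    "SimulationResult",
    "final_length_light",
    "temperature_target",
    "elongation_step",
    "elongation_duration",
    "appearance_interval",
    "advance_development",
    "simulate",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class ModelConfig:
    """Model parameters.

    Attributes
    ----------
    fil_intercept : float
        Intercept of the light response of final internode length, cm.
    fil_par_slope : float
        Decrease of final length per unit PAR4d, cm per umol m^-2 s^-1
        (applied subtractively).
    k_elong : float
        First-order relative approach rate toward the target, d^-1.
    De20 : float
        Reference elongation duration at 20 degC, d.  Equals the 42 degC d
        thermal-time duration over the 10 degC span above the 10 degC base.
    Da20 : float
        Reference appearance interval (phyllochron) at 20 degC, d;
        reciprocal of the 0.7 d^-1 appearance rate.
    initial_length : float
        Length at which an internode appears, cm.
    temperature_sensitive : bool
        True for the MA-T scenario; False makes F_av identically 1 (MA-20).
    arrhenius : ArrheniusParams
        Temperature response parameters.
    rfr_function : callable ``(rank, day) -> cm`` or None
        Pluggable light-quality term f(R:FR); None means 0 (no canopy
        light-quality signal).
    analysis_min_rank : int
        Lowest rank included in summaries and evaluation (low ranks form
        before the analysed growth period).
    fil_floor : float
        Lower clamp on the light-determined final length, cm.
    window : SignalWindow
        Placement of the PAR4d/T4d signal window.
    fractional_final_step : bool
        If True (default) a non-integer elongation duration applies its
        last partial day scaled by the fractional remainder; if False the
        duration is floored to whole days.
    """

    fil_intercept: float = 13.4
    fil_par_slope: float = 0.014
    k_elong: float = 0.5
    De20: float = 4.2
    Da20: float = 1.4
    initial_length: float = 3.0
    temperature_sensitive: bool = True
    arrhenius: ArrheniusParams = field(default_factory=ArrheniusParams)
    rfr_function: Callable[[int, int], float] | None = None
    analysis_min_rank: int = 5
    fil_floor: float = 3.0
    window: SignalWindow = field(default_factory=SignalWindow)
    fractional_final_step: bool = True

    def __post_init__(self) -> None:
        for name in ("k_elong", "De20", "Da20", "initial_length", "fil_intercept"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.fil_par_slope < 0:
            raise ValueError("fil_par_slope is applied subtractively and must be >= 0")

    def fav(self, T_celsius: float) -> float:
        """Temperature factor for this scenario: F_av(T), or 1 if insensitive."""
        if not self.temperature_sensitive:
            return 1.0
        return normalized_response(T_celsius, self.arrhenius)

    def as_scenario(self, temperature_sensitive: bool) -> "ModelConfig":
        return replace(self, temperature_sensitive=temperature_sensitive)


@dataclass
class InternodeState:
    """One internode: identity, fixed signals, and its length trajectory."""

    rank: int
    appearance_day: int
    length: float
    par4d: float
    t4d: float
    fav: float
    fil_light: float
    target_length: float
    elong_duration: float
    active: bool = True
    elongated_days: float = 0.0

    @property
    def final_length(self) -> float:
        return self.length


@dataclass
class PlantState:
    """Whole-plant state: development accumulator and internode collection."""

    stage: float
    internodes: list[InternodeState]
    day: int


@dataclass
class SimulationResult:
    """Output of :func:`simulate`.

    Attributes
    ----------
    trajectory : pandas.DataFrame
        One row per day and internode: day, rank, length_cm, active.
    internodes : pandas.DataFrame
        Per-internode summary: rank, appearance_day, par4d, t4d, fav,
        fil_light, target_cm, duration_d, final_cm, active.
    daily : pandas.DataFrame
        Per-day summary: day, n_internodes, mean_final_cm (mean final
        length over finished internodes of rank >= analysis_min_rank;
        NaN while none have finished).
    plant : PlantState
        Final plant state.
    """

    trajectory: pd.DataFrame
    internodes: pd.DataFrame
    daily: pd.DataFrame
    plant: PlantState


def final_length_light(par4d: float, rfr_term: float = 0.0, config: ModelConfig | None = None) -> float:
    """Light-determined final internode length (cm) from PAR4d and f(R:FR).

    ``max(fil_floor, intercept - slope * PAR4d + rfr_term)``: the linear
    response goes negative above ~957 umol m^-2 s^-1, so it is clamped at
    the appearance length.
    """
    if config is None:
        config = ModelConfig()
    if par4d < 0:
        raise ValueError(f"PAR4d must be >= 0, got {par4d}")
    fil = config.fil_intercept - config.fil_par_slope * par4d + rfr_term
    return max(config.fil_floor, fil)


def temperature_target(fil_light: float, t4d: float, config: ModelConfig) -> float:
    """Temperature-modulated final length target FIL_T = F_av(T4d) * FIL (cm)."""
    return config.fav(t4d) * fil_light


def elongation_duration(t4d: float, config: ModelConfig) -> float:
    """Elongation duration De(T) = De20 / F_av(T4d), days.

    Fixed once at internode appearance from the organ's T4d signal.
    """
    return config.De20 / config.fav(t4d)


def appearance_interval(T_celsius: float, config: ModelConfig) -> float:
    """Interval between successive appearances Da(T) = Da20 / F_av(T), days."""
    return config.Da20 / config.fav(T_celsius)


def elongation_step(internode: InternodeState, config: ModelConfig, dt: float = 1.0) -> float:
    """Advance one internode by ``dt`` days of first-order elongation.

    The increment is ``max(0, dt * k * (target - length))``: internodes
    never shrink even if the target lies below the current length.
    Inactive internodes are left untouched (logged no-op).

    Returns the updated length (cm).
    """
    if not internode.active:
        logger.debug("elongation_step on frozen internode rank %d ignored", internode.rank)
        return internode.length
    increment = dt * config.k_elong * (internode.target_length - internode.length)
    internode.length += max(0.0, increment)
    return internode.length


def _new_internode(rank: int, day: int, climate: ClimateSeries, config: ModelConfig) -> InternodeState:
    par4d = window_mean(climate, "par", day, config.window)
    t4d = window_mean(climate, "temperature", day, config.window)
    rfr = config.rfr_function(rank, day) if config.rfr_function is not None else 0.0
    fil = final_length_light(par4d, rfr, config)
    fav = config.fav(t4d)
    target = max(config.fil_floor, fav * fil)
    duration = config.De20 / fav
    logger.info(
        "internode rank %d appeared on day %d: PAR4d=%.1f T4d=%.2f Fav=%.3f "
        "FIL=%.2f target=%.2f De=%.2f",
        rank, day, par4d, t4d, fav, fil, target, duration,
    )
    return InternodeState(
        rank=rank,
        appearance_day=day,
        length=config.initial_length,
        par4d=par4d,
        t4d=t4d,
        fav=fav,
        fil_light=fil,
        target_length=target,
        elong_duration=duration,
    )


def advance_development(
    plant: PlantState,
    today_temperature: float,
    config: ModelConfig,
    climate: ClimateSeries,
) -> list[InternodeState]:
    """Advance the development accumulator by one day; create any new internodes.

    The accumulator gains ``F_av(T_today) / Da20`` leaves per day (current
    daily mean temperature, re-evaluated every day).  Each integer
    threshold crossed produces one internode at the initial length, whose
    PAR4d/T4d signals, target and elongation duration are computed and
    fixed immediately.  Fractional progress carries over to the next day;
    several crossings in one day each produce an internode.

    Returns the list of internodes created today (possibly empty).
    """
    plant.stage += config.fav(today_temperature) / config.Da20
    created: list[InternodeState] = []
    while len(plant.internodes) < int(plant.stage + _EPS):
        rank = len(plant.internodes) + 1
        node = _new_internode(rank, plant.day, climate, config)
        plant.internodes.append(node)
        created.append(node)
    return created


def _age_internodes(plant: PlantState, config: ModelConfig, newly_created: list[InternodeState]) -> None:
    """One day of elongation and termination for every active internode.

    Internodes created today keep their appearance length until the next
    day.  An internode elongates for exactly ``elong_duration`` days; a
    non-integer duration ends with a partial day whose increment is scaled
    by the remaining fraction (or is dropped entirely in ``floor`` mode).
    """
    new_ids = {id(n) for n in newly_created}
    for node in plant.internodes:
        if not node.active or id(node) in new_ids:
            continue
        remaining = node.elong_duration - node.elongated_days
        if remaining <= _EPS:
            node.active = False
            continue
        dt = min(1.0, remaining)
        if dt < 1.0 and not config.fractional_final_step:
            node.active = False
            continue
        elongation_step(node, config, dt=dt)
        node.elongated_days += dt
        if node.elong_duration - node.elongated_days <= _EPS:
            node.active = False


def simulate(climate: ClimateSeries, config: ModelConfig, n_steps: int) -> SimulationResult:
    """Run the daily-step simulation for ``n_steps`` steps.

    The run starts at step 2 with the first true leaf and internode
    present: internode 1 at the initial 3 cm, development accumulator at
    1 leaf.  Each subsequent step (one day) applies, in order:

    1. :func:`advance_development` with the day's mean temperature,
    2. one elongation day for every active internode,
    3. termination of internodes whose elongation time is exhausted,
       freezing their length.

    Steps are identified with climate day indices counted from the first
    climate day, i.e. step ``s`` uses the climate record of day
    ``first_day + s - 1``.

    Raises
    ------
    ValueError
        If the climate series is shorter than ``n_steps`` (checked before
        any computation).
    """
    if n_steps < 2:
        raise ValueError(f"need at least 2 steps, got {n_steps}")
    if len(climate) < n_steps:
        raise ValueError(
            f"climate series has {len(climate)} day(s) but {n_steps} steps requested"
        )
    day_of_step = lambda s: climate.first_day + s - 1

    start_day = day_of_step(2)
    plant = PlantState(stage=1.0, internodes=[], day=start_day)
    plant.internodes.append(_new_internode(1, start_day, climate, config))

    traj_rows: list[tuple[int, int, float, bool]] = []
    daily_rows: list[tuple[int, int, float]] = []

    def record(day: int) -> None:
        for node in plant.internodes:
            traj_rows.append((day, node.rank, node.length, node.active))
        finished = [
            n.length
            for n in plant.internodes
            if not n.active and n.rank >= config.analysis_min_rank
        ]
        mean_final = sum(finished) / len(finished) if finished else float("nan")
        daily_rows.append((day, len(plant.internodes), mean_final))

    record(start_day)
    for step in range(3, n_steps + 1):
        plant.day = day_of_step(step)
        today_T = climate.value("temperature", plant.day)
        created = advance_development(plant, today_T, config, climate)
        _age_internodes(plant, config, created)
        record(plant.day)

    trajectory = pd.DataFrame(traj_rows, columns=["day", "rank", "length_cm", "active"])
    daily = pd.DataFrame(daily_rows, columns=["day", "n_internodes", "mean_final_cm"])
    internodes = pd.DataFrame(
        [
            {
                "rank": n.rank,
                "appearance_day": n.appearance_day,
                "par4d": n.par4d,
                "t4d": n.t4d,
                "fav": n.fav,
                "fil_light": n.fil_light,
                "target_cm": n.target_length,
                "duration_d": n.elong_duration,
                "final_cm": n.length,
                "active": n.active,
            }
            for n in plant.internodes
        ]
    )
    return SimulationResult(trajectory=trajectory, internodes=internodes, daily=daily, plant=plant)
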