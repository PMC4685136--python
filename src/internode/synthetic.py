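"""Synthetic greenhouse climate generator.

A phenomenological emulator of daily greenhouse climate, not a physical
greenhouse model: daily mean PAR follows a truncated AR(1) Gaussian
process (weather persistence), and daily mean temperature tracks a period
mean plus a sunny-day warming term proportional to the PAR anomaly, with
Gaussian noise, clipped between the heating set-point and just above the
ventilation threshold.

Two named presets encode the summary climate of the two greenhouse
experiments the model was evaluated against: E1 (PAR 464 +- 116
umol m^-2 s^-1, mean temperature 21.9 degC) and E2 (404 +- 120, 22.4 degC),
both with 20 degC heating set-point and 24 degC ventilation opening, so
realized daily means span roughly 20-24 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .climate import ClimateSeries

__all__ = ["ClimateGenConfig", "generate", "PRESETS", "preset"]


@dataclass(frozen=True)
class ClimateGenConfig:
    """Configuration of the synthetic climate generator.

    Attributes
    ----------
    n_days : int
        Length of the series (day indices 1..n_days).
    seed : int
        Seed for the pseudo-random generator; same seed, same series.
    par_mean, par_sd : float
        Stationary mean and SD of daily mean PAR, umol m^-2 s^-1.
    par_autocorr : float
        AR(1) lag-1 autocorrelation of PAR in [0, 1); day-to-day weather
        persistence.
    temp_mean : float
        Period mean of daily mean temperature, degC.
    temp_base : float
        Heating set-point proxy, degC; lower clip of daily means.
    temp_vent : float
        Ventilation-opening threshold, degC; daily means are clipped at
        temp_vent + 0.5 (ventilation caps but does not instantly remove
        excess heat).
    temp_par_coupling : float
        Sunny-day warming, degC per umol m^-2 s^-1 of PAR anomaly.
    temp_noise_sd : float
        SD of the independent temperature noise, degC.
    """

    n_days: int = 45
    seed: int = 0
    par_mean: float = 464.0
    par_sd: float = 116.0
    par_autocorr: float = 0.5
    temp_mean: float = 21.9
    temp_base: float = 20.0
    temp_vent: float = 24.0
    temp_par_coupling: float = 0.005
    temp_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.par_mean <= 0:
            raise ValueError("par_mean must be positive")
        if self.par_sd < 0 or self.temp_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0 <= self.par_autocorr < 1):
            raise ValueError("par_autocorr must lie in [0, 1)")
        if self.temp_base >= self.temp_vent:
            raise ValueError("temp_base must be below temp_vent")


#: Presets encoding the two experimental greenhouse periods.
PRESETS: dict[str, ClimateGenConfig] = {
    "E1": ClimateGenConfig(par_mean=464.0, par_sd=116.0, temp_mean=21.9),
    "E2": ClimateGenConfig(par_mean=404.0, par_sd=120.0, temp_mean=22.4),
}


def preset(name: str, **overrides) -> ClimateGenConfig:
    """Named preset config, optionally with fields overridden."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return replace(base, **overrides)


def generate(config: ClimateGenConfig) -> ClimateSeries:
    """Generate a synthetic greenhouse climate series.

    PAR is a stationary AR(1) Gaussian process with the configured mean,
    SD and lag-1 autocorrelation, truncated at 0 (the target mean sits
    ~4 SD above 0, so truncation is negligible).  Temperature is
    ``temp_mean + coupling * (PAR - par_mean) + noise`` clipped to
    ``[temp_base, temp_vent + 0.5]``.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_days
    rho = config.par_autocorr
    # innovations scaled so the stationary SD equals par_sd
    innov_sd = config.par_sd * np.sqrt(1.0 - rho**2)
    z = np.empty(n)
    z[0] = rng.normal(0.0, config.par_sd)
    shocks = rng.normal(0.0, innov_sd, size=max(n - 1, 0))
    for i in range(1, n):
        z[i] = rho * z[i - 1] + shocks[i - 1]
    par = np.clip(config.par_mean + z, 0.0, None)

    temp = (
        config.temp_mean
        + config.temp_par_coupling * (par - config.par_mean)
        + rng.normal(0.0, config.temp_noise_sd, size=n)
    )
    temp = np.clip(temp, config.temp_base, config.temp_vent + 0.5)

    return ClimateSeries(day=np.arange(1, n + 1), par=par, temperature=temp)
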