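"""Scenario comparison and model evaluation statistics.

Evaluation of simulated versus measured final internode lengths follows
the mean-squared-deviation decomposition: with error e = simulated -
measured, ``RMSD = sqrt(mean(e^2))``, ``bias = mean(e)`` and the
systematic prediction error ``SPE = 100 * bias^2 / RMSD^2`` is the share
of the squared deviation attributable to systematic offset (the remainder
is random scatter, since MSD = bias^2 + var(e) in population form).

Scenario comparison runs the temperature-sensitive (MA-T) and the
temperature-insensitive (MA-20) model on the same climate and attributes
the per-rank difference in final length to (i) the shift in the PAR4d
signal caused by temperature-driven earlier appearance and (ii) the
direct temperature factor on the length target; a residual collects
interaction and clamping effects.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .climate import ClimateSeries
from .model import ModelConfig, SimulationResult, simulate

__all__ = [
    "EvalStats",
    "eval_stats",
    "cv",
    "pearson_r",
    "compare_scenarios",
    "ScenarioComparison",
]

logger = logging.getLogger(__name__)

#: Attribution shares are only reported for length differences larger than
#: this (cm); below it the ratio is numerically meaningless.
MIN_DELTA_FOR_SHARE = 0.1


@dataclass(frozen=True)
class EvalStats:
    """Agreement statistics between simulated and measured length-by-rank data."""

    rmsd: float
    bias: float
    spe: float
    n_pairs: int
    mean_sim: float
    mean_meas: float
    cv_sim: float
    cv_meas: float

    def summary(self) -> str:
        return (
            f"n={self.n_pairs}  RMSD={self.rmsd:.1f} cm  bias={self.bias:.1f} cm  "
            f"SPE={self.spe:.0f}%  mean sim/meas={self.mean_sim:.1f}/{self.mean_meas:.1f} cm  "
            f"CV sim/meas={self.cv_sim:.0f}/{self.cv_meas:.0f}%"
        )


def cv(values) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) as % of the mean."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    sd = arr.std(ddof=1) if len(arr) > 1 else 0.0
    return float(100.0 * sd / mean)


def pearson_r(x, y) -> float:
    """Product-moment correlation between two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def eval_stats(
    simulated: pd.Series | dict[int, float],
    measured: pd.Series | dict[int, float],
    min_rank: int = 5,
) -> EvalStats:
    """Evaluation statistics over ranks present in both inputs.

    Parameters
    ----------
    simulated, measured : mapping rank -> length (cm)
        Length-by-rank patterns; pandas Series indexed by rank or dicts.
    min_rank : int
        Ranks below this are excluded before pairing.

    Ranks are paired on the intersection of the two inputs, up to the
    smaller maximum rank; simulated and measured counts routinely differ
    and intersection never invents data.
    """
    sim = pd.Series(simulated, dtype=float)
    meas = pd.Series(measured, dtype=float)
    sim = sim[sim.index >= min_rank]
    meas = meas[meas.index >= min_rank]
    common = sim.index.intersection(meas.index)
    if len(common) == 0:
        raise ValueError("no common ranks >= min_rank between simulated and measured data")
    if len(common) < max(len(sim), len(meas)):
        logger.info(
            "rank pairing: %d common ranks (sim has %d, measured has %d)",
            len(common), len(sim), len(meas),
        )
    s = sim.loc[common].to_numpy()
    m = meas.loc[common].to_numpy()
    err = s - m
    bias = float(err.mean())
    rmsd = float(np.sqrt((err**2).mean()))
    spe = 100.0 * bias**2 / rmsd**2 if rmsd > 0 else 0.0
    return EvalStats(
        rmsd=rmsd,
        bias=bias,
        spe=float(spe),
        n_pairs=int(len(common)),
        mean_sim=float(s.mean()),
        mean_meas=float(m.mean()),
        cv_sim=cv(s),
        cv_meas=cv(m),
    )


@dataclass
class ScenarioComparison:
    """Result of :func:`compare_scenarios`.

    Attributes
    ----------
    attribution : pandas.DataFrame
        Per-rank table with columns rank, appearance_day_t, appearance_day_20,
        appearance_shift_d, delta_fil_cm, par_component_cm,
        temp_component_cm, residual_cm, par_share_pct.
    summary : dict
        Scenario-level counts and mean final-length difference.
    result_t, result_20 : SimulationResult
        The underlying runs.
    """

    attribution: pd.DataFrame
    summary: dict
    result_t: SimulationResult
    result_20: SimulationResult


def compare_scenarios(
    climate: ClimateSeries, config: ModelConfig, n_steps: int
) -> ScenarioComparison:
    """Run MA-T and MA-20 on the same climate and attribute length differences.

    For each rank present in both runs:

    * ``delta_fil`` = final length (MA-T) - final length (MA-20);
    * ``par_component`` = -slope * (PAR4d_MA-T - PAR4d_MA-20): the part of
      the difference caused by the appearance-time shift moving the light
      signal window;
    * ``temp_component`` = (F_av(T4d) - 1) * FIL_light (MA-T): the direct
      temperature scaling of the length target;
    * ``residual`` = delta_fil - par_component - temp_component
      (interaction, clamping and unfinished-elongation effects).

    ``par_share`` = 100 * |par_component| / |delta_fil|, reported only when
    |delta_fil| > 0.1 cm.
    """
    res_t = simulate(climate, config.as_scenario(True), n_steps)
    res_20 = simulate(climate, config.as_scenario(False), n_steps)

    t = res_t.internodes.set_index("rank")
    b = res_20.internodes.set_index("rank")
    common = t.index.intersection(b.index)

    rows = []
    for rank in common:
        nt, nb = t.loc[rank], b.loc[rank]
        delta = float(nt.final_cm - nb.final_cm)
        par_comp = -config.fil_par_slope * float(nt.par4d - nb.par4d)
        temp_comp = (float(nt.fav) - 1.0) * float(nt.fil_light)
        residual = delta - par_comp - temp_comp
        share = (
            100.0 * abs(par_comp) / abs(delta)
            if abs(delta) > MIN_DELTA_FOR_SHARE
            else np.nan
        )
        rows.append(
            {
                "rank": int(rank),
                "appearance_day_t": int(nt.appearance_day),
                "appearance_day_20": int(nb.appearance_day),
                "appearance_shift_d": int(nb.appearance_day - nt.appearance_day),
                "delta_fil_cm": delta,
                "par_component_cm": par_comp,
                "temp_component_cm": temp_comp,
                "residual_cm": residual,
                "par_share_pct": share,
            }
        )
    attribution = pd.DataFrame(
        rows,
        columns=[
            "rank", "appearance_day_t", "appearance_day_20", "appearance_shift_d",
            "delta_fil_cm", "par_component_cm", "temp_component_cm",
            "residual_cm", "par_share_pct",
        ],
    )

    def _mean_final(res: SimulationResult) -> float:
        df = res.internodes
        sel = df[(df["rank"] >= config.analysis_min_rank) & (~df["active"])]
        return float(sel["final_cm"].mean()) if len(sel) else float("nan")

    summary = {
        "n_internodes_t": int(len(res_t.internodes)),
        "n_internodes_20": int(len(res_20.internodes)),
        "mean_final_t_cm": _mean_final(res_t),
        "mean_final_20_cm": _mean_final(res_20),
        "mean_delta_fil_cm": float(attribution["delta_fil_cm"].mean())
        if len(attribution)
        else float("nan"),
        "max_appearance_shift_d": int(attribution["appearance_shift_d"].max())
        if len(attribution)
        else 0,
    }
    return ScenarioComparison(
        attribution=attribution, summary=summary, result_t=res_t, result_20=res_20
    )
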