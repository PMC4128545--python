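"""Evolution-relevant summaries of competition trajectories.

The quantity of interest for the tragedy of the commons is not absolute
density but the relative abundance of the enzyme-producing (GM) phage,
P_G/(P_G+P_W).  These helpers extract that frequency series, classify the
outcome of a run by comparing its endpoint to its start, and sweep the three
named burst-size configurations with everything else held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import ModelParameters
from .simulate import SimulationSpec, Trajectory, simulate

__all__ = [
    "CompetitionSummary",
    "gm_frequency_series",
    "summarize_competition",
    "compare_burst_configs",
    "DEFAULT_NEUTRAL_TOLERANCE",
]

#: Frequency change below which a run counts as neutral.  Symmetric runs are
#: exact to the last bit, so anything larger than this signals asymmetry.
DEFAULT_NEUTRAL_TOLERANCE = 1e-6

OUTCOME_GM_LOST = "gm_lost_declining"
OUTCOME_GM_WINNING = "gm_winning"
OUTCOME_NEUTRAL = "neutral"


@dataclass(frozen=True)
class CompetitionSummary:
    """Endpoint summary of one two-phage run."""

    initial_gm_frequency: float
    final_gm_frequency: float
    min_total_bacteria: float
    t_min_total_bacteria: float
    peak_release_rate: float
    t_peak_release_rate: float
    clamp_events: int
    outcome: str

    def as_dict(self) -> dict:
        return {
            "initial_gm_frequency": self.initial_gm_frequency,
            "final_gm_frequency": self.final_gm_frequency,
            "min_total_bacteria": self.min_total_bacteria,
            "t_min_total_bacteria": self.t_min_total_bacteria,
            "peak_release_rate": self.peak_release_rate,
            "t_peak_release_rate": self.t_peak_release_rate,
            "clamp_events": self.clamp_events,
            "outcome": self.outcome,
        }


def _require_two_phage(traj: Trajectory) -> None:
    if not (traj.has_gm and traj.has_wild):
        raise ValueError(
            "trajectory contains a single phage type; relative frequencies are "
            "undefined — use density summaries on the trajectory frame instead"
        )


def gm_frequency_series(traj: Trajectory) -> pd.Series:
    """GM phage frequency P_G/(P_G+P_W) at each output time.

    Times with zero total phage are NaN (undefined), never imputed as 0 —
    after washout extinguishes both phages the frequency carries no signal.
    Raises for single-phage trajectories.
    """
    _require_two_phage(traj)
    return pd.Series(
        traj.frame["gm_frequency"].to_numpy(),
        index=pd.Index(traj.times, name="t"),
        name="gm_frequency",
    )


def summarize_competition(
    traj: Trajectory, neutral_tolerance: float = DEFAULT_NEUTRAL_TOLERANCE
) -> CompetitionSummary:
    """Classify a two-phage run by its endpoint frequency change.

    The outcome is ``neutral`` when |final - initial| <= neutral_tolerance,
    otherwise ``gm_lost_declining`` or ``gm_winning`` by the sign of the
    change.  Also records the bacterial-density minimum and the peak of the
    refuge release rate h(E), the two features that separate the
    enzyme-driven collapse from the phage-free regime.
    """
    if neutral_tolerance < 0:
        raise ValueError("neutral_tolerance must be >= 0")
    freqs = gm_frequency_series(traj)
    defined = freqs.dropna()
    if defined.empty:
        raise ValueError("GM frequency is undefined at every output time")
    initial = float(defined.iloc[0])
    final = float(defined.iloc[-1])

    frame = traj.frame
    i_min = int(frame["total_bacteria"].to_numpy().argmin())
    i_peak = int(frame["release_rate"].to_numpy().argmax())

    delta = final - initial
    if abs(delta) <= neutral_tolerance:
        outcome = OUTCOME_NEUTRAL
    elif delta < 0:
        outcome = OUTCOME_GM_LOST
    else:
        outcome = OUTCOME_GM_WINNING

    return CompetitionSummary(
        initial_gm_frequency=initial,
        final_gm_frequency=final,
        min_total_bacteria=float(frame["total_bacteria"].iloc[i_min]),
        t_min_total_bacteria=float(frame["t"].iloc[i_min]),
        peak_release_rate=float(frame["release_rate"].iloc[i_peak]),
        t_peak_release_rate=float(frame["t"].iloc[i_peak]),
        clamp_events=traj.clamp_events,
        outcome=outcome,
    )


def compare_burst_configs(
    base_params: ModelParameters,
    spec: SimulationSpec,
    neutral_tolerance: float = DEFAULT_NEUTRAL_TOLERANCE,
) -> pd.DataFrame:
    """Run the three burst presets with everything else held fixed.

    ``spec`` supplies the initial state, t_end, dt and history mode; its
    params are replaced by ``base_params`` with each preset's bursts in
    turn.  Returns one CompetitionSummary row per preset, indexed by preset
    name, in increasing order of GM advantage.
    """
    if not (spec.initial_state.P_G > 0 and spec.initial_state.P_W > 0):
        raise ValueError("compare_burst_configs needs both phages present initially")
    rows = {}
    for preset in ("gm_disadvantaged", "equal", "gm_advantaged"):
        params = base_params.with_bursts(preset)
        traj = simulate(
            SimulationSpec(
                params=params,
                initial_state=spec.initial_state,
                t_end=spec.t_end,
                dt=spec.dt,
                history_mode=spec.history_mode,
                output_thin=spec.output_thin,
            )
        )
        rows[preset] = summarize_competition(traj, neutral_tolerance).as_dict()
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "burst_preset"
    return table
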