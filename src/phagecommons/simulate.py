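"""Fixed-step Euler integration of the delayed phage competition model.

The latent period turns the model into a system of delay differential
equations: every step needs the state exactly L minutes in the past.  A ring
buffer holds the last round(L/dt)+1 states so the delayed lookup is an index
offset, never an interpolation.  Integration is plain forward Euler at a
fixed step (default dt = 1e-3 min), which keeps runs bit-reproducible;
components driven below zero by an Euler undershoot are clamped to zero and
the events counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    ModelParameters,
    StateVector,
    _packed,
    _rates,
    release_rate,
)

__all__ = [
    "SimulationSpec",
    "HistoryBuffer",
    "Trajectory",
    "SimulationError",
    "initialize_history",
    "euler_step",
    "simulate",
    "run_scenario",
    "SCENARIOS",
    "scenario_spec",
]

logger = logging.getLogger("phagecommons")

#: Reference step size used for published-style runs; larger steps are
#: accepted for quick exploration but logged as a warning.
REFERENCE_DT = 1e-3

#: Fraction of clamped steps above which a run is flagged as suspect.
CLAMP_WARN_FRACTION = 1e-3


class SimulationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class SimulationSpec:
    """Complete, reproducible description of one integration run.

    ``history_mode`` controls the pre-t=0 past: ``hold-initial`` fills the
    history with the initial state; ``zero-phage`` fills it with the initial
    state stripped of phage and infected cells (bacteria only), modelling
    phage added at t=0 to a previously uninfected culture.
    """

    params: ModelParameters
    initial_state: StateVector
    t_end: float
    dt: float = REFERENCE_DT
    history_mode: str = "hold-initial"
    output_thin: Optional[int] = None  # record every m-th step; default 1/dt

    def __post_init__(self) -> None:
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise ValueError(f"dt must be positive, got {self.dt!r}")
        if not (self.t_end > 0 and math.isfinite(self.t_end)):
            raise ValueError(f"t_end must be positive, got {self.t_end!r}")
        L = self.params.lysis_time
        steps = round(L / self.dt)
        if steps < 1 or abs(steps * self.dt - L) > 1e-9 * L:
            raise ValueError(
                f"dt={self.dt!r} must evenly divide the lysis time L={L!r} "
                f"(round(L/dt)*dt deviates from L)"
            )
        if self.history_mode not in ("hold-initial", "zero-phage"):
            raise ValueError(f"unknown history_mode {self.history_mode!r}")
        if self.output_thin is not None and self.output_thin < 1:
            raise ValueError("output_thin must be >= 1")

    @property
    def delay_steps(self) -> int:
        return round(self.params.lysis_time / self.dt)

    @property
    def n_steps(self) -> int:
        return round(self.t_end / self.dt)

    @property
    def resolved_thin(self) -> int:
        """Output thinning actually used: default is one record per minute."""
        if self.output_thin is not None:
            return self.output_thin
        return max(1, round(1.0 / self.dt))


class HistoryBuffer:
    """Ring of the last ``delay_steps + 1`` states at spacing dt.

    Slot layout guarantees the delayed lookup returns the record exactly
    ``delay_steps`` steps in the past: with capacity ``delay_steps + 1`` the
    oldest record in a full ring is the delayed one.
    """

    def __init__(self, delay_steps: int, dt: float) -> None:
        if delay_steps < 1:
            raise ValueError("delay_steps must be >= 1")
        self.delay_steps = delay_steps
        self.capacity = delay_steps + 1
        self.dt = dt
        self.time = 0.0
        self.clamp_events = 0
        self._slots: list[tuple[float, ...]] = [None] * self.capacity  # type: ignore
        self._idx = -1  # slot of the current record
        self._filled = 0

    def fill(self, past: tuple[float, ...], current: tuple[float, ...]) -> None:
        """Fill the whole ring: ``past`` for t in [-L, -dt], ``current`` at t=0."""
        for i in range(self.capacity - 1):
            self._slots[i] = past
        self._slots[self.capacity - 1] = current
        self._idx = self.capacity - 1
        self._filled = self.capacity
        self.time = 0.0

    def push(self, state: tuple[float, ...]) -> None:
        """Append the state one step after the current record."""
        self._idx = (self._idx + 1) % self.capacity
        self._slots[self._idx] = state
        self._filled = min(self._filled + 1, self.capacity)
        self.time += self.dt

    def current(self) -> tuple[float, ...]:
        if self._filled < self.capacity:
            raise RuntimeError("history buffer not initialized")
        return self._slots[self._idx]

    def delayed(self) -> tuple[float, ...]:
        """State exactly ``delay_steps`` steps (L minutes) in the past."""
        if self._filled < self.capacity:
            raise RuntimeError("history buffer not initialized")
        return self._slots[(self._idx + 1) % self.capacity]

    def current_state(self) -> StateVector:
        return StateVector.from_tuple(self.current())

    def delayed_state(self) -> StateVector:
        return StateVector.from_tuple(self.delayed())


def initialize_history(spec: SimulationSpec) -> HistoryBuffer:
    """Build and fill the history ring for t in [-L, 0].

    ``hold-initial`` copies the initial state into every past record;
    ``zero-phage`` zeroes P_G, P_W, I_G and I_W in the past records while
    keeping bacteria and enzyme, so infection only begins at t=0.
    """
    buffer = HistoryBuffer(spec.delay_steps, spec.dt)
    current = spec.initial_state.as_tuple()
    if spec.history_mode == "hold-initial":
        past = current
    else:  # zero-phage
        b, r, _, _, _, _, e = current
        past = (b, r, 0.0, 0.0, 0.0, 0.0, e)
    buffer.fill(past, current)
    return buffer


def _step(
    cur: tuple[float, ...],
    dly: tuple[float, ...],
    pc: tuple[float, ...],
    dt: float,
) -> tuple[tuple[float, ...], int]:
    """One Euler update; returns the clamped new state and the clamp count.

    Shared verbatim by :func:`euler_step` and the :func:`simulate` loop so
    the two paths are bit-identical.
    """
    rates = _rates(cur, dly, pc)
    new = [c + dt * r for c, r in zip(cur, rates)]
    clamped = 0
    for i, value in enumerate(new):
        if value < 0.0:
            new[i] = 0.0
            clamped += 1
    state = tuple(new)
    if not math.isfinite(sum(state)):
        raise SimulationError(
            f"non-finite state: state={state} rates={rates} "
            f"current={cur} delayed={dly}"
        )
    return state, clamped


def euler_step(buffer: HistoryBuffer, params: ModelParameters, dt: float) -> StateVector:
    """Advance the buffer one Euler step and return the new state.

    Negative components produced by the linear update are clamped to zero;
    each clamped component increments ``buffer.clamp_events``.
    """
    try:
        state, clamped = _step(buffer.current(), buffer.delayed(), _packed(params), dt)
    except SimulationError as err:
        raise SimulationError(f"at t={buffer.time + dt:g} min: {err}") from None
    buffer.clamp_events += clamped
    buffer.push(state)
    return StateVector.from_tuple(state)


_COLUMNS = ("B", "R", "P_G", "P_W", "I_G", "I_W", "E")


@dataclass(frozen=True)
class Trajectory:
    """Thinned time course of one run plus derived columns.

    ``frame`` columns: t (minutes), the seven state densities, and the
    derived release_rate h(E), gm_frequency P_G/(P_G+P_W) (NaN where the
    total phage density is zero), and total_bacteria B+R.  Storage is
    linear; any log scaling is presentation only.
    """

    frame: pd.DataFrame
    clamp_events: int
    spec: SimulationSpec

    @property
    def params(self) -> ModelParameters:
        return self.spec.params

    @property
    def times(self) -> np.ndarray:
        return self.frame["t"].to_numpy()

    def state_at(self, index: int) -> StateVector:
        row = self.frame.iloc[index]
        return StateVector(*(float(row[c]) for c in _COLUMNS))

    @property
    def final_state(self) -> StateVector:
        return self.state_at(-1)

    @property
    def has_gm(self) -> bool:
        return bool((self.frame["P_G"] > 0).any())

    @property
    def has_wild(self) -> bool:
        return bool((self.frame["P_W"] > 0).any())


def _derived_frame(
    times: list[float], rows: list[tuple[float, ...]], params: ModelParameters
) -> pd.DataFrame:
    frame = pd.DataFrame(rows, columns=list(_COLUMNS))
    frame.insert(0, "t", times)
    frame["release_rate"] = release_rate(frame["E"].to_numpy(), params)
    total_phage = frame["P_G"] + frame["P_W"]
    with np.errstate(invalid="ignore", divide="ignore"):
        frame["gm_frequency"] = np.where(
            total_phage > 0, frame["P_G"] / total_phage, np.nan
        )
    frame["total_bacteria"] = frame["B"] + frame["R"]
    return frame


def simulate(spec: SimulationSpec) -> Trajectory:
    """Integrate the model over [0, t_end] with the fixed-step Euler scheme.

    Deterministic: an identical spec yields a bit-identical trajectory.  The
    output keeps every ``spec.resolved_thin``-th step (plus t=0 and the final
    step).  A run in which more than 0.1% of steps clamp a negative
    component is flagged with a warning.
    """
    if spec.dt > REFERENCE_DT * (1 + 1e-12):
        logger.warning(
            "dt=%g exceeds the reference step %g; results are exploratory",
            spec.dt,
            REFERENCE_DT,
        )
    buffer = initialize_history(spec)
    pc = _packed(spec.params)
    dt = spec.dt
    thin = spec.resolved_thin
    n = spec.n_steps

    cur = buffer.current()
    times = [0.0]
    rows = [cur]
    clamps = 0
    i = 0
    # Local bindings for the hot loop; arithmetic matches euler_step exactly.
    slots = buffer._slots
    capacity = buffer.capacity
    idx = buffer._idx
    step_fn = _step
    try:
        for i in range(1, n + 1):
            dly = slots[(idx + 1) % capacity]
            cur, clamped = step_fn(cur, dly, pc, dt)
            clamps += clamped
            idx = (idx + 1) % capacity
            slots[idx] = cur
            if i % thin == 0 or i == n:
                times.append(i * dt)
                rows.append(cur)
    except SimulationError as err:
        raise SimulationError(f"at t={i * dt:g} min: {err}") from None
    buffer._idx = idx
    buffer.time = n * dt
    buffer.clamp_events = clamps

    if n > 0 and clamps > CLAMP_WARN_FRACTION * n:
        logger.warning(
            "%d of %d steps clamped a negative component (%.2f%%)",
            clamps,
            n,
            100.0 * clamps / n,
        )
    return Trajectory(frame=_derived_frame(times, rows, spec.params), clamp_events=clamps, spec=spec)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

#: Default initial densities for the illustrative scenarios (per mL).  The
#: published dynamics start phage "low" against an established culture; these
#: concrete values are package choices calibrated to reproduce the four
#: qualitative regimes, and every one can be overridden.
DEFAULT_BACTERIA = 2.5e8
DEFAULT_PHAGE = 1e4
DEFAULT_T_END = 1500.0

#: scenario id -> (burst preset, GM phage present, wild phage present)
SCENARIOS: dict[str, tuple[str, bool, bool]] = {
    "fig1a": ("equal", False, True),   # wild phage alone
    "fig1b": ("equal", True, False),   # GM phage alone
    "fig1c": ("gm_disadvantaged", True, True),  # tragedy: GM burst 17 vs 20
    "fig1d": ("gm_advantaged", True, True),     # bursts swapped
}


def scenario_spec(
    scenario_id: str,
    params: Optional[ModelParameters] = None,
    **overrides,
) -> SimulationSpec:
    """Build the SimulationSpec for a named scenario.

    ``params`` overrides the baseline rate constants (the scenario's burst
    preset is still applied); keyword overrides are SimulationSpec fields
    (initial_state, t_end, dt, history_mode, output_thin).
    """
    try:
        preset, with_gm, with_wild = SCENARIOS[scenario_id]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    base = (params or ModelParameters()).with_bursts(preset)
    initial = overrides.pop(
        "initial_state",
        StateVector(
            B=DEFAULT_BACTERIA,
            R=DEFAULT_BACTERIA,
            P_G=DEFAULT_PHAGE if with_gm else 0.0,
            P_W=DEFAULT_PHAGE if with_wild else 0.0,
        ),
    )
    spec = SimulationSpec(
        params=base,
        initial_state=initial,
        t_end=overrides.pop("t_end", DEFAULT_T_END),
        **overrides,
    )
    return spec


def run_scenario(
    scenario_id: str,
    params: Optional[ModelParameters] = None,
    **overrides,
) -> Trajectory:
    """Integrate one of the four named competition scenarios.

    fig1a: wild phage alone (no enzyme production; bacteria persist).
    fig1b: GM phage alone (enzyme drains the refuge; bacteria crash).
    fig1c: both phages, GM burst 17 vs wild 20 — the GM phage declines
           from 50% frequency (the tragedy of the commons).
    fig1d: bursts swapped — the wild phage declines instead.
    """
    return simulate(scenario_spec(scenario_id, params=params, **overrides))
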