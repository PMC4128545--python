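"""Delayed-lysis dynamics of a transgenic enzyme-producing phage.

The system tracks two bacterial populations and two phage genotypes in a
continuously diluted (chemostat-like) environment.  Free bacteria ``B`` are
open to infection; refuge bacteria ``R`` are protected (wall growth or
phage-resistant surface states) and leak into the free state at a rate
``h(E)`` that rises with the concentration of a diffusible matrix-degrading
enzyme ``E``.  Only the genetically modified (GM) phage ``P_G`` produces the
enzyme, released at lysis; the wild phage ``P_W`` shares the benefit without
paying the cost.  Lysis happens a fixed latent period ``L`` minutes after
infection, so progeny production depends on the infection flux ``L`` minutes
in the past discounted by washout survival ``exp(-w*L)``.

State variables (densities per mL):

======  ====================================================
``B``   free (infectable) bacteria
``R``   refuge bacteria
``P_G`` GM (enzyme-producing) phage
``P_W`` wild phage
``I_G`` bacteria infected by GM phage, awaiting lysis
``I_W`` bacteria infected by wild phage, awaiting lysis
``E``   extracellular enzyme (abstract units of yield Z per lysis)
======  ====================================================

The rate equations (a dot denotes d/dt, a subscript ``L`` the value L
minutes in the past)::

    B'   = v(1-(B+R)/C)B - kP_G B - kP_W B - wB + R h(E)
    R'   = v(1-(B+R)/C)R - R h(E)
    P_G' = b_G k P_GL B_L e^{-wL} - kP_G(B+I_G+I_W) - wP_G
    P_W' = b_W k P_WL B_L e^{-wL} - kP_W(B+I_G+I_W) - wP_W
    I_G' = -k P_GL B_L e^{-wL} + kP_G B - wI_G
    I_W' = -k P_WL B_L e^{-wL} + kP_W B - wI_W
    E'   = Z k P_GL B_L e^{-wL} - wE
    h(E) = h_max / (1 + shape * decay^E)

Logistic growth applies to the total bacterial density B+R.  The refuge
equation carries no washout term: refuge cells are modelled as wall-bound
and immune to dilution.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "ModelParameters",
    "StateVector",
    "DerivativeVector",
    "BURST_PRESETS",
    "release_rate",
    "derivative_field",
    "load_config",
    "default_parameters_path",
]

#: Named burst-size configurations: (GM burst, wild burst).
BURST_PRESETS: dict[str, tuple[float, float]] = {
    "gm_disadvantaged": (17.0, 20.0),
    "equal": (20.0, 20.0),
    "gm_advantaged": (20.0, 17.0),
}


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the competition model.

    Defaults are the published baseline parameterization: adsorption
    k=1e-9 mL/min, washout w=0.05/min, lysis time L=10 min, maximum
    bacterial growth rate v=0.1/min, enzyme yield Z=0.1 per lysis,
    carrying capacity C=5e9 cells/mL, and bursts 17 (GM) versus 20 (wild).
    The refuge-release function h(E) = release_max / (1 + release_shape *
    release_decay**E) has baseline h(0) = release_max/(1+release_shape)
    = 0.01/min and saturates at release_max = 0.2/min.
    """

    adsorption_rate: float = 1e-9      # k, mL/min per particle
    washout_rate: float = 0.05         # w, 1/min
    burst_gm: float = 17.0             # b_G, progeny per lysis
    burst_wild: float = 20.0           # b_W, progeny per lysis
    lysis_time: float = 10.0           # L, min
    max_growth_rate: float = 0.1       # v, 1/min
    enzyme_yield: float = 0.1          # Z, enzyme units per lysis
    carrying_capacity: float = 5e9     # C, cells/mL
    release_max: float = 0.2           # h_max, 1/min
    release_shape: float = 19.0        # dimensionless
    release_decay: float = 0.999997    # per-enzyme-unit base, in (0,1)

    def __post_init__(self) -> None:
        positive = (
            "adsorption_rate", "washout_rate", "lysis_time",
            "max_growth_rate", "carrying_capacity",
            "release_max", "release_shape",
        )
        for name in positive:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        # zero is allowed for bursts (sterile phage) and enzyme yield (an
        # enzyme-free GM phage is the wild-type limit of the model)
        for name in ("burst_gm", "burst_wild", "enzyme_yield"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if not 0.0 < self.release_decay < 1.0:
            raise ValueError(
                f"release_decay must lie in (0, 1), got {self.release_decay!r}"
            )

    @property
    def baseline_release_rate(self) -> float:
        """h(0): refuge release rate with no enzyme present (per minute)."""
        return self.release_max / (1.0 + self.release_shape)

    @property
    def lysis_survival(self) -> float:
        """Probability an infected cell survives washout through the latent period."""
        return math.exp(-self.washout_rate * self.lysis_time)

    def with_bursts(self, preset: str) -> "ModelParameters":
        """Return a copy using a named burst configuration from BURST_PRESETS."""
        try:
            b_g, b_w = BURST_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown burst preset {preset!r}; choose from {sorted(BURST_PRESETS)}"
            ) from None
        return replace(self, burst_gm=b_g, burst_wild=b_w)

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        """Build parameters from a flat mapping, rejecting unknown keys."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_config(self, path: str | Path) -> None:
        """Write a flat ``key = value`` config file."""
        lines = ["# phagecommons model parameters"]
        lines += [f"{k} = {v!r}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(load_config(path))


def load_config(path: str | Path) -> dict[str, float]:
    """Parse a flat ``key = value`` config file into a dict of floats."""
    result: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        try:
            result[key.strip()] = float(value.strip())
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: malformed number {value.strip()!r} for key {key.strip()!r}"
            ) from None
    return result


def default_parameters_path() -> Path:
    """Path of the packaged baseline parameter config."""
    return Path(importlib.resources.files("phagecommons") / "data" / "baseline.cfg")


@dataclass(frozen=True)
class StateVector:
    """Densities of the seven dynamical variables at one time point (per mL)."""

    B: float = 0.0
    R: float = 0.0
    P_G: float = 0.0
    P_W: float = 0.0
    I_G: float = 0.0
    I_W: float = 0.0
    E: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.items():
            if not math.isfinite(value):
                raise ValueError(f"state component {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"state component {name} must be >= 0, got {value!r}")

    def items(self) -> Iterator[tuple[str, float]]:
        return iter(
            (f.name, getattr(self, f.name)) for f in fields(self)
        )

    def as_tuple(self) -> tuple[float, ...]:
        return (self.B, self.R, self.P_G, self.P_W, self.I_G, self.I_W, self.E)

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple(), dtype=float)

    @classmethod
    def from_tuple(cls, values: tuple[float, ...]) -> "StateVector":
        return cls(*values)

    @property
    def total_bacteria(self) -> float:
        return self.B + self.R

    @property
    def total_phage(self) -> float:
        return self.P_G + self.P_W


@dataclass(frozen=True)
class DerivativeVector:
    """Instantaneous rates of change, per mL per minute, one per state component."""

    B: float
    R: float
    P_G: float
    P_W: float
    I_G: float
    I_W: float
    E: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.B, self.R, self.P_G, self.P_W, self.I_G, self.I_W, self.E)

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple(), dtype=float)


def release_rate(E, params: ModelParameters):
    """Rate h(E) at which refuge bacteria re-enter the free state (per minute).

    h(E) = h_max / (1 + shape * decay**E): a saturating sigmoid in the enzyme
    density, equal to h_max/(1+shape) with no enzyme and approaching h_max as
    E grows without bound.  Accepts a scalar or an ndarray of enzyme
    densities; negative densities are rejected.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("enzyme density E must be >= 0")
    out = params.release_max / (1.0 + params.release_shape * params.release_decay ** E)
    return float(out) if out.ndim == 0 else out


def _packed(params: ModelParameters) -> tuple[float, ...]:
    """Constants needed by the inner loop, precomputed once per run."""
    return (
        params.adsorption_rate,
        params.washout_rate,
        params.burst_gm,
        params.burst_wild,
        params.max_growth_rate,
        params.enzyme_yield,
        params.carrying_capacity,
        params.release_max,
        params.release_shape,
        params.release_decay,
        params.lysis_survival,
    )


def _rates(
    cur: tuple[float, ...], dly: tuple[float, ...], pc: tuple[float, ...]
) -> tuple[float, ...]:
    """Scalar core of the derivative field; shared by the public API and the
    integrator's hot loop.  ``cur``/``dly`` are 7-tuples (B,R,P_G,P_W,I_G,I_W,E);
    ``pc`` comes from :func:`_packed`."""
    B, R, P_G, P_W, I_G, I_W, E = cur
    B_L, _, P_GL, P_WL, _, _, _ = dly
    k, w, b_g, b_w, v, z, cap, hmax, shape, decay, surv = pc

    h = hmax / (1.0 + shape * decay ** E)
    lysis_g = k * P_GL * B_L * surv   # delayed GM lysis flux
    lysis_w = k * P_WL * B_L * surv   # delayed wild lysis flux
    sinks = B + I_G + I_W             # phage are lost to free and infected cells
    growth = v * (1.0 - (B + R) / cap)

    return (
        growth * B - k * P_G * B - k * P_W * B - w * B + R * h,
        growth * R - R * h,
        b_g * lysis_g - k * P_G * sinks - w * P_G,
        b_w * lysis_w - k * P_W * sinks - w * P_W,
        -lysis_g + k * P_G * B - w * I_G,
        -lysis_w + k * P_W * B - w * I_W,
        z * lysis_g - w * E,
    )


def derivative_field(
    current: StateVector, delayed: StateVector, params: ModelParameters
) -> DerivativeVector:
    """Evaluate the right-hand side of the model at one instant.

    Parameters
    ----------
    current
        State at time t.
    delayed
        State at time t - L (L minutes earlier); supplies the delayed
        infection flux that drives lysis, progeny release and enzyme
        production.
    params
        Model rate constants.

    Returns
    -------
    DerivativeVector
        The seven instantaneous rates of change.
    """
    rates = _rates(current.as_tuple(), delayed.as_tuple(), _packed(params))
    if not all(math.isfinite(r) for r in rates):
        raise ArithmeticError(
            f"non-finite derivative: rates={rates} current={current} delayed={delayed}"
        )
    return DerivativeVector(*rates)
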