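"""Synthetic pooled-assay data with the structure the inference assumes.

Each reaction pools ``n`` plaque isolates drawn from a population with true
transgene frequency T, so the three outcome classes occur with probabilities
((1-T)^n, T^n, 1 - (1-T)^n - T^n).  The generator draws reaction outcomes
directly from that trinomial — the same sampling model the likelihood
inverts — which makes parameter-recovery and credible-interval coverage
experiments exact tests of the inference machinery, not of any additional
assay realism (no PCR failure, plaque-picking bias or classification error
is modelled).

All randomness flows from one explicit integer seed through
``numpy.random.SeedSequence`` spawning; there is no global random state.
The default design (n=10 plaques per reaction, R=6 reactions) mirrors the
screening layout the estimator was built for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .inference import (
    Outcome,
    PooledAssayData,
    Reaction,
    credible_interval,
    mle_frequency,
    reaction_class_probs,
)
from .simulate import Trajectory

__all__ = [
    "AssayDesign",
    "sample_pooled_assay",
    "sample_plaque_counts",
    "assay_from_trajectory",
    "recovery_experiment",
]

DEFAULT_POOL_SIZE = 10
DEFAULT_N_REACTIONS = 6


@dataclass(frozen=True)
class AssayDesign:
    """Design of one synthetic pooled assay at known truth."""

    t_true: float
    n: int = DEFAULT_POOL_SIZE
    r: int = DEFAULT_N_REACTIONS
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_true <= 1.0:
            raise ValueError(f"t_true must lie in [0, 1], got {self.t_true!r}")
        if self.n < 1:
            raise ValueError(f"pool size n must be >= 1, got {self.n}")
        if self.r < 1:
            raise ValueError(f"number of reactions r must be >= 1, got {self.r}")
        if self.seed is None:
            raise ValueError("seed is mandatory; no implicit entropy")


def _rng(seed_or_rng: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_pooled_assay(
    design: AssayDesign, rng: Optional[np.random.Generator] = None
) -> PooledAssayData:
    """Draw R independent pooled reactions at the design's true frequency.

    Each reaction falls into (ALL_NEG, ALL_POS, MIXED) with probabilities
    ((1-T)^n, T^n, 1-(1-T)^n-T^n).  Deterministic given the design seed; an
    explicit ``rng`` (used by the recovery harness) takes precedence.
    """
    gen = rng if rng is not None else _rng(design.seed)
    probs = reaction_class_probs(design.t_true, design.n)
    x, y, z = (int(c) for c in gen.multinomial(design.r, probs))
    return PooledAssayData.from_counts(design.n, all_neg=x, all_pos=y, mixed=z)


def sample_plaque_counts(
    freq: float, n_plaques: int, seed: Union[int, np.random.Generator]
) -> tuple[int, int]:
    """Binomial draw of (positives, negatives) among single-plaque isolates."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"freq must lie in [0, 1], got {freq!r}")
    if n_plaques < 0:
        raise ValueError("n_plaques must be >= 0")
    gen = _rng(seed)
    positives = int(gen.binomial(n_plaques, freq))
    return positives, n_plaques - positives


def assay_from_trajectory(
    traj: Trajectory,
    times: Sequence[float],
    design: AssayDesign,
) -> list[PooledAssayData]:
    """Sample a pooled assay from the phage population at each requested time.

    At each time the true frequency is the trajectory's GM frequency at the
    nearest output point; a pooled assay of the design's (n, R) layout is
    then drawn.  One child generator is spawned from the design seed per
    requested time, so the result is deterministic.  Raises if the
    trajectory has a single phage type, a time falls outside the simulated
    span, or the frequency is undefined (both phages extinct) at a
    requested time.
    """
    if not (traj.has_gm and traj.has_wild):
        raise ValueError(
            "trajectory contains a single phage type; GM frequency is undefined"
        )
    grid = traj.times
    freqs = traj.frame["gm_frequency"].to_numpy()
    children = np.random.SeedSequence(design.seed).spawn(len(times))
    assays = []
    for t, child in zip(times, children):
        if t < grid[0] or t > grid[-1]:
            raise ValueError(
                f"requested time {t} outside the simulated span "
                f"[{grid[0]}, {grid[-1]}]"
            )
        idx = int(np.abs(grid - t).argmin())
        t_true = float(freqs[idx])
        if math.isnan(t_true):
            raise ValueError(
                f"GM frequency undefined at t={grid[idx]} (total phage density 0)"
            )
        sub = AssayDesign(t_true=t_true, n=design.n, r=design.r, seed=design.seed)
        assays.append(sample_pooled_assay(sub, rng=np.random.default_rng(child)))
    return assays


def recovery_experiment(
    t_grid: Sequence[float],
    n: int = DEFAULT_POOL_SIZE,
    r: int = DEFAULT_N_REACTIONS,
    reps: int = 1000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Parameter-recovery summary of the estimator at known truths.

    For each true frequency in ``t_grid``: draw ``reps`` independent pooled
    assays of R reactions with pool size n, estimate T by maximum likelihood
    and the equal-tail credible interval on each, and report bias
    (mean(T_hat) - T), RMSE, and the fraction of intervals containing the
    truth.  Deterministic given ``seed``.

    Estimates depend on the data only through the outcome counts (X, Y, Z),
    which are cached, so large ``reps`` costs little more than the distinct
    count patterns encountered.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if seed is None:
        raise ValueError("seed is mandatory; no implicit entropy")
    t_grid = list(t_grid)
    if not t_grid:
        raise ValueError("t_grid must be non-empty")
    for t in t_grid:
        if not 0.0 < t < 1.0:
            raise ValueError(f"recovery truths must lie strictly in (0, 1), got {t!r}")

    cache: dict[tuple[int, int, int, int], tuple[float, float, float]] = {}

    def estimates(x: int, y: int, z: int) -> tuple[float, float, float]:
        key = (n, x, y, z)
        if key not in cache:
            data = PooledAssayData.from_counts(n, all_neg=x, all_pos=y, mixed=z)
            t_hat = mle_frequency(data)
            lo, hi = credible_interval(data, level=level)
            cache[key] = (t_hat, lo, hi)
        return cache[key]

    children = np.random.SeedSequence(seed).spawn(len(t_grid))
    rows = []
    for t_true, child in zip(t_grid, children):
        gen = np.random.default_rng(child)
        probs = reaction_class_probs(t_true, n)
        counts = gen.multinomial(r, probs, size=reps)
        errors = np.empty(reps)
        covered = np.empty(reps, dtype=bool)
        for i, (x, y, z) in enumerate(counts):
            t_hat, lo, hi = estimates(int(x), int(y), int(z))
            errors[i] = t_hat - t_true
            covered[i] = lo <= t_true <= hi
        rows.append(
            {
                "t_true": t_true,
                "n": n,
                "r": r,
                "reps": reps,
                "bias": float(errors.mean()),
                "rmse": float(np.sqrt(np.mean(errors ** 2))),
                "coverage": float(covered.mean()),
            }
        )
    return pd.DataFrame(rows)
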