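"""Transgene frequency estimation from pooled plaque PCR reactions.

Screening plaques one at a time is wasteful when the transgene frequency T
is near 0 or 1, so n plaque isolates are pooled into a single PCR reaction.
With U = 1 - T, a pool of n isolates reads all-negative with probability
U^n, all-positive with probability T^n, and mixed otherwise
(1 - U^n - T^n).  For X all-negative, Y all-positive and Z mixed reactions
the likelihood is the multinomial kernel

    M(T) = A^X * B^Y * C^Z,   A = U^n,  B = T^n,  C = 1 - U^n - T^n

(the combinatorial constant is dropped).  The point estimate is the
maximizer of M on [0, 1]; the interval estimate treats the normalized M as a
posterior density of T under a flat prior and takes the equal-tail quantiles
(default central 95%).  Unanimous data admit conjugate closed forms — the
posterior for N all-negative plaques is Beta(1, N+1), giving the upper bound
1 - ((1-level)/2)^(1/(N+1)) — which serve as cross-checks on the quadrature.

Heterogeneous pool sizes are supported: the log likelihood is a sum over
reactions, each contributing the log probability of its own outcome class at
its own n.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

__all__ = [
    "Outcome",
    "Reaction",
    "PooledAssayData",
    "FrequencyEstimate",
    "FrequencyTestResult",
    "reaction_class_probs",
    "log_likelihood",
    "mle_frequency",
    "credible_interval",
    "estimate_frequency",
    "unanimous_bound",
    "chi_square_frequency_test",
]

#: Grid sizes: coarse grid + local refinement for the MLE, fine uniform grid
#: for posterior quadrature (chosen so conjugate closed-form checks agree to
#: 1e-4).
MLE_GRID_POINTS = 10_001
POSTERIOR_GRID_POINTS = 100_001


class Outcome(str, enum.Enum):
    """Classification of one pooled PCR reaction."""

    ALL_NEG = "ALL_NEG"   # transgene absent from every isolate in the pool
    ALL_POS = "ALL_POS"   # transgene present in every isolate
    MIXED = "MIXED"       # both types present in the pool

    @classmethod
    def parse(cls, value: Union[str, "Outcome"]) -> "Outcome":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown outcome {value!r}; expected one of "
                f"{[o.value for o in cls]}"
            ) from None


@dataclass(frozen=True)
class Reaction:
    """One pooled PCR reaction: pool size and three-class outcome."""

    n: int
    outcome: Outcome

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"pool size n must be >= 1, got {self.n}")
        object.__setattr__(self, "outcome", Outcome.parse(self.outcome))
        if self.n == 1 and self.outcome is Outcome.MIXED:
            raise ValueError("a single-plaque reaction cannot be MIXED")


class PooledAssayData:
    """A set of pooled reactions, possibly with heterogeneous pool sizes."""

    def __init__(self, reactions: Iterable[Reaction]) -> None:
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        if not all(isinstance(r, Reaction) for r in self.reactions):
            raise TypeError("reactions must be Reaction instances")
        # (n, outcome) -> count; the sufficient statistic for the likelihood
        self._groups = Counter((r.n, r.outcome) for r in self.reactions)

    @classmethod
    def from_counts(
        cls, n: int, all_neg: int = 0, all_pos: int = 0, mixed: int = 0
    ) -> "PooledAssayData":
        """Common-pool-size constructor from the aggregate counts (X, Y, Z)."""
        for name, count in (("all_neg", all_neg), ("all_pos", all_pos), ("mixed", mixed)):
            if count < 0:
                raise ValueError(f"{name} count must be >= 0, got {count}")
        reactions: list[Reaction] = []
        for outcome, count in (
            (Outcome.ALL_NEG, all_neg),
            (Outcome.ALL_POS, all_pos),
            (Outcome.MIXED, mixed),
        ):
            if count:
                reactions.extend([Reaction(n, outcome)] * count)
        return cls(reactions)

    def __len__(self) -> int:
        return len(self.reactions)

    def __eq__(self, other) -> bool:
        return isinstance(other, PooledAssayData) and self._groups == other._groups

    def __repr__(self) -> str:
        return f"PooledAssayData({len(self)} reactions, groups={dict(self._groups)})"

    def _count(self, outcome: Outcome) -> int:
        return sum(c for (_, o), c in self._groups.items() if o is outcome)

    @property
    def n_all_neg(self) -> int:
        """X: reactions in which every isolate lacked the transgene."""
        return self._count(Outcome.ALL_NEG)

    @property
    def n_all_pos(self) -> int:
        """Y: reactions in which every isolate carried the transgene."""
        return self._count(Outcome.ALL_POS)

    @property
    def n_mixed(self) -> int:
        """Z: reactions containing both types."""
        return self._count(Outcome.MIXED)

    @property
    def n_reactions(self) -> int:
        """R = X + Y + Z."""
        return len(self.reactions)

    @property
    def common_pool_size(self) -> Optional[int]:
        """The shared n when every reaction pooled the same number of plaques."""
        sizes = {r.n for r in self.reactions}
        return sizes.pop() if len(sizes) == 1 else None

    @property
    def is_unanimous_negative(self) -> bool:
        return len(self) > 0 and self.n_all_neg == len(self)

    @property
    def is_unanimous_positive(self) -> bool:
        return len(self) > 0 and self.n_all_pos == len(self)

    @property
    def total_plaques(self) -> int:
        return sum(r.n for r in self.reactions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": range(1, len(self) + 1),
                "n_plaques": [r.n for r in self.reactions],
                "outcome": [r.outcome.value for r in self.reactions],
            }
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "PooledAssayData":
        frame = pd.read_csv(path, sep="\t", comment="#")
        required = {"n_plaques", "outcome"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"assay table missing columns: {sorted(missing)}")
        return cls(
            Reaction(int(row.n_plaques), Outcome.parse(row.outcome))
            for row in frame.itertuples()
        )


@dataclass(frozen=True)
class FrequencyEstimate:
    """Point and interval estimate of the transgene frequency T."""

    t_hat: float
    lower: float
    upper: float
    level: float
    grid: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError("credible interval must satisfy 0 <= lo <= hi <= 1")


@dataclass(frozen=True)
class FrequencyTestResult:
    """Pearson goodness-of-fit test of an observed frequency against an expectation."""

    statistic: float
    df: int
    pvalue: float


def reaction_class_probs(T: float, n: int) -> tuple[float, float, float]:
    """Outcome-class probabilities (A, B, C) for one pooled reaction.

    A = (1-T)^n (all-negative), B = T^n (all-positive), C = 1 - A - B
    (mixed).  C is computed as the complement so the three always sum to 1
    exactly; tiny negative rounding residues at n = 1 are clipped to 0.
    """
    if not 0.0 <= T <= 1.0:
        raise ValueError(f"frequency T must lie in [0, 1], got {T!r}")
    if n < 1:
        raise ValueError(f"pool size n must be >= 1, got {n}")
    U = 1.0 - T
    A = U ** n
    B = T ** n
    C = 1.0 - A - B
    if C < 0.0:
        C = 0.0
    return A, B, C


def _class_log_probs(T: np.ndarray, n: int) -> dict[Outcome, np.ndarray]:
    """log A, log B, log C on a grid of T values (−inf where the class is null)."""
    U = 1.0 - T
    A = U ** n
    B = T ** n
    C = np.clip(1.0 - A - B, 0.0, None)
    with np.errstate(divide="ignore"):
        return {
            Outcome.ALL_NEG: np.log(A),
            Outcome.ALL_POS: np.log(B),
            Outcome.MIXED: np.log(C),
        }


def log_likelihood(T, data: PooledAssayData):
    """Unnormalized log likelihood of the assay data at frequency T.

    Sum over reactions of the log probability of the observed class; −inf
    exactly when an observed class is impossible at that T (e.g. an
    ALL_POS reaction at T = 0).  Accepts a scalar or an ndarray of T values
    in [0, 1]; an empty dataset gives 0 everywhere.
    """
    T_arr = np.asarray(T, dtype=float)
    if np.any((T_arr < 0.0) | (T_arr > 1.0)):
        raise ValueError("frequency T must lie in [0, 1]")
    total = np.zeros_like(T_arr, dtype=float)
    for (n, outcome), count in data._groups.items():
        total = total + count * _class_log_probs(T_arr, n)[outcome]
    return float(total) if total.ndim == 0 else total


def mle_frequency(data: PooledAssayData) -> float:
    """Maximum-likelihood estimate of the transgene frequency.

    Unanimous data sit at the boundary (0 for all-negative, 1 for
    all-positive).  Otherwise the maximizer is located on a dense uniform
    grid and polished with bounded scalar optimization; exact ties resolve
    to the smaller T (np.argmax returns the first maximum).
    """
    if len(data) == 0:
        raise ValueError("cannot estimate a frequency from an empty dataset")
    if data.is_unanimous_negative:
        return 0.0
    if data.is_unanimous_positive:
        return 1.0

    grid = np.linspace(0.0, 1.0, MLE_GRID_POINTS)
    ll = log_likelihood(grid, data)
    best = int(np.argmax(ll))
    h = grid[1] - grid[0]
    lo = max(0.0, grid[best] - h)
    hi = min(1.0, grid[best] + h)
    res = optimize.minimize_scalar(
        lambda t: -log_likelihood(float(t), data),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if math.isfinite(res.fun) and -res.fun >= ll[best]:
        return float(res.x)
    return float(grid[best])


def _posterior(
    data: PooledAssayData, grid_points: int = POSTERIOR_GRID_POINTS
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized flat-prior posterior density of T on a uniform grid."""
    grid = np.linspace(0.0, 1.0, grid_points)
    ll = log_likelihood(grid, data)
    peak = np.max(ll)
    if not np.isfinite(peak):
        raise ValueError(
            "likelihood is zero everywhere on [0, 1]; the data are internally "
            "inconsistent"
        )
    density = np.exp(ll - peak)
    mass = integrate.trapezoid(density, grid)
    if mass <= 0:
        raise ValueError("posterior has zero mass")
    return grid, density / mass


def credible_interval(
    data: PooledAssayData,
    level: float = 0.95,
    grid_points: int = POSTERIOR_GRID_POINTS,
) -> tuple[float, float]:
    """Equal-tail Bayesian credible interval for T under a flat prior.

    The normalized likelihood is treated as the posterior density; the
    bounds are its (1-level)/2 and 1-(1-level)/2 quantiles, obtained by
    trapezoidal quadrature of the CDF on a uniform grid and monotone linear
    inversion.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level!r}")
    grid, density = _posterior(data, grid_points)
    cdf = integrate.cumulative_trapezoid(density, grid, initial=0.0)
    cdf /= cdf[-1]
    tail = (1.0 - level) / 2.0
    lo = float(np.interp(tail, cdf, grid))
    hi = float(np.interp(1.0 - tail, cdf, grid))
    return lo, hi


def estimate_frequency(
    data: PooledAssayData,
    level: float = 0.95,
    grid_points: int = POSTERIOR_GRID_POINTS,
) -> FrequencyEstimate:
    """MLE plus equal-tail credible interval, with the posterior grid used."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level!r}")
    t_hat = mle_frequency(data)
    grid, density = _posterior(data, grid_points)
    cdf = integrate.cumulative_trapezoid(density, grid, initial=0.0)
    cdf /= cdf[-1]
    tail = (1.0 - level) / 2.0
    lower = float(np.interp(tail, cdf, grid))
    upper = float(np.interp(1.0 - tail, cdf, grid))
    return FrequencyEstimate(
        t_hat=t_hat,
        lower=lower,
        upper=upper,
        level=level,
        grid=grid,
        density=density,
    )


def unanimous_bound(
    total_plaques: int, level: float = 0.95, direction: str = "all_negative"
) -> float:
    """Closed-form credible bound for unanimous data.

    For N plaques all lacking the transgene the posterior is
    Beta(1, N+1) and the informative (upper) bound is
    1 - ((1-level)/2)^(1/(N+1)); for N all carrying it the posterior is
    Beta(N+1, 1) and the (lower) bound is ((1-level)/2)^(1/(N+1)).
    """
    if total_plaques < 1:
        raise ValueError("total_plaques must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level!r}")
    tail = (1.0 - level) / 2.0
    root = tail ** (1.0 / (total_plaques + 1))
    if direction == "all_negative":
        return 1.0 - root
    if direction == "all_positive":
        return root
    raise ValueError(
        f"direction must be 'all_negative' or 'all_positive', got {direction!r}"
    )


def chi_square_frequency_test(
    positives: int,
    total: int,
    expected_T: float,
    continuity_correction: bool = False,
) -> FrequencyTestResult:
    """Pearson 1-df test of an observed transgene count against an expected frequency.

    Compares the 2-cell table (positives, negatives) with expected counts
    (expected_T * total, (1 - expected_T) * total).  The optional Yates
    continuity correction subtracts 0.5 from each absolute deviation; it is
    off by default.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= positives <= total:
        raise ValueError("positives must lie in [0, total]")
    if not 0.0 < expected_T < 1.0:
        raise ValueError("expected_T must lie strictly in (0, 1)")
    observed = np.array([positives, total - positives], dtype=float)
    expected = np.array([expected_T * total, (1.0 - expected_T) * total])
    dev = np.abs(observed - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float(np.sum(dev ** 2 / expected))
    pvalue = float(stats.chi2.sf(statistic, df=1))
    return FrequencyTestResult(statistic=statistic, df=1, pvalue=pvalue)
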