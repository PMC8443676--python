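"""Wright-Fisher metapopulation model of plasmid accumulation.

``N`` isolated demes each host one clonal population carrying ``i`` unique
plasmid types.  Each generation ("epoch") all demes are replaced by ``N``
multinomial draws weighted by population fitness ``w_i = 1 - Delta_tot(i)``,
and every lineage is additionally invaded by one new plasmid type with
probability ``q``.  The selection-invasion balance arrests the
single-population runaway ("tragedy of the commons") and yields a
stationary distribution of plasmid counts whose shape depends on
plasmid-plasmid epistasis:

* no epistasis (independent multiplicative costs) -> Poisson-like;
* positive epistasis (all plasmids beyond the first are free,
  ``Delta_tot = Delta`` for ``i > 0``) -> geometric/exponential tail with
  constant consecutive ratio ``(1 - Delta) q / ((1 - q) Delta)``;
* negative epistasis (super-multiplicative burden,
  exponent ``i**1.5``) -> sub-Poissonian, truncated tail.

The infinite-N stationary distribution follows from the fixed point of the
epoch resampling probabilities: with ``w_0 = 1``,
``f_i = f_{i-1} w_{i-1} q / ((1 - q)(1 - w_i))``.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "EpistasisSpec",
    "WFParams",
    "StationaryDistribution",
    "fitness",
    "epoch_probabilities",
    "simulate_epochs",
    "stationary_distribution",
    "generalized_stationary_distribution",
    "tail_ratio_diagnostics",
]

_FORMS = ("none", "positive", "negative", "power", "custom")


@dataclass(frozen=True)
class EpistasisSpec:
    """Named rule mapping unique-plasmid count to total fitness cost.

    Forms: ``none`` = multiplicative ``1 - (1 - Delta)**m``; ``positive`` =
    constant ``Delta`` for any ``m > 0``; ``negative`` = ``1 - (1 -
    Delta)**(m**1.5)``; ``power`` = ``1 - (1 - Delta)**(m**a)`` with free
    exponent ``a``; ``custom`` = explicit table.
    """

    form: str
    Delta: float = 0.0
    a: float | None = None
    custom_costs: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown epistasis form {self.form!r}; choose from {_FORMS}")
        if self.form != "custom" and not 0.0 <= self.Delta < 1.0:
            raise ValueError("Delta must lie in [0, 1)")
        if self.form == "power" and self.a is None:
            raise ValueError("power form requires the exponent a")
        if self.form == "custom" and self.custom_costs is None:
            raise ValueError("custom form requires a cost table")

    def total_cost(self, i: int | np.ndarray):
        i = np.asarray(i)
        if np.any(i < 0):
            raise ValueError("plasmid count must be nonnegative")
        if self.form == "none":
            out = 1.0 - (1.0 - self.Delta) ** i
        elif self.form == "positive":
            out = np.where(i > 0, self.Delta, 0.0)
        elif self.form == "negative":
            out = 1.0 - (1.0 - self.Delta) ** (i.astype(float) ** 1.5)
        elif self.form == "power":
            out = 1.0 - (1.0 - self.Delta) ** (i.astype(float) ** self.a)
        else:
            try:
                out = np.vectorize(lambda k: float(self.custom_costs[int(k)]))(i)
            except KeyError as exc:
                raise ValueError(f"custom cost table is missing entry {exc}") from exc
        out = np.asarray(out, dtype=float)
        if np.any((out < -1e-12) | (out > 1.0 + 1e-12)):
            raise ValueError("total cost left [0, 1]")
        return out if out.ndim else float(out)

    def fitness(self, i: int | np.ndarray):
        return 1.0 - self.total_cost(i)


def fitness(i: int | np.ndarray, epistasis: EpistasisSpec):
    """Population fitness ``w_i = 1 - Delta_tot(i)``."""
    return epistasis.fitness(i)


@dataclass(frozen=True)
class WFParams:
    """Run configuration of the stochastic metapopulation simulation."""

    N: int
    q: float
    epistasis: EpistasisSpec
    i_max: int = 50
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.q < 1.0:
            raise ValueError("q must lie in [0, 1)")
        if self.i_max < 1:
            raise ValueError("i_max must be >= 1")


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary probabilities over unique plasmid types per deme."""

    f: np.ndarray
    q: float | None = None
    epistasis: EpistasisSpec | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "f", f)
        if np.any(f < 0):
            raise ValueError("stationary probabilities must be nonnegative")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("stationary probabilities must sum to 1")

    @property
    def i_max(self) -> int:
        return len(self.f) - 1

    @property
    def mean(self) -> float:
        return float(np.dot(np.arange(len(self.f)), self.f))


def epoch_probabilities(
    counts: Sequence[float], epistasis: EpistasisSpec, q: float
) -> np.ndarray:
    """Multinomial replacement probabilities for one epoch.

    Entry ``i`` combines lineages already at ``i`` that were not invaded
    with lineages at ``i - 1`` that were; the vector has one extra slot at
    ``i_max + 1`` for invasions out of the top class and sums to one
    exactly.
    """
    n = np.asarray(counts, dtype=float)
    if np.any(n < 0):
        raise ValueError("deme counts must be nonnegative")
    L = len(n)
    w = np.asarray(epistasis.fitness(np.arange(L)), dtype=float)
    nw = n * w
    denom = nw.sum()
    if denom <= 0:
        raise ValueError("no viable population: sum of n_j * w_j is zero")
    p = np.empty(L + 1)
    p[0] = nw[0] * (1.0 - q)
    p[1:L] = nw[1:] * (1.0 - q) + nw[:-1] * q
    p[L] = nw[-1] * q
    return p / denom


def simulate_epochs(
    params: WFParams, initial_counts: Sequence[int] | None = None
) -> np.ndarray:
    """Stochastic epoch-by-epoch simulation; returns counts of shape
    ``(epochs + 1, i_max + 1)`` including the initial state.

    Every epoch synchronously replaces all ``N`` demes with one multinomial
    draw from :func:`epoch_probabilities`; draws that overflow ``i_max``
    are folded into the top class (warned once).  Reproducible for a given
    seed: the single generator is consumed by one multinomial per epoch.
    """
    L = params.i_max + 1
    if initial_counts is None:
        n = np.zeros(L, dtype=np.int64)
        n[0] = params.N
    else:
        n = np.asarray(initial_counts, dtype=np.int64).copy()
        if len(n) != L or n.sum() != params.N or np.any(n < 0):
            raise ValueError("initial counts must be nonnegative and sum to N over 0..i_max")
    rng = np.random.default_rng(params.seed)
    history = np.empty((params.epochs + 1, L), dtype=np.int64)
    history[0] = n
    warned = False
    for t in range(params.epochs):
        p = epoch_probabilities(n, params.epistasis, params.q)
        draw = rng.multinomial(params.N, p)
        if draw[-1] and not warned:
            warnings.warn(
                f"plasmid counts exceeded i_max={params.i_max}; folding into the top class"
            )
            warned = True
        n = draw[:-1].copy()
        n[-1] += draw[-1]
        history[t + 1] = n
    return history


def stationary_distribution(
    epistasis: EpistasisSpec,
    q: float,
    i_max: int = 50,
    auto_extend: bool = True,
    tail_tol: float = 1e-15,
    hard_cap: int = 100_000,
) -> StationaryDistribution:
    """Infinite-N stationary distribution via the analytic recursion.

    Requires a strictly positive cost for every ``i >= 1`` (a cost-free
    plasmid class makes the recursion denominator vanish) and a convergent
    tail (consecutive ratio < 1).  With ``auto_extend`` the support grows
    past ``i_max`` until the dropped tail mass is below ``tail_tol``, so
    the result is a fixed point of :func:`epoch_probabilities` to well
    below 1e-12.
    """
    if not 0.0 <= q < 1.0:
        raise ValueError("q must lie in [0, 1)")
    if q == 0.0:
        f = np.zeros(i_max + 1)
        f[0] = 1.0
        return StationaryDistribution(f, q=q, epistasis=epistasis)
    vals = [1.0]
    total = 1.0
    i = 1
    w_prev = 1.0
    while True:
        cost_i = float(np.asarray(epistasis.total_cost(i)))
        if cost_i <= 0:
            raise ValueError(
                f"total cost at i={i} is zero; a cost-free plasmid class has no "
                "stationary cap (zero recursion denominator)"
            )
        w_i = 1.0 - cost_i
        f_i = vals[-1] * w_prev * q / ((1.0 - q) * cost_i)
        if i > 1 and f_i >= vals[-1] and i >= i_max:
            raise ValueError(
                "stationary recursion diverges (consecutive ratio >= 1); "
                "increase the cost/invasion ratio Delta/q"
            )
        vals.append(f_i)
        total += f_i
        w_prev = w_i
        if i >= i_max:
            if not auto_extend:
                break
            if f_i / total < tail_tol and f_i < vals[-2]:
                break
            if i >= hard_cap:
                raise ValueError(
                    "stationary support exceeded the hard cap without tail decay"
                )
        i += 1
    f = np.asarray(vals) / total
    return StationaryDistribution(f, q=q, epistasis=epistasis)


def generalized_stationary_distribution(
    cost_fn: Callable[[int], float],
    q_fn: Callable[[int], float],
    i_max: int = 200,
) -> StationaryDistribution:
    """Stationary distribution when both the total cost and the invasion
    probability are arbitrary functions of the current plasmid count.

    With ``w_i = 1 - cost_fn(i)`` and ``q_i = q_fn(i)``, requires
    ``w_0 (1 - q_0) > w_i (1 - q_i)`` for all ``i >= 1``; then
    ``f_i = f_{i-1} w_{i-1} q_{i-1} / (w_0 (1 - q_0) - w_i (1 - q_i))``.
    Constant ``q`` and a fixed epistasis form reduce exactly to
    :func:`stationary_distribution`.
    """
    w0 = 1.0 - float(cost_fn(0))
    q0 = float(q_fn(0))
    if not 0.0 <= q0 < 1.0:
        raise ValueError("q(0) must lie in [0, 1)")
    ref = w0 * (1.0 - q0)
    vals = [1.0]
    for i in range(1, i_max + 1):
        w_prev = 1.0 - float(cost_fn(i - 1))
        q_prev = float(q_fn(i - 1))
        w_i = 1.0 - float(cost_fn(i))
        q_i = float(q_fn(i))
        denom = ref - w_i * (1.0 - q_i)
        if denom <= 0:
            raise ValueError(
                f"stationarity precondition violated at i={i}: "
                "w_0 (1 - q_0) must exceed w_i (1 - q_i)"
            )
        vals.append(vals[-1] * w_prev * q_prev / denom)
    f = np.asarray(vals)
    return StationaryDistribution(f / f.sum())


def tail_ratio_diagnostics(
    f: StationaryDistribution | Sequence[float], rtol: float = 1e-9
) -> tuple[np.ndarray, bool]:
    """Consecutive ratios ``f_{i+1} / f_i`` for ``i >= 1`` and a constancy flag.

    The flag is true when the maximum relative deviation of the ratios
    from their geometric mean is below ``rtol`` — the signature of an
    exponential (geometric) tail.
    """
    arr = np.asarray(f.f if isinstance(f, StationaryDistribution) else f, dtype=float)
    if np.count_nonzero(arr > 0) < 3:
        raise ValueError("need at least 3 positive entries to compute tail ratios")
    pos = arr[1:]
    # stop at the first zero beyond the support
    end = len(pos)
    for j, v in enumerate(pos):
        if v <= 0:
            end = j
            break
    pos = pos[:end]
    if len(pos) < 2:
        raise ValueError("need at least two positive entries beyond i=0")
    ratios = pos[1:] / pos[:-1]
    gmean = float(np.exp(np.mean(np.log(ratios))))
    flag = bool(np.max(np.abs(ratios / gmean - 1.0)) < rtol)
    return ratios, flag
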