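"""Co-infection dynamics of multiple compatible plasmid types.

Extends the single-plasmid conjugation chemostat to ``m`` plasmid types
from distinct incompatibility groups: types segregate and transfer
independently, and the growth cost of carrying ``k`` types combines either
multiplicatively (``Delta_tot = 1 - (1 - Delta)**k``) or additively
(clamped at 1).  Tracking every subset of types yields ``2**m + 1``
equations; for identical plasmids started at equal abundances the exact
reduction to ``m + 2`` equations over the number of carried types is also
provided, together with steady-state type-count distributions and the
binomial / Poisson-binomial reference distributions they approach in the
low-cost limit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.special import comb

from .dynamics import (
    ConjugationParams,
    conjugation_invasion_threshold,
    integrate_to_steady_state,
)

__all__ = [
    "CommunityParams",
    "TypeCountDistribution",
    "total_cost",
    "build_full_rhs",
    "build_reduced_rhs",
    "single_type_threshold",
    "steady_state_type_distribution",
    "poisson_binomial",
    "distribution_distance",
    "mean_types_and_fitness",
]

CostModel = Literal["multiplicative", "additive"]

_FULL_SYSTEM_MAX_M = 12


@dataclass(frozen=True)
class CommunityParams:
    """Parameters of the m-type co-infection model (identical types)."""

    m: int
    Delta: float
    gamma_c: float
    p_ell: float = 0.0
    delta: float = 1.0
    S: float = 1.0
    alpha: float = 1.0
    cost_model: CostModel = "multiplicative"
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 <= self.Delta < 1.0:
            raise ValueError("Delta must lie in [0, 1)")
        if not 0.0 <= self.p_ell <= 1.0:
            raise ValueError("p_ell must lie in [0, 1]")
        for name in ("gamma_c", "delta", "S", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def single_type(self) -> ConjugationParams:
        """The corresponding one-plasmid parameter set (per-type rates)."""
        return ConjugationParams(
            alpha=self.alpha,
            Delta=self.Delta,
            gamma_c=self.gamma_c,
            p_ell=self.p_ell,
            delta=self.delta,
            S=self.S,
        )


@dataclass(frozen=True)
class TypeCountDistribution:
    """Probabilities over the number of unique plasmid types carried."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if np.any(p < -1e-12):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")

    def __len__(self) -> int:
        return len(self.probs)

    def __getitem__(self, i):
        return self.probs[i]

    @property
    def mean(self) -> float:
        return float(np.dot(np.arange(len(self.probs)), self.probs))


def total_cost(k: int | np.ndarray, Delta: float, cost_model: CostModel = "multiplicative"):
    """Total growth cost of carrying ``k`` unique plasmid types."""
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("k must be nonnegative")
    if cost_model == "multiplicative":
        out = 1.0 - (1.0 - Delta) ** k
    elif cost_model == "additive":
        out = np.minimum(k * Delta, 1.0)
    else:
        raise ValueError(f"unknown cost model {cost_model!r}")
    return out if out.ndim else float(out)


def single_type_threshold(params: CommunityParams) -> float:
    """Critical per-type conjugation rate for one plasmid invading alone."""
    return conjugation_invasion_threshold(params.single_type())


def build_full_rhs(params: CommunityParams) -> Callable[[np.ndarray], np.ndarray]:
    """Derivative function over all 2**m subset classes plus nutrient.

    State layout: ``y[A]`` for bitmask subsets ``A`` of the m types,
    followed by the nutrient ``C``.  Division of a class produces one new
    cell whose retained types are independent Bernoulli(1 - p_ell) picks
    from the parent's set; each missing type is gained by conjugation from
    all carriers of that type.  At ``m = 1`` this is exactly the
    single-plasmid conjugation model.
    """
    m = params.m
    if m > _FULL_SYSTEM_MAX_M:
        raise ValueError(
            f"full subset system limited to m <= {_FULL_SYSTEM_MAX_M}; "
            "use build_reduced_rhs for identical plasmids"
        )
    n = 1 << m
    sizes = np.array([bin(A).count("1") for A in range(n)])
    growth_coeff = (1.0 - total_cost(sizes, params.Delta, params.cost_model)) * params.alpha

    # segregation: offspring of class A lands in B <= A with binomial weight
    seg_src, seg_dst, seg_w = [], [], []
    pl = params.p_ell
    for A in range(n):
        if pl == 0.0:
            seg_src.append(A)
            seg_dst.append(A)
            seg_w.append(1.0)
            continue
        B = A
        while True:  # iterate submasks of A
            kept = bin(B).count("1")
            lost = sizes[A] - kept
            seg_src.append(A)
            seg_dst.append(B)
            seg_w.append((1.0 - pl) ** kept * pl**lost)
            if B == 0:
                break
            B = (B - 1) & A
    seg_src = np.array(seg_src)
    seg_dst = np.array(seg_dst)
    seg_w = np.array(seg_w)

    # conjugation: class A gains type i (not in A) from carriers of i
    c_src, c_type, c_dst = [], [], []
    for A in range(n):
        for i in range(m):
            if not A >> i & 1:
                c_src.append(A)
                c_type.append(i)
                c_dst.append(A | (1 << i))
    c_src = np.array(c_src, dtype=int)
    c_type = np.array(c_type, dtype=int)
    c_dst = np.array(c_dst, dtype=int)
    membership = np.array(
        [[bool(A >> i & 1) for A in range(n)] for i in range(m)], dtype=float
    )

    delta, S, gamma_c = params.delta, params.S, params.gamma_c

    def rhs(y: np.ndarray) -> np.ndarray:
        x = y[:-1]
        C = y[-1]
        g = growth_coeff * C * x  # per-class division rates
        dx = np.bincount(seg_dst, weights=g[seg_src] * seg_w, minlength=n)
        dx -= delta * x
        if gamma_c > 0:
            D = membership @ x  # density of carriers of each type
            flux = gamma_c * x[c_src] * D[c_type]
            dx -= np.bincount(c_src, weights=flux, minlength=n)
            dx += np.bincount(c_dst, weights=flux, minlength=n)
        return np.concatenate([dx, [S - g.sum()]])

    return rhs


def build_reduced_rhs(params: CommunityParams) -> Callable[[np.ndarray], np.ndarray]:
    """Derivative function over type-count classes (m + 2 equations).

    Valid for identical plasmids at symmetric abundances: offspring of a
    k-carrier keep ``j <= k`` types with binomial weight; a k-carrier is
    promoted to ``k + 1`` at rate ``gamma_c (m - k) x_k D`` where
    ``D = sum_j x_j j / m`` is the carrier density of any fixed type.
    """
    if not params.symmetric:
        raise ValueError("the reduced system requires the symmetric flag")
    m = params.m
    ks = np.arange(m + 1)
    growth_coeff = (1.0 - total_cost(ks, params.Delta, params.cost_model)) * params.alpha
    pl = params.p_ell
    # W[k, j]: probability the new daughter of a k-carrier keeps j types
    W = np.zeros((m + 1, m + 1))
    for k in range(m + 1):
        j = np.arange(k + 1)
        W[k, : k + 1] = comb(k, j) * (1.0 - pl) ** j * pl ** (k - j)
    WT = W.T.copy()
    delta, S, gamma_c = params.delta, params.S, params.gamma_c
    frac = ks / m

    def rhs(y: np.ndarray) -> np.ndarray:
        x = y[:-1]
        C = y[-1]
        g = growth_coeff * C * x
        dx = WT @ g - delta * x
        if gamma_c > 0:
            D = float(frac @ x)
            promo = gamma_c * (m - ks) * x * D
            dx -= promo
            dx[1:] += promo[:-1]
        return np.concatenate([dx, [S - g.sum()]])

    return rhs


def subset_state_to_counts(x: np.ndarray, m: int) -> np.ndarray:
    """Sum subset-class densities into type-count classes."""
    sizes = np.array([bin(A).count("1") for A in range(1 << m)])
    return np.bincount(sizes, weights=x, minlength=m + 1)


def steady_state_type_distribution(
    params: CommunityParams,
    gamma_multiplier: float | None = None,
    full: bool = False,
    step: float = 0.01,
    t_max: float = 1e5,
    tol: float = 1e-9,
) -> TypeCountDistribution:
    """Steady-state distribution of unique plasmid types per cell.

    The community is seeded at the plasmid-free equilibrium with a small
    equal inoculum of each single-type class (1e-6 of the resident density
    per type) and integrated to steady state.  ``gamma_multiplier``, if
    given, rescales the conjugation rate relative to the single-plasmid
    invasion threshold gamma_c*.
    """
    if gamma_multiplier is not None:
        gamma_c = gamma_multiplier * single_type_threshold(params)
        params = replace(params, gamma_c=gamma_c)
    m = params.m
    rho_star = params.S / params.delta
    C_star = params.delta / params.alpha
    if full:
        rhs = build_full_rhs(params)
        y0 = np.zeros((1 << m) + 1)
        y0[0] = rho_star
        for i in range(m):
            y0[1 << i] = 1e-6 * rho_star
        y0[-1] = C_star
    else:
        rhs = build_reduced_rhs(params)
        y0 = np.zeros(m + 2)
        y0[0] = rho_star
        y0[1] = m * 1e-6 * rho_star
        y0[-1] = C_star
    y, t, converged = integrate_to_steady_state(
        rhs, y0, step=step, t_max=t_max, tol=tol
    )
    if not converged:
        deriv = rhs(y)
        raise RuntimeError(
            "co-infection dynamics did not reach steady state by "
            f"t={t:g} (max |dx/dt| = {np.max(np.abs(deriv)):.3e})"
        )
    x = y[:-1]
    counts = subset_state_to_counts(x, m) if full else x
    total = counts.sum()
    if total <= 0:
        raise RuntimeError("all cell classes vanished; cannot form a distribution")
    probs = np.clip(counts / total, 0.0, None)
    return TypeCountDistribution(probs / probs.sum())


def poisson_binomial(p_vector: Sequence[float]) -> TypeCountDistribution:
    """Exact Poisson-binomial pmf by iterative convolution.

    Equal success probabilities reduce to Binomial(m, p); an empty vector
    gives a point mass at zero.
    """
    p_vector = np.asarray(p_vector, dtype=float)
    if np.any((p_vector < 0) | (p_vector > 1)):
        raise ValueError("all success probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for p in p_vector:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return TypeCountDistribution(pmf / pmf.sum())


def distribution_distance(
    d1: TypeCountDistribution | Sequence[float],
    d2: TypeCountDistribution | Sequence[float],
) -> float:
    """Total variation distance, padding the shorter support with zeros."""
    a = np.asarray(d1.probs if isinstance(d1, TypeCountDistribution) else d1, float)
    b = np.asarray(d2.probs if isinstance(d2, TypeCountDistribution) else d2, float)
    n = max(len(a), len(b))
    a = np.pad(a, (0, n - len(a)))
    b = np.pad(b, (0, n - len(b)))
    return 0.5 * float(np.abs(a - b).sum())


def mean_types_and_fitness(
    dist: TypeCountDistribution,
    Delta: float,
    cost_model: CostModel = "multiplicative",
) -> tuple[float, float]:
    """Expected unique types per cell and expected relative growth rate."""
    k = np.arange(len(dist.probs))
    mean_k = float(np.dot(k, dist.probs))
    fitness = float(np.dot(1.0 - total_cost(k, Delta, cost_model), dist.probs))
    return mean_k, fitness
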