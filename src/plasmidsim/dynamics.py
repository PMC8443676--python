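"""Single-plasmid chemostat models of parasitic plasmid spread.

Two horizontal-transfer mechanisms are modeled for a costly ("parasitic")
plasmid competing in a well-mixed chemostat:

* **conjugation** — plasmid-bearing cells infect plasmid-free cells on
  contact (mass action at rate ``gamma_c``);
* **transformation** — cell death releases ``n_eff`` free plasmids which
  decay at rate ``delta_p`` and infect plasmid-free cells at rate
  ``gamma_t``.

State variables are the plasmid-free cell density ``rho``, the
plasmid-bearing density ``rho_p``, the nutrient concentration ``C`` and
(transformation only) the free-plasmid density ``P``.  Both cell classes
grow proportionally to nutrient with coefficient ``alpha``; carrying the
plasmid reduces growth by the factor ``1 - Delta``; at each division of a
plasmid-bearing cell the new daughter is plasmid-free with probability
``p_ell``; all cells die at rate ``delta``; nutrient is supplied at rate
``S``.

The module provides the right-hand sides, invasion thresholds, closed-form
and numeric equilibria, linear stability analysis with analytic Jacobians,
copy-number optimization (cost scales as ``Delta = Delta_p * n_p``,
segregation loss as ``p_ell = 2**(1 - n_p)``), a fixed-step RK4 integrator,
and phase diagrams over the (Delta, transfer-rate) plane.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "NO_INVASION",
    "ConjugationParams",
    "TransformationParams",
    "CopyNumberParams",
    "SystemState",
    "Trajectory",
    "Equilibrium",
    "PhaseDiagram",
    "conjugation_rhs",
    "transformation_rhs",
    "conjugation_jacobian",
    "transformation_jacobian",
    "plasmid_free_equilibrium",
    "conjugation_invasion_threshold",
    "transformation_invasion_threshold",
    "conjugative_invasion_barrier",
    "optimal_copy_number",
    "continuous_optimal_copy_number",
    "integrate",
    "integrate_to_steady_state",
    "find_equilibria",
    "classify_stability",
    "phase_diagram",
    "phase_diagram_frame",
]

#: Sentinel returned by invasion-threshold solvers when no finite transfer
#: rate permits invasion (release below the replication deficit).
NO_INVASION = math.inf

Mechanism = Literal["conjugation", "transformation"]

# integrator / solver tolerances (package-wide defaults)
_NEG_CLIP = 1e-12          # components in (-_NEG_CLIP, 0) are clipped to 0
_STEADY_TOL = 1e-9         # global relative-derivative steady-state criterion
_ROOT_TOL = 1e-10          # max |rhs| accepted for a reported equilibrium
_TOL_EIG = 1e-8            # margin on eigenvalue real parts


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be nonnegative, got {value}")


@dataclass(frozen=True)
class ConjugationParams:
    """Rates of the conjugative single-plasmid model."""

    alpha: float = 1.0
    Delta: float = 0.0
    gamma_c: float = 0.0
    p_ell: float = 0.0
    delta: float = 0.1
    S: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma_c", "delta", "S"):
            _check_nonneg(name, getattr(self, name))
        if not 0.0 <= self.Delta < 1.0:
            raise ValueError(f"Delta must lie in [0, 1), got {self.Delta}")
        if not 0.0 <= self.p_ell <= 1.0:
            raise ValueError(f"p_ell must lie in [0, 1], got {self.p_ell}")


@dataclass(frozen=True)
class TransformationParams:
    """Rates of the transformative single-plasmid model.

    ``n_eff`` is the number of viable free plasmids released per cell
    death; ``delta_p`` is the free-plasmid decay rate.
    """

    alpha: float = 1.0
    Delta: float = 0.0
    gamma_t: float = 0.0
    p_ell: float = 0.0
    delta: float = 0.1
    S: float = 1.0
    n_eff: float = 0.6
    delta_p: float = 0.3

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma_t", "delta", "S", "n_eff", "delta_p"):
            _check_nonneg(name, getattr(self, name))
        if not 0.0 <= self.Delta < 1.0:
            raise ValueError(f"Delta must lie in [0, 1), got {self.Delta}")
        if not 0.0 <= self.p_ell <= 1.0:
            raise ValueError(f"p_ell must lie in [0, 1], got {self.p_ell}")


@dataclass(frozen=True)
class CopyNumberParams:
    """Copy-number scalings: cost ``Delta = Delta_p * n_p`` per cell,
    segregation loss ``p_ell = 2**(1 - n_p)``, and viable release fraction
    ``p_v`` (transformation: ``n_eff = p_v * n_p``)."""

    Delta_p: float
    n_p: float = 1.0
    p_v: float = 1.0

    def __post_init__(self) -> None:
        if self.Delta_p <= 0:
            raise ValueError("Delta_p must be positive")
        if self.n_p < 1:
            raise ValueError("n_p must be >= 1")
        if not 0.0 <= self.p_v <= 1.0:
            raise ValueError("p_v must lie in [0, 1]")


@dataclass(frozen=True)
class SystemState:
    """Nonnegative abundances: cells, nutrient and (optionally) free plasmids."""

    rho: float
    rho_p: float
    C: float
    P: float | None = None

    def __post_init__(self) -> None:
        for name in ("rho", "rho_p", "C"):
            _check_nonneg(name, getattr(self, name))
        if self.P is not None:
            _check_nonneg("P", self.P)

    def to_array(self) -> np.ndarray:
        if self.P is None:
            return np.array([self.rho, self.rho_p, self.C], dtype=float)
        return np.array([self.rho, self.rho_p, self.C, self.P], dtype=float)

    @staticmethod
    def from_array(y: np.ndarray) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape == (3,):
            return SystemState(y[0], y[1], y[2])
        if y.shape == (4,):
            return SystemState(y[0], y[1], y[2], y[3])
        raise ValueError(f"state vector must have length 3 or 4, got shape {y.shape}")


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed sequence of states from the RK4 integrator."""

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


@dataclass
class Equilibrium:
    state: SystemState
    kind: Literal["no_plasmid", "plasmid_only", "coexistence"]
    stability: Literal["stable", "unstable", "marginal"] | None = None
    eigenvalues: np.ndarray | None = None


@dataclass(frozen=True)
class PhaseDiagram:
    """Grid of ecological outcomes over plasmid cost and transfer rate."""

    delta_axis: np.ndarray
    gamma_axis: np.ndarray
    labels: np.ndarray  # shape (len(delta_axis), len(gamma_axis)), dtype object
    mechanism: str


# ---------------------------------------------------------------------------
# right-hand sides and Jacobians


def _conjugation_rhs_arr(y: np.ndarray, p: ConjugationParams) -> np.ndarray:
    rho, rho_p, C = y
    growth_free = p.alpha * C * rho
    growth_plas = (1.0 - p.Delta) * p.alpha * C * rho_p
    conj = p.gamma_c * rho * rho_p
    loss = p.p_ell * growth_plas
    return np.array(
        [
            growth_free - conj + loss - p.delta * rho,
            growth_plas + conj - loss - p.delta * rho_p,
            p.S - growth_free - growth_plas,
        ]
    )


def _transformation_rhs_arr(y: np.ndarray, p: TransformationParams) -> np.ndarray:
    rho, rho_p, C, P = y
    growth_free = p.alpha * C * rho
    growth_plas = (1.0 - p.Delta) * p.alpha * C * rho_p
    infect = p.gamma_t * rho * P
    loss = p.p_ell * growth_plas
    return np.array(
        [
            growth_free - infect + loss - p.delta * rho,
            growth_plas + infect - loss - p.delta * rho_p,
            p.S - growth_free - growth_plas,
            p.n_eff * p.delta * rho_p - infect - p.delta_p * P,
        ]
    )


def conjugation_rhs(
    state: SystemState | Sequence[float], params: ConjugationParams
) -> np.ndarray:
    """Time derivatives (d rho/dt, d rho_p/dt, dC/dt) of the conjugation model."""
    y = state.to_array() if isinstance(state, SystemState) else np.asarray(state, float)
    if y.shape != (3,):
        raise ValueError("conjugation state must have components (rho, rho_p, C)")
    if np.any(y < 0):
        raise ValueError("state components must be nonnegative")
    return _conjugation_rhs_arr(y, params)


def transformation_rhs(
    state: SystemState | Sequence[float], params: TransformationParams
) -> np.ndarray:
    """Time derivatives (d rho/dt, d rho_p/dt, dC/dt, dP/dt) of the transformation model."""
    if isinstance(state, SystemState):
        if state.P is None:
            raise ValueError("transformation state requires the free-plasmid component P")
        y = state.to_array()
    else:
        y = np.asarray(state, float)
    if y.shape != (4,):
        raise ValueError("transformation state must have components (rho, rho_p, C, P)")
    if np.any(y < 0):
        raise ValueError("state components must be nonnegative")
    return _transformation_rhs_arr(y, params)


def conjugation_jacobian(y: np.ndarray, p: ConjugationParams) -> np.ndarray:
    """Analytic Jacobian of the conjugation right-hand side."""
    rho, rho_p, C = np.asarray(y, float)
    a, D, g, pl, d = p.alpha, p.Delta, p.gamma_c, p.p_ell, p.delta
    return np.array(
        [
            [a * C - g * rho_p - d, -g * rho + pl * (1 - D) * a * C, a * rho + pl * (1 - D) * a * rho_p],
            [g * rho_p, (1 - pl) * (1 - D) * a * C + g * rho - d, (1 - pl) * (1 - D) * a * rho_p],
            [-a * C, -(1 - D) * a * C, -a * rho - (1 - D) * a * rho_p],
        ]
    )


def transformation_jacobian(y: np.ndarray, p: TransformationParams) -> np.ndarray:
    """Analytic Jacobian of the transformation right-hand side."""
    rho, rho_p, C, P = np.asarray(y, float)
    a, D, g, pl, d = p.alpha, p.Delta, p.gamma_t, p.p_ell, p.delta
    return np.array(
        [
            [a * C - g * P - d, pl * (1 - D) * a * C, a * rho + pl * (1 - D) * a * rho_p, -g * rho],
            [g * P, (1 - pl) * (1 - D) * a * C - d, (1 - pl) * (1 - D) * a * rho_p, g * rho],
            [-a * C, -(1 - D) * a * C, -a * rho - (1 - D) * a * rho_p, 0.0],
            [-g * P, p.n_eff * d, 0.0, -g * rho - p.delta_p],
        ]
    )


def _rhs_and_jac(params) -> tuple[Callable, Callable, int]:
    if isinstance(params, ConjugationParams):
        return (
            lambda y: _conjugation_rhs_arr(y, params),
            lambda y: conjugation_jacobian(y, params),
            3,
        )
    if isinstance(params, TransformationParams):
        return (
            lambda y: _transformation_rhs_arr(y, params),
            lambda y: transformation_jacobian(y, params),
            4,
        )
    raise TypeError(f"unsupported parameter type {type(params)!r}")


# ---------------------------------------------------------------------------
# equilibria and invasion thresholds


def plasmid_free_equilibrium(
    params: ConjugationParams | TransformationParams,
) -> SystemState:
    """The plasmid-free fixed point: rho* = S/delta, C* = delta/alpha."""
    if params.delta <= 0:
        raise ValueError("delta must be positive for a plasmid-free equilibrium")
    if params.alpha <= 0:
        raise ValueError("alpha must be positive for a plasmid-free equilibrium")
    rho_star = params.S / params.delta
    C_star = params.delta / params.alpha
    if isinstance(params, TransformationParams):
        return SystemState(rho_star, 0.0, C_star, 0.0)
    return SystemState(rho_star, 0.0, C_star)


def _loss_burden(Delta: float, p_ell: float) -> float:
    # combined per-division replication deficit: cost plus segregation loss
    return Delta + p_ell * (1.0 - Delta)


def conjugation_invasion_threshold(params: ConjugationParams) -> float:
    """Critical conjugation rate gamma_c* above which the plasmid invades.

    The plasmid-free state destabilizes when
    ``gamma_c * rho* > delta * (Delta + p_ell (1 - Delta))`` with
    ``rho* = S / delta``; equality does not invade.
    """
    if params.S <= 0:
        raise ValueError("S must be positive (rho* undefined)")
    if params.delta <= 0:
        raise ValueError("delta must be positive")
    rho_star = params.S / params.delta
    return params.delta * _loss_burden(params.Delta, params.p_ell) / rho_star


def transformation_invasion_threshold(params: TransformationParams) -> float:
    """Critical transformation rate gamma_t*, or :data:`NO_INVASION`.

    When the per-death plasmid release ``n_eff`` does not exceed the total
    replication deficit ``Delta + p_ell (1 - Delta)``, the plasmid-free
    state is stable for every transfer rate and the sentinel is returned.
    """
    if params.S <= 0:
        raise ValueError("S must be positive (rho* undefined)")
    if params.delta <= 0:
        raise ValueError("delta must be positive")
    burden = _loss_burden(params.Delta, params.p_ell)
    denom = params.n_eff - burden
    if denom <= 0:
        return NO_INVASION
    rho_star = params.S / params.delta
    return params.delta_p * burden / (rho_star * denom)


def conjugative_invasion_barrier(n_p: float, Delta_p: float, delta: float) -> float:
    """Right-hand side of the conjugative invasion condition as a function of
    copy number: ``delta * (Delta_p n_p + 2**(1 - n_p) (1 - Delta_p n_p))``."""
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    if Delta_p * n_p >= 1:
        raise ValueError("total cost Delta_p * n_p must be < 1")
    cost = Delta_p * n_p
    return delta * (cost + 2.0 ** (1.0 - n_p) * (1.0 - cost))


def optimal_copy_number(
    copy_params: CopyNumberParams, mechanism: Mechanism
) -> float:
    """Copy number minimizing the invasion barrier.

    Conjugation: integer argmin of :func:`conjugative_invasion_barrier`
    (ties break to the smallest copy number).  Transformation: the optimum
    is ``1 / Delta_p`` — the host's growth budget is fully consumed —
    provided release still exceeds the deficit there (``p_v > Delta_p``);
    otherwise :data:`NO_INVASION`.
    """
    Dp = copy_params.Delta_p
    if Dp >= 1:
        raise ValueError("Delta_p must be < 1")
    if mechanism == "transformation":
        n_opt = 1.0 / Dp
        # invasion-condition denominator at the optimum: p_v*n_p - 1 (Delta -> 1)
        if copy_params.p_v * n_opt - 1.0 <= 0:
            return NO_INVASION
        return n_opt
    if mechanism != "conjugation":
        raise ValueError(f"unknown mechanism {mechanism!r}")
    n_max = int(math.floor((1.0 - 1e-12) / Dp))
    grid = np.arange(1, max(n_max, 1) + 1)
    values = [conjugative_invasion_barrier(int(n), Dp, 1.0) for n in grid]
    return int(grid[int(np.argmin(values))])


def continuous_optimal_copy_number(copy_params: CopyNumberParams) -> float:
    """Real-valued minimizer of the conjugative barrier (diagnostic only)."""
    Dp = copy_params.Delta_p
    n_max = (1.0 - 1e-9) / Dp
    res = optimize.minimize_scalar(
        lambda n: conjugative_invasion_barrier(n, Dp, 1.0),
        bounds=(1.0, n_max),
        method="bounded",
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# integration


def integrate(
    rhs: Callable[[np.ndarray], np.ndarray],
    initial: SystemState | Sequence[float],
    duration: float,
    step: float = 0.01,
    record_stride: int = 1,
) -> Trajectory:
    """Classical fixed-step fourth-order Runge–Kutta integration.

    Components dipping below zero by less than ``1e-12`` are clipped to
    zero; larger undershoots raise, indicating the step is too large.
    """
    if step <= 0 or duration <= 0:
        raise ValueError("step and duration must be positive")
    y = initial.to_array() if isinstance(initial, SystemState) else np.asarray(
        initial, dtype=float
    ).copy()
    n_steps = int(round(duration / step))
    times = [0.0]
    states = [y.copy()]
    h = step
    t = 0.0
    for i in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if np.any(y < 0):
            low = float(y.min())
            if low < -_NEG_CLIP:
                raise RuntimeError(
                    f"state component reached {low:.3e} < -{_NEG_CLIP}; "
                    "reduce the integration step"
                )
            np.clip(y, 0.0, None, out=y)
        t = (i + 1) * h
        if (i + 1) % record_stride == 0 or i == n_steps - 1:
            times.append(t)
            states.append(y.copy())
    return Trajectory(np.asarray(times), np.asarray(states))


def integrate_to_steady_state(
    rhs: Callable[[np.ndarray], np.ndarray],
    initial: SystemState | Sequence[float],
    step: float = 0.01,
    t_max: float = 1e5,
    tol: float = _STEADY_TOL,
    check_every: int = 200,
) -> tuple[np.ndarray, float, bool]:
    """Integrate until ``max|dy/dt| / max(max|y|, 1e-12) < tol``.

    Returns ``(state, time, converged)``.
    """
    y = initial.to_array() if isinstance(initial, SystemState) else np.asarray(
        initial, dtype=float
    ).copy()
    h = step
    t = 0.0
    n_total = int(round(t_max / h))
    i = 0
    while i < n_total:
        block = min(check_every, n_total - i)
        for _ in range(block):
            k1 = rhs(y)
            k2 = rhs(y + 0.5 * h * k1)
            k3 = rhs(y + 0.5 * h * k2)
            k4 = rhs(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if np.any(y < 0):
                low = float(y.min())
                if low < -_NEG_CLIP:
                    raise RuntimeError(
                        f"state component reached {low:.3e}; reduce the step"
                    )
                np.clip(y, 0.0, None, out=y)
        i += block
        t = i * h
        deriv = rhs(y)
        scale = max(float(np.max(np.abs(y))), 1e-12)
        if float(np.max(np.abs(deriv))) / scale < tol:
            return y, t, True
    return y, t, False


# ---------------------------------------------------------------------------
# equilibria


def _conjugation_interior_closed_form(p: ConjugationParams) -> np.ndarray | None:
    """Interior equilibrium of the conjugative model for p_ell = 0.

    From the fixed-point conditions: rho_p* = S/(delta Delta) - delta/gamma_c,
    alpha C* = S gamma_c / (delta Delta), rho* = delta Delta / gamma_c
    - (1 - Delta) rho_p*.  Returns None when any component is non-positive.
    """
    if p.gamma_c <= 0 or p.Delta <= 0:
        return None
    rho_p = p.S / (p.delta * p.Delta) - p.delta / p.gamma_c
    C = p.S * p.gamma_c / (p.delta * p.Delta * p.alpha)
    rho = p.delta * p.Delta / p.gamma_c - (1.0 - p.Delta) * rho_p
    if rho_p <= 1e-12 or rho <= 1e-12 or C <= 0:
        return None
    return np.array([rho, rho_p, C])


def _transformation_interior_roots(p: TransformationParams) -> list[np.ndarray]:
    """Interior equilibria of the transformative model for p_ell = 0.

    The four fixed-point conditions reduce to a scalar equation in the
    free-plasmid density P; sign changes are bracketed on a log grid and
    refined with Brent's method.  Both stable nodes and saddles are
    returned.
    """
    g, d, dp, ne, a, D, S = (
        p.gamma_t,
        p.delta,
        p.delta_p,
        p.n_eff,
        p.alpha,
        p.Delta,
        p.S,
    )
    if g <= 0 or D <= 0:
        return []
    P_max = d * D / ((1.0 - D) * g)  # above this the cell ratio rho/rho_p < 0

    def residual(P: float) -> float:
        aC = d + g * P
        k = (d * D - (1.0 - D) * g * P) / (g * P)  # rho / rho_p
        rho_p = S / (aC * (k + 1.0 - D))
        rho = k * rho_p
        return ne * d * rho_p - (g * rho + dp) * P

    grid = np.geomspace(P_max * 1e-12, P_max * (1.0 - 1e-9), 400)
    vals = np.array([residual(P) for P in grid])
    roots: list[np.ndarray] = []
    sign = np.sign(vals)
    for j in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        P = optimize.brentq(residual, grid[j], grid[j + 1], xtol=1e-14, rtol=1e-14)
        aC = d + g * P
        k = (d * D - (1.0 - D) * g * P) / (g * P)
        rho_p = S / (aC * (k + 1.0 - D))
        rho = k * rho_p
        y = np.array([rho, rho_p, aC / a, P])
        if rho > 1e-12 and rho_p > 1e-12:
            roots.append(y)
    return roots


def _numeric_root(rhs, jac, seed: np.ndarray) -> np.ndarray | None:
    sol = optimize.root(rhs, seed, jac=jac, method="hybr", tol=1e-12)
    if not sol.success:
        return None
    y = sol.x
    if np.any(y < -1e-9):
        return None
    y = np.clip(y, 0.0, None)
    if float(np.max(np.abs(rhs(y)))) > _ROOT_TOL:
        return None
    return y


def find_equilibria(
    params: ConjugationParams | TransformationParams,
) -> list[Equilibrium]:
    """All located equilibria, each verified to zero the right-hand side.

    The plasmid-free state is always present in closed form.  The
    plasmid-only state is closed-form for ``p_ell = 0`` and continued
    numerically otherwise (finite segregation loss re-seeds plasmid-free
    cells, so the branch acquires a small ``rho > 0``).  Interior
    (coexistence) equilibria are closed-form for conjugation, located by
    scalar bracketing for transformation, and by multi-start root-finding
    for finite ``p_ell``.
    """
    rhs, jac, dim = _rhs_and_jac(params)
    is_transf = dim == 4
    out: list[Equilibrium] = []

    eq0 = plasmid_free_equilibrium(params)
    out.append(classify_stability(Equilibrium(eq0, "no_plasmid"), params))

    # plasmid-only branch
    C_po = params.delta / ((1.0 - params.Delta) * params.alpha)
    rho_p_po = params.S / params.delta
    if is_transf:
        P_po = params.n_eff * params.delta * rho_p_po / params.delta_p
        seed = np.array([0.0, rho_p_po, C_po, P_po])
    else:
        seed = np.array([0.0, rho_p_po, C_po])
    if params.p_ell == 0:
        y_po = seed
    else:
        y_po = _numeric_root(rhs, jac, seed + 1e-3)
        if y_po is None:
            warnings.warn("plasmid-only equilibrium not located (p_ell > 0)")
    if y_po is not None and float(np.max(np.abs(rhs(y_po)))) <= _ROOT_TOL:
        out.append(
            classify_stability(
                Equilibrium(SystemState.from_array(y_po), "plasmid_only"), params
            )
        )

    # interior branch(es)
    interiors: list[np.ndarray] = []
    if params.p_ell == 0:
        if is_transf:
            interiors = _transformation_interior_roots(params)
        else:
            y_int = _conjugation_interior_closed_form(params)
            if y_int is not None:
                interiors = [y_int]
    else:
        seeds = []
        closed = None
        if not is_transf:
            closed = _conjugation_interior_closed_form(replace(params, p_ell=0.0))
        if closed is not None:
            seeds.append(closed)
        # endpoint of an invasion run as a generic seed
        y0 = eq0.to_array()
        y0[1] = 1e-6 * max(y0[0], 1.0)
        try:
            y_end, _, _ = integrate_to_steady_state(rhs, y0, t_max=2000.0)
            seeds.append(y_end)
        except RuntimeError:
            pass
        for s in seeds:
            y_int = _numeric_root(rhs, jac, np.asarray(s, float))
            if y_int is not None and y_int[0] > 1e-9 and y_int[1] > 1e-9:
                known = list(interiors)
                if y_po is not None:
                    known.append(y_po)  # finite p_ell: plasmid-only branch has rho > 0
                if not any(np.allclose(y_int, u, atol=1e-8) for u in known):
                    interiors.append(y_int)
        if not interiors:
            warnings.warn("no interior equilibrium located; reporting boundary states only")
    for y_int in interiors:
        if float(np.max(np.abs(rhs(y_int)))) <= _ROOT_TOL:
            out.append(
                classify_stability(
                    Equilibrium(SystemState.from_array(y_int), "coexistence"), params
                )
            )
    return out


def classify_stability(
    eq: Equilibrium,
    params: ConjugationParams | TransformationParams,
    tol_eig: float = _TOL_EIG,
) -> Equilibrium:
    """Fill in eigenvalues of the analytic Jacobian and a stability verdict.

    ``stable`` iff every real part is below ``-tol_eig``; a leading real
    part within ``±tol_eig`` of zero is flagged ``marginal``.
    """
    _, jac, dim = _rhs_and_jac(params)
    y = eq.state.to_array()
    if len(y) != dim:
        raise ValueError("state dimensionality does not match the parameter set")
    eigvals = np.linalg.eigvals(jac(y))
    max_re = float(np.max(eigvals.real))
    if max_re < -tol_eig:
        stability = "stable"
    elif max_re > tol_eig:
        stability = "unstable"
    else:
        stability = "marginal"
    eq.eigenvalues = eigvals
    eq.stability = stability
    return eq


# ---------------------------------------------------------------------------
# phase diagrams


def _point_label(params: ConjugationParams | TransformationParams) -> str:
    eqs = find_equilibria(params)
    by_kind: dict[str, list[Equilibrium]] = {}
    for e in eqs:
        by_kind.setdefault(e.kind, []).append(e)
    np_stable = by_kind["no_plasmid"][0].stability == "stable"
    po = by_kind.get("plasmid_only", [None])[0]
    po_stable = po is not None and po.stability == "stable"
    interior_stable = any(
        e.stability == "stable" for e in by_kind.get("coexistence", [])
    )
    if np_stable and po_stable:
        return "bistable"
    if interior_stable:
        return "coexistence"
    if po_stable:
        return "plasmid_only"
    if np_stable:
        return "no_plasmid"
    warnings.warn(
        "no stable equilibrium located at a grid point; labeling coexistence"
    )
    return "coexistence"


def phase_diagram(
    delta_axis: Sequence[float],
    gamma_axis: Sequence[float],
    mechanism: Mechanism,
    base_params: ConjugationParams | TransformationParams | None = None,
) -> PhaseDiagram:
    """Label every (Delta, transfer rate) grid point by its stable states.

    Labels: ``no_plasmid`` (only the plasmid-free state is stable),
    ``coexistence`` (a stable interior equilibrium), ``plasmid_only``
    (only the plasmid-only state is stable), ``bistable`` (plasmid-free
    and plasmid-only both locally stable).
    """
    delta_axis = np.asarray(delta_axis, dtype=float)
    gamma_axis = np.asarray(gamma_axis, dtype=float)
    if delta_axis.size == 0 or gamma_axis.size == 0:
        raise ValueError("phase-diagram axes must be nonempty")
    if base_params is None:
        base_params = (
            ConjugationParams() if mechanism == "conjugation" else TransformationParams()
        )
    labels = np.empty((delta_axis.size, gamma_axis.size), dtype=object)
    for i, D in enumerate(delta_axis):
        for j, g in enumerate(gamma_axis):
            if mechanism == "conjugation":
                p = replace(base_params, Delta=float(D), gamma_c=float(g))
            else:
                p = replace(base_params, Delta=float(D), gamma_t=float(g))
            labels[i, j] = _point_label(p)
    return PhaseDiagram(delta_axis, gamma_axis, labels, mechanism)


def default_phase_axes(
    mechanism: Mechanism, n_delta: int = 100, n_gamma: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Linear Delta axis over (0, 1), log-spaced transfer-rate axis."""
    delta_axis = np.linspace(0.02, 0.98, n_delta)
    gamma_axis = np.geomspace(1e-4, 1.0, n_gamma)
    return delta_axis, gamma_axis


def phase_diagram_frame(diagram: PhaseDiagram):
    """Long-format table (Delta, gamma, label) for TSV export."""
    import pandas as pd

    dd, gg = np.meshgrid(diagram.delta_axis, diagram.gamma_axis, indexing="ij")
    return pd.DataFrame(
        {
            "Delta": dd.ravel(),
            "gamma": gg.ravel(),
            "label": diagram.labels.ravel(),
        }
    )
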