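"""Fitting Wright-Fisher stationary distributions to plasmid-count histograms.

The observed histogram is truncated to bins with at least ten observations
(probabilities keep the full-histogram denominator), and the stationary
distribution's parameters are estimated by minimizing the sum of squared
differences between log model probabilities and log observed probabilities
— bounded nonlinear least squares on log-transformed parameters with
Latin-hypercube multi-starts.  In the strong-positive-epistasis regime
only the ratio q/Delta is well determined; a flat objective direction is
detected from the Gauss-Newton Hessian and flagged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .histogram import Histogram
from .wright_fisher import EpistasisSpec, stationary_distribution

__all__ = ["FitResult", "truncate_for_fit", "fit_model", "compare_fits"]

_LOG_BOUND_LO = -6.0            # log10 of the lower Delta/q bound
_LOG_BOUND_HI = np.log10(0.5)   # log10 of the upper Delta/q bound
# the power exponent a is fitted on a log scale with a lower bound small
# enough that the family numerically nests the constant-cost (positive
# epistasis) limit a -> 0
_LOG_A_BOUNDS = (-6.0, np.log10(3.0))
_PENALTY = 1e3                  # residual magnitude on invalid parameter draws


@dataclass
class FitResult:
    """Best-fit stationary-model parameters for one epistasis form."""

    form: str
    Delta: float
    q: float
    a: float | None
    objective: float
    bins: np.ndarray
    residuals: np.ndarray
    identifiability_warning: bool
    n_starts: int
    success: bool

    @property
    def ratio(self) -> float:
        """q / Delta — the combination that stays identifiable when the
        objective is flat along the (Delta, q) scaling direction."""
        return self.q / self.Delta

    def spec(self) -> EpistasisSpec:
        return EpistasisSpec(form=self.form, Delta=self.Delta, a=self.a)


def truncate_for_fit(
    h: Histogram, min_count: float = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Bins retained for fitting (counts >= min_count, boundary inclusive)
    and their observed probabilities over the FULL histogram total."""
    keep = np.nonzero(h.counts >= min_count)[0]
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} bins have >= {min_count} observations; "
            "the fit is under-determined"
        )
    return keep, h.counts[keep] / h.total


def _model_log_probs(
    form: str, Delta: float, q: float, a: float | None, bins: np.ndarray
) -> np.ndarray | None:
    """Log stationary probabilities at the retained bins, or None if the
    parameter draw has no convergent stationary distribution."""
    try:
        spec = EpistasisSpec(form=form, Delta=Delta, a=a)
        f = stationary_distribution(spec, q, i_max=int(bins.max()) + 1)
    except ValueError:
        return None
    probs = f.f[bins]
    if np.any(probs <= 0):
        return None
    return np.log(probs)


def fit_model(
    h: Histogram,
    form: str = "positive",
    min_count: float = 10,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit one epistasis form to a histogram by log-space least squares.

    Free parameters are ``log10 Delta`` and ``log10 q`` (plus ``log10 a``
    for the power form), bounded to Delta, q in [1e-6, 0.5] and a in
    [1e-6, 3], started from ``n_starts`` Latin-hypercube points.  Power
    fits additionally start from the positive-form solution at the small-a
    boundary, so the nested constant-cost limit is always reachable.
    """
    bins, p_obs = truncate_for_fit(h, min_count=min_count)
    log_obs = np.log(p_obs)
    has_a = form == "power"
    ndim = 3 if has_a else 2
    lo = np.array([_LOG_BOUND_LO, _LOG_BOUND_LO] + ([_LOG_A_BOUNDS[0]] if has_a else []))
    hi = np.array([_LOG_BOUND_HI, _LOG_BOUND_HI] + ([_LOG_A_BOUNDS[1]] if has_a else []))

    def residual(theta: np.ndarray) -> np.ndarray:
        Delta = 10.0 ** theta[0]
        q = 10.0 ** theta[1]
        a = 10.0 ** theta[2] if has_a else None
        log_model = _model_log_probs(form, Delta, q, a, bins)
        if log_model is None:
            # smooth-ish push back toward the convergent region
            return np.full(len(bins), _PENALTY * (1.0 + theta[1] - theta[0]))
        return log_model - log_obs

    sampler = qmc.LatinHypercube(d=ndim, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lo, hi)
    if form == "positive":
        # constant-cost stationary tails diverge for q >= Delta; start inside
        swap = starts[:, 1] >= starts[:, 0]
        starts[swap, 0], starts[swap, 1] = starts[swap, 1].copy(), starts[swap, 0].copy()
    starts = list(starts)
    if has_a:
        pos_fit = fit_model(h, "positive", min_count=min_count, n_starts=n_starts, seed=seed)
        starts.append(
            np.array([np.log10(pos_fit.Delta), np.log10(pos_fit.q), _LOG_A_BOUNDS[0]])
        )
    best = None
    any_success = False
    for x0 in starts:
        try:
            res = optimize.least_squares(
                residual, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14
            )
        except Exception:  # noqa: BLE001 — a bad start must not kill the fit
            continue
        any_success = any_success or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not any_success:
        raise RuntimeError(
            f"optimizer failed to converge from all {n_starts} starts for form {form!r}"
        )
    theta = best.x
    Delta = 10.0 ** theta[0]
    q = 10.0 ** theta[1]
    a = 10.0 ** theta[2] if has_a else None
    resid = residual(theta)
    objective = float(np.dot(resid, resid))
    # Gauss-Newton Hessian: a near-singular direction means only a parameter
    # combination (in practice q/Delta) is estimable
    H = best.jac.T @ best.jac
    eigs = np.linalg.eigvalsh(H)
    ident_warn = bool(eigs[0] < 1e-6 * eigs[-1])
    return FitResult(
        form=form,
        Delta=float(Delta),
        q=float(q),
        a=a,
        objective=objective,
        bins=bins,
        residuals=resid,
        identifiability_warning=ident_warn,
        n_starts=n_starts,
        success=True,
    )


def compare_fits(
    h: Histogram,
    forms: Sequence[str] = ("positive", "none", "negative"),
    min_count: float = 10,
    n_starts: int = 10,
    seed: int = 0,
) -> list[FitResult]:
    """Fit each epistasis form and rank by objective (best first)."""
    if len(forms) < 1:
        raise ValueError("at least one epistasis form is required")
    results = [
        fit_model(h, form=f, min_count=min_count, n_starts=n_starts, seed=seed)
        for f in forms
    ]
    return sorted(results, key=lambda r: r.objective)
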