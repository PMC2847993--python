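"""Steady-state analysis of the non-linear (recycling) translation model.

At steady state all four reaction fluxes are equal to a common value ``w``
(the stationary protein synthesis rate).  Writing ``x = [60S]_s/[60S]_0``
for the free fraction of the large subunit, the fluxes and conservation
laws give every steady concentration in terms of ``x``::

    w            = k4 (1-x) [60S]0
    [80S]_s      = (1-x) [60S]0
    [AUG]_s      = w / (k3 x [60S]0)
    [mRNA:40S]_s = w / k2
    [eIF4F]_s    = [eIF4F]0 - w/k2
    [40S]_s      = w / (k1 [eIF4F]_s)

and closing the 40S conservation law yields one scalar equation in ``x``
which is solved numerically (:func:`steady_state_exact`).

Dropping the subdominant ``[mRNA:40S]`` term (bounded by the scarce factor
pool) turns the closure into a cubic in ``x`` with dimensionless
coefficients built from

    alpha = k4/(k1 [eIF4F]0),   beta  = k2 [eIF4F]0 / (k4 [60S]0),
    gamma = k4/(k3 [60S]0),     delta = [40S]0/[60S]0.

``beta`` is the **regime ratio**: it compares the maximal initiation flux
(k2·[eIF4F]0, every factor molecule cycling at full speed) with the
maximal ribosome-recycling flux (k4·[60S]0, every large subunit engaged).
``beta > 1`` is the *efficient initiation* scenario (recycling limits the
rate, the physical root is the small ``x0``); ``beta < 1`` is *inefficient
initiation* (the factor pool limits the rate, the physical root is
``x1 ≈ 1-beta``).  To leading order the stationary rate is therefore
``min(k2 [eIF4F]0, k4 [60S]0)`` and never depends on k1 or k3 directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core_models import (
    DomainError,
    NonlinearParams,
    NonlinearState,
    SEPARATION_FACTOR,
    _nonlinear_fluxes,
)

__all__ = [
    "CubicCoeffs",
    "RootSet",
    "SteadyStateResult",
    "NoSteadyStateError",
    "beta",
    "classify_regime",
    "is_regime_boundary",
    "steady_state_exact",
    "cubic_roots",
    "steady_protein_rate",
    "polysome_proxy",
    "critical_thresholds",
]

#: Width of the band around beta = 1 inside which asymptotic (regime-split)
#: formulas are not trusted and results carry a boundary flag.
REGIME_BOUNDARY_BAND = 0.05


class NoSteadyStateError(RuntimeError):
    """The scalar flux-balance equation has no admissible root in (0, 1]."""


# ---------------------------------------------------------------------------
# regime ratio
# ---------------------------------------------------------------------------


def beta(p: NonlinearParams) -> float:
    """Regime ratio ``k2*[eIF4F]0 / (k4*[60S]0)``.

    Maximal initiation flux over maximal ribosome-recycling flux; selects
    between the efficient (>1) and inefficient (<1) initiation scenarios.
    """
    return p.k2 * p.total_eIF4F / (p.k4 * p.total_60S)


def is_regime_boundary(p: NonlinearParams, band: float = REGIME_BOUNDARY_BAND) -> bool:
    """True when beta sits within ``band`` of the degenerate value 1."""
    return abs(beta(p) - 1.0) < band


def classify_regime(p: NonlinearParams) -> str:
    """``"efficient"`` iff beta > 1, else ``"inefficient"``.

    Near beta = 1 the classification is still returned but
    :func:`is_regime_boundary` should be consulted; the asymptotic
    machinery degrades there.
    """
    return "efficient" if beta(p) > 1.0 else "inefficient"


# ---------------------------------------------------------------------------
# exact steady state
# ---------------------------------------------------------------------------


def _back_substitute(x: float, p: NonlinearParams) -> np.ndarray:
    """Steady concentrations implied by a free-60S fraction ``x``."""
    w = p.k4 * (1.0 - x) * p.total_60S
    c80 = (1.0 - x) * p.total_60S
    c60 = x * p.total_60S
    mrna = w / p.k2
    eif = p.total_eIF4F - mrna
    aug = w / (p.k3 * x * p.total_60S) if x > 0 else np.inf
    c40 = w / (p.k1 * eif) if eif > 0 else np.inf
    return np.array([c40, c60, eif, mrna, aug, c80])


def _closure(x: float, p: NonlinearParams) -> float:
    """Residual of the 40S conservation law as a function of ``x``."""
    c40, _, _, mrna, aug, c80 = _back_substitute(x, p)
    return c40 + mrna + aug + c80 - p.total_40S


@dataclass
class SteadyStateResult:
    """Steady state of the non-linear model with provenance of the root."""

    x: float
    concentrations: NonlinearState
    prsynth: float
    regime: str
    source: str  # "exact_rootfind" | "cubic_x0" | "cubic_x1"
    beta: float
    regime_boundary: bool = False
    flux_residual: float = 0.0
    warnings: list[str] = field(default_factory=list)

    def state_array(self) -> np.ndarray:
        return self.concentrations.to_array()


def steady_state_exact(p: NonlinearParams, xtol: float = 1e-14) -> SteadyStateResult:
    """Solve the scalar flux-balance closure for the physical steady state.

    The closure residual is monotone decreasing on the physical branch
    ``x in (max(0, 1-beta), 1]``: it diverges to +inf at the left edge
    (either [AUG] or [40S] blows up) and equals ``-[40S]0`` at ``x = 1``.
    Bracketed root finding (Brent) therefore always succeeds for valid
    parameters; failure indicates an inconsistent model and raises
    :class:`NoSteadyStateError` with a diagnostic.
    """
    b = beta(p)
    x_lo = max(0.0, 1.0 - b)
    # march in from the singular edge until the residual is positive
    span = 1.0 - x_lo
    left = None
    for frac in np.geomspace(1e-14, 0.5, 60):
        cand = x_lo + frac * span
        if _closure(cand, p) > 0:
            left = cand
            break
    if left is None:
        raise NoSteadyStateError(
            f"no admissible root in ({x_lo:g}, 1]: closure residual is negative "
            f"throughout (beta={b:g}); the parameter set is inconsistent with a "
            "positive-flux steady state"
        )
    x = brentq(_closure, left, 1.0, args=(p,), xtol=xtol, rtol=8.9e-16)
    conc = _back_substitute(x, p)
    fluxes = _nonlinear_fluxes(conc, p)
    residual = float(np.max(np.abs(np.diff(fluxes)))) if fluxes.max() > 0 else 0.0
    return SteadyStateResult(
        x=float(x),
        concentrations=NonlinearState.from_array(conc),
        prsynth=float(fluxes[3]),
        regime=classify_regime(p),
        source="exact_rootfind",
        beta=b,
        regime_boundary=is_regime_boundary(p),
        flux_residual=residual,
    )


# ---------------------------------------------------------------------------
# asymptotic cubic
# ---------------------------------------------------------------------------


@dataclass
class CubicCoeffs:
    """Dimensionless coefficients of the asymptotic cubic in ``x``.

    The cubic is ``x**3 + a2*x**2 + a1*x + a0 = 0`` with::

        a2 = delta + beta - 2 + gamma + alpha*beta
        a1 = (delta - 1)(beta - 1) - alpha*beta - gamma*(2 - beta)
        a0 = gamma * (1 - beta)

    Under the standing parameter ordering, ``delta > 1`` and ``gamma << 1``;
    if additionally ``k1 >> k4/[eIF4F]0`` then ``alpha << beta``.  Violations
    are recorded as warnings, not errors.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    params: NonlinearParams
    warnings: list[str] = field(default_factory=list)

    @property
    def a2(self) -> float:
        return self.delta + self.beta - 2.0 + self.gamma + self.alpha * self.beta

    @property
    def a1(self) -> float:
        return (
            (self.delta - 1.0) * (self.beta - 1.0)
            - self.alpha * self.beta
            - self.gamma * (2.0 - self.beta)
        )

    @property
    def a0(self) -> float:
        return self.gamma * (1.0 - self.beta)

    def polynomial(self) -> np.ndarray:
        return np.array([1.0, self.a2, self.a1, self.a0])


@dataclass
class RootSet:
    """Approximate roots of the cubic and the admissible physical branch."""

    x0: float
    x1: float
    x2: float
    admissible: str | None  # "x0" | "x1" | None

    @property
    def admissible_value(self) -> float | None:
        return {"x0": self.x0, "x1": self.x1, None: None}[self.admissible]


def cubic_coeffs(p: NonlinearParams, factor: float = SEPARATION_FACTOR) -> CubicCoeffs:
    b = beta(p)
    coeffs = CubicCoeffs(
        alpha=p.k4 / (p.k1 * p.total_eIF4F),
        beta=b,
        gamma=p.k4 / (p.k3 * p.total_60S),
        delta=p.total_40S / p.total_60S,
        params=p,
    )
    if coeffs.delta <= 1.0:
        coeffs.warnings.append("delta <= 1: 40S pool is not abundant vs 60S")
    if coeffs.gamma * factor >= 1.0:
        coeffs.warnings.append("gamma is not small: elongation is not fast")
    if p.k1 * p.total_eIF4F < factor * p.k4 and coeffs.alpha * factor >= coeffs.beta:
        coeffs.warnings.append("alpha is not small vs beta (k1 close to k4/[eIF4F]0)")
    if not p.ordering_satisfied(factor):
        coeffs.warnings.append("parameter ordering assumptions not satisfied")
    return coeffs


def _is_admissible(x: float, p: NonlinearParams) -> bool:
    if not (0.0 < x <= 1.0):
        return False
    c40, _, eif, _, aug, _ = _back_substitute(x, p)
    return eif > 0 and np.isfinite(c40) and c40 > 0 and np.isfinite(aug)


def cubic_roots(
    p: NonlinearParams, factor: float = SEPARATION_FACTOR
) -> tuple[CubicCoeffs, RootSet]:
    """Approximate steady-state roots from the asymptotic cubic.

    ``x0 = -a0/a1`` is the root near zero (efficient-initiation branch);
    ``x1`` and ``x2`` come from the residual quadratic ``x**2+a2*x+a1``.
    ``x2`` is always negative.  The admissible root is selected by
    positivity of the back-substituted ``[eIF4F]_s`` and ``[40S]_s``; if
    neither root is admissible the exact solver is the fallback (a warning
    is recorded on the coefficient object).
    """
    coeffs = cubic_coeffs(p, factor)
    if coeffs.warnings:
        for msg in coeffs.warnings:
            warnings.warn(msg, stacklevel=2)
    a2, a1, a0 = coeffs.a2, coeffs.a1, coeffs.a0
    x0 = -a0 / a1 if a1 != 0 else np.nan
    disc = a2 * a2 - 4.0 * a1
    if disc >= 0:
        sq = np.sqrt(disc)
        x1 = 0.5 * (-a2 + sq)
        x2 = 0.5 * (-a2 - sq)
    else:  # outside the asymptotic validity domain
        x1 = x2 = np.nan
    admissible = None
    # prefer x1 (the O(1) root) when both survive back-substitution; the
    # near-zero root then yields a negative factor concentration anyway
    for name, value in (("x1", x1), ("x0", x0)):
        if np.isfinite(value) and _is_admissible(float(value), p):
            admissible = name
            break
    if admissible is None:
        coeffs.warnings.append(
            "no admissible cubic root; falling back to the exact solver"
        )
        warnings.warn(coeffs.warnings[-1], stacklevel=2)
    return coeffs, RootSet(x0=float(x0), x1=float(x1), x2=float(x2), admissible=admissible)


def steady_state_cubic(
    p: NonlinearParams, factor: float = SEPARATION_FACTOR
) -> SteadyStateResult:
    """Steady state from the admissible cubic root (exact solver fallback)."""
    coeffs, roots = cubic_roots(p, factor)
    if roots.admissible is None:
        result = steady_state_exact(p)
        result.warnings.extend(coeffs.warnings)
        return result
    x = float(roots.admissible_value)  # type: ignore[arg-type]
    conc = _back_substitute(x, p)
    fluxes = _nonlinear_fluxes(conc, p)
    return SteadyStateResult(
        x=x,
        concentrations=NonlinearState.from_array(conc),
        prsynth=float(p.k4 * (1.0 - x) * p.total_60S),
        regime=classify_regime(p),
        source=f"cubic_{roots.admissible}",
        beta=coeffs.beta,
        regime_boundary=is_regime_boundary(p),
        flux_residual=float(np.max(np.abs(np.diff(fluxes)))),
        warnings=list(coeffs.warnings),
    )


# ---------------------------------------------------------------------------
# closed-form observables
# ---------------------------------------------------------------------------


def steady_protein_rate(p: NonlinearParams) -> float:
    """Asymptotic steady protein synthesis rate ``k4*(1-x)*[60S]0``.

    Uses the admissible cubic root; to leading order this equals
    ``min(k2*[eIF4F]0, k4*[60S]0)`` — the factor-limited rate under
    inefficient initiation, the recycling-limited rate under efficient
    initiation.  Independent of k1 and k3 up to the root corrections.
    """
    return steady_state_cubic(p).prsynth


def limiting_rate(p: NonlinearParams) -> float:
    """Leading-order rate ``min(k2*[eIF4F]0, k4*[60S]0)`` without corrections."""
    return min(p.k2 * p.total_eIF4F, p.k4 * p.total_60S)


def polysome_proxy(p: NonlinearParams) -> float:
    """Bound-ribosome load at steady state, as a fraction of the 40S pool.

    ``([mRNA:40S]_s + [AUG]_s + [80S]_s) / [40S]0`` is the model's proxy
    for the polysome size (number of ribosomes engaged on the transcript,
    up to the constant mRNA concentration folded into the rate constants).
    It rises and falls together with the steady synthesis rate under
    inhibition of any step upstream of ribosome release.
    """
    ss = steady_state_exact(p)
    c = ss.concentrations
    return (c.c_mRNA40S + c.cAUG + c.c80S) / p.total_40S


def critical_thresholds(p: NonlinearParams) -> dict[str, float]:
    """Parameter values at which the initiation regime flips (beta = 1).

    ``k4_threshold = k2*[eIF4F]0/[60S]0``: lowering k4 through this value
    switches inefficient initiation to efficient, after which k4 controls
    the steady rate directly.  ``k2_threshold = k4*[60S]0/[eIF4F]0`` is the
    symmetric threshold for k2.
    """
    return {
        "k4_threshold": p.k2 * p.total_eIF4F / p.total_60S,
        "k2_threshold": p.k4 * p.total_60S / p.total_eIF4F,
    }
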