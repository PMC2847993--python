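"""Closed-form analysis of the linear three-step translation cycle.

With elongation much faster than both initiation steps (``k3 >> k1, k2``)
the cycle ``40S -> mRNA:40S -> AUG -> 40S`` relaxes on two time scales:
a fast elongation transient ``~1/k3`` during which ``[AUG]`` settles onto
its slaved value ``(k2/k3)[mRNA:40S]``, and a slow exchange between the
free subunit and the initiation complex.  Eliminating the fast variable
gives the approximate solution (for the all-free initial condition)::

    [mRNA:40S](t) = [40S]0 * k1/(k1+k2) * (1 - exp(-(k1+k2) t))
    [AUG](t)      = (k2/k3) [mRNA:40S](t) * (1 - exp(-k3 t))
    Prsynth(t)    = [40S]0 * k1 k2/(k1+k2) * (1 - exp(-(k1+k2) t))

from which the steady synthesis rate and its relaxation time are

    Prsynth_ss = [40S]0 * k1 k2 / (k1 + k2),      t_rel = 1/(k1 + k2).

``t_rel`` is governed by the *second slowest* rate constant of the cycle:
with ``k1 << k2`` (the A-cap situation) it is ``~1/k2``, so a microRNA
suppressing ``k2`` leaves the steady rate untouched while drastically
lengthening the relaxation — the dynamical signature that steady-state
measurements alone cannot see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_models import (
    DomainError,
    LinearParams,
    SEPARATION_FACTOR,
    Trajectory,
    _linear_fluxes,
)

__all__ = [
    "LinearAnalytics",
    "linear_analytic_trajectory",
    "linear_steady_and_relaxation",
    "linear_mirna_scan",
    "linear_setting_params",
    "DEFAULT_SCAN_FACTORS",
]

#: Spread of inhibition factors used by the default microRNA scans.
DEFAULT_SCAN_FACTORS = np.geomspace(1.0, 1e-4, 25)


@dataclass(frozen=True)
class LinearAnalytics:
    """Steady rate and time scales of the linear cycle approximation."""

    prsynth_ss: float
    t_rel: float
    slow_timescale: float
    fast_timescale: float
    separation: float
    separation_ok: bool


def _check_separation(p: LinearParams, factor: float) -> tuple[float, bool]:
    sep = p.elongation_separation()
    ok = sep >= factor
    if not ok:
        warnings.warn(
            f"elongation separation k3/max(k1,k2) = {sep:.3g} < {factor:g}; "
            "the two-time-scale approximation degrades",
            stacklevel=3,
        )
    return sep, ok


def linear_steady_and_relaxation(
    p: LinearParams, factor: float = SEPARATION_FACTOR
) -> LinearAnalytics:
    """Steady synthesis rate and relaxation time of the linear cycle."""
    sep, ok = _check_separation(p, factor)
    s = p.k1 + p.k2
    return LinearAnalytics(
        prsynth_ss=p.total_40S * p.k1 * p.k2 / s,
        t_rel=1.0 / s,
        slow_timescale=1.0 / s,
        fast_timescale=1.0 / p.k3,
        separation=sep,
        separation_ok=ok,
    )


def linear_analytic_trajectory(
    p: LinearParams, times: np.ndarray, factor: float = SEPARATION_FACTOR
) -> Trajectory:
    """Evaluate the closed-form approximate solution on a time grid.

    Starts exactly at the all-free initial condition and converges to the
    cycle steady state ``c ∝ (1/k1, 1/k2, 1/k3)`` as ``t -> inf`` (up to the
    neglected ``O(k/k3)`` corrections).  The free-subunit coordinate is
    closed through the conservation law, so the total 40S pool is exact at
    every sample.  If the time-scale separation is below ``factor`` the
    result carries a warning flag in ``meta`` rather than raising.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0 or np.any(np.diff(times) <= 0):
        raise DomainError("times must be a non-empty strictly increasing 1-D array")
    if times[0] < 0:
        raise DomainError("times must be nonnegative")
    sep, ok = _check_separation(p, factor)
    s = p.k1 + p.k2
    slow = 1.0 - np.exp(-s * times)
    mrna = p.total_40S * p.k1 / s * slow
    aug = (p.k2 / p.k3) * mrna * (1.0 - np.exp(-p.k3 * times))
    c40 = p.total_40S - mrna - aug
    states = np.column_stack([c40, mrna, aug])
    fluxes = np.array([_linear_fluxes(y, p) for y in states])
    return Trajectory(
        times=times,
        states=states,
        fluxes=fluxes,
        protein_rate=p.k3 * aug,
        species=("c40S", "c_mRNA40S", "cAUG"),
        params=p,
        meta={"analytic": True, "separation": sep, "separation_warning": not ok},
    )


# ---------------------------------------------------------------------------
# microRNA inhibition scans (wild-type and A-cap settings)
# ---------------------------------------------------------------------------

#: Base parameter sets for the two experimental situations.  "Wild-type"
#: cap: the two initiation steps are comparable (k1 = k2).  "A-cap": an
#: artificial cap with very weak recruitment capacity, k1 << k2; the ratio
#: 1/1000 keeps the cap-dependent step limiting across the whole
#: experimentally observable range of k2 inhibition, so the steady rate
#: stays pinned at ~k1*[40S]0 there.  Elongation is far off-scale so that
#: it remains the fastest step across the entire scan range.
_LINEAR_BASES = {
    "wt": LinearParams(k1=1.0, k2=1.0, k3=1e5),
    "acap": LinearParams(k1=0.001, k2=1.0, k3=1e5),
}


def linear_setting_params(setting: str) -> LinearParams:
    """Canonical base parameters for ``"wt"`` or ``"acap"`` scans."""
    try:
        return _LINEAR_BASES[setting]
    except KeyError:
        raise DomainError(
            f"unknown linear setting {setting!r}; expected one of "
            f"{sorted(_LINEAR_BASES)}"
        ) from None


def linear_mirna_scan(
    p: LinearParams,
    mechanism: str,
    inhibition_factors: "np.ndarray | None" = None,
    setting: str = "custom",
):
    """Scan a microRNA mechanism: multiply one rate constant by factors <= 1.

    ``mechanism`` is the inhibited constant (``"k1"``, ``"k2"`` or
    ``"k3"``).  Returns a :class:`ribodyn.signatures.ScanResult` with the
    analytic steady rate and relaxation time at every factor; factor 1
    reproduces the baseline exactly.
    """
    from .signatures import ScanResult

    if mechanism not in ("k1", "k2", "k3"):
        raise DomainError(f"unknown linear mechanism {mechanism!r}")
    factors = (
        DEFAULT_SCAN_FACTORS.copy()
        if inhibition_factors is None
        else np.asarray(inhibition_factors, dtype=float)
    )
    if np.any(factors <= 0) or np.any(factors > 1):
        raise DomainError("inhibition factors must lie in (0, 1]")
    rates = np.empty_like(factors)
    times = np.empty_like(factors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, f in enumerate(factors):
            q = p.replace(**{mechanism: getattr(p, mechanism) * f})
            an = linear_steady_and_relaxation(q)
            rates[i] = an.prsynth_ss
            times[i] = an.t_rel
    return ScanResult(
        mechanism=mechanism,
        setting=setting,
        factors=factors,
        steady_rates=rates,
        relaxation_times=times,
        meta={"model": "linear", "base": p},
    )
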