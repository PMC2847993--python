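"""Asymptotology of linear (monomolecular) reaction networks.

The toolkit behind the translation-model analysis: the exact
eigen-solution of first-order networks (used throughout as the numerical
oracle), relaxation and lumping of an irreversible chain, the limiting
step of an irreversible catalytic cycle, and the classic quasiequilibrium
(QE) vs quasi-steady-state (QSS) reduction of ``S + E <-> SE -> P + E``.

For a network ``dc/dt = K0 + K c`` with eigenpairs ``K r_i = lambda_i r_i``,
``l_i K = lambda_i l_i`` normalized to ``(l_i, r_j) = delta_ij``, the
solution is ``c(t) = c_s + sum_i r_i (l_i, c(0) - c_s) exp(lambda_i t)``.

For an irreversible cycle ``A_1 -> A_2 -> ... -> A_n -> A_1`` with rate
constants ``k_i`` and conserved total ``b``:

* the exact stationary rate is ``w = b / sum_i (1/k_i)`` and the exact
  stationary concentrations are ``c_i = w / k_i``;
* if one constant ``k_min`` is well separated below the others, the cycle
  has a *limiting step*: ``w ≈ k_min * b``, in zeroth order all mass sits
  at the reactant of the slow step, the nonzero eigenvalues approach
  ``-k_i`` over the non-limiting steps, and the relaxation time is the
  inverse of the **second smallest** rate constant;
* without separation (e.g. all ``k_i`` equal) the spectrum is complex and
  the system shows damped oscillations — the limiting-step picture is
  refused rather than degraded silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .core_models import DomainError, SEPARATION_FACTOR

__all__ = [
    "AmbiguityError",
    "MonomolecularNetwork",
    "EigenSolution",
    "CycleModel",
    "ChainAnalysis",
    "CycleAnalysis",
    "QeQssDemo",
    "solve_monomolecular",
    "chain_analysis",
    "cycle_analysis",
    "qe_qss_demo",
    "chain_network",
    "cycle_network",
]


class AmbiguityError(ValueError):
    """No clearly separated minimal rate constant: near-ties listed."""


# ---------------------------------------------------------------------------
# monomolecular networks and their exact solution
# ---------------------------------------------------------------------------


@dataclass
class MonomolecularNetwork:
    """First-order reaction network ``dc/dt = K0 + K c``.

    ``rates[(i, j)] = k`` encodes ``A_i -> A_j`` (0-based).  Production
    from and degradation to the pseudo-species sink are given separately.
    """

    n: int
    rates: dict[tuple[int, int], float] = field(default_factory=dict)
    production: "np.ndarray | None" = None  # K0, shape (n,)
    degradation: "np.ndarray | None" = None  # first-order loss to the sink
    init: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise DomainError("network must have at least one species")
        for (i, j), k in self.rates.items():
            if not (0 <= i < self.n and 0 <= j < self.n) or i == j:
                raise DomainError(f"invalid edge {(i, j)}")
            if k < 0 or not np.isfinite(k):
                raise DomainError(f"edge {(i, j)} has invalid rate {k!r}")

    def matrix(self) -> np.ndarray:
        K = np.zeros((self.n, self.n))
        for (i, j), k in self.rates.items():
            K[j, i] += k
            K[i, i] -= k
        if self.degradation is not None:
            K[np.diag_indices(self.n)] -= np.asarray(self.degradation, float)
        return K

    def k0(self) -> np.ndarray:
        if self.production is None:
            return np.zeros(self.n)
        return np.asarray(self.production, float)

    def initial(self) -> np.ndarray:
        if self.init is None:
            return np.zeros(self.n)
        return np.asarray(self.init, float)


def chain_network(
    ks: Sequence[float], init: "np.ndarray | None" = None
) -> MonomolecularNetwork:
    """Irreversible chain ``A_1 -> A_2 -> ... -> A_n`` (n = len(ks)+1)."""
    ks = list(ks)
    return MonomolecularNetwork(
        n=len(ks) + 1,
        rates={(i, i + 1): float(k) for i, k in enumerate(ks)},
        init=init,
    )


def cycle_network(
    ks: Sequence[float], init: "np.ndarray | None" = None
) -> MonomolecularNetwork:
    """Irreversible cycle ``A_1 -> ... -> A_n -> A_1`` (n = len(ks))."""
    ks = list(ks)
    n = len(ks)
    rates = {(i, (i + 1) % n): float(k) for i, k in enumerate(ks)}
    return MonomolecularNetwork(n=n, rates=rates, init=init)


@dataclass
class EigenSolution:
    """Dense eigen-solution of ``dc/dt = K0 + K c``."""

    eigenvalues: np.ndarray
    right: np.ndarray  # columns r_i
    left: np.ndarray  # rows l_i, normalized so left @ right = I
    steady_state: np.ndarray
    K: np.ndarray
    K0: np.ndarray
    defective: bool = False

    def evaluate(self, times: np.ndarray, c0: np.ndarray) -> np.ndarray:
        """Concentrations on a grid, shape (len(times), n)."""
        times = np.atleast_1d(np.asarray(times, float))
        c0 = np.asarray(c0, float)
        if self.defective:
            return np.array(
                [self.steady_state + expm(self.K * t) @ (c0 - self.steady_state)
                 for t in times]
            )
        amp = self.left @ (c0 - self.steady_state)  # (l_i, c0 - c_s)
        phases = np.exp(np.outer(times, self.eigenvalues))  # (t, i)
        out = self.steady_state + (phases * amp) @ self.right.T
        return np.real_if_close(out, tol=1e6).real

    def slow_eigenvalue(self) -> complex:
        """Nonzero eigenvalue of smallest magnitude (sets the relaxation time)."""
        lam = self.eigenvalues
        nz = lam[np.abs(lam) > 1e-12 * max(np.abs(lam).max(), 1.0)]
        if len(nz) == 0:
            raise ValueError("no nonzero eigenvalues")
        return nz[np.argmin(np.abs(nz))]


def solve_monomolecular(net: MonomolecularNetwork) -> EigenSolution:
    """Exact eigen-solution of a monomolecular network.

    A defective kinetic matrix (repeated eigenvalue without a full
    eigenbasis) triggers a warning and a fallback: :meth:`EigenSolution.
    evaluate` then propagates with the matrix exponential instead of the
    spectral formula.  Rates are never perturbed to force diagonalizability.
    """
    K = net.matrix()
    K0 = net.k0()
    lam, R = np.linalg.eig(K)
    scale = max(np.abs(lam).max(), 1.0)
    defective = np.linalg.matrix_rank(R, tol=1e-10) < net.n
    if defective:
        warnings.warn(
            "kinetic matrix is defective; falling back to matrix-exponential "
            "propagation",
            stacklevel=2,
        )
        L = np.full_like(R, np.nan)
    else:
        L = np.linalg.inv(R)  # rows are left eigenvectors, (l_i, r_j) = delta_ij

    zero_mask = np.abs(lam) <= 1e-12 * scale
    if np.any(np.abs(K0) > 0):
        if np.any(zero_mask):
            raise DomainError(
                "network with production has a singular kinetic matrix; "
                "no finite steady state"
            )
        c_s = np.linalg.solve(K, -K0)
    elif np.any(zero_mask) and not defective:
        c0 = net.initial()
        c_s = np.zeros(net.n, dtype=complex)
        for i in np.where(zero_mask)[0]:
            c_s += R[:, i] * (L[i] @ c0)
        c_s = np.real_if_close(c_s, tol=1e6).real
    else:
        c_s = np.zeros(net.n)
    return EigenSolution(
        eigenvalues=lam, right=R, left=L, steady_state=c_s, K=K, K0=K0,
        defective=defective,
    )


# ---------------------------------------------------------------------------
# irreversible chain: relaxation and lumping
# ---------------------------------------------------------------------------


@dataclass
class ChainAnalysis:
    """Limiting-step picture of an irreversible chain ``A_1 -> ... -> A_n``."""

    tau: float
    limiting_index: int  # 0-based position q of the slowest step
    k_limiting: float
    lumped_left_vector: np.ndarray  # ones on species 1..q
    slow_right_vector: np.ndarray  # mass moves A_q -> A_n
    steady_state: np.ndarray  # everything at the chain end


def _separated_min(ks: np.ndarray, factor: float, what: str) -> int:
    order = np.argsort(ks)
    if len(ks) > 1 and ks[order[1]] < factor * ks[order[0]]:
        ties = [
            (int(i), float(ks[i]))
            for i in order
            if ks[i] < factor * ks[order[0]]
        ]
        raise AmbiguityError(
            f"no separated minimal constant in {what}: near-ties {ties} "
            f"(separation factor {factor:g})"
        )
    return int(order[0])


def chain_analysis(
    ks: Sequence[float], total: float = 1.0, factor: float = SEPARATION_FACTOR
) -> ChainAnalysis:
    """Relaxation time, lumping vector and steady state of a chain.

    The smallest constant ``k_q`` gives the smallest positive eigenvalue:
    ``tau = 1/k_q``.  On time scales beyond ``1/k_q`` the species
    ``A_1..A_q`` act as one lumped pool (left vector with ones on positions
    1..q) decaying into ``A_n``; the steady state has the whole total at
    the chain end.
    """
    ks = np.asarray(list(ks), dtype=float)
    if np.any(ks <= 0):
        raise DomainError("chain rate constants must be positive")
    n = len(ks) + 1
    q = _separated_min(ks, factor, "chain")
    left = np.zeros(n)
    left[: q + 1] = 1.0
    right = np.zeros(n)
    right[q] = 1.0
    right[-1] = -1.0
    steady = np.zeros(n)
    steady[-1] = total
    return ChainAnalysis(
        tau=1.0 / ks[q],
        limiting_index=q,
        k_limiting=float(ks[q]),
        lumped_left_vector=left,
        slow_right_vector=right,
        steady_state=steady,
    )


# ---------------------------------------------------------------------------
# irreversible catalytic cycle with limiting step
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleModel:
    """Irreversible cycle with first-order constants and conserved total."""

    ks: tuple[float, ...]
    b: float = 1.0

    def __post_init__(self) -> None:
        if len(self.ks) < 2:
            raise DomainError("a cycle needs at least two steps")
        if any(k <= 0 for k in self.ks) or self.b <= 0:
            raise DomainError("cycle constants and total must be positive")


@dataclass
class CycleAnalysis:
    """Exact and limiting-step quantities of an irreversible cycle."""

    w_exact: float
    c_exact: np.ndarray
    eigenvalues_exact: np.ndarray
    oscillatory: bool
    limiting_available: bool = False
    limiting_reason: str | None = None
    w_limiting: float | None = None
    c_zero_order: "np.ndarray | None" = None
    eigen_approx: "np.ndarray | None" = None
    tau: float | None = None
    limiting_index: int | None = None


def cycle_analysis(
    cyc: CycleModel, factor: float = SEPARATION_FACTOR
) -> CycleAnalysis:
    """Stationary rate, eigenvalues and limiting-step approximation.

    The exact outputs (harmonic-sum stationary rate, stationary
    concentrations ``c_i = w/k_i``, dense spectrum) are always produced.
    The limiting-step outputs require the smallest constant to be
    separated by at least ``factor``; otherwise they are flagged
    unavailable with a reason (damped oscillations are possible there).
    """
    ks = np.asarray(cyc.ks, dtype=float)
    w = cyc.b / np.sum(1.0 / ks)
    c_exact = w / ks
    lam = np.linalg.eigvals(cycle_network(ks).matrix())
    oscillatory = bool(np.any(np.abs(lam.imag) > 1e-9 * max(np.abs(lam).max(), 1.0)))
    out = CycleAnalysis(
        w_exact=float(w),
        c_exact=c_exact,
        eigenvalues_exact=lam,
        oscillatory=oscillatory,
    )
    try:
        q = _separated_min(ks, factor, "cycle")
    except AmbiguityError as exc:
        out.limiting_available = False
        out.limiting_reason = str(exc)
        return out
    out.limiting_available = True
    out.limiting_index = q
    out.w_limiting = float(ks[q] * cyc.b)
    zero = np.zeros(len(ks))
    zero[q] = cyc.b  # all mass at the reactant of the "narrow place"
    out.c_zero_order = zero
    out.eigen_approx = np.array([-k for i, k in enumerate(ks) if i != q])
    rest = np.delete(ks, q)
    out.tau = float(1.0 / rest.min())  # second slowest constant overall
    return out


# ---------------------------------------------------------------------------
# QE vs QSS on S + E <-> SE -> P + E
# ---------------------------------------------------------------------------


@dataclass
class QeQssDemo:
    """Reductions of the catalytic mechanism ``S + E <-> SE -> P + E``.

    ``qss_rate(cS)`` is the Michaelis-Menten product-formation rate
    ``k2 bE cS/(cS + K_M)`` with ``K_M = (kappa_minus + k2)/kappa_plus``
    (valid for a scarce catalyst, ``bE << bS``).  ``qe_cse(Cs)`` solves the
    quadratic quasiequilibrium manifold for the complex given the slow
    variable ``Cs = cS + cSE`` (valid for a fast binding equilibrium).
    """

    bS: float
    bE: float
    kappa_plus: float
    kappa_minus: float
    k2: float
    qss_warning: bool = False

    @property
    def K_M(self) -> float:
        return (self.kappa_minus + self.k2) / self.kappa_plus

    def qss_cse(self, cS: "float | np.ndarray") -> "float | np.ndarray":
        cS = np.asarray(cS, float)
        return self.bE * cS / (cS + self.K_M)

    def qss_rate(self, cS: "float | np.ndarray") -> "float | np.ndarray":
        return self.k2 * self.qss_cse(cS)

    def qe_cse(self, Cs: "float | np.ndarray") -> "float | np.ndarray":
        """Complex concentration on the quasiequilibrium manifold.

        Smaller root of ``kp (Cs - cSE)(bE - cSE) = km cSE`` (the physical
        branch, ``cSE <= min(Cs, bE)``).
        """
        Cs = np.asarray(Cs, float)
        kp, km = self.kappa_plus, self.kappa_minus
        a = kp
        bq = -(kp * (Cs + self.bE) + km)
        c = kp * Cs * self.bE
        disc = np.sqrt(bq * bq - 4.0 * a * c)
        return (-bq - disc) / (2.0 * a)

    def qe_reduced_rhs(self, Cs: float) -> float:
        return -self.k2 * float(self.qe_cse(Cs))

    def full_rhs(self, y: np.ndarray) -> np.ndarray:
        cS, cE, cSE, cP = y
        v_bind = self.kappa_plus * cS * cE
        v_unbind = self.kappa_minus * cSE
        v_cat = self.k2 * cSE
        return np.array(
            [
                v_unbind - v_bind,
                v_unbind + v_cat - v_bind,
                v_bind - v_unbind - v_cat,
                v_cat,
            ]
        )

    def integrate_full(
        self, t_end: float, n_points: int = 300
    ) -> tuple[np.ndarray, np.ndarray]:
        """Integrate the full 3-reaction system from (bS, bE, 0, 0)."""
        times = np.linspace(0.0, t_end, n_points)
        sol = solve_ivp(
            lambda t, y: self.full_rhs(y),
            (0.0, t_end),
            np.array([self.bS, self.bE, 0.0, 0.0]),
            t_eval=times,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        return sol.t, sol.y.T

    def integrate_qss(
        self, t_end: float, n_points: int = 300
    ) -> tuple[np.ndarray, np.ndarray]:
        """Integrate the reduced substrate equation; returns (t, [cS, cP])."""
        times = np.linspace(0.0, t_end, n_points)
        sol = solve_ivp(
            lambda t, y: [-self.qss_rate(y[0])],
            (0.0, t_end),
            [self.bS],
            t_eval=times,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        cS = sol.y[0]
        return sol.t, np.column_stack([cS, self.bS - cS])


def qe_qss_demo(
    bS: float, bE: float, kappa_plus: float, kappa_minus: float, k2: float
) -> QeQssDemo:
    """Build the QE/QSS demonstration; warns when ``bE`` is not scarce."""
    _vals = dict(bS=bS, bE=bE, kappa_plus=kappa_plus, kappa_minus=kappa_minus, k2=k2)
    for name, v in _vals.items():
        if v <= 0:
            raise DomainError(f"{name} must be positive")
    warn = bE * SEPARATION_FACTOR > bS
    if warn:
        warnings.warn(
            f"QSS validity requires a scarce catalyst (bE << bS); got "
            f"bE/bS = {bE / bS:.3g}",
            stacklevel=2,
        )
    return QeQssDemo(
        bS=bS, bE=bE, kappa_plus=kappa_plus, kappa_minus=kappa_minus, k2=k2,
        qss_warning=warn,
    )
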