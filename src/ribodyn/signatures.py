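"""Kinetic signatures of microRNA mechanisms.

A microRNA acting on one translation step is modeled by scaling the
corresponding rate constant by an inhibition factor in (0, 1].  Its
*kinetic signature* is the pair of qualitative responses of

* the steady-state protein synthesis rate, and
* the relaxation time (latest time at which any chemical species still
  differs from its steady value by 10%),

across experimental settings (wild-type vs A-cap transcript, efficient vs
inefficient initiation).  The signature discriminates mechanisms that are
indistinguishable from the steady rate alone: an inhibited step that is
not rate-limiting leaves the steady rate untouched but can lengthen the
relaxation dramatically.

Labels are coarse, order-of-magnitude judgements.  They are evaluated on
an *observable window* of moderate inhibition (default factors >= 0.05,
i.e. up to 20-fold suppression — the range an experiment can realistically
titrate), while curve-shape features (threshold location, interior
extrema) use the full scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core_models import (
    DomainError,
    IntegrationError,
    NonlinearParams,
    Trajectory,
    integrate,
)
from .nonlinear_steady import SteadyStateResult, steady_state_exact

__all__ = [
    "ScanResult",
    "SignatureLabel",
    "SignatureTable",
    "Thresholds",
    "NotConvergedError",
    "VocabularyError",
    "RATE_LABELS",
    "TIME_LABELS",
    "NONLINEAR_SETTINGS",
    "relaxation_time",
    "measure_relaxation_time",
    "inhibition_scan",
    "classify_signature",
    "signature_table",
    "linear_signature_table",
    "mechanism_lookup",
    "REFERENCE_NONLINEAR_TABLE",
    "REFERENCE_LINEAR_TABLE",
]

logger = logging.getLogger(__name__)

RATE_LABELS = frozenset(
    {
        "no_change",
        "decreases",
        "decreases_slightly",
        "decreases_after_threshold",
        "slightly_decreases_after_strong_inhibition",
    }
)
TIME_LABELS = frozenset(
    {
        "no_change",
        "increases",
        "increases_slightly",
        "increases_drastically",
        "goes_up_and_down",
    }
)


class NotConvergedError(RuntimeError):
    """Trajectory never settles into the steady-state band."""


class VocabularyError(ValueError):
    """A label outside the closed signature vocabularies."""


# ---------------------------------------------------------------------------
# canonical experimental settings (non-linear model)
# ---------------------------------------------------------------------------

_WT_INEFFICIENT = NonlinearParams(k1=2.0, k2=2.0, k3=5.0, k4=1.0)
_WT_EFFICIENT = NonlinearParams(k1=2.0, k2=3.0, k3=50.0, k4=0.1)

#: The four experimental settings of the non-linear scans: normal cap vs
#: A-cap transcript (the latter modeled by k1 = 0.01, a cap with very weak
#: recruitment capacity), crossed with inefficient (beta < 1) vs efficient
#: (beta > 1) initiation.
NONLINEAR_SETTINGS: dict[str, NonlinearParams] = {
    "wt_inefficient": _WT_INEFFICIENT,
    "wt_efficient": _WT_EFFICIENT,
    "acap_inefficient": _WT_INEFFICIENT.replace(k1=0.01),
    "acap_efficient": _WT_EFFICIENT.replace(k1=0.01),
}

_NONLINEAR_MECHANISMS = ("k1", "k2", "k3", "k4")


# ---------------------------------------------------------------------------
# relaxation time
# ---------------------------------------------------------------------------


def relaxation_time(
    traj: Trajectory,
    ss: "SteadyStateResult | np.ndarray",
    band: float = 0.10,
    abs_floor: "float | None" = None,
) -> float:
    """Latest time at which any species leaves the +-band around steady state.

    Species whose steady value is below ``abs_floor`` (default ``1e-6`` of
    the largest conserved pool) are compared on an absolute scale to avoid
    relative blow-ups near zero.  The crossing is interpolated between
    grid samples.  Raises :class:`NotConvergedError` if any species is
    still outside the band at the final sample.
    """
    target = ss.state_array() if isinstance(ss, SteadyStateResult) else np.asarray(ss)
    p = traj.params
    totals = (
        max(p.totals()) if isinstance(p, NonlinearParams) else p.total_40S
    )
    if abs_floor is None:
        abs_floor = 1e-6 * totals
    tol = band * np.maximum(np.abs(target), abs_floor)
    dev = np.abs(traj.states - target)  # (t, species)
    outside = dev > tol
    bad = outside[-1]
    if bad.any():
        names = [traj.species[j] for j in np.where(bad)[0]]
        raise NotConvergedError(
            f"species {names} still outside the {band:.0%} band at "
            f"t={traj.times[-1]:g}"
        )
    any_outside = outside.any(axis=1)
    if not any_outside.any():
        return 0.0
    i = int(np.where(any_outside)[0][-1])  # last sample outside
    # interpolate the exit of the worst offender between samples i and i+1
    j = int(np.argmax(dev[i] / tol))
    d0, d1 = dev[i, j] - tol[j], dev[i + 1, j] - tol[j]
    if d0 <= 0 or d0 == d1:
        return float(traj.times[i])
    frac = min(max(d0 / (d0 - d1), 0.0), 1.0)
    return float(traj.times[i] + frac * (traj.times[i + 1] - traj.times[i]))


def measure_relaxation_time(
    p: NonlinearParams,
    band: float = 0.10,
    init: "np.ndarray | None" = None,
    n_points: int = 700,
    max_extensions: int = 6,
) -> tuple[float, Trajectory]:
    """Relaxation time from a fresh integration, auto-extending the horizon.

    The horizon starts at ``50 / slowest first-order scale`` and is grown
    tenfold until the trajectory ends inside the band and the measured
    time is well clear of the horizon.
    """
    ss = steady_state_exact(p)
    slow = min(p.k4, p.k2, p.k1 * p.total_eIF4F)
    t_end = 50.0 / slow
    for _ in range(max_extensions):
        traj = integrate(p, init=init, t_end=t_end, n_points=n_points)
        try:
            t_rel = relaxation_time(traj, ss, band=band)
        except NotConvergedError:
            t_end *= 10.0
            continue
        if t_rel < 0.5 * t_end:
            return t_rel, traj
        t_end *= 10.0
    raise NotConvergedError(
        f"relaxation did not converge within t_end={t_end:g} (beta={ss.beta:g})"
    )


# ---------------------------------------------------------------------------
# inhibition scans
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Steady rates and relaxation times along an inhibition scan."""

    mechanism: str
    setting: str
    factors: np.ndarray  # descending from 1
    steady_rates: np.ndarray
    relaxation_times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, float)
        self.steady_rates = np.asarray(self.steady_rates, float)
        self.relaxation_times = np.asarray(self.relaxation_times, float)
        if not (
            len(self.factors)
            == len(self.steady_rates)
            == len(self.relaxation_times)
        ):
            raise ValueError("scan arrays must have equal length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mechanism": self.mechanism,
                "setting": self.setting,
                "factor": self.factors,
                "prsynth_ss": self.steady_rates,
                "t_rel": self.relaxation_times,
            }
        )

    def decades(self) -> float:
        return float(np.log10(self.factors.max() / self.factors.min()))


#: Default inhibition grid: three decades, factor 1 included exactly.
DEFAULT_FACTORS = np.geomspace(1.0, 1e-3, 25)


def _perturbed(p: NonlinearParams, mechanism: str, f: float) -> NonlinearParams:
    if mechanism in _NONLINEAR_MECHANISMS:
        return p.replace(**{mechanism: getattr(p, mechanism) * f})
    if mechanism == "eIF4F_total":
        return p.replace(total_eIF4F=p.total_eIF4F * f)
    raise DomainError(f"unknown mechanism {mechanism!r}")


def inhibition_scan(
    p_base: NonlinearParams,
    mechanism: str,
    setting: str = "custom",
    factors: "np.ndarray | None" = None,
    band: float = 0.10,
) -> ScanResult:
    """Scan one mechanism: steady rate and relaxation time per factor.

    The steady rate comes from the exact flux-balance solver and the
    relaxation time from a fresh integration from the all-free initial
    condition.  Solver failures at individual factors are logged and
    recorded as NaN rather than aborting the scan.
    """
    factors = (
        DEFAULT_FACTORS.copy() if factors is None else np.asarray(factors, float)
    )
    if np.any(factors <= 0) or np.any(factors > 1):
        raise DomainError("inhibition factors must lie in (0, 1]")
    rates = np.full(len(factors), np.nan)
    times = np.full(len(factors), np.nan)
    for i, f in enumerate(factors):
        q = _perturbed(p_base, mechanism, float(f))
        try:
            if f == 1.0:
                ss = steady_state_exact(p_base)
                rates[i] = ss.prsynth
                times[i], _ = measure_relaxation_time(p_base, band=band)
            else:
                rates[i] = steady_state_exact(q).prsynth
                times[i], _ = measure_relaxation_time(q, band=band)
        except (IntegrationError, NotConvergedError, RuntimeError) as exc:
            logger.warning(
                "scan %s/%s failed at factor %.3g: %s", setting, mechanism, f, exc
            )
    return ScanResult(
        mechanism=mechanism,
        setting=setting,
        factors=factors,
        steady_rates=rates,
        relaxation_times=times,
        meta={"base": p_base, "band": band},
    )


# ---------------------------------------------------------------------------
# qualitative classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureLabel:
    """Qualitative (rate, relaxation-time) response to an inhibition scan."""

    rate_label: str
    time_label: str
    confident: bool = True

    def __post_init__(self) -> None:
        if self.rate_label not in RATE_LABELS:
            raise VocabularyError(f"unknown rate label {self.rate_label!r}")
        if self.time_label not in TIME_LABELS:
            raise VocabularyError(f"unknown time label {self.time_label!r}")


@dataclass(frozen=True)
class Thresholds:
    """Tunable constants of the qualitative classifier (frozen defaults).

    Magnitude judgements use fold changes inside the observable window
    (factors >= ``window``); curve-shape features (knee position, interior
    extrema with their subsequent decline) may use the full scan.

    ``rate_no_change`` / ``time_no_change``: fold changes below these are
    invisible.  ``strong``: folds at least this are a clear effect; below,
    a slight one.  ``drastic``: relaxation-time growth at least this is
    drastic.  ``flat_decades``: a rate decline is threshold-like when the
    curve first leaves the no-change band after at least this many decades
    of inhibition; ``strong_inhibition_factor`` splits such declines into
    "after threshold" (knee at milder inhibition) vs "after strong
    inhibition" (knee below this factor).  A relaxation-time curve "goes
    up and down" when an interior window maximum at least ``updown_rise``
    above baseline is followed by a decline of at least ``updown_dip``.
    ``full_increase``: a sub-``strong`` rise still rising at the window
    edge counts as a clear increase when the full-scan fold reaches this.
    ``panel_fraction``: the time no-change band widens to this fraction of
    the largest relaxation response among mechanisms probed in the same
    setting (a small shift is invisible next to a 30-fold one).
    """

    rate_no_change: float = 1.10
    time_no_change: float = 1.25
    strong: float = 2.0
    drastic: float = 10.0
    flat_decades: float = 0.22
    strong_inhibition_factor: float = 0.30
    updown_rise: float = 1.25
    updown_dip: float = 0.08
    full_increase: float = 2.2
    panel_fraction: float = 0.25
    window: float = 0.05


def _window_mask(factors: np.ndarray, window: float) -> np.ndarray:
    return factors >= window * (1.0 - 1e-9)


def _first_departure(
    factors: np.ndarray, y: np.ndarray, level: float
) -> "float | None":
    """Largest factor at which ``y`` first drops below ``level`` (log interp)."""
    below = y < level
    if not below.any():
        return None
    i = int(np.argmax(below))  # factors are descending
    if i == 0:
        return float(factors[0])
    lf0, lf1 = np.log(factors[i - 1]), np.log(factors[i])
    ly0, ly1 = np.log(y[i - 1]), np.log(y[i])
    lf = lf0 + (np.log(level) - ly0) * (lf1 - lf0) / (ly1 - ly0)
    return float(np.exp(lf))


def _classify_rate(factors: np.ndarray, rates: np.ndarray, th: Thresholds) -> str:
    y = rates / rates[0]
    m = _window_mask(factors, th.window)
    fold_down = 1.0 / y[m].min()
    if fold_down < th.rate_no_change and y[m].max() < th.rate_no_change:
        return "no_change"
    if fold_down < th.strong:
        return "decreases_slightly"
    knee = _first_departure(factors[m], y[m], 1.0 / th.rate_no_change)
    flat_run = -np.log10(knee) if knee else 0.0
    if flat_run >= th.flat_decades:
        if knee >= th.strong_inhibition_factor:
            return "decreases_after_threshold"
        return "slightly_decreases_after_strong_inhibition"
    return "decreases"


def _classify_time(
    factors: np.ndarray,
    times: np.ndarray,
    th: Thresholds,
    time_saliency: "float | None",
) -> tuple[str, bool]:
    z = times / times[0]
    m = _window_mask(factors, th.window)
    zw = z[m]
    # rise and fall: interior window maximum with a genuine later decline
    peak = int(np.argmax(zw))
    if 0 < peak < len(zw) - 1 and zw[peak] >= th.updown_rise:
        after = z[peak:]  # window entries lead the (descending) factor grid
        if after.min() <= zw[peak] * (1.0 - th.updown_dip):
            return "goes_up_and_down", True
    fold_up = float(zw.max())
    fold_down = 1.0 / float(zw.min())
    band = th.time_no_change
    if time_saliency is not None:
        band = max(band, th.panel_fraction * time_saliency)
    if fold_up < band and fold_down < th.time_no_change:
        return "no_change", True
    if fold_up >= th.drastic:
        return "increases_drastically", True
    if fold_up >= th.strong:
        return "increases", True
    if fold_up >= th.time_no_change:
        still_rising = np.argmax(zw) == len(zw) - 1
        if still_rising and z.max() >= th.full_increase:
            return "increases", True
        return "increases_slightly", True
    # monotone decrease: outside the published shape vocabulary
    return "no_change", False


def classify_signature(
    scan: ScanResult,
    thresholds: "Thresholds | None" = None,
    time_saliency: "float | None" = None,
) -> SignatureLabel:
    """Map scan curves to the closed qualitative vocabularies.

    Deterministic decision rules on fold changes within the observable
    window plus curve-shape features (knee location for threshold-type
    declines; interior extrema with a subsequent decline for rise-and-fall
    relaxation times).  ``time_saliency`` is the largest relaxation-time
    window fold among sibling mechanisms in the same setting; when given,
    it widens the time no-change band so that judgements are relative to
    the setting's dominant response.  An unrecognizable shape is labeled
    with ``confident=False`` rather than guessed silently.
    """
    th = thresholds or Thresholds()
    ok = np.isfinite(scan.steady_rates) & np.isfinite(scan.relaxation_times)
    if ok.sum() < 5 or not ok[0]:
        raise DomainError("scan has too few valid points to classify")
    factors = scan.factors[ok]
    if np.log10(factors.max() / factors.min()) < 3.0 - 1e-9:
        warnings.warn(
            "scan covers fewer than 3 decades of inhibition; labels may be "
            "unreliable",
            stacklevel=2,
        )
    rate_label = _classify_rate(factors, scan.steady_rates[ok], th)
    time_label, confident = _classify_time(
        factors, scan.relaxation_times[ok], th, time_saliency
    )
    return SignatureLabel(rate_label, time_label, confident)


def time_window_fold(scan: ScanResult, window: "float | None" = None) -> float:
    """Largest relaxation-time rise (fold over baseline) inside the window."""
    th_window = Thresholds().window if window is None else window
    ok = np.isfinite(scan.relaxation_times)
    z = scan.relaxation_times[ok] / scan.relaxation_times[ok][0]
    m = _window_mask(scan.factors[ok], th_window)
    return float(z[m].max())


# ---------------------------------------------------------------------------
# signature tables
# ---------------------------------------------------------------------------


@dataclass
class SignatureTable:
    """Mapping (setting, mechanism) -> qualitative signature."""

    cells: dict[tuple[str, str], SignatureLabel]

    def __getitem__(self, key: tuple[str, str]) -> SignatureLabel:
        return self.cells[key]

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "setting": s,
                "mechanism": m,
                "rate": lab.rate_label,
                "time": lab.time_label,
                "confident": lab.confident,
            }
            for (s, m), lab in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            f"{s}/{m}": {"rate": lab.rate_label, "time": lab.time_label}
            for (s, m), lab in sorted(self.cells.items())
        }


def signature_table(
    settings: "dict[str, NonlinearParams] | None" = None,
    mechanisms: tuple[str, ...] = _NONLINEAR_MECHANISMS,
    factors: "np.ndarray | None" = None,
    thresholds: "Thresholds | None" = None,
) -> SignatureTable:
    """Full signature table of the non-linear model (4 settings x 4 steps)."""
    settings = NONLINEAR_SETTINGS if settings is None else settings
    cells = {}
    for sname, p in settings.items():
        scans = {
            mech: inhibition_scan(p, mech, setting=sname, factors=factors)
            for mech in mechanisms
        }
        saliency = max(time_window_fold(s) for s in scans.values())
        for mech, scan in scans.items():
            cells[(sname, mech)] = classify_signature(
                scan, thresholds, time_saliency=saliency
            )
    return SignatureTable(cells)


def linear_signature_table(
    factors: "np.ndarray | None" = None,
    thresholds: "Thresholds | None" = None,
) -> SignatureTable:
    """Signature table of the linear model (wt and A-cap x k1..k3)."""
    from .linear_translation import linear_mirna_scan, linear_setting_params

    cells = {}
    for sname in ("wt", "acap"):
        p = linear_setting_params(sname)
        scans = {
            mech: linear_mirna_scan(p, mech, factors, setting=sname)
            for mech in ("k1", "k2", "k3")
        }
        saliency = max(time_window_fold(s) for s in scans.values())
        for mech, scan in scans.items():
            cells[(sname, mech)] = classify_signature(
                scan, thresholds, time_saliency=saliency
            )
    return SignatureTable(cells)


# ---------------------------------------------------------------------------
# reference predictions and inverse lookup
# ---------------------------------------------------------------------------

#: Reference qualitative predictions of the linear model: how the steady
#: rate and relaxation time respond when a microRNA suppresses each step,
#: for a wild-type cap (k1 = k2) and an A-cap transcript (k1 << k2).
REFERENCE_LINEAR_TABLE: dict[tuple[str, str], SignatureLabel] = {
    ("wt", "k1"): SignatureLabel("decreases", "increases_slightly"),
    ("wt", "k2"): SignatureLabel("decreases", "increases_slightly"),
    ("wt", "k3"): SignatureLabel("no_change", "no_change"),
    ("acap", "k1"): SignatureLabel("decreases", "no_change"),
    ("acap", "k2"): SignatureLabel("no_change", "increases_drastically"),
    ("acap", "k3"): SignatureLabel("no_change", "no_change"),
}

#: Reference qualitative predictions of the non-linear model across the
#: four experimental settings.
REFERENCE_NONLINEAR_TABLE: dict[tuple[str, str], SignatureLabel] = {
    ("wt_inefficient", "k1"): SignatureLabel("decreases_slightly", "no_change"),
    ("wt_inefficient", "k2"): SignatureLabel("decreases", "no_change"),
    ("wt_inefficient", "k3"): SignatureLabel("no_change", "no_change"),
    ("wt_inefficient", "k4"): SignatureLabel(
        "decreases_after_threshold", "goes_up_and_down"
    ),
    ("wt_efficient", "k1"): SignatureLabel("no_change", "no_change"),
    ("wt_efficient", "k2"): SignatureLabel(
        "slightly_decreases_after_strong_inhibition", "goes_up_and_down"
    ),
    ("wt_efficient", "k3"): SignatureLabel("no_change", "no_change"),
    ("wt_efficient", "k4"): SignatureLabel("decreases", "no_change"),
    ("acap_inefficient", "k1"): SignatureLabel("decreases", "no_change"),
    ("acap_inefficient", "k2"): SignatureLabel("decreases", "no_change"),
    ("acap_inefficient", "k3"): SignatureLabel("no_change", "no_change"),
    ("acap_inefficient", "k4"): SignatureLabel(
        "slightly_decreases_after_strong_inhibition", "goes_up_and_down"
    ),
    ("acap_efficient", "k1"): SignatureLabel(
        "decreases_after_threshold", "goes_up_and_down"
    ),
    ("acap_efficient", "k2"): SignatureLabel(
        "slightly_decreases_after_strong_inhibition", "goes_up_and_down"
    ),
    ("acap_efficient", "k3"): SignatureLabel("no_change", "no_change"),
    ("acap_efficient", "k4"): SignatureLabel("decreases", "increases"),
}


def mechanism_lookup(
    observed: dict[str, "SignatureLabel | tuple[str | None, str | None]"],
    model: str = "nonlinear",
    include_no_effect: bool = True,
) -> set[str]:
    """Mechanisms consistent with observed signatures (inverse table use).

    ``observed`` maps setting names to observed labels; either label in a
    pair may be None (unobserved).  Returns every mechanism whose reference
    row matches all provided observations; the pseudo-mechanism
    ``"no_effect"`` (all cells no_change) is included when it matches, so
    an everywhere-silent outcome is reported as indistinguishable from a
    non-critical step.
    """
    table = (
        REFERENCE_NONLINEAR_TABLE if model == "nonlinear" else REFERENCE_LINEAR_TABLE
    )
    settings = {s for s, _ in table}
    mechanisms = sorted({m for _, m in table})

    def _pair(v) -> tuple["str | None", "str | None"]:
        if isinstance(v, SignatureLabel):
            return v.rate_label, v.time_label
        rate, time = v
        if rate is not None and rate not in RATE_LABELS:
            raise VocabularyError(f"unknown rate label {rate!r}")
        if time is not None and time not in TIME_LABELS:
            raise VocabularyError(f"unknown time label {time!r}")
        return rate, time

    obs = {}
    for setting, v in observed.items():
        if setting not in settings:
            raise VocabularyError(
                f"unknown setting {setting!r}; expected one of {sorted(settings)}"
            )
        obs[setting] = _pair(v)
    if not obs:
        raise DomainError("at least one observed setting is required")

    def _matches(row: dict[str, SignatureLabel]) -> bool:
        for setting, (rate, time) in obs.items():
            cell = row[setting]
            if rate is not None and cell.rate_label != rate:
                return False
            if time is not None and cell.time_label != time:
                return False
        return True

    result = set()
    for mech in mechanisms:
        row = {s: table[(s, mech)] for s in settings}
        if _matches(row):
            result.add(mech)
    if include_no_effect:
        silent = {s: SignatureLabel("no_change", "no_change") for s in settings}
        if _matches(silent):
            result.add("no_effect")
    return result
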