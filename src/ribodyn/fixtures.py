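"""Named parameter sets and configuration loading.

The registry collects the canonical parameter sets of the translation
models: the original baseline of the non-linear model, its slow-recycling
variant (the regime switch showcase), the strong-separation set used to
probe the staged approximation, the efficient-initiation scan set, and
their weak-cap (A-cap) counterparts.  All values are in relative,
unitless model units.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from .core_models import DomainError, LinearParams, NonlinearParams

__all__ = [
    "Fixture",
    "FIXTURES",
    "get_fixture",
    "list_fixtures",
    "param_hash",
    "load_params",
]


@dataclass(frozen=True)
class Fixture:
    name: str
    params: NonlinearParams
    provenance: str


_DEFAULT = NonlinearParams(k1=2.0, k2=2.0, k3=5.0, k4=1.0,
                           total_40S=100.0, total_60S=25.0, total_eIF4F=6.0)

FIXTURES: dict[str, Fixture] = {
    f.name: f
    for f in (
        Fixture(
            "default",
            _DEFAULT,
            "baseline parameter set of the non-linear model "
            "(inefficient initiation, beta = 0.48)",
        ),
        Fixture(
            "efficient",
            _DEFAULT.replace(k4=0.1),
            "slow-recycling variant (k4 = 0.1) switching to efficient "
            "initiation, beta = 4.8; three-stage relaxation",
        ),
        Fixture(
            "strong_separation",
            NonlinearParams(k1=1.0, k2=5.0, k3=50.0, k4=0.01),
            "strongly separated rates (k4 = 0.01, fast elongation); the "
            "staged approximation is tightest here",
        ),
        Fixture(
            "efficient_scan",
            NonlinearParams(k1=2.0, k2=3.0, k3=50.0, k4=0.1),
            "efficient-initiation base of the inhibition scans, beta = 7.2",
        ),
        Fixture(
            "acap_default",
            _DEFAULT.replace(k1=0.01),
            "weak-cap (A-cap) transcript on the baseline set: k1 = 0.01",
        ),
        Fixture(
            "acap_efficient_scan",
            NonlinearParams(k1=0.01, k2=3.0, k3=50.0, k4=0.1),
            "weak-cap (A-cap) transcript on the efficient-scan set",
        ),
    )
}


def get_fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name]
    except KeyError:
        raise DomainError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None


def list_fixtures() -> list[str]:
    return sorted(FIXTURES)


def param_hash(p: "NonlinearParams | LinearParams") -> str:
    """Short stable hash of a parameter record (for output provenance)."""
    payload = json.dumps(
        {k: float(getattr(p, k)) for k in sorted(p.__dataclass_fields__)},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


_LINEAR_KEYS = {"k1", "k2", "k3", "total_40S"}
_NONLINEAR_KEYS = {
    "k1", "k2", "k3", "k4", "total_40S", "total_60S", "total_eIF4F"
}


def load_params(source: "str | Path | dict") -> "LinearParams | NonlinearParams":
    """Build a parameter record from a YAML/JSON file or a plain dict.

    The mapping must contain ``model: linear|nonlinear`` plus exactly the
    rate and pool keys of that model; unknown keys are rejected.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise DomainError("parameter config must be a mapping")
    model = data.pop("model", "nonlinear")
    allowed = _LINEAR_KEYS if model == "linear" else _NONLINEAR_KEYS
    if model not in ("linear", "nonlinear"):
        raise DomainError(f"unknown model {model!r}")
    unknown = set(data) - allowed
    if unknown:
        raise DomainError(f"unknown parameter keys: {sorted(unknown)}")
    cls = LinearParams if model == "linear" else NonlinearParams
    try:
        return cls(**{k: float(v) for k, v in data.items()})
    except TypeError as exc:
        raise DomainError(f"incomplete parameter set: {exc}") from exc
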