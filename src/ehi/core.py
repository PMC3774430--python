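"""Domain types and rating functions for the Exposure Hazard Index (EHI).

The EHI is a semi-quantitative occupational chemical-exposure risk score,

    EHI = TI * EI * PDI,

where TI is a toxicity index derived from the chemical's occupational
exposure limit (8-h time-weighted average, OEL-TWA, in ppm), EI in [0, 1]
is an exposure index derived from the daily exposure duration, and PDI in
[0, 1] is a protection-deficiency index combining a management index MI
(count of implemented management measures) and a protection index PI
(engineering-control / PPE combination).  Each index exists in two rating
schemes: the *original* categorical bands and the *corrected* continuous
ratings calibrated against a panel of senior industrial hygienists (see
:mod:`ehi.calibration`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal, Optional

__all__ = [
    "ValidationError",
    "Scheme",
    "EngineeringControl",
    "PPEProvision",
    "ChemicalAgent",
    "ExposureEntry",
    "ManagementProfile",
    "ControlProfile",
    "IndexBundle",
    "PDI_FORMULAS",
    "ORIGINAL_TI_LEVELS",
    "effective_oel",
    "rate_ti",
    "rate_ei",
    "rate_mi",
    "rate_pi",
    "compute_pdi",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


Scheme = Literal["original", "corrected"]
_SCHEMES = ("original", "corrected")


def _check_scheme(scheme: str) -> str:
    if scheme not in _SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; expected one of {_SCHEMES}")
    return scheme


class EngineeringControl(str, Enum):
    """Engineering-control effectiveness level.

    EEe: effective (enclosure or local exhaust ventilation);
    EEp: partially effective (general ventilation only);
    EEn: none.
    """

    EEe = "EEe"
    EEp = "EEp"
    EEn = "EEn"


class PPEProvision(str, Enum):
    """Whether appropriate personal protective equipment is provided."""

    PPEe = "PPEe"
    PPEn = "PPEn"


def _positive_finite(value: float, what: str, owner: str) -> None:
    if not (value > 0 and math.isfinite(value)):
        raise ValidationError(f"{owner}: {what} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class ChemicalAgent:
    """A chemical with its exposure-limit information.

    At least one of ``oel_twa`` / ``oel_ceiling`` (ppm) must be present,
    unless the agent is flagged ``no_oel_or_carcinogen`` — carcinogens and
    new chemicals without an OEL are rated pragmatically at the lowest
    OEL-TWA in use (0.001 ppm, original TI 128).
    """

    name: str
    cas: Optional[str] = None
    oel_twa: Optional[float] = None
    oel_ceiling: Optional[float] = None
    no_oel_or_carcinogen: bool = False

    def __post_init__(self) -> None:
        if self.oel_twa is not None:
            _positive_finite(self.oel_twa, "oel_twa", self.name)
        if self.oel_ceiling is not None:
            _positive_finite(self.oel_ceiling, "oel_ceiling", self.name)
        if self.oel_twa is None and self.oel_ceiling is None and not self.no_oel_or_carcinogen:
            raise ValidationError(
                f"agent {self.name!r}: needs an OEL-TWA or OEL-Ceiling, "
                "or the no_oel_or_carcinogen flag"
            )


@dataclass(frozen=True)
class ExposureEntry:
    """One worker-exposure row: a chemical and its daily duration in minutes."""

    agent: ChemicalAgent
    exposure_minutes: float

    def __post_init__(self) -> None:
        if not (self.exposure_minutes >= 0 and math.isfinite(self.exposure_minutes)):
            raise ValidationError(
                f"exposure_minutes must be finite and >= 0, got {self.exposure_minutes!r} "
                f"for agent {self.agent.name!r}"
            )


_MEASURE_NAMES = ("personnel", "msds", "sop", "training")


@dataclass(frozen=True)
class ManagementProfile:
    """Count N (0-4) of implemented management measures.

    The four measures are safety/health personnel, MSDS availability,
    standard operating procedures, and hazardous-material training.  The
    individual booleans are optional; when all four are given their true
    count must equal ``n_measures``.
    """

    n_measures: int
    personnel: Optional[bool] = None
    msds: Optional[bool] = None
    sop: Optional[bool] = None
    training: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.n_measures not in (0, 1, 2, 3, 4):
            raise ValidationError(f"n_measures must be an integer in 0..4, got {self.n_measures!r}")
        flags = [getattr(self, m) for m in _MEASURE_NAMES]
        if all(f is not None for f in flags) and sum(bool(f) for f in flags) != self.n_measures:
            raise ValidationError(
                f"management flags sum to {sum(bool(f) for f in flags)} "
                f"but n_measures={self.n_measures}"
            )

    @classmethod
    def from_flags(cls, personnel: bool, msds: bool, sop: bool, training: bool) -> "ManagementProfile":
        return cls(
            n_measures=sum((personnel, msds, sop, training)),
            personnel=personnel, msds=msds, sop=sop, training=training,
        )


@dataclass(frozen=True)
class ControlProfile:
    """Engineering-control level plus PPE provision for an enterprise."""

    engineering: EngineeringControl
    ppe: PPEProvision

    def __post_init__(self) -> None:
        # accept canonical strings ("EEe", "PPEn") as well as enum members
        object.__setattr__(self, "engineering", _coerce(EngineeringControl, self.engineering))
        object.__setattr__(self, "ppe", _coerce(PPEProvision, self.ppe))

    @property
    def combo(self) -> str:
        """Canonical combination label, e.g. ``"EEp+PPEe"``."""
        return f"{self.engineering.value}+{self.ppe.value}"


def _coerce(enum_cls, value):
    try:
        return enum_cls(value)
    except ValueError:
        valid = [m.value for m in enum_cls]
        raise ValidationError(f"unknown {enum_cls.__name__} value {value!r}; expected one of {valid}") from None


@dataclass(frozen=True)
class IndexBundle:
    """All five index values for one chemical exposure, plus their EHI product."""

    ti: float
    ei: float
    mi: float
    pi: float
    pdi: float
    ehi: float
    scheme: str = "corrected"


# ---------------------------------------------------------------------------
# Original categorical TI bands: lower bound exclusive, upper inclusive,
# e.g. 100 ppm >= OEL-TWA > 10 ppm -> 4.  Anything at or below 0.001 ppm
# (and carcinogens / no-OEL agents) rates 128.
ORIGINAL_TI_LEVELS: tuple[tuple[float, float], ...] = (
    (1000.0, 1.0),
    (100.0, 2.0),
    (10.0, 4.0),
    (1.0, 8.0),
    (0.1, 16.0),
    (0.01, 32.0),
    (0.001, 64.0),
)

#: OEL-TWA (ppm) assigned to carcinogens and agents without any OEL.
NO_OEL_PPM = 0.001

#: Original categorical MI ratings for N = 0..4.
ORIGINAL_MI = (0.00, 0.25, 0.50, 0.75, 1.00)

#: Original PI ratings per control combination.
ORIGINAL_PI = {
    "EEn+PPEn": 0.00,
    "EEn+PPEe": 0.20,
    "EEp+PPEn": 0.30,
    "EEp+PPEe": 0.50,
    "EEe+PPEn": 0.80,
    "EEe+PPEe": 1.00,
}


def effective_oel(agent: ChemicalAgent) -> float:
    """Return the OEL-TWA (ppm) used for TI rating.

    The TWA is used when present; a ceiling-only chemical is assigned
    three times its OEL-Ceiling; carcinogens / no-OEL agents are assigned
    0.001 ppm.
    """
    if agent.oel_twa is not None:
        return agent.oel_twa
    if agent.oel_ceiling is not None:
        return 3.0 * agent.oel_ceiling
    if agent.no_oel_or_carcinogen:
        return NO_OEL_PPM
    raise ValidationError(f"agent {agent.name!r} has no OEL information")


def _original_ti(oel: float) -> float:
    for bound, rating in ORIGINAL_TI_LEVELS:
        if oel > bound:
            return rating
    return 128.0


def rate_ti(agent: ChemicalAgent, scheme: Scheme = "corrected", params=None) -> float:
    """Toxicity index of ``agent``.

    Original scheme: the eight-level band table (1, 2, 4, ..., 128).
    Corrected scheme: the continuous power law ``K0 * 2**(-log10(OEL))``,
    which doubles the rating for every tenfold decrease in the OEL-TWA.
    Under the corrected scheme a carcinogen / no-OEL agent is rated at the
    0.001-ppm substitute OEL, unless ``params.ti_pin_carcinogen`` pins it
    to the original 128.
    """
    _check_scheme(scheme)
    oel = effective_oel(agent)
    if oel <= 0:
        raise ValidationError(f"agent {agent.name!r}: non-positive effective OEL {oel!r}")
    if scheme == "original":
        return _original_ti(oel)
    params = _default_params(params)
    if agent.no_oel_or_carcinogen and agent.oel_twa is None and agent.oel_ceiling is None \
            and params.ti_pin_carcinogen:
        return 128.0
    return params.k0 * 2.0 ** (-math.log10(oel))


def rate_ei(exposure_minutes: float, scheme: Scheme = "corrected", params=None) -> float:
    """Exposure index in [0, 1] from the daily exposure duration in minutes.

    Original scheme: 0.30 below 2 h, 0.60 from 2 h to below 4 h, 1.00 at
    4 h or more.  Corrected scheme: the fitted linear regression
    ``slope * ED + intercept`` clamped to [0, 1].
    """
    _check_scheme(scheme)
    if not (exposure_minutes >= 0 and math.isfinite(exposure_minutes)):
        raise ValidationError(f"exposure_minutes must be finite and >= 0, got {exposure_minutes!r}")
    if scheme == "original":
        if exposure_minutes < 120:
            return 0.30
        if exposure_minutes < 240:
            return 0.60
        return 1.00
    params = _default_params(params)
    ei = params.ei_slope * exposure_minutes + params.ei_intercept
    if params.ei_clamp:
        ei = min(1.0, max(0.0, ei))
    return ei


def rate_mi(n_measures: int, scheme: Scheme = "corrected", params=None) -> float:
    """Management index in [0, 1] from the count N of implemented measures."""
    _check_scheme(scheme)
    if n_measures not in (0, 1, 2, 3, 4):
        raise ValidationError(f"n_measures must be in 0..4, got {n_measures!r}")
    if scheme == "original":
        return ORIGINAL_MI[n_measures]
    params = _default_params(params)
    return params.mi_table[int(n_measures)]


def rate_pi(controls: ControlProfile, scheme: Scheme = "corrected", params=None) -> float:
    """Protection index in [0, 1] from the engineering-control/PPE combination."""
    _check_scheme(scheme)
    if scheme == "original":
        return ORIGINAL_PI[controls.combo]
    params = _default_params(params)
    return params.pi_table[controls.combo]


# PDI formulas: higher MI and PI must give lower deficiency.  The default
# averages the two complements; alternatives are selectable by config.
PDI_FORMULAS = {
    "average_complement": lambda mi, pi: 1.0 - (mi + pi) / 2.0,
    "product_complement": lambda mi, pi: (1.0 - mi) * (1.0 - pi),
    "sum_complement": lambda mi, pi: 2.0 - mi - pi,
}

DEFAULT_PDI_FORMULA = "average_complement"


def compute_pdi(mi: float, pi: float, formula: str = DEFAULT_PDI_FORMULA) -> float:
    """Protection deficiency index from MI and PI.

    Default formula ``1 - (MI + PI)/2``: 0 at full protection
    (MI = PI = 1), 1 with none, strictly decreasing in each argument.
    """
    for name, value in (("mi", mi), ("pi", pi)):
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    try:
        fn = PDI_FORMULAS[formula]
    except KeyError:
        raise ValidationError(
            f"unknown PDI formula {formula!r}; expected one of {sorted(PDI_FORMULAS)}"
        ) from None
    return fn(mi, pi)


def _default_params(params):
    if params is None:
        from .calibration import default_corrected_params

        return default_corrected_params()
    return params
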