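"""Expert-system calibration of the EHI rating functions.

The original categorical ratings are corrected against the mean ratings
of a 20-member panel of senior industrial hygienists elicited on a
seven-enterprise pilot survey:

* TI — a power law ``TI = K0 * 2**(-log10 OEL)`` (doubling per tenfold
  OEL decrease); the scale constant K0 is fit in log2 space, where the
  model is linear with known slope and the fit reduces to a mean;
* EI — ordinary least squares of the expert mean ratings on exposure
  duration (through-origin variant available), clamped to [0, 1];
* MI and PI — corrected lookup tables, with a linear N-regression
  provided as a fallback for user-supplied expert tables;
* a validation regression of expert enterprise scores on corrected
  enterprise scores (slope, intercept, R²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import yaml

from .core import (
    DEFAULT_PDI_FORMULA,
    PDI_FORMULAS,
    ValidationError,
)

__all__ = [
    "ConfigurationError",
    "ExpertRatingRow",
    "CalibrationParams",
    "ValidationFit",
    "fit_ti_scale",
    "fit_linear",
    "build_calibration",
    "validate_against_expert",
    "default_corrected_params",
    "save_calibration",
    "load_calibration",
]


class ConfigurationError(ValueError):
    """Raised when a calibration configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class ExpertRatingRow:
    """One row of an expert-rating table: predictor, panel mean, panel SD."""

    predictor: Union[float, int, str]
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValidationError(f"mean rating must be >= 0, got {self.mean!r}")
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd!r}")


_PI_ORDER = ("EEn+PPEn", "EEn+PPEe", "EEp+PPEn", "EEp+PPEe", "EEe+PPEn", "EEe+PPEe")


@dataclass(frozen=True)
class CalibrationParams:
    """All fitted/tabulated constants of the corrected EHI model."""

    k0: float
    ei_slope: float
    ei_intercept: float
    mi_table: dict[int, float]
    pi_table: dict[str, float]
    ei_clamp: bool = True
    mi_slope: Optional[float] = None
    mi_intercept: Optional[float] = None
    pdi_formula: str = DEFAULT_PDI_FORMULA
    ti_pin_carcinogen: bool = False

    def __post_init__(self) -> None:
        if not self.k0 > 0:
            raise ValidationError(f"k0 must be > 0, got {self.k0!r}")
        if not self.ei_slope > 0:
            raise ValidationError(f"ei_slope must be > 0, got {self.ei_slope!r}")
        if sorted(self.mi_table) != [0, 1, 2, 3, 4]:
            raise ValidationError(f"mi_table must cover N = 0..4, got keys {sorted(self.mi_table)}")
        mi = [self.mi_table[n] for n in range(5)]
        if any(b < a for a, b in zip(mi, mi[1:])):
            raise ValidationError(f"mi_table must be monotone non-decreasing in N, got {mi}")
        if set(self.pi_table) != set(_PI_ORDER):
            raise ValidationError(f"pi_table must cover all six control combinations, got {sorted(self.pi_table)}")
        pi = [self.pi_table[c] for c in _PI_ORDER]
        if any(b < a for a, b in zip(pi, pi[1:])):
            raise ValidationError(f"pi_table must be monotone along {_PI_ORDER}, got {pi}")
        if self.pdi_formula not in PDI_FORMULAS:
            raise ValidationError(f"unknown pdi_formula {self.pdi_formula!r}")

    # --- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "ti": {"k0": float(self.k0), "pin_carcinogen": bool(self.ti_pin_carcinogen)},
            "ei": {
                "slope": float(self.ei_slope),
                "intercept": float(self.ei_intercept),
                "clamp": bool(self.ei_clamp),
            },
            "mi": {
                "table": {int(k): float(v) for k, v in sorted(self.mi_table.items())},
                "slope": None if self.mi_slope is None else float(self.mi_slope),
                "intercept": None if self.mi_intercept is None else float(self.mi_intercept),
            },
            "pi": {"table": {k: float(self.pi_table[k]) for k in _PI_ORDER}},
            "pdi": {"formula": self.pdi_formula},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CalibrationParams":
        try:
            return cls(
                k0=data["ti"]["k0"],
                ti_pin_carcinogen=data["ti"].get("pin_carcinogen", False),
                ei_slope=data["ei"]["slope"],
                ei_intercept=data["ei"]["intercept"],
                ei_clamp=data["ei"].get("clamp", True),
                mi_table={int(k): float(v) for k, v in data["mi"]["table"].items()},
                mi_slope=data["mi"].get("slope"),
                mi_intercept=data["mi"].get("intercept"),
                pi_table=dict(data["pi"]["table"]),
                pdi_formula=data.get("pdi", {}).get("formula", DEFAULT_PDI_FORMULA),
            )
        except KeyError as exc:
            raise ConfigurationError(f"calibration config is missing section/key {exc}") from None


@dataclass(frozen=True)
class ValidationFit:
    """OLS fit of expert enterprise scores on corrected enterprise scores."""

    slope: float
    intercept: float
    r_squared: float
    n: int


# ---------------------------------------------------------------------------


def fit_ti_scale(rows: Iterable[tuple[float, float]]) -> float:
    """Fit the TI power-law scale constant K0.

    The corrected TI model is ``TI = K0 * 2**(-log10 OEL)``; in log2 space
    ``log2 TI = log2 K0 - log10 OEL``, so the least-squares estimate of
    ``log2 K0`` is the mean of ``log2(rating) + log10(oel)`` over the rows.
    """
    rows = list(rows)
    if not rows:
        raise ValidationError("fit_ti_scale needs at least one (oel, rating) row")
    acc = []
    for oel, rating in rows:
        if not (oel > 0 and rating > 0):
            raise ValidationError(f"OELs and ratings must be > 0, got ({oel!r}, {rating!r})")
        acc.append(math.log2(rating) + math.log10(oel))
    return float(2.0 ** np.mean(acc))


def fit_linear(
    pairs: Sequence[tuple[float, float]], through_origin: bool = False
) -> tuple[float, float]:
    """Ordinary least squares of y on x; intercept forced to 0 on request."""
    if len(pairs) < 2:
        raise ValidationError("fit_linear needs at least two (x, y) pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("fit_linear: all x values identical")
    if through_origin:
        slope = float(x @ y / (x @ x))
        return slope, 0.0
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(slope), float(intercept)


def build_calibration(
    ti_rows: Iterable[tuple[float, float]],
    ei_rows: Iterable[tuple[float, float]],
    mi_rows: Iterable[tuple[int, float]],
    pi_rows: Iterable[tuple[str, float]],
    *,
    ei_through_origin: bool = False,
    pdi_formula: str = DEFAULT_PDI_FORMULA,
    ti_pin_carcinogen: bool = False,
) -> CalibrationParams:
    """Assemble :class:`CalibrationParams` from expert-rating tables.

    ``ti_rows`` are (OEL ppm, rating); ``ei_rows`` are (ED minutes,
    rating); ``mi_rows`` are (N, rating) covering N = 0..4; ``pi_rows``
    are (combination label, rating) covering all six combinations.  MI
    and PI become lookup tables; a linear MI regression over N = 1..4
    (capped at 1.0 on evaluation) is stored alongside as a fallback for
    intermediate N on user-supplied tables.
    """
    ti_rows, ei_rows = list(ti_rows), list(ei_rows)
    mi_rows, pi_rows = list(mi_rows), list(pi_rows)
    for name, rows in (("ti", ti_rows), ("ei", ei_rows), ("mi", mi_rows), ("pi", pi_rows)):
        if not rows:
            raise ConfigurationError(f"missing expert table: {name}")
    k0 = fit_ti_scale(ti_rows)
    ei_slope, ei_intercept = fit_linear(ei_rows, through_origin=ei_through_origin)
    mi_table = {int(n): float(r) for n, r in mi_rows}
    # regression domain excludes N=0: the panel rates N=0 as 0 while the
    # corrected table keeps a floor, so the line is fit to N >= 1 only
    mi_fit_rows = [(n, r) for n, r in mi_table.items() if n >= 1]
    mi_slope = mi_intercept = None
    if len(mi_fit_rows) >= 2:
        mi_slope, mi_intercept = fit_linear(mi_fit_rows)
    pi_table = {str(c): float(r) for c, r in pi_rows}
    return CalibrationParams(
        k0=k0,
        ei_slope=ei_slope,
        ei_intercept=ei_intercept,
        mi_table=mi_table,
        mi_slope=mi_slope,
        mi_intercept=mi_intercept,
        pi_table=pi_table,
        pdi_formula=pdi_formula,
        ti_pin_carcinogen=ti_pin_carcinogen,
    )


def validate_against_expert(pairs: Sequence[tuple[float, float]]) -> ValidationFit:
    """Regress expert enterprise EHI on corrected enterprise EHI.

    Returns slope, intercept and R²; a slope near 1 and intercept near 0
    indicate the corrected model tracks the expert panel.  R² is defined
    as 0 when the response has zero variance.
    """
    if len(pairs) < 2:
        raise ValidationError("validate_against_expert needs at least two pairs")
    slope, intercept = fit_linear(pairs)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    x = np.asarray([p[0] for p in pairs], dtype=float)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return ValidationFit(slope=slope, intercept=intercept, r_squared=r2, n=len(pairs))


# ---------------------------------------------------------------------------

_DEFAULT_PARAMS: Optional[CalibrationParams] = None


def default_corrected_params() -> CalibrationParams:
    """The corrected calibration built from the published reference tables.

    K0 is fit to the published corrected TI column (which the power law
    reproduces almost exactly); the EI regression is fit to the expert
    mean ratings; MI and PI are the published corrected lookups.
    """
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        from . import reference as ref

        _DEFAULT_PARAMS = build_calibration(
            ti_rows=ref.TI_CORRECTED_ROWS,
            ei_rows=[(r.predictor, r.mean) for r in ref.EI_EXPERT_ROWS],
            mi_rows=list(ref.MI_CORRECTED.items()),
            pi_rows=list(ref.PI_CORRECTED.items()),
        )
    return _DEFAULT_PARAMS


def save_calibration(params: CalibrationParams, path) -> None:
    """Write a calibration to a YAML config file."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_calibration(path) -> CalibrationParams:
    """Read a calibration from a YAML config file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"calibration file {path} does not contain a mapping")
    return CalibrationParams.from_dict(data)
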