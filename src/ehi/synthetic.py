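"""Seeded generator of synthetic survey databanks.

The real 2006-2009 national databank was never publicly deposited, so
this module emulates its *structure*: 25 manufacturing industries with
the published per-industry enterprise counts (702 enterprises in all),
per-enterprise chemical lists drawn from a palette spanning OEL-TWAs of
0.001-1,000 ppm, exposure durations of 10-480 min, 0-4 management
measures, and the six engineering/PPE control combinations.  Only the
counts and ranges are anchored to the published survey; the joint
distributions are synthetic choices (see the package methods note).

Each enterprise draws from its own pseudo-random stream derived from
(seed, enterprise index), so extending the industry list does not
perturb existing draws.  ``generate_tiered`` additionally skews
configured "high-risk" industries toward longer durations, fewer
management measures, weaker controls and more toxic chemicals, for
recovery testing of the prioritization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    ChemicalAgent,
    ControlProfile,
    ExposureEntry,
    ManagementProfile,
    ValidationError,
    effective_oel,
)
from .io import SurveyTable
from .scoring import EnterpriseRecord

__all__ = ["GeneratorConfig", "default_palette", "generate", "generate_tiered"]

_COMBOS = ("EEn+PPEn", "EEn+PPEe", "EEp+PPEn", "EEp+PPEe", "EEe+PPEn", "EEe+PPEe")


def default_palette() -> tuple[ChemicalAgent, ...]:
    """The nine pilot-survey chemicals plus two synthetic edge-case agents.

    The extra agents — a ceiling-only chemical and a carcinogen without
    any OEL — are synthetic additions so that the ceiling (3x) and
    no-OEL (0.001 ppm) effective-OEL rules are exercised end to end.
    """
    from . import reference as ref

    agents = [ChemicalAgent(name=n, cas=c, oel_twa=o) for n, c, o in ref.REFERENCE_CHEMICALS]
    agents.append(ChemicalAgent(name="Synthetic ceiling-only agent", oel_ceiling=5.0))
    agents.append(ChemicalAgent(name="Synthetic carcinogen (no OEL)", no_oel_or_carcinogen=True))
    return tuple(agents)


def _default_industries() -> tuple[tuple[str, str, int], ...]:
    from . import reference as ref

    return tuple((code, name, n) for code, name, n, _ in ref.NATIONAL_INDUSTRIES)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic survey generator.

    Defaults reproduce the published survey structure: the 25 industries
    with their printed enterprise counts, and the pilot-survey chemical
    palette.  The duration support {10..480} min covers the published
    10-250 min observed range extended to a full 8-h shift, so both EI
    clamps are exercised.
    """

    industries: tuple[tuple[str, str, int], ...] = field(default_factory=_default_industries)
    palette: tuple[ChemicalAgent, ...] = field(default_factory=default_palette)
    n_chemicals_choices: tuple[int, ...] = (1, 2, 3, 4)
    n_chemicals_probs: tuple[float, ...] = (0.35, 0.35, 0.20, 0.10)
    ed_values: tuple[float, ...] = (10, 30, 40, 48, 75, 225, 250, 480)
    ed_probs: tuple[float, ...] = (0.10, 0.15, 0.15, 0.15, 0.15, 0.15, 0.10, 0.05)
    n_measures_probs: tuple[float, ...] = (0.10, 0.20, 0.30, 0.25, 0.15)  # N = 0..4
    control_probs: tuple[float, ...] = (0.10, 0.10, 0.20, 0.25, 0.15, 0.20)  # per _COMBOS
    high_risk_codes: frozenset[str] = frozenset()
    tier_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.industries:
            raise ValidationError("generator config needs at least one industry")
        for code, name, n in self.industries:
            if n < 1:
                raise ValidationError(f"industry {code} ({name}): n_enterprises must be >= 1, got {n}")
        for label, probs in (
            ("n_chemicals_probs", self.n_chemicals_probs),
            ("ed_probs", self.ed_probs),
            ("n_measures_probs", self.n_measures_probs),
            ("control_probs", self.control_probs),
        ):
            probs = np.asarray(probs, dtype=float)
            if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
                raise ValidationError(f"{label} must be non-negative and sum to 1")
        if len(self.n_chemicals_probs) != len(self.n_chemicals_choices):
            raise ValidationError("n_chemicals_probs length mismatch")
        if len(self.ed_probs) != len(self.ed_values):
            raise ValidationError("ed_probs length mismatch")
        if len(self.n_measures_probs) != 5:
            raise ValidationError("n_measures_probs must have 5 entries (N = 0..4)")
        if len(self.control_probs) != 6:
            raise ValidationError("control_probs must have 6 entries")
        if max(self.n_chemicals_choices) > len(self.palette):
            raise ValidationError("cannot draw more chemicals than the palette holds")
        if not 0.0 <= self.tier_strength <= 1.0:
            raise ValidationError(f"tier_strength must lie in [0, 1], got {self.tier_strength}")


def _mix(base: Sequence[float], extreme: Sequence[float], s: float) -> np.ndarray:
    p = (1.0 - s) * np.asarray(base, float) + s * np.asarray(extreme, float)
    return p / p.sum()


def _tier_distributions(config: GeneratorConfig):
    """Skewed distributions for high-risk industries at the configured strength."""
    s = config.tier_strength
    # longest durations, N = 0, no controls, and toxicity-weighted chemicals
    ed_extreme = np.zeros(len(config.ed_values))
    ed_extreme[np.argsort(config.ed_values)[-2:]] = 0.5
    n_extreme = np.array([0.7, 0.3, 0.0, 0.0, 0.0])
    control_extreme = np.array([0.7, 0.15, 0.15, 0.0, 0.0, 0.0])
    oels = np.array([effective_oel(a) for a in config.palette])
    chem_extreme = (1.0 / oels) / (1.0 / oels).sum()
    chem_base = np.full(len(config.palette), 1.0 / len(config.palette))
    return (
        _mix(config.ed_probs, ed_extreme, s),
        _mix(config.n_measures_probs, n_extreme, s),
        _mix(config.control_probs, control_extreme, s),
        _mix(chem_base, chem_extreme, s),
    )


def _generate(config: GeneratorConfig, tiered: bool) -> SurveyTable:
    base_chem = np.full(len(config.palette), 1.0 / len(config.palette))
    base = (
        np.asarray(config.ed_probs, float),
        np.asarray(config.n_measures_probs, float),
        np.asarray(config.control_probs, float),
        base_chem,
    )
    hot = _tier_distributions(config) if tiered else base
    records = []
    global_index = 0
    for code, name, n_enterprises in config.industries:
        ed_p, n_p, c_p, chem_p = hot if (tiered and code in config.high_risk_codes) else base
        for j in range(n_enterprises):
            rng = np.random.default_rng([config.seed, global_index])
            global_index += 1
            k = int(rng.choice(config.n_chemicals_choices, p=config.n_chemicals_probs))
            chem_idx = rng.choice(len(config.palette), size=k, replace=False, p=chem_p)
            exposures = tuple(
                ExposureEntry(
                    agent=config.palette[int(ci)],
                    exposure_minutes=float(rng.choice(config.ed_values, p=ed_p)),
                )
                for ci in chem_idx
            )
            n_measures = int(rng.choice(5, p=n_p))
            ee, ppe = _COMBOS[int(rng.choice(6, p=c_p))].split("+")
            records.append(
                EnterpriseRecord(
                    enterprise_id=f"E{code}-{j + 1:04d}",
                    industry_code=code,
                    industry_name=name,
                    exposures=exposures,
                    management=ManagementProfile(n_measures=n_measures),
                    controls=ControlProfile(engineering=ee, ppe=ppe),
                )
            )
    return SurveyTable(records=tuple(records), source=f"synthetic(seed={config.seed})",
                       n_rows_read=sum(len(r.exposures) for r in records))


def generate(config: Optional[GeneratorConfig] = None) -> SurveyTable:
    """Generate a synthetic survey databank; deterministic for a fixed seed."""
    return _generate(config or GeneratorConfig(), tiered=False)


def generate_tiered(config: GeneratorConfig) -> SurveyTable:
    """Generate a databank whose ``high_risk_codes`` industries are skewed risky.

    With ``tier_strength`` 0 (or no high-risk codes) this reduces exactly
    to :func:`generate`.
    """
    return _generate(config, tiered=True)
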