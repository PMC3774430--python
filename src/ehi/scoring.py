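"""Enterprise scoring, industry aggregation and control-priority banding.

Per chemical, ``EHI = TI * EI * PDI``; per enterprise, chemical effects
are taken as additive so the enterprise score is the sum over its
chemicals.  Enterprises are grouped by 2-digit industry code; each
industry is summarised by a statistic of its enterprise scores (default:
the 95th percentile), and industries are ranked into four control
priorities by the 90th/70th/50th percentiles of those statistics, with
inclusive lower bounds (a statistic exactly at a cutoff takes the higher
band).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationParams, default_corrected_params
from .core import (
    ControlProfile,
    ExposureEntry,
    IndexBundle,
    ManagementProfile,
    Scheme,
    ValidationError,
    compute_pdi,
    rate_ei,
    rate_mi,
    rate_pi,
    rate_ti,
)

__all__ = [
    "EnterpriseRecord",
    "ScoredExposure",
    "EnterpriseScore",
    "IndustrySummary",
    "PriorityAssignment",
    "score_enterprise",
    "summarize_industries",
    "percentile",
    "assign_priorities",
    "distribution_stats",
    "band_index_profiles",
]


@dataclass(frozen=True)
class EnterpriseRecord:
    """One surveyed enterprise.

    The survey records one management profile and one control profile per
    enterprise; chemical exposures are a list of (agent, duration) rows.
    """

    enterprise_id: str
    industry_code: str
    industry_name: str
    exposures: tuple[ExposureEntry, ...]
    management: ManagementProfile
    controls: ControlProfile

    def __post_init__(self) -> None:
        object.__setattr__(self, "exposures", tuple(self.exposures))


@dataclass(frozen=True)
class ScoredExposure:
    chemical: str
    indices: IndexBundle


@dataclass(frozen=True)
class EnterpriseScore:
    """Per-chemical index bundles and the summed enterprise EHI."""

    enterprise_id: str
    industry_code: str
    per_chemical: tuple[ScoredExposure, ...]
    ehi_total: float


@dataclass(frozen=True)
class IndustrySummary:
    industry_code: str
    industry_name: str
    n_enterprises: int
    statistic: float
    statistic_kind: str = "p95"


@dataclass(frozen=True)
class PriorityAssignment:
    """Percentile cutoffs and the band (1 = highest priority) per industry."""

    cutoffs: tuple[float, float, float]  # (p90, p70, p50)
    bands: dict[str, int]

    def band_sizes(self) -> tuple[int, int, int, int]:
        sizes = [0, 0, 0, 0]
        for band in self.bands.values():
            sizes[band - 1] += 1
        return tuple(sizes)


def score_enterprise(
    record: EnterpriseRecord,
    params: Optional[CalibrationParams] = None,
    scheme: Scheme = "corrected",
) -> EnterpriseScore:
    """Score one enterprise: per-chemical EHI = TI * EI * PDI, summed.

    An enterprise with no recorded exposures scores 0.
    """
    if params is None:
        params = default_corrected_params()
    mi = rate_mi(record.management.n_measures, scheme, params)
    pi = rate_pi(record.controls, scheme, params)
    pdi = compute_pdi(mi, pi, params.pdi_formula)
    scored = []
    for i, entry in enumerate(record.exposures):
        try:
            ti = rate_ti(entry.agent, scheme, params)
            ei = rate_ei(entry.exposure_minutes, scheme, params)
        except ValidationError as exc:
            raise ValidationError(
                f"enterprise {record.enterprise_id!r}, exposure row {i}: {exc}"
            ) from exc
        bundle = IndexBundle(ti=ti, ei=ei, mi=mi, pi=pi, pdi=pdi, ehi=ti * ei * pdi, scheme=scheme)
        scored.append(ScoredExposure(chemical=entry.agent.name, indices=bundle))
    total = float(sum(s.indices.ehi for s in scored))
    return EnterpriseScore(
        enterprise_id=record.enterprise_id,
        industry_code=record.industry_code,
        per_chemical=tuple(scored),
        ehi_total=total,
    )


def percentile(values: Sequence[float], p: float) -> float:
    """Linear-interpolation percentile (inclusive method).

    With the values sorted ascending, the rank is ``h = (n - 1) p + 1``
    and the result interpolates linearly between the flanking order
    statistics; p = 0 gives the minimum and p = 1 the maximum.
    """
    vals = sorted(float(v) for v in values)
    if not vals:
        raise ValidationError("percentile of an empty sequence")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p!r}")
    h = (len(vals) - 1) * p
    lo = math.floor(h)
    hi = math.ceil(h)
    return vals[lo] + (h - lo) * (vals[hi] - vals[lo])


_STATISTICS = {
    "p95": lambda vals: percentile(vals, 0.95),
    "mean": lambda vals: float(np.mean(vals)),
}


def summarize_industries(
    scores: Iterable[EnterpriseScore],
    records: Iterable[EnterpriseRecord],
    statistic_kind: str = "p95",
) -> list[IndustrySummary]:
    """Group enterprise scores by industry and compute the industry statistic.

    Default statistic: the 95th percentile of the enterprise EHI values in
    the industry.  Every score must join to a record (for the industry
    name); summaries are returned sorted by industry code.
    """
    if statistic_kind not in _STATISTICS:
        raise ValidationError(f"unknown statistic {statistic_kind!r}; expected one of {sorted(_STATISTICS)}")
    by_id = {r.enterprise_id: r for r in records}
    groups: dict[str, list[float]] = {}
    names: dict[str, str] = {}
    for score in scores:
        rec = by_id.get(score.enterprise_id)
        if rec is None:
            raise ValidationError(f"score for unknown enterprise {score.enterprise_id!r}")
        groups.setdefault(rec.industry_code, []).append(score.ehi_total)
        names[rec.industry_code] = rec.industry_name
    stat = _STATISTICS[statistic_kind]
    return [
        IndustrySummary(
            industry_code=code,
            industry_name=names[code],
            n_enterprises=len(vals),
            statistic=stat(vals),
            statistic_kind=statistic_kind,
        )
        for code, vals in sorted(groups.items())
    ]


def assign_priorities(summaries: Sequence[IndustrySummary]) -> PriorityAssignment:
    """Assign the four control-priority bands from percentile cutoffs.

    Cutoffs are the 90th/70th/50th percentiles of the industry statistics;
    band 1 if statistic >= p90, band 2 if p70 <= statistic < p90, band 3
    if p50 <= statistic < p70, band 4 otherwise.
    """
    if not summaries:
        raise ValidationError("assign_priorities needs at least one industry summary")
    if len(summaries) < 4:
        warnings.warn(
            f"only {len(summaries)} industries; percentile banding is fragile below 4",
            stacklevel=2,
        )
    stats = [s.statistic for s in summaries]
    p90, p70, p50 = (percentile(stats, p) for p in (0.90, 0.70, 0.50))
    bands = {}
    for s in summaries:
        if s.statistic >= p90:
            band = 1
        elif s.statistic >= p70:
            band = 2
        elif s.statistic >= p50:
            band = 3
        else:
            band = 4
        bands[s.industry_code] = band
    return PriorityAssignment(cutoffs=(p90, p70, p50), bands=bands)


def distribution_stats(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1 denominator) standard deviation."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValidationError("distribution_stats needs n >= 2 for the sample SD")
    return float(vals.mean()), float(vals.std(ddof=1))


def band_index_profiles(
    scores: Iterable[EnterpriseScore],
    records: Iterable[EnterpriseRecord],
    assignment: PriorityAssignment,
) -> pd.DataFrame:
    """Mean +/- SE of TI, EI, MI, PI per priority band.

    Pools all chemical-level index values of the enterprises in each band.
    Returns a tidy frame with columns (band, index, n, mean, se, ci_low,
    ci_high) where the CI is mean +/- 1.96 SE; SE is 0 when n < 2.  Bands
    with no chemical-level values are omitted with a warning.
    """
    by_id = {r.enterprise_id: r for r in records}
    pooled: dict[int, dict[str, list[float]]] = {}
    for score in scores:
        rec = by_id[score.enterprise_id]
        band = assignment.bands[rec.industry_code]
        dest = pooled.setdefault(band, {"ti": [], "ei": [], "mi": [], "pi": []})
        for sc in score.per_chemical:
            for name in ("ti", "ei", "mi", "pi"):
                dest[name].append(getattr(sc.indices, name))
    rows = []
    for band in sorted(assignment.bands.values()):
        if band in {r[0] for r in rows}:
            continue
        if band not in pooled or not pooled[band]["ti"]:
            warnings.warn(f"band {band} has no chemical-level values; omitted", stacklevel=2)
            continue
        for name in ("ti", "ei", "mi", "pi"):
            vals = np.asarray(pooled[band][name])
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
            rows.append((band, name, vals.size, mean, se, mean - 1.96 * se, mean + 1.96 * se))
    return pd.DataFrame(rows, columns=["band", "index", "n", "mean", "se", "ci_low", "ci_high"])
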