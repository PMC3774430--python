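"""Survey-databank CSV input/output and the end-to-end pipeline.

The survey CSV carries one row per enterprise x chemical.  Required
columns: enterprise_id, industry_code, industry_name, chemical_name,
exposure_minutes, engineering_control (EEe|EEp|EEn), ppe (PPEe|PPEn),
and management given either as n_management (0-4) or as the four 0/1
columns personnel/msds/sop/training.  Optional: cas, oel_twa_ppm,
oel_ceiling_ppm, carcinogen_no_oel (0/1).  Management and control values
must agree across an enterprise's rows (the survey granularity is one
profile per enterprise); industry codes are text, preserving leading
zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationParams, default_corrected_params
from .core import (
    ChemicalAgent,
    ControlProfile,
    ExposureEntry,
    ManagementProfile,
    Scheme,
    ValidationError,
)
from .scoring import (
    EnterpriseRecord,
    EnterpriseScore,
    IndustrySummary,
    PriorityAssignment,
    assign_priorities,
    distribution_stats,
    score_enterprise,
    summarize_industries,
)

__all__ = [
    "SchemaError",
    "SurveyTable",
    "PipelineResult",
    "read_survey_csv",
    "write_survey_csv",
    "records_to_frame",
    "run_pipeline",
    "scores_to_frame",
    "summaries_to_frame",
    "priorities_to_frame",
]

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Raised when a survey CSV is missing required columns."""


REQUIRED_COLUMNS = (
    "enterprise_id",
    "industry_code",
    "industry_name",
    "chemical_name",
    "exposure_minutes",
    "engineering_control",
    "ppe",
)
MEASURE_COLUMNS = ("personnel", "msds", "sop", "training")
OPTIONAL_COLUMNS = ("cas", "oel_twa_ppm", "oel_ceiling_ppm", "carcinogen_no_oel",
                    "n_management") + MEASURE_COLUMNS


@dataclass(frozen=True)
class SurveyTable:
    """Validated survey records plus provenance of the read."""

    records: tuple[EnterpriseRecord, ...]
    source: Optional[str] = None
    n_rows_read: int = 0
    rejections: tuple[tuple[int, str], ...] = ()  # (line number, reason)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "rejections", tuple(self.rejections))

    def __len__(self) -> int:
        return len(self.records)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _row_management(row: pd.Series) -> ManagementProfile:
    n = row.get("n_management")
    n = None if n is None or (isinstance(n, float) and np.isnan(n)) else int(n)
    flags = [row.get(c) for c in MEASURE_COLUMNS]
    have_flags = all(f is not None and not (isinstance(f, float) and np.isnan(f)) for f in flags)
    if have_flags:
        flags = [bool(int(f)) for f in flags]
        if n is not None and sum(flags) != n:
            raise ValidationError(
                f"n_management={n} inconsistent with measure flags summing to {sum(flags)}"
            )
        return ManagementProfile.from_flags(*flags)
    if n is None:
        raise ValidationError("need n_management or all four measure columns")
    return ManagementProfile(n_measures=n)


def _row_to_parts(row: pd.Series):
    agent = ChemicalAgent(
        name=str(row["chemical_name"]),
        cas=None if pd.isna(row.get("cas")) or row.get("cas") in (None, "") else str(row["cas"]),
        oel_twa=_opt_float(row.get("oel_twa_ppm")),
        oel_ceiling=_opt_float(row.get("oel_ceiling_ppm")),
        no_oel_or_carcinogen=bool(int(row.get("carcinogen_no_oel") or 0)),
    )
    entry = ExposureEntry(agent=agent, exposure_minutes=float(row["exposure_minutes"]))
    management = _row_management(row)
    controls = ControlProfile(engineering=row["engineering_control"], ppe=row["ppe"])
    return entry, management, controls


def read_survey_csv(path, strict: bool = False) -> SurveyTable:
    """Read and validate a survey CSV into typed enterprise records.

    In strict mode the first invalid row aborts with its line number; in
    lenient mode invalid rows are logged, skipped and counted in the
    returned table's ``rejections``.
    """
    df = pd.read_csv(path, dtype={"industry_code": str, "cas": str}, encoding="utf-8")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey CSV {path} is missing required column(s): {', '.join(missing)}")
    if "n_management" not in df.columns and not all(c in df.columns for c in MEASURE_COLUMNS):
        raise SchemaError(
            f"survey CSV {path} needs n_management or all of {', '.join(MEASURE_COLUMNS)}"
        )

    per_ent: dict[str, dict] = {}
    rejections: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            entry, management, controls = _row_to_parts(row)
            eid = str(row["enterprise_id"])
            ent = per_ent.setdefault(
                eid,
                {
                    "industry_code": str(row["industry_code"]),
                    "industry_name": str(row["industry_name"]),
                    "management": management,
                    "controls": controls,
                    "exposures": [],
                },
            )
            if ent["management"] != management or ent["controls"] != controls:
                raise ValidationError(
                    f"enterprise {eid!r}: management/control profile differs between rows"
                )
            ent["exposures"].append(entry)
        except (ValidationError, ValueError) as exc:
            if strict:
                raise ValidationError(f"{path} line {line}: {exc}") from exc
            log.warning("%s line %d rejected: %s", path, line, exc)
            rejections.append((line, str(exc)))

    records = [
        EnterpriseRecord(
            enterprise_id=eid,
            industry_code=ent["industry_code"],
            industry_name=ent["industry_name"],
            exposures=tuple(ent["exposures"]),
            management=ent["management"],
            controls=ent["controls"],
        )
        for eid, ent in per_ent.items()
    ]
    return SurveyTable(
        records=tuple(records),
        source=str(path),
        n_rows_read=len(df),
        rejections=tuple(rejections),
    )


def records_to_frame(records: Sequence[EnterpriseRecord]) -> pd.DataFrame:
    """Flatten enterprise records back to the one-row-per-chemical schema."""
    rows = []
    for rec in records:
        for entry in rec.exposures:
            a = entry.agent
            rows.append(
                {
                    "enterprise_id": rec.enterprise_id,
                    "industry_code": rec.industry_code,
                    "industry_name": rec.industry_name,
                    "chemical_name": a.name,
                    "cas": a.cas if a.cas is not None else "",
                    "oel_twa_ppm": a.oel_twa if a.oel_twa is not None else "",
                    "oel_ceiling_ppm": a.oel_ceiling if a.oel_ceiling is not None else "",
                    "carcinogen_no_oel": int(a.no_oel_or_carcinogen),
                    "exposure_minutes": entry.exposure_minutes,
                    "n_management": rec.management.n_measures,
                    "engineering_control": rec.controls.engineering.value,
                    "ppe": rec.controls.ppe.value,
                }
            )
    return pd.DataFrame(rows)


def write_survey_csv(table, path) -> None:
    """Write records (a SurveyTable or sequence of records) to the survey CSV schema."""
    records = table.records if isinstance(table, SurveyTable) else table
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineResult:
    scores: tuple[EnterpriseScore, ...]
    summaries: tuple[IndustrySummary, ...]
    priorities: PriorityAssignment
    report: dict


def run_pipeline(
    survey: SurveyTable,
    params: Optional[CalibrationParams] = None,
    scheme: Scheme = "corrected",
    statistic_kind: str = "p95",
) -> PipelineResult:
    """Score all enterprises, summarise industries and assign priorities.

    The report carries the mean/SD of the industry statistics, the band
    sizes and the percentile cutoffs.  The composition is deterministic
    and independent of record order.
    """
    if not survey.records:
        raise ValidationError("run_pipeline: no enterprises in survey")
    if params is None:
        params = default_corrected_params()
    records = sorted(survey.records, key=lambda r: r.enterprise_id)
    try:
        scores = tuple(score_enterprise(r, params, scheme) for r in records)
    except ValidationError as exc:
        raise ValidationError(f"scoring stage: {exc}") from exc
    try:
        summaries = tuple(summarize_industries(scores, records, statistic_kind))
    except ValidationError as exc:
        raise ValidationError(f"industry-summary stage: {exc}") from exc
    try:
        priorities = assign_priorities(summaries)
    except ValidationError as exc:
        raise ValidationError(f"prioritization stage: {exc}") from exc
    stats = [s.statistic for s in summaries]
    mean, sd = distribution_stats(stats) if len(stats) >= 2 else (float(stats[0]), float("nan"))
    report = {
        "n_enterprises": len(records),
        "n_industries": len(summaries),
        "statistic_kind": statistic_kind,
        "industry_statistic_mean": mean,
        "industry_statistic_sd": sd,
        "cutoffs": {"p90": priorities.cutoffs[0], "p70": priorities.cutoffs[1], "p50": priorities.cutoffs[2]},
        "band_sizes": list(priorities.band_sizes()),
    }
    return PipelineResult(scores=scores, summaries=summaries, priorities=priorities, report=report)


def scores_to_frame(result_or_scores, records: Optional[Sequence[EnterpriseRecord]] = None) -> pd.DataFrame:
    """Per-chemical score table (enterprise_id, industry_code, chemical, indices, ehi, ehi_total)."""
    scores = result_or_scores.scores if isinstance(result_or_scores, PipelineResult) else result_or_scores
    rows = []
    for score in scores:
        for sc in score.per_chemical:
            b = sc.indices
            rows.append(
                {
                    "enterprise_id": score.enterprise_id,
                    "industry_code": score.industry_code,
                    "chemical": sc.chemical,
                    "ti": b.ti,
                    "ei": b.ei,
                    "mi": b.mi,
                    "pi": b.pi,
                    "pdi": b.pdi,
                    "ehi": b.ehi,
                    "ehi_total": score.ehi_total,
                }
            )
        if not score.per_chemical:
            rows.append(
                {
                    "enterprise_id": score.enterprise_id,
                    "industry_code": score.industry_code,
                    "chemical": "",
                    "ti": np.nan, "ei": np.nan, "mi": np.nan,
                    "pi": np.nan, "pdi": np.nan, "ehi": np.nan,
                    "ehi_total": score.ehi_total,
                }
            )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: Sequence[IndustrySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "industry_code": s.industry_code,
                "industry_name": s.industry_name,
                "n_enterprises": s.n_enterprises,
                "statistic": s.statistic,
                "statistic_kind": s.statistic_kind,
            }
            for s in summaries
        ]
    )


def priorities_to_frame(priorities: PriorityAssignment) -> pd.DataFrame:
    return pd.DataFrame(
        [{"industry_code": code, "band": band} for code, band in sorted(priorities.bands.items())]
    )
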