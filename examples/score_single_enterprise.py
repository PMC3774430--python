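"""Score one enterprise with the corrected EHI model.

Builds a small plastics plant handling DMF and toluene, scores it with
the built-in corrected calibration, and prints the per-chemical index
values.  Each chemical's EHI is TI x EI x PDI; the enterprise score is
their sum (chemical effects are treated as additive).
"""

from ehi import (
    ChemicalAgent,
    ControlProfile,
    ExposureEntry,
    ManagementProfile,
    score_enterprise,
)
from ehi.scoring import EnterpriseRecord

record = EnterpriseRecord(
    enterprise_id="demo-001",
    industry_code="22",
    industry_name="Plastic products manufacturing",
    exposures=(
        ExposureEntry(ChemicalAgent("DMF", cas="68-12-2", oel_twa=10.0), exposure_minutes=225),
        ExposureEntry(ChemicalAgent("Toluene", cas="108-88-3", oel_twa=100.0), exposure_minutes=48),
    ),
    management=ManagementProfile(n_measures=2),     # e.g. MSDS + training
    controls=ControlProfile("EEp", "PPEe"),         # general ventilation, PPE provided
)

score = score_enterprise(record)
for sc in score.per_chemical:
    b = sc.indices
    print(f"{sc.chemical:10s} TI={b.ti:6.2f} EI={b.ei:.2f} MI={b.mi:.2f} "
          f"PI={b.pi:.2f} PDI={b.pdi:.2f} -> EHI={b.ehi:.2f}")
print(f"enterprise EHI total: {score.ehi_total:.2f}")
# TI doubles per tenfold drop in the OEL-TWA, so DMF (10 ppm) carries twice
# the toxicity weight of toluene (100 ppm); the 225-min DMF task dominates.
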