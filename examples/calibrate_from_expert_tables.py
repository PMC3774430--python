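"""Fit the corrected calibration from the embedded expert-rating tables.

Shows the three fitted pieces: the TI power-law scale constant K0, the
EI linear regression on exposure duration, and the MI/PI corrected
lookups, then round-trips the calibration through YAML.
"""

import tempfile
from pathlib import Path

from ehi import build_calibration, load_calibration, save_calibration
from ehi import reference as ref

params = build_calibration(
    ti_rows=ref.TI_CORRECTED_ROWS,
    ei_rows=[(r.predictor, r.mean) for r in ref.EI_EXPERT_ROWS],
    mi_rows=list(ref.MI_CORRECTED.items()),
    pi_rows=list(ref.PI_CORRECTED.items()),
)
print(f"TI scale constant K0 = {params.k0:.2f}  (TI = K0 * 2^(-log10 OEL))")
print(f"EI regression: EI = {params.ei_slope:.5f} * ED + {params.ei_intercept:.4f}, clamped to [0, 1]")
print(f"MI lookup: {params.mi_table}")
print(f"PI lookup: {params.pi_table}")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "calibration.yaml"
    save_calibration(params, path)
    assert load_calibration(path) == params
    print(f"YAML round-trip OK ({path.name})")
# K0 ~= 17.88: a chemical with OEL-TWA 1 ppm rates TI 17.88, 10 ppm rates
# half that (8.94), and so on, doubling per tenfold decrease in the OEL.
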