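"""Published reference tables of the EHI model.

Two data sets are embedded here:

* the expert-elicitation calibration tables from the seven-enterprise
  pilot survey (nine chemicals, seven exposure durations, the five
  management-measure counts and six control combinations), each with the
  original rating, the expert-panel mean +/- SD, and the corrected rating;
* the 25 manufacturing industries of the 2006-2009 Taiwanese national
  chemical-hazard survey, with surveyed-enterprise counts (total 702) and
  the published per-industry EHI_cor statistic (95th percentile of the
  enterprise scores).

The 2-digit industry codes are synthetic SIC-style labels assigned here
for bookkeeping; the survey publication identifies industries by name
only.  Everything else is as published.
"""

from __future__ import annotations

from .calibration import ExpertRatingRow

__all__ = [
    "TI_EXPERT_ROWS",
    "TI_CORRECTED_ROWS",
    "EI_EXPERT_ROWS",
    "EI_CORRECTED",
    "MI_EXPERT_ROWS",
    "MI_CORRECTED",
    "PI_EXPERT_ROWS",
    "PI_CORRECTED",
    "REFERENCE_CHEMICALS",
    "NATIONAL_INDUSTRIES",
]

# --- chemical toxicity block -------------------------------------------------
# (name, cas, oel_twa ppm, TI_original, TI_expert mean, sd, TI_corrected)
_TI_BLOCK = (
    ("Toluene diisocyanate (TDI)", "584-84-9", 0.005, 64.00, 86.31, 6.28, 88.10),
    ("Methylene bisphenyl isocyanate (MDI)", "101-68-8", 0.02, 32.00, 56.71, 4.34, 58.04),
    ("N,N-Dimethylformamide (DMF)", "68-12-2", 10.0, 8.00, 10.23, 1.03, 8.94),
    ("Ethylene glycol (EG)", "107-21-1", 50.0, 4.00, 4.52, 0.67, 5.51),
    ("Methylene chloride (MC)", "75-09-2", 50.0, 4.00, 4.52, 0.67, 5.51),
    ("Toluene", "108-88-3", 100.0, 4.00, 3.86, 0.37, 4.47),
    ("Methyl ethyl ketone (MEK)", "78-93-3", 200.0, 2.00, 3.09, 0.42, 3.63),
    ("Ethyl acetate (EAc)", "141-78-6", 400.0, 2.00, 2.91, 0.42, 2.94),
    ("Acetone", "67-64-1", 750.0, 2.00, 2.30, 0.36, 2.44),
)

#: Expert-panel TI ratings (mean +/- SD) keyed by OEL-TWA in ppm.
TI_EXPERT_ROWS = tuple(
    ExpertRatingRow(predictor=oel, mean=es, sd=sd) for _, _, oel, _, es, sd, _ in _TI_BLOCK
)

#: Published corrected TI ratings keyed by OEL-TWA in ppm.
TI_CORRECTED_ROWS = tuple((oel, cor) for _, _, oel, _, _, _, cor in _TI_BLOCK)

#: The nine pilot-survey chemicals as (name, cas, oel_twa ppm).
REFERENCE_CHEMICALS = tuple((name, cas, oel) for name, cas, oel, *_ in _TI_BLOCK)

# --- exposure-duration block -------------------------------------------------
# (ED minutes, EI_original, EI_expert mean, sd, EI_corrected)
_EI_BLOCK = (
    (10, 0.30, 0.02, 0.01, 0.02),
    (30, 0.30, 0.07, 0.02, 0.07),
    (40, 0.30, 0.09, 0.05, 0.10),
    (48, 0.30, 0.12, 0.05, 0.11),
    (75, 0.30, 0.14, 0.08, 0.18),
    (225, 0.60, 0.53, 0.11, 0.52),
    (250, 1.00, 0.60, 0.13, 0.58),
)

EI_EXPERT_ROWS = tuple(
    ExpertRatingRow(predictor=float(ed), mean=es, sd=sd) for ed, _, es, sd, _ in _EI_BLOCK
)

#: Published corrected EI ratings keyed by ED in minutes.
EI_CORRECTED = {ed: cor for ed, _, _, _, cor in _EI_BLOCK}

# --- management block --------------------------------------------------------
# (N, MI_original, MI_expert mean, sd, MI_corrected)
_MI_BLOCK = (
    (0, 0.00, 0.00, 0.00, 0.18),
    (1, 0.25, 0.38, 0.36, 0.39),
    (2, 0.50, 0.59, 0.06, 0.60),
    (3, 0.75, 0.82, 0.06, 0.81),
    (4, 1.00, 1.00, 0.00, 1.00),
)

MI_EXPERT_ROWS = tuple(
    ExpertRatingRow(predictor=n, mean=es, sd=sd) for n, _, es, sd, _ in _MI_BLOCK
)

#: Published corrected MI lookup, N -> rating.
MI_CORRECTED = {n: cor for n, _, _, _, cor in _MI_BLOCK}

# --- protection block --------------------------------------------------------
# (combo, PI_original, PI_expert mean, sd, PI_corrected)
_PI_BLOCK = (
    ("EEn+PPEn", 0.00, 0.00, 0.00, 0.00),
    ("EEn+PPEe", 0.20, 0.18, 0.06, 0.18),
    ("EEp+PPEn", 0.30, 0.42, 0.03, 0.42),
    ("EEp+PPEe", 0.50, 0.61, 0.12, 0.61),
    ("EEe+PPEn", 0.80, 0.74, 0.04, 0.74),
    ("EEe+PPEe", 1.00, 1.00, 0.00, 1.00),
)

PI_EXPERT_ROWS = tuple(
    ExpertRatingRow(predictor=combo, mean=es, sd=sd) for combo, _, es, sd, _ in _PI_BLOCK
)

#: Published corrected PI lookup, combination label -> rating.
PI_CORRECTED = {combo: cor for combo, _, _, _, cor in _PI_BLOCK}

# --- national survey industries ----------------------------------------------
#: (code, name, n surveyed enterprises, published EHI_cor statistic).
#: Codes are synthetic SIC-style 2-digit labels; n sums to 702.
NATIONAL_INDUSTRIES = (
    ("22", "Plastic products manufacturing", 37, 43.47),
    ("17", "Petroleum products manufacturing", 7, 35.54),
    ("25", "Metal products manufacturing", 137, 33.17),
    ("31", "Transportation manufacturing", 17, 31.32),
    ("28", "Electrical equipment manufacturing", 22, 27.23),
    ("26", "Electronic components manufacturing", 34, 23.46),
    ("18", "Chemical materials manufacturing", 94, 21.66),
    ("15", "Paper products manufacturing", 17, 21.44),
    ("24", "Metalworking manufacturing", 49, 17.29),
    ("19", "Chemical products manufacturing", 16, 14.06),
    ("23", "Non-metallic mineral products manufacturing", 15, 12.58),
    ("13", "Leather products manufacturing", 9, 12.03),
    ("27", "Electronic products manufacturing", 30, 10.41),
    ("14", "Wood products manufacturing", 5, 10.16),
    ("16", "Printing and data storage products manufacturing", 20, 9.41),
    ("20", "Drug manufacturing", 5, 8.94),
    ("11", "Textile industrial", 15, 8.21),
    ("08", "Foods manufacturing", 50, 7.54),
    ("29", "Machinery and equipment manufacturing", 74, 5.71),
    ("32", "Furniture manufacturing", 10, 5.10),
    ("30", "Automotive manufacturing", 17, 2.48),
    ("34", "Machinery and equipment maintenance industry", 3, 2.28),
    ("21", "Rubber products manufacturing", 13, 1.33),
    ("09", "Beverage manufacturing", 3, 1.22),
    ("12", "Clothing products manufacturing", 3, 0.82),
)
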