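"""Published summary counts from the 112-patient derivation cohort.

The score was derived from a retrospective opportunistic colorectal cancer
screening cohort (112 adults aged 40-88, single urban primary-care centre).
Per-patient data were never released; these cell counts, transcribed from
the published summary tables, are the complete printed evidence and drive
both the pseudo-cohort reconstruction and the reproduction checks.
"""

from __future__ import annotations

COHORT_N = 112

#: Risk band (four-band scheme) -> (FOBT-positive, FOBT-negative) counts.
BAND_FOBT_COUNTS: dict[str, tuple[int, int]] = {
    "0-3": (3, 28),
    "4": (2, 18),
    "5": (7, 34),
    ">=6": (8, 12),
}

#: Published per-band positivity, percent, as printed (2 decimals).
BAND_POS_RATES_PCT: dict[str, float] = {
    "0-3": 9.68,
    "4": 10.00,
    "5": 17.07,
    ">=6": 40.00,
}

#: Three-band positivity as printed (low = 0-3, medium = 4-5, high = 6-7).
THREE_BAND_POS_RATES_PCT: dict[str, float] = {
    "low": 9.68,
    "medium": 14.75,
    "high": 40.00,
}

TOTAL_POSITIVES = 20

#: Gender counts (males, females).
N_MALE, N_FEMALE = 51, 61

#: BMI class -> (FOBT-positive, FOBT-negative) counts.
BMI_FOBT_COUNTS: dict[str, tuple[int, int]] = {
    "underweight": (0, 1),
    "normal": (4, 15),
    "overweight": (8, 46),
    "obese_I": (6, 24),
    "obese_II": (0, 5),
    "obese_III": (2, 1),
}

#: (gender, n_comorbidities) -> (FOBT-positive, FOBT-negative) counts.
GENDER_COMORBIDITY_FOBT_COUNTS: dict[tuple[str, int], tuple[int, int]] = {
    ("female", 0): (1, 9),
    ("female", 1): (2, 14),
    ("female", 2): (4, 19),
    ("female", 3): (2, 10),
    ("male", 0): (0, 9),
    ("male", 1): (2, 6),
    ("male", 2): (7, 21),
    ("male", 3): (2, 4),
}

#: Cohort-wide comorbidity totals.
COMORBIDITY_TOTALS: dict[str, int] = {"dm": 25, "dysl": 77, "hta": 78}

#: Patients with none of the three comorbidities.
N_ZERO_COMORBIDITY = 19

#: Comorbidity counts split by gender (male, female).
COMORBIDITY_BY_GENDER: dict[str, tuple[int, int]] = {
    "dm": (11, 14),
    "dysl": (37, 40),
    "hta": (34, 44),
}

#: Age-range class counts for the whole cohort.
AGE_CLASS_COUNTS: dict[str, int] = {"40-49": 8, "50-59": 26, "60-69": 38, ">=70": 40}

#: Current smokers by gender (male, female).
SMOKERS_BY_GENDER: tuple[int, int] = (11, 9)

#: FOBT-positive patients by (age class, BMI class, gender); cells absent
#: from the published breakdown are zero. Totals 20 and its margins agree
#: with BMI_FOBT_COUNTS.
POSITIVES_BY_AGE_BMI_GENDER: dict[tuple[str, str, str], int] = {
    ("40-49", "overweight", "female"): 1,
    ("50-59", "normal", "female"): 1,
    ("50-59", "overweight", "male"): 1,
    ("50-59", "obese_III", "male"): 1,
    ("60-69", "normal", "female"): 1,
    ("60-69", "normal", "male"): 1,
    ("60-69", "overweight", "female"): 2,
    ("60-69", "overweight", "male"): 1,
    ("60-69", "obese_I", "female"): 1,
    ("60-69", "obese_I", "male"): 4,
    (">=70", "normal", "male"): 1,
    (">=70", "overweight", "female"): 3,
    (">=70", "obese_I", "male"): 1,
    (">=70", "obese_III", "female"): 1,
}

#: Patients with a given comorbidity by (BMI class, comorbidity, FOBT
#: result, gender); cells absent from the published breakdown are zero.
COMORBIDITY_BY_BMI_FOBT_GENDER: dict[tuple[str, str, str, str], int] = {
    ("underweight", "hta", "negative", "female"): 1,
    ("normal", "dm", "positive", "male"): 1,
    ("normal", "dm", "negative", "male"): 1,
    ("normal", "dm", "negative", "female"): 2,
    ("normal", "dysl", "positive", "male"): 2,
    ("normal", "dysl", "negative", "male"): 2,
    ("normal", "dysl", "negative", "female"): 6,
    ("normal", "hta", "positive", "male"): 2,
    ("normal", "hta", "positive", "female"): 1,
    ("normal", "hta", "negative", "male"): 3,
    ("normal", "hta", "negative", "female"): 7,
    ("overweight", "dm", "positive", "female"): 1,
    ("overweight", "dm", "negative", "male"): 3,
    ("overweight", "dm", "negative", "female"): 4,
    ("overweight", "dysl", "positive", "male"): 2,
    ("overweight", "dysl", "positive", "female"): 5,
    ("overweight", "dysl", "negative", "male"): 17,
    ("overweight", "dysl", "negative", "female"): 13,
    ("overweight", "hta", "positive", "male"): 2,
    ("overweight", "hta", "positive", "female"): 4,
    ("overweight", "hta", "negative", "male"): 15,
    ("overweight", "hta", "negative", "female"): 13,
    ("obese_I", "dm", "positive", "male"): 3,
    ("obese_I", "dm", "negative", "male"): 3,
    ("obese_I", "dm", "negative", "female"): 4,
    ("obese_I", "dysl", "positive", "male"): 5,
    ("obese_I", "dysl", "positive", "female"): 1,
    ("obese_I", "dysl", "negative", "male"): 6,
    ("obese_I", "dysl", "negative", "female"): 10,
    ("obese_I", "hta", "positive", "male"): 3,
    ("obese_I", "hta", "positive", "female"): 1,
    ("obese_I", "hta", "negative", "male"): 6,
    ("obese_I", "hta", "negative", "female"): 12,
    ("obese_II", "dm", "negative", "female"): 2,
    ("obese_II", "dysl", "negative", "male"): 1,
    ("obese_II", "dysl", "negative", "female"): 4,
    ("obese_II", "hta", "negative", "male"): 1,
    ("obese_II", "hta", "negative", "female"): 4,
    ("obese_III", "dm", "positive", "female"): 1,
    ("obese_III", "dysl", "positive", "male"): 1,
    ("obese_III", "dysl", "positive", "female"): 1,
    ("obese_III", "dysl", "negative", "male"): 1,
    ("obese_III", "hta", "positive", "male"): 1,
    ("obese_III", "hta", "positive", "female"): 1,
    ("obese_III", "hta", "negative", "male"): 1,
}

#: Published whole-cohort descriptive values used by the reproduction check.
PUBLISHED_SUMMARY = {
    "t_value": -3.49663,
    "p_one_tailed": 0.00644,
    "positives_pct": 17.86,
    "female_pct": 54.46,
    "overweight_pct": 48.21,
    "obese_pct": 33.93,
    "any_comorbidity_pct": 83.03,
}

#: Age and BMI descriptive blocks as published (whole cohort). The raw
#: per-patient values behind them were not released, so these are context
#: for the generator defaults rather than reconstruction targets.
AGE_SUMMARY = {
    "mean": 65.3,
    "median": 66.5,
    "mode": 67,
    "sd": 11,
    "skewness": -0.27,
    "min": 40,
    "max": 88,
    "count": 112,
    "confidence_level_95": 2.07,
}
BMI_SUMMARY = {
    "mean": 28.46,
    "median": 27.90,
    "mode": 26.30,
    "sd": 4.66,
    "skewness": 0.31,
    "min": 17.60,
    "max": 41.20,
    "count": 112,
    "confidence_level_95": 0.87,
}
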